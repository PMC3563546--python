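"""Pre-correction data checks and the post-correction average-labeling report.

Checks run on the raw table before any correction and produce a flag mask with
the same shape as the data, so the feedback can be overlaid on the input in a
spreadsheet.  Any flagged cell normally terminates the run before correction;
the CLI's ``--force`` overrides that.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .io_tabular import RawTable
from .model import MDV, Dataset

__all__ = [
    "QCMask",
    "check_missing",
    "check_intensity_bounds",
    "check_retention_times",
    "run_checks",
    "average_labeling",
    "summarize_labeling",
    "LabelingReport",
]

_OK = "ok"


@dataclass
class QCMask:
    """Per-cell flag matrix mirroring the checked table's layout."""

    table: RawTable
    flags: List[List[str]]

    @classmethod
    def clean(cls, table: RawTable) -> "QCMask":
        return cls(table, [[_OK] * table.n_chromatograms for _ in table.rows])

    @property
    def n_flagged(self) -> int:
        return sum(f != _OK for row in self.flags for f in row)

    def merge(self, other: "QCMask") -> "QCMask":
        """Overlay another mask; earlier flags win per cell."""
        merged = [
            [a if a != _OK else b for a, b in zip(ra, rb)]
            for ra, rb in zip(self.flags, other.flags)
        ]
        return QCMask(self.table, merged)


def check_missing(raw: RawTable) -> QCMask:
    """Flag empty and non-numeric cells as ``missing``."""
    mask = QCMask.clean(raw)
    for i, row in enumerate(raw.rows):
        for j, cell in enumerate(row.cells):
            try:
                float(cell)
            except ValueError:
                mask.flags[i][j] = "missing"
    return mask


def check_intensity_bounds(raw: RawTable, lo: float, hi: float) -> QCMask:
    """Flag intensities outside the linear detector range [lo, hi].

    Applied to every row, boundary masses included.  Non-numeric cells are
    left to the missing-value check.
    """
    mask = QCMask.clean(raw)
    values = raw.float_matrix()
    for i in range(values.shape[0]):
        for j in range(values.shape[1]):
            v = values[i, j]
            if np.isnan(v):
                continue
            if v < lo:
                mask.flags[i][j] = "below-min"
            elif v > hi:
                mask.flags[i][j] = "above-max"
    return mask


def check_retention_times(
    rt: RawTable, k: float, pooled: bool = False
) -> QCMask:
    """Flag retention times deviating more than ``k`` standard deviations.

    By default the mean and SD are computed per fragment row across all
    chromatograms (a pooled statistic would mix analytes with different
    retention times); ``pooled=True`` pools every cell of the table instead.
    A single-chromatogram table has no SD, so the check is skipped with a
    warning.
    """
    mask = QCMask.clean(rt)
    values = rt.float_matrix()
    if values.shape[1] < 2 and not pooled:
        warnings.warn("retention-time check skipped: need >= 2 chromatograms")
        return mask
    if pooled:
        flat = values[~np.isnan(values)]
        if flat.size < 2:
            warnings.warn("retention-time check skipped: not enough values")
            return mask
        mean = np.full(values.shape[0], flat.mean())
        sd = np.full(values.shape[0], flat.std(ddof=1))
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean = np.nanmean(values, axis=1)
            sd = np.nanstd(values, axis=1, ddof=1)
    for i in range(values.shape[0]):
        if np.isnan(sd[i]) or sd[i] == 0.0:
            continue
        for j in range(values.shape[1]):
            v = values[i, j]
            if not np.isnan(v) and abs(v - mean[i]) > k * sd[i]:
                mask.flags[i][j] = "rt-outlier"
    return mask


def run_checks(
    raw: RawTable,
    config,
    rt_table: RawTable | None = None,
) -> Tuple[QCMask, QCMask | None]:
    """Run the checks selected in the configuration.

    Returns the merged mask over the measurement table and, when a
    retention-time table was checked, a second mask in that table's layout
    (retention times live in their own file: one data type per file).
    """
    mask = QCMask.clean(raw)
    if "missing" in config.checks:
        mask = mask.merge(check_missing(raw))
    if "intensity" in config.checks:
        mask = mask.merge(
            check_intensity_bounds(raw, config.intensity_min, config.intensity_max)
        )
    rt_mask = None
    if "retention_time" in config.checks and rt_table is not None:
        rt_mask = check_retention_times(
            rt_table, config.rt_sd_multiplier, pooled=config.rt_pooled
        )
    return mask, rt_mask


def average_labeling(mdv: MDV) -> float:
    """Fractional enrichment of one MDV: sum_i i*m_i / (numC * sum_i m_i).

    0 for a fully unlabeled and 1 for a fully labeled fragment; invariant
    under scaling of the vector.
    """
    m = np.asarray(mdv.values, dtype=float)
    total = m.sum()
    if total == 0:
        raise ValueError(f"{mdv.fragment.fragment_id}: all-zero MDV")
    weights = np.arange(len(m))
    return float((weights * m).sum() / (mdv.fragment.num_c * total))


@dataclass
class LabelingReport:
    """Average labeling per MDV, per chromatogram, per replicate group, overall."""

    per_mdv: pd.DataFrame  # fragments x chromatograms
    per_chromatogram: pd.Series
    per_group: pd.Series
    overall: float

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# average labeling per MDV\n")
            self.per_mdv.to_csv(fh, sep="\t")
            fh.write("# average labeling per chromatogram\n")
            self.per_chromatogram.to_csv(fh, sep="\t", header=["labeling"])
            fh.write("# average labeling per replicate group\n")
            self.per_group.to_csv(fh, sep="\t", header=["labeling"])
            fh.write(f"# overall\t{self.overall!r}\n")


def summarize_labeling(
    dataset: Dataset, groups: Sequence[Tuple[str, Sequence[int]]]
) -> LabelingReport:
    """Average-labeling diagnostic over a corrected dataset.

    Chromatogram, group and overall values are unweighted means over MDVs
    (corrected MDVs are normalized, so intensity weighting is meaningless).
    Run on labeled and unlabeled samples alike, this exposes contaminated
    MDVs, analytes or chromatograms.
    """
    data = {}
    index = [fd.fragment.fragment_id for fd in dataset.fragments]
    for j, cid in enumerate(dataset.chromatogram_ids):
        data[cid] = [
            average_labeling(fd.mdv(j, is_fraction=dataset.is_fraction))
            for fd in dataset.fragments
        ]
    per_mdv = pd.DataFrame(data, index=index)
    per_chrom = per_mdv.mean(axis=0)
    per_group = pd.Series(
        {name: per_chrom.iloc[list(cols)].mean() for name, cols in groups},
        dtype=float,
    )
    return LabelingReport(per_mdv, per_chrom, per_group, float(per_mdv.values.mean()))
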