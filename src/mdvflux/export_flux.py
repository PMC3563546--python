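"""Replicate aggregation and writers for flux-software measurement formats.

Biological replicates occupy consecutive chromatogram columns, in the same
order as the group sizes given in the configuration.  Per replicate group the
corrected fractions are averaged mass by mass; a single-replicate group gets a
default deviation of 0.05 at every mass so that downstream flux software that
requires an error value can still consume the data.

Writers cover the 13CFLUX FTBL measurement sections (MASS_SPECTROMETRY and
LABEL_MEASUREMENTS) and a simple OpenFLUX-style CSV.  Values are written as
fractions (0-1); percent scaling is only for human-readable TSV output.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .model import Dataset

log = logging.getLogger(__name__)

__all__ = [
    "ReplicateSummary",
    "DEFAULT_DEVIATION",
    "make_groups",
    "replicate_stats",
    "write_ftbl_ms",
    "write_openflux_csv",
    "write_summary_tsv",
]

#: Deviation substituted when a group has a single replicate.
DEFAULT_DEVIATION = 0.05


@dataclass
class ReplicateSummary:
    """Mean and deviation of one replicate group's corrected fractions.

    ``means[fragment_id]`` and ``deviations[fragment_id]`` are vectors over
    the masses M+0 .. M+numC; means sum to 1 per fragment.
    """

    group_id: str
    n: int
    fragment_ids: List[str]
    analyte_ids: Dict[str, str]
    num_c: Dict[str, int]
    means: Dict[str, np.ndarray]
    deviations: Dict[str, np.ndarray]


def make_groups(
    sizes: Sequence[int], names: Optional[Sequence[str]] = None
) -> List[Tuple[str, List[int]]]:
    """Turn consecutive group sizes into (name, column-indices) pairs.

    Generic names ``group1..groupN`` are used when no identifier list is
    supplied.
    """
    if names is not None and len(names) != len(sizes):
        raise ValueError(
            f"{len(names)} group names given for {len(sizes)} groups"
        )
    groups = []
    start = 0
    for g, size in enumerate(sizes):
        name = names[g] if names is not None else f"group{g + 1}"
        groups.append((name, list(range(start, start + size))))
        start += size
    return groups


def replicate_stats(
    dataset: Dataset, groups: Sequence[Tuple[str, Sequence[int]]]
) -> List[ReplicateSummary]:
    """Per-mass mean and sample standard deviation over each replicate group.

    Groups of one replicate get the default deviation (0.05) at every mass.
    The dataset must already be corrected and normalized to fractions.
    """
    if not dataset.is_fraction:
        raise ValueError("replicate_stats needs corrected, normalized data")
    out = []
    for name, cols in groups:
        cols = list(cols)
        means, devs = {}, {}
        frag_ids, analytes, num_c = [], {}, {}
        for fd in dataset.fragments:
            fid = fd.fragment.fragment_id
            block = fd.values[:, cols]
            mean = block.mean(axis=1)
            # renormalize: means of normalized columns already sum to 1
            if len(cols) == 1:
                dev = np.full(fd.fragment.n_masses, DEFAULT_DEVIATION)
            else:
                dev = block.std(axis=1, ddof=1)
            frag_ids.append(fid)
            analytes[fid] = fd.fragment.analyte_id
            num_c[fid] = fd.fragment.num_c
            means[fid] = mean
            devs[fid] = dev
        out.append(
            ReplicateSummary(name, len(cols), frag_ids, analytes, num_c, means, devs)
        )
    return out


# ---------------------------------------------------------------------------
# FTBL (13CFLUX measurement sections)

def _ftbl_ms_lines(summary: ReplicateSummary) -> List[str]:
    """MASS_SPECTROMETRY rows: META_NAME, FRAGMENT, WEIGHT, VALUE, DEVIATION.

    Tab-indented table rows; the metabolite name and fragment spec appear only
    on the first row of each fragment (double-tab continuation rows).
    """
    lines = [
        "MASS_SPECTROMETRY",
        "\tMETA_NAME\tFRAGMENT\tWEIGHT\tVALUE\tDEVIATION",
    ]
    for fid in summary.fragment_ids:
        frag_spec = ",".join(str(i + 1) for i in range(summary.num_c[fid]))
        for w in range(summary.num_c[fid] + 1):
            head = (
                f"\t{summary.analyte_ids[fid]}\t{frag_spec}"
                if w == 0
                else "\t\t"
            )
            lines.append(
                f"{head}\t{w}\t{summary.means[fid][w]:.6f}"
                f"\t{summary.deviations[fid][w]:.6f}"
            )
    return lines


def _ftbl_label_lines(summary: ReplicateSummary) -> List[str]:
    """LABEL_MEASUREMENTS rows: META_NAME, CUM_GROUP, VALUE, DEVIATION."""
    lines = [
        "LABEL_MEASUREMENTS",
        "\tMETA_NAME\tCUM_GROUP\tVALUE\tDEVIATION",
    ]
    for fid in summary.fragment_ids:
        for w in range(summary.num_c[fid] + 1):
            head = f"\t{summary.analyte_ids[fid]}" if w == 0 else "\t"
            lines.append(
                f"{head}\t{w + 1}\t{summary.means[fid][w]:.6f}"
                f"\t{summary.deviations[fid][w]:.6f}"
            )
    return lines


_SECTION_OF = {
    "mass-spectrometry": ("MASS_SPECTROMETRY", _ftbl_ms_lines),
    "label-measurements": ("LABEL_MEASUREMENTS", _ftbl_label_lines),
}


def _inject_into_model(model_text: str, header: str, rows: List[str]) -> str:
    """Append measurement rows to an existing FTBL section of a model file.

    Rows are inserted at the end of the section (before the next top-level
    section header); every other line is preserved byte for byte.
    """
    lines = model_text.splitlines()
    try:
        start = next(i for i, ln in enumerate(lines) if ln.strip() == header)
    except StopIteration:
        raise ValueError(f"model file has no {header} section") from None
    end = start + 1
    while end < len(lines) and (not lines[end] or lines[end][0] in "\t "):
        end += 1
    return "\n".join(lines[:end] + rows + lines[end:]) + "\n"


def write_ftbl_ms(
    summaries: Sequence[ReplicateSummary],
    out_dir: str | Path,
    section: str = "mass-spectrometry",
    model_file: Optional[str | Path] = None,
) -> List[Path]:
    """Write FTBL measurement sections, one file per replicate group.

    With ``model_file`` the rows are instead appended to that model's existing
    section, producing one injected copy of the model per group.
    """
    if section not in _SECTION_OF:
        raise ValueError(f"unknown FTBL section {section!r}")
    header, render = _SECTION_OF[section]
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for summary in summaries:
        lines = render(summary)
        if model_file is not None:
            text = _inject_into_model(
                Path(model_file).read_text(), header, lines[2:]
            )
            path = out_dir / f"{summary.group_id}_{Path(model_file).name}"
        else:
            text = "\n".join(lines) + "\n"
            suffix = "ms" if section == "mass-spectrometry" else "label"
            path = out_dir / f"{summary.group_id}_{suffix}.ftbl"
        path.write_text(text)
        written.append(path)
    return written


def write_openflux_csv(
    summaries: Sequence[ReplicateSummary], out_dir: str | Path
) -> List[Path]:
    """Write corrected means/deviations as OpenFLUX-style CSV, one file per group.

    Dialect (documented here, not fixed by any upstream source): one row per
    mass isotopomer, columns ``fragment,weight,mean,stdev``, fractions in
    0-1, comma separated, no header beyond the first line.
    """
    out_dir = Path(out_dir)
    written = []
    for summary in summaries:
        if not summary.fragment_ids:
            warnings.warn(f"group {summary.group_id}: empty dataset, no file written")
            continue
        out_dir.mkdir(parents=True, exist_ok=True)
        rows = ["fragment,weight,mean,stdev"]
        for fid in summary.fragment_ids:
            for w in range(summary.num_c[fid] + 1):
                rows.append(
                    f"{fid},{w},{summary.means[fid][w]:.6f},"
                    f"{summary.deviations[fid][w]:.6f}"
                )
        path = out_dir / f"{summary.group_id}_openflux.csv"
        path.write_text("\n".join(rows) + "\n")
        written.append(path)
    return written


def write_summary_tsv(
    summaries: Sequence[ReplicateSummary], path: str | Path
) -> None:
    """Human-readable TSV of group means and deviations, in percent."""
    lines = ["group\tfragment\tmass\tmean_percent\tdeviation_percent\tn"]
    for summary in summaries:
        for fid in summary.fragment_ids:
            for w in range(summary.num_c[fid] + 1):
                lines.append(
                    f"{summary.group_id}\t{fid}\tM+{w}"
                    f"\t{100 * summary.means[fid][w]:.4f}"
                    f"\t{100 * summary.deviations[fid][w]:.4f}\t{summary.n}"
                )
    Path(path).write_text("\n".join(lines) + "\n")
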