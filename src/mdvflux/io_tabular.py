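"""Reading and writing the tab-separated matrix dialect, and fragment assembly.

The standard layout is a plain TSV matrix: the first column holds analyte
identifiers, the second the nominal mass of each mass isotopomer, and every
further column the measurements of one chromatogram.  The first file row is an
optional title, the second carries the chromatogram identifiers.  One file
holds exactly one type of data (intensities, retention times, ...), so the
same reader serves them all.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .isotopes import ConfigurationError, ElementIsotopeTable, default_isotope_table
from .model import Dataset, FragmentData, FragmentDefinition, parse_formula

log = logging.getLogger(__name__)

__all__ = [
    "RawTable",
    "Row",
    "RunConfig",
    "AssemblyFeedback",
    "read_measurement_table",
    "write_raw_table",
    "write_feedback_mask",
    "write_dataset",
    "assemble_fragments",
    "read_config",
    "read_obm_table",
    "read_replicate_names",
    "read_fragment_library",
    "read_isotope_table",
]


class ParseError(ValueError):
    """A malformed input file; the message names the offending row."""


@dataclass
class Row:
    analyte_id: str
    mass: int
    cells: List[str]  # raw text, one per chromatogram; empty string = missing


@dataclass
class RawTable:
    """A measurement matrix exactly as read from file (cells kept as text)."""

    chromatogram_ids: List[str]
    rows: List[Row]
    title: str = ""

    @property
    def n_chromatograms(self) -> int:
        return len(self.chromatogram_ids)

    def float_matrix(self) -> np.ndarray:
        """All cells as floats; missing/non-numeric cells become NaN."""
        out = np.full((len(self.rows), self.n_chromatograms), np.nan)
        for i, row in enumerate(self.rows):
            for j, cell in enumerate(row.cells):
                try:
                    out[i, j] = float(cell)
                except ValueError:
                    pass
        return out


def _is_data_row(cells: Sequence[str]) -> bool:
    if len(cells) < 2 or not cells[0].strip():
        return False
    try:
        int(cells[1])
    except ValueError:
        return False
    return True


def read_measurement_table(path: str | Path) -> RawTable:
    """Read a TSV matrix (measurements, retention times, ...).

    The title row is optional: when the second file row already looks like a
    data row (analyte id + integer mass), the first row is taken as the
    chromatogram-identifier row and the title is empty.
    """
    lines = Path(path).read_text().splitlines()
    grid = [line.split("\t") for line in lines if line.strip("\t ") != ""]
    if len(grid) < 2:
        raise ParseError(f"{path}: need at least a header row and one data row")
    if _is_data_row(grid[1]):
        title, header, data = "", grid[0], grid[1:]
    else:
        title, header, data = grid[0][0].strip(), grid[1], grid[2:]
    chrom_ids = [c.strip() for c in header[2:]]
    if not chrom_ids:
        raise ParseError(f"{path}: no chromatogram columns in the header row")
    rows: List[Row] = []
    for k, cells in enumerate(data):
        rownum = k + (2 if title or not _is_data_row(grid[1]) else 1) + 1
        if len(cells) != 2 + len(chrom_ids):
            raise ParseError(
                f"{path}: row {rownum} has {len(cells)} cells, "
                f"expected {2 + len(chrom_ids)}"
            )
        try:
            mass = int(cells[1])
        except ValueError:
            raise ParseError(f"{path}: row {rownum}: mass {cells[1]!r} not an integer")
        rows.append(Row(cells[0].strip(), mass, [c.strip() for c in cells[2:]]))
    return RawTable(chrom_ids, rows, title)


def write_raw_table(table: RawTable, path: str | Path) -> None:
    width = 2 + table.n_chromatograms
    out = []
    out.append("\t".join([table.title] + [""] * (width - 1)))
    out.append("\t".join(["", ""] + table.chromatogram_ids))
    for row in table.rows:
        out.append("\t".join([row.analyte_id, str(row.mass)] + list(row.cells)))
    Path(path).write_text("\n".join(out) + "\n")


def write_feedback_mask(mask, path: str | Path) -> None:
    """Write a QC mask as a TSV overlay: flagged cells carry the flag code,
    clean cells are empty, layout identical to the checked table."""
    table = mask.table
    out = [
        "\t".join([table.title] + [""] * (1 + table.n_chromatograms)),
        "\t".join(["", ""] + table.chromatogram_ids),
    ]
    for i, row in enumerate(table.rows):
        cells = ["" if f == "ok" else f for f in mask.flags[i]]
        out.append("\t".join([row.analyte_id, str(row.mass)] + cells))
    Path(path).write_text("\n".join(out) + "\n")


def write_dataset(dataset: Dataset, path: str | Path, percent: bool = True) -> None:
    """Write corrected fractions in the standard layout (percent by default)."""
    scale = 100.0 if (percent and dataset.is_fraction) else 1.0
    rows: List[Row] = []
    for fd in dataset.fragments:
        for k in range(fd.fragment.n_masses):
            cells = [repr(float(v * scale)) for v in fd.values[k]]
            rows.append(Row(fd.fragment.analyte_id, fd.fragment.base_mass + k, cells))
    write_raw_table(RawTable(list(dataset.chromatogram_ids), rows, ""), path)


# ---------------------------------------------------------------------------
# configuration

_CORRECTIONS = ("proton_loss", "proton_gain", "na", "obm")
_CHECKS = ("missing", "intensity", "retention_time")
_FORMATS = ("tsv", "ftbl_ms", "ftbl_label", "openflux")

_KNOWN_KEYS = {
    "corrections", "checks", "intensity_min", "intensity_max",
    "rt_sd_multiplier", "rt_pooled", "leading_boundary", "trailing_boundary",
    "replicate_groups", "output_formats", "tracer_element", "data_file",
    "rt_file", "obm_file", "group_names_file", "fragments_file",
    "isotope_table_file", "ftbl_model_file",
}


@dataclass
class RunConfig:
    """All run options, parsed from a flat ``key = value`` file.

    ``corrections`` is ordered: corrections are applied exactly in the order
    they are listed.
    """

    corrections: List[str] = field(default_factory=list)
    checks: List[str] = field(default_factory=lambda: ["missing"])
    intensity_min: float = 0.0
    intensity_max: float = float("inf")
    rt_sd_multiplier: float = 3.0
    rt_pooled: bool = False
    leading_boundary: int = 0
    trailing_boundary: int = 0
    replicate_groups: List[int] = field(default_factory=list)
    output_formats: List[str] = field(default_factory=lambda: ["tsv"])
    tracer_element: str = "C"
    data_file: Optional[str] = None
    rt_file: Optional[str] = None
    obm_file: Optional[str] = None
    group_names_file: Optional[str] = None
    fragments_file: Optional[str] = None
    isotope_table_file: Optional[str] = None
    ftbl_model_file: Optional[str] = None

    def __post_init__(self) -> None:
        for c in self.corrections:
            if c not in _CORRECTIONS:
                raise ConfigurationError(f"unknown correction {c!r}")
        for c in self.checks:
            if c not in _CHECKS:
                raise ConfigurationError(f"unknown check {c!r}")
        for f in self.output_formats:
            if f not in _FORMATS:
                raise ConfigurationError(f"unknown output format {f!r}")
        if self.leading_boundary < 0 or self.trailing_boundary < 0:
            raise ConfigurationError("boundary counts must be >= 0")
        if any(g < 1 for g in self.replicate_groups):
            raise ConfigurationError("replicate group sizes must be >= 1")

    def groups_for(self, n_chromatograms: int) -> List[int]:
        """Replicate group sizes; empty spec means every chromatogram alone."""
        if not self.replicate_groups:
            return [1] * n_chromatograms
        if sum(self.replicate_groups) != n_chromatograms:
            raise ConfigurationError(
                f"replicate group sizes sum to {sum(self.replicate_groups)}, "
                f"but there are {n_chromatograms} chromatograms"
            )
        return list(self.replicate_groups)


def _norm_token(tok: str) -> str:
    return tok.strip().lower().replace("-", "_").replace(" ", "_")


def read_config(path: str | Path) -> RunConfig:
    """Parse the flat key/value configuration file.

    Unknown keys produce a warning (not an error) to tolerate dialect drift;
    list values are comma-separated and order-preserving.
    """
    kv: Dict[str, str] = {}
    for n, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ParseError(f"{path}: line {n}: expected 'key = value'")
        key, _, val = line.partition("=")
        kv[_norm_token(key)] = val.strip()

    kwargs: Dict[str, object] = {}
    for key, val in kv.items():
        if key not in _KNOWN_KEYS:
            warnings.warn(f"{path}: unknown configuration key {key!r} ignored")
            continue
        if key in ("corrections", "checks", "output_formats"):
            kwargs[key] = [_norm_token(t) for t in val.split(",") if t.strip()]
        elif key == "replicate_groups":
            kwargs[key] = [int(t) for t in val.split(",") if t.strip()]
        elif key in ("intensity_min", "intensity_max", "rt_sd_multiplier"):
            kwargs[key] = float(val)
        elif key in ("leading_boundary", "trailing_boundary"):
            kwargs[key] = int(val)
        elif key == "rt_pooled":
            kwargs[key] = _norm_token(val) in ("1", "true", "yes", "on")
        else:
            kwargs[key] = val
    if "data_file" not in kwargs:
        raise ConfigurationError(f"{path}: mandatory key 'data_file' missing")
    return RunConfig(**kwargs)


def read_obm_table(path: str | Path) -> Dict[str, float]:
    """Read the original-biomass table: ``chromatogram-id <tab> fraction``."""
    out: Dict[str, float] = {}
    for n, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ParseError(f"{path}: line {n}: expected 'id<TAB>fraction'")
        frac = float(parts[1])
        if not (0.0 <= frac <= 1.0):
            raise ConfigurationError(
                f"{path}: line {n}: OBM fraction {frac} outside [0, 1]"
            )
        out[parts[0].strip()] = frac
    return out


def read_replicate_names(path: str | Path) -> List[str]:
    """One replicate-group name per line."""
    return [
        line.strip()
        for line in Path(path).read_text().splitlines()
        if line.strip() and not line.startswith("#")
    ]


def read_fragment_library(path: str | Path) -> List[FragmentDefinition]:
    """Fragment library TSV: analyte_id, fragment_id, formula, numC, base_mass
    and an optional tracer-element column (default C)."""
    frags: List[FragmentDefinition] = []
    for n, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        parts = [p.strip() for p in line.split("\t")]
        if parts[0].lower() == "analyte_id":  # header row
            continue
        if len(parts) not in (5, 6):
            raise ParseError(f"{path}: line {n}: expected 5 or 6 columns")
        tracer = parts[5] if len(parts) == 6 else "C"
        frags.append(
            FragmentDefinition(
                parts[0], parts[1], parse_formula(parts[2]),
                int(parts[3]), int(parts[4]), tracer,
            )
        )
    return frags


def read_isotope_table(path: str | Path) -> ElementIsotopeTable:
    """Isotope-table override TSV with columns element, shift, abundance.

    Heavy shifts (+1, +2) are read from the file; the light isotope (+0) is
    the remainder unless given explicitly.  Elements absent from the file keep
    their built-in abundances.
    """
    heavy: Dict[str, Dict[int, float]] = {}
    for n, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if parts[0].lower() == "element":
            continue
        if len(parts) != 3:
            raise ParseError(f"{path}: line {n}: expected element, shift, abundance")
        heavy.setdefault(parts[0].strip(), {})[int(parts[1])] = float(parts[2])
    merged = dict(default_isotope_table().abundances)
    for el, shifts in heavy.items():
        p1, p2 = shifts.get(1, 0.0), shifts.get(2, 0.0)
        p0 = shifts.get(0, 1.0 - p1 - p2)
        vec = (p0, p1, p2) if p2 > 0 else ((p0, p1) if p1 > 0 else (p0,))
        merged[el] = vec
    return ElementIsotopeTable(merged)


# ---------------------------------------------------------------------------
# fragment assembly

@dataclass
class AssemblyFeedback:
    """One problem found while assembling fragments from table rows."""

    kind: str  # "incomplete" | "unknown"
    analyte_id: str
    masses: List[int]
    message: str


def assemble_fragments(
    raw: RawTable,
    library: Sequence[FragmentDefinition],
    config: RunConfig,
) -> Tuple[Dataset, List[AssemblyFeedback]]:
    """Assemble rows into per-fragment MDV matrices.

    Rows are expected in mass order per fragment: a run of consecutive masses
    starting at ``base_mass - leading_boundary`` forms one MDV plus its
    boundary rows.  An out-of-order mass starts a new candidate fragment, so a
    mass missing in the middle of an MDV is never assumed zero — the fragment
    is treated as incomplete, excluded from correction, and reported.  Every
    input row ends up in an MDV, a boundary vector, or a feedback message.
    """
    lead, trail = config.leading_boundary, config.trailing_boundary
    by_key = {f.key: f for f in library}
    known_analytes = {f.analyte_id for f in library}

    # split rows into maximal runs of same analyte, masses ascending by 1
    runs: List[List[Row]] = []
    for row in raw.rows:
        if (
            runs
            and runs[-1][-1].analyte_id == row.analyte_id
            and row.mass == runs[-1][-1].mass + 1
        ):
            runs[-1].append(row)
        else:
            runs.append([row])

    values = raw.float_matrix()
    index_of = {id(row): i for i, row in enumerate(raw.rows)}
    fragments: List[FragmentData] = []
    feedback: List[AssemblyFeedback] = []

    def matrix(rows: List[Row]) -> np.ndarray:
        if not rows:
            return np.zeros((0, raw.n_chromatograms))
        return values[[index_of[id(r)] for r in rows], :]

    for run in runs:
        pos = 0
        while pos < len(run):
            analyte = run[pos].analyte_id
            frag = by_key.get((analyte, run[pos].mass + lead))
            if frag is None:
                # skip to the next position that starts a known fragment
                end = pos + 1
                while end < len(run) and (
                    (run[end].analyte_id, run[end].mass + lead) not in by_key
                ):
                    end += 1
                masses = [r.mass for r in run[pos:end]]
                reason = (
                    "unknown analyte"
                    if analyte not in known_analytes
                    else "no fragment starts at this mass"
                )
                feedback.append(
                    AssemblyFeedback(
                        "unknown", analyte, masses,
                        f"{analyte}: rows at masses {masses} skipped ({reason})",
                    )
                )
                pos = end
                continue
            need = lead + frag.n_masses + trail
            chunk = run[pos : pos + need]
            if len(chunk) < need:
                masses = [r.mass for r in chunk]
                feedback.append(
                    AssemblyFeedback(
                        "incomplete", analyte, masses,
                        f"{frag.fragment_id}: incomplete fragment at masses "
                        f"{masses} (expected {need} consecutive rows from "
                        f"{frag.base_mass - lead}); excluded from correction",
                    )
                )
                pos += len(chunk)
                continue
            fragments.append(
                FragmentData(
                    frag,
                    values=matrix(chunk[lead : lead + frag.n_masses]),
                    leading=matrix(chunk[:lead]),
                    trailing=matrix(chunk[lead + frag.n_masses :]),
                )
            )
            pos += need

    for fb in feedback:
        log.warning(fb.message)
    return Dataset(list(raw.chromatogram_ids), fragments), feedback
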