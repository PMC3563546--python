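"""Domain types: analyte fragments, MDVs and assembled datasets.

A mass isotopomer distribution vector (MDV) holds the measured intensities of
a fragment's mass isotopomers M+0 .. M+numC, where ``numC`` is the number of
tracer-element (backbone) atoms.  Boundary masses below M+0 (``M-n``) and
above M+numC (``M+numC+n``) may be carried along for quality checks and
proton-shift estimation; they never enter the corrected output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Tuple

import numpy as np

from .isotopes import ConfigurationError

__all__ = [
    "FragmentDefinition",
    "MDV",
    "ProtonShiftModel",
    "FragmentData",
    "Dataset",
    "builtin_library",
    "parse_formula",
]


def parse_formula(text: str) -> Dict[str, int]:
    """Parse a Hill-style formula string like ``'C11H26NO2Si2'``.

    Counts default to 1; two-letter symbols have a lowercase second letter.
    """
    import re

    out: Dict[str, int] = {}
    pos = 0
    for m in re.finditer(r"([A-Z][a-z]?)(\d*)", text):
        if not m.group(0):
            continue
        if m.start() != pos:
            raise ConfigurationError(f"cannot parse formula {text!r} at {pos}")
        pos = m.end()
        out[m.group(1)] = out.get(m.group(1), 0) + (int(m.group(2) or 1))
    if pos != len(text):
        raise ConfigurationError(f"cannot parse formula {text!r} at {pos}")
    return out


@dataclass(frozen=True)
class FragmentDefinition:
    """An analyte fragment: full elemental formula plus backbone tracer count.

    ``formula`` is the complete composition of the measured ion, including any
    derivatization atoms (e.g. Si from silylation); ``num_c`` counts only the
    tracer-element atoms of the metabolite backbone, which fixes the MDV
    length at ``num_c + 1``.  ``base_mass`` is the nominal m/z of M+0 and,
    together with the analyte id, identifies the fragment in input tables.
    """

    analyte_id: str
    fragment_id: str
    formula: Mapping[str, int]
    num_c: int
    base_mass: int
    tracer_element: str = "C"

    def __post_init__(self) -> None:
        if self.num_c < 1:
            raise ConfigurationError(
                f"{self.fragment_id}: numC must be >= 1, got {self.num_c}"
            )
        if self.num_c > self.formula.get(self.tracer_element, 0):
            raise ConfigurationError(
                f"{self.fragment_id}: numC={self.num_c} exceeds "
                f"{self.tracer_element} count in formula"
            )
        if any(v < 0 for v in self.formula.values()):
            raise ConfigurationError(f"{self.fragment_id}: negative atom count")

    @property
    def n_masses(self) -> int:
        return self.num_c + 1

    @property
    def key(self) -> Tuple[str, int]:
        """Matching key used during fragment assembly."""
        return (self.analyte_id, self.base_mass)


@dataclass
class MDV:
    """One fragment's intensity vector for a single chromatogram."""

    fragment: FragmentDefinition
    values: np.ndarray
    leading: np.ndarray = field(default_factory=lambda: np.zeros(0))
    trailing: np.ndarray = field(default_factory=lambda: np.zeros(0))
    is_fraction: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.leading = np.asarray(self.leading, dtype=float)
        self.trailing = np.asarray(self.trailing, dtype=float)
        if len(self.values) != self.fragment.n_masses:
            raise ValueError(
                f"{self.fragment.fragment_id}: MDV length {len(self.values)} "
                f"!= numC+1 = {self.fragment.n_masses}"
            )
        if self.is_fraction:
            if np.any(self.values < 0) or abs(self.values.sum() - 1.0) > 1e-9:
                raise ValueError(
                    f"{self.fragment.fragment_id}: fractional MDV must be "
                    "non-negative and sum to 1"
                )

    def with_values(self, values: np.ndarray, is_fraction: bool = True) -> "MDV":
        return replace(self, values=np.asarray(values, float), is_fraction=is_fraction)


@dataclass(frozen=True)
class ProtonShiftModel:
    """A proton loss or gain affecting a fixed fraction alpha of all species."""

    direction: str  # "loss" or "gain"
    alpha: float

    def __post_init__(self) -> None:
        if self.direction not in ("loss", "gain"):
            raise ValueError(f"direction must be 'loss' or 'gain', got {self.direction!r}")
        if not (0.0 <= self.alpha < 1.0):
            raise ValueError(f"alpha must be in [0, 1), got {self.alpha}")


@dataclass
class FragmentData:
    """All chromatograms' measurements of one fragment, as a matrix.

    ``values`` has shape ``(numC+1, n_chromatograms)``; ``leading`` and
    ``trailing`` hold the boundary masses with the same column layout.
    """

    fragment: FragmentDefinition
    values: np.ndarray
    leading: np.ndarray
    trailing: np.ndarray

    def mdv(self, col: int, is_fraction: bool = False) -> MDV:
        return MDV(
            self.fragment,
            self.values[:, col],
            self.leading[:, col],
            self.trailing[:, col],
            is_fraction=is_fraction,
        )


@dataclass
class Dataset:
    """Assembled fragment matrices over a common set of chromatograms."""

    chromatogram_ids: List[str]
    fragments: List[FragmentData]
    is_fraction: bool = False

    @property
    def n_chromatograms(self) -> int:
        return len(self.chromatogram_ids)


# Illustrative TMS-derivatised amino-acid fragments.  The shipped library is
# deliberately tiny: real work supplies a fragment-library TSV (see
# io_tabular.read_fragment_library) with the full formula of every measured
# ion, derivatization included.
_BUILTIN = [
    ("Ala", "Ala_m57", "C11H26NO2Si2", 3, 260),
    ("Ala", "Ala_m85", "C10H26NOSi2", 2, 232),
    ("Gly", "Gly_m57", "C10H24NO2Si2", 2, 246),
    ("Ser", "Ser_m57", "C14H36NO3Si3", 3, 390),
    ("Asp", "Asp_m57", "C18H40NO4Si3", 4, 418),
]


def builtin_library() -> List[FragmentDefinition]:
    """The small built-in fragment library (silylated amino acids)."""
    return [
        FragmentDefinition(a, f, parse_formula(formula), num_c, mass)
        for a, f, formula, num_c, mass in _BUILTIN
    ]
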