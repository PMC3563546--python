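"""Natural-isotope abundance tables and the isotope-statistics primitives.

Every correction in this package ultimately reduces to the probability that a
molecule picks up ``k`` extra mass units from naturally occurring stable
isotopes (NOIs).  Per element we keep a short abundance vector for the mass
shifts +0, +1 and +2 — heavier isotopes contribute negligibly at natural
abundance and are truncated, which is the standard practice in isotopomer
correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Mapping

import numpy as np

__all__ = [
    "ElementIsotopeTable",
    "IsotopeCountAssignment",
    "default_isotope_table",
    "isotope_vector",
    "multinomial_abundance",
    "na_distribution",
]

#: Natural heavy-isotope abundances (fraction per atom) at mass shifts +1/+2.
#: The light isotope takes the remainder.  33S (+1, 0.75 %) may be zeroed via
#: an override table if only 34S is wanted.
_DEFAULT_HEAVY: Dict[str, tuple[float, float]] = {
    "C": (0.011, 0.0),       # 13C 1.1 %
    "H": (0.000115, 0.0),    # 2H 0.0115 %
    "N": (0.00366, 0.0),     # 15N 0.366 %
    "O": (0.00038, 0.002),   # 17O 0.038 %, 18O 0.2 %
    "S": (0.0075, 0.042),    # 33S 0.75 %, 34S 4.2 %
    "Si": (0.047, 0.031),    # 29Si 4.7 %, 30Si 3.1 %
}


class ConfigurationError(ValueError):
    """Raised for invalid isotope tables, configs or fragment definitions."""


@dataclass(frozen=True)
class ElementIsotopeTable:
    """Per-element natural-abundance vectors for mass shifts +0, +1, +2.

    ``abundances[el][k]`` is the probability that a single atom of element
    ``el`` carries a mass shift of ``+k``.  Vectors have length <= 3; they may
    sum to slightly less than 1 when heavier isotopes were truncated.
    """

    abundances: Mapping[str, tuple[float, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for el, vec in self.abundances.items():
            if len(vec) > 3:
                raise ConfigurationError(
                    f"isotope vector for {el!r} longer than 3 (shifts +0..+2)"
                )
            if any(a < 0.0 or a > 1.0 for a in vec):
                raise ConfigurationError(f"abundances for {el!r} outside [0, 1]")
            if sum(vec) > 1.0 + 1e-9:
                raise ConfigurationError(f"abundances for {el!r} sum above 1")

    def __contains__(self, element: str) -> bool:
        return element in self.abundances

    def vector(self, element: str) -> np.ndarray:
        """Return the abundance vector of ``element`` (shift +0 first)."""
        try:
            return np.asarray(self.abundances[element], dtype=float)
        except KeyError:
            raise ConfigurationError(
                f"element {element!r} missing from the isotope table"
            ) from None


def default_isotope_table() -> ElementIsotopeTable:
    """The built-in table for C, H, N, O, S and Si at natural abundance."""
    abund = {}
    for el, (p1, p2) in _DEFAULT_HEAVY.items():
        if p2 > 0.0:
            abund[el] = (1.0 - p1 - p2, p1, p2)
        elif p1 > 0.0:
            abund[el] = (1.0 - p1, p1)
        else:
            abund[el] = (1.0,)
    return ElementIsotopeTable(abund)


def isotope_vector(table: ElementIsotopeTable, element: str) -> np.ndarray:
    """Natural-abundance vector of one element for mass shifts +0/+1/+2."""
    return table.vector(element)


@dataclass(frozen=True)
class IsotopeCountAssignment:
    """An assignment of isotope occurrence counts to the atoms of one element.

    ``counts[k]`` is the number of atoms carrying mass shift ``+k``; the
    counts must sum to the total atom count ``n_atoms``.
    """

    element: str
    n_atoms: int
    counts: Mapping[int, int]

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("isotope occurrence counts must be non-negative")
        if sum(self.counts.values()) != self.n_atoms:
            raise ValueError(
                f"isotope counts sum to {sum(self.counts.values())}, "
                f"expected N = {self.n_atoms}"
            )


def multinomial_abundance(
    assignment: IsotopeCountAssignment, table: ElementIsotopeTable
) -> float:
    """Probability of one isotope-count assignment under natural abundance.

    For N atoms with isotopes :math:`I_i` of per-atom probability
    :math:`p(I_i)` occurring :math:`f(I_i)` times, the abundance is the
    multinomial term :math:`N!\\,\\prod_i p(I_i)^{f(I_i)} / f(I_i)!`.
    """
    p = table.vector(assignment.element)
    prob = math.factorial(assignment.n_atoms)
    for shift, count in assignment.counts.items():
        if count == 0:
            continue
        p_i = p[shift] if shift < len(p) else 0.0
        prob *= p_i**count / math.factorial(count)
    return float(prob)


def na_distribution(
    formula: Mapping[str, int],
    table: ElementIsotopeTable,
    max_len: int | None = None,
) -> np.ndarray:
    """Mass-shift probability vector of a whole formula at natural abundance.

    Convolves the per-atom truncated isotope vectors of every atom in
    ``formula``; entry ``k`` is the probability of a total mass shift of
    ``+k``.  With ``max_len`` the result is truncated (entries beyond are
    dropped, never redistributed), so the vector may sum to < 1.

    Parameters
    ----------
    formula:
        Element symbol -> atom count (non-negative integers).
    table:
        Natural-abundance table covering every element of the formula.
    max_len:
        Optional output length, e.g. ``numC + 1`` for a fragment MDV.
    """
    dist = np.array([1.0])
    for element, count in formula.items():
        if count < 0:
            raise ValueError(f"negative atom count for {element!r}")
        if count == 0:
            continue
        vec = table.vector(element)
        for _ in range(count):
            dist = np.convolve(dist, vec)
            if max_len is not None and len(dist) > max_len:
                dist = dist[:max_len]
    if max_len is not None:
        out = np.zeros(max_len)
        out[: len(dist)] = dist[:max_len]
        return out
    return dist
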