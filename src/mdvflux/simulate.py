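"""Forward-model simulator and brute-force oracles.

The simulator generates raw measurement tables from a known ground truth by
running the physics of the corrections forwards: the true labeling
distribution is diluted with unlabeled original biomass, convolved with the
fragment's natural-abundance pattern, passed through the proton loss/gain
equations (which populate the boundary masses), scaled to ion counts and
optionally perturbed with multiplicative Gaussian detector noise.  Feeding the
result back through the correction pipeline must recover the truth exactly in
the noise-free case — the package's master round-trip test.

The proton shift is applied to the full signal including the biomass
contribution: every molecule in the ion source, labeled or not, is equally
likely to lose or gain the proton.

``brute_force_na`` is the independent oracle for the natural-abundance
machinery: it enumerates every per-atom isotope assignment explicitly instead
of convolving, so it shares no code with the production path.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np

from .correction import build_correction_matrix
from .io_tabular import RawTable, Row
from .isotopes import ElementIsotopeTable, default_isotope_table
from .model import FragmentDefinition, builtin_library, parse_formula

__all__ = [
    "SimulationSpec",
    "GroundTruth",
    "simulate_dataset",
    "simulate_rt_table",
    "default_spec",
    "benchmark_spec",
    "brute_force_na",
]


@dataclass
class SimulationSpec:
    """A fully stated simulated experiment.

    alpha_loss / alpha_gain are the proton-shift scaling factors (at most one
    should normally be non-zero); ``obm_fractions`` gives the unlabeled
    original-biomass fraction per chromatogram; ``noise`` is the relative SD
    of multiplicative Gaussian noise on ion counts.
    """

    fragments: List[FragmentDefinition]
    true_mdvs: Dict[str, np.ndarray]
    n_chromatograms: int
    replicate_group_sizes: List[int] = field(default_factory=list)
    alpha_loss: float = 0.0
    alpha_gain: float = 0.0
    obm_fractions: Optional[List[float]] = None
    leading_boundary: int = 0
    trailing_boundary: int = 0
    intensity_scale: float = 1e6
    noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise < 0:
            raise ValueError("noise must be >= 0")
        for fid, mdv in self.true_mdvs.items():
            mdv = np.asarray(mdv, dtype=float)
            if abs(mdv.sum() - 1.0) > 1e-9 or np.any(mdv < 0):
                raise ValueError(f"true MDV for {fid!r} is not a distribution")
            self.true_mdvs[fid] = mdv
        if self.alpha_loss > 0 and self.leading_boundary < 1:
            self.leading_boundary = 1
        if self.alpha_gain > 0 and self.trailing_boundary < 1:
            self.trailing_boundary = 1


@dataclass
class GroundTruth:
    """What the simulator actually generated, for assertions."""

    true_mdvs: Dict[str, np.ndarray]
    alpha_loss: float
    alpha_gain: float
    obm_fractions: List[float]


def _forward_proton_shift(v: np.ndarray, alpha: float, direction: str) -> np.ndarray:
    """A fraction alpha of every species moves one mass unit down (loss) or
    up (gain); operates on the extended vector including boundary slots."""
    out = (1.0 - alpha) * v
    if direction == "loss":
        out[:-1] += alpha * v[1:]
    else:
        out[1:] += alpha * v[:-1]
    return out


def simulate_dataset(
    spec: SimulationSpec, table: Optional[ElementIsotopeTable] = None
) -> tuple[RawTable, GroundTruth]:
    """Generate a raw measurement table from a known ground truth.

    Returns the table in the standard TSV layout (one row per mass, boundary
    rows included) plus the ground truth. Deterministic for a fixed seed.
    """
    if table is None:
        table = default_isotope_table()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_chromatograms
    obm = spec.obm_fractions if spec.obm_fractions is not None else [0.0] * n
    if len(obm) != n:
        raise ValueError("need one OBM fraction per chromatogram")
    chrom_ids = [f"chrom{j + 1:03d}" for j in range(n)]
    lead, trail = spec.leading_boundary, spec.trailing_boundary

    rows: List[Row] = []
    for frag in spec.fragments:
        truth = spec.true_mdvs[frag.fragment_id]
        if len(truth) != frag.n_masses:
            raise ValueError(f"true MDV for {frag.fragment_id} has wrong length")
        cm = build_correction_matrix(frag, table).matrix
        e0 = np.eye(frag.n_masses)[0]
        columns = []
        for j in range(n):
            mixed = (1.0 - obm[j]) * truth + obm[j] * e0
            signal = cm @ mixed
            ext = np.concatenate([np.zeros(lead), signal, np.zeros(trail)])
            if spec.alpha_loss > 0:
                ext = _forward_proton_shift(ext, spec.alpha_loss, "loss")
            if spec.alpha_gain > 0:
                ext = _forward_proton_shift(ext, spec.alpha_gain, "gain")
            counts = ext * spec.intensity_scale
            if spec.noise > 0:
                counts = counts * (1.0 + spec.noise * rng.standard_normal(len(counts)))
                counts = np.clip(counts, 0.0, None)
            columns.append(counts)
        block = np.column_stack(columns)
        for k in range(lead + frag.n_masses + trail):
            mass = frag.base_mass - lead + k
            rows.append(
                Row(frag.analyte_id, mass, [repr(float(v)) for v in block[k]])
            )
    raw = RawTable(chrom_ids, rows, title="simulated")
    truth = GroundTruth(dict(spec.true_mdvs), spec.alpha_loss, spec.alpha_gain, list(obm))
    return raw, truth


def simulate_rt_table(
    spec: SimulationSpec, jitter_sd: float = 0.05, outliers: int = 0
) -> RawTable:
    """Retention times in the measurement layout: one base RT per fragment
    plus normal jitter; optionally the first ``outliers`` fragments get one
    grossly shifted chromatogram for QC tests."""
    rng = np.random.default_rng(spec.seed + 1)
    n = spec.n_chromatograms
    chrom_ids = [f"chrom{j + 1:03d}" for j in range(n)]
    lead, trail = spec.leading_boundary, spec.trailing_boundary
    rows: List[Row] = []
    for i, frag in enumerate(spec.fragments):
        base_rt = 200.0 + 25.0 * i
        rts = base_rt + jitter_sd * rng.standard_normal(n)
        if i < outliers:
            rts[0] += 100.0 * jitter_sd
        for k in range(lead + frag.n_masses + trail):
            mass = frag.base_mass - lead + k
            rows.append(Row(frag.analyte_id, mass, [f"{v:.4f}" for v in rts]))
    return RawTable(chrom_ids, rows, title="retention times")


def default_spec(seed: int = 0, noise: float = 0.0, **overrides) -> SimulationSpec:
    """The default stated world: 2 analytes, 3 fragments, 6 chromatograms in
    two replicate groups of 3, proton loss alpha = 0.05, 20 % original
    biomass, noise-free unless asked otherwise."""
    frags = builtin_library()[:3]  # Ala_m57, Ala_m85, Gly_m57
    rng = np.random.default_rng(seed)
    true_mdvs = {
        f.fragment_id: rng.dirichlet(np.ones(f.n_masses)) for f in frags
    }
    kwargs = dict(
        fragments=frags,
        true_mdvs=true_mdvs,
        n_chromatograms=6,
        replicate_group_sizes=[3, 3],
        alpha_loss=0.05,
        obm_fractions=[0.2] * 6,
        leading_boundary=1,
        trailing_boundary=0,
        noise=noise,
        seed=seed,
    )
    kwargs.update(overrides)
    return SimulationSpec(**kwargs)


def benchmark_spec(seed: int = 0) -> SimulationSpec:
    """A dataset with the reference benchmark's shape: 128 chromatograms,
    65 fragments, 412 mass rows (one trailing boundary per fragment)."""
    frags: List[FragmentDefinition] = []
    for i in range(65):
        num_c = 4 if i < 43 else 5  # 43*5 + 22*6 + 65 boundary rows = 412
        formula = parse_formula(f"C{num_c + 6}H{2 * num_c + 15}NO2Si2")
        frags.append(
            FragmentDefinition(
                f"met{i // 2 + 1:02d}",
                f"met{i // 2 + 1:02d}_f{i % 2 + 1}",
                formula,
                num_c,
                base_mass=150 + 30 * i,
            )
        )
    rng = np.random.default_rng(seed)
    true_mdvs = {f.fragment_id: rng.dirichlet(np.ones(f.n_masses)) for f in frags}
    return SimulationSpec(
        fragments=frags,
        true_mdvs=true_mdvs,
        n_chromatograms=128,
        replicate_group_sizes=[4] * 32,
        trailing_boundary=1,
        noise=0.01,
        seed=seed,
    )


def brute_force_na(
    formula: Mapping[str, int],
    table: ElementIsotopeTable,
    max_len: Optional[int] = None,
) -> np.ndarray:
    """Exhaustive-enumeration oracle for the natural-abundance distribution.

    Enumerates every assignment of an isotope to every individual atom and
    accumulates probability per total mass shift.  Exact but exponential —
    feasible only for formulas of roughly ten atoms or fewer.
    """
    atoms: List[np.ndarray] = []
    for element, count in formula.items():
        vec = table.vector(element)
        atoms.extend([vec] * count)
    max_shift = sum(len(v) - 1 for v in atoms)
    acc = np.zeros(max_shift + 1 if atoms else 1)
    if not atoms:
        acc[0] = 1.0
    else:
        for assignment in itertools.product(*(range(len(v)) for v in atoms)):
            prob = 1.0
            for vec, shift in zip(atoms, assignment):
                prob *= vec[shift]
            acc[sum(assignment)] += prob
    if max_len is not None:
        out = np.zeros(max_len)
        upto = min(max_len, len(acc))
        out[:upto] = acc[:upto]
        return out
    return acc
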