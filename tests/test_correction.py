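"""Correction matrix construction, NA/proton/OBM corrections and composition."""

import numpy as np
import pytest

from mdvflux.correction import (
    AlphaEstimationError,
    CorrectionError,
    apply_corrections,
    build_correction_matrix,
    correct_na,
    correct_obm,
    correct_proton_shift,
    estimate_alpha,
    normalize,
)
from mdvflux.io_tabular import RunConfig, assemble_fragments
from mdvflux.isotopes import na_distribution
from mdvflux.model import MDV, FragmentDefinition, ProtonShiftModel, builtin_library
from mdvflux.simulate import SimulationSpec, brute_force_na, simulate_dataset


class TestCorrectionMatrix:
    def test_no_heavy_isotopes_gives_identity(self, no_heavy_table, c3_fragment):
        cm = build_correction_matrix(c3_fragment, no_heavy_table)
        np.testing.assert_array_equal(cm.matrix, np.eye(4))

    def test_c2_skeleton_columns(self, table, c2_fragment):
        cm = build_correction_matrix(c2_fragment, table).matrix
        oracle = brute_force_na({"C": 2}, table)
        np.testing.assert_allclose(cm[:, 0], oracle, atol=1e-12)
        np.testing.assert_allclose(
            cm[:, 0], [0.978121, 0.021758, 0.000121], atol=1e-6
        )
        np.testing.assert_allclose(cm[:, 2], [0, 0, 1], atol=1e-12)

    @pytest.mark.parametrize("frag", builtin_library(), ids=lambda f: f.fragment_id)
    def test_structural_invariants(self, table, frag):
        cm = build_correction_matrix(frag, table).matrix
        n = frag.n_masses
        assert cm.shape == (n, n)
        assert np.all(np.triu(cm, 1) == 0), "upper triangle must be zero"
        assert np.all(np.diag(cm) > 0)
        assert np.all(cm.sum(axis=0) <= 1 + 1e-9)
        # column 0 is the NA distribution of the full formula
        np.testing.assert_allclose(
            cm[:, 0], na_distribution(frag.formula, table, max_len=n), atol=1e-15
        )


class TestCorrectNa:
    def test_unlabeled_na_pattern_corrects_to_pure_m0(self, table, c3_fragment):
        measured = na_distribution(c3_fragment.formula, table, max_len=4)
        mdv = MDV(c3_fragment, measured)
        cm = build_correction_matrix(c3_fragment, table)
        out = correct_na(mdv, cm)
        np.testing.assert_allclose(out.values, [1, 0, 0, 0], atol=1e-10)
        assert out.is_fraction

    def test_identity_matrix_only_normalizes(self, no_heavy_table, c2_fragment):
        mdv = MDV(c2_fragment, [2.0, 2.0, 0.0])
        cm = build_correction_matrix(c2_fragment, no_heavy_table)
        out = correct_na(mdv, cm)
        np.testing.assert_allclose(out.values, [0.5, 0.5, 0.0])

    def test_fifty_fifty_mixture_round_trip(self, table, c3_fragment):
        truth = np.array([0.5, 0.0, 0.0, 0.5])
        cm = build_correction_matrix(c3_fragment, table)
        measured = cm.matrix @ truth
        out = correct_na(MDV(c3_fragment, measured), cm)
        np.testing.assert_allclose(out.values, truth, atol=1e-10)

    def test_nnls_matches_direct_solve_noise_free(self, table, rng):
        """On clean data the non-negative solve equals plain inversion."""
        frag = builtin_library()[0]
        cm = build_correction_matrix(frag, table)
        truth = rng.dirichlet(np.ones(frag.n_masses))
        measured = cm.matrix @ truth
        out = correct_na(MDV(frag, measured), cm)
        direct = np.linalg.solve(cm.matrix, measured)
        np.testing.assert_allclose(out.values, direct / direct.sum(), atol=1e-10)

    def test_output_is_distribution(self, table, rng):
        frag = builtin_library()[1]
        cm = build_correction_matrix(frag, table)
        for _ in range(20):
            noisy = cm.matrix @ rng.dirichlet(np.ones(frag.n_masses))
            noisy *= 1 + 0.05 * rng.standard_normal(len(noisy))
            out = correct_na(MDV(frag, np.clip(noisy, 0, None)), cm)
            assert np.all(out.values >= 0)
            assert out.values.sum() == pytest.approx(1.0, abs=1e-9)


class TestNormalize:
    def test_basic_cases(self):
        np.testing.assert_allclose(normalize(np.array([2.0, 2.0])), [0.5, 0.5])
        np.testing.assert_allclose(normalize(np.array([0.0, 5.0, 0.0])), [0, 1, 0])

    def test_all_zero_rejected(self):
        with pytest.raises(CorrectionError):
            normalize(np.zeros(3))


def loss_fixture(alpha=0.1, truth=(0.8, 0.15, 0.05)):
    """Forward-simulated proton loss on a 2-carbon MDV with an M-1 boundary."""
    truth = np.asarray(truth, float)
    frag = FragmentDefinition("A", "A_C2", {"C": 2, "H": 4}, 2, 100)
    measured = (1 - alpha) * truth
    measured[:-1] += alpha * truth[1:]
    boundary = alpha * truth[0]
    return MDV(frag, measured, leading=[boundary]), frag, truth


class TestProtonShift:
    def test_alpha_estimate_recovers_forward_simulation(self):
        mdv, _, _ = loss_fixture(alpha=0.1)
        np.testing.assert_allclose(mdv.values, [0.735, 0.14, 0.045], atol=1e-12)
        np.testing.assert_allclose(mdv.leading, [0.08], atol=1e-12)
        model = estimate_alpha(mdv, "loss")
        assert model.alpha == pytest.approx(0.1, abs=1e-6)

    def test_zero_boundary_means_zero_alpha(self):
        frag = FragmentDefinition("A", "A_C2", {"C": 2}, 2, 100)
        mdv = MDV(frag, [0.8, 0.15, 0.05], leading=[0.0])
        assert estimate_alpha(mdv, "loss").alpha == 0.0

    def test_boundary_larger_than_adjacent_fails(self):
        frag = FragmentDefinition("A", "A_C2", {"C": 2}, 2, 100)
        mdv = MDV(frag, [0.1, 0.5, 0.4], leading=[0.2])
        with pytest.raises(AlphaEstimationError):
            estimate_alpha(mdv, "loss")

    def test_missing_boundary_fails(self):
        frag = FragmentDefinition("A", "A_C2", {"C": 2}, 2, 100)
        with pytest.raises(AlphaEstimationError, match="M-1"):
            estimate_alpha(MDV(frag, [0.8, 0.15, 0.05]), "loss")
        with pytest.raises(AlphaEstimationError, match="M\\+numC\\+1"):
            estimate_alpha(MDV(frag, [0.8, 0.15, 0.05]), "gain")

    def test_zero_alpha_correction_is_identity(self):
        mdv, _, truth = loss_fixture(alpha=0.0)
        out = correct_proton_shift(mdv, ProtonShiftModel("loss", 0.0))
        np.testing.assert_allclose(out.values, truth, atol=1e-12)

    def test_loss_round_trip(self):
        mdv, _, truth = loss_fixture(alpha=0.1)
        out = correct_proton_shift(mdv, ProtonShiftModel("loss", 0.1))
        np.testing.assert_allclose(out.values, truth, atol=1e-9)

    def test_gain_is_mirror_of_loss(self):
        alpha, truth = 0.1, np.array([0.05, 0.15, 0.8])
        frag = FragmentDefinition("A", "A_C2", {"C": 2}, 2, 100)
        measured = (1 - alpha) * truth
        measured[1:] += alpha * truth[:-1]
        boundary = alpha * truth[-1]
        mdv = MDV(frag, measured, trailing=[boundary])
        model = estimate_alpha(mdv, "gain")
        assert model.alpha == pytest.approx(alpha, abs=1e-6)
        out = correct_proton_shift(mdv, model)
        np.testing.assert_allclose(out.values, truth, atol=1e-9)


class TestCorrectObm:
    def test_zero_fraction_is_identity(self, c2_fragment):
        mdv = MDV(c2_fragment, [0.2, 0.3, 0.5])
        out = correct_obm(mdv, 0.0, np.array([1.0, 0.0, 0.0]))
        np.testing.assert_allclose(out.values, [0.2, 0.3, 0.5], atol=1e-12)

    def test_fully_labeled_c2_with_40_percent_biomass(self, table, c2_fragment):
        na = na_distribution(c2_fragment.formula, table, max_len=3)
        measured = 0.6 * np.array([0.0, 0.0, 1.0]) + 0.4 * na
        np.testing.assert_allclose(
            measured, [0.391248, 0.008703, 0.600048], atol=1e-6
        )
        out = correct_obm(MDV(c2_fragment, measured), 0.4, na)
        np.testing.assert_allclose(out.values, [0, 0, 1], atol=1e-5)

    def test_nothing_left_after_subtraction_errors(self, c2_fragment):
        # an OBM vector dominating the signal everywhere zeroes the residual
        mdv = MDV(c2_fragment, [1.0, 0.0, 0.0])
        with pytest.raises(CorrectionError, match="nothing left"):
            correct_obm(mdv, 0.9, np.array([2.0, 1.0, 1.0]))

    def test_f_of_one_rejected(self, c2_fragment):
        with pytest.raises(CorrectionError):
            correct_obm(MDV(c2_fragment, [1.0, 0.0, 0.0]), 1.0, np.eye(3)[0])


class TestApplyCorrections:
    def simulated(self, corrections, alpha=0.08, f=0.25, seed=11):
        frags = builtin_library()[:2]
        rng = np.random.default_rng(seed)
        spec = SimulationSpec(
            fragments=frags,
            true_mdvs={fr.fragment_id: rng.dirichlet(np.ones(fr.n_masses))
                       for fr in frags},
            n_chromatograms=2,
            alpha_loss=alpha,
            obm_fractions=[f, f],
            leading_boundary=1 if alpha > 0 else 0,
            seed=seed,
        )
        raw, truth = simulate_dataset(spec)
        cfg = RunConfig(corrections=corrections,
                        leading_boundary=spec.leading_boundary)
        ds, _ = assemble_fragments(raw, frags, cfg)
        obm = {cid: f for cid in ds.chromatogram_ids}
        return ds, cfg, obm, truth

    def test_empty_correction_list_only_normalizes(self, table):
        ds, cfg, _, _ = self.simulated([], alpha=0.0, f=0.0)
        out, msgs = apply_corrections(ds, cfg, None, table)
        assert msgs == []
        for fd_in, fd_out in zip(ds.fragments, out.fragments):
            expected = fd_in.values / fd_in.values.sum(axis=0)
            np.testing.assert_allclose(fd_out.values, expected, atol=1e-12)

    def test_full_round_trip_recovers_truth(self, table):
        ds, cfg, obm, truth = self.simulated(["proton_loss", "na", "obm"])
        out, msgs = apply_corrections(ds, cfg, obm, table)
        assert msgs == []
        for fd in out.fragments:
            expected = truth.true_mdvs[fd.fragment.fragment_id]
            for j in range(fd.values.shape[1]):
                np.testing.assert_allclose(fd.values[:, j], expected, atol=1e-6)

    def test_boundaries_removed_from_output(self, table):
        ds, cfg, obm, _ = self.simulated(["proton_loss", "na", "obm"])
        out, _ = apply_corrections(ds, cfg, obm, table)
        for fd in out.fragments:
            assert fd.leading.shape[0] == 0 and fd.trailing.shape[0] == 0

    def test_scale_invariance(self, table):
        """Ion-count scale must not affect corrected fractions (the single
        final normalization and per-step normalization are equivalent)."""
        ds, cfg, obm, _ = self.simulated(["proton_loss", "na", "obm"])
        out1, _ = apply_corrections(ds, cfg, obm, table)
        for fd in ds.fragments:
            fd.values *= 7.3e3
            fd.leading *= 7.3e3
            fd.trailing *= 7.3e3
        out2, _ = apply_corrections(ds, cfg, obm, table)
        for f1, f2 in zip(out1.fragments, out2.fragments):
            np.testing.assert_allclose(f1.values, f2.values, atol=1e-12)

    def test_missing_obm_chromatogram_named(self, table):
        ds, cfg, obm, _ = self.simulated(["na", "obm"], alpha=0.0)
        del obm["chrom002"]
        with pytest.raises(CorrectionError, match="chrom002"):
            apply_corrections(ds, cfg, obm, table)

    def test_na_pattern_measures_as_unlabeled(self, table):
        """An MDV that is exactly the fragment's NA pattern has average
        labeling ~0 after correction."""
        from mdvflux.qc import average_labeling

        frag = builtin_library()[0]
        measured = na_distribution(frag.formula, table, max_len=frag.n_masses)
        cm = build_correction_matrix(frag, table)
        out = correct_na(MDV(frag, measured), cm)
        assert average_labeling(out) < 1e-9
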