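"""Pre-correction checks and the average-labeling diagnostic."""

import numpy as np
import pytest

from mdvflux.io_tabular import RawTable, Row, RunConfig
from mdvflux.model import MDV, Dataset, FragmentData, FragmentDefinition
from mdvflux.qc import (
    average_labeling,
    check_intensity_bounds,
    check_missing,
    check_retention_times,
    run_checks,
    summarize_labeling,
)


def table_of(values, analyte="Ala", base_mass=100):
    """values: 2-D list (rows x chromatograms) of strings."""
    n = len(values[0])
    rows = [Row(analyte, base_mass + i, list(v)) for i, v in enumerate(values)]
    return RawTable([f"c{j + 1}" for j in range(n)], rows)


class TestMissing:
    def test_complete_table_clean(self):
        mask = check_missing(table_of([["1", "2"], ["3", "4"]]))
        assert mask.n_flagged == 0

    @pytest.mark.parametrize("bad", ["", "n.d.", "NA?"])
    def test_empty_or_text_cell_flagged(self, bad):
        mask = check_missing(table_of([["1", "2"], [bad, "4"]]))
        assert mask.n_flagged == 1
        assert mask.flags[1][0] == "missing"


class TestIntensityBounds:
    def test_within_range_clean(self):
        mask = check_intensity_bounds(table_of([["100", "200"]]), 50, 1000)
        assert mask.n_flagged == 0

    def test_boundary_row_checked_too(self):
        # first row is a leading boundary mass; still subject to the check
        raw = table_of([["5000", "10"], ["100", "100"]], base_mass=99)
        mask = check_intensity_bounds(raw, 50, 1000)
        assert mask.flags[0][0] == "above-max"
        assert mask.flags[0][1] == "below-min"
        assert mask.n_flagged == 2

    def test_unbounded_range_never_flags(self):
        raw = table_of([["0", "1e12"], ["-5", "3"]])
        assert check_intensity_bounds(raw, 0, np.inf).n_flagged == 1  # only -5


class TestRetentionTimes:
    def test_identical_rts_clean(self):
        raw = table_of([["5.0"] * 6])
        assert check_retention_times(raw, k=3).n_flagged == 0

    def test_single_outlier_flagged_at_its_position(self):
        rng = np.random.default_rng(42)
        base = 300 + 0.05 * rng.standard_normal(24)
        sd = base.std(ddof=1)
        base[7] += 10 * sd  # shift one chromatogram by 10 SD of the rest
        raw = table_of([[f"{v:.6f}" for v in base]])
        mask = check_retention_times(raw, k=3)
        flagged = [(i, j) for i, row in enumerate(mask.flags)
                   for j, f in enumerate(row) if f != "ok"]
        assert flagged == [(0, 7)]

    def test_infinite_k_never_flags(self):
        raw = table_of([["1", "2", "100"]])
        assert check_retention_times(raw, k=np.inf).n_flagged == 0

    def test_single_chromatogram_skipped_with_warning(self):
        raw = table_of([["5.0"], ["6.0"]])
        with pytest.warns(UserWarning, match="skipped"):
            mask = check_retention_times(raw, k=3)
        assert mask.n_flagged == 0

    def test_pooled_mode_mixes_fragments(self):
        # two fragments at very different RTs: pooled stats flag both rows,
        # per-fragment stats flag none
        raw = table_of([["5.0", "5.01", "4.99"], ["505.0", "505.1", "504.9"]])
        assert check_retention_times(raw, k=3).n_flagged == 0
        assert check_retention_times(raw, k=0.5, pooled=True).n_flagged > 0


class TestRunChecks:
    def test_selected_checks_merge(self):
        raw = table_of([["", "2000"], ["10", "20"]])
        cfg = RunConfig(checks=["missing", "intensity"],
                        intensity_min=5, intensity_max=1000)
        mask, rt_mask = run_checks(raw, cfg)
        assert rt_mask is None
        assert mask.flags[0][0] == "missing"
        assert mask.flags[0][1] == "above-max"


def mdv_of(values, num_c=None):
    values = np.asarray(values, float)
    num_c = num_c or len(values) - 1
    frag = FragmentDefinition("A", f"A_C{num_c}", {"C": num_c}, num_c, 100)
    return MDV(frag, values)


class TestAverageLabeling:
    @pytest.mark.parametrize(
        "values, expected",
        [
            ((1, 0, 0, 0), 0.0),
            ((0, 0, 0, 1), 1.0),
            ((0.25, 0.25, 0.25, 0.25), 0.5),
            ((0.5, 0.5), 0.5),
            ((2.0, 1.0, 1.0), 0.375),
        ],
    )
    def test_formula(self, values, expected):
        assert average_labeling(mdv_of(values)) == pytest.approx(expected)

    def test_scale_invariant(self, rng):
        values = rng.dirichlet(np.ones(4))
        assert average_labeling(mdv_of(values * 1e6)) == pytest.approx(
            average_labeling(mdv_of(values))
        )

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            average_labeling(mdv_of((0.0, 0.0)))


class TestSummarizeLabeling:
    def dataset(self, columns_by_fragment):
        fragments = []
        n = None
        for fid, cols in columns_by_fragment.items():
            values = np.column_stack(cols)
            num_c = values.shape[0] - 1
            frag = FragmentDefinition("A", fid, {"C": num_c}, num_c, 100)
            fragments.append(FragmentData(
                frag, values, np.zeros((0, values.shape[1])),
                np.zeros((0, values.shape[1]))))
            n = values.shape[1]
        return Dataset([f"c{j + 1}" for j in range(n)], fragments, is_fraction=True)

    def test_unlabeled_dataset_all_zero(self):
        ds = self.dataset({"f1": [(1, 0, 0)] * 4})
        report = summarize_labeling(ds, [("g1", [0, 1]), ("g2", [2, 3])])
        assert np.all(report.per_mdv.values == 0)
        assert report.overall == 0

    def test_group_value_is_mean_of_chromatograms(self):
        ds = self.dataset({"f1": [(1, 0, 0), (0, 0, 1)]})
        report = summarize_labeling(ds, [("g1", [0, 1])])
        assert report.per_chromatogram.tolist() == [0.0, 1.0]
        assert report.per_group["g1"] == pytest.approx(0.5)

    def test_mixed_fixture_matches_hand_computation(self):
        # two analytes, two chromatograms, hand-computed labeling values
        ds = self.dataset({
            "f1": [(0.5, 0.5, 0.0), (0.0, 0.5, 0.5)],   # labeling 0.25, 0.75
            "f2": [(0.0, 1.0), (1.0, 0.0)],              # labeling 1.0, 0.0
        })
        report = summarize_labeling(ds, [("g1", [0, 1])])
        assert report.per_mdv.loc["f1"].tolist() == pytest.approx([0.25, 0.75])
        assert report.per_mdv.loc["f2"].tolist() == pytest.approx([1.0, 0.0])
        assert report.per_chromatogram.tolist() == pytest.approx([0.625, 0.375])
        assert report.overall == pytest.approx(0.5)

    def test_report_written_as_tsv(self, tmp_path):
        ds = self.dataset({"f1": [(1, 0, 0), (0, 0, 1)]})
        report = summarize_labeling(ds, [("g1", [0, 1])])
        path = tmp_path / "labeling.tsv"
        report.write(path)
        text = path.read_text()
        assert "per MDV" in text and "g1" in text
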