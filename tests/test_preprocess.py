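import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fosnet.preprocess import (
    apply_rout,
    bootstrap_means,
    compute_densities,
    percent_change,
    rout_filter,
)


def _section_table(rows):
    return pd.DataFrame(rows, columns=["animal_id", "genotype", "sex", "treatment", "region", "count", "area_mm2"])


class TestComputeDensities:
    def test_mean_of_two_sections(self):
        raw = _section_table(
            [("a1", "AA", "M", "saline", "PL", 10, 1.0), ("a1", "AA", "M", "saline", "PL", 20, 1.0)]
        )
        out = compute_densities(raw)
        assert out.loc[0, "density_cells_per_mm2"] == pytest.approx(15.0)

    def test_zero_count_gives_zero_density(self):
        raw = _section_table([("a1", "AA", "M", "saline", "PL", 0, 2.0)])
        assert compute_densities(raw)["density_cells_per_mm2"].iloc[0] == 0.0

    def test_damaged_sections_excluded(self):
        raw = _section_table(
            [("a1", "AA", "M", "saline", "PL", 10, 1.0), ("a1", "AA", "M", "saline", "PL", 999, 1.0)]
        )
        raw["damaged"] = [False, True]
        assert compute_densities(raw)["density_cells_per_mm2"].iloc[0] == pytest.approx(10.0)

    def test_all_damaged_gives_missing_not_failure(self):
        raw = _section_table([("a1", "AA", "M", "saline", "PL", 10, 1.0)])
        raw["damaged"] = [True]
        out = compute_densities(raw)
        assert len(out) == 1 and np.isnan(out["density_cells_per_mm2"].iloc[0])

    def test_matches_bruteforce_on_random_sections(self):
        rng = np.random.default_rng(0)
        rows = []
        for a in ("a1", "a2", "a3"):
            for r in ("PL", "NAc"):
                for _ in range(rng.integers(2, 6)):
                    rows.append((a, "AA", "M", "acute", r, int(rng.integers(0, 100)), float(rng.uniform(0.5, 2))))
        raw = _section_table(rows)
        out = compute_densities(raw).set_index(["animal_id", "region"])
        for (a, r), grp in raw.groupby(["animal_id", "region"]):
            expected = np.mean([c / ar for c, ar in zip(grp["count"], grp["area_mm2"])])
            assert out.loc[(a, r), "density_cells_per_mm2"] == pytest.approx(expected)

    def test_invalid_area_rejected(self):
        raw = _section_table([("a1", "AA", "M", "saline", "PL", 10, 0.0)])
        with pytest.raises(ValueError):
            compute_densities(raw)


class TestRoutFilter:
    def test_tight_cluster_untouched(self):
        kept, out = rout_filter([100, 101, 99, 100])
        assert out.size == 0 and kept.size == 4

    def test_gross_outlier_removed(self):
        # by the stated rule: median 100, MAD 1, scale 1.4826, t(1000) ~= 607,
        # p ~ 0 -> BH rejects index 4 only
        kept, out = rout_filter([100, 101, 99, 100, 1000])
        assert list(out) == [4]
        assert 1000 not in kept

    def test_two_values_returned_unchanged(self):
        kept, out = rout_filter([1.0, 500.0])
        assert np.array_equal(kept, [1.0, 500.0]) and out.size == 0

    def test_zero_residuals_never_removed(self):
        kept, out = rout_filter([7.0] * 10)
        assert out.size == 0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            rout_filter([])

    @given(st.floats(min_value=5.0, max_value=1000.0))
    @settings(max_examples=30, deadline=None)
    def test_removal_monotone_in_outlier_magnitude(self, mag):
        base = [10.0, 10.5, 9.5, 10.2, 9.8, 10.1]
        _, small = rout_filter(base + [10.0 + mag])
        _, large = rout_filter(base + [10.0 + 2 * mag])
        assert large.size >= small.size

    def test_apply_rout_logs_removals(self):
        rows = []
        for i, v in enumerate([100, 101, 99, 100, 1000]):
            rows.append((f"a{i}", "AA", "M", "acute", "PL", v))
        t = pd.DataFrame(rows, columns=["animal_id", "genotype", "sex", "treatment", "region", "density_cells_per_mm2"])
        filtered, removed = apply_rout(t)
        assert len(filtered) == 4 and len(removed) == 1
        assert removed["density_cells_per_mm2"].iloc[0] == 1000


def _density_table(values_by_group):
    rows = []
    for (g, s, t), vals in values_by_group.items():
        for i, v in enumerate(vals):
            rows.append((f"{g}{s}{t}{i}", g, s, t, "PL", v))
    return pd.DataFrame(rows, columns=["animal_id", "genotype", "sex", "treatment", "region", "density_cells_per_mm2"])


class TestPercentChange:
    def test_closed_form_values(self):
        t = _density_table(
            {("AA", "M", "saline"): [100.0, 100.0, 100.0], ("AA", "M", "acute"): [100.0, 150.0, 0.0]}
        )
        pc = percent_change(t)
        got = pc.group("AA", "M", "acute")["PL"].to_numpy()
        assert got == pytest.approx([0.0, 50.0, -100.0])

    def test_saline_group_mean_is_zero(self):
        t = _density_table({("AA", "M", "saline"): [80.0, 120.0, 100.0]})
        pc = percent_change(t)
        assert pc.group("AA", "M", "saline")["PL"].mean() == pytest.approx(0.0)

    def test_stratified_vs_pooled_baseline(self):
        t = _density_table(
            {
                ("AA", "M", "saline"): [100.0, 100.0],
                ("GG", "M", "saline"): [200.0, 200.0],
                ("AA", "M", "acute"): [150.0],
                ("GG", "M", "acute"): [150.0],
            }
        )
        strat = percent_change(t)
        assert strat.group("AA", "M", "acute")["PL"].iloc[0] == pytest.approx(50.0)
        assert strat.group("GG", "M", "acute")["PL"].iloc[0] == pytest.approx(-25.0)
        pooled = percent_change(t, pooled_baseline=True)
        assert pooled.group("AA", "M", "acute")["PL"].iloc[0] == pytest.approx(0.0)

    @given(
        st.lists(st.floats(min_value=1.0, max_value=500.0), min_size=3, max_size=8),
        st.floats(min_value=0.0, max_value=200.0),
    )
    @settings(max_examples=30, deadline=None)
    def test_shift_follows_closed_formula(self, saline, shift):
        """Adding a constant c to all values maps percent change per the formula."""
        x = 123.0
        t = _density_table({("AA", "M", "saline"): saline, ("AA", "M", "acute"): [x]})
        t2 = t.copy()
        t2["density_cells_per_mm2"] += shift
        b = np.mean(saline)
        got = percent_change(t2).group("AA", "M", "acute")["PL"].iloc[0]
        assert got == pytest.approx(100.0 * (x - b) / (b + shift))

    def test_missing_saline_stratum_rejected(self):
        t = _density_table({("AA", "M", "acute"): [100.0, 110.0], ("GG", "F", "saline"): [90.0, 95.0]})
        with pytest.raises(ValueError):
            percent_change(t)


class TestBootstrapMeans:
    @pytest.fixture()
    def mat(self):
        rng = np.random.default_rng(1)
        return pd.DataFrame(rng.normal(50, 10, size=(8, 4)), columns=list("abcd"))

    def test_identity_hook_equals_sample_mean(self, mat):
        bs = bootstrap_means(mat, n_boot=1, identity=True)
        assert np.allclose(bs.replicates[0], mat.mean(axis=0))

    def test_seed_determinism(self, mat):
        a = bootstrap_means(mat, n_boot=50, seed=3)
        b = bootstrap_means(mat, n_boot=50, seed=3)
        assert np.array_equal(a.replicates, b.replicates)

    def test_replicate_mean_near_sample_mean(self, mat):
        """CLT: mean of 2000 replicate means within 2 SE of the sample mean."""
        bs = bootstrap_means(mat, n_boot=2000, seed=0)
        se = mat.std(axis=0, ddof=1).to_numpy() / np.sqrt(len(mat))
        assert np.all(np.abs(bs.replicates.mean(axis=0) - mat.mean(axis=0).to_numpy()) < 2 * se)

    def test_invalid_sizes_rejected(self, mat):
        with pytest.raises(ValueError):
            bootstrap_means(mat, n_boot=0)
        with pytest.raises(ValueError):
            bootstrap_means(mat.iloc[:1], n_boot=5)
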