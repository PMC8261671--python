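import copy

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrbpome import (
    ConfigurationError,
    DifferentialConfig,
    PairwiseFC,
    ValidationError,
    assign_fdr,
    build_null_distribution,
    call_differential,
    compute_fdr_grid,
    compute_pairwise_fcs,
    default_thresholds,
    fit_fdr_model,
    normalize_total_area,
    preprocess,
)
from mrbpome.differential import NullModel

from conftest import make_dataset, make_design


def norm_from_log2(log2_unt, log2_str, n_ctrl=0):
    """Build a NormalizedDataset with prescribed biological log2 values."""
    log2_unt = np.atleast_2d(np.asarray(log2_unt, dtype=float))
    log2_str = np.atleast_2d(np.asarray(log2_str, dtype=float))
    design = make_design(n_bio=log2_unt.shape[1], n_ctrl=n_ctrl)
    # invert the pseudocount-log2 so normalize reproduces the targets exactly
    areas = np.hstack([np.exp2(log2_unt) - 1, np.exp2(log2_str) - 1])
    ds = make_dataset(areas, design)
    norm = normalize_total_area(ds, total=float(areas.sum(axis=0).max() or 1))
    # bypass column scaling: set layers directly for exact control
    norm.normalized = areas
    norm.log2_values = np.log2(areas + 1.0)
    return norm


def brute_force_grid(null_means, thresholds, tail_mode="folded"):
    """Independent per-threshold count, scalar loop."""
    values = [abs(v) for v in null_means] if tail_mode == "folded" else list(null_means)
    out = []
    for t in thresholds:
        out.append(100.0 * sum(1 for v in values if v >= t) / len(values))
    return np.array(out)


def normal_equations(x, y):
    """Closed-form OLS for y = a + b x."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    b = (n * np.sum(x * y) - x.sum() * y.sum()) / (
        n * np.sum(x * x) - x.sum() ** 2
    )
    a = (y.sum() - b * x.sum()) / n
    return b, a


def make_model(slope, intercept, tail_mode="folded", **kwargs):
    return NullModel(
        pooled_fcs=np.empty(0),
        null_means=np.empty(0),
        thresholds=default_thresholds(tail_mode),
        grid_fdr=np.empty(0),
        slope=slope,
        intercept=intercept,
        tail_mode=tail_mode,
        seed=None,
        **kwargs,
    )


class TestPairwiseFC:
    def test_constant_shift(self):
        pw = compute_pairwise_fcs(norm_from_log2([[3, 3, 3]], [[5, 5, 5]]))
        np.testing.assert_allclose(pw.fcs, np.full((1, 9), 2.0))
        np.testing.assert_allclose(pw.avg_fc, [2.0])

    def test_two_replicates_enumeration(self):
        # stress [4,6], untreated [3,5]: ordered pairs {1,-1,3,1}, mean 1
        pw = compute_pairwise_fcs(norm_from_log2([[3, 5]], [[4, 6]]))
        assert sorted(pw.fcs[0].tolist()) == [-1.0, 1.0, 1.0, 3.0]
        np.testing.assert_allclose(pw.avg_fc, [1.0])

    def test_identical_conditions_zero(self):
        pw = compute_pairwise_fcs(norm_from_log2([[2, 4, 6]], [[2, 4, 6]]))
        np.testing.assert_allclose(pw.avg_fc, [0.0])

    def test_pair_count(self):
        pw = compute_pairwise_fcs(
            norm_from_log2([[1, 2, 3], [1, 1, 1]], [[4, 5, 6], [2, 2, 2]])
        )
        assert pw.fcs.shape == (2, 9)
        assert pw.pairs_per_protein == 9

    def test_missing_condition_errors(self):
        design = make_design(conditions=("untreated",))
        ds = make_dataset(np.ones((2, 6)), design)
        norm = normalize_total_area(ds)
        with pytest.raises(ConfigurationError):
            compute_pairwise_fcs(norm)

    def test_antisymmetry_under_label_swap(self, sim_small):
        datasets, _ = sim_small
        norm, _ = preprocess(datasets["TOP3"])
        swapped = copy.deepcopy(norm)
        swap = {"untreated": "stress", "stress": "untreated"}
        swapped.design = [
            type(s)(s.sample_id, swap[s.condition], s.assay, s.replicate, s.method)
            for s in norm.design
        ]
        a = compute_pairwise_fcs(norm).avg_fc
        b = compute_pairwise_fcs(swapped).avg_fc
        np.testing.assert_array_equal(a, -b)


class TestNullDistribution:
    def _pairwise(self, fcs):
        fcs = np.asarray(fcs, dtype=float)
        return PairwiseFC(
            proteins=[f"P{i}" for i in range(fcs.shape[0])],
            fcs=fcs,
            avg_fc=fcs.mean(axis=1),
        )

    def test_constant_pool(self):
        pw = self._pairwise(np.full((5, 9), 1.25))
        model = build_null_distribution(pw, n_experiments=50, seed=0)
        np.testing.assert_allclose(model.null_means, 1.25)

    def test_n_experiments(self):
        pw = self._pairwise(np.random.default_rng(0).normal(size=(20, 9)))
        model = build_null_distribution(pw, n_experiments=10_000, seed=0)
        assert len(model.null_means) == 10_000

    def test_seed_determinism(self):
        pw = self._pairwise(np.random.default_rng(0).normal(size=(20, 9)))
        a = build_null_distribution(pw, n_experiments=500, seed=42)
        b = build_null_distribution(pw, n_experiments=500, seed=42)
        np.testing.assert_array_equal(a.null_means, b.null_means)

    def test_pool_too_small(self):
        pw = self._pairwise(np.ones((1, 9)))
        pw.fcs = pw.fcs[:, :4]  # 4 values but pairs_per_protein inferred = 4
        pw2 = PairwiseFC(proteins=["P"], fcs=np.ones((1, 9)), avg_fc=np.ones(1))
        pw2.fcs = np.ones((0, 9)).reshape(0, 9)
        model_ok = build_null_distribution(pw, n_experiments=3, seed=0)
        assert len(model_ok.null_means) == 3
        with pytest.raises(ValidationError, match="pool"):
            build_null_distribution(
                PairwiseFC(proteins=[], fcs=np.empty((0, 9)), avg_fc=np.empty(0)),
                n_experiments=3,
                seed=0,
            )

    def test_signflip_scope(self):
        pw = self._pairwise(np.random.default_rng(3).normal(size=(30, 9)))
        model = build_null_distribution(
            pw, n_experiments=2000, seed=1, shuffle_scope="within_protein_signflip"
        )
        per_protein = np.abs(pw.avg_fc)
        assert np.all(np.isin(np.abs(model.null_means).round(12),
                              per_protein.round(12)))


class TestFdrGrid:
    def test_folded_example(self):
        nm = np.array([-1.2, -0.3, 0.4, 2.1])
        grid = compute_fdr_grid(nm, np.array([1.0]), "folded")
        np.testing.assert_allclose(grid, [50.0])

    def test_folded_zero_threshold_is_100(self):
        nm = np.random.default_rng(0).normal(size=100)
        grid = compute_fdr_grid(nm, np.array([0.0]), "folded")
        np.testing.assert_allclose(grid, [100.0])

    def test_signed_grid_has_41_points(self):
        th = default_thresholds("signed")
        assert len(th) == 41
        assert th[0] == -10.0 and th[-1] == 10.0
        assert len(default_thresholds("folded")) == 21

    def test_empty_thresholds_error(self):
        with pytest.raises(ValidationError):
            compute_fdr_grid(np.ones(5), np.empty(0))

    @settings(max_examples=30, deadline=None)
    @given(seed=st.integers(0, 10_000), tail=st.sampled_from(["folded", "signed"]))
    def test_oracle_equivalence(self, seed, tail):
        rng = np.random.default_rng(seed)
        nm = rng.normal(scale=rng.uniform(0.2, 3.0), size=200)
        th = default_thresholds(tail)
        np.testing.assert_array_equal(
            compute_fdr_grid(nm, th, tail), brute_force_grid(nm, th, tail)
        )

    def test_folded_grid_nonincreasing(self):
        nm = np.random.default_rng(5).normal(size=500)
        grid = compute_fdr_grid(nm, default_thresholds("folded"), "folded")
        assert np.all(np.diff(grid) <= 0)


class TestFitModel:
    def test_hand_ols(self):
        slope, intercept = fit_fdr_model(
            np.array([0.0, 1.0, 2.0]), np.array([50.0, 30.0, 10.0])
        )
        assert slope == pytest.approx(-20.0)
        assert intercept == pytest.approx(50.0)

    def test_perfect_line_zero_residuals(self):
        x = np.linspace(0, 10, 21)
        y = 80 - 6 * x
        slope, intercept = fit_fdr_model(x, y)
        np.testing.assert_allclose(intercept + slope * x, y, atol=1e-10)

    def test_constant_grid_at_100(self):
        x = default_thresholds("folded")
        slope, intercept = fit_fdr_model(x, np.full_like(x, 100.0))
        assert slope == pytest.approx(0.0)
        assert intercept == pytest.approx(100.0)

    def test_identical_thresholds_error(self):
        with pytest.raises(ValidationError):
            fit_fdr_model(np.array([1.0, 1.0]), np.array([10.0, 20.0]))

    @settings(max_examples=40, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_full_fit_matches_normal_equations(self, seed):
        rng = np.random.default_rng(seed)
        x = np.sort(rng.uniform(0, 10, size=12))
        x[0], x[1] = 0.0, x[0] + 0.1  # ensure distinct
        y = rng.uniform(0.5, 99.5, size=12)
        slope, intercept = fit_fdr_model(x, y, fit_region="full")
        b, a = normal_equations(x, y)
        assert slope == pytest.approx(b, abs=1e-8)
        assert intercept == pytest.approx(a, abs=1e-8)

    def test_transition_fit_ignores_zero_tail(self):
        x = default_thresholds("folded")
        y = np.zeros_like(x)
        y[0], y[1], y[2], y[3] = 100.0, 40.0, 8.0, 1.0
        slope_t, icpt_t = fit_fdr_model(x, y, fit_region="transition")
        slope_f, icpt_f = fit_fdr_model(x, y, fit_region="full")
        # transition crossing tracks the null; the full fit is much flatter
        assert (icpt_t - 5) / -slope_t < (icpt_f - 5) / -slope_f
        b, a = normal_equations(x[:5], y[:5])  # through the first zero
        assert slope_t == pytest.approx(b, abs=1e-8)
        assert icpt_t == pytest.approx(a, abs=1e-8)

    def test_folded_slope_nonpositive(self):
        for seed in range(5):
            nm = np.random.default_rng(seed).normal(
                scale=0.3 + 0.3 * seed, size=2000
            )
            th = default_thresholds("folded")
            grid = compute_fdr_grid(nm, th, "folded")
            for region in ("transition", "full"):
                slope, _ = fit_fdr_model(th, grid, fit_region=region)
                assert slope <= 0


class TestAssignFdr:
    def test_clamped_to_zero(self):
        row = assign_fdr(3.0, make_model(-20.0, 50.0))
        assert row["fdr_percent"].iloc[0] == 0.0
        assert bool(row["significant"].iloc[0])

    def test_zero_fc(self):
        row = assign_fdr(0.0, make_model(-20.0, 50.0))
        assert row["fdr_percent"].iloc[0] == 50.0
        assert not bool(row["significant"].iloc[0])
        assert row["direction"].iloc[0] == "none"

    def test_plain_prediction(self):
        row = assign_fdr(1.5, make_model(-20.0, 50.0))
        assert row["fdr_percent"].iloc[0] == pytest.approx(20.0)
        assert not bool(row["significant"].iloc[0])

    def test_folded_uses_absolute_value(self):
        rows = assign_fdr(np.array([-3.0, 3.0]), make_model(-10.0, 40.0))
        assert rows["fdr_percent"].tolist() == [10.0, 10.0]
        assert rows["direction"].tolist() == ["less", "more"]

    def test_bounds(self):
        fcs = np.linspace(-30, 30, 101)
        rows = assign_fdr(fcs, make_model(-20.0, 50.0))
        assert rows["fdr_percent"].between(0, 100).all()

    def test_signed_mirrored_model(self):
        model = make_model(
            -8.0, 42.0, tail_mode="signed", slope_neg=-6.0, intercept_neg=40.0
        )
        rows = assign_fdr(np.array([2.0, -2.0]), model)
        assert rows["fdr_percent"].iloc[0] == pytest.approx(42 - 16)
        assert rows["fdr_percent"].iloc[1] == pytest.approx(40 - 12)

    def test_signed_without_mirror_errors(self):
        with pytest.raises(ValidationError):
            assign_fdr(-1.0, make_model(-8.0, 42.0, tail_mode="signed"))


class TestCallDifferential:
    def test_identical_conditions_nothing_significant(self, sim_small):
        datasets, _ = sim_small
        norm, _ = preprocess(datasets["TOP3"])
        # copy untreated biological values over the stress ones
        unt = [i for i, s in enumerate(norm.design)
               if s.condition == "untreated" and s.assay == "biological"]
        stress = [i for i, s in enumerate(norm.design)
                  if s.condition == "stress" and s.assay == "biological"]
        for a, b in zip(stress, unt):
            norm.log2_values[:, a] = norm.log2_values[:, b]
        table, model = call_differential(
            norm, DifferentialConfig(n_experiments=2000, seed=0)
        )
        np.testing.assert_allclose(table["avg_fc"], 0.0)
        if model.intercept > 5:
            assert not table["significant"].any()

    def test_reproducible(self, sim_small):
        datasets, _ = sim_small
        norm, _ = preprocess(datasets["LFQ"])
        cfg = DifferentialConfig(n_experiments=2000, seed=9)
        t1, m1 = call_differential(norm, cfg)
        t2, m2 = call_differential(norm, cfg)
        assert t1.equals(t2)
        np.testing.assert_array_equal(m1.null_means, m2.null_means)

    def test_fdr_range_and_direction(self, sim_small):
        datasets, _ = sim_small
        norm, _ = preprocess(datasets["iBAQ"])
        table, _ = call_differential(
            norm, DifferentialConfig(n_experiments=2000, seed=3)
        )
        assert table["fdr_percent"].between(0, 100).all()
        pos = table["avg_fc"] > 0
        assert (table.loc[pos, "direction"] == "more").all()
        assert (table.loc[table["avg_fc"] < 0, "direction"] == "less").all()
        assert (table["method"] == "iBAQ").all()

    def test_signed_mode_runs(self, sim_small):
        datasets, _ = sim_small
        norm, _ = preprocess(datasets["TOP3"])
        table, model = call_differential(
            norm,
            DifferentialConfig(n_experiments=2000, seed=1, tail_mode="signed"),
        )
        assert len(model.thresholds) == 41
        assert model.slope_neg is not None
        assert table["fdr_percent"].between(0, 100).all()

    def test_grid_recorded_in_model(self, sim_small):
        datasets, _ = sim_small
        norm, _ = preprocess(datasets["TOP3"])
        _, model = call_differential(
            norm,
            DifferentialConfig(n_experiments=2000, seed=4, tail_mode="folded"),
        )
        np.testing.assert_array_equal(
            model.grid_fdr,
            brute_force_grid(model.null_means, model.thresholds, "folded"),
        )
        d = model.to_dict()
        assert d["n_experiments"] == 2000
        assert d["seed"] == 4
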