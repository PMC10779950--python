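"""Benchmark metrics, bootstrap CIs and relative free-energy tables."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from fmoscore import (
    BenchmarkDesign,
    FunctionForm,
    UndefinedMetricError,
    bootstrap_ci,
    ddg_table,
    evaluate_benchmark,
    fit_benchmark,
    gen_benchmark,
    metrics,
)


def kendall_tau_b_oracle(x, y) -> float:
    """O(n^2) pair enumeration with tie correction: tau_b = (C-D)/sqrt((n0-nx)(n0-ny))."""
    n = len(x)
    concordant = discordant = tied_x = tied_y = 0
    for i, j in itertools.combinations(range(n), 2):
        dx, dy = x[i] - x[j], y[i] - y[j]
        if dx == 0:
            tied_x += 1
        if dy == 0:
            tied_y += 1
        if dx != 0 and dy != 0:
            if dx * dy > 0:
                concordant += 1
            else:
                discordant += 1
    n0 = n * (n - 1) // 2
    return (concordant - discordant) / np.sqrt((n0 - tied_x) * (n0 - tied_y))


class TestMetrics:
    def test_perfect_agreement(self):
        m = metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert m.pearson_r == pytest.approx(1.0)
        assert m.kendall_tau == pytest.approx(1.0)
        assert m.rmse == 0.0 and m.mue == 0.0
        assert m.frac_within_2kcal == 1.0

    def test_full_reversal(self):
        m = metrics([3.0, 2.0, 1.0], [1.0, 2.0, 3.0])
        assert m.kendall_tau == pytest.approx(-1.0)
        assert m.pearson_r == pytest.approx(-1.0)

    def test_single_swap_tau(self):
        # ranks [1,3,2,4] vs [1,2,3,4]: 5 concordant, 1 discordant pair
        m = metrics([1.0, 3.0, 2.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert m.kendall_tau == pytest.approx(4.0 / 6.0)

    def test_zero_variance_is_an_error_not_zero(self):
        with pytest.raises(UndefinedMetricError):
            metrics([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_rmse_dominates_mue(self, rng):
        for _ in range(200):
            n = rng.integers(2, 40)
            p, e = rng.normal(size=n), rng.normal(size=n)
            m = metrics(p, e)
            assert m.rmse >= m.mue >= 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_tau_b_matches_oracle_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 4, size=12).astype(float)  # heavy ties
        y = rng.integers(0, 4, size=12).astype(float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            pytest.skip("degenerate draw")
        m = metrics(x, y)
        assert m.kendall_tau == pytest.approx(kendall_tau_b_oracle(x, y), abs=1e-12)

    def test_tau_invariant_under_monotone_transform(self, rng):
        p, e = rng.normal(size=20), rng.normal(size=20)
        m1 = metrics(p, e)
        m2 = metrics(np.exp(p), e**3)
        assert m1.kendall_tau == pytest.approx(m2.kendall_tau, abs=1e-12)


class TestBootstrapCI:
    def test_fixed_seed_reproducible(self, rng):
        p, e = rng.normal(size=20), rng.normal(size=20)
        a = bootstrap_ci(p, e, "rmse", n_reps=500, seed=7)
        b = bootstrap_ci(p, e, "rmse", n_reps=500, seed=7)
        assert (a.point, a.lo, a.hi) == (b.point, b.lo, b.hi)

    def test_point_equals_full_sample_metric(self, rng):
        p, e = rng.normal(size=15), rng.normal(size=15)
        ci = bootstrap_ci(p, e, "pearson_r", n_reps=200, seed=1)
        assert ci.point == metrics(p, e).pearson_r

    def test_constant_residuals_degenerate_interval(self, rng):
        e = rng.normal(size=12)
        p = e + 1.5
        ci = bootstrap_ci(p, e, "rmse", n_reps=300, seed=2)
        assert ci.point == ci.lo == ci.hi == pytest.approx(1.5)

    def test_interval_brackets_point(self, rng):
        p, e = rng.normal(size=25), rng.normal(size=25)
        for metric in ("rmse", "mue", "pearson_r", "kendall_tau"):
            ci = bootstrap_ci(p, e, metric, n_reps=2000, seed=3)
            assert ci.lo <= ci.point <= ci.hi

    def test_undefined_resamples_redrawn_and_counted(self):
        # length-2 vectors: half of all resamples repeat one pair -> r undefined
        ci = bootstrap_ci([1.0, 2.0], [1.0, 2.0], "pearson_r", n_reps=200, seed=4)
        assert ci.n_redrawn > 0
        assert ci.point == pytest.approx(1.0)

    def test_matches_scipy_percentile_bootstrap(self, rng):
        """Independent cross-check of the percentile interval on a smooth metric."""
        p, e = rng.normal(size=40), rng.normal(scale=2.0, size=40)

        def stat(pp, ee):
            return float(np.sqrt(np.mean((pp - ee) ** 2)))

        ours = bootstrap_ci(p, e, "rmse", n_reps=20000, seed=5)
        ref = sps.bootstrap(
            (p, e), stat, paired=True, vectorized=False, method="percentile",
            n_resamples=20000, random_state=np.random.default_rng(99),
        )
        assert ours.lo == pytest.approx(ref.confidence_interval.low, abs=0.05)
        assert ours.hi == pytest.approx(ref.confidence_interval.high, abs=0.05)

    def test_callable_metric(self, rng):
        x = rng.normal(size=100)
        ci = bootstrap_ci(
            x, np.zeros_like(x), lambda p, e: float(np.mean(p - e)), n_reps=1000, seed=6
        )
        assert ci.lo < np.mean(x) < ci.hi


class TestEvaluateBenchmark:
    def test_perfect_fit_single_target(self):
        design = BenchmarkDesign(seed=21, n_targets=1, ligands_per_target=10, noise_sd=0.0)
        records, _ = gen_benchmark(design)
        bench = fit_benchmark(records, FunctionForm.FMO_COSMO_SE)
        stats = evaluate_benchmark(bench, records, n_reps=200, seed=0, per_target_ci=False)
        assert stats.averaged.values["pearson_r"] == pytest.approx(1.0, abs=1e-9)
        assert stats.averaged.values["rmse"] == pytest.approx(0.0, abs=1e-9)
        assert stats.averaged.values["frac_within_2kcal"] == 1.0

    def test_average_is_unweighted_mean_of_targets(self):
        records, _ = gen_benchmark(BenchmarkDesign(seed=22, n_targets=3, ligands_per_target=12))
        bench = fit_benchmark(records, FunctionForm.FMO_COSMO_SE)
        stats = evaluate_benchmark(bench, records, n_reps=100, seed=0, per_target_ci=False)
        for name in ("pearson_r", "rmse"):
            per = [ts.values[name] for ts in stats.per_target.values()]
            assert stats.averaged.values[name] == pytest.approx(np.mean(per))

    def test_ci_bounds_ordered_and_bracket_typical_values(self):
        records, _ = gen_benchmark(BenchmarkDesign(seed=23, n_targets=2, ligands_per_target=15))
        bench = fit_benchmark(records, FunctionForm.FMO_COSMO_SE)
        stats = evaluate_benchmark(
            bench, records, n_reps=500, seed=1, ci_metrics=("pearson_r", "rmse")
        )
        for ts in list(stats.per_target.values()) + [stats.averaged]:
            for lo, hi in ts.ci.values():
                assert lo <= hi

    def test_fixed_seed_reproducible(self):
        records, _ = gen_benchmark(BenchmarkDesign(seed=24, n_targets=2, ligands_per_target=10))
        bench = fit_benchmark(records, FunctionForm.FMO_COSMO_SE)
        a = evaluate_benchmark(bench, records, n_reps=300, seed=5, ci_metrics=("pearson_r",))
        b = evaluate_benchmark(bench, records, n_reps=300, seed=5, ci_metrics=("pearson_r",))
        assert a.to_dict() == b.to_dict()


class TestDdgTable:
    def _setup(self, seed=31):
        records, _ = gen_benchmark(BenchmarkDesign(seed=seed, n_targets=2, ligands_per_target=8))
        bench = fit_benchmark(records, FunctionForm.FMO_COSMO_SE)
        refs = {"T01": "T01_L001", "T02": "T02_L001"}
        return records, bench, refs

    def test_reference_maps_to_zero(self):
        records, bench, refs = self._setup()
        df = ddg_table(bench, records, refs)
        ref_rows = df[df.complex_id.isin(refs.values())]
        assert (ref_rows.ddg_pred == 0.0).all()
        assert (ref_rows.ddg_exp == 0.0).all()

    def test_offset_invariance(self):
        """Shifting all predictions of a target by a constant leaves ddG unchanged."""
        records, bench, refs = self._setup()
        df = ddg_table(bench, records, refs)
        for fr in bench.fits.values():
            fr.intercept += 3.21
        df_shift = ddg_table(bench, records, refs)
        assert np.allclose(df.ddg_pred, df_shift.ddg_pred, atol=1e-9)

    def test_two_ligand_toy_arithmetic(self):
        records, bench, refs = self._setup()
        df = ddg_table(bench, records, refs)
        t1 = df[df.target_id == "T01"].set_index("complex_id")
        exp = {r.complex_id: r.dg_exp for r in records if r.target_id == "T01"}
        assert t1.loc["T01_L002", "ddg_exp"] == pytest.approx(
            exp["T01_L002"] - exp["T01_L001"]
        )

    def test_missing_reference_rejected(self):
        records, bench, _ = self._setup()
        with pytest.raises(KeyError, match="T02"):
            ddg_table(bench, records, {"T01": "T01_L001"})
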