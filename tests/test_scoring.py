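"""Function-form fitting, prediction and per-target benchmark fits."""

import numpy as np
import pytest

from fmoscore import (
    BenchmarkDesign,
    ComplexEnergyRecord,
    FunctionForm,
    MissingTermError,
    SingularFitError,
    fit,
    fit_benchmark,
    gen_benchmark,
    load_model,
    predict,
    save_model,
)
from fmoscore.scoring import group_by_target, loo_predictions


def _noiseless_records(n=8, seed=0, coefs=(0.1, 0.2, 0.5), intercept=1.0):
    rng = np.random.default_rng(seed)
    records = []
    for k in range(n):
        e_int = rng.normal(-140, 30)
        g_cos = rng.normal(100, 25)
        e_def = rng.normal(5, 3)
        dg = coefs[0] * e_int + coefs[1] * g_cos + coefs[2] * e_def + intercept
        records.append(
            ComplexEnergyRecord(
                complex_id=f"c{k}", target_id="t1", e_int=e_int,
                g_sol={"cosmo": g_cos}, e_def=e_def, dg_exp=dg,
            )
        )
    return records


class TestFit:
    def test_noiseless_coefficients_recovered(self):
        records = _noiseless_records()
        fr = fit(records, FunctionForm.FMO_COSMO_SE)
        assert fr.coefficients["e_int"] == pytest.approx(0.1, abs=1e-8)
        assert fr.coefficients["g_sol_cosmo"] == pytest.approx(0.2, abs=1e-8)
        assert fr.coefficients["e_def"] == pytest.approx(0.5, abs=1e-8)
        assert fr.intercept == pytest.approx(1.0, abs=1e-8)
        y = np.array([r.dg_exp for r in records])
        assert np.corrcoef(fr.predictions, y)[0, 1] == pytest.approx(1.0, abs=1e-10)

    def test_constant_response_gives_zero_slopes(self):
        records = _noiseless_records()
        for r in records:
            r.dg_exp = -7.5
        fr = fit(records, FunctionForm.FMO_COSMO_SE)
        assert all(abs(c) < 1e-10 for c in fr.coefficients.values())
        assert fr.intercept == pytest.approx(-7.5, abs=1e-10)

    def test_noisy_recovery_within_standard_errors(self):
        """With Gaussian noise the OLS estimates stay within a few SEs of truth."""
        design = BenchmarkDesign(seed=2024, n_targets=1, ligands_per_target=200)
        records, truth = gen_benchmark(design)
        fr = fit(records, FunctionForm.FMO_COSMO_SE)
        # se(coef) ~ noise_sd / (sd(term) * sqrt(n))
        n = len(records)
        for term, true_c in truth.coefficients.items():
            se = truth.noise_sd / (design.term_sds[term] * np.sqrt(n))
            assert abs(fr.coefficients[term] - true_c) < 4 * se

    def test_constant_term_column_named_in_error(self):
        records = _noiseless_records()
        for r in records:
            r.e_def = 5.0
        with pytest.raises(SingularFitError, match="e_def"):
            fit(records, FunctionForm.FMO_COSMO_SE)

    def test_collinear_terms_rejected(self):
        records = _noiseless_records()
        for r in records:
            r.g_sol["cosmo"] = -0.5 * r.e_int  # exact collinearity
        with pytest.raises(SingularFitError, match="rank deficient"):
            fit(records, FunctionForm.FMO_COSMO_SE)

    def test_insufficient_points(self):
        with pytest.raises(ValueError, match="at least"):
            fit(_noiseless_records(n=4), FunctionForm.FMO_COSMO_SE)

    def test_missing_experimental_affinity(self):
        records = _noiseless_records()
        records[3].dg_exp = None
        with pytest.raises(MissingTermError, match="c3"):
            fit(records, FunctionForm.FMO_COSMO_SE)

    def test_row_order_invariance(self):
        records = _noiseless_records(n=12, seed=5)
        a = fit(records, FunctionForm.FMO_COSMO_SE)
        b = fit(list(reversed(records)), FunctionForm.FMO_COSMO_SE)
        for t in a.coefficients:
            assert a.coefficients[t] == pytest.approx(b.coefficients[t], abs=1e-9)


class TestPredict:
    def test_training_rows_reproduce_stored_predictions(self):
        records = _noiseless_records(n=10, seed=3)
        fr = fit(records, FunctionForm.FMO_COSMO_SE)
        for rec, stored in zip(records, fr.predictions):
            assert predict(fr, rec) == stored  # bitwise: same evaluation path

    def test_scaling_term_and_coefficient_cancels(self):
        records = _noiseless_records(n=10, seed=4)
        fr = fit(records, FunctionForm.FMO_COSMO_SE)
        rec = records[0]
        lam = 3.7
        scaled_fit = fit(
            [
                ComplexEnergyRecord(
                    complex_id=r.complex_id, target_id=r.target_id,
                    e_int=r.e_int * lam, g_sol=dict(r.g_sol), e_def=r.e_def,
                    dg_exp=r.dg_exp,
                )
                for r in records
            ],
            FunctionForm.FMO_COSMO_SE,
        )
        scaled_rec = ComplexEnergyRecord(
            complex_id=rec.complex_id, target_id=rec.target_id,
            e_int=rec.e_int * lam, g_sol=dict(rec.g_sol), e_def=rec.e_def,
        )
        assert scaled_fit.coefficients["e_int"] == pytest.approx(
            fr.coefficients["e_int"] / lam, rel=1e-9
        )
        assert predict(scaled_fit, scaled_rec) == pytest.approx(predict(fr, rec), rel=1e-9)

    def test_missing_term_raises(self):
        records = _noiseless_records()
        fr = fit(records, FunctionForm.FMO_COSMO_SE)
        bare = ComplexEnergyRecord(complex_id="x", target_id="t1", e_int=-100.0)
        with pytest.raises(MissingTermError):
            predict(fr, bare)


class TestFitBenchmark:
    def test_eight_targets_fitted_independently(self):
        records, _ = gen_benchmark(BenchmarkDesign(seed=1, n_targets=8, ligands_per_target=10))
        bench = fit_benchmark(records, FunctionForm.FMO_COSMO_SE)
        assert len(bench) == 8 and not bench.failures
        # permuting record order changes nothing
        rng = np.random.default_rng(0)
        shuffled = [records[k] for k in rng.permutation(len(records))]
        bench2 = fit_benchmark(shuffled, FunctionForm.FMO_COSMO_SE)
        for tid in bench:
            for t in bench[tid].coefficients:
                assert bench[tid].coefficients[t] == pytest.approx(
                    bench2[tid].coefficients[t], abs=1e-9
                )

    def test_target_with_missing_term_flagged_not_dropped(self):
        records, _ = gen_benchmark(BenchmarkDesign(seed=3, n_targets=3, ligands_per_target=8))
        for r in records:
            if r.target_id == "T02":
                r.e_def = None
        bench = fit_benchmark(records, FunctionForm.FMO_COSMO_SE)
        assert set(bench.fits) == {"T01", "T03"}
        assert "T02" in bench.failures and "e_def" in bench.failures["T02"]

    def test_nested_forms_cannot_fit_worse_in_sample(self):
        """Each added regressor can only raise the in-sample correlation."""
        records, _ = gen_benchmark(BenchmarkDesign(seed=6, n_targets=4, ligands_per_target=20))
        for tid, group in group_by_target(records).items():
            y = np.array([r.dg_exp for r in group])
            rs = {}
            for form in (FunctionForm.FMO, FunctionForm.FMO_COSMO, FunctionForm.FMO_COSMO_SE):
                fr = fit(group, form)
                rs[form] = np.corrcoef(fr.predictions, y)[0, 1]
            assert rs[FunctionForm.FMO_COSMO_SE] >= rs[FunctionForm.FMO_COSMO] - 1e-10
            assert rs[FunctionForm.FMO_COSMO] >= rs[FunctionForm.FMO] - 1e-10

    def test_affine_recentering_absorbed_by_intercept(self):
        records = _noiseless_records(n=10, seed=8)
        fr = fit(records, FunctionForm.FMO_COSMO_SE)
        shifted = [
            ComplexEnergyRecord(
                complex_id=r.complex_id, target_id=r.target_id, e_int=r.e_int + 50.0,
                g_sol=dict(r.g_sol), e_def=r.e_def, dg_exp=r.dg_exp,
            )
            for r in records
        ]
        fr2 = fit(shifted, FunctionForm.FMO_COSMO_SE)
        assert fr2.coefficients["e_int"] == pytest.approx(fr.coefficients["e_int"], abs=1e-9)
        for a, b in zip(fr.predictions, fr2.predictions):
            assert a == pytest.approx(b, abs=1e-8)


class TestModelSerialization:
    def test_save_load_round_trip(self, tmp_path):
        records, _ = gen_benchmark(BenchmarkDesign(seed=9, n_targets=2, ligands_per_target=8))
        bench = fit_benchmark(records, FunctionForm.FMO_COSMO_SE)
        path = tmp_path / "model.json"
        save_model(bench, path, seed=9)
        back = load_model(path)
        assert back.form == bench.form
        for tid in bench:
            assert back[tid].coefficients == pytest.approx(bench[tid].coefficients)
            assert predict(back[tid], records[0] if tid == "T01" else records[-1]) == (
                pytest.approx(predict(bench[tid], records[0] if tid == "T01" else records[-1]))
            )


class TestLeaveOneOut:
    def test_loo_differs_from_insample_under_noise(self):
        records, _ = gen_benchmark(BenchmarkDesign(seed=11, n_targets=1, ligands_per_target=12))
        fr = fit(records, FunctionForm.FMO_COSMO_SE)
        loo = loo_predictions(records, FunctionForm.FMO_COSMO_SE)
        assert loo.shape == fr.predictions.shape
        assert not np.allclose(loo, fr.predictions)
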