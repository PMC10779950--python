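"""Benchmark statistics with bootstrap confidence intervals.

For each target the predicted and experimental binding free energies are
compared through Pearson r, Kendall tau-b, RMSE, MUE, R^2 (squared Pearson r)
and the fraction of predictions within 2 kcal/mol of experiment.  Confidence
intervals are percentile bootstrap over resampled ligand pairs (default
10,000 repetitions); "averaged" statistics are unweighted means of the
per-target point estimates, their CIs formed by resampling within each target
and averaging per repetition.

Rank metrics on relative free energies (ddG) are invariant to per-target
additive offsets of the predictions, which is why in-sample intercepts do not
inflate ranking power.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import UndefinedMetricError
from .scoring import BenchmarkFit, group_by_target, predict
from .thermo import ComplexEnergyRecord

__all__ = [
    "METRIC_NAMES",
    "DDG_THRESHOLD",
    "MetricSet",
    "BootstrapCI",
    "TargetStats",
    "BenchmarkStats",
    "metrics",
    "bootstrap_ci",
    "evaluate_benchmark",
    "ddg_table",
]

METRIC_NAMES = ("pearson_r", "kendall_tau", "rmse", "mue", "r2", "frac_within_2kcal")

#: Accuracy threshold (kcal/mol) for the "within chemical accuracy" fraction.
DDG_THRESHOLD = 2.0

# Total resampling draws may exceed n_reps by at most this factor before the
# redraw loop for undefined metrics gives up.
_MAX_REDRAW_FACTOR = 100


def _validate_pair(pred: np.ndarray, exp: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred, dtype=float).ravel()
    exp = np.asarray(exp, dtype=float).ravel()
    if pred.shape != exp.shape:
        raise ValueError(f"length mismatch: {pred.size} predictions vs {exp.size} experimental")
    if pred.size < 2:
        raise ValueError("need at least two paired values")
    if not (np.all(np.isfinite(pred)) and np.all(np.isfinite(exp))):
        raise ValueError("values must be finite")
    return pred, exp


def _pearson(pred: np.ndarray, exp: np.ndarray) -> float:
    if np.ptp(pred) == 0 or np.ptp(exp) == 0:
        raise UndefinedMetricError("Pearson r undefined: zero variance in a vector")
    return float(sps.pearsonr(pred, exp).statistic)


def _kendall(pred: np.ndarray, exp: np.ndarray) -> float:
    if np.ptp(pred) == 0 or np.ptp(exp) == 0:
        raise UndefinedMetricError("Kendall tau undefined: zero variance in a vector")
    return float(sps.kendalltau(pred, exp, variant="b").statistic)


def _rmse(pred: np.ndarray, exp: np.ndarray) -> float:
    return float(np.sqrt(np.mean((pred - exp) ** 2)))


def _mue(pred: np.ndarray, exp: np.ndarray) -> float:
    return float(np.mean(np.abs(pred - exp)))


def _r2(pred: np.ndarray, exp: np.ndarray) -> float:
    return _pearson(pred, exp) ** 2


def _frac_within(pred: np.ndarray, exp: np.ndarray) -> float:
    return float(np.mean(np.abs(pred - exp) <= DDG_THRESHOLD))


_METRIC_FNS: dict[str, Callable[[np.ndarray, np.ndarray], float]] = {
    "pearson_r": _pearson,
    "kendall_tau": _kendall,
    "rmse": _rmse,
    "mue": _mue,
    "r2": _r2,
    "frac_within_2kcal": _frac_within,
}


@dataclass(frozen=True)
class MetricSet:
    """Point estimates of all benchmark metrics for one pred/exp pairing."""

    pearson_r: float
    kendall_tau: float
    rmse: float
    mue: float
    r2: float
    frac_within_2kcal: float
    n: int

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def metrics(pred: Sequence[float], exp: Sequence[float]) -> MetricSet:
    """All benchmark metrics for paired kcal/mol vectors.

    Raises :class:`UndefinedMetricError` when either vector has zero variance
    (correlations undefined — deliberately distinct from reporting 0).
    """
    p, e = _validate_pair(np.asarray(pred), np.asarray(exp))
    return MetricSet(
        pearson_r=_pearson(p, e),
        kendall_tau=_kendall(p, e),
        rmse=_rmse(p, e),
        mue=_mue(p, e),
        r2=_r2(p, e),
        frac_within_2kcal=_frac_within(p, e),
        n=p.size,
    )


# ---------------------------------------------------------------------------
# bootstrap

def _rows_pearson(p: np.ndarray, e: np.ndarray) -> np.ndarray:
    """Row-wise Pearson r over resample matrices; NaN where undefined."""
    pc = p - p.mean(axis=1, keepdims=True)
    ec = e - e.mean(axis=1, keepdims=True)
    num = np.sum(pc * ec, axis=1)
    den = np.sqrt(np.sum(pc**2, axis=1) * np.sum(ec**2, axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > 0, num / den, np.nan)
    return np.clip(r, -1.0, 1.0)


def _metric_rows(
    metric: str | Callable[[np.ndarray, np.ndarray], float],
    pred: np.ndarray,
    exp: np.ndarray,
    idx: np.ndarray,
) -> np.ndarray:
    """Metric evaluated on each resample row of ``idx``; NaN marks undefined."""
    p = pred[idx]
    e = exp[idx]
    if metric == "pearson_r":
        return _rows_pearson(p, e)
    if metric == "r2":
        return _rows_pearson(p, e) ** 2
    if metric == "rmse":
        return np.sqrt(np.mean((p - e) ** 2, axis=1))
    if metric == "mue":
        return np.mean(np.abs(p - e), axis=1)
    if metric == "frac_within_2kcal":
        return np.mean(np.abs(p - e) <= DDG_THRESHOLD, axis=1)
    fn = _METRIC_FNS.get(metric, metric) if isinstance(metric, str) else metric
    if not callable(fn):
        raise KeyError(f"unknown metric {metric!r}")
    out = np.empty(idx.shape[0])
    for k in range(idx.shape[0]):
        try:
            out[k] = fn(p[k], e[k])
        except UndefinedMetricError:
            out[k] = np.nan
    return out


def _resample_values(
    metric: str | Callable,
    pred: np.ndarray,
    exp: np.ndarray,
    n_reps: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, int]:
    """``n_reps`` bootstrap metric values; undefined resamples redrawn and counted."""
    n = pred.size
    values = np.empty(n_reps)
    filled = 0
    redrawn = 0
    drawn_total = 0
    while filled < n_reps:
        want = n_reps - filled
        idx = rng.integers(0, n, size=(want, n))
        drawn_total += want
        if drawn_total > _MAX_REDRAW_FACTOR * n_reps:
            raise UndefinedMetricError(
                f"metric {metric!r} undefined on nearly all resamples "
                "(degenerate data); cannot form a bootstrap distribution"
            )
        v = _metric_rows(metric, pred, exp, idx)
        ok = np.isfinite(v)
        bad = int(want - ok.sum())
        redrawn += bad
        v = v[ok]
        values[filled : filled + v.size] = v
        filled += v.size
    return values, redrawn


@dataclass(frozen=True)
class BootstrapCI:
    """Point estimate with a percentile bootstrap interval."""

    point: float
    lo: float
    hi: float
    n_reps: int
    n_redrawn: int = 0

    def covers(self, value: float) -> bool:
        return self.lo <= value <= self.hi


def bootstrap_ci(
    pred: Sequence[float],
    exp: Sequence[float],
    metric: str | Callable[[np.ndarray, np.ndarray], float],
    n_reps: int = 10000,
    seed: int | np.random.Generator | None = None,
    alpha: float = 0.05,
) -> BootstrapCI:
    """Percentile bootstrap CI for a metric over resampled (pred, exp) pairs.

    ``metric`` is a name from :data:`METRIC_NAMES` or any callable
    ``f(pred, exp) -> float``.  Pairs are resampled with replacement;
    resamples on which the metric is undefined (an
    :class:`UndefinedMetricError`, or NaN from a callable) are redrawn and
    counted in ``n_redrawn``.  Fully reproducible for a fixed integer seed.
    """
    p, e = _validate_pair(np.asarray(pred), np.asarray(exp))
    if n_reps < 1:
        raise ValueError(f"n_reps must be >= 1, got {n_reps}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if isinstance(metric, str):
        if metric not in _METRIC_FNS:
            raise KeyError(f"unknown metric {metric!r}; known: {sorted(_METRIC_FNS)}")
        fn = _METRIC_FNS[metric]
    else:
        fn = metric
    point = float(fn(p, e))
    values, redrawn = _resample_values(metric, p, e, n_reps, rng)
    lo, hi = np.quantile(values, [alpha / 2.0, 1.0 - alpha / 2.0])
    return BootstrapCI(point=point, lo=float(lo), hi=float(hi), n_reps=n_reps, n_redrawn=redrawn)


# ---------------------------------------------------------------------------
# benchmark evaluation

@dataclass
class TargetStats:
    """Metrics and CIs for one target's ligand series."""

    n: int
    values: dict[str, float]
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)


@dataclass
class BenchmarkStats:
    """Per-target and averaged benchmark statistics."""

    form: str
    per_target: dict[str, TargetStats]
    averaged: TargetStats
    n_reps: int
    seed: int | None

    def to_dict(self) -> dict:
        def _ts(ts: TargetStats) -> dict:
            return {
                "n": ts.n,
                "values": ts.values,
                "ci": {k: list(v) for k, v in ts.ci.items()},
            }

        return {
            "form": self.form,
            "n_reps": self.n_reps,
            "seed": self.seed,
            "per_target": {tid: _ts(ts) for tid, ts in self.per_target.items()},
            "averaged": _ts(self.averaged),
        }


def _paired_vectors(
    bench: BenchmarkFit, records: Iterable[ComplexEnergyRecord]
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    out = {}
    for tid, group in sorted(group_by_target(records).items()):
        if tid not in bench.fits:
            raise KeyError(f"no fit available for target {tid!r} (failures: {bench.failures})")
        fr = bench.fits[tid]
        missing = [r.complex_id for r in group if r.dg_exp is None]
        if missing:
            raise ValueError(f"target {tid!r} has records without dg_exp: {missing}")
        pred = np.array([predict(fr, r) for r in group])
        exp = np.array([r.dg_exp for r in group], dtype=float)
        out[tid] = (pred, exp)
    return out


def evaluate_benchmark(
    bench: BenchmarkFit,
    records: Iterable[ComplexEnergyRecord],
    n_reps: int = 10000,
    seed: int | None = 0,
    ci_metrics: Sequence[str] = METRIC_NAMES,
    per_target_ci: bool = True,
) -> BenchmarkStats:
    """Evaluate fitted models against experimental dG across all targets.

    Per-target metrics come from ``predict`` vs ``dg_exp``; averaged values
    are unweighted means of per-target point estimates.  The averaged CI for
    a metric resamples each target's ligands independently in every bootstrap
    repetition and averages the per-target metric values, so targets with few
    ligands are not drowned out by large series.
    """
    rng = np.random.default_rng(seed)
    pairs = _paired_vectors(bench, records)
    per_target: dict[str, TargetStats] = {}
    for tid, (pred, exp) in pairs.items():
        ms = metrics(pred, exp)
        ci = {}
        if per_target_ci:
            for name in ci_metrics:
                b = bootstrap_ci(pred, exp, name, n_reps=n_reps, seed=rng)
                ci[name] = (b.lo, b.hi)
        per_target[tid] = TargetStats(n=ms.n, values=ms.as_dict(), ci=ci)

    avg_values = {
        name: float(np.mean([ts.values[name] for ts in per_target.values()]))
        for name in METRIC_NAMES
    }
    avg_ci: dict[str, tuple[float, float]] = {}
    for name in ci_metrics:
        per_rep = np.zeros(n_reps)
        for tid, (pred, exp) in pairs.items():
            vals, _ = _resample_values(name, pred, exp, n_reps, rng)
            per_rep += vals
        per_rep /= len(pairs)
        lo, hi = np.quantile(per_rep, [0.025, 0.975])
        avg_ci[name] = (float(lo), float(hi))
    averaged = TargetStats(
        n=sum(ts.n for ts in per_target.values()), values=avg_values, ci=avg_ci
    )
    return BenchmarkStats(
        form=bench.form.value,
        per_target=per_target,
        averaged=averaged,
        n_reps=n_reps,
        seed=seed if not isinstance(seed, np.random.Generator) else None,
    )


def ddg_table(
    bench: BenchmarkFit,
    records: Iterable[ComplexEnergyRecord],
    references: Mapping[str, str],
) -> pd.DataFrame:
    """Relative free energies ddG = dG(ligand) - dG(reference) per target.

    ``references`` maps each target to its reference ligand's complex_id; the
    reference row maps to (0, 0) exactly.  Columns: target_id, complex_id,
    ddg_pred, ddg_exp (kcal/mol).
    """
    rows = []
    for tid, group in sorted(group_by_target(records).items()):
        if tid not in references:
            raise KeyError(f"no reference ligand given for target {tid!r}")
        fr = bench.fits[tid]
        ref_id = references[tid]
        by_id = {r.complex_id: r for r in group}
        if ref_id not in by_id:
            raise KeyError(f"reference ligand {ref_id!r} not found in target {tid!r}")
        ref = by_id[ref_id]
        if ref.dg_exp is None:
            raise ValueError(f"reference ligand {ref_id!r} has no dg_exp")
        ref_pred = predict(fr, ref)
        for r in group:
            if r.dg_exp is None:
                raise ValueError(f"record {r.complex_id!r} has no dg_exp")
            rows.append(
                {
                    "target_id": tid,
                    "complex_id": r.complex_id,
                    "ddg_pred": 0.0 if r.complex_id == ref_id else predict(fr, r) - ref_pred,
                    "ddg_exp": 0.0 if r.complex_id == ref_id else r.dg_exp - ref.dg_exp,
                }
            )
    return pd.DataFrame(rows, columns=["target_id", "complex_id", "ddg_pred", "ddg_exp"])
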