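"""The scoring functions: per-target linear models over energy terms.

Eight nested function forms combine the computed energy terms:

================  =============================================
form              terms (each with a fitted weight + intercept)
================  =============================================
FMO               e_int
FMO_PBSA          e_int, g_sol_pbsa
FMO_GBSA          e_int, g_sol_gbsa
FMO_COSMO         e_int, g_sol_cosmo
FMO_PCM           e_int, g_sol_pcm
FMO_SMD           e_int, g_sol_smd
FMO_COSMO_SE      e_int, g_sol_cosmo, e_def        (= FMOScore)
FMO_COSMO_SE_IE   e_int, g_sol_cosmo, e_def, neg_t_ds
================  =============================================

Each target (congeneric ligand series) gets its own ordinary-least-squares
fit of the experimental dG on the form's terms.  Coefficients are never
hardcoded: the model ships as a fitting procedure, and published coefficient
sets can be loaded through the JSON model format if a user has them.

Metrics on these fits are in-sample unless the leave-one-out helper is used;
the benchmark protocol this mirrors reports in-sample fits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.linear_model import LinearRegression

from .errors import MissingTermError, SingularFitError
from .thermo import ComplexEnergyRecord

__all__ = [
    "FunctionForm",
    "FitResult",
    "BenchmarkFit",
    "term_value",
    "fit",
    "predict",
    "fit_benchmark",
    "loo_predictions",
    "save_model",
    "load_model",
]


class FunctionForm(str, Enum):
    """The eight function forms, named (never numbered) for unambiguity."""

    FMO = "FMO"
    FMO_PBSA = "FMO_PBSA"
    FMO_GBSA = "FMO_GBSA"
    FMO_COSMO = "FMO_COSMO"
    FMO_PCM = "FMO_PCM"
    FMO_SMD = "FMO_SMD"
    FMO_COSMO_SE = "FMO_COSMO_SE"
    FMO_COSMO_SE_IE = "FMO_COSMO_SE_IE"

    @property
    def terms(self) -> tuple[str, ...]:
        return _FORM_TERMS[self]


_FORM_TERMS: dict[FunctionForm, tuple[str, ...]] = {
    FunctionForm.FMO: ("e_int",),
    FunctionForm.FMO_PBSA: ("e_int", "g_sol_pbsa"),
    FunctionForm.FMO_GBSA: ("e_int", "g_sol_gbsa"),
    FunctionForm.FMO_COSMO: ("e_int", "g_sol_cosmo"),
    FunctionForm.FMO_PCM: ("e_int", "g_sol_pcm"),
    FunctionForm.FMO_SMD: ("e_int", "g_sol_smd"),
    FunctionForm.FMO_COSMO_SE: ("e_int", "g_sol_cosmo", "e_def"),
    FunctionForm.FMO_COSMO_SE_IE: ("e_int", "g_sol_cosmo", "e_def", "neg_t_ds"),
}


def term_value(rec: ComplexEnergyRecord, term: str) -> float:
    """Extract one named term from a record, raising MissingTermError if absent."""
    if term == "e_int":
        return rec.e_int
    if term.startswith("g_sol_"):
        return rec.solvation(term[len("g_sol_") :])
    if term == "e_def":
        if rec.e_def is None:
            raise MissingTermError(f"complex {rec.complex_id!r} has no e_def term")
        return rec.e_def
    if term == "neg_t_ds":
        if rec.neg_t_ds is None:
            raise MissingTermError(f"complex {rec.complex_id!r} has no neg_t_ds term")
        return rec.neg_t_ds
    raise KeyError(f"unknown term {term!r}")


@dataclass
class FitResult:
    """A fitted function form for one target.

    ``coefficients`` maps each term to its weight (dimensionless, since both
    sides are kcal/mol); ``predictions`` are the in-sample dG_pred values in
    training-row order.
    """

    form: FunctionForm
    target_id: str
    coefficients: dict[str, float]
    intercept: float
    n_points: int
    complex_ids: list[str] = field(default_factory=list)
    predictions: np.ndarray | None = None

    def __post_init__(self) -> None:
        if tuple(self.coefficients) != self.form.terms:
            raise ValueError(
                f"coefficients {tuple(self.coefficients)} do not match the "
                f"{self.form.value} terms {self.form.terms}"
            )

    def to_dict(self) -> dict:
        return {
            "form": self.form.value,
            "target_id": self.target_id,
            "coefficients": self.coefficients,
            "intercept": self.intercept,
            "n_points": self.n_points,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "FitResult":
        return cls(
            form=FunctionForm(d["form"]),
            target_id=d["target_id"],
            coefficients=dict(d["coefficients"]),
            intercept=float(d["intercept"]),
            n_points=int(d["n_points"]),
        )


def _design(records: Sequence[ComplexEnergyRecord], form: FunctionForm) -> np.ndarray:
    return np.array([[term_value(r, t) for t in form.terms] for r in records], dtype=float)


def _predict_row(coefs: Mapping[str, float], intercept: float, values: Mapping[str, float]) -> float:
    out = intercept
    for t, c in coefs.items():
        out += c * values[t]
    return out


def fit(records: Sequence[ComplexEnergyRecord], form: FunctionForm) -> FitResult:
    """Ordinary least squares of dG_exp on the form's terms, with intercept.

    Every record must carry ``dg_exp`` and each term of ``form``; at least
    ``len(terms) + 2`` points are required.  A constant term column or an
    otherwise rank-deficient design raises :class:`SingularFitError` naming
    the offending term where identifiable.  Deterministic for fixed input and
    invariant to row order.
    """
    records = list(records)
    k = len(form.terms)
    if len(records) < k + 2:
        raise ValueError(
            f"{form.value} needs at least {k + 2} records with dg_exp, got {len(records)}"
        )
    missing_exp = [r.complex_id for r in records if r.dg_exp is None]
    if missing_exp:
        raise MissingTermError(f"records without dg_exp cannot be fitted: {missing_exp}")
    x = _design(records, form)
    y = np.array([r.dg_exp for r in records], dtype=float)
    spans = np.ptp(x, axis=0)
    for t, s in zip(form.terms, spans):
        if s == 0:
            raise SingularFitError(
                f"term {t!r} is constant across the {len(records)} records of target "
                f"{records[0].target_id!r}; its coefficient is unidentifiable"
            )
    centered = x - x.mean(axis=0)
    if np.linalg.matrix_rank(centered) < k:
        raise SingularFitError(
            f"design matrix for target {records[0].target_id!r} is rank deficient "
            f"(collinear terms among {form.terms})"
        )
    model = LinearRegression().fit(x, y)
    coefs = {t: float(c) for t, c in zip(form.terms, model.coef_)}
    intercept = float(model.intercept_)
    preds = np.array(
        [
            _predict_row(coefs, intercept, dict(zip(form.terms, row)))
            for row in x
        ]
    )
    return FitResult(
        form=form,
        target_id=records[0].target_id,
        coefficients=coefs,
        intercept=intercept,
        n_points=len(records),
        complex_ids=[r.complex_id for r in records],
        predictions=preds,
    )


def predict(fit_result: FitResult, rec: ComplexEnergyRecord) -> float:
    """dG_pred (kcal/mol) for one record under a fitted form."""
    values = {t: term_value(rec, t) for t in fit_result.form.terms}
    return _predict_row(fit_result.coefficients, fit_result.intercept, values)


@dataclass
class BenchmarkFit:
    """Per-target fits for one function form, plus the targets that failed.

    Behaves as a mapping from target_id to :class:`FitResult`; targets whose
    records do not satisfy the fit preconditions land in ``failures`` with
    the error message instead of being silently dropped.
    """

    form: FunctionForm
    fits: dict[str, FitResult]
    failures: dict[str, str] = field(default_factory=dict)

    def __getitem__(self, target_id: str) -> FitResult:
        return self.fits[target_id]

    def __iter__(self):
        return iter(self.fits)

    def __len__(self) -> int:
        return len(self.fits)

    def items(self):
        return self.fits.items()


def group_by_target(
    records: Iterable[ComplexEnergyRecord],
) -> dict[str, list[ComplexEnergyRecord]]:
    groups: dict[str, list[ComplexEnergyRecord]] = {}
    for r in records:
        groups.setdefault(r.target_id, []).append(r)
    return groups


def fit_benchmark(records: Iterable[ComplexEnergyRecord], form: FunctionForm) -> BenchmarkFit:
    """Fit ``form`` independently on every target present in ``records``."""
    fits: dict[str, FitResult] = {}
    failures: dict[str, str] = {}
    for tid, group in sorted(group_by_target(records).items()):
        try:
            fits[tid] = fit(group, form)
        except (MissingTermError, SingularFitError, ValueError) as exc:
            failures[tid] = str(exc)
    return BenchmarkFit(form=form, fits=fits, failures=failures)


def loo_predictions(records: Sequence[ComplexEnergyRecord], form: FunctionForm) -> np.ndarray:
    """Leave-one-out dG_pred for one target's records.

    Each record is predicted from a fit on the remaining records.  This is an
    optional stricter protocol; the standard benchmark metrics here are
    in-sample.
    """
    records = list(records)
    out = np.empty(len(records))
    for k, rec in enumerate(records):
        rest = records[:k] + records[k + 1 :]
        out[k] = predict(fit(rest, form), rec)
    return out


def save_model(bench: BenchmarkFit, path: str | Path, seed: int | None = None) -> None:
    """Serialize per-target fits as JSON (form, coefficients, provenance)."""
    payload = {
        "format": "fmoscore-model/1",
        "form": bench.form.value,
        "seed": seed,
        "targets": {tid: fr.to_dict() for tid, fr in bench.fits.items()},
        "failures": bench.failures,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_model(path: str | Path) -> BenchmarkFit:
    payload = json.loads(Path(path).read_text())
    form = FunctionForm(payload["form"])
    fits = {tid: FitResult.from_dict(d) for tid, d in payload["targets"].items()}
    return BenchmarkFit(form=form, fits=fits, failures=dict(payload.get("failures", {})))
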