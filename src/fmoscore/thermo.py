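"""Thermodynamic bookkeeping for protein--ligand binding.

The binding free energy in solution is decomposed as

    dG_bind = dE_int + dE_def - T*dS_gas + dG_sol

where ``dE_int`` is the gas-phase protein--ligand interaction energy (the sum
of inter-fragment interaction energies from an FMO calculation), ``dE_def``
the ligand deformation (strain) energy, ``-T*dS_gas`` the gas-phase binding
entropy contribution (e.g. from the interaction-entropy estimator) and
``dG_sol`` the change in implicit-solvation free energy on binding.

This module also converts experimental affinities (IC50 or Kd) to free
energies via dG = kB*T*ln(c / 1 M), which is negative for sub-molar binders,
matching the sign convention of every other term handled here.

All energies are kcal/mol; concentrations are molar; temperatures kelvin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping

from .errors import MissingTermError, SchemaError

__all__ = [
    "KB_KCAL_PER_MOL_K",
    "HARTREE_TO_KCAL",
    "DEFAULT_TEMPERATURE",
    "SOLVATION_MODELS",
    "AffinityKind",
    "AffinityMeasurement",
    "ComplexEnergyRecord",
    "GasPhaseSplit",
    "affinity_to_dg",
    "assemble_dg",
    "gas_phase_split",
]

#: Boltzmann constant in kcal/(mol*K).
KB_KCAL_PER_MOL_K = 0.0019872041

#: Conversion factor applied only at QM-parser boundaries; everything
#: downstream is kcal/mol.
HARTREE_TO_KCAL = 627.509

#: Default temperature (K) for affinity conversion and interaction entropy.
DEFAULT_TEMPERATURE = 300.0

#: Implicit-solvation models a record may carry, keyed lower-case.
SOLVATION_MODELS = ("pbsa", "gbsa", "cosmo", "pcm", "smd")


class AffinityKind(str, Enum):
    """Kind of experimental affinity measurement."""

    IC50 = "IC50"
    KD = "Kd"


@dataclass(frozen=True)
class AffinityMeasurement:
    """An experimental affinity: a positive molar concentration at a temperature.

    IC50 values are treated interchangeably with Kd for the purpose of the
    free-energy conversion, the usual approximation for congeneric inhibitor
    series assayed under fixed conditions.
    """

    value: float
    kind: AffinityKind = AffinityKind.IC50
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        if not (math.isfinite(self.value) and self.value > 0):
            raise ValueError(f"affinity must be a positive finite molar value, got {self.value}")
        if not (math.isfinite(self.temperature) and self.temperature > 0):
            raise ValueError(f"temperature must be positive finite kelvin, got {self.temperature}")


def affinity_to_dg(m: AffinityMeasurement) -> float:
    """Convert an affinity measurement to a binding free energy in kcal/mol.

    dG = kB * T * ln(c / c0) with standard state c0 = 1 M, so sub-molar
    affinities map to negative (favourable) free energies.  Strictly monotone
    increasing in the concentration and linear in its logarithm; a 10-fold
    potency change shifts dG by kB*T*ln(10) ~ 1.37 kcal/mol at 300 K.
    """
    return KB_KCAL_PER_MOL_K * m.temperature * math.log(m.value)


def _check_finite(name: str, value: float | None) -> None:
    if value is not None and not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value}")


@dataclass
class ComplexEnergyRecord:
    """Energy terms and experimental affinity for one protein--ligand complex.

    The row type of the whole pipeline: scoring-function fits consume lists of
    these, grouped by ``target_id``.  Absent optional terms are ``None``; an
    operation that needs an absent term raises :class:`MissingTermError`
    rather than silently treating it as zero.
    """

    complex_id: str
    target_id: str
    e_int: float
    g_sol: dict[str, float] = field(default_factory=dict)
    e_def: float | None = None
    neg_t_ds: float | None = None
    dg_exp: float | None = None
    ic50_molar: float | None = None

    def __post_init__(self) -> None:
        if not self.target_id:
            raise ValueError("target_id must be non-empty")
        _check_finite("e_int", self.e_int)
        for model, value in self.g_sol.items():
            _check_finite(f"g_sol[{model}]", value)
        _check_finite("e_def", self.e_def)
        _check_finite("neg_t_ds", self.neg_t_ds)
        _check_finite("dg_exp", self.dg_exp)
        if self.ic50_molar is not None and not (
            math.isfinite(self.ic50_molar) and self.ic50_molar > 0
        ):
            raise ValueError(f"ic50_molar must be positive finite, got {self.ic50_molar}")

    def solvation(self, model: str) -> float:
        """Return dG_sol for ``model`` (case-insensitive) or raise MissingTermError."""
        key = model.lower()
        try:
            return self.g_sol[key]
        except KeyError:
            raise MissingTermError(
                f"complex {self.complex_id!r} has no solvation term for model {model!r}; "
                f"available: {sorted(self.g_sol) or 'none'}"
            ) from None


def assemble_dg(
    rec: ComplexEnergyRecord,
    solvation_model: str | None = "cosmo",
    include_def: bool = True,
    include_entropy: bool = True,
) -> float:
    """Unweighted sum of the selected free-energy terms of ``rec`` (kcal/mol).

    This is the raw thermodynamic assembly

        dG = dE_int + dG_sol(model) [+ dE_def] [+ (-T*dS)]

    with no fitted coefficients (for those see :mod:`fmoscore.scoring`).
    Passing ``solvation_model=None`` omits the solvation term; omitting a term
    is identical to it being zero.  Requesting a term the record does not
    carry raises :class:`MissingTermError` naming the term.
    """
    total = rec.e_int
    if solvation_model is not None:
        total += rec.solvation(solvation_model)
    if include_def:
        if rec.e_def is None:
            raise MissingTermError(f"complex {rec.complex_id!r} has no deformation energy (e_def)")
        total += rec.e_def
    if include_entropy:
        if rec.neg_t_ds is None:
            raise MissingTermError(f"complex {rec.complex_id!r} has no entropy term (neg_t_ds)")
        total += rec.neg_t_ds
    return total


@dataclass(frozen=True)
class GasPhaseSplit:
    """Decomposition of the gas-phase binding enthalpy (kcal/mol)."""

    e_int: float
    e_def: float
    dh_gas: float


def gas_phase_split(
    e_com: float, e_pro: float, e_lig_bound: float, e_lig_free: float
) -> GasPhaseSplit:
    """Split component energies into interaction, deformation and total enthalpy.

    dE_int  = E(complex) - E(protein) - E(ligand, bound conformation)
    dE_def  = E(ligand, bound conformation) - E(ligand, relaxed)
    dH_gas  = dE_int + dE_def = E(complex) - E(protein) - E(ligand, relaxed)

    The last identity holds exactly by construction for any finite inputs.
    """
    for name, v in (
        ("e_com", e_com),
        ("e_pro", e_pro),
        ("e_lig_bound", e_lig_bound),
        ("e_lig_free", e_lig_free),
    ):
        if not math.isfinite(v):
            raise ValueError(f"{name} must be finite, got {v}")
    e_int = e_com - e_pro - e_lig_bound
    e_def = e_lig_bound - e_lig_free
    return GasPhaseSplit(e_int=e_int, e_def=e_def, dh_gas=e_int + e_def)


def record_from_mapping(row: Mapping[str, object]) -> ComplexEnergyRecord:
    """Build a record from a flat mapping using the CSV column contract.

    Solvation terms live in ``g_sol_<model>`` keys; missing/None/NaN entries
    become absent terms.
    """

    def _opt(key: str) -> float | None:
        v = row.get(key)
        if v is None:
            return None
        v = float(v)  # type: ignore[arg-type]
        return None if math.isnan(v) else v

    e_int = _opt("e_int")
    if e_int is None:
        raise SchemaError(f"row {row.get('complex_id')!r} lacks the mandatory e_int value")
    g_sol = {}
    for model in SOLVATION_MODELS:
        v = _opt(f"g_sol_{model}")
        if v is not None:
            g_sol[model] = v
    return ComplexEnergyRecord(
        complex_id=str(row["complex_id"]),
        target_id=str(row["target_id"]),
        e_int=e_int,
        g_sol=g_sol,
        e_def=_opt("e_def"),
        neg_t_ds=_opt("neg_t_ds"),
        dg_exp=_opt("dg_exp"),
        ic50_molar=_opt("ic50_molar"),
    )
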