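"""Synthetic benchmarks and parser fixtures.

Real inputs to this package are energy tables computed by quantum-chemistry
and MD engines over curated benchmark structures.  The generators here
emulate the statistical shape of such tables so the whole pipeline is
testable without any QM, MD or download:

* :func:`gen_benchmark` draws per-target ligand series whose experimental dG
  is a noisy linear function of the energy terms.  Default magnitudes mimic a
  large, partially cancelling decomposition — interaction energy around
  -140 +/- 30 kcal/mol against a solvation penalty around +100 +/- 25, a few
  kcal/mol of ligand strain, and experimental dG around -9 +/- 2 kcal/mol —
  the regime in which the linear fit is genuinely nontrivial.
* :func:`gen_interaction_series` draws i.i.d. Gaussian interaction-energy
  "frames", the stand-in for MD snapshots feeding the interaction-entropy
  estimator (whose Gaussian closed form beta*sigma^2/2 makes it an oracle).
* :func:`gen_qm_fixture_texts` renders a PiedaTable and a solvation pair into
  the fixture text dialect of :mod:`fmoscore.qm_io`, making generator->parser
  round-trips the parsing oracle.

All generators are pure functions of (parameters, seed).  What this synthetic
data does not emulate: correlated errors between energy terms, non-Gaussian
experimental noise, autocorrelated MD frames, and real QM table formatting
quirks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .pieda import Fragment, PairInteraction, PiedaTable
from .thermo import (
    DEFAULT_TEMPERATURE,
    KB_KCAL_PER_MOL_K,
    SOLVATION_MODELS,
    ComplexEnergyRecord,
)
from .entropy_ie import InteractionSeries

__all__ = [
    "BenchmarkDesign",
    "GroundTruth",
    "FixtureTexts",
    "gen_benchmark",
    "gen_interaction_series",
    "gen_qm_fixture_texts",
    "gen_random_pieda_table",
    "noise_sd_for_design_r",
]

_DEFAULT_COEFFICIENTS = {"e_int": 0.05, "g_sol_cosmo": 0.05, "e_def": 0.3}
_DEFAULT_TERM_MEANS = {"e_int": -140.0, "g_sol_cosmo": 100.0, "e_def": 5.0, "neg_t_ds": 15.0}
_DEFAULT_TERM_SDS = {"e_int": 30.0, "g_sol_cosmo": 25.0, "e_def": 3.0, "neg_t_ds": 5.0}


@dataclass
class BenchmarkDesign:
    """Design of a synthetic multi-target binding benchmark.

    Defaults model an eight-target benchmark of congeneric series (about 30
    ligands each), with experimental dG generated from the FMOScore terms
    (interaction energy, COSMO solvation, deformation) plus Gaussian noise of
    1 kcal/mol — roughly the uncertainty of a well-run biochemical assay and
    a signal-to-noise giving a population correlation near 0.9.  The entropy
    term is drawn but does not enter the true dG, mirroring its role as a
    candidate regressor that the final scoring function dropped.
    """

    seed: int
    n_targets: int = 8
    ligands_per_target: int = 30
    coefficients: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_COEFFICIENTS))
    intercept: float = -8.5
    term_means: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_TERM_MEANS))
    term_sds: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_TERM_SDS))
    noise_sd: float = 1.0
    #: SD of the disagreement between alternative solvation models and COSMO.
    solvation_spread: float = 5.0

    def __post_init__(self) -> None:
        if self.n_targets < 1:
            raise ValueError("n_targets must be >= 1")
        if self.ligands_per_target < 1:
            raise ValueError("ligands_per_target must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        unknown = set(self.coefficients) - set(self.term_means)
        if unknown:
            raise ValueError(f"coefficients reference terms without distributions: {unknown}")

    @property
    def signal_sd(self) -> float:
        """SD of the deterministic part of dG (terms drawn independently)."""
        return math.sqrt(
            sum((c * self.term_sds[t]) ** 2 for t, c in self.coefficients.items())
        )

    @property
    def population_r(self) -> float:
        """Population correlation between true linear signal and noisy dG_exp."""
        s = self.signal_sd
        return s / math.sqrt(s**2 + self.noise_sd**2)


@dataclass(frozen=True)
class GroundTruth:
    """The generating model behind a synthetic benchmark, for recovery tests."""

    coefficients: dict[str, float]
    intercept: float
    noise_sd: float
    signal_sd: float
    population_r: float


def noise_sd_for_design_r(
    design: BenchmarkDesign, r: float, insample_n: int | None = None
) -> float:
    """Noise SD that yields a design correlation of ``r`` for this benchmark.

    With ``insample_n`` set, corrects for the upward bias of in-sample OLS
    correlation (E[R^2] ~ rho^2 + (1-rho^2) k/(n-1) for k regressors on n
    points), so that the expected *fitted* in-sample R matches ``r`` — the
    relevant calibration when the evaluation protocol is in-sample fitting.
    """
    if not 0 < r < 1:
        raise ValueError("design r must be in (0, 1)")
    rho2 = r**2
    if insample_n is not None:
        k = len(design.coefficients)
        if insample_n <= k + 1:
            raise ValueError("insample_n too small for the bias correction")
        shrink = k / (insample_n - 1)
        rho2 = (r**2 - shrink) / (1.0 - shrink)
        if rho2 <= 0:
            raise ValueError(f"design r={r} unreachable with n={insample_n} points")
    return design.signal_sd * math.sqrt(1.0 / rho2 - 1.0)


def gen_benchmark(design: BenchmarkDesign) -> tuple[list[ComplexEnergyRecord], GroundTruth]:
    """Draw a synthetic benchmark: records plus the generating coefficients.

    Per ligand, each term in ``term_means`` is an independent Gaussian draw;
    the four alternative solvation models (PBSA/GBSA/PCM/SMD) are the COSMO
    value plus Gaussian model disagreement of SD ``solvation_spread``.
    dG_exp = intercept + sum(coef * term) + N(0, noise_sd), and the implied
    IC50 is back-computed from dG_exp at 300 K.  Deterministic per seed.
    """
    rng = np.random.default_rng(design.seed)
    kt = KB_KCAL_PER_MOL_K * DEFAULT_TEMPERATURE
    records: list[ComplexEnergyRecord] = []
    for t in range(design.n_targets):
        tid = f"T{t + 1:02d}"
        for lig in range(design.ligands_per_target):
            terms = {
                name: rng.normal(design.term_means[name], design.term_sds[name])
                for name in design.term_means
            }
            dg = design.intercept + rng.normal(0.0, design.noise_sd)
            for name, coef in design.coefficients.items():
                dg += coef * terms[name]
            cosmo = terms["g_sol_cosmo"]
            g_sol = {"cosmo": cosmo}
            for model in SOLVATION_MODELS:
                if model != "cosmo":
                    g_sol[model] = cosmo + rng.normal(0.0, design.solvation_spread)
            records.append(
                ComplexEnergyRecord(
                    complex_id=f"{tid}_L{lig + 1:03d}",
                    target_id=tid,
                    e_int=terms["e_int"],
                    g_sol=g_sol,
                    e_def=terms["e_def"],
                    neg_t_ds=terms["neg_t_ds"],
                    dg_exp=dg,
                    ic50_molar=math.exp(dg / kt),
                )
            )
    truth = GroundTruth(
        coefficients=dict(design.coefficients),
        intercept=design.intercept,
        noise_sd=design.noise_sd,
        signal_sd=design.signal_sd,
        population_r=design.population_r,
    )
    return records, truth


def gen_interaction_series(
    mean: float,
    sd: float,
    n: int,
    temperature: float = DEFAULT_TEMPERATURE,
    seed: int = 0,
) -> InteractionSeries:
    """i.i.d. Gaussian interaction-energy frames (kcal/mol); sd=0 gives a constant series.

    For Gaussian fluctuations the interaction-entropy estimator has the
    closed form -T*dS = beta*sigma^2/2 = sigma^2 / (2 kB T), which makes these
    series the estimator's accuracy oracle.
    """
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    values = mean + sd * rng.standard_normal(n) if sd > 0 else np.full(n, float(mean))
    return InteractionSeries(values=values, temperature=temperature)


@dataclass(frozen=True)
class FixtureTexts:
    """Parser-fixture texts: an FMO PIEDA output and a MOPAC gas/solvated pair."""

    fmo_text: str
    mopac_gas_text: str
    mopac_solvated_text: str


def _fmt_pieda_text(table: PiedaTable) -> str:
    lines = [
        " SYNTHETIC FMO-PIEDA OUTPUT (fmoscore fixture dialect)",
        " ENERGY UNITS: KCAL/MOL",
        "",
        f" FRAGMENT LIST   NFRAG= {len(table.fragments):4d}",
    ]
    for k, frag in enumerate(table.fragments, start=1):
        tag = "   LIGAND" if frag.is_ligand else ""
        lines.append(f" {k:5d}  {frag.label}{tag}")
    lines += [
        "",
        " PAIR INTERACTION ENERGY DECOMPOSITION ANALYSIS (PIEDA)",
        f" {'I':>5} {'J':>5} {'ES':>13} {'EX':>13} {'CT+MIX':>13} {'DI':>13} {'TOTAL':>13}",
    ]
    for p in table.pairs:
        lines.append(
            f" {p.i + 1:5d} {p.j + 1:5d} {p.es:13.4f} {p.ex:13.4f} "
            f"{p.ct_mix:13.4f} {p.di:13.4f} {p.total:13.4f}"
        )
    lines.append(" END PIEDA")
    return "\n".join(lines) + "\n"


def _fmt_mopac_text(hof: float, cosmo: bool) -> str:
    solv = " (COSMO, EPS=78.4)" if cosmo else " (GAS PHASE)"
    return (
        f" *** SYNTHETIC MOPAC-STYLE PM7 OUTPUT{solv} ***\n"
        "\n"
        "          SCF FIELD WAS ACHIEVED\n"
        "\n"
        f"          FINAL HEAT OF FORMATION = {hof:15.5f} KCAL/MOL\n"
        "\n"
        "          JOB ENDED NORMALLY\n"
    )


def gen_qm_fixture_texts(
    table: PiedaTable,
    g_gas: float = -140.0,
    g_solvated: float = -150.0,
) -> FixtureTexts:
    """Render a PiedaTable and a solvation pair as parser-conformant text.

    The emitted texts parse back (via :func:`fmoscore.qm_io.parse_fmo_output`
    and :func:`fmoscore.qm_io.parse_mopac_cosmo`) to the input values; energy
    fields are printed with 4 decimals, so supply values rounded to 1e-4 for
    an exact round-trip.
    """
    return FixtureTexts(
        fmo_text=_fmt_pieda_text(table),
        mopac_gas_text=_fmt_mopac_text(g_gas, cosmo=False),
        mopac_solvated_text=_fmt_mopac_text(g_solvated, cosmo=True),
    )


def gen_random_pieda_table(
    n_residues: int, seed: int, ligand_label: str = "L:LIG:1", pair_fraction: float = 1.0
) -> PiedaTable:
    """Random decomposed PIE table with one ligand fragment and ``n_residues`` residues.

    Component magnitudes loosely follow ligand--residue interactions in a
    buried pocket (ES and DI attractive, EX repulsive); all values rounded to
    4 decimals with totals equal to the exact component sums, so text
    round-trips are lossless.  ``pair_fraction`` < 1 leaves some residues
    without a ligand pair.
    """
    if n_residues < 0:
        raise ValueError("n_residues must be >= 0")
    rng = np.random.default_rng(seed)
    aa = ("ALA", "ARG", "GLU", "THR", "LEU", "PRO", "GLN", "LYS", "HIS", "SER")
    fragments = [
        Fragment(label=f"A:{aa[i % len(aa)]}:{100 + i}") for i in range(n_residues)
    ]
    fragments.append(Fragment(label=ligand_label, is_ligand=True))
    lig = n_residues
    pairs = []
    for i in range(n_residues):
        if rng.random() > pair_fraction:
            continue
        es = round(float(rng.normal(-5.0, 4.0)), 4)
        ex = round(float(abs(rng.normal(4.0, 3.0))), 4)
        ct = round(float(rng.normal(-2.0, 2.0)), 4)
        di = round(float(rng.normal(-3.0, 2.0)), 4)
        pairs.append(PairInteraction(i=i, j=lig, es=es, ex=ex, ct_mix=ct, di=di))
    return PiedaTable(fragments=fragments, pairs=pairs)
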