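# Methods

## Thermodynamic model

The binding free energy in solution is decomposed as

    ΔG_bind = ΔE_int + ΔE_def^lig − TΔS_gas + ΔG_sol

with the gas-phase enthalpy split

    ΔE_int = E_com − E_pro − E_lig(com)
    ΔE_def = E_lig(com) − E_lig
    ΔH_gas = ΔE_int + ΔE_def = E_com − E_pro − E_lig

an exact algebraic identity that the code preserves bit-for-bit (a property
test asserts it on random tuples). ΔE_int is the sum of ligand–residue
inter-fragment interaction energies from an FMO2 calculation; ΔG_sol comes
from an implicit-solvent model applied to the same complex/protein/ligand
species; ΔE_def is the strain paid by the ligand to adopt its bioactive
conformation; −TΔS_gas is estimated, when used at all, by the
interaction-entropy method.

**Experimental affinities.** IC50 or Kd values are converted as
ΔG = k_B·T·ln(c/c°), c° = 1 M, natural log, k_B = 0.0019872041 kcal/(mol·K),
default T = 300 K (overridable; whether a given dataset was converted at 298
or 300 K is rarely reported, and the 0.7% difference is far below assay
noise). The sign convention makes sub-molar affinities negative
(favourable), consistent with every other term in the decomposition; a
literal reading of the common shorthand "−k_BT·log(IC50)" would flip the
sign for potent binders and is deliberately not used. All internal energies
are kcal/mol; Hartree→kcal/mol conversion (627.509) happens only at parser
boundaries, and only when a unit banner announces Hartree — never silently.

## Scoring functions

Eight nested linear forms combine the terms (see README table). Fits are
per-target ordinary least squares with intercept — each congeneric series
gets its own coefficients, reflecting that the absolute scale of summed PIEs
varies strongly between binding sites. Preconditions: every record carries
ΔG_exp and the form's terms, and n ≥ (number of terms) + 2. A constant term
column raises a singular-fit error naming the term rather than returning an
arbitrary coefficient. Metrics are in-sample, matching the evaluation
protocol this package mirrors, which describes no train/test split; a
leave-one-out helper (`scoring.loo_predictions`) is provided for users who
want an out-of-sample view, clearly separate from the standard protocol.
Coefficients are never hardcoded; published coefficient sets can be loaded
through the JSON model format.

Because the forms are nested, in-sample R is monotone over the chain
FMO ⊆ FMO_COSMO ⊆ FMO_COSMO_SE — asserted as an invariant (an OLS superset
of regressors cannot fit worse in-sample).

## Interaction entropy

−TΔS = k_BT·ln⟨exp(βΔE)⟩ over the mean-centred fluctuation ΔE of the
protein–ligand gas-phase interaction energy along an MD trajectory.
Numerics: evaluated as k_BT·(logsumexp(βΔE) − ln N) with max shift; at 300 K
β ≈ 1.68 mol/kcal, so the naive exponential overflows near 400 kcal/mol of
fluctuation and loses precision much earlier. The estimate is ≥ 0 by
Jensen's inequality (mean-centred argument); sub-epsilon negative rounding
is clamped to zero. A warning fires when β·max(ΔE) > 20, where a handful of
frames dominate the average and the estimator is known to be untrustworthy.
Gaussian fluctuations give the closed form βσ²/2, used as the accuracy
oracle (relative error < 5% at N = 10⁵, σ = 1 kcal/mol). Convergence is
probed by estimates over contiguous equal-length blocks (trailing remainder
dropped); a converged series shows small block spread.

## Deformation energy

Duplicate conformers are grouped by single-linkage over the relation
|ΔE| ≤ 0.1 kcal/mol AND RMSD ≤ 0.5 Å (defaults; both exposed). Thresholds at
this scale treat conformers within thermal noise and sub-bond-length
geometry differences as one structure; upstream conformer generators emit no
canonical values, so these are this package's own defaults. Each group keeps
its lowest-energy member (energy ties broken by conformer id, making the
result independent of input order). The reference energy is the minimum over
the k = 3 lowest representatives — mirroring workflows that re-optimise only
the best few conformers before the final single point — and
ΔE_def = E(bound) − E(reference). Negative values are possible when the
ensemble missed the relaxed neighbour of the bound pose; they are returned
with a warning, never clamped, because clamping would hide the upstream
sampling failure. Whether the reference is a gas-phase or solvent-phase
minimum is the caller's choice: the module takes energies as given.

## Benchmark statistics

Pearson product-moment R, Kendall τ-b (tie-corrected — plausible with
rounded ΔG data), RMSE, MUE, R² (= squared Pearson R), and the fraction of
predictions within 2 kcal/mol of experiment. Zero variance in either vector
raises an undefined-metric error, deliberately distinct from reporting 0.

Confidence intervals are 95% percentile bootstrap over resampled ligand
pairs, 10,000 repetitions by default, fully seeded. Resamples on which a
metric is undefined (e.g. all-tied draws) are redrawn and counted; the loop
aborts if undefined draws exceed 100× the requested repetitions. "Averaged"
statistics are unweighted means of per-target point estimates (no
ligand-count weighting — each target is one benchmark case); their CIs come
from resampling within each target per repetition and averaging, so small
series retain their weight. Pooling all targets into one vector before
bootstrapping is implemented nowhere because per-target intercepts make
pooled absolute metrics incomparable; ΔΔG tables (per-target reference
ligand, offset-invariant) are the supported cross-target comparison.

## Synthetic benchmark generator

`gen_benchmark` emulates the statistical shape of a multi-target
curated-benchmark energy table: 8 targets × 30 ligands by default (the scale
of a ~250-complex, eight-target benchmark), terms drawn i.i.d. Gaussian per
ligand with ΔE_int ≈ −140 ± 30, ΔG_sol ≈ +100 ± 25, ΔE_def ≈ +5 ± 3,
−TΔS ≈ +15 ± 5 kcal/mol — anchored to the magnitude of a representative
inhibitor's summed PIE (≈ −140 kcal/mol) and typical ΔG_exp ≈ −9 ± 2 — so
the large-but-cancelling regime that makes the linear fit nontrivial is
represented. True coefficients (0.05, 0.05, 0.3; intercept −8.5) scale those
terms onto the experimental range; ΔG noise is 1.0 kcal/mol, a typical
biochemical-assay uncertainty, giving population R ≈ 0.91. The four non-COSMO
solvation models are the COSMO value plus Gaussian disagreement (σ = 5
kcal/mol); the entropy term is drawn but excluded from the true ΔG,
mirroring its role as a candidate regressor the final score dropped.
`noise_sd_for_design_r` inverts the signal/noise relation for a requested
design correlation, optionally correcting for in-sample OLS inflation
(E[R²] ≈ ρ² + (1−ρ²)k/(n−1)) so that the *fitted* in-sample R matches the
request.

Not emulated: correlated errors between energy terms, heavy-tailed assay
noise, autocorrelated MD frames, series-specific activity cliffs, and real
QM log formatting quirks. Passing tests therefore demonstrate the
correctness of the fitting/evaluation machinery and estimators under the
stated statistical model, not the physical accuracy of any QM engine.

## Parser dialect

One documented fixed-width PIEDA layout (fragment list with a `LIGAND` tag;
rows of I, J, ES, EX, CT+MIX, DI, TOTAL in kcal/mol) modelled on FMO 5.1
listings, read with whitespace-tolerant parsing so loosely aligned variants
also load. Real GAMESS logs vary across versions and print levels; full
multi-version fidelity is out of scope. Stored pair totals must agree with
their component sum within 0.05 kcal/mol (printed tables round components
individually; an aggregate printed beside four rounded components can differ
by a kcal/mol or two, which is why the bundled reference fixture sums to
−140 while the aggregate quoted with it is −141.7). MOPAC-style outputs must
contain exactly one final heat of formation each; the solvation free energy
is solvated minus gas.

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` run the estimator oracles at
N = 10⁵ frames, the identity and metric properties at 10⁴ random draws,
parser round-trips over 100 random fixtures, benchmark recovery on the
default 8 × 30 design, and bootstrap CI coverage at 500–2,000 replications
of 1,000–2,000 resamples — sizes at which every Monte-Carlo tolerance above
is comfortably resolved while the whole suite completes in well under a
minute on one core.
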