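# fmoscore

Binding free-energy scoring for structure-based drug design, built on energy
terms from fragment molecular orbital (FMO) calculations.

Force-field scoring struggles with the weak interactions (CH–π, cation–π,
halogen–π) that often decide congeneric-series potency, while full quantum
mechanics on a protein–ligand complex is prohibitive. The FMO method makes
ab initio QM tractable by fragmenting the system (one residue per fragment)
and reconstructing the energy from monomer and dimer terms (FMO2), yielding
per-residue pair interaction energies (PIE/IFIE) and their PIEDA
decomposition into electrostatics (ES), exchange repulsion (EX), charge
transfer (CT+MIX) and dispersion (DI). But the gas-phase interaction energy
alone is not a binding free energy: solvation, ligand strain and entropy all
contribute.

This package implements the scoring side of that workflow. Its model family
combines, per protein target, the terms of the thermodynamic decomposition

```
ΔG_bind = ΔE_int + ΔE_def^lig − TΔS_gas + ΔG_sol
```

by ordinary least squares against experimental affinities:

```
ΔG_pred = c₀ + c₁·ΔE_int + c₂·ΔG_sol(COSMO) + c₃·ΔE_def        (FMO_COSMO_SE)
```

with seven sibling forms (interaction energy alone; PBSA/GBSA/COSMO/PCM/SMD
solvation variants; an additional interaction-entropy term). The package
also provides

- parsers for GAMESS-FMO-style PIEDA listings and MOPAC-style PM7/COSMO
  outputs (`fmoscore.qm_io`),
- PIEDA bookkeeping: ligand PIE sums and ranked per-residue interaction
  profiles (`fmoscore.pieda`),
- conformer-ensemble deduplication and deformation (strain) energy
  (`fmoscore.deformation`),
- the interaction-entropy estimator −TΔS = k_BT·ln⟨exp(βΔE)⟩ over MD
  interaction-energy fluctuations, with overflow-safe evaluation and block
  convergence diagnostics (`fmoscore.entropy_ie`),
- benchmark statistics — Pearson R, Kendall τ-b, RMSE, MUE, R², fraction of
  predictions within 2 kcal/mol, ΔΔG tables — with percentile-bootstrap
  confidence intervals (`fmoscore.stats_eval`),
- a synthetic-benchmark generator emulating the statistical shape of real
  multi-target energy tables (`fmoscore.synthetic`).

The quantum chemistry and MD themselves (GAMESS, MOPAC, Gaussian, xtb,
Amber) run upstream; fmoscore consumes their energies.

## Worked example

```python
import fmoscore as f

# a synthetic 8-target benchmark, ~30 ligands per target, ΔG noise 1 kcal/mol
design = f.BenchmarkDesign(seed=5)
records, truth = f.gen_benchmark(design)

bench = f.fit_benchmark(records, f.FunctionForm.FMO_COSMO_SE)
stats = f.evaluate_benchmark(bench, records, n_reps=2000, seed=1)
avg = stats.averaged.values
lo, hi = stats.averaged.ci["pearson_r"]
print(f"average Pearson R = {avg['pearson_r']:.3f} (95% CI {lo:.3f}–{hi:.3f})")
print(f"average RMSE      = {avg['rmse']:.3f} kcal/mol")
```

prints

```
average Pearson R = 0.892 (95% CI 0.860–0.916)
average RMSE      = 0.986 kcal/mol
```

i.e. per-target linear fits on the three FMOScore terms recover the
generator's designed signal-to-noise (population R ≈ 0.91 at these settings),
and the average error sits near the 1 kcal/mol experimental noise floor.
The same flow works from the shell:

```bash
fmoscore synth benchmark --seed 5 -o bench/
fmoscore fit bench/energies.csv --form FMO_COSMO_SE -o model.json
fmoscore evaluate bench/energies.csv --reps 10000 --seed 1 -o stats.json
fmoscore pieda fixtures/fmo_pieda.out --top 10        # per-residue profile
fmoscore ie series.txt --temperature 300 --blocks 5   # interaction entropy
```

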