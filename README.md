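# suprafibre

Mechanism, kinetics and structure of monomer exchange in supramolecular
fibre models.

Supramolecular polymers — here, fibres of stacked
benzene-1,3,5-tricarboxamide (BTA) monomers held together by core
stacking and threefold H-bonding — continuously exchange monomers with
the surrounding solution. Exchange is not a single event: a monomer
first escapes from a structural defect (*hot spot*) onto the fibre
surface (**Step 1**, A→B, barrier ~2 kcal/mol in water, ~µs), and only
then jumps into the solvent (**Step 2**, B→C, ~10 kcal/mol, ~ms).
Creating a hot spot from the ordered interior (**Step 0**) is slower
still, which is why exchange originates at defects. `suprafibre` gives a
desk-scale, fully synthetic implementation of the machinery behind that
picture, for computational chemists who want the estimators without the
cluster:

- **Model landscapes** with labelled A/B/C exchange states and designed
  barriers (water-soluble fibres 1 and 2, the BTA-C6 stack in pentane
  and gas phase, core-interaction ε-scaling variants, an H-bond-free
  variant).
- **Sampling**: overdamped/BAOAB Langevin dynamics, well-tempered
  metadynamics, and three free-energy-surface estimators (bias
  inversion F = −γ/(γ−1)·V, standard metadynamics, Boltzmann-inverted
  histograms), with PLUMED-dialect HILLS/COLVAR/FES text I/O.
- **Kinetics**: infrequent metadynamics with the rescaled transition
  time t = t_MetaD·⟨e^{βV(s,t)}⟩, Poisson fits of the rare-event law
  P(n≥1) = 1 − e^{−t/τ} (τ = sample mean), parametric-bootstrap
  Kolmogorov–Smirnov reliability checks, and the t0–t4 timescale table.
- **Structure**: synthetic coarse-grained fibres with injectable defects;
  per-monomer coordination (rational switching function), solvent
  accessible surface area (sphere-point rolling probe), incorporation
  energy ΔE (12-6 + screened charges), hot-spot classification
  (coordination ≤ 1 and SASA above average) and the ΔE–SASA regression.
- **Dynamics**: surrogate trajectories with designed residence kinetics;
  axial Δz analysis, drift-velocity-vs-radius profiles, hysteresis
  residence/hopping extraction.

## Worked example

```python
from suprafibre.pipeline import recover_barrier, step1_tau
from suprafibre.kinetics import seconds_per_reduced_time
from suprafibre.fibre import default_defected_ensemble
from suprafibre.structure import (compute_monomer_metrics, classify_hot_spots,
                                  regress_dE_sasa, SwitchingParams)

# Step-1 free-energy barrier from converged WT-MetaD + bias inversion
barrier, fes = recover_barrier("fibre1_step1", "A", "B", seed=11)
print(f"Step-1 barrier (A->B): {barrier:.2f} kcal/mol")

# characteristic escape time from 20 infrequent-metadynamics replicas
fit = step1_tau("fibre1_step1", n_replicas=20, seed=11)
kappa = seconds_per_reduced_time()
print(f"Step-1 escape time t1: {fit.tau * kappa:.3g} s  (KS p = {fit.p_value:.2f})")

# structural hot spots on the default defected 80-mer ensemble
frames = default_defected_ensemble()
mets = compute_monomer_metrics(frames)
print(regress_dE_sasa(mets).summary())
hard = compute_monomer_metrics(frames[:2], sw=SwitchingParams(mode="hard_cutoff"),
                               n_sphere_points=240)
print(f"hot spots: {sorted(classify_hot_spots(hard))}")
```

prints

```
Step-1 barrier (A->B): 2.15 kcal/mol
Step-1 escape time t1: 1.4e-06 s  (KS p = 0.31)
ΔE = +0.0200·SASA -14.08  (R² = 0.9805, n = 80)
hot spots: [11, 12, 31, 32, 43, 44, 45, 54, 55]
```

The recovered barrier sits on the designed 2 kcal/mol (hill-noise
±0.1–0.2); the fitted escape time lands on the µs scale the Step-1
process represents, and the KS p-value says the 20 rescaled times are
consistent with the exponential rare-event law. On the defected fibre,
incorporation energy weakens linearly as solvent exposure grows
(R² ≈ 0.98) and the flagged hot spots are exactly the fragment-end and
isolated monomers created by the injected breaks.

A `suprafibre` command-line tool wraps the same pipelines
(`suprafibre generate`, `suprafibre sample metad`, `suprafibre kinetics`,
`suprafibre pipeline`, …); see `suprafibre --help`.

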