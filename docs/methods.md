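# Methods

`suprafibre` re-creates, at desk scale, the computational machinery used to
study how monomers exchange in and out of supramolecular BTA
(benzene-1,3,5-tricarboxamide) fibres: enhanced-sampling free-energy
reconstruction, rare-event kinetics from biased simulations, and the
structural/dynamical analyses that identify exchange *hot spots* on the
fibre surface. Multi-microsecond coarse-grained MD of solvated fibres is
not reproducible on a workstation, so every input is synthetic and
*designed*: model landscapes carry the reported barrier heights of the original study conditions, synthetic
fibres carry injectable defects with the reported structural signatures,
and surrogate trajectories carry designed residence kinetics. The
implemented estimators must then recover those designed values — that is
the package's validation logic, and it is what the test suite and
`scripts/acceptance.py` check.

## Model free-energy landscapes

A landscape is a sum of negative Gaussian wells plus quartic confining
walls on a 1-D (optionally 2-D) collective-variable (CV) space, with
labelled metastable states:

- **A** — monomer stacked on a surface hot spot,
- **B** — monomer adsorbed on the fibre surface,
- **C** — monomer dissolved in the solvent,
- **A0** (optional) — monomer buried in the fibre interior.

Only barrier heights and state topologies are specified by the study
conditions, not functional forms, so the Gaussian-plus-walls form is our
choice. Well depths are
calibrated numerically (least squares on a refined grid scan) so that the
analytic saddle-minus-minimum barrier equals the designed value to better
than 1e-6 kcal/mol; entries with more states additionally pin relative
state levels. The catalogue encodes:

| entry | designed barriers (kcal/mol) |
|---|---|
| `fibre1_step1` | A→B = 2.0 |
| `fibre2_step1` | A→B = 2.0 + kBT·ln 10 ≈ 3.373 |
| `fibre1_step2` | B→C = 10.0 |
| `fibre2_step2` | B→C = 20.0 (solvent-jump penalty doubled) |
| `pentane` | A→B = 3.0, B→C = 15.0 |
| `gas` | A→B = 12.0, B→C = 30.0 |
| `eps075/eps15/eps30_step1` | A→B from Kramers inversion of the designed t1 |
| `noHB_step1` | A→B = 0.214 (H-bond charges removed) |
| `fibre1_step0` | A0→A ≈ 9.55 (hot-spot creation, ~0.3 s scale) |

**The Step-1 family and the smoothstep shelf.** The slow Step-1 variants
(fibre 2, 1.5ε, 3ε) share the fibre-1 double well *exactly*; their extra
barrier is a compact quintic smoothstep "shelf" placed on the A-side slope
(fully flat before the saddle). Well and saddle shapes — hence the Kramers
prefactor — are therefore identical across the sub-family, and designed
escape-time ratios follow exp(ΔΔG/kBT) up to a small (<10%) dilution from
the ramp zone; the exact overdamped mean-first-passage-time (MFPT)
quadrature gives 8.3 for the nominal factor-10 fibre-2/fibre-1 ratio,
i.e. 0.92 decades. Raising a barrier by deepening a Gaussian well instead
changes the well curvature and silently shifts the prefactor — that design
was measured (double-integral MFPT) to give a ratio of ~6 and was
discarded for the shelf construction.

The fast variants (0.75ε, noHB) use correspondingly shallower independent
double wells. Their barriers come from Kramers inversion of the designed
Step-1 times with the prefactor pinned by the reference (2.0 kcal/mol ↔
1 µs): ΔG = 2.0 + kBT·ln(t1/1 µs). For 0.75ε the mid-range inversion
target would give a non-positive barrier, so the upper end of its
reported 10–100 ns range (t1 = 1e-7 s → ΔG = 0.627 kcal/mol) is used;
noHB uses t1 = 5e-8 s → ΔG = 0.214 kcal/mol. These two timescales are
ordering-level calibrations, not predictions: with different well depths
their prefactors differ, so only the qualitative ε-ladder ordering
(0.75ε < 1ε < 1.5ε < 3ε, noHB < 1ε) is designed, and only that ordering is
asserted.

**Units and time calibration.** Landscape energies are kcal/mol; CV space
and time are dimensionless (diffusion D = 0.1 CV²/time for every entry).
One calibration constant per designed step maps reduced time to seconds:
`seconds_per_reduced_time()` pins the fibre-1 Step-1 escape to its
designed 1 µs via the exact MFPT quadrature. kB = 0.0019872041
kcal/(mol·K), T = 300 K throughout.

## Sampling

- **Integrators.** Overdamped Euler–Maruyama (default for CV dynamics;
  D = kBT/friction) and underdamped BAOAB (unit mass). Stability requires
  dt·friction < 2; the default dt = 0.01 keeps β·D·U″·dt ≲ 0.5 on the
  stiffest catalogue entry.
- **Well-tempered metadynamics.** Gaussian hills of height
  w0·exp(−V/(kBΔT)), ΔT = (γ−1)T. The bias is cached on a grid (default
  spacing 0.05 CV units) updated incrementally at each deposition; the
  cache equals direct hill summation at the nodes to machine precision,
  and queries interpolate linearly. Bias forces use centred differences of
  the cached grid.
- **FES estimators.** (i) Well-tempered inversion F = −γ/(γ−1)·V, using
  the *time-averaged* bias over the tail of the run (the converged WT bias
  carries frozen-in ripples of order w0 that averaging does not remove but
  smaller late hills do; averaging mainly suppresses the residual
  fluctuation). (ii) Standard (non-tempered) metadynamics with F = −⟨V⟩
  time-averaged after a burn-in. (iii) Boltzmann inversion of unbiased
  histograms, empty bins masked as NaN. All three agree within
  0.1 kcal/mol RMSD on the 2-kcal/mol landscape under the tested
  protocols (asserted at 0.3).
- **Barrier measurement.** Minimax path value minus the source minimum:
  running maximum between state minima in 1-D, a Dijkstra-with-max search
  over grid adjacency in 2-D (checked against threshold-flood-fill
  enumeration on small grids). Unsampled gaps raise, naming the location.
- **FES convergence recipe.** γ = 1 + (ΔG_max + 2)/kBT (the
  barrier-matched rule), w0 and hill width scaled to the landscape
  (w0 = 0.1, σ = 0.1 for shallow entries; w0 = ΔG/30, σ = width/3 for the
  deep ones), 2.0–2.6 M steps. On eight seeds the fibre-1 Step-1 barrier
  is recovered at 2.09 ± 0.06 kcal/mol; the deep entries (10/15/30
  kcal/mol) converge to within ~1% because their wells are steep and
  ripple noise is relatively tiny.

## Kinetics

Infrequent metadynamics with slow deposition (pace 500 steps, hill width
one third of the narrowest well — conventional values; the original
setup's parameters are supplementary-level detail and not reproduced).
The bias at the current CV is recorded each step *before* any deposition
at that step, and the unbiased transition time is the accumulated
Σ dt·e^{βV}; the acceleration factor α = t_unbiased/t_biased is ≥ 1 by
construction. Commitment is 50 consecutive recorded steps inside the
target interval (no standard stop criterion exists; the dwell length is
configurable). Runs exhausting the step budget are flagged censored and
excluded from fits but counted; fits require ≥ 80% committed replicas.

Transition times over replicas (default 20, replica i seeded seed+i) are
fitted by the rare-event law P(n≥1) = 1 − e^{−t/τ} with τ the exponential
MLE (the sample mean), a seeded bootstrap 95% CI, and a Kolmogorov–Smirnov
check whose null distribution comes from a parametric bootstrap (τ
re-estimated per replicate, 1000 replicates) — the naive KS table would be
anti-conservative with an estimated parameter. Calibration: exponential
samples pass at p > 0.05 in ≥ 90/100 repetitions; narrow-Gaussian samples
are rejected in ≥ 90/100.

Known bias: at the default pace the fitted τ overshoots the exact MFPT by
roughly 1.3–1.9× on the shallow reference landscape (hills occasionally
touch the transition state; commitment dwell adds rescaled time). The
overshoot is common-mode across the Step-1 family, so designed *ratios*
survive (measured log10(τ_fibre2/τ_fibre1) ≈ 0.86–1.25 over seeds against
the designed 0.92–1.0), and it shrinks with finer, sparser hills — the
cross-estimator consistency test uses σ = width/4, pace 1000 for exactly
that reason. A 100×-faster pace (5 steps) floods the transition state and
reliably fails the KS check with ≥ 40 replicas — the negative control.

## Synthetic fibres and structural metrics

A fibre is n monomers (default 80) stacked on the z axis at c = 3.5 Å,
each one core bead plus three "amide" beads (carrying ±q point charges
that mimic the threefold inter-monomer H-bonding; signs alternate with
monomer parity so stacked neighbours attract) and three outer side beads.
The box is periodic along z only; all distances use z-minimum-image.
Geometry is schematic — side beads exist to give SASA and pair-energy
structure, not force-field realism.

- **Pair energy ΔE** (incorporation energy): 12-6 terms with
  geometric-mean ε / arithmetic-mean σ (core–core ε = 0.627·eps_scale
  kcal/mol; all σ set so the 12-6 minimum sits at the stacking distance)
  plus a screened point-charge term k·q₁q₂·e^{−r/λ}/(ε_r·r) with ε_r = 15
  and λ = 3.5 Å between amide beads, 12 Å cutoff. The Yukawa screening is
  what makes ΔE a *contact-counting* quantity: with bare 1/r the
  alternating charge tails reach third neighbours and smear the ΔE–SASA
  relation.
- **Coordination**: rational switching function
  (1−(r/r0)⁶)/(1−(r/r0)¹²) with r0 = 5 Å (value n/m at r = r0), or a hard
  count within 4.5 Å. The defaults put an ideal interior monomer at 2.05
  and a fragment end at ≈ 1.01 (rational) / exactly 1 (hard). Hot-spot
  classification in crisp counting contexts uses hard mode.
- **SASA**: Shrake–Rupley-style rolling probe (1.9 Å, one CG-water scale)
  with deterministic Fibonacci sphere points (default 960; < 50 rejected),
  per-type bead radii (core/amide 2.3 Å, side 2.6 Å), z-periodic
  occluders.
- **Hot spots**: coordination ≤ 1 *and* SASA strictly above the ensemble
  mean (ties excluded), evaluated on frame-averaged per-monomer values
  when a trajectory is given.

**Default defected ensemble.** Five axial breaks — three isolated gaps
(8/10/14 Å) and an adjacent pair that leaves one monomer isolated in
place — with 0.15 Å thermal jitter, eight frames of independent jitter,
seed 2024. The gaps are all wide enough to sever the stacking contact, so
each defect removes an integer number of contacts: every lost contact
subtracts a fixed ≈ 7 kcal/mol of ΔE and adds a fixed ≈ 250 Å² of SASA,
which is the mechanism behind the near-perfect linear ΔE–SASA trend
(R² ≈ 0.98–0.99 across seeds, slope positive: incorporation weakens as
exposure grows). This defect list is a documented calibration: narrow
gaps or lateral folds probe the *short-range* part of the pair potential,
whose length scale (≈ 1 Å) is much shorter than the SASA saturation scale
(≈ 5 Å), and would bend the relation (measured R² ≈ 0.73 for a graded-gap
family). Real fibres realise the linear regime because their energy is
spread over many side-chain contacts roughly proportional to buried area;
the synthetic ensemble realises it by contact counting instead.

## Surrogate trajectories and internal dynamics

Surrogates stand in for long unbiased runs. A tagged monomer alternates
residences on hot spots — i.i.d. exponential with designed mean t4 —
with short travel excursions (coordination drops to ~0); hops target hot
spots drawn from a configurable distribution, and the visiting monomer
does not "heal" its host when hot spots are re-identified per frame. All
other monomers drift axially with speed set by a radial profile
(direction flips each persistence interval), so surface monomers are
designed faster than the core; specific monomers can instead be pinned to
deterministic drifts (the +5 nm / −3 nm maximum-shift scenario).

Analyses: Δz(t) per monomer (z unwrapped by minimum image, centre-of-mass
z of the core region — the central 50% of monomers by radial distance —
subtracted per frame; the choice of reference is ours), reported in nm; drift speed as mean |Δz(window)|/window over
non-overlapping windows (default scale duration/20; magnitudes rather than signed means, so
back-and-forth surface motion registers as mobility), binned radially with s.e.m. over
monomers; residence events by two-threshold hysteresis (open at 0.7,
close at 0.3) on the coordination-to-nearest-hot-spot series, final open
event censored. Residence fits recover the designed t4 to a few percent
with ≥ 200 events, and the designed fibre-2/fibre-1 residence ratio of 10
is recovered within ~10% through the full extraction pipeline.

## Problem sizes

Defaults were chosen as the smallest runs that leave clear margins:
2–2.6 M Langevin steps per FES, 20 replicas per τ fit (12 for the
five-system ε ladder, 40 for the KS negative control where test power
needs them), 80-monomer fibres with 8 jitter frames, ≥ 200 residence
events per surrogate fit. The full test suite runs in under two minutes
on one CPU; the acceptance script in about half a minute.

## Known limitations

- Landscape kinetics are overdamped 1-D model dynamics; no claim is made
  about real solvated-fibre prefactors, only about designed barriers and
  ratios.
- The ε-ladder's two fast variants have non-matched prefactors (see
  above); their absolute designed times are nominal.
- The fibre geometry is a single straight stack; "radial distance from
  the fibre axis" only becomes informative when defects displace monomers
  laterally.
- Infrequent-metadynamics τ carries the pace-dependent upward bias
  documented above; it is reported as-is, never corrected.
- The 2-D machinery (fields, hills, minimax barriers) is functional but
  the catalogue and the kinetics drivers are 1-D.
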