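"""End-to-end scenario orchestration.

Thin, reproducible drivers tying the stages together: build a catalogue
landscape → converge well-tempered metadynamics → invert the bias →
measure barriers; run replica infrequent metadynamics → fit τ; generate
defected fibres → structural metrics; run surrogates → internal
dynamics.  Every entry point takes an explicit seed and derives all
stage seeds from it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .constants import ROOM, SimulationConstants
from .fibre import (DefectSpec, FibreSpec, PairPotentialParams,
                    default_defected_ensemble, generate_fibre)
from .kinetics import (PoissonFit, TimescaleTable, collect_transition_times,
                       default_infrequent_params, fit_poisson,
                       residence_times_to_t4, seconds_per_reduced_time)
from .landscapes import catalogue_field
from .sampling import (FESGrid, GridSpec, LangevinParams, MetaDParams,
                       barrier_height, fes_from_bias, friction_for, run_metad)
from .structure import (SwitchingParams, classify_hot_spots,
                        compute_monomer_metrics, regress_dE_sasa)
from .surrogate import SurrogateKineticsSpec, simulate_fibre_surrogate
from .dynamics import (delta_z, drift_profile, extract_residence_events,
                       hotspot_coordination_series)

__all__ = [
    "fes_recipe", "recover_barrier", "step1_tau",
    "hotspot_fibre_spec", "surrogate_residence_fit", "two_population_drift",
    "run_exchange_pipeline",
]


def fes_recipe(field, const: SimulationConstants = ROOM) -> MetaDParams:
    """Hill parameters for converging a catalogue landscape's FES.

    The bias factor follows the barrier-matched rule
    γ = 1 + (ΔG_max + 2 kcal/mol)/(kB·T); hill height scales with the
    landscape depth and hill width with the narrowest well.
    """
    full = max(field.spec.designed_barriers.values(), default=2.0)
    gamma = 1.0 + (full + 2.0) / const.kT
    if full <= 4.0:
        return MetaDParams(w0=0.1, sigma=0.1, pace=300, gamma=gamma,
                           grid=GridSpec.for_field(field))
    sigma = min(min(w.width) for w in field.spec.wells) / 3.0
    return MetaDParams(w0=max(0.2, full / 30.0), sigma=sigma, pace=500,
                       gamma=gamma, grid=GridSpec.for_field(field))


def _fes_steps(field) -> int:
    full = max(field.spec.designed_barriers.values(), default=2.0)
    if full <= 10.0:
        return 2_000_000
    if full <= 15.0:
        return 2_200_000
    return 2_600_000


def recover_barrier(name: str, source: str, target: str, seed: int,
                    n_steps: Optional[int] = None,
                    const: SimulationConstants = ROOM
                    ) -> tuple[float, FESGrid]:
    """Run WT-MetaD to convergence on a catalogue entry and measure a
    barrier from the bias-inverted FES (tail-averaged bias)."""
    field = catalogue_field(name)
    metad = fes_recipe(field, const)
    p = LangevinParams(dt=0.01, friction=friction_for(field, const),
                       temperature=const.temperature,
                       n_steps=n_steps or _fes_steps(field), seed=seed,
                       init=float(field.state_minimum(source)[0][0]))
    run = run_metad(field, metad, p, const=const, average_from=0.4)
    fes = fes_from_bias(run.bias, states=field.spec.states,
                        bias_average=run.bias_average)
    return barrier_height(fes, source, target), fes


def step1_tau(name: str, n_replicas: int = 20, seed: int = 0,
              const: SimulationConstants = ROOM,
              max_steps: int = 4_000_000) -> PoissonFit:
    """Fitted Step-1 (A→B) characteristic time from replica infrequent
    WT-MetaD escapes on a catalogue Step-1 landscape (reduced time)."""
    field = catalogue_field(name)
    recs = collect_transition_times(field, "A", "B", n_replicas=n_replicas,
                                    seed=seed, const=const, max_steps=max_steps)
    times = [r.t_unbiased for r in recs if not r.censored]
    if len(times) < 0.8 * n_replicas:
        raise RuntimeError(
            f"{name}: only {len(times)}/{n_replicas} runs committed")
    return fit_poisson(times, seed=seed + 90_001)


def hotspot_fibre_spec(seed: int = 0, n_monomers: int = 24) -> FibreSpec:
    """A fibre with a few persistent surface hot spots and one loose
    monomer, used as the stage for surrogate hopping runs."""
    return FibreSpec(
        n_monomers=n_monomers,
        defects=(DefectSpec("break", n_monomers // 5, 9.0),
                 DefectSpec("break", (3 * n_monomers) // 5, 9.0),
                 DefectSpec("dissolved", n_monomers - 4, 30.0)),
        thermal_noise=0.0, seed=seed)


def surrogate_residence_fit(t4: float, seed: int, n_events: int = 220,
                            dt_factor: float = 0.02) -> PoissonFit:
    """Designed-t4 recovery: run an unbiased surrogate long enough for
    ``n_events`` residences and fit the extracted intervals."""
    conf = generate_fibre(hotspot_fibre_spec(seed=seed))
    kin = SurrogateKineticsSpec(residence_mean=t4, seed=seed,
                                tagged=conf.n_monomers - 4)
    duration = n_events * (t4 * 1.1 + max(2 * dt_factor * t4, 0.02 * t4))
    traj = simulate_fibre_surrogate(conf, kin, duration=duration,
                                    dt=dt_factor * t4)
    series = hotspot_coordination_series(traj)
    events = extract_residence_events(series)
    return residence_times_to_t4(events, seed=seed + 7)


def two_population_drift(seed: int = 0, duration: float = 600.0,
                         dt: float = 0.5, fast_speed: float = 0.6):
    """Fast-surface / static-core surrogate and its radial drift profile."""
    defects = tuple(DefectSpec("fold", i, 8.0) for i in (3, 9, 14, 19))
    spec = FibreSpec(n_monomers=24, defects=defects, thermal_noise=0.0,
                     seed=seed)
    conf = generate_fibre(spec)
    kin = SurrogateKineticsSpec(
        residence_mean=1e9, enable_hopping=False, seed=seed,
        drift_profile=((0.0, 0.0), (4.0, 0.0), (7.0, fast_speed),
                       (12.0, fast_speed)))
    traj = simulate_fibre_surrogate(conf, kin, duration=duration, dt=dt)
    series = delta_z(traj)
    return drift_profile(series, window=duration / 20.0, bins=2), traj


def run_exchange_pipeline(outdir, seed: int = 0, n_replicas: int = 20,
                          systems: tuple[str, ...] = ("fibre1", "fibre2"),
                          dry_run: bool = False, force: bool = False) -> dict:
    """Full fibre-exchange study: barriers, τ fits, structure, dynamics.

    Writes a JSON report (plus TSV tables) under ``outdir`` and returns
    the report dict.
    """
    outdir = Path(outdir)
    report_path = outdir / "report.json"
    plan = {
        "stages": ["barriers", "kinetics", "structure", "dynamics"],
        "systems": list(systems), "seed": seed, "n_replicas": n_replicas,
    }
    if dry_run:
        return {"plan": plan}
    if report_path.exists() and not force:
        raise FileExistsError(f"{report_path} exists; use force to overwrite")
    outdir.mkdir(parents=True, exist_ok=True)

    report: dict = {"plan": plan}
    kappa = seconds_per_reduced_time()

    barriers = {}
    for sysname in systems:
        b1, _ = recover_barrier(f"{sysname}_step1", "A", "B", seed=seed + 11)
        b2, _ = recover_barrier(f"{sysname}_step2", "B", "C", seed=seed + 12)
        barriers[sysname] = {"step1_A_to_B": b1, "step2_B_to_C": b2}
    report["barriers_kcal_mol"] = barriers

    table = TimescaleTable()
    taus = {}
    for i, sysname in enumerate(systems):
        fit = step1_tau(f"{sysname}_step1", n_replicas=n_replicas,
                        seed=seed + 100 * (i + 1))
        taus[sysname] = fit
        table.add(sysname, "t1", fit.tau * kappa,
                  ci=(fit.tau_CI[0] * kappa, fit.tau_CI[1] * kappa),
                  provenance="biased")
    report["t1_seconds"] = {s: taus[s].tau * kappa for s in taus}
    if len(systems) >= 2:
        a, b = systems[0], systems[1]
        report["log10_t1_ratio"] = float(
            np.log10(taus[b].tau / taus[a].tau))
    report["poisson_fits"] = {s: {"tau_reduced": taus[s].tau, "n": taus[s].n,
                                  "ks_p": taus[s].p_value} for s in taus}

    frames = default_defected_ensemble(seed=seed + 500)
    mets = compute_monomer_metrics(frames)
    reg = regress_dE_sasa(mets)
    hard = compute_monomer_metrics(
        frames[:2], sw=SwitchingParams(mode="hard_cutoff"), n_sphere_points=240)
    report["structure"] = {
        "r_squared": reg.r_squared, "slope": reg.slope,
        "n_hot_spots": len(classify_hot_spots(hard)),
    }

    prof, _ = two_population_drift(seed=seed + 900)
    report["dynamics"] = {
        "drift_inner_nm_per_t": float(prof.mean_speed[0]),
        "drift_outer_nm_per_t": float(prof.mean_speed[-1]),
    }

    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=2)
    mets_rows = [
        {"monomer": m.monomer_id, "coordination": m.coordination,
         "sasa": m.sasa, "dE": m.dE, "hot_spot": m.is_hot_spot}
        for m in mets]
    import pandas as pd
    pd.DataFrame(mets_rows).to_csv(outdir / "monomer_metrics.tsv",
                                   sep="\t", index=False)
    return report
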