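"""Static plots: FES profiles, transition-time fits, structure and drift.

Each function draws onto a provided axes (or a fresh figure) and returns
the axes, matplotlib-style; nothing is shown interactively.
"""

from __future__ import annotations

import numpy as np

__all__ = ["plot_fes", "plot_poisson_fit", "plot_dE_vs_sasa",
           "plot_drift_profile"]


def _axes(ax):
    if ax is not None:
        return ax
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    return plt.subplots()[1]


def plot_fes(fes, ax=None, label=None):
    """1-D free-energy profile with state shading and optional s.e.m."""
    ax = _axes(ax)
    m = np.isfinite(fes.F)
    ax.plot(np.ravel(fes.grid)[m], fes.F[m], label=label or fes.method)
    if fes.sem is not None:
        g = np.ravel(fes.grid)[m]
        ax.fill_between(g, fes.F[m] - fes.sem[m], fes.F[m] + fes.sem[m],
                        alpha=0.25)
    for name, box in getattr(fes, "states", {}).items():
        lo, hi = box[0]
        ax.axvspan(lo, hi, alpha=0.08)
        ax.text(0.5 * (lo + hi), ax.get_ylim()[1] * 0.95, name,
                ha="center", va="top")
    ax.set_xlabel("collective variable")
    ax.set_ylabel("free energy (kcal/mol)")
    return ax


def plot_poisson_fit(fit, ax=None):
    """Empirical transition-time CDF against the fitted 1 − e^{−t/τ}."""
    ax = _axes(ax)
    t = np.sort(fit.times)
    ecdf = np.arange(1, len(t) + 1) / len(t)
    ax.step(t, ecdf, where="post", label=f"empirical (n={fit.n})")
    tt = np.linspace(0, t[-1] * 1.2, 200)
    ax.plot(tt, fit.cdf(tt), "--",
            label=f"1 - exp(-t/{fit.tau:.3g})  (KS p={fit.p_value:.2f})")
    ax.set_xlabel("transition time")
    ax.set_ylabel("P(n >= 1)")
    ax.legend()
    return ax


def plot_dE_vs_sasa(metrics, regression=None, ax=None):
    """Incorporation energy against solvent exposure, hot spots marked."""
    ax = _axes(ax)
    sa = np.array([m.sasa for m in metrics])
    de = np.array([m.dE for m in metrics])
    hot = np.array([m.is_hot_spot for m in metrics])
    ax.scatter(sa[~hot], de[~hot], s=18, label="monomers")
    if hot.any():
        ax.scatter(sa[hot], de[hot], s=26, color="crimson", label="hot spots")
    if regression is not None:
        xs = np.linspace(sa.min(), sa.max(), 50)
        ax.plot(xs, regression.slope * xs + regression.intercept, "k--",
                label=f"R² = {regression.r_squared:.3f}")
    ax.set_xlabel("SASA (Å²)")
    ax.set_ylabel("ΔE (kcal/mol)")
    ax.legend()
    return ax


def plot_drift_profile(profile, ax=None):
    """Mean |v_z| per radial bin with s.e.m. bars."""
    ax = _axes(ax)
    mid = profile.bin_edges.mean(axis=1)
    ax.errorbar(mid, profile.mean_speed, yerr=profile.sem, fmt="o-")
    ax.set_xlabel("distance from fibre axis (Å)")
    ax.set_ylabel("|v_z| (nm / time)")
    return ax
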