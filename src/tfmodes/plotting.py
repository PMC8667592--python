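"""Quick-look plots for titration curves, manifolds and posteriors.

Convenience only: each function draws onto a provided (or fresh) matplotlib
Axes and returns it, so figures compose in notebooks and scripts.
"""

from __future__ import annotations

import numpy as np

from .manifold import ManifoldDataset, manifold_steric_reference
from .thermo import EffectiveParameters, FoldChangeCurve, fold_change_weak

__all__ = ["plot_fold_change_curve", "plot_manifold", "plot_alpha_beta_posterior"]


def _ax(ax):
    if ax is None:
        import matplotlib.pyplot as plt
        _, ax = plt.subplots()
    return ax


def plot_fold_change_curve(curve: FoldChangeCurve,
                           eff: EffectiveParameters | None = None, ax=None):
    """Fold change vs TF number (log-log) with an optional model overlay."""
    ax = _ax(ax)
    pts = curve.points
    ax.plot(pts["n_tf"], pts["fc"], "o", ms=4, alpha=0.7,
            label=f"position {curve.position_label}")
    if eff is not None:
        n = np.geomspace(max(pts["n_tf"].min(), 1e-2), pts["n_tf"].max(), 200)
        ax.plot(n, fold_change_weak(n, eff), "-", lw=1.5, label="model")
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("TFs per cell")
    ax.set_ylabel("fold change")
    ax.axhline(1.0, color="0.7", lw=0.8, zorder=0)
    ax.legend(frameon=False)
    return ax


def plot_manifold(dataset: ManifoldDataset, results=None, ax=None):
    """Concentration manifold: fold change at a position vs fold change at +1.

    ``results`` may be a fitted :class:`~tfmodes.inference.ManifoldResults`;
    its posterior-median curve is drawn through the data.
    """
    ax = _ax(ax)
    p = dataset.pairs
    ax.errorbar(p["fc_plus1"], p["fc_query"], yerr=p.get("fc_query_se"),
                fmt="o", ms=4, alpha=0.7, label=f"position {dataset.position_label}")
    if results is not None:
        u = np.geomspace(max(p["fc_plus1"].min(), 1e-4), 1.0, 300)
        ax.plot(u, manifold_steric_reference(u, results.median("fc_max"),
                                             results.median("k_factor")),
                "-", lw=1.5, label="posterior median")
    ax.invert_xaxis()          # TF concentration increases right to left
    ax.set_xlabel("fold change at +1 (steric reference)")
    ax.set_ylabel("fold change at position")
    ax.plot([1], [1], "k+", ms=8)   # zero-TF anchor
    ax.legend(frameon=False)
    return ax


def plot_alpha_beta_posterior(results, ax=None, n_points=2000):
    """(alpha, beta) posterior cloud on log axes with the quadrant lines."""
    ax = _ax(ax)
    a = results.samples["alpha"].reshape(-1)
    b = results.samples["beta"].reshape(-1)
    ok = np.isfinite(a) & np.isfinite(b) & (a > 0) & (b > 0)
    a, b = a[ok], b[ok]
    if len(a) > n_points:
        idx = np.linspace(0, len(a) - 1, n_points).astype(int)
        a, b = a[idx], b[idx]
    ax.scatter(a, b, s=3, alpha=0.2)
    ax.axvline(1.0, color="k", lw=0.8, ls="--")
    ax.axhline(1.0, color="k", lw=0.8, ls="--")
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel(r"acceleration $\alpha$")
    ax.set_ylabel(r"stabilization $\beta$")
    return ax
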