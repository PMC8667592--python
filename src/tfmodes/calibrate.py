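"""Fluorescence calibration, cytometry gating, and proportional binning.

Three measurement-processing steps stand between raw single-cell events and
a fold-change curve:

* fluctuation counting — the fluorescence-per-molecule factor ``v`` follows
  from binomial partitioning at division, ``(I1 - I2)^2 = v (I1 + I2)``;
* ellipsoid gating — events are retained when their (log10 FSC, log10 SSC)
  squared Mahalanobis distance falls below a chi-square(2) quantile, which
  keeps the central mass of single-cell scatter;
* proportional binning — equal-count bins on the RFP channel, reporting the
  per-bin median RFP and median fold change.

The scaling factor ``mu`` (TFs per cytometer RFP unit) comes from matched
steric (+1) curves measured in both unit systems: with ``FC_max = 0`` the
fold change is ``1/(1 + chi * x)`` in either system, and ``mu`` is the ratio
of the two fitted ``chi`` values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .thermo import FoldChangeCurve

__all__ = [
    "CalibrationResult",
    "estimate_calibration_factor",
    "subtract_autofluorescence",
    "ellipsoid_gate",
    "proportional_bin_edges",
    "bin_events_proportional",
    "binned_fold_change",
    "rfp_threshold_filter",
    "fit_mu_scaling",
]


@dataclass
class CalibrationResult:
    """Unit-conversion factors tying fluorescence to molecule counts."""

    v: float | None = None          # fluorescence units per molecule
    v_se: float | None = None
    mu: float | None = None         # TFs per cytometer RFP unit
    chi_rfp: float | None = None    # effective coefficient, cytometry units
    chi_mic: float | None = None    # effective coefficient, molecule units


def estimate_calibration_factor(pairs: pd.DataFrame, n_boot: int = 1000,
                                seed: int = 0) -> CalibrationResult:
    """Fluctuation-counting estimate of ``v`` from division pairs.

    Fits ``(i1 - i2)^2 = v * (i1 + i2)`` through the origin by weighted least
    squares with 1/x^2 weights (the squared-difference residual variance
    scales as x^2 under binomial partitioning), which reduces to the mean of
    ``(i1 - i2)^2 / (i1 + i2)``.  The SE is a bootstrap over pairs.
    """
    x = (pairs["i1"] + pairs["i2"]).to_numpy(dtype=float)
    y = ((pairs["i1"] - pairs["i2"]) ** 2).to_numpy(dtype=float)
    if len(x) < 2:
        raise ValueError("need >= 2 division pairs")
    if len(pairs[["i1", "i2"]].drop_duplicates()) == 1:
        raise ValueError("all pairs identical: fit is singular")
    if np.any(x <= 0):
        raise ValueError("total intensities must be > 0")
    ratios = y / x
    v = float(ratios.mean())
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(ratios), size=(n_boot, len(ratios)))
    v_se = float(ratios[idx].mean(axis=1).std(ddof=1))
    return CalibrationResult(v=v, v_se=v_se)


def subtract_autofluorescence(events: pd.DataFrame,
                              af_events: pd.DataFrame) -> pd.DataFrame:
    """Subtract autofluorescence channel means measured on a control strain.

    Negative post-subtraction values are kept (not clipped) so that ratios
    of means stay unbiased.
    """
    out = events.copy()
    out["rfp"] = out["rfp"] - af_events["rfp"].mean()
    out["yfp"] = out["yfp"] - af_events["yfp"].mean()
    return out


def proportional_bin_edges(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Quantile edges putting an (approximately) equal event count per bin."""
    values = np.asarray(values, dtype=float)
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if n_bins > len(values):
        raise ValueError("more bins than events")
    edges = np.quantile(values, np.linspace(0.0, 1.0, n_bins + 1))
    edges[0], edges[-1] = -np.inf, np.inf
    return edges


def bin_events_proportional(events: pd.DataFrame, n_bins: int,
                            channel: str = "rfp",
                            edges: np.ndarray | None = None) -> pd.DataFrame:
    """Assign proportional (equal-count) bins on ``channel``.

    Returns a copy of ``events`` with a ``bin_id`` column.  When ``edges``
    is given (e.g. computed on a pooled dataset) it is used verbatim so
    several tables can share one grid.
    """
    if len(events) == 0:
        raise ValueError("no events to bin")
    if edges is None:
        edges = proportional_bin_edges(events[channel].to_numpy(), n_bins)
    out = events.copy()
    out["bin_id"] = pd.cut(out[channel], bins=edges, labels=False, include_lowest=True)
    return out


def ellipsoid_gate(events: pd.DataFrame, level: float = 0.95,
                   n_rfp_bins: int = 16, per_bin: bool = True) -> pd.DataFrame:
    """Scatter-channel ellipsoid gate on (log10 FSC, log10 SSC).

    Within each proportional RFP bin (or globally when ``per_bin=False``),
    the mean and covariance of the log-scatter channels define an ellipsoid;
    events whose squared Mahalanobis distance is at most the chi-square
    (2 df) quantile at ``level`` are retained.  ``level=0.95`` keeps the
    central 95% of a bivariate-normal cloud; ``level=0.05`` reproduces the
    literal 5th-percentile cutoff reading, retaining ~5%.

    Returns the events with a boolean ``retained`` column; per-bin retention
    counts are stored in ``result.attrs["gate_log"]``.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    cutoff = stats.chi2.ppf(level, df=2)
    binned = bin_events_proportional(events, n_rfp_bins, channel="rfp")
    if not per_bin:
        binned["bin_id"] = 0
    X = np.log10(np.column_stack([binned["fsc"], binned["ssc"]]))
    retained = np.zeros(len(binned), dtype=bool)
    log_rows = []
    for bin_id, idx in binned.groupby("bin_id").indices.items():
        if len(idx) < 3:
            warnings.warn(f"RFP bin {bin_id}: fewer than 3 events, skipped")
            continue
        xb = X[idx]
        cov = np.cov(xb, rowvar=False)
        if np.linalg.matrix_rank(cov) < 2:
            warnings.warn(f"RFP bin {bin_id}: singular scatter covariance, skipped")
            continue
        d = xb - xb.mean(axis=0)
        md2 = np.einsum("ij,jk,ik->i", d, np.linalg.inv(cov), d)
        keep = md2 <= cutoff
        retained[idx] = keep
        log_rows.append({"bin_id": bin_id, "n_in": len(idx), "n_retained": int(keep.sum())})
    out = binned.drop(columns=["bin_id"])
    out["retained"] = retained
    out.attrs["gate_log"] = pd.DataFrame(log_rows)
    return out


def rfp_threshold_filter(events: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Drop events below an RFP floor where cytometry abundance is unreliable."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    out = events[events["rfp"] >= threshold].reset_index(drop=True)
    n_removed = len(events) - len(out)
    out.attrs["n_removed"] = n_removed
    if len(out) == 0:
        warnings.warn("RFP threshold removed every event")
    return out


def binned_fold_change(events: pd.DataFrame, control_events: pd.DataFrame,
                       edges: np.ndarray, position_label: int | None = None) -> FoldChangeCurve:
    """Per-bin fold change curve: median YFP ratio against median RFP.

    ``events`` and ``control_events`` are binned on the shared ``edges`` so
    bins index the same effective TF abundance; the per-bin fold change is
    ``median(yfp)/median(yfp_control)`` and the abscissa the per-bin median
    RFP of the regulated events.  Bins empty in either table are dropped.
    """
    reg = bin_events_proportional(events, n_bins=len(edges) - 1, edges=edges)
    ctl = bin_events_proportional(control_events, n_bins=len(edges) - 1, edges=edges)
    ctrl_med = ctl.groupby("bin_id")["yfp"].median()
    rows = []
    for bin_id, grp in reg.groupby("bin_id"):
        if bin_id not in ctrl_med.index or len(grp) == 0:
            continue
        med_yfp = grp["yfp"].median()
        fc = med_yfp / ctrl_med.loc[bin_id]
        if fc <= 0:
            continue
        # SE of the median ratio via the large-sample normal approximation
        se = fc * np.sqrt(1.2533 ** 2 * (grp["yfp"].std(ddof=1) / med_yfp) ** 2 / len(grp))
        rows.append({"condition_id": int(bin_id), "replicate_id": 0,
                     "n_tf": grp["rfp"].median(), "fc": fc, "fc_se": se})
    if position_label is None:
        labels = events["position_label"].unique()
        position_label = int(labels[0]) if len(labels) == 1 else 0
    return FoldChangeCurve(position_label=position_label, points=pd.DataFrame(rows))


def _fit_steric_chi(n_tf: np.ndarray, fc: np.ndarray) -> float:
    """Least-squares chi for the pure-repression curve fc = 1/(1 + chi*x)."""

    def model(x, log_chi):
        return 1.0 / (1.0 + np.exp(log_chi) * x)

    best, best_cost = None, np.inf
    scale = max(np.median(n_tf[n_tf > 0]), 1e-12)
    for start in np.log(np.geomspace(0.01, 100.0, 5) / scale):
        try:
            popt, _ = optimize.curve_fit(model, n_tf, fc, p0=[start], maxfev=10000)
        except RuntimeError:
            continue
        cost = float(np.sum((model(n_tf, *popt) - fc) ** 2))
        if cost < best_cost:
            best, best_cost = popt[0], cost
    if best is None:
        raise RuntimeError("steric-curve fit failed to converge")
    return float(np.exp(best))


def fit_mu_scaling(curve_cytometry_plus1: FoldChangeCurve,
                   curve_microscopy_plus1: FoldChangeCurve) -> CalibrationResult:
    """Cytometry-to-TF-number scaling from matched steric (+1) curves.

    Both curves measure the same pure-repression strain, one with the
    abscissa in cytometer RFP units and one in molecule counts; fitting
    ``1/(1 + chi x)`` to each gives ``chi_rfp`` and ``chi_mic`` and the
    scaling ``mu = chi_rfp / chi_mic`` in TFs per RFP unit.
    """
    result = CalibrationResult()
    for name, curve in (("chi_rfp", curve_cytometry_plus1),
                        ("chi_mic", curve_microscopy_plus1)):
        pts = curve.condition_means() if curve.points["replicate_id"].nunique() > 1 \
            else curve.points
        if (pts["fc"] > 1.5).any():
            warnings.warn(f"{name}: curve does not look repressive; "
                          "the steric model may be misspecified")
        setattr(result, name, _fit_steric_chi(pts["n_tf"].to_numpy(),
                                              pts["fc"].to_numpy()))
    result.mu = result.chi_rfp / result.chi_mic
    return result
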