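"""Concentration-manifold reformulation of the fold-change model.

A concentration manifold plots the fold change at one binding position
against the fold change at another position, with both measured at the same
effective TF concentration.  Because TF copy number and binding affinity
enter both axes identically (the binding sequence, hence affinity, is held
fixed between positions), they cancel, leaving only the intrinsic regulatory
parameters: the saturating fold change ``FC_max`` and the stabilization
factor ``K = 1 + P*beta`` at each position.

Against a steric reference position (``FC_max = 0``, ``beta = 0``, i.e. the
site directly downstream of the transcription start), the manifold reduces
to a one-position expression: a straight line from (1, 1) to (0, FC_max)
when ``K = 1`` and a curve that rises (or falls) faster than linear when
``K > 1``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .thermo import FoldChangeCurve

__all__ = [
    "ManifoldDataset",
    "manifold_general",
    "manifold_steric_reference",
    "beta_from_k",
    "alpha_from_fcmax_beta",
    "pair_by_concentration",
]

_MANIFOLD_COLUMNS = ["position_label", "bin_id", "fc_plus1", "fc_query",
                     "fc_plus1_se", "fc_query_se"]


@dataclass
class ManifoldDataset:
    """Paired fold changes (reference position, query position) per TF level.

    ``pairs`` has one row per common abundance bin with columns ``bin_id``,
    ``fc_plus1`` (steric reference), ``fc_query`` and their standard errors.
    The zero-TF anchor (1, 1) is the analytic limit of every manifold.
    """

    position_label: int
    pairs: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=_MANIFOLD_COLUMNS[1:]))

    def __post_init__(self) -> None:
        df = self.pairs
        missing = {"fc_plus1", "fc_query"} - set(df.columns)
        if missing:
            raise ValueError(f"manifold pairs missing columns: {sorted(missing)}")
        if "bin_id" not in df.columns:
            df = df.assign(bin_id=np.arange(len(df)))
        for col in ("fc_plus1_se", "fc_query_se"):
            if col not in df.columns:
                df = df.assign(**{col: np.nan})
        if len(df) and (df["fc_plus1"] <= 0).any():
            raise ValueError("reference fold change must be > 0")
        # measurement noise can push near-anchor bins slightly above the
        # zero-TF limit of 1; fold those onto the anchor
        if len(df) and (df["fc_plus1"] > 1.0).any():
            df = df.assign(fc_plus1=df["fc_plus1"].clip(upper=1.0))
        self.pairs = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.pairs)

    def to_csv(self, path) -> None:
        df = self.pairs.copy()
        df.insert(0, "position_label", self.position_label)
        df[_MANIFOLD_COLUMNS].to_csv(path, index=False, encoding="utf-8")

    @classmethod
    def from_csv(cls, path) -> "ManifoldDataset":
        df = pd.read_csv(path, encoding="utf-8")
        labels = df["position_label"].unique()
        if len(labels) != 1:
            raise ValueError("manifold CSV must contain a single position_label")
        return cls(position_label=int(labels[0]),
                   pairs=df.drop(columns=["position_label"]))


def manifold_general(fc_x, fc_max_x: float, k_x: float, fc_max_y: float,
                     k_y: float, affinity_ratio: float = 1.0):
    """Fold change at position y as a function of fold change at position x.

    Eliminates the TF concentration between the two weak-promoter fold-change
    curves.  ``affinity_ratio`` is ``epsilon_y/epsilon_x``, the ratio of the
    specific-binding Boltzmann factors; it is 1 when both positions carry the
    same binding sequence.  ``fc_x`` must lie strictly between ``fc_max_x``
    and 1 (or equal 1, the zero-TF anchor); ``fc_x == fc_max_x`` is the
    saturation singularity and is returned as the ``fc_max_y`` limit.
    """
    fc_x = np.asarray(fc_x, dtype=float)
    if np.any(fc_x <= 0):
        raise ValueError("fold change must be > 0")
    ratio_k = affinity_ratio * k_y / k_x
    with np.errstate(divide="ignore", invalid="ignore"):
        s = ratio_k * (fc_x - 1.0) / (fc_max_x - fc_x)
        out = (1.0 + fc_max_y * s) / (1.0 + s)
    out = np.where(np.isclose(fc_x, fc_max_x), fc_max_y, out)
    out = np.where(fc_x == 1.0, 1.0, out)
    return float(out) if out.ndim == 0 else out


def manifold_steric_reference(fc_plus1, fc_max_y: float, k_y: float):
    """Manifold against a pure steric-hindrance reference position.

    ``fc_y = (1 + fc_max_y*k_y*(1-u)/u) / (1 + k_y*(1-u)/u)`` with
    ``u = fc_plus1 in (0, 1]``.  ``u = 1`` is the zero-TF anchor (returns 1);
    ``u -> 0`` is handled analytically and returns ``fc_max_y``.
    """
    u = np.asarray(fc_plus1, dtype=float)
    if np.any(u < 0) or np.any(u > 1.0 + 1e-12):
        raise ValueError("reference fold change must lie in [0, 1]")
    with np.errstate(divide="ignore", invalid="ignore"):
        s = k_y * (1.0 - u) / u
        out = np.where(u > 0, (1.0 + fc_max_y * s) / (1.0 + s), fc_max_y)
    return float(out) if out.ndim == 0 else out


def beta_from_k(k_factor, P: float):
    """Stabilization ``beta = (K - 1)/P``; exact inverse of ``K = 1 + P*beta``.

    The prior convention of the manifold inference is ``K >= 1``; smaller
    values raise, matching the assumption that destabilization below the
    steric floor is not representable.
    """
    if P <= 0:
        raise ValueError("P must be > 0")
    k_factor = np.asarray(k_factor, dtype=float)
    if np.any(k_factor < 1.0):
        raise ValueError("k_factor must be >= 1 under the K >= 1 prior convention")
    out = (k_factor - 1.0) / P
    return float(out) if out.ndim == 0 else out


def alpha_from_fcmax_beta(fc_max, beta, P: float):
    """Acceleration from the jointly sampled ``fc_max`` and derived ``beta``.

    ``alpha = (fc_max/beta) * (1 + (P/(1+P)) * (beta - 1))``.  This inverts
    the exact-form saturating fold change ``alpha*beta*(1+P)/(1+P*beta)``
    (the ``1+P`` correction is retained rather than dropped in the weak
    promoter limit).  ``beta = 0`` leaves alpha unidentifiable and raises.
    """
    if P <= 0:
        raise ValueError("P must be > 0")
    beta = np.asarray(beta, dtype=float)
    fc_max = np.asarray(fc_max, dtype=float)
    if np.any(beta == 0):
        raise ValueError("alpha is unidentifiable at beta = 0 (steric exclusion)")
    out = (fc_max / beta) * (1.0 + (P / (1.0 + P)) * (beta - 1.0))
    return float(out) if out.ndim == 0 else out


def pair_by_concentration(curve_plus1: FoldChangeCurve,
                          curve_y: FoldChangeCurve) -> ManifoldDataset:
    """Pair two binned curves on their common abundance bins.

    Both curves must be binned on the same grid so each ``condition_id``
    labels the same effective TF concentration; bins present in only one
    curve are dropped with a warning.
    """
    ref = curve_plus1.points.set_index("condition_id")
    qry = curve_y.points.set_index("condition_id")
    common = ref.index.intersection(qry.index)
    dropped = len(ref.index.union(qry.index)) - len(common)
    if len(common) == 0:
        raise ValueError("no common abundance bins between curves")
    if dropped:
        warnings.warn(f"dropped {dropped} bins missing from one of the curves")
    pairs = pd.DataFrame({
        "bin_id": common,
        "fc_plus1": ref.loc[common, "fc"].to_numpy(),
        "fc_query": qry.loc[common, "fc"].to_numpy(),
        "fc_plus1_se": ref.loc[common, "fc_se"].to_numpy(),
        "fc_query_se": qry.loc[common, "fc_se"].to_numpy(),
    })
    pairs = pairs.sort_values("fc_plus1", ascending=False, ignore_index=True)
    return ManifoldDataset(position_label=curve_y.position_label, pairs=pairs)
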