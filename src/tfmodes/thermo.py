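"""Thermodynamic model of a single transcription factor regulating one promoter.

The promoter is treated as a four-state system in thermodynamic equilibrium:
unbound, RNAP-bound, TF-bound, and co-bound.  Two coarse-grained parameters
describe what the TF does to transcription from the co-bound state:

* ``beta`` — (de)stabilization of RNAP: the co-bound statistical weight is
  multiplied by ``beta = exp(-delta_eps_I)``; ``beta > 1`` lengthens RNAP dwell
  times, ``beta < 1`` shortens them, ``beta = 0`` is steric exclusion.
* ``alpha`` — (de)acceleration of initiation: the transcription rate from the
  co-bound state is ``alpha`` times the RNAP-only rate.

Every regulatory curve of fold change versus TF copy number collapses onto a
two-parameter family governed by the saturating fold change ``FC_max`` and the
effective concentration coefficient ``chi``, which is the basis of the data
collapse and of the concentration-manifold inference in :mod:`tfmodes.manifold`.

All Boltzmann arithmetic is done in log space so that extreme binding energies
(|energy| well beyond 50 kBT) neither overflow nor underflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import logsumexp

__all__ = [
    "GENOME_NS_SITES",
    "PromoterParameters",
    "TFRegulatoryParameters",
    "EffectiveParameters",
    "FoldChangeCurve",
    "state_weights",
    "p_bound",
    "fold_change_full",
    "fold_change_weak",
    "saturating_fold_change_exact",
    "effective_from_mechanistic",
    "collapse_transform",
]

#: Nonspecific background site count, equated to the E. coli genome size in bp.
GENOME_NS_SITES = 4.6e6


@dataclass(frozen=True)
class PromoterParameters:
    """Core-promoter configuration.

    Parameters
    ----------
    n_p : float
        RNAP copy number per cell.
    delta_eps_p : float
        RNAP-promoter binding energy in kBT (negative = favorable).
    n_ns : float
        Nonspecific genomic background sites (bp); never fitted.
    r : float
        Basal transcription rate from the RNAP-only state (arbitrary units).

    The defaults reproduce the weak synthetic promoter used throughout:
    occupancy parameter ``P = (n_p/n_ns) exp(-delta_eps_p) ~ 6.65e-2``.
    """

    n_p: float = 460.0
    delta_eps_p: float = -6.5
    n_ns: float = GENOME_NS_SITES
    r: float = 1.0

    def __post_init__(self) -> None:
        if self.n_p <= 0:
            raise ValueError("n_p must be > 0")
        if self.n_ns <= 0:
            raise ValueError("n_ns must be > 0")

    @property
    def log_P(self) -> float:
        return np.log(self.n_p / self.n_ns) - self.delta_eps_p

    @property
    def P(self) -> float:
        """RNAP occupancy weight relative to the unbound state."""
        return float(np.exp(self.log_P))

    @classmethod
    def from_occupancy(cls, P: float, n_p: float = 460.0,
                       n_ns: float = GENOME_NS_SITES, r: float = 1.0) -> "PromoterParameters":
        """Build parameters whose derived occupancy equals ``P`` exactly."""
        if P <= 0:
            raise ValueError("P must be > 0")
        delta_eps_p = float(np.log(n_p / n_ns) - np.log(P))
        return cls(n_p=n_p, delta_eps_p=delta_eps_p, n_ns=n_ns, r=r)


@dataclass(frozen=True)
class TFRegulatoryParameters:
    """Intrinsic regulatory parameters of one TF at one binding position.

    ``beta = 0`` encodes steric hindrance; the interaction energy
    ``delta_eps_I = -log(beta)`` is then +infinity and is reported as such.
    """

    alpha: float = 1.0
    beta: float = 1.0
    delta_eps_tf: float = 0.0
    n_ns: float = GENOME_NS_SITES

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.beta < 0:
            raise ValueError("beta must be >= 0 (0 = steric exclusion)")
        if self.n_ns <= 0:
            raise ValueError("n_ns must be > 0")

    @property
    def epsilon(self) -> float:
        """exp(-delta_eps_tf), the specific-binding Boltzmann factor."""
        return float(np.exp(-self.delta_eps_tf))

    @property
    def lambda_aff(self) -> float:
        """Scaled affinity ``exp(-delta_eps_tf)/n_ns`` (per molecule)."""
        return float(np.exp(-self.delta_eps_tf - np.log(self.n_ns)))

    @property
    def delta_eps_I(self) -> float:
        """TF-RNAP interaction energy in kBT; -log(beta), +inf when beta=0."""
        with np.errstate(divide="ignore"):
            return float(-np.log(self.beta))


@dataclass(frozen=True)
class EffectiveParameters:
    """The two-number summary of a regulatory curve.

    fc_max : saturating fold change at infinite TF (weak-promoter form
        ``alpha*beta/(1+P*beta)``).
    chi : effective-concentration coefficient per TF molecule,
        ``lambda_aff*(1+P*beta)``.
    k_factor : stabilization factor ``K = 1 + P*beta``.
    """

    fc_max: float
    chi: float
    k_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.fc_max < 0:
            raise ValueError("fc_max must be >= 0")
        if self.chi <= 0:
            raise ValueError("chi must be > 0")
        if self.k_factor < 0:
            raise ValueError("k_factor must be >= 0")


_CURVE_COLUMNS = ["position_label", "condition_id", "replicate_id", "n_tf", "fc", "fc_se"]


@dataclass
class FoldChangeCurve:
    """A fold-change-versus-TF-number curve for one binding position.

    ``points`` carries one row per (condition, replicate) measurement with
    columns ``n_tf``, ``fc``, ``fc_se``, ``condition_id``, ``replicate_id``.
    Fold change is the expression ratio against the zero-TF strain, so every
    curve implicitly anchors at (0, 1).
    """

    position_label: int
    points: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=_CURVE_COLUMNS[1:]))

    def __post_init__(self) -> None:
        pts = self.points
        missing = {"n_tf", "fc"} - set(pts.columns)
        if missing:
            raise ValueError(f"curve points missing columns: {sorted(missing)}")
        if "fc_se" not in pts.columns:
            pts = pts.assign(fc_se=np.nan)
        if "condition_id" not in pts.columns:
            pts = pts.assign(condition_id=np.arange(len(pts)))
        if "replicate_id" not in pts.columns:
            pts = pts.assign(replicate_id=0)
        if len(pts) and (pts["fc"] <= 0).any():
            raise ValueError("fold change values must be > 0")
        if len(pts) and (pts["n_tf"] < 0).any():
            raise ValueError("n_tf must be >= 0")
        self.points = pts.reset_index(drop=True)

    def condition_means(self) -> pd.DataFrame:
        """Mean n_tf/fc per condition with the SE over replicates."""
        g = self.points.groupby("condition_id")
        out = g.agg(n_tf=("n_tf", "mean"), fc=("fc", "mean"),
                    fc_se=("fc", "sem"), n_rep=("fc", "size"))
        return out.reset_index()

    def to_csv(self, path) -> None:
        df = self.points.copy()
        df.insert(0, "position_label", self.position_label)
        df[_CURVE_COLUMNS].to_csv(path, index=False, encoding="utf-8")

    @classmethod
    def from_csv(cls, path) -> "FoldChangeCurve":
        df = pd.read_csv(path, encoding="utf-8")
        labels = df["position_label"].unique()
        if len(labels) != 1:
            raise ValueError("curve CSV must contain a single position_label")
        return cls(position_label=int(labels[0]),
                   points=df.drop(columns=["position_label"]))


# ---------------------------------------------------------------------------
# statistical weights and fold change


def _log_weights(promoter: PromoterParameters, tf: TFRegulatoryParameters,
                 n_tf) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Log Boltzmann weights of (unbound, RNAP-only, TF-only, co-bound)."""
    n_tf = np.asarray(n_tf, dtype=float)
    if np.any(n_tf < 0):
        raise ValueError("n_tf must be >= 0")
    with np.errstate(divide="ignore"):
        log_t = np.where(n_tf > 0, np.log(n_tf / promoter.n_ns) - tf.delta_eps_tf, -np.inf)
        log_beta = np.log(tf.beta) if tf.beta > 0 else -np.inf
    log_p = promoter.log_P
    zero = np.zeros_like(log_t)
    return zero, zero + log_p, log_t, log_t + log_p + log_beta


def state_weights(promoter: PromoterParameters, tf: TFRegulatoryParameters,
                  n_tf) -> np.ndarray:
    """Statistical weights of the four promoter states at TF count ``n_tf``.

    Returns an array ``[unbound, rnap_only, tf_only, cobound]`` with shape
    ``(4,) + shape(n_tf)``; their sum over the first axis is the partition
    function Z.
    """
    logs = _log_weights(promoter, tf, n_tf)
    return np.exp(np.stack(logs, axis=0))


def p_bound(n_tf, promoter: PromoterParameters, tf: TFRegulatoryParameters):
    """Probability that RNAP occupies the promoter at TF count ``n_tf``."""
    lw = _log_weights(promoter, tf, n_tf)
    log_num = logsumexp(np.stack([lw[1], lw[3]], axis=0), axis=0)
    log_z = logsumexp(np.stack(lw, axis=0), axis=0)
    out = np.exp(log_num - log_z)
    return float(out) if np.ndim(n_tf) == 0 else out


def fold_change_full(n_tf, promoter: PromoterParameters, tf: TFRegulatoryParameters):
    """Exact fold change in expression, no weak-promoter approximation.

    ``(1+P) * (1 + alpha*beta*t) / (1 + P + t*(1 + P*beta))`` with
    ``t = (n_tf/n_ns) exp(-delta_eps_tf)``; equals 1 at ``n_tf = 0`` and tends
    to ``alpha*beta*(1+P)/(1+P*beta)`` as ``n_tf`` grows.
    """
    lw = _log_weights(promoter, tf, n_tf)
    log_alpha = np.log(tf.alpha)
    # numerator states weighted by their transcription rates (r and alpha*r)
    log_expr = logsumexp(np.stack([lw[1], lw[3] + log_alpha], axis=0), axis=0)
    log_z = logsumexp(np.stack(lw, axis=0), axis=0)
    log_p = promoter.log_P
    log_expr0 = log_p - np.logaddexp(0.0, log_p)  # P/(1+P)
    out = np.exp(log_expr - log_z - log_expr0)
    return float(out) if np.ndim(n_tf) == 0 else out


def fold_change_weak(n_tf, eff: EffectiveParameters):
    """Weak-promoter fold change ``(1 + FC_max*chi*n)/(1 + chi*n)``."""
    n_tf = np.asarray(n_tf, dtype=float)
    if np.any(n_tf < 0):
        raise ValueError("n_tf must be >= 0")
    x = eff.chi * n_tf
    out = (1.0 + eff.fc_max * x) / (1.0 + x)
    return float(out) if out.ndim == 0 else out


def saturating_fold_change_exact(tf: TFRegulatoryParameters,
                                 promoter: PromoterParameters) -> float:
    """Exact-form saturating fold change ``alpha*beta*(1+P)/(1+P*beta)``.

    This is the true large-TF limit of :func:`fold_change_full` and the
    convention the manifold back-transform to (alpha, beta) inverts; it exceeds
    the weak-form ``fc_max`` by the factor ``1+P``.
    """
    P = promoter.P
    return tf.alpha * tf.beta * (1.0 + P) / (1.0 + P * tf.beta)


def effective_from_mechanistic(tf: TFRegulatoryParameters,
                               promoter: PromoterParameters) -> EffectiveParameters:
    """Collapse mechanistic parameters into (fc_max, chi, K)."""
    P = promoter.P
    k = 1.0 + P * tf.beta
    fc_max = tf.alpha * tf.beta / k
    chi = tf.lambda_aff * k
    return EffectiveParameters(fc_max=fc_max, chi=chi, k_factor=k)


def collapse_transform(curve: FoldChangeCurve, eff: EffectiveParameters) -> FoldChangeCurve:
    """Re-express a curve against the effective TF concentration ``chi*n_tf``.

    Curves sharing ``fc_max`` but differing in affinity or stabilization become
    pointwise identical in this coordinate.
    """
    if eff.chi <= 0:
        raise ValueError("chi must be > 0")
    pts = curve.points.copy()
    pts["n_tf"] = pts["n_tf"] * eff.chi
    return replace(curve, points=pts)
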