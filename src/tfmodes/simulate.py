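"""Synthetic single-cell datasets with known regulatory ground truth.

The generator emulates the structure of a TF-titration experiment: a
TF-mCherry fusion induced across an 11-point series spanning a few to a few
thousand molecules per cell, a YFP reporter whose expression follows the
exact thermodynamic fold-change model, additive autofluorescence backgrounds,
log-scale correlated forward/side scatter, and mother/daughter fluorescence
pairs produced by binomial partitioning at division.  Every stochastic
element is driven by an explicit seed so identical scenarios reproduce
byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .thermo import PromoterParameters, TFRegulatoryParameters, FoldChangeCurve, fold_change_full

__all__ = [
    "SyntheticScenario",
    "simulate_cells",
    "simulate_autofluorescence",
    "simulate_division_pairs",
    "fold_change_table",
]

EVENT_COLUMNS = ["position_label", "condition_id", "replicate_id", "is_control",
                 "fsc", "ssc", "rfp", "yfp"]


def _default_induction() -> tuple[float, ...]:
    # 11 induction levels from leaky (a few TFs/cell) to a few thousand
    return tuple(np.geomspace(3.0, 3000.0, 11))


@dataclass
class SyntheticScenario:
    """Study conditions for one synthetic titration experiment.

    ``positions`` maps a binding-position label to the true regulatory
    parameters at that position; a steric reference (+1) is a position with
    ``beta = 0``.  Induction conditions are specified directly as target mean
    TF counts per cell; per-cell TF counts are lognormal around the condition
    mean with coefficient of variation ``tf_noise_cv``.
    """

    positions: dict[int, TFRegulatoryParameters]
    promoter: PromoterParameters = field(default_factory=PromoterParameters)
    induction_means: tuple[float, ...] = field(default_factory=_default_induction)
    cells_per_condition: int = 1000
    n_replicates: int = 3
    tf_noise_cv: float = 0.3
    yfp_noise_cv: float = 0.2
    yfp_baseline: float = 2000.0
    autofluorescence: dict = field(default_factory=lambda: {
        "rfp_mean": 150.0, "rfp_sd": 20.0, "yfp_mean": 150.0, "yfp_sd": 20.0})
    calib_v: float = 10.0
    scatter_mean: tuple[float, float] = (4.5, 4.2)     # log10 FSC, SSC
    scatter_sd: tuple[float, float] = (0.15, 0.18)
    scatter_corr: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cells_per_condition <= 0 or self.n_replicates <= 0:
            raise ValueError("counts must be > 0")
        if self.tf_noise_cv < 0 or self.yfp_noise_cv < 0:
            raise ValueError("noise CVs must be >= 0")
        if any(m <= 0 for m in self.induction_means):
            raise ValueError("induction means must be > 0")


def _lognormal(rng: np.random.Generator, mean, cv: float, size) -> np.ndarray:
    """Lognormal draws with the given arithmetic mean and CV."""
    mean = np.asarray(mean, dtype=float)
    if cv == 0:
        return np.broadcast_to(mean, size).copy()
    sigma2 = np.log(1.0 + cv ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=size)


def _scatter(rng: np.random.Generator, scn: SyntheticScenario, n: int) -> tuple[np.ndarray, np.ndarray]:
    sx, sy = scn.scatter_sd
    rho = scn.scatter_corr
    cov = np.array([[sx ** 2, rho * sx * sy], [rho * sx * sy, sy ** 2]])
    draws = rng.multivariate_normal(scn.scatter_mean, cov, size=n)
    return 10.0 ** draws[:, 0], 10.0 ** draws[:, 1]


def _one_population(rng: np.random.Generator, scn: SyntheticScenario,
                    tf: TFRegulatoryParameters | None, position_label: int,
                    is_control: bool) -> pd.DataFrame:
    frames = []
    af = scn.autofluorescence
    n = scn.cells_per_condition
    for rep in range(scn.n_replicates):
        for cond, mean_tf in enumerate(scn.induction_means):
            counts = np.round(_lognormal(rng, mean_tf, scn.tf_noise_cv, n))
            rfp = scn.calib_v * counts + rng.normal(af["rfp_mean"], af["rfp_sd"], n)
            if is_control or tf is None:
                fc = np.ones(n)
            else:
                fc = fold_change_full(counts, scn.promoter, tf)
            yfp = (scn.yfp_baseline * fc * _lognormal(rng, 1.0, scn.yfp_noise_cv, n)
                   + rng.normal(af["yfp_mean"], af["yfp_sd"], n))
            fsc, ssc = _scatter(rng, scn, n)
            frames.append(pd.DataFrame({
                "position_label": position_label, "condition_id": cond,
                "replicate_id": rep, "is_control": is_control,
                "fsc": fsc, "ssc": ssc, "rfp": rfp, "yfp": yfp}))
    return pd.concat(frames, ignore_index=True)


def simulate_cells(scenario: SyntheticScenario) -> pd.DataFrame:
    """Simulate cytometry events for every position plus the no-site control.

    Returns one table with columns ``position_label, condition_id,
    replicate_id, is_control, fsc, ssc, rfp, yfp``.  Control events (the
    circuit with the binding site deleted) share the TF titration but have
    unit fold change; they carry ``position_label = 0`` by convention.
    """
    rng = np.random.default_rng(scenario.seed)
    frames = [_one_population(rng, scenario, tf, label, False)
              for label, tf in scenario.positions.items()]
    frames.append(_one_population(rng, scenario, None, 0, True))
    return pd.concat(frames, ignore_index=True)


def simulate_autofluorescence(scenario: SyntheticScenario, n_cells: int = 2000,
                              seed: int | None = None) -> pd.DataFrame:
    """Events from an autofluorescence strain (no mCherry, no reporter)."""
    rng = np.random.default_rng(scenario.seed + 1 if seed is None else seed)
    af = scenario.autofluorescence
    fsc, ssc = _scatter(rng, scenario, n_cells)
    return pd.DataFrame({
        "position_label": 0, "condition_id": -1, "replicate_id": 0,
        "is_control": True, "fsc": fsc, "ssc": ssc,
        "rfp": rng.normal(af["rfp_mean"], af["rfp_sd"], n_cells),
        "yfp": rng.normal(af["yfp_mean"], af["yfp_sd"], n_cells)})


def simulate_division_pairs(calib_v: float, n_pairs: int,
                            count_range: tuple[int, int] = (100, 1000),
                            seed: int = 0, background_sd: float = 0.0) -> pd.DataFrame:
    """Mother/daughter fluorescence pairs under binomial partitioning.

    Mother molecule counts are uniform over ``count_range``; each molecule
    segregates to daughter 1 with probability 1/2; intensities are
    ``calib_v`` per molecule plus optional Gaussian background noise.
    Columns: ``i1, i2, n_mother``.
    """
    if calib_v <= 0:
        raise ValueError("calib_v must be > 0")
    rng = np.random.default_rng(seed)
    lo, hi = count_range
    n = rng.integers(lo, hi + 1, size=n_pairs)
    n1 = rng.binomial(n, 0.5)
    i1 = calib_v * n1.astype(float)
    i2 = calib_v * (n - n1).astype(float)
    if background_sd > 0:
        i1 = i1 + rng.normal(0.0, background_sd, n_pairs)
        i2 = i2 + rng.normal(0.0, background_sd, n_pairs)
    return pd.DataFrame({"i1": i1, "i2": i2, "n_mother": n})


def fold_change_table(events: pd.DataFrame, control_events: pd.DataFrame,
                      calib_v: float, mu: float = 1.0) -> FoldChangeCurve:
    """Per-(condition, replicate) fold-change curve from event tables.

    Expects autofluorescence-subtracted events for a single position.  Fold
    change per condition/replicate is ``mean(yfp_regulated)/mean(yfp_control)``
    and the abscissa is the mean background-subtracted RFP divided by
    ``calib_v`` (times ``mu`` when the RFP is in cytometry units).
    """
    labels = events["position_label"].unique()
    if len(labels) != 1:
        raise ValueError("fold_change_table expects events from one position")
    rows = []
    ctrl = control_events.groupby(["condition_id", "replicate_id"])["yfp"].mean()
    for (cond, rep), grp in events.groupby(["condition_id", "replicate_id"]):
        if (cond, rep) not in ctrl.index:
            raise ValueError(f"condition {cond} replicate {rep} missing a control partner")
        fc = grp["yfp"].mean() / ctrl.loc[(cond, rep)]
        n_tf = mu * grp["rfp"].mean() / calib_v
        rows.append({"condition_id": cond, "replicate_id": rep,
                     "n_tf": max(n_tf, 0.0), "fc": fc, "fc_se": np.nan})
    return FoldChangeCurve(position_label=int(labels[0]), points=pd.DataFrame(rows))
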