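"""End-to-end orchestration: simulate -> calibrate -> gate -> bin -> infer -> report.

A :class:`RunConfig` fully determines a run: the synthetic scenario (or input
tables), the gating and binning settings, the model choice and sampler
settings, and one master seed from which every stage seed is derived.
Re-running the same config reproduces the summary outputs byte for byte.
Every filtering stage appends a structured record (events in / events out)
to the run log so conservation is machine-checkable.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import calibrate as cal
from . import simulate as sim
from .inference import ManifoldModel, ManifoldPriors, ManifoldResults, StabilizationOnlyModel
from .manifold import pair_by_concentration
from .thermo import PromoterParameters, TFRegulatoryParameters

__all__ = ["RunConfig", "run_pipeline", "report_phase_diagram",
           "classify_quadrant", "scenario_to_dict", "scenario_from_dict"]

QUADRANTS = {
    (True, True): "coherent activation (accelerate + stabilize)",
    (False, False): "coherent repression (decelerate + destabilize)",
    (False, True): "incoherent (stabilize + decelerate)",
    (True, False): "incoherent (accelerate + destabilize)",
}


@dataclass
class RunConfig:
    """Everything needed to reproduce one pipeline run."""

    scenario: sim.SyntheticScenario
    reference_label: int = 1           # the steric downstream (+1) position
    do_calibrate: bool = True
    do_gate: bool = True
    do_threshold: bool = True
    gate_level: float = 0.95
    gate_bins: int = 16
    gate_per_bin: bool = True
    rfp_threshold: float = 400.0
    analysis_bins: int = 22
    model: str = "manifold"            # or "stabilization_only"
    draws: int = 1250
    tune: int = 600
    chains: int = 4
    n_division_pairs: int = 3000
    seed: int = 0
    outdir: str = "tfmodes_run"

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["scenario"] = scenario_to_dict(self.scenario)
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        d["scenario"] = scenario_from_dict(d["scenario"])
        return cls(**d)


def scenario_to_dict(scn: sim.SyntheticScenario) -> dict:
    d = dataclasses.asdict(scn)
    d["positions"] = {str(k): dataclasses.asdict(v) for k, v in scn.positions.items()}
    d["promoter"] = dataclasses.asdict(scn.promoter)
    return d


def scenario_from_dict(d: dict) -> sim.SyntheticScenario:
    d = dict(d)
    d["positions"] = {int(k): TFRegulatoryParameters(**v)
                      for k, v in d["positions"].items()}
    d["promoter"] = PromoterParameters(**d["promoter"])
    for key in ("induction_means", "scatter_mean", "scatter_sd"):
        d[key] = tuple(d[key])
    return sim.SyntheticScenario(**d)


def classify_quadrant(results: ManifoldResults, mass_threshold: float = 0.8) -> dict:
    """Assign a regulatory quadrant from posterior mass around (alpha=1, beta=1).

    A position is placed in a quadrant when at least ``mass_threshold`` of
    the (alpha, beta) posterior lies inside it; posteriors whose tails span
    quadrants (the weak-stabilization degeneracy) are labeled unresolved.
    """
    a = results.samples["alpha"].reshape(-1)
    b = results.samples["beta"].reshape(-1)
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    masses = {}
    for (acc, stab), name in QUADRANTS.items():
        in_q = ((a > 1) == acc) & ((b > 1) == stab)
        masses[name] = float(np.mean(in_q))
    best = max(masses, key=masses.get)
    resolved = masses[best] >= mass_threshold
    fc_med = results.median("fc_max")
    return {"quadrant": best if resolved else "unresolved",
            "resolved": bool(resolved),
            "quadrant_mass": masses[best],
            "net_effect": "activation" if fc_med > 1 else "repression",
            "fc_max_median": fc_med,
            "alpha_median": results.median("alpha"),
            "beta_median": results.median("beta")}


def report_phase_diagram(results_by_position: dict[int, ManifoldResults],
                         mass_threshold: float = 0.8) -> pd.DataFrame:
    """Coherent/incoherent classification per position from posterior mass."""
    rows = []
    for label, res in sorted(results_by_position.items()):
        rows.append({"position_label": label,
                     **classify_quadrant(res, mass_threshold)})
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured run and persist all artifacts under ``outdir``.

    Returns a dict with the per-stage log, the per-position results and the
    paths of the written artifacts.  Any stage failure raises with the stage
    name; artifacts from completed stages remain on disk.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(config.to_json(), encoding="utf-8")
    log: list[dict] = []
    scn = config.scenario
    stage = "simulate"
    try:
        events = sim.simulate_cells(scn)
        af = sim.simulate_autofluorescence(scn)
        events.to_csv(out / "events.csv", index=False)
        log.append({"stage": stage, "n_in": 0, "n_out": len(events)})

        calib = None
        if config.do_calibrate:
            stage = "calibrate"
            pairs = sim.simulate_division_pairs(
                scn.calib_v, config.n_division_pairs, seed=config.seed + 11)
            calib = cal.estimate_calibration_factor(pairs, seed=config.seed + 12)
            log.append({"stage": stage, "n_in": len(pairs), "n_out": len(pairs)})

        stage = "autofluorescence"
        events = cal.subtract_autofluorescence(events, af)

        if config.do_gate:
            stage = "gate"
            n_in = len(events)
            flagged = cal.ellipsoid_gate(events, level=config.gate_level,
                                         n_rfp_bins=config.gate_bins,
                                         per_bin=config.gate_per_bin)
            flagged.to_csv(out / "gated_events.csv", index=False)
            events = flagged[flagged["retained"]].drop(columns=["retained"])
            log.append({"stage": stage, "n_in": n_in, "n_out": len(events),
                        "n_removed": n_in - len(events)})

        if config.do_threshold:
            stage = "rfp_threshold"
            n_in = len(events)
            events = cal.rfp_threshold_filter(events, config.rfp_threshold)
            log.append({"stage": stage, "n_in": n_in, "n_out": len(events),
                        "n_removed": n_in - len(events)})

        stage = "bin_and_pair"
        regulated = events[~events["is_control"]]
        control = events[events["is_control"]]
        edges = cal.proportional_bin_edges(regulated["rfp"].to_numpy(),
                                           config.analysis_bins)
        curves, datasets = {}, {}
        ref_events = regulated[regulated["position_label"] == config.reference_label]
        ref_curve = cal.binned_fold_change(ref_events, control, edges,
                                           position_label=config.reference_label)
        curves[config.reference_label] = ref_curve
        for label in sorted(regulated["position_label"].unique()):
            if label == config.reference_label:
                continue
            curve = cal.binned_fold_change(
                regulated[regulated["position_label"] == label], control, edges,
                position_label=label)
            curves[label] = curve
            curve.to_csv(out / f"curve_{label}.csv")
            datasets[label] = pair_by_concentration(ref_curve, curve)
            datasets[label].to_csv(out / f"manifold_{label}.csv")
        ref_curve.to_csv(out / f"curve_{config.reference_label}.csv")
        log.append({"stage": stage, "n_in": len(events),
                    "n_out": sum(len(d) for d in datasets.values())})

        stage = "infer"
        results: dict[int, ManifoldResults] = {}
        summaries = {}
        if config.model == "manifold":
            for j, (label, ds) in enumerate(sorted(datasets.items())):
                res = ManifoldModel(ds, promoter=scn.promoter).fit(
                    draws=config.draws, tune=config.tune, chains=config.chains,
                    seed=config.seed + 100 + j)
                results[label] = res
                res.to_frame().to_csv(out / f"chains_{label}.csv", index=False)
                summ = res.summary()
                summaries[str(label)] = {
                    p: {"median": round(summ.loc[p, "median"], 6),
                        "ci68": [round(summ.loc[p, "ci68_low"], 6),
                                 round(summ.loc[p, "ci68_high"], 6)]}
                    for p in summ.index}
        elif config.model == "stabilization_only":
            res = StabilizationOnlyModel(datasets).fit(
                draws=config.draws, tune=config.tune, chains=config.chains,
                seed=config.seed + 100)
            summ = res.summary()
            summaries = {p: {"median": round(summ.loc[p, "median"], 6)}
                         for p in summ.index}
        else:
            raise ValueError(f"unknown model {config.model!r}")

        stage = "report"
        summary = {"seed": config.seed, "model": config.model,
                   "positions": summaries,
                   "calibration_v": None if calib is None else round(calib.v, 6)}
        if results:
            phases = report_phase_diagram(results)
            phases.to_csv(out / "phase_diagram.csv", index=False)
            summary["phases"] = {str(r["position_label"]): r["quadrant"]
                                 for _, r in phases.iterrows()}
        (out / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True), encoding="utf-8")
        (out / "log.json").write_text(json.dumps(log, indent=2), encoding="utf-8")
    except Exception as err:
        (out / "log.json").write_text(json.dumps(
            log + [{"stage": stage, "error": str(err)}], indent=2), encoding="utf-8")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err
    return {"log": log, "results": results, "curves": curves,
            "datasets": datasets, "summary": summary, "outdir": str(out)}
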