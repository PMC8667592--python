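# tfmodes

Decomposing a transcription factor's regulatory effect into **RNAP
stabilization** and **transcription-initiation acceleration**, for people who
study bacterial gene regulation quantitatively: systems/synthetic biologists
fitting thermodynamic models to single-cell reporter data, and method
developers who want a fully synthetic, ground-truthed test bed for that
inference chain.

## The model

A promoter bound by a single transcription factor (TF) is treated as a
four-state system in thermodynamic equilibrium (unbound / RNAP-bound /
TF-bound / co-bound).  Two dimensionless parameters capture everything the TF
does to transcription when co-bound with RNAP:

* **β (stabilization)** multiplies the statistical weight of the co-bound
  state — β > 1 means the TF lengthens RNAP dwell times, β < 1 shortens them,
  β = 0 is steric exclusion;
* **α (acceleration)** multiplies the transcription rate from the co-bound
  state — α > 1 speeds initiation, α < 1 slows it.

With the promoter occupancy parameter *P* = (*N*ₚ/*N*_NS)·e^(−Δεₚ) (≈ 6.65×10⁻²
for the weak promoter used here) and the scaled TF affinity
λ = e^(−Δε_TF)/*N*_NS, every fold-change-versus-TF-number curve collapses to

    fold change = (1 + FC_max · χN) / (1 + χN),
    FC_max = αβ / (1 + Pβ),        χ = λ(1 + Pβ),

so a curve is fully described by its saturating fold change *FC*_max and the
effective concentration χ*N*.  Because χ entangles affinity with
stabilization, α and β cannot be separated from a single titration curve when
β ≪ 1/P ≈ 15 (the *weak-stabilization limit*).

The **concentration manifold** removes affinity and copy number entirely:
plotting the fold change at a query position against the fold change at a
steric reference site (+1, where FC_max = 0 and β = 0) at matched TF levels
gives a curve that depends only on (FC_max, K) with K = 1 + Pβ — a straight
line from (1, 1) to (0, FC_max) when K = 1, and super-linear curvature when
K > 1.  A Gaussian-likelihood Bayesian fit of (FC_max, K, σ) on these pairs,
followed by the draw-wise transforms β = (K−1)/P and
α = (FC_max/β)(1 + (P/(1+P))(β−1)), yields posteriors for the two regulatory
modes and classifies each binding position as coherent (α and β pushing the
same way) or incoherent (opposing).

The package also implements the surrounding measurement chain on synthetic
single-cell data with known ground truth: fluctuation-counting calibration
((I₁−I₂)² = v(I₁+I₂) from binomial partitioning at division), chi-square
ellipsoid gating on log-scatter channels, proportional (equal-count) RFP
binning, the cytometry-to-molecule scaling μ, bootstrap least-squares fits of
(FC_max, χ), a global-affinity model, and a stabilization-only (α = 1)
alternative whose activation ceiling (1+P)/P ≈ 16 is what rules it out on
strongly activated positions.

## Worked example

```python
import tfmodes as tm
from tfmodes.studies import manifold_pairs_from_truth, regime_truth

promoter = tm.PromoterParameters()          # P ~ 6.65e-2
print("P =", round(promoter.P, 5), " 1/P =", round(1 / promoter.P, 1))

tf = tm.TFRegulatoryParameters(alpha=2.161, beta=219.757, delta_eps_tf=-9.5)
eff = tm.effective_from_mechanistic(tf, promoter)
print(f"FC_max = {eff.fc_max:.2f}  chi = {eff.chi:.3g}  K = {eff.k_factor:.2f}")

# synthetic concentration-manifold data from a strongly stabilizing activator,
# then re-inference of (FC_max, K) and the derived (alpha, beta)
fc_truth, k_truth = regime_truth("coherent_activation", promoter.P)
dataset, sigma = manifold_pairs_from_truth(fc_truth, k_truth, seed=42)
result = tm.ManifoldModel(dataset, promoter=promoter).fit(seed=0)
print(result.summary().round(3))
```

prints

```
P = 0.06651  1/P = 15.0
FC_max = 30.41  chi = 0.0454  K = 15.62
            median  ci68_low  ci68_high  r_hat  ess_bulk
parameter
fc_max      32.387    31.996     32.765  1.003   969.650
k_factor    15.025    13.273     17.176  1.007   862.294
sigma        1.446     1.238      1.724  1.003   715.434
beta       210.861   184.515    243.202  1.007   862.294
alpha        2.164     2.125      2.204  1.005   982.580
```

The generating truth (α = 2.161, β = 219.757, so K = 15.62 and an exact-form
saturating fold change of 32.43) sits inside every 68% credible interval: the
manifold fit recovers both regulatory modes, and the diagnostics (R-hat,
bulk effective sample size over 4 walker groups) confirm the chains mixed.
`tm.plot_manifold(dataset, result)` and
`tm.plot_alpha_beta_posterior(result)` draw the fit and the posterior cloud;
`tm.classify_quadrant(result)` labels the position — here *coherent
activation (accelerate + stabilize)*.

For the full simulate → calibrate → gate → bin → pair → infer → report chain,
build a `tm.RunConfig` around a `tm.SyntheticScenario` and call
`tm.run_pipeline(config)` (or use the `tfmodes` CLI: `tfmodes run --config
run.json`).  Every artifact lands in the configured run directory and
re-running a config reproduces the summaries byte for byte.

## Layout

| module | contents |
| --- | --- |
| `tfmodes.thermo` | promoter/TF parameter types, state weights, exact and weak-limit fold change, effective parameters, data collapse |
| `tfmodes.manifold` | concentration-manifold transforms, (FC_max, K) ↔ (α, β) maps, curve pairing |
| `tfmodes.simulate` | synthetic cytometry events, division pairs, fold-change tables |
| `tfmodes.calibrate` | fluctuation counting, ellipsoid gating, proportional binning, μ scaling |
| `tfmodes.inference` | `TitrationCurveModel`, `ManifoldModel`, `GlobalAffinityModel`, `StabilizationOnlyModel` and their Results objects; bin-robustness sweep |
| `tfmodes.pipeline` | `RunConfig`, `run_pipeline`, quadrant/phase reporting |
| `tfmodes.studies` | frozen synthetic validation studies (recovery, falsification, bin sweep) |
| `tfmodes.cli` | `tfmodes` command-line entry point |

See `docs/methods.md` for the modeling assumptions, parameter defaults,
numerical choices and known limitations.
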