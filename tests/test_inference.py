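"""Bootstrap curve fitting, Bayesian manifold inference, alternative models."""

import warnings

import numpy as np
import pandas as pd
import pytest

import tfmodes as tm

from conftest import REGIMES, abundance_grid, manifold_dataset_from_truth, regime_truth


def make_titration_curve(eff, seed=0, fc_noise_cv=0.08, n_reps=3,
                         conditions=None, label=-61):
    conditions = np.geomspace(3, 3000, 11) if conditions is None else conditions
    rng = np.random.default_rng(seed)
    rows = []
    for c, n in enumerate(conditions):
        for r in range(n_reps):
            fc = tm.fold_change_weak(n, eff) * rng.lognormal(0.0, fc_noise_cv)
            rows.append({"condition_id": c, "replicate_id": r, "n_tf": n, "fc": fc})
    return tm.FoldChangeCurve(position_label=label, points=pd.DataFrame(rows))


class TestBootstrapCurveFit:
    def test_noise_free_steric_curve(self):
        x = np.geomspace(10, 1e5, 12)
        curve = tm.FoldChangeCurve(position_label=1, points=pd.DataFrame(
            {"condition_id": range(12), "n_tf": x, "fc": 1.0 / (1.0 + 1e-3 * x)}))
        fit = tm.fit_curve_bootstrap(curve, n_boot=50, seed=0)
        assert fit.fc_max_mean < 1e-3           # consistent with zero
        assert abs(fit.chi_mean - 1e-3) < 1e-6
        assert not fit.diagnostic_failure

    def test_unsaturated_repression_consistent_with_zero(self):
        # weak binding: curve never saturates, fc_max CI reaches 0
        eff = tm.EffectiveParameters(fc_max=0.0, chi=3e-5)
        curve = make_titration_curve(eff, seed=4, label=1)
        fit = tm.fit_curve_bootstrap(curve, n_boot=200, seed=1)
        assert fit.fc_max_ci95[0] < 0.05

    def test_intervals_contain_point_estimate(self):
        eff = tm.EffectiveParameters(fc_max=4.0, chi=2e-3, k_factor=1.5)
        fit = tm.fit_curve_bootstrap(make_titration_curve(eff, seed=2),
                                     n_boot=200, seed=3)
        assert fit.fc_max_ci95[0] <= fit.fc_max_mean <= fit.fc_max_ci95[1]
        assert fit.chi_ci95[0] <= fit.chi_mean <= fit.chi_ci95[1]

    def test_bootstrap_ci_covers_truth(self):
        """95% CIs cover the generating (fc_max, chi) at roughly nominal rate."""
        eff = tm.EffectiveParameters(fc_max=4.0, chi=2e-3, k_factor=1.5)
        hits_fc = hits_chi = 0
        n_rep = 40
        for rep in range(n_rep):
            curve = make_titration_curve(eff, seed=100 + rep)
            fit = tm.fit_curve_bootstrap(curve, n_boot=150, seed=rep)
            hits_fc += fit.fc_max_ci95[0] <= 4.0 <= fit.fc_max_ci95[1]
            hits_chi += fit.chi_ci95[0] <= 2e-3 <= fit.chi_ci95[1]
        # 95% +/- 5% band, plus binomial noise at 40 repeats
        assert hits_fc / n_rep >= 0.85
        assert hits_chi / n_rep >= 0.85

    def test_too_few_levels_rejected(self):
        curve = tm.FoldChangeCurve(position_label=1, points=pd.DataFrame(
            {"condition_id": [0, 1], "n_tf": [1.0, 10.0], "fc": [0.9, 0.5]}))
        with pytest.raises(ValueError):
            tm.TitrationCurveModel(curve)


class TestManifoldModel:
    def test_identifiable_regime_recovery_and_convergence(self, promoter):
        fc_t, k_t = regime_truth("coherent_activation", promoter.P)
        ds, _ = manifold_dataset_from_truth(fc_t, k_t, seed=5)
        res = tm.ManifoldModel(ds, promoter=promoter).fit(seed=6)
        assert res.converged
        summ = res.summary()
        assert (summ.loc[["fc_max", "k_factor", "sigma"], "r_hat"] < 1.01).all()
        assert (summ.loc[["fc_max", "k_factor", "sigma"], "ess_bulk"] > 400).all()
        assert res.median("fc_max") == pytest.approx(fc_t, rel=0.1)
        lo, hi = res.ci68("beta")
        assert lo < (k_t - 1) / promoter.P < hi * 1.5

    def test_weak_stabilization_limit(self, promoter):
        ds, _ = manifold_dataset_from_truth(4.0, 1.05, seed=7, noise_frac=0.01)
        res = tm.ManifoldModel(ds, promoter=promoter).fit(seed=8)
        assert res.median("fc_max") == pytest.approx(4.0, rel=0.05)
        assert res.median("k_factor") < 1.3
        # alpha and beta individually unconstrained, strongly anticorrelated
        assert res.log_alpha_beta_correlation() <= -0.9

    def test_zero_information_posterior_is_prior(self, promoter):
        pairs = pd.DataFrame({"fc_plus1": np.ones(8), "fc_query": np.ones(8)})
        ds = tm.ManifoldDataset(position_label=-61, pairs=pairs)
        priors = tm.ManifoldPriors(fc_max=(0.0, 10.0), sigma=(0.0, 1.0))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = tm.ManifoldModel(ds, promoter=promoter, priors=priors).fit(seed=9)
        # anchor-only data say nothing about fc_max or K: flat posteriors
        fc = res.fc_max_samples
        assert np.std(fc) > 0.6 * (10.0 / np.sqrt(12))    # near-uniform spread
        assert np.std(res.k_factor_samples) > 150.0

    def test_prior_saturation_warned(self, promoter):
        fc_t, k_t = regime_truth("coherent_activation", promoter.P)
        ds, _ = manifold_dataset_from_truth(fc_t, k_t, seed=10)
        priors = tm.ManifoldPriors(fc_max=(0.0, 5.0))    # truth ~32 excluded
        with pytest.warns(UserWarning, match="prior saturation"):
            res = tm.ManifoldModel(ds, promoter=promoter, priors=priors).fit(seed=11)
        assert res.prior_saturated

    def test_too_few_pairs_rejected(self):
        ds = tm.ManifoldDataset(position_label=-61, pairs=pd.DataFrame(
            {"fc_plus1": [1.0, 0.5], "fc_query": [1.0, 2.0]}))
        with pytest.raises(ValueError):
            tm.ManifoldModel(ds)


class TestDeriveAlphaBeta:
    def test_k_equal_one_flagged(self, P):
        samples = {"fc_max": np.full((2, 10), 3.0), "k_factor": np.ones((2, 10))}
        with pytest.warns(UserWarning, match="unidentifiable"):
            out = tm.derive_alpha_beta(samples, P)
        assert np.all(out["beta"] == 0.0)
        assert np.all(np.isnan(out["alpha"]))

    def test_round_trip_exact_form(self, P):
        rng = np.random.default_rng(13)
        k = 1.0 + rng.lognormal(0, 1, (4, 2500))
        fc = rng.lognormal(0, 1, (4, 2500))
        out = tm.derive_alpha_beta({"fc_max": fc, "k_factor": k}, P)
        # recompute the exact-form saturating fold change from (alpha, beta)
        recon = (out["alpha"] * out["beta"] * (1 + P)) / (1 + P * out["beta"])
        assert np.max(np.abs(recon - fc) / fc) < 1e-9


class TestGlobalAffinity:
    def test_single_steric_curve_identifies_lambda(self, promoter):
        lam = 3e-4
        chi = lam / (1.0 + promoter.P)
        x = np.geomspace(10, 1e5, 12)
        curve = tm.FoldChangeCurve(position_label=1, points=pd.DataFrame(
            {"condition_id": range(12), "n_tf": x, "fc": 1.0 / (1.0 + chi * x)}))
        res = tm.fit_global_affinity({1: curve}, {1: (0.0, 1.0)},
                                     promoter=promoter, seed=1)
        assert res.lambda_mean == pytest.approx(lam, rel=0.02)

    def test_multi_position_recovery(self, promoter):
        P = promoter.P
        lam = 1e-4
        rng = np.random.default_rng(21)
        curves, eff = {}, {}
        x = np.geomspace(10, 2e5, 12)
        for label, (fc_max, k) in {1: (0.0, 1.0), -60: (32.4, 15.6),
                                   -54: (0.55, 3.3)}.items():
            chi = lam * k / (1.0 + P)
            fc = (1 + fc_max * chi * x) / (1 + chi * x)
            # additive noise matched to the Gaussian likelihood
            fc = np.clip(fc + rng.normal(0, 0.02 * fc.max(), len(x)), 1e-6, None)
            curves[label] = tm.FoldChangeCurve(position_label=label, points=pd.DataFrame(
                {"condition_id": range(12), "n_tf": x, "fc": fc}))
            eff[label] = (fc_max, k)
        res = tm.fit_global_affinity(curves, eff, promoter=promoter, seed=2)
        assert res.lambda_mean == pytest.approx(lam, rel=0.10)

    def test_heterogeneous_affinity_leaves_residual_trend(self, promoter):
        """A per-position lambda violation shows up as posterior misfit."""
        P = promoter.P
        x = np.geomspace(10, 2e5, 12)

        def build(lams):
            curves, eff = {}, {}
            for (label, (fc_max, k)), lam in zip(
                    {1: (0.0, 1.0), -60: (32.4, 15.6)}.items(), lams):
                chi = lam * k / (1.0 + P)
                curves[label] = tm.FoldChangeCurve(
                    position_label=label, points=pd.DataFrame(
                        {"condition_id": range(12), "n_tf": x,
                         "fc": (1 + fc_max * chi * x) / (1 + chi * x)}))
                eff[label] = (fc_max, k)
            return curves, eff

        def worst_residual(curves, eff, res):
            worst = 0.0
            for label, curve in curves.items():
                fc_max, k = eff[label]
                chi = res.lambda_mean * k / (1.0 + P)
                pred = (1 + fc_max * chi * x) / (1 + chi * x)
                scale = max(np.max(np.abs(curve.points["fc"])), 1.0)
                worst = max(worst, np.abs(
                    np.mean(curve.points["fc"].to_numpy() - pred)) / scale)
            return worst

        hom = build([1e-4, 1e-4])
        het = build([1e-4, 1e-3])    # tenfold affinity violation at -60
        res_hom = tm.fit_global_affinity(*hom, promoter=promoter, seed=3)
        res_het = tm.fit_global_affinity(*het, promoter=promoter, seed=3)
        assert worst_residual(*hom, res_hom) < 0.01
        assert worst_residual(*het, res_het) > 5 * worst_residual(*hom, res_hom)

    def test_requires_steric_reference(self, promoter):
        x = np.geomspace(10, 1e5, 6)
        c = tm.FoldChangeCurve(position_label=-60, points=pd.DataFrame(
            {"condition_id": range(6), "n_tf": x, "fc": np.linspace(1, 5, 6)}))
        with pytest.raises(ValueError, match="\\+1 reference"):
            tm.GlobalAffinityModel({-60: c}, {-60: (5.0, 2.0)})


class TestStabilizationOnly:
    def test_activation_ceiling_value(self):
        assert tm.stabilization_only_bound(6.65e-2) == pytest.approx(16.038, abs=0.01)

    def test_alpha_one_data_well_fit(self, promoter):
        P = promoter.P
        datasets = {}
        for label, beta in ((-60, 30.0), (-50, 150.0)):
            fc_max = beta * (1 + P) / (1 + P * beta)
            ds, _ = manifold_dataset_from_truth(fc_max, 1 + P * beta,
                                                seed=abs(label), position_label=label)
            datasets[label] = ds
        res = tm.StabilizationOnlyModel(datasets).fit(draws=2500, tune=1500, seed=1)
        for label, beta in ((-60, 30.0), (-50, 150.0)):
            # good fit: beta lands near truth and nothing is underfit
            assert np.median(res.beta_samples(label)) == pytest.approx(beta, rel=0.2)
            ds = datasets[label]
            sig = 0.05 * np.max(np.abs(ds.pairs["fc_query"]))
            assert abs(res.mean_residual(label)) < 2 * sig

    def test_strong_activation_systematically_underfit(self, promoter):
        """Fold changes above (1+P)/P cannot be explained without acceleration."""
        P = promoter.P
        fc_t, k_t = 264.72, 2.965      # needs alpha ~ 25; ceiling is ~16
        strong, sig = manifold_dataset_from_truth(fc_t, k_t, seed=2,
                                                  position_label=-64)
        datasets = {-64: strong}
        for label, beta in ((-60, 30.0), (-50, 150.0)):
            fc_max = beta * (1 + P) / (1 + P * beta)
            datasets[label], _ = manifold_dataset_from_truth(
                fc_max, 1 + P * beta, seed=abs(label), position_label=label)
        res = tm.StabilizationOnlyModel(datasets).fit(draws=2500, tune=1500, seed=3)
        assert res.mean_residual(-64) > 5 * sig


class TestBinRobustness:
    @pytest.fixture(scope="class")
    def gated_events(self):
        scn = tm.SyntheticScenario(
            positions={
                1: tm.TFRegulatoryParameters(alpha=1.0, beta=0.0, delta_eps_tf=-12.5),
                -60: tm.TFRegulatoryParameters(alpha=2.161, beta=219.757,
                                               delta_eps_tf=-12.5),
            },
            cells_per_condition=600, n_replicates=3, seed=17)
        ev = tm.simulate_cells(scn)
        af = tm.simulate_autofluorescence(scn)
        ev = tm.subtract_autofluorescence(ev, af)
        gated = tm.ellipsoid_gate(ev, level=0.95, n_rfp_bins=16)
        ev = gated[gated["retained"]].drop(columns=["retained"])
        ev = tm.rfp_threshold_filter(ev, 400.0)
        return ev[~ev["is_control"]], ev[ev["is_control"]]

    def test_reference_bin_count_ratio_is_zero(self, gated_events):
        reg, ctl = gated_events
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sweep = tm.bin_robustness_sweep(reg, ctl, bin_counts=[22],
                                            reference_bins=22, seed=1)
        assert sweep["mean_log10_beta_ratio"].iloc[0] == 0.0
        assert sweep["mean_log10_alpha_ratio"].iloc[0] == 0.0

    def test_stable_above_twelve_bins(self, gated_events):
        reg, ctl = gated_events
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sweep = tm.bin_robustness_sweep(reg, ctl, bin_counts=[14, 18, 22],
                                            reference_bins=22, seed=2)
        assert (sweep["mean_log10_beta_ratio"].abs() < 0.25).all()

    def test_oversized_bin_count_skipped(self, gated_events):
        reg, ctl = gated_events
        with pytest.warns(UserWarning, match="exceeds event count"):
            sweep = tm.bin_robustness_sweep(
                reg, ctl, bin_counts=[len(reg) + len(ctl) + 10],
                reference_bins=22, seed=3)
        assert len(sweep) == 0
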