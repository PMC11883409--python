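"""Epoch construction, interaction mixed models, and the fitness regressions."""

import numpy as np
import pandas as pd
import pytest

from splitbelt.phases import (build_epochs, fitness_regression, interaction_lmm,
                              metabolic_lag_regression)
from splitbelt.synth import generate_fitness_dataset


def toy_metrics(n_subjects=3, duration=1200.0, dt=1.1, seed=0):
    rng = np.random.default_rng(seed)
    frames, breaths = [], []
    for i in range(n_subjects):
        t = np.arange(0.0, duration, dt)
        frames.append(pd.DataFrame({
            "subject": f"S{i}", "t": t,
            "sla": rng.normal(0, 0.01, t.size),
            "mos_fast": rng.normal(3, 0.1, t.size),
            "mos_slow": rng.normal(2.5, 0.1, t.size),
            "w_net": rng.normal(-5, 1, t.size),
        }))
        tb = np.arange(0.0, duration, 4.0)
        breaths.append(pd.DataFrame({
            "subject": f"S{i}", "t": tb,
            "w_net_metabolic": rng.normal(150, 5, tb.size)}))
    return pd.concat(frames, ignore_index=True), pd.concat(breaths, ignore_index=True)


class TestBuildEpochs:
    def test_initial_bin_count_with_partial_bin_retained(self):
        """r_f = 23 s, 3-s bins: 7 full bins plus a retained 2-s bin."""
        sm, bm = toy_metrics(1)
        ep = build_epochs(sm, bm, r_f=23.0)
        initial = ep[ep["epoch"] == "initial"]
        assert initial["bin"].nunique() == 8

    def test_later_biomechanics_window_has_40_bins(self):
        sm, bm = toy_metrics(1)
        ep = build_epochs(sm, bm, r_f=23.0)
        later = ep[ep["epoch"] == "later"]
        assert later["bin"].nunique() == 40
        assert later["bin_mid"].between(900, 1020).all()

    def test_zero_lag_aligns_metabolic_and_biomech_bins(self):
        sm, bm = toy_metrics(1)
        bm2 = sm[["subject", "t"]].assign(w_net_metabolic=1.0)
        ep0 = build_epochs(sm, bm2, r_f=23.0, lag=0.0)
        initial = ep0[ep0["epoch"] == "initial"]
        assert initial["w_net_metabolic"].notna().all()

    def test_bins_never_mix_subjects(self):
        sm, bm = toy_metrics(3)
        ep = build_epochs(sm, bm, r_f=23.0)
        per = ep.groupby("subject")["bin"].count()
        assert (per == per.iloc[0]).all()

    def test_bin_means_invariant_to_sample_order(self):
        sm, bm = toy_metrics(2)
        ep1 = build_epochs(sm, bm, r_f=23.0)
        shuffled = sm.sample(frac=1.0, random_state=1)
        ep2 = build_epochs(shuffled, bm, r_f=23.0)
        pd.testing.assert_frame_equal(
            ep1.sort_values(["subject", "epoch", "bin"]).reset_index(drop=True),
            ep2.sort_values(["subject", "epoch", "bin"]).reset_index(drop=True))

    def test_r_f_beyond_trial_rejected(self):
        sm, bm = toy_metrics(1)
        with pytest.raises(ValueError, match="r_f"):
            build_epochs(sm, bm, r_f=2000.0)


def constructed_epochs(slope_initial, slope_later, n_subjects=3, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_subjects):
        for epoch, slope, nb in (("initial", slope_initial, 8),
                                 ("later", slope_later, 40)):
            x = np.linspace(-1, 1, nb) + 0.1 * i
            y = slope * x + 0.05 * i + rng.normal(0, noise, nb)
            rows.append(pd.DataFrame({
                "subject": f"S{i}", "epoch": epoch, "bin": np.arange(nb),
                "bin_mid": np.arange(nb) * 3.0, "mos_fast": x, "sla": y,
                "w_net_metabolic": y}))
    return pd.concat(rows, ignore_index=True)


class TestInteractionLmm:
    def test_noiseless_slopes_recovered_exactly(self):
        ep = constructed_epochs(2.0, 0.0)
        res = interaction_lmm(ep, predictor="mos_fast", outcome="sla")
        assert res.slope_initial == pytest.approx(2.0, abs=1e-8)
        assert res.slope_later == pytest.approx(0.0, abs=1e-8)
        assert res.coef["mos_fast:later"] == pytest.approx(-2.0, abs=1e-8)

    def test_equal_slopes_zero_interaction(self):
        ep = constructed_epochs(1.5, 1.5)
        res = interaction_lmm(ep, predictor="mos_fast", outcome="sla")
        assert res.coef["mos_fast:later"] == pytest.approx(0.0, abs=1e-8)

    def test_single_subject_reduces_to_ols(self):
        """With one subject the random intercept vanishes and coefficients
        equal ordinary least squares to 1e-8."""
        ep = constructed_epochs(1.2, 0.3, n_subjects=1, noise=0.05, seed=2)
        res = interaction_lmm(ep, predictor="mos_fast", outcome="sla")
        later = (ep["epoch"] == "later").astype(float).to_numpy()
        x = ep["mos_fast"].to_numpy()
        X = np.column_stack([np.ones_like(x), x, later, x * later])
        beta = np.linalg.lstsq(X, ep["sla"].to_numpy(), rcond=None)[0]
        got = [res.coef["intercept"], res.coef["mos_fast"], res.coef["later"],
               res.coef["mos_fast:later"]]
        np.testing.assert_allclose(got, beta, atol=1e-8)

    def test_agrees_with_statsmodels_mixedlm(self):
        """Independent oracle: statsmodels MixedLM (ML) on the same data."""
        import statsmodels.formula.api as smf

        ep = constructed_epochs(1.0, 0.2, n_subjects=6, noise=0.3, seed=4)
        res = interaction_lmm(ep, predictor="mos_fast", outcome="sla")
        ep2 = ep.assign(later=(ep["epoch"] == "later").astype(float))
        m = smf.mixedlm("sla ~ mos_fast * later", ep2,
                        groups=ep2["subject"]).fit(reml=False)
        assert res.coef["mos_fast"] == pytest.approx(m.params["mos_fast"], abs=2e-3)
        assert res.coef["mos_fast:later"] == pytest.approx(
            m.params["mos_fast:later"], abs=2e-3)
        # exact profile likelihood can only be at least as good as the oracle's
        assert res.loglik >= m.llf - 1e-3
        assert res.loglik == pytest.approx(m.llf, abs=0.05)

    def test_single_epoch_rejected(self):
        ep = constructed_epochs(1.0, 0.0)
        with pytest.raises(ValueError, match="both epochs"):
            interaction_lmm(ep[ep["epoch"] == "initial"], predictor="mos_fast")

    def test_metabolic_regression_swaps_outcome_and_predictor(self):
        ep = constructed_epochs(1.0, 1.0)
        res = metabolic_lag_regression(ep)
        assert res.outcome == "w_net_metabolic" and res.predictor == "sla"


class TestFitnessRegression:
    def test_exact_quadratic_selected_with_exact_coefficients(self):
        df = generate_fitness_dataset(20, quad_coeffs=(-0.018, 0.001), noise_sd=0.0)
        res = fitness_regression(df)
        assert res.model == "quadratic"
        assert res.coef["tilt"] == pytest.approx(-0.018, abs=1e-10)
        assert res.coef["convexity"] == pytest.approx(0.001, abs=1e-10)
        assert res.vertex_centered == pytest.approx(9.0, abs=1e-6)

    def test_gender_covariate_dropped_when_uninformative(self):
        df = generate_fitness_dataset(24, quad_coeffs=(-0.018, 0.001),
                                      noise_sd=0.01, seed=5)
        res = fitness_regression(df)
        assert res.model == "quadratic"
        assert not res.gender_covariate

    def test_exact_linear_data_selects_linear(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({
            "vo2peak": rng.normal(40, 5, 16),
            "gender": ["woman", "man"] * 8,
        })
        df["vo2peak_centered"] = (df["vo2peak"]
                                  - df.groupby("gender")["vo2peak"].transform("mean"))
        df["delta_sla"] = 0.004 * df["vo2peak_centered"]
        res = fitness_regression(df)
        assert res.model == "linear"
        assert res.coef["tilt"] == pytest.approx(0.004, abs=1e-10)

    def test_degenerate_design_rejected(self):
        df = pd.DataFrame({"vo2peak": [40.0] * 6, "gender": ["man"] * 6,
                           "delta_sla": np.arange(6.0)})
        with pytest.raises(ValueError, match="degenerate"):
            fitness_regression(df)

    def test_vertex_mapped_back_to_raw_scale(self):
        df = generate_fitness_dataset(24, quad_coeffs=(-0.018, 0.001), noise_sd=0.0,
                                      seed=3)
        res = fitness_regression(df)
        assert res.vertex_raw == pytest.approx(df["vo2peak"].mean() + 9.0, abs=1e-6)
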