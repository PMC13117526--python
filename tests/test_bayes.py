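"""Bayesian outcome models: Pr(sup), regression posteriors, EEG LMM, MICE, panel."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pigtrial.bayes import (
    fit_eeg_model,
    fit_ihc_panel,
    fit_mrs_model,
    impute_chained,
    pr_superiority,
    sample_linear_regression,
)
from pigtrial.scores import REGIONS
from pigtrial.synthetic import TrialConfig, generate_trial


def make_animals(n_per_arm, seed=0):
    rng = np.random.default_rng(seed)
    ids = [f"P{i:02d}" for i in range(2 * n_per_arm)]
    return pd.DataFrame(
        {
            "animal_id": ids,
            "arm": ["vehicle"] * n_per_arm + ["treated"] * n_per_arm,
            "sex": rng.choice(["M", "F"], 2 * n_per_arm),
            "weight_kg": 2.0,
        }
    )


def make_mrs(animals, effect, sd, seed, voxel="BGT"):
    rng = np.random.default_rng(seed)
    shift = np.where(animals["arm"] == "treated", effect, 0.0)
    return pd.DataFrame(
        {
            "animal_id": animals["animal_id"],
            "voxel": voxel,
            "log10_lacnaa": rng.normal(0.1 + shift, sd),
        }
    )


def make_ihc(animals, shift_sd_units, seed, base=500.0, sd=100.0, rho=0.5):
    rng = np.random.default_rng(seed)
    rows = []
    for _, a in animals.iterrows():
        u = rng.normal(0, sd * np.sqrt(rho))
        for r in REGIONS:
            d = base + u + rng.normal(0, sd * np.sqrt(1 - rho))
            if a["arm"] == "treated":
                d += shift_sd_units * sd
            rows.append(
                {"animal_id": a["animal_id"], "region": r, "marker": "NeuN", "density": d}
            )
    return pd.DataFrame(rows)


class TestPrSuperiority:
    def test_all_favourable(self):
        assert pr_superiority(np.ones(2000), "greater") == 1.0
        assert pr_superiority(-np.ones(2000), "less") == 1.0

    def test_symmetric_draws_near_half(self):
        draws = np.random.default_rng(0).standard_normal(50_000)
        assert pr_superiority(draws, "greater") == pytest.approx(0.5, abs=0.01)

    def test_direction_never_inferred(self):
        with pytest.raises(ValueError):
            pr_superiority(np.ones(2000), "up")

    def test_too_few_draws(self):
        with pytest.raises(ValueError):
            pr_superiority(np.ones(10), "greater")

    def test_matches_gaussian_closed_form(self):
        # known-variance conjugate case: Pr(sup) = Phi(estimate / SE)
        est, se = 0.3, 0.18
        draws = np.random.default_rng(1).normal(est, se, 40_000)
        expected = stats.norm.cdf(est / se)
        mc_se = np.sqrt(expected * (1 - expected) / draws.size)
        assert pr_superiority(draws, "greater") == pytest.approx(expected, abs=3 * mc_se)


class TestLinearRegressionSampler:
    def test_posterior_mean_matches_ols(self):
        rng = np.random.default_rng(2)
        X = np.column_stack([np.ones(30), rng.integers(0, 2, 30)])
        y = 0.5 * X[:, 1] + rng.normal(0, 1, 30)
        draws, rhat = sample_linear_regression(X, y, seed=3)
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        flat = draws[:, :, 1].ravel()
        mc_se = flat.std() / np.sqrt(flat.size)
        assert flat.mean() == pytest.approx(ols[1], abs=3 * mc_se)
        assert rhat < 1.01

    def test_singular_design_rejected(self):
        X = np.ones((10, 2))
        with pytest.raises(ValueError):
            sample_linear_regression(X, np.zeros(10))


class TestMRSModel:
    def test_identical_arms_give_half(self):
        animals = make_animals(12)
        rng = np.random.default_rng(5)
        vals = rng.normal(0.3, 0.4, 12)
        mrs = pd.DataFrame(
            {
                "animal_id": animals["animal_id"],
                "voxel": "BGT",
                "log10_lacnaa": np.concatenate([vals, vals]),  # mirrored arms
            }
        )
        s = fit_mrs_model(mrs, animals, seed=1)
        assert s.pr_sup == pytest.approx(0.5, abs=0.03)
        assert s.converged

    def test_single_arm_errors(self):
        animals = make_animals(6)
        animals["arm"] = "vehicle"
        mrs = make_mrs(animals, 0.0, 0.4, 0)
        with pytest.raises(ValueError):
            fit_mrs_model(mrs, animals)

    def test_posterior_mean_matches_ols_with_sex(self):
        animals = make_animals(12, seed=3)
        mrs = make_mrs(animals, -0.5, 0.4, seed=7)
        s = fit_mrs_model(mrs, animals, adjust_sex=True, seed=2)
        df = mrs.merge(animals, on="animal_id")
        X = np.column_stack(
            [np.ones(len(df)), df["arm"].eq("treated"), df["sex"].eq("M")]
        ).astype(float)
        ols = np.linalg.lstsq(X, df["log10_lacnaa"], rcond=None)[0]
        mc_se = s.draws.std() / np.sqrt(s.draws.size)
        assert s.point == pytest.approx(ols[1], abs=3 * mc_se)
        assert s.direction == "less"

    def test_null_pr_sup_uniform_across_replicates(self):
        # point-null generating process => Pr(sup) ~ Uniform(0,1)
        animals = make_animals(12)
        prs = []
        for s in range(500):
            mrs = make_mrs(animals, 0.0, 0.4, seed=40_000 + s)
            fit = fit_mrs_model(mrs, animals, seed=s, n_chains=4, n_draws=500)
            prs.append(fit.pr_sup)
        assert stats.kstest(prs, "uniform").pvalue > 0.01


class TestEEGModel:
    def test_constant_score_four_is_null(self, trial):
        rows = [
            {"animal_id": a, "hour": h, "score": 4}
            for a in trial.animals["animal_id"]
            for h in range(60)
        ]
        s = fit_eeg_model(pd.DataFrame(rows), trial.animals, seed=3,
                          n_draws=500, n_warmup=300)
        assert abs(s.point) < 0.05
        assert s.pr_sup == pytest.approx(0.5, abs=0.1)

    def test_too_few_epochs_errors(self, trial):
        short = trial.eeg[trial.eeg["hour"] < 6]
        with pytest.raises(ValueError):
            fit_eeg_model(short, trial.animals)

    def test_pr_sup_monotone_in_recovery_advantage(self):
        grid = [0.0, 0.015, 0.04]
        means = []
        for shift in grid:
            prs = []
            for rep in range(4):
                ds = generate_trial(
                    TrialConfig(eeg_recovery_shift=shift, seed=300 + rep)
                )
                s = fit_eeg_model(ds.eeg, ds.animals, seed=rep,
                                  n_draws=400, n_warmup=200)
                prs.append(s.pr_sup)
            means.append(np.mean(prs))
        assert means[0] < means[1] < means[2]

    def test_null_simulation_calibrated(self):
        # no arm effect: overall pr_sup should rarely be extreme
        inside = 0
        n_rep = 100
        for rep in range(n_rep):
            ds = generate_trial(
                TrialConfig(n_per_arm=8, eeg_recovery_shift=0.0, seed=600 + rep)
            )
            s = fit_eeg_model(ds.eeg, ds.animals, seed=rep, n_draws=400, n_warmup=200)
            inside += 0.05 < s.pr_sup < 0.95
        assert inside >= 0.90 * n_rep

    def test_per_epoch_contrasts_shape(self, trial):
        s = fit_eeg_model(trial.eeg, trial.animals, seed=0, n_draws=400, n_warmup=200)
        pe = s.extra["per_epoch"]
        assert len(pe) == 10
        assert set(pe.columns) == {"epoch", "effect", "cri_lo", "cri_hi", "pr_sup"}
        assert s.rhat < 1.01


class TestImputeChained:
    def _table(self, seed=0, n=60, miss=0.1):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, n)
        y = 0.8 * x + rng.normal(0, 0.6, n)
        z = -0.5 * x + rng.normal(0, 0.6, n)
        df = pd.DataFrame({"x": x, "y": y, "z": z})
        mask = rng.random(df.shape) < miss
        return df, df.mask(mask)

    def test_complete_table_identity(self):
        df, _ = self._table(miss=0.0)
        outs = impute_chained(df, n_imputations=3, seed=1)
        for o in outs:
            pd.testing.assert_frame_equal(o, df)

    def test_observed_cells_never_altered(self):
        _, dfm = self._table(seed=2)
        for o in impute_chained(dfm, n_imputations=2, seed=5):
            obs = dfm.notna()
            assert np.allclose(o.values[obs.values], dfm.values[obs.values])
            assert not o.isna().any().any()

    def test_seed_reproducibility(self):
        _, dfm = self._table(seed=3)
        a = impute_chained(dfm, n_imputations=3, seed=9)
        b = impute_chained(dfm, n_imputations=3, seed=9)
        for x, y in zip(a, b):
            pd.testing.assert_frame_equal(x, y)

    def test_mcar_pooled_means_unbiased(self):
        df, dfm = self._table(seed=4, n=400, miss=0.1)
        outs = impute_chained(dfm, n_imputations=5, seed=2)
        pooled = np.mean([o["y"].mean() for o in outs])
        se = df["y"].std() / np.sqrt(len(df))
        assert abs(pooled - df["y"].mean()) < 3 * se

    def test_all_missing_column_errors(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [np.nan] * 3})
        with pytest.raises(ValueError, match="b"):
            impute_chained(df)


class TestIHCPanel:
    def test_complete_data_matches_single_fit(self):
        animals = make_animals(12, seed=1)
        ihc = make_ihc(animals, 0.5, seed=2)
        a = fit_ihc_panel(ihc, animals, n_imputations=5, seed=7)
        b = fit_ihc_panel(ihc, animals, n_imputations=1, seed=7)
        pd.testing.assert_frame_equal(a.per_region, b.per_region)
        assert a.overall.pr_sup == b.overall.pr_sup
        assert a.n_imputations == 1  # no imputation variance on complete data

    def test_bh_adjustment_invariants(self):
        animals = make_animals(12, seed=3)
        ihc = make_ihc(animals, 0.4, seed=5)
        res = fit_ihc_panel(ihc, animals, seed=1)
        pr = res.per_region
        assert (pr["p_bh"] >= pr["p_raw"] - 1e-12).all()
        # BH-adjusted p monotone in raw p
        order = pr.sort_values("p_raw")
        assert order["p_bh"].is_monotonic_increasing

    def test_missing_region_errors(self):
        animals = make_animals(6)
        ihc = make_ihc(animals, 0.0, seed=0)
        ihc = ihc[ihc["region"] != "Hip"]
        with pytest.raises(ValueError, match="Hip"):
            fit_ihc_panel(ihc, animals)

    def test_heavily_missing_region_errors(self):
        animals = make_animals(8)
        ihc = make_ihc(animals, 0.0, seed=0)
        hip = ihc["region"] == "Hip"
        ihc.loc[ihc[hip].index[:10], "density"] = np.nan
        with pytest.raises(ValueError, match="missing"):
            fit_ihc_panel(ihc, animals)

    def test_uniform_shift_detected_with_power(self):
        # +1 SD shift in every region at n=12/arm: overall pr_sup > 0.95
        hits = 0
        n_rep = 50
        for rep in range(n_rep):
            animals = make_animals(12, seed=rep)
            ihc = make_ihc(animals, 1.0, seed=1000 + rep)
            res = fit_ihc_panel(ihc, animals, seed=rep, n_draws=300)
            hits += res.overall.pr_sup > 0.95
        assert hits >= 0.90 * n_rep

    def test_imputation_inflates_uncertainty(self):
        animals = make_animals(12, seed=9)
        ihc = make_ihc(animals, 0.5, seed=9)
        complete = fit_ihc_panel(ihc, animals, seed=3)
        rng = np.random.default_rng(0)
        drop = rng.random(len(ihc)) < 0.15
        ihc_miss = ihc.copy()
        ihc_miss.loc[drop, "density"] = np.nan
        imputed = fit_ihc_panel(ihc_miss, animals, n_imputations=5, seed=3)
        w_complete = complete.overall.cri95[1] - complete.overall.cri95[0]
        w_imputed = imputed.overall.cri95[1] - imputed.overall.cri95[0]
        # Rubin-style pooling: missing information cannot shrink the interval
        assert w_imputed > 0.8 * w_complete
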