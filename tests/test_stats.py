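"""Mixed-model recipes: recovery, calibration, adjusted R-squared ordering."""

import numpy as np
import pandas as pd
import pytest

from netlag.stats import (ModelSpec, fit_lmm, normalize_within_subject,
                          run_recipe)


def lmm_data(rng, beta=1.0, n_subj=8, n_per=8, re_sd=0.5, noise_sd=1.0):
    rows = []
    for s in range(n_subj):
        u = rng.normal(0, re_sd)
        for _ in range(n_per):
            x = rng.normal()
            rows.append({"subject": f"s{s}", "x": x,
                         "y": beta * x + u + rng.normal(0, noise_sd)})
    return pd.DataFrame(rows)


class TestFitLmm:
    def test_noiseless_fit_is_exact(self):
        rng = np.random.default_rng(0)
        rows = []
        for s in range(4):
            for _ in range(5):
                x = rng.normal()
                rows.append({"subject": f"s{s}", "x": x, "y": 2.0 * x + 1.0})
        res = fit_lmm(pd.DataFrame(rows), ModelSpec("y", ("x",)))
        assert res.params["x"] == pytest.approx(2.0, abs=1e-6)
        assert res.params["Intercept"] == pytest.approx(1.0, abs=1e-6)

    def test_ci_coverage_near_nominal(self):
        rng = np.random.default_rng(1)
        cover = 0
        n = 120
        for _ in range(n):
            res = fit_lmm(lmm_data(rng, beta=1.0), ModelSpec("y", ("x",)))
            lo, hi = res.conf_int.loc["x"]
            cover += lo <= 1.0 <= hi
        assert 0.88 <= cover / n <= 0.99

    def test_null_rejection_near_alpha(self):
        rng = np.random.default_rng(2)
        n = 150
        rej = sum(
            fit_lmm(lmm_data(rng, beta=0.0),
                    ModelSpec("y", ("x",))).tests["x"].p < 0.05
            for _ in range(n))
        assert rej / n < 0.12

    def test_missing_column_rejected(self):
        with pytest.raises(ValueError):
            fit_lmm(pd.DataFrame({"y": [1.0, 2.0]}), ModelSpec("y", ("x",)))

    def test_satterthwaite_df_matches_lmerTest_reference(self):
        """Frozen cross-check against R lmerTest (Satterthwaite anova) on a
        fixed dataset: DenDF 29.681, F 1.2281, p 0.2767."""
        rng = np.random.default_rng(3)
        rows = []
        for s in range(6):
            u = rng.normal(0, 0.7)
            for _ in range(6):
                x = rng.normal()
                rows.append({"subject": f"s{s}", "x": x,
                             "y": 0.3 * x + u + rng.normal()})
        res = fit_lmm(pd.DataFrame(rows), ModelSpec("y", ("x",)))
        t = res.tests["x"]
        assert t.df_den == pytest.approx(29.681, abs=0.05)
        assert t.f_stat == pytest.approx(1.2281, rel=2e-3)
        assert t.p == pytest.approx(0.2767, abs=3e-3)

    def test_single_subject_rejected(self):
        df = pd.DataFrame({"subject": ["a"] * 5, "x": np.arange(5.0),
                           "y": np.arange(5.0)})
        with pytest.raises(ValueError):
            fit_lmm(df, ModelSpec("y", ("x",)))


class TestNormalizeWithinSubject:
    def test_zero_mean_unit_sd_per_subject(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({"subject": np.repeat(["a", "b"], 10),
                           "v": rng.normal(5, 3, 20)})
        out = normalize_within_subject(df, ["v"])
        g = out.groupby("subject")["v"]
        assert np.allclose(g.mean(), 0.0, atol=1e-12)
        assert np.allclose(g.std(), 1.0, atol=1e-12)


def ttp_cohort(rng, n_subj=6, n_elec=6, jitter_sd=120.0):
    """TTP table with true latencies DAN 500 / SN 700 / DMN 1000 ms."""
    rows = []
    for s in range(n_subj):
        u = rng.normal(0, 40.0)
        for net, mu in (("DAN", 500.0), ("SN", 700.0), ("DMN", 1000.0)):
            for _ in range(n_elec):
                rows.append({"subject": f"s{s}", "network": net,
                             "ttp_ms": mu + u + rng.normal(0, jitter_sd)})
    return pd.DataFrame(rows)


class TestRecipes:
    def test_ttp_network_effect_and_ordering(self):
        rng = np.random.default_rng(4)
        hits = 0
        n_rep = 20
        for _ in range(n_rep):
            res = run_recipe("ttp_network", ttp_cohort(rng))
            ok = res.significant("C(network)") and res.extras["ordering_recovered"]
            hits += ok
        assert hits >= int(0.9 * n_rep)

    def test_dprime_coupling_detects_lag_only_association(self):
        rng = np.random.default_rng(5)
        found = 0
        n_rep = 15
        for _ in range(n_rep):
            rows = []
            for s in range(6):
                for r in range(6):
                    lag_z = rng.normal(-0.5, 0.3)
                    rows.append({"subject": f"s{s}", "run": r,
                                 "d_prime": -1.2 * lag_z + rng.normal(0, 0.25),
                                 "zero_lag_z": rng.normal(0, 0.3),
                                 "lag_min_z": lag_z})
            res = run_recipe("dprime_coupling", pd.DataFrame(rows))
            found += (res.significant("lag_min_z")
                      and not res.significant("zero_lag_z"))
        assert found >= int(0.8 * n_rep)

    def test_dprime_coupling_excludes_hard_runs(self):
        rng = np.random.default_rng(6)
        rows = []
        for s in range(4):
            for r in range(8):
                rows.append({"subject": f"s{s}", "run": r,
                             "d_prime": rng.normal(2, 0.5),
                             "zero_lag_z": rng.normal(), "lag_min_z": rng.normal(),
                             "mountain_rate": 0.10 if r < 4 else 0.25})
        res = run_recipe("dprime_coupling", pd.DataFrame(rows))
        assert res.n_obs == 16     # 25%-mountain runs excluded

    def test_task_rest_r2_ordering_lag_driven(self):
        rng = np.random.default_rng(7)
        wins = 0
        n_rep = 15
        for _ in range(n_rep):
            rows = []
            for s in range(8):
                for pair in range(6):
                    for cond, lag_mu in (("task", -0.8), ("rest", -0.3)):
                        rows.append({
                            "subject": f"s{s}", "pair": f"p{pair}",
                            "condition": cond,
                            "lag_min_z": rng.normal(lag_mu, 0.25),
                            "zero_lag_z": rng.normal(-0.1, 0.25)})
            res = run_recipe("task_rest", pd.DataFrame(rows))
            wins += res.adj_r2["both"] > res.adj_r2["zero_lag_only"]
        assert wins >= int(0.9 * n_rep)
        assert set(res.adj_r2) == {"both", "lag_min_only", "zero_lag_only"}

    def test_window_accuracy_detects_error_elevation(self):
        rng = np.random.default_rng(8)
        rows = []
        for s in range(6):
            u = rng.normal(0, 0.1)
            for acc, mu in (("correct", 0.0), ("error", 0.4)):
                for _ in range(5):
                    rows.append({"subject": f"s{s}", "accuracy": acc,
                                 "value": mu + u + rng.normal(0, 0.2)})
        res = run_recipe("window_accuracy", pd.DataFrame(rows))
        assert res.significant("C(accuracy)")

    def test_unknown_recipe_lists_names(self):
        with pytest.raises(ValueError, match="task_rest"):
            run_recipe("nope", pd.DataFrame())


class TestBandContributionComparison:
    def test_hfb_dominant_contributions_flagged(self):
        from netlag.stats import compare_band_contributions
        rng = np.random.default_rng(9)
        bands = ("delta", "theta", "alpha", "beta1", "beta2", "gamma", "hfb")
        rows = []
        for s in range(12):
            raw = rng.dirichlet(np.ones(7) * 2.0)
            raw[-1] += 0.8                 # HFB systematically dominant
            raw /= raw.sum()
            for b, v in zip(bands, raw):
                rows.append({"subject": f"s{s}", "band": b,
                             "contribution": v})
        out = compare_band_contributions(pd.DataFrame(rows))
        assert out["anova"]["p"] < 0.05
        hfb_tests = [t for t in out["pairwise"] if "hfb" in t["bands"]]
        assert len(hfb_tests) == 6
        assert all(t["significant"] for t in hfb_tests)

    def test_uniform_contributions_mostly_null(self):
        from netlag.stats import compare_band_contributions
        rng = np.random.default_rng(10)
        bands = ("delta", "theta", "alpha", "beta1", "beta2", "gamma", "hfb")
        rows = [{"subject": f"s{s}", "band": b, "contribution": v}
                for s in range(12)
                for b, v in zip(bands, rng.dirichlet(np.ones(7) * 5.0))]
        out = compare_band_contributions(pd.DataFrame(rows))
        assert out["anova"]["p"] > 0.01
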