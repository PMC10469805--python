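import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from admixprs import (
    compare_r2,
    compute_pcs,
    filter_mci_controls,
    fit_linear,
    fit_logistic,
    power_logistic_continuous,
    run_primary_analysis,
    simulate_power_logistic,
    subgroup_association,
)
from admixprs.panel import GenotypePanel


def make_cohort(n, rng, log_or=0.0, household_sd=0.0, prevalence=0.15):
    prs = rng.normal(size=n)
    age = rng.normal(60, 8, n)
    sex = rng.integers(0, 2, n)
    hh = rng.integers(0, n // 3, n)
    hh_eff = rng.normal(0, household_sd, n // 3 + 1)[hh] if household_sd else 0.0
    eta = log_or * prs + 0.02 * (age - 60) + hh_eff
    b0 = np.log(prevalence / (1 - prevalence))
    y = (rng.random(n) < expit(b0 + eta)).astype(int)
    return pd.DataFrame(
        {
            "mci": y,
            "prs": prs,
            "age_baseline": age,
            "sex": sex,
            "household_id": hh,
        }
    )


class TestFitLogistic:
    def test_consistency_with_generating_log_or(self):
        rng = np.random.default_rng(0)
        df = make_cohort(40_000, rng, log_or=0.25)
        res = fit_logistic(df, "prs", ("age_baseline", "sex"))
        assert abs(res.estimate - 0.25) < 0.05
        assert res.ci_low < 0.25 < res.ci_high
        # exponentiating the log-OR CI reproduces the OR CI
        assert res.or_ci == pytest.approx(
            (np.exp(res.ci_low), np.exp(res.ci_high))
        )

    def test_duplicated_exposure_collinearity_error(self):
        rng = np.random.default_rng(1)
        df = make_cohort(500, rng)
        df["prs_copy"] = df["prs"]
        with pytest.raises(ValueError, match="collinear"):
            fit_logistic(df, "prs", ("prs_copy",))

    def test_single_class_outcome_rejected(self):
        rng = np.random.default_rng(2)
        df = make_cohort(200, rng)
        df["mci"] = 0
        with pytest.raises(ValueError, match="both classes"):
            fit_logistic(df, "prs")

    def test_matches_r_glm_reference(self, tmp_path):
        """Estimates agree with R's glm to 1e-6 on a shared fixture."""
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript unavailable: reference comparison cannot run")
        rng = np.random.default_rng(3)
        df = make_cohort(400, rng, log_or=0.3)
        csv = tmp_path / "fixture.csv"
        df.to_csv(csv, index=False)
        rscript = tmp_path / "fit.R"
        rscript.write_text(
            "d <- read.csv(commandArgs(TRUE)[1])\n"
            "f <- glm(mci ~ prs + age_baseline + sex, data=d, family=binomial,\n"
            "         control=glm.control(epsilon=1e-12))\n"
            "cat(sprintf('%.10f %.10f', coef(f)['prs'],\n"
            "    sqrt(vcov(f)['prs','prs'])))\n"
        )
        out = subprocess.run(
            ["Rscript", str(rscript), str(csv)],
            capture_output=True,
            text=True,
            check=True,
        )
        r_beta, r_se = map(float, out.stdout.split())
        res = fit_logistic(df, "prs", ("age_baseline", "sex"))
        assert res.estimate == pytest.approx(r_beta, abs=1e-6)
        assert res.se == pytest.approx(r_se, abs=1e-6)

    def test_cluster_robust_se_inflates_under_clustering(self):
        # household-shared outcome noise + household-level exposure: the
        # sandwich SE must exceed the classical one on average
        rng = np.random.default_rng(4)
        ratios = []
        for _ in range(20):
            n_households = 300
            hh_x = rng.normal(size=n_households)
            hh_eff = rng.normal(0, 1.0, size=n_households)
            hh = np.repeat(np.arange(n_households), 4)
            y = 0.1 * hh_x[hh] + hh_eff[hh] + rng.normal(size=len(hh))
            df = pd.DataFrame({"y": y, "x": hh_x[hh], "household_id": hh})
            classical = fit_linear(df, "y", "x")
            robust = fit_linear(df, "y", "x", cluster_var="household_id")
            ratios.append(robust.se / classical.se)
        assert np.mean(ratios) > 1.1


class TestFitLinear:
    def test_identity_regression(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame({"y": rng.normal(size=100)})
        df["x"] = df["y"]
        res = fit_linear(df, "y", "x")
        assert res.estimate == pytest.approx(1.0)
        assert res.se < 1e-10

    def test_slope_recovery(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=5000)
        y = 0.1 * x + rng.normal(size=5000)
        df = pd.DataFrame({"y": y, "x": x})
        res = fit_linear(df, "y", "x")
        assert abs(res.estimate - 0.1) < 0.03


class TestComputePcs:
    def test_pc1_separates_divergent_groups(self):
        rng = np.random.default_rng(7)
        n, m = 1000, 500
        group = rng.integers(0, 2, n)
        f = np.where(group[:, None] == 0, 0.2, 0.7)
        dos = rng.binomial(2, np.broadcast_to(f, (n, m))).astype(float)
        variants = pd.DataFrame(
            {"chrom": "1", "pos": np.arange(1, m + 1) * 100, "ref": "A", "alt": "G"}
        )
        panel = GenotypePanel([str(i) for i in range(n)], variants, dos)
        pcs = compute_pcs(panel, 2)
        r = np.corrcoef(pcs["PC1"], group)[0, 1]
        assert abs(r) > 0.9

    def test_shape_contract(self):
        rng = np.random.default_rng(8)
        dos = rng.binomial(2, 0.5, size=(50, 10)).astype(float)
        variants = pd.DataFrame(
            {"chrom": "1", "pos": np.arange(1, 11) * 100, "ref": "A", "alt": "G"}
        )
        panel = GenotypePanel([str(i) for i in range(50)], variants, dos)
        pcs = compute_pcs(panel, 1)
        assert pcs.shape == (50, 1)

    def test_zero_variance_rejected(self):
        variants = pd.DataFrame(
            {"chrom": ["1"], "pos": [100], "ref": ["A"], "alt": ["G"]}
        )
        panel = GenotypePanel(["a", "b"], variants, np.ones((2, 1)))
        with pytest.raises(ValueError, match="rank|variance"):
            compute_pcs(panel, 1)


class TestPower:
    def test_null_effect_returns_alpha_over_two(self):
        assert power_logistic_continuous(1000, 0.1, 1.0, 0.05) == pytest.approx(
            0.025, abs=1e-12
        )

    def test_printed_biobank_scenario_high_power(self):
        p = 885 / 23158
        values = [
            power_logistic_continuous(23158, p, o, 0.05) for o in (1.28, 1.19, 1.27)
        ]
        assert min(values) > 0.98

    def test_monotone_in_n_and_effect(self):
        grid_n = [power_logistic_continuous(n, 0.1, 1.3) for n in (200, 800, 3200)]
        assert grid_n == sorted(grid_n) and grid_n[0] < grid_n[-1]
        grid_or = [power_logistic_continuous(800, 0.1, o) for o in (1.1, 1.3, 1.6)]
        assert grid_or == sorted(grid_or) and grid_or[0] < grid_or[-1]
        # symmetric in the direction of effect
        assert power_logistic_continuous(800, 0.1, 1.3) == pytest.approx(
            power_logistic_continuous(800, 0.1, 1 / 1.3)
        )

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            power_logistic_continuous(0, 0.1, 1.3)
        with pytest.raises(ValueError):
            power_logistic_continuous(100, 1.5, 1.3)
        with pytest.raises(ValueError):
            power_logistic_continuous(100, 0.1, -1.0)


class TestFilterMciControls:
    def test_filter_arithmetic(self):
        df = pd.DataFrame(
            {
                "mci": [1, 1, 0, 0, 0],
                "dementia": [1, 0, 1, 0, 0],
            }
        )
        out, summary = filter_mci_controls(df)
        # the non-MCI dementia row is removed; MCI cases stay regardless
        assert summary.n_removed == 1
        assert summary.n_remaining == 4
        assert summary.n_cases == 2
        assert summary.case_percent == pytest.approx(50.0)

    def test_no_flagged_rows_is_identity(self):
        df = pd.DataFrame({"mci": [1, 0, 0], "dementia": [0, 0, 0]})
        out, summary = filter_mci_controls(df)
        pd.testing.assert_frame_equal(out, df)
        assert summary.n_removed == 0


class TestSubgroups:
    def test_zero_threshold_equals_full_sample(self):
        rng = np.random.default_rng(9)
        df = make_cohort(2000, rng, log_or=0.3)
        df["anc_african"] = rng.dirichlet((2, 2, 2), size=2000)[:, 0]
        full = fit_logistic(df, "prs", ("age_baseline",))
        sub = subgroup_association(
            df, df["prs"].to_numpy(), ("ancestry", "african", 0.0),
            covariates=("age_baseline",),
        )
        assert sub.iloc[0]["estimate"] == pytest.approx(full.estimate)
        assert sub.iloc[0]["n"] == 2000

    def test_ancestry_groups_overlap(self):
        rng = np.random.default_rng(10)
        df = make_cohort(3000, rng, log_or=0.2)
        Q = rng.dirichlet((3, 3, 3), size=3000)
        for i, a in enumerate(("european", "african", "amerindian")):
            df[f"anc_{a}"] = Q[:, i]
        total = 0
        for a in ("european", "african", "amerindian"):
            sub = subgroup_association(
                df, df["prs"].to_numpy(), ("ancestry", a, 0.2),
                covariates=("age_baseline",),
            )
            total += int(sub.iloc[0]["n"])
        assert total >= 3000  # overlapping subgroups cover the sample

    def test_small_subgroup_flagged_unstable(self):
        rng = np.random.default_rng(11)
        df = make_cohort(300, rng, prevalence=0.05)
        df["background"] = np.where(np.arange(300) < 30, "tiny", "big")
        out = subgroup_association(
            df, df["prs"].to_numpy(), ("background",), covariates=()
        )
        tiny = out[out["subgroup"] == "tiny"].iloc[0]
        assert bool(tiny["unstable"])


class TestPrimaryAnalysis:
    def test_empty_sensitivity_filter_matches_primary(self):
        rng = np.random.default_rng(12)
        df = make_cohort(2500, rng, log_or=0.3)
        df["apoe_e2_count"] = rng.integers(0, 2, len(df))
        df["apoe_e4_count"] = rng.integers(0, 3, len(df))
        df["mci_plus_flag"] = 0
        scores = {"PRSsum": {"with_apoe": df["prs"].to_numpy()}}
        res = run_primary_analysis(
            df, scores, covariates=("age_baseline", "sex"), sensitivity=True
        )
        prim = res[res["analysis"] == "primary"].drop(columns="analysis")
        sens = res[res["analysis"] == "sensitivity"].drop(columns="analysis")
        pd.testing.assert_frame_equal(
            prim.reset_index(drop=True), sens.reset_index(drop=True)
        )
        # blocks present: unadjusted + adjusted (with APOE terms)
        assert set(res["block"]) == {
            "prs_with_apoe_unadjusted",
            "prs_with_apoe_adjusted",
        }


class TestCompareR2:
    def test_identical_scores_null(self):
        rng = np.random.default_rng(13)
        df = make_cohort(800, rng, log_or=0.4)
        s = df["prs"].to_numpy()
        res = compare_r2(s, s, df, covariates=("age_baseline",), n_boot=200, seed=1)
        assert res.delta_r2 == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_informative_beats_noise(self):
        rng = np.random.default_rng(14)
        hits = 0
        for rep in range(5):
            df = make_cohort(1500, rng, log_or=0.5)
            noise = rng.normal(size=len(df))
            res = compare_r2(
                df["prs"].to_numpy(),
                noise,
                df,
                covariates=(),
                n_boot=200,
                seed=rep,
            )
            assert res.delta_r2 > 0
            hits += res.p_value < 0.05
        assert hits >= 4

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(15)
        df = make_cohort(600, rng, log_or=0.3)
        noise = rng.normal(size=len(df))
        a = compare_r2(df["prs"].to_numpy(), noise, df, n_boot=200, seed=7)
        b = compare_r2(df["prs"].to_numpy(), noise, df, n_boot=200, seed=7)
        assert a.ci == b.ci and a.p_value == b.p_value


class TestSimulatedPower:
    def test_monte_carlo_matches_closed_form_single_point(self):
        closed = power_logistic_continuous(1000, 0.1, 1.4)
        mc = simulate_power_logistic(1000, 0.1, 1.4, n_reps=2000, seed=3)
        assert abs(closed - mc) < 0.03
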