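import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dyadsync.stats import (
    bh_adjust,
    correlate_individual_differences,
    fit_ccc_model,
    fit_faa_model,
)


def bh_oracle(p):
    """Brute-force Benjamini-Hochberg step-up."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


class TestBH:
    @settings(derandomize=True, max_examples=60)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=25))
    def test_matches_step_up_oracle(self, ps):
        np.testing.assert_allclose(bh_adjust(ps), bh_oracle(ps), atol=1e-12)

    def test_adjusted_monotone_in_raw_order(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0, 1, 50)
        adj = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()
        assert (adj >= p - 1e-12).all()


def _synthetic_faa_epochs(rng, n_subjects=6, conditions=("A", "B"),
                          n_epochs=120, cond_effect=None, noise=0.3):
    rows = []
    for s in range(n_subjects):
        intercept = rng.normal(0, 0.1)
        for c in conditions:
            mu = intercept + (cond_effect or {}).get(c, 0.0)
            faa = mu + rng.normal(0, noise, n_epochs)
            for e in range(n_epochs):
                rows.append((f"s{s}", f"d{s//2}", c, e, faa[e], True, "relative"))
    return pd.DataFrame(rows, columns=["subject_id", "dyad_id", "condition",
                                       "epoch_index", "faa", "valid", "alpha_mode"])


class TestFAAModel:
    def test_condition_effect_recovered(self, rng):
        df = _synthetic_faa_epochs(rng, cond_effect={"B": 0.3})
        res = fit_faa_model(df)
        f = res.f_table.set_index("effect")
        assert f.loc["Condition", "p"] < 1e-4
        emm = res.emm.set_index("condition")["emm"]
        assert emm["B"] - emm["A"] == pytest.approx(0.3, abs=0.1)

    def test_emm_of_effect_free_balanced_sim_equals_grand_mean(self, rng):
        df = _synthetic_faa_epochs(rng)
        res = fit_faa_model(df)
        grand = df["faa"].mean()
        assert np.allclose(res.emm["emm"], grand, atol=3 * 0.3 / np.sqrt(len(df) / 2))

    def test_f_table_degrees_of_freedom_are_residual(self, rng):
        df = _synthetic_faa_epochs(rng)
        res = fit_faa_model(df)
        n, p = res.n_obs, 6  # intercept + cond + tc + tc2 + 2 interactions
        assert (res.f_table["df2"] == n - p).all()

    def test_single_condition_degrades_to_time_only(self, rng):
        df = _synthetic_faa_epochs(rng, conditions=("A",))
        res = fit_faa_model(df)
        assert set(res.f_table["effect"]) == {"Time (slope)", "Time (quadratic)"}

    def test_trend_rows_every_60_epochs(self, rng):
        df = _synthetic_faa_epochs(rng, n_epochs=240)
        res = fit_faa_model(df)
        a_slopes = res.trends.query("condition == 'A' and feature == 'slope'")
        # epoch indices run 0..239, so increments fall at 0/60/120/180
        assert list(a_slopes["at_epoch"]) == [0, 60, 120, 180]
        assert (a_slopes["ci_low"] <= a_slopes["estimate"]).all()
        assert (a_slopes["estimate"] <= a_slopes["ci_high"]).all()

    def test_fixed_effects_match_lme4_reml(self, rng, tmp_path):
        """Independent oracle: the same REML model fit by R's lme4."""
        df = _synthetic_faa_epochs(rng, n_subjects=4, n_epochs=30)
        span = df.groupby("condition")["epoch_index"].transform("max")
        df["tc"] = df["epoch_index"] / span - 0.5
        df["tc2"] = df["tc"] ** 2
        csv = tmp_path / "faa.csv"
        df.to_csv(csv, index=False)
        rscript = tmp_path / "fit.R"
        rscript.write_text(textwrap.dedent(f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            m <- lmer(faa ~ condition * (tc + tc2) + (1 | subject_id), data = d,
                      REML = TRUE)
            fe <- fixef(m)
            for (n in names(fe)) cat(n, fe[[n]], "\\n")
        """))
        out = subprocess.run(["Rscript", str(rscript)], capture_output=True,
                             text=True, check=True)
        lme4_fe = {}
        for line in out.stdout.strip().splitlines():
            name, value = line.split()
            name = (name.replace("(Intercept)", "Intercept")
                    .replace("conditionB", "C(condition)[T.B]"))
            lme4_fe[name] = float(value)
        import statsmodels.formula.api as smf

        ours = smf.mixedlm("faa ~ C(condition) * (tc + tc2)", df,
                           groups=df["subject_id"]).fit(reml=True)
        assert set(lme4_fe) == set(ours.fe_params.index)
        for name, value in lme4_fe.items():
            assert ours.fe_params[name] == pytest.approx(value, abs=1e-4)


def _synthetic_ccc_table(rng, n_subjects=20, effect=None):
    rows = []
    for s in range(n_subjects):
        u = rng.normal(0, 0.03)
        for c in ("A", "B", "C"):
            for lag in (0, 1, 2, 3):
                mu = u + (effect or {}).get((c, lag), 0.0)
                rows.append((f"d{s//2}", f"s{s}", c, lag, mu + rng.normal(0, 0.08)))
    return pd.DataFrame(rows, columns=["dyad_id", "subject_id", "condition",
                                       "lag_bins", "ccc"])


class TestCCCModel:
    def test_localized_effect_dominates_matching_lag_contrasts(self, rng):
        eff = {("B", 2): 0.25}
        res = fit_ccc_model(_synthetic_ccc_table(rng, effect=eff))
        con = res.contrasts
        hit = con[(con.lag_bins == 2) & con.contrast.str.contains("B")]
        miss = con[(con.lag_bins == 0) & con.contrast.str.contains("B")]
        assert (hit["p_fdr"] < 0.01).all()
        assert (miss["p_raw"] > 0.001).all()

    def test_contrast_count_per_lag(self, rng):
        res = fit_ccc_model(_synthetic_ccc_table(rng))
        per_lag = res.contrasts.groupby("lag_bins").size()
        assert (per_lag == 3).all()  # C(3,2) with 3 conditions

    def test_lag_relabeling_permutes_estimates_consistently(self, rng):
        df = _synthetic_ccc_table(rng)
        res1 = fit_ccc_model(df)
        relabel = {0: 3, 1: 2, 2: 1, 3: 0}
        df2 = df.assign(lag_bins=df["lag_bins"].map(relabel))
        res2 = fit_ccc_model(df2)
        e1 = res1.emm.set_index(["condition", "lag_bins"])["emm"]
        e2 = res2.emm.set_index(["condition", "lag_bins"])["emm"]
        for (c, lag), v in e1.items():
            assert e2[(c, relabel[lag])] == pytest.approx(v, abs=1e-6)

    def test_missing_cell_flagged_not_estimated(self, rng):
        df = _synthetic_ccc_table(rng)
        df = df[~((df.condition == "C") & (df.lag_bins == 3))]
        res = fit_ccc_model(df)
        flagged = res.contrasts[(res.contrasts.lag_bins == 3)
                                & res.contrasts.contrast.str.contains("C")]
        assert (flagged["note"] == "cell not estimable").all()


class TestCorrelations:
    def _summary_and_covariates(self, rng, n=30, slope=0.8):
        value = rng.normal(0, 1, n)
        cov = pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(n)],
            "constructed": slope * value + rng.normal(0, 0.5, n),
            "independent": rng.normal(5, 2, n),
            "constant": np.ones(n),
        })
        summary = pd.DataFrame({"subject_id": [f"s{i}" for i in range(n)],
                                "value": value})
        return summary, cov

    def test_constructed_covariate_recovered(self, rng):
        summary, cov = self._summary_and_covariates(rng)
        out = correlate_individual_differences(summary, cov)
        r = out.set_index("variable").loc["constructed", "r"]
        expected = 0.8 / np.sqrt(0.8**2 + 0.25)
        assert r == pytest.approx(expected, abs=0.15)

    def test_degrees_of_freedom_are_n_minus_two(self, rng):
        summary, cov = self._summary_and_covariates(rng, n=30)
        out = correlate_individual_differences(summary, cov)
        assert (out.query("note == ''")["df"] == 28).all()

    def test_zero_variance_covariate_skipped_with_reason(self, rng):
        summary, cov = self._summary_and_covariates(rng)
        out = correlate_individual_differences(summary, cov).set_index("variable")
        assert "zero variance" in out.loc["constant", "note"]
        assert np.isnan(out.loc["constant", "r"])

    def test_adjusted_p_not_below_raw(self, rng):
        summary, cov = self._summary_and_covariates(rng)
        out = correlate_individual_differences(summary, cov).dropna(subset=["p_raw"])
        assert (out["p_fdr"] >= out["p_raw"] - 1e-12).all()

    def test_winsorized_variant_tames_an_outlier(self, rng):
        summary, cov = self._summary_and_covariates(rng)
        cov.loc[0, "independent"] = 1e4
        plain = correlate_individual_differences(summary, cov)
        wins = correlate_individual_differences(summary, cov, winsorize=True)
        r_plain = plain.set_index("variable").loc["independent", "r"]
        r_wins = wins.set_index("variable").loc["independent", "r"]
        assert abs(r_wins) < 0.5
        assert wins["winsorized"].all()
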