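"""Mixed-effects models, marginal means, contrasts and correlations.

Three analyses operate on pipeline outputs:

* ``fit_faa_model`` — epoch-level FAA ~ condition x (linear + quadratic
  time) with a random intercept per person, REML.  Time is the epoch
  index rescaled to [0, 1] within condition and centered, so the linear
  and quadratic terms are comparable across conditions of different
  length.  Marginal means are evaluated at the mean epoch; linear trends
  are extracted every 60 epochs (30 s) per condition with 95% CIs.
* ``fit_ccc_model`` — subject-level CCC ~ condition x lag (both
  categorical) with a random intercept per person; pairwise condition
  contrasts within each lag, FDR-corrected.
* ``correlate_individual_differences`` — Pearson correlations between a
  per-subject summary and covariates, Benjamini-Hochberg corrected, with
  an optional winsorized variant.

F tests use Wald statistics with residual (n - p) denominator degrees of
freedom.  The optimizer identity is recorded on every fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import ConvergenceWarning

__all__ = [
    "FAAModelResult",
    "CCCModelResult",
    "fit_faa_model",
    "fit_ccc_model",
    "correlate_individual_differences",
    "bh_adjust",
]


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if len(p) == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class FAAModelResult:
    f_table: pd.DataFrame        # effect, F, df1, df2, p
    emm: pd.DataFrame            # condition, emm, ci_low, ci_high
    trends: pd.DataFrame         # condition, at_epoch, slope, slope_ci_*, quad, quad_ci_*
    converged: bool
    singular: bool
    optimizer: str
    n_obs: int


@dataclass
class CCCModelResult:
    f_table: pd.DataFrame
    emm: pd.DataFrame            # condition, lag_bins, emm, ci_low, ci_high
    contrasts: pd.DataFrame      # lag_bins, contrast, estimate, se, t, df, p_raw, p_fdr
    converged: bool
    singular: bool
    optimizer: str
    n_obs: int


def _fit_mixedlm(formula: str, data: pd.DataFrame, groups: str):
    """REML fit with a Nelder-Mead first attempt and BFGS fallback.

    The fixed-effect design is built explicitly so that all-zero columns
    (dummies of unobserved condition x lag cells) can be dropped; the fit
    then covers exactly the estimable cells.
    """
    import statsmodels.api as sm
    from patsy import dmatrix

    X = dmatrix(formula.split("~", 1)[1], data, return_type="dataframe")
    nonzero = [c for c in X.columns if (X[c] != 0).any()]
    X = X[nonzero]
    y = data[formula.split("~", 1)[0].strip()].to_numpy()
    model = sm.MixedLM(y, X, groups=data[groups])
    singular = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            result = model.fit(reml=True, method="nm", maxiter=200)
            optimizer = "nelder-mead"
        except Exception:
            result = model.fit(reml=True)
            optimizer = "default(bfgs/lbfgs)"
        if not result.converged:
            result = model.fit(reml=True, method="lbfgs")
            optimizer = "lbfgs"
        for w in caught:
            if issubclass(w.category, ConvergenceWarning) or "singular" in str(
                w.message
            ).lower():
                singular = True
    return result, optimizer, singular


def _wald_f(result, L: np.ndarray, df_denom: int) -> tuple[float, int, float]:
    """Wald F statistic for H0: L beta = 0, residual denominator df."""
    beta = np.asarray(result.fe_params)
    cov = np.asarray(result.cov_params())[: len(beta), : len(beta)]
    q = L.shape[0]
    lb = L @ beta
    # pinv: with missing cells the fixed-effect covariance can be rank
    # deficient; the test then covers the estimable subspace
    mid = np.linalg.pinv(L @ cov @ L.T) @ lb
    f_stat = float(lb @ mid / q)
    p = float(sps.f.sf(f_stat, q, df_denom))
    return f_stat, q, p


def _term_rows(exog_names: list[str], matcher) -> np.ndarray:
    rows = []
    for i, name in enumerate(exog_names):
        if matcher(name):
            row = np.zeros(len(exog_names))
            row[i] = 1.0
            rows.append(row)
    return np.array(rows)


def fit_faa_model(
    faa_epochs: pd.DataFrame,
    trend_increment_epochs: int = 60,
    alpha: float = 0.05,
) -> FAAModelResult:
    """Mixed model for epoch-level FAA across condition and time.

    Expects the ``faa_epochs`` tidy frame (``subject_id, condition,
    epoch_index, faa, valid``); invalid epochs are ignored (missingness
    handled at the epoch level).  With a single condition the model
    degrades to time-only.
    """
    df = faa_epochs[faa_epochs["valid"]].dropna(subset=["faa"]).copy()
    if df["subject_id"].nunique() < 2:
        raise ValueError("need at least 2 subjects")
    # time: epoch index scaled to [0, 1] within condition, then centered
    span = df.groupby("condition")["epoch_index"].transform("max").clip(lower=1)
    df["tc"] = df["epoch_index"] / span - 0.5
    df["tc2"] = df["tc"] ** 2

    n_cond = df["condition"].nunique()
    if n_cond >= 2:
        formula = "faa ~ C(condition) * (tc + tc2)"
    else:
        formula = "faa ~ tc + tc2"
    result, optimizer, singular = _fit_mixedlm(formula, df, "subject_id")
    names = result.model.exog_names
    n_obs = len(df)
    df_denom = n_obs - len(names)

    terms = []
    if n_cond >= 2:
        terms.append(("Condition", lambda s: s.startswith("C(condition)") and ":" not in s))
    terms.append(("Time (slope)", lambda s: s == "tc"))
    terms.append(("Time (quadratic)", lambda s: s == "tc2"))
    if n_cond >= 2:
        terms.append(("Condition x Time (slope)",
                      lambda s: s.startswith("C(condition)") and s.endswith(":tc")))
        terms.append(("Condition x Time (quadratic)",
                      lambda s: s.startswith("C(condition)") and s.endswith(":tc2")))
    f_rows = []
    for label, match in terms:
        L = _term_rows(names, match)
        if len(L) == 0:
            continue
        f_stat, q, p = _wald_f(result, L, df_denom)
        f_rows.append((label, f_stat, q, df_denom, p))
    f_table = pd.DataFrame(f_rows, columns=["effect", "F", "df1", "df2", "p"])

    # marginal means at the mean epoch (tc = mean tc = 0, tc2 at its mean)
    conditions = list(df["condition"].drop_duplicates())
    m_tc = float(df["tc"].mean())
    m_tc2 = float(df["tc2"].mean())
    beta = np.asarray(result.fe_params)
    cov = np.asarray(result.cov_params())[: len(beta), : len(beta)]
    tcrit = sps.t.ppf(1 - alpha / 2, df_denom)

    def design_row(cond: str, tc: float, tc2: float) -> np.ndarray:
        row = np.zeros(len(names))
        for i, name in enumerate(names):
            if name == "Intercept":
                row[i] = 1.0
            elif name == "tc":
                row[i] = tc
            elif name == "tc2":
                row[i] = tc2
            elif name == f"C(condition)[T.{cond}]":
                row[i] = 1.0
            elif name == f"C(condition)[T.{cond}]:tc":
                row[i] = tc
            elif name == f"C(condition)[T.{cond}]:tc2":
                row[i] = tc2
        return row

    emm_rows = []
    for cond in conditions:
        r = design_row(cond, m_tc, m_tc2)
        est = float(r @ beta)
        se = float(np.sqrt(r @ cov @ r))
        emm_rows.append((cond, est, est - tcrit * se, est + tcrit * se))
    emm = pd.DataFrame(emm_rows, columns=["condition", "emm", "ci_low", "ci_high"])

    # linear and quadratic trend at 30 s (60-epoch) increments
    trend_rows = []
    for cond in conditions:
        span_c = int(df.loc[df["condition"] == cond, "epoch_index"].max())
        for e in range(0, span_c + 1, trend_increment_epochs):
            tc = e / max(span_c, 1) - 0.5
            # d faa / d tc evaluated at tc, and the quadratic coefficient
            slope_row = np.zeros(len(names))
            quad_row = np.zeros(len(names))
            for i, name in enumerate(names):
                if name == "tc" or name == f"C(condition)[T.{cond}]:tc":
                    slope_row[i] = 1.0
                elif name == "tc2" or name == f"C(condition)[T.{cond}]:tc2":
                    slope_row[i] = 2.0 * tc
                    quad_row[i] = 1.0
            for label, row in (("slope", slope_row), ("quadratic", quad_row)):
                est = float(row @ beta)
                se = float(np.sqrt(row @ cov @ row))
                trend_rows.append(
                    (cond, e, label, est, est - tcrit * se, est + tcrit * se,
                     not (est - tcrit * se <= 0 <= est + tcrit * se))
                )
    trends = pd.DataFrame(
        trend_rows,
        columns=["condition", "at_epoch", "feature", "estimate",
                 "ci_low", "ci_high", "nonzero"],
    )
    return FAAModelResult(f_table, emm, trends, bool(result.converged),
                          singular, optimizer, n_obs)


def fit_ccc_model(ccc_subject: pd.DataFrame, alpha: float = 0.05) -> CCCModelResult:
    """Mixed model for subject-level CCC across condition and lag.

    Condition and lag are categorical; pairwise condition contrasts are
    computed within each lag and Benjamini-Hochberg corrected within that
    lag's family.
    """
    df = ccc_subject.dropna(subset=["ccc"]).copy()
    if df["condition"].nunique() < 2 or df["lag_bins"].nunique() < 2:
        raise ValueError("need >= 2 conditions and >= 2 lags")
    df["lag_bins"] = df["lag_bins"].astype(int)
    formula = "ccc ~ C(condition) * C(lag_bins)"
    result, optimizer, singular = _fit_mixedlm(formula, df, "subject_id")
    names = result.model.exog_names
    n_obs = len(df)
    df_denom = n_obs - len(names)

    f_rows = []
    for label, match in (
        ("Condition", lambda s: s.startswith("C(condition)") and ":" not in s),
        ("Lag", lambda s: s.startswith("C(lag_bins)") and ":" not in s),
        ("Condition x Lag", lambda s: ":" in s and s.startswith("C(condition)")),
    ):
        L = _term_rows(names, match)
        if len(L):
            f_stat, q, p = _wald_f(result, L, df_denom)
            f_rows.append((label, f_stat, q, df_denom, p))
    f_table = pd.DataFrame(f_rows, columns=["effect", "F", "df1", "df2", "p"])

    beta = np.asarray(result.fe_params)
    cov = np.asarray(result.cov_params())[: len(beta), : len(beta)]
    tcrit = sps.t.ppf(1 - alpha / 2, df_denom)
    conditions = list(df["condition"].drop_duplicates())
    lags = sorted(df["lag_bins"].unique())
    observed_cells = set(map(tuple, df[["condition", "lag_bins"]].drop_duplicates().to_numpy()))

    def cell_row(cond, lag) -> np.ndarray:
        row = np.zeros(len(names))
        for i, name in enumerate(names):
            if name == "Intercept":
                row[i] = 1.0
            elif name in (f"C(condition)[T.{cond}]", f"C(lag_bins)[T.{lag}]",
                          f"C(condition)[T.{cond}]:C(lag_bins)[T.{lag}]"):
                row[i] = 1.0
        return row

    emm_rows = []
    for cond in conditions:
        for lag in lags:
            r = cell_row(cond, lag)
            est = float(r @ beta)
            se = float(np.sqrt(r @ cov @ r))
            emm_rows.append((cond, lag, est, est - tcrit * se, est + tcrit * se))
    emm = pd.DataFrame(
        emm_rows, columns=["condition", "lag_bins", "emm", "ci_low", "ci_high"]
    )

    contrast_rows = []
    for lag in lags:
        fam = []
        for i, c1 in enumerate(conditions):
            for c2 in conditions[i + 1:]:
                if (c1, lag) not in observed_cells or (c2, lag) not in observed_cells:
                    fam.append((f"{c1} - {c2}", np.nan, np.nan, np.nan, np.nan,
                                "cell not estimable"))
                    continue
                r = cell_row(c1, lag) - cell_row(c2, lag)
                est = float(r @ beta)
                se = float(np.sqrt(r @ cov @ r))
                t = est / se if se > 0 else np.nan
                p = 2 * sps.t.sf(abs(t), df_denom) if np.isfinite(t) else np.nan
                fam.append((f"{c1} - {c2}", est, se, t, p, ""))
        raw = np.array([row[4] for row in fam], dtype=float)
        ok = np.isfinite(raw)
        adj = np.full(len(raw), np.nan)
        if ok.any():
            adj[ok] = bh_adjust(raw[ok])
        for row, p_adj in zip(fam, adj):
            contrast_rows.append((lag, *row[:5], p_adj, row[5]))
    contrasts = pd.DataFrame(
        contrast_rows,
        columns=["lag_bins", "contrast", "estimate", "se", "t", "p_raw",
                 "p_fdr", "note"],
    )
    contrasts["df"] = df_denom
    return CCCModelResult(f_table, emm, contrasts, bool(result.converged),
                          singular, optimizer, n_obs)


def correlate_individual_differences(
    summary: pd.DataFrame,
    covariates: pd.DataFrame,
    value_col: str = "value",
    winsorize: bool = False,
    winsorize_limits: tuple[float, float] = (0.05, 0.05),
) -> pd.DataFrame:
    """Pearson correlations between a per-subject summary and covariates.

    ``summary`` needs ``subject_id`` and ``value_col``.  Every numeric
    column of ``covariates`` (other than identifiers) is correlated with
    the summary; p-values are Benjamini-Hochberg adjusted within this
    family.  With ``winsorize`` both variables are winsorized at the
    given percentile limits before the correlation.
    """
    merged = summary.merge(covariates, on="subject_id")
    cols = [
        c for c in covariates.columns
        if c not in ("subject_id", "dyad_id")
        and pd.api.types.is_numeric_dtype(covariates[c])
    ]
    rows = []
    p_raw = []
    for c in cols:
        sub = merged[[value_col, c]].dropna()
        x = sub[value_col].to_numpy(dtype=float)
        y = sub[c].to_numpy(dtype=float)
        if winsorize:
            x = np.asarray(sps.mstats.winsorize(x, limits=winsorize_limits))
            y = np.asarray(sps.mstats.winsorize(y, limits=winsorize_limits))
        n = len(x)
        if n < 3 or np.std(y) == 0 or np.std(x) == 0:
            rows.append((c, np.nan, n, max(n - 2, 0), np.nan, "zero variance or too few points"))
            p_raw.append(np.nan)
            continue
        r, p = sps.pearsonr(x, y)
        rows.append((c, float(r), n, n - 2, float(p), ""))
        p_raw.append(float(p))
    p_raw = np.array(p_raw, dtype=float)
    ok = np.isfinite(p_raw)
    adj = np.full(len(p_raw), np.nan)
    if ok.any():
        adj[ok] = bh_adjust(p_raw[ok])
    out = pd.DataFrame(rows, columns=["variable", "r", "n", "df", "p_raw", "note"])
    out["p_fdr"] = adj
    out["winsorized"] = winsorize
    return out[["variable", "r", "n", "df", "p_raw", "p_fdr", "winsorized", "note"]]
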