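"""Within-dyad concordance of binned FAA at concurrent and lagged offsets.

Epoch-level FAA is averaged into non-overlapping bins of four contiguous
500 ms epochs (2 s); a full 2 min condition yields 60 bins, a 1.5 min
condition 45.  A bin's value is the mean of its *valid* epochs; the bin
is missing only when data are missing across the full 2 s.

Agreement between partners uses Lin's concordance correlation
coefficient,

    ccc(x, y) = 2 cov(x, y) / (var x + var y + (mean x - mean y)^2),

with population (1/n) moments by default (a 1/(n-1) toggle exists).  CCC
penalises location and scale shifts as well as decorrelation, and is
bounded by the Pearson correlation in magnitude.

Lag convention: "a person's FAA predicted by their partner's previous
values" means the reference person's series leads — at lag k the pairs
are (reference at bin t, partner at bin t - k).  Lag 0 is identical for
the two partners of a dyad; positive lags are not.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["bin_faa", "ccc", "dyad_ccc", "aggregate_ccc", "lagged_pairs"]


def bin_faa(faa: pd.DataFrame, bin_epochs: int = 4) -> pd.DataFrame:
    """Average epoch-level FAA into bins of ``bin_epochs`` epochs.

    Trailing epochs that do not fill a bin are dropped.  Returns a tidy
    frame ``subject_id, dyad_id, condition, bin_index, faa_bin, valid``.
    """
    rows = []
    for (sid, did, cond), grp in faa.groupby(
        ["subject_id", "dyad_id", "condition"], sort=False
    ):
        grp = grp.sort_values("epoch_index")
        n_epochs = int(grp["epoch_index"].max()) + 1
        n_bins = n_epochs // bin_epochs
        values = np.full(n_epochs, np.nan)
        valid = np.zeros(n_epochs, dtype=bool)
        values[grp["epoch_index"].to_numpy()] = grp["faa"].to_numpy()
        valid[grp["epoch_index"].to_numpy()] = grp["valid"].to_numpy()
        for b in range(n_bins):
            sl = slice(b * bin_epochs, (b + 1) * bin_epochs)
            v = valid[sl]
            if v.any():
                rows.append((sid, did, cond, b, float(values[sl][v].mean()), True))
            else:
                rows.append((sid, did, cond, b, np.nan, False))
    return pd.DataFrame(
        rows,
        columns=["subject_id", "dyad_id", "condition", "bin_index", "faa_bin", "valid"],
    )


def ccc(x, y, ddof: int = 0) -> float:
    """Lin's concordance correlation coefficient.

    Pairs with a missing member are dropped.  Returns NaN when fewer than
    3 pairs remain or when the denominator is zero (both series constant
    and equal).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("series must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        return np.nan
    mx, my = x.mean(), y.mean()
    vx = x.var(ddof=ddof)
    vy = y.var(ddof=ddof)
    cov = ((x - mx) * (y - my)).sum() / (n - ddof)
    denom = vx + vy + (mx - my) ** 2
    if denom <= 0:
        return np.nan
    return float(2.0 * cov / denom)


def lagged_pairs(
    ref: pd.DataFrame, partner: pd.DataFrame, lag: int
) -> tuple[np.ndarray, np.ndarray]:
    """Aligned (reference[t], partner[t - lag]) bin values, both valid.

    ``ref`` and ``partner`` are single subject x condition bin frames.
    """
    r = ref.sort_values("bin_index")
    p = partner.sort_values("bin_index")
    rv = r.set_index("bin_index")["faa_bin"]
    pv = p.set_index("bin_index")["faa_bin"]
    rok = r.set_index("bin_index")["valid"]
    pok = p.set_index("bin_index")["valid"]
    ts = [t for t in rv.index if (t - lag) in pv.index
          and bool(rok[t]) and bool(pok[t - lag])]
    return (
        rv.loc[ts].to_numpy(dtype=float),
        pv.loc[[t - lag for t in ts]].to_numpy(dtype=float),
    )


def dyad_ccc(
    bins_p1: pd.DataFrame,
    bins_p2: pd.DataFrame,
    lags: tuple[int, ...] = (0, 1, 2, 3),
    ddof: int = 0,
    min_pairs: int = 3,
) -> pd.DataFrame:
    """Concordance per condition and lag, from both partners' perspectives.

    Output columns: ``dyad_id, subject_id, partner_id, condition,
    lag_bins, ccc, n_pairs, note``.  At lag 0 the two perspectives give
    the identical value (CCC is symmetric); both rows are emitted so the
    subject-level table is balanced.
    """
    did = bins_p1["dyad_id"].iloc[0]
    rows = []
    conditions = sorted(
        set(bins_p1["condition"]) & set(bins_p2["condition"]),
        key=list(bins_p1["condition"].drop_duplicates()).index,
    )
    for cond in conditions:
        b1 = bins_p1[bins_p1["condition"] == cond]
        b2 = bins_p2[bins_p2["condition"] == cond]
        for ref_name, ref, partner in (
            (b1["subject_id"].iloc[0], b1, b2),
            (b2["subject_id"].iloc[0], b2, b1),
        ):
            partner_name = (
                b2["subject_id"].iloc[0] if ref is b1 else b1["subject_id"].iloc[0]
            )
            for lag in lags:
                x, y = lagged_pairs(ref, partner, lag)
                note = ""
                if len(x) < min_pairs:
                    value = np.nan
                    note = f"only {len(x)} aligned valid pairs"
                else:
                    value = ccc(x, y, ddof=ddof)
                    if np.isnan(value):
                        note = "degenerate series (zero denominator)"
                rows.append(
                    (did, ref_name, partner_name, cond, lag, value, len(x), note)
                )
    return pd.DataFrame(
        rows,
        columns=["dyad_id", "subject_id", "partner_id", "condition",
                 "lag_bins", "ccc", "n_pairs", "note"],
    )


def group_ccc(
    all_bins: dict[str, tuple[pd.DataFrame, pd.DataFrame]],
    lags: tuple[int, ...] = (0, 1, 2, 3),
    ddof: int = 0,
    pool_conditions: bool = False,
) -> pd.DataFrame:
    """Group-level CCC: pairs pooled across dyads (both perspectives) per
    condition x lag.  ``all_bins`` maps dyad_id -> (bins_p1, bins_p2).

    With ``pool_conditions`` an extra row per lag (condition
    ``"(pooled)"``) concatenates pairs over all conditions as well —
    the summary used when asking at which lag coupling peaks overall.
    """
    conditions: list[str] = []
    for b1, _ in all_bins.values():
        for c in b1["condition"].drop_duplicates():
            if c not in conditions:
                conditions.append(c)
    pairs: dict[tuple[str, int], list] = {}
    for cond in conditions:
        for lag in lags:
            xs, ys = [], []
            for b1, b2 in all_bins.values():
                c1 = b1[b1["condition"] == cond]
                c2 = b2[b2["condition"] == cond]
                if c1.empty or c2.empty:
                    continue
                for ref, partner in ((c1, c2), (c2, c1)):
                    x, y = lagged_pairs(ref, partner, lag)
                    xs.append(x)
                    ys.append(y)
            pairs[(cond, lag)] = [
                np.concatenate(xs) if xs else np.array([]),
                np.concatenate(ys) if ys else np.array([]),
            ]
    rows = []
    for (cond, lag), (x, y) in pairs.items():
        rows.append((cond, lag, ccc(x, y, ddof=ddof), len(x)))
    if pool_conditions:
        for lag in lags:
            x = np.concatenate([pairs[(c, lag)][0] for c in conditions])
            y = np.concatenate([pairs[(c, lag)][1] for c in conditions])
            rows.append(("(pooled)", lag, ccc(x, y, ddof=ddof), len(x)))
    return pd.DataFrame(rows, columns=["condition", "lag_bins", "ccc", "n_pairs"])


def aggregate_ccc(subject_ccc: pd.DataFrame,
                  excess_kurtosis: bool = True) -> dict[str, pd.DataFrame]:
    """Summaries of the subject-level concordance table.

    Returns ``per_dyad_mean`` (mean of per-subject CCCs per condition x
    lag — the averaging alternative to pooled group CCC) and
    ``descriptives``: mean, SD, min, max, skew and kurtosis of
    subject-level CCCs per condition, collapsed across persons and lags.
    Kurtosis is excess (normal = 0) by default; moment-based skewness.
    """
    df = subject_ccc.dropna(subset=["ccc"])
    per_dyad = (
        df.groupby(["condition", "lag_bins"], sort=False)["ccc"]
        .mean()
        .reset_index()
        .rename(columns={"ccc": "mean_subject_ccc"})
    )
    fisher = excess_kurtosis
    desc = (
        df.groupby("condition", sort=False)["ccc"]
        .agg(
            mean="mean",
            sd=lambda v: v.std(ddof=1),
            min="min",
            max="max",
            skew=lambda v: sps.skew(v, bias=True),
            kurtosis=lambda v: sps.kurtosis(v, fisher=fisher, bias=True),
        )
        .reset_index()
    )
    return {"per_dyad_mean": per_dyad, "descriptives": desc}
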