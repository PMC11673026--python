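import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dyadsync.synchrony import aggregate_ccc, bin_faa, ccc, dyad_ccc, group_ccc, lagged_pairs


def moment_oracle(x, y, ddof=0):
    """Brute-force CCC from raw moment sums (independent of the implementation)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    vx = sum((xi - mx) ** 2 for xi in x) / (n - ddof)
    vy = sum((yi - my) ** 2 for yi in y) / (n - ddof)
    cov = sum((xi - mx) * (yi - my) for xi, yi in zip(x, y)) / (n - ddof)
    return 2 * cov / (vx + vy + (mx - my) ** 2)


def _faa_frame(values, valid=None, subject="s1", dyad="d1", condition="A"):
    n = len(values)
    return pd.DataFrame(
        {
            "subject_id": subject,
            "dyad_id": dyad,
            "condition": condition,
            "epoch_index": np.arange(n),
            "faa": values,
            "valid": np.ones(n, bool) if valid is None else valid,
            "alpha_mode": "relative",
        }
    )


class TestBinFAA:
    @pytest.mark.parametrize("n_epochs,n_bins", [(240, 60), (180, 45)])
    def test_bin_counts_for_full_and_short_conditions(self, n_epochs, n_bins):
        bins = bin_faa(_faa_frame(np.arange(n_epochs, dtype=float)))
        assert len(bins) == n_bins

    def test_bin_value_is_mean_of_valid_epochs(self):
        valid = np.array([True, True, False, False])
        bins = bin_faa(_faa_frame([0.1, 0.3, 9.0, 9.0], valid))
        assert bins["faa_bin"].iloc[0] == pytest.approx(0.2)
        assert bins["valid"].iloc[0]

    def test_bin_invalid_only_when_all_epochs_missing(self):
        valid = np.array([False] * 4 + [True] * 4)
        bins = bin_faa(_faa_frame(np.ones(8), valid))
        assert list(bins["valid"]) == [False, True]
        assert np.isnan(bins["faa_bin"].iloc[0])

    def test_trailing_epochs_not_filling_a_bin_dropped(self):
        bins = bin_faa(_faa_frame(np.arange(10, dtype=float)))
        assert len(bins) == 2


class TestCCC:
    def test_perfect_concordance_is_one(self):
        assert ccc([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0, abs=1e-15)

    def test_perfect_discordance_is_minus_one(self):
        assert ccc([1, 0, -1], [-1, 0, 1]) == pytest.approx(-1.0, abs=1e-15)

    def test_hand_computed_shifted_series(self):
        # x=(1,2,3), y=(2,3,4): 2*(2/3) / (2/3 + 2/3 + 1) = 4/7
        assert ccc([1, 2, 3], [2, 3, 4]) == pytest.approx(4 / 7, abs=1e-15)

    def test_matches_moment_oracle_on_random_pairs(self, rng):
        for _ in range(300):
            n = rng.integers(3, 40)
            x = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3), n)
            y = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3), n)
            for ddof in (0, 1):
                assert ccc(x, y, ddof=ddof) == pytest.approx(
                    moment_oracle(x, y, ddof), abs=1e-12
                )

    def test_undefined_below_three_pairs(self):
        assert np.isnan(ccc([1, 2], [1, 2]))

    def test_zero_denominator_is_undefined(self):
        assert np.isnan(ccc([2, 2, 2], [2, 2, 2]))

    def test_missing_pairs_dropped(self):
        x = [1, 2, np.nan, 3]
        y = [1, 2, 5, 3]
        assert ccc(x, y) == pytest.approx(1.0)

    @settings(derandomize=True, max_examples=80)
    @given(st.lists(st.floats(-50, 50), min_size=3, max_size=30),
           st.data())
    def test_symmetry_bounds_and_lin_inequality(self, xs, data):
        ys = data.draw(st.lists(st.floats(-50, 50), min_size=len(xs),
                                max_size=len(xs)))
        x, y = np.array(xs), np.array(ys)
        c = ccc(x, y)
        if np.isnan(c):
            return
        assert c == pytest.approx(ccc(y, x), abs=1e-12)
        assert -1 - 1e-12 <= c <= 1 + 1e-12
        if np.std(x) > 1e-9 and np.std(y) > 1e-9:
            r = np.corrcoef(x, y)[0, 1]
            assert abs(c) <= abs(r) + 1e-9

    def test_location_shift_strictly_penalized(self):
        x = np.arange(10, dtype=float)
        values = [ccc(x, x + c) for c in (0.0, 0.5, 1.0, 2.0)]
        assert values[0] == pytest.approx(1.0)
        assert all(a > b for a, b in zip(values, values[1:]))


class TestDyadCCC:
    def _bins(self, values, subject, valid=None):
        n = len(values)
        return pd.DataFrame(
            {
                "subject_id": subject,
                "dyad_id": "d1",
                "condition": "A",
                "bin_index": np.arange(n),
                "faa_bin": values,
                "valid": np.ones(n, bool) if valid is None else valid,
            }
        )

    def test_identical_series_concurrent_lag_is_one(self):
        rng = np.random.default_rng(0)
        v = rng.normal(0, 1, 30)
        out = dyad_ccc(self._bins(v, "p1"), self._bins(v, "p2"), lags=(0,))
        assert np.allclose(out["ccc"], 1.0)

    def test_lag_zero_identical_for_both_partners(self, rng):
        a = rng.normal(0, 1, 40)
        b = rng.normal(0, 1, 40)
        out = dyad_ccc(self._bins(a, "p1"), self._bins(b, "p2"), lags=(0, 1))
        lag0 = out[out["lag_bins"] == 0]["ccc"]
        assert lag0.iloc[0] == pytest.approx(lag0.iloc[1], abs=1e-15)

    def test_shifted_partner_recovered_at_matching_lag(self, rng):
        """B equals A delayed by 2 bins; with A's *partner* as reference the
        construction is exact at lag 2 and imperfect at other lags."""
        a = rng.normal(0, 1, 40)
        b = np.concatenate([[a[0], a[0]], a[:-2]])  # B[t] = A[t-2]
        out = dyad_ccc(self._bins(a, "p1"), self._bins(b, "p2"),
                       lags=(0, 1, 2, 3)).set_index(["subject_id", "lag_bins"])
        # reference = p2 (whose values follow the partner's previous values)
        assert out.loc[("p2", 2), "ccc"] == pytest.approx(1.0, abs=1e-12)
        assert out.loc[("p2", 1), "ccc"] < 1.0
        assert out.loc[("p2", 0), "ccc"] < 1.0

    def test_alignment_matches_brute_force_index_oracle(self, rng):
        a = rng.normal(0, 1, 25)
        b = rng.normal(0, 1, 25)
        lag = 3
        out = dyad_ccc(self._bins(a, "p1"), self._bins(b, "p2"), lags=(lag,))
        got = out.set_index("subject_id").loc["p1", "ccc"]
        # brute force: reference p1 at bin t paired with p2 at bin t-lag
        pairs = [(a[t], b[t - lag]) for t in range(lag, 25)]
        x, y = zip(*pairs)
        assert got == pytest.approx(moment_oracle(x, y), abs=1e-12)

    def test_n_pairs_bookkeeping_with_missing_bins(self, rng):
        a = rng.normal(0, 1, 60)
        valid = np.ones(60, bool)
        valid[[4, 10]] = False
        out = dyad_ccc(self._bins(a, "p1", valid), self._bins(a, "p2"),
                       lags=(0, 2))
        for _, row in out.iterrows():
            assert row["n_pairs"] <= 60 - row["lag_bins"]
        lag0 = out[(out.subject_id == "p1") & (out.lag_bins == 0)]
        assert lag0["n_pairs"].iloc[0] == 58

    def test_insufficient_pairs_reported_with_reason(self):
        a = [1.0, 2.0, 3.0]
        out = dyad_ccc(self._bins(a, "p1"), self._bins(a, "p2"), lags=(2,))
        assert out["ccc"].isna().all()
        assert (out["note"] != "").all()


class TestAggregate:
    def _subject_table(self, rng, n_subjects=10, conditions=("A", "B", "C", "D", "E")):
        rows = []
        for s in range(n_subjects):
            for c in conditions:
                for lag in range(4):
                    rows.append((f"d{s//2}", f"s{s}", f"p{s^1}", c, lag,
                                 rng.normal(0, 0.1), 60 - lag, ""))
        return pd.DataFrame(rows, columns=[
            "dyad_id", "subject_id", "partner_id", "condition", "lag_bins",
            "ccc", "n_pairs", "note"])

    def test_descriptives_table_shape_five_conditions_six_statistics(self, rng):
        out = aggregate_ccc(self._subject_table(rng))
        desc = out["descriptives"]
        assert len(desc) == 5
        assert list(desc.columns) == ["condition", "mean", "sd", "min", "max",
                                      "skew", "kurtosis"]

    def test_symmetric_sample_has_near_zero_skew(self, rng):
        out = aggregate_ccc(self._subject_table(rng, n_subjects=40))
        assert np.abs(out["descriptives"]["skew"]).max() < 0.6

    def test_single_dyad_group_value_equals_pooled_value(self, coupled_bins):
        b1, b2 = coupled_bins
        g = group_ccc({"d": (b1, b2)}, lags=(0,))
        # oracle: pool the aligned pairs by hand and apply the formula
        for cond in ("A", "B"):
            c1 = b1[b1.condition == cond]
            c2 = b2[b2.condition == cond]
            x1, y1 = lagged_pairs(c1, c2, 0)
            x2, y2 = lagged_pairs(c2, c1, 0)
            pooled = moment_oracle(np.concatenate([x1, x2]),
                                   np.concatenate([y1, y2]))
            got = g[(g.condition == cond) & (g.lag_bins == 0)]["ccc"].iloc[0]
            assert got == pytest.approx(pooled, abs=1e-12)
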