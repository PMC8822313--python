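"""Life-table construction and descriptive estimators."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rteha import (
    BinningScheme,
    LifeTable,
    TrialRecord,
    assign_bin,
    diff_curves,
    tabulate,
)

# printed reference values for the 220-trial masked-priming example
GOLDEN = {
    "RS": [220] * 7 + [213, 200, 174, 134, 86, 49, 17, 8],
    "h": [0] * 6 + [0.032, 0.061, 0.130, 0.230, 0.358, 0.430, 0.653, 0.529, 0.500],
    "se_h": [0] * 6 + [0.012, 0.016, 0.024, 0.032, 0.041, 0.053, 0.068, 0.121, 0.177],
    "S": [1] * 6 + [0.968, 0.909, 0.791, 0.609, 0.391, 0.223, 0.077, 0.036, 0.018],
    "P": [0] * 6 + [0.032, 0.059, 0.118, 0.182, 0.218, 0.168, 0.145, 0.041, 0.018],
    "se_P": [0] * 6 + [0.012, 0.016, 0.022, 0.026, 0.028, 0.025, 0.024, 0.013, 0.009],
    "ca": [np.nan] * 6 + [0.29, 0.77, 0.92, 1.0, 0.98, 1.0, 1.0, 1.0, 1.0],
    "se_ca": [np.nan] * 6 + [0.171, 0.117, 0.052, 0.0, 0.021, 0.0, 0.0, 0.0, 0.0],
}


class TestAssignBin:
    @pytest.mark.parametrize(
        "rt,expected",
        [(365, 10), (400, 10), (40, 1), (0.5, 1), (600, 15), (None, 15)],
    )
    def test_half_open_right_closed(self, scheme15, rt, expected):
        assert assign_bin(rt, scheme15) == expected

    @pytest.mark.parametrize("rt", [0, -5, 600.1, 650])
    def test_out_of_range_rejected(self, scheme15, rt):
        with pytest.raises(ValueError):
            assign_bin(rt, scheme15)


class TestTabulate:
    def test_direct_counts(self, scheme15):
        trials = [
            TrialRecord("p", (), 50, 1),
            TrialRecord("p", (), 55, 0),
            TrialRecord("p", (), 130, 1),
        ]
        counts = tabulate(trials, scheme15)
        assert counts.loc[2, "E"] == 2
        assert counts.loc[2, "n_correct"] == 1
        assert counts.loc[2, "n_error"] == 1
        assert counts.loc[4, "E"] == 1
        assert counts["E"].sum() == 3
        assert list(counts.loc[[1, 2, 3], "RS"]) == [3, 3, 1]

    def test_all_censored(self, scheme15):
        trials = [TrialRecord("p") for _ in range(4)]
        counts = tabulate(trials, scheme15)
        assert counts["E"].sum() == 0
        assert counts.loc[15, "rc"] == 4
        assert (counts["RS"] == 4).all()

    def test_empty_and_mixed_strata_rejected(self, scheme15):
        with pytest.raises(ValueError, match="empty"):
            tabulate([], scheme15)
        mixed = [TrialRecord("a", (), 100, 1), TrialRecord("b", (), 100, 1)]
        with pytest.raises(ValueError, match="strata"):
            tabulate(mixed, scheme15)

    def test_interior_censoring(self, scheme15):
        trials = [TrialRecord("p", (), 100, 1),
                  TrialRecord("p", censor_time=250.0),
                  TrialRecord("p", (), 500, 1)]
        counts = tabulate(trials, scheme15)
        assert counts.loc[7, "rc"] == 1
        assert counts.loc[8, "RS"] == 1

    def test_example_risk_sets(self, example_trials, scheme15, example_counts):
        counts = tabulate(example_trials, scheme15)
        assert list(counts["RS"]) == GOLDEN["RS"]
        pd.testing.assert_frame_equal(
            counts[["E", "rc", "n_correct", "n_error"]],
            example_counts[["E", "rc", "n_correct", "n_error"]],
            check_dtype=False,
        )


class TestGoldenValues:
    """Every printed estimate of the worked example is reproduced."""

    @pytest.mark.parametrize("col", ["h", "se_h", "S", "P", "se_P", "se_ca"])
    def test_three_decimal_columns(self, example_lifetable, col):
        got = np.round(getattr(example_lifetable, col), 3)
        expected = np.array(GOLDEN[col], dtype=float)
        np.testing.assert_array_equal(np.isnan(got), np.isnan(expected))
        np.testing.assert_allclose(got[~np.isnan(expected)],
                                   expected[~np.isnan(expected)], atol=5e-4)

    def test_conditional_accuracy(self, example_lifetable):
        got = np.round(example_lifetable.ca, 2)
        expected = np.array(GOLDEN["ca"])
        np.testing.assert_array_equal(np.isnan(got), np.isnan(expected))
        np.testing.assert_allclose(got[6:], expected[6:], atol=5e-3)


class TestInvariants:
    def test_count_conservation(self, example_counts):
        assert example_counts["E"].sum() + example_counts["rc"].sum() == 220

    def test_mass_plus_final_survival(self, example_lifetable):
        lt = example_lifetable
        # no interior censoring: the 4 deadline-censored trials are S(15)
        assert lt.P.sum() + lt.S[-1] == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(lt.P, lt.table["E"] / 220, atol=1e-12)
        counts_beyond = 220 * lt.S
        np.testing.assert_allclose(counts_beyond, np.round(counts_beyond), atol=1e-9)

    def test_survivor_is_nonincreasing(self, example_lifetable):
        S = example_lifetable.S
        assert np.all(np.diff(S) <= 0)
        assert example_lifetable.F[-1] == pytest.approx(1 - S[-1])

    def test_exhausted_risk_set_gives_na(self, scheme15):
        counts = pd.DataFrame({
            "E": [0] * 9 + [5, 0, 0, 0, 0, 0],
            "rc": [0] * 15,
            "n_correct": [0] * 9 + [5, 0, 0, 0, 0, 0],
            "n_error": [0] * 15,
        }, index=pd.RangeIndex(1, 16, name="t"))
        counts.loc[10, "E"] = 5  # all 5 trials respond in bin 10
        lt = LifeTable.from_counts(counts, scheme15)
        assert lt.h[9] == 1.0
        assert lt.S[9] == 0.0
        assert np.isnan(lt.h[10:]).all()
        assert np.isnan(lt.S[10:]).all()

    def test_zero_event_bin(self, example_lifetable):
        # bins 1-6 have no events: h = 0, S stays 1, P = 0, ca is NA
        assert (example_lifetable.h[:6] == 0).all()
        assert (example_lifetable.S[:6] == 1).all()
        assert np.isnan(example_lifetable.ca[:6]).all()

    @given(st.data())
    @settings(max_examples=50, deadline=None)
    def test_dominance_hierarchy(self, data):
        """A complete ordering on hazards implies one on F and S."""
        K = data.draw(st.integers(2, 12))
        h_b = np.array(data.draw(st.lists(
            st.floats(0.0, 0.95), min_size=K, max_size=K)))
        lift = np.array(data.draw(st.lists(
            st.floats(0.01, 0.05), min_size=K, max_size=K)))
        h_a = np.minimum(h_b + lift, 1.0 - 1e-9)
        S_a, S_b = np.cumprod(1 - h_a), np.cumprod(1 - h_b)
        assert np.all(S_a < S_b)
        assert np.all((1 - S_a) > (1 - S_b))


class TestBruteForceOracle:
    """Life-table estimates agree with direct enumeration over the trials."""

    @pytest.mark.parametrize("seed", range(5))
    def test_small_samples(self, seed):
        rng = np.random.default_rng(seed)
        scheme = BinningScheme.from_width(50.0, 500.0)
        n = int(rng.integers(3, 21))
        trials = []
        for _ in range(n):
            if rng.uniform() < 0.2:
                trials.append(TrialRecord("p"))
            else:
                trials.append(TrialRecord(
                    "p", (), float(rng.uniform(1, 500)), int(rng.uniform() < 0.8)))
        lt = LifeTable.from_trials(trials, scheme)

        for t in range(1, 11):
            lo, hi = scheme.edges[t - 1], scheme.edges[t]
            in_bin = [tr for tr in trials if not tr.is_censored and lo < tr.rt <= hi]
            at_risk = [tr for tr in trials
                       if tr.is_censored or tr.rt > lo]
            h_true = len(in_bin) / len(at_risk) if at_risk else np.nan
            surviving = [tr for tr in trials if tr.is_censored or tr.rt > hi]
            if at_risk:
                assert lt.h[t - 1] == pytest.approx(h_true)
                assert lt.P[t - 1] == pytest.approx(len(in_bin) / n)
                assert lt.S[t - 1] == pytest.approx(len(surviving) / n)
            if in_bin:
                ca_true = sum(tr.correct for tr in in_bin) / len(in_bin)
                assert lt.ca[t - 1] == pytest.approx(ca_true)
            else:
                assert np.isnan(lt.ca[t - 1])


class TestDiffCurves:
    def test_identical_tables(self, example_lifetable):
        d = diff_curves(example_lifetable, example_lifetable, "h")
        np.testing.assert_allclose(d["diff"], 0.0, atol=1e-15)
        np.testing.assert_allclose(
            d["se_diff"], np.sqrt(2) * example_lifetable.se_h, atol=1e-12)

    def test_se_combines_in_quadrature(self):
        assert np.sqrt(0.032**2 + 0.024**2) == pytest.approx(0.040, abs=5e-4)

    def test_na_propagates(self, example_lifetable):
        d = diff_curves(example_lifetable, example_lifetable, "ca")
        assert np.isnan(d["diff"][:6]).all()

    def test_mismatched_schemes_rejected(self, example_lifetable):
        other_scheme = BinningScheme.from_width(50.0, 600.0)
        counts = pd.DataFrame({
            "E": [1] * 12, "rc": [0] * 12,
            "n_correct": [1] * 12, "n_error": [0] * 12,
        }, index=pd.RangeIndex(1, 13, name="t"))
        other = LifeTable.from_counts(counts, other_scheme)
        with pytest.raises(ValueError, match="scheme"):
            diff_curves(example_lifetable, other, "h")
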