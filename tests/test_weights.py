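"""Incidence tables and the age-stratum sampling-weight calibration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import wcohort as wc
from wcohort.weights import IncidenceTable, censoring_survival


def table(rates, width=5.0, label="t"):
    lo = np.arange(len(rates)) * width
    return IncidenceTable(lo, lo + width, np.asarray(rates, float), label=label)


def frame(exit_ages, events, interview_ages=None, reasons=None):
    exit_ages = np.asarray(exit_ages, float)
    return pd.DataFrame({
        "exit_age": exit_ages,
        "event": np.asarray(events, int),
        "interview_age": (exit_ages if interview_ages is None
                          else np.asarray(interview_ages, float)),
        "censor_reason": (["none" if e else "last_contact" for e in events]
                          if reasons is None else reasons),
    })


class TestIncidenceTable:
    def test_validation(self):
        with pytest.raises(ValueError, match="start at age 0"):
            IncidenceTable(np.array([5.0]), np.array([10.0]), np.array([0.1]))
        with pytest.raises(ValueError, match="contiguous"):
            IncidenceTable(np.array([0.0, 10.0]), np.array([5.0, 15.0]),
                           np.array([0.1, 0.1]))
        with pytest.raises(ValueError, match="negative"):
            table([0.1, -0.1])

    def test_stratum_boundaries_are_half_open(self):
        t = table([0.1, 0.1, 0.1])
        assert list(t.stratum_of([0.0, 5.0, 5.01, 10.0, 14.9, 200.0])) == \
            [0, 0, 1, 1, 2, 2]

    def test_cumulative_hazard_is_piecewise_linear(self):
        t = table([0.01, 0.02])
        assert t.cumulative_hazard(5.0) == pytest.approx(0.05)
        assert t.cumulative_hazard(7.5) == pytest.approx(0.05 + 0.05)
        assert t.cumulative_hazard(100.0) == pytest.approx(0.15)

    def test_roundtrip(self, tmp_path):
        t = table([0.01, 0.02, 0.0])
        t.to_csv(tmp_path / "inc.tsv")
        back = IncidenceTable.from_csv(tmp_path / "inc.tsv", label="t")
        assert np.allclose(back.rate, t.rate)
        assert np.allclose(back.age_hi, t.age_hi)


class TestExpectedProportion:
    def test_zero_rates(self):
        t = table([0.0, 0.0, 0.0])
        assert all(wc.expected_affected_proportion(t, k) == 0.0 for k in range(3))

    def test_closed_forms(self):
        assert wc.expected_affected_proportion(table([0.01]), 0) == \
            pytest.approx(1 - np.exp(-0.05), abs=1e-12)
        t2 = table([0.01, 0.02])
        assert wc.expected_affected_proportion(t2, 1) == \
            pytest.approx(1 - np.exp(-0.15), abs=1e-12)

    def test_stratum_out_of_range(self):
        with pytest.raises(IndexError):
            wc.expected_affected_proportion(table([0.01]), 5)

    def test_censoring_discount(self):
        t = table([0.01, 0.01])
        p_net = wc.expected_affected_proportion(t, 1)
        # everyone censored by a competing cause at age 2 with survival 0.5
        p_obs = wc.expected_affected_proportion(
            t, 1, censoring=(np.array([2.0]), np.array([0.5])))
        assert p_obs < p_net
        # closed form: F(2) + 0.5*(F(10)-F(2))
        f = lambda a: 1 - np.exp(-0.01 * a)
        assert p_obs == pytest.approx(f(2.0) + 0.5 * (f(10.0) - f(2.0)),
                                      abs=1e-12)


def test_censoring_survival_nelson_aalen():
    rec = frame([1.0, 2.0, 3.0, 4.0], [0, 0, 0, 0],
                reasons=["last_contact", "polypectomy", "last_contact",
                         "last_contact"])
    times, surv = censoring_survival(rec)
    assert list(times) == [2.0]
    assert surv[0] == pytest.approx(np.exp(-1 / 3))


class TestComputeWeights:
    def test_defining_formulas(self):
        # one stratum with expected proportion 0.10, 20 subjects, 10 affected
        rate = -np.log(0.9) / 5.0
        t = table([rate])
        rec = frame(np.full(20, 3.0), [1] * 10 + [0] * 10)
        wt = wc.compute_weights(rec, t, competing_adjust=False)
        row = wt.table.iloc[0]
        assert row["w_affected"] == pytest.approx(0.2, abs=1e-12)
        assert row["w_unaffected"] == pytest.approx(1.8, abs=1e-12)
        assert 10 * row["w_affected"] / 20 == pytest.approx(0.10, abs=1e-12)

    def test_identity_when_sample_matches_population(self):
        rate = -np.log(0.75) / 5.0           # p = 0.25
        t = table([rate])
        rec = frame(np.full(8, 2.0), [1, 1, 0, 0, 0, 0, 0, 0])
        wt = wc.compute_weights(rec, t, competing_adjust=False)
        assert np.allclose(wt.table[["w_affected", "w_unaffected"]].iloc[0], 1.0)

    def test_degenerate_strata_fall_back_flagged(self):
        t = table([0.01, 0.01, 0.01])
        rec = frame([2.0, 3.0, 7.0, 8.0], [0, 0, 1, 1])
        wt = wc.compute_weights(rec, t, stratify_by="exit",
                                competing_adjust=False, min_stratum_count=0)
        tab = wt.table.set_index("stratum")
        assert tab.loc[0, "fallback"] == "no_affected"
        assert (tab.loc[0, ["w_affected", "w_unaffected"]] == 1.0).all()
        assert tab.loc[1, "fallback"] == "all_affected"
        assert tab.loc[1, "w_affected"] == 1.0
        assert tab.loc[2, "fallback"] == "empty"

    def test_merge_degenerate_pools_upward(self):
        t = table([0.01, 0.01])
        rec = frame([2.0, 3.0, 7.0, 8.0], [0, 0, 1, 0])
        wt = wc.compute_weights(rec, t, stratify_by="exit",
                                competing_adjust=False, min_stratum_count=0,
                                merge_degenerate=True)
        tab = wt.table
        # stratum 0 (no affected) pooled with stratum 1: shared counts/weights
        assert tab.loc[0, "group"] == tab.loc[1, "group"] == 1
        assert tab.loc[0, "n"] == tab.loc[1, "n"] == 4
        assert tab.loc[0, "w_affected"] == tab.loc[1, "w_affected"]
        assert (tab["fallback"] == "").all()

    def test_min_count_pooling_stabilises_sparse_strata(self):
        t = table([0.004] * 10)
        rng = np.random.default_rng(8)
        exits = rng.uniform(0, 50, 60)
        rec = frame(exits, (rng.random(60) < 0.1).astype(int))
        raw = wc.compute_weights(rec, t, competing_adjust=False,
                                 min_stratum_count=0).table
        pooled = wc.compute_weights(rec, t, competing_adjust=False,
                                    min_stratum_count=5).table
        # every pooled group reaches the minimum or is the open-ended tail
        groups = pooled.drop_duplicates("group")
        assert ((groups["d"] >= 5) & (groups["n"] - groups["d"] >= 5)
                | (groups["group"] == pooled["group"].max())).all()
        assert len(pooled["group"].unique()) < len(raw)

    def test_certain_disease_with_survivors_is_an_error(self):
        t = table([2.0] * 12, label="implausible")     # p -> 1 rapidly
        rec = frame([30.0, 40.0], [1, 0])
        with pytest.raises(ValueError, match="implausible"):
            wc.compute_weights(rec, t, competing_adjust=False)

    def test_monotone_in_rates(self):
        rng = np.random.default_rng(4)
        t1 = table(rng.uniform(0.0, 0.02, 10))
        t2 = IncidenceTable(t1.age_lo, t1.age_hi, t1.rate * 1.7, label="up")
        rec = frame(rng.uniform(0, 60, 300), rng.integers(0, 2, 300))
        w1 = wc.compute_weights(rec, t1, competing_adjust=False).table
        w2 = wc.compute_weights(rec, t2, competing_adjust=False).table
        ok = (w1["fallback"] == "") & (w2["fallback"] == "")
        assert (w2.loc[ok, "w_affected"] >= w1.loc[ok, "w_affected"] - 1e-12).all()

    def test_noncarrier_wrapper_matches_and_zero_rates_fall_back(self):
        t = table([0.005] * 10)
        rng = np.random.default_rng(2)
        rec = frame(rng.uniform(0, 50, 100), rng.integers(0, 2, 100))
        a = wc.compute_weights(rec, t).table
        b = wc.attach_noncarrier_weights(rec, t).table
        pd.testing.assert_frame_equal(a, b)
        zero = table([0.0] * 10)
        nocase = frame(rng.uniform(0, 50, 50), np.zeros(50, int))
        wt = wc.attach_noncarrier_weights(nocase, zero).table
        assert (wt.loc[wt["n"] > 0, "fallback"] == "no_affected").all()
        assert np.allclose(wt[["w_affected", "w_unaffected"]], 1.0)


@settings(max_examples=60, deadline=None)
@given(st.data())
@pytest.mark.parametrize("stratify_by", ["interview", "exit"])
def test_calibration_invariants_on_random_cohorts(stratify_by, data):
    """On every non-degenerate stratum the weighted affected proportion equals
    p_k and the mean weight is one, to 1e-10."""
    rng = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
    n = data.draw(st.integers(10, 250))
    n_strata = data.draw(st.integers(1, 14))
    t = table(rng.uniform(0, 0.01, n_strata))
    exit_ages = rng.uniform(0, n_strata * 5, n)
    interview = np.maximum(exit_ages, rng.uniform(0, n_strata * 5, n))
    events = rng.integers(0, 2, n)
    reasons = np.where(events == 1, "none",
                       rng.choice(["last_contact", "polypectomy",
                                   "other_cancer"], n))
    rec = frame(exit_ages, events, interview_ages=interview, reasons=reasons)
    wt = wc.compute_weights(rec, t, stratify_by=stratify_by)
    w = wt.weight_for(rec, t)
    assert (w >= 0).all()
    k = t.stratum_of(rec["interview_age" if stratify_by == "interview"
                         else "exit_age"])
    tab = wt.table
    ev = rec["event"].to_numpy()
    group_of = tab["group"].to_numpy()
    for g in tab.loc[tab["fallback"] == "", "group"].unique():
        mask = group_of[k] == g
        if mask.sum() == 0:
            continue
        p = tab.loc[tab["group"] == g, "p"].iloc[0]
        assert abs(w[mask].mean() - 1.0) < 1e-10
        assert abs(w[mask & (ev == 1)].sum() / mask.sum() - p) < 1e-10


def test_assign_weights_adds_column(carrier_records):
    inc = wc.default_carrier_incidence()
    wt = wc.compute_weights(carrier_records, inc)
    out = wc.assign_weights(carrier_records, wt, inc)
    assert "weight" not in carrier_records.columns
    assert (out["weight"] >= 0).all()
    assert len(out) == len(carrier_records)


def test_weight_table_roundtrip(tmp_path, carrier_records):
    inc = wc.default_carrier_incidence()
    wt = wc.compute_weights(carrier_records, inc)
    wt.to_csv(tmp_path / "wt.tsv")
    back = pd.read_csv(tmp_path / "wt.tsv", sep="\t")
    assert np.allclose(back["w_affected"], wt.table["w_affected"])
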