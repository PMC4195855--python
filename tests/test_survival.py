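"""Log-rank, permutation p, region reduction/fusion, adjustment, effect sizes."""

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter
from lifelines.statistics import logrank_test

from cnascan import (
    CNARegion,
    CohortMatrix,
    bh_adjust,
    hazard_ratio,
    holm_adjust,
    km_median,
    logrank,
    make_genome,
    permutation_p,
    reduce_to_regions,
    region_call_matrix,
    scan,
    simulate_region_cohort,
    stratify_four_groups,
    validate,
)


def logrank_oracle(times, events, groups):
    """Independent 2x2-table oracle: O-E and hypergeometric variance summed
    over each distinct death time, written as plainly as possible."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    groups = np.asarray(groups, bool)
    O = E = V = 0.0
    for u in sorted(set(times[events == 1])):
        at_risk = times >= u
        n = at_risk.sum()
        n1 = (at_risk & groups).sum()
        dead = (times == u) & (events == 1)
        d = dead.sum()
        O += (dead & groups).sum()
        E += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return (O - E) ** 2 / V if V > 0 else 0.0


def _cohort(calls, surv, regions=None):
    return CohortMatrix(calls, surv, regions or [])


class TestLogrank:
    def test_hand_computed_example(self):
        """Two early deaths in A vs two late in B: chi2 = (2 - 5/6)^2 / (17/36)."""
        times = [1.0, 2.0, 3.0, 4.0]
        events = [1, 1, 1, 1]
        groups = [1, 1, 0, 0]
        chi2, p = logrank(times, events, groups)
        assert chi2 == pytest.approx(49.0 / 17.0, abs=1e-12)

    def test_symmetric_groups_score_zero(self):
        times = [1, 1, 2, 2, 3, 3]
        events = [1] * 6
        groups = [1, 0, 1, 0, 1, 0]
        chi2, p = logrank(times, events, groups)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == 1.0

    def test_matches_independent_oracle_on_small_fixtures(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            n = int(rng.integers(4, 11))
            times = rng.integers(1, 6, n).astype(float)
            events = rng.integers(0, 2, n)
            groups = rng.integers(0, 2, n).astype(bool)
            if events.sum() == 0 or groups.all() or not groups.any():
                continue
            chi2, _ = logrank(times, events, groups)
            assert chi2 == pytest.approx(logrank_oracle(times, events, groups),
                                         abs=1e-9)

    def test_matches_lifelines(self):
        rng = np.random.default_rng(2)
        for _ in range(3):
            n = 60
            g = rng.random(n) < 0.3
            t = rng.exponential(np.where(g, 50, 100))
            e = (t < 80).astype(int)
            t = np.minimum(t, 80.0)
            chi2, p = logrank(t, e, g)
            ll = logrank_test(t[g], t[~g], e[g], e[~g])
            assert chi2 == pytest.approx(ll.test_statistic, rel=1e-9)
            assert p == pytest.approx(ll.p_value, rel=1e-9)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="event"):
            logrank([1, 2], [0, 0], [1, 0])

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="two"):
            logrank([1, 2], [1, 1], [1, 1])

    def test_zero_variance_returns_p_one(self, caplog):
        # the carrier leaves follow-up before the only death
        chi2, p = logrank([0.5, 1.0, 2.0], [0, 1, 0], [1, 0, 0])
        assert p == 1.0


class TestPermutationP:
    def test_zero_statistic_gives_p_one(self):
        times = [1, 1, 2, 2, 3, 3]
        p, chi2 = permutation_p(times, [1] * 6, [1, 0, 1, 0, 1, 0],
                                n_perm=200, seed=1)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == 1.0

    def test_constant_carrier_gives_p_one(self):
        p, _ = permutation_p([1, 2, 3], [1, 1, 1], [1, 1, 1], n_perm=100, seed=1)
        assert p == 1.0

    def test_deterministic_per_seed_and_never_zero(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(100, 40)
        e = np.ones(40, int)
        g = rng.random(40) < 0.4
        p1, _ = permutation_p(t, e, g, n_perm=300, seed=7)
        p2, _ = permutation_p(t, e, g, n_perm=300, seed=7)
        assert p1 == p2
        assert p1 >= 1.0 / 301.0

    def test_null_calibration_quick(self):
        """Permutation p-values are roughly uniform under the null."""
        rng = np.random.default_rng(4)
        ps = []
        for _ in range(60):
            t = rng.exponential(100, 50)
            e = (t < 150).astype(int)
            t = np.minimum(t, 150.0)
            g = rng.random(50) < 0.3
            if g.all() or not g.any():
                continue
            ps.append(permutation_p(t, e, g, n_perm=200, seed=int(rng.integers(2**31)))[0])
        ps = np.array(ps)
        assert 0.2 < ps.mean() < 0.8
        assert (ps <= 0.05).mean() < 0.2


class TestRegionReduction:
    def test_identical_calls_one_region_per_chromosome(self, flat_bins):
        calls = np.full((len(flat_bins), 4), -1)
        regions = reduce_to_regions(calls, flat_bins)
        assert len(regions) == flat_bins["chrom"].nunique()

    def test_single_focal_loss_three_regions(self, flat_bins):
        sub = flat_bins[flat_bins["chrom"] == "1"].reset_index(drop=True)
        calls = np.zeros((len(sub), 1))
        calls[50:100, 0] = -1
        regions = reduce_to_regions(calls, sub)
        assert len(regions) == 3
        assert regions[1].start == int(sub["start"].iloc[50])
        assert regions[1].end == int(sub["end"].iloc[99])

    def test_staggered_fixture_matches_breakpoint_union(self, flat_bins):
        sub = flat_bins[flat_bins["chrom"] == "1"].reset_index(drop=True)
        n = len(sub)
        spans = [(10, 60), (40, 120), (60, 60), (150, 199), (0, 30)]
        calls = np.zeros((n, len(spans)))
        for j, (a, b) in enumerate(spans):
            calls[a : b + 1, j] = -1
        regions = reduce_to_regions(calls, sub)
        # brute force: a boundary wherever any sample's call changes
        expected_starts = {0}
        for i in range(1, n):
            if (calls[i] != calls[i - 1]).any():
                expected_starts.add(i)
        assert len(regions) == len(expected_starts)
        got = {int(np.flatnonzero(sub["start"].to_numpy() == r.start)[0])
               for r in regions}
        assert got == expected_starts

    def test_region_call_matrix_reads_back_constant_calls(self, flat_bins):
        calls = np.zeros((len(flat_bins), 2))
        calls[10:40, 0] = -1
        regions = reduce_to_regions(calls, flat_bins)
        mat = region_call_matrix(calls, flat_bins, regions, sample_ids=["a", "b"])
        assert mat.shape == (2, len(regions))
        # the focal region reads -1 for sample a, 0 for sample b
        focal = [r for r in regions if r.start == int(flat_bins["start"].iloc[10])][0]
        assert mat.loc["a", focal.label] == -1
        assert mat.loc["b", focal.label] == 0


class TestAdjusters:
    def test_holm_textbook_vector(self):
        p = [0.01, 0.02, 0.03, 0.04, 0.05]
        # step-down by hand: max-monotone of (5, 4, 3, 2, 1) * sorted p
        expected = [0.05, 0.08, 0.09, 0.09, 0.09]
        assert holm_adjust(p) == pytest.approx(expected)

    def test_bh_textbook_vector(self):
        p = np.array([0.01, 0.02, 0.03, 0.04, 0.05])
        m = 5
        ranked = p * m / np.arange(1, 6)
        expected = np.minimum.accumulate(ranked[::-1])[::-1]
        assert bh_adjust(p) == pytest.approx(expected)

    def test_bh_dominated_by_holm(self):
        rng = np.random.default_rng(5)
        p = rng.random(20)
        assert (bh_adjust(p) <= holm_adjust(p) + 1e-12).all()

    def test_adjusted_monotone_in_raw(self):
        rng = np.random.default_rng(6)
        p = rng.random(15)
        order = np.argsort(p)
        for adj in (bh_adjust, holm_adjust):
            a = adj(p)[order]
            assert (np.diff(a) >= -1e-12).all()
            assert (adj(p) >= p - 1e-12).all()


class TestScan:
    def _planted_cohort(self, seed=0):
        return simulate_region_cohort(
            120,
            {"bad": 0.25, "good": 0.40, "null_a": 0.3, "null_b": 0.2},
            hazard_ratios={"bad": 3.5, "good": 0.3},
            seed=seed,
        )

    def test_scan_reports_all_testable_regions(self):
        calls, surv = self._planted_cohort(1)
        res = scan(_cohort(calls, surv), n_perm=300, seed=1)
        assert set(res["region"]) == {"bad", "good", "null_a", "null_b"}
        assert ((res["p_adjusted"] >= res["p_raw"] - 1e-12)).all()
        assert res["p_raw"].between(0, 1, inclusive="right").all()

    def test_planted_risk_region_found(self):
        calls, surv = self._planted_cohort(2)
        res = scan(_cohort(calls, surv), n_perm=500, seed=2).set_index("region")
        assert res.loc["bad", "p_adjusted"] < 0.05
        assert res.loc["bad", "hr"] > 1.5

    def test_regions_with_too_few_carriers_skipped(self):
        calls, surv = self._planted_cohort(3)
        calls["rare"] = 0
        calls.iloc[0, calls.columns.get_loc("rare")] = -1
        res = scan(_cohort(calls, surv), n_perm=100, seed=3)
        assert "rare" not in set(res["region"])

    def test_consecutive_significant_regions_fused(self):
        """Adjacent same-chromosome regions carried by the same patients
        merge into one fused region spanning both."""
        rng = np.random.default_rng(7)
        n = 80
        carrier = rng.random(n) < 0.3
        ids = [f"P{i}" for i in range(n)]
        calls = pd.DataFrame(
            {"5:1-100": np.where(carrier, -1, 0),
             "5:101-200": np.where(carrier, -1, 0),
             "5:201-300": np.where(rng.random(n) < 0.3, -1, 0)},
            index=pd.Index(ids, name="patient_id"),
        )
        t = rng.exponential(np.where(carrier, 30, 120))
        surv = pd.DataFrame({"id": ids, "time_months": t, "event": 1})
        regions = [CNARegion("5", 1, 100), CNARegion("5", 101, 200),
                   CNARegion("5", 201, 300)]
        res = scan(_cohort(calls, surv, regions), n_perm=400, alpha_fuse=0.05, seed=8)
        fused = res[res["n_fused"] == 2]
        assert len(fused) == 1
        assert fused.iloc[0]["start"] == 1 and fused.iloc[0]["end"] == 200
        assert fused.iloc[0]["n_carriers"] == carrier.sum()
        assert len(res) == 2  # fused pair + the null region

    def test_no_fusion_when_nothing_significant(self):
        rng = np.random.default_rng(9)
        n = 60
        ids = [f"P{i}" for i in range(n)]
        calls = pd.DataFrame(
            {"5:1-100": np.where(rng.random(n) < 0.3, -1, 0),
             "5:101-200": np.where(rng.random(n) < 0.3, -1, 0)},
            index=pd.Index(ids, name="patient_id"),
        )
        surv = pd.DataFrame({"id": ids,
                             "time_months": rng.exponential(100, n),
                             "event": 1})
        regions = [CNARegion("5", 1, 100), CNARegion("5", 101, 200)]
        res = scan(_cohort(calls, surv, regions), n_perm=300, alpha_fuse=1e-4, seed=10)
        assert (res["n_fused"] == 1).all()
        assert len(res) == 2

    def test_validate_single_region_adjusted_equals_raw(self):
        calls, surv = self._planted_cohort(4)
        res = validate(_cohort(calls[["bad"]], surv), n_perm=300, seed=4)
        assert len(res) == 1
        assert res.iloc[0]["p_adjusted"] == pytest.approx(res.iloc[0]["p_raw"])


class TestStratification:
    def _cohort_with_arms(self):
        ids = ["a", "b", "c", "d", "e"]
        calls = pd.DataFrame(
            {
                "1p": [-1, -1, 0, -1, 0],
                "19q": [-1, 0, 0, -1, 0],
                "10q": [0, 0, -1, -1, 0],
            },
            index=pd.Index(ids, name="patient_id"),
        )
        surv = pd.DataFrame({"id": ids, "time_months": [10.0] * 5,
                             "event": [1] * 5})
        return _cohort(calls, surv)

    def test_four_group_labels(self):
        groups = stratify_four_groups(self._cohort_with_arms(), "1p", "19q", "10q")
        assert groups.tolist() == [
            "1p/19q-only",  # codel, no 10q
            "neither",      # 1p only is not a co-deletion
            "10q-only",
            "both",
            "neither",
        ]

    def test_group_sizes_match_planted_prevalence(self):
        calls, surv = simulate_region_cohort(
            400, {"1p": 0.4, "19q": 0.4, "10q": 0.18}, seed=11
        )
        # make 19q match 1p so the co-deletion is a single truncal event
        calls["19q"] = calls["1p"]
        groups = stratify_four_groups(_cohort(calls, surv), "1p", "19q", "10q")
        codel_frac = groups.isin(["1p/19q-only", "both"]).mean()
        assert codel_frac == pytest.approx(0.4, abs=0.07)


class TestEffectSizes:
    def test_km_median_hand_example(self):
        assert km_median([1, 2, 3, 4], [1, 1, 1, 1]) == pytest.approx(2.0)

    def test_km_median_undefined_when_all_censored(self):
        assert np.isnan(km_median([5, 6, 7], [0, 0, 0]))

    def test_km_median_recovers_exponential(self):
        rng = np.random.default_rng(12)
        t = rng.exponential(200.4 / np.log(2), 5_000)
        med = km_median(t, np.ones_like(t, dtype=int))
        assert med == pytest.approx(200.4, rel=0.05)

    def test_identical_groups_hr_one(self):
        t = np.r_[np.arange(1, 21), np.arange(1, 21)].astype(float)
        e = np.ones(40, int)
        g = np.r_[np.ones(20), np.zeros(20)]
        hr = hazard_ratio(t, e, g)
        assert hr.hr == pytest.approx(1.0, abs=1e-6)

    def test_label_swap_inverts_hr(self):
        rng = np.random.default_rng(13)
        g = rng.random(200) < 0.3
        t = rng.exponential(np.where(g, 40, 100))
        e = np.ones(200, int)
        a = hazard_ratio(t, e, g)
        b = hazard_ratio(t, e, ~g)
        assert a.hr == pytest.approx(1.0 / b.hr, rel=1e-6)

    def test_matches_lifelines_partial_likelihood(self):
        rng = np.random.default_rng(14)
        g = (rng.random(150) < 0.4).astype(float)
        t = rng.exponential(np.where(g > 0, 50, 100))
        e = (t < 120).astype(int)
        t = np.minimum(t, 120.0)
        ours = hazard_ratio(t, e, g)
        df = pd.DataFrame({"t": t, "e": e, "x": g})
        ll = CoxPHFitter().fit(df, "t", "e")
        assert np.log(ours.hr) == pytest.approx(ll.params_["x"], abs=1e-6)
        lo, hi = ll.confidence_intervals_.iloc[0]
        assert np.log(ours.ci_low) == pytest.approx(lo, abs=1e-4)
        assert np.log(ours.ci_high) == pytest.approx(hi, abs=1e-4)

    def test_monotone_likelihood_flagged(self):
        # every carrier dies before any control event: beta diverges
        t = np.r_[np.arange(1, 6), np.arange(10, 15)].astype(float)
        e = np.ones(10, int)
        g = np.r_[np.ones(5), np.zeros(5)]
        hr = hazard_ratio(t, e, g)
        assert not hr.converged
        assert hr.ci_high == np.inf

    def test_one_event_per_group_required(self):
        with pytest.raises(ValueError, match="event"):
            hazard_ratio([1, 2, 3, 4], [1, 1, 0, 0], [1, 1, 0, 0])
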