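"""Log-rank statistic, permutation scan, and Kaplan-Meier estimator."""

from itertools import permutations

import numpy as np
import pytest
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

import metacna as m

from conftest import event_matrix_from_arrays


def _surv(times, events):
    return m.SurvivalData(np.asarray(times, float), np.asarray(events, int))


class TestLogrank:
    def test_identical_groups_zero(self):
        g = _surv([1, 2, 3, 4], [1, 1, 0, 1])
        assert m.logrank_statistic(g, g) == pytest.approx(0.0)

    def test_hand_tabulated_censored_group(self):
        # A fully censored at 1, 2; B events at 3, 4: by the time either event
        # occurs the A risk set is empty, so O-E = 0 and V = 0 at both event
        # times and the statistic is 0
        a = _surv([1, 2], [0, 0])
        b = _surv([3, 4], [1, 1])
        assert m.logrank_statistic(a, b) == 0.0

    def test_symmetric_under_group_swap(self):
        a = _surv([2, 5, 7, 9], [1, 0, 1, 1])
        b = _surv([1, 3, 4], [1, 1, 0])
        assert m.logrank_statistic(a, b) == pytest.approx(m.logrank_statistic(b, a))

    def test_matches_lifelines(self):
        rng = np.random.default_rng(1)
        ta, ea = rng.exponential(10, 30), (rng.random(30) < 0.7).astype(int)
        tb, eb = rng.exponential(6, 25), (rng.random(25) < 0.8).astype(int)
        mine = m.logrank_statistic(_surv(ta, ea), _surv(tb, eb))
        ref = logrank_test(ta, tb, ea, eb).test_statistic
        assert mine == pytest.approx(ref, rel=1e-9)

    def test_requires_events(self):
        with pytest.raises(ValueError, match="no events"):
            m.logrank_statistic(_surv([1, 2], [0, 0]), _surv([3], [0]))


class TestPermutationScan:
    def test_matches_exhaustive_enumeration_n6(self):
        times = np.array([2.0, 4.0, 3.0, 7.0, 1.0, 5.0])
        events = np.array([1, 1, 0, 1, 1, 1])
        carriers = np.array([[True, True, False, False, True, False]])
        obs = m.logrank_statistic(
            _surv(times[carriers[0]], events[carriers[0]]),
            _surv(times[~carriers[0]], events[~carriers[0]]),
        )
        exceed = total = 0
        for perm in permutations(range(6)):
            tp, ep = times[list(perm)], events[list(perm)]
            stat = m.logrank_statistic(
                _surv(tp[carriers[0]], ep[carriers[0]]),
                _surv(tp[~carriers[0]], ep[~carriers[0]]),
            )
            exceed += stat >= obs - 1e-12
            total += 1
        exact = exceed / total
        matrix = event_matrix_from_arrays(carriers)
        scan = m.permutation_scan(
            matrix,
            _surv(times, events),
            m.ScanConfig(B=9999, seed=15, min_group=2),
            "gain",
        )
        se = np.sqrt(exact * (1 - exact) / 9999)
        assert scan["p_perm"][0] == pytest.approx(exact, abs=3 * se)

    def test_region_carried_by_all_untested(self):
        gain = np.ones((1, 8), bool)
        matrix = event_matrix_from_arrays(gain)
        scan = m.permutation_scan(
            matrix, _surv(np.arange(1, 9), np.ones(8)), m.ScanConfig(B=199), "gain"
        )
        assert not scan["tested"][0]
        assert np.isnan(scan["p_perm"][0])

    def test_planted_hazard_region_detected(self):
        config = m.CohortConfig(
            n_pre=50, n_post=30, n_chrom=1, targets_per_chrom=20,
            truth_regions=[
                m.TruthRegion("chr1", 50_000, 150_000, "gain", 0.58, 0.4, 0.4,
                              hazard_ratio=3.0)
            ],
            n_genes=5, seed=11,
        )
        cohort = m.generate_cohort(config)
        gain = cohort.carriers.to_numpy()
        matrix = event_matrix_from_arrays(gain)
        surv = m.SurvivalData(
            cohort.clinical["pfs_months"].to_numpy(),
            cohort.clinical["progression"].to_numpy(),
        )
        scan = m.permutation_scan(matrix, surv, m.ScanConfig(B=999, seed=13), "gain")
        assert scan["p_perm"][0] <= 0.005

    def test_reproducible_and_bounded(self):
        rng = np.random.default_rng(3)
        gain = rng.random((20, 30)) < 0.4
        matrix = event_matrix_from_arrays(gain)
        surv = _surv(rng.exponential(10, 30), rng.random(30) < 0.8)
        cfg = m.ScanConfig(B=199, seed=5, alpha_perm=0.01)
        a = m.permutation_scan(matrix, surv, cfg, "gain")
        b = m.permutation_scan(matrix, surv, cfg, "gain")
        tested = a["tested"].to_numpy()
        np.testing.assert_array_equal(a["p_perm"][tested], b["p_perm"][tested])
        assert (a["p_perm"][tested] >= 1 / 200).all()
        assert (a["p_perm"][tested] <= 1.0).all()

    def test_chi_square_reference_agrees_with_permutation(self):
        rng = np.random.default_rng(7)
        n = 60
        gain = np.zeros((1, n), bool)
        gain[0, :25] = True
        times = rng.exponential(10, n)
        times[:25] *= 0.75
        events = (rng.random(n) < 0.85).astype(int)
        matrix = event_matrix_from_arrays(gain)
        scan = m.permutation_scan(
            matrix, _surv(times, events), m.ScanConfig(B=1999, seed=8), "gain"
        )
        from scipy import stats as sps

        stat = scan["statistic"][0]
        p_chi2 = sps.chi2.sf(stat, 1)
        assert scan["p_perm"][0] == pytest.approx(p_chi2, abs=0.05)

    def test_misaligned_samples_rejected(self):
        matrix = event_matrix_from_arrays(np.zeros((2, 4), bool))
        surv = m.SurvivalData(
            np.ones(4), np.ones(4, int), sample_ids=["x1", "x2", "x3", "x4"]
        )
        with pytest.raises(ValueError, match="sample sets"):
            m.permutation_scan(matrix, surv, m.ScanConfig(B=199), "gain")


class TestKaplanMeier:
    def test_all_events_closed_form(self):
        km = m.km_estimate(_surv([1, 2, 3], [1, 1, 1]))
        np.testing.assert_allclose(km.survival, [2 / 3, 1 / 3, 0.0])
        assert km.median == 2.0

    def test_all_censored_flat_no_median(self):
        km = m.km_estimate(_surv([1, 2, 3], [0, 0, 0]))
        assert km.survival_at(10.0) == 1.0
        assert km.median is None

    def test_product_limit_with_censoring(self):
        # events at 1 and 2, censored at 3: S = 2/3 then (2/3)*(1/2) = 1/3
        km = m.km_estimate(_surv([1, 2, 3], [1, 1, 0]))
        np.testing.assert_allclose(km.survival, [2 / 3, 1 / 3])
        assert km.survival_at(2.5) == pytest.approx(1 / 3)

    def test_matches_lifelines(self):
        rng = np.random.default_rng(2)
        t = rng.exponential(8, 40)
        e = (rng.random(40) < 0.7).astype(int)
        km = m.km_estimate(_surv(t, e))
        kmf = KaplanMeierFitter().fit(t, e)
        for ti, si in zip(km.times, km.survival):
            assert si == pytest.approx(kmf.predict(ti), rel=1e-9)

    def test_non_increasing_right_continuous(self):
        rng = np.random.default_rng(4)
        km = m.km_estimate(_surv(rng.exponential(5, 50), rng.random(50) < 0.6))
        assert (np.diff(km.survival) <= 1e-12).all()
        assert km.survival_at(0.0) <= 1.0
        assert km.survival_at(-0.5) == 1.0
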