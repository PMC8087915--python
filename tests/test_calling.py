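"""Ratio computation, pooled reference, segmentation, calls, and QC."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import metacna as m
from metacna.calling import _best_split

from conftest import coverage_tables, make_track


def _coverage(counts, chrom="chr1"):
    n = len(counts)
    return pd.DataFrame(
        {
            "target_id": [f"{chrom}_t{i}" for i in range(n)],
            "chrom": chrom,
            "start": np.arange(n) * 1000,
            "end": np.arange(n) * 1000 + 100,
            "count": counts,
        }
    )


class TestLog2Ratio:
    def test_identical_profiles_give_zero(self):
        cov = _coverage([100, 200, 300, 400])
        track = m.compute_log2_ratio(cov, cov.copy())
        np.testing.assert_allclose(track.log2, 0.0, atol=1e-9)

    def test_global_doubling_is_unidentifiable(self):
        normal = _coverage([100, 200, 300, 400])
        tumor = normal.copy()
        tumor["count"] = tumor["count"] * 2
        track = m.compute_log2_ratio(tumor, normal, pseudocount=0.0)
        np.testing.assert_allclose(track.log2, 0.0, atol=1e-9)

    def test_planted_double_copy_region(self):
        # one 10-target region at twice background ratio in a 100-target map
        counts = np.full(100, 1000.0)
        tumor = _coverage(counts.copy())
        tumor.loc[40:49, "count"] = 2000.0
        normal = _coverage(counts)
        track = m.compute_log2_ratio(tumor, normal)
        in_region = np.zeros(100, bool)
        in_region[40:50] = True
        np.testing.assert_allclose(track.log2[in_region], 1.0, atol=0.01)
        np.testing.assert_allclose(track.log2[~in_region], 0.0, atol=0.01)

    def test_median_is_centered(self):
        rng = np.random.default_rng(0)
        tumor = _coverage(rng.poisson(200, 50))
        normal = _coverage(rng.poisson(200, 50))
        track = m.compute_log2_ratio(tumor, normal)
        assert abs(np.median(track.log2)) < 1e-9

    def test_sex_chromosomes_dropped(self):
        cov = pd.concat([_coverage([10, 20]), _coverage([30, 40], chrom="chrX")])
        track = m.compute_log2_ratio(cov, cov.copy())
        assert set(track.targets["chrom"]) == {"chr1"}

    def test_errors(self):
        a = _coverage([1, 2, 3])
        b = _coverage([1, 2, 3, 4])
        with pytest.raises(ValueError, match="target maps"):
            m.compute_log2_ratio(a, b)
        zero = _coverage([0, 0, 0])
        with pytest.raises(ValueError, match="all-zero normal"):
            m.compute_log2_ratio(a, zero)


class TestPooledReference:
    def test_two_identical_normals_reproduce_input(self):
        cov = _coverage([10, 20, 30])
        ref = m.build_pooled_reference([cov, cov.copy()])
        np.testing.assert_allclose(ref["count"], [10, 20, 30])

    def test_two_sample_hand_average(self):
        # totals 30 and 50 scaled to 40 each: (13.33, 26.67) and (24, 16)
        ref = m.build_pooled_reference([_coverage([10, 20]), _coverage([30, 20])])
        np.testing.assert_allclose(ref["count"], [(40 / 3 + 24) / 2, (80 / 3 + 16) / 2])

    def test_requires_two_normals(self):
        with pytest.raises(ValueError, match="at least 2"):
            m.build_pooled_reference([_coverage([1, 2])])

    def test_tumor_vs_pool_is_finite(self):
        rng = np.random.default_rng(1)
        normals = [_coverage(rng.poisson(150, 30)) for _ in range(4)]
        tumor = _coverage(rng.poisson(150, 30))
        ref = m.build_pooled_reference(normals)
        track = m.compute_log2_ratio(tumor, ref, reference_kind="pooled")
        assert np.isfinite(track.log2).all()
        assert track.reference_kind == "pooled"


class TestSegmentation:
    def test_constant_track_single_segment_per_chromosome(self):
        seg = m.segment_ratios(make_track(np.zeros(40)))
        assert len(seg) == 1
        assert seg["n_targets"].iloc[0] == 40

    def test_noiseless_step_recovered_exactly(self):
        seg = m.segment_ratios(make_track(np.r_[np.zeros(20), np.ones(20)]))
        assert seg["n_targets"].tolist() == [20, 20]
        np.testing.assert_allclose(seg["mean_log2"], [0.0, 1.0], atol=1e-12)

    def test_matches_exhaustive_single_split_oracle(self):
        # single-step track: the best arc touches the end, so the optimum
        # coincides with the best single cut scored at every position
        rng = np.random.default_rng(3)
        x = np.r_[rng.normal(0, 0.15, 25), rng.normal(0.8, 0.15, 25)]
        oracle = max(
            range(3, len(x) - 2),
            key=lambda k: abs(stats.ttest_ind(x[:k], x[k:]).statistic),
        )
        seg = m.segment_ratios(make_track(x), seed=5)
        assert len(seg) == 2
        assert seg["n_targets"].iloc[0] == oracle

    def test_idempotent_on_segment_means(self):
        rng = np.random.default_rng(4)
        x = np.r_[rng.normal(0, 0.2, 20), rng.normal(1, 0.2, 15), rng.normal(0, 0.2, 25)]
        seg = m.segment_ratios(make_track(x), seed=6)
        means = np.repeat(seg["mean_log2"].to_numpy(), seg["n_targets"].to_numpy())
        seg2 = m.segment_ratios(make_track(means), seed=8)
        assert seg2["n_targets"].tolist() == seg["n_targets"].tolist()

    def test_segments_tile_the_chromosome(self):
        rng = np.random.default_rng(5)
        x = np.r_[rng.normal(0, 0.3, 30), rng.normal(0.8, 0.3, 20), rng.normal(0, 0.3, 30)]
        seg = m.segment_ratios(make_track(x), seed=9)
        assert seg["start"].iloc[0] == 0
        assert (seg["end"].to_numpy()[:-1] == seg["start"].to_numpy()[1:]).all()
        assert seg["n_targets"].sum() == 80

    def test_interior_focal_event_detected(self):
        rng = np.random.default_rng(6)
        x = rng.normal(0, 0.2, 90)
        x[30:60] += 0.8
        seg = m.segment_ratios(make_track(x), seed=10)
        called = m.call_segments(seg)
        gains = called[called["call"].isin(["gain", "high_gain"])]
        assert len(gains) == 1
        assert gains["start"].iloc[0] == 30_000
        assert gains["n_targets"].iloc[0] == 30

    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError, match="finite"):
            make_track([0.0, np.nan, 0.0])

    def test_best_split_zero_variance_step(self):
        i, j, t = _best_split(np.r_[np.zeros(10), np.ones(10)], 3)
        assert (i, j) == (0, 10) or (i, j) == (10, 20)
        assert t == np.inf


class TestBoundaryRecovery:
    def test_planted_boundaries_recovered_within_two_targets(self):
        # low-overdispersion regime: >= 95% of planted boundaries within
        # +-2 targets (20 kb at the synthetic 10 kb target spacing)
        config = m.CohortConfig(
            n_pre=20, n_post=0, n_chrom=2, targets_per_chrom=100,
            truth_regions=[
                m.TruthRegion("chr1", 300_000, 600_000, "gain", 0.58, 1.0, 1.0)
            ],
            depth_dispersion=0.01, seed=41,
        )
        cohort = m.generate_cohort(config)
        hits = total = 0
        for sample in cohort.carriers.columns:
            tumor, normal = coverage_tables(cohort, sample)
            track = m.compute_log2_ratio(tumor, normal, sample_id=sample)
            seg = m.segment_ratios(track, seed=1)
            chr1 = seg[seg["chrom"] == "chr1"]
            breakpoints = set(chr1["start"]) | set(chr1["end"])
            for boundary in (300_000, 600_000):
                total += 1
                hits += any(abs(boundary - b) <= 20_000 for b in breakpoints)
        assert hits / total >= 0.95


class TestCalls:
    @pytest.mark.parametrize(
        "mean_log2,expected",
        [
            (0.0, "neutral"),
            (0.2, "gain"),  # boundary is inclusive
            (-0.2, "loss"),
            (1.0, "high_gain"),
            (-1.3, "homozygous_loss"),
            (0.19, "neutral"),
            (-0.19, "neutral"),
        ],
    )
    def test_threshold_calls(self, mean_log2, expected):
        seg = pd.DataFrame({"mean_log2": [mean_log2]})
        assert m.call_segments(seg)["call"].iloc[0] == expected

    def test_unordered_thresholds_rejected(self):
        with pytest.raises(ValueError, match="thresholds"):
            m.call_segments(
                pd.DataFrame({"mean_log2": [0.0]}),
                m.CallThresholds(hom_loss=-0.1, loss=-0.2, gain=0.2, high_gain=1.0),
            )


class TestQC:
    def test_constant_track_zero_dlrs(self):
        track = make_track(np.ones(20) * 0.3)
        seg = m.call_segments(m.segment_ratios(track))
        assert m.qc_metrics(track, seg).dlrs == 0.0

    def test_alternating_track_closed_form(self):
        h = 0.4
        x = np.tile([0.0, h], 15)
        track = make_track(x)
        seg = m.call_segments(
            pd.DataFrame(
                {"chrom": ["chr1"], "start": [0], "end": [30_000],
                 "n_targets": [30], "mean_log2": [h / 2]}
            )
        )
        qc = m.qc_metrics(track, seg)
        assert qc.dlrs == pytest.approx(h / np.sqrt(2))

    def test_all_neutral_fraction_zero(self):
        track = make_track(np.zeros(10))
        seg = m.call_segments(m.segment_ratios(track))
        qc = m.qc_metrics(track, seg)
        assert qc.fraction_genome_altered == 0.0

    def test_fraction_genome_altered_span_weighted(self):
        seg = m.call_segments(
            pd.DataFrame(
                {"chrom": "chr1", "start": [0, 750], "end": [750, 1000],
                 "n_targets": [3, 1], "mean_log2": [0.0, 0.9]}
            )
        )
        qc = m.qc_metrics(make_track([0, 0, 0, 0.9]), seg)
        assert qc.fraction_genome_altered == pytest.approx(0.25)

    def test_dlrs_decreases_with_depth_dispersion(self):
        dlrs = {}
        for disp in (0.0, 0.05):
            vals = []
            for seed in (51, 52):
                config = m.CohortConfig(
                    n_pre=3, n_post=0, n_chrom=1, targets_per_chrom=60,
                    depth_dispersion=disp, n_genes=5, seed=seed,
                )
                cohort = m.generate_cohort(config)
                for sample in cohort.tumor_counts.columns:
                    tumor, normal = coverage_tables(cohort, sample)
                    track = m.compute_log2_ratio(tumor, normal)
                    seg = m.call_segments(m.segment_ratios(track))
                    vals.append(m.qc_metrics(track, seg).dlrs)
            dlrs[disp] = np.mean(vals)
        assert dlrs[0.0] < dlrs[0.05]
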