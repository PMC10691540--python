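"""Coverage building, mode detection, filtering/merging and peak fitting."""

import numpy as np
import pysam
import pytest

from apamix.annotation import GeneModel, GenomicInterval, Transcript
from apamix.peaks import (
    CoverageTrack, PeakMode, attribute_reads_to_modes, build_coverage,
    cluster_modes, detect_modes, filter_and_merge_modes, fit_cluster_em,
    fit_isolated, smooth_coverage,
)
from conftest import make_bam


def _gene(strand="+", utr=(0, 2000), chrom="chrT"):
    iv = GenomicInterval(chrom, *utr, strand)
    g = GeneModel("g1", chrom, strand, [Transcript("g1.t1", [iv], iv)])
    g.extended_utr_regions = [iv]
    return g


def _track(counts, in_utr=None, reps=(), strand="+"):
    counts = np.asarray(counts, dtype=np.int64)
    mask = np.ones(len(counts), bool) if in_utr is None else np.asarray(in_utr)
    return CoverageTrack("g1", GenomicInterval("chrT", 0, len(counts), strand),
                         counts, mask, np.asarray(sorted(reps), dtype=np.int64),
                         n_umis=len(reps))


class TestBuildCoverage:
    def test_reads_sharing_a_umi_collapse_to_one_representative(self, tmp_path):
        reads = [(f"r{i}", 100, [(0, 90)], {"CB": "c1", "UB": "u1"}, 0)
                 for i in range(5)]
        bam_path = make_bam(tmp_path / "dup.bam", reads)
        with pysam.AlignmentFile(bam_path) as bam:
            track = build_coverage(bam, _gene())
        assert track.n_umis == 1
        assert track.counts[100:190].tolist() == [1] * 90
        assert track.counts.sum() == 90

    def test_spliced_cigar_increments_only_matched_bases(self, tmp_path):
        reads = [("r1", 100, [(0, 50), (3, 200), (0, 40)],
                  {"CB": "c1", "UB": "u1"}, 0)]
        bam_path = make_bam(tmp_path / "spliced.bam", reads)
        with pysam.AlignmentFile(bam_path) as bam:
            track = build_coverage(bam, _gene())
        assert track.counts[100:150].sum() == 50
        assert track.counts[150:350].sum() == 0       # the N gap
        assert track.counts[350:390].sum() == 40

    def test_missing_tags_are_tallied_not_counted(self, tmp_path):
        reads = [("r1", 100, [(0, 90)], {"CB": "c1", "UB": "u1"}, 0),
                 ("r2", 300, [(0, 90)], {"CB": "c1"}, 0)]
        bam_path = make_bam(tmp_path / "tags.bam", reads)
        with pysam.AlignmentFile(bam_path) as bam:
            track = build_coverage(bam, _gene())
        assert track.n_umis == 1
        assert track.n_dropped_tags == 1

    def test_empty_region_gives_zero_track(self, tmp_path):
        bam_path = make_bam(tmp_path / "empty.bam",
                            [("r1", 5000, [(0, 90)],
                              {"CB": "c1", "UB": "u1"}, 0)])
        with pysam.AlignmentFile(bam_path) as bam:
            track = build_coverage(bam, _gene(utr=(0, 1000)))
        assert track.counts.sum() == 0 and track.n_umis == 0

    def test_minus_strand_track_is_transcription_oriented(self, tmp_path):
        reads = [("r1", 100, [(0, 90)], {"CB": "c1", "UB": "u1"}, 16)]
        bam_path = make_bam(tmp_path / "minus.bam", reads)
        with pysam.AlignmentFile(bam_path) as bam:
            track = build_coverage(bam, _gene(strand="-", utr=(0, 1000)))
        # genomic [100,190) maps to offsets [1000-190, 1000-100)
        assert track.counts[810:900].tolist() == [1] * 90
        assert track.offset_to_genomic(899) == 100


class TestSmoothing:
    def test_zero_track_stays_zero(self):
        assert smooth_coverage(np.zeros(100)).sum() == 0

    def test_single_count_gives_symmetric_maximum(self):
        curve = smooth_coverage(np.eye(1, 201, 100).ravel(), bandwidth=10)
        assert np.argmax(curve) == 100
        np.testing.assert_allclose(curve[:100], curve[101:][::-1], atol=1e-12)

    def test_two_separated_counts_give_two_maxima(self):
        # oracle: direct evaluation of the kernel sum
        counts = np.zeros(600)
        counts[[200, 400]] = 1
        curve = smooth_coverage(counts, bandwidth=25)
        x = np.arange(600.0)
        oracle = sum(
            np.exp(-0.5 * ((x - p) / 25) ** 2) / (25 * np.sqrt(2 * np.pi))
            for p in (200, 400)
        )
        # the smoother truncates its kernel at 4 sigma; allow for the tails
        np.testing.assert_allclose(curve, oracle, atol=1e-5)
        modes = detect_modes(curve)
        assert [m.position for m in modes] == [200, 400]

    def test_mass_conserved_for_interior_signal(self):
        rng = np.random.default_rng(0)
        counts = np.zeros(2000)
        counts[800:1200] = rng.integers(0, 50, 400)
        curve = smooth_coverage(counts, bandwidth=25)
        assert abs(curve.sum() - counts.sum()) < 0.01 * counts.sum()


class TestDetectModes:
    def test_monotone_curve_has_no_interior_modes(self):
        assert detect_modes(np.arange(100.0)) == []
        assert detect_modes(np.arange(100.0)[::-1]) == []

    def test_plateau_reports_center(self):
        curve = np.zeros(400)
        curve[200:205] = 5.0
        curve[150:200] = 1.0
        curve[205:250] = 1.0
        (mode,) = detect_modes(curve)
        assert mode.position == 202

    def test_agrees_with_brute_force_scan_on_random_curves(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            curve = smooth_coverage(
                rng.poisson(2.0, 500).astype(float), bandwidth=5)
            found = [m.position for m in detect_modes(curve)]
            brute = [
                i for i in range(1, len(curve) - 1)
                if curve[i] > 0 and curve[i - 1] < curve[i] >= curve[i + 1]
                and curve[i] > curve[i + 1]
            ]
            assert found == brute


class TestFilterAndMerge:
    def test_read_count_and_relative_abundance_rules(self):
        modes = [PeakMode(100, 10, 200), PeakMode(500, 1, 4),
                 PeakMode(900, 2, 12)]
        out = filter_and_merge_modes(modes)
        assert [m.position for m in out] == [100, 900]

    def test_close_modes_merge_at_floored_mean(self):
        modes = [PeakMode(100, 5, 50), PeakMode(140, 4, 50)]
        (merged,) = filter_and_merge_modes(modes)
        assert merged.position == 120
        assert merged.raw_reads == 100

    def test_sequential_left_to_right_merging(self):
        modes = [PeakMode(100, 5, 50), PeakMode(145, 4, 50),
                 PeakMode(260, 3, 50)]
        out = filter_and_merge_modes(modes)
        assert [m.position for m in out] == [122, 260]

    def test_extra_utr_modes_dropped_unless_kept_for_fitting(self):
        mask = np.zeros(1000, bool)
        mask[:500] = True
        modes = [PeakMode(100, 5, 100, in_utr=True),
                 PeakMode(800, 5, 100, in_utr=False)]
        assert len(filter_and_merge_modes(modes)) == 1
        assert len(filter_and_merge_modes(modes, keep_outside=True)) == 2

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = rng.integers(1, 10)
            modes = [PeakMode(int(p), 1.0, int(r)) for p, r in zip(
                np.sort(rng.integers(0, 2000, n)),
                rng.integers(0, 300, n))]
            once = filter_and_merge_modes(modes)
            twice = filter_and_merge_modes(once)
            assert [(m.position, m.raw_reads) for m in once] == \
                   [(m.position, m.raw_reads) for m in twice]


class TestClusterModes:
    def test_far_apart_modes_are_isolated(self):
        clusters = cluster_modes([PeakMode(1000, 1, 1), PeakMode(1400, 1, 1)])
        assert [len(c) for c in clusters] == [1, 1]

    def test_within_radius_modes_cluster(self):
        clusters = cluster_modes([PeakMode(1000, 1, 1), PeakMode(1250, 1, 1)])
        assert [len(c) for c in clusters] == [2]

    def test_transitive_chaining(self):
        clusters = cluster_modes([PeakMode(1000, 1, 1), PeakMode(1250, 1, 1),
                                  PeakMode(1500, 1, 1)])
        assert [len(c) for c in clusters] == [3]


class TestFitIsolated:
    def test_recovers_gaussian_shape_parameters(self):
        x = np.arange(1000)
        counts = np.round(100 * np.exp(-0.5 * ((x - 500) / 30) ** 2)).astype(int)
        track = _track(counts)
        peak = fit_isolated(track, PeakMode(500, 100.0, 1000))
        assert abs(peak.mu - 500) <= 2
        assert abs(peak.sigma - 30) <= 0.15 * 30

    def test_single_base_spike_hits_sigma_clamp(self):
        counts = np.zeros(400, int)
        counts[200] = 50
        peak = fit_isolated(_track(counts), PeakMode(200, 50.0, 50))
        assert peak.sigma == pytest.approx(5.0, abs=1e-6)
        assert peak.mu == pytest.approx(200, abs=0.5)

    def test_symmetric_shape_centers_exactly(self):
        counts = np.zeros(400, int)
        counts[198:203] = [10, 20, 30, 20, 10]
        peak = fit_isolated(_track(counts), PeakMode(200, 30.0, 90))
        assert peak.mu == pytest.approx(200, abs=1e-6)


class TestFitClusterEM:
    def test_k1_matches_isolated_fit(self):
        rng = np.random.default_rng(1)
        pos = np.clip(rng.normal(500, 30, 4000).round().astype(int), 0, 999)
        counts = np.bincount(pos, minlength=1000)
        track = _track(counts)
        em, = fit_cluster_em(track, [PeakMode(500, 1.0, 4000)], window=200)
        iso = fit_isolated(track, PeakMode(500, 1.0, 4000), window=200)
        assert abs(em.mu - iso.mu) < 5
        assert abs(em.sigma - iso.sigma) < 6

    def test_superimposed_components_converge_with_total_mass_one(self):
        rng = np.random.default_rng(2)
        pos = np.clip(rng.normal(500, 25, 3000).round().astype(int), 0, 999)
        counts = np.bincount(pos, minlength=1000)
        track = _track(counts)
        peaks = fit_cluster_em(track, [PeakMode(495, 1.0, 1500),
                                       PeakMode(505, 1.0, 1500)])
        assert sum(p.weight for p in peaks) == pytest.approx(1.0, abs=1e-9)

    def test_loglik_monotone_and_mixture_recovered(self):
        rng = np.random.default_rng(5)
        pos = np.concatenate([rng.normal(1000, 30, 3000),
                              rng.normal(1150, 30, 2000)])
        counts = np.bincount(pos.round().astype(int), minlength=2000)
        track = _track(counts)
        peaks, trace = fit_cluster_em(
            track, [PeakMode(1000, 1.0, 3000), PeakMode(1150, 1.0, 2000)],
            window=300, return_trace=True)
        diffs = np.diff(trace)
        assert (diffs >= -1e-9 * np.abs(np.asarray(trace[:-1]))).all()
        assert abs(peaks[0].mu - 1000) <= 10 and abs(peaks[1].mu - 1150) <= 10
        assert abs(peaks[0].weight - 0.6) <= 0.05

    def test_agrees_with_independent_mixture_fitter(self):
        # cross-check against scikit-learn's EM on the expanded positions
        from sklearn.mixture import GaussianMixture
        rng = np.random.default_rng(5)
        pos = np.concatenate([rng.normal(1000, 30, 3000),
                              rng.normal(1150, 30, 2000)]).round().astype(int)
        counts = np.bincount(pos, minlength=2000)
        track = _track(counts)
        ours = fit_cluster_em(
            track, [PeakMode(1000, 1.0, 3000), PeakMode(1150, 1.0, 2000)],
            window=300)
        gm = GaussianMixture(2, means_init=[[1000], [1150]],
                             random_state=0).fit(pos.reshape(-1, 1))
        ref_mu = np.sort(gm.means_.ravel())
        assert abs(ours[0].mu - ref_mu[0]) < 3
        assert abs(ours[1].mu - ref_mu[1]) < 3


def test_nearest_mode_read_attribution():
    modes = [PeakMode(100, 1.0), PeakMode(300, 1.0)]
    attribute_reads_to_modes(modes, np.array([90, 110, 195, 290, 310, 350]))
    assert [m.raw_reads for m in modes] == [3, 3]
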