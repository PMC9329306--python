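"""CAM-bin ranking, overlap histograms, enrichment and reasoning reports."""

from __future__ import annotations

import numpy as np
import pytest

import sleepcam as sc
from sleepcam.errors import NoTruePositives, ZeroPrevalence
from sleepcam.explain import (
    merge_histograms,
    rank_bins,
    wave_coverage,
)
from sleepcam.io import WaveAnnotation
from sleepcam.model import CamOutput


def _cam_from_bins(bins_row: np.ndarray, stage: str = "N2") -> CamOutput:
    """CamOutput whose half-second bins for ``stage`` equal bins_row and
    whose prediction is forced to ``stage`` via the GAP logit."""
    s = list(sc.STAGES).index(stage)
    m = np.zeros((5, 60))
    m[s] = bins_row
    m[s] += 10.0  # dominate the time-mean so predict_stage == stage
    return CamOutput(map=m, step_s=0.5, probabilities=_softmax_rows(m))


def _softmax_rows(m):
    z = m.mean(axis=1)
    e = np.exp(z - z.max())
    return e / e.sum()


class TestRankBins:
    def test_strictly_decreasing_row(self):
        bins = np.zeros((5, 60))
        bins[3] = np.arange(60, 0, -1)
        pct = rank_bins(bins, "N2")
        assert pct[0] == pytest.approx(100 * 0.5 / 60)
        assert pct[0] < 100 / 60
        assert np.all(np.diff(pct) > 0)

    def test_constant_row_all_tied_at_50(self):
        bins = np.zeros((5, 60))
        np.testing.assert_allclose(rank_bins(bins, "W"), 50.0)

    def test_single_peak_occupies_top_bin(self):
        bins = np.zeros((5, 60))
        bins[0, 17] = 5.0
        pct = rank_bins(bins, "W")
        assert pct[17] == pct.min()
        assert pct[17] < 5.0

    def test_shift_invariance(self):
        rng = np.random.default_rng(0)
        bins = rng.normal(size=(5, 60))
        np.testing.assert_allclose(rank_bins(bins, "N3"),
                                   rank_bins(bins + 123.0, "N3"))


class TestWaveCoverage:
    def test_half_open_intersection(self):
        waves = sc.WaveAnnotationSet([WaveAnnotation(31.0, 1.0, "spindle")])
        mask = wave_coverage(waves, epoch_index=1, wave_type="spindle")
        # epoch 1 covers [30, 60); the wave occupies points [31.0,31.5),[31.5,32)
        assert mask[2] and mask[3]
        assert mask.sum() == 2

    def test_channel_restriction(self):
        waves = sc.WaveAnnotationSet([WaveAnnotation(0.0, 1.0, "spindle", "C3-M2")])
        assert wave_coverage(waves, 0, "spindle", channel="C3-M2").sum() == 2
        assert wave_coverage(waves, 0, "spindle", channel="C4-M1").sum() == 0
        assert wave_coverage(waves, 0, "spindle").sum() == 2  # any channel


class TestOverlapHistogram:
    def _indicator_setup(self):
        """CAM equals the indicator of annotated spindle bins."""
        waves = sc.WaveAnnotationSet([
            WaveAnnotation(5.0, 2.0, "spindle"),
            WaveAnnotation(20.0, 1.0, "spindle"),
        ])
        cover = wave_coverage(waves, 0, "spindle").astype(float)
        cam = _cam_from_bins(cover)
        ref = sc.Hypnogram(labels=["N2"])
        return [(0, cam)], ref, waves

    def test_indicator_cam_tops_are_pure(self):
        cams, ref, waves = self._indicator_setup()
        hist = sc.overlap_histogram(cams, ref, waves, "N2", "spindle")
        prevalence = hist.prevalence
        assert prevalence == pytest.approx(6 / 60)
        # the wave points occupy exactly the top 10% of ranked bins
        top = hist.bin_edges[1:] <= 10.0 + 1e-9
        assert hist.overlap_counts[top].sum() == 6
        assert hist.counts[top].sum() == 6
        assert hist.overlap_counts[~top].sum() == 0

    def test_constant_cam_gives_uniform_overlap(self):
        waves = sc.WaveAnnotationSet([WaveAnnotation(0.0, 6.0, "spindle")])
        cam = _cam_from_bins(np.zeros(60))
        ref = sc.Hypnogram(labels=["N2"])
        hist = sc.overlap_histogram([(0, cam)], ref, waves, "N2", "spindle")
        # all points tie at rank 50 -> single percentile bin holds everything
        filled = hist.counts > 0
        assert filled.sum() == 1
        assert hist.overlap_fraction[filled][0] == pytest.approx(12 / 60)

    def test_true_positive_restriction(self):
        cams, _, waves = self._indicator_setup()
        ref_wrong = sc.Hypnogram(labels=["N3"])  # prediction N2 != reference
        with pytest.raises(NoTruePositives):
            sc.overlap_histogram(cams, ref_wrong, waves, "N2", "spindle")

    def test_brute_force_fraction_equality(self):
        """Histogram fractions equal direct enumeration of all 0.5-s points."""
        rng = np.random.default_rng(5)
        waves = sc.WaveAnnotationSet([
            WaveAnnotation(float(o), 1.0, "spindle")
            for o in sorted(rng.choice(np.arange(0, 58, 2), 5, replace=False))
        ])
        cams = [(ep, _cam_from_bins(rng.normal(size=60))) for ep in range(3)]
        ref = sc.Hypnogram(labels=["N2", "N2", "N2"])
        hist = sc.overlap_histogram(cams, ref, waves, "N2", "spindle")
        n = np.zeros(20, dtype=int)
        overlap = np.zeros(20, dtype=int)
        for ep, cam in cams:
            pct = rank_bins(sc.cam_to_half_second_bins(cam), "N2")
            cover = wave_coverage(waves, ep, "spindle")
            for point in range(60):
                b = min(int(pct[point] // 5), 19)
                n[b] += 1
                overlap[b] += int(cover[point])
        np.testing.assert_array_equal(hist.counts, n)
        np.testing.assert_array_equal(hist.overlap_counts, overlap)
        nz = n > 0
        np.testing.assert_allclose(hist.overlap_fraction[nz],
                                   overlap[nz] / n[nz], atol=1e-12)

    def test_shift_invariance_of_histogram(self):
        cams, ref, waves = self._indicator_setup()
        shifted = [(i, CamOutput(map=c.map + 7.0, step_s=c.step_s,
                                 probabilities=c.probabilities))
                   for i, c in cams]
        a = sc.overlap_histogram(cams, ref, waves, "N2", "spindle")
        b = sc.overlap_histogram(shifted, ref, waves, "N2", "spindle")
        np.testing.assert_array_equal(a.counts, b.counts)
        np.testing.assert_array_equal(a.overlap_counts, b.overlap_counts)


class TestEnrichment:
    def test_indicator_cam_reaches_inverse_prevalence(self):
        waves = sc.WaveAnnotationSet([WaveAnnotation(5.0, 3.0, "spindle")])
        cover = wave_coverage(waves, 0, "spindle").astype(float)
        cam = _cam_from_bins(cover)
        ref = sc.Hypnogram(labels=["N2"])
        hist = sc.overlap_histogram([(0, cam)], ref, waves, "N2", "spindle")
        e = sc.enrichment(hist, top_percent=10.0)
        assert e == pytest.approx(1.0 / hist.prevalence)

    def test_constant_cam_enrichment_is_one(self):
        waves = sc.WaveAnnotationSet([WaveAnnotation(0.0, 6.0, "spindle")])
        cam = _cam_from_bins(np.zeros(60))
        ref = sc.Hypnogram(labels=["N2"])
        hist = sc.overlap_histogram([(0, cam)], ref, waves, "N2", "spindle")
        # all mass in one bin; top share equals overall prevalence
        assert sc.enrichment(hist, top_percent=100.0) == pytest.approx(1.0)

    def test_zero_prevalence_flagged(self):
        cam = _cam_from_bins(np.arange(60.0))
        ref = sc.Hypnogram(labels=["N2"])
        hist = sc.overlap_histogram([(0, cam)], ref,
                                    sc.WaveAnnotationSet([]), "N2", "spindle")
        with pytest.raises(ZeroPrevalence):
            sc.enrichment(hist, top_percent=10.0)


class TestMergeHistograms:
    def test_counts_add(self):
        waves = sc.WaveAnnotationSet([WaveAnnotation(5.0, 3.0, "spindle")])
        cover = wave_coverage(waves, 0, "spindle").astype(float)
        cam = _cam_from_bins(cover)
        ref = sc.Hypnogram(labels=["N2"])
        h = sc.overlap_histogram([(0, cam)], ref, waves, "N2", "spindle")
        m = merge_histograms([h, h, h])
        assert m.n_epochs == 3 * h.n_epochs
        np.testing.assert_array_equal(m.counts, 3 * h.counts)
        np.testing.assert_allclose(m.overlap_fraction, h.overlap_fraction)


class TestReasoningReport:
    def test_top_k_sorted_descending(self):
        rng = np.random.default_rng(1)
        cam = _cam_from_bins(rng.normal(size=60))
        rep = sc.reasoning_report(2, cam, waves=None, k=5)
        assert len(rep.intervals) == 5
        values = [iv.cam_value for iv in rep.intervals]
        assert values == sorted(values, reverse=True)
        assert rep.intervals[0].start_s >= 60.0  # inside epoch 2

    def test_full_epoch_listing(self):
        cam = _cam_from_bins(np.arange(60.0))
        rep = sc.reasoning_report(0, cam, waves=None, k=60)
        assert len(rep.intervals) == 60

    def test_overlapping_waves_listed(self):
        waves = sc.WaveAnnotationSet([WaveAnnotation(0.0, 0.5, "kcomplex")])
        row = np.zeros(60)
        row[0] = 5.0
        cam = _cam_from_bins(row)
        rep = sc.reasoning_report(0, cam, waves=waves, k=1)
        assert rep.intervals[0].overlapping_waves == ["kcomplex"]
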