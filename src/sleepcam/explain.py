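"""The CAM reasoning audit: do high-activation sub-intervals coincide with
expert-annotated characteristic waves?

For each true-positive epoch (model prediction equals the expert stage) the
predicted stage's CAM is averaged into 60 half-second bins and the bins are
ranked within the epoch by their top-percentile (the highest CAM bin sits
near percentile 0, the lowest near 100; ties share the mean rank). Ranked
bins are pooled across epochs into percentile bins (default 20 bins of 5%),
and each percentile bin reports the fraction of its half-second points that
intersect an annotated wave interval of the requested type. A model that
attends to the waves shows overlap concentrated in the top percentiles;
the enrichment factor condenses this into (top-bin overlap) / (overall
prevalence), which is 1 for a non-localizing (constant) CAM.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

from .errors import NoTruePositives, ShapeMismatch, ZeroPrevalence
from .io import STAGES, Hypnogram, WaveAnnotationSet
from .model import CamOutput, cam_to_half_second_bins, predict_stage

_STAGE_IDX = {s: i for i, s in enumerate(STAGES)}
EPOCH_BINS = 60  # half-second bins per 30-s epoch


def rank_bins(cam_bins: np.ndarray, stage: str) -> np.ndarray:
    """Within-epoch top-percentile rank of each half-second bin.

    Uses the requested stage's row of a (5, 60) binned CAM. The bin with the
    largest CAM value gets the smallest top-percentile; ties take the mean
    rank. Ranks are mid-percentiles in (0, 100): with 60 bins a unique
    maximum lands at 100 * 0.5/60 ~= 0.83, a fully tied row at 50.
    """
    cam_bins = np.asarray(cam_bins, dtype=np.float64)
    if stage not in _STAGE_IDX:
        raise KeyError(f"unknown stage {stage!r}")
    if cam_bins.ndim != 2 or cam_bins.shape[0] != len(STAGES):
        raise ShapeMismatch(f"expected (5, n_bins) matrix, got {cam_bins.shape}")
    row = cam_bins[_STAGE_IDX[stage]]
    ranks = rankdata(-row, method="average")  # 1 = largest CAM
    return (ranks - 0.5) / len(row) * 100.0


def wave_coverage(
    waves: WaveAnnotationSet,
    epoch_index: int,
    wave_type: str,
    channel: str | None = None,
) -> np.ndarray:
    """Boolean mask over the epoch's 60 half-second points: True where the
    point's half-open interval intersects an annotation of ``wave_type``.

    ``channel=None`` matches annotations on any channel; passing a channel
    name restricts to annotations on that channel or marked "any".
    """
    start = epoch_index * 30.0
    mask = np.zeros(EPOCH_BINS, dtype=bool)
    for e in waves.of_type(wave_type):
        if channel is not None and e.channel not in (channel, "any"):
            continue
        lo = max(0, int(np.ceil((e.onset_s - start) / 0.5 - 1e-9)))
        hi = min(EPOCH_BINS, int(np.ceil((e.end_s - start) / 0.5 - 1e-9)))
        if hi > lo:
            mask[lo:hi] = True
    return mask


@dataclass
class PercentileOverlapHistogram:
    """Overlap fraction between top-percentile CAM bins and wave intervals."""

    stage: str
    wave_type: str
    bin_edges: np.ndarray          # length n_bins+1, partitions [0, 100]
    overlap_fraction: np.ndarray   # per percentile bin, in [0, 1]
    counts: np.ndarray             # half-second points per percentile bin
    overlap_counts: np.ndarray     # of which intersect a wave interval
    n_epochs: int = 0

    @property
    def prevalence(self) -> float:
        """Overall fraction of scored points lying inside a wave interval."""
        total = self.counts.sum()
        return float(self.overlap_counts.sum() / total) if total else 0.0


def overlap_histogram(
    cams: Sequence[tuple[int, CamOutput]],
    reference: Hypnogram,
    waves: WaveAnnotationSet,
    stage: str,
    wave_type: str,
    n_bins: int = 20,
    channel: str | None = None,
) -> PercentileOverlapHistogram:
    """Aggregate CAM-rank vs. wave-overlap over true-positive epochs.

    ``cams`` pairs each epoch index (position in the reference hypnogram)
    with its CamOutput. Only epochs where the model's prediction and the
    expert label both equal ``stage`` contribute.
    """
    edges = np.linspace(0.0, 100.0, n_bins + 1)
    counts = np.zeros(n_bins, dtype=np.int64)
    overlap = np.zeros(n_bins, dtype=np.int64)
    n_tp = 0
    for epoch_index, cam in cams:
        if reference[epoch_index] != stage or predict_stage(cam) != stage:
            continue
        n_tp += 1
        pct = rank_bins(cam_to_half_second_bins(cam), stage)
        cover = wave_coverage(waves, epoch_index, wave_type, channel)
        which = np.clip(np.searchsorted(edges, pct, side="right") - 1, 0, n_bins - 1)
        np.add.at(counts, which, 1)
        np.add.at(overlap, which, cover.astype(np.int64))
    if n_tp == 0:
        raise NoTruePositives(f"no epoch with predicted = reference = {stage}")
    frac = np.divide(overlap, counts, out=np.zeros(n_bins), where=counts > 0)
    return PercentileOverlapHistogram(
        stage=stage, wave_type=wave_type, bin_edges=edges,
        overlap_fraction=frac, counts=counts, overlap_counts=overlap,
        n_epochs=n_tp,
    )


def merge_histograms(
    hists: Sequence[PercentileOverlapHistogram],
) -> PercentileOverlapHistogram:
    """Pool overlap histograms from several records (same stage/wave/bins)."""
    hists = list(hists)
    if not hists:
        raise ValueError("nothing to merge")
    first = hists[0]
    for h in hists[1:]:
        if (h.stage != first.stage or h.wave_type != first.wave_type
                or not np.array_equal(h.bin_edges, first.bin_edges)):
            raise ValueError("histograms are not commensurate")
    counts = np.sum([h.counts for h in hists], axis=0)
    overlap = np.sum([h.overlap_counts for h in hists], axis=0)
    frac = np.divide(overlap, counts, out=np.zeros(len(counts), dtype=float),
                     where=counts > 0)
    return PercentileOverlapHistogram(
        stage=first.stage, wave_type=first.wave_type, bin_edges=first.bin_edges,
        overlap_fraction=frac, counts=counts, overlap_counts=overlap,
        n_epochs=sum(h.n_epochs for h in hists),
    )


def enrichment(hist: PercentileOverlapHistogram, top_percent: float) -> float:
    """Overlap within the top percentile bins relative to overall prevalence.

    1.0 means the CAM is uninformative about wave location; an indicator CAM
    that marks exactly the wave intervals reaches 1/prevalence.
    """
    sel = hist.bin_edges[1:] <= top_percent + 1e-9
    if not sel.any():
        raise ValueError(f"top_percent {top_percent} smaller than one bin")
    prev = hist.prevalence
    if prev == 0.0:
        raise ZeroPrevalence(f"wave {hist.wave_type!r} never occurs in scored points")
    top_counts = hist.counts[sel].sum()
    if top_counts == 0:
        return 0.0
    top_frac = hist.overlap_counts[sel].sum() / top_counts
    return float(top_frac / prev)


@dataclass
class HighlightedInterval:
    """One half-second sub-interval with its CAM value and wave overlaps."""

    start_s: float
    end_s: float
    cam_value: float
    overlapping_waves: list[str] = field(default_factory=list)


@dataclass
class ReasoningReport:
    """Top-k CAM sub-intervals of one epoch, with any annotated waves."""

    epoch_index: int
    predicted_stage: str
    intervals: list[HighlightedInterval]
    cam_bins: np.ndarray  # full (5, 60) binned CAM for inspection

    def as_dict(self) -> dict:
        return {
            "epoch_index": self.epoch_index,
            "predicted_stage": self.predicted_stage,
            "intervals": [
                {
                    "start_s": iv.start_s, "end_s": iv.end_s,
                    "cam_value": iv.cam_value,
                    "overlapping_waves": iv.overlapping_waves,
                }
                for iv in self.intervals
            ],
        }


def reasoning_report(
    epoch_index: int,
    cam: CamOutput,
    waves: WaveAnnotationSet | None = None,
    k: int = 5,
) -> ReasoningReport:
    """List the k half-second sub-intervals with the highest CAM values for
    the predicted stage, each with overlapping annotations (if provided)."""
    stage = predict_stage(cam)
    bins = cam_to_half_second_bins(cam)
    row = bins[_STAGE_IDX[stage]]
    order = np.argsort(-row, kind="stable")[: max(0, k)]
    start0 = epoch_index * 30.0
    intervals = []
    for b in order:
        lo, hi = start0 + b * 0.5, start0 + (b + 1) * 0.5
        names: list[str] = []
        if waves is not None:
            names = sorted({e.wave_type for e in waves.overlapping(lo, hi)})
        intervals.append(HighlightedInterval(
            start_s=lo, end_s=hi, cam_value=float(row[b]), overlapping_waves=names,
        ))
    return ReasoningReport(
        epoch_index=epoch_index, predicted_stage=stage,
        intervals=intervals, cam_bins=bins,
    )
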