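"""Frame- and segment-level performance metrics for syllable segmentations.

Evaluation is carried out at the resolution of one spectrogram step
(32 samples at 48 kHz, ~0.67 ms): each frame is positive when its midpoint
falls inside a syllable interval, and whether a frame is predicted correctly
determines accuracy, precision, recall, and F-score.  The segment error
rate compares syllable counts: (predicted - observed) / observed, with an
absolute variant agnostic to the direction of the miscount.

Predicted tracks are post-filtered before scoring: syllables shorter than
0.02 s — the shortest syllable observed in annotated song — are discarded.

Undefined ratios (zero denominators) propagate as NaN and are excluded from
aggregation, never coerced to 0 or 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .audio import FRAME_DUR_S
from .segments import SegmentationTrack

__all__ = [
    "FrameLabels",
    "EvalResult",
    "SpeciesSummary",
    "filter_min_duration",
    "rasterize",
    "frame_confusion",
    "frame_metrics",
    "segment_error_rate",
    "evaluate_pair",
    "aggregate_species",
    "METRIC_NAMES",
]

METRIC_NAMES = ("accuracy", "precision", "recall", "f_score", "ser_signed", "ser_abs")


@dataclass
class FrameLabels:
    """Boolean per-frame syllable labels at a fixed frame duration."""

    frame_dur_s: float
    labels: np.ndarray

    def __post_init__(self) -> None:
        if self.frame_dur_s <= 0:
            raise ValueError("frame_dur_s must be positive")
        self.labels = np.asarray(self.labels, dtype=bool)

    @property
    def n_frames(self) -> int:
        return self.labels.size


@dataclass
class EvalResult:
    """Confusion counts and derived metrics for one (true, predicted) pair."""

    tp: int
    fp: int
    fn: int
    tn: int
    accuracy: float
    precision: float
    recall: float
    f_score: float
    n_true: int
    n_pred: int
    ser_signed: float
    ser_abs: float

    @classmethod
    def from_counts(cls, tp: int, fp: int, fn: int, tn: int, n_true: int, n_pred: int) -> "EvalResult":
        acc, prec, rec, f = frame_metrics(tp, fp, fn, tn)
        ser_signed, ser_abs = segment_error_rate(n_pred, n_true)
        return cls(tp, fp, fn, tn, acc, prec, rec, f, n_true, n_pred, ser_signed, ser_abs)

    def metrics(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


@dataclass
class SpeciesSummary:
    """Per-species roll-up: pooled counts plus across-recording mean and sd."""

    pooled: EvalResult
    per_recording_mean: dict[str, float]
    per_recording_sd: dict[str, float] | None
    n_recordings: int


def filter_min_duration(
    track: SegmentationTrack, min_dur_s: float = 0.02
) -> SegmentationTrack:
    """Drop predicted syllables strictly shorter than ``min_dur_s``."""
    kept = [s for s in track.segments if s.duration_s >= min_dur_s]
    return replace(track, segments=kept)


def rasterize(
    track: SegmentationTrack, frame_dur_s: float = FRAME_DUR_S, n_frames: int | None = None
) -> FrameLabels:
    """Midpoint-rule rasterization: frame ``i`` is positive iff its midpoint
    ``(i + 0.5) * frame_dur_s`` lies in some segment ``[onset, offset)``.

    The midpoint rule is deterministic and unbiased; a boundary moves at most
    one frame's worth of labeled time.
    """
    if n_frames is None:
        n_frames = int(track.duration_s / frame_dur_s + 1e-9)
    if n_frames <= 0:
        raise ValueError("n_frames must be positive")
    mids = (np.arange(n_frames) + 0.5) * frame_dur_s
    labels = np.zeros(n_frames, dtype=bool)
    if track.segments:
        onsets = np.array([s.onset_s for s in track.segments])
        offsets = np.array([s.offset_s for s in track.segments])
        idx = np.searchsorted(onsets, mids, side="right") - 1
        valid = idx >= 0
        labels[valid] = mids[valid] < offsets[idx[valid]]
    return FrameLabels(frame_dur_s=frame_dur_s, labels=labels)


def frame_confusion(
    true_labels: FrameLabels, pred_labels: FrameLabels
) -> tuple[int, int, int, int]:
    """Elementwise 2x2 confusion counts (tp, fp, fn, tn)."""
    if true_labels.n_frames != pred_labels.n_frames:
        raise ValueError(
            f"frame count mismatch: {true_labels.n_frames} vs {pred_labels.n_frames}"
        )
    if not math.isclose(true_labels.frame_dur_s, pred_labels.frame_dur_s):
        raise ValueError("frame durations differ")
    t, p = true_labels.labels, pred_labels.labels
    tp = int(np.sum(t & p))
    fp = int(np.sum(~t & p))
    fn = int(np.sum(t & ~p))
    tn = int(np.sum(~t & ~p))
    return tp, fp, fn, tn


def frame_metrics(tp: int, fp: int, fn: int, tn: int) -> tuple[float, float, float, float]:
    """Accuracy, precision, recall, and F-score (harmonic mean) from counts.

    Ratios with zero denominators are returned as NaN.
    """
    total = tp + fp + fn + tn
    if total <= 0:
        raise ValueError("no frames to evaluate")
    if min(tp, fp, fn, tn) < 0:
        raise ValueError("negative confusion counts")
    accuracy = (tp + tn) / total
    precision = tp / (tp + fp) if (tp + fp) > 0 else math.nan
    recall = tp / (tp + fn) if (tp + fn) > 0 else math.nan
    if math.isnan(precision) or math.isnan(recall) or (precision + recall) == 0:
        f = math.nan
    else:
        f = 2 * precision * recall / (precision + recall)
    return accuracy, precision, recall, f


def segment_error_rate(n_pred: int, n_true: int) -> tuple[float, float]:
    """(predicted - observed)/observed syllable counts, signed and absolute."""
    if n_true < 0 or n_pred < 0:
        raise ValueError("segment counts must be non-negative")
    if n_true == 0:
        return math.nan, math.nan
    signed = (n_pred - n_true) / n_true
    return signed, abs(signed)


def evaluate_pair(
    true_track: SegmentationTrack,
    pred_track: SegmentationTrack,
    frame_dur_s: float = FRAME_DUR_S,
    min_dur_s: float = 0.02,
) -> EvalResult:
    """Score one predicted segmentation against its manual annotation.

    The minimum-duration filter applies to the predicted track only; both
    tracks are then rasterized on a common frame grid.
    """
    if abs(true_track.duration_s - pred_track.duration_s) > frame_dur_s:
        raise ValueError(
            f"duration mismatch: {true_track.duration_s} vs {pred_track.duration_s}"
        )
    pred = filter_min_duration(pred_track, min_dur_s=min_dur_s)
    n_frames = int(true_track.duration_s / frame_dur_s + 1e-9)
    t = rasterize(true_track, frame_dur_s, n_frames)
    p = rasterize(pred, frame_dur_s, n_frames)
    tp, fp, fn, tn = frame_confusion(t, p)
    return EvalResult.from_counts(tp, fp, fn, tn, len(true_track.segments), len(pred.segments))


def aggregate_species(results: list[EvalResult]) -> SpeciesSummary:
    """Pool confusion/segment counts across recordings and summarize spread.

    The pooled estimate recomputes every metric from summed counts (so pooled
    accuracy is the duration-weighted mean of per-recording accuracies); the
    across-recording mean and sample sd (n-1 denominator) skip NaN values.
    With a single recording the sd is reported as absent.
    """
    if not results:
        raise ValueError("no results to aggregate")
    pooled = EvalResult.from_counts(
        tp=sum(r.tp for r in results),
        fp=sum(r.fp for r in results),
        fn=sum(r.fn for r in results),
        tn=sum(r.tn for r in results),
        n_true=sum(r.n_true for r in results),
        n_pred=sum(r.n_pred for r in results),
    )
    means: dict[str, float] = {}
    sds: dict[str, float] = {}
    for name in METRIC_NAMES:
        vals = np.array([r.metrics()[name] for r in results], dtype=float)
        vals = vals[~np.isnan(vals)]
        means[name] = float(vals.mean()) if vals.size else math.nan
        sds[name] = float(vals.std(ddof=1)) if vals.size > 1 else math.nan
    sd_out = sds if len(results) > 1 else None
    return SpeciesSummary(
        pooled=pooled,
        per_recording_mean=means,
        per_recording_sd=sd_out,
        n_recordings=len(results),
    )
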