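"""Data model and file formats for syllable segmentations.

A *segmentation* assigns onset/offset times (and optionally a frequency
band) to every syllable in a recording.  Two interchange formats are
supported: Raven selection tables (tab-separated text, the export format
of the Raven sound-analysis program) and a birdsong-recognition-dataset
style XML dialect in which positions are encoded in samples.

Intervals use half-open semantics ``[onset, offset)``: abutting segments
do not overlap.  All times in the data model are seconds.
"""

from __future__ import annotations

import io
import math
import os
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace

import pandas as pd

__all__ = [
    "Segment",
    "SegmentationTrack",
    "FormatError",
    "TrackValidationError",
    "read_raven_selection_table",
    "write_raven_selection_table",
    "read_birdsong_xml",
    "write_birdsong_xml",
    "validate_track",
]

RAVEN_BEGIN = "Begin Time (s)"
RAVEN_END = "End Time (s)"
RAVEN_LOW = "Low Freq (Hz)"
RAVEN_HIGH = "High Freq (Hz)"


class FormatError(ValueError):
    """A file does not conform to the expected annotation format."""


class TrackValidationError(ValueError):
    """A segmentation violates a structural invariant (order, overlap, bounds)."""


@dataclass(frozen=True)
class Segment:
    """One labeled syllable: a time interval plus an optional frequency box."""

    onset_s: float
    offset_s: float
    low_hz: float | None = None
    high_hz: float | None = None
    label: str = "1"

    def __post_init__(self) -> None:
        if not (self.onset_s < self.offset_s):
            raise TrackValidationError(
                f"segment onset {self.onset_s} must precede offset {self.offset_s}"
            )
        if self.onset_s < 0:
            raise TrackValidationError(f"negative onset {self.onset_s}")
        if (
            self.low_hz is not None
            and self.high_hz is not None
            and not (self.low_hz < self.high_hz)
        ):
            raise TrackValidationError(
                f"low frequency {self.low_hz} must be below high frequency {self.high_hz}"
            )
        if not self.label:
            raise TrackValidationError("segment label must be non-empty")

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


@dataclass
class SegmentationTrack:
    """An ordered set of labeled syllable intervals over one recording.

    ``role`` distinguishes manually annotated ("true") tracks from model
    output ("predicted").  Construction sorts segments by onset and checks
    they fit within ``duration_s``; disjointness is enforced separately by
    :func:`validate_track` so that raw, possibly-overlapping candidates can
    still be represented and repaired.
    """

    recording_id: str
    sample_rate_hz: int
    duration_s: float
    segments: list[Segment] = field(default_factory=list)
    role: str = "true"
    species: str | None = None

    def __post_init__(self) -> None:
        if self.sample_rate_hz <= 0:
            raise TrackValidationError("sample_rate_hz must be positive")
        if self.duration_s <= 0:
            raise TrackValidationError("duration_s must be positive")
        if self.role not in ("true", "predicted"):
            raise TrackValidationError(f"role must be 'true' or 'predicted', got {self.role!r}")
        self.segments = sorted(self.segments, key=lambda s: (s.onset_s, s.offset_s))
        for i, seg in enumerate(self.segments):
            if seg.offset_s > self.duration_s + 1e-9:
                raise TrackValidationError(
                    f"segment {i} offset {seg.offset_s} exceeds duration {self.duration_s}"
                )

    def __len__(self) -> int:
        return len(self.segments)

    @property
    def annotated_seconds(self) -> float:
        """Total syllable time, assuming disjoint segments."""
        return sum(s.duration_s for s in self.segments)

    def overlapping_indices(self) -> list[tuple[int, int]]:
        """Pairs of consecutive segment indices that overlap under [a, b)."""
        out = []
        for i in range(len(self.segments) - 1):
            if self.segments[i + 1].onset_s < self.segments[i].offset_s:
                out.append((i, i + 1))
        return out

    @property
    def is_disjoint(self) -> bool:
        return not self.overlapping_indices()


def validate_track(track: SegmentationTrack, policy: str = "error") -> SegmentationTrack:
    """Check or repair interval disjointness.

    policy="error" raises :class:`TrackValidationError` listing the offending
    indices; policy="merge" fuses overlapping or abutting segments sharing a
    label into one (union interval, union frequency box), preserving total
    annotated duration.  Manual annotation boxes should not overlap, so
    "error" is the default and "merge" is opt-in.
    """
    if policy not in ("error", "merge"):
        raise ValueError(f"unknown policy {policy!r}")
    if policy == "error":
        bad = track.overlapping_indices()
        if bad:
            raise TrackValidationError(f"overlapping segments at index pairs {bad}")
        return track

    merged: list[Segment] = []
    for seg in track.segments:
        if (
            merged
            and seg.label == merged[-1].label
            and seg.onset_s <= merged[-1].offset_s + 1e-12
        ):
            prev = merged[-1]
            lows = [f for f in (prev.low_hz, seg.low_hz) if f is not None]
            highs = [f for f in (prev.high_hz, seg.high_hz) if f is not None]
            merged[-1] = Segment(
                onset_s=prev.onset_s,
                offset_s=max(prev.offset_s, seg.offset_s),
                low_hz=min(lows) if lows else None,
                high_hz=max(highs) if highs else None,
                label=prev.label,
            )
        else:
            merged.append(seg)
    out = replace(track, segments=merged)
    bad = out.overlapping_indices()
    if bad:  # distinct labels cannot be merged away
        raise TrackValidationError(
            f"overlapping segments with different labels at index pairs {bad}"
        )
    return out


# ---------------------------------------------------------------------------
# Raven selection tables
# ---------------------------------------------------------------------------

def _as_text(source: str | os.PathLike) -> str:
    if isinstance(source, os.PathLike):
        return open(source, encoding="utf-8").read()
    if "\n" in source or "\t" in source:
        return source
    return open(source, encoding="utf-8").read()


def read_raven_selection_table(
    source: str | os.PathLike,
    duration_s: float,
    sample_rate_hz: int,
    recording_id: str = "",
    role: str = "true",
    species: str | None = None,
) -> SegmentationTrack:
    """Parse a Raven selection table (tab-separated, header row) into a track.

    Requires the "Begin Time (s)" and "End Time (s)" columns of Raven's
    default export dialect; "Low Freq (Hz)" / "High Freq (Hz)" are attached
    when present and any other columns are ignored.
    """
    text = _as_text(source)
    try:
        frame = pd.read_csv(io.StringIO(text), sep="\t", float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise FormatError("empty selection table") from exc
    for col in (RAVEN_BEGIN, RAVEN_END):
        if col not in frame.columns:
            raise FormatError(f"selection table is missing required column {col!r}")
    segments = []
    for i in range(len(frame)):
        begin = float(frame[RAVEN_BEGIN].iloc[i])
        end = float(frame[RAVEN_END].iloc[i])
        if end <= begin:
            raise TrackValidationError(
                f"row {i + 1}: End Time {end} is not after Begin Time {begin}"
            )
        low = high = None
        if RAVEN_LOW in frame.columns and pd.notna(frame[RAVEN_LOW].iloc[i]):
            low = float(frame[RAVEN_LOW].iloc[i])
        if RAVEN_HIGH in frame.columns and pd.notna(frame[RAVEN_HIGH].iloc[i]):
            high = float(frame[RAVEN_HIGH].iloc[i])
        label = "1"
        if "Annotation" in frame.columns and pd.notna(frame["Annotation"].iloc[i]):
            label = str(frame["Annotation"].iloc[i])
        segments.append(Segment(begin, end, low, high, label))
    return SegmentationTrack(
        recording_id=recording_id,
        sample_rate_hz=sample_rate_hz,
        duration_s=duration_s,
        segments=segments,
        role=role,
        species=species,
    )


def write_raven_selection_table(track: SegmentationTrack) -> str:
    """Serialize a track as a Raven selection table; inverse of the reader."""
    cols = [
        "Selection", "View", "Channel",
        RAVEN_BEGIN, RAVEN_END, RAVEN_LOW, RAVEN_HIGH, "Annotation",
    ]
    lines = ["\t".join(cols)]
    for i, seg in enumerate(track.segments, start=1):
        lines.append(
            "\t".join(
                [
                    str(i),
                    "Spectrogram 1",
                    "1",
                    repr(seg.onset_s),
                    repr(seg.offset_s),
                    "" if seg.low_hz is None else repr(seg.low_hz),
                    "" if seg.high_hz is None else repr(seg.high_hz),
                    seg.label,
                ]
            )
        )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# birdsong-recognition-dataset style XML
# ---------------------------------------------------------------------------

def write_birdsong_xml(track: SegmentationTrack) -> str:
    """Serialize a track as XML with per-syllable positions in samples.

    One ``<Sequence>`` element per recording; each ``<Note>`` carries its
    position and length in samples (seconds times the sample rate, rounded
    to nearest, so the symmetric error is at most half a sample) and its
    label.  The sample rate is embedded so the file is self-describing.
    """
    sr = track.sample_rate_hz
    root = ET.Element("Sequences")
    seq = ET.SubElement(root, "Sequence")
    ET.SubElement(seq, "WaveFileName").text = f"{track.recording_id}.wav"
    ET.SubElement(seq, "SampleRate").text = str(sr)
    ET.SubElement(seq, "Position").text = "0"
    ET.SubElement(seq, "Length").text = str(round(track.duration_s * sr))
    ET.SubElement(seq, "NumNote").text = str(len(track.segments))
    for seg in track.segments:
        if seg.offset_s > track.duration_s + 1e-9:
            raise TrackValidationError(
                f"segment offset {seg.offset_s} beyond duration {track.duration_s}"
            )
        pos = round(seg.onset_s * sr)
        length = max(1, round(seg.offset_s * sr) - pos)
        note = ET.SubElement(seq, "Note")
        ET.SubElement(note, "Position").text = str(pos)
        ET.SubElement(note, "Length").text = str(length)
        ET.SubElement(note, "Label").text = seg.label
    return ET.tostring(root, encoding="unicode")


def read_birdsong_xml(text: str, role: str = "true") -> SegmentationTrack:
    """Parse the XML dialect emitted by :func:`write_birdsong_xml`."""
    try:
        root = ET.fromstring(text)
    except ET.ParseError as exc:
        raise FormatError(f"malformed XML: {exc}") from exc
    seq = root.find("Sequence")
    if seq is None:
        raise FormatError("no <Sequence> element found")
    sr = int(seq.findtext("SampleRate", default="48000"))
    n_samples = int(seq.findtext("Length", default="0"))
    name = seq.findtext("WaveFileName", default="recording.wav")
    recording_id = name[:-4] if name.endswith(".wav") else name
    segments = []
    for note in seq.iter("Note"):
        pos = int(note.findtext("Position"))
        length = int(note.findtext("Length"))
        if length <= 0:
            raise TrackValidationError(f"note at sample {pos} has non-positive length {length}")
        label = note.findtext("Label", default="1")
        segments.append(Segment(pos / sr, (pos + length) / sr, label=label))
    track = SegmentationTrack(
        recording_id=recording_id,
        sample_rate_hz=sr,
        duration_s=n_samples / sr if n_samples else max(s.offset_s for s in segments),
        segments=segments,
        role=role,
    )
    return validate_track(track, policy="error")
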