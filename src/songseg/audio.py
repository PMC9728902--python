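"""Audio standardization, spectrograms, and annotation-balanced slicing.

Recordings are standardized to mono 48 kHz.  Spectrograms use a 512-sample
FFT with a 32-sample step (~0.67 ms), a 500–15,000 Hz band, a log transform
with a minimum power-log floor of 6.25 to suppress background noise, and
per-spectrogram z-scoring — the configuration under which segmentation
models in this pipeline are evaluated.

Slicing rebalances long recordings so that roughly half of every emitted
slice is annotated song: syllable clusters separated by at least ``gap_s``
of silence are split apart, and each cluster is padded with neighboring
silence up to the target annotated fraction.  Whole files with long silent
stretches otherwise teach a segmenter to predict silence everywhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import NamedTuple

import numpy as np
from scipy import signal
from scipy.io import wavfile

from .segments import Segment, SegmentationTrack, write_raven_selection_table

__all__ = [
    "TARGET_RATE_HZ",
    "FRAME_DUR_S",
    "SpectrogramConfig",
    "Spectrogram",
    "SliceWindow",
    "standardize_audio",
    "compute_spectrogram",
    "cluster_annotations",
    "slice_recording",
    "balance_by_species",
    "read_wav",
    "write_wav",
    "export_slices",
]

TARGET_RATE_HZ = 48_000
#: evaluation frame: one spectrogram step at the standard rate (~0.67 ms)
FRAME_DUR_S = 32 / 48_000


@dataclass(frozen=True)
class SpectrogramConfig:
    nfft: int = 512
    step: int = 32
    fmin_hz: float = 500.0
    fmax_hz: float = 15_000.0
    log_transform: bool = True
    min_power_log: float | None = 6.25
    normalize: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.step <= self.nfft):
            raise ValueError(f"require 0 < step <= nfft, got step={self.step}, nfft={self.nfft}")
        if not (self.fmin_hz < self.fmax_hz):
            raise ValueError("fmin_hz must be below fmax_hz")


@dataclass
class Spectrogram:
    frame_times_s: np.ndarray
    freqs_hz: np.ndarray
    logpower: np.ndarray  # (freq, time)
    config: SpectrogramConfig

    @property
    def n_frames(self) -> int:
        return self.logpower.shape[1]


def standardize_audio(
    wave: np.ndarray, sample_rate_hz: int, target_hz: int = TARGET_RATE_HZ
) -> tuple[np.ndarray, int]:
    """Convert to mono (channel mean) and resample to ``target_hz``.

    Accepts 1-D arrays or 2-D arrays with up to two channels on either axis.
    Resampling is polyphase band-limited; duration is preserved to within
    one output sample.
    """
    wave = np.asarray(wave, dtype=np.float64)
    if wave.size == 0:
        raise ValueError("empty signal")
    if wave.ndim == 2:
        ch_axis = 0 if wave.shape[0] <= wave.shape[1] else 1
        n_ch = wave.shape[ch_axis]
        if n_ch > 2:
            raise ValueError(f"expected mono or stereo, got {n_ch} channels")
        wave = wave.mean(axis=ch_axis)
    elif wave.ndim != 1:
        raise ValueError(f"expected 1-D or 2-D samples, got {wave.ndim}-D")
    if sample_rate_hz == target_hz:
        return wave, target_hz
    g = math.gcd(int(target_hz), int(sample_rate_hz))
    out = signal.resample_poly(wave, target_hz // g, sample_rate_hz // g)
    return out, target_hz


def compute_spectrogram(
    wave: np.ndarray,
    config: SpectrogramConfig | None = None,
    sample_rate_hz: int = TARGET_RATE_HZ,
) -> Spectrogram:
    """Short-time power spectrum on non-padded frames.

    Frame ``i`` covers samples ``[i*step, i*step + nfft)`` and is stamped at
    the window center; the frame count is exactly
    ``floor((n_samples - nfft)/step) + 1``.  Power is log-transformed, floored
    at ``min_power_log`` (log-domain threshold), restricted to the configured
    band, and z-scored over the whole matrix unless it is constant.
    """
    cfg = config or SpectrogramConfig()
    wave = np.asarray(wave, dtype=np.float64)
    if wave.ndim != 1:
        raise ValueError("expected standardized mono audio")
    if wave.size < cfg.nfft:
        raise ValueError(f"signal length {wave.size} shorter than nfft {cfg.nfft}")
    freqs, times, power = signal.spectrogram(
        wave,
        fs=sample_rate_hz,
        window="hann",
        nperseg=cfg.nfft,
        noverlap=cfg.nfft - cfg.step,
        detrend=False,
        scaling="spectrum",
        mode="psd",
    )
    if cfg.log_transform:
        with np.errstate(divide="ignore"):
            power = np.log(power)
    if cfg.min_power_log is not None:
        power = np.maximum(power, cfg.min_power_log)
    band = (freqs >= cfg.fmin_hz) & (freqs <= cfg.fmax_hz)
    power = power[band]
    freqs = freqs[band]
    if cfg.normalize:
        sd = power.std()
        if sd > 0:  # constant input: z-scoring undefined, leave as is
            power = (power - power.mean()) / sd
    return Spectrogram(frame_times_s=times, freqs_hz=freqs, logpower=power, config=cfg)


def cluster_annotations(
    track: SegmentationTrack, gap_s: float = 1.0
) -> list[tuple[int, int]]:
    """Group consecutive segments separated by silence shorter than ``gap_s``.

    Returns half-open index ranges ``(start, stop)`` into ``track.segments``.
    The gap comparison is strict: silence of exactly ``gap_s`` ("at least"
    one second of non-annotated sound) splits clusters.
    """
    if not track.segments:
        return []
    clusters = []
    start = 0
    for i in range(1, len(track.segments)):
        gap = track.segments[i].onset_s - track.segments[i - 1].offset_s
        if gap >= gap_s:
            clusters.append((start, i))
            start = i
    clusters.append((start, len(track.segments)))
    return clusters


class SliceWindow(NamedTuple):
    start_s: float
    end_s: float

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def slice_recording(
    track: SegmentationTrack,
    target_fraction: float = 0.5,
    gap_s: float = 1.0,
) -> list[tuple[SliceWindow, SegmentationTrack]]:
    """Cut one slice per syllable cluster, aiming for ``target_fraction`` annotated.

    Each cluster (see :func:`cluster_annotations`) is atomic: the slice fully
    contains it and is never shorter than its extent, so intra-cluster silence
    can push the annotated fraction below the target.  Silence padding of
    ``max(span, A/target_fraction) - span`` seconds is split symmetrically,
    clipped at the file boundaries and at half the silence gap to each
    neighboring cluster (keeping slices disjoint), with unused allowance
    reassigned to the other side.  Returned tracks use slice-local times.
    """
    if not (0 < target_fraction <= 1):
        raise ValueError("target_fraction must be in (0, 1]")
    clusters = cluster_annotations(track, gap_s=gap_s)
    out: list[tuple[SliceWindow, SegmentationTrack]] = []
    for idx, (a, b) in enumerate(clusters):
        segs = track.segments[a:b]
        first, last = segs[0], segs[-1]
        span = last.offset_s - first.onset_s
        annotated = sum(s.duration_s for s in segs)
        target_dur = max(span, annotated / target_fraction)
        pad = target_dur - span
        # left/right expansion limits: file edge or midpoint of inter-cluster gap
        if a == 0:
            left_limit = 0.0
        else:
            prev_off = track.segments[a - 1].offset_s
            left_limit = prev_off + (first.onset_s - prev_off) / 2
        if b == len(track.segments):
            right_limit = track.duration_s
        else:
            next_on = track.segments[b].onset_s
            right_limit = last.offset_s + (next_on - last.offset_s) / 2
        avail_left = first.onset_s - left_limit
        avail_right = right_limit - last.offset_s
        pad_left = min(pad / 2, avail_left)
        pad_right = min(pad - pad_left, avail_right)
        pad_left = min(pad - pad_right, avail_left)
        start = first.onset_s - pad_left
        end = last.offset_s + pad_right
        local = [
            replace(s, onset_s=s.onset_s - start, offset_s=s.offset_s - start)
            for s in segs
        ]
        window = SliceWindow(start, end)
        out.append(
            (
                window,
                SegmentationTrack(
                    recording_id=f"{track.recording_id}__s{idx}",
                    sample_rate_hz=track.sample_rate_hz,
                    duration_s=window.duration_s,
                    segments=local,
                    role=track.role,
                    species=track.species,
                ),
            )
        )
    return out


def balance_by_species(
    tracks_by_species: dict[str, list[SegmentationTrack]],
    seed: int | None = None,
) -> dict[str, list[SegmentationTrack]]:
    """Equalize per-species data (in seconds) down to the smallest species.

    Greedily accumulates slices in a seeded random order until each species'
    total duration first reaches the minimum species total, so every selected
    total is within one slice-duration of that minimum.  Mitigates sampling
    bias when a multi-species training set is dominated by one taxon.
    """
    if not tracks_by_species:
        raise ValueError("no species given")
    for sp, tracks in tracks_by_species.items():
        if not tracks:
            raise ValueError(f"species {sp!r} has no slices")
    totals = {sp: sum(t.duration_s for t in ts) for sp, ts in tracks_by_species.items()}
    floor = min(totals.values())
    rng = np.random.default_rng(seed)
    selected: dict[str, list[SegmentationTrack]] = {}
    for sp in sorted(tracks_by_species):
        tracks = list(tracks_by_species[sp])
        order = rng.permutation(len(tracks))
        chosen, total = [], 0.0
        for j in order:
            if total >= floor - 1e-9:
                break
            chosen.append(tracks[j])
            total += tracks[j].duration_s
        selected[sp] = chosen
    return selected


# ---------------------------------------------------------------------------
# WAV helpers
# ---------------------------------------------------------------------------

def read_wav(path: str | Path) -> tuple[np.ndarray, int]:
    """Read a PCM or float WAV as float64 in [-1, 1]."""
    sr, data = wavfile.read(path)
    data = np.asarray(data)
    if data.dtype == np.int16:
        data = data / 32768.0
    elif data.dtype == np.int32:
        data = data / 2147483648.0
    elif data.dtype == np.uint8:
        data = (data.astype(np.float64) - 128.0) / 128.0
    return data.astype(np.float64), int(sr)


def write_wav(path: str | Path, wave: np.ndarray, sample_rate_hz: int = TARGET_RATE_HZ) -> None:
    """Write mono float audio as 16-bit PCM, clipping to [-1, 1]."""
    pcm = np.clip(np.asarray(wave, dtype=np.float64), -1.0, 1.0)
    wavfile.write(path, sample_rate_hz, (pcm * 32767).astype(np.int16))


def export_slices(
    wave: np.ndarray,
    sample_rate_hz: int,
    track: SegmentationTrack,
    out_dir: str | Path,
    target_fraction: float = 0.5,
    gap_s: float = 1.0,
) -> list[Path]:
    """Write ``<recording_id>__sN.wav`` slices with selection-table sidecars."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for window, local in slice_recording(track, target_fraction=target_fraction, gap_s=gap_s):
        i0 = int(round(window.start_s * sample_rate_hz))
        i1 = int(round(window.end_s * sample_rate_hz))
        wav_path = out_dir / f"{local.recording_id}.wav"
        write_wav(wav_path, wave[i0:i1], sample_rate_hz)
        (out_dir / f"{local.recording_id}.selections.txt").write_text(
            write_raven_selection_table(local)
        )
        paths.append(wav_path)
    return paths
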