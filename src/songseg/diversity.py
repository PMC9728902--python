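"""Song-diversity statistics from syllable spectrogram shapes.

Each syllable is reduced to a 500-dimensional shape vector: its log-power
surface is bilinearly resampled onto a fixed 25 (time) x 20 (frequency)
grid, with time normalized over the syllable's duration and frequency over
the analysis band, then min-max scaled to [0, 1].  Pooled shape vectors are
projected by PCA, retaining the smallest number of leading components that
explain at least half of the variance, and a species' diversity is its
*pseudo-hypervolume*: the product of the per-component sample standard
deviations of its syllables' scores.  The product-of-SDs proxy tracks the
formal convex-hull volume (which is computationally prohibitive beyond a
handful of dimensions) while remaining cheap in ~20 dimensions; the hull
oracle here makes that agreement testable up to 7 components.

Resampling draws 50 syllables per species, repeats the PCA + hypervolume
computation 50 times, and max-normalizes each repetition so the most
diverse species scores 1.0; the per-species mean and sd across repetitions
are the diversity metric.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.spatial import ConvexHull, QhullError
from sklearn.decomposition import PCA

from .audio import Spectrogram
from .segments import SegmentationTrack

__all__ = [
    "N_TIME",
    "N_FREQ",
    "SyllableShapeMatrix",
    "HypervolumeResult",
    "featurize_syllable",
    "extract_shape_matrix",
    "pca_retain",
    "pseudo_hypervolume",
    "relative_normalize",
    "resampled_hypervolumes",
    "hull_volume_oracle",
]

N_TIME = 25
N_FREQ = 20
N_FEATURES = N_TIME * N_FREQ  # 500


@dataclass
class SyllableShapeMatrix:
    """Per-syllable 500-dimensional shape vectors with species labels."""

    features: np.ndarray  # (n_syllables, 500)
    species: np.ndarray
    syllable_ids: np.ndarray

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.species = np.asarray(self.species)
        self.syllable_ids = np.asarray(self.syllable_ids)
        if self.features.ndim != 2 or self.features.shape[1] != N_FEATURES:
            raise ValueError(f"features must be (n, {N_FEATURES})")
        if np.isnan(self.features).any():
            raise ValueError("features contain missing values")
        if len(self.species) != len(self.features) or len(self.syllable_ids) != len(self.features):
            raise ValueError("species / syllable_ids length mismatch")

    @property
    def species_names(self) -> list[str]:
        return sorted(set(self.species.tolist()))


@dataclass
class HypervolumeResult:
    """Relative pseudo-hypervolume mean/sd per species over resampling reps."""

    mean: dict[str, float]
    sd: dict[str, float]
    retained_pcs_per_rep: list[int]
    reps: int
    n_per_species: int
    seed: int | None


def featurize_syllable(patch: np.ndarray) -> np.ndarray:
    """Resample one syllable's log-power patch onto the fixed 25x20 grid.

    ``patch`` is (freq, time).  Both axes are normalized to [0, 1] (time
    over the syllable's duration, so duration is removed from the shape)
    and interpolated bilinearly; the result is flattened time-major to a
    length-500 vector and min-max scaled to [0, 1].  A constant-amplitude
    patch scales degenerately to the zero vector.
    """
    patch = np.asarray(patch, dtype=float)
    if patch.ndim != 2 or patch.shape[0] < 2 or patch.shape[1] < 2:
        raise ValueError(f"patch must be at least 2x2 (freq x time), got {patch.shape}")
    f_axis = np.linspace(0.0, 1.0, patch.shape[0])
    t_axis = np.linspace(0.0, 1.0, patch.shape[1])
    interp = RegularGridInterpolator((f_axis, t_axis), patch, method="linear")
    tq = np.linspace(0.0, 1.0, N_TIME)
    fq = np.linspace(0.0, 1.0, N_FREQ)
    tt, ff = np.meshgrid(tq, fq, indexing="ij")  # (25, 20), time-major
    grid = interp(np.column_stack([ff.ravel(), tt.ravel()])).reshape(N_TIME, N_FREQ)
    lo, hi = grid.min(), grid.max()
    if hi - lo > 1e-9 * max(abs(hi), abs(lo), 1.0):
        grid = (grid - lo) / (hi - lo)
    else:
        grid = np.zeros_like(grid)
    return grid.ravel()


def extract_shape_matrix(
    pairs: list[tuple[Spectrogram, SegmentationTrack]],
) -> SyllableShapeMatrix:
    """Featurize every syllable of annotated (spectrogram, track) pairs.

    The patch for a syllable spans its ``[onset, offset)`` frames and its
    frequency box when present (whole analysis band otherwise).  Syllables
    too short or too narrow-band to yield a 2x2 patch are skipped.
    """
    feats, species, ids = [], [], []
    for spect, track in pairs:
        for j, seg in enumerate(track.segments):
            tmask = (spect.frame_times_s >= seg.onset_s) & (spect.frame_times_s < seg.offset_s)
            lo = seg.low_hz if seg.low_hz is not None else spect.freqs_hz[0]
            hi = seg.high_hz if seg.high_hz is not None else spect.freqs_hz[-1]
            fmask = (spect.freqs_hz >= lo) & (spect.freqs_hz <= hi)
            patch = spect.logpower[np.ix_(fmask, tmask)]
            if patch.shape[0] < 2 or patch.shape[1] < 2:
                continue
            feats.append(featurize_syllable(patch))
            species.append(track.species or "unknown")
            ids.append(f"{track.recording_id}:{j}")
    if not feats:
        raise ValueError("no syllables could be featurized")
    return SyllableShapeMatrix(np.array(feats), np.array(species), np.array(ids))


def pca_retain(
    features: np.ndarray, variance_threshold: float = 0.5
) -> tuple[np.ndarray, int]:
    """Project onto the smallest set of leading PCs explaining the threshold.

    Covariance-based PCA on centered, unscaled features (the features share
    units).  Returns the n x k score matrix and k.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least two rows for PCA")
    if not (0 < variance_threshold <= 1):
        raise ValueError("variance_threshold must be in (0, 1]")
    if np.allclose(X.var(axis=0), 0):
        raise ValueError("zero total variance: PCA undefined")
    pca = PCA()
    scores = pca.fit_transform(X)
    cum = np.cumsum(pca.explained_variance_ratio_)
    k = int(np.searchsorted(cum, variance_threshold - 1e-12) + 1)
    return scores[:, :k], k


def pseudo_hypervolume(scores: np.ndarray, k: int | None = None) -> float:
    """Product over retained components of the sample sd (n-1 denominator).

    Returns NaN for fewer than two points (the statistic is undefined).
    """
    S = np.asarray(scores, dtype=float)
    if S.ndim == 1:
        S = S[:, None]
    if k is not None:
        if k < 1:
            raise ValueError("k must be >= 1")
        S = S[:, :k]
    if S.shape[0] < 2:
        return math.nan
    return float(np.prod(S.std(axis=0, ddof=1)))


def relative_normalize(values: dict[str, float]) -> dict[str, float]:
    """Divide by the maximum so the most diverse species scores 1.0."""
    if not values:
        raise ValueError("no values to normalize")
    top = max(values.values())
    if not (top > 0):
        raise ValueError(f"non-positive maximum {top}: cannot normalize")
    return {k: v / top for k, v in values.items()}


def resampled_hypervolumes(
    shapes: SyllableShapeMatrix,
    reps: int = 50,
    n_per_species: int = 50,
    variance_threshold: float = 0.5,
    seed: int | None = None,
) -> HypervolumeResult:
    """Resampled relative pseudo-hypervolume per species.

    Per repetition: draw ``n_per_species`` syllables per species (without
    replacement when that many are available, with replacement otherwise),
    pool them, run the retained-variance PCA, compute each species'
    pseudo-hypervolume on its own scores, and max-normalize.  Sampling
    operates on rows sorted by syllable id, so input order is irrelevant
    under a fixed seed.
    """
    names = shapes.species_names
    rows_by_species: dict[str, np.ndarray] = {}
    for sp in names:
        rows = np.flatnonzero(shapes.species == sp)
        rows = rows[np.argsort(shapes.syllable_ids[rows].astype(str))]
        if rows.size < 2:
            raise ValueError(f"species {sp!r} has fewer than 2 syllables")
        rows_by_species[sp] = rows
    rng = np.random.default_rng(seed)
    rel = {sp: np.empty(reps) for sp in names}
    ks: list[int] = []
    for r in range(reps):
        chosen, labels = [], []
        for sp in names:
            rows = rows_by_species[sp]
            replace_draw = rows.size < n_per_species
            pick = rng.choice(rows.size, size=n_per_species, replace=replace_draw)
            chosen.append(rows[pick])
            labels.extend([sp] * pick.size)
        pooled = shapes.features[np.concatenate(chosen)]
        labels = np.array(labels)
        scores, k = pca_retain(pooled, variance_threshold)
        ks.append(k)
        raw = {sp: pseudo_hypervolume(scores[labels == sp], k) for sp in names}
        normed = relative_normalize(raw)
        for sp in names:
            rel[sp][r] = normed[sp]
    mean = {sp: float(rel[sp].mean()) for sp in names}
    sd = {sp: float(rel[sp].std(ddof=1)) if reps > 1 else math.nan for sp in names}
    return HypervolumeResult(
        mean=mean, sd=sd, retained_pcs_per_rep=ks,
        reps=reps, n_per_species=n_per_species, seed=seed,
    )


def hull_volume_oracle(points: np.ndarray, max_dim: int = 7) -> float:
    """Exact convex-hull volume, the formal hypervolume the proxy stands for.

    Restricted to at most ``max_dim`` dimensions (hull volume cost explodes
    with dimension, which is why the product-of-SDs proxy exists).  A
    degenerate point set signals zero volume.
    """
    P = np.asarray(points, dtype=float)
    if P.ndim != 2:
        raise ValueError("points must be 2-D (n, d)")
    d = P.shape[1]
    if d > max_dim:
        raise ValueError(f"dimension {d} exceeds hull oracle limit {max_dim}")
    if P.shape[0] < d + 1:
        raise ValueError(f"need at least {d + 1} points in {d}-D")
    try:
        return float(ConvexHull(P).volume)
    except QhullError:
        return 0.0
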