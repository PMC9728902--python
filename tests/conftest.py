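import numpy as np
import pytest

from songseg import Segment, SegmentationTrack


def random_track(
    rng: np.random.Generator,
    duration_s: float = 10.0,
    n_segments: int = 8,
    role: str = "true",
    min_len: float = 1e-3,
) -> SegmentationTrack:
    """Sorted, disjoint random segmentation for property tests."""
    cuts = np.sort(rng.uniform(0, duration_s, 2 * n_segments))
    segs = [
        Segment(float(cuts[2 * i]), float(cuts[2 * i + 1]))
        for i in range(n_segments)
        if cuts[2 * i + 1] - cuts[2 * i] >= min_len
    ]
    return SegmentationTrack("rand", 48_000, duration_s, segs, role=role)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260920)


@pytest.fixture
def simple_track() -> SegmentationTrack:
    return SegmentationTrack(
        "rec1",
        48_000,
        10.0,
        [
            Segment(1.0, 2.0, low_hz=1000.0, high_hz=4000.0),
            Segment(3.0, 4.5),
            Segment(6.0, 6.5, low_hz=2000.0, high_hz=3000.0),
        ],
    )
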