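import numpy as np
import pytest

from gazeseq import pipeline, synthetic_study as ss
from gazeseq.gaze_io import DEFAULT_GEOMETRY, DisplayGeometry

GLOBAL_FRAME = (DEFAULT_GEOMETRY.total_width, DEFAULT_GEOMETRY.height)


@pytest.fixture(scope="session")
def geometry() -> DisplayGeometry:
    return DEFAULT_GEOMETRY


@pytest.fixture(scope="session")
def small_study():
    """One reader, 40 cases split over two sessions; scanpaths attached."""
    readings, cases = ss.generate_study(
        n_readers_per_tier={"N": 0, "A": 1, "E": 0},
        n_cases=40,
        session_breaks={"A1": [20]},
        duration=2.0,
        seed=11,
    )
    return readings, cases


@pytest.fixture(scope="session")
def small_study_frame(small_study):
    """Analysis frame (decision, density, fd) for the small study."""
    readings, cases = small_study
    return pipeline.study_frame(readings, cases, DEFAULT_GEOMETRY, grid_size=256)


def koch_polyline(iterations: int) -> np.ndarray:
    """Vertices of the classic self-similar 1/3-rescaling curve."""
    pts = np.array([[0.0, 0.0], [1.0, 0.0]])
    angle = -np.pi / 3
    rot = np.array(
        [[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]]
    )
    for _ in range(iterations):
        out = []
        for a, b in zip(pts[:-1], pts[1:]):
            step = (b - a) / 3.0
            p1 = a + step
            p3 = a + 2 * step
            p2 = p1 + rot @ step
            out += [a, p1, p2, p3]
        out.append(pts[-1])
        pts = np.array(out)
    return pts
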