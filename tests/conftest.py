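import numpy as np
import pytest

from sternomet import phantom as ph
from sternomet.segmentation import Chain, trace_contours


@pytest.fixture(scope="session")
def corpus_phantom():
    """Clean corpus phantom at the reference pooled measurements."""
    return ph.render_phantom({"B": 9.46, "CSW1": 2.65, "CSW2": 3.12},
                             spacing=0.05, kind="corpus", seed=1)


@pytest.fixture(scope="session")
def manubrium_phantom():
    return ph.render_phantom({"M": 5.23, "MW": 5.63},
                             spacing=0.05, kind="manubrium", seed=1)


@pytest.fixture(scope="session")
def corrupted_corpus(corpus_phantom):
    image, truth = corpus_phantom
    return ph.corrupt_image(image, truth, ph.CorruptionSpec(seed=5)), truth


def polygon_contour(points, image=None):
    """Build a Contour (with computed features) from a closed polygon."""
    pts = np.asarray(points, dtype=float)
    [contour] = trace_contours([Chain(points=pts, closed=True)], image)
    contour.accepted = True
    return contour


@pytest.fixture
def make_contour():
    return polygon_contour
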