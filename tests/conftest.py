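import numpy as np
import pytest

from endosin import (
    AlgorithmConfig,
    ClassLabel,
    Detection,
    EndoscopyFrame,
    Laterality,
    PolygonMask,
)


def rect_mask(x1, y1, x2, y2):
    return PolygonMask.from_vertices([(x1, y1), (x2, y1), (x2, y2), (x1, y2)])


def rect_detection(label, x1, y1, x2, y2, confidence=0.9):
    return Detection.from_mask(ClassLabel(label), confidence, rect_mask(x1, y1, x2, y2))


@pytest.fixture
def cfg():
    return AlgorithmConfig()


@pytest.fixture
def right_frame():
    """Right-cavity frame with MT, IT and one mucus blob sitting in the MM region."""
    mt = rect_detection("MT", 400, 100, 600, 400)
    it = rect_detection("IT", 380, 500, 650, 700)
    mucus = rect_detection("mucus", 350, 80, 400, 500, confidence=0.8)
    return EndoscopyFrame(
        frame_id="f1",
        width=1024,
        height=768,
        laterality=Laterality.RIGHT,
        detections=(mt, it, mucus),
        gt_label="positive",
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
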