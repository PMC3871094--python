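import numpy as np
import pytest

from reefwatch import synthetic as sy
from reefwatch.segmentation import ROIPolygon


@pytest.fixture(scope="session")
def chart():
    """Full-size (640x480) chart reference derived from the synthetic spectra."""
    return sy.default_chart_reference()


@pytest.fixture(scope="session")
def small_chart():
    """Compact chart layout that fits a 240x320 test frame."""
    return sy.default_chart_reference(patch_size=24, window=16, origin=(4, 10), gap=2)


@pytest.fixture
def small_scene(small_chart):
    """Factory for quick-to-render 240x320 scenes."""
    roi = ROIPolygon(np.array([[45, 10], [45, 310], [230, 310], [230, 10]], float))

    def make(**kwargs):
        kwargs.setdefault("image_size", (240, 320))
        kwargs.setdefault("chart", small_chart)
        kwargs.setdefault("roi", roi)
        return sy.SceneSpec(**kwargs)

    return make


@pytest.fixture
def small_center():
    """Panel-center window for the 240x320 test frame."""
    return sy.default_center_region((240, 320), size=40)
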