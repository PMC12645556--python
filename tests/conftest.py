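import math

import numpy as np
import pytest

from spinemetry import SpineTemplate, generate_spine


@pytest.fixture
def arc_template():
    """Noise-free 60-degree arc of radius 20 mm, 24 vertebrae."""
    return SpineTemplate(
        shape="arc",
        deformity_amplitude=60.0,
        spine_length=20.0 * math.pi / 3.0,  # R * theta
        noise_sd=0.0,
    )


@pytest.fixture
def straight_cloud():
    cloud, _ = generate_spine(SpineTemplate(shape="straight", noise_sd=0.0))
    return cloud


def circle_points(radius: float, span_deg: float, n: int) -> np.ndarray:
    """n points on a coronal-plane circular arc starting along +z."""
    phi = np.linspace(0.0, math.radians(span_deg), n)
    return np.c_[radius * (1.0 - np.cos(phi)), np.zeros(n), radius * np.sin(phi)]
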