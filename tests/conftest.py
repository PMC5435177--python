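import numpy as np
import pytest

import lithosym as ls


@pytest.fixture
def ellipse60():
    """Axis-aligned ellipse (semi-axes 2, 1) at 60 equal parameter values:
    mirror-symmetric about both axes by construction."""
    u = 2 * np.pi * np.arange(60) / 60
    return ls.Contour("ellipse", "top", np.column_stack([2 * np.cos(u), np.sin(u)]))


@pytest.fixture
def egg():
    """Pointed egg outline, 120 x 70 mm, pointedness 0.3, 60 vertices."""
    return ls.base_outline(120.0, 70.0, 0.3, n=60)


@pytest.fixture
def unit_square():
    v = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
    return ls.Contour("sq", "top", v)
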