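import numpy as np
import pytest

from fibremetrics.image import GrayImage
from fibremetrics.ridge import Fibre, FibreNetwork
from fibremetrics.synthetic import _render_polyline


def render_lines(polylines, width=4.0, size=128, bg=10.0, fg=200.0):
    """Render explicit centreline polylines into a GrayImage."""
    canvas = np.zeros((size, size))
    for p in polylines:
        _render_polyline(canvas, np.asarray(p, dtype=float), width)
    return GrayImage(bg + (fg - bg) * canvas)


def make_network(fibre_vertices, junctions=(), shape=(128, 128)):
    """Build a FibreNetwork from explicit vertex lists."""
    fibres = [Fibre(np.asarray(v, dtype=float)) for v in fibre_vertices]
    return FibreNetwork(fibres, np.asarray(junctions, dtype=float).reshape(-1, 2), shape)


@pytest.fixture
def y_network():
    """Three fibres radiating from one junction at (64, 64)."""
    j = (64.0, 64.0)
    arms = [
        [(64.0, 64.0), (64.0, 20.0)],
        [(64.0, 64.0), (20.0, 100.0)],
        [(64.0, 64.0), (108.0, 100.0)],
    ]
    return make_network(arms, junctions=[j])


@pytest.fixture
def loop_network():
    """A closed circular fibre (no junctions, no end points)."""
    phi = np.linspace(0, 2 * np.pi, 200)
    circle = np.column_stack([64 + 30 * np.sin(phi), 64 + 30 * np.cos(phi)])
    circle[-1] = circle[0]
    return make_network([circle])


@pytest.fixture
def straight_network():
    return make_network([[(10.0, 5.0), (10.0, 105.0)]])
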