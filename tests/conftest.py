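import numpy as np
import pytest

from peritract.curvegeom import Streamline


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


def make_circle(radius=10.0, n=400, arc_fraction=0.9):
    t = np.linspace(0, 2 * np.pi * arc_fraction, n)
    pts = np.stack([radius * np.cos(t), radius * np.sin(t), np.zeros_like(t)], axis=1)
    return Streamline(pts)


def make_helix(a=3.0, b=4.0, turns=2.0, n=2000):
    t = np.linspace(0, 2 * np.pi * turns, n)
    pts = np.stack([a * np.cos(t), a * np.sin(t), b * t], axis=1)
    return Streamline(pts)


def make_line(length=50.0, n=60, offset=(0.0, 0.0, 0.0), direction=(1.0, 0.0, 0.0)):
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    t = np.linspace(0, length, n)
    return Streamline(np.asarray(offset, float) + t[:, None] * d)


def random_rotation(rng):
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


@pytest.fixture
def circle():
    return make_circle()


@pytest.fixture
def helix():
    return make_helix()
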