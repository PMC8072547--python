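import numpy as np
import pytest
from hypothesis import settings

from tmespat import CellClass, PointPattern, RGrid, Window

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def unit_square():
    return Window.unit_square()


@pytest.fixture
def toy3(unit_square):
    """The hand-enumerated 3-point pattern: nn distances (0.2, 0.2, √0.52),
    boundary distances all 0.2, one pair at distance 0.2."""
    return PointPattern(
        np.array([0.2, 0.2, 0.8]), np.array([0.2, 0.4, 0.8]), unit_square
    )


@pytest.fixture
def grid_025():
    return RGrid(np.linspace(0.0, 0.25, 501))


def random_marked_pattern(rng, n=None, window=None):
    """Random pattern with all four classes present (>= 2 each)."""
    window = window or Window.unit_square()
    n = n or int(rng.integers(8, 21))
    x, y = window.sample_uniform(n, rng)
    marks = np.concatenate(
        [np.repeat([1, 2, 3, 4], 2), rng.integers(1, 5, size=n - 8)]
    )
    rng.shuffle(marks)
    return PointPattern(x, y, window, marks)


# ---------------------------------------------------------------------------
# independent brute-force oracles (naive double loops, no shared code with
# the estimators under test)


def oracle_k(p, r_values):
    """Naive homogeneous translation-corrected K."""
    n, area = p.n, p.window.area
    out = np.zeros(len(r_values))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            dx = p.x[j] - p.x[i]
            dy = p.y[j] - p.y[i]
            d = np.hypot(dx, dy)
            w = area / p.window.translation_overlap(dx, dy)
            out += (d <= r_values) * w
    return area * out / (n * (n - 1))


def oracle_g(p, r_values):
    """Naive border-corrected G."""
    n = p.n
    nn = np.full(n, np.inf)
    for i in range(n):
        for j in range(n):
            if i != j:
                nn[i] = min(nn[i], np.hypot(p.x[j] - p.x[i], p.y[j] - p.y[i]))
    b = np.asarray(p.window.boundary_distance(p.x, p.y))
    out = np.full(len(r_values), np.nan)
    for k, r in enumerate(r_values):
        den = np.sum(b >= r - 1e-12)
        if den > 0:
            out[k] = np.sum((nn <= r + 1e-12) & (b >= r - 1e-12)) / den
    return out


def oracle_k_cross(p, from_class, to_class, r_values):
    """Naive homogeneous cross K."""
    area = p.window.area
    fi = np.flatnonzero(p.marks == int(from_class))
    ti = np.flatnonzero(p.marks == int(to_class))
    out = np.zeros(len(r_values))
    for i in fi:
        for j in ti:
            dx = p.x[j] - p.x[i]
            dy = p.y[j] - p.y[i]
            d = np.hypot(dx, dy)
            w = area / p.window.translation_overlap(dx, dy)
            out += (d <= r_values) * w
    return area * out / (len(fi) * len(ti))
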