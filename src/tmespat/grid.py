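"""Distance grids on which summary functions are evaluated.

Interaction scales beyond 100 µm blur into tissue-level inhomogeneity, so
the default analysis range is capped at 100 µm and additionally at a quarter
of the shorter window side for small regions of interest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .window import Window

__all__ = ["RGrid", "R_MAX_CAP_UM"]

R_MAX_CAP_UM = 100.0


@dataclass(frozen=True)
class RGrid:
    """Strictly increasing, uniformly spaced distances starting at 0."""

    values: np.ndarray

    def __post_init__(self):
        v = np.ascontiguousarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1 or len(v) < 2:
            raise ValueError("r grid needs at least two values")
        if v[0] != 0.0:
            raise ValueError("r grid must start at 0")
        steps = np.diff(v)
        if not np.all(steps > 0):
            raise ValueError("r grid must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=1e-8):
            raise ValueError("r grid must be uniformly spaced")

    @property
    def r_max(self) -> float:
        return float(self.values[-1])

    def __len__(self) -> int:
        return len(self.values)

    @classmethod
    def default(cls, window: Window, n_steps: int = 512, r_max: float | None = None) -> "RGrid":
        """512 equal steps from 0 to ``min(100 µm, shorter side / 4)``."""
        if r_max is None:
            r_max = min(R_MAX_CAP_UM, window.shorter_side / 4.0)
        return cls(np.linspace(0.0, float(r_max), n_steps + 1))

    @classmethod
    def linear(cls, r_max: float, n_steps: int = 512) -> "RGrid":
        return cls(np.linspace(0.0, float(r_max), n_steps + 1))
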