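"""Right-continuous step functions (scalar and matrix valued).

All estimators in this package are càdlàg step processes on the grid of
observed transition times; these two small carriers provide evaluation at
arbitrary times, left limits, and increments.
"""

from __future__ import annotations

import numpy as np


class StepFunction:
    """Scalar right-continuous step function.

    ``f(t) = y0`` for ``t < x[0]`` and ``f(t) = y[k]`` for
    ``x[k] <= t < x[k+1]``.
    """

    __slots__ = ("x", "y", "y0")

    def __init__(self, x, y, y0: float = 1.0):
        self.x = np.asarray(x, dtype=np.float64)
        self.y = np.asarray(y, dtype=np.float64)
        if self.x.ndim != 1 or self.x.shape != self.y.shape:
            raise ValueError("x and y must be 1-d arrays of equal length")
        if np.any(np.diff(self.x) < 0):
            raise ValueError("jump times must be sorted")
        self.y0 = float(y0)

    def __call__(self, t):
        t = np.asarray(t, dtype=np.float64)
        if len(self.x) == 0:
            out = np.full(t.shape, self.y0)
            return out if out.ndim else float(out)
        idx = np.searchsorted(self.x, t, side="right") - 1
        out = np.where(idx >= 0, self.y[np.clip(idx, 0, None)], self.y0)
        return out if out.ndim else float(out)

    def left_limit(self, t):
        """Value just before ``t``, i.e. ``f(t-)``."""
        t = np.asarray(t, dtype=np.float64)
        if len(self.x) == 0:
            out = np.full(t.shape, self.y0)
            return out if out.ndim else float(out)
        idx = np.searchsorted(self.x, t, side="left") - 1
        out = np.where(idx >= 0, self.y[np.clip(idx, 0, None)], self.y0)
        return out if out.ndim else float(out)

    @property
    def jump_times(self) -> np.ndarray:
        return self.x

    @property
    def values(self) -> np.ndarray:
        return self.y

    def clip(self, lo: float = 0.0, hi: float = 1.0) -> "StepFunction":
        return StepFunction(self.x, np.clip(self.y, lo, hi), float(np.clip(self.y0, lo, hi)))

    def __repr__(self) -> str:
        return f"StepFunction({len(self.x)} jumps, y0={self.y0})"


class MatrixStepFunction:
    """Matrix-valued right-continuous step function on a shared time grid.

    Used for cumulative transition-rate matrices (rows sum to zero), estimated
    transition-probability matrices (rows sum to one) and multiplier
    (xi) processes.
    """

    __slots__ = ("x", "values", "v0")

    def __init__(self, x, values, v0=None):
        self.x = np.asarray(x, dtype=np.float64)
        self.values = np.asarray(values, dtype=np.float64)
        if self.values.ndim != 3 or self.values.shape[0] != self.x.shape[0]:
            raise ValueError("values must have shape (len(x), K, K)")
        k = self.values.shape[1]
        if v0 is None:
            v0 = np.zeros((k, k))
        self.v0 = np.asarray(v0, dtype=np.float64)

    @property
    def n_states(self) -> int:
        return self.values.shape[1]

    def __call__(self, t):
        t = np.asarray(t, dtype=np.float64)
        if len(self.x) == 0:
            return np.broadcast_to(self.v0, t.shape + self.v0.shape).copy()
        idx = np.searchsorted(self.x, t, side="right") - 1
        return np.where(
            idx.reshape(idx.shape + (1, 1)) >= 0,
            self.values[np.clip(idx, 0, None)],
            self.v0,
        )

    def left_limit(self, t):
        t = np.asarray(t, dtype=np.float64)
        if len(self.x) == 0:
            return np.broadcast_to(self.v0, t.shape + self.v0.shape).copy()
        idx = np.searchsorted(self.x, t, side="left") - 1
        return np.where(
            idx.reshape(idx.shape + (1, 1)) >= 0,
            self.values[np.clip(idx, 0, None)],
            self.v0,
        )

    @property
    def increments(self) -> np.ndarray:
        """Jumps ``dF(x[k]) = F(x[k]) - F(x[k]-)``, shape ``(m, K, K)``."""
        if len(self.x) == 0:
            return self.values.copy()
        return np.diff(np.concatenate([self.v0[None], self.values]), axis=0)

    def entry(self, g: int, h: int) -> StepFunction:
        return StepFunction(self.x, self.values[:, g, h], y0=float(self.v0[g, h]))

    def __repr__(self) -> str:
        return f"MatrixStepFunction({len(self.x)} jumps, K={self.n_states})"
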