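"""Piecewise-linear response curves ("graphical functions").

The growth, decomposition and mortality responses to temperature, water
stress and soil moisture are all specified as user-editable breakpoint
lists mapping a driver value to a dimensionless index.  Between
breakpoints the curve is linearly interpolated; outside the breakpoint
range it is clamped to the end values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class ResponseCurve:
    """A piecewise-linear mapping from a driver to a bounded index.

    Parameters
    ----------
    x : breakpoint driver values, strictly increasing.
    y : index values at the breakpoints, each in [0, 1].
    name : optional label used in validation error messages.
    """

    x: np.ndarray
    y: np.ndarray
    name: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        label = self.name or "response curve"
        if x.ndim != 1 or x.size == 0:
            raise ValueError(f"{label}: needs at least one breakpoint")
        if x.size != y.size:
            raise ValueError(f"{label}: x and y lengths differ")
        if x.size > 1 and not np.all(np.diff(x) > 0):
            raise ValueError(f"{label}: breakpoint x values must be strictly increasing")
        if np.any(y < 0.0) or np.any(y > 1.0):
            raise ValueError(f"{label}: breakpoint y values must lie in [0, 1]")

    @classmethod
    def from_pairs(cls, pairs, name: str = "") -> "ResponseCurve":
        pairs = list(pairs)
        if not pairs:
            raise ValueError(f"{name or 'response curve'}: empty breakpoint list")
        xs, ys = zip(*pairs)
        return cls(np.asarray(xs, float), np.asarray(ys, float), name=name)

    def __call__(self, x):
        """Evaluate the curve; clamps to the end values outside the range."""
        return eval_curve(self, x)

    def to_pairs(self):
        return [(float(a), float(b)) for a, b in zip(self.x, self.y)]


def eval_curve(curve: ResponseCurve, x):
    """Linear interpolation between bracketing breakpoints, clamped outside.

    ``np.interp`` implements exactly this contract (constant extrapolation
    at both ends); scalars in, scalar out.
    """
    out = np.interp(x, curve.x, curve.y)
    if np.isscalar(x) or np.ndim(x) == 0:
        return float(out)
    return out
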