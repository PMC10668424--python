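"""Restricted cubic spline basis (3 knots, linear tails).

The two-column basis for a continuous predictor x with knots t1 < t2 < t3 is
(x, s(x)) where, writing d(x, t) = max(x - t, 0)^3,

    s(x) = [d(x,t1) - d(x,t2)*(t3-t1)/(t3-t2) + d(x,t3)*(t2-t1)/(t3-t2)]
           / (t3 - t1)^2

(Harrell's normalization). The construction is cubic between the boundary
knots and exactly linear outside them, which keeps extrapolation tame.
Knots default to the 10th/50th/90th percentiles of the training values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

KNOT_PERCENTILES = (10.0, 50.0, 90.0)


@dataclass(frozen=True)
class SplineBasis:
    """Fitted restricted-cubic basis for one variable (3 knots)."""

    variable: str
    knots: tuple[float, float, float]

    def transform(self, x) -> np.ndarray:
        """Evaluate the (x, s(x)) basis; returns an n x 2 array."""
        x = np.asarray(x, dtype=float)
        t1, t2, t3 = self.knots

        def d(t):
            return np.maximum(x - t, 0.0) ** 3

        s = (d(t1) - d(t2) * (t3 - t1) / (t3 - t2)
             + d(t3) * (t2 - t1) / (t3 - t2)) / (t3 - t1) ** 2
        return np.column_stack([x, s])


def build_spline_basis(values, variable: str = "x", n_knots: int = 3) -> SplineBasis:
    """Place knots at the 10th/50th/90th percentiles of ``values``.

    Requires at least 10 distinct values so the percentiles are meaningful;
    the three knots must come out strictly increasing.
    """
    if n_knots != 3:
        raise NotImplementedError("only the 3-knot restricted cubic basis is supported")
    v = np.asarray(values, dtype=float)
    if np.unique(v).size < 10:
        raise ValueError(
            f"variable {variable!r} needs >= 10 distinct values for spline knots"
        )
    knots = tuple(np.percentile(v, KNOT_PERCENTILES))
    if not (knots[0] < knots[1] < knots[2]):
        raise ValueError(f"knots for {variable!r} are not strictly increasing: {knots}")
    return SplineBasis(variable, knots)
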