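"""Penalised B-spline (P-spline) basis helpers shared by the model modules.

Cubic B-spline bases with interior knots placed at quantiles of the training
ages, paired with a second-order difference penalty on the basis
coefficients.  Evaluation outside the training age range clamps the age to
the nearest boundary, so fitted curves extend flat beyond the data — the
convention used by most growth-chart software.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

DEGREE = 3


@dataclass(frozen=True)
class SplineBasis:
    """A fixed cubic B-spline basis over one covariate (age)."""

    knots: np.ndarray  # full knot vector incl. repeated boundary knots
    lo: float
    hi: float

    @property
    def n_basis(self) -> int:
        return len(self.knots) - DEGREE - 1

    def design(self, x) -> np.ndarray:
        x = np.clip(np.asarray(x, float), self.lo, self.hi)
        return BSpline.design_matrix(x, self.knots, DEGREE).toarray()

    def penalty(self) -> np.ndarray:
        """Second-order difference penalty matrix D'D on the coefficients."""
        m = self.n_basis
        if m < 3:
            return np.zeros((m, m))
        d = np.diff(np.eye(m), n=2, axis=0)
        return d.T @ d

    def to_dict(self) -> dict:
        return {"knots": self.knots.tolist(), "lo": self.lo, "hi": self.hi}

    @classmethod
    def from_dict(cls, d: dict) -> "SplineBasis":
        return cls(knots=np.asarray(d["knots"], float), lo=d["lo"], hi=d["hi"])


def make_basis(ages, n_interior: int = 10) -> SplineBasis:
    """Build a cubic basis with interior knots at age quantiles.

    Duplicate quantile knots (heavily tied ages) are collapsed; with a
    single distinct age the design is degenerate and a ValueError is raised.
    """
    ages = np.asarray(ages, float)
    lo, hi = float(ages.min()), float(ages.max())
    if hi <= lo:
        raise ValueError("degenerate design: a single distinct age value")
    qs = np.linspace(0, 1, n_interior + 2)[1:-1]
    interior = np.unique(np.quantile(ages, qs))
    interior = interior[(interior > lo) & (interior < hi)]
    knots = np.concatenate([[lo] * (DEGREE + 1), interior, [hi] * (DEGREE + 1)])
    return SplineBasis(knots=knots, lo=lo, hi=hi)
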