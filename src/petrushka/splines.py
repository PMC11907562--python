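"""Restricted cubic spline basis (truncated-power form).

With k knots t_1 < ... < t_k, the basis holds the linear term plus k-2
nonlinear columns

    X_j(x) = (x - t_j)_+^3
             - (x - t_{k-1})_+^3 (t_k - t_j)/(t_k - t_{k-1})
             + (x - t_k)_+^3 (t_{k-1} - t_j)/(t_k - t_{k-1}),    j = 1..k-2,

scaled by (t_k - t_1)^2 to keep coefficients on a comparable footing. The
construction is exactly linear beyond the boundary knots, and a linear
function of x is reproduced with all nonlinear coefficients at zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError

DEFAULT_KNOT_QUANTILES = {
    3: (0.10, 0.50, 0.90),
    4: (0.05, 0.35, 0.65, 0.95),
    5: (0.05, 0.275, 0.50, 0.725, 0.95),
}

__all__ = ["SplineBasis", "build_spline_basis"]


@dataclass(frozen=True)
class SplineBasis:
    """Knot locations plus the basis-expansion map for one predictor."""

    knots: np.ndarray

    @property
    def n_nonlinear(self) -> int:
        return len(self.knots) - 2

    def transform(self, x) -> np.ndarray:
        """Nonlinear basis columns, shape (n, k-2); pair with the linear term."""
        x = np.asarray(x, dtype=float)
        t = self.knots
        k = len(t)
        scale = (t[-1] - t[0]) ** 2
        cols = []
        for j in range(k - 2):
            c = (np.clip(x - t[j], 0, None) ** 3
                 - np.clip(x - t[k - 2], 0, None) ** 3 * (t[-1] - t[j]) / (t[-1] - t[k - 2])
                 + np.clip(x - t[-1], 0, None) ** 3 * (t[k - 2] - t[j]) / (t[-1] - t[k - 2]))
            cols.append(c / scale)
        return np.column_stack(cols) if cols else np.empty((len(x), 0))

    def design(self, x) -> np.ndarray:
        """Full design for this predictor: linear term then nonlinear columns."""
        x = np.asarray(x, dtype=float)
        return np.column_stack([x, self.transform(x)])


def build_spline_basis(x, n_knots: int = 4,
                       quantiles: tuple[float, ...] | None = None) -> SplineBasis:
    """Place knots at the default quantiles of ``x`` and return the basis.

    Four knots (the default) sit at the 0.05, 0.35, 0.65 and 0.95 quantiles,
    giving two nonlinear columns on top of the linear term.
    """
    x = np.asarray(x, dtype=float)
    if n_knots < 3:
        raise DegenerateInputError("restricted cubic splines need >= 3 knots")
    if quantiles is None:
        if n_knots not in DEFAULT_KNOT_QUANTILES:
            quantiles = tuple(np.linspace(0.05, 0.95, n_knots))
        else:
            quantiles = DEFAULT_KNOT_QUANTILES[n_knots]
    knots = np.quantile(x, quantiles)
    if len(np.unique(knots)) < n_knots or len(np.unique(x)) < n_knots:
        raise DegenerateInputError(
            f"need >= {n_knots} distinct values with distinct quantile knots")
    return SplineBasis(knots=np.asarray(knots, dtype=float))
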