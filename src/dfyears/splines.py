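"""Restricted cubic splines of log age for the cumulative-hazard model.

The basis is the natural-cubic form used by flexible parametric survival
models: with boundary knots ``k_min < k_max`` and internal knots ``k_j``,

    v_j(x) = (x - k_j)^3_+  -  l_j (x - k_min)^3_+  -  (1 - l_j)(x - k_max)^3_+,
    l_j = (k_max - k_j) / (k_max - k_min),

which is linear beyond both boundary knots.  With no internal knots the spline
degenerates to the linear term alone and the model reduces to a Weibull.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class KnotSet:
    """Boundary and internal knots on the log-age scale."""

    boundary: tuple[float, float]
    internal: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        lo, hi = self.boundary
        if not lo < hi:
            raise ValueError("boundary knots must be ordered")
        if len(self.internal) > 4:
            raise ValueError("at most 4 internal knots are supported")
        allk = (lo, *self.internal, hi)
        if any(a >= b for a, b in zip(allk, allk[1:])):
            raise ValueError("knots must be strictly increasing within the boundary")

    @property
    def n_basis(self) -> int:
        """Number of coefficients including the intercept."""
        return len(self.internal) + 2


def _pos3(z: np.ndarray) -> np.ndarray:
    return np.clip(z, 0.0, None) ** 3


def rcs_design(x, knots: KnotSet) -> np.ndarray:
    """Design matrix (1, x, v_1..v_m) of the restricted cubic spline at x."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    lo, hi = knots.boundary
    cols = [np.ones_like(x), x]
    for kj in knots.internal:
        lam = (hi - kj) / (hi - lo)
        cols.append(_pos3(x - kj) - lam * _pos3(x - lo) - (1 - lam) * _pos3(x - hi))
    return np.column_stack(cols)


def rcs_deriv(x, knots: KnotSet) -> np.ndarray:
    """d/dx of each design column: (0, 1, v_1'..v_m')."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    lo, hi = knots.boundary
    cols = [np.zeros_like(x), np.ones_like(x)]
    for kj in knots.internal:
        lam = (hi - kj) / (hi - lo)
        cols.append(
            3 * np.clip(x - kj, 0, None) ** 2
            - 3 * lam * np.clip(x - lo, 0, None) ** 2
            - 3 * (1 - lam) * np.clip(x - hi, 0, None) ** 2
        )
    return np.column_stack(cols)


def place_knots(event_ages, n_internal: int) -> KnotSet:
    """Boundary knots at min/max log event age, internal at equal centiles.

    One internal knot sits at the median log event age; two at the 33rd/67th
    centiles; three at 25/50/75; four at 20/40/60/80.  Centiles that collide
    (duplicate-heavy event ages) are dropped with a warning.
    """
    ages = np.asarray(event_ages, dtype=float)
    ages = ages[np.isfinite(ages) & (ages > 0)]
    if not 0 <= n_internal <= 4:
        raise ValueError("n_internal must be between 0 and 4")
    if len(np.unique(ages)) < n_internal + 2:
        raise ValueError(
            f"need at least {n_internal + 2} distinct event ages for "
            f"{n_internal} internal knots; use fewer knots"
        )
    logs = np.log(ages)
    lo, hi = float(logs.min()), float(logs.max())
    if n_internal == 0:
        return KnotSet((lo, hi))
    qs = np.arange(1, n_internal + 1) / (n_internal + 1)
    internal = np.quantile(logs, qs)
    internal = internal[(internal > lo) & (internal < hi)]
    uniq = np.unique(internal)
    if len(uniq) < n_internal:
        warnings.warn(
            f"knot centiles coincide; using {len(uniq)} internal knots "
            f"instead of {n_internal}",
            stacklevel=2,
        )
    return KnotSet((lo, hi), tuple(float(k) for k in uniq))
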