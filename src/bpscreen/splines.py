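"""Restricted (natural) cubic spline basis over gestational age.

The basis parameterizes the shape of the mean-arterial-pressure trajectory
across gestation.  With K knots it has K-1 columns: the identity (linear)
term plus K-2 restricted cubic terms built from truncated cubes, with the
tail restrictions forcing the fitted curve to be linear beyond the first
and last knots.  Terms are scaled by (k_K - k_1)^2 so coefficients stay on
a numerically comfortable scale.
"""

from __future__ import annotations

import numpy as np

#: Knot placement (weeks of gestation) used for the pregnancy MAP normogram.
DEFAULT_KNOTS = (11.0, 18.0, 30.0, 36.0, 40.0)


def rcs_basis(ga, knots=DEFAULT_KNOTS) -> np.ndarray:
    """Evaluate the restricted cubic spline basis at gestational age ``ga``.

    Parameters
    ----------
    ga : float or array-like
        Gestational age(s), weeks.
    knots : sequence of float
        Strictly increasing knot locations, at least 3.

    Returns
    -------
    ndarray of shape (..., K-1)
        Columns ``(ga, s_1(ga), ..., s_{K-2}(ga))``.  All nonlinear columns
        vanish at and below the first knot, and every column is linear in
        ``ga`` beyond the boundary knots.
    """
    k = np.asarray(knots, dtype=float)
    if k.ndim != 1 or k.size < 3:
        raise ValueError("need at least 3 strictly increasing knots")
    if np.any(np.diff(k) <= 0):
        raise ValueError("knots must be strictly increasing")
    x = np.asarray(ga, dtype=float)
    scalar = x.ndim == 0
    x = np.atleast_1d(x)

    K = k.size
    scale = (k[-1] - k[0]) ** 2

    def tpc(t, knot):  # truncated cube
        d = t - knot
        return np.where(d > 0.0, d, 0.0) ** 3

    cols = [x]
    denom = k[-1] - k[-2]
    for j in range(K - 2):
        term = (
            tpc(x, k[j])
            - tpc(x, k[-2]) * (k[-1] - k[j]) / denom
            + tpc(x, k[-1]) * (k[-2] - k[j]) / denom
        ) / scale
        cols.append(term)
    out = np.stack(cols, axis=-1)
    return out[0] if scalar else out


def n_terms(knots=DEFAULT_KNOTS) -> int:
    """Number of basis columns (linear term included)."""
    return len(knots) - 1
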