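"""Restricted cubic splines (Harrell truncated-power basis, three knots).

With knots k1 < k2 < k3 the basis has two columns: the identity term and one
restricted nonlinear term

    [ (x-k1)+^3 - (x-k2)+^3 (k3-k1)/(k3-k2) + (x-k3)+^3 (k2-k1)/(k3-k2) ]
        / (k3-k1)^2

which is linear outside [k1, k3] and has continuous first and second
derivatives everywhere.
"""

from __future__ import annotations

import numpy as np


def percentile_knots(x, percentiles=(10.0, 50.0, 90.0)):
    """Knots at the given percentiles of the realised distribution of ``x``."""
    knots = np.percentile(np.asarray(x, dtype=float), list(percentiles))
    return tuple(float(k) for k in knots)


def rcs_basis(x, knots):
    """Restricted cubic spline basis matrix with columns (x, nonlinear term).

    Parameters
    ----------
    x : array-like
        Evaluation points.
    knots : sequence of 3 strictly increasing reals.
    """
    x = np.asarray(x, dtype=float)
    k1, k2, k3 = (float(k) for k in knots)
    if not (k1 < k2 < k3):
        raise ValueError(f"knots must be strictly increasing, got {knots}")

    def pos3(u):
        return np.clip(u, 0.0, None) ** 3

    nonlin = (
        pos3(x - k1)
        - pos3(x - k2) * (k3 - k1) / (k3 - k2)
        + pos3(x - k3) * (k2 - k1) / (k3 - k2)
    ) / (k3 - k1) ** 2
    return np.column_stack([x, nonlin])
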