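"""Closed-form cell-division distributions for knockout cells.

A single cell carrying a knockout divides a random number of times per
wild-type population doubling cycle.  For a single knockout (SKO) of a gene
with theoretical phenotype ``p`` in [-1, 1] the number of divisions ``x`` is
categorical on {0, 1, 2}:

    P(x = 0) = max(-p, 0)      cell dies
    P(x = 1) = 1 - |p|         divides once, like wild type
    P(x = 2) = max(p, 0)       divides twice

For a double knockout (DKO) with independent per-gene division counts
``x1``, ``x2`` the joint number of divisions is

    y = 1(x1 * x2 != 0) * (x1 + x2 - 1)  in {0, 1, 2, 3}

so a cell produces ``1(y != 0) * 2**y`` descendants (0, 2, 4 or 8).  The
genetic-interaction value ``pi`` is the gap in expected descendants between
the interaction-perturbed phenotype pair and the base pair.

All functions are vectorized over numpy arrays and perform no I/O.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "sko_division_probs",
    "dko_division_probs",
    "expected_descendants",
    "true_gi",
]

#: descendants produced by a cell that divides y times, y = 0..3
DESCENDANTS = np.array([0.0, 2.0, 4.0, 8.0])


def _check_phenotype(p, name: str) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if np.any(np.abs(p) > 1):
        raise ValueError(f"{name} must lie in [-1, 1]")
    return p


def sko_division_probs(p):
    """Division-count distribution (P(x=0), P(x=1), P(x=2)) of an SKO cell.

    Parameters
    ----------
    p : float or array-like
        Theoretical phenotype(s) in [-1, 1].

    Returns
    -------
    ndarray with shape ``p.shape + (3,)``; each row sums to 1.
    """
    p = _check_phenotype(p, "p")
    out = np.stack(
        [np.maximum(-p, 0.0), 1.0 - np.abs(p), np.maximum(p, 0.0)], axis=-1
    )
    return out


def dko_division_probs(p1, p2):
    """Division-count distribution (p0, p1, p2, p3) of a DKO cell.

    The two knockouts act independently; the joint division count is
    ``y = 1(x1*x2 != 0)(x1 + x2 - 1)``.  Setting one phenotype to 0 reduces
    the distribution to the SKO distribution of the other gene (with zero
    probability of three divisions).
    """
    p1 = _check_phenotype(p1, "p1")
    p2 = _check_phenotype(p2, "p2")
    n1, z1, pp1 = np.maximum(-p1, 0.0), 1.0 - np.abs(p1), np.maximum(p1, 0.0)
    n2, z2, pp2 = np.maximum(-p2, 0.0), 1.0 - np.abs(p2), np.maximum(p2, 0.0)
    p0 = n1 * n2 + n1 * z2 + n1 * pp2 + z1 * n2 + pp1 * n2
    p1y = z1 * z2
    p2y = z1 * pp2 + pp1 * z2
    p3y = pp1 * pp2
    return np.stack([p0, p1y, p2y, p3y], axis=-1)


def expected_descendants(probs):
    """Expected number of descendants of one cell per doubling cycle.

    ``probs`` is a 4-vector (or an array of 4-vectors) over division counts
    0..3; the result is ``0*p0 + 2*p1 + 4*p2 + 8*p3`` in [0, 8].
    """
    probs = np.asarray(probs, dtype=float)
    return probs @ DESCENDANTS


def true_gi(p1, p2, p1_i, p2_i):
    """Ground-truth genetic interaction ``pi`` of a gene pair.

    ``pi`` is the difference in expected descendants per doubling cycle
    between the interaction-perturbed phenotypes ``(p1_i, p2_i)`` and the
    base phenotypes ``(p1, p2)``; it lies in [-8, 8] and is 0 whenever the
    perturbed phenotypes equal the base ones (no interaction).
    """
    return expected_descendants(dko_division_probs(p1_i, p2_i)) - expected_descendants(
        dko_division_probs(p1, p2)
    )
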