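"""Close-pair extraction: cross-set displacement vectors inside a window.

Given two point sets A and B (2D or 3D, nm) and a window of radius ``r``
centred on a current shift guess ``c``, collect every displacement
``b - a`` with ``|b - a - c| <= r`` (closed ball).  This is the inner loop
of the mean-shift estimator, so it must scale near-linearly with the number
of points: the fast path offsets B by ``-c`` and runs a KD-tree ball query
against A, touching only pairs near the window.  A brute-force O(|A||B|)
enumeration with the identical inclusion rule is kept as the test oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["DisplacementSet", "cross_pairs", "brute_force_pairs"]

# below this many candidate pairs a vectorized all-pairs pass beats tree setup
_ALL_PAIRS_MAX = 1_000_000


@dataclass(frozen=True)
class DisplacementSet:
    """Cross-set displacements falling inside one observation window.

    ``vectors`` holds the displacements b − a (shape (count, dim), nm);
    every row v satisfies |v − center| ≤ radius.
    """

    vectors: np.ndarray
    center: np.ndarray
    radius: float

    @property
    def count(self) -> int:
        return int(self.vectors.shape[0])

    @property
    def dim(self) -> int:
        return int(self.vectors.shape[1])


def _check_inputs(A: np.ndarray, B: np.ndarray, center: np.ndarray, radius: float):
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    center = np.asarray(center, dtype=float).ravel()
    if A.shape[0] == 0 or B.shape[0] == 0:
        raise ValueError("point sets must be non-empty")
    if A.shape[1] != B.shape[1]:
        raise ValueError(f"dimension mismatch: A is {A.shape[1]}D, B is {B.shape[1]}D")
    if center.shape[0] != A.shape[1]:
        raise ValueError("center dimension does not match point sets")
    if not radius > 0:
        raise ValueError("radius must be > 0")
    return A, B, center, float(radius)


def cross_pairs(A, B, center, radius, scale: np.ndarray | None = None) -> DisplacementSet:
    """All displacements b − a within ``radius`` of ``center`` (closed ball).

    Parameters
    ----------
    A, B : (n, d) arrays
        Point sets in nm, d = 2 or 3.
    center : (d,) array
        Current shift guess the window is centred on.
    radius : float
        Window radius in nm.
    scale : (d,) array, optional
        Per-axis scale turning the ball into an axis-aligned ellipsoid:
        inclusion tests |(v − center)/scale| ≤ radius.  Used for 3D data
        where the axial precision differs from the lateral one.

    Returns
    -------
    DisplacementSet
        Vector content is deterministic; ordering is unspecified.
    """
    A, B, center, radius = _check_inputs(A, B, center, radius)
    if scale is not None:
        scale = np.asarray(scale, dtype=float).ravel()
        A = A / scale
        B = B / scale
        q = cross_pairs(A, B, center / scale, radius)
        return DisplacementSet(q.vectors * scale, np.asarray(center, float) * 1.0, radius)

    if A.shape[0] * B.shape[0] <= _ALL_PAIRS_MAX:
        return brute_force_pairs(A, B, center, radius)

    # query each b-c against A: |b - c - a| <= r  <=>  |b - a - c| <= r
    tree = cKDTree(A)
    neighbors = tree.query_ball_point(B - center, r=radius)
    lens = np.fromiter((len(ix) for ix in neighbors), dtype=np.intp, count=len(neighbors))
    if lens.sum() == 0:
        return DisplacementSet(np.empty((0, A.shape[1])), center, radius)
    a_idx = np.concatenate([ix for ix in neighbors if ix]).astype(np.intp)
    b_idx = np.repeat(np.arange(B.shape[0]), lens)
    return DisplacementSet(B[b_idx] - A[a_idx], center, radius)


def brute_force_pairs(A, B, center, radius) -> DisplacementSet:
    """Exhaustive O(|A||B|) enumeration with the same closed-ball rule.

    Test oracle for :func:`cross_pairs`; use only on small instances.
    """
    A, B, center, radius = _check_inputs(A, B, center, radius)
    diff = B[None, :, :] - A[:, None, :]  # (|A|, |B|, d)
    d2 = np.sum((diff - center) ** 2, axis=-1)
    mask = d2 <= radius * radius
    return DisplacementSet(diff[mask], center, radius)
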