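"""Drift trajectory estimation from binned pairwise shift estimates.

Localizations are distributed into non-overlapping temporal bins with equal
numbers of frames; the mean-shift estimator is run between every pair of
bins (i < j), giving an overdetermined set of relative displacements
Δ_ij ≈ d_j − d_i with per-axis errors ε_ij.  A weighted linear
least-squares fit (weights 1/ε_ij²) solves for the control-point drifts
d_k, anchored at d_1 = 0, and the drift at any frame is linearly
interpolated between control points (clamped beyond the ends).  The
redundancy — K(K−1)/2 equations for K−1 unknowns per axis — is what buys
precision over a chain of consecutive-bin estimates.

Overlapping temporal bins are supported only as a diagnostic: because the
same localizations then appear in neighbouring bins, their pairwise shifts
are biased toward zero and the fitted trajectory underestimates the accrued
drift.  Production use should keep bins non-overlapping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .localization_io import LocalizationTable
from .meanshift import MSParams, ShiftEstimate, mean_shift

__all__ = [
    "TemporalBinning",
    "PairwiseShiftMatrix",
    "DriftTrajectory",
    "bin_frames",
    "bin_frames_overlapping",
    "pairwise_shifts",
    "fit_trajectory",
    "interpolate_drift",
    "apply_drift_correction",
    "estimate_drift",
]


@dataclass(frozen=True)
class TemporalBinning:
    """Assignment of frames 1..F_max to K temporal bins.

    edges : (K, 2) int array of half-open frame intervals [start, end).
    centers : representative time per bin (frames; interval midpoint).
    overlapping : True only for the diagnostic 50%-overlap mode.
    """

    edges: np.ndarray
    overlapping: bool = False

    def __post_init__(self):
        edges = np.asarray(self.edges, dtype=np.int64)
        object.__setattr__(self, "edges", edges)
        if edges.ndim != 2 or edges.shape[1] != 2 or edges.shape[0] < 2:
            raise ValueError("need at least 2 bins of [start, end) edges")
        if np.any(edges[:, 1] <= edges[:, 0]):
            raise ValueError("empty or inverted bin interval")
        if not self.overlapping and np.any(edges[1:, 0] < edges[:-1, 1]):
            raise ValueError("bins overlap; use bin_frames_overlapping for that")

    @property
    def K(self) -> int:
        return int(self.edges.shape[0])

    @property
    def centers(self) -> np.ndarray:
        return (self.edges[:, 0] + self.edges[:, 1] - 1) / 2.0

    def membership(self, frame: np.ndarray) -> list[np.ndarray]:
        """Boolean row masks of a frame vector, one per bin."""
        return [(frame >= s) & (frame < e) for s, e in self.edges]


def bin_frames(f_max: int, bin_width: int) -> TemporalBinning:
    """Equal-width non-overlapping bins covering frames 1..f_max.

    K = floor(f_max / bin_width); any trailing remainder frames are folded
    into the last bin so no localization is discarded.  Fewer than two full
    bins is an error (drift is then undefined).
    """
    if bin_width < 2:
        raise ValueError("bin_width must be >= 2 frames")
    K = f_max // bin_width
    if K < 2:
        raise ValueError(
            f"f_max={f_max} with bin_width={bin_width} yields {K} full bins; need >= 2"
        )
    starts = 1 + bin_width * np.arange(K)
    ends = starts + bin_width
    ends[-1] = f_max + 1  # absorb remainder
    return TemporalBinning(np.column_stack([starts, ends]))


def bin_frames_overlapping(f_max: int, bin_width: int) -> TemporalBinning:
    """50%-overlapping bins (stride = bin_width / 2). Diagnostic use only."""
    if bin_width < 2 or bin_width % 2:
        raise ValueError("bin_width must be an even integer >= 2")
    stride = bin_width // 2
    starts = 1 + stride * np.arange((f_max - bin_width) // stride + 1)
    if starts.size < 2:
        raise ValueError("fewer than 2 overlapping bins")
    edges = np.column_stack([starts, starts + bin_width])
    edges[-1, 1] = max(edges[-1, 1], f_max + 1)
    return TemporalBinning(edges, overlapping=True)


@dataclass
class PairwiseShiftMatrix:
    """Shift estimates Δ_ij (and errors ε_ij) for all bin pairs i < j."""

    K: int
    dim: int
    entries: dict[tuple[int, int], ShiftEstimate]

    def valid_items(self):
        return [(ij, e) for ij, e in self.entries.items() if e.valid]


def pairwise_shifts(
    table: LocalizationTable,
    binning: TemporalBinning,
    params: MSParams = MSParams(),
    start_trajectory: "DriftTrajectory | None" = None,
    adjacent_only: bool = False,
) -> PairwiseShiftMatrix:
    """Run mean-shift between the point sets of every bin pair i < j.

    ``start_trajectory`` optionally seeds each pair's iteration with the
    coarse drift difference from a first pass (two-pass mode for very large
    drifts); the default start is zero for every pair.  ``adjacent_only``
    restricts to consecutive pairs (j = i + 1) — the cheap chain used as
    the first pass when the accrued drift may exceed the initial window.
    Bins with too few localizations simply produce invalid entries.
    """
    masks = binning.membership(table.frame)
    points = [table.xy[m] for m in masks]
    entries: dict[tuple[int, int], ShiftEstimate] = {}
    dim = table.dim
    centers = binning.centers
    for i in range(binning.K):
        for j in range(i + 1, binning.K):
            if adjacent_only and j != i + 1:
                continue
            if points[i].shape[0] == 0 or points[j].shape[0] == 0:
                entries[(i, j)] = ShiftEstimate(
                    np.full(dim, np.nan), np.full(dim, np.nan), 0, 0, False, False
                )
                continue
            start = None
            if start_trajectory is not None:
                start = interpolate_drift(start_trajectory, centers[j]) - interpolate_drift(
                    start_trajectory, centers[i]
                )
            entries[(i, j)] = mean_shift(points[i], points[j], params, start=start)
    return PairwiseShiftMatrix(binning.K, dim, entries)


@dataclass
class DriftTrajectory:
    """Control-point drift trajectory with 68% confidence half-widths.

    times : (K,) control-point times in frames (bin centres).
    d : (K, dim) drift vectors in nm, d[0] = 0 by convention.
    ci68 : (K, dim) per-axis 68% half-widths in nm (0 at the anchor).
    """

    times: np.ndarray
    d: np.ndarray
    ci68: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, float)
        self.d = np.atleast_2d(np.asarray(self.d, float))
        self.ci68 = np.atleast_2d(np.asarray(self.ci68, float))
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("control-point times must be strictly increasing")

    @property
    def dim(self) -> int:
        return int(self.d.shape[1])

    @property
    def K(self) -> int:
        return int(self.d.shape[0])


def fit_trajectory(
    matrix: PairwiseShiftMatrix,
    binning: TemporalBinning,
    exclude_adjacent: bool = False,
    chi2_rescale: bool = False,
    error_gate: float | None = None,
) -> DriftTrajectory:
    """Error-weighted redundant least-squares fit of the drift control points.

    Per axis, minimizes Σ w_ij (Δ_ij − (d_j − d_i))² over d_2..d_K with
    w_ij = 1/ε_ij² and d_1 ≡ 0.  The 68% half-widths are the square roots of
    the diagonal of the inverse weighted normal matrix; errors are treated
    as absolute (no a-posteriori χ² rescaling) unless ``chi2_rescale``.

    ``exclude_adjacent`` drops pairs with j = i + 1 before solving — a
    diagnostic for blinking-induced temporal correlation.  ``error_gate``
    (nm) additionally drops entries whose RMS estimated error exceeds it
    (the σ/4 robustness guide, off by default).

    Raises if the surviving pair graph does not connect all bins.
    """
    items = matrix.valid_items()
    if exclude_adjacent:
        items = [((i, j), e) for (i, j), e in items if j != i + 1]
    if error_gate is not None:
        items = [(ij, e) for ij, e in items if e.rms_err <= error_gate]
    if not items:
        raise ValueError("no valid pairwise shift estimates to fit")

    K, dim = matrix.K, matrix.dim
    # connectivity check via union-find
    parent = list(range(K))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for (i, j), _ in items:
        parent[find(i)] = find(j)
    roots = {find(k) for k in range(K)}
    if len(roots) > 1:
        groups = {}
        for k in range(K):
            groups.setdefault(find(k), []).append(k)
        raise ValueError(f"pair graph is disconnected; components: {sorted(groups.values())}")

    d = np.zeros((K, dim))
    ci = np.zeros((K, dim))
    rows = len(items)
    for ax in range(dim):
        # design matrix over unknowns d_2..d_K (d_1 anchored at 0)
        Aw = np.zeros((rows, K - 1))
        bw = np.zeros(rows)
        resid_w = []
        for r, ((i, j), e) in enumerate(items):
            w = 1.0 / e.err[ax] ** 2
            sw = np.sqrt(w)
            if i > 0:
                Aw[r, i - 1] = -sw
            Aw[r, j - 1] = sw
            bw[r] = sw * e.shift[ax]
        sol, *_ = np.linalg.lstsq(Aw, bw, rcond=None)
        N = Aw.T @ Aw  # weighted normal matrix
        cov = np.linalg.inv(N)
        var = np.diag(cov).copy()
        if chi2_rescale and rows > K - 1:
            chi2 = float(np.sum((Aw @ sol - bw) ** 2)) / (rows - (K - 1))
            var *= chi2
        d[1:, ax] = sol
        ci[1:, ax] = np.sqrt(var)
    return DriftTrajectory(binning.centers, d, ci)


def interpolate_drift(traj: DriftTrajectory, frame) -> np.ndarray:
    """Drift vector at the given frame(s): linear between control points,
    clamped (constant) before the first and after the last."""
    frame = np.asarray(frame, dtype=float)
    out = np.stack(
        [np.interp(frame, traj.times, traj.d[:, ax]) for ax in range(traj.dim)],
        axis=-1,
    )
    return out


def apply_drift_correction(table: LocalizationTable, traj: DriftTrajectory) -> LocalizationTable:
    """Subtract the interpolated drift from every localization's coordinates.

    Frames, ordering and precisions are untouched.
    """
    if traj.dim != table.dim:
        raise ValueError("trajectory and table dimensions differ")
    corr = table.xy - interpolate_drift(traj, table.frame)
    return table.with_coordinates(corr)


def estimate_drift(
    table: LocalizationTable,
    bin_width: int,
    params: MSParams = MSParams(),
    exclude_adjacent: bool = False,
    two_pass: bool = False,
    **fit_kwargs,
) -> DriftTrajectory:
    """Convenience pipeline: bin → pairwise mean-shift → weighted fit.

    ``two_pass`` handles drifts that accrue beyond the initial window: the
    first pass chains only consecutive bins (whose relative drift is small)
    to get a coarse trajectory, which then seeds the start point of every
    pair in the full redundant second pass.
    """
    binning = bin_frames(table.f_max, bin_width)
    if two_pass:
        coarse = pairwise_shifts(table, binning, params, adjacent_only=True)
        coarse_traj = fit_trajectory(coarse, binning)
        matrix = pairwise_shifts(table, binning, params, start_trajectory=coarse_traj)
    else:
        matrix = pairwise_shifts(table, binning, params)
    return fit_trajectory(matrix, binning, exclude_adjacent=exclude_adjacent, **fit_kwargs)
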