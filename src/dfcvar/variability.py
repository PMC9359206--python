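"""Sliding-window correlation and the temporal-variability statistic I.

For a pair of time courses segmented into ``m`` overlapping windows with
windowed Pearson correlations ``r_1 .. r_m``, the temporal variability is
the mean squared successive difference

    I = 1/(m-1) * sum_{k=2..m} (r_k - r_{k-1})**2

computed on raw correlations (no Fisher transform).  High I means the
coupling between the two series is unstable over time; a perfectly
stationary correlation gives I = 0.  Windows are rectangular (untapered)
and advance by a fixed step; the default scheme (50 TR, step 1) keeps the
window no shorter than one period of the slowest retained frequency
(1 / 0.01 Hz at TR = 2 s).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from dfcvar.core_io import BoldVolumeSeries, RoiTimeSeries, SeedDefinition, seed_neighborhood

logger = logging.getLogger(__name__)


class DegenerateWindowError(ValueError):
    """A window with zero variance makes the windowed correlation undefined."""


class InsufficientDataError(ValueError):
    """Fewer time points or windows than the computation requires."""


@dataclass(frozen=True)
class WindowScheme:
    """Sliding-window layout: window length and step, both in TR units."""

    length_tr: int = 50
    step_tr: int = 1

    def __post_init__(self) -> None:
        if self.length_tr < 2:
            raise ValueError("length_tr must be >= 2")
        if self.step_tr < 1:
            raise ValueError("step_tr must be >= 1")

    def n_windows(self, T: int) -> int:
        if T < self.length_tr:
            raise InsufficientDataError(
                f"{T} time points < window length {self.length_tr}"
            )
        return (T - self.length_tr) // self.step_tr + 1


@dataclass
class WindowedCorrelationSeries:
    """Windowed Pearson correlations ``r_k`` in window order."""

    r: np.ndarray
    scheme: WindowScheme

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=np.float64)
        if self.r.ndim != 1:
            raise ValueError("r must be a vector")
        if not np.all(np.isfinite(self.r)):
            raise ValueError("non-finite windowed correlation")


@dataclass
class VariabilityMatrix:
    """Symmetric [R x R] matrix of I per region pair; diagonal fixed at 0."""

    values: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        R = self.values.shape[0]
        if self.values.shape != (R, R):
            raise ValueError("values must be square")
        if len(self.labels) != R:
            raise ValueError("label count must match matrix size")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("matrix must be symmetric")
        if np.any(self.values < -1e-12):
            raise ValueError("I is a mean of squares and cannot be negative")

    def pair_value(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])


@dataclass
class VariabilityMap:
    """Voxel-wise I map for one seed; NaN outside the mask, 0 at the seed."""

    data: np.ndarray
    affine: np.ndarray
    seed_label: str
    scheme: WindowScheme
    n_masked_out: int = 0


def min_window_length(fmin_hz: float, tr_seconds: float) -> int:
    """Shortest admissible window (in TR) covering one period of ``fmin_hz``.

    A window shorter than ``1/fmin`` cannot resolve the slowest retained
    frequency, so the minimum length is ``ceil((1/fmin) / TR)``.
    """
    if fmin_hz <= 0 or tr_seconds <= 0:
        raise ValueError("fmin_hz and tr_seconds must be positive")
    return int(math.ceil((1.0 / fmin_hz) / tr_seconds))


def build_windows(T: int, scheme: WindowScheme) -> list[range]:
    """Half-open window index ranges ``[s, s + length)`` for step multiples s."""
    m = scheme.n_windows(T)
    return [
        range(s, s + scheme.length_tr)
        for s in range(0, m * scheme.step_tr, scheme.step_tr)
    ]


def _window_moments(x: np.ndarray, scheme: WindowScheme) -> tuple[np.ndarray, np.ndarray]:
    """Windowed sums and sums of squares for each column of ``x`` ([T x R]).

    Uses prefix sums so all windows cost O(T R) regardless of overlap.
    Returns ``(S1, S2)`` of shape [m x R].
    """
    T = x.shape[0]
    L, step = scheme.length_tr, scheme.step_tr
    m = scheme.n_windows(T)
    starts = np.arange(m) * step
    c1 = np.vstack([np.zeros((1, x.shape[1])), np.cumsum(x, axis=0)])
    c2 = np.vstack([np.zeros((1, x.shape[1])), np.cumsum(x * x, axis=0)])
    return c1[starts + L] - c1[starts], c2[starts + L] - c2[starts]


def windowed_correlation(
    x: np.ndarray, y: np.ndarray, scheme: WindowScheme
) -> WindowedCorrelationSeries:
    """Pearson correlation of ``x`` and ``y`` within each sliding window."""
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    xy = np.column_stack([x, y])
    L = scheme.length_tr
    (S1, S2) = _window_moments(xy, scheme)
    c12 = np.concatenate([[0.0], np.cumsum(x * y)])
    m = scheme.n_windows(x.shape[0])
    starts = np.arange(m) * scheme.step_tr
    Sxy = c12[starts + L] - c12[starts]
    var = S2 - S1 * S1 / L  # L * sample variance
    bad = np.nonzero(np.any(var <= 1e-12 * np.maximum(S2, 1.0), axis=1))[0]
    if bad.size:
        raise DegenerateWindowError(
            f"zero-variance window(s) at index {bad[0]} (of {bad.size} degenerate)"
        )
    cov = Sxy - S1[:, 0] * S1[:, 1] / L
    r = cov / np.sqrt(var[:, 0] * var[:, 1])
    return WindowedCorrelationSeries(r=np.clip(r, -1.0, 1.0), scheme=scheme)


def temporal_variability(rs: WindowedCorrelationSeries | np.ndarray) -> float:
    """Mean squared successive difference of the windowed correlations.

    ``I = 1/(m-1) * sum_{k=2..m} (r_k - r_{k-1})**2``; requires at least two
    windows.  Each ``|r_k - r_{k-1}| <= 2``, so ``I <= 4``.
    """
    r = rs.r if isinstance(rs, WindowedCorrelationSeries) else np.asarray(rs, dtype=np.float64)
    if r.size < 2:
        raise InsufficientDataError("temporal variability needs at least 2 windows")
    d = np.diff(r)
    return float(np.mean(d * d))


def _pairwise_windowed_stats(
    values: np.ndarray, scheme: WindowScheme
) -> np.ndarray:
    """Windowed correlation matrices for all region pairs: shape [m x R x R].

    Degenerate (zero-variance) windows raise, naming pair and window, rather
    than silently imputing r = 0 (which would bias I downward).
    """
    T, R = values.shape
    L, step = scheme.length_tr, scheme.step_tr
    m = scheme.n_windows(T)
    starts = np.arange(m) * step
    S1, S2 = _window_moments(values, scheme)
    var = S2 - S1 * S1 / L
    degenerate = var <= 1e-12 * np.maximum(S2, 1.0)
    if degenerate.any():
        w, j = np.argwhere(degenerate)[0]
        raise DegenerateWindowError(
            f"region column {j} has zero variance in window {w}"
        )
    # cross products via prefix sums of outer products
    cp = np.einsum("ti,tj->tij", values, values)
    ccp = np.concatenate([np.zeros((1, R, R)), np.cumsum(cp, axis=0)])
    Sxy = ccp[starts + L] - ccp[starts]
    cov = Sxy - np.einsum("wi,wj->wij", S1, S1) / L
    sd = np.sqrt(var)
    r = cov / np.einsum("wi,wj->wij", sd, sd)
    return np.clip(r, -1.0, 1.0)


def roi_variability_matrix(rois: RoiTimeSeries, scheme: WindowScheme) -> VariabilityMatrix:
    """Temporal variability I for every pair of ROI columns.

    Entry (i, j) equals ``temporal_variability(windowed_correlation(col_i,
    col_j))``; the matrix is symmetric by construction with zero diagonal.
    """
    if rois.n_regions < 2:
        raise ValueError("need at least 2 regions")
    if scheme.n_windows(rois.n_timepoints) < 2:
        raise InsufficientDataError("need at least 2 windows for I")
    r = _pairwise_windowed_stats(rois.values, scheme)
    d = np.diff(r, axis=0)
    I = np.mean(d * d, axis=0)
    np.fill_diagonal(I, 0.0)
    I = (I + I.T) / 2.0
    return VariabilityMatrix(values=I, labels=list(rois.labels))


def mean_fc_matrix(rois: RoiTimeSeries, scheme: WindowScheme) -> np.ndarray:
    """Mean over windows of the windowed correlation, for every ROI pair.

    Companion quantity to :func:`roi_variability_matrix` used by the
    variability-FC coupling check; diagonal is 1.
    """
    if rois.n_regions < 2:
        raise ValueError("need at least 2 regions")
    r = _pairwise_windowed_stats(rois.values, scheme)
    return r.mean(axis=0)


def seed_variability_map(
    vol: BoldVolumeSeries,
    seed: SeedDefinition,
    scheme: WindowScheme,
    block_size: int = 4096,
) -> VariabilityMap:
    """Voxel-wise I between the seed neighborhood mean and every masked voxel.

    Voxels inside the 7-voxel seed neighborhood are fixed at 0.  Voxels whose
    series produce a degenerate (zero-variance) window are masked out of the
    map (NaN) and counted.  The computation streams over flat blocks of
    ``block_size`` voxels so memory stays bounded; block boundaries do not
    affect the result.
    """
    neighborhood = seed_neighborhood(vol, seed)
    seed_series = np.stack([vol.data[idx] for idx in neighborhood]).mean(axis=0)
    T = vol.n_volumes
    m = scheme.n_windows(T)
    if m < 2:
        raise InsufficientDataError("need at least 2 windows for I")

    L, step = scheme.length_tr, scheme.step_tr
    starts = np.arange(m) * step
    s = seed_series
    cs1 = np.concatenate([[0.0], np.cumsum(s)])
    cs2 = np.concatenate([[0.0], np.cumsum(s * s)])
    s_sum = cs1[starts + L] - cs1[starts]
    s_var = (cs2[starts + L] - cs2[starts]) - s_sum * s_sum / L
    if np.any(s_var <= 1e-12 * max(float(np.max(cs2)), 1.0)):
        raise DegenerateWindowError("seed series has a zero-variance window")

    mask_idx = np.flatnonzero(vol.brain_mask.ravel())
    flat = vol.data.reshape(-1, T)
    out = np.full(vol.brain_mask.size, np.nan)
    n_masked_out = 0
    for lo in range(0, mask_idx.size, block_size):
        sel = mask_idx[lo : lo + block_size]
        x = flat[sel].T  # [T x B]
        c1 = np.vstack([np.zeros((1, x.shape[1])), np.cumsum(x, axis=0)])
        c2 = np.vstack([np.zeros((1, x.shape[1])), np.cumsum(x * x, axis=0)])
        cxy = np.vstack([np.zeros((1, x.shape[1])), np.cumsum(x * s[:, None], axis=0)])
        S1 = c1[starts + L] - c1[starts]
        S2 = c2[starts + L] - c2[starts]
        Sxy = cxy[starts + L] - cxy[starts]
        var = S2 - S1 * S1 / L
        ok = ~np.any(var <= 1e-12 * np.maximum(S2, 1.0), axis=0)
        n_masked_out += int(np.sum(~ok))
        cov = Sxy - S1 * s_sum[:, None] / L
        with np.errstate(invalid="ignore", divide="ignore"):
            r = cov / np.sqrt(var * s_var[:, None])
        r = np.clip(r, -1.0, 1.0)
        d = np.diff(r, axis=0)
        vals = np.mean(d * d, axis=0)
        vals[~ok] = np.nan
        out[sel] = vals
    if n_masked_out:
        logger.warning("seed_variability_map: %d voxels masked out (degenerate windows)", n_masked_out)
    data = out.reshape(vol.brain_mask.shape)
    for idx in neighborhood:
        data[idx] = 0.0
    return VariabilityMap(
        data=data,
        affine=vol.affine,
        seed_label=seed.label,
        scheme=scheme,
        n_masked_out=n_masked_out,
    )
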