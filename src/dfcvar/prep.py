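"""Temporal preprocessing of BOLD series: band-pass filtering, nuisance
regression, and head-motion quality control.

The stages mirror common resting-state practice for already-normalized data:
a zero-phase Butterworth band-pass (0.01-0.08 Hz), then least-squares
removal of white-matter, CSF, linear-trend, and 12-motion-parameter
confounds.  The global mean signal is deliberately never regressed:
global-signal removal can distort between-group comparisons of
inter-regional correlation in clinical cohorts.  Subjects move; sessions
with a maximum translation above 3.0 mm or rotation above 3.0 degrees are
excluded, and framewise displacement (Power convention, 50 mm sphere) is
reported for the rest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

TRANSLATION_LIMIT_MM = 3.0
ROTATION_LIMIT_DEG = 3.0
FD_SPHERE_RADIUS_MM = 50.0


class DegeneracyError(ValueError):
    """Raised when a confound design matrix is rank deficient."""


@dataclass
class ConfoundSet:
    """Nuisance regressors for one scanning session.

    ``motion12`` holds the six rigid-body parameters and their backward
    differences (first row of the differences defined as 0).
    """

    wm_mean: np.ndarray
    csf_mean: np.ndarray
    motion12: np.ndarray
    linear_trend: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.wm_mean = np.asarray(self.wm_mean, dtype=np.float64).ravel()
        self.csf_mean = np.asarray(self.csf_mean, dtype=np.float64).ravel()
        self.motion12 = np.asarray(self.motion12, dtype=np.float64)
        T = self.wm_mean.size
        if self.motion12.shape != (T, 12):
            raise ValueError(f"motion12 must be [T x 12] with T={T}")
        if self.csf_mean.size != T:
            raise ValueError("confound columns must share length T")
        if self.linear_trend is None:
            self.linear_trend = np.arange(T, dtype=np.float64)
        self.linear_trend = np.asarray(self.linear_trend, dtype=np.float64).ravel()
        if self.linear_trend.size != T:
            raise ValueError("linear_trend must have length T")

    @classmethod
    def from_motion(
        cls, motion6: np.ndarray, wm_mean: np.ndarray, csf_mean: np.ndarray
    ) -> "ConfoundSet":
        """Build the 12-parameter motion block from raw 6-parameter traces."""
        motion6 = _check_motion(motion6)
        deriv = np.vstack([np.zeros((1, 6)), np.diff(motion6, axis=0)])
        return cls(
            wm_mean=wm_mean, csf_mean=csf_mean, motion12=np.hstack([motion6, deriv])
        )

    def design_matrix(self) -> np.ndarray:
        return np.column_stack(
            [self.wm_mean, self.csf_mean, self.linear_trend, self.motion12]
        )


@dataclass(frozen=True)
class MotionQcReport:
    """Per-session motion summary and the exclusion decision."""

    max_translation_mm: float
    max_rotation_deg: float
    mean_fd_mm: float
    excluded: bool


def _check_motion(motion6: np.ndarray) -> np.ndarray:
    motion6 = np.asarray(motion6, dtype=np.float64)
    if motion6.ndim != 2 or motion6.shape[1] != 6:
        raise ValueError("motion parameters must be a [T x 6] matrix")
    return motion6


def bandpass(
    series: np.ndarray,
    tr_seconds: float,
    low_hz: float = 0.01,
    high_hz: float = 0.08,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass applied per column.

    Columns are demeaned first and the output is left zero-mean, so constant
    series map to zero.  The filter runs forward and backward (``filtfilt``)
    to cancel phase distortion, which matters because windowed correlations
    are sensitive to relative lags.
    """
    series = np.asarray(series, dtype=np.float64)
    squeeze = series.ndim == 1
    if squeeze:
        series = series[:, None]
    nyquist = 0.5 / tr_seconds
    if not (0 < low_hz < high_hz):
        raise ValueError("need 0 < low_hz < high_hz")
    if high_hz >= nyquist:
        raise ValueError(f"high_hz={high_hz} must be below Nyquist {nyquist:.4f} Hz")
    T = series.shape[0]
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=1.0 / tr_seconds, output="sos")
    padlen = min(3 * (2 * order + 1), T - 1)
    if T <= padlen:
        raise ValueError(f"series too short ({T} points) for the filter")
    centered = series - series.mean(axis=0, keepdims=True)
    out = signal.sosfiltfilt(sos, centered, axis=0, padlen=padlen)
    out = out - out.mean(axis=0, keepdims=True)
    return out[:, 0] if squeeze else out


def regress_confounds(series: np.ndarray, confounds: ConfoundSet) -> np.ndarray:
    """Residualize each column on an intercept plus the confound columns.

    The global mean signal is never part of the design.  A rank-deficient
    design (e.g. a duplicated confound) raises ``DegeneracyError`` naming
    the collinear columns rather than silently projecting.
    """
    series = np.asarray(series, dtype=np.float64)
    squeeze = series.ndim == 1
    if squeeze:
        series = series[:, None]
    X = confounds.design_matrix()
    T = series.shape[0]
    if X.shape[0] != T:
        raise ValueError("confound length must match series length")
    design = np.column_stack([np.ones(T), X])
    # scale-invariant rank check on the centered, normalized design
    norms = np.linalg.norm(design, axis=0)
    rank = np.linalg.matrix_rank(design / np.maximum(norms, 1e-300), tol=1e-8)
    if rank < design.shape[1]:
        names = ["intercept", "wm", "csf", "trend"] + [f"motion{i}" for i in range(12)]
        raise DegeneracyError(
            f"confound design is rank deficient (rank {rank} < {design.shape[1]}); "
            f"columns: {names[:design.shape[1]]}"
        )
    beta, *_ = np.linalg.lstsq(design, series, rcond=None)
    resid = series - design @ beta
    return resid.ravel() if squeeze else resid


def framewise_displacement(motion6: np.ndarray) -> np.ndarray:
    """Framewise displacement per volume (Power convention).

    ``FD_t = sum |d translations| + 50 mm * sum |d rotations(rad)|`` with the
    first frame defined as 0.  Rotations must be in radians; the 50 mm factor
    converts angle to arc displacement on a head-sized sphere.
    """
    motion6 = _check_motion(motion6)
    d = np.abs(np.diff(motion6, axis=0))
    fd = d[:, :3].sum(axis=1) + FD_SPHERE_RADIUS_MM * d[:, 3:].sum(axis=1)
    return np.concatenate([[0.0], fd])


def qc_exclude(motion6: np.ndarray) -> MotionQcReport:
    """Flag a session for exclusion on gross head motion.

    Translations are assessed as the maximum absolute displacement per axis
    relative to the reference volume; rotations likewise, converted to
    degrees.  A session exceeding 3.0 mm or 3.0 degrees is excluded.
    """
    motion6 = _check_motion(motion6)
    max_trans = float(np.max(np.abs(motion6[:, :3])))
    max_rot_deg = float(np.degrees(np.max(np.abs(motion6[:, 3:]))))
    fd = framewise_displacement(motion6)
    return MotionQcReport(
        max_translation_mm=max_trans,
        max_rotation_deg=max_rot_deg,
        mean_fd_mm=float(fd.mean()),
        excluded=(max_trans > TRANSLATION_LIMIT_MM) or (max_rot_deg > ROTATION_LIMIT_DEG),
    )
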