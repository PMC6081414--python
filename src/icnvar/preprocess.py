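"""Temporal filtering and head-motion quality control.

Covers the in-scope preprocessing computations: zero-phase band-pass
filtering of time series into the low-frequency BOLD band (0.01-0.1 Hz),
framewise displacement (FD) from rigid-body motion parameters, and
exclusion of subjects whose mean FD exceeds a threshold.

The band-pass is a second-order Butterworth applied forward and backward
(``scipy.signal.filtfilt``).  Zero-phase filtering matters here: any phase
lag introduced by the filter would propagate directly into the
instantaneous-phase estimates computed downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import signal

from .records import SubjectRecord


@dataclass(frozen=True)
class FDSeries:
    """Per-frame framewise displacement in mm; the first frame is 0 by definition."""

    values: np.ndarray

    @property
    def mean_fd(self) -> float:
        return float(np.mean(self.values))


def bandpass(
    series: np.ndarray,
    tr_seconds: float,
    f_lo: float = 0.01,
    f_hi: float = 0.1,
    order: int = 2,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the first axis.

    Accepts a 1D series or a T x N matrix (columns filtered independently).
    Raises if the band is not strictly inside (0, Nyquist) or the series is
    too short for the forward-backward pass.
    """
    series = np.asarray(series, dtype=float)
    if tr_seconds <= 0:
        raise ValueError("tr_seconds must be positive")
    nyquist = 0.5 / tr_seconds
    if not (0.0 < f_lo < f_hi < nyquist):
        raise ValueError(
            f"band [{f_lo}, {f_hi}] Hz must satisfy 0 < f_lo < f_hi < Nyquist ({nyquist:g} Hz)"
        )
    sos = signal.butter(order, [f_lo, f_hi], btype="bandpass", fs=1.0 / tr_seconds, output="sos")
    # filtfilt pads by reflection; require a comfortable margin over the pad.
    padlen = 3 * (2 * order + 1)
    if series.shape[0] <= padlen:
        raise ValueError(f"series length {series.shape[0]} too short for filtering (need > {padlen})")
    return signal.sosfiltfilt(sos, series, axis=0, padlen=padlen)


def framewise_displacement(
    motion: np.ndarray,
    head_radius_mm: float = 50.0,
    rotations_in_degrees: bool = False,
) -> FDSeries:
    """Power-style framewise displacement from a T x 6 motion trace.

    Columns 0-2 are translations in mm, columns 3-5 rotations (radians
    unless ``rotations_in_degrees``).  FD(t) is the sum of absolute
    frame-to-frame changes of the six parameters, rotations converted to
    arc length on a sphere of ``head_radius_mm``.  FD depends only on
    frame-to-frame differentials, so constant offsets leave it unchanged.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion trace must be a T x 6 array (3 translations + 3 rotations)")
    if motion.shape[0] < 2:
        raise ValueError("need at least 2 frames to compute FD")
    if not np.isfinite(motion).all():
        raise ValueError("motion parameters contain non-finite values")
    rot = np.deg2rad(motion[:, 3:]) if rotations_in_degrees else motion[:, 3:]
    d_trans = np.abs(np.diff(motion[:, :3], axis=0)).sum(axis=1)
    d_rot = np.abs(np.diff(rot, axis=0)).sum(axis=1)
    fd = np.concatenate([[0.0], d_trans + head_radius_mm * d_rot])
    return FDSeries(values=fd)


def exclude_high_motion(
    records: list[SubjectRecord],
    threshold_mm: float = 0.5,
) -> tuple[list[SubjectRecord], list[SubjectRecord]]:
    """Partition subjects by mean FD: retained (mean_fd <= threshold) vs excluded.

    The comparator is strict on the excluded side, so a subject sitting
    exactly at the threshold is retained.
    """
    retained, excluded = [], []
    for rec in records:
        if rec.mean_fd is None or not np.isfinite(rec.mean_fd):
            raise ValueError(f"subject {rec.subject_id} has no valid mean_fd")
        (excluded if rec.mean_fd > threshold_mm else retained).append(rec)
    return retained, excluded


def load_motion_txt(path) -> np.ndarray:
    """Read a 6-column whitespace-delimited motion parameter file."""
    arr = np.loadtxt(Path(path))
    if arr.ndim != 2 or arr.shape[1] != 6:
        raise ValueError(f"{path}: expected 6 columns of motion parameters")
    return arr


def save_motion_txt(motion: np.ndarray, path) -> None:
    np.savetxt(Path(path), np.asarray(motion, dtype=float), fmt="%.6f")
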