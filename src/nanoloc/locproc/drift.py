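"""Stage-drift estimation and correction.

Drift is represented per frame as the displacement (dx, dy) of the sample
relative to a reference frame; correcting subtracts that displacement from
every localization of the frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.registration import phase_cross_correlation

from ..errors import DriftDomainError, NanolocError


@dataclass
class DriftModel:
    """Per-frame displacement table; ``dx[reference_frame] == 0``."""

    dx: np.ndarray  # nm, one entry per frame 0..n-1
    dy: np.ndarray
    reference_frame: int = 0
    low_confidence: bool = False

    def __post_init__(self):
        self.dx = np.asarray(self.dx, dtype=np.float64)
        self.dy = np.asarray(self.dy, dtype=np.float64)
        if self.dx.shape != self.dy.shape or self.dx.ndim != 1:
            raise NanolocError("dx and dy must be 1-D arrays of equal length")
        if not (0 <= self.reference_frame < len(self.dx)):
            raise NanolocError("reference frame outside drift domain")
        if abs(self.dx[self.reference_frame]) > 1e-9 or abs(self.dy[self.reference_frame]) > 1e-9:
            raise NanolocError("displacement at the reference frame must be zero")

    @property
    def n_frames(self) -> int:
        return len(self.dx)

    @classmethod
    def zero(cls, n_frames: int) -> "DriftModel":
        return cls(np.zeros(n_frames), np.zeros(n_frames))

    @classmethod
    def linear(cls, n_frames: int, total_dx: float, total_dy: float) -> "DriftModel":
        """Linear drift reaching (total_dx, total_dy) at the last frame."""
        t = np.arange(n_frames) / max(n_frames - 1, 1)
        return cls(total_dx * t, total_dy * t)

    def displacement(self, frames) -> np.ndarray:
        frames = np.asarray(frames, dtype=np.int64)
        if len(frames) and (frames.min() < 0 or frames.max() >= self.n_frames):
            raise DriftDomainError(
                f"frame outside drift domain [0, {self.n_frames - 1}]"
            )
        return np.column_stack([self.dx[frames], self.dy[frames]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"frame": np.arange(self.n_frames), "dx": self.dx, "dy": self.dy}
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "DriftModel":
        df = pd.read_csv(path)
        return cls(df["dx"].to_numpy(), df["dy"].to_numpy())


def apply_drift(table: pd.DataFrame, drift: DriftModel) -> pd.DataFrame:
    """Shift each localization by the drift of its frame (simulation forward model)."""
    disp = drift.displacement(table["frame"].to_numpy())
    out = table.copy()
    out["x"] = out["x"] + disp[:, 0]
    out["y"] = out["y"] + disp[:, 1]
    return out


def correct_drift(table: pd.DataFrame, drift: DriftModel) -> pd.DataFrame:
    """Remove drift: exact inverse of :func:`apply_drift`."""
    disp = drift.displacement(table["frame"].to_numpy())
    out = table.copy()
    out["x"] = out["x"] - disp[:, 0]
    out["y"] = out["y"] - disp[:, 1]
    return out


def register_second_channel(table_b: pd.DataFrame, drift_a: DriftModel) -> pd.DataFrame:
    """Apply the first channel's drift model to the second channel's table."""
    return correct_drift(table_b, drift_a)


def _moving_average(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with truncated (not padded) windows at the edges."""
    if window <= 1:
        return values
    half = window // 2
    csum = np.concatenate([[0.0], np.cumsum(values)])
    idx = np.arange(len(values))
    lo = np.maximum(0, idx - half)
    hi = np.minimum(len(values), idx + (window - half))
    return (csum[hi] - csum[lo]) / (hi - lo)


def estimate_drift_fiducials(
    table: pd.DataFrame,
    fiducial_ids,
    n_frames: int | None = None,
    reference_frame: int = 0,
    smooth_window: int = 10,
    fiducial_column: str = "fiducial_id",
) -> DriftModel:
    """Estimate drift from static fiducial markers.

    For each fiducial the displacement at frame f is its position minus its
    position at the reference frame; per-frame drift is the mean over
    fiducials, linearly interpolated across frames where a fiducial was not
    localized, then smoothed with a moving average.
    """
    fiducial_ids = list(fiducial_ids)
    if not fiducial_ids:
        raise NanolocError("no fiducials given")
    if fiducial_column not in table.columns:
        raise NanolocError(f"table lacks a {fiducial_column!r} column")
    if n_frames is None:
        n_frames = int(table["frame"].max()) + 1

    frames_axis = np.arange(n_frames)
    per_fid = np.full((len(fiducial_ids), n_frames, 2), np.nan)
    for i, fid in enumerate(fiducial_ids):
        rows = table[table[fiducial_column] == fid]
        if len(rows) == 0:
            raise NanolocError(f"fiducial {fid} has no localizations")
        if len(rows) < 0.5 * n_frames:
            raise NanolocError(
                f"fiducial {fid} localized in fewer than 50% of frames"
            )
        f = rows["frame"].to_numpy()
        for axis, col in enumerate(("x", "y")):
            per_fid[i, :, axis] = np.interp(frames_axis, f, rows[col].to_numpy())

    traj = np.nanmean(per_fid, axis=0)  # (n_frames, 2)
    traj[:, 0] = _moving_average(traj[:, 0], smooth_window)
    traj[:, 1] = _moving_average(traj[:, 1], smooth_window)
    dx = traj[:, 0] - traj[reference_frame, 0]
    dy = traj[:, 1] - traj[reference_frame, 1]
    return DriftModel(dx, dy, reference_frame=reference_frame)


def _render(xy: np.ndarray, bins_x: np.ndarray, bins_y: np.ndarray) -> np.ndarray:
    img, _, _ = np.histogram2d(xy[:, 0], xy[:, 1], bins=[bins_x, bins_y])
    return img


def estimate_drift_xcorr(
    table: pd.DataFrame,
    segment_frames: int,
    render_pixel: float = 20.0,
    n_frames: int | None = None,
    min_locs_per_segment: int = 100,
    upsample: int = 50,
    peak_zscore_threshold: float = 8.0,
) -> DriftModel:
    """Estimate drift by cross-correlating super-resolved segment images.

    The acquisition is cut into temporal segments of ``segment_frames``
    frames; each is rendered as a 2-D localization histogram at
    ``render_pixel`` nm, and the shift of segment k relative to segment 0 is
    the sub-pixel peak of their cross-correlation. Per-frame drift is the
    linear interpolation between segment midpoints. On featureless (CSR)
    data the correlation peak is not salient and the model is flagged
    ``low_confidence``.
    """
    if n_frames is None:
        n_frames = int(table["frame"].max()) + 1
    if segment_frames <= 0:
        raise NanolocError("segment_frames must be positive")
    n_segments = n_frames // segment_frames
    if n_segments < 2:
        raise NanolocError("need at least two temporal segments")

    pad = 2 * render_pixel
    x0, x1 = table["x"].min() - pad, table["x"].max() + pad
    y0, y1 = table["y"].min() - pad, table["y"].max() + pad
    bins_x = np.arange(x0, x1 + render_pixel, render_pixel)
    bins_y = np.arange(y0, y1 + render_pixel, render_pixel)

    frames = table["frame"].to_numpy()
    xy = table[["x", "y"]].to_numpy()

    midpoints = []
    shifts = []
    low_confidence = False
    ref_img = None
    for k in range(n_segments):
        lo, hi = k * segment_frames, (k + 1) * segment_frames
        if k == n_segments - 1:
            hi = n_frames  # last segment absorbs the remainder
        sel = (frames >= lo) & (frames < hi)
        if sel.sum() < min_locs_per_segment:
            raise NanolocError(
                f"segment {k} has {int(sel.sum())} localizations "
                f"(< {min_locs_per_segment})"
            )
        img = _render(xy[sel], bins_x, bins_y)
        midpoints.append((lo + hi - 1) / 2)
        if k == 0:
            ref_img = img
            shifts.append((0.0, 0.0))
            continue
        shift, _error, _phase = phase_cross_correlation(
            ref_img, img, upsample_factor=upsample, normalization=None
        )
        # salience: without shared structure the correlation map is noise and
        # its maximum is not an outlier relative to the map's distribution
        corr = np.real(
            np.fft.ifft2(np.fft.fft2(ref_img) * np.conj(np.fft.fft2(img)))
        )
        spread = corr.std()
        if spread == 0 or (corr.max() - corr.mean()) / spread < peak_zscore_threshold:
            low_confidence = True
        # image axis 0 is x here (histogram2d convention); shift maps ref->img
        shifts.append((-shift[0] * render_pixel, -shift[1] * render_pixel))

    midpoints = np.asarray(midpoints)
    shifts = np.asarray(shifts)
    frames_axis = np.arange(n_frames)

    def interp_extrap(y: np.ndarray) -> np.ndarray:
        out = np.interp(frames_axis, midpoints, y)
        # linear extrapolation beyond the first/last segment midpoints
        left = frames_axis < midpoints[0]
        right = frames_axis > midpoints[-1]
        slope0 = (y[1] - y[0]) / (midpoints[1] - midpoints[0])
        slope1 = (y[-1] - y[-2]) / (midpoints[-1] - midpoints[-2])
        out[left] = y[0] + slope0 * (frames_axis[left] - midpoints[0])
        out[right] = y[-1] + slope1 * (frames_axis[right] - midpoints[-1])
        return out

    dx = interp_extrap(shifts[:, 0])
    dy = interp_extrap(shifts[:, 1])
    model = DriftModel(dx - dx[0], dy - dy[0], reference_frame=0)
    model.low_confidence = low_confidence
    return model
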