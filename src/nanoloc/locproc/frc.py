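"""Fourier Ring Correlation resolution estimate.

The localization table is split into two statistically independent halves,
each rendered as a 2-D histogram image; the correlation of their Fourier
transforms is averaged over rings of constant spatial frequency and the
resolution is read where the (smoothed) curve first drops below 1/7.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..errors import NanolocError

FRC_THRESHOLD = 1.0 / 7.0


@dataclass
class FRCCurve:
    frequency: np.ndarray  # 1/nm, strictly increasing
    correlation: np.ndarray  # per ring, in [-1, 1]
    resolution: float  # nm; math.inf when the curve never crosses 1/7

    @property
    def resolved(self) -> bool:
        return math.isfinite(self.resolution)


def render_image(
    table: pd.DataFrame, render_pixel: float, extent=None
) -> np.ndarray:
    """2-D localization histogram at ``render_pixel`` nm per pixel."""
    if extent is None:
        extent = (
            table["x"].min(), table["x"].max(),
            table["y"].min(), table["y"].max(),
        )
    x0, x1, y0, y1 = extent
    bins_x = np.arange(x0, x1 + render_pixel, render_pixel)
    bins_y = np.arange(y0, y1 + render_pixel, render_pixel)
    img, _, _ = np.histogram2d(
        table["x"].to_numpy(), table["y"].to_numpy(), bins=[bins_x, bins_y]
    )
    return img


def frc_curve(img_a: np.ndarray, img_b: np.ndarray, render_pixel: float) -> FRCCurve:
    """Ring-averaged Fourier correlation of two equally shaped images."""
    if img_a.shape != img_b.shape:
        raise NanolocError("half-images must have identical shapes")
    if img_a.sum() == 0 or img_b.sum() == 0:
        raise NanolocError("empty half-image")
    # crop to a common square so rings are isotropic
    n = min(img_a.shape)
    img_a = img_a[:n, :n]
    img_b = img_b[:n, :n]

    fa = np.fft.fftshift(np.fft.fft2(img_a))
    fb = np.fft.fftshift(np.fft.fft2(img_b))

    yy, xx = np.indices((n, n))
    center = n // 2
    radius = np.hypot(yy - center, xx - center).astype(np.int64)
    n_rings = n // 2

    num = np.real(fa * np.conj(fb))
    den_a = np.abs(fa) ** 2
    den_b = np.abs(fb) ** 2

    rings = np.arange(1, n_rings)
    flat = radius.ravel()
    num_r = np.bincount(flat, weights=num.ravel(), minlength=n_rings)[1:n_rings]
    a_r = np.bincount(flat, weights=den_a.ravel(), minlength=n_rings)[1:n_rings]
    b_r = np.bincount(flat, weights=den_b.ravel(), minlength=n_rings)[1:n_rings]
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = num_r / np.sqrt(a_r * b_r)
    corr = np.clip(np.nan_to_num(corr), -1.0, 1.0)
    freq = rings / (n * render_pixel)

    resolution = _threshold_crossing(freq, corr)
    return FRCCurve(frequency=freq, correlation=corr, resolution=resolution)


def _threshold_crossing(freq: np.ndarray, corr: np.ndarray) -> float:
    """First 1/7 crossing of the 3-bin-smoothed curve, linearly interpolated."""
    kernel = np.ones(3) / 3
    smooth = np.convolve(np.pad(corr, 1, mode="edge"), kernel, mode="valid")
    below = smooth < FRC_THRESHOLD
    idx = np.argmax(below) if below.any() else None
    if idx is None or idx == 0:
        if below.all():
            return float(1.0 / freq[0])
        return math.inf
    f0, f1 = freq[idx - 1], freq[idx]
    c0, c1 = smooth[idx - 1], smooth[idx]
    f_cross = f0 + (c0 - FRC_THRESHOLD) * (f1 - f0) / (c0 - c1)
    return float(1.0 / f_cross)


def frc_resolution(
    table: pd.DataFrame,
    render_pixel: float = 10.0,
    split: str = "even_odd_frames",
    min_locs: int = 2000,
    rng: np.random.Generator | None = None,
) -> FRCCurve:
    """Split a table in two halves and estimate the image resolution.

    ``split`` is ``"even_odd_frames"`` (default, robust to blinking) or
    ``"random_halves"``.
    """
    if len(table) < min_locs:
        raise NanolocError(f"need >= {min_locs} localizations for FRC")
    if split == "even_odd_frames":
        even = table["frame"] % 2 == 0
        half_a, half_b = table[even], table[~even]
    elif split == "random_halves":
        rng = np.random.default_rng() if rng is None else rng
        pick = rng.random(len(table)) < 0.5
        half_a, half_b = table[pick], table[~pick]
    else:
        raise NanolocError(f"unknown split: {split!r}")
    if len(half_a) == 0 or len(half_b) == 0:
        raise NanolocError("one half of the split is empty")

    extent = (table["x"].min(), table["x"].max(), table["y"].min(), table["y"].max())
    img_a = render_image(half_a, render_pixel, extent)
    img_b = render_image(half_b, render_pixel, extent)
    return frc_curve(img_a, img_b, render_pixel)
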