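"""Confocal foci-density and phagocytic-index quantifications."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import h_maxima

from .errors import NanolocError


@dataclass
class FociResult:
    positions: np.ndarray  # (n, 2) pixel coordinates (row, col)
    count: int
    cell_area_um2: float
    density_per_um2: float


def detect_foci(image: np.ndarray, noise_tolerance: float) -> np.ndarray:
    """Detect intensity maxima with prominence above ``noise_tolerance``.

    A focus is a local maximum (8-connected) standing out from its
    surrounding flooded region by more than the tolerance; a flat plateau
    yields one focus at its lowest-index pixel. Returns (n, 2) integer
    (row, col) positions.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise NanolocError("detect_foci expects a 2-D image")
    if noise_tolerance <= 0:
        raise NanolocError("noise_tolerance must be positive")
    if np.ptp(image) <= noise_tolerance:
        return np.empty((0, 2), dtype=np.int64)

    mask = h_maxima(image, noise_tolerance, footprint=np.ones((3, 3)))
    labels, n = ndimage.label(mask, structure=np.ones((3, 3)))
    positions = []
    for lab in range(1, n + 1):
        rows, cols = np.nonzero(labels == lab)
        k = np.argmin(rows * image.shape[1] + cols)  # lowest flat index of the plateau
        positions.append((rows[k], cols[k]))
    return np.array(positions, dtype=np.int64).reshape(-1, 2)


def foci_density(
    foci: np.ndarray, mask: np.ndarray, pixel_size_um: float
) -> FociResult:
    """Foci per um^2 of the masked cell area; foci outside the mask are excluded."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise NanolocError("empty cell mask")
    if pixel_size_um <= 0:
        raise NanolocError("pixel_size_um must be positive")
    foci = np.asarray(foci, dtype=np.int64).reshape(-1, 2)
    inside = foci[mask[foci[:, 0], foci[:, 1]]] if len(foci) else foci
    area_um2 = float(mask.sum()) * pixel_size_um**2
    return FociResult(
        positions=inside,
        count=len(inside),
        cell_area_um2=area_um2,
        density_per_um2=len(inside) / area_um2,
    )


def phagocytic_index(
    p_cond: float, p_cond_cytd: float, p_ctrl: float, p_ctrl_cytd: float
) -> float:
    """CytD-background-subtracted engulfment, normalized to the untreated control.

    index = (p_cond - p_cond_cytd) / (p_ctrl - p_ctrl_cytd); a negative
    numerator is clamped to 0 with a warning, a non-positive denominator is
    an error. Percentages must lie in [0, 100].
    """
    for value in (p_cond, p_cond_cytd, p_ctrl, p_ctrl_cytd):
        if not 0 <= value <= 100:
            raise NanolocError("percentages must be in [0, 100]")
    denominator = p_ctrl - p_ctrl_cytd
    if denominator <= 0:
        raise NanolocError("control engulfment does not exceed its CytD background")
    numerator = p_cond - p_cond_cytd
    if numerator < 0:
        warnings.warn("condition engulfment below CytD background; clamping to 0")
        numerator = 0.0
    return numerator / denominator
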