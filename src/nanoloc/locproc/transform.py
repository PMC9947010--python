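"""Affine channel registration (chromatic-aberration correction).

The transform mapping channel A bead positions onto channel B is fit by
linear least squares on matched pairs of multi-color bead localizations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..errors import NanolocError


@dataclass
class AffineTransform:
    """p -> matrix @ p + offset, coordinates in nm."""

    matrix: np.ndarray  # (2, 2)
    offset: np.ndarray  # (2,)
    residual_rms: float = 0.0

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.float64).reshape(2, 2)
        self.offset = np.asarray(self.offset, dtype=np.float64).reshape(2)
        if abs(np.linalg.det(self.matrix)) <= 1e-12:
            raise NanolocError("affine linear part is singular")

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(2), np.zeros(2))

    def __call__(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=np.float64) @ self.matrix.T + self.offset

    def inverse(self) -> "AffineTransform":
        inv = np.linalg.inv(self.matrix)
        return AffineTransform(inv, -inv @ self.offset)

    def to_params(self) -> np.ndarray:
        """Six numbers: a11 a12 a21 a22 tx ty."""
        return np.concatenate([self.matrix.ravel(), self.offset])

    @classmethod
    def from_params(cls, params) -> "AffineTransform":
        params = np.asarray(params, dtype=np.float64)
        return cls(params[:4].reshape(2, 2), params[4:6])

    def write_text(self, path) -> None:
        np.savetxt(path, self.to_params()[None, :])

    @classmethod
    def read_text(cls, path) -> "AffineTransform":
        return cls.from_params(np.loadtxt(path).ravel())


def fit_channel_transform(points_a, points_b) -> AffineTransform:
    """Least-squares affine t with t(A_i) ~= B_i over matched bead pairs.

    Requires at least 3 non-collinear pairs; reports the residual RMS in nm.
    """
    a = np.asarray(points_a, dtype=np.float64)
    b = np.asarray(points_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 2:
        raise NanolocError("matched point sets must both be (n, 2)")
    if len(a) < 3:
        raise NanolocError("need at least 3 matched pairs")
    design = np.column_stack([a, np.ones(len(a))])
    if np.linalg.matrix_rank(design) < 3:
        raise NanolocError("matched pairs are collinear")
    coeffs, *_ = np.linalg.lstsq(design, b, rcond=None)
    matrix = coeffs[:2].T
    offset = coeffs[2]
    residuals = design @ coeffs - b
    rms = float(np.sqrt(np.mean(np.sum(residuals**2, axis=1))))
    return AffineTransform(matrix, offset, residual_rms=rms)


def apply_transform(table: pd.DataFrame, transform: AffineTransform) -> pd.DataFrame:
    """Map the x, y columns of a localization table through an affine transform."""
    out = table.copy()
    mapped = transform(out[["x", "y"]].to_numpy())
    out["x"] = mapped[:, 0]
    out["y"] = mapped[:, 1]
    return out
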