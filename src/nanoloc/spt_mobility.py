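"""Single-particle-tracking mobility analysis.

Localizations are linked into tracks, the mean jump distance (MJD) of each
track — the average distance travelled between consecutive frames — is
computed, the pooled MJD histogram is decomposed into a low- and a
high-mobility Gaussian component, and the high-mobility area fraction
(R-value) is derived. Tracks are classified low/high at a 140 nm MJD
threshold.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.spatial import cKDTree

from .errors import (
    DegenerateFitError,
    FitFailureError,
    NanolocError,
    UndefinedStatisticError,
)

MIN_TRACK_LOCALIZATIONS = 11  # "more than 10 localizations" kept
MOBILITY_THRESHOLD_NM = 140.0
DEFAULT_BIN_WIDTH_NM = 10.0
DEFAULT_HIST_RANGE_NM = (0.0, 400.0)


@dataclass
class Track:
    """Frame-ordered positions of one particle."""

    id: int
    frames: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=np.int64)
        self.x = np.asarray(self.x, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.float64)
        if not (len(self.frames) == len(self.x) == len(self.y)):
            raise NanolocError("frames/x/y length mismatch")
        if len(self.frames) > 1 and not (np.diff(self.frames) > 0).all():
            raise NanolocError("track frames must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class TrackSet:
    tracks: list[Track]
    population: np.ndarray | None = None  # optional ground-truth labels

    def __len__(self) -> int:
        return len(self.tracks)

    def __iter__(self):
        return iter(self.tracks)

    def mjds(self) -> np.ndarray:
        """Per-track MJDs, skipping tracks without a consecutive-frame pair."""
        values = []
        for track in self.tracks:
            try:
                values.append(compute_mjd(track))
            except UndefinedStatisticError:
                continue
        return np.asarray(values)

    def to_frame(self) -> pd.DataFrame:
        parts = [
            pd.DataFrame({"track_id": t.id, "frame": t.frames, "x": t.x, "y": t.y})
            for t in self.tracks
        ]
        if not parts:
            return pd.DataFrame(columns=["track_id", "frame", "x", "y"])
        return pd.concat(parts, ignore_index=True)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def link_tracks(
    table: pd.DataFrame,
    max_link_distance: float,
    max_frame_gap: int = 0,
) -> TrackSet:
    """Greedy nearest-neighbor frame-to-frame linking.

    In each frame, candidate (open track end, localization) pairs within
    ``max_link_distance`` are assigned in ascending distance order, ties
    broken by lower localization id; unmatched localizations open new
    tracks, and ends unmatched for more than ``max_frame_gap`` frames close.
    """
    if max_link_distance < 0 or max_frame_gap < 0:
        raise NanolocError("linking parameters must be non-negative")
    if "channel" in table.columns and table["channel"].nunique() > 1:
        raise NanolocError("link_tracks requires a single channel")

    frames = table["frame"].to_numpy()
    xy = table[["x", "y"]].to_numpy()
    ids = table["id"].to_numpy()
    order = np.argsort(frames, kind="stable")

    t_frames: list[list[int]] = []
    t_x: list[list[float]] = []
    t_y: list[list[float]] = []
    last_frame: list[int] = []
    open_idx: list[int] = []

    start = 0
    while start < len(order):
        f = int(frames[order[start]])
        stop = start
        while stop < len(order) and frames[order[stop]] == f:
            stop += 1
        rows = order[start:stop]

        open_idx = [ti for ti in open_idx if f - last_frame[ti] - 1 <= max_frame_gap]

        matched_rows: set[int] = set()
        matched_tracks: set[int] = set()
        if open_idx:
            ends = np.array([[t_x[ti][-1], t_y[ti][-1]] for ti in open_idx])
            tree = cKDTree(ends)
            pts = xy[rows]
            candidates = []
            for k, neighbors in enumerate(tree.query_ball_point(pts, max_link_distance)):
                for j in neighbors:
                    d = float(np.hypot(*(pts[k] - ends[j])))
                    candidates.append((d, int(ids[rows[k]]), int(rows[k]), open_idx[j]))
            candidates.sort(key=lambda c: (c[0], c[1]))
            for _d, _lid, row, ti in candidates:
                if row in matched_rows or ti in matched_tracks:
                    continue
                matched_rows.add(row)
                matched_tracks.add(ti)
                t_frames[ti].append(f)
                t_x[ti].append(xy[row, 0])
                t_y[ti].append(xy[row, 1])
                last_frame[ti] = f

        for row in rows:
            if int(row) in matched_rows:
                continue
            open_idx.append(len(t_frames))
            t_frames.append([f])
            t_x.append([xy[row, 0]])
            t_y.append([xy[row, 1]])
            last_frame.append(f)

        start = stop

    tracks = [
        Track(id=i, frames=t_frames[i], x=t_x[i], y=t_y[i]) for i in range(len(t_frames))
    ]
    return TrackSet(tracks=tracks)


def filter_tracks(
    trackset: TrackSet, min_localizations: int = MIN_TRACK_LOCALIZATIONS
) -> tuple[TrackSet, int, int]:
    """Keep tracks with at least ``min_localizations`` points (default: >10).

    Returns (filtered set, n_kept, n_removed).
    """
    kept = [t for t in trackset.tracks if len(t) >= min_localizations]
    pop = None
    if trackset.population is not None:
        mask = np.array([len(t) >= min_localizations for t in trackset.tracks])
        pop = np.asarray(trackset.population)[mask]
    return TrackSet(tracks=kept, population=pop), len(kept), len(trackset) - len(kept)


def compute_mjd(track: Track) -> float:
    """Mean Euclidean jump over consecutive-frame pairs of one track.

    Pairs whose frames differ by more than 1 (gap-closed links) are
    excluded; a track without any consecutive pair has no MJD.
    """
    dframe = np.diff(track.frames)
    consecutive = dframe == 1
    if not consecutive.any():
        raise UndefinedStatisticError(f"track {track.id}: no consecutive-frame pair")
    dx = np.diff(track.x)[consecutive]
    dy = np.diff(track.y)[consecutive]
    return float(np.mean(np.hypot(dx, dy)))


def mjd_histogram(
    mjds,
    bin_width: float = DEFAULT_BIN_WIDTH_NM,
    hist_range: tuple[float, float] = DEFAULT_HIST_RANGE_NM,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Left-closed histogram of MJDs plus an overflow count beyond the range.

    Returns (bin_edges, counts, overflow).
    """
    if bin_width <= 0:
        raise NanolocError("bin_width must be positive")
    mjds = np.asarray(mjds, dtype=np.float64)
    if mjds.size == 0:
        raise NanolocError("no MJDs to histogram")
    lo, hi = hist_range
    edges = np.arange(lo, hi + bin_width, bin_width)
    in_range = (mjds >= lo) & (mjds < edges[-1])
    counts, _ = np.histogram(mjds[in_range], bins=edges)
    overflow = int((~in_range).sum())
    return edges, counts, overflow


def _two_gaussians(x, a1, m1, s1, a2, m2, s2):
    return a1 * np.exp(-((x - m1) ** 2) / (2 * s1**2)) + a2 * np.exp(
        -((x - m2) ** 2) / (2 * s2**2)
    )


@dataclass
class TwoGaussianFit:
    """Two-component Gaussian decomposition of an MJD histogram."""

    amp_low: float
    mean_low: float
    sd_low: float
    amp_high: float
    mean_high: float
    sd_high: float
    threshold: float = MOBILITY_THRESHOLD_NM
    degenerate: bool = False
    diagnostics: dict = field(default_factory=dict)

    @property
    def area_low(self) -> float:
        return self.amp_low * self.sd_low * math.sqrt(2 * math.pi)

    @property
    def area_high(self) -> float:
        return self.amp_high * self.sd_high * math.sqrt(2 * math.pi)

    @property
    def r(self) -> float:
        return r_value(self)

    def to_json(self) -> str:
        payload = {
            "low": {"amplitude": self.amp_low, "mean_nm": self.mean_low, "sd_nm": self.sd_low, "area": self.area_low},
            "high": {"amplitude": self.amp_high, "mean_nm": self.mean_high, "sd_nm": self.sd_high, "area": self.area_high},
            "threshold_nm": self.threshold,
            "degenerate": self.degenerate,
            "r_value": None if self.degenerate else self.r,
            "diagnostics": self.diagnostics,
        }
        return json.dumps(payload, indent=2)


def fit_two_gaussians(
    mjds,
    bin_width: float = DEFAULT_BIN_WIDTH_NM,
    hist_range: tuple[float, float] = DEFAULT_HIST_RANGE_NM,
    threshold: float = MOBILITY_THRESHOLD_NM,
    min_samples: int = 200,
    degenerate_area_fraction: float = 0.01,
) -> TwoGaussianFit:
    """Least-squares two-Gaussian fit of the MJD histogram.

    The model ``A1*g(m1,s1) + A2*g(m2,s2)`` is fit to the binned counts;
    components are reported ordered by mean. Initialization uses the moments
    of the sub-samples below/above ``threshold`` (quantile fallback when a
    side is nearly empty); restarts perturb the initial guess. The fit is
    flagged degenerate when either component's area is below
    ``degenerate_area_fraction`` of the total or when the two means are
    closer than twice the wider SD (one population split in two).
    """
    mjds = np.asarray(mjds, dtype=np.float64)
    if mjds.size < min_samples:
        raise NanolocError(f"need >= {min_samples} MJDs to fit (got {mjds.size})")

    edges, counts, _ = mjd_histogram(mjds, bin_width, hist_range)
    centers = 0.5 * (edges[:-1] + edges[1:])

    low_side = mjds[mjds < threshold]
    high_side = mjds[mjds >= threshold]
    if len(low_side) < 2 or len(high_side) < 2:
        q30, q70 = np.quantile(mjds, [0.3, 0.7])
        low_side = mjds[mjds <= q30]
        high_side = mjds[mjds >= q70]

    def moments(sub):
        return float(np.mean(sub)), max(float(np.std(sub)), bin_width / 2)

    m1, s1 = moments(low_side)
    m2, s2 = moments(high_side)
    a1 = max(counts.max() * len(low_side) / mjds.size, 1.0)
    a2 = max(counts.max() * len(high_side) / mjds.size, 1.0)
    p0 = [a1, m1, s1, a2, m2, s2]

    lo, hi = hist_range
    bounds = (
        [0.0, lo, 1e-6, 0.0, lo, 1e-6],
        [np.inf, hi, hi - lo, np.inf, hi, hi - lo],
    )

    rng = np.random.default_rng(0)
    last_error: Exception | None = None
    for attempt in range(5):
        guess = list(p0)
        if attempt:
            jitter = 1 + 0.2 * rng.standard_normal(6)
            guess = [max(g * j, 1e-6) for g, j in zip(p0, jitter)]
        try:
            popt, pcov = curve_fit(
                _two_gaussians, centers, counts, p0=guess, bounds=bounds, maxfev=20000
            )
            break
        except (RuntimeError, ValueError) as exc:  # pragma: no cover - rare
            last_error = exc
    else:
        raise FitFailureError(
            "two-Gaussian fit did not converge after restarts",
            diagnostics={"p0": p0, "error": str(last_error), "n": int(mjds.size)},
        )

    a1, m1, s1, a2, m2, s2 = popt
    if m1 > m2:
        a1, m1, s1, a2, m2, s2 = a2, m2, s2, a1, m1, s1

    residual = counts - _two_gaussians(centers, a1, m1, s1, a2, m2, s2)
    fit = TwoGaussianFit(
        amp_low=a1, mean_low=m1, sd_low=s1,
        amp_high=a2, mean_high=m2, sd_high=s2,
        threshold=threshold,
        diagnostics={
            "rss": float(np.sum(residual**2)),
            "n_samples": int(mjds.size),
            "n_bins": int(len(centers)),
            "param_sd": np.sqrt(np.diag(pcov)).tolist(),
        },
    )
    total_area = fit.area_low + fit.area_high
    if total_area <= 0 or min(fit.area_low, fit.area_high) < degenerate_area_fraction * total_area:
        fit.degenerate = True
    # two heavily overlapping components are one population split in two
    if fit.mean_high - fit.mean_low < 2.0 * max(fit.sd_low, fit.sd_high):
        fit.degenerate = True
    return fit


def r_value(fit: TwoGaussianFit, force: bool = False) -> float:
    """High-mobility area fraction: area_high / (area_low + area_high)."""
    if fit.degenerate and not force:
        raise DegenerateFitError("fit is degenerate; pass force=True to compute R anyway")
    total = fit.area_low + fit.area_high
    if total <= 0:
        raise DegenerateFitError("zero total area")
    return fit.area_high / total


def classify_tracks(
    trackset: TrackSet, threshold: float = MOBILITY_THRESHOLD_NM
) -> tuple[list[str], float]:
    """Label each track 'low' (MJD < threshold) or 'high' (MJD >= threshold).

    Tracks without a defined MJD get the label 'undefined'. Returns the
    labels and the fraction of high-mobility tracks among defined ones.
    """
    labels = []
    n_high = n_defined = 0
    for track in trackset.tracks:
        try:
            mjd = compute_mjd(track)
        except UndefinedStatisticError:
            labels.append("undefined")
            continue
        n_defined += 1
        if mjd >= threshold:
            labels.append("high")
            n_high += 1
        else:
            labels.append("low")
    fraction_high = n_high / n_defined if n_defined else float("nan")
    return labels, fraction_high
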