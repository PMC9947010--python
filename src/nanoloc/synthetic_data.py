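"""Ground-truth generators for every downstream analysis stage.

Two forward models are provided:

* :func:`simulate_tracks` — mixtures of 2-D Brownian walkers observed at a
  fixed frame rate with per-axis Gaussian localization noise, for the
  mobility (mean-jump-distance) pipeline.
* :func:`simulate_clustered_points` — blinking emitters arranged in disk
  clusters over a uniform (CSR) background, for the tessellation and
  co-localization pipeline.

Both are deterministic given their seed. Coordinates are nm in image
convention (origin top-left, y increasing downward); frames are integers
``0..n-1`` with physical time ``frame * frame_interval``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidConfigError, NanolocError
from .locproc.drift import DriftModel, apply_drift  # noqa: F401  (re-exported forward model)
from .locproc.io import make_table, sort_table
from .locproc.transform import AffineTransform
from .spt_mobility import Track, TrackSet

DEFAULT_FRAME_INTERVAL_S = 1.0 / 33.0  # acquisition rate 33 Hz


def mean_jump_nm(diffusion_um2_s: float, frame_interval_s: float, loc_precision_nm: float) -> float:
    """Expected mean jump distance sqrt(pi * (D*dt + sigma^2)) in nm.

    A per-axis observed jump is the true Brownian step (variance ``2*D*dt``)
    plus the difference of two independent localization errors (variance
    ``2*sigma^2``), so the jump length is Rayleigh with scale
    ``sqrt(2*(D*dt + sigma^2))`` and mean ``sqrt(pi*(D*dt + sigma^2))``.
    """
    d_nm2_s = diffusion_um2_s * 1e6
    return math.sqrt(math.pi * (d_nm2_s * frame_interval_s + loc_precision_nm**2))


def diffusion_for_mean_jump(
    target_mjd_nm: float, frame_interval_s: float, loc_precision_nm: float
) -> float:
    """Diffusion coefficient (um^2/s) whose expected mean jump equals the target."""
    d_nm2_s = (target_mjd_nm**2 / math.pi - loc_precision_nm**2) / frame_interval_s
    if d_nm2_s < 0:
        raise InvalidConfigError(
            f"target MJD {target_mjd_nm} nm is below the localization-noise floor"
        )
    return d_nm2_s / 1e6


@dataclass
class SimTrackConfig:
    """Two-(or k-)population Brownian track simulation parameters."""

    n_tracks: int
    track_length: int
    populations: list[tuple[float, float]]  # (diffusion um^2/s, weight)
    frame_interval: float = DEFAULT_FRAME_INTERVAL_S
    loc_precision: float = 24.8  # nm per axis
    field_size: tuple[float, float] = (20000.0, 20000.0)  # nm
    seed: int = 0

    def __post_init__(self):
        if self.n_tracks <= 0:
            raise InvalidConfigError("n_tracks must be positive")
        if self.track_length < 2:
            raise InvalidConfigError("track_length must be at least 2")
        if self.frame_interval <= 0:
            raise InvalidConfigError("frame_interval must be positive")
        if self.field_size[0] <= 0 or self.field_size[1] <= 0:
            raise InvalidConfigError("field_size must be positive")
        if not self.populations:
            raise InvalidConfigError("at least one population required")
        weights = [w for _, w in self.populations]
        if abs(sum(weights) - 1.0) > 1e-9:
            raise InvalidConfigError("population weights must sum to 1")
        if any(d < 0 for d, _ in self.populations):
            raise InvalidConfigError("diffusion coefficients must be >= 0")
        if self.loc_precision < 0:
            raise InvalidConfigError("loc_precision must be >= 0")


@dataclass
class SimClusterConfig:
    """Disk-cluster + CSR-background blinking-emitter simulation parameters."""

    n_clusters: int
    cluster_radius: float  # nm
    locs_per_cluster: int  # emitters per cluster
    background_density: float = 0.0  # emitters / um^2
    blinks_per_emitter: float = 0.0  # extra localizations per emitter, Poisson mean
    loc_precision: float = 10.0  # nm
    field_size: tuple[float, float] = (10000.0, 10000.0)  # nm
    n_frames: int = 1000
    seed: int = 0

    def __post_init__(self):
        if min(self.n_clusters, self.locs_per_cluster, self.n_frames) < 0:
            raise InvalidConfigError("counts must be >= 0")
        if self.cluster_radius <= 0:
            raise InvalidConfigError("cluster_radius must be positive")
        if self.background_density < 0 or self.blinks_per_emitter < 0:
            raise InvalidConfigError("rates must be >= 0")
        if self.field_size[0] <= 0 or self.field_size[1] <= 0:
            raise InvalidConfigError("field_size must be positive")
        if self.n_clusters > 0 and 2 * self.cluster_radius > min(self.field_size):
            raise InvalidConfigError("cluster diameter exceeds field size")


@dataclass
class GroundTruth:
    """Per-localization and per-track truth accompanying a simulated table."""

    emitter_id: np.ndarray  # aligned with table rows
    cluster_id: np.ndarray | None = None  # per localization, -1 = background
    population: np.ndarray | None = None  # per track
    drift: DriftModel | None = None
    channel_transform: AffineTransform | None = None

    def to_frame(self) -> pd.DataFrame:
        data = {"emitter_id": self.emitter_id}
        if self.cluster_id is not None:
            data["cluster_id"] = self.cluster_id
        return pd.DataFrame(data)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _reflect(positions: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Fold coordinates into [lo, hi] by specular reflection at both walls."""
    span = hi - lo
    r = np.mod(positions - lo, 2 * span)
    return lo + np.where(r > span, 2 * span - r, r)


def simulate_tracks(config: SimTrackConfig) -> tuple[TrackSet, pd.DataFrame]:
    """Simulate Brownian tracks and return (observed TrackSet, localization table).

    Each track draws its population by weight, starts uniformly in the field,
    takes per-axis Gaussian steps of SD ``sqrt(2*D*dt)`` reflected at the
    field edges, and is observed with independent per-axis noise of SD
    ``loc_precision``. All tracks span frames ``0..track_length-1``.
    """
    rng = np.random.default_rng(config.seed)
    n, length = config.n_tracks, config.track_length
    weights = np.array([w for _, w in config.populations])
    diffusion = np.array([d for d, _ in config.populations])

    pop = rng.choice(len(weights), size=n, p=weights / weights.sum())
    step_sd = np.sqrt(2.0 * diffusion[pop] * 1e6 * config.frame_interval)  # nm

    start = rng.uniform([0, 0], config.field_size, size=(n, 2))
    steps = rng.standard_normal((n, length - 1, 2)) * step_sd[:, None, None]
    true = np.concatenate([start[:, None, :], start[:, None, :] + np.cumsum(steps, axis=1)], axis=1)
    true[..., 0] = _reflect(true[..., 0], 0.0, config.field_size[0])
    true[..., 1] = _reflect(true[..., 1], 0.0, config.field_size[1])

    observed = true + rng.standard_normal(true.shape) * config.loc_precision

    tracks = [
        Track(id=i, frames=np.arange(length), x=observed[i, :, 0], y=observed[i, :, 1])
        for i in range(n)
    ]
    trackset = TrackSet(tracks=tracks, population=pop)

    frames = np.tile(np.arange(length), n)
    track_of_row = np.repeat(np.arange(n), length)
    df = pd.DataFrame(
        {
            "id": np.arange(n * length, dtype=np.int64),
            "frame": frames,
            "x": observed[:, :, 0].ravel(),
            "y": observed[:, :, 1].ravel(),
            "sigma": np.full(n * length, np.nan),
            "intensity": np.full(n * length, np.nan),
            "channel": np.zeros(n * length, dtype=np.int64),
            "emitter_id": track_of_row,
        }
    )
    df = sort_table(df)
    table = df.drop(columns=["emitter_id"]).reset_index(drop=True)
    table.attrs["ground_truth"] = GroundTruth(
        emitter_id=df["emitter_id"].to_numpy(), population=pop
    )
    return trackset, table


def simulate_clustered_points(config: SimClusterConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate blinking emitters in disk clusters over a CSR background.

    Cluster centers are uniform in the field inset by one cluster radius (so
    every disk lies fully inside); member emitters are uniform within their
    disk; background emitters are CSR at ``background_density``. Each emitter
    yields ``1 + Poisson(blinks_per_emitter)`` localizations on uniformly
    random frames, each jittered by ``loc_precision`` per axis.
    """
    rng = np.random.default_rng(config.seed)
    lx, ly = config.field_size
    r = config.cluster_radius

    emitters = []
    cluster_of_emitter = []
    if config.n_clusters > 0:
        centers = rng.uniform([r, r], [lx - r, ly - r], size=(config.n_clusters, 2))
        for c in range(config.n_clusters):
            theta = rng.uniform(0, 2 * math.pi, config.locs_per_cluster)
            rad = r * np.sqrt(rng.uniform(0, 1, config.locs_per_cluster))
            pts = centers[c] + np.column_stack([rad * np.cos(theta), rad * np.sin(theta)])
            emitters.append(pts)
            cluster_of_emitter.append(np.full(config.locs_per_cluster, c))

    area_um2 = lx * ly / 1e6
    n_bg = rng.poisson(config.background_density * area_um2)
    if n_bg > 0:
        emitters.append(rng.uniform([0, 0], [lx, ly], size=(n_bg, 2)))
        cluster_of_emitter.append(np.full(n_bg, -1))

    if not emitters:
        empty = make_table(np.empty(0, np.int64), np.empty(0), np.empty(0))
        return empty, GroundTruth(emitter_id=np.empty(0, np.int64), cluster_id=np.empty(0, np.int64))

    positions = np.concatenate(emitters)
    cluster_of_emitter = np.concatenate(cluster_of_emitter).astype(np.int64)
    n_emitters = len(positions)

    blinks = 1 + rng.poisson(config.blinks_per_emitter, n_emitters)
    emitter_of_loc = np.repeat(np.arange(n_emitters), blinks)
    n_locs = len(emitter_of_loc)
    frames = rng.integers(0, config.n_frames, n_locs)
    xy = positions[emitter_of_loc] + rng.standard_normal((n_locs, 2)) * config.loc_precision

    df = pd.DataFrame(
        {
            "id": np.arange(n_locs, dtype=np.int64),
            "frame": frames.astype(np.int64),
            "x": xy[:, 0],
            "y": xy[:, 1],
            "sigma": np.full(n_locs, np.nan),
            "intensity": np.full(n_locs, np.nan),
            "channel": np.zeros(n_locs, dtype=np.int64),
            "emitter_id": emitter_of_loc,
        }
    )
    df = sort_table(df)
    gt = GroundTruth(
        emitter_id=df["emitter_id"].to_numpy(),
        cluster_id=cluster_of_emitter[df["emitter_id"].to_numpy()],
    )
    table = df.drop(columns=["emitter_id"]).reset_index(drop=True)
    return table, gt


def make_two_channel(
    table: pd.DataFrame,
    transform: AffineTransform,
    mode: str,
    jitter_nm: float = 15.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Derive a second channel from a single-channel table.

    Modes
    -----
    ``coclustered``
        Channel B re-observes the same underlying structure: a copy of A
        with fresh localization jitter of SD ``jitter_nm``.
    ``independent``
        Channel B is a CSR pattern of the same size over A's bounding box.
    ``mirrored``
        Channel B is A flipped vertically within its bounding box (the
        standard negative control).

    Channel B is then mapped through ``transform`` (e.g. a chromatic-shift
    model) and tagged ``channel=1``.
    """
    rng = np.random.default_rng(seed)
    a = table.copy()
    a["channel"] = np.int64(0)
    b = table.copy()
    n = len(b)
    if mode == "coclustered":
        b[["x", "y"]] = b[["x", "y"]].to_numpy() + rng.standard_normal((n, 2)) * jitter_nm
    elif mode == "independent":
        lo = b[["x", "y"]].min().to_numpy()
        hi = b[["x", "y"]].max().to_numpy()
        b[["x", "y"]] = rng.uniform(lo, hi, size=(n, 2))
    elif mode == "mirrored":
        y0, y1 = b["y"].min(), b["y"].max()
        b["y"] = (y0 + y1) - b["y"]
    else:
        raise NanolocError(f"unknown two-channel mode: {mode!r}")
    b[["x", "y"]] = transform(b[["x", "y"]].to_numpy())
    b["channel"] = np.int64(1)
    b["id"] = np.arange(n, dtype=np.int64)
    return sort_table(a), sort_table(b)


def add_fiducials(
    table: pd.DataFrame,
    n: int,
    brightness: float = 1e5,
    n_frames: int | None = None,
    loc_precision: float = 5.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[int]]:
    """Add ``n`` static bright emitters localized in every frame.

    Fiducial rows are flagged in a ``fiducial_id`` column (-1 elsewhere) and
    positioned uniformly in the table's bounding box. Returns the augmented
    table and the list of fiducial ids.
    """
    if n < 0:
        raise InvalidConfigError("n must be >= 0")
    out = table.copy()
    if "fiducial_id" not in out.columns:
        out["fiducial_id"] = np.int64(-1)
    if n == 0:
        return out, []
    rng = np.random.default_rng(seed)
    if n_frames is None:
        n_frames = int(table["frame"].max()) + 1
    lo = table[["x", "y"]].min().to_numpy()
    hi = table[["x", "y"]].max().to_numpy()
    positions = rng.uniform(lo, hi, size=(n, 2))

    next_id = int(out["id"].max()) + 1 if len(out) else 0
    frames = np.tile(np.arange(n_frames), n)
    fid_of_row = np.repeat(np.arange(n), n_frames)
    xy = positions[fid_of_row] + rng.standard_normal((n * n_frames, 2)) * loc_precision
    rows = pd.DataFrame(
        {
            "id": next_id + np.arange(n * n_frames, dtype=np.int64),
            "frame": frames.astype(np.int64),
            "x": xy[:, 0],
            "y": xy[:, 1],
            "sigma": np.full(n * n_frames, np.nan),
            "intensity": np.full(n * n_frames, float(brightness)),
            "channel": np.full(
                n * n_frames, out["channel"].iloc[0] if len(out) else 0, dtype=np.int64
            ),
            "fiducial_id": fid_of_row.astype(np.int64),
        }
    )
    merged = sort_table(pd.concat([out, rows], ignore_index=True))
    return merged, list(range(n))
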