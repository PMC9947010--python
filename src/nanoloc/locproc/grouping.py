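"""Merge repeated localizations of a single blinking emitter.

An emitter that stays on over several frames (or re-blinks within the
allowed frame gap) produces a chain of localizations; clustering analyses
require those chains collapsed to one record. A chain accretes a
localization when it lies within ``max_distance`` of the chain's running
centroid, with candidate pairs considered in ascending distance order so the
result is deterministic.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from ..errors import NanolocError

DEFAULT_PIXEL_NM = 160.0  # 16 um EMCCD pixel / 100x objective


def group_localizations(
    table: pd.DataFrame,
    max_distance: float = DEFAULT_PIXEL_NM,
    max_frame_gap: int | None = None,
) -> pd.DataFrame:
    """Group consecutive-frame localizations into single emitter records.

    Parameters
    ----------
    table:
        Single-channel localization table.
    max_distance:
        Maximum distance (nm) from a chain's running centroid; defaults to
        one camera pixel (160 nm).
    max_frame_gap:
        Chains unmatched for more than this many frames are closed;
        ``None`` (default) keeps every chain open for the whole acquisition.

    Returns
    -------
    Grouped table: one row per chain at the unweighted centroid of its
    members, frame = first frame of the chain, intensity summed, sigma
    averaged, id = id of the first member.
    """
    if max_distance < 0:
        raise NanolocError("max_distance must be non-negative")
    if "channel" in table.columns and table["channel"].nunique() > 1:
        raise NanolocError("group_localizations requires a single channel")
    if len(table) == 0:
        return table.copy()

    frames = table["frame"].to_numpy()
    xy = table[["x", "y"]].to_numpy()
    ids = table["id"].to_numpy()
    intensity = (
        table["intensity"].to_numpy()
        if "intensity" in table.columns
        else np.full(len(table), np.nan)
    )
    sigma = (
        table["sigma"].to_numpy() if "sigma" in table.columns else np.full(len(table), np.nan)
    )

    # open chains, parallel lists
    c_sum = []  # running coordinate sums, (2,)
    c_n = []
    c_first_frame = []
    c_first_id = []
    c_last_frame = []
    c_int = []
    c_sig = []  # sigma sums (NaN-aware handled at the end)
    closed: list[int] = []  # indices into the chain lists, order of first frame

    order = np.argsort(frames, kind="stable")
    start = 0
    open_idx: list[int] = []
    while start < len(order):
        f = frames[order[start]]
        stop = start
        while stop < len(order) and frames[order[stop]] == f:
            stop += 1
        rows = order[start:stop]

        if max_frame_gap is not None:
            still_open = []
            for ci in open_idx:
                if f - c_last_frame[ci] - 1 > max_frame_gap:
                    closed.append(ci)
                else:
                    still_open.append(ci)
            open_idx = still_open

        matched_rows: set[int] = set()
        matched_chains: set[int] = set()
        if open_idx:
            centroids = np.array([c_sum[ci] / c_n[ci] for ci in open_idx])
            tree = cKDTree(centroids)
            pts = xy[rows]
            candidates = []  # (distance, loc id, row, chain index)
            for k, neighbors in enumerate(tree.query_ball_point(pts, max_distance)):
                for j in neighbors:
                    d = float(np.hypot(*(pts[k] - centroids[j])))
                    candidates.append((d, ids[rows[k]], rows[k], open_idx[j]))
            candidates.sort(key=lambda c: (c[0], c[1]))
            for d, _lid, row, ci in candidates:
                if row in matched_rows or ci in matched_chains:
                    continue
                matched_rows.add(row)
                matched_chains.add(ci)
                c_sum[ci] = c_sum[ci] + xy[row]
                c_n[ci] += 1
                c_last_frame[ci] = f
                c_int[ci] = np.nansum([c_int[ci], intensity[row]])
                c_sig[ci].append(sigma[row])

        for row in rows:
            if row in matched_rows:
                continue
            open_idx.append(len(c_sum))
            c_sum.append(xy[row].copy())
            c_n.append(1)
            c_first_frame.append(int(f))
            c_first_id.append(int(ids[row]))
            c_last_frame.append(int(f))
            c_int.append(float(intensity[row]) if np.isfinite(intensity[row]) else np.nan)
            c_sig.append([sigma[row]])

        start = stop

    closed.extend(open_idx)
    closed.sort(key=lambda ci: (c_first_frame[ci], c_first_id[ci]))

    out = pd.DataFrame(
        {
            "id": [c_first_id[ci] for ci in closed],
            "frame": [c_first_frame[ci] for ci in closed],
            "x": [c_sum[ci][0] / c_n[ci] for ci in closed],
            "y": [c_sum[ci][1] / c_n[ci] for ci in closed],
            "sigma": [float(np.nanmean(c_sig[ci])) if np.isfinite(c_sig[ci]).any() else np.nan for ci in closed],
            "intensity": [c_int[ci] for ci in closed],
            "channel": np.full(len(closed), table["channel"].iloc[0] if "channel" in table.columns else 0, dtype=np.int64),
            "n_merged": [c_n[ci] for ci in closed],
        }
    )
    return out
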