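"""Localization-table I/O.

The in-memory representation of a localization table is a pandas DataFrame
with canonical column names::

    id         integer, unique within the table
    frame      0-based integer acquisition frame
    x, y       nm
    sigma      nm, SD of the Gaussian fit (optional)
    intensity  photons (optional)
    channel    small integer (optional, defaults to 0)

Any further columns are carried through untouched. On disk the table is a
ThunderSTORM-dialect CSV whose header quotes each column name and carries
units in brackets, e.g. ``"x [nm]"``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..errors import ParseError

#: canonical name -> ThunderSTORM CSV header
THUNDERSTORM_HEADERS = {
    "id": "id",
    "frame": "frame",
    "x": "x [nm]",
    "y": "y [nm]",
    "sigma": "sigma [nm]",
    "intensity": "intensity [photon]",
    "channel": "channel",
}
_CSV_TO_CANONICAL = {v: k for k, v in THUNDERSTORM_HEADERS.items()}

MANDATORY_COLUMNS = ("frame", "x", "y")


def make_table(
    frame,
    x,
    y,
    sigma=None,
    intensity=None,
    channel=None,
    ids=None,
) -> pd.DataFrame:
    """Assemble a canonical localization table from columns.

    Missing optional columns are filled with defaults (sigma/intensity NaN,
    channel 0). Rows are sorted by (channel, frame) and ids assigned
    sequentially when not given.
    """
    frame = np.asarray(frame, dtype=np.int64)
    n = frame.shape[0]
    table = pd.DataFrame(
        {
            "id": np.arange(n, dtype=np.int64) if ids is None else np.asarray(ids, dtype=np.int64),
            "frame": frame,
            "x": np.asarray(x, dtype=np.float64),
            "y": np.asarray(y, dtype=np.float64),
            "sigma": np.full(n, np.nan) if sigma is None else np.asarray(sigma, dtype=np.float64),
            "intensity": np.full(n, np.nan) if intensity is None else np.asarray(intensity, dtype=np.float64),
            "channel": np.zeros(n, dtype=np.int64) if channel is None else np.asarray(channel, dtype=np.int64),
        }
    )
    return sort_table(table)


def sort_table(table: pd.DataFrame) -> pd.DataFrame:
    """Sort by (channel, frame), keeping id order stable within a frame."""
    by = [c for c in ("channel", "frame", "id") if c in table.columns]
    return table.sort_values(by, kind="stable", ignore_index=True)


def validate_table(table: pd.DataFrame) -> None:
    """Check table invariants; raise ``ParseError`` on violation."""
    for col in MANDATORY_COLUMNS:
        if col not in table.columns:
            raise ParseError(f"missing mandatory column: {col!r}")
    if len(table) and (table["frame"] < 0).any():
        raise ParseError("negative frame index")
    if not np.isfinite(table[["x", "y"]].to_numpy()).all():
        raise ParseError("non-finite coordinates")
    if "id" in table.columns and table["id"].duplicated().any():
        raise ParseError("duplicate localization ids")


def read_localizations(
    path,
    dialect: str = "thunderstorm",
    one_based_frames: bool = False,
) -> pd.DataFrame:
    """Read a ThunderSTORM-dialect CSV into a canonical table.

    Parameters
    ----------
    path:
        CSV file with a quoted header row.
    dialect:
        Only ``"thunderstorm"`` is recognized.
    one_based_frames:
        If True the file's frame numbers start at 1 and are shifted to the
        internal 0-based convention.
    """
    if dialect != "thunderstorm":
        raise ParseError(f"unknown dialect: {dialect!r}")
    try:
        raw = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"empty or headerless file: {path}") from exc
    raw.columns = [c.strip() for c in raw.columns]

    # a file without a header is read with data in the column names
    if not any(c in _CSV_TO_CANONICAL for c in raw.columns):
        raise ParseError(
            "no recognized header; expected ThunderSTORM columns such as "
            '"frame","x [nm]","y [nm]"'
        )

    table = raw.rename(columns=_CSV_TO_CANONICAL)
    for col in MANDATORY_COLUMNS:
        if col not in table.columns:
            raise ParseError(f"missing mandatory column: {THUNDERSTORM_HEADERS[col]!r}")
    table["frame"] = table["frame"].astype(np.int64)
    if one_based_frames:
        table["frame"] -= 1
    if "channel" not in table.columns:
        table["channel"] = np.int64(0)
    if "id" not in table.columns:
        table["id"] = np.arange(len(table), dtype=np.int64)
    table = sort_table(table)
    validate_table(table)
    return table


def write_localizations(table: pd.DataFrame, path, one_based_frames: bool = False) -> None:
    """Write a canonical table as a ThunderSTORM-dialect CSV.

    Optional canonical columns that are entirely absent are not written;
    unknown (extra) columns are written under their own names.
    """
    out = table.copy()
    if one_based_frames:
        out["frame"] = out["frame"] + 1
    out = out.rename(columns=THUNDERSTORM_HEADERS)
    out.to_csv(path, index=False, quoting=2)  # QUOTE_NONNUMERIC, like the reference dialect
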