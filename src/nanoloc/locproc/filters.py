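"""Quality filters on localization tables."""

from __future__ import annotations

import pandas as pd

from ..errors import NanolocError

DEFAULT_MAX_SIGMA_NM = 200.0


def filter_sigma(
    table: pd.DataFrame, max_sigma: float = DEFAULT_MAX_SIGMA_NM
) -> tuple[pd.DataFrame, int]:
    """Drop out-of-focus localizations whose Gaussian-fit SD exceeds ``max_sigma``.

    Rows with ``sigma`` strictly greater than the cutoff (200 nm by default)
    are removed; row order is preserved.

    Returns
    -------
    (filtered_table, n_removed)
    """
    if "sigma" not in table.columns or table["sigma"].isna().all():
        raise NanolocError("sigma column absent: cannot filter on fit SD")
    keep = table["sigma"] <= max_sigma
    filtered = table.loc[keep].reset_index(drop=True)
    return filtered, int((~keep).sum())
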