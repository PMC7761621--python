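"""Relative protein abundance shares from label-free quantification (LFQ).

Given per-replicate LFQ intensities for a declared set of proteins (e.g. the
three VDAC paralogs), each protein's share is its mean intensity divided by
the summed mean intensities, in percent.  Dispersion is reported as percent
coefficient of variation across replicates (sample SD / mean x 100).  Missing
LFQ values are ignored in the means — LFQ missingness is not absence — and a
protein with no value at all is excluded with a warning.
"""

from __future__ import annotations

import math
import warnings
from typing import Mapping, Sequence

import pandas as pd

from .errors import DataError, UndefinedShareError

SHARE_DECIMALS = 2


def lfq_share(intensities: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Relative abundance shares from per-replicate LFQ intensities.

    Parameters
    ----------
    intensities
        Mapping of protein accession to its per-replicate LFQ values; a
        single mean may be passed as a one-element list.  ``None``/NaN
        entries are treated as missing.

    Returns
    -------
    DataFrame indexed by protein with columns ``mean_intensity``,
    ``sd_percent`` (CV%, NaN with fewer than two values) and
    ``share_percent`` (rounded to 2 decimals; shares sum to 100 up to
    rounding).
    """
    if not intensities:
        raise DataError("no proteins given")
    means, cvs = {}, {}
    for protein, values in intensities.items():
        clean = [v for v in values if v is not None and not math.isnan(v)]
        if any(v < 0 for v in clean):
            raise DataError(f"negative LFQ intensity for {protein!r}")
        if not clean:
            warnings.warn(
                f"protein {protein!r} has no LFQ value in any replicate; excluded",
                stacklevel=2,
            )
            continue
        series = pd.Series(clean, dtype=float)
        means[protein] = float(series.mean())
        cvs[protein] = (
            float(series.std(ddof=1) / series.mean() * 100.0)
            if len(clean) > 1 and series.mean() > 0
            else float("nan")
        )
    if not means:
        raise DataError("all proteins have only missing LFQ values")
    total = sum(means.values())
    if total <= 0:
        raise UndefinedShareError("total LFQ intensity is zero; shares undefined")
    table = pd.DataFrame(
        {
            "mean_intensity": pd.Series(means),
            "sd_percent": pd.Series(cvs),
            "share_percent": pd.Series(
                {p: round(100.0 * m / total, SHARE_DECIMALS) for p, m in means.items()}
            ),
        }
    )
    table.index.name = "protein"
    return table


def lfq_share_from_table(frame: pd.DataFrame) -> pd.DataFrame:
    """Shares from a long-format table with columns protein, replicate, intensity."""
    required = {"protein", "intensity"}
    missing = required - set(frame.columns)
    if missing:
        raise DataError(f"LFQ table is missing column(s) {sorted(missing)}")
    grouped = {
        protein: list(sub["intensity"].astype(float))
        for protein, sub in frame.groupby("protein", sort=True)
    }
    return lfq_share(grouped)
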