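"""In-silico karyotyping: parent-normalized coverage deviation per window.

Mapped-read counts in genomic windows are normalized by each sample's total
mapped reads; the line's normalized rate is divided by that of each wheat
parent in its crossing history, and the ratio closest to 1 is kept as the
window's coverage deviation.  The deviation proxies the copy number of wheat
DNA relative to the parents: ~1 is normal, values approaching 0 mark
deletions or introgressions, ~0.5 heterozygous/monosomic loss, ~2
duplication.  Windows with deviation in the normal band (0.8-1.2 by default)
are considered free of copy-number change.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .config import DEFAULT
from .io_formats import WindowCountTable


def normalize_counts(table: WindowCountTable) -> pd.DataFrame:
    """Per-window mapped-read rate: count / total mapped reads."""
    if table.total_reads <= 0:
        raise ValueError("total_reads must be positive to normalize counts")
    out = table.grid().copy()
    out["rate"] = table.frame["count"].to_numpy(dtype=float) / table.total_reads
    return out


def _check_same_grid(a: pd.DataFrame, b: pd.DataFrame) -> None:
    ga = a[["chrom", "start", "end"]].reset_index(drop=True)
    gb = b[["chrom", "start", "end"]].reset_index(drop=True)
    if len(ga) != len(gb) or not ga.equals(gb):
        raise ValueError("window grids differ between samples")


def coverage_deviation(
    line: WindowCountTable,
    parents: Mapping[str, WindowCountTable],
    normal_band: tuple[float, float] = DEFAULT.normal_band,
) -> pd.DataFrame:
    """Compute the coverage-deviation track of a line against its parents.

    For every window the line/parent normalized-rate ratio is computed per
    parent and the ratio minimizing ``|ratio - 1|`` is kept, recording which
    parent was chosen (the parent with coverage closest to the line is
    assumed to be the parental donor of that window).  Equidistant ties break
    to the lower ratio, conservatively favouring loss events.  Windows where
    no parent has coverage are undefined (NaN deviation).

    Returns a track with columns chrom, start, end, deviation, parent, label.
    """
    if not parents:
        raise ValueError("at least one parent track is required")
    line_rates = normalize_counts(line)
    track = line_rates[["chrom", "start", "end"]].copy()
    n = len(track)
    best_dev = np.full(n, np.nan)
    best_dist = np.full(n, np.inf)
    best_parent = np.full(n, None, dtype=object)
    lr = line_rates["rate"].to_numpy()
    for name in parents:
        p_rates = normalize_counts(parents[name])
        _check_same_grid(line_rates, p_rates)
        pr = p_rates["rate"].to_numpy()
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(pr > 0, lr / pr, np.nan)
        dist = np.abs(ratio - 1.0)
        better = ~np.isnan(ratio) & (
            (dist < best_dist) | ((dist == best_dist) & (ratio < best_dev))
        )
        best_dev[better] = ratio[better]
        best_dist[better] = dist[better]
        best_parent[better] = name
    track["deviation"] = best_dev
    track["parent"] = best_parent
    track["label"] = classify_windows(track["deviation"], normal_band)
    return track


def classify_windows(
    deviation: pd.Series | np.ndarray,
    normal_band: tuple[float, float] = DEFAULT.normal_band,
) -> pd.Series:
    """Label windows as normal / reduced / elevated / undefined from their
    deviation (normal = within the band, inclusive)."""
    dev = np.asarray(deviation, dtype=float)
    lo, hi = normal_band
    labels = np.full(dev.shape, "undefined", dtype=object)
    labels[~np.isnan(dev) & (dev < lo)] = "reduced"
    labels[~np.isnan(dev) & (dev > hi)] = "elevated"
    labels[~np.isnan(dev) & (dev >= lo) & (dev <= hi)] = "normal"
    return pd.Series(labels, index=getattr(deviation, "index", None), name="label")
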