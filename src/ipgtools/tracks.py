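"""Generic aggregation of base-pair-resolution scored intervals into bins."""
from __future__ import annotations

import numpy as np
import pandas as pd

from .core import BinTable, SignalTrack

__all__ = ["aggregate_track"]


def aggregate_track(intervals: pd.DataFrame, bins: BinTable,
                    stat: str = "mean") -> SignalTrack:
    """Aggregate scored intervals (chrom/start/end/score) to a per-bin track.

    stat:
      * ``mean`` — overlap-weighted mean score over covered base pairs
      * ``sum`` — score mass assigned proportionally to bp overlap
      * ``fraction`` — sum of scores divided by number of records per bin
        (e.g. methylated CpGs over total CpGs; records assigned to the bin
        containing their start)

    Bins with no overlapping data are NaN, never 0.
    """
    if stat not in {"mean", "sum", "fraction"}:
        raise ValueError(f"unknown stat {stat!r}")
    n = bins.n_bins
    num = np.zeros(n)
    den = np.zeros(n)
    chromsizes = bins.chromsizes
    offsets = {c: bins.chrom_slice(c).start for c in bins.chrom_names}
    for row in intervals.itertuples(index=False):
        if row.chrom not in offsets:
            continue
        if row.end > chromsizes[row.chrom] or row.start < 0:
            raise ValueError("interval extends past chromosome end")
        off = offsets[row.chrom]
        if stat == "fraction":
            b = off + int(row.start // bins.bin_size)
            num[b] += row.score
            den[b] += 1.0
            continue
        b0 = int(row.start // bins.bin_size)
        b1 = int((row.end - 1) // bins.bin_size)
        length = row.end - row.start
        for b in range(b0, b1 + 1):
            lo = max(row.start, (b) * bins.bin_size)
            hi = min(row.end, (b + 1) * bins.bin_size)
            ov = hi - lo
            if ov <= 0:
                continue
            if stat == "sum":   # apportion score mass by bp overlap
                num[off + b] += row.score * ov / length
            else:
                num[off + b] += row.score * ov
            den[off + b] += ov
    value = np.full(n, np.nan)
    covered = den > 0
    if stat in ("mean", "fraction"):
        value[covered] = num[covered] / den[covered]
    else:  # sum of score mass apportioned by overlap
        value[covered] = num[covered]
    return SignalTrack(bins, value)
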