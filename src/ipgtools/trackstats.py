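"""Descriptive statistics coupling signal tracks to domains and labels."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve

from .core import IntervalSet, SignalTrack
from .spectral import IPGAssignment

__all__ = ["Stackup", "stackup", "metaplot", "percentile_histogram",
           "PercentileHistogram", "roc_for_label", "ROCResult"]


@dataclass
class Stackup:
    """One row per domain: fixed-width flanks + rescaled intradomain columns."""

    values: np.ndarray       # (n_domains, flank_bins + rescale_bins + flank_bins)
    rescale_bins: int
    flank: int
    flank_bins: int
    domains: object          # pandas DataFrame of domain records in row order


def _resample_domain(track: SignalTrack, chrom: str, start: int, end: int,
                     n_out: int) -> np.ndarray:
    """Overlap-weighted resampling of the intradomain signal to n_out columns.

    The signal is treated as piecewise constant per bin; each output column
    covers an equal bp share of the domain, so the bp-weighted intradomain
    mean is preserved exactly.
    """
    bins = track.bins
    bs = bins.bin_size
    sl = bins.chrom_slice(chrom)
    out = np.full(n_out, np.nan)
    edges = np.linspace(start, end, n_out + 1)
    for k in range(n_out):
        lo, hi = edges[k], edges[k + 1]
        b0, b1 = int(lo // bs), int(np.ceil(hi / bs))
        num = den = 0.0
        for b in range(b0, b1):
            gi = sl.start + b
            if gi >= sl.stop:
                break
            v = track.value[gi]
            ov = min(hi, (b + 1) * bs) - max(lo, b * bs)
            if ov > 0 and np.isfinite(v):
                num += v * ov
                den += ov
        if den > 0:
            out[k] = num / den
    return out


def stackup(track: SignalTrack, domains: IntervalSet, rescale_bins: int = 25,
            flank: int = 500_000, sort_key="size") -> Stackup:
    """Rescaled stacked heatmap of ``track`` over ``domains``.

    Each domain's signal is resampled to ``rescale_bins`` columns by
    overlap-weighted averaging; flanks are appended at native resolution.
    Rows are sorted by ``sort_key``: "size" (descending domain length),
    "none", or a SignalTrack whose intradomain mean is the key.
    """
    bins = track.bins
    bs = bins.bin_size
    fb = int(flank // bs)
    df = domains.df
    if isinstance(sort_key, SignalTrack):
        keys = []
        for row in df.itertuples(index=False):
            mid = _resample_domain(sort_key, row.chrom, row.start, row.end, 1)
            keys.append(mid[0])
        order = np.argsort(np.asarray(keys), kind="stable")[::-1]
    elif sort_key == "size":
        order = np.argsort((df["end"] - df["start"]).to_numpy(), kind="stable")[::-1]
    elif sort_key == "none":
        order = np.arange(len(df))
    else:
        raise ValueError(f"unknown sort_key {sort_key!r}")
    df = df.iloc[order].reset_index(drop=True)
    rows = []
    for row in df.itertuples(index=False):
        if row.chrom not in bins.chrom_names:
            rows.append(np.full(2 * fb + rescale_bins, np.nan))
            continue
        sl = bins.chrom_slice(row.chrom)
        mid = _resample_domain(track, row.chrom, row.start, row.end, rescale_bins)
        left = np.full(fb, np.nan)
        right = np.full(fb, np.nan)
        b0 = sl.start + int(row.start // bs)
        for k in range(fb):
            gi = b0 - fb + k
            if sl.start <= gi < sl.stop:
                left[k] = track.value[gi]
        b1 = sl.start + int(np.ceil(row.end / bs))
        for k in range(fb):
            gi = b1 + k
            if sl.start <= gi < sl.stop:
                right[k] = track.value[gi]
        rows.append(np.concatenate([left, mid, right]))
    return Stackup(np.array(rows) if rows else np.empty((0, 2 * fb + rescale_bins)),
                   rescale_bins, flank, fb, df)


def metaplot(stack: Stackup):
    """Column-wise mean and sd of a stackup, ignoring missing values."""
    if len(stack.values) == 0:
        raise ValueError("empty stackup")
    import warnings as _w
    with _w.catch_warnings():
        _w.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(stack.values, axis=0)
        sd = np.nanstd(stack.values, axis=0)
    return mean, sd


@dataclass
class PercentileHistogram:
    """Per-percentile-group statistics of one or more tracks."""

    group: np.ndarray        # group index per bin, -1 outside
    sizes: np.ndarray
    means: dict
    sds: dict


def percentile_histogram(track_to_rank: SignalTrack, tracks: dict[str, SignalTrack],
                         n_percentiles: int = 100) -> PercentileHistogram:
    """Rank bins by one track, split into equal-count groups, summarize others.

    Group sizes differ by at most one; ties are broken by stable bin order.
    Missing values are excluded pairwise.
    """
    mask = track_to_rank.finite_mask()
    idx = np.flatnonzero(mask)
    if n_percentiles > len(idx):
        raise ValueError("n_percentiles exceeds number of valid bins")
    rank = idx[np.argsort(track_to_rank.value[idx], kind="stable")]
    group = np.full(len(track_to_rank), -1, dtype=np.int64)
    chunks = np.array_split(rank, n_percentiles)
    for q, chunk in enumerate(chunks):
        group[chunk] = q
    sizes = np.array([len(c) for c in chunks])
    means, sds = {}, {}
    for name, tr in tracks.items():
        mu = np.full(n_percentiles, np.nan)
        sd = np.full(n_percentiles, np.nan)
        for q, chunk in enumerate(chunks):
            vals = tr.value[chunk]
            vals = vals[np.isfinite(vals)]
            if len(vals):
                mu[q] = vals.mean()
                sd[q] = vals.std()
        means[name], sds[name] = mu, sd
    return PercentileHistogram(group, sizes, means, sds)


@dataclass
class ROCResult:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def roc_for_label(track: SignalTrack, labels: IPGAssignment,
                  target_ipg: str) -> ROCResult:
    """ROC/AUC of a thresholded track as a binary classifier for one IPG.

    AUC is the trapezoid area, equivalently P(score+ > score-) + 0.5 P(tie).
    Bins missing in either the track or the labels are excluded.
    """
    mask = np.isfinite(track.value) & np.array(
        [x is not None for x in labels.ipg_label])
    y = (labels.ipg_label[mask] == target_ipg).astype(int)
    score = track.value[mask]
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class")
    fpr, tpr, thr = roc_curve(y, score)
    return ROCResult(fpr, tpr, thr, float(roc_auc_score(y, score)))
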