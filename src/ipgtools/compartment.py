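"""Distance decay P(s), saddle plots and pairwise IPG observed/expected."""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ContactMatrix, IntervalSet, SignalTrack
from .spectral import IPGAssignment

__all__ = ["ContactDecay", "SaddleSummary", "expected_cis", "ps_by_group",
           "ps_derivative", "saddle", "ipg_pairwise_oe"]

STRATUM_RATIO = 2 ** 0.125


@dataclass
class ContactDecay:
    """Contact frequency per geometric stratum of genomic separation."""

    s: np.ndarray            # representative separation per stratum (bp)
    P: np.ndarray            # mean contact frequency
    n_pixels: np.ndarray
    normalization_s: float | None = None


def _diag_sums(values: np.ndarray, valid: np.ndarray):
    """Per-diagonal sums and valid-pixel counts of one chromosome block."""
    n = values.shape[0]
    sums = np.zeros(n)
    counts = np.zeros(n)
    vv = np.outer(valid, valid)
    for d in range(1, n):
        diag = np.diagonal(values, offset=d)
        ok = np.diagonal(vv, offset=d)
        sums[d] = diag[ok].sum()
        counts[d] = ok.sum()
    return sums, counts


def _pool_strata(diag_sums: np.ndarray, diag_counts: np.ndarray,
                 bin_size: int, normalization_s: float | None = None) -> ContactDecay:
    n = len(diag_sums)
    d = np.arange(1, n)
    strat = np.floor(np.log(d) / np.log(STRATUM_RATIO)).astype(int)
    n_strat = strat.max() + 1 if len(strat) else 0
    s_rep = np.zeros(n_strat)
    P = np.full(n_strat, np.nan)
    npx = np.zeros(n_strat)
    for k in range(n_strat):
        sel = d[strat == k]
        if len(sel) == 0:
            s_rep[k] = bin_size * STRATUM_RATIO ** (k + 0.5)
            continue
        cnt = diag_counts[sel].sum()
        npx[k] = cnt
        s_rep[k] = np.exp(np.mean(np.log(sel * bin_size)))
        if cnt > 0:
            P[k] = diag_sums[sel].sum() / cnt
    decay = ContactDecay(s_rep, P, npx, normalization_s)
    if normalization_s is not None:
        _normalize(decay)
    return decay


def _normalize(decay: ContactDecay) -> None:
    ok = np.isfinite(decay.P) & (decay.P > 0)
    ref = float(np.interp(np.log(decay.normalization_s),
                          np.log(decay.s[ok]), np.log(decay.P[ok])))
    decay.P = decay.P / np.exp(ref)


def expected_cis(m: ContactMatrix) -> dict[str, ContactDecay]:
    """Per-chromosome mean contact frequency per geometric separation stratum."""
    out = {}
    for name in m.bins.chrom_names:
        sl = m.bins.chrom_slice(name)
        valid = m.bins.valid[sl]
        if valid.sum() < 2:
            warnings.warn(f"chromosome {name} has < 2 valid bins; skipped")
            continue
        sums, counts = _diag_sums(m.values[sl, sl], valid)
        out[name] = _pool_strata(sums, counts, m.bins.bin_size)
    return out


def ps_by_group(m: ContactMatrix, domains: IntervalSet,
                normalization_s: float = 10_000) -> dict[str, ContactDecay]:
    """P(s) per group, restricted to pixels inside a single same-group domain.

    Curves are normalized to unity at ``normalization_s``.
    """
    out = {}
    max_bins = max(m.bins.chrom_slice(c).stop - m.bins.chrom_slice(c).start
                   for c in m.bins.chrom_names)
    for label in domains.labels():
        sums = np.zeros(max_bins)
        counts = np.zeros(max_bins)
        for row in domains.subset(label).df.itertuples(index=False):
            if row.chrom not in m.bins.chrom_names:
                continue
            sl = m.bins.chrom_slice(row.chrom)
            inside = np.flatnonzero((m.bins.start[sl] >= row.start)
                                    & (m.bins.end[sl] <= row.end)) + sl.start
            if len(inside) < 2:
                continue
            sub = m.values[np.ix_(inside, inside)]
            v = m.bins.valid[inside]
            ds, dc = _diag_sums(sub, v)
            sums[:len(ds)] += ds
            counts[:len(dc)] += dc
        if counts.sum() == 0:
            warnings.warn(f"group {label}: no qualifying pixels; curve missing")
            out[label] = None
            continue
        out[label] = _pool_strata(sums, counts, m.bins.bin_size,
                                  normalization_s=normalization_s)
    return out


def ps_derivative(decay: ContactDecay, smooth_window: int = 1) -> np.ndarray:
    """Log-log slope of P(s) by centered finite differences.

    ``smooth_window`` > 1 applies a moving average to log P beforehand.
    Strata with nonpositive or missing P yield NaN.
    """
    if len(decay.s) < 3:
        raise ValueError("need >= 3 strata for a derivative")
    logs = np.log(decay.s)
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = np.where(decay.P > 0, np.log(decay.P), np.nan)
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        pad = smooth_window // 2
        padded = np.pad(logp, pad, mode="edge")
        sm = np.convolve(padded, kernel, mode="valid")[:len(logp)]
        logp = sm
    slope = np.full(len(logp), np.nan)
    for i in range(1, len(logp) - 1):
        if np.isfinite(logp[i - 1 : i + 2]).all():
            slope[i] = (logp[i + 1] - logp[i - 1]) / (logs[i + 1] - logs[i - 1])
    return slope


def _oe_matrix(m: ContactMatrix, scope: str) -> np.ndarray:
    """Observed/expected per pixel; NaN outside the scope or on invalid bins.

    cis expected is the per-chromosome per-diagonal mean over valid pixels;
    trans expected is the mean over all valid pixels of each chromosome pair.
    """
    n = m.n_bins
    oe = np.full((n, n), np.nan)
    valid = m.bins.valid
    names = m.bins.chrom_names
    if scope == "cis":
        for name in names:
            sl = m.bins.chrom_slice(name)
            block = m.values[sl, sl]
            v = valid[sl]
            nb = block.shape[0]
            vv = np.outer(v, v)
            exp = np.full((nb, nb), np.nan)
            for d in range(1, nb):
                diag = np.diagonal(block, offset=d)
                ok = np.diagonal(vv, offset=d)
                if ok.sum() > 0:
                    e = diag[ok].mean()
                    if e > 0:
                        idx = np.arange(nb - d)
                        exp[idx, idx + d] = e
                        exp[idx + d, idx] = e
            with np.errstate(invalid="ignore", divide="ignore"):
                res = block / exp
            res[~vv] = np.nan
            oe[sl, sl] = res
    elif scope == "trans":
        for a in range(len(names)):
            for b in range(a + 1, len(names)):
                sa = m.bins.chrom_slice(names[a])
                sb = m.bins.chrom_slice(names[b])
                block = m.values[sa, sb]
                vv = np.outer(valid[sa], valid[sb])
                if vv.sum() == 0:
                    continue
                e = block[vv].mean()
                if e <= 0:
                    continue
                res = np.where(vv, block / e, np.nan)
                oe[sa, sb] = res
                oe[sb, sa] = res.T
    else:
        raise ValueError(f"unknown scope {scope!r}")
    return oe


@dataclass
class SaddleSummary:
    """Mean observed/expected between bins grouped by track percentile."""

    n_quantiles: int
    edges: np.ndarray
    matrix: np.ndarray
    scope: str


def _quantile_groups(values: np.ndarray, mask: np.ndarray, n_quantiles: int,
                     order: str = "ascending"):
    """Per-bin quantile-group index (-1 outside mask).

    Bins are digitized by the value quantile edges, so tied values always
    land in the same group (groups are only approximately equal-count when
    the track has heavy ties).
    """
    idx = np.flatnonzero(mask)
    if n_quantiles > len(idx):
        raise ValueError("n_quantiles exceeds number of valid bins")
    vals = values[idx]
    order_idx = np.argsort(vals, kind="stable")
    sizes = [len(c) for c in np.array_split(np.arange(len(idx)), n_quantiles)]
    pos_group = np.repeat(np.arange(n_quantiles), sizes)
    g = pos_group.copy()
    # keep tied values in one group: assign each tie block the group of its
    # median rank position
    sorted_vals = vals[order_idx]
    block_starts = np.flatnonzero(np.r_[True, sorted_vals[1:] != sorted_vals[:-1]])
    block_ends = np.r_[block_starts[1:], len(sorted_vals)]
    for a, b in zip(block_starts, block_ends):
        g[a:b] = pos_group[(a + b - 1) // 2]
    if order == "descending":
        g = n_quantiles - 1 - g
    group = np.full(len(values), -1, dtype=np.int64)
    group[idx[order_idx]] = g
    edges = np.quantile(vals, np.linspace(0, 1, n_quantiles + 1))
    return group, edges


def saddle(m: ContactMatrix, track: SignalTrack, n_quantiles: int = 50,
           scope: str = "cis", order: str = "ascending",
           trim: float = 0.0) -> SaddleSummary:
    """Mean observed/expected contact between track-percentile bin groups.

    ``trim`` optionally excludes the given fraction of extreme-valued bins
    at each end of the ranking before grouping.
    """
    mask = m.bins.valid & np.isfinite(track.value)
    if trim > 0:
        lo, hi = np.quantile(track.value[mask], [trim, 1 - trim])
        mask = mask & (track.value >= lo) & (track.value <= hi)
    group, edges = _quantile_groups(track.value, mask, n_quantiles, order)
    oe = _oe_matrix(m, scope)
    gsum = np.zeros((n_quantiles, n_quantiles))
    gcnt = np.zeros((n_quantiles, n_quantiles))
    finite = np.isfinite(oe) & (group[:, None] >= 0) & (group[None, :] >= 0)
    gi, gj = np.meshgrid(group, group, indexing="ij")
    np.add.at(gsum, (gi[finite], gj[finite]), oe[finite])
    np.add.at(gcnt, (gi[finite], gj[finite]), 1.0)
    with np.errstate(invalid="ignore"):
        mat = gsum / gcnt
    mat = (mat + mat.T) / 2
    return SaddleSummary(n_quantiles, edges, mat, scope)


def ipg_pairwise_oe(m: ContactMatrix, labels: IPGAssignment,
                    scope: str = "trans") -> pd.DataFrame:
    """Mean observed/expected between bins grouped by IPG label pair."""
    lab = labels.ipg_label
    names = [x for x in dict.fromkeys(lab) if x is not None]
    lut = {x: i for i, x in enumerate(names)}
    group = np.array([lut.get(x, -1) for x in lab], dtype=np.int64)
    oe = _oe_matrix(m, scope)
    k = len(names)
    gsum = np.zeros((k, k))
    gcnt = np.zeros((k, k))
    finite = np.isfinite(oe) & (group[:, None] >= 0) & (group[None, :] >= 0)
    gi, gj = np.meshgrid(group, group, indexing="ij")
    np.add.at(gsum, (gi[finite], gj[finite]), oe[finite])
    np.add.at(gcnt, (gi[finite], gj[finite]), 1.0)
    with np.errstate(invalid="ignore"):
        mat = gsum / gcnt
    mat = (mat + mat.T) / 2
    return pd.DataFrame(mat, index=names, columns=names)
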