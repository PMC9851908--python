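"""Diamond insulation scores, prominence-based boundary calls, CTCF pileups."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .core import ContactMatrix, IntervalSet
from .spectral import IPGAssignment

__all__ = ["InsulationProfile", "CTCFSite", "insulation_score",
           "call_insulating_loci", "boundary_stats_by_group", "pileup_at_sites"]


@dataclass
class CTCFSite:
    """An oriented CTCF motif site with ChIP fold-change."""

    chrom: str
    midpoint: int
    strand: str
    fc: float

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError("strand must be + or -")
        if self.fc <= 0:
            raise ValueError("fold change must be positive")


@dataclass
class InsulationProfile:
    """Per-bin log2 diamond insulation score and its called minima."""

    bins: object
    score: np.ndarray
    window: int
    minima: IntervalSet | None = None


def insulation_score(m: ContactMatrix, window: int = 100_000) -> InsulationProfile:
    """Diamond insulation: mean balanced contact in the ``window`` x ``window``
    off-diagonal diamond at each bin, as log2 of the ratio to the
    chromosome-wide mean. NaN within ``window`` of chromosome edges.
    """
    w = int(window // m.bins.bin_size)
    if w < 2:
        raise ValueError("window must span at least 2 bins")
    n = m.n_bins
    raw = np.full(n, np.nan)
    valid = m.bins.valid
    for name in m.bins.chrom_names:
        sl = m.bins.chrom_slice(name)
        block = m.values[sl, sl]
        v = valid[sl]
        nb = block.shape[0]
        # diamond between the w bins upstream of i and the w bins from i on,
        # so a boundary scores at the first bin of the downstream block
        for i in range(w, nb - w + 1):
            rows = slice(i - w, i)
            cols = slice(i, i + w)
            sub = block[rows, cols]
            ok = np.outer(v[rows], v[cols])
            if ok.any():
                raw[sl.start + i] = sub[ok].mean()
        chrom_vals = raw[sl.start:sl.stop]
        mean = np.nanmean(chrom_vals) if np.isfinite(chrom_vals).any() else np.nan
        if np.isfinite(mean) and mean > 0:
            with np.errstate(invalid="ignore", divide="ignore"):
                raw[sl.start:sl.stop] = np.log2(chrom_vals / mean)
    return InsulationProfile(m.bins, raw, window)


def call_insulating_loci(profile: InsulationProfile,
                         min_prominence: float = 0.01) -> IntervalSet:
    """Local minima of the insulation score with topographic prominence
    (on the negated score) >= ``min_prominence``, per chromosome."""
    bins = profile.bins
    records = []
    for name in bins.chrom_names:
        sl = bins.chrom_slice(name)
        score = profile.score[sl.start:sl.stop]
        finite = np.isfinite(score)
        # split into finite runs so NaN flanks do not fabricate minima
        idx = np.flatnonzero(finite)
        if len(idx) == 0:
            continue
        splits = np.flatnonzero(np.diff(idx) > 1)
        for run in np.split(idx, splits + 1):
            if len(run) < 3:
                continue
            seg = score[run]
            peaks, props = find_peaks(-seg, prominence=(min_prominence, None))
            for p, prom in zip(peaks, props["prominences"]):
                b = sl.start + run[p]
                records.append((name, int(bins.start[b]), int(bins.end[b]),
                                "boundary", float(prom)))
    return IntervalSet.from_records(records)


def boundary_stats_by_group(loci: IntervalSet, labels: IPGAssignment) -> dict:
    """Per-IPG boundary density (count per Mb of territory) and prominences."""
    bins = labels.bins
    bin_size = bins.bin_size
    out = {}
    names = [x for x in dict.fromkeys(labels.ipg_label) if x is not None]
    locus_bin_labels = []
    for row in loci.df.itertuples(index=False):
        if row.chrom in bins.chrom_names:
            b = bins.bin_index(row.chrom, (row.start + row.end) // 2)
            locus_bin_labels.append((labels.ipg_label[b], row.score))
    for name in names:
        territory_mb = (labels.ipg_label == name).sum() * bin_size / 1e6
        proms = [s for lab, s in locus_bin_labels if lab == name]
        out[name] = {
            "territory_mb": float(territory_mb),
            "count": len(proms),
            "density_per_mb": len(proms) / territory_mb if territory_mb > 0 else np.nan,
            "prominences": np.array(proms),
        }
    return out


def _group_diag_expected(m: ContactMatrix, member: np.ndarray,
                         max_dist: int) -> np.ndarray:
    """Per-distance expected restricted to within-group domain pixels,
    falling back to the global cis expected where the group has no data."""
    sums = np.zeros(max_dist + 1)
    counts = np.zeros(max_dist + 1)
    gsums = np.zeros(max_dist + 1)
    gcounts = np.zeros(max_dist + 1)
    valid = m.bins.valid
    for name in m.bins.chrom_names:
        sl = m.bins.chrom_slice(name)
        block = m.values[sl, sl]
        v = valid[sl]
        nb = block.shape[0]
        mem = member[sl.start:sl.stop]
        for d in range(0, min(max_dist, nb - 1) + 1):
            diag = np.diagonal(block, offset=d)
            ok = v[:nb - d] & v[d:]
            if ok.any():
                gsums[d] += diag[ok].sum()
                gcounts[d] += ok.sum()
            okm = ok & mem[:nb - d] & mem[d:]
            if okm.any():
                sums[d] += diag[okm].sum()
                counts[d] += okm.sum()
    with np.errstate(invalid="ignore"):
        exp = np.where(counts > 0, sums / np.maximum(counts, 1),
                       np.where(gcounts > 0, gsums / np.maximum(gcounts, 1), np.nan))
    return exp


def pileup_at_sites(m: ContactMatrix, sites: list[CTCFSite], flank: int = 300_000,
                    group_labels: IPGAssignment | None = None):
    """Mean observed/expected snippets centered on the diagonal at CTCF sites.

    Minus-strand snippets are mirrored so orientations align. Expected maps
    are distance-expected computed separately per IPG (within-group pixels).
    Returns (maps: dict group -> 2D array, skipped: dict group -> count).
    """
    bins = m.bins
    if flank % bins.bin_size:
        raise ValueError("flank must be a multiple of the bin size")
    f = flank // bins.bin_size
    if group_labels is not None:
        group_of_bin = group_labels.ipg_label
        groups = [x for x in dict.fromkeys(group_of_bin) if x is not None]
    else:
        group_of_bin = np.array(["all"] * bins.n_bins, dtype=object)
        groups = ["all"]
    expected = {}
    for g in groups:
        member = group_of_bin == g
        expected[g] = _group_diag_expected(m, member, 2 * f)
    acc = {g: np.zeros((2 * f + 1, 2 * f + 1)) for g in groups}
    cnt = {g: 0 for g in groups}
    skipped = {g: 0 for g in groups}
    for site in sites:
        if site.chrom not in bins.chrom_names:
            continue
        sl = bins.chrom_slice(site.chrom)
        c = bins.bin_index(site.chrom, site.midpoint)
        g = group_of_bin[c]
        if g is None or g not in acc:
            continue
        if c - f < sl.start or c + f >= sl.stop:
            skipped[g] += 1
            continue
        win = slice(c - f, c + f + 1)
        if not bins.valid[win].all():
            skipped[g] += 1
            continue
        snip = m.values[win, win].copy()
        dist = np.abs(np.arange(2 * f + 1)[:, None] - np.arange(2 * f + 1)[None, :])
        e = expected[g][dist]
        with np.errstate(invalid="ignore", divide="ignore"):
            snip = np.where(e > 0, snip / e, np.nan)
        if site.strand == "-":
            snip = snip[::-1, ::-1]
        acc[g] += np.nan_to_num(snip)
        cnt[g] += 1
    maps = {g: (acc[g] / cnt[g] if cnt[g] else np.full((2 * f + 1, 2 * f + 1), np.nan))
            for g in groups}
    return maps, skipped
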