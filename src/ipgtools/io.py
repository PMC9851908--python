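"""Readers and writers for the supported on-disk formats.

Contact matrices: single-resolution cooler-layout HDF5 (chroms/bins/pixels
groups, upper-triangle pixel list) and a plain-text COO dialect — a TSV of
``bin1_id  bin2_id  count`` (upper triangle only) with a sidecar bin-table
TSV (``chrom  start  end``). Tracks: bedGraph. Intervals: BED4/BED6.
"""
from __future__ import annotations

import json

import h5py
import numpy as np
import pandas as pd

from .core import BinTable, ContactMatrix, IntervalSet, SignalTrack

__all__ = [
    "read_contact_matrix", "write_contact_matrix",
    "read_coo_text", "write_coo_text",
    "read_bedgraph", "write_bedgraph",
    "read_bed", "write_bed", "read_ctcf_sites",
]


# ---------------------------------------------------------------- cooler HDF5

def write_cooler(path, m: ContactMatrix) -> None:
    """Write a single-resolution cooler-layout HDF5 file.

    Dataset timestamps are disabled so identical matrices serialize to
    byte-identical files.
    """
    bins = m.bins
    names = bins.chrom_names
    cid = bins.chrom_ids
    iu = np.triu_indices(m.n_bins)
    vals = m.values[iu]
    nz = vals != 0
    b1, b2, px = iu[0][nz], iu[1][nz], vals[nz]
    with h5py.File(path, "w") as f:
        f.attrs["format"] = "HDF5::Cooler"
        f.attrs["bin-size"] = bins.bin_size
        f.attrs["nbins"] = bins.n_bins
        f.attrs["nchroms"] = len(names)
        f.attrs["nnz"] = len(px)
        if bins.centromere_pos is not None:
            f.attrs["centromeres"] = json.dumps(bins.centromere_pos)
        g = f.create_group("chroms")
        g.create_dataset("name", data=np.array(names, dtype="S64"), track_times=False)
        g.create_dataset("length", data=np.array(
            [bins.chromsizes[c] for c in names], dtype=np.int64),
            track_times=False)
        g = f.create_group("bins")
        g.create_dataset("chrom", data=cid.astype(np.int32), track_times=False)
        g.create_dataset("start", data=bins.start, track_times=False)
        g.create_dataset("end", data=bins.end, track_times=False)
        if m.weights is not None:
            g.create_dataset("weight", data=m.weights, track_times=False)
        g = f.create_group("pixels")
        g.create_dataset("bin1_id", data=b1.astype(np.int64), track_times=False)
        g.create_dataset("bin2_id", data=b2.astype(np.int64), track_times=False)
        g.create_dataset("count", data=px, track_times=False)
        g = f.create_group("indexes")
        g.create_dataset("bin1_offset", data=np.searchsorted(
            b1, np.arange(bins.n_bins + 1)).astype(np.int64),
            track_times=False)
        chrom_offset = np.searchsorted(cid, np.arange(len(names) + 1))
        g.create_dataset("chrom_offset", data=chrom_offset.astype(np.int64), track_times=False)


def read_cooler(path, resolution: int | None = None) -> ContactMatrix:
    with h5py.File(path, "r") as f:
        if "bin-size" not in f.attrs:
            raise ValueError("resolution unavailable")
        bin_size = int(f.attrs["bin-size"])
        if resolution is not None and resolution != bin_size:
            raise ValueError("resolution unavailable")
        names = [n.decode() for n in f["chroms/name"][:]]
        cid = f["bins/chrom"][:]
        start = f["bins/start"][:]
        end = f["bins/end"][:]
        centromeres = (json.loads(f.attrs["centromeres"])
                       if "centromeres" in f.attrs else None)
        weights = f["bins/weight"][:] if "weight" in f["bins"] else None
        b1 = f["pixels/bin1_id"][:]
        b2 = f["pixels/bin2_id"][:]
        px = f["pixels/count"][:]
    chrom = np.array([names[i] for i in cid], dtype=object)
    valid = None if weights is None else np.isfinite(weights)
    bins = BinTable(chrom, start, end, bin_size,
                    centromere_pos=centromeres, valid=valid)
    n = bins.n_bins
    values = np.zeros((n, n))
    values[b1, b2] = px
    values[b2, b1] = px
    return ContactMatrix(bins, values, weights=weights,
                         balanced=weights is not None)


def read_contact_matrix(path, resolution: int | None = None,
                        bins_path=None, symmetrize: bool = False) -> ContactMatrix:
    """Read a contact matrix from cooler HDF5 or COO text (with bin sidecar)."""
    path = str(path)
    if h5py.is_hdf5(path):
        return read_cooler(path, resolution)
    if bins_path is None:
        raise ValueError("COO text input requires a bin-table sidecar (bins_path)")
    return read_coo_text(path, bins_path, resolution=resolution, symmetrize=symmetrize)


def write_contact_matrix(path, m: ContactMatrix) -> None:
    write_cooler(path, m)


# ------------------------------------------------------------------ COO text

def write_coo_text(matrix_path, bins_path, m: ContactMatrix) -> None:
    m.bins.to_frame().drop(columns="valid").to_csv(bins_path, sep="\t", index=False)
    iu = np.triu_indices(m.n_bins)
    vals = m.values[iu]
    nz = vals != 0
    pd.DataFrame({"bin1_id": iu[0][nz], "bin2_id": iu[1][nz],
                  "count": vals[nz]}).to_csv(matrix_path, sep="\t", index=False)


def read_coo_text(matrix_path, bins_path, resolution: int | None = None,
                  symmetrize: bool = False) -> ContactMatrix:
    bdf = pd.read_csv(bins_path, sep="\t")
    widths = (bdf["end"] - bdf["start"]).to_numpy()
    bin_size = resolution if resolution is not None else int(widths.max())
    bins = BinTable(bdf["chrom"].to_numpy(dtype=object),
                    bdf["start"].to_numpy(), bdf["end"].to_numpy(), bin_size)
    pdf = pd.read_csv(matrix_path, sep="\t")
    b1 = pdf["bin1_id"].to_numpy()
    b2 = pdf["bin2_id"].to_numpy()
    if not symmetrize and np.any(b1 > b2):
        raise ValueError("asymmetric COO input: lower-triangle entries present "
                         "(pass symmetrize=True to fold)")
    n = bins.n_bins
    values = np.zeros((n, n))
    np.add.at(values, (b1, b2), pdf["count"].to_numpy(dtype=float))
    # mirror; with symmetrize=True mirrored duplicate records are summed
    values = values + values.T
    values[np.diag_indices(n)] /= 2
    return ContactMatrix(bins, values)


# ------------------------------------------------------------ bedGraph / BED

def write_bedgraph(path, track: SignalTrack) -> None:
    b = track.bins
    with open(path, "w") as f:
        for c, s, e, v in zip(b.chrom, b.start, b.end, track.value):
            if np.isfinite(v):
                f.write(f"{c}\t{s}\t{e}\t{v:.10g}\n")


def read_bedgraph(path, bins: BinTable, name: str = "") -> SignalTrack:
    """Read a bedGraph whose records align exactly with ``bins``; absent bins NaN."""
    value = np.full(bins.n_bins, np.nan)
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "value"], comment="#")
    key = {(c, int(s)): i for i, (c, s) in enumerate(zip(bins.chrom, bins.start))}
    for row in df.itertuples(index=False):
        idx = key.get((row.chrom, int(row.start)))
        if idx is None:
            raise ValueError("bedGraph record does not align with bin table")
        value[idx] = row.value
    return SignalTrack(bins, value, name=name)


def write_bed(path, intervals: IntervalSet) -> None:
    with open(path, "w") as f:
        for row in intervals.df.itertuples(index=False):
            score = "." if not np.isfinite(row.score) else f"{row.score:.10g}"
            f.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.label}\t{score}\t.\n")


def read_bed(path) -> IntervalSet:
    rows = []
    with open(path) as f:
        for line in f:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            label = parts[3] if len(parts) > 3 else "."
            score = (float(parts[4]) if len(parts) > 4 and parts[4] != "."
                     else np.nan)
            rows.append((chrom, start, end, label, score))
    return IntervalSet.from_records(rows)


def read_ctcf_sites(path):
    """Read CTCF sites from BED6 (name, fold-change score, strand)."""
    from .insulation import CTCFSite
    sites = []
    with open(path) as f:
        for line in f:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            fc = float(parts[4])
            strand = parts[5]
            sites.append(CTCFSite(chrom=chrom, midpoint=(start + end) // 2,
                                  strand=strand, fc=fc))
    return sites
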