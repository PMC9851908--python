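"""Core domain types shared by all pipeline stages.

Coordinates are 0-based, half-open everywhere. Chromosome order is fixed by
the bin table and never re-sorted implicitly. Missing data are explicit
(NaN for float tracks/weights, -1 for integer labels), never silently 0.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["BinTable", "ContactMatrix", "SignalTrack", "IntervalSet"]


@dataclass
class BinTable:
    """Fixed-resolution tiling of a genome into bins.

    Bins tile each chromosome without gaps or overlaps; ``end - start``
    equals ``bin_size`` except possibly at the last bin of a chromosome.
    ``valid`` is the per-bin mask surviving coverage filtering.
    """

    chrom: np.ndarray          # str per bin
    start: np.ndarray          # int bp
    end: np.ndarray            # int bp
    bin_size: int
    centromere_pos: dict[str, int] | None = None
    valid: np.ndarray = None   # bool per bin

    def __post_init__(self):
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.start = np.asarray(self.start, dtype=np.int64)
        self.end = np.asarray(self.end, dtype=np.int64)
        if self.valid is None:
            self.valid = np.ones(len(self.start), dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
        self._validate()

    def _validate(self):
        if not (len(self.chrom) == len(self.start) == len(self.end) == len(self.valid)):
            raise ValueError("bin table columns must have equal length")
        if np.any(self.end <= self.start):
            raise ValueError("non-tiling bin table: empty or negative bins")
        # per-chromosome contiguity: starts begin at 0, each bin abuts the next
        for name in self.chrom_names:
            sl = self.chrom_slice(name)
            s, e = self.start[sl], self.end[sl]
            if s[0] != 0 or np.any(s[1:] != e[:-1]):
                raise ValueError("non-tiling bin table")
            if np.any((e - s)[:-1] != self.bin_size) or (e - s)[-1] > self.bin_size:
                raise ValueError("non-tiling bin table: bin width != bin_size")

    @classmethod
    def from_chromsizes(cls, chromsizes: dict[str, int], bin_size: int,
                        centromeres: dict[str, int] | None = None) -> "BinTable":
        chroms, starts, ends = [], [], []
        for name, length in chromsizes.items():
            edges = np.arange(0, length + bin_size, bin_size)
            edges[-1] = min(edges[-1], length)
            if edges[-1] == edges[-2]:
                edges = edges[:-1]
            chroms.extend([name] * (len(edges) - 1))
            starts.extend(edges[:-1])
            ends.extend(edges[1:])
        return cls(np.array(chroms, dtype=object), np.array(starts), np.array(ends),
                   bin_size, centromere_pos=centromeres)

    def __len__(self) -> int:
        return len(self.start)

    @property
    def n_bins(self) -> int:
        return len(self.start)

    @property
    def chrom_names(self) -> list[str]:
        # preserve first-appearance order
        seen, out = set(), []
        for c in self.chrom:
            if c not in seen:
                seen.add(c)
                out.append(c)
        return out

    def chrom_slice(self, name: str) -> slice:
        idx = np.flatnonzero(self.chrom == name)
        return slice(int(idx[0]), int(idx[-1]) + 1)

    @property
    def chrom_ids(self) -> np.ndarray:
        """Integer chromosome id per bin, in table order."""
        mapping = {c: i for i, c in enumerate(self.chrom_names)}
        return np.array([mapping[c] for c in self.chrom], dtype=np.int64)

    @property
    def chromsizes(self) -> dict[str, int]:
        return {c: int(self.end[self.chrom_slice(c)][-1]) for c in self.chrom_names}

    def centromere_distance(self) -> np.ndarray:
        """Distance (bp) from each bin midpoint to its chromosome's centromere."""
        if self.centromere_pos is None:
            raise ValueError("bin table has no centromere positions")
        mid = (self.start + self.end) / 2
        cen = np.array([self.centromere_pos[c] for c in self.chrom], dtype=float)
        return np.abs(mid - cen)

    def bin_index(self, chrom: str, pos: int) -> int:
        sl = self.chrom_slice(chrom)
        return sl.start + int(pos // self.bin_size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"chrom": self.chrom, "start": self.start,
                             "end": self.end, "valid": self.valid})

    def same_grid(self, other: "BinTable") -> bool:
        return (self.bin_size == other.bin_size
                and len(self) == len(other)
                and bool(np.all(self.chrom == other.chrom))
                and bool(np.all(self.start == other.start)))

    def with_valid(self, valid: np.ndarray) -> "BinTable":
        return replace(self, valid=np.asarray(valid, dtype=bool))


@dataclass
class ContactMatrix:
    """Symmetric binned genome-wide contact matrix (dense, desk scale).

    ``weights`` are per-bin iterative-correction weights: NaN exactly where
    ``bins.valid`` is False. ``balanced`` marks that ``values`` already holds
    corrected frequencies.
    """

    bins: BinTable
    values: np.ndarray
    weights: np.ndarray | None = None
    balanced: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = self.bins.n_bins
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match bin table")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("contact matrix must be symmetric")

    @property
    def n_bins(self) -> int:
        return self.bins.n_bins

    def cis_mask(self) -> np.ndarray:
        cid = self.bins.chrom_ids
        return cid[:, None] == cid[None, :]

    def valid_pair_mask(self) -> np.ndarray:
        v = self.bins.valid
        return v[:, None] & v[None, :]

    def copy(self) -> "ContactMatrix":
        return ContactMatrix(self.bins, self.values.copy(),
                             None if self.weights is None else self.weights.copy(),
                             self.balanced)


@dataclass
class SignalTrack:
    """Per-bin quantitative signal at the bin table's resolution; NaN = missing."""

    bins: BinTable
    value: np.ndarray
    name: str = ""

    def __post_init__(self):
        self.value = np.asarray(self.value, dtype=float)
        if len(self.value) != self.bins.n_bins:
            raise ValueError("track length does not match bin table")

    def __len__(self) -> int:
        return len(self.value)

    def finite_mask(self) -> np.ndarray:
        return np.isfinite(self.value) & self.bins.valid


@dataclass
class IntervalSet:
    """Sorted set of labeled, scored genomic intervals (0-based half-open)."""

    df: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["chrom", "start", "end", "label", "score"]))

    def __post_init__(self):
        df = self.df.copy()
        for col, default in (("label", "."), ("score", np.nan)):
            if col not in df.columns:
                df[col] = default
        df = df[["chrom", "start", "end", "label", "score"]]
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if (df["end"] < df["start"]).any():
            raise ValueError("negative-length interval")
        self.df = df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)

    @classmethod
    def from_records(cls, records) -> "IntervalSet":
        return cls(pd.DataFrame(records, columns=["chrom", "start", "end", "label", "score"]))

    def __len__(self) -> int:
        return len(self.df)

    def subset(self, label: str) -> "IntervalSet":
        return IntervalSet(self.df[self.df["label"] == label])

    def labels(self) -> list[str]:
        seen, out = set(), []
        for lab in self.df["label"]:
            if lab not in seen:
                seen.add(lab)
                out.append(lab)
        return out

    def total_length(self) -> int:
        return int((self.df["end"] - self.df["start"]).sum())

    def bin_membership(self, bins: BinTable) -> np.ndarray:
        """Boolean per-bin mask: bin fully inside some interval of this set."""
        out = np.zeros(bins.n_bins, dtype=bool)
        for _, row in self.df.iterrows():
            if row.chrom not in bins.chrom_names:
                continue
            sl = bins.chrom_slice(row.chrom)
            hit = (bins.start[sl] >= row.start) & (bins.end[sl] <= row.end)
            out[sl.start:sl.stop][hit] = True
        return out


def labels_to_intervals(bins: BinTable, labels: np.ndarray,
                        ignore: set | None = None) -> IntervalSet:
    """Collapse a per-bin label vector into maximal constant-label intervals."""
    ignore = ignore or set()
    records = []
    labels = np.asarray(labels, dtype=object)
    for name in bins.chrom_names:
        sl = bins.chrom_slice(name)
        labs = labels[sl]
        i = 0
        while i < len(labs):
            j = i
            while j + 1 < len(labs) and labs[j + 1] == labs[i]:
                j += 1
            if labs[i] not in ignore:
                records.append((name, int(bins.start[sl][i]), int(bins.end[sl][j]),
                                labs[i], np.nan))
            i = j + 1
    return IntervalSet.from_records(records)
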