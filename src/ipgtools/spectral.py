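"""Spectral identification of interaction profile groups (IPGs) from trans Hi-C.

Pipeline: cis pixels are masked by resampling from trans pixels of the same
row/column, the matrix is rebalanced so rows and columns sum to 1, the
leading eigenpairs are taken in descending order of eigenvalue modulus
(the trivial constant eigenvector of the stochastic matrix is dropped),
eigenvectors are rescaled and clustered row-wise with k-means, and clusters
with matching functional profiles are consolidated into IPGs.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .balance import _ice
from .core import ContactMatrix, SignalTrack

__all__ = ["Eigenspectrum", "IPGAssignment", "mask_cis", "stochastic_scale",
           "eigendecompose", "cluster_bins", "consolidate_clusters", "SpectralIPG"]


@dataclass
class Eigenspectrum:
    """Leading eigenpairs (E1..Em) of the processed trans matrix."""

    bins: object
    eigenvalues: np.ndarray      # ordered by descending modulus
    vectors: np.ndarray          # (n_bins, m), NaN on invalid bins
    orientation_ref: str = ""

    @property
    def m(self) -> int:
        return len(self.eigenvalues)


@dataclass
class IPGAssignment:
    """Per-bin cluster labels, consolidated IPG labels and their mapping."""

    bins: object
    k: int
    cluster_label: np.ndarray    # int per bin, -1 on invalid
    ipg_label: np.ndarray        # object per bin, None on invalid
    cluster_to_ipg: dict
    silhouette: float


def mask_cis(m: ContactMatrix, seed: int = 0) -> ContactMatrix:
    """Replace every cis pixel by a random trans pixel from its row or column.

    Per pixel (i, j): a fair coin picks donor bin i or j, then a value is
    drawn uniformly from that bin's valid trans pixels. Trans pixels are
    unchanged; symmetry is restored by mirroring the upper triangle.
    """
    names = m.bins.chrom_names
    if len(names) < 2:
        raise ValueError("cis masking requires >=2 chromosomes")
    rng = np.random.default_rng(seed)
    cid = m.bins.chrom_ids
    valid = m.bins.valid
    out = m.values.copy()
    for name in names:
        sl = m.bins.chrom_slice(name)
        block = np.arange(sl.start, sl.stop)
        donors_cols = np.flatnonzero((cid != cid[sl.start]) & valid)
        D = m.values[np.ix_(block, donors_cols)]
        nc = len(block)
        ii, jj = np.triu_indices(nc)          # cis pixels incl. the diagonal
        coin = rng.integers(0, 2, size=len(ii)).astype(bool)
        donor_row = np.where(coin, ii, jj)
        col = rng.integers(0, D.shape[1], size=len(ii))
        vals = D[donor_row, col]
        out[block[ii], block[jj]] = vals
        out[block[jj], block[ii]] = vals
    return ContactMatrix(m.bins, out, balanced=m.balanced)


def stochastic_scale(m: ContactMatrix, tol: float = 1e-10,
                     max_iter: int = 1000) -> ContactMatrix:
    """Iterative proportional fitting so every valid row/column sums to 1."""
    valid = m.bins.valid
    balanced, weights = _ice(m.values, valid, tol, max_iter)
    marg = balanced.sum(axis=1)[valid]
    c = marg.mean()
    return ContactMatrix(m.bins, balanced / c, weights=weights / np.sqrt(c),
                         balanced=True)


def _is_constant(v: np.ndarray, tol: float = 1e-3) -> bool:
    mu = np.mean(v)
    return abs(mu) > 0 and float(np.std(v) / abs(mu)) < tol


def eigendecompose(m: ContactMatrix, n_eigs: int = 9,
                   orientation_track: SignalTrack | None = None) -> Eigenspectrum:
    """Leading eigenpairs by eigenvalue modulus, excluding the trivial vector.

    The row-stochastic symmetric matrix has a constant eigenvector at
    eigenvalue 1; it is detected by its near-zero coefficient of variation
    and dropped before numbering E1..Em. Each eigenvector's sign is fixed so
    its correlation with ``orientation_track`` is non-negative (fallback:
    first nonzero entry positive).
    """
    valid = m.bins.valid
    n_valid = int(valid.sum())
    if n_eigs >= n_valid:
        raise ValueError("n_eigs must be smaller than the number of valid bins")
    sub = m.values[np.ix_(valid, valid)]
    w, V = np.linalg.eigh(sub)
    order = np.argsort(-np.abs(w), kind="stable")
    w, V = w[order], V[:, order]
    keep = [k for k in range(len(w)) if not _is_constant(V[:, k])]
    keep = keep[:n_eigs]
    w, V = w[keep], V[:, keep]

    ref = None
    if orientation_track is not None:
        ref = orientation_track.value[valid]
    for k in range(V.shape[1]):
        v = V[:, k]
        sign = 0.0
        if ref is not None:
            ok = np.isfinite(ref)
            if ok.sum() > 1:
                sign = np.sign(np.corrcoef(v[ok], ref[ok])[0, 1])
        if sign == 0 or not np.isfinite(sign):
            nz = np.flatnonzero(v)
            sign = np.sign(v[nz[0]]) if len(nz) else 1.0
        V[:, k] = v * sign
    vectors = np.full((m.n_bins, len(w)), np.nan)
    vectors[valid] = V
    name = orientation_track.name if orientation_track is not None else ""
    return Eigenspectrum(m.bins, w, vectors, orientation_ref=name)


def rescaled_components(spec: Eigenspectrum, rescale: str = "eigenvalue") -> np.ndarray:
    """Eigenvector rows in the representation used for clustering (valid bins)."""
    valid = np.isfinite(spec.vectors).all(axis=1)
    X = spec.vectors[valid]
    if rescale == "eigenvalue":
        X = X * np.abs(spec.eigenvalues)[None, :]
    elif rescale == "unit-variance":
        X = (X - X.mean(axis=0)) / X.std(axis=0)
    elif rescale != "none":
        raise ValueError(f"unknown rescale mode {rescale!r}")
    return X


def cluster_bins(spec: Eigenspectrum, k: int = 8, rescale: str = "eigenvalue",
                 seed: int = 0, n_init: int = 40) -> IPGAssignment:
    """k-means on rescaled eigenvector rows; silhouette on the same space."""
    valid = np.isfinite(spec.vectors).all(axis=1)
    X = rescaled_components(spec, rescale)
    if k > len(X):
        raise ValueError("k exceeds number of valid bins")
    labels = None
    for attempt in range(n_init):
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed + attempt)
        cand = km.fit_predict(X)
        if len(np.unique(cand)) == k:
            labels = cand
            break
    if labels is None:
        raise RuntimeError(f"k-means produced an empty cluster in {n_init} restarts")
    sil = float(silhouette_score(X, labels)) if 1 < k < len(X) else float("nan")
    cluster_label = np.full(len(valid), -1, dtype=np.int64)
    cluster_label[valid] = labels
    ipg_label = np.array([f"C{c}" if c >= 0 else None for c in cluster_label],
                         dtype=object)
    mapping = {c: f"C{c}" for c in range(k)}
    return IPGAssignment(spec.bins, k, cluster_label, ipg_label, mapping, sil)


def _union_find_groups(k: int, pairs) -> list[list[int]]:
    parent = list(range(k))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for a, b in pairs:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)
    groups = {}
    for c in range(k):
        groups.setdefault(find(c), []).append(c)
    return [groups[r] for r in sorted(groups)]


def consolidate_clusters(assign: IPGAssignment, tracks: dict[str, SignalTrack],
                         merge_threshold: float = 0.9,
                         cluster_to_ipg: dict | None = None) -> IPGAssignment:
    """Merge clusters whose standardized functional profiles correlate.

    Cluster pairs whose z-scored mean-track profile vectors have Pearson
    correlation strictly above ``merge_threshold`` are merged (transitively).
    An explicit ``cluster_to_ipg`` map overrides the automatic merge.
    """
    k = assign.k
    if cluster_to_ipg is not None:
        items = list(cluster_to_ipg.items()) if isinstance(cluster_to_ipg, dict) \
            else list(cluster_to_ipg)
        seen = set()
        for c, _ in items:
            if c in seen:
                raise ValueError(f"cluster {c} mapped twice in user map")
            seen.add(c)
        mapping = dict(items)
    else:
        profiles = np.zeros((k, len(tracks)))
        for t, (name, tr) in enumerate(tracks.items()):
            for c in range(k):
                sel = (assign.cluster_label == c) & np.isfinite(tr.value)
                profiles[c, t] = tr.value[sel].mean() if sel.any() else np.nan
        mu, sd = np.nanmean(profiles, axis=0), np.nanstd(profiles, axis=0)
        z = (profiles - mu) / np.where(sd > 0, sd, 1.0)
        pairs = []
        for a in range(k):
            for b in range(a + 1, k):
                va, vb = z[a], z[b]
                ok = np.isfinite(va) & np.isfinite(vb)
                if ok.sum() > 1 and np.std(va[ok]) > 0 and np.std(vb[ok]) > 0:
                    r = float(np.corrcoef(va[ok], vb[ok])[0, 1])
                    if r > merge_threshold:
                        pairs.append((a, b))
        groups = _union_find_groups(k, pairs)
        mapping = {}
        for g, members in enumerate(groups):
            for c in members:
                mapping[c] = f"IPG{g}"
    ipg_label = np.array([mapping.get(c) if c >= 0 else None
                          for c in assign.cluster_label], dtype=object)
    return replace(assign, ipg_label=ipg_label, cluster_to_ipg=mapping)


class SpectralIPG(ClusterMixin, BaseEstimator):
    """Interaction-profile-group caller as a scikit-learn style clusterer.

    ``fit`` takes a raw (filtered) :class:`ContactMatrix`; fitted attributes
    are ``eigenspectrum_``, ``assignment_``, ``labels_`` (consolidated IPG
    label per bin, ``None`` on invalid bins) and ``silhouette_``.

    Parameters follow the reference workflow: 9 leading eigenvectors,
    k-means with k=8, eigenvalue-modulus rescaling, seeded cis masking.
    """

    def __init__(self, n_eigs: int = 9, k: int = 8, rescale: str = "eigenvalue",
                 mask_seed: int = 0, cluster_seed: int = 0, n_init: int = 40,
                 merge_threshold: float = 0.9, orientation_track: str | None = None):
        self.n_eigs = n_eigs
        self.k = k
        self.rescale = rescale
        self.mask_seed = mask_seed
        self.cluster_seed = cluster_seed
        self.n_init = n_init
        self.merge_threshold = merge_threshold
        self.orientation_track = orientation_track

    def fit(self, X: ContactMatrix, y=None, tracks: dict[str, SignalTrack] | None = None):
        masked = mask_cis(X, seed=self.mask_seed)
        scaled = stochastic_scale(masked)
        orient = None
        if tracks and self.orientation_track in (tracks or {}):
            orient = tracks[self.orientation_track]
        self.eigenspectrum_ = eigendecompose(scaled, n_eigs=self.n_eigs,
                                             orientation_track=orient)
        assign = cluster_bins(self.eigenspectrum_, k=self.k, rescale=self.rescale,
                              seed=self.cluster_seed, n_init=self.n_init)
        if tracks:
            assign = consolidate_clusters(assign, tracks,
                                          merge_threshold=self.merge_threshold)
        self.assignment_ = assign
        self.labels_ = assign.ipg_label
        self.silhouette_ = assign.silhouette
        return self

    def fit_predict(self, X: ContactMatrix, y=None, **kwargs):
        return self.fit(X, **kwargs).labels_
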