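"""Two-state HMM segmentation of genomic signal tracks.

Bernoulli HMM for broad histone-mark (H3K9me3-like) domain calling on
binarized tracks; Gaussian HMM for replication-timing domains; plus
two-stage Repli-seq processing (log2 Early/Late ratio, z-scored) and
differential replication timing region calling.

Baum-Welch and Viterbi are provided by hmmlearn; missing bins break
sequences (chromosome-internal NaN gaps start new HMM sequences) rather
than being imputed.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from hmmlearn.hmm import CategoricalHMM, GaussianHMM
from sklearn.base import BaseEstimator

from .core import BinTable, IntervalSet, SignalTrack

__all__ = ["HMMModel", "RTTrack", "binarize_track", "fit_hmm", "viterbi_path",
           "viterbi_domains", "rt_process", "differential_rt", "DomainHMM"]


@dataclass
class HMMModel:
    """A fitted two-state HMM; state 1 is the higher-emission state."""

    family: str                     # "bernoulli" | "gaussian"
    initial: np.ndarray             # (2,)
    transition: np.ndarray          # (2, 2) row-stochastic
    emission_p: np.ndarray | None = None      # Bernoulli P(x=1 | state)
    means: np.ndarray | None = None           # Gaussian
    sds: np.ndarray | None = None
    loglik_history: np.ndarray = field(default_factory=lambda: np.array([]))
    converged: bool = True

    def to_hmmlearn(self):
        if self.family == "bernoulli":
            h = CategoricalHMM(n_components=2, init_params="", params="")
            h.n_features = 2
            h.startprob_ = self.initial
            h.transmat_ = self.transition
            h.emissionprob_ = np.column_stack([1 - self.emission_p, self.emission_p])
        else:
            h = GaussianHMM(n_components=2, covariance_type="diag",
                            init_params="", params="")
            h.startprob_ = self.initial
            h.transmat_ = self.transition
            h.means_ = self.means.reshape(-1, 1)
            h.covars_ = (self.sds ** 2).reshape(-1, 1)
        return h


def binarize_track(track: SignalTrack, threshold: float = 1.0,
                   pseudocount: float = 1.0, log: bool = True) -> SignalTrack:
    """Binarize a track: z-score of log(signal + pseudocount) >= threshold.

    Missing stays missing. A constant track has undefined z-scores and is
    rejected.
    """
    x = track.value
    finite = np.isfinite(x)
    if log:
        finite &= (x + pseudocount) > 0  # nonpositive after pseudocount: missing
    if not finite.any():
        raise ValueError("all-missing track")
    with np.errstate(invalid="ignore", divide="ignore"):
        y = np.log(x + pseudocount) if log else x.astype(float)
    mu = np.nanmean(y[finite])
    sd = np.nanstd(y[finite])
    if sd == 0:
        raise ValueError("degenerate track: zero variance")
    z = (y - mu) / sd
    out = np.full_like(x, np.nan)
    out[finite] = (z[finite] >= threshold).astype(float)
    return SignalTrack(track.bins, out, name=f"{track.name}_binary")


def _prepare(observations) -> tuple[np.ndarray, list[int]]:
    seqs = [np.asarray(s, dtype=float).ravel() for s in observations]
    seqs = [s for s in seqs if len(s)]
    X = np.concatenate(seqs).reshape(-1, 1)
    lengths = [len(s) for s in seqs]
    return X, lengths


def fit_hmm(observations, family: str = "bernoulli", seed: int = 0,
            max_iter: int = 100, tol: float = 1e-4,
            n_restarts: int = 5) -> HMMModel:
    """Baum-Welch fit of a two-state HMM over per-chromosome sequences.

    Initialization: quantile split (Bernoulli) or a median split of values
    (Gaussian), jittered across ``n_restarts`` seeded restarts; the best
    log-likelihood wins. States are relabeled so state 1 has the higher
    emission probability/mean. Non-convergence returns the best model with
    ``converged=False``.
    """
    X, lengths = _prepare(observations)
    if len(np.unique(X)) < 2:
        raise ValueError("need >= 2 distinct observed values")
    rng = np.random.default_rng(seed)
    best, best_score = None, -np.inf
    for _ in range(n_restarts):
        if family == "bernoulli":
            h = CategoricalHMM(n_components=2, n_iter=max_iter, tol=tol,
                               init_params="", params="ste",
                               random_state=int(rng.integers(2 ** 31)))
            h.n_features = 2
            p0 = float(np.clip(0.05 + rng.normal(0, 0.02), 0.01, 0.3))
            p1 = float(np.clip(0.9 + rng.normal(0, 0.02), 0.6, 0.99))
            h.emissionprob_ = np.array([[1 - p0, p0], [1 - p1, p1]])
        elif family == "gaussian":
            h = GaussianHMM(n_components=2, covariance_type="diag",
                            n_iter=max_iter, tol=tol, init_params="",
                            params="stmc",
                            random_state=int(rng.integers(2 ** 31)))
            med = np.median(X)
            lo, hi = X[X <= med], X[X > med]
            h.means_ = np.array([[lo.mean() + rng.normal(0, 0.05)],
                                 [hi.mean() + rng.normal(0, 0.05)]])
            h.covars_ = np.array([[max(lo.var(), 1e-3)], [max(hi.var(), 1e-3)]])
        else:
            raise ValueError(f"unknown family {family!r}")
        h.startprob_ = np.array([0.5, 0.5])
        stay = float(np.clip(0.95 + rng.normal(0, 0.02), 0.8, 0.995))
        h.transmat_ = np.array([[stay, 1 - stay], [1 - stay, stay]])
        obs = X.astype(int) if family == "bernoulli" else X
        try:
            h.fit(obs, lengths)
        except ValueError:
            continue
        score = h.score(obs, lengths)
        if score > best_score:
            best, best_score = h, score
    if best is None:
        raise RuntimeError("all HMM restarts failed")
    # fix state identity: state 1 = higher emission
    if family == "bernoulli":
        p = best.emissionprob_[:, 1]
        order = np.argsort(p)
        model = HMMModel(
            family, best.startprob_[order],
            best.transmat_[np.ix_(order, order)],
            emission_p=p[order])
    else:
        mu = best.means_.ravel()
        order = np.argsort(mu)
        model = HMMModel(
            family, best.startprob_[order],
            best.transmat_[np.ix_(order, order)],
            means=mu[order], sds=np.sqrt(best.covars_.ravel()[order]))
    model.loglik_history = np.asarray(best.monitor_.history, dtype=float)
    model.converged = bool(best.monitor_.converged)
    return model


def viterbi_path(model: HMMModel, seq: np.ndarray) -> np.ndarray:
    """Most probable state path for one observation sequence."""
    h = model.to_hmmlearn()
    x = np.asarray(seq, dtype=float).reshape(-1, 1)
    if model.family == "bernoulli":
        x = x.astype(int)
    return h.predict(x)


def _finite_segments(track: SignalTrack):
    """Yield (global bin index of segment start, values) per finite run."""
    bins = track.bins
    for name in bins.chrom_names:
        sl = bins.chrom_slice(name)
        vals = track.value[sl.start:sl.stop]
        idx = np.flatnonzero(np.isfinite(vals))
        if len(idx) == 0:
            continue
        splits = np.flatnonzero(np.diff(idx) > 1)
        for run in np.split(idx, splits + 1):
            yield sl.start + run[0], vals[run]


def viterbi_domains(model: HMMModel, track: SignalTrack,
                    min_gap: int = 1) -> IntervalSet:
    """Maximal runs of Viterbi state 1 as domains.

    Runs separated by at most ``min_gap`` bins of state 0 (within one
    contiguous sequence) are merged.
    """
    bins = track.bins
    records = []
    for start_bin, vals in _finite_segments(track):
        path = viterbi_path(model, vals)
        # smooth: merge 1-runs separated by short 0-runs
        runs = []
        i = 0
        while i < len(path):
            j = i
            while j + 1 < len(path) and path[j + 1] == path[i]:
                j += 1
            runs.append((path[i], i, j))
            i = j + 1
        merged = []
        for state, a, b in runs:
            if state == 1:
                if merged and a - merged[-1][1] - 1 <= min_gap:
                    merged[-1] = (merged[-1][0], b)
                else:
                    merged.append((a, b))
        for a, b in merged:
            ga, gb = start_bin + a, start_bin + b
            records.append((str(bins.chrom[ga]), int(bins.start[ga]),
                            int(bins.end[gb]), "domain", np.nan))
    return IntervalSet.from_records(records)


@dataclass
class RTTrack:
    """Two-stage Repli-seq summary: log2(Early/Late) count ratio, z-scored."""

    bins: BinTable
    early_count: np.ndarray
    late_count: np.ndarray
    ratio: np.ndarray
    z: np.ndarray
    degenerate: bool = False


def rt_process(early: SignalTrack, late: SignalTrack) -> RTTrack:
    """log2 ratio of library-size-normalized early/late counts, z-scored.

    Counts are scaled to equal library totals. Bins with a zero count in
    either fraction are missing (never imputed). A zero-variance ratio
    track yields z = 0 and the ``degenerate`` flag.
    """
    if not early.bins.same_grid(late.bins):
        raise ValueError("early and late tracks are on different bin tables")
    e = np.where(np.isfinite(early.value), early.value, 0.0)
    l = np.where(np.isfinite(late.value), late.value, 0.0)
    te, tl = e.sum(), l.sum()
    if te == 0 or tl == 0:
        raise ValueError("zero total count in a fraction")
    en, ln = e / te, l / tl
    ratio = np.full(len(e), np.nan)
    ok = (en > 0) & (ln > 0)
    ratio[ok] = np.log2(en[ok] / ln[ok])
    finite = np.isfinite(ratio)
    mu = ratio[finite].mean()
    sd = ratio[finite].std()
    degenerate = sd == 0
    z = np.full_like(ratio, np.nan)
    z[finite] = 0.0 if degenerate else (ratio[finite] - mu) / sd
    return RTTrack(early.bins, e, l, ratio, z, degenerate)


def differential_rt(a: RTTrack, b: RTTrack, cutoff: float = 0.75,
                    merge_distance: int = 250_000) -> IntervalSet:
    """Regions where |z_b - z_a| >= cutoff, sign-labeled and merged.

    Bins with increased Early/Late in ``b`` are labeled ``hastened``,
    decreased ``delayed``. Flagged intervals of the same label separated by
    at most ``merge_distance`` bp are merged.
    """
    if not a.bins.same_grid(b.bins):
        raise ValueError("mismatched bin tables")
    bins = a.bins
    diff = b.z - a.z
    records = []
    for label, mask in (("hastened", diff >= cutoff), ("delayed", diff <= -cutoff)):
        flagged = np.flatnonzero(mask & np.isfinite(diff))
        clusters = []
        for i in flagged:
            c, s, e = bins.chrom[i], int(bins.start[i]), int(bins.end[i])
            if clusters and clusters[-1][0] == c and s - clusters[-1][2] <= merge_distance:
                clusters[-1][2] = e
            else:
                clusters.append([c, s, e])
        records.extend((c, s, e, label, np.nan) for c, s, e in clusters)
    return IntervalSet.from_records(records)


class DomainHMM(BaseEstimator):
    """Two-state domain segmenter as a scikit-learn style estimator.

    family="bernoulli" binarizes the input track (z of log signal at
    ``threshold``) then fits a Bernoulli HMM; family="gaussian" fits the
    raw values. Fitted attributes: ``model_`` and ``domains_``.
    """

    def __init__(self, family: str = "bernoulli", threshold: float = 1.0,
                 min_gap: int = 1, seed: int = 0, max_iter: int = 100,
                 tol: float = 1e-4, n_restarts: int = 5):
        self.family = family
        self.threshold = threshold
        self.min_gap = min_gap
        self.seed = seed
        self.max_iter = max_iter
        self.tol = tol
        self.n_restarts = n_restarts

    def _observed(self, track: SignalTrack) -> SignalTrack:
        if self.family == "bernoulli":
            return binarize_track(track, threshold=self.threshold)
        return track

    def fit(self, X: SignalTrack, y=None):
        obs_track = self._observed(X)
        seqs = [vals for _, vals in _finite_segments(obs_track)]
        self.model_ = fit_hmm(seqs, family=self.family, seed=self.seed,
                              max_iter=self.max_iter, tol=self.tol,
                              n_restarts=self.n_restarts)
        self.domains_ = viterbi_domains(self.model_, obs_track,
                                        min_gap=self.min_gap)
        return self

    def predict(self, X: SignalTrack) -> np.ndarray:
        """Per-bin Viterbi state (-1 on missing bins)."""
        obs_track = self._observed(X)
        out = np.full(len(obs_track), -1, dtype=np.int64)
        for start_bin, vals in _finite_segments(obs_track):
            out[start_bin:start_bin + len(vals)] = viterbi_path(self.model_, vals)
        return out
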