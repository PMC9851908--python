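"""Two-state HMM segmentation, Repli-seq processing and differential timing."""
import numpy as np
import pytest

import ipgtools as ig
from ipgtools.hmm import (HMMModel, binarize_track, differential_rt, fit_hmm,
                          rt_process, viterbi_domains, viterbi_path)


def track(values, bin_size=25_000, chrom="c"):
    values = np.asarray(values, dtype=float)
    bins = ig.BinTable.from_chromsizes({chrom: len(values) * bin_size}, bin_size)
    return ig.SignalTrack(bins, values)


def brute_force_viterbi(model: HMMModel, obs):
    """Exhaustive max-probability path enumeration."""
    import itertools
    best, best_lp = None, -np.inf
    for path in itertools.product([0, 1], repeat=len(obs)):
        lp = np.log(model.initial[path[0]])
        for t in range(1, len(obs)):
            lp += np.log(model.transition[path[t - 1], path[t]])
        for t, (s, x) in enumerate(zip(path, obs)):
            if model.family == "bernoulli":
                p = model.emission_p[s] if x == 1 else 1 - model.emission_p[s]
                lp += np.log(p)
            else:
                lp += -0.5 * np.log(2 * np.pi * model.sds[s] ** 2) \
                    - (x - model.means[s]) ** 2 / (2 * model.sds[s] ** 2)
        if lp > best_lp:
            best, best_lp = path, lp
    return np.array(best)


def random_model(rng, family):
    init = rng.dirichlet([1, 1])
    trans = np.vstack([rng.dirichlet([5, 1]), rng.dirichlet([1, 5])])
    if family == "bernoulli":
        p = np.sort(rng.uniform(0.05, 0.95, size=2))
        return HMMModel(family, init, trans, emission_p=p)
    means = np.sort(rng.normal(size=2) * 2)
    sds = rng.uniform(0.3, 1.0, size=2)
    return HMMModel(family, init, trans, means=means, sds=sds)


def sample_from(model, n, rng):
    states = np.empty(n, dtype=int)
    states[0] = rng.choice(2, p=model.initial)
    for t in range(1, n):
        states[t] = rng.choice(2, p=model.transition[states[t - 1]])
    if model.family == "bernoulli":
        obs = (rng.random(n) < model.emission_p[states]).astype(float)
    else:
        obs = rng.normal(model.means[states], model.sds[states])
    return states, obs


class TestBinarize:
    def test_constant_track_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            binarize_track(track(np.ones(50)))

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError, match="all-missing"):
            binarize_track(track(np.full(10, np.nan)))

    def test_bimodal_track_labels_high_mode(self, rng):
        lo = rng.normal(1.0, 0.1, 300)
        hi = rng.normal(60.0, 5.0, 60)
        t = track(np.concatenate([lo, hi]))
        out = binarize_track(t, threshold=1.0)
        assert np.all(out.value[300:] == 1.0)
        assert np.all(out.value[:300] == 0.0)

    def test_missing_propagates(self, rng):
        vals = rng.random(50) * 10
        vals[7] = np.nan
        out = binarize_track(track(vals))
        assert np.isnan(out.value[7])
        assert np.isfinite(np.delete(out.value, 7)).all()


class TestViterbi:
    @pytest.mark.parametrize("family", ["bernoulli", "gaussian"])
    def test_matches_exhaustive_enumeration(self, family):
        rng = np.random.default_rng(42)
        for trial in range(8):
            model = random_model(rng, family)
            n = int(rng.integers(3, 13))
            _, obs = sample_from(model, n, rng)
            assert np.array_equal(viterbi_path(model, obs),
                                  brute_force_viterbi(model, obs)), \
                f"trial {trial}: viterbi disagrees with enumeration"

    def test_all_ones_single_domain_per_chromosome(self):
        model = HMMModel("bernoulli", np.array([0.5, 0.5]),
                         np.array([[0.98, 0.02], [0.02, 0.98]]),
                         emission_p=np.array([0.05, 0.9]))
        bins = ig.BinTable.from_chromsizes({"a": 20 * 25_000, "b": 10 * 25_000},
                                           25_000)
        t = ig.SignalTrack(bins, np.ones(30))
        domains = viterbi_domains(model, t)
        assert len(domains) == 2
        assert domains.df.iloc[0].end - domains.df.iloc[0].start == 20 * 25_000

    def test_min_gap_merging(self):
        model = HMMModel("bernoulli", np.array([0.5, 0.5]),
                         np.array([[0.5, 0.5], [0.5, 0.5]]),
                         emission_p=np.array([0.01, 0.99]))
        obs = [1, 1, 1, 0, 1, 1, 0, 0, 0, 1, 1]
        domains0 = viterbi_domains(model, track(obs), min_gap=0)
        domains1 = viterbi_domains(model, track(obs), min_gap=1)
        assert len(domains0) == 3
        assert len(domains1) == 2  # single-bin gap bridged

    def test_domains_invariant_to_trailing_missing_bins(self):
        model = HMMModel("bernoulli", np.array([0.5, 0.5]),
                         np.array([[0.9, 0.1], [0.1, 0.9]]),
                         emission_p=np.array([0.05, 0.9]))
        obs = [0, 0, 1, 1, 1, 0, 0]
        a = viterbi_domains(model, track(obs))
        b = viterbi_domains(model, track(obs + [np.nan] * 5))
        assert a.df.equals(b.df)


class TestFitHMM:
    def test_requires_two_distinct_values(self):
        with pytest.raises(ValueError, match="distinct"):
            fit_hmm([np.zeros(100)], family="bernoulli")

    def test_bernoulli_parameter_recovery(self):
        rng = np.random.default_rng(0)
        true = HMMModel("bernoulli", np.array([0.5, 0.5]),
                        np.array([[0.98, 0.02], [0.02, 0.98]]),
                        emission_p=np.array([0.05, 0.9]))
        _, obs = sample_from(true, 10_000, rng)
        model = fit_hmm([obs], family="bernoulli", seed=1)
        assert model.emission_p[0] == pytest.approx(0.05, abs=0.05)
        assert model.emission_p[1] == pytest.approx(0.9, abs=0.05)
        assert model.transition[0, 0] == pytest.approx(0.98, abs=0.01)
        assert model.transition[1, 1] == pytest.approx(0.98, abs=0.01)

    def test_gaussian_parameter_recovery(self):
        rng = np.random.default_rng(3)
        true = HMMModel("gaussian", np.array([0.5, 0.5]),
                        np.array([[0.97, 0.03], [0.03, 0.97]]),
                        means=np.array([-1.0, 1.0]), sds=np.array([0.3, 0.3]))
        _, obs = sample_from(true, 10_000, rng)
        model = fit_hmm([obs], family="gaussian", seed=1)
        assert model.means[0] == pytest.approx(-1.0, abs=0.1)
        assert model.means[1] == pytest.approx(1.0, abs=0.1)

    def test_loglik_nondecreasing(self):
        rng = np.random.default_rng(5)
        true = HMMModel("bernoulli", np.array([0.5, 0.5]),
                        np.array([[0.95, 0.05], [0.05, 0.95]]),
                        emission_p=np.array([0.1, 0.8]))
        _, obs = sample_from(true, 2_000, rng)
        model = fit_hmm([obs], family="bernoulli", seed=0)
        hist = model.loglik_history
        assert np.all(np.diff(hist) >= -1e-8)

    def test_planted_domain_recovery_jaccard(self):
        rng = np.random.default_rng(9)
        true = HMMModel("bernoulli", np.array([0.5, 0.5]),
                        np.array([[0.97, 0.03], [0.05, 0.95]]),
                        emission_p=np.array([0.05, 0.9]))
        states, obs = sample_from(true, 4_000, rng)
        t = track(obs)
        model = fit_hmm([obs], family="bernoulli", seed=2)
        domains = viterbi_domains(model, t)
        called = domains.bin_membership(t.bins)
        inter = (called & (states == 1)).sum()
        union = (called | (states == 1)).sum()
        assert inter / union > 0.9

    def test_estimator_wrapper(self, rng):
        lo = rng.normal(1.0, 0.3, 300)
        hi = rng.normal(30.0, 3.0, 100)
        sig = np.concatenate([lo, hi, lo])
        est = ig.DomainHMM(family="bernoulli", seed=0)
        est.fit(track(sig))
        assert est.model_.emission_p[1] > est.model_.emission_p[0]
        called = est.domains_.bin_membership(track(sig).bins)
        assert called[300:400].mean() > 0.9
        assert called[:300].mean() < 0.1
        states = est.predict(track(sig))
        assert set(states) <= {0, 1}


class TestRT:
    def test_ratio_and_zscore_arithmetic(self, rng):
        e = rng.integers(1, 100, size=60).astype(float)
        l = rng.integers(1, 100, size=60).astype(float)
        rt = rt_process(track(e), track(l))
        ratio = np.log2((e / e.sum()) / (l / l.sum()))
        assert np.allclose(rt.ratio, ratio)
        assert np.nanmean(rt.z) == pytest.approx(0.0, abs=1e-12)
        assert np.nanstd(rt.z) == pytest.approx(1.0, abs=1e-12)

    def test_equal_fractions_degenerate(self):
        e = np.full(20, 5.0)
        rt = rt_process(track(e), track(e))
        assert np.allclose(rt.ratio[np.isfinite(rt.ratio)], 0.0)
        assert rt.degenerate
        assert np.allclose(rt.z[np.isfinite(rt.z)], 0.0)

    def test_doubled_early_gives_unit_ratio_before_normalization(self):
        # library-size normalization removes a global factor of 2, so the
        # planted ratio survives only through per-bin structure
        rng = np.random.default_rng(1)
        base = rng.integers(10, 100, size=50).astype(float)
        rt = rt_process(track(base * 2), track(base))
        assert np.allclose(rt.ratio, 0.0, atol=1e-12)

    def test_zero_bins_missing(self):
        e = np.array([0.0, 5.0, 0.0, 3.0])
        l = np.array([0.0, 5.0, 2.0, 3.0])
        rt = rt_process(track(e), track(l))
        assert np.isnan(rt.ratio[0]) and np.isnan(rt.ratio[2])

    def test_zero_total_errors(self):
        with pytest.raises(ValueError, match="zero total"):
            rt_process(track(np.zeros(10)), track(np.ones(10)))


class TestDifferentialRT:
    @staticmethod
    def rt_from_z(z, bin_size=50_000):
        t = track(z, bin_size=bin_size)
        nan = np.full(len(z), np.nan)
        return ig.RTTrack(t.bins, nan, nan, nan, np.asarray(z, dtype=float))

    def test_identical_tracks_empty(self):
        a = self.rt_from_z(np.linspace(-1, 1, 30))
        out = differential_rt(a, a)
        assert len(out) == 0

    def test_gap_merging_at_default_distance(self):
        # flagged bins at 0, then gaps of 200 kb and 300 kb
        z = np.zeros(30)
        z[[0, 5, 12]] = 2.0  # gaps: bins 1-4 (200 kb), 6-11 (300 kb)
        a = self.rt_from_z(np.zeros(30))
        b = self.rt_from_z(z)
        out = differential_rt(a, b, cutoff=0.75, merge_distance=250_000)
        assert len(out) == 2
        assert set(out.df["label"]) == {"hastened"}

    def test_antisymmetric_up_to_label_swap(self, rng):
        za = rng.normal(size=40)
        zb = rng.normal(size=40)
        ab = differential_rt(self.rt_from_z(za), self.rt_from_z(zb))
        ba = differential_rt(self.rt_from_z(zb), self.rt_from_z(za))
        swap = {"hastened": "delayed", "delayed": "hastened"}
        ab_swapped = ab.df.assign(label=ab.df["label"].map(swap))
        assert ab_swapped.sort_values(["chrom", "start"]).reset_index(drop=True)[
            ["chrom", "start", "end", "label"]].equals(
            ba.df[["chrom", "start", "end", "label"]])

    def test_mismatched_bins_rejected(self):
        a = self.rt_from_z(np.zeros(30))
        b = self.rt_from_z(np.zeros(25))
        with pytest.raises(ValueError, match="mismatched"):
            differential_rt(a, b)
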