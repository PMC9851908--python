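"""Cis masking, stochastic scaling, eigendecomposition and IPG clustering."""
import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

import ipgtools as ig
from ipgtools.spectral import (Eigenspectrum, cluster_bins, consolidate_clusters,
                               eigendecompose, mask_cis, stochastic_scale)
from conftest import random_symmetric_matrix


class TestMaskCis:
    def test_trans_pixels_untouched(self, toy_bins, rng):
        m = random_symmetric_matrix(toy_bins, rng)
        out = mask_cis(m, seed=0)
        trans = ~m.cis_mask()
        assert np.array_equal(out.values[trans], m.values[trans])

    def test_constant_trans_forces_constant_mask(self, toy_bins):
        vals = np.zeros((len(toy_bins), len(toy_bins)))
        cid = toy_bins.chrom_ids
        trans = cid[:, None] != cid[None, :]
        vals[trans] = 3.5
        m = ig.ContactMatrix(toy_bins, vals)
        out = mask_cis(m, seed=1)
        assert np.all(out.values[~trans] == 3.5)

    def test_masked_values_come_from_donor_rows(self, toy_bins, rng):
        m = random_symmetric_matrix(toy_bins, rng)
        out = mask_cis(m, seed=2)
        cid = toy_bins.chrom_ids
        for i in range(len(toy_bins)):
            for j in range(i, len(toy_bins)):
                if cid[i] != cid[j]:
                    continue
                donors = set(m.values[i, cid != cid[i]]) | \
                    set(m.values[j, cid != cid[j]])
                assert out.values[i, j] in donors

    def test_single_chromosome_rejected(self, rng):
        bins = ig.BinTable.from_chromsizes({"c": 100_000}, 10_000)
        m = random_symmetric_matrix(bins, rng)
        with pytest.raises(ValueError, match=">=2 chromosomes"):
            mask_cis(m)

    def test_seed_determinism(self, toy_bins, rng):
        m = random_symmetric_matrix(toy_bins, rng)
        assert np.array_equal(mask_cis(m, seed=5).values,
                              mask_cis(m, seed=5).values)


class TestStochasticScale:
    def test_uniform_matrix_scales_to_one_over_n(self):
        bins = ig.BinTable.from_chromsizes({"a": 50_000, "b": 50_000}, 10_000)
        vals = np.ones((10, 10))
        m = ig.ContactMatrix(bins, vals)
        out = stochastic_scale(m)
        assert np.allclose(out.values, 0.1)

    def test_marginals_reach_unity(self, toy_bins, rng):
        m = random_symmetric_matrix(toy_bins, rng)
        out = stochastic_scale(m)
        assert np.allclose(out.values.sum(axis=1), 1.0, atol=1e-5)

    def test_invalid_bins_excluded(self, toy_bins, rng):
        m = random_symmetric_matrix(toy_bins, rng)
        valid = np.ones(len(toy_bins), bool)
        valid[4] = False
        m.bins = m.bins.with_valid(valid)
        out = stochastic_scale(m)
        assert np.all(out.values[4, :] == 0)
        marg = out.values.sum(axis=1)
        assert np.allclose(marg[valid], 1.0, atol=1e-5)


class TestEigendecompose:
    def test_matches_dense_solver_on_random_symmetric(self):
        rng = np.random.default_rng(0)
        bins = ig.BinTable.from_chromsizes({"a": 150_000, "b": 150_000}, 10_000)
        vals = rng.random((30, 30))
        vals = (vals + vals.T) / 2
        np.fill_diagonal(vals, 0)
        m = ig.ContactMatrix(bins, vals)
        es = eigendecompose(m, n_eigs=5)
        w_ref, v_ref = np.linalg.eigh(vals)
        order = np.argsort(-np.abs(w_ref))
        for k in range(5):
            assert es.eigenvalues[k] == pytest.approx(w_ref[order[k]], abs=1e-8)
            v = v_ref[:, order[k]]
            dot = abs(np.dot(v, es.vectors[:, k]))
            assert dot == pytest.approx(1.0, abs=1e-8)

    def test_two_block_matrix_has_two_valued_leading_vector(self):
        bins = ig.BinTable.from_chromsizes({"a": 40_000, "b": 40_000}, 10_000)
        # trans-like block structure: two groups, strong within-group affinity
        group = np.array([0, 0, 1, 1, 0, 0, 1, 1])
        vals = np.where(group[:, None] == group[None, :], 2.0, 0.5)
        np.fill_diagonal(vals, 0.0)
        m = stochastic_scale(ig.ContactMatrix(bins, vals))
        es = eigendecompose(m, n_eigs=2)
        e1 = es.vectors[:, 0]
        assert len(np.unique(np.round(e1[group == 0], 6))) <= 2
        assert np.sign(e1[group == 0].mean()) != np.sign(e1[group == 1].mean())

    def test_trivial_constant_vector_dropped(self, toy_bins, rng):
        m = stochastic_scale(random_symmetric_matrix(toy_bins, rng))
        es = eigendecompose(m, n_eigs=3)
        # eigenvalue 1 belongs to the constant vector and must not appear
        assert np.all(np.abs(es.eigenvalues) < 1.0 - 1e-6)
        for k in range(es.m):
            v = es.vectors[np.isfinite(es.vectors[:, k]), k]
            assert np.std(v) / max(abs(np.mean(v)), 1e-12) > 1e-3

    def test_orientation_track_fixes_sign(self, toy_bins, rng):
        m = stochastic_scale(random_symmetric_matrix(toy_bins, rng))
        ref = ig.SignalTrack(toy_bins, rng.random(len(toy_bins)), name="ref")
        es = eigendecompose(m, n_eigs=3, orientation_track=ref)
        for k in range(es.m):
            v = es.vectors[:, k]
            assert np.corrcoef(v, ref.value)[0, 1] >= 0
        assert es.orientation_ref == "ref"

    def test_too_many_eigs_rejected(self, toy_bins, rng):
        m = random_symmetric_matrix(toy_bins, rng)
        with pytest.raises(ValueError, match="n_eigs"):
            eigendecompose(m, n_eigs=len(toy_bins))

    def test_rank_m_reconstruction_error_decreases(self, small_dataset):
        _, contacts, _ = small_dataset
        m = ig.filter_bins(contacts)
        scaled = stochastic_scale(mask_cis(m, seed=0))
        es = eigendecompose(scaled, n_eigs=9)
        valid = m.bins.valid
        sub = scaled.values[np.ix_(valid, valid)]
        V = es.vectors[valid]
        errs = []
        base = sub - np.outer(np.ones(len(sub)), np.ones(len(sub))) / len(sub)
        for k in range(1, 10):
            approx = (V[:, :k] * es.eigenvalues[:k]) @ V[:, :k].T
            errs.append(np.linalg.norm(base - approx))
        assert all(a > b for a, b in zip(errs, errs[1:]))


class TestClusterBins:
    @staticmethod
    def blob_spectrum(rng, n=300, k=3, sep=5.0):
        centers = rng.normal(size=(k, 4)) * sep
        labels = rng.integers(0, k, size=n)
        X = centers[labels] + rng.normal(scale=0.2, size=(n, 4))
        bins = ig.BinTable.from_chromsizes({"c": n * 1000}, 1000)
        return Eigenspectrum(bins, np.ones(4), X), labels

    def test_planted_blobs_recovered_exactly(self, rng):
        spec, labels = self.blob_spectrum(rng)
        assign = cluster_bins(spec, k=3, seed=0)
        assert adjusted_rand_score(labels, assign.cluster_label) == 1.0
        assert assign.silhouette > 0.8

    def test_single_cluster_silhouette_missing(self, rng):
        spec, _ = self.blob_spectrum(rng)
        assign = cluster_bins(spec, k=1, seed=0)
        assert np.isnan(assign.silhouette)

    def test_k_larger_than_bins_rejected(self, rng):
        spec, _ = self.blob_spectrum(rng, n=5)
        with pytest.raises(ValueError):
            cluster_bins(spec, k=10)

    def test_seed_determinism(self, rng):
        spec, _ = self.blob_spectrum(rng, k=5)
        a = cluster_bins(spec, k=5, seed=3)
        b = cluster_bins(spec, k=5, seed=3)
        assert np.array_equal(a.cluster_label, b.cluster_label)


class TestConsolidate:
    @staticmethod
    def assignment_with_profiles(profiles, n_per=20):
        k = len(profiles)
        n = k * n_per
        bins = ig.BinTable.from_chromsizes({"c": n * 1000}, 1000)
        clabel = np.repeat(np.arange(k), n_per)
        assign = ig.IPGAssignment(bins, k, clabel,
                                  np.array([f"C{c}" for c in clabel], dtype=object),
                                  {c: f"C{c}" for c in range(k)}, 0.5)
        tracks = {}
        profiles = np.asarray(profiles, dtype=float)
        for t in range(profiles.shape[1]):
            tracks[f"t{t}"] = ig.SignalTrack(bins, profiles[clabel, t])
        return assign, tracks

    def test_identical_profiles_merged(self):
        assign, tracks = self.assignment_with_profiles(
            [[1.0, 2.0, 0.5], [1.0, 2.0, 0.5], [5.0, 0.1, 3.0]])
        out = consolidate_clusters(assign, tracks, merge_threshold=0.99)
        assert out.cluster_to_ipg[0] == out.cluster_to_ipg[1]
        assert out.cluster_to_ipg[2] != out.cluster_to_ipg[0]

    def test_threshold_one_is_identity(self):
        assign, tracks = self.assignment_with_profiles(
            [[1.0, 2.0, 0.5], [1.0, 2.0, 0.5], [5.0, 0.1, 3.0]])
        out = consolidate_clusters(assign, tracks, merge_threshold=1.0)
        assert len(set(out.cluster_to_ipg.values())) == 3

    def test_user_map_overrides_and_rejects_conflicts(self):
        assign, tracks = self.assignment_with_profiles(
            [[1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
        out = consolidate_clusters(assign, tracks,
                                   cluster_to_ipg={0: "X", 1: "X", 2: "Y"})
        assert list(out.ipg_label[:40]) == ["X"] * 40
        with pytest.raises(ValueError, match="mapped twice"):
            consolidate_clusters(assign, tracks,
                                 cluster_to_ipg=[(0, "X"), (0, "Y")])


class TestPipeline:
    def test_masking_seed_neutrality(self, small_dataset):
        truth, contacts, tracks = small_dataset
        m = ig.filter_bins(contacts)
        labels = []
        for mask_seed in (0, 1):
            est = ig.SpectralIPG(mask_seed=mask_seed, cluster_seed=0)
            est.fit(m, tracks=tracks)
            v = np.array([x is not None for x in est.labels_])
            labels.append([str(x) for x in est.labels_[v]])
        assert adjusted_rand_score(labels[0], labels[1]) > 0.95

    def test_estimator_api(self, small_dataset):
        truth, contacts, tracks = small_dataset
        m = ig.filter_bins(contacts)
        est = ig.SpectralIPG(k=8, n_eigs=9)
        assert est.get_params()["k"] == 8
        out = est.fit_predict(m, tracks=tracks)
        assert len(out) == m.n_bins
        assert est.eigenspectrum_.m == 9
        assert np.isfinite(est.silhouette_)
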