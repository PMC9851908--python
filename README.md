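# ipgtools

Tools for calling **interaction profile groups (IPGs)** — sets of genomic
bins with similar long-range (*trans*) Hi-C contact profiles, a
generalization of A/B subcompartments — and for the downstream analytics
that characterize them: saddle plots, per-group contact-decay curves
*P*(*s*), diamond insulation with prominence-ranked boundaries, CTCF
pileups, two-state HMM domain segmentation, replication-timing comparison,
and a 1D loop-extrusion simulator with CTCF capture/release.

The package targets desk-scale binned contact maps (a few thousand bins)
and ships a synthetic-data generator that plants five chromatin-state-like
IPGs (A1/A2/B0/B1/B4), so every stage of the pipeline can be validated
against known ground truth without any downloads.

## The core procedure

Given a raw binned contact matrix **C** (cooler-layout HDF5 or text COO):

1. **Filter** low-coverage bins (MAD-max rule) and balance by **iterative
   correction** so per-bin marginals are equal.
2. **Mask cis**: every within-chromosome pixel (i, j) is replaced by a
   pixel sampled uniformly from the *trans* entries of row i or column j
   (fair coin per pixel), removing distance-decay structure.
3. **Rescale** the masked matrix so every row and column sums to 1.
4. **Eigendecompose**: take the leading eigenpairs of the symmetric
   row-stochastic matrix in descending order of eigenvalue modulus |λ₁| ≥
   |λ₂| ≥ …, dropping the trivial constant eigenvector; the eigenvectors
   E1…E9 are each bin's coordinates in interaction-profile space.
5. **Cluster**: multiply each unit eigenvector by |λ| and run k-means
   (k = 8 by default) on the rows; report the silhouette score.
6. **Consolidate**: merge clusters whose standardized functional-track
   profiles (ChIP-like signals, replication timing, …) correlate above a
   threshold — typically centromere-proximal/-distal pairs of the same
   chromatin state — yielding the final IPG labels.

The loop-extrusion model is a 1D lattice of 1-kb monomers: loop-extruding
factors occupy pairs of monomers, each leg steps outward with probability
½ per step, CTCF sites capture incoming legs with probability
min((fc − 1)/fc_med, 1), captured legs release with probability 0.006 per
step, and factors unload with probability 1/100 per step and reload at
random (average separation 600 monomers).

## Worked example

```python
import numpy as np
from sklearn.metrics import adjusted_rand_score
import ipgtools as ig

# synthetic genome: 3 chromosomes, 1,500 50-kb bins, 5 planted states
truth, contacts, tracks = ig.simulate_dataset(seed=1)

m = ig.filter_bins(contacts)
est = ig.SpectralIPG(n_eigs=9, k=8, mask_seed=11, cluster_seed=21)
est.fit(m, tracks=tracks)

valid = np.array([x is not None for x in est.labels_])
ari = adjusted_rand_score(truth.state[valid],
                          [str(x) for x in est.labels_[valid]])
print(f"clusters: {est.assignment_.k}  silhouette: {est.silhouette_:.3f}")
print(f"IPGs after consolidation: {len(set(est.labels_[valid]))}  ARI: {ari:.3f}")
```

prints

```
clusters: 8  silhouette: 0.685
IPGs after consolidation: 5  ARI: 1.000
```

i.e. k-means finds eight clusters (states split into centromere-proximal
and -distal arms by the positional E2-like gradient), consolidation merges
them back into the five planted states, and the recovered labels agree
perfectly with the planted ones (adjusted Rand index 1.0).

The same pipeline is available from the shell:

```bash
ipg simulate --out data --seed 1
ipg balance data/contacts.cool data/balanced.cool
ipg cluster data/contacts.cool --out-prefix data/ipg --k 8
ipg insulation data/balanced.cool --out-prefix data/ins --window 200000
ipg lef-sim --out-prefix data/lef --n-monomers 60000 --steps 20000 --seed 1
```

All seeded commands are byte-reproducible.

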