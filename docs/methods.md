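# Methods

## Scope and data model

All coordinates are 0-based, half-open; chromosome order is fixed by the
bin table and never re-sorted. Missing data are explicit everywhere (NaN
for real values, −1/None for labels) and never silently imputed as zero.
Contact matrices are held dense, which is adequate for the desk-scale
genomes this package targets (≲ 5,000 bins); the cooler-layout HDF5
reader/writer stores the upper triangle only and disables HDF5 timestamps
so that seeded runs serialize byte-identically.

## Balancing and filtering

Bin filtering marks a bin invalid when its raw coverage falls more than
`mad_threshold` (default 5) median absolute deviations below the median
coverage, or when it has fewer than `min_nnz` (default 2) nonzero pixels.
Iterative correction runs the standard ICE multiplicative update on the
valid submatrix; convergence is declared when the relative variance of
the nonzero marginals drops below `tol` (default 1e-5, max 300
iterations). Balancing a balanced matrix moves the weights by less than
the tolerance (idempotence), and the symmetric update preserves the zero
pattern exactly.

## Spectral IPG calling

Cis masking replaces each within-chromosome pixel by a uniformly sampled
*trans* pixel of the same row or column (fair coin per pixel, seeded);
only valid donor columns are used, and symmetry is restored by mirroring
the upper triangle. The masked matrix is rescaled by iterative
proportional fitting until every valid row sums to 1 (relative marginal
variance < 1e-10). The full symmetric eigendecomposition is taken
(`numpy.linalg.eigh` on the valid submatrix — cheap at this scale),
eigenpairs are ordered by descending |λ|, and the trivial constant
eigenvector at λ = 1 is detected by its coefficient of variation
(< 1e-3) and dropped before numbering E1…Em. Eigenvector signs are
arbitrary; they are fixed against a user-named orientation track
(non-negative correlation), falling back to "first nonzero entry
positive".

For clustering, each unit-norm eigenvector is multiplied by its
eigenvalue modulus (so components are weighted by the structure they
capture) and k-means is run on the rows with 40 restarts, keeping the
best inertia. Forty restarts (rather than the more conventional 10) are
deliberate: on a three-chromosome genome the valid bins form roughly
`n_states × n_chromosomes` tight blobs in eigenvector space, and
inertia-optimal partitions of ~15 blobs into k = 8 clusters are easy for
k-means to miss from few starts; the extra restarts cost under two
seconds. Alternative rescalings (`unit-variance`, `none`) are exposed.

Consolidation computes each cluster's mean functional-track profile,
standardizes each track across clusters, and merges clusters whose
profile vectors correlate strictly above `merge_threshold` (default 0.9,
transitively via union–find). An explicit cluster→IPG map overrides the
automatic merge and rejects clusters mapped twice.

Translocated or otherwise untrustworthy regions are handled by
invalidating bins (a user-supplied BED of exclusions); there is no
automatic structural-variant detection.

## The synthetic genome

The generator is the ground-truth instrument for the whole package. Its
default configuration — three chromosomes of 600/500/400 bins at 50 kb
with offset centromeres — is the smallest layout on which *trans*
eigendecomposition, the positional gradient, and per-chromosome analyses
are all exercised.

States are painted as Markovian domains: run lengths are geometric with
mean `domain_length_mean` (default 20 bins = 1 Mb), successive states are
drawn from the stationary probabilities (0.10, 0.30, 0.20, 0.25, 0.15 for
A1/A2/B0/B1/B4, approximating the genome shares seen in colon-cancer
epithelial cells, where the speckle-proximal active state is small and
constitutive heterochromatin covers roughly a sixth of the genome).

Expected pixel intensity factorizes as
`λ_ij = affinity[s_i, s_j] · g(|cd_i − cd_j|) · d(s_ij)` with

* `g(Δ) = exp(−w·Δ/L)` — the centromere-distance similarity term
  (`w = positional_strength`, default 0.3; `L = 10 Mb`), which produces an
  E2-like positional gradient orthogonal to the state structure;
* `d(s) = (s/bin)^(−γ)` in cis (γ = 1), optionally multiplied by an
  extrusion-shoulder factor `1 + A·exp(−s/s₀)` with a per-state scale s₀
  when both bins share a state;
* a constant (`trans_level = 0.1`) in trans.

Counts are Poisson at an expected total of 1e7 pairs by default.

**Why the affinity contrasts are larger than genome-wide observed/expected
values in real data.** With three chromosomes, cis masking resamples a
third of every row (a twenty-third in a real genome); the realized random
cis blocks perturb the eigenvectors with chromosome-coherent offsets that
do not shrink with sequencing depth. For the five states to remain
separable by k-means under this scaled-down geometry, the homotypic
preferences must be proportionally stronger — the default affinity matrix
has trans O/E contrasts up to ~13 where genome-wide maps show ~2. The
qualitative structure is preserved: the B4-like state has the largest
self-affinity, the B0-like row is the flattest (neutral profile), A1 and
A2 couple to each other more strongly than to any inactive state. One
consequence of the desk scale is that the A1–A2 heterotypic coupling must
stay *below* both self-affinities (in real maps it can reach the A2
self-affinity); at equal coupling the two active states merge into a
single k-means continuum that no downstream consolidation can split.

Tracks are Gaussian per-state emissions (speckle-marker-like, H3K9me3-like,
H3K27me3-like, H2A.Z-like, and a replication-timing-like track bimodal in
the planted early/late class), sd 0.5. CTCF sites are planted per bin with
state-dependent probability — lowest by far in the B4-like state, which
models heterochromatin's depletion of extrusion barriers — with
log-normal fold-changes.

What the generator does **not** emulate: translocations and copy-number
structure, mappability artifacts, distance-dependent noise correlations,
sub-bin features (loops/stripes as discrete dots), and trans contacts
beyond a state-plus-position product form. Passing recovery tests
therefore demonstrates correctness of the algorithms under the stated
generative model, not robustness to every artifact of real Hi-C.

## Compartment metrics

Distance-decay curves pool per-diagonal means into geometric strata of
ratio 2^(1/8); the representative separation of a stratum is the
geometric mean of its diagonals. Pooling introduces ≲3% curvature on a
pure power law, which is below the tolerances used anywhere. Group P(s)
includes a pixel only when both bins lie inside the *same* labeled
domain, and curves are normalized to exactly 1 at `normalization_s`
(default 10 kb) by log-log interpolation. The log-derivative uses
centered differences with an optional moving-average smoothing of log P.

Observed/expected uses the per-chromosome per-diagonal mean as the cis
expected and the per-chromosome-pair mean as the trans expected. Saddle
quantile groups are rank-based equal-count groups with one refinement:
a block of tied track values is assigned en bloc to the group of its
median rank, so indicator-like tracks split at the value boundary instead
of scattering ties across groups (group counts then deviate from equal
only as much as the ties force).

## Insulation and pileups

The diamond insulation score at bin i is the mean balanced contact in the
`window × window` block between the `w` bins upstream and the `w` bins
from i onward (w = window/bin size, default 100 kb at 25-kb bins), taken
as log2 of its ratio to the chromosome-wide mean. With this convention a
sharp two-block boundary scores at exactly the first bin of the
downstream block. Insulating loci are local minima of the score with
topographic prominence (computed on the negated score per chromosome,
`scipy.signal.find_peaks`) at or above the threshold; the reported tiers
0.01 and 0.1 correspond to permissive and stringent boundary sets, and
calls are monotone in the threshold by construction. NaN runs split
chromosomes into independent segments so masked regions cannot fabricate
minima; edge plateaus act as maxima.

CTCF pileups cut on-diagonal snippets of ±flank bins at each site
midpoint, divide by a *group-specific* distance-expected (computed from
pixels inside the group's own domains, falling back to the global cis
expected at separations the group does not cover), mirror minus-strand
snippets, and average per group. Sites within a flank of a chromosome
edge or an invalid bin are skipped and counted.

## Domain HMMs and replication timing

Both segmentation families are two-state hidden Markov models fitted by
Baum–Welch (hmmlearn backend) on per-chromosome sequences; NaN gaps break
sequences rather than being imputed. Initialization is a jittered
quantile split (Bernoulli: p ≈ 0.05/0.9; Gaussian: k-means-style median
split of values) over 5 seeded restarts keeping the best likelihood —
EM on two well-separated states is insensitive to this choice, but the
restarts guard against label collapse on short inputs. State identity is
fixed post hoc (state 1 = higher emission), and Viterbi runs of state 1
become domains, with runs separated by at most `min_gap` bins (default 1)
merged. Broad-mark tracks are binarized beforehand as
z(log(x + 1)) ≥ 1.

Two-stage Repli-seq processing scales early and late counts to equal
library totals, takes log2(Early/Late) per bin (missing whenever either
fraction is zero), and z-scores the result. Differential-timing calling
thresholds |Δz| at 0.75 and merges flagged bins of the same sign
(hastened/delayed) separated by at most 250 kb.

## Loop-extrusion simulator

The 1D dynamics follow the rules stated in the package docstring
(`ipgtools.lef`): two-sided stepping at probability ½ per leg,
occupancy exclusion without queuing, CTCF capture on arrival at a
blocking-orientation site with probability min((fc − 1)/fc_med, 1),
release at 0.006 per step, unloading at 1/100 per step with instant
uniform reloading so the factor count stays at
⌊n_monomers/mean_separation⌋. Orientation semantics are the convergent
rule — a '+' site captures left-moving (upstream) legs, a '−' site
right-moving legs — with an orientation-agnostic mode available.
`fc_med` is the median fold change over the simulated site list. Blocked
regions are impermeable to legs and excluded from loading, which
implements the assay in which extrusion into a heterochromatic interval
is forbidden and peripheral stripes disappear.

At low density the steady-state mean loop size approaches
(growth rate)/(unload rate) = 1 monomer/step × 100 steps ≈ 100 monomers;
at the default separation of 600 monomers, factor–factor collisions
depress this by roughly 10%, so the quantitative steady-state checks run
at separation 6,000 (100 factors on a 600,000-monomer lattice, ~2 × 10⁶
factor-steps — a few seconds of CPU). Captured-leg dwell times are
geometric with mean 1/0.006 ≈ 167 steps; the dwell assay uses densely
spaced always-capturing sites with unloading disabled, because unloading
would censor dwell episodes and bias the conditional mean toward
1/(release + unload).

The contact-map synthesis adds one contact per sampled factor at its leg
pair on top of a smooth s⁻¹ background carrying a configurable multiple
of the loop-contact mass, binned to the requested resolution. It is a
deliberately minimal 1D readout for insulation-level analyses — no
polymer conformations are simulated, so it reproduces loop-base dots and
boundary insulation but not stripe fine structure; the
`md_steps_per_1d = 400` field is retained as metadata for comparability
with 3D implementations.

## Problem sizes and numerical choices

Validation and the reproduction script run at: 1,500-bin genomes at 1e7
pairs for recovery (full pipeline ≈ 2 s); 300-bin two-chromosome genomes
at 1e6 pairs for saddle recovery; 10-kb-bin single-chromosome genomes at
2e7 pairs for P(s); 20 replicates of 10,000 observations for HMM
parameter recovery; ~2 × 10⁶ factor-steps for extrusion steady state.
Ties everywhere break by stable bin order; k-means, masking and all
generators take explicit seeds; degenerate inputs (constant tracks,
single-class labels, empty groups) raise or warn rather than returning
silent zeros.

## Known limitations

* Dense matrices cap practical genome size at a few thousand bins.
* The eigenvector numbering (E1…) counts from the first non-constant
  component; on matrices that are not doubly stochastic no component is
  dropped.
* Cluster count k is not chosen automatically; the silhouette is reported
  and k is a parameter (the library default k = 8 with 9 eigenvectors
  mirrors the reference workflow on colon-cancer cells).
* The Bernoulli HMM operates on binarized tracks; information lost in
  binarization is not recoverable downstream.
* The LEF contact map is a 1D surrogate; quantities that depend on 3D
  polymer conformations (radius of gyration, spatial distances) are out
  of scope.
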