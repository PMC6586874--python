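# Methods

This note records the models, algorithms, defaults and design choices behind
`cytoqf`, and what the synthetic benchmark does and does not demonstrate.

## Pipeline overview

The package analyses cytometry-style event tables (events × channels) in
three stages, each usable independently:

1. **Subset identification** — recursive projection-pursuit clustering
   (`epp`), built on a 2D density-mode clusterer (`dbm2d`).
2. **Subset matching** — quadratic-form cluster matching between two
   samples with split/missing resolution (`qfmatch`, `qf_core`).
3. **Display** — joint MDS of subset medians and an agglomerative QF-tree
   (`viz`).

Input is assumed compensated and pre-gated for live singlets; the package
performs neither step. Fluorescence channels are normally brought onto the
Logicle display scale before clustering.

## Logicle transform

The Logicle scale is the standard biexponential display for compensated
fluorescence data: logarithmic at high signal, linear through zero. We use
the (T, M, W, A) parameterization: `T` top-of-scale data value, `M` total
decades, `W` linearization width in decades, `A` extra negative decades.
The forward transform inverts the biexponential
`B(y) = a·e^{by} − c·e^{−dy} + f` (coefficients fixed by `B(x1)=0`,
`B(1)=T` and the smoothness condition on `d`) by a bracketed vectorized
bisection; 80 halvings give display-scale resolution far below
`1e−6·T` on data scale, which the round-trip tests verify.

Defaults: `T = 262144`, `M = 4.5`, `A = 0`; `W` is estimated per channel as
`max(0, (M − log10(T/|r|))/2)` with `r` the 5th percentile of the channel's
negative values, falling back to `0.5` decades for channels with no negative
events. These are the customary instrument-scale defaults; all are
overridable per call and via `PipelineConfig`. Channels whose names match
`FSC*`/`SSC*`/`Time` are linearly rescaled to `[0, M]` instead — scatter
and time are already linear quantities.

Rows containing non-finite values are dropped on load (never imputed); the
count is logged and kept on the `EventMatrix`.

## 2D density clustering (DBM-style) and the boundary index

Density is a binned KDE: a 128×128 histogram over the data range padded by
3 bandwidths, smoothed with a Gaussian kernel using per-axis plug-in
bandwidths `h_i = sd_i · n^{−1/6}` (the Silverman/Scott rule for d = 2),
renormalized to integrate to 1 (±1e−6).

Clustering is watershed-by-ascent: each grid cell points to its densest
8-neighbor (ties broken toward the lower flat index, making the result
deterministic and independent of event order); pointer-chasing yields the
basin of a density mode for every cell. Two refinements follow:

* **Saddle merging.** Basins whose highest connecting saddle density
  exceeds θ = 0.5 of the lower of the two peak densities are merged,
  repeatedly, most-connected pair first. This is a transparent stand-in for
  a full statistical significance test of mode separation; θ is
  configurable.
* **Insignificant-cluster dissolution.** Isolated tail events create tiny
  density islands with no active cells connecting them to any other basin,
  so no saddle exists and the merge rule cannot absorb them. Clusters
  holding under 1% of the events are therefore dissolved and their events
  reassigned. Without this, a single Gaussian occasionally fragments into
  satellites of a handful of events.

Cells below 1e−4 of the peak density start unclustered; every event in such
a cell (or in a dissolved cluster) is assigned to the nearest clustered
event, so the final labeling covers all events.

The **boundary misclassification index** for a proposed two-way split is
the plug-in Bayes error of the two-class problem: with side priors
`π_s = n_s/n` and per-side KDEs `p̂_s` on a common grid (each side keeps its
own bandwidth), the index is `Σ_cells min(π₁p̂₁, π₂p̂₂)·cell_area ∈ [0, 0.5]`.
It is deterministic and symmetric; on two unit Gaussians 2 SD apart with
equal priors it reproduces the closed form Φ(−1) ≈ 0.159 within 0.02. The
kernel smoothing biases it slightly upward for separable classes and
slightly downward in the degenerate identical-classes case.

## Recursive projection pursuit

At every node of the gating recursion, each unordered pair of measured
channels is clustered in 2D. For every multi-cluster outcome, candidate
two-way separations are all bipartitions of the clusters (cluster-vs-rest
plus mixed groupings; with more than 10 clusters, cluster-vs-rest only) and
each is scored with the boundary index. The globally smallest-error
candidate splits the node when

* its error ≤ `max_error` (default **0.05**), and
* both sides hold ≥ `min_leaf_size` events (default
  `max(200, 0.2% of the sample)`).

Otherwise the node is a leaf. Leaves are labeled 1..K in depth-first
discovery order; side 1 of a split is the side containing the
lowest-index event, and ties in error resolve to the lexicographically
first channel pair — together these make the whole recursion deterministic.

The search is over axis-aligned channel pairs only (exhaustive and
practical up to ~20 channels); rotated 2D projections are not searched. The
stopping thresholds are design choices — there is no universally correct
minimum subset size — and both are exposed in `EPPConfig`.

The 0.05 error ceiling sets the method's resolution: two equal unit-SD
Gaussian subpopulations must sit ≳ 3.3 SD apart (Bayes error
Φ(−1.645) ≈ 0.05) to be splittable even in principle, and the KDE
bandwidth inflates the effective overlap at small n.

## Adaptive binning and the quadratic-form dissimilarity

To compare clusterings of two samples, the merged pair of samples is
partitioned by recursive median splits: each node splits at the median of
its highest-variance dimension (ties toward the lower dimension index;
events equal to the threshold go right). The depth is global,

    L = round(log2(n_merged / (2·ln N))),  floored at 0,

with `N` the smaller sample's event count, giving `B = 2^L` bins averaging
≈ `2·ln N` events each — e.g. two samples of 1000 events give B = 128, two
of 20000 give B = 2048. A balanced global depth is the simplest reading of
the events-per-bin target; empty bins are retained (frequency 0) so both
samples share one bin index space, and an empty bin inherits its nearest
non-empty ancestor's centroid.

Each cluster becomes a frequency vector `f` over the bins (member counts,
normalized). Dissimilarity between two clusters is

    QF(f, g) = sqrt((f−g)ᵀ A (f−g)),   A_ij = 1 − d_ij/d_max,

with `d_ij` the Euclidean distance between bin centroids and `d_max` its
maximum, computed once per binning. Because `f−g` sums to zero and
Euclidean distance matrices are conditionally negative definite, the form
is positive semidefinite on exactly the vectors that arise; round-off
negatives are clamped before the square root. The vectorized evaluation is
tested against a brute-force double loop to 1e−12, and metric axioms
(symmetry, identity, triangle inequality) are property-tested.

Degenerate case `B = 1`: all QF scores are zero; matching falls back to
median-distance ordering with a logged warning.

## Matching, merging, split vs missing

Only cluster pairs whose medians lie within `4·max(sd_a, sd_b)` in **every**
dimension are scored (dimensions where both SDs are zero require exact
median equality). Matching is greedy: repeatedly accept the globally
smallest remaining score one-to-one, ties to the lexicographically lower
label pair. Optimal (Hungarian) assignment was considered and rejected as
the default: the greedy rule is the direct reading of
"smallest score wins" and differs only in pathological near-tie tables.

Leftover clusters are merging candidates. For a candidate `c` in sample S
and each counterpart `x` in the other sample with a scored `(x, c)` pair,
all combinations of `c` with `x`'s current partner and S's other candidates
(capped at 1024 combinations) are pooled, re-gated against `x`, and
re-scored **on the original binning** (re-binning per combination would let
the bin layout, not the data, move the decision). If the best pooled score
is strictly below the candidate's initial pairwise score against `x`, `x`
is recorded as split across the pooled group; if no combination improves on
any counterpart, `c` is missing. Every subset ends up in exactly one match,
one split group, or the missing list (asserted at run time).

## Displays

**MDS.** Classical (Torgerson) scaling of the pooled subset-median distance
matrix: double-center the squared distances, take the top-2 eigenpairs.
Chosen over iterative stress majorization for exactness on planar
configurations and full determinism; orientation is canonicalized (axes by
eigenvalue, signs so the first loaded point is positive). Circle radius is
`sqrt(frequency)` so circle *area* is proportional to subset frequency;
matched subsets share a color.

**QF-tree.** Bottom-up agglomeration of one sample's subsets under
`QF + c·DM`, `DM` being the Euclidean distance between group medians.
`c = min(initial QF) / max(initial DM)` is fixed once from the leaf-level
tables (re-scaling per level would make heights incomparable across
levels). At each level the merged group is pooled as one cluster and every
pairwise comparison is re-binned on the two groups involved. Because the
dissimilarity is recomputed per level it is not guaranteed monotone;
decreasing merge heights are clamped to the running maximum with a logged
warning. The Newick export carries the QF component of each merge as the
branch length; all-identical-medians input degrades to pure QF (`c = 0`,
logged).

## Synthetic benchmark

The generator draws diagonal-covariance Gaussian mixtures with fixed
per-sample PCG64 streams (bit-reproducible for a given seed). The canonical
pair emulates a two-sample study where one population splits:

* Sample A: three unit-SD components, 8000/6000/6000 events, means
  (0,0,0), (12,0,0), (0,12,0) — pairwise separation 12 SD.
* Sample B: A's first two components unchanged, plus two 3000-event
  components at (0,12,∓2): their joint mean equals A3's mean and their
  joint count equals A3's count, so together they occupy A3's region while
  forming two resolvable modes.

The split centers sit 4 SD apart by design: the method's own stopping rule
caps detectable splits at Bayes error 0.05 (≈ 3.3 SD for equal unit-SD
pairs), and the saddle-merge rule needs roughly ≥ 3.4 SD after kernel
smoothing, so a 4-SD split is detectable with margin while remaining a
genuinely overlapping pair (≈ 2.3% Bayes error). The expected matching —
A1↔B1, A2↔B2, A3 split across {B3, B4} — is recorded in the fixture's
metadata so tests assert against the construction.

What the generator does **not** emulate: spectral spillover, asymmetric or
heavy-tailed populations, doublets/debris, acquisition drift, rare
populations below the minimum-leaf threshold, and correlated channels.
Passing the benchmark therefore demonstrates the pipeline's mechanics
(recursion, matching, merging, displays) under clean mixture conditions,
not robustness to instrument artifacts.

Problem sizes used by the test suite and the acceptance script: 20 000
events per sample (3 channels) for single-run checks; 20 replicate seeds at
full scale for the leaf-count recovery rate and at half scale for the
match-recovery rate.

## Known limitations

* Axis-aligned projections only; a rotated separating direction between two
  populations can be missed if no channel pair exposes it.
* The saddle-ratio merge rule and the 1% dissolution threshold are
  heuristics standing in for a significance test of mode separation.
* The boundary index inherits KDE bias: splits near the 0.05 ceiling can
  flip with sample size because bandwidth scales as n^(−1/6).
* Matching is pairwise between two samples; multi-sample alignment must be
  composed from pairwise runs.
* QF-tree cost grows as O(k³) pairwise re-binnings for k subsets; fine for
  tens of subsets, not thousands.
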