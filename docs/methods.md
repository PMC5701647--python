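# Methods

This note documents the models, estimators and numerical choices behind
`hemilat`, in the spirit of a package methods appendix: what is
computed, under which assumptions, and where the design was genuinely
open.

## Network construction

**Functional.** Given an ROI time-series matrix (time × 90 regions),
connectivity is the pairwise Pearson correlation, Fisher-transformed
(`z = atanh r`) to stabilize variance. Correlations are clipped to
|r| ≤ 0.999999 before the transform because `atanh(±1)` diverges and
degenerate correlations do occur in synthetic and short-series data.
Negative z values are set to zero — the physiological meaning of
negative resting-state correlations is contested, and the downstream
metrics assume nonnegative weights. Columns with zero variance are an
error (they indicate a dead region extraction), named by index.

**Structural.** Edge weights are streamline densities,
`w_ij = counts_ij / (vol_i + vol_j)`, which corrects streamline counts
for the sizes of the two interconnected regions. Counts must be
symmetric and volumes strictly positive.

**Hemispheric split.** The 90-region parcellation has 45 homotopic
left/right pairs. Interhemispheric entries are discarded and each
hemisphere's 45×45 block is reordered by homotopic pair index, so
element (i, j) of the left network and element (i, j) of the right
network refer to the same region pair. All paired analyses (laterality
index, NBS) rely on this alignment.

**Sparsity thresholding (functional only).** Each hemispheric
functional network is thresholded to fixed sparsity s by keeping the
K = round(s · N(N−1)/2) strongest edges at their original weights
(N = 45, so 990 possible edges; s = 0.10 keeps 99). Rounding is
half-away-from-zero and ties at the cutoff break deterministically
(descending weight, then ascending (i, j)), making edge sets nested
across the grid and outputs bit-reproducible. The default grid is
0.10–0.35 in 1% steps (26 levels), chosen to keep networks connected
while spanning the small-world regime; every metric is computed per
level and then integrated over the grid (trapezoidal area divided by
the grid span). Structural networks are analyzed unthresholded: their
density weighting already encodes wiring cost, and thresholding sparse
streamline networks can disconnect them.

## Weighted graph metrics

Edge length is the reciprocal of edge weight, `L_ij = 1/w_ij` — a
stronger connection is a shorter path. All shortest paths use Dijkstra
on these lengths.

* **C_w** — Onnela weighted clustering: per node,
  `(k_i(k_i−1))^-1 Σ_{j,k} (w_ij w_jk w_ki)^{1/3}` over ordered
  neighbor pairs, averaged over all N nodes; degree < 2 contributes 0.
  Bounded in [0, 1] when weights are ≤ 1.
* **L_w** — mean shortest path length over reachable ordered pairs.
  Unreachable pairs are excluded from the mean and counted in
  `n_unreachable_pairs` rather than raising: extreme thresholds can
  disconnect a network and the analysis should degrade gracefully.
* **E_global** — mean of `1/L_ij` over all ordered pairs with
  `1/∞ = 0`, i.e. the full `N(N−1)` denominator.
* **E_local** — for each node, the global efficiency of the subgraph
  induced by its neighbors (weights retained), averaged over nodes.
* **E_nodal(i)** — `(N−1)^-1 Σ_{j≠i} 1/L_ij`. The per-node
  normalization is 1/(N−1) (the harmonic-mean definition); the
  laterality index is invariant to this constant because it cancels in
  the ratio, so the choice cannot affect downstream results.
* **σ, γ, λ** — γ = C_w/⟨C_w^rand⟩ and λ = L_w/⟨L_w^rand⟩ over
  `n_null` (default 100) degree-preserving rewired versions of the
  network; σ = γ/λ. Null networks are produced by weighted double-edge
  swaps: two edges (a,b), (c,d) are replaced by (a,d), (c,b) unless
  that creates a self-loop or multi-edge; weights travel with their
  edges, so the binary degree sequence and the weight multiset are
  preserved exactly. The default intensity is 10 accepted swaps per
  edge. If the input was connected and the result is not, rewiring is
  retried with a fresh stream (up to 10 attempts) and the attempt with
  the fewest components is returned as a last resort. Graphs with no
  admissible swap (e.g. complete graphs) are returned unchanged, which
  makes σ exactly 1 there — the correct degenerate answer.

**Joint weight normalization.** Before metric computation the left and
right networks of a subject/modality are divided by their single joint
maximum weight. Per-network normalization would cancel exactly the
global weight asymmetries under study; the joint maximum bounds C_w in
[0, 1] while preserving the left/right weight ratio. All reported
metrics except σ, γ, λ are scale-homogeneous, so the laterality index
is unaffected by this normalization.

## Laterality index

`AS(X) = 100 × [X(R) − X(L)] / [X(R) + X(L)]`, bounded in [−100, 100]
for nonnegative metrics; the result is clamped against one-ulp
floating-point overshoot at the boundary. Negative AS means a leftward
metric advantage, except for L_w where longer paths mean worse
integration, so positive AS(L_w) indicates a leftward integration
advantage; the stored number always follows the formula and only the
interpretation flips. If both hemisphere values are zero the score is
undefined and reported as missing. For functional networks, AS is
computed on sparsity-integrated metric values, one score per metric.

A useful closed form anchors the whole pipeline: if left weights are
exactly c × right weights on identical topology, every
scale-homogeneous metric yields AS = 100(1−c)/(1+c) (and −that for
L_w), e.g. −4.7619… for c = 1.1. This is the package's primary
parameter-recovery oracle.

## Paired network-based statistic

For each homotopic edge, a paired t statistic is computed on
left-minus-right differences across subjects. Edges with |t| above a
component-forming threshold (default 3.0 — NBS results are
threshold-dependent, so the threshold is always reported) are grouped
into connected components, separately for the left > right and
right > left tails: components of mixed sign are not meaningful
subnetworks. Significance of a component of size K (edge count) comes
from a permutation null: each permutation independently swaps the
left/right networks within each subject with probability 1/2 — a sign
flip of the paired differences — and records the maximal component size
of each tail; `p = (1 + #{perm: max ≥ K}) / (1 + n_perm)` against the
component's own tail. The +1 smoothing keeps finite-permutation p
values positive. Each one-tailed analysis controls its family-wise
error; measured on 45-node null cohorts (n = 30, t = 3.0) the
realized two-tailed rate sits near the nominal 5% and is conservative
rather than inflated, because component sizes are strongly discrete at
these parameters. An exhaustive mode enumerates all 2^n sign patterns
(n ≤ 20) and reports the exact proportion without smoothing, since the
identity relabeling is part of the enumeration. Edges whose differences
have zero variance across subjects (absent in every subject, common in
sparse structural stacks) have an undefined t and are excluded from
component formation. Balanced permutation (exactly half the subjects
swapped) is a known alternative to independent flips; independent flips
are the exact group-invariance test for paired signs and are used here.

## Group statistics

**Hemisphere effect.** For each metric, values are stacked across
hemispheres (2n observations) and an ANCOVA F for the hemisphere factor
is computed by the full-versus-reduced residual-sum-of-squares
comparison (full: intercept + hemisphere + gender; reduced: intercept +
gender), df = (1, 2n − 3) — with n = 76 subjects this gives the
familiar (1, 149). The stacked-observation model treats hemisphere as a
between-observation factor, consistent with those degrees of freedom; a
repeated-measures model would use different df. F equals the squared t
of the hemisphere coefficient (asserted in tests). p values are
FDR-corrected (Benjamini–Hochberg, via statsmodels) within families:
the 5 global metrics form one family and the 45 regional efficiencies
another, per modality.

**Asymmetry–behavior association.** Partial Pearson correlations
between AS scores and behavioral measures, residualizing both on
[intercept, age, gender, handedness, education]; two-sided p from the t
transform with df = n − n_cov − 2. Constant covariate columns are
dropped with a logged warning — handedness is constant in an
all-right-handed cohort, and dropping it reproduces what any
least-squares fit would silently do anyway. Only metrics with a
significant hemisphere effect are scanned (limiting the number of
tests), and the scan's p values are reported uncorrected by default and
flagged exploratory; an optional BH flag corrects them.

## Synthetic cohort generator

The generator emulates the statistical character of elderly-cohort
multimodal connectome data; it makes no attempt to model tractography,
hemodynamics, motion or physiological noise.

* **Structural**: one cohort-level template per run — a distance-free
  random support (intrahemispheric density 0.30, interhemispheric 0.10)
  with log-normal weights (log-mean −3, log-sd 1), the left block an
  exact mirror of the right. Per subject, multiplicative log-normal
  noise (sd 0.10) is applied independently per edge. With zero noise
  and a null effect the left block equals the mirrored right block
  exactly. Densities and the skewed weight distribution are typical of
  deterministic tractography on a 45-node parcellation; the
  distance-free support is a deliberate simplification.
* **Injected asymmetry**: a multiplicative effect matrix on the target
  hemisphere's block — global (all weights × (1+δ)), nodal (a region's
  row/column), or edge-subnetwork (named homotopic edges, forced into
  the template). Interhemispheric edges never carry signal because the
  analysis discards them.
* **Functional**: time series drawn from a zero-mean multivariate
  normal with a block-modular covariance mirrored across hemispheres
  (5 modules of 9 pairs; within-module r = 0.40, between 0.10,
  interhemispheric 0.10 — moderate resting-state-like modularity).
  Asymmetry scales the target block's off-diagonal covariance; if the
  scaled matrix loses positive definiteness it is repaired by
  eigenvalue clipping with a logged warning (or rejected if repair is
  disabled).
* **Behavior**: 12 scores with the means and SDs of a
  community-dwelling elderly battery (RAVLT, Digit Span, SDMT, Boston
  Naming, Block Design, Color Trails, MMSE, MoCA). Coupled columns are
  `mean + sd·(r·z + √(1−r²)·ε)` with z the standardized true asymmetry
  — the population correlation equals the requested `coupling_r`
  exactly. The coupling target is the subject's *generating* asymmetry
  (the AS of total intrahemispheric structural weight), keeping ground
  truth well-defined for recovery tests.
* **Covariates**: age ~ N(70.1, 5.3²) clipped to [60, 82], ~80%
  female, education ~ N(6, 4²) clipped at 0, all right-handed.
* **Seeding**: per-subject seeds are hashed from (master seed, subject
  index), so bundles are bit-reproducible and independent of iteration
  order.

What passing tests on this generator do **not** show: robustness to
spatially structured tractography error, hemodynamic confounds, motion
artifacts, non-Gaussian BOLD dynamics, or atlas misregistration — none
of which the generator produces.

## Problem sizes and runtime defaults

Function-level defaults follow the analysis conventions (100 null
networks, 5,000 NBS permutations). The `run` pipeline's default config
uses a 20-subject cohort, 10 nulls per small-worldness estimate and 500
NBS permutations so a complete end-to-end run finishes in about a
minute on one core; both knobs are plain config entries. The acceptance
script uses 200 oracle graphs, 100 null NBS cohorts at 1,000
permutations each, and 20 planted-effect replicates.

## Known limitations

* The structural generator's support is distance-free; real streamline
  networks have strong geometric structure (and hence different
  small-world baselines).
* The ANCOVA is not a repeated-measures model; it reproduces the
  stacked-data df convention rather than modeling within-subject
  correlation.
* NBS power and calibration depend on the component-forming threshold;
  3.0 is a reporting default, not a recommendation.
* σ for functional networks is computed per sparsity level and then
  integrated; computing it at a single representative threshold is a
  defensible alternative that was not taken.
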