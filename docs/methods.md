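# Methods

## Pipeline model

`fcgraph` analyses a pre/post resting-state design. The unit of data is
one regional time-series matrix per subject and session: `n_regions`
rows (default 116, the granularity of an AAL-style whole-brain
parcellation) by `n_timepoints` columns sampled every `TR` seconds
(default 2.8 s; ~10 minutes gives ≈214 volumes). The analysis chain is

1. **Sub-band filtering.** Each regional series is decomposed with a
   stationary (shift-invariant) discrete wavelet transform (Daubechies-4)
   and reconstructed from the detail levels whose dyadic frequency band
   [fs/2^(j+1), fs/2^j] overlaps the configured band. At TR = 2.8 s the
   default 0.06–0.1 Hz band selects levels 1–2 (0.089–0.179 and
   0.045–0.089 Hz); no single dyadic level matches 0.06–0.1 Hz exactly,
   so overlap is the selection rule. The approximation branch (DC and
   drift) is always discarded. Boundary handling is periodic wrap
   padding to the next multiple of 2^J, truncated back to the input
   length; the transform is linear and length-preserving. Measured on a
   0.08 Hz tone at TR 2.8 s the filter retains 99.96 % of the variance,
   and 0.005 % for a 0.005 Hz tone. An ideal zero-phase FFT band-pass is
   available behind the same interface (`method="fft"`) for users who
   prefer a brick-wall filter.
2. **Adjacency.** Pearson correlation between all region pairs. The
   diagonal is defined as 0: self-correlation is uninformative and the
   strength sum runs over j ≠ i. Zero-variance regions are an error,
   reported by label.
3. **Thresholding.** An edge exists where w_ij ≥ r, for r in a strictly
   increasing ladder (default 0.3, 0.4, 0.5, 0.6, 0.7). Negative
   correlations never form edges, and ties at the threshold are kept
   (≥, not >) — one rule had to be fixed and this one is documented.
   Strength S_i = Σ_j w_ij is the single measure computed on the
   complete weighted matrix rather than any thresholded graph.

## Graph measures and conventions

All measures operate on binary undirected graphs. At high thresholds
graphs fragment, so the degenerate-input conventions matter:

- Distances are breadth-first edge counts; unreachable pairs carry the
  explicit sentinel +inf and are excluded from every mean.
- L_i averages finite distances only; nodes with no reachable partner
  get NaN; L averages L_i over nodes with at least one reachable
  partner; an edgeless graph yields a result flagged undefined.
- Global efficiency averages 1/d over ordered pairs with unreachable
  pairs contributing 0, which keeps it defined (and 0) on the edgeless
  graph. By Jensen's inequality it is ≥ 1/L on connected graphs.
- C_i and local efficiency are 0 for nodes of degree < 2 (the formula
  denominators vanish).
- Betweenness uses ordered source–target pairs and the
  1/((N−1)(N−2)) normalisation; it is computed by Brandes'
  pair-dependency accumulation, O(N·E), which on small graphs equals
  exhaustive shortest-path enumeration to ≤1e−12 (and matches networkx
  exactly).
- Hub selection ranks by degree or betweenness with deterministic
  tie-break by node order.

## Community structure

Q is evaluated exactly as (1/2α) Σ_modules Σ_{i,j} (A_ij − k_i k_j/2α).
The Louvain optimiser is the greedy two-phase scheme: seeded-shuffle
local moves (ties in gain break toward the lowest module id), then
aggregation with self-loops carrying intra-module weight, iterated until
no gain. Because the outcome is visit-order sensitive, `n_restarts`
(default 10) independent substreams are run and the best-Q partition
kept; results are deterministic given the seed. On graphs small enough
for exhaustive partition search the optimiser attains the global
optimum in the test suite. Participation coefficients follow
Ω_j = 1 − Σ_c (β_jc/β_j)²; isolated nodes get Ω = 0 since the formula is
undefined at degree 0.

The pipeline runs community detection on the group-mean correlation
graph per session (individual-subject partitions are available through
the library); group-mean graphs are the more stable substrate for
module-level summaries at n = 12.

## Null models and small-worldness

Degree-preserving nulls come from double-edge swaps: pick two edges
(a,b), (c,d), replace with (a,d), (c,b) unless a self-loop or duplicate
would arise. The default effort is 10 accepted swaps per edge, a common
mixing heuristic; illegal draws are re-drawn within a bounded attempt
budget (100× the target) so termination is guaranteed, and graphs that
admit no legal swap (e.g. complete graphs) are returned unchanged with
a warning. γ = C_real/C_rand, λ = L_real/L_rand, σ = γ/λ with the null
mean and SD recorded from `n_null` (default 1000) independent
rewirings, each seeded from the master seed by counter so the result is
independent of evaluation order. When the null ensemble has zero mean
clustering γ is undefined and flagged. Note that in fragmented modular
graphs the finite-pairs convention can give λ < 1 (the real graph's
reachable pairs are mostly short within-module paths while the rewired
nulls are globally connected); σ remains interpretable as the
clustering-dominance ratio.

A property worth recording: for ring lattices at fixed n, γ *decreases*
with lattice degree k ≥ 4, because null clustering grows like k/n
faster than the lattice's 3(k−2)/(4(k−1)). Lattices remain the
high-γ, high-λ extreme; the test suite asserts that directional fact.

## Statistics

Pre/post comparisons use the two-sided Wilcoxon signed-rank test.
Incomplete pairs (non-finite values, e.g. undefined path lengths) and
zero differences are dropped; absolute differences are mid-ranked. With
≤25 informative pairs the p-value is exact — the permutation
distribution of W+ over sign assignments is built by convolution over
doubled ranks, which remains exact under ties. Beyond 25 pairs a normal
approximation with tie-corrected variance and continuity correction is
used; both branches agree with scipy on tie-free data. Fewer than 5
informative pairs cannot reach two-sided 0.05 and the test is flagged
undefined rather than scored.

Node-level maps are corrected across the node count within each
(measure, threshold) family, Benjamini–Hochberg by default with
Bonferroni available — the FDR default reflects that the correction
procedure is a free choice here, and BH is the field's standard for
116-node maps. Global tests are corrected across the threshold ladder
within each measure, and a claim "at all thresholds" is operationalised
as the same direction at every threshold (`consistent_direction`).
Global pairing is by subject by default; pairing the per-region group
means across sessions (`pairing="regions"`) is provided for pooled
regional contrasts. Between-group contrasts use the unpaired rank-sum
test with Bonferroni across the group count (groups are independent
samples, so a paired test would be wrong there).

## Synthetic data: what it emulates and what it does not

The generator plants a block-constant correlation matrix: r_within
inside each module (default 4 modules of 29 regions), r_between
elsewhere, unit diagonal. The post session adds `post_delta` to
within-module pairs only (a custom pair mask is accepted), emulating a
module-level connectivity increase after learning — or a decrease for
negative delta. Series are built by ideal zero-phase band-pass filtering
of white Gaussian noise to the configured band (default 0.01–0.1 Hz, the
classic resting-state range), standardisation, then mixing with the
symmetric matrix square root of the target correlation matrix, which
controls the planted covariance exactly in expectation. ≥90 % of each
series' spectral power lies in band by construction. If a planted matrix
ever fails positive semi-definiteness it is projected to the nearest PSD
correlation matrix (eigenvalue clipping + diagonal renormalisation) and
the adjustment is recorded in the ground-truth sidecar; the default
block structure is PSD outright. One master seed spawns per-subject
substreams, so adding subjects never perturbs existing ones and
regeneration is bit-identical.

Defaults are calibrated for testability, the generator's stated purpose:
r_within = 0.4 and r_between = 0.1 place the planted pre (0.4) and
post (0.4 + δ) within-module correlations astride the 0.3–0.7 threshold
ladder, so a planted increment changes edge counts at every threshold.
(With r_within ≥ 0.5 the low thresholds saturate — within-module pairs
are always edges in both sessions — and threshold-level degree changes
become pure sampling noise.) `noise_sd` scales series amplitude only;
correlations are scale-free.

What the generator does **not** emulate: haemodynamic response shapes,
scanner noise physics, motion artefacts, global-signal structure, or
empirically realistic connectivity distributions. Passing tests
demonstrate that the pipeline recovers planted covariance structure from
band-limited Gaussian data of the study's dimensions — not that any
specific neurobiological effect would be detected in real cohorts.

## Problem sizes used in validation

The test suite and acceptance script run at the study's native scale
where the claim depends on it (12 subjects × 116 regions × 214
timepoints for effect-recovery and pooled regional tests; 100-node
reference graphs with 100 nulls for small-worldness) and at reduced
scale where the claim is size-free: oracle-equivalence checks use 200
random graphs of ≤10 nodes, where exhaustive enumeration is feasible,
and the type-I-error calibration uses 200 replicates of a 12-subject,
24-region, 128-timepoint dataset — the rejection-rate claim concerns the
test, not the region count.

## Known limitations

- Weighted-graph variants of path length, clustering and efficiency are
  out of scope; only the binary measures are offered.
- The wavelet sub-band is a single configurable band per run; the
  dyadic-overlap rule means the effective band edges are the wavelet
  levels', not the requested numbers.
- Louvain is a heuristic; the restart scheme mitigates but does not
  remove order sensitivity on near-degenerate modularity landscapes.
- Rewiring does not preserve connectedness; at high thresholds null
  graphs can fragment, which the finite-pairs conventions absorb but
  users should keep in mind when reading λ.
- NIfTI parcellation requires voxel-identical functional and label
  grids; no resampling or preprocessing (motion correction, nuisance
  regression) is performed.
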