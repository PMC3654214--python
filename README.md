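# fcgraph

Graph-theoretic analysis of resting-state functional connectivity, built
for pre/post designs: two resting fMRI sessions bracketing an
intervention (e.g. a motor-learning task), with the question of how the
brain's correlation network reorganises between them.

`fcgraph` takes regional BOLD time series (one regions × timepoints
matrix per subject and session), reduces each series to a low-frequency
wavelet sub-band (default 0.06–0.1 Hz), computes the Pearson correlation
between every pair of regions to form a weighted adjacency matrix
*A*ᵢⱼ, and thresholds it at a ladder of correlation levels
(*r* = 0.3 … 0.7) to obtain binary undirected graphs. On these it
computes the standard topological measures:

- **degree** *Dᵢ* and **strength** *Sᵢ* = Σⱼ *w*ᵢⱼ (strength on the
  complete weighted matrix, not the thresholded graph);
- **characteristic path length** *L* and **global efficiency** (mean
  inverse shortest path);
- **clustering coefficient** *Cᵢ* = *Rᵢ* / (*Dᵢ*(*Dᵢ*−1)/2) and **local
  efficiency** (efficiency of each node's neighbour subgraph);
- **betweenness centrality** *Xᵢ* with the 1/((N−1)(N−2)) normalisation,
  via Brandes' algorithm;
- **small-worldness** σ = γ/λ, where γ = C/C_rand and λ = L/L_rand
  against degree-preserving (double-edge-swap) null graphs;
- **modularity** *Q* by Louvain optimisation and the **participation
  coefficient** Ωⱼ = 1 − Σ_c (β_jc/βⱼ)².

Pre/post sessions are compared with two-sided Wilcoxon signed-rank tests
(exact permutation p-values up to 25 informative pairs), corrected across
nodes with Benjamini–Hochberg or Bonferroni.

Because resting-state cohorts are rarely shareable, the package includes
a first-class synthetic-data module: band-limited Gaussian series with a
planted modular correlation structure and a configurable post-session
within-module correlation increment, so every stage can be validated
against a known ground truth.

## Worked example

```python
import numpy as np
from fcgraph import (SyntheticConfig, generate_dataset, correlation_matrix,
                     threshold_binarize, clustering_coefficients,
                     louvain_partition, small_worldness, wilcoxon_signed_rank,
                     node_strength)

cfg = SyntheticConfig(n_subjects=12, post_delta=+0.1, seed=1)  # 116 regions, TR 2.8 s
ds = generate_dataset(cfg)

cm = correlation_matrix(ds.get("sub-01", "pre"))
g = threshold_binarize(cm, 0.4)
print(g.n_edges)                                    # 862
print(round(clustering_coefficients(g)[1], 3))      # 0.682

part = louvain_partition(g, seed=0)
print(part.n_modules, round(part.q, 3))             # 4 0.73

sw = small_worldness(g, n_null=100, seed=0)
print(round(sw.gamma, 2), round(sw.lam, 2), round(sw.sigma, 2))  # 4.04 0.73 5.54

strength = {k: node_strength(correlation_matrix(ts))[0] for k, ts in ds.series.items()}
pre = np.mean([strength[(s, "pre")] for s in ds.subjects], axis=0)
post = np.mean([strength[(s, "post")] for s in ds.subjects], axis=0)
print(wilcoxon_signed_rank(pre, post).p)            # 1.12e-12
```

Louvain recovers the planted four-module structure exactly (Q ≈ 0.73),
the graph is far more clustered than its rewired nulls (γ ≈ 4, σ ≈ 5.5;
λ < 1 here because at this threshold the graph is strongly modular and
path lengths average over reachable pairs only), and the planted +0.1
within-module increment shows up as a regional strength increase whose
paired Wilcoxon p-value across the 116 regional group means is far below
0.001.

The same flow is available from the shell:

```sh
fcgraph simulate --subjects 12 --post-delta 0.1 --seed 1 --out data/
fcgraph run-all --mode timeseries --input-dir data/ --out results/
```

`run-all` executes filter → correlate → threshold → metrics → community →
nulls → statistics and writes a `manifest.json` with a content hash of
every output, so a re-run with the same seed is verifiably identical.

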