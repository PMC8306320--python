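# rivernet

Co-occurrence network analysis of river bacterioplankton communities along
a human-activity gradient.

## What it does

Bacterioplankton communities in human-impacted rivers reorganize under
land-use pressure: network connectivity, the balance of negative
(competitive) vs positive (cooperative) associations, keystone taxa and
module composition all shift between low- and high-disturbance reaches.
`rivernet` packages that whole analysis as a tested, reproducible pipeline
for microbial ecologists working from OTU count tables:

- **Ensemble co-occurrence networks** — four association measures per taxon
  pair (Spearman, Pearson, Bray–Curtis, symmetrized Kullback–Leibler) on
  relative abundances, permutation significance (add-one estimator,
  independent per-taxon shuffles), Benjamini–Hochberg FDR per measure, and
  an edge rule requiring |r| > 0.8 plus ≥ 2 concordant significant measures.
- **Topology indices** — the standard 13-index summary: node/link counts,
  negative/positive ratio NP, power-law fit R², average degree
  avgK = 2·TL/TN, clustering avgCC, path distance APD, Freeman degree
  centralization CD, graph density GD = avgK/(TN−1), modularity M and
  module count NM.
- **Keystone roles** — within-module degree z-score (zi) and participation
  coefficient pi = 1 − Σₛ(k_is/k_i)²; network hubs (zi > 2.5, pi > 0.62),
  module hubs, connectors, peripherals.
- **Neutral community model** — Sloan's model
  F(p) = 1 − I(d; N_T·m·p, N_T·m·(1−p)) relating a taxon's occurrence
  frequency to its mean relative abundance p, with community size N_T and
  immigration rate m fitted by bounded least squares (an exact
  beta-binomial detection variant is the default; see `docs/methods.md`).
- **HAILS** — human-activity intensity of land surface,
  100 × (farmland + urban area)/total area per sub-basin, with tertile or
  fixed-threshold reach classification.
- **Environment statistics** — Shapiro–Wilk screening with log transforms,
  Pearson correlation tables with pairwise deletion, keystone × chemistry
  bipartite networks, one-way ANOVA with Fisher's LSD post hoc tests.
- **Synthetic data with ground truth** — planted correlation blocks,
  neutrally assembled communities with known m, linked environmental
  covariates and land-use gradients, so every stage is testable without any
  sequencing download.

## Worked example

Generate a community with two planted modules of 10 taxa each (pairwise
Spearman 0.9, 60 samples), infer the network and summarize it:

```python
from rivernet.synth import PlantedDesign, generate_planted_counts, planted_pairs
from rivernet.preprocess import filter_taxa
from rivernet.inference import InferenceConfig, infer_network
from rivernet.modules import detect_modules
from rivernet.topology import summarize

design = PlantedDesign(n_samples=60, n_taxa=60, block_sizes=(10, 10),
                       within_block_corr=0.9, seed=0)
matrix = generate_planted_counts(design)
net = infer_network(filter_taxa(matrix, 30), InferenceConfig(seed=1))
part = detect_modules(net)
summary = summarize(net, part.assignment, part.modularity)
pairs = planted_pairs(matrix)
recovered = sum(1 for a, b, _ in pairs if net.graph.has_edge(a, b))
print(f"nodes={summary.total_nodes} links={summary.total_links} "
      f"avgK={summary.avg_degree:.3f} GD={summary.graph_density:.3f} "
      f"M={summary.modularity:.3f} NM={summary.n_modules}")
print(f"planted pairs recovered: {recovered}/{len(pairs)}")
```

prints

```
nodes=20 links=88 avgK=8.800 GD=0.463 M=0.500 NM=2
planted pairs recovered: 88/90
```

Only the 20 planted taxa enter the network (the 40 background taxa are
independent, so no pair clears |r| > 0.8 with FDR support); 88 of the 90
within-block pairs are recovered as edges, and module detection splits the
graph into exactly the two planted blocks (modularity 0.500).

The same workflow is available from the shell:

```sh
rivernet simulate --out-dir data/          # counts, taxonomy, metadata, land use
rivernet network data/counts.tsv --out net.tsv --graphml net.graphml
rivernet ncm data/counts.tsv               # m and R² of the neutral fit
rivernet hails data/landuse.tsv            # HAILS % and low/middle/high classes
rivernet run config.yaml                   # full bundle with manifest
```

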