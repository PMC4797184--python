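# pinmod

Module (community) detection and benchmarking for protein interaction
networks (PINs).

Proteins that act together — in a complex or a dynamic functional unit —
tend to form densely connected neighborhoods in interaction networks, so
detecting network *modules* is a standard route from interaction maps to
biological function.  `pinmod` bundles, behind one interface:

- **Four correlation-distance detection methods.**  The premise: two nodes
  of the same module sit at similar distances to the rest of the network.
  From the all-pairs shortest-path matrix *S* (or the weight matrix
  *M = A·S*, the matrix product of the adjacency matrix and *S*, which is
  generally asymmetric), row correlations ρ (Pearson or Spearman) become
  distances *D = 1 − ρ*; Ward hierarchical clustering of *D* is cut at the
  level *k* ∈ {1, …, n} that maximizes Newman modularity
  *Q = Σᵢ (eᵢᵢ − aᵢ²)*.  The four methods are `dsp-pearson`,
  `dsp-spearman`, `dm-pearson`, `dm-spearman`.
- **Reference algorithms.**  Native greedy modularity agglomeration
  (`fastgreedy`, the Clauset–Newman–Moore scheme, reporting the maximum-*Q*
  cut of the merge sequence) and asynchronous seeded label propagation
  (`labelprop`); `walktrap`, `spinglass` and `multilevel` are exposed
  through a python-igraph adapter when that backend is installed.
- **Partition metrics.**  Modularity via its (e, a) decomposition and
  normalized mutual information from the partition contingency table, with
  NMI = I/max(H(U), H(V)) by default (identical partitions score 1.0) and
  the sum-normalized variant I/(H(U)+H(V)) behind a flag.
- **A planted-community benchmark generator.**  Power-law degrees
  (exponent γ = 1, mean 10, max 20 by default) and power-law community
  sizes; each node splits its degree into a (1−μ) internal and μ external
  part, stubs are wired by a configuration-model construction, and the
  mixing parameter μ dials the difficulty.  Perturbation operators add
  uniform random edges or delete edges under degree ≥ 2 and non-bridge
  guards (the perturbed network always stays connected).
- **Enrichment analysis.**  One-sided Fisher's exact test per
  (module, gene-set) pair with Bonferroni correction, multi-module and
  cross-organism summaries, plus a synthetic-annotation generator so the
  pipeline is testable without an ontology download.
- **Bundled reference tables** for ten BioGRID-derived PINs (network sizes,
  published edge densities, per-method modularity and module counts) used
  by the summary statistics and the *Q*-vs-module-count regressions.

## Worked example

```python
import pinmod as pm

pn = pm.generate(pm.BenchmarkConfig(n=300, mu=0.15, k_min=30, k_max=60, seed=7))
print("generated:", pn.graph.n_nodes, "nodes,", pn.graph.n_edges, "edges,",
      pn.truth.n_communities, "planted communities, realized mu %.3f" % pn.realized_mu)

g = pm.giant_connected_component(pn.graph)
for name in ("dm-pearson", "fastgreedy", "labelprop"):
    p = pm.run_algorithm(g, pm.AlgorithmSpec(name=name, seed=7))
    print(f"{name:12s} Q={pm.modularity(g, p):.4f}  modules={p.n_communities}  "
          f"NMI vs truth={pm.nmi(pn.truth.restrict(set(g.nodes)), p):.4f}")
```

prints

```
generated: 300 nodes, 1458 edges, 7 planted communities, realized mu 0.165
dm-pearson   Q=0.6874  modules=7  NMI vs truth=1.0000
fastgreedy   Q=0.6673  modules=7  NMI vs truth=0.9390
labelprop    Q=0.6874  modules=7  NMI vs truth=1.0000
```

The benchmark plants 7 communities at mixing μ = 0.15 (about 16 % of edge
ends run between communities).  The correlation-distance method recovers
the planted partition exactly (NMI = 1); fast-greedy finds a partition of
slightly lower modularity that merges part of two communities
(NMI = 0.94).

The same workflows are available from the shell:

```sh
pinmod generate --n 1000 --mu 0.1 --seed 1 -o net.tsv --truth truth.tsv
pinmod detect --method dm-pearson -i net.tsv -o modules.tsv
pinmod eval nmi -p truth.tsv -p modules.tsv
pinmod report            # bundled-table summaries and regressions
```

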