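# coocnet

Comparative co-occurrence network analysis for compositional microbiome
count data.

Amplicon sequencing yields *compositional* counts: each sample's reads are
constrained to a fixed depth, so naive correlations between taxa are
distorted by the closure. `coocnet` implements the network half of a
typical 16S comparative study — the part that starts after denoising and
taxonomic assignment — for questions like: *do two host groups assemble
their microbiota differently, which taxa are keystones, and how robust is
each community's interaction network?* The motivating system is the midgut
microbiota of two mosquito host groups, with a dominant commensal hub taxon
(an *Escherichia-Shigella* analogue) and a ubiquitous low-connectivity
endosymbiont (a *Wolbachia* analogue).

## What it does

1. **Table preparation** (`coocnet.prep`) — negative-control-based
   contaminant screening (one-sided Fisher exact test on prevalence),
   genus-level collapse of SILVA-style lineages, rare-taxon filtering
   (< 10 total reads or < 3 samples), and the centered log-ratio transform
   `clr(x_i) = ln(x_i + c) − mean_j ln(x_j + c)`.
2. **SparCC correlations** (`coocnet.sparcc`) — basis correlations from the
   log-ratio variance matrix `t_ij = Var[ln(x_i/x_j)]` via the sparsity
   approximation `Σ_j t_ij ≈ (D−1)ω_i + Σ_{j≠i} ω_j`, with
   `ρ_ij = (ω_i + ω_j − t_ij) / 2√(ω_i ω_j)`, Dirichlet posterior
   resampling, strong-pair exclusion, and permutation-bootstrap pseudo
   p-values.
3. **Signed networks** (`coocnet.network`) — edges where `|ρ| > 0.7`
   (0.5 / 0.75 presets available), the standard topology panel (nodes,
   edges, sign split, diameter, average degree, path length, modularity Q,
   module count, clustering), Louvain modules on |weight|, and degree /
   betweenness / closeness / eigenvector centralities.
4. **Keystones** (`coocnet.keystone`) — taxa that are simultaneously
   ubiquitous, highly eigenvector-central (≥ 0.75 of the maximum) and more
   abundant than the community-average clr.
5. **Cross-network statistics** (`coocnet.compare`) — core association
   network (sign-consistent shared edges), Fisher-z differential network
   with Benjamini–Hochberg control, Jaccard similarity of top-quartile
   centrality sets with hypergeometric `P(J ≤ j)` / `P(J ≥ j)`, adjusted
   Rand index with a permutation p-value, module-equivalence percentages
   (`100·|A∩B| / |A∪B|`), and partner-overlap Venn counts for a focal taxon.
6. **Robustness** (`coocnet.robustness`) — random / degree / betweenness /
   cascading node-removal attack curves measured as connectivity loss
   (fraction of initially reachable node pairs lost), the node fraction
   needed for 80 % loss, and node-addition growth curves (LCC size,
   average path length) with Wilcoxon signed-rank + BH paired comparisons.
7. **In-silico knockouts** (`coocnet.knockout`) — ego sub-networks for a
   focal taxon and before/after bundles for its removal, by node deletion
   or full re-estimation.
8. **Synthetic data** (`coocnet.synth`) — a generator with planted ground
   truth (factor-model correlation blocks, keystone hub, symbiont clique,
   contaminants) emulating a two-group, 13-samples-per-group, ~800-genus
   study, so every stage above is testable without downloads.

## Worked example

```python
from coocnet import (GroundTruthSpec, RunConfig, run_pipeline,
                     simulate_two_group_study)

spec = GroundTruthSpec(n_taxa=50, module_sizes=(12, 9),
                       symbiont_partner_count=5,
                       contaminant_ids=("g__ContamA", "g__ContamB", "g__ContamC"),
                       depth=20_000, n_negative_controls=4)
tables = simulate_two_group_study(seed=3, base_spec=spec)
cfg = RunConfig(out_dir="demo_out", attack_reps=5, addition_n_max=30,
                addition_reps=3, seed=3,
                attack_strategies=("random", "degree", "cascading"))
report = run_pipeline(cfg, tables=tables)
print(report["groups"]["groupA"]["n_contaminants_removed"])
print(report["comparison"]["can_nodes"], report["comparison"]["can_edges"])
print(report["robustness"]["fraction_to_target_loss"])
```

prints

```
3
17 16
{'groupA': 0.38461538461538464, 'groupB': 0.12}
```

meaning: the prevalence screen removed the three planted reagent
contaminants; the two groups' networks share a 17-node, 16-edge core of
sign-consistent edges; and under a cascading attack group A's network needs
38 % of its nodes removed to lose 80 % of its reachable pairs versus 12 %
for group B — group A's community network is the more attack-tolerant one.
The same pipeline is exposed as a CLI (`coocnet simulate | prep | sparcc |
network | keystones | compare | attack | grow | knockout | run-all`).

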