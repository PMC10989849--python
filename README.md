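# ecolinks

Quantify putative **biotic associations** of microbes at the community level
from sample × taxon abundance tables.

The workflow has four stages plus a synthetic-data generator:

1. **Network inference** (`ecolinks.network`) — signed correlation networks
   (Pearson/Spearman with t-transform p-values, Benjamini–Hochberg q-values,
   hard |r|/q thresholding), an optional random-matrix eigenvalue-spacing
   scan to choose the correlation cut-off, and import of externally inferred
   edge lists (e.g. from covariance-based tools).
2. **Process assignment** (`ecolinks.processes`) — per-edge Mantel link tests
   of the pair's abundance distances against geographic and environmental
   distance matrices; each edge is classified as `dispersal_limitation`,
   `environmental_selection`, `overlap`, or `biotic`.
3. **Quantification** (`ecolinks.quantify`) — per-taxon mean positive /
   negative connectedness in the biotic-filtered network, collapsed to
   per-sample positive and negative community association strengths by
   abundance weighting.
4. **Consequence** (`ecolinks.consequence`) — forward-selection OLS relating
   alpha diversity to abiotic + biotic predictors, and per-factor Mantel
   tests against Bray–Curtis community dissimilarity.
5. **Synthetic data** (`ecolinks.simulate`) — communities with planted
   environmentally driven, spatially driven, and copula-coupled taxon pairs
   plus independent noise taxa, with ground-truth labels for every planted
   pair.

## CLI

The console script `ecolinks` (equivalently `python -m ecolinks.cli`) exposes
one subcommand per stage:

```sh
# generate a fixture with planted structure (spec fields are SyntheticSpec
# attributes in flat YAML, e.g. "n_samples: 60")
ecolinks simulate --spec spec.yaml --seed 7 --out fixture/

# infer a correlation network (add --rmt to pick r-min by the spacing scan)
ecolinks network --abundance fixture/abundance.tsv --method pearson \
    --r-min 0.6 --q-max 0.05 --out edges.tsv

# classify edges by assembly process
ecolinks assign --abundance fixture/abundance.tsv --edges edges.tsv \
    --geo fixture/geo.tsv --env fixture/env.tsv --geo-mode euclidean \
    --alpha 0.05 --n-perm 999 --seed 1 --out assignment.tsv

# connectedness + community strengths (pass the biotic-filtered edge list)
ecolinks quantify --abundance fixture/abundance.tsv --edges biotic_edges.tsv \
    --out-connectedness connectedness.tsv --out-strength strength.tsv

# diversity consequences
ecolinks consequence --abundance fixture/abundance.tsv --factors factors.tsv \
    --response richness --out-alpha alpha.json --out-beta beta.tsv

# everything at once, deterministically
ecolinks pipeline --spec spec.yaml --seed 13 --out run/
```

All file formats are plain TSV (abundance tables samples-as-rows by default,
`--taxa-as-rows` to flip; metadata tables keyed by `sample_id`; edge lists
`taxon_a  taxon_b  weight  p  q` with a JSON metadata sidecar).

## Library example

```python
import ecolinks as el

bundle = el.generate_community(el.SyntheticSpec(
    n_samples=60, n_noise_taxa=100,
    n_env_pairs=5, n_space_pairs=5, n_biotic_pos_pairs=5, seed=1))

R, P = el.correlation_matrix(bundle.table, "pearson")
net = el.threshold_network(R, P, el.fdr_adjust_matrix(P), r_min=0.6, q_max=0.05)

assignment = el.assign_processes(
    net, bundle.table,
    el.geo_distance(bundle.geo, mode="euclidean"),
    el.env_distance(bundle.env),
    alpha=0.05, n_perm=999, seed=1)
print(el.process_fractions(assignment))

biotic = assignment.biotic_network(net)
profile = el.connectedness(biotic, table=bundle.table)
strength = el.community_strength(bundle.table, profile)
print(strength.table.head())
```
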