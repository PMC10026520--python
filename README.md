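# snapshot-ccre

Clustering and visualization of candidate cis-regulatory elements (cCREs)
across an ordered series of cell types (e.g. a hematopoietic differentiation
tree) by **binarized indexing**:

1. **Index** — each cCRE gets a binary string (one bit per cell type, bit
   order from a user-supplied cell differentiation tree) recording peak
   presence/absence; cCREs sharing a string form an **Index-Set (IS)**.
2. **Filter** — a negative-binomial background over IS sizes (top 5% of ISs
   excluded from the fit, BH-FDR < 0.01) yields an abundance threshold;
   small ISs are temporarily removed.
3. **Rescue** — per-IS multivariate Gaussians (QDA) re-classify the cCREs of
   filtered ISs into abundant ISs (or a null class when the max softmax
   posterior is < 0.5), replacing their indices and correcting spurious
   peak calls.
4. **Merge** — complete-linkage hierarchical clustering of IS mean-signal
   vectors, cut at an AIC-selected K, gives **Meta-Index-Sets**.
5. **Annotate / visualize** — dominant epigenetic state per cCRE per cell
   type (four-rule cascade + deterministic tiebreak), representative states
   and colors per cluster, binary maps, heatmaps, per-cluster tree/violin/
   state-bar panels.

Evaluation protocols included: sliding-window Shannon entropy of the sorted
binary map, noise-injection adjusted-Rand-index reproducibility, and
K-means rare-cluster recovery frequency.

## CLI

```sh
# synthetic input bundle with known ground truth (+ ready-to-run config)
snapshot simulate --out demo/ --seed 1

# full pipeline: index -> filter -> rescue -> meta -> states -> figures
snapshot run --config demo/config.yaml

# individual stages re-run from the prior stage's TSVs
snapshot index  --config demo/config.yaml
snapshot filter --config demo/config.yaml
snapshot rescue --config demo/config.yaml
snapshot meta   --config demo/config.yaml
snapshot states --config demo/config.yaml
snapshot plot   --config demo/config.yaml

# entropy / ARI / rarity evaluation of a finished run
snapshot eval --config demo/config.yaml --heights 5,10,50
```

The YAML config names input files (`peaks`, `signals`, `states` as
cell-type → path maps, `tree`, `colors`, optional `master`), the output
directory, and optional sections `normalization` (`method`: none | scale |
quantile | s3norm), `abundance` (`exclusion_fraction`, `fdr_alpha`,
`manual_threshold`), `rescue` (`feature_mode`: signal | binary,
`null_posterior_cutoff`, `ridge`) and `meta` (`k_min`, `k_max`,
`include_null`). All outputs are headered TSVs keyed by index strings; a
`manifest.json` records artifact checksums and stage counts.

## Inputs

* peak calls: BED3+ per cell type
* signals: bedGraph (or bigWig) per cell type; per-cCRE mean is used
* cell tree: `parent<TAB>child` edges, one per line; bit order is the
  depth-first pre-order (overridable with `leaf_order`)
* states: BED4 fixed-width segmentation per cell type + a
  `state<TAB>R,G,B` color table
* optional master cCRE list (BED); otherwise peaks are pooled and merged
  (>= 1 bp overlap; book-ended intervals stay separate)

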