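# netpharm

Network-pharmacology analysis of plasma metabolite biomarkers:

* **MEI stage** — builds the bipartite biomarker–enzyme interaction network
  from relation tables, computes degree centrality, selects hub biomarkers
  (degree strictly greater than a cutoff, default 10) and tallies enzyme
  function categories.
* **MTI stage** — thresholds a biomarker×target docking-score matrix on the
  pKd scale (default threshold 5.52 ≙ Kd = 3 μM, strict `>` comparator),
  builds one biomarker–target network per physiological system (nervous /
  immune / endocrine), summarizes node/edge counts and mean partner ratios,
  classifies targets by system-membership count, and intersects target sets
  across systems.
* **DSWMP stage** — scores every pathway per system with a
  docking-score-weighted index (sum of passing pKd weights over
  pathway-member targets, normalized by a configurable biomarker count) and
  ranks the top-k pathways, tabulating cross-system overlap.
* **Synthetic data** — a simulator for full study bundles (catalog sizes,
  skewed enzyme degrees, controllable above-threshold score fraction,
  overlapping per-system target sets) plus an exact-shape bipartite fixture
  generator whose attached score matrices threshold back to the original
  network.

## CLI

```sh
# generate a synthetic study bundle directory
netpharm simulate --seed 1 --out bundle/

# individual stages on a bundle directory
netpharm mei   --bundle-dir bundle/ --out mei_out/
netpharm mti   --bundle-dir bundle/ --out mti_out/ --threshold 5.52 --comparator greater
netpharm dswmp --bundle-dir bundle/ --out ds_out/ --count-mode contributing_biomarkers --top-k 10
netpharm validate --bundle-dir bundle/

# full pipeline from a config file
netpharm run --config study.yaml --out run_out/
```

`study.yaml` either names input tables or requests simulation:

```yaml
simulate:          # or: bundle_dir: path/   or: inputs: {biomarkers: ..., ...}
  seed: 1
threshold_pkd: 5.52
comparator: greater            # or greater_equal
count_mode: contributing_biomarkers   # or n_biomarkers / per_biomarker_edge_count
top_k: 10
hub_min_degree: 10
```

Outputs: `report.json` (self-describing; echoes every parameter), degree and
function-tally TSVs, per-system network summaries, shared-target list,
ranked pathway tables, an alluvial (system → pathway) table, and SIF +
GraphML network exports for Cytoscape. Reports are byte-identical for a
fixed config and seed; pass `--timestamp` to stamp wall-clock time in.

### Input tables

UTF-8 CSV/TSV with headers (delimiter inferred from extension):
`biomarkers(id,name,platform,trend)`, `enzymes(id,name,functions)` with
semicolon-separated functions, `relations(biomarker_id,enzyme_id)`,
`targets(id,name,systems)` with semicolon-separated systems,
`scores_long(biomarker_id,target_id,pkd)` or wide form (first column
`biomarker_id`, remaining columns target accessions), and
`pathways(pathway_id,pathway_name,target_id)` one membership per row.
Missing score cells mean "no measured interaction" and never pass a
threshold.

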