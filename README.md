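# perturbnet

Identify a structurally conserved, context-shifting gene-network module from
time-series expression data integrated with protein–protein interactions
(PPI).

The pipeline:

1. **Quantile normalization** (optional) of the gene × time-point expression
   matrix.
2. **Perturbation scoring** — each gene's expression at a time point minus
   its mean across all time points.
3. **Stage grouping** — per-time-point scores averaged over user-defined
   groups of adjacent time points ("stages").
4. **Thresholding** — grouped scores pooled over all genes × stages; scores
   strictly outside mean ± k·sd (default k = 1) mark a gene as *perturbed*
   at that stage.
5. **Stage-specific networks** — PPI scaffold edges with at least one
   perturbed endpoint per stage.
6. **Common network** — the exact intersection of all stage networks' edge
   sets: constant topology, potentially shifting node scores.
7. **Shift statistic** — the mean absolute difference of grouped scores over
   the common network's member genes between two stages, computed for all
   adjacent stage pairs plus the (first, last) pair.
8. **Resampling significance test** — random same-sized stage networks drawn
   from the pooled observed edges are intersected and scored to build a null
   distribution (default); an alternative null permutes stage labels
   instead. Both an empirical (add-one) and a one-sided
   normal-approximation p-value are reported.

A synthetic-data module plants a conserved module with monotonically
drifting scores so the full pipeline is testable without any downloads.

## CLI

```sh
# generate a synthetic dataset with a planted module
perturbnet simulate -o demo --genes 200 --timepoints 8 --stages 4 \
    --module-size 8 --module-edges 10 --amplitude 6 --seed 1

# full pipeline: writes score tables, per-stage networks, the common
# network (TSV + GraphML with per-stage node scores), and report.txt
perturbnet run demo/expression.tsv demo/interactions.tsv demo/grouping.yaml \
    -o demo/out --seed 1 --iterations 10000

# individual steps
perturbnet normalize demo/expression.tsv -o normalized.tsv
perturbnet score demo/expression.tsv --grouping demo/grouping.yaml -o scores.tsv
perturbnet networks demo/expression.tsv demo/interactions.tsv demo/grouping.yaml -o nets/
perturbnet common   demo/expression.tsv demo/interactions.tsv demo/grouping.yaml -o common.tsv
perturbnet test     demo/expression.tsv demo/interactions.tsv demo/grouping.yaml --seed 1
```

Common flags: `--seed`, `--threshold-k`, `--iterations`, `--no-normalize`,
`--gene-list FILE` (restrict scaffold and scores to listed genes, both edge
endpoints required), `--null {pooled|label-permute}`,
`--dialect {plain_tsv|series_matrix}` (the latter skips `!`-prefixed GEO
series-matrix metadata), `--collapse {mean|max}` for duplicate gene rows.

### File formats

- Expression: TSV; first column gene id, header row of time labels.
- Interactions: ≥2-column TSV of gene symbols (extra columns ignored;
  self-loops dropped, duplicates merged).
- Grouping: YAML/JSON mapping `stage label -> [column labels]`, ordered.
- Gene list: one id per line. Networks out: edge TSV and GraphML.
- Report: `key<TAB>value` text, flattened with dotted keys.

## Notes on the statistical test

The default pooled-edge null is the procedure of the original method. Under
a global null with no time structure it is *anti-conservative*: the observed
common network over-represents genes with extreme scores, whereas uniform
pool draws do not (characterized in
`tests/test_significance.py::TestPooledNullBias`). The `label-permute` null
is exchangeable under the global null and is used for the calibration
acceptance test. The empty-intersection count of the null is always
reported so users can judge the resampling distribution.
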