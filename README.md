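# fusionscope

Post-caller analysis of gene fusions detected in long-read (ONT) RNA-seq of
glioma cohorts. The package takes the raw output of an ensemble of fusion
callers (LongGF, JAFFAL, FusionSeeker dialects are built in) and carries it
through the full downstream analysis:

- **Harmonization** — exact within-caller deduplication, cross-caller merge
  of calls agreeing within a 50 bp breakpoint window (single-linkage, order
  independent), and collapse of reciprocal orientations to the
  higher-support call.
- **Filtering cascade** — cancer-gene gate (fusion panel ∪ Cancer Gene
  Census), minimum read support (≥ 3), blacklist (pseudogenes, ribosomal
  proteins, HLA, mitochondrial), strand-consistency check (fail-open on
  unknown strands), subtraction of gene pairs seen in healthy-tissue
  controls, and removal of fusions with no usable breakpoint annotation.
  Every removal is attributed to exactly one stage in a chained audit.
- **Tiered breakpoint annotation** — MANE Select → longest protein-coding →
  all transcripts; classes CDS / UTR5 / UTR3 / noncoding exon / near-exon
  (intronic within 200 bp of an exon boundary) / intronic / intergenic /
  unannotated. CDS and near-exon count as potentially functional.
- **Prioritization** — panel/census membership, a glioma-specific census
  subset extracted by tumour-type keyword matching (token-level, so
  "glioma" never matches inside "paraganglioma"), oncogene/TSG lists and
  the oncogene–TSG link flag, CNS-recurrent partners, and DepMap-style
  essentiality over glioma cell lines (max dependency probability ≥ 0.9,
  min gene effect ≤ −1).
- **Isoform analyses** — TPM, the count-based expression pre-filter, the
  two-method consensus differential-expression merge (both FDR ≤ 0.05 and
  |log2FC| ≥ 1 with concordant sign; mean log2FC, max FDR), group
  expression summaries with percentile ranks.
- **Novel-isoform clustering** — recurrent novel structures grouped per
  gene by exon count and a 100 bp boundary tolerance, with a validation
  pass that keeps every member within tolerance of the final group
  representative.
- **Breakpoint–isoform overlap** — non-canonical isoform ends/starts within
  a proportional distance of a fusion breakpoint (10% of gene length,
  clamped to [500, 2000] bp); fusions with both partners hit in the same
  sample are flagged as showing a fusion-like isoform pattern.
- **Construct design** — breakpoint-defined fusion cDNAs (5' CDS start
  through breakpoint + 3' breakpoint through transcript end), a 5'-UTR rule
  carrying the entire 5' CDS, ORF/frame/premature-stop analysis, and
  junction microhomology.
- **Synthetic data** — a seeded generator producing a GENCODE-style
  annotation, genome, multi-caller call tables with planted artifact
  classes (each removed by exactly one pipeline stage), isoform/expression
  fixtures with planted clusters and fusion-like truncations, and a
  `truth.json` ground truth, so the whole pipeline is testable offline.

A small curated table of fusions selected for in vivo functional testing
ships with the package (`fusionscope curated`).

## Quickstart

```bash
# generate a synthetic workspace with ground truth
fusionscope simulate --out ws --seed 7

# run the full pipeline; per-stage TSVs + summary.json land in out/
fusionscope run --workspace ws --out out

# curated-table summary
fusionscope curated
```

From Python:

```python
from fusionscope import run_pipeline, simulate_workspace

ws = simulate_workspace("ws", seed=7)
result = run_pipeline(ws, "out")
print(result.summary)
```

Thresholds live in `fusionscope.params.Parameters` and can be overridden
with a flat YAML file passed as `--config` (keys either bare, e.g.
`min_support_reads: 4`, or namespaced as `params.min_support_reads`).

## Workspace layout

A workspace directory contains: `annotation.gtf`, `genome.fa`,
`calls_<caller>.tsv`, gene-list resources (`panel_genes.txt`, `census.tsv`,
`oncogenes.txt`, `tsgs.txt`, `cns_partners.txt`, blacklists,
`control_pairs.tsv`), DepMap-style matrices (`depmap_dependency.tsv`,
`depmap_effect.tsv`, `depmap_lines.txt`), isoform tables (`isoforms.tsv`,
`counts.tsv`, `lengths.tsv`, `labels.tsv`), DE result tables
(`de_edger.tsv`, `de_deseq2.tsv`), and for simulated workspaces
`truth.json`.

## Testing

```bash
python -m pytest -q tests/
python scripts/acceptance.py --seed 1 --out acceptance.json
```

The test suite combines unit tests with frozen worked examples,
property-based suites (brute-force oracles for window merging, breakpoint
classification, ORF analysis and microhomology; idempotence and
permutation-invariance properties), and end-to-end recovery tests on
seeded simulations. The acceptance script recomputes the headline
quantities (curated-table counts, artifact removal, true-fusion recovery,
cluster recovery, fusion-like recall, end-to-end runtime) and writes them
as JSON.

See `docs/methods.md` for the precise definitions of every rule.
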