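# Methods

This document defines every rule the pipeline applies, in the order the
pipeline applies them. Parameter names refer to fields of
`fusionscope.params.Parameters`; defaults are given in parentheses.

## 1. Call harmonization (`fusionscope.harmonize`)

Input tables from each caller are normalized into a common `FusionCall`
record (gene pair, 5'/3' genomic breakpoints, strands, supporting reads,
sample, caller set). Three dialects are built in:

- **longgf** — `GeneA:GeneB` in one column, `chrom:pos` breakpoints.
- **jaffal** — separate gene columns, separate chrom/base columns.
- **fusionseeker** — gene pair joined by `--`, coordinates as
  `chrom|pos|strand`.

Harmonization then applies three operators, in order:

1. **Exact dedup** (per caller): calls identical in (sample, gene pair,
   both breakpoints) collapse to one record with summed supporting reads.
2. **Window dedup** (`merge_window_bp`, 50): within a sample and gene
   pair, calls whose 5' and 3' breakpoints both differ by at most the
   window are merged by single-linkage (transitive closure via
   union-find). The merged record takes the breakpoints of the
   highest-support member, the maximum support, and the union of callers.
   The operator is order independent and idempotent.
3. **Reciprocal collapse**: if `A::B` and `B::A` exist in the same sample
   with both breakpoints matching within the window (after swapping
   roles), the lower-support orientation is removed. Ties keep both.

## 2. Filtering cascade (`fusionscope.filtering`)

Six stages run in a fixed order. Each stage records its input count,
output count, and the keys it removed in a `FilterAudit`; the audit
enforces that each stage's input equals the previous stage's output, so
every removal is attributed to exactly one stage.

1. **gene_list_gate** — keep calls where at least one partner is in the
   fusion panel or the Cancer Gene Census.
2. **support_filter** — keep calls with supporting reads ≥
   `min_support_reads` (3, inclusive).
3. **blacklist_filter** — drop calls where either partner is a
   pseudogene, ribosomal protein gene, HLA gene, or mitochondrial gene.
4. **strand_consistency** — drop calls whose reported strands contradict
   the annotation. Missing strands fail open: the call is kept and
   flagged `strand_unknown` (no annotation to check against) or
   `strand_unverified` (call did not report strands).
5. **control_subtraction** — drop unordered gene pairs observed in
   healthy-control tissue.
6. **breakpoint_class_drop** — drop calls whose breakpoints cannot be
   assigned to any annotated gene on either side (class `unannotated` /
   `intergenic` at every tier).

## 3. Breakpoint annotation (`fusionscope.breakpoints`)

Each breakpoint is classified against a three-tier transcript hierarchy:

1. **MANE** — the gene's MANE Select transcript, if any.
2. **longest_coding** — the longest protein-coding transcript.
3. **all** — any remaining transcript.

Classification starts at the highest available tier and escalates to the
next tier only if the result is `intronic` or the tier has no transcript.
Within a transcript the classes are: `CDS`, `UTR5`, `UTR3` (strand
aware), `noncoding_exon` (exonic in a transcript without CDS),
`intronic`, `intergenic` (outside the transcript span), `unannotated`
(no gene at the position). Intronic breakpoints within
`near_exon_bp` (200) of the nearest exon boundary are reclassified
`near_exon`. `CDS` and `near_exon` are treated as potentially functional.

## 4. Prioritization (`fusionscope.prioritize`)

Per surviving fusion, flags are computed for: panel membership, census
membership, membership in the **glioma census subset** (census rows whose
tumour-type text, split on `,;/` into tokens, contains a token with a
glioma keyword as a substring — except the token "paraganglioma", which
is excluded at token level), oncogene and tumour-suppressor roles,
the **oncogene–TSG link** (one partner oncogene and the other TSG, either
orientation), CNS-recurrent partner genes, and **essentiality**: over the
glioma cell lines in the DepMap-style matrices, max dependency
probability ≥ `depmap_dependency_min` (0.9) or min gene effect ≤
`depmap_effect_max` (−1), both inclusive. A summary reports counts and
fractions per flag.

## 5. Isoform expression (`fusionscope.isoforms`)

- **TPM**: counts are divided by effective length, scaled so each sample
  sums to 1e6 (all-zero samples stay zero).
- **Expression filter**: keep isoforms with ≥ `min_count_per_sample` (10)
  counts in at least `min_group_size` samples of either group and ≥
  `min_total_count` (15) total, all inclusive.
- **Consensus DE**: an isoform is consensus-significant iff both input
  methods report FDR ≤ `de_fdr` (0.05) and |log2FC| ≥ `de_lfc` (1), with
  concordant sign. The consensus effect is the mean log2FC; the consensus
  FDR is the maximum of the two.
- **Expression summaries**: per-group means plus midrank percentile ranks
  in (0, 100].

## 6. Novel-isoform clustering (`fusionscope.novel`)

Novel isoforms of a gene are partitioned by exon count, then grouped by a
seed-and-extend pass: an isoform joins a group if its transcript start
and every exon boundary are within `cluster_tol_bp` (100) of the group's
running-mean representative. A validation pass then re-checks every
member against the final representative and splits/re-clusters any
violations, so the output is a true partition in which each member is
within tolerance of its group representative. Representatives are
rounded half-up to integer coordinates. Genes are ranked by recurrent
(size ≥ 2) groups and total novel support.

## 7. Breakpoint–isoform overlap (`fusionscope.overlap`)

For each fusion partner gene, the proximity threshold is 10%
(`prox_gene_fraction`) of the gene's genomic length, clamped to
[`prox_min_bp`, `prox_max_bp`] = [500, 2000] bp. A novel isoform "hits"
a breakpoint if a non-canonical end (5' partner) or start (3' partner)
lies within the threshold. A boundary is non-canonical if it is more
than `cluster_tol_bp` from every canonical boundary of the gene; genes
with no annotated canonical structure fall back to flagging the hit
low-confidence. By default only isoforms from the same sample as the
fusion call count. A fusion shows a **fusion-like isoform pattern** if,
in a single sample, both the 5' partner has a proximal non-canonical end
and the 3' partner has a proximal non-canonical start.

## 8. Construct design (`fusionscope.constructs`)

For each fusion, the 5' segment runs from the CDS start of the selected
5' transcript (tier order as in §3) to the breakpoint, and the 3'
segment from the breakpoint to the transcript end, both in spliced
(cDNA) coordinates with strand-aware genomic↔spliced mapping. CDS
coordinates exclude the stop codon. Breakpoints classified `near_exon`
are snapped to the nearest exon boundary. If the 5' breakpoint falls in
the 5' UTR, the **5'-UTR rule** applies: the construct instead carries
the entire 5' CDS and frame is annotated relative to that full CDS.
Analysis reports: junction offset, frame status (`in_frame` iff the
junction offset modulo 3 equals the 3' CDS phase at the junction),
position of the first in-frame stop codon and whether it is premature
(before the natural stop), translated protein, and **junction
microhomology** — the largest k for which the last k bases of the 5'
segment equal the k reference bases immediately upstream of the 3'
breakpoint.

## 9. Synthetic data (`fusionscope.synthetic`)

All randomness flows through a single `numpy` generator seeded by the
caller. The simulator produces:

- a GENCODE-style annotation (genes with MANE and alternative
  transcripts, pseudogene/ribosomal/HLA/mitochondrial gene classes) and
  a genome in which every CDS is a clean open reading frame (ATG start,
  no internal stop, stop codon immediately after the CDS);
- multi-caller call tables for planted true fusions (breakpoint jitter
  ≤ 20 bp, strictly below half the merge window so jittered duplicates
  always merge) and planted artifacts, each designed to be removed by
  exactly one cascade stage (off-list pairs, low support, blacklist
  partners, strand flips, control pairs, unannotatable breakpoints,
  reciprocal echoes removed at harmonization);
- isoform/count/DE fixtures with planted consensus-DE isoforms, planted
  novel-isoform clusters whose centres are separated by 3× the cluster
  tolerance (so recovery is exact), and planted fusion-like truncation
  pairs, restricted to fusions whose partner genes are unique to that
  fusion and placed within the proximity threshold with a safety margin;
- a `truth.json` ground-truth record.

### Limitations

The simulator validates mechanics, not biology: expression levels, read
support and jitter are drawn from simple parametric distributions, the
genome is random sequence outside the constraints above, and caller
error modes beyond the planted artifact classes are not modelled.
Recovery statistics on synthetic data therefore bound software
correctness, not expected performance on real cohorts.

## 10. Pipeline and outputs (`fusionscope.pipeline`)

`run_pipeline` wires the stages in the order above and, given an output
directory, writes per-stage TSVs (`harmonized_calls`, `filter_audit`,
`filtered_fusions`, `breakpoint_classes`, `prioritized_fusions`, `tpm`,
`expression_summary`, `consensus_de`, `novel_groups`,
`novel_gene_ranking`, `overlap_hits`, `fusion_like`, `constructs`) and a
`summary.json` with stage counts and the audit chain. Construct design
never aborts the pipeline: failures are recorded per fusion with a
status string.
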