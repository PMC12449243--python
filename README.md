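# nanosc

Desk-scale toolkit for the bespoke computational stages of long-read (Oxford
Nanopore) single-cell RNA-seq secondary analysis: extracting cell barcodes and
UMIs from noisy full-length reads, probabilistic barcode correction against an
abundance-ranked whitelist, BAM tagging, per-cell UMI deduplication,
barcode × feature quantification, and multi-stage QC tracking — together with
a truth-tracked read simulator so every stage is verifiable without external
data or an aligner.

## Who this is for

Long-read single-cell libraries carry a 16 nt cell barcode and a UMI on every
cDNA molecule, but ONT error rates make both hard to read back directly.
Pipelines for this data chain together several small, bespoke steps between
basecalling and a count matrix; `nanosc` implements those steps as a tested,
importable library (plus a thin `nanosc` CLI) so they can be studied,
validated and reused at desk scale.

## The model at the core

**Barcode correction.** High-quality putative barcodes are ranked by
abundance; the whitelist is either everything above a knee on the log-log
rank/abundance curve or, given an expected cell count *E*, everything whose
count exceeds `count(rank ⌈0.05·E⌉)/20`. For an observed barcode *b* with
per-base Phred qualities *Q*, each whitelist candidate *c* within Hamming
distance 2 is scored by

    L(b | c) = ∏_i  { p_i/3        if b_i ≠ c_i
                    { 1 − p_i      otherwise,       p_i = 10^(−Q_i/10)

    P(c | b) ∝ (count_c + 1) · L(b | c)

normalised over the candidate set; the argmax candidate is accepted when its
posterior is ≥ 0.975.

**UMI deduplication.** Within each (cell barcode, locus) group — locus being
the soft-clip-adjusted 5′ position in genome mode or the transcript in
transcriptome mode — UMIs are clustered with the directional rule: a directed
edge `a → b` exists when `hamming(a,b) ≤ 1` and `count(a) ≥ 2·count(b) − 1`,
and clusters grow by traversal from the highest-count unclaimed UMI. One
representative alignment per cluster survives.

## Worked example

Simulate a 12-cell library at a 2% substitution rate and run every stage:

```sh
nanosc simulate --n-cells 12 --reads-per-cell 30 --sub-rate 0.02 --seed 4 --out-dir sim
nanosc extract  --fastq sim/reads.fastq --out-fastq trimmed.fastq --out-table barcodes.csv
nanosc whitelist --table barcodes.csv --out wl.txt
nanosc correct  --table barcodes.csv --whitelist wl.txt --out corrected.csv
nanosc tag      --bam sim/genome.sam --table corrected.csv --out tagged.sam
nanosc dedup    --bam tagged.sam --mode genome --out dedup.sam
nanosc count    --bam dedup.sam --gtf sim/annotation.gtf --out-dir matrix
nanosc qc       --matrix matrix --out report.json
```

Each stage prints its counters as JSON; one run of the above printed:

```
{"n_reads": 360, "n_cells": 12, "truth_molecules": 216}
{"n_input": 360, "n_filtered": 0, "n_structured": 360, "n_unstructured": 0, "n_with_polyt": 353, "n_discordant": 0}
{"n_ranked": 104, "n_whitelist": 12}
{"exact": 264, "corrected": 90, "ambiguous": 0, "no_candidate": 6}
{"n_records": 360, "n_tagged": 360, "n_with_CB": 354, "n_dropped": 0, "n_untagged": 0}
{"n_in": 354, "n_out": 224, "n_molecules": 224}
{"n_records": 224, "n_assigned": 224, "n_ambiguous": 0, "n_unassigned": 0, "n_no_cb": 0}
{"n_cells": 12, "mean_reads_per_cell": 18.666666666666668, "median_ncount": 18.0, "median_nfeature": 7.0}
```

Reading the numbers: all 360 reads carried a recognisable
adapter/barcode/UMI layout; the knee call recovered exactly the 12 simulated
cells from 104 distinct putative barcodes; 354/360 reads ended with a
confident corrected barcode (CB tag); deduplication collapsed them to 224
molecules (216 true molecules plus a few UMI-error singletons at this noise
level); and every molecule was assigned to a gene in the count matrix.

The same stages are importable — `nanosc.run_pipeline(...)` runs the whole
funnel and returns the per-stage statistics, the whitelist, the count matrix
and a stage-tracking store.

## Layout

| module | role |
|---|---|
| `nanosc.extraction` | read filtering, structure location, barcode/UMI extraction |
| `nanosc.correction` | whitelist construction, posterior barcode correction |
| `nanosc.tagging` | CR/CB/UR/CY/UY BAM tagging; per-chromosome splitting |
| `nanosc.dedup` | directional UMI clustering and deduplication |
| `nanosc.quantify` | GTF models, gene/transcript counting, MatrixMarket I/O |
| `nanosc.qc` | stage-tracking CSV, per-cell metrics, flag summaries |
| `nanosc.simulate` | toy references, ONT-like reads, truth tables, perfect SAM |

See `docs/methods.md` for the model details, parameter defaults and known
limitations.
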