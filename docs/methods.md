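# Methods

This note documents the models and procedures implemented in `nanosc`, the
defaults they use and why, what the simulator does and does not emulate, and
the numerical choices that make every stage deterministic.

## Read structure extraction

A 3′ 10X long read is modelled as
`adapter + barcode(16) + UMI(12) + poly-T + cDNA`, possibly
reverse-complemented end to end. The adapter (default: the 22 nt partial 10X
read-1 primer) is located by **semi-global edit-distance alignment** (edlib),
not Hamming matching, because ONT errors are indel-rich; the default
tolerance is 3 edits within a 100 bp search window from the read start. Both
the read and its reverse complement are searched; the lower edit distance
wins and ties prefer the forward orientation. Barcode and UMI spans are laid
out immediately after the adapter end.

The poly-T tail is detected greedily after the UMI, tolerating one non-T per
10 bases (minimum budget one) and trimming back to the last T; a run of ≥10
qualifies. A missing tail does not reject the read — it is only recorded —
since nothing in the chemistry guarantees the tail survives basecalling.
Trimming removes everything through the UMI, or through the poly-T when
found, with qualities removed in lockstep.

Filtering (mean Phred and length bounds) is available but defaults to off
(`min_mean_quality=0`), so extraction statistics satisfy
`n_structured + n_unstructured (+ n_filtered) = n_input`.

Coordinates are 0-based half-open throughout; qualities are Phred+33.

## Whitelist and barcode correction

Putative barcodes whose **minimum** base quality is ≥15 contribute abundance
counts; ranking is count-descending with lexicographic tie-break for
determinism.

Cell calling uses one of two rules:

* **Expected cells E**: threshold = count at rank `⌈0.05·E⌉` divided by 20;
  keep entries strictly above it. This reproduces the convention used by
  short-read cell callers.
* **Knee**: the knee of the log-rank/log-count curve. The point of maximum
  curvature is located via the chord-distance criterion — the point furthest
  above the straight line joining the curve's endpoints in log-log space —
  because discrete curvature estimates are unstable on the near-vertical
  ambient cliff these curves show (the curvature formula suppresses exactly
  the steep region the knee lives on). Because per-cell depth wobbles, the
  deviation forms a plateau across the cell population; the last point
  within 0.1 log10 units of the plateau maximum is taken, so a cell
  sequenced slightly shallower than its peers is not cut. The knee rule
  assumes an ambient background population exists; on a curve with no spread
  all entries are kept. With a known cell count, prefer `expected_cells`.

Correction scores every whitelist candidate within Hamming distance 2 (the
candidate search switches between a linear scan and Hamming-ball hash lookup
depending on whitelist size; both routes are contractually identical and
tested against each other). The likelihood treats each base independently:
an observed mismatch at error probability `p = 10^(−Q/10)` contributes
`p/3` (uniform substitution), a match contributes `1 − p`. Error
probabilities are clipped to `[1e−10, 0.75]`, which makes a Q0 base (e.g. an
N) maximally uninformative instead of producing zero likelihoods. The prior
is the whitelist abundance plus a pseudocount of 1 (raw counts, not ranks;
the pseudocount avoids zero priors for rarely seen true cells). Posteriors
are normalised over the candidate set and the best candidate is accepted at
≥97.5%. Ties break lexicographically. There is no UMI sequence correction
and no second pass at reduced Hamming radius for ambiguous barcodes.

## Tagging and splitting

Correction results join alignments by exact read-id match. Every matched
record gets `CR`/`CY` (raw barcode + qualities) and `UR`/`UY` (raw UMI +
qualities); `CB` is added only for `exact`/`corrected` rows. Secondary and
supplementary alignments receive the same tags as the primary; unmapped
reads are retained and tagged (useful for QC). Splitting routes records by
contig (genome mode) or by the chromosome of the aligned transcript
(transcriptome mode, via the GTF's transcript→seqname map), with explicit
`unmapped`/`unassigned` buckets, and never duplicates or drops a record.

## UMI deduplication

Only primary, CB-tagged alignments are deduplicated. Genome-mode grouping
keys on (contig, strand, soft-clip-adjusted 5′ position): start minus
leading clip on the forward strand, end plus trailing clip on the reverse —
raw positions shift under ONT indels and clipping, the adjusted anchor does
not. Transcriptome mode keys on the transcript alone, since fragment starts
within a transcript vary by degradation, not molecule identity.

Directional clustering visits UMIs in count-descending (then lexicographic)
order; each unclaimed UMI seeds a cluster grown by BFS over directed edges
`a → b` (`hamming ≤ 1`, `count(a) ≥ 2·count(b) − 1`) through unclaimed nodes
only. The seed is always the cluster's maximal-count member, so it is the
representative. `method="unique"` instead treats each distinct UMI as its
own molecule. The surviving alignment per cluster is chosen by highest
mapping quality, then longest reference span, then smallest read id —
invented purely for determinism. Output is coordinate-sorted; byte-identical
across runs on the same input.

## Quantification

The in-repo quantifier is a deliberately simple, deterministic counter so
the pipeline is testable end-to-end at desk scale; it does not attempt
model-based isoform assignment or EM read reassignment. Gene mode assigns an
alignment to the gene whose exon union covers **≥50% of its aligned
reference bases** (intron-spanning `N` operations are excluded by
construction); reads meeting the bar for two or more genes are dropped as
ambiguous rather than fractionally assigned — simple and conservative.
Strand is ignored because ONT cDNA strand is ambiguous. Transcript mode
counts primary records per (CB, reference transcript).

Matrices are features × barcodes MatrixMarket integer triplets with
`barcodes.tsv.gz` and `features.tsv.gz` (id, name, kind) alongside — the
prevailing single-cell layout, read back verbatim by `read_matrix`.

## QC tracking

The tracking CSV records a seven-stage funnel per sample: raw, trimmed,
structured, aligned, primary_mapped, cb_tagged, deduplicated. The invariant
`structured ≥ cb_tagged ≥ deduplicated` is checked on every end-to-end run.
Medians (nCount/nFeature) use the lower median for even cell counts so
reported metrics are always attained values.

## Simulator

The simulator is the ground-truth generator for every test. Defaults model a
small but structured experiment: 50 cells × 40 reads per cell, 8 genes with
2 isoforms each on two contigs (4–6 exons of 120–300 bp separated by
60–200 bp introns), 12 nt UMIs, poly-T length 15, base qualities uniform in
20–40. Sixty percent of each cell's reads are distinct molecules; the rest
are PCR duplicates of them, so deduplication has real work to do. Reads are
fragments anchored at a random transcript position (≥100 bp), and half of
all reads are reverse-complemented to force strand handling.

Cell barcodes are drawn with pairwise Hamming distance ≥5 and per-cell UMIs
with pairwise distance ≥3 — mirroring the separation real barcode designs
aim for — which makes the truth tables unambiguous at the simulated error
rates: an observed barcode with ≤2 errors has exactly one whitelist
candidate, and distinct molecules cannot be merged by a single UMI error.

Errors are independent per-base substitutions/insertions/deletions with
logged positions. This deliberately omits homopolymer bias, quality–error
correlation, ambient RNA, doublets and saturation; it is sufficient to
exercise Hamming-neighbourhood and posterior logic, and **passing tests on
simulated data therefore demonstrate algorithmic correctness, not
performance on real ONT libraries**. The perfect-placement SAM stands in
for an aligner: one primary record per read at its true origin, spliced
CIGARs in genome mode, carrying the clean fragment sequence.

All randomness flows from a single integer seed through
`numpy.random.default_rng`; FASTQ/SAM/table outputs are byte-identical
across runs with the same seed.

## Problem sizes and numerical choices

Tests and the acceptance script run the standard conditions (50 × 40 reads,
0% and 2% substitution) plus oracle sweeps (1,000 candidate-search
instances, thousands of sampled UMI multisets over 3-mers); these sizes give
stable statistics in seconds on a single CPU. Posterior normalisation is
done in log space with max-subtraction; posteriors sum to 1 within 1e−9.
Every tie anywhere (ranking, candidate order, cluster seeds, representative
selection) breaks lexicographically or by read id, never by hash order.

## Known limitations

* The error model's independence assumption understates real ONT
  homopolymer error clustering; poly-T detection tolerances were chosen for
  that simpler model.
* The gene counter's 50% overlap rule has no notion of antisense or
  intronic signal and drops ambiguous reads outright.
* The knee caller expects a background population and a single cliff; exotic
  multi-plateau curves (e.g. heavy ambient contamination) should use
  `expected_cells`.
* 5′ chemistry is supported structurally (10 nt UMI profile) but the TSO is
  not modelled or removed.
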