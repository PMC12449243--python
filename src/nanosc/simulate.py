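"""Synthetic ONT-like single-cell reads with a full truth table.

The simulator builds a toy two-contig genome with spliced genes, draws a
whitelist of well-separated cell barcodes, creates per-cell molecules
(transcript + UMI + fragment start), and emits reads of the form
``adapter + barcode + UMI + polyT + cDNA fragment`` with independent
per-base substitution/insertion/deletion errors.  Half the reads are
reverse-complemented to exercise strand handling.  Alongside the FASTQ it
produces a truth table, the true whitelist, a truth count matrix, and
perfect-placement SAM files, so every pipeline stage can be checked
against ground truth without an aligner.

The error model is deliberately simple — independent per-base events, no
homopolymer bias — which is enough to exercise Hamming-neighbourhood and
posterior logic.  Cell barcodes are drawn with pairwise Hamming distance
>= 5 and per-cell UMIs with pairwise distance >= 3, mirroring the
separation real barcode designs aim for and making ground truth
unambiguous at the simulated error rates.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pysam
from Bio.Seq import reverse_complement

from .chemistry import ChemistryProfile, get_profile
from .extraction import ReadRecord, quals_to_string, write_fastq, _open_text
from .correction import hamming_distance
from .quantify import CountMatrix

_BASES = np.array(list("ACGT"))

POLYT_LENGTH = 15
MIN_FRAGMENT_LENGTH = 100
#: fraction of reads that are distinct molecules; the rest are PCR duplicates
MOLECULE_FRACTION = 0.6


@dataclass(frozen=True)
class SimParams:
    """Study conditions for one simulation run."""

    n_cells: int = 50
    n_genes: int = 8
    isoforms_per_gene: int = 2
    reads_per_cell: int = 40
    umi_length: int = 12
    sub_rate: float = 0.0
    ins_rate: float = 0.0
    del_rate: float = 0.0
    chemistry: ChemistryProfile = field(default_factory=lambda: get_profile("10x-3p-v3"))
    seed: int = 0

    def __post_init__(self) -> None:
        for rate in (self.sub_rate, self.ins_rate, self.del_rate):
            if not (0 <= rate < 0.5):
                raise ValueError("error rates must lie in [0, 0.5)")
        if min(self.n_cells, self.n_genes, self.reads_per_cell, self.umi_length) <= 0:
            raise ValueError("counts must be positive")


@dataclass
class ToyTranscript:
    transcript_id: str
    gene_id: str
    contig: str
    exons: list[tuple[int, int]]  # genomic, 0-based half-open, sorted
    sequence: str


@dataclass
class ToyReference:
    contigs: dict[str, str]
    transcripts: dict[str, ToyTranscript]
    tx2chrom: dict[str, str]
    tx2gene: dict[str, str]
    gtf_lines: list[str]

    def gene_ids(self) -> list[str]:
        return sorted({t.gene_id for t in self.transcripts.values()})

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": out_dir / "genome.fa",
            "gtf": out_dir / "annotation.gtf",
            "transcripts": out_dir / "transcripts.fa",
        }
        with open(paths["genome"], "w") as fa:
            for name in sorted(self.contigs):
                fa.write(f">{name}\n{self.contigs[name]}\n")
        with open(paths["gtf"], "w") as gtf:
            gtf.write("\n".join(self.gtf_lines) + "\n")
        with open(paths["transcripts"], "w") as fa:
            for tx_id in sorted(self.transcripts):
                fa.write(f">{tx_id}\n{self.transcripts[tx_id].sequence}\n")
        return paths


@dataclass
class TruthRow:
    read_id: str
    cell_barcode: str
    umi: str
    transcript_id: str
    gene_id: str
    strand: str
    n_errors_introduced: int
    frag_start: int
    frag_len: int


@dataclass
class SimResult:
    params: SimParams
    reference: ToyReference
    reads: list[ReadRecord]
    truth: list[TruthRow]
    whitelist: list[str]
    truth_matrix: CountMatrix


@dataclass
class CorruptionResult:
    sequence: str
    qualities: Optional[list[int]]
    n_errors: int
    positions: list[int]


# ---------------------------------------------------------------------------
# Reference construction


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, n)])


def make_toy_reference(
    n_genes: int = 8, isoforms_per_gene: int = 2, seed: int = 0
) -> ToyReference:
    """Toy genome on two contigs with spliced, non-overlapping genes.

    Each gene gets 4-6 exons; isoform 1 uses all of them and further
    isoforms each drop a distinct internal exon, so transcript sequences
    equal the concatenation of their exons by construction.
    """
    if n_genes <= 0 or isoforms_per_gene <= 0:
        raise ValueError("counts must be positive")
    rng = np.random.default_rng(seed)
    contig_names = ["chr1", "chr2"]
    cursors = {name: 200 for name in contig_names}
    transcripts: dict[str, ToyTranscript] = {}
    gtf_lines: list[str] = []
    gene_spans: dict[str, list[tuple[str, int, int]]] = {name: [] for name in contig_names}
    for g in range(n_genes):
        contig = contig_names[g % 2]
        gene_id = f"gene{g + 1:03d}"
        gene_name = gene_id
        n_exons = max(4, isoforms_per_gene + 2)
        exons: list[tuple[int, int]] = []
        pos = cursors[contig]
        for _ in range(n_exons):
            length = int(rng.integers(120, 301))
            exons.append((pos, pos + length))
            pos += length + int(rng.integers(60, 201))
        cursors[contig] = exons[-1][1] + 500
        gene_spans[contig].append((gene_id, exons[0][0], exons[-1][1]))
        attrs = f'gene_id "{gene_id}"; gene_name "{gene_name}";'
        gtf_lines.append(
            f"{contig}\tnanosc\tgene\t{exons[0][0] + 1}\t{exons[-1][1]}\t.\t+\t.\t{attrs}"
        )
        internal = list(range(1, n_exons - 1))
        for iso in range(isoforms_per_gene):
            tx_id = f"{gene_id}.t{iso + 1}"
            keep = (
                exons
                if iso == 0
                else [e for j, e in enumerate(exons) if j != internal[iso - 1]]
            )
            tx_attrs = f'{attrs} transcript_id "{tx_id}";'
            gtf_lines.append(
                f"{contig}\tnanosc\ttranscript\t{keep[0][0] + 1}\t{keep[-1][1]}\t.\t+\t.\t{tx_attrs}"
            )
            for s, e in keep:
                gtf_lines.append(f"{contig}\tnanosc\texon\t{s + 1}\t{e}\t.\t+\t.\t{tx_attrs}")
            transcripts[tx_id] = ToyTranscript(tx_id, gene_id, contig, keep, "")
    contigs = {name: _random_dna(rng, cursors[name]) for name in contig_names}
    for tx in transcripts.values():
        tx.sequence = "".join(contigs[tx.contig][s:e] for s, e in tx.exons)
    tx2chrom = {t: tx.contig for t, tx in transcripts.items()}
    tx2gene = {t: tx.gene_id for t, tx in transcripts.items()}
    return ToyReference(contigs, transcripts, tx2chrom, tx2gene, gtf_lines)


# ---------------------------------------------------------------------------
# Error model


def corrupt_sequence(
    seq: str,
    sub_rate: float,
    ins_rate: float,
    del_rate: float,
    rng: np.random.Generator,
    quals: Optional[list[int]] = None,
) -> CorruptionResult:
    """Apply independent per-base substitution/insertion/deletion errors.

    Qualities, when given, track the sequence in lockstep (inserted bases
    get a fresh quality draw).  Error positions refer to the original
    sequence coordinates.
    """
    out: list[str] = []
    out_quals: list[int] = [] if quals is not None else None  # type: ignore[assignment]
    n_errors = 0
    positions: list[int] = []
    for i, base in enumerate(seq):
        if del_rate and rng.random() < del_rate:
            n_errors += 1
            positions.append(i)
        else:
            if sub_rate and rng.random() < sub_rate:
                base = str(rng.choice(_BASES[_BASES != base]))
                n_errors += 1
                positions.append(i)
            out.append(base)
            if out_quals is not None:
                out_quals.append(quals[i])
        if ins_rate and rng.random() < ins_rate:
            out.append(str(_BASES[rng.integers(0, 4)]))
            if out_quals is not None:
                out_quals.append(int(rng.integers(20, 41)))
            n_errors += 1
            positions.append(i)
    return CorruptionResult("".join(out), out_quals, n_errors, positions)


# ---------------------------------------------------------------------------
# Read simulation


def _distinct_kmers(rng: np.random.Generator, n: int, k: int, min_distance: int) -> list[str]:
    """Draw n random k-mers pairwise >= min_distance apart (rejection sampling)."""
    chosen: list[str] = []
    attempts = 0
    while len(chosen) < n:
        attempts += 1
        if attempts > 100000:
            raise RuntimeError("could not draw sufficiently separated k-mers")
        candidate = _random_dna(rng, k)
        if all(hamming_distance(candidate, other) >= min_distance for other in chosen):
            chosen.append(candidate)
    return chosen


def simulate_reads(params: SimParams, reference: ToyReference) -> SimResult:
    """Generate reads, truth table, whitelist and truth count matrix."""
    rng = np.random.default_rng(params.seed)
    chem = params.chemistry
    whitelist = _distinct_kmers(rng, params.n_cells, chem.barcode_length, 5)
    tx_ids = sorted(reference.transcripts)
    reads: list[ReadRecord] = []
    truth: list[TruthRow] = []
    molecule_triplets: dict[tuple[str, str], int] = {}
    read_index = 0
    for barcode in whitelist:
        n_molecules = max(1, round(params.reads_per_cell * MOLECULE_FRACTION))
        umis = _distinct_kmers(rng, n_molecules, params.umi_length, 3)
        molecules = []
        for umi in umis:
            tx = reference.transcripts[tx_ids[rng.integers(0, len(tx_ids))]]
            max_start = max(1, len(tx.sequence) - MIN_FRAGMENT_LENGTH)
            frag_start = int(rng.integers(0, max_start))
            molecules.append((umi, tx, frag_start))
        # every molecule yields one read; the remainder are duplicates
        picks = list(range(n_molecules)) + list(
            rng.integers(0, n_molecules, max(0, params.reads_per_cell - n_molecules))
        )
        for mol_idx in picks:
            umi, tx, frag_start = molecules[mol_idx]
            fragment = tx.sequence[frag_start:]
            clean = chem.adapter + barcode + umi + "T" * POLYT_LENGTH + fragment
            quals = [int(q) for q in rng.integers(20, 41, len(clean))]
            corrupted = corrupt_sequence(
                clean, params.sub_rate, params.ins_rate, params.del_rate, rng, quals
            )
            sequence, qualities = corrupted.sequence, corrupted.qualities
            strand = "+"
            if rng.random() < 0.5:
                strand = "-"
                sequence = reverse_complement(sequence)
                qualities = list(reversed(qualities))
            read_id = f"read{read_index:06d}"
            read_index += 1
            reads.append(ReadRecord(read_id, sequence, qualities))
            truth.append(
                TruthRow(
                    read_id,
                    barcode,
                    umi,
                    tx.transcript_id,
                    tx.gene_id,
                    strand,
                    corrupted.n_errors,
                    frag_start,
                    len(fragment),
                )
            )
        for umi, tx, _ in molecules:
            key = (barcode, tx.gene_id)
            molecule_triplets[key] = molecule_triplets.get(key, 0) + 1
    gene_names = {g: g for g in reference.gene_ids()}
    truth_matrix = CountMatrix.from_triplets(molecule_triplets, "gene", gene_names)
    return SimResult(params, reference, reads, truth, sorted(whitelist), truth_matrix)


# ---------------------------------------------------------------------------
# Perfect-placement alignments


def _tx_interval_to_blocks(
    tx: ToyTranscript, start: int, length: int
) -> list[tuple[int, int]]:
    """Map a transcript-coordinate interval onto genomic exon blocks."""
    blocks: list[tuple[int, int]] = []
    offset = 0
    remaining_start, remaining = start, length
    for es, ee in tx.exons:
        exon_len = ee - es
        if remaining <= 0:
            break
        if remaining_start >= exon_len:
            remaining_start -= exon_len
            continue
        block_start = es + remaining_start
        take = min(exon_len - remaining_start, remaining)
        blocks.append((block_start, block_start + take))
        remaining -= take
        remaining_start = 0
    return blocks


def simulate_alignments(
    truth: list[TruthRow],
    reference: ToyReference,
    mode: Literal["genome", "transcriptome"],
    sam_out: str | Path,
) -> int:
    """Write one primary SAM record per truth row at its true origin.

    Genome mode uses spliced placement (M blocks joined by N skips across
    introns); transcriptome mode aligns the fragment to its transcript.
    Records carry the clean fragment sequence with a consistent CIGAR.
    """
    if mode == "genome":
        names = sorted(reference.contigs)
        lengths = [len(reference.contigs[n]) for n in names]
    else:
        names = sorted(reference.transcripts)
        lengths = [len(reference.transcripts[n].sequence) for n in names]
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": n, "LN": ln} for n, ln in zip(names, lengths)],
        }
    )
    tid = {n: i for i, n in enumerate(names)}
    records = []
    for row in truth:
        tx = reference.transcripts[row.transcript_id]
        fragment = tx.sequence[row.frag_start : row.frag_start + row.frag_len]
        rec = pysam.AlignedSegment(header)
        rec.query_name = row.read_id
        rec.query_sequence = fragment
        rec.query_qualities = pysam.qualitystring_to_array("I" * len(fragment))
        rec.flag = 0
        rec.mapping_quality = 60
        if mode == "transcriptome":
            rec.reference_id = tid[row.transcript_id]
            rec.reference_start = row.frag_start
            rec.cigarstring = f"{row.frag_len}M"
        else:
            blocks = _tx_interval_to_blocks(tx, row.frag_start, row.frag_len)
            rec.reference_id = tid[tx.contig]
            rec.reference_start = blocks[0][0]
            cigar = []
            for i, (bs, be) in enumerate(blocks):
                if i:
                    cigar.append(f"{bs - blocks[i - 1][1]}N")
                cigar.append(f"{be - bs}M")
            rec.cigarstring = "".join(cigar)
        records.append(rec)
    records.sort(key=lambda r: (r.reference_id, r.reference_start, r.query_name))
    mode_flag = "wh" if str(sam_out).endswith(".sam") else "wb"
    with pysam.AlignmentFile(str(sam_out), mode_flag, header=header) as out:
        for rec in records:
            out.write(rec)
    return len(records)


# ---------------------------------------------------------------------------
# File emission


def write_truth_table(truth: list[TruthRow], path: str | Path) -> None:
    with _open_text(path, "wt") as out:
        writer = csv.writer(out)
        writer.writerow(
            [
                "read_id",
                "cell_barcode",
                "umi",
                "transcript_id",
                "gene_id",
                "strand",
                "n_errors_introduced",
                "frag_start",
                "frag_len",
            ]
        )
        for r in truth:
            writer.writerow(
                [
                    r.read_id,
                    r.cell_barcode,
                    r.umi,
                    r.transcript_id,
                    r.gene_id,
                    r.strand,
                    r.n_errors_introduced,
                    r.frag_start,
                    r.frag_len,
                ]
            )


def run_simulation(params: SimParams, out_dir: str | Path) -> SimResult:
    """Full simulation with all artifacts written under ``out_dir``."""
    from .quantify import write_matrix

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    reference = make_toy_reference(params.n_genes, params.isoforms_per_gene, params.seed)
    reference.write(out_dir)
    sim = simulate_reads(params, reference)
    write_fastq(sim.reads, out_dir / "reads.fastq")
    write_truth_table(sim.truth, out_dir / "truth.csv")
    with open(out_dir / "whitelist.txt", "w") as handle:
        for bc in sim.whitelist:
            handle.write(bc + "\n")
    simulate_alignments(sim.truth, reference, "genome", out_dir / "genome.sam")
    simulate_alignments(sim.truth, reference, "transcriptome", out_dir / "transcriptome.sam")
    write_matrix(sim.truth_matrix, out_dir / "truth_matrix")
    return sim
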