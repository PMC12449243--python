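"""Barcode x feature UMI-count matrices from deduplicated alignments.

Gene-level counting assigns each genome alignment to the gene whose exon
union covers at least half of its aligned reference bases (strand is
ignored because ONT cDNA strand is ambiguous); transcript-level counting
keys on the alignment's reference name.  Matrices are written in the
standard single-cell triplet layout: ``matrix.mtx.gz`` (features x
barcodes) next to ``barcodes.tsv.gz`` and ``features.tsv.gz``.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping, Optional

import gffutils
import pysam
import scipy.io
import scipy.sparse as sp

from .tagging import _open_alignment


@dataclass
class GeneModel:
    gene_id: str
    gene_name: str
    contig: str
    strand: str
    exons: list[tuple[int, int]]  # 0-based half-open, sorted, non-overlapping

    def exon_length(self) -> int:
        return sum(e - s for s, e in self.exons)


@dataclass(frozen=True)
class Feature:
    feature_id: str
    feature_name: str
    kind: str  # gene | transcript


@dataclass
class CountMatrix:
    """Sparse barcode x feature UMI counts (stored features x barcodes)."""

    barcodes: list[str]
    features: list[Feature]
    counts: sp.csr_matrix

    def __post_init__(self) -> None:
        if self.counts.shape != (len(self.features), len(self.barcodes)):
            raise ValueError("count matrix shape does not match features x barcodes")

    @classmethod
    def from_triplets(
        cls,
        triplets: Mapping[tuple[str, str], int],
        kind: str,
        feature_names: Optional[Mapping[str, str]] = None,
    ) -> "CountMatrix":
        """Build from a ``(barcode, feature_id) -> count`` mapping."""
        barcodes = sorted({bc for bc, _ in triplets})
        feature_ids = sorted({f for _, f in triplets})
        bc_idx = {b: i for i, b in enumerate(barcodes)}
        ft_idx = {f: i for i, f in enumerate(feature_ids)}
        rows, cols, vals = [], [], []
        for (bc, ft), n in triplets.items():
            if n <= 0:
                raise ValueError("counts must be positive")
            rows.append(ft_idx[ft])
            cols.append(bc_idx[bc])
            vals.append(n)
        counts = sp.csr_matrix(
            (vals, (rows, cols)), shape=(len(feature_ids), len(barcodes)), dtype=int
        )
        names = feature_names or {}
        features = [Feature(f, names.get(f, f), kind) for f in feature_ids]
        return cls(barcodes, features, counts)

    def total_mass(self) -> int:
        return int(self.counts.sum())

    def equals(self, other: "CountMatrix") -> bool:
        return (
            self.barcodes == other.barcodes
            and self.features == other.features
            and (self.counts != other.counts).nnz == 0
        )


# ---------------------------------------------------------------------------
# Annotation


def load_annotation(
    gtf: str | Path,
) -> tuple[list[GeneModel], dict[str, str], dict[str, str]]:
    """Parse a GTF into gene models plus transcript->chromosome/gene maps.

    Exons of each gene are unioned into sorted non-overlapping intervals;
    GTF 1-based inclusive coordinates become 0-based half-open.
    """
    db = gffutils.create_db(
        str(gtf),
        ":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    per_gene: dict[str, GeneModel] = {}
    tx2chrom: dict[str, str] = {}
    tx2gene: dict[str, str] = {}
    n_exons = 0
    for exon in db.features_of_type("exon"):
        n_exons += 1
        if "gene_id" not in exon.attributes:
            raise ValueError(f"GTF exon without gene_id at {exon.seqid}:{exon.start}")
        if "transcript_id" not in exon.attributes:
            raise ValueError(f"GTF exon without transcript_id at {exon.seqid}:{exon.start}")
        gene_id = exon.attributes["gene_id"][0]
        tx_id = exon.attributes["transcript_id"][0]
        gene_name = exon.attributes.get("gene_name", [gene_id])[0]
        tx2chrom[tx_id] = exon.seqid
        tx2gene[tx_id] = gene_id
        model = per_gene.setdefault(
            gene_id, GeneModel(gene_id, gene_name, exon.seqid, exon.strand or "+", [])
        )
        model.exons.append((exon.start - 1, exon.end))
    if n_exons == 0:
        raise ValueError(f"{gtf}: no exon features found")
    models = []
    for gene_id in sorted(per_gene):
        model = per_gene[gene_id]
        model.exons = _union_intervals(model.exons)
        models.append(model)
    return models, tx2chrom, tx2gene


def _union_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


# ---------------------------------------------------------------------------
# Assignment and counting

MIN_OVERLAP_FRACTION = 0.5


def assign_gene(
    aln: pysam.AlignedSegment, models: list[GeneModel]
) -> str | Literal["ambiguous"] | None:
    """Gene whose exon union covers >= 50% of the alignment's aligned bases.

    Two or more qualifying genes give ``ambiguous``; none gives ``None``.
    """
    blocks = aln.get_blocks()
    aligned = sum(e - s for s, e in blocks)
    if aligned == 0:
        return None
    hits = []
    for model in models:
        if model.contig != aln.reference_name:
            continue
        overlap = 0
        for bs, be in blocks:
            for es, ee in model.exons:
                overlap += max(0, min(be, ee) - max(bs, es))
        if overlap / aligned >= MIN_OVERLAP_FRACTION:
            hits.append(model.gene_id)
    if not hits:
        return None
    return hits[0] if len(hits) == 1 else "ambiguous"


def count_genome(
    dedup_bam: str | Path, gtf: str | Path
) -> tuple[CountMatrix, dict[str, int]]:
    """Gene-level counts over deduplicated CB-tagged genome alignments."""
    models, _, _ = load_annotation(gtf)
    names = {m.gene_id: m.gene_name for m in models}
    triplets: dict[tuple[str, str], int] = {}
    stats = {"n_records": 0, "n_assigned": 0, "n_ambiguous": 0, "n_unassigned": 0, "n_no_cb": 0}
    with _open_alignment(dedup_bam) as src:
        for rec in src.fetch(until_eof=True):
            if rec.is_secondary or rec.is_supplementary or rec.is_unmapped:
                continue
            stats["n_records"] += 1
            if not rec.has_tag("CB"):
                stats["n_no_cb"] += 1
                continue
            gene = assign_gene(rec, models)
            if gene is None:
                stats["n_unassigned"] += 1
            elif gene == "ambiguous":
                stats["n_ambiguous"] += 1
            else:
                stats["n_assigned"] += 1
                key = (rec.get_tag("CB"), gene)
                triplets[key] = triplets.get(key, 0) + 1
    if stats["n_records"] and stats["n_records"] == stats["n_no_cb"]:
        raise ValueError(f"{dedup_bam}: no CB tags found; tag and deduplicate first")
    return CountMatrix.from_triplets(triplets, "gene", names), stats


def count_transcriptome(
    dedup_bam: str | Path,
    tx2gene: Optional[Mapping[str, str]] = None,
    strict: bool = False,
) -> tuple[CountMatrix, dict[str, int]]:
    """Transcript-level counts keyed on alignment reference names."""
    triplets: dict[tuple[str, str], int] = {}
    stats = {"n_records": 0, "n_assigned": 0, "n_no_cb": 0}
    missing: set[str] = set()
    with _open_alignment(dedup_bam) as src:
        for rec in src.fetch(until_eof=True):
            if rec.is_secondary or rec.is_supplementary or rec.is_unmapped:
                continue
            stats["n_records"] += 1
            if not rec.has_tag("CB"):
                stats["n_no_cb"] += 1
                continue
            tx = rec.reference_name
            if tx2gene is not None and tx not in tx2gene:
                missing.add(tx)
            stats["n_assigned"] += 1
            key = (rec.get_tag("CB"), tx)
            triplets[key] = triplets.get(key, 0) + 1
    if strict and missing:
        raise ValueError("transcripts missing from tx2gene: " + ", ".join(sorted(missing)[:10]))
    names = dict(tx2gene) if tx2gene else None
    return CountMatrix.from_triplets(triplets, "transcript", names), stats


# ---------------------------------------------------------------------------
# Matrix I/O


def write_matrix(matrix: CountMatrix, out_dir: str | Path) -> Path:
    """Write matrix.mtx.gz + barcodes.tsv.gz + features.tsv.gz."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with gzip.open(out_dir / "matrix.mtx.gz", "wb") as handle:
        scipy.io.mmwrite(handle, sp.coo_matrix(matrix.counts), field="integer")
    with gzip.open(out_dir / "barcodes.tsv.gz", "wt") as handle:
        for bc in matrix.barcodes:
            handle.write(bc + "\n")
    with gzip.open(out_dir / "features.tsv.gz", "wt") as handle:
        for ft in matrix.features:
            handle.write(f"{ft.feature_id}\t{ft.feature_name}\t{ft.kind}\n")
    return out_dir


def read_matrix(matrix_dir: str | Path) -> CountMatrix:
    matrix_dir = Path(matrix_dir)
    with gzip.open(matrix_dir / "matrix.mtx.gz", "rb") as handle:
        counts = sp.csr_matrix(scipy.io.mmread(handle), dtype=int)
    with gzip.open(matrix_dir / "barcodes.tsv.gz", "rt") as handle:
        barcodes = [line.strip() for line in handle if line.strip()]
    features = []
    with gzip.open(matrix_dir / "features.tsv.gz", "rt") as handle:
        for line in handle:
            if line.strip():
                fid, name, kind = line.rstrip("\n").split("\t")
                features.append(Feature(fid, name, kind))
    return CountMatrix(barcodes, features, counts)
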