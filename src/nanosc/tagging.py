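"""Joining barcode-correction results onto aligned reads.

Tags follow the established single-cell convention: ``CR``/``CY`` raw
barcode and its qualities, ``UR``/``UY`` raw UMI and qualities, and ``CB``
the corrected barcode (present only when correction succeeded).  Splitting
helpers shard a BAM for per-chromosome deduplication.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Mapping, Optional

import pysam

from .extraction import _open_text

TAG_TABLE_COLUMNS = [
    "read_id",
    "barcode",
    "barcode_quals",
    "umi",
    "umi_quals",
    "corrected_barcode",
    "status",
]


def _open_alignment(path: str | Path, mode: str = "r", template=None, header=None):
    suffix = Path(path).suffix
    if mode == "w":
        mode = "wh" if suffix == ".sam" else "wb"
        return pysam.AlignmentFile(str(path), mode, template=template, header=header)
    return pysam.AlignmentFile(str(path), "r", check_sq=False)


def load_corrected_table(path: str | Path) -> dict[str, dict[str, str]]:
    """Corrected-table rows keyed by read_id."""
    with _open_text(path) as handle:
        reader = csv.DictReader(handle)
        missing = [c for c in TAG_TABLE_COLUMNS if c not in (reader.fieldnames or [])]
        if missing:
            raise ValueError(f"corrected table {path}: missing columns {missing}")
        return {row["read_id"]: row for row in reader}


def tag_bam(
    bam_in: str | Path,
    corrected_table: str | Path | Mapping[str, Mapping[str, str]],
    bam_out: str | Path,
    drop_uncorrected: bool = False,
    strict: bool = False,
) -> dict[str, int]:
    """Write CR/CB/UR/CY/UY tags onto every alignment found in the table.

    Records whose correction status is ``exact`` or ``corrected`` gain a
    ``CB`` tag; others keep only the raw tags.  With ``drop_uncorrected``
    CB-less records are omitted from the output.
    """
    table = (
        corrected_table
        if isinstance(corrected_table, Mapping)
        else load_corrected_table(corrected_table)
    )
    stats = {"n_records": 0, "n_tagged": 0, "n_with_CB": 0, "n_dropped": 0, "n_untagged": 0}
    untagged_ids: list[str] = []
    with _open_alignment(bam_in) as src:
        with _open_alignment(bam_out, "w", template=src) as dst:
            for rec in src.fetch(until_eof=True):
                stats["n_records"] += 1
                row = table.get(rec.query_name)
                if row is None:
                    stats["n_untagged"] += 1
                    untagged_ids.append(rec.query_name)
                    if drop_uncorrected:
                        stats["n_dropped"] += 1
                        continue
                    dst.write(rec)
                    continue
                rec.set_tag("CR", row["barcode"], value_type="Z")
                rec.set_tag("CY", row["barcode_quals"], value_type="Z")
                rec.set_tag("UR", row["umi"], value_type="Z")
                rec.set_tag("UY", row["umi_quals"], value_type="Z")
                has_cb = row["status"] in ("exact", "corrected") and row["corrected_barcode"]
                if has_cb:
                    rec.set_tag("CB", row["corrected_barcode"], value_type="Z")
                    stats["n_with_CB"] += 1
                elif drop_uncorrected:
                    stats["n_dropped"] += 1
                    continue
                stats["n_tagged"] += 1
                dst.write(rec)
    if strict and untagged_ids:
        raise ValueError(
            f"{len(untagged_ids)} aligned reads absent from corrected table: "
            + ", ".join(untagged_ids[:10])
        )
    return stats


def _split(
    bam_in: str | Path,
    out_dir: str | Path,
    route,
    suffix: str,
) -> dict[str, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    writers: dict[str, pysam.AlignmentFile] = {}
    paths: dict[str, Path] = {}
    with _open_alignment(bam_in) as src:
        try:
            for rec in src.fetch(until_eof=True):
                bucket = route(rec)
                if bucket not in writers:
                    paths[bucket] = out_dir / f"{bucket}{suffix}"
                    writers[bucket] = _open_alignment(paths[bucket], "w", template=src)
                writers[bucket].write(rec)
        finally:
            for w in writers.values():
                w.close()
    return paths


def split_by_chromosome(bam_in: str | Path, out_dir: str | Path) -> dict[str, Path]:
    """One output file per contig plus an ``unmapped`` bucket."""
    suffix = Path(bam_in).suffix or ".bam"

    def route(rec: pysam.AlignedSegment) -> str:
        return rec.reference_name if not rec.is_unmapped else "unmapped"

    return _split(bam_in, out_dir, route, suffix)


def split_by_feature_groups(
    bam_in: str | Path,
    tx2chrom: Mapping[str, str],
    out_dir: str | Path,
    strict: bool = True,
) -> dict[str, Path]:
    """Group transcriptome alignments by the chromosome their transcript lives on.

    Unknown transcripts raise in strict mode, otherwise land in an
    ``unassigned`` bucket; unmapped records always go to ``unmapped``.
    """
    suffix = Path(bam_in).suffix or ".bam"
    missing: set[str] = set()

    def route(rec: pysam.AlignedSegment) -> str:
        if rec.is_unmapped:
            return "unmapped"
        chrom = tx2chrom.get(rec.reference_name)
        if chrom is None:
            missing.add(rec.reference_name)
            return "unassigned"
        return chrom

    paths = _split(bam_in, out_dir, route, suffix)
    if strict and missing:
        raise ValueError(
            "transcripts missing from tx2chrom: " + ", ".join(sorted(missing)[:10])
        )
    return paths
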