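"""End-to-end desk-scale pipeline: extract -> whitelist -> correct -> tag ->
dedup -> count, with stage tracking.

This is the glue the command-line stages compose; it exists so simulated
runs (and tests) can exercise the whole funnel in one call.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

from .chemistry import ChemistryProfile
from .correction import (
    CorrectionParams,
    WhitelistEntry,
    build_whitelist,
    correct_table,
    rank_barcodes,
    save_whitelist,
)
from .dedup import DedupParams, dedup_bam
from .extraction import extract_batch, read_barcode_table
from .qc import TrackingStore, cell_metrics, mapping_summary
from .quantify import CountMatrix, count_genome, write_matrix
from .tagging import tag_bam


@dataclass
class PipelineResult:
    out_dir: Path
    extract_stats: dict
    correct_stats: dict
    tag_stats: dict
    dedup_stats: dict
    count_stats: dict
    matrix: CountMatrix
    whitelist: list[WhitelistEntry]
    tracking: TrackingStore


def run_pipeline(
    fastq: str | Path,
    bam: str | Path,
    gtf: str | Path,
    out_dir: str | Path,
    chem: ChemistryProfile,
    params: CorrectionParams = CorrectionParams(),
    expected_cells: Optional[int] = None,
    sample: str = "sample",
) -> PipelineResult:
    """Run every stage on one sample; all intermediates land in ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    trimmed_fastq = out_dir / "trimmed.fastq"
    table = out_dir / "barcodes.csv"
    corrected = out_dir / "corrected.csv"
    tagged = out_dir / "tagged.sam"
    deduped = out_dir / "dedup.sam"

    extract_stats = extract_batch(fastq, chem, trimmed_fastq, table)

    ranked = rank_barcodes(read_barcode_table(table), params.min_whitelist_quality)
    whitelist = build_whitelist(ranked, expected_cells)
    save_whitelist(whitelist, out_dir / "whitelist.txt")

    correct_stats = correct_table(table, whitelist, corrected, params)
    tag_stats = tag_bam(bam, corrected, tagged)
    dedup_stats = dedup_bam(tagged, deduped, DedupParams(mode="genome"))
    matrix, count_stats = count_genome(deduped, gtf)
    write_matrix(matrix, out_dir / "matrix")

    aligned = mapping_summary(bam)
    tracking = TrackingStore()
    tracking.record_stage(sample, "raw", extract_stats["n_input"])
    tracking.record_stage(
        sample, "trimmed", extract_stats["n_input"] - extract_stats["n_filtered"]
    )
    tracking.record_stage(sample, "structured", extract_stats["n_structured"])
    tracking.record_stage(sample, "aligned", aligned["n_mapped"])
    tracking.record_stage(sample, "primary_mapped", aligned["n_primary"])
    tracking.record_stage(sample, "cb_tagged", tag_stats["n_with_CB"])
    tracking.record_stage(sample, "deduplicated", dedup_stats["n_out"])

    return PipelineResult(
        out_dir=out_dir,
        extract_stats=extract_stats,
        correct_stats=correct_stats,
        tag_stats=tag_stats,
        dedup_stats=dedup_stats,
        count_stats=count_stats,
        matrix=matrix,
        whitelist=whitelist,
        tracking=tracking,
    )
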