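"""Per-cell UMI deduplication with the directional network method.

Alignments are grouped by (cell barcode, locus) — the locus being the
soft-clip-adjusted 5' position in genome mode or the transcript in
transcriptome mode — and each group's UMIs are clustered.  The directional
rule draws an edge from UMI ``a`` to UMI ``b`` when they are within
``umi_hamming`` and ``count(a) >= 2*count(b) - 1``; clusters are grown by
breadth-first traversal from the highest-count unclaimed UMI, so a chain
of sequencing errors collapses onto the abundant original molecule.
"""

from __future__ import annotations

import csv
from collections import Counter, defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Literal, Optional, Sequence

import pysam

from .extraction import _open_text
from .correction import hamming_distance
from .tagging import _open_alignment

Mode = Literal["genome", "transcriptome"]


@dataclass(frozen=True)
class DedupKey:
    cell_barcode: str
    locus: tuple


@dataclass
class UmiCluster:
    representative_umi: str
    member_umis: list[tuple[str, int]]
    n_reads: int


@dataclass(frozen=True)
class DedupParams:
    method: Literal["directional", "unique"] = "directional"
    umi_hamming: int = 1
    mode: Mode = "genome"

    def __post_init__(self) -> None:
        if self.umi_hamming < 0:
            raise ValueError("umi_hamming must be >= 0")


def _clip_adjusted_5p(rec: pysam.AlignedSegment) -> tuple[str, str, int]:
    """(contig, strand, 5' position) with soft clips folded back in.

    ONT indels and clipping shift raw positions; adjusting by the clip
    length recovers a stable per-molecule anchor.
    """
    cigar = rec.cigartuples or []
    leading = cigar[0][1] if cigar and cigar[0][0] in (4, 5) else 0
    trailing = cigar[-1][1] if cigar and cigar[-1][0] in (4, 5) else 0
    if rec.is_reverse:
        return (rec.reference_name, "-", rec.reference_end + trailing)
    return (rec.reference_name, "+", rec.reference_start - leading)


def group_alignments(
    bam_in: str | Path, mode: Mode = "genome"
) -> Iterator[tuple[DedupKey, list[pysam.AlignedSegment]]]:
    """Group CB-tagged primary alignments by deduplication key.

    Secondary/supplementary/unmapped records and records without a CB tag
    are ignored.  A CB-tagged record without a UR tag is an error.
    """
    groups: dict[DedupKey, list[pysam.AlignedSegment]] = defaultdict(list)
    with _open_alignment(bam_in) as src:
        for rec in src.fetch(until_eof=True):
            if rec.is_secondary or rec.is_supplementary or rec.is_unmapped:
                continue
            if not rec.has_tag("CB"):
                continue
            if not rec.has_tag("UR"):
                raise ValueError(f"read {rec.query_name!r} carries CB but no UR tag")
            locus = (
                _clip_adjusted_5p(rec)
                if mode == "genome"
                else (rec.reference_name,)
            )
            groups[DedupKey(rec.get_tag("CB"), locus)].append(rec)
    yield from groups.items()


def cluster_umis_directional(umi_counts: dict[str, int], umi_hamming: int = 1) -> list[UmiCluster]:
    """Cluster UMIs with the directional rule.

    Nodes are visited in count-descending (then lexicographic) order; each
    unclaimed node seeds a cluster grown by following directed edges
    ``a -> b`` (``hamming(a,b) <= umi_hamming`` and
    ``count(a) >= 2*count(b) - 1``) through unclaimed nodes only.
    """
    if not umi_counts:
        return []
    lengths = {len(u) for u in umi_counts}
    if len(lengths) > 1:
        raise ValueError(f"mixed UMI lengths in one group: {sorted(lengths)}")
    order = sorted(umi_counts, key=lambda u: (-umi_counts[u], u))
    claimed: set[str] = set()
    clusters: list[UmiCluster] = []
    for seed in order:
        if seed in claimed:
            continue
        members = [seed]
        claimed.add(seed)
        frontier = [seed]
        while frontier:
            a = frontier.pop(0)
            for b in order:
                if b in claimed:
                    continue
                if (
                    hamming_distance(a, b) <= umi_hamming
                    and umi_counts[a] >= 2 * umi_counts[b] - 1
                ):
                    claimed.add(b)
                    members.append(b)
                    frontier.append(b)
        clusters.append(
            UmiCluster(
                representative_umi=seed,
                member_umis=[(u, umi_counts[u]) for u in members],
                n_reads=sum(umi_counts[u] for u in members),
            )
        )
    return clusters


def cluster_umis_unique(umi_counts: dict[str, int]) -> list[UmiCluster]:
    """Every distinct UMI is its own molecule (MarkDuplicates-like)."""
    return [
        UmiCluster(umi, [(umi, n)], n)
        for umi, n in sorted(umi_counts.items())
    ]


def select_representative(alignments: Sequence[pysam.AlignedSegment]) -> pysam.AlignedSegment:
    """Deterministic representative: best mapq, longest reference span, smallest id."""
    if not alignments:
        raise ValueError("cannot select a representative from an empty group")

    def span(rec: pysam.AlignedSegment) -> int:
        return (rec.reference_end or 0) - (rec.reference_start or 0)

    return min(alignments, key=lambda r: (-r.mapping_quality, -span(r), r.query_name))


def dedup_bam(
    bam_in: str | Path,
    bam_out: str | Path,
    params: DedupParams = DedupParams(),
    stats_csv: Optional[str | Path] = None,
) -> dict[str, int]:
    """Collapse duplicates, keeping one representative alignment per molecule.

    Returns ``n_in`` (CB-tagged primary records considered), ``n_out``
    and ``n_molecules`` (always equal).  Output is coordinate-sorted.
    """
    kept: list[pysam.AlignedSegment] = []
    per_key: list[tuple[DedupKey, int, int]] = []
    n_in = 0
    n_records = 0
    with _open_alignment(bam_in) as src:
        n_records = sum(1 for _ in src.fetch(until_eof=True))
    for key, alignments in group_alignments(bam_in, params.mode):
        n_in += len(alignments)
        umi_counts = Counter(rec.get_tag("UR") for rec in alignments)
        if params.method == "directional":
            clusters = cluster_umis_directional(dict(umi_counts), params.umi_hamming)
        else:
            clusters = cluster_umis_unique(dict(umi_counts))
        for cluster in clusters:
            member_set = {u for u, _ in cluster.member_umis}
            members = [rec for rec in alignments if rec.get_tag("UR") in member_set]
            kept.append(select_representative(members))
        per_key.append((key, len(alignments), len(clusters)))
    if n_records and n_in == 0:
        raise ValueError(
            f"{bam_in}: no CB-tagged primary alignments found; run tagging first"
        )
    kept.sort(key=lambda r: (r.reference_id, r.reference_start, r.query_name))
    with _open_alignment(bam_in) as src:
        with _open_alignment(bam_out, "w", template=src) as dst:
            for rec in kept:
                dst.write(rec)
    if stats_csv is not None:
        with _open_text(stats_csv, "wt") as out:
            writer = csv.writer(out)
            writer.writerow(["cell_barcode", "locus", "n_in", "n_out"])
            for key, n_grp_in, n_grp_out in sorted(
                per_key, key=lambda t: (t[0].cell_barcode, t[0].locus)
            ):
                writer.writerow([key.cell_barcode, "|".join(map(str, key.locus)), n_grp_in, n_grp_out])
    return {"n_in": n_in, "n_out": len(kept), "n_molecules": len(kept)}
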