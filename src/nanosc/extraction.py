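"""Read filtering and 10X structure extraction from noisy long reads.

A 3' 10X long read looks like::

    [adapter][16 nt cell barcode][UMI][poly-T tail][cDNA ...]

possibly reverse-complemented.  This module locates that structure with an
edit-distance adapter search, records the putative barcode/UMI together
with their base qualities, and emits a barcode-free read ready for
alignment.
"""

from __future__ import annotations

import csv
import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional, TextIO

import edlib
from Bio import SeqIO
from Bio.Seq import reverse_complement

from .chemistry import ChemistryProfile

PHRED_OFFSET = 33


class FastqParseError(ValueError):
    """Raised for malformed FASTQ records (names the offending read)."""


@dataclass
class ReadRecord:
    """One sequencing read with per-base Phred qualities."""

    read_id: str
    sequence: str
    qualities: list[int]
    description: str = ""

    def __post_init__(self) -> None:
        if len(self.qualities) != len(self.sequence):
            raise FastqParseError(
                f"read {self.read_id!r}: sequence length {len(self.sequence)} "
                f"!= quality length {len(self.qualities)}"
            )

    def mean_quality(self) -> float:
        if not self.qualities:
            return 0.0
        return sum(self.qualities) / len(self.qualities)

    def reverse_complement(self) -> "ReadRecord":
        return ReadRecord(
            read_id=self.read_id,
            sequence=reverse_complement(self.sequence),
            qualities=list(reversed(self.qualities)),
            description=self.description,
        )


@dataclass(frozen=True)
class StructureHit:
    """Location of the adapter/barcode/UMI layout on a read.

    Offsets are 0-based half-open and refer to the read *in the orientation
    of the hit*: for ``strand == "-"`` they index into the read's reverse
    complement.
    """

    strand: str  # "+" or "-"
    adapter_end: int
    bc_span: tuple[int, int]
    umi_span: tuple[int, int]
    polyt_end: Optional[int] = None
    adapter_distance: int = 0


@dataclass
class PutativeBarcodeRecord:
    """Uncorrected barcode/UMI call for one read."""

    read_id: str
    barcode: str
    barcode_quals: list[int]
    umi: str
    umi_quals: list[int]
    strand: str

    def __post_init__(self) -> None:
        if len(self.barcode) != len(self.barcode_quals):
            raise ValueError(f"read {self.read_id!r}: barcode/quality length mismatch")
        if len(self.umi) != len(self.umi_quals):
            raise ValueError(f"read {self.read_id!r}: UMI/quality length mismatch")


def quals_to_string(quals: Iterable[int]) -> str:
    return "".join(chr(q + PHRED_OFFSET) for q in quals)


def string_to_quals(s: str) -> list[int]:
    return [ord(c) - PHRED_OFFSET for c in s]


# ---------------------------------------------------------------------------
# FASTQ I/O (Biopython-backed; transparent gzip)


def _open_text(path: str | Path, mode: str = "rt") -> TextIO:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)  # type: ignore[return-value]
    return open(path, mode)


def read_fastq(path: str | Path) -> Iterator[ReadRecord]:
    """Stream a (possibly gzipped) FASTQ file as :class:`ReadRecord`."""
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fastq"):
            yield ReadRecord(
                read_id=rec.id,
                sequence=str(rec.seq).upper(),
                qualities=list(rec.letter_annotations["phred_quality"]),
                description=rec.description,
            )


def write_fastq(records: Iterable[ReadRecord], path: str | Path) -> int:
    """Write 4-line FASTQ; returns the number of records written."""
    n = 0
    with _open_text(path, "wt") as out:
        for r in records:
            out.write(f"@{r.read_id}\n{r.sequence}\n+\n{quals_to_string(r.qualities)}\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# Filtering


def filter_reads(
    reads: Iterable[ReadRecord],
    min_mean_quality: float = 0.0,
    min_length: int = 0,
    max_length: int = 10**9,
) -> tuple[list[ReadRecord], int]:
    """Keep reads with mean Phred >= ``min_mean_quality`` and length within bounds.

    Returns the kept reads (input order preserved) and the dropped count.
    """
    if min_mean_quality < 0 or min_length < 0:
        raise ValueError("thresholds must be non-negative")
    if min_length > max_length:
        raise ValueError("min_length must not exceed max_length")
    kept: list[ReadRecord] = []
    n_dropped = 0
    for read in reads:
        n = len(read.sequence)
        if min_length <= n <= max_length and read.mean_quality() >= min_mean_quality:
            kept.append(read)
        else:
            n_dropped += 1
    return kept, n_dropped


# ---------------------------------------------------------------------------
# Structure location


def _find_adapter(sequence: str, chem: ChemistryProfile) -> Optional[tuple[int, int, int]]:
    """Best adapter hit in the search window: (distance, start, end) or None.

    Semi-global alignment (free ends on the read) so adapter indels do not
    shift the reported span.  Ties on distance resolve to the most 5' start.
    """
    window = sequence[: chem.search_window]
    if len(window) < len(chem.adapter) - chem.max_adapter_edit_distance:
        return None
    aln = edlib.align(
        chem.adapter, window, mode="HW", task="locations", k=chem.max_adapter_edit_distance
    )
    if aln["editDistance"] < 0 or not aln["locations"]:
        return None
    start, end = min(aln["locations"], key=lambda loc: loc[0])
    return aln["editDistance"], start, end + 1  # edlib ends are inclusive


def _polyt_end(sequence: str, start: int, min_run: int) -> Optional[int]:
    """End of a poly-T run beginning at ``start``, or None if below ``min_run``.

    Tolerates roughly one non-T per 10 bases (minimum budget 1) and trims
    trailing non-T bases so the reported end sits on a T.
    """
    non_t = 0
    end = start
    i = start
    while i < len(sequence):
        if sequence[i] != "T":
            non_t += 1
        if non_t > max(1, (i - start + 1) // 10):
            break
        if sequence[i] == "T":
            end = i + 1
        i += 1
    return end if end - start >= min_run else None


def _locate_forward(read: ReadRecord, chem: ChemistryProfile, strand: str) -> Optional[StructureHit]:
    found = _find_adapter(read.sequence, chem)
    if found is None:
        return None
    distance, _, adapter_end = found
    bc_end = adapter_end + chem.barcode_length
    umi_end = bc_end + chem.umi_length
    if umi_end > len(read.sequence):
        return None
    return StructureHit(
        strand=strand,
        adapter_end=adapter_end,
        bc_span=(adapter_end, bc_end),
        umi_span=(bc_end, umi_end),
        polyt_end=_polyt_end(read.sequence, umi_end, chem.polyt_min_run),
        adapter_distance=distance,
    )


def locate_structure(read: ReadRecord, chem: ChemistryProfile) -> Optional[StructureHit]:
    """Find the adapter+barcode+UMI layout on either strand of a read.

    Both the read and its reverse complement are searched; the lower
    adapter edit distance wins, with the forward strand preferred on ties.
    Poly-T absence does not reject the hit, it is simply not recorded.
    """
    fwd = _locate_forward(read, chem, "+")
    rev = _locate_forward(read.reverse_complement(), chem, "-")
    if fwd is None:
        return rev
    if rev is None:
        return fwd
    return fwd if fwd.adapter_distance <= rev.adapter_distance else rev


def extract_read(
    read: ReadRecord, hit: StructureHit, chem: ChemistryProfile
) -> tuple[ReadRecord, PutativeBarcodeRecord]:
    """Split a structured read into its barcode-free cDNA part and barcode record.

    The trimmed read drops everything through the UMI (and through the
    poly-T tail when one was found); qualities are trimmed in lockstep.
    """
    oriented = read if hit.strand == "+" else read.reverse_complement()
    trim_at = hit.polyt_end if hit.polyt_end is not None else hit.umi_span[1]
    if not (0 <= hit.bc_span[0] < hit.bc_span[1] <= len(oriented.sequence)) or trim_at > len(
        oriented.sequence
    ):
        raise ValueError(f"read {read.read_id!r}: structure spans out of bounds")
    bc_lo, bc_hi = hit.bc_span
    umi_lo, umi_hi = hit.umi_span
    record = PutativeBarcodeRecord(
        read_id=read.read_id,
        barcode=oriented.sequence[bc_lo:bc_hi],
        barcode_quals=oriented.qualities[bc_lo:bc_hi],
        umi=oriented.sequence[umi_lo:umi_hi],
        umi_quals=oriented.qualities[umi_lo:umi_hi],
        strand=hit.strand,
    )
    trimmed = ReadRecord(
        read_id=read.read_id,
        sequence=oriented.sequence[trim_at:],
        qualities=oriented.qualities[trim_at:],
        description=read.description,
    )
    return trimmed, record


# ---------------------------------------------------------------------------
# Batch extraction

TABLE_COLUMNS = ["read_id", "barcode", "barcode_quals", "umi", "umi_quals", "strand"]


def write_barcode_table(records: Iterable[PutativeBarcodeRecord], path: str | Path) -> int:
    n = 0
    with _open_text(path, "wt") as out:
        writer = csv.writer(out)
        writer.writerow(TABLE_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.read_id,
                    r.barcode,
                    quals_to_string(r.barcode_quals),
                    r.umi,
                    quals_to_string(r.umi_quals),
                    r.strand,
                ]
            )
            n += 1
    return n


def read_barcode_table(path: str | Path) -> Iterator[PutativeBarcodeRecord]:
    with _open_text(path) as handle:
        reader = csv.DictReader(handle)
        missing = [c for c in TABLE_COLUMNS if c not in (reader.fieldnames or [])]
        if missing:
            raise ValueError(f"barcode table {path}: missing columns {missing}")
        for row in reader:
            yield PutativeBarcodeRecord(
                read_id=row["read_id"],
                barcode=row["barcode"],
                barcode_quals=string_to_quals(row["barcode_quals"]),
                umi=row["umi"],
                umi_quals=string_to_quals(row["umi_quals"]),
                strand=row["strand"],
            )


def _load_putative_table(path: str | Path) -> dict[str, str]:
    """Upstream putative-barcode CSV: read_id, putative_bc[, putative_bc_min_q, ...]."""
    with _open_text(path) as handle:
        reader = csv.DictReader(handle)
        fields = reader.fieldnames or []
        if "read_id" not in fields or "putative_bc" not in fields:
            raise ValueError(
                f"putative table {path}: requires header columns read_id and putative_bc"
            )
        return {row["read_id"]: row["putative_bc"] for row in reader}


def extract_batch(
    fastq_in: str | Path,
    chem: ChemistryProfile,
    fastq_out: str | Path,
    table_out: str | Path,
    putative_table: Optional[str | Path] = None,
    strict: bool = False,
    min_mean_quality: float = 0.0,
    min_length: int = 0,
    max_length: int = 10**9,
) -> dict[str, int]:
    """Run filtering + structure extraction over a FASTQ file.

    Writes a barcode-free FASTQ and a barcode/UMI/quality CSV.  When a
    putative-barcode table is supplied, extracted barcodes differing from
    the table's call by edit distance > 1 are counted as discordant.
    Returns counters: n_input, n_filtered, n_structured, n_unstructured,
    n_with_polyt, n_discordant.
    """
    putative = _load_putative_table(putative_table) if putative_table else None
    stats = {
        "n_input": 0,
        "n_filtered": 0,
        "n_structured": 0,
        "n_unstructured": 0,
        "n_with_polyt": 0,
        "n_discordant": 0,
    }
    missing_ids: list[str] = []
    trimmed_reads: list[ReadRecord] = []
    barcode_records: list[PutativeBarcodeRecord] = []
    for read in read_fastq(fastq_in):
        stats["n_input"] += 1
        kept, dropped = filter_reads([read], min_mean_quality, min_length, max_length)
        if dropped:
            stats["n_filtered"] += 1
            continue
        hit = locate_structure(read, chem)
        if hit is None:
            stats["n_unstructured"] += 1
            continue
        trimmed, record = extract_read(read, hit, chem)
        if not trimmed.sequence:
            stats["n_unstructured"] += 1
            continue
        stats["n_structured"] += 1
        if hit.polyt_end is not None:
            stats["n_with_polyt"] += 1
        if putative is not None:
            if read.read_id not in putative:
                missing_ids.append(read.read_id)
            else:
                d = edlib.align(record.barcode, putative[read.read_id], mode="NW")["editDistance"]
                if d > 1:
                    stats["n_discordant"] += 1
        trimmed_reads.append(trimmed)
        barcode_records.append(record)
    if strict and missing_ids:
        raise ValueError(
            f"{len(missing_ids)} structured reads absent from putative table: "
            + ", ".join(missing_ids[:10])
        )
    write_fastq(trimmed_reads, fastq_out)
    write_barcode_table(barcode_records, table_out)
    return stats
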