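"""Stage-by-stage read tracking and per-cell summary metrics.

The tracking store records how many reads survive each pipeline stage per
sample; its CSV gives the read-count funnel at a glance.  Cell metrics
summarise a count matrix the way tertiary tools report them: number of
cells, mean reads per cell, and lower-median nCount/nFeature.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pysam

from .extraction import _open_text
from .quantify import CountMatrix
from .tagging import _open_alignment

STAGES = (
    "raw",
    "trimmed",
    "structured",
    "aligned",
    "primary_mapped",
    "cb_tagged",
    "deduplicated",
)

#: the tail of the funnel must be non-increasing: every tagged read was
#: structured, every surviving molecule came from a tagged read.
FUNNEL_STAGES = ("structured", "cb_tagged", "deduplicated")


@dataclass
class CellMetrics:
    n_cells: int
    mean_reads_per_cell: float
    median_ncount: float
    median_nfeature: float


class TrackingStore:
    """Upsert store of (sample, stage) -> read count."""

    def __init__(self) -> None:
        self._counts: dict[tuple[str, str], int] = {}

    def record_stage(self, sample: str, stage: str, n: int) -> "TrackingStore":
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES}")
        if n < 0:
            raise ValueError(f"read count must be non-negative, got {n}")
        self._counts[(sample, stage)] = n
        return self

    def get(self, sample: str, stage: str) -> Optional[int]:
        return self._counts.get((sample, stage))

    def samples(self) -> list[str]:
        return sorted({s for s, _ in self._counts})

    def __len__(self) -> int:
        return len(self._counts)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, TrackingStore) and self._counts == other._counts

    def check_funnel(self, sample: str) -> bool:
        """True when structured >= cb_tagged >= deduplicated for the sample."""
        values = [self.get(sample, stage) for stage in FUNNEL_STAGES]
        present = [v for v in values if v is not None]
        return all(a >= b for a, b in zip(present, present[1:]))


def emit_tracking_csv(store: TrackingStore, path: str | Path) -> Path:
    """One row per sample, one column per stage; missing stages stay blank."""
    path = Path(path)
    with _open_text(path, "wt") as out:
        writer = csv.writer(out)
        writer.writerow(["sample", *STAGES])
        for sample in store.samples():
            row = [sample]
            for stage in STAGES:
                n = store.get(sample, stage)
                row.append("" if n is None else str(n))
            writer.writerow(row)
    return path


def read_tracking_csv(path: str | Path) -> TrackingStore:
    store = TrackingStore()
    with _open_text(path) as handle:
        for row in csv.DictReader(handle):
            for stage in STAGES:
                if row.get(stage, "") != "":
                    store.record_stage(row["sample"], stage, int(row[stage]))
    return store


def _lower_median(values: np.ndarray) -> float:
    """Median that returns an element of the sample for even sizes (determinism)."""
    ordered = np.sort(values)
    return float(ordered[(len(ordered) - 1) // 2])


def cell_metrics(matrix: CountMatrix) -> CellMetrics:
    """Per-cell summary over barcodes with nonzero mass.

    An empty matrix yields ``n_cells=0`` with NaN medians.
    """
    if not matrix.barcodes:
        return CellMetrics(0, 0.0, math.nan, math.nan)
    ncount = np.asarray(matrix.counts.sum(axis=0)).ravel()
    nfeature = np.asarray((matrix.counts > 0).sum(axis=0)).ravel()
    nonzero = ncount > 0
    n_cells = int(nonzero.sum())
    if n_cells == 0:
        return CellMetrics(0, 0.0, math.nan, math.nan)
    return CellMetrics(
        n_cells=n_cells,
        mean_reads_per_cell=float(ncount[nonzero].sum() / n_cells),
        median_ncount=_lower_median(ncount[nonzero]),
        median_nfeature=_lower_median(nfeature[nonzero]),
    )


def mapping_summary(bam: str | Path) -> dict[str, int]:
    """Flag-level counts: total records, primaries, mapped, CB-tagged."""
    stats = {"n_records": 0, "n_primary": 0, "n_mapped": 0, "n_cb_tagged": 0}
    with _open_alignment(bam) as src:
        for rec in src.fetch(until_eof=True):
            stats["n_records"] += 1
            if not (rec.is_secondary or rec.is_supplementary):
                stats["n_primary"] += 1
            if not rec.is_unmapped:
                stats["n_mapped"] += 1
            if rec.has_tag("CB"):
                stats["n_cb_tagged"] += 1
    return stats
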