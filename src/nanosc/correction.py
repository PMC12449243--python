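"""Whitelist construction and Bayesian barcode correction.

Putative barcodes are noisy observations of a small set of true cell
barcodes.  Correction proceeds in two stages:

1. rank high-quality putative barcodes by abundance and call the whitelist
   (either from an expected cell count or from the knee of the rank ×
   abundance curve);
2. for each observed barcode, score every whitelist candidate within
   Hamming distance ``max_hamming`` with a quality-aware likelihood and an
   abundance prior, and accept the best candidate when its posterior
   clears ``posterior_threshold``.

The likelihood of candidate ``c`` given the observed barcode and its
per-base Phred qualities is ``prod_i [ p_i/3  if mismatch at i else 1-p_i ]``
with ``p_i = 10^(-Q_i/10)``; the prior is proportional to the candidate's
whitelist count plus a pseudocount, and posteriors are normalised over the
candidate set.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from itertools import combinations, product
from math import ceil, inf, log
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from .extraction import (
    PutativeBarcodeRecord,
    TABLE_COLUMNS,
    _open_text,
    string_to_quals,
)

_BASES = "ACGT"

#: error probabilities are clipped to keep match/mismatch likelihoods finite;
#: a Q0 base (e.g. an N) becomes maximally uninformative rather than fatal.
_MAX_ERROR_PROB = 0.75
_MIN_ERROR_PROB = 1e-10


@dataclass(frozen=True)
class WhitelistEntry:
    barcode: str
    count: int
    rank: int


@dataclass(frozen=True)
class CorrectionParams:
    """Thresholds governing barcode correction.

    ``max_hamming=2`` and ``posterior_threshold=0.975`` are the defaults
    for noisy long reads; ``min_whitelist_quality`` gates which putative
    barcodes contribute abundance counts.
    """

    max_hamming: int = 2
    posterior_threshold: float = 0.975
    prior_pseudocount: float = 1.0
    min_whitelist_quality: int = 15

    def __post_init__(self) -> None:
        if not (0 < self.posterior_threshold <= 1):
            raise ValueError("posterior_threshold must be in (0, 1]")
        if self.max_hamming < 0:
            raise ValueError("max_hamming must be >= 0")


@dataclass(frozen=True)
class CorrectionResult:
    raw_barcode: str
    corrected_barcode: Optional[str]
    posterior: Optional[float]
    n_candidates: int
    status: str  # exact | corrected | ambiguous | no_candidate


def hamming_distance(a: str, b: str) -> int:
    """Number of substituted positions between two equal-length strings."""
    if len(a) != len(b):
        raise ValueError(f"hamming_distance requires equal lengths ({len(a)} vs {len(b)})")
    return sum(x != y for x, y in zip(a, b))


# ---------------------------------------------------------------------------
# Whitelist


def rank_barcodes(
    records: Iterable[PutativeBarcodeRecord], min_quality: int = 15
) -> list[WhitelistEntry]:
    """Abundance-rank barcodes whose minimum base quality passes the gate.

    Deterministic order: count descending, then barcode ascending.
    """
    counts: dict[str, int] = {}
    for rec in records:
        if rec.barcode_quals and min(rec.barcode_quals) >= min_quality:
            counts[rec.barcode] = counts.get(rec.barcode, 0) + 1
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [WhitelistEntry(bc, n, rank) for rank, (bc, n) in enumerate(ordered, start=1)]


def _knee_index(counts: np.ndarray) -> int:
    """Index (0-based) of the knee on the log-rank/log-count curve.

    The knee — the point of maximum curvature on the rank/abundance curve —
    is located with the chord-distance criterion: the point furthest above
    the straight line joining the curve's endpoints in log-log space.  On
    the near-vertical cliffs real barcode curves show, this is a far more
    stable estimate of the curvature maximum than discrete second
    differences.
    """
    ranks = np.arange(1, len(counts) + 1, dtype=float)
    x = np.log10(ranks)
    y = np.log10(np.maximum(counts.astype(float), 1.0))
    dx, dy = x[-1] - x[0], y[-1] - y[0]
    chord = y[0] + dy * (x - x[0]) / (dx if dx else 1.0)
    deviation = y - chord
    # the deviation plateaus across the cell population and collapses at the
    # ambient cliff; take the last point still on the plateau (within 0.1
    # log10 units of the maximum) so sampling wobble in per-cell depth does
    # not truncate the whitelist.
    plateau = np.flatnonzero(deviation > deviation.max() - 0.1)
    return int(plateau[-1])


def build_whitelist(
    ranked: Sequence[WhitelistEntry], expected_cells: Optional[int] = None
) -> list[WhitelistEntry]:
    """Call cell barcodes from the abundance ranking.

    With ``expected_cells`` the count threshold is the abundance at rank
    ``ceil(0.05 * expected_cells)`` divided by 20, and entries strictly
    above it are kept.  Without it, the knee (maximum curvature on the
    log-log rank/abundance curve) separates cells from background; the
    knee search assumes an ambient-barcode background is present — on a
    curve with no spread all entries are returned.
    """
    if not ranked:
        return []
    if expected_cells is not None:
        if expected_cells > len(ranked):
            raise ValueError(
                f"expected_cells={expected_cells} exceeds {len(ranked)} ranked barcodes"
            )
        anchor = max(1, ceil(0.05 * expected_cells))
        threshold = ranked[anchor - 1].count / 20.0
        return [e for e in ranked if e.count > threshold]
    counts = np.array([e.count for e in ranked])
    if counts.min() == counts.max() or len(ranked) < 3:
        return list(ranked)
    knee = _knee_index(counts)
    return list(ranked[: knee + 1])


def load_whitelist(path: str | Path) -> list[WhitelistEntry]:
    """Plain-text whitelist: one barcode per line, optional tab-separated count."""
    entries: list[tuple[str, int]] = []
    with _open_text(path) as handle:
        for line in handle:
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            entries.append((parts[0], int(parts[1]) if len(parts) > 1 else 1))
    ordered = sorted(entries, key=lambda kv: (-kv[1], kv[0]))
    return [WhitelistEntry(bc, n, rank) for rank, (bc, n) in enumerate(ordered, start=1)]


def save_whitelist(whitelist: Sequence[WhitelistEntry], path: str | Path) -> None:
    with _open_text(path, "wt") as out:
        for e in whitelist:
            out.write(f"{e.barcode}\t{e.count}\n")


# ---------------------------------------------------------------------------
# Candidate search


def hamming_ball_size(length: int, d: int) -> int:
    """Number of distinct sequences within Hamming distance ``d`` of a k-mer."""
    from math import comb

    return sum(comb(length, k) * 3**k for k in range(d + 1))


def _neighbors_within(query: str, d: int) -> Iterable[str]:
    """All sequences within Hamming distance d of query (including itself)."""
    yield query
    n = len(query)
    for k in range(1, d + 1):
        for positions in combinations(range(n), k):
            for subs in product(_BASES, repeat=k):
                if any(query[p] == s for p, s in zip(positions, subs)):
                    continue
                seq = list(query)
                for p, s in zip(positions, subs):
                    seq[p] = s
                yield "".join(seq)


def candidates_within(
    query: str, whitelist: Sequence[WhitelistEntry], d: int
) -> list[WhitelistEntry]:
    """Whitelist entries within Hamming distance ``d`` of ``query``.

    For large whitelists the Hamming ball around the query is enumerated
    against a hash index; small whitelists are scanned directly.  Both
    routes return entries in whitelist order.
    """
    if whitelist and any(len(e.barcode) != len(query) for e in whitelist):
        raise ValueError("whitelist barcodes must match the query length")
    if len(whitelist) <= 4 * hamming_ball_size(len(query), d):
        return [e for e in whitelist if hamming_distance(query, e.barcode) <= d]
    index = {e.barcode: e for e in whitelist}
    hits = {e.rank: e for seq in _neighbors_within(query, d) if (e := index.get(seq))}
    return [hits[r] for r in sorted(hits)]


# ---------------------------------------------------------------------------
# Posterior scoring


def barcode_posterior(
    observed: str,
    quals: Sequence[int],
    candidates: Sequence[WhitelistEntry],
    params: CorrectionParams = CorrectionParams(),
) -> list[float]:
    """Posterior probability of each candidate being the true barcode.

    Returns one probability per candidate (same order); empty candidates
    give an empty list.  Posteriors are normalised over the candidate set.
    """
    if not candidates:
        return []
    p = np.clip(10.0 ** (-np.asarray(quals, dtype=float) / 10.0), _MIN_ERROR_PROB, _MAX_ERROR_PROB)
    log_match = np.log1p(-p)
    log_mismatch = np.log(p / 3.0)
    scores = []
    for cand in candidates:
        mismatch = np.fromiter(
            (o != c for o, c in zip(observed, cand.barcode)), dtype=bool, count=len(observed)
        )
        loglik = float(np.where(mismatch, log_mismatch, log_match).sum())
        prior = cand.count + params.prior_pseudocount
        scores.append((log(prior) if prior > 0 else -inf) + loglik)
    scores_arr = np.array(scores)
    scores_arr -= scores_arr.max()
    weights = np.exp(scores_arr)
    return list(weights / weights.sum())


def correct_barcode(
    observed: str,
    quals: Sequence[int],
    whitelist: Sequence[WhitelistEntry],
    params: CorrectionParams = CorrectionParams(),
) -> CorrectionResult:
    """Correct one observed barcode against the whitelist.

    Status is ``exact`` when the observed barcode is itself on the
    whitelist and clears the posterior threshold, ``corrected`` when the
    best other candidate does, ``ambiguous`` when candidates exist but
    none clears it, and ``no_candidate`` otherwise.  Posterior ties break
    to the lexicographically smaller barcode.
    """
    candidates = candidates_within(observed, whitelist, params.max_hamming)
    if not candidates:
        return CorrectionResult(observed, None, None, 0, "no_candidate")
    posteriors = barcode_posterior(observed, quals, candidates, params)
    by_barcode = {c.barcode: p for c, p in zip(candidates, posteriors)}
    if observed in by_barcode and by_barcode[observed] >= params.posterior_threshold:
        return CorrectionResult(observed, observed, by_barcode[observed], len(candidates), "exact")
    best_barcode, best_posterior = min(by_barcode.items(), key=lambda kv: (-kv[1], kv[0]))
    if best_posterior >= params.posterior_threshold:
        return CorrectionResult(
            observed, best_barcode, best_posterior, len(candidates), "corrected"
        )
    return CorrectionResult(observed, None, best_posterior, len(candidates), "ambiguous")


def correct_table(
    table_in: str | Path,
    whitelist: Sequence[WhitelistEntry] | str | Path,
    table_out: str | Path,
    params: CorrectionParams = CorrectionParams(),
) -> dict[str, int]:
    """Correct every row of an extraction table; returns per-status counts.

    The output CSV carries the input columns plus ``corrected_barcode``
    (empty when uncorrected), ``posterior`` and ``status``.
    """
    if isinstance(whitelist, (str, Path)):
        whitelist = load_whitelist(whitelist)
    stats = {"exact": 0, "corrected": 0, "ambiguous": 0, "no_candidate": 0}
    out_columns = TABLE_COLUMNS + ["corrected_barcode", "posterior", "status"]
    with _open_text(table_in) as handle, _open_text(table_out, "wt") as out:
        reader = csv.DictReader(handle)
        missing = [c for c in TABLE_COLUMNS if c not in (reader.fieldnames or [])]
        if missing:
            raise ValueError(f"extraction table {table_in}: missing columns {missing}")
        writer = csv.DictWriter(out, fieldnames=out_columns, extrasaction="ignore")
        writer.writeheader()
        for row in reader:
            result = correct_barcode(
                row["barcode"], string_to_quals(row["barcode_quals"]), whitelist, params
            )
            stats[result.status] += 1
            row["corrected_barcode"] = result.corrected_barcode or ""
            row["posterior"] = "" if result.posterior is None else f"{result.posterior:.6g}"
            row["status"] = result.status
            writer.writerow(row)
    return stats
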