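"""Whitelist construction and posterior barcode correction."""

import csv
import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nanosc.correction import (
    CorrectionParams,
    WhitelistEntry,
    barcode_posterior,
    build_whitelist,
    candidates_within,
    correct_barcode,
    correct_table,
    hamming_ball_size,
    hamming_distance,
    rank_barcodes,
)
from nanosc.extraction import PutativeBarcodeRecord


def wl(*pairs):
    return [WhitelistEntry(bc, n, i + 1) for i, (bc, n) in enumerate(pairs)]


def record(barcode, qual=30, read_id="r"):
    return PutativeBarcodeRecord(
        read_id, barcode, [qual] * len(barcode), "A" * 12, [30] * 12, "+"
    )


class TestHamming:
    @pytest.mark.parametrize(
        "a,b,d", [("ACGT", "ACGT", 0), ("ACGT", "ACGA", 1), ("AAAA", "TTTT", 4)]
    )
    def test_known_distances(self, a, b, d):
        assert hamming_distance(a, b) == d

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            hamming_distance("ACG", "ACGT")


class TestRankBarcodes:
    def test_abundance_ranking(self):
        records = [record("A" * 16)] * 5 + [record("C" * 16)] * 3
        ranked = rank_barcodes(records, min_quality=15)
        assert [(e.barcode, e.count, e.rank) for e in ranked] == [
            ("A" * 16, 5, 1),
            ("C" * 16, 3, 2),
        ]

    def test_tie_breaks_lexicographically(self):
        records = [record("T" * 16)] * 2 + [record("A" * 16)] * 2
        ranked = rank_barcodes(records, min_quality=15)
        assert ranked[0].barcode == "A" * 16

    def test_quality_gate(self):
        assert rank_barcodes([record("A" * 16, qual=10)] * 4, min_quality=15) == []


class TestBuildWhitelist:
    def test_expected_cells_rule(self):
        ranked = wl(*[(f"BC{i}", c) for i, c in enumerate([100, 90, 80, 5, 4, 3])])
        kept = build_whitelist(ranked, expected_cells=3)
        # anchor rank ceil(0.05*3)=1 -> threshold 100/20=5 -> counts > 5
        assert [e.count for e in kept] == [100, 90, 80]

    def test_single_barcode(self):
        assert len(build_whitelist(wl(("A" * 16, 7)), expected_cells=1)) == 1

    def test_expected_cells_exceeding_ranked_errors(self):
        with pytest.raises(ValueError):
            build_whitelist(wl(("A" * 16, 7)), expected_cells=2)

    def test_knee_recovers_simulated_cells(self, sim_noisy, run_noisy):
        _, sim, _ = sim_noisy
        _, result = run_noisy
        called = {e.barcode for e in result.whitelist}
        assert len(called & set(sim.whitelist)) / len(sim.whitelist) >= 0.95


class TestCandidatesWithin:
    def test_hand_case(self):
        entries = wl(("AAAA", 3), ("AAAT", 2), ("GGGG", 1))
        hits = candidates_within("AAAC", entries, 1)
        assert {e.barcode for e in hits} == {"AAAA", "AAAT"}

    def test_d0_is_exact_lookup(self):
        entries = wl(("AAAA", 3), ("AAAT", 2))
        assert [e.barcode for e in candidates_within("AAAT", entries, 0)] == ["AAAT"]

    def test_neighborhood_size_16mer(self):
        # 1 + 3*16 + 9*C(16,2) distinct sequences within Hamming 2
        assert hamming_ball_size(16, 2) == 1129

    def test_matches_linear_scan_oracle(self):
        rng = random.Random(123)
        bases = "ACGT"
        for _ in range(200):
            n = rng.randint(1, 400)
            entries = wl(
                *{("".join(rng.choice(bases) for _ in range(8)), rng.randint(1, 9)) for _ in range(n)}
            )
            query = "".join(rng.choice(bases) for _ in range(8))
            d = rng.randint(0, 2)
            expected = {e.barcode for e in entries if hamming_distance(query, e.barcode) <= d}
            assert {e.barcode for e in candidates_within(query, entries, d)} == expected


class TestPosterior:
    def test_single_candidate_is_certain(self):
        post = barcode_posterior("AAAA", [30] * 4, wl(("AAAT", 5)))
        assert post == [pytest.approx(1.0)]

    def test_symmetric_case_splits_evenly(self):
        entries = wl(("AAAA", 1), ("AAAT", 1))
        post = barcode_posterior("AAAG", [10] * 4, entries)
        assert post == [pytest.approx(0.5), pytest.approx(0.5)]

    def test_prior_nine_to_one(self):
        entries = wl(("AAAA", 9), ("AAAT", 1))
        params = CorrectionParams(prior_pseudocount=0.0)
        post = barcode_posterior("AAAG", [10] * 4, entries, params)
        assert post == [pytest.approx(0.9), pytest.approx(0.1)]

    @settings(deadline=None, max_examples=50)
    @given(
        st.lists(
            st.tuples(st.text(alphabet="ACGT", min_size=6, max_size=6), st.integers(1, 50)),
            min_size=1,
            max_size=8,
            unique_by=lambda t: t[0],
        ),
        st.integers(0, 2**31 - 1),
    )
    def test_posteriors_normalise(self, entries, seed):
        rng = np.random.default_rng(seed)
        observed = "".join(rng.choice(list("ACGT"), 6))
        quals = [int(q) for q in rng.integers(2, 41, 6)]
        post = barcode_posterior(observed, quals, wl(*entries))
        assert sum(post) == pytest.approx(1.0, abs=1e-9)


class TestCorrectBarcode:
    PARAMS = CorrectionParams()

    def test_exact_hit(self):
        result = correct_barcode("AAAA", [30] * 4, wl(("AAAA", 5)), self.PARAMS)
        assert result.status == "exact"
        assert result.corrected_barcode == "AAAA"
        assert result.posterior == pytest.approx(1.0)

    def test_symmetric_case_is_ambiguous(self):
        result = correct_barcode("AAAG", [10] * 4, wl(("AAAA", 1), ("AAAT", 1)), self.PARAMS)
        assert result.status == "ambiguous"
        assert result.corrected_barcode is None

    def test_far_from_whitelist_is_no_candidate(self):
        result = correct_barcode("TTTT", [30] * 4, wl(("AAAA", 5)), self.PARAMS)
        assert result.status == "no_candidate" and result.n_candidates == 0

    def test_single_mismatch_corrects(self):
        result = correct_barcode("AAAT", [30] * 4, wl(("AAAA", 50)), self.PARAMS)
        assert result.status == "corrected"
        assert result.corrected_barcode == "AAAA"

    def test_idempotent_on_whitelist_barcodes(self):
        entries = wl(("ACGTAC", 10), ("TTTTTT", 8), ("GGGCCC", 2))
        for e in entries:
            result = correct_barcode(e.barcode, [35] * 6, entries, self.PARAMS)
            assert result.status == "exact" and result.corrected_barcode == e.barcode

    def test_threshold_monotonicity(self):
        entries = wl(("AAAA", 20), ("AAAT", 5), ("CCCC", 3))
        observed = [("AAAG", [12] * 4), ("AAAA", [30] * 4), ("AATT", [8] * 4)]
        accepted = []
        for thr in (0.5, 0.9, 0.975, 0.999):
            params = CorrectionParams(posterior_threshold=thr)
            n = sum(
                correct_barcode(bc, q, entries, params).status in ("exact", "corrected")
                for bc, q in observed
            )
            accepted.append(n)
        assert accepted == sorted(accepted, reverse=True)


class TestCorrectTable:
    def test_zero_error_all_exact(self, run_clean):
        _, result = run_clean
        stats = result.correct_stats
        assert stats["corrected"] == stats["ambiguous"] == stats["no_candidate"] == 0
        assert stats["exact"] > 0

    def test_noisy_recovery_against_truth(self, sim_noisy, run_noisy):
        _, sim, _ = sim_noisy
        _, result = run_noisy
        called = {e.barcode for e in result.whitelist}
        truth = {r.read_id: r.cell_barcode for r in sim.truth}
        ok = total = 0
        with open(result.out_dir / "corrected.csv") as fh:
            for row in csv.DictReader(fh):
                if truth[row["read_id"]] in called:
                    total += 1
                    ok += row["corrected_barcode"] == truth[row["read_id"]]
        assert ok / total >= 0.95

    def test_empty_table(self, tmp_path):
        table = tmp_path / "empty.csv"
        table.write_text("read_id,barcode,barcode_quals,umi,umi_quals,strand\n")
        stats = correct_table(table, wl(("A" * 16, 5)), tmp_path / "out.csv")
        assert sum(stats.values()) == 0

    def test_schema_mismatch_names_columns(self, tmp_path):
        table = tmp_path / "bad.csv"
        table.write_text("read_id,barcode\nr1,AAAA\n")
        with pytest.raises(ValueError, match="umi"):
            correct_table(table, wl(("AAAA", 5)), tmp_path / "out.csv")
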