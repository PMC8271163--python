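"""Read pre-processing order and the seed-and-extend aligner.

The aligner is checked against an exhaustive scorer that enumerates every
start position and every interior gap placement with the same scoring.
"""

from __future__ import annotations

import numpy as np
import pytest

from crac_decay import preprocess_align as pa
from crac_decay.io_formats import SequencedRead


def read(seq: str, rid: str = "r") -> SequencedRead:
    return SequencedRead(rid, seq)


class TestCollapse:
    def test_keeps_first_representative_per_sequence(self):
        reads = [
            read("AAAA", "a"), read("CCCC", "b"), read("AAAA", "c"),
            read("GGGG", "d"), read("CCCC", "e"),
        ]
        unique, n_input = pa.collapse_duplicates(reads)
        assert n_input == 5
        assert [r.read_id for r in unique] == ["a", "b", "d"]

    def test_all_distinct_is_identity(self):
        reads = [read(s, s) for s in ("AA", "CC", "GG")]
        unique, _ = pa.collapse_duplicates(reads)
        assert unique == reads

    def test_retained_sequence_set_is_order_independent(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), 8)) for _ in range(50)]
        fwd = {r.sequence for r in pa.collapse_duplicates([read(s) for s in seqs])[0]}
        rev = {r.sequence for r in pa.collapse_duplicates([read(s) for s in seqs[::-1]])[0]}
        assert fwd == rev == set(seqs)


class TestBarcodes:
    def test_prefix_stripped_on_assignment(self):
        bins = pa.split_by_barcode([read("ACGTTTTT")], ["ACGT", "TGCA"])
        assert [r.sequence for r in bins["ACGT"]] == ["TTTT"]

    def test_unmatched_reads_are_kept_not_dropped(self):
        bins = pa.split_by_barcode([read("GGGGTTTT")], ["ACGT", "TGCA"])
        assert len(bins["unmatched"]) == 1
        assert bins["unmatched"][0].sequence == "GGGGTTTT"

    def test_counts_conserved_across_bins(self, rng):
        reads = [read("".join(rng.choice(list("ACGT"), 10))) for _ in range(100)]
        bins = pa.split_by_barcode(reads, ["ACGT", "TGCA"])
        assert sum(len(v) for v in bins.values()) == 100

    def test_unequal_barcode_lengths_rejected(self):
        with pytest.raises(ValueError, match="same length"):
            pa.split_by_barcode([], ["ACGT", "ACG"])


class TestAdapterTrim:
    ADAPTER = "TGGAATTCTCGGGTGCCAAGG"

    def test_full_adapter_removed(self):
        insert = "ACGTACGTACGTACGTACGT"
        kept, n_disc = pa.trim_adapter([read(insert + self.ADAPTER)], self.ADAPTER)
        assert n_disc == 0
        assert kept[0].sequence == insert

    def test_read_without_adapter_unchanged(self):
        kept, _ = pa.trim_adapter([read("ACGTACGTACGTACGTACGTAAAA")], self.ADAPTER)
        assert kept[0].sequence == "ACGTACGTACGTACGTACGTAAAA"

    def test_short_insert_discarded_and_counted(self):
        kept, n_disc = pa.trim_adapter(
            [read("ACGTACGTAC" + self.ADAPTER)], self.ADAPTER, min_len=18
        )
        assert kept == [] and n_disc == 1

    def test_partial_suffix_below_min_overlap_ignored(self):
        seq = "ACGTACGTACGTACGTACGT" + self.ADAPTER[:4]
        kept, _ = pa.trim_adapter([read(seq)], self.ADAPTER, min_overlap=5)
        assert kept[0].sequence == seq


class TestPreprocessReport:
    def test_stage_conservation(self, rng):
        barcodes = ["ACGT", "TGCA"]
        adapter = "TGGAATTCTCGGGTGCCAAGG"
        reads = []
        for i in range(200):
            barcode = barcodes[i % 2] if i % 5 else "GGGG"
            insert_len = int(rng.integers(5, 40))
            insert = "".join(rng.choice(list("ACGT"), insert_len))
            reads.append(read((barcode + insert + adapter)[:50], f"r{i}"))
        bins, report = pa.preprocess(reads, barcodes, adapter)
        assert report.n_input == 200
        assert (
            report.n_after_trim + report.min_len_filtered + report.n_unmatched
            == report.n_after_collapse
        )
        assert sum(report.n_barcode_matched.values()) == (
            report.n_after_collapse - report.n_unmatched
        )


# ---------------------------------------------------------------------------
# Aligner vs exhaustive oracle


def exhaustive_best_score(
    seq: str, transcripts: dict[str, str], max_mismatch: int = 1
) -> tuple[int | None, set[tuple[str, int, int | None]]]:
    """Enumerate every start and gap placement with the aligner's scoring.

    Returns (best score, set of (transcript, start, gap_pos) achieving it).
    """
    m = len(seq)
    best_score = None
    placements: set[tuple[str, int, int | None]] = set()
    for tid, ref in transcripts.items():
        for start in range(0, len(ref) - m + 1):
            mism = sum(a != b for a, b in zip(seq, ref[start : start + m]))
            if mism <= max_mismatch:
                score = m - pa.MISMATCH_PENALTY * mism
                if best_score is None or score > best_score:
                    best_score, placements = score, set()
                if score == best_score:
                    placements.add((tid, start, None))
        for start in range(0, len(ref) - m):
            seg = ref[start : start + m + 1]
            for g in range(1, m):
                mism = sum(a != b for a, b in zip(seq[:g], seg[:g]))
                mism += sum(a != b for a, b in zip(seq[g:], seg[g + 1 :]))
                if mism <= max_mismatch:
                    score = m - pa.MISMATCH_PENALTY * mism - pa.GAP_PENALTY
                    if best_score is None or score > best_score:
                        best_score, placements = score, set()
                    if score == best_score:
                        placements.add((tid, start, g))
    return best_score, placements


def realized_score(aln, transcripts: dict[str, str], seq: str) -> int:
    ref = transcripts[aln.transcript_id]
    pos, off, mism, gap = aln.start, 0, 0, 0
    for op, n in aln.cigar:
        if op == "M":
            mism += sum(
                a != b for a, b in zip(seq[off : off + n], ref[pos : pos + n])
            )
            off += n
            pos += n
        elif op == "D":
            gap += 1
            pos += n
    return len(seq) - pa.MISMATCH_PENALTY * mism - pa.GAP_PENALTY * gap


@pytest.fixture(scope="module")
def transcripts():
    gen = np.random.default_rng(77)
    return {f"tx{i}": "".join(gen.choice(list("ACGT"), 400)) for i in range(3)}


class TestAligner:
    def test_exact_substring(self, transcripts):
        seq = transcripts["tx1"][37:67]
        aln = pa.align_read(read(seq), pa.TranscriptomeIndex(transcripts))
        assert (aln.transcript_id, aln.start, aln.cigar) == ("tx1", 37, (("M", 30),))

    def test_single_deletion_read(self, transcripts):
        ref = transcripts["tx2"]
        seq = ref[50:65] + ref[66:80]  # position 65 deleted
        aln = pa.align_read(read(seq), pa.TranscriptomeIndex(transcripts))
        assert aln.transcript_id == "tx2"
        assert aln.start == 50
        # deletion placement may left-shift inside a homopolymer run
        expected_gap = 15
        while expected_gap > 1 and ref[50 + expected_gap - 1] == ref[65]:
            expected_gap -= 1
        assert aln.cigar == (
            ("M", expected_gap), ("D", 1), ("M", 29 - expected_gap),
        )

    def test_multimapper_assignment_reproducible(self, transcripts):
        dup = dict(transcripts)
        dup["txA"] = "AACC" * 30
        dup["txB"] = dup["txA"]
        reads = [read(dup["txA"][10:40], f"r{i}") for i in range(20)]
        out1, _ = pa.align_reads(reads, dup, seed=5)
        out2, _ = pa.align_reads(reads, dup, seed=5)
        assert out1 == out2
        assert {a.transcript_id for a in out1} <= {"txA", "txB"}

    def test_empty_index_rejected(self):
        with pytest.raises(pa.AlignmentIndexError):
            pa.TranscriptomeIndex({})

    @pytest.mark.parametrize("case_seed", range(8))
    def test_matches_exhaustive_oracle(self, transcripts, case_seed):
        """Seed-and-extend agrees with full enumeration on score and placement."""
        gen = np.random.default_rng(1000 + case_seed)
        tid = f"tx{int(gen.integers(3))}"
        ref = transcripts[tid]
        m = int(gen.integers(25, 41))
        start = int(gen.integers(0, len(ref) - m - 1))
        seq = list(ref[start : start + m + 1])
        if case_seed % 2:  # delete one interior base
            del seq[int(gen.integers(1, m))]
        else:
            seq = seq[:m]
        if case_seed % 3 == 0:  # one substitution
            i = int(gen.integers(1, len(seq) - 1))
            seq[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[i]]
        seq = "".join(seq)
        best, placements = exhaustive_best_score(seq, transcripts)
        aln = pa.align_read(read(seq), pa.TranscriptomeIndex(transcripts))
        assert best is not None
        assert aln is not None
        assert realized_score(aln, transcripts, seq) == best
        gap = None
        consumed = 0
        for op, n in aln.cigar:
            if op == "D":
                gap = consumed
                break
            consumed += n
        # leftmost representative of the best-scoring placements at this locus
        same_locus = {
            g for t, s, g in placements if t == aln.transcript_id and s == aln.start
        }
        assert gap in same_locus
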