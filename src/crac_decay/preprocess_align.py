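"""CRAC read pre-processing and a small-scale transcriptome aligner.

The pre-processing order mirrors the wet-lab pipeline: PCR-duplicate
collapse on the raw reads (before barcode removal), 5' in-line barcode
demultiplexing, then exact-suffix 3' adapter trimming with a minimum-length
filter. The aligner is a seed-and-extend mapper over an exact k-mer index
that scores alignments with up to ``max_mismatch`` substitutions and at
most one single-nucleotide deletion — the event class that marks a
crosslink site — with seeded random tie-breaking among equal-scoring loci.
"""

from __future__ import annotations

import zlib
from collections import defaultdict
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np

from .io_formats import ReadAlignment, SequencedRead

MATCH_SCORE = 1
MISMATCH_PENALTY = 3  # score = matches - penalty terms; mismatch net -2
GAP_PENALTY = 3


@dataclass
class PreprocessReport:
    n_input: int = 0
    n_after_collapse: int = 0
    n_barcode_matched: dict[str, int] = field(default_factory=dict)
    n_unmatched: int = 0
    n_after_trim: int = 0
    min_len_filtered: int = 0

    def to_rows(self) -> list[tuple[str, int]]:
        rows = [
            ("input", self.n_input),
            ("after_collapse", self.n_after_collapse),
        ]
        rows += [(f"barcode_{b}", n) for b, n in self.n_barcode_matched.items()]
        rows += [
            ("unmatched", self.n_unmatched),
            ("after_trim", self.n_after_trim),
            ("min_len_filtered", self.min_len_filtered),
        ]
        return rows


def collapse_duplicates(
    reads: Iterable[SequencedRead],
) -> tuple[list[SequencedRead], int]:
    """One representative per identical full-length sequence (first seen).

    Returns (unique reads, input count). Collapse runs on the raw reads,
    barcodes still attached.
    """
    seen: set[str] = set()
    unique: list[SequencedRead] = []
    n_input = 0
    for read in reads:
        n_input += 1
        if read.sequence in seen:
            continue
        seen.add(read.sequence)
        unique.append(read)
    return unique, n_input


def split_by_barcode(
    reads: Iterable[SequencedRead], barcode_set: Sequence[str]
) -> dict[str, list[SequencedRead]]:
    """Assign reads to the barcode matching their 5' prefix, stripping it.

    Non-matching reads land in the ``"unmatched"`` bin (barcode kept).
    """
    lengths = {len(b) for b in barcode_set}
    if len(lengths) != 1:
        raise ValueError("barcodes must all have the same length")
    if len(set(barcode_set)) != len(barcode_set):
        raise ValueError("barcodes must be mutually distinct")
    blen = lengths.pop()
    bins: dict[str, list[SequencedRead]] = {b: [] for b in barcode_set}
    bins["unmatched"] = []
    lookup = set(barcode_set)
    for read in reads:
        prefix = read.sequence[:blen]
        if prefix in lookup:
            quals = read.qualities[blen:] if read.qualities else None
            bins[prefix].append(
                SequencedRead(read.read_id, read.sequence[blen:], quals)
            )
        else:
            bins["unmatched"].append(read)
    return bins


def trim_adapter(
    reads: Iterable[SequencedRead],
    adapter: str,
    min_overlap: int = 5,
    min_len: int = 18,
) -> tuple[list[SequencedRead], int]:
    """Remove the longest read suffix exactly matching an adapter prefix.

    Matches shorter than ``min_overlap`` are ignored; reads shorter than
    ``min_len`` after trimming are discarded and counted. Returns
    (kept reads, number discarded).
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    kept: list[SequencedRead] = []
    n_discarded = 0
    for read in reads:
        seq = read.sequence
        cut = len(seq)
        max_ov = min(len(seq), len(adapter))
        for ov in range(max_ov, min_overlap - 1, -1):
            if seq[-ov:] == adapter[:ov]:
                cut = len(seq) - ov
                break
        trimmed = seq[:cut]
        if len(trimmed) < min_len:
            n_discarded += 1
            continue
        quals = read.qualities[:cut] if read.qualities else None
        kept.append(SequencedRead(read.read_id, trimmed, quals))
    return kept, n_discarded


def preprocess(
    reads: Sequence[SequencedRead],
    barcode_set: Sequence[str],
    adapter: str,
    min_overlap: int = 5,
    min_len: int = 18,
) -> tuple[dict[str, list[SequencedRead]], PreprocessReport]:
    """Collapse -> demultiplex -> trim, with a conservation-checked report."""
    report = PreprocessReport()
    unique, report.n_input = collapse_duplicates(reads)
    report.n_after_collapse = len(unique)
    bins = split_by_barcode(unique, barcode_set)
    report.n_unmatched = len(bins["unmatched"])
    trimmed_bins: dict[str, list[SequencedRead]] = {}
    for barcode in barcode_set:
        report.n_barcode_matched[barcode] = len(bins[barcode])
        kept, n_disc = trim_adapter(bins[barcode], adapter, min_overlap, min_len)
        report.min_len_filtered += n_disc
        trimmed_bins[barcode] = kept
    report.n_after_trim = sum(len(v) for v in trimmed_bins.values())
    assert (
        report.n_after_trim + report.min_len_filtered + report.n_unmatched
        == report.n_after_collapse
    )
    return trimmed_bins, report


# ---------------------------------------------------------------------------
# Alignment


class AlignmentIndexError(ValueError):
    pass


_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


class TranscriptomeIndex:
    """Exact k-mer index over transcript sequences (DNA alphabet)."""

    def __init__(self, sequences: Mapping[str, str], k: int = 12) -> None:
        if not sequences:
            raise AlignmentIndexError("empty transcriptome index")
        self.k = k
        self.sequences = dict(sequences)
        self.encoded = {t: _encode(s) for t, s in sequences.items()}
        self.kmers: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for tid, seq in sequences.items():
            for i in range(len(seq) - k + 1):
                self.kmers[seq[i : i + k]].append((tid, i))


@dataclass
class AlignmentCandidate:
    transcript_id: str
    start: int
    score: int
    mismatches: int
    gap_pos: int | None  # read offset after which the transcript base is deleted


def _evaluate_candidate(
    read: np.ndarray, ref: np.ndarray, start: int, max_mismatch: int
) -> AlignmentCandidate | None:
    """Best alignment of the read at a fixed start: ungapped or one 1-nt del.

    The deletion (if any) is placed leftmost among equally good interior
    placements — the standard left-alignment convention for homopolymers.
    """
    m = read.size
    best: AlignmentCandidate | None = None
    if start >= 0 and start + m <= ref.size:
        mism = int(np.count_nonzero(read != ref[start : start + m]))
        if mism <= max_mismatch:
            best = AlignmentCandidate(
                "", start, m - MISMATCH_PENALTY * mism, mism, None
            )
    if start >= 0 and start + m + 1 <= ref.size:
        seg = ref[start : start + m + 1]
        pre = np.concatenate(([0], np.cumsum(read != seg[:m])))
        suf_mismatch = read != seg[1:]
        suf = np.concatenate((np.cumsum(suf_mismatch[::-1])[::-1], [0]))
        totals = pre[1:m] + suf[1:m]  # gap after g read bases, g in 1..m-1
        if totals.size:
            g = int(np.argmin(totals)) + 1
            mism = int(totals[g - 1])
            if mism <= max_mismatch:
                score = m - MISMATCH_PENALTY * mism - GAP_PENALTY
                if best is None or score > best.score:
                    best = AlignmentCandidate("", start, score, mism, g)
    return best


def _cigar_for(m: int, gap_pos: int | None) -> tuple[tuple[str, int], ...]:
    if gap_pos is None:
        return (("M", m),)
    return (("M", gap_pos), ("D", 1), ("M", m - gap_pos))


def align_read(
    read: SequencedRead,
    index: TranscriptomeIndex,
    max_mismatch: int = 1,
    rng: np.random.Generator | None = None,
) -> ReadAlignment | None:
    """Seed-and-extend alignment of one read; None if no locus qualifies.

    Seeds are taken from the read start, middle and end so a single
    deletion or substitution cannot disrupt all of them; ties between
    equal-scoring loci are broken at random under the supplied generator
    for reproducible multi-mapper assignment.
    """
    k = index.k
    seq = read.sequence
    m = len(seq)
    if m < k:
        return None
    offsets = sorted({0, (m - k) // 2, m - k})
    candidates: set[tuple[str, int]] = set()
    for off in offsets:
        for tid, pos in index.kmers.get(seq[off : off + k], ()):
            candidates.add((tid, pos - off))
            candidates.add((tid, pos - off - 1))
    if not candidates:
        return None
    encoded = _encode(seq)
    best_score = None
    best: list[tuple[str, AlignmentCandidate]] = []
    for tid, start in sorted(candidates):
        cand = _evaluate_candidate(encoded, index.encoded[tid], start, max_mismatch)
        if cand is None:
            continue
        if best_score is None or cand.score > best_score:
            best_score = cand.score
            best = [(tid, cand)]
        elif cand.score == best_score:
            best.append((tid, cand))
    if not best:
        return None
    if len(best) > 1:
        pick = int(rng.integers(len(best))) if rng is not None else 0
    else:
        pick = 0
    tid, cand = best[pick]
    return ReadAlignment(
        read_id=read.read_id,
        transcript_id=tid,
        start=cand.start,
        cigar=_cigar_for(m, cand.gap_pos),
    )


def align_reads(
    reads: Iterable[SequencedRead],
    sequences: Mapping[str, str],
    k: int = 12,
    max_mismatch: int = 1,
    seed: int = 0,
) -> tuple[list[ReadAlignment], int]:
    """Align a read set against a transcriptome; returns (alignments, n_unaligned).

    The tie-break generator is derived from ``seed`` only, so repeated runs
    on the same input give identical multi-mapper assignments.
    """
    index = TranscriptomeIndex(sequences, k=k)
    rng = np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(b"align")]))
    alignments: list[ReadAlignment] = []
    n_unaligned = 0
    for read in reads:
        aln = align_read(read, index, max_mismatch=max_mismatch, rng=rng)
        if aln is None:
            n_unaligned += 1
        else:
            alignments.append(aln)
    return alignments, n_unaligned
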