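"""Per-transcript coverage and crosslink-deletion profiles.

Coverage counts every position in a read's reference footprint (M and D
ops); the deletions vector counts only single-nucleotide deletions — the
crosslink signature — at the position of the deleted base. Multi-nucleotide
deletions remain in coverage but are excluded from crosslink evidence.
"""

from __future__ import annotations

from collections import Counter
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io_formats import Biotype, ReadAlignment, TranscriptModel


@dataclass
class CrosslinkProfile:
    transcript_id: str
    replicate_id: str
    coverage: np.ndarray  # int, length sequence_length
    deletions: np.ndarray  # int, length sequence_length
    reads: list[tuple[int, int]] = field(default_factory=list)  # (start, footprint)
    library_size: int = 0
    n_multi_deletion_reads: int = 0

    @property
    def read_count(self) -> int:
        return len(self.reads)


class ProfileError(ValueError):
    pass


def build_profiles(
    alignments: Iterable[ReadAlignment],
    models: Mapping[str, TranscriptModel],
    replicate_id: str,
) -> dict[str, CrosslinkProfile]:
    """Accumulate coverage/deletion vectors per transcript for one replicate.

    ``library_size`` (total mapped reads in the replicate) is stamped on
    every profile for rpm normalization downstream. Profile addition is
    linear: identical reads double coverage.
    """
    profiles: dict[str, CrosslinkProfile] = {}
    total = 0
    for aln in alignments:
        try:
            model = models[aln.transcript_id]
        except KeyError:
            raise ProfileError(f"unknown transcript {aln.transcript_id!r}") from None
        length = model.sequence_length
        if aln.end > length:
            raise ProfileError(
                f"{aln.read_id}: footprint [{aln.start},{aln.end}) exceeds "
                f"{aln.transcript_id} length {length}"
            )
        prof = profiles.get(aln.transcript_id)
        if prof is None:
            prof = CrosslinkProfile(
                transcript_id=aln.transcript_id,
                replicate_id=replicate_id,
                coverage=np.zeros(length, dtype=np.int64),
                deletions=np.zeros(length, dtype=np.int64),
            )
            profiles[aln.transcript_id] = prof
        prof.coverage[aln.start : aln.end] += 1
        prof.reads.append((aln.start, aln.footprint))
        dels = aln.deletion_positions()
        if any(n > 1 for _, n in dels):
            prof.n_multi_deletion_reads += 1
        for pos, n in dels:
            if n == 1:
                prof.deletions[pos] += 1
        total += 1
    for prof in profiles.values():
        prof.library_size = total
    return profiles


def class_distribution(
    alignments: Iterable[ReadAlignment],
    models: Mapping[str, TranscriptModel],
) -> dict[Biotype, float]:
    """Fraction of mapped reads per RNA class (each read counted once)."""
    counts: Counter = Counter()
    for aln in alignments:
        counts[models[aln.transcript_id].biotype] += 1
    total = sum(counts.values())
    if total == 0:
        return {}
    return {bt: n / total for bt, n in counts.items()}


def replicate_correlation(
    profiles_a: Mapping[str, CrosslinkProfile],
    profiles_b: Mapping[str, CrosslinkProfile],
    models: Mapping[str, TranscriptModel],
) -> tuple[float, int]:
    """Spearman rho between replicates on per-transcript read counts.

    Counts default to zero for transcripts without reads; ties are
    mid-ranked by the rank correlation itself. Returns (rho, n transcripts).
    """
    tids = list(models)
    a = np.array([profiles_a[t].read_count if t in profiles_a else 0 for t in tids])
    b = np.array([profiles_b[t].read_count if t in profiles_b else 0 for t in tids])
    if np.count_nonzero(a) < 3 or np.count_nonzero(b) < 3:
        raise ValueError("fewer than 3 transcripts with nonzero counts")
    rho = stats.spearmanr(a, b).statistic
    return float(rho), len(tids)
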