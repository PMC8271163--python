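"""Deletion-centered motif discovery for crosslink sites.

The crosslink position of a CRAC read is marked by a single-nucleotide
deletion; windows of transcript sequence centered on those deletions are the
substrate for enrichment analysis. Discovery follows a DREME-style scheme:
exact words are tested for presence/absence enrichment against
mononucleotide-shuffled windows with a one-sided Fisher test, then the best
words are greedily generalized position-by-position to two-letter IUPAC
codes, accepting a generalization only if it lowers the enrichment p-value.
Only the given strand is scanned, occurrence counting is presence/absence
per window, widths run 6-10 nt, and motifs are reported when
E = p x (candidates tested at that width) falls below threshold.
"""

from __future__ import annotations

import re
from collections import Counter
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

from .io_formats import ReadAlignment

# IUPAC degenerate nucleotide codes over the RNA alphabet.
IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "U": frozenset("U"),
    "R": frozenset("AG"),
    "Y": frozenset("CU"),
    "S": frozenset("CG"),
    "W": frozenset("AU"),
    "K": frozenset("GU"),
    "M": frozenset("AC"),
    "B": frozenset("CGU"),
    "D": frozenset("AGU"),
    "H": frozenset("ACU"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGU"),
}

TWO_LETTER_CODES = ("R", "Y", "S", "W", "K", "M")

_CODE_FOR_SET = {letters: code for code, letters in IUPAC.items()}


def _rna(sequence: str) -> str:
    return sequence.upper().replace("T", "U")


def consensus_regex(consensus: str) -> re.Pattern:
    parts = []
    for code in _rna(consensus):
        try:
            letters = IUPAC[code]
        except KeyError:
            raise ValueError(f"unknown IUPAC code {code!r}") from None
        parts.append("[" + "".join(sorted(letters)) + "]")
    return re.compile("".join(parts))


def match_consensus(sequence: str, consensus: str) -> list[int]:
    """All (possibly overlapping) match offsets of an IUPAC consensus.

    Both strings are interpreted in the RNA alphabet (T is read as U);
    only the given strand is scanned.
    """
    seq = _rna(sequence)
    pattern = consensus_regex(consensus)
    offsets = []
    pos = 0
    while True:
        m = pattern.search(seq, pos)
        if m is None:
            break
        offsets.append(m.start())
        pos = m.start() + 1
    return offsets


@dataclass
class MotifWindow:
    """Transcript sequence around one crosslink-induced deletion.

    The sequence is cut from the transcript (not the read) so the deleted,
    crosslinked base itself is present; ``center_offset`` is its index
    within the window and stays correct when the window is clipped at a
    transcript end.
    """

    read_id: str
    transcript_id: str
    center: int  # deletion position on the transcript, 0-based
    sequence: str  # RNA alphabet
    center_offset: int

    def __post_init__(self) -> None:
        if not 0 <= self.center_offset < len(self.sequence):
            raise ValueError("center_offset outside window")


@dataclass
class MotifResult:
    consensus: str
    width: int
    p_enrichment: float
    e_value: float
    site_count: int
    n_candidates_tested: int
    pwm: np.ndarray  # (width, 4) over A,C,G,U; columns sum to 1
    positional_p: Optional[float] = None

    def __post_init__(self) -> None:
        if self.e_value < self.p_enrichment:
            raise ValueError("e_value must be >= p_enrichment")


class MotifInputError(ValueError):
    pass


def extract_windows(
    alignments: Iterable[ReadAlignment],
    sequences: Mapping[str, str],
    top_transcripts: set[str],
    flank: int,
) -> list[MotifWindow]:
    """One window per deletion-bearing read on a top-ranked transcript.

    ``flank`` is 10 or 50 (window spans 21 or 101 nt around the deleted
    base). Reads without a single 1-nt deletion, or on transcripts outside
    the top set, contribute nothing.
    """
    if flank not in (10, 50):
        raise ValueError(f"flank must be 10 or 50, got {flank}")
    windows = []
    for aln in alignments:
        if aln.transcript_id not in top_transcripts:
            continue
        dels = [(pos, n) for pos, n in aln.deletion_positions() if n == 1]
        if len(dels) != 1:
            continue
        center = dels[0][0]
        seq = sequences[aln.transcript_id]
        lo = max(0, center - flank)
        hi = min(len(seq), center + flank + 1)
        windows.append(
            MotifWindow(
                read_id=aln.read_id,
                transcript_id=aln.transcript_id,
                center=center,
                sequence=_rna(seq[lo:hi]),
                center_offset=center - lo,
            )
        )
    return windows


def _presence_counts(seqs: Sequence[str], width: int) -> Counter:
    counts: Counter = Counter()
    for seq in seqs:
        seen = {seq[i : i + width] for i in range(len(seq) - width + 1)}
        counts.update(seen)
    return counts


def enrichment_pvalue(
    fg_with: int, n_fg: int, bg_with: int, n_bg: int
) -> float:
    """One-sided Fisher p for over-representation in the foreground.

    Computed as the hypergeometric survival probability of drawing at
    least ``fg_with`` motif-containing windows in ``n_fg`` draws from the
    pooled population — identical to ``fisher_exact(..., 'greater')`` on
    the presence/absence 2x2 table.
    """
    return float(
        stats.hypergeom.sf(fg_with - 1, n_fg + n_bg, fg_with + bg_with, n_fg)
    )


def enrichment_log_pvalue(
    fg_with: int, n_fg: int, bg_with: int, n_bg: int
) -> float:
    """Natural log of :func:`enrichment_pvalue`; immune to underflow.

    Used internally to rank and compare candidates whose p-values are far
    below double precision.
    """
    return float(
        stats.hypergeom.logsf(fg_with - 1, n_fg + n_bg, fg_with + bg_with, n_fg)
    )


def _count_present(seqs: Sequence[str], pattern: re.Pattern) -> int:
    return sum(1 for s in seqs if pattern.search(s) is not None)


def shuffle_windows(windows: Sequence[str], rng: np.random.Generator) -> list[str]:
    """Mononucleotide shuffle of each window (background set)."""
    out = []
    for seq in windows:
        chars = np.array(list(seq))
        rng.shuffle(chars)
        out.append("".join(chars))
    return out


def _generalize(
    consensus: str,
    fg: Sequence[str],
    bg: Sequence[str],
    p_current: float,
    max_sweeps: int = 3,
) -> tuple[str, float, int]:
    """Greedy per-position IUPAC generalization; accept only if p drops.

    ``p_current`` and the returned p are natural-log p-values; the third
    return value counts candidate generalizations evaluated, for the
    caller's multiple-testing accounting. Each position's acceptance must
    beat a Bonferroni margin over the codes tried there, so a
    generalization that wins only by selection among its siblings is
    rejected — this keeps the greedy search honest on unstructured input.
    """
    n_fg, n_bg = len(fg), len(bg)
    current = list(consensus)
    n_evaluated = 0
    for _ in range(max_sweeps):
        changed = False
        for i, base in enumerate(current):
            if base not in "ACGU":
                continue
            best_code, best_logp = None, p_current
            n_trials = 0
            for code in TWO_LETTER_CODES:
                if base not in IUPAC[code]:
                    continue
                trial = current.copy()
                trial[i] = code
                pattern = consensus_regex("".join(trial))
                a = _count_present(fg, pattern)
                c = _count_present(bg, pattern)
                logp = enrichment_log_pvalue(a, n_fg, c, n_bg)
                n_trials += 1
                n_evaluated += 1
                if logp < best_logp:
                    best_code, best_logp = code, logp
            if (
                best_code is not None
                and best_logp + np.log(max(n_trials, 1)) < p_current
            ):
                current[i] = best_code
                p_current = best_logp
                changed = True
        if not changed:
            break
    return "".join(current), p_current, n_evaluated


def build_pwm(windows: Sequence[str], consensus: str) -> np.ndarray:
    """Position-probability matrix from the first match in each window."""
    pattern = consensus_regex(consensus)
    width = len(consensus)
    counts = np.zeros((width, 4))
    order = {"A": 0, "C": 1, "G": 2, "U": 3}
    for seq in windows:
        m = pattern.search(seq)
        if m is None:
            continue
        for j, base in enumerate(seq[m.start() : m.start() + width]):
            counts[j, order[base]] += 1
    totals = counts.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1
    return counts / totals


def discover_motif(
    windows: Sequence[MotifWindow],
    width_range: tuple[int, int] = (6, 10),
    e_threshold: float = 0.05,
    min_word_count: int = 5,
    min_windows: int = 50,
    n_generalize_seeds: int = 8,
    seed: int = 0,
) -> list[MotifResult]:
    """DREME-style degenerate motif discovery on deletion-centered windows.

    Returns results (one best generalized motif per width) with
    E-value < ``e_threshold``, best first. Two independent mononucleotide
    shuffles of the windows are drawn under the run seed: candidates are
    selected and generalized against the first, but the reported
    enrichment p is recomputed against the second, so the greedy search
    cannot certify a motif with the same noise it optimized. The E-value
    Bonferroni-scales that p by everything examined at the winning width
    (exact words plus generalization trials).
    """
    if len(windows) < min_windows:
        raise MotifInputError(
            f"only {len(windows)} windows (< {min_windows}); increase flank "
            "or sequencing depth"
        )
    rng = np.random.default_rng(seed)
    fg = [w.sequence for w in windows]
    bg_select = shuffle_windows(fg, rng)
    bg_eval = shuffle_windows(fg, rng)
    n_fg, n_bg = len(fg), len(bg_select)
    results = []
    for width in range(width_range[0], width_range[1] + 1):
        fg_counts = _presence_counts(fg, width)
        bg_counts = _presence_counts(bg_select, width)
        words = [w for w, c in fg_counts.items() if c >= min_word_count]
        if not words:
            continue
        a = np.array([fg_counts[w] for w in words])
        c = np.array([bg_counts.get(w, 0) for w in words])
        log_pvals = stats.hypergeom.logsf(a - 1, n_fg + n_bg, a + c, n_fg)
        n_tested = len(words)
        order = np.argsort(log_pvals, kind="stable")
        best: Optional[tuple[str, float]] = None
        for idx in order[:n_generalize_seeds]:
            cons, logp, n_evals = _generalize(
                words[idx], fg, bg_select, float(log_pvals[idx])
            )
            n_tested += n_evals
            if best is None or logp < best[1]:
                best = (cons, logp)
        if best is None:
            continue
        consensus = best[0]
        pattern = consensus_regex(consensus)
        fg_with = _count_present(fg, pattern)
        p_best = float(
            np.exp(
                enrichment_log_pvalue(
                    fg_with, n_fg, _count_present(bg_eval, pattern), n_bg
                )
            )
        )
        e_value = p_best * n_tested
        if e_value < e_threshold:
            results.append(
                MotifResult(
                    consensus=consensus,
                    width=width,
                    p_enrichment=p_best,
                    e_value=e_value,
                    site_count=fg_with,
                    n_candidates_tested=n_tested,
                    pwm=build_pwm(fg, consensus),
                )
            )
    results.sort(key=lambda r: r.e_value)
    return results


@dataclass
class CentralEnrichment:
    positional_p: float
    n_matched_windows: int
    n_covering_center: int
    offset_histogram: dict[int, int] = field(default_factory=dict)


def central_enrichment(
    windows: Sequence[MotifWindow], consensus: str
) -> CentralEnrichment:
    """Test whether consensus matches concentrate at the deleted base.

    Per window the match nearest the center (preferring matches whose span
    covers it) is recorded; a one-sided binomial test compares the number
    of center-covering matches with the expectation under uniform
    placement of the match start over the valid offsets of that window.
    """
    width = len(consensus)
    pattern = consensus_regex(consensus)
    n_matched = 0
    n_cover = 0
    p0_sum = 0.0
    hist: Counter = Counter()
    for w in windows:
        offsets = []
        pos = 0
        while True:
            m = pattern.search(w.sequence, pos)
            if m is None:
                break
            offsets.append(m.start())
            pos = m.start() + 1
        if not offsets:
            continue
        n_matched += 1
        c = w.center_offset
        covering = [o for o in offsets if o <= c <= o + width - 1]
        chosen = (
            min(covering, key=lambda o: abs(o + (width - 1) / 2 - c))
            if covering
            else min(offsets, key=lambda o: abs(o + (width - 1) / 2 - c))
        )
        hist[chosen - c] += 1
        if covering:
            n_cover += 1
        n_starts = len(w.sequence) - width + 1
        lo = max(0, c - width + 1)
        hi = min(n_starts - 1, c)
        n_cover_starts = max(0, hi - lo + 1)
        p0_sum += n_cover_starts / n_starts if n_starts > 0 else 0.0
    if n_matched == 0:
        return CentralEnrichment(1.0, 0, 0, {})
    p0 = p0_sum / n_matched
    p = stats.binomtest(n_cover, n_matched, p0, alternative="greater").pvalue
    return CentralEnrichment(float(p), n_matched, n_cover, dict(hist))


def write_meme_minimal(results: Sequence[MotifResult], path) -> None:
    """PWMs in MEME minimal text format (alphabet ACGU)."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGU\n\n")
        fh.write("strands: +\n\n")
        fh.write(
            "Background letter frequencies\nA 0.25 C 0.25 G 0.25 U 0.25\n\n"
        )
        for r in results:
            fh.write(f"MOTIF {r.consensus}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {r.width} "
                f"nsites= {r.site_count} E= {r.e_value:.3g}\n"
            )
            for row in r.pwm:
                fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")
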