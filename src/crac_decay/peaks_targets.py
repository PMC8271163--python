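"""Peak calling, gene peak scores, expression-normalized target ranking.

Candidate peaks are order-``order`` local maxima of the coverage profile
(a position whose coverage is >= every position within ``order`` nt on both
sides); significance is assessed per transcript with a permutation null
that uniformly re-places the transcript's read start positions, followed by
Benjamini-Hochberg control across all candidates of a replicate. Retained
peak heights in reads-per-million are summed per gene, averaged over the
two replicates, and divided by mean FPKM to rank targets.
"""

from __future__ import annotations

import zlib
from collections import Counter
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .crosslink import CrosslinkProfile
from .io_formats import Biotype, Region, TranscriptModel


@dataclass
class PeakCallingParams:
    order: int = 20
    fdr_threshold: float = 0.001
    n_permutations: int = 100
    min_coverage: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError("order must be >= 1")
        if not 0.0 < self.fdr_threshold < 1.0:
            raise ValueError("fdr_threshold must lie in (0, 1)")

    def min_attainable_q(self) -> float:
        """Smallest q-value the permutation scheme can produce.

        Empirical p-values are floored at 1/(n_permutations + 1) and BH
        adjustment never drops below the smallest raw p, so the FDR
        threshold is only reachable when this floor is below it.
        """
        return 1.0 / (self.n_permutations + 1)


@dataclass
class Peak:
    transcript_id: str
    position: int  # 0-based
    height: int  # raw coverage at the maximum
    intensity_rpm: float
    p_value: float
    q_value: float
    replicate_id: str
    region: Region = Region.NA


def window_max_candidates(
    coverage: np.ndarray, order: int, min_coverage: int
) -> list[int]:
    """Positions that are >= all coverage within ``order`` nt either side.

    Within a plateau of equal qualifying values only the leftmost position
    is reported. ``order`` >= vector length degenerates to the global
    maximum — not an error.
    """
    cov = np.asarray(coverage)
    n = cov.size
    if n == 0:
        return []
    # sliding window maximum over [i-order, i+order], clipped at the ends
    win = 2 * order + 1
    pad = np.concatenate(
        (np.full(order, -1, dtype=cov.dtype), cov, np.full(order, -1, dtype=cov.dtype))
    )
    from numpy.lib.stride_tricks import sliding_window_view

    winmax = sliding_window_view(pad, win).max(axis=1)
    qualifies = (cov >= winmax) & (cov >= min_coverage)
    out: list[int] = []
    for i in np.flatnonzero(qualifies):
        if i > 0 and qualifies[i - 1] and cov[i - 1] == cov[i]:
            continue
        out.append(int(i))
    return out


def _null_max_coverage(
    length: int,
    reads: Sequence[tuple[int, int]],
    n_permutations: int,
    rng: np.random.Generator,
    chunk: int = 400,
) -> np.ndarray:
    """Max coverage of null profiles re-placing read starts uniformly."""
    footprints = np.minimum(np.array([f for _, f in reads]), length)
    high = np.maximum(length - footprints + 1, 1)
    width = length + 1
    maxima = np.empty(n_permutations)
    done = 0
    n_reads = footprints.size
    while done < n_permutations:
        p = min(chunk, n_permutations - done)
        starts = rng.integers(0, high, size=(p, n_reads))
        row_offsets = (np.arange(p) * width)[:, None]
        delta = np.bincount(
            (starts + row_offsets).ravel(), minlength=p * width
        ) - np.bincount(
            (starts + footprints + row_offsets).ravel(), minlength=p * width
        )
        cov = delta.astype(np.int32).reshape(p, width).cumsum(axis=1)
        maxima[done : done + p] = cov.max(axis=1)
        done += p
    return maxima


def call_peaks(
    profiles: Mapping[str, CrosslinkProfile] | CrosslinkProfile,
    params: PeakCallingParams,
) -> list[Peak]:
    """Order-``order`` local-maximum peaks surviving a permutation FDR screen.

    Each candidate's empirical p is the add-one-smoothed fraction of null
    transcript maxima at least as high as the candidate; BH adjustment runs
    across all candidates of the replicate and peaks with
    q <= ``fdr_threshold`` are retained. The per-transcript null generator
    is derived from (seed, transcript id) so results do not depend on
    iteration order.
    """
    if isinstance(profiles, CrosslinkProfile):
        profiles = {profiles.transcript_id: profiles}
    candidates: list[tuple[CrosslinkProfile, int, float]] = []
    stage1 = min(params.n_permutations, 2000)
    for tid in sorted(profiles):
        prof = profiles[tid]
        positions = window_max_candidates(
            prof.coverage, params.order, params.min_coverage
        )
        if not positions:
            continue
        rng = np.random.default_rng(
            np.random.SeedSequence([params.seed, zlib.crc32(tid.encode())])
        )
        null_max = _null_max_coverage(
            prof.coverage.size, prof.reads, stage1, rng
        )
        heights = np.array([int(prof.coverage[pos]) for pos in positions])
        exceed = np.array(
            [int(np.count_nonzero(null_max >= h)) for h in heights]
        )
        n_done = stage1
        # adaptive refinement: only candidates whose stage-1 p is still in
        # the decision zone (within 10x of the FDR threshold) get the full
        # permutation budget; clearly non-significant ones stop early.
        if n_done < params.n_permutations and np.any(
            (1 + exceed) / (n_done + 1) <= 10 * params.fdr_threshold
        ):
            extra = _null_max_coverage(
                prof.coverage.size,
                prof.reads,
                params.n_permutations - stage1,
                rng,
            )
            exceed = exceed + np.array(
                [int(np.count_nonzero(extra >= h)) for h in heights]
            )
            n_done = params.n_permutations
        for pos, exc in zip(positions, exceed):
            p = (1 + int(exc)) / (n_done + 1)
            candidates.append((prof, int(pos), p))
    if not candidates:
        return []
    pvals = np.array([p for _, _, p in candidates])
    qvals = stats.false_discovery_control(pvals, method="bh")
    peaks: list[Peak] = []
    for (prof, pos, p), q in zip(candidates, qvals):
        if q > params.fdr_threshold:
            continue
        height = int(prof.coverage[pos])
        rpm = height * 1e6 / prof.library_size if prof.library_size else 0.0
        peaks.append(
            Peak(
                transcript_id=prof.transcript_id,
                position=pos,
                height=height,
                intensity_rpm=rpm,
                p_value=float(p),
                q_value=float(q),
                replicate_id=prof.replicate_id,
            )
        )
    return peaks


def gene_peak_scores(
    peaks_by_replicate: Mapping[str, Sequence[Peak]],
    models: Mapping[str, TranscriptModel],
) -> pd.DataFrame:
    """Per-gene summed peak intensities (rpm) per replicate, plus the mean.

    Defined over exactly two replicates; a gene detected in only one
    contributes 0 rpm from the other, down-weighting single-replicate
    evidence rather than erasing it.
    """
    if len(peaks_by_replicate) != 2:
        raise ValueError(
            f"expected exactly 2 replicates, got {len(peaks_by_replicate)}"
        )
    rep_names = sorted(peaks_by_replicate)
    sums: dict[str, dict[str, float]] = {r: {} for r in rep_names}
    for rep in rep_names:
        for peak in peaks_by_replicate[rep]:
            gene = models[peak.transcript_id].gene_id
            sums[rep][gene] = sums[rep].get(gene, 0.0) + peak.intensity_rpm
    genes = sorted(set(sums[rep_names[0]]) | set(sums[rep_names[1]]))
    rows = []
    for gene in genes:
        s1 = sums[rep_names[0]].get(gene, 0.0)
        s2 = sums[rep_names[1]].get(gene, 0.0)
        rows.append((gene, s1, s2, (s1 + s2) / 2))
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "peak_score_rep1_rpm",
            "peak_score_rep2_rpm",
            "mean_peak_score_rpm",
        ],
    )


@dataclass
class RankingResult:
    table: pd.DataFrame
    removed_not_in_expression: list[str] = field(default_factory=list)
    removed_zero_fpkm: list[str] = field(default_factory=list)
    top_n: int = 500

    @property
    def top_genes(self) -> list[str]:
        return list(self.table.head(self.top_n)["gene_id"])


def rank_targets(
    scores: pd.DataFrame,
    expression: pd.DataFrame,
    top_n: int = 500,
) -> RankingResult:
    """FPKM-normalized target ranking.

    ``normalized_score = mean_peak_score_rpm / mean_fpkm``; genes with zero
    mean FPKM are eliminated, genes missing from the expression table are
    removed and reported. Ties sort by higher raw peak score, then gene id.
    """
    if not {"gene_id", "fpkm_rep1", "fpkm_rep2"}.issubset(expression.columns):
        raise ValueError("expression table needs gene_id, fpkm_rep1, fpkm_rep2")
    expr = expression.set_index("gene_id")
    if not expr.index.is_unique:
        raise ValueError("duplicate gene_id in expression table")
    rows = []
    removed_missing: list[str] = []
    removed_zero: list[str] = []
    for rec in scores.itertuples(index=False):
        if rec.gene_id not in expr.index:
            removed_missing.append(rec.gene_id)
            continue
        f1, f2 = expr.loc[rec.gene_id, ["fpkm_rep1", "fpkm_rep2"]]
        mean_fpkm = (float(f1) + float(f2)) / 2
        if mean_fpkm == 0.0:
            removed_zero.append(rec.gene_id)
            continue
        rows.append(
            (
                rec.gene_id,
                rec.peak_score_rep1_rpm,
                rec.peak_score_rep2_rpm,
                rec.mean_peak_score_rpm,
                mean_fpkm,
                rec.mean_peak_score_rpm / mean_fpkm,
            )
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "peak_score_rep1_rpm",
            "peak_score_rep2_rpm",
            "mean_peak_score_rpm",
            "mean_fpkm",
            "normalized_score",
        ],
    )
    table = table.sort_values(
        by=["normalized_score", "mean_peak_score_rpm", "gene_id"],
        ascending=[False, False, True],
        kind="stable",
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return RankingResult(
        table=table,
        removed_not_in_expression=removed_missing,
        removed_zero_fpkm=removed_zero,
        top_n=top_n,
    )


@dataclass
class RegionAnnotation:
    peaks: list[Peak]
    region_fractions: dict[Region, float]
    peaks_per_transcript: Counter


def annotate_regions(
    peaks: Sequence[Peak], models: Mapping[str, TranscriptModel]
) -> RegionAnnotation:
    """Label peaks with their transcript region and summarize.

    Boundaries are half-open: position ``utr5_len - 1`` is UTR5, position
    ``utr5_len`` is CDS. Peaks on non-mRNA transcripts get region NA and
    are excluded from the fractions.
    """
    counts: Counter = Counter()
    per_transcript: Counter = Counter()
    annotated: list[Peak] = []
    for peak in peaks:
        model = models[peak.transcript_id]
        region = model.region_of(peak.position)
        peak.region = region
        annotated.append(peak)
        per_transcript[peak.transcript_id] += 1
        if region is not Region.NA:
            counts[region] += 1
    total = sum(counts.values())
    fractions = (
        {r: counts.get(r, 0) / total for r in (Region.UTR5, Region.CDS, Region.UTR3)}
        if total
        else {}
    )
    return RegionAnnotation(annotated, fractions, per_transcript)


@dataclass
class MetageneProfile:
    bin_edges: np.ndarray  # on the scaled [0, 3) axis
    density: np.ndarray  # unit area over the whole axis
    bins_per_region: int
    mean_region_lengths: dict[Region, float]
    n_peaks: int


def metagene_profile(
    peaks: Sequence[Peak],
    models: Mapping[str, TranscriptModel],
    bins_per_region: int = 25,
) -> MetageneProfile:
    """Peak density over a scaled UTR5|CDS|UTR3 axis (each region -> unit length).

    Peak positions map to their fractional position within their region;
    the histogram over 3 x ``bins_per_region`` bins is normalized to unit
    area. Mean region lengths of the contributing mRNAs are reported so
    the scaled axis can be read in nucleotides.
    """
    coords: list[float] = []
    region_index = {Region.UTR5: 0, Region.CDS: 1, Region.UTR3: 2}
    lengths: dict[Region, list[int]] = {r: [] for r in region_index}
    seen_models: set[str] = set()
    for peak in peaks:
        model = models[peak.transcript_id]
        if model.biotype is not Biotype.mRNA:
            continue
        region = model.region_of(peak.position)
        starts = {
            Region.UTR5: 0,
            Region.CDS: model.utr5_len,
            Region.UTR3: model.utr5_len + model.cds_len,
        }
        sizes = {
            Region.UTR5: model.utr5_len,
            Region.CDS: model.cds_len,
            Region.UTR3: model.utr3_len,
        }
        size = sizes[region]
        if size == 0:
            continue
        frac = (peak.position - starts[region] + 0.5) / size
        coords.append(region_index[region] + frac)
        if model.transcript_id not in seen_models:
            seen_models.add(model.transcript_id)
            for r in region_index:
                lengths[r].append(sizes[r])
    edges = np.linspace(0.0, 3.0, 3 * bins_per_region + 1)
    hist, _ = np.histogram(coords, bins=edges)
    width = 3.0 / (3 * bins_per_region)
    total = hist.sum()
    density = hist / (total * width) if total else hist.astype(float)
    mean_lengths = {
        r: (float(np.mean(v)) if v else 0.0) for r, v in lengths.items()
    }
    return MetageneProfile(edges, density, bins_per_region, mean_lengths, int(total))


def write_peaks_bed(peaks: Sequence[Peak], path) -> None:
    """BED6 in transcript space; score = rpm x 10 rounded; name = transcript."""
    with open(path, "w") as fh:
        for p in peaks:
            score = int(round(p.intensity_rpm * 10))
            fh.write(
                f"{p.transcript_id}\t{p.position}\t{p.position + 1}\t"
                f"{p.transcript_id}\t{score}\t+\n"
            )
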