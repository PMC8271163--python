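"""Synthetic CRAC / RNA-seq / SLAM-seq data with known ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes, at desk scale:

* a transcriptome of mostly mRNAs with 5'UTR/CDS/3'UTR structure and a
  minority of structural RNA classes;
* a subset of "bound" transcripts carrying one planted crosslink site — a
  concrete expansion of a degenerate consensus (default AUKAAWU),
  concentrated in 3'UTRs;
* CRAC reads sampled around the sites, each carrying a single-nucleotide
  deletion at the crosslinked uridine with a configurable probability, on
  top of expression-proportional background fragments, PCR-duplicated,
  barcoded and adapter-tagged;
* FPKM expression tables with lognormal replicate noise and a configurable
  zero-expression fraction;
* SLAM-seq T->C conversion counts decaying exponentially with the
  transcript's half-life, binomially sampled per timepoint and technical
  replicate.

All randomness descends from one seed; repeated runs are bit-identical.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import Biotype, Region, SequencedRead, TranscriptModel
from .motif import IUPAC

DEFAULT_TIMEPOINTS = (0, 30, 60, 120, 540, 1440)  # minutes


@dataclass
class SimulationConfig:
    """Study conditions for the simulator; defaults are the test-bench setup."""

    n_transcripts: int = 300
    utr5_range: tuple[int, int] = (50, 150)
    cds_range: tuple[int, int] = (300, 900)
    utr3_range: tuple[int, int] = (200, 600)
    ncrna_range: tuple[int, int] = (80, 300)
    biotype_fractions: dict[str, float] = field(
        default_factory=lambda: {
            "mRNA": 0.90,
            "rRNA": 0.04,
            "tRNA": 0.02,
            "snoRNA": 0.02,
            "snRNA": 0.01,
            "miscRNA": 0.01,
        }
    )
    n_bound: int = 60
    region_site_probs: tuple[float, float, float] = (0.1, 0.1, 0.8)
    motif: str = "AUKAAWU"
    del_rate: float = 0.3
    pcr_dup_mean: float = 1.0
    barcode_set: tuple[str, ...] = ("ACGT", "TGAC")
    adapter: str = "TGGAATTCTCGGGTGCCAAGG"
    read_len: int = 50
    fragment_range: tuple[int, int] = (26, 40)
    n_site_reads: int = 250
    depth_per_fpkm: float = 1.0
    fpkm_log_mean: float = 3.0
    fpkm_log_sigma: float = 1.0
    expression_noise_sigma: float = 0.2
    zero_expression_fraction: float = 0.05
    thalf_median_min: float = 224.0
    thalf_log_sigma: float = 0.4
    bound_thalf_factor: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.biotype_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"biotype fractions sum to {total}, expected 1")
        if abs(sum(self.region_site_probs) - 1.0) > 1e-9:
            raise ValueError("region_site_probs must sum to 1")
        if not 0.0 <= self.del_rate <= 1.0:
            raise ValueError("del_rate must lie in [0, 1]")
        for code in self.motif:
            if code not in IUPAC:
                raise ValueError(f"motif has non-IUPAC code {code!r}")
        if len({len(b) for b in self.barcode_set}) != 1:
            raise ValueError("barcodes must have equal length")


@dataclass
class PlantedSite:
    transcript_id: str
    motif_start: int  # 0-based start of the planted instance
    site_position: int  # crosslinked base (a U of the instance), 0-based
    region: Region
    instance: str  # concrete expansion, RNA alphabet


@dataclass
class GroundTruth:
    sites: dict[str, PlantedSite]  # keyed by transcript_id (bound only)
    fpkm: dict[str, float]  # per transcript
    t_half: dict[str, float]  # minutes, per transcript
    gene_of: dict[str, str]
    zero_expression_genes: set[str] = field(default_factory=set)
    unique_read_sequences: dict[str, int] = field(default_factory=dict)


@dataclass
class SimulatedTranscriptome:
    models: dict[str, TranscriptModel]
    sequences: dict[str, str]  # DNA alphabet
    truth: GroundTruth
    config: SimulationConfig


def _expand_motif(motif: str, rng: np.random.Generator) -> str:
    """Concrete RNA instance of an IUPAC consensus."""
    return "".join(
        rng.choice(sorted(IUPAC[code])) for code in motif.upper()
    )


def _crosslink_offset(instance: str) -> int:
    """Offset of the crosslinked base: the innermost left-aligned U.

    Crosslinking chemistry acts on uridines, so the simulated deletion is
    always placed on a U of the planted instance. Among the U positions
    nearest the motif center, the leftmost U of its run is chosen: deleting
    any base of a homopolymer yields the same read, and the aligner
    reports the leftmost placement, so only a run-leftmost U gives a
    ground-truth coordinate that deletion mapping can recover exactly.
    """
    center = (len(instance) - 1) / 2
    u_positions = [
        i
        for i, b in enumerate(instance)
        if b == "U" and (i == 0 or instance[i - 1] != "U")
    ]
    if not u_positions:
        raise ValueError(f"planted instance {instance!r} contains no U")
    return min(u_positions, key=lambda i: (abs(i - center), i))


def simulate_transcriptome(cfg: SimulationConfig) -> SimulatedTranscriptome:
    """Random transcriptome with planted crosslink sites and ground truth.

    Sequences are i.i.d. uniform over ACGT except the planted instances
    (consensus expansions, U written as T); the site region is drawn from
    ``region_site_probs``. Deterministic under ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    names = list(cfg.biotype_fractions)
    fractions = np.array([cfg.biotype_fractions[n] for n in names])
    biotypes = rng.choice(names, size=cfg.n_transcripts, p=fractions)
    models: dict[str, TranscriptModel] = {}
    sequences: dict[str, str] = {}
    gene_of: dict[str, str] = {}
    for i, biotype_s in enumerate(biotypes):
        tid = f"TX{i:04d}"
        gene = f"G{i:04d}"
        biotype = Biotype(biotype_s)
        if biotype is Biotype.mRNA:
            u5 = int(rng.integers(*cfg.utr5_range, endpoint=True))
            cds = int(rng.integers(*cfg.cds_range, endpoint=True))
            u3 = int(rng.integers(*cfg.utr3_range, endpoint=True))
            model = TranscriptModel(tid, gene, biotype, u5, cds, u3, u5 + cds + u3)
        else:
            length = int(rng.integers(*cfg.ncrna_range, endpoint=True))
            model = TranscriptModel(tid, gene, biotype, 0, 0, 0, length)
        models[tid] = model
        gene_of[tid] = gene
        sequences[tid] = "".join(
            rng.choice(list("ACGT"), size=model.sequence_length)
        )
    mrna_ids = [t for t, m in models.items() if m.biotype is Biotype.mRNA]
    if cfg.n_bound > len(mrna_ids):
        raise ValueError("n_bound exceeds number of mRNA transcripts")
    bound = rng.choice(mrna_ids, size=cfg.n_bound, replace=False)
    width = len(cfg.motif)
    sites: dict[str, PlantedSite] = {}
    region_names = (Region.UTR5, Region.CDS, Region.UTR3)
    for tid in bound:
        m = models[tid]
        spans = {
            Region.UTR5: (0, m.utr5_len),
            Region.CDS: (m.utr5_len, m.utr5_len + m.cds_len),
            Region.UTR3: (m.utr5_len + m.cds_len, m.sequence_length),
        }
        probs = np.array(cfg.region_site_probs, dtype=float)
        # regions too short for the motif are excluded, renormalizing
        for j, reg in enumerate(region_names):
            lo, hi = spans[reg]
            if hi - lo < width:
                probs[j] = 0.0
        if probs.sum() == 0:
            raise ValueError(f"{tid}: no region can hold the motif")
        probs /= probs.sum()
        reg = region_names[int(rng.choice(3, p=probs))]
        lo, hi = spans[reg]
        start = int(rng.integers(lo, hi - width + 1))
        instance = _expand_motif(cfg.motif, rng)
        seq = sequences[tid]
        sequences[tid] = (
            seq[:start] + instance.replace("U", "T") + seq[start + width :]
        )
        site_pos = start + _crosslink_offset(instance)
        sites[tid] = PlantedSite(tid, start, site_pos, reg, instance)
    fpkm = {
        tid: float(rng.lognormal(cfg.fpkm_log_mean, cfg.fpkm_log_sigma))
        for tid in models
    }
    t_half = {}
    for tid in models:
        th = float(rng.lognormal(np.log(cfg.thalf_median_min), cfg.thalf_log_sigma))
        if tid in sites:
            th *= cfg.bound_thalf_factor
        t_half[tid] = th
    truth = GroundTruth(sites=sites, fpkm=fpkm, t_half=t_half, gene_of=gene_of)
    return SimulatedTranscriptome(models, sequences, truth, cfg)


def simulate_crac_reads(
    sim: SimulatedTranscriptome, n_replicates: int = 2
) -> list[list[SequencedRead]]:
    """CRAC read libraries, one list per replicate.

    Site fragments keep the crosslink interior and lose the crosslinked
    base with probability ``del_rate``; background fragments are placed
    uniformly with depth proportional to FPKM; every unique fragment is
    duplicated Poisson(pcr_dup_mean)+1 times; reads are barcode + fragment
    + adapter truncated to ``read_len``. Ground truth rides in the read id
    (``frag``/``site``/``del`` fields). The per-replicate count of distinct
    full-length read sequences is recorded in
    ``truth.unique_read_sequences`` for duplicate-collapse checks.
    """
    cfg = sim.config
    barcode_len = len(cfg.barcode_set[0])
    if cfg.read_len <= barcode_len + len(cfg.motif):
        raise ValueError("read_len too short for barcode plus motif")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    libraries: list[list[SequencedRead]] = []
    for rep in range(n_replicates):
        barcode = cfg.barcode_set[rep % len(cfg.barcode_set)]
        reads: list[SequencedRead] = []
        frag_counter = 0

        def emit(tid: str, start: int, deleted_at: int | None, tag: str) -> None:
            nonlocal frag_counter
            seq = sim.sequences[tid]
            flen = int(rng.integers(*cfg.fragment_range, endpoint=True))
            start = max(0, min(start, len(seq) - flen))
            frag = seq[start : start + flen]
            del_flag = 0
            if deleted_at is not None and start <= deleted_at < start + flen:
                if rng.random() < cfg.del_rate:
                    off = deleted_at - start
                    frag = frag[:off] + frag[off + 1 :]
                    del_flag = 1
            full = (barcode + frag + cfg.adapter)[: cfg.read_len]
            n_copies = int(rng.poisson(cfg.pcr_dup_mean)) + 1
            for copy in range(n_copies):
                rid = (
                    f"sim:rep{rep + 1}:frag{frag_counter:06d}:c{copy}:"
                    f"{tid}:{tag}:del={del_flag}"
                )
                reads.append(SequencedRead(rid, full, [40] * len(full)))
            frag_counter += 1

        for tid, site in sim.truth.sites.items():
            seq_len = len(sim.sequences[tid])
            for _ in range(cfg.n_site_reads):
                flen_hint = cfg.fragment_range[0]
                margin = 3
                offset = int(rng.integers(margin, flen_hint - margin))
                start = max(0, min(site.site_position - offset, seq_len - 1))
                emit(tid, start, site.site_position, f"site={site.site_position}")
        for tid in sim.models:
            lam = sim.truth.fpkm[tid] * cfg.depth_per_fpkm
            n_bg = int(rng.poisson(lam))
            seq_len = len(sim.sequences[tid])
            for _ in range(n_bg):
                start = int(rng.integers(0, max(1, seq_len - cfg.fragment_range[0])))
                emit(tid, start, None, "bg")
        sim.truth.unique_read_sequences[f"rep{rep + 1}"] = len(
            {r.sequence for r in reads}
        )
        libraries.append(reads)
    return libraries


def simulate_expression(
    sim: SimulatedTranscriptome,
    sigma: float | None = None,
    zero_fraction: float | None = None,
) -> pd.DataFrame:
    """Two-replicate FPKM table: truth x lognormal noise, some genes zeroed.

    The zeroed genes are recorded in ``truth.zero_expression_genes``.
    """
    cfg = sim.config
    sigma = cfg.expression_noise_sigma if sigma is None else sigma
    zero_fraction = (
        cfg.zero_expression_fraction if zero_fraction is None else zero_fraction
    )
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    tids = list(sim.models)
    genes = [sim.truth.gene_of[t] for t in tids]
    base = np.array([sim.truth.fpkm[t] for t in tids])
    rep1 = base * rng.lognormal(0.0, sigma, size=len(tids)) if sigma > 0 else base.copy()
    rep2 = base * rng.lognormal(0.0, sigma, size=len(tids)) if sigma > 0 else base.copy()
    n_zero = int(round(zero_fraction * len(tids)))
    zero_idx = rng.choice(len(tids), size=n_zero, replace=False) if n_zero else []
    for i in zero_idx:
        rep1[i] = rep2[i] = 0.0
        sim.truth.zero_expression_genes.add(genes[i])
    return pd.DataFrame(
        {"gene_id": genes, "fpkm_rep1": rep1, "fpkm_rep2": rep2}
    )


def simulate_slamseq_counts(
    truth: GroundTruth,
    timepoints: Sequence[float] = DEFAULT_TIMEPOINTS,
    coverage: int = 2500,
    r0: float = 0.02,
    n_tech_reps: int = 2,
    seed: int = 0,
) -> pd.DataFrame:
    """SLAM-seq style T->C conversion counts per gene/timepoint/tech rep.

    ``tc_count ~ Binomial(coverage, r0 * 2^(-t / t_half))`` independently
    per entry; at t = 0 the expected rate is exactly ``r0`` and at
    t = t_half exactly ``r0 / 2``.
    """
    if 0 not in timepoints and 0.0 not in timepoints:
        raise ValueError("timepoints must include 0")
    if not 0.0 < r0 < 1.0:
        raise ValueError("r0 must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    rows = []
    for tid, th in truth.t_half.items():
        if th <= 0:
            raise ValueError(f"{tid}: non-positive half-life")
        gene = truth.gene_of[tid]
        for t in timepoints:
            rate = r0 * 2.0 ** (-t / th)
            for rep in range(1, n_tech_reps + 1):
                tc = int(rng.binomial(coverage, rate))
                rows.append((gene, float(t), rep, coverage, tc))
    return pd.DataFrame(
        rows, columns=["gene_id", "timepoint", "tech_rep", "t_coverage", "tc_count"]
    )
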