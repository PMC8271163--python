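"""End-to-end orchestration: simulate -> preprocess -> align -> peaks -> rank.

This is the driver the CLI and the recovery benchmarks share. Peak calling
defaults here to 20000 permutations, unlike the bare
:class:`~crac_decay.peaks_targets.PeakCallingParams` default of 100: the
empirical p-value floor is 1/(n_permutations + 1) and BH-adjusted q-values
never fall below the smallest raw p, so resolving the q <= 0.001 retention
threshold across several hundred candidates needs on the order of 10^4
permutations (see docs/methods.md). Refinement to that depth is adaptive,
so only candidates near the decision boundary pay for it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import crosslink, peaks_targets, preprocess_align, synthetic_data
from .crosslink import CrosslinkProfile
from .io_formats import ReadAlignment
from .peaks_targets import Peak, PeakCallingParams, RankingResult
from .preprocess_align import PreprocessReport
from .synthetic_data import SimulatedTranscriptome, SimulationConfig

PIPELINE_N_PERMUTATIONS = 20000


@dataclass
class PipelineResult:
    sim: SimulatedTranscriptome
    expression: pd.DataFrame
    reports: dict[str, PreprocessReport]
    alignments: dict[str, list[ReadAlignment]]
    n_unaligned: dict[str, int]
    profiles: dict[str, dict[str, CrosslinkProfile]]
    peaks: dict[str, list[Peak]]
    ranking: RankingResult
    peak_params: PeakCallingParams
    scores: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def genes_with_peaks(self) -> set[str]:
        genes: set[str] = set()
        for rep_peaks in self.peaks.values():
            for p in rep_peaks:
                genes.add(self.sim.models[p.transcript_id].gene_id)
        return genes


def run_crac_pipeline(
    cfg: SimulationConfig,
    peak_params: PeakCallingParams | None = None,
    top_n: int | None = None,
) -> PipelineResult:
    """Run the CRAC arm of the analysis on a fresh simulation of ``cfg``.

    ``top_n`` defaults to the number of planted bound transcripts so the
    head of the ranking is directly comparable with the ground truth.
    """
    if peak_params is None:
        peak_params = PeakCallingParams(
            n_permutations=PIPELINE_N_PERMUTATIONS, seed=cfg.seed
        )
    if top_n is None:
        top_n = cfg.n_bound
    sim = synthetic_data.simulate_transcriptome(cfg)
    libraries = synthetic_data.simulate_crac_reads(sim)
    expression = synthetic_data.simulate_expression(sim)
    reports: dict[str, PreprocessReport] = {}
    alignments: dict[str, list[ReadAlignment]] = {}
    n_unaligned: dict[str, int] = {}
    profiles: dict[str, dict[str, CrosslinkProfile]] = {}
    peaks: dict[str, list[Peak]] = {}
    for rep_idx, reads in enumerate(libraries, start=1):
        rep = f"rep{rep_idx}"
        barcode = cfg.barcode_set[(rep_idx - 1) % len(cfg.barcode_set)]
        bins, report = preprocess_align.preprocess(
            reads, cfg.barcode_set, cfg.adapter
        )
        reports[rep] = report
        alns, n_un = preprocess_align.align_reads(
            bins[barcode], sim.sequences, seed=cfg.seed
        )
        alignments[rep] = alns
        n_unaligned[rep] = n_un
        profiles[rep] = crosslink.build_profiles(alns, sim.models, rep)
        peaks[rep] = peaks_targets.call_peaks(profiles[rep], peak_params)
    scores = peaks_targets.gene_peak_scores(peaks, sim.models)
    ranking = peaks_targets.rank_targets(scores, expression, top_n=top_n)
    return PipelineResult(
        sim=sim,
        expression=expression,
        reports=reports,
        alignments=alignments,
        n_unaligned=n_unaligned,
        profiles=profiles,
        peaks=peaks,
        ranking=ranking,
        peak_params=peak_params,
        scores=scores,
    )
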