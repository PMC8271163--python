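"""Peak calling, FDR screen behavior, scoring, ranking and annotation."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from crac_decay import peaks_targets as pt
from crac_decay.crosslink import CrosslinkProfile
from crac_decay.io_formats import Biotype, Region, TranscriptModel

MRNA = TranscriptModel("tx1", "g1", Biotype.mRNA, 60, 300, 200, 560)


def brute_force_candidates(cov, order, min_cov):
    """Independent O(L*order) windowed-max scan with the leftmost-plateau rule."""
    n = len(cov)
    qualifies = []
    for i in range(n):
        lo, hi = max(0, i - order), min(n, i + order + 1)
        qualifies.append(cov[i] >= min_cov and cov[i] >= max(cov[lo:hi]))
    return [
        i
        for i in range(n)
        if qualifies[i]
        and not (i > 0 and qualifies[i - 1] and cov[i - 1] == cov[i])
    ]


def profile_from_reads(length, reads, tid="tx1", rep="rep1", library_size=None):
    cov = np.zeros(length, dtype=np.int64)
    for start, fp in reads:
        cov[start : start + fp] += 1
    return CrosslinkProfile(
        transcript_id=tid,
        replicate_id=rep,
        coverage=cov,
        deletions=np.zeros(length, dtype=np.int64),
        reads=list(reads),
        library_size=library_size or len(reads),
    )


class TestCandidates:
    def test_single_spike_is_sole_candidate(self):
        cov = np.zeros(500, int)
        cov[250] = 50
        assert pt.window_max_candidates(cov, 20, 5) == [250]

    def test_nearby_smaller_spike_suppressed_within_order(self):
        cov = np.zeros(500, int)
        cov[250] = 50
        cov[260] = 30
        assert pt.window_max_candidates(cov, 20, 5) == [250]
        # outside the order window both survive
        cov2 = np.zeros(500, int)
        cov2[250] = 50
        cov2[295] = 30
        assert pt.window_max_candidates(cov2, 20, 5) == [250, 295]

    def test_plateau_reports_leftmost_once(self):
        cov = np.zeros(100, int)
        cov[40:45] = 7
        assert pt.window_max_candidates(cov, 20, 5) == [40]

    def test_order_exceeding_length_gives_global_max(self):
        cov = np.array([5, 9, 5, 6])
        assert pt.window_max_candidates(cov, 50, 5) == [1]

    @pytest.mark.parametrize("length", [100, 1000, 10000])
    @pytest.mark.parametrize("order", [3, 20])
    def test_matches_brute_force_scan(self, length, order):
        gen = np.random.default_rng(length + order)
        cov = gen.integers(0, 30, size=length)
        assert pt.window_max_candidates(cov, order, 5) == brute_force_candidates(
            cov, order, 5
        )


class TestPermutationScreen:
    def test_isolated_spike_survives(self):
        reads = [(250, 1)] * 50
        prof = profile_from_reads(500, reads)
        params = pt.PeakCallingParams(n_permutations=2000, fdr_threshold=0.05, seed=0)
        peaks = pt.call_peaks(prof, params)
        assert len(peaks) == 1
        assert peaks[0].position == 250
        assert peaks[0].height == 50
        assert peaks[0].q_value <= 0.05

    def test_site_pileup_peaks_stay_inside_footprint(self):
        gen = np.random.default_rng(4)
        reads = [(int(gen.integers(85, 101)), 30) for _ in range(200)]
        reads += [(int(gen.integers(0, 470)), 30) for _ in range(30)]
        prof = profile_from_reads(500, reads)
        params = pt.PeakCallingParams(n_permutations=2000, fdr_threshold=0.05, seed=0)
        peaks = pt.call_peaks(prof, params)
        assert peaks
        assert all(85 <= p.position < 131 for p in peaks)

    def test_uniform_coverage_fails_screen(self):
        reads = [(start, 20) for start in range(0, 180, 20) for _ in range(10)]
        prof = profile_from_reads(200, reads)
        params = pt.PeakCallingParams(n_permutations=2000, fdr_threshold=0.05, seed=0)
        assert pt.call_peaks(prof, params) == []

    def test_q_floor_documented_by_params(self):
        params = pt.PeakCallingParams()
        assert params.min_attainable_q() > params.fdr_threshold

    def test_rpm_intensity_uses_library_size(self):
        prof = profile_from_reads(500, [(250, 1)] * 50, library_size=10**6)
        params = pt.PeakCallingParams(n_permutations=2000, fdr_threshold=0.05, seed=0)
        (peak,) = pt.call_peaks(prof, params)
        assert peak.intensity_rpm == pytest.approx(peak.height)


class TestGeneScores:
    def _peak(self, rpm, rep, tid="tx1"):
        return pt.Peak(tid, 10, 5, rpm, 1e-4, 1e-4, rep)

    def test_summing_and_averaging(self):
        by_rep = {
            "rep1": [self._peak(30, "rep1"), self._peak(12, "rep1")],
            "rep2": [self._peak(38, "rep2")],
        }
        table = pt.gene_peak_scores(by_rep, {"tx1": MRNA})
        row = table.iloc[0]
        assert row["peak_score_rep1_rpm"] == pytest.approx(42)
        assert row["peak_score_rep2_rpm"] == pytest.approx(38)
        assert row["mean_peak_score_rpm"] == pytest.approx(40)

    def test_single_replicate_gene_averaged_with_zero(self):
        by_rep = {"rep1": [self._peak(42, "rep1")], "rep2": []}
        table = pt.gene_peak_scores(by_rep, {"tx1": MRNA})
        assert table.iloc[0]["mean_peak_score_rpm"] == pytest.approx(21)

    def test_requires_exactly_two_replicates(self):
        with pytest.raises(ValueError, match="2 replicates"):
            pt.gene_peak_scores({"rep1": []}, {})


class TestRanking:
    def _scores(self, rows):
        return pd.DataFrame(
            rows,
            columns=[
                "gene_id", "peak_score_rep1_rpm", "peak_score_rep2_rpm",
                "mean_peak_score_rpm",
            ],
        )

    def _expr(self, rows):
        return pd.DataFrame(rows, columns=["gene_id", "fpkm_rep1", "fpkm_rep2"])

    def test_normalized_score_arithmetic(self):
        result = pt.rank_targets(
            self._scores([("g1", 40, 40, 40)]), self._expr([("g1", 10, 10)])
        )
        assert result.table.iloc[0]["normalized_score"] == pytest.approx(4.0)

    def test_zero_fpkm_gene_eliminated(self):
        result = pt.rank_targets(
            self._scores([("g1", 40, 40, 40), ("g2", 40, 40, 40)]),
            self._expr([("g1", 10, 10), ("g2", 0, 0)]),
        )
        assert result.table["gene_id"].tolist() == ["g1"]
        assert result.removed_zero_fpkm == ["g2"]

    def test_gene_missing_from_expression_removed_and_reported(self):
        result = pt.rank_targets(
            self._scores([("g1", 40, 40, 40), ("gX", 1, 1, 1)]),
            self._expr([("g1", 10, 10)]),
        )
        assert result.removed_not_in_expression == ["gX"]

    def test_sort_descending_with_tie_rules(self):
        result = pt.rank_targets(
            self._scores([
                ("a", 10, 10, 10), ("b", 20, 20, 20), ("c", 10, 10, 10),
            ]),
            self._expr([("a", 5, 5), ("b", 5, 5), ("c", 5, 5)]),
        )
        assert result.table["gene_id"].tolist() == ["b", "a", "c"]
        assert result.table["rank"].tolist() == [1, 2, 3]
        diffs = np.diff(result.table["normalized_score"].to_numpy())
        assert (diffs <= 0).all()

    def test_ranking_invariant_to_library_size_scaling(self):
        # rpm self-normalization: scaling every library by c rescales all
        # scores by 1/c and leaves the order untouched
        scores = self._scores([("a", 30, 34, 32), ("b", 12, 10, 11), ("c", 44, 40, 42)])
        scaled = scores.copy()
        for col in ("peak_score_rep1_rpm", "peak_score_rep2_rpm", "mean_peak_score_rpm"):
            scaled[col] = scaled[col] / 10
        expr = self._expr([("a", 2, 2), ("b", 1, 1), ("c", 8, 8)])
        order1 = pt.rank_targets(scores, expr).table["gene_id"].tolist()
        order2 = pt.rank_targets(scaled, expr).table["gene_id"].tolist()
        assert order1 == order2


class TestRegions:
    def _peak(self, pos, tid="tx1"):
        return pt.Peak(tid, pos, 5, 1.0, 1e-4, 1e-4, "rep1")

    def test_boundary_positions(self):
        ann = pt.annotate_regions(
            [self._peak(59), self._peak(60)], {"tx1": MRNA}
        )
        assert [p.region for p in ann.peaks] == [Region.UTR5, Region.CDS]

    def test_non_mrna_peak_gets_na_and_is_excluded(self):
        rrna = TranscriptModel("r1", "g2", Biotype.rRNA, 0, 0, 0, 120)
        ann = pt.annotate_regions(
            [self._peak(400), self._peak(10, "r1")], {"tx1": MRNA, "r1": rrna}
        )
        assert ann.region_fractions[Region.UTR3] == 1.0
        assert ann.peaks[1].region is Region.NA

    def test_peaks_per_transcript_histogram(self):
        ann = pt.annotate_regions(
            [self._peak(10), self._peak(400), self._peak(500)], {"tx1": MRNA}
        )
        assert ann.peaks_per_transcript["tx1"] == 3


class TestMetagene:
    def _peak(self, pos):
        return pt.Peak("tx1", pos, 5, 1.0, 1e-4, 1e-4, "rep1")

    def test_unit_area(self):
        peaks = [self._peak(p) for p in (5, 100, 400, 450, 500)]
        prof = pt.metagene_profile(peaks, {"tx1": MRNA}, bins_per_region=25)
        width = 3.0 / 75
        assert prof.density.sum() * width == pytest.approx(1.0)
        assert prof.n_peaks == 5

    def test_region_midpoints_land_in_central_bins(self):
        peaks = [self._peak(30), self._peak(210), self._peak(460)]
        prof = pt.metagene_profile(peaks, {"tx1": MRNA}, bins_per_region=25)
        hot = np.flatnonzero(prof.density)
        assert len(hot) == 3
        assert [h // 25 for h in hot] == [0, 1, 2]
        assert all(h % 25 == 12 for h in hot)
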