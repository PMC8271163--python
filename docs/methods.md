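# Methods

`crac-decay` re-implements, at desk scale, the computational route from raw
CRAC sequencing reads to a ranked list of RNA-binding-protein target
transcripts, and from SLAM-seq conversion counts to per-transcript mRNA
half-lives and bound-vs-unbound stability comparisons. This note records
the models, the parameters that matter, and the numerical choices made
where the design was genuinely open.

## Coordinate conventions

All internal coordinates are 0-based, half-open, 5'→3' on the mature
transcript. Conversions to 1-based conventions happen only at file
boundaries (GTF, SAM). Only transcript-space alignments are supported;
spliced CIGAR ops (`N`) are rejected rather than skipped, because silently
consuming them would corrupt coverage vectors. mRNA region boundaries are
half-open: position `utr5_len` is the first CDS base.

## Read pre-processing and alignment

Pre-processing follows the wet-lab order: PCR-duplicate collapse on the
raw reads (identical full-length sequence, first-seen representative kept,
barcodes still attached), 5' in-line barcode demultiplexing with an
explicit "unmatched" bin, then 3' adapter trimming. Trimming removes the
longest read suffix exactly matching an adapter prefix with at least
`min_overlap` (5) nt; reads shorter than `min_len` (18) nt afterwards are
discarded and counted. Exact-match trimming is adequate for error-free
synthetic reads; real libraries with sequencing errors should enter
through the SAM entry point after external trimming. Collapsing before
demultiplexing conflates barcode and insert identity only when barcodes
are degenerate; here they are fixed sequences, so the order is safe — the
functions are separable if a user needs the opposite order.

The aligner is a seed-and-extend mapper over an exact k-mer index
(k = 12). Seeds are taken from the start, middle and end of the read, so
one substitution or one deletion cannot disrupt all seeds of an otherwise
error-free read. Candidate loci are scored with match +1, substitution −2
net, single-nucleotide deletion −3, allowing at most `max_mismatch` (1)
substitutions and at most one 1-nt deletion — the event class that marks a
crosslink. The optimal interior gap placement is found from prefix/suffix
mismatch arrays in O(read length); equally scoring placements take the
leftmost position (standard left-alignment, so deletions inside
homopolymers have a canonical coordinate). Ties between loci are broken
uniformly at random under the run seed, making multi-mapper assignment
reproducible. The test-suite checks the aligner against an exhaustive
enumeration of every start and gap placement with the same scoring.

## Crosslink profiles

Coverage counts every position of a read's reference footprint (M and D
ops); the deletion vector counts only 1-nt deletions, at the coordinate of
the deleted base. Multi-nucleotide deletions stay in coverage but are
excluded from crosslink evidence, since only single-nucleotide deletions
are the reverse-transcriptase signature of a crosslinked base. RNA-class
read distributions count each mapped read once toward its transcript's
biotype; replicate concordance is Spearman's rho over per-transcript read
counts.

## Peak calling and target ranking

Candidate peaks are order-20 local maxima of the coverage vector: position
i qualifies when coverage[i] ≥ coverage[j] for all |i−j| ≤ 20 and
coverage[i] ≥ `min_coverage` (5). Within a contiguous plateau of equal
qualifying values the leftmost position is reported once; equal maxima
farther apart than the order are distinct candidates.

Significance uses a within-transcript permutation null: the transcript's
reads are re-placed uniformly (footprint lengths preserved), the maximum
coverage of each null profile is recorded, and a candidate's empirical p
is the add-one-smoothed fraction of null maxima at least as high as its
height. This preserves per-transcript depth and read length and needs no
parametric assumption. Benjamini–Hochberg adjustment then runs across all
candidates of a replicate, retaining q ≤ `fdr_threshold` (0.001).

One numerical consequence deserves emphasis: the smallest attainable
empirical p is 1/(n_permutations + 1), and BH-adjusted q-values never fall
below the smallest raw p. At the conservative default of 100 permutations
the floor is ≈ 0.0099, so a 0.001 FDR screen retains nothing — the
defaults describe the screen, not a working operating point. The pipeline
driver therefore runs 20,000 permutations (floor 5 × 10⁻⁵), which resolves
q ≤ 0.001 for a few hundred candidates. Refinement is adaptive: every
candidate gets a first stage of 2,000 permutations, and only candidates
whose stage-1 p lies within 10× of the FDR threshold escalate to the full
budget, so clearly non-significant candidates stop early and the exact
empirical-p definition is preserved for everything near the decision
boundary. `PeakCallingParams.min_attainable_q()` exposes the floor.

Peak intensity is the coverage height at the maximum in reads-per-million
(rpm) of the replicate's mapped reads — the simplest reading of a
pointwise profile. Per gene and replicate, retained peak intensities are
summed; the two replicate scores are averaged, with a gene detected in
only one replicate contributing 0 from the other (down-weighted, not
dropped). The mean score is divided by the gene's mean FPKM across the two
expression replicates; genes with zero mean FPKM, or absent from the
expression table, are eliminated and reported. Ranking is by descending
normalized score, ties broken by higher raw score then gene id. The final
list length is data-dependent and not a target.

Region annotation uses the half-open UTR5/CDS/UTR3 partition; peaks on
non-mRNA transcripts are labelled NA and excluded from region fractions.
The metagene profile maps each peak to its fractional position within its
region, histograms over 25 bins per region, and normalizes the piecewise
density to unit area over the scaled three-region axis; mean region
lengths are reported alongside so the axis can be read in nucleotides.

## Motif discovery

Windows of transcript sequence (not read sequence — the deleted,
crosslinked base must be present) are cut around each 1-nt deletion in
reads on top-ranked targets, flank 10 or 50 nt, T written as U. Discovery
is DREME-style: for each width 6–10, every exact word present in at least
5 windows is tested for presence/absence enrichment against
mononucleotide-shuffled windows with a one-sided Fisher test (computed as
the hypergeometric survival function; `scipy.stats.fisher_exact` is the
independent oracle in the tests). The best words are greedily generalized
position-by-position to two-letter IUPAC codes. Only the given strand is
ever scanned.

Three safeguards keep the greedy search honest, because unconstrained
greedy generalization can certify spurious motifs on unstructured input:

1. a generalization is accepted only if its p beats a Bonferroni margin
   over the codes tried at that position (p × n_codes < p_current);
2. the reported enrichment p is recomputed against a second, independent
   shuffle that played no part in selection;
3. the E-value multiplies that p by everything examined at the winning
   width — exact words plus generalization trials.

With these, 20/20 runs on unplanted windows report nothing at E < 0.05,
while a planted AUKAAWU-family site is recovered (as AUKAAWU or a
compatible sub/superset consensus) with E-values far below threshold at
both flank settings. Log-space p-values are used internally so that
selection still discriminates when p underflows double precision.
Mononucleotide shuffling is the default background; it preserves base
composition but not dinucleotide structure, which slightly flatters
composition-driven signals on real data.

Positional concentration: per window, the consensus match nearest the
deleted base (preferring matches whose span covers it) is recorded; a
one-sided binomial test compares the number of center-covering matches
with the expectation under uniform placement of a match start over the
window's valid offsets (for an unclipped flank-10 window and a 7-mer,
p₀ = 7/15). This null makes uniformly placed matches produce unremarkable
p-values, which the tests verify.

## SLAM-seq decay model

Labeled transcripts carry T→C conversions; after the chase begins, the
conversion rate of a transcript with half-life t½ decays as
r(t) = r₀ · 2^(−t/t½). Technical replicates are pooled by summing counts
before rates are formed (coverage-weighted, unlike a mean of rates), rates
are normalized to the t = 0 rate per gene (genes with zero t₀ rate are
excluded and reported), and y(t) = exp(−λt) is fitted by nonlinear least
squares with λ ≥ 0, initialized from a log-linear regression of ln y on t.
The log-linear estimate doubles as an independent oracle in the tests:
on noiseless data both routes agree to 10⁻⁸ relative. Fitting in linear
space down-weights the late, near-zero timepoints relative to a log-space
fit, which matters once counts are noisy. Fits need ≥ 4 usable timepoints
including t = 0; a fitted λ ≤ 10⁻⁷ min⁻¹ (under 0.02% decay across the
24 h chase — no measurable decay) is reported as `degenerate` with no
numeric half-life rather than an absurd number. No background conversion
rate is subtracted; a background model is a config extension point.
Group summaries are pointwise medians and quartiles of the normalized
series plus the median half-life over status-ok fits, computed per
biological replicate without cross-replicate pooling.

## Group comparisons

"Bound" is the top-N head of the normalized ranking; "Not bound" is every
gene with no retained peak in either replicate; peak-bearing genes outside
the top-N belong to neither group. Half-life and expression log₂
fold-change comparisons use a two-sided Mann–Whitney U test — exact when
both groups have ≤ 8 tie-free values, normal approximation with tie
correction otherwise, and p = 1 by convention when the pooled data carry
no ordering information at all. Fold change is
log₂((A + pc)/(B + pc)) on replicate-mean FPKM with a pseudocount
(default 1 FPKM) guarding zeros; the pseudocount is reported in output.

## Synthetic data: what it emulates and what it does not

The generator plants known structure so every stage has a recoverable
ground truth: a transcriptome of ~90% mRNAs with UTR/CDS/UTR structure;
60 of 300 transcripts bound, each carrying one concrete expansion of the
degenerate consensus AUKAAWU with region probabilities (0.1, 0.1, 0.8)
mirroring the 3'UTR preference of the motivating system; CRAC fragments
sampled around each site (250 per site) with the crosslinked base deleted
at rate 0.3 (the true per-read deletion frequency is not an established
quantity; 0.3 is a modeling choice); expression-proportional background
fragments, so FPKM normalization is consequential; Poisson PCR
duplication (mean 1 extra copy); fixed barcodes and a 3' adapter;
lognormal FPKM truth with two noisy replicates and a 5% zero-expression
fraction; and binomial T→C counts at chase timepoints 0, 30, 60, 120, 540
and 1440 min with r₀ = 0.02 and lognormal half-lives (median 224 min;
bound transcripts scaled by 0.8, putting their median near 180 min).

The ground-truth crosslink is the run-leftmost U of the planted instance
nearest the motif center: deleting any base of a homopolymer yields the
same read, and the aligner reports the leftmost placement, so only this
choice gives a coordinate that deletion mapping can recover exactly.

Not simulated: sequencing errors and quality scores, fragment-length
distributions beyond a uniform 26–40 nt range, substitution/truncation
crosslink signatures, spliced alignment, dinucleotide composition. Passing
recovery tests therefore demonstrates the correctness of the pipeline's
logic under the stated generative model, not robustness to the error
modes of real libraries.

## Problem sizes and determinism

The recovery benchmarks run the full pipeline at 300 transcripts / 60
bound / ~45k reads per replicate, the decay benchmark at 500 genes with
pooled coverage 5,000, and the peak-FDR calibration on 1,000 clean
transcripts — sizes chosen so the whole suite completes comfortably on a
single CPU. All randomness descends from explicit seeds (simulation
config, aligner tie-breaks, per-transcript permutation generators derived
from (seed, transcript id) so results are independent of iteration
order); repeated runs are bit-identical.

## Known limitations

* The permutation null re-places whole reads uniformly, ignoring any
  positional bias of fragment starts (e.g. 3'-end bias of real libraries).
* Exact-match adapter trimming and the 1-substitution alignment budget are
  calibrated to error-free synthetic reads.
* The E-value is a Bonferroni-style bound, not MEME's E-value semantics.
* FPKM normalization is gene-level; transcript-level expression and
  isoform ambiguity are out of scope.
* Replicate handling is fixed at two CRAC replicates (an explicit error
  otherwise), matching the averaging the scores are defined over.
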