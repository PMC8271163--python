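# crac-decay

Tools for two linked questions about a sequence-specific RNA-binding
protein (RBP): **which transcripts does it bind**, and **what does binding
do to their stability**?

The binding question is answered from CRAC data (cross-linking and
analysis of cDNAs). UV crosslinking leaves a covalent nucleotide–amino
acid adduct; reverse transcriptase reading through it introduces a
single-nucleotide deletion into the cDNA, so deletions in aligned reads
pinpoint direct protein–RNA contacts. The pipeline goes: PCR-duplicate
collapse → barcode demultiplexing → adapter trimming → transcriptome
alignment that models one 1-nt deletion per read → per-transcript
coverage/deletion profiles → order-20 local-maximum peak calling with a
within-transcript permutation FDR screen → per-gene peak scores in rpm,
averaged over two replicates and normalized by mean FPKM → a ranked
target list → deletion-centered degenerate motif discovery (DREME-style
exact words generalized to IUPAC codes, widths 6–10, shuffled background,
E < 0.05, given strand only) with a positional test for concentration at
the crosslink.

The stability question is answered from SLAM-seq time courses: 4SU-labeled
uridines read as T→C conversions, and after the chase the conversion rate
of a transcript with half-life t½ decays as r(t) = r₀·2^(−t/t½).
Technical replicates are pooled by summing counts, rates are normalized to
t = 0, and y(t) = e^(−λt) is fitted by non-linear least squares with
λ ≥ 0; t½ = ln 2 / λ. Bound (top-N ranked) and unbound (peak-free)
transcripts are then compared on half-life and expression log₂ fold
change with two-sided Mann–Whitney U tests.

Because the original sequencing libraries are not bundled, the package
ships a first-class synthetic-data generator that plants known crosslink
sites (an AUKAAWU-family motif, mostly in 3'UTRs), expression-dependent
read depth, PCR duplication, and binomial T→C conversion counts — every
pipeline stage is tested by recovering what was planted.

## Worked example

Fitting the first-order decay model to two median conversion-rate curves
(timepoints 0, 30, 60, 120, 540, 1440 minutes; values normalized to t=0):

```python
import numpy as np
from crac_decay import decay

t = np.array([0.0, 30.0, 60.0, 120.0, 540.0, 1440.0])
for label, y in [
    ("bound", (1.0000, 0.8909, 0.7937, 0.6300, 0.1250, 0.0039)),
    ("all",   (1.0000, 0.9113, 0.8306, 0.6898, 0.1881, 0.0116)),
]:
    y = np.asarray(y)
    series = decay.ConversionSeries(label, t, y, y / y[0], np.full(6, 5000.0))
    fit = decay.fit_decay(series)
    print(f"{label}: t1/2 = {fit.t_half:.1f} min ({fit.status.value})")
```

prints

```
bound: t1/2 = 180.0 min (ok)
all: t1/2 = 224.0 min (ok)
```

i.e. the bound cohort turns over ~20% faster than the transcriptome-wide
median — the signature of an RBP that recruits deadenylation machinery to
its targets.

The CRAC arm runs end to end from the command line on simulated data:

```
crac-decay simulate --outdir sim --seed 3
crac-decay preprocess --fastq sim/crac_rep1.fastq \
    --barcodes ACGT,TGAC --adapter TGGAATTCTCGGGTGCCAAGG --outdir prep1
crac-decay align --fastq prep1/trimmed_ACGT.fastq \
    --fasta sim/transcriptome.fa --gtf sim/annotation.gtf --out-sam rep1.sam
# ... same for rep2, then:
crac-decay rank --sam rep1.sam --sam rep2.sam --gtf sim/annotation.gtf \
    --expression sim/expression.tsv --top-n 60 --out ranking.tsv
crac-decay motif --sam rep1.sam --fasta sim/transcriptome.fa \
    --ranking ranking.tsv --gtf sim/annotation.gtf --top-n 60 \
    --flank 10 --out motifs.meme
```

On a small simulation the motif step prints, among others:

```
AUKAAWU  width=7  E=1.26e-111  central_p=2.91e-66  sites=198
```

— the planted consensus recovered exactly (K = G/U, W = A/U), with its
matches overwhelmingly covering the crosslinked base (`central_p` is the
binomial p for concentration at the deletion), and an E-value far below
the 0.05 reporting threshold.

`crac-decay slam` fits half-lives from a conversion-count table and
`crac-decay compare` runs the bound-vs-unbound comparison; see
`docs/methods.md` for the models, parameter defaults and their rationale,
and the limits of what the synthetic benchmarks demonstrate.

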