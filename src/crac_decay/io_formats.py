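"""File formats and the coordinate conventions shared by the whole pipeline.

Everything internal is 0-based, half-open, 5'->3' on the mature transcript.
Conversions to/from 1-based conventions (GTF, SAM) happen only at file
boundaries. Only transcript-space alignments are handled: reads are mapped
to mature transcript sequences, so spliced CIGAR ops (``N``) are rejected
rather than silently skipped.
"""

from __future__ import annotations

import enum
from collections.abc import Iterable, Iterator, Mapping
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class Biotype(str, enum.Enum):
    """RNA class of a transcript (mRNA carries a 5'UTR/CDS/3'UTR partition)."""

    mRNA = "mRNA"
    rRNA = "rRNA"
    tRNA = "tRNA"
    snoRNA = "snoRNA"
    snRNA = "snRNA"
    miscRNA = "miscRNA"
    other = "other"


class Region(str, enum.Enum):
    UTR5 = "UTR5"
    CDS = "CDS"
    UTR3 = "UTR3"
    NA = "NA"


@dataclass(frozen=True)
class TranscriptModel:
    """Transcript-space gene model: biotype plus region segment lengths.

    For mRNA the three segments tile the transcript exactly
    (``utr5_len + cds_len + utr3_len == sequence_length``); non-mRNA
    biotypes carry zero-length segments and only a total length.
    """

    transcript_id: str
    gene_id: str
    biotype: Biotype
    utr5_len: int
    cds_len: int
    utr3_len: int
    sequence_length: int

    def __post_init__(self) -> None:
        if self.sequence_length <= 0:
            raise ValueError(
                f"{self.transcript_id}: sequence_length must be positive"
            )
        if min(self.utr5_len, self.cds_len, self.utr3_len) < 0:
            raise ValueError(f"{self.transcript_id}: negative segment length")
        if self.biotype is Biotype.mRNA:
            total = self.utr5_len + self.cds_len + self.utr3_len
            if total != self.sequence_length:
                raise ValueError(
                    f"{self.transcript_id}: mRNA segments sum to {total}, "
                    f"expected {self.sequence_length}"
                )
        else:
            if self.utr5_len or self.cds_len or self.utr3_len:
                raise ValueError(
                    f"{self.transcript_id}: non-mRNA biotype must have "
                    "zero-length UTR/CDS segments"
                )

    def region_of(self, position: int) -> Region:
        """Region containing a 0-based transcript position.

        Boundaries are half-open: ``[0, utr5)`` is UTR5, ``[utr5,
        utr5+cds)`` is CDS, the rest UTR3. Non-mRNA positions map to NA.
        """
        if not 0 <= position < self.sequence_length:
            raise ValueError(
                f"position {position} outside {self.transcript_id} "
                f"(length {self.sequence_length})"
            )
        if self.biotype is not Biotype.mRNA:
            return Region.NA
        if position < self.utr5_len:
            return Region.UTR5
        if position < self.utr5_len + self.cds_len:
            return Region.CDS
        return Region.UTR3


@dataclass
class SequencedRead:
    read_id: str
    sequence: str
    qualities: Optional[list[int]] = None

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"{self.read_id}: empty sequence")
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ValueError(f"{self.read_id}: quality/sequence length mismatch")


# CIGAR ops supported in transcript space.
CIGAR_OPS = ("M", "D", "I", "S")
_PYSAM_OP = {0: "M", 1: "I", 2: "D", 4: "S"}
_PYSAM_CODE = {v: k for k, v in _PYSAM_OP.items()}
_PYSAM_OP_NAMES = {3: "N", 5: "H", 6: "P", 7: "=", 8: "X"}


@dataclass(frozen=True)
class ReadAlignment:
    """A read placed on a transcript; strand is always transcript-forward."""

    read_id: str
    transcript_id: str
    start: int  # 0-based on the transcript
    cigar: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"{self.read_id}: negative start")
        prev = None
        for op, length in self.cigar:
            if op not in CIGAR_OPS:
                raise ValueError(f"{self.read_id}: unsupported CIGAR op {op!r}")
            if length < 1:
                raise ValueError(f"{self.read_id}: CIGAR length < 1")
            if op == prev:
                raise ValueError(f"{self.read_id}: adjacent identical CIGAR ops")
            prev = op

    @property
    def footprint(self) -> int:
        """Reference span: total M and D length."""
        return sum(n for op, n in self.cigar if op in ("M", "D"))

    @property
    def end(self) -> int:
        return self.start + self.footprint

    def deletion_positions(self) -> list[tuple[int, int]]:
        """(transcript position of first deleted base, deletion length) per D op."""
        out = []
        pos = self.start
        for op, n in self.cigar:
            if op == "D":
                out.append((pos, n))
            if op in ("M", "D"):
                pos += n
        return out


class AnnotationError(ValueError):
    pass


@dataclass
class RejectedTranscript:
    transcript_id: str
    reason: str


@dataclass
class AnnotationResult:
    models: dict[str, TranscriptModel]
    rejected: list[RejectedTranscript] = field(default_factory=list)


_FEATURE_REGION = {
    "five_prime_utr": "utr5",
    "CDS": "cds",
    "three_prime_utr": "utr3",
}


def _parse_gtf_attributes(text: str, line_no: int) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in text.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        parts = chunk.split(None, 1)
        if len(parts) != 2:
            raise AnnotationError(
                f"line {line_no}: malformed attribute field {chunk!r}"
            )
        key, value = parts
        attrs[key] = value.strip().strip('"')
    return attrs


def load_annotation(path) -> AnnotationResult:
    """Parse a transcript-space GTF subset into TranscriptModel records.

    Expected features: ``transcript`` (with ``biotype`` attribute) plus, for
    mRNA, ``five_prime_utr`` / ``CDS`` / ``three_prime_utr`` whose 1-based
    inclusive spans are summed per transcript. Transcripts violating the
    model invariants are not dropped silently: they are returned in
    ``rejected`` with a reason.
    """
    lengths: dict[str, dict[str, int]] = {}
    meta: dict[str, tuple[str, str, int]] = {}  # tid -> (gene, biotype, length)
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise AnnotationError(
                    f"line {line_no}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            feature, start_s, end_s, attr_text = (
                fields[2],
                fields[3],
                fields[4],
                fields[8],
            )
            attrs = _parse_gtf_attributes(attr_text, line_no)
            try:
                tid = attrs["transcript_id"]
            except KeyError:
                raise AnnotationError(
                    f"line {line_no}: missing transcript_id attribute"
                ) from None
            start_1, end_1 = int(start_s), int(end_s)
            # 1-based inclusive -> 0-based half-open span length
            span = (end_1) - (start_1 - 1)
            if feature == "transcript":
                if tid in meta:
                    raise AnnotationError(
                        f"line {line_no}: duplicated transcript_id {tid!r}"
                    )
                gene = attrs.get("gene_id", tid)
                biotype = attrs.get("biotype", "other")
                meta[tid] = (gene, biotype, span)
            elif feature in _FEATURE_REGION:
                bucket = lengths.setdefault(
                    tid, {"utr5": 0, "cds": 0, "utr3": 0}
                )
                bucket[_FEATURE_REGION[feature]] += span
    result = AnnotationResult(models={})
    for tid, (gene, biotype_s, total) in meta.items():
        segs = lengths.get(tid, {"utr5": 0, "cds": 0, "utr3": 0})
        try:
            biotype = Biotype(biotype_s)
        except ValueError:
            biotype = Biotype.other
        try:
            model = TranscriptModel(
                transcript_id=tid,
                gene_id=gene,
                biotype=biotype,
                utr5_len=segs["utr5"],
                cds_len=segs["cds"],
                utr3_len=segs["utr3"],
                sequence_length=total,
            )
        except ValueError as exc:
            result.rejected.append(RejectedTranscript(tid, str(exc)))
            continue
        result.models[tid] = model
    return result


def write_annotation(models: Mapping[str, TranscriptModel], path) -> None:
    """Emit the GTF subset read by :func:`load_annotation` (round-trippable)."""
    with open(path, "w") as fh:
        for m in models.values():
            attrs = (
                f'transcript_id "{m.transcript_id}"; gene_id "{m.gene_id}"; '
                f'biotype "{m.biotype.value}";'
            )
            def row(feature: str, start0: int, end0: int) -> str:
                # 0-based half-open -> 1-based inclusive
                return (
                    f"{m.transcript_id}\tcrac_decay\t{feature}\t{start0 + 1}"
                    f"\t{end0}\t.\t+\t.\t{attrs}\n"
                )
            fh.write(row("transcript", 0, m.sequence_length))
            if m.biotype is Biotype.mRNA:
                a, b = 0, m.utr5_len
                if b > a:
                    fh.write(row("five_prime_utr", a, b))
                a, b = b, b + m.cds_len
                if b > a:
                    fh.write(row("CDS", a, b))
                a, b = b, b + m.utr3_len
                if b > a:
                    fh.write(row("three_prime_utr", a, b))


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


class FastqError(ValueError):
    pass


def read_fastq(path) -> Iterator[SequencedRead]:
    """Stream 4-line FASTQ records; truncation reports the record index."""
    index = 0
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            yield SequencedRead(
                read_id=rec.id,
                sequence=str(rec.seq),
                qualities=list(rec.letter_annotations["phred_quality"]),
            )
            index += 1
    except ValueError as exc:
        raise FastqError(f"truncated/malformed FASTQ record {index}: {exc}") from exc


def write_fastq(reads: Iterable[SequencedRead], path) -> None:
    with open(path, "w") as fh:
        for read in reads:
            quals = read.qualities
            if quals is None:
                quals = [40] * len(read.sequence)
            qual_s = "".join(chr(q + 33) for q in quals)
            fh.write(f"@{read.read_id}\n{read.sequence}\n+\n{qual_s}\n")


# ---------------------------------------------------------------------------
# SAM


class SamError(ValueError):
    pass


def read_sam(path, models: Optional[Mapping[str, TranscriptModel]] = None):
    """Yield ReadAlignment for primary mapped records of a text SAM file.

    Secondary/supplementary/unmapped records are skipped. CIGAR ops outside
    {M, D, I, S} (e.g. the spliced-alignment op N) raise SamError naming the
    op; a reference absent from the supplied models raises SamError.
    """
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            tid = rec.reference_name
            if models is not None and tid not in models:
                raise SamError(
                    f"{rec.query_name}: unknown transcript {tid!r}"
                )
            ops = []
            for code, length in rec.cigartuples or []:
                if code not in _PYSAM_OP:
                    name = _PYSAM_OP_NAMES.get(code, str(code))
                    raise SamError(
                        f"{rec.query_name}: unsupported CIGAR op {name!r}"
                    )
                ops.append((_PYSAM_OP[code], length))
            yield ReadAlignment(
                read_id=rec.query_name,
                transcript_id=tid,
                start=rec.reference_start,  # pysam is already 0-based
                cigar=tuple(ops),
            )


def write_sam(
    alignments: Iterable[ReadAlignment],
    models: Mapping[str, TranscriptModel],
    path,
    sequences: Optional[Mapping[str, str]] = None,
    program: Optional[dict] = None,
) -> None:
    """Write alignments as text SAM with @SQ headers from the models."""
    order = list(models)
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [
            {"SN": tid, "LN": models[tid].sequence_length} for tid in order
        ],
    }
    if program:
        header["PG"] = [program]
    index = {tid: i for i, tid in enumerate(order)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for aln in alignments:
            if aln.transcript_id not in index:
                raise SamError(
                    f"{aln.read_id}: unknown transcript {aln.transcript_id!r}"
                )
            rec = pysam.AlignedSegment(out.header)
            rec.query_name = aln.read_id
            rec.reference_id = index[aln.transcript_id]
            rec.reference_start = aln.start
            rec.mapping_quality = 255
            rec.cigartuples = [(_PYSAM_CODE[op], n) for op, n in aln.cigar]
            if sequences is not None and aln.read_id in sequences:
                rec.query_sequence = sequences[aln.read_id]
            out.write(rec)


# ---------------------------------------------------------------------------
# bedGraph


def coverage_to_bedgraph_intervals(
    coverage: np.ndarray,
) -> list[tuple[int, int, float]]:
    """Run-length encode a coverage vector, dropping zero runs.

    Adjacent equal-value intervals are merged by construction of the RLE.
    """
    cov = np.asarray(coverage)
    if cov.size == 0:
        return []
    change = np.flatnonzero(np.diff(cov) != 0) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [cov.size]))
    return [
        (int(s), int(e), float(cov[s]))
        for s, e in zip(starts, ends)
        if cov[s] != 0
    ]


def write_coverage_bedgraph(profiles: Mapping[str, np.ndarray], path) -> None:
    """Write per-transcript coverage vectors as 0-based half-open bedGraph."""
    with open(path, "w") as fh:
        for tid, coverage in profiles.items():
            for start, end, value in coverage_to_bedgraph_intervals(coverage):
                if value == int(value):
                    value = int(value)
                fh.write(f"{tid}\t{start}\t{end}\t{value}\n")
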