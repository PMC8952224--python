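"""Candidate lncRNA discovery: the five-step structural/expression filter
with an in-house coding-potential consensus.

The filter, applied strictly in order with the first failure recorded:

1. exon structure — single-exon transcripts removed;
2. size — spliced length must exceed 200 nt (and exon count meet the
   configured minimum, default >= 2);
3. annotation — transcripts whose exonic bases overlap a reference
   protein-coding transcript on the same strand by more than 50% are
   removed; matches to reference lncRNAs are kept and labeled ``known``;
4. expression — maximum per-sample FPKM must reach 0.5;
5. coding potential — the ORF/Fickett consensus must call ``noncoding``.

Coding potential combines two independent signals, mirroring multi-tool
consensus filtering: a transcript is called coding when EITHER its longest
sense-strand ORF reaches 300 nt OR its Fickett TESTCODE score reaches 0.95;
both must be weak for a ``noncoding`` call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix, TranscriptModel

__all__ = [
    "CodingPotentialReport",
    "FilterTrace",
    "FilterConfig",
    "longest_orf",
    "fickett_score",
    "consensus_coding",
    "coding_report",
    "filter_candidates",
]

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

# Fickett (1982) TESTCODE lookup tables, as reproduced in CPAT.
# Position parameter: for each base, max over the three codon-phase counts
# divided by (min + 1); content parameter: base fraction of the sequence.
# The first bin matching value >= threshold supplies the probability.
_POSITION_BINS = (1.9, 1.8, 1.7, 1.6, 1.5, 1.4, 1.3, 1.2, 1.1, 0.0)
_CONTENT_BINS = (0.33, 0.31, 0.29, 0.27, 0.25, 0.23, 0.21, 0.19, 0.17, 0.0)
_POSITION_PROB = {
    "A": (0.94, 0.68, 0.84, 0.93, 0.58, 0.68, 0.45, 0.34, 0.20, 0.22),
    "C": (0.80, 0.70, 0.70, 0.81, 0.66, 0.48, 0.51, 0.33, 0.30, 0.23),
    "G": (0.90, 0.88, 0.74, 0.64, 0.53, 0.48, 0.27, 0.16, 0.08, 0.08),
    "T": (0.97, 0.97, 0.91, 0.68, 0.69, 0.44, 0.54, 0.20, 0.09, 0.09),
}
_POSITION_WEIGHT = {"A": 0.26, "C": 0.18, "G": 0.31, "T": 0.33}
_CONTENT_PROB = {
    "A": (0.28, 0.49, 0.44, 0.55, 0.62, 0.49, 0.67, 0.65, 0.81, 0.21),
    "C": (0.82, 0.64, 0.51, 0.64, 0.59, 0.59, 0.43, 0.44, 0.39, 0.31),
    "G": (0.40, 0.54, 0.47, 0.64, 0.64, 0.73, 0.41, 0.41, 0.33, 0.29),
    "T": (0.28, 0.24, 0.39, 0.40, 0.55, 0.75, 0.56, 0.69, 0.51, 0.58),
}
_CONTENT_WEIGHT = {"A": 0.11, "C": 0.12, "G": 0.15, "T": 0.14}

FICKETT_CODING_CUTOFF = 0.95
ORF_CODING_CUTOFF_NT = 300
MIN_FICKETT_LENGTH = 200


@dataclass(frozen=True)
class CodingPotentialReport:
    transcript_id: str
    longest_orf_nt: int
    fickett_score: float
    orf_vote: str  # coding | noncoding
    fickett_vote: str
    consensus: str


@dataclass(frozen=True)
class FilterTrace:
    transcript_id: str
    step_failed: int | None  # 1..5, or None when passed
    reason: str


@dataclass(frozen=True)
class FilterConfig:
    min_exons: int = 2
    min_length_nt: int = 200  # spliced length must exceed this
    max_coding_overlap: float = 0.5  # fraction of candidate exonic bases
    min_fpkm: float = 0.5
    orf_cutoff_nt: int = ORF_CODING_CUTOFF_NT
    fickett_cutoff: float = FICKETT_CODING_CUTOFF


def _normalize(sequence: str) -> str:
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper().replace("U", "T")
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"non-nucleotide characters in sequence: {sorted(bad)}")
    return seq


def longest_orf(sequence: str) -> int:
    """Longest ATG-to-stop open reading frame, sense strand, 3 frames.

    Returns the ORF length in nucleotides including the stop codon; 0 when
    no complete ORF exists. Accepts DNA or RNA alphabets (U read as T).
    """
    seq = _normalize(sequence)
    best = 0
    for frame in range(3):
        start: int | None = None
        for i in range(frame, len(seq) - 2, 3):
            codon = seq[i : i + 3]
            if start is None:
                if codon == "ATG":
                    start = i
            elif codon in STOP_CODONS:
                best = max(best, i + 3 - start)
                start = None
    return best


def fickett_score(sequence: str) -> float:
    """Fickett TESTCODE statistic from the published lookup tables.

    Sum over the four bases of position probability x weight plus content
    probability x weight. Requires at least 200 nt. Not strand-symmetric:
    the reverse complement of a sequence generally scores differently.
    """
    seq = _normalize(sequence)
    if len(seq) < MIN_FICKETT_LENGTH:
        raise ValueError(
            f"fickett_score needs >= {MIN_FICKETT_LENGTH} nt, got {len(seq)}"
        )
    score = 0.0
    n = len(seq)
    for base in "ACGT":
        phase_counts = [
            sum(1 for i in range(p, n, 3) if seq[i] == base) for p in range(3)
        ]
        position_value = max(phase_counts) / (min(phase_counts) + 1)
        content_value = sum(phase_counts) / n
        for bins, probs, weights, value in (
            (_POSITION_BINS, _POSITION_PROB, _POSITION_WEIGHT, position_value),
            (_CONTENT_BINS, _CONTENT_PROB, _CONTENT_WEIGHT, content_value),
        ):
            for k, threshold in enumerate(bins):
                if value >= threshold:
                    score += probs[base][k] * weights[base]
                    break
    return score


def consensus_coding(report: CodingPotentialReport) -> str:
    """Coding iff either signal is strong; noncoding needs both weak."""
    if report.orf_vote == "coding" or report.fickett_vote == "coding":
        return "coding"
    return "noncoding"


def coding_report(
    transcript_id: str,
    sequence: str,
    orf_cutoff_nt: int = ORF_CODING_CUTOFF_NT,
    fickett_cutoff: float = FICKETT_CODING_CUTOFF,
) -> CodingPotentialReport:
    orf = longest_orf(sequence)
    fick = fickett_score(sequence)
    orf_vote = "coding" if orf >= orf_cutoff_nt else "noncoding"
    fickett_vote = "coding" if fick >= fickett_cutoff else "noncoding"
    consensus = "coding" if (orf_vote == "coding" or fickett_vote == "coding") else "noncoding"
    return CodingPotentialReport(
        transcript_id, orf, fick, orf_vote, fickett_vote, consensus
    )


def _exonic_overlap_fraction(
    candidate: TranscriptModel, reference: TranscriptModel
) -> float:
    """Fraction of the candidate's exonic bases covered by the reference's
    exons, same chromosome and strand only."""
    if (
        candidate.chromosome != reference.chromosome
        or candidate.strand != reference.strand
    ):
        return 0.0
    covered = 0
    for (cs, ce) in candidate.exons:
        for (rs, re_) in reference.exons:
            lo, hi = max(cs, rs), min(ce, re_)
            if lo <= hi:
                covered += hi - lo + 1
    return covered / candidate.spliced_length


def filter_candidates(
    transcripts: Sequence[TranscriptModel],
    fpkm: ExpressionMatrix,
    reference: Sequence[TranscriptModel],
    config: FilterConfig = FilterConfig(),
) -> tuple[list[TranscriptModel], list[FilterTrace], pd.DataFrame]:
    """Run the five-step filter over candidate transcripts.

    Returns the surviving transcripts (order preserved), one FilterTrace per
    input transcript, and the coding-potential report table for transcripts
    that reached step 5. Survivors matching a reference lncRNA are relabeled
    ``known_lncRNA``. Transcripts must all be present in the FPKM matrix and
    carry sequences for the coding-potential step.
    """
    missing = [t.transcript_id for t in transcripts if t.transcript_id not in fpkm.values.index]
    if missing:
        raise ValueError(f"transcripts missing from FPKM: {missing[:10]}")
    ref_coding = [r for r in reference if r.biotype == "protein_coding"]
    ref_lnc = [r for r in reference if r.biotype == "known_lncRNA"]
    ref_by_chrom: dict[tuple[str, str], list[TranscriptModel]] = {}
    for r in ref_coding:
        ref_by_chrom.setdefault((r.chromosome, r.strand), []).append(r)
    lnc_by_chrom: dict[tuple[str, str], list[TranscriptModel]] = {}
    for r in ref_lnc:
        lnc_by_chrom.setdefault((r.chromosome, r.strand), []).append(r)

    survivors: list[TranscriptModel] = []
    traces: list[FilterTrace] = []
    reports: list[CodingPotentialReport] = []
    for t in transcripts:
        # step 1: single-exon transcripts out
        if t.exon_count < 2:
            traces.append(FilterTrace(t.transcript_id, 1, "single-exon transcript"))
            continue
        # step 2: size / exon-count selection
        if t.spliced_length <= config.min_length_nt or t.exon_count < config.min_exons:
            traces.append(
                FilterTrace(
                    t.transcript_id,
                    2,
                    f"spliced length {t.spliced_length} nt / "
                    f"{t.exon_count} exons below cutoff",
                )
            )
            continue
        # step 3: known-annotation screen
        key = (t.chromosome, t.strand)
        coding_overlap = max(
            (_exonic_overlap_fraction(t, r) for r in ref_by_chrom.get(key, [])),
            default=0.0,
        )
        if coding_overlap > config.max_coding_overlap:
            traces.append(
                FilterTrace(
                    t.transcript_id,
                    3,
                    f"{coding_overlap:.0%} exonic overlap with reference "
                    "protein-coding transcript",
                )
            )
            continue
        known = (
            max(
                (_exonic_overlap_fraction(t, r) for r in lnc_by_chrom.get(key, [])),
                default=0.0,
            )
            > config.max_coding_overlap
        ) or t.biotype == "known_lncRNA"
        # step 4: expression level
        max_fpkm = float(fpkm.values.loc[t.transcript_id].max())
        if max_fpkm < config.min_fpkm:
            traces.append(
                FilterTrace(
                    t.transcript_id, 4, f"max FPKM {max_fpkm:.3g} below {config.min_fpkm}"
                )
            )
            continue
        # step 5: coding potential
        if t.sequence is None:
            raise ValueError(f"transcript {t.transcript_id} reached the coding-"
                             "potential step without a sequence")
        rep = coding_report(
            t.transcript_id, t.sequence, config.orf_cutoff_nt, config.fickett_cutoff
        )
        reports.append(rep)
        if rep.consensus == "coding":
            traces.append(
                FilterTrace(
                    t.transcript_id,
                    5,
                    f"coding potential (ORF {rep.longest_orf_nt} nt, "
                    f"Fickett {rep.fickett_score:.2f})",
                )
            )
            continue
        out = t
        if known and t.biotype != "known_lncRNA":
            out = TranscriptModel(
                t.transcript_id, t.gene_id, t.chromosome, t.strand, t.start,
                t.end, list(t.exons), "known_lncRNA", t.sequence,
            )
        survivors.append(out)
        traces.append(FilterTrace(t.transcript_id, None, "passed"))

    report_df = pd.DataFrame(
        [
            {
                "transcript_id": r.transcript_id,
                "longest_orf_nt": r.longest_orf_nt,
                "fickett_score": r.fickett_score,
                "orf_vote": r.orf_vote,
                "fickett_vote": r.fickett_vote,
                "consensus": r.consensus,
            }
            for r in reports
        ]
    )
    return survivors, traces, report_df
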