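"""Multi-filter lncRNA classification and trans-correlation linking.

A transcript is called a lncRNA when it is either already annotated with
the lncRNA biotype, or passes every filter: spliced length > 200 nt,
at least two exons, and *unanimously* non-coding votes from three
independent coding-potential predictors (longest-ORF metrics, the
Fickett TESTCODE statistic, and an in-frame hexamer usage
log-likelihood ratio trained on coding vs non-coding corpora).

Trans-acting lncRNA-mRNA links are inferred from Pearson correlation of
log-transformed expression profiles.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

from .models import GenomeAnnotation, GenomeSequence, TranscriptModel, revcomp

STOP_CODONS = {"TAA", "TAG", "TGA"}

# Cutoffs for the ORF vote: conventional CPAT-style thresholds.
ORF_LENGTH_CUTOFF = 100      # codons
ORF_COVERAGE_CUTOFF = 0.5
FICKETT_CUTOFF = 0.95
MIN_LNCRNA_LENGTH = 200      # nt, strict ">"
MIN_EXONS = 2

# Fickett (1982) TESTCODE lookup tables: probability that a window with a
# given position/composition parameter is coding, and the weight of each
# parameter. Rows run from the highest parameter bucket to the lowest.
_POSITION_PROB = {
    "A": [0.94, 0.68, 0.84, 0.93, 0.58, 0.68, 0.45, 0.34, 0.20, 0.22],
    "C": [0.80, 0.70, 0.70, 0.81, 0.66, 0.48, 0.51, 0.33, 0.30, 0.23],
    "G": [0.90, 0.88, 0.74, 0.64, 0.53, 0.48, 0.27, 0.16, 0.08, 0.08],
    "T": [0.97, 0.97, 0.91, 0.68, 0.69, 0.44, 0.54, 0.20, 0.09, 0.09],
}
_POSITION_WEIGHT = {"A": 0.26, "C": 0.18, "G": 0.31, "T": 0.33}
_POSITION_EDGES = [1.9, 1.8, 1.7, 1.6, 1.5, 1.4, 1.3, 1.2, 1.1, 0.0]

_CONTENT_PROB = {
    "A": [0.28, 0.49, 0.44, 0.55, 0.62, 0.49, 0.67, 0.65, 0.81, 0.21],
    "C": [0.82, 0.64, 0.51, 0.64, 0.59, 0.59, 0.43, 0.44, 0.39, 0.31],
    "G": [0.40, 0.54, 0.47, 0.64, 0.64, 0.73, 0.41, 0.41, 0.33, 0.29],
    "T": [0.28, 0.24, 0.39, 0.40, 0.55, 0.75, 0.56, 0.69, 0.51, 0.58],
}
_CONTENT_WEIGHT = {"A": 0.11, "C": 0.12, "G": 0.15, "T": 0.14}
_CONTENT_EDGES = [0.33, 0.31, 0.29, 0.27, 0.25, 0.23, 0.21, 0.19, 0.17, 0.0]


@dataclass
class OrfResult:
    length_codons: int
    start: int       # 0-based offset of the ATG in the sense sequence
    frame: int
    coverage: float


@dataclass
class HexamerModel:
    """Add-one-smoothed in-frame hexamer frequencies for two corpora."""

    log_ratio: dict[str, float] = field(default_factory=dict)


@dataclass
class CodingPotentialReport:
    transcript_id: str
    spliced_length: int
    exon_count: int
    orf_length: int
    orf_coverage: float
    fickett_score: float
    hexamer_llr: float
    votes: dict[str, str] = field(default_factory=dict)
    final_label: str = "coding"

    def __post_init__(self):
        if not 0.0 <= self.orf_coverage <= 1.0:
            raise ValueError("orf_coverage outside [0, 1]")


@dataclass
class TransPair:
    lncrna_id: str
    target_gene_id: str
    r: float
    sign: str  # positive | negative


def spliced_sequence(annotation: GenomeAnnotation, genome: GenomeSequence,
                     transcript_id: str) -> str:
    """Exonic sequence of a transcript, 5'->3' on the coding strand."""
    if transcript_id not in annotation.transcripts:
        raise KeyError(f"unknown transcript {transcript_id!r}")
    t = annotation.transcripts[transcript_id]
    seq = "".join(genome.fetch(t.chrom, s, e) for s, e in t.exons)
    return revcomp(seq) if t.strand == "-" else seq


def spliced_cds(annotation: GenomeAnnotation, genome: GenomeSequence,
                transcript_id: str) -> str:
    t = annotation.transcripts[transcript_id]
    seq = "".join(genome.fetch(t.chrom, s, e) for s, e in t.cds_segments)
    return revcomp(seq) if t.strand == "-" else seq


def longest_orf(seq: str) -> OrfResult:
    """Longest ATG..stop reading frame over the three sense-strand frames.

    The reported length in codons includes the start codon and excludes
    the stop; coverage is the ORF's nucleotide footprint (stop included
    when present) divided by the sequence length. An ORF running off the
    3' end without a stop is counted up to the last complete codon.
    """
    seq = seq.upper()
    n = len(seq)
    best = OrfResult(0, -1, -1, 0.0)
    for frame in range(3):
        start: int | None = None
        for i in range(frame, n - 2, 3):
            codon = seq[i:i + 3]
            if start is None:
                if codon == "ATG":
                    start = i
            elif codon in STOP_CODONS:
                length = (i - start) // 3
                if length > best.length_codons:
                    footprint = i + 3 - start
                    best = OrfResult(length, start, frame, footprint / n)
                start = None
        if start is not None:  # open-ended ORF at the 3' end
            last = frame + ((n - frame) // 3) * 3
            length = (last - start) // 3
            if length > best.length_codons:
                best = OrfResult(length, start, frame, (last - start) / n)
    return best


def _lookup(value: float, edges: list[float], probs: list[float]) -> float:
    for edge, prob in zip(edges, probs):
        if value >= edge:
            return prob
    return probs[-1]


def fickett_score(seq: str) -> float:
    """Fickett TESTCODE statistic from base position bias and composition."""
    seq = seq.upper()
    if len(seq) < 200:
        raise ValueError("Fickett statistic requires >= 200 nt")
    score = 0.0
    for base in "ACGT":
        phase_counts = [seq[k::3].count(base) for k in range(3)]
        position_value = max(phase_counts) / (min(phase_counts) + 1)
        score += _lookup(position_value, _POSITION_EDGES,
                         _POSITION_PROB[base]) * _POSITION_WEIGHT[base]
        content = seq.count(base) / len(seq)
        score += _lookup(content, _CONTENT_EDGES,
                         _CONTENT_PROB[base]) * _CONTENT_WEIGHT[base]
    return score


def _inframe_hexamers(seq: str):
    for i in range(0, len(seq) - 5, 3):
        yield seq[i:i + 6]


def train_hexamer_model(coding_seqs: list[str],
                        noncoding_seqs: list[str]) -> HexamerModel:
    """In-frame hexamer frequency tables with add-one smoothing."""
    if not coding_seqs or not noncoding_seqs:
        raise ValueError("both training corpora must be non-empty")
    alphabet = ["".join(h) for h in product("ACGT", repeat=6)]

    def freqs(seqs: list[str]) -> dict[str, float]:
        counts = dict.fromkeys(alphabet, 1.0)
        for s in seqs:
            for h in _inframe_hexamers(s.upper()):
                if h in counts:
                    counts[h] += 1.0
        total = sum(counts.values())
        return {h: c / total for h, c in counts.items()}

    fc = freqs(coding_seqs)
    fn = freqs(noncoding_seqs)
    return HexamerModel({h: math.log(fc[h] / fn[h]) for h in alphabet})


def hexamer_llr(model: HexamerModel, seq: str) -> float:
    """Mean per-hexamer log(f_coding / f_noncoding) over in-frame 6-mers."""
    seq = seq.upper()
    if len(seq) < 6:
        raise ValueError("sequence shorter than one hexamer")
    vals = [model.log_ratio[h] for h in _inframe_hexamers(seq)
            if h in model.log_ratio]
    if not vals:
        raise ValueError("no scorable hexamers (ambiguous bases?)")
    return float(np.mean(vals))


def coding_potential_report(transcript: TranscriptModel, seq: str,
                            hexamer_model: HexamerModel
                            ) -> CodingPotentialReport:
    """Run the three predictors on a spliced sequence and collect votes."""
    orf = longest_orf(seq)
    orf_vote = ("coding" if orf.length_codons >= ORF_LENGTH_CUTOFF
                or orf.coverage >= ORF_COVERAGE_CUTOFF else "noncoding")
    if len(seq) >= 200:
        fickett = fickett_score(seq)
        fickett_vote = "coding" if fickett >= FICKETT_CUTOFF else "noncoding"
    else:
        # too short to be a lncRNA anyway; score for the record only
        fickett = float("nan")
        fickett_vote = "coding"
    llr = hexamer_llr(hexamer_model, seq) if len(seq) >= 6 else 0.0
    hex_vote = "coding" if llr > 0 else "noncoding"
    votes = {"orf": orf_vote, "fickett": fickett_vote, "hexamer": hex_vote}
    final = ("noncoding" if all(v == "noncoding" for v in votes.values())
             else "coding")
    return CodingPotentialReport(
        transcript_id=transcript.transcript_id,
        spliced_length=len(seq),
        exon_count=transcript.exon_count,
        orf_length=orf.length_codons,
        orf_coverage=orf.coverage,
        fickett_score=fickett,
        hexamer_llr=llr,
        votes=votes,
        final_label=final,
    )


def classify_lncrna(transcript: TranscriptModel,
                    report: CodingPotentialReport,
                    known_biotype: str | None = None) -> bool:
    """lncRNA iff annotated as such, or long + multi-exonic + unanimously
    non-coding by all three predictors."""
    biotype = known_biotype if known_biotype is not None else transcript.biotype
    if biotype == "lncRNA":
        return True
    return (report.spliced_length > MIN_LNCRNA_LENGTH
            and report.exon_count >= MIN_EXONS
            and report.final_label == "noncoding")


def trans_correlate(lnc_expr: pd.DataFrame, mrna_expr: pd.DataFrame,
                    threshold: float = 0.9) -> list[TransPair]:
    """All lncRNA-mRNA pairs with |Pearson r| >= threshold.

    Profiles are log2(count+1)-transformed; both frames must share the
    same sample columns (>= 3 samples). Zero-variance profiles cannot be
    correlated and are skipped with a warning.
    """
    if list(lnc_expr.columns) != list(mrna_expr.columns):
        raise ValueError("expression frames must share identical samples")
    if lnc_expr.shape[1] < 3:
        raise ValueError("need >= 3 samples for correlation")
    lx = np.log2(lnc_expr.to_numpy(dtype=float) + 1)
    mx = np.log2(mrna_expr.to_numpy(dtype=float) + 1)
    lv = lx.std(axis=1) > 0
    mv = mx.std(axis=1) > 0
    if (~lv).any() or (~mv).any():
        warnings.warn(
            f"skipping {int((~lv).sum())} lncRNA and {int((~mv).sum())} "
            "mRNA zero-variance profiles")
    pairs: list[TransPair] = []
    lz = (lx[lv] - lx[lv].mean(axis=1, keepdims=True))
    mz = (mx[mv] - mx[mv].mean(axis=1, keepdims=True))
    lz /= np.linalg.norm(lz, axis=1, keepdims=True)
    mz /= np.linalg.norm(mz, axis=1, keepdims=True)
    r = lz @ mz.T
    lids = np.asarray(lnc_expr.index)[lv]
    mids = np.asarray(mrna_expr.index)[mv]
    for i, j in zip(*np.nonzero(np.abs(r) >= threshold)):
        val = float(np.clip(r[i, j], -1.0, 1.0))
        pairs.append(TransPair(str(lids[i]), str(mids[j]), val,
                               "positive" if val >= 0 else "negative"))
    return pairs
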