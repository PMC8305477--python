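"""Core domain types shared by every pipeline stage.

All genomic intervals are 0-based half-open internally. The on-disk
conventions (GFF3 1-based inclusive, VCF 1-based positions) are converted
at the I/O boundary and nowhere else.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

VALID_BASES = set("ACGTN")
STRANDS = ("+", "-")
BIOTYPES = ("protein_coding", "lncRNA", "novel", "other")

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase nucleotide string."""
    return seq.translate(COMPLEMENT)[::-1]


class GenomeSequence:
    """Uppercased nucleotide sequences keyed by chromosome name."""

    def __init__(self, sequences: Mapping[str, str]):
        self._seqs: dict[str, str] = {}
        for chrom, seq in sequences.items():
            seq = seq.upper()
            if not seq:
                raise ValueError(f"empty sequence for chromosome {chrom!r}")
            bad = set(seq) - VALID_BASES
            if bad:
                raise ValueError(f"non-IUPAC characters {sorted(bad)} in {chrom!r}")
            self._seqs[chrom] = seq

    @property
    def chroms(self) -> list[str]:
        return list(self._seqs)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def length(self, chrom: str) -> int:
        return len(self._seqs[chrom])

    def sequence(self, chrom: str) -> str:
        return self._seqs[chrom]

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Bases in [start, end), 0-based half-open."""
        if not 0 <= start <= end <= len(self._seqs[chrom]):
            raise IndexError(f"{chrom}:{start}-{end} out of bounds")
        return self._seqs[chrom][start:end]

    def base(self, chrom: str, pos0: int) -> str:
        return self.fetch(chrom, pos0, pos0 + 1)

    def __eq__(self, other) -> bool:
        return isinstance(other, GenomeSequence) and self._seqs == other._seqs


@dataclass
class TranscriptModel:
    """A spliced transcript: exon structure plus optional CDS segments."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds_segments: list[tuple[int, int]] = field(default_factory=list)
    biotype: str = "other"

    def __post_init__(self):
        if self.strand not in STRANDS:
            raise ValueError(f"bad strand {self.strand!r}")
        if self.biotype not in BIOTYPES:
            raise ValueError(f"bad biotype {self.biotype!r}")
        self.exons = sorted(tuple(e) for e in self.exons)
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: no exons")
        prev_end = -1
        for s, e in self.exons:
            if s >= e:
                raise ValueError(f"{self.transcript_id}: empty exon [{s},{e})")
            if s < prev_end:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
            prev_end = e
        self.cds_segments = sorted(tuple(c) for c in self.cds_segments)
        for s, e in self.cds_segments:
            if not any(es <= s and e <= ee for es, ee in self.exons):
                raise ValueError(
                    f"{self.transcript_id}: CDS [{s},{e}) outside exonic space"
                )
        if self.biotype == "protein_coding" and self.cds_segments:
            if self.cds_length % 3 != 0:
                raise ValueError(
                    f"{self.transcript_id}: CDS length {self.cds_length} "
                    "not divisible by 3"
                )

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_segments)

    @property
    def exon_count(self) -> int:
        return len(self.exons)

    def contains(self, pos0: int) -> bool:
        return self.start <= pos0 < self.end

    def in_exon(self, pos0: int) -> bool:
        return any(s <= pos0 < e for s, e in self.exons)

    def in_cds(self, pos0: int) -> bool:
        return any(s <= pos0 < e for s, e in self.cds_segments)


@dataclass
class Gene:
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    transcript_ids: list[str] = field(default_factory=list)
    biotype: str = "other"


class GenomeAnnotation:
    """Transcript/gene catalogue with an interval index for overlap queries."""

    def __init__(self, transcripts: Iterable[TranscriptModel],
                 genes: Iterable[Gene] | None = None):
        self.transcripts: dict[str, TranscriptModel] = {}
        self.genes: dict[str, Gene] = {}
        txs = list(transcripts)
        if genes is not None:
            for g in genes:
                self.genes[g.gene_id] = g
        for t in txs:
            self.transcripts[t.transcript_id] = t
            if t.gene_id not in self.genes:
                self.genes[t.gene_id] = Gene(
                    gene_id=t.gene_id, chrom=t.chrom, strand=t.strand,
                    start=t.start, end=t.end, biotype=t.biotype,
                )
            g = self.genes[t.gene_id]
            if t.transcript_id not in g.transcript_ids:
                g.transcript_ids.append(t.transcript_id)
            g.start = min(g.start, t.start)
            g.end = max(g.end, t.end)
        for t in txs:
            if t.gene_id not in self.genes:
                raise ValueError(f"transcript {t.transcript_id}: unknown gene")
        self._index: dict[str, IntervalTree] = {}
        for t in txs:
            tree = self._index.setdefault(t.chrom, IntervalTree())
            tree.addi(t.start, t.end, t.transcript_id)

    def overlapping_transcripts(self, chrom: str, start: int,
                                end: int) -> list[TranscriptModel]:
        """Transcripts whose genomic span intersects [start, end)."""
        tree = self._index.get(chrom)
        if tree is None:
            return []
        hits = sorted(iv.data for iv in tree.overlap(start, end))
        return [self.transcripts[tid] for tid in hits]

    def splice_junctions(self, chrom: str) -> list[int]:
        """Internal exon boundaries (0-based positions of exon/intron edges)."""
        out = set()
        for t in self.transcripts.values():
            if t.chrom != chrom or t.exon_count < 2:
                continue
            for i, (s, e) in enumerate(t.exons):
                if i > 0:
                    out.add(s)
                if i < t.exon_count - 1:
                    out.add(e)
        return sorted(out)


@dataclass
class SampleDepths:
    dp: int
    ref_depth: int
    alt_depth: int

    def __post_init__(self):
        if min(self.dp, self.ref_depth, self.alt_depth) < 0:
            raise ValueError("negative depth")
        if self.ref_depth + self.alt_depth > self.dp:
            raise ValueError("AD exceeds DP")

    @property
    def aaf(self) -> float | None:
        tot = self.ref_depth + self.alt_depth
        return None if tot == 0 else self.alt_depth / tot


@dataclass
class VariantSite:
    """A biallelic SNV with GATK-style site annotations and per-sample depths.

    ``pos`` follows the VCF convention (1-based); ``pos0`` is the internal
    coordinate. Missing site annotations (``None``) mean the corresponding
    hard filter is not applicable and passes.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    qd: float | None = None
    mq: float | None = None
    mq_rank_sum: float | None = None
    read_pos_rank_sum: float | None = None
    samples: dict[str, SampleDepths] = field(default_factory=dict)
    rs_id: str | None = None

    def __post_init__(self):
        if self.ref == self.alt:
            raise ValueError(f"{self.chrom}:{self.pos} ref == alt")
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise ValueError(f"{self.chrom}:{self.pos} not a SNV")

    @property
    def pos0(self) -> int:
        return self.pos - 1

    def mean_dp(self) -> float:
        if not self.samples:
            return 0.0
        return float(np.mean([s.dp for s in self.samples.values()]))

    def min_dp(self) -> int:
        return min((s.dp for s in self.samples.values()), default=0)


class RegionMask:
    """A labelled set of genomic intervals (sorted and merged per chrom)."""

    def __init__(self, label: str, intervals: Mapping[str, Sequence[tuple[int, int]]]):
        self.label = label
        self.intervals: dict[str, list[tuple[int, int]]] = {}
        for chrom, ivs in intervals.items():
            merged: list[list[int]] = []
            for s, e in sorted(ivs):
                if s >= e:
                    raise ValueError(f"empty interval [{s},{e}) in mask {label}")
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            self.intervals[chrom] = [(s, e) for s, e in merged]

    def contains(self, chrom: str, pos0: int) -> bool:
        ivs = self.intervals.get(chrom, [])
        lo, hi = 0, len(ivs)
        while lo < hi:
            mid = (lo + hi) // 2
            s, e = ivs[mid]
            if pos0 < s:
                hi = mid
            elif pos0 >= e:
                lo = mid + 1
            else:
                return True
        return False

    def __eq__(self, other) -> bool:
        return (isinstance(other, RegionMask) and self.label == other.label
                and self.intervals == other.intervals)


class ExpressionMatrix:
    """TAR x sample integer count matrix plus a two-group design."""

    def __init__(self, counts: pd.DataFrame, groups: Mapping[str, str]):
        if not np.issubdtype(counts.values.dtype, np.integer):
            if not np.allclose(counts.values, np.round(counts.values)):
                raise ValueError("counts must be integers")
            counts = counts.round().astype(np.int64)
        if (counts.values < 0).any():
            raise ValueError("negative counts")
        missing = set(groups) - set(counts.columns)
        if missing:
            raise ValueError(f"design samples absent from matrix: {sorted(missing)}")
        unassigned = set(counts.columns) - set(groups)
        if unassigned:
            raise ValueError(f"samples without group: {sorted(unassigned)}")
        self.counts = counts
        self.groups = dict(groups)
        levels = sorted(set(self.groups.values()))
        if len(levels) != 2:
            raise ValueError(f"expected exactly two groups, got {levels}")
        self.group_levels: tuple[str, str] = (levels[0], levels[1])

    @property
    def tar_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.sample_ids if self.groups[s] == group]

    def __eq__(self, other) -> bool:
        return (isinstance(other, ExpressionMatrix)
                and self.counts.equals(other.counts)
                and self.groups == other.groups)
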