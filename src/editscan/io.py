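"""Readers and writers for the external formats the pipeline touches.

FASTA goes through Biopython, GFF3 through gffutils, VCF through pysam.
GFF3/VCF coordinates are 1-based on disk and converted to the internal
0-based half-open convention here; nothing downstream converts again.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping

import gffutils
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import (
    ExpressionMatrix,
    Gene,
    GenomeAnnotation,
    GenomeSequence,
    RegionMask,
    SampleDepths,
    TranscriptModel,
    VariantSite,
)

log = logging.getLogger(__name__)

# ---------------------------------------------------------------- FASTA


def read_fasta(path: str | Path) -> GenomeSequence:
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate FASTA header {rec.id!r}")
        seqs[rec.id] = str(rec.seq)
    if not seqs:
        raise ValueError(f"no records in {path}")
    return GenomeSequence(seqs)


def write_fasta(genome: GenomeSequence, path: str | Path, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(genome.sequence(c)), id=c, description="")
        for c in genome.chroms
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------- GFF3

_TRANSCRIPT_FEATURES = {"mRNA", "lnc_RNA", "transcript", "ncRNA"}
_BIOTYPE_FROM_FEATURE = {"mRNA": "protein_coding", "lnc_RNA": "lncRNA"}


def read_gff3(path: str | Path) -> GenomeAnnotation:
    """Parse gene/transcript/exon/CDS features into a GenomeAnnotation.

    Transcript biotype comes from the ``biotype`` attribute when present,
    otherwise from the feature type (mRNA -> protein_coding, lnc_RNA ->
    lncRNA). GFF3 columns are 1-based inclusive; internal intervals are
    0-based half-open, i.e. [start-1, end).
    """
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes: dict[str, Gene] = {}
    for g in db.features_of_type("gene"):
        genes[g.id] = Gene(
            gene_id=g.id, chrom=g.seqid, strand=g.strand,
            start=g.start - 1, end=g.end,
            biotype=g.attributes.get("biotype", ["other"])[0],
        )
    transcripts: list[TranscriptModel] = []
    for ftype in sorted(_TRANSCRIPT_FEATURES):
        for t in db.features_of_type(ftype):
            parents = t.attributes.get("Parent", [])
            if not parents:
                raise ValueError(f"transcript {t.id} has no Parent gene")
            gene_id = parents[0]
            if gene_id not in genes:
                raise ValueError(f"transcript {t.id}: orphan Parent {gene_id}")
            exons = [
                (c.start - 1, c.end) for c in db.children(t, featuretype="exon")
            ]
            cds = [
                (c.start - 1, c.end) for c in db.children(t, featuretype="CDS")
            ]
            biotype = t.attributes.get(
                "biotype", [_BIOTYPE_FROM_FEATURE.get(ftype, "other")]
            )[0]
            transcripts.append(TranscriptModel(
                transcript_id=t.id, gene_id=gene_id, chrom=t.seqid,
                strand=t.strand, exons=exons, cds_segments=cds, biotype=biotype,
            ))
    return GenomeAnnotation(transcripts, genes.values())


def write_gff3(annotation: GenomeAnnotation, path: str | Path) -> None:
    lines = ["##gff-version 3"]
    for gid in sorted(annotation.genes):
        g = annotation.genes[gid]
        lines.append("\t".join([
            g.chrom, "editscan", "gene", str(g.start + 1), str(g.end), ".",
            g.strand, ".", f"ID={g.gene_id};biotype={g.biotype}",
        ]))
        for tid in g.transcript_ids:
            t = annotation.transcripts[tid]
            ftype = {"protein_coding": "mRNA", "lncRNA": "lnc_RNA"}.get(
                t.biotype, "transcript")
            lines.append("\t".join([
                t.chrom, "editscan", ftype, str(t.start + 1), str(t.end), ".",
                t.strand, ".",
                f"ID={t.transcript_id};Parent={t.gene_id};biotype={t.biotype}",
            ]))
            for i, (s, e) in enumerate(t.exons, 1):
                lines.append("\t".join([
                    t.chrom, "editscan", "exon", str(s + 1), str(e), ".",
                    t.strand, ".",
                    f"ID={t.transcript_id}.exon{i};Parent={t.transcript_id}",
                ]))
            # phase is derivable from cumulative CDS length on the coding strand
            segs = t.cds_segments if t.strand == "+" else t.cds_segments[::-1]
            cum = 0
            for i, (s, e) in enumerate(segs, 1):
                phase = (3 - cum % 3) % 3
                lines.append("\t".join([
                    t.chrom, "editscan", "CDS", str(s + 1), str(e), ".",
                    t.strand, str(phase),
                    f"ID={t.transcript_id}.cds{i};Parent={t.transcript_id}",
                ]))
                cum += e - s
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------- VCF

_INFO_KEYS = {"QD": "qd", "MQ": "mq", "MQRankSum": "mq_rank_sum",
              "ReadPosRankSum": "read_pos_rank_sum"}


def read_vcf(path: str | Path, sample_ids: list[str] | None = None
             ) -> tuple[list[VariantSite], int]:
    """Read biallelic SNVs from a VCF; returns (sites, n_skipped_non_snv).

    Multi-allelic rows are split into one VariantSite per ALT allele; the
    AD entries for other alleles are discarded. Records whose REF or ALT
    is not a single base are skipped and counted.
    """
    sites: list[VariantSite] = []
    skipped = 0
    with pysam.VariantFile(str(path)) as vcf:
        vcf_samples = list(vcf.header.samples)
        if sample_ids is None:
            sample_ids = vcf_samples
        missing = set(sample_ids) - set(vcf_samples)
        if missing:
            raise ValueError(f"samples not in VCF: {sorted(missing)}")
        if "AD" not in vcf.header.formats:
            raise ValueError(f"{path}: FORMAT AD missing from header")
        declared_info = set(vcf.header.info)
        for rec in vcf:
            for alt_index, alt in enumerate(rec.alts or ()):
                if len(rec.ref) != 1 or len(alt) != 1 or alt == "*":
                    skipped += 1
                    continue
                info = {}
                for key, attr in _INFO_KEYS.items():
                    val = rec.info.get(key) if key in declared_info else None
                    # round away float32 storage noise (GATK prints <= 3 dp)
                    info[attr] = round(float(val), 3) if val is not None else None
                samples = {}
                for sid in sample_ids:
                    call = rec.samples[sid]
                    ad = call.get("AD")
                    if ad is None:
                        raise ValueError(
                            f"{path}: sample {sid} missing AD at "
                            f"{rec.chrom}:{rec.pos}")
                    dp = call.get("DP")
                    ref_d = int(ad[0])
                    alt_d = int(ad[alt_index + 1])
                    samples[sid] = SampleDepths(
                        dp=int(dp) if dp is not None else ref_d + alt_d,
                        ref_depth=ref_d, alt_depth=alt_d,
                    )
                rs = rec.id if rec.id and rec.id != "." else None
                sites.append(VariantSite(
                    chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alt=alt,
                    samples=samples, rs_id=rs, **info,
                ))
    if skipped:
        log.info("read_vcf(%s): skipped %d non-SNV allele(s)", path, skipped)
    return sites, skipped


_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=QD,Number=1,Type=Float,Description="Quality by depth">
##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">
##INFO=<ID=MQRankSum,Number=1,Type=Float,Description="Mapping quality rank sum">
##INFO=<ID=ReadPosRankSum,Number=1,Type=Float,Description="Read position rank sum">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
"""


def write_vcf(sites: Iterable[VariantSite], sample_ids: list[str],
              path: str | Path, contig_lengths: Mapping[str, int] | None = None
              ) -> None:
    lines = [_VCF_HEADER.rstrip("\n")]
    if contig_lengths:
        for chrom, length in contig_lengths.items():
            lines.append(f"##contig=<ID={chrom},length={length}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(sample_ids))
    for site in sites:
        info_parts = []
        for key, attr in _INFO_KEYS.items():
            val = getattr(site, attr)
            if val is not None:
                info_parts.append(f"{key}={val:g}")
        info = ";".join(info_parts) if info_parts else "."
        fmt_fields = []
        for sid in sample_ids:
            s = site.samples[sid]
            fmt_fields.append(f"{s.dp}:{s.ref_depth},{s.alt_depth}")
        lines.append("\t".join([
            site.chrom, str(site.pos), site.rs_id or ".", site.ref, site.alt,
            ".", "PASS", info, "DP:AD", *fmt_fields,
        ]))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------- BED masks


def read_bed_mask(path: str | Path, label: str | None = None) -> RegionMask:
    """BED3(+name): 0-based half-open intervals; label from column 4 or arg."""
    intervals: dict[str, list[tuple[int, int]]] = {}
    file_label = label
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track")):
            continue
        fields = line.split("\t")
        chrom, start, end = fields[0], int(fields[1]), int(fields[2])
        if file_label is None and len(fields) > 3:
            file_label = fields[3]
        intervals.setdefault(chrom, []).append((start, end))
    return RegionMask(file_label or "custom", intervals)


def write_bed_mask(mask: RegionMask, path: str | Path) -> None:
    lines = []
    for chrom in sorted(mask.intervals):
        for s, e in mask.intervals[chrom]:
            lines.append(f"{chrom}\t{s}\t{e}\t{mask.label}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------- counts/design


def read_counts(counts_path: str | Path, design_path: str | Path
                ) -> ExpressionMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    if counts.isna().any().any():
        raise ValueError(f"{counts_path}: missing values")
    if (counts.values < 0).any():
        raise ValueError(f"{counts_path}: negative counts")
    groups = read_design(design_path)
    return ExpressionMatrix(counts, groups)


def read_design(path: str | Path) -> dict[str, str]:
    design = pd.read_csv(path, sep="\t")
    if not {"sample", "group"} <= set(design.columns):
        raise ValueError(f"{path}: need 'sample' and 'group' columns")
    return dict(zip(design["sample"].astype(str), design["group"].astype(str)))


def write_counts(matrix: ExpressionMatrix, counts_path: str | Path,
                 design_path: str | Path) -> None:
    matrix.counts.to_csv(counts_path, sep="\t", index_label="tar_id")
    pd.DataFrame({
        "sample": matrix.sample_ids,
        "group": [matrix.groups[s] for s in matrix.sample_ids],
    }).to_csv(design_path, sep="\t", index=False)


# ---------------------------------------------------------------- summaries


def summarize_libraries(raw_read_totals: list[int]) -> dict[str, float]:
    """Library-level totals: total read count and mean in millions (2 dp)."""
    if not raw_read_totals:
        raise ValueError("no libraries")
    if any(n <= 0 for n in raw_read_totals):
        raise ValueError("library read totals must be positive")
    total = int(sum(raw_read_totals))
    mean_mln = round(total / len(raw_read_totals) / 1e6, 2)
    return {"total": total, "mean_mln": mean_mln}
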