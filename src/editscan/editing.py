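"""RNA-editing-site discovery from called SNVs.

The cascade mirrors standard practice for editing detection from
RNA-seq variant calls: GATK-style hard quality filters, removal of sites
in error-prone genomic context (splice-junction vicinity, simple repeats,
paralogs, bidirectional gene overlaps), a prevalence filter (alternative
allele seen in at least half the libraries), removal of known SNPs and
hypervariable sites (any-sample AAF > 0.7), then a chi-square test of
allelic imbalance between treatment groups on pooled allele depths with
Benjamini-Hochberg FDR. Candidates are the canonical substitutions
(A-to-I read as A>G on the sense strand, C-to-U as C>T) with
FDR < 0.001 and |dAAF| > 0.1, annotated with a VEP-style consequence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Seq import Seq

from .de import bh_adjust
from .models import (
    GenomeAnnotation,
    GenomeSequence,
    RegionMask,
    TranscriptModel,
    VariantSite,
    revcomp,
)

CANONICAL_CLASSES = ("A_to_I", "C_to_U", "noncanonical")

# most severe first; ties between transcripts resolved by this ranking
CONSEQUENCE_SEVERITY = [
    "missense", "synonymous", "five_prime_utr", "three_prime_utr",
    "noncoding_exonic", "intron", "upstream", "downstream", "intergenic",
]


@dataclass
class FilterConfig:
    """Thresholds of the editing cascade; defaults follow GATK hard
    filtering and the downstream significance rules (strict inequalities
    throughout, e.g. a site with DP exactly 10 or MQ exactly 40 passes)."""

    min_dp: float = 10.0
    min_mq: float = 40.0
    min_qd: float = 2.0
    min_mq_rank_sum: float = -12.5
    min_read_pos_rank_sum: float = -8.0
    splice_window: int = 4
    min_alt_sample_fraction: float = 0.5
    max_sample_aaf: float = 0.7
    daaf_threshold: float = 0.1
    fdr_threshold: float = 0.001
    upstream_downstream_window: int = 5000
    dp_rule: str = "mean"  # mean | min : per-site depth summary

    def __post_init__(self):
        for name in ("min_alt_sample_fraction", "max_sample_aaf"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.splice_window < 0 or self.upstream_downstream_window < 0:
            raise ValueError("windows must be non-negative")
        if self.dp_rule not in ("mean", "min"):
            raise ValueError("dp_rule must be 'mean' or 'min'")


@dataclass
class AuditStage:
    stage_name: str
    n_in: int
    n_removed: int
    n_out: int


@dataclass
class CascadeAudit:
    stages: list[AuditStage] = field(default_factory=list)

    def add(self, name: str, n_in: int, n_out: int) -> None:
        stage = AuditStage(name, n_in, n_in - n_out, n_out)
        if self.stages and self.stages[-1].n_out != n_in:
            raise ValueError("audit stages do not chain")
        self.stages.append(stage)


@dataclass
class EditingCandidate:
    site: VariantSite
    aaf_per_sample: dict[str, float | None]
    aaf_group_mean: dict[str, float]
    daaf: float
    chi2_stat: float
    p: float
    fdr: float
    canonical_class: str = "noncanonical"
    consequence: str = "intergenic"
    host_gene: str | None = None
    is_candidate: bool = False
    degenerate: bool = False  # a group had zero pooled depth


# ---------------------------------------------------------------- filters


def hard_filter(variants: Sequence[VariantSite], cfg: FilterConfig
                ) -> list[VariantSite]:
    """GATK-style site-quality filter; missing annotations pass."""

    def fails(v: VariantSite) -> bool:
        dp = v.mean_dp() if cfg.dp_rule == "mean" else v.min_dp()
        if dp < cfg.min_dp:
            return True
        checks = ((v.mq, cfg.min_mq), (v.qd, cfg.min_qd),
                  (v.mq_rank_sum, cfg.min_mq_rank_sum),
                  (v.read_pos_rank_sum, cfg.min_read_pos_rank_sum))
        return any(val is not None and val < thr for val, thr in checks)

    return [v for v in variants if not fails(v)]


def context_filter(variants: Sequence[VariantSite],
                   annotation: GenomeAnnotation,
                   masks: Iterable[RegionMask],
                   cfg: FilterConfig) -> list[VariantSite]:
    """Drop sites near splice junctions or inside any region mask.

    A site within ``splice_window`` nt of an exon/intron boundary on
    either side is removed (the boundary position itself counts as
    distance 0).
    """
    masks = list(masks)
    junctions: dict[str, np.ndarray] = {}

    def near_junction(v: VariantSite) -> bool:
        if v.chrom not in junctions:
            junctions[v.chrom] = np.asarray(
                annotation.splice_junctions(v.chrom), dtype=int)
        js = junctions[v.chrom]
        if js.size == 0:
            return False
        # junction j is the 0-based coordinate of the boundary; bases at
        # j-w .. j+w-1 are within w nt of it on either side
        return bool(np.any((v.pos0 >= js - cfg.splice_window)
                           & (v.pos0 <= js + cfg.splice_window - 1)))

    def masked(v: VariantSite) -> bool:
        return any(m.contains(v.chrom, v.pos0) for m in masks)

    return [v for v in variants if not near_junction(v) and not masked(v)]


def prevalence_filter(variants: Sequence[VariantSite], cfg: FilterConfig
                      ) -> list[VariantSite]:
    """Keep sites with an alternative allele in at least half the samples."""
    out = []
    for v in variants:
        n = len(v.samples)
        need = math.ceil(cfg.min_alt_sample_fraction * n)
        n_alt = sum(1 for s in v.samples.values() if s.alt_depth > 0)
        if n_alt >= need:
            out.append(v)
    return out


def snp_and_hypervariable_filter(variants: Sequence[VariantSite],
                                 cfg: FilterConfig) -> list[VariantSite]:
    """Drop rs-annotated SNPs and sites with any-sample AAF > threshold."""
    out = []
    for v in variants:
        if v.rs_id is not None:
            continue
        aafs = [s.aaf for s in v.samples.values() if s.aaf is not None]
        if aafs and max(aafs) > cfg.max_sample_aaf:
            continue
        out.append(v)
    return out


# ---------------------------------------------------------------- statistics


def compute_aaf(site: VariantSite, design: Mapping[str, str]
                ) -> tuple[dict[str, float | None], dict[str, float]]:
    """Per-sample AAF and the mean AAF per group (undefined samples
    excluded from the group mean)."""
    per_sample = {sid: s.aaf for sid, s in site.samples.items()}
    group_mean: dict[str, float] = {}
    for group in sorted(set(design.values())):
        vals = [per_sample[sid] for sid in site.samples
                if design[sid] == group and per_sample[sid] is not None]
        group_mean[group] = float(np.mean(vals)) if vals else float("nan")
    return per_sample, group_mean


def chi2_pooled(alt_a: int, ref_a: int, alt_b: int, ref_b: int
                ) -> tuple[float, float]:
    """Chi-square test (df=1, no continuity correction) of equal
    alternative-allele proportion between two pooled groups.

    Returns (statistic, two-sided p). Degenerate margins give (0, 1).
    """
    n = alt_a + ref_a + alt_b + ref_b
    row_a, row_b = alt_a + ref_a, alt_b + ref_b
    col_alt, col_ref = alt_a + alt_b, ref_a + ref_b
    if min(row_a, row_b, col_alt, col_ref) == 0:
        return 0.0, 1.0
    stat = n * (alt_a * ref_b - alt_b * ref_a) ** 2 / (
        row_a * row_b * col_alt * col_ref)
    from scipy.stats import chi2
    return float(stat), float(chi2.sf(stat, df=1))


def differential_editing(variants: Sequence[VariantSite],
                         design: Mapping[str, str],
                         cfg: FilterConfig,
                         treated_group: str | None = None
                         ) -> list[EditingCandidate]:
    """Test every site for differential allele fraction between groups.

    dAAF = mean AAF(treated) - mean AAF(control); the chi-square uses
    pooled per-group allele depths; FDR is Benjamini-Hochberg across all
    tested sites. ``is_candidate`` requires fdr < cfg.fdr_threshold and
    |dAAF| > cfg.daaf_threshold (the canonical restriction is applied by
    the cascade, after classification).
    """
    groups = sorted(set(design.values()))
    if len(groups) != 2:
        raise ValueError("design must define exactly two groups")
    if treated_group is None:
        treated_group = groups[1]
    control_group = next(g for g in groups if g != treated_group)
    results: list[EditingCandidate] = []
    pvals = []
    for v in variants:
        pooled = {g: [0, 0] for g in groups}  # [alt, ref]
        for sid, s in v.samples.items():
            pooled[design[sid]][0] += s.alt_depth
            pooled[design[sid]][1] += s.ref_depth
        degenerate = any(sum(pooled[g]) == 0 for g in groups)
        if degenerate:
            stat, p = 0.0, 1.0
        else:
            stat, p = chi2_pooled(pooled[treated_group][0],
                                  pooled[treated_group][1],
                                  pooled[control_group][0],
                                  pooled[control_group][1])
        per_sample, group_mean = compute_aaf(v, design)
        daaf = group_mean[treated_group] - group_mean[control_group]
        if math.isnan(daaf):
            daaf = 0.0
        results.append(EditingCandidate(
            site=v, aaf_per_sample=per_sample, aaf_group_mean=group_mean,
            daaf=daaf, chi2_stat=stat, p=p, fdr=1.0, degenerate=degenerate,
        ))
        pvals.append(p)
    if results:
        fdrs = bh_adjust(np.asarray(pvals))
        for r, fdr in zip(results, fdrs):
            r.fdr = float(fdr)
            r.is_candidate = (r.fdr < cfg.fdr_threshold
                              and abs(r.daaf) > cfg.daaf_threshold)
    return results


# ---------------------------------------------------------------- annotation


def classify_substitution(ref: str, alt: str, host_strand: str) -> str:
    """Canonical editing class of a genomic substitution.

    A-to-I editing appears as A>G on the transcribed (sense) strand:
    A>G on '+' hosts or T>C on '-' hosts. C-to-U appears as C>T on '+'
    or G>A on '-'. Everything else is noncanonical.
    """
    sub = (ref, alt)
    if host_strand == "-":
        sub = (revcomp(ref), revcomp(alt))
    if sub == ("A", "G"):
        return "A_to_I"
    if sub == ("C", "T"):
        return "C_to_U"
    return "noncanonical"


def host_gene_strand(site: VariantSite, annotation: GenomeAnnotation,
                     window: int = 0) -> tuple[str | None, str]:
    """Gene hosting (or nearest within ``window`` of) a site and its
    strand; intergenic sites fall back to the genomic '+' strand."""
    hits = annotation.overlapping_transcripts(site.chrom, site.pos0,
                                              site.pos0 + 1)
    if hits:
        return hits[0].gene_id, hits[0].strand
    if window > 0:
        near = annotation.overlapping_transcripts(
            site.chrom, max(0, site.pos0 - window), site.pos0 + 1 + window)
        if near:
            best = min(near, key=lambda t: min(abs(site.pos0 - t.start),
                                               abs(site.pos0 - (t.end - 1))))
            return best.gene_id, best.strand
    return None, "+"


def _cds_offset(t: TranscriptModel, pos0: int) -> int | None:
    """Offset of a genomic position within the spliced CDS (coding strand)."""
    segs = t.cds_segments
    off = 0
    for s, e in segs:
        if s <= pos0 < e:
            fwd = off + (pos0 - s)
            total = sum(ee - ss for ss, ee in segs)
            return fwd if t.strand == "+" else total - 1 - fwd
        off += e - s
    return None


def _transcript_consequence(site: VariantSite, t: TranscriptModel,
                            genome: GenomeSequence) -> str:
    pos0 = site.pos0
    if not t.in_exon(pos0):
        return "intron"
    if not t.cds_segments:
        return "noncoding_exonic"
    if t.in_cds(pos0):
        cds_seq = "".join(genome.fetch(t.chrom, s, e)
                          for s, e in t.cds_segments)
        if t.strand == "-":
            cds_seq = revcomp(cds_seq)
        off = _cds_offset(t, pos0)
        assert off is not None
        ref_base = site.ref if t.strand == "+" else revcomp(site.ref)
        alt_base = site.alt if t.strand == "+" else revcomp(site.alt)
        if cds_seq[off] != ref_base:
            # annotation/genome disagreement with the call; be conservative
            return "missense"
        codon_i = off // 3
        codon = cds_seq[codon_i * 3:codon_i * 3 + 3]
        mutated = (codon[:off % 3] + alt_base + codon[off % 3 + 1:])
        aa_ref = str(Seq(codon).translate())
        aa_alt = str(Seq(mutated).translate())
        return "synonymous" if aa_ref == aa_alt else "missense"
    # exonic, outside the CDS: 5' or 3' UTR by transcript orientation
    cds_start = t.cds_segments[0][0]
    cds_end = t.cds_segments[-1][1]
    if pos0 < cds_start:
        return "five_prime_utr" if t.strand == "+" else "three_prime_utr"
    if pos0 >= cds_end:
        return "three_prime_utr" if t.strand == "+" else "five_prime_utr"
    return "noncoding_exonic"  # unreachable for well-formed models


def annotate_consequence(site: VariantSite, annotation: GenomeAnnotation,
                         genome: GenomeSequence, cfg: FilterConfig
                         ) -> tuple[str, str | None]:
    """Single most-severe consequence of a site and its host gene.

    Severity ranking: missense > synonymous > 5'UTR > 3'UTR >
    noncoding-exonic > intron > upstream > downstream > intergenic.
    """
    hits = annotation.overlapping_transcripts(site.chrom, site.pos0,
                                              site.pos0 + 1)
    if hits:
        ranked = sorted(
            ((CONSEQUENCE_SEVERITY.index(
                _transcript_consequence(site, t, genome)), t) for t in hits),
            key=lambda x: x[0])
        sev, t = ranked[0]
        return CONSEQUENCE_SEVERITY[sev], t.gene_id
    w = cfg.upstream_downstream_window
    near = annotation.overlapping_transcripts(
        site.chrom, max(0, site.pos0 - w), site.pos0 + 1 + w)
    if near:
        best = min(near, key=lambda t: min(abs(site.pos0 - t.start),
                                           abs(site.pos0 - (t.end - 1))))
        before = site.pos0 < best.start
        if best.strand == "+":
            cons = "upstream" if before else "downstream"
        else:
            cons = "downstream" if before else "upstream"
        return cons, best.gene_id
    return "intergenic", None


# ---------------------------------------------------------------- cascade


def run_cascade(variants: Sequence[VariantSite],
                annotation: GenomeAnnotation,
                genome: GenomeSequence,
                masks: Iterable[RegionMask],
                design: Mapping[str, str],
                cfg: FilterConfig | None = None,
                treated_group: str | None = None
                ) -> tuple[list[EditingCandidate], CascadeAudit]:
    """Full editing-discovery cascade with a per-stage audit trail.

    Returns the surviving candidates (canonical, significant, annotated)
    and the audit of every stage.
    """
    cfg = cfg or FilterConfig()
    audit = CascadeAudit()
    stage_in = list(variants)

    survivors = hard_filter(stage_in, cfg)
    audit.add("hard_filter", len(stage_in), len(survivors))

    prev = survivors
    survivors = context_filter(prev, annotation, masks, cfg)
    audit.add("context_filter", len(prev), len(survivors))

    prev = survivors
    survivors = prevalence_filter(prev, cfg)
    audit.add("prevalence_filter", len(prev), len(survivors))

    prev = survivors
    survivors = snp_and_hypervariable_filter(prev, cfg)
    audit.add("snp_aaf_filter", len(prev), len(survivors))

    tested = differential_editing(survivors, design, cfg, treated_group)
    significant = [r for r in tested if r.is_candidate]
    audit.add("differential_test", len(tested), len(significant))

    for r in significant:
        gene_id, strand = host_gene_strand(
            r.site, annotation, cfg.upstream_downstream_window)
        r.canonical_class = classify_substitution(r.site.ref, r.site.alt,
                                                  strand)
        r.host_gene = gene_id
    candidates = [r for r in significant
                  if r.canonical_class != "noncanonical"]
    audit.add("canonical_restriction", len(significant), len(candidates))

    for r in candidates:
        r.consequence, host = annotate_consequence(r.site, annotation,
                                                   genome, cfg)
        if host is not None:
            r.host_gene = host
    return candidates, audit
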