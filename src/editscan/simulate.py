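"""Synthetic study generator with recorded ground truth.

Emits a complete toy two-group RNA-seq study — genome, gene annotation,
region masks, a count matrix with planted log2 fold changes, and a
multi-sample VCF containing true editing sites (group-differential
editing rates), germline SNPs and sequencing-noise sites — so every
downstream stage can be tested against known truth without external
data.

Design of the sequence model:

* protein-coding genes carry an in-frame CDS (ATG .. stop) built from a
  position-biased codon distribution, giving them the periodicity and
  hexamer usage real coding sequence has;
* lncRNAs are multi-exonic, > 200 nt, and ORF-poor by construction: a
  12-mer that contains a stop codon in all three frames is stitched into
  the spliced sequence every 60 nt, capping any ORF well below 30 codons;
* bidirectional pairs are head-to-head genes with TSS distance < 1 kb,
  covered by the ``bidirectional`` mask; planted (AC)n runs are covered
  by the ``ssr`` mask.

Editing sites are placed on exonic adenosines of the transcribed strand
(or the corresponding C for C-to-U sites), away from splice junctions and
masks; per-sample alternative depths are Binomial(DP, group editing
rate) over Poisson-distributed DP, with an optional beta-binomial
overdispersion knob.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as esio
from .models import (
    ExpressionMatrix,
    Gene,
    GenomeAnnotation,
    GenomeSequence,
    RegionMask,
    SampleDepths,
    TranscriptModel,
    VariantSite,
    revcomp,
)

# stop codon in every reading frame; stitched into lncRNA sequence
_STOP_BLOCK = "TTAATTAATTAA"
_STOP_SPACING = 60

# position-biased codon model for synthetic CDS (first base purine-rich,
# wobble position G/C-rich) — enough signal for TESTCODE and hexamer LLR
_BASE_W = {
    0: {"G": 0.40, "A": 0.30, "C": 0.20, "T": 0.10},
    1: {"A": 0.40, "T": 0.30, "C": 0.20, "G": 0.10},
    2: {"G": 0.40, "C": 0.30, "T": 0.20, "A": 0.10},
}
_STOPS = {"TAA", "TAG", "TGA"}


def _codon_table() -> tuple[list[str], np.ndarray]:
    codons, weights = [], []
    for b1 in "ACGT":
        for b2 in "ACGT":
            for b3 in "ACGT":
                c = b1 + b2 + b3
                if c in _STOPS:
                    continue
                codons.append(c)
                weights.append(_BASE_W[0][b1] * _BASE_W[1][b2] * _BASE_W[2][b3])
    w = np.asarray(weights)
    return codons, w / w.sum()


_CODONS, _CODON_P = _codon_table()


@dataclass
class SimulationConfig:
    seed: int = 22
    n_chroms: int = 2
    chrom_length: int = 100_000
    n_coding_genes: int = 20
    n_lncrnas: int = 12
    n_bidirectional_pairs: int = 2
    n_ssr_runs: int = 6
    n_paralog_regions: int = 4
    replicates_per_group: int = 3
    de_fraction: float = 0.1
    lfc_magnitude: float = 2.0
    nb_dispersion: float = 0.01
    count_mean_range: tuple[float, float] = (200.0, 2000.0)
    size_factor_range: tuple[float, float] = (0.7, 1.4)
    mean_depth_at_sites: float = 50.0
    n_editing_sites: int = 50
    editing_rate_by_group: tuple[float, float] = (0.4, 0.05)
    c_to_u_fraction: float = 0.2
    n_snp_sites: int = 200
    n_noise_sites: int = 500
    noise_alt_rate: float = 0.01
    hard_fail_fraction: float = 0.1
    depth_overdispersion: float = 0.0  # beta-binomial rho; 0 = pure binomial
    groups: tuple[str, str] = ("CTRL", "EMF")  # (control, treated)

    def __post_init__(self):
        if self.replicates_per_group < 2:
            raise ValueError("need >= 2 replicates per group")
        for r in self.editing_rate_by_group:
            if not 0 <= r <= 1:
                raise ValueError("editing rates must lie in [0, 1]")
        counts = (self.n_chroms, self.n_coding_genes, self.n_lncrnas,
                  self.n_bidirectional_pairs, self.n_editing_sites,
                  self.n_snp_sites, self.n_noise_sites)
        if any(c < 0 for c in counts):
            raise ValueError("counts must be non-negative")

    @property
    def sample_ids(self) -> list[str]:
        ctrl, trt = self.groups
        n = self.replicates_per_group
        return ([f"{ctrl}_{i + 1}" for i in range(n)]
                + [f"{trt}_{i + 1}" for i in range(n)])

    @property
    def design(self) -> dict[str, str]:
        ctrl, trt = self.groups
        n = self.replicates_per_group
        d = {f"{ctrl}_{i + 1}": ctrl for i in range(n)}
        d.update({f"{trt}_{i + 1}": trt for i in range(n)})
        return d


@dataclass
class SyntheticTruth:
    """Planted effects, recorded for recovery measurements."""

    de_truth: dict[str, float] = field(default_factory=dict)
    lncrna_truth: dict[str, bool] = field(default_factory=dict)
    editing_truth: dict[str, dict] = field(default_factory=dict)
    snp_sites: set[str] = field(default_factory=set)
    noise_sites: set[str] = field(default_factory=set)

    @staticmethod
    def site_key(chrom: str, pos: int) -> str:
        return f"{chrom}:{pos}"

    def to_json(self, path: str | Path) -> None:
        payload = {
            "de_truth": self.de_truth,
            "lncrna_truth": self.lncrna_truth,
            "editing_truth": self.editing_truth,
            "snp_sites": sorted(self.snp_sites),
            "noise_sites": sorted(self.noise_sites),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        d = json.loads(Path(path).read_text())
        return cls(d["de_truth"], d["lncrna_truth"], d["editing_truth"],
                   set(d["snp_sites"]), set(d["noise_sites"]))


# ------------------------------------------------------------ sequences


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def _coding_spliced(rng: np.random.Generator, n_inner_codons: int,
                    utr5: int, utr3: int) -> tuple[str, int, int]:
    """Spliced transcript sequence with an in-frame CDS; returns
    (sequence, cds_start, cds_len) in spliced coordinates."""
    codons = rng.choice(len(_CODONS), size=n_inner_codons, p=_CODON_P)
    body = "".join(_CODONS[i] for i in codons)
    stop = str(rng.choice(["TAA", "TAG", "TGA"]))
    cds = "ATG" + body + stop
    seq = _random_seq(rng, utr5) + cds + _random_seq(rng, utr3)
    return seq, utr5, len(cds)


def lncrna_spliced(rng: np.random.Generator, length: int) -> str:
    """ORF-poor sequence: stop-in-every-frame blocks every 60 nt."""
    out = []
    produced = 0
    while produced < length:
        filler = _STOP_SPACING - len(_STOP_BLOCK)
        out.append(_random_seq(rng, filler))
        out.append(_STOP_BLOCK)
        produced += _STOP_SPACING
    return "".join(out)[:length]


def _split_exons(rng: np.random.Generator, spliced_len: int, n_exons: int
                 ) -> list[int]:
    """Partition a spliced length into n_exons parts of >= 60 nt each."""
    n_exons = max(1, min(n_exons, spliced_len // 60))
    cuts = sorted(rng.choice(
        np.arange(60, spliced_len - 60 * (n_exons - 1) + 1)
        if n_exons > 1 else [spliced_len], size=n_exons - 1, replace=False
    )) if n_exons > 1 else []
    # re-space cuts so every part >= 60
    lengths = []
    prev = 0
    for i, c in enumerate(cuts):
        c = max(c, prev + 60)
        lengths.append(c - prev)
        prev = c
    lengths.append(spliced_len - prev)
    return lengths


def _spliced_to_genomic(exons: list[tuple[int, int]], strand: str,
                        a: int, b: int) -> list[tuple[int, int]]:
    """Map spliced interval [a, b) to sorted genomic segments."""
    order = exons if strand == "+" else exons[::-1]
    segs = []
    off = 0
    for s, e in order:
        ln = e - s
        lo, hi = max(a, off), min(b, off + ln)
        if lo < hi:
            if strand == "+":
                segs.append((s + (lo - off), s + (hi - off)))
            else:
                segs.append((e - (hi - off), e - (lo - off)))
        off += ln
    return sorted(segs)


def _write_spliced(genome: np.ndarray, exons: list[tuple[int, int]],
                   strand: str, seq: str) -> None:
    """Write a spliced (coding-strand) sequence into the genome array."""
    order = exons if strand == "+" else exons[::-1]
    off = 0
    for s, e in order:
        ln = e - s
        chunk = seq[off:off + ln]
        if strand == "-":
            chunk = revcomp(chunk)
        genome[s:e] = list(chunk)
        off += ln


# ------------------------------------------------------------ annotation


def generate_genome_and_annotation(
    config: SimulationConfig,
) -> tuple[GenomeSequence, GenomeAnnotation, list[RegionMask], SyntheticTruth]:
    rng = np.random.default_rng(config.seed)
    chroms = [f"chr{i + 1}" for i in range(config.n_chroms)]
    arrays = {c: np.array(list(_random_seq(rng, config.chrom_length)))
              for c in chroms}
    cursors = {c: 1000 for c in chroms}
    transcripts: list[TranscriptModel] = []
    genes: list[Gene] = []
    truth = SyntheticTruth()
    mask_ivs: dict[str, dict[str, list[tuple[int, int]]]] = {
        "ssr": {}, "paralog": {}, "bidirectional": {}}

    def pick_chrom(i: int) -> str:
        return chroms[i % len(chroms)]

    def place(chrom: str, span: int) -> int:
        start = cursors[chrom] + int(rng.integers(300, 1200))
        if start + span > config.chrom_length - 1000:
            raise ValueError(
                "chromosome too short for the requested gene content")
        cursors[chrom] = start + span
        return start

    def build_gene(gene_id: str, chrom: str, strand: str, biotype: str,
                   start: int | None = None) -> TranscriptModel:
        if biotype == "protein_coding":
            n_codons = int(rng.integers(110, 220))
            utr5 = int(rng.integers(60, 150))
            utr3 = int(rng.integers(60, 150))
            seq, cds_a, cds_len = _coding_spliced(rng, n_codons, utr5, utr3)
            n_exons = int(rng.integers(3, 6))
        else:
            length = int(rng.integers(300, 800))
            seq, cds_a, cds_len = lncrna_spliced(rng, length), 0, 0
            n_exons = int(rng.integers(2, 5))
        exon_lens = _split_exons(rng, len(seq), n_exons)
        intron_lens = [int(rng.integers(100, 300))
                       for _ in range(len(exon_lens) - 1)]
        span = sum(exon_lens) + sum(intron_lens)
        g_start = place(chrom, span) if start is None else start
        exons = []
        pos = g_start
        for i, ln in enumerate(exon_lens):
            exons.append((pos, pos + ln))
            pos += ln + (intron_lens[i] if i < len(intron_lens) else 0)
        cursors[chrom] = max(cursors[chrom], exons[-1][1])
        cds_segments = (_spliced_to_genomic(exons, strand, cds_a,
                                            cds_a + cds_len)
                        if cds_len else [])
        _write_spliced(arrays[chrom], exons, strand, seq)
        t = TranscriptModel(
            transcript_id=f"{gene_id}.t1", gene_id=gene_id, chrom=chrom,
            strand=strand, exons=exons, cds_segments=cds_segments,
            biotype=biotype)
        transcripts.append(t)
        genes.append(Gene(gene_id, chrom, strand, t.start, t.end,
                          [t.transcript_id], biotype))
        return t

    gi = 0
    # bidirectional head-to-head pairs (protein coding, masked)
    for p in range(config.n_bidirectional_pairs):
        chrom = pick_chrom(gi)
        left = build_gene(f"BDG{2 * p + 1}", chrom, "-", "protein_coding")
        gap = int(rng.integers(200, 800))
        right_start = left.end + gap
        cursors[chrom] = right_start
        right = build_gene(f"BDG{2 * p + 2}", chrom, "+", "protein_coding",
                           start=right_start)
        mask_ivs["bidirectional"].setdefault(chrom, []).append(
            (left.start, right.end))
        truth.lncrna_truth[left.transcript_id] = False
        truth.lncrna_truth[right.transcript_id] = False
        gi += 1
    # ordinary coding genes and lncRNAs, interleaved across chromosomes
    for i in range(config.n_coding_genes):
        strand = "+" if rng.random() < 0.5 else "-"
        t = build_gene(f"PCG{i + 1}", pick_chrom(gi), strand,
                       "protein_coding")
        truth.lncrna_truth[t.transcript_id] = False
        gi += 1
    for i in range(config.n_lncrnas):
        strand = "+" if rng.random() < 0.5 else "-"
        # half annotated with the lncRNA biotype, half left to discover
        biotype = "lncRNA" if i % 2 == 0 else "novel"
        t = build_gene(f"LNC{i + 1}", pick_chrom(gi), strand, biotype)
        truth.lncrna_truth[t.transcript_id] = True
        gi += 1
    # SSR runs and paralog decoys in intergenic space
    for i in range(config.n_ssr_runs):
        chrom = pick_chrom(i)
        run = "AC" * 20
        start = place(chrom, len(run))
        arrays[chrom][start:start + len(run)] = list(run)
        mask_ivs["ssr"].setdefault(chrom, []).append((start, start + len(run)))
    for i in range(config.n_paralog_regions):
        chrom = pick_chrom(i + 1)
        span = int(rng.integers(300, 700))
        start = place(chrom, span)
        mask_ivs["paralog"].setdefault(chrom, []).append((start, start + span))

    genome = GenomeSequence({c: "".join(arrays[c]) for c in chroms})
    annotation = GenomeAnnotation(transcripts, genes)
    masks = [RegionMask(label, ivs) for label, ivs in mask_ivs.items()]
    return genome, annotation, masks, truth


# ------------------------------------------------------------ counts


def simulate_count_matrix(config: SimulationConfig, tar_ids: list[str],
                          rng: np.random.Generator
                          ) -> tuple[ExpressionMatrix, dict[str, float]]:
    """NB counts with planted fold changes on a given TAR universe.

    Per-TAR baseline means are log-uniform over ``count_mean_range``; a
    ``de_fraction`` of TARs receives |log2FC| = lfc_magnitude with a
    random sign applied to the treated group; per-sample size factors
    are log-uniform over ``size_factor_range`` (targeting a library CV
    near 0.1). Counts are Gamma-Poisson draws with NB dispersion
    ``nb_dispersion`` (0 gives pure Poisson).
    """
    n = len(tar_ids)
    lo, hi = config.count_mean_range
    mu = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
    lfc = np.zeros(n)
    n_de = int(round(config.de_fraction * n))
    if n_de:
        idx = rng.choice(n, size=n_de, replace=False)
        lfc[idx] = rng.choice([-1.0, 1.0], size=n_de) * config.lfc_magnitude
    samples = config.sample_ids
    ctrl, trt = config.groups
    sf = np.exp(rng.uniform(np.log(config.size_factor_range[0]),
                            np.log(config.size_factor_range[1]),
                            size=len(samples)))
    counts = np.empty((n, len(samples)), dtype=np.int64)
    for j, sid in enumerate(samples):
        mean = mu * sf[j]
        if config.design[sid] == trt:
            mean = mean * 2.0 ** lfc
        if config.nb_dispersion > 0:
            shape = 1.0 / config.nb_dispersion
            lam = rng.gamma(shape, mean / shape)
        else:
            lam = mean
        counts[:, j] = rng.poisson(lam)
    matrix = ExpressionMatrix(
        pd.DataFrame(counts, index=tar_ids, columns=samples), config.design)
    return matrix, {tid: float(l) for tid, l in zip(tar_ids, lfc)}


def generate_counts(config: SimulationConfig, annotation: GenomeAnnotation,
                    truth: SyntheticTruth,
                    rng: np.random.Generator | None = None
                    ) -> ExpressionMatrix:
    rng = rng or np.random.default_rng(config.seed + 1)
    tar_ids = sorted(annotation.genes)
    matrix, de_truth = simulate_count_matrix(config, tar_ids, rng)
    truth.de_truth = de_truth
    return matrix


# ------------------------------------------------------------ variants


def _alt_depth(rng: np.random.Generator, dp: int, rate: float,
               rho: float) -> int:
    if dp == 0:
        return 0
    if rho > 0 and 0 < rate < 1:
        conc = (1 - rho) / rho
        rate = rng.beta(rate * conc, (1 - rate) * conc)
    return int(rng.binomial(dp, rate))


def _passing_info(rng: np.random.Generator) -> dict:
    return {
        "qd": float(np.round(rng.uniform(15, 35), 2)),
        "mq": float(np.round(rng.uniform(50, 60), 2)),
        "mq_rank_sum": float(np.round(rng.normal(0, 1), 2)),
        "read_pos_rank_sum": float(np.round(rng.normal(0, 1), 2)),
    }


def _eligible_editing_positions(annotation: GenomeAnnotation,
                                genome: GenomeSequence,
                                masks: list[RegionMask],
                                margin: int = 6) -> dict[str, list[tuple]]:
    """Exonic positions of unmasked coding genes, away from exon edges,
    keyed by the sense-strand base ('A' for A-to-I, 'C' for C-to-U)."""
    out: dict[str, list[tuple]] = {"A": [], "C": []}
    for tid in sorted(annotation.transcripts):
        t = annotation.transcripts[tid]
        if t.biotype != "protein_coding":
            continue
        for s, e in t.exons:
            for pos in range(s + margin, e - margin):
                if any(m.contains(t.chrom, pos) for m in masks):
                    continue
                base = genome.base(t.chrom, pos)
                sense = base if t.strand == "+" else revcomp(base)
                if sense in out:
                    out[sense].append((t.chrom, pos, t.strand, t.gene_id))
    return out


def generate_variants(config: SimulationConfig, annotation: GenomeAnnotation,
                      genome: GenomeSequence, masks: list[RegionMask],
                      truth: SyntheticTruth,
                      rng: np.random.Generator | None = None
                      ) -> list[VariantSite]:
    rng = rng or np.random.default_rng(config.seed + 2)
    samples = config.sample_ids
    design = config.design
    ctrl, trt = config.groups
    rate_trt, rate_ctrl = config.editing_rate_by_group
    used: set[tuple[str, int]] = set()
    sites: list[VariantSite] = []

    def draw_dp(low_depth: bool = False) -> int:
        mean = 5.0 if low_depth else config.mean_depth_at_sites
        return int(rng.poisson(mean))

    def make_site(chrom: str, pos0: int, ref: str, alt: str,
                  rates: dict[str, float], rs_id: str | None,
                  info: dict, low_depth: bool = False) -> VariantSite:
        recs = {}
        for sid in samples:
            dp = draw_dp(low_depth)
            alt_d = _alt_depth(rng, dp, rates[design[sid]],
                               config.depth_overdispersion)
            recs[sid] = SampleDepths(dp=dp, ref_depth=dp - alt_d,
                                     alt_depth=alt_d)
        return VariantSite(chrom=chrom, pos=pos0 + 1, ref=ref, alt=alt,
                           samples=recs, rs_id=rs_id, **info)

    # ---- true editing sites in unmasked coding genes
    eligible = _eligible_editing_positions(annotation, genome, masks)
    n_ctou = int(round(config.c_to_u_fraction * config.n_editing_sites))
    plan = [("C", "C_to_U")] * n_ctou + \
           [("A", "A_to_I")] * (config.n_editing_sites - n_ctou)
    for sense_base, cls in plan:
        pool = [p for p in eligible[sense_base]
                if (p[0], p[1]) not in used]
        if not pool:
            raise ValueError("not enough eligible editing positions")
        chrom, pos0, strand, gene_id = pool[int(rng.integers(len(pool)))]
        used.add((chrom, pos0))
        ref = genome.base(chrom, pos0)
        sense_alt = "G" if sense_base == "A" else "T"
        alt = sense_alt if strand == "+" else revcomp(sense_alt)
        site = make_site(chrom, pos0, ref, alt,
                         {ctrl: rate_ctrl, trt: rate_trt}, None,
                         _passing_info(rng))
        sites.append(site)
        truth.editing_truth[SyntheticTruth.site_key(chrom, site.pos)] = {
            "rate_treated": rate_trt, "rate_control": rate_ctrl,
            "canonical_class": cls, "gene": gene_id,
        }

    def random_free_position(chrom: str) -> int:
        while True:
            pos0 = int(rng.integers(500, genome.length(chrom) - 500))
            if (chrom, pos0) not in used:
                return pos0

    chroms = genome.chroms
    # ---- germline SNP sites (rs-annotated; AAF near 0, 0.5 or 1)
    for i in range(config.n_snp_sites):
        chrom = chroms[int(rng.integers(len(chroms)))]
        pos0 = random_free_position(chrom)
        used.add((chrom, pos0))
        ref = genome.base(chrom, pos0)
        if ref == "N":
            ref = "A"
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        aaf = float(rng.choice([0.02, 0.5, 0.98], p=[0.25, 0.5, 0.25]))
        site = make_site(chrom, pos0, ref, alt, {ctrl: aaf, trt: aaf},
                         f"rs{100000 + i}", _passing_info(rng))
        sites.append(site)
        truth.snp_sites.add(SyntheticTruth.site_key(chrom, site.pos))

    # ---- sequencing-noise sites, a fraction drawn to fail a hard filter
    n_fail = int(round(config.hard_fail_fraction * config.n_noise_sites))
    for i in range(config.n_noise_sites):
        chrom = chroms[int(rng.integers(len(chroms)))]
        pos0 = random_free_position(chrom)
        used.add((chrom, pos0))
        ref = genome.base(chrom, pos0)
        if ref == "N":
            ref = "A"
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        info = _passing_info(rng)
        low_depth = False
        if i < n_fail:
            which = int(rng.integers(5))
            if which == 0:
                low_depth = True
            elif which == 1:
                info["mq"] = float(np.round(rng.uniform(20, 39.9), 2))
            elif which == 2:
                info["qd"] = float(np.round(rng.uniform(0.1, 1.9), 2))
            elif which == 3:
                info["mq_rank_sum"] = float(np.round(rng.uniform(-20, -13), 2))
            else:
                info["read_pos_rank_sum"] = float(
                    np.round(rng.uniform(-15, -8.5), 2))
        rate = {ctrl: config.noise_alt_rate, trt: config.noise_alt_rate}
        site = make_site(chrom, pos0, ref, alt, rate, None, info, low_depth)
        sites.append(site)
        truth.noise_sites.add(SyntheticTruth.site_key(chrom, site.pos))

    sites.sort(key=lambda v: (v.chrom, v.pos))
    return sites


# ------------------------------------------------------------ full study


def generate_study(config: SimulationConfig, out_dir: str | Path | None = None):
    """Generate the complete study; optionally write the fixture files.

    Returns (genome, annotation, masks, matrix, variants, truth). When
    ``out_dir`` is given, writes genome.fa, annotation.gff3, masks/*.bed,
    counts.tsv, design.tsv, variants.vcf and truth.json there.
    """
    genome, annotation, masks, truth = generate_genome_and_annotation(config)
    matrix = generate_counts(config, annotation, truth)
    variants = generate_variants(config, annotation, genome, masks, truth)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "masks").mkdir(exist_ok=True)
        esio.write_fasta(genome, out / "genome.fa")
        esio.write_gff3(annotation, out / "annotation.gff3")
        for m in masks:
            esio.write_bed_mask(m, out / "masks" / f"{m.label}.bed")
        esio.write_counts(matrix, out / "counts.tsv", out / "design.tsv")
        contigs = {c: genome.length(c) for c in genome.chroms}
        esio.write_vcf(variants, config.sample_ids, out / "variants.vcf",
                       contigs)
        truth.to_json(out / "truth.json")
        (out / "sim_config.json").write_text(
            json.dumps(dataclasses.asdict(config), indent=1))
    return genome, annotation, masks, matrix, variants, truth
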