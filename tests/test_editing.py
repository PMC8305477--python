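"""The editing-discovery cascade: filters, statistics, annotation."""

import numpy as np
import pytest
from scipy import stats

from editscan import editing
from editscan.editing import FilterConfig
from editscan.models import (
    Gene,
    GenomeAnnotation,
    GenomeSequence,
    RegionMask,
    SampleDepths,
    TranscriptModel,
    VariantSite,
)

CFG = FilterConfig()
DESIGN = {"c1": "CTRL", "c2": "CTRL", "c3": "CTRL",
          "e1": "EMF", "e2": "EMF", "e3": "EMF"}


def _site(pos=100, ref="A", alt="G", dp=30, alts=(5, 5, 5, 5, 5, 5),
          rs_id=None, **info):
    samples = {sid: SampleDepths(dp, dp - a, a)
               for sid, a in zip(DESIGN, alts)}
    return VariantSite(chrom="chr1", pos=pos, ref=ref, alt=alt,
                       samples=samples, rs_id=rs_id, **info)


class TestHardFilter:
    def test_low_mean_depth_removed(self):
        v = _site(dp=9)
        assert editing.hard_filter([v], CFG) == []

    def test_exact_boundaries_kept(self):
        # strict '<' thresholds: DP 10, MQ 40, QD 2 all pass
        v = _site(dp=10, mq=40.0, qd=2.0, mq_rank_sum=-12.5,
                  read_pos_rank_sum=-8.0)
        assert editing.hard_filter([v], CFG) == [v]

    def test_missing_annotation_passes(self):
        v = _site(dp=30)  # no MQRankSum etc. at all
        assert editing.hard_filter([v], CFG) == [v]

    def test_each_annotation_enforced(self):
        for kw in ({"mq": 39.9}, {"qd": 1.9}, {"mq_rank_sum": -12.6},
                   {"read_pos_rank_sum": -8.1}):
            assert editing.hard_filter([_site(**kw)], CFG) == []

    def test_idempotent(self):
        sites = [_site(dp=9), _site(pos=200, mq=50.0), _site(pos=300)]
        once = editing.hard_filter(sites, CFG)
        assert editing.hard_filter(once, CFG) == once


def _two_exon_annotation():
    # exons [0,100) and [200,300): junctions at 100 and 200
    t = TranscriptModel("t1", "g1", "chr1", "+", [(0, 100), (200, 300)])
    return GenomeAnnotation([t])


class TestContextFilter:
    def test_site_near_junction_removed(self):
        ann = _two_exon_annotation()
        v = _site(pos=103)  # pos0 102: 2 nt into the intron from pos 100
        assert editing.context_filter([v], ann, [], CFG) == []

    def test_mid_exon_site_kept(self):
        ann = _two_exon_annotation()
        v = _site(pos=51)
        assert editing.context_filter([v], ann, [], CFG) == [v]

    def test_masked_site_removed(self):
        ann = _two_exon_annotation()
        mask = RegionMask("ssr", {"chr1": [(45, 60)]})
        v = _site(pos=51)
        assert editing.context_filter([v], ann, [mask], CFG) == []

    def test_matches_brute_force_junction_scan(self):
        ann = _two_exon_annotation()
        junctions = [100, 200]
        rng = np.random.default_rng(37)
        sites = [_site(pos=int(p))
                 for p in rng.integers(1, 300, size=1000)]
        kept = editing.context_filter(sites, ann, [], CFG)
        expected = [
            v for v in sites
            if all(not (j - CFG.splice_window <= v.pos0
                        <= j + CFG.splice_window - 1) for j in junctions)]
        assert kept == expected

    def test_idempotent(self):
        ann = _two_exon_annotation()
        rng = np.random.default_rng(38)
        sites = [_site(pos=int(p)) for p in rng.integers(1, 300, 100)]
        once = editing.context_filter(sites, ann, [], CFG)
        assert editing.context_filter(once, ann, [], CFG) == once


class TestPrevalenceFilter:
    def test_half_of_samples_kept(self):
        v = _site(alts=(3, 2, 4, 0, 0, 0))
        assert editing.prevalence_filter([v], CFG) == [v]

    def test_below_half_removed(self):
        v = _site(alts=(3, 2, 0, 0, 0, 0))
        assert editing.prevalence_filter([v], CFG) == []

    def test_odd_sample_count_uses_ceiling(self):
        samples = {f"s{i}": SampleDepths(20, 15, 5 if i < 2 else 0)
                   for i in range(5)}
        v = VariantSite(chrom="chr1", pos=1, ref="A", alt="G",
                        samples=samples)
        assert editing.prevalence_filter([v], CFG) == []  # 2 of 5 < ceil(2.5)
        samples["s2"] = SampleDepths(20, 15, 5)
        v3 = VariantSite(chrom="chr1", pos=1, ref="A", alt="G",
                         samples=samples)
        assert editing.prevalence_filter([v3], CFG) == [v3]


class TestSnpFilter:
    def test_rs_annotated_removed(self):
        v = _site(alts=(6, 6, 6, 6, 6, 6), rs_id="rs1")  # AAF 0.2
        assert editing.snp_and_hypervariable_filter([v], CFG) == []

    def test_hypervariable_sample_removed(self):
        alts = (5, 5, 5, 5, 5, 22)  # 22/30 = 0.733 > 0.7
        v = _site(alts=alts)
        assert editing.snp_and_hypervariable_filter([v], CFG) == []

    def test_exactly_at_threshold_kept(self):
        alts = (5, 5, 5, 5, 5, 21)  # 21/30 = 0.70, strict inequality
        v = _site(alts=alts)
        assert editing.snp_and_hypervariable_filter([v], CFG) == [v]


class TestAaf:
    def test_simple_fraction(self):
        assert SampleDepths(25, 15, 5).aaf == pytest.approx(0.25)

    def test_zero_depth_excluded_from_group_mean(self):
        samples = {"c1": SampleDepths(0, 0, 0),
                   "c2": SampleDepths(10, 5, 5),
                   "e1": SampleDepths(10, 8, 2),
                   "e2": SampleDepths(10, 6, 4)}
        v = VariantSite(chrom="chr1", pos=1, ref="A", alt="G",
                        samples=samples)
        design = {"c1": "CTRL", "c2": "CTRL", "e1": "EMF", "e2": "EMF"}
        per_sample, group_mean = editing.compute_aaf(v, design)
        assert per_sample["c1"] is None
        assert group_mean["CTRL"] == pytest.approx(0.5)
        assert group_mean["EMF"] == pytest.approx(0.3)


class TestChiSquare:
    def test_worked_pooled_table(self):
        stat, p = editing.chi2_pooled(30, 70, 10, 90)
        assert stat == pytest.approx(12.5)
        assert p == pytest.approx(stats.chi2.sf(12.5, 1))

    def test_identical_tables_are_null(self):
        stat, p = editing.chi2_pooled(20, 80, 20, 80)
        assert stat == 0.0 and p == 1.0

    def test_matches_scipy_contingency_on_random_tables(self):
        rng = np.random.default_rng(41)
        for _ in range(1000):
            a, b, c, d = rng.integers(1, 200, size=4)
            stat, p = editing.chi2_pooled(int(a), int(b), int(c), int(d))
            ref = stats.chi2_contingency([[a, b], [c, d]], correction=False)
            assert stat == pytest.approx(ref.statistic, abs=1e-8)
            assert p == pytest.approx(ref.pvalue, abs=1e-8)


class TestDifferentialEditing:
    def test_differential_site_is_candidate(self):
        v = _site(dp=50, alts=(2, 3, 2, 20, 22, 18))
        res = editing.differential_editing([v], DESIGN, CFG,
                                           treated_group="EMF")[0]
        assert res.daaf > 0.1 and res.fdr < 0.001 and res.is_candidate

    def test_zero_group_depth_flagged_null(self):
        samples = {sid: SampleDepths(0 if g == "CTRL" else 30,
                                     0 if g == "CTRL" else 25,
                                     0 if g == "CTRL" else 5)
                   for sid, g in DESIGN.items()}
        v = VariantSite(chrom="chr1", pos=1, ref="A", alt="G",
                        samples=samples)
        res = editing.differential_editing([v], DESIGN, CFG)[0]
        assert res.degenerate and res.p == 1.0 and not res.is_candidate

    def test_null_sites_rarely_called(self):
        # equal editing rates in both groups: FDR 0.001 keeps calls < 0.1%
        called = total = 0
        for seed in range(20):
            rng = np.random.default_rng(500 + seed)
            sites = []
            for i in range(500):
                dp = rng.poisson(50, size=6)
                alts = rng.binomial(dp, 0.1)
                samples = {sid: SampleDepths(int(d), int(d - a), int(a))
                           for sid, d, a in zip(DESIGN, dp, alts)}
                sites.append(VariantSite(chrom="chr1", pos=i + 1, ref="A",
                                         alt="G", samples=samples))
            res = editing.differential_editing(sites, DESIGN, CFG)
            called += sum(r.is_candidate for r in res)
            total += len(res)
        assert called / total < 0.001


class TestClassifySubstitution:
    @pytest.mark.parametrize("ref,alt,strand,expected", [
        ("A", "G", "+", "A_to_I"),
        ("T", "C", "-", "A_to_I"),
        ("C", "T", "+", "C_to_U"),
        ("G", "A", "-", "C_to_U"),
        ("G", "A", "+", "noncanonical"),
        ("A", "C", "+", "noncanonical"),
        ("T", "C", "+", "noncanonical"),
    ])
    def test_canonical_rules(self, ref, alt, strand, expected):
        assert editing.classify_substitution(ref, alt, strand) == expected

    def test_strand_flip_covariance(self):
        from editscan.models import revcomp
        for ref in "ACGT":
            for alt in "ACGT":
                if ref == alt:
                    continue
                direct = editing.classify_substitution(ref, alt, "+")
                mirrored = editing.classify_substitution(
                    revcomp(ref), revcomp(alt), "-")
                assert direct == mirrored


def _coding_annotation():
    """+ strand gene: exons [100,160)+[200,260); CDS [130,160)+[200,230);
    CDS sequence is AAA x20 (Lys)."""
    seq = ["C"] * 400
    for i in range(130, 160):
        seq[i] = "A"
    for i in range(200, 230):
        seq[i] = "A"
    genome = GenomeSequence({"chr1": "".join(seq)})
    t = TranscriptModel("t1", "g1", "chr1", "+", [(100, 160), (200, 260)],
                        [(130, 160), (200, 230)], biotype="protein_coding")
    return GenomeAnnotation([t]), genome


class TestConsequence:
    def test_third_codon_position_synonymous(self):
        ann, genome = _coding_annotation()
        v = _site(pos=133, ref="A", alt="G")  # pos0 132: codon 1 base 3
        cons, gene = editing.annotate_consequence(v, ann, genome, CFG)
        assert cons == "synonymous" and gene == "g1"  # AAA -> AAG (Lys)

    def test_second_codon_position_missense(self):
        ann, genome = _coding_annotation()
        v = _site(pos=132, ref="A", alt="G")  # codon 1 base 2: AAA -> AGA
        cons, _ = editing.annotate_consequence(v, ann, genome, CFG)
        assert cons == "missense"

    def test_utrs_by_orientation(self):
        ann, genome = _coding_annotation()
        five, _ = editing.annotate_consequence(
            _site(pos=111, ref="C", alt="T"), ann, genome, CFG)
        three, _ = editing.annotate_consequence(
            _site(pos=241, ref="C", alt="T"), ann, genome, CFG)
        assert (five, three) == ("five_prime_utr", "three_prime_utr")

    def test_intron(self):
        ann, genome = _coding_annotation()
        cons, _ = editing.annotate_consequence(
            _site(pos=181, ref="C", alt="T"), ann, genome, CFG)
        assert cons == "intron"

    def test_upstream_window(self):
        # site 3,000 nt 5' of a + strand gene start, window 5,000
        genome = GenomeSequence({"chr1": "A" * 10_000})
        t = TranscriptModel("t1", "g1", "chr1", "+", [(5000, 5600)])
        ann = GenomeAnnotation([t])
        cons, gene = editing.annotate_consequence(
            _site(pos=2001, ref="A", alt="G"), ann, genome, CFG)
        assert cons == "upstream" and gene == "g1"

    def test_intergenic_beyond_window(self):
        genome = GenomeSequence({"chr1": "A" * 20_000})
        t = TranscriptModel("t1", "g1", "chr1", "+", [(15000, 15600)])
        ann = GenomeAnnotation([t])
        cons, gene = editing.annotate_consequence(
            _site(pos=2001, ref="A", alt="G"), ann, genome, CFG)
        assert cons == "intergenic" and gene is None


class TestCascade:
    def test_audit_chains_and_counts(self, study):
        cfg = study["config"]
        candidates, audit = editing.run_cascade(
            study["variants"], study["annotation"], study["genome"],
            study["masks"], cfg.design, treated_group=cfg.groups[1])
        for k in range(1, len(audit.stages)):
            assert audit.stages[k].n_in == audit.stages[k - 1].n_out
        for s in audit.stages:
            assert s.n_out == s.n_in - s.n_removed
        assert audit.stages[-1].n_out == len(candidates)

    def test_cascade_equals_stage_composition(self, study):
        cfg = study["config"]
        fc = FilterConfig()
        step = editing.hard_filter(study["variants"], fc)
        step = editing.context_filter(step, study["annotation"],
                                      study["masks"], fc)
        step = editing.prevalence_filter(step, fc)
        step = editing.snp_and_hypervariable_filter(step, fc)
        tested = editing.differential_editing(step, cfg.design, fc,
                                              treated_group=cfg.groups[1])
        manual = set()
        for r in tested:
            if not r.is_candidate:
                continue
            _, strand = editing.host_gene_strand(
                r.site, study["annotation"], fc.upstream_downstream_window)
            if editing.classify_substitution(
                    r.site.ref, r.site.alt, strand) != "noncanonical":
                manual.add((r.site.chrom, r.site.pos))
        candidates, _ = editing.run_cascade(
            study["variants"], study["annotation"], study["genome"],
            study["masks"], cfg.design, fc, treated_group=cfg.groups[1])
        assert {(c.site.chrom, c.site.pos) for c in candidates} == manual

    def test_empty_input_gives_empty_audit_of_zeros(self, study):
        candidates, audit = editing.run_cascade(
            [], study["annotation"], study["genome"], study["masks"],
            study["config"].design)
        assert candidates == []
        assert all(s.n_in == s.n_out == 0 for s in audit.stages)
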