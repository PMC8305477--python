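"""lncRNA classification: predictors, boundary rules, correlation links."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from editscan import lncrna, simulate
from editscan.lncrna import CodingPotentialReport
from editscan.models import (
    Gene,
    GenomeAnnotation,
    GenomeSequence,
    TranscriptModel,
)


def _mini_annotation(strand="+", exons=None, seq="ATGCCCGGGTTT"):
    exons = exons or [(0, len(seq))]
    t = TranscriptModel("t1", "g1", "chr1", strand, exons, biotype="other")
    return GenomeAnnotation([t]), GenomeSequence({"chr1": seq})


class TestSplicedSequence:
    def test_plus_strand_concatenation(self):
        ann, genome = _mini_annotation(exons=[(0, 3), (6, 9)])
        assert lncrna.spliced_sequence(ann, genome, "t1") == "ATG" + "GGG"

    def test_minus_strand_reverse_complement(self):
        ann, genome = _mini_annotation(strand="-", exons=[(0, 4)],
                                       seq="ATGC")
        assert lncrna.spliced_sequence(ann, genome, "t1") == "GCAT"

    def test_unknown_transcript_rejected(self):
        ann, genome = _mini_annotation()
        with pytest.raises(KeyError):
            lncrna.spliced_sequence(ann, genome, "nope")


def _brute_force_orf(seq):
    """Independent O(n^2) scan over all (start, stop) codon pairs."""
    seq = seq.upper()
    best_len, best_cov = 0, 0.0
    n = len(seq)
    for i in range(n - 2):
        if seq[i:i + 3] != "ATG":
            continue
        j = i
        while j + 3 <= n:
            codon = seq[j:j + 3]
            if j > i and codon in {"TAA", "TAG", "TGA"}:
                length = (j - i) // 3
                if length > best_len:
                    best_len, best_cov = length, (j + 3 - i) / n
                break
            j += 3
        else:
            last = i + ((n - i) // 3) * 3
            length = (last - i) // 3
            if length > best_len:
                best_len, best_cov = length, (last - i) / n
    return best_len, best_cov


class TestLongestOrf:
    def test_minimal_orf_counts_start_excludes_stop(self):
        orf = lncrna.longest_orf("ATGAAATAG")
        assert orf.length_codons == 2  # ATG AAA
        assert orf.coverage == pytest.approx(1.0)  # stop included

    def test_no_atg_gives_zero(self):
        assert lncrna.longest_orf("CCCCCCCCC").length_codons == 0

    def test_matches_brute_force_on_random_sequences(self):
        rng = np.random.default_rng(17)
        for _ in range(300):
            n = int(rng.integers(10, 400))
            seq = "".join(rng.choice(list("ACGT"), size=n))
            orf = lncrna.longest_orf(seq)
            exp_len, exp_cov = _brute_force_orf(seq)
            assert orf.length_codons == exp_len
            if exp_len:
                # ties between equal-length ORFs may differ in whether the
                # winning ORF ends in a stop, so check the footprint relation
                footprint = round(orf.coverage * n)
                assert footprint in (3 * exp_len, 3 * exp_len + 3)


def _fickett_oracle(seq):
    """Second, independent coding of the published TESTCODE tables."""
    score = 0.0
    for base in "ACGT":
        counts = [sum(1 for i in range(k, len(seq), 3) if seq[i] == base)
                  for k in range(3)]
        pos_val = max(counts) / (min(counts) + 1)
        # descending edge list negated into an ascending one for bisection
        idx = int(np.searchsorted(
            -np.asarray(lncrna._POSITION_EDGES), -pos_val, side="left"))
        score += (lncrna._POSITION_PROB[base][idx]
                  * lncrna._POSITION_WEIGHT[base])
        content = seq.count(base) / len(seq)
        cidx = int(np.searchsorted(
            -np.asarray(lncrna._CONTENT_EDGES), -content, side="left"))
        score += (lncrna._CONTENT_PROB[base][cidx]
                  * lncrna._CONTENT_WEIGHT[base])
    return score


class TestFickett:
    def test_uniform_repeat_votes_noncoding(self):
        score = lncrna.fickett_score("ACGT" * 100)
        assert score < lncrna.FICKETT_CUTOFF

    def test_matches_independent_table_lookup(self):
        rng = np.random.default_rng(19)
        for _ in range(300):
            seq = "".join(rng.choice(list("ACGT"), size=300,
                                     p=[0.4, 0.1, 0.2, 0.3]))
            assert lncrna.fickett_score(seq) == \
                pytest.approx(_fickett_oracle(seq), abs=1e-12)

    def test_short_sequence_rejected(self):
        with pytest.raises(ValueError):
            lncrna.fickett_score("ATG" * 50)


class TestHexamer:
    def test_identical_corpora_score_zero(self):
        rng = np.random.default_rng(23)
        corpus = ["".join(rng.choice(list("ACGT"), size=300))
                  for _ in range(10)]
        model = lncrna.train_hexamer_model(corpus, corpus)
        assert lncrna.hexamer_llr(model, corpus[0]) == pytest.approx(0.0)

    def test_held_out_cds_scores_positive(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(400 + seed)
            coding = [lncrna_seq for lncrna_seq in (
                simulate._coding_spliced(rng, 150, 0, 0)[0]
                for _ in range(8))]
            noncoding = [simulate.lncrna_spliced(rng, 450)
                         for _ in range(8)]
            model = lncrna.train_hexamer_model(coding[1:], noncoding)
            if lncrna.hexamer_llr(model, coding[0]) > 0:
                hits += 1
        assert hits >= 18

    def test_too_short_rejected(self):
        model = lncrna.train_hexamer_model(["ATGATG"], ["CCCCCC"])
        with pytest.raises(ValueError):
            lncrna.hexamer_llr(model, "ACGT")

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            lncrna.train_hexamer_model([], ["AAAAAA"])


def _report(**kw):
    defaults = dict(transcript_id="t", spliced_length=500, exon_count=3,
                    orf_length=10, orf_coverage=0.1, fickett_score=0.5,
                    hexamer_llr=-0.2,
                    votes={"orf": "noncoding", "fickett": "noncoding",
                           "hexamer": "noncoding"},
                    final_label="noncoding")
    defaults.update(kw)
    return CodingPotentialReport(**defaults)


def _transcript(exons, biotype="novel"):
    return TranscriptModel("t", "g", "chr1", "+", exons, biotype=biotype)


class TestClassifyRules:
    def test_short_transcript_rejected(self):
        t = _transcript([(0, 80), (100, 170)])
        assert not lncrna.classify_lncrna(t, _report(spliced_length=150))

    def test_single_exon_rejected(self):
        t = _transcript([(0, 500)])
        assert not lncrna.classify_lncrna(
            t, _report(spliced_length=500, exon_count=1))

    def test_long_multiexon_unanimous_noncoding_accepted(self):
        t = _transcript([(0, 200), (300, 500), (600, 700)])
        assert lncrna.classify_lncrna(t, _report())

    def test_known_lncrna_biotype_short_circuits(self):
        t = _transcript([(0, 100)], biotype="lncRNA")
        assert lncrna.classify_lncrna(
            t, _report(spliced_length=100, exon_count=1,
                       final_label="coding",
                       votes={"orf": "coding", "fickett": "coding",
                              "hexamer": "coding"}))

    def test_any_coding_vote_vetoes(self):
        t = _transcript([(0, 200), (300, 600)])
        for predictor in ("orf", "fickett", "hexamer"):
            votes = {"orf": "noncoding", "fickett": "noncoding",
                     "hexamer": "noncoding", predictor: "coding"}
            rep = _report(votes=votes, final_label="coding")
            assert not lncrna.classify_lncrna(t, rep)

    @given(st.lists(st.booleans(), min_size=3, max_size=3))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_final_label_is_monotone_in_votes(self, coding_flags):
        names = ["orf", "fickett", "hexamer"]
        votes = {n: ("coding" if f else "noncoding")
                 for n, f in zip(names, coding_flags)}
        label = ("noncoding"
                 if all(v == "noncoding" for v in votes.values())
                 else "coding")
        # flipping one vote to coding never moves the label to noncoding
        for n in names:
            flipped = dict(votes, **{n: "coding"})
            flipped_label = ("noncoding" if all(
                v == "noncoding" for v in flipped.values()) else "coding")
            assert not (label == "coding" and flipped_label == "noncoding")


class TestTransCorrelate:
    def _frames(self, lnc, mrna):
        samples = [f"s{i}" for i in range(lnc.shape[1])]
        return (pd.DataFrame(lnc, index=[f"L{i}" for i in range(len(lnc))],
                             columns=samples),
                pd.DataFrame(mrna, index=[f"M{i}" for i in range(len(mrna))],
                             columns=samples))

    def test_scaled_profile_gives_perfect_correlation(self):
        lnc = np.array([[1, 3, 7, 15, 31, 63]])
        # (x+1)^2 - 1 doubles the log2(count+1) profile exactly
        mrna = (lnc + 1) ** 2 - 1
        pairs = lncrna.trans_correlate(*self._frames(lnc, mrna), 0.9)
        assert len(pairs) == 1
        assert pairs[0].r == pytest.approx(1.0, abs=1e-9)
        assert pairs[0].sign == "positive"
        # a plain 2x scaling is still near-perfectly correlated
        pairs2 = lncrna.trans_correlate(*self._frames(lnc, 2 * lnc), 0.9)
        assert pairs2 and pairs2[0].r > 0.99

    def test_uncorrelated_profiles_give_no_pairs(self):
        rng = np.random.default_rng(29)
        lf, mf = self._frames(rng.integers(1, 100, (5, 30)),
                              rng.integers(1, 100, (5, 30)))
        assert lncrna.trans_correlate(lf, mf, 0.9) == []

    def test_matches_brute_force_pearson(self):
        rng = np.random.default_rng(31)
        lnc = rng.integers(0, 500, (10, 10))
        mrna = rng.integers(0, 500, (10, 10))
        lf, mf = self._frames(lnc, mrna)
        threshold = 0.5
        pairs = lncrna.trans_correlate(lf, mf, threshold)
        got = {(p.lncrna_id, p.target_gene_id): p.r for p in pairs}
        expected = {}
        for i in range(10):
            for j in range(10):
                r = stats.pearsonr(np.log2(lnc[i] + 1.0),
                                   np.log2(mrna[j] + 1.0)).statistic
                if abs(r) >= threshold:
                    expected[(f"L{i}", f"M{j}")] = r
        assert set(got) == set(expected)
        for k in got:
            assert got[k] == pytest.approx(expected[k], abs=1e-8)

    def test_zero_variance_profile_skipped_with_warning(self):
        lf, mf = self._frames(np.array([[5, 5, 5, 5]]),
                              np.array([[1, 2, 3, 4]]))
        with pytest.warns(UserWarning):
            assert lncrna.trans_correlate(lf, mf, 0.9) == []

    def test_too_few_samples_rejected(self):
        lf, mf = self._frames(np.array([[1, 2]]), np.array([[1, 2]]))
        with pytest.raises(ValueError):
            lncrna.trans_correlate(lf, mf, 0.9)
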