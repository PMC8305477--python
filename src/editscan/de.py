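"""Consensus negative-binomial differential expression.

Two independent NB tests are run per TAR (transcriptionally active
region): a Wald test on the log fold change with a moment estimate of the
dispersion, and an exact conditional test on the pooled group totals. A
TAR is called differentially expressed only when *both* tests clear the
adjusted-p and |log2FC| thresholds with a consistent sign — the
intersection rule used when DESeq2- and edgeR-style calls must agree.

Also provides median-of-ratios size factors, Benjamini-Hochberg
adjustment, DE summary arithmetic, and a Hart-type RNA-seq sample-size
formula.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .models import ExpressionMatrix, GenomeAnnotation

PSEUDOCOUNT = 0.5


@dataclass
class MethodResult:
    log2fc: float
    p: float
    padj: float = float("nan")


@dataclass
class DEResult:
    tar_id: str
    method_a: MethodResult
    method_b: MethodResult
    consensus: bool = False
    direction: str = "none"  # up | down | none


@dataclass
class DESummary:
    n_total: int
    n_up: int
    n_down: int
    pct_down: float
    n_protein_coding: int
    n_lncrna: int


@dataclass
class PowerParams:
    """Inputs to the Hart sample-size formula.

    depth: mean per-gene sequencing coverage; cv: biological coefficient
    of variation; effect: fold change to detect (> 1); alpha: two-sided
    type-I error; power: target 1 - beta.
    """

    depth: float
    cv: float
    effect: float
    alpha: float = 0.05
    power: float = 0.8

    def __post_init__(self):
        if self.depth <= 0 or self.cv < 0:
            raise ValueError("depth must be > 0 and cv >= 0")
        if self.effect <= 1:
            raise ValueError("effect (fold change) must exceed 1")
        if not (0 < self.alpha < 1 and 0 < self.power < 1):
            raise ValueError("alpha and power must lie in (0, 1)")


def size_factors(matrix: ExpressionMatrix) -> pd.Series:
    """DESeq-style median-of-ratios normalization factors.

    The pseudo-reference is the per-TAR geometric mean over samples,
    computed on TARs with all-positive counts; each sample's factor is
    the median ratio of its counts to the reference.
    """
    counts = matrix.counts.to_numpy(dtype=float)
    all_pos = (counts > 0).all(axis=1)
    if not all_pos.any():
        raise ValueError("no TAR with all-positive counts")
    sub = counts[all_pos]
    ref = np.exp(np.mean(np.log(sub), axis=1))
    factors = np.median(sub / ref[:, None], axis=0)
    return pd.Series(factors, index=matrix.sample_ids, name="size_factor")


def _group_arrays(matrix: ExpressionMatrix, normalized: np.ndarray
                  ) -> tuple[np.ndarray, np.ndarray]:
    g_ref, g_alt = matrix.group_levels
    cols = list(matrix.sample_ids)
    idx_a = [cols.index(s) for s in matrix.samples_in(g_ref)]
    idx_b = [cols.index(s) for s in matrix.samples_in(g_alt)]
    if not idx_a or not idx_b:
        raise ValueError("each group needs at least one replicate")
    return normalized[:, idx_a], normalized[:, idx_b]


def _moment_dispersion(qa: np.ndarray, qb: np.ndarray) -> np.ndarray:
    """Pooled within-group method-of-moments NB dispersion, >= 0."""
    disps = []
    weights = []
    for q in (qa, qb):
        n = q.shape[1]
        if n < 2:
            continue
        m = q.mean(axis=1)
        v = q.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            d = np.where(m > 0, (v - m) / np.maximum(m, 1e-300) ** 2, 0.0)
        disps.append(d)
        weights.append(n - 1)
    pooled = np.average(np.stack(disps), axis=0, weights=weights)
    return np.maximum(pooled, 0.0)


def nb_wald_test(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Method A: delta-method Wald test on log2 fold change.

    Counts are normalized by median-of-ratios size factors. Per TAR the
    NB variance m + alpha*m^2 of each group mean (alpha from the pooled
    moment estimate) is propagated through log2((m_b+0.5)/(m_a+0.5)).
    Returns a DataFrame with columns log2fc, p indexed by TAR.
    """
    sf = size_factors(matrix).to_numpy()
    q = matrix.counts.to_numpy(dtype=float) / sf
    qa, qb = _group_arrays(matrix, q)
    na, nb = qa.shape[1], qb.shape[1]
    if na < 2 or nb < 2:
        raise ValueError("need >= 2 replicates per group")
    ma, mb = qa.mean(axis=1), qb.mean(axis=1)
    alpha = _moment_dispersion(qa, qb)
    log2fc = np.log2((mb + PSEUDOCOUNT) / (ma + PSEUDOCOUNT))
    var_ma = (ma + alpha * ma ** 2) / na
    var_mb = (mb + alpha * mb ** 2) / nb
    ln2sq = math.log(2) ** 2
    se = np.sqrt(
        var_ma / ((ma + PSEUDOCOUNT) ** 2 * ln2sq)
        + var_mb / ((mb + PSEUDOCOUNT) ** 2 * ln2sq)
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, log2fc / np.maximum(se, 1e-300), 0.0)
    p = 2 * stats.norm.sf(np.abs(z))
    p = np.clip(p, 0.0, 1.0)
    zero = (ma == 0) & (mb == 0)
    log2fc[zero], p[zero] = 0.0, 1.0
    return pd.DataFrame({"log2fc": log2fc, "p": p}, index=matrix.tar_ids)


def _exact_conditional_p(ya: int, yb: int, na: int, nb: int,
                         alpha: float) -> float:
    """Two-sided exact NB test of group-A total conditional on the grand total.

    Group totals are modelled as sums of iid NB draws with common mean and
    dispersion alpha; dispersion zero degenerates to the Poisson /
    conditional-binomial case. The p-value sums the probabilities of all
    splits no more likely than the observed one (edgeR's doubling rule is
    not used; the direct small-p sum is symmetric by construction).
    """
    s = ya + yb
    if s == 0:
        return 1.0
    k = np.arange(s + 1)
    mu = s / (na + nb)  # common per-sample mean under the null
    if alpha <= 0:
        # Poisson limit: conditional distribution is Binomial(s, na/(na+nb))
        logpa = stats.binom.logpmf(k, s, na / (na + nb))
        w = np.exp(logpa - logpa.max())
    else:
        ra, rb = na / alpha, nb / alpha
        pa = ra / (ra + na * mu)
        pb = rb / (rb + nb * mu)
        logw = (stats.nbinom.logpmf(k, ra, pa)
                + stats.nbinom.logpmf(s - k, rb, pb))
        w = np.exp(logw - logw.max())
    w /= w.sum()
    w_obs = w[ya]
    return float(min(1.0, w[w <= w_obs * (1 + 1e-12)].sum()))


def nb_exact_test(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Method B: exact conditional NB test on equalized library counts.

    Counts are scaled to a common effective library size (divided by the
    median-of-ratios factor and rounded), then each TAR's group totals
    are compared by the exact conditional test with the pooled moment
    dispersion.
    """
    sf = size_factors(matrix).to_numpy()
    q = np.round(matrix.counts.to_numpy(dtype=float) / sf)
    qa, qb = _group_arrays(matrix, q)
    na, nb = qa.shape[1], qb.shape[1]
    if na < 2 or nb < 2:
        raise ValueError("need >= 2 replicates per group")
    ma, mb = qa.mean(axis=1), qb.mean(axis=1)
    alpha = _moment_dispersion(qa, qb)
    log2fc = np.log2((mb + PSEUDOCOUNT) / (ma + PSEUDOCOUNT))
    ya = qa.sum(axis=1).astype(int)
    yb = qb.sum(axis=1).astype(int)
    p = np.array([
        _exact_conditional_p(int(a), int(b), na, nb, float(d))
        for a, b, d in zip(ya, yb, alpha)
    ])
    zero = (ya == 0) & (yb == 0)
    log2fc[zero], p[zero] = 0.0, 1.0
    return pd.DataFrame({"log2fc": log2fc, "p": p}, index=matrix.tar_ids)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-D array of p-values")
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def consensus_de(res_a: pd.DataFrame, res_b: pd.DataFrame,
                 padj_threshold: float = 0.05, lfc_threshold: float = 1.0
                 ) -> list[DEResult]:
    """Intersect the two methods' calls into consensus DE verdicts.

    A TAR is DE iff both methods give padj < padj_threshold AND
    |log2FC| > lfc_threshold, and the two log2FC estimates agree in sign.
    """
    if set(res_a.index) != set(res_b.index):
        raise ValueError("methods tested different TAR universes")
    res_b = res_b.loc[res_a.index]
    padj_a = bh_adjust(res_a["p"].to_numpy())
    padj_b = bh_adjust(res_b["p"].to_numpy())
    out: list[DEResult] = []
    for i, tar in enumerate(res_a.index):
        a = MethodResult(float(res_a["log2fc"].iloc[i]),
                         float(res_a["p"].iloc[i]), float(padj_a[i]))
        b = MethodResult(float(res_b["log2fc"].iloc[i]),
                         float(res_b["p"].iloc[i]), float(padj_b[i]))
        hit = (a.padj < padj_threshold and b.padj < padj_threshold
               and abs(a.log2fc) > lfc_threshold
               and abs(b.log2fc) > lfc_threshold
               and a.log2fc * b.log2fc > 0)
        direction = "none"
        if hit:
            direction = "up" if a.log2fc > 0 else "down"
        out.append(DEResult(str(tar), a, b, hit, direction))
    return out


def summarize_de(results: list[DEResult],
                 annotation: GenomeAnnotation | None = None) -> DESummary:
    """Totals, up/down split and biotype split of the consensus DE set."""
    de = [r for r in results if r.consensus]
    n_up = sum(1 for r in de if r.direction == "up")
    n_down = sum(1 for r in de if r.direction == "down")
    n_total = len(de)
    if n_total == 0:
        warnings.warn("empty DE set; pct_down reported as 0")
        pct_down = 0.0
    else:
        pct_down = round(100.0 * n_down / n_total, 2)
    n_pc = n_lnc = 0
    if annotation is not None:
        for r in de:
            biotype = None
            if r.tar_id in annotation.genes:
                biotype = annotation.genes[r.tar_id].biotype
            elif r.tar_id in annotation.transcripts:
                biotype = annotation.transcripts[r.tar_id].biotype
            else:
                raise KeyError(f"DE id {r.tar_id} not in annotation")
            if biotype == "protein_coding":
                n_pc += 1
            elif biotype == "lncRNA":
                n_lnc += 1
    return DESummary(n_total, n_up, n_down, pct_down, n_pc, n_lnc)


def summarize_counts(n_down: int, n_up: int, n_protein_coding: int = 0,
                     n_lncrna: int = 0) -> DESummary:
    """DESummary straight from printed per-direction counts."""
    n_total = n_down + n_up
    pct_down = round(100.0 * n_down / n_total, 2) if n_total else 0.0
    return DESummary(n_total, n_up, n_down, pct_down, n_protein_coding,
                     n_lncrna)


def sample_size(params: PowerParams) -> int:
    """Hart-type per-group sample size for NB RNA-seq counts.

    n = ceil( 2 (z_{1-alpha/2} + z_{power})^2 (1/depth + cv^2) / ln(effect)^2 ),
    floored at 1.
    """
    z_a = stats.norm.ppf(1 - params.alpha / 2)
    z_b = stats.norm.ppf(params.power)
    n = (2 * (z_a + z_b) ** 2 * (1 / params.depth + params.cv ** 2)
         / math.log(params.effect) ** 2)
    return max(1, math.ceil(n))
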