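"""Truth-recovery measurements on replicated synthetic studies.

Each function regenerates the study under the default conditions
(3 vs 3 replicates, site depth 50, editing rates 0.4 vs 0.05, 50 planted
editing sites, 200 SNPs, 500 noise sites; NB counts with dispersion 0.01
and planted |log2FC| = 2) across a set of seeds and measures how well
the pipeline recovers the planted truth.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import de, editing, lncrna, simulate
from .simulate import SimulationConfig, SyntheticTruth


def _seeds(base_seed: int, n: int) -> list[int]:
    return [(base_seed + 7919 * i) % (2 ** 31) for i in range(n)]


def editing_recovery(base_seed: int = 22, n_seeds: int = 20,
                     config: SimulationConfig | None = None) -> dict:
    """Sensitivity on planted editing sites, SNP leakage and the null
    false-candidate fraction of the full cascade."""
    template = config or SimulationConfig()
    found = planted = snp_called = noise_called = noise_total = 0
    for seed in _seeds(base_seed, n_seeds):
        cfg = dataclasses.replace(template, seed=seed)
        genome, annotation, masks, _, variants, truth = \
            simulate.generate_study(cfg)
        cands, _ = editing.run_cascade(
            variants, annotation, genome, masks, cfg.design,
            treated_group=cfg.groups[1])
        called = {SyntheticTruth.site_key(c.site.chrom, c.site.pos)
                  for c in cands}
        planted += len(truth.editing_truth)
        found += len(called & set(truth.editing_truth))
        snp_called += len(called & truth.snp_sites)
        noise_called += len(called & truth.noise_sites)
        noise_total += len(truth.noise_sites)
    return {
        "sensitivity": found / planted,
        "snp_sites_called": snp_called,
        "null_false_fraction": noise_called / noise_total,
        "n_planted": planted,
    }


def de_performance(base_seed: int = 22, n_seeds: int = 20,
                   n_tars: int = 500) -> dict:
    """Consensus-DE null call rate (no planted effects) and sensitivity
    for planted |log2FC| = 2 at the default mean range."""
    null_calls = null_total = hits = true_total = 0
    for seed in _seeds(base_seed, n_seeds):
        rng = np.random.default_rng(seed)
        tar_ids = [f"T{i}" for i in range(n_tars)]
        null_cfg = SimulationConfig(seed=seed, de_fraction=0.0)
        mat, _ = simulate.simulate_count_matrix(null_cfg, tar_ids, rng)
        res = de.consensus_de(de.nb_wald_test(mat), de.nb_exact_test(mat))
        null_calls += sum(r.consensus for r in res)
        null_total += n_tars

        rng = np.random.default_rng(seed + 1)
        alt_cfg = SimulationConfig(seed=seed)
        mat, truth = simulate.simulate_count_matrix(alt_cfg, tar_ids, rng)
        res = de.consensus_de(de.nb_wald_test(mat), de.nb_exact_test(mat))
        called = {r.tar_id for r in res if r.consensus}
        true_de = {t for t, l in truth.items() if l != 0}
        hits += len(called & true_de)
        true_total += len(true_de)
    return {
        "null_rate": null_calls / null_total,
        "sensitivity": hits / true_total,
        "n_true": true_total,
    }


def lncrna_accuracy(base_seed: int = 22, n_seeds: int = 20,
                    config: SimulationConfig | None = None) -> dict:
    """Sensitivity/specificity of the lncRNA classifier against planted
    biotypes, with the hexamer model trained on annotated transcripts."""
    template = config or SimulationConfig()
    tp = fn = tn = fp = 0
    for seed in _seeds(base_seed, n_seeds):
        cfg = dataclasses.replace(template, seed=seed)
        genome, annotation, _, truth = \
            simulate.generate_genome_and_annotation(cfg)
        coding = [lncrna.spliced_cds(annotation, genome, tid)
                  for tid, t in sorted(annotation.transcripts.items())
                  if t.biotype == "protein_coding" and t.cds_segments]
        noncoding = [lncrna.spliced_sequence(annotation, genome, tid)
                     for tid, t in sorted(annotation.transcripts.items())
                     if t.biotype == "lncRNA"]
        model = lncrna.train_hexamer_model(coding, noncoding)
        for tid, t in annotation.transcripts.items():
            seq = lncrna.spliced_sequence(annotation, genome, tid)
            report = lncrna.coding_potential_report(t, seq, model)
            pred = lncrna.classify_lncrna(t, report)
            if truth.lncrna_truth[tid]:
                tp, fn = (tp + 1, fn) if pred else (tp, fn + 1)
            else:
                fp, tn = (fp + 1, tn) if pred else (fp, tn + 1)
    return {
        "sensitivity": tp / (tp + fn),
        "specificity": tn / (tn + fp),
        "n_lncrna": tp + fn,
        "n_other": tn + fp,
    }
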