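"""End-to-end orchestration: simulate -> DE -> lncRNA -> editing.

One RunConfig drives every stage; the run emits all intermediate files
plus a machine-readable ``report.json`` whose counts equal the module
outputs. All thresholds live here — code paths take them as arguments
and have no hidden defaults of their own.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, de, editing, io as esio, lncrna, simulate

log = logging.getLogger("editscan")


@dataclass
class RunConfig:
    out_dir: str = "editscan_run"
    seed: int = 22
    padj_threshold: float = 0.05
    lfc_threshold: float = 1.0
    correlation_threshold: float = 0.9
    filters: editing.FilterConfig = field(default_factory=editing.FilterConfig)
    sim: simulate.SimulationConfig = field(
        default_factory=simulate.SimulationConfig)

    def __post_init__(self):
        if not 0 < self.padj_threshold < 1:
            raise ValueError("padj_threshold must lie in (0, 1)")
        if self.lfc_threshold < 0 or not 0 < self.correlation_threshold <= 1:
            raise ValueError("bad lncRNA/DE threshold")


_COERCIBLE = (int, float, bool)


def _build_section(cls, data: dict, errors: list[str], prefix: str):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in data.items():
        if key not in fields:
            errors.append(f"unknown key {prefix}{key}")
            continue
        ftype = fields[key].type
        if isinstance(value, str):
            try:
                value = float(value) if "." in value else int(value)
                log.warning("coerced %s%s from string", prefix, key)
            except ValueError:
                pass
        if isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        errors.append(f"{prefix.rstrip('.') or 'config'}: {exc}")
        return None


def validate_config(path: str | Path) -> RunConfig:
    """Load a YAML run config: defaults filled, unknown keys rejected,
    every violation reported at once."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: top level must be a mapping")
    errors: list[str] = []
    filt = _build_section(editing.FilterConfig, raw.pop("filters", {}),
                          errors, "filters.")
    sim = _build_section(simulate.SimulationConfig, raw.pop("sim", {}),
                         errors, "sim.")
    top = _build_section(RunConfig, raw, errors, "")
    if errors or top is None or filt is None or sim is None:
        raise ValueError(f"{path}: invalid config: " + "; ".join(errors))
    top.filters = filt
    top.sim = sim
    return top


def _config_hash(config: RunConfig) -> str:
    payload = dataclasses.asdict(config)
    payload.pop("out_dir", None)  # paths don't change the analysis
    blob = json.dumps(payload, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _write_de_table(results: list[de.DEResult], path: Path) -> None:
    rows = [{
        "tar_id": r.tar_id,
        "log2FC_a": r.method_a.log2fc, "padj_a": r.method_a.padj,
        "log2FC_b": r.method_b.log2fc, "padj_b": r.method_b.padj,
        "consensus": r.consensus, "direction": r.direction,
    } for r in results]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _write_candidates(cands: list[editing.EditingCandidate], path: Path,
                      groups: tuple[str, str]) -> None:
    ctrl, trt = groups
    rows = [{
        "chrom": c.site.chrom, "pos": c.site.pos,
        "ref": c.site.ref, "alt": c.site.alt,
        f"aaf_{trt}": c.aaf_group_mean.get(trt),
        f"aaf_{ctrl}": c.aaf_group_mean.get(ctrl),
        "daaf": c.daaf, "chi2": c.chi2_stat, "p": c.p, "fdr": c.fdr,
        "canonical_class": c.canonical_class,
        "consequence": c.consequence, "host_gene": c.host_gene,
    } for c in cands]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def run_all(config: RunConfig) -> dict:
    """Run every stage on a fresh synthetic study; returns the report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    log.addHandler(handler)
    try:
        config.sim = dataclasses.replace(config.sim, seed=config.seed)
        log.info("[simulate] seed=%d", config.seed)
        genome, annotation, masks, matrix, variants, truth = \
            simulate.generate_study(config.sim, out)

        log.info("[de] %d TARs x %d samples", *matrix.counts.shape)
        res_a = de.nb_wald_test(matrix)
        res_b = de.nb_exact_test(matrix)
        results = de.consensus_de(res_a, res_b, config.padj_threshold,
                                  config.lfc_threshold)
        _write_de_table(results, out / "de.tsv")
        summary = de.summarize_de(results, annotation)

        log.info("[lncrna] classifying %d transcripts",
                 len(annotation.transcripts))
        coding_corpus = [
            lncrna.spliced_cds(annotation, genome, tid)
            for tid, t in sorted(annotation.transcripts.items())
            if t.biotype == "protein_coding" and t.cds_segments]
        noncoding_corpus = [
            lncrna.spliced_sequence(annotation, genome, tid)
            for tid, t in sorted(annotation.transcripts.items())
            if t.biotype == "lncRNA"]
        model = lncrna.train_hexamer_model(coding_corpus, noncoding_corpus)
        lnc_rows = []
        lnc_gene_ids = []
        for tid, t in sorted(annotation.transcripts.items()):
            seq = lncrna.spliced_sequence(annotation, genome, tid)
            report = lncrna.coding_potential_report(t, seq, model)
            is_lnc = lncrna.classify_lncrna(t, report)
            if is_lnc:
                lnc_gene_ids.append(t.gene_id)
            lnc_rows.append({
                "transcript_id": tid, "biotype": t.biotype,
                "spliced_length": report.spliced_length,
                "exon_count": report.exon_count,
                "orf_length": report.orf_length,
                "fickett_score": report.fickett_score,
                "hexamer_llr": report.hexamer_llr,
                "final_label": report.final_label, "is_lncRNA": is_lnc,
            })
        pd.DataFrame(lnc_rows).to_csv(out / "lncrna.tsv", sep="\t",
                                      index=False)
        mrna_gene_ids = [g for g, gene in sorted(annotation.genes.items())
                         if gene.biotype == "protein_coding"]
        pairs = lncrna.trans_correlate(
            matrix.counts.loc[[g for g in lnc_gene_ids
                               if g in matrix.counts.index]],
            matrix.counts.loc[[g for g in mrna_gene_ids
                               if g in matrix.counts.index]],
            config.correlation_threshold)
        pd.DataFrame([dataclasses.asdict(p) for p in pairs]).to_csv(
            out / "trans_pairs.tsv", sep="\t", index=False)

        log.info("[editing] cascade on %d sites", len(variants))
        candidates, audit = editing.run_cascade(
            variants, annotation, genome, masks, config.sim.design,
            config.filters, treated_group=config.sim.groups[1])
        _write_candidates(candidates, out / "candidates.tsv",
                          config.sim.groups)
        pd.DataFrame([dataclasses.asdict(s) for s in audit.stages]).to_csv(
            out / "audit.tsv", sep="\t", index=False)

        consequence_hist: dict[str, int] = {}
        for c in candidates:
            consequence_hist[c.consequence] = \
                consequence_hist.get(c.consequence, 0) + 1
        report = {
            "version": __version__,
            "config_hash": _config_hash(config),
            "seed": config.seed,
            "thresholds": {
                "padj": config.padj_threshold,
                "lfc": config.lfc_threshold,
                "correlation": config.correlation_threshold,
                "daaf": config.filters.daaf_threshold,
                "fdr": config.filters.fdr_threshold,
            },
            "de_summary": dataclasses.asdict(summary),
            "n_lncRNAs": len(lnc_gene_ids),
            "n_trans_pairs": len(pairs),
            "editing_audit": [dataclasses.asdict(s) for s in audit.stages],
            "n_editing_candidates": len(candidates),
            "consequence_histogram": dict(sorted(consequence_hist.items())),
        }
        (out / "report.json").write_text(json.dumps(report, indent=1,
                                                    sort_keys=True))
        return report
    finally:
        log.removeHandler(handler)
        handler.close()
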