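"""End-to-end orchestration of the target-nomination pipeline.

Stages run in fixed order: probe->gene integration of the two studies,
batch correction with quality assessment, differential expression,
condition-specific dependency networks, causal-hypothesis scoring,
literature mining, and the integrative target filter.  Every stage writes
its outputs as TSV/JSON under the run directory and reports row counts
into a provenance manifest; reruns with the same configuration are
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import (causal_reasoning, dependency_net, diffexp, integration,
               litmine, synthetic_data, target_selection)
from .datatypes import ExpressionDataset, read_sample_map
from .errors import ConfigError

log = logging.getLogger("octargets")


@dataclass
class PipelineConfig:
    """Paths and thresholds for one pipeline run."""

    expr1: str = ""
    expr2: str = ""
    annot1: str = ""
    annot2: str = ""
    gapfill: str = ""
    sample_map: str = ""
    relations: str = ""
    corpus: str = ""
    gene_info: str = ""
    outdir: str = "run"
    fc_threshold: float = 1.5
    adjp_threshold: float = 0.05
    q_threshold: float = 0.05
    fisher_alpha: float = 0.05
    causal_depth: int = 1
    n_perm: int = 20000
    bonferroni_alpha: float = 0.05
    power_delta: float = 1.0
    batch_strategy: str = "combat"
    seed: int = 0

    def validate(self, check_paths: bool = True) -> None:
        for name, v in (("fc_threshold", self.fc_threshold),):
            if v < 1:
                raise ConfigError(f"{name} must be >= 1")
        for name in ("adjp_threshold", "q_threshold", "fisher_alpha", "bonferroni_alpha"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ConfigError(f"{name} must be in (0, 1], got {v}")
        if self.causal_depth < 1 or self.n_perm < 1:
            raise ConfigError("causal_depth and n_perm must be >= 1")
        if check_paths:
            for name in ("expr1", "expr2", "annot1", "annot2", "gapfill",
                         "sample_map", "relations", "corpus", "gene_info"):
                p = getattr(self, name)
                if not p or not Path(p).exists():
                    raise ConfigError(f"input path {name!r} missing or not found: {p}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f.name for f in cls.__dataclass_fields__.values()}
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _write(df: pd.DataFrame, path: Path, **kw) -> int:
    df.to_csv(path, sep="\t", float_format="%.6g", **kw)
    return len(df)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages; returns the provenance manifest."""
    cfg.validate()
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": cfg.config_hash(), "seed": cfg.seed, "stages": {}}

    def stage(name):
        t0 = time.time()

        def done(**counts):
            manifest["stages"][name] = counts
            log.info("stage %-12s %s (%.2fs)", name, counts, time.time() - t0)

        return done

    # -- integration -------------------------------------------------------
    done = stage("integration")
    sample_map = read_sample_map(cfg.sample_map).reset_index()
    gapfill = pd.read_csv(cfg.gapfill, sep="\t", dtype=str)
    studies = []
    for expr_path, annot_path in ((cfg.expr1, cfg.annot1), (cfg.expr2, cfg.annot2)):
        matrix = pd.read_csv(expr_path, sep="\t", index_col=0)
        matrix.index = matrix.index.astype(str)
        annot = pd.read_csv(annot_path, sep="\t", dtype=str).fillna("")
        sm = sample_map[sample_map["sample"].isin(matrix.columns)]
        studies.append(integration.probe_table_to_dataset(matrix, annot, gapfill, sm))
    merged = integration.merge_by_gene(*studies)
    merged.to_tsv(out / "integrated.tsv", out / "integrated_samples.tsv")
    done(genes=merged.n_genes, samples=merged.n_samples)

    # -- batch correction and assessment -----------------------------------
    done = stage("batch_correction")
    before = integration.assess_pca_mixing(merged)
    corrected = integration.combat_adjust(merged, strategy=cfg.batch_strategy)
    after = integration.assess_batch_correction(corrected, delta=cfg.power_delta)
    corrected.to_tsv(out / "corrected.tsv", out / "corrected_samples.tsv")
    _write(after.pc_scores, out / "pc_scores.tsv", index_label="sample")
    (out / "batch_assessment.json").write_text(json.dumps({
        "mixing_before": round(before.mixing_score, 6),
        "mixing_after": round(after.mixing_score, 6),
        "frac_power_ge_0.8": round(after.frac_powered, 6),
        "power_delta": cfg.power_delta,
        "strategy": cfg.batch_strategy,
    }, indent=1))
    done(genes=corrected.n_genes, samples=corrected.n_samples)

    # -- differential expression -------------------------------------------
    done = stage("diffexp")
    fit = diffexp.moderate_variances(diffexp.fit_group_contrast(corrected))
    de_table = diffexp.select_de(fit, cfg.fc_threshold, cfg.adjp_threshold)
    _write(de_table, out / "de_genes.tsv")
    _write(diffexp.full_table(fit), out / "all_genes.tsv")
    done(de_genes=len(de_table), tested=corrected.n_genes)

    # -- dependency networks ------------------------------------------------
    done = stage("dependency_net")
    de_genes = list(de_table.index)
    if len(de_genes) >= 2:
        nets, edge_tables, degrees = dependency_net.condition_networks(
            corrected, de_genes, cfg.q_threshold)
        for cond, edges in edge_tables.items():
            _write(edges[edges["q"] <= cfg.q_threshold], out / f"edges_{cond}.tsv",
                   index=False)
        n_edges = {c: nets[c].number_of_edges() for c in nets}
    else:
        degrees = pd.DataFrame(columns=["deg_cancer", "deg_control", "diff"],
                               index=pd.Index(de_genes, name="gene"), dtype=int)
        for cond in ("cancer", "control"):
            _write(pd.DataFrame(columns=["gene_a", "gene_b", "pcor", "p", "q"]),
                   out / f"edges_{cond}.tsv", index=False)
        n_edges = {"cancer": 0, "control": 0}
    _write(degrees, out / "connectivity.tsv")
    done(**{f"edges_{k}": v for k, v in n_edges.items()})

    # -- causal reasoning ----------------------------------------------------
    done = stage("causal_reasoning")
    graph = causal_reasoning.load_relations(cfg.relations)
    hyps = causal_reasoning.evaluate_hypotheses(
        graph, de_table, depth=cfg.causal_depth, n_perm=cfg.n_perm, seed=cfg.seed)
    _write(causal_reasoning.hypothesis_table(hyps), out / "hypotheses.tsv", index=False)
    causal_net = causal_reasoning.filter_and_consolidate(
        hyps, de_table, corrected, p_threshold=cfg.bonferroni_alpha)
    _write(causal_net.relations, out / "causal_net_relations.tsv", index=False)
    _write(causal_net.degrees.rename_axis("gene").to_frame(),
           out / "causal_net_degrees.tsv")
    done(hypotheses=len(hyps), significant=len(causal_net.hypotheses),
         relations=len(causal_net.relations))

    # -- literature mining ---------------------------------------------------
    done = stage("litmine")
    corpus = litmine.load_corpus(cfg.corpus)
    synonyms = litmine.build_synonym_table(cfg.gene_info)
    (out / "synonym_table.tsv").write_text(litmine.format_synonym_table(synonyms))
    counts, signif, evidence, gstats = litmine.annotate_genes(
        de_genes, corpus, synonyms, alpha=cfg.fisher_alpha)
    _write(counts, out / "litmine_matrix.tsv")
    _write(signif, out / "fisher_out.tsv", index=False)
    _write(gstats, out / "global_counts.tsv", index_label="tier")
    pubs = out / "gene_pubs"
    pubs.mkdir(exist_ok=True)
    for gene, rows in evidence.items():
        if rows:
            pd.DataFrame(rows).to_csv(pubs / f"{gene}_pub.txt", sep="\t", index=False)
    done(annotated=int((counts["qualified_hits"] > 0).sum()) if len(counts) else 0,
         significant=int(signif["significant"].sum()) if len(signif) else 0)

    # -- integrative target selection ---------------------------------------
    done = stage("target_selection")
    ledger = target_selection.select_targets(signif, degrees, causal_net, de_table)
    target_selection.write_target_report(ledger, out)
    _write(ledger.records, out / "target_ledger.tsv", index=False)
    done(candidates=len(ledger.candidates),
         stage1=len(ledger.stage_survivors(1)))

    manifest["mean_diff"] = None if pd.isna(ledger.mean_diff) else round(ledger.mean_diff, 6)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def run_demo(outdir, seed: int = 0, sim: synthetic_data.SimulationConfig | None = None,
             **overrides) -> dict:
    """Generate synthetic inputs under ``outdir/inputs`` and run everything."""
    outdir = Path(outdir)
    inputs = outdir / "inputs"
    sim = sim or synthetic_data.SimulationConfig(seed=seed)
    synthetic_data.generate_all(sim, inputs)
    cfg = PipelineConfig(
        expr1=str(inputs / "expr_study1.tsv"),
        expr2=str(inputs / "expr_study2.tsv"),
        annot1=str(inputs / "annot_study1.tsv"),
        annot2=str(inputs / "annot_study2.tsv"),
        gapfill=str(inputs / "gapfill.tsv"),
        sample_map=str(inputs / "sample_map.tsv"),
        relations=str(inputs / "relations.tsv"),
        corpus=str(inputs / "corpus.xml"),
        gene_info=str(inputs / "gene_info.tsv"),
        outdir=str(outdir / "run"),
        seed=seed,
        **overrides,
    )
    return run_pipeline(cfg)
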