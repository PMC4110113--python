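"""Integrative target filter: hallmarks x topology x causal membership.

Stage 1 keeps genes significantly associated with at least one of the
five cancer hallmarks.  The mean dependency-network connectivity
difference (``Diff = deg_cancer - deg_control``) over those genes defines
the topologically-evolved (TE) cut: ``diff > mean_diff`` (strict).
Stage 2 keeps genes that are TE or belong to the consolidated causal
network (as hypothesis or downstream gene).  Stage 3 keeps genes with at
least two significant hallmarks; those are the candidate therapeutic
targets.  Every gene carries the stage at which it was rejected.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .causal_reasoning import ConsolidatedCausalNet
from .errors import ReconciliationError
from .litmine import HALLMARK_KEYWORDS, MARKER_KEYWORDS

HALLMARKS = tuple(HALLMARK_KEYWORDS)
MARKERS = tuple(MARKER_KEYWORDS)

REPORT_COLUMNS = [
    "gene", "tier", "deg_cancer", "deg_control", "diff", "logFC", "adj_p",
    *HALLMARKS, *MARKERS, "is_TE", "is_causal_hypothesis", "is_causal_net_gene",
    "causal_degree", "verdict",
]


@dataclass
class TargetLedger:
    records: pd.DataFrame  # one row per gene, REPORT_COLUMNS
    mean_diff: float

    @property
    def candidates(self) -> list[str]:
        return self.records.loc[self.records["verdict"] == "candidate", "gene"].tolist()

    def stage_survivors(self, stage: int) -> list[str]:
        rejected = {f"rejected_stage{k}" for k in range(1, stage + 1)}
        keep = ~self.records["verdict"].isin(rejected)
        return self.records.loc[keep, "gene"].tolist()


def select_targets(signif: pd.DataFrame, degrees: pd.DataFrame,
                   causal: ConsolidatedCausalNet | None,
                   deg_table: pd.DataFrame,
                   mean_over: str = "stage1") -> TargetLedger:
    """Run the three-stage integrative filter.

    Parameters
    ----------
    signif
        Fisher output with columns (gene, tier, concept, p, significant).
    degrees
        Dependency-network degree table indexed by gene with columns
        deg_cancer / deg_control / diff.
    causal
        Consolidated causal network (may be ``None`` for no causal evidence).
    deg_table
        DE table indexed by gene with logFC and adj_p.
    mean_over
        ``stage1`` (default) averages Diff over hallmark-significant genes;
        ``all`` averages over every gene in the degree table.
    """
    genes = list(deg_table.index)
    missing = [g for g in genes if g not in degrees.index]
    if missing:
        raise ReconciliationError(
            f"{len(missing)} genes missing from degree table", missing)

    sig = signif[signif["significant"]] if len(signif) else signif
    sig_map: dict[str, set[str]] = {}
    tier_map: dict[str, str] = {}
    for row in signif.itertuples():
        tier_map.setdefault(row.gene, row.tier)
    for row in sig.itertuples():
        sig_map.setdefault(row.gene, set()).add(row.concept)

    hyp_genes = causal.hypothesis_genes if causal is not None else set()
    down_genes = causal.downstream_genes if causal is not None else set()
    causal_deg = causal.degrees if causal is not None else pd.Series(dtype=int)

    stage1 = [g for g in genes if sig_map.get(g, set()) & set(HALLMARKS)]
    pool = stage1 if mean_over == "stage1" else genes
    mean_diff = float(degrees.loc[pool, "diff"].mean()) if pool else float("nan")

    rows = []
    for g in genes:
        concepts = sig_map.get(g, set())
        hallmarks = concepts & set(HALLMARKS)
        diff = int(degrees.loc[g, "diff"])
        is_te = bool(pool) and diff > mean_diff
        in_causal = g in hyp_genes or g in down_genes
        if not hallmarks:
            verdict = "rejected_stage1"
        elif not (is_te or in_causal):
            verdict = "rejected_stage2"
        elif len(hallmarks) < 2:
            verdict = "rejected_stage3"
        else:
            verdict = "candidate"
        rows.append({
            "gene": g,
            "tier": tier_map.get(g, ""),
            "deg_cancer": int(degrees.loc[g, "deg_cancer"]),
            "deg_control": int(degrees.loc[g, "deg_control"]),
            "diff": diff,
            "logFC": float(deg_table.loc[g, "logFC"]),
            "adj_p": float(deg_table.loc[g, "adj_p"]),
            **{h: h in hallmarks for h in HALLMARKS},
            **{m: m in concepts for m in MARKERS},
            "is_TE": is_te,
            "is_causal_hypothesis": g in hyp_genes,
            "is_causal_net_gene": g in down_genes,
            "causal_degree": int(causal_deg.get(g, 0)),
            "verdict": verdict,
        })
    records = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    return TargetLedger(records=records, mean_diff=mean_diff)


def write_target_report(ledger: TargetLedger, outdir) -> dict[str, Path]:
    """Write the target-list and integrative-analysis tables as TSV.

    ``target_list.tsv`` holds the candidate rows (plus a review-file copy
    for manual curation); ``integrative_analysis.tsv`` holds every
    hallmark-significant gene with the attributes the filter used.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    candidates = ledger.records[ledger.records["verdict"] == "candidate"]
    paths["target_list"] = outdir / "target_list.tsv"
    candidates.to_csv(paths["target_list"], sep="\t", index=False, float_format="%.6g")

    stage1 = ledger.records[ledger.records["verdict"] != "rejected_stage1"]
    paths["integrative_analysis"] = outdir / "integrative_analysis.tsv"
    stage1.to_csv(paths["integrative_analysis"], sep="\t", index=False, float_format="%.6g")

    # curation sheet: candidates flagged for manual literature review
    review = candidates.assign(manual_review="PENDING")
    paths["review"] = outdir / "target_review.tsv"
    review.to_csv(paths["review"], sep="\t", index=False, float_format="%.6g")
    return paths
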