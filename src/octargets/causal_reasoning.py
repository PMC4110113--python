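"""Signed causal-graph hypothesis scoring against observed DE directions.

A hypothesis is an (entity, direction) pair proposed as an upstream
regulator.  Its predicted effect on every gene reachable within a bounded
number of directed steps is the product of the hypothesis direction and
the edge signs along a path; genes reached with conflicting signs are
ambiguous.  Each prediction is scored against the DE table (correct = +1,
incorrect = -1, ambiguous / not-measured = 0), significance comes from a
permutation null that reassigns the observed multiset of DE directions
(exact enumeration on small downstream overlaps), and surviving
hypotheses are consolidated — after removing hypotheses whose own
measured expression contradicts their direction and all incorrectly
predicted relationships — into one causal network with degree statistics.
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from lxml import etree

from .datatypes import ExpressionDataset
from .errors import EmptyGraphError, InputFormatError

_SIGN_WORDS = {
    "increase": 1, "increases": 1, "activation": 1, "+1": 1, "1": 1, "+": 1,
    "decrease": -1, "decreases": -1, "inhibition": -1, "-1": -1, "-": -1,
}


@dataclass
class SignedGraph:
    """Directed graph with signed edges (+1 activation, -1 inhibition)."""

    graph: nx.MultiDiGraph
    skipped: int = 0  # relations of unsupported type

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def out_edges(self, node):
        """(target, sign) pairs for every outgoing edge of ``node``."""
        return [(t, d["sign"]) for _, t, d in self.graph.out_edges(node, data=True)]


def signed_graph_from_frame(relations: pd.DataFrame) -> SignedGraph:
    """Build a SignedGraph from a (source, target, sign/type[, label]) frame."""
    g = nx.MultiDiGraph()
    skipped = 0
    seen: set[tuple[str, str, int]] = set()
    type_col = "sign" if "sign" in relations.columns else "type"
    for row in relations.itertuples(index=False):
        src, tgt = str(getattr(row, "source")), str(getattr(row, "target"))
        raw = str(getattr(row, type_col)).strip().lower()
        sign = _SIGN_WORDS.get(raw)
        if sign is None or src == tgt:
            skipped += 1
            continue
        key = (src, tgt, sign)
        if key in seen:
            continue
        seen.add(key)
        label = str(getattr(row, "pathway_label", "")) if hasattr(row, "pathway_label") else ""
        g.add_edge(src, tgt, sign=sign, label=label)
    if g.number_of_edges() == 0:
        raise EmptyGraphError("no usable signed relations")
    return SignedGraph(g, skipped)


def _load_kgml(path) -> pd.DataFrame:
    tree = etree.parse(str(path))
    root = tree.getroot()
    names: dict[str, str] = {}
    for entry in root.iter("entry"):
        name = (entry.get("name") or "").split()[0] if entry.get("name") else ""
        names[entry.get("id")] = name.split(":")[-1] if name else entry.get("id")
    rows = []
    pathway = root.get("title") or root.get("name") or ""
    for rel in root.iter("relation"):
        src = names.get(rel.get("entry1"), rel.get("entry1"))
        tgt = names.get(rel.get("entry2"), rel.get("entry2"))
        subtypes = [s.get("name") for s in rel.iter("subtype")]
        kind = next((s for s in subtypes if s in ("activation", "inhibition")),
                    subtypes[0] if subtypes else "")
        rows.append((src, tgt, kind, pathway))
    return pd.DataFrame(rows, columns=["source", "target", "type", "pathway_label"])


def load_relations(path) -> SignedGraph:
    """Parse a relations TSV or a KGML-subset XML into a SignedGraph.

    TSV needs columns (source, target, sign-or-type); relation types other
    than activation/inhibition (e.g. ``expression``) are skipped and
    counted on ``.skipped``.
    """
    path = Path(path)
    try:
        head = path.read_text(errors="replace")[:200].lstrip()
    except OSError as exc:
        raise InputFormatError(f"cannot read relations file {path}: {exc}") from exc
    if path.suffix.lower() in (".xml", ".kgml") or head.startswith("<"):
        frame = _load_kgml(path)
    else:
        frame = pd.read_csv(path, sep="\t", dtype=str)
        missing = {"source", "target"} - set(frame.columns)
        if missing:
            raise InputFormatError(f"relations TSV lacks columns: {sorted(missing)}")
    return signed_graph_from_frame(frame)


# ---------------------------------------------------------------------------
# prediction and scoring
# ---------------------------------------------------------------------------

AMBIGUOUS = 0


@dataclass
class PredictionOutcome:
    gene: str
    predicted: int  # +1 / -1 / 0 (ambiguous)
    observed: int | None = None  # +1 / -1 / None (absent from DE table)
    verdict: str = "NE"  # C+ / C- / I+ / I- / NE


@dataclass
class Hypothesis:
    node: str
    direction: int
    depth: int
    outcomes: list[PredictionOutcome] = field(default_factory=list)
    score: int = 0
    n_correct: int = 0
    n_incorrect: int = 0
    n_unexplained: int = 0
    p: float = float("nan")
    p_bonferroni: float = float("nan")
    expression_flag: str = ""

    @property
    def correct_genes(self) -> list[str]:
        return [o.gene for o in self.outcomes if o.verdict.startswith("C")]

    @property
    def incorrect_genes(self) -> list[str]:
        return [o.gene for o in self.outcomes if o.verdict.startswith("I")]


def predict_downstream(g: SignedGraph, node: str, direction: int,
                       depth: int = 1) -> list[PredictionOutcome]:
    """Signed reachability within ``depth`` directed steps.

    The predicted sign of a reachable gene is ``direction`` times the
    product of edge signs along a path; genes implied with opposite signs
    by different paths (or by parallel contradictory edges) are ambiguous.
    The hypothesis node itself is excluded.
    """
    if node not in g.graph:
        raise InputFormatError(f"hypothesis node {node!r} not in graph")
    signs: dict[str, set[int]] = {}

    def walk(current: str, steps_left: int, sign: int) -> None:
        if steps_left == 0:
            return
        for target, edge_sign in g.out_edges(current):
            s = sign * edge_sign
            if target != node:
                signs.setdefault(target, set()).add(s)
            walk(target, steps_left - 1, s)

    walk(node, depth, direction)
    out = []
    for gene in sorted(signs):
        ss = signs[gene]
        predicted = ss.pop() if len(ss) == 1 else AMBIGUOUS
        out.append(PredictionOutcome(gene=gene, predicted=predicted))
    return out


def score_hypothesis(node: str, direction: int, depth: int,
                     predictions: list[PredictionOutcome],
                     deg: pd.DataFrame) -> Hypothesis:
    """Fill verdicts and the cumulative correctness score.

    ``deg`` is the DE table indexed by gene with a ``direction`` column.
    Correct predictions score +1, incorrect -1; ambiguous predictions and
    genes absent from the DE table are "not explained" and score 0.
    """
    observed = deg["direction"].to_dict()
    h = Hypothesis(node=node, direction=direction, depth=depth)
    for pred in predictions:
        o = PredictionOutcome(gene=pred.gene, predicted=pred.predicted)
        obs = observed.get(pred.gene)
        if pred.predicted == AMBIGUOUS or obs is None:
            o.verdict = "NE"
            h.n_unexplained += 1
        else:
            o.observed = int(obs)
            suffix = "+" if obs > 0 else "-"
            if pred.predicted == obs:
                o.verdict = "C" + suffix
                h.n_correct += 1
            else:
                o.verdict = "I" + suffix
                h.n_incorrect += 1
        h.outcomes.append(o)
    h.score = h.n_correct - h.n_incorrect
    return h


def _falling(n: int, k: int) -> float:
    out = 1.0
    for i in range(k):
        out *= n - i
    return out


def hypothesis_pvalue(h: Hypothesis, deg: pd.DataFrame, n_perm: int = 10000,
                      seed: int = 0, exact_limit: int = 12) -> float:
    """P(null score >= observed) under direction reassignment.

    The null keeps the observed counts of up- and down-regulated genes and
    randomly reassigns those directions across the DE gene set.  Only the
    downstream genes that are in the DE table and unambiguously predicted
    matter; when there are at most ``exact_limit`` of them the tail is
    enumerated exactly (multivariate hypergeometric weights), otherwise a
    seeded permutation estimate ``(1 + #{null >= obs}) / (1 + n_perm)`` is
    used.
    """
    dirs = deg["direction"].to_numpy(dtype=int)
    n_total = dirs.size
    preds = np.array([o.predicted for o in h.outcomes
                      if o.predicted != AMBIGUOUS and o.observed is not None],
                     dtype=int)
    k = preds.size
    if k == 0 or n_total == 0:
        return 1.0
    observed_score = h.score
    n_up = int((dirs > 0).sum())
    n_down = n_total - n_up

    if k <= exact_limit:
        denom = _falling(n_total, k)
        p = 0.0
        for assignment in itertools.product((1, -1), repeat=k):
            arr = np.asarray(assignment)
            j = int((arr > 0).sum())
            if j > n_up or (k - j) > n_down:
                continue
            weight = _falling(n_up, j) * _falling(n_down, k - j) / denom
            if int((preds * arr).sum()) >= observed_score:
                p += weight
        return float(min(1.0, p))

    rng = np.random.default_rng(seed)
    perm = np.tile(dirs, (n_perm, 1))
    rng.permuted(perm, axis=1, out=perm)
    scores = perm[:, :k] @ preds
    hits = int((scores >= observed_score).sum())
    return (1 + hits) / (1 + n_perm)


def evaluate_hypotheses(g: SignedGraph, deg: pd.DataFrame, depth: int = 1,
                        n_perm: int = 10000, seed: int = 0) -> list[Hypothesis]:
    """Score and test every (node, +/-) hypothesis; Bonferroni over all."""
    hypotheses = []
    nodes = [n for n in g.nodes if g.graph.out_degree(n) > 0]
    n_tests = 2 * len(g.nodes)
    for node in nodes:
        predictions = predict_downstream(g, node, 1, depth)
        for direction in (1, -1):
            preds = [PredictionOutcome(o.gene, o.predicted * direction) for o in predictions]
            h = score_hypothesis(node, direction, depth, preds, deg)
            sub_seed = seed + (zlib.crc32(f"{node}:{direction}".encode()) % 100000)
            h.p = hypothesis_pvalue(h, deg, n_perm=n_perm, seed=sub_seed)
            h.p_bonferroni = min(1.0, h.p * n_tests)
            hypotheses.append(h)
    return hypotheses


def hypothesis_table(hypotheses: list[Hypothesis]) -> pd.DataFrame:
    rows = []
    for h in hypotheses:
        rows.append({
            "node": h.node, "direction": h.direction, "depth": h.depth,
            "score": h.score, "n_correct": h.n_correct,
            "n_incorrect": h.n_incorrect, "n_unexplained": h.n_unexplained,
            "correct_genes": "|".join(h.correct_genes),
            "incorrect_genes": "|".join(h.incorrect_genes),
            "p": h.p, "p_bonferroni": h.p_bonferroni,
        })
    return pd.DataFrame(rows).sort_values(
        ["p", "node", "direction"], kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# consolidation
# ---------------------------------------------------------------------------


@dataclass
class ConsolidatedCausalNet:
    """Surviving hypotheses and their correctly predicted relationships."""

    hypotheses: list[Hypothesis]
    relations: pd.DataFrame  # hypothesis, regulation, downstream, verdict
    degrees: pd.Series  # per-node unique-neighbour count
    hypothesis_genes: set[str]
    downstream_genes: set[str]

    @property
    def dual_genes(self) -> set[str]:
        """Nodes acting both as hypothesis and as downstream target."""
        return self.hypothesis_genes & self.downstream_genes

    @property
    def members(self) -> set[str]:
        return self.hypothesis_genes | self.downstream_genes


def filter_and_consolidate(hypotheses: list[Hypothesis], deg: pd.DataFrame,
                           ds: ExpressionDataset | None = None,
                           p_threshold: float = 0.05) -> ConsolidatedCausalNet:
    """Build the consolidated causal network from significant hypotheses.

    Hypotheses need ``p_bonferroni <= p_threshold``; a hypothesis whose
    own measured expression change (DE direction, or the raw group-mean
    logFC sign for non-DE genes) contradicts its direction is dropped.
    Hypothesis genes absent from the expression data are retained with a
    ``no-expression-evidence`` flag.  Only correctly predicted (C-verdict)
    relationships enter the network.
    """
    logfc_sign: dict[str, int] = {}
    if ds is not None:
        is_cancer = (ds.condition == "cancer").to_numpy()
        lfc = (ds.values.loc[:, is_cancer].mean(axis=1)
               - ds.values.loc[:, ~is_cancer].mean(axis=1))
        logfc_sign = np.sign(lfc).astype(int).to_dict()

    survivors = []
    for h in hypotheses:
        if not (h.p_bonferroni <= p_threshold):
            continue
        if h.node in deg.index:
            measured = int(deg.loc[h.node, "direction"])
        elif h.node in logfc_sign and logfc_sign[h.node] != 0:
            measured = logfc_sign[h.node]
        else:
            h.expression_flag = "no-expression-evidence"
            survivors.append(h)
            continue
        if measured == h.direction:
            survivors.append(h)

    rows = []
    adjacency: dict[str, set[str]] = {}
    for h in survivors:
        for o in h.outcomes:
            if not o.verdict.startswith("C"):
                continue
            regulation = h.direction * o.predicted  # +1 activation, -1 inhibition
            rows.append({"hypothesis": h.node, "regulation": regulation,
                         "downstream": o.gene, "verdict": o.verdict})
            adjacency.setdefault(h.node, set()).add(o.gene)
            adjacency.setdefault(o.gene, set()).add(h.node)
    relations = pd.DataFrame(rows, columns=["hypothesis", "regulation",
                                            "downstream", "verdict"])
    degrees = pd.Series({n: len(v) for n, v in sorted(adjacency.items())}, dtype=int,
                        name="degree")
    return ConsolidatedCausalNet(
        hypotheses=survivors,
        relations=relations,
        degrees=degrees,
        hypothesis_genes={h.node for h in survivors},
        downstream_genes=set(relations["downstream"]) if len(relations) else set(),
    )
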