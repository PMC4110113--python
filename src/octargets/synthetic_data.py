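"""Synthetic generators for every pipeline input, with known ground truth.

The generators emulate the shape of a two-cohort oral-cancer microarray
compendium at desk scale: two probe-level expression studies on partially
overlapping gene universes with additive/multiplicative batch effects,
probe annotation tables with the usual many-to-many pathologies, a signed
causal-relation digraph with planted active regulators, and a PubMed-XML
abstract corpus with planted gene-hallmark co-occurrence sentences plus
decoys (reviews, bare acronyms, gene-free keyword sentences).

All randomness flows from a single top-level seed; each generator draws
from its own fixed sub-stream so outputs are byte-identical for identical
configurations.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from lxml import etree

from .errors import ConfigError

# sub-stream identifiers (first entry of the seed sequence)
_STREAM_EXPR = 1
_STREAM_PROBE = 2
_STREAM_CAUSAL = 3
_STREAM_CORPUS = 4

HALLMARKS = ("apoptosis", "angiogenesis", "cell_proliferation", "metastasis", "inflammation")
MARKERS = ("therapeutic", "prognostic", "diagnostic")

#: curated roster of real gene symbols with synonyms, other designations and
#: descriptive names, mirroring the structure of NCBI gene_info columns.
NAMED_GENES: dict[str, dict[str, str]] = {
    "MMP1": {
        "synonyms": "CLG",
        "other": "fibroblast collagenase|interstitial collagenase|matrix metalloprotease 1",
        "description": "matrix metalloproteinase 1",
    },
    "TP53": {"synonyms": "p53|LFS1", "other": "cellular tumor antigen p53",
             "description": "tumor protein p53"},
    "EGFR": {"synonyms": "ERBB|ERBB1|HER1", "other": "-",
             "description": "epidermal growth factor receptor"},
    "ADM": {"synonyms": "AM", "other": "-", "description": "adrenomedullin"},
    "BIRC5": {"synonyms": "API4|EPR-1", "other": "survivin",
              "description": "baculoviral IAP repeat containing 5"},
    "BIRC3": {"synonyms": "AIP1|API2", "other": "-",
              "description": "baculoviral IAP repeat containing 3"},
    "CTGF": {"synonyms": "CCN2", "other": "-",
             "description": "connective tissue growth factor"},
    "LYN": {"synonyms": "JTK8", "other": "-",
            "description": "LYN proto-oncogene, Src family tyrosine kinase"},
    "CD70": {"synonyms": "CD27L|TNFSF7", "other": "CD27 ligand",
             "description": "CD70 molecule"},
    "SKIL": {"synonyms": "SNO", "other": "ski-related oncogene",
             "description": "SKI like proto-oncogene"},
    "CTLA4": {"synonyms": "CD152", "other": "-",
              "description": "cytotoxic T-lymphocyte associated protein 4"},
    "NRAS": {"synonyms": "N-ras", "other": "neuroblastoma RAS viral oncogene homolog",
             "description": "NRAS proto-oncogene, GTPase"},
}

#: planted multi-hallmark target genes: each is given a strong cancer-only
#: co-expression module (high dependency-network degree difference) and
#: causal-network membership, so the integrative filter should nominate all
#: of them on a clean run.
HUB_GENES = ("TP53", "EGFR", "ADM", "MMP1")
#: hub genes doubling as active causal hypotheses (upstream regulators)
ACTIVE_HYPOTHESIS_POOL = (("TP53", 1), ("EGFR", 1))
#: decoy genes with literature evidence that the mining rules must reject
DECOY_REVIEW_GENE = "CD70"
DECOY_ACRONYM_GENE = "LYN"

DEFAULT_PLANTED: tuple[tuple[str, str], ...] = (
    ("TP53", "apoptosis"),
    ("TP53", "cell_proliferation"),
    ("EGFR", "cell_proliferation"),
    ("EGFR", "metastasis"),
    ("ADM", "angiogenesis"),
    ("ADM", "inflammation"),
    ("MMP1", "metastasis"),
    ("MMP1", "inflammation"),
    ("BIRC5", "apoptosis"),
    ("CTGF", "angiogenesis"),
)

# phrase used when writing a supporting sentence for a concept (generation
# vocabulary; the mining keyword lists live in litmine and are independent)
_CONCEPT_PHRASE = {
    "apoptosis": "apoptosis",
    "angiogenesis": "angiogenesis",
    "cell_proliferation": "cell proliferation",
    "metastasis": "metastatic dissemination",
    "inflammation": "inflammation",
    "therapeutic": "therapeutic target",
    "prognostic": "prognosis",
    "diagnostic": "diagnostic marker",
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for the synthetic compendium.

    Defaults emulate the two-cohort design at desk scale: two batches with
    a cancer:control ratio of roughly 2:1, log2-scale Gaussian noise with
    sd 0.25 (typical of normalized array data), planted fold changes of
    1.5 log2 units, and a location-scale batch effect on the second study.
    """

    seed: int = 0
    n_genes: int = 600
    n_cancer_per_batch: int = 25
    n_control_per_batch: int = 12
    frac_de: float = 0.15
    logfc_magnitude: float = 1.5
    noise_sd: float = 0.25
    batch_shift: float = 2.0
    batch_scale: float = 1.2
    n_causal_nodes: int = 50
    n_causal_edges: int = 130
    n_active_hypotheses: int = 2
    causal_noise: float = 0.1
    n_abstracts: int = 90
    frac_reviews: float = 0.2
    planted_annotations: tuple[tuple[str, str], ...] = DEFAULT_PLANTED

    def validate(self) -> None:
        counts = {
            "n_genes": self.n_genes,
            "n_cancer_per_batch": self.n_cancer_per_batch,
            "n_control_per_batch": self.n_control_per_batch,
            "n_causal_nodes": self.n_causal_nodes,
            "n_causal_edges": self.n_causal_edges,
            "n_active_hypotheses": self.n_active_hypotheses,
            "n_abstracts": self.n_abstracts,
        }
        for name, v in counts.items():
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise ConfigError(f"{name} must be an integer >= 1, got {v!r}")
        for name, v in (("frac_de", self.frac_de), ("causal_noise", self.causal_noise),
                        ("frac_reviews", self.frac_reviews)):
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v!r}")
        if self.batch_scale <= 0:
            raise ConfigError("batch_scale must be > 0")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if self.n_causal_edges < self.n_active_hypotheses:
            raise ConfigError("n_causal_edges must be >= n_active_hypotheses")
        if self.n_genes < len(NAMED_GENES) + 2 * (self.n_genes // 10) + 20:
            raise ConfigError("n_genes too small to host the named roster and overlap margins")
        bad = [c for _, c in self.planted_annotations
               if c not in HALLMARKS and c not in MARKERS]
        if bad:
            raise ConfigError(f"unknown concepts in planted_annotations: {bad}")


@dataclass
class GroundTruth:
    """Everything the generators planted, for downstream recovery checks."""

    de_genes: dict[str, int] = field(default_factory=dict)  # gene -> +1/-1
    batch_params: dict[str, tuple[float, float]] = field(default_factory=dict)
    active_hypotheses: list[tuple[str, int]] = field(default_factory=list)
    annotation_truth: set[tuple[str, str]] = field(default_factory=set)
    target_genes: list[str] = field(default_factory=list)
    decoy_genes: list[str] = field(default_factory=list)
    hub_partners: dict[str, list[str]] = field(default_factory=dict)
    causal_directions: dict[str, int] = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "de_genes": self.de_genes,
            "batch_params": {k: list(v) for k, v in self.batch_params.items()},
            "active_hypotheses": [list(t) for t in self.active_hypotheses],
            "annotation_truth": sorted(list(t) for t in self.annotation_truth),
            "target_genes": self.target_genes,
            "decoy_genes": self.decoy_genes,
            "hub_partners": self.hub_partners,
            "causal_directions": self.causal_directions,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            de_genes={g: int(v) for g, v in d["de_genes"].items()},
            batch_params={k: tuple(v) for k, v in d["batch_params"].items()},
            active_hypotheses=[(g, int(s)) for g, s in d["active_hypotheses"]],
            annotation_truth={(g, c) for g, c in d["annotation_truth"]},
            target_genes=d["target_genes"],
            decoy_genes=d["decoy_genes"],
            hub_partners={k: list(v) for k, v in d["hub_partners"].items()},
            causal_directions={g: int(v) for g, v in d["causal_directions"].items()},
        )


# ---------------------------------------------------------------------------
# gene universe and study layout
# ---------------------------------------------------------------------------

def gene_universe(cfg: SimulationConfig) -> list[str]:
    """Ordered gene identifiers; the named roster sits inside the overlap."""
    margin = cfg.n_genes // 10
    n_filler = cfg.n_genes - len(NAMED_GENES)
    fillers = [f"G{i:04d}" for i in range(1, n_filler + 1)]
    return fillers[:margin] + list(NAMED_GENES) + fillers[margin:]


def study_gene_sets(cfg: SimulationConfig) -> dict[str, list[str]]:
    """Per-study gene coverage: each study misses one flank of the universe."""
    universe = gene_universe(cfg)
    margin = cfg.n_genes // 10
    return {"study1": universe[: cfg.n_genes - margin], "study2": universe[margin:]}


# ---------------------------------------------------------------------------
# causal relations
# ---------------------------------------------------------------------------

def gen_causal_relations(cfg: SimulationConfig):
    """Random signed digraph with planted active upstream regulators.

    Returns ``(relations, active_hypotheses, causal_directions)`` where
    ``relations`` is a DataFrame (source, target, sign, pathway_label),
    ``active_hypotheses`` is a list of (node, sign) pairs and
    ``causal_directions`` maps each one-step downstream gene to the DE
    direction implied by sign propagation (with ``causal_noise`` of the
    signs flipped).
    """
    cfg.validate()
    rng = np.random.default_rng([_STREAM_CAUSAL, cfg.seed])
    universe = gene_universe(cfg)
    overlap = [g for g in study_gene_sets(cfg)["study1"] if g in set(study_gene_sets(cfg)["study2"])]

    actives = [t for t in ACTIVE_HYPOTHESIS_POOL][: cfg.n_active_hypotheses]
    while len(actives) < cfg.n_active_hypotheses:
        # beyond the named pool, promote filler genes to regulators
        cand = [g for g in overlap if g.startswith("G")
                and g not in {a for a, _ in actives}][len(actives)]
        actives.append((cand, int(rng.choice([1, -1]))))

    forced_down = {"TP53": "ADM", "EGFR": "MMP1"}
    node_pool = [g for g in overlap if g not in {a for a, _ in actives}]
    rng.shuffle(node_pool)

    nodes: list[str] = [a for a, _ in actives]
    for g in ("ADM", "MMP1", "BIRC5", "CTGF"):
        if g in set(overlap) and g not in nodes:
            nodes.append(g)
    for g in node_pool:
        if len(nodes) >= cfg.n_causal_nodes:
            break
        if g not in nodes:
            nodes.append(g)
    nodes = nodes[: max(cfg.n_causal_nodes, len(nodes))]

    edges: list[tuple[str, str, int, str]] = []
    seen: set[tuple[str, str]] = set()

    def add_edge(src, tgt, sign, label):
        if src == tgt or (src, tgt) in seen:
            return False
        edges.append((src, tgt, int(sign), label))
        seen.add((src, tgt))
        return True

    # each active hypothesis gets a downstream set large enough that its
    # score can clear Bonferroni despite causal_noise sign flips
    per_hyp = max(1, min(40, (cfg.n_causal_edges - 10) // max(1, len(actives))))
    downstream_used: set[str] = {a for a, _ in actives}
    for hyp, _sign in actives:
        targets = []
        first = forced_down.get(hyp)
        if first and first in set(overlap) and first not in downstream_used:
            targets.append(first)
        for g in nodes + node_pool:
            if len(targets) >= per_hyp:
                break
            if g not in downstream_used and g not in targets and g != hyp:
                targets.append(g)
        for t in targets:
            add_edge(hyp, t, rng.choice([1, -1]), "synthetic_pathway_core")
            downstream_used.add(t)
            if t not in nodes:
                nodes.append(t)

    # fill with random background edges among causal nodes
    attempts = 0
    while len(edges) < cfg.n_causal_edges and attempts < 50 * cfg.n_causal_edges:
        attempts += 1
        src, tgt = rng.choice(len(nodes), size=2, replace=False)
        add_edge(nodes[src], nodes[tgt], rng.choice([1, -1]),
                 f"synthetic_pathway_{int(rng.integers(1, 6))}")

    relations = pd.DataFrame(edges, columns=["source", "target", "sign", "pathway_label"])

    # one-step signed propagation from active hypotheses, with noise flips
    causal_directions: dict[str, int] = {}
    for hyp, sign in actives:
        for _, row in relations[relations["source"] == hyp].iterrows():
            d = int(sign * row["sign"])
            if rng.random() < cfg.causal_noise:
                d = -d
            causal_directions.setdefault(str(row["target"]), d)
    return relations, actives, causal_directions


# ---------------------------------------------------------------------------
# differential-expression layout shared between generators
# ---------------------------------------------------------------------------

def _de_plan(cfg: SimulationConfig):
    """Deterministic assignment of DE genes, directions and hub modules."""
    universe = gene_universe(cfg)
    overlap_set = set(study_gene_sets(cfg)["study1"]) & set(study_gene_sets(cfg)["study2"])
    n_de = int(round(cfg.frac_de * cfg.n_genes))
    if n_de == 0:
        return {}, {}, []

    relations, actives, causal_directions = gen_causal_relations(cfg)
    rng = np.random.default_rng([_STREAM_EXPR, cfg.seed, 7])

    de: dict[str, int] = {}
    for hyp, sign in actives:
        de[hyp] = sign
    for gene, d in causal_directions.items():
        if len(de) < n_de:
            de.setdefault(gene, d)
    for g in ("ADM", "MMP1", "BIRC5", "CTGF", DECOY_REVIEW_GENE, DECOY_ACRONYM_GENE):
        if g in overlap_set and len(de) < n_de:
            de.setdefault(g, int(rng.choice([1, -1])))
    fillers = [g for g in universe if g in overlap_set and g not in de]
    rng.shuffle(fillers)
    for g in fillers:
        if len(de) >= n_de:
            break
        de[g] = int(rng.choice([1, -1]))

    # cancer-only co-expression modules around the planted target hubs;
    # four partners per hub keeps each hub-partner partial correlation
    # strong (a larger star dilutes the per-edge conditional dependence)
    hub_partners: dict[str, list[str]] = {}
    pool = [g for g in de if g.startswith("G")]
    idx = 0
    for hub in HUB_GENES:
        if hub not in de:
            continue
        partners = pool[idx: idx + 4]
        idx += 4
        if len(partners) >= 3:
            hub_partners[hub] = partners
    return de, hub_partners, actives


# ---------------------------------------------------------------------------
# probe design and expression
# ---------------------------------------------------------------------------

def _probe_design(cfg: SimulationConfig) -> dict[str, pd.DataFrame]:
    """Per-study probe tables: probe_id, gene_ids (list), accession, quirk.

    Quirks planted per study: one probe mapped to two genes, one gene
    covered by sibling probes (one sibling an outlier in study1), one probe
    whose gene is only recoverable through the accession gap-fill map, and
    one unannotatable probe.
    """
    designs = {}
    for k, (study, genes) in enumerate(study_gene_sets(cfg).items(), start=1):
        rows = []
        gapfill_gene = next(g for g in genes if g.startswith("G"))
        for i, g in enumerate(genes, start=1):
            if g == gapfill_gene:
                # annotation lost; accession still present
                rows.append((f"S{k}P{i:05d}", [], f"NM_{k}{i:05d}", "gapfill"))
            else:
                rows.append((f"S{k}P{i:05d}", [g], f"NM_{k}{i:05d}", ""))
        n = len(genes)
        if study == "study1":
            rows.append((f"S{k}P{n + 1:05d}", ["BIRC5"], "", "sibling"))
            rows.append((f"S{k}P{n + 2:05d}", ["BIRC5"], "", "sibling_outlier"))
            rows.append((f"S{k}P{n + 3:05d}", ["BIRC5", "BIRC3"], "", "multigene"))
            rows.append((f"S{k}P{n + 4:05d}", [], "XR_ORPHAN1", "orphan"))
        else:
            rows.append((f"S{k}P{n + 1:05d}", ["CTGF"], "", "sibling"))
            rows.append((f"S{k}P{n + 2:05d}", [], "XR_ORPHAN2", "orphan"))
        designs[study] = pd.DataFrame(rows, columns=["probe_id", "gene_ids", "accession", "quirk"])
    return designs


def gen_probe_annotation(cfg: SimulationConfig):
    """Annotation tables plus the accession->gene gap-fill map.

    Returns ``(tables, gapfill)``: per-study DataFrames with columns
    (probe_id, gene_ids pipe-joined, accession) and a DataFrame mapping
    accessions back to gene identifiers for probes whose direct annotation
    is missing.  Orphan probes stay unannotatable even after gap-fill.
    """
    cfg.validate()
    designs = _probe_design(cfg)
    tables = {}
    gap_rows = []
    for study, design in designs.items():
        out = design.copy()
        out["gene_ids"] = ["|".join(g) for g in out["gene_ids"]]
        tables[study] = out[["probe_id", "gene_ids", "accession"]]
        genes = study_gene_sets(cfg)[study]
        lost = design.loc[design["quirk"] == "gapfill"]
        for _, row in lost.iterrows():
            gene = next(g for g in genes if g.startswith("G"))
            gap_rows.append((row["accession"], gene))
    gapfill = pd.DataFrame(gap_rows, columns=["accession", "gene_id"])
    return tables, gapfill


def gen_expression_batches(cfg: SimulationConfig):
    """Probe-level expression tables for both studies plus the sample map.

    Returns ``(tables, sample_map, truth)``.  DE genes are shifted by
    ``direction * logfc_magnitude`` in cancer samples; study2 values are
    transformed ``x -> batch_scale * x + batch_shift``; per-gene Gaussian
    noise with sd ``noise_sd`` on the log2 scale; planted hub genes share a
    cancer-only latent factor with their partner genes, creating the
    condition-specific dependency structure downstream stages look for.
    """
    cfg.validate()
    rng = np.random.default_rng([_STREAM_EXPR, cfg.seed])
    universe = gene_universe(cfg)
    base = pd.Series(rng.normal(7.0, 1.5, len(universe)), index=universe)

    de, hub_partners, actives = _de_plan(cfg)
    designs = _probe_design(cfg)

    tables = {}
    sm_rows = []
    batch_params = {"study1": (0.0, 1.0), "study2": (cfg.batch_shift, cfg.batch_scale)}
    for k, (study, design) in enumerate(designs.items(), start=1):
        n_c, n_n = cfg.n_cancer_per_batch, cfg.n_control_per_batch
        samples = [f"S{k}C{i:02d}" for i in range(1, n_c + 1)] + \
                  [f"S{k}N{i:02d}" for i in range(1, n_n + 1)]
        cond = np.array(["cancer"] * n_c + ["control"] * n_n)
        for s, c in zip(samples, cond):
            sm_rows.append((s, c, study))

        genes = study_gene_sets(cfg)[study]
        gmat = pd.DataFrame(
            base[genes].to_numpy()[:, None] + rng.normal(0, cfg.noise_sd, (len(genes), len(samples))),
            index=genes, columns=samples,
        )
        is_cancer = cond == "cancer"
        for g, d in de.items():
            if g in gmat.index:
                gmat.loc[g, is_cancer] += d * cfg.logfc_magnitude
        # star-coupled hub modules: partners track the hub's observed values
        # in cancer samples only, giving the hub a high dependency-network
        # degree under cancer and none under control
        for hub, partners in hub_partners.items():
            if hub not in gmat.index:
                continue
            hub_vals = gmat.loc[hub, is_cancer].to_numpy()
            centered = hub_vals - hub_vals.mean()
            for p_gene in partners:
                if p_gene in gmat.index:
                    gmat.loc[p_gene, is_cancer] += 2.0 * centered

        pvals = np.empty((len(design), len(samples)))
        for r, (_, row) in enumerate(design.iterrows()):
            gl = row["gene_ids"]
            if not gl:
                pvals[r] = rng.normal(5.0, 1.0, len(samples))
            else:
                sig = gmat.loc[gl].mean(axis=0).to_numpy()
                pvals[r] = sig + rng.normal(0, 0.05, len(samples))
                if row["quirk"] == "sibling_outlier":
                    pvals[r] += 2.0
        shift, scale = batch_params[study]
        pvals = scale * pvals + shift
        tables[study] = pd.DataFrame(pvals, index=design["probe_id"].to_list(),
                                     columns=samples)

    sample_map = pd.DataFrame(sm_rows, columns=["sample", "condition", "batch"])
    truth = GroundTruth(
        de_genes=de,
        batch_params=batch_params,
        active_hypotheses=actives,
        target_genes=[h for h in HUB_GENES if h in de],
        decoy_genes=[DECOY_REVIEW_GENE, DECOY_ACRONYM_GENE],
        hub_partners=hub_partners,
    )
    if de:
        _, _, causal_directions = gen_causal_relations(cfg)
        truth.causal_directions = causal_directions
    return tables, sample_map, truth


# ---------------------------------------------------------------------------
# gene_info and abstract corpus
# ---------------------------------------------------------------------------

def gen_gene_info(cfg: SimulationConfig) -> pd.DataFrame:
    """gene_info-style table for the whole universe plus one non-human row."""
    cols = ["#tax_id", "GeneID", "Symbol", "LocusTag", "Synonyms", "dbXrefs",
            "chromosome", "map_location", "description", "type_of_gene",
            "Symbol_from_nomenclature_authority", "Full_name_from_nomenclature_authority",
            "Nomenclature_status", "Other_designations", "Modification_date"]
    rows = []
    for i, g in enumerate(gene_universe(cfg), start=1):
        info = NAMED_GENES.get(g)
        if info:
            syn, other, desc = info["synonyms"], info["other"], info["description"]
        else:
            syn, other, desc = "-", f"uncharacterized protein {g}", f"putative gene {g}"
        rows.append(["9606", str(10000 + i), g, "-", syn, "-", "1", "1q21", desc,
                     "protein-coding", g, desc, "O", other, "20240101"])
    rows.append(["10090", "99999", "Trp53", "-", "p53", "-", "11", "11 B2",
                 "transformation related protein 53", "protein-coding", "Trp53",
                 "transformation related protein 53", "O", "-", "20240101"])
    return pd.DataFrame(rows, columns=cols)


def _long_synonym(gene: str) -> str:
    """A multi-word name for the gene, suitable as an expanded form."""
    info = NAMED_GENES.get(gene)
    if info:
        for src in (info["description"], info["other"]):
            for cand in src.split("|"):
                if cand != "-" and " " in cand:
                    return cand
        return info["description"]
    return f"uncharacterized protein {gene}"


_FILLER_SENTENCES = [
    "Tumor budding was evaluated in resection specimens.",
    "Smoking history was recorded for all participants.",
    "Patients underwent follow-up imaging every six months.",
    "Histological grade was assessed by two independent pathologists.",
    "No significant difference in overall survival was observed.",
    "Demographic characteristics were balanced between groups.",
    "Resection margins were clear in the majority of cases.",
    "Alcohol consumption was self-reported at enrolment.",
]


def gen_abstract_corpus(cfg: SimulationConfig):
    """PubMed-XML corpus, gene_info table and planted annotation truth.

    Every planted (gene, concept) pair receives three supporting records
    whose conclusions region holds one sentence carrying an expanded gene
    synonym and a concept keyword; at least one support per pair is a
    non-review unless ``frac_reviews == 1``.  Decoys include a review-only
    gene, an acronym-collision gene with no expanded form, gene-free
    keyword sentences, and both structured and unstructured abstracts.

    Returns ``(xml_bytes, gene_info, annotation_truth)``.
    """
    cfg.validate()
    rng = np.random.default_rng([_STREAM_CORPUS, cfg.seed])
    gene_info = gen_gene_info(cfg)
    universe = set(gene_universe(cfg))
    bad = [g for g, _ in cfg.planted_annotations if g not in universe]
    if bad:
        raise ConfigError(f"planted annotation genes outside universe: {bad}")

    records = []  # dicts: pmid, title, sections [(label|None, text)], mesh, review

    def support_record(gene, concept, i):
        syn = _long_synonym(gene)
        phrase = _CONCEPT_PHRASE[concept]
        concl = (f"Our findings indicate that {syn} drives {phrase} in oral "
                 f"squamous cell carcinoma and may represent a therapeutic target.")
        mesh = ["Humans", "Neoplasms"]
        if gene != "CTGF":  # CTGF evidence is generic-cancer only (tier C path)
            mesh.append("Mouth Neoplasms")
        title = f"Role of {syn} in oral carcinogenesis: cohort {i + 1}"
        if i % 2 == 0:
            sections = [
                ("BACKGROUND", "The molecular drivers of oral cancer remain incompletely defined."),
                ("METHODS", "Tumor and matched normal tissues were profiled by microarray."),
                ("RESULTS", f"Expression of {syn} differed markedly between groups. "
                            "Validation was performed in an independent cohort."),
                ("CONCLUSIONS", concl),
            ]
        else:
            body = ("We studied resected oral tumors from a hospital registry. "
                    "Expression profiling was carried out on all specimens. "
                    "Clinical covariates were available for most patients. ")
            sections = [(None, body + concl)]
        return {"title": title, "sections": sections, "mesh": mesh, "review": False,
                "forced_nonreview": True}

    truth: set[tuple[str, str]] = set()
    for gene, concept in cfg.planted_annotations:
        truth.add((gene, concept))
        for i in range(4):
            records.append(support_record(gene, concept, i))

    # decoy 1: review article carrying hallmark evidence for CD70
    records.append({
        "title": "CD70 in cancer immunotherapy: a review",
        "sections": [(None, "CD27 ligand signalling modulates apoptosis of tumor cells "
                            "in many malignancies including oral cancer. "
                            "This review summarises current evidence.")],
        "mesh": ["Humans", "Neoplasms", "Mouth Neoplasms"],
        "review": True, "forced_review": True,
    })
    # decoy 2: bare acronym with no expanded form anywhere before it
    records.append({
        "title": "Serum markers in head and neck cancer",
        "sections": [(None, "We measured a panel of serum proteins in oral cancer patients. "
                            "LYN levels correlated with apoptosis markers in serum.")],
        "mesh": ["Humans", "Neoplasms", "Mouth Neoplasms"],
        "review": False, "forced_nonreview": True,
    })
    # decoy 3: keyword sentences with no gene mention at all
    records.append({
        "title": "Histopathological grading of oral tumors",
        "sections": [("CONCLUSIONS", "Invasion depth predicts metastasis and poor prognosis.")],
        "mesh": ["Humans", "Neoplasms", "Mouth Neoplasms"],
        "review": False,
    })

    while len(records) < cfg.n_abstracts:
        k = int(rng.integers(2, 5))
        body = " ".join(_FILLER_SENTENCES[int(j)] for j in rng.integers(0, len(_FILLER_SENTENCES), k))
        mesh = ["Humans", "Neoplasms"]
        if rng.random() < 0.7:
            mesh.append("Mouth Neoplasms")
        records.append({"title": "Observational study of oral lesions",
                        "sections": [(None, body)], "mesh": mesh, "review": False})

    # review flags: Bernoulli(frac_reviews) with planted guarantees
    for rec in records:
        if rec.get("forced_review"):
            rec["review"] = True
        elif rec.get("forced_nonreview") and cfg.frac_reviews < 1.0:
            rec["review"] = False
        else:
            rec["review"] = bool(rng.random() < cfg.frac_reviews)
    if cfg.frac_reviews >= 1.0:
        for rec in records:
            rec["review"] = True

    xml = _records_to_pubmed_xml(records)
    return xml, gene_info, truth


def _records_to_pubmed_xml(records: list[dict]) -> bytes:
    root = etree.Element("PubmedArticleSet")
    for i, rec in enumerate(records, start=1):
        art = etree.SubElement(root, "PubmedArticle")
        cit = etree.SubElement(art, "MedlineCitation")
        etree.SubElement(cit, "PMID").text = str(10_000_000 + i)
        article = etree.SubElement(cit, "Article")
        etree.SubElement(article, "ArticleTitle").text = rec["title"]
        abstract = etree.SubElement(article, "Abstract")
        for label, text in rec["sections"]:
            at = etree.SubElement(abstract, "AbstractText")
            if label:
                at.set("Label", label)
            at.text = text
        ptl = etree.SubElement(article, "PublicationTypeList")
        etree.SubElement(ptl, "PublicationType").text = "Journal Article"
        if rec["review"]:
            etree.SubElement(ptl, "PublicationType").text = "Review"
        mhl = etree.SubElement(cit, "MeshHeadingList")
        for term in rec["mesh"]:
            mh = etree.SubElement(mhl, "MeshHeading")
            etree.SubElement(mh, "DescriptorName").text = term
    return etree.tostring(root, pretty_print=True, xml_declaration=True, encoding="UTF-8")


# ---------------------------------------------------------------------------
# planted dependency structure for network-recovery checks
# ---------------------------------------------------------------------------

def gen_ggm_data(n_genes: int = 50, n_edges: int = 20, pcor: float = 0.6,
                 n_samples: int = 100, seed: int = 0):
    """Multivariate-normal sample with a planted partial-correlation graph.

    Builds a precision matrix with unit diagonal and ``-pcor`` on randomly
    chosen disjoint edges (node degree capped at 1, so the matrix stays
    positive definite for any ``|pcor| < 1`` and every planted edge has
    exactly the stated partial correlation), then draws ``n_samples``
    observations.

    Returns ``(values, edges)``: a genes x samples DataFrame and the set
    of planted (gene_a, gene_b) pairs in canonical order.
    """
    if not 0 < pcor < 1:
        raise ConfigError("pcor must be in (0, 1) to keep the precision matrix PD")
    if 2 * n_edges > n_genes:
        raise ConfigError("need n_genes >= 2 * n_edges for a disjoint edge set")
    rng = np.random.default_rng(seed)
    genes = [f"N{i:03d}" for i in range(1, n_genes + 1)]
    omega = np.eye(n_genes)
    degree = np.zeros(n_genes, dtype=int)
    edges: set[tuple[str, str]] = set()
    attempts = 0
    while len(edges) < n_edges and attempts < 10000:
        attempts += 1
        i, j = rng.choice(n_genes, size=2, replace=False)
        if degree[i] >= 1 or degree[j] >= 1:
            continue
        a, b = sorted((genes[i], genes[j]))
        if (a, b) in edges:
            continue
        edges.add((a, b))
        omega[i, j] = omega[j, i] = -pcor
        degree[i] += 1
        degree[j] += 1
    if len(edges) < n_edges:
        raise ConfigError("could not place the requested number of edges")
    cov = np.linalg.inv(omega)
    X = rng.multivariate_normal(np.zeros(n_genes), cov, size=n_samples)
    values = pd.DataFrame(X.T, index=genes,
                          columns=[f"s{i:03d}" for i in range(1, n_samples + 1)])
    return values, edges


# ---------------------------------------------------------------------------
# one-call writer
# ---------------------------------------------------------------------------

def generate_all(cfg: SimulationConfig, outdir) -> GroundTruth:
    """Write every pipeline input under ``outdir`` and return the truth.

    Files written: expr_study{1,2}.tsv, sample_map.tsv, annot_study{1,2}.tsv,
    gapfill.tsv, relations.tsv, corpus.xml, gene_info.tsv, ground_truth.json.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables, sample_map, truth = gen_expression_batches(cfg)
    for k, (study, tab) in enumerate(tables.items(), start=1):
        tab.to_csv(outdir / f"expr_study{k}.tsv", sep="\t", index_label="probe_id",
                   float_format="%.6f")
    sample_map.to_csv(outdir / "sample_map.tsv", sep="\t", index=False)

    annots, gapfill = gen_probe_annotation(cfg)
    for k, (study, tab) in enumerate(annots.items(), start=1):
        tab.to_csv(outdir / f"annot_study{k}.tsv", sep="\t", index=False)
    gapfill.to_csv(outdir / "gapfill.tsv", sep="\t", index=False)

    relations, actives, _ = gen_causal_relations(cfg)
    relations.to_csv(outdir / "relations.tsv", sep="\t", index=False)

    xml, gene_info, annotation_truth = gen_abstract_corpus(cfg)
    (outdir / "corpus.xml").write_bytes(xml)
    gene_info.to_csv(outdir / "gene_info.tsv", sep="\t", index=False)

    truth.annotation_truth = annotation_truth
    truth.to_json(outdir / "ground_truth.json")
    return truth
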