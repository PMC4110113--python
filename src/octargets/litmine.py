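"""Rule-based literature mining of a local PubMed-XML corpus.

Gene symbols are expanded to synonyms (from a gene_info-style table),
turned into tagged boolean queries (``[TIAB]`` title/abstract phrases,
``[MH]`` MeSH terms), and evaluated against the corpus.  Matching
non-review records pass acronym disambiguation, their conclusions region
is sectioned out, and single sentences carrying both a gene synonym and a
concept keyword assign marker types (therapeutic / prognostic /
diagnostic) and cancer hallmarks (apoptosis / angiogenesis / cell
proliferation / metastasis / inflammation) to the gene.  A two-tier
context is used: oral-cancer articles first (``mouth neoplasms[MH]``),
falling back to any cancer (``neoplasms[MH]``) when nothing qualifies.
Per-concept counts are tested against global corpus counts with Fisher's
exact test.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import pandas as pd
from lxml import etree
from scipy import stats

from .errors import AccountingError, InputFormatError, QueryParseError

MARKER_KEYWORDS: dict[str, tuple[str, ...]] = {
    "therapeutic": ("therapeutic", "therapy"),
    "prognostic": ("prognostic", "prognosis"),
    "diagnostic": ("diagnostic", "diagnosis", "predictive", "tumor marker"),
}

HALLMARK_KEYWORDS: dict[str, tuple[str, ...]] = {
    "apoptosis": ("cell death", "apoptosis", "anti-apoptosis", "anti-apoptotic"),
    "angiogenesis": ("angiogenesis", "angiogenic"),
    "cell_proliferation": ("cell growth", "proliferation", "proliferative"),
    "metastasis": ("cell migration", "cell motility", "invasion", "metastasis",
                   "metastases", "metastatic"),
    "inflammation": ("inflammation", "inflammatory"),
}

CONCEPT_KEYWORDS = {**MARKER_KEYWORDS, **HALLMARK_KEYWORDS}

#: term lists used in the corpus-wide (global) queries per concept; the
#: apoptosis list additionally carries the bare adjective
GLOBAL_QUERY_TERMS: dict[str, tuple[str, ...]] = {
    **{c: kw for c, kw in CONCEPT_KEYWORDS.items()},
    "apoptosis": ("cell death", "apoptosis", "apoptotic", "anti-apoptosis",
                  "anti-apoptotic"),
}

CONTEXT_TERMS = {"mouth_neoplasms": "mouth neoplasms", "neoplasms": "neoplasms"}
TIER_OF_CONTEXT = {"mouth_neoplasms": "MN", "neoplasms": "C"}


# ---------------------------------------------------------------------------
# corpus records
# ---------------------------------------------------------------------------


@dataclass
class AbstractRecord:
    pmid: str
    title: str
    sections: list[tuple[str | None, str]]
    mesh_terms: list[str]
    is_review: bool

    @property
    def abstract_text(self) -> str:
        return " ".join(text for _, text in self.sections)

    @property
    def searchable_text(self) -> str:
        return self.title + " " + self.abstract_text


def load_corpus(path) -> list[AbstractRecord]:
    """Parse PubMed-XML (PubmedArticleSet) into AbstractRecord objects.

    ``path`` may be a filesystem path or a file-like object.
    """
    tree = etree.parse(path if hasattr(path, "read") else str(path))
    records = []
    seen = set()
    for art in tree.getroot().iter("PubmedArticle"):
        pmid = art.findtext(".//PMID") or ""
        if pmid in seen:
            raise InputFormatError(f"duplicate PMID {pmid} in corpus")
        seen.add(pmid)
        title = art.findtext(".//ArticleTitle") or ""
        sections = []
        for at in art.iter("AbstractText"):
            sections.append((at.get("Label"), at.text or ""))
        ptypes = [pt.text or "" for pt in art.iter("PublicationType")]
        mesh = [dn.text or "" for dn in art.iter("DescriptorName")]
        records.append(AbstractRecord(
            pmid=pmid, title=title, sections=sections, mesh_terms=mesh,
            is_review=any(p.strip().lower() == "review" for p in ptypes),
        ))
    return records


# ---------------------------------------------------------------------------
# synonym table
# ---------------------------------------------------------------------------


def build_synonym_table(gene_info, tax_id: str = "9606") -> dict[str, list[str]]:
    """Symbol -> ordered unique name list from a gene_info-style table.

    Names are collected from the synonyms, other-designations and
    descriptive-name columns (in that order), after restricting to the
    requested taxon.  The symbol itself always leads the list; ``-``
    placeholders and names containing ``#`` are dropped.
    """
    if not isinstance(gene_info, pd.DataFrame):
        gene_info = pd.read_csv(gene_info, sep="\t", dtype=str).fillna("-")
    cols = {c.lstrip("#"): c for c in gene_info.columns}
    if "Symbol" not in cols:
        raise InputFormatError("gene_info table lacks a Symbol column")
    tax_col = cols.get("tax_id")
    if tax_col is not None:
        gene_info = gene_info[gene_info[tax_col].astype(str) == tax_id]

    table: dict[str, list[str]] = {}
    for _, row in gene_info.iterrows():
        symbol = str(row[cols["Symbol"]])
        names = [symbol]
        sources = []
        for key in ("Synonyms", "Other_designations", "description"):
            if key in cols:
                sources.append(str(row[cols[key]]))
        for src in sources:
            for name in src.split("|"):
                name = name.strip()
                if not name or name == "-" or "#" in name:
                    continue
                if name not in names:
                    names.append(name)
        table[symbol] = names
    return table


def format_synonym_table(table: dict[str, list[str]]) -> str:
    """Two-column layout: symbol TAB '#'-joined alternative names."""
    lines = []
    for symbol in table:
        others = [n for n in table[symbol] if n != symbol]
        lines.append(f"{symbol}\t{'#'.join(others)}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# boolean queries
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Term:
    text: str
    tag: str  # TIAB or MH


@dataclass(frozen=True)
class And:
    children: tuple

@dataclass(frozen=True)
class Or:
    children: tuple


def serialize_query(node, top: bool = True) -> str:
    if isinstance(node, Term):
        return f"{node.text}[{node.tag}]"
    joiner = " AND " if isinstance(node, And) else " OR "
    inner = joiner.join(serialize_query(c, top=False) for c in node.children)
    if top and isinstance(node, And):
        return inner
    return f"({inner})"


def parse_query(text: str):
    """Parse the tag/boolean query subset; AND binds tighter than OR."""
    pos = 0
    n = len(text)

    def skip_ws():
        nonlocal pos
        while pos < n and text[pos].isspace():
            pos += 1

    term_re = re.compile(r"([^()\[\]]+?)\[(TIAB|MH)\]")

    def parse_atom():
        nonlocal pos
        skip_ws()
        if pos >= n:
            raise QueryParseError("unexpected end of query", pos)
        if text[pos] == "(":
            pos += 1
            node = parse_or()
            skip_ws()
            if pos >= n or text[pos] != ")":
                raise QueryParseError("missing closing parenthesis", pos)
            pos += 1
            return node
        m = term_re.match(text, pos)
        if not m:
            raise QueryParseError(f"expected term at position {pos}", pos)
        pos = m.end()
        return Term(m.group(1).strip(), m.group(2))

    def parse_and():
        nonlocal pos
        children = [parse_atom()]
        while True:
            skip_ws()
            if text.startswith("AND", pos):
                pos += 3
                children.append(parse_atom())
            else:
                break
        return children[0] if len(children) == 1 else And(tuple(children))

    def parse_or():
        nonlocal pos
        children = [parse_and()]
        while True:
            skip_ws()
            if text.startswith("OR", pos):
                pos += 2
                children.append(parse_and())
            else:
                break
        return children[0] if len(children) == 1 else Or(tuple(children))

    node = parse_or()
    skip_ws()
    if pos != n:
        raise QueryParseError(f"trailing input at position {pos}", pos)
    return node


def _concept_block() -> Or:
    """The fixed concept-keyword block of every gene-specific query."""
    t = lambda w: Term(w, "TIAB")
    marker = And((
        Or(tuple(t(w) for w in ("therapeutic", "therapy", "diagnostic", "diagnosis",
                                "prognostic", "prognosis", "inflammatory"))),
        Or(tuple(t(w) for w in ("target", "molecule", "marker"))),
    ))
    cell = And((t("cell"), Or(tuple(
        t(w) for w in ("proliferation", "proliferative", "death", "growth",
                       "immortalization", "migration")))))
    hallmark = Or(tuple(
        t(w) for w in ("apoptosis", "apoptotic", "anti-apoptosis", "anti-apoptotic",
                       "angiogenesis", "metastasis", "metastatic", "inflammation",
                       "invasion")
    ) + (And((t("immune"), Or(tuple(
        t(w) for w in ("modulation", "resistance", "destruction"))))),))
    return Or((marker, cell, hallmark))


def build_query(gene: str, synonyms: list[str], context: str = "mouth_neoplasms"):
    """Gene-specific query: synonym block AND concept block AND context.

    Returns ``(tree, serialized_string)``; the serialization follows the
    tagged template with the context MeSH term last.
    """
    if context not in CONTEXT_TERMS:
        raise ValueError(f"unknown context {context!r}")
    names = list(dict.fromkeys([gene, *synonyms]))
    syn_block = Or(tuple(Term(s, "TIAB") for s in names))
    tree = And((And((syn_block, _concept_block())), Term(CONTEXT_TERMS[context], "MH")))
    return tree, serialize_query(tree)


def build_global_query(concept: str, context: str = "mouth_neoplasms"):
    """Corpus-wide concept query used for the Fisher global statistics."""
    terms = GLOBAL_QUERY_TERMS[concept]
    tree = And((Or(tuple(Term(w, "TIAB") for w in terms)),
                Term(CONTEXT_TERMS[context], "MH")))
    return tree, serialize_query(tree)


# ---------------------------------------------------------------------------
# query evaluation
# ---------------------------------------------------------------------------


@lru_cache(maxsize=4096)
def _phrase_pattern(phrase: str) -> re.Pattern:
    # whole-phrase, word-boundary match; hyphens count as word characters
    body = re.escape(phrase).replace(r"\ ", r"\s+")
    return re.compile(rf"(?<![\w-]){body}(?![\w-])", re.IGNORECASE)


def phrase_in(phrase: str, text: str) -> bool:
    return bool(_phrase_pattern(phrase).search(text))


def _matches(node, rec: AbstractRecord) -> bool:
    if isinstance(node, Term):
        if node.tag == "MH":
            return any(node.text.lower() == m.lower() for m in rec.mesh_terms)
        return phrase_in(node.text, rec.searchable_text)
    if isinstance(node, And):
        return all(_matches(c, rec) for c in node.children)
    return any(_matches(c, rec) for c in node.children)


def evaluate_query(query, corpus: list[AbstractRecord]) -> list[AbstractRecord]:
    """Records matching a query tree (or serialized query string)."""
    if isinstance(query, str):
        query = parse_query(query)
    return [rec for rec in corpus if _matches(query, rec)]


# ---------------------------------------------------------------------------
# abstract sectioning and sentences
# ---------------------------------------------------------------------------

_PROTECTED = ("et al.", "Fig.", "vs.", "e.g.", "i.e.", "approx.", "ca.", "Dr.")
_BOUNDARY = re.compile(r"(?<=[.!?])\s+(?=[A-Z])")


def _protect(text: str) -> str:
    for abbr in _PROTECTED:
        text = text.replace(abbr, abbr[:-1] + "\x00")
    return text


def sentence_spans(text: str) -> list[tuple[int, int]]:
    """(start, end) character spans of sentences in ``text``."""
    if not text.strip():
        return []
    protected = _protect(text)
    starts = [0]
    for m in _BOUNDARY.finditer(protected):
        starts.append(m.end())
    spans = []
    for i, s in enumerate(starts):
        e = starts[i + 1] if i + 1 < len(starts) else len(text)
        spans.append((s, s + len(text[s:e].rstrip())))  # drop the separator
    return spans


def split_sentences(text: str) -> list[str]:
    """Sentence segmentation on terminal punctuation + whitespace + capital.

    Decimal numbers survive (a digit after the period blocks the split)
    and a fixed abbreviation list (et al., Fig., vs., e.g., ...) is
    protected.
    """
    return [text[s:e] for s, e in sentence_spans(text)]


def extract_conclusion(rec: AbstractRecord) -> str:
    """The conclusions region of an abstract.

    Structured abstracts with a CONCLUSION(S)-labelled section contribute
    that section verbatim; otherwise the suffix starting at the sentence
    containing the 75% character position of the abstract (conclusions
    conventionally occupy the final quarter).
    """
    labelled = [text for label, text in rec.sections
                if label and label.strip().upper().startswith("CONCLUSION")]
    if labelled:
        return " ".join(labelled)
    text = rec.abstract_text
    if not text.strip():
        return ""
    spans = sentence_spans(text)
    target = 0.75 * len(text)
    for s, e in spans:
        if e > target:
            return text[s:]
    return text[spans[-1][0]:]


# ---------------------------------------------------------------------------
# acronym disambiguation and sentence classification
# ---------------------------------------------------------------------------


def is_acronym_like(name: str, max_len: int = 6, min_upper: int = 2) -> bool:
    return len(name) <= max_len and sum(c.isupper() or c.isdigit() for c in name) >= min_upper


def disambiguate_acronym(rec: AbstractRecord, gene: str,
                         synonyms: list[str]) -> bool:
    """Keep/drop decision for a record mentioning the gene.

    If the gene is matched through a non-acronym name (multi-word or long
    synonym) the record is kept outright.  When only acronym-like mentions
    occur, the record is kept only if an expanded (multi-word) synonym
    appears somewhere before the first acronym occurrence — the title
    counting as preceding the abstract — and dropped otherwise.
    """
    text = rec.searchable_text
    long_names = [s for s in synonyms if not is_acronym_like(s)]
    acronyms = [s for s in [gene, *synonyms] if is_acronym_like(s)]
    if any(phrase_in(s, text) for s in long_names):
        return True
    first = None
    for s in acronyms:
        m = _phrase_pattern(s).search(text)
        if m and (first is None or m.start() < first):
            first = m.start()
    if first is None:
        return False  # gene not actually mentioned
    preceding = text[:first]
    expanded = [s for s in synonyms if " " in s]
    return any(phrase_in(s, preceding) for s in expanded)


def classify_sentences(sentences: list[str], synonyms: list[str]):
    """Concepts assigned by same-sentence co-occurrence.

    A concept is assigned iff a single sentence contains both a gene
    synonym and one of the concept's keywords (case-insensitive whole
    phrases).  Returns ``(concepts, evidence)`` with the supporting
    sentences per concept.
    """
    concepts: set[str] = set()
    evidence: list[tuple[str, str]] = []
    for sentence in sentences:
        if not any(phrase_in(s, sentence) for s in synonyms):
            continue
        for concept, keywords in CONCEPT_KEYWORDS.items():
            if any(phrase_in(k, sentence) for k in keywords):
                concepts.add(concept)
                evidence.append((concept, sentence))
    return concepts, evidence


# ---------------------------------------------------------------------------
# accumulation and significance
# ---------------------------------------------------------------------------

COUNT_COLUMNS = ["tier", "total_hits", "qualified_hits", *MARKER_KEYWORDS, *HALLMARK_KEYWORDS]


def global_counts(corpus: list[AbstractRecord]) -> pd.DataFrame:
    """Context totals and per-concept global counts for both tiers."""
    rows = {}
    for context in CONTEXT_TERMS:
        ctx_records = evaluate_query(Term(CONTEXT_TERMS[context], "MH"), corpus)
        row = {"total": len(ctx_records)}
        for concept in CONCEPT_KEYWORDS:
            tree, _ = build_global_query(concept, context)
            row[concept] = len(evaluate_query(tree, corpus))
        rows[TIER_OF_CONTEXT[context]] = row
    return pd.DataFrame(rows).T


def _mine_records(gene: str, synonyms: list[str],
                  records: list[AbstractRecord]):
    """Apply review exclusion, disambiguation and classification."""
    qualified = []
    for rec in records:
        if rec.is_review:
            continue
        if not disambiguate_acronym(rec, gene, synonyms):
            continue
        sentences = split_sentences(extract_conclusion(rec))
        concepts, evidence = classify_sentences(sentences, [gene, *synonyms])
        if concepts:
            qualified.append((rec, concepts, evidence))
    return qualified


def accumulate_counts(genes, corpus: list[AbstractRecord],
                      synonym_table: dict[str, list[str]]):
    """Per-gene annotation counts with the two-tier context fallback.

    Returns ``(counts, evidence)``: a DataFrame over ``COUNT_COLUMNS``
    indexed by gene and a per-gene list of qualified-record evidence rows
    (pmid, marker/hallmark assignments, supporting sentences).
    """
    rows = {}
    evidence_out: dict[str, list[dict]] = {}
    for gene in genes:
        synonyms = [s for s in synonym_table.get(gene, [gene]) if s != gene]
        chosen = None
        for context in ("mouth_neoplasms", "neoplasms"):
            tree, _ = build_query(gene, synonyms, context)
            hits = evaluate_query(tree, corpus)
            qualified = _mine_records(gene, synonyms, hits)
            chosen = (context, hits, qualified)
            if qualified:
                break
        context, hits, qualified = chosen
        row = {"tier": TIER_OF_CONTEXT[context], "total_hits": len(hits),
               "qualified_hits": len(qualified)}
        for concept in CONCEPT_KEYWORDS:
            row[concept] = sum(concept in concepts for _, concepts, _ in qualified)
        rows[gene] = row
        evidence_out[gene] = [
            {
                "pmid": rec.pmid,
                "marker": int(any(c in MARKER_KEYWORDS for c in concepts)),
                "marker_types": ",".join(sorted(c for c in concepts if c in MARKER_KEYWORDS)),
                "hallmark": int(any(c in HALLMARK_KEYWORDS for c in concepts)),
                "hallmark_types": ",".join(sorted(c for c in concepts if c in HALLMARK_KEYWORDS)),
                "sentences": " | ".join(dict.fromkeys(s for _, s in ev)),
            }
            for rec, concepts, ev in qualified
        ]
    counts = pd.DataFrame.from_dict(rows, orient="index")
    counts.index.name = "gene"
    if len(counts):
        counts = counts[COUNT_COLUMNS]
    return counts, evidence_out


def contingency_table(g_total: int, g_c: int, n_g: int, k: int) -> list[list[int]]:
    """2x2 layout contrasting a gene's articles with the context corpus.

    ``[[G_total - G_c, n_g - k], [G_c, k]]``: first column splits all
    context articles by concept involvement, second column does the same
    for the gene's qualified articles.
    """
    table = [[g_total - g_c, n_g - k], [g_c, k]]
    if min(min(r) for r in table) < 0:
        raise AccountingError(f"negative contingency cell: {table}")
    return table


def fisher_significance(counts: pd.DataFrame, globals_df: pd.DataFrame,
                        alpha: float = 0.05, bh: bool = False) -> pd.DataFrame:
    """Two-sided Fisher exact test per (gene, concept).

    The 2x2 table contrasts the gene's qualified articles with the whole
    context corpus: ``[[G_total - G_c, n_g - k], [G_c, k]]`` where
    ``G_total`` is the number of context articles, ``G_c`` of those
    mentioning the concept, ``n_g`` the gene's qualified articles and
    ``k`` those assigning the concept.  ``significant`` flags ``p <=
    alpha`` (optionally after BH adjustment across all tests).
    """
    rows = []
    for gene, row in counts.iterrows():
        if row["qualified_hits"] == 0:
            continue
        tier = row["tier"]
        g_total = int(globals_df.loc[tier, "total"])
        n_g = int(row["qualified_hits"])
        for concept in CONCEPT_KEYWORDS:
            g_c = int(globals_df.loc[tier, concept])
            k = int(row[concept])
            table = contingency_table(g_total, g_c, n_g, k)
            p = float(stats.fisher_exact(table, alternative="two-sided")[1])
            rows.append({"gene": gene, "tier": tier, "concept": concept,
                         "a": table[0][0], "b": table[0][1],
                         "c": table[1][0], "d": table[1][1], "p": p})
    out = pd.DataFrame(rows, columns=["gene", "tier", "concept", "a", "b", "c", "d", "p"])
    if len(out):
        if bh:
            from .diffexp import bh_adjust
            out["p_adj"] = bh_adjust(out["p"].to_numpy())
            out["significant"] = (out["p_adj"] <= alpha) & (out["d"] > 0)
        else:
            out["significant"] = (out["p"] <= alpha) & (out["d"] > 0)
    else:
        out["significant"] = pd.Series(dtype=bool)
    return out


def fisher_pvalue(table) -> float:
    """Two-sided Fisher exact p for one 2x2 table (convenience wrapper)."""
    if min(min(r) for r in table) < 0:
        raise AccountingError(f"negative contingency cell: {table}")
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def annotate_genes(genes, corpus: list[AbstractRecord],
                   synonym_table: dict[str, list[str]], alpha: float = 0.05,
                   bh: bool = False):
    """Counts, Fisher significance and evidence in one call."""
    counts, evidence = accumulate_counts(genes, corpus, synonym_table)
    gstats = global_counts(corpus)
    signif = fisher_significance(counts, gstats, alpha=alpha, bh=bh)
    return counts, signif, evidence, gstats
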