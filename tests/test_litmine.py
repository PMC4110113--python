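"""Literature mining: synonym tables, tagged queries, sectioning,
disambiguation, classification, counting and Fisher significance."""

import io

import numpy as np
import pandas as pd
import pytest
from scipy import special

from octargets import litmine as lm, synthetic_data as sd
from octargets.errors import AccountingError, QueryParseError

MMP1_SYNONYMS = ["CLG", "fibroblast collagenase", "interstitial collagenase",
                 "matrix metalloprotease 1", "matrix metalloproteinase 1"]


def _record(pmid="1", title="", sections=None, mesh=None, review=False):
    return lm.AbstractRecord(pmid=pmid, title=title,
                             sections=sections or [(None, "")],
                             mesh_terms=mesh or ["Mouth Neoplasms"],
                             is_review=review)


class TestSynonymTable:
    def test_mmp1_line_matches_reference_format(self):
        gene_info = sd.gen_gene_info(sd.SimulationConfig())
        table = lm.build_synonym_table(gene_info)
        line = lm.format_synonym_table({"MMP1": table["MMP1"]}).strip()
        assert line == ("MMP1\tCLG#fibroblast collagenase#interstitial collagenase#"
                        "matrix metalloprotease 1#matrix metalloproteinase 1")

    def test_symbol_only_and_deduplication(self):
        df = pd.DataFrame({
            "#tax_id": ["9606", "9606", "10090"],
            "Symbol": ["AAA", "BBB", "Ccc"],
            "Synonyms": ["-", "x1|shared name", "m1"],
            "Other_designations": ["-", "shared name|other bbb", "-"],
            "description": ["-", "bbb descriptive", "mouse gene"],
        })
        table = lm.build_synonym_table(df)
        assert table["AAA"] == ["AAA"]
        assert table["BBB"] == ["BBB", "x1", "shared name", "other bbb", "bbb descriptive"]
        assert "Ccc" not in table  # non-human row filtered out


class TestQueries:
    def test_gene_query_serialization_golden(self):
        _, s = lm.build_query("MMP1", MMP1_SYNONYMS, "mouth_neoplasms")
        expected = (
            "((MMP1[TIAB] OR CLG[TIAB] OR fibroblast collagenase[TIAB] OR "
            "interstitial collagenase[TIAB] OR matrix metalloprotease 1[TIAB] OR "
            "matrix metalloproteinase 1[TIAB]) AND (((therapeutic[TIAB] OR "
            "therapy[TIAB] OR diagnostic[TIAB] OR diagnosis[TIAB] OR "
            "prognostic[TIAB] OR prognosis[TIAB] OR inflammatory[TIAB]) AND "
            "(target[TIAB] OR molecule[TIAB] OR marker[TIAB])) OR (cell[TIAB] AND "
            "(proliferation[TIAB] OR proliferative[TIAB] OR death[TIAB] OR "
            "growth[TIAB] OR immortalization[TIAB] OR migration[TIAB])) OR "
            "(apoptosis[TIAB] OR apoptotic[TIAB] OR anti-apoptosis[TIAB] OR "
            "anti-apoptotic[TIAB] OR angiogenesis[TIAB] OR metastasis[TIAB] OR "
            "metastatic[TIAB] OR inflammation[TIAB] OR invasion[TIAB] OR "
            "(immune[TIAB] AND (modulation[TIAB] OR resistance[TIAB] OR "
            "destruction[TIAB]))))) AND mouth neoplasms[MH]"
        )
        assert s == expected

    def test_global_apoptosis_query_golden(self):
        _, s = lm.build_global_query("apoptosis", "mouth_neoplasms")
        assert s == ("(cell death[TIAB] OR apoptosis[TIAB] OR apoptotic[TIAB] OR "
                     "anti-apoptosis[TIAB] OR anti-apoptotic[TIAB]) AND "
                     "mouth neoplasms[MH]")

    def test_single_synonym_no_spurious_or(self):
        _, s = lm.build_query("ADM", [], "neoplasms")
        assert s.startswith("((ADM[TIAB]) AND")
        assert " OR ADM" not in s

    def test_parse_round_trip_and_errors(self):
        _, s = lm.build_query("MMP1", MMP1_SYNONYMS)
        assert lm.serialize_query(lm.parse_query(s)) == s
        with pytest.raises(QueryParseError):
            lm.parse_query("(apoptosis[TIAB] AND")
        with pytest.raises(QueryParseError) as err:
            lm.parse_query("apoptosis[BAD]")
        assert err.value.position is not None


class TestEvaluation:
    def test_boolean_and_mesh_semantics(self):
        rec = _record(title="A study", sections=[(None, "We measured apoptosis.")],
                      mesh=["Mouth Neoplasms", "Humans"])
        assert lm.evaluate_query("apoptosis[TIAB] AND mouth neoplasms[MH]", [rec])
        assert not lm.evaluate_query("apoptosis[TIAB] AND neoplasms[MH]", [rec])

    def test_whole_phrase_rule(self):
        rec = _record(sections=[(None, "An apoptotic response was seen.")])
        assert not lm.evaluate_query("apoptosis[TIAB]", [rec])
        assert lm.evaluate_query("apoptotic[TIAB]", [rec])
        anti = _record(sections=[(None, "This anti-apoptotic protein acts.")])
        assert not lm.evaluate_query("apoptotic[TIAB]", [anti])  # hyphen binds
        assert lm.evaluate_query("anti-apoptotic[TIAB]", [anti])

    def test_fixture_matches_hand_evaluation(self):
        corpus = [
            _record("1", "MMP1 in cancer", [(None, "It drives invasion.")],
                    ["Mouth Neoplasms"]),
            _record("2", "CLG biology", [(None, "No keywords here at all.")],
                    ["Neoplasms"]),
            _record("3", "Unrelated", [(None, "invasion of tissue")], ["Neoplasms"]),
            _record("4", "matrix metalloproteinase 1",
                    [(None, "A prognostic marker candidate.")], ["Mouth Neoplasms"]),
        ] + [
            _record(str(i), "Filler", [(None, "plain text")], ["Humans"])
            for i in range(5, 13)
        ]
        q = "(MMP1[TIAB] OR matrix metalloproteinase 1[TIAB]) AND mouth neoplasms[MH]"
        got = {r.pmid for r in lm.evaluate_query(q, corpus)}
        assert got == {"1", "4"}  # record 2 lacks the terms & mesh, 3 the gene


class TestSectioning:
    def test_labelled_conclusion_verbatim(self):
        rec = _record(sections=[("BACKGROUND", "Setup text."),
                                ("CONCLUSIONS", "The key finding.")])
        assert lm.extract_conclusion(rec) == "The key finding."

    def test_last_quarter_of_unstructured_abstract(self):
        sentences = [f"This sentence has fixed size {i}." for i in range(1, 9)]
        text = " ".join(sentences)
        rec = _record(sections=[(None, text)])
        assert lm.extract_conclusion(rec) == " ".join(sentences[-2:])

    def test_single_sentence_abstract(self):
        rec = _record(sections=[(None, "Only one sentence here.")])
        assert lm.extract_conclusion(rec) == "Only one sentence here."
        assert lm.extract_conclusion(_record(sections=[(None, "  ")])) == ""

    def test_sentence_splitting_rules(self):
        assert lm.split_sentences("A result. It held.") == ["A result.", "It held."]
        got = lm.split_sentences("We found p = 0.05. Next we continued.")
        assert got == ["We found p = 0.05.", "Next we continued."]
        assert lm.split_sentences("no terminal punctuation") == ["no terminal punctuation"]
        protected = lm.split_sentences("Seen by Smith et al. Nothing more.")
        assert protected == ["Seen by Smith et al. Nothing more."]


class TestDisambiguation:
    def test_expanded_form_before_acronym_keeps(self):
        rec = _record(sections=[(None, "High matrix metalloproteinase 1 (MMP1) "
                                       "drives invasion.")])
        assert lm.disambiguate_acronym(rec, "MMP1", MMP1_SYNONYMS)

    def test_bare_acronym_dropped(self):
        rec = _record(sections=[(None, "MMP1 was elevated in serum.")])
        assert not lm.disambiguate_acronym(rec, "MMP1", MMP1_SYNONYMS)

    def test_long_synonym_bypasses_rule(self):
        rec = _record(sections=[(None, "Levels of fibroblast collagenase rose.")])
        assert lm.disambiguate_acronym(rec, "MMP1", MMP1_SYNONYMS)

    def test_title_counts_as_preceding(self):
        rec = _record(title="Role of interstitial collagenase",
                      sections=[(None, "MMP1 increased sharply.")])
        assert lm.disambiguate_acronym(rec, "MMP1", MMP1_SYNONYMS)


class TestClassification:
    def test_cooccurrence_assigns_concept(self):
        concepts, ev = lm.classify_sentences(
            ["High matrix metalloproteinase 1 predicts metastatic spread."],
            ["MMP1", *MMP1_SYNONYMS])
        assert "metastasis" in concepts

    def test_same_sentence_rule(self):
        concepts, _ = lm.classify_sentences(
            ["We measured matrix metalloproteinase 1 levels.",
             "Metastatic spread was frequent."],
            ["MMP1", *MMP1_SYNONYMS])
        assert concepts == set()

    def test_multiple_lists_in_one_sentence(self):
        concepts, _ = lm.classify_sentences(
            ["The angiogenic role of interstitial collagenase affects prognosis."],
            ["MMP1", *MMP1_SYNONYMS])
        assert {"angiogenesis", "prognostic"} <= concepts


class TestCountsAndFisher:
    def test_review_only_gene_falls_back_to_generic_context(self):
        synonyms = {"GENE1": ["GENE1", "gene one protein"]}
        oral_review = _record("1", "gene one protein in oral cancer",
                              [("CONCLUSIONS", "gene one protein drives apoptosis.")],
                              ["Mouth Neoplasms", "Neoplasms"], review=True)
        generic = _record("2", "gene one protein elsewhere",
                          [("CONCLUSIONS", "gene one protein drives apoptosis.")],
                          ["Neoplasms"])
        counts, _ = lm.accumulate_counts(["GENE1"], [oral_review, generic], synonyms)
        assert counts.loc["GENE1", "tier"] == "C"
        assert counts.loc["GENE1", "qualified_hits"] == 1
        assert counts.loc["GENE1", "apoptosis"] == 1

    def test_planted_counts_and_absent_gene(self):
        synonyms = {"GENE1": ["GENE1", "gene one protein"],
                    "GENE2": ["GENE2", "gene two protein"]}
        corpus = [
            _record(str(i), "gene one protein study",
                    [("CONCLUSIONS", "gene one protein promotes apoptosis.")],
                    ["Mouth Neoplasms", "Neoplasms"])
            for i in range(3)
        ]
        counts, _ = lm.accumulate_counts(["GENE1", "GENE2"], corpus, synonyms)
        assert counts.loc["GENE1", "apoptosis"] == 3
        assert counts.loc["GENE2", "total_hits"] == 0
        assert counts.loc["GENE2", "qualified_hits"] == 0

    def test_fisher_worked_example(self):
        table = lm.contingency_table(53049, 5190, 27, 20)
        assert table == [[47859, 7], [5190, 20]]
        p = lm.fisher_pvalue(table)
        assert p == pytest.approx(2.991e-15, rel=1e-3)

    def test_no_association_gives_p_one(self):
        assert lm.fisher_pvalue([[90, 9], [10, 1]]) == pytest.approx(1.0)

    def test_matches_hypergeometric_enumeration(self):
        table = [[10, 2], [5, 8]]
        # brute-force: all tables with the same margins, two-sided by
        # cumulating probabilities <= that of the observed table
        r1, r2 = sum(table[0]), sum(table[1])
        c1 = table[0][0] + table[1][0]
        n = r1 + r2

        def prob(a):
            b, c = r1 - a, c1 - a
            d = r2 - c
            if min(b, c, d) < 0:
                return 0.0
            return float(np.exp(
                special.gammaln(r1 + 1) + special.gammaln(r2 + 1)
                + special.gammaln(c1 + 1) + special.gammaln(n - c1 + 1)
                - special.gammaln(n + 1) - special.gammaln(a + 1)
                - special.gammaln(b + 1) - special.gammaln(c + 1)
                - special.gammaln(d + 1)))

        p_obs = prob(table[0][0])
        brute = sum(prob(a) for a in range(0, min(r1, c1) + 1)
                    if prob(a) <= p_obs * (1 + 1e-9))
        assert lm.fisher_pvalue(table) == pytest.approx(brute, rel=1e-9)

    def test_negative_cell_rejected(self):
        with pytest.raises(AccountingError):
            lm.contingency_table(10, 8, 5, 9)

    def test_adding_support_is_monotone(self):
        synonyms = {"GENE1": ["GENE1", "gene one protein"]}
        support = [
            _record(str(i), "gene one protein study",
                    [("CONCLUSIONS", "gene one protein promotes apoptosis.")],
                    ["Mouth Neoplasms", "Neoplasms"])
            for i in range(6)
        ]
        filler = [_record(str(100 + i), "filler", [(None, "nothing relevant")],
                          ["Mouth Neoplasms", "Neoplasms"]) for i in range(20)]
        ps = []
        for n_support in (2, 3, 4):
            corpus = support[:n_support] + filler
            counts, signif, _, _ = lm.annotate_genes(["GENE1"], corpus, synonyms)
            assert counts.loc["GENE1", "apoptosis"] == n_support
            row = signif[(signif.gene == "GENE1") & (signif.concept == "apoptosis")]
            ps.append(float(row["p"].iloc[0]))
        assert ps[0] >= ps[1] >= ps[2]


class TestEndToEnd:
    def test_recovers_planted_pairs_and_rejects_decoys(self, sim_cfg):
        xml, gene_info, truth = sd.gen_abstract_corpus(sim_cfg)
        corpus = lm.load_corpus(io.BytesIO(xml))
        synonyms = lm.build_synonym_table(gene_info)
        genes = sorted({g for g, _ in truth} | {"CD70", "LYN"})
        counts, signif, evidence, _ = lm.annotate_genes(genes, corpus, synonyms)
        sig_pairs = {(r.gene, r.concept) for r in signif.itertuples()
                     if r.significant and r.concept in lm.HALLMARK_KEYWORDS}
        assert sig_pairs == truth
        for decoy in ("CD70", "LYN"):
            assert counts.loc[decoy, "qualified_hits"] == 0
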