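import itertools
import random

import pytest

from genorm.corpus import ArticleMetadata, NormalizedGene
from genorm.disambig import (
    ALL_RULES,
    Context,
    Rule,
    RuleResult,
    VoteSummary,
    apply_rule,
    select_candidate,
    weighted_vote,
)

from conftest import make_article


def ctx(article, section_index=0, sentence_index=0, mention_text=""):
    return Context(article, section_index, sentence_index, mention_text)


@pytest.fixture
def two_section_article():
    return make_article(sections=[
        ("introduction", "Introduction",
         "We studied TP53 in our assay. The HELA line was used throughout."),
        ("results", "Results", "Expression was measured at 17p13 loci. Mass was 43.7 kDa."),
    ])


class TestApplyRule:
    def test_cell_same_section_not_sentence(self, two_section_article, toy_kb):
        # HELA occurs in sentence 1 of the introduction, mention in sentence 0
        r = apply_rule(Rule.CELL, "1001", ctx(two_section_article, 0, 0), toy_kb,
                       ArticleMetadata())
        assert (r.y, r.w) == (1, 0.5)

    def test_cell_same_sentence(self, two_section_article, toy_kb):
        r = apply_rule(Rule.CELL, "1001", ctx(two_section_article, 0, 1), toy_kb,
                       ArticleMetadata())
        assert (r.y, r.w) == (1, 1.0)

    def test_cell_absent_article_wide(self, two_section_article, toy_kb):
        # 3T3-L1 (gene 1002's cell keyword) appears nowhere
        r = apply_rule(Rule.CELL, "1002", ctx(two_section_article, 0, 0), toy_kb,
                       ArticleMetadata())
        assert r.y == -1 and r.value == -1.0

    def test_cell_elsewhere_in_article(self, toy_kb):
        art = make_article(sections=[
            ("introduction", "I", "We studied TP53."),
            ("results", "R", "The HELA line was used."),
        ])
        r = apply_rule(Rule.CELL, "1001", ctx(art, 0, 0), toy_kb, ArticleMetadata())
        assert r.y == 0

    def test_chromosome_location_never_negative(self, toy_kb):
        art = make_article(sections=[("introduction", "I", "No location given.")])
        r = apply_rule(Rule.CHROMOSOME_LOCATION, "1001", ctx(art, 0, 0), toy_kb,
                       ArticleMetadata())
        assert r.y == 0

    def test_chromosome_location_positive(self, two_section_article, toy_kb):
        r = apply_rule(Rule.CHROMOSOME_LOCATION, "1001", ctx(two_section_article, 1, 0),
                       toy_kb, ArticleMetadata())
        assert (r.y, r.w) == (1, 1.0)

    def test_mass_tolerance(self, toy_kb):
        art = make_article(sections=[("results", "R", "A band at 44 kDa appeared.")])
        # 44 within 5% of 43.7
        r = apply_rule(Rule.MASS, "1001", ctx(art, 0, 0), toy_kb, ArticleMetadata())
        assert r.y == 1
        art2 = make_article(sections=[("results", "R", "A band at 80 kDa appeared.")])
        r2 = apply_rule(Rule.MASS, "1001", ctx(art2, 0, 0), toy_kb, ArticleMetadata())
        assert r2.y == 0  # two-valued

    def test_history(self, two_section_article, toy_kb):
        md = ArticleMetadata()
        md.normalized["tp53"] = NormalizedGene(gene_id="1001", taxon_id="9606", mentions=[1])
        r = apply_rule(Rule.HISTORY, "1001", ctx(two_section_article), toy_kb, md)
        assert r.y == 1
        r2 = apply_rule(Rule.HISTORY, "1003", ctx(two_section_article), toy_kb, md)
        assert r2.y == 0

    def test_ppi_uses_memory(self, two_section_article, toy_kb):
        md = ArticleMetadata()
        md.normalized["brca1"] = NormalizedGene(gene_id="1003", taxon_id="9606", mentions=[1])
        r = apply_rule(Rule.PPI, "1001", ctx(two_section_article), toy_kb, md)
        assert r.y == 1
        r2 = apply_rule(Rule.PPI, "1002", ctx(two_section_article), toy_kb, md)
        assert r2.y == 0

    def test_full_name_acronym(self, two_section_article, toy_kb):
        md = ArticleMetadata()
        md.add_abbreviation("sonic hedgehog", "SHH")
        r = apply_rule(Rule.FULL_NAME_ACRONYM, "1006",
                       ctx(two_section_article, mention_text="SHH"), toy_kb, md)
        assert r.y == 1

    def test_species_rule(self, toy_kb, toy_species_table):
        art = make_article(sections=[("introduction", "I", "TP53 in Mus musculus tissue.")])
        r = apply_rule(Rule.SPECIES, "1002", ctx(art, 0, 0), toy_kb, ArticleMetadata(),
                       species_table=toy_species_table)
        assert (r.y, r.w) == (1, 1.0)
        r2 = apply_rule(Rule.SPECIES, "1005", ctx(art, 0, 0), toy_kb, ArticleMetadata(),
                        species_table=toy_species_table)
        assert r2.y == -1

    def test_unknown_rule(self, two_section_article, toy_kb):
        with pytest.raises(ValueError):
            apply_rule("NotARule", "1001", ctx(two_section_article), toy_kb, ArticleMetadata())

    def test_unknown_gene(self, two_section_article, toy_kb):
        with pytest.raises(ValueError):
            apply_rule(Rule.CELL, "9999", ctx(two_section_article), toy_kb, ArticleMetadata())

    def test_rule_value_domain(self):
        with pytest.raises(ValueError):
            RuleResult(Rule.CELL, 2, 1.0)
        with pytest.raises(ValueError):
            RuleResult(Rule.CELL, 1, 0.25)


class TestWeightedVote:
    def test_all_thirteen_rules_applied(self, two_section_article, toy_kb):
        v = weighted_vote("1003", ctx(two_section_article), toy_kb, ArticleMetadata())
        assert len(v.results) == 13
        assert {r.rule_id for r in v.results} == set(ALL_RULES)

    def test_total_is_sum(self, two_section_article, toy_kb, toy_species_table):
        v = weighted_vote("1001", ctx(two_section_article, 0, 1), toy_kb,
                          ArticleMetadata(), toy_species_table)
        assert v.total == pytest.approx(sum(r.value for r in v.results))
        assert v.votes_against == sum(1 for r in v.results if r.y == -1)

    def test_bounds(self, two_section_article, toy_kb, toy_species_table):
        for gid in ("1001", "1002", "1003"):
            v = weighted_vote(gid, ctx(two_section_article), toy_kb,
                              ArticleMetadata(), toy_species_table)
            assert -13 <= v.total <= 13

    def test_species_keyword_in_sentence_separates(self, toy_kb, toy_species_table):
        art = make_article(sections=[
            ("introduction", "I", "TP53 was elevated in Mus musculus livers."),
        ])
        md = ArticleMetadata()
        v_mouse = weighted_vote("1002", ctx(art, 0, 0), toy_kb, md, toy_species_table)
        v_human = weighted_vote("1001", ctx(art, 0, 0), toy_kb, md, toy_species_table)
        assert v_mouse.total > v_human.total

    def test_monotone_in_scope(self, toy_kb):
        # moving the cell keyword from section- to sentence-scope raises the value
        art_section = make_article(sections=[
            ("introduction", "I", "TP53 was studied. The HELA line was used."),
        ])
        art_sentence = make_article(sections=[
            ("introduction", "I", "TP53 was studied in the HELA line. Filler text here."),
        ])
        md = ArticleMetadata()
        r_sec = apply_rule(Rule.CELL, "1001", ctx(art_section, 0, 0), toy_kb, md)
        r_sent = apply_rule(Rule.CELL, "1001", ctx(art_sentence, 0, 0), toy_kb, md)
        assert r_sent.value >= r_sec.value
        assert (r_sec.value, r_sent.value) == (0.5, 1.0)


def vs(gene_id, against=0, total=0.0):
    # VoteSummary with synthetic rule results matching the requested counts
    results = [RuleResult(list(ALL_RULES)[i], -1, 1.0) for i in range(against)]
    remainder = total + against
    i = against
    while remainder >= 1 and i < 13:
        results.append(RuleResult(list(ALL_RULES)[i], 1, 1.0))
        remainder -= 1
        i += 1
    if remainder == 0.5 and i < 13:
        results.append(RuleResult(list(ALL_RULES)[i], 1, 0.5))
    return VoteSummary(gene_id=gene_id, results=results)


class TestSelectCandidate:
    def test_longest_wins_regardless_of_votes(self):
        c = [("A", "transforming growth factor beta", vs("A", against=3)),
             ("B", "TGF-b", vs("B", against=0))]
        assert select_candidate(c) == "A"

    def test_fewest_votes_against_on_equal_length(self):
        c = [("A", "TP53X", vs("A", against=2)),
             ("B", "TP53Y", vs("B", against=0))]
        assert select_candidate(c) == "B"

    def test_total_tiebreak(self):
        c = [("A", "TP53", vs("A", against=0, total=1.0)),
             ("B", "TP54", vs("B", against=0, total=2.0))]
        assert select_candidate(c) == "B"

    def test_full_tie_smallest_id(self):
        c = [("B", "TP53", vs("B")), ("A", "TP53", vs("A"))]
        assert select_candidate(c) == "A"

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_candidate([])

    def test_permutation_invariance(self):
        cands = [
            ("A", "TP53", vs("A", against=1)),
            ("B", "TP53", vs("B", against=0, total=1.0)),
            ("C", "LONGNAME9", vs("C", against=2)),
            ("D", "TP53", vs("D", against=0, total=1.0)),
        ]
        winners = {select_candidate(list(p)) for p in itertools.permutations(cands)}
        assert len(winners) == 1

    def test_two_species_fixture_planted_taxon_wins(self, toy_kb, toy_species_table):
        # 200 deterministic fixtures: same surface, two taxa, keyword in-sentence
        rng = random.Random(1)
        wins = 0
        for _ in range(200):
            species_word = rng.choice(["Mus musculus", "mouse"])
            art = make_article(sections=[
                ("introduction", "I",
                 f"TP53 was measured in {species_word} samples. Filler sentence."),
            ])
            md = ArticleMetadata()
            votes = {
                gid: weighted_vote(gid, ctx(art, 0, 0, "TP53"), toy_kb, md,
                                   toy_species_table)
                for gid in ("1001", "1002")
            }
            winner = select_candidate([(g, "TP53", v) for g, v in votes.items()])
            wins += winner == "1002"
        assert wins == 200
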