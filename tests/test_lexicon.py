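import pytest
from hypothesis import given, settings, strategies as st

from genorm.corpus import SectionKind
from genorm.lexicon import (
    ARTICLE_SCOPE,
    ConfigError,
    SchemaError,
    StrategyConfig,
    StrategyMode,
    detect_species,
    enabled_for_section,
    exact_match,
    generate_variants,
    load_dictionary,
    normalize_name,
    partial_match,
    select_entries,
    write_dictionary,
)

from conftest import make_article


class TestLoadDictionary:
    def test_grouping(self, tmp_path):
        p = tmp_path / "d.tsv"
        p.write_text(
            "gene_id\ttaxon_id\tname\tname_type\n"
            "1\t9606\tAAA\tofficial\n"
            "1\t9606\talpha A\tsynonym\n"
            "2\t9606\tBBB\tofficial\n"
        )
        d = load_dictionary(str(p))
        assert len(d) == 2
        assert d.entry("1").names == {"AAA", "alpha A"}

    def test_duplicate_rows_deduplicated(self, tmp_path):
        p = tmp_path / "d.tsv"
        p.write_text(
            "gene_id\ttaxon_id\tname\tname_type\n"
            "1\t9606\tAAA\tofficial\n1\t9606\tAAA\tofficial\n"
        )
        assert load_dictionary(str(p)).entry("1").names == {"AAA"}

    def test_missing_column(self, tmp_path):
        p = tmp_path / "d.tsv"
        p.write_text("gene_id\tname\n1\tAAA\n")
        with pytest.raises(SchemaError, match="taxon_id"):
            load_dictionary(str(p))

    def test_blank_name_row_numbered(self, tmp_path):
        p = tmp_path / "d.tsv"
        p.write_text("gene_id\ttaxon_id\tname\tname_type\n1\t9606\t\tofficial\n")
        with pytest.raises(SchemaError, match=":2"):
            load_dictionary(str(p))

    def test_empty_file_warns(self, tmp_path):
        p = tmp_path / "d.tsv"
        p.write_text("gene_id\ttaxon_id\tname\tname_type\n")
        with pytest.warns(UserWarning):
            d = load_dictionary(str(p))
        assert len(d) == 0

    def test_round_trip(self, tmp_path, toy_dictionary):
        p = tmp_path / "d.tsv"
        write_dictionary(toy_dictionary, str(p))
        d2 = load_dictionary(str(p))
        assert {e.gene_id for e in d2.entries} == {e.gene_id for e in toy_dictionary.entries}


class TestGenerateVariants:
    def test_tgf_beta(self):
        v = generate_variants("TGF-beta")
        assert {"tgf beta", "tgfbeta", "tgf-β"} <= v

    def test_p53_case_only(self):
        assert generate_variants("p53") == {"p53"}

    def test_roman_to_arabic(self):
        assert "factor 2" in generate_variants("factor II")

    def test_arabic_to_roman(self):
        assert any("ii" in x for x in generate_variants("factor 2"))

    def test_protein_token_removal(self):
        assert "tumor p53" in generate_variants("tumor protein p53")

    def test_original_included(self):
        assert "Weird-Name" in generate_variants("Weird-Name")

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            generate_variants("")

    @given(st.text(alphabet="ABCdef-β123 ", min_size=1, max_size=12))
    @settings(max_examples=50, deadline=None)
    def test_idempotent(self, name):
        if not name.strip():
            return
        v1 = generate_variants(name)
        v2 = set()
        for x in v1:
            v2 |= generate_variants(x)
        assert v2 == v1


class TestExactMatch:
    def test_multi_species_name(self, toy_dictionary):
        ids = exact_match("TP53", toy_dictionary, {"9606", "10090"})
        assert ids == {"1001", "1002"}

    def test_taxon_filter(self, toy_dictionary):
        assert exact_match("TP53", toy_dictionary, {"10090"}) == {"1002"}

    def test_unknown(self, toy_dictionary):
        assert exact_match("XYZZY99", toy_dictionary, {"9606"}) == set()

    def test_empty_mention(self, toy_dictionary):
        with pytest.raises(ValueError):
            exact_match("", toy_dictionary, {"9606"})

    def test_variant_lookup(self, toy_dictionary):
        # "TGF-beta" entry reachable through its hyphen-free variant
        assert exact_match("tgfbeta", toy_dictionary, {"9606"}) == {"1004"}

    def test_brute_force_oracle(self, toy_dictionary):
        # exact_match(m) == linear scan over variant closures
        enabled = {"9606", "10090", "10116", "4565"}
        for mention in ["TP53", "tgf beta", "sonic hedgehog", "Ins1", "nothing here"]:
            brute = set()
            for e in toy_dictionary.entries:
                if e.taxon_id not in enabled:
                    continue
                if normalize_name(mention) in {normalize_name(v) for v in e.variants}:
                    brute.add(e.gene_id)
            try:
                got = exact_match(mention, toy_dictionary, enabled)
            except ValueError:
                continue
            assert got == brute


class TestPartialMatch:
    def test_missing_trailing_token_ranks_first(self, toy_dictionary):
        # full dictionary name: "breast cancer type 1 susceptibility protein"
        res = partial_match(
            "breast cancer type 1 susceptibility", toy_dictionary, {"9606"}
        )
        assert res and res[0][0] == "1003"
        assert 0 < res[0][1] <= 1.0

    def test_no_shared_token(self, toy_dictionary):
        assert partial_match("qqqq zzzz", toy_dictionary, {"9606"}) == []

    def test_tie_break_by_gene_id(self, toy_dictionary):
        res = partial_match("TP53", toy_dictionary, {"9606", "10090"})
        scores = {}
        for gid, s in res:
            scores.setdefault(s, []).append(gid)
        for gids in scores.values():
            assert gids == sorted(gids)

    def test_top_n(self, toy_dictionary):
        res = partial_match("protein", toy_dictionary, {"9606", "10090"}, top_n=2)
        assert len(res) <= 2

    def test_empty_mention(self, toy_dictionary):
        with pytest.raises(ValueError):
            partial_match("", toy_dictionary, {"9606"})


class TestDetectSpecies:
    def test_binomial(self, toy_species_table):
        assert "4565" in detect_species("grown in Triticum aestivum fields", toy_species_table)

    def test_empty(self, toy_species_table):
        assert detect_species("", toy_species_table) == set()

    def test_abbreviated_binomial(self, toy_species_table):
        assert "4932" in detect_species("cultures of S. cerevisiae were grown", toy_species_table)

    def test_case_sensitivity_honored(self, toy_species_table):
        # "H. sapiens" is case-sensitive; lowercase "h. sapiens" must not hit it
        assert "9606" not in detect_species("the h. sapiens data", toy_species_table)
        assert "9606" in detect_species("the human data", toy_species_table)

    def test_word_boundaries(self, toy_species_table):
        assert "10116" not in detect_species("aspirated material", toy_species_table)


class TestSelectEntries:
    def _article(self, intro_text, results_text="Nothing here."):
        return make_article(sections=[
            ("introduction", "Introduction", intro_text),
            ("results", "Results", results_text),
        ])

    def test_static_single_scope(self, toy_dictionary, toy_species_table):
        art = self._article("We mention Triticum aestivum.")
        cfg = StrategyConfig(mode=StrategyMode.STATIC, common_species=["9606", "10090"])
        scopes = select_entries(art, toy_dictionary, cfg, toy_species_table)
        assert scopes == {ARTICLE_SCOPE: {"9606", "10090"}}

    def test_dynamic_article_subset_of_common(self, toy_dictionary, toy_species_table):
        art = self._article("We mention human tissue only.")
        cfg = StrategyConfig(mode=StrategyMode.DYNAMIC_ARTICLE, common_species=["9606", "10090"])
        scopes = select_entries(art, toy_dictionary, cfg, toy_species_table)
        assert scopes[ARTICLE_SCOPE] == {"9606", "10090"}

    def test_dynamic_article_adds_rare_taxon(self, toy_dictionary, toy_species_table):
        art = self._article("Grown in Triticum aestivum.")
        cfg = StrategyConfig(mode=StrategyMode.DYNAMIC_ARTICLE, common_species=["9606", "10090"])
        scopes = select_entries(art, toy_dictionary, cfg, toy_species_table)
        assert scopes[ARTICLE_SCOPE] == {"9606", "10090", "4565"}

    def test_oracle_exact_taxa(self, toy_dictionary, toy_species_table):
        art = self._article("anything")
        cfg = StrategyConfig(mode=StrategyMode.ORACLE, oracle_taxa={"4565", "9606"})
        scopes = select_entries(art, toy_dictionary, cfg, toy_species_table)
        assert scopes[ARTICLE_SCOPE] == {"4565", "9606"}

    def test_oracle_requires_taxa(self):
        with pytest.raises(ConfigError):
            StrategyConfig(mode=StrategyMode.ORACLE)

    def test_section_scopes_contained_in_article_scope(self, toy_dictionary, toy_species_table):
        art = self._article("Triticum aestivum here.", "Rat data with rat keywords.")
        common = ["9606"]
        a_cfg = StrategyConfig(mode=StrategyMode.DYNAMIC_ARTICLE, common_species=common)
        s_cfg = StrategyConfig(mode=StrategyMode.DYNAMIC_SECTION, common_species=common)
        a_scopes = select_entries(art, toy_dictionary, a_cfg, toy_species_table)
        s_scopes = select_entries(art, toy_dictionary, s_cfg, toy_species_table)
        for si in range(len(art.sections)):
            assert enabled_for_section(s_scopes, si) <= a_scopes[ARTICLE_SCOPE]

    def test_deterministic(self, toy_dictionary, toy_species_table):
        art = self._article("Triticum aestivum and rat and human.")
        cfg = StrategyConfig(mode=StrategyMode.DYNAMIC_SECTION, common_species=["9606"])
        s1 = select_entries(art, toy_dictionary, cfg, toy_species_table)
        s2 = select_entries(art, toy_dictionary, cfg, toy_species_table)
        assert s1 == s2
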