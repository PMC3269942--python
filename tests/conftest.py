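import pytest

from genorm.corpus import Article, Section, SectionKind
from genorm.disambig import GeneRecord, KnowledgeBase
from genorm.lexicon import GeneDictionary, GeneEntry, SpeciesKeywordTable
from genorm.synthio import SimConfig, gen_dictionary, gen_kb


def make_article(article_id="A1", sections=None):
    """Build a segmented article from (kind, heading, text) triples."""
    secs = []
    for kind, heading, text in sections or []:
        s = Section(kind=SectionKind(kind), heading=heading, text=text)
        s.segment()
        secs.append(s)
    return Article(article_id=article_id, sections=secs)


@pytest.fixture
def toy_dictionary():
    entries = [
        GeneEntry("1001", "9606", {"TP53", "tumor protein p53"}),
        GeneEntry("1002", "10090", {"TP53", "tumor protein p53"}),
        GeneEntry("1003", "9606", {"BRCA1", "breast cancer type 1 susceptibility protein"}),
        GeneEntry("1004", "9606", {"TGF-beta", "transforming growth factor beta"}),
        GeneEntry("1005", "4565", {"EXPB11", "expansin B11"}),
        GeneEntry("1006", "9606", {"SHH", "sonic hedgehog"}),
        GeneEntry("1007", "10116", {"Ins1", "insulin 1"}),
        GeneEntry("1008", "9606", {"factor II", "coagulation factor II"}),
        GeneEntry("1009", "9606", {"VDAC1"}),
        GeneEntry("1010", "9606", {"SOCS3", "suppressor of cytokine signaling 3"}),
    ]
    return GeneDictionary(entries)


@pytest.fixture
def toy_species_table():
    return SpeciesKeywordTable(
        {
            "9606": {("Homo sapiens", False), ("human", False), ("H. sapiens", True)},
            "10090": {("Mus musculus", False), ("mouse", False), ("M. musculus", True)},
            "10116": {("Rattus norvegicus", False), ("rat", False)},
            "4565": {("Triticum aestivum", False), ("T. aestivum", True)},
            "4932": {("Saccharomyces cerevisiae", False), ("S. cerevisiae", True), ("yeast", False)},
        }
    )


@pytest.fixture
def toy_kb(toy_dictionary):
    records = {}
    for e in toy_dictionary.entries:
        records[e.gene_id] = GeneRecord(gene_id=e.gene_id, taxon_id=e.taxon_id)
    records["1001"].cell_keywords = {"HELA"}
    records["1001"].masses = {43.7}
    records["1001"].chromosome_locations = {"17p13"}
    records["1002"].cell_keywords = {"3T3-L1"}
    records["1001"].ppi_partners = {"1003"}
    records["1003"].ppi_partners = {"1001"}
    records["1006"].full_names = {"sonic hedgehog"}
    return KnowledgeBase(records)


@pytest.fixture(scope="session")
def small_sim():
    cfg = SimConfig(
        seed=1, n_species=6, n_common=3, genes_per_species=12,
        ambiguity_rate=0.3, articles=10, plants_per_article=3,
    )
    d, table = gen_dictionary(cfg)
    kb = gen_kb(d, cfg)
    return cfg, d, table, kb
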