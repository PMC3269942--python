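"""Deterministic synthetic corpora: dictionaries, knowledge bases, species
tables, articles with planted gene mentions, and gold identifier lists.

Everything is driven by one seeded random stream, so a given configuration
regenerates byte-identical output.  Gene names use a stem+numeral morphology
so that both range expansion and variant generation have targets; full names
are built to be parsable by the abbreviation extractor.
"""

from __future__ import annotations

import dataclasses
import json
import os
import random
from dataclasses import dataclass, field

from .corpus import Article, Section, SectionKind
from .disambig import GeneRecord, KnowledgeBase
from .lexicon import GeneDictionary, GeneEntry, SpeciesKeywordTable, write_dictionary, write_species_table


@dataclass(frozen=True)
class SimConfig:
    seed: int = 1
    n_species: int = 6
    n_common: int = 3
    genes_per_species: int = 12
    ambiguity_rate: float = 0.2
    articles: int = 10
    sections_per_article: int = 6
    plants_per_article: int = 3
    abbreviation_rate: float = 0.5
    range_rate: float = 0.2
    species_keyword_rate: float = 0.9

    def __post_init__(self) -> None:
        for name in ("ambiguity_rate", "abbreviation_rate", "range_rate",
                     "species_keyword_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1]: {v}")
        for name in ("n_species", "genes_per_species", "articles",
                     "sections_per_article", "plants_per_article", "n_common"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_common > self.n_species:
            raise ValueError("n_common must be <= n_species")

    @property
    def common_taxa(self) -> list[str]:
        return [_taxon_id(i) for i in range(self.n_common)]

    @property
    def all_taxa(self) -> list[str]:
        return [_taxon_id(i) for i in range(self.n_species)]


@dataclass
class GoldStandard:
    """Per-article planted identifiers plus the plant manifest."""

    ids: set[tuple[str, str]] = field(default_factory=set)  # (gene_id, taxon_id)
    plants: list[dict] = field(default_factory=list)

    @property
    def gene_ids(self) -> set[str]:
        return {g for g, _ in self.ids}

    @property
    def taxa(self) -> set[str]:
        return {t for _, t in self.ids}


_CONSONANTS = "bcdfgklmnprstvz"
_VOWELS = "aeiou"

_GENUS_STEMS = (
    "Abro", "Belli", "Cardo", "Dravo", "Elmi", "Fungo", "Gravi", "Helio",
    "Ixo", "Jasco", "Kelvo", "Lumo", "Morpho", "Nivo", "Orlo", "Praxo",
)
_SPECIES_EPITHETS = (
    "albus", "brevis", "cavus", "durus", "elegans", "fuscus", "gracilis",
    "humilis", "inermis", "junceus", "kelticus", "longus", "minutus",
    "nitidus", "ovatus", "parvus",
)

_CELL_POOL = ("QX1 cells", "RB7 cells", "TM9 line", "VK3 cells", "WL2 line", "ZD5 cells")
_TISSUE_POOL = ("cortex tissue", "hepatic lobe", "gill filament", "root tip",
                "wing disc", "spleen tissue")
_DOMAIN_POOL = ("zinc-finger domain", "kinase domain", "SH2 domain",
                "leucine zipper", "WD40 repeat", "bromodomain")
_FAMILY_POOL = ("cyclase family", "transporter family", "helicase family",
                "ligase family", "reductase family", "synthase family")
_GO_POOL = ("signal transduction", "apoptotic process", "lipid transport",
            "chromatin remodeling", "ion homeostasis", "cell adhesion")
_WORD_POOL = ("binding", "associated", "related", "induced", "regulated", "linked")
_NOUN_POOL = ("kinase", "factor", "receptor", "channel", "enzyme", "carrier")

_FILLER = (
    "The measurements were repeated three times under identical conditions.",
    "Samples were collected at regular intervals and stored appropriately.",
    "Statistical analysis confirmed the reproducibility of these observations.",
    "The experimental protocol followed standard laboratory procedures.",
    "Further validation was performed with independent replicates.",
)


def _taxon_id(i: int) -> str:
    return str(7001 + i)


def _stem(rng: random.Random) -> str:
    n = rng.randint(2, 3)
    s = "".join(rng.choice(_CONSONANTS) + rng.choice(_VOWELS) for _ in range(n))
    return s


def _species_name(i: int) -> tuple[str, str]:
    genus = _GENUS_STEMS[i % len(_GENUS_STEMS)]
    epithet = _SPECIES_EPITHETS[i % len(_SPECIES_EPITHETS)]
    if i >= len(_GENUS_STEMS):
        genus = genus + "n"
    binomial = f"{genus.lower().capitalize()}us {epithet}"
    abbrev = f"{binomial[0]}. {epithet}"
    return binomial, abbrev


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------


def gen_dictionary(cfg: SimConfig) -> tuple[GeneDictionary, SpeciesKeywordTable]:
    """Synthetic dictionary plus species-keyword table.

    A fraction ``ambiguity_rate`` of gene symbols is shared verbatim between
    two species (distinct gene_ids), emulating inter-species name ambiguity.
    """
    rng = random.Random(cfg.seed)
    taxa = cfg.all_taxa
    entries: list[GeneEntry] = []
    symbol_taxa: dict[str, set[str]] = {}
    full_names: dict[str, str] = {}
    next_id = 10001
    used_symbols: set[str] = set()

    def new_symbol() -> str:
        while True:
            sym = _stem(rng).upper() + str(rng.randint(1, 9))
            if sym not in used_symbols:
                used_symbols.add(sym)
                return sym

    # Each reuse removes one distinct name and marks one as duplicated, so a
    # duplicated-name fraction of r over distinct names needs r*N/(1+r) reuses.
    n_genes = cfg.n_species * cfg.genes_per_species
    n_reuse = round(cfg.ambiguity_rate * n_genes / (1.0 + cfg.ambiguity_rate))
    eligible = list(range(cfg.genes_per_species, n_genes))  # taxa after first
    reuse_slots = set(rng.sample(eligible, min(n_reuse, len(eligible))))

    slot = 0
    for taxon in taxa:
        for _ in range(cfg.genes_per_species):
            sym = None
            if slot in reuse_slots:
                singles = sorted(
                    s for s, tset in symbol_taxa.items()
                    if len(tset) == 1 and taxon not in tset
                )
                if singles:
                    sym = rng.choice(singles)
            if sym is None:
                sym = new_symbol()
            symbol_taxa.setdefault(sym, set()).add(taxon)
            gid = str(next_id)
            next_id += 1
            stem_word = sym[:-1].lower()
            full = (
                f"{stem_word} {rng.choice(_WORD_POOL)} "
                f"{rng.choice(_NOUN_POOL)} {sym[-1]}"
            )
            full_names[gid] = full
            entries.append(
                GeneEntry(gene_id=gid, taxon_id=taxon, names={sym, full})
            )
            slot += 1

    patterns: dict[str, set[tuple[str, bool]]] = {}
    for i, taxon in enumerate(taxa):
        binomial, abbrev = _species_name(i)
        patterns[taxon] = {(binomial, False), (abbrev, True)}
    d = GeneDictionary(entries)
    d.full_names = full_names  # carried for KB generation
    return d, SpeciesKeywordTable(patterns)


def gen_kb(d: GeneDictionary, cfg: SimConfig) -> KnowledgeBase:
    """Knowledge base fueling the disambiguation rules, PPI closure symmetric."""
    rng = random.Random(cfg.seed + 1)
    full_names: dict[str, str] = getattr(d, "full_names", {})
    records: dict[str, GeneRecord] = {}
    gene_ids = sorted(e.gene_id for e in d.entries)
    for e in sorted(d.entries, key=lambda e: e.gene_id):
        gid = e.gene_id
        records[gid] = GeneRecord(
            gene_id=gid,
            taxon_id=e.taxon_id,
            cell_keywords=set(rng.sample(_CELL_POOL, rng.randint(1, 3))),
            tissue_keywords=set(rng.sample(_TISSUE_POOL, rng.randint(1, 3))),
            domain_keywords=set(rng.sample(_DOMAIN_POOL, rng.randint(1, 3))),
            family_keywords=set(rng.sample(_FAMILY_POOL, rng.randint(1, 3))),
            go_terms=set(rng.sample(_GO_POOL, rng.randint(1, 2))),
            chromosome_locations={f"{rng.randint(1, 22)}q{rng.randint(11, 44)}"},
            sequence_lengths={rng.randint(100, 4000)},
            masses={round(rng.uniform(10.0, 250.0), 1)},
            rs_numbers={f"rs{rng.randint(10000, 99999)}"},
            full_names={full_names[gid]} if gid in full_names else set(),
        )
    for gid in gene_ids:
        for _ in range(rng.randint(0, 2)):
            partner = rng.choice(gene_ids)
            if partner != gid:
                records[gid].ppi_partners.add(partner)
                records[partner].ppi_partners.add(gid)  # symmetric closure
    return KnowledgeBase(records)


def _plant_sentences(
    rng: random.Random,
    cfg: SimConfig,
    entry: GeneEntry,
    full_name: str,
    table: SpeciesKeywordTable,
) -> tuple[str, str, str, dict]:
    """Intro / results / caption sentences for one planted gene."""
    sym = min(n for n in entry.names if " " not in n)
    binomial = next(
        surface for surface, cs in sorted(table.patterns[entry.taxon_id]) if not cs
    )
    with_abbrev = rng.random() < cfg.abbreviation_rate
    with_species = rng.random() < cfg.species_keyword_rate
    species_part = f" in {binomial}" if with_species else ""
    if with_abbrev:
        intro = f"We investigated the {full_name} ({sym}){species_part}."
    else:
        intro = f"We investigated {sym}{species_part}."
    results = f"Expression of {sym} increased markedly after treatment."
    caption = f"Levels of {sym} across conditions."
    manifest = {
        "gene_id": entry.gene_id,
        "taxon_id": entry.taxon_id,
        "symbol": sym,
        "with_abbreviation": with_abbrev,
        "with_species_keyword": with_species,
    }
    return intro, results, caption, manifest


def gen_article(
    d: GeneDictionary,
    kb: KnowledgeBase,
    table: SpeciesKeywordTable,
    cfg: SimConfig,
    article_index: int,
) -> tuple[Article, GoldStandard]:
    """One synthetic article with planted mentions and its gold entry."""
    rng = random.Random(cfg.seed * 100003 + article_index)
    entries = sorted(d.entries, key=lambda e: e.gene_id)
    # sample plants with pairwise-distinct symbols: one surface maps to one
    # identifier within an article (cross-article ambiguity is preserved)
    plants: list[GeneEntry] = []
    used: set[str] = set()
    for entry in rng.sample(entries, len(entries)):
        sym = min(n for n in entry.names if " " not in n)
        if sym in used:
            continue
        used.add(sym)
        plants.append(entry)
        if len(plants) == cfg.plants_per_article:
            break
    full_names = getattr(d, "full_names", {})
    gold = GoldStandard()

    intro_sents: list[str] = []
    results_sents: list[str] = []
    caption_sents: list[str] = []
    for entry in plants:
        intro, results, caption, manifest = _plant_sentences(
            rng, cfg, entry, full_names.get(entry.gene_id, max(entry.names, key=len)), table
        )
        gold.ids.add((entry.gene_id, entry.taxon_id))
        manifest["section"] = "introduction"
        manifest["sentence_index"] = len(intro_sents)
        gold.plants.append(manifest)
        intro_sents.append(intro)
        results_sents.append(results)
        caption_sents.append(caption)

    focus_taxon = plants[0].taxon_id
    focus_binomial = next(
        s for s, cs in sorted(table.patterns[focus_taxon]) if not cs
    )
    intro_sents.append(f"All experiments used {focus_binomial} material.")
    if rng.random() < cfg.range_rate:
        stem = _stem(rng).upper()
        hi = rng.randint(3, 5)
        results_sents.append(
            f"We also examined the {stem}1-{stem}{hi} cluster for completeness."
        )
    intro_sents.append(rng.choice(_FILLER))
    results_sents.append(rng.choice(_FILLER))

    n_other = max(cfg.sections_per_article - 5, 1)
    other_sections = [
        Section(
            kind=SectionKind.OTHER,
            heading=f"Additional analysis {j + 1}",
            text=" ".join(rng.sample(_FILLER, 2)),
        )
        for j in range(n_other)
    ]
    sections = [
        Section(
            kind=SectionKind.TITLE,
            heading="Title",
            text=f"A study of gene regulation in {focus_binomial}.",
        ),
        Section(
            kind=SectionKind.ABSTRACT,
            heading="Abstract",
            text=(
                f"We characterize {min(n for n in plants[0].names if ' ' not in n)} "
                f"function in {focus_binomial}. " + rng.choice(_FILLER)
            ),
        ),
        Section(kind=SectionKind.INTRODUCTION, heading="Introduction",
                text=" ".join(intro_sents)),
        Section(kind=SectionKind.RESULTS, heading="Results",
                text=" ".join(results_sents)),
        *other_sections,
        Section(kind=SectionKind.FIGURE_CAPTION, heading="Figure 1",
                text=" ".join(caption_sents)),
    ]
    for s in sections:
        s.segment()
    art = Article(article_id=f"SYN{article_index:04d}", sections=sections)
    return art, gold


def gen_corpus(cfg: SimConfig, out_dir: str) -> dict:
    """Write the full synthetic corpus; returns the manifest."""
    os.makedirs(out_dir, exist_ok=True)
    articles_dir = os.path.join(out_dir, "articles")
    os.makedirs(articles_dir, exist_ok=True)
    d, table = gen_dictionary(cfg)
    kb = gen_kb(d, cfg)
    write_dictionary(d, os.path.join(out_dir, "dict.tsv"))
    kb.to_json(os.path.join(out_dir, "kb.json"))
    write_species_table(table, os.path.join(out_dir, "species.tsv"))

    from .corpus import write_article

    gold_rows: list[tuple[str, str, str]] = []
    manifest_plants: dict[str, list[dict]] = {}
    for i in range(cfg.articles):
        art, gold = gen_article(d, kb, table, cfg, i)
        write_article(art, os.path.join(articles_dir, f"{art.article_id}.json"))
        for gid, taxon in sorted(gold.ids):
            gold_rows.append((art.article_id, gid, taxon))
        manifest_plants[art.article_id] = gold.plants
    with open(os.path.join(out_dir, "gold.tsv"), "w", encoding="utf-8") as fh:
        fh.write("article_id\tgene_id\ttaxon_id\n")
        for row in gold_rows:
            fh.write("\t".join(row) + "\n")
    manifest = {
        "config": dataclasses.asdict(cfg),
        "n_genes": len(d.entries),
        "plants": manifest_plants,
    }
    with open(os.path.join(out_dir, "manifest.json"), "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest


def read_gold_with_taxa(path: str) -> dict[str, set[tuple[str, str]]]:
    """Gold TSV with taxa: article_id -> {(gene_id, taxon_id)}."""
    out: dict[str, set[tuple[str, str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if not parts or parts[0] in ("article_id", ""):
                continue
            out.setdefault(parts[0], set()).add((parts[1], parts[2]))
    return out
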