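"""Gene-name dictionary with orthographic variants, matching and entry selection.

The dictionary maps normalized names (and generated orthographic variants) to
gene identifiers, each tied to a species.  Entry selection implements three
strategies for reducing the species complexity of the dictionary: a static
common-species list, dynamic selection from species keywords detected in the
article or in each section, and an oracle mode fed from gold-standard taxa.
"""

from __future__ import annotations

import csv
import math
import re
import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, TYPE_CHECKING

if TYPE_CHECKING:  # pragma: no cover
    from .corpus import Article


class SchemaError(ValueError):
    pass


class ConfigError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Variant generation
# ---------------------------------------------------------------------------

GREEK = {
    "alpha": "α", "beta": "β", "gamma": "γ", "delta": "δ", "epsilon": "ε",
    "zeta": "ζ", "eta": "η", "theta": "θ", "kappa": "κ", "lambda": "λ",
    "mu": "μ", "sigma": "σ", "omega": "ω",
}
GREEK_REV = {v: k for k, v in GREEK.items()}

_ROMAN = [(10, "x"), (9, "ix"), (5, "v"), (4, "iv"), (1, "i")]
_ROMAN_VALUES = {"i": 1, "v": 5, "x": 10}
_ROMAN_RE = re.compile(r"^[ivx]+$")


def _roman_to_int(s: str) -> Optional[int]:
    if not _ROMAN_RE.match(s):
        return None
    total, prev = 0, 0
    for c in reversed(s):
        v = _ROMAN_VALUES[c]
        total += v if v >= prev else -v
        prev = max(prev, v)
    return total if 1 <= total <= 20 else None


def _int_to_roman(n: int) -> str:
    out = []
    for v, sym in _ROMAN:
        while n >= v:
            out.append(sym)
            n -= v
    return "".join(out)


def normalize_name(name: str) -> str:
    """Canonical key for exact matching: case-fold, drop hyphens, squeeze spaces."""
    s = name.casefold().replace("-", " ").replace("–", " ")
    return " ".join(s.split())


def _greek_swaps(name: str) -> set[str]:
    """Greek word <-> symbol at letter boundaries (handles hyphenated tokens)."""
    out = set()
    for word, symbol in GREEK.items():
        rx = re.compile(r"(?<![a-zA-Z])" + word + r"(?![a-zA-Z])", re.IGNORECASE)
        if rx.search(name):
            out.add(rx.sub(symbol, name))
        if symbol in name:
            out.add(name.replace(symbol, word))
    return out


def _token_swaps(name: str) -> set[str]:
    """Single-pass token rewrites: Roman<->Arabic trailing numeral, drop filler."""
    out = set()
    tokens = name.split()
    for i, tok in enumerate(tokens):
        repls = set()
        low = tok.casefold()
        r = _roman_to_int(low)
        if r is not None and i == len(tokens) - 1:
            repls.add(str(r))
        if low.isdigit() and i == len(tokens) - 1 and 1 <= int(low) <= 20:
            repls.add(_int_to_roman(int(low)))
        for repl in repls:
            out.add(" ".join(tokens[:i] + [repl] + tokens[i + 1 :]))
        if low in ("protein", "gene") and len(tokens) > 1:
            out.add(" ".join(tokens[:i] + tokens[i + 1 :]))
    return out


def generate_variants(name: str) -> set[str]:
    """Orthographic variant closure of ``name``.

    Rules: case folding; hyphen <-> space <-> deletion; Greek letter word <->
    symbol; trailing Roman <-> Arabic numeral; optional removal of the filler
    tokens "protein"/"gene".  The original string is always included and the
    result is a fixed point of the rule set.
    """
    if not name:
        raise ValueError("name must be non-empty")
    seen: set[str] = set()
    frontier = {name}
    while frontier:
        nxt: set[str] = set()
        for v in frontier:
            if v in seen or not v:
                continue
            seen.add(v)
            nxt.add(v.casefold())
            if "-" in v or "–" in v:
                nxt.add(v.replace("-", " ").replace("–", " "))
                nxt.add(v.replace("-", "").replace("–", ""))
            nxt |= _token_swaps(v)
            nxt |= _greek_swaps(v)
        frontier = {" ".join(v.split()) for v in nxt} - seen
    return {v for v in seen if v}


# ---------------------------------------------------------------------------
# Dictionary
# ---------------------------------------------------------------------------


class NameType(str, Enum):
    OFFICIAL = "official"
    SYNONYM = "synonym"
    VARIANT = "variant"


@dataclass
class GeneEntry:
    gene_id: str
    taxon_id: str
    names: set[str] = field(default_factory=set)
    variants: set[str] = field(default_factory=set)

    def generate_variants(self) -> None:
        self.variants = set(self.names)
        for n in self.names:
            self.variants |= generate_variants(n)


_TOKEN_RE = re.compile(r"[a-z0-9]+")


def tokenize(name: str) -> list[str]:
    return _TOKEN_RE.findall(name.casefold())


class GeneDictionary:
    """Indexed gene-name dictionary.

    ``name_index`` maps normalized names to gene_id sets for exact lookup;
    ``token_index`` is an inverted token index used for partial matching.
    """

    def __init__(self, entries: Iterable[GeneEntry] = (), with_variants: bool = True):
        self.entries: list[GeneEntry] = list(entries)
        self.with_variants = with_variants
        self.name_index: dict[str, set[str]] = {}
        self.token_index: dict[str, set[str]] = {}
        self._by_id: dict[str, GeneEntry] = {}
        self.rebuild()

    def rebuild(self) -> None:
        self.name_index = defaultdict(set)
        self.token_index = defaultdict(set)
        self._by_id = {}
        for e in self.entries:
            if self.with_variants and not e.variants:
                e.generate_variants()
            self._by_id[e.gene_id] = e
            for name in e.variants if self.with_variants else e.names:
                self.name_index[normalize_name(name)].add(e.gene_id)
            for name in e.names:
                for tok in tokenize(name):
                    self.token_index[tok].add(e.gene_id)
        self.name_index = dict(self.name_index)
        self.token_index = dict(self.token_index)

    def entry(self, gene_id: str) -> GeneEntry:
        return self._by_id[gene_id]

    def taxon_of(self, gene_id: str) -> str:
        return self._by_id[gene_id].taxon_id

    def __len__(self) -> int:
        return len(self.entries)

    def enabled_entry_count(self, enabled: set[str]) -> int:
        return sum(1 for e in self.entries if e.taxon_id in enabled)


DICT_COLUMNS = ("gene_id", "taxon_id", "name", "name_type")


def load_dictionary(path: str, with_variants: bool = True) -> GeneDictionary:
    """Load a dictionary from TSV columns gene_id, taxon_id, name, name_type."""
    grouped: dict[tuple[str, str], set[str]] = defaultdict(set)
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            warnings.warn(f"empty dictionary file: {path}")
            return GeneDictionary([], with_variants=with_variants)
        missing = set(DICT_COLUMNS) - set(reader.fieldnames)
        if missing:
            raise SchemaError(f"dictionary missing columns: {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            name = (row["name"] or "").strip()
            if not name:
                raise SchemaError(f"{path}:{lineno}: blank gene name")
            grouped[(row["gene_id"], row["taxon_id"])].add(name)
    entries = [
        GeneEntry(gene_id=gid, taxon_id=tid, names=names)
        for (gid, tid), names in sorted(grouped.items())
    ]
    if not entries:
        warnings.warn(f"empty dictionary file: {path}")
    return GeneDictionary(entries, with_variants=with_variants)


def write_dictionary(d: GeneDictionary, path: str, expand: bool = False) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(DICT_COLUMNS)
        for e in sorted(d.entries, key=lambda e: (e.gene_id, e.taxon_id)):
            for n in sorted(e.names):
                w.writerow([e.gene_id, e.taxon_id, n, "official"])
            if expand:
                for v in sorted(e.variants - e.names):
                    w.writerow([e.gene_id, e.taxon_id, v, "variant"])


# ---------------------------------------------------------------------------
# Matching
# ---------------------------------------------------------------------------


def exact_match(mention: str, d: GeneDictionary, enabled: set[str]) -> set[str]:
    """Exact lookup of the normalized mention, restricted to enabled taxa."""
    if not mention or not mention.strip():
        raise ValueError("mention must be non-empty")
    ids = d.name_index.get(normalize_name(mention), set())
    return {gid for gid in ids if d.taxon_of(gid) in enabled}


def partial_match(
    mention: str, d: GeneDictionary, enabled: set[str], top_n: int = 5
) -> list[tuple[str, float]]:
    """IDF-weighted token-overlap retrieval over the inverted index.

    Score = sum of idf over shared tokens / sum of idf over mention tokens,
    in (0, 1].  Results descend by score, ties broken by gene_id ascending.
    """
    if not mention or not mention.strip():
        raise ValueError("mention must be non-empty")
    toks = tokenize(mention)
    if not toks:
        return []
    n_docs = max(len(d.entries), 1)

    def idf(tok: str) -> float:
        df = len(d.token_index.get(tok, ()))
        return math.log((n_docs + 1) / (df + 1)) + 1.0

    denom = sum(idf(t) for t in set(toks))
    shared: dict[str, float] = defaultdict(float)
    for tok in set(toks):
        for gid in d.token_index.get(tok, ()):
            if d.taxon_of(gid) in enabled:
                shared[gid] += idf(tok)
    scored = [(gid, min(s / denom, 1.0)) for gid, s in shared.items()]
    scored.sort(key=lambda p: (-p[1], p[0]))
    return scored[:top_n]


# ---------------------------------------------------------------------------
# Species keywords and entry-selection strategies
# ---------------------------------------------------------------------------


class SpeciesKeywordTable:
    """taxon_id -> surface patterns (names, abbreviated binomials, strains)."""

    def __init__(self, patterns: dict[str, set[tuple[str, bool]]]):
        # pattern entries are (surface, case_sensitive)
        for taxon, pats in patterns.items():
            if not pats:
                raise ValueError(f"taxon {taxon} has no patterns")
        self.patterns = patterns
        self._compiled: list[tuple[str, re.Pattern]] = []
        for taxon, pats in sorted(patterns.items()):
            for surface, case_sensitive in sorted(pats):
                flags = 0 if case_sensitive else re.IGNORECASE
                rx = re.compile(
                    r"(?<![A-Za-z])" + re.escape(surface) + r"(?![A-Za-z])", flags
                )
                self._compiled.append((taxon, rx))

    @property
    def taxa(self) -> set[str]:
        return set(self.patterns)

    def detect(self, text: str) -> set[str]:
        if not text:
            return set()
        return {taxon for taxon, rx in self._compiled if rx.search(text)}

    def count_occurrences(self, text: str) -> dict[str, int]:
        counts: dict[str, int] = defaultdict(int)
        for taxon, rx in self._compiled:
            counts[taxon] += len(rx.findall(text))
        return {t: c for t, c in counts.items() if c > 0}


def load_species_table(path: str) -> SpeciesKeywordTable:
    """Load TSV columns taxon_id, pattern, case_sensitive(0|1)."""
    patterns: dict[str, set[tuple[str, bool]]] = defaultdict(set)
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = {"taxon_id", "pattern", "case_sensitive"} - set(reader.fieldnames or ())
        if missing:
            raise SchemaError(f"species table missing columns: {sorted(missing)}")
        for row in reader:
            patterns[row["taxon_id"]].add(
                (row["pattern"], row["case_sensitive"].strip() == "1")
            )
    return SpeciesKeywordTable(dict(patterns))


def write_species_table(table: SpeciesKeywordTable, path: str) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["taxon_id", "pattern", "case_sensitive"])
        for taxon in sorted(table.patterns):
            for surface, cs in sorted(table.patterns[taxon]):
                w.writerow([taxon, surface, int(cs)])


def detect_species(text_scope: str, table: SpeciesKeywordTable) -> set[str]:
    """Taxa whose patterns match anywhere in the scope text."""
    return table.detect(text_scope)


#: Default common-species list (NCBI taxonomy IDs of widely studied organisms).
#: Content is configuration, not contract; override via StrategyConfig.
DEFAULT_COMMON_SPECIES = [
    "9606",    # Homo sapiens
    "10090",   # Mus musculus
    "10116",   # Rattus norvegicus
    "7227",    # Drosophila melanogaster
    "559292",  # Saccharomyces cerevisiae S288C
    "6239",    # Caenorhabditis elegans
    "3702",    # Arabidopsis thaliana
    "7955",    # Danio rerio
    "8355",    # Xenopus laevis
    "9031",    # Gallus gallus
    "562",     # Escherichia coli
    "9913",    # Bos taurus
    "9823",    # Sus scrofa
    "4932",    # Saccharomyces cerevisiae
    "284812",  # Schizosaccharomyces pombe
    "9615",    # Canis lupus familiaris
    "1423",    # Bacillus subtilis
    "9986",    # Oryctolagus cuniculus
    "4530",    # Oryza sativa
    "5833",    # Plasmodium falciparum
    "83333",   # Escherichia coli K-12
    "9544",    # Macaca mulatta
]


class StrategyMode(str, Enum):
    STATIC = "static"
    DYNAMIC_ARTICLE = "dynamic_article"
    DYNAMIC_SECTION = "dynamic_section"
    ORACLE = "oracle"


@dataclass
class StrategyConfig:
    mode: StrategyMode = StrategyMode.STATIC
    common_species: list[str] = field(default_factory=lambda: list(DEFAULT_COMMON_SPECIES))
    oracle_taxa: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if isinstance(self.mode, str):
            self.mode = StrategyMode(self.mode)
        if self.mode == StrategyMode.ORACLE and not self.oracle_taxa:
            raise ConfigError("oracle mode requires non-empty oracle_taxa")
        if self.mode == StrategyMode.STATIC and not self.common_species:
            raise ConfigError("static mode requires non-empty common_species")


ARTICLE_SCOPE = "__article__"


def select_entries(
    article: "Article",
    d: GeneDictionary,
    cfg: StrategyConfig,
    table: SpeciesKeywordTable,
) -> dict:
    """Enabled taxa per scope.

    static / dynamic_article / oracle return a single article-wide scope keyed
    ``"__article__"``; dynamic_section returns one scope per section index.
    Dynamic modes union the common-species list with the taxa detected by
    species keywords in the scope text.
    """
    common = set(cfg.common_species)
    if cfg.mode == StrategyMode.STATIC:
        return {ARTICLE_SCOPE: set(common)}
    if cfg.mode == StrategyMode.ORACLE:
        return {ARTICLE_SCOPE: set(cfg.oracle_taxa)}
    if cfg.mode == StrategyMode.DYNAMIC_ARTICLE:
        return {ARTICLE_SCOPE: common | detect_species(article.full_text(), table)}
    if cfg.mode == StrategyMode.DYNAMIC_SECTION:
        return {
            si: common | detect_species(sec.text, table)
            for si, sec in enumerate(article.sections)
        }
    raise ConfigError(f"unknown strategy mode: {cfg.mode}")


def enabled_for_section(scopes: dict, section_index: int) -> set[str]:
    """Resolve the enabled-taxa set for a section under any strategy."""
    if ARTICLE_SCOPE in scopes:
        return scopes[ARTICLE_SCOPE]
    return scopes[section_index]
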