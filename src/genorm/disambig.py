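"""Rule-based disambiguation: weighted vote classifiers and candidate selection.

Each rule inspects context evidence for a candidate gene identifier and emits
y × w, where y ∈ {1, 0, -1} and w weights positive evidence by proximity
(same sentence: 1; same section: 0.5).  The vote is the linear combination of
all rule values.  When mention boundaries or identifiers disagree, the
candidate-selection step picks the identifier with the longest mention string
and the fewest rules voting against it.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

from .corpus import Article, ArticleMetadata
from .lexicon import SpeciesKeywordTable, normalize_name


class Rule(str, Enum):
    SPECIES = "Species"
    CELL = "Cell"
    PPI = "PPI"
    HISTORY = "History"
    FULL_NAME_ACRONYM = "FullNameAcronym"
    TISSUE = "Tissue"
    DOMAIN = "Domain"
    FAMILY = "Family"
    MASS = "Mass"
    GENE_ONTOLOGY = "GeneOntology"
    CHROMOSOME_LOCATION = "ChromosomeLocation"
    SEQUENCE_LENGTH = "SequenceLength"
    RS_NUMBER = "RSNumber"


ALL_RULES: tuple[Rule, ...] = tuple(Rule)

#: Rules allowed to vote -1 when no evidence exists anywhere in the article.
#: The remaining rules are two-valued (1/0) because their evidence is often
#: simply not described in a paper; override via ``three_valued=`` arguments.
DEFAULT_THREE_VALUED: frozenset[Rule] = frozenset(
    {Rule.SPECIES, Rule.CELL, Rule.TISSUE, Rule.DOMAIN, Rule.FAMILY}
)

MASS_REL_TOL = 0.05  # relative tolerance for mass matching (kDa)

_MASS_RE = re.compile(r"(\d+(?:\.\d+)?)\s*kDa", re.IGNORECASE)
_LENGTH_RE = re.compile(r"(\d+)\s*(?:aa|bp)\b", re.IGNORECASE)
_RS_RE = re.compile(r"\brs\d+\b", re.IGNORECASE)


@dataclass(frozen=True)
class RuleResult:
    rule_id: Rule
    y: int
    w: float

    def __post_init__(self) -> None:
        if self.y not in (1, 0, -1):
            raise ValueError(f"y must be in {{1,0,-1}}: {self.y}")
        if self.w not in (1.0, 0.5):
            raise ValueError(f"w must be 1 or 0.5: {self.w}")

    @property
    def value(self) -> float:
        return self.y * self.w


@dataclass
class VoteSummary:
    gene_id: str
    results: list[RuleResult] = field(default_factory=list)

    @property
    def total(self) -> float:
        return sum(r.value for r in self.results)

    @property
    def votes_against(self) -> int:
        return sum(1 for r in self.results if r.y == -1)

    @property
    def votes_for(self) -> set[Rule]:
        return {r.rule_id for r in self.results if r.y == 1}


@dataclass
class GeneRecord:
    gene_id: str
    taxon_id: str
    cell_keywords: set[str] = field(default_factory=set)
    tissue_keywords: set[str] = field(default_factory=set)
    domain_keywords: set[str] = field(default_factory=set)
    family_keywords: set[str] = field(default_factory=set)
    go_terms: set[str] = field(default_factory=set)
    chromosome_locations: set[str] = field(default_factory=set)
    sequence_lengths: set[int] = field(default_factory=set)
    masses: set[float] = field(default_factory=set)
    rs_numbers: set[str] = field(default_factory=set)
    ppi_partners: set[str] = field(default_factory=set)
    full_names: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.sequence_lengths):
            raise ValueError("sequence lengths must be non-negative")
        if any(v < 0 for v in self.masses):
            raise ValueError("masses must be non-negative")


_LIST_FIELDS = (
    "cell_keywords", "tissue_keywords", "domain_keywords", "family_keywords",
    "go_terms", "chromosome_locations", "rs_numbers", "ppi_partners",
    "full_names",
)


class KnowledgeBase:
    """Per-identifier knowledge: species, context keywords, PPIs, numerics."""

    def __init__(self, records: dict[str, GeneRecord]):
        for gid, rec in records.items():
            if not rec.taxon_id:
                raise ValueError(f"gene {gid} has no taxon_id")
        self.records = records

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.records

    def __getitem__(self, gene_id: str) -> GeneRecord:
        return self.records[gene_id]

    def get(self, gene_id: str) -> Optional[GeneRecord]:
        return self.records.get(gene_id)

    @classmethod
    def from_json(cls, path: str) -> "KnowledgeBase":
        with open(path, encoding="utf-8") as fh:
            raw = json.load(fh)
        records = {}
        for gid, obj in raw.items():
            records[gid] = GeneRecord(
                gene_id=gid,
                taxon_id=str(obj["taxon_id"]),
                sequence_lengths=set(obj.get("sequence_lengths", ())),
                masses=set(obj.get("masses", ())),
                **{f: set(obj.get(f, ())) for f in _LIST_FIELDS},
            )
        return cls(records)

    def to_json(self, path: str) -> None:
        out = {}
        for gid, rec in sorted(self.records.items()):
            obj: dict = {"taxon_id": rec.taxon_id}
            for f in _LIST_FIELDS:
                obj[f] = sorted(getattr(rec, f))
            obj["sequence_lengths"] = sorted(rec.sequence_lengths)
            obj["masses"] = sorted(rec.masses)
            out[gid] = obj
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(out, fh, indent=1, sort_keys=True)
            fh.write("\n")


# ---------------------------------------------------------------------------
# Context scopes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Context:
    """Position of the mention under disambiguation."""

    article: Article
    section_index: int
    sentence_index: int
    mention_text: str = ""

    def sentence_text(self) -> str:
        sec = self.article.sections[self.section_index]
        if 0 <= self.sentence_index < len(sec.sentences):
            return sec.sentences[self.sentence_index].text
        return ""

    def section_text(self) -> str:
        return self.article.sections[self.section_index].text

    def rest_text(self) -> str:
        return "\n".join(
            s.text
            for i, s in enumerate(self.article.sections)
            if i != self.section_index
        )


def _keyword_in(text: str, keywords: set[str]) -> bool:
    low = text.casefold()
    for kw in keywords:
        k = kw.casefold()
        idx = low.find(k)
        while idx != -1:
            before_ok = idx == 0 or not low[idx - 1].isalnum()
            after = idx + len(k)
            after_ok = after >= len(low) or not low[after].isalnum()
            if before_ok and after_ok:
                return True
            idx = low.find(k, idx + 1)
    return False


def _scoped_result(
    rule: Rule,
    found_in_sentence: bool,
    found_in_section: bool,
    found_in_article: bool,
    three_valued: frozenset[Rule],
) -> RuleResult:
    """Map evidence scope to y × w: sentence → 1×1, section → 1×0.5,
    elsewhere in article → 0, absent → -1 (three-valued rules) or 0."""
    if found_in_sentence:
        return RuleResult(rule, 1, 1.0)
    if found_in_section:
        return RuleResult(rule, 1, 0.5)
    if found_in_article:
        return RuleResult(rule, 0, 1.0)
    y = -1 if rule in three_valued else 0
    return RuleResult(rule, y, 1.0)


# ---------------------------------------------------------------------------
# Rules
# ---------------------------------------------------------------------------


def _species_keywords(taxon_id: str, table: Optional[SpeciesKeywordTable]) -> set[str]:
    if table is None or taxon_id not in table.patterns:
        return set()
    return {surface for surface, _ in table.patterns[taxon_id]}


def _numbers_matching_mass(text: str, masses: set[float]) -> bool:
    for m in _MASS_RE.finditer(text):
        v = float(m.group(1))
        for target in masses:
            if target > 0 and abs(v - target) / target <= MASS_REL_TOL:
                return True
            if target == 0 and v == 0:
                return True
    return False


def _numbers_matching_length(text: str, lengths: set[int]) -> bool:
    found = {int(m.group(1)) for m in _LENGTH_RE.finditer(text)}
    return bool(found & lengths)


def _rs_matching(text: str, rs_numbers: set[str]) -> bool:
    found = {m.group(0).lower() for m in _RS_RE.finditer(text)}
    return bool(found & {r.lower() for r in rs_numbers})


def apply_rule(
    rule_id: Rule,
    gene_id: str,
    context: Context,
    kb: KnowledgeBase,
    metadata: ArticleMetadata,
    species_table: Optional[SpeciesKeywordTable] = None,
    three_valued: frozenset[Rule] = DEFAULT_THREE_VALUED,
) -> RuleResult:
    """Evaluate one disambiguation rule for a candidate identifier.

    Keyword rules search the same sentence, then the same section, then the
    rest of the article.  History, PPI and FullNameAcronym read the metadata
    memory instead of scanning text.
    """
    if not isinstance(rule_id, Rule):
        raise ValueError(f"unknown rule: {rule_id!r}")

    if rule_id == Rule.HISTORY:
        y = 1 if gene_id in metadata.normalized_ids() else 0
        return RuleResult(rule_id, y, 1.0)

    rec = kb.get(gene_id)
    if rec is None:
        raise ValueError(f"gene_id not in knowledge base: {gene_id}")

    if rule_id == Rule.PPI:
        y = 1 if rec.ppi_partners & metadata.normalized_ids() else 0
        return RuleResult(rule_id, y, 1.0)

    if rule_id == Rule.FULL_NAME_ACRONYM:
        long_forms = {
            normalize_name(lf)
            for lf, sf in metadata.abbreviations
            if normalize_name(sf) == normalize_name(context.mention_text)
        }
        kb_names = {normalize_name(n) for n in rec.full_names}
        y = 1 if (long_forms & kb_names
                  or normalize_name(context.mention_text) in kb_names) else 0
        return RuleResult(rule_id, y, 1.0)

    if rule_id == Rule.SPECIES:
        keywords = _species_keywords(rec.taxon_id, species_table)
        check = lambda text: _keyword_in(text, keywords)  # noqa: E731
    elif rule_id == Rule.CELL:
        check = lambda text: _keyword_in(text, rec.cell_keywords)  # noqa: E731
    elif rule_id == Rule.TISSUE:
        check = lambda text: _keyword_in(text, rec.tissue_keywords)  # noqa: E731
    elif rule_id == Rule.DOMAIN:
        check = lambda text: _keyword_in(text, rec.domain_keywords)  # noqa: E731
    elif rule_id == Rule.FAMILY:
        check = lambda text: _keyword_in(text, rec.family_keywords)  # noqa: E731
    elif rule_id == Rule.GENE_ONTOLOGY:
        check = lambda text: any(  # noqa: E731
            t.casefold() in text.casefold() for t in rec.go_terms
        )
    elif rule_id == Rule.CHROMOSOME_LOCATION:
        check = lambda text: _keyword_in(text, rec.chromosome_locations)  # noqa: E731
    elif rule_id == Rule.MASS:
        check = lambda text: _numbers_matching_mass(text, rec.masses)  # noqa: E731
    elif rule_id == Rule.SEQUENCE_LENGTH:
        check = lambda text: _numbers_matching_length(text, rec.sequence_lengths)  # noqa: E731
    elif rule_id == Rule.RS_NUMBER:
        check = lambda text: _rs_matching(text, rec.rs_numbers)  # noqa: E731
    else:  # pragma: no cover
        raise ValueError(f"unhandled rule: {rule_id}")

    return _scoped_result(
        rule_id,
        check(context.sentence_text()),
        check(context.section_text()),
        check(context.rest_text()),
        three_valued,
    )


def weighted_vote(
    gene_id: str,
    context: Context,
    kb: KnowledgeBase,
    metadata: ArticleMetadata,
    species_table: Optional[SpeciesKeywordTable] = None,
    three_valued: frozenset[Rule] = DEFAULT_THREE_VALUED,
) -> VoteSummary:
    """Apply all rules and combine their weighted values."""
    results = [
        apply_rule(rule, gene_id, context, kb, metadata, species_table, three_valued)
        for rule in ALL_RULES
    ]
    return VoteSummary(gene_id=gene_id, results=results)


def select_candidate(candidates: list[tuple[str, str, VoteSummary]]) -> str:
    """Pick one identifier from competing (gene_id, mention_text, vote) triples.

    Order: longest mention string, then fewest votes against, then highest
    vote total, then smallest gene_id.  Total order — permutation invariant.
    """
    if not candidates:
        raise ValueError("candidates must be non-empty")
    best = min(
        candidates,
        key=lambda c: (-len(c[1]), c[2].votes_against, -c[2].total, c[0]),
    )
    return best[0]
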