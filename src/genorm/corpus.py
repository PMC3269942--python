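"""Full-text article data model, JSON I/O, sentence segmentation and preprocessing.

Articles are represented as an ordered list of typed sections; each section's
text is segmented into sentences with character spans back into the section
text.  Preprocessing populates per-article metadata: abbreviation pairs found
with the Schwartz-Hearst long-form/short-form pairing algorithm, author
keywords, and the cross-stage normalization memory used by the pipeline.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional


class SectionKind(str, Enum):
    TITLE = "title"
    ABSTRACT = "abstract"
    INTRODUCTION = "introduction"
    RESULTS = "results"
    CONCLUSION = "conclusion"
    OTHER = "other"
    FIGURE_CAPTION = "figure_caption"
    TABLE_CAPTION = "table_caption"
    APPENDIX = "appendix"
    SECTION_TITLE = "section_title"


#: Heading token -> section kind.  Case-insensitive lookup on the stripped
#: heading.  Unknown headings map to OTHER.
HEADING_KIND_MAP = {
    "title": SectionKind.TITLE,
    "abstract": SectionKind.ABSTRACT,
    "introduction": SectionKind.INTRODUCTION,
    "background": SectionKind.INTRODUCTION,
    "results": SectionKind.RESULTS,
    "results and discussion": SectionKind.RESULTS,
    "conclusion": SectionKind.CONCLUSION,
    "conclusions": SectionKind.CONCLUSION,
    "discussion": SectionKind.OTHER,
    "methods": SectionKind.OTHER,
    "materials and methods": SectionKind.OTHER,
    "appendix": SectionKind.APPENDIX,
}


class ParseError(ValueError):
    """Raised when an article file does not conform to the JSON schema."""


class ValidationError(ValueError):
    """Raised when a structurally valid file violates an article invariant."""


@dataclass(frozen=True)
class Sentence:
    text: str
    index: int
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValidationError(
                f"sentence span must be non-empty: [{self.start}, {self.end})"
            )


@dataclass
class Section:
    kind: SectionKind
    heading: str
    text: str
    sentences: list[Sentence] = field(default_factory=list)

    def segment(self) -> None:
        self.sentences = split_sentences(self.text)


@dataclass
class NormalizedGene:
    """A successfully normalized identifier kept in the cross-stage memory."""

    gene_id: str
    taxon_id: str
    mentions: list = field(default_factory=list)  # list[GeneMention]
    stage: int = 1
    vote: Optional[object] = None  # VoteSummary
    match_kind: str = "exact"  # "exact" | "partial"


@dataclass
class ArticleMetadata:
    abbreviations: set[tuple[str, str]] = field(default_factory=set)
    keywords: set[str] = field(default_factory=set)
    normalized: dict[str, NormalizedGene] = field(default_factory=dict)
    original_strings: dict[str, str] = field(default_factory=dict)
    focus_species: Optional[str] = None
    blacklist_additions: set[str] = field(default_factory=set)

    def add_abbreviation(self, long_form: str, short_form: str) -> None:
        if not short_form or len(short_form) >= len(long_form):
            raise ValidationError(
                f"short form must be non-empty and shorter than long form: "
                f"({long_form!r}, {short_form!r})"
            )
        self.abbreviations.add((long_form, short_form))

    def normalized_ids(self) -> set[str]:
        return {ng.gene_id for ng in self.normalized.values()}


@dataclass
class Article:
    article_id: str
    sections: list[Section] = field(default_factory=list)
    metadata: ArticleMetadata = field(default_factory=ArticleMetadata)

    def __post_init__(self) -> None:
        self._check_unique(SectionKind.TITLE)
        self._check_unique(SectionKind.ABSTRACT)

    def _check_unique(self, kind: SectionKind) -> None:
        n = sum(1 for s in self.sections if s.kind == kind)
        if n > 1:
            raise ValidationError(f"article has {n} sections of kind {kind.value}")

    def sections_of(self, kind: SectionKind) -> list[Section]:
        return [s for s in self.sections if s.kind == kind]

    def first_of(self, kind: SectionKind) -> Optional[Section]:
        for s in self.sections:
            if s.kind == kind:
                return s
        return None

    def iter_sentences(self) -> Iterable[tuple[int, Section, Sentence]]:
        for si, sec in enumerate(self.sections):
            for sent in sec.sentences:
                yield si, sec, sent

    def full_text(self) -> str:
        return "\n".join(s.text for s in self.sections)


# ---------------------------------------------------------------------------
# Sentence segmentation
# ---------------------------------------------------------------------------

# Tokens whose trailing period must not end a sentence.
_PROTECTED = (
    "Fig", "Figs", "Eq", "Eqs", "Ref", "Refs", "Tab", "al", "et al", "e.g",
    "i.e", "vs", "cf", "Dr", "Prof", "St", "No", "ca", "approx", "sp", "spp",
)
_PROTECTED_RE = re.compile(
    r"(?:\b(?:" + "|".join(re.escape(t).replace(r"\.", r"\.") for t in _PROTECTED) + r")\.)$"
)
_BOUNDARY_RE = re.compile(r"[.!?]+[\"')\]]*\s+")


def split_sentences(text: str) -> list[Sentence]:
    """Segment ``text`` into sentences with half-open character spans.

    Splits after sentence-final punctuation followed by whitespace, except
    when the candidate boundary terminates a protected abbreviation such as
    "Fig." or "et al.".  Spans cover all non-whitespace characters and never
    overlap.
    """
    sentences: list[Sentence] = []
    if not text or not text.strip():
        return sentences
    start = 0
    for m in _BOUNDARY_RE.finditer(text):
        prefix = text[start : m.end()].rstrip()
        if _PROTECTED_RE.search(prefix):
            continue
        # do not split on a decimal like "3. 5" is fine; "3.5" never matches
        end = start + len(text[start : m.end()].rstrip())
        chunk = text[start:end]
        lead = len(chunk) - len(chunk.lstrip())
        if chunk.strip():
            sentences.append(
                Sentence(text=chunk.strip(), index=len(sentences),
                         start=start + lead, end=end)
            )
        start = m.end()
    tail = text[start:]
    if tail.strip():
        lead = len(tail) - len(tail.lstrip())
        end = start + len(tail.rstrip())
        sentences.append(
            Sentence(text=tail.strip(), index=len(sentences),
                     start=start + lead, end=end)
        )
    return sentences


# ---------------------------------------------------------------------------
# Collapsed-range expansion
# ---------------------------------------------------------------------------

_RANGE_RE = re.compile(
    r"\b([A-Za-z][A-Za-z-]*?)(\d+)\s*[-–]\s*(?:([A-Za-z][A-Za-z-]*?)(\d+)|(\d+))\b"
)

DEFAULT_RANGE_CAP = 100


def expand_ranges(text: str, cap: int = DEFAULT_RANGE_CAP) -> list[tuple[tuple[int, int], list[str]]]:
    """Expand collapsed name ranges like ``SOCS1-SOCS7`` or ``VDAC1-3``.

    Returns ``[(span, names), ...]`` where ``span`` is the half-open character
    range of the detected pattern and ``names`` the full ascending enumeration
    (``["SOCS1", ..., "SOCS7"]``).  Ranges with mismatched prefixes,
    descending numerals, or more than ``cap`` components are ignored.
    """
    out: list[tuple[tuple[int, int], list[str]]] = []
    for m in _RANGE_RE.finditer(text):
        prefix, lo_s = m.group(1), m.group(2)
        if m.group(5) is not None:  # PREFIX+int "-" int
            hi_s = m.group(5)
        else:  # PREFIX+int "-" PREFIX+int
            if m.group(3) != prefix:
                continue
            hi_s = m.group(4)
        lo, hi = int(lo_s), int(hi_s)
        if hi <= lo or (hi - lo + 1) > cap:
            continue
        names = [f"{prefix}{i}" for i in range(lo, hi + 1)]
        out.append(((m.start(), m.end()), names))
    return out


# ---------------------------------------------------------------------------
# Schwartz-Hearst abbreviation extraction
# ---------------------------------------------------------------------------

_PAREN_RE = re.compile(r"\(([^()]{1,60})\)")


def _valid_short_form(sf: str) -> bool:
    if not (2 <= len(sf) <= 20):
        return False
    if not any(c.isalpha() for c in sf):
        return False
    # at most two tokens; first character alphanumeric
    if len(sf.split()) > 2:
        return False
    return sf[0].isalnum()


def _find_long_form(candidate: str, short_form: str) -> Optional[str]:
    """Right-to-left character match of Schwartz & Hearst.

    Every character of the short form must appear, in order, in the candidate
    long form; the match for the short form's first character must be at the
    start of a word of the long form.
    """
    s_idx = len(short_form) - 1
    l_idx = len(candidate) - 1
    while s_idx >= 0:
        c = short_form[s_idx].lower()
        if not c.isalnum():
            s_idx -= 1
            continue
        while l_idx >= 0 and (
            candidate[l_idx].lower() != c
            or (s_idx == 0 and l_idx > 0 and candidate[l_idx - 1].isalnum())
        ):
            l_idx -= 1
        if l_idx < 0:
            return None
        l_idx -= 1
        s_idx -= 1
    long_form = candidate[l_idx + 1 :].strip()
    if not long_form:
        return None
    # long form must be longer than the short form and not contain it wholesale
    if len(long_form) <= len(short_form):
        return None
    n_words = len(long_form.split())
    n_chars = sum(1 for c in short_form if c.isalnum())
    if n_words > min(n_chars + 5, n_chars * 2):
        return None
    return long_form


def extract_abbreviation_pairs(text: str) -> set[tuple[str, str]]:
    """Find (long form, short form) definition pairs in one sentence."""
    pairs: set[tuple[str, str]] = set()
    for m in _PAREN_RE.finditer(text):
        short = m.group(1).strip()
        if not _valid_short_form(short):
            continue
        before = text[: m.start()].rstrip()
        if not before:
            continue
        # candidate window: up to min(|sf|+5, 2*|sf|) words before the paren
        words = before.split()
        n_chars = sum(1 for c in short if c.isalnum())
        window = min(n_chars + 5, n_chars * 2)
        candidate = " ".join(words[-window:]) if window > 0 else ""
        if not candidate:
            continue
        long_form = _find_long_form(candidate, short)
        if long_form is not None and len(short) < len(long_form):
            pairs.add((long_form, short))
    return pairs


def extract_abbreviations(article: Article) -> set[tuple[str, str]]:
    """Run Schwartz-Hearst pairing over every sentence of the article."""
    pairs: set[tuple[str, str]] = set()
    for _, _, sent in article.iter_sentences():
        pairs |= extract_abbreviation_pairs(sent.text)
    return pairs


def init_metadata(article: Article) -> ArticleMetadata:
    """Populate article metadata from preprocessing (in place; returned too)."""
    md = article.metadata
    for long_form, short_form in extract_abbreviations(article):
        md.add_abbreviation(long_form, short_form)
    return md


# ---------------------------------------------------------------------------
# JSON I/O
# ---------------------------------------------------------------------------


def _classify_heading(heading: str, declared: Optional[str]) -> SectionKind:
    if declared:
        try:
            return SectionKind(declared)
        except ValueError:
            raise ParseError(f"unknown section kind: {declared!r}")
    return HEADING_KIND_MAP.get(heading.strip().lower(), SectionKind.OTHER)


def article_from_dict(doc: dict) -> Article:
    if not isinstance(doc, dict):
        raise ParseError("document root must be a JSON object")
    if "article_id" not in doc:
        raise ParseError("missing required field: article_id")
    if "sections" not in doc or not isinstance(doc["sections"], list):
        raise ParseError("missing or non-list field: sections")
    sections: list[Section] = []
    for i, raw in enumerate(doc["sections"]):
        if not isinstance(raw, dict) or "text" not in raw:
            raise ParseError(f"sections[{i}] missing field: text")
        heading = raw.get("heading", "")
        kind = _classify_heading(heading, raw.get("kind"))
        sec = Section(kind=kind, heading=heading, text=raw["text"])
        sec.segment()
        sections.append(sec)
    art = Article(article_id=str(doc["article_id"]), sections=sections)
    for kw in doc.get("keywords", []):
        art.metadata.keywords.add(str(kw))
    return art


def article_to_dict(article: Article) -> dict:
    return {
        "article_id": article.article_id,
        "keywords": sorted(article.metadata.keywords),
        "sections": [
            {"kind": s.kind.value, "heading": s.heading, "text": s.text}
            for s in article.sections
        ],
    }


def read_article(path: str) -> Article:
    with open(path, encoding="utf-8") as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ParseError(f"invalid JSON in {path}: {exc}") from exc
    return article_from_dict(doc)


def write_article(article: Article, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(article_to_dict(article), fh, indent=1, sort_keys=True)
        fh.write("\n")
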