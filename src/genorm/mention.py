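"""Gene-mention tagging, boundary post-processing and blacklist filtering.

The tagger contract accepts any callable producing non-overlapping spans; the
shipped default is a deterministic longest-match dictionary tagger.  Post
processing extends mention boundaries using full names, abbreviations and
keywords stored in the article metadata, captures trailing parenthesized
synonyms, and removes terms found on a (static plus per-article dynamic)
blacklist.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Callable, Optional

from .corpus import ArticleMetadata, Sentence
from .lexicon import GeneDictionary, normalize_name


class MentionSource(str, Enum):
    TAGGER = "tagger"
    DICTIONARY = "dictionary"
    PARENTHETICAL = "parenthetical"


class TaggerContractError(ValueError):
    """A plugged tagger returned overlapping or out-of-range spans."""


@dataclass(frozen=True)
class GeneMention:
    text: str
    section_index: int
    sentence_index: int
    start: int
    end: int
    source: MentionSource = MentionSource.TAGGER
    original_text: Optional[str] = None

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


#: Tagger contract: sentence text -> list of (start, end) non-overlapping spans.
Tagger = Callable[[str], list[tuple[int, int]]]


class DictionaryTagger:
    """Longest-match tagger over the enabled entries of a dictionary.

    Scans the sentence left to right; at each word boundary tries the longest
    window (bounded by ``max_tokens``) whose normalized text is a dictionary
    name of an enabled taxon.
    """

    _WORD_RE = re.compile(r"\S+")

    def __init__(self, d: GeneDictionary, enabled: set[str], max_tokens: int = 8):
        self.dict = d
        self.enabled = enabled
        self.max_tokens = max_tokens

    def _is_hit(self, text: str) -> bool:
        ids = self.dict.name_index.get(normalize_name(text))
        if not ids:
            return False
        return any(self.dict.taxon_of(g) in self.enabled for g in ids)

    def __call__(self, sentence_text: str) -> list[tuple[int, int]]:
        words = list(self._WORD_RE.finditer(sentence_text))
        spans: list[tuple[int, int]] = []
        i = 0
        while i < len(words):
            hit = None
            for j in range(min(i + self.max_tokens, len(words)), i, -1):
                start, end = words[i].start(), words[j - 1].end()
                cand = sentence_text[start:end]
                trimmed = cand.rstrip(".,;:!?)")
                if trimmed and self._is_hit(trimmed):
                    hit = (start, start + len(trimmed), j)
                    break
            if hit:
                spans.append((hit[0], hit[1]))
                i = hit[2]
            else:
                i += 1
        return spans


def tag_mentions(
    sentence: Sentence,
    tagger: Tagger,
    section_index: int = 0,
    source: MentionSource = MentionSource.TAGGER,
) -> list[GeneMention]:
    """Apply a tagger to one sentence, validating the span contract."""
    spans = sorted(tagger(sentence.text))
    prev_end = -1
    mentions: list[GeneMention] = []
    for start, end in spans:
        if start < prev_end:
            raise TaggerContractError(
                f"overlapping spans from tagger at offset {start}"
            )
        if not (0 <= start < end <= len(sentence.text)):
            raise TaggerContractError(f"span out of range: ({start}, {end})")
        prev_end = end
        mentions.append(
            GeneMention(
                text=sentence.text[start:end],
                section_index=section_index,
                sentence_index=sentence.index,
                start=start,
                end=end,
                source=source,
            )
        )
    return mentions


# ---------------------------------------------------------------------------
# Boundary adjustment
# ---------------------------------------------------------------------------

_PAREN_AFTER_RE = re.compile(r"^\s*\(([^()]{1,60})\)")
MAX_PARENTHETICAL_TOKENS = 5


def _stored_strings(metadata: ArticleMetadata) -> set[str]:
    stored: set[str] = set(metadata.keywords)
    for long_form, short_form in metadata.abbreviations:
        stored.add(long_form)
        stored.add(short_form)
    return stored


def _extend_one(m: GeneMention, sentence: Sentence, stored: set[str]) -> GeneMention:
    best: Optional[tuple[int, int, str]] = None
    for s in stored:
        if len(s) <= len(m.text) or m.text not in s:
            continue
        # locate an occurrence of the stored string that covers the mention span
        for occ in re.finditer(re.escape(s), sentence.text):
            if occ.start() <= m.start and occ.end() >= m.end:
                if best is None or (occ.end() - occ.start()) > (best[1] - best[0]):
                    best = (occ.start(), occ.end(), s)
                break
    if best is None:
        return m
    start, end, s = best
    return replace(m, text=s, start=start, end=end, original_text=m.text)


def _parenthetical_after(m: GeneMention, sentence: Sentence) -> Optional[GeneMention]:
    tail = sentence.text[m.end :]
    pm = _PAREN_AFTER_RE.match(tail)
    if not pm:
        return None
    inner = pm.group(1).strip()
    if not inner or len(inner.split()) > MAX_PARENTHETICAL_TOKENS:
        return None
    if any(c in inner for c in ".;!?"):
        return None
    inner_start = m.end + tail.index(inner)
    return GeneMention(
        text=inner,
        section_index=m.section_index,
        sentence_index=m.sentence_index,
        start=inner_start,
        end=inner_start + len(inner),
        source=MentionSource.PARENTHETICAL,
    )


def adjust_boundaries(
    mentions: list[GeneMention],
    sentence: Sentence,
    metadata: ArticleMetadata,
) -> list[GeneMention]:
    """Boundary post-processing over one sentence's mentions.

    (i) A mention whose text is a proper substring of a stored full name,
    abbreviation, or keyword occurring in the sentence is extended to the full
    stored string; the pre-adjustment text is kept as ``original_text`` and in
    ``metadata.original_strings``.  (ii) A short parenthesized phrase directly
    after a mention becomes an additional mention.
    """
    stored = _stored_strings(metadata)
    out: list[GeneMention] = []
    occupied: list[tuple[int, int]] = []

    def overlaps(span: tuple[int, int]) -> bool:
        return any(s < span[1] and span[0] < e for s, e in occupied)

    for m in sorted(mentions, key=lambda m: m.start):
        adj = _extend_one(m, sentence, stored)
        if overlaps(adj.span):  # extension collided with a previous mention
            adj = m
        if overlaps(adj.span):
            continue
        occupied.append(adj.span)
        out.append(adj)
        if adj.original_text is not None:
            metadata.original_strings[adj.text] = adj.original_text
        extra = _parenthetical_after(adj, sentence)
        if extra is not None and not overlaps(extra.span):
            occupied.append(extra.span)
            out.append(extra)
    return sorted(out, key=lambda m: m.start)


# ---------------------------------------------------------------------------
# Blacklist
# ---------------------------------------------------------------------------


@dataclass
class Blacklist:
    terms: set[str] = field(default_factory=set)
    dynamic_additions: set[str] = field(default_factory=set)

    @classmethod
    def from_terms(cls, terms) -> "Blacklist":
        return cls(terms={normalize_name(t) for t in terms if t.strip()})

    @classmethod
    def load(cls, path: str) -> "Blacklist":
        terms: set[str] = set()
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if line:
                    terms.add(normalize_name(line))
        return cls(terms=terms)

    def reset_dynamic(self) -> None:
        self.dynamic_additions = set()

    def __contains__(self, text: str) -> bool:
        key = normalize_name(text)
        return key in self.terms or key in self.dynamic_additions


def filter_blacklist(mentions: list[GeneMention], bl: Blacklist) -> list[GeneMention]:
    """Drop mentions whose normalized text is blacklisted; order preserved."""
    return [m for m in mentions if m.text not in bl]


def update_blacklist(bl: Blacklist, metadata: ArticleMetadata) -> Blacklist:
    """Propagate the blacklist across abbreviation pairs.

    For each (long form, short form) pair where one side is blacklisted, the
    other side joins the per-article dynamic additions.
    """
    for long_form, short_form in metadata.abbreviations:
        if long_form in bl and short_form not in bl:
            bl.dynamic_additions.add(normalize_name(short_form))
        elif short_form in bl and long_form not in bl:
            bl.dynamic_additions.add(normalize_name(long_form))
    return bl
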