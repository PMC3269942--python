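"""Three-stage gene normalization over a full-text article.

Stage 1 normalizes the informationally richest sections in the order
introduction → abstract → title, keeping successful normalizations in the
article metadata.  Stage 2 builds a mini-dictionary from that memory, rechecks
the whole article, and resolves species for occurrences outside
title/abstract/introduction by in-sentence species keywords or the article's
focus species.  Stage 3 runs mention recognition plus normalization on the
remaining sections (captions and appendix included), resolving disagreements
with candidate selection.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional

from .corpus import Article, ArticleMetadata, NormalizedGene, Section, SectionKind, init_metadata
from .disambig import Context, KnowledgeBase, VoteSummary, select_candidate, weighted_vote
from .lexicon import (
    GeneDictionary,
    SpeciesKeywordTable,
    StrategyConfig,
    enabled_for_section,
    exact_match,
    normalize_name,
    partial_match,
    select_entries,
)
from .mention import (
    Blacklist,
    DictionaryTagger,
    GeneMention,
    MentionSource,
    adjust_boundaries,
    filter_blacklist,
    tag_mentions,
    update_blacklist,
)

TAI_KINDS = {SectionKind.TITLE, SectionKind.ABSTRACT, SectionKind.INTRODUCTION}

#: Factory mapping an enabled-taxa set to a tagger callable.
TaggerFactory = Callable[[set], Callable[[str], list[tuple[int, int]]]]


@dataclass
class PipelineConfig:
    default_taxon: str = "9606"
    partial_top_n: int = 5
    min_confidence: float = 0.0
    blacklist: Blacklist = field(default_factory=Blacklist)


def _stage1_sections(article: Article) -> list[int]:
    """Section indices in processing order: introduction, abstract, title."""
    order: list[int] = []
    intro = next(
        (i for i, s in enumerate(article.sections) if s.kind == SectionKind.INTRODUCTION),
        None,
    )
    if intro is None:
        # fall back to the first body section
        intro = next(
            (i for i, s in enumerate(article.sections) if s.kind not in
             (SectionKind.TITLE, SectionKind.ABSTRACT)),
            None,
        )
    if intro is not None:
        order.append(intro)
    for kind in (SectionKind.ABSTRACT, SectionKind.TITLE):
        idx = next((i for i, s in enumerate(article.sections) if s.kind == kind), None)
        if idx is not None:
            order.append(idx)
    return order


def _default_tagger_factory(d: GeneDictionary) -> TaggerFactory:
    return lambda enabled: DictionaryTagger(d, enabled)


def _mentions_for_sentence(
    article: Article,
    section_index: int,
    sentence,
    tagger,
    cfg: PipelineConfig,
) -> list[GeneMention]:
    ms = tag_mentions(sentence, tagger, section_index=section_index)
    ms = adjust_boundaries(ms, sentence, article.metadata)
    return filter_blacklist(ms, cfg.blacklist)


def _disambiguate(
    mention: GeneMention,
    candidates: set[str],
    article: Article,
    kb: KnowledgeBase,
    table: Optional[SpeciesKeywordTable],
) -> tuple[str, VoteSummary]:
    ctx = Context(
        article=article,
        section_index=mention.section_index,
        sentence_index=mention.sentence_index,
        mention_text=mention.text,
    )
    votes = {
        gid: weighted_vote(gid, ctx, kb, article.metadata, table)
        for gid in candidates
    }
    if len(candidates) == 1:
        gid = next(iter(candidates))
        return gid, votes[gid]
    winner = select_candidate([(gid, mention.text, v) for gid, v in votes.items()])
    return winner, votes[winner]


def _normalize_mention(
    mention: GeneMention,
    article: Article,
    d: GeneDictionary,
    kb: KnowledgeBase,
    enabled: set,
    table: Optional[SpeciesKeywordTable],
    cfg: PipelineConfig,
    stage: int,
) -> Optional[NormalizedGene]:
    key = normalize_name(mention.text)
    md = article.metadata
    if key in md.normalized:
        md.normalized[key].mentions.append(mention)
        return md.normalized[key]
    candidates = exact_match(mention.text, d, enabled)
    match_kind = "exact"
    if not candidates:
        # retry the pre-adjustment string before giving up on exact matching
        if mention.original_text:
            candidates = exact_match(mention.original_text, d, enabled)
    if not candidates:
        partial = partial_match(mention.text, d, enabled, top_n=cfg.partial_top_n)
        candidates = {gid for gid, _ in partial}
        match_kind = "partial"
        if not candidates:
            return None
    gid, vote = _disambiguate(mention, candidates, article, kb, table)
    ng = NormalizedGene(
        gene_id=gid,
        taxon_id=kb[gid].taxon_id if gid in kb else d.taxon_of(gid),
        mentions=[mention],
        stage=stage,
        vote=vote,
        match_kind=match_kind,
    )
    md.normalized[key] = ng
    return ng


def run_stage1(
    article: Article,
    d: GeneDictionary,
    kb: KnowledgeBase,
    cfg: StrategyConfig,
    table: SpeciesKeywordTable,
    pipeline_cfg: Optional[PipelineConfig] = None,
    tagger_factory: Optional[TaggerFactory] = None,
    scopes: Optional[dict] = None,
) -> ArticleMetadata:
    """Normalize introduction, abstract and title, filling the memory."""
    pcfg = pipeline_cfg or PipelineConfig()
    scopes = scopes if scopes is not None else select_entries(article, d, cfg, table)
    factory = tagger_factory or _default_tagger_factory(d)
    for si in _stage1_sections(article):
        enabled = enabled_for_section(scopes, si)
        tagger = factory(enabled)
        for sent in article.sections[si].sentences:
            for m in _mentions_for_sentence(article, si, sent, tagger, pcfg):
                _normalize_mention(m, article, d, kb, enabled, table, pcfg, stage=1)
    return article.metadata


def determine_focus_species(
    article: Article,
    table: SpeciesKeywordTable,
    common_species: Optional[list[str]] = None,
    default_taxon: str = "9606",
) -> str:
    """Most frequent species by keyword occurrence count over the article."""
    counts = table.count_occurrences(article.full_text())
    if not counts:
        warnings.warn(
            f"no species keyword found in article {article.article_id}; "
            f"using default taxon {default_taxon}"
        )
        article.metadata.focus_species = default_taxon
        return default_taxon
    common = common_species or []

    def rank(taxon: str) -> tuple:
        pos = common.index(taxon) if taxon in common else len(common)
        return (-counts[taxon], pos, taxon)

    focus = min(counts, key=rank)
    article.metadata.focus_species = focus
    return focus


def _build_mini_dictionary(metadata: ArticleMetadata) -> dict[str, list[NormalizedGene]]:
    """mention surface (normalized) -> normalized records sharing that surface."""
    mini: dict[str, list[NormalizedGene]] = {}
    for ng in metadata.normalized.values():
        for m in ng.mentions:
            key = normalize_name(m.text)
            bucket = mini.setdefault(key, [])
            if all(b is not ng for b in bucket):
                bucket.append(ng)
    for bucket in mini.values():
        bucket.sort(key=lambda ng: ng.gene_id)
    return mini


def _scan_for_names(
    sentence_text: str, names: list[str]
) -> list[tuple[int, int, str]]:
    """Longest-match occurrences of mini-dictionary surfaces in a sentence."""
    hits: list[tuple[int, int, str]] = []
    taken: list[tuple[int, int]] = []
    for name in sorted(names, key=len, reverse=True):
        for m in re.finditer(
            r"(?<!\w)" + re.escape(name) + r"(?!\w)", sentence_text, re.IGNORECASE
        ):
            span = (m.start(), m.end())
            if any(s < span[1] and span[0] < e for s, e in taken):
                continue
            taken.append(span)
            hits.append((span[0], span[1], name))
    return sorted(hits)


def run_stage2(
    article: Article,
    kb: KnowledgeBase,
    table: SpeciesKeywordTable,
    pipeline_cfg: Optional[PipelineConfig] = None,
    common_species: Optional[list[str]] = None,
) -> ArticleMetadata:
    """Propagate stage-1 normalizations across the whole article.

    Inside title/abstract/introduction the scan only appends missed
    occurrences of already-normalized identifiers.  Elsewhere, when several
    identifiers share a surface, an in-sentence species keyword selects the
    matching taxon; otherwise the focus-species candidate wins.
    """
    pcfg = pipeline_cfg or PipelineConfig()
    md = article.metadata
    if md.focus_species is None:
        determine_focus_species(article, table, common_species, pcfg.default_taxon)
    mini = _build_mini_dictionary(md)
    if not mini:
        return md
    surfaces: dict[str, str] = {}
    for key, ngs in mini.items():
        for ng in ngs:
            for m in ng.mentions:
                if normalize_name(m.text) == key:
                    surfaces.setdefault(m.text, key)
    known_spans = {
        (ng_m.section_index, ng_m.sentence_index, ng_m.start, ng_m.end)
        for ngs in mini.values()
        for ng in ngs
        for ng_m in ng.mentions
    }
    for si, sec, sent in article.iter_sentences():
        in_tai = sec.kind in TAI_KINDS
        for start, end, surface in _scan_for_names(sent.text, list(surfaces)):
            if (si, sent.index, start, end) in known_spans:
                continue
            candidates = mini[surfaces[surface]]
            if in_tai or len(candidates) == 1:
                chosen = candidates[0]
            else:
                sent_taxa = table.detect(sent.text)
                by_species = [ng for ng in candidates if ng.taxon_id in sent_taxa]
                by_focus = [ng for ng in candidates if ng.taxon_id == md.focus_species]
                pool = by_species or by_focus or candidates
                chosen = min(pool, key=lambda ng: ng.gene_id)
            chosen.mentions.append(
                GeneMention(
                    text=sent.text[start:end],
                    section_index=si,
                    sentence_index=sent.index,
                    start=start,
                    end=end,
                    source=MentionSource.DICTIONARY,
                )
            )
            known_spans.add((si, sent.index, start, end))
    return md


def run_stage3(
    article: Article,
    d: GeneDictionary,
    kb: KnowledgeBase,
    cfg: StrategyConfig,
    table: SpeciesKeywordTable,
    pipeline_cfg: Optional[PipelineConfig] = None,
    tagger_factory: Optional[TaggerFactory] = None,
    scopes: Optional[dict] = None,
) -> ArticleMetadata:
    """Mention recognition + normalization over the remaining sections.

    Where a tagger mention overlaps a stage-2 dictionary assignment with a
    different boundary or identifier, candidate selection resolves the
    disagreement.
    """
    pcfg = pipeline_cfg or PipelineConfig()
    scopes = scopes if scopes is not None else select_entries(article, d, cfg, table)
    factory = tagger_factory or _default_tagger_factory(d)
    md = article.metadata
    stage2_spans: dict[tuple[int, int], list[tuple[GeneMention, NormalizedGene]]] = {}
    for ng in md.normalized.values():
        for m in ng.mentions:
            stage2_spans.setdefault((m.section_index, m.sentence_index), []).append((m, ng))
    for si, sec in enumerate(article.sections):
        if sec.kind in TAI_KINDS:
            continue
        enabled = enabled_for_section(scopes, si)
        tagger = factory(enabled)
        for sent in sec.sentences:
            prior = stage2_spans.get((si, sent.index), [])
            for m in _mentions_for_sentence(article, si, sent, tagger, pcfg):
                clash = next(
                    (
                        (pm, png)
                        for pm, png in prior
                        if pm.start < m.end and m.start < pm.end
                    ),
                    None,
                )
                if clash is None:
                    _normalize_mention(m, article, d, kb, enabled, table, pcfg, stage=3)
                    continue
                pm, png = clash
                if pm.span == m.span:
                    continue  # same boundary: stage-2 assignment stands
                candidates = exact_match(m.text, d, enabled)
                if m.original_text and not candidates:
                    candidates = exact_match(m.original_text, d, enabled)
                if not candidates:
                    continue
                gid, vote = _disambiguate(m, candidates, article, kb, table)
                if gid == png.gene_id:
                    continue
                prior_vote = png.vote or VoteSummary(gene_id=png.gene_id)
                winner = select_candidate(
                    [(gid, m.text, vote), (png.gene_id, pm.text, prior_vote)]
                )
                if winner == gid:
                    key = normalize_name(m.text)
                    if key not in md.normalized:
                        md.normalized[key] = NormalizedGene(
                            gene_id=gid,
                            taxon_id=kb[gid].taxon_id if gid in kb else d.taxon_of(gid),
                            mentions=[m],
                            stage=3,
                            vote=vote,
                            match_kind="exact",
                        )
                    else:
                        md.normalized[key].mentions.append(m)
    return md


def normalize_article(
    article: Article,
    d: GeneDictionary,
    kb: KnowledgeBase,
    cfg: StrategyConfig,
    table: SpeciesKeywordTable,
    pipeline_cfg: Optional[PipelineConfig] = None,
    tagger_factory: Optional[TaggerFactory] = None,
    ranker=None,
) -> list[tuple[str, float]]:
    """Full workflow: preprocess, select entries, stages 1-3, rank.

    Returns (gene_id, confidence) sorted by confidence descending, gene_id
    ascending on ties.  With no ranker, confidence is a logistic map of the
    disambiguation vote total (deterministic fallback).
    """
    pcfg = pipeline_cfg or PipelineConfig()
    if not article.metadata.abbreviations:
        init_metadata(article)
    pcfg.blacklist.reset_dynamic()
    update_blacklist(pcfg.blacklist, article.metadata)
    scopes = select_entries(article, d, cfg, table)
    run_stage1(article, d, kb, cfg, table, pcfg, tagger_factory, scopes)
    determine_focus_species(article, table, cfg.common_species, pcfg.default_taxon)
    run_stage2(article, kb, table, pcfg, cfg.common_species)
    run_stage3(article, d, kb, cfg, table, pcfg, tagger_factory, scopes)

    md = article.metadata
    if ranker is not None:
        ranked = ranker(article, list(md.normalized.values()))
    else:
        import math

        scored: dict[str, float] = {}
        for ng in md.normalized.values():
            total = ng.vote.total if ng.vote is not None else 0.0
            conf = 1.0 / (1.0 + math.exp(-(total + 0.1 * len(ng.mentions))))
            scored[ng.gene_id] = max(scored.get(ng.gene_id, 0.0), conf)
        ranked = list(scored.items())
    ranked = [(g, c) for g, c in ranked if c >= pcfg.min_confidence]
    ranked.sort(key=lambda p: (-p[1], p[0]))
    return ranked
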