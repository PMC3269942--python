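"""Feature extraction and margin-classifier ranking of normalized identifiers.

Five feature families per identifier: matching method (exact/partial),
disambiguation vote (weighted total plus 13 per-rule booleans), frequency
(article count, fraction of mentions in the Results section), location
booleans over the article's parts, and author-provided known information
(keyword and full-name/abbreviation matches).  A linear margin classifier
trained on labeled examples scores identifiers; a fitted logistic map turns
decision values into confidences in (0, 1).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import LinearSVC

from .corpus import Article, ArticleMetadata, NormalizedGene, SectionKind
from .disambig import ALL_RULES
from .lexicon import normalize_name

DEFAULT_N1 = 3  # last-n sentences of the abstract
DEFAULT_N2 = 3  # last-n sentences of the first body section

LOCATION_NAMES = (
    "loc_title",
    "loc_abstract",
    "loc_last_n1_abstract",
    "loc_first_section",
    "loc_last_n2_first_section",
    "loc_results",
    "loc_other_sections",
    "loc_last_section",
    "loc_section_titles",
    "loc_appendix",
    "loc_figure_captions",
    "loc_table_captions",
)

FEATURE_NAMES: tuple[str, ...] = (
    ("match_exact", "match_partial", "vote_total")
    + tuple(f"rule_{r.value}" for r in ALL_RULES)
    + ("freq_article", "freq_results_pct")
    + LOCATION_NAMES
    + ("keyword_match", "fullname_abbrev_match")
)

N_FEATURES = len(FEATURE_NAMES)


class FeatureError(ValueError):
    pass


def _first_body_index(article: Article) -> int | None:
    for i, s in enumerate(article.sections):
        if s.kind == SectionKind.INTRODUCTION:
            return i
    for i, s in enumerate(article.sections):
        if s.kind not in (SectionKind.TITLE, SectionKind.ABSTRACT):
            return i
    return None


def _last_body_index(article: Article) -> int | None:
    for i in range(len(article.sections) - 1, -1, -1):
        if article.sections[i].kind == SectionKind.CONCLUSION:
            return i
    for i in range(len(article.sections) - 1, -1, -1):
        if article.sections[i].kind not in (
            SectionKind.TITLE,
            SectionKind.ABSTRACT,
            SectionKind.FIGURE_CAPTION,
            SectionKind.TABLE_CAPTION,
        ):
            return i
    return None


def extract_features(
    ng: NormalizedGene,
    article: Article,
    metadata: ArticleMetadata,
    n1: int = DEFAULT_N1,
    n2: int = DEFAULT_N2,
) -> np.ndarray:
    """Feature vector for one normalized identifier (order = FEATURE_NAMES)."""
    if not ng.mentions:
        raise FeatureError(f"identifier {ng.gene_id} has no mentions")
    known_keys = {k for k, v in metadata.normalized.items() if v is ng}
    if not known_keys and all(v.gene_id != ng.gene_id for v in metadata.normalized.values()):
        raise FeatureError(f"identifier {ng.gene_id} absent from metadata")

    v = np.zeros(N_FEATURES)
    idx = {name: i for i, name in enumerate(FEATURE_NAMES)}

    v[idx["match_exact"]] = 1.0 if ng.match_kind == "exact" else 0.0
    v[idx["match_partial"]] = 1.0 if ng.match_kind == "partial" else 0.0

    if ng.vote is not None:
        v[idx["vote_total"]] = ng.vote.total
        for rule in ng.vote.votes_for:
            v[idx[f"rule_{rule.value}"]] = 1.0

    freq = len(ng.mentions)
    v[idx["freq_article"]] = math.log1p(freq)
    n_results = sum(
        1
        for m in ng.mentions
        if article.sections[m.section_index].kind == SectionKind.RESULTS
    )
    v[idx["freq_results_pct"]] = n_results / freq

    first_body = _first_body_index(article)
    last_body = _last_body_index(article)
    for m in ng.mentions:
        sec = article.sections[m.section_index]
        kind = sec.kind
        if kind == SectionKind.TITLE:
            v[idx["loc_title"]] = 1.0
        elif kind == SectionKind.ABSTRACT:
            v[idx["loc_abstract"]] = 1.0
            if m.sentence_index >= len(sec.sentences) - n1:
                v[idx["loc_last_n1_abstract"]] = 1.0
        elif kind == SectionKind.RESULTS:
            v[idx["loc_results"]] = 1.0
        elif kind == SectionKind.SECTION_TITLE:
            v[idx["loc_section_titles"]] = 1.0
        elif kind == SectionKind.APPENDIX:
            v[idx["loc_appendix"]] = 1.0
        elif kind == SectionKind.FIGURE_CAPTION:
            v[idx["loc_figure_captions"]] = 1.0
        elif kind == SectionKind.TABLE_CAPTION:
            v[idx["loc_table_captions"]] = 1.0
        else:
            v[idx["loc_other_sections"]] = 1.0
        if m.section_index == first_body:
            v[idx["loc_first_section"]] = 1.0
            if m.sentence_index >= len(sec.sentences) - n2:
                v[idx["loc_last_n2_first_section"]] = 1.0
        if m.section_index == last_body:
            v[idx["loc_last_section"]] = 1.0

    names = {normalize_name(m.text) for m in ng.mentions}
    keywords = {normalize_name(k) for k in metadata.keywords}
    if names & keywords:
        v[idx["keyword_match"]] = 1.0
    abbrev_strings = set()
    for lf, sf in metadata.abbreviations:
        abbrev_strings.add(normalize_name(lf))
        abbrev_strings.add(normalize_name(sf))
    if names & abbrev_strings:
        v[idx["fullname_abbrev_match"]] = 1.0
    return v


@dataclass
class RankerModel:
    """Linear margin classifier with a logistic confidence calibration."""

    weights: np.ndarray
    bias: float
    calib_scale: float = 1.0
    calib_offset: float = 0.0
    feature_names: tuple[str, ...] = field(default=FEATURE_NAMES)

    def decision(self, vectors: np.ndarray) -> np.ndarray:
        vectors = np.atleast_2d(vectors)
        if vectors.shape[1] != len(self.weights):
            raise FeatureError(
                f"expected {len(self.weights)} features, got {vectors.shape[1]}"
            )
        return vectors @ self.weights + self.bias

    def save(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "version": 1,
                    "weights": list(self.weights),
                    "bias": self.bias,
                    "calib_scale": self.calib_scale,
                    "calib_offset": self.calib_offset,
                    "feature_names": list(self.feature_names),
                },
                fh,
                indent=1,
            )
            fh.write("\n")

    @classmethod
    def load(cls, path: str) -> "RankerModel":
        with open(path, encoding="utf-8") as fh:
            obj = json.load(fh)
        return cls(
            weights=np.asarray(obj["weights"], dtype=float),
            bias=float(obj["bias"]),
            calib_scale=float(obj["calib_scale"]),
            calib_offset=float(obj["calib_offset"]),
            feature_names=tuple(obj["feature_names"]),
        )


def train_ranker(
    examples: list[tuple[np.ndarray, int]],
    seed: int = 0,
    C: float = 1.0,
) -> RankerModel:
    """Fit a linear margin classifier on (vector, label∈{0,1}) examples.

    Confidence calibration is a logistic map whose scale is set from the
    spread of training decision values (strictly increasing, so ranking by
    confidence equals ranking by decision value).
    """
    if not examples:
        raise ValueError("no training examples")
    X = np.vstack([np.asarray(v, dtype=float) for v, _ in examples])
    y = np.asarray([int(lab) for _, lab in examples])
    if len(set(y.tolist())) < 2:
        raise ValueError("training requires both labels")
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    clf = LinearSVC(C=C, random_state=seed, max_iter=20000)
    clf.fit(X, y)
    model = RankerModel(weights=clf.coef_.ravel().copy(), bias=float(clf.intercept_[0]))
    d = model.decision(X)
    spread = float(np.std(d))
    model.calib_scale = 1.0 / spread if spread > 1e-9 else 1.0
    model.calib_offset = float(np.median(d))
    return model


def score_ids(model: RankerModel, vectors: np.ndarray | list) -> list[float]:
    """Confidences in (0,1), strictly monotone in the decision value."""
    if isinstance(vectors, list) and not vectors:
        return []
    arr = np.atleast_2d(np.asarray(vectors, dtype=float))
    if arr.size == 0:
        return []
    d = model.decision(arr)
    z = np.clip(model.calib_scale * (d - model.calib_offset), -500.0, 500.0)
    conf = 1.0 / (1.0 + np.exp(-z))
    eps = 1e-12  # keep the open interval (0, 1)
    return [float(c) for c in np.clip(conf, eps, 1.0 - eps)]


def rank_article(
    model: RankerModel,
    ngs: list[NormalizedGene],
    article: Article,
    metadata: ArticleMetadata,
    n1: int = DEFAULT_N1,
    n2: int = DEFAULT_N2,
) -> list[tuple[str, float]]:
    """Rank all normalized identifiers of an article by confidence."""
    if not ngs:
        return []
    per_id: dict[str, float] = {}
    vectors = [extract_features(ng, article, metadata, n1, n2) for ng in ngs]
    confs = score_ids(model, np.vstack(vectors))
    for ng, c in zip(ngs, confs):
        per_id[ng.gene_id] = max(per_id.get(ng.gene_id, 0.0), c)
    out = list(per_id.items())
    out.sort(key=lambda p: (-p[1], p[0]))
    return out


def make_ranker(model: RankerModel, n1: int = DEFAULT_N1, n2: int = DEFAULT_N2):
    """Adapter for normalize_article's ranker slot."""

    def ranker(article: Article, ngs: list[NormalizedGene]) -> list[tuple[str, float]]:
        return rank_article(model, ngs, article, article.metadata, n1, n2)

    return ranker
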