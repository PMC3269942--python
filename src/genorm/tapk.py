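"""Threshold Average Precision at a median of k errors per query (TAP-k).

For a ranked identifier list with reliability E-values, the per-query TAP at a
threshold E0 is

    TAP(E0) = (sum of precisions at each correct ID with E-value <= E0
               + p(E0)) / (R + 1)

where R is the number of gold identifiers, the sentinel is the last returned
ID with E-value <= E0, and p(E0) is the fraction of IDs up to and including
the sentinel that are correct.  The sentinel term penalizes terminal
pre-threshold incorrect IDs.  The threshold E_k(A) is the smallest E-value at
which the median number of errors per query reaches k; TAP-k is the mean TAP
over queries at that threshold.
"""

from __future__ import annotations

import csv
from collections import defaultdict
from dataclasses import dataclass, field


@dataclass
class QueryResult:
    query_id: str
    gold: set[str]
    retrieved: list[tuple[str, float]]  # (gene_id, e_value), e_value ascending

    def __post_init__(self) -> None:
        if not self.gold:
            raise ValueError(f"query {self.query_id} has an empty gold set")
        evs = [e for _, e in self.retrieved]
        if any(b < a for a, b in zip(evs, evs[1:])):
            raise ValueError(f"query {self.query_id}: e_values must be non-decreasing")
        ids = [g for g, _ in self.retrieved]
        if len(ids) != len(set(ids)):
            raise ValueError(f"query {self.query_id}: duplicate retrieved IDs")

    @classmethod
    def from_confidences(
        cls, query_id: str, gold: set[str], ranked: list[tuple[str, float]]
    ) -> "QueryResult":
        """Adapt (gene_id, confidence∈(0,1]) descending to ascending E-values."""
        retrieved = [(g, 1.0 - c) for g, c in ranked]
        return cls(query_id=query_id, gold=gold, retrieved=retrieved)


@dataclass
class TapResult:
    per_query_tap: dict[str, float]
    threshold_Ek: float
    k: int

    @property
    def mean_tap(self) -> float:
        vals = list(self.per_query_tap.values())
        return sum(vals) / len(vals) if vals else 0.0


def query_tap(q: QueryResult, E0: float) -> float:
    """Per-query threshold average precision at threshold ``E0``."""
    R = len(q.gold)
    below = [(gid, gid in q.gold) for gid, ev in q.retrieved if ev <= E0]
    if not below:
        return 0.0
    total = 0.0
    n_correct = 0
    for i, (_, correct) in enumerate(below, start=1):
        if correct:
            n_correct += 1
            total += n_correct / i
    # sentinel: last ID at or below the threshold
    p_sentinel = n_correct / len(below)
    return (total + p_sentinel) / (R + 1)


def _errors_at(q: QueryResult, E0: float) -> int:
    return sum(1 for gid, ev in q.retrieved if ev <= E0 and gid not in q.gold)


def _median_reaches(errors: list[int], k: int) -> bool:
    """True when the median errors-per-query is at least k, read literally as
    "at least 50% of the queries have at least k errors"."""
    return 2 * sum(1 for e in errors if e >= k) >= len(errors)


def find_threshold_Ek(queries: list[QueryResult], k: int) -> float:
    """Smallest E-value at which the median errors-per-query reaches k.

    Candidate thresholds are the retrieved E-values; ties at the threshold are
    included (<= comparison).  If the median never reaches k the maximum
    E-value is returned.
    """
    if not queries:
        raise ValueError("queries must be non-empty")
    if k < 1:
        raise ValueError("k must be >= 1")
    all_evs = sorted({ev for q in queries for _, ev in q.retrieved})
    if not all_evs:
        return 0.0
    for e0 in all_evs:
        if _median_reaches([_errors_at(q, e0) for q in queries], k):
            return e0
    return all_evs[-1]


def mean_tapk(queries: list[QueryResult], k: int) -> TapResult:
    """Query-averaged TAP at the E_k(A) threshold."""
    e0 = find_threshold_Ek(queries, k)
    per_query = {q.query_id: query_tap(q, e0) for q in queries}
    return TapResult(per_query_tap=per_query, threshold_Ek=e0, k=k)


def improvement_report(baseline: float, system: float) -> tuple[float, float]:
    """Delta and relative improvement (%, 2 decimals) of system over baseline."""
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    delta = system - baseline
    relative_pct = round(100.0 * delta / baseline, 2)
    return (round(delta, 4), relative_pct)


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------


def read_gold(path: str) -> dict[str, set[str]]:
    """Gold TSV: article_id <tab> gene_id."""
    gold: dict[str, set[str]] = defaultdict(set)
    with open(path, encoding="utf-8", newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            if row[0] == "article_id":
                continue
            gold[row[0]].add(row[1])
    return dict(gold)


def read_ranked(path: str, evalue: bool = False) -> dict[str, list[tuple[str, float]]]:
    """Ranked TSV: article_id <tab> gene_id <tab> rank <tab> confidence.

    With ``evalue=True`` the fourth column is read as an E-value directly;
    otherwise confidences are adapted via e = 1 - c.
    """
    per_article: dict[str, list[tuple[int, str, float]]] = defaultdict(list)
    with open(path, encoding="utf-8", newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#") or row[0] == "article_id":
                continue
            aid, gid, rank, score = row[0], row[1], int(row[2]), float(row[3])
            ev = score if evalue else 1.0 - score
            per_article[aid].append((rank, gid, ev))
    out: dict[str, list[tuple[str, float]]] = {}
    for aid, rows in per_article.items():
        rows.sort()
        out[aid] = [(gid, ev) for _, gid, ev in rows]
    return out


def build_queries(
    gold: dict[str, set[str]], ranked: dict[str, list[tuple[str, float]]]
) -> list[QueryResult]:
    """One query per gold article; articles with no predictions get empty lists."""
    queries = []
    for aid in sorted(gold):
        queries.append(
            QueryResult(query_id=aid, gold=gold[aid], retrieved=ranked.get(aid, []))
        )
    return queries


def write_ranked(path: str, per_article: dict[str, list[tuple[str, float]]]) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["article_id", "gene_id", "rank", "confidence"])
        for aid in sorted(per_article):
            for rank, (gid, conf) in enumerate(per_article[aid], start=1):
                w.writerow([aid, gid, rank, f"{conf:.6f}"])
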