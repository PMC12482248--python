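"""Fingerprint retrieval and evaluation metrics.

Ranking orders a fingerprint collection by the normalized Euclidean
distance to a query (ascending; rank 1 is the best match).  Detection
quality is summarised by the substructure F1-score (count-clipped
multiset precision/recall, with a presence-only mode for baselines that
cannot count) and the molecule exact-match rate (percentage of
molecules whose substructures are all perfectly recovered).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Hashable, Iterable, Sequence

from .fingerprint import SVMF, svmf_distance


class RetrievalError(ValueError):
    pass


@dataclass(frozen=True)
class RetrievalRanking:
    query_id: str
    ordered: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        dists = [s for _, s in self.ordered]
        if any(b < a for a, b in zip(dists, dists[1:])):
            raise RetrievalError("distances must be non-decreasing")

    @property
    def rank_of(self) -> dict[str, int]:
        return {mol_id: pos + 1 for pos, (mol_id, _) in enumerate(self.ordered)}


def rank_dataset(
    query: SVMF,
    dataset: Sequence[tuple[str, SVMF]],
    query_id: str = "query",
) -> RetrievalRanking:
    """Stable ascending sort of the dataset by distance to the query.

    Ties keep dataset insertion order, so rankings are deterministic.
    """
    if not dataset:
        raise RetrievalError("empty dataset")
    scored = [
        (mol_id, svmf_distance(query, fp)) for mol_id, fp in dataset
    ]
    ordered = tuple(sorted(scored, key=lambda pair: pair[1]))
    return RetrievalRanking(query_id=query_id, ordered=ordered)


def mean_rank(
    queries: Sequence[tuple[SVMF, str]],
    dataset: Sequence[tuple[str, SVMF]],
) -> float:
    """Average 1-based rank of each query's target molecule."""
    if not queries:
        raise RetrievalError("no queries")
    total = 0
    for pos, (query, target_id) in enumerate(queries):
        ranking = rank_dataset(query, dataset, query_id=str(pos))
        rank = ranking.rank_of.get(target_id)
        if rank is None:
            raise RetrievalError(
                f"query {pos}: target {target_id!r} not in dataset"
            )
        total += rank
    return total / len(queries)


def per_query_ranks(
    queries: Sequence[tuple[SVMF, str]],
    dataset: Sequence[tuple[str, SVMF]],
) -> list[int]:
    """1-based rank of each query's target, in query order."""
    ranks = []
    for pos, (query, target_id) in enumerate(queries):
        ranking = rank_dataset(query, dataset, query_id=str(pos))
        rank = ranking.rank_of.get(target_id)
        if rank is None:
            raise RetrievalError(
                f"query {pos}: target {target_id!r} not in dataset"
            )
        ranks.append(rank)
    return ranks


def substructure_f1(
    truth: Iterable[Hashable],
    pred: Iterable[Hashable],
    presence_only: bool = False,
) -> float:
    """Count-clipped multiset F1 between true and predicted substructures.

    TP = sum_i min(count_truth(i), count_pred(i)); precision = TP/|pred|,
    recall = TP/|truth|.  ``presence_only`` collapses counts to 0/1 for
    comparison against methods that do not localise instances.  Both
    empty -> 1; exactly one empty -> 0.
    """
    ct = Counter(truth)
    cp = Counter(pred)
    if presence_only:
        ct = Counter(set(ct))
        cp = Counter(set(cp))
    n_truth = sum(ct.values())
    n_pred = sum(cp.values())
    if n_truth == 0 and n_pred == 0:
        return 1.0
    if n_truth == 0 or n_pred == 0:
        return 0.0
    tp = sum(min(ct[k], cp[k]) for k in ct)
    if tp == 0:
        return 0.0
    precision = tp / n_pred
    recall = tp / n_truth
    return 2 * precision * recall / (precision + recall)


def molecule_exact_match(f1_scores: Sequence[float]) -> float:
    """Percentage of molecules with F1 exactly 1 (all substructures found).

    F1 reaches 1.0 exactly (in floating point) iff TP = |truth| = |pred|,
    so comparing against 1.0 is safe.
    """
    if not f1_scores:
        raise RetrievalError("empty score list")
    if any(not 0 <= s <= 1 for s in f1_scores):
        raise RetrievalError("scores must lie in [0, 1]")
    return 100.0 * sum(1 for s in f1_scores if s == 1.0) / len(f1_scores)
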