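"""Automated clustering-and-switching segmentation of fluency sequences.

A fluency sequence (the words a participant produced for one semantic
category) is segmented by walking consecutive response pairs and comparing
the cosine similarity of their word vectors against a category-specific
threshold: the median similarity over all unordered word pairs in that
category's word pool.  A similarity strictly below the threshold opens a new
cluster (a *switch*); a cluster is a maximal run of two or more consecutive
words whose internal similarities all stay at or above the threshold.
Switch counts are the dependent variable of the downstream negative-binomial
condition-effect model.

The module is fully deterministic.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .embeddings import MISSING, EmbeddingStore, cosine_similarity, resolve_token

__all__ = [
    "CategoryThreshold",
    "SwitchAnnotation",
    "SwitchingError",
    "category_threshold",
    "annotate_sequence",
    "switch_table",
    "write_thresholds",
]


class SwitchingError(ValueError):
    """Raised when a sequence or pool cannot be segmented."""


@dataclass(frozen=True)
class CategoryThreshold:
    """Median pairwise similarity over a category's word pool."""

    category: str
    threshold: float
    pool_size: int
    pair_count: int

    def __post_init__(self):
        if not -1.0 <= self.threshold <= 1.0:
            raise ValueError(f"threshold {self.threshold} outside [-1, 1]")


@dataclass
class SwitchAnnotation:
    """Segmentation of one response sequence.

    ``boundary_flags`` has one entry per consecutive pair of *resolvable*
    tokens (True = switch).  ``clusters`` are ``(start, end)`` index spans
    (inclusive, in original token positions) covering runs of >= 2 tokens;
    singleton runs belong to no cluster.  ``excluded_tokens`` records
    positions spliced out of the similarity chain and why.
    """

    sequence_id: str
    tokens: list[str]
    boundary_flags: list[bool]
    n_switches: int
    clusters: list[tuple[int, int]]
    excluded_tokens: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)


def category_threshold(
    word_pool: Sequence[str],
    store: EmbeddingStore,
    policy: str = "skip",
    category: str = "",
) -> CategoryThreshold:
    """Median cosine similarity across all unordered pairs of distinct
    resolvable pool words.

    Even pair counts use the mean of the two middle order statistics
    (``numpy.median``).  Fewer than two resolvable words raise
    :class:`SwitchingError`.
    """
    seen: dict[str, np.ndarray] = {}
    for word in word_pool:
        if word in seen:
            continue
        vec = resolve_token(word, store, policy=policy)
        if vec is not MISSING:
            seen[word] = vec
    if len(seen) < 2:
        raise SwitchingError(
            f"category {category!r}: need >= 2 resolvable distinct words, "
            f"got {len(seen)}"
        )
    mat = np.vstack(list(seen.values()))
    mat = mat / np.linalg.norm(mat, axis=1, keepdims=True)
    sims = np.clip(mat @ mat.T, -1.0, 1.0)
    iu = np.triu_indices(len(seen), k=1)
    pairwise = sims[iu]
    return CategoryThreshold(
        category=category,
        threshold=float(np.median(pairwise)),
        pool_size=len(seen),
        pair_count=int(pairwise.size),
    )


def annotate_sequence(
    tokens: Sequence[str],
    store: EmbeddingStore,
    threshold: CategoryThreshold | float,
    policy: str = "skip",
    sequence_id: str = "",
) -> SwitchAnnotation:
    """Segment one production sequence into clusters and switches.

    Unresolvable tokens are spliced out of the similarity chain (the
    similarity is computed between the flanking resolvable tokens) and
    recorded in ``excluded_tokens``.  The boundary rule is strict: a
    consecutive-pair similarity exactly equal to the threshold stays inside
    the cluster.
    """
    tokens = list(tokens)
    if not tokens:
        raise SwitchingError("empty token list")
    thr = threshold.threshold if isinstance(threshold, CategoryThreshold) else float(threshold)

    resolved: list[tuple[int, np.ndarray]] = []
    excluded: list[tuple[int, str]] = []
    for pos, tok in enumerate(tokens):
        vec = resolve_token(tok, store, policy=policy)
        if vec is MISSING:
            excluded.append((pos, "out-of-vocabulary"))
        else:
            resolved.append((pos, vec))
    if not resolved:
        raise SwitchingError(f"sequence {sequence_id!r}: no resolvable tokens")

    flags: list[bool] = []
    for (_, u), (_, v) in zip(resolved, resolved[1:]):
        flags.append(cosine_similarity(u, v) < thr)

    # clusters: maximal runs of resolved tokens with no internal switch
    clusters: list[tuple[int, int]] = []
    run_start = 0  # index into `resolved`
    for i, is_switch in enumerate(flags + [True]):
        if is_switch:
            run_end = i  # run covers resolved[run_start..run_end]
            if run_end - run_start + 1 >= 2:
                clusters.append((resolved[run_start][0], resolved[run_end][0]))
            run_start = i + 1

    return SwitchAnnotation(
        sequence_id=sequence_id,
        tokens=tokens,
        boundary_flags=flags,
        n_switches=int(sum(flags)),
        clusters=clusters,
        excluded_tokens=excluded,
    )


def pooled_category_words(
    trials: pd.DataFrame, require_correct: bool = True
) -> dict[str, list[str]]:
    """Per-category word pool: distinct correct, non-repeated responses
    produced for that category across all participants and sessions."""
    df = trials[trials["task"] == "semantic_fluency"]
    if require_correct and "correct" in df.columns:
        df = df[df["correct"].astype("boolean").fillna(False).astype(bool)]
    pools: dict[str, list[str]] = {}
    for cat, grp in df.groupby("item", sort=True):
        pools[str(cat)] = sorted(set(grp["response"].astype(str)))
    return pools


def compute_thresholds(
    trials: pd.DataFrame,
    store: EmbeddingStore,
    policy: str = "skip",
    word_pools: Optional[dict[str, Sequence[str]]] = None,
) -> dict[str, CategoryThreshold]:
    """Category-specific thresholds from produced responses (default) or an
    externally supplied norm list (``word_pools``)."""
    pools = word_pools if word_pools is not None else pooled_category_words(trials)
    return {
        cat: category_threshold(words, store, policy=policy, category=cat)
        for cat, words in pools.items()
    }


def switch_table(
    trials: pd.DataFrame,
    store: EmbeddingStore,
    thresholds: dict[str, CategoryThreshold],
    policy: str = "skip",
    chain_correct_only: bool = True,
) -> pd.DataFrame:
    """One row per participant x session x category with the switch count.

    Only correct, non-repeated responses enter the similarity chain by
    default.  A category present in the data but missing from ``thresholds``
    raises :class:`SwitchingError`.
    """
    df = trials[trials["task"] == "semantic_fluency"].copy()
    if chain_correct_only and "correct" in df.columns:
        df = df[df["correct"].astype("boolean").fillna(False).astype(bool)]
    present = set(df["item"].astype(str))
    missing = present - set(thresholds)
    if missing:
        raise SwitchingError(f"no threshold for categories: {sorted(missing)}")

    rows = []
    keys = ["participant", "session", "condition", "item"]
    for (pid, sess, cond, cat), grp in df.groupby(keys, sort=True):
        grp = grp.sort_values("trial_index")
        tokens = grp["response"].astype(str).tolist()
        ann = annotate_sequence(
            tokens,
            store,
            thresholds[str(cat)],
            policy=policy,
            sequence_id=f"{pid}/s{sess}/{cat}",
        )
        rows.append(
            {
                "participant": pid,
                "session": sess,
                "condition": cond,
                "category": cat,
                "n_switches": ann.n_switches,
                "n_clusters": ann.n_clusters,
                "n_items": len(tokens),
            }
        )
    return pd.DataFrame(rows)


def write_thresholds(thresholds: dict[str, CategoryThreshold], path) -> None:
    pd.DataFrame(
        [
            {
                "category": t.category,
                "threshold": t.threshold,
                "pool_size": t.pool_size,
                "pair_count": t.pair_count,
            }
            for t in thresholds.values()
        ]
    ).to_csv(path, sep="\t", index=False)
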