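"""Consensus QA and the CASP16 model-selection strategies.

A model pool is described by a symmetric pairwise-similarity matrix
(TM-score) and a :class:`~foldrank.containers.ScoreTable` of per-model
QA scores.  The five strategies mirror the submission protocols of the
MULTICOM predictors:

``multicom_ai``
    rank by global plDDT, then greedily add structurally diverse
    models (pairwise TM below a cutoff), guaranteeing one AlphaFold3
    model when available.
``multicom_gate``
    rank by GATE, K-means-cluster the pool on its similarity rows and
    submit the best model of each cluster (plus an AlphaFold3 model if
    none was selected).
``multicom_llm``
    top-1 by AlphaFold3 ranking score, remainder by the mean of GATE
    and global plDDT.
``multicom``
    top-1 by the mean of AlphaFold3 ranking score and GATE, remainder
    by cycling through avg(GATE, plDDT), GATE, GCPNet-EMA, EnQA and PSS.
``multicom_human``
    top-1 by the mean of GATE and global plDDT, remainder by plDDT;
    manual adjustments enter as an explicit override list.

Scores on unlike scales are min-max normalised per column before any
averaging (switchable); all ties break lexicographically on model id
so selections are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.cluster import KMeans

from .containers import ScoreTable
from .errors import ArgumentError, ConfigError

__all__ = [
    "SelectionConfig",
    "ClusterAssignment",
    "pss",
    "aggregate_scores",
    "order_models",
    "cluster_models",
    "diversity_select",
    "select_top",
    "STRATEGIES",
]

STRATEGIES = ("multicom_ai", "multicom_gate", "multicom_llm", "multicom", "multicom_human")


@dataclass
class SelectionConfig:
    strategy: str = "multicom_ai"
    n_select: int = 5
    diversity_tm_cutoff: float = 0.8
    n_clusters: int = 5
    require_af3: bool = True
    rng_seed: int = 0
    primary_score: str = "gate"
    normalize_scores: bool = True  # min-max per column before averaging

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ConfigError(
                f"unknown strategy {self.strategy!r}; choose from {STRATEGIES}"
            )
        if self.n_select < 1:
            raise ArgumentError("n_select must be >= 1")
        if not (0 < self.diversity_tm_cutoff <= 1):
            raise ArgumentError("diversity_tm_cutoff must be in (0, 1]")


@dataclass
class ClusterAssignment:
    """K-means partition of a model pool, clusters ordered by the score
    of their representative (best first)."""

    labels: np.ndarray  # (n_models,) cluster index per model
    representatives: list[str]  # model_id per cluster
    cluster_sizes: list[int]


def _check_similarity(similarity: np.ndarray, n_min: int = 2) -> np.ndarray:
    sim = np.asarray(similarity, dtype=np.float64)
    if sim.ndim != 2 or sim.shape[0] != sim.shape[1]:
        raise ArgumentError(f"similarity must be square, got {sim.shape}")
    if sim.shape[0] < n_min:
        raise ArgumentError(f"similarity must be at least {n_min}x{n_min}")
    if not np.allclose(sim, sim.T, atol=1e-8):
        raise ArgumentError("similarity matrix is not symmetric")
    return sim


def pss(similarity: np.ndarray) -> np.ndarray:
    """Average pairwise similarity score: mean of each row excluding the
    diagonal.  The consensus QA signal — high for models resembling the
    bulk of the pool."""
    sim = _check_similarity(similarity)
    n = sim.shape[0]
    return (sim.sum(axis=1) - np.diag(sim)) / (n - 1)


def _normalize_column(col: np.ndarray) -> np.ndarray:
    out = np.full_like(col, np.nan)
    present = np.isfinite(col)
    if not present.any():
        return out
    lo, hi = col[present].min(), col[present].max()
    if hi == lo:
        out[present] = 0.5  # constant column carries no ranking signal
    else:
        out[present] = (col[present] - lo) / (hi - lo)
    return out


def aggregate_scores(
    table: ScoreTable,
    names: Sequence[str],
    weights: Sequence[float] | None = None,
    normalize: bool = True,
) -> np.ndarray:
    """Per-model (weighted) mean of the named score columns.

    Each column is min-max normalised over the models where it is
    present (unless ``normalize=False``); a model's aggregate averages
    only its present values.  Models missing every named score get NaN
    and are ranked last by :func:`order_models`.
    """
    if not names:
        raise ArgumentError("aggregate_scores needs at least one score name")
    if weights is not None and len(weights) != len(names):
        raise ArgumentError("weights length must match names")
    w = np.asarray(weights if weights is not None else np.ones(len(names)), dtype=float)
    cols = np.stack([
        _normalize_column(table.column(n)) if normalize else table.column(n)
        for n in names
    ])  # (k, n_models)
    present = np.isfinite(cols)
    wsum = (present * w[:, None]).sum(axis=0)
    total = np.where(present, cols * w[:, None], 0.0).sum(axis=0)
    with np.errstate(invalid="ignore"):
        return np.where(wsum > 0, total / wsum, np.nan)


def order_models(table: ScoreTable, scores: np.ndarray) -> list[str]:
    """Model ids sorted by score descending; NaN last; ties by id."""
    keyed = sorted(
        zip(table.model_ids, scores),
        key=lambda kv: (not np.isfinite(kv[1]), -(kv[1] if np.isfinite(kv[1]) else 0.0), kv[0]),
    )
    return [mid for mid, _ in keyed]


def _primary_scores(table: ScoreTable, config: SelectionConfig) -> np.ndarray:
    for name in (config.primary_score, "plddt_global"):
        if name in table:
            col = table.column(name)
            if np.isfinite(col).any():
                return col
    return np.full(len(table.model_ids), np.nan)


def cluster_models(
    similarity: np.ndarray, table: ScoreTable, config: SelectionConfig
) -> ClusterAssignment:
    """K-means on the rows of (1 - similarity).

    A model's dissimilarity profile against the whole pool is its
    feature vector, so models of one conformation cluster together
    regardless of pool composition.  k collapses to the number of
    distinct profiles when the pool is degenerate.  Fixed seed and 10
    restarts keep the assignment deterministic.
    """
    sim = _check_similarity(similarity)
    if sim.shape[0] != len(table.model_ids):
        raise ArgumentError("similarity size does not match score table")
    features = 1.0 - sim
    n_distinct = len(np.unique(np.round(features, 8), axis=0))
    k = max(1, min(config.n_clusters, n_distinct))
    if k == 1:
        labels = np.zeros(sim.shape[0], dtype=int)
    else:
        km = KMeans(n_clusters=k, n_init=10, random_state=config.rng_seed)
        labels = km.fit_predict(features)
    primary = _primary_scores(table, config)

    def best_in(cluster: int) -> tuple[str, float]:
        members = [
            (table.model_ids[i], primary[i])
            for i in np.flatnonzero(labels == cluster)
        ]
        members.sort(key=lambda kv: (
            not np.isfinite(kv[1]), -(kv[1] if np.isfinite(kv[1]) else 0.0), kv[0]
        ))
        return members[0]

    reps = [best_in(c) for c in range(labels.max() + 1)]
    order = sorted(
        range(len(reps)),
        key=lambda c: (
            not np.isfinite(reps[c][1]),
            -(reps[c][1] if np.isfinite(reps[c][1]) else 0.0),
            reps[c][0],
        ),
    )
    relabel = {old: new for new, old in enumerate(order)}
    return ClusterAssignment(
        labels=np.array([relabel[l] for l in labels]),
        representatives=[reps[c][0] for c in order],
        cluster_sizes=[int((labels == c).sum()) for c in order],
    )


def _ensure_af3(
    selection: list[str],
    ranked_ids: Sequence[str],
    generators: dict[str, str] | None,
) -> list[str]:
    """Swap the last slot for the best-ranked AlphaFold3 model when the
    selection contains none and the pool has one."""
    if generators is None:
        return selection
    if any(generators.get(mid) == "af3" for mid in selection):
        return selection
    for mid in ranked_ids:
        if generators.get(mid) == "af3":
            return [*selection[:-1], mid]
    return selection


def diversity_select(
    ranked_ids: Sequence[str],
    similarity: np.ndarray,
    model_ids: Sequence[str],
    config: SelectionConfig,
    generators: dict[str, str] | None = None,
) -> list[str]:
    """Greedy diverse top-n: walk the ranking, keeping a model only if
    its TM-score to every kept model is below the diversity cutoff;
    backfill by rank when fewer than ``n_select`` survive."""
    if not ranked_ids:
        raise ArgumentError("ranked_ids must be non-empty")
    sim = _check_similarity(similarity)
    index = {mid: i for i, mid in enumerate(model_ids)}
    kept: list[str] = [ranked_ids[0]]
    for mid in ranked_ids[1:]:
        if len(kept) >= config.n_select:
            break
        if all(sim[index[mid], index[k]] < config.diversity_tm_cutoff for k in kept):
            kept.append(mid)
    if len(kept) < config.n_select:
        for mid in ranked_ids:
            if mid not in kept:
                kept.append(mid)
            if len(kept) >= config.n_select:
                break
    kept = kept[: config.n_select]
    if config.require_af3:
        kept = _ensure_af3(kept, ranked_ids, generators)
    return kept


def _require(table: ScoreTable, strategy: str, names: Sequence[str]) -> None:
    missing = [n for n in names if n not in table]
    if missing:
        raise ConfigError(
            f"strategy {strategy!r} requires score column(s) {missing}"
        )


def _next_unused(ranked: Sequence[str], used: set[str]) -> str | None:
    for mid in ranked:
        if mid not in used:
            return mid
    return None


def select_top(
    similarity: np.ndarray,
    table: ScoreTable,
    config: SelectionConfig,
    generators: dict[str, str] | None = None,
    override: Sequence[str] | None = None,
) -> list[str]:
    """Ordered top-n selection under the configured strategy.

    ``generators`` maps model_id to its producing predictor (``af3``
    matters for the AlphaFold3-inclusion rules).  ``override`` is an
    explicit ranked list standing in for manual adjustment: its entries
    are forced to the front, the computed selection fills the rest.
    """
    _check_similarity(similarity)
    n_avail = len(table.model_ids)
    nsel = min(config.n_select, n_avail)

    def ranked_by(names: Sequence[str]) -> list[str]:
        return order_models(
            table, aggregate_scores(table, names, normalize=config.normalize_scores)
        )

    strategy = config.strategy
    if strategy == "multicom_ai":
        _require(table, strategy, ["plddt_global"])
        selection = diversity_select(
            ranked_by(["plddt_global"]), similarity, table.model_ids, config, generators
        )
    elif strategy == "multicom_gate":
        _require(table, strategy, ["gate"])
        ranked = ranked_by(["gate"])
        clusters = cluster_models(similarity, table, config)
        selection = clusters.representatives[:nsel]
        for mid in ranked:  # backfill when fewer clusters than slots
            if len(selection) >= nsel:
                break
            if mid not in selection:
                selection.append(mid)
        if config.require_af3:
            selection = _ensure_af3(selection, ranked, generators)
    elif strategy == "multicom_llm":
        _require(table, strategy, ["af3_ranking", "gate", "plddt_global"])
        top1 = ranked_by(["af3_ranking"])[0]
        selection = [top1]
        for mid in ranked_by(["gate", "plddt_global"]):
            if len(selection) >= nsel:
                break
            if mid not in selection:
                selection.append(mid)
    elif strategy == "multicom":
        needed = ["af3_ranking", "gate", "plddt_global", "gcpnet_ema", "enqa", "pss"]
        _require(table, strategy, needed)
        top1 = ranked_by(["af3_ranking", "gate"])[0]
        selection = [top1]
        criteria = [["gate", "plddt_global"], ["gate"], ["gcpnet_ema"], ["enqa"], ["pss"]]
        rankings = [ranked_by(names) for names in criteria]
        i = 0
        while len(selection) < nsel:
            pick = _next_unused(rankings[i % len(rankings)], set(selection))
            if pick is None:
                break
            selection.append(pick)
            i += 1
    elif strategy == "multicom_human":
        _require(table, strategy, ["gate", "plddt_global"])
        top1 = ranked_by(["gate", "plddt_global"])[0]
        selection = [top1]
        for mid in ranked_by(["plddt_global"]):
            if len(selection) >= nsel:
                break
            if mid not in selection:
                selection.append(mid)
    else:  # pragma: no cover - guarded by SelectionConfig
        raise ConfigError(f"unknown strategy {strategy!r}")

    if override:
        known = set(table.model_ids)
        bad = [m for m in override if m not in known]
        if bad:
            raise ConfigError(f"override references unknown model(s): {bad}")
        merged = list(dict.fromkeys([*override, *selection]))
        selection = merged[:nsel]
    return selection[:nsel]
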