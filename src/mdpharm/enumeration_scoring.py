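"""Combinatorial subset generation, scoring and ranking of pharmacophore
models, and the screening-loop termination policy.

The total score of a subset is the symmetry factor min(N_A,N_B)/max(N_A,N_B)
times the sum of per-feature scores normalized, per feature kind, by the
master's maximum raw score of that kind.  The symmetry factor enforces the
dual-binding mode: subsets drawn entirely from one partner score 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Iterator

import numpy as np

from .pharmacophore_model import PharmacophoreModel, symmetry_factor

__all__ = [
    "SubsetPlan",
    "ScoredModel",
    "RunReport",
    "enumerate_subsets",
    "score_model",
    "rank_and_cap",
    "span_filter",
    "screening_loop",
]

DEFAULT_PER_K_CAP = 50_000
DEFAULT_HIT_BUDGET = 10_000
MAX_SUBSET_SIZE = 10      # no ligand satisfies more than 10 features
MIN_SUBSET_SIZE = 3       # a pharmacophore needs >= 3 points to fix a pose


@dataclass
class SubsetPlan:
    """Sweep policy: which subset sizes, caps, and the hit budget."""

    k_sequence: list[int] | None = None   # descending; default min(N,10)..4
    per_k_cap: int = DEFAULT_PER_K_CAP
    hit_budget: int = DEFAULT_HIT_BUDGET
    min_span: float | None = None         # A; keep models spanning more
    k_min: int = 4
    prune_zero_score: bool = True

    def resolved_k_sequence(self, n_features: int) -> list[int]:
        if self.k_sequence is not None:
            seq = list(self.k_sequence)
        else:
            start = min(n_features, MAX_SUBSET_SIZE)
            seq = list(range(start, max(self.k_min, MIN_SUBSET_SIZE) - 1, -1))
        for k in seq:
            if k < MIN_SUBSET_SIZE:
                raise ValueError(f"subset size {k} < {MIN_SUBSET_SIZE} is not screenable")
            if k > n_features:
                raise ValueError(f"subset size {k} exceeds feature count {n_features}")
        return seq


@dataclass
class ScoredModel:
    feature_ids: tuple[int, ...]
    total_score: float
    symmetry_factor: float
    max_pairwise_distance: float


def enumerate_subsets(master: PharmacophoreModel, k: int) -> Iterator[tuple[int, ...]]:
    """All C(N, k) feature-id subsets in lexicographic order."""
    n = master.n_features
    if k < 1 or k > n:
        raise ValueError(f"k={k} out of range for {n} features")
    return combinations(range(n), k)


def score_model(
    subset: tuple[int, ...], master: PharmacophoreModel
) -> ScoredModel:
    """Score one subset against the master's per-kind normalization maxima."""
    feats = [master.features[i] for i in subset]
    n_a, n_b = master.partner_counts(subset)
    sym = symmetry_factor(n_a, n_b)
    total = sym * sum(f.normalized_score for f in feats)
    pos = np.array([f.position for f in feats])
    if len(feats) >= 2:
        d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=2)
        max_d = float(d.max())
    else:
        max_d = 0.0
    return ScoredModel(
        feature_ids=tuple(int(i) for i in subset),
        total_score=float(total),
        symmetry_factor=float(sym),
        max_pairwise_distance=max_d,
    )


def rank_and_cap(models: list[ScoredModel], plan: SubsetPlan) -> list[ScoredModel]:
    """Descending total score, ties by lexicographic feature ids, truncated
    at the per-k cap."""
    ranked = sorted(models, key=lambda m: (-m.total_score, m.feature_ids))
    return ranked[: plan.per_k_cap]


def span_filter(model: ScoredModel, min_span: float | None) -> bool:
    """Keep iff the maximum pairwise feature distance exceeds ``min_span``
    (always keep when disabled)."""
    if min_span is None:
        return True
    return model.max_pairwise_distance > min_span


@dataclass
class RunReport:
    """Per-k accounting in the layout of the screening-parameters table."""

    rows: list[dict] = field(default_factory=list)
    total_hits: int = 0
    terminated_early: bool = False
    error: str | None = None

    def to_table(self) -> "pd.DataFrame":  # noqa: F821
        import pandas as pd

        return pd.DataFrame(self.rows)


def screening_loop(
    master: PharmacophoreModel,
    plan: SubsetPlan,
    screen_fn: Callable[[ScoredModel], int],
) -> RunReport:
    """Sweep subset sizes descending; per k: enumerate, score, cap, span-filter,
    screen; stop descending once cumulative hits exceed the budget.

    The budget is checked after each k completes, making the sequential
    semantics exact and deterministic.
    """
    report = RunReport()
    for k in plan.resolved_k_sequence(master.n_features):
        enumerated = 0
        scored: list[ScoredModel] = []
        for subset in enumerate_subsets(master, k):
            enumerated += 1
            m = score_model(subset, master)
            if plan.prune_zero_score and m.total_score == 0.0:
                continue
            scored.append(m)
        ranked = rank_and_cap(scored, plan)
        kept = [m for m in ranked if span_filter(m, plan.min_span)]
        hits_k = 0
        for m in kept:
            try:
                hits_k += int(screen_fn(m))
            except Exception as exc:  # noqa: BLE001 - abort with partial report
                report.error = f"screening failed at k={k}: {exc}"
                report.rows.append(
                    {
                        "k": k,
                        "subsets_enumerated": enumerated,
                        "models_screened": len(kept),
                        "hits": hits_k,
                    }
                )
                return report
        report.rows.append(
            {
                "k": k,
                "subsets_enumerated": enumerated,
                "models_screened": len(kept),
                "hits": hits_k,
            }
        )
        report.total_hits += hits_k
        if report.total_hits > plan.hit_budget:
            report.terminated_early = True
            break
    return report


def binomial_sum(n: int, k_values) -> int:
    """Independent check value: sum of C(n, k) over the swept sizes."""
    return sum(math.comb(n, k) for k in k_values)
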