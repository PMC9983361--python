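"""Greedy backward elimination over motion items.

Each assessment motion costs patient time and effort, so the smallest
motion set that still scores acceptably is clinically valuable. Starting
from the full motion set, every round tentatively removes each remaining
motion's entire feature block, re-runs gain-ranked feature selection with
leave-one-out cross-validation on each candidate set, and keeps the
candidate with the best (ACC±0, weighted kappa); removal ties are broken
by dropping the motion whose block carries the least total gain in the
current model. The recursion continues until a single motion remains.
The *chosen* set is the smallest one along the trace whose LOOCV ACC±0
meets the acceptance threshold (0.70 by default) — fewest motions, not
best score; if no round qualifies, the trace is returned with an explicit
``no_acceptable_set`` flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import RigiposeError
from .features import FeatureMatrix
from .modeling import GainSelectedScorer

__all__ = ["MinimizationRound", "MinimizationTrace", "minimize_items"]


@dataclass
class MinimizationRound:
    """One elimination round: what was removed and how the survivor scored."""

    round_index: int
    removed_motion: str
    remaining_motions: tuple[str, ...]
    acc0: float
    acc1: float
    kappa: float
    feature_count: int
    scorer: GainSelectedScorer | None = None


@dataclass
class MinimizationTrace:
    """Full elimination trace plus the chosen (smallest acceptable) round."""

    target: str
    threshold: float
    rounds: list[MinimizationRound]
    chosen_round: int | None  # index into rounds, None if nothing acceptable
    full_set_acc0: float
    full_set_kappa: float

    def __post_init__(self) -> None:
        sizes = [len(r.remaining_motions) for r in self.rounds]
        if any(b - a != -1 for a, b in zip(sizes, sizes[1:])):
            raise RigiposeError("remaining motion sets must shrink by one per round")
        if self.chosen_round is not None:
            if self.rounds[self.chosen_round].acc0 < self.threshold:
                raise RigiposeError("chosen round falls below the threshold")

    @property
    def no_acceptable_set(self) -> bool:
        return self.chosen_round is None

    @property
    def chosen_motions(self) -> tuple[str, ...] | None:
        if self.chosen_round is None:
            return None
        return self.rounds[self.chosen_round].remaining_motions

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "round": r.round_index,
                "removed": r.removed_motion,
                "motions": ",".join(r.remaining_motions),
                "n_motions": len(r.remaining_motions),
                "acc0": round(r.acc0, 4),
                "acc1": round(r.acc1, 4),
                "kappa": round(r.kappa, 4),
                "feature_count": r.feature_count,
                "chosen": r.round_index == self.chosen_round,
            }
            for r in self.rounds
        ]
        return pd.DataFrame(rows)


def _block_gain(scorer: GainSelectedScorer, motion: str) -> float:
    from .features import FeatureDescriptor

    total = 0.0
    for name, g in scorer.feature_gains_.items():
        if FeatureDescriptor.parse(name).motion == motion:
            total += float(g)
    return total


def _loocv_metrics(scorer: GainSelectedScorer, y) -> tuple[float, float, float]:
    import numpy as np
    from sklearn.metrics import cohen_kappa_score

    pred = scorer.loocv_predictions_
    y = np.asarray(y, dtype=int)
    acc0 = float(np.mean(pred == y))
    acc1 = float(np.mean(np.abs(pred - y) <= 1))
    kappa = float(
        cohen_kappa_score(y, pred, labels=[0, 1, 2, 3], weights=scorer.kappa_weights)
    )
    return acc0, acc1, kappa


def minimize_items(
    X: FeatureMatrix,
    threshold: float = 0.70,
    scorer_factory=None,
    keep_models: bool = False,
) -> MinimizationTrace:
    """Run greedy backward elimination over the motions of a feature matrix.

    Parameters
    ----------
    X : FeatureMatrix
        Training matrix whose descriptors span at least two motions.
    threshold : float
        Minimum LOOCV ACC±0 a reduced set must reach to be acceptable.
    scorer_factory : callable, optional
        Zero-argument callable returning an unfitted
        :class:`GainSelectedScorer`; defaults to the package defaults.
    keep_models : bool
        Keep each surviving round's fitted scorer on the trace (memory).
    """
    if scorer_factory is None:
        scorer_factory = GainSelectedScorer
    motions = list(X.motions)
    if len(motions) < 2:
        raise RigiposeError("nothing to minimize: matrix spans a single motion")

    # Baseline on the full set (context for the trace, never the chosen set).
    base = scorer_factory().fit(X.X, X.y)
    base_acc0, _, base_kappa = _loocv_metrics(base, X.y)

    current_motions = tuple(motions)
    current_scorer = base
    rounds: list[MinimizationRound] = []
    round_index = 0
    while len(current_motions) > 1:
        candidates = []
        for m in sorted(current_motions):
            remaining = tuple(x for x in current_motions if x != m)
            sub = X.restrict_motions(remaining)
            scorer = scorer_factory().fit(sub.X, sub.y)
            acc0, acc1, kappa = _loocv_metrics(scorer, sub.y)
            candidates.append((m, remaining, scorer, acc0, acc1, kappa))
        # Best candidate by (acc0, kappa); ties by smallest block gain in the
        # current model (drop the least informative motion first).
        best_key = max((c[3], c[5]) for c in candidates)
        tied = [c for c in candidates if (c[3], c[5]) == best_key]
        if len(tied) > 1:
            tied.sort(key=lambda c: (_block_gain(current_scorer, c[0]), c[0]))
        removed, remaining, scorer, acc0, acc1, kappa = tied[0]
        rounds.append(
            MinimizationRound(
                round_index=round_index,
                removed_motion=removed,
                remaining_motions=remaining,
                acc0=acc0,
                acc1=acc1,
                kappa=kappa,
                feature_count=len(scorer.selected_features_),
                scorer=scorer if keep_models else None,
            )
        )
        current_motions = remaining
        current_scorer = scorer
        round_index += 1

    chosen: int | None = None
    for r in rounds:  # later rounds have fewer motions; keep the smallest
        if r.acc0 >= threshold:
            chosen = r.round_index
    return MinimizationTrace(
        target=X.target,
        threshold=threshold,
        rounds=rounds,
        chosen_round=chosen,
        full_set_acc0=base_acc0,
        full_set_kappa=base_kappa,
    )
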