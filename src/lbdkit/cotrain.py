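"""Two-view co-training for the sentence relation classifiers.

Two classifiers — one per feature view — start from a small labeled
seed set.  Each round draws a fresh section of the unlabeled pool, both
models score it, and each model's most/least confident instances (the
top and bottom ``fraction``) become pseudo-labeled training examples for
the *other* view.  The canonical schedule draws sections of 2,000…6,000
over five rounds with fraction 0.10, growing each training set
500 → 900 → 1,500 → 2,300 → 3,300 → 4,500.

The loop is agnostic to the classifier behind each view: a view backend
is any object with ``fit(ids, labels) -> model`` and
``score(model, ids) -> array``, which lets tests drive the scheduler
with stub classifiers and production code plug in the kernel SVMs (see
:mod:`lbdkit.views`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Protocol, Sequence

import numpy as np

from lbdkit.classify import EvalReport, evaluate

__all__ = [
    "CoTrainConfig",
    "RoundState",
    "CoTrainHistory",
    "ViewBackend",
    "select_confident",
    "run_cotraining",
    "pick_model",
]


class ViewBackend(Protocol):
    name: str

    def fit(self, ids: Sequence[str], labels: Sequence[int]): ...

    def score(self, model, ids: Sequence[str]) -> np.ndarray: ...


@dataclass(frozen=True)
class CoTrainConfig:
    rounds: int = 5
    fraction: float = 0.10
    pool_sizes: tuple[int, ...] = (2000, 3000, 4000, 5000, 6000)
    seed: int = 0
    C: float = 1.0

    def __post_init__(self) -> None:
        if len(self.pool_sizes) != self.rounds:
            raise ValueError(
                f"pool_sizes has {len(self.pool_sizes)} entries for "
                f"{self.rounds} rounds"
            )
        if not (0.0 < self.fraction <= 0.5):
            raise ValueError(f"fraction must be in (0, 0.5], got {self.fraction}")


@dataclass
class RoundState:
    round_index: int
    train_sizes: tuple[int, int]
    reports: tuple[EvalReport, EvalReport]
    selected: tuple[tuple[list[str], list[str]], tuple[list[str], list[str]]]


@dataclass
class CoTrainHistory:
    """Per-round training-set sizes, per-view test metrics, selections.

    Round 0 is the state before any pool is consumed (models trained on
    the seed set only).
    """

    rounds: list[RoundState] = field(default_factory=list)
    view_names: tuple[str, str] = ("view1", "view2")

    def sizes(self, view: int = 0) -> list[int]:
        return [r.train_sizes[view] for r in self.rounds]

    def f_scores(self, view: int) -> list[float]:
        return [r.reports[view].f_score for r in self.rounds]

    def to_dict(self) -> dict:
        return {
            "view_names": list(self.view_names),
            "rounds": [
                {
                    "round": r.round_index,
                    "train_sizes": list(r.train_sizes),
                    "metrics": [rep.to_dict() for rep in r.reports],
                    "selected": [
                        {"positive": sel[0], "negative": sel[1]}
                        for sel in r.selected
                    ],
                }
                for r in self.rounds
            ],
        }


def select_confident(
    scores: Sequence[tuple[str, float]], fraction: float
) -> tuple[list[str], list[str]]:
    """Split off the most and least confident instances of a scored pool.

    Returns (positive ids, negative ids): the top and bottom
    ⌊fraction·n⌋ by decision score.  Ties keep the stable input order,
    so the bottom slice prefers later-listed instances.  Overlapping
    slices (2⌊fraction·n⌋ > n) are a hard error.
    """
    n = len(scores)
    if n == 0:
        raise ValueError("cannot select from an empty score list")
    k = int(np.floor(fraction * n))
    if k < 1:
        raise ValueError(
            f"fraction {fraction} selects zero instances from a pool of {n}"
        )
    if 2 * k > n:
        raise ValueError(
            f"selection slices overlap: 2*{k} > {n} instances"
        )
    order = sorted(range(n), key=lambda i: (-scores[i][1], i))
    positives = [scores[i][0] for i in order[:k]]
    negatives = [scores[i][0] for i in order[-k:]]
    return positives, negatives


def run_cotraining(
    labeled: Mapping[str, int],
    pool: Sequence[str],
    test: Mapping[str, int],
    views: tuple[ViewBackend, ViewBackend],
    cfg: CoTrainConfig,
) -> CoTrainHistory:
    """Run the co-training schedule and record its full history.

    ``labeled`` maps seed instance ids to ±1; ``pool`` lists unlabeled
    ids; ``test`` maps held-out ids to gold ±1 (never used for training
    or selection).  Each round r draws the next ``cfg.pool_sizes[r]``
    unseen pool instances from a seeded permutation; view 1's confident
    selections (with pseudo-labels) extend view 2's training set and vice
    versa; an instance picked by both views with opposite pseudo-labels
    in the same round is discarded from both.  Pseudo-labels are never
    revised and consumed pool instances never return.
    """
    rng = np.random.default_rng(cfg.seed)
    need = sum(cfg.pool_sizes)
    if len(pool) < need:
        raise ValueError(
            f"pool of {len(pool)} cannot supply {need} instances over "
            f"{cfg.rounds} rounds"
        )
    order = list(np.array(sorted(pool))[rng.permutation(len(pool))])
    cursor = 0

    T1: dict[str, int] = dict(labeled)
    T2: dict[str, int] = dict(labeled)
    test_ids = sorted(test)
    gold = [test[i] for i in test_ids]

    history = CoTrainHistory(view_names=(views[0].name, views[1].name))

    def _evaluate(model, view: ViewBackend) -> EvalReport:
        s = view.score(model, test_ids)
        preds = np.where(s > 0, 1, -1)
        return evaluate(preds, gold)

    def _fit(view: ViewBackend, T: dict[str, int]):
        ids = sorted(T)
        return view.fit(ids, [T[i] for i in ids])

    M1, M2 = _fit(views[0], T1), _fit(views[1], T2)
    history.rounds.append(
        RoundState(
            round_index=0,
            train_sizes=(len(T1), len(T2)),
            reports=(_evaluate(M1, views[0]), _evaluate(M2, views[1])),
            selected=(([], []), ([], [])),
        )
    )

    for r in range(cfg.rounds):
        size = cfg.pool_sizes[r]
        if cursor + size > len(order):
            raise ValueError(f"pool exhausted at round {r + 1}")
        section = order[cursor:cursor + size]
        cursor += size

        s1 = views[0].score(M1, section)
        s2 = views[1].score(M2, section)
        pos1, neg1 = select_confident(list(zip(section, s1)), cfg.fraction)
        pos2, neg2 = select_confident(list(zip(section, s2)), cfg.fraction)

        # cross-view contradiction: drop from both selections
        conflict = (set(pos1) & set(neg2)) | (set(neg1) & set(pos2))
        pos1 = [i for i in pos1 if i not in conflict]
        neg1 = [i for i in neg1 if i not in conflict]
        pos2 = [i for i in pos2 if i not in conflict]
        neg2 = [i for i in neg2 if i not in conflict]

        for i in pos1:
            T2[i] = 1
        for i in neg1:
            T2[i] = -1
        for i in pos2:
            T1[i] = 1
        for i in neg2:
            T1[i] = -1

        M1, M2 = _fit(views[0], T1), _fit(views[1], T2)
        history.rounds.append(
            RoundState(
                round_index=r + 1,
                train_sizes=(len(T1), len(T2)),
                reports=(_evaluate(M1, views[0]), _evaluate(M2, views[1])),
                selected=((pos1, neg1), (pos2, neg2)),
            )
        )
    return history


def pick_model(history: CoTrainHistory, criterion: str = "best_f") -> tuple[int, int]:
    """Choose (view index, round index) from a co-training history.

    ``best_f`` maximizes held-out F-score (ties → earlier round, then
    lower view index); ``last`` returns the final round's better view.
    """
    if not history.rounds:
        raise ValueError("empty co-training history")
    if criterion == "last":
        r = history.rounds[-1]
        view = 0 if r.reports[0].f_score >= r.reports[1].f_score else 1
        return view, r.round_index
    if criterion != "best_f":
        raise ValueError(f"unknown criterion {criterion!r}")
    best = None
    for r in history.rounds:
        for v in (0, 1):
            f = r.reports[v].f_score
            if best is None or f > best[0] + 1e-12:
                best = (f, v, r.round_index)
    return best[1], best[2]
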