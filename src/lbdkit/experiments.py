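"""Parameter-recovery experiments on synthetic planted-rule corpora.

These drive the full pipeline at desk scale: generate a clean labeled
corpus, train the graph-kernel classifier on half, measure held-out F;
then hide most training labels and check that co-training from the
small seed does not fall below the seed-only classifiers.  Problem
sizes (1,000 sentences per corpus, 100-sentence seeds, three 130-strong
pool sections) keep a full ten-seed replication within a few minutes on
one core while leaving enough unlabeled data for the schedule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from lbdkit.classify import EvalReport, evaluate
from lbdkit.cotrain import CoTrainConfig, run_cotraining
from lbdkit.graph import KernelConfig
from lbdkit.synth import GeneratorConfig, generate_corpus
from lbdkit.views import GraphKernelView, WordFeatureView

__all__ = ["planted_rule_recovery", "cotraining_gain", "CotrainOutcome"]


def _split(sents, seed: int, n_train: int, n_test: int):
    rng = np.random.default_rng(seed)
    by_id = {s.sentence_id: s for s in sents}
    ids = sorted(by_id)
    order = [ids[i] for i in rng.permutation(len(ids))]
    return by_id, order[:n_train], order[n_train:n_train + n_test]


def _gold(by_id, ids):
    return {i: (1 if by_id[i].label == "positive" else -1) for i in ids}


def planted_rule_recovery(
    seed: int, n_train: int = 500, n_test: int = 500, C: float = 1.0
) -> EvalReport:
    """Held-out F of the graph-kernel SVM on a clean planted-rule corpus."""
    cfg = GeneratorConfig(n_sentences=n_train + n_test, noise_rate=0.0,
                          seed=seed)
    sents, _ = generate_corpus(cfg)
    by_id, train_ids, test_ids = _split(sents, seed, n_train, n_test)
    view = GraphKernelView(by_id, KernelConfig(), C=C)
    gold_train = _gold(by_id, train_ids)
    model = view.fit(train_ids, [gold_train[i] for i in train_ids])
    scores = view.score(model, test_ids)
    gold_test = _gold(by_id, test_ids)
    return evaluate(np.where(scores > 0, 1, -1),
                    [gold_test[i] for i in test_ids])


@dataclass
class CotrainOutcome:
    initial_f: float
    best_f: float
    sizes: list[int]


def cotraining_gain(
    seed: int,
    hidden_fraction: float = 0.8,
    rounds: int = 3,
    pool_size: int = 130,
    n_train: int = 500,
    n_test: int = 500,
) -> CotrainOutcome:
    """Co-train from a mostly-hidden training set; compare best vs initial F.

    ``hidden_fraction`` of the training sentences lose their labels and
    form the unlabeled pool; the remainder seed both views.  Returns the
    round-0 best F across views and the best F over all rounds.
    """
    cfg = GeneratorConfig(n_sentences=n_train + n_test, noise_rate=0.0,
                          seed=seed)
    sents, _ = generate_corpus(cfg)
    by_id, train_ids, test_ids = _split(sents, seed, n_train, n_test)
    n_seed = int(round((1 - hidden_fraction) * n_train))
    labeled_ids, pool_ids = train_ids[:n_seed], train_ids[n_seed:]

    ct_cfg = CoTrainConfig(rounds=rounds, fraction=0.10,
                           pool_sizes=(pool_size,) * rounds, seed=seed)
    views = (GraphKernelView(by_id, KernelConfig()),
             WordFeatureView(by_id))
    history = run_cotraining(
        _gold(by_id, labeled_ids), pool_ids, _gold(by_id, test_ids),
        views, ct_cfg,
    )
    initial = max(history.rounds[0].reports[v].f_score for v in (0, 1))
    best = max(r.reports[v].f_score for r in history.rounds for v in (0, 1))
    return CotrainOutcome(initial_f=initial, best_f=best,
                          sizes=history.sizes(0))
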