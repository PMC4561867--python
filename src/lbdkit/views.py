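"""Concrete co-training view backends over annotated sentences.

``GraphKernelView`` featurizes each sentence once into its label-pair
walk-weight matrix and serves precomputed-kernel SVMs; cross-kernels for
scoring are sparse dot products in the shared label-pair space.
``WordFeatureView`` serves linear SVMs over the sparse word-feature
vectors under a corpus-level vocabulary.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
from scipy import sparse

from lbdkit.classify import KernelModel, predict_scores, train
from lbdkit.corpus import AnnotatedSentence
from lbdkit.features import (
    WordLists,
    extract_features,
    fit_vocabulary,
    vectorize_many,
)
from lbdkit.graph import (
    KernelConfig,
    _normalized_rows,
    build_graph,
    graph_matrix,
    stack_graph_matrices,
)

__all__ = ["GraphKernelView", "WordFeatureView"]


class GraphKernelView:
    """Precomputed all-paths-kernel SVM view, keyed by sentence id."""

    name = "graph_kernel"

    def __init__(
        self,
        sentences: Mapping[str, AnnotatedSentence],
        cfg: KernelConfig | None = None,
        C: float = 1.0,
    ):
        self.cfg = cfg or KernelConfig()
        self.C = C
        self._registry: dict[tuple[str, str], int] = {}
        self._rows: dict[str, sparse.csr_matrix] = {}
        self._sentences = sentences

    def _row(self, sid: str) -> sparse.csr_matrix:
        if sid not in self._rows:
            gm = graph_matrix(build_graph(self._sentences[sid], self.cfg))
            X, self._registry = stack_graph_matrices([gm], self._registry)
            self._rows[sid] = X
        return self._rows[sid]

    def _matrix(self, ids: Sequence[str]) -> sparse.csr_matrix:
        rows = [self._row(i) for i in ids]
        width = max(len(self._registry), 1)
        out = []
        for r in rows:
            if r.shape[1] != width:
                r = r.copy()
                r.resize((1, width))
            out.append(r)
        X = sparse.vstack(out, format="csr")
        return _normalized_rows(X) if self.cfg.normalize else X

    def fit(self, ids: Sequence[str], labels: Sequence[int]):
        X = self._matrix(ids)
        K = (X @ X.T).toarray()
        model = train((K + K.T) / 2.0, labels, C=self.C, view="graph_kernel")
        return (model, ids)

    def score(self, model, ids: Sequence[str]) -> np.ndarray:
        kmodel, train_ids = model
        K = (self._matrix(ids) @ self._matrix(train_ids).T).toarray()
        return predict_scores(kmodel, K)


class WordFeatureView:
    """Linear SVM over sparse Boolean word-feature vectors."""

    name = "word_features"

    def __init__(
        self,
        sentences: Mapping[str, AnnotatedSentence],
        lists: WordLists | None = None,
        window: int = 3,
        C: float = 1.0,
    ):
        self.lists = lists or WordLists.default()
        self.window = window
        self.C = C
        self._sentences = sentences
        self._vectors = {
            sid: extract_features(s, self.lists, window)
            for sid, s in sentences.items()
        }
        self._vocab = fit_vocabulary(self._vectors.values())

    def _matrix(self, ids: Sequence[str]) -> sparse.csr_matrix:
        return vectorize_many([self._vectors[i] for i in ids], self._vocab)

    def fit(self, ids: Sequence[str], labels: Sequence[int]) -> KernelModel:
        return train(self._matrix(ids), labels, C=self.C, view="word_features")

    def score(self, model: KernelModel, ids: Sequence[str]) -> np.ndarray:
        return predict_scores(model, self._matrix(ids))
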