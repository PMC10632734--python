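"""Tissue-of-origin prediction from cell-line similarity networks.

A leave-one-out k-nearest-neighbor classifier over a cell-line similarity
network: each cell line is predicted from the majority tissue label of its K
most similar other cell lines, ties resolved by the single most similar
neighbor's label. Overall precision/recall/F1 are support-weighted means of
per-class scores; the baseline is a random classifier drawing labels from
the observed label multiset, averaged over many iterations.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import precision_recall_fscore_support
from sklearn.utils.validation import check_is_fitted


@dataclass
class LabeledNetwork:
    """Cell-line similarity network plus one tissue label per cell line."""

    weights: np.ndarray
    node_ids: list[str]
    labels: dict[str, str]

    def __post_init__(self) -> None:
        missing = [n for n in self.node_ids if n not in self.labels]
        if missing:
            raise ValueError(f"cell lines without a tissue label: {missing[:5]}")

    def label_array(self) -> np.ndarray:
        return np.array([self.labels[n] for n in self.node_ids])


class KnnTissueClassifier(BaseEstimator, ClassifierMixin):
    """Majority-vote kNN on a precomputed similarity network.

    ``fit`` takes the symmetric similarity matrix and the label vector;
    ``predict`` performs leave-one-out prediction over the fitted cell
    lines (each one predicted from all others). Neighbor ranking is by
    descending similarity with ties broken by node order; a voting tie goes
    to the label of the single highest-similarity neighbor.
    """

    def __init__(self, k: int = 5):
        self.k = k

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        n = X.shape[0]
        if X.shape != (n, n):
            raise ValueError("X must be a square similarity matrix")
        if len(y) != n:
            raise ValueError("one label per cell line required")
        if not 1 <= self.k < n:
            raise ValueError(f"k={self.k} out of range for {n} cell lines")
        self.similarity_ = X
        self.y_ = y
        self.classes_ = np.unique(y)
        return self

    def predict(self, X=None) -> np.ndarray:
        check_is_fitted(self, "similarity_")
        W, y, k = self.similarity_, self.y_, self.k
        n = W.shape[0]
        preds = []
        for i in range(n):
            w = W[i].copy()
            w[i] = -np.inf  # leave-one-out: self is never a neighbor
            order = np.argsort(-w, kind="stable")
            nb = order[:k]
            votes = Counter(y[j] for j in nb)
            top = votes.most_common()
            if len(top) > 1 and top[0][1] == top[1][1]:
                preds.append(y[nb[0]])  # tie: nearest neighbor decides
            else:
                preds.append(top[0][0])
        return np.array(preds)


def knn_predict(net: LabeledNetwork, k: int) -> np.ndarray:
    truth = net.label_array()
    return KnnTissueClassifier(k=k).fit(net.weights, truth).predict()


def weighted_prf(predictions, truth) -> dict:
    """Per-class and support-weighted overall precision/recall/F1.

    Classes with zero predicted positives receive precision 0.
    """
    predictions = np.asarray(predictions)
    truth = np.asarray(truth)
    classes = np.unique(np.concatenate([truth, predictions]))
    p, r, f, support = precision_recall_fscore_support(
        truth, predictions, labels=classes, zero_division=0)
    wp, wr, wf, _ = precision_recall_fscore_support(
        truth, predictions, labels=classes, average="weighted", zero_division=0)
    per_class = {
        str(c): {"precision": float(pi), "recall": float(ri), "f1": float(fi),
                 "support": int(si)}
        for c, pi, ri, fi, si in zip(classes, p, r, f, support)
    }
    return {"per_class": per_class,
            "weighted": {"precision": float(wp), "recall": float(wr),
                         "f1": float(wf)}}


def confusion_table(predictions, truth) -> pd.DataFrame:
    """Confusion matrix (true classes x predicted classes) with margins.

    The appended ``true_total`` row holds the per-class supports and the
    ``predicted_total`` column the per-class prediction counts.
    """
    predictions = np.asarray(predictions)
    truth = np.asarray(truth)
    classes = sorted(set(truth) | set(predictions))
    mat = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for t, pr in zip(truth, predictions):
        mat.loc[t, pr] += 1
    out = mat.copy()
    out["predicted_total"] = 0
    for c in classes:
        out.loc[c, "predicted_total"] = int((predictions == c).sum())
    top = {c: int((truth == c).sum()) for c in classes}
    top["predicted_total"] = len(truth)
    out = pd.concat([pd.DataFrame([top], index=["true_total"]), out])
    return out


def random_baseline(labels, iterations: int = 100, seed: int = 0) -> dict:
    """Random-classifier baseline: labels drawn uniformly from the observed
    label multiset; mean weighted precision/recall/F1 over iterations."""
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    scores = np.zeros((iterations, 3))
    for it in range(iterations):
        draw = rng.choice(labels, size=len(labels), replace=True)
        w = weighted_prf(draw, labels)["weighted"]
        scores[it] = (w["precision"], w["recall"], w["f1"])
    mean = scores.mean(axis=0)
    return {"precision": float(mean[0]), "recall": float(mean[1]),
            "f1": float(mean[2]), "iterations": iterations}


def read_labels_tsv(path) -> dict[str, str]:
    """Two-column TSV: cell_line_id <tab> tissue lineage."""
    labels: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 2 and parts[0] and parts[0] != "cell_line_id":
                labels[parts[0]] = parts[1]
    return labels


def write_labels_tsv(labels: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        fh.write("cell_line_id\tlineage\n")
        for cid in sorted(labels):
            fh.write(f"{cid}\t{labels[cid]}\n")
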