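"""Reporting: PCA embedding, feature-importance ranking, tree export,
and the standard figures (PCA scatter, importance bars, confusion matrix,
ROC curve, schematic connectivity graph)."""

from __future__ import annotations

from dataclasses import dataclass

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.preprocessing import MinMaxScaler
from sklearn.tree import DecisionTreeClassifier, export_text

from .channels import LAYOUT_2D
from .classify import LABEL_COLUMN, split_xy

#: Provenance families used for importance shares (Fig.-7-style report).
def feature_family(name: str) -> str:
    head = name.split("|")[0]
    if head == "qeeg":
        return "qEEG"
    if head == "wt":
        return "Wavelet"
    if head == "ae":
        return "Autoencoder"
    if head == "net":
        tail = name.split("|")[2]
        return {
            "deg": "Node Degree",
            "pathlen": "Path Length",
            "cc": "Clustering Coefficient",
        }.get(tail, "Network")
    return "Other"


@dataclass
class PCAEmbedding:
    coords: np.ndarray  # [subjects x 2]
    loadings: np.ndarray  # [2 x features]
    explained_variance_ratio: np.ndarray
    labels: pd.Series | None = None


def pca_2d(table: pd.DataFrame) -> PCAEmbedding:
    """First two principal components of the min-max-scaled feature table."""
    if LABEL_COLUMN in table.columns:
        X, y = split_xy(table)
    else:
        X, y = table, None
    if X.shape[0] < 3 or X.shape[1] < 2:
        raise ValueError("need at least 3 subjects and 2 features")
    Xs = MinMaxScaler().fit_transform(X.values)
    if np.allclose(Xs.var(axis=0), 0):
        raise ValueError("rank-0 input: all features constant")
    pca = PCA(n_components=2, svd_solver="full")
    coords = pca.fit_transform(Xs)
    return PCAEmbedding(
        coords=coords,
        loadings=pca.components_,
        explained_variance_ratio=pca.explained_variance_ratio_,
        labels=y,
    )


@dataclass
class FeatureRanking:
    ranked: list[tuple[str, float]]  # (name, F-score), descending
    family_shares: dict[str, float]  # percentages, sum to 100


def top_features(
    scores: dict[str, float], k: int = 20, restrict_to: list[str] | None = None
) -> FeatureRanking:
    """Top-k features by ANOVA F-score with provenance-family percentages."""
    names = restrict_to if restrict_to is not None else list(scores)
    if k > len(names):
        raise ValueError(f"k = {k} exceeds {len(names)} available features")
    ranked = sorted(names, key=lambda c: (-scores[c], c))[:k]
    shares: dict[str, float] = {}
    for name in ranked:
        fam = feature_family(name)
        shares[fam] = shares.get(fam, 0.0) + 100.0 / k
    return FeatureRanking(
        ranked=[(n, float(scores[n])) for n in ranked], family_shares=shares
    )


@dataclass
class TreeExport:
    text: str
    feature_names: list[str]
    nodes: dict  # flat arrays of the tree structure

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Apply the exported rules; reproduces the model's predictions."""
        X = np.asarray(X, dtype=float)
        out = []
        for row in X:
            node = 0
            while self.nodes["left"][node] != -1:
                f, thr = self.nodes["feature"][node], self.nodes["threshold"][node]
                node = (
                    self.nodes["left"][node]
                    if row[f] <= thr
                    else self.nodes["right"][node]
                )
            out.append(self.nodes["leaf_class"][node])
        return np.array(out)


def export_decision_tree(
    model: DecisionTreeClassifier, feature_names: list[str]
) -> TreeExport:
    """Textual rules plus a re-executable rule table for a fitted tree."""
    if not hasattr(model, "tree_"):
        raise ValueError("model is not a fitted decision tree")
    t = model.tree_
    leaf_class = [model.classes_[int(np.argmax(v))] for v in t.value[:, 0, :]]
    nodes = {
        "left": t.children_left.copy(),
        "right": t.children_right.copy(),
        "feature": t.feature.copy(),
        "threshold": t.threshold.copy(),
        "leaf_class": np.array(leaf_class),
    }
    text = export_text(model, feature_names=list(feature_names))
    return TreeExport(text=text, feature_names=list(feature_names), nodes=nodes)


# ---------------------------------------------------------------- figures


def plot_pca(emb: PCAEmbedding, path=None, ax=None):
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    if emb.labels is not None:
        for lab in sorted(emb.labels.unique()):
            m = (emb.labels == lab).values
            ax.scatter(emb.coords[m, 0], emb.coords[m, 1], label=lab, s=25)
        ax.legend(fontsize=8)
    else:
        ax.scatter(emb.coords[:, 0], emb.coords[:, 1], s=25)
    evr = emb.explained_variance_ratio
    ax.set_xlabel(f"PC1 ({evr[0]:.0%})")
    ax.set_ylabel(f"PC2 ({evr[1]:.0%})")
    if path:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_importance(ranking: FeatureRanking, path=None, ax=None):
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 0.3 * len(ranking.ranked) + 1))
    names = [n for n, _ in ranking.ranked][::-1]
    vals = [v for _, v in ranking.ranked][::-1]
    ax.barh(range(len(names)), vals)
    ax.set_yticks(range(len(names)), names, fontsize=7)
    ax.set_xlabel("ANOVA F-value")
    if path:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_confusion(cm: np.ndarray, classes: list[str], path=None, ax=None):
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3.5))
    ax.imshow(cm, cmap="Blues")
    ax.set_xticks(range(len(classes)), classes, rotation=45)
    ax.set_yticks(range(len(classes)), classes)
    for i in range(cm.shape[0]):
        for j in range(cm.shape[1]):
            ax.text(j, i, str(cm[i, j]), ha="center", va="center")
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    if path:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_roc(fpr: np.ndarray, tpr: np.ndarray, auc: float | None = None, path=None, ax=None):
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    label = f"AUC = {auc:.2f}" if auc is not None else None
    ax.plot(fpr, tpr, label=label)
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    if label:
        ax.legend()
    if path:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_network(
    W: np.ndarray, channel_names: list[str], path=None, ax=None, top_frac: float = 0.2
):
    """Schematic head-plot of the strongest connections (width ~ weight)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    pos = {
        ch: LAYOUT_2D.get(ch, (np.cos(2 * np.pi * i / len(channel_names)),
                               np.sin(2 * np.pi * i / len(channel_names))))
        for i, ch in enumerate(channel_names)
    }
    n = len(channel_names)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    pairs.sort(key=lambda p: -W[p[0], p[1]])
    keep = pairs[: max(1, int(top_frac * len(pairs)))]
    wmax = max(W[i, j] for i, j in keep) or 1.0
    for i, j in keep:
        xi, yi = pos[channel_names[i]]
        xj, yj = pos[channel_names[j]]
        ax.plot([xi, xj], [yi, yj], "b-", lw=2.5 * W[i, j] / wmax, alpha=0.6)
    for ch, (x, y) in pos.items():
        ax.plot(x, y, "ko", ms=4)
        ax.annotate(ch, (x, y), fontsize=6, ha="center", va="bottom")
    circle = plt.Circle((0, 0), 1.25, fill=False, color="gray", lw=0.8)
    ax.add_patch(circle)
    ax.set_xlim(-1.5, 1.5)
    ax.set_ylim(-1.5, 1.5)
    ax.set_aspect("equal")
    ax.axis("off")
    if path:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
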