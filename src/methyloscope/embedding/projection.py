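"""2-D projection of pooled embeddings and class-separation scoring."""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.manifold import TSNE
from sklearn.metrics import roc_auc_score, silhouette_score
from sklearn.model_selection import StratifiedKFold

from methyloscope.cgi import HIGH, UNMETHYLATED
from methyloscope.embedding.mlm import EmbeddingMatrix
from methyloscope.errors import ConfigError


def project_tsne(
    embeddings: EmbeddingMatrix,
    perplexity: float = 30.0,
    seed: int = 42,
    n_iter: int = 1000,
) -> np.ndarray:
    """t-SNE to 2-D; deterministic given the seed.  Requires n > 3*perplexity."""
    n = embeddings.vectors.shape[0]
    if n <= 3 * perplexity:
        raise ConfigError(
            f"n={n} too small for perplexity {perplexity}; "
            f"need n > 3*perplexity (lower the perplexity)"
        )
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        random_state=seed,
        max_iter=n_iter,
        init="pca",
    )
    coords = tsne.fit_transform(embeddings.vectors)
    return np.asarray(coords, dtype=float)


def class_separation(
    embeddings: EmbeddingMatrix,
    meth_classes: Mapping[str, str] | Sequence[str],
    n_folds: int = 5,
    seed: int = 0,
    min_class_size: int = 10,
) -> dict:
    """Silhouette + cross-validated linear-probe AUC, unmethylated vs high.

    The 'low' class is excluded from the binary score and reported
    separately; classes below ``min_class_size`` are skipped with a warning.
    """
    if isinstance(meth_classes, Mapping):
        labels = np.array([meth_classes[c] for c in embeddings.cgi_ids], dtype=object)
    else:
        labels = np.asarray(list(meth_classes), dtype=object)
        if labels.size != len(embeddings.cgi_ids):
            raise ConfigError("labels length mismatch")
    report: dict = {"class_counts": {}}
    for cls in sorted(set(labels.tolist())):
        report["class_counts"][cls] = int((labels == cls).sum())
    keep = np.isin(labels, (UNMETHYLATED, HIGH))
    for cls in (UNMETHYLATED, HIGH):
        if report["class_counts"].get(cls, 0) < min_class_size:
            warnings.warn(f"class {cls!r} below {min_class_size} members; skipped")
            return {**report, "silhouette": None, "auc": None}
    X = embeddings.vectors[keep]
    y = (labels[keep] == HIGH).astype(int)
    report["silhouette"] = float(silhouette_score(X, y))
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    scores = np.zeros(len(y))
    for train, test in skf.split(X, y):
        probe = LogisticRegression(max_iter=2000)
        probe.fit(X[train], y[train])
        scores[test] = probe.predict_proba(X[test])[:, 1]
    report["auc"] = float(roc_auc_score(y, scores))
    return report
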