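"""Decontamination quality metrics.

Positive / Negative / Combined scores measure whether annotated native
cell-type markers stay detectable in their own clusters while
non-native markers are removed; silhouette-width deltas on
CLR-normalized counts measure whether decontamination sharpens
clustering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.metrics import silhouette_samples


@dataclass
class MarkerAnnotation:
    """Per-cluster native and non-native ADT marker lists."""

    native: dict
    non_native: dict

    def __post_init__(self) -> None:
        for k in set(self.native) & set(self.non_native):
            overlap = set(self.native[k]) & set(self.non_native[k])
            if overlap:
                raise ValueError(
                    f"cluster {k!r}: markers both native and non-native: "
                    f"{sorted(overlap)}"
                )

    def validate_features(self, feature_names) -> None:
        names = set(map(str, feature_names))
        missing = sorted(
            {
                m
                for table in (self.native, self.non_native)
                for ms in table.values()
                for m in ms
            }
            - names
        )
        if missing:
            raise KeyError(f"markers absent from matrix: {missing}")

    @classmethod
    def from_tsv(cls, path: str) -> "MarkerAnnotation":
        """Read a TSV with columns cluster, native, non_native
        (comma-separated marker lists)."""
        tab = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        split = lambda s: [m for m in str(s).split(",") if m]
        native = {r["cluster"]: split(r["native"]) for _, r in tab.iterrows()}
        non_native = {
            r["cluster"]: split(r["non_native"]) for _, r in tab.iterrows()
        }
        return cls(native=native, non_native=non_native)


@dataclass
class ScoreReport:
    """Positive/Negative/Combined decontamination scores (0-100 scale)."""

    positive: float
    negative: float
    combined: float
    per_cluster: pd.DataFrame
    detection_threshold: float

    def to_dict(self) -> dict:
        return {
            "positive": self.positive,
            "negative": self.negative,
            "combined": self.combined,
            "detection_threshold": self.detection_threshold,
        }


def _dense(X) -> np.ndarray:
    from .io import CountMatrix

    if isinstance(X, CountMatrix):
        return X.dense().astype(float)
    if sp.issparse(X):
        return np.asarray(X.todense(), dtype=float)
    return np.asarray(X, dtype=float)


def detection(X, threshold: float = 1.0) -> np.ndarray:
    """Boolean detection matrix: entry true iff value > threshold
    (strictly greater)."""
    return _dense(X) > threshold


def _score(X, labels, marker_table: dict, feature_names, threshold: float):
    """Average detection percentage over (cluster, marker) pairs, with
    equal weight per pair within a cluster and per cluster overall."""
    x = _dense(X)
    labels = np.asarray(labels)
    names = [str(n) for n in feature_names]
    col = {n: j for j, n in enumerate(names)}
    det = x > threshold
    cluster_means = []
    rows = []
    for clust, markers in marker_table.items():
        if not markers:
            continue
        mask = labels == clust
        if not mask.any():
            raise KeyError(f"cluster {clust!r} has no droplets")
        missing = [m for m in markers if m not in col]
        if missing:
            raise KeyError(f"markers absent from matrix: {missing}")
        pcts = [100.0 * det[mask, col[m]].mean() for m in markers]
        for m, p in zip(markers, pcts):
            rows.append({"cluster": clust, "marker": m, "pct_detected": p})
        cluster_means.append(float(np.mean(pcts)))
    if not cluster_means:
        raise ValueError("annotation covers no cluster")
    return float(np.mean(cluster_means)), pd.DataFrame(rows)


def positive_score(X, labels, ann: MarkerAnnotation, threshold: float = 1.0) -> float:
    """Percent of cells with detectable native markers in their own
    cluster (higher is better)."""
    return _score(X, labels, ann.native, _feature_names(X), threshold)[0]


def negative_score(X, labels, ann: MarkerAnnotation, threshold: float = 1.0) -> float:
    """Percent of cells with detectable non-native (contaminating)
    markers (lower is better)."""
    return _score(X, labels, ann.non_native, _feature_names(X), threshold)[0]


def _feature_names(X):
    from .io import CountMatrix

    if isinstance(X, CountMatrix):
        return X.feature_names
    raise TypeError(
        "pass feature names explicitly via combined_score(..., "
        "feature_names=...) for plain arrays"
    )


def combined_score(
    X, labels, ann: MarkerAnnotation, threshold: float = 1.0, feature_names=None
) -> ScoreReport:
    """Positive minus Negative score, with per-(cluster, marker) detail."""
    if feature_names is None:
        feature_names = _feature_names(X)
    pos, pos_tab = _score(X, labels, ann.native, feature_names, threshold)
    neg, neg_tab = _score(X, labels, ann.non_native, feature_names, threshold)
    pos_tab["kind"] = "native"
    neg_tab["kind"] = "non_native"
    return ScoreReport(
        positive=pos,
        negative=neg,
        combined=pos - neg,
        per_cluster=pd.concat([pos_tab, neg_tab], ignore_index=True),
        detection_threshold=threshold,
    )


def clr_normalize(X) -> np.ndarray:
    """Centered log-ratio transform per droplet.

    ``log1p`` of each count minus the droplet's mean ``log1p`` across
    ADTs; rows of the output sum to zero.
    """
    x = _dense(X)
    if (x < 0).any():
        raise ValueError("CLR requires non-negative input")
    logged = np.log1p(x)
    return logged - logged.mean(axis=1, keepdims=True)


class CLRNormalizer(TransformerMixin, BaseEstimator):
    """Stateless sklearn transformer applying :func:`clr_normalize`."""

    def fit(self, X, y=None):
        self.n_features_in_ = _dense(X).shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        return clr_normalize(X)


def silhouette_delta(
    before, after, labels, *, clr: bool = True, n_pca: int | None = None
) -> tuple[pd.DataFrame, float]:
    """Per-cluster mean silhouette widths before/after decontamination.

    Both matrices are CLR-normalized (unless ``clr=False``) and
    silhouettes computed on Euclidean distances; ``n_pca`` optionally
    projects to that many principal components first. Singleton
    clusters have undefined widths and are flagged NaN.

    Returns the per-cluster table and the dataset mean delta.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette requires >= 2 clusters")

    def widths(X):
        x = clr_normalize(X) if clr else _dense(X)
        if n_pca is not None:
            from sklearn.decomposition import PCA

            x = PCA(n_components=n_pca).fit_transform(x)
        s = silhouette_samples(x, labels)
        out = {}
        for c in np.unique(labels):
            mask = labels == c
            out[c] = float(s[mask].mean()) if mask.sum() > 1 else float("nan")
        return out

    wb, wa = widths(before), widths(after)
    rows = [
        {
            "cluster": c,
            "before": wb[c],
            "after": wa[c],
            "delta": wa[c] - wb[c],
            "singleton": np.isnan(wb[c]),
        }
        for c in wb
    ]
    tab = pd.DataFrame(rows)
    mean_delta = float(tab["delta"].dropna().mean())
    return tab, mean_delta
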