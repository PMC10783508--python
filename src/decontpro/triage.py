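"""Exploratory triage of raw droplets in CITE-seq data.

Droplet barcodes present in the raw matrix but absent from the
cell-calling (filtered) matrix are treated as empty. Clustering the
empty droplets on their log ADT / RNA library sizes typically reveals
three populations: "mislabeled cells" (high ADT, low RNA — e.g. low-RNA
neutrophils missed by RNA-based cell calling), "spongelets" (medium,
non-specific ADT levels), and true ambient droplets (low everything).
The normalized ADT profile of each class, and of the background peak of
true cells, characterizes the contamination sources the decontamination
model removes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans

from .io import CountMatrix

CLASS_CELL = "cell"
CLASS_MISLABELED = "mislabeled_cell"
CLASS_SPONGELET = "spongelet"
CLASS_AMBIENT = "ambient"

# empty-droplet classes ordered by descending mean ADT library size
_EMPTY_CLASSES = [CLASS_MISLABELED, CLASS_SPONGELET, CLASS_AMBIENT]


class AlignmentError(ValueError):
    """Barcode axes of two matrices do not match."""


class DegenerateProfileError(ValueError):
    """A profile was requested over droplets with zero total counts."""


@dataclass
class LibrarySizes:
    """Per-droplet ADT and RNA total counts."""

    adt_total: np.ndarray
    rna_total: np.ndarray

    def __post_init__(self) -> None:
        self.adt_total = np.asarray(self.adt_total)
        self.rna_total = np.asarray(self.rna_total)
        if self.adt_total.shape != self.rna_total.shape:
            raise AlignmentError("adt_total and rna_total lengths differ")
        if (self.adt_total < 0).any() or (self.rna_total < 0).any():
            raise ValueError("library sizes must be non-negative")


@dataclass
class TriageResult:
    """Per-droplet empty/cell status and empty-droplet class labels."""

    empty_mask: np.ndarray
    class_label: np.ndarray
    class_profiles: dict
    class_stats: pd.DataFrame

    def labels_for(self, cls: str) -> np.ndarray:
        return np.where(self.class_label == cls)[0]


def library_sizes(adt: CountMatrix, rna: CountMatrix) -> LibrarySizes:
    """Sum ADT and RNA counts per droplet.

    Matrices must share the same barcode axis in the same order.
    """
    if adt.n_droplets != rna.n_droplets or not np.array_equal(
        adt.barcodes, rna.barcodes
    ):
        raise AlignmentError("ADT and RNA matrices have mismatched barcodes")
    return LibrarySizes(adt.library_sizes(), rna.library_sizes())


def identify_empties(
    raw_barcodes,
    filtered_barcodes,
    totals: np.ndarray | None = None,
    *,
    strip_suffix: bool = False,
) -> tuple[np.ndarray, np.ndarray, list]:
    """Split raw droplets into cells and empties.

    A raw barcode absent from the filtered (cell-called) matrix is an
    empty droplet. Droplets with zero ADT+RNA total (``totals``) are
    excluded from both sets. Barcodes are matched as exact strings
    including any ``-1``-style gem-group suffix; ``strip_suffix=True``
    drops a trailing ``-<digits>`` on both sides before matching (for
    joining files from pipelines that disagree about the suffix).

    Returns
    -------
    empty_mask, keep_mask, missing
        Boolean masks over the raw barcodes, plus the list of filtered
        barcodes that were not found in the raw matrix (these are
        reported, not fatal).
    """
    raw_barcodes = np.asarray(raw_barcodes, dtype=object)
    if strip_suffix:
        strip = lambda b: re.sub(r"-\d+$", "", str(b))
        raw_barcodes = np.array([strip(b) for b in raw_barcodes], dtype=object)
        filtered_barcodes = [strip(b) for b in filtered_barcodes]
    filtered = set(filtered_barcodes)
    missing = sorted(filtered - set(raw_barcodes))
    in_filtered = np.array([b in filtered for b in raw_barcodes], dtype=bool)
    if totals is None:
        keep = np.ones(len(raw_barcodes), dtype=bool)
    else:
        keep = np.asarray(totals) > 0
    empty_mask = keep & ~in_filtered
    return empty_mask, keep, missing


def normalized_profile(adt: CountMatrix, subset_mask) -> np.ndarray:
    """Fraction of total ADT counts per ADT across a droplet subset.

    Sums each ADT over the selected droplets and divides by the subset's
    grand total, yielding a point on the simplex.
    """
    subset_mask = np.asarray(subset_mask)
    sub = adt.counts[subset_mask] if subset_mask.dtype == bool else adt.counts[subset_mask]
    per_adt = np.asarray(sub.sum(axis=0)).ravel().astype(float)
    total = per_adt.sum()
    if total <= 0:
        raise DegenerateProfileError("selected droplets have zero total counts")
    return per_adt / total


def profile_correlation(p: np.ndarray, q: np.ndarray) -> float:
    """Pearson correlation of two ADT profiles."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape or p.size < 3:
        raise ValueError("profiles must have equal length >= 3")
    if np.ptp(p) == 0 or np.ptp(q) == 0:
        raise ValueError("correlation undefined for a constant profile")
    return float(scipy.stats.pearsonr(p, q)[0])


class EmptyDropletTriage(ClusterMixin, BaseEstimator):
    """Cluster empty droplets by library size into triage classes.

    K-means (``n_clusters`` groups, default 3) on the ``log10(x + 1)``
    ADT and RNA library sizes of the empty droplets. The two features
    are used on their common decades scale without per-feature
    standardization: rescaling an uninformative axis to unit variance
    would let its noise dominate the clustering when one modality
    carries all the separation.
    Clusters are named by descending mean ADT library size:
    ``mislabeled_cell`` > ``spongelet`` > ``ambient``. The cell class is
    taken from the filtered barcode set, not from k-means.

    Parameters
    ----------
    n_clusters : int
        Number of empty-droplet clusters (the triage naming scheme
        expects 3; other values yield ``empty_0``, ``empty_1``, ... by
        descending mean ADT total).
    n_init : int
        K-means restarts.
    random_state : int or None
        Seed for k-means.

    Attributes
    ----------
    labels_ : ndarray of str
        Class label per droplet passed to :meth:`fit`.
    cluster_order_ : ndarray
        K-means cluster indices sorted by descending mean ADT total.
    """

    def __init__(self, n_clusters: int = 3, n_init: int = 10, random_state=None):
        self.n_clusters = n_clusters
        self.n_init = n_init
        self.random_state = random_state

    def fit(self, lib: LibrarySizes, empty_mask: np.ndarray):
        empty_mask = np.asarray(empty_mask, dtype=bool)
        n_empty = int(empty_mask.sum())
        if n_empty < self.n_clusters:
            raise ValueError(
                f"{n_empty} empty droplets < n_clusters={self.n_clusters}"
            )
        feats = np.column_stack(
            [
                np.log10(lib.adt_total[empty_mask] + 1.0),
                np.log10(lib.rna_total[empty_mask] + 1.0),
            ]
        )
        km = KMeans(
            n_clusters=self.n_clusters,
            n_init=self.n_init,
            random_state=self.random_state,
        ).fit(feats)
        mean_adt = np.array(
            [
                lib.adt_total[empty_mask][km.labels_ == c].mean()
                for c in range(self.n_clusters)
            ]
        )
        # descending mean ADT; ties broken by lower cluster index
        order = np.lexsort((np.arange(self.n_clusters), -mean_adt))
        if self.n_clusters == 3:
            names = _EMPTY_CLASSES
        else:
            names = [f"empty_{r}" for r in range(self.n_clusters)]
        rank_of = np.empty(self.n_clusters, dtype=int)
        rank_of[order] = np.arange(self.n_clusters)
        empty_names = np.array([names[rank_of[c]] for c in km.labels_], dtype=object)
        labels = np.full(len(empty_mask), CLASS_CELL, dtype=object)
        labels[empty_mask] = empty_names
        self.labels_ = labels
        self.cluster_order_ = order
        self.kmeans_ = km
        return self

    def fit_predict(self, lib: LibrarySizes, empty_mask: np.ndarray) -> np.ndarray:
        return self.fit(lib, empty_mask).labels_


def cluster_empties(
    lib: LibrarySizes,
    empty_mask: np.ndarray,
    adt: CountMatrix,
    k: int = 3,
    seed: int | None = None,
    keep_mask: np.ndarray | None = None,
) -> TriageResult:
    """Classify empty droplets and summarize each triage class.

    Thin wrapper around :class:`EmptyDropletTriage` that also computes
    per-class normalized ADT profiles and droplet statistics. Droplets
    where ``keep_mask`` is false (zero-total droplets) are labeled
    ``excluded`` and ignored in profiles and stats.
    """
    empty_mask = np.asarray(empty_mask, dtype=bool)
    labels = EmptyDropletTriage(n_clusters=k, random_state=seed).fit_predict(
        lib, empty_mask
    )
    if keep_mask is not None:
        labels = labels.copy()
        labels[~np.asarray(keep_mask, dtype=bool)] = "excluded"
    profiles = {}
    rows = []
    for cls in [CLASS_CELL] + (
        _EMPTY_CLASSES if k == 3 else [f"empty_{r}" for r in range(k)]
    ):
        mask = labels == cls
        n = int(mask.sum())
        mean_adt = float(lib.adt_total[mask].mean()) if n else float("nan")
        rows.append({"class": cls, "n_droplets": n, "mean_adt_total": mean_adt})
        if n:
            try:
                profiles[cls] = normalized_profile(adt, mask)
            except DegenerateProfileError:
                pass
    stats = pd.DataFrame(rows)
    return TriageResult(empty_mask, labels, profiles, stats)


def _kde_valley_cutoff(counts_j: np.ndarray) -> float:
    """Auto background cutoff for one ADT: the deepest density minimum
    between the two highest modes of log1p(count); global median when
    the density is unimodal. Returned on the raw count scale."""
    y = np.log1p(counts_j.astype(float))
    if np.ptp(y) == 0:
        return float(np.expm1(y[0]))
    kde = scipy.stats.gaussian_kde(y)  # Scott's rule bandwidth
    grid = np.linspace(y.min(), y.max(), 512)
    dens = kde(grid)
    # interior local maxima/minima
    up = np.r_[False, dens[1:] > dens[:-1]]
    down = np.r_[dens[:-1] > dens[1:], False]
    maxima = np.where(up & down)[0]
    if len(maxima) < 2:
        return float(np.median(counts_j))
    top2 = maxima[np.argsort(dens[maxima])[-2:]]
    lo, hi = sorted(top2)
    between = slice(lo, hi + 1)
    valley = lo + int(np.argmin(dens[between]))
    return float(np.expm1(grid[valley]))


def background_peak_profile(
    adt_cells: CountMatrix, cutoffs=None
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized profile of the background peak of cell droplets.

    Only counts ``x_ij <= cutoff_j`` contribute. ``cutoffs`` is one
    per-ADT threshold (manual curation of the background peaks); when
    omitted, each cutoff is placed automatically at the deepest
    kernel-density valley between the two highest modes of
    ``log1p(count)`` (an extension to the manual curation, flagged in
    reports). Returns ``(profile, cutoffs)``.
    """
    X = adt_cells.dense()
    J = X.shape[1]
    if cutoffs is None:
        cutoffs = np.array([_kde_valley_cutoff(X[:, j]) for j in range(J)])
    else:
        cutoffs = np.asarray(cutoffs, dtype=float)
        if cutoffs.shape != (J,):
            raise ValueError(f"expected {J} cutoffs, got {cutoffs.shape}")
    masked = np.where(X <= cutoffs[None, :], X, 0)
    per_adt = masked.sum(axis=0).astype(float)
    total = per_adt.sum()
    if total <= 0:
        raise DegenerateProfileError("no counts fall inside the background peaks")
    return per_adt / total, cutoffs


DEFAULT_EXCLUDE_PATTERNS = ("HTO", "Hashtag", "isotype", "IgG")


class EmptyFilterResult(ValueError):
    """All droplets were removed by the preprocessing filters."""


def filter_cell_droplets(
    adt: CountMatrix,
    rna: CountMatrix,
    low_q: float = 0.01,
    high_q: float = 0.99,
    mito_max: float = 0.15,
    exclude_patterns=DEFAULT_EXCLUDE_PATTERNS,
) -> tuple[CountMatrix, CountMatrix, pd.DataFrame]:
    """Preprocess cell droplets before model fitting.

    Stages, in order: (1) drop hashing/isotype ADT features whose name
    matches any of ``exclude_patterns`` (case-insensitive substring);
    (2) drop droplets outside the [``low_q``, ``high_q``] quantiles of
    either modality's library size (inclusive bounds, linear empirical
    quantiles); (3) drop droplets whose mitochondrial fraction of RNA
    counts (genes with an ``MT-``/``mt-`` name prefix) is >= ``mito_max``.

    Returns the filtered (ADT, RNA) pair and a per-stage removal report.
    """
    if adt.n_droplets != rna.n_droplets or not np.array_equal(
        adt.barcodes, rna.barcodes
    ):
        raise AlignmentError("ADT and RNA matrices have mismatched barcodes")
    report = []
    if exclude_patterns:
        pat = re.compile("|".join(re.escape(p) for p in exclude_patterns), re.I)
        drop = np.array(
            [bool(pat.search(str(n))) for n in adt.feature_names], dtype=bool
        )
    else:
        drop = np.zeros(adt.n_features, dtype=bool)
    adt = adt.subset_features(~drop)
    report.append({"stage": "exclude_features", "removed": int(drop.sum())})
    if adt.n_features == 0:
        raise EmptyFilterResult(f"no ADT features left; report={report}")

    keep = np.ones(adt.n_droplets, dtype=bool)
    for lib in (adt.library_sizes(), rna.library_sizes()):
        lo = np.quantile(lib, low_q)
        hi = np.quantile(lib, high_q)
        keep &= (lib >= lo) & (lib <= hi)
    report.append({"stage": "library_quantiles", "removed": int((~keep).sum())})

    mito = np.array(
        [str(n).startswith(("MT-", "mt-")) for n in rna.feature_names], dtype=bool
    )
    rna_tot = rna.library_sizes().astype(float)
    mito_tot = np.asarray(rna.counts[:, mito].sum(axis=1)).ravel().astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(rna_tot > 0, mito_tot / np.maximum(rna_tot, 1), 0.0)
    mito_pass = frac < mito_max
    report.append(
        {"stage": "mito_fraction", "removed": int((keep & ~mito_pass).sum())}
    )
    keep &= mito_pass
    if not keep.any():
        raise EmptyFilterResult(f"all droplets removed; report={report}")
    return (
        adt.subset_droplets(keep),
        rna.subset_droplets(keep),
        pd.DataFrame(report),
    )
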