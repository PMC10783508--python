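"""Reading and writing droplet x feature count matrices.

Supports the CellRanger Matrix Market triplet layout (matrix.mtx[.gz] with
features.tsv[.gz] / barcodes.tsv[.gz] sidecars) and the 10x HDF5 matrix
layout. Matrices are held as a :class:`CountMatrix`: a sparse non-negative
integer matrix with droplets as rows and features as columns, plus barcode
and feature metadata.
"""

from __future__ import annotations

import gzip
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

GENE_EXPRESSION = "Gene Expression"
ANTIBODY_CAPTURE = "Antibody Capture"


class FormatError(ValueError):
    """A file does not follow the expected on-disk layout."""


class DimensionError(ValueError):
    """Matrix dimensions disagree with sidecar metadata."""


@dataclass
class CountMatrix:
    """Droplets x features integer count matrix with axis metadata.

    Parameters
    ----------
    counts
        Sparse CSR matrix of shape (n_droplets, n_features), integer dtype.
    barcodes
        Droplet identifiers, unique, length ``counts.shape[0]``.
    feature_names
        Feature identifiers, length ``counts.shape[1]``.
    feature_types
        Modality tag per feature (e.g. ``"Gene Expression"``,
        ``"Antibody Capture"``).
    feature_ids
        Optional stable feature ids (e.g. Ensembl ids); defaults to names.
    """

    counts: sp.csr_matrix
    barcodes: np.ndarray
    feature_names: np.ndarray
    feature_types: np.ndarray
    feature_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if not np.issubdtype(self.counts.dtype, np.integer):
            data = self.counts.data
            if data.size and not np.allclose(data, np.round(data)):
                raise ValueError("counts must be integer-valued")
            self.counts = self.counts.astype(np.int64)
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be non-negative")
        self.barcodes = np.asarray(self.barcodes, dtype=object)
        self.feature_names = np.asarray(self.feature_names, dtype=object)
        self.feature_types = np.asarray(self.feature_types, dtype=object)
        if self.feature_ids is None:
            self.feature_ids = self.feature_names.copy()
        else:
            self.feature_ids = np.asarray(self.feature_ids, dtype=object)
        n, m = self.counts.shape
        if len(self.barcodes) != n:
            raise DimensionError(
                f"{len(self.barcodes)} barcodes for {n} matrix rows"
            )
        if len(self.feature_names) != m or len(self.feature_types) != m:
            raise DimensionError(
                f"{len(self.feature_names)} feature names / "
                f"{len(self.feature_types)} types for {m} matrix columns"
            )
        if len(set(self.barcodes)) != n:
            raise ValueError("barcodes are not unique")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    @property
    def n_droplets(self) -> int:
        return self.counts.shape[0]

    @property
    def n_features(self) -> int:
        return self.counts.shape[1]

    def dense(self) -> np.ndarray:
        return np.asarray(self.counts.todense())

    def subset_droplets(self, mask_or_idx) -> "CountMatrix":
        idx = np.asarray(mask_or_idx)
        return CountMatrix(
            self.counts[idx],
            self.barcodes[idx],
            self.feature_names,
            self.feature_types,
            self.feature_ids,
        )

    def subset_features(self, mask_or_idx) -> "CountMatrix":
        idx = np.asarray(mask_or_idx)
        return CountMatrix(
            self.counts[:, idx],
            self.barcodes,
            self.feature_names[idx],
            self.feature_types[idx],
            self.feature_ids[idx],
        )

    def library_sizes(self) -> np.ndarray:
        """Per-droplet total counts (integer row sums)."""
        return np.asarray(self.counts.sum(axis=1)).ravel().astype(np.int64)


def _read_lines(path: str) -> list[str]:
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        return [line.rstrip("\n") for line in fh if line.strip()]


def _read_features_table(features_path: str) -> pd.DataFrame:
    tab = pd.read_csv(
        features_path, sep="\t", header=None, dtype=str, comment=None
    )
    if tab.shape[1] == 1:
        # genes.tsv from older pipelines: id only
        tab[1] = tab[0]
    if tab.shape[1] < 3:
        tab[2] = GENE_EXPRESSION
    return tab


def read_mtx_triplet(
    matrix_path: str,
    features_path: str,
    barcodes_path: str,
    *,
    features_as_rows: bool = True,
) -> CountMatrix:
    """Read a CellRanger-style Matrix Market triplet directory.

    In the CellRanger dialect MTX rows are features and columns are
    barcodes; the matrix is transposed on load so droplets are rows.
    Set ``features_as_rows=False`` for exports that already store
    droplets as MTX rows.
    """
    try:
        mat = scipy.io.mmread(str(matrix_path))
    except ValueError as exc:
        raise FormatError(f"malformed Matrix Market file {matrix_path}: {exc}") from exc
    mat = sp.coo_matrix(mat)
    if features_as_rows:
        mat = mat.T
    mat = sp.csr_matrix(mat)
    features = _read_features_table(features_path)
    barcodes = np.array(_read_lines(barcodes_path), dtype=object)
    # barcodes files may carry extra columns
    barcodes = np.array([b.split("\t")[0] for b in barcodes], dtype=object)
    if mat.shape[1] != len(features):
        raise DimensionError(
            f"matrix has {mat.shape[1]} features but {features_path} lists "
            f"{len(features)}"
        )
    if mat.shape[0] != len(barcodes):
        raise DimensionError(
            f"matrix has {mat.shape[0]} barcodes but {barcodes_path} lists "
            f"{len(barcodes)}"
        )
    return CountMatrix(
        mat,
        barcodes,
        features[1].to_numpy(dtype=object),
        features[2].to_numpy(dtype=object),
        features[0].to_numpy(dtype=object),
    )


def write_matrix(cm: CountMatrix, out_dir: str) -> None:
    """Write ``cm`` as a CellRanger-style triplet directory (uncompressed)."""
    os.makedirs(out_dir, exist_ok=True)
    scipy.io.mmwrite(
        os.path.join(out_dir, "matrix.mtx"), sp.coo_matrix(cm.counts.T)
    )
    feat = pd.DataFrame(
        {0: cm.feature_ids, 1: cm.feature_names, 2: cm.feature_types}
    )
    feat.to_csv(
        os.path.join(out_dir, "features.tsv"), sep="\t", header=False, index=False
    )
    pd.Series(cm.barcodes).to_csv(
        os.path.join(out_dir, "barcodes.tsv"), sep="\t", header=False, index=False
    )


def read_matrix_dir(path: str, **kwargs) -> CountMatrix:
    """Read a triplet directory, accepting gzipped or plain sidecars."""

    def pick(stem: str) -> str:
        for name in (stem, stem + ".gz"):
            cand = os.path.join(path, name)
            if os.path.exists(cand):
                return cand
        raise FileNotFoundError(f"no {stem}[.gz] in {path}")

    try:
        features = pick("features.tsv")
    except FileNotFoundError:
        features = pick("genes.tsv")
    return read_mtx_triplet(pick("matrix.mtx"), features, pick("barcodes.tsv"), **kwargs)


def read_10x_h5(path: str) -> CountMatrix:
    """Read a 10x HDF5 matrix file (CellRanger >= 3 layout).

    The file holds one ``matrix`` group with CSC arrays (features x
    barcodes) and a ``features`` subgroup with ``name`` / ``feature_type``
    datasets; the result is transposed so droplets are rows.
    """
    import h5py

    with h5py.File(path, "r") as fh:
        if "matrix" not in fh:
            raise FormatError(f"{path}: missing group 'matrix'")
        grp = fh["matrix"]
        for key in ("data", "indices", "indptr", "shape", "barcodes", "features"):
            if key not in grp:
                raise FormatError(f"{path}: missing dataset 'matrix/{key}'")
        feats = grp["features"]
        for key in ("name", "feature_type"):
            if key not in feats:
                raise FormatError(f"{path}: missing dataset 'matrix/features/{key}'")
        shape = tuple(grp["shape"][:])  # (n_features, n_barcodes)
        mat = sp.csc_matrix(
            (grp["data"][:], grp["indices"][:], grp["indptr"][:]), shape=shape
        )
        barcodes = np.array([b.decode() for b in grp["barcodes"][:]], dtype=object)
        names = np.array([n.decode() for n in feats["name"][:]], dtype=object)
        types = np.array([t.decode() for t in feats["feature_type"][:]], dtype=object)
        if "id" in feats:
            ids = np.array([i.decode() for i in feats["id"][:]], dtype=object)
        else:
            ids = names.copy()
    return CountMatrix(sp.csr_matrix(mat.T), barcodes, names, types, ids)


def write_10x_h5(cm: CountMatrix, path: str) -> None:
    """Write ``cm`` in the 10x HDF5 matrix layout (features x barcodes CSC)."""
    import h5py

    mat = sp.csc_matrix(cm.counts.T)
    with h5py.File(path, "w") as fh:
        grp = fh.create_group("matrix")
        grp.create_dataset("data", data=mat.data)
        grp.create_dataset("indices", data=mat.indices)
        grp.create_dataset("indptr", data=mat.indptr)
        grp.create_dataset("shape", data=np.array(mat.shape, dtype=np.int64))
        grp.create_dataset(
            "barcodes", data=np.array([str(b).encode() for b in cm.barcodes])
        )
        feats = grp.create_group("features")
        feats.create_dataset(
            "id", data=np.array([str(i).encode() for i in cm.feature_ids])
        )
        feats.create_dataset(
            "name", data=np.array([str(n).encode() for n in cm.feature_names])
        )
        feats.create_dataset(
            "feature_type",
            data=np.array([str(t).encode() for t in cm.feature_types]),
        )


class EmptyModalityError(ValueError):
    """Requested modality has no features in the matrix."""


def split_modalities(cm: CountMatrix) -> tuple[CountMatrix, CountMatrix]:
    """Split a multimodal matrix into (ADT, RNA) parts.

    ADT columns are those tagged ``"Antibody Capture"``; RNA columns those
    tagged ``"Gene Expression"``. Barcodes are shared and stay aligned.
    """
    types = np.asarray(cm.feature_types)
    adt_mask = types == ANTIBODY_CAPTURE
    rna_mask = types == GENE_EXPRESSION
    if not adt_mask.any():
        raise EmptyModalityError("no 'Antibody Capture' features in matrix")
    if not rna_mask.any():
        raise EmptyModalityError("no 'Gene Expression' features in matrix")
    return cm.subset_features(adt_mask), cm.subset_features(rna_mask)


def write_decomposition(decomp, out_dir: str, barcodes=None, feature_names=None) -> None:
    """Write a three-way count decomposition to ``out_dir``.

    Emits ``native.mtx``, ``ambient.mtx``, ``background.mtx`` (droplets as
    MTX columns, matching the CellRanger orientation) and a
    ``fractions.csv`` with one row per droplet giving the share of its
    library attributed to each source.
    """
    os.makedirs(out_dir, exist_ok=True)
    for name in ("native", "ambient", "background"):
        arr = getattr(decomp, name)
        scipy.io.mmwrite(os.path.join(out_dir, f"{name}.mtx"), sp.coo_matrix(arr.T))
    frac = decomp.fractions
    df = pd.DataFrame(
        frac, columns=["native", "ambient", "background"]
    )
    if barcodes is not None:
        df.insert(0, "barcode", list(barcodes))
    df.to_csv(os.path.join(out_dir, "fractions.csv"), index=False)
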