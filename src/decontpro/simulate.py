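"""Generative simulator for ADT count data with known ground truth.

Counts are generated from the same hierarchical process the
decontamination model assumes: each droplet's expected count rate is a
three-way mixture of a native cell-type profile, the ambient profile,
and a flat per-entry background rate. Emitting the three Poisson
components separately (their sum is distributionally identical to one
Poisson at the summed rate) yields an exact ground-truth split of every
count, which recovery and scoring tests consume directly.

`simulate_raw` additionally emulates a full raw droplet matrix with the
four droplet populations seen in real CITE-seq runs: cells, high-ADT /
low-RNA mislabeled cells, medium-ADT spongelets, and low-ADT ambient
droplets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats

from .io import ANTIBODY_CAPTURE, GENE_EXPRESSION, CountMatrix


def _truncnorm(rng, mean, sd, lo, hi, size):
    mean = np.broadcast_to(mean, size)
    a = (lo - mean) / sd
    b = (hi - mean) / sd
    draw = scipy.stats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng)
    return np.asarray(draw).reshape(size)


@dataclass
class SimConfig:
    """Study conditions for the generative process.

    Defaults emulate a mid-size CITE-seq ADT panel: per-droplet ambient
    contamination averaging ~5% of counts, per-entry background rates
    averaging 0.25% (~5% of a droplet's counts summed over the default
    20-ADT panel, since background accrues per ADT), and log-normal ADT
    library sizes centred near 3000 counts — a regime whose median
    native fraction lands near 90%.
    """

    I: int = 2000
    J: int = 20
    K: int = 4
    lib_size_law: tuple = (np.log(3000.0), 0.4)  # log-normal (meanlog, sdlog)
    delta_law: tuple = (2.0, 38.0)  # Beta on (0,1): mean 0.05
    mu_law: tuple = (2.0, 398.0)  # Beta scaled to (0,0.5): mean 0.0025
    tau1: float = 2e-5
    tau2: float = 2e-6
    beta_upper: float = 0.5
    phi_concentration: float = 1.0
    eta_concentration: float = 1.0
    phi: np.ndarray | None = None  # fixed native profiles override the draw
    # raw-matrix emulation: class -> (n_droplets, mean ADT total).
    # Class ADT means and the strong spongelet/ambient numerical
    # dominance over mislabeled cells mirror real PBMC raw matrices
    # (where spongelets and ambient droplets each outnumber mislabeled
    # cells by well over an order of magnitude).
    empty_populations: dict = field(
        default_factory=lambda: {
            "mislabeled_cell": (140, 5168.0),
            "spongelet": (3500, 268.0),
            "ambient": (7200, 20.0),
        }
    )
    n_genes: int = 100
    cell_rna_law: tuple = (np.log(10000.0), 0.5)
    # empty droplets carry uniformly low RNA (tens of UMIs)
    ambient_rna_law: tuple = (np.log(30.0), 0.5)
    seed: int | None = None

    def __post_init__(self) -> None:
        if min(self.I, self.J, self.K) < 1:
            raise ValueError("dimensions must be >= 1")
        if self.phi_concentration <= 0 or self.eta_concentration <= 0:
            raise ValueError("Dirichlet concentrations must be > 0")
        for cls, (n, _) in self.empty_populations.items():
            if n < 0:
                raise ValueError(f"negative droplet count for class {cls!r}")


@dataclass
class SimTruth:
    """Ground-truth latent state behind a simulated count matrix."""

    phi: np.ndarray
    eta: np.ndarray
    theta: np.ndarray
    beta: np.ndarray
    delta: np.ndarray
    mu: np.ndarray
    labels: np.ndarray
    lib_sizes: np.ndarray
    component_counts: dict  # {"native"|"ambient"|"background": I x J int arrays}

    def contamination_fraction(self) -> np.ndarray:
        """Per-droplet (ambient + background) share of emitted counts."""
        total = sum(self.component_counts.values()).sum(axis=1).astype(float)
        native = self.component_counts["native"].sum(axis=1)
        with np.errstate(invalid="ignore"):
            return np.where(total > 0, 1.0 - native / total, np.nan)


def _adt_names(J: int) -> np.ndarray:
    return np.array([f"ADT{j:03d}" for j in range(J)], dtype=object)


def _barcodes(n: int, prefix: str = "BC") -> np.ndarray:
    return np.array([f"{prefix}{i:07d}-1" for i in range(n)], dtype=object)


def simulate_cells(cfg: SimConfig, rng=None) -> tuple[CountMatrix, np.ndarray, SimTruth]:
    """Draw a cell-containing ADT count matrix from the generative process.

    Returns the matrix, per-droplet cluster labels (0..K-1) and the
    full latent truth including the exact per-entry native / ambient /
    background split.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    I, J, K = cfg.I, cfg.J, cfg.K
    if cfg.phi is not None:
        phi = np.asarray(cfg.phi, dtype=float)
        if phi.shape != (K, J):
            raise ValueError(f"phi override must be {K}x{J}")
    else:
        phi = rng.dirichlet(np.full(J, cfg.phi_concentration), size=K)
    eta = rng.dirichlet(np.full(J, cfg.eta_concentration))
    delta = rng.beta(*cfg.delta_law, size=I)
    mu = cfg.beta_upper * rng.beta(*cfg.mu_law, size=J)
    theta = _truncnorm(rng, delta[:, None], cfg.tau1, 0.0, 1.0, (I, J))
    beta = _truncnorm(rng, mu[None, :], cfg.tau2, 0.0, cfg.beta_upper, (I, J))
    L = np.maximum(1, np.round(rng.lognormal(*cfg.lib_size_law, size=I))).astype(int)
    labels = rng.integers(0, K, size=I)
    # guarantee every cluster occupied
    labels[:K] = np.arange(K)

    w_nat = (1.0 - beta) * (1.0 - theta) * phi[labels]
    w_amb = (1.0 - beta) * theta * eta[None, :]
    w_bg = beta
    comp = {
        "native": rng.poisson(L[:, None] * w_nat),
        "ambient": rng.poisson(L[:, None] * w_amb),
        "background": rng.poisson(L[:, None] * w_bg),
    }
    counts = comp["native"] + comp["ambient"] + comp["background"]
    cm = CountMatrix(
        sp.csr_matrix(counts),
        _barcodes(I),
        _adt_names(J),
        np.full(J, ANTIBODY_CAPTURE, dtype=object),
    )
    truth = SimTruth(phi, eta, theta, beta, delta, mu, labels, L, comp)
    return cm, labels, truth


def _profile_counts(rng, n: int, profile: np.ndarray, mean_total: float, sdlog=0.3):
    """Multinomial draws at log-normal totals around ``mean_total``."""
    totals = np.maximum(
        1, np.round(rng.lognormal(np.log(mean_total), sdlog, size=n))
    ).astype(int)
    return np.vstack([rng.multinomial(t, profile) for t in totals])


def simulate_raw(
    cfg: SimConfig, rng=None
) -> tuple[CountMatrix, CountMatrix, pd.DataFrame, SimTruth]:
    """Emulate paired raw ADT + RNA matrices with planted droplet classes.

    Cells come from :func:`simulate_cells`. Appended empty droplets:
    mislabeled cells carry cell-like ADT profiles at high totals but
    ambient-level RNA; spongelets share one non-specific medium-level
    profile; ambient droplets follow the ambient profile at low totals.

    Returns (adt_raw, rna_raw, truth_table, cell_truth); the truth table
    has one row per raw droplet with its planted class, and the filtered
    (cell) barcodes are exactly the rows labeled ``cell``.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    adt_cells, labels, truth = simulate_cells(cfg, rng)
    J = cfg.J
    blocks = [adt_cells.dense()]
    classes = ["cell"] * cfg.I

    pops = cfg.empty_populations
    spongelet_profile = rng.dirichlet(np.full(J, 2.0))
    for cls in ("mislabeled_cell", "spongelet", "ambient"):
        n, mean_total = pops.get(cls, (0, 0.0))
        if n == 0:
            continue
        if cls == "mislabeled_cell":
            ks = rng.integers(0, cfg.K, size=n)
            rows = np.vstack(
                [
                    _profile_counts(rng, 1, truth.phi[k], mean_total)
                    for k in ks
                ]
            )
        elif cls == "spongelet":
            rows = _profile_counts(rng, n, spongelet_profile, mean_total)
        else:
            rows = _profile_counts(rng, n, truth.eta, mean_total)
        blocks.append(rows)
        classes.extend([cls] * n)

    adt_all = np.vstack(blocks)
    n_total = adt_all.shape[0]
    barcodes = _barcodes(n_total)
    classes = np.array(classes, dtype=object)

    gene_profile = rng.dirichlet(np.full(cfg.n_genes, 1.0))
    rna_rows = np.empty((n_total, cfg.n_genes), dtype=int)
    is_cell = classes == "cell"
    for mask, law in ((is_cell, cfg.cell_rna_law), (~is_cell, cfg.ambient_rna_law)):
        idx = np.where(mask)[0]
        if idx.size:
            totals = np.maximum(
                1, np.round(rng.lognormal(*law, size=idx.size))
            ).astype(int)
            rna_rows[idx] = np.vstack(
                [rng.multinomial(t, gene_profile) for t in totals]
            )

    adt_raw = CountMatrix(
        sp.csr_matrix(adt_all),
        barcodes,
        _adt_names(J),
        np.full(J, ANTIBODY_CAPTURE, dtype=object),
    )
    rna_raw = CountMatrix(
        sp.csr_matrix(rna_rows),
        barcodes,
        np.array([f"GENE{g:04d}" for g in range(cfg.n_genes)], dtype=object),
        np.full(cfg.n_genes, GENE_EXPRESSION, dtype=object),
    )
    table = pd.DataFrame({"barcode": barcodes, "true_class": classes})
    return adt_raw, rna_raw, table, truth


def planted_marker_design(
    K: int, J: int, markers_per_cluster: int, marker_mass: float = 0.9
):
    """Construct native profiles with disjoint marker blocks.

    Each cluster's profile concentrates ``marker_mass`` of its native
    expression uniformly on its own ``markers_per_cluster`` ADTs and
    spreads the remainder over all other ADTs. Returns the K x J
    profile matrix and the matching marker annotation (each cluster's
    markers are native to it and non-native to every other cluster).
    """
    from .metrics import MarkerAnnotation

    if K * markers_per_cluster > J:
        raise ValueError(
            f"{K} clusters x {markers_per_cluster} markers > {J} ADTs"
        )
    if not 0.0 < marker_mass < 1.0:
        raise ValueError("marker_mass must be in (0, 1)")
    names = _adt_names(J)
    phi = np.full((K, J), (1.0 - marker_mass) / (J - markers_per_cluster))
    native, non_native = {}, {}
    for k in range(K):
        block = slice(k * markers_per_cluster, (k + 1) * markers_per_cluster)
        phi[k, block] = marker_mass / markers_per_cluster
        native[k] = list(names[block])
    for k in range(K):
        non_native[k] = sorted(
            set().union(*(native[m] for m in range(K) if m != k))
        )
    assert np.allclose(phi.sum(axis=1), 1.0)
    return phi, MarkerAnnotation(native=native, non_native=non_native)
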