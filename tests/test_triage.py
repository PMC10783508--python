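import numpy as np
import pytest
import scipy.sparse as sp

from decontpro.io import ANTIBODY_CAPTURE, GENE_EXPRESSION, CountMatrix
from decontpro.simulate import SimConfig, simulate_raw
from decontpro.triage import (
    AlignmentError,
    DegenerateProfileError,
    EmptyDropletTriage,
    LibrarySizes,
    background_peak_profile,
    cluster_empties,
    filter_cell_droplets,
    identify_empties,
    library_sizes,
    normalized_profile,
    profile_correlation,
)


def _adt(counts, names=None):
    counts = np.asarray(counts)
    J = counts.shape[1]
    return CountMatrix(
        sp.csr_matrix(counts),
        np.array([f"B{i}" for i in range(counts.shape[0])], dtype=object),
        np.array(names or [f"ADT{j}" for j in range(J)], dtype=object),
        np.full(J, ANTIBODY_CAPTURE, dtype=object),
    )


def _rna(counts, names=None):
    counts = np.asarray(counts)
    J = counts.shape[1]
    return CountMatrix(
        sp.csr_matrix(counts),
        np.array([f"B{i}" for i in range(counts.shape[0])], dtype=object),
        np.array(names or [f"G{j}" for j in range(J)], dtype=object),
        np.full(J, GENE_EXPRESSION, dtype=object),
    )


class TestLibrarySizes:
    def test_direct_summation(self):
        lib = library_sizes(_adt([[1, 2], [3, 4]]), _rna([[1, 0], [0, 5]]))
        assert np.array_equal(lib.adt_total, [3, 7])
        assert np.array_equal(lib.rna_total, [1, 5])

    def test_all_zero(self):
        lib = library_sizes(_adt(np.zeros((3, 2))), _rna(np.zeros((3, 4))))
        assert not lib.adt_total.any() and not lib.rna_total.any()

    def test_sparse_matches_dense_row_sums(self, random_count_matrix):
        from decontpro.io import split_modalities

        adt, rna = split_modalities(random_count_matrix)
        lib = library_sizes(adt, rna)
        assert np.array_equal(lib.adt_total, adt.dense().sum(axis=1))
        assert np.array_equal(lib.rna_total, rna.dense().sum(axis=1))

    def test_mismatched_barcodes_raise(self):
        rna = _rna([[1, 0], [0, 5]])
        rna.barcodes = np.array(["X1", "X2"], dtype=object)
        with pytest.raises(AlignmentError):
            library_sizes(_adt([[1, 2], [3, 4]]), rna)


class TestIdentifyEmpties:
    def test_raw_equals_filtered_gives_no_empties(self):
        mask, keep, missing = identify_empties(["A", "B"], ["A", "B"], [3, 4])
        assert not mask.any() and keep.all() and missing == []

    def test_zero_total_droplet_excluded_from_both(self):
        mask, keep, _ = identify_empties(["A", "B", "C"], ["A"], [5, 0, 2])
        assert list(mask) == [False, False, True]
        assert list(keep) == [True, False, True]

    def test_filtered_barcode_absent_from_raw_reported(self):
        _, _, missing = identify_empties(["A"], ["A", "Z"], [1])
        assert missing == ["Z"]


class TestClusterEmpties:
    def test_planted_blobs_recovered(self):
        rng = np.random.default_rng(0)
        sizes = {"mislabeled_cell": 5000, "spongelet": 270, "ambient": 20}
        rows, classes = [], []
        for cls, mean in sizes.items():
            for _ in range(60):
                total = max(1, int(rng.normal(mean, mean * 0.05)))
                rows.append([total // 2, total - total // 2])
                classes.append(cls)
        adt = np.array(rows)
        rna = rng.poisson(30, size=(len(rows), 3))
        lib = LibrarySizes(adt.sum(axis=1), rna.sum(axis=1))
        empty = np.ones(len(rows), dtype=bool)
        result = cluster_empties(lib, empty, _adt(adt), k=3, seed=0)
        assert np.array_equal(result.class_label, np.array(classes, dtype=object))

    def test_profiles_are_simplexes_and_counts_sum(self):
        rng = np.random.default_rng(1)
        adt = rng.poisson([100, 50], size=(40, 2)) + 1
        rna = rng.poisson(20, size=(40, 3))
        lib = LibrarySizes(adt.sum(axis=1), rna.sum(axis=1))
        empty = np.ones(40, dtype=bool)
        empty[:5] = False  # five cells
        res = cluster_empties(lib, empty, _adt(adt), k=3, seed=0)
        for prof in res.class_profiles.values():
            assert prof.min() >= 0
            assert abs(prof.sum() - 1.0) < 1e-9
        assert res.class_stats["n_droplets"].sum() == 40

    def test_order_permutation_invariance_up_to_labels(self):
        rng = np.random.default_rng(3)
        adt = np.concatenate(
            [rng.poisson(5000, (30, 1)), rng.poisson(200, (30, 1)), rng.poisson(20, (30, 1))]
        )
        adt = np.hstack([adt, adt])
        rna = rng.poisson(10, size=(90, 2))
        lib = LibrarySizes(adt.sum(axis=1), rna.sum(axis=1))
        empty = np.ones(90, dtype=bool)
        perm = rng.permutation(90)
        res1 = cluster_empties(lib, empty, _adt(adt), k=3, seed=0)
        lib_p = LibrarySizes(lib.adt_total[perm], lib.rna_total[perm])
        res2 = cluster_empties(lib_p, empty, _adt(adt[perm]), k=3, seed=0)
        assert np.array_equal(res1.class_label[perm], res2.class_label)

    def test_too_few_empties_raise(self):
        lib = LibrarySizes([1, 2], [1, 2])
        with pytest.raises(ValueError):
            EmptyDropletTriage(n_clusters=3).fit(lib, np.array([True, True]))


class TestNormalizedProfile:
    @pytest.mark.parametrize(
        "counts,mask,expected",
        [
            ([[2, 2]], [True], [0.5, 0.5]),
            ([[7]], [True], [1.0]),
            ([[1, 0], [1, 2]], [True, True], [0.5, 0.5]),
        ],
    )
    def test_hand_values(self, counts, mask, expected):
        prof = normalized_profile(_adt(counts), np.array(mask))
        assert np.allclose(prof, expected)

    def test_all_zero_subset_raises(self):
        with pytest.raises(DegenerateProfileError):
            normalized_profile(_adt([[0, 0]]), np.array([True]))


class TestProfileCorrelation:
    def test_identity_is_one(self):
        p = np.array([0.5, 0.3, 0.2])
        assert profile_correlation(p, p) == pytest.approx(1.0)

    def test_constant_vector_raises(self):
        with pytest.raises(ValueError):
            profile_correlation(np.array([1 / 3] * 3), np.array([0.5, 0.3, 0.2]))

    def test_matches_numpy_corrcoef(self):
        rng = np.random.default_rng(0)
        p = rng.dirichlet(np.ones(10))
        q = rng.dirichlet(np.ones(10))
        assert profile_correlation(p, q) == pytest.approx(np.corrcoef(p, q)[0, 1])


class TestBackgroundPeakProfile:
    def test_infinite_cutoffs_equal_full_profile(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(10, size=(50, 3)) + 1
        adt = _adt(counts)
        prof, _ = background_peak_profile(adt, np.full(3, np.inf))
        assert np.allclose(prof, normalized_profile(adt, np.ones(50, dtype=bool)))

    def test_zero_cutoffs_degenerate(self):
        counts = np.ones((10, 2), dtype=int)
        with pytest.raises(DegenerateProfileError):
            background_peak_profile(_adt(counts), np.zeros(2))

    def test_cutoff_length_mismatch(self):
        with pytest.raises(ValueError):
            background_peak_profile(_adt([[1, 2]]), np.array([1.0]))

    def test_auto_cutoff_separates_bimodal_mixture(self):
        rng = np.random.default_rng(7)
        low = rng.poisson(3, size=800)
        high = rng.poisson(200, size=200)
        counts = np.concatenate([low, high])[:, None]
        counts = np.hstack([counts, np.ones_like(counts)])
        prof, cutoffs = background_peak_profile(_adt(counts))
        # cutoff falls between the modes
        assert 10 < cutoffs[0] < 150
        masked = counts[:, 0][counts[:, 0] <= cutoffs[0]]
        low_mass = masked.sum() / max(low.sum() + high[high <= cutoffs[0]].sum(), 1)
        assert low_mass >= 0.99


class TestFilterCellDroplets:
    def _pair(self, n=200, seed=0, adt_names=None):
        rng = np.random.default_rng(seed)
        adt = rng.poisson(50, size=(n, 4)) + 1
        gene_names = ["MT-CO1", "G1", "G2", "G3"]
        rna = rng.poisson(30, size=(n, 4)) + 1
        rna[:, 0] = rng.poisson(3, size=n)  # mito fraction well below 15%
        return _adt(adt, adt_names), _rna(rna, gene_names)

    def test_mito_boundary_is_inclusive(self):
        adt, rna = self._pair(n=100)
        # droplet 0: exactly 15% mito of its RNA total
        dense = rna.dense()
        dense[0] = [15, 35, 25, 25]
        rna = _rna(dense, ["MT-CO1", "G1", "G2", "G3"])
        adt2, rna2, report = filter_cell_droplets(
            adt, rna, low_q=0.0, high_q=1.0, mito_max=0.15
        )
        assert "B0" not in set(adt2.barcodes)

    def test_quantile_filter_removes_extreme_ranks(self):
        # 100 droplets with strictly increasing ADT and RNA totals
        adt = np.arange(1, 101)[:, None] * [1, 0, 0, 0] + [[0, 1, 1, 1]]
        rna = np.arange(1, 101)[:, None] * [1, 0, 0, 0] + [[0, 1, 1, 1]]
        a, r, report = filter_cell_droplets(
            _adt(adt), _rna(rna, ["G0", "G1", "G2", "G3"]), mito_max=1.1
        )
        kept = set(a.barcodes)
        assert "B0" not in kept and "B99" not in kept
        assert "B50" in kept

    def test_hto_isotype_features_removed_first(self):
        adt, rna = self._pair(adt_names=["CD3", "HTO-1", "IgG1-isotype", "CD4"])
        a, _, report = filter_cell_droplets(adt, rna, low_q=0.0, high_q=1.0)
        assert list(a.feature_names) == ["CD3", "CD4"]
        assert report.loc[report.stage == "exclude_features", "removed"].iloc[0] == 2

    def test_no_pattern_match_leaves_adt_unchanged(self):
        adt, rna = self._pair(adt_names=["CD3", "CD4", "CD8", "CD19"])
        a, _, report = filter_cell_droplets(adt, rna, low_q=0.0, high_q=1.0)
        assert list(a.feature_names) == ["CD3", "CD4", "CD8", "CD19"]


class TestTriageOnSimulatedRaw:
    def test_planted_classes_recovered(self):
        cfg = SimConfig(
            I=200, J=10, K=2, seed=11,
            empty_populations={
                "mislabeled_cell": (60, 5000.0),
                "spongelet": (120, 270.0),
                "ambient": (400, 20.0),
            },
        )
        adt_raw, rna_raw, table, truth = simulate_raw(cfg)
        lib = library_sizes(adt_raw, rna_raw)
        totals = lib.adt_total + lib.rna_total
        filtered = table.loc[table.true_class == "cell", "barcode"]
        mask, keep, _ = identify_empties(adt_raw.barcodes, filtered, totals)
        res = cluster_empties(lib, mask, adt_raw, k=3, seed=0, keep_mask=keep)
        empties = table.true_class != "cell"
        acc = (res.class_label[empties] == table.true_class[empties]).mean()
        assert acc >= 0.95
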