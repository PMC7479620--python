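import warnings

import anndata as ad
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from sklearn.metrics import adjusted_rand_score

import hemopipe as hp
from oracles import agglomerate_oracle, exclusion_oracle


def _adata(counts, genes=None, barcodes=None):
    counts = np.asarray(counts)
    n, g = counts.shape
    return ad.AnnData(
        X=sp.csr_matrix(counts),
        obs=pd.DataFrame(index=barcodes or [f"c{i}" for i in range(n)]),
        var=pd.DataFrame(index=genes or [f"g{i}" for i in range(g)]),
    )


class TestNormalize:
    def test_forced_values(self):
        adata = _adata([[100, 9900]])
        norm = hp.normalize_counts(adata, target_total=10_000)
        assert norm.values[0, 0] == pytest.approx(np.log(101))

    def test_zero_count_zero_value(self):
        adata = _adata([[0, 5]])
        norm = hp.normalize_counts(adata)
        assert norm.values[0, 0] == 0.0

    def test_round_trip_recovers_counts(self, small_cohort):
        _, adata, _ = small_cohort
        real = adata[np.asarray(adata.X.sum(axis=1)).ravel() > 0]
        norm = hp.normalize_counts(real)
        recovered = (
            np.expm1(norm.dense())
            * (norm.cell_totals[:, None] / norm.target_total)
        )
        assert np.allclose(recovered, real.X.toarray(), rtol=1e-6, atol=1e-8)

    def test_zero_total_cell_named(self):
        adata = _adata([[0, 0], [1, 2]], barcodes=["dead", "live"])
        with pytest.raises(ValueError, match="dead"):
            hp.normalize_counts(adata)


class TestVariableGenes:
    def test_constant_gene_never_selected(self):
        # equal cell depths so the constant column stays constant after scaling
        adata = _adata([[5, 1, 7], [5, 1, 7], [1, 5, 7]], genes=["a", "b", "const"])
        norm = hp.normalize_counts(adata)
        hvg = hp.select_variable_genes(norm, n=2)
        assert "const" not in hvg

    def test_dispersion_ranking(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(5, size=(200, 50)) + 1  # stable background
        counts[:, 0] = rng.poisson(5, 200) + 1  # "flat"
        counts[:, 1] = (rng.poisson(5, 200) * rng.integers(0, 10, 200)) + 1  # "wild"
        genes = ["flat", "wild"] + [f"bg{i}" for i in range(48)]
        adata = _adata(counts, genes=genes)
        norm = hp.normalize_counts(adata)
        hvg = hp.select_variable_genes(norm, n=50)
        assert hvg.index("wild") < hvg.index("flat")

    def test_fewer_eligible_than_requested_warns(self):
        adata = _adata([[1, 2], [3, 4]])
        norm = hp.normalize_counts(adata)
        with pytest.warns(UserWarning, match="eligible"):
            hvg = hp.select_variable_genes(norm, n=50)
        assert len(hvg) <= 2


class TestPseudobulk:
    def test_single_group_is_column_sums(self):
        adata = _adata([[1, 2], [3, 4]])
        prof = hp.pseudobulk(adata, ["A", "A"])
        assert np.array_equal(prof.raw.loc["A"].to_numpy(), [4, 6])

    def test_hand_summed_groups(self):
        adata = _adata([[1, 0], [2, 1], [0, 3]])
        prof = hp.pseudobulk(adata, ["A", "A", "B"])
        assert np.array_equal(prof.raw.loc["A"].to_numpy(), [3, 1])
        assert np.array_equal(prof.raw.loc["B"].to_numpy(), [0, 3])
        assert prof.sizes.to_dict() == {"A": 2, "B": 1}

    def test_conservation_of_total_counts(self, planted_cohort):
        _, adata, truth = planted_cohort
        labels = [f"s{t}" for t in truth.cell_subtype]
        prof = hp.pseudobulk(adata, labels)
        assert prof.raw.to_numpy().sum() == adata.X.sum()


class TestCorrelationMatrix:
    def test_perfect_linearity(self):
        prof = hp.PseudobulkProfile(
            raw=pd.DataFrame([[1, 2, 3, 4], [2, 4, 6, 8]], index=["A", "B"]),
            logcpm=pd.DataFrame([[1, 2, 3, 4], [2, 4, 6, 8]], index=["A", "B"]),
            sizes=pd.Series({"A": 1, "B": 1}),
        )
        corr = hp.correlation_matrix(prof, [0, 1, 2, 3])
        assert corr.r[0, 1] == pytest.approx(1.0)

    def test_anti_linearity(self):
        prof = hp.PseudobulkProfile(
            raw=pd.DataFrame([[1, 2, 3, 4], [4, 3, 2, 1]], index=["A", "B"]),
            logcpm=pd.DataFrame([[1, 2, 3, 4], [4, 3, 2, 1]], index=["A", "B"]),
            sizes=pd.Series({"A": 1, "B": 1}),
        )
        corr = hp.correlation_matrix(prof, [0, 1, 2, 3])
        assert corr.r[0, 1] == pytest.approx(-1.0)

    def test_direct_formula_oracle(self):
        a, b = np.array([1, 0, 2, 5.0]), np.array([0, 1, 3, 4.0])
        expected = (
            ((a - a.mean()) * (b - b.mean())).sum()
            / np.sqrt(((a - a.mean()) ** 2).sum() * ((b - b.mean()) ** 2).sum())
        )
        prof = hp.PseudobulkProfile(
            raw=pd.DataFrame([a, b], index=["A", "B"]),
            logcpm=pd.DataFrame([a, b], index=["A", "B"]),
            sizes=pd.Series({"A": 1, "B": 1}),
        )
        corr = hp.correlation_matrix(prof, [0, 1, 2, 3])
        assert corr.r[0, 1] == pytest.approx(expected)

    def test_zero_variance_group_named(self):
        prof = hp.PseudobulkProfile(
            raw=pd.DataFrame([[1, 2], [3, 3]], index=["A", "Bflat"]),
            logcpm=pd.DataFrame([[1, 2], [3, 3]], index=["A", "Bflat"]),
            sizes=pd.Series({"A": 1, "Bflat": 1}),
        )
        with pytest.raises(ValueError, match="Bflat"):
            hp.correlation_matrix(prof, [0, 1])


class TestExcludeUncorrelated:
    def _corr(self, names, r):
        return hp.CorrelationMatrix(groups=list(names), r=np.asarray(r, float))

    def test_no_exclusion_when_all_high(self):
        corr = self._corr("ABC", [[1, .95, .96], [.95, 1, .97], [.96, .97, 1]])
        retained, excluded, _ = hp.exclude_uncorrelated(corr, pd.Series({"A": 5, "B": 5, "C": 5}))
        assert excluded == [] and retained == ["A", "B", "C"]

    def test_single_low_group_removed(self):
        corr = self._corr("ABC", [[1, .99, .10], [.99, 1, .12], [.10, .12, 1]])
        retained, excluded, final = hp.exclude_uncorrelated(
            corr, pd.Series({"A": 5, "B": 5, "C": 5}))
        assert excluded == ["C"]
        assert retained == ["A", "B"]
        assert final.r[0, 1] == pytest.approx(0.99)

    def test_two_group_guard_warns(self):
        corr = self._corr("AB", [[1, .5], [.5, 1]])
        with pytest.warns(UserWarning, match="retained"):
            retained, excluded, _ = hp.exclude_uncorrelated(
                corr, pd.Series({"A": 5, "B": 5}))
        assert retained == ["A", "B"] and excluded == []

    def test_terminal_condition_property(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            k = rng.integers(3, 7)
            m = rng.normal(size=(k, 30))
            r = np.corrcoef(m)
            names = [f"G{i}" for i in range(k)]
            sizes = pd.Series(rng.integers(3, 50, k), index=names)
            retained, excluded, final = hp.exclude_uncorrelated(
                hp.CorrelationMatrix(groups=names, r=r), sizes, r_min=0.2)
            if len(retained) > 2:
                assert final.off_diagonal().min() >= 0.2
            else:
                assert len(retained) == 2


class TestMergeSupergroups:
    def test_no_op_below_threshold(self, planted_cohort):
        _, adata, truth = planted_cohort
        # C and N never correlate at 0.95; restrict to those subtypes
        mask = np.isin(truth.cell_subtype, [4, 5])
        sub = adata[mask]
        labels = np.array(["C", "N"])[np.searchsorted([4, 5], truth.cell_subtype[mask])]
        norm = hp.normalize_counts(sub)
        genes = hp.select_variable_genes(norm, 500)
        mapping, corr = hp.merge_supergroups(sub, labels, genes)
        assert mapping == {"C": "C", "N": "N"}

    def test_duplicate_groups_forced_merge(self):
        counts = np.array([[5, 1, 3], [5, 1, 3], [1, 9, 2], [1, 9, 2]])
        adata = _adata(counts)
        # identical member counts in A1/A2 and B1/B2
        mapping, _ = hp.merge_supergroups(
            adata, ["A1", "A2", "B1", "B2"], ["g0", "g1", "g2"], r_merge=0.9999
        )
        assert mapping["A1"] == mapping["A2"]
        assert mapping["B1"] == mapping["B2"]
        assert mapping["A1"] != mapping["B1"]

    def test_final_max_correlation_below_threshold(self, planted_cohort):
        _, adata, truth = planted_cohort
        labels = [f"s{t}" for t in truth.cell_subtype]
        norm = hp.normalize_counts(adata)
        genes = hp.select_variable_genes(norm, 2000)
        mapping, corr = hp.merge_supergroups(adata, labels, genes, r_merge=0.95)
        if corr is not None and len(corr.groups) > 1:
            assert corr.off_diagonal().max() < 0.95

    def test_oracle_agreement_random_structures(self):
        """Merge order and final partition match re-pooling agglomeration
        across random small cohorts (<= 6 groups)."""
        rng = np.random.default_rng(17)
        for trial in range(30):
            n_groups = int(rng.integers(2, 7))
            n_cells = int(rng.integers(n_groups, 40))
            base = rng.lognormal(0, 1, size=(n_groups, 25))
            labels = rng.integers(0, n_groups, n_cells)
            labels[:n_groups] = np.arange(n_groups)  # every group non-empty
            counts = rng.poisson(base[labels] * 20)
            counts[:, 0] += 1  # avoid all-zero pseudobulk rows
            genes = [f"g{i}" for i in range(25)]
            adata = _adata(counts, genes=genes)
            lab = pd.Series([f"G{l}" for l in labels], index=adata.obs_names)
            log = []
            mapping, _ = hp.merge_supergroups(adata, lab, genes,
                                              r_merge=0.98, merge_log=log)
            df = pd.DataFrame(counts, columns=genes, index=adata.obs_names)
            oracle_partition, oracle_merges = agglomerate_oracle(
                df, lab, genes, r_merge=0.98)
            got_partition = set(
                frozenset(m for m, s in mapping.items() if s == sg)
                for sg in set(mapping.values())
            )
            assert got_partition == oracle_partition, f"trial {trial}"
            assert log == oracle_merges, f"trial {trial}"

    def test_exclusion_oracle_agreement(self):
        rng = np.random.default_rng(23)
        for trial in range(30):
            n_groups = int(rng.integers(3, 7))
            n_cells = int(rng.integers(n_groups, 40))
            base = rng.lognormal(0, 1, size=(n_groups, 25))
            labels = rng.integers(0, n_groups, n_cells)
            labels[:n_groups] = np.arange(n_groups)
            counts = rng.poisson(base[labels] * 20)
            counts[:, 0] += 1
            genes = [f"g{i}" for i in range(25)]
            adata = _adata(counts, genes=genes)
            lab = pd.Series([f"G{l}" for l in labels], index=adata.obs_names)
            prof = hp.pseudobulk(adata, lab)
            sub = prof.logcpm[genes]
            if (sub.std(axis=1, ddof=0) == 0).any():
                continue
            corr = hp.correlation_matrix(prof, genes)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                retained, excluded, _ = hp.exclude_uncorrelated(
                    corr, prof.sizes, r_min=0.7)
            df = pd.DataFrame(counts, columns=genes, index=adata.obs_names)
            o_retained, o_excluded = exclusion_oracle(
                df, lab, genes, prof.sizes, r_min=0.7)
            assert retained == o_retained and excluded == o_excluded, f"trial {trial}"


class TestLibraryBias:
    def test_dominated_group_flagged(self):
        labels = ["A"] * 10
        libs = ["L1"] * 6 + ["L2"] * 4
        assert hp.flag_library_biased(labels, libs, frac=0.5) == {"A"}

    def test_even_split_not_flagged(self):
        labels = ["A"] * 10
        libs = ["L1"] * 5 + ["L2"] * 5
        assert hp.flag_library_biased(labels, libs, frac=0.5) == set()

    def test_uniform_mixing_rarely_flagged(self, planted_cohort):
        _, adata, truth = planted_cohort
        labels = [f"s{t}" for t in truth.cell_subtype]
        real = ~truth.ambient_flag
        flagged = hp.flag_library_biased(
            labels, adata.obs["library"].to_numpy()[real], frac=0.5)
        assert flagged == set()


class TestOptimizeResolution:
    def test_label_permutation_equivariance(self, planted_cohort):
        _, adata, truth = planted_cohort
        fine = np.array([f"s{t}" for t in truth.cell_subtype], dtype=object)
        renamed = np.array([f"x{9 - t}" for t in truth.cell_subtype], dtype=object)
        norm = hp.normalize_counts(adata)
        genes = hp.select_variable_genes(norm, 2000)
        m1, _ = hp.merge_supergroups(adata, fine, genes)
        m2, _ = hp.merge_supergroups(adata, renamed, genes)
        p1 = pd.Series(fine).map(m1)
        p2 = pd.Series(renamed).map(m2)
        assert adjusted_rand_score(p1, p2) == pytest.approx(1.0)

    def test_single_resolution_grid(self, planted_cohort):
        _, adata, truth = planted_cohort
        backend = hp.PlantedBackend(
            fine_labels=np.array([f"s{t}" for t in truth.cell_subtype], dtype=object),
            coarse_labels=truth.coarse_group,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sol = hp.optimize_resolution(adata, backend, res_grid=[1.0], seed=0)
        assert len(sol.trace) == 1
        assert sol.resolution == 1.0
        assert sol.excluded_clusters == {"s5"}

    def test_leiden_backend_deterministic_and_recovers_subtypes(self):
        cfg = hp.SynthConfig(n_cells=400, n_genes=300, n_subtypes=2, seed=1)
        adata, truth = hp.generate_cohort(cfg)
        norm = hp.normalize_counts(adata)
        backend = hp.LeidenBackend(n_pcs=20)
        l1 = backend(norm, 0.5, seed=0)
        l2 = backend(norm, 0.5, seed=0)
        assert (l1 == l2).all()
        assert adjusted_rand_score(truth.cell_subtype, l1) >= 0.95

    def test_homogeneous_data_tie_break_lowest_resolution(self):
        cfg = hp.SynthConfig(n_cells=300, n_genes=200, n_subtypes=1, seed=21)
        adata, truth = hp.generate_cohort(cfg)
        backend = hp.PlantedBackend(
            fine_labels=np.repeat("s0", adata.n_obs),
            coarse_labels=np.repeat("G0", adata.n_obs),
            coarse_below=10.0,  # single cluster at every swept resolution
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sol = hp.optimize_resolution(adata, backend, res_grid=[0.1, 0.5, 1.0], seed=0)
        assert sol.deg_count == 0
        assert sol.resolution == 0.1
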