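import numpy as np
import pandas as pd
import pytest

from panelgp.genotype_io import GenotypeDataset
from panelgp.kinship import (PAIRWISE_COMPLETE, allele_frequencies, build_grm,
                             invert_grm)

from conftest import random_dataset


def _dataset_from_matrix(X):
    n, m = X.shape
    markers = pd.DataFrame({
        "snp_id": [f"s{j}" for j in range(m)], "chrom": ["1"] * m,
        "pos": np.arange(1, m + 1), "a1": ["A"] * m, "a2": ["G"] * m,
    })
    samples = pd.DataFrame({
        "fid": ["f"] * n, "iid": [f"i{k}" for k in range(n)],
        "sire": ["0"] * n, "dam": ["0"] * n, "sex": ["0"] * n,
    })
    return GenotypeDataset(np.asarray(X, dtype=float), markers, samples)


class TestAlleleFrequencies:
    def test_all_heterozygote_is_half(self):
        ds = _dataset_from_matrix(np.ones((4, 3)))
        np.testing.assert_allclose(allele_frequencies(ds), 0.5)

    def test_zero_one_two_is_half(self):
        ds = _dataset_from_matrix(np.array([[0.0], [1.0], [2.0]]))
        np.testing.assert_allclose(allele_frequencies(ds), 0.5)

    def test_matches_per_marker_recount(self):
        rng = np.random.default_rng(0)
        ds = random_dataset(rng, n=25, m=40, missing_rate=0.1)
        p = allele_frequencies(ds)
        for j in range(ds.n_markers):
            col = ds.dosages[:, j]
            col = col[~np.isnan(col)]
            assert p[j] == pytest.approx(col.sum() / (2 * col.size), abs=1e-15)

    def test_all_missing_marker_rejected(self):
        rng = np.random.default_rng(1)
        ds = random_dataset(rng, n=5, m=4)
        ds.dosages[:, 2] = np.nan
        with pytest.raises(ValueError, match="non-missing"):
            allele_frequencies(ds)


class TestBuildGrm:
    def test_double_loop_oracle(self):
        """3 x 4 explicit dosages against a naive double loop over pairs."""
        X = np.array([[0, 1, 2, 1], [2, 1, 0, 0], [1, 2, 1, 1]], dtype=float)
        p = np.array([0.5, 2 / 3, 0.5, 1 / 3])
        ds = _dataset_from_matrix(X)
        G = build_grm(ds, freqs=p).matrix
        L = X.shape[1]
        for i in range(3):
            for j in range(3):
                expect = sum(
                    (X[i, l] - 2 * p[l]) * (X[j, l] - 2 * p[l]) / (2 * p[l] * (1 - p[l]))
                    for l in range(L)
                ) / L
                assert G[i, j] == pytest.approx(expect, abs=1e-12)

    def test_identical_rows_share_diagonal_value(self):
        X = np.array([[0, 1, 2, 1], [0, 1, 2, 1], [2, 1, 0, 1]], dtype=float)
        G = build_grm(_dataset_from_matrix(X)).matrix
        assert G[0, 1] == pytest.approx(G[0, 0], abs=1e-12)
        assert G[0, 0] == pytest.approx(G[1, 1], abs=1e-12)

    def test_unrelated_hw_sample_scales_to_identity(self):
        """Unrelated individuals at HWE: diagonal -> 1, off-diagonal -> 0."""
        rng = np.random.default_rng(2)
        n, m = 200, 10_000
        p = rng.uniform(0.1, 0.5, m)
        X = rng.binomial(2, p, size=(n, m)).astype(float)
        G = build_grm(_dataset_from_matrix(X)).matrix
        off = G[~np.eye(n, dtype=bool)]
        assert abs(np.mean(np.diag(G)) - 1.0) < 0.02
        assert abs(off.mean()) < 0.02

    def test_pairwise_policy_matches_mean_impute_when_complete(self):
        rng = np.random.default_rng(3)
        ds = random_dataset(rng, n=10, m=30)
        ds.dosages[0] = np.clip(ds.dosages[0] + 1, 0, 2)  # avoid monomorphism edge
        G1 = build_grm(ds).matrix
        G2 = build_grm(ds, missing_policy=PAIRWISE_COMPLETE).matrix
        np.testing.assert_allclose(G1, G2, atol=1e-12)


class TestFamilyStructure:
    def test_sib_and_unrelated_expectations(self, family_sim):
        """Full sibs average G ~ 0.5; across families ~ 0; diagonal ~ 1."""
        _, dataset, _, _ = family_sim
        G = build_grm(dataset).matrix
        fids = dataset.samples["fid"].to_numpy()
        same_fam = fids[:, None] == fids[None, :]
        sib = same_fam & ~np.eye(len(fids), dtype=bool)
        unrel = ~same_fam
        assert abs(G[sib].mean() - 0.5) < 0.02
        assert abs(G[unrel].mean()) < 0.02
        assert abs(np.diag(G).mean() - 1.0) < 0.05

    def test_offdiagonal_distribution_is_bimodal(self, family_sim):
        """Off-diagonal G separates into ~0 (unrelated) and ~0.5 (sib) modes."""
        _, dataset, _, _ = family_sim
        G = build_grm(dataset).matrix
        iu = np.triu_indices_from(G, k=1)
        vals = G[iu]
        near_zero = np.mean(np.abs(vals) < 0.25)
        near_half = np.mean(np.abs(vals - 0.5) < 0.25)
        assert near_zero + near_half > 0.99
        assert near_half > 0.0  # sib mode present


class TestInvertGrm:
    def test_identity(self):
        inv, ridge = invert_grm(np.eye(5))
        np.testing.assert_allclose(inv, np.eye(5), atol=1e-12)
        assert ridge == 0.0

    def test_singular_requires_recorded_ridge(self):
        X = np.array([[0, 1, 2, 1], [0, 1, 2, 1], [2, 1, 0, 1]], dtype=float)
        G = build_grm(_dataset_from_matrix(X)).matrix  # duplicated individual
        inv, ridge = invert_grm(G)
        assert ridge > 0
        assert np.abs((G + ridge * np.eye(3)) @ inv - np.eye(3)).max() < 1e-6

    def test_residual_norm_with_explicit_ridge(self):
        rng = np.random.default_rng(4)
        A = rng.standard_normal((20, 8))
        G = A @ A.T / 8  # PSD, rank-deficient
        inv, ridge = invert_grm(G, ridge=1e-3)
        assert ridge == pytest.approx(1e-3)
        assert np.abs((G + ridge * np.eye(20)) @ inv - np.eye(20)).max() < 1e-8

    def test_non_symmetric_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            invert_grm(np.array([[1.0, 0.5], [0.2, 1.0]]))


class TestSerialization:
    def test_tsv_round_trip(self, tmp_path):
        rng = np.random.default_rng(5)
        A = rng.standard_normal((6, 4))
        G = A @ A.T / 4
        ids = [f"F_{k}" for k in range(6)]
        from panelgp.kinship import read_grm_tsv, write_grm_tsv
        write_grm_tsv(G, ids, tmp_path / "g.tsv")
        back, back_ids = read_grm_tsv(tmp_path / "g.tsv")
        assert back_ids == ids
        np.testing.assert_allclose(back, G, atol=1e-12)

    def test_sparse_lower_triangle(self, tmp_path):
        from panelgp.kinship import write_grm_sparse
        G = np.array([[1.0, 0.5], [0.5, 1.1]])
        write_grm_sparse(G, ["a", "b"], tmp_path / "g.txt", tmp_path / "g.ids")
        lines = (tmp_path / "g.txt").read_text().splitlines()
        assert len(lines) == 3  # n(n+1)/2 entries
        i, j, v = lines[1].split("\t")
        assert (int(i), int(j), float(v)) == (2, 1, 0.5)
        assert (tmp_path / "g.ids").read_text().split() == ["a", "b"]


def test_strategy_choice_does_not_shift_sib_relationships(family_sim):
    """Genome-wide and within-chromosome panels of equal density give
    statistically indistinguishable full-sib mean relationships."""
    from scipy import stats
    from panelgp.panel_design import (GENOMEWIDE_RANDOM, WITHIN_CHROMOSOME,
                                      derive_panel_seed, sample_panel)

    _, dataset, _, _ = family_sim
    fids = dataset.samples["fid"].to_numpy()
    sib = (fids[:, None] == fids[None, :]) & ~np.eye(len(fids), dtype=bool)
    means = {}
    for strategy in (GENOMEWIDE_RANDOM, WITHIN_CHROMOSOME):
        vals = []
        for rep in range(1, 7):
            panel = sample_panel(dataset, 300, strategy,
                                 derive_panel_seed(3, strategy, 300, rep), rep)
            G = build_grm(dataset.subset(markers=panel.marker_ids)).matrix
            vals.append(G[sib].mean())
        means[strategy] = vals
    t = stats.ttest_ind(means[GENOMEWIDE_RANDOM], means[WITHIN_CHROMOSOME])
    assert t.pvalue > 0.01
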