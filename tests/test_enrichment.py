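"""Protein-deviation associations and hypergeometric gene-set enrichment."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from protclock import (GeneSetCollection, associate_proteins, hypergeom_test,
                       map_proteins_to_genes, run_gene_set_analysis)


class TestAssociateProteins:
    def test_protein_identical_to_deviation(self):
        rng = np.random.default_rng(0)
        dev = rng.normal(size=1000)
        mat = pd.DataFrame({"P1": dev})
        res = associate_proteins(dev, mat)
        assert res.loc["P1", "beta"] == pytest.approx(1.0)
        assert res.loc["P1", "p"] < 1e-10

    def test_matches_normal_equations_oracle(self):
        """beta and p for each protein equal the closed-form (X'X)^-1 X'y fit
        with an intercept and covariates, protein by protein."""
        rng = np.random.default_rng(1)
        n, m = 200, 4
        covs = pd.DataFrame({"age": rng.uniform(39, 70, n),
                             "sex": rng.integers(0, 2, n).astype(float)})
        mat = pd.DataFrame(rng.normal(size=(n, m)),
                           columns=[f"P{j}" for j in range(m)])
        dev = 0.3 * mat["P1"] + 0.05 * covs["age"] + rng.normal(size=n)
        res = associate_proteins(dev.to_numpy(), mat, covs)
        from scipy import stats
        for j in range(m):
            X = np.column_stack([np.ones(n), covs.to_numpy(),
                                 mat.iloc[:, j].to_numpy()])
            coef, res_ss, *_ = np.linalg.lstsq(X, dev.to_numpy(), rcond=None)
            dof = n - X.shape[1]
            sigma2 = float(res_ss[0]) / dof
            cov_beta = sigma2 * np.linalg.inv(X.T @ X)
            se = math.sqrt(cov_beta[-1, -1])
            p = 2 * stats.t.sf(abs(coef[-1] / se), dof)
            assert res.iloc[j]["beta"] == pytest.approx(coef[-1], abs=1e-8)
            assert res.iloc[j]["p"] == pytest.approx(p, rel=1e-6)

    def test_null_proteins_rarely_bonferroni_significant(self):
        """1000 null proteins x 5 seeds: Bonferroni keeps family-wise
        significance rare (<= 2 hits in any run would already be unusual)."""
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            n, m = 150, 1000
            dev = rng.normal(size=n)
            mat = pd.DataFrame(rng.normal(size=(n, m)),
                               columns=[f"P{j}" for j in range(m)])
            res = associate_proteins(dev, mat)
            hits += int((res["bonferroni_p"] < 0.05).sum())
        assert hits <= 2

    def test_bonferroni_definition(self):
        rng = np.random.default_rng(3)
        mat = pd.DataFrame(rng.normal(size=(50, 7)),
                           columns=[f"P{j}" for j in range(7)])
        res = associate_proteins(rng.normal(size=50), mat)
        assert np.allclose(res["bonferroni_p"], np.minimum(res["p"] * 7, 1.0))

    def test_rank_deficient_covariates_rejected(self):
        covs = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0], "b": [2.0, 4.0, 6.0, 8.0]})
        mat = pd.DataFrame({"P1": [0.1, 0.5, -0.2, 0.3]})
        with pytest.raises(ValueError):
            associate_proteins(np.zeros(4), mat, covs)


class TestHypergeom:
    def test_single_term_closed_form(self):
        p = hypergeom_test(5, 5, 5, 20)
        assert p == pytest.approx(1 / math.comb(20, 5), rel=1e-9)

    def test_k_zero_is_one(self):
        assert hypergeom_test(0, 5, 5, 20) == pytest.approx(1.0)

    def test_matches_enumeration_small_universes(self):
        """Exact tail by enumerating every draw for N <= 30."""
        rng = np.random.default_rng(4)
        for _ in range(25):
            N = int(rng.integers(5, 31))
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            k = int(rng.integers(0, min(n, K) + 1))
            # P(X >= k) by summing the pmf from the definition
            expect = sum(
                math.comb(K, i) * math.comb(N - K, n - i) / math.comb(N, n)
                for i in range(k, min(n, K) + 1)
                if n - i <= N - K
            )
            assert hypergeom_test(k, n, K, N) == pytest.approx(expect, rel=1e-10)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_test(6, 5, 5, 20)
        with pytest.raises(ValueError):
            hypergeom_test(1, 25, 5, 20)


def _collection(sets, background_size=20_260):
    return GeneSetCollection({k: frozenset(v) for k, v in sets.items()},
                             background_size=background_size)


class TestGeneSetAnalysis:
    def test_planted_signal_is_bonferroni_significant(self):
        """50-gene set with 30 of 100 input genes inside, N = 20,260: the
        planted set must survive Bonferroni over a 50-set collection."""
        planted = [f"GENE{i:05d}" for i in range(50)]
        rng = np.random.default_rng(8)
        sets = {"PLANTED": planted}
        for s in range(49):
            sets[f"RANDOM{s}"] = [f"GENE{i:05d}" for i in
                                  rng.integers(1000, 20_000, size=60)]
        coll = _collection(sets)
        input_genes = planted[:30] + [f"OTHER{i:04d}" for i in range(70)]
        res = run_gene_set_analysis(input_genes, coll, min_overlap=5)
        top = res.set_index("set")
        assert top.loc["PLANTED", "overlap"] == 30
        assert top.loc["PLANTED", "bonferroni_p"] < 0.05

    def test_min_overlap_filter_excludes_small_overlaps(self):
        sets = {"SMALL": [f"G{i}" for i in range(10)],
                "BIG": [f"H{i}" for i in range(20)]}
        coll = _collection(sets)
        genes = ["G0", "G1", "G2", "G3"] + [f"H{i}" for i in range(6)]
        res = run_gene_set_analysis(genes, coll, min_overlap=5)
        assert "SMALL" not in set(res["set"])  # overlap 4 < 5, however extreme
        assert "BIG" in set(res["set"])

    def test_null_input_rarely_significant(self):
        """Random input genes: on average <= ~5% of sets nominally significant."""
        rng = np.random.default_rng(12)
        universe = [f"GENE{i:05d}" for i in range(2000)]
        sets = {f"S{s}": list(rng.choice(universe, size=50, replace=False))
                for s in range(30)}
        coll = _collection(sets, background_size=2000)
        sig = total = 0
        for seed in range(10):
            rng2 = np.random.default_rng(100 + seed)
            genes = list(rng2.choice(universe, size=200, replace=False))
            res = run_gene_set_analysis(genes, coll, min_overlap=0)
            sig += int((res["p"] < 0.05).sum())
            total += len(res)
        assert sig / total < 0.10

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            run_gene_set_analysis([], _collection({"A": ["G1"]}))

    def test_background_membership_enforced(self):
        coll = GeneSetCollection({"A": frozenset({"G1", "G2", "G3", "G4", "G5"})},
                                 background_size=10,
                                 background=frozenset(f"G{i}" for i in range(10)))
        res = run_gene_set_analysis(["G1", "G2", "G3", "G4", "G5", "NOTHERE"],
                                    coll, min_overlap=2)
        assert res.loc[0, "n_input"] == 5  # outsider dropped


class TestProteinGeneMapping:
    def test_one_to_one(self):
        mapping = {"P1": ("G1",), "P2": ("G2",)}
        assert map_proteins_to_genes(["P1", "P2"], mapping) == ["G1", "G2"]

    def test_one_to_many_and_dedup(self):
        mapping = {"P1": ("G1", "G2"), "P2": ("G2",)}
        genes = map_proteins_to_genes(["P1", "P2"], mapping)
        assert genes == ["G1", "G2"]

    def test_matches_set_union_oracle(self):
        rng = np.random.default_rng(5)
        mapping = {f"P{i}": tuple(f"G{g}" for g in rng.integers(0, 40, rng.integers(1, 4)))
                   for i in range(30)}
        chosen = [f"P{i}" for i in range(0, 30, 2)]
        got = map_proteins_to_genes(chosen, mapping)
        assert set(got) == set(itertools.chain.from_iterable(
            mapping[p] for p in chosen))

    def test_unmapped_protein_rejected(self):
        with pytest.raises(ValueError):
            map_proteins_to_genes(["PX"], {"P1": ("G1",)})
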