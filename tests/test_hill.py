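"""Hill numbers, gamma/alpha/beta decomposition and coverage-standardised
pair similarity."""

import itertools
import warnings

import numpy as np
import pandas as pd
import pytest

from betadecay import _rarefy
from betadecay.dataset import UnitIncidence
from betadecay.hill import (
    hill_at_effort,
    hill_incidence,
    pair_decompose,
    pairwise_similarity,
    similarity_matrices,
    sorensen_transform,
    standardized_pair_similarity,
)
from betadecay.incidence import IncidenceAssemblage

from conftest import random_unit_matrix


class TestHillIncidence:
    def test_order_zero_is_observed_richness(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            asm = IncidenceAssemblage.from_units(random_unit_matrix(rng, 9, 8))
            assert hill_incidence(asm, 0) == asm.S_obs

    def test_even_two_species_gives_two_at_q1(self):
        asm = IncidenceAssemblage(T=4, Y=np.array([2, 2]))
        assert hill_incidence(asm, 1) == pytest.approx(2.0, abs=1e-12)

    def test_worked_q2(self):
        # pi = (1/4, 1/4, 1/2): 1 / sum(pi^2) = 1/0.375
        asm = IncidenceAssemblage(T=4, Y=np.array([1, 1, 2]))
        assert hill_incidence(asm, 2) == pytest.approx(1 / 0.375, abs=1e-12)

    def test_evenness_property_all_orders_equal(self):
        asm = IncidenceAssemblage(T=8, Y=np.array([3, 3, 3, 3]))
        vals = [hill_incidence(asm, q) for q in (0, 1, 2)]
        assert np.allclose(vals, vals[0], atol=1e-12)

    def test_cross_check_against_skbio(self):
        """Independent route: exp(Shannon) and inverse Simpson from
        scikit-bio on the relative incidence frequencies."""
        from skbio.diversity.alpha import dominance, shannon

        rng = np.random.default_rng(1)
        for _ in range(5):
            asm = IncidenceAssemblage.from_units(random_unit_matrix(rng, 12, 8))
            counts = asm.Y[asm.Y > 0]
            assert hill_incidence(asm, 1) == pytest.approx(
                np.exp(shannon(counts, base=np.e)), rel=1e-10
            )
            assert hill_incidence(asm, 2) == pytest.approx(
                1.0 / dominance(counts), rel=1e-10
            )


class TestSorensenTransform:
    @pytest.mark.parametrize("q", [0, 1, 2])
    @pytest.mark.parametrize("variant", ["sorensen", "jaccard"])
    def test_endpoints(self, q, variant):
        assert sorensen_transform(1.0, q, 2, variant) == pytest.approx(1.0)
        assert sorensen_transform(2.0, q, 2, variant) == pytest.approx(0.0)

    def test_worked_case(self):
        assert sorensen_transform(4 / 3, 0, 2) == pytest.approx(2 / 3, abs=1e-12)
        # Jaccard-type counterpart of the same decomposition: 2/4
        assert sorensen_transform(4 / 3, 0, 2, "jaccard") == pytest.approx(
            0.5, abs=1e-12
        )

    def test_decreasing_in_beta(self):
        for q in (0, 1, 2):
            vals = [sorensen_transform(b, q, 2) for b in np.linspace(1, 2, 11)]
            assert np.all(np.diff(vals) < 0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            sorensen_transform(0.9, 0, 2)
        with pytest.raises(ValueError):
            sorensen_transform(2.1, 2, 2)


class TestPairDecompose:
    @pytest.mark.parametrize("q", [0, 1, 2])
    def test_identical_assemblages(self, q):
        rng = np.random.default_rng(2)
        asm = IncidenceAssemblage.from_units(random_unit_matrix(rng, 10, 8))
        d = pair_decompose(asm, asm, q)
        assert d.beta == pytest.approx(1.0, abs=1e-9)
        assert d.similarity == pytest.approx(1.0, abs=1e-9)

    def test_disjoint_complete_turnover(self):
        A = IncidenceAssemblage(T=4, Y=np.array([2, 2, 0, 0]))
        B = IncidenceAssemblage(T=4, Y=np.array([0, 0, 2, 2]))
        d = pair_decompose(A, B, 0)
        assert d.beta == pytest.approx(2.0, abs=1e-12)
        assert d.similarity == pytest.approx(0.0, abs=1e-12)

    def test_worked_sorensen_case(self):
        # 2 shared + 1 unique species each, all singletons:
        # gamma=4, alpha=3, beta=4/3, C_02 = 2a/(2a+b+c) = 4/6
        A = IncidenceAssemblage(T=4, Y=np.array([1, 1, 1, 0]))
        B = IncidenceAssemblage(T=4, Y=np.array([1, 1, 0, 1]))
        d = pair_decompose(A, B, 0)
        assert (d.gamma, d.alpha) == (4.0, 3.0)
        assert d.beta == pytest.approx(4 / 3, abs=1e-12)
        assert d.similarity == pytest.approx(2 / 3, abs=1e-12)

    def test_both_empty_rejected(self):
        empty = IncidenceAssemblage(T=4, Y=np.zeros(3, dtype=int))
        with pytest.raises(ValueError):
            pair_decompose(empty, empty, 0)

    def test_beta_bounded(self):
        rng = np.random.default_rng(3)
        for q in (0, 1, 2):
            for _ in range(10):
                A = IncidenceAssemblage.from_units(random_unit_matrix(rng, 8, 6))
                B = IncidenceAssemblage.from_units(random_unit_matrix(rng, 8, 6))
                d = pair_decompose(A, B, q)
                assert 1.0 - 1e-9 <= d.beta <= 2.0 + 1e-9


class TestHillAtEffort:
    def test_rarefied_matches_expected_count_enumeration(self):
        """For T <= 4 and <= 5 species, the rarefied Hill numbers equal the
        Hill numbers of the exact expected frequency counts obtained by
        enumerating every unit subset, to 1e-12."""
        rng = np.random.default_rng(4)
        for _ in range(10):
            T = int(rng.integers(3, 5))
            X = random_unit_matrix(rng, int(rng.integers(1, 6)), T, p=0.6)
            asm = IncidenceAssemblage.from_units(X)
            U = asm.U
            for t in range(1, T + 1):
                subs = list(itertools.combinations(range(T), t))
                EQ = np.zeros(T + 1)
                for c in subs:
                    ys = X[:, list(c)].sum(axis=1)
                    for y in ys[ys > 0]:
                        EQ[y] += 1
                EQ /= len(subs)
                Ut = t * U / T
                j = np.arange(1, T + 1)
                d0 = EQ[1:].sum()
                d1 = np.exp(np.log(Ut) - (EQ[1:] * j * np.log(j)).sum() / Ut)
                d2 = Ut**2 / (EQ[1:] * j**2).sum()
                assert hill_at_effort(asm, 0, t) == pytest.approx(d0, abs=1e-12)
                assert hill_at_effort(asm, 1, t) == pytest.approx(d1, abs=1e-12)
                assert hill_at_effort(asm, 2, t) == pytest.approx(d2, abs=1e-12)

    def test_full_effort_reproduces_observed_hill(self):
        rng = np.random.default_rng(5)
        for q in (0, 1, 2):
            for _ in range(5):
                asm = IncidenceAssemblage.from_units(random_unit_matrix(rng, 15, 12))
                assert hill_at_effort(asm, q, asm.T) == pytest.approx(
                    hill_incidence(asm, q), rel=1e-12
                )

    def test_monotone_in_effort_across_extrapolation(self):
        rng = np.random.default_rng(6)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            for _ in range(10):
                asm = IncidenceAssemblage.from_units(
                    random_unit_matrix(rng, 25, 16, p=0.2)
                )
                ts = np.linspace(1, 2.4 * asm.T, 40)
                for q in (0, 1, 2):
                    vals = [hill_at_effort(asm, q, t) for t in ts]
                    assert np.all(np.diff(vals) >= -1e-9)

    def test_far_extrapolation_warns(self):
        asm = IncidenceAssemblage(T=4, Y=np.array([1, 1, 2]))
        with pytest.warns(RuntimeWarning):
            hill_at_effort(asm, 0, 12)


class TestStandardizedPairSimilarity:
    @pytest.mark.parametrize("q", [0, 1, 2])
    @pytest.mark.parametrize("C", [0.5, 0.7, 0.9])
    def test_identical_plots_similarity_one(self, q, C):
        rng = np.random.default_rng(7)
        X = random_unit_matrix(rng, 14, 16, p=0.25)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            s = standardized_pair_similarity(X, X, q, C)
        assert s == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("q", [0, 1, 2])
    def test_disjoint_plots_similarity_zero(self, q):
        rng = np.random.default_rng(8)
        XA = np.zeros((20, 16), np.uint8)
        XB = np.zeros((20, 16), np.uint8)
        XA[:10] = random_unit_matrix(rng, 10, 16, p=0.3)
        XB[10:] = random_unit_matrix(rng, 10, 16, p=0.3)
        s = standardized_pair_similarity(XA, XB, q, 0.6)
        assert s == pytest.approx(0.0, abs=1e-9)

    def test_consistency_with_unstandardised_at_observed_coverage(self):
        """With the coverage target set to the pooled sample's own
        coverage, standardisation is a no-op: the similarity equals the
        plain gamma/alpha decomposition (pair without same-unit
        co-detections, where the two pooling conventions coincide)."""
        rng = np.random.default_rng(9)
        T = 16
        XA = np.zeros((14, T), np.uint8)
        XB = np.zeros((14, T), np.uint8)
        XA[:9, :8] = (rng.random((9, 8)) < 0.22).astype(np.uint8)
        XB[5:, 8:] = (rng.random((9, 8)) < 0.22).astype(np.uint8)
        gh = _rarefy.freq_histogram((XA | XB).sum(axis=1), T)
        C_pool = float(_rarefy.coverage_at(gh, T, float(T))[0])
        assert 0 < C_pool < 1
        A = IncidenceAssemblage(T=T, Y=XA.sum(axis=1))
        B = IncidenceAssemblage(T=T, Y=XB.sum(axis=1))
        for q in (0, 1, 2):
            s_std = standardized_pair_similarity(XA, XB, q, C_pool)
            s_raw = pair_decompose(A, B, q).similarity
            assert s_std == pytest.approx(s_raw, abs=1e-6)

    def test_gamma_alpha_monotone_in_coverage_target(self):
        """Raising the coverage target toward the asymptote never
        decreases the standardised gamma or alpha components."""
        rng = np.random.default_rng(10)
        XA = random_unit_matrix(rng, 30, 16, p=0.12)
        XB = random_unit_matrix(rng, 30, 16, p=0.12)
        gh, ah = np.array([]), np.array([])
        from betadecay.hill import _pair_hists

        gh, ah = _pair_hists(XA.astype(bool), XB.astype(bool), 16)
        targets = np.linspace(0.4, 0.97, 15)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            for q in (0, 1, 2):
                gammas, alphas = [], []
                for C in targets:
                    t, _ = _rarefy.effort_for_coverage_hist(gh, 16, C)
                    gammas.append(_rarefy.hill_at_effort_hist(gh, 16, t, q)[0])
                    alphas.append(_rarefy.hill_at_effort_hist(ah, 16, t, q)[0])
                assert np.all(np.diff(gammas) >= -1e-9)
                assert np.all(np.diff(alphas) >= -1e-9)


class TestPairwiseEngine:
    def _random_incidence(self, seed, S=25, P=6, T=16, p=0.2):
        rng = np.random.default_rng(seed)
        det = (rng.random((S, P, T)) < p).astype(np.uint8)
        det[:, :, 0] = 1  # keep every plot non-empty
        return UnitIncidence(
            det,
            species=pd.Index([f"s{i}" for i in range(S)]),
            plots=pd.Index([f"p{j}" for j in range(P)]),
        )

    def test_matches_scalar_path(self):
        inc = self._random_incidence(11)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mats = pairwise_similarity(inc, q_list=(0, 1, 2), C_target=0.75)
            for q in (0, 1, 2):
                for i in range(3):
                    for j in range(i + 1, 4):
                        s = standardized_pair_similarity(
                            inc.detections[:, i, :], inc.detections[:, j, :], q, 0.75
                        )
                        assert mats[q].iloc[i, j] == pytest.approx(s, abs=1e-10)

    def test_matrix_is_symmetric_unit_diagonal_bounded(self):
        inc = self._random_incidence(12, P=8)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mats = pairwise_similarity(inc, q_list=(0, 1, 2), C_target=0.7)
        for q, m in mats.items():
            v = m.to_numpy()
            assert np.allclose(v, v.T)
            assert np.allclose(np.diag(v), 1.0)
            assert v.min() >= -1e-12 and v.max() <= 1 + 1e-12

    def test_plot_permutation_equivariance(self):
        inc = self._random_incidence(13, P=7)
        perm = [3, 0, 6, 2, 5, 1, 4]
        permuted = inc.select_plots(inc.plots[perm])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            m0 = pairwise_similarity(inc, q_list=(0,), C_target=0.7)[0]
            m1 = pairwise_similarity(permuted, q_list=(0,), C_target=0.7)[0]
        reindexed = m0.loc[m1.index, m1.columns]
        np.testing.assert_allclose(m1.to_numpy(), reindexed.to_numpy(), atol=1e-12)


class TestSimilarityMatrices:
    def test_default_configuration_yields_21_matrices(self, small_dataset):
        meta, inc, _pool, traits = small_dataset
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mats = similarity_matrices(inc, traits=traits)
        assert len(mats) == 21
        labels = {(m.subset, m.q) for m in mats}
        assert len(labels) == 21
        assert {m.C_target for m in mats if m.subset == "all"} == {0.8}
        assert {m.C_target for m in mats if m.subset != "all"} == {0.7}

    def test_single_subset_single_order(self, small_dataset):
        _meta, inc, _pool, _traits = small_dataset
        mats = similarity_matrices(inc, subsets={"all": None}, q_list=(0,))
        assert len(mats) == 1 and mats[0].subset == "all"

    def test_sparse_subset_skipped(self, small_dataset):
        _meta, inc, _pool, _traits = small_dataset
        # a subset with no detections anywhere cannot form a matrix
        ghost = {"ghost": pd.Index([])}
        mats = similarity_matrices(inc, subsets=ghost, q_list=(0,))
        assert mats == []
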