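"""Block assembly, transition normalisation and restart propagation."""

import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from conftest import planted_config
from heteroprop.domains import build_domain_matrix, build_domain_similarity
from heteroprop.io import DomainAssociationTable
from heteroprop.ppi_weights import TopologyParams, WeightedPPIMatrix, build_weighted_ppi
from heteroprop.propagation import (
    assemble_hbm,
    build_transition,
    initial_scores,
    propagate,
    solve_stationary,
)
from heteroprop.simulate import generate_dataset


def _instance_from_config(cfg):
    graph, catalog, table, _ = generate_dataset(cfg)
    mpp = build_weighted_ppi(graph, catalog, TopologyParams())
    mpd = build_domain_matrix(table, graph.proteins)
    mdd = build_domain_similarity(mpp, mpd)
    return assemble_hbm(mpp, mpd, mdd)


def _random_instance(seed, n_proteins=6, n_domains=3):
    rng = np.random.default_rng(seed)
    proteins = tuple(f"P{i}" for i in range(n_proteins))
    w = rng.random((n_proteins, n_proteins)) * (rng.random((n_proteins, n_proteins)) < 0.5)
    w = np.triu(w, 1)
    w = w + w.T
    mpp = WeightedPPIMatrix(proteins, sp.csr_matrix(w))
    records = []
    for j in range(n_domains):
        members = rng.choice(n_proteins, size=int(rng.integers(1, 4)), replace=False)
        for i in members:
            records.append((proteins[i], f"PF{j}"))
    mpd = build_domain_matrix(DomainAssociationTable(tuple(records)), proteins)
    mdd = build_domain_similarity(mpp, mpd)
    return assemble_hbm(mpp, mpd, mdd)


class TestAssembly:
    def test_block_layout_tiny(self):
        proteins = ("u", "v")
        mpp = WeightedPPIMatrix(proteins, sp.csr_matrix(np.array([[0, 0.5], [0.5, 0]])))
        mpd = build_domain_matrix(DomainAssociationTable((("u", "d1"),)), proteins)
        mdd = build_domain_similarity(mpp, mpd)
        hbm = assemble_hbm(mpp, mpd, mdd)
        dense = hbm.combined().toarray()
        assert dense.shape == (3, 3)
        np.testing.assert_allclose(dense, dense.T)
        assert dense[0, 2] == 1.0 and dense[1, 2] == 0.0

    def test_combined_equals_blockwise_placement(self):
        hbm = _random_instance(5)
        dense = hbm.combined().toarray()
        n_p = hbm.n_proteins
        np.testing.assert_allclose(dense[:n_p, :n_p], hbm.mpp.matrix.toarray())
        np.testing.assert_allclose(dense[:n_p, n_p:], hbm.mpd.incidence.toarray())
        np.testing.assert_allclose(dense[n_p:, :n_p], hbm.mpd.incidence.toarray().T)
        np.testing.assert_allclose(dense[n_p:, n_p:], hbm.mdd.values)

    def test_index_mismatch_rejected(self):
        hbm = _random_instance(5)
        other = _random_instance(6, n_proteins=4)
        with pytest.raises(ValueError):
            assemble_hbm(hbm.mpp, other.mpd, hbm.mdd)


class TestTransition:
    def test_equal_weight_neighbours_with_one_domain(self):
        # protein u: two equal-weight neighbours and one domain, lambda=0.2
        proteins = ("u", "v", "w")
        w = np.array([[0, 0.5, 0.5], [0.5, 0, 0], [0.5, 0, 0]])
        mpp = WeightedPPIMatrix(proteins, sp.csr_matrix(w))
        mpd = build_domain_matrix(DomainAssociationTable((("u", "d1"),)), proteins)
        mdd = build_domain_similarity(mpp, mpd)
        t = build_transition(assemble_hbm(mpp, mpd, mdd), 0.2).matrix.toarray()
        np.testing.assert_allclose(t[0], [0.0, 0.4, 0.4, 0.2])
        assert t[0].sum() == pytest.approx(1.0)

    def test_protein_without_domain_keeps_full_mass(self):
        proteins = ("u", "v", "w")
        w = np.array([[0, 0.3, 0.7], [0.3, 0, 0], [0.7, 0, 0]])
        mpp = WeightedPPIMatrix(proteins, sp.csr_matrix(w))
        mpd = build_domain_matrix(DomainAssociationTable((("v", "d1"),)), proteins)
        mdd = build_domain_similarity(mpp, mpd)
        t = build_transition(assemble_hbm(mpp, mpd, mdd), 0.2).matrix.toarray()
        assert t[0, :3].sum() == pytest.approx(1.0)
        np.testing.assert_allclose(t[0, :3], [0.0, 0.3, 0.7])

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_per_row_normalisation_oracle(self, seed):
        hbm = _random_instance(seed)
        lam = 0.2
        t = build_transition(hbm, lam).matrix.toarray()
        expected = oracles.naive_transition(
            hbm.mpp.matrix.toarray(),
            hbm.mpd.incidence.toarray(),
            hbm.mdd.values,
            lam,
        )
        np.testing.assert_allclose(t, expected, atol=1e-12)

    def test_bad_lambda_rejected(self):
        hbm = _random_instance(0)
        with pytest.raises(ValueError):
            build_transition(hbm, 1.5)

    def test_negative_weights_rejected(self):
        proteins = ("u", "v")
        mpp = WeightedPPIMatrix(proteins, sp.csr_matrix(np.array([[0, -0.5], [-0.5, 0]])))
        mpd = build_domain_matrix(DomainAssociationTable((("u", "d1"),)), proteins)
        mdd = build_domain_similarity(
            WeightedPPIMatrix(proteins, sp.csr_matrix((2, 2))), mpd
        )
        with pytest.raises(ValueError):
            build_transition(assemble_hbm(mpp, mpd, mdd), 0.2)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(seed=st.integers(0, 10_000), lam=st.floats(0.0, 1.0))
    def test_row_sum_law_on_planted_instances(self, seed, lam):
        hbm = _instance_from_config(planted_config(seed=seed))
        t = build_transition(hbm, lam)
        sums = t.row_sums()
        assert np.all((np.abs(sums - 1) < 1e-9) | (np.abs(sums) < 1e-12))
        # protein rows with >=1 domain place exactly lam in the domain block
        dom_mass = np.asarray(
            t.matrix[: t.n_proteins, t.n_proteins :].sum(axis=1)
        ).ravel()
        has_dom = (
            np.asarray(hbm.mpd.incidence.sum(axis=1)).ravel() > 0
        )
        np.testing.assert_allclose(dom_mass[has_dom], lam, atol=1e-9)
        np.testing.assert_allclose(dom_mass[~has_dom], 0.0, atol=1e-12)


class TestInitialScores:
    def test_domain_scores_are_max_over_protein_list(self):
        proteins = ("u", "v", "w")
        w = np.array([[0, 0.9, 0.2], [0.9, 0, 0], [0.2, 0, 0]])
        mpp = WeightedPPIMatrix(proteins, sp.csr_matrix(w))
        mpd = build_domain_matrix(
            DomainAssociationTable((("v", "d1"), ("w", "d1"), ("w", "d2"))), proteins
        )
        pr0 = initial_scores(mpp, mpd, "u")
        np.testing.assert_allclose(pr0, [0.0, 0.9, 0.2, 0.9, 0.2])

    def test_domain_with_no_scored_proteins_gets_zero(self):
        proteins = ("u", "v", "w")
        w = np.array([[0, 0.9, 0], [0.9, 0, 0], [0, 0, 0]])
        mpp = WeightedPPIMatrix(proteins, sp.csr_matrix(w))
        mpd = build_domain_matrix(DomainAssociationTable((("w", "d1"),)), proteins)
        pr0 = initial_scores(mpp, mpd, "u")
        assert pr0[-1] == 0.0

    @pytest.mark.parametrize("seed", [4, 8])
    def test_matches_direct_evaluation(self, seed):
        hbm = _random_instance(seed, n_proteins=8, n_domains=4)
        for u_idx, u in enumerate(hbm.mpp.proteins):
            pr0 = initial_scores(hbm.mpp, hbm.mpd, u)
            expected = oracles.naive_initial_scores(
                hbm.mpp.matrix.toarray(), hbm.mpd.incidence.toarray(), u_idx
            )
            np.testing.assert_allclose(pr0, expected)

    def test_unknown_protein_raises(self):
        hbm = _random_instance(4)
        with pytest.raises(KeyError):
            initial_scores(hbm.mpp, hbm.mpd, "nope")


class TestPropagation:
    def test_gamma_one_returns_restart_vector(self):
        hbm = _random_instance(1)
        t = build_transition(hbm, 0.2)
        pr0 = initial_scores(hbm.mpp, hbm.mpd, hbm.mpp.proteins[0])
        sv = propagate(t, pr0, gamma=1.0)
        assert sv.converged and sv.iterations == 1
        np.testing.assert_allclose(sv.values, pr0)

    def test_symmetric_pair_gets_equal_scores(self):
        proteins = ("a", "b")
        w = np.array([[0, 0.5], [0.5, 0]])
        mpp = WeightedPPIMatrix(proteins, sp.csr_matrix(w))
        mpd = build_domain_matrix(
            DomainAssociationTable((("a", "d"), ("b", "d"))), proteins
        )
        mdd = build_domain_similarity(mpp, mpd)
        t = build_transition(assemble_hbm(mpp, mpd, mdd), 0.2)
        pr0 = np.array([0.5, 0.5, 0.5])
        sv = propagate(t, pr0, gamma=0.5)
        assert sv.values[0] == pytest.approx(sv.values[1])

    def test_zero_restart_vector_stays_zero(self):
        hbm = _random_instance(2)
        t = build_transition(hbm, 0.2)
        sv = propagate(t, np.zeros(t.n_nodes), gamma=0.5)
        np.testing.assert_allclose(sv.values, 0.0)

    def test_max_iter_reported_not_raised(self):
        hbm = _random_instance(2)
        t = build_transition(hbm, 0.2)
        pr0 = initial_scores(hbm.mpp, hbm.mpd, hbm.mpp.proteins[0])
        sv = propagate(t, pr0, gamma=0.01, epsilon=1e-300, max_iter=3)
        assert not sv.converged and sv.iterations == 3

    def test_negative_restart_rejected(self):
        hbm = _random_instance(2)
        t = build_transition(hbm, 0.2)
        with pytest.raises(ValueError):
            propagate(t, -np.ones(t.n_nodes))

    @pytest.mark.parametrize("seed", [0, 3, 7])
    @pytest.mark.parametrize("orientation", ["row", "column"])
    def test_iteration_agrees_with_linear_solve(self, seed, orientation):
        hbm = _random_instance(seed, n_proteins=8, n_domains=3)
        t = build_transition(hbm, 0.2)
        pr0 = initial_scores(hbm.mpp, hbm.mpd, hbm.mpp.proteins[0])
        it = propagate(t, pr0, gamma=0.5, epsilon=1e-12, orientation=orientation)
        ex = solve_stationary(t, pr0, gamma=0.5, orientation=orientation)
        assert np.abs(it.values - ex.values).sum() < 1e-8

    def test_solve_degenerate_cases(self):
        hbm = _random_instance(1)
        t = build_transition(hbm, 0.2)
        pr0 = initial_scores(hbm.mpp, hbm.mpd, hbm.mpp.proteins[0])
        np.testing.assert_allclose(solve_stationary(t, pr0, gamma=1.0).values, pr0)
        zero_t = build_transition(hbm, 0.2)
        zero_t.matrix = sp.csr_matrix(t.matrix.shape)
        np.testing.assert_allclose(
            solve_stationary(zero_t, pr0, gamma=0.5).values, 0.5 * pr0
        )
        with pytest.raises(ValueError):
            solve_stationary(t, pr0, gamma=0.0)

    def test_contraction_bound_on_iteration_count(self):
        gamma, eps = 0.5, 1e-6
        for seed in range(5):
            hbm = _random_instance(seed, n_proteins=10, n_domains=4)
            t = build_transition(hbm, 0.2)
            pr0 = initial_scores(hbm.mpp, hbm.mpd, hbm.mpp.proteins[0])
            sv = propagate(t, pr0, gamma=gamma, epsilon=eps)
            assert sv.converged
            first = (1 - gamma) * (t.matrix @ pr0) + gamma * pr0
            d1 = np.abs(first - pr0).sum()
            if d1 < eps:
                assert sv.iterations == 1
            else:
                bound = np.log(eps / d1) / np.log(1 - gamma) + 2
                assert sv.iterations <= bound
            # successive L1 differences contract by at least (1 - gamma)
            prev = pr0
            cur = first
            last_diff = d1
            for _ in range(5):
                nxt = (1 - gamma) * (t.matrix @ cur) + gamma * pr0
                diff = np.abs(nxt - cur).sum()
                assert diff <= (1 - gamma) * last_diff + 1e-15
                prev, cur, last_diff = cur, nxt, diff
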