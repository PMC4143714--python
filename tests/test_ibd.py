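"""Conditional genotype-pair probabilities, EM MLE and moment estimator."""

import itertools

import numpy as np
import pytest

from kinscan import ibd, simulate
from kinscan.ibd import (IBDVector, PairGenotypeData, em_mle, em_mle_batch,
                         genotype_pair_prob, kinship_from_ibd, loglik,
                         mom_estimate, pair_prob_table)


def brute_force_pair_prob(g1, g2, d, q):
    """Oracle: enumerate ordered allele configurations under HWE.

    Individual 1 carries ordered alleles (a1, a2), individual 2
    (b1, b2); d of individual 2's allele slots are copies of the
    corresponding slots of individual 1, the rest drawn independently.
    Alleles are 1 (minor, prob q) or 0 (major).
    """
    p = 1.0 - q
    prob = 0.0
    for a1, a2 in itertools.product((0, 1), repeat=2):
        pa = (q if a1 else p) * (q if a2 else p)
        if d == 2:
            configs = [((a1, a2), pa)]
        elif d == 1:
            # the shared allele may sit in either slot of either member
            configs = []
            for b_new in (0, 1):
                pb = q if b_new else p
                for shared in (a1, a2):
                    for order in ((shared, b_new), (b_new, shared)):
                        configs.append(((order), pa * pb * 0.25))
        else:
            configs = [((b1, b2), pa * (q if b1 else p) * (q if b2 else p))
                       for b1, b2 in itertools.product((0, 1), repeat=2)]
        for (b1, b2), pr in configs:
            if a1 + a2 == g1 and b1 + b2 == g2:
                prob += pr
    return prob


class TestGenotypePairProb:
    @pytest.mark.parametrize("q", [0.1, 0.3, 0.5])
    @pytest.mark.parametrize("d", [0, 1, 2])
    def test_matches_allele_enumeration_oracle(self, d, q):
        for g1 in (0, 1, 2):
            for g2 in (0, 1, 2):
                assert genotype_pair_prob(g1, g2, d, q) == pytest.approx(
                    brute_force_pair_prob(g1, g2, d, q), abs=1e-12)

    @pytest.mark.parametrize("d", [0, 1, 2])
    def test_normalization(self, d):
        total = sum(genotype_pair_prob(g1, g2, d, 0.3)
                    for g1 in (0, 1, 2) for g2 in (0, 1, 2))
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_opposite_homozygotes_need_ibd_zero(self):
        for d in (1, 2):
            assert genotype_pair_prob(2, 0, d, 0.37) == 0.0
        assert genotype_pair_prob(2, 2, 0, 0.5) == pytest.approx(0.0625)

    def test_monomorphic_frequency_rejected(self):
        with pytest.raises(ibd.MonomorphicMarkerError):
            genotype_pair_prob(0, 0, 0, 0.0)

    def test_table_layout_consistent_with_scalar(self):
        q = np.array([0.2, 0.45])
        table = pair_prob_table(q)
        for m, qm in enumerate(q):
            for g1, g2, d in itertools.product((0, 1, 2), (0, 1, 2), (0, 1, 2)):
                assert table[m, 3 * g1 + g2, d] == pytest.approx(
                    genotype_pair_prob(g1, g2, d, qm), abs=1e-15)


class TestLoglik:
    def test_single_marker_hand_values(self):
        pair = PairGenotypeData([2], [2], [0.5])
        assert loglik(pair, (1, 0, 0)) == pytest.approx(np.log(0.0625))
        assert loglik(pair, (0, 0, 1)) == pytest.approx(np.log(0.25))

    def test_mixture_between_endpoints(self):
        pair = PairGenotypeData([2], [2], [0.5])
        lo = loglik(pair, (1, 0, 0))
        hi = loglik(pair, (0, 0, 1))
        mid = loglik(pair, (0.5, 0, 0.5))
        assert lo < mid < hi

    def test_impossible_relationship_is_minus_inf(self):
        pair = PairGenotypeData([2], [0], [0.3])  # opposite homozygotes
        assert loglik(pair, (0, 1, 0)) == -np.inf
        assert np.isfinite(loglik(pair, (1, 0, 0)))

    def test_no_data_error(self):
        with pytest.raises(ibd.NoDataError):
            loglik(PairGenotypeData([], [], []), (1, 0, 0))


def _simplex_grid(step=0.001):
    p0 = np.arange(0.0, 1.0 + step / 2, step)
    grid = []
    for a in p0:
        b = np.arange(0.0, 1.0 - a + step / 2, step)
        g = np.empty((b.size, 3))
        g[:, 0] = a
        g[:, 1] = b
        g[:, 2] = np.clip(1.0 - a - b, 0.0, None)
        grid.append(g)
    return np.concatenate(grid)


class TestEM:
    def test_duplicate_pair_hits_mz_vertex(self):
        freqs = simulate.draw_marker_freqs(3000, 11)
        rng = np.random.default_rng(12)
        g = ((rng.random(3000) < freqs).astype(np.int8)
             + (rng.random(3000) < freqs).astype(np.int8))
        res = em_mle(PairGenotypeData(g, g.copy(), freqs))
        assert np.allclose(np.asarray(res.ibd), (0, 0, 1), atol=5e-5)
        assert res.converged

    def test_single_marker_opposite_homozygotes(self):
        res = em_mle(PairGenotypeData([2], [0], [0.4]))
        assert res.ibd.p0 == pytest.approx(1.0, abs=1e-6)

    def test_loglik_monotone_every_iteration(self):
        rng = np.random.default_rng(4)
        freqs = simulate.draw_marker_freqs(300, 5)
        g1, g2 = simulate.simulate_pair_unlinked((0.4, 0.35, 0.25), freqs, seed=6)
        pair = PairGenotypeData(g1, g2, freqs)
        lls = []
        p = np.array([1 / 3] * 3)
        for _ in range(60):
            lls.append(loglik(pair, p))
            res = em_mle(pair, init=p, max_iter=1, tol=0.0)
            p = np.asarray(res.ibd)
        assert all(b - a > -1e-10 for a, b in zip(lls, lls[1:]))

    @pytest.mark.parametrize("truth,seed", [((1, 0, 0), 0), ((0.25, 0.5, 0.25), 1),
                                            ((0.5, 0.5, 0), 2)])
    def test_matches_grid_search_oracle(self, truth, seed):
        freqs = simulate.draw_marker_freqs(200, 100 + seed)
        g1, g2 = simulate.simulate_pair_unlinked(truth, freqs, seed=200 + seed)
        pair = PairGenotypeData(g1, g2, freqs)
        res = em_mle(pair)
        grid = _simplex_grid(0.001)
        c = ibd._cond_probs(pair)  # (M, 3)
        best, best_ll = None, -np.inf
        for lo in range(0, len(grid), 50_000):  # chunked: full grid is ~500k points
            chunk = grid[lo:lo + 50_000]
            with np.errstate(divide="ignore"):
                lls = np.log(chunk @ c.T).sum(axis=1)
            k = int(np.argmax(lls))
            if lls[k] > best_ll:
                best_ll, best = lls[k], chunk[k]
        assert np.max(np.abs(np.asarray(res.ibd) - best)) < 0.003

    def test_invariant_to_swap_and_permutation(self):
        freqs = simulate.draw_marker_freqs(800, 21)
        g1, g2 = simulate.simulate_pair_unlinked((0.5, 0.5, 0), freqs, seed=22)
        a = em_mle(PairGenotypeData(g1, g2, freqs))
        b = em_mle(PairGenotypeData(g2, g1, freqs))
        perm = np.random.default_rng(23).permutation(800)
        c = em_mle(PairGenotypeData(g1[perm], g2[perm], freqs[perm]))
        assert np.allclose(np.asarray(a.ibd), np.asarray(b.ibd), atol=1e-9)
        assert np.allclose(np.asarray(a.ibd), np.asarray(c.ibd), atol=1e-9)

    def test_batch_agrees_with_scalar(self):
        rng = np.random.default_rng(31)
        M = 1500
        freqs = simulate.draw_marker_freqs(M, 30)
        table = pair_prob_table(freqs)
        conds, masks, pairs = [], [], []
        for i, truth in enumerate([(1, 0, 0), (0.25, 0.5, 0.25), (0, 1, 0),
                                   (0.75, 0.25, 0)]):
            g1, g2 = simulate.simulate_pair_unlinked(truth, freqs, seed=40 + i)
            pairs.append(PairGenotypeData(g1, g2, freqs))
            cat = 3 * g1.astype(np.intp) + g2.astype(np.intp)
            conds.append(table[np.arange(M), cat, :])
            masks.append(np.ones(M, bool))
        p, ll, _ = em_mle_batch(np.stack(conds), np.stack(masks))
        for k, pair in enumerate(pairs):
            ref = em_mle(pair, max_iter=5000)
            assert np.max(np.abs(p[k] - np.asarray(ref.ibd))) < 2e-3
            assert ll[k] == pytest.approx(ref.loglik, abs=2e-3)

    def test_bad_init_rejected(self):
        pair = PairGenotypeData([1], [1], [0.3])
        with pytest.raises(ValueError):
            em_mle(pair, init=(1, 0, 0))


class TestMoM:
    def test_identical_genotypes(self):
        freqs = simulate.draw_marker_freqs(2000, 50)
        rng = np.random.default_rng(51)
        g = ((rng.random(2000) < freqs).astype(np.int8)
             + (rng.random(2000) < freqs).astype(np.int8))
        res = mom_estimate(PairGenotypeData(g, g.copy(), freqs))
        assert res.ibd.p2 == pytest.approx(1.0, abs=1e-9)

    def test_unrelated_pair_recovers_p0(self):
        freqs = simulate.draw_marker_freqs(50_000, 52)
        g1, g2 = simulate.simulate_pair_unlinked((1, 0, 0), freqs, seed=53)
        res = mom_estimate(PairGenotypeData(g1, g2, freqs))
        assert abs(res.ibd.p0 - 1.0) < 0.05

    def test_raw_unconstrained_truncated_on_simplex(self):
        freqs = simulate.draw_marker_freqs(500, 54)
        g1, g2 = simulate.simulate_pair_unlinked((1, 0, 0), freqs, seed=55)
        res = mom_estimate(PairGenotypeData(g1, g2, freqs))
        est = np.asarray(res.ibd)
        assert est.sum() == pytest.approx(1.0)
        assert np.all(est >= 0)

    def test_near_monomorphic_warns(self):
        pair = PairGenotypeData([0, 0], [0, 0], [1e-6, 1e-6])
        with pytest.warns(UserWarning, match="ill-conditioned"):
            mom_estimate(pair)


class TestKinshipFromIBD:
    @pytest.mark.parametrize("vec,phi", [((0, 1, 0), 0.25), ((1, 0, 0), 0.0),
                                         ((0.375, 0.5, 0.125), 0.1875),
                                         ((0, 0, 1), 0.5)])
    def test_catalog_values(self, vec, phi):
        assert kinship_from_ibd(vec) == pytest.approx(phi, abs=1e-15)


class TestIBDVector:
    def test_validation(self):
        v = IBDVector.from_array([0.25, 0.5, 0.25])
        assert v.p1 == 0.5
        with pytest.raises(ValueError):
            IBDVector.from_array([0.5, 0.6, -0.1])
        with pytest.raises(ValueError):
            IBDVector.from_array([0.2, 0.2, 0.2])
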