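import itertools

import numpy as np
import pytest

from piosphere.errors import DegenerateMatrixError, ValidationError
from piosphere.structure import (AnnealSchedule, bipartite_modularity_Q,
                                 modularity_significance, optimize_modularity,
                                 patefield_null, seasonal_comparison, win,
                                 win_max, wine)


def triangular_matrix(R=8, C=6):
    """Deterministic packed matrix: values decay away from the corner."""
    T = np.zeros((R, C))
    for i in range(R):
        b = max(1, int(np.ceil(C * (R - i) / R)))
        T[i, :b] = np.round(50 * 0.5 ** np.arange(b)) + 1
    return T


class TestPatefieldNull:
    def test_margins_conserved_every_draw(self, rng):
        M = rng.poisson(3, (5, 7))
        M[0, 0] += 5
        ens = patefield_null(M, n_draws=200, seed=1)
        assert (ens.matrices.sum(axis=2) == M.sum(axis=1)).all()
        assert (ens.matrices.sum(axis=1) == M.sum(axis=0)).all()
        assert (ens.matrices >= 0).all()

    def test_2x2_unit_margins_enumerates_two_tables(self):
        M = np.eye(2, dtype=int)
        ens = patefield_null(M, n_draws=4000, seed=5)
        ident = (ens.matrices[:, 0, 0] == 1).mean()
        # two admissible tables, each ~0.5
        assert 0.45 < ident < 0.55

    def test_seed_reproducible(self):
        M = np.arange(1, 7).reshape(2, 3)
        a = patefield_null(M, 50, seed=9).matrices
        b = patefield_null(M, 50, seed=9).matrices
        assert (a == b).all()

    def test_zero_matrix_degenerate(self):
        with pytest.raises(DegenerateMatrixError):
            patefield_null(np.zeros((2, 2)), 10, seed=0)


class TestWin:
    def test_permutation_invariance(self, rng):
        M = rng.poisson(4, (6, 5)) + np.diag(np.arange(5) + 10).sum() * 0
        M[0] += 20  # break margin ties so the canonical order is unique
        M[:, 0] += 15
        w0 = win(M)
        perm = M[rng.permutation(6)][:, rng.permutation(5)]
        assert win(perm) == pytest.approx(w0, abs=1e-12)

    def test_1x1_defined_and_finite(self):
        assert win([[7]]) == pytest.approx(1.0)

    def test_all_zero_degenerate(self):
        with pytest.raises(DegenerateMatrixError):
            win(np.zeros((3, 3)))

    def test_win_max_bounds_packed_matrix(self):
        T = triangular_matrix()
        assert win(T) == pytest.approx(win_max(T), abs=1e-12)
        gappy = np.array([[5, 0, 3], [2, 1, 0]])  # interior absence
        assert win(gappy) < win_max(gappy)


class TestWine:
    def test_packed_triangle_near_one(self):
        T = triangular_matrix()
        res = wine(T, patefield_null(T, 400, seed=3))
        assert res.wine > 0.9
        assert res.p_value <= 0.05 and res.z_score > 2

    def test_anti_diagonal_negative(self):
        M = np.fliplr(np.diag([5, 5, 5, 5, 5]))
        res = wine(M, patefield_null(M, 600, seed=4))
        assert res.wine < 0

    def test_self_null_centred(self):
        """A draw from the null ensemble scores WINE ~ 0 on average."""
        rng = np.random.default_rng(11)
        # long-tailed row totals typical of trap data: many sparse rows
        lam = 300 * 0.65 ** np.arange(25)
        base = rng.poisson(lam[:, None] / 7.0, (25, 7))
        base = base[base.sum(axis=1) > 0]
        source = patefield_null(base, 40, seed=11)
        vals = []
        for i in range(40):
            M = source.matrices[i]
            res = wine(M, patefield_null(M, 120, seed=100 + i))
            if not res.degenerate_normalization:
                vals.append(res.wine)
        assert len(vals) >= 15
        assert abs(np.mean(vals)) < 0.08

    def test_zero_spread_null_raises(self):
        M = np.array([[3]])
        with pytest.raises(DegenerateMatrixError):
            wine(M, patefield_null(M, 10, seed=0))

    def test_zero_free_matrix_flags_degenerate_normalization(self, rng):
        """With no empty cells the maximal repacking is a no-op, so the
        normalized estimator is undefined (NaN) though z and p survive."""
        M = rng.poisson(20, (6, 5)) + 1
        res = wine(M, patefield_null(M, 200, seed=1))
        assert res.degenerate_normalization and np.isnan(res.wine)
        assert np.isfinite(res.z_score) and 0 <= res.p_value <= 1


def brute_force_best_Q(M):
    """Exhaustive maximum of Q over all joint partitions (<= 8 nodes)."""
    R, C = M.shape
    nodes = list(range(R + C))

    def partitions(seq):
        if not seq:
            yield []
            return
        first, rest = seq[0], seq[1:]
        for part in partitions(rest):
            for i in range(len(part)):
                yield part[:i] + [part[i] + [first]] + part[i + 1:]
            yield [[first]] + part

    best = -np.inf
    for part in partitions(nodes):
        lab = np.empty(R + C, dtype=int)
        for m, block in enumerate(part):
            lab[block] = m
        best = max(best, bipartite_modularity_Q(M, lab[:R], lab[R:]))
    return best


class TestModularity:
    def test_two_block_hand_value(self):
        assert bipartite_modularity_Q([[5, 0], [0, 5]], [0, 1], [0, 1]) == \
            pytest.approx(0.5, abs=1e-12)

    def test_single_module_zero(self, rng):
        M = rng.poisson(3, (4, 5)) + 1
        assert bipartite_modularity_Q(M, [0] * 4, [0] * 5) == pytest.approx(0, abs=1e-12)

    def test_incomplete_partition_rejected(self):
        with pytest.raises(ValidationError):
            bipartite_modularity_Q([[1, 2], [3, 4]], [0], [0, 1])

    def test_optimizer_matches_exhaustive_on_small_matrices(self, rng):
        for _ in range(6):
            R = int(rng.integers(2, 5))
            C = int(rng.integers(2, 9 - R))
            M = rng.poisson(3, (R, C)).astype(float)
            M.flat[0] += 1
            bq = brute_force_best_Q(M)
            res = optimize_modularity(M, restarts=10, seed=int(rng.integers(2**31)))
            assert res.Q == pytest.approx(bq, abs=1e-9)

    def test_reported_q_recomputes(self, rng):
        M = rng.poisson(4, (6, 7)).astype(float) + 1
        res = optimize_modularity(M, restarts=4, seed=2)
        assert bipartite_modularity_Q(M, res.row_modules, res.column_modules) == \
            pytest.approx(res.Q, abs=1e-12)

    def test_planted_two_block_recovered(self, rng):
        M = np.zeros((10, 10))
        M[:5, :5] = rng.poisson(8, (5, 5))
        M[5:, 5:] = rng.poisson(8, (5, 5))
        M += rng.poisson(0.3, (10, 10))
        res = optimize_modularity(M, restarts=10, seed=7)
        assert res.n_modules == 2
        assert len(set(res.row_modules[:5])) == 1
        assert res.row_modules[0] != res.row_modules[5]
        assert (res.column_modules[:5] == res.row_modules[0]).all()

    def test_significance_deterministic_and_detects_blocks(self, rng):
        M = np.zeros((6, 6))
        M[:3, :3] = rng.poisson(10, (3, 3)) + 2
        M[3:, 3:] = rng.poisson(10, (3, 3)) + 2
        ens = patefield_null(M, 60, seed=8)
        a = modularity_significance(M, ens, restarts=4, seed=21)
        b = modularity_significance(M, ens, restarts=4, seed=21)
        assert a.Q == b.Q and a.p_value == b.p_value
        assert a.p_value <= 0.05 and a.z_score > 2


class TestModularitySelfNull:
    def test_null_drawn_matrix_not_significant_on_average(self):
        """A matrix drawn from a fixed-margin ensemble shows no modularity
        excess: its p-value against its own ensemble is central, not small."""
        from piosphere.community import SurveyDesign, build_interaction_matrices
        from piosphere.synthetic import GeneratorConfig, generate_survey

        ps = []
        for s in range(8):
            cfg = GeneratorConfig(design=SurveyDesign(n_transects=1),
                                  n_species=12, target_total=800, seed=s)
            im = build_interaction_matrices(generate_survey(cfg))[0]
            M = patefield_null(im, 1, seed=s + 50).matrices[0]
            ens = patefield_null(M, 30, seed=s + 99)
            ps.append(modularity_significance(M, ens, restarts=2, seed=s).p_value)
        assert 0.2 <= np.mean(ps) <= 0.8


class TestSeasonalComparison:
    def test_identical_seasons_p_one(self):
        nulls = np.linspace(0, 1, 50)
        res = seasonal_comparison(0.5, nulls, 0.5, nulls,
                                  n_permutations=999, seed=0)
        assert res.p_value == 1.0
        assert res.statistic == pytest.approx(0.0)

    def test_strong_separation_small_p(self, rng):
        null_wet = rng.normal(5.0, 1.0, 300)
        null_dry = rng.normal(0.0, 1.0, 300)
        res = seasonal_comparison(0.0, null_wet, 0.0, null_dry,
                                  n_permutations=999, seed=1)
        assert res.p_value <= 0.001

    def test_d_vectors_match_draw_counts(self, rng):
        res = seasonal_comparison(1.0, rng.normal(size=40), 2.0,
                                  rng.normal(size=60),
                                  n_permutations=500, seed=2)
        assert len(res.D_wet) == 40 and len(res.D_dry) == 60

    def test_matches_exhaustive_enumeration_small_groups(self, rng):
        """Random-permutation p approximates the exact label-exchange p."""
        wet = np.array([0.1, 0.9, 1.4])
        dry = np.array([-0.3, 0.2, 0.6])
        obs = wet.mean() - dry.mean()
        pooled = np.concatenate([wet, dry])
        stats = [
            pooled[list(c)].mean() - np.delete(pooled, list(c)).mean()
            for c in itertools.combinations(range(6), 3)]
        exact = np.mean(np.abs(stats) >= abs(obs) - 1e-12)
        res = seasonal_comparison(0.0, wet, 0.0, dry,
                                  n_permutations=4999, seed=3)
        assert res.p_value == pytest.approx(exact, abs=0.05)

    def test_low_permutations_warn(self, rng):
        with pytest.warns(UserWarning):
            seasonal_comparison(0.0, rng.normal(size=5), 0.0,
                                rng.normal(size=5), n_permutations=50, seed=4)

    def test_empty_null_vector_rejected(self):
        with pytest.raises(ValidationError):
            seasonal_comparison(0.0, [], 0.0, [1.0])
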