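import numpy as np
import pytest

from namdd import (
    AnalysisConfig,
    PathAssociation,
    SolverSettings,
    path_pvalue,
    permutation_test,
    permute_dataset,
)
from namdd.core_io import ValidationError


class TestPermuteDataset:
    def test_column_marginals_preserved(self, small_dataset):
        perm = permute_dataset(small_dataset, seed=5)
        np.testing.assert_allclose(
            np.sort(perm.X, axis=0), np.sort(small_dataset.X, axis=0)
        )
        np.testing.assert_allclose(
            np.sort(perm.Y, axis=0), np.sort(small_dataset.Y, axis=0)
        )
        assert perm.z.sum() == small_dataset.z.sum()

    def test_streams_are_independent(self, small_dataset):
        perm = permute_dataset(small_dataset, seed=5)
        # X and Y rows must not be permuted identically (seeded independent
        # streams); row sums act as row fingerprints
        rx = np.argsort(perm.X.sum(axis=1))
        ry = np.argsort(perm.Y.sum(axis=1))
        ox = np.argsort(small_dataset.X.sum(axis=1))
        oy = np.argsort(small_dataset.Y.sum(axis=1))
        assert not np.array_equal(rx[ox], ry[oy])

    def test_seed_determinism(self, small_dataset):
        a = permute_dataset(small_dataset, seed=9)
        b = permute_dataset(small_dataset, seed=9)
        np.testing.assert_array_equal(a.X, b.X)
        c = permute_dataset(small_dataset, seed=10)
        assert not np.array_equal(a.X, c.X)


class TestPathPvalue:
    def test_worked_example_eight_in_thousand(self):
        observed = 1.9
        nulls = np.concatenate([np.full(8, 1.0), np.full(992, 1.95)])
        assert path_pvalue(observed, nulls) == pytest.approx(0.008)

    def test_all_null_above_gives_zero(self):
        assert path_pvalue(1.2, [1.3, 1.4, 1.5]) == 0.0

    def test_all_null_below_gives_one(self):
        assert path_pvalue(1.9, [1.2, 1.3]) == 1.0

    def test_empty_null_rejected(self):
        with pytest.raises(ValidationError):
            path_pvalue(1.0, [])

    def test_literal_plus_upper_identity(self, rng):
        # strict lower count and inclusive upper count partition the null
        # set, so the two modes always sum to exactly one
        nulls = np.round(rng.uniform(1.2, 2.0, 200), 2)
        obs = float(nulls[17])
        lit = path_pvalue(obs, nulls, mode="literal")
        up = path_pvalue(obs, nulls, mode="upper")
        assert lit + up == pytest.approx(1.0)


class TestPermutationTest:
    @pytest.fixture
    def setup(self, small_dataset):
        cfg = AnalysisConfig(
            T=5, phi=0.6, n_perm=10, seed=3,
            alpha_grid=[0.5], beta_grid=[0.5], lambda_grid=[0.1],
            n_cv_folds=3, max_iter=150, tol=1e-4,
        )
        solver = SolverSettings(alpha=0.5, beta=0.5, u=1, v=1,
                                max_iter=150, tol=1e-4)
        path = PathAssociation("cg0", "g0", 1.0, 1.0)
        return small_dataset, cfg, solver, path

    def test_smoke_run_contract(self, setup):
        data, cfg, solver, path = setup
        res = permutation_test(path, data, cfg, solver, lambda_star=0.1,
                               T_perm=5, seed=1)
        assert len(res.null_scores) == 10
        assert res.p_value * 10 == pytest.approx(round(res.p_value * 10))
        assert 0.0 <= res.p_value <= 1.0

    def test_reproducible_from_seed(self, setup):
        data, cfg, solver, path = setup
        a = permutation_test(path, data, cfg, solver, 0.1, T_perm=5, seed=4)
        b = permutation_test(path, data, cfg, solver, 0.1, T_perm=5, seed=4)
        assert a.null_scores == b.null_scores
        assert a.p_value == b.p_value

    def test_unknown_site_rejected(self, setup):
        data, cfg, solver, _ = setup
        bad = PathAssociation("nope", "g0", 1.0, 1.0)
        with pytest.raises(ValidationError):
            permutation_test(bad, data, cfg, solver, 0.1, T_perm=5)

    def test_null_data_gives_unexceptional_pvalues(self, rng):
        # on data with no real structure the observed path score is a
        # typical draw from its own permutation null, so the literal
        # P-value should rarely sit at the extreme p = 0 (observed below
        # every null score)
        from namdd import OmicsDataset, fit_edges

        cfg = AnalysisConfig(
            T=4, phi=0.6, n_perm=25, seed=0,
            alpha_grid=[3.0], beta_grid=[1.5], lambda_grid=[0.5],
            n_cv_folds=3, max_iter=150, tol=1e-4,
        )
        solver = SolverSettings(alpha=3.0, beta=1.5, u=1, v=1,
                                max_iter=150, tol=1e-4)
        n_extreme = 0
        for rep in range(12):
            r = np.random.default_rng(700 + rep)
            n = 40
            data = OmicsDataset(
                X=r.standard_normal((n, 3)),
                Y=r.standard_normal((n, 2)),
                z=np.array([0, 1] * (n // 2)),
                sample_ids=[f"s{i}" for i in range(n)],
                site_ids=["cgA", "cgB", "cgC"],
                gene_ids=["gA", "gB"],
            )
            edges, _ = fit_edges(
                data, cfg, params={"alpha": 3.0, "beta": 1.5, "lambda": 0.5}
            )
            path = PathAssociation(
                "cgA", "gA", float(edges.mg_scores[0, 0]), float(edges.gd_scores[0])
            )
            res = permutation_test(path, data, cfg, solver, 0.5,
                                   T_perm=4, seed=800 + rep)
            n_extreme += res.p_value == 0.0 and res.n_ties == 0
        assert n_extreme <= 2

    def test_strong_path_beats_null(self, setup):
        # the real path cg0 -> g0 -> disease carries strong signal, so its
        # observed score should exceed most permuted scores (upper-tail
        # p small, literal p large)
        data, cfg, _, _ = setup
        from namdd import fit_edges

        # penalties near the noise-correlation scale sqrt(N/2) so permuted
        # data rarely selects the edge
        solver = SolverSettings(alpha=4.0, beta=2.0, u=1, v=1,
                                max_iter=300, tol=1e-5)
        edges, _ = fit_edges(
            data, cfg, params={"alpha": 4.0, "beta": 2.0, "lambda": 0.3}
        )
        obs = float(edges.mg_scores[0, 0] + edges.gd_scores[0])
        assert obs >= 1.5
        res = permutation_test(
            PathAssociation("cg0", "g0", edges.mg_scores[0, 0], edges.gd_scores[0]),
            data, cfg, solver, 0.3, T_perm=5, seed=2,
        )
        assert res.p_value >= 0.9  # literal mode: most nulls are smaller
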