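"""Factor machinery: eigen/score oracles, rotation, retention, two-level recovery."""

import numpy as np
import pandas as pd
import pytest

from connectogrip.factor import (
    FactorConfig,
    FactorError,
    FactorModel,
    NoFactorsRetainedError,
    SecondLevelModel,
    composite_edge_weights,
    first_level,
    fit_factor_model,
    match_factors,
    network_scores,
    second_level,
    standardize_columns,
    tucker_congruence,
)
from connectogrip.simulate import CohortSpec, generate_cohort
from connectogrip.pipeline import build_edge_table
from connectogrip.config import RunConfig


def _df(arr, prefix="v"):
    arr = np.asarray(arr, dtype=float)
    return pd.DataFrame(arr, columns=[f"{prefix}{j}" for j in range(arr.shape[1])])


class TestStandardize:
    def test_unit_sample_sd(self):
        out, dropped = standardize_columns(_df([[1.0], [2.0], [3.0]]))
        assert np.allclose(out.to_numpy().ravel(), [-1, 0, 1])
        assert dropped == []

    def test_constant_column_dropped_with_warning(self, caplog):
        out, dropped = standardize_columns(_df([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]]))
        assert dropped == ["v1"]
        assert list(out.columns) == ["v0"]
        assert any("zero-variance" in r.message for r in caplog.records)

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        x = _df(rng.normal(size=(50, 4)))
        once, _ = standardize_columns(x)
        twice, _ = standardize_columns(once)
        assert np.allclose(once.to_numpy(), twice.to_numpy(), atol=1e-12)

    def test_too_few_rows(self):
        with pytest.raises(FactorError, match="2 rows"):
            standardize_columns(_df([[1.0, 2.0]]))


class TestFitFactorModel:
    def test_unrotated_pc_loadings_match_svd_oracle(self):
        """PC loadings equal eigenvector * sqrt(eigenvalue) from an independent
        SVD of the standardized data (routes share no code)."""
        rng = np.random.default_rng(1)
        x = _df(rng.normal(size=(120, 6)) @ rng.normal(size=(6, 6)))
        cfg = FactorConfig(rotation="none", retention="fixed_k", fixed_k=3)
        model = fit_factor_model(x, cfg)
        z, _ = standardize_columns(x)
        u, s, vt = np.linalg.svd(z.to_numpy(), full_matrices=False)
        oracle = vt.T[:, :3] * (s[:3] / np.sqrt(len(x) - 1))
        for j in range(3):
            i_star = np.argmax(np.abs(oracle[:, j]))
            if oracle[i_star, j] < 0:
                oracle[:, j] *= -1
        assert np.allclose(model.loadings.to_numpy(), oracle, atol=1e-8)

    def test_rank_one_noiseless(self):
        rng = np.random.default_rng(2)
        s = rng.normal(size=(80, 1))
        x = _df(s @ np.array([[1.0, 2.0, -3.0, 0.5]]))
        cfg = FactorConfig(retention="kaiser_eigenvalue_gt_1", rotation="none")
        model = fit_factor_model(x, cfg)
        assert model.n_factors == 1
        assert model.eigenvalues[0] == pytest.approx(4.0, abs=1e-10)
        assert np.allclose(model.eigenvalues[1:], 0.0, atol=1e-10)
        assert np.allclose(np.abs(model.loadings.to_numpy()), 1.0, atol=1e-10)

    def test_planted_one_factor_loadings_recovered(self):
        rng = np.random.default_rng(3)
        n, p, lam = 500, 8, 0.8
        s = rng.normal(size=(n, 1))
        e = rng.normal(size=(n, p)) * np.sqrt(1 - lam**2)
        x = _df(lam * s + e)
        model = fit_factor_model(x, FactorConfig(retention="kaiser_eigenvalue_gt_1"))
        assert model.n_factors == 1
        assert np.allclose(np.abs(model.loadings.to_numpy().ravel()), lam, atol=0.05)

    def test_varimax_preserves_communalities_and_total_variance(self):
        rng = np.random.default_rng(4)
        x = _df(rng.normal(size=(200, 7)) @ rng.normal(size=(7, 7)))
        cfg_rot = FactorConfig(retention="fixed_k", fixed_k=3, rotation="varimax")
        cfg_none = FactorConfig(retention="fixed_k", fixed_k=3, rotation="none")
        rot = fit_factor_model(x, cfg_rot)
        raw = fit_factor_model(x, cfg_none)
        assert np.allclose(
            rot.communalities.to_numpy(), raw.communalities.to_numpy(), atol=1e-10
        )
        assert (rot.loadings.to_numpy() ** 2).sum() == pytest.approx(
            (raw.loadings.to_numpy() ** 2).sum(), abs=1e-10
        )

    def test_varimax_matches_statsmodels_on_unit_communalities(self):
        """Independent cross-check: with equal row norms, Kaiser normalization
        is a no-op and our rotation must agree with statsmodels varimax."""
        from statsmodels.multivariate.factor_rotation import rotate_factors

        rng = np.random.default_rng(5)
        raw = rng.normal(size=(12, 2))
        load = raw / np.linalg.norm(raw, axis=1, keepdims=True)
        from connectogrip.factor import _varimax

        ours = load @ _varimax(load)
        theirs, _ = rotate_factors(load, "varimax")
        # align columns and signs
        a, c = match_factors(ours, theirs)
        assert np.all(c > 1 - 1e-8)

    def test_regression_scores_match_closed_form_oracle(self):
        """Scores equal standardized Z R^-1 Lambda on data whose sample
        correlation is an exact hand-built 5-variable matrix."""
        r_target = np.array(
            [
                [1.0, 0.5, 0.3, 0.1, 0.0],
                [0.5, 1.0, 0.4, 0.2, 0.1],
                [0.3, 0.4, 1.0, 0.3, 0.2],
                [0.1, 0.2, 0.3, 1.0, 0.4],
                [0.0, 0.1, 0.2, 0.4, 1.0],
            ]
        )
        rng = np.random.default_rng(6)
        raw = rng.normal(size=(60, 5))
        centered = raw - raw.mean(0)
        # whiten (inverse Cholesky of the sample covariance), then color so the
        # sample correlation is exactly r_target
        white = centered @ np.linalg.inv(np.linalg.cholesky(np.cov(centered, rowvar=False))).T
        x = _df(white @ np.linalg.cholesky(r_target).T)
        cfg = FactorConfig(retention="fixed_k", fixed_k=2, rotation="varimax")
        model = fit_factor_model(x, cfg)
        z, _ = standardize_columns(x)
        assert np.allclose(np.corrcoef(z.to_numpy(), rowvar=False), r_target, atol=1e-10)
        raw_scores = z.to_numpy() @ np.linalg.inv(r_target) @ model.loadings.to_numpy()
        oracle = raw_scores / raw_scores.std(0, ddof=1)
        assert np.allclose(model.scores.to_numpy(), oracle, atol=1e-8)

    def test_kaiser_empty_retention_suggests_fixed_k(self):
        x = _df(np.random.default_rng(7).normal(size=(30, 1)))
        with pytest.raises(NoFactorsRetainedError, match="fixed_k"):
            fit_factor_model(x, FactorConfig(retention="kaiser_eigenvalue_gt_1"))

    def test_bit_reproducible(self):
        rng = np.random.default_rng(8)
        s = rng.normal(size=(40, 2))
        x = _df(s @ rng.normal(size=(2, 6)) + 0.3 * rng.normal(size=(40, 6)))
        cfg = FactorConfig(seed=123)
        m1 = fit_factor_model(x, cfg)
        m2 = fit_factor_model(x, cfg)
        assert np.array_equal(m1.loadings.to_numpy(), m2.loadings.to_numpy())
        assert np.array_equal(m1.scores.to_numpy(), m2.scores.to_numpy())


def _edge_table(n=60, seed=0, n_networks=3, **kw):
    spec = CohortSpec(n_participants=n, n_networks=n_networks, seed=seed, **kw)
    cohort = generate_cohort(spec, make_trials=False)
    table = build_edge_table(cohort, RunConfig(seed=seed))
    return table, [r.name for r in cohort.regions], cohort


class TestTwoLevel:
    def test_one_model_per_region_over_19_edges(self):
        table, names, _ = _edge_table(40, seed=1)
        models = first_level(table, names, FactorConfig(seed=1))
        assert set(models) <= set(names)
        for region, model in models.items():
            assert model.loadings.shape[0] == 19
            assert all(region in c for c in model.loadings.columns)

    def test_row_permutation_leaves_loadings_unchanged(self):
        table, names, _ = _edge_table(40, seed=2)
        models = first_level(table, names, FactorConfig(seed=2))
        perm = table.sample(frac=1.0, random_state=9)
        models_p = first_level(perm, names, FactorConfig(seed=2))
        for region in models:
            assert np.allclose(
                models[region].loadings.to_numpy(),
                models_p[region].loadings.to_numpy(),
                atol=1e-9,
            )

    def test_planted_region_factor_congruence(self):
        table, names, cohort = _edge_table(200, seed=3, pattern_range=(0.6, 0.9))
        groups = cohort.spec.groups()
        region = groups[0][0]
        models = first_level(table, names, FactorConfig(seed=3))
        model = models[region]
        planted = cohort.truth.pattern.loc[model.loadings.index, "G1"].to_numpy()
        _, congr = match_factors(model.loadings.to_numpy(), planted[:, None])
        assert congr[0] >= 0.95

    def test_second_level_recovers_k_and_single_latent(self):
        table, names, _ = _edge_table(200, seed=4, pattern_range=(0.6, 0.9))
        second = second_level(first_level(table, names, FactorConfig(seed=4)), FactorConfig(seed=4))
        assert len(second.network_names) == 3
        # single global latent: every region in one network
        table1, names1, _ = _edge_table(200, seed=5, n_networks=1, pattern_range=(0.6, 0.9))
        second1 = second_level(first_level(table1, names1, FactorConfig(seed=5)), FactorConfig(seed=5))
        assert len(second1.network_names) == 1

    def test_network_scores_near_orthogonal(self):
        table, names, _ = _edge_table(300, seed=6, pattern_range=(0.6, 0.9))
        second = second_level(first_level(table, names, FactorConfig(seed=6)), FactorConfig(seed=6))
        corr = np.corrcoef(second.scores.to_numpy(), rowvar=False)
        off = corr[~np.eye(corr.shape[0], dtype=bool)]
        assert np.max(np.abs(off)) <= 0.1

    def test_retention_sanity_under_column_shuffling(self):
        """Destroying structure by shuffling each edge column independently
        must not produce spurious networks."""
        ok = 0
        for seed in range(10):
            table, names, _ = _edge_table(200, seed=seed + 20)
            rng = np.random.default_rng(seed)
            shuffled = table.copy()
            for c in shuffled.columns:
                shuffled[c] = rng.permutation(shuffled[c].to_numpy())
            try:
                models = first_level(shuffled, names, FactorConfig(seed=seed))
                second = second_level(models, FactorConfig(seed=seed))
                retained = len(second.network_names)
                eigs = second.model.eigenvalues[:retained]
                ok += int(retained == 0 or np.all(eigs <= 1.3))
            except (NoFactorsRetainedError, FactorError):
                ok += 1  # nothing survived retention: vacuously clean
        assert ok >= 9

    def test_network_scores_lookup(self):
        table, names, _ = _edge_table(50, seed=7)
        second = second_level(first_level(table, names, FactorConfig(seed=7)), FactorConfig(seed=7))
        assert np.allclose(second.scores.mean(axis=0), 0.0, atol=1e-10)
        s = network_scores(second, table.index[0])
        assert list(s.index) == second.network_names
        with pytest.raises(FactorError, match="ghost"):
            network_scores(second, "ghost")


def _toy_second_level():
    """Hand-built two-level model over 3 regions A, B, C (edges A|B, A|C, B|C)."""
    edges_a = ["A|B", "A|C"]
    edges_b = ["A|B", "B|C"]

    def mk(region, edges, loads):
        loadings = pd.DataFrame(loads, index=edges)
        loadings.columns = [f"{region}::F{j + 1}" for j in range(loadings.shape[1])]
        scores = pd.DataFrame(
            np.zeros((4, loadings.shape[1])), columns=loadings.columns,
            index=[f"P{i}" for i in range(4)],
        )
        return FactorModel(
            loadings=loadings,
            scores=scores,
            eigenvalues=np.ones(len(edges)),
            communalities=pd.Series(1.0, index=edges),
            score_weights=loadings.copy(),
            score_scale=np.ones(loadings.shape[1]),
        )

    first = {"A": mk("A", edges_a, [[0.8], [0.5]]), "B": mk("B", edges_b, [[-0.9], [0.2]])}
    l2 = pd.DataFrame(
        {"N1": [0.6, 0.8]}, index=["A::F1", "B::F1"]
    )
    scores = pd.DataFrame(np.zeros((4, 1)), columns=["N1"], index=[f"P{i}" for i in range(4)])
    model = FactorModel(
        loadings=l2,
        scores=scores,
        eigenvalues=np.array([1.5, 0.5]),
        communalities=pd.Series(1.0, index=l2.index),
        score_weights=l2.copy(),
        score_scale=np.ones(1),
    )
    return SecondLevelModel(model=model, first_level=first)


class TestCompositeWeights:
    def test_single_path_product(self):
        nd = composite_edge_weights(_toy_second_level(), "N1", ["A", "B", "C"])
        assert nd.weights["A|C"] == pytest.approx(0.5 * 0.6)  # only the A::F1 path
        assert nd.weights["B|C"] == pytest.approx(0.2 * 0.8)  # only the B::F1 path

    def test_max_abs_path_selection_keeps_sign(self):
        # edge A|B has paths 0.8*0.6 = 0.48 (via A) and -0.9*0.8 = -0.72 (via B)
        nd = composite_edge_weights(_toy_second_level(), "N1", ["A", "B", "C"])
        assert nd.weights["A|B"] == pytest.approx(-0.72)
        assert "A|B" in set(nd.reported["edge"])

    def test_threshold_filters_and_top_n(self):
        # |A|C| = 0.30 < 0.4 is filtered out; |A|B| = 0.72 stays
        nd = composite_edge_weights(_toy_second_level(), "N1", ["A", "B", "C"], threshold=0.4)
        assert set(nd.reported["edge"]) == {"A|B"}
        nd_hi = composite_edge_weights(_toy_second_level(), "N1", ["A", "B", "C"], threshold=0.99)
        assert nd_hi.reported.empty

    def test_unknown_network(self):
        with pytest.raises(FactorError, match="N9"):
            composite_edge_weights(_toy_second_level(), "N9", ["A", "B", "C"])


class TestCongruence:
    def test_tucker_congruence_is_cosine(self):
        a = np.array([1.0, 0.0, 1.0])
        assert tucker_congruence(a, 2 * a) == pytest.approx(1.0)
        assert tucker_congruence(a, -a) == pytest.approx(-1.0)
        assert tucker_congruence(a, np.array([0.0, 1.0, 0.0])) == pytest.approx(0.0)

    def test_match_factors_assignment(self):
        planted = np.eye(4)[:, :3]
        recovered = planted[:, [2, 0, 1]] * np.array([1, -1, 1])
        a, c = match_factors(recovered, planted)
        assert list(a) == [1, 2, 0]
        assert np.allclose(c, 1.0)
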