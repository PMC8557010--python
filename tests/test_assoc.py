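"""Joint PC association test, direction, meta-analysis, thresholds."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import grexfine as gf


def _cube_from(arrays: dict[str, dict[str, np.ndarray]]) -> gf.GReXCube:
    n = len(next(iter(next(iter(arrays.values())).values())))
    idx = [f"i{k}" for k in range(n)]
    return gf.GReXCube({t: pd.DataFrame(cols, index=idx) for t, cols in arrays.items()})


def _pheno(y, covars=None, index=None):
    n = len(y)
    idx = index if index is not None else [f"i{k}" for k in range(n)]
    data = pd.DataFrame({"trait": np.asarray(y, dtype=float)}, index=idx)
    names = ()
    if covars is not None:
        for j, c in enumerate(np.atleast_2d(np.asarray(covars, dtype=float)).T
                              if np.ndim(covars) == 2 else [np.asarray(covars, dtype=float)]):
            data[f"c{j}"] = c
        names = tuple(c for c in data.columns if c != "trait")
    return gf.PhenotypeTable(data=data, covariates=names)


class TestMultixcanQuantitative:
    def test_perfect_predictor_floors_p(self, rng):
        x = rng.standard_normal(300)
        cube = _cube_from({"t1": {"g": x}, "t2": {"g": x + 0.01 * rng.standard_normal(300)}})
        r = gf.multixcan_fit(cube, "g", _pheno(x))
        assert r.p < 1e-100
        assert r.direction == 1

    def test_matches_naive_ols_partial_f_oracle(self, rng):
        """With no PC truncation the joint test equals the partial F of the
        standardized tissue columns, computed here from scratch via lstsq."""
        n = 200
        g1 = rng.standard_normal(n)
        g2 = 0.3 * g1 + rng.standard_normal(n)
        cov = rng.standard_normal((n, 2))
        y = 0.2 * g1 + cov @ [0.5, -0.3] + rng.standard_normal(n)
        cube = _cube_from({"t1": {"g": g1}, "t2": {"g": g2}})
        pheno = _pheno(y, covars=cov)
        r = gf.multixcan_fit(cube, "g", pheno)
        assert r.n_components == 2

        def ssr(X):
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            e = y - X @ beta
            return e @ e

        Z = np.column_stack([(g - g.mean()) / g.std() for g in (g1, g2)])
        X_red = np.column_stack([np.ones(n), cov])
        X_full = np.column_stack([X_red, Z])
        k, df_resid = 2, n - X_full.shape[1]
        f = ((ssr(X_red) - ssr(X_full)) / k) / (ssr(X_full) / df_resid)
        assert r.statistic == pytest.approx(f, rel=1e-10)
        assert r.p == pytest.approx(stats.f.sf(f, k, df_resid), rel=1e-10)

    def test_identical_tissue_columns_keep_one_component(self, rng):
        x = rng.standard_normal(150)
        cube = _cube_from({"t1": {"g": x}, "t2": {"g": 2 * x + 5}, "t3": {"g": -x}})
        r = gf.multixcan_fit(cube, "g", _pheno(rng.standard_normal(150)))
        assert r.n_components == 1
        assert r.n_tissues == 3

    def test_affine_rescaling_of_tissues_is_exact_noop(self, rng):
        """Per-column standardization makes the test invariant to a*x+b."""
        n = 180
        g1, g2 = rng.standard_normal(n), rng.standard_normal(n)
        y = rng.standard_normal(n)
        a = _cube_from({"t1": {"g": g1}, "t2": {"g": g2}})
        b = _cube_from({"t1": {"g": 3.5 * g1 - 2.0}, "t2": {"g": 0.1 * g2 + 7.0}})
        ra = gf.multixcan_fit(a, "g", _pheno(y))
        rb = gf.multixcan_fit(b, "g", _pheno(y))
        assert ra.statistic == pytest.approx(rb.statistic, rel=1e-10)
        assert ra.p == pytest.approx(rb.p, rel=1e-10)

    def test_condition_limit_truncates_near_duplicate(self, rng):
        x = rng.standard_normal(400)
        near = x + 1e-4 * rng.standard_normal(400)
        cube = _cube_from({"t1": {"g": x}, "t2": {"g": near}})
        tight = gf.multixcan_fit(cube, "g", _pheno(rng.standard_normal(400)), condition_limit=30)
        loose = gf.multixcan_fit(cube, "g", _pheno(rng.standard_normal(400)), condition_limit=1e12)
        assert tight.n_components == 1
        assert loose.n_components == 2


class TestMultixcanBinary:
    def test_single_tissue_z_matches_hand_irls(self, rng):
        """Wald Z from single_tissue_assoc vs a from-scratch Newton-Raphson
        logistic fit (score/Hessian written out explicitly)."""
        n = 500
        x = rng.standard_normal(n)
        lin = -0.4 + 0.8 * x
        y = (rng.random(n) < 1 / (1 + np.exp(-lin))).astype(float)
        cube = _cube_from({"t": {"g": x}})
        tab = gf.single_tissue_assoc(cube, _pheno(y))
        X = np.column_stack([np.ones(n), x])
        beta = np.zeros(2)
        for _ in range(50):
            mu = 1 / (1 + np.exp(-(X @ beta)))
            W = mu * (1 - mu)
            H = X.T @ (X * W[:, None])
            step = np.linalg.solve(H, X.T @ (y - mu))
            beta = beta + step
            if np.abs(step).max() < 1e-12:
                break
        se = np.sqrt(np.linalg.inv(H)[1, 1])
        assert tab["Z"].iloc[0] == pytest.approx(beta[1] / se, rel=1e-6)

    def test_lr_chi2_matches_hand_loglik(self, rng):
        n = 600
        x = rng.standard_normal(n)
        y = (rng.random(n) < 1 / (1 + np.exp(-0.5 * x))).astype(float)
        cube = _cube_from({"t": {"g": x}})
        r = gf.multixcan_fit(cube, "g", _pheno(y))

        def loglik(X):
            beta = np.zeros(X.shape[1])
            for _ in range(60):
                mu = 1 / (1 + np.exp(-(X @ beta)))
                H = X.T @ (X * (mu * (1 - mu))[:, None])
                beta = beta + np.linalg.solve(H, X.T @ (y - mu))
            mu = 1 / (1 + np.exp(-(X @ beta)))
            return float(np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))

        z = (x - x.mean()) / x.std()
        lr = 2 * (loglik(np.column_stack([np.ones(n), z])) - loglik(np.ones((n, 1))))
        assert r.statistic == pytest.approx(lr, rel=1e-6)
        assert r.p == pytest.approx(stats.chi2.sf(lr, 1), rel=1e-6)

    def test_driver_gene_recovered_with_positive_direction(self, small_cube, small_pheno):
        out = gf.multixcan_all(small_cube, small_pheno)
        row = out[out["gene"] == "GENE001"].iloc[0]
        assert row["p"] < gf.bonferroni_threshold(5, 127)
        assert row["direction"] == 1


class TestAssignDirection:
    def test_examples_and_tie(self):
        tab = pd.DataFrame({
            "gene": ["a", "a", "b", "b", "c", "d"],
            "tissue": ["t1", "t2"] * 3,
            "Z": [2.0, 1.0, -1.0, -3.0, 1.5, np.nan],
            "failed": [False] * 6,
        })
        out = gf.assign_direction(tab).set_index("gene")
        assert out.loc["a", "direction"] == 1
        assert out.loc["a", "mean_Z"] == pytest.approx(1.5)
        assert out.loc["b", "direction"] == -1
        assert out.loc["c", "direction"] == 1
        assert bool(out.loc["d", "undefined"])

    def test_exact_zero_mean_ties_positive(self):
        tab = pd.DataFrame({"gene": ["g", "g"], "tissue": ["t1", "t2"],
                            "Z": [1.0, -1.0], "failed": [False, False]})
        out = gf.assign_direction(tab)
        assert out["direction"].iloc[0] == 1


def _res(p, direction, gene="g"):
    return gf.AssociationResult(gene, 2, 2, np.nan, p, direction, float(direction))


class TestMetalCombine:
    def test_single_cohort_is_identity(self):
        m = gf.metal_combine([_res(0.01, -1)], [500])
        assert m.z_meta == pytest.approx(-stats.norm.isf(0.005))
        assert m.p_meta == pytest.approx(0.01)

    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_identical_cohorts_scale_z_by_sqrt_k(self, k):
        m = gf.metal_combine([_res(0.03, 1)] * k, [200] * k)
        assert m.z_meta == pytest.approx(np.sqrt(k) * stats.norm.isf(0.015), rel=1e-12)

    def test_hand_computed_two_cohort_example(self):
        z1, z2 = stats.norm.isf(0.025), -stats.norm.isf(0.10)
        expected = (np.sqrt(100) * z1 + np.sqrt(300) * z2) / np.sqrt(400)
        m = gf.metal_combine([_res(0.05, 1), _res(0.20, -1)], [100, 300])
        assert m.z_meta == pytest.approx(expected, rel=1e-12)
        assert m.p_meta == pytest.approx(2 * stats.norm.sf(abs(expected)), rel=1e-12)

    def test_zero_p_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            m = gf.metal_combine([_res(0.0, 1)], [100])
        assert np.isfinite(m.z_meta)

    def test_undirected_cohort_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="dropped"):
            m = gf.metal_combine([_res(0.01, 1), _res(0.5, 0)], [100, 900])
        assert m.cohort_ns == [100]
        assert m.p_meta == pytest.approx(0.01)

    def test_all_dropped_is_error(self):
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="all cohorts"):
                gf.metal_combine([_res(0.5, 0)], [100])

    def test_length_mismatch_is_error(self):
        with pytest.raises(ValueError, match="mismatch"):
            gf.metal_combine([_res(0.5, 1)], [100, 200])


class TestThresholds:
    @pytest.mark.parametrize("traits,genes,value", [
        (5, 127, 0.05 / 635),
        (1531, 1, 0.05 / 1531),
        (1795, 1, 0.05 / 1795),
    ])
    def test_bonferroni_values(self, traits, genes, value):
        assert gf.bonferroni_threshold(traits, genes) == pytest.approx(value, rel=1e-12)

    def test_bonferroni_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            gf.bonferroni_threshold(0, 10)

    def _null_setup(self, seed=3, n=400, n_genes=120):
        rng = np.random.default_rng(seed)
        genes = [f"G{j:03d}" for j in range(n_genes)]
        idx = [f"i{k}" for k in range(n)]
        cube = gf.GReXCube({"t": pd.DataFrame(rng.standard_normal((n, n_genes)),
                                              index=idx, columns=genes)})
        pheno = _pheno(rng.standard_normal(n), index=idx)
        table = pd.DataFrame({"gene": genes, "position": np.arange(n_genes) * 1e5})
        return table, cube, pheno

    def test_null_threshold_near_alpha_on_average(self):
        """A single cohort's 5th-percentile null p is noisy (order statistic
        of ~120 values), so average the threshold over independent cohorts."""
        thrs = []
        for seed in range(8):
            table, cube, pheno = self._null_setup(seed=100 + seed)
            thr, pooled = gf.permutation_threshold(table, 5, 4e5, cube, pheno,
                                                   n_perm=30, seed=11)
            assert len(pooled) >= 100
            thrs.append(thr)
        assert np.mean(thrs) == pytest.approx(0.05, abs=0.025)

    def test_pooled_values_come_from_the_gene_tests(self):
        table, cube, pheno = self._null_setup()
        _, pooled = gf.permutation_threshold(table, 5, 4e5, cube, pheno,
                                             n_perm=30, seed=1)
        all_p = set(gf.multixcan_all(cube, pheno)["p"])
        assert set(pooled) <= all_p

    def test_literal_orientation_returns_95th_percentile(self):
        table, cube, pheno = self._null_setup()
        _, pooled = gf.permutation_threshold(table, 5, 4e5, cube, pheno,
                                             n_perm=50, seed=2, orientation="literal")
        thr, pooled2 = gf.permutation_threshold(table, 5, 4e5, cube, pheno,
                                                n_perm=50, seed=2, orientation="literal")
        assert np.array_equal(pooled, pooled2)
        assert thr == pytest.approx(np.percentile(pooled, 95))

    def test_deterministic_for_fixed_seed(self):
        table, cube, pheno = self._null_setup()
        a, _ = gf.permutation_threshold(table, 5, 4e5, cube, pheno, n_perm=30, seed=7)
        b, _ = gf.permutation_threshold(table, 5, 4e5, cube, pheno, n_perm=30, seed=7)
        assert a == b

    def test_insufficient_windows_is_error(self):
        table, cube, pheno = self._null_setup()
        with pytest.raises(ValueError, match="matched windows"):
            gf.permutation_threshold(table, 5, 9e9, cube, pheno, n_perm=30, seed=0)

    def test_small_genome_is_error(self):
        table, cube, pheno = self._null_setup(n_genes=30)
        with pytest.raises(ValueError, match="10x"):
            gf.permutation_threshold(table, 5, 4e5, cube, pheno, n_perm=30, seed=0)

    def test_too_few_permutations_is_error(self):
        table, cube, pheno = self._null_setup()
        with pytest.raises(ValueError, match="n_perm"):
            gf.permutation_threshold(table, 5, 4e5, cube, pheno, n_perm=5, seed=0)
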