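"""Penalized IWLS / empirical-Bayes REML fitting against dense oracles."""

import numpy as np
import pandas as pd
import pytest
import scipy.optimize
import scipy.sparse as sp

from adstar.fit import (
    ConvergenceError,
    FitConfig,
    build_model,
    effective_dof,
    fit,
    fit_gaussian_smooth,
    penalized_deviance,
)
from adstar.smoothers import apply_constraint, bspline_basis, rw2_penalty
from conftest import manual_panel

FIXED_LAMBDAS = {"time": 5.0, "temperature": 2.0, "spatial": 1.0}


def dense_newton_oracle(spec, lambdas):
    """Minimize the penalized Poisson negative log-likelihood directly."""
    X = spec.full_design().toarray()
    y, off = spec.y, spec.offset
    slices = spec.slices()
    p = X.shape[1]
    P = np.zeros((p, p))
    for b in spec.blocks:
        if b.is_smooth:
            sl = slices[b.name]
            P[sl, sl] = lambdas[b.name] * b.penalty.matrix

    def nll(beta):
        eta = off + X @ beta
        return -(y @ eta - np.exp(eta).sum()) + 0.5 * beta @ P @ beta

    def grad(beta):
        mu = np.exp(off + X @ beta)
        return -(X.T @ (y - mu)) + P @ beta

    def hess(beta):
        mu = np.exp(off + X @ beta)
        return (X * mu[:, None]).T @ X + P

    x0 = np.zeros(p)
    x0[slices["intercept"]] = np.log(y.sum() / np.exp(off).sum())
    res = scipy.optimize.minimize(
        nll, x0, jac=grad, hess=hess, method="trust-exact",
        options={"gtol": 1e-10, "maxiter": 500},
    )
    assert res.success or np.linalg.norm(grad(res.x)) < 1e-6
    return res.x


class TestInnerLoop:
    def test_intercept_only_closed_form(self):
        panel, _ = manual_panel(n_days=21, districts=("A", "B"), seed=2)
        cfg = FitConfig(
            include_dow=False, include_dsli=False, include_time=False,
            include_temp=False, include_spatial=False, phi=1.0,
        )
        res = fit(panel, cfg)
        y = panel.counts()
        offset = np.log(
            [panel.populations[d] for d in panel.records["district"]]
        )
        expected = np.log(y.sum() / np.exp(offset).sum())
        assert res.coef("intercept")[0] == pytest.approx(expected, abs=1e-8)

    def test_matches_dense_newton_with_fixed_lambdas(self, tiny_scenario):
        panel, _ = tiny_scenario
        cfg = FitConfig(
            time_knots=8, temp_knots=5, fixed_lambdas=FIXED_LAMBDAS, phi=1.0
        )
        spec = build_model(panel, cfg)
        res = fit(panel, spec)
        oracle = dense_newton_oracle(spec, FIXED_LAMBDAS)
        assert np.allclose(res.beta, oracle, atol=1e-6)

    def test_penalized_deviance_trace_descends(self, tiny_scenario):
        panel, _ = tiny_scenario
        res = fit(panel, FitConfig(time_knots=8, temp_knots=5))
        tr = pd.DataFrame(res.trace)
        for _, block in tr.groupby("outer"):
            dev = block["penalized_deviance"].to_numpy()
            assert np.all(np.diff(dev) <= 1e-8)

    def test_penalized_deviance_recomputation(self, tiny_scenario):
        panel, _ = tiny_scenario
        res = fit(panel, FitConfig(time_knots=8, temp_knots=5))
        direct = penalized_deviance(res)
        # independent recomputation from (y, mu, b, K)
        y, mu = res.spec.y, res.mu
        dev = 2.0 * np.sum(
            np.where(y > 0, y * np.log(y / mu), 0.0) - (y - mu)
        )
        pen = 0.0
        for b in res.spec.blocks:
            if b.is_smooth:
                bj = res.coef(b.name)
                lam = res.variance.phi / res.variance.tau2[b.name]
                pen += lam * (bj @ b.penalty.matrix @ bj)
        assert direct == pytest.approx(dev + pen, rel=1e-10)

    def test_saturated_fit_has_zero_deviance(self):
        # one parameter per observation, no penalty: deviance term vanishes
        y = np.array([3.0, 7.0, 1.0, 4.0])
        mu = y.copy()
        dev = 2.0 * np.sum(np.where(y > 0, y * np.log(y / mu), 0.0) - (y - mu))
        assert dev == pytest.approx(0.0, abs=1e-12)

    def test_zero_counts_rejected(self):
        panel, _ = manual_panel(counts_value=0, districts=("A", "B"))
        with pytest.raises(ValueError, match="zero"):
            fit(panel, FitConfig())


class TestOuterLoop:
    def test_gaussian_reml_matches_grid_search(self):
        """EB fixed-point tau2 agrees with a direct restricted-likelihood
        grid search on a Gaussian one-smooth model."""
        rng = np.random.default_rng(7)
        n, sigma = 150, 0.3
        x = np.sort(rng.uniform(0, 1, n))
        f = np.sin(2 * np.pi * x)
        y = f + rng.normal(scale=sigma, size=n)
        _, B = bspline_basis(x, 8, degree=3)
        sm = apply_constraint("s", B, rw2_penalty(B.shape[1]))
        got = fit_gaussian_smooth(y, sm, sigma2=sigma**2, use_prior=False)

        # oracle: grid REML via the mixed-model spectral reparameterization
        D = sm.design.toarray()
        K = sm.penalty.matrix
        evals, evecs = np.linalg.eigh(K)
        pos = evals > 1e-9 * evals[-1]
        Zr = D @ evecs[:, pos] / np.sqrt(evals[pos])  # random-effect design
        Xf = np.column_stack([np.ones(n), D @ evecs[:, ~pos]])  # fixed part

        def neg_restricted_ll(tau2):
            V = sigma**2 * np.eye(n) + tau2 * Zr @ Zr.T
            Vi = np.linalg.inv(V)
            XtViX = Xf.T @ Vi @ Xf
            beta = np.linalg.solve(XtViX, Xf.T @ Vi @ y)
            r = y - Xf @ beta
            _, ld_V = np.linalg.slogdet(V)
            _, ld_X = np.linalg.slogdet(XtViX)
            return 0.5 * (ld_V + ld_X + r @ Vi @ r)

        grid = np.exp(np.linspace(np.log(1e-4), np.log(1e2), 400))
        vals = [neg_restricted_ll(t) for t in grid]
        t_star = grid[int(np.argmin(vals))]
        step = grid[1] / grid[0]
        assert t_star / step <= got["tau2"] <= t_star * step

    def test_phi_estimated_near_truth(self, small_scenario):
        panel, truth = small_scenario
        res = fit(panel, FitConfig())
        assert res.variance.phi == pytest.approx(truth.phi, rel=0.15)

    def test_variance_components_positive(self, small_scenario):
        panel, _ = small_scenario
        res = fit(panel, FitConfig())
        assert res.variance.phi > 0
        assert all(v > 0 for v in res.variance.tau2.values())

    def test_covariance_symmetric_psd_and_means_positive(self, small_scenario):
        panel, _ = small_scenario
        res = fit(panel, FitConfig())
        C = res.covariance
        assert np.allclose(C, C.T)
        assert np.linalg.eigvalsh(C).min() > -1e-8 * np.abs(C).max()
        assert (res.mu > 0).all()

    def test_nonconvergence_carries_trace(self, tiny_scenario):
        panel, _ = tiny_scenario
        with pytest.raises(ConvergenceError) as exc:
            fit(panel, FitConfig(time_knots=8, temp_knots=5, outer_max=1))
        assert len(exc.value.trace) >= 1


class TestEffectiveDof:
    def test_unpenalized_blocks_have_full_edf(self):
        panel, _ = manual_panel(n_days=28, districts=("A", "B"), seed=4)
        cfg = FitConfig(
            include_time=False, include_temp=False, include_spatial=False,
            phi=1.0,
        )
        res = fit(panel, cfg)
        edf = effective_dof(res)
        assert edf["intercept"] == pytest.approx(1.0, abs=1e-6)
        assert edf["dow"] == pytest.approx(6.0, abs=1e-6)
        # one 2-day event: only lag0..lag7 classes present in 28 days
        n_dsli = res.spec.slices()["dsli"].stop - res.spec.slices()["dsli"].start
        assert edf["dsli"] == pytest.approx(n_dsli, abs=1e-6)

    def test_infinite_lambda_shrinks_edf_to_nullspace(self, tiny_scenario):
        panel, _ = tiny_scenario
        big = {"time": 1e9, "temperature": 1e9, "spatial": 1e9}
        res = fit(
            panel,
            FitConfig(time_knots=8, temp_knots=5, fixed_lambdas=big, phi=1.0),
        )
        for b in res.spec.blocks:
            if b.is_smooth:
                assert res.edf[b.name] == pytest.approx(
                    b.nullspace_dim, abs=1e-3
                )

    def test_edf_in_bounds_and_sums_to_dense_hat_trace(self, tiny_scenario):
        panel, _ = tiny_scenario
        cfg = FitConfig(
            time_knots=8, temp_knots=5, fixed_lambdas=FIXED_LAMBDAS, phi=1.0
        )
        res = fit(panel, cfg)
        for b in res.spec.blocks:
            if b.is_smooth:
                assert b.nullspace_dim - 1e-6 <= res.edf[b.name] <= b.n_coef
        # dense oracle for the total hat trace
        X = res.spec.full_design().toarray()
        W = res.mu
        slices = res.spec.slices()
        P = np.zeros((X.shape[1],) * 2)
        for b in res.spec.blocks:
            if b.is_smooth:
                sl = slices[b.name]
                P[sl, sl] = FIXED_LAMBDAS[b.name] * b.penalty.matrix
        A = (X * W[:, None]).T @ X + P
        H = np.linalg.solve(A, (X * W[:, None]).T @ X)
        assert res.total_edf == pytest.approx(np.trace(H), abs=1e-6)


class TestModelStructure:
    def test_district_relabeling_permutes_only_spatial(self, tiny_scenario):
        panel, _ = tiny_scenario
        relabel = {d: f"Z{i}" for i, d in enumerate(reversed(panel.districts))}
        rec = panel.records.copy()
        rec["district"] = rec["district"].map(relabel)
        from adstar.panel import build_panel

        idx = pd.DatetimeIndex(panel.records["date"].unique())
        temps = pd.Series(
            panel.records.drop_duplicates("date")["temperature"].to_numpy(),
            index=idx,
        )
        panel2 = build_panel(
            rec[["date", "district", "visits"]],
            temps,
            {relabel[d]: p for d, p in panel.populations.items()},
            [(relabel[a], relabel[b]) for a, b in panel.graph.edges()],
            panel.lag,
        )
        cfg = FitConfig(time_knots=8, temp_knots=5)
        r1, r2 = fit(panel, cfg), fit(panel2, cfg)
        f1, f2 = r1.fixed_effects(), r2.fixed_effects()
        assert np.allclose(f1["coef"], f2["coef"], atol=1e-5)
        s1 = r1.spatial_effects().set_index("district")["effect"]
        s2 = r2.spatial_effects().set_index("district")["effect"]
        for d in panel.districts:
            assert s1[d] == pytest.approx(s2[relabel[d]], abs=1e-5)

    def test_no_storm_calendar_reduces_to_no_exposure_model(self):
        from datetime import date

        from adstar.simulate import ScenarioConfig, generate

        cfg = ScenarioConfig(
            n_districts=3,
            study_start=date(2001, 1, 1),
            study_end=date(2001, 12, 31),
            calendar="random",
            n_events=0,
            effects="null",
            age_groups=("all",),
            seed=9,
        )
        panels, _ = generate(cfg)
        panel = panels["all"]
        fit_cfg = FitConfig(time_knots=10, temp_knots=5)
        with_dsli = fit(panel, fit_cfg)
        without = fit(panel, FitConfig(time_knots=10, temp_knots=5,
                                       include_dsli=False))
        assert "lag0" in with_dsli.spec.dropped_columns
        assert not any(b.name == "dsli" for b in with_dsli.spec.blocks)
        f1 = with_dsli.fixed_effects().set_index("variable")["coef"]
        f2 = without.fixed_effects().set_index("variable")["coef"]
        assert np.allclose(f1, f2, atol=1e-8)
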