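"""Design construction, the block likelihood and its oracles, ML fitting, sandwich."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.optimize import approx_fprime

from longgei.covariance import HlmParams, hlm_family_cov, krc_family_cov
from longgei.data import build_dataset
from longgei.model import (
    LongitudinalGEIModel,
    MeanModelSpec,
    RankDeficiencyError,
    build_design,
    gls_profile,
)
from longgei.simulate import SimulationConfig, simulate_dataset

from conftest import make_members, make_record


class TestMeanModelSpec:
    def test_column_counts_and_nesting(self):
        cols = {m: MeanModelSpec(m).column_names() for m in (1, 2, 3)}
        assert len(cols[1]) == 1 + 4 + 1  # intercept + C + E
        assert set(cols[2]) - set(cols[1]) == {"G"}
        assert set(cols[3]) - set(cols[2]) == {"G:E"}

    def test_invalid_model_id(self):
        with pytest.raises(ValueError):
            MeanModelSpec(4)


class TestBuildDesign:
    def test_interaction_column_is_product(self, two_family_dataset):
        ds = two_family_dataset
        dosage = {r.individual_id: 2.0 for f in ds.families.values() for r in f.records}
        y, X, layouts, slices, names, flags = build_design(ds, MeanModelSpec(3), dosage)
        e = X[:, names.index("alcohol")]
        np.testing.assert_allclose(X[:, names.index("G:E")], 2.0 * e)
        assert X[:, names.index("G")].tolist() == [2.0] * len(y)

    def test_g_constant_within_individual(self, small_sim):
        ds, gt, _ = small_sim
        y, X, layouts, slices, names, _ = build_design(
            ds, MeanModelSpec(2), gt.dosage(gt.snp_ids[0])
        )
        gcol = X[:, names.index("G")]
        for lay, s in zip(layouts, slices):
            block = gcol[s]
            for iid in set(r.individual_id for r in lay.records):
                vals = [g for g, r in zip(block, lay.records) if r.individual_id == iid]
                assert len(set(vals)) == 1

    def test_missing_dosage_rejected(self, two_family_dataset):
        ds = two_family_dataset
        dosage = {
            r.individual_id: np.nan for f in ds.families.values() for r in f.records
        }
        with pytest.raises(ValueError, match="missing dosage"):
            build_design(ds, MeanModelSpec(2), dosage)

    def test_constant_column_flagged(self, two_family_dataset):
        ds = two_family_dataset
        dosage = {r.individual_id: 0.0 for f in ds.families.values() for r in f.records}
        *_, flags = build_design(ds, MeanModelSpec(2), dosage)
        assert "G" in flags["constant_columns"]


def _dense_loglik(y, X, beta, covs, slices):
    """Oracle: stacked multivariate-normal log-density over all observations."""
    from scipy.linalg import block_diag

    V = block_diag(*covs)
    return stats.multivariate_normal.logpdf(y, mean=X @ beta, cov=V)


class TestLikelihoodOracles:
    def test_single_observation_closed_form(self):
        members = [make_members("F1", 0)[0], make_members("F2", 0)[0]]
        records = [make_record(m, 1, hdlc=0.0, alcohol=0.0, age=0.0, bmi=1.0) for m in members]
        ds = build_dataset(members, records, visit_grid=(1,))
        # y = 0 everywhere, X spans the intercept only after dropping collinear
        m = LongitudinalGEIModel(
            y=np.zeros(2), X=np.ones((2, 1)), layouts=list(ds.families.values()),
            slices=[slice(0, 1), slice(1, 2)], structure="hlm", exog_names=["const"], T=1,
        )
        # theta giving V = [[1]] per family: s2f ~ 0, s2e = 1, any arma
        theta = np.array([-30.0, 0.0, 0.0, 0.0])
        per_obs = 0.5 * np.log(2 * np.pi)
        assert m.nloglike(theta) == pytest.approx(2 * per_obs, abs=1e-6)

    @pytest.mark.parametrize("structure", ["krc", "hlm"])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_block_equals_dense_mvn(self, structure, seed, two_family_dataset):
        """Block likelihood == dense joint normal density, <=30 observations."""
        ds = two_family_dataset
        m = LongitudinalGEIModel.from_dataset(ds, MeanModelSpec(1), structure)
        rng = np.random.default_rng(seed)
        theta = rng.normal(scale=0.3, size=m.structure.n_params)
        params = m.structure.params(theta)
        cov_fn = krc_family_cov if structure == "krc" else hlm_family_cov
        covs = [cov_fn(f, ds, params).matrix for f in ds.families]
        beta = m.profile_beta(theta)
        dense = _dense_loglik(m.y, m.X, beta, covs, m.slices)
        assert m.loglike(theta) == pytest.approx(dense, abs=1e-8)

    def test_block_additivity_over_families(self, two_family_dataset):
        ds = two_family_dataset
        m = LongitudinalGEIModel.from_dataset(ds, MeanModelSpec(1), "hlm")
        theta = np.array([0.1, 0.2, 0.1, 0.1])
        beta = m.profile_beta(theta)
        params = m.structure.params(theta)
        total = 0.0
        for (fid, lay), s in zip(ds.families.items(), m.slices):
            V = hlm_family_cov(fid, ds, params).matrix
            r = m.y[s] - m.X[s] @ beta
            total += stats.multivariate_normal.logpdf(r, cov=V)
        assert m.loglike(theta) == pytest.approx(total, abs=1e-8)

    @pytest.mark.parametrize("structure", ["krc", "hlm"])
    def test_analytic_gradient_matches_fd(self, structure, small_sim):
        ds, _, _ = small_sim
        m = LongitudinalGEIModel.from_dataset(ds, MeanModelSpec(1), structure)
        theta = m.starting_values(1)[0] + 0.05
        _, g = m._lik.value_and_grad(theta)
        gn = approx_fprime(theta, m.nloglike, 1e-6)
        np.testing.assert_allclose(g, gn, rtol=2e-4, atol=2e-4 * max(1, np.abs(gn).max()))


class TestGLS:
    def test_identity_weights_give_ols(self, two_family_dataset):
        ds = two_family_dataset
        m = LongitudinalGEIModel.from_dataset(ds, MeanModelSpec(1), "hlm")
        covs = [np.eye(s.stop - s.start) for s in m.slices]
        beta = gls_profile(m.y, m.X, covs, m.slices)
        ols, *_ = np.linalg.lstsq(m.X, m.y, rcond=None)
        np.testing.assert_allclose(beta, ols, atol=1e-8)

    def test_scalar_case(self):
        beta = gls_profile(np.array([2.0]), np.array([[1.0]]), [np.array([[4.0]])], [slice(0, 1)])
        assert beta[0] == pytest.approx(2.0)

    def test_matches_normal_equations(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(12, 3))
        y = rng.normal(size=12)
        slices = [slice(0, 5), slice(5, 12)]
        covs = []
        for s in slices:
            A = rng.normal(size=(s.stop - s.start, s.stop - s.start))
            covs.append(A @ A.T + 3 * np.eye(s.stop - s.start))
        from scipy.linalg import block_diag

        V = block_diag(*covs)
        Vi = np.linalg.inv(V)
        expected = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
        np.testing.assert_allclose(gls_profile(y, X, covs, slices), expected, atol=1e-10)


class TestFit:
    def test_recovers_hlm_truth(self):
        """Estimates from the generating structure sit close to the truth."""
        cfg = SimulationConfig(
            n_families=400, n_snps=1, covariance="hlm",
            dropout_hazard=0.0, intermittent_missing=0.0,
        )
        ds, _, _ = simulate_dataset(cfg, 21)
        r = LongitudinalGEIModel.from_dataset(ds, MeanModelSpec(1), "hlm").fit()
        assert r.converged
        p = r.cov_struct_params
        # ~3 Monte-Carlo SE at this size, checked generously
        assert p.sigma2_f == pytest.approx(cfg.hlm_sigma2_f, rel=0.25)
        assert p.sigma2_e == pytest.approx(cfg.hlm_sigma2_e, rel=0.15)
        assert p.gamma == pytest.approx(cfg.hlm_gamma, abs=0.08)
        assert p.rho == pytest.approx(cfg.hlm_rho, abs=0.08)
        assert r.fe_params["alcohol"] == pytest.approx(cfg.beta_e, abs=0.25)

    def test_one_family_rejected(self):
        members = make_members("F1", 1)
        records = [make_record(m, 1) for m in members]
        ds = build_dataset(members, records)
        with pytest.raises(ValueError, match="2 families"):
            LongitudinalGEIModel.from_dataset(ds, MeanModelSpec(1), "hlm")

    def test_rank_deficient_design_rejected(self, two_family_dataset):
        ds = two_family_dataset
        dosage = {r.individual_id: 1.0 for f in ds.families.values() for r in f.records}
        with pytest.raises(RankDeficiencyError):
            LongitudinalGEIModel.from_dataset(ds, MeanModelSpec(2), "hlm", snp_dosages=dosage)

    def test_location_scale_invariance(self, small_sim):
        """Shifting Y moves only the intercept; rescaling E rescales its betas."""
        ds, gt, _ = small_sim
        m = LongitudinalGEIModel.from_dataset(ds, MeanModelSpec(1), "hlm")
        r = m.fit()
        m2 = LongitudinalGEIModel(
            m.y + 10.0, m.X, m.layouts, m.slices, "hlm", m.exog_names, T=m.T
        )
        r2 = m2.fit()
        assert r2.llf == pytest.approx(r.llf, abs=1e-4)
        assert r2.fe_params["const"] == pytest.approx(r.fe_params["const"] + 10.0, abs=1e-4)
        others = [n for n in m.exog_names if n != "const"]
        pd.testing.assert_series_equal(
            r2.fe_params[others], r.fe_params[others], atol=1e-5, check_exact=False
        )
        X3 = m.X.copy()
        j = m.exog_names.index("alcohol")
        X3[:, j] *= 2.0
        r3 = LongitudinalGEIModel(m.y, X3, m.layouts, m.slices, "hlm", m.exog_names, T=m.T).fit()
        assert r3.llf == pytest.approx(r.llf, abs=1e-4)
        assert r3.fe_params["alcohol"] == pytest.approx(r.fe_params["alcohol"] / 2.0, abs=1e-5)

    def test_loglik_monotone_in_nesting(self, small_sim):
        ds, gt, _ = small_sim
        d = gt.dosage(gt.snp_ids[0])
        lls = []
        warm = None
        for mid in (1, 2, 3):
            m = LongitudinalGEIModel.from_dataset(
                ds, MeanModelSpec(mid), "hlm", snp_dosages=None if mid == 1 else d
            )
            r = m.fit(start_params=warm)
            warm = r.theta
            lls.append(r.llf)
        assert lls[1] >= lls[0] - 1e-5
        assert lls[2] >= lls[1] - 1e-5

    def test_summary_mentions_structure(self, small_sim):
        ds, _, _ = small_sim
        r = LongitudinalGEIModel.from_dataset(ds, MeanModelSpec(1), "hlm").fit()
        s = r.summary()
        assert "HLM" in s and "log-likelihood" in s


class TestStatsmodelsCrossCheck:
    def test_one_visit_matches_mixedlm_random_intercept(self):
        """With one visit the HLM reduces to a plain family random-intercept
        model, which statsmodels MixedLM fits independently: maximized ML
        log-likelihoods, fixed effects and variance components must agree."""
        from statsmodels.regression.mixed_linear_model import MixedLM

        cfg = SimulationConfig(
            n_families=80, n_visits=1, n_snps=1, covariance="hlm",
            dropout_hazard=0.0, intermittent_missing=0.0,
        )
        ds, _, _ = simulate_dataset(cfg, 33)
        m = LongitudinalGEIModel.from_dataset(ds, MeanModelSpec(1), "hlm")
        r = m.fit()
        groups = np.concatenate(
            [[lay.family_id] * lay.n_cells for lay in m.layouts]
        )
        sm_res = MixedLM(m.y, m.X, groups=groups).fit(reml=False)
        assert r.llf == pytest.approx(sm_res.llf, abs=1e-5)
        np.testing.assert_allclose(
            r.fe_params.to_numpy(), np.asarray(sm_res.fe_params), atol=1e-4
        )
        p = r.cov_struct_params
        assert p.sigma2_f == pytest.approx(float(np.asarray(sm_res.cov_re)[0, 0]), rel=1e-3)
        assert p.sigma2_e == pytest.approx(float(sm_res.scale), rel=1e-3)


class TestSandwich:
    def test_psd_and_close_to_model_cov_when_correct(self):
        cfg = SimulationConfig(
            n_families=400, n_snps=1, covariance="hlm",
            dropout_hazard=0.0, intermittent_missing=0.0,
        )
        ds, _, _ = simulate_dataset(cfg, 22)
        r = LongitudinalGEIModel.from_dataset(ds, MeanModelSpec(1), "hlm").fit()
        w = np.linalg.eigvalsh(r.cov_robust.to_numpy())
        assert w.min() >= -1e-10
        ratio = r.bse / r.bse_model
        assert ((ratio > 0.85) & (ratio < 1.15)).all()

    def test_meat_is_sum_of_score_outer_products(self, two_family_dataset):
        """B equals the explicit sum of per-family score outer products, and a
        family whose residual vector is zero contributes nothing to it."""
        ds = two_family_dataset
        m = LongitudinalGEIModel.from_dataset(ds, MeanModelSpec(1), "hlm")
        theta = np.zeros(4)
        beta, A, B = m._lik.gls(theta)
        params = m.structure.params(theta)
        expected = np.zeros_like(B)
        for (fid, _), s in zip(ds.families.items(), m.slices):
            V = hlm_family_cov(fid, ds, params).matrix
            g = m.X[s].T @ np.linalg.solve(V, m.y[s] - m.X[s] @ beta)
            expected += np.outer(g, g)
            # zeroing this family's residual removes exactly its outer product
            gz = m.X[s].T @ np.linalg.solve(V, np.zeros(s.stop - s.start))
            assert np.abs(np.outer(gz, gz)).max() == 0.0
        np.testing.assert_allclose(B, expected, atol=1e-8)
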