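"""Maximum-likelihood linear mixed models for longitudinal family data.

The model for HDL cholesterol at person-visit cells is one of three nested
mean structures,

    Model 1:  E[Y] = alpha + beta_c' C + beta_e E
    Model 2:  E[Y] = alpha + beta_c' C + beta_e E + beta_g G
    Model 3:  E[Y] = alpha + beta_c' C + beta_e E + beta_g G + beta_ge G*E

(C = age, sex, BMI, medication use; E = alcohol; G = SNP dosage), combined
with a family-block marginal covariance from either the Kronecker (KRC) or
hierarchical (HLM) family (:mod:`longgei.covariance`).

Fitting is full ML.  Fixed effects are profiled out by GLS, so the optimizer
works on the covariance parameters alone; the per-family block likelihood and
its analytic gradient (the profiled-beta term vanishes by the envelope
theorem) feed L-BFGS-B on the unconstrained transformed scale.  The Results
object carries both the model-based and the cluster-robust ("sandwich",
families as clusters) covariance of the fixed effects:

    A = sum_f X_f' V_f^-1 X_f,   B = sum_f (X_f' V_f^-1 r_f)(X_f' V_f^-1 r_f)'
    cov_model = A^-1,            cov_robust = A^-1 B A^-1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .covariance import HlmStructure, KrcStructure, get_structure
from .data import FamilyLayout, LongitudinalFamilyDataset

logger = logging.getLogger(__name__)

__all__ = [
    "MeanModelSpec",
    "LongitudinalGEIModel",
    "LongitudinalGEIResults",
    "build_design",
    "RankDeficiencyError",
]

_PENALTY = 1e10


class RankDeficiencyError(np.linalg.LinAlgError):
    pass


@dataclass(frozen=True)
class MeanModelSpec:
    """Which of the three nested mean models, and which columns feed it.

    Model 1 has no genetic term, Model 2 adds the SNP main effect G, Model 3
    adds the G x E interaction on top; the intercept is always present.
    """

    model_id: int = 1
    covariates: tuple[str, ...] = ("age", "sex_male", "bmi", "med_use")
    exposure: str = "alcohol"

    def __post_init__(self):
        if self.model_id not in (1, 2, 3):
            raise ValueError("model_id must be 1, 2 or 3")

    @property
    def has_g(self) -> bool:
        return self.model_id >= 2

    @property
    def has_ge(self) -> bool:
        return self.model_id == 3

    def column_names(self) -> list[str]:
        names = ["const", *self.covariates, self.exposure]
        if self.has_g:
            names.append("G")
        if self.has_ge:
            names.append("G:E")
        return names


def _record_value(rec, name: str) -> float:
    if name == "sex_male":
        return 1.0 if rec.sex == "male" else 0.0
    return float(getattr(rec, name))


def build_design(
    dataset: LongitudinalFamilyDataset,
    spec: MeanModelSpec,
    snp_dosages: Mapping[str, float] | pd.Series | None = None,
):
    """Stack y, X and family block slices in the dataset's cell order.

    Columns are ordered [1, C..., E, (G), (G:E)]; G is constant across an
    individual's visits while E is time-varying.  For models 2-3 every
    retained individual must have a dosage (drop genotype-missing individuals
    from the dataset first).

    Returns ``(y, X, layouts, slices, names, flags)`` where ``flags`` carries
    data-quality signals such as a monomorphic (constant-column) SNP.
    """
    if spec.has_g and snp_dosages is None:
        raise ValueError(f"model {spec.model_id} requires SNP dosages")
    names = spec.column_names()
    layouts = list(dataset.families.values())
    rows_y: list[float] = []
    rows_X: list[list[float]] = []
    slices: list[slice] = []
    pos = 0
    for lay in layouts:
        for rec in lay.records:
            row = [1.0]
            row.extend(_record_value(rec, c) for c in spec.covariates)
            e = float(rec.alcohol)
            row.append(e)
            if spec.has_g:
                try:
                    g = float(snp_dosages[rec.individual_id])
                except KeyError as exc:
                    raise KeyError(
                        f"no dosage for individual {rec.individual_id!r}"
                    ) from exc
                if np.isnan(g):
                    raise ValueError(
                        f"missing dosage for retained individual {rec.individual_id!r}; "
                        "drop genotype-missing individuals before building the design"
                    )
                row.append(g)
                if spec.has_ge:
                    row.append(g * e)
            rows_X.append(row)
            rows_y.append(float(rec.hdlc))
        slices.append(slice(pos, pos + lay.n_cells))
        pos += lay.n_cells
    X = np.asarray(rows_X, dtype=float)
    y = np.asarray(rows_y, dtype=float)
    flags: dict[str, object] = {}
    if X.shape[0]:
        const_cols = [
            names[j] for j in range(1, X.shape[1]) if np.ptp(X[:, j]) == 0.0
        ]
        if const_cols:
            flags["constant_columns"] = const_cols
    return y, X, layouts, slices, names, flags


# ---------------------------------------------------------------------------
# block Gaussian likelihood with profiled GLS fixed effects
# ---------------------------------------------------------------------------

class _BlockLikelihood:
    """-loglik(theta) and gradient for family-block Gaussian data.

    Per family f:  r_f' V_f^-1 r_f + log det V_f + m_f log 2pi, halved and
    summed, with r_f = y_f - X_f beta_hat(theta) and beta_hat the GLS profile
    estimate.  Gradient uses tr(V^-1 dV) - u' dV u with u = V^-1 r; the
    d beta_hat / d theta term vanishes because the GLS score in beta is zero.
    """

    def __init__(self, y, X, layouts: Sequence[FamilyLayout], slices, structure):
        self.structure = structure
        self.y_blocks = [y[s] for s in slices]
        self.X_blocks = [X[s] for s in slices]
        self.indices = [lay.full_indices for lay in layouts]
        self.sizes = [lay.n_members for lay in layouts]
        self.m_total = sum(len(ix) for ix in self.indices)
        self.p = X.shape[1]
        self.n_params = structure.n_params

    def value_and_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        try:
            templates = self.structure.templates(theta, self.sizes)
        except (ValueError, FloatingPointError):
            return _PENALTY, np.zeros(self.n_params)
        p = self.p
        A = np.zeros((p, p))
        b = np.zeros(p)
        logdet = 0.0
        Vinvs = []
        for yf, Xf, ix, n in zip(self.y_blocks, self.X_blocks, self.indices, self.sizes):
            K, _ = templates[n]
            V = K[np.ix_(ix, ix)]
            try:
                c, low = linalg.cho_factor(V, lower=True, check_finite=False)
            except linalg.LinAlgError:
                return _PENALTY, np.zeros(self.n_params)
            Vinv = linalg.cho_solve((c, low), np.eye(len(ix)), check_finite=False)
            XtVinv = Xf.T @ Vinv
            A += XtVinv @ Xf
            b += XtVinv @ yf
            logdet += 2.0 * np.sum(np.log(np.diag(c)))
            Vinvs.append(Vinv)
        try:
            beta = linalg.solve(A, b, assume_a="pos")
        except linalg.LinAlgError:
            return _PENALTY, np.zeros(self.n_params)
        quad = 0.0
        grad = np.zeros(self.n_params)
        for yf, Xf, ix, n, Vinv in zip(
            self.y_blocks, self.X_blocks, self.indices, self.sizes, Vinvs
        ):
            _, Kdot = templates[n]
            r = yf - Xf @ beta
            u = Vinv @ r
            quad += float(r @ u)
            Bdot = Kdot[:, ix][:, :, ix]
            grad += np.einsum("ij,pij->p", Vinv, Bdot)
            grad -= np.einsum("i,pij,j->p", u, Bdot, u)
        f = 0.5 * (quad + logdet + self.m_total * np.log(2.0 * np.pi))
        self._last = (beta, A)
        return f, 0.5 * grad

    def value(self, theta: np.ndarray) -> float:
        return self.value_and_grad(theta)[0]

    # -- quantities at a fixed theta --------------------------------------
    def gls(self, theta: np.ndarray):
        """beta_hat, A (GLS precision), B (score outer products) at theta."""
        templates = self.structure.templates(theta, self.sizes)
        p = self.p
        A = np.zeros((p, p))
        b = np.zeros(p)
        pieces = []
        for yf, Xf, ix, n in zip(self.y_blocks, self.X_blocks, self.indices, self.sizes):
            K, _ = templates[n]
            V = K[np.ix_(ix, ix)]
            c = linalg.cho_factor(V, lower=True, check_finite=False)
            Vinv = linalg.cho_solve(c, np.eye(len(ix)), check_finite=False)
            XtVinv = Xf.T @ Vinv
            A += XtVinv @ Xf
            b += XtVinv @ yf
            pieces.append((yf, Xf, XtVinv))
        beta = linalg.solve(A, b, assume_a="pos")
        B = np.zeros((p, p))
        for yf, Xf, XtVinv in pieces:
            g = XtVinv @ (yf - Xf @ beta)
            B += np.outer(g, g)
        return beta, A, B


def gls_profile(y, X, family_covs: Sequence[np.ndarray], slices) -> np.ndarray:
    """Explicit profiled GLS: beta = (sum X'V^-1 X)^-1 sum X'V^-1 y."""
    p = X.shape[1]
    A = np.zeros((p, p))
    b = np.zeros(p)
    for V, s in zip(family_covs, slices):
        Xf, yf = X[s], y[s]
        Vi = np.linalg.inv(V)
        A += Xf.T @ Vi @ Xf
        b += Xf.T @ Vi @ yf
    try:
        return np.linalg.solve(A, b)
    except np.linalg.LinAlgError as e:
        raise RankDeficiencyError("singular GLS normal equations") from e


# ---------------------------------------------------------------------------
# starting values
# ---------------------------------------------------------------------------

def _mom_start(structure, y, X, layouts, slices, T):
    """Method-of-moments start from OLS residuals.

    Per-visit covariances of within-individual residual pairs seed
    Sigma_visit; within-family same-visit cross products seed rho_f /
    sigma2_f; lag-1 and lag-2 autocovariances seed the ARMA pair.
    """
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    v_total = float(np.var(resid)) or 1.0

    # index residuals by (family, member, visit)
    cross_fam = []  # same-visit, different-member products
    lag_cov = {k: [] for k in range(0, T)}
    S = np.zeros((T, T))
    Scount = np.zeros((T, T))
    for lay, s in zip(layouts, slices):
        r = resid[s]
        cells = lay.cells
        for a in range(len(cells)):
            ta, ia = cells[a]
            S[ta, ta] += r[a] * r[a]
            Scount[ta, ta] += 1
            for b_ in range(a + 1, len(cells)):
                tb, ib = cells[b_]
                prod = r[a] * r[b_]
                if ia == ib:
                    S[ta, tb] += prod
                    S[tb, ta] += prod
                    Scount[ta, tb] += 1
                    Scount[tb, ta] += 1
                    lag_cov[abs(tb - ta)].append(prod)
                elif ta == tb:
                    cross_fam.append(prod)

    with np.errstate(invalid="ignore", divide="ignore"):
        S = np.where(Scount > 0, S / np.maximum(Scount, 1), np.nan)
    diag_mean = np.nanmean(np.diag(S)) if np.isfinite(np.nanmean(np.diag(S))) else v_total
    S = np.where(np.isnan(S), 0.3 * diag_mean * (~np.eye(T, dtype=bool)), S)
    np.fill_diagonal(S, np.where(np.isnan(np.diag(S)), diag_mean, np.diag(S)))
    # shrink toward the diagonal and clip eigenvalues for a safe SPD start
    S = 0.85 * S + 0.15 * np.diag(np.diag(S))
    w, Q = np.linalg.eigh(S)
    S = (Q * np.maximum(w, 1e-3 * diag_mean)) @ Q.T

    c_fam = float(np.mean(cross_fam)) if cross_fam else 0.1 * v_total
    s2f = min(max(c_fam, 1e-3 * v_total), 0.8 * v_total)

    from .covariance import HlmParams, KrcParams, logchol_from_cov

    if isinstance(structure, KrcStructure):
        rho0 = np.clip(c_fam / diag_mean, structure._lo + 0.02, 0.9)
        return structure.theta(KrcParams(visit_chol=logchol_from_cov(S), rho_f=float(rho0)))
    s2e = max(v_total - s2f, 0.2 * v_total)
    c1 = float(np.mean(lag_cov[1])) if T > 1 and lag_cov[1] else 0.5 * v_total
    c2 = float(np.mean(lag_cov[2])) if T > 2 and lag_cov[2] else 0.8 * c1
    gamma0 = np.clip((c1 - s2f) / s2e, 0.05, 0.95)
    rho0 = np.clip((c2 - s2f) / (c1 - s2f) if abs(c1 - s2f) > 1e-8 else 0.7, 0.05, 0.95)
    return structure.theta(HlmParams(s2f, s2e, float(gamma0), float(rho0)))


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

class LongitudinalGEIModel:
    """Linear mixed model for one mean/covariance specification.

    Parameters
    ----------
    y, X : response vector and fixed-effect design in dataset cell order.
    layouts, slices : per-family cell layouts and row slices into y/X.
    structure : "krc" or "hlm", or a ready Structure object.
    exog_names : design column names.
    """

    def __init__(self, y, X, layouts, slices, structure, exog_names, T=None, flags=None):
        self.y = np.asarray(y, dtype=float)
        self.X = np.asarray(X, dtype=float)
        self.layouts = list(layouts)
        self.slices = list(slices)
        self.exog_names = list(exog_names)
        self.flags = dict(flags or {})
        if len(self.layouts) < 2:
            raise ValueError("at least 2 families are required for ML fitting")
        if T is None:
            raise ValueError("number of grid visits T is required")
        self.T = T
        n_max = max(l.n_members for l in self.layouts)
        self.structure = (
            get_structure(structure, T, n_max) if isinstance(structure, str) else structure
        )
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise RankDeficiencyError(
                f"design is rank deficient (columns {self.exog_names})"
            )
        self._lik = _BlockLikelihood(self.y, self.X, self.layouts, self.slices, self.structure)

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_dataset(
        cls,
        dataset: LongitudinalFamilyDataset,
        spec: MeanModelSpec | None = None,
        structure: str = "hlm",
        snp_dosages=None,
    ) -> "LongitudinalGEIModel":
        spec = spec or MeanModelSpec()
        y, X, layouts, slices, names, flags = build_design(dataset, spec, snp_dosages)
        return cls(
            y, X, layouts, slices, structure, names, T=dataset.n_visits, flags=flags
        )

    # -- likelihood surface -----------------------------------------------
    def nloglike(self, theta) -> float:
        """Negative block log-likelihood at covariance parameters theta."""
        return self._lik.value(np.asarray(theta, dtype=float))

    def loglike(self, theta) -> float:
        return -self.nloglike(theta)

    def score_nloglike(self, theta) -> np.ndarray:
        return self._lik.value_and_grad(np.asarray(theta, dtype=float))[1]

    def profile_beta(self, theta) -> np.ndarray:
        beta, _, _ = self._lik.gls(np.asarray(theta, dtype=float))
        return beta

    def starting_values(self, n_starts: int = 3, seed: int = 0) -> list[np.ndarray]:
        """Multi-start list: MoM-informed, identity-scaled, perturbed MoM."""
        mom = _mom_start(
            self.structure, self.y, self.X, self.layouts, self.slices, self.T
        )
        starts = [mom]
        if n_starts >= 2:
            beta, *_ = np.linalg.lstsq(self.X, self.y, rcond=None)
            v = float(np.var(self.y - self.X @ beta)) or 1.0
            starts.append(self.structure.default_theta(scale=v))
        rng = np.random.default_rng(seed)
        while len(starts) < n_starts:
            starts.append(mom + rng.normal(scale=0.05, size=mom.size))
        return starts[:n_starts]

    # -- fitting -----------------------------------------------------------
    def fit(
        self,
        start_params=None,
        n_starts: int = 3,
        seed: int = 0,
        gtol: float = 1e-5,
        maxiter: int = 500,
    ) -> "LongitudinalGEIResults":
        """ML fit by L-BFGS-B with analytic gradients over the best of several starts.

        ``start_params`` (a theta vector or list of them) overrides the
        default multi-start.  Convergence requires a finite optimum with
        max-norm gradient below ``gtol`` (adaptively scaled by problem size).
        """
        if start_params is None:
            starts = self.starting_values(n_starts=n_starts, seed=seed)
        elif isinstance(start_params, (list, tuple)):
            starts = [np.asarray(s, dtype=float) for s in start_params]
        else:
            starts = [np.asarray(start_params, dtype=float)]

        # gradient tolerance scaled mildly with the data size: the objective is
        # a sum over ~n_obs terms, so component gradients inherit that scale
        tol = gtol * max(1.0, np.sqrt(self._lik.m_total))
        opts = {"maxiter": maxiter, "ftol": 1e-13, "gtol": 1e-8}

        def minimize(th0):
            res = optimize.minimize(
                self._lik.value_and_grad, th0, jac=True, method="L-BFGS-B", options=opts
            )
            # L-BFGS often halts on ftol with a loose gradient; restarting
            # resets the Hessian approximation and polishes the optimum
            for _ in range(2):
                if not (res.fun < _PENALTY) or np.max(np.abs(res.jac)) < tol:
                    break
                res2 = optimize.minimize(
                    self._lik.value_and_grad, res.x, jac=True,
                    method="L-BFGS-B", options=opts,
                )
                res2.nit += res.nit
                if res2.fun > res.fun:
                    break
                res = res2
            return res

        best = None
        for th0 in starts:
            res = minimize(th0)
            if best is None or res.fun < best.fun:
                best = res
            if res.fun < _PENALTY and np.max(np.abs(res.jac)) < tol:
                break  # a clean optimum from an informed start; stop early

        theta = best.x
        f, g = self._lik.value_and_grad(theta)
        converged = bool(np.isfinite(f) and f < _PENALTY and np.max(np.abs(g)) < tol)
        beta, A, B = self._lik.gls(theta)
        cov_model = linalg.inv(A)
        cov_model = 0.5 * (cov_model + cov_model.T)
        cov_robust = cov_model @ B @ cov_model
        cov_robust = 0.5 * (cov_robust + cov_robust.T)
        return LongitudinalGEIResults(
            model=self,
            theta=theta,
            fe_params=pd.Series(beta, index=self.exog_names),
            llf=-f,
            converged=converged,
            grad_norm=float(np.max(np.abs(g))),
            cov_model=pd.DataFrame(cov_model, index=self.exog_names, columns=self.exog_names),
            cov_robust=pd.DataFrame(cov_robust, index=self.exog_names, columns=self.exog_names),
            n_iter=int(best.nit),
            optimizer_message=str(best.message),
        )


@dataclass
class LongitudinalGEIResults:
    """ML estimates, uncertainties and diagnostics for one fitted model."""

    model: LongitudinalGEIModel
    theta: np.ndarray
    fe_params: pd.Series
    llf: float
    converged: bool
    grad_norm: float
    cov_model: pd.DataFrame
    cov_robust: pd.DataFrame
    n_iter: int
    optimizer_message: str

    @property
    def nobs(self) -> int:
        return self.model._lik.m_total

    @property
    def n_families(self) -> int:
        return len(self.model.layouts)

    @property
    def cov_struct_params(self):
        """Covariance parameters (KrcParams or HlmParams) at the optimum."""
        return self.model.structure.params(self.theta)

    @property
    def bse(self) -> pd.Series:
        """Cluster-robust (sandwich) standard errors, families as clusters."""
        return pd.Series(np.sqrt(np.diag(self.cov_robust)), index=self.fe_params.index)

    @property
    def bse_model(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov_model)), index=self.fe_params.index)

    def cov_params(self, robust: bool = True) -> pd.DataFrame:
        return self.cov_robust if robust else self.cov_model

    def summary(self) -> str:
        struct = self.model.structure.name.upper()
        lines = [
            f"Longitudinal family LMM ({struct}), ML",
            f"  n_obs {self.nobs}, families {self.n_families}, visits {self.model.T}",
            f"  log-likelihood {self.llf:.4f}   converged {self.converged} "
            f"(|grad|_max {self.grad_norm:.2e}, {self.n_iter} iterations)",
            "",
            f"  {'term':<10}{'coef':>12}{'robust SE':>12}{'model SE':>12}",
        ]
        for name in self.fe_params.index:
            lines.append(
                f"  {name:<10}{self.fe_params[name]:>12.4f}"
                f"{self.bse[name]:>12.4f}{self.bse_model[name]:>12.4f}"
            )
        cp = self.cov_struct_params
        if isinstance(self.model.structure, HlmStructure):
            lines.append(
                f"  covariance: sigma2_f {cp.sigma2_f:.4f}  sigma2_e {cp.sigma2_e:.4f}"
                f"  gamma {cp.gamma:.4f}  rho {cp.rho:.4f}"
            )
        else:
            sv = cp.sigma_visit(self.model.T)
            lines.append(
                f"  covariance: rho_f {cp.rho_f:.4f}  diag(Sigma_visit) "
                + np.array2string(np.diag(sv), precision=3)
            )
        return "\n".join(lines)
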