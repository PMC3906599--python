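"""The two marginal covariance families for longitudinal family phenotypes.

KRC (Kronecker) model
    ``V = Sigma_visit (x) Omega_family`` with an unstructured (UN)
    visit-by-visit covariance and a compound-symmetry (CS) correlation across
    family members.  Identifiability of the Kronecker scale is fixed by
    constraining ``Omega_family`` to unit diagonal, so all variance lives in
    ``Sigma_visit``.

HLM (hierarchical) model
    A family random intercept (variance ``sigma2_f``) shared by every
    person-visit of the family, plus within-individual ARMA(1,1) serial
    correlation scaled by ``sigma2_e``:

    ``cov[(i,t),(j,t')] = sigma2_f + sigma2_e * arma(t,t')``  if i = j,
    ``sigma2_f`` otherwise, where ``arma(t,t+k) = gamma * rho**(k-1)``.

Both are exposed twice: as plain matrix builders (:func:`krc_family_cov`,
:func:`hlm_family_cov`) over a family's observed cells, and as ``*Structure``
objects that map an unconstrained optimizer vector ``theta`` to per-family
covariance blocks and their analytic derivatives.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.special import expit, logit

from .data import FamilyLayout, LongitudinalFamilyDataset

__all__ = [
    "KrcParams",
    "HlmParams",
    "FamilyCovariance",
    "cs_correlation",
    "un_from_logchol",
    "logchol_from_cov",
    "arma11_correlation",
    "krc_family_cov",
    "hlm_family_cov",
    "KrcStructure",
    "HlmStructure",
    "get_structure",
    "PositiveDefiniteError",
    "ParameterizationError",
]


class PositiveDefiniteError(ValueError):
    pass


class ParameterizationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# elementary builders
# ---------------------------------------------------------------------------

def cs_correlation(n: int, rho_f: float) -> np.ndarray:
    """Compound-symmetry correlation: unit diagonal, constant off-diagonal.

    Positive definite iff ``-1/(n-1) < rho_f < 1`` (any ``rho_f`` for n=1).
    """
    if n < 1:
        raise ParameterizationError("family size must be >= 1")
    if n > 1 and not (-1.0 / (n - 1) < rho_f < 1.0):
        raise PositiveDefiniteError(
            f"rho_f={rho_f} outside (-1/{n - 1}, 1) for family size {n}"
        )
    out = np.full((n, n), float(rho_f))
    np.fill_diagonal(out, 1.0)
    return out


def un_from_logchol(visit_chol: Sequence[float], T: int) -> np.ndarray:
    """Rebuild the unstructured visit covariance from its log-Cholesky vector.

    The vector packs the lower triangle of L row by row; diagonal entries are
    stored on log scale, so any real vector maps to an SPD matrix L L'.
    """
    v = np.asarray(visit_chol, dtype=float)
    if v.shape != (T * (T + 1) // 2,):
        raise ParameterizationError(
            f"visit_chol length {v.size} != T(T+1)/2 = {T * (T + 1) // 2}"
        )
    L = np.zeros((T, T))
    L[np.tril_indices(T)] = v
    np.fill_diagonal(L, np.exp(np.diag(L)))
    return L @ L.T


def logchol_from_cov(sigma: np.ndarray) -> np.ndarray:
    """Inverse of :func:`un_from_logchol` (requires SPD input)."""
    try:
        L = np.linalg.cholesky(np.asarray(sigma, dtype=float))
    except np.linalg.LinAlgError as e:
        raise PositiveDefiniteError("matrix is not positive definite") from e
    M = L.copy()
    np.fill_diagonal(M, np.log(np.diag(L)))
    return M[np.tril_indices(L.shape[0])]


def arma11_correlation(T: int, gamma: float, rho: float) -> np.ndarray:
    """ARMA(1,1) within-individual correlation: lag-k entry ``gamma * rho**(k-1)``.

    AR(1) is the special case gamma == rho; gamma == 0 gives independence.
    """
    if not (abs(gamma) < 1 and abs(rho) < 1):
        raise ParameterizationError("|gamma| and |rho| must be < 1")
    R = np.eye(T)
    for k in range(1, T):
        val = gamma * rho ** (k - 1)
        idx = np.arange(T - k)
        R[idx, idx + k] = val
        R[idx + k, idx] = val
    if T > 1:
        w = np.linalg.eigvalsh(R)
        if w.min() <= 1e-12:
            raise PositiveDefiniteError(
                f"ARMA(1,1) correlation not PD for T={T}, gamma={gamma}, rho={rho}"
            )
    return R


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass
class KrcParams:
    """UN (x) CS parameters: log-Cholesky of Sigma_visit plus family correlation."""

    visit_chol: np.ndarray
    rho_f: float

    def sigma_visit(self, T: int) -> np.ndarray:
        return un_from_logchol(self.visit_chol, T)

    def to_dict(self, T: int) -> dict:
        return {
            "structure": "krc",
            "visit_chol": [float(x) for x in np.ravel(self.visit_chol)],
            "rho_f": float(self.rho_f),
            "sigma_visit": self.sigma_visit(T).tolist(),
        }


@dataclass
class HlmParams:
    """Family intercept variance + ARMA(1,1) residual parameters."""

    sigma2_f: float
    sigma2_e: float
    gamma: float
    rho: float

    def __post_init__(self):
        if self.sigma2_f < 0:
            raise ParameterizationError("sigma2_f must be >= 0")
        if self.sigma2_e <= 0:
            raise ParameterizationError("sigma2_e must be > 0")

    def to_dict(self) -> dict:
        return {
            "structure": "hlm",
            "sigma2_f": float(self.sigma2_f),
            "sigma2_e": float(self.sigma2_e),
            "gamma": float(self.gamma),
            "rho": float(self.rho),
        }


@dataclass
class FamilyCovariance:
    """Marginal covariance of one family's observed person-visit cells."""

    family_id: str
    matrix: np.ndarray


def _subset(full: np.ndarray, layout: FamilyLayout) -> np.ndarray:
    ix = layout.full_indices
    return full[np.ix_(ix, ix)]


def krc_family_cov(
    family: str, dataset: LongitudinalFamilyDataset, params: KrcParams
) -> FamilyCovariance:
    """Sigma_visit (x) Omega_family over the family's grid, cut to observed cells.

    The principal-submatrix cut preserves positive definiteness, so missing
    person-visits never break the model.
    """
    layout = dataset.families[family]
    T = dataset.n_visits
    sigma = params.sigma_visit(T)
    omega = cs_correlation(layout.n_members, params.rho_f)
    return FamilyCovariance(family, _subset(np.kron(sigma, omega), layout))


def hlm_family_cov(
    family: str, dataset: LongitudinalFamilyDataset, params: HlmParams
) -> FamilyCovariance:
    """Family intercept + within-individual ARMA(1,1), cut to observed cells."""
    layout = dataset.families[family]
    T = dataset.n_visits
    n = layout.n_members
    R = arma11_correlation(T, params.gamma, params.rho)
    full = params.sigma2_f + params.sigma2_e * np.kron(R, np.eye(n))
    return FamilyCovariance(family, _subset(full, layout))


# ---------------------------------------------------------------------------
# optimizer-facing structures
# ---------------------------------------------------------------------------
#
# A structure maps an unconstrained vector theta to, for each distinct family
# size n, the full-grid covariance template K_n (T*n x T*n, visit-major) and
# the stacked derivative templates dK_n/dtheta (n_params x T*n x T*n).
# Families subset these by their observed-cell indices.

class KrcStructure:
    """Unconstrained parameterization of the Kronecker UN (x) CS model.

    theta = [visit_chol (T(T+1)/2, log-Cholesky), z_rho] where
    ``rho_f = lo + (1 - lo) * expit(z_rho)`` and ``lo = -1/(n_max - 1)`` is the
    CS bound for the largest family in the dataset (global parameter shared
    across families).
    """

    name = "krc"

    def __init__(self, T: int, n_max: int):
        self.T = T
        self.n_max = max(int(n_max), 1)
        self._lo = -1.0 / (self.n_max - 1) + 1e-6 if self.n_max > 1 else -0.999
        self.n_params = T * (T + 1) // 2 + 1

    # -- theta <-> interpretable params ----------------------------------
    def params(self, theta: np.ndarray) -> KrcParams:
        theta = np.asarray(theta, dtype=float)
        z = theta[-1]
        rho = self._lo + (1.0 - self._lo) * expit(z)
        return KrcParams(visit_chol=theta[:-1].copy(), rho_f=float(rho))

    def theta(self, params: KrcParams) -> np.ndarray:
        u = (params.rho_f - self._lo) / (1.0 - self._lo)
        u = np.clip(u, 1e-10, 1 - 1e-10)
        return np.concatenate([np.ravel(params.visit_chol), [logit(u)]])

    def default_theta(self, scale: float = 1.0) -> np.ndarray:
        v = np.zeros(self.T * (self.T + 1) // 2)
        d = np.cumsum(np.arange(1, self.T + 1)) - 1  # diagonal positions
        v[d] = 0.5 * np.log(scale)
        th = np.concatenate([v, [0.0]])
        return th

    # -- templates --------------------------------------------------------
    def templates(
        self, theta: np.ndarray, sizes: Iterable[int]
    ) -> dict[int, tuple[np.ndarray, np.ndarray]]:
        theta = np.asarray(theta, dtype=float)
        T = self.T
        ntri = T * (T + 1) // 2
        L = np.zeros((T, T))
        tril = np.tril_indices(T)
        L[tril] = theta[:ntri]
        diag = np.diag(L).copy()
        np.fill_diagonal(L, np.exp(diag))
        sigma = L @ L.T

        # dSigma/dtheta_k = E_k L' + L E_k', with the diagonal chain factor
        dsigmas = np.empty((ntri, T, T))
        rows, cols = tril
        for k in range(ntri):
            E = np.zeros((T, T))
            i, j = rows[k], cols[k]
            E[i, j] = L[i, j] if i == j else 1.0  # d(exp)/dtheta on diagonal
            dsigmas[k] = E @ L.T + L @ E.T

        z = theta[-1]
        s = expit(z)
        rho = self._lo + (1.0 - self._lo) * s
        drho = (1.0 - self._lo) * s * (1.0 - s)

        out: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        for n in sorted(set(int(s_) for s_ in sizes)):
            omega = np.full((n, n), rho)
            np.fill_diagonal(omega, 1.0)
            domega = np.full((n, n), drho)
            np.fill_diagonal(domega, 0.0)
            K = np.kron(sigma, omega)
            Kdot = np.empty((self.n_params, T * n, T * n))
            for k in range(ntri):
                Kdot[k] = np.kron(dsigmas[k], omega)
            Kdot[ntri] = np.kron(sigma, domega)
            out[n] = (K, Kdot)
        return out


class HlmStructure:
    """Unconstrained parameterization of the hierarchical model.

    theta = [log sigma2_f, log sigma2_e, atanh(gamma), atanh(rho)].
    """

    name = "hlm"

    def __init__(self, T: int, n_max: int | None = None):
        self.T = T
        self.n_params = 4

    def params(self, theta: np.ndarray) -> HlmParams:
        theta = np.asarray(theta, dtype=float)
        return HlmParams(
            sigma2_f=float(np.exp(theta[0])),
            sigma2_e=float(np.exp(theta[1])),
            gamma=float(np.tanh(theta[2])),
            rho=float(np.tanh(theta[3])),
        )

    def theta(self, params: HlmParams) -> np.ndarray:
        return np.array(
            [
                np.log(max(params.sigma2_f, 1e-10)),
                np.log(params.sigma2_e),
                np.arctanh(np.clip(params.gamma, -1 + 1e-10, 1 - 1e-10)),
                np.arctanh(np.clip(params.rho, -1 + 1e-10, 1 - 1e-10)),
            ]
        )

    def default_theta(self, scale: float = 1.0) -> np.ndarray:
        return np.array(
            [np.log(0.1 * scale), np.log(0.9 * scale), np.arctanh(0.3), np.arctanh(0.5)]
        )

    def templates(
        self, theta: np.ndarray, sizes: Iterable[int]
    ) -> dict[int, tuple[np.ndarray, np.ndarray]]:
        theta = np.asarray(theta, dtype=float)
        T = self.T
        s2f, s2e = np.exp(theta[0]), np.exp(theta[1])
        g, r = np.tanh(theta[2]), np.tanh(theta[3])
        dg, dr = 1.0 - g * g, 1.0 - r * r

        R = np.eye(T)
        dRg = np.zeros((T, T))
        dRr = np.zeros((T, T))
        for k in range(1, T):
            idx = np.arange(T - k)
            R[idx, idx + k] = R[idx + k, idx] = g * r ** (k - 1)
            dRg[idx, idx + k] = dRg[idx + k, idx] = r ** (k - 1)
            if k >= 2:
                dRr[idx, idx + k] = dRr[idx + k, idx] = g * (k - 1) * r ** (k - 2)

        out: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        for n in sorted(set(int(s_) for s_ in sizes)):
            I_n = np.eye(n)
            J = np.ones((T * n, T * n))
            K = s2f * J + s2e * np.kron(R, I_n)
            Kdot = np.empty((4, T * n, T * n))
            Kdot[0] = s2f * J  # d/d log s2f
            Kdot[1] = s2e * np.kron(R, I_n)
            Kdot[2] = s2e * dg * np.kron(dRg, I_n)
            Kdot[3] = s2e * dr * np.kron(dRr, I_n)
            out[n] = (K, Kdot)
        return out


def get_structure(name: str, T: int, n_max: int):
    """Structure factory: ``"krc"`` or ``"hlm"``."""
    if name == "krc":
        return KrcStructure(T, n_max)
    if name == "hlm":
        return HlmStructure(T, n_max)
    raise ValueError(f"unknown covariance structure {name!r}")
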