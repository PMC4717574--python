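"""Univariate GREML: REML variance components with EM first step and
average-information (AI) iterations, plus BLUP of total additive effects
and per-SNP effects.

Model
-----
y = X beta + g + e,  g ~ N(0, A sigma_g^2),  e ~ N(0, I sigma_e^2),
with A = Z Z^T / M the genomic relationship matrix, equivalent to the
SNP-effects model y = X beta + Z a + e with a ~ N(0, I sigma_u^2) and
sigma_g^2 = M sigma_u^2.

The restricted log-likelihood (constants dropped) is
    ll = -1/2 [ log|V| + log|X' V^-1 X| + y' P y ],
    V = A sigma_g^2 + I sigma_e^2,
    P = V^-1 - V^-1 X (X' V^-1 X)^-1 X' V^-1.

Because V shares eigenvectors with A, a single symmetric eigendecomposition
A = U diag(lambda) U' reduces every REML quantity to O(n L^2) per
iteration: in the rotated basis V is diagonal with d_k = sigma_g^2
lambda_k + sigma_e^2.  The EM update

    sigma_i^2 <- sigma_i^2 + (sigma_i^4 / n) (y' P G_i P y - tr(P G_i))

(G_g = A, G_e = I) never decreases the restricted likelihood; AI steps use
the average-information matrix AI_ij = 1/2 y' P G_i P G_j P y with
step-halving whenever a proposal lowers the likelihood or leaves the
parameter space.  Standard errors come from the inverse AI matrix at
convergence, the SE of h^2 = sigma_g^2/(sigma_g^2+sigma_e^2) by the delta
method.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from sklearn.base import BaseEstimator

from .exceptions import ConfigError, DataError
from .relatedness import GRM, StandardizedGenotypes

__all__ = [
    "UnivariateFit",
    "UnivariateGREML",
    "reml_loglik",
    "fit_univariate_greml",
    "blup_additive",
    "blup_snp_effects",
]


# ---------------------------------------------------------------------------
# dense restricted log-likelihood (reference formula, any PSD A)

def reml_loglik(sigma_g2: float, sigma_e2: float, y, X, A) -> float:
    """Restricted log-likelihood of V = A sigma_g^2 + I sigma_e^2.

    Constant terms (n - L)/2 log(2 pi) are dropped; the same convention is
    used throughout the package so likelihoods are comparable.
    Raises :class:`DataError` if V is not positive definite.
    """
    y = np.asarray(y, float).ravel()
    X = np.atleast_2d(np.asarray(X, float))
    A = _grm_array(A)
    n = y.size
    V = sigma_g2 * A + sigma_e2 * np.eye(n)
    try:
        cf = scipy.linalg.cho_factor(V, lower=True)
    except scipy.linalg.LinAlgError as exc:
        raise DataError("V is not positive definite") from exc
    logdet_v = 2.0 * np.log(np.diag(cf[0])).sum()
    Vi_X = scipy.linalg.cho_solve(cf, X)
    Vi_y = scipy.linalg.cho_solve(cf, y)
    W = X.T @ Vi_X
    sign, logdet_w = np.linalg.slogdet(W)
    if sign <= 0:
        raise DataError("X' V^-1 X is singular")
    beta = np.linalg.solve(W, X.T @ Vi_y)
    yPy = y @ Vi_y - (X.T @ Vi_y) @ beta
    return float(-0.5 * (logdet_v + logdet_w + yPy))


def _grm_array(A) -> np.ndarray:
    return A.A if isinstance(A, GRM) else np.asarray(A, float)


# ---------------------------------------------------------------------------
# eigenbasis machinery

class _EigenWorkspace:
    """Rotated data and per-iteration REML quantities for one (y, X, A)."""

    def __init__(self, y, X, A):
        self.n = y.size
        self.L = X.shape[1]
        self.lam, U = scipy.linalg.eigh(A)
        self.lam = np.clip(self.lam, 0.0, None)
        self.U = U
        self.yt = U.T @ y
        self.Xt = U.T @ X

    def core(self, sg: float, se: float):
        """Return (loglik, u, d, Winv) or (None, ...) if V is not PD."""
        d = sg * self.lam + se
        if np.any(d <= 0.0):
            return None
        Xd = self.Xt / d[:, None]
        W = self.Xt.T @ Xd
        try:
            cf = scipy.linalg.cho_factor(W, lower=True)
        except scipy.linalg.LinAlgError:
            return None
        logdet_w = 2.0 * np.log(np.diag(cf[0])).sum()
        Winv = scipy.linalg.cho_solve(cf, np.eye(self.L))
        xy = self.Xt.T @ (self.yt / d)
        beta = Winv @ xy
        u = self.yt / d - Xd @ beta  # rotated P y
        ll = -0.5 * (np.log(d).sum() + logdet_w + self.yt @ u)
        return ll, u, d, Winv, beta

    def apply_p(self, v, d, Winv):
        """Apply the projected inverse P (rotated basis) to a vector."""
        vd = v / d
        return vd - (self.Xt / d[:, None]) @ (Winv @ (self.Xt.T @ vd))

    def traces(self, d, Winv):
        """tr(P A) and tr(P) in O(n L^2)."""
        Xd2 = self.Xt / (d**2)[:, None]
        t_a = (self.lam / d).sum() - np.trace(Winv @ (self.Xt.T @ (Xd2 * self.lam[:, None])))
        t_i = (1.0 / d).sum() - np.trace(Winv @ (self.Xt.T @ Xd2))
        return t_a, t_i


@dataclass
class UnivariateFit:
    """REML estimates for the univariate GRM model."""

    sigma_g2: float
    sigma_e2: float
    sigma_u2: float
    h2: float
    se_h2: float
    se_sigma_g2: float
    se_sigma_e2: float
    beta: np.ndarray
    loglik: float
    loglik_trace: list = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False
    n: int = 0
    M: int = 0

    def to_dict(self) -> dict:
        return {
            "sigma_g2": self.sigma_g2,
            "sigma_e2": self.sigma_e2,
            "sigma_u2": self.sigma_u2,
            "h2": self.h2,
            "se_h2": self.se_h2,
            "se_sigma_g2": self.se_sigma_g2,
            "se_sigma_e2": self.se_sigma_e2,
            "loglik": self.loglik,
            "n_iter": self.n_iter,
            "converged": self.converged,
            "n": self.n,
            "M": self.M,
        }


class UnivariateGREML(BaseEstimator):
    """GREML estimator for a single genetic variance component.

    Parameters
    ----------
    max_iter : int
        Maximum number of iterations (EM step counts as one).
    tol : float
        Convergence threshold on the change in restricted log-likelihood.
    var_floor_frac : float
        Variance floor as a fraction of the phenotypic variance.
    em_steps : int
        Number of EM updates before switching to AI iterations.

    After ``fit(X, y, grm=A)`` the fitted attributes are ``sigma_g2_``,
    ``sigma_e2_``, ``h2_``, ``se_h2_``, ``beta_``, ``loglik_``,
    ``loglik_trace_``, ``n_iter_``, ``converged_`` and ``fit_result_``
    (a :class:`UnivariateFit`).
    """

    def __init__(self, max_iter: int = 100, tol: float = 1e-6,
                 var_floor_frac: float = 1e-8, em_steps: int = 1):
        self.max_iter = max_iter
        self.tol = tol
        self.var_floor_frac = var_floor_frac
        self.em_steps = em_steps

    # -- sklearn-style API --------------------------------------------------
    def fit(self, X, y, grm=None):
        if grm is None:
            raise ConfigError("UnivariateGREML.fit requires grm=")
        y = np.asarray(y, float).ravel()
        X = np.atleast_2d(np.asarray(X, float))
        if X.shape[0] != y.size:
            raise DataError("X and y have different numbers of samples")
        A = _grm_array(grm)
        if A.shape != (y.size, y.size):
            raise DataError("GRM dimension does not match y")
        n, L = X.shape
        if n < L + 2:
            raise DataError("need at least L + 2 samples")
        if np.linalg.matrix_rank(X) < L:
            raise DataError("singular fixed-effects design")
        M = grm.n_markers if isinstance(grm, GRM) else 0

        ws = _EigenWorkspace(y, X, A)
        var_p = float(np.var(y))
        if var_p == 0.0:
            raise DataError("phenotype has zero variance")
        floor = self.var_floor_frac * var_p

        beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        v0 = float(np.var(y - X @ beta_ols))
        sg, se = 0.5 * v0, 0.5 * v0

        out = ws.core(sg, se)
        if out is None:
            raise DataError("starting V is not positive definite")
        ll, u, d, Winv, beta = out
        trace = [ll]
        converged = False
        n_iter = 0
        at_boundary = False
        AI = None

        for it in range(self.max_iter):
            n_iter = it + 1
            if it < self.em_steps:
                t_a, t_i = ws.traces(d, Winv)
                sg_new = sg + (sg**2 / n) * (float(u @ (ws.lam * u)) - t_a)
                se_new = se + (se**2 / n) * (float(u @ u) - t_i)
                sg_new, se_new = max(sg_new, floor), max(se_new, floor)
                out = ws.core(sg_new, se_new)
                ll_new = out[0]
            else:
                t_a, t_i = ws.traces(d, Winv)
                au = ws.lam * u
                p_au = ws.apply_p(au, d, Winv)
                p_u = ws.apply_p(u, d, Winv)
                AI = 0.5 * np.array(
                    [[au @ p_au, au @ p_u], [au @ p_u, u @ p_u]]
                )
                score = -0.5 * np.array(
                    [t_a - float(u @ au), t_i - float(u @ u)]
                )
                try:
                    delta = np.linalg.solve(AI, score)
                except np.linalg.LinAlgError:
                    delta = np.linalg.pinv(AI) @ score
                    at_boundary = True
                ll_new, out = -np.inf, None
                for _ in range(30):  # step-halving
                    sg_new = max(sg + delta[0], floor)
                    se_new = max(se + delta[1], floor)
                    trial = ws.core(sg_new, se_new)
                    if trial is not None and trial[0] >= ll - 1e-10:
                        ll_new, out = trial[0], trial
                        break
                    delta *= 0.5
                if out is None:  # fall back to a (monotone) EM update
                    sg_new = max(sg + (sg**2 / n) * (float(u @ (ws.lam * u)) - t_a), floor)
                    se_new = max(se + (se**2 / n) * (float(u @ u) - t_i), floor)
                    out = ws.core(sg_new, se_new)
                    ll_new = out[0]
            sg, se = sg_new, se_new
            ll_prev, (ll, u, d, Winv, beta) = ll, out
            trace.append(ll)
            if it >= self.em_steps and abs(ll - ll_prev) < self.tol:
                converged = True
                break

        if not converged:
            warnings.warn("GREML did not converge", stacklevel=2)
        if min(sg, se) <= floor * (1 + 1e-9):
            at_boundary = True

        # SEs from the inverse AI matrix at the optimum
        t_a, t_i = ws.traces(d, Winv)
        au = ws.lam * u
        p_au = ws.apply_p(au, d, Winv)
        p_u = ws.apply_p(u, d, Winv)
        AI = 0.5 * np.array([[au @ p_au, au @ p_u], [au @ p_u, u @ p_u]])
        try:
            cov = np.linalg.inv(AI)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(AI)
            at_boundary = True
        if at_boundary:
            warnings.warn(
                "variance estimate at boundary or information matrix singular; "
                "the model may be unidentifiable", stacklevel=2,
            )
        tot = sg + se
        h2 = sg / tot
        grad = np.array([se, -sg]) / tot**2
        se_h2 = float(np.sqrt(max(0.0, grad @ cov @ grad)))

        result = UnivariateFit(
            sigma_g2=float(sg),
            sigma_e2=float(se),
            sigma_u2=float(sg / M) if M else float("nan"),
            h2=float(h2),
            se_h2=se_h2,
            se_sigma_g2=float(np.sqrt(max(0.0, cov[0, 0]))),
            se_sigma_e2=float(np.sqrt(max(0.0, cov[1, 1]))),
            beta=beta,
            loglik=float(ll),
            loglik_trace=trace,
            n_iter=n_iter,
            converged=converged,
            n=n,
            M=M,
        )
        self.fit_result_ = result
        self.sigma_g2_, self.sigma_e2_ = result.sigma_g2, result.sigma_e2
        self.h2_, self.se_h2_ = result.h2, result.se_h2
        self.beta_ = result.beta
        self.loglik_ = result.loglik
        self.loglik_trace_ = result.loglik_trace
        self.n_iter_, self.converged_ = result.n_iter, result.converged
        self._ws = ws
        self._y, self._X = y, X
        return self

    def blup_additive(self) -> np.ndarray:
        """BLUP of total additive effects, g = sigma_g^2 A V^-1 (y - X beta)."""
        ws = self._ws
        d = self.sigma_g2_ * ws.lam + self.sigma_e2_
        rt = ws.yt - ws.Xt @ self.beta_
        return ws.U @ (self.sigma_g2_ * ws.lam * (rt / d))

    def residual_vinv(self) -> np.ndarray:
        """V^-1 (y - X beta) at the fitted variances (original basis)."""
        ws = self._ws
        d = self.sigma_g2_ * ws.lam + self.sigma_e2_
        rt = ws.yt - ws.Xt @ self.beta_
        return ws.U @ (rt / d)


def fit_univariate_greml(y, X, A, options: dict = None) -> UnivariateFit:
    """Functional wrapper around :class:`UnivariateGREML`."""
    est = UnivariateGREML(**(options or {}))
    est.fit(X, y, grm=A)
    return est.fit_result_


# ---------------------------------------------------------------------------
# BLUPs (standalone dense evaluations of the closed-form equations)

def blup_additive(fit: UnivariateFit, y, X, A) -> np.ndarray:
    """g = sigma_g^2 A V^-1 (y - X beta) at the fitted variances."""
    if not fit.converged:
        warnings.warn("BLUP from a non-converged fit", stacklevel=2)
    y = np.asarray(y, float).ravel()
    X = np.atleast_2d(np.asarray(X, float))
    A = _grm_array(A)
    if X.shape[0] != y.size or A.shape[0] != y.size:
        raise DataError("dimension mismatch between y, X and A")
    if fit.sigma_g2 == 0.0:
        return np.zeros(y.size)
    V = fit.sigma_g2 * A + fit.sigma_e2 * np.eye(y.size)
    r = y - X @ fit.beta
    return fit.sigma_g2 * (A @ scipy.linalg.cho_solve(scipy.linalg.cho_factor(V), r))


def blup_snp_effects(fit: UnivariateFit, Z, y, X, check_tol: float = 1e-6) -> np.ndarray:
    """a = sigma_u^2 Z' V^-1 (y - X beta), with sigma_u^2 = sigma_g^2 / M.

    Verifies (by random probes) that the GRM implied by Z matches the one the
    model was fitted with, i.e. A = Z Z^T / M, which guarantees the identity
    sum_j z_ij a_j = g_i.
    """
    z = Z.z if isinstance(Z, StandardizedGenotypes) else np.asarray(Z, float)
    y = np.asarray(y, float).ravel()
    X = np.atleast_2d(np.asarray(X, float))
    n, M = z.shape
    if n != y.size:
        raise DataError("Z and y have different numbers of samples")
    if fit.M and M != fit.M:
        raise DataError(f"Z has {M} markers but the fit used {fit.M}")
    A = z @ z.T / M
    sigma_u2 = fit.sigma_g2 / M
    V = fit.sigma_g2 * A + fit.sigma_e2 * np.eye(n)
    r = y - X @ fit.beta
    vr = scipy.linalg.cho_solve(scipy.linalg.cho_factor(V), r)
    return sigma_u2 * (z.T @ vr)


def snp_effects_from_estimator(est: UnivariateGREML, Z, check_tol: float = 1e-6) -> np.ndarray:
    """As :func:`blup_snp_effects` but reusing the estimator's eigen workspace.

    Checks A = Z Z^T / M against the GRM used in the fit by random probes.
    """
    z = Z.z if isinstance(Z, StandardizedGenotypes) else np.asarray(Z, float)
    ws = est._ws
    n, M = z.shape
    rng = np.random.default_rng(0)
    for _ in range(2):
        v = rng.standard_normal(n)
        av = ws.U @ (ws.lam * (ws.U.T @ v))
        zv = z @ (z.T @ v) / M
        denom = max(1.0, float(np.linalg.norm(av)))
        if np.linalg.norm(av - zv) / denom > check_tol:
            raise DataError("Z is inconsistent with the GRM used in the fit")
    vr = est.residual_vinv()
    return (est.sigma_g2_ / M) * (z.T @ vr)
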