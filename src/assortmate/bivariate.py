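"""Bivariate GREML: genetic, environmental and phenotypic correlations
between two traits under a block mixed-model covariance structure.

Model (stacked traits):
    y = (y1; y2) = X beta + (g1; g2) + (e1; e2)
    var(g) = [[A1 sg1, A12 sg12], [A12' sg12, A2 sg2]]
    var(e) = [[I se1, I12 se12], [I12' se12, I se2]]
where I12 marks which individual of trait 1 is which individual of trait 2
(the overlap map).  Six (co)variance components are estimated by REML with
an EM first step and AI iterations; proposals that leave the
positive-definite cone are rejected by step-halving.

When both traits are measured on the same individuals with a single GRM
(A1 = A2 = A12, I12 = I), every REML quantity reduces, after one
eigendecomposition of the GRM, to independent 2x2 blocks per eigenvalue; the
fit is then O(n) per iteration.  A dense general-covariance path handles
arbitrary overlap maps and distinct A-blocks at small n.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from sklearn.base import BaseEstimator

from .exceptions import ConfigError, DataError
from .relatedness import GRM

__all__ = [
    "OverlapMap",
    "BivariateFit",
    "BivariateGREML",
    "fit_bivariate_greml",
    "correlations_from_components",
]


@dataclass
class OverlapMap:
    """Pairs (i, j): individual i of trait 1 is individual j of trait 2."""

    pairs: list
    n1: int
    n2: int

    def __post_init__(self):
        if self.pairs:
            i_side = [p[0] for p in self.pairs]
            j_side = [p[1] for p in self.pairs]
            if len(set(i_side)) != len(i_side) or len(set(j_side)) != len(j_side):
                raise DataError("each index may appear at most once per side")

    @classmethod
    def identity(cls, n: int) -> "OverlapMap":
        return cls(pairs=[(i, i) for i in range(n)], n1=n, n2=n)

    def matrix(self) -> np.ndarray:
        m = np.zeros((self.n1, self.n2))
        for i, j in self.pairs:
            m[i, j] = 1.0
        return m

    @property
    def is_identity(self) -> bool:
        return self.n1 == self.n2 and self.pairs == [(i, i) for i in range(self.n1)]


def correlations_from_components(
    sigma_g1_2, sigma_g2_2, sigma_g12, sigma_e1_2, sigma_e2_2, sigma_e12
):
    """(r_G, r_E, r_P) from the six (co)variance components."""
    if min(sigma_g1_2, sigma_g2_2, sigma_e1_2, sigma_e2_2) <= 0:
        raise DataError("variance components must be positive")
    r_g = sigma_g12 / np.sqrt(sigma_g1_2 * sigma_g2_2)
    r_e = sigma_e12 / np.sqrt(sigma_e1_2 * sigma_e2_2)
    r_p = (sigma_g12 + sigma_e12) / np.sqrt(
        (sigma_g1_2 + sigma_e1_2) * (sigma_g2_2 + sigma_e2_2)
    )
    return float(r_g), float(r_e), float(r_p)


@dataclass
class BivariateFit:
    sigma_g1_2: float
    sigma_g2_2: float
    sigma_g12: float
    sigma_e1_2: float
    sigma_e2_2: float
    sigma_e12: float
    h2_1: float
    h2_2: float
    se_h2_1: float
    se_h2_2: float
    r_g: float
    r_e: float
    r_p: float
    se_r_g: float
    se_r_e: float
    se_r_p: float
    beta1: np.ndarray
    beta2: np.ndarray
    loglik: float
    loglik_trace: list = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False

    def to_dict(self) -> dict:
        return {
            k: getattr(self, k)
            for k in (
                "sigma_g1_2", "sigma_g2_2", "sigma_g12",
                "sigma_e1_2", "sigma_e2_2", "sigma_e12",
                "h2_1", "h2_2", "se_h2_1", "se_h2_2",
                "r_g", "r_e", "r_p", "se_r_g", "se_r_e", "se_r_p",
                "loglik", "n_iter", "converged",
            )
        }


# ---------------------------------------------------------------------------
# shared-GRM, full-overlap eigen path

class _BivEigen:
    """2x2-block REML workspace in the eigenbasis of a shared GRM."""

    # (a, b, c) coefficients of G_i per eigen-index: G_ik = [[a, b], [b, c]]
    # with entries linear in lambda for genetic and constant for residual.
    PARAM_NAMES = ("g1", "g2", "g12", "e1", "e2", "e12")

    def __init__(self, y1, y2, X1, X2, A):
        self.n = y1.size
        self.L1, self.L2 = X1.shape[1], X2.shape[1]
        self.lam, U = scipy.linalg.eigh(A)
        self.lam = np.clip(self.lam, 0.0, None)
        self.U = U
        self.y = np.column_stack([U.T @ y1, U.T @ y2])  # (n, 2)
        self.X1 = U.T @ X1
        self.X2 = U.T @ X2

    # -- per-parameter (a, b, c) arrays -------------------------------------
    def _coeffs(self, name):
        lam, one = self.lam, np.ones(self.n)
        zero = np.zeros(self.n)
        return {
            "g1": (lam, zero, zero),
            "g2": (zero, zero, lam),
            "g12": (zero, lam, zero),
            "e1": (one, zero, zero),
            "e2": (zero, zero, one),
            "e12": (zero, one, zero),
        }[name]

    def core(self, theta):
        """theta = (g1, g2, g12, e1, e2, e12) -> None if V not PD, else state."""
        g1, g2, g12, e1, e2, e12 = theta
        p = g1 * self.lam + e1
        r = g2 * self.lam + e2
        q = g12 * self.lam + e12
        det = p * r - q * q
        if np.any(p <= 0) or np.any(r <= 0) or np.any(det <= 0):
            return None
        i11, i12, i22 = r / det, -q / det, p / det

        L1, L2 = self.L1, self.L2
        W = np.empty((L1 + L2, L1 + L2))
        W[:L1, :L1] = self.X1.T @ (i11[:, None] * self.X1)
        W[:L1, L1:] = self.X1.T @ (i12[:, None] * self.X2)
        W[L1:, :L1] = W[:L1, L1:].T
        W[L1:, L1:] = self.X2.T @ (i22[:, None] * self.X2)
        try:
            cf = scipy.linalg.cho_factor(W, lower=True)
        except scipy.linalg.LinAlgError:
            return None
        logdet_w = 2.0 * np.log(np.diag(cf[0])).sum()
        Winv = scipy.linalg.cho_solve(cf, np.eye(L1 + L2))

        state = {"inv": (i11, i12, i22), "det": det, "Winv": Winv}
        a = self._vinv(self.y, state)
        xy = np.concatenate([self.X1.T @ a[:, 0], self.X2.T @ a[:, 1]])
        beta = Winv @ xy
        xb = np.column_stack([self.X1 @ beta[:L1], self.X2 @ beta[L1:]])
        u = a - self._vinv(xb, state)
        ll = -0.5 * (np.log(det).sum() + logdet_w + float((self.y * u).sum()))
        state.update(ll=ll, u=u, beta=beta)
        return state

    def _vinv(self, S, state):
        i11, i12, i22 = state["inv"]
        out = np.empty_like(S)
        out[:, 0] = i11 * S[:, 0] + i12 * S[:, 1]
        out[:, 1] = i12 * S[:, 0] + i22 * S[:, 1]
        return out

    def apply_p(self, S, state):
        t = self._vinv(S, state)
        h = np.concatenate([self.X1.T @ t[:, 0], self.X2.T @ t[:, 1]])
        wh = state["Winv"] @ h
        xb = np.column_stack([self.X1 @ wh[: self.L1], self.X2 @ wh[self.L1 :]])
        return t - self._vinv(xb, state)

    def apply_g(self, name, S):
        a, b, c = self._coeffs(name)
        out = np.empty_like(S)
        out[:, 0] = a * S[:, 0] + b * S[:, 1]
        out[:, 1] = b * S[:, 0] + c * S[:, 1]
        return out

    def trace_pg(self, name, state):
        i11, i12, i22 = state["inv"]
        a, b, c = self._coeffs(name)
        tr_vinv_g = float((i11 * a + 2.0 * i12 * b + i22 * c).sum())
        # E = Cinv G Cinv per eigen-index
        t11 = a * i11 + b * i12
        t12 = b * i11 + c * i12
        t21 = a * i12 + b * i22
        t22 = b * i12 + c * i22
        e11 = t11 * i11 + t12 * i12
        e12 = t11 * i12 + t12 * i22
        e21 = t21 * i11 + t22 * i12  # == e12 by symmetry of G and Cinv
        e22 = t21 * i12 + t22 * i22
        L1 = self.L1
        T = np.empty_like(state["Winv"])
        T[:L1, :L1] = self.X1.T @ (e11[:, None] * self.X1)
        T[:L1, L1:] = self.X1.T @ (e12[:, None] * self.X2)
        T[L1:, :L1] = self.X2.T @ (e21[:, None] * self.X1)
        T[L1:, L1:] = self.X2.T @ (e22[:, None] * self.X2)
        return tr_vinv_g - float(np.trace(state["Winv"] @ T))

    def em_step(self, theta, state, floor):
        """Exact EM update of the 2x2 genetic and residual covariance matrices."""
        g1, g2, g12, e1, e2, e12 = theta
        n = self.n
        u = state["u"]
        i11, i12, i22 = state["inv"]
        Winv = state["Winv"]
        L1 = self.L1
        # per-eigen-index 2x2 diagonal blocks of V^-1 X (X'V^-1X)^-1 X'V^-1
        B = np.empty((n, 2, L1 + self.L2))
        B[:, 0, :L1] = i11[:, None] * self.X1
        B[:, 1, :L1] = i12[:, None] * self.X1
        B[:, 0, L1:] = i12[:, None] * self.X2
        B[:, 1, L1:] = i22[:, None] * self.X2
        BW = np.einsum("kaj,ji->kai", B, Winv)
        Mk = np.einsum("kai,kbi->kab", BW, B)
        p11 = i11 - Mk[:, 0, 0]
        p12 = i12 - Mk[:, 0, 1]
        p22 = i22 - Mk[:, 1, 1]

        lam = self.lam
        Qg = np.array(
            [
                [u[:, 0] @ (lam * u[:, 0]) - (lam * p11).sum(),
                 u[:, 0] @ (lam * u[:, 1]) - (lam * p12).sum()],
                [u[:, 0] @ (lam * u[:, 1]) - (lam * p12).sum(),
                 u[:, 1] @ (lam * u[:, 1]) - (lam * p22).sum()],
            ]
        )
        Qe = np.array(
            [
                [u[:, 0] @ u[:, 0] - p11.sum(), u[:, 0] @ u[:, 1] - p12.sum()],
                [u[:, 0] @ u[:, 1] - p12.sum(), u[:, 1] @ u[:, 1] - p22.sum()],
            ]
        )
        Sg = np.array([[g1, g12], [g12, g2]])
        Se = np.array([[e1, e12], [e12, e2]])
        Sg = Sg + (Sg @ Qg @ Sg) / n
        Se = Se + (Se @ Qe @ Se) / n
        Sg[0, 0], Sg[1, 1] = max(Sg[0, 0], floor), max(Sg[1, 1], floor)
        Se[0, 0], Se[1, 1] = max(Se[0, 0], floor), max(Se[1, 1], floor)
        return np.array([Sg[0, 0], Sg[1, 1], Sg[0, 1], Se[0, 0], Se[1, 1], Se[0, 1]])

    def ai_and_score(self, state):
        u = state["u"]
        names = self.PARAM_NAMES
        w = [self.apply_g(nm, u) for nm in names]
        pw = [self.apply_p(wi, state) for wi in w]
        k = len(names)
        AI = np.empty((k, k))
        score = np.empty(k)
        for i in range(k):
            for j in range(i, k):
                AI[i, j] = AI[j, i] = 0.5 * float((w[i] * pw[j]).sum())
            score[i] = -0.5 * (self.trace_pg(names[i], state) - float((u * w[i]).sum()))
        return AI, score


class BivariateGREML(BaseEstimator):
    """Bivariate GREML estimator.

    ``fit(X1, y1, X2, y2, grm=A)`` handles the shared-GRM full-overlap case
    via the eigenbasis fast path; pass ``grm_blocks=(A1, A2, A12)`` and
    ``overlap=OverlapMap(...)`` for the general case (dense, small n).
    Fitted attributes mirror :class:`BivariateFit` with trailing underscores
    (``h2_1_``, ``r_g_``, ...), plus ``fit_result_``.
    """

    def __init__(self, max_iter: int = 100, tol: float = 1e-6,
                 var_floor_frac: float = 1e-8, em_steps: int = 1):
        self.max_iter = max_iter
        self.tol = tol
        self.var_floor_frac = var_floor_frac
        self.em_steps = em_steps

    def fit(self, X1, y1, X2, y2, grm=None, grm_blocks=None, overlap=None):
        y1 = np.asarray(y1, float).ravel()
        y2 = np.asarray(y2, float).ravel()
        X1 = np.atleast_2d(np.asarray(X1, float))
        X2 = np.atleast_2d(np.asarray(X2, float))
        for X, y, tag in ((X1, y1, "1"), (X2, y2, "2")):
            if X.shape[0] != y.size:
                raise DataError(f"X{tag} and y{tag} differ in sample count")
            if np.linalg.matrix_rank(X) < X.shape[1]:
                raise DataError(f"singular fixed-effects design for trait {tag}")

        if grm is not None and (overlap is None or overlap.is_identity):
            if y1.size != y2.size:
                raise DataError("shared-GRM path requires equal sample counts")
            A = grm.A if isinstance(grm, GRM) else np.asarray(grm, float)
            ws = _BivEigen(y1, y2, X1, X2, A)
            return self._fit_loop(ws, y1, y2)
        if grm_blocks is None:
            if grm is None:
                raise ConfigError("provide grm= or grm_blocks=")
            A = grm.A if isinstance(grm, GRM) else np.asarray(grm, float)
            grm_blocks = (A, A, A)
        if overlap is None:
            raise ConfigError("general path requires an OverlapMap")
        ws = _BivDense(y1, y2, X1, X2, grm_blocks, overlap)
        return self._fit_loop(ws, y1, y2)

    def _fit_loop(self, ws, y1, y2):
        var_p = 0.5 * (np.var(y1) + np.var(y2))
        floor = self.var_floor_frac * var_p
        b1, *_ = np.linalg.lstsq(ws_X(ws, 1), y1, rcond=None)
        b2, *_ = np.linalg.lstsq(ws_X(ws, 2), y2, rcond=None)
        v1 = float(np.var(y1 - ws_X(ws, 1) @ b1))
        v2 = float(np.var(y2 - ws_X(ws, 2) @ b2))
        theta = np.array([0.5 * v1, 0.5 * v2, 0.0, 0.5 * v1, 0.5 * v2, 0.0])

        state = ws.core(theta)
        if state is None:
            raise DataError("starting covariance is not positive definite")
        ll = state["ll"]
        trace = [ll]
        converged = False
        n_iter = 0
        for it in range(self.max_iter):
            n_iter = it + 1
            if it < self.em_steps:
                theta_new = ws.em_step(theta, state, floor)
                new_state = ws.core(theta_new)
                if new_state is None:  # numerically degenerate; damp toward old
                    theta_new = 0.5 * (theta + theta_new)
                    new_state = ws.core(theta_new)
                    if new_state is None:
                        raise DataError("EM step left the parameter space")
            else:
                AI, score = ws.ai_and_score(state)
                try:
                    delta = np.linalg.solve(AI, score)
                except np.linalg.LinAlgError:
                    delta = np.linalg.pinv(AI) @ score
                new_state = None
                for _ in range(30):
                    theta_new = theta + delta
                    theta_new[:2] = np.maximum(theta_new[:2], floor)
                    theta_new[3:5] = np.maximum(theta_new[3:5], floor)
                    trial = ws.core(theta_new)
                    if trial is not None and trial["ll"] >= ll - 1e-10:
                        new_state = trial
                        break
                    delta = 0.5 * delta
                if new_state is None:
                    theta_new = ws.em_step(theta, state, floor)
                    new_state = ws.core(theta_new)
                    if new_state is None:
                        warnings.warn("no admissible REML step; stopping", stacklevel=2)
                        break
            theta, ll_prev = theta_new, ll
            state, ll = new_state, new_state["ll"]
            trace.append(ll)
            if it >= self.em_steps and abs(ll - ll_prev) < self.tol:
                converged = True
                break
        if not converged:
            warnings.warn("bivariate GREML did not converge", stacklevel=2)

        AI, _ = ws.ai_and_score(state)
        try:
            cov = np.linalg.inv(AI)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(AI)

        g1, g2, g12, e1, e2, e12 = theta
        r_g, r_e, r_p = correlations_from_components(g1, g2, g12, e1, e2, e12)
        r_g, r_e = float(np.clip(r_g, -1, 1)), float(np.clip(r_e, -1, 1))
        h2_1 = g1 / (g1 + e1)
        h2_2 = g2 / (g2 + e2)

        def dm(grad):
            return float(np.sqrt(max(0.0, grad @ cov @ grad)))

        # gradients in theta order (g1, g2, g12, e1, e2, e12)
        se_h2_1 = dm(np.array([e1 / (g1 + e1) ** 2, 0, 0, -g1 / (g1 + e1) ** 2, 0, 0]))
        se_h2_2 = dm(np.array([0, e2 / (g2 + e2) ** 2, 0, 0, -g2 / (g2 + e2) ** 2, 0]))
        sq_g = np.sqrt(g1 * g2)
        se_r_g = dm(np.array([
            -0.5 * g12 / (g1 * sq_g), -0.5 * g12 / (g2 * sq_g), 1.0 / sq_g, 0, 0, 0,
        ]))
        sq_e = np.sqrt(e1 * e2)
        se_r_e = dm(np.array([
            0, 0, 0, -0.5 * e12 / (e1 * sq_e), -0.5 * e12 / (e2 * sq_e), 1.0 / sq_e,
        ]))
        p1, p2, cp = g1 + e1, g2 + e2, g12 + e12
        sq_p = np.sqrt(p1 * p2)
        d_v1 = -0.5 * cp / (p1 * sq_p)
        d_v2 = -0.5 * cp / (p2 * sq_p)
        se_r_p = dm(np.array([d_v1, d_v2, 1.0 / sq_p, d_v1, d_v2, 1.0 / sq_p]))

        beta = state["beta"]
        L1 = ws_X(ws, 1).shape[1]
        result = BivariateFit(
            sigma_g1_2=float(g1), sigma_g2_2=float(g2), sigma_g12=float(g12),
            sigma_e1_2=float(e1), sigma_e2_2=float(e2), sigma_e12=float(e12),
            h2_1=float(h2_1), h2_2=float(h2_2),
            se_h2_1=se_h2_1, se_h2_2=se_h2_2,
            r_g=r_g, r_e=r_e, r_p=float(r_p),
            se_r_g=se_r_g, se_r_e=se_r_e, se_r_p=se_r_p,
            beta1=beta[:L1], beta2=beta[L1:],
            loglik=float(ll), loglik_trace=trace,
            n_iter=n_iter, converged=converged,
        )
        self.fit_result_ = result
        for name in ("h2_1", "h2_2", "r_g", "r_e", "r_p", "loglik", "converged"):
            setattr(self, name + "_", getattr(result, name))
        return self


def ws_X(ws, trait: int) -> np.ndarray:
    """Original-basis design of a workspace trait (for OLS starts)."""
    if isinstance(ws, _BivEigen):
        return ws.U @ (ws.X1 if trait == 1 else ws.X2)
    return ws.X1 if trait == 1 else ws.X2


# ---------------------------------------------------------------------------
# dense general-covariance path

class _BivDense:
    """Dense REML workspace for arbitrary A-blocks and overlap maps."""

    def __init__(self, y1, y2, X1, X2, grm_blocks, overlap: OverlapMap):
        A1, A2, A12 = (b.A if isinstance(b, GRM) else np.asarray(b, float) for b in grm_blocks)
        n1, n2 = y1.size, y2.size
        if A1.shape != (n1, n1) or A2.shape != (n2, n2) or A12.shape != (n1, n2):
            raise DataError("A-blocks are not conformable with y1/y2")
        if overlap.n1 != n1 or overlap.n2 != n2:
            raise DataError("overlap map does not match sample counts")
        self.n = n1 + n2
        self.y = np.concatenate([y1, y2])
        self.X1, self.X2 = X1, X2
        self.X = scipy.linalg.block_diag(X1, X2)
        I12 = overlap.matrix()
        zero = np.zeros((n1, n2))
        self.G = [
            _sym_block(A1, zero, np.zeros((n2, n2))),           # g1
            _sym_block(np.zeros((n1, n1)), zero, A2),           # g2
            _offdiag_block(A12),                                # g12
            _sym_block(np.eye(n1), zero, np.zeros((n2, n2))),   # e1
            _sym_block(np.zeros((n1, n1)), zero, np.eye(n2)),   # e2
            _offdiag_block(I12),                                # e12
        ]

    def core(self, theta):
        V = sum(t * g for t, g in zip(theta, self.G))
        try:
            cf = scipy.linalg.cho_factor(V, lower=True)
        except scipy.linalg.LinAlgError:
            return None
        logdet_v = 2.0 * np.log(np.diag(cf[0])).sum()
        Vi = scipy.linalg.cho_solve(cf, np.eye(self.n))
        ViX = Vi @ self.X
        W = self.X.T @ ViX
        sign, logdet_w = np.linalg.slogdet(W)
        if sign <= 0:
            return None
        Winv = np.linalg.inv(W)
        P = Vi - ViX @ Winv @ ViX.T
        u = P @ self.y
        beta = Winv @ (ViX.T @ self.y)
        ll = -0.5 * (logdet_v + logdet_w + float(self.y @ u))
        return {"ll": ll, "u": u, "P": P, "beta": beta}

    def em_step(self, theta, state, floor):
        # Damped scaled-gradient step (EM-like: monotone direction, bounded);
        # exact EM matrix updates are only used on the eigen fast path.
        AI, score = self.ai_and_score(state)
        scale = np.abs(theta) + 0.1 * np.mean(np.abs(theta))
        delta = scale * score / max(1.0, np.abs(score).max())
        out = np.array(theta, float)
        for _ in range(30):
            cand = out + delta
            cand[:2] = np.maximum(cand[:2], floor)
            cand[3:5] = np.maximum(cand[3:5], floor)
            if self.core(cand) is not None:
                return cand
            delta = 0.5 * delta
        return out

    def ai_and_score(self, state):
        u, P = state["u"], state["P"]
        k = len(self.G)
        w = [g @ u for g in self.G]
        pw = [P @ wi for wi in w]
        AI = np.empty((k, k))
        score = np.empty(k)
        for i in range(k):
            for j in range(i, k):
                AI[i, j] = AI[j, i] = 0.5 * float(w[i] @ pw[j])
            tr_pg = float((P * self.G[i]).sum())
            score[i] = -0.5 * (tr_pg - float(u @ w[i]))
        return AI, score


def _sym_block(B11, B12, B22):
    top = np.hstack([B11, B12])
    bot = np.hstack([B12.T, B22])
    return np.vstack([top, bot])


def _offdiag_block(B12):
    n1, n2 = B12.shape
    return _sym_block(np.zeros((n1, n1)), B12, np.zeros((n2, n2)))


def fit_bivariate_greml(
    y1, y2, X1, X2, A_blocks, overlap: OverlapMap = None, options: dict = None
) -> BivariateFit:
    """Functional wrapper around :class:`BivariateGREML`.

    ``A_blocks`` is either a single (shared) GRM or a tuple (A1, A2, A12).
    """
    est = BivariateGREML(**(options or {}))
    if isinstance(A_blocks, (tuple, list)):
        est.fit(X1, y1, X2, y2, grm_blocks=A_blocks, overlap=overlap)
    else:
        est.fit(X1, y1, X2, y2, grm=A_blocks, overlap=overlap)
    return est.fit_result_
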