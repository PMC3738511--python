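"""Restricted-maximum-likelihood fitting of variance-components models.

The two models this package fits (global dye/block normalization and the
per-transcript treatment ANOVA) are both of the form

    y = X beta + sum_k Z_k u_k + e,   u_k ~ N(0, sigma_k^2 I),  e ~ N(0, sigma_e^2 I)

with indicator random-effect design matrices Z_k (array, array x dye,
array x block).  Writing gamma_k = sigma_k^2 / sigma_e^2 and
W = I + sum_k gamma_k Z_k Z_k', the profiled -2 REML criterion is

    (n - p) log(r' W^-1 r) + log|W| + log|X' W^-1 X|

which we minimize over gamma >= 0.  All W^-1 quantities are obtained from
cross-products via the Woodbury identity, so one objective evaluation costs
O(q^3) in the total number of random-effect levels q, independent of n.

Variance components are constrained non-negative; the boundary gamma = 0 is
always evaluated explicitly so null components are reported as exact zeros.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, optimize

_GAMMA_MAX = 1e6
_LOG_GRID = np.concatenate([[-np.inf], np.linspace(-8.0, 8.0, 25)])


class RemlError(RuntimeError):
    """The REML fit could not be computed (singular or degenerate design)."""


@dataclass
class RemlFit:
    """A fitted variance-components model.

    Attributes
    ----------
    beta : fixed-effect estimates (order of the supplied X columns)
    cov_beta : sigma_e^2 (X' W^-1 X)^-1, the GLS covariance of ``beta``
    sigma2 : per-component variances in Z-list order
    sigma2_resid : residual variance
    gamma : variance ratios sigma_k^2 / sigma_e^2
    blups : predicted random effects, one vector per component
    loglik : -0.5 * profiled -2 REML criterion (constants dropped)
    converged : False when the optimizer reported failure
    """

    beta: np.ndarray
    cov_beta: np.ndarray
    sigma2: np.ndarray
    sigma2_resid: float
    gamma: np.ndarray
    blups: list
    loglik: float
    converged: bool
    n_obs: int
    rank_x: int


class _RemlWorkspace:
    """Cross-products of (y, X, Z) reused across objective evaluations."""

    def __init__(self, y, X, Z_blocks):
        y = np.asarray(y, dtype=float)
        X = np.asarray(X, dtype=float)
        self.n, self.p = X.shape
        self.rank_x = np.linalg.matrix_rank(X)
        if self.rank_x < self.p:
            raise RemlError("fixed-effect design matrix is rank deficient")
        if self.n <= self.p:
            raise RemlError("more fixed-effect parameters than observations")
        self.y, self.X = y, X
        self.Z_blocks = [np.asarray(Z, dtype=float) for Z in Z_blocks]
        self.block_sizes = [Z.shape[1] for Z in self.Z_blocks]
        Z = np.hstack(self.Z_blocks) if self.Z_blocks else np.zeros((self.n, 0))
        self.Z = Z
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)
        self.ZtZ = Z.T @ Z
        self.ZtX = Z.T @ X
        self.Zty = Z.T @ y
        # expansion of per-component gamma to per-column gamma
        self.expand = np.repeat(np.arange(len(self.block_sizes)), self.block_sizes)
        # indicator blocks with disjoint rows give a diagonal Z'Z, which
        # admits a closed-form Woodbury step (the per-transcript model)
        diag = np.diag(self.ZtZ)
        self.ZtZ_diag = diag if (
            self.ZtZ.size and np.count_nonzero(self.ZtZ - np.diag(diag)) == 0
        ) else None

    def _solve(self, gamma):
        """Return (neg2reml, beta, A=X'W^-1X, sigma2_e, u) at the given ratios."""
        g_col = np.asarray(gamma, dtype=float)[self.expand] if len(
            self.block_sizes) else np.zeros(0)
        q = len(g_col)
        solve_M = None
        if q and self.ZtZ_diag is not None:
            m = 1.0 + g_col * self.ZtZ_diag
            logdet_M = float(np.sum(np.log(m)))
            w = g_col / m
            A = self.XtX - self.ZtX.T @ (self.ZtX * w[:, None])
            b = self.Xty - self.ZtX.T @ (w * self.Zty)
            yWy = self.yty - float(self.Zty @ (w * self.Zty))
            solve_M = ("diag", m)
        elif q:
            s = np.sqrt(g_col)
            M = np.eye(q) + (s[:, None] * self.ZtZ * s[None, :])
            try:
                L = np.linalg.cholesky(M)
            except np.linalg.LinAlgError as exc:
                raise RemlError("singular mixed-model system") from exc
            logdet_M = 2.0 * float(np.sum(np.log(np.diag(L))))
            T = s[:, None] * self.ZtX          # q x p
            t = s * self.Zty                   # q
            rhs = np.column_stack([T, t])
            sol = linalg.cho_solve((L, True), rhs, check_finite=False)
            MinvT, Minvt = sol[:, :-1], sol[:, -1]
            A = self.XtX - T.T @ MinvT
            b = self.Xty - T.T @ Minvt
            yWy = self.yty - float(t @ Minvt)
            solve_M = ("chol", (L, s))
        else:
            logdet_M = 0.0
            A = self.XtX
            b = self.Xty
            yWy = self.yty
        sign, logdet_A = np.linalg.slogdet(A)
        if sign <= 0:
            raise RemlError("X'W^-1X not positive definite")
        beta = np.linalg.solve(A, b)
        rWr = yWy - float(b @ beta)
        rWr = max(rWr, 1e-300)
        neg2 = (self.n - self.p) * np.log(rWr) + logdet_M + logdet_A
        sigma2_e = rWr / (self.n - self.p)
        u = None
        if q:
            Ztr = self.Zty - self.ZtX @ beta
            if solve_M[0] == "diag":
                u = g_col * Ztr / solve_M[1]
            else:
                L, s = solve_M[1]
                ZWr = Ztr - self.ZtZ @ (
                    s * linalg.cho_solve((L, True), s * Ztr, check_finite=False))
                u = g_col * ZWr
        return neg2, beta, A, sigma2_e, u

    def objective(self, gamma):
        return self._solve(gamma)[0]


def _optimize_single(ws: _RemlWorkspace):
    """1-D grid + Brent refinement over log gamma, with gamma = 0 compared."""
    vals = []
    for lg in _LOG_GRID:
        g = 0.0 if np.isinf(lg) else float(np.exp(lg))
        try:
            vals.append((ws.objective([g]), lg))
        except RemlError:
            vals.append((np.inf, lg))
    vals_only = [v for v, _ in vals]
    i_best = int(np.argmin(vals_only))
    best_val, best_lg = vals[i_best]
    converged = np.isfinite(best_val)
    if i_best == 0 or not converged:
        gamma = 0.0 if i_best == 0 else 0.0
        return np.array([gamma]), converged
    lo = _LOG_GRID[max(i_best - 1, 1)]
    hi = _LOG_GRID[min(i_best + 1, len(_LOG_GRID) - 1)]
    if lo == hi:
        return np.array([float(np.exp(best_lg))]), converged
    res = optimize.minimize_scalar(
        lambda lg: ws.objective([float(np.exp(lg))]),
        bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-6},
    )
    gamma = float(np.exp(res.x))
    if res.fun > best_val:  # keep the grid optimum on a failed refine
        gamma = float(np.exp(best_lg))
    # re-compare with the boundary
    if ws.objective([0.0]) <= ws.objective([gamma]):
        gamma = 0.0
    return np.array([gamma]), True


def _optimize_multi(ws: _RemlWorkspace, k: int):
    """Lattice prescan plus Nelder-Mead polish over log variance ratios.

    The ratios of different components can sit orders of magnitude apart,
    so the search runs in log space; boundary (zero) components are handled
    by explicit comparison after the polish.
    """

    def safe_obj(theta):
        try:
            return ws.objective(np.exp(np.clip(theta, -30, 30)))
        except RemlError:
            return np.inf

    lattice = [-6.0, -3.0, -1.0, 0.0, 1.0, 3.0]
    best_theta, best_val = None, np.inf
    for combo in np.stack(np.meshgrid(*([lattice] * k)), axis=-1).reshape(-1, k):
        v = safe_obj(combo)
        if v < best_val:
            best_theta, best_val = combo, v
    if not np.isfinite(best_val):
        return np.zeros(k), False

    res = optimize.minimize(
        safe_obj, best_theta, method="Nelder-Mead",
        options={"maxfev": 600, "xatol": 1e-4, "fatol": 1e-6},
    )
    theta = res.x if res.fun <= best_val else best_theta
    gamma = np.exp(np.clip(theta, -30, 30))
    fun = min(res.fun, best_val)
    # try zeroing each small component (and all of them) against the optimum
    for mask in _zero_masks(gamma):
        cand = np.where(mask, 0.0, gamma)
        v = safe_obj_gamma(ws, cand)
        if v <= fun + 1e-9:
            gamma, fun = cand, v
    return gamma, bool(res.success) or np.isfinite(fun)


def _zero_masks(gamma, threshold=1e-4):
    small = gamma < threshold
    masks = []
    for i in range(len(gamma)):
        if small[i]:
            m = np.zeros(len(gamma), dtype=bool)
            m[i] = True
            masks.append(m)
    if small.any():
        masks.append(small.copy())
    return masks


def safe_obj_gamma(ws, gamma):
    try:
        return ws.objective(gamma)
    except RemlError:
        return np.inf


def fit_reml(y, X, Z_blocks, force_gamma=None) -> RemlFit:
    """Fit the variance-components model by REML.

    Parameters
    ----------
    y, X : response vector and fixed-effect design matrix.
    Z_blocks : list of indicator matrices, one per random-effect component.
    force_gamma : optional fixed variance ratios (skips optimization); used
        to evaluate the fixed-effects limit gamma = 0.
    """
    ws = _RemlWorkspace(y, X, Z_blocks)
    k = len(ws.block_sizes)
    if force_gamma is not None:
        gamma = np.asarray(force_gamma, dtype=float)
        converged = True
    elif k == 0:
        gamma, converged = np.zeros(0), True
    elif k == 1:
        gamma, converged = _optimize_single(ws)
    else:
        gamma, converged = _optimize_multi(ws, k)
    neg2, beta, A, sigma2_e, u = ws._solve(gamma)
    cov_beta = sigma2_e * np.linalg.inv(A)
    blups = []
    if k:
        offsets = np.cumsum([0] + ws.block_sizes)
        for i in range(k):
            blups.append(u[offsets[i]:offsets[i + 1]] if u is not None
                         else np.zeros(ws.block_sizes[i]))
    return RemlFit(
        beta=beta, cov_beta=cov_beta,
        sigma2=gamma * sigma2_e, sigma2_resid=sigma2_e, gamma=gamma,
        blups=blups, loglik=-0.5 * neg2, converged=converged,
        n_obs=ws.n, rank_x=ws.rank_x,
    )


def conditional_residuals(fit: RemlFit, y, X, Z_blocks) -> np.ndarray:
    """y - X beta - Z u: residuals net of fixed effects and BLUPs."""
    y = np.asarray(y, dtype=float)
    resid = y - np.asarray(X, dtype=float) @ fit.beta
    for Z, u in zip(Z_blocks, fit.blups):
        resid = resid - np.asarray(Z, dtype=float) @ u
    return resid


def indicator_matrix(codes) -> tuple[np.ndarray, list]:
    """0/1 design matrix with one column per distinct level of *codes*."""
    codes = list(codes)
    levels = list(dict.fromkeys(codes))
    idx = {lv: j for j, lv in enumerate(levels)}
    Z = np.zeros((len(codes), len(levels)))
    Z[np.arange(len(codes)), [idx[c] for c in codes]] = 1.0
    return Z, levels


def dummy_matrix(codes, drop_first=True) -> tuple[np.ndarray, list]:
    """Treatment-coded dummies (reference = first level in appearance order)."""
    Z, levels = indicator_matrix(codes)
    if drop_first:
        return Z[:, 1:], levels[1:]
    return Z, levels
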