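"""Poisson log-linear mixed models for per-gene read counts.

The model for one gene over the samples of one (tissue, time) contrast is

    y_i ~ Poisson(mu_i)
    log mu_i = log(L_i) + beta0 + beta_trt * heat_i + u_rep(i) + v_plate(i)

with library-size offset log(L_i), a treatment fixed effect, and independent
Gaussian random intercepts for biological replicate and plate,
u_r ~ N(0, sigma2_rep), v_p ~ N(0, sigma2_plate).

The marginal likelihood integrates the random effects out of the Poisson
likelihood.  Two evaluators are provided:

* a Laplace approximation over the joint random-effect vector (works for
  crossed replicate/plate factors), and
* adaptive Gauss--Hermite quadrature (default 15 nodes) when there is a
  single grouping factor, in which case the marginal likelihood factorises
  over groups into one-dimensional integrals.

Fitting profiles the fixed effects inside a penalized IRLS and optimizes the
variance components on the outside, the strategy used by lme4.  Variance
estimates may legitimately sit on the boundary at zero; in that case the
corresponding factor simply drops out of the model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, special
from scipy.stats import chi2

__all__ = [
    "GlmmFit",
    "poisson_glm_loglik",
    "marginal_loglik",
    "fit_poisson_glmm",
    "lrt_test",
]

_ETA_MAX = 30.0  # linear-predictor clamp; exp(30) ~ 1e13 counts
_SIGMA_TINY = 1e-8  # below this a variance component is treated as absent


@dataclass
class GlmmFit:
    """Result of fitting the per-gene Poisson mixed model."""

    beta0: float
    beta_trt: float
    sigma2_rep: float
    sigma2_plate: float
    loglik: float
    converged: bool
    has_treatment: bool
    n_obs: int

    @property
    def log2_fc(self) -> float:
        """Treatment effect re-expressed as a log2 fold change."""
        return self.beta_trt / np.log(2.0)


def _validate_counts(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if y.ndim != 1:
        raise ValueError("counts must be a 1-D vector")
    if np.any(y < 0) or np.any(y != np.floor(y)) or not np.all(np.isfinite(y)):
        raise ValueError("counts must be non-negative integers")
    return y


def poisson_glm_loglik(y: np.ndarray, eta: np.ndarray) -> float:
    """Poisson log-likelihood at linear predictor eta (log-mean scale)."""
    eta = np.clip(eta, -_ETA_MAX, _ETA_MAX)
    return float(np.sum(y * eta - np.exp(eta) - special.gammaln(y + 1.0)))


def group_codes(labels) -> np.ndarray:
    """Integer codes 0..k-1 for a vector of group labels."""
    _, codes = np.unique(np.asarray(labels), return_inverse=True)
    return codes.astype(int)


def _laplace_loglik(y, X, beta, offset, factors, sigma2s) -> float:
    """Laplace-approximate marginal log-likelihood at fixed (beta, sigma2s).

    ``factors`` is a list of integer code vectors (one per random factor),
    ``sigma2s`` the matching variances.  Factors with essentially-zero
    variance are dropped.
    """
    y = np.asarray(y, float)
    eta0 = X @ beta + offset
    active = [(c, s2) for c, s2 in zip(factors, sigma2s) if s2 > _SIGMA_TINY]
    if not active:
        return poisson_glm_loglik(y, eta0)

    blocks = []
    sizes = []
    dinv = []
    for codes, s2 in active:
        q = int(codes.max()) + 1
        blocks.append(codes)
        sizes.append(q)
        dinv.extend([1.0 / s2] * q)
    q_tot = int(np.sum(sizes))
    dinv = np.asarray(dinv)
    offsets_q = np.concatenate([[0], np.cumsum(sizes)[:-1]])

    # Z u expressed through index arithmetic: column index of obs i in factor f
    col_idx = [codes + off for codes, off in zip(blocks, offsets_q)]

    u = np.zeros(q_tot)
    for _ in range(100):
        eta = eta0.copy()
        for ci in col_idx:
            eta = eta + u[ci]
        eta = np.clip(eta, -_ETA_MAX, _ETA_MAX)
        mu = np.exp(eta)
        resid = y - mu
        grad = -dinv * u
        for ci in col_idx:
            np.add.at(grad, ci, resid)
        # Hessian H = Z' diag(mu) Z + D^-1  (q_tot x q_tot, small)
        H = np.zeros((q_tot, q_tot))
        for a in range(len(col_idx)):
            for b in range(len(col_idx)):
                np.add.at(H, (col_idx[a], col_idx[b]), mu)
        H[np.diag_indices_from(H)] += dinv
        step = np.linalg.solve(H, grad)
        u = u + step
        if np.max(np.abs(grad)) < 1e-10 and np.max(np.abs(step)) < 1e-10:
            break

    eta = eta0.copy()
    for ci in col_idx:
        eta = eta + u[ci]
    eta = np.clip(eta, -_ETA_MAX, _ETA_MAX)
    mu = np.exp(eta)
    f_u = (
        poisson_glm_loglik(y, eta)
        - 0.5 * float(np.sum(dinv * u * u))
        - 0.5 * float(np.sum(np.log(2.0 * np.pi / dinv)))
    )
    H = np.zeros((q_tot, q_tot))
    for a in range(len(col_idx)):
        for b in range(len(col_idx)):
            np.add.at(H, (col_idx[a], col_idx[b]), mu)
    H[np.diag_indices_from(H)] += dinv
    sign, logdet = np.linalg.slogdet(H)
    return f_u + 0.5 * q_tot * np.log(2.0 * np.pi) - 0.5 * logdet


def _agh_loglik(y, X, beta, offset, codes, sigma2, nodes: int = 15) -> float:
    """Adaptive Gauss--Hermite marginal log-likelihood, one grouping factor.

    The marginal likelihood factorises over groups; each factor is a 1-D
    integral handled by quadrature centred at the conditional mode with the
    conditional curvature as scale.
    """
    if sigma2 <= _SIGMA_TINY:
        return poisson_glm_loglik(y, X @ beta + offset)
    y = np.asarray(y, float)
    eta0 = X @ beta + offset
    x_k, w_k = np.polynomial.hermite.hermgauss(nodes)
    log_w = np.log(w_k)

    total = 0.0
    n_groups = int(codes.max()) + 1
    for g in range(n_groups):
        idx = codes == g
        yg = y[idx]
        og = eta0[idx]
        # 1-D Newton for the conditional mode of h(u)
        u = 0.0
        for _ in range(100):
            mu = np.exp(np.clip(og + u, -_ETA_MAX, _ETA_MAX))
            g1 = float(np.sum(yg - mu)) - u / sigma2
            g2 = -float(np.sum(mu)) - 1.0 / sigma2
            step = -g1 / g2
            u += step
            if abs(g1) < 1e-12 and abs(step) < 1e-12:
                break
        mu = np.exp(np.clip(og + u, -_ETA_MAX, _ETA_MAX))
        tau = 1.0 / np.sqrt(float(np.sum(mu)) + 1.0 / sigma2)
        pts = u + np.sqrt(2.0) * tau * x_k
        h = np.array(
            [
                poisson_glm_loglik(yg, og + p)
                - 0.5 * p * p / sigma2
                - 0.5 * np.log(2.0 * np.pi * sigma2)
                for p in pts
            ]
        )
        terms = log_w + h + x_k**2
        m = terms.max()
        total += m + np.log(np.sum(np.exp(terms - m))) + np.log(np.sqrt(2.0) * tau)
    return total


def marginal_loglik(
    y,
    X,
    beta,
    offset,
    factors,
    sigma2s,
    method: str = "auto",
    gh_nodes: int = 15,
) -> float:
    """Marginal Poisson mixed-model log-likelihood at fixed parameters.

    Parameters
    ----------
    factors : list of integer code arrays, one per random factor.
    sigma2s : matching variances; a variance of 0 removes the factor.
    method : "auto" uses quadrature when a single factor is active, else
        Laplace; "laplace" and "agh" force the choice ("agh" requires a
        single active factor).
    """
    y = _validate_counts(y)
    X = np.atleast_2d(np.asarray(X, float))
    beta = np.asarray(beta, float)
    offset = np.asarray(offset, float)
    factors = [np.asarray(f, dtype=int) for f in factors]
    sigma2s = [float(s) for s in sigma2s]
    if any(s < 0 for s in sigma2s):
        raise ValueError("variances must be non-negative")
    active = [(f, s) for f, s in zip(factors, sigma2s) if s > _SIGMA_TINY]
    if method == "auto":
        method = "agh" if len(active) == 1 else "laplace"
    if method == "agh":
        if len(active) > 1:
            raise ValueError("quadrature requires a single active grouping factor")
        if not active:
            return poisson_glm_loglik(y, X @ beta + offset)
        return _agh_loglik(y, X, beta, offset, active[0][0], active[0][1], gh_nodes)
    if method == "laplace":
        return _laplace_loglik(y, X, beta, offset, factors, sigma2s)
    raise ValueError(f"unknown method {method!r}")


def _pirls(y, A, offset, pen, p, beta_start, lgam, max_iter=200, tol=1e-8):
    """Joint penalized-IRLS mode over v = (beta, u) with design A = [X Z].

    ``pen`` is the diagonal penalty (zeros for beta, 1/sigma2 per random
    level).  Returns (v, mu_at_mode, poisson_loglik_at_mode, converged).
    """
    m = A.shape[1]
    v = np.zeros(m)
    v[:p] = beta_start
    conv = False
    for _ in range(max_iter):
        eta = np.clip(A @ v + offset, -_ETA_MAX, _ETA_MAX)
        mu = np.exp(eta)
        grad = A.T @ (y - mu) - pen * v
        H = A.T @ (A * mu[:, None])
        H[np.diag_indices_from(H)] += pen
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            break
        v = v + step
        if np.max(np.abs(grad)) < tol and np.max(np.abs(step)) < tol:
            conv = True
            break
    eta = np.clip(A @ v + offset, -_ETA_MAX, _ETA_MAX)
    mu = np.exp(eta)
    ll_pois = float(np.sum(y * eta - mu)) - lgam
    return v, mu, ll_pois, conv


def _profiled_laplace(y, X, offset, factors, sigmas, beta_start, lgam=None):
    """Laplace log-likelihood with beta at the joint (beta, u) mode."""
    if lgam is None:
        lgam = float(np.sum(special.gammaln(y + 1.0)))
    sigma2s = [s * s for s in sigmas]
    active = [(c, s2) for c, s2 in zip(factors, sigma2s) if s2 > _SIGMA_TINY]
    if not active:
        beta, ll, conv = _fit_poisson_glm(y, X, offset, beta_start)
        return beta, ll, conv
    n, p = X.shape
    zs = []
    pen = [np.zeros(p)]
    for codes, s2 in active:
        q = int(codes.max()) + 1
        Z = np.zeros((n, q))
        Z[np.arange(n), codes] = 1.0
        zs.append(Z)
        pen.append(np.full(q, 1.0 / s2))
    A = np.hstack([X] + zs)
    pen = np.concatenate(pen)
    q_tot = A.shape[1] - p
    v, mu, ll_pois, conv = _pirls(y, A, offset, pen, p, beta_start, lgam)
    u = v[p:]
    dinv = pen[p:]
    f_u = (
        ll_pois
        - 0.5 * float(np.sum(dinv * u * u))
        - 0.5 * float(np.sum(np.log(2.0 * np.pi / dinv)))
    )
    Zall = A[:, p:]
    Huu = Zall.T @ (Zall * mu[:, None])
    Huu[np.diag_indices_from(Huu)] += dinv
    sign, logdet = np.linalg.slogdet(Huu)
    ll = f_u + 0.5 * q_tot * np.log(2.0 * np.pi) - 0.5 * logdet
    return v[:p], ll, conv


def _fit_poisson_glm(y, X, offset, beta_start, max_iter=50, tol=1e-10):
    """Plain Poisson GLM Newton fit (variance components absent)."""
    beta = np.asarray(beta_start, float).copy()
    conv = False
    for _ in range(max_iter):
        eta = np.clip(X @ beta + offset, -_ETA_MAX, _ETA_MAX)
        mu = np.exp(eta)
        grad = X.T @ (y - mu)
        H = (X * mu[:, None]).T @ X
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            break
        beta = beta + np.clip(step, -10, 10)
        if np.max(np.abs(grad)) < tol and np.max(np.abs(step)) < 1e-10:
            conv = True
            break
    return beta, poisson_glm_loglik(y, np.clip(X @ beta + offset, -_ETA_MAX, _ETA_MAX)), conv


def _glm_start(y, X, offset):
    """Closed-form start for the intercept(+treatment) design."""
    p = X.shape[1]
    L = np.exp(offset)
    beta = np.zeros(p)
    if p == 1:
        tot = y.sum()
        beta[0] = np.log(tot / L.sum()) if tot > 0 else -_ETA_MAX / 2
    else:
        trt = X[:, 1] > 0.5
        y0, L0 = y[~trt].sum(), L[~trt].sum()
        y1, L1 = y[trt].sum(), L[trt].sum()
        b0 = np.log(y0 / L0) if y0 > 0 else np.log(0.5 / L0)
        b1 = np.log(y1 / L1) if y1 > 0 else np.log(0.5 / L1)
        beta[0] = b0
        beta[1] = b1 - b0
    return beta


def fit_poisson_glmm(
    y,
    X,
    offset,
    factors,
    max_iter: int = 200,
    sigma_max: float = 5.0,
    sigma_start: float = 0.2,
):
    """Maximize the Laplace marginal likelihood over (beta, sigma_rep, sigma_plate).

    Returns (beta, sigmas, loglik, converged).  Variance components are
    optimized on the standard-deviation scale with a lower bound of exactly
    zero, so boundary estimates are reachable; the pure-GLM boundary fit is
    always evaluated and kept if better.
    """
    y = _validate_counts(y)
    X = np.atleast_2d(np.asarray(X, float))
    offset = np.asarray(offset, float)
    factors = [np.asarray(f, int) for f in factors]
    n, p = X.shape
    lgam = float(np.sum(special.gammaln(y + 1.0)))
    beta_start = _glm_start(y, X, offset)

    # boundary candidate: all variances zero
    beta_glm, ll_glm, conv_glm = _fit_poisson_glm(y, X, offset, beta_start)

    # design [X | Z_rep | Z_plate] built once; a vanishing variance is
    # handled by a huge penalty, which reproduces the GLM limit smoothly
    zs = []
    sizes = []
    for codes in factors:
        q = int(codes.max()) + 1
        Z = np.zeros((n, q))
        Z[np.arange(n), codes] = 1.0
        zs.append(Z)
        sizes.append(q)
    A = np.hstack([X] + zs)
    q_tot = int(np.sum(sizes))
    pen = np.zeros(p + q_tot)
    bounds_lo = np.concatenate([[0], np.cumsum(sizes)[:-1]]).astype(int) + p
    log_2pi = np.log(2.0 * np.pi)
    state = {"beta": beta_glm.copy(), "best": None}

    def neg_ll(sigmas):
        for k, (s, q) in enumerate(zip(sigmas, sizes)):
            pen[bounds_lo[k] : bounds_lo[k] + q] = 1.0 / max(s * s, 1e-12)
        v, mu, ll_pois, _ = _pirls(y, A, offset, pen, p, state["beta"], lgam)
        state["beta"] = v[:p].copy()
        u = v[p:]
        dinv = pen[p:]
        f_u = (
            ll_pois
            - 0.5 * float(np.sum(dinv * u * u))
            + 0.5 * float(np.sum(np.log(dinv)))
            - 0.5 * q_tot * log_2pi
        )
        Zall = A[:, p:]
        Huu = Zall.T @ (Zall * mu[:, None])
        Huu[np.diag_indices_from(Huu)] += dinv
        _, logdet = np.linalg.slogdet(Huu)
        ll = f_u + 0.5 * q_tot * log_2pi - 0.5 * logdet
        if state["best"] is None or ll > state["best"][2]:
            state["best"] = (np.asarray(sigmas, float).copy(), v[:p].copy(), ll)
        return -ll

    n_fac = len(factors)
    res = optimize.minimize(
        neg_ll,
        x0=np.full(n_fac, sigma_start),
        method="L-BFGS-B",
        bounds=[(0.0, sigma_max)] * n_fac,
        options={"maxiter": max_iter, "ftol": 1e-9},
    )
    sigmas, beta, ll = state["best"]
    if ll_glm >= ll - 1e-9:
        return beta_glm, np.zeros(n_fac), ll_glm, conv_glm
    return beta, sigmas, ll, bool(res.success)


def lrt_test(full: GlmmFit, reduced: GlmmFit) -> tuple[float, float]:
    """Likelihood-ratio test of the treatment effect, chi-square with 1 df.

    The statistic 2*(loglik_full - loglik_reduced) is clamped at zero so
    numerical noise in nested fits can never produce a negative statistic.
    """
    if not full.has_treatment or reduced.has_treatment:
        raise ValueError(
            "lrt_test expects a full model with the treatment term and a "
            "reduced model without it"
        )
    if full.n_obs != reduced.n_obs:
        raise ValueError("full and reduced models were fitted to different data")
    stat = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    return stat, float(chi2.sf(stat, df=1))
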