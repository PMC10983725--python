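"""Likelihood machinery for the surveillance regression models.

Relationship 1 (disease incidence) is a zero-inflated NB2 regression with a
log-linear dispersion submodel and a latent stationary Gaussian AR(1) process
per centre entering the log-mean.  Its marginal likelihood integrates the
latent vector out per centre: blocks of size one use adaptive Gauss-Hermite
quadrature (near-exact), larger blocks a Laplace approximation (mode found by
damped Newton, log-determinant correction), the standard approach for this
model class.  With ``sigma_ar = 0`` the likelihood reduces exactly to the
closed-form ZINB sum.

Relationships 2 and 3 are Gaussian regressions of the patient/occupancy ratio
with a log-linear residual-variance submodel, handled by ``gaussian_nll``.

The NB2 parameterisation has variance mu * (1 + mu/theta), quadratic in the
mean, with theta > 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp, expit

__all__ = [
    "nb2_logpmf",
    "zinb_logpmf",
    "zinb_unconditional_mean",
    "Rel1Data",
    "marginal_loglik_zinb_ar1",
    "ar1_correlation",
    "gaussian_nll",
    "gaussian_nll_grad",
]

_ETA_CAP = 30.0  # cap on log-mean to avoid overflow in exp
_GH_NODES = 25


def nb2_logpmf(y, mu, theta):
    """Log-pmf of the NB2 distribution with mean ``mu`` and dispersion ``theta``.

    Variance is ``mu * (1 + mu / theta)``; the Poisson limit is ``theta -> inf``.
    Numerically stable for large ``y`` and ``mu``.
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if np.any(mu <= 0) or np.any(theta <= 0):
        raise ValueError("nb2_logpmf requires mu > 0 and theta > 0")
    if np.any(y < 0) or np.any(y != np.floor(y)):
        raise ValueError("nb2_logpmf requires non-negative integer counts")
    return (
        gammaln(y + theta)
        - gammaln(theta)
        - gammaln(y + 1.0)
        + theta * (np.log(theta) - np.log(theta + mu))
        + y * (np.log(mu) - np.log(theta + mu))
    )


def zinb_logpmf(y, mu, theta, p):
    """Log-pmf of the zero-inflated NB2: structural zero w.p. ``p``, else NB2."""
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    theta = np.asarray(theta, dtype=float)
    p = np.asarray(p, dtype=float)
    nb = nb2_logpmf(np.maximum(y, 0.0), mu, theta)
    with np.errstate(divide="ignore"):
        log1mp = np.log1p(-p)
        logp = np.log(p)
    nonzero = log1mp + nb
    # y == 0: log(p + (1-p) * NB(0)) via logaddexp for stability
    zero = np.logaddexp(logp, log1mp + nb)
    return np.where(y > 0, nonzero, zero)


def zinb_unconditional_mean(p, mu):
    """Marginal expected count of the zero-inflated NB2, ``(1 - p) * mu``."""
    p = np.asarray(p, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("zero-inflation probability must lie in [0, 1]")
    return (1.0 - p) * np.asarray(mu, dtype=float)


def ar1_correlation(months: np.ndarray, phi: float) -> np.ndarray:
    """Correlation matrix ``phi ** |m_i - m_j|`` for integer month indices.

    A stationary Gaussian AR(1) observed at (possibly gapped) integer times is
    still Markov, so the distance-power form is exact.
    """
    m = np.asarray(months, dtype=float)
    d = np.abs(m[:, None] - m[None, :])
    if phi == 0.0:
        return np.eye(m.size)
    return np.sign(phi) ** d * np.abs(phi) ** d if phi < 0 else phi**d


@dataclass
class Rel1Data:
    """Design bundle for the relationship-1 likelihood.

    ``X``/``Z``/``D`` are the conditional, zero-inflation and dispersion design
    matrices (already on the per-10 covariate scale, intercept first).
    ``groups`` lists, per centre, (row index array, month index array) with
    months sorted ascending.
    """

    y: np.ndarray
    X: np.ndarray
    Z: np.ndarray
    D: np.ndarray
    groups: list

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float)
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.Z = np.atleast_2d(np.asarray(self.Z, dtype=float))
        self.D = np.atleast_2d(np.asarray(self.D, dtype=float))

    @property
    def n(self) -> int:
        return self.y.size

    def batched_blocks(self) -> "_BatchedBlocks":
        if not hasattr(self, "_batch"):
            self._batch = _BatchedBlocks(self.groups)
        return self._batch


def _block_kernel(y, p, theta):
    """Build a fast per-block evaluator of the ZINB log-density and its first
    two derivatives w.r.t. the latent value u (additive on the log-mean).

    ``y``, ``p``, ``theta`` are fixed within a block while the optimiser moves
    u, so every u-independent term (gamma functions, mixture logs) is
    precomputed here and the returned closure only does exp/log arithmetic.
    """
    y = np.asarray(y, dtype=float)
    theta = np.asarray(theta, dtype=float)
    p = np.clip(np.asarray(p, dtype=float), 1e-300, 1.0 - 1e-15)
    log1mp = np.log1p(-p)
    logp = np.log(p)
    const_nb = (gammaln(y + theta) - gammaln(theta) - gammaln(y + 1.0)
                + theta * np.log(theta))
    is_pos = y > 0

    def l_l1_l2(eta_u):
        eta_u = np.minimum(eta_u, _ETA_CAP)
        mu = np.exp(eta_u)
        tm = theta + mu
        log_tm = np.log(tm)
        nb = const_nb - theta * log_tm + y * (eta_u - log_tm)
        s = theta * mu / tm  # -d log NB(0)/du

        l_pos = log1mp + nb
        l1_pos = y - mu * (y + theta) / tm
        l2_pos = -(y + theta) * theta * mu / tm**2

        # zeros: mixture of structural zero and NB zero
        log_f0 = np.logaddexp(logp, log1mp + nb)
        w = np.exp(log1mp + nb - log_f0)  # P(NB branch | zero)
        l1_zero = -w * s
        l2_zero = w * (s**2 - s * theta / tm) - (w * s) ** 2

        l = np.where(is_pos, l_pos, log_f0)
        l1 = np.where(is_pos, l1_pos, l1_zero)
        l2 = np.where(is_pos, l2_pos, l2_zero)
        return l, l1, l2

    return l_l1_l2


def _obs_l_l1_l2(y, eta_u, p, theta):
    """One-shot evaluation of the per-observation kernel (testing hook)."""
    return _block_kernel(y, p, theta)(np.asarray(eta_u, dtype=float))


class _BatchedBlocks:
    """Padded stack of all multi-observation latent blocks of a panel.

    Blocks (centres) have unequal lengths; padding to the longest block lets
    the inner Newton run on stacked arrays with batched ``solve``/``slogdet``
    instead of a Python loop over centres.  Padded slots carry neutral values
    (unit precision, zero log-density) so they contribute nothing.
    """

    def __init__(self, groups):
        self.groups = [(idx, months) for idx, months in groups if idx.size > 1]
        self.B = len(self.groups)
        self.nmax = max((idx.size for idx, _ in self.groups), default=0)
        self.flat_idx = np.zeros((self.B, self.nmax), dtype=int)
        self.mask = np.zeros((self.B, self.nmax), dtype=bool)
        for b, (idx, _) in enumerate(self.groups):
            self.flat_idx[b, : idx.size] = idx
            self.mask[b, : idx.size] = True
        self.diag = np.arange(self.nmax)

    def pad(self, x, fill=0.0):
        out = x[self.flat_idx]
        out[~self.mask] = fill
        return out

    def precision(self, sigma, phi):
        """Stacked padded precision matrices and per-block covariance logdets."""
        Q = np.zeros((self.B, self.nmax, self.nmax))
        logdet = np.zeros(self.B)
        for b, (idx, months) in enumerate(self.groups):
            Qb, ld = _ar1_precision(months, sigma, phi)
            n = idx.size
            Q[b, :n, :n] = Qb
            Q[b, self.diag[n:], self.diag[n:]] = 1.0  # neutral padding
            logdet[b] = ld
        return Q, logdet


def _ar1_precision(months, sigma, phi):
    """Precision and log-determinant of the AR(1) covariance at given months."""
    n = len(months)
    cov = sigma**2 * ar1_correlation(months, phi)
    # guard conditioning for |phi| near 1
    cov[np.diag_indices(n)] += 1e-10 * sigma**2 + 1e-300
    Q = np.linalg.inv(cov)
    _, logdet_cov = np.linalg.slogdet(cov)
    return Q, logdet_cov


def _laplace_block(kernel, eta, Q, logdet_cov, u0=None):
    """Laplace-approximated log of the latent-AR(1) marginal for one centre.

    ``kernel`` is the per-block evaluator from ``_block_kernel``; the inner
    mode is found by damped Newton with a positive-definite step matrix.
    """
    n = eta.size
    u = np.zeros(n) if u0 is None else u0.copy()
    l, l1, l2 = kernel(eta + u)
    J = l.sum() - 0.5 * u @ Q @ u
    for _ in range(100):
        grad = l1 - Q @ u
        if np.max(np.abs(grad)) < 1e-8:
            break
        H_step = Q - np.diag(np.minimum(l2, -1e-12))
        du = np.linalg.solve(H_step, grad)
        step = 1.0
        for _ in range(40):
            u_new = u + step * du
            l_new, l1_new, l2_new = kernel(eta + u_new)
            J_new = l_new.sum() - 0.5 * u_new @ Q @ u_new
            if J_new >= J - 1e-12:
                break
            step *= 0.5
        if J_new < J - 1e-10:
            break  # no ascent possible
        u, l, l1, l2, J = u_new, l_new, l1_new, l2_new, J_new

    H = Q - np.diag(l2)
    sign_h, logdet_h = np.linalg.slogdet(H)
    if sign_h <= 0:  # curvature guard at a non-concave point
        H = Q - np.diag(np.minimum(l2, -1e-12))
        sign_h, logdet_h = np.linalg.slogdet(H)
    return l.sum() - 0.5 * u @ Q @ u - 0.5 * (logdet_cov + logdet_h), u


def _laplace_batched(batch: _BatchedBlocks, y, eta, p, theta, Q, logdet_cov, u0=None):
    """Laplace log-marginals for all multi-observation blocks at once.

    Same damped Newton as ``_laplace_block`` but on padded (B, nmax) stacks
    with per-block step control.  Returns (per-block log-likelihood sum, mode).
    """
    B, nmax, mask, diag = batch.B, batch.nmax, batch.mask, batch.diag
    y_p = batch.pad(np.asarray(y, dtype=float), fill=1.0)
    eta_p = batch.pad(eta, fill=0.0)
    p_p = batch.pad(p, fill=0.5)
    th_p = batch.pad(theta, fill=1.0)

    p_p = np.clip(p_p, 1e-300, 1.0 - 1e-15)
    log1mp = np.log1p(-p_p)
    logp = np.log(p_p)
    const_nb = (gammaln(y_p + th_p) - gammaln(th_p) - gammaln(y_p + 1.0)
                + th_p * np.log(th_p))
    is_pos = y_p > 0

    def kernel(eta_u, rows=slice(None)):
        """Evaluate l, l', l'' for a subset of blocks (rows of the pad)."""
        yp, thp, l1mp, lgp, cnb, pos, msk = (
            y_p[rows], th_p[rows], log1mp[rows], logp[rows],
            const_nb[rows], is_pos[rows], mask[rows])
        eta_u = np.minimum(eta_u, _ETA_CAP)
        mu = np.exp(eta_u)
        tm = thp + mu
        log_tm = np.log(tm)
        nb = cnb - thp * log_tm + yp * (eta_u - log_tm)
        s = thp * mu / tm
        l_pos = l1mp + nb
        l1_pos = yp - mu * (yp + thp) / tm
        l2_pos = -(yp + thp) * thp * mu / tm**2
        log_f0 = np.logaddexp(lgp, l1mp + nb)
        w = np.exp(l1mp + nb - log_f0)
        l1_zero = -w * s
        l2_zero = w * (s**2 - s * thp / tm) - (w * s) ** 2
        l = np.where(pos, l_pos, log_f0)
        l1 = np.where(pos, l1_pos, l1_zero)
        l2 = np.where(pos, l2_pos, l2_zero)
        l[~msk] = 0.0
        l1[~msk] = 0.0
        l2[~msk] = 0.0
        return l, l1, l2

    def objective(u, l, rows=slice(None)):
        return l.sum(axis=1) - 0.5 * np.einsum("bi,bij,bj->b", u, Q[rows], u)

    u = np.zeros((B, nmax)) if u0 is None else u0.copy()
    l, l1, l2 = kernel(eta_p + u)
    J = objective(u, l)
    frozen = np.zeros(B, dtype=bool)  # blocks whose line search stalled
    for _ in range(60):
        grad = l1 - np.einsum("bij,bj->bi", Q, u)
        grad[~mask] = 0.0
        active = ~frozen & (np.abs(grad).max(axis=1) >= 1e-8)
        if not active.any():
            break
        H_step = Q.copy()
        H_step[:, diag, diag] -= np.minimum(l2, -1e-12)
        du = np.linalg.solve(H_step, grad[..., None])[..., 0]
        du[~active] = 0.0
        # backtracking line search, re-evaluating only still-failing blocks
        step = np.ones(B)
        u_new, l_new, l1_new, l2_new, J_new = (
            u.copy(), l.copy(), l1.copy(), l2.copy(), J.copy())
        sub = np.where(active)[0]
        u_new[sub] = u[sub] + du[sub]
        for _ in range(30):
            ls, l1s, l2s = kernel(eta_p[sub] + u_new[sub], rows=sub)
            l_new[sub], l1_new[sub], l2_new[sub] = ls, l1s, l2s
            J_new[sub] = objective(u_new[sub], ls, rows=sub)
            failing = J_new[sub] < J[sub] - 1e-12
            if not failing.any():
                break
            sub = sub[failing]
            step[sub] *= 0.5
            u_new[sub] = u[sub] + step[sub, None] * du[sub]
        improved = active & (J_new >= J - 1e-10)
        frozen |= active & ~improved  # line search exhausted: no ascent possible
        if not improved.any():
            break
        u[improved] = u_new[improved]
        l[improved], l1[improved], l2[improved] = (
            l_new[improved], l1_new[improved], l2_new[improved])
        J[improved] = J_new[improved]

    H = Q.copy()
    H[:, diag, diag] -= l2
    sign_h, logdet_h = np.linalg.slogdet(H)
    if np.any(sign_h <= 0):  # curvature guard at non-concave points
        bad = sign_h <= 0
        Hb = Q[bad].copy()
        Hb[:, diag, diag] -= np.minimum(l2[bad], -1e-12)
        _, logdet_h[bad] = np.linalg.slogdet(Hb)
    ll = J - 0.5 * (logdet_cov + logdet_h)
    return float(ll.sum()), u


_gh_x, _gh_w = np.polynomial.hermite.hermgauss(_GH_NODES)
_log_gh_w = np.log(_gh_w)


def _agq_single(y, eta, p, theta, sigma):
    """Adaptive Gauss-Hermite marginal log-likelihood for a single observation."""
    kernel = _block_kernel(np.array([float(y)]), np.array([float(p)]),
                           np.array([float(theta)]))
    Q = np.array([[1.0 / sigma**2]])
    _, u_hat = _laplace_block(kernel, np.array([float(eta)]), Q,
                              2.0 * np.log(sigma))
    u0 = float(u_hat[0])
    _, _, l2 = kernel(np.array([eta + u0]))
    h = 1.0 / sigma**2 - float(l2[0])
    s = 1.0 / np.sqrt(max(h, 1e-12))
    u_k = u0 + np.sqrt(2.0) * s * _gh_x
    l_k, _, _ = kernel(eta + u_k)
    terms = _log_gh_w + _gh_x**2 + l_k - u_k**2 / (2.0 * sigma**2)
    return float(
        logsumexp(terms)
        + 0.5 * np.log(2.0)
        + np.log(s)
        - 0.5 * np.log(2.0 * np.pi * sigma**2)
    )


def marginal_loglik_zinb_ar1(params, data: Rel1Data, warm_starts: dict | None = None,
                             cov_cache: dict | None = None):
    """Marginal log-likelihood of the ZINB-AR(1) model over a centre-month panel.

    The per-centre latent AR(1) vector is integrated out (adaptive quadrature
    for singleton centres, Laplace otherwise).  With ``params.sigma_ar == 0``
    this returns the exact closed-form ZINB log-likelihood.

    ``warm_starts`` (group position -> previous latent mode) and ``cov_cache``
    (keyed by group and (sigma, phi)) speed up repeated evaluation inside an
    optimiser; both are optional plain dicts owned by the caller.
    """
    eta = data.X @ params.beta
    if params.beta_zi.size:
        p = expit(data.Z @ params.beta_zi)
    else:
        p = np.zeros(data.n)
    theta = np.exp(np.clip(data.D @ params.beta_disp, -30.0, 30.0))
    sigma, phi = params.sigma_ar, params.phi

    if sigma <= 0.0:
        mu = np.exp(np.clip(eta, -_ETA_CAP, _ETA_CAP))
        ll = zinb_logpmf(data.y, mu, theta, p)
        if not np.all(np.isfinite(ll)):
            return -np.inf
        return float(ll.sum())

    total = 0.0
    for idx, _ in data.groups:
        if idx.size == 1:
            i = idx[0]
            total += _agq_single(float(data.y[i]), float(eta[i]), float(p[i]),
                                 float(theta[i]), sigma)

    batch = data.batched_blocks()
    if batch.B:
        key = (sigma, phi)
        if cov_cache is not None and key in cov_cache:
            Q, logdet_cov = cov_cache[key]
        else:
            Q, logdet_cov = batch.precision(sigma, phi)
            if cov_cache is not None:
                if len(cov_cache) > 64:
                    cov_cache.clear()
                cov_cache[key] = (Q, logdet_cov)
        u0 = None if warm_starts is None else warm_starts.get("u")
        ll_b, u_hat = _laplace_batched(batch, data.y, eta, p, theta, Q, logdet_cov, u0=u0)
        if warm_starts is not None:
            warm_starts["u"] = u_hat
        total += ll_b
    if not np.isfinite(total):
        return -np.inf
    return float(total)


def gaussian_nll(beta, gamma, y, X, Zv):
    """Negative log-likelihood of the Gaussian model with log-linear variance."""
    res = y - X @ beta
    logvar = Zv @ gamma
    return 0.5 * float(np.sum(np.log(2.0 * np.pi) + logvar + res**2 * np.exp(-logvar)))


def gaussian_nll_grad(beta, gamma, y, X, Zv):
    """Analytic gradient of ``gaussian_nll`` w.r.t. ``(beta, gamma)`` stacked."""
    res = y - X @ beta
    inv_var = np.exp(-(Zv @ gamma))
    g_beta = -X.T @ (res * inv_var)
    g_gamma = 0.5 * Zv.T @ (1.0 - res**2 * inv_var)
    return np.concatenate([g_beta, g_gamma])
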