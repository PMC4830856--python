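"""Compiled numerical kernels for the polychoric and graphical-lasso estimators.

The permutation-based network comparison re-estimates the complete pipeline
(polychoric matrix -> glasso path -> EBIC selection) for every permutation,
so the per-estimation cost must stay in the low-millisecond range.  These
kernels are the single implementation used everywhere; the thin wrappers in
:mod:`qolnet.polychoric` and :mod:`qolnet.ggm` add validation and typed
containers on top.

Numerical notes
---------------
* ``_bvnu`` is a port of Genz's rectangle algorithm for the bivariate normal
  upper-orthant probability (Gauss-Legendre quadrature over a trigonometric
  substitution, with the Drezner-Wesolowsky tail expansion for |r| > 0.925);
  absolute accuracy is ~1e-14.
* The polychoric likelihood is maximised over rho in [-0.999, 0.999] by
  root-finding on the score function d loglik / d rho, which is available in
  closed form through Plackett's identity d Phi2(h,k,rho)/d rho = phi2(h,k,rho).
* The graphical lasso is the blockwise coordinate-descent algorithm on the
  covariance side; the diagonal of the precision matrix is unpenalised, so
  for a correlation input and lambda >= max |r_ij| the solution is exactly
  diag(1/r_ii).
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

_SQRT2 = math.sqrt(2.0)
_TWOPI = 2.0 * math.pi

# Gauss-Legendre abscissas/weights (half rules: 6-, 12- and 20-point).
_GL_W = np.array(
    [
        # 6-point
        0.1713244923791705, 0.3607615730481384, 0.4679139345726904,
        # 12-point
        0.04717533638651177, 0.1069393259953183, 0.1600783285433464,
        0.2031674267230659, 0.2334925365383547, 0.2491470458134029,
        # 20-point
        0.01761400713915212, 0.04060142980038694, 0.06267204833410906,
        0.08327674157670475, 0.1019301198172404, 0.1181945319615184,
        0.1316886384491766, 0.1420961093183821, 0.1491729864726037,
        0.1527533871307259,
    ]
)
_GL_X = np.array(
    [
        0.9324695142031522, 0.6612093864662647, 0.2386191860831970,
        0.9815606342467191, 0.9041172563704750, 0.7699026741943050,
        0.5873179542866171, 0.3678314989981802, 0.1252334085114692,
        0.9931285991850949, 0.9639719272779138, 0.9122344282513259,
        0.8391169718222188, 0.7463319064601508, 0.6360536807265150,
        0.5108670019508271, 0.3737060887154196, 0.2277858511416451,
        0.07652652113349733,
    ]
)


@njit(cache=True)
def _phi(x):
    """Standard normal CDF."""
    return 0.5 * math.erfc(-x / _SQRT2)


@njit(cache=True)
def _bvnu(dh, dk, r):
    """P(X > dh, Y > dk) for standard bivariate normal with correlation r."""
    if abs(r) < 0.3:
        lo, hi = 0, 3
    elif abs(r) < 0.75:
        lo, hi = 3, 9
    else:
        lo, hi = 9, 19
    h = dh
    k = dk
    hk = h * k
    bvn = 0.0
    if abs(r) < 0.925:
        if abs(r) > 0.0:
            hs = (h * h + k * k) / 2.0
            asr = math.asin(r)
            for i in range(lo, hi):
                sn = math.sin(asr * (1.0 - _GL_X[i]) / 2.0)
                bvn += _GL_W[i] * math.exp((sn * hk - hs) / (1.0 - sn * sn))
                sn = math.sin(asr * (1.0 + _GL_X[i]) / 2.0)
                bvn += _GL_W[i] * math.exp((sn * hk - hs) / (1.0 - sn * sn))
            bvn = bvn * asr / (2.0 * _TWOPI)
        bvn += _phi(-h) * _phi(-k)
    else:
        if r < 0.0:
            k = -k
            hk = -hk
        if abs(r) < 1.0:
            a_s = (1.0 - r) * (1.0 + r)
            a = math.sqrt(a_s)
            bs = (h - k) * (h - k)
            c = (4.0 - hk) / 8.0
            d = (12.0 - hk) / 16.0
            asr = -(bs / a_s + hk) / 2.0
            if asr > -100.0:
                bvn = (
                    a
                    * math.exp(asr)
                    * (1.0 - c * (bs - a_s) * (1.0 - d * bs / 5.0) / 3.0
                       + c * d * a_s * a_s / 5.0)
                )
            if -hk < 100.0:
                b = math.sqrt(bs)
                sp = math.sqrt(_TWOPI) * _phi(-b / a)
                bvn -= math.exp(-hk / 2.0) * sp * b * (
                    1.0 - c * bs * (1.0 - d * bs / 5.0) / 3.0
                )
            a = a / 2.0
            for i in range(lo, hi):
                for i_s in range(-1, 2, 2):
                    xs = a * (i_s * _GL_X[i] + 1.0)
                    xs = xs * xs
                    rs = math.sqrt(1.0 - xs)
                    asr2 = -(bs / xs + hk) / 2.0
                    if asr2 > -100.0:
                        sp2 = 1.0 + c * xs * (1.0 + d * xs)
                        ep = math.exp(-hk * (1.0 - rs) / (2.0 * (1.0 + rs))) / rs
                        bvn += a * _GL_W[i] * math.exp(asr2) * (ep - sp2)
            bvn = -bvn / _TWOPI
        if r > 0.0:
            hm = h if h > k else k
            bvn += _phi(-hm)
        else:
            bvn = -bvn
            if k > h:
                bvn += _phi(k) - _phi(h)
    if bvn < 0.0:
        bvn = 0.0
    elif bvn > 1.0:
        bvn = 1.0
    return bvn


@njit(cache=True)
def _bvn_cdf(h, k, r):
    """P(X <= h, Y <= k); h, k may be +-inf."""
    if h == np.inf:
        if k == np.inf:
            return 1.0
        return _phi(k)
    if k == np.inf:
        return _phi(h)
    if h == -np.inf or k == -np.inf:
        return 0.0
    return _bvnu(-h, -k, r)


@njit(cache=True)
def _bvn_pdf(h, k, r):
    om = 1.0 - r * r
    return math.exp(-(h * h - 2.0 * r * h * k + k * k) / (2.0 * om)) / (
        _TWOPI * math.sqrt(om)
    )


_PROB_FLOOR = 1e-12
_RHO_CLAMP = 0.999


@njit(cache=True)
def _pair_loglik_score(table, tau1, tau2, rho):
    """Log-likelihood and its rho-derivative for one contingency table.

    Cell probabilities are floored at 1e-12 inside the log so that tables
    with empty interior cells (perfect association) stay finite.
    """
    k1 = table.shape[0]
    k2 = table.shape[1]
    # CDF grid over extended thresholds (-inf, tau..., +inf)
    g = np.empty((k1 + 1, k2 + 1))
    d = np.zeros((k1 + 1, k2 + 1))
    for a in range(k1 + 1):
        t1 = -np.inf if a == 0 else (np.inf if a == k1 else tau1[a - 1])
        for b in range(k2 + 1):
            t2 = -np.inf if b == 0 else (np.inf if b == k2 else tau2[b - 1])
            g[a, b] = _bvn_cdf(t1, t2, rho)
            if 0 < a < k1 and 0 < b < k2:
                d[a, b] = _bvn_pdf(tau1[a - 1], tau2[b - 1], rho)
    ll = 0.0
    score = 0.0
    for a in range(k1):
        for b in range(k2):
            nab = table[a, b]
            if nab == 0.0:
                continue
            pi = g[a + 1, b + 1] - g[a, b + 1] - g[a + 1, b] + g[a, b]
            dpi = d[a + 1, b + 1] - d[a, b + 1] - d[a + 1, b] + d[a, b]
            if pi < _PROB_FLOOR:
                pi = _PROB_FLOOR
            ll += nab * math.log(pi)
            score += nab * dpi / pi
    return ll, score


@njit(cache=True)
def _pair_rho(table, tau1, tau2):
    """Two-step polychoric: ML over rho with thresholds held fixed.

    Root of the score on [-0.999, 0.999] by the Illinois variant of regula
    falsi; monotone-likelihood tables clamp at the interval ends.
    """
    lo = -_RHO_CLAMP
    hi = _RHO_CLAMP
    _, s_hi = _pair_loglik_score(table, tau1, tau2, hi)
    if s_hi >= 0.0:
        return hi
    _, s_lo = _pair_loglik_score(table, tau1, tau2, lo)
    if s_lo <= 0.0:
        return lo
    f_lo = s_lo
    f_hi = s_hi
    side = 0
    x = 0.0
    for _ in range(200):
        x = (lo * f_hi - hi * f_lo) / (f_hi - f_lo)
        if x <= lo or x >= hi:
            x = 0.5 * (lo + hi)
        _, fx = _pair_loglik_score(table, tau1, tau2, x)
        if fx > 0.0:
            lo = x
            f_lo = fx
            if side == 1:
                f_hi *= 0.5
            side = 1
        elif fx < 0.0:
            hi = x
            f_hi = fx
            if side == -1:
                f_lo *= 0.5
            side = -1
        else:
            return x
        if hi - lo < 1e-9:
            break
    return 0.5 * (lo + hi)


@njit(cache=True)
def _polychoric_matrix_kernel(codes, ncat, tau_pad):
    """Pairwise polychoric correlation matrix from 0-based integer codes.

    codes: (n, p) int64; ncat: (p,) int64 category counts; tau_pad: (p, Kmax-1)
    thresholds padded with zeros beyond ncat[i]-1.
    """
    n, p = codes.shape
    kmax = 0
    for i in range(p):
        if ncat[i] > kmax:
            kmax = ncat[i]
    r_mat = np.eye(p)
    table = np.zeros((kmax, kmax))
    for i in range(p):
        for j in range(i + 1, p):
            k1 = ncat[i]
            k2 = ncat[j]
            for a in range(k1):
                for b in range(k2):
                    table[a, b] = 0.0
            for t in range(n):
                table[codes[t, i], codes[t, j]] += 1.0
            rho = _pair_rho(
                table[:k1, :k2].copy(), tau_pad[i, : k1 - 1], tau_pad[j, : k2 - 1]
            )
            r_mat[i, j] = rho
            r_mat[j, i] = rho
    return r_mat


# ----------------------------------------------------------------------------
# Graphical lasso (blockwise coordinate descent, covariance side)
# ----------------------------------------------------------------------------


@njit(cache=True)
def _soft(x, t):
    if x > t:
        return x - t
    if x < -t:
        return x + t
    return 0.0


@njit(cache=True)
def _glasso_core(s_mat, lam, tol, max_sweeps, w_mat, b_mat):
    """One glasso solve, warm-started from (w_mat, b_mat) in place.

    Returns the number of sweeps used, or -1 if the sweep cap was hit before
    the maximum elementwise change of W fell below tol.
    """
    p = s_mat.shape[0]
    for sweep in range(max_sweeps):
        max_delta = 0.0
        for j in range(p):
            # lasso on column j: min 0.5 b' W11 b - s12' b + lam |b|_1
            for _ in range(200):
                inner = 0.0
                for i in range(p):
                    if i == j:
                        continue
                    acc = 0.0
                    for k in range(p):
                        if k != j and k != i:
                            acc += w_mat[i, k] * b_mat[k, j]
                    bnew = _soft(s_mat[i, j] - acc, lam) / w_mat[i, i]
                    diff = bnew - b_mat[i, j]
                    if abs(diff) > inner:
                        inner = abs(diff)
                    b_mat[i, j] = bnew
                if inner < 1e-9:
                    break
            for i in range(p):
                if i == j:
                    continue
                acc = 0.0
                for k in range(p):
                    if k != j:
                        acc += w_mat[i, k] * b_mat[k, j]
                diff = acc - w_mat[i, j]
                if abs(diff) > max_delta:
                    max_delta = abs(diff)
                w_mat[i, j] = acc
                w_mat[j, i] = acc
        if max_delta < tol:
            return sweep + 1
    return -1


@njit(cache=True)
def _recover_theta(w_mat, b_mat):
    """Precision matrix from the converged covariance-side solution.

    theta_ij = -beta_ij * theta_jj with exact zeros wherever beta is zero;
    symmetrised by averaging (both halves agree at convergence).
    """
    p = w_mat.shape[0]
    theta = np.zeros((p, p))
    for j in range(p):
        acc = 0.0
        for k in range(p):
            if k != j:
                acc += w_mat[k, j] * b_mat[k, j]
        t22 = 1.0 / (w_mat[j, j] - acc)
        theta[j, j] = t22
        for i in range(p):
            if i != j:
                theta[i, j] = -b_mat[i, j] * t22
    for i in range(p):
        for j in range(i + 1, p):
            v = 0.5 * (theta[i, j] + theta[j, i])
            theta[i, j] = v
            theta[j, i] = v
    return theta


@njit(cache=True)
def _glasso_single(s_mat, lam, tol, max_sweeps):
    w_mat = s_mat.copy()
    b_mat = np.zeros_like(s_mat)
    sweeps = _glasso_core(s_mat, lam, tol, max_sweeps, w_mat, b_mat)
    theta = _recover_theta(w_mat, b_mat)
    return theta, w_mat, sweeps


@njit(cache=True)
def _ebic_value(s_mat, theta, n, gamma):
    """EBIC = -2 * (n/2)(logdet Theta - tr(S Theta)) + E log n + 4 E gamma log p."""
    p = theta.shape[0]
    chol = np.linalg.cholesky(theta)
    logdet = 0.0
    for i in range(p):
        logdet += math.log(chol[i, i])
    logdet *= 2.0
    tr = 0.0
    n_edges = 0
    for i in range(p):
        for j in range(p):
            tr += s_mat[i, j] * theta[j, i]
            if j > i and theta[i, j] != 0.0:
                n_edges += 1
    ll = 0.5 * n * (logdet - tr)
    return -2.0 * ll + n_edges * math.log(n) + 4.0 * gamma * n_edges * math.log(p), n_edges


@njit(cache=True)
def _select_path_kernel(s_mat, lambdas, n, gamma, tol, max_sweeps):
    """Warm-started glasso along a decreasing lambda path; EBIC per lambda.

    Ties in EBIC resolve toward the sparser (larger-lambda, earlier) model.
    Returns (best_theta, best_index, ebics, edge_counts); best_index == -1
    signals a non-converged fit somewhere along the path.
    """
    p = s_mat.shape[0]
    m = lambdas.shape[0]
    w_mat = s_mat.copy()
    b_mat = np.zeros((p, p))
    ebics = np.empty(m)
    edge_counts = np.zeros(m, dtype=np.int64)
    best = np.inf
    best_idx = -1
    best_theta = np.eye(p)
    for li in range(m):
        sweeps = _glasso_core(s_mat, lambdas[li], tol, max_sweeps, w_mat, b_mat)
        if sweeps < 0:
            for lj in range(li, m):
                ebics[lj] = np.nan
            return best_theta, -1, ebics, edge_counts
        theta = _recover_theta(w_mat, b_mat)
        eb, n_edges = _ebic_value(s_mat, theta, n, gamma)
        ebics[li] = eb
        edge_counts[li] = n_edges
        if eb < best:
            best = eb
            best_idx = li
            best_theta = theta.copy()
    return best_theta, best_idx, ebics, edge_counts


@njit(cache=True)
def _pcor_from_theta(theta):
    p = theta.shape[0]
    w = np.zeros((p, p))
    for i in range(p):
        for j in range(p):
            if i != j and theta[i, j] != 0.0:
                w[i, j] = -theta[i, j] / math.sqrt(theta[i, i] * theta[j, j])
    return w


def warm_up() -> None:
    """Trigger JIT compilation of every kernel on tiny inputs."""
    codes = np.array([[0, 1], [1, 0], [1, 1], [0, 0]], dtype=np.int64)
    ncat = np.array([2, 2], dtype=np.int64)
    tau = np.zeros((2, 1))
    r = _polychoric_matrix_kernel(codes, ncat, tau)
    lams = np.array([0.5, 0.1])
    _select_path_kernel(np.eye(2), lams, 10, 0.5, 1e-6, 100)
    theta, _, _ = _glasso_single(np.eye(2), 0.1, 1e-6, 100)
    _pcor_from_theta(theta)
    _bvn_cdf(0.3, -0.2, 0.5)
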