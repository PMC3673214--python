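"""Variance-component score test on the two-kernel model (SKAT-style).

The score statistic for the tested-set variance component, evaluated at the
null (tau = 0) REML fit, is

    Q = y' P0 K_v P0 y,     P0 = Sigma0^-1 - Sigma0^-1 F (F' Sigma0^-1 F)^-1 F' Sigma0^-1

with Sigma0 = sigma_g^2 (K_w + delta I) the fitted null covariance and
K_v = V V'/s_v the kernel of the tested set.  Under the null Q is distributed
as a weighted sum of independent 1-df chi-squares whose weights are the
nonzero eigenvalues of V' P0 V / s_v.  Tail probabilities are computed by
numerical inversion of the characteristic function (Davies/Imhof); a
moment-matching approximation stands by as a flagged fallback when the
inversion misbehaves.

All linear algebra runs through the low-rank factor of the confounder kernel:
no n x n matrix is formed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate, stats

from .lmm_core import KernelFactor, TwoKernelFit, _check_design

logger = logging.getLogger(__name__)


@dataclass
class ScoreResult:
    set_id: str
    q_statistic: float
    p_value: float
    method: str  # "davies" or "liu_fallback"


class _NullPrecision:
    """Applies Sigma0^-1 and the REML projection P0 through the factor of K_w."""

    def __init__(self, y, F, W: KernelFactor, null_fit: TwoKernelFit):
        y = np.asarray(y, dtype=float).ravel()
        n = len(y)
        F = _check_design(F, n)
        self.sigma_g2 = max(null_fit.sigma_g2, 1e-300)
        self.delta = null_fit.delta
        Xw = W.factor / math.sqrt(W.scale)
        if Xw.size:
            U, d, _ = np.linalg.svd(Xw, full_matrices=False)
            keep = d > d.max() * 1e-12
            self.U, self.S = U[:, keep], d[keep] ** 2
        else:
            self.U, self.S = np.zeros((n, 0)), np.zeros(0)
        self.F = F
        self.SF = self.sigma_inv(F)
        A = F.T @ self.SF
        A = 0.5 * (A + A.T)
        try:
            self.A_inv_factor = np.linalg.cholesky(A)
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(
                "collinear fixed effects under the null covariance"
            ) from err
        self.A = A

    def sigma_inv(self, M):
        """Sigma0^-1 M for a vector or tall matrix M, via Woodbury."""
        M = np.asarray(M, dtype=float)
        vec = M.ndim == 1
        if vec:
            M = M[:, None]
        M1 = self.U.T @ M
        out = self.U @ (M1 / (self.S + self.delta)[:, None])
        out += (M - self.U @ M1) / self.delta
        out /= self.sigma_g2
        return out[:, 0] if vec else out

    def project(self, M):
        """P0 M = Sigma0^-1 M - Sigma0^-1 F (F' Sigma0^-1 F)^-1 F' Sigma0^-1 M."""
        SM = self.sigma_inv(M)
        coef = np.linalg.solve(self.A, self.F.T @ SM)
        return SM - self.SF @ coef


def score_statistic(y, F, null_fit: TwoKernelFit, W: KernelFactor,
                    V: KernelFactor):
    """Score statistic Q and the chi-square mixture weights of its null.

    ``null_fit`` must be the tau = 0 REML fit on (y, F, W).  Returns
    ``(Q, eigenweights)`` where the weights are the nonzero eigenvalues of
    V' P0 V / s_v (computed in the k_v x k_v Gram form).
    """
    prec = _NullPrecision(y, F, W, null_fit)
    y = np.asarray(y, dtype=float).ravel()
    Vf = V.factor
    P0y = prec.project(y)
    u = Vf.T @ P0y
    Q = float(u @ u) / V.scale
    G = Vf.T @ prec.project(Vf) / V.scale
    G = 0.5 * (G + G.T)
    lam = np.linalg.eigvalsh(G)
    lam = lam[lam > max(lam[-1], 0.0) * 1e-12] if lam.size else lam
    return Q, lam


def _imhof_pvalue(q: float, lam: np.ndarray) -> float:
    """P(sum lam_i chi2_1 > q) by Imhof's characteristic-function integral.

    The integrand sin(theta(u)) / (u rho(u)) decays only like u^(-1-m/2), so
    the tail is integrated with oscillatory-weight quadrature after writing
    sin(theta) = sin(phi)cos(qu/2) - cos(phi)sin(qu/2), where
    phi(u) = 0.5 sum arctan(lam u) is smooth and bounded.
    """

    def phi(u):
        return 0.5 * float(np.sum(np.arctan(lam * u)))

    def inv_urho(u):
        return math.exp(-0.25 * float(np.sum(np.log1p((lam * u) ** 2)))) / u

    def head(u):
        return math.sin(phi(u) - 0.5 * q * u) * inv_urho(u)

    w = 0.5 * q
    u0 = 1.0 / float(lam.max())
    val1, err1 = integrate.quad(head, 0.0, u0, limit=200,
                                epsabs=1e-10, epsrel=1e-8)
    val2, err2 = integrate.quad(lambda u: math.sin(phi(u)) * inv_urho(u),
                                u0, np.inf, weight="cos", wvar=w, limit=400)
    val3, err3 = integrate.quad(lambda u: math.cos(phi(u)) * inv_urho(u),
                                u0, np.inf, weight="sin", wvar=w, limit=400)
    err = err1 + err2 + err3
    if err > 1e-6:
        raise RuntimeError(f"Imhof integral error estimate too large: {err}")
    return 0.5 + (val1 + val2 - val3) / math.pi


def _liu_pvalue(q: float, lam: np.ndarray) -> float:
    """Moment-matched noncentral chi-square approximation (Liu et al. style)."""
    c1, c2, c3, c4 = (float(np.sum(lam**j)) for j in (1, 2, 3, 4))
    s1 = c3 / c2**1.5
    s2 = c4 / c2**2
    mu_q = c1
    sigma_q = math.sqrt(2.0 * c2)
    if s1**2 > s2:
        a = 1.0 / (s1 - math.sqrt(s1**2 - s2))
        ncp = s1 * a**3 - a**2
        df = a**2 - 2.0 * ncp
    else:
        df = 1.0 / s2
        ncp = 0.0
    mu_x = df + ncp
    sigma_x = math.sqrt(2.0 * (df + 2.0 * ncp))
    tstar = (q - mu_q) / sigma_q
    return float(stats.ncx2.sf(tstar * sigma_x + mu_x, df, ncp))


def davies_pvalue(q: float, eigenweights) -> tuple[float, str]:
    """Tail probability of the weighted chi-square mixture at ``q``.

    Uses characteristic-function inversion (the Davies/Imhof approach); if
    the numerical inversion fails or returns a probability outside [0, 1],
    falls back to the moment-matching approximation with the method flag set
    to ``"liu_fallback"``.  Returns ``(p_value, method)``.
    """
    lam = np.asarray(eigenweights, dtype=float)
    lam = lam[lam > 0]
    if q <= 0.0 or lam.size == 0:
        return 1.0, "davies"
    try:
        p = _imhof_pvalue(q, lam)
        if not np.isfinite(p) or p < -1e-6 or p > 1.0 + 1e-6:
            raise RuntimeError(f"inversion outside [0, 1]: {p}")
        method = "davies"
    except Exception as err:  # noqa: BLE001 - any inversion failure -> fallback
        logger.debug("characteristic-function inversion failed (%s); "
                     "using moment-matching fallback", err)
        p = _liu_pvalue(q, lam)
        method = "liu_fallback"
    p = float(min(max(p, np.finfo(float).tiny), 1.0))
    return p, method


def score_test_set(set_id: str, y, F, null_fit: TwoKernelFit, W: KernelFactor,
                   V: KernelFactor) -> ScoreResult:
    """Run the score test for one SNP set and wrap the result."""
    if V.k == 0:
        return ScoreResult(set_id=set_id, q_statistic=0.0, p_value=1.0,
                           method="davies")
    Q, lam = score_statistic(y, F, null_fit, W, V)
    p, method = davies_pvalue(Q, lam)
    return ScoreResult(set_id=set_id, q_statistic=Q, p_value=p, method=method)
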