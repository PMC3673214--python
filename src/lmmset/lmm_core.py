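"""Two-variance-component linear mixed model with linear-time REML.

The phenotype covariance is modelled as

    Sigma(tau, delta) = sigma_g^2 [ (1 - tau) W W'/s_w + tau V V'/s_v + delta I ]

where ``W`` holds standardized confounder SNPs (the background kernel), ``V``
the standardized SNPs of the tested set, ``s_w``/``s_v`` the SNP counts
(realized-relationship normalization), ``tau in [0, 1]`` allocates genetic
variance between the two kernels and ``delta = sigma_e^2 / sigma_g^2`` is the
residual-to-genetic variance ratio.  The null hypothesis of the set test is
``tau = 0``.

Because both kernels factor over at most k = k_w + k_v << n SNPs, the
restricted likelihood can be evaluated from the spectrum of a k x k Gram
matrix after a single O(n k^2) pass over the data: no n x n matrix is ever
formed, and the whole (tau, delta) optimization costs O(k^3) per step.  Fixed
effects (always including an intercept) and sigma_g^2 are profiled out in
closed form.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

logger = logging.getLogger(__name__)

_LOG_2PI = math.log(2.0 * math.pi)
_TAU_ZERO_TOL = 1e-5  # tau-hat below this is recorded as exactly 0


class NumericalError(RuntimeError):
    pass


@dataclass
class KernelFactor:
    """Tall factor of a genetic-similarity kernel: K = factor factor' / scale.

    Columns are SNPs standardized to zero mean and unit variance (constant
    columns dropped at construction); ``scale`` is the number of SNPs that
    went in, giving the realized-relationship normalization.
    """

    factor: np.ndarray
    scale: float

    def __post_init__(self):
        if self.scale <= 0:
            raise ValueError("kernel scale must be positive")
        self.factor = np.asarray(self.factor, dtype=float)
        if self.factor.ndim != 2:
            raise ValueError("factor must be an n x k matrix")

    @property
    def n(self) -> int:
        return self.factor.shape[0]

    @property
    def k(self) -> int:
        return self.factor.shape[1]

    @classmethod
    def from_encoded(cls, X: np.ndarray) -> "KernelFactor":
        """Standardize encoded dosage columns; drop constant ones."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        keep = sd > 0
        if not keep.all():
            logger.debug("dropping %d constant columns from kernel factor",
                         int((~keep).sum()))
        Z = (X[:, keep] - mu[keep]) / sd[keep]
        k = int(keep.sum())
        return cls(factor=Z, scale=float(max(k, 1)))

    @classmethod
    def empty(cls, n: int) -> "KernelFactor":
        return cls(factor=np.zeros((n, 0)), scale=1.0)


@dataclass
class TwoKernelFit:
    """REML fit of the two-kernel model at the optimum (tau-hat, delta-hat)."""

    tau: float
    delta: float
    sigma_g2: float
    beta: np.ndarray
    reml_loglik: float

    def __post_init__(self):
        if not np.isfinite(self.reml_loglik):
            raise NumericalError(
                f"non-finite restricted likelihood at tau={self.tau}, delta={self.delta}"
            )
        if not 0.0 <= self.tau <= 1.0:
            raise ValueError("tau outside [0, 1]")
        if self.delta <= 0:
            raise ValueError("delta must be positive")


def stacked_factor(W: KernelFactor, V: KernelFactor, tau: float) -> np.ndarray:
    """Side-by-side factor X with X X' = (1-tau) W W'/s_w + tau V V'/s_v."""
    if not 0.0 <= tau <= 1.0:
        raise ValueError(f"tau={tau} outside [0, 1]")
    if W.n != V.n:
        raise ValueError(f"factor row mismatch: {W.n} vs {V.n}")
    return np.hstack([
        math.sqrt((1.0 - tau) / W.scale) * W.factor,
        math.sqrt(tau / V.scale) * V.factor,
    ])


class _RotatedProfile:
    """Restricted likelihood of Sigma = sigma_g^2 (X X' + delta I), profiled.

    Works from the nonzero spectrum S of X X' and the rotations of y and F
    onto the corresponding eigenvectors; evaluating one delta costs
    O(r p^2 + p^3) with r = rank(X).
    """

    def __init__(self, S, y1, F1, yty, FtF, Fty, n):
        self.S = np.asarray(S, float)
        self.y1 = np.asarray(y1, float)
        self.F1 = np.asarray(F1, float)
        self.yty = float(yty)
        self.FtF = np.asarray(FtF, float)
        self.Fty = np.asarray(Fty, float)
        self.n = int(n)
        self.p = self.FtF.shape[0]
        sign, self.logdet_FtF = np.linalg.slogdet(self.FtF)
        if sign <= 0:
            raise np.linalg.LinAlgError("rank-deficient fixed-effect design")
        # complement (null-space of X) pieces, clamped against round-off
        self.y2ty2 = max(self.yty - float(self.y1 @ self.y1), 0.0)
        self.F2tF2 = self.FtF - self.F1.T @ self.F1
        self.F2ty2 = self.Fty - self.F1.T @ self.y1

    def eval(self, delta: float):
        if delta <= 0:
            raise ValueError(f"delta={delta} must be positive")
        S, n, p = self.S, self.n, self.p
        r = S.size
        w = 1.0 / (S + delta)
        A = (self.F1 * w[:, None]).T @ self.F1 + self.F2tF2 / delta
        b = self.F1.T @ (w * self.y1) + self.F2ty2 / delta
        c = float(w @ (self.y1**2)) + self.y2ty2 / delta
        A = 0.5 * (A + A.T)
        try:
            beta = np.linalg.solve(A, b)
        except np.linalg.LinAlgError as err:
            raise NumericalError(f"singular GLS system at delta={delta}") from err
        r2 = max(c - float(b @ beta), 1e-300)
        sigma_g2 = r2 / (n - p)
        logdet_Sigma = float(np.log(S + delta).sum()) + (n - r) * math.log(delta)
        sign, logdet_A = np.linalg.slogdet(A)
        if sign <= 0:
            raise NumericalError(f"indefinite F' Sigma^-1 F at delta={delta}")
        ll = -0.5 * (
            (n - p) * (_LOG_2PI + math.log(sigma_g2))
            + logdet_Sigma + logdet_A - self.logdet_FtF + (n - p)
        )
        return ll, beta, sigma_g2


def _check_design(F: np.ndarray, n: int):
    F = np.asarray(F, dtype=float)
    if F.ndim != 2 or F.shape[0] != n:
        raise ValueError("fixed-effect design must be n x p")
    p = F.shape[1]
    if p < 1:
        raise ValueError("fixed effects must include at least an intercept")
    if n <= p:
        raise ValueError("need more individuals than fixed effects")
    if np.linalg.matrix_rank(F) < p:
        # name the offending columns for the error message
        _, R = np.linalg.qr(F)
        bad = [j for j in range(p) if abs(R[j, j]) < 1e-10 * max(1.0, abs(R[0, 0]))]
        raise np.linalg.LinAlgError(f"collinear fixed-effect columns: {bad}")
    return F


def _profile_from_svd(y, F, X) -> _RotatedProfile:
    n = len(y)
    if X.size:
        U, d, _ = np.linalg.svd(X, full_matrices=False)
        keep = d > d.max() * 1e-12 if d.size else np.zeros(0, bool)
        U, d = U[:, keep], d[keep]
        S = d**2
        y1, F1 = U.T @ y, U.T @ F
    else:
        S = np.zeros(0)
        y1, F1 = np.zeros(0), np.zeros((0, F.shape[1]))
    return _RotatedProfile(S, y1, F1, y @ y, F.T @ F, F.T @ y, n)


def reml_profile(y, F, X, delta: float):
    """Restricted log-likelihood of Sigma = sigma_g^2 (X X' + delta I).

    beta and sigma_g^2 are profiled out in closed form; computed through the
    economy SVD of the n x k factor ``X`` (cost O(n k^2), memory O(n k)).
    Returns ``(loglik, beta, sigma_g2)``.
    """
    y = np.asarray(y, dtype=float).ravel()
    F = _check_design(F, len(y))
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return _profile_from_svd(y, F, X).eval(delta)


class TwoKernelWorkspace:
    """Per-(y, F, W, V) cache enabling O(k^3) likelihood evaluations.

    One O(n k^2) pass forms the Gram blocks of C = [W_std, V_std] together
    with the projections of y and F; every subsequent (tau, delta) evaluation
    works on k x k matrices only.  ``replace_test_factor`` swaps in a
    row-permuted copy of V at O(n k k_v) cost, which is what makes the
    permutation scheme cheap.
    """

    def __init__(self, y, F, W: KernelFactor, V: KernelFactor):
        self.y = np.asarray(y, dtype=float).ravel()
        n = len(self.y)
        self.F = _check_design(F, n)
        if W.n != n or V.n != n:
            raise ValueError("kernel factors do not match cohort size")
        self.W, self.V = W, V
        self.n = n
        self.kw, self.kv = W.k, V.k
        self.yty = float(self.y @ self.y)
        self.FtF = self.F.T @ self.F
        self.Fty = self.F.T @ self.y
        self._WtW = W.factor.T @ W.factor
        self._Wty = W.factor.T @ self.y
        self._WtF = W.factor.T @ self.F
        self._set_V_blocks(V.factor)
        self._profile_cache: dict[float, _RotatedProfile] = {}

    def _set_V_blocks(self, Vf: np.ndarray):
        self._Vf = Vf
        self._WtV = self.W.factor.T @ Vf
        self._VtV = Vf.T @ Vf
        self._Vty = Vf.T @ self.y
        self._VtF = Vf.T @ self.F
        self._profile_cache = {}

    def replace_test_factor(self, perm: np.ndarray):
        """Apply a row permutation to V only (y, F, W untouched)."""
        self._set_V_blocks(self.V.factor[perm])

    def restore_test_factor(self):
        self._set_V_blocks(self.V.factor)

    def profile(self, tau: float) -> _RotatedProfile:
        if not 0.0 <= tau <= 1.0:
            raise ValueError(f"tau={tau} outside [0, 1]")
        cached = self._profile_cache.get(tau)
        if cached is not None:
            return cached
        dw = math.sqrt((1.0 - tau) / self.W.scale)
        dv = math.sqrt(tau / self.V.scale)
        d = np.concatenate([np.full(self.kw, dw), np.full(self.kv, dv)])
        k = d.size
        if k == 0:
            prof = _RotatedProfile(np.zeros(0), np.zeros(0),
                                   np.zeros((0, self.F.shape[1])),
                                   self.yty, self.FtF, self.Fty, self.n)
            self._profile_cache[tau] = prof
            return prof
        G = np.empty((k, k))
        G[: self.kw, : self.kw] = self._WtW
        G[: self.kw, self.kw:] = self._WtV
        G[self.kw:, : self.kw] = self._WtV.T
        G[self.kw:, self.kw:] = self._VtV
        M = (d[:, None] * G) * d[None, :]
        S, Q = np.linalg.eigh(M)
        # relative cut for round-off zeros plus an absolute floor (eigenvalues
        # of genuine kernel directions are O(n) for standardized columns)
        keep = S > max(max(S[-1], 0.0) * 1e-12, self.n * 1e-13)
        S, Q = S[keep], Q[:, keep]
        # B maps Gram coordinates to the orthonormal eigenbasis of X X'
        B = Q / np.sqrt(S)[None, :]
        Cy = np.concatenate([self._Wty, self._Vty])
        CF = np.vstack([self._WtF, self._VtF])
        y1 = B.T @ (d * Cy)
        F1 = B.T @ (d[:, None] * CF)
        prof = _RotatedProfile(S, y1, F1, self.yty, self.FtF, self.Fty, self.n)
        self._profile_cache[tau] = prof
        return prof


def _optimize_delta(prof: _RotatedProfile, logdelta_bounds=(-10.0, 10.0),
                    xatol: float = 1e-6):
    """Inner 1-D Brent search over log delta; returns (ll, delta, beta, sigma_g2)."""

    def neg(logdelta: float) -> float:
        return -prof.eval(math.exp(logdelta))[0]

    res = minimize_scalar(neg, bounds=logdelta_bounds, method="bounded",
                          options={"xatol": xatol})
    candidates = [(res.x, -res.fun)]
    for b in logdelta_bounds:
        candidates.append((b, -neg(b)))
    logdelta, ll = max(candidates, key=lambda t: t[1])
    delta = math.exp(logdelta)
    ll, beta, sigma_g2 = prof.eval(delta)
    if not np.isfinite(ll):
        raise NumericalError(f"non-finite likelihood at delta={delta}")
    return ll, delta, beta, sigma_g2


def fit_two_kernel(
    y=None, F=None, W: KernelFactor | None = None, V: KernelFactor | None = None,
    tau_fixed: float | None = None, *, workspace: TwoKernelWorkspace | None = None,
    tau_xatol: float = 1e-5,
) -> TwoKernelFit:
    """Maximize the restricted likelihood over (tau, delta).

    If ``tau_fixed`` is given (e.g. 0 for the null model) only the inner Brent
    search over log delta runs; otherwise an outer Brent search over tau in
    [0, 1] wraps it, with both endpoints evaluated explicitly to guard against
    boundary optima.  A tau-hat below 1e-5 is recorded as exactly 0.

    A prebuilt :class:`TwoKernelWorkspace` may be supplied instead of
    (y, F, W, V); the pipeline uses this to amortize the O(n k^2) setup over
    permutations.
    """
    ws = workspace if workspace is not None else TwoKernelWorkspace(y, F, W, V)

    best: dict[float, tuple] = {}

    def fit_at(tau: float):
        if tau not in best:
            best[tau] = _optimize_delta(ws.profile(tau))
        return best[tau]

    if tau_fixed is not None:
        if not 0.0 <= tau_fixed <= 1.0:
            raise ValueError(f"tau_fixed={tau_fixed} outside [0, 1]")
        tau_hat = tau_fixed
    else:
        res = minimize_scalar(lambda t: -fit_at(t)[0], bounds=(0.0, 1.0),
                              method="bounded", options={"xatol": tau_xatol})
        fit_at(0.0)
        fit_at(1.0)
        tau_hat = max(best, key=lambda t: best[t][0])

    ll, delta, beta, sigma_g2 = fit_at(tau_hat)
    if tau_fixed is None and tau_hat < _TAU_ZERO_TOL:
        # boundary rule: tiny tau-hat is the tau = 0 component of the null
        ll0, delta0, beta0, sg0 = fit_at(0.0)
        if ll0 >= ll - 1e-9:
            tau_hat, ll, delta, beta, sigma_g2 = 0.0, ll0, delta0, beta0, sg0
        else:
            tau_hat = 0.0
    return TwoKernelFit(tau=tau_hat, delta=delta, sigma_g2=sigma_g2,
                        beta=beta, reml_loglik=ll)


def lrt_statistic(fit_alt: TwoKernelFit, fit_null: TwoKernelFit) -> float:
    """2 x (restricted loglik alt - null), clipped to zero from below.

    A clip larger than 1e-4 signals an optimizer failure and is logged.
    """
    stat = 2.0 * (fit_alt.reml_loglik - fit_null.reml_loglik)
    if stat < 0.0:
        if stat < -1e-4:
            logger.warning("negative LRT %.3g clipped to 0 (optimizer failure?)", stat)
        stat = 0.0
    if fit_alt.tau == 0.0:
        stat = 0.0
    return stat
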