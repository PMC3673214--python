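"""Calibration diagnostics: genomic-control lambda, univariate scans
(uncorrected, mixed-model-corrected, conditional) and the set-size check.

The genomic-control inflation factor lambda is the ratio of the median
observed 1-df chi-square statistic (obtained by transforming P-values) to
the theoretical null median 0.45494; values well above 1 indicate
confounding.  The conditional scan reproduces, per SNP of a set, the
marginal mixed-model P-value and the P-value conditioned on the remaining
set SNPs as fixed covariates - the mechanism by which a set test can unmask
signal hidden by within-set linkage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .genio import GenotypeData, SnpSet, encode_and_impute
from .lmm_core import KernelFactor, fit_two_kernel
from .set_pipeline import SetTestResult, build_confounder_factor

logger = logging.getLogger(__name__)

CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, 1))  # 0.454936...


@dataclass
class ScanResult:
    snp_id: str
    beta_hat: float
    p_value: float
    model: str  # "linreg" or "lmm"


def genomic_lambda(p_values) -> float:
    """Median observed chi-square over the theoretical null median."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("no P-values")
    chi = stats.chi2.isf(p, 1)
    return float(np.median(chi) / CHI2_1_MEDIAN)


class _GlsTester:
    """GLS fixed-effect t-tests under Sigma = X X' + delta I (low rank)."""

    def __init__(self, Xfac: np.ndarray, delta: float):
        self.delta = delta
        if Xfac.size:
            U, d, _ = np.linalg.svd(Xfac, full_matrices=False)
            keep = d > d.max() * 1e-12
            self.U, self.S = U[:, keep], d[keep] ** 2
        else:
            self.U = np.zeros((Xfac.shape[0], 0))
            self.S = np.zeros(0)

    def sigma_inv(self, M):
        vec = M.ndim == 1
        if vec:
            M = M[:, None]
        M1 = self.U.T @ M
        out = self.U @ (M1 / (self.S + self.delta)[:, None])
        out += (M - self.U @ M1) / self.delta
        return out[:, 0] if vec else out

    def t_test(self, y, G, j_test):
        """GLS t-test of column ``j_test`` of design ``G``; sigma2 profiled."""
        n, p = G.shape
        SG = self.sigma_inv(G)
        A = G.T @ SG
        try:
            Ainv = np.linalg.inv(A)
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError("collinear design in GLS test") from err
        beta = Ainv @ (SG.T @ y)
        resid = y - G @ beta
        sigma2 = float(resid @ self.sigma_inv(resid)) / (n - p)
        se = np.sqrt(sigma2 * Ainv[j_test, j_test])
        if se == 0:
            return beta[j_test], 1.0
        t = beta[j_test] / se
        return float(beta[j_test]), float(2.0 * stats.t.sf(abs(t), df=n - p))


def univariate_scan(data: GenotypeData, model: str = "linreg",
                    W_ids=None, exclusion_cm: float = 2.0,
                    covariates=None) -> list[ScanResult]:
    """Per-SNP fixed-effect association tests.

    ``model="linreg"`` is the ordinary least-squares t-test (no correction);
    ``model="lmm"`` tests each SNP under the confounder kernel built from
    ``W_ids``, excluding from the kernel the tested SNP and anything within
    ``exclusion_cm`` of it (delta is estimated once on the global null model
    and plugged in per SNP).
    """
    X = encode_and_impute(data)
    y = np.asarray(data.phenotype, dtype=float)
    n = data.n
    base = [np.ones((n, 1))]
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        base.append(C[:, None] if C.ndim == 1 else C)
    F = np.hstack(base)
    results = []

    if model == "linreg":
        tester = _GlsTester(np.zeros((n, 0)), 1.0)
        for j in range(data.s):
            x = X[:, j]
            if np.ptp(x) == 0:  # monomorphic: nothing to test
                results.append(ScanResult(data.snps[j].snp_id, 0.0, 1.0,
                                          "linreg"))
                continue
            G = np.hstack([F, x[:, None]])
            if np.linalg.matrix_rank(G) < G.shape[1]:
                raise np.linalg.LinAlgError(
                    f"SNP {data.snps[j].snp_id} collinear with covariates")
            beta, p = tester.t_test(y, G, G.shape[1] - 1)
            results.append(ScanResult(data.snps[j].snp_id, beta, p, "linreg"))
        return results

    if model != "lmm":
        raise ValueError(f"unknown scan model {model!r}")
    if W_ids is None:
        raise ValueError("lmm scan needs confounder SNP ids")

    idx = data.snp_index()
    cm = data.map_cm()
    # global null fit gives the plug-in delta
    W_all = KernelFactor.from_encoded(X[:, [idx[s] for s in W_ids]])
    null_fit = fit_two_kernel(y, F, W_all, KernelFactor.empty(n), tau_fixed=0.0)
    w_info = [(s, data.snps[idx[s]].chromosome, cm[idx[s]]) for s in W_ids]
    cache_key, tester = None, None
    for j in range(data.s):
        chrom, pos = data.snps[j].chromosome, cm[j]
        sid = data.snps[j].snp_id
        if np.ptp(X[:, j]) == 0:
            results.append(ScanResult(sid, 0.0, 1.0, "lmm"))
            continue
        kept = [idx[s] for s, c, p_ in w_info
                if s != sid and not (c == chrom and abs(p_ - pos) <= exclusion_cm)]
        key = tuple(kept)
        if key != cache_key:
            fac = KernelFactor.from_encoded(X[:, kept]) if kept \
                else KernelFactor.empty(n)
            Xfac = fac.factor / np.sqrt(fac.scale)
            tester = _GlsTester(Xfac, null_fit.delta)
            cache_key = key
        G = np.hstack([F, X[:, j][:, None]])
        if np.linalg.matrix_rank(G) < G.shape[1]:
            raise np.linalg.LinAlgError(f"SNP {sid} collinear with covariates")
        beta, p = tester.t_test(y, G, G.shape[1] - 1)
        results.append(ScanResult(sid, beta, p, "lmm"))
    return results


def conditional_univariate(data: GenotypeData, snp_set: SnpSet, W_ids,
                           exclusion_cm: float = 2.0):
    """Marginal and conditional mixed-model P-values for each SNP of a set.

    The conditional test adds all *other* set SNPs as fixed covariates
    (collinear columns dropped at tolerance 1e-8).  Returns a list of dicts
    with marginal and conditional P-values per SNP.
    """
    X = encode_and_impute(data)
    y = np.asarray(data.phenotype, dtype=float)
    n = data.n
    idx = data.snp_index()
    W = build_confounder_factor(data, W_ids, snp_set, exclusion_cm, X)
    Xfac = W.factor / np.sqrt(W.scale)
    F = np.ones((n, 1))
    null_fit = fit_two_kernel(y, F, W, KernelFactor.empty(n), tau_fixed=0.0)
    tester = _GlsTester(Xfac, null_fit.delta)

    cols = {s: X[:, idx[s]] for s in snp_set.snp_ids if s in idx}
    out = []
    for sid in snp_set.snp_ids:
        if sid not in cols:
            continue
        x = cols[sid]
        G_marg = np.hstack([F, x[:, None]])
        beta_m, p_m = tester.t_test(y, G_marg, 1)
        others = [cols[o] for o in snp_set.snp_ids if o != sid and o in cols]
        collinear = False
        if others:
            O = np.column_stack(others)
            G_full = np.hstack([F, O, x[:, None]])
            # drop conditioning columns that leave the design rank-deficient
            keep = []
            base = F.copy()
            for c in range(O.shape[1]):
                cand = np.hstack([base, O[:, c][:, None]])
                sv = np.linalg.svd(cand, compute_uv=False)
                if sv[-1] > 1e-8 * sv[0]:
                    base = cand
                    keep.append(c)
            G_full = np.hstack([base, x[:, None]])
            sv = np.linalg.svd(G_full, compute_uv=False)
            if sv[-1] <= 1e-8 * sv[0]:
                collinear = True
                beta_c, p_c = 0.0, 1.0
            else:
                beta_c, p_c = tester.t_test(y, G_full, G_full.shape[1] - 1)
        else:
            beta_c, p_c = beta_m, p_m
        out.append({"snp_id": sid, "beta_marginal": beta_m, "p_marginal": p_m,
                    "beta_conditional": beta_c, "p_conditional": p_c,
                    "collinear": collinear})
    return out


def setsize_correlation(results: list[SetTestResult]):
    """Pearson correlation of log10(P) with set size over results with P < 1.

    Unity P-values (the zero-degree-of-freedom boundary component) are
    excluded, as they would violate the correlation test's assumptions.
    Returns ``(r, p_value, degenerate_flag)``.
    """
    pts = [(r.n_snps_tested, np.log10(r.p_value)) for r in results
           if r.p_value < 1.0]
    if len(pts) < 3:
        return np.nan, np.nan, True
    sizes, logp = map(np.asarray, zip(*pts))
    if np.ptp(sizes) == 0 or np.ptp(logp) == 0:
        return np.nan, np.nan, True
    r, p = stats.pearsonr(sizes, logp)
    return float(r), float(p), False


def qq_data(p_values, n_grid: int | None = None):
    """(expected, observed) -log10 P pairs with a 99% beta envelope.

    Rows are sorted by expected value; the envelope columns give the
    pointwise 99% interval of the i-th order statistic under uniformity.
    """
    p = np.sort(np.asarray(p_values, dtype=float))
    m = p.size
    ranks = np.arange(1, m + 1)
    expected = ranks / (m + 1.0)
    lo = stats.beta.ppf(0.005, ranks, m - ranks + 1)
    hi = stats.beta.ppf(0.995, ranks, m - ranks + 1)
    return np.column_stack([-np.log10(expected), -np.log10(p),
                            -np.log10(hi), -np.log10(lo)])
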