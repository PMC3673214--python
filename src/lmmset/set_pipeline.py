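"""End-to-end set-association testing with confounder correction.

The procedure for one run:

1. rank all SNPs by univariate linear-regression P-value and keep the top k
   as confounder SNPs (k chosen by cross-validated predictive likelihood when
   ``k_confounder="auto"``);
2. for each tested set, remove from the confounder list any SNP that is in
   the set or within ``exclusion_cm`` centimorgans of a set SNP on the same
   chromosome (proximal contamination would absorb the signal being tested);
3. generate null LRT statistics by permuting individuals *within the test-set
   genotypes only* - the same few permutations reused for every set - leaving
   phenotype, covariates and confounder SNPs intact so the confounding
   structure survives under the null;
4. estimate the zero-mass pi of the null mixture as the fraction of null
   fits with tau-hat = 0, and fit the scaled chi-square tail to the top
   decile of null statistics;
5. compute the real (unpermuted) LRT statistic for every set;
6. convert statistics to P-values with the fitted null and apply a
   Bonferroni threshold of alpha / #sets.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .genio import EmptyDataError, GenotypeData, SnpSet, encode_and_impute, \
    minor_allele_frequency
from .lmm_core import (KernelFactor, TwoKernelWorkspace, fit_two_kernel,
                       lrt_statistic)
from .null_mixture import NullMixture, estimate_pi, fit_tail, mixture_pvalue

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Knobs of one set-test run (defaults follow the method's prescription)."""

    n_permutations: int = 10
    exclusion_cm: float = 2.0
    tail_fraction: float = 0.1
    alpha: float = 0.05
    seed: int = 0
    k_confounder: int | str = "auto"

    def __post_init__(self):
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.exclusion_cm < 0:
            raise ValueError("exclusion_cm must be >= 0")
        if not 0.0 < self.tail_fraction <= 1.0:
            raise ValueError("tail_fraction must be in (0, 1]")


@dataclass
class SetTestResult:
    set_id: str
    n_snps_tested: int
    tau_hat: float
    lrt: float
    p_value: float
    degenerate: bool = False
    boundary: bool = False

    def __post_init__(self):
        if self.lrt == 0.0 and self.p_value != 1.0:
            raise ValueError("zero statistic must carry P = 1")


@dataclass
class SetTestRun:
    results: list[SetTestResult]
    mixture: NullMixture
    metadata: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Confounder-SNP selection
# ---------------------------------------------------------------------------

def univariate_linreg_pvalues(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Two-sided t-test P-value of each column of X regressed on y (with
    intercept), vectorized through the sample correlation."""
    n = len(y)
    yc = y - y.mean()
    sy = yc.std()
    Xc = X - X.mean(axis=0)
    sx = Xc.std(axis=0)
    ok = (sx > 0) & (sy > 0)
    r = np.zeros(X.shape[1])
    r[ok] = (Xc[:, ok].T @ yc) / (n * sx[ok] * sy)
    r = np.clip(r, -1 + 1e-15, 1 - 1e-15)
    t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[~ok] = 1.0
    return p


_K_GRID_BASE = (10, 20, 50, 100, 200, 500, 1000, 2000, 5000, 10000)


def _fold_predictive_loglik(Ztr: np.ndarray, Zte: np.ndarray, ytr, yte) -> float:
    """Out-of-sample Gaussian predictive log-density of the single-kernel LMM
    built on the standardized training SNP columns ``Ztr``."""
    k = Ztr.shape[1]
    Ftr = np.ones((len(ytr), 1))
    Wtr = KernelFactor(factor=Ztr, scale=float(k))
    fit = fit_two_kernel(ytr, Ftr, Wtr, KernelFactor.empty(len(ytr)),
                         tau_fixed=0.0)
    delta, sg2, beta = fit.delta, fit.sigma_g2, float(fit.beta[0])
    Xtr = Ztr / np.sqrt(k)
    Xte = Zte / np.sqrt(k)
    U, d, Vt = np.linalg.svd(Xtr, full_matrices=False)
    keep = d > (d.max() * 1e-12 if d.size else 0)
    U, d, Vr = U[:, keep], d[keep], Vt[keep].T
    resid = ytr - beta
    r1 = U.T @ resid
    alpha = U @ (r1 / (d**2 + delta)) + (resid - U @ r1) / delta
    mu = beta + Xte @ (Xtr.T @ alpha)
    # conditional covariance factor: Xte (I - M) Xte' + delta I, with
    # M = Vr diag(d^2/(d^2+delta)) Vr'
    shrink = 1.0 - np.sqrt(delta / (d**2 + delta))
    Cte = Xte - (Xte @ Vr) * shrink[None, :] @ Vr.T
    nte = len(yte)
    U2, d2, _ = np.linalg.svd(Cte, full_matrices=False)
    keep2 = d2 > (d2.max() * 1e-12 if d2.size else 0)
    U2, S2 = U2[:, keep2], d2[keep2] ** 2
    e = yte - mu
    e1 = U2.T @ e
    quad = float(e1**2 @ (1.0 / (S2 + delta))) + \
        max(float(e @ e - e1 @ e1), 0.0) / delta
    logdet = float(np.log(S2 + delta).sum()) + (nte - S2.size) * np.log(delta)
    return -0.5 * (nte * np.log(2 * np.pi * sg2) + logdet + quad / sg2)


def select_confounder_snps(data: GenotypeData, k: int | str = "auto",
                           encoded: np.ndarray | None = None,
                           cv_folds: int = 5) -> list[str]:
    """Rank SNPs by univariate linear-regression P-value; return the top k.

    With ``k="auto"`` the count is chosen from a coarse grid (capped at n/2
    and at the SNP count) by maximizing the out-of-sample predictive
    log-likelihood of the single-kernel LMM under ``cv_folds``-fold
    cross-validation.  The ranking is recomputed inside each training fold
    (using the full-data ranking would leak the held-out phenotype into the
    choice of SNPs and systematically favour large k); among grid values
    within two log-likelihood units of the best, the smallest wins.
    """
    X = encode_and_impute(data) if encoded is None else encoded
    y = np.asarray(data.phenotype, dtype=float)
    p = univariate_linreg_pvalues(X, y)
    order = np.argsort(p, kind="stable")
    ids = data.snp_ids

    if k != "auto":
        k = int(k)
        if not 1 <= k <= data.s:
            raise ValueError(f"k={k} outside [1, {data.s}]")
        return [ids[j] for j in order[:k]]

    cap = min(data.s, data.n // 2)
    grid = [g for g in _K_GRID_BASE if g <= cap]
    if not grid:
        grid = [max(cap, 1)]
    if data.n < 4 * cv_folds:
        raise ValueError(
            f"n={data.n} too small for {cv_folds}-fold selection; "
            "pass an explicit k_confounder"
        )
    rng = np.random.default_rng(12345)  # deterministic fold assignment
    perm = rng.permutation(data.n)
    folds = np.array_split(perm, cv_folds)
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    Zall = (X - mu) / sd
    scores = np.zeros(len(grid))
    for test_idx in folds:
        train = np.ones(data.n, dtype=bool)
        train[test_idx] = False
        order_tr = np.argsort(univariate_linreg_pvalues(X[train], y[train]),
                              kind="stable")
        for gi, g in enumerate(grid):
            cols = order_tr[:g]
            scores[gi] += _fold_predictive_loglik(
                Zall[np.ix_(train, cols)], Zall[np.ix_(test_idx, cols)],
                y[train], y[test_idx])
    # parsimony: smallest k within two log-likelihood units of the best
    best_val = scores.max()
    best = min(gi for gi in range(len(grid)) if scores[gi] >= best_val - 2.0)
    logger.info("auto confounder selection: k=%d (CV loglik %s over grid %s)",
                grid[best], [f"{s:.1f}" for s in scores], grid)
    return [ids[j] for j in order[: grid[best]]]


def build_confounder_factor(data: GenotypeData, selected_ids, test_set: SnpSet,
                            exclusion_cm: float = 2.0,
                            encoded: np.ndarray | None = None) -> KernelFactor:
    """Confounder kernel factor for one tested set.

    Removes from the selected SNPs any SNP belonging to the test set and any
    SNP on the same chromosome within ``exclusion_cm`` centimorgans of a
    test-set SNP, then standardizes the remaining columns.
    """
    X = encode_and_impute(data) if encoded is None else encoded
    idx = data.snp_index()
    cm = data.map_cm()
    test_ids = set(test_set.snp_ids)
    test_pos = [(data.snps[idx[s]].chromosome, cm[idx[s]])
                for s in test_set.snp_ids if s in idx]
    kept = []
    for sid in selected_ids:
        j = idx[sid]
        if sid in test_ids:
            continue
        chrom, pos = data.snps[j].chromosome, cm[j]
        if any(c == chrom and abs(pos - p) <= exclusion_cm for c, p in test_pos):
            continue
        kept.append(j)
    if not kept:
        return KernelFactor.empty(data.n)
    return KernelFactor.from_encoded(X[:, kept])


def permute_set_genotypes(V_columns: np.ndarray, permutation: np.ndarray) -> np.ndarray:
    """Apply one row permutation identically to every column of the set."""
    permutation = np.asarray(permutation)
    if permutation.shape[0] != V_columns.shape[0] or \
            not np.array_equal(np.sort(permutation), np.arange(V_columns.shape[0])):
        raise ValueError("not a permutation of the rows")
    return V_columns[permutation]


def draw_permutations(n: int, n_permutations: int, seed: int) -> list[np.ndarray]:
    """The shared permutations: drawn once from the master seed, reused for
    every set."""
    rng = np.random.default_rng(seed)
    return [rng.permutation(n) for _ in range(n_permutations)]


# ---------------------------------------------------------------------------
# The pipeline
# ---------------------------------------------------------------------------

def _design(data: GenotypeData, covariates):
    if data.phenotype is None:
        raise ValueError("dataset carries no phenotype")
    y = np.asarray(data.phenotype, dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("phenotype is constant")
    cols = [np.ones((data.n, 1))]
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        cols.append(C)
    return y, np.hstack(cols)


def _rare_binary_warning(data: GenotypeData, sets, y):
    vals = set(np.unique(y))
    if not vals <= {0.0, 1.0}:
        return
    maf = minor_allele_frequency(data.dosage)
    idx = data.snp_index()
    rare = {s.set_id for s in sets
            if any(maf[idx[sid]] < 0.01 for sid in s.snp_ids if sid in idx)}
    if rare:
        warnings.warn(
            f"binary phenotype treated as 0/1 quantitative while {len(rare)} "
            "sets contain SNPs with MAF < 0.01; linear-model statistics can "
            "be inflated for rare variants", stacklevel=3)


class _SetFitter:
    """Holds per-set kernels and produces null/alt/permutation statistics."""

    def __init__(self, data, encoded, y, F, selected_ids, config: RunConfig):
        self.data, self.encoded = data, encoded
        self.y, self.F = y, F
        self.selected_ids = selected_ids
        self.config = config
        self.idx = data.snp_index()
        self.n_perm_fits = 0

    def prepare(self, snp_set: SnpSet):
        cols = [self.idx[s] for s in snp_set.snp_ids if s in self.idx]
        V = KernelFactor.from_encoded(self.encoded[:, cols]) if cols \
            else KernelFactor.empty(self.data.n)
        W = build_confounder_factor(self.data, self.selected_ids, snp_set,
                                    self.config.exclusion_cm, self.encoded)
        if V.k == 0:
            return None  # degenerate set
        ws = TwoKernelWorkspace(self.y, self.F, W, V)
        null_fit = fit_two_kernel(workspace=ws, tau_fixed=0.0)
        return ws, null_fit, len(cols)

    def alt_stat(self, ws, null_fit):
        alt = fit_two_kernel(workspace=ws)
        return lrt_statistic(alt, null_fit), alt

    def perm_stats(self, ws, null_fit, perms):
        out = []
        for perm in perms:
            ws.replace_test_factor(perm)
            self.n_perm_fits += 1
            out.append(self.alt_stat(ws, null_fit)[0])
        ws.restore_test_factor()
        return out


def permutation_statistics(data: GenotypeData, sets, config: RunConfig,
                           n_rounds: int | None = None, covariates=None,
                           selected_ids=None,
                           share_across_sets: bool = True) -> np.ndarray:
    """Null LRT statistics from within-set permutations.

    Returns an array of shape (n_rounds, n_sets); degenerate sets yield NaN
    columns.  With ``share_across_sets`` (the pipeline's convention) the r-th
    permutation is identical for every set; the type-I-error harness instead
    draws independent permutations per set for its held-out evaluation
    statistics, so that a single unlucky permutation cannot shift every
    set's statistic at once.
    """
    y, F = _design(data, covariates)
    encoded = encode_and_impute(data)
    if selected_ids is None:
        selected_ids = select_confounder_snps(data, config.k_confounder,
                                              encoded=encoded)
    n_rounds = config.n_permutations if n_rounds is None else n_rounds
    shared = draw_permutations(data.n, n_rounds, config.seed) \
        if share_across_sets else None
    fitter = _SetFitter(data, encoded, y, F, selected_ids, config)
    stats_out = np.full((n_rounds, len(sets)), np.nan)
    for j, snp_set in enumerate(sets):
        prep = fitter.prepare(snp_set)
        if prep is None:
            continue
        ws, null_fit, _ = prep
        if shared is not None:
            perms = shared
        else:
            rng = np.random.default_rng([config.seed, 7, j])
            perms = [rng.permutation(data.n) for _ in range(n_rounds)]
        stats_out[:, j] = fitter.perm_stats(ws, null_fit, perms)
    return stats_out


def run_set_tests(data: GenotypeData, sets, config: RunConfig,
                  covariates=None, selected_ids=None,
                  uncorrected: bool = False) -> SetTestRun:
    """Execute the full six-step set-test procedure.

    Deterministic given ``config.seed``.  Results come back sorted by
    P-value (ties broken by set id); the metadata dict carries the fitted
    mixture, the Bonferroni threshold and the exact permutation fit count.
    """
    if not sets:
        raise ValueError("no sets to test")
    y, F = _design(data, covariates)
    _rare_binary_warning(data, sets, y)
    encoded = encode_and_impute(data)
    if uncorrected:
        selected_ids = []
    elif selected_ids is None:
        selected_ids = select_confounder_snps(data, config.k_confounder,
                                              encoded=encoded)
    perms = draw_permutations(data.n, config.n_permutations, config.seed)
    fitter = _SetFitter(data, encoded, y, F, selected_ids, config)

    prepared = {}
    null_stats = []
    for snp_set in sets:
        prep = fitter.prepare(snp_set)
        prepared[snp_set.set_id] = (snp_set, prep)
        if prep is not None:
            ws, null_fit, _ = prep
            null_stats.extend(fitter.perm_stats(ws, null_fit, perms))
    if uncorrected and all(p is None for _, p in prepared.values()):
        raise EmptyDataError(
            "uncorrected run with no usable test kernels: every set is "
            "degenerate and there is no confounder kernel")
    null_stats = np.asarray(null_stats)
    n_nonzero = int((null_stats > 0).sum())
    if n_nonzero < 20:
        raise EmptyDataError(
            f"only {n_nonzero} non-zero permutation statistics; raise "
            "n_permutations or test more sets")
    pi = estimate_pi(null_stats)
    mixture = fit_tail(null_stats, pi, tail_fraction=config.tail_fraction)

    results = []
    for snp_set, prep in prepared.values():
        if prep is None:
            results.append(SetTestResult(
                set_id=snp_set.set_id, n_snps_tested=0, tau_hat=0.0,
                lrt=0.0, p_value=1.0, degenerate=True, boundary=True))
            continue
        ws, null_fit, n_snps = prep
        stat, alt = fitter.alt_stat(ws, null_fit)
        results.append(SetTestResult(
            set_id=snp_set.set_id, n_snps_tested=n_snps, tau_hat=alt.tau,
            lrt=stat, p_value=float(mixture_pvalue(stat, mixture)),
            boundary=(alt.tau == 0.0)))
    results.sort(key=lambda r: (r.p_value, r.set_id))
    metadata = {
        "pi": mixture.pi, "a": mixture.a, "d": mixture.d,
        "seed": config.seed,
        "n_sets": len(sets),
        "n_permutations": config.n_permutations,
        "n_permutation_fits": fitter.n_perm_fits,
        "n_confounder_snps": len(selected_ids),
        "bonferroni_threshold": config.alpha / len(sets),
        "uncorrected": uncorrected,
    }
    return SetTestRun(results=results, mixture=mixture, metadata=metadata)


def run_score_tests(data: GenotypeData, sets, config: RunConfig,
                    covariates=None, selected_ids=None):
    """Variance-component score test per set on the same per-set null fits
    as the LRT pipeline (same selection, same exclusion)."""
    from .score_test import score_test_set

    y, F = _design(data, covariates)
    encoded = encode_and_impute(data)
    if selected_ids is None:
        selected_ids = select_confounder_snps(data, config.k_confounder,
                                              encoded=encoded)
    fitter = _SetFitter(data, encoded, y, F, selected_ids, config)
    out = []
    for snp_set in sets:
        prep = fitter.prepare(snp_set)
        if prep is None:
            from .score_test import ScoreResult
            out.append(ScoreResult(set_id=snp_set.set_id, q_statistic=0.0,
                                   p_value=1.0, method="davies"))
            continue
        ws, null_fit, _ = prep
        out.append(score_test_set(snp_set.set_id, y, F, null_fit, ws.W, ws.V))
    out.sort(key=lambda r: (r.p_value, r.set_id))
    return out


def run_uncorrected_set_tests(data: GenotypeData, sets, config: RunConfig,
                              covariates=None) -> SetTestRun:
    """Same pipeline with the confounder kernel omitted (null model is fixed
    effects plus residual only); used for the comparison experiments."""
    return run_set_tests(data, sets, config, covariates=covariates,
                         uncorrected=True)


def write_results_tsv(run: SetTestRun, path) -> None:
    """Results table with a commented header carrying the fitted null and the
    run configuration.  Byte-identical across reruns of the same inputs."""
    md = run.metadata
    with open(path, "w") as fh:
        fh.write(f"# null_mixture pi={md['pi']:.10g} a={md['a']:.10g} "
                 f"d={md['d']:.10g}\n")
        fh.write(f"# seed={md['seed']} n_permutations={md['n_permutations']} "
                 f"n_confounder_snps={md['n_confounder_snps']} "
                 f"uncorrected={int(md['uncorrected'])}\n")
        fh.write(f"# bonferroni_threshold={md['bonferroni_threshold']:.10g}\n")
        fh.write("set_id\tn_snps\ttau_hat\tlrt\tp_value\t"
                 "p_bonferroni_significant\tflags\n")
        for r in run.results:
            flags = ",".join(f for f, on in
                             [("degenerate", r.degenerate),
                              ("boundary", r.boundary)] if on) or "-"
            sig = int(r.p_value <= md["bonferroni_threshold"])
            fh.write(f"{r.set_id}\t{r.n_snps_tested}\t{r.tau_hat:.6g}\t"
                     f"{r.lrt:.6g}\t{r.p_value:.6g}\t{sig}\t{flags}\n")
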