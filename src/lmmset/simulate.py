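"""Synthetic structured cohorts and the calibration/power experiment harness.

Genotypes follow a Balding-Nichols model: an ancestral minor-allele frequency
is drawn per SNP, per-population frequencies are drawn from the
Fst-parameterized beta around it, and individuals are assigned to populations
in blocks of relatives (two founders plus Mendelian offspring).  This
produces the two confounders the set test is built to absorb - population
structure and family relatedness - in a self-contained, seed-deterministic
generator.

Phenotypes come from the generative linear mixed model itself:

    y = u_conf + u_set + e,   u_conf ~ N(0, s2_confound * K_W),
                              u_set  ~ N(0, s2_set * K_causal),
                              e      ~ N(0, s2_e * I)

drawn through the low-rank kernel factors (never an n x n matrix).  Causal
SNPs are kept at least 2 cM away from the confounder SNPs so that tested
sets are unambiguously true positives.

The default variance shares (confounding 0.3 / residual 0.7 under the null)
and the default structure (four populations at Fst 0.1, four-member family
blocks) give an uncorrected univariate inflation lambda of roughly 1.2-1.4
at n = 2000 - the regime of a strongly confounded case-control cohort.
Set sizes are drawn lognormal with mean 11 and standard deviation 24
(clipped below at the configured minimum), echoing gene-set size
distributions on dense SNP panels.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .genio import GenotypeData, SnpRecord, SnpSet
from .lmm_core import KernelFactor, fit_two_kernel
from .null_mixture import (chibar_pvalue, estimate_pi, fit_mixture_ml,
                           fit_tail, mixture_pvalue)
from .score_test import score_test_set
from .set_pipeline import RunConfig, _SetFitter, _design, draw_permutations
from .genio import encode_and_impute

logger = logging.getLogger(__name__)


@dataclass
class SimConfig:
    """Generator settings: cohort layout, structure, and variance shares."""

    n_individuals: int = 1000
    n_snps: int = 2000
    n_chromosomes: int = 5
    cm_spacing: float = 0.25
    n_sets: int = 100
    set_size_mean: float = 11.0
    set_size_sd: float = 24.0
    set_size_min: int = 2
    set_size_fixed: int | None = None
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_populations: int = 4
    fst: float = 0.1
    family_block_size: int = 4
    sigma_confound2: float = 0.3
    sigma_set2: float = 0.0
    sigma_e2: float = 0.7
    seed: int = 0

    def __post_init__(self):
        if min(self.sigma_confound2, self.sigma_set2, self.sigma_e2) < 0:
            raise ValueError("variance shares must be >= 0")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie inside (0, 0.5]")


def simulate_genotypes(config: SimConfig) -> GenotypeData:
    """Draw a structured cohort of 0/1/2 genotypes (no missing calls).

    SNPs are laid out with uniform ``cm_spacing`` along each chromosome
    (1 cM = 1 Mb physically), so centimorgan-based exclusion and windowing
    are exercised downstream.
    """
    rng = np.random.default_rng(config.seed)
    n, s = config.n_individuals, config.n_snps
    npop, fst = config.n_populations, config.fst

    p_anc = rng.uniform(*config.maf_range, size=s)
    if fst > 0 and npop > 1:
        a = p_anc * (1 - fst) / fst
        b = (1 - p_anc) * (1 - fst) / fst
        p_pop = rng.beta(a, b, size=(npop, s))
        p_pop = np.clip(p_pop, 1e-4, 1 - 1e-4)
    else:
        p_pop = np.tile(p_anc, (npop, 1))

    pop_of = np.repeat(np.arange(npop), math.ceil(n / npop))[:n]
    block = max(config.family_block_size, 1)
    dosage = np.empty((n, s), dtype=float)
    i = 0
    while i < n:
        members = min(block, n - i)
        # all block members share a population
        freq = p_pop[pop_of[i]]
        founders = rng.binomial(2, freq, size=(min(members, 2), s)).astype(float)
        dosage[i : i + founders.shape[0]] = founders
        for c in range(2, members):
            # Mendelian transmission: each parent passes one allele
            alleles = [rng.binomial(1, founders[par] / 2.0) for par in (0, 1)]
            dosage[i + c] = alleles[0] + alleles[1]
        i += members

    per_chrom = math.ceil(s / config.n_chromosomes)
    snps = []
    for j in range(s):
        chrom = j // per_chrom + 1
        offset = j % per_chrom
        cm = offset * config.cm_spacing
        snps.append(SnpRecord(
            snp_id=f"rs{j}", chromosome=str(chrom), position_bp=int(cm * 1e6),
            position_cm=cm, allele_minor="A", allele_major="B"))
    individuals = [(f"F{i // block}", f"I{i}") for i in range(n)]
    return GenotypeData(individuals=individuals, snps=snps, dosage=dosage,
                        phenotype=None)


def _kernel_draw(Z: np.ndarray, var: float, rng) -> np.ndarray:
    """One draw of u ~ N(0, var * Z Z' / k) through the factor."""
    k = Z.shape[1]
    if var == 0.0 or k == 0:
        return np.zeros(Z.shape[0])
    z = rng.standard_normal(k)
    return math.sqrt(var / k) * (Z @ z)


def _standardize(X: np.ndarray) -> np.ndarray:
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def simulate_phenotype(data: GenotypeData, W_ids, causal_ids,
                       config: SimConfig, rng=None) -> np.ndarray:
    """Generative-model phenotype: confounding + set signal + noise.

    Causal SNPs within 2 cM of any confounder SNP are silently excluded so
    the signal cannot leak into the confounder kernel.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    idx = data.snp_index()
    cm = data.map_cm()
    X = encode_and_impute(data)

    w_idx = [idx[s] for s in W_ids]
    w_pos = [(data.snps[j].chromosome, cm[j]) for j in w_idx]
    c_idx = []
    for sid in causal_ids:
        j = idx[sid]
        chrom, pos = data.snps[j].chromosome, cm[j]
        if any(c == chrom and abs(pos - p) <= 2.0 for c, p in w_pos):
            continue
        c_idx.append(j)

    y = np.zeros(data.n)
    y += _kernel_draw(_standardize(X[:, w_idx]) if w_idx else np.zeros((data.n, 0)),
                      config.sigma_confound2, rng)
    y += _kernel_draw(_standardize(X[:, c_idx]) if c_idx else np.zeros((data.n, 0)),
                      config.sigma_set2, rng)
    y += math.sqrt(config.sigma_e2) * rng.standard_normal(data.n)
    return y


def _draw_set_sizes(config: SimConfig, n_sets: int, rng) -> np.ndarray:
    if config.set_size_fixed is not None:
        return np.full(n_sets, config.set_size_fixed, dtype=int)
    # lognormal matched to the requested mean and sd
    cv2 = (config.set_size_sd / config.set_size_mean) ** 2
    sigma2 = math.log1p(cv2)
    mu = math.log(config.set_size_mean) - sigma2 / 2.0
    sizes = np.round(rng.lognormal(mu, math.sqrt(sigma2), size=n_sets))
    return np.maximum(sizes, config.set_size_min).astype(int)


def make_sets(data: GenotypeData, config: SimConfig, rng=None,
              avoid_ids=(), min_gap_cm: float = 2.0) -> list[SnpSet]:
    """Draw non-overlapping contiguous SNP windows as test sets.

    SNPs in ``avoid_ids`` - and anything within ``min_gap_cm`` of them - are
    not eligible, mirroring the rule that keeps true-positive sets clear of
    the confounder kernel.
    """
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    idx = data.snp_index()
    cm = data.map_cm()
    avoid = set()
    av_pos = [(data.snps[idx[s]].chromosome, cm[idx[s]])
              for s in avoid_ids if s in idx]
    for j, r in enumerate(data.snps):
        if any(c == r.chromosome and abs(cm[j] - p) <= min_gap_cm
               for c, p in av_pos):
            avoid.add(j)
    eligible = [j for j in range(data.s) if j not in avoid]
    sizes = _draw_set_sizes(config, config.n_sets, rng)
    used = set()
    out = []
    for t, size in enumerate(sizes):
        placed = False
        for _ in range(200):
            start = rng.integers(0, max(len(eligible) - size, 1))
            members = eligible[start : start + size]
            chroms = {data.snps[j].chromosome for j in members}
            if len(members) < max(size, 1) or len(chroms) > 1 or \
                    used.intersection(members):
                continue
            used.update(members)
            out.append(SnpSet(
                set_id=f"set{t:04d}",
                snp_ids=tuple(data.snps[j].snp_id for j in members)))
            placed = True
            break
        if not placed:
            logger.debug("could not place set %d of size %d", t, size)
    if not out:
        raise ValueError("no sets could be placed; dataset too small")
    return out


# ---------------------------------------------------------------------------
# Experiments
# ---------------------------------------------------------------------------

def binomial_ci99(rate_n: int, alpha: float) -> tuple[float, float]:
    """Exact (Clopper-Pearson) 99% interval for a nominal rate ``alpha``."""
    lo = stats.binom.ppf(0.005, rate_n, alpha) / rate_n
    hi = stats.binom.ppf(0.995, rate_n, alpha) / rate_n
    return float(lo), float(hi)


def typeI_experiment(config: SimConfig, alphas=(0.05, 0.01), n_fit_rounds=10,
                     n_eval_rounds=10, k_confounder=50, run_config=None):
    """Estimate the empirical type-I error of the full pipeline.

    Null statistics come from within-set permutations on a structured,
    confounded cohort with no set signal.  ``n_fit_rounds`` permutation
    rounds feed the null-mixture fit (exactly as the pipeline would use
    them); ``n_eval_rounds`` further rounds provide held-out null statistics
    whose fitted P-values are scored against each nominal level.  The
    chi-bar-square comparator and the non-truncated ML comparator are scored
    on the same held-out statistics.

    Returns a list of per-alpha dict rows plus the fitted mixture.
    """
    cfg = replace(config, sigma_set2=0.0)
    data = simulate_genotypes(cfg)
    rng = np.random.default_rng(cfg.seed + 1)
    # confounding driven by a spread-out batch of background SNPs
    bg = [data.snps[j].snp_id for j in
          rng.choice(data.s, size=min(100, data.s // 4), replace=False)]
    data.phenotype = simulate_phenotype(data, bg, [], cfg, rng)
    sets = make_sets(data, cfg, rng)
    rc = run_config or RunConfig(seed=cfg.seed, k_confounder=k_confounder)

    # the mixture is fitted exactly as the pipeline fits it: a few
    # permutations shared across all sets
    fit_stats = _permutation_rounds(data, sets, rc, n_fit_rounds,
                                    share_across_sets=True).ravel()
    # held-out null statistics use independent permutations per set, so the
    # empirical rate is not dominated by a handful of shared draws
    eval_stats = _permutation_rounds(data, sets, rc, n_eval_rounds,
                                     share_across_sets=False).ravel()
    fit_stats = fit_stats[~np.isnan(fit_stats)]
    eval_stats = eval_stats[~np.isnan(eval_stats)]

    pi = estimate_pi(fit_stats)
    mixture = fit_tail(fit_stats, pi, tail_fraction=rc.tail_fraction)
    ml_mixture = fit_mixture_ml(fit_stats)

    p_mix = mixture_pvalue(eval_stats, mixture)
    p_chibar = chibar_pvalue(eval_stats)
    p_ml = mixture_pvalue(eval_stats, ml_mixture)

    rows = []
    m = eval_stats.size
    for alpha in alphas:
        lo, hi = binomial_ci99(m, alpha)
        rate = float((p_mix <= alpha).mean())
        rows.append({
            "alpha": alpha, "n_null": m, "rate": rate,
            "ci99_low": lo, "ci99_high": hi,
            "pass": bool(lo <= rate <= hi),
            "rate_chibar": float((p_chibar <= alpha).mean()),
            "rate_ml": float((p_ml <= alpha).mean()),
        })
    return rows, mixture


def _permutation_rounds(data, sets, rc: RunConfig, n_rounds,
                        share_across_sets=True) -> np.ndarray:
    from .set_pipeline import permutation_statistics
    return permutation_statistics(data, sets, rc, n_rounds=n_rounds,
                                  share_across_sets=share_across_sets)


def power_experiment(config: SimConfig, alphas=(0.05, 0.01), n_replicates=1,
                     k_confounder_gen=50, run_config=None):
    """Paired power comparison of the LRT and the score test.

    Each replicate draws a structured cohort, designates ``k_confounder_gen``
    random background SNPs as the confounder kernel of the generative model,
    places ``config.n_sets`` true sets clear of those SNPs, and generates a
    phenotype in which the union of the set SNPs carries ``sigma_set2`` of
    the variance.  Both tests run on identical per-set null fits; detections
    are counted per nominal level, and a one-sided paired sign test asks
    whether the LRT detects sets the score test misses more often than the
    reverse.
    """
    per_rep_raw = []
    pooled_nulls = []
    for rep in range(n_replicates):
        cfg = replace(config, seed=config.seed + 1000 * rep)
        data = simulate_genotypes(cfg)
        rng = np.random.default_rng(cfg.seed + 1)
        bg_idx = rng.choice(cfg.n_snps, size=min(k_confounder_gen, cfg.n_snps // 4),
                            replace=False)
        W_ids = [data.snps[j].snp_id for j in bg_idx]
        sets = make_sets(data, cfg, rng, avoid_ids=W_ids)
        causal_ids = [sid for s in sets for sid in s.snp_ids]
        data.phenotype = simulate_phenotype(data, W_ids, causal_ids, cfg, rng)
        rc = run_config or RunConfig(seed=cfg.seed)
        lrt_stats, null_stats, score_p = _paired_set_statistics(
            data, sets, rc, W_ids)
        pooled_nulls.append(null_stats)
        per_rep_raw.append((lrt_stats, score_p))

    # one null mixture from the permutation statistics of all replicates:
    # the replicates share the generating process, and pooling shrinks the
    # calibration noise that would otherwise swamp small power differences
    pooled_nulls = np.concatenate(pooled_nulls)
    mixture = fit_tail(pooled_nulls, estimate_pi(pooled_nulls))

    counts = {a: {"lrt": 0, "score": 0, "lrt_only": 0, "score_only": 0}
              for a in alphas}
    n_sets_total = 0
    per_replicate = []
    for rep, (lrt_stats, score_p) in enumerate(per_rep_raw):
        lrt_p = mixture_pvalue(lrt_stats, mixture)
        n_sets_total += len(lrt_p)
        rep_row = {"replicate": rep, "n_sets": len(lrt_p)}
        for a in alphas:
            l_hit = lrt_p <= a
            s_hit = score_p <= a
            counts[a]["lrt"] += int(l_hit.sum())
            counts[a]["score"] += int(s_hit.sum())
            counts[a]["lrt_only"] += int((l_hit & ~s_hit).sum())
            counts[a]["score_only"] += int((~l_hit & s_hit).sum())
            rep_row[f"lrt@{a}"] = int(l_hit.sum())
            rep_row[f"score@{a}"] = int(s_hit.sum())
        per_replicate.append(rep_row)

    rows = []
    for a in alphas:
        c = counts[a]
        disc = c["lrt_only"] + c["score_only"]
        sign_p = float(stats.binomtest(c["lrt_only"], disc, 0.5,
                                       alternative="greater").pvalue) \
            if disc else 1.0
        rows.append({"alpha": a, "n_sets": n_sets_total, **c,
                     "sign_test_p": sign_p})
    return rows, per_replicate


def _paired_set_statistics(data, sets, rc: RunConfig, selected_ids):
    """LRT statistics, permutation null statistics, and score P-values for
    the same sets on identical per-set null fits."""
    y, F = _design(data, None)
    encoded = encode_and_impute(data)
    perms = draw_permutations(data.n, rc.n_permutations, rc.seed)
    fitter = _SetFitter(data, encoded, y, F, selected_ids, rc)
    prepared = []
    null_stats = []
    for snp_set in sets:
        prep = fitter.prepare(snp_set)
        if prep is None:
            continue
        ws, null_fit, _ = prep
        null_stats.extend(fitter.perm_stats(ws, null_fit, perms))
        prepared.append((snp_set, ws, null_fit))
    lrt_stats, score_p = [], []
    idx = data.snp_index()
    for snp_set, ws, null_fit in prepared:
        stat, _ = fitter.alt_stat(ws, null_fit)
        lrt_stats.append(stat)
        cols = [idx[s] for s in snp_set.snp_ids if s in idx]
        V = KernelFactor.from_encoded(encoded[:, cols])
        score_p.append(score_test_set(snp_set.set_id, y, F, null_fit, ws.W, V)
                       .p_value)
    return (np.asarray(lrt_stats), np.asarray(null_stats),
            np.asarray(score_p))


def confounding_experiment(config: SimConfig, n_replicates: int = 3,
                           k_background: int = 40, run_config=None):
    """Measure how much correction buys on structured null cohorts.

    Per replicate: draw a structured cohort, generate a confounded null
    phenotype from ``k_background`` latent background SNPs, then (a) run
    uncorrected and kernel-corrected univariate scans and record the
    genomic-control lambda over the non-generator polymorphic SNPs, and
    (b) run the corrected and uncorrected set pipelines on variable-size
    sets and pool the results for the set-size / log10 P correlation.

    Lambda of a single scan is noisy because all tests share one phenotype
    draw; the returned lambdas are means over replicates.
    """
    from .diagnostics import genomic_lambda, setsize_correlation, \
        univariate_scan
    from .set_pipeline import run_set_tests, run_uncorrected_set_tests

    lam_unc, lam_corr = [], []
    pooled_corr, pooled_unc = [], []
    for rep in range(n_replicates):
        cfg = replace(config, sigma_set2=0.0, seed=config.seed + 101 * rep)
        data = simulate_genotypes(cfg)
        rng = np.random.default_rng(cfg.seed + 1)
        bg_idx = rng.choice(cfg.n_snps, size=k_background, replace=False)
        bg = [data.snps[j].snp_id for j in bg_idx]
        data.phenotype = simulate_phenotype(data, bg, [], cfg, rng)
        null_ids = {data.snps[j].snp_id for j in range(data.s)
                    if j not in set(bg_idx)}

        scan_lin = univariate_scan(data, model="linreg")
        scan_lmm = univariate_scan(data, model="lmm", W_ids=bg)
        lam_unc.append(genomic_lambda(
            [r.p_value for r in scan_lin if r.snp_id in null_ids
             and r.p_value < 1.0]))
        lam_corr.append(genomic_lambda(
            [r.p_value for r in scan_lmm if r.snp_id in null_ids
             and r.p_value < 1.0]))

        sets = make_sets(data, cfg, rng)
        rc = run_config or RunConfig(seed=cfg.seed, k_confounder=k_background)
        pooled_corr.extend(
            run_set_tests(data, sets, rc, selected_ids=bg).results)
        pooled_unc.extend(
            run_uncorrected_set_tests(data, sets, rc).results)

    r_c, p_c, deg_c = setsize_correlation(pooled_corr)
    r_u, p_u, deg_u = setsize_correlation(pooled_unc)
    return {
        "lambda_uncorrected": float(np.mean(lam_unc)),
        "lambda_corrected": float(np.mean(lam_corr)),
        "setsize_r_corrected": r_c, "setsize_p_corrected": p_c,
        "setsize_r_uncorrected": r_u, "setsize_p_uncorrected": p_u,
        "n_sets_pooled": len(pooled_unc),
    }


def tau_recovery(config: SimConfig, tau_true: float, n_replicates: int = 50,
                 k_w: int = 50, k_v: int = 10, delta_true: float = 1.0):
    """Fit the two-kernel model to data generated at a known tau.

    Returns the per-replicate tau-hat estimates.  The generative covariance
    is sigma_g2 [(1-tau) K_w + tau K_v] + sigma_e2 I with sigma_g2 = 1 and
    sigma_e2 = delta_true.
    """
    estimates = []
    for rep in range(n_replicates):
        rng = np.random.default_rng(config.seed + 7919 * rep)
        n = config.n_individuals
        Zw = rng.standard_normal((n, k_w))
        Zv = rng.standard_normal((n, k_v))
        W = KernelFactor(factor=Zw, scale=float(k_w))
        V = KernelFactor(factor=Zv, scale=float(k_v))
        y = _kernel_draw(Zw, 1.0 - tau_true, rng) + \
            _kernel_draw(Zv, tau_true, rng) + \
            math.sqrt(delta_true) * rng.standard_normal(n)
        F = np.ones((n, 1))
        fit = fit_two_kernel(y, F, W, V)
        estimates.append(fit.tau)
    return np.asarray(estimates)
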