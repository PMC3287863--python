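"""Weighted combination of trio-conditional and case-control effect estimates.

Two arms estimate the same per-allele genetic effect:

* a conditional-on-parental-genotypes (CPG) likelihood over case trios,
  giving a log relative risk ``beta_CPG`` — robust to population structure
  because it conditions on the parents;
* a logistic regression of affection on allele count over the case-control
  subsample (trio offspring plus unrelated controls), giving a log odds
  ratio ``beta_CC``.

A Wald homogeneity test checks that the two estimates agree; if it does not
reject, they are pooled by weighted least squares,

    beta_c = W1 * beta_CPG + W2 * beta_CC,  (W1, W2) = S^-1 1 / (1' S^-1 1),

with S the 2x2 covariance of the estimates, whose off-diagonal accounts for
the trio probands shared by both arms via a stacked influence-function
(sandwich) estimate.  The combined Wald statistic is referred to chi2(1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .core import (
    AssociationResult,
    CCRule,
    CombinedSample,
    Status,
    build_cc_subsample,
    founder_maf,
    trio_usable_mask,
)

#: divergence guard for both arms: |beta| above this is treated as separation
BETA_CAP = 10.0
NEWTON_TOL = 1e-8
NEWTON_MAX_ITER = 50


@dataclass
class CPGFit:
    beta_hat: float
    se: float
    loglik: float
    n_informative_trios: int
    status: Status = Status.OK


@dataclass
class CCFit:
    beta_hat: float
    se: float
    n_cases: int
    n_controls: int
    status: Status = Status.OK
    # per-unit slope influence values, aligned with the subsample rows
    influence: np.ndarray | None = None


@dataclass
class CombinedEstimate:
    beta_combined: float
    se_combined: float
    w1: float
    w2: float
    homogeneity_stat: float
    homogeneity_p: float
    cross_cov: float
    homogeneity_rejected: bool = False


def transmission_probs(g_f: np.ndarray, g_m: np.ndarray) -> np.ndarray:
    """Mendelian offspring distribution tau(g' | g_f, g_m), trios x {0,1,2}.

    A parent with genotype g transmits the minor allele with probability g/2;
    the two transmissions are independent.
    """
    pf = np.asarray(g_f, dtype=float) / 2.0
    pm = np.asarray(g_m, dtype=float) / 2.0
    tau = np.empty((pf.size, 3))
    tau[:, 0] = (1 - pf) * (1 - pm)
    tau[:, 1] = pf * (1 - pm) + pm * (1 - pf)
    tau[:, 2] = pf * pm
    return tau


def informative_mask(g_f: np.ndarray, g_m: np.ndarray) -> np.ndarray:
    """Trios with at least one heterozygous parent carry likelihood information."""
    return (np.asarray(g_f) == 1) | (np.asarray(g_m) == 1)


def _tilted_moments(beta: float, tau: np.ndarray):
    """Normalizer, mean and variance of the exp(beta*g)-tilted offspring law."""
    w = tau * np.exp(beta * np.arange(3.0))
    z = w.sum(axis=1)
    e1 = (w @ np.arange(3.0)) / z
    e2 = (w @ np.arange(3.0) ** 2) / z
    return z, e1, e2 - e1**2


def cpg_loglik(beta: float, g_f, g_m, g_o) -> float:
    """Log conditional likelihood of the case-trio offspring genotypes.

    Each case trio contributes
    ``log[ tau(g_o) e^{beta g_o} / sum_g tau(g) e^{beta g} ]``; trios with two
    homozygous parents contribute a constant.
    """
    g_o = np.asarray(g_o)
    tau = transmission_probs(g_f, g_m)
    z, _, _ = _tilted_moments(beta, tau)
    tau_obs = tau[np.arange(g_o.size), g_o]
    if np.any(tau_obs <= 0):
        raise ValueError("Mendelian-inconsistent trio in CPG likelihood")
    return float(np.sum(np.log(tau_obs) + beta * g_o - np.log(z)))


def cpg_score_info(beta: float, g_f, g_m, g_o) -> tuple[float, float]:
    """Score and observed information of the CPG log likelihood at ``beta``."""
    g_o = np.asarray(g_o)
    tau = transmission_probs(g_f, g_m)
    _, e1, var = _tilted_moments(beta, tau)
    return float(np.sum(g_o - e1)), float(np.sum(var))


def fit_cpg(g_f, g_m, g_o) -> CPGFit:
    """Maximize the CPG likelihood by safeguarded Newton iteration.

    The log likelihood is concave (its curvature is a sum of offspring-law
    variances), so Newton from 0 with step-halving converges whenever a finite
    maximizer exists; one-sided transmission patterns diverge and are flagged.
    """
    g_f, g_m, g_o = (np.asarray(a) for a in (g_f, g_m, g_o))
    info_mask = informative_mask(g_f, g_m)
    n_inf = int(info_mask.sum())
    if n_inf == 0:
        return CPGFit(np.nan, np.nan, np.nan, 0, Status.NO_INFORMATIVE_TRIOS)

    beta = 0.0
    ll = cpg_loglik(beta, g_f, g_m, g_o)
    for _ in range(NEWTON_MAX_ITER):
        score, info = cpg_score_info(beta, g_f, g_m, g_o)
        if info <= 0:
            return CPGFit(np.nan, np.nan, np.nan, n_inf, Status.DEGENERATE)
        step = score / info
        # step-halving safeguard
        new_beta, new_ll = beta, ll
        for _ in range(30):
            cand = beta + step
            cand_ll = cpg_loglik(cand, g_f, g_m, g_o)
            if cand_ll >= ll - 1e-12:
                new_beta, new_ll = cand, cand_ll
                break
            step /= 2.0
        if abs(new_beta) > BETA_CAP:
            return CPGFit(np.nan, np.nan, np.nan, n_inf, Status.DEGENERATE)
        converged = abs(new_beta - beta) < NEWTON_TOL
        beta, ll = new_beta, new_ll
        if converged:
            break
    else:
        return CPGFit(np.nan, np.nan, np.nan, n_inf, Status.DEGENERATE)

    _, info = cpg_score_info(beta, g_f, g_m, g_o)
    if info <= 0:
        return CPGFit(np.nan, np.nan, np.nan, n_inf, Status.DEGENERATE)
    return CPGFit(float(beta), float(1.0 / np.sqrt(info)), float(ll), n_inf)


def fit_cc_logistic(y: np.ndarray, g: np.ndarray) -> CCFit:
    """Additive-genotype logistic regression of affection on allele count."""
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    n_cases, n_controls = int(y.sum()), int((1 - y).sum())
    if n_cases == 0 or n_controls == 0 or np.ptp(g) == 0:
        return CCFit(np.nan, np.nan, n_cases, n_controls, Status.DEGENERATE)

    X = sm.add_constant(g)
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(y, X).fit(disp=0, method="newton", maxiter=100,
                                     warn_convergence=False)
        beta, se = float(fit.params[1]), float(fit.bse[1])
        converged = bool(fit.mle_retvals.get("converged", True))
    except Exception:
        return CCFit(np.nan, np.nan, n_cases, n_controls, Status.DEGENERATE)
    if not converged or not np.isfinite(beta) or not np.isfinite(se) or abs(beta) > BETA_CAP:
        return CCFit(np.nan, np.nan, n_cases, n_controls, Status.DEGENERATE)

    # per-unit influence of the slope: rows of I^-1 s_i
    p = fit.predict(X)
    scores = (y - p)[:, None] * X  # n x 2 per-unit score
    info = X.T @ (X * (p * (1 - p))[:, None])
    try:
        infl = scores @ np.linalg.inv(info)
    except np.linalg.LinAlgError:
        return CCFit(np.nan, np.nan, n_cases, n_controls, Status.DEGENERATE)
    return CCFit(beta, se, n_cases, n_controls, influence=infl[:, 1])


def cross_covariance(
    cpg_fit: CPGFit,
    cc_fit: CCFit,
    g_f: np.ndarray,
    g_m: np.ndarray,
    g_o: np.ndarray,
    case_trio_rows_in_cc: np.ndarray,
) -> float:
    """Covariance of the two estimates from their shared units.

    Independent units are trios and unrelated subjects.  A case trio enters
    both arms (the trio term of the CPG likelihood; its proband's logistic
    term), so the cross-covariance is the cross-moment of the two
    per-unit influence values over those shared trios; disjoint samples give
    exactly zero.  ``case_trio_rows_in_cc[t]`` is the row of case trio ``t``'s
    proband inside the CC subsample, or -1 when absent.
    """
    if cpg_fit.status != Status.OK or cc_fit.status != Status.OK:
        raise ValueError("cross_covariance requires two ok fits")
    tau = transmission_probs(g_f, g_m)
    _, e1, _ = _tilted_moments(cpg_fit.beta_hat, tau)
    _, info = cpg_score_info(cpg_fit.beta_hat, g_f, g_m, g_o)
    infl_cpg = (np.asarray(g_o) - e1) / info

    total = 0.0
    for t, row in enumerate(case_trio_rows_in_cc):
        if row >= 0:
            total += infl_cpg[t] * cc_fit.influence[row]
    return float(total)


def homogeneity_wald(
    cpg_fit: CPGFit, cc_fit: CCFit, cross_cov: float
) -> tuple[float, float]:
    """Wald test of equality of the two effect estimates, chi2(1)."""
    var_diff = cpg_fit.se**2 + cc_fit.se**2 - 2.0 * cross_cov
    if var_diff <= 0:
        raise ValueError("non-positive variance of the estimate difference")
    stat = (cpg_fit.beta_hat - cc_fit.beta_hat) ** 2 / var_diff
    return float(stat), float(stats.chi2.sf(stat, df=1))


def combine_and_test(
    cpg_fit: CPGFit,
    cc_fit: CCFit,
    cross_cov: float,
    snp_id: str = "",
    alpha_h: float = 0.05,
) -> AssociationResult:
    """Pool the two estimates by weighted least squares and test beta_c = 0.

    When the homogeneity pre-test rejects at ``alpha_h`` the estimates are not
    poolable; the within-family CPG Wald test is reported instead, flagged
    ``homogeneity_rejected``.
    """
    try:
        h_stat, h_p = homogeneity_wald(cpg_fit, cc_fit, cross_cov)
    except ValueError:
        return AssociationResult(
            snp_id=snp_id, method="chen_lin", status=Status.DEGENERATE,
            homogeneity_p=None,
            extras={"n_informative_trios": cpg_fit.n_informative_trios},
        )

    if h_p < alpha_h:
        stat = (cpg_fit.beta_hat / cpg_fit.se) ** 2
        return AssociationResult(
            snp_id=snp_id, method="chen_lin", statistic=float(stat),
            p_value=float(stats.chi2.sf(stat, df=1)),
            estimate=cpg_fit.beta_hat, se=cpg_fit.se, homogeneity_p=h_p,
            extras={
                "homogeneity_rejected": True,
                "n_informative_trios": cpg_fit.n_informative_trios,
            },
        )

    Sigma = np.array(
        [[cpg_fit.se**2, cross_cov], [cross_cov, cc_fit.se**2]]
    )
    try:
        Sinv = np.linalg.inv(Sigma)
    except np.linalg.LinAlgError:
        return AssociationResult(
            snp_id=snp_id, method="chen_lin", status=Status.DEGENERATE,
            homogeneity_p=h_p,
        )
    ones = np.ones(2)
    denom = ones @ Sinv @ ones
    if denom <= 0:
        return AssociationResult(
            snp_id=snp_id, method="chen_lin", status=Status.DEGENERATE,
            homogeneity_p=h_p,
        )
    w = Sinv @ ones / denom
    beta_c = float(w @ np.array([cpg_fit.beta_hat, cc_fit.beta_hat]))
    se_c = float(1.0 / np.sqrt(denom))
    stat = (beta_c / se_c) ** 2
    return AssociationResult(
        snp_id=snp_id, method="chen_lin", statistic=float(stat),
        p_value=float(stats.chi2.sf(stat, df=1)),
        estimate=beta_c, se=se_c, homogeneity_p=h_p,
        extras={
            "homogeneity_rejected": False,
            "w1": float(w[0]), "w2": float(w[1]),
            "cross_cov": float(cross_cov),
            "n_informative_trios": cpg_fit.n_informative_trios,
        },
    )


def chen_lin_test(
    sample: CombinedSample,
    snp: int,
    alpha_h: float = 0.05,
    rule: CCRule | None = None,
    assume_independent: bool = False,
) -> AssociationResult:
    """Full per-SNP pipeline: CPG arm, logistic arm, homogeneity, combination.

    ``assume_independent`` zeroes the cross-covariance (sensitivity switch).
    """
    snp_id = sample.genotypes.snp_ids[snp]
    if founder_maf(sample, snp) == 0.0:
        return AssociationResult(snp_id=snp_id, method="chen_lin",
                                 status=Status.MONOMORPHIC)

    usable = trio_usable_mask(sample, snp)
    g_f, g_m, g_o = sample.trio_genotype_arrays(snp)
    o_y = sample.offspring_phenotypes()
    case_mask = usable & (o_y == 1)
    cpg_fit = fit_cpg(g_f[case_mask], g_m[case_mask], g_o[case_mask])
    if cpg_fit.status != Status.OK:
        return AssociationResult(
            snp_id=snp_id, method="chen_lin", status=cpg_fit.status,
            extras={"n_informative_trios": cpg_fit.n_informative_trios},
        )

    cc_idx, cc_y, trio_of_row = build_cc_subsample(sample, rule)
    g_all = sample.genotypes.values[:, snp]
    keep = g_all[cc_idx] >= 0  # drop per-SNP missing genotypes
    cc_idx, cc_y = cc_idx[keep], cc_y[keep]
    cc_fit = fit_cc_logistic(cc_y, g_all[cc_idx])
    if cc_fit.status != Status.OK:
        return AssociationResult(snp_id=snp_id, method="chen_lin",
                                 status=cc_fit.status,
                                 extras={"n_informative_trios": cpg_fit.n_informative_trios})

    if assume_independent:
        cov = 0.0
    else:
        row_of = {int(r): i for i, r in enumerate(cc_idx)}
        case_trio_indices = np.nonzero(case_mask)[0]
        rows = np.array(
            [row_of.get(sample.trios[t].offspring_idx, -1) for t in case_trio_indices],
            dtype=int,
        )
        cov = cross_covariance(
            cpg_fit, cc_fit,
            g_f[case_mask], g_m[case_mask], g_o[case_mask], rows,
        )
    return combine_and_test(cpg_fit, cc_fit, cov, snp_id=snp_id, alpha_h=alpha_h)
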