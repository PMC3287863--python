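"""GEE-style score test decomposed over unrelated subjects and trios.

Treating traits as constants, the score is Z = U + R with

* ``U = sum_unrelated (y_i - mu_y,i)(g_i - mu_g,i)`` — population arm, with
  per-individual means from linear regressions of trait and genotype on
  principal components (sample means when L = 0);
* ``R = sum_offspring (y_ij - mu^_y,ij)(r_o,ij - (r_m,i + r_f,i)/2)`` — family
  arm, where r are PC-residualized genotypes of offspring, mother and father
  (a TDT-like adjustment of the parental genotypes; with L = 0 the
  adjustment cancels and the term is exactly g_o - (g_m + g_f)/2, the
  Mendelian transmission residual).

The variance treats genotypes as the only random quantities:
``var(Z) = sum_unrelated (y_i - mu_y,i)^2 sigma^2_g +
sum_offspring (y_ij - mu^_y,ij)^2 v_g,i`` with ``sigma^2_g`` the residual
genotype variance among unrelateds and ``v_g`` the Mendelian transmission
variance from the parents' heterozygosity.  ``Z^2/var(Z)`` is referred to
chi2(1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import (
    MISSING,
    AssociationResult,
    CombinedSample,
    Status,
    founder_maf,
    trio_usable_mask,
)
from .pca import PCBasis, fit_pcs, project_scores, residualize


@dataclass
class AdjustedMoments:
    mu_y: np.ndarray
    mu_g: np.ndarray


@dataclass
class MendelianMoments:
    e_g: np.ndarray  # (g_m + g_f) / 2
    v_g: np.ndarray  # (1{g_m=1} + 1{g_f=1}) / 4


@dataclass
class ScoreDecomposition:
    U: float
    R: float
    Z: float
    var_Z: float
    stat: float
    p: float


def mendelian_moments(g_m, g_f) -> MendelianMoments:
    """Exact mean and variance of the offspring allele count given the parents.

    Each parent transmits a minor allele with probability g/2, independently,
    so the count has mean (g_m + g_f)/2 and variance contributed only by
    heterozygous parents, (1{g_m=1} + 1{g_f=1})/4.
    """
    g_m = np.asarray(g_m, dtype=float)
    g_f = np.asarray(g_f, dtype=float)
    if np.any((g_m < 0) | (g_m > 2) | (g_f < 0) | (g_f > 2)):
        raise ValueError("parental genotypes must lie in {0,1,2}")
    e_g = (g_m + g_f) / 2.0
    v_g = ((g_m == 1).astype(float) + (g_f == 1).astype(float)) / 4.0
    return MendelianMoments(e_g=e_g, v_g=v_g)


def adjust_unrelated(
    y: np.ndarray, g: np.ndarray, pc_scores: np.ndarray | None
) -> AdjustedMoments:
    """PC-adjusted trait and genotype means for the unrelated individuals:
    fitted values of OLS regressions (with intercept) on the scores."""
    n = len(y)
    fit_rows = np.ones(n, dtype=bool)
    _, mu_y = residualize(np.asarray(y, dtype=float), pc_scores, fit_rows)
    _, mu_g = residualize(np.asarray(g, dtype=float), pc_scores, fit_rows)
    return AdjustedMoments(mu_y=mu_y, mu_g=mu_g)


def adjust_parents(
    g_m: np.ndarray,
    g_f: np.ndarray,
    scores_m: np.ndarray | None,
    scores_f: np.ndarray | None,
    coef: np.ndarray | None,
) -> tuple[np.ndarray, np.ndarray]:
    """TDT-like PC residualization of parental genotypes.

    ``coef`` are the genotype-on-scores coefficients fitted on the unrelated
    set (intercept first); with L = 0 both parents are shifted by the same
    constant, which cancels downstream in the transmission residual.
    """
    g_m = np.asarray(g_m, dtype=float)
    g_f = np.asarray(g_f, dtype=float)
    if coef is None:
        return g_m, g_f
    Xm = np.column_stack([np.ones(len(g_m))] + ([scores_m] if scores_m is not None else []))
    Xf = np.column_stack([np.ones(len(g_f))] + ([scores_f] if scores_f is not None else []))
    return g_m - Xm @ coef, g_f - Xf @ coef


def _genotype_coef(
    g_unrel: np.ndarray, scores_unrel: np.ndarray | None
) -> np.ndarray:
    X = np.ones((len(g_unrel), 1))
    if scores_unrel is not None:
        X = np.column_stack([X, scores_unrel])
    coef, *_ = np.linalg.lstsq(X, np.asarray(g_unrel, dtype=float), rcond=None)
    return coef


def score_decomposition(
    y_unrel: np.ndarray,
    g_unrel: np.ndarray,
    scores_unrel: np.ndarray | None,
    y_off: np.ndarray,
    g_off: np.ndarray,
    g_m: np.ndarray,
    g_f: np.ndarray,
    scores_off: np.ndarray | None,
    scores_m: np.ndarray | None,
    scores_f: np.ndarray | None,
    mu_y_off: np.ndarray | None = None,
) -> ScoreDecomposition:
    """Assemble U, R, Z and the score test from already-aligned arrays.

    ``mu_y_off``: adjusted trait mean used to center offspring traits
    (defaults to the unrelated-fitted trait regression evaluated at the
    offspring scores; the unrelated-set mean when L = 0).
    """
    y_unrel = np.asarray(y_unrel, dtype=float)
    g_unrel = np.asarray(g_unrel, dtype=float)
    n_unrel = len(y_unrel)
    if n_unrel:
        moments = adjust_unrelated(y_unrel, g_unrel, scores_unrel)
        y_c = y_unrel - moments.mu_y
        g_c = g_unrel - moments.mu_g
        U = float(np.sum(y_c * g_c))
        sigma2_g = float(np.mean(g_c**2))
    else:
        y_c = np.empty(0)
        U, sigma2_g = 0.0, 0.0

    n_off = len(y_off)
    if n_off:
        if mu_y_off is None:
            if n_unrel == 0:
                # no population arm to borrow a trait mean from
                mu_y_off = np.full(n_off, float(np.mean(y_off)))
            else:
                Xu = np.ones((n_unrel, 1))
                if scores_unrel is not None:
                    Xu = np.column_stack([Xu, scores_unrel])
                coef_y, *_ = np.linalg.lstsq(Xu, y_unrel, rcond=None)
                Xo = np.ones((n_off, 1))
                if scores_off is not None:
                    Xo = np.column_stack([Xo, scores_off])
                mu_y_off = Xo @ coef_y
        coef_g = _genotype_coef(g_unrel, scores_unrel) if scores_unrel is not None else None
        r_m, r_f = adjust_parents(g_m, g_f, scores_m, scores_f, coef_g)
        if coef_g is None:
            r_o = np.asarray(g_off, dtype=float)
        else:
            Xo_g = np.column_stack([np.ones(n_off), scores_off])
            r_o = np.asarray(g_off, dtype=float) - Xo_g @ coef_g
        mm = mendelian_moments(np.asarray(g_m), np.asarray(g_f))
        y_off_c = np.asarray(y_off, dtype=float) - mu_y_off
        R = float(np.sum(y_off_c * (r_o - (r_m + r_f) / 2.0)))
        var_R = float(np.sum(y_off_c**2 * mm.v_g))
    else:
        R, var_R = 0.0, 0.0

    Z = U + R
    var_Z = float(np.sum(y_c**2) * sigma2_g) + var_R
    if var_Z <= 0:
        return ScoreDecomposition(U, R, Z, var_Z, np.nan, np.nan)
    stat = Z**2 / var_Z
    return ScoreDecomposition(U, R, Z, var_Z, float(stat),
                              float(stats.chi2.sf(stat, df=1)))


def _sample_arrays(sample: CombinedSample):
    G = sample.genotypes.values
    unrel = np.asarray(sample.unrelated_idx, dtype=int)
    f_idx = np.array([t.father_idx for t in sample.trios], dtype=int)
    m_idx = np.array([t.mother_idx for t in sample.trios], dtype=int)
    o_idx = np.array([t.offspring_idx for t in sample.trios], dtype=int)
    y_unrel = sample.unrelated_phenotypes()
    y_off = sample.offspring_phenotypes()
    return G, unrel, f_idx, m_idx, o_idx, y_unrel, y_off


def zhang_test_all(
    sample: CombinedSample,
    L: int = 10,
    basis: PCBasis | None = None,
) -> list[AssociationResult]:
    """Per-SNP score tests over the whole panel with one shared PC basis."""
    G, unrel, f_idx, m_idx, o_idx, y_unrel, y_off = _sample_arrays(sample)
    founders = G[sorted(set(sample.founder_idx().tolist()))]
    if L > 0 and basis is None:
        basis = fit_pcs(founders, L)

    def scores_of(rows):
        if L == 0 or rows.size == 0:
            return None
        return project_scores(basis, G[rows])

    s_unrel = scores_of(unrel)
    s_f, s_m, s_o = scores_of(f_idx), scores_of(m_idx), scores_of(o_idx)

    results = []
    for j, snp_id in enumerate(sample.genotypes.snp_ids):
        results.append(
            _zhang_single(
                sample, j, snp_id, G, unrel, f_idx, m_idx, o_idx,
                y_unrel, y_off, s_unrel, s_f, s_m, s_o, L,
            )
        )
    return results


def _zhang_single(
    sample, j, snp_id, G, unrel, f_idx, m_idx, o_idx,
    y_unrel, y_off, s_unrel, s_f, s_m, s_o, L,
):
    if founder_maf(sample, j) == 0.0:
        return AssociationResult(snp_id=snp_id, method="zhang",
                                 status=Status.MONOMORPHIC)
    g_u = G[unrel, j]
    keep_u = g_u != MISSING
    usable = trio_usable_mask(sample, j) if len(sample.trios) else np.empty(0, bool)

    sd = score_decomposition(
        y_unrel[keep_u], g_u[keep_u],
        s_unrel[keep_u] if s_unrel is not None else None,
        y_off[usable], G[o_idx[usable], j],
        G[m_idx[usable], j], G[f_idx[usable], j],
        s_o[usable] if s_o is not None else None,
        s_m[usable] if s_m is not None else None,
        s_f[usable] if s_f is not None else None,
    )
    extras = {"U": sd.U, "R": sd.R, "var_Z": sd.var_Z, "L": L}
    if not np.isfinite(sd.stat):
        return AssociationResult(snp_id=snp_id, method="zhang",
                                 status=Status.DEGENERATE, extras=extras)
    return AssociationResult(
        snp_id=snp_id, method="zhang", statistic=sd.stat, p_value=sd.p,
        estimate=sd.Z, se=float(np.sqrt(sd.var_Z)), extras=extras,
    )


def zhang_test(
    sample: CombinedSample,
    snp: int,
    L: int = 10,
    basis: PCBasis | None = None,
) -> AssociationResult:
    """Single-SNP wrapper; pass a pre-fitted basis when scanning a panel."""
    G, unrel, f_idx, m_idx, o_idx, y_unrel, y_off = _sample_arrays(sample)
    if L > 0 and basis is None:
        basis = fit_pcs(G[sorted(set(sample.founder_idx().tolist()))], L)

    def scores_of(rows):
        if L == 0 or rows.size == 0:
            return None
        return project_scores(basis, G[rows])

    return _zhang_single(
        sample, snp, sample.genotypes.snp_ids[snp], G, unrel,
        f_idx, m_idx, o_idx, y_unrel, y_off,
        scores_of(unrel), scores_of(f_idx), scores_of(m_idx), scores_of(o_idx), L,
    )
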