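"""PC-residual covariance test over families and unrelated subjects.

Genotypes and phenotypes are regressed on principal components fitted to the
unrelated individuals (trio parents plus unrelated cases/controls); the
association statistic is the covariance of the residuals,

    T = (1/N_T) sum_i sum_j  y~_ij g~_ij,

summed over families i (an unrelated subject is a singleton family) and
members j.  Its variance uses the family-level empirical second moment,

    var(T) = (1/N_T^2) sum_i ( sum_j y~_ij g~_ij )^2,

so within-family correlation inflates the variance, not the statistic; the
Wald statistic T^2/var(T) is referred to chi2(1).  Any constant rescaling of
T cancels in the ratio.
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
)
from .pca import PCBasis, fit_pcs, project_scores, residualize


@dataclass
class ZhuStatistic:
    T: float
    var_T: float
    wald: float
    p: float


@dataclass
class FamilyLayout:
    """Row ordering (unrelateds, then each trio's father/mother/offspring),
    family start offsets, phenotypes, and the PC fitting-set mask."""

    rows: np.ndarray        # genotype-matrix row index per layout position
    offsets: np.ndarray     # family start positions (for reduceat)
    y: np.ndarray
    fit_mask: np.ndarray    # True where the position is unrelated or a parent
    n_families: int


def build_family_layout(sample: CombinedSample) -> FamilyLayout:
    rows = list(sample.unrelated_idx)
    offsets = list(range(len(rows)))
    fit = [True] * len(rows)
    for t in sample.trios:
        offsets.append(len(rows))
        rows.extend([t.father_idx, t.mother_idx, t.offspring_idx])
        fit.extend([True, True, False])
    ids = sample.genotypes.individual_ids
    y = np.array(
        [sample.individuals[ids[r]].affected for r in rows], dtype=float
    )
    if np.any(np.isnan(y)):
        raise ValueError("missing phenotype in testing set")
    return FamilyLayout(
        rows=np.asarray(rows, dtype=int),
        offsets=np.asarray(offsets, dtype=int),
        y=y,
        fit_mask=np.asarray(fit, dtype=bool),
        n_families=len(offsets),
    )


def zhu_statistic(
    y_res: np.ndarray, g_res: np.ndarray, offsets: np.ndarray
) -> ZhuStatistic:
    """Covariance statistic and family-robust Wald test from residuals."""
    prod = np.asarray(y_res) * np.asarray(g_res)
    n_total = prod.size
    fam_sums = np.add.reduceat(prod, offsets)
    T = fam_sums.sum() / n_total
    var_T = (fam_sums**2).sum() / n_total**2
    if var_T <= 0:
        return ZhuStatistic(float(T), float(var_T), np.nan, np.nan)
    wald = T**2 / var_T
    return ZhuStatistic(float(T), float(var_T), float(wald),
                        float(stats.chi2.sf(wald, df=1)))


def _result(snp_id: str, z: ZhuStatistic, L: int) -> AssociationResult:
    if not np.isfinite(z.wald):
        return AssociationResult(snp_id=snp_id, method="zhu",
                                 status=Status.DEGENERATE,
                                 extras={"T": z.T, "var_T": z.var_T, "L": L})
    return AssociationResult(
        snp_id=snp_id, method="zhu", statistic=z.wald, p_value=z.p,
        estimate=z.T, se=float(np.sqrt(z.var_T)),
        extras={"T": z.T, "var_T": z.var_T, "L": L},
    )


def zhu_test_all(
    sample: CombinedSample,
    L: int = 10,
    basis: PCBasis | None = None,
) -> list[AssociationResult]:
    """Per-SNP tests for the whole panel, sharing one PC basis and one
    phenotype residualization (vectorized over complete-data SNPs)."""
    layout = build_family_layout(sample)
    G = sample.genotypes.values
    founders = G[sorted(set(sample.founder_idx().tolist()))]
    if L > 0 and basis is None:
        basis = fit_pcs(founders, L)
    scores = (
        project_scores(basis, G[layout.rows]) if L > 0 else None
    )
    y_res, _ = residualize(layout.y, scores, layout.fit_mask)

    results: list[AssociationResult] = []
    G_lay = G[layout.rows].astype(float)
    complete = ~np.any(G_lay == MISSING, axis=0)
    g_res_bulk = np.full_like(G_lay, np.nan)
    if complete.any():
        g_res_bulk[:, complete], _ = residualize(
            G_lay[:, complete], scores, layout.fit_mask
        )

    for j, snp_id in enumerate(sample.genotypes.snp_ids):
        if founder_maf(sample, j) == 0.0:
            results.append(AssociationResult(snp_id=snp_id, method="zhu",
                                             status=Status.MONOMORPHIC))
            continue
        if complete[j]:
            z = zhu_statistic(y_res, g_res_bulk[:, j], layout.offsets)
        else:
            z = _zhu_single_missing(layout, G_lay[:, j], scores, y_res)
        results.append(_result(snp_id, z, L))
    return results


def _zhu_single_missing(layout, g_col, scores, y_res) -> ZhuStatistic:
    """Complete-case per marker: rows missing this genotype drop out of the
    regression and of the family sums."""
    present = g_col != MISSING
    g_res, _ = residualize(
        g_col[present],
        scores[present] if scores is not None else None,
        layout.fit_mask[present],
    )
    # rebuild family offsets over the kept rows
    fam_of = np.searchsorted(layout.offsets, np.arange(g_col.size), side="right") - 1
    fam_kept = fam_of[present]
    change = np.ones(fam_kept.size, dtype=bool)
    change[1:] = fam_kept[1:] != fam_kept[:-1]
    offsets = np.nonzero(change)[0]
    return zhu_statistic(y_res[present], g_res, offsets)


def zhu_test(
    sample: CombinedSample,
    snp: int,
    L: int = 10,
    basis: PCBasis | None = None,
) -> AssociationResult:
    """Single-SNP convenience wrapper; the basis should be fitted once per
    dataset and passed in when testing many SNPs."""
    layout = build_family_layout(sample)
    G = sample.genotypes.values
    if L > 0 and basis is None:
        basis = fit_pcs(G[sorted(set(sample.founder_idx().tolist()))], L)
    scores = project_scores(basis, G[layout.rows]) if L > 0 else None
    y_res, _ = residualize(layout.y, scores, layout.fit_mask)
    snp_id = sample.genotypes.snp_ids[snp]
    if founder_maf(sample, snp) == 0.0:
        return AssociationResult(snp_id=snp_id, method="zhu",
                                 status=Status.MONOMORPHIC)
    g_col = G[layout.rows, snp].astype(float)
    if np.any(g_col == MISSING):
        z = _zhu_single_missing(layout, g_col, scores, y_res)
    else:
        g_res, _ = residualize(g_col, scores, layout.fit_mask)
        z = zhu_statistic(y_res, g_res, layout.offsets)
    return _result(snp_id, z, L)
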