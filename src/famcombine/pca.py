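"""Principal components of unrelated genotypes, shared by the PC-adjusted tests.

The basis is fitted ONLY on unrelated individuals (trio parents plus unrelated
cases/controls); trio offspring receive coordinates by projecting their
standardized genotype rows onto the parent-fitted loadings.  SNP j is
standardized by its unrelated-set mean and by ``sqrt(2 p_j (1 - p_j))`` with
``p_j`` the unrelated-set allele frequency; constant columns are dropped from
the basis but tracked so that fit and projection treat them identically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .core import MISSING


@dataclass
class PCBasis:
    n_components: int
    loadings: np.ndarray       # kept-SNPs x L
    column_means: np.ndarray   # per-SNP (all SNPs)
    column_scales: np.ndarray  # per-SNP (all SNPs); 0 marks a dropped column
    kept: np.ndarray           # boolean mask over SNPs
    scores: np.ndarray         # fitting-set individuals x L


def _standardize(G: np.ndarray, means: np.ndarray, scales: np.ndarray,
                 kept: np.ndarray) -> np.ndarray:
    X = G[:, kept].astype(float)
    X[X == MISSING] = np.nan
    X = (X - means[kept]) / scales[kept]
    return np.nan_to_num(X, nan=0.0)  # missing -> mean after centering


def fit_pcs(unrelated_genotypes: np.ndarray, n_components: int) -> PCBasis:
    """Top-L principal components of the standardized unrelated genotype matrix.

    Deterministic up to component sign; signs are fixed so the
    largest-magnitude loading of each component is positive.
    """
    G = np.asarray(unrelated_genotypes)
    n, s = G.shape
    if not 0 < n_components < n:
        raise ValueError(f"n_components must lie in (0, {n}), got {n_components}")

    Gf = G.astype(float)
    Gf[Gf == MISSING] = np.nan
    means = np.nanmean(Gf, axis=0)
    p = means / 2.0
    scales = np.sqrt(2.0 * p * (1.0 - p))
    kept = (scales > 0) & np.isfinite(scales)
    if kept.sum() < n_components:
        raise ValueError("fewer variable SNPs than requested components")

    X = _standardize(G, means, scales, kept)
    pca = PCA(n_components=n_components, random_state=0)
    scores = pca.fit_transform(X)
    loadings = pca.components_.T  # kept-SNPs x L

    # sign convention: largest-|loading| entry positive
    flip = np.sign(loadings[np.argmax(np.abs(loadings), axis=0), np.arange(n_components)])
    flip[flip == 0] = 1.0
    loadings = loadings * flip
    scores = scores * flip

    scales_out = np.where(kept, scales, 0.0)
    return PCBasis(
        n_components=n_components, loadings=loadings, column_means=means,
        column_scales=scales_out, kept=kept, scores=scores,
    )


def project_scores(basis: PCBasis, genotypes: np.ndarray) -> np.ndarray:
    """PC coordinates for arbitrary individuals on the fitted basis."""
    G = np.atleast_2d(np.asarray(genotypes))
    if G.shape[1] != basis.kept.size:
        raise ValueError(
            f"genotype row length {G.shape[1]} does not match basis SNP count "
            f"{basis.kept.size}"
        )
    X = _standardize(G, basis.column_means, basis.column_scales, basis.kept)
    return X @ basis.loadings


def residualize(
    values: np.ndarray,
    scores_all: np.ndarray | None,
    fit_rows: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Residuals of an OLS regression (with intercept) of values on PC scores.

    Coefficients are estimated on ``fit_rows`` only (the unrelated set) and
    applied to every row.  ``scores_all=None`` or zero columns means
    intercept-only: residual = value - fitting-set mean.  Returns
    ``(residuals, fitted)``.  Collinear components are handled by the
    least-squares pseudoinverse.
    """
    v = np.asarray(values, dtype=float)
    n = v.shape[0]
    if scores_all is None or scores_all.shape[1] == 0:
        X = np.ones((n, 1))
    else:
        X = np.column_stack([np.ones(n), scores_all])
    coef, *_ = np.linalg.lstsq(X[fit_rows], v[fit_rows], rcond=None)
    fitted = X @ coef
    return v - fitted, fitted
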