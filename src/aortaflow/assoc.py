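"""Mixed-linear-model association scan (MLMA).

Per-SNP fixed-effect test in the model

    y = μ + x·β + g + e,   g ~ N(0, A·σ²g),   e ~ N(0, I·σ²e),

with the variance components estimated once under the null (no candidate
SNP) and held fixed for every SNP, as GCTA's ``--mlma`` does.  After
whitening by V^(-1/2) the per-SNP fit is ordinary least squares, and the
Wald statistic β̂²/SE² is referred to χ²₁.  SNPs with p below the
genome-wide threshold 5×10⁻⁸ are flagged.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import GenotypeMatrix
from .grm import GRM
from .vc import GREML, VarianceComponentsResults

__all__ = ["mlma_scan", "genomic_lambda", "GENOME_WIDE_P"]

GENOME_WIDE_P = 5e-8

#: median of chi-square with 1 df, the genomic-control normaliser
_CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, 1))


def genomic_lambda(chisq: np.ndarray) -> float:
    """Genomic-control inflation factor: median χ² over its null median."""
    chisq = np.asarray(chisq, dtype=float)
    chisq = chisq[np.isfinite(chisq)]
    if chisq.size == 0:
        raise ValueError("no finite test statistics")
    return float(np.median(chisq) / _CHI2_1_MEDIAN)


def mlma_scan(
    y: np.ndarray,
    genotypes: GenotypeMatrix,
    grm: GRM | np.ndarray,
    covariates: np.ndarray | None = None,
    varcomp: VarianceComponentsResults | None = None,
) -> pd.DataFrame:
    """Scan every SNP for association under the polygenic mixed model.

    Parameters
    ----------
    y : array
        Trait values aligned with ``genotypes.ids``.
    genotypes : GenotypeMatrix
        Post-QC dosages; missing dosages are mean-imputed per SNP for the
        scan only.
    grm : GRM or ndarray
        Relationship matrix aligned with ``y``.
    covariates : ndarray, optional
        Extra fixed-effect columns (an intercept is always included).
    varcomp : VarianceComponentsResults, optional
        Null variance components; estimated by AI-REML when omitted.

    Returns
    -------
    DataFrame with columns ``snp, chrom, pos, freq, beta, se, chisq, p,
    genome_wide`` in panel order.  Zero-variance SNPs are skipped with a
    warning (NaN statistics).
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if genotypes.n != n:
        raise ValueError("genotypes and trait vector do not align")
    a = grm.a if isinstance(grm, GRM) else np.asarray(grm, dtype=float)
    X = np.ones((n, 1))
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        X = np.hstack([X, cov])

    if varcomp is None:
        varcomp = GREML(y, a, X=X).fit()
    sg, se_var = varcomp.sigma2_g, varcomp.sigma2_e

    lam, vec = np.linalg.eigh(a)
    d = np.clip(lam, 0.0, None) * sg + se_var
    w = 1.0 / np.sqrt(d)
    # whitening transform T = D^{-1/2} U^T : Var(Ty) = I
    ty = w * (vec.T @ y)
    tX = w[:, None] * (vec.T @ X)

    dos = genotypes.dosages.astype(np.float64)
    dos[genotypes.missing_mask()] = np.nan
    freq = np.nanmean(dos, axis=0) / 2.0
    col_mean = 2.0 * freq
    dos = np.where(np.isnan(dos), col_mean, dos)
    snp_var = dos.var(axis=0)
    tG = w[:, None] * (vec.T @ dos)

    # residualise the whitened trait and SNPs on the whitened fixed effects
    q, _ = np.linalg.qr(tX)
    ry = ty - q @ (q.T @ ty)
    rG = tG - q @ (q.T @ tG)

    xx = (rG * rG).sum(axis=0)
    xy = (rG * ry[:, None]).sum(axis=0)
    ok = (xx > 1e-12) & (snp_var > 0)
    if not ok.all():
        warnings.warn(
            f"{int((~ok).sum())} zero-variance SNP(s) skipped in the scan",
            stacklevel=2,
        )
    beta = np.full(genotypes.m, np.nan)
    se = np.full(genotypes.m, np.nan)
    beta[ok] = xy[ok] / xx[ok]
    se[ok] = 1.0 / np.sqrt(xx[ok])
    chisq = (beta / se) ** 2
    p = stats.chi2.sf(chisq, 1)
    out = genotypes.panel.table[["snp", "chrom", "pos"]].copy()
    out["freq"] = freq
    out["beta"] = beta
    out["se"] = se
    out["chisq"] = chisq
    out["p"] = p
    out["genome_wide"] = p < GENOME_WIDE_P
    return out
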