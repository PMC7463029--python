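"""Genomic relationship matrix (GRM) from SNP dosages.

The realised additive relationship between individuals j and k is
estimated from m post-QC SNPs as

    A_jk = (1/m_jk) Σ_i (x_ij − 2p̂_i)(x_ik − 2p̂_i) / (2 p̂_i (1 − p̂_i)),

with p̂_i the sample allele frequency and m_jk the number of SNPs
non-missing in both individuals (pairwise-complete, as in GCTA).  The
diagonal uses GCTA's corrected estimator

    A_jj = 1 + (1/m_j) Σ_i (x_ij² − (1 + 2p̂_i) x_ij + 2p̂_i²) / (2 p̂_i (1 − p̂_i)),

whose expectation is 1 + F_j for inbreeding coefficient F_j.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import GenotypeMatrix

__all__ = ["GRM", "compute_grm"]


@dataclass
class GRM:
    """Realised relationship matrix with per-pair SNP counts."""

    a: np.ndarray  # symmetric (n, n)
    n_pairs: np.ndarray  # SNPs used per pair, (n, n)
    ids: list[str]
    m: int

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        n = len(self.ids)
        if self.a.shape != (n, n):
            raise ValueError("GRM shape does not match registry")
        if not np.allclose(self.a, self.a.T, atol=1e-10):
            raise ValueError("GRM must be symmetric")
        if (self.n_pairs > self.m).any():
            raise ValueError("per-pair SNP count exceeds total SNP count")

    @property
    def n(self) -> int:
        return len(self.ids)

    def subset(self, keep_ids) -> "GRM":
        pos = {iid: k for k, iid in enumerate(self.ids)}
        idx = [pos[i] for i in keep_ids]
        sel = np.ix_(idx, idx)
        return GRM(self.a[sel], self.n_pairs[sel], list(keep_ids), self.m)


def compute_grm(genotypes: GenotypeMatrix) -> GRM:
    """Build the GRM from a post-QC dosage matrix.

    Monomorphic SNPs make the standardisation degenerate and indicate the
    MAF filter was bypassed; they raise a ``ValueError`` naming the SNP.
    """
    dos = genotypes.dosages.astype(np.float64)
    miss = genotypes.missing_mask()
    dos[miss] = np.nan
    p = np.nanmean(dos, axis=0) / 2.0
    bad = np.where(~((p > 0) & (p < 1)))[0]
    if bad.size:
        name = genotypes.panel.table["snp"].iloc[bad[0]]
        raise ValueError(
            f"monomorphic SNP {name!r} in GRM input; apply the MAF filter first"
        )
    denom = np.sqrt(2.0 * p * (1.0 - p))
    w = (dos - 2.0 * p) / denom
    w_filled = np.where(np.isnan(w), 0.0, w)
    obs = (~np.isnan(w)).astype(np.float64)
    counts = obs @ obs.T
    s = w_filled @ w_filled.T
    with np.errstate(invalid="ignore", divide="ignore"):
        a = np.where(counts > 0, s / np.maximum(counts, 1), 0.0)
    # GCTA diagonal: 1 + (1/m_j) * sum (x^2 - (1+2p)x + 2p^2) / (2pq)
    diag_terms = (dos**2 - (1.0 + 2.0 * p) * dos + 2.0 * p**2) / (2.0 * p * (1.0 - p))
    m_j = obs.sum(axis=1)
    a[np.diag_indices_from(a)] = 1.0 + np.nansum(diag_terms, axis=1) / m_j
    a = (a + a.T) / 2.0
    return GRM(a, counts.astype(np.int64), list(genotypes.ids), genotypes.m)
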