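"""Pedigree kinship coefficients.

The kinship coefficient φ_jk is the probability that an allele sampled at
random from j and one from k are identical by descent; 2φ is the expected
additive genetic relationship used as the covariance structure of the
polygenic model.  Computed by the standard recursion over a topologically
sorted pedigree:

* founders: φ_jj = 1/2, φ_jk = 0 for distinct founders (assumed unrelated);
* non-founder j with parents f, m: φ_jj = (1 + φ_fm)/2 and
  φ_jk = (φ_fk + φ_mk)/2 for any k that precedes j.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import Pedigree

__all__ = ["KinshipMatrix", "kinship_matrix"]


@dataclass
class KinshipMatrix:
    """Symmetric matrix of kinship coefficients with its id registry."""

    phi: np.ndarray
    ids: list[str]

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float)
        if self.phi.shape != (len(self.ids), len(self.ids)):
            raise ValueError("kinship matrix shape does not match registry")
        if not np.allclose(self.phi, self.phi.T):
            raise ValueError("kinship matrix must be symmetric")

    @property
    def n(self) -> int:
        return len(self.ids)

    def pair(self, a: str, b: str) -> float:
        pos = {iid: k for k, iid in enumerate(self.ids)}
        return float(self.phi[pos[a], pos[b]])

    def subset(self, keep_ids) -> "KinshipMatrix":
        pos = {iid: k for k, iid in enumerate(self.ids)}
        idx = [pos[i] for i in keep_ids]
        return KinshipMatrix(self.phi[np.ix_(idx, idx)], list(keep_ids))


def kinship_matrix(pedigree: Pedigree) -> KinshipMatrix:
    """Recursive kinship coefficients for every pair in the pedigree.

    The pedigree's row order is topological (validated on construction), so
    a single forward sweep suffices; each new individual's row is the
    average of its parents' rows.
    """
    n = pedigree.n
    fa, mo = pedigree.parent_indices()
    if ((fa < 0) != (mo < 0)).any():
        # one known parent: treat the unknown one as an unrelated founder,
        # which the recursion realises as a phantom zero row
        pass
    phi = np.zeros((n, n))
    for j in range(n):
        f, m = fa[j], mo[j]
        if f < 0 and m < 0:
            phi[j, j] = 0.5
        else:
            row_f = phi[f, :j] if f >= 0 else 0.0
            row_m = phi[m, :j] if m >= 0 else 0.0
            phi[j, :j] = 0.5 * (row_f + row_m)
            phi[:j, j] = phi[j, :j]
            phi_fm = phi[f, m] if (f >= 0 and m >= 0) else 0.0
            phi[j, j] = 0.5 * (1.0 + phi_fm)
    return KinshipMatrix(phi, pedigree.ids)
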