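"""PLINK-style genotype quality control.

Filters run in a fixed, logged order mirroring a standard family-GWAS QC:

1. SNP call rate (``--geno``),
2. minor allele frequency (``--maf``),
3. Hardy–Weinberg exact test, founders only by default (``--hwe``),
4. sample call rate (``--mind``),
5. per-individual mean heterozygosity window,
6. Mendelian-inconsistency detection in trios and duos (``--mendel``),
   with flagged child genotypes set to missing.

Boundary conventions follow PLINK: a value *strictly below* a minimum is
removed (MAF exactly at the threshold is kept), and the heterozygosity
window is inclusive at both ends.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .cohort import MISSING, GenotypeMatrix, Pedigree

__all__ = [
    "QcThresholds",
    "QcReport",
    "hwe_exact_test",
    "snp_filters",
    "sample_filters",
    "mendel_check",
    "run_qc",
    "run_two_stage_qc",
]


@dataclass(frozen=True)
class QcThresholds:
    """Filter thresholds; defaults are the conventional PLINK settings."""

    snp_call_rate_min: float = 0.95
    sample_call_rate_min: float = 0.95
    maf_min: float = 0.05
    hwe_p_min: float = 1e-8
    het_window: tuple[float, float] | None = None  # None: mean +/- 3 SD
    hwe_founders_only: bool = True
    hwe_midp: bool = False

    def __post_init__(self) -> None:
        for v in (self.snp_call_rate_min, self.sample_call_rate_min,
                  self.maf_min, self.hwe_p_min):
            if not 0.0 <= v <= 1.0:
                raise ValueError("thresholds must lie in [0, 1]")
        if self.het_window is not None and self.het_window[0] > self.het_window[1]:
            raise ValueError("heterozygosity window lower bound exceeds upper")


@dataclass
class QcReport:
    """Per-filter removal counts plus the surviving registries."""

    n_snps_in: int
    n_samples_in: int
    snps_removed: dict[str, int] = field(default_factory=dict)
    samples_removed: dict[str, int] = field(default_factory=dict)
    kept_snps: list[str] = field(default_factory=list)
    kept_samples: list[str] = field(default_factory=list)
    mendel_errors: list[tuple] = field(default_factory=list)
    filter_order: list[str] = field(default_factory=list)

    def check_counts(self) -> None:
        if sum(self.snps_removed.values()) + len(self.kept_snps) != self.n_snps_in:
            raise AssertionError("SNP removed+kept counts do not add up")
        if (sum(self.samples_removed.values()) + len(self.kept_samples)
                != self.n_samples_in):
            raise AssertionError("sample removed+kept counts do not add up")

    def as_dict(self) -> dict:
        return {
            "n_snps_in": self.n_snps_in,
            "n_samples_in": self.n_samples_in,
            "snps_removed": self.snps_removed,
            "samples_removed": self.samples_removed,
            "n_snps_kept": len(self.kept_snps),
            "n_samples_kept": len(self.kept_samples),
            "n_mendel_errors": len(self.mendel_errors),
            "filter_order": self.filter_order,
        }


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def _hwe_log_probs(n_het_values: np.ndarray, n: int, n_a: int) -> np.ndarray:
    """Log-probabilities of heterozygote counts given allele counts.

    P(n_Aa = h) = n! · n_A! · n_a! · 2^h
                  / [ (2n)! · ((n_A−h)/2)! · h! · ((n_a−h)/2)! ],

    the exact conditional (hypergeometric-type) distribution of the
    heterozygote count given the observed allele counts.
    """
    h = n_het_values
    n_b = 2 * n - n_a
    return (
        gammaln(n + 1) - gammaln((n_a - h) / 2 + 1) - gammaln(h + 1)
        - gammaln((n_b - h) / 2 + 1)
        + h * np.log(2.0)
        + gammaln(n_a + 1) + gammaln(n_b + 1) - gammaln(2 * n + 1)
    )


def hwe_exact_test(n_aa: int, n_ab: int, n_bb: int, midp: bool = False) -> float:
    """Exact conditional test of Hardy–Weinberg equilibrium.

    Sums, over every heterozygote count compatible with the observed
    allele counts, the probabilities of configurations no more probable
    than the observed one.  Monomorphic tables return 1.  ``midp`` applies
    the mid-p correction (half weight on the observed configuration).
    """
    for c in (n_aa, n_ab, n_bb):
        if c < 0 or int(c) != c:
            raise ValueError("genotype counts must be non-negative integers")
    n = n_aa + n_ab + n_bb
    if n < 1:
        raise ValueError("at least one individual required")
    n_a = 2 * n_aa + n_ab  # A-allele count
    if n_a == 0 or n_a == 2 * n:
        return 1.0
    minor = min(n_a, 2 * n - n_a)
    h_values = np.arange(minor % 2, minor + 1, 2)
    logp = _hwe_log_probs(h_values, n, n_a)
    logp -= np.logaddexp.reduce(logp)  # normalise for numerical safety
    obs = np.where(h_values == n_ab)[0][0]
    tail = logp <= logp[obs] + 1e-12
    p = float(np.exp(np.logaddexp.reduce(logp[tail])))
    if midp:
        p -= 0.5 * float(np.exp(logp[obs]))
    return min(p, 1.0)


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def _genotype_counts(dos: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    return ((dos == 2).sum(axis=0), (dos == 1).sum(axis=0), (dos == 0).sum(axis=0))


def snp_filters(
    genotypes: GenotypeMatrix,
    thresholds: QcThresholds,
    pedigree: Pedigree | None = None,
) -> tuple[np.ndarray, dict[str, int]]:
    """SNP-level filters: call rate, then MAF, then HWE.

    HWE is tested in founders only (relatedness inflates rejection) when a
    pedigree is supplied and ``thresholds.hwe_founders_only`` is set.
    Returns a keep-mask over SNPs and the per-filter removal counts.
    """
    dos = genotypes.dosages
    n, m = dos.shape
    removed: dict[str, int] = {}
    keep = np.ones(m, dtype=bool)

    call_rate = (dos != MISSING).mean(axis=0)
    fail = keep & (call_rate < thresholds.snp_call_rate_min)
    removed["snp_call_rate"] = int(fail.sum())
    keep &= ~fail

    with np.errstate(invalid="ignore"):
        freq = genotypes.allele_freq()
    maf = np.minimum(freq, 1.0 - freq)
    maf = np.where(np.isnan(maf), 0.0, maf)
    fail = keep & (maf < thresholds.maf_min)
    removed["maf"] = int(fail.sum())
    keep &= ~fail

    if thresholds.hwe_founders_only and pedigree is not None:
        founder_rows = [k for k, iid in enumerate(genotypes.ids)
                        if iid in set(pedigree.founder_ids)]
        sub = dos[founder_rows]
    else:
        sub = dos
    n_hwe_fail = 0
    for i in np.where(keep)[0]:
        col = sub[:, i]
        col = col[col != MISSING]
        if col.size == 0:
            continue
        p = hwe_exact_test(int((col == 2).sum()), int((col == 1).sum()),
                           int((col == 0).sum()), midp=thresholds.hwe_midp)
        if p < thresholds.hwe_p_min:
            keep[i] = False
            n_hwe_fail += 1
    removed["hwe"] = n_hwe_fail
    return keep, removed


def sample_filters(
    genotypes: GenotypeMatrix,
    thresholds: QcThresholds,
) -> tuple[np.ndarray, dict[str, int], tuple[float, float]]:
    """Sample-level filters: call rate, then the heterozygosity window.

    The window defaults to mean ± 3 SD of the observed per-individual
    heterozygosity (the published 0.31–0.33 window is cohort-specific);
    bounds are inclusive.  Raises if the window would exclude everyone,
    with a small histogram in the message for diagnosis.
    """
    dos = genotypes.dosages
    removed: dict[str, int] = {}
    keep = np.ones(dos.shape[0], dtype=bool)

    call_rate = (dos != MISSING).mean(axis=1)
    fail = call_rate < thresholds.sample_call_rate_min
    removed["sample_call_rate"] = int(fail.sum())
    keep &= ~fail

    non_missing = (dos != MISSING).sum(axis=1)
    het = np.divide((dos == 1).sum(axis=1), non_missing,
                    out=np.zeros(dos.shape[0]), where=non_missing > 0)
    if thresholds.het_window is None:
        ref = het[keep]
        window = (float(ref.mean() - 3 * ref.std()), float(ref.mean() + 3 * ref.std()))
    else:
        window = thresholds.het_window
    fail = keep & ((het < window[0]) | (het > window[1]))
    if (keep & ~fail).sum() == 0:
        counts, edges = np.histogram(het[keep], bins=10)
        hist = ", ".join(
            f"[{edges[k]:.3f},{edges[k + 1]:.3f}):{counts[k]}"
            for k in range(len(counts))
        )
        raise ValueError(
            f"heterozygosity window {window} excludes every sample; "
            f"observed distribution: {hist}"
        )
    removed["heterozygosity"] = int(fail.sum())
    keep &= ~fail
    return keep, removed, window


# ---------------------------------------------------------------------------
# Mendelian consistency
# ---------------------------------------------------------------------------

# child dosages impossible given (father, mother) dosages
_IMPOSSIBLE_TRIO = {
    (0, 0): (1, 2),
    (0, 1): (2,),
    (1, 0): (2,),
    (0, 2): (0, 2),
    (2, 0): (0, 2),
    (1, 2): (0,),
    (2, 1): (0,),
    (2, 2): (0, 1),
    (1, 1): (),
}


def mendel_check(
    genotypes: GenotypeMatrix,
    pedigree: Pedigree,
    set_missing: bool = True,
    max_rounds: int = 10,
) -> tuple[GenotypeMatrix, list[tuple]]:
    """Flag biallelic transmission errors in trios and duos.

    For trios (both parents genotyped) the full impossibility table is
    used; for duos only the opposite-homozygote conflict is checkable.
    Flagged child genotypes are set to missing and the check repeats until
    no new errors appear — an iterated approximation to a full
    multi-generation consistency analysis.

    Returns the (possibly modified) genotype matrix and the error list of
    ``(family, snp_id, child, father, mother)`` tuples.
    """
    dos = genotypes.dosages.copy()
    pos = {iid: k for k, iid in enumerate(genotypes.ids)}
    snp_ids = genotypes.panel.table["snp"].to_numpy()
    errors: list[tuple] = []
    rows = [
        (r.family, r.id, r.father, r.mother)
        for r in pedigree.table.itertuples(index=False)
        if (r.father or r.mother) and r.id in pos
    ]
    for _ in range(max_rounds):
        new_errors: list[tuple] = []
        for fam, child, father, mother in rows:
            c = dos[pos[child]]
            fi = pos.get(father) if father else None
            mi = pos.get(mother) if mother else None
            f = dos[fi] if fi is not None else None
            m = dos[mi] if mi is not None else None
            bad = np.zeros(c.shape, dtype=bool)
            if f is not None and m is not None:
                both = (c != MISSING) & (f != MISSING) & (m != MISSING)
                for (df, dm), impossible in _IMPOSSIBLE_TRIO.items():
                    if not impossible:
                        continue
                    combo = both & (f == df) & (m == dm)
                    for dc in impossible:
                        bad |= combo & (c == dc)
            for parent in (f, m):
                if parent is None:
                    continue
                duo = (c != MISSING) & (parent != MISSING)
                bad |= duo & (parent == 0) & (c == 2)
                bad |= duo & (parent == 2) & (c == 0)
            for i in np.where(bad)[0]:
                new_errors.append((fam, snp_ids[i], child, father, mother))
            if set_missing and bad.any():
                dos[pos[child], bad] = MISSING
        errors.extend(new_errors)
        if not new_errors or not set_missing:
            break
    out = GenotypeMatrix(dos, genotypes.ids, genotypes.panel)
    return out, errors


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def run_qc(
    genotypes: GenotypeMatrix,
    pedigree: Pedigree | None = None,
    thresholds: QcThresholds | None = None,
) -> tuple[GenotypeMatrix, QcReport]:
    """Run the full QC in the declared order and return survivors.

    Order: SNP call rate → MAF → HWE → sample call rate → heterozygosity →
    Mendelian check.  The order matters (e.g. MAF is computed before bad
    samples are dropped) and is recorded in the report.
    """
    thresholds = thresholds or QcThresholds()
    report = QcReport(n_snps_in=genotypes.m, n_samples_in=genotypes.n)
    report.filter_order = [
        "snp_call_rate", "maf", "hwe",
        "sample_call_rate", "heterozygosity", "mendel",
    ]
    keep_snps, snp_removed = snp_filters(genotypes, thresholds, pedigree)
    report.snps_removed.update(snp_removed)
    g = genotypes.subset(keep_snps=keep_snps)

    keep_samples, sample_removed, _ = sample_filters(g, thresholds)
    report.samples_removed.update(sample_removed)
    g = g.subset(keep_ids=[iid for iid, k in zip(g.ids, keep_samples) if k])

    if pedigree is not None:
        g, errors = mendel_check(g, pedigree)
        report.mendel_errors = errors
    report.kept_snps = list(g.panel.table["snp"])
    report.kept_samples = list(g.ids)
    report.check_counts()
    return g, report


def run_two_stage_qc(
    genotypes: GenotypeMatrix,
    pedigree: Pedigree | None = None,
    stage1: QcThresholds | None = None,
    stage2: QcThresholds | None = None,
) -> tuple[GenotypeMatrix, list[QcReport]]:
    """Two-stage QC: a permissive first pass (MAF 1%) then the final pass
    (MAF 5%, call rates 95%, HWE 1e-8), run back to back."""
    stage1 = stage1 or QcThresholds(maf_min=0.01)
    stage2 = stage2 or QcThresholds(maf_min=0.05)
    g1, r1 = run_qc(genotypes, pedigree, stage1)
    g2, r2 = run_qc(g1, pedigree, stage2)
    return g2, [r1, r2]
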