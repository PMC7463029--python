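"""Genotype QC: exact HWE test, filters, Mendelian checks."""

import math

import numpy as np
import pandas as pd
import pytest

from aortaflow.cohort import GenotypeMatrix, SnpPanel, random_panel, simulate_genotypes
from aortaflow.qc import (
    QcThresholds,
    hwe_exact_test,
    mendel_check,
    run_qc,
    sample_filters,
    snp_filters,
)


def hwe_enumeration_oracle(n_aa, n_ab, n_bb):
    """Exact-integer enumeration of the conditional heterozygote distribution.

    Weights w_h = n! 2^h / (n_AA! h! n_bb!) share a common normaliser, so
    the p-value is a ratio of exact integers.
    """
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab
    n_b = 2 * n - n_a
    if n_a == 0 or n_b == 0:
        return 1.0
    minor = min(n_a, n_b)
    weights = {}
    for h in range(minor % 2, minor + 1, 2):
        weights[h] = (math.factorial(n) * 2**h
                      // (math.factorial((n_a - h) // 2)
                          * math.factorial(h)
                          * math.factorial((n_b - h) // 2)))
    w_obs = weights[n_ab]
    num = sum(w for w in weights.values() if w <= w_obs)
    return num / sum(weights.values())


def make_genotypes(dosages, ids=None):
    dosages = np.asarray(dosages, dtype=np.int8)
    n, m = dosages.shape
    ids = ids or [f"i{k}" for k in range(n)]
    panel = SnpPanel(pd.DataFrame({
        "snp": [f"s{j}" for j in range(m)],
        "chrom": 1, "pos": np.arange(1, m + 1),
        "a1": "A", "a2": "G", "freq": np.nan,
    }))
    return GenotypeMatrix(dosages, ids, panel)


class TestHweExact:
    @pytest.mark.parametrize("counts,expected", [
        ((1, 0, 1), 1 / 3),
        ((0, 2, 0), 1.0),
        ((7, 0, 0), 1.0),  # monomorphic
        ((0, 0, 9), 1.0),
    ])
    def test_small_tables(self, counts, expected):
        assert hwe_exact_test(*counts) == pytest.approx(expected, abs=1e-12)

    def test_matches_enumeration_oracle_small(self):
        for n in range(1, 31):
            for n_aa in range(n + 1):
                for n_ab in range(n - n_aa + 1):
                    n_bb = n - n_aa - n_ab
                    got = hwe_exact_test(n_aa, n_ab, n_bb)
                    want = hwe_enumeration_oracle(n_aa, n_ab, n_bb)
                    assert got == pytest.approx(want, rel=1e-9), (n_aa, n_ab, n_bb)

    def test_midp_never_larger(self):
        assert hwe_exact_test(10, 5, 10, midp=True) < hwe_exact_test(10, 5, 10)

    def test_type_one_error_near_nominal(self):
        """SNPs simulated in HWE are rejected at ~5% at alpha = 0.05."""
        rng = np.random.default_rng(12)
        m, n, p = 2000, 500, 0.3
        rejections = 0
        for _ in range(m):
            g = rng.binomial(2, p, size=n)
            pval = hwe_exact_test(int((g == 2).sum()), int((g == 1).sum()),
                                  int((g == 0).sum()))
            rejections += pval < 0.05
        rate = rejections / m
        se = np.sqrt(0.05 * 0.95 / m)
        assert 0.05 - 4 * se <= rate <= 0.05 + 4 * se

    def test_rejects_bad_counts(self):
        with pytest.raises(ValueError):
            hwe_exact_test(-1, 0, 2)
        with pytest.raises(ValueError):
            hwe_exact_test(0, 0, 0)


def eight_snp_fixture():
    """8 SNPs over 40 samples: 1 fails call rate, 2 fail MAF, 1 fails HWE."""
    rng = np.random.default_rng(99)
    n = 40
    dosages = np.zeros((n, 8), dtype=np.int8)
    # s0: call rate 37/40 = 0.925 < 0.95
    dosages[:, 0] = rng.binomial(2, 0.5, n)
    dosages[:3, 0] = -1
    # s1, s2: one alt allele -> MAF 1/80 < 0.05
    dosages[:, 1] = 0
    dosages[0, 1] = 1
    dosages[:, 2] = 0
    dosages[1, 2] = 1
    # s3: every sample heterozygous -> extreme HWE violation
    dosages[:, 3] = 1
    # s4..s7: HWE-consistent, common, complete
    for j in range(4, 8):
        dosages[:, j] = np.sort(rng.binomial(2, 0.5, n))
    return make_genotypes(dosages)


class TestSnpFilters:
    def test_crafted_fixture_retains_four(self):
        g = eight_snp_fixture()
        keep, removed = snp_filters(g, QcThresholds())
        assert removed == {"snp_call_rate": 1, "maf": 2, "hwe": 1}
        assert keep.sum() == 4
        assert list(np.where(~keep)[0]) == [0, 1, 2, 3]

    def test_disabled_thresholds_keep_everything(self):
        g = eight_snp_fixture()
        keep, _ = snp_filters(g, QcThresholds(snp_call_rate_min=0.0,
                                              maf_min=0.0, hwe_p_min=0.0))
        assert keep.all()

    def test_maf_boundary_is_kept(self):
        # 4 of 80 alleles -> MAF exactly 0.05: strict "<" keeps it
        dosages = np.zeros((40, 1), dtype=np.int8)
        dosages[:4, 0] = 1
        g = make_genotypes(dosages)
        keep, _ = snp_filters(g, QcThresholds(hwe_p_min=0.0))
        assert keep[0]

    def test_filter_order_matters(self):
        """MAF uses all samples, including those a later filter removes."""
        n = 20
        dosages = np.zeros((n, 1), dtype=np.int8)
        dosages[0, 0] = 2  # the only carrier: MAF = 2/40 = 0.05 -> kept
        extra = np.tile(np.array([0, 1, 2], dtype=np.int8), (n, 40))[:, :40]
        dosages = np.hstack([dosages, extra])
        dosages[0, 1:] = -1  # carrier fails sample call rate later
        g = make_genotypes(dosages)
        keep_declared, _ = snp_filters(g, QcThresholds(hwe_p_min=0.0))
        assert keep_declared[0]
        # permuted order (samples first) would drop the SNP as monomorphic
        g_after = g.subset(keep_ids=[i for i in g.ids if i != "i0"])
        keep_permuted, _ = snp_filters(g_after, QcThresholds(hwe_p_min=0.0))
        assert not keep_permuted[0]


class TestSampleFilters:
    def test_all_missing_sample_removed(self):
        dosages = np.ones((10, 20), dtype=np.int8)
        dosages[3, :] = -1
        g = make_genotypes(dosages)
        keep, removed, _ = sample_filters(
            g, QcThresholds(het_window=(0.0, 1.0)))
        assert not keep[3]
        assert removed["sample_call_rate"] == 1

    def test_het_window_boundaries_inclusive(self):
        dosages = np.zeros((3, 100), dtype=np.int8)
        dosages[0, :31] = 1  # het 0.31: boundary, retained
        dosages[1, :30] = 1  # het 0.30: below, removed
        dosages[2, :33] = 1  # het 0.33: boundary, retained
        g = make_genotypes(dosages)
        keep, removed, _ = sample_filters(
            g, QcThresholds(het_window=(0.31, 0.33)))
        assert list(keep) == [True, False, True]

    def test_expected_het_of_balanced_founders(self):
        rng = np.random.default_rng(3)
        dosages = rng.binomial(2, 0.5, size=(50, 2000)).astype(np.int8)
        g = make_genotypes(dosages)
        # window recentred at the binomial expectation 0.5 keeps everyone
        keep, _, _ = sample_filters(g, QcThresholds(het_window=(0.45, 0.55)))
        assert keep.all()
        # the published window is dataset-specific and excludes p=0.5 founders
        with pytest.raises(ValueError, match="excludes every sample"):
            sample_filters(g, QcThresholds(het_window=(0.31, 0.33)))


class TestMendel:
    def test_trio_combinations(self, trio_pedigree):
        # parents AA (dosage 2) x AA: child het impossible; AA x aa: het obligate
        dosages = np.array([
            [2, 2],
            [2, 0],
            [1, 1],
            [2, 1],
        ], dtype=np.int8)
        g = GenotypeMatrix(dosages, trio_pedigree.ids,
                           make_genotypes(dosages).panel)
        out, errors = mendel_check(g, trio_pedigree)
        flagged = {(e[1], e[2]) for e in errors}
        assert ("s0", "kid1") in flagged  # (2,2) -> 1 impossible
        assert ("s1", "kid1") not in flagged  # (2,0) -> 1 obligate
        assert ("s1", "kid2") not in flagged
        assert out.dosages[2, 0] == -1  # blanked

    def test_clean_gene_drop_has_no_errors(self, cohort_pedigree):
        panel = random_panel(300, seed=8)
        g = simulate_genotypes(cohort_pedigree, panel, seed=8)
        _, errors = mendel_check(g, cohort_pedigree)
        assert errors == []

    def test_injected_errors_exactly_recovered(self, cohort_pedigree):
        from aortaflow.qc import _IMPOSSIBLE_TRIO

        panel = random_panel(400, seed=9)
        g = simulate_genotypes(cohort_pedigree, panel, seed=9)
        t = cohort_pedigree.table
        has_children = set(t["father"]) | set(t["mother"])
        leaves = [k for k, r in enumerate(t.itertuples())
                  if r.father and r.id not in has_children]
        pos = {iid: k for k, iid in enumerate(g.ids)}
        dos = g.dosages.copy()
        rng = np.random.default_rng(10)
        injected = set()
        while len(injected) < 50:
            j = int(rng.choice(leaves))
            s = int(rng.integers(g.m))
            row = t.iloc[j]
            f = dos[pos[row.father], s]
            m = dos[pos[row.mother], s]
            if f < 0 or m < 0 or (j, s) in injected:
                continue
            impossible = _IMPOSSIBLE_TRIO[(int(f), int(m))]
            if not impossible:
                continue
            dos[j, s] = impossible[0]
            injected.add((j, s))
        g2 = GenotypeMatrix(dos, g.ids, g.panel)
        _, errors = mendel_check(g2, cohort_pedigree)
        snp_pos = {s: k for k, s in enumerate(g.panel.table["snp"])}
        flagged = {(pos[e[2]], snp_pos[e[1]]) for e in errors}
        assert flagged == injected


class TestRunQc:
    def test_counts_are_conserved(self, cohort_pedigree):
        panel = random_panel(300, seed=11, maf_range=(0.02, 0.5))
        g = simulate_genotypes(cohort_pedigree, panel, missing_rate=0.03, seed=11)
        kept, report = run_qc(g, cohort_pedigree, QcThresholds())
        report.check_counts()
        assert kept.m == len(report.kept_snps)
        assert kept.n == len(report.kept_samples)
        assert report.filter_order[0] == "snp_call_rate"
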