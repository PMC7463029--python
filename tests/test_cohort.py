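"""Synthetic-cohort generators: structure, genetics, calibration."""

import numpy as np
import pytest

from aortaflow.cohort import (
    StructureConfig,
    SubjectProfile,
    TraitSpec,
    cohort_profiles,
    random_panel,
    simulate_covariates,
    simulate_flow_series,
    simulate_genotypes,
    simulate_pedigrees,
    simulate_trait,
)
from aortaflow.flow import flow_metrics
from aortaflow.kinship import kinship_matrix


class TestPedigrees:
    def test_cohort_scale_phenotyped_count(self, cohort_pedigree):
        """108 families yield ~341 phenotyped members (within 15%)."""
        n = len(cohort_pedigree.phenotyped_ids)
        assert 341 * 0.85 <= n <= 341 * 1.15

    def test_forced_structure(self):
        cfg = StructureConfig(sibship_probs={3: 1.0}, grandparent_prob=0.0)
        ped = simulate_pedigrees(1, cfg, seed=0)
        assert ped.n == 5  # two parents + three sibs
        assert sum(ped.table["proband"]) == 1

    def test_every_family_has_min_sibship_and_proband(self, cohort_pedigree):
        t = cohort_pedigree.table
        for fam, grp in t.groupby("family"):
            sibs = grp[grp["father"] != ""]
            # sibship = children of the parent couple (exclude gp->mother link)
            core = sibs[sibs["id"].str.contains("_S")]
            assert len(core) >= 3
            assert grp["proband"].sum() == 1

    def test_determinism(self):
        a = simulate_pedigrees(10, seed=7).table
        b = simulate_pedigrees(10, seed=7).table
        assert a.to_csv() == b.to_csv()
        c = simulate_pedigrees(10, seed=8).table
        assert a.to_csv() != c.to_csv()

    def test_invalid_sibship_distribution(self):
        with pytest.raises(ValueError, match="sum to 1"):
            StructureConfig(sibship_probs={3: 0.5, 4: 0.2})
        with pytest.raises(ValueError, match="min_sibship"):
            StructureConfig(sibship_probs={2: 1.0}, min_sibship=3)


class TestGenotypes:
    def test_homozygous_parents_transmit_only_their_allele(self, trio_pedigree):
        panel = random_panel(500, seed=1)
        g = simulate_genotypes(trio_pedigree, panel, seed=1)
        dad, mum, k1, k2 = g.dosages
        both_zero = (dad == 0) & (mum == 0)
        assert (k1[both_zero] == 0).all() and (k2[both_zero] == 0).all()
        both_two = (dad == 2) & (mum == 2)
        assert (k1[both_two] == 2).all() and (k2[both_two] == 2).all()
        opposite = ((dad == 0) & (mum == 2)) | ((dad == 2) & (mum == 0))
        assert (k1[opposite] == 1).all()

    def test_founder_mean_dosage(self):
        import pandas as pd

        from aortaflow.cohort import Pedigree

        rows = [("F1", f"i{k}", "", "", "male", True, True, False, 0)
                for k in range(20)]
        ped = Pedigree(pd.DataFrame(rows, columns=Pedigree.COLUMNS))
        panel = random_panel(10_000, seed=2, maf_range=(0.5, 0.5))
        g = simulate_genotypes(ped, panel, seed=2)
        assert g.dosages.mean() == pytest.approx(1.0, abs=0.02)

    def test_fullsib_dosage_correlation(self, trio_pedigree):
        """Empirical sib dosage correlation approximates 2*phi = 0.5."""
        panel = random_panel(20_000, seed=3, maf_range=(0.5, 0.5))
        g = simulate_genotypes(trio_pedigree, panel, seed=3)
        corr = np.corrcoef(g.dosages[2], g.dosages[3])[0, 1]
        assert corr == pytest.approx(0.5, abs=0.02)

    def test_allele_frequency_conserved(self, cohort_pedigree):
        """Gene dropping conserves founder frequencies in expectation."""
        panel = random_panel(1000, seed=4, maf_range=(0.2, 0.4))
        g = simulate_genotypes(cohort_pedigree, panel, seed=4)
        # aggregate over SNPs: mean deviation scaled by per-SNP SE
        p0 = panel.freq
        p_hat = g.allele_freq()
        se = np.sqrt(p0 * (1 - p0) / (2 * g.n))
        z = (p_hat - p0) / se
        assert abs(z.mean()) < 3 / np.sqrt(panel.m) * 3

    def test_missingness_rate(self, cohort_pedigree):
        panel = random_panel(500, seed=5)
        g = simulate_genotypes(cohort_pedigree, panel, missing_rate=0.05, seed=5)
        assert g.missing_mask().mean() == pytest.approx(0.05, abs=0.01)


class TestCovariates:
    def test_moments(self, cohort_pedigree):
        covs = [simulate_covariates(cohort_pedigree, seed=s) for s in range(12)]
        bmi = np.concatenate([c["bmi"] for c in covs])
        assert bmi.size > 5000
        assert bmi.mean() == pytest.approx(25.88, abs=0.15)
        assert bmi.std() == pytest.approx(3.77, abs=0.2)
        sbp = np.concatenate([c["sbp"] for c in covs])
        assert sbp.mean() == pytest.approx(139.71, abs=1.0)

    def test_hypertension_ascertainment(self, cohort_pedigree):
        rates = []
        for s in range(10):
            cov = simulate_covariates(cohort_pedigree, seed=100 + s)
            pro = cohort_pedigree.table["proband"].to_numpy()
            assert cov.loc[pro, "hypertension"].all()
            rates.append(cov.loc[cov["phenotyped"], "hypertension"].mean())
        assert np.mean(rates) == pytest.approx(0.39, abs=0.03)

    def test_age_within_range(self, cohort_pedigree):
        cov = simulate_covariates(cohort_pedigree, seed=0)
        assert cov["age"].between(19, 73).all()


class TestTraits:
    def test_spec_identity_and_validation(self):
        spec = TraitSpec(h2=0.37, total_var=2.5)
        assert spec.sigma2_g / (spec.sigma2_g + spec.sigma2_e) == pytest.approx(
            0.37, abs=1e-12)
        with pytest.raises(ValueError):
            TraitSpec(h2=1.2)

    def test_total_variance_decomposition(self, cohort_pedigree, cohort_kinship):
        """var(g) + var(e) reproduces the target total variance."""
        vs = [
            np.var(simulate_trait(cohort_pedigree, cohort_kinship,
                                  TraitSpec(0.4), seed=s))
            for s in range(200)
        ]
        assert np.mean(vs) == pytest.approx(1.0, abs=0.05)

    def test_fullsib_correlation_tracks_h2(self, trio_pedigree):
        """Sib trait correlation ~ 2*phi*h2 = 0.4 at h2 = 0.8."""
        kin = kinship_matrix(trio_pedigree)
        sims = np.array([
            simulate_trait(trio_pedigree, kin, TraitSpec(0.8), seed=s)
            for s in range(4000)
        ])
        corr = np.corrcoef(sims[:, 2], sims[:, 3])[0, 1]
        assert corr == pytest.approx(0.4, abs=0.05)

    def test_zero_h2_trait_ignores_kinship(self, trio_pedigree):
        kin = kinship_matrix(trio_pedigree)
        sims = np.array([
            simulate_trait(trio_pedigree, kin, TraitSpec(0.0), seed=s)
            for s in range(2000)
        ])
        corr = np.corrcoef(sims[:, 2], sims[:, 3])[0, 1]
        assert abs(corr) < 0.05

    def test_causal_snp_mode_hits_sigma2g(self, cohort_pedigree, cohort_kinship):
        panel = random_panel(500, seed=6)
        g = simulate_genotypes(cohort_pedigree, panel, seed=6)
        spec = TraitSpec(0.6, mode="causal-snp")
        rng_y = simulate_trait(cohort_pedigree, cohort_kinship, spec, seed=6,
                               genotypes=g)
        assert np.isfinite(rng_y).all()
        # realised genetic variance is rescaled to sigma2_g exactly
        y2 = simulate_trait(cohort_pedigree, cohort_kinship,
                            TraitSpec(1.0, mode="causal-snp"), seed=6,
                            genotypes=g)
        assert np.var(y2) == pytest.approx(1.0, rel=1e-6)


class TestFlowPhantoms:
    def test_noise_free_parabolic_apex(self):
        # odd grid puts a pixel exactly on the axis
        prof = SubjectProfile(radius_mm=20.0, peak_velocity=1.0, grid=65,
                              pixel_spacing_mm=1.25, noise_sd=0.0)
        series = simulate_flow_series(prof, seed=0)
        assert series.frames.max() == pytest.approx(1.0, abs=1e-12)

    def test_determinism(self):
        prof = SubjectProfile(noise_sd=0.02)
        a = simulate_flow_series(prof, seed=9)
        b = simulate_flow_series(prof, seed=9)
        np.testing.assert_array_equal(a.frames, b.frames)

    def test_radius_exceeding_grid(self):
        with pytest.raises(ValueError, match="radius"):
            simulate_flow_series(SubjectProfile(radius_mm=50.0, grid=64), seed=0)

    def test_cohort_calibration(self):
        """Cohort defaults reproduce the target flow means."""
        profs = cohort_profiles(300, seed=11)
        u_pm, u_max, d = [], [], []
        for k, p in enumerate(profs):
            fm = flow_metrics(simulate_flow_series(p, seed=k))
            u_pm.append(fm.u_pm)
            u_max.append(fm.u_max)
            d.append(fm.diameter_m)
        assert np.mean(u_pm) == pytest.approx(0.450, abs=0.03)
        assert np.mean(u_max) == pytest.approx(0.793, abs=0.05)
        assert np.mean(d) == pytest.approx(0.031, abs=0.002)
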