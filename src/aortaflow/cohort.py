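"""Synthetic family cohort with known genetic ground truth.

Generates every input the downstream pipeline consumes, without any
external data:

* extended pedigrees ascertained through a hypertensive proband, with
  sibships of three or more (``simulate_pedigrees``);
* biallelic SNP genotypes: founders drawn in Hardy–Weinberg equilibrium and
  transmitted down the pedigree by gene dropping (``simulate_genotypes``);
* covariates with realistic moments — BMI ~ N(25.88, 3.77²),
  systolic BP ~ N(139.71, 21.83²), ~49% male, ~39% hypertensive with the
  proband always hypertensive (``simulate_covariates``);
* quantitative traits with a configurable additive polygenic fraction h²,
  either kinship-MVN or built from causal SNPs (``simulate_trait``);
* pulsatile cross-sectional velocity cines whose cohort defaults are
  calibrated to reproduce typical ascending-aortic values
  (U_pm ≈ 0.45 m/s, U_max ≈ 0.79 m/s, D ≈ 0.031 m)
  (``simulate_flow_series``, ``cohort_profiles``).

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .flow import CineFlowSeries

__all__ = [
    "StructureConfig",
    "Pedigree",
    "SnpPanel",
    "GenotypeMatrix",
    "TraitSpec",
    "SubjectProfile",
    "simulate_pedigrees",
    "simulate_genotypes",
    "simulate_covariates",
    "simulate_trait",
    "simulate_flow_series",
    "cohort_profiles",
    "random_panel",
]


# ---------------------------------------------------------------------------
# pedigrees
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StructureConfig:
    """Family-structure and ascertainment configuration.

    The default family is (optional grandparent couple) → parent couple →
    sibship of ≥ ``min_sibship`` drawn from ``sibship_probs``; spouses are
    unrelated founders.  One sib per family is the proband (always
    phenotyped, always hypertensive); other members are phenotyped with
    generation-specific probabilities reflecting attendance at imaging.
    """

    sibship_probs: dict[int, float] = field(
        default_factory=lambda: {3: 0.5, 4: 0.3, 5: 0.2}
    )
    min_sibship: int = 3
    grandparent_prob: float = 0.3
    pheno_prob_sib: float = 0.65
    pheno_prob_parent: float = 0.20
    pheno_prob_grandparent: float = 0.05
    male_prob: float = 0.49

    def __post_init__(self) -> None:
        probs = np.array(list(self.sibship_probs.values()), dtype=float)
        if probs.size == 0 or not np.isclose(probs.sum(), 1.0):
            raise ValueError("sibship-size probabilities must sum to 1")
        if (probs < 0).any():
            raise ValueError("sibship-size probabilities must be non-negative")
        if any(k < self.min_sibship for k in self.sibship_probs):
            raise ValueError(f"all sibship sizes must be >= min_sibship={self.min_sibship}")

    @property
    def mean_sibship(self) -> float:
        return float(sum(k * v for k, v in self.sibship_probs.items()))

    @property
    def expected_phenotyped_per_family(self) -> float:
        """Expected phenotyped members per family (proband always counts)."""
        sibs = 1.0 + (self.mean_sibship - 1.0) * self.pheno_prob_sib
        parents = 2.0 * self.pheno_prob_parent
        gps = self.grandparent_prob * 2.0 * self.pheno_prob_grandparent
        return sibs + parents + gps


class Pedigree:
    """A set of families stored as a flat table.

    Columns: ``family, id, father, mother, sex, founder, phenotyped,
    proband, generation``.  Parent ids are empty strings for founders.
    Rows are in topological order (parents precede children).
    """

    COLUMNS = [
        "family", "id", "father", "mother", "sex",
        "founder", "phenotyped", "proband", "generation",
    ]

    def __init__(self, table: pd.DataFrame):
        missing = set(self.COLUMNS) - set(table.columns)
        if missing:
            raise ValueError(f"pedigree table missing columns: {sorted(missing)}")
        self.table = table.reset_index(drop=True)
        self._validate()

    def _validate(self) -> None:
        ids = set(self.table["id"])
        if len(ids) != len(self.table):
            raise ValueError("duplicate individual ids")
        seen: set[str] = set()
        for row in self.table.itertuples(index=False):
            for parent in (row.father, row.mother):
                if parent:
                    if parent not in ids:
                        raise ValueError(f"unknown parent {parent!r} of {row.id!r}")
                    if parent not in seen:
                        raise ValueError(
                            "pedigree rows are not topologically ordered "
                            f"(parent {parent!r} after child {row.id!r}); "
                            "a cycle or mis-sorted table"
                        )
            if bool(row.founder) != (not row.father and not row.mother):
                raise ValueError(f"founder flag inconsistent for {row.id!r}")
            seen.add(row.id)

    # -- convenience accessors ------------------------------------------------
    @property
    def ids(self) -> list[str]:
        return list(self.table["id"])

    @property
    def n(self) -> int:
        return len(self.table)

    @property
    def families(self) -> list[str]:
        return list(dict.fromkeys(self.table["family"]))

    @property
    def founder_ids(self) -> list[str]:
        return list(self.table.loc[self.table["founder"], "id"])

    @property
    def phenotyped_ids(self) -> list[str]:
        return list(self.table.loc[self.table["phenotyped"], "id"])

    def parent_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """Row indices of (father, mother) per individual; -1 for founders."""
        pos = {iid: k for k, iid in enumerate(self.table["id"])}
        fa = np.array([pos.get(f, -1) if f else -1 for f in self.table["father"]])
        mo = np.array([pos.get(m, -1) if m else -1 for m in self.table["mother"]])
        return fa, mo

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "Pedigree":
        t = pd.read_csv(path, sep="\t", keep_default_na=False, dtype={
            "family": str, "id": str, "father": str, "mother": str, "sex": str,
        })
        for col in ("founder", "phenotyped", "proband"):
            t[col] = t[col].astype(bool)
        return cls(t)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"<Pedigree: {len(self.families)} families, {self.n} individuals, "
                f"{len(self.phenotyped_ids)} phenotyped>")


def simulate_pedigrees(
    n_families: int,
    config: StructureConfig | None = None,
    seed: int = 0,
) -> Pedigree:
    """Generate ``n_families`` extended families.

    Each family has a sibship of at least ``config.min_sibship``, with one
    sib designated the proband.  Deterministic under a fixed seed.
    """
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    config = config or StructureConfig()
    rng = np.random.default_rng(seed)
    sizes = np.array(list(config.sibship_probs.keys()))
    probs = np.array(list(config.sibship_probs.values()), dtype=float)
    probs = probs / probs.sum()

    rows: list[tuple] = []
    for f in range(n_families):
        fam = f"F{f + 1:04d}"
        gen0: list[tuple[str, str]] = []  # (id, sex) of the grandparent couple
        has_gp = rng.random() < config.grandparent_prob
        if has_gp:
            gpf, gpm = f"{fam}_GF", f"{fam}_GM"
            for iid, sex in ((gpf, "male"), (gpm, "female")):
                pheno = rng.random() < config.pheno_prob_grandparent
                rows.append((fam, iid, "", "", sex, True, pheno, False, 0))
            gen0 = [(gpf, gpm)]
        # parent couple: the mother descends from the grandparents if present
        fa_id, mo_id = f"{fam}_P1", f"{fam}_P2"
        parent_gen = 1 if has_gp else 0
        rows.append((fam, fa_id, "", "", "male", True,
                     rng.random() < config.pheno_prob_parent, False, parent_gen))
        if has_gp:
            rows.append((fam, mo_id, gen0[0][0], gen0[0][1], "female", False,
                         rng.random() < config.pheno_prob_parent, False, parent_gen))
        else:
            rows.append((fam, mo_id, "", "", "female", True,
                         rng.random() < config.pheno_prob_parent, False, parent_gen))
        n_sibs = int(rng.choice(sizes, p=probs))
        proband_idx = int(rng.integers(n_sibs))
        for s in range(n_sibs):
            iid = f"{fam}_S{s + 1}"
            sex = "male" if rng.random() < config.male_prob else "female"
            is_proband = s == proband_idx
            pheno = is_proband or (rng.random() < config.pheno_prob_sib)
            rows.append((fam, iid, fa_id, mo_id, sex, False, pheno,
                         is_proband, parent_gen + 1))
    table = pd.DataFrame(rows, columns=Pedigree.COLUMNS)
    return Pedigree(table)


# ---------------------------------------------------------------------------
# SNP panel and genotypes
# ---------------------------------------------------------------------------

@dataclass
class SnpPanel:
    """SNP metadata: id, chromosome, position, alleles, founder frequency."""

    table: pd.DataFrame  # columns: snp, chrom, pos, a1, a2, freq

    COLUMNS = ["snp", "chrom", "pos", "a1", "a2", "freq"]

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.table.columns)
        if missing:
            raise ValueError(f"panel missing columns: {sorted(missing)}")
        self.table = self.table.reset_index(drop=True)
        for _, grp in self.table.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.unique(pos).size != pos.size:
                raise ValueError("duplicate positions within a chromosome")
        freq = self.table["freq"].to_numpy(dtype=float)
        if np.isfinite(freq).all() and ((freq <= 0) | (freq >= 1)).any():
            raise ValueError("simulated founder frequencies must lie in (0, 1)")

    @property
    def m(self) -> int:
        return len(self.table)

    @property
    def freq(self) -> np.ndarray:
        return self.table["freq"].to_numpy(dtype=float)

    def subset(self, keep: np.ndarray) -> "SnpPanel":
        return SnpPanel(self.table.loc[keep].reset_index(drop=True))


def random_panel(
    m: int,
    seed: int = 0,
    maf_range: tuple[float, float] = (0.05, 0.5),
    n_chrom: int = 22,
) -> SnpPanel:
    """A panel of ``m`` independent SNPs with uniform founder MAF."""
    rng = np.random.default_rng(seed)
    freq = rng.uniform(*maf_range, size=m)
    chrom = np.sort(rng.integers(1, n_chrom + 1, size=m))
    pos = np.empty(m, dtype=int)
    for c in np.unique(chrom):
        idx = np.where(chrom == c)[0]
        draw = np.unique(rng.integers(1, 250_000_000, size=idx.size))
        while draw.size < idx.size:  # top up the rare collisions
            extra = rng.integers(1, 250_000_000, size=idx.size - draw.size)
            draw = np.unique(np.concatenate([draw, extra]))
        pos[idx] = np.sort(draw)
    table = pd.DataFrame({
        "snp": [f"snp{i + 1}" for i in range(m)],
        "chrom": chrom,
        "pos": pos,
        "a1": "A",
        "a2": "G",
        "freq": freq,
    })
    return SnpPanel(table)


MISSING = -1  # sentinel dosage for a missing genotype


@dataclass
class GenotypeMatrix:
    """Dosage matrix (individuals × SNPs), values {0, 1, 2, -1=missing}.

    Dosage counts copies of the panel's A1 allele.  Row/column registries
    align with a :class:`Pedigree` and a :class:`SnpPanel`.
    """

    dosages: np.ndarray  # int8, shape (n, m)
    ids: list[str]
    panel: SnpPanel

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.shape != (len(self.ids), self.panel.m):
            raise ValueError("dosage matrix shape does not match registries")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def m(self) -> int:
        return self.panel.m

    def missing_mask(self) -> np.ndarray:
        return self.dosages == MISSING

    def allele_freq(self) -> np.ndarray:
        """Sample A1 allele frequency per SNP over non-missing genotypes."""
        d = self.dosages.astype(float)
        d[self.missing_mask()] = np.nan
        with np.errstate(invalid="ignore"):
            return np.nanmean(d, axis=0) / 2.0

    def subset(self, keep_ids=None, keep_snps=None) -> "GenotypeMatrix":
        dos, ids, panel = self.dosages, self.ids, self.panel
        if keep_ids is not None:
            pos = {iid: k for k, iid in enumerate(ids)}
            rows = [pos[i] for i in keep_ids]
            dos = dos[rows]
            ids = list(keep_ids)
        if keep_snps is not None:
            keep_snps = np.asarray(keep_snps)
            if keep_snps.dtype == bool:
                idx = np.where(keep_snps)[0]
            else:
                idx = keep_snps
            dos = dos[:, idx]
            panel = panel.subset(idx)
        return GenotypeMatrix(dos.copy(), ids, panel)


def simulate_genotypes(
    pedigree: Pedigree,
    panel: SnpPanel,
    missing_rate: float = 0.0,
    seed: int = 0,
) -> GenotypeMatrix:
    """Gene-drop genotypes through a pedigree.

    Founders receive two alleles i.i.d. Bernoulli(p_i); every non-founder
    inherits one allele from each parent, chosen uniformly at random
    (Mendelian segregation).  Missingness is then applied at
    ``missing_rate`` uniformly at random.
    """
    if panel.m == 0:
        raise ValueError("SNP panel is empty")
    if not 0 <= missing_rate < 1:
        raise ValueError("missing_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    n, m = pedigree.n, panel.m
    fa, mo = pedigree.parent_indices()
    p = panel.freq
    hap = np.zeros((2, n, m), dtype=np.int8)
    for j in range(n):
        if fa[j] < 0:  # founder
            hap[0, j] = rng.random(m) < p
            hap[1, j] = rng.random(m) < p
        else:
            pick_f = rng.integers(0, 2, size=m)
            pick_m = rng.integers(0, 2, size=m)
            hap[0, j] = np.where(pick_f == 0, hap[0, fa[j]], hap[1, fa[j]])
            hap[1, j] = np.where(pick_m == 0, hap[0, mo[j]], hap[1, mo[j]])
    dosages = (hap[0] + hap[1]).astype(np.int8)
    if missing_rate > 0:
        dosages[rng.random((n, m)) < missing_rate] = MISSING
    return GenotypeMatrix(dosages, pedigree.ids, panel)


# ---------------------------------------------------------------------------
# covariates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CovariateConfig:
    """Moments of the simulated covariate distributions."""

    bmi_mean: float = 25.88
    bmi_sd: float = 3.77
    sbp_mean: float = 139.71
    sbp_sd: float = 21.83
    hypertension_rate: float = 0.39
    age_range: tuple[float, float] = (19.0, 73.0)
    sibling_age_mean: float = 48.0
    sibling_age_sd: float = 8.0
    generation_gap_mean: float = 28.0
    generation_gap_sd: float = 4.0


def simulate_covariates(
    pedigree: Pedigree,
    seed: int = 0,
    config: CovariateConfig | None = None,
) -> pd.DataFrame:
    """Simulate per-individual covariates.

    Ages follow the generational structure: sibship members are centred near
    48 y and each parent generation is ~28 y older, clipped to the
    configured range.  Hypertension is calibrated so that the *phenotyped*
    cohort is hypertensive at the configured rate, with probands always
    hypertensive (the ascertainment rule).
    """
    config = config or CovariateConfig()
    rng = np.random.default_rng(seed)
    t = pedigree.table
    n = pedigree.n

    # ages: draw sib-generation anchors per family, derive other generations
    age = np.empty(n)
    sib_gen = t.groupby("family")["generation"].transform("max").to_numpy()
    fam_codes, fam_idx = np.unique(t["family"], return_inverse=True)
    anchors = rng.normal(config.sibling_age_mean, config.sibling_age_sd,
                         size=fam_codes.size)
    gaps = rng.normal(config.generation_gap_mean, config.generation_gap_sd, size=n)
    noise = rng.normal(0.0, 3.0, size=n)
    gen = t["generation"].to_numpy()
    age = anchors[fam_idx] + (sib_gen - gen) * gaps + np.where(gen == sib_gen, noise, 0.0)
    age = np.clip(age, *config.age_range)

    bmi = rng.normal(config.bmi_mean, config.bmi_sd, size=n)
    bmi = np.clip(bmi, 14.0, None)
    sbp = rng.normal(config.sbp_mean, config.sbp_sd, size=n)
    sbp = np.clip(sbp, 70.0, None)

    proband = t["proband"].to_numpy(dtype=bool)
    pheno = t["phenotyped"].to_numpy(dtype=bool)
    # rate among non-probands solving the phenotyped-cohort mixture
    f_pro = proband[pheno].mean() if pheno.any() else 0.0
    base = max(0.0, (config.hypertension_rate - f_pro) / max(1.0 - f_pro, 1e-12))
    hyper = rng.random(n) < base
    hyper[proband] = True

    sex01 = (t["sex"] == "male").astype(int).to_numpy()
    return pd.DataFrame({
        "family": t["family"],
        "id": t["id"],
        "sex": sex01,
        "age": age,
        "age2": (age - age.mean()) ** 2,
        "bmi": bmi,
        "sbp": sbp,
        "hypertension": hyper.astype(int),
        "phenotyped": pheno,
    })


# ---------------------------------------------------------------------------
# heritable traits
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TraitSpec:
    """Additive polygenic trait specification.

    ``h2`` is the narrow-sense heritability σ²g/(σ²g+σ²e); variances are
    derived from (h2, total_var) so the identity holds exactly.  ``mode``
    selects how the genetic value g is generated: ``"kinship"`` draws
    g ~ MVN(0, 2Φσ²g) per family; ``"causal-snp"`` sums effects of causal
    SNPs drawn from the genotyped panel and rescales to σ²g.
    """

    h2: float
    total_var: float = 1.0
    betas: dict[str, float] = field(default_factory=dict)
    mode: str = "kinship"
    n_causal: int = 100

    def __post_init__(self) -> None:
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError("h2 must lie in [0, 1]")
        if self.total_var <= 0:
            raise ValueError("total variance must be positive")
        if self.mode not in ("kinship", "causal-snp"):
            raise ValueError(f"unknown trait mode {self.mode!r}")

    @property
    def sigma2_g(self) -> float:
        return self.h2 * self.total_var

    @property
    def sigma2_e(self) -> float:
        return (1.0 - self.h2) * self.total_var


def simulate_trait(
    pedigree: Pedigree,
    kinship,
    spec: TraitSpec,
    covariates: pd.DataFrame | None = None,
    seed: int = 0,
    genotypes: GenotypeMatrix | None = None,
) -> np.ndarray:
    """Simulate y = Σβ·covariate + g + e for every pedigree member.

    ``kinship`` is a :class:`aortaflow.kinship.KinshipMatrix` aligned with
    the pedigree.  In causal-SNP mode ``genotypes`` must be supplied and
    the realised genetic values are rescaled so their sample variance is
    exactly σ²g.
    """
    rng = np.random.default_rng(seed)
    n = pedigree.n
    if spec.mode == "kinship":
        if list(kinship.ids) != pedigree.ids:
            raise ValueError("kinship registry must match the pedigree")
        g = np.zeros(n)
        if spec.sigma2_g > 0:
            pos = {iid: k for k, iid in enumerate(pedigree.ids)}
            for fam in pedigree.families:
                idx = [pos[i] for i in
                       pedigree.table.loc[pedigree.table["family"] == fam, "id"]]
                cov = 2.0 * kinship.phi[np.ix_(idx, idx)] * spec.sigma2_g
                # guard: 2*phi must be PSD; a failure signals a kinship bug
                try:
                    chol = np.linalg.cholesky(cov + 1e-12 * np.eye(len(idx)))
                except np.linalg.LinAlgError as exc:
                    raise ValueError("2*Phi is not positive semi-definite") from exc
                g[idx] = chol @ rng.standard_normal(len(idx))
    else:
        if genotypes is None:
            raise ValueError("causal-snp mode requires genotypes")
        if genotypes.ids != pedigree.ids:
            raise ValueError("genotype registry must match the pedigree")
        m = genotypes.m
        k = min(spec.n_causal, m)
        causal = rng.choice(m, size=k, replace=False)
        eff = rng.standard_normal(k)
        dos = genotypes.dosages[:, causal].astype(float)
        dos[dos == MISSING] = np.nan
        col_mean = np.nanmean(dos, axis=0)
        dos = np.where(np.isnan(dos), col_mean, dos)
        g = (dos - col_mean) @ eff
        sd = g.std()
        if spec.sigma2_g > 0 and sd > 0:
            g = g * np.sqrt(spec.sigma2_g) / sd
        else:
            g = np.zeros(n)
    e = rng.normal(0.0, np.sqrt(spec.sigma2_e), size=n) if spec.sigma2_e > 0 else np.zeros(n)
    y = g + e
    if spec.betas:
        if covariates is None:
            raise ValueError("covariate effects requested without a covariate table")
        cov = covariates.set_index("id").loc[pedigree.ids]
        for name, beta in spec.betas.items():
            col = cov[name].to_numpy(dtype=float)
            sd = col.std()
            y = y + beta * ((col - col.mean()) / sd if sd > 0 else 0.0)
    return y


# ---------------------------------------------------------------------------
# velocity-cine phantoms
# ---------------------------------------------------------------------------

def _default_waveform(n_frames: int, systolic_fraction: float = 0.35,
                      diastolic_level: float = 0.05) -> np.ndarray:
    """Half-sine systolic pulse followed by low diastolic flow; peak = 1."""
    t = np.arange(n_frames) / n_frames
    w = np.where(
        t < systolic_fraction,
        np.sin(np.pi * t / systolic_fraction),
        diastolic_level,
    )
    w = np.maximum(w, 0.0)
    return w / w.max()  # systolic peak exactly 1


@dataclass(frozen=True)
class SubjectProfile:
    """Geometry and flow parameters of one synthetic subject.

    ``profile_exponent`` k sets the radial velocity profile
    u(r) = v_c (1 − (r/R)^k); k = 2 is Poiseuille (parabolic), larger k a
    flattened, more plug-like profile as seen in large arteries.
    """

    radius_mm: float = 15.5
    peak_velocity: float = 0.79  # centreline velocity at peak systole, m/s
    profile_exponent: float = 2.0
    noise_sd: float = 0.0  # Gaussian pixel noise, m/s
    grid: int = 64
    pixel_spacing_mm: float = 1.25
    n_frames: int = 30
    frame_interval_ms: float = 30.0
    systolic_fraction: float = 0.35


def simulate_flow_series(profile: SubjectProfile, seed: int = 0) -> CineFlowSeries:
    """Render a pulsatile velocity cine for one subject.

    A disc-shaped lumen mask of the requested radius; per-frame velocity is
    waveform(t) × radial profile plus i.i.d. Gaussian pixel noise.
    """
    g = profile.grid
    radius_px = profile.radius_mm / profile.pixel_spacing_mm
    if radius_px >= g / 2:
        raise ValueError("lumen radius exceeds the image grid")
    rng = np.random.default_rng(seed)
    c = (g - 1) / 2.0
    yy, xx = np.mgrid[0:g, 0:g]
    r = np.hypot(yy - c, xx - c)
    mask = r <= radius_px
    shape = np.clip(1.0 - (r / radius_px) ** profile.profile_exponent, 0.0, None)
    waveform = _default_waveform(profile.n_frames, profile.systolic_fraction)
    frames = waveform[:, None, None] * (profile.peak_velocity * shape)[None]
    if profile.noise_sd > 0:
        frames = frames + rng.normal(0.0, profile.noise_sd, size=frames.shape)
    return CineFlowSeries(
        frames=frames,
        mask=mask,
        pixel_spacing_mm=(profile.pixel_spacing_mm, profile.pixel_spacing_mm),
        frame_interval_ms=profile.frame_interval_ms,
    )


@dataclass(frozen=True)
class CohortFlowConfig:
    """Cohort-level distribution of subject flow profiles.

    Defaults reproduce typical ascending-aortic statistics: with profile
    exponent k the peak spatial-mean velocity is v_c·k/(k+2), so k = 2.6
    and mean centreline velocity 0.79 m/s give U_pm ≈ 0.447 m/s and
    U_max ≈ 0.79 m/s, and a mean radius of 15.5 mm gives D ≈ 0.031 m.
    """

    radius_mean_mm: float = 15.5
    radius_sd_mm: float = 1.75
    velocity_mean: float = 0.79
    velocity_sd: float = 0.20
    profile_exponent: float = 2.6
    noise_sd: float = 0.005
    radius_bounds_mm: tuple[float, float] = (10.0, 22.0)
    velocity_bounds: tuple[float, float] = (0.15, 1.80)


def cohort_profiles(
    n_subjects: int,
    seed: int = 0,
    config: CohortFlowConfig | None = None,
    radius_z: np.ndarray | None = None,
    velocity_z: np.ndarray | None = None,
) -> list[SubjectProfile]:
    """Draw per-subject flow profiles from the cohort distribution.

    ``radius_z`` / ``velocity_z`` optionally supply standardised latent
    values (e.g. heritable traits) that replace the i.i.d. normal draws, so
    genetic structure can be injected into the geometry and flow.
    """
    config = config or CohortFlowConfig()
    rng = np.random.default_rng(seed)
    zr = rng.standard_normal(n_subjects) if radius_z is None else np.asarray(radius_z)
    zv = rng.standard_normal(n_subjects) if velocity_z is None else np.asarray(velocity_z)
    radius = np.clip(config.radius_mean_mm + config.radius_sd_mm * zr,
                     *config.radius_bounds_mm)
    vel = np.clip(config.velocity_mean + config.velocity_sd * zv,
                  *config.velocity_bounds)
    return [
        SubjectProfile(
            radius_mm=float(radius[i]),
            peak_velocity=float(vel[i]),
            profile_exponent=config.profile_exponent,
            noise_sd=config.noise_sd,
        )
        for i in range(n_subjects)
    ]
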