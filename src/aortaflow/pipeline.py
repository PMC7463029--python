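"""End-to-end pipeline on a synthetic cohort.

``run_pipeline`` executes the full analysis in order — simulate cohort →
render cines → flow metrics → covariate adjustment → genotype QC →
pedigree heritability → GRM/SNP heritability → mixed-model GWAS — and
emits a per-trait summary table (trait, method, P, h² %, n) together with
a manifest recording every threshold and seed.

The genetic architecture of the synthetic cohort enters through two
heritable latent variables: one driving lumen radius (geometry) and one
driving peak centreline velocity (flow).  Every measured metric is a
deterministic function of these plus measurement noise, so geometry-only
metrics (CSA, D), averaged-flow metrics (U_pm, Re_pm) and single-pixel
metrics (U_max, Re_max) inherit differing fractions of the latent
heritabilities — qualitatively matching how averaged metrics retain more
genetic signal than noise-dominated pointwise maxima.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._version import __version__ as _version
from .adjust import adjust_standardize, build_candidates, stepwise_select
from .assoc import mlma_scan
from .cohort import (
    CohortFlowConfig,
    CovariateConfig,
    StructureConfig,
    TraitSpec,
    cohort_profiles,
    random_panel,
    simulate_covariates,
    simulate_flow_series,
    simulate_genotypes,
    simulate_pedigrees,
    simulate_trait,
)
from .flow import FluidConstants, flow_metrics
from .grm import compute_grm
from .kinship import kinship_matrix
from .plink import atomic_write_text, write_metrics
from .qc import QcThresholds, run_qc
from .vc import GREML, PedigreeVarianceComponents

__all__ = ["RunConfig", "run_pipeline", "METRIC_COLUMNS"]

METRIC_COLUMNS = ["csa_mm2", "diameter_m", "u_pm", "u_max", "re_pm", "re_max"]


@dataclass(frozen=True)
class RunConfig:
    """Everything a pipeline run depends on; serialises to one JSON text."""

    seed: int = 0
    n_families: int = 108
    structure: StructureConfig = field(default_factory=StructureConfig)
    covariates: CovariateConfig = field(default_factory=CovariateConfig)
    flow: CohortFlowConfig = field(default_factory=CohortFlowConfig)
    fluid: FluidConstants = field(default_factory=FluidConstants)
    qc: QcThresholds = field(default_factory=QcThresholds)
    n_snps: int = 2000
    panel_maf_range: tuple[float, float] = (0.05, 0.5)
    missing_rate: float = 0.01
    genotyped_fraction: float = 0.9
    h2_diameter: float = 0.30
    h2_velocity: float = 0.40
    betas_diameter: dict[str, float] = field(
        default_factory=lambda: {"sex": 0.35, "age": 0.30, "bmi": 0.20,
                                 "hypertension": 0.10}
    )
    betas_velocity: dict[str, float] = field(
        default_factory=lambda: {"sex": 0.30, "age": -0.25, "bmi": 0.20}
    )
    do_genetics: bool = True
    do_gwas: bool = True
    gwas_traits: tuple[str, ...] = ("re_pm",)

    # -- lossless round trip --------------------------------------------------
    def to_json(self) -> str:
        def encode(obj):
            if dataclasses.is_dataclass(obj):
                return {f.name: encode(getattr(obj, f.name))
                        for f in dataclasses.fields(obj)}
            if isinstance(obj, tuple):
                return list(obj)
            if isinstance(obj, dict):
                return {str(k): v for k, v in obj.items()}
            return obj

        return json.dumps(encode(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        raw = json.loads(text)
        structure = raw.get("structure", {})
        if "sibship_probs" in structure:
            structure["sibship_probs"] = {int(k): v
                                          for k, v in structure["sibship_probs"].items()}
        sub = {
            "structure": StructureConfig(**structure),
            "covariates": CovariateConfig(**_tupled(raw.get("covariates", {}),
                                                    ["age_range"])),
            "flow": CohortFlowConfig(**_tupled(raw.get("flow", {}),
                                               ["radius_bounds_mm", "velocity_bounds"])),
            "fluid": FluidConstants(**raw.get("fluid", {})),
            "qc": QcThresholds(**_tupled(raw.get("qc", {}), ["het_window"])),
        }
        top = {k: v for k, v in raw.items() if k not in sub}
        top = _tupled(top, ["panel_maf_range", "gwas_traits"])
        return cls(**top, **sub)


def _tupled(data: dict, keys: list[str]) -> dict:
    out = dict(data)
    for k in keys:
        if k in out and isinstance(out[k], list):
            out[k] = tuple(out[k])
    return out


def _child_seeds(seed: int, n: int) -> list[int]:
    """Deterministic per-stage seeds derived from the run seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


def run_pipeline(config: RunConfig | None = None, outdir=None) -> dict:
    """Run the whole analysis; optionally write results under ``outdir``.

    Returns a dict with the pedigree, covariates, metric table, adjusted
    traits, QC report, per-trait variance-component fits, association
    results and the Table-style ``summary`` DataFrame.  Any stage failure
    raises with the stage name prefixed.
    """
    config = config or RunConfig()
    seeds = _child_seeds(config.seed, 10)
    out: dict = {"config": config}

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    # --- cohort -------------------------------------------------------------
    pedigree = stage("simulate_pedigrees",
                     lambda: simulate_pedigrees(config.n_families,
                                                config.structure, seeds[0]))
    covariates = stage("simulate_covariates",
                       lambda: simulate_covariates(pedigree, seeds[1],
                                                   config.covariates))
    kin = stage("kinship", lambda: kinship_matrix(pedigree))
    out.update(pedigree=pedigree, covariates=covariates, kinship=kin)

    # --- heritable latents driving geometry and flow ------------------------
    z_d = stage("latent_diameter", lambda: simulate_trait(
        pedigree, kin, TraitSpec(config.h2_diameter, betas=config.betas_diameter),
        covariates, seeds[2]))
    z_v = stage("latent_velocity", lambda: simulate_trait(
        pedigree, kin, TraitSpec(config.h2_velocity, betas=config.betas_velocity),
        covariates, seeds[3]))

    pheno_ids = pedigree.phenotyped_ids
    pos = {iid: k for k, iid in enumerate(pedigree.ids)}
    rows = [pos[i] for i in pheno_ids]

    # --- cines and flow metrics ---------------------------------------------
    def render_and_measure():
        profiles = cohort_profiles(len(pheno_ids), seeds[4], config.flow,
                                   radius_z=z_d[rows], velocity_z=z_v[rows])
        cine_seeds = _child_seeds(seeds[4], len(profiles))
        records = []
        for iid, prof, s in zip(pheno_ids, profiles, cine_seeds):
            series = simulate_flow_series(prof, s)
            fm = flow_metrics(series, config.fluid)
            records.append({"id": iid, **fm.as_dict()})
        return pd.DataFrame(records)

    metrics = stage("flow_metrics", render_and_measure)
    out["metrics"] = metrics

    # --- covariate adjustment -----------------------------------------------
    cov_pheno = covariates.set_index("id").loc[pheno_ids]
    candidates = build_candidates(cov_pheno)  # indexed by individual id

    def adjust_all():
        adjusted = {}
        for trait in METRIC_COLUMNS:
            y = metrics[trait]
            model = stepwise_select(y, candidates, trait_name=trait)
            adjusted[trait] = (model, adjust_standardize(y, model, candidates))
        return adjusted

    adjusted = stage("adjust", adjust_all)
    out["adjusted"] = adjusted

    fits: dict[str, dict] = {t: {} for t in METRIC_COLUMNS}
    assoc: dict[str, pd.DataFrame] = {}
    summary_rows = []

    if config.do_genetics:
        panel = stage("panel", lambda: random_panel(config.n_snps, seeds[5],
                                                    config.panel_maf_range))
        genotypes = stage("simulate_genotypes",
                          lambda: simulate_genotypes(pedigree, panel,
                                                     config.missing_rate, seeds[6]))
        # ~10% of participants were never genotyped
        rng = np.random.default_rng(seeds[7])
        genotyped = [iid for iid in pedigree.ids
                     if rng.random() < config.genotyped_fraction]
        g_typed = genotypes.subset(keep_ids=genotyped)
        g_qc, qc_report = stage("qc", lambda: run_qc(g_typed, pedigree, config.qc))
        out.update(genotypes=g_qc, qc_report=qc_report)
        grm = stage("grm", lambda: compute_grm(g_qc))
        out["grm"] = grm

        fam_of = dict(zip(pedigree.table["id"], pedigree.table["family"]))
        for trait in METRIC_COLUMNS:
            _, adj = adjusted[trait]
            retained = adj.retained
            ids_ped = list(retained.index)
            kin_sub = kin.subset(ids_ped)
            fit_ped = stage(f"pedigree_h2[{trait}]", lambda: PedigreeVarianceComponents(
                retained.to_numpy(), kin_sub,
                [fam_of[i] for i in ids_ped]).fit())
            fits[trait]["pedigree"] = fit_ped
            summary_rows.append((trait, "pedigree", fit_ped.pvalue,
                                 100 * fit_ped.h2, fit_ped.n))

            ids_snp = [i for i in ids_ped if i in set(g_qc.ids)]
            y_snp = retained.loc[ids_snp].to_numpy()
            grm_sub = grm.subset(ids_snp)
            fit_snp = stage(f"snp_h2[{trait}]",
                            lambda: GREML(y_snp, grm_sub).fit())
            fits[trait]["snp"] = fit_snp
            summary_rows.append((trait, "snp", fit_snp.pvalue,
                                 100 * fit_snp.h2, fit_snp.n))

            if config.do_gwas and trait in config.gwas_traits:
                g_sub = g_qc.subset(keep_ids=ids_snp)
                assoc[trait] = stage(f"mlma[{trait}]", lambda: mlma_scan(
                    y_snp, g_sub, grm_sub, varcomp=fit_snp))
    out["fits"] = fits
    out["assoc"] = assoc
    summary = pd.DataFrame(summary_rows,
                           columns=["trait", "method", "p", "h2_pct", "n"])
    out["summary"] = summary

    # --- manifest and optional outputs --------------------------------------
    cfg_json = config.to_json()
    from .flow import TURBULENT_RE_THRESHOLD

    manifest = {
        "version": _version,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "stage_seeds": seeds,
        "n_phenotyped": len(pheno_ids),
        "pct_re_pm_above_turbulent_threshold": float(
            100.0 * (metrics["re_pm"] > TURBULENT_RE_THRESHOLD).mean()),
    }
    out["manifest"] = manifest
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_metrics(metrics, outdir / "metrics.tsv")
        atomic_write_text(outdir / "summary.tsv",
                          summary.to_csv(sep="\t", index=False))
        atomic_write_text(outdir / "config.json", cfg_json)
        atomic_write_text(outdir / "manifest.json", json.dumps(manifest, indent=2))
        if config.do_genetics:
            atomic_write_text(outdir / "qc.json",
                              json.dumps(out["qc_report"].as_dict(), indent=2))
        for trait, df in assoc.items():
            atomic_write_text(outdir / f"assoc_{trait}.tsv",
                              df.to_csv(sep="\t", index=False))
    return out
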