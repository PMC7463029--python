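"""Covariate adjustment of haemodynamic traits.

Each trait is adjusted by bidirectional stepwise multiple linear
regression over the candidate covariates {age, age², sex, BMI, systolic
BP, hypertension}: forward entry of the most significant candidate with
partial-test p below the entry threshold, then backward removal of any
included covariate whose partial p meets the removal threshold, repeated
to a fixed point.  Residuals from the final model are standardised to mean
0 and variance 1, and individuals beyond three standard deviations are
excluded (without refitting).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "AdjustmentModel",
    "AdjustedTrait",
    "build_candidates",
    "stepwise_select",
    "adjust_standardize",
]

CANDIDATE_COLUMNS = ["age", "age2", "sex", "bmi", "sbp", "hypertension"]


def build_candidates(covariates: pd.DataFrame, center_age: bool = True) -> pd.DataFrame:
    """Candidate design columns from a covariate table.

    ``age2`` is the square of the *centred* age by default, which curbs
    its collinearity with ``age``; sex and hypertension are 0/1.
    """
    out = pd.DataFrame(index=covariates.index)
    age = covariates["age"].astype(float)
    out["age"] = age
    out["age2"] = (age - age.mean()) ** 2 if center_age else age**2
    out["sex"] = covariates["sex"].astype(int)
    out["bmi"] = covariates["bmi"].astype(float)
    out["sbp"] = covariates["sbp"].astype(float)
    out["hypertension"] = covariates["hypertension"].astype(int)
    return out


@dataclass
class AdjustmentModel:
    """Final stepwise model for one trait."""

    trait: str
    included: list[str]
    params: pd.Series
    pvalues: pd.Series
    entry_p: float
    removal_p: float
    rsquared: float
    n: int

    def predict(self, candidates: pd.DataFrame) -> np.ndarray:
        X = sm.add_constant(candidates[self.included], has_constant="add")
        return X.to_numpy() @ self.params.reindex(X.columns).to_numpy()

    def as_dict(self) -> dict:
        return {
            "trait": self.trait,
            "included": self.included,
            "params": {k: float(v) for k, v in self.params.items()},
            "pvalues": {k: float(v) for k, v in self.pvalues.items()},
            "entry_p": self.entry_p,
            "removal_p": self.removal_p,
            "rsquared": self.rsquared,
            "n": self.n,
        }


@dataclass
class AdjustedTrait:
    """Standardised residuals with the 3-SD exclusion applied."""

    z: pd.Series  # indexed like the input trait; NaN where input was NaN
    excluded: list  # index labels with |z| > threshold
    n_retained: int
    threshold: float = 3.0

    @property
    def retained(self) -> pd.Series:
        keep = self.z.dropna()
        return keep[~keep.index.isin(self.excluded)]


def _fit_ols(y: np.ndarray, X: pd.DataFrame):
    design = sm.add_constant(X, has_constant="add")
    return sm.OLS(y, design.astype(float)).fit()


def stepwise_select(
    trait: pd.Series | np.ndarray,
    candidates: pd.DataFrame,
    entry_p: float = 0.05,
    removal_p: float = 0.05,
    trait_name: str = "trait",
    max_steps: int = 100,
    condition_limit: float = 1e10,
) -> AdjustmentModel:
    """Bidirectional stepwise selection at the given p thresholds.

    ``removal_p`` defaults to the symmetric 0.05; SPSS's default (0.10)
    can be supplied instead.  A candidate whose entry would make the
    design numerically collinear (condition number above
    ``condition_limit``) is dropped with a warning.
    """
    y = np.asarray(trait, dtype=float)
    ok = np.isfinite(y) & np.isfinite(candidates.to_numpy(dtype=float)).all(axis=1)
    n_complete = int(ok.sum())
    if candidates.shape[1] and n_complete < 10 * candidates.shape[1]:
        raise ValueError("too few complete cases for stepwise selection")
    y = y[ok]
    cand = candidates.loc[ok].reset_index(drop=True)
    included: list[str] = []
    for _ in range(max_steps):
        changed = False
        # forward entry
        best_p, best_c = None, None
        for c in cand.columns:
            if c in included:
                continue
            X = cand[included + [c]]
            design = sm.add_constant(X, has_constant="add").to_numpy(dtype=float)
            if np.linalg.cond(design) > condition_limit:
                warnings.warn(
                    f"candidate {c!r} is collinear with the current model; skipped",
                    stacklevel=2,
                )
                continue
            fit = _fit_ols(y, X)
            p = fit.pvalues[c]
            if p < entry_p and (best_p is None or p < best_p):
                best_p, best_c = p, c
        if best_c is not None:
            included.append(best_c)
            changed = True
        # backward removal
        if included:
            fit = _fit_ols(y, cand[included])
            worst = fit.pvalues[included].idxmax()
            if fit.pvalues[worst] >= removal_p:
                included.remove(worst)
                changed = True
        if not changed:
            break
    fit = _fit_ols(y, cand[included]) if included else _fit_ols(y, cand[[]])
    return AdjustmentModel(
        trait=trait_name,
        included=included,
        params=fit.params,
        pvalues=fit.pvalues,
        entry_p=entry_p,
        removal_p=removal_p,
        rsquared=float(fit.rsquared) if included else 0.0,
        n=n_complete,
    )


def adjust_standardize(
    trait: pd.Series,
    model: AdjustmentModel,
    candidates: pd.DataFrame,
    sd_threshold: float = 3.0,
) -> AdjustedTrait:
    """Standardised residuals from the fitted model, with 3-SD exclusion.

    Residuals are z-scored over all complete cases (exact mean 0,
    variance 1 before exclusion); individuals with |z| above the
    threshold are flagged excluded.  Coefficients are *not* refitted
    after exclusion.
    """
    trait = pd.Series(np.asarray(trait, dtype=float), index=candidates.index)
    ok = trait.notna() & np.isfinite(candidates.to_numpy(dtype=float)).all(axis=1)
    resid = trait[ok].to_numpy() - model.predict(candidates.loc[ok])
    sd = resid.std(ddof=0)
    if sd == 0:
        raise ValueError("zero residual variance; trait is perfectly explained")
    z = (resid - resid.mean()) / sd
    zs = pd.Series(np.nan, index=trait.index)
    zs[ok] = z
    excluded = list(zs.index[ok][np.abs(z) > sd_threshold])
    return AdjustedTrait(
        z=zs,
        excluded=excluded,
        n_retained=int(ok.sum()) - len(excluded),
        threshold=sd_threshold,
    )
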