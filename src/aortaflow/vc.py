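"""Variance-components models for narrow-sense heritability.

Two complementary estimators of h² = σ²g/(σ²g + σ²e) for a quantitative
trait y under the polygenic model

    y = Xβ + g + e,   g ~ N(0, K·σ²g),   e ~ N(0, I·σ²e),

where K is an additive relationship matrix:

* :class:`PedigreeVarianceComponents` — K = 2Φ from the expected pedigree
  kinship; maximum likelihood, with a likelihood-ratio test of the
  environment-only model against the polygenic + environment model.
* :class:`GREML` — K = A, the realised genomic relationship matrix;
  restricted maximum likelihood via average-information (AI) updates with
  an EM fallback, the GCTA-GREML algorithm.

Both fits return a :class:`VarianceComponentsResults` carrying estimates,
standard errors, log-likelihoods, the LRT p-value and diagnostics.  Because
σ²g = 0 lies on the boundary of the parameter space, the default reference
distribution for the LRT is the 50:50 mixture of χ²₀ and χ²₁; a plain χ²₁
(conservative) is available via ``null_dist="chi2"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .kinship import KinshipMatrix

__all__ = [
    "VarianceComponentsResults",
    "PedigreeVarianceComponents",
    "GREML",
    "vc_loglik",
    "lrt_pvalue",
]

_H2_TOL = 1e-10


def lrt_pvalue(lrt: float, null_dist: str = "mixture") -> float:
    """P-value of a boundary LRT statistic.

    ``"mixture"`` uses the 50:50 mixture of χ²₀ and χ²₁ appropriate when
    the null pins a variance at the boundary; ``"chi2"`` the plain χ²₁.
    """
    lrt = max(float(lrt), 0.0)
    if null_dist == "mixture":
        return 1.0 if lrt == 0.0 else 0.5 * float(stats.chi2.sf(lrt, 1))
    if null_dist == "chi2":
        return float(stats.chi2.sf(lrt, 1))
    raise ValueError(f"unknown null distribution {null_dist!r}")


@dataclass
class VarianceComponentsResults:
    """Estimates and diagnostics from a variance-components fit."""

    method: str
    n: int
    sigma2_g: float
    sigma2_e: float
    h2: float
    se_h2: float | None
    loglik: float
    loglik_null: float
    lrt: float
    pvalue: float
    null_dist: str = "mixture"
    converged: bool = True
    n_iter: int = 0
    identifiable: bool = True
    message: str = ""

    @property
    def total_variance(self) -> float:
        return self.sigma2_g + self.sigma2_e

    def summary(self) -> str:
        lines = [
            f"{'Variance components fit':^58}",
            "=" * 58,
            f"Method:              {self.method}",
            f"No. observations:    {self.n}",
            f"Converged:           {self.converged}   (iterations: {self.n_iter})",
            "-" * 58,
            f"sigma2_g:            {self.sigma2_g:.6g}",
            f"sigma2_e:            {self.sigma2_e:.6g}",
            f"h2:                  {self.h2:.4f}"
            + (f"  (SE {self.se_h2:.4f})" if self.se_h2 is not None else ""),
            f"logL (full):         {self.loglik:.6f}",
            f"logL (null):         {self.loglik_null:.6f}",
            f"LRT:                 {self.lrt:.4f}",
            f"P value ({self.null_dist}):   {self.pvalue:.4g}",
            "=" * 58,
        ]
        if not self.identifiable:
            lines.append("Warning: variance components not separately identifiable "
                         "(relationship matrix ~ identity).")
        if self.message:
            lines.append(self.message)
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# explicit log-likelihood (block-diagonal by family)
# ---------------------------------------------------------------------------

def vc_loglik(
    y: np.ndarray,
    phi: np.ndarray | KinshipMatrix,
    sigma2_g: float,
    sigma2_e: float,
    mu: float = 0.0,
    families: np.ndarray | None = None,
) -> float:
    """Multivariate-normal log-likelihood with covariance 2Φσ²g + Iσ²e.

    ``families`` optionally labels independent blocks; the covariance is
    then block-diagonal and the likelihood is the sum over families.
    """
    y = np.asarray(y, dtype=float)
    if isinstance(phi, KinshipMatrix):
        phi = phi.phi
    phi = np.asarray(phi, dtype=float)
    if phi.shape != (y.size, y.size):
        raise ValueError("kinship dimension does not match the trait vector")
    if families is None:
        blocks = [np.arange(y.size)]
    else:
        families = np.asarray(families)
        blocks = [np.where(families == f)[0] for f in dict.fromkeys(families)]
    ll = 0.0
    for idx in blocks:
        r = y[idx] - mu
        omega = 2.0 * phi[np.ix_(idx, idx)] * sigma2_g + np.eye(idx.size) * sigma2_e
        sign, logdet = np.linalg.slogdet(omega)
        if sign <= 0:
            raise ValueError("covariance is not positive definite at these parameters")
        ll += -0.5 * (idx.size * np.log(2 * np.pi) + logdet
                      + r @ np.linalg.solve(omega, r))
    return float(ll)


# ---------------------------------------------------------------------------
# pedigree ML model
# ---------------------------------------------------------------------------

class PedigreeVarianceComponents:
    """Maximum-likelihood polygenic model on pedigree kinship.

    Families are independent blocks, so the covariance
    Ω = σ²·(h²·2Φ + (1−h²)·I) is block-diagonal; each block is
    eigendecomposed once, after which the mean and the total variance σ²
    have closed-form profile maximisers and the likelihood is maximised by
    a bounded scalar search over h² ∈ [0, 1].

    Parameters
    ----------
    y : array
        Covariate-adjusted, standardised trait values.
    kinship : KinshipMatrix
        Aligned with ``y`` (use ``KinshipMatrix.subset`` first if needed).
    families : sequence of labels
        Family of each observation; cross-family kinship is assumed zero.
    """

    def __init__(self, y, kinship: KinshipMatrix, families):
        self.y = np.asarray(y, dtype=float)
        n = self.y.size
        if kinship.n != n or len(families) != n:
            raise ValueError("y, kinship and families must align")
        if not np.isfinite(self.y).all():
            raise ValueError("trait contains non-finite values")
        self.ids = list(kinship.ids)
        self.families = np.asarray(families)
        # per-family eigendecomposition of 2*Phi
        lam_parts, yt_parts, ut_parts = [], [], []
        for fam in dict.fromkeys(self.families):
            idx = np.where(self.families == fam)[0]
            k2 = 2.0 * kinship.phi[np.ix_(idx, idx)]
            lam, vec = np.linalg.eigh(k2)
            lam_parts.append(np.clip(lam, 0.0, None))
            yt_parts.append(vec.T @ self.y[idx])
            ut_parts.append(vec.T @ np.ones(idx.size))
        self.lam = np.concatenate(lam_parts)
        self.yt = np.concatenate(yt_parts)
        self.ut = np.concatenate(ut_parts)
        self.n = n

    # -- profile likelihood over h2 ------------------------------------------
    def profile_loglik(self, h2: float) -> float:
        """Log-likelihood at h², with μ and σ² profiled out analytically."""
        d = h2 * self.lam + (1.0 - h2)
        if (d <= 0).any():
            return -np.inf
        mu = (self.ut * self.yt / d).sum() / (self.ut * self.ut / d).sum()
        r = self.yt - mu * self.ut
        s2 = (r * r / d).sum() / self.n
        if s2 <= 0:
            return -np.inf
        return float(-0.5 * (self.n * np.log(2 * np.pi * s2)
                             + np.log(d).sum() + self.n))

    def _h2_identifiable(self) -> bool:
        return bool(np.abs(self.lam - 1.0).max() > 1e-9)

    def fit(self, null_dist: str = "mixture") -> VarianceComponentsResults:
        """Fit the polygenic and environment-only models and test them.

        The null (σ²g = 0) is i.i.d. normal with closed-form MLEs; the full
        model maximises the profile likelihood over h² (coarse grid then
        bounded refinement).  The LRT compares the two.
        """
        ll0 = self.profile_loglik(0.0)
        identifiable = self._h2_identifiable()
        if not identifiable:
            return VarianceComponentsResults(
                method="ML (pedigree kinship)", n=self.n,
                sigma2_g=0.0, sigma2_e=float(np.var(self.y)),
                h2=0.0, se_h2=None,
                loglik=ll0, loglik_null=ll0, lrt=0.0,
                pvalue=1.0, null_dist=null_dist,
                converged=True, identifiable=False,
                message="2*Phi ~ identity: only the total variance is identifiable",
            )
        grid = np.linspace(0.0, 1.0 - 1e-9, 21)
        vals = np.array([self.profile_loglik(h) for h in grid])
        k = int(np.argmax(vals))
        lo = grid[max(k - 1, 0)]
        hi = grid[min(k + 1, grid.size - 1)]
        res = optimize.minimize_scalar(
            lambda h: -self.profile_loglik(h),
            bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-10},
        )
        h2 = float(res.x)
        ll = self.profile_loglik(h2)
        if ll0 >= ll:  # boundary optimum
            h2, ll = 0.0, ll0
        if 1.0 - h2 < 1e-6:
            h2 = min(h2, 1.0 - 1e-9)
        # profiled sigma^2 at the optimum
        d = h2 * self.lam + (1.0 - h2)
        mu = (self.ut * self.yt / d).sum() / (self.ut * self.ut / d).sum()
        s2 = float(((self.yt - mu * self.ut) ** 2 / d).sum() / self.n)
        lrt = max(2.0 * (ll - ll0), 0.0)
        se = self._se_h2(h2)
        return VarianceComponentsResults(
            method="ML (pedigree kinship)", n=self.n,
            sigma2_g=h2 * s2, sigma2_e=(1.0 - h2) * s2,
            h2=h2, se_h2=se,
            loglik=ll, loglik_null=ll0, lrt=lrt,
            pvalue=lrt_pvalue(lrt, null_dist), null_dist=null_dist,
            converged=bool(res.success), n_iter=int(res.nfev),
        )

    def _se_h2(self, h2: float) -> float | None:
        """SE from the curvature of the profile log-likelihood (interior only)."""
        if h2 <= _H2_TOL or h2 >= 1 - 1e-6:
            return None
        eps = min(1e-4, h2 / 2, (1 - h2) / 2)
        f0 = self.profile_loglik(h2)
        fp = self.profile_loglik(h2 + eps)
        fm = self.profile_loglik(h2 - eps)
        curv = (fp - 2 * f0 + fm) / eps**2
        if curv >= 0:
            return None
        return float(1.0 / np.sqrt(-curv))


# ---------------------------------------------------------------------------
# AI-REML on a genomic (or any) relationship matrix
# ---------------------------------------------------------------------------

class GREML:
    """Single-component GREML: restricted ML for V = A·σ²g + I·σ²e.

    The relationship matrix is eigendecomposed once; every AI-REML
    iteration then costs O(n·p).  Updates follow the average-information
    algorithm; any step that lowers the restricted likelihood or leaves
    the parameter space falls back to an EM step, which cannot decrease
    it.  Fixed effects default to an intercept; pass ``X`` to include
    covariates inside the REML fit instead of pre-adjusting.

    Parameters
    ----------
    y : array
        Trait values (typically standardised residuals).
    grm : GRM, KinshipMatrix or ndarray
        Positive semi-definite relationship matrix. A ``KinshipMatrix`` is
        interpreted as 2Φ.
    X : ndarray, optional
        Fixed-effect design (n × p); a column of ones is used when omitted.
    """

    def __init__(self, y, grm, X: np.ndarray | None = None, ridge: float = 1e-8):
        self.y = np.asarray(y, dtype=float)
        n = self.y.size
        a = self._as_matrix(grm)
        if a.shape != (n, n):
            raise ValueError("relationship matrix does not match the trait vector")
        if X is None:
            X = np.ones((n, 1))
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        lam, vec = np.linalg.eigh(a + ridge * np.eye(n))
        self.lam = np.clip(lam, 0.0, None)
        self.yt = vec.T @ self.y
        self.Xt = vec.T @ X
        self.n = n
        self.p = X.shape[1]

    @staticmethod
    def _as_matrix(grm) -> np.ndarray:
        if isinstance(grm, KinshipMatrix):
            return 2.0 * grm.phi
        a = getattr(grm, "a", grm)
        return np.asarray(a, dtype=float)

    # -- restricted likelihood machinery -------------------------------------
    def _quantities(self, sg: float, se: float) -> dict:
        d = sg * self.lam + se
        if (d <= 0).any():
            raise FloatingPointError("V not positive definite")
        Xt, yt = self.Xt, self.yt
        XtVi = Xt.T / d  # p x n
        XtViX = XtVi @ Xt
        L = np.linalg.cholesky(XtViX)
        beta = np.linalg.solve(XtViX, XtVi @ yt)
        r = yt - Xt @ beta
        Py = r / d
        q = float(r @ Py)
        logdet_xvx = 2.0 * float(np.log(np.diag(L)).sum())
        ll = -0.5 * ((self.n - self.p) * np.log(2 * np.pi)
                     + float(np.log(d).sum()) + logdet_xvx + q)
        return {"d": d, "XtViX": XtViX, "XtVi": XtVi, "Py": Py, "ll": float(ll)}

    def reml_loglik(self, sigma2_g: float, sigma2_e: float) -> float:
        """Restricted log-likelihood at the given variance components."""
        return self._quantities(sigma2_g, sigma2_e)["ll"]

    def _P(self, w: np.ndarray, qty: dict) -> np.ndarray:
        Viw = w / qty["d"]
        tmp = qty["XtVi"] @ w
        return Viw - qty["XtVi"].T @ np.linalg.solve(qty["XtViX"], tmp)

    def _score_ai(self, qty: dict) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        d, Py = qty["d"], qty["Py"]
        XtViX_inv = np.linalg.inv(qty["XtViX"])
        Xt = self.Xt

        def tr_P(weights: np.ndarray) -> float:
            t1 = float((weights / d).sum())
            M = (Xt.T * (weights / d**2)) @ Xt
            return t1 - float(np.trace(XtViX_inv @ M))

        quad = np.array([float(Py @ (self.lam * Py)), float(Py @ Py)])
        trace = np.array([tr_P(self.lam), tr_P(np.ones(self.n))])
        score = -0.5 * (trace - quad)
        w = [self.lam * Py, Py]
        Pw = [self._P(wi, qty) for wi in w]
        ai = 0.5 * np.array([[float(w[i] @ Pw[j]) for j in range(2)] for i in range(2)])
        return score, ai, quad

    def fit(
        self,
        max_iter: int = 100,
        tol: float = 1e-8,
        null_dist: str = "mixture",
        start: tuple[float, float] | None = None,
    ) -> VarianceComponentsResults:
        """AI-REML with EM fallback; LRT against the σ²g = 0 null.

        Raises ``RuntimeError`` on non-convergence after ``max_iter``
        iterations, with the iteration trace in the message.
        """
        vp = float(np.var(self.y))
        if vp <= 0:
            raise ValueError("trait has zero variance")
        floor = 1e-8 * vp
        identifiable = bool(np.abs(self.lam - 1.0).max() > 1e-6)
        ll_null = self._null_loglik()
        if not identifiable:
            return VarianceComponentsResults(
                method="AI-REML (GRM)", n=self.n,
                sigma2_g=0.0, sigma2_e=vp, h2=0.0, se_h2=None,
                loglik=ll_null, loglik_null=ll_null, lrt=0.0, pvalue=1.0,
                null_dist=null_dist, converged=True, identifiable=False,
                message="relationship matrix ~ identity: only the total "
                        "variance is identifiable",
            )
        theta = np.array(start) if start is not None else np.array([vp / 2, vp / 2])
        theta = np.maximum(theta, floor)
        qty = self._quantities(*theta)
        trace_log: list[str] = [f"iter 0: ll={qty['ll']:.6f}"]
        n_iter = 0
        converged = False
        ai = np.eye(2)
        for n_iter in range(1, max_iter + 1):
            score, ai, quad = self._score_ai(qty)
            step_ok = False
            try:
                proposal = theta + np.linalg.solve(ai, score)
                proposal = np.maximum(proposal, floor)
                qty_new = self._quantities(*proposal)
                if qty_new["ll"] >= qty["ll"] - 1e-10:
                    step_ok = True
            except (np.linalg.LinAlgError, FloatingPointError):
                pass
            if not step_ok:
                # EM fallback: guaranteed not to decrease the likelihood
                d, Py = qty["d"], qty["Py"]
                trace_g = self._trace_P(self.lam, qty)
                trace_e = self._trace_P(np.ones(self.n), qty)
                em = np.array([
                    theta[0] + theta[0] ** 2 / self.n
                    * (float(Py @ (self.lam * Py)) - trace_g),
                    theta[1] + theta[1] ** 2 / self.n
                    * (float(Py @ Py) - trace_e),
                ])
                proposal = np.maximum(em, floor)
                qty_new = self._quantities(*proposal)
            if qty_new["ll"] < qty["ll"] - 1e-6:
                raise RuntimeError(
                    "restricted likelihood decreased: "
                    + "; ".join(trace_log[-5:])
                )
            delta = qty_new["ll"] - qty["ll"]
            theta, qty = proposal, qty_new
            trace_log.append(
                f"iter {n_iter}: ll={qty['ll']:.6f} ({'AI' if step_ok else 'EM'})"
            )
            if abs(delta) < tol:
                converged = True
                break
        if not converged:
            raise RuntimeError(
                f"AI-REML did not converge in {max_iter} iterations: "
                + "; ".join(trace_log[-5:])
            )
        sg, se_var = float(theta[0]), float(theta[1])
        total = sg + se_var
        h2 = sg / total if total > 0 else 0.0
        at_boundary = sg <= 2 * floor
        se_h2 = None
        try:
            cov = np.linalg.inv(ai)
            grad = np.array([se_var, -sg]) / total**2
            var_h2 = float(grad @ cov @ grad)
            if var_h2 > 0 and not at_boundary:
                se_h2 = float(np.sqrt(var_h2))
        except np.linalg.LinAlgError:
            pass
        ll = qty["ll"]
        lrt = max(2.0 * (ll - ll_null), 0.0)
        if at_boundary:
            lrt = 0.0
        return VarianceComponentsResults(
            method="AI-REML (GRM)", n=self.n,
            sigma2_g=sg if not at_boundary else 0.0,
            sigma2_e=se_var if not at_boundary else total,
            h2=h2 if not at_boundary else 0.0,
            se_h2=se_h2,
            loglik=max(ll, ll_null), loglik_null=ll_null, lrt=lrt,
            pvalue=lrt_pvalue(lrt, null_dist), null_dist=null_dist,
            converged=converged, n_iter=n_iter,
        )

    def _trace_P(self, weights: np.ndarray, qty: dict) -> float:
        d = qty["d"]
        t1 = float((weights / d).sum())
        M = (self.Xt.T * (weights / d**2)) @ self.Xt
        return t1 - float(np.trace(np.linalg.solve(qty["XtViX"], M)))

    def _null_loglik(self) -> float:
        """Restricted likelihood of the environment-only model (closed form)."""
        beta, *_ = np.linalg.lstsq(self.Xt, self.yt, rcond=None)
        rss = float(((self.yt - self.Xt @ beta) ** 2).sum())
        s2 = rss / (self.n - self.p)
        return self.reml_loglik(0.0, s2)
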