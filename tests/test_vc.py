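"""Variance-components fits against dense-matrix likelihood oracles."""

import numpy as np
import pytest
from scipy import stats

from aortaflow.cohort import TraitSpec, simulate_trait
from aortaflow.kinship import kinship_matrix
from aortaflow.vc import GREML, PedigreeVarianceComponents, lrt_pvalue, vc_loglik


# ---------------------------------------------------------------------------
# independent dense oracles (deliberately different code paths)
# ---------------------------------------------------------------------------

def ml_loglik_dense(y, k2, h2, s2):
    """Full ML log-likelihood with GLS-profiled mean, dense algebra."""
    n = y.size
    omega = s2 * (h2 * k2 + (1 - h2) * np.eye(n))
    oi = np.linalg.inv(omega)
    one = np.ones(n)
    mu = (one @ oi @ y) / (one @ oi @ one)
    r = y - mu
    return float(-0.5 * (n * np.log(2 * np.pi)
                         + np.linalg.slogdet(omega)[1] + r @ oi @ r))


def reml_loglik_dense(y, a, sg, se):
    """Restricted log-likelihood with an intercept, dense algebra."""
    n = y.size
    v = sg * a + se * np.eye(n)
    vi = np.linalg.inv(v)
    x = np.ones((n, 1))
    xvx = x.T @ vi @ x
    beta = np.linalg.solve(xvx, x.T @ vi @ y)
    r = y - x @ beta
    return float(-0.5 * ((n - 1) * np.log(2 * np.pi)
                         + np.linalg.slogdet(v)[1]
                         + np.linalg.slogdet(xvx)[1]
                         + r @ vi @ r))


def grid_maximise(fun, n_coarse=200, n_fine=200):
    """Two-stage brute-force grid maximisation over (h2, scale)."""
    h_grid = np.linspace(0.0, 0.999, n_coarse)
    s_grid = np.geomspace(0.05, 20.0, n_coarse)
    best = (-np.inf, None, None)
    for h in h_grid:
        vals = [fun(h, s) for s in s_grid]
        k = int(np.argmax(vals))
        if vals[k] > best[0]:
            best = (vals[k], h, s_grid[k])
    _, h0, s0 = best
    h_fine = np.linspace(max(h0 - 0.01, 0), min(h0 + 0.01, 0.999999), n_fine)
    s_fine = np.geomspace(s0 * 0.9, s0 * 1.1, n_fine)
    out = -np.inf
    for h in h_fine:
        out = max(out, max(fun(h, s) for s in s_fine))
    return out


@pytest.fixture(scope="module")
def small_design(cohort_pedigree, cohort_kinship):
    """First few families (~n<=30 phenotyped), with a simulated trait."""
    ped = cohort_pedigree
    fams = ped.families[:6]
    sub = ped.table[ped.table["family"].isin(fams)]
    ids = [r.id for r in sub.itertuples() if r.phenotyped][:30]
    kin = cohort_kinship.subset(ids)
    fam_of = dict(zip(ped.table["id"], ped.table["family"]))
    y_all = simulate_trait(ped, cohort_kinship, TraitSpec(0.5), seed=77)
    pos = {iid: k for k, iid in enumerate(ped.ids)}
    y = y_all[[pos[i] for i in ids]]
    return y, kin, [fam_of[i] for i in ids]


class TestVcLoglik:
    def test_reduces_to_iid_when_sigma2g_zero(self, small_design):
        y, kin, fams = small_design
        ll = vc_loglik(y, kin.phi, 0.0, 0.7, mu=0.1, families=fams)
        iid = stats.norm(0.1, np.sqrt(0.7)).logpdf(y).sum()
        assert ll == pytest.approx(iid, abs=1e-10)

    def test_matches_dense_mvn(self, trio_pedigree):
        kin = kinship_matrix(trio_pedigree)
        y = np.array([0.3, -1.2, 0.8, 0.1])
        ll = vc_loglik(y, kin, 0.4, 0.6, mu=0.2)
        omega = 2 * kin.phi * 0.4 + np.eye(4) * 0.6
        dense = stats.multivariate_normal(mean=0.2 * np.ones(4),
                                          cov=omega).logpdf(y)
        assert ll == pytest.approx(float(dense), abs=1e-10)

    def test_permutation_invariance(self, small_design):
        y, kin, fams = small_design
        rng = np.random.default_rng(5)
        perm = rng.permutation(y.size)
        ll = vc_loglik(y, kin.phi, 0.3, 0.7, families=fams)
        ll_p = vc_loglik(y[perm], kin.phi[np.ix_(perm, perm)], 0.3, 0.7,
                         families=np.asarray(fams)[perm])
        assert ll == pytest.approx(ll_p, abs=1e-9)


class TestPedigreeFit:
    def test_unrelated_sample_is_unidentifiable(self):
        from aortaflow.kinship import KinshipMatrix

        n = 40
        kin = KinshipMatrix(0.5 * np.eye(n), [f"i{k}" for k in range(n)])
        y = np.random.default_rng(0).standard_normal(n)
        res = PedigreeVarianceComponents(y, kin, ["F"] * n).fit()
        assert not res.identifiable
        assert res.lrt == 0.0

    def test_full_ll_never_below_null(self, small_design):
        y, kin, fams = small_design
        res = PedigreeVarianceComponents(y, kin, fams).fit()
        assert res.loglik >= res.loglik_null - 1e-9
        assert res.lrt >= 0

    def test_scale_invariance_of_h2(self, small_design):
        y, kin, fams = small_design
        r1 = PedigreeVarianceComponents(y, kin, fams).fit()
        r2 = PedigreeVarianceComponents(3.7 * y, kin, fams).fit()
        assert r2.h2 == pytest.approx(r1.h2, abs=1e-6)
        assert r2.sigma2_g == pytest.approx(3.7**2 * r1.sigma2_g, rel=1e-5)

    def test_matches_grid_oracle(self, small_design):
        y, kin, fams = small_design
        res = PedigreeVarianceComponents(y, kin, fams).fit()
        k2 = 2 * kin.phi
        ll_grid = grid_maximise(lambda h, s: ml_loglik_dense(y, k2, h, s))
        assert res.loglik == pytest.approx(ll_grid, abs=1e-4)

    def test_boundary_pvalue_conventions(self):
        assert lrt_pvalue(0.0) == 1.0
        assert lrt_pvalue(2.706, "mixture") == pytest.approx(0.05, abs=0.002)
        assert lrt_pvalue(2.706, "chi2") == pytest.approx(0.10, abs=0.003)


class TestGreml:
    def test_identity_grm_unidentifiable(self):
        y = np.random.default_rng(1).standard_normal(60)
        res = GREML(y, np.eye(60)).fit()
        assert not res.identifiable

    def test_matches_grid_oracle(self, small_design):
        y, kin, fams = small_design
        a = 2 * kin.phi
        res = GREML(y, a).fit(tol=1e-10)
        total = res.sigma2_g + res.sigma2_e

        def fun(h, s):
            sg, se = h * s * total, (1 - h) * s * total
            if se <= 0:
                return -np.inf
            return reml_loglik_dense(y, a, sg, se)

        ll_grid = grid_maximise(fun)
        assert res.loglik == pytest.approx(ll_grid, abs=1e-4)

    def test_reml_loglik_matches_dense(self, small_design):
        y, kin, _ = small_design
        a = 2 * kin.phi
        model = GREML(y, a, ridge=0.0)
        assert model.reml_loglik(0.3, 0.7) == pytest.approx(
            reml_loglik_dense(y, a, 0.3, 0.7), abs=1e-8)

    def test_permutation_invariance(self, small_design):
        y, kin, _ = small_design
        a = 2 * kin.phi
        rng = np.random.default_rng(9)
        perm = rng.permutation(y.size)
        r1 = GREML(y, a).fit()
        r2 = GREML(y[perm], a[np.ix_(perm, perm)]).fit()
        assert r2.h2 == pytest.approx(r1.h2, abs=1e-5)
        assert r2.loglik == pytest.approx(r1.loglik, abs=1e-6)

    def test_agrees_with_pedigree_ml_on_same_kinship(
            self, cohort_pedigree, cohort_kinship):
        """ML (pedigree) and REML (same 2*Phi) agree on h2 on average."""
        ped = cohort_pedigree
        ids = ped.phenotyped_ids
        kin = cohort_kinship.subset(ids)
        fam_of = dict(zip(ped.table["id"], ped.table["family"]))
        fams = [fam_of[i] for i in ids]
        pos = {iid: k for k, iid in enumerate(ped.ids)}
        rows = [pos[i] for i in ids]
        for h2 in (0.0, 0.4, 0.8):
            diffs, ml_means = [], []
            for rep in range(12):
                y = simulate_trait(ped, cohort_kinship, TraitSpec(h2),
                                   seed=1000 * int(h2 * 10) + rep)[rows]
                r_ml = PedigreeVarianceComponents(y, kin, fams).fit()
                r_reml = GREML(y, kin).fit()
                diffs.append(r_ml.h2 - r_reml.h2)
                ml_means.append(r_ml.h2)
            assert abs(np.mean(diffs)) < 0.06
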