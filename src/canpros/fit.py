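"""Maximum-likelihood segregation analysis over ascertainment-adjusted
pedigree likelihoods, statsmodels-style.

:class:`SegregationModel` holds the data (pedigrees + incidence constraint)
and the model configuration (which parameters are free); ``fit()`` maximises
the summed conditioned log-likelihoods on a transformed scale (logit for
frequencies and ``alpha``, log for relative risks, ``sigma70`` and the SD
rate) and returns a :class:`SegregationResults` with estimates, standard
errors from the numerical Hessian, AIC and a ``summary()`` table.  Baseline
hazards are re-constrained to the population incidence at every parameter
evaluation.

Single nuclear families (the shape produced by the family simulator) are
peeled in vectorised batches; arbitrary loop-free pedigrees fall back to the
generic peeler.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, logit
from scipy.stats import chi2, norm

from ._peelcore import nuclear_loglik
from .genetics import GenotypeSpace, SpaceOptions
from .hazards import constrain
from .likelihood import condition, individual_likelihood, resolve_scheme
from .parameters import ModelParameters
from .pedigree import GENES

# free-parameter registry: name -> (transform, inverse)
_LOGIT = (lambda x: logit(x), lambda y: float(expit(y)))
_LOG = (np.log, lambda y: float(np.exp(y)))
TRANSFORMS = {
    "f_brca2": _LOGIT, "f_brca1": _LOGIT, "f_hoxb13": _LOGIT, "f_rec": _LOGIT,
    "alpha": _LOGIT,
    "rr_rec_hom": _LOG, "rr_hoxb13_pre1930": _LOG, "rr_hoxb13_post1930": _LOG,
    "sigma70": _LOG, "sd_rate": _LOG,
}


class FitError(ValueError):
    pass


# ---------------------------------------------------------------------------
# vectorised data preparation

class _Members:
    """Columnar arrays for a flat list of individuals."""

    def __init__(self, inds):
        self.inds = list(inds)
        n = len(self.inds)
        self.n = n
        self.birth_year = np.array([i.birth_year for i in self.inds], dtype=int)
        self.male = np.array([i.sex == "M" for i in self.inds])
        self.affected = np.array([i.prostate_dx_age is not None for i in self.inds])
        self.dx_age = np.array([i.prostate_dx_age or 0 for i in self.inds], dtype=int)
        self.censor = np.array([i.censor_age for i in self.inds], dtype=int)
        self.tests = np.zeros((n, len(GENES)), dtype=int)  # 0 untested, 1 pos, 2 neg
        for j, g in enumerate(GENES):
            for i, ind in enumerate(self.inds):
                r = ind.test_results.get(g, "untested")
                self.tests[i, j] = {"untested": 0, "carrier": 1, "noncarrier": 2}[r]
        self.pgs = np.array([np.nan if i.pgs_z is None else i.pgs_z for i in self.inds])
        # censor age 0 with no diagnoses = no phenotype information at all
        self.female_plain = np.array([
            (i.sex == "F") and i.breast_dx_age is None and i.ovarian_dx_age is None
            and i.censor_age == 0 for i in self.inds])

    def lik_matrix(self, hazards, include_tests=True, include_pgs=True,
                   phenotypes=True):
        """(n, S) likelihood vectors, vectorised over individuals."""
        space = hazards.space
        params = hazards.params
        S = space.n_states
        L = np.ones((self.n, S))
        if phenotypes:
            for by in np.unique(self.birth_year[self.male]):
                H = hazards.cumhaz(by)
                lam = hazards.hazard_matrix(by)
                sel = self.male & (self.birth_year == by)
                idx_u = np.where(sel & ~self.affected)[0]
                if idx_u.size:
                    ages = np.clip(self.censor[idx_u], 0, hazards.max_age)
                    L[idx_u] = np.exp(-H[:, ages].T)
                idx_a = np.where(sel & self.affected)[0]
                if idx_a.size:
                    ages = np.clip(self.dx_age[idx_a], 0, hazards.max_age - 1)
                    L[idx_a] = np.exp(-H[:, ages].T) * (1.0 - np.exp(-lam[:, ages].T))
            # females with phenotype data are rare; handle individually
            for i in np.where(~self.male & ~self.female_plain)[0]:
                L[i] = individual_likelihood(self.inds[i], hazards,
                                             include_tests=False, include_pgs=False)
        if include_tests:
            sens = {"BRCA2": params.sens_brca2, "BRCA1": params.sens_brca1,
                    "HOXB13": params.sens_hoxb13}
            for j, g in enumerate(GENES):
                col = self.tests[:, j]
                if not col.any():
                    continue
                if g not in space.loci:
                    if (col == 1).any():
                        raise FitError(f"positive {g} test but locus inactive")
                    continue
                carrier = space.counts(g) >= 1
                pos = np.where(carrier, sens[g], 0.0)
                neg = np.where(carrier, 1.0 - sens[g], 1.0)
                L[col == 1] *= pos[None, :]
                L[col == 2] *= neg[None, :]
        if include_pgs:
            idx = np.where(~np.isnan(self.pgs))[0]
            if idx.size:
                s = params.pgs_noise_sd
                z = self.pgs[idx][:, None]
                L[idx] *= np.exp(-0.5 * ((z - space.a_values[None, :]) / s) ** 2) \
                    / (s * np.sqrt(2 * np.pi))
        return L


class _NuclearGroup:
    """Families with the same number of children, stacked for batch peeling."""

    def __init__(self, fams):
        # fams: list of (father, mother, [children], proband_child_index, scheme)
        self.n = len(fams)
        self.nc = len(fams[0][2])
        self.fathers = _Members([f[0] for f in fams])
        self.mothers = _Members([f[1] for f in fams])
        self.children = [_Members([f[2][c] for f in fams]) for c in range(self.nc)]
        self.proband_child = np.array([f[3] for f in fams], dtype=int)
        self.scheme = np.array([{"none": 0, "proband_phenotype": 1,
                                 "family_phenotypes": 2}[f[4]] for f in fams])

    def loglik(self, hazards):
        space = hazards.space
        trans = space.factor_trans
        prior = space.prior
        Lf = self.fathers.lik_matrix(hazards)
        Lm = self.mothers.lik_matrix(hazards)
        Lc = np.stack([c.lik_matrix(hazards) for c in self.children], axis=1) \
            if self.nc else np.zeros((self.n, 0, space.n_states))
        ll = nuclear_loglik(Lf, Lm, Lc, trans, prior)
        total = ll.sum()
        if (self.scheme > 0).any():
            Lcp = np.stack([c.lik_matrix(hazards, include_tests=False, include_pgs=False)
                            for c in self.children], axis=1)
        if (self.scheme == 1).any():
            # conditioning on the proband's phenotype alone: relatives
            # marginalise to the population prior, leaving a single sum
            rows = np.where(self.scheme == 1)[0]
            Lp = Lcp[rows, self.proband_child[rows], :]
            total -= np.log(Lp @ prior).sum()
        if (self.scheme == 2).any():
            Lfp = self.fathers.lik_matrix(hazards, include_tests=False, include_pgs=False)
            Lmp = self.mothers.lik_matrix(hazards, include_tests=False, include_pgs=False)
            llp = nuclear_loglik(Lfp, Lmp, Lcp, trans, prior)
            total -= llp[self.scheme == 2].sum()
        return float(total)


def _prepare(pedigrees, scheme):
    """Split pedigrees into batched nuclear groups and a generic remainder."""
    by_nc = {}
    slow = []
    for ped in pedigrees:
        fams = ped.nuclear_families()
        sch = resolve_scheme(ped, scheme)
        ok = len(fams) == 1
        if ok:
            f, mo, kids = fams[0]
            members = set([f, mo] + kids)
            ok = members == set(ped.members) and \
                ped.members[f].is_founder and ped.members[mo].is_founder
            ok = ok and (sch != "proband_phenotype" or ped.proband_id in kids)
        if not ok:
            slow.append((ped, sch))
            continue
        f, mo, kids = fams[0]
        pidx = kids.index(ped.proband_id) if ped.proband_id in kids else 0
        by_nc.setdefault(len(kids), []).append(
            (ped.members[f], ped.members[mo], [ped.members[k] for k in kids], pidx, sch))
    groups = [_NuclearGroup(fams) for fams in by_nc.values()]
    return groups, slow


# ---------------------------------------------------------------------------
# model / results

class SegregationModel:
    """Segregation-analysis likelihood over a collection of pedigrees.

    Parameters
    ----------
    pedigrees : sequence of Pedigree
    incidence : IncidenceTable
        Population rates the genotype-averaged hazards are constrained to.
    params : ModelParameters
        Starting values; also supplies every fixed parameter.
    free : sequence of str
        Names of free parameters (see ``canpros.fit.TRANSFORMS``).
    scheme : str
        Ascertainment-conditioning scheme, or 'auto' to pick per proband
        detection mode, or 'none'.
    """

    def __init__(self, pedigrees, incidence, params: ModelParameters = None,
                 free=(), scheme="auto", space_options: SpaceOptions = None,
                 max_age=90):
        self.pedigrees = list(pedigrees)
        if not self.pedigrees:
            raise FitError("at least one pedigree required")
        self.incidence = incidence
        self.start_params = params or ModelParameters()
        self.free = tuple(free)
        for name in self.free:
            if name not in TRANSFORMS:
                raise FitError(f"unknown free parameter {name!r}")
        self.scheme = scheme
        self.space_options = space_options or SpaceOptions()
        self.max_age = max_age
        self._groups, self._slow = _prepare(self.pedigrees, scheme)
        self._cache = {}

    # -- parameter plumbing -------------------------------------------------
    def _to_theta(self, params):
        return np.array([TRANSFORMS[n][0](getattr(params, n)) for n in self.free])

    def _to_params(self, theta):
        kw = {n: TRANSFORMS[n][1](t) for n, t in zip(self.free, theta)}
        return self.start_params.replace(**kw)

    def loglik(self, theta=None, params=None):
        """Summed ascertainment-conditioned log-likelihood."""
        if params is None:
            params = self._to_params(theta if theta is not None else np.empty(0))
        key = tuple(round(float(getattr(params, n)), 14) for n in TRANSFORMS)
        if key in self._cache:
            return self._cache[key]
        space = GenotypeSpace(params, self.space_options)
        hazards = constrain(self.incidence, params, space=space, max_age=self.max_age)
        total = 0.0
        for g in self._groups:
            total += g.loglik(hazards)
        for ped, sch in self._slow:
            total += condition(ped, hazards, scheme=sch)
        if not np.isfinite(total):
            total = -1e12
        self._cache[key] = total
        return total

    def fit(self, method="nelder-mead", polish=True, n_restarts=1, seed=0,
            xtol=1e-5, ftol=1e-6, maxiter=400, compute_se=True):
        """Maximise the likelihood; deterministic given ``seed`` and init."""
        theta0 = self._to_theta(self.start_params)
        k = len(theta0)
        if k == 0:
            ll = self.loglik(theta0)
            return SegregationResults(self, theta0, ll, converged=True,
                                      bse=np.empty(0))
        rng = np.random.default_rng(seed)
        starts = [theta0] + [theta0 + rng.normal(0, 0.5, size=k)
                             for _ in range(max(0, n_restarts - 1))]
        best = None
        converged = False
        for s in starts:
            res = optimize.minimize(
                lambda th: -self.loglik(th), s, method="Nelder-Mead",
                options={"xatol": xtol, "fatol": ftol, "maxiter": maxiter * max(1, k)})
            if best is None or res.fun < best.fun:
                best = res
                converged = bool(res.success)
        if polish:
            res = optimize.minimize(lambda th: -self.loglik(th), best.x,
                                    method="BFGS",
                                    options={"gtol": 1e-5, "maxiter": 50})
            if res.fun <= best.fun:
                best = res
                converged = converged or bool(res.success)
        theta = np.asarray(best.x, dtype=float)
        ll = -float(best.fun)
        bse = self._hessian_se(theta) if compute_se else np.full(k, np.nan)
        boundary = bool(np.any(np.abs(theta) > 12))
        return SegregationResults(self, theta, ll, converged=converged,
                                  bse=bse, boundary=boundary)

    def _hessian_se(self, theta, step=1e-3):
        k = len(theta)
        H = np.zeros((k, k))
        f0 = self.loglik(theta)
        hs = step * np.maximum(1.0, np.abs(theta))
        for i in range(k):
            ei = np.zeros(k); ei[i] = hs[i]
            for j in range(i, k):
                ej = np.zeros(k); ej[j] = hs[j]
                if i == j:
                    H[i, i] = (self.loglik(theta + ei) - 2 * f0 +
                               self.loglik(theta - ei)) / hs[i] ** 2
                else:
                    H[i, j] = H[j, i] = (
                        self.loglik(theta + ei + ej) - self.loglik(theta + ei - ej)
                        - self.loglik(theta - ei + ej) + self.loglik(theta - ei - ej)
                    ) / (4 * hs[i] * hs[j])
        try:
            cov = np.linalg.inv(-H)
            d = np.diag(cov)
            return np.where(d > 0, np.sqrt(np.abs(d)), np.nan)
        except np.linalg.LinAlgError:
            return np.full(k, np.nan)


class SegregationResults:
    """Fit results: estimates, SEs (transformed scale), log-likelihood, AIC."""

    def __init__(self, model, theta, llf, converged, bse, boundary=False):
        self.model = model
        self.theta = np.asarray(theta, dtype=float)
        self.llf = float(llf)
        self.converged = converged
        self.boundary = boundary
        self.bse = pd.Series(np.asarray(bse, dtype=float), index=list(model.free))
        self.params = model._to_params(self.theta)
        self.params_transformed = pd.Series(self.theta, index=list(model.free))
        self.k_free = len(model.free)

    @property
    def aic(self):
        return 2 * self.k_free - 2 * self.llf

    def conf_int(self, alpha=0.05, natural=True):
        """Wald intervals on the transformed scale, optionally back-mapped."""
        z = norm.ppf(1 - alpha / 2)
        rows = {}
        for name in self.model.free:
            th = self.params_transformed[name]
            se = self.bse[name]
            lo, hi = th - z * se, th + z * se
            if natural:
                inv = TRANSFORMS[name][1]
                lo, hi = inv(lo), inv(hi)
            rows[name] = (lo, hi)
        return pd.DataFrame(rows, index=["lower", "upper"]).T

    def estimates(self):
        """Natural-scale point estimates of the free parameters."""
        return pd.Series({n: getattr(self.params, n) for n in self.model.free})

    def lrt(self, reduced: "SegregationResults"):
        """Likelihood-ratio test of this (full) model against a nested one."""
        full_free = set(self.model.free)
        red_free = set(reduced.model.free)
        if not red_free < full_free:
            raise FitError("LRT requires the reduced model's free parameters to "
                           "be a strict subset of the full model's")
        for name in TRANSFORMS:
            if name in full_free:
                continue
            if getattr(self.model.start_params, name) != getattr(reduced.model.start_params, name):
                raise FitError(f"models differ in fixed parameter {name!r}; not nested")
        df = self.k_free - reduced.k_free
        stat = max(0.0, 2 * (self.llf - reduced.llf))
        return stat, df, float(chi2.sf(stat, df))

    def summary(self):
        ci = self.conf_int() if self.k_free else None
        lines = ["Segregation analysis results",
                 "=" * 60,
                 f"pedigrees: {len(self.model.pedigrees)}   scheme: {self.model.scheme}",
                 f"log-likelihood: {self.llf:.4f}   AIC: {self.aic:.4f}",
                 f"converged: {self.converged}   boundary: {self.boundary}",
                 "-" * 60]
        if self.k_free:
            lines.append(f"{'param':<22}{'estimate':>12}{'ci95_lo':>12}{'ci95_hi':>12}")
            for name in self.model.free:
                est = getattr(self.params, name)
                lines.append(f"{name:<22}{est:>12.5g}"
                             f"{ci.loc[name, 'lower']:>12.5g}{ci.loc[name, 'upper']:>12.5g}")
        else:
            lines.append("(all parameters fixed)")
        return "\n".join(lines)


def compare(results):
    """AIC comparison table for fits on identical data."""
    results = list(results)
    n_ped = {len(r.model.pedigrees) for r in results}
    if len(n_ped) != 1:
        raise FitError("compare() requires fits on identical data")
    df = pd.DataFrame({
        "free": [",".join(r.model.free) or "(none)" for r in results],
        "k": [r.k_free for r in results],
        "llf": [r.llf for r in results],
        "aic": [r.aic for r in results],
    })
    df["delta_aic"] = df["aic"] - df["aic"].min()
    return df.sort_values("aic").reset_index(drop=True)
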