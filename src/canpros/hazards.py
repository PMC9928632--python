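"""Incidence-constrained genotype-specific hazards.

Genotype-specific prostate cancer hazards are ``lambda(t|s) = lambda0(t) *
RR(s, t)``.  The baseline ``lambda0`` is not free: at every age the
population-average hazard among still-unaffected men must equal the external
incidence rate,

    sum_s p_t(s) * lambda0(t) * RR(s, t) = lambda_pop(t),

where ``p_t`` is the genotype distribution among survivors to age ``t``
(prior survival-weighted year by year).  Solving age by age gives
``lambda0(t) = lambda_pop(t) / E[RR | unaffected at t]``.

Risks are cause-specific cumulative risks: no competing (all-cause)
mortality is applied, matching how lifetime risks are usually presented for
this model family.  Ages are integer years; a rate tabulated for a coarse
band applies to every one-year interval inside it.
"""

from __future__ import annotations

import numpy as np

from .genetics import GenotypeSpace
from .incidence import IncidenceTable
from .parameters import ModelParameters


class HazardError(ValueError):
    pass


class ConstrainedHazards:
    """Per-birth-cohort baseline hazards and per-state cumulative hazards.

    Arrays per birth year: ``lambda0`` (T,), per-state hazard matrix
    ``lam[s, t]`` and cumulative hazard ``cumhaz[s, t] = sum_{u<t} lam[s,u]``
    with shape (S, T+1).
    """

    def __init__(self, space: GenotypeSpace, incidence: IncidenceTable,
                 max_age: int = 90, sex="M", site="prostate"):
        self.space = space
        self.params = space.params
        self.incidence = incidence
        self.max_age = int(max_age)
        self.sex = sex
        self.site = site
        self._by: dict[int, dict] = {}
        self._shared: dict = {}

    def _build(self, birth_year):
        T = self.max_age
        lam_pop = self.incidence.rates_for_cohort(birth_year, self.sex, self.site, T)
        # hazards depend on the birth year only through the rate vector and
        # the HOXB13 birth-cohort relative risk; share identical builds
        key = (birth_year >= 1930, lam_pop.tobytes())
        if key in self._shared:
            return self._shared[key]
        self._shared[key] = out = self._build_uncached(birth_year, lam_pop)
        return out

    def _build_uncached(self, birth_year, lam_pop):
        T = self.max_age
        rr = np.exp(self.space.log_rr(np.arange(T), birth_year))  # (S, T)
        prior = self.space.prior
        if prior.sum() <= 0:
            raise HazardError("degenerate genotype prior")
        p = prior / prior.sum()
        lam0 = np.zeros(T)
        lam = np.zeros_like(rr)
        for t in range(T):
            mean_rr = float(p @ rr[:, t])
            if mean_rr <= 0:
                raise HazardError(f"E[RR] <= 0 at age {t}; degenerate parameters")
            lam0[t] = lam_pop[t] / mean_rr
            lam[:, t] = lam0[t] * rr[:, t]
            p = p * np.exp(-lam[:, t])
            p = p / p.sum()
        cumhaz = np.concatenate([np.zeros((rr.shape[0], 1)), np.cumsum(lam, axis=1)], axis=1)
        return {"lam_pop": lam_pop, "lam0": lam0, "lam": lam, "cumhaz": cumhaz}

    def for_birth_year(self, birth_year):
        birth_year = int(birth_year)
        if birth_year not in self._by:
            self._by[birth_year] = self._build(birth_year)
        return self._by[birth_year]

    def baseline(self, birth_year):
        return self.for_birth_year(birth_year)["lam0"]

    def hazard_matrix(self, birth_year):
        """(S, T) per-state annual hazards."""
        return self.for_birth_year(birth_year)["lam"]

    def cumhaz(self, birth_year):
        """(S, T+1) per-state cumulative hazards; column t = H(t)."""
        return self.for_birth_year(birth_year)["cumhaz"]

    def population_rates(self, birth_year):
        return self.for_birth_year(birth_year)["lam_pop"]

    def survivor_distribution(self, birth_year, age):
        """Genotype distribution among men unaffected at ``age``."""
        w = self.space.prior * np.exp(-self.cumhaz(birth_year)[:, age])
        return w / w.sum()


def constrain(incidence: IncidenceTable, params: ModelParameters, birth_year=None,
              space: GenotypeSpace | None = None, max_age: int = 90,
              sex="M", site="prostate") -> ConstrainedHazards:
    """Build constrained hazards; cohorts are constrained lazily on lookup.

    If ``birth_year`` is given that cohort is constrained eagerly (useful to
    surface degenerate-parameter errors early).
    """
    if space is None:
        space = GenotypeSpace(params)
    elif space.params != params:
        raise HazardError("space was built from different ModelParameters")
    h = ConstrainedHazards(space, incidence, max_age=max_age, sex=sex, site=site)
    if birth_year is not None:
        h.for_birth_year(birth_year)
    return h


def cumulative_risk(hazards: ConstrainedHazards, weights, from_age, to_age,
                    birth_year=1960):
    """Probability of a first event in ``[from_age, to_age)``.

    ``weights`` is a distribution over joint states (or a single flat state
    index); it is re-weighted by survival to ``from_age``, so the result is
    conditional on being unaffected at ``from_age``.
    """
    if not (0 <= from_age < to_age <= hazards.max_age):
        raise HazardError(f"need 0 <= from_age < to_age <= {hazards.max_age}")
    H = hazards.cumhaz(birth_year)
    if np.isscalar(weights):
        w = np.zeros(hazards.space.n_states)
        w[int(weights)] = 1.0
    else:
        w = np.asarray(weights, dtype=float)
    w = w * np.exp(-H[:, from_age])
    tot = w.sum()
    if tot <= 0:
        raise HazardError("no surviving probability mass at from_age")
    w = w / tot
    return float(w @ (1.0 - np.exp(-(H[:, to_age] - H[:, from_age]))))
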