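"""Joint genotype space: major loci x discretised polygenic components.

The state space is the product of up to four biallelic loci (allele counts
0/1/2, Hardy-Weinberg priors, Mendelian transmission) and two independent
discretised polygenic sub-components:

* ``A`` -- the part of the polygenic component (PGC) captured by the measured
  polygenic score (PGS); the observed PGS is a Gaussian measurement of the
  individual's ``A`` level.
* ``B`` -- the residual part, never observed directly.

Each sub-component uses the hypergeometric polygenic approximation: levels
``(i - k)/sqrt(k/2)`` for ``i = 0..2k`` with Binomial(2k, 1/2) weights (unit
variance, zero mean, exactly stationary under random mating), and each parent
transmits ``k`` of its ``2k`` exchangeable polygenic "alleles" to a child
(hypergeometric sampling), giving mid-parent offspring means and a mean
segregation variance of half the population variance.

An individual's total polygenic log-hazard effect at age ``t`` is

    sigma(t) * (alpha * A + sqrt(1 - alpha^2) * B)

so the genotype is fixed over life while its effect tracks the age-dependent
SD ``sigma(t)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.stats import binom, hypergeom

from .parameters import ModelParameters

LOCI = ("BRCA2", "BRCA1", "HOXB13", "REC")


# ---------------------------------------------------------------------------
# polygene grid

@lru_cache(maxsize=None)
def _polygene_tables(n_levels: int):
    if n_levels % 2 != 1 or n_levels < 1:
        raise ValueError("polygene grid needs an odd positive number of levels")
    k = (n_levels - 1) // 2
    counts = np.arange(n_levels)
    if k == 0:
        return np.zeros(1), np.ones(1), np.ones((1, 1, 1))
    scale = np.sqrt(k / 2.0)
    values = (counts - k) / scale
    probs = binom.pmf(counts, 2 * k, 0.5)
    # transmitted counts: child = (k alleles sampled from father's 2k) +
    # (k sampled from mother's 2k)
    H = hypergeom.pmf(np.arange(k + 1)[:, None], 2 * k, counts[None, :], k)  # (k+1, n)
    T = np.zeros((n_levels, n_levels, n_levels))
    for a in range(k + 1):
        for b in range(k + 1):
            T[a + b] += H[a][:, None] * H[b][None, :]
    return values, probs, T


@dataclass(frozen=True)
class PolygeneGrid:
    """Discretised standardized polygenic sub-component."""

    n_levels: int = 7

    @property
    def values(self):
        return _polygene_tables(self.n_levels)[0]

    @property
    def probs(self):
        return _polygene_tables(self.n_levels)[1]

    @property
    def transmission(self):
        """T[c, f, m] = P(child level c | father f, mother m)."""
        return _polygene_tables(self.n_levels)[2]


# ---------------------------------------------------------------------------
# biallelic locus tables

def _locus_prior(q):
    p = 1.0 - q
    return np.array([p * p, 2 * p * q, q * q])


_MENDEL = None


def _locus_transmission():
    """T[c, f, m] for allele counts under Mendelian segregation."""
    global _MENDEL
    if _MENDEL is None:
        T = np.zeros((3, 3, 3))
        for f in range(3):
            for m in range(3):
                pf, pm = f / 2.0, m / 2.0
                T[0, f, m] = (1 - pf) * (1 - pm)
                T[1, f, m] = pf * (1 - pm) + (1 - pf) * pm
                T[2, f, m] = pf * pm
        _MENDEL = T
    return _MENDEL


# ---------------------------------------------------------------------------
# joint space

@dataclass(frozen=True)
class SpaceOptions:
    """Discretisation choices for the joint state space.

    ``n_levels_obs``/``n_levels_res`` set the PGS-part and residual polygene
    grids (odd; 1 disables a component).  ``loci`` optionally forces the set
    of active major loci; by default a locus is active iff its allele
    frequency is positive, which keeps toy/reduced spaces small.
    """

    n_levels_obs: int = 7
    n_levels_res: int = 7
    loci: tuple | None = None


class GenotypeSpace:
    """Flattened joint distribution over (major genotypes, A, B).

    Factor order: active loci (subset of BRCA2, BRCA1, HOXB13, REC, in that
    order), then the observed-part grid ``A``, then the residual grid ``B``.
    """

    def __init__(self, params: ModelParameters, options: SpaceOptions = SpaceOptions()):
        self.params = params
        self.options = options
        freqs = {"BRCA2": params.f_brca2, "BRCA1": params.f_brca1,
                 "HOXB13": params.f_hoxb13, "REC": params.f_rec}
        if options.loci is None:
            active = tuple(l for l in LOCI if freqs[l] > 0)
        else:
            active = tuple(l for l in LOCI if l in options.loci)
        self.loci = active

        self.factor_names = list(active) + ["A", "B"]
        self.factor_priors = []
        self.factor_trans = []
        for l in active:
            self.factor_priors.append(_locus_prior(freqs[l]))
            self.factor_trans.append(_locus_transmission())
        self.grid_a = PolygeneGrid(options.n_levels_obs)
        self.grid_b = PolygeneGrid(options.n_levels_res)
        for g in (self.grid_a, self.grid_b):
            self.factor_priors.append(g.probs)
            self.factor_trans.append(g.transmission)

        self.dims = tuple(len(p) for p in self.factor_priors)
        self.n_states = int(np.prod(self.dims))

        # per-state attribute arrays
        grids = np.meshgrid(*[np.arange(d) for d in self.dims], indexing="ij")
        flat = [g.ravel() for g in grids]
        self.allele_counts = {l: flat[i] for i, l in enumerate(active)}
        self.a_values = self.grid_a.values[flat[len(active)]]
        self.b_values = self.grid_b.values[flat[len(active) + 1]]

        prior = np.ones(self.n_states)
        for i, p in enumerate(self.factor_priors):
            prior *= p[flat[i]]
        self.prior = prior

        a_frac, b_frac = params.pgs_sd_fractions()
        # multiplier of sigma(t) on the log-hazard scale
        self.pg_multiplier = a_frac * self.a_values + b_frac * self.b_values

    # -- risk attributes ----------------------------------------------------
    def counts(self, locus):
        """Allele counts per state (zeros if the locus is inactive)."""
        return self.allele_counts.get(locus, np.zeros(self.n_states, dtype=int))

    def major_log_rr(self, ages, birth_year):
        """(n_states, n_ages) log relative risk from the major loci."""
        ages = np.atleast_1d(np.asarray(ages))
        p = self.params
        out = np.zeros((self.n_states, len(ages)))
        c2 = self.counts("BRCA2") >= 1
        out += np.outer(c2, np.log(p.rr_brca2.at(ages)))
        c1 = self.counts("BRCA1") >= 1
        out += np.outer(c1, np.log(p.rr_brca1.at(ages)))
        ch = self.counts("HOXB13").astype(float)
        out += np.log(p.rr_hoxb13(birth_year)) * ch[:, None]
        cr = self.counts("REC")
        lr = np.log(p.rr_rec_hom)
        if p.rec_mode == "recessive":
            out += lr * (cr == 2).astype(float)[:, None]
        elif p.rec_mode == "dominant":
            out += lr * (cr >= 1).astype(float)[:, None]
        else:  # multiplicative per allele
            out += lr * cr.astype(float)[:, None]
        return out

    def log_rr(self, ages, birth_year):
        """(n_states, n_ages) total log RR including the polygenic effect."""
        ages = np.atleast_1d(np.asarray(ages))
        sig = self.params.polygenic_sd(ages)
        return self.major_log_rr(ages, birth_year) + np.outer(self.pg_multiplier, sig)

    # -- sampling -----------------------------------------------------------
    def sample_founders(self, n, rng):
        """(n, n_factors) integer factor states drawn from the prior."""
        cols = [rng.choice(len(p), size=n, p=p) for p in self.factor_priors]
        return np.stack(cols, axis=1)

    def sample_children(self, fathers, mothers, rng):
        """Factor states of offspring given parental factor-state arrays."""
        n = fathers.shape[0]
        out = np.empty_like(fathers)
        for i, T in enumerate(self.factor_trans):
            probs = T[:, fathers[:, i], mothers[:, i]].T  # (n, d)
            u = rng.random(n)
            out[:, i] = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)
        return out

    def flatten_states(self, factor_states):
        return np.ravel_multi_index(tuple(factor_states.T), self.dims)


# ---------------------------------------------------------------------------
# module-level convenience operations

def polygenic_sd(age, params: ModelParameters):
    """SD of the polygenic component at ``age`` (log-linear in age)."""
    return params.polygenic_sd(age)


def decompose_pgs(params: ModelParameters, age=None):
    """Split the polygenic SD into PGS-explained and residual parts.

    With ``age=None`` returns the SD *fractions* ``(alpha, sqrt(1-alpha^2))``;
    otherwise the age-specific SDs.  Variances always add to ``sigma(age)**2``.
    """
    fa, fb = params.pgs_sd_fractions()
    if age is None:
        return fa, fb
    sig = params.polygenic_sd(age)
    return fa * sig, fb * sig


def genotype_prior(params: ModelParameters, birth_year=None,
                   options: SpaceOptions | None = None):
    """Population distribution over major genotypes (HWE x linkage equilib.).

    Returns ``(states, probs)`` where states is an (n, 4) array of allele
    counts in locus order BRCA2, BRCA1, HOXB13, REC.  The distribution does
    not depend on birth year (only relative risks do); the argument is kept
    for interface symmetry.
    """
    opts = options or SpaceOptions(n_levels_obs=1, n_levels_res=1)
    opts = SpaceOptions(n_levels_obs=1, n_levels_res=1, loci=opts.loci)
    space = GenotypeSpace(params, opts)
    states = np.stack([space.counts(l) for l in LOCI], axis=1)
    return states, space.prior.copy()


def relative_risk(genotype, polygene_value, pgs_z, age, birth_year,
                  params: ModelParameters):
    """Multiplicative hazard ratio for one joint state.

    ``genotype`` maps locus name to allele count (missing = 0).  The
    polygene enters as ``exp(sigma(age) * polygene_value)`` (standardised
    total level); if ``pgs_z`` is given instead of a residual split the
    observed and residual parts are combined as
    ``alpha * pgs_z + sqrt(1-alpha^2) * polygene_value``.
    """
    p = params
    log_rr = 0.0
    if genotype.get("BRCA2", 0) >= 1:
        log_rr += float(np.log(p.rr_brca2.at(age)))
    if genotype.get("BRCA1", 0) >= 1:
        log_rr += float(np.log(p.rr_brca1.at(age)))
    log_rr += genotype.get("HOXB13", 0) * np.log(p.rr_hoxb13(birth_year))
    cr = genotype.get("REC", 0)
    if p.rec_mode == "recessive":
        log_rr += (cr == 2) * np.log(p.rr_rec_hom)
    elif p.rec_mode == "dominant":
        log_rr += (cr >= 1) * np.log(p.rr_rec_hom)
    else:
        log_rr += cr * np.log(p.rr_rec_hom)
    sig = float(p.polygenic_sd(age))
    fa, fb = p.pgs_sd_fractions()
    if pgs_z is None:
        log_rr += sig * polygene_value
    else:
        log_rr += sig * (fa * pgs_z + fb * polygene_value)
    return float(np.exp(log_rr))


def transmission(space: GenotypeSpace, father_state, mother_state):
    """Offspring distribution over joint states given parental joint states.

    States are flat indices into ``space``; returns a vector of length
    ``space.n_states``.
    """
    f = np.array(np.unravel_index(father_state, space.dims))
    m = np.array(np.unravel_index(mother_state, space.dims))
    out = np.ones(1)
    for i, T in enumerate(space.factor_trans):
        out = np.kron(out, T[:, f[i], m[i]])
    return out
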