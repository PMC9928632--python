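"""Pedigree likelihood by Elston-Stewart peeling, with ascertainment
conditioning.

Each individual contributes (a) survival to their censoring age times, if
affected, the probability of an event in the diagnosis year ``[a, a+1)``;
(b) per-gene genetic-test factors, ``P(positive | carrier) = sensitivity``
with perfect specificity; (c) a Gaussian PGS factor around the observed-part
polygene level.  Female relatives contribute breast/ovarian phenotypes
through externally supplied penetrance multipliers (no polygenic effect on
female cancers).

The likelihood of a loop-free pedigree is computed exactly by recursive
elimination of nuclear families (peeling); ascertainment is adjusted by
conditioning: ``log L(full data) - log L(conditioning data)``.
"""

from __future__ import annotations

import numpy as np

from ._peelcore import transmit_down, transmit_up
from .hazards import ConstrainedHazards
from .pedigree import GENES, Pedigree

SCHEMES = ("proband_phenotype", "family_phenotypes", "none", "auto")

_SENS_ATTR = {"BRCA2": "sens_brca2", "BRCA1": "sens_brca1", "HOXB13": "sens_hoxb13"}


class LikelihoodError(ValueError):
    pass


def _female_cancer_factor(ind, hazards: ConstrainedHazards):
    """Breast/ovarian phenotype likelihood per state (females).

    Uses unconstrained external hazards: population female incidence times
    the BRCA1/2 penetrance multipliers.  Sites absent from the incidence
    table are skipped (the phenotype is then uninformative by construction).
    """
    space = hazards.space
    params = hazards.params
    fp = params.female_penetrance
    out = np.ones(space.n_states)
    c1 = space.counts("BRCA1") >= 1
    c2 = space.counts("BRCA2") >= 1
    sites = {"breast": (ind.breast_dx_age, fp.breast_rr_brca1, fp.breast_rr_brca2),
             "ovarian": (ind.ovarian_dx_age, fp.ovarian_rr_brca1, fp.ovarian_rr_brca2)}
    available = set(hazards.incidence.sites("F"))
    for site, (dx_age, rr1, rr2) in sites.items():
        if site not in available:
            continue
        rates = hazards.incidence.rates_for_cohort(ind.birth_year, "F", site, hazards.max_age)
        stop = min(dx_age if dx_age is not None else ind.censor_age, hazards.max_age - 1)
        ages = np.arange(hazards.max_age)
        lrr = (np.outer(c1, np.log(rr1.at(ages))) + np.outer(c2, np.log(rr2.at(ages))))
        lam = rates[None, :] * np.exp(lrr)  # (S, T)
        H = lam[:, :stop].sum(axis=1)
        f = np.exp(-H)
        if dx_age is not None:
            f = f * (1.0 - np.exp(-lam[:, min(dx_age, hazards.max_age - 1)]))
        out = out * f
    return out


def individual_likelihood(ind, hazards: ConstrainedHazards,
                          include_tests=True, include_pgs=True,
                          include_phenotype=True):
    """Per-state likelihood vector for one individual.

    The product of phenotype, genetic-test and PGS factors; masking switches
    support ascertainment conditioning.
    """
    space = hazards.space
    params = hazards.params
    L = np.ones(space.n_states)
    if include_phenotype:
        if ind.sex == "M":
            H = hazards.cumhaz(ind.birth_year)
            lam = hazards.hazard_matrix(ind.birth_year)
            if ind.prostate_dx_age is not None:
                a = min(int(ind.prostate_dx_age), hazards.max_age - 1)
                L = L * np.exp(-H[:, a]) * (1.0 - np.exp(-lam[:, a]))
            else:
                c = min(int(ind.censor_age), hazards.max_age)
                L = L * np.exp(-H[:, c])
        else:
            L = L * _female_cancer_factor(ind, hazards)
    if include_tests:
        for g in GENES:
            res = ind.test_results.get(g, "untested")
            if res == "untested":
                continue
            sens = getattr(params, _SENS_ATTR[g])
            if g not in space.loci:
                if res == "carrier":
                    raise LikelihoodError(
                        f"individual {ind.id}: positive {g} test but the locus is "
                        f"inactive (frequency 0) in this state space")
                continue
            carrier = space.counts(g) >= 1
            if res == "carrier":
                L = L * np.where(carrier, sens, 0.0)
            else:
                L = L * np.where(carrier, 1.0 - sens, 1.0)
    if include_pgs and ind.pgs_z is not None:
        s = params.pgs_noise_sd
        z = float(ind.pgs_z)
        L = L * np.exp(-0.5 * ((z - space.a_values) / s) ** 2) / (s * np.sqrt(2 * np.pi))
    return L


def member_likelihoods(ped: Pedigree, hazards: ConstrainedHazards,
                       include_tests=True, include_pgs=True,
                       phenotype_ids=None):
    """Likelihood vectors for every member; ``phenotype_ids`` restricts whose
    phenotypes are observed (None = all; empty set = none)."""
    out = {}
    for ind in ped:
        keep = phenotype_ids is None or ind.id in phenotype_ids
        out[ind.id] = individual_likelihood(
            ind, hazards, include_tests=include_tests,
            include_pgs=include_pgs, include_phenotype=keep)
    return out


def _pivots(fam_members, ind_fams, fi, processed):
    out = []
    for x in dict.fromkeys(fam_members):
        if any(not processed[fj] for fj in ind_fams[x] if fj != fi):
            out.append(x)
    return out


def _peel_engine(ped: Pedigree, hazards: ConstrainedHazards, liks, target=None):
    """Shared peeling recursion.

    Returns ``(loglik, posterior)``; ``posterior`` is the normalised state
    distribution of ``target`` (or None).  ``loglik`` is -inf for impossible
    data.
    """
    space = hazards.space
    prior = space.prior
    trans = space.factor_trans
    m = {}
    for ind in ped:
        v = np.asarray(liks[ind.id], dtype=float)
        m[ind.id] = v * prior if ind.is_founder else v.copy()

    fams = ped.nuclear_families()
    ind_fams = {i: [] for i in ped.members}
    for fi, (f, mo, kids) in enumerate(fams):
        for x in [f, mo] + kids:
            ind_fams[x].append(fi)
    processed = [False] * len(fams)
    logscale = 0.0
    final_terms = []

    def fam_value(fi, exclude_child=None):
        f, mo, kids = fams[fi]
        A = None
        for c in kids:
            if c == exclude_child:
                continue
            M = transmit_up(m[c], trans)
            A = M if A is None else A * M
        if A is None:
            A = np.ones((space.n_states, space.n_states))
        return A

    while not all(processed):
        progressed = False
        n_left = processed.count(False)
        for fi in range(len(fams)):
            if processed[fi]:
                continue
            f, mo, kids = fams[fi]
            members = [f, mo] + kids
            has_target = target is not None and target in members
            if has_target and n_left == 1:
                continue  # finalisation handles the last target family
            piv = _pivots(members, ind_fams, fi, processed)
            if has_target and target not in piv:
                piv = piv + [target]
            if len(piv) > 1:
                continue
            pivot = piv[0] if piv else None
            if pivot is None:
                A = fam_value(fi)
                val = float(np.einsum("f,fm,m->", m[f], A, m[mo]))
                if val <= 0:
                    return -np.inf, None
                final_terms.append(np.log(val))
            elif pivot == f or pivot == mo:
                other = mo if pivot == f else f
                A = fam_value(fi)
                if pivot == f:
                    msg = A @ m[other]
                else:
                    msg = m[other] @ A
                m[pivot] = m[pivot] * msg
                s = m[pivot].max()
                if s <= 0:
                    return -np.inf, None
                m[pivot] /= s
                logscale += np.log(s)
            else:
                A = fam_value(fi, exclude_child=pivot)
                B = A * m[f][:, None] * m[mo][None, :]
                msg = transmit_down(B, trans)
                m[pivot] = m[pivot] * msg
                s = m[pivot].max()
                if s <= 0:
                    return -np.inf, None
                m[pivot] /= s
                logscale += np.log(s)
            processed[fi] = True
            progressed = True
            n_left -= 1
        if not progressed:
            if target is not None and n_left == 1:
                break
            raise LikelihoodError(
                f"pedigree {ped.fam_id}: no peelable nuclear family (loop?)")

    posterior = None
    if target is not None:
        remaining = [fi for fi in range(len(fams)) if not processed[fi]]
        if not remaining:
            vec = m[target]
        else:
            fi = remaining[0]
            f, mo, kids = fams[fi]
            if target in kids:
                A = fam_value(fi, exclude_child=target)
                B = A * m[f][:, None] * m[mo][None, :]
                vec = m[target] * transmit_down(B, trans)
            else:
                other = mo if target == f else f
                A = fam_value(fi)
                msg = (A @ m[other]) if target == f else (m[other] @ A)
                vec = m[target] * msg
        tot = vec.sum()
        if tot <= 0:
            return -np.inf, None
        posterior = vec / tot
        final_terms.append(np.log(tot))
    else:
        for ind in ped:
            if not ind_fams[ind.id]:
                val = m[ind.id].sum()
                if val <= 0:
                    return -np.inf, None
                final_terms.append(np.log(val))
    return logscale + sum(final_terms), posterior


def peel(ped: Pedigree, hazards: ConstrainedHazards, liks=None, **mask):
    """Exact pedigree log-likelihood (equals the full joint-state sum)."""
    if liks is None:
        liks = member_likelihoods(ped, hazards, **mask)
    ll, _ = _peel_engine(ped, hazards, liks)
    return ll


def _conditioning_liks(ped, hazards, scheme):
    if scheme == "proband_phenotype":
        if ped.proband_id is None:
            raise LikelihoodError(f"pedigree {ped.fam_id}: no proband for conditioning")
        return member_likelihoods(ped, hazards, include_tests=False,
                                  include_pgs=False, phenotype_ids={ped.proband_id})
    if scheme == "family_phenotypes":
        return member_likelihoods(ped, hazards, include_tests=False, include_pgs=False)
    raise LikelihoodError(f"unknown conditioning scheme {scheme!r}")


def resolve_scheme(ped: Pedigree, scheme="auto"):
    """Map 'auto' to a concrete scheme from the proband's detection mode.

    Symptomatic probands condition on the proband's phenotype only; screen-
    or unknown-detected probands condition on all family phenotypes (their
    families' FH may have influenced testing and hence ascertainment).
    """
    if scheme != "auto":
        return scheme
    if ped.proband is None:
        return "none"
    if ped.proband.detection_mode == "symptomatic":
        return "proband_phenotype"
    return "family_phenotypes"


def condition(ped: Pedigree, hazards: ConstrainedHazards, scheme="auto"):
    """Ascertainment-adjusted log-likelihood: full minus conditioning peel."""
    scheme = resolve_scheme(ped, scheme)
    if scheme not in SCHEMES:
        raise LikelihoodError(f"unknown scheme {scheme!r}")
    full = peel(ped, hazards)
    if scheme == "none":
        return full
    cond = peel(ped, hazards, liks=_conditioning_liks(ped, hazards, scheme))
    if not np.isfinite(cond):
        raise LikelihoodError(
            f"pedigree {ped.fam_id}: conditioning event has likelihood 0")
    return full - cond
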