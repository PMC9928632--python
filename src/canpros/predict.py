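"""Posterior genotype inference and absolute-risk prediction for consultands.

The consultand's posterior state distribution given family phenotypes,
genetic tests and PGS is obtained from the same pedigree likelihood used for
fitting (peeled with the consultand as the terminal pivot), conditioned on
the consultand being unaffected at the current age.  Absolute risks follow by
averaging state-specific cumulative risks over the posterior; risks are
cause-specific (no competing mortality) and conditional on being cancer-free
at the current age.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._peelcore import contract_kernels, nuclear_message, parent_child_kernels
from .genetics import GenotypeSpace, SpaceOptions
from .hazards import ConstrainedHazards, constrain
from .likelihood import LikelihoodError, _peel_engine, member_likelihoods
from .parameters import ModelParameters
from .pedigree import Individual, Pedigree


class PredictionError(ValueError):
    pass


@dataclass
class RiskCurve:
    """Cumulative prostate cancer risk for a consultand by target age."""

    consultand_id: str
    current_age: int
    ages: np.ndarray
    risks: np.ndarray
    carrier_probs: dict = field(default_factory=dict)

    def to_frame(self):
        return pd.DataFrame({"age": self.ages, "cumulative_risk": self.risks})

    def at(self, age):
        i = int(np.searchsorted(self.ages, age))
        if i >= len(self.ages) or self.ages[i] != age:
            raise KeyError(f"age {age} not on the curve grid")
        return float(self.risks[i])

    def plot(self, ax=None, reference=None, **kw):
        """Plot the cumulative risk curve (optionally with a population
        reference curve, as in the published scenario figures)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.ages, 100 * self.risks,
                label=kw.pop("label", f"consultand {self.consultand_id}"), **kw)
        if reference is not None:
            ax.plot(reference.ages, 100 * reference.risks, color="black",
                    label="population average")
        ax.set_xlabel("age (years)")
        ax.set_ylabel("cumulative prostate cancer risk (%)")
        ax.legend()
        return ax


def posterior_states(ped: Pedigree, consultand_id, hazards: ConstrainedHazards):
    """Posterior distribution over the consultand's joint genotype states.

    Proportional to the pedigree likelihood with the consultand's state
    clamped; includes conditioning on the consultand being unaffected at
    their censoring (current) age.
    """
    if consultand_id not in ped.members:
        raise PredictionError(f"consultand {consultand_id} not in pedigree {ped.fam_id}")
    cons = ped.members[consultand_id]
    if cons.prostate_dx_age is not None:
        raise PredictionError("consultand is affected; the model predicts future "
                              "first cancers only")
    liks = member_likelihoods(ped, hazards)
    ll, post = _peel_engine(ped, hazards, liks, target=consultand_id)
    if post is None:
        raise LikelihoodError(f"pedigree {ped.fam_id}: zero-likelihood data")
    return post


def predict_risk(ped: Pedigree, consultand_id, hazards: ConstrainedHazards,
                 target_ages) -> RiskCurve:
    """Absolute cumulative risk curve from the consultand's current age."""
    cons = ped.members[consultand_id]
    cur = int(cons.censor_age)
    ages = np.asarray(sorted(int(a) for a in np.atleast_1d(target_ages)))
    if (ages < cur).any():
        raise PredictionError("target ages must be >= the current age")
    post = posterior_states(ped, consultand_id, hazards)
    H = hazards.cumhaz(cons.birth_year)
    ages_c = np.clip(ages, None, hazards.max_age)
    delta = H[:, ages_c] - H[:, [cur]]
    risks = post @ (1.0 - np.exp(-delta))
    space = hazards.space
    carrier = {g: float(post[space.counts(g) >= 1].sum()) for g in space.loci}
    return RiskCurve(consultand_id, cur, ages, risks, carrier)


# ---------------------------------------------------------------------------
# model-implied familial relative risks

def _person(id, sex, by, censor=0, dx=None, father=None, mother=None):
    return Individual(id=id, sex=sex, birth_year=by, censor_age=censor,
                      prostate_dx_age=dx, father_id=father, mother_id=mother,
                      detection_mode="unknown" if dx else "not_applicable")


def familial_relative_risk(params: ModelParameters, incidence, relation,
                           proband_dx_age, target_ages,
                           consultand_birth_year=1960, father_birth_year=1935,
                           space_options: SpaceOptions | None = None,
                           max_age=90):
    """Model-implied FRR: hazard of a relative of an affected index case over
    the population hazard, by the relative's age.

    ``relation`` names the affected index relative as seen from the
    consultand: 'father', 'brother' or 'son'.  Computed by exact summation
    over the joint family state space (parents integrated out for brothers).
    """
    a = int(proband_dx_age)
    cby, fby = consultand_birth_year, father_birth_year
    if relation == "father":
        members = [_person("F", "M", fby, censor=a, dx=a),
                   _person("M", "F", fby + 2),
                   _person("C", "M", cby, father="F", mother="M")]
    elif relation == "brother":
        members = [_person("F", "M", fby), _person("M", "F", fby + 2),
                   _person("B", "M", cby, censor=a, dx=a, father="F", mother="M"),
                   _person("C", "M", cby, father="F", mother="M")]
    elif relation == "son":
        sby = cby + 30
        members = [_person("C", "M", cby), _person("W", "F", cby + 2),
                   _person("S", "M", sby, censor=a, dx=a, father="C", mother="W")]
    else:
        raise PredictionError(f"unsupported relation {relation!r}")
    ped = Pedigree("frr", members)
    space = GenotypeSpace(params, space_options or SpaceOptions())
    hazards = constrain(incidence, params, space=space, max_age=max_age)
    post0 = posterior_states(ped, "C", hazards)  # consultand uninformative
    H = hazards.cumhaz(cby)
    lam = hazards.hazard_matrix(cby)
    lam_pop = hazards.population_rates(cby)
    ages = np.asarray(sorted(int(t) for t in np.atleast_1d(target_ages)))
    out = np.full(len(ages), np.nan)
    for i, t in enumerate(ages):
        if t >= max_age or lam_pop[t] <= 0:
            continue
        w = post0 * np.exp(-H[:, t])
        w = w / w.sum()
        out[i] = float(w @ lam[:, t]) / lam_pop[t]
    return pd.Series(out, index=ages, name=f"frr_{relation}")


# ---------------------------------------------------------------------------
# batched cohort prediction from family-history summaries

INFORMATION_LEVELS = ("age", "fh", "pv", "pgs", "full")
_TEST_INT = {"0": 0, "P": 1, "N": 2}


def _own_weights(records, hazards, use_pv, use_pgs):
    """(n, S) prior x own-survival x tests x PGS weights, vectorised."""
    space = hazards.space
    params = hazards.params
    n = len(records)
    W = np.empty((n, space.n_states))
    ages = records["baseline_age"].to_numpy(dtype=int)
    bys = records["birth_year"].to_numpy(dtype=int)
    for by in np.unique(bys):
        sel = bys == by
        H = hazards.cumhaz(by)
        W[sel] = (space.prior[None, :] * np.exp(-H[:, ages[sel]].T))
    if use_pv:
        sens = {"brca2_test": params.sens_brca2, "brca1_test": params.sens_brca1,
                "hoxb13_test": params.sens_hoxb13}
        locus = {"brca2_test": "BRCA2", "brca1_test": "BRCA1", "hoxb13_test": "HOXB13"}
        for col, s in sens.items():
            if col not in records:
                continue
            codes = records[col].map(_TEST_INT).fillna(0).to_numpy(dtype=int)
            if not codes.any() or locus[col] not in space.loci:
                continue
            carrier = space.counts(locus[col]) >= 1
            W[codes == 1] *= np.where(carrier, s, 0.0)[None, :]
            W[codes == 2] *= np.where(carrier, 1.0 - s, 1.0)[None, :]
    if use_pgs and "pgs" in records:
        z = records["pgs"].to_numpy(dtype=float)
        idx = np.where(~np.isnan(z))[0]
        if idx.size:
            s = params.pgs_noise_sd
            W[idx] *= np.exp(-0.5 * ((z[idx][:, None] - space.a_values[None, :]) / s) ** 2)
    return W


def _parse_brother_dx(val):
    if isinstance(val, str) and val.strip():
        return [int(float(x)) for x in val.split(";") if x.strip()]
    return []


def predict_cohort(records: pd.DataFrame, params: ModelParameters, incidence,
                   horizons=(5, 10), information="full",
                   space_options: SpaceOptions | None = None, max_age=90,
                   use_unaffected=True):
    """Predict fixed-horizon risks for cohort records with FH summaries.

    Each record is expanded into a minimal pedigree (father, mother, listed
    affected brothers, consultand).  When ``use_unaffected`` is true and the
    records carry ``father_censor_age`` / ``n_brothers`` columns, relatives
    known to be unaffected contribute their survival as well; otherwise no
    assumptions are made about unlisted or unaffected relatives (the
    validation-cohort convention, where FH questionnaires list affected
    relatives only).  ``information`` controls which baseline data are used:
    'age' (population risk only), 'fh', 'pv', 'pgs' or 'full'.

    Returns a DataFrame with one ``risk_{h}`` column per horizon.
    """
    if information not in INFORMATION_LEVELS:
        raise PredictionError(f"information must be one of {INFORMATION_LEVELS}")
    space = GenotypeSpace(params, space_options or SpaceOptions())
    hazards = constrain(incidence, params, space=space, max_age=max_age)
    S = space.n_states
    n = len(records)
    records = records.reset_index(drop=True)
    use_fh = information in ("fh", "full")
    use_pv = information in ("pv", "full")
    use_pgs = information in ("pgs", "full")

    W = _own_weights(records, hazards, use_pv, use_pgs)
    ages = records["baseline_age"].to_numpy(dtype=int)
    bys = records["birth_year"].to_numpy(dtype=int)

    # family configuration per subject: (father code, affected brother dx
    # tuple, n unaffected brothers, birth year).  Many subjects share a
    # configuration, so the family message is computed once per unique one.
    fam_key = [None] * n
    if use_fh:
        fa = records.get("father_affected", pd.Series(0, index=records.index)) \
            .fillna(0).to_numpy(dtype=int)
        fdx = records.get("father_dx_age", pd.Series(np.nan, index=records.index)) \
            .to_numpy(dtype=float)
        fby = records.get("father_birth_year",
                          pd.Series(bys - 28, index=records.index)).to_numpy(dtype=int)
        fcens = records.get("father_censor_age",
                            pd.Series(np.nan, index=records.index)).to_numpy(dtype=float)
        nbro_tot = records.get("n_brothers",
                               pd.Series(np.nan, index=records.index)).to_numpy(dtype=float)
        bro = [_parse_brother_dx(v) for v in
               records.get("brother_dx_ages", pd.Series("", index=records.index))]
        for i in range(n):
            if fa[i] == 1:
                dxa = int(fdx[i]) if np.isfinite(fdx[i]) else min(ages[i] + 28, 85)
                father = ("A", dxa, int(fby[i]))
            elif use_unaffected and np.isfinite(fcens[i]) and fcens[i] > 0:
                father = ("U", int(fcens[i]), int(fby[i]))
            else:
                father = None
            n_unaff = 0
            if use_unaffected and np.isfinite(nbro_tot[i]):
                n_unaff = max(0, int(nbro_tot[i]) - len(bro[i]))
            if father is None and not bro[i] and n_unaff == 0:
                continue
            fam_key[i] = (father, tuple(sorted(bro[i])), n_unaff,
                          int(bys[i]), int(ages[i]))

    post = np.empty_like(W)
    idx_plain = np.where([k is None for k in fam_key])[0]
    # no informative relatives: random-mating transmission marginalises the
    # parents away, so the posterior is just the survivor-weighted own weight
    if idx_plain.size:
        post[idx_plain] = W[idx_plain] / W[idx_plain].sum(axis=1, keepdims=True)

    keymap = {}
    for i in range(n):
        if fam_key[i] is not None:
            keymap.setdefault(fam_key[i], []).append(i)
    if keymap:
        trans = space.factor_trans
        priors = space.factor_priors
        k_parent = parent_child_kernels(trans, priors)

        def survival_lik(age, by):
            H = hazards.cumhaz(by)
            return np.exp(-H[:, min(int(age), hazards.max_age)])

        def affected_lik(dx_age, by):
            H = hazards.cumhaz(by)
            lam = hazards.hazard_matrix(by)
            a_ = min(int(dx_age), hazards.max_age - 1)
            return np.exp(-H[:, a_]) * (1.0 - np.exp(-lam[:, a_]))

        def father_lik(code):
            if code is None:
                return np.ones(S)
            kind, age, by = code
            return affected_lik(age, by) if kind == "A" else survival_lik(age, by)

        messages = {}
        keys = list(keymap)
        # no-sibling configurations: marginalise the mother per factor
        k0 = [k for k in keys if not k[1] and k[2] == 0]
        if k0:
            w = np.stack([space.prior * father_lik(k[0]) for k in k0])
            V = contract_kernels(w, k_parent)
            messages.update(zip(k0, V))
        # sibling configurations: joint parental states, grouped by the
        # number of sibling vectors, batched
        rest = [k for k in keys if k not in messages]
        by_ns = {}
        for k in rest:
            by_ns.setdefault(len(k[1]) + k[2], []).append(k)
        ones = np.ones(S)
        batch = max(1, int(3e7 / (S * S)))
        for ns, ks in by_ns.items():
            for start in range(0, len(ks), batch):
                chunk = ks[start:start + batch]
                B = len(chunk)
                Lf = np.stack([father_lik(k[0]) for k in chunk])
                sib = np.empty((B, ns, S))
                for b, k in enumerate(chunk):
                    j = 0
                    for dxa in k[1]:
                        sib[b, j] = affected_lik(dxa, k[3])
                        j += 1
                    if k[2] > 0:
                        u = survival_lik(k[4], k[3])
                        for _ in range(k[2]):
                            sib[b, j] = u
                            j += 1
                V = nuclear_message(Lf, np.tile(ones, (B, 1)), sib, trans,
                                    space.prior)
                messages.update(zip(chunk, V))
        for k, rows in keymap.items():
            # own weight already includes the prior; divide it out so the
            # transmission message supplies the consultand's prior
            pv = messages[k][None, :] * (W[rows] / space.prior[None, :])
            post[rows] = pv / pv.sum(axis=1, keepdims=True)

    out = pd.DataFrame(index=records.index)
    for h in horizons:
        risk = np.empty(n)
        for by in np.unique(bys):
            sel = bys == by
            H = hazards.cumhaz(by)
            to = np.clip(ages[sel] + h, None, hazards.max_age)
            delta = H[:, to] - H[:, ages[sel]]
            risk[sel] = np.einsum("ns,sn->n", post[sel], 1.0 - np.exp(-delta))
        out[f"risk_{h}"] = risk
    return out
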