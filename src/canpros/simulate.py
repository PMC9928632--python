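"""Synthetic families, prospective cohorts and incidence fixtures.

Everything is generated under the model's own generative process: founder
genotypes from the population prior, Mendelian/hypergeometric transmission,
event times sampled by inverse transform from the incidence-constrained
genotype-specific annual hazards, ascertainment by rejection (the proband
must be an affected son meeting the arm criteria), and measured data (tests,
PGS) drawn with the configured sensitivities and measurement noise.

Randomness: family ``i`` uses its own stream derived from ``(seed, i)``, so
any subset of families is reproducible independently of ``n``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genetics import GenotypeSpace, SpaceOptions
from .hazards import constrain
from .incidence import IncidenceTable
from .parameters import ModelParameters
from .pedigree import Individual, Pedigree


class SimulationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# incidence fixtures

def make_incidence_fixture(scale=1.0, onset_age=45, midpoint=71.0, steepness=0.14,
                           plateau=0.0085, max_age=90, sex="M", site="prostate"):
    """Smooth increasing-then-plateauing annual male rates (logistic in age).

    The default integrates to a realistic lifetime risk; ``scale=0`` gives an
    all-zero table.  Deterministic.
    """
    ages = np.arange(max_age)
    rates = scale * plateau / (1.0 + np.exp(-steepness * (ages - midpoint)))
    rates[ages < onset_age] = 0.0
    bands = [(int(a), int(a) + 1, float(r)) for a, r in zip(ages, rates)]
    return IncidenceTable.from_bands(bands, sex=sex, site=site)


# approximate England & Wales male prostate cancer rates (per 100,000
# person-years, five-year bands, pre-PSA-expansion era); the implied
# cumulative risk to age 85 is about 16%, consistent with UK population
# estimates for the modelled birth cohorts.
_UK_PROSTATE = [(0, 40, 0.0), (40, 45, 8.0), (45, 50, 25.0), (50, 55, 85.0),
                (55, 60, 220.0), (60, 65, 420.0), (65, 70, 640.0),
                (70, 75, 760.0), (75, 80, 790.0), (80, 90, 735.0)]
# crude female breast / ovarian rates (information channel for BRCA carriers
# among female relatives; not a calibrated female model)
_UK_BREAST = [(0, 30, 10.0), (30, 40, 45.0), (40, 50, 150.0), (50, 60, 225.0),
              (60, 70, 265.0), (70, 90, 300.0)]
_UK_OVARY = [(0, 40, 5.0), (40, 50, 15.0), (50, 60, 30.0), (60, 70, 45.0),
             (70, 90, 52.0)]

_TARGET_RISK_85 = 0.16


def uk_incidence(include_female=True, max_age=90):
    """Approximate UK incidence table (prostate; optionally breast/ovarian).

    Rates are scaled so the male prostate cumulative risk to age 85 equals
    the UK population figure of 16% exactly on the annual grid.
    """
    raw = np.zeros(max_age)
    for a, b, r in _UK_PROSTATE:
        raw[a:min(b, max_age)] = r / 1e5
    target_h = -np.log(1.0 - _TARGET_RISK_85)
    scale = target_h / raw[:85].sum()
    bands = [(a, min(b, max_age), r / 1e5 * scale) for a, b, r in _UK_PROSTATE]
    tab = IncidenceTable.from_bands(bands, sex="M", site="prostate")
    if include_female:
        tab = tab.combined(IncidenceTable.from_bands(
            [(a, min(b, max_age), r / 1e5) for a, b, r in _UK_BREAST],
            sex="F", site="breast"))
        tab = tab.combined(IncidenceTable.from_bands(
            [(a, min(b, max_age), r / 1e5) for a, b, r in _UK_OVARY],
            sex="F", site="ovarian"))
    return tab


# ---------------------------------------------------------------------------
# configuration

@dataclass(frozen=True)
class SimulationConfig:
    """Study-design knobs for the family and cohort generators."""

    params: ModelParameters = field(default_factory=ModelParameters)
    space_options: SpaceOptions = field(default_factory=SpaceOptions)
    incidence: IncidenceTable | None = None
    max_age: int = 90

    # family structure
    n_brothers_mean: float = 1.5
    n_sisters_mean: float = 0.0
    father_birth_range: tuple = (1905, 1926)   # uniform integer [lo, hi)
    son_birth_offset: tuple = (25, 34)
    study_year: int = 2005

    # ascertainment
    arm: str = "population"                    # population|young_onset|fh_enriched
    young_onset_cut: int = 60
    detection_probs: tuple = (0.50, 0.24, 0.26)  # symptomatic, screen, unknown
    max_rejections: int = 5000

    # measured data on probands (families) / participants (cohort)
    test_genes: tuple = ("BRCA2", "BRCA1", "HOXB13")
    pgs_measured: bool = True

    # cohort design
    baseline_year: int = 2008
    baseline_age_range: tuple = (40, 70)       # [lo, hi)
    admin_censor: float = 13.0
    brca_availability: float = 1.0             # fraction with BRCA1/2 data
    include_truth: bool = False

    def with_incidence(self):
        if self.incidence is not None:
            return self
        return replace(self, incidence=uk_incidence())


def _event_ages(space, hazards, states_flat, birth_years, rng):
    """Event age per individual by inverse transform (max_age => never)."""
    n = len(states_flat)
    out = np.empty(n, dtype=int)
    u = rng.random(n)
    birth_years = np.asarray(birth_years)
    for by in np.unique(birth_years):
        sel = np.where(birth_years == by)[0]
        H = hazards.cumhaz(by)
        F = 1.0 - np.exp(-H[states_flat[sel]])      # (m, T+1), F[:,0]=0
        k = (F <= u[sel][:, None]).sum(axis=1) - 1  # event in year k
        out[sel] = np.minimum(k, hazards.max_age)
    return out


# ---------------------------------------------------------------------------
# family simulation

def _simulate_one_family(cfg, space, hazards, rng, fam_id, chunk=16):
    p = cfg.params
    attempts = 0
    while attempts < cfg.max_rejections:
        attempts += chunk
        # single ascertainment: the candidate proband slot is fixed before
        # phenotypes are seen, so the selection event is exactly "this son is
        # affected (and meets the arm criteria)" -- the event the likelihood
        # conditions on.  Candidate probands are screened in vectorised
        # chunks; the rest of the accepted family is sampled afterwards.
        cf_by = rng.integers(*cfg.father_birth_range, size=chunk)
        cn_sons = 1 + rng.poisson(cfg.n_brothers_mean, size=chunk)
        cpi = rng.integers(0, cn_sons)
        cfather = space.sample_founders(chunk, rng)
        cmother = space.sample_founders(chunk, rng)
        cprob = space.sample_children(cfather, cmother, rng)
        cson_by = cf_by + rng.integers(*cfg.son_birth_offset, size=chunk)
        ccensor = np.clip(cfg.study_year - cson_by, 0, cfg.max_age)
        cev = _event_ages(space, hazards, space.flatten_states(cprob), cson_by, rng)
        ok = cev < ccensor
        if cfg.arm == "young_onset":
            ok &= cev < cfg.young_onset_cut
        hit = np.flatnonzero(ok)
        if hit.size == 0:
            continue
        j = int(hit[0])
        f_by = int(cf_by[j])
        m_by = f_by + int(rng.integers(-3, 4))
        n_sons = int(cn_sons[j])
        pi = int(cpi[j])
        n_daughters = rng.poisson(cfg.n_sisters_mean)
        father, mother = cfather[j:j + 1], cmother[j:j + 1]
        # remaining children (brothers of the proband + daughters)
        n_rest = n_sons - 1 + n_daughters
        rest = space.sample_children(np.repeat(father, n_rest, axis=0),
                                     np.repeat(mother, n_rest, axis=0), rng) \
            if n_rest else np.empty((0, len(space.dims)), dtype=int)
        kids = np.concatenate([rest[:pi], cprob[j:j + 1], rest[pi:]], axis=0) \
            if n_rest else cprob[j:j + 1]
        son_by = f_by + rng.integers(*cfg.son_birth_offset, size=n_sons)
        son_by[pi] = cson_by[j]
        son_states = space.flatten_states(kids[:n_sons])
        censor = np.clip(cfg.study_year - son_by, 0, cfg.max_age)
        ev = _event_ages(space, hazards, son_states, son_by, rng)
        ev[pi] = cev[j]
        affected = ev < censor
        dx = np.where(affected, ev, 0)
        f_state = space.flatten_states(father)
        f_censor = min(max(cfg.study_year - f_by, 0), cfg.max_age)
        f_ev = int(_event_ages(space, hazards, f_state, np.array([f_by]), rng)[0])
        f_affected = f_ev < f_censor
        if cfg.arm == "fh_enriched":
            n_affected_fdr = int(affected.sum()) - 1 + int(f_affected)
            if n_affected_fdr < 1:
                continue
        det = ["symptomatic", "screen", "unknown"][
            int(rng.choice(3, p=np.asarray(cfg.detection_probs)))]
        members = [
            Individual(id="F", sex="M", birth_year=f_by, censor_age=f_censor),
            # female cancers are not simulated: censor 0 marks their
            # phenotype as unobserved rather than "unaffected"
            Individual(id="M", sex="F", birth_year=m_by, censor_age=0),
        ]
        if f_affected:
            members[0].prostate_dx_age = f_ev
            members[0].detection_mode = "unknown"
        for i in range(n_sons):
            ind = Individual(id=f"S{i+1}", sex="M", father_id="F", mother_id="M",
                             birth_year=int(son_by[i]), censor_age=int(censor[i]))
            if affected[i]:
                ind.prostate_dx_age = int(dx[i])
                ind.detection_mode = "unknown"
            members.append(ind)
        for j in range(n_daughters):
            members.append(Individual(
                id=f"D{j+1}", sex="F", father_id="F", mother_id="M",
                birth_year=int(f_by + 28 + j), censor_age=0))
        # proband: measured data
        prob = members[2 + pi]
        prob.is_proband = True
        prob.detection_mode = det
        st = kids[pi]
        for g in cfg.test_genes:
            if g not in space.loci:
                continue
            li = space.factor_names.index(g)
            carrier = st[li] >= 1
            sens = {"BRCA2": p.sens_brca2, "BRCA1": p.sens_brca1,
                    "HOXB13": p.sens_hoxb13}[g]
            positive = carrier and (rng.random() < sens)
            prob.test_results[g] = "carrier" if positive else "noncarrier"
        if cfg.pgs_measured:
            a_val = space.grid_a.values[st[space.factor_names.index("A")]]
            prob.pgs_z = float(a_val + rng.normal(0, p.pgs_noise_sd))
        return Pedigree(str(fam_id), members, proband_id=prob.id,
                        ascertainment_arm=cfg.arm)
    raise SimulationError(
        f"family {fam_id}: no acceptable family after {cfg.max_rejections} "
        f"rejections (acceptance probability ~ 0 under arm {cfg.arm!r})")


def simulate_families(config: SimulationConfig, n, seed=0):
    """Simulate ``n`` ascertained pedigrees; bit-reproducible given seed."""
    cfg = config.with_incidence()
    space = GenotypeSpace(cfg.params, cfg.space_options)
    hazards = constrain(cfg.incidence, cfg.params, space=space, max_age=cfg.max_age)
    out = []
    for i in range(n):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(i,)))
        out.append(_simulate_one_family(cfg, space, hazards, rng, f"fam{i}"))
    return out


# ---------------------------------------------------------------------------
# prospective cohort simulation (vectorised)

def simulate_cohort(config: SimulationConfig, n, seed=0) -> pd.DataFrame:
    """Simulate a prospective cohort of unaffected men with FH summaries.

    Baseline ages follow a UK-Biobank-like distribution (40-69, weighted
    toward the early sixties).  FH summaries are derived from each
    participant's hidden simulated family (father + brothers); unaffected
    relatives are not reported, matching the minimal-pedigree prediction
    convention.  PV results are drawn with the configured sensitivities and
    masked for a ``1 - brca_availability`` fraction; the PGS is the
    observed-part polygene level plus Gaussian measurement noise.
    """
    cfg = config.with_incidence()
    p = cfg.params
    space = GenotypeSpace(cfg.params, cfg.space_options)
    hazards = constrain(cfg.incidence, cfg.params, space=space, max_age=cfg.max_age)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(1000001,)))

    lo, hi = cfg.baseline_age_range
    ages_grid = np.arange(lo, hi)
    w = 1.0 + 2.0 * np.clip((ages_grid - lo) / max(1, 62 - lo), 0, 1)
    w /= w.sum()

    m = int(n * 1.2) + 200
    age0 = rng.choice(ages_grid, size=m, p=w)
    cby = cfg.baseline_year - age0
    fby = cby - 28          # fixed generational gap (shared by prediction)
    n_bro = rng.poisson(cfg.n_brothers_mean, size=m)
    max_b = int(n_bro.max()) if m else 0

    father = space.sample_founders(m, rng)
    mother = space.sample_founders(m, rng)
    cons = space.sample_children(father, mother, rng)
    bro_states = [space.sample_children(father, mother, rng) for _ in range(max_b)]

    cons_flat = space.flatten_states(cons)
    ev_c = _event_ages(space, hazards, cons_flat, cby, rng)
    keep = ev_c >= age0           # unaffected at baseline
    idx = np.where(keep)[0][:n]
    if len(idx) < n:
        raise SimulationError("oversampling factor too small for requested n")

    ev_f = _event_ages(space, hazards, space.flatten_states(father[idx]), fby[idx], rng)
    f_age0 = cfg.baseline_year - fby[idx]
    f_aff = ev_f < np.minimum(f_age0, cfg.max_age)

    bro_lists = [[] for _ in range(len(idx))]
    for b in range(max_b):
        mask = n_bro[idx] > b
        if not mask.any():
            continue
        rows = np.where(mask)[0]
        st = space.flatten_states(bro_states[b][idx[rows]])
        ev = _event_ages(space, hazards, st, cby[idx[rows]], rng)
        aff = ev < age0[idx[rows]]
        for j, r in enumerate(rows):
            if aff[j]:
                bro_lists[r].append(int(ev[j]))
    bro_dx = [";".join(str(x) for x in lst) for lst in bro_lists]

    # measured data
    def test_col(locus, sens):
        li = space.factor_names.index(locus) if locus in space.factor_names else None
        out = np.full(len(idx), "0", dtype=object)
        if li is None:
            return out
        carrier = cons[idx, li] >= 1
        pos = carrier & (rng.random(len(idx)) < sens)
        out[:] = np.where(pos, "P", "N")
        return out

    t2 = test_col("BRCA2", p.sens_brca2)
    t1 = test_col("BRCA1", p.sens_brca1)
    th = test_col("HOXB13", p.sens_hoxb13)
    avail = rng.random(len(idx)) < cfg.brca_availability
    t2 = np.where(avail, t2, "0")
    t1 = np.where(avail, t1, "0")

    a_idx = space.factor_names.index("A")
    pgs = space.grid_a.values[cons[idx, a_idx]] + rng.normal(0, p.pgs_noise_sd, len(idx))

    time_to_event = ev_c[idx] - age0[idx] + 1.0
    event = (time_to_event <= cfg.admin_censor).astype(int)
    time = np.where(event == 1, time_to_event, cfg.admin_censor)

    df = pd.DataFrame({
        "id": [f"p{j}" for j in range(len(idx))],
        "baseline_age": age0[idx],
        "birth_year": cby[idx],
        "father_affected": f_aff.astype(int),
        "father_dx_age": np.where(f_aff, ev_f, np.nan),
        "father_birth_year": fby[idx],
        "father_censor_age": np.minimum(f_age0, cfg.max_age),
        "n_brothers": n_bro[idx],
        "brother_dx_ages": bro_dx,
        "brca2_test": t2,
        "brca1_test": t1,
        "hoxb13_test": th,
        "pgs": pgs,
        "event": event,
        "time": time,
    })
    if cfg.include_truth:
        df["true_state"] = cons_flat[idx]
        df["true_event_age"] = ev_c[idx]
    return df
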