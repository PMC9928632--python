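import numpy as np
import pandas as pd
import pytest

import canpros as cp
from canpros.genetics import GenotypeSpace, SpaceOptions
from canpros.hazards import constrain
from canpros.incidence import IncidenceTable
from canpros.likelihood import member_likelihoods
from canpros.pedigree import Pedigree
from canpros.predict import (
    PredictionError,
    familial_relative_risk,
    posterior_states,
    predict_cohort,
    predict_risk,
)
from conftest import person
from _oracles import enumerate_posterior


def test_no_information_posterior_is_survivor_prior(toy_space, toy_hazards):
    ped = Pedigree("p", [person("c", censor=50)])
    post = posterior_states(ped, "c", toy_hazards)
    w = toy_space.prior * np.exp(-toy_hazards.cumhaz(1960)[:, 50])
    np.testing.assert_allclose(post, w / w.sum(), rtol=1e-12)


def test_positive_test_forces_carrier(uk_inc):
    p = cp.ModelParameters(f_brca2=0.01, f_brca1=0, f_hoxb13=0, f_rec=0)
    space = GenotypeSpace(p, SpaceOptions(3, 3))
    hz = constrain(uk_inc, p, space=space)
    ped = Pedigree("p", [person("c", censor=45, tests={"BRCA2": "carrier"})])
    post = posterior_states(ped, "c", hz)
    carrier = space.counts("BRCA2") >= 1
    assert post[carrier].sum() == pytest.approx(1.0, abs=1e-12)


def test_affected_consultand_rejected(toy_hazards):
    ped = Pedigree("p", [person("c", censor=60, dx=55)])
    with pytest.raises(PredictionError, match="affected"):
        posterior_states(ped, "c", toy_hazards)


def test_posterior_matches_enumeration_with_affected_brother(toy_space,
                                                             toy_hazards):
    ped = Pedigree("p", [
        person("f"), person("m", sex="F"),
        person("b", censor=51, dx=50, father="f", mother="m"),
        person("c", censor=45, father="f", mother="m"),
    ])
    post = posterior_states(ped, "c", toy_hazards)
    liks = member_likelihoods(ped, toy_hazards)
    want = enumerate_posterior(ped, toy_space, liks, "c")
    np.testing.assert_allclose(post, want, rtol=1e-10)


def test_risk_curve_invariants(toy_hazards):
    ped = Pedigree("p", [person("c", censor=45)])
    curve = predict_risk(ped, "c", toy_hazards, [45, 55, 65, 75, 85])
    assert curve.risks[0] == 0.0  # risk at the current age
    assert ((curve.risks >= 0) & (curve.risks <= 1)).all()
    assert (np.diff(curve.risks) >= 0).all()
    with pytest.raises(PredictionError):
        predict_risk(ped, "c", toy_hazards, [40])


def test_no_variation_means_identical_curves(uk_inc):
    """sigma ~ 0 and no major genes: family history cannot matter."""
    p = cp.ModelParameters(f_brca2=0, f_brca1=0, f_hoxb13=0, f_rec=0,
                           sigma70=1e-9)
    hz = constrain(uk_inc, p, space=GenotypeSpace(p, SpaceOptions(1, 1)))
    lone = Pedigree("a", [person("c", censor=45)])
    fam = Pedigree("b", [person("f", censor=75, dx=55), person("m", sex="F"),
                         person("c", censor=45, father="f", mother="m")])
    r1 = predict_risk(lone, "c", hz, [85]).risks[0]
    r2 = predict_risk(fam, "c", hz, [85]).risks[0]
    assert r1 == pytest.approx(r2, rel=1e-9)


def test_risk_monotone_in_pgs_and_fh(toy_hazards):
    risks = []
    for z in (-1.5, 0.0, 1.5):
        ped = Pedigree("p", [person("c", censor=45, pgs=z)])
        risks.append(predict_risk(ped, "c", toy_hazards, [80]).risks[0])
    assert risks[0] < risks[1] < risks[2]
    # more affected first-degree relatives, higher risk
    def with_brothers(k):
        mem = [person("f"), person("m", sex="F"),
               person("c", censor=45, father="f", mother="m")]
        mem += [person(f"b{i}", censor=56, dx=55, father="f", mother="m")
                for i in range(k)]
        return predict_risk(Pedigree("p", mem), "c", toy_hazards, [80]).risks[0]
    assert with_brothers(0) < with_brothers(1) < with_brothers(2)


def test_risk_decreasing_in_relatives_dx_age(toy_hazards):
    def father_dx(a):
        ped = Pedigree("p", [person("f", censor=a, dx=a),
                             person("m", sex="F"),
                             person("c", censor=45, father="f", mother="m")])
        return predict_risk(ped, "c", toy_hazards, [85]).risks[0]
    assert father_dx(50) > father_dx(65) > father_dx(80)


def test_negative_test_between_untested_and_noncarrier(uk_inc):
    p = cp.ModelParameters(f_brca2=0.05, f_brca1=0, f_hoxb13=0, f_rec=0,
                           sens_brca2=0.83)
    hz = constrain(uk_inc, p, space=GenotypeSpace(p, SpaceOptions(3, 3)))

    def risk(tests):
        ped = Pedigree("p", [person("f", censor=60, dx=55), person("m", sex="F"),
                             person("c", censor=45, father="f", mother="m",
                                    tests=tests)])
        return predict_risk(ped, "c", hz, [85]).risks[0]

    untested = risk({})
    negative = risk({"BRCA2": "noncarrier"})
    # true noncarrier: force with a perfectly sensitive test
    p2 = p.replace(sens_brca2=1 - 1e-12)
    hz2 = constrain(uk_inc, p2, space=GenotypeSpace(p2, SpaceOptions(3, 3)))
    ped = Pedigree("p", [person("f", censor=60, dx=55), person("m", sex="F"),
                         person("c", censor=45, father="f", mother="m",
                                tests={"BRCA2": "noncarrier"})])
    true_non = predict_risk(ped, "c", hz2, [85]).risks[0]
    assert true_non < negative < untested


def test_frr_unity_without_familial_variation(uk_inc):
    p = cp.ModelParameters(f_brca2=0, f_brca1=0, f_hoxb13=0, f_rec=0,
                           sigma70=1e-9)
    frr = familial_relative_risk(p, uk_inc, "brother", 55, [50, 60, 70],
                                 space_options=SpaceOptions(1, 1))
    np.testing.assert_allclose(frr.values, 1.0, rtol=1e-6)


def test_frr_matches_enumeration_toy_dominant(uk_inc):
    """Single dominant locus: FRR from the two-person state space equals the
    brute-force kin ratio."""
    p = cp.ModelParameters(f_brca2=0, f_brca1=0, f_hoxb13=0, f_rec=0.05,
                           rr_rec_hom=4.0, rec_mode="dominant", sigma70=1e-9)
    opts = SpaceOptions(1, 1)
    space = GenotypeSpace(p, opts)
    hz = constrain(uk_inc, p, space=space)
    a, t = 55, 65
    frr = familial_relative_risk(p, uk_inc, "father", a, [t],
                                 space_options=opts).iloc[0]
    # oracle: P(son hazard at t | father affected in [a,a+1), son unaffected to t)
    H = hz.cumhaz(1960)
    lam = hz.hazard_matrix(1960)
    Hf = hz.cumhaz(1935)
    lamf = hz.hazard_matrix(1935)
    num = den = 0.0
    from _oracles import joint_transmission
    for sf in range(space.n_states):
        for sm in range(space.n_states):
            w = space.prior[sf] * space.prior[sm]
            lf = np.exp(-Hf[sf, a]) * (1 - np.exp(-lamf[sf, a]))
            tr = joint_transmission(space, sf, sm)
            for sc in range(space.n_states):
                wc = w * lf * tr[sc] * np.exp(-H[sc, t])
                num += wc * lam[sc, t]
                den += wc
    assert frr == pytest.approx(num / den / hz.population_rates(1960)[t],
                                rel=1e-9)


def test_brother_frr_exceeds_father_frr_with_recessive(uk_inc):
    p = cp.ModelParameters(f_brca2=0, f_brca1=0, f_hoxb13=0, f_rec=0.15,
                           rr_rec_hom=8.0, sigma70=1e-9)
    opts = SpaceOptions(1, 1)
    fb = familial_relative_risk(p, uk_inc, "brother", 60, [55, 65], space_options=opts)
    ff = familial_relative_risk(p, uk_inc, "father", 60, [55, 65], space_options=opts)
    assert (fb.values > ff.values).all()


# ---------------------------------------------------------------------------
# batched cohort prediction

@pytest.fixture(scope="module")
def small_cohort():
    p = cp.ModelParameters()
    opts = SpaceOptions(3, 3)
    cfg = cp.SimulationConfig(params=p, space_options=opts)
    rec = cp.simulate_cohort(cfg, 800, seed=9)
    return p, opts, rec


def test_cohort_predictions_match_generic_peeler(small_cohort, uk_inc):
    p, opts, rec = small_cohort
    pred = predict_cohort(rec, p, uk_inc, information="full", space_options=opts)
    space = GenotypeSpace(p, opts)
    hz = constrain(uk_inc, p, space=space)
    code = {"P": "carrier", "N": "noncarrier", "0": "untested"}
    sub = rec[(rec.father_affected == 1) | (rec.brother_dx_ages != "")].head(8)
    for i, r in sub.iterrows():
        mem = [person("F", by=int(r.father_birth_year),
                      censor=int(r.father_dx_age) if r.father_affected
                      else int(r.father_censor_age),
                      dx=int(r.father_dx_age) if r.father_affected else None),
               person("M", sex="F", by=int(r.father_birth_year) + 2)]
        listed = [int(float(x)) for x in str(r.brother_dx_ages).split(";") if x]
        for j, b in enumerate(listed):
            mem.append(person(f"B{j}", by=int(r.birth_year), censor=b, dx=b,
                              father="F", mother="M"))
        for j in range(int(r.n_brothers) - len(listed)):
            mem.append(person(f"U{j}", by=int(r.birth_year),
                              censor=int(r.baseline_age), father="F", mother="M"))
        mem.append(person("C", by=int(r.birth_year), censor=int(r.baseline_age),
                          father="F", mother="M",
                          tests={g: code[r[c]] for g, c in
                                 [("BRCA2", "brca2_test"), ("BRCA1", "brca1_test"),
                                  ("HOXB13", "hoxb13_test")]},
                          pgs=float(r.pgs)))
        ped = Pedigree("x", mem)
        post = posterior_states(ped, "C", hz)
        H = hz.cumhaz(int(r.birth_year))
        a = int(r.baseline_age)
        want = post @ (1 - np.exp(-(H[:, min(a + 10, 90)] - H[:, a])))
        assert pred.loc[i, "risk_10"] == pytest.approx(want, rel=1e-9)


def test_information_levels_nested_discrimination(small_cohort, uk_inc):
    p, opts, rec = small_cohort
    full = predict_cohort(rec, p, uk_inc, information="full", space_options=opts)
    age = predict_cohort(rec, p, uk_inc, information="age", space_options=opts)
    # age-only risks are constant within a baseline age
    g = pd.DataFrame({"a": rec.baseline_age, "r": age.risk_10}).groupby("a")["r"].nunique()
    assert (g == 1).all()
    # full-information risks vary within age
    assert full.risk_10.nunique() > age.risk_10.nunique()


def test_risk_conservation_over_population(small_cohort, uk_inc):
    """Averaging predicted risks over model-simulated consultands agrees
    with the mean simulated outcome probability (Monte-Carlo)."""
    p, opts, rec = small_cohort
    full = predict_cohort(rec, p, uk_inc, information="full", space_options=opts)
    events = ((rec.event == 1) & (rec.time <= 10)).mean()
    pred = full.risk_10.mean()
    se = np.sqrt(events * (1 - events) / len(rec))
    assert abs(pred - events) < 4 * se
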