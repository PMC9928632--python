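import itertools

import numpy as np
import pytest

import canpros as cp
from canpros.genetics import GenotypeSpace, SpaceOptions
from canpros.hazards import constrain
from canpros.incidence import IncidenceTable
from canpros.likelihood import (
    LikelihoodError,
    condition,
    individual_likelihood,
    member_likelihoods,
    peel,
)
from canpros.pedigree import Pedigree
from conftest import person
from _oracles import enumerate_loglik


def _structures():
    """Pedigree shapes of <= 5 members used for oracle equivalence."""
    return {
        "singleton": [person("a", censor=70)],
        "couple_child": [person("f", censor=75, dx=60), person("m", sex="F"),
                         person("c", censor=50, father="f", mother="m")],
        "three_sons": [person("f", censor=80), person("m", sex="F"),
                       person("s1", censor=60, dx=55, father="f", mother="m"),
                       person("s2", censor=58, father="f", mother="m"),
                       person("s3", censor=52, dx=50, father="f", mother="m")],
        "three_generations": [person("gf", censor=85, dx=70),
                              person("gm", sex="F"),
                              person("f", censor=62, father="gf", mother="gm"),
                              person("m", sex="F"),
                              person("c", censor=41, dx=40, father="f", mother="m")],
        "half_sibs": [person("f", censor=78, dx=66), person("m1", sex="F"),
                      person("m2", sex="F"),
                      person("c1", censor=55, father="f", mother="m1"),
                      person("c2", censor=50, dx=48, father="f", mother="m2")],
    }


@pytest.mark.parametrize("name", list(_structures()))
def test_peel_equals_enumeration(name, toy_space, toy_hazards):
    ped = Pedigree(name, _structures()[name])
    liks = member_likelihoods(ped, toy_hazards)
    got = peel(ped, toy_hazards)
    want = enumerate_loglik(ped, toy_space, liks)
    assert got == pytest.approx(want, rel=1e-10)


def test_singleton_definition(toy_space, toy_hazards):
    ped = Pedigree("s", [person("a", censor=70)])
    liks = member_likelihoods(ped, toy_hazards)
    assert peel(ped, toy_hazards) == pytest.approx(
        np.log(toy_space.prior @ liks["a"]), rel=1e-12)


def test_member_order_permutation_invariance(toy_hazards):
    base = _structures()["three_generations"]
    lls = []
    for order in ([0, 1, 2, 3, 4], [4, 3, 2, 1, 0], [2, 0, 4, 1, 3]):
        ped = Pedigree("perm", [base[i] for i in order])
        lls.append(peel(ped, toy_hazards))
    assert lls[0] == pytest.approx(lls[1], rel=1e-12)
    assert lls[0] == pytest.approx(lls[2], rel=1e-12)


def test_total_probability_over_phenotype_space(toy_hazards):
    """Summing the family likelihood over every phenotype configuration
    (each member: event in year t < a, or unaffected at a) equals 1."""
    a = {"f": 48, "m": 0, "c": 47}
    total = 0.0
    for f_ev in list(range(40, a["f"])) + [None]:
        for c_ev in list(range(40, a["c"])) + [None]:
            ped = Pedigree("tp", [
                person("f", censor=a["f"] if f_ev is None else f_ev, dx=f_ev),
                person("m", sex="F"),
                person("c", censor=a["c"] if c_ev is None else c_ev, dx=c_ev,
                       father="f", mother="m"),
            ])
            total += np.exp(peel(ped, toy_hazards))
    assert total == pytest.approx(1.0, abs=1e-10)


def test_survival_closed_form():
    p = cp.ModelParameters(f_brca2=0, f_brca1=0, f_hoxb13=0, f_rec=0,
                           sigma70=1e-9)
    tab = IncidenceTable.from_bands([(0, 90, 0.003)])
    hz = constrain(tab, p, space=GenotypeSpace(p, SpaceOptions(1, 1)))
    ind = person("a", censor=40)
    L = individual_likelihood(ind, hz)
    assert L[0] == pytest.approx(np.exp(-0.003 * 40), rel=1e-9)
    aff = person("b", censor=50, dx=50)
    L = individual_likelihood(aff, hz)
    assert L[0] == pytest.approx(np.exp(-0.003 * 50) * (1 - np.exp(-0.003)),
                                 rel=1e-9)


def test_affected_year_factor_matches_integration_oracle():
    """The annual event factor S(a)(1-exp(-lam_a)) equals the integral of
    the event density over [a, a+1) under the piecewise-constant hazard."""
    lam = 0.004
    p = cp.ModelParameters(f_brca2=0, f_brca1=0, f_hoxb13=0, f_rec=0,
                           sigma70=1e-9)
    tab = IncidenceTable.from_bands([(0, 90, lam)])
    hz = constrain(tab, p, space=GenotypeSpace(p, SpaceOptions(1, 1)))
    a = 63
    L = individual_likelihood(person("x", censor=a, dx=a), hz)[0]
    # numerical integration of lam * exp(-lam * t) over the year
    ts = np.linspace(a, a + 1, 20001)
    dens = lam * np.exp(-lam * ts)
    oracle = np.trapezoid(dens, ts)
    assert L == pytest.approx(oracle, rel=1e-7)


def test_genetic_test_factors():
    p = cp.ModelParameters(f_brca2=0.01, f_brca1=0, f_hoxb13=0, f_rec=0)
    space = GenotypeSpace(p, SpaceOptions(1, 1))
    hz = constrain(cp.uk_incidence(), p, space=space)
    # negative test on a true carrier: factor 1 - sensitivity = 0.17
    ind = person("x", tests={"BRCA2": "noncarrier"})
    L = individual_likelihood(ind, hz)
    carrier = space.counts("BRCA2") >= 1
    np.testing.assert_allclose(L[carrier], 1 - 0.83)
    np.testing.assert_allclose(L[~carrier], 1.0)
    # positive test: perfect specificity excludes noncarriers
    ind = person("y", tests={"BRCA2": "carrier"})
    L = individual_likelihood(ind, hz)
    np.testing.assert_allclose(L[carrier], 0.83)
    np.testing.assert_allclose(L[~carrier], 0.0)


def test_conditioning_trivials(nuclear_ped, toy_hazards):
    full = peel(nuclear_ped, toy_hazards)
    # scheme none reproduces the unadjusted peel
    assert condition(nuclear_ped, toy_hazards, "none") == pytest.approx(full)
    # conditioning set == full data (no tests/PGS present, all phenotypes)
    adj = condition(nuclear_ped, toy_hazards, "family_phenotypes")
    assert adj == pytest.approx(0.0, abs=1e-10)


def test_conditioning_matches_enumeration(toy_space, toy_hazards):
    ped = Pedigree("c", [
        person("f", censor=75), person("m", sex="F"),
        person("p", censor=60, dx=55, father="f", mother="m", proband=True,
               pgs=0.8),
    ])
    adj = condition(ped, toy_hazards, "proband_phenotype")
    liks = member_likelihoods(ped, toy_hazards)
    full = enumerate_loglik(ped, toy_space, liks)
    liks_cond = member_likelihoods(ped, toy_hazards, include_tests=False,
                                   include_pgs=False, phenotype_ids={"p"})
    cond = enumerate_loglik(ped, toy_space, liks_cond)
    assert adj == pytest.approx(full - cond, rel=1e-10)


def test_impossible_conditioning_raises(toy_hazards):
    ped = Pedigree("x", [person("p", censor=30, dx=20, proband=True)])
    with pytest.raises(LikelihoodError):
        condition(ped, toy_hazards, "proband_phenotype")


def test_auto_scheme_resolution(toy_hazards):
    sym = Pedigree("a", [person("p", censor=70, dx=60, proband=True)])
    sym.proband.detection_mode = "symptomatic"
    scr = Pedigree("b", [person("p", censor=70, dx=60, proband=True)])
    scr.proband.detection_mode = "screen"
    from canpros.likelihood import resolve_scheme
    assert resolve_scheme(sym, "auto") == "proband_phenotype"
    assert resolve_scheme(scr, "auto") == "family_phenotypes"


def test_affected_brother_raises_carrier_posterior(toy_params, toy_hazards):
    """Monotonicity: an affected brother increases the consultand's
    posterior probability of carrying the recessive risk genotype."""
    from canpros.predict import posterior_states
    base = [person("f"), person("m", sex="F"),
            person("c", censor=45, father="f", mother="m")]
    with_bro = base + [person("b", censor=58, dx=55, father="f", mother="m")]
    hz = toy_hazards
    post0 = posterior_states(Pedigree("p0", base), "c", hz)
    post1 = posterior_states(Pedigree("p1", with_bro), "c", hz)
    hom = hz.space.counts("REC") == 2
    assert post1[hom].sum() > post0[hom].sum()


def test_factored_kernels_match_dense_sums(toy_space):
    """parent-child and sibling kernels equal the brute-force joint sums."""
    from canpros._peelcore import (contract_kernels, parent_child_kernels,
                                   sibling_kernels)
    from _oracles import joint_transmission
    rng = np.random.default_rng(3)
    S = toy_space.n_states
    w = rng.random(S)
    # child distribution given a known father, mother marginalised
    kp = parent_child_kernels(toy_space.factor_trans, toy_space.factor_priors)
    got = contract_kernels(w[None, :], kp)[0]
    want = np.zeros(S)
    for sf in range(S):
        for sm in range(S):
            want += w[sf] * toy_space.prior[sm] * joint_transmission(
                toy_space, sf, sm)
    np.testing.assert_allclose(got, want, rtol=1e-10)
    # sibling-pair joint with both parents integrated out
    ks = sibling_kernels(toy_space.factor_trans, toy_space.factor_priors)
    got = contract_kernels(w[None, :], ks)[0]
    want = np.zeros(S)
    for sf in range(S):
        for sm in range(S):
            tr = joint_transmission(toy_space, sf, sm)
            want += toy_space.prior[sf] * toy_space.prior[sm] * (w @ tr) * tr
    np.testing.assert_allclose(got, want, rtol=1e-10)
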