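import numpy as np
import pytest

import canpros as cp
from canpros.genetics import GenotypeSpace, SpaceOptions
from canpros.hazards import constrain
from canpros.pedigree import Individual, Pedigree


@pytest.fixture(scope="session")
def uk_inc():
    return cp.uk_incidence()


@pytest.fixture(scope="session")
def toy_params():
    """One recessive locus + small polygene grids: 27-state toy model."""
    return cp.ModelParameters(f_brca2=0.0, f_brca1=0.0, f_hoxb13=0.0,
                              f_rec=0.2, rr_rec_hom=5.0)


@pytest.fixture(scope="session")
def toy_space(toy_params):
    return GenotypeSpace(toy_params, SpaceOptions(3, 3))


@pytest.fixture(scope="session")
def toy_hazards(toy_params, toy_space, uk_inc):
    return constrain(uk_inc, toy_params, space=toy_space)


def person(id, sex="M", by=1960, censor=0, dx=None, father=None, mother=None,
           tests=None, pgs=None, proband=False):
    tr = {"BRCA2": "untested", "BRCA1": "untested", "HOXB13": "untested"}
    tr.update(tests or {})
    return Individual(
        id=id, sex=sex, birth_year=by, censor_age=censor, prostate_dx_age=dx,
        father_id=father, mother_id=mother, test_results=tr, pgs_z=pgs,
        is_proband=proband,
        detection_mode="unknown" if dx is not None else "not_applicable")


@pytest.fixture
def nuclear_ped():
    """Father affected at 62, unaffected mother-in-name-only, two sons."""
    return Pedigree("nuc", [
        person("f", by=1935, censor=70, dx=62),
        person("m", sex="F", by=1936),
        person("s1", by=1962, censor=45, father="f", mother="m"),
        person("s2", by=1964, censor=41, dx=40, father="f", mother="m",
               proband=True),
    ], ascertainment_arm="population")
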