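import numpy as np
import pytest

from embryosel.cohort import ClinicalProfile
from embryosel.morphometry import CassFeatures


@pytest.fixture
def rng():
    return np.random.default_rng(20240301)


def make_cass_features(
    embryo_id="E1",
    n_d2=4,
    n_d3=8,
    tcv_d1=7.0e5,
    tcv_d2=6.8e5,
    tcv_d3=6.5e5,
    cod_d2=1.1,
    cod_d3=1.2,
    frag_d2=0.03,
    frag_d3=0.07,
    day3_optimum=8.4,
):
    return CassFeatures(
        embryo_id=embryo_id,
        tcv_d1=tcv_d1,
        tcv_d2=tcv_d2,
        tcv_d3=tcv_d3,
        n_d2=n_d2,
        n_d3=n_d3,
        cod_d2=cod_d2,
        cod_d3=cod_d3,
        frag_d2=frag_d2,
        frag_d3=frag_d3,
        parity_d2=1 if n_d2 % 2 == 0 else 0,
        n_d3_dev=abs(n_d3 - day3_optimum),
    )


def make_profile(female_age=31.0, male_age=33.0, **kw):
    return ClinicalProfile(female_age=female_age, male_age=male_age, **kw)


@pytest.fixture
def cass_features_factory():
    return make_cass_features


@pytest.fixture
def profile_factory():
    return make_profile
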