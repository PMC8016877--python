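import pytest

from trf_heritance import simgen


@pytest.fixture(scope="session")
def study_ref():
    """The packaged study reference: 7 isoacceptor families x 3 members."""
    return simgen.study_reference()


@pytest.fixture(scope="session")
def small_ref():
    """Two families x two members, fully divergent between families."""
    return simgen.make_reference(2, 2, within_family_identity=0.9,
                                 length_range=(70, 80), seed=3,
                                 isoacceptors=["GlyGCC", "GluCTC"])


@pytest.fixture()
def sim_config():
    return simgen.SimConfig()
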