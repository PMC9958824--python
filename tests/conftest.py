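import hypothesis
import pytest
from hypothesis import strategies as st

from isoswell import IonSpec, TissueState, load_config, path_coefficients

hypothesis.settings.register_profile(
    "default", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("default")


@pytest.fixture(scope="session")
def table1_config():
    return load_config("table1")


@pytest.fixture(scope="session")
def table1_state(table1_config):
    return table1_config.initial_state()


@pytest.fixture(scope="session")
def table1_coeffs(table1_state):
    return path_coefficients(table1_state)


@st.composite
def ion_tables(draw):
    """Random electro-neutral, isotonic two-compartment states.

    Two permeant cations, one permeant anion, and one impermeant anion whose
    inside concentration exceeds the outside one (so a shrinkage solution
    exists).  Electroneutrality fixes the cation totals; isotonicity then
    ties the permeant-anion concentrations across the membrane.
    """
    finite = dict(allow_nan=False, allow_infinity=False)
    alpha = draw(st.floats(0.05, 0.9, **finite))
    a_out = draw(st.floats(1.0, 50.0, **finite))
    a_in = a_out + draw(st.floats(0.5, 200.0, **finite))
    x_in = draw(st.floats(0.1, 150.0, **finite))
    x_out = x_in + (a_in - a_out)
    cat_out = x_out + a_out
    cat_in = x_in + a_in
    split_out = draw(st.floats(0.1, 0.9, **finite))
    split_in = draw(st.floats(0.1, 0.9, **finite))
    species = (
        IonSpec("C1", 1, True, cat_out * split_out, cat_in * split_in),
        IonSpec("C2", 1, True, cat_out * (1.0 - split_out), cat_in * (1.0 - split_in)),
        IonSpec("X1", -1, True, x_out, x_in),
        IonSpec("A", -1, False, a_out, a_in),
    )
    return TissueState.from_specs(species, alpha)
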