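import numpy as np
import pytest

from lmp2f12 import (Molecule, prepare_f12, prepare_local, rhf_reference,
                     run_canonical_mp2, water_monomer)


@pytest.fixture(scope="session")
def h2():
    return Molecule(["H", "H"], [[0.0, 0.0, 0.0], [0.0, 0.0, 1.4]])


@pytest.fixture(scope="session")
def h2_ref(h2):
    return rhf_reference(h2, "svp-d")


@pytest.fixture(scope="session")
def he_ref():
    return rhf_reference(Molecule(["He"], [[0.0, 0.0, 0.0]]), "svp-d")


@pytest.fixture(scope="session")
def h2o():
    return water_monomer()


@pytest.fixture(scope="session")
def h2o_ref(h2o):
    return rhf_reference(h2o, "svp-d")


@pytest.fixture(scope="session")
def h2o_ctx(h2o_ref):
    return prepare_local(h2o_ref)


@pytest.fixture(scope="session")
def h2o_f12ctx(h2o_ref):
    return prepare_f12(h2o_ref)


@pytest.fixture(scope="session")
def h2_f12ctx(h2_ref):
    return prepare_f12(h2_ref)


@pytest.fixture(scope="session")
def he_f12ctx(he_ref):
    return prepare_f12(he_ref)


@pytest.fixture(scope="session")
def he_large_mp2():
    ref = rhf_reference(Molecule(["He"], [[0.0, 0.0, 0.0]]), "ref-large")
    return run_canonical_mp2(ref)


@pytest.fixture(scope="session")
def h2o_large_mp2(h2o):
    ref = rhf_reference(h2o, "ref-large")
    return run_canonical_mp2(ref)
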