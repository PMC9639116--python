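import numpy as np
import pytest

from ionatmos import (
    CylinderModel,
    IonSpecies,
    build_ideal_duplex,
    solve_pb,
)

# 33-nt strand-1 sequence of the studied duplex (read 5'->3' here)
RNA_SEQ = "GAGAUGCUAACCCUGAUCGCUGAUUCCUUGGAC"
DNA_SEQ = RNA_SEQ.replace("U", "T")


@pytest.fixture(scope="session")
def rna_model():
    return build_ideal_duplex(RNA_SEQ, "A")


@pytest.fixture(scope="session")
def dna_model():
    return build_ideal_duplex(DNA_SEQ, "B")


@pytest.fixture(scope="session")
def salt_100mM():
    return [IonSpecies("NA", +1, 0.1), IonSpecies("CL", -1, 0.1)]


@pytest.fixture(scope="session")
def dna_cylinder():
    return CylinderModel(radius=1.0, surface_charge=-0.89)


@pytest.fixture(scope="session")
def rna_cylinder():
    return CylinderModel(radius=1.3, surface_charge=-0.83)


@pytest.fixture(scope="session")
def dna_solution(dna_cylinder, salt_100mM):
    return solve_pb(dna_cylinder, salt_100mM)
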