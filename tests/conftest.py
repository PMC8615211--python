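import pytest

from mdartools.classify import run_pipeline
from mdartools.synthetic_data import REF_ID, FamilySpec, generate_family


@pytest.fixture(scope="session")
def default_family():
    """The default synthetic family: 5 species x (1 I, 1 II, 1 III_pts1,
    2 III_cyto), 435-residue core, mutation rate 0.05, seed 1."""
    return generate_family(FamilySpec())


@pytest.fixture(scope="session")
def default_classifications(default_family):
    _, aligned, _ = default_family
    return run_pipeline(aligned, REF_ID)


@pytest.fixture(scope="session")
def clean_family():
    """Same family with mutation rate 0 and one MDAR-like copy per species."""
    classes = {"I": 1, "II": 1, "III_pts1": 1, "III_cyto": 2, "MDAR_like": 1}
    return generate_family(
        FamilySpec(mutation_rate=0.0, classes_per_species=classes)
    )
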