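import pytest

from labeldiff import fixtures, report, structure


@pytest.fixture(scope="session")
def demo_dictionary():
    return fixtures.load_demo_dictionary()


@pytest.fixture(scope="session")
def compare_config(demo_dictionary):
    return report.CompareConfig(dictionary=demo_dictionary)


@pytest.fixture(scope="session")
def simple_pair():
    """One deterministic pair with a change in every category."""
    spec = fixtures.PairSpec(
        pair_id="simple",
        changes=(
            fixtures.InjectedChange(
                "cardio-respiratory arrest",
                structure.ADVERSE_REACTIONS,
                "6.1",
                "newly_added",
            ),
            fixtures.InjectedChange(
                "abscess", structure.WARNINGS_PRECAUTIONS, "5.2", "newly_added"
            ),
            fixtures.InjectedChange(
                "chest discomfort", structure.CONTRAINDICATIONS, "", "newly_added"
            ),
            fixtures.InjectedChange(
                "syncope", structure.DRUG_INTERACTIONS, "", "removed"
            ),
            fixtures.InjectedChange(
                "tremor", structure.ADVERSE_REACTIONS, "6.2", "pre_existing"
            ),
        ),
    )
    return fixtures.generate_pair(spec, seed=7)


@pytest.fixture(scope="session")
def identity_pair():
    """Old and new versions generated from an unchanged specification."""
    spec = fixtures.PairSpec(pair_id="identity", changes=())
    return fixtures.generate_pair(spec, seed=3)
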