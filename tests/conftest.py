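import pytest

from monomerizer import default_monomers, default_rules
from monomerizer.molgraph import parse_smiles
from monomerizer.pipeline import Annotator


@pytest.fixture(scope="session")
def rules():
    return default_rules()


@pytest.fixture(scope="session")
def monomers():
    return default_monomers()


@pytest.fixture(scope="session")
def cysteine(monomers):
    return monomers["Cysteine"]


@pytest.fixture(scope="session")
def glycine(monomers):
    return monomers["Glycine"]


@pytest.fixture(scope="session")
def peptide_rules(rules):
    """The two standalone peptide-bond rules only."""
    return [r for r in rules if r.standalone]


@pytest.fixture(scope="session")
def annotator(monomers, rules):
    """One shared annotator over the full amino-acid database."""
    return Annotator(monomers, rules)


@pytest.fixture(scope="session")
def peptide_pairing():
    return [("peptide bond from C(=O)OH", "peptide bond from NH2")]


@pytest.fixture
def small_molecules():
    return {
        "ethane": parse_smiles("CC"),
        "propane": parse_smiles("CCC"),
        "cyclopropane": parse_smiles("C1CC1"),
        "isobutane": parse_smiles("CC(C)C"),
        "benzene": parse_smiles("c1ccccc1"),
    }
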