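import numpy as np
import pytest

import molgat as mg

# SMILES spanning the chemistry the pipeline must handle: chains, rings,
# aromatics, heteroatoms, branches, charges, two-letter elements.
FIXTURE_SMILES = [
    "C", "O", "N", "CC", "CO", "CCO", "OCC", "CCC", "CCCC", "CCCCCCCC",
    "CCOCC", "COC", "CC(C)C", "CC(C)(C)C", "CC(O)C", "OC(C)C",
    "C1CC1", "C1CCC1", "C1CCCCC1", "c1ccccc1", "Cc1ccccc1", "c1ccccc1O",
    "c1ccncc1", "c1ccc2ccccc2c1", "CC(=O)O", "CC(=O)C", "C=C", "C#C",
    "C=CC=C", "CC#N", "CCS", "CSC", "CCl", "CBr", "CI", "CF",
    "ClCCl", "FC(F)F", "CCN", "CCNCC", "CN(C)C", "C(=O)N", "CC(N)C(=O)O",
    "OCCO", "OCC(O)CO", "CCCCO", "CCCCC", "CCCCCC", "CCOC(=O)C",
    "[NH4+]", "[O-]C(=O)C",
]


@pytest.fixture(scope="session")
def ethanol_graph():
    rec = mg.MoleculeRecord("CCO", -0.77)
    return mg.build_graph(rec, mg.featurize_smiles("CCO"))


@pytest.fixture(scope="session")
def fixture_graphs():
    """MolGraphs for a diverse subset of fixture SMILES (geometry included)."""
    graphs = []
    for smi in FIXTURE_SMILES[:30]:
        rec = mg.MoleculeRecord(smi, 0.0)
        graphs.append(mg.build_graph(rec, mg.featurize_smiles(smi)))
    return graphs


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
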