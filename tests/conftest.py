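import numpy as np
import pytest

from tkisense.catalog import parse_mutation_name
from tkisense.synthetic import GEOMETRY_CASES, gen_geometry_fixture
from tkisense.tensorize import build_master_index

FIG7_NAMES = ("delE746_A750", "V769_D770insASV", "A763_Y764insFQEA")


@pytest.fixture(scope="session")
def fig7_cohort():
    """The three-mutant worked-example cohort over a 740-780 window."""
    specs = [parse_mutation_name(n) for n in FIG7_NAMES]
    wt_residues = list(range(740, 781))
    master = build_master_index(specs, wt_residues)
    return specs, wt_residues, master


@pytest.fixture(scope="session")
def geometry_fixtures(tmp_path_factory):
    """All packaged geometry fixture cases, written once per session."""
    out = tmp_path_factory.mktemp("geomfix")
    return {case: gen_geometry_fixture(case, out) for case in GEOMETRY_CASES}


@pytest.fixture(scope="session")
def gefitinib_sdf(tmp_path_factory):
    """A 3-D gefitinib structure built from its connectivity, as SDF."""
    from rdkit import Chem
    from rdkit.Chem import AllChem

    smiles = "COc1cc2ncnc(Nc3ccc(F)c(Cl)c3)c2cc1OCCCN1CCOCC1"
    mol = Chem.AddHs(Chem.MolFromSmiles(smiles))
    params = AllChem.ETKDGv3()
    params.randomSeed = 7
    AllChem.EmbedMolecule(mol, params)
    path = tmp_path_factory.mktemp("lig") / "gefitinib.sdf"
    with Chem.SDWriter(str(path)) as w:
        w.write(mol)
    return path


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
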