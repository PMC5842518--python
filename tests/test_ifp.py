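"""Ligand perception, interaction geometry, and fingerprint assembly."""

import dataclasses

import numpy as np
import pytest

from tkisense.ifp import (BIT_NAMES, N_BITS, Frame, GeometryParams, IFPMatrix,
                          binding_site_residues, detect_interactions,
                          frame_ifp, perceive_ligand, read_frames,
                          trajectory_ifp)

BIT = {name: i for i, name in enumerate(BIT_NAMES)}


# ---------------------------------------------------------------- perception

def test_perceive_benzene(geometry_fixtures):
    lig = perceive_ligand(geometry_fixtures["no_contact"]["mol2"])
    assert len(lig.rings) == 1 and len(lig.rings[0]) == 6
    assert lig.apolar.sum() == 6
    assert not lig.donors.any() and not lig.acceptors.any()
    assert np.all(lig.charges == 0)


def test_perceive_methanol_hydroxyl(geometry_fixtures):
    """An O-H oxygen is both donor and acceptor; the carbon is not apolar."""
    lig = perceive_ligand(geometry_fixtures["hbond_acceptor"]["mol2"])
    o = lig.atom_names.index("O1")
    c = lig.atom_names.index("C1")
    assert lig.donors[o] and lig.acceptors[o]
    assert not lig.apolar[c]          # carbon bonded to oxygen
    assert lig.donor_h[o]             # explicit hydroxyl H recorded


def test_perceive_charges(geometry_fixtures):
    acetate = perceive_ligand(geometry_fixtures["salt_bridge_pos"]["mol2"])
    assert (acetate.charges < 0).any()
    ammonium = perceive_ligand(geometry_fixtures["salt_bridge_neg"]["mol2"])
    n = ammonium.elements.index("N")
    assert ammonium.charges[n] > 0
    assert not ammonium.acceptors[n]  # positively charged N has no lone pair


def test_perceive_gefitinib_quinazoline(gefitinib_sdf):
    """Quinazoline nitrogens are acceptors; the aniline N-H is a donor."""
    lig = perceive_ligand(gefitinib_sdf)
    n_idx = [i for i, e in enumerate(lig.elements) if e == "N"]
    assert len(n_idx) == 4            # 2 ring N, aniline NH, morpholine N
    assert sum(lig.acceptors[i] for i in n_idx) >= 3
    assert sum(lig.donors[i] for i in n_idx) == 1   # the aniline N-H
    assert len(lig.rings) >= 3        # quinazoline (2 fused) + anilino ring
    assert (lig.apolar & (np.asarray(lig.elements) == "F")).any()


def test_perceive_rejects_missing_bonds(tmp_path):
    xyz = tmp_path / "lig.xyz"
    xyz.write_text("3\nno bonds\nO 0 0 0\nH 1 0 0\nH 0 1 0\n")
    with pytest.raises(ValueError, match="MOL2 or SDF"):
        perceive_ligand(xyz)


# ----------------------------------------------------------------- geometry

def test_fixture_bits_match_ground_truth(geometry_fixtures):
    for case, fx in geometry_fixtures.items():
        lig = perceive_ligand(fx["mol2"])
        frame = read_frames(fx["pdb"])[0]
        assert detect_interactions(frame, 100, lig) == fx["bits"], case


def test_unknown_residue_raises(geometry_fixtures):
    fx = geometry_fixtures["no_contact"]
    lig = perceive_ligand(fx["mol2"])
    frame = read_frames(fx["pdb"])[0]
    with pytest.raises(KeyError):
        detect_interactions(frame, 999, lig)


def test_atom_order_permutation_safety(geometry_fixtures, rng):
    """Shuffling atom order within a frame never changes any bit."""
    for case in ("hbond_donor", "stack_face", "salt_bridge_pos"):
        fx = geometry_fixtures[case]
        lig = perceive_ligand(fx["mol2"])
        frame = read_frames(fx["pdb"])[0]
        ref = detect_interactions(frame, 100, lig)
        atoms = list(frame.protein_atoms)
        rng.shuffle(atoms)
        shuffled = Frame(protein_atoms=atoms, ligand_xyz=frame.ligand_xyz)
        assert detect_interactions(shuffled, 100, lig) == ref


def test_cutoff_monotonicity(geometry_fixtures):
    """Enlarging every distance cutoff can only switch bits on, never off."""
    base = GeometryParams()
    wide = dataclasses.replace(
        base,
        apolar_cutoff=base.apolar_cutoff + 2,
        f2f_centroid_cutoff=base.f2f_centroid_cutoff + 2,
        e2f_centroid_cutoff=base.e2f_centroid_cutoff + 2,
        hbond_cutoff=base.hbond_cutoff + 2,
        elec_cutoff=base.elec_cutoff + 2,
    )
    for case, fx in geometry_fixtures.items():
        lig = perceive_ligand(fx["mol2"])
        frame = read_frames(fx["pdb"])[0]
        before = detect_interactions(frame, 100, lig, base)
        after = detect_interactions(frame, 100, lig, wide)
        assert all(b <= a for b, a in zip(before, after)), case


def test_rigid_motion_invariance(geometry_fixtures, rng):
    """A joint rotation+translation of protein and ligand changes no bit."""
    from scipy.spatial.transform import Rotation

    for case in ("apolar_contact", "stack_edge", "hbond_acceptor",
                 "salt_bridge_neg"):
        fx = geometry_fixtures[case]
        lig = perceive_ligand(fx["mol2"])
        frame = read_frames(fx["pdb"])[0]
        ref = detect_interactions(frame, 100, lig)
        R = Rotation.random(random_state=42).as_matrix()
        t = rng.normal(size=3) * 10
        moved_atoms = [
            dataclasses.replace(a, xyz=R @ a.xyz + t)
            for a in frame.protein_atoms
        ]
        lig_xyz = {n: R @ c + t for n, c in zip(lig.atom_names, lig.coords)}
        lig_xyz.update({n: R @ c + t
                        for n, c in zip(lig.h_names, lig.h_coords)})
        moved = Frame(protein_atoms=moved_atoms, ligand_xyz=lig_xyz)
        assert detect_interactions(moved, 100, lig) == ref, case


def test_brute_force_oracle(geometry_fixtures):
    """Distance-rule bits agree with an independent all-pairs evaluation."""
    params = GeometryParams()
    cases = ("no_contact", "apolar_contact", "salt_bridge_pos",
             "salt_bridge_neg", "hbond_donor", "hbond_acceptor")
    prot_donors = {"GLY": {"N"}, "LEU": {"N"}, "SER": {"N", "OG"},
                   "LYS": {"N", "NZ"}, "ASP": {"N"}}
    prot_acceptors = {"GLY": {"O"}, "LEU": {"O"}, "SER": {"O", "OG"},
                      "LYS": {"O"}, "ASP": {"O", "OD1", "OD2"}}
    prot_apolar = {"GLY": set(), "LEU": {"CB", "CG", "CD1", "CD2"},
                   "SER": set(), "LYS": {"CB", "CG", "CD"},
                   "ASP": {"CB"}}
    prot_pos = {"LYS": {"NZ"}}
    prot_neg = {"ASP": {"OD1", "OD2"}}
    for case in cases:
        fx = geometry_fixtures[case]
        lig = perceive_ligand(fx["mol2"])
        frame = read_frames(fx["pdb"])[0]
        res = frame.residue_atoms(100)
        resname = res[0].resname
        heavy = {a.name: a.xyz for a in res if a.element != "H"}

        def pairs(prot_names, lig_mask):
            for pn in prot_names & heavy.keys():
                for j in np.flatnonzero(lig_mask):
                    yield float(np.linalg.norm(heavy[pn] - lig.coords[j]))

        apolar = any(d <= params.apolar_cutoff
                     for d in pairs(prot_apolar[resname], lig.apolar))
        pdon = any(d <= params.hbond_cutoff
                   for d in pairs(prot_donors[resname], lig.acceptors))
        pacc = any(d <= params.hbond_cutoff
                   for d in pairs(prot_acceptors[resname], lig.donors))
        ppos = any(d <= params.elec_cutoff
                   for d in pairs(prot_pos.get(resname, set()),
                                  lig.charges < 0))
        pneg = any(d <= params.elec_cutoff
                   for d in pairs(prot_neg.get(resname, set()),
                                  lig.charges > 0))
        got = detect_interactions(frame, 100, lig)
        # angle terms can only switch distance-rule H-bond hits off
        assert got[BIT["apolar"]] == int(apolar), case
        assert got[BIT["hbond_pdon"]] <= int(pdon), case
        assert got[BIT["hbond_pacc"]] <= int(pacc), case
        assert got[BIT["elec_ppos"]] == int(ppos), case
        assert got[BIT["elec_pneg"]] == int(pneg), case


# ----------------------------------------------------- vectors and matrices

def test_frame_ifp_ordering(geometry_fixtures):
    """Residue words are concatenated in ascending residue order."""
    fx = geometry_fixtures["apolar_contact"]
    lig = perceive_ligand(fx["mol2"])
    frame = read_frames(fx["pdb"])[0]
    far = [dataclasses.replace(a, resnum=50, xyz=a.xyz + 80.0)
           for a in frame.protein_atoms]
    two = Frame(protein_atoms=frame.protein_atoms + far,
                ligand_xyz=frame.ligand_xyz)
    vec = frame_ifp(two, [50, 100], lig)
    assert len(vec) == 2 * N_BITS
    assert not vec[:N_BITS].any()                       # residue 50 is far
    assert tuple(vec[N_BITS:]) == fx["bits"]


def test_frame_ifp_rejects_empty_and_unsorted(geometry_fixtures):
    fx = geometry_fixtures["no_contact"]
    lig = perceive_ligand(fx["mol2"])
    frame = read_frames(fx["pdb"])[0]
    with pytest.raises(ValueError, match="empty"):
        frame_ifp(frame, [], lig)
    with pytest.raises(ValueError, match="ascending"):
        frame_ifp(frame, [100, 50], lig)


def test_trajectory_identical_frames(geometry_fixtures, tmp_path):
    """Identical frames give identical rows; shape is F x 7R."""
    from tkisense.synthetic import _write_pdb, _fixture_cases

    case = _fixture_cases()["apolar_contact"]
    resname, atoms = case["residue"]
    pdb = tmp_path / "traj.pdb"
    _write_pdb(pdb, resname, atoms, n_models=3)
    lig = perceive_ligand(geometry_fixtures["apolar_contact"]["mol2"])
    frames = read_frames(pdb)
    assert len(frames) == 3
    mat = trajectory_ifp(frames, [100], lig, complex_name="x")
    assert mat.values.shape == (3, N_BITS)
    assert (mat.values == mat.values[0]).all()


def test_translated_ligand_gives_zero_row(geometry_fixtures):
    fx = geometry_fixtures["apolar_contact"]
    lig = perceive_ligand(fx["mol2"])
    frame = read_frames(fx["pdb"])[0]
    shifted = Frame(
        protein_atoms=frame.protein_atoms,
        ligand_xyz={n: c + 100.0 for n, c in
                    zip(lig.atom_names, lig.coords)},
    )
    assert not frame_ifp(shifted, [100], lig).any()


def test_binding_site_selection(geometry_fixtures):
    near = geometry_fixtures["apolar_contact"]
    lig = perceive_ligand(near["mol2"])
    frame = read_frames(near["pdb"])[0]
    assert binding_site_residues(frame, lig) == [100]
    far = geometry_fixtures["no_contact"]
    lig2 = perceive_ligand(far["mol2"])
    frame2 = read_frames(far["pdb"])[0]
    assert binding_site_residues(frame2, lig2) == []


def test_ifp_matrix_csv_roundtrip(tmp_path, rng):
    values = rng.integers(0, 2, size=(6, 2 * N_BITS))
    mat = IFPMatrix(values=values, residue_labels=["745", "746"],
                    complex_name="demo")
    path = tmp_path / "demo.csv"
    mat.to_csv(path)
    back = IFPMatrix.from_csv(path)
    np.testing.assert_array_equal(back.values, values)
    assert back.residue_labels == ["745", "746"]


def test_geometry_params_validation():
    with pytest.raises(ValueError, match="positive"):
        GeometryParams(apolar_cutoff=-1).validate()
    with pytest.raises(ValueError, match="degrees"):
        GeometryParams(f2f_angle_max=200).validate()
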