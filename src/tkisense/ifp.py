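"""Per-frame structural interaction fingerprints (SIFt-style).

For every binding-site residue and trajectory frame, seven independent bits
record whether that residue and the ligand form: an apolar (van der Waals)
contact, aromatic face-to-face stacking, aromatic edge-to-face stacking, a
hydrogen bond with the protein as donor, a hydrogen bond with the protein as
acceptor, an electrostatic contact with the protein positively charged, or
one with the protein negatively charged.  Concatenating the 7-bit words of
all residues gives the frame's fingerprint vector; stacking vectors over the
trajectory gives the complex's fingerprint matrix — its binding mode.

Protein frames come from a multi-model PDB; ligand chemistry (bonds, formal
charges, aromaticity) comes from a MOL2 or SDF file and is perceived once,
then shared across frames.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "N_BITS", "BIT_NAMES", "GeometryParams", "InteractionBits", "LigandTemplate",
    "Frame", "IFPMatrix", "perceive_ligand", "read_frames", "binding_site_residues",
    "detect_interactions", "frame_ifp", "trajectory_ifp",
]

N_BITS = 7
#: Fixed bit order within each residue's 7-bit word.
BIT_NAMES = (
    "apolar",         # van der Waals contact between apolar heavy atoms
    "aromatic_f2f",   # aromatic face-to-face stacking
    "aromatic_e2f",   # aromatic edge-to-face stacking
    "hbond_pdon",     # H-bond, protein is the donor
    "hbond_pacc",     # H-bond, protein is the acceptor
    "elec_ppos",      # electrostatic, protein positively charged
    "elec_pneg",      # electrostatic, protein negatively charged
)

InteractionBits = tuple[int, int, int, int, int, int, int]


@dataclass
class GeometryParams:
    """Geometric thresholds for the seven interaction types.

    Distances in Angstrom, angles in degrees.  Defaults follow common
    SIFt/IFP practice and are fully overridable.
    """

    apolar_cutoff: float = 4.5
    f2f_centroid_cutoff: float = 4.0
    f2f_angle_max: float = 30.0
    e2f_centroid_cutoff: float = 5.0
    e2f_angle_min: float = 60.0
    e2f_angle_max: float = 90.0
    hbond_cutoff: float = 3.5
    hbond_angle_min: float = 135.0   # D-H...A angle, used when an explicit H exists
    elec_cutoff: float = 4.0

    def validate(self) -> None:
        for name in ("apolar_cutoff", "f2f_centroid_cutoff", "e2f_centroid_cutoff",
                     "hbond_cutoff", "elec_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("f2f_angle_max", "e2f_angle_min", "e2f_angle_max",
                     "hbond_angle_min"):
            if not (0.0 <= getattr(self, name) <= 180.0):
                raise ValueError(f"{name} must lie in [0, 180] degrees")


# ---------------------------------------------------------------------------
# Ligand perception
# ---------------------------------------------------------------------------

_HALOGENS = {"F", "Cl", "Br", "I"}


@dataclass
class LigandTemplate:
    """Chemistry of the ligand, perceived once and shared across frames."""

    atom_names: list[str]            # heavy atoms, template order
    elements: list[str]
    coords: np.ndarray               # (n_heavy, 3) template conformer
    charges: np.ndarray              # formal charges, heavy atoms
    apolar: np.ndarray               # bool masks over heavy atoms
    donors: np.ndarray
    acceptors: np.ndarray
    rings: list[list[int]]           # aromatic rings as heavy-atom index lists
    donor_h: dict[int, list[int]]    # heavy index -> indices into h_coords
    h_coords: np.ndarray             # (n_h, 3) explicit hydrogens, template
    h_names: list[str] = field(default_factory=list)


def perceive_ligand(path: str | Path) -> LigandTemplate:
    """Perceive ligand atom types from a MOL2 or SDF file.

    Rules: apolar = C and S atoms not bonded to N or O, plus halogens;
    donor = N/O bearing a hydrogen (explicit or implicit); acceptor = N/O
    with an available lone pair (formal charge <= 0 and, for nitrogen, at
    most three connections and not a pyrrole-type ring NH); aromatic rings
    from the perceived aromaticity.
    """
    from rdkit import Chem, RDLogger

    RDLogger.DisableLog("rdApp.warning")
    path = Path(path)
    if path.suffix.lower() == ".mol2":
        mol = Chem.MolFromMol2File(str(path), removeHs=False)
    elif path.suffix.lower() in (".sdf", ".mol"):
        mol = next(iter(Chem.SDMolSupplier(str(path), removeHs=False)), None)
    else:
        raise ValueError(
            f"unsupported ligand format {path.suffix!r}: supply a MOL2 or SDF "
            "file with explicit bond and charge information"
        )
    if mol is None:
        raise ValueError(
            f"could not parse ligand {path}: supply a valid MOL2 or SDF file "
            "with explicit bond information"
        )
    conf = mol.GetConformer()
    heavy = [a for a in mol.GetAtoms() if a.GetSymbol() != "H"]
    index_of = {a.GetIdx(): i for i, a in enumerate(heavy)}

    names, elements, charges = [], [], []
    apolar, donors, acceptors = [], [], []
    coords = np.zeros((len(heavy), 3))
    h_coords, h_names = [], []
    donor_h: dict[int, list[int]] = {}

    for i, a in enumerate(heavy):
        sym = a.GetSymbol()
        if a.HasProp("_TriposAtomName"):
            names.append(a.GetProp("_TriposAtomName"))
        else:
            names.append(f"{sym.upper()}{i + 1}")
        elements.append(sym)
        charges.append(a.GetFormalCharge())
        coords[i] = conf.GetAtomPosition(a.GetIdx())
        nbr_syms = {n.GetSymbol() for n in a.GetNeighbors()}
        apolar.append(
            sym in _HALOGENS
            or (sym in ("C", "S") and not ({"N", "O"} & nbr_syms))
        )
        n_h = a.GetTotalNumHs(includeNeighbors=True)
        is_no = sym in ("N", "O")
        donors.append(is_no and n_h > 0)
        if sym == "O":
            acceptors.append(a.GetFormalCharge() <= 0)
        elif sym == "N":
            pyrrole_like = a.GetIsAromatic() and n_h > 0
            acceptors.append(
                a.GetFormalCharge() <= 0
                and a.GetDegree() + n_h <= 3
                and not pyrrole_like
            )
        else:
            acceptors.append(False)

    for a in mol.GetAtoms():
        if a.GetSymbol() != "H":
            continue
        h_idx = len(h_coords)
        h_coords.append(np.array(conf.GetAtomPosition(a.GetIdx())))
        h_names.append(
            a.GetProp("_TriposAtomName") if a.HasProp("_TriposAtomName")
            else f"H{h_idx + 1}"
        )
        for n in a.GetNeighbors():
            if n.GetIdx() in index_of:
                donor_h.setdefault(index_of[n.GetIdx()], []).append(h_idx)

    rings = []
    for ring in mol.GetRingInfo().AtomRings():
        atoms = [mol.GetAtomWithIdx(j) for j in ring]
        if all(a.GetIsAromatic() for a in atoms):
            rings.append([index_of[j] for j in ring])

    return LigandTemplate(
        atom_names=names,
        elements=elements,
        coords=coords,
        charges=np.asarray(charges, dtype=float),
        apolar=np.asarray(apolar, dtype=bool),
        donors=np.asarray(donors, dtype=bool),
        acceptors=np.asarray(acceptors, dtype=bool),
        rings=rings,
        donor_h=donor_h,
        h_coords=(np.asarray(h_coords) if h_coords else np.zeros((0, 3))),
        h_names=h_names,
    )


# ---------------------------------------------------------------------------
# Protein typing templates (by residue / atom name; no protonation engine)
# ---------------------------------------------------------------------------

_STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

# Side-chain donors / acceptors (heavy atoms); backbone handled separately.
_SC_DONORS = {
    "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"}, "ASN": {"ND2"},
    "GLN": {"NE2"}, "LYS": {"NZ"}, "ARG": {"NE", "NH1", "NH2"},
    "TRP": {"NE1"}, "HIS": {"ND1", "NE2"},
}
_SC_ACCEPTORS = {
    "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"}, "ASN": {"OD1"},
    "GLN": {"OE1"}, "ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"},
    "HIS": {"ND1", "NE2"},
}
_POSITIVE = {"LYS": {"NZ"}, "ARG": {"NE", "NH1", "NH2"}}
_NEGATIVE = {"ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"}}
_AROMATIC_RINGS = {
    "PHE": [["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]],
    "TYR": [["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]],
    "TRP": [["CG", "CD1", "NE1", "CE2", "CD2"],
            ["CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"]],
    "HIS": [["CG", "ND1", "CD2", "CE1", "NE2"]],
}
# Carbons bonded to N or O (excluded from the apolar set); CA and backbone C
# are excluded for every residue.
_POLAR_BONDED_C = {
    "SER": {"CB"}, "THR": {"CB"}, "ASP": {"CG"}, "ASN": {"CG"},
    "GLU": {"CD"}, "GLN": {"CD"}, "ARG": {"CD", "CZ"}, "LYS": {"CE"},
    "PRO": {"CD"}, "TRP": {"CD1", "CE2"}, "HIS": {"CG", "CD2", "CE1"},
    "TYR": {"CZ"},
}


def _element_of(atom_name: str, element: str) -> str:
    if element and element.strip():
        return element.strip().capitalize()
    name = atom_name.strip()
    while name and name[0].isdigit():
        name = name[1:]
    return name[:1].upper()


@dataclass
class ProteinAtom:
    name: str
    element: str
    resnum: int
    resname: str
    chain: str
    xyz: np.ndarray


@dataclass
class Frame:
    """One trajectory frame: typed protein atoms plus ligand coordinates."""

    protein_atoms: list[ProteinAtom]
    ligand_xyz: dict[str, np.ndarray]   # atom name -> coords (heavy + any H)

    def residue_atoms(self, resnum: int) -> list[ProteinAtom]:
        atoms = [a for a in self.protein_atoms if a.resnum == resnum]
        if not atoms:
            raise KeyError(f"residue {resnum} not present in frame")
        return atoms

    def residue_numbers(self) -> list[int]:
        return sorted({a.resnum for a in self.protein_atoms})


def read_frames(
    path: str | Path, ligand_resnames: set[str] | None = None
) -> list[Frame]:
    """Read a multi-model PDB into a list of :class:`Frame`.

    Standard amino-acid records become protein atoms; any other non-water
    residue (or one whose name is in ``ligand_resnames``) supplies the
    per-frame ligand coordinates, keyed by atom name.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("traj", str(path))
    frames: list[Frame] = []
    for model in structure:
        protein: list[ProteinAtom] = []
        ligand: dict[str, np.ndarray] = {}
        for chain in model:
            for res in chain:
                resname = res.get_resname().strip()
                is_ligand = (
                    resname in ligand_resnames
                    if ligand_resnames is not None
                    else (resname not in _STANDARD_AA and resname != "HOH")
                )
                for atom in res:
                    if is_ligand:
                        ligand[atom.get_name()] = atom.coord.astype(float)
                    elif resname in _STANDARD_AA:
                        protein.append(ProteinAtom(
                            name=atom.get_name(),
                            element=_element_of(atom.get_name(), atom.element),
                            resnum=res.get_id()[1],
                            resname=resname,
                            chain=chain.get_id(),
                            xyz=atom.coord.astype(float),
                        ))
        frames.append(Frame(protein_atoms=protein, ligand_xyz=ligand))
    if not frames:
        raise ValueError(f"no MODEL records found in {path}")
    return frames


def _ligand_heavy_coords(frame: Frame, ligand: LigandTemplate) -> np.ndarray:
    """Per-frame heavy-atom coordinates, template order.

    Falls back to the template conformer when the frame carries no ligand
    coordinates (static-ligand workflows and fixtures).
    """
    if not frame.ligand_xyz:
        return ligand.coords
    try:
        return np.stack([frame.ligand_xyz[n] for n in ligand.atom_names])
    except KeyError as exc:
        raise ValueError(
            f"frame ligand is missing atom {exc.args[0]!r} named in the "
            "ligand template"
        ) from exc


def _ligand_h_coords(frame: Frame, ligand: LigandTemplate) -> np.ndarray | None:
    if not frame.ligand_xyz:
        return ligand.h_coords if len(ligand.h_coords) else None
    if ligand.h_names and all(n in frame.ligand_xyz for n in ligand.h_names):
        return np.stack([frame.ligand_xyz[n] for n in ligand.h_names])
    return None


def binding_site_residues(
    frame: Frame, ligand: LigandTemplate, cutoff: float = 6.0
) -> list[int]:
    """Residues with any heavy atom within ``cutoff`` of any ligand heavy atom.

    Evaluated on one (by convention the first) frame and then frozen for the
    whole trajectory, so fingerprint columns stay comparable across frames.
    """
    lig = _ligand_heavy_coords(frame, ligand)
    hits = set()
    for atom in frame.protein_atoms:
        if atom.element == "H":
            continue
        if np.min(np.linalg.norm(lig - atom.xyz, axis=1)) <= cutoff:
            hits.add(atom.resnum)
    return sorted(hits)


# ---------------------------------------------------------------------------
# Interaction detection
# ---------------------------------------------------------------------------

def _ring_geometry(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centroid and unit normal of a (near-)planar ring, via SVD."""
    centroid = coords.mean(axis=0)
    _, _, vt = np.linalg.svd(coords - centroid)
    return centroid, vt[2]


def _plane_angle(n1: np.ndarray, n2: np.ndarray) -> float:
    """Acute angle between two ring planes, degrees, in [0, 90]."""
    c = abs(float(np.dot(n1, n2)))
    return math.degrees(math.acos(min(1.0, c)))


def _residue_hydrogens(atoms: list[ProteinAtom]) -> dict[str, list[np.ndarray]]:
    """Map donor heavy-atom name -> coordinates of hydrogens covalently near it."""
    hs = [a for a in atoms if a.element == "H"]
    out: dict[str, list[np.ndarray]] = {}
    for heavy in atoms:
        if heavy.element == "H":
            continue
        near = [h.xyz for h in hs if np.linalg.norm(h.xyz - heavy.xyz) < 1.25]
        if near:
            out[heavy.name] = near
    return out


def _dha_angle(d: np.ndarray, h: np.ndarray, a: np.ndarray) -> float:
    v1, v2 = d - h, a - h
    c = float(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))


def _hbond(
    donor_xyz: np.ndarray,
    donor_hs: list[np.ndarray],
    acceptor_xyz: np.ndarray,
    params: GeometryParams,
) -> bool:
    """Distance rule, tightened by the D-H...A angle when an H is present."""
    if np.linalg.norm(donor_xyz - acceptor_xyz) > params.hbond_cutoff:
        return False
    if not donor_hs:
        return True
    return any(
        _dha_angle(donor_xyz, h, acceptor_xyz) >= params.hbond_angle_min
        for h in donor_hs
    )


def detect_interactions(
    frame: Frame,
    resnum: int,
    ligand: LigandTemplate,
    params: GeometryParams | None = None,
) -> InteractionBits:
    """Seven interaction bits between one residue and the ligand in one frame.

    Each bit is 1 iff at least one atom pair (or ring pair) satisfies the
    corresponding geometric rule; the result is deterministic and invariant
    to atom ordering within the frame.
    """
    params = params or GeometryParams()
    params.validate()
    atoms = frame.residue_atoms(resnum)
    resname = atoms[0].resname
    by_name = {a.name: a for a in atoms if a.element != "H"}
    lig_xyz = _ligand_heavy_coords(frame, ligand)
    lig_h = _ligand_h_coords(frame, ligand)

    # apolar
    excl = _POLAR_BONDED_C.get(resname, set()) | {"C", "CA"}
    prot_apolar = np.array([
        a.xyz for a in atoms
        if a.element in ("C", "S") and a.name not in excl
    ])
    apolar = 0
    if len(prot_apolar) and ligand.apolar.any():
        d = np.linalg.norm(
            prot_apolar[:, None, :] - lig_xyz[None, ligand.apolar, :], axis=2
        )
        apolar = int(d.min() <= params.apolar_cutoff)

    # aromatic stacking
    f2f = e2f = 0
    for ring_names in _AROMATIC_RINGS.get(resname, []):
        if not all(n in by_name for n in ring_names):
            continue
        pc, pn = _ring_geometry(np.stack([by_name[n].xyz for n in ring_names]))
        for ring in ligand.rings:
            lc, ln = _ring_geometry(lig_xyz[ring])
            dist = float(np.linalg.norm(pc - lc))
            ang = _plane_angle(pn, ln)
            if dist <= params.f2f_centroid_cutoff and ang <= params.f2f_angle_max:
                f2f = 1
            if (dist <= params.e2f_centroid_cutoff
                    and params.e2f_angle_min <= ang <= params.e2f_angle_max):
                e2f = 1

    # hydrogen bonds
    res_h = _residue_hydrogens(atoms)
    donor_names = set(_SC_DONORS.get(resname, set()))
    if resname != "PRO":
        donor_names.add("N")
    acceptor_names = set(_SC_ACCEPTORS.get(resname, set())) | {"O", "OXT"}

    pdon = 0
    lig_acc_idx = np.flatnonzero(ligand.acceptors)
    for dn in donor_names:
        if dn not in by_name or pdon:
            continue
        dxyz = by_name[dn].xyz
        hs = res_h.get(dn, [])
        if any(_hbond(dxyz, hs, lig_xyz[j], params) for j in lig_acc_idx):
            pdon = 1

    pacc = 0
    lig_don_idx = np.flatnonzero(ligand.donors)
    for j in lig_don_idx:
        if pacc:
            break
        hs: list[np.ndarray] = []
        if lig_h is not None:
            hs = [lig_h[k] for k in ligand.donor_h.get(int(j), [])]
        for an in acceptor_names:
            if an in by_name and _hbond(lig_xyz[j], hs, by_name[an].xyz, params):
                pacc = 1
                break

    # electrostatics
    def _charge_contact(prot_names: set[str], lig_mask: np.ndarray) -> int:
        pts = [by_name[n].xyz for n in prot_names if n in by_name]
        if not pts or not lig_mask.any():
            return 0
        d = np.linalg.norm(
            np.stack(pts)[:, None, :] - lig_xyz[None, lig_mask, :], axis=2
        )
        return int(d.min() <= params.elec_cutoff)

    ppos = _charge_contact(_POSITIVE.get(resname, set()), ligand.charges < 0)
    pneg = _charge_contact(_NEGATIVE.get(resname, set()), ligand.charges > 0)

    return (apolar, f2f, e2f, pdon, pacc, ppos, pneg)


def frame_ifp(
    frame: Frame,
    residues: list[int],
    ligand: LigandTemplate,
    params: GeometryParams | None = None,
) -> np.ndarray:
    """Concatenated 7-bit words for the given residues, ascending order."""
    if not residues:
        raise ValueError("residue list must not be empty")
    if list(residues) != sorted(residues):
        raise ValueError("residues must be sorted ascending")
    bits = [detect_interactions(frame, r, ligand, params) for r in residues]
    return np.asarray([b for word in bits for b in word], dtype=np.uint8)


@dataclass
class IFPMatrix:
    """Frames x (7 * residues) binary fingerprint matrix of one complex."""

    values: np.ndarray
    residue_labels: list[str]
    complex_name: str = ""
    drug: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("IFP matrix must be 2-D (frames x bits)")
        if self.values.shape[1] != N_BITS * len(self.residue_labels):
            raise ValueError(
                f"matrix width {self.values.shape[1]} does not match "
                f"{len(self.residue_labels)} residues x {N_BITS} bits"
            )

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    def column_names(self) -> list[str]:
        return [f"{r}:{b}" for r in self.residue_labels for b in BIT_NAMES]

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, columns=self.column_names()).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path: str | Path, complex_name: str = "",
                 drug: str = "") -> "IFPMatrix":
        df = pd.read_csv(path)
        labels = [c.rsplit(":", 1)[0] for c in df.columns[::N_BITS]]
        return cls(values=df.to_numpy(), residue_labels=labels,
                   complex_name=complex_name or Path(path).stem, drug=drug)

    def to_bitstrings(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for row in self.values:
                fh.write("".join(str(int(b)) for b in row) + "\n")


def trajectory_ifp(
    frames: list[Frame],
    residues: list[int],
    ligand: LigandTemplate,
    params: GeometryParams | None = None,
    complex_name: str = "",
    drug: str = "",
) -> IFPMatrix:
    """Fingerprint matrix over a trajectory: row f is ``frame_ifp(frames[f])``."""
    if not frames:
        raise ValueError("need at least one frame")
    resset = set(residues)
    for i, fr in enumerate(frames):
        if not resset <= set(fr.residue_numbers()):
            missing = sorted(resset - set(fr.residue_numbers()))
            raise ValueError(f"frame {i} is missing residues {missing}")
    rows = [frame_ifp(fr, list(residues), ligand, params) for fr in frames]
    return IFPMatrix(
        values=np.stack(rows),
        residue_labels=[str(r) for r in residues],
        complex_name=complex_name,
        drug=drug,
    )
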