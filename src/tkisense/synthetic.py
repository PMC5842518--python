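"""Desk-scale synthetic inputs with the statistical structure of the pipeline.

Two generators:

* :func:`gen_ifp_tensor` — class-structured binary fingerprint matrices.
  Each residue-bit evolves as a two-state Markov chain over frames (contacts
  in MD are temporally persistent, which is what makes the frame mode
  compressible), with its stationary on-probability set per sensitivity
  class at a chosen subset of discriminative residues and to a small
  background rate elsewhere.  Some samples carry real indel mutation specs
  so the zero-padding path is exercised.

* :func:`gen_geometry_fixture` — minimal residue + ligand coordinate pairs
  (multi-model PDB + MOL2) constructed analytically so that a known set of
  interaction bits, recorded alongside as ground truth, falls inside the
  default geometric thresholds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .catalog import MutantSpec, parse_mutation_name
from .ifp import N_BITS, BIT_NAMES, IFPMatrix
from .tensorize import build_master_index, owned_slots

__all__ = ["SimScenario", "gen_ifp_tensor", "gen_geometry_fixture",
           "GEOMETRY_CASES"]

_CLASS_NAMES = ("high", "moderate", "low")


@dataclass
class SimScenario:
    """Parameters of one synthetic cohort.

    Defaults mirror the real study cohort: 30 samples split 12/10/8 across
    the high/moderate/low sensitivity classes, 100 frames per trajectory, a
    30-residue binding-site window (WT residues 746-775) containing both the
    recurrent exon 19 deletion and two exon 20 insertions so padding is
    always exercised, and strongly class-separated contact probabilities
    (0.9 / 0.5 / 0.1) at six discriminative residues over a 0.05 background.
    """

    class_sizes: tuple[int, int, int] = (12, 10, 8)
    F: int = 100
    wt_residues: tuple[int, ...] = tuple(range(746, 776))
    discriminative: tuple[int, ...] = (751, 754, 758, 762, 766, 771)
    p_on_class: tuple[float, float, float] = (0.9, 0.5, 0.1)
    p_bg: float = 0.05
    flip_rate: float = 0.02
    indel_names: dict[int, str] = field(default_factory=lambda: {
        0: "delE746_A750",            # high-class sample
        12: "A763_Y764insFQEA",       # moderate-class sample
        22: "V769_D770insASV",        # low-class sample
    })
    seed: int = 0

    @property
    def M(self) -> int:
        return sum(self.class_sizes)

    def validate(self) -> None:
        probs = (*self.p_on_class, self.p_bg, self.flip_rate)
        if not all(0.0 <= p <= 1.0 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if not set(self.discriminative) <= set(self.wt_residues):
            raise ValueError("discriminative residues must be in the WT window")
        for idx in self.indel_names:
            if not (0 <= idx < self.M):
                raise ValueError(f"indel sample index {idx} out of range")

    @classmethod
    def null(cls, seed: int = 0) -> "SimScenario":
        """No class signal: every class shares the moderate on-probability."""
        return cls(p_on_class=(0.5, 0.5, 0.5), seed=seed)


def _markov_chain(rng, p: float, flip_rate: float, F: int, n: int) -> np.ndarray:
    """n independent 2-state chains over F frames with stationary P(on) = p.

    Off-switch hazard is ``flip_rate`` per frame; the on-switch hazard is
    scaled so the stationary distribution equals the target marginal, and the
    initial state is drawn from it, so every frame has marginal p exactly.
    """
    if p <= 0.0 or p >= 1.0:
        return np.full((F, n), int(round(p)), dtype=np.uint8)
    q10 = flip_rate                       # P(1 -> 0)
    q01 = min(1.0, flip_rate * p / (1.0 - p))   # P(0 -> 1)
    out = np.empty((F, n), dtype=np.uint8)
    state = (rng.random(n) < p).astype(np.uint8)
    out[0] = state
    for f in range(1, F):
        u = rng.random(n)
        flip = np.where(state == 1, u < q10, u < q01)
        state = np.where(flip, 1 - state, state).astype(np.uint8)
        out[f] = state
    return out


def gen_ifp_tensor(
    scenario: SimScenario,
) -> tuple[list[IFPMatrix], list[str], list[MutantSpec]]:
    """Generate per-sample fingerprint matrices, labels, and mutation specs.

    Matrices carry each mutant's *own* residues only (deleted residues
    dropped, inserted residues added), exactly as a real per-complex
    fingerprint would, so they must go through the master-index padding
    before stacking.  Deterministic for a fixed scenario seed.
    """
    scenario.validate()
    rng = np.random.default_rng(scenario.seed)
    labels = [
        _CLASS_NAMES[c]
        for c, size in enumerate(scenario.class_sizes)
        for _ in range(size)
    ]
    specs = []
    for i in range(scenario.M):
        if i in scenario.indel_names:
            spec = parse_mutation_name(scenario.indel_names[i])
            spec.name = f"sample{i:02d}_{spec.name}"
        else:
            spec = MutantSpec(name=f"sample{i:02d}_wt")
        specs.append(spec)

    # Residue content per sample derived from the master-index ownership
    # rules so generator and padder always agree.
    master = build_master_index(specs, list(scenario.wt_residues))
    # The d-th discriminative residue applies the p_on_class ladder to the
    # classes in cyclic rotation d mod 3: no single residue separates all
    # three classes, mirroring binding modes where different residues
    # distinguish different mutant groups.
    disc_rot = {r: d % len(scenario.p_on_class)
                for d, r in enumerate(sorted(scenario.discriminative))}
    matrices: list[IFPMatrix] = []
    for i, (spec, label) in enumerate(zip(specs, labels)):
        owned = owned_slots(spec, master)
        slots = [s for s, own in zip(master.slots, owned) if own]
        cls = _CLASS_NAMES.index(label)
        cols = []
        for slot in slots:
            disc = (not slot.is_insertion) and slot.wt_left in disc_rot
            if disc:
                rot = disc_rot[slot.wt_left]
                p = scenario.p_on_class[(cls + rot) % len(scenario.p_on_class)]
            else:
                p = scenario.p_bg
            cols.append(_markov_chain(rng, p, scenario.flip_rate,
                                      scenario.F, N_BITS))
        values = np.concatenate(cols, axis=1)
        matrices.append(IFPMatrix(
            values=values,
            residue_labels=[s.label() for s in slots],
            complex_name=spec.name,
            drug="synthetic",
        ))
    return matrices, labels, specs


# ---------------------------------------------------------------------------
# Geometry fixtures
# ---------------------------------------------------------------------------

def _hexagon(center, radius=1.39, phase=0.0, plane="xy"):
    pts = []
    for k in range(6):
        a = phase + k * np.pi / 3
        if plane == "xy":
            offset = (radius * np.cos(a), radius * np.sin(a), 0.0)
        else:  # xz
            offset = (radius * np.cos(a), 0.0, radius * np.sin(a))
        pts.append(tuple(np.add(center, offset)))
    return pts


def _benzene(center, phase=0.0, plane="xy"):
    pts = _hexagon(center, phase=phase, plane=plane)
    atoms = [(f"C{i+1}", x, y, z, "C.ar", 0.0) for i, (x, y, z) in enumerate(pts)]
    bonds = [(1, 2, "ar"), (2, 3, "ar"), (3, 4, "ar"),
             (4, 5, "ar"), (5, 6, "ar"), (6, 1, "ar")]
    return "benzene", atoms, bonds


def _acetone():
    atoms = [
        ("O1", 2.90, 0.00, 0.00, "O.2", 0.0),
        ("C2", 4.12, 0.25, 0.00, "C.2", 0.0),
        ("C3", 4.60, 1.65, 0.00, "C.3", 0.0),
        ("C4", 5.00, -1.00, 0.00, "C.3", 0.0),
    ]
    bonds = [(1, 2, "2"), (2, 3, "1"), (2, 4, "1")]
    return "acetone", atoms, bonds


def _methanol():
    atoms = [
        ("O1", 2.90, 0.00, 0.00, "O.3", 0.0),
        ("C1", 3.60, 1.20, 0.00, "C.3", 0.0),
        ("H1", 1.94, 0.00, 0.00, "H", 0.0),
    ]
    bonds = [(1, 2, "1"), (1, 3, "1")]
    return "methanol", atoms, bonds


def _acetate():
    atoms = [
        ("O1", 3.80, 0.00, 0.00, "O.co2", -0.5),
        ("C2", 5.05, 0.00, 0.00, "C.2", 0.0),
        ("O2", 4.32, 1.01, 0.00, "O.co2", -0.5),
        ("C1", 5.94, -1.23, 0.00, "C.3", 0.0),
    ]
    bonds = [(2, 1, "ar"), (2, 3, "ar"), (2, 4, "1")]
    return "acetate", atoms, bonds


def _methylammonium():
    atoms = [
        ("N1", 3.80, 0.00, 0.00, "N.4", 1.0),
        ("C1", 5.30, 0.00, 0.00, "C.3", 0.0),
    ]
    bonds = [(1, 2, "1")]
    return "methylammonium", atoms, bonds


def _res(resname, named_xyz):
    return resname, [(n, tuple(x)) for n, x in named_xyz]


_PHE_RING = [
    ("CG", (1.39, 0.00, 0.00)), ("CD1", (0.695, 1.204, 0.00)),
    ("CD2", (0.695, -1.204, 0.00)), ("CE1", (-0.695, 1.204, 0.00)),
    ("CE2", (-0.695, -1.204, 0.00)), ("CZ", (-1.39, 0.00, 0.00)),
]
_PHE_REST = [
    ("CB", (2.90, 0.00, -0.40)), ("CA", (3.70, 1.20, -0.80)),
    ("N", (3.50, 2.40, -0.10)), ("C", (5.20, 0.90, -0.90)),
    ("O", (5.90, -0.10, -1.20)),
]


def _fixture_cases() -> dict[str, dict]:
    benzene_far = _benzene((50.0, 0.0, 0.0))
    benzene_apolar = _benzene((5.19, 0.0, 0.0), phase=np.pi)  # vertex at x=3.80
    benzene_face = _benzene((0.0, 0.0, 3.60), phase=np.pi / 6)
    benzene_edge = _benzene((0.0, 0.0, 4.80), plane="xz")
    return {
        "no_contact": dict(
            residue=_res("GLY", [
                ("N", (0.0, 0.0, 0.0)), ("CA", (1.45, 0.0, 0.0)),
                ("C", (2.0, 1.4, 0.0)), ("O", (1.4, 2.4, 0.0)),
            ]),
            ligand=benzene_far,
            truth=(0, 0, 0, 0, 0, 0, 0),
        ),
        "apolar_contact": dict(
            residue=_res("LEU", [
                ("CD1", (0.0, 0.0, 0.0)), ("CG", (-1.2, 0.9, 0.0)),
                ("CD2", (-1.0, 2.0, 1.0)), ("CB", (-2.6, 0.5, 0.0)),
                ("CA", (-3.6, 1.6, 0.0)), ("N", (-3.4, 2.9, 0.5)),
                ("C", (-5.0, 1.2, 0.0)), ("O", (-5.5, 0.1, 0.0)),
            ]),
            ligand=benzene_apolar,   # nearest ring C at 3.80 A from CD1
            truth=(1, 0, 0, 0, 0, 0, 0),
        ),
        "hbond_donor": dict(
            residue=_res("SER", [
                ("OG", (0.0, 0.0, 0.0)), ("HG", (0.96, 0.0, 0.0)),
                ("CB", (-0.8, -1.2, 0.0)), ("CA", (-2.3, -1.1, 0.0)),
                ("N", (-2.9, 0.15, 0.3)), ("C", (-3.0, -2.35, 0.0)),
                ("O", (-2.4, -3.4, 0.0)),
            ]),
            ligand=_acetone(),       # carbonyl O at 2.90 A, D-H...A = 180 deg
            truth=(0, 0, 0, 1, 0, 0, 0),
        ),
        "hbond_acceptor": dict(
            residue=_res("GLY", [
                ("O", (0.0, 0.0, 0.0)), ("C", (-1.23, 0.2, 0.0)),
                ("CA", (-2.1, -0.9, 0.0)), ("N", (-3.5, -0.6, 0.0)),
            ]),
            ligand=_methanol(),      # hydroxyl donates to backbone O at 2.90 A
            truth=(0, 0, 0, 0, 1, 0, 0),
        ),
        # Stacked rings are also apolar contacts: ring carbons sit well
        # inside the 4.5 A van der Waals cutoff whenever centroids are close
        # enough to stack, so the apolar bit is part of the ground truth.
        "stack_face": dict(
            residue=_res("PHE", _PHE_RING + _PHE_REST),
            ligand=benzene_face,     # parallel, centroid distance 3.60 A
            truth=(1, 1, 0, 0, 0, 0, 0),
        ),
        "stack_edge": dict(
            residue=_res("PHE", _PHE_RING + _PHE_REST),
            ligand=benzene_edge,     # perpendicular, centroid distance 4.80 A
            truth=(1, 0, 1, 0, 0, 0, 0),
        ),
        "salt_bridge_pos": dict(
            residue=_res("LYS", [
                ("NZ", (0.0, 0.0, 0.0)), ("CE", (-1.3, 0.6, 0.0)),
                ("CD", (-2.7, 0.05, 0.0)), ("CG", (-4.0, 0.8, 0.0)),
                ("CB", (-5.3, 0.15, 0.0)), ("CA", (-6.6, 0.9, 0.0)),
                ("N", (-6.8, 2.2, 0.4)), ("C", (-7.9, 0.1, 0.0)),
                ("O", (-8.0, -1.1, 0.0)),
            ]),
            ligand=_acetate(),       # carboxylate O- at 3.80 A from NZ
            truth=(0, 0, 0, 0, 0, 1, 0),
        ),
        "salt_bridge_neg": dict(
            residue=_res("ASP", [
                ("OD1", (0.0, 0.0, 0.0)), ("CG", (-1.0, 0.75, 0.0)),
                ("OD2", (-0.7, 1.98, 0.0)), ("CB", (-2.45, 0.4, 0.0)),
                ("CA", (-3.5, 1.5, 0.0)), ("N", (-3.4, 2.7, 0.4)),
                ("C", (-4.9, 0.9, 0.0)), ("O", (-5.9, 1.6, 0.0)),
            ]),
            ligand=_methylammonium(),  # ammonium N+ at 3.80 A from OD1
            truth=(0, 0, 0, 0, 0, 0, 1),
        ),
    }


GEOMETRY_CASES = tuple(_fixture_cases())


def _write_pdb(path: Path, resname: str, atoms, n_models: int = 1) -> None:
    lines = []
    for m in range(1, n_models + 1):
        lines.append(f"MODEL     {m:4d}")
        for i, (name, (x, y, z)) in enumerate(atoms, start=1):
            element = "H" if name.startswith("H") else name[0]
            lines.append(
                f"ATOM  {i:5d} {name:<4s} {resname:>3s} A{100:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {element:>2s}"
            )
        lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


def _write_mol2(path: Path, name: str, atoms, bonds) -> None:
    lines = [
        "@<TRIPOS>MOLECULE", name,
        f"{len(atoms)} {len(bonds)} 1", "SMALL", "USER_CHARGES",
        "@<TRIPOS>ATOM",
    ]
    for i, (aname, x, y, z, sybyl, charge) in enumerate(atoms, start=1):
        lines.append(
            f"{i} {aname} {x:.4f} {y:.4f} {z:.4f} {sybyl} 1 LIG {charge:.3f}"
        )
    lines.append("@<TRIPOS>BOND")
    for i, (a, b, order) in enumerate(bonds, start=1):
        lines.append(f"{i} {a} {b} {order}")
    path.write_text("\n".join(lines) + "\n")


def gen_geometry_fixture(case: str, out_dir: str | Path) -> dict:
    """Write one geometry fixture: ``<case>.pdb``, ``<case>.mol2`` and
    ``<case>.truth.json`` with the constructed ground-truth bits.

    The ground truth comes from the analytic construction of the
    coordinates, not from running the fingerprint code.
    """
    cases = _fixture_cases()
    if case not in cases:
        raise ValueError(f"unknown fixture case {case!r}; choose from "
                         f"{sorted(cases)}")
    spec = cases[case]
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    resname, res_atoms = spec["residue"]
    lig_name, lig_atoms, lig_bonds = spec["ligand"]
    pdb = out_dir / f"{case}.pdb"
    mol2 = out_dir / f"{case}.mol2"
    truth_path = out_dir / f"{case}.truth.json"
    _write_pdb(pdb, resname, res_atoms)
    _write_mol2(mol2, lig_name, lig_atoms, lig_bonds)
    truth = {
        "case": case,
        "residue": 100,
        "resname": resname,
        "bits": {b: v for b, v in zip(BIT_NAMES, spec["truth"])},
    }
    truth_path.write_text(json.dumps(truth, indent=2) + "\n")
    return {"pdb": pdb, "mol2": mol2, "truth": truth_path, "bits": spec["truth"]}
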