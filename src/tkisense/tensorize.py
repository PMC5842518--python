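"""Length-normalization of interaction fingerprints across indel mutants.

Multilinear PCA needs every sample to have the same shape, but mutants with
insertions or deletions have different residue counts and therefore different
fingerprint lengths.  This module builds a *master index* — the ordered union
of residue slots over a cohort — and zero-pads each mutant's frames x bits
matrix into that common coordinate system: slots for residues a mutant lacks
(its own deletions, other mutants' insertions) are filled with zeros, seven
per residue slot.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .catalog import Edit, EditKind, MutantSpec
from .ifp import N_BITS, BIT_NAMES, IFPMatrix

__all__ = ["Slot", "MasterIndex", "IFPTensor", "build_master_index", "pad_ifp",
           "stack_and_center"]


@dataclass(frozen=True, order=True)
class Slot:
    """One residue position in the master index.

    A wild-type slot has ``ins_id == ""`` and ``offset == 0``.  An insertion
    slot is keyed by its left flanking WT residue, the inserted sequence that
    owns it (so distinct insertions between the same flanks get disjoint
    blocks), and the 0-based offset within that insertion.
    """

    wt_left: int        # WT residue (WT slot) or left flank (insertion slot)
    ins_id: str = ""    # inserted sequence owning this slot, "" for WT slots
    offset: int = 0

    @property
    def is_insertion(self) -> bool:
        return bool(self.ins_id)

    def label(self) -> str:
        if not self.is_insertion:
            return str(self.wt_left)
        return f"{self.wt_left}+{self.ins_id}.{self.offset + 1}"


@dataclass
class MasterIndex:
    """Ordered residue slots shared by a cohort of mutants."""

    slots: list[Slot]
    wt_residues: list[int]

    def __len__(self) -> int:
        return len(self.slots)

    @property
    def n_columns(self) -> int:
        return N_BITS * len(self.slots)

    def column_labels(self) -> list[str]:
        return [f"{s.label()}:{b}" for s in self.slots for b in BIT_NAMES]

    def slot_range(self, after_wt: int, before_wt: int) -> slice:
        """Index range of the slots strictly between two WT residues."""
        lo = self.slots.index(Slot(after_wt)) + 1
        hi = self.slots.index(Slot(before_wt))
        return slice(lo, hi)


def _iter_insertions(spec: MutantSpec):
    """Yield (left_flank, inserted_seq) for slots a spec adds beyond WT.

    A pure insertion adds all its residues between its flanks.  A
    deletion-insertion places inserted residues in the leftmost slots of the
    deleted WT span; only an overhang (insert longer than the span) would
    need extra slots.
    """
    for e in spec.edits:
        if e.kind is EditKind.INSERTION:
            yield e.start, e.inserted
        elif e.kind is EditKind.DELETION_INSERTION:
            span = e.end - e.start + 1
            if len(e.inserted) > span:
                yield e.end, e.inserted[span:]


def build_master_index(
    specs: list[MutantSpec], wt_residues: list[int]
) -> MasterIndex:
    """Ordered union of WT residues and every insertion slot in the cohort.

    Deterministic and independent of cohort order: insertion blocks between
    the same flanking pair are ordered alphabetically by inserted sequence.
    """
    wt_residues = sorted(wt_residues)
    wt_set = set(wt_residues)
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate mutant names in cohort: {dupes}")
    for spec in specs:
        for e in spec.edits:
            for pos in (e.start, e.end):
                if pos not in wt_set:
                    raise ValueError(
                        f"{spec.name!r}: edit position {pos} not in wt_residues"
                    )
    # left flank -> sorted set of inserted sequences
    ins_at: dict[int, set[str]] = {}
    for spec in specs:
        for left, seq in _iter_insertions(spec):
            ins_at.setdefault(left, set()).add(seq)
    slots: list[Slot] = []
    for wt in wt_residues:
        slots.append(Slot(wt))
        for seq in sorted(ins_at.get(wt, ())):
            for k in range(len(seq)):
                slots.append(Slot(wt, ins_id=seq, offset=k))
    return MasterIndex(slots=slots, wt_residues=wt_residues)


def owned_slots(spec: MutantSpec, master: MasterIndex) -> list[bool]:
    """Which master slots carry this mutant's own residues (in order).

    A mutant owns every WT slot it does not delete, the slots of its own
    insertions, and — for deletion-insertions — the leftmost slots of the
    deleted span, one per inserted residue.
    """
    deleted: set[int] = set()
    delins_kept: set[int] = set()
    own_ins: set[tuple[int, str]] = {(l, s) for l, s in _iter_insertions(spec)}
    for e in spec.edits:
        if e.kind in (EditKind.DELETION, EditKind.DELETION_INSERTION):
            span = list(range(e.start, e.end + 1))
            keep = len(e.inserted) if e.kind is EditKind.DELETION_INSERTION else 0
            delins_kept.update(span[:keep])
            deleted.update(span[keep:])
    owned = []
    for slot in master.slots:
        if slot.is_insertion:
            owned.append((slot.wt_left, slot.ins_id) in own_ins)
        else:
            owned.append(slot.wt_left not in deleted or slot.wt_left in delins_kept)
    return owned


def pad_ifp(matrix: IFPMatrix, spec: MutantSpec, master: MasterIndex) -> IFPMatrix:
    """Zero-pad one mutant's IFP matrix into the master coordinate system.

    The mutant's columns are copied, in order, into the slots it owns; every
    other slot contributes seven zero columns.  Padding is information
    preserving: dropping the un-owned slots recovers the input bit-exactly.
    """
    owned = owned_slots(spec, master)
    n_own = sum(owned)
    if matrix.values.shape[1] != N_BITS * n_own:
        raise ValueError(
            f"{spec.name!r}: IFP matrix has {matrix.values.shape[1]} columns "
            f"but the spec owns {n_own} slots ({N_BITS * n_own} columns) in the "
            "master index"
        )
    out = np.zeros((matrix.values.shape[0], master.n_columns),
                   dtype=matrix.values.dtype)
    src = 0
    for j, own in enumerate(owned):
        if own:
            out[:, N_BITS * j:N_BITS * (j + 1)] = \
                matrix.values[:, N_BITS * src:N_BITS * (src + 1)]
            src += 1
    return IFPMatrix(
        values=out,
        residue_labels=[s.label() for s in master.slots],
        complex_name=matrix.complex_name,
        drug=matrix.drug,
    )


@dataclass
class IFPTensor:
    """Stacked, centered cohort tensor: samples x frames x fingerprint bits."""

    data: np.ndarray                 # (M, F, 7*R*), centered
    names: list[str]
    labels: list[str]
    mean: np.ndarray                 # (F, 7*R*) sample mean before centering
    master: MasterIndex | None = None

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


def stack_and_center(
    matrices: list[IFPMatrix],
    labels: list[str],
    master: MasterIndex | None = None,
) -> IFPTensor:
    """Stack padded per-complex matrices and subtract the sample mean.

    Samples keep the order in which they are given (catalog order for the
    real cohort), recorded in ``names`` so cross-validation folds are
    reproducible.
    """
    if len(matrices) < 2:
        raise ValueError("need at least two samples to center")
    if len(labels) != len(matrices):
        raise ValueError("one label per matrix required")
    shape = matrices[0].values.shape
    for m in matrices:
        if m.values.shape != shape:
            raise ValueError(
                f"sample {m.complex_name!r} has shape {m.values.shape}, "
                f"expected {shape}"
            )
    data = np.stack([m.values for m in matrices]).astype(float)
    mean = data.mean(axis=0)
    data -= mean
    return IFPTensor(
        data=data,
        names=[m.complex_name for m in matrices],
        labels=list(labels),
        mean=mean,
        master=master,
    )
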