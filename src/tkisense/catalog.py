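"""EGFR kinase-domain mutation catalog.

Parses the compact clinical nomenclature used for recurrent EGFR kinase-domain
variants (``delE746_A750``, ``V769_D770insASV``, ``L858R``, complex mutations
joined with ``_``) into explicit residue-level edits against wild-type
numbering (UniProt P00533), and carries the high / moderate / low
gefitinib-erlotinib sensitivity labels of the 30-mutant cohort.
"""

from __future__ import annotations

import csv
import enum
import re
import warnings
from dataclasses import dataclass, field
from importlib import resources

__all__ = [
    "KINASE_DOMAIN_START",
    "KINASE_DOMAIN_END",
    "Sensitivity",
    "EditKind",
    "Edit",
    "MutantSpec",
    "MutationParseError",
    "wt_kinase_sequence",
    "wt_residue",
    "parse_mutation_name",
    "format_mutation_name",
    "sensitivity_from_ic50",
    "load_cohort_catalog",
]

#: Modeled kinase-domain span (template 1M17, residues 696-988).
KINASE_DOMAIN_START = 696
KINASE_DOMAIN_END = 988


class Sensitivity(str, enum.Enum):
    """In vitro gefitinib/erlotinib sensitivity band."""

    HIGH = "high"
    MODERATE = "moderate"
    LOW = "low"


class EditKind(str, enum.Enum):
    SUBSTITUTION = "substitution"
    DELETION = "deletion"
    INSERTION = "insertion"
    DELETION_INSERTION = "deletion_insertion"


class MutationParseError(ValueError):
    """Raised when a mutation name does not follow the supported grammar."""


@dataclass(frozen=True)
class Edit:
    """One residue-level edit in wild-type coordinates.

    ``start``/``end`` are wild-type residue numbers.  For an insertion they
    are the flanking residues (``end == start + 1``) and ``deleted`` is empty;
    for a substitution both equal the mutated position.
    """

    kind: EditKind
    start: int
    end: int
    deleted: str = ""
    inserted: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"edit start {self.start} > end {self.end}")
        for pos in (self.start, self.end):
            if not (KINASE_DOMAIN_START <= pos <= KINASE_DOMAIN_END):
                raise MutationParseError(
                    f"residue {pos} outside modeled kinase domain "
                    f"{KINASE_DOMAIN_START}-{KINASE_DOMAIN_END}"
                )
        if self.kind is EditKind.SUBSTITUTION:
            if len(self.deleted) != 1 or len(self.inserted) != 1:
                raise ValueError("substitution must replace exactly one residue")
        if self.kind is EditKind.INSERTION:
            if self.deleted:
                raise ValueError("insertion cannot delete residues")
            if self.end != self.start + 1:
                raise ValueError("insertion flanks must be adjacent residues")


@dataclass
class MutantSpec:
    """A named EGFR variant: a list of edits plus an optional sensitivity label."""

    name: str
    edits: list[Edit] = field(default_factory=list)
    sensitivity: Sensitivity | None = None
    ic50_nM: dict[str, float] = field(default_factory=dict)
    category: str = ""

    def __post_init__(self) -> None:
        # Insertions live *between* their flanks and occupy no WT position;
        # all other edit kinds claim their start..end span exclusively.
        claimed: set[int] = set()
        for e in self.edits:
            if e.kind is EditKind.INSERTION:
                continue
            span = set(range(e.start, e.end + 1))
            if claimed & span:
                raise ValueError(f"overlapping edits in {self.name!r}")
            claimed |= span

    @property
    def is_wild_type(self) -> bool:
        return not self.edits


_SEQ_CACHE: str | None = None


def wt_kinase_sequence() -> str:
    """Wild-type EGFR kinase-domain sequence, residues 696-988."""
    global _SEQ_CACHE
    if _SEQ_CACHE is None:
        text = (
            resources.files("tkisense.data").joinpath("wt_egfr_kinase.fasta").read_text()
        )
        _SEQ_CACHE = "".join(
            line.strip() for line in text.splitlines() if not line.startswith(">")
        )
        assert len(_SEQ_CACHE) == KINASE_DOMAIN_END - KINASE_DOMAIN_START + 1
    return _SEQ_CACHE


def wt_residue(pos: int) -> str:
    """One-letter wild-type residue at UniProt position ``pos``."""
    if not (KINASE_DOMAIN_START <= pos <= KINASE_DOMAIN_END):
        raise MutationParseError(
            f"residue {pos} outside modeled kinase domain "
            f"{KINASE_DOMAIN_START}-{KINASE_DOMAIN_END}"
        )
    return wt_kinase_sequence()[pos - KINASE_DOMAIN_START]


def _wt_span(start: int, end: int) -> str:
    return "".join(wt_residue(p) for p in range(start, end + 1))


_AA = "ACDEFGHIKLMNPQRSTVWY"
_RESPOS = re.compile(rf"^([{_AA}])(\d+)$")
_RESPOS_INS = re.compile(rf"^([{_AA}])(\d+)ins([{_AA}]+)$")
_SUBST = re.compile(rf"^([{_AA}])(\d+)([{_AA}])$")


def _check_letter(name: str, pos: int, letter: str) -> None:
    actual = wt_residue(pos)
    if actual != letter:
        warnings.warn(
            f"{name!r}: residue {pos} is {actual} in the wild-type sequence, "
            f"not {letter}",
            stacklevel=3,
        )


def parse_mutation_name(name: str) -> MutantSpec:
    """Parse a mutation name into a :class:`MutantSpec`.

    Supported tokens, joined by ``_`` for complex mutations:

    - ``del<Res><Pos>_<Res><Pos>[ins<Seq>]`` — deletion / deletion-insertion
    - ``<Res><Pos>_<Res><Pos>ins<Seq>``      — insertion between flanks
    - ``<Res><Pos><Res>``                    — substitution

    An empty name denotes the wild type.  Deleted-sequence letters are taken
    from the packaged wild-type sequence; a mismatch between a named flanking
    residue and that sequence is a warning, not an error.
    """
    raw = name
    name = re.sub(r"\s+", "", name)
    if not name:
        return MutantSpec(name="")
    pieces = name.split("_")
    edits: list[Edit] = []
    i = 0
    while i < len(pieces):
        p = pieces[i]
        if p.startswith("del"):
            m1 = _RESPOS.match(p[3:])
            if m1 is None or i + 1 >= len(pieces):
                raise MutationParseError(f"unparseable token {p!r} in {raw!r}")
            nxt = pieces[i + 1]
            m2 = _RESPOS_INS.match(nxt) or _RESPOS.match(nxt)
            if m2 is None:
                raise MutationParseError(f"unparseable token {nxt!r} in {raw!r}")
            start, end = int(m1.group(2)), int(m2.group(2))
            inserted = m2.group(3) if m2.lastindex == 3 else ""
            kind = EditKind.DELETION_INSERTION if inserted else EditKind.DELETION
            edits.append(
                Edit(kind=kind, start=start, end=end,
                     deleted=_wt_span(start, end), inserted=inserted)
            )
            _check_letter(raw, start, m1.group(1))
            _check_letter(raw, end, m2.group(1))
            i += 2
            continue
        m1 = _RESPOS.match(p)
        if m1 is not None and i + 1 < len(pieces):
            m2 = _RESPOS_INS.match(pieces[i + 1])
            if m2 is not None:
                start, end = int(m1.group(2)), int(m2.group(2))
                edits.append(
                    Edit(kind=EditKind.INSERTION, start=start, end=end,
                         inserted=m2.group(3))
                )
                _check_letter(raw, start, m1.group(1))
                _check_letter(raw, end, m2.group(1))
                i += 2
                continue
        m = _SUBST.match(p)
        if m is None:
            raise MutationParseError(f"unparseable token {p!r} in {raw!r}")
        pos = int(m.group(2))
        edits.append(
            Edit(kind=EditKind.SUBSTITUTION, start=pos, end=pos,
                 deleted=m.group(1), inserted=m.group(3))
        )
        _check_letter(raw, pos, m.group(1))
        i += 1
    return MutantSpec(name=re.sub(r"\s+", "", raw), edits=edits)


def format_mutation_name(spec: MutantSpec) -> str:
    """Inverse of :func:`parse_mutation_name` (canonical, whitespace-free)."""
    tokens = []
    for e in spec.edits:
        if e.kind is EditKind.SUBSTITUTION:
            tokens.append(f"{e.deleted}{e.start}{e.inserted}")
        elif e.kind is EditKind.INSERTION:
            tokens.append(
                f"{wt_residue(e.start)}{e.start}_{wt_residue(e.end)}{e.end}ins{e.inserted}"
            )
        else:
            tok = f"del{e.deleted[0]}{e.start}_{e.deleted[-1]}{e.end}"
            if e.inserted:
                tok += f"ins{e.inserted}"
            tokens.append(tok)
    return "_".join(tokens)


def sensitivity_from_ic50(ic50_nM: float) -> Sensitivity:
    """Map an IC50 (nM) to a sensitivity band.

    Bands: < 100 nM high; 100-999 nM moderate; >= 1000 nM low.  Values in the
    formally uncovered (999, 1000) interval fall in the moderate band so the
    mapping is total with cut-offs at 100 and 1000.
    """
    ic50 = float(ic50_nM)
    if not ic50 > 0:
        raise ValueError(f"IC50 must be positive, got {ic50_nM!r}")
    if ic50 < 100:
        return Sensitivity.HIGH
    if ic50 < 1000:
        return Sensitivity.MODERATE
    return Sensitivity.LOW


def load_cohort_catalog() -> list[MutantSpec]:
    """The 30-mutant cohort with its printed sensitivity labels.

    Labels are stored, never recomputed from IC50: delE746_S752insV is labeled
    high for both drugs although its gefitinib IC50 (306 nM) alone would band
    as moderate, because exon 19 deletions respond well clinically.
    """
    text = resources.files("tkisense.data").joinpath("egfr_cohort30.csv").read_text()
    specs: list[MutantSpec] = []
    for row in csv.DictReader(text.splitlines()):
        spec = parse_mutation_name(row["name"])
        spec.sensitivity = Sensitivity(row["sensitivity"])
        spec.category = row["category"]
        for drug in ("gefitinib", "erlotinib"):
            val = row.get(f"ic50_{drug}_nM", "")
            if val:
                spec.ic50_nM[drug] = float(val)
        specs.append(spec)
    return specs
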