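"""Macromolecular structure container and file I/O.

A deliberately small hierarchy: a :class:`StructureModel` is an ordered list of
:class:`AtomRecord` objects grouped into residues and chains, with author
residue numbering preserved exactly as read.  All downstream geometry operates
on author-numbered residue ranges (inclusive on both ends), matching the way
domain boundaries are quoted in the structural literature (e.g. a β-propeller
spanning "aa 1–332").

Parsing and serialisation of PDB/mmCIF go through :mod:`gemmi`; FASTA through
:mod:`Bio.SeqIO`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import gemmi
import numpy as np

__all__ = [
    "AtomRecord",
    "DomainSelection",
    "SequenceRecord",
    "StructureModel",
    "StructureError",
    "SelectionError",
    "read_structure",
    "write_structure",
    "select_domain",
    "extract_sequence",
    "read_fasta",
    "write_fasta",
]

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


class StructureError(ValueError):
    """Raised for unparseable or empty structure files."""


class SelectionError(KeyError):
    """Raised when a domain selection resolves to no residues."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom with author numbering retained.

    ``position`` is a length-3 tuple in Å; ``is_het`` flags heteroatoms and
    waters (retained on read, excluded from polymer sequences).
    """

    element: str
    name: str
    position: tuple[float, float, float]
    residue_number: int
    residue_name: str
    chain_id: str
    insertion_code: str = ""
    is_het: bool = False

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() not in ("H", "D")

    @property
    def is_standard(self) -> bool:
        return self.residue_name in THREE_TO_ONE

    def moved_to(self, xyz: np.ndarray) -> "AtomRecord":
        return dataclasses.replace(self, position=(float(xyz[0]), float(xyz[1]), float(xyz[2])))


@dataclass(frozen=True)
class DomainSelection:
    """A named domain: one chain (or subunit name mapped to a chain) plus an
    inclusive author-numbered residue interval."""

    subunit: str
    start: int
    end: int
    domain_label: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"selection start {self.start} > end {self.end}")


@dataclass
class SequenceRecord:
    """One-letter sequence with an author-numbering offset.

    ``numbering_offset`` maps string index 0 to an author residue number, so
    index ``i`` is residue ``numbering_offset + i`` when numbering is gapless.
    Gaps in the author numbering are recorded as string indices after which a
    gap occurs.
    """

    id: str
    residues: str
    numbering_offset: int = 1
    gaps_after: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        bad = set(self.residues) - set("ACDEFGHIKLMNPQRSTVWYX")
        if bad:
            raise ValueError(f"non-amino-acid letters in sequence {self.id!r}: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)

    def author_number(self, index: int) -> int:
        """Author residue number of string index ``index`` (gapless numbering)."""
        return self.numbering_offset + index

    def index_of(self, author_number: int) -> int:
        return author_number - self.numbering_offset

    def window(self, start: int, end: int) -> str:
        """Slice by inclusive author numbers, clipped to the sequence."""
        i = max(self.index_of(start), 0)
        j = min(self.index_of(end) + 1, len(self.residues))
        return self.residues[i:j]


class StructureModel:
    """Ordered atom container with chain/residue grouping.

    Residues within a chain sort by (residue_number, insertion_code); the
    insertion-code blank sorts first, per PDB convention.
    """

    def __init__(self, atoms: Iterable[AtomRecord], id: str = "model"):
        self.id = id
        self.atoms: list[AtomRecord] = list(atoms)
        for a in self.atoms:
            if not np.all(np.isfinite(a.position)):
                raise StructureError(f"non-finite coordinates on atom {a.name} {a.chain_id}{a.residue_number}")

    # -- basic queries ----------------------------------------------------

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def chain_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id, None)
        return list(seen)

    @property
    def polymer_chain_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            if not a.is_het:
                seen.setdefault(a.chain_id, None)
        return list(seen)

    def coords(self, heavy_only: bool = True) -> np.ndarray:
        sel = [a.position for a in self.atoms if (a.is_heavy or not heavy_only)]
        return np.asarray(sel, dtype=float).reshape(-1, 3)

    def ca_coords(self, chain_id: str | None = None) -> np.ndarray:
        sel = [
            a.position
            for a in self.atoms
            if a.name == "CA" and not a.is_het and (chain_id is None or a.chain_id == chain_id)
        ]
        return np.asarray(sel, dtype=float).reshape(-1, 3)

    def residues(self, chain_id: str | None = None) -> Iterator[tuple[str, int, str, str, list[AtomRecord]]]:
        """Yield (chain_id, residue_number, insertion_code, residue_name, atoms)
        in file order, grouped."""
        key = None
        group: list[AtomRecord] = []
        for a in self.atoms:
            if chain_id is not None and a.chain_id != chain_id:
                continue
            k = (a.chain_id, a.residue_number, a.insertion_code, a.residue_name)
            if k != key:
                if group:
                    yield (*key, group)  # type: ignore[misc]
                key, group = k, []
            group.append(a)
        if group:
            yield (*key, group)  # type: ignore[misc]

    def n_residues(self, chain_id: str | None = None) -> int:
        return sum(1 for _ in self.residues(chain_id))

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """Return a copy with ``x -> R x + t`` applied to every atom."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        xyz = np.asarray([a.position for a in self.atoms], dtype=float).reshape(-1, 3)
        moved = xyz @ R.T + t
        return StructureModel(
            [a.moved_to(m) for a, m in zip(self.atoms, moved)], id=self.id
        )

    def subset(self, predicate) -> "StructureModel":
        return StructureModel([a for a in self.atoms if predicate(a)], id=self.id)


# -- structure file I/O ---------------------------------------------------


def _from_gemmi(st: gemmi.Structure, id: str) -> StructureModel:
    atoms: list[AtomRecord] = []
    if len(st) == 0:
        raise StructureError(f"empty model in {id!r}")
    model = st[0]
    for chain in model:
        for res in chain:
            is_het = res.het_flag == "H"
            for atom in res:
                atoms.append(
                    AtomRecord(
                        element=atom.element.name,
                        name=atom.name,
                        position=(atom.pos.x, atom.pos.y, atom.pos.z),
                        residue_number=res.seqid.num,
                        insertion_code=(res.seqid.icode or "").strip(),
                        residue_name=res.name,
                        chain_id=chain.name,
                        is_het=is_het,
                    )
                )
    if not atoms:
        raise StructureError(f"no atoms in {id!r}")
    return StructureModel(atoms, id=id)


def read_structure(path: str | Path, format: str = "auto") -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    Author residue numbering is preserved (mmCIF label numbering is mapped to
    author numbering by gemmi at parse time).  Heteroatoms and waters are kept
    but flagged.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format.lower()
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        elif fmt in ("mmcif", "cif"):
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        elif fmt == "auto":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Detect)
        else:
            raise ValueError(f"unknown format {format!r}")
    except (RuntimeError, ValueError) as exc:
        if isinstance(exc, ValueError) and "unknown format" in str(exc):
            raise
        raise StructureError(f"cannot parse {path.name}: {exc}") from exc
    st.setup_entities()
    return _from_gemmi(st, id=path.stem)


def to_gemmi(model: StructureModel) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = model.id
    gm = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    for cid, num, icode, rname, atoms in model.residues():
        if cid not in chains:
            chains[cid] = gemmi.Chain(cid)
        res = gemmi.Residue()
        res.name = rname
        res.seqid = gemmi.SeqId(num, icode or " ")
        res.het_flag = "H" if atoms[0].is_het else "A"
        for a in atoms:
            ga = gemmi.Atom()
            ga.name = a.name
            ga.element = gemmi.Element(a.element)
            ga.pos = gemmi.Position(*a.position)
            ga.occ = 1.0
            ga.b_iso = 0.0
            res.add_atom(ga)
        chains[cid].add_residue(res)
    for ch in chains.values():
        gm.add_chain(ch)
    st.add_model(gm)
    st.setup_entities()
    return st


def write_structure(model: StructureModel, path: str | Path) -> None:
    """Write a :class:`StructureModel` as PDB (coordinates to 10^-3 Å)."""
    st = to_gemmi(model)
    st.write_pdb(str(path))


# -- selections and sequences ---------------------------------------------


def select_domain(model: StructureModel, selection: DomainSelection) -> StructureModel:
    """Return the substructure whose author residue numbers fall inside the
    selection's inclusive range on the named chain."""
    sub = model.subset(
        lambda a: a.chain_id == selection.subunit
        and selection.start <= a.residue_number <= selection.end
    )
    if len(sub) == 0:
        raise SelectionError(
            f"selection {selection.subunit}:{selection.start}-{selection.end} "
            f"({selection.domain_label or 'unnamed'}) resolves to no residues"
        )
    return sub


def extract_sequence(model: StructureModel, chain_id: str) -> SequenceRecord:
    """One-letter sequence of a chain's polymer residues in residue-number
    order, with numbering gaps recorded.  Non-standard residues map to X."""
    entries = [
        (num, icode, rname)
        for cid, num, icode, rname, _ in model.residues(chain_id)
        if cid == chain_id and rname != "HOH"
    ]
    if not entries:
        raise SelectionError(f"no chain {chain_id!r} in model {model.id!r}")
    entries.sort(key=lambda e: (e[0], e[1]))
    letters = []
    gaps: list[int] = []
    prev_num: int | None = None
    for i, (num, icode, rname) in enumerate(entries):
        letters.append(THREE_TO_ONE.get(rname, "X"))
        if prev_num is not None and not icode and num > prev_num + 1:
            gaps.append(i - 1)
        prev_num = num
    return SequenceRecord(
        id=f"{model.id}:{chain_id}",
        residues="".join(letters),
        numbering_offset=entries[0][0],
        gaps_after=tuple(gaps),
    )


# -- FASTA ----------------------------------------------------------------


def read_fasta(path: str | Path, numbering_offset: int = 1) -> list[SequenceRecord]:
    from Bio import SeqIO

    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        offset = numbering_offset
        # an "offset=<n>" token in the description overrides the default
        for token in rec.description.split():
            if token.startswith("offset="):
                offset = int(token.split("=", 1)[1])
        records.append(SequenceRecord(id=rec.id, residues=str(rec.seq).upper(), numbering_offset=offset))
    return records


def write_fasta(records: Sequence[SequenceRecord], path: str | Path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord as BioSeqRecord

    bio = [
        BioSeqRecord(Seq(r.residues), id=r.id, description=f"offset={r.numbering_offset}")
        for r in records
    ]
    seqio_write(bio, str(path), "fasta")
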