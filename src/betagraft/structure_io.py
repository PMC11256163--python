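"""Reading, selecting and writing protein structures and sequences.

All coordinates are carried in a flat, ordered list of :class:`Atom` records
inside a :class:`Structure`.  Author residue numbering is preserved verbatim
everywhere (the HET-s prion domain runs 218-289 and every substitution
identifier such as ``K229Q`` refers to that numbering); no 0-based index ever
leaks into a public interface.

Parsing of PDB and mmCIF files is delegated to :mod:`gemmi`; FASTA output is
written with Biopython.  Hydrogens are dropped on read because geometry and
solvent-accessibility calculations downstream follow heavy-atom conventions.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import gemmi
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

__all__ = [
    "Atom",
    "Structure",
    "SequenceRecord",
    "StructureParseError",
    "UnknownFormatError",
    "EmptySelectionError",
    "read_structure",
    "select",
    "extract_sequence",
    "write_fasta",
    "write_pdb",
]


class StructureParseError(ValueError):
    """Raised when a coordinate file cannot be parsed."""


class UnknownFormatError(ValueError):
    """Raised when the structure format cannot be determined."""


class EmptySelectionError(ValueError):
    """Raised when a selection matches no atoms."""


#: three-letter -> one-letter codes for the 20 standard amino acids
AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}


@dataclass(frozen=True)
class Atom:
    """One heavy atom with author numbering preserved."""

    serial: int
    name: str
    element: str
    coord: tuple[float, float, float]
    residue_name: str
    residue_number: int
    chain_id: str
    model_id: int = 1
    insertion_code: str = ""
    occupancy: float = 1.0
    b_factor: float = 0.0


@dataclass
class Structure:
    """An ordered collection of atoms plus provenance.

    Within one (model, chain) the atoms are kept in ascending author residue
    order after normalization; iteration order is otherwise the file order.
    """

    atoms: list[Atom] = field(default_factory=list)
    id: str = ""
    source_format: str = "synthetic"  # {"pdb", "mmcif", "synthetic"}

    def __post_init__(self) -> None:
        if not self.atoms:
            return
        self._normalize()

    def _normalize(self) -> None:
        # stable sort: (model, chain-first-appearance, residue number, icode)
        chain_order: dict[tuple[int, str], int] = {}
        for a in self.atoms:
            chain_order.setdefault((a.model_id, a.chain_id), len(chain_order))
        self.atoms.sort(
            key=lambda a: (
                a.model_id,
                chain_order[(a.model_id, a.chain_id)],
                a.residue_number,
                a.insertion_code,
            )
        )

    # -- introspection helpers -------------------------------------------
    def model_ids(self) -> list[int]:
        return sorted({a.model_id for a in self.atoms})

    def chain_ids(self, model: Optional[int] = None) -> list[str]:
        if model is None:
            model = self.model_ids()[0]
        seen: dict[str, None] = {}
        for a in self.atoms:
            if a.model_id == model:
                seen.setdefault(a.chain_id)
        return list(seen)

    def residue_numbers(self, chain: str, model: Optional[int] = None) -> list[int]:
        if model is None:
            model = self.model_ids()[0]
        seen: dict[int, None] = {}
        for a in self.atoms:
            if a.model_id == model and a.chain_id == chain:
                seen.setdefault(a.residue_number)
        return list(seen)

    def atom_coords(
        self,
        chain: str,
        atom_name: str = "CA",
        model: Optional[int] = None,
    ) -> dict[int, tuple[float, float, float]]:
        """Map author residue number -> coordinate of the named atom."""
        if model is None:
            model = self.model_ids()[0]
        out: dict[int, tuple[float, float, float]] = {}
        for a in self.atoms:
            if (
                a.model_id == model
                and a.chain_id == chain
                and a.name == atom_name
                and a.residue_number not in out
            ):
                out[a.residue_number] = a.coord
        return out

    def residue_atoms(
        self, chain: str, residue_number: int, model: Optional[int] = None
    ) -> list[Atom]:
        if model is None:
            model = self.model_ids()[0]
        return [
            a
            for a in self.atoms
            if a.model_id == model
            and a.chain_id == chain
            and a.residue_number == residue_number
        ]


@dataclass(frozen=True)
class SequenceRecord:
    """A one-letter amino-acid sequence anchored to author numbering.

    ``start_number`` is the author number of the first residue, so position
    ``p`` maps to index ``p - start_number``.
    """

    id: str
    sequence: str
    start_number: int

    def __post_init__(self) -> None:
        bad = set(self.sequence) - set(AA1_TO_3) - {"X"}
        if bad:
            raise ValueError(f"non-standard letters in sequence: {sorted(bad)}")

    @property
    def end_number(self) -> int:
        return self.start_number + len(self.sequence) - 1

    def letter_at(self, position: int) -> str:
        """One-letter code at an author position (inclusive numbering)."""
        if not (self.start_number <= position <= self.end_number):
            raise IndexError(
                f"position {position} outside sequence range "
                f"{self.start_number}-{self.end_number}"
            )
        return self.sequence[position - self.start_number]


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

_PDB_EXTENSIONS = {".pdb", ".ent"}
_CIF_EXTENSIONS = {".cif", ".mmcif"}


def _detect_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".gz":
        suffix = Path(path.stem).suffix.lower()
    if suffix in _PDB_EXTENSIONS:
        return "pdb"
    if suffix in _CIF_EXTENSIONS:
        return "mmcif"
    # content sniff: mmCIF starts with data_, PDB with a record keyword
    try:
        with open(path, "r", errors="replace") as fh:
            for line in fh:
                if not line.strip():
                    continue
                if line.startswith("data_") or line.startswith("#"):
                    return "mmcif"
                if line[:6].strip() in {
                    "HEADER", "ATOM", "HETATM", "MODEL", "REMARK", "TITLE",
                    "CRYST1", "SEQRES", "EXPDTA", "COMPND",
                }:
                    return "pdb"
                break
    except OSError as exc:
        raise StructureParseError(f"cannot read {path}: {exc}") from exc
    raise UnknownFormatError(f"cannot determine structure format of {path}")


def _validate_pdb_records(path: Path) -> None:
    """Reject truncated ATOM/HETATM records instead of silently skipping them."""
    with open(path, "r", errors="replace") as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec in {"ATOM", "HETATM"} and len(line.rstrip("\n")) < 54:
                raise StructureParseError(
                    f"{path}: truncated {rec} record at line {lineno} "
                    "(coordinate fields missing)"
                )


def read_structure(path: str | os.PathLike, format: Optional[str] = None) -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure`.

    All models are returned; author residue numbers and insertion codes are
    preserved unchanged.  Hydrogen/deuterium atoms are dropped, and only the
    first alternate conformer (altloc '' or 'A') is kept.

    Parameters
    ----------
    path:
        Coordinate file.  Format is auto-detected from the extension or
        content unless ``format`` ("pdb" or "mmcif") is given.
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(p)
    fmt = format or _detect_format(p)
    if fmt not in {"pdb", "mmcif"}:
        raise UnknownFormatError(f"unsupported format {fmt!r}")
    if fmt == "pdb":
        _validate_pdb_records(p)
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(p))
        else:
            st = gemmi.read_structure(str(p), format=gemmi.CoorFormat.Mmcif)
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"cannot parse {p}: {exc}") from exc

    atoms: list[Atom] = []
    serial = 0
    for model in st:
        model_id = int(model.num)
        for chain in model:
            for residue in chain:
                for atom in residue:
                    if atom.element.is_hydrogen:
                        continue
                    if atom.altloc not in ("", "\x00", "A"):
                        continue
                    serial += 1
                    atoms.append(
                        Atom(
                            serial=serial,
                            name=atom.name,
                            element=atom.element.name,
                            coord=(atom.pos.x, atom.pos.y, atom.pos.z),
                            residue_name=residue.name,
                            residue_number=residue.seqid.num,
                            insertion_code=(residue.seqid.icode or "").strip(),
                            chain_id=chain.name,
                            model_id=model_id,
                            occupancy=atom.occ,
                            b_factor=atom.b_iso,
                        )
                    )
    if not atoms:
        raise StructureParseError(f"{p}: no heavy atoms found")
    return Structure(atoms=atoms, id=p.stem, source_format=fmt)


# ---------------------------------------------------------------------------
# selection
# ---------------------------------------------------------------------------

def select(
    structure: Structure,
    model: Optional[int] = None,
    chains: Optional[Iterable[str]] = None,
    residue_range: Optional[tuple[int, int]] = None,
) -> Structure:
    """Filter a structure by model, chains and an inclusive author-number range.

    Both residue bounds are inclusive, in author numbering.
    """
    if model is not None and model not in structure.model_ids():
        raise EmptySelectionError(
            f"model {model} not present (have {structure.model_ids()})"
        )
    if chains is not None:
        chains = set(chains)
        have = set()
        for m in structure.model_ids():
            have.update(structure.chain_ids(m))
        missing = chains - have
        if missing:
            raise EmptySelectionError(
                f"chain(s) {sorted(missing)} not present (have {sorted(have)})"
            )
    lo, hi = (None, None) if residue_range is None else residue_range
    kept = [
        a
        for a in structure.atoms
        if (model is None or a.model_id == model)
        and (chains is None or a.chain_id in chains)
        and (lo is None or lo <= a.residue_number <= hi)
    ]
    if not kept:
        raise EmptySelectionError(
            f"selection (model={model}, chains={chains}, "
            f"residue_range={residue_range}) matched no atoms"
        )
    return Structure(atoms=kept, id=structure.id, source_format=structure.source_format)


def first_model(structure: Structure) -> Structure:
    """Convenience: restrict a (possibly multi-model NMR) structure to model 1.

    NMR ensembles deposit many models of one fold; downstream geometry treats
    a single conformer, so the first model is the default working copy.
    """
    return select(structure, model=structure.model_ids()[0])


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------

def extract_sequence(structure: Structure, chain: str) -> SequenceRecord:
    """Extract the one-letter sequence of a chain, anchored to author numbering.

    Requires a single-model structure (use :func:`select` or
    :func:`first_model` on NMR ensembles first).  Non-standard residues that
    are still amino acids (e.g. MSE) map to ``'X'``; waters and ligands are
    skipped entirely.
    """
    models = structure.model_ids()
    if len(models) != 1:
        raise ValueError(
            f"structure has {len(models)} models; select one before "
            "extracting a sequence"
        )
    if chain not in structure.chain_ids(models[0]):
        raise EmptySelectionError(f"chain {chain!r} not present")

    letters: list[str] = []
    numbers: list[int] = []
    seen: set[tuple[int, str]] = set()
    for a in structure.atoms:
        if a.chain_id != chain:
            continue
        key = (a.residue_number, a.insertion_code)
        if key in seen:
            continue
        seen.add(key)
        one = AA3_TO_1.get(a.residue_name)
        if one is None:
            info = gemmi.find_tabulated_residue(a.residue_name)
            if info is not None and info.is_amino_acid():
                one = "X"
            else:
                continue  # water / ligand
        letters.append(one)
        numbers.append(a.residue_number)
    if not letters:
        raise ValueError(f"chain {chain!r} contains no amino-acid residues")
    return SequenceRecord(
        id=f"{structure.id}_{chain}" if structure.id else chain,
        sequence="".join(letters),
        start_number=numbers[0],
    )


def write_fasta(records: Sequence[SequenceRecord], path: str | os.PathLike) -> None:
    """Write sequence records as standard FASTA (60-character line wrap)."""
    if not records:
        raise ValueError("no records to write")
    bio_records = []
    for rec in records:
        if not rec.sequence:
            raise ValueError(f"record {rec.id!r} has an empty sequence")
        bio_records.append(
            _BioSeqRecord(
                Seq(rec.sequence),
                id=rec.id,
                description=f"start={rec.start_number}",
            )
        )
    with open(path, "w") as fh:
        SeqIO.write(bio_records, fh, "fasta")


def read_fasta(path: str | os.PathLike) -> list[SequenceRecord]:
    """Read FASTA back into records; honors the ``start=N`` description tag."""
    out: list[SequenceRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        start = 1
        for token in rec.description.split():
            if token.startswith("start="):
                start = int(token[len("start="):])
        out.append(SequenceRecord(id=rec.id, sequence=str(rec.seq), start_number=start))
    return out


# ---------------------------------------------------------------------------
# writing coordinates
# ---------------------------------------------------------------------------

def _to_gemmi(structure: Structure) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = structure.id or "betagraft"
    for model_id in structure.model_ids():
        model = gemmi.Model(model_id)
        for chain_id in structure.chain_ids(model_id):
            chain = gemmi.Chain(chain_id)
            # group atoms into residues first: gemmi copies on add_residue
            groups: list[tuple[tuple[int, str, str], list[Atom]]] = []
            for a in structure.atoms:
                if a.model_id != model_id or a.chain_id != chain_id:
                    continue
                key = (a.residue_number, a.insertion_code, a.residue_name)
                if not groups or groups[-1][0] != key:
                    groups.append((key, []))
                groups[-1][1].append(a)
            for (num, icode, name), group_atoms in groups:
                residue = gemmi.Residue()
                residue.name = name
                residue.seqid = gemmi.SeqId(num, icode or " ")
                for a in group_atoms:
                    atom = gemmi.Atom()
                    atom.name = a.name
                    atom.element = gemmi.Element(a.element)
                    atom.pos = gemmi.Position(*a.coord)
                    atom.occ = a.occupancy
                    atom.b_iso = a.b_factor
                    residue.add_atom(atom)
                chain.add_residue(residue)
            model.add_chain(chain)
        st.add_model(model)
    st.setup_entities()
    return st


def write_pdb(structure: Structure, path: str | os.PathLike) -> None:
    """Write a structure as a PDB file (via gemmi)."""
    _to_gemmi(structure).write_pdb(str(path))


def write_mmcif(structure: Structure, path: str | os.PathLike) -> None:
    """Write a structure as mmCIF (via gemmi)."""
    st = _to_gemmi(structure)
    st.make_mmcif_document().write_file(str(path))
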