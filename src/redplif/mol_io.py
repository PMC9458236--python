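"""Readers for the structure and table formats a docking post-processing run touches.

Supported inputs: PDB (``ATOM``/``HETATM``), AutoDock PDBQT (single receptor
or ligand files, and multi-model docking output with ``REMARK VINA RESULT``
score lines), Tripos MOL2, and plain-text SMILES-with-name activity lists.
Everything is normalized into a small internal model (:class:`Atom`,
:class:`Molecule`, :class:`PoseSet`) that the perception and fingerprint
layers consume.

All parsers preserve file order and never renumber atoms or residues.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Atom",
    "Molecule",
    "PoseSet",
    "ParseError",
    "STANDARD_AMINO_ACIDS",
    "read_pdb",
    "read_pdbqt",
    "read_vina_poses",
    "read_mol2",
    "read_label_list",
]


class ParseError(ValueError):
    """Raised when a structure or table file cannot be parsed."""


#: Three-letter codes of the 20 canonical amino acids.
STANDARD_AMINO_ACIDS = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

# Heavy backbone atoms plus the hydrogens attached to N/CA. Used to flag
# main-chain atoms so the side-chain-only ("nobb") mode can drop them.
_BACKBONE_NAMES = frozenset(
    ["N", "CA", "C", "O", "OXT", "H", "H1", "H2", "H3", "HN", "HA", "HA2", "HA3", "HXT"]
)


@dataclass
class Atom:
    """One atom with its residue context.

    ``partial_charge`` is in elementary charges and 0.0 when the source
    format carries no charge column.  ``is_backbone`` is only ever true for
    atoms of standard amino-acid residues read from ATOM records.
    """

    serial: int
    name: str
    element: str
    coords: np.ndarray
    partial_charge: float = 0.0
    residue_name: str = ""
    residue_number: int = 0
    chain: str = ""
    insertion_code: str = ""
    is_backbone: bool = False
    atom_type: str = ""  # AD or SYBYL type annotation, format dependent

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.serial} ({self.name}): coords must be a finite 3-vector")

    @property
    def residue_key(self) -> tuple[str, int, str]:
        """Identity of the parent residue: (chain, number, insertion code)."""
        return (self.chain, self.residue_number, self.insertion_code)

    @property
    def is_heavy(self) -> bool:
        return self.element != "H"


@dataclass
class Molecule:
    """An ordered collection of atoms with optional bonds.

    Bond entries are ``(i, j, order)`` with 0-based atom indices; order is a
    float so aromatic (1.5) and amide (treated as 1) bonds round-trip from
    MOL2.  Atom order is file order.
    """

    atoms: list[Atom] = field(default_factory=list)
    bonds: list[tuple[int, int, float]] = field(default_factory=list)
    name: str = ""

    def __post_init__(self) -> None:
        n = len(self.atoms)
        for i, j, _ in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond ({i},{j}) endpoint out of range for {n} atoms")

    def __len__(self) -> int:
        return len(self.atoms)

    def coords(self) -> np.ndarray:
        """(n, 3) array of coordinates in file order."""
        return np.array([a.coords for a in self.atoms], dtype=float)

    def residues(self) -> dict[tuple[str, int, str], list[int]]:
        """Atom indices grouped by residue key, in order of first appearance."""
        out: dict[tuple[str, int, str], list[int]] = {}
        for i, a in enumerate(self.atoms):
            out.setdefault(a.residue_key, []).append(i)
        return out


@dataclass
class PoseSet:
    """The poses ("modes") of one docking run, with their scores in kcal/mol.

    Scores are kept in file order, which for docking output is rank order;
    the reader itself asserts nothing about ordering.
    """

    poses: list[Molecule]
    scores: list[float]
    source_tag: str = ""

    def __post_init__(self) -> None:
        if len(self.poses) != len(self.scores):
            raise ValueError("one score per pose required")

    def __len__(self) -> int:
        return len(self.poses)


def _guess_element(atom_name: str, resname: str = "") -> str:
    """Element from a PDB-style atom name (no element column available)."""
    stripped = atom_name.strip()
    if not stripped:
        return "X"
    # Two-letter elements that actually occur in protein/ligand files.
    two = stripped[:2].upper()
    if two in {"CL", "BR", "FE", "ZN", "MG", "MN", "SE", "NA"} and resname not in STANDARD_AMINO_ACIDS:
        return two.capitalize()
    first = stripped[0]
    if first.isdigit():  # names like 1HB
        return stripped[1].upper()
    return first.upper()


def _parse_pdb_atom_line(line: str, lineno: int, with_charge: bool) -> Atom:
    """Parse one ATOM/HETATM record (PDB fixed columns; PDBQT adds charge+type)."""
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        altloc = line[16:17].strip()
        resname = line[17:20].strip()
        chain = line[21:22].strip()
        resnum = int(line[22:26])
        icode = line[26:27].strip()
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except (ValueError, IndexError) as exc:
        raise ParseError(f"line {lineno}: malformed ATOM/HETATM record: {exc}") from exc

    charge = 0.0
    ad_type = ""
    if with_charge:
        # PDBQT: after occupancy/b-factor come the partial charge and the
        # AutoDock atom type; tokenize the tail to tolerate column drift.
        tail = line[54:].split()
        if len(tail) < 4:
            raise ParseError(f"line {lineno}: PDBQT record missing charge/type columns")
        try:
            charge = float(tail[-2])
        except ValueError as exc:
            raise ParseError(f"line {lineno}: bad partial charge {tail[-2]!r}") from exc
        ad_type = tail[-1]

    is_polymer = line.startswith("ATOM") and resname in STANDARD_AMINO_ACIDS
    element = _guess_element(name, resname)
    atom = Atom(
        serial=serial,
        name=name,
        element=element,
        coords=np.array([x, y, z]),
        partial_charge=charge,
        residue_name=resname,
        residue_number=resnum,
        chain=chain,
        insertion_code=icode,
        is_backbone=is_polymer and name in _BACKBONE_NAMES,
        atom_type=ad_type,
    )
    atom._altloc = altloc  # transient, used for first-altloc filtering
    return atom


def _read_pdb_like(lines: list[str], name: str, with_charge: bool) -> Molecule:
    atoms: list[Atom] = []
    seen_altloc: set[tuple[tuple[str, int, str], str]] = set()
    dropped = 0
    for lineno, line in enumerate(lines, start=1):
        rec = line[:6].strip()
        if rec not in ("ATOM", "HETATM"):
            continue  # ROOT/BRANCH/TORSDOF/REMARK/TER etc. are tolerated
        atom = _parse_pdb_atom_line(line, lineno, with_charge)
        altloc = atom._altloc
        if altloc:
            key = (atom.residue_key, atom.name)
            if key in seen_altloc:
                dropped += 1
                continue
            seen_altloc.add(key)
        del atom._altloc
        atoms.append(atom)
    if dropped:
        logger.warning("%s: kept first altloc only; dropped %d alternate-location atoms", name, dropped)
    if not atoms:
        raise ParseError(f"{name}: no ATOM/HETATM records found")
    return Molecule(atoms=atoms, name=name)


def read_pdb(path: str | Path) -> Molecule:
    """Read a PDB file into a :class:`Molecule`.

    One atom per ATOM/HETATM record, in file order.  Backbone flags are set
    from atom names for standard amino-acid residues; HETATM atoms are never
    flagged as backbone.  Alternate locations keep the first altloc (warned).
    """
    path = Path(path)
    return _read_pdb_like(path.read_text().splitlines(), path.name, with_charge=False)


def read_pdbqt(path: str | Path) -> Molecule:
    """Read an AutoDock PDBQT file (receptor or ligand, single structure).

    Partial charges come from the PDBQT charge column and the AutoDock atom
    type is kept as ``Atom.atom_type``.  Flexibility-tree records
    (ROOT/BRANCH/TORSDOF) are skipped.
    """
    path = Path(path)
    return _read_pdb_like(path.read_text().splitlines(), path.name, with_charge=True)


def read_vina_poses(path: str | Path, source_tag: str = "") -> PoseSet:
    """Read a multi-model PDBQT docking-output file into a :class:`PoseSet`.

    Each MODEL block must contain a ``REMARK VINA RESULT: <affinity> ...``
    line; the affinity (kcal/mol) becomes the pose score.  Poses are returned
    in file order.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    poses: list[Molecule] = []
    scores: list[float] = []
    block: list[str] | None = None
    score: float | None = None
    model_no = 0
    for lineno, line in enumerate(lines, start=1):
        if line.startswith("MODEL"):
            if block is not None:
                raise ParseError(f"{path.name} line {lineno}: nested MODEL")
            model_no += 1
            block, score = [], None
        elif line.startswith("ENDMDL"):
            if block is None:
                raise ParseError(f"{path.name} line {lineno}: ENDMDL without MODEL")
            if score is None:
                raise ParseError(f"{path.name}: MODEL {model_no} has no 'REMARK VINA RESULT' line")
            pose = _read_pdb_like(block, f"{path.stem}:mode{model_no}", with_charge=True)
            poses.append(pose)
            scores.append(score)
            block = None
        elif block is not None:
            if line.startswith("REMARK VINA RESULT:"):
                fields = line.split(":", 1)[1].split()
                try:
                    score = float(fields[0])
                except (IndexError, ValueError) as exc:
                    raise ParseError(f"{path.name} line {lineno}: bad VINA RESULT line") from exc
            else:
                block.append(line)
    if block is not None:
        raise ParseError(f"{path.name}: MODEL without closing ENDMDL")
    if not poses:
        raise ParseError(f"{path.name}: no MODEL blocks found")
    return PoseSet(poses=poses, scores=scores, source_tag=source_tag or path.stem)


_MOL2_BOND_ORDERS = {"1": 1.0, "2": 2.0, "3": 3.0, "am": 1.0, "ar": 1.5, "du": 1.0, "un": 1.0, "nc": 0.0}


def read_mol2(path: str | Path) -> Molecule:
    """Read a Tripos MOL2 file.

    Bonds are populated from the ``@<TRIPOS>BOND`` section when present
    (aromatic order stored as 1.5); SYBYL atom types are kept as
    ``Atom.atom_type``, and per-atom charges are read when the ATOM records
    carry them.
    """
    path = Path(path)
    section = ""
    mol_name = path.stem
    atoms: list[Atom] = []
    bonds: list[tuple[int, int, float]] = []
    mol_lines = 0
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if line.startswith("@<TRIPOS>"):
            section = line[9:].upper()
            mol_lines = 0
            continue
        if not line or line.startswith("#"):
            continue
        if section == "MOLECULE":
            mol_lines += 1
            if mol_lines == 1:
                mol_name = line
        elif section == "ATOM":
            fields = line.split()
            if len(fields) < 6:
                raise ParseError(f"{path.name} line {lineno}: truncated ATOM line")
            try:
                serial = int(fields[0])
                x, y, z = (float(v) for v in fields[2:5])
            except ValueError as exc:
                raise ParseError(f"{path.name} line {lineno}: bad ATOM line: {exc}") from exc
            sybyl = fields[5]
            element = sybyl.split(".")[0].capitalize()
            resnum = int(fields[6]) if len(fields) > 6 else 0
            subst = fields[7] if len(fields) > 7 else ""
            charge = float(fields[8]) if len(fields) > 8 else 0.0
            # substructure names look like "LIG1" / "ALA42" / "<0>"
            resname = subst.rstrip("0123456789") if subst else ""
            atoms.append(
                Atom(
                    serial=serial,
                    name=fields[1],
                    element=element,
                    coords=np.array([x, y, z]),
                    partial_charge=charge,
                    residue_name=resname,
                    residue_number=resnum,
                    atom_type=sybyl,
                )
            )
        elif section == "BOND":
            fields = line.split()
            if len(fields) < 4:
                raise ParseError(f"{path.name} line {lineno}: truncated BOND line")
            i, j = int(fields[1]) - 1, int(fields[2]) - 1
            order = _MOL2_BOND_ORDERS.get(fields[3].lower())
            if order is None:
                raise ParseError(f"{path.name} line {lineno}: unknown bond order {fields[3]!r}")
            bonds.append((i, j, order))
    if not atoms:
        raise ParseError(f"{path.name}: no @<TRIPOS>ATOM section with atoms")
    return Molecule(atoms=atoms, bonds=bonds, name=mol_name)


def read_label_list(
    path: str | Path,
    label: int,
    *,
    name_column: int = 1,
    auto_name: bool = False,
) -> dict[str, int]:
    """Read a SMILES-with-name activity list (".ism" style) into name -> label.

    The first whitespace-separated token of each line is a SMILES string,
    carried as opaque text and never interpreted chemically; the token at
    ``name_column`` (default: first token after the SMILES) is the compound
    name.  ``label`` is assigned to every compound in the file (1 for an
    actives file, 0 for a decoys file).  With ``auto_name`` a nameless line
    gets ``line<N>``.
    """
    path = Path(path)
    mapping: dict[str, int] = {}
    duplicates: list[str] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        tokens = line.split()
        if len(tokens) <= name_column:
            if auto_name:
                name = f"line{lineno}"
            else:
                raise ParseError(f"{path.name} line {lineno}: no name column")
        else:
            name = tokens[name_column]
        if name in mapping:
            duplicates.append(name)
        mapping[name] = label
    if duplicates:
        raise ParseError(f"{path.name}: duplicate compound names: {sorted(set(duplicates))}")
    return mapping
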