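"""Chemical feature perception for interaction detection.

Protein residues are perceived from hand-curated templates over the 20
canonical amino acids (PDB atom naming); ligands are perceived rule-driven
from geometry, bonds and partial charges, because docking-output PDBQT
carries no bond records.

Conventions (fixed here, configurable nowhere — they define the fingerprint
semantics):

* His is neutral by default: acceptor on the unprotonated ring nitrogen,
  donor on the protonated one, inferred from which ring hydrogens (HD1/HE2)
  are present; cationic only when both are present.  Asp/Glu are always
  anionic, Lys/Arg always cationic (physiological-pH preparation).
* Halogens count as apolar contact partners, not as acceptors.
* Apolar atoms are C/S with no O/N neighbor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np

from .mol_io import Atom, Molecule

__all__ = [
    "ResidueFeatures",
    "LigandFeatures",
    "PerceptionError",
    "perceive_residue",
    "perceive_ligand",
    "ring_plane",
    "RESIDUE_TEMPLATES",
]


class PerceptionError(ValueError):
    """Raised when a molecule or residue cannot be chemically perceived."""


@dataclass
class Ring:
    """An aromatic ring: member atom indices, centroid and unit plane normal."""

    atom_indices: tuple[int, ...]
    centroid: np.ndarray
    normal: np.ndarray


@dataclass
class Features:
    """Interaction-relevant feature sets, indices into the parent molecule."""

    apolar_atoms: set[int] = field(default_factory=set)
    aromatic_rings: list[Ring] = field(default_factory=list)
    donors: list[tuple[int, tuple[int, ...]]] = field(default_factory=list)  # (heavy, H atoms)
    acceptors: set[int] = field(default_factory=set)
    cation_groups: list[set[int]] = field(default_factory=list)
    anion_groups: list[set[int]] = field(default_factory=list)


@dataclass
class ResidueFeatures(Features):
    side_chain_atoms: set[int] = field(default_factory=set)
    residue_name: str = ""


class LigandFeatures(Features):
    pass


def ring_plane(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares plane through ≥3 points: (centroid, unit normal).

    The normal's sign is arbitrary; consumers must use absolute angles.
    Raises :class:`PerceptionError` for collinear input.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.shape[0] < 3:
        raise PerceptionError("ring plane needs at least 3 atoms")
    centroid = coords.mean(axis=0)
    centered = coords - centroid
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] < 1e-8 * max(s[0], 1e-12):
        raise PerceptionError("ring atoms are collinear; no unique plane")
    return centroid, vt[2]


# ---------------------------------------------------------------------------
# Protein residue templates
# ---------------------------------------------------------------------------
# Per residue: aromatic ring atom names, donor heavy atoms with their polar-H
# names, acceptor atoms, cation/anion groups, and apolar side-chain atoms
# (side-chain C/S with no O/N neighbor in the residue's covalent template).

_T = dict  # readability alias

RESIDUE_TEMPLATES: dict[str, dict] = {
    "ALA": _T(apolar=["CB"]),
    "ARG": _T(
        apolar=["CB", "CG"],
        donors=[("NE", ["HE"]), ("NH1", ["HH11", "HH12"]), ("NH2", ["HH21", "HH22"])],
        cations=[["NE", "CZ", "NH1", "NH2"]],
    ),
    "ASN": _T(apolar=["CB"], donors=[("ND2", ["HD21", "HD22"])], acceptors=["OD1"]),
    "ASP": _T(apolar=["CB"], acceptors=["OD1", "OD2"], anions=[["OD1", "OD2"]]),
    "CYS": _T(apolar=["CB", "SG"]),
    "GLN": _T(apolar=["CB", "CG"], donors=[("NE2", ["HE21", "HE22"])], acceptors=["OE1"]),
    "GLU": _T(apolar=["CB", "CG"], acceptors=["OE1", "OE2"], anions=[["OE1", "OE2"]]),
    "GLY": _T(),
    "HIS": _T(apolar=["CB"], rings=[["CG", "ND1", "CD2", "CE1", "NE2"]]),  # N roles set at runtime
    "ILE": _T(apolar=["CB", "CG1", "CG2", "CD1"]),
    "LEU": _T(apolar=["CB", "CG", "CD1", "CD2"]),
    "LYS": _T(apolar=["CB", "CG", "CD"], donors=[("NZ", ["HZ1", "HZ2", "HZ3"])], cations=[["NZ"]]),
    "MET": _T(apolar=["CB", "CG", "SD", "CE"]),
    "PHE": _T(
        apolar=["CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
        rings=[["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]],
    ),
    "PRO": _T(apolar=["CB", "CG"]),
    "SER": _T(donors=[("OG", ["HG"])], acceptors=["OG"]),
    "THR": _T(apolar=["CG2"], donors=[("OG1", ["HG1"])], acceptors=["OG1"]),
    "TRP": _T(
        apolar=["CB", "CG", "CD2", "CE3", "CZ3", "CH2", "CZ2"],
        donors=[("NE1", ["HE1"])],
        rings=[["CG", "CD1", "NE1", "CE2", "CD2"], ["CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3"]],
    ),
    "TYR": _T(
        apolar=["CB", "CG", "CD1", "CD2", "CE1", "CE2"],
        donors=[("OH", ["HH"])],
        acceptors=["OH"],
        rings=[["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]],
    ),
    "VAL": _T(apolar=["CB", "CG1", "CG2"]),
}


def perceive_residue(molecule: Molecule, atom_indices: Sequence[int]) -> ResidueFeatures:
    """Perceive one standard amino-acid residue by template lookup.

    ``atom_indices`` are the residue's atom indices into ``molecule`` (e.g.
    one entry of :meth:`Molecule.residues`); returned index sets refer to the
    same molecule.  Unknown residue names raise (no silent skip).
    """
    atoms = {i: molecule.atoms[i] for i in atom_indices}
    if not atoms:
        raise PerceptionError("empty residue")
    resname = next(iter(atoms.values())).residue_name
    template = RESIDUE_TEMPLATES.get(resname)
    if template is None:
        raise PerceptionError(f"unknown residue name {resname!r}: no perception template")

    by_name = {a.name: i for i, a in atoms.items()}
    feats = ResidueFeatures(residue_name=resname)
    feats.side_chain_atoms = {i for i, a in atoms.items() if not a.is_backbone}

    feats.apolar_atoms = {by_name[n] for n in template.get("apolar", []) if n in by_name}
    for names in template.get("rings", []):
        idx = [by_name[n] for n in names if n in by_name]
        if len(idx) == len(names):
            centroid, normal = ring_plane(np.array([atoms[i].coords for i in idx]))
            feats.aromatic_rings.append(Ring(tuple(idx), centroid, normal))
    for heavy, hnames in template.get("donors", []):
        if heavy in by_name:
            hs = tuple(by_name[h] for h in hnames if h in by_name)
            feats.donors.append((by_name[heavy], hs))
    feats.acceptors = {by_name[n] for n in template.get("acceptors", []) if n in by_name}
    for names in template.get("cations", []):
        grp = {by_name[n] for n in names if n in by_name}
        if grp:
            feats.cation_groups.append(grp)
    for names in template.get("anions", []):
        grp = {by_name[n] for n in names if n in by_name}
        if grp:
            feats.anion_groups.append(grp)

    if resname == "HIS":
        _assign_histidine_nitrogens(feats, by_name)

    # Main-chain polar atoms participate too (dropped again by the
    # side-chain-only mode): the carbonyl O accepts, the amide N donates.
    for oname in ("O", "OXT"):
        if oname in by_name:
            feats.acceptors.add(by_name[oname])
    if "N" in by_name and resname != "PRO":
        hs = tuple(by_name[h] for h in ("H", "HN", "H1", "H2", "H3") if h in by_name)
        feats.donors.append((by_name["N"], hs))
    return feats


def _assign_histidine_nitrogens(feats: ResidueFeatures, by_name: dict[str, int]) -> None:
    """Donor/acceptor/cation roles of the imidazole nitrogens.

    Protonation is read from the hydrogens present in the atom records:
    both ring N protonated -> cationic; one protonated -> that N donates,
    the other accepts; none recorded -> assume the common NE2-protonated
    tautomer (donor without explicit H; the angle test then degrades to
    distance-only downstream).
    """
    has_hd1, has_he2 = "HD1" in by_name, "HE2" in by_name
    nd1, ne2 = by_name.get("ND1"), by_name.get("NE2")
    if nd1 is None or ne2 is None:
        return
    if has_hd1 and has_he2:
        feats.cation_groups.append({nd1, ne2})
        feats.donors.append((nd1, (by_name["HD1"],)))
        feats.donors.append((ne2, (by_name["HE2"],)))
        return
    if has_hd1:
        donor, acceptor, h = nd1, ne2, (by_name["HD1"],)
    elif has_he2:
        donor, acceptor, h = ne2, nd1, (by_name["HE2"],)
    else:
        donor, acceptor, h = ne2, nd1, ()
    feats.donors.append((donor, h))
    feats.acceptors.add(acceptor)


# ---------------------------------------------------------------------------
# Ligand perception
# ---------------------------------------------------------------------------

# Covalent radii (Å) for distance-based bond inference (PDBQT has no bonds).
_COVALENT_RADII = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "S": 1.05, "P": 1.07,
    "F": 0.57, "Cl": 1.02, "Br": 1.20, "I": 1.39, "B": 0.84, "Se": 1.20,
}
_BOND_TOLERANCE = 0.45  # Å added to the radius sum
_HALOGENS = {"F", "Cl", "Br", "I"}
_CHARGE_CATION = 0.30  # e; formal-charge proxy on PDBQT partial charges
_CHARGE_ANION = -0.30
_AROMATIC_PLANARITY_DEG = 7.5  # mean out-of-plane tolerance


def infer_bonds(molecule: Molecule) -> list[tuple[int, int, float]]:
    """Bond inference by the covalent-radius criterion d <= r_i + r_j + 0.45 Å."""
    coords = molecule.coords()
    n = len(molecule)
    radii = np.array([_COVALENT_RADII.get(a.element, 0.77) for a in molecule.atoms])
    bonds: list[tuple[int, int, float]] = []
    for i in range(n):
        d = np.linalg.norm(coords[i + 1:] - coords[i], axis=1)
        cut = radii[i] + radii[i + 1:] + _BOND_TOLERANCE
        for off in np.nonzero((d <= cut) & (d > 1e-6))[0]:
            bonds.append((i, i + 1 + int(off), 1.0))
    return bonds


def perceive_ligand(molecule: Molecule) -> LigandFeatures:
    """Perceive interaction features of a ligand.

    Bonds are taken from the molecule when present (MOL2) and otherwise
    inferred geometrically (PDBQT).  Rules:

    * rings from a minimum cycle basis; aromatic if 5–6 members, all
      C/N/O/S, planar within 7.5° mean out-of-plane deviation, each member
      with ≤3 heavy neighbors;
    * donors: N/O with ≥1 bound H; acceptors: N/O not positively charged;
    * cations: N with 4 heavy/H neighbors or charge ≥ +0.30 e;
      anions: carboxylate/phosphate/sulfate O pairs, or O with
      charge ≤ −0.30 e;
    * apolar: C/S bonded only to C/S/H, plus halogens.

    Disconnected fragments are allowed; an empty molecule raises.
    """
    if len(molecule) == 0:
        raise PerceptionError("cannot perceive an empty molecule")
    bonds = molecule.bonds if molecule.bonds else infer_bonds(molecule)
    graph = nx.Graph()
    graph.add_nodes_from(range(len(molecule)))
    graph.add_edges_from((i, j) for i, j, _ in bonds)
    atoms = molecule.atoms

    def heavy_neighbors(i: int) -> list[int]:
        return [j for j in graph.neighbors(i) if atoms[j].element != "H"]

    def h_neighbors(i: int) -> list[int]:
        return [j for j in graph.neighbors(i) if atoms[j].element == "H"]

    feats = LigandFeatures()

    # rings
    for cycle in nx.minimum_cycle_basis(graph):
        if not (5 <= len(cycle) <= 6):
            continue
        if any(atoms[i].element not in {"C", "N", "O", "S"} for i in cycle):
            continue
        if any(len(heavy_neighbors(i)) > 3 for i in cycle):
            continue
        coords = np.array([atoms[i].coords for i in cycle])
        try:
            centroid, normal = ring_plane(coords)
        except PerceptionError:
            continue
        vecs = coords - centroid
        out_of_plane = np.abs(vecs @ normal) / np.maximum(np.linalg.norm(vecs, axis=1), 1e-9)
        mean_dev_deg = math.degrees(float(np.mean(np.arcsin(np.clip(out_of_plane, 0, 1)))))
        if mean_dev_deg <= _AROMATIC_PLANARITY_DEG:
            order = _ring_path_order(graph, cycle)
            feats.aromatic_rings.append(Ring(tuple(order), centroid, normal))

    anion_atoms: set[int] = set()
    # charged groups
    for i, a in enumerate(atoms):
        if a.element == "N" and (len(list(graph.neighbors(i))) == 4 or a.partial_charge >= _CHARGE_CATION):
            feats.cation_groups.append({i})
    # oxyanion O pairs on a common C/P/S center
    for i, a in enumerate(atoms):
        if a.element not in {"C", "P", "S"}:
            continue
        terminal_o = [
            j for j in heavy_neighbors(i)
            if atoms[j].element == "O" and heavy_neighbors(j) == [i] and not h_neighbors(j)
        ]
        if len(terminal_o) >= 2:
            feats.anion_groups.append(set(terminal_o))
            anion_atoms.update(terminal_o)
    for i, a in enumerate(atoms):
        if a.element == "O" and a.partial_charge <= _CHARGE_ANION and i not in anion_atoms:
            feats.anion_groups.append({i})
            anion_atoms.add(i)

    cation_atoms = set().union(*feats.cation_groups) if feats.cation_groups else set()

    for i, a in enumerate(atoms):
        if a.element in {"N", "O"}:
            hs = tuple(h_neighbors(i))
            if hs:
                feats.donors.append((i, hs))
            if i not in cation_atoms and a.partial_charge < _CHARGE_CATION:
                feats.acceptors.add(i)
        elif a.element in _HALOGENS:
            feats.apolar_atoms.add(i)
        elif a.element in {"C", "S"}:
            if all(atoms[j].element in {"C", "S", "H"} or atoms[j].element in _HALOGENS
                   for j in graph.neighbors(i)):
                feats.apolar_atoms.add(i)
    return feats


def _ring_path_order(graph: nx.Graph, cycle: list[int]) -> list[int]:
    """Order cycle-basis members along the ring (cycle_basis order is arbitrary)."""
    sub = graph.subgraph(cycle)
    start = cycle[0]
    order = [start]
    prev = None
    while len(order) < len(cycle):
        nxt = [n for n in sub.neighbors(order[-1]) if n != prev and n not in order]
        if not nxt:
            return cycle  # fused/bridged; fall back to basis order
        prev = order[-1]
        order.append(nxt[0])
    return order
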