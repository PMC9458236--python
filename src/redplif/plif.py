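"""Per-residue protein–ligand interaction fingerprints (PLIF).

Each binding-site residue contributes a block of 7 bits, one per interaction
type, over a fixed ordered residue list; the full fingerprint of one
receptor/pose pair is the concatenation of the blocks.  Bit numbering is
1-based everywhere user-facing, so descriptor ``N`` of the downstream
ensemble table is exactly bit ``N`` here.

The per-block type order is fixed and must not be changed — the descriptor
numbering of any published analysis depends on it:

====  ==========================  ==============================
bit   label                       meaning
====  ==========================  ==============================
1     apolar                      hydrophobic contact
2     aromatic_face_to_face       ring stacking, parallel planes
3     aromatic_edge_to_face       ring stacking, tilted planes
4     hbond_protein_donor         H-bond, residue donates
5     hbond_protein_acceptor      H-bond, residue accepts
6     ionic_protein_cation        ionic, residue is the cation
7     ionic_protein_anion         ionic, residue is the anion
====  ==========================  ==============================

The ``nobb`` option restricts the receptor side to side-chain atoms before
any detection, i.e. interactions with main-chain atoms are ignored.
"""

from __future__ import annotations

import enum
import logging
import math
import re
from dataclasses import dataclass, field

import numpy as np

from .chem_perception import (
    Features,
    LigandFeatures,
    ResidueFeatures,
    perceive_ligand,
    perceive_residue,
)
from .mol_io import Molecule

logger = logging.getLogger(__name__)

__all__ = [
    "InteractionType",
    "GeometryParams",
    "Bitstring",
    "BITS_PER_RESIDUE",
    "bit_index",
    "describe_bit",
    "compute_plif",
    "parse_display_name",
]

BITS_PER_RESIDUE = 7


class InteractionType(enum.IntEnum):
    """The 7 interaction classes; the integer value is the in-block bit offset."""

    APOLAR = 1
    AROMATIC_FACE_TO_FACE = 2
    AROMATIC_EDGE_TO_FACE = 3
    HBOND_PROTEIN_DONOR = 4
    HBOND_PROTEIN_ACCEPTOR = 5
    IONIC_PROTEIN_CATION = 6
    IONIC_PROTEIN_ANION = 7

    @property
    def label(self) -> str:
        return self.name.lower()


@dataclass
class GeometryParams:
    """Geometric detection thresholds (all configurable; defaults follow the
    classical structural interaction fingerprint scheme).

    apolar_cutoff:            max heavy-atom distance for hydrophobic contact (Å)
    aromatic_centroid_cutoff: max ring-centroid distance for stacking (Å)
    f2f_max_plane_angle:      plane angle ≤ this → face-to-face, else edge-to-face (deg)
    hbond_da_cutoff:          max donor–acceptor distance (Å)
    hbond_min_dha_angle:      min D–H···A angle when the donor H is present (deg)
    ionic_cutoff:             max closest inter-group distance for ionic contact (Å)
    """

    apolar_cutoff: float = 4.5
    aromatic_centroid_cutoff: float = 4.0
    f2f_max_plane_angle: float = 30.0
    hbond_da_cutoff: float = 3.5
    hbond_min_dha_angle: float = 135.0
    ionic_cutoff: float = 4.0

    def __post_init__(self) -> None:
        for name in ("apolar_cutoff", "aromatic_centroid_cutoff", "f2f_max_plane_angle",
                     "hbond_da_cutoff", "hbond_min_dha_angle", "ionic_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.f2f_max_plane_angle >= 90:
            raise ValueError("f2f_max_plane_angle must be < 90°")


@dataclass
class Bitstring:
    """A fingerprint over an ordered residue list; 7 bits per residue.

    ``bits`` is a boolean vector of length ``7 * len(residue_list)``;
    external indexing is 1-based (bit N of the fingerprint is ``bits[N-1]``).
    """

    residue_list: tuple[str, ...]
    bits: np.ndarray

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=bool)
        if self.bits.shape != (BITS_PER_RESIDUE * len(self.residue_list),):
            raise ValueError("bit vector length must be 7 × number of residues")

    def __len__(self) -> int:
        return self.bits.size

    def get(self, index: int) -> bool:
        """Value of 1-based bit ``index``."""
        if not 1 <= index <= self.bits.size:
            raise IndexError(f"bit index {index} out of range 1..{self.bits.size}")
        return bool(self.bits[index - 1])

    def on_bits(self) -> list[int]:
        """Sorted 1-based indices of set bits."""
        return [int(i) + 1 for i in np.nonzero(self.bits)[0]]

    def to01(self) -> str:
        return "".join("1" if b else "0" for b in self.bits)


def bit_index(residue_position: int, interaction: InteractionType, residue_list=None) -> int:
    """1-based fingerprint index of (residue position, interaction type).

    ``residue_position`` is the 1-based rank of the residue in the ordered
    binding-site list; the index is ``(position − 1) × 7 + type ordinal``.
    When ``residue_list`` is given the position is range-checked against it.
    """
    if residue_position < 1:
        raise IndexError(f"residue position must be ≥ 1, got {residue_position}")
    if residue_list is not None and residue_position > len(residue_list):
        raise IndexError(
            f"residue position {residue_position} exceeds list length {len(residue_list)}"
        )
    return (residue_position - 1) * BITS_PER_RESIDUE + int(interaction)


def describe_bit(index: int, residue_list) -> tuple[str, InteractionType]:
    """Inverse of :func:`bit_index`: (residue display name, interaction type)."""
    n = BITS_PER_RESIDUE * len(residue_list)
    if not 1 <= index <= n:
        raise IndexError(f"bit index {index} out of range 1..{n}")
    pos, offset = divmod(index - 1, BITS_PER_RESIDUE)
    return residue_list[pos], InteractionType(offset + 1)


_DISPLAY_RE = re.compile(r"^([A-Za-z]{3})(\d+)([A-Za-z]?)$")


def parse_display_name(name: str) -> tuple[str, int, str]:
    """Split a residue display name like ``Asp72`` into (RESNAME, number, icode)."""
    m = _DISPLAY_RE.match(name.strip())
    if not m:
        raise ValueError(f"cannot parse residue display name {name!r}")
    return m.group(1).upper(), int(m.group(2)), m.group(3).upper()


def _plane_angle_deg(n1: np.ndarray, n2: np.ndarray) -> float:
    """Acute angle between two plane normals, in degrees (0..90)."""
    c = abs(float(np.dot(n1, n2)) / (np.linalg.norm(n1) * np.linalg.norm(n2)))
    return math.degrees(math.acos(min(1.0, c)))


def _angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a–b–c in degrees."""
    u, v = a - b, c - b
    cosang = float(np.dot(u, v)) / (np.linalg.norm(u) * np.linalg.norm(v) + 1e-12)
    return math.degrees(math.acos(max(-1.0, min(1.0, cosang))))


def _min_dist(mol_a: Molecule, ia: set[int], mol_b: Molecule, ib: set[int]) -> float:
    if not ia or not ib:
        return math.inf
    ca = np.array([mol_a.atoms[i].coords for i in sorted(ia)])
    cb = np.array([mol_b.atoms[i].coords for i in sorted(ib)])
    return float(np.min(np.linalg.norm(ca[:, None, :] - cb[None, :, :], axis=2)))


def _hbond(
    donor_mol: Molecule,
    donors: list[tuple[int, tuple[int, ...]]],
    acceptor_mol: Molecule,
    acceptors: set[int],
    params: GeometryParams,
) -> bool:
    """Any donor/acceptor pair within distance, with the D–H···A angle test
    applied whenever the donor's polar hydrogen is recorded (distance-only
    otherwise)."""
    for d_idx, h_idxs in donors:
        d = donor_mol.atoms[d_idx].coords
        for a_idx in acceptors:
            a = acceptor_mol.atoms[a_idx].coords
            if np.linalg.norm(d - a) > params.hbond_da_cutoff:
                continue
            if not h_idxs:
                return True
            for h_idx in h_idxs:
                h = donor_mol.atoms[h_idx].coords
                if _angle_deg(d, h, a) >= params.hbond_min_dha_angle:
                    return True
    return False


def _restrict_to_side_chain(feats: ResidueFeatures) -> ResidueFeatures:
    """Drop every feature atom that is not a side-chain atom (the nobb mode)."""
    sc = feats.side_chain_atoms
    out = ResidueFeatures(residue_name=feats.residue_name)
    out.side_chain_atoms = set(sc)
    out.apolar_atoms = feats.apolar_atoms & sc
    out.aromatic_rings = [r for r in feats.aromatic_rings if set(r.atom_indices) <= sc]
    out.donors = [(d, tuple(h for h in hs if h in sc)) for d, hs in feats.donors if d in sc]
    out.acceptors = feats.acceptors & sc
    out.cation_groups = [g & sc for g in feats.cation_groups if g & sc]
    out.anion_groups = [g & sc for g in feats.anion_groups if g & sc]
    return out


def detect_residue_interactions(
    receptor: Molecule,
    res_feats: ResidueFeatures,
    pose: Molecule,
    lig_feats: LigandFeatures,
    params: GeometryParams,
) -> np.ndarray:
    """The 7-bit block of one residue against one ligand pose."""
    bits = np.zeros(BITS_PER_RESIDUE, dtype=bool)

    # 1: apolar contact
    if _min_dist(receptor, res_feats.apolar_atoms, pose, lig_feats.apolar_atoms) <= params.apolar_cutoff:
        bits[0] = True

    # 2/3: aromatic stacking, split by inter-plane angle
    for rring in res_feats.aromatic_rings:
        for lring in lig_feats.aromatic_rings:
            if np.linalg.norm(rring.centroid - lring.centroid) <= params.aromatic_centroid_cutoff:
                angle = _plane_angle_deg(rring.normal, lring.normal)
                if angle <= params.f2f_max_plane_angle:
                    bits[1] = True
                else:
                    bits[2] = True

    # 4: residue donates, ligand accepts / 5: ligand donates, residue accepts
    if _hbond(receptor, res_feats.donors, pose, lig_feats.acceptors, params):
        bits[3] = True
    if _hbond(pose, lig_feats.donors, receptor, res_feats.acceptors, params):
        bits[4] = True

    # 6: residue cation vs ligand anion / 7: residue anion vs ligand cation
    for rgrp in res_feats.cation_groups:
        if any(_min_dist(receptor, rgrp, pose, lgrp) <= params.ionic_cutoff
               for lgrp in lig_feats.anion_groups):
            bits[5] = True
    for rgrp in res_feats.anion_groups:
        if any(_min_dist(receptor, rgrp, pose, lgrp) <= params.ionic_cutoff
               for lgrp in lig_feats.cation_groups):
            bits[6] = True
    return bits


def _match_residues(receptor: Molecule, residue_list) -> list[list[int]]:
    """Atom-index groups of ``receptor`` for each display name in order."""
    groups = receptor.residues()
    by_identity: dict[tuple[str, int, str], list[int]] = {}
    for key, idxs in groups.items():
        resname = receptor.atoms[idxs[0]].residue_name
        chain, resnum, icode = key
        by_identity.setdefault((resname, resnum, icode), []).extend(idxs)
    out = []
    for display in residue_list:
        resname, resnum, icode = parse_display_name(display)
        idxs = by_identity.get((resname, resnum, icode))
        if idxs is None:
            raise KeyError(f"residue {display} not found in receptor {receptor.name!r}")
        out.append(idxs)
    return out


def compute_plif(
    receptor: Molecule,
    pose: Molecule,
    residue_list,
    nobb: bool = True,
    params: GeometryParams | None = None,
    lig_feats: LigandFeatures | None = None,
) -> Bitstring:
    """Fingerprint of one receptor/pose pair over ``residue_list``.

    ``residue_list`` is the ordered binding-site list of display names
    (``"Asp72"``-style).  With ``nobb`` (the default, matching side-chain-only
    fingerprinting) receptor atoms are restricted to side-chain atoms before
    any detection.  A residue named in the list but absent from the receptor
    raises :class:`KeyError` naming it.

    A pre-perceived ``lig_feats`` may be passed to avoid re-perceiving the
    same pose against several receptors.
    """
    params = params or GeometryParams()
    if lig_feats is None:
        lig_feats = perceive_ligand(pose)
    residue_list = tuple(residue_list)
    bits = np.zeros(BITS_PER_RESIDUE * len(residue_list), dtype=bool)
    for pos, atom_idxs in enumerate(_match_residues(receptor, residue_list)):
        feats = perceive_residue(receptor, atom_idxs)
        if nobb:
            feats = _restrict_to_side_chain(feats)
        block = detect_residue_interactions(receptor, feats, pose, lig_feats, params)
        bits[pos * BITS_PER_RESIDUE:(pos + 1) * BITS_PER_RESIDUE] = block
    return Bitstring(residue_list=residue_list, bits=bits)
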