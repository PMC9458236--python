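"""Binding-pocket residue selection and docking-box geometry.

Residues are selected around a reference ligand by a heavy-atom distance
cutoff (the conventional 5 Å pocket definition), per-receptor lists are
merged into a consensus ordered list for the fingerprint configuration, and
an axis-aligned docking box is derived for external docking engines.

The module also ships the 57-residue acetylcholinesterase consensus pocket
list used throughout the examples and tests (399-bit fingerprint).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mol_io import Molecule
from .plif import parse_display_name

__all__ = [
    "BindingSiteSpec",
    "select_residues",
    "consensus_residues",
    "compute_box",
    "vina_config_text",
    "ACHE_CONSENSUS_RESIDUES",
]

#: Consensus acetylcholinesterase pocket: union of the per-cluster 5 Å
#: selections around the bound reference peptide, ordered by residue number.
#: 57 residues -> a 399-bit fingerprint.
ACHE_CONSENSUS_RESIDUES: tuple[str, ...] = (
    "Gln69", "Tyr70", "Val71", "Asp72", "Gln74", "Phe75", "Phe78", "Ser79",
    "Gly80", "Ser81", "Glu82", "Met83", "Trp84", "Asn85", "Pro86", "Trp114",
    "Tyr116", "Gly117", "Gly118", "Gly119", "Phe120", "Tyr121", "Ser122",
    "Gly123", "Ser124", "Leu127", "Val129", "Tyr130", "Glu199", "Ser200",
    "Ala201", "Gly202", "Ser226", "Trp233", "Trp279", "Phe288", "Phe290",
    "Asn324", "Asp326", "Glu327", "Gly328", "Ser329", "Phe330", "Phe331",
    "Leu332", "Leu333", "Tyr334", "Val400", "Trp432", "Met436", "Ile439",
    "His440", "Gly441", "Tyr442", "Glu443", "Ile444", "Glu445",
)


@dataclass
class BindingSiteSpec:
    """An ordered pocket residue list plus the docking-box geometry (Å)."""

    residues: tuple[str, ...]
    box_center: np.ndarray
    box_size: np.ndarray

    def __post_init__(self) -> None:
        self.box_center = np.asarray(self.box_center, dtype=float)
        self.box_size = np.asarray(self.box_size, dtype=float)
        if not np.all(self.box_size > 0):
            raise ValueError("box_size must be strictly positive in all dimensions")


def _display(resname: str, resnum: int, icode: str = "") -> str:
    return f"{resname.capitalize()}{resnum}{icode}"


def _heavy_coords(mol: Molecule, indices=None) -> np.ndarray:
    atoms = mol.atoms if indices is None else [mol.atoms[i] for i in indices]
    coords = [a.coords for a in atoms if a.is_heavy]
    if not coords:
        raise ValueError("no heavy atoms")
    return np.array(coords)


def select_residues(receptor: Molecule, reference_ligand: Molecule, cutoff: float = 5.0) -> list[str]:
    """Pocket residues: any residue heavy atom within ``cutoff`` Å of any
    reference-ligand heavy atom.  Returns display names sorted by
    (chain, residue number, insertion code).  Empty selection raises (the
    ligand does not touch the receptor)."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    lig = _heavy_coords(reference_ligand)
    selected: list[tuple[tuple[str, int, str], str]] = []
    for key, idxs in receptor.residues().items():
        try:
            res = _heavy_coords(receptor, idxs)
        except ValueError:
            continue
        d = np.linalg.norm(res[:, None, :] - lig[None, :, :], axis=2)
        if float(d.min()) <= cutoff:
            resname = receptor.atoms[idxs[0]].residue_name
            selected.append((key, _display(resname, key[1], key[2])))
    if not selected:
        raise ValueError(f"no residue within {cutoff} Å of the reference ligand")
    selected.sort(key=lambda t: t[0])
    return [name for _, name in selected]


def consensus_residues(per_receptor_lists) -> list[str]:
    """Sorted union of per-receptor pocket lists (display names).

    Order-insensitive in its inputs and idempotent.  Two different residue
    names at the same position (same number + insertion code) are a clash
    between receptor structures and raise.
    """
    lists = list(per_receptor_lists)
    if not lists:
        raise ValueError("at least one residue list required")
    seen: dict[tuple[int, str], str] = {}
    for lst in lists:
        for display in lst:
            resname, resnum, icode = parse_display_name(display)
            key = (resnum, icode)
            prev = seen.get(key)
            if prev is not None and prev != resname:
                raise ValueError(f"conflicting residue names at {resnum}{icode}: {prev} vs {resname}")
            seen[key] = resname
    return [_display(resname, num, icode) for (num, icode), resname in sorted(seen.items())]


def compute_box(
    receptor: Molecule,
    reference_ligand: Molecule,
    selected_residues,
    padding: float = 5.0,
) -> BindingSiteSpec:
    """Docking box: centered on the reference-ligand heavy-atom centroid,
    sized to the axis-aligned extent of the selected residues' heavy atoms
    plus ``2 × padding`` per dimension, never smaller than the ligand extent.
    """
    if padding < 0:
        raise ValueError("padding must be ≥ 0")
    residues = tuple(selected_residues)
    if not residues:
        raise ValueError("empty residue selection")
    wanted = {parse_display_name(r) for r in residues}
    res_coords = []
    for key, idxs in receptor.residues().items():
        resname = receptor.atoms[idxs[0]].residue_name
        if (resname, key[1], key[2]) in wanted:
            res_coords.append(_heavy_coords(receptor, idxs))
    if not res_coords:
        raise ValueError("none of the selected residues is present in the receptor")
    res_coords = np.vstack(res_coords)
    lig = _heavy_coords(reference_ligand)
    center = lig.mean(axis=0)
    size = (res_coords.max(axis=0) - res_coords.min(axis=0)) + 2.0 * padding
    size = np.maximum(size, lig.max(axis=0) - lig.min(axis=0))
    size = np.maximum(size, 1e-6)  # degenerate flat selections still need a box
    return BindingSiteSpec(residues=residues, box_center=center, box_size=size)


def vina_config_text(spec: BindingSiteSpec) -> str:
    """The box as an AutoDock Vina config block."""
    cx, cy, cz = spec.box_center
    sx, sy, sz = spec.box_size
    return (
        f"center_x = {cx:.3f}\ncenter_y = {cy:.3f}\ncenter_z = {cz:.3f}\n"
        f"size_x = {sx:.3f}\nsize_y = {sy:.3f}\nsize_z = {sz:.3f}\n"
    )
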