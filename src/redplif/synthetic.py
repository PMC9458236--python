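"""Synthetic complexes, emulated docking output, and screening tables.

Everything the pipeline consumes can be generated here with known ground
truth and no external data:

* :func:`make_complex` — minimal receptor/ligand pairs in which specified
  (residue, interaction-type) contacts hold (or fail) by construction, with
  stated geometric margins.  Residues are single side chains on a short
  backbone stub, spaced far apart so contacts never cross-talk.
* :func:`make_vina_output` — multi-model PDBQT docking-output files with
  ``REMARK VINA RESULT`` score lines.
* :func:`make_table` — descriptor tables with a planted decision rule,
  controllable label noise and class-conditional score distributions.

All generators are deterministic under a fixed seed.  Geometries are
chemically minimal, not physically realistic: they exercise detector
semantics, not force fields.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .chem_perception import RESIDUE_TEMPLATES
from .mol_io import Atom, Molecule, PoseSet, STANDARD_AMINO_ACIDS, _BACKBONE_NAMES
from .plif import InteractionType

__all__ = [
    "PlantedInteractionSpec",
    "SyntheticTableSpec",
    "build_complex",
    "make_complex",
    "make_vina_output",
    "make_table",
    "make_generic_residue",
    "write_pdb",
    "write_pdbqt",
    "write_vina_multimodel",
    "DEFAULT_RESIDUE_FOR_TYPE",
]

_RESIDUE_SPACING = 30.0  # Å between planted residues; >> every cutoff

#: Which side chain realizes each interaction type in planted complexes.
DEFAULT_RESIDUE_FOR_TYPE = {
    InteractionType.APOLAR: "ALA",
    InteractionType.AROMATIC_FACE_TO_FACE: "PHE",
    InteractionType.AROMATIC_EDGE_TO_FACE: "PHE",
    InteractionType.HBOND_PROTEIN_DONOR: "SER",
    InteractionType.HBOND_PROTEIN_ACCEPTOR: "SER",
    InteractionType.IONIC_PROTEIN_CATION: "LYS",
    InteractionType.IONIC_PROTEIN_ANION: "ASP",
}


@dataclass
class PlantedInteractionSpec:
    """One planted (residue, interaction type) contact.

    ``distance`` is the defining geometric distance of the detector
    (heavy-atom contact distance, ring-centroid separation, donor–acceptor
    distance, or closest inter-group distance).  ``angle`` is the ring plane
    angle for aromatic types and the off-axis placement angle for H-bond
    acceptor placement (0 → ideal 180° D–H···A).  ``target='backbone'``
    aims an H-bond at the main-chain carbonyl O instead of the side chain
    (only for HBOND_PROTEIN_ACCEPTOR; used to exercise the side-chain-only
    mode).
    """

    interaction: InteractionType
    distance: float
    angle: float = 0.0
    residue: str | None = None
    target: str = "side_chain"
    jitter: float = 0.0


# -- residue geometry -------------------------------------------------------

_BACKBONE_COORDS = [
    ("N", "N", (-1.46, 0.0, 0.0)),
    ("H", "H", (-1.90, 0.92, 0.0)),
    ("CA", "C", (0.0, 0.0, 0.0)),
    ("C", "C", (1.52, 0.0, 0.0)),
    ("O", "O", (2.15, 1.05, 0.0)),
]

_PHE_CENTROID = np.array([0.0, 0.0, 4.39])
_PHE_RING = [
    ("CG", 270.0), ("CD1", 330.0), ("CE1", 30.0), ("CZ", 90.0), ("CE2", 150.0), ("CD2", 210.0),
]

_SIDE_CHAINS: dict[str, list[tuple[str, str, tuple[float, float, float]]]] = {
    "GLY": [],
    "ALA": [("CB", "C", (0.0, 0.0, 1.53))],
    "SER": [("CB", "C", (0.0, 0.0, 1.53)), ("OG", "O", (0.0, 0.0, 2.95)),
            ("HG", "H", (0.0, 0.0, 3.91))],
    "ASP": [("CB", "C", (0.0, 0.0, 1.53)), ("CG", "C", (0.0, 0.0, 3.06)),
            ("OD1", "O", (1.09, 0.0, 3.74)), ("OD2", "O", (-1.09, 0.0, 3.74))],
    "LYS": [("CB", "C", (0.0, 0.0, 1.53)), ("CG", "C", (0.0, 0.53, 2.95)),
            ("CD", "C", (0.0, 0.0, 4.37)), ("CE", "C", (0.0, 0.53, 5.79)),
            ("NZ", "N", (0.0, 0.0, 7.21)),
            ("HZ1", "H", (0.94, 0.0, 7.54)), ("HZ2", "H", (-0.47, 0.82, 7.54)),
            ("HZ3", "H", (-0.47, -0.82, 7.54))],
    "PHE": [("CB", "C", (0.0, 0.0, 1.53))]
    + [(name, "C", tuple(_PHE_CENTROID + 1.39 * np.array([math.cos(math.radians(a)), 0.0,
                                                          math.sin(math.radians(a))])))
       for name, a in _PHE_RING],
}

# feature anchor of each fixture residue, in local coordinates
_ANCHORS = {
    "ALA": np.array([0.0, 0.0, 1.53]),        # CB
    "SER": np.array([0.0, 0.0, 2.95]),        # OG
    "ASP": np.array([1.09, 0.0, 3.74]),       # OD1
    "LYS": np.array([0.0, 0.0, 7.21]),        # NZ
    "PHE": _PHE_CENTROID,                      # ring centroid (normal +y)
    "GLY": np.array([2.15, 1.05, 0.0]),        # backbone carbonyl O
}

_EZ = np.array([0.0, 0.0, 1.0])
_EY = np.array([0.0, 1.0, 0.0])


def _residue_atoms(resname: str, resnum: int, origin: np.ndarray,
                   serial_start: int, flip_ser_h: bool = False) -> list[Atom]:
    records = _BACKBONE_COORDS + _SIDE_CHAINS[resname]
    atoms = []
    for k, (name, element, xyz) in enumerate(records):
        pos = np.asarray(xyz, dtype=float)
        if flip_ser_h and resname == "SER" and name == "HG":
            pos = np.array([0.96, 0.0, 2.95])  # hydroxyl H points sideways
        atoms.append(Atom(serial=serial_start + k, name=name, element=element,
                          coords=origin + pos, residue_name=resname,
                          residue_number=resnum, chain="A",
                          is_backbone=name in _BACKBONE_NAMES))
    return atoms


def _aromatic_probe(centroid: np.ndarray, plane_angle_deg: float, serial_start: int,
                    resnum: int) -> list[Atom]:
    """Six-membered aromatic probe; plane rotated about the local x axis so
    its normal makes ``plane_angle_deg`` with +y (the fixture Phe ring
    normal).  Every ring carbon carries a radial O substituent so the probe
    is not itself hydrophobic — stacking specs then plant exactly the
    aromatic bit, without an apolar side-channel."""
    theta = math.radians(plane_angle_deg)
    u = np.array([1.0, 0.0, 0.0])
    v = np.array([0.0, math.sin(theta), -math.cos(theta)])
    atoms = []
    for k in range(6):
        phi = math.radians(60.0 * k)
        radial = math.cos(phi) * u + math.sin(phi) * v
        atoms.append(Atom(serial=serial_start + k, name=f"C{k + 1}", element="C",
                          coords=centroid + 1.39 * radial, residue_name="LIG",
                          residue_number=resnum))
        atoms.append(Atom(serial=serial_start + 6 + k, name=f"O{k + 1}", element="O",
                          coords=centroid + 2.75 * radial, partial_charge=-0.2,
                          residue_name="LIG", residue_number=resnum))
    return atoms


def _lig_atom(serial: int, name: str, element: str, coords: np.ndarray,
              charge: float, resnum: int) -> Atom:
    return Atom(serial=serial, name=name, element=element, coords=np.asarray(coords, float),
                partial_charge=charge, residue_name="LIG", residue_number=resnum,
                atom_type=element)


def build_complex(specs: list[PlantedInteractionSpec], seed: int = 0) -> tuple[Molecule, Molecule]:
    """In-memory (receptor, ligand) realizing the planted contacts.

    Residue ``i`` sits at ``(30·i, 0, 0)`` with its side chain along +z and
    its probe fragment placed by the spec's distance/angle.  Raises for a
    residue/interaction combination the fixture geometry cannot realize.
    """
    rng = np.random.default_rng(seed)
    rec_atoms: list[Atom] = []
    lig_atoms: list[Atom] = []
    if not specs:
        # a contact-free complex: one residue, one probe far outside every cutoff
        rec_atoms = _residue_atoms("GLY", 1, np.zeros(3), 1000)
        lig_atoms = [_lig_atom(1, "C1", "C", np.array([0.0, 0.0, 20.0]), 0.0, 1)]
        return (Molecule(atoms=rec_atoms, name="planted_receptor"),
                Molecule(atoms=lig_atoms, name="planted_ligand"))
    for i, spec in enumerate(specs):
        if spec.target == "backbone":
            resname = (spec.residue or "GLY").upper()
        else:
            resname = (spec.residue or DEFAULT_RESIDUE_FOR_TYPE[spec.interaction]).upper()
        if resname not in _SIDE_CHAINS:
            raise ValueError(f"no fixture geometry for residue {resname!r}")
        if spec.target == "backbone":
            if spec.interaction is not InteractionType.HBOND_PROTEIN_ACCEPTOR:
                raise ValueError("backbone targeting is only defined for protein-acceptor H-bonds")
        elif spec.residue is None or resname == DEFAULT_RESIDUE_FOR_TYPE[spec.interaction]:
            pass
        elif resname not in _compatible_residues(spec.interaction):
            raise ValueError(f"{resname} cannot realize {spec.interaction.label}")
        origin = np.array([_RESIDUE_SPACING * i, 0.0, 0.0])
        flip = (spec.interaction is InteractionType.HBOND_PROTEIN_ACCEPTOR
                and spec.target != "backbone")
        rec_atoms.extend(_residue_atoms(resname, i + 1, origin, 1000 + 20 * i, flip_ser_h=flip))
        lig_atoms.extend(_probe_fragment(spec, resname, origin, 1 + 10 * i, i + 1))
    if spec_jitter := max((s.jitter for s in specs), default=0.0):
        for a in lig_atoms:
            a.coords = a.coords + rng.uniform(-spec_jitter, spec_jitter, 3)
    receptor = Molecule(atoms=rec_atoms, name="planted_receptor")
    ligand = Molecule(atoms=lig_atoms, name="planted_ligand")
    return receptor, ligand


def _compatible_residues(interaction: InteractionType) -> set[str]:
    out = set()
    for resname in _SIDE_CHAINS:
        t = RESIDUE_TEMPLATES[resname]
        if interaction is InteractionType.APOLAR and t.get("apolar"):
            out.add(resname)
        elif interaction in (InteractionType.AROMATIC_FACE_TO_FACE,
                             InteractionType.AROMATIC_EDGE_TO_FACE) and t.get("rings"):
            out.add(resname)
        elif interaction is InteractionType.HBOND_PROTEIN_DONOR and t.get("donors"):
            out.add(resname)
        elif interaction is InteractionType.HBOND_PROTEIN_ACCEPTOR and t.get("acceptors"):
            out.add(resname)
        elif interaction is InteractionType.IONIC_PROTEIN_CATION and t.get("cations"):
            out.add(resname)
        elif interaction is InteractionType.IONIC_PROTEIN_ANION and t.get("anions"):
            out.add(resname)
    return out


def _probe_fragment(spec: PlantedInteractionSpec, resname: str, origin: np.ndarray,
                    serial: int, resnum: int) -> list[Atom]:
    d = spec.distance
    it = spec.interaction
    anchor = origin + _ANCHORS["GLY" if spec.target == "backbone" else resname]
    if it is InteractionType.APOLAR:
        return [_lig_atom(serial, "C1", "C", anchor + d * _EZ, 0.0, resnum)]
    if it is InteractionType.IONIC_PROTEIN_ANION:
        return [_lig_atom(serial, "N1", "N", anchor + d * _EZ, 0.60, resnum)]
    if it is InteractionType.IONIC_PROTEIN_CATION:
        return [_lig_atom(serial, "O1", "O", anchor + d * _EZ, -0.60, resnum)]
    if it in (InteractionType.AROMATIC_FACE_TO_FACE, InteractionType.AROMATIC_EDGE_TO_FACE):
        return _aromatic_probe(anchor + d * _EY, spec.angle, serial, resnum)
    if it is InteractionType.HBOND_PROTEIN_DONOR:
        alpha = math.radians(spec.angle)
        direction = np.array([math.sin(alpha), 0.0, math.cos(alpha)])
        return [_lig_atom(serial, "O1", "O", anchor + d * direction, -0.20, resnum)]
    if it is InteractionType.HBOND_PROTEIN_ACCEPTOR:
        axis = _EY if spec.target == "backbone" else _EZ
        o_pos = anchor + d * axis
        h_pos = o_pos - 0.96 * axis  # H on the line back to the acceptor
        return [_lig_atom(serial, "O1", "O", o_pos, -0.20, resnum),
                _lig_atom(serial + 1, "H1", "H", h_pos, 0.20, resnum)]
    raise ValueError(f"unhandled interaction {it!r}")


def make_generic_residue(resname: str, resnum: int, origin=(0.0, 0.0, 0.0),
                         serial_start: int = 1) -> list[Atom]:
    """A standard residue with every atom its perception template names.

    Ring atoms sit on regular polygons; other side-chain atoms are laid out
    along a helix.  Geometry is schematic — meant for perception-coverage
    and rigid-motion tests, not for planted-contact geometry.
    """
    resname = resname.upper()
    if resname not in STANDARD_AMINO_ACIDS:
        raise ValueError(f"not a standard residue: {resname!r}")
    template = RESIDUE_TEMPLATES[resname]
    origin = np.asarray(origin, dtype=float)
    placed: dict[str, np.ndarray] = {n: np.asarray(x) for n, _, x in _BACKBONE_COORDS}
    for r, names in enumerate(template.get("rings", [])):
        centroid = np.array([0.0, 2.5 * r, 4.0])
        radius = 1.39 if len(names) == 6 else 1.17
        for k, name in enumerate(names):
            if name not in placed:
                phi = 2 * math.pi * k / len(names)
                placed[name] = centroid + radius * np.array([math.cos(phi), 0.3 * r, math.sin(phi)])
    wanted: list[str] = list(template.get("apolar", [])) + list(template.get("acceptors", []))
    for heavy, hs in template.get("donors", []):
        wanted.append(heavy)
        wanted.extend(hs)
    for grp in template.get("cations", []) + template.get("anions", []):
        wanted.extend(grp)
    if resname == "HIS":
        wanted.append("HE2")  # neutral NE2-protonated tautomer
    for k, name in enumerate(w for w in wanted if w not in placed):
        ang = 0.9 * k
        placed[name] = np.array([1.2 * math.cos(ang), 1.2 * math.sin(ang), 1.5 + 0.8 * k])
    atoms = []
    for k, (name, pos) in enumerate(placed.items()):
        element = "H" if name.startswith("H") else name[0]
        atoms.append(Atom(serial=serial_start + k, name=name, element=element,
                          coords=origin + pos, residue_name=resname, residue_number=resnum,
                          chain="A", is_backbone=name in _BACKBONE_NAMES))
    return atoms


# -- file writers -----------------------------------------------------------

def _pdb_line(a: Atom, with_charge: bool) -> str:
    record = "ATOM" if a.residue_name in STANDARD_AMINO_ACIDS else "HETATM"
    name = f" {a.name:<3s}" if len(a.name) < 4 else a.name
    line = (f"{record:<6s}{a.serial:>5d} {name:4s}{'':1s}{a.residue_name:>3s} "
            f"{a.chain or 'A':1s}{a.residue_number:>4d}{a.insertion_code or '':1s}   "
            f"{a.coords[0]:8.3f}{a.coords[1]:8.3f}{a.coords[2]:8.3f}")
    if with_charge:
        ad_type = a.atom_type or a.element
        line += f"  1.00  0.00    {a.partial_charge:6.3f} {ad_type:<2s}"
    return line


def write_pdb(molecule: Molecule, path: str | Path) -> Path:
    path = Path(path)
    lines = [_pdb_line(a, with_charge=False) for a in molecule.atoms]
    path.write_text("\n".join(lines) + "\nEND\n")
    return path


def write_pdbqt(molecule: Molecule, path: str | Path) -> Path:
    path = Path(path)
    lines = [_pdb_line(a, with_charge=True) for a in molecule.atoms]
    path.write_text("\n".join(lines) + "\n")
    return path


def write_vina_multimodel(path: str | Path, poses: list[Molecule], scores: list[float]) -> Path:
    """A docking-output multi-model PDBQT with one VINA RESULT line per MODEL."""
    path = Path(path)
    blocks = []
    for k, (pose, score) in enumerate(zip(poses, scores), start=1):
        body = "\n".join(_pdb_line(a, with_charge=True) for a in pose.atoms)
        blocks.append(f"MODEL {k}\nREMARK VINA RESULT:    {score:7.1f}      0.000      0.000\n"
                      f"{body}\nENDMDL")
    path.write_text("\n".join(blocks) + "\n")
    return path


def make_complex(specs: list[PlantedInteractionSpec], out_dir: str | Path,
                 seed: int = 0) -> tuple[Path, Path]:
    """Write a planted complex: receptor PDBQT + ligand PDBQT, plus a JSON
    manifest of the specs and seed.  Returns (receptor path, ligand path)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    receptor, ligand = build_complex(specs, seed=seed)
    rpath = write_pdbqt(receptor, out_dir / "receptor.pdbqt")
    lpath = write_pdbqt(ligand, out_dir / "ligand.pdbqt")
    manifest = {
        "seed": seed,
        "specs": [{"interaction": s.interaction.label, "distance": s.distance,
                   "angle": s.angle, "residue": s.residue, "target": s.target,
                   "jitter": s.jitter} for s in specs],
        "files": [rpath.name, lpath.name],
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return rpath, lpath


# -- emulated docking output ------------------------------------------------

def make_vina_output(out_dir: str | Path, n_runs: int = 6, n_modes: int = 5,
                     score_mean: float = -8.5, score_sd: float = 0.8,
                     seed: int = 0, prefix: str = "run") -> list[Path]:
    """Emulated docking-output files: ``n_runs`` multi-model PDBQT files of
    ``n_modes`` poses each, scores sorted ascending within each run (rank
    order), byte-reproducible under a fixed seed."""
    if n_modes < 1:
        raise ValueError("n_modes must be ≥ 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    paths = []
    for r in range(n_runs):
        scores = np.round(np.sort(rng.normal(score_mean, score_sd, size=n_modes)), 1)
        poses = []
        for m in range(n_modes):
            center = rng.uniform(-2.0, 2.0, 3)
            atoms = [
                _lig_atom(1, "C1", "C", center, 0.05, 1),
                _lig_atom(2, "C2", "C", center + [1.5, 0, 0], 0.05, 1),
                _lig_atom(3, "O1", "O", center + [2.2, 1.1, 0], -0.35, 1),
            ]
            poses.append(Molecule(atoms=atoms, name=f"{prefix}{r + 1}_mode{m + 1}"))
        paths.append(write_vina_multimodel(out_dir / f"{prefix}{r + 1}.pdbqt",
                                           poses, [float(s) for s in scores]))
    return paths


# -- synthetic descriptor tables --------------------------------------------

@dataclass
class SyntheticTableSpec:
    """Spec for a planted screening table.

    Actives satisfy every planted condition (variable, threshold, ``">="``
    or ``"<"``); decoys violate at least one.  ``bit_noise`` is the per-rule
    probability of an active violating / a decoy satisfying a condition.
    Descriptor values are pose fractions quantized to ``k/denominator``.
    Docking scores are class-conditionally normal; the defaults leave the
    classes imperfectly separated around a realistic score cutoff.
    """

    n_active: int
    n_decoy: int
    rule: list[tuple[str, float, str]] = field(default_factory=lambda: [("V295", 0.5, ">=")])
    bit_noise: float = 0.0
    n_bits: int = 399
    denominator: int = 30
    active_score: tuple[float, float] = (-9.5, 0.5)
    decoy_score: tuple[float, float] = (-7.5, 0.7)
    background_rate: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_active + self.n_decoy < 10:
            raise ValueError("need at least 10 compounds")
        if not 0 <= self.bit_noise <= 1:
            raise ValueError("bit_noise must be in [0, 1]")


def make_table(spec: SyntheticTableSpec) -> pd.DataFrame:
    """Generate the planted table (columns ``y, name, dg, V1..Vn``)."""
    rng = np.random.default_rng(spec.seed)
    m = spec.denominator
    n = spec.n_active + spec.n_decoy
    y = np.concatenate([np.ones(spec.n_active, int), np.zeros(spec.n_decoy, int)])
    V = rng.binomial(m, spec.background_rate, size=(n, spec.n_bits)) / m

    cols = {f"V{i}": i - 1 for i in (range(1, spec.n_bits + 1))}
    rule_idx = []
    for var, thr, op in spec.rule:
        if var not in cols:
            raise ValueError(f"rule variable {var} outside V1..V{spec.n_bits}")
        if op not in (">=", "<"):
            raise ValueError(f"rule direction must be '>=' or '<', got {op!r}")
        rule_idx.append((cols[var], thr, op))

    def satisfy(j: int, thr: float, op: str, rows: np.ndarray) -> None:
        lo, hi = (int(np.ceil(thr * m)), m) if op == ">=" else (0, int(np.ceil(thr * m)) - 1)
        if lo > hi:
            raise ValueError(f"threshold {thr} leaves no {op}-side values on a /{m} grid")
        V[rows, j] = rng.integers(lo, hi + 1, size=rows.size) / m

    def violate(j: int, thr: float, op: str, rows: np.ndarray) -> None:
        satisfy(j, thr, "<" if op == ">=" else ">=", rows)

    if rule_idx:  # an empty rule means a signal-free (pure background) table
        actives = np.arange(spec.n_active)
        decoys = np.arange(spec.n_active, n)
        for j, thr, op in rule_idx:
            flip = rng.random(spec.n_active) < spec.bit_noise
            satisfy(j, thr, op, actives[~flip])
            violate(j, thr, op, actives[flip])
        # each clean decoy violates one condition; the others follow background
        broken = rng.integers(0, len(rule_idx), size=spec.n_decoy)
        for k, (j, thr, op) in enumerate(rule_idx):
            hit = decoys[(broken == k) & (rng.random(spec.n_decoy) >= spec.bit_noise)]
            violate(j, thr, op, hit)

    dg = np.where(y == 1,
                  rng.normal(*spec.active_score, size=n),
                  rng.normal(*spec.decoy_score, size=n)).round(2)
    names = [f"{'CHEMBL' if label else 'C'}{100000 + i}" for i, label in enumerate(y)]
    table = pd.DataFrame({"y": y, "name": names, "dg": dg})
    return pd.concat([table, pd.DataFrame(V, columns=list(cols))], axis=1)
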