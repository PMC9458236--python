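"""Brute-force re-implementation of the interaction definitions.

Used only as an independent oracle against the fingerprint detector: plain
double loops over atom/feature pairs applying the geometric criteria
literally, sharing no code with the production detection path.
"""

from __future__ import annotations

import math

import numpy as np

from redplif.chem_perception import perceive_ligand, perceive_residue
from redplif.plif import BITS_PER_RESIDUE, GeometryParams, parse_display_name


def _dist(a, b):
    return math.sqrt(sum((x - y) ** 2 for x, y in zip(a, b)))


def _angle(a, b, c):
    u = np.asarray(a) - np.asarray(b)
    v = np.asarray(c) - np.asarray(b)
    cosang = float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))
    return math.degrees(math.acos(max(-1.0, min(1.0, cosang))))


def brute_force_plif(receptor, pose, residue_list, nobb, params: GeometryParams | None = None):
    """1-based set-bit list computed by exhaustive pairwise checks."""
    params = params or GeometryParams()
    lig = perceive_ligand(pose)
    pa = {i: pose.atoms[i].coords for i in range(len(pose))}
    on = set()

    groups = receptor.residues()
    lookup = {}
    for key, idxs in groups.items():
        resname = receptor.atoms[idxs[0]].residue_name
        lookup[(resname, key[1], key[2])] = idxs

    for pos, display in enumerate(residue_list):
        idxs = lookup[parse_display_name(display)]
        res = perceive_residue(receptor, idxs)
        ra = {i: receptor.atoms[i].coords for i in idxs}
        allowed = res.side_chain_atoms if nobb else set(idxs)
        base = pos * BITS_PER_RESIDUE

        # apolar: any allowed residue apolar atom near any ligand apolar atom
        for i in res.apolar_atoms:
            if i not in allowed:
                continue
            for j in lig.apolar_atoms:
                if _dist(ra[i], pa[j]) <= params.apolar_cutoff:
                    on.add(base + 1)

        # aromatic: centroid distance + plane angle
        for rring in res.aromatic_rings:
            if not set(rring.atom_indices) <= allowed:
                continue
            for lring in lig.aromatic_rings:
                if _dist(rring.centroid, lring.centroid) <= params.aromatic_centroid_cutoff:
                    cosang = abs(float(np.dot(rring.normal, lring.normal)))
                    angle = math.degrees(math.acos(min(1.0, cosang)))
                    on.add(base + (2 if angle <= params.f2f_max_plane_angle else 3))

        # H-bonds
        for d_idx, hs in res.donors:
            if d_idx not in allowed:
                continue
            hs = [h for h in hs if h in allowed]
            for a_idx in lig.acceptors:
                if _dist(ra[d_idx], pa[a_idx]) > params.hbond_da_cutoff:
                    continue
                if not hs:
                    on.add(base + 4)
                elif any(_angle(ra[d_idx], ra[h], pa[a_idx]) >= params.hbond_min_dha_angle
                         for h in hs):
                    on.add(base + 4)
        for d_idx, hs in lig.donors:
            for a_idx in res.acceptors:
                if a_idx not in allowed:
                    continue
                if _dist(pa[d_idx], ra[a_idx]) > params.hbond_da_cutoff:
                    continue
                if not hs:
                    on.add(base + 5)
                elif any(_angle(pa[d_idx], pa[h], ra[a_idx]) >= params.hbond_min_dha_angle
                         for h in hs):
                    on.add(base + 5)

        # ionic
        for rgrp in res.cation_groups:
            for lgrp in lig.anion_groups:
                if any(_dist(ra[i], pa[j]) <= params.ionic_cutoff
                       for i in rgrp if i in allowed for j in lgrp):
                    on.add(base + 6)
        for rgrp in res.anion_groups:
            for lgrp in lig.cation_groups:
                if any(_dist(ra[i], pa[j]) <= params.ionic_cutoff
                       for i in rgrp if i in allowed for j in lgrp):
                    on.add(base + 7)
    return sorted(on)
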