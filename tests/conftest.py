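"""Shared fixtures: planted complexes and small structure files.

Everything is generated programmatically; nothing is downloaded or stored.
"""

from __future__ import annotations

import numpy as np
import pytest

from redplif.plif import InteractionType
from redplif.synthetic import PlantedInteractionSpec, build_complex

# (interaction, in-block bit offset, fixture residue)
ALL_TYPES = [
    (InteractionType.APOLAR, 1, "Ala"),
    (InteractionType.AROMATIC_FACE_TO_FACE, 2, "Phe"),
    (InteractionType.AROMATIC_EDGE_TO_FACE, 3, "Phe"),
    (InteractionType.HBOND_PROTEIN_DONOR, 4, "Ser"),
    (InteractionType.HBOND_PROTEIN_ACCEPTOR, 5, "Ser"),
    (InteractionType.IONIC_PROTEIN_CATION, 6, "Lys"),
    (InteractionType.IONIC_PROTEIN_ANION, 7, "Asp"),
]


def planted(specs):
    """(receptor, ligand, residue display list) for a list of specs."""
    receptor, ligand = build_complex(specs)
    residues = []
    for key, idxs in receptor.residues().items():
        resname = receptor.atoms[idxs[0]].residue_name
        residues.append(f"{resname.capitalize()}{key[1]}")
    return receptor, ligand, residues


@pytest.fixture
def rng():
    return np.random.default_rng(20220902)


@pytest.fixture
def seven_type_complex():
    """One positive-control contact of every interaction type."""
    specs = [
        PlantedInteractionSpec(InteractionType.IONIC_PROTEIN_ANION, 3.0),
        PlantedInteractionSpec(InteractionType.APOLAR, 4.0),
        PlantedInteractionSpec(InteractionType.AROMATIC_FACE_TO_FACE, 3.6, angle=10.0),
        PlantedInteractionSpec(InteractionType.AROMATIC_EDGE_TO_FACE, 3.6, angle=60.0),
        PlantedInteractionSpec(InteractionType.HBOND_PROTEIN_DONOR, 3.0),
        PlantedInteractionSpec(InteractionType.HBOND_PROTEIN_ACCEPTOR, 3.0),
        PlantedInteractionSpec(InteractionType.IONIC_PROTEIN_CATION, 3.0),
    ]
    return planted(specs)
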