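"""Shared fixtures: tiny hand-built structures and pocket helpers."""

from __future__ import annotations

import numpy as np
import pytest

from pocketsig.pockets import Pocket
from pocketsig.structio import AtomRecord, ProteinStructure


def structure_from_points(
    points,
    elements=None,
    residues=None,
    structure_id="toy",
    hetero_flags=None,
):
    """Build a ProteinStructure with one atom per point."""
    points = np.asarray(points, dtype=float)
    n = len(points)
    elements = elements or ["C"] * n
    residues = residues or ["ALA"] * n
    hetero_flags = hetero_flags or [False] * n
    atoms = [
        AtomRecord(
            serial=i + 1,
            atom_name=elements[i],
            element=elements[i],
            residue_name=residues[i],
            residue_seq=i + 1,
            chain_id="A",
            coords=points[i],
            is_hetero=hetero_flags[i],
        )
        for i in range(n)
    ]
    return ProteinStructure(id=structure_id, atoms=atoms)


def pocket_of(structure, indices=None, volume=100.0, rank=1):
    """Pocket covering the given atom indices (default: all non-hetero)."""
    if indices is None:
        indices = [i for i, a in enumerate(structure.atoms) if not a.is_hetero]
    coords = np.array([structure.atoms[i].coords for i in indices])
    return Pocket(
        structure_id=structure.id,
        atom_indices=list(indices),
        volume=volume,
        rank=rank,
        centroid=coords.mean(axis=0),
    )


def random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def pdb_3atoms(tmp_path):
    """A minimal hand-written 3-atom PDB file."""
    text = (
        "ATOM      1  N   MET A   1      11.104   6.134  -6.504  1.00 10.00           N\n"
        "ATOM      2  CA  MET A   1      11.639   6.071  -5.147  1.00 10.00           C\n"
        "ATOM      3  O   MET A   1      10.821   7.352  -3.197  1.00 10.00           O\n"
        "END\n"
    )
    path = tmp_path / "three.pdb"
    path.write_text(text)
    return path
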