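"""Grid-based cavity detection and binding-pocket extraction.

A pocket is the set of heavy protein atoms lining a buried cavity. Cavities
are found on a regular grid: voxels within the solvent-excluded radius of any
heavy atom are occupied; remaining empty voxels are classified as buried when
at least a fixed fraction of rays cast from them hit protein; pockets are the
6-connected components of buried empty voxels that cannot be reached from the
box boundary through low-burial (exposed) space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree, ConvexHull, QhullError

from .structio import ProteinStructure

VDW_RADIUS = 1.7  # generic heavy-atom van der Waals radius, Å
PROBE_RADIUS_DEFAULT = 1.4  # water probe, Å
BURIAL_FRACTION = 0.55
N_RAYS = 32
RAY_LENGTH = 8.0  # Å
MIN_POCKET_ATOMS = 8
MIN_POCKET_VOLUME = 50.0  # Å³; smaller cavities are grid noise
CONTACT_DISTANCE = 4.5  # heavy-atom contact cutoff, Å


@dataclass
class Pocket:
    """Atoms lining one cavity of a structure.

    atom_indices index into the parent structure's atom list and refer to
    heavy, non-hetero atoms only. rank 1 is the largest-volume pocket.
    """

    structure_id: str
    atom_indices: list[int]
    volume: float
    rank: int
    centroid: np.ndarray

    def __post_init__(self) -> None:
        if not self.atom_indices:
            raise ValueError("pocket must contain at least one atom")
        if len(set(self.atom_indices)) != len(self.atom_indices):
            raise ValueError("pocket atom indices must be unique")
        if self.volume < 0:
            raise ValueError("pocket volume must be >= 0")
        self.centroid = np.asarray(self.centroid, dtype=float)

    def coords(self, structure: ProteinStructure) -> np.ndarray:
        return np.array([structure.atoms[i].coords for i in self.atom_indices])

    def elements(self, structure: ProteinStructure) -> list[str]:
        return [structure.atoms[i].element for i in self.atom_indices]

    def residues(self, structure: ProteinStructure) -> list[str]:
        return [structure.atoms[i].residue_name for i in self.atom_indices]


def _ray_directions(n: int = N_RAYS) -> np.ndarray:
    """n approximately uniform directions on the sphere (Fibonacci lattice)."""
    i = np.arange(n) + 0.5
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def detect_pockets(
    structure: ProteinStructure,
    grid_spacing: float = 1.0,
    probe_radius: float = PROBE_RADIUS_DEFAULT,
) -> list[Pocket]:
    """Detect cavities and return their lining pockets, largest first.

    Deterministic for fixed inputs. Pockets with fewer than
    ``MIN_POCKET_ATOMS`` lining atoms are discarded. Returns an empty list
    (with a warning) for degenerate geometry.
    """
    heavy = structure.heavy_atom_indices(include_hetero=False)
    if len(heavy) < 20:
        raise ValueError(
            f"structure {structure.id}: need >= 20 heavy atoms, got {len(heavy)}"
        )
    coords = np.array([structure.atoms[i].coords for i in heavy])

    # degenerate geometry: all atoms nearly collinear
    centered = coords - coords.mean(axis=0)
    svals = np.linalg.svd(centered, compute_uv=False)
    if svals[1] < 1e-6:
        warnings.warn(f"structure {structure.id}: degenerate (collinear) geometry")
        return []

    lo = coords.min(axis=0) - 2.0
    hi = coords.max(axis=0) + 2.0
    shape = np.maximum(np.ceil((hi - lo) / grid_spacing).astype(int) + 1, 2)
    axes = [lo[d] + grid_spacing * np.arange(shape[d]) for d in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    centers = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])

    tree = cKDTree(coords)
    excluded_r = VDW_RADIUS + probe_radius
    dist, _ = tree.query(centers, k=1)
    occupied = (dist <= excluded_r).reshape(shape)
    empty = ~occupied

    # burial: fraction of rays from the voxel center that hit protein.
    # Voxels far from every atom cannot be buried; skip their ray casting.
    empty_flat = np.flatnonzero(empty.ravel())
    if empty_flat.size == 0:
        return []
    near = dist.ravel()[empty_flat] <= RAY_LENGTH - 1.0
    cand_flat = empty_flat[near]
    burial = np.zeros(empty_flat.size)
    if cand_flat.size:
        vox_ijk = np.column_stack(np.unravel_index(cand_flat, shape)).astype(np.int32)
        dirs = _ray_directions()
        steps = np.arange(grid_spacing, RAY_LENGTH + 1e-9, grid_spacing)
        # integer grid offsets per (ray, step), deduplicated per ray
        offsets = np.rint(
            dirs[:, None, :] * steps[None, :, None] / grid_spacing
        ).astype(np.int32)  # (n_rays, n_steps, 3)
        ray_hit_frac = np.zeros(cand_flat.size)
        occ_flat = occupied.ravel()
        sh = np.asarray(shape, dtype=np.int64)
        for r in range(offsets.shape[0]):
            off = np.unique(offsets[r], axis=0)
            pts_ijk = vox_ijk[:, None, :] + off[None, :, :]
            inside = np.all((pts_ijk >= 0) & (pts_ijk < sh), axis=-1)
            flat = (
                np.clip(pts_ijk[..., 0], 0, sh[0] - 1) * sh[1] * sh[2]
                + np.clip(pts_ijk[..., 1], 0, sh[1] - 1) * sh[2]
                + np.clip(pts_ijk[..., 2], 0, sh[2] - 1)
            )
            ray_hit_frac += (occ_flat[flat] & inside).any(axis=1)
        burial[near] = ray_hit_frac / offsets.shape[0]

    buried = np.zeros(shape, dtype=bool).ravel()
    buried[empty_flat[burial >= BURIAL_FRACTION]] = True
    buried = buried.reshape(shape)
    exposed_empty = empty & ~buried

    # exterior = empty voxels reachable from the box boundary through
    # low-burial space (plus any buried voxels directly connected to it
    # are still interior); flood-fill over exposed empty voxels only
    structure6 = ndimage.generate_binary_structure(3, 1)
    labels, n_lab = ndimage.label(exposed_empty, structure=structure6)
    boundary_labels = set()
    for face in (
        labels[0, :, :], labels[-1, :, :],
        labels[:, 0, :], labels[:, -1, :],
        labels[:, :, 0], labels[:, :, -1],
    ):
        boundary_labels.update(np.unique(face))
    boundary_labels.discard(0)
    exterior = np.isin(labels, sorted(boundary_labels))

    # pocket voxels: empty voxels not reachable from the boundary through
    # low-burial space (deep cavity cores count even when too far from the
    # walls for rays to hit); require adjacency to the solvent-excluded
    # region so free-floating enclosed slivers are ignored
    adjacent_to_protein = ndimage.binary_dilation(occupied, structure=structure6)
    cavity = empty & ~exterior

    labels_c, n_c = ndimage.label(cavity, structure=structure6)
    pockets: list[tuple[float, np.ndarray, np.ndarray]] = []
    for lab in range(1, n_c + 1):
        mask = labels_c == lab
        if not (mask & adjacent_to_protein).any():
            continue
        vox = np.argwhere(mask)
        vox_coords = lo + vox * grid_spacing
        volume = float(mask.sum()) * grid_spacing**3
        pockets.append((volume, vox_coords, vox))

    # lining atoms: heavy atoms within contact distance of cavity voxels
    results: list[Pocket] = []
    for volume, vox_coords, _ in pockets:
        if volume < MIN_POCKET_VOLUME:
            continue
        vtree = cKDTree(vox_coords)
        pairs = vtree.query_ball_point(coords, r=CONTACT_DISTANCE)
        lining = [heavy[i] for i, hits in enumerate(pairs) if hits]
        if len(lining) < MIN_POCKET_ATOMS:
            continue
        results.append((volume, vox_coords.mean(axis=0), lining))

    results.sort(key=lambda t: (-t[0], t[2]))
    out = [
        Pocket(
            structure_id=structure.id,
            atom_indices=lining,
            volume=volume,
            rank=i + 1,
            centroid=centroid,
        )
        for i, (volume, centroid, lining) in enumerate(results)
    ]
    return out


def binding_pocket(
    complex_structure: ProteinStructure,
    ligand_code: str,
    contact_cutoff: float = CONTACT_DISTANCE,
) -> Pocket:
    """Extract the pocket contacting the named ligand in a co-crystal.

    Pocket atoms are heavy protein atoms within ``contact_cutoff`` of any
    heavy ligand atom. Volume comes from the detected cavity nearest the
    pocket atoms when one exists, else from the convex hull of the pocket.
    """
    groups = complex_structure.ligand_groups
    lig_indices: list[int] = []
    for (resname, _chain, _seq), idx in groups.items():
        if resname == ligand_code:
            lig_indices.extend(idx)
    if not lig_indices:
        available = sorted({k[0] for k in groups} - {"HOH"})
        raise ValueError(
            f"ligand {ligand_code!r} not found in {complex_structure.id}; "
            f"available hetero codes: {available}"
        )
    lig_coords = np.array([
        complex_structure.atoms[i].coords
        for i in lig_indices
        if complex_structure.atoms[i].element.upper() not in ("H", "D")
    ])

    heavy = complex_structure.heavy_atom_indices(include_hetero=False)
    coords = np.array([complex_structure.atoms[i].coords for i in heavy])
    tree = cKDTree(lig_coords)
    dist, _ = tree.query(coords, k=1)
    pocket_atoms = [heavy[i] for i in np.flatnonzero(dist <= contact_cutoff)]
    if not pocket_atoms:
        raise ValueError(
            f"empty binding pocket: no protein atoms within {contact_cutoff} Å "
            f"of ligand {ligand_code!r}"
        )
    pocket_coords = np.array([complex_structure.atoms[i].coords for i in pocket_atoms])
    centroid = pocket_coords.mean(axis=0)

    volume = 0.0
    try:
        detected = detect_pockets(complex_structure)
    except ValueError:
        detected = []
    if detected:
        # cavity whose centroid is nearest the ligand
        lig_centroid = lig_coords.mean(axis=0)
        nearest = min(detected, key=lambda p: float(np.linalg.norm(p.centroid - lig_centroid)))
        if np.linalg.norm(nearest.centroid - lig_centroid) <= RAY_LENGTH:
            volume = nearest.volume
    if volume == 0.0 and len(pocket_atoms) >= 4:
        try:
            volume = float(ConvexHull(pocket_coords).volume)
        except QhullError:
            volume = 0.0

    return Pocket(
        structure_id=complex_structure.id,
        atom_indices=pocket_atoms,
        volume=volume,
        rank=1,
        centroid=centroid,
    )


def top_pockets(pockets: list[Pocket], k: int) -> list[Pocket]:
    """First k pockets by rank (all of them when fewer than k exist)."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    ranked = sorted(pockets, key=lambda p: p.rank)
    return ranked[:k]


def read_pocket_table(path, structures: dict[str, ProteinStructure]) -> dict[str, list[Pocket]]:
    """Ingest externally computed pockets from a TSV.

    Columns: structure_id, rank, volume, comma-separated atom serials.
    Lets users substitute genuine cavity-finder output for the built-in one.
    """
    out: dict[str, list[Pocket]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#") or line.startswith("structure_id"):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 tab-separated columns")
            sid, rank_s, vol_s, serials_s = fields
            if sid not in structures:
                raise ValueError(f"{path}:{lineno}: unknown structure {sid!r}")
            structure = structures[sid]
            serial_to_idx = {a.serial: i for i, a in enumerate(structure.atoms)}
            try:
                serials = [int(s) for s in serials_s.split(",") if s.strip()]
                rank = int(rank_s)
                volume = float(vol_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad numeric field") from exc
            missing = [s for s in serials if s not in serial_to_idx]
            if missing:
                raise ValueError(f"{path}:{lineno}: unknown atom serials {missing}")
            indices = [serial_to_idx[s] for s in serials]
            coords = np.array([structure.atoms[i].coords for i in indices])
            out.setdefault(sid, []).append(
                Pocket(
                    structure_id=sid,
                    atom_indices=indices,
                    volume=volume,
                    rank=rank,
                    centroid=coords.mean(axis=0),
                )
            )
    for sid, plist in out.items():
        ranks = sorted(p.rank for p in plist)
        if ranks != list(range(1, len(plist) + 1)):
            raise ValueError(f"{path}: ranks for {sid!r} must be 1..k without gaps")
        plist.sort(key=lambda p: p.rank)
    return out


def write_pocket_table(pockets: list[Pocket], structures: dict[str, ProteinStructure], path) -> None:
    lines = ["structure_id\trank\tvolume\tatom_serials"]
    for p in pockets:
        serials = ",".join(
            str(structures[p.structure_id].atoms[i].serial) for i in p.atom_indices
        )
        lines.append(f"{p.structure_id}\t{p.rank}\t{p.volume:.3f}\t{serials}")
    from pathlib import Path as _P
    _P(path).write_text("\n".join(lines) + "\n")
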