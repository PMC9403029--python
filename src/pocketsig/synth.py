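"""Synthetic structures with planted pocket motifs.

Each structure embeds a noisy, partially dropped-out copy of a motif inside
a hollow scaffold shell, so the motif lines a detectable cavity. Benchmarks
pair a positive motif with a negative motif sharing a controllable fraction
of positions ("confusability"). Everything is deterministic under the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .structio import AtomRecord, ProteinStructure, write_structure

MOTIF_RADIUS = 10.0  # motif points sampled in a ball of this radius, Å
MIN_POSITION_DIST = 1.5  # Å
SCAFFOLD_CLEARANCE = 4.0  # min scaffold-to-motif distance, Å
SCAFFOLD_MIN_DIST = 1.8  # min scaffold-to-scaffold distance, Å
SHELL_THICKNESS = 1.5  # Å
TYPE_PERTURB_PROB = 0.1
ELEMENTS = ("C", "N", "O", "S")
RESIDUES = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)


@dataclass
class MotifTemplate:
    id: str
    positions: list[tuple[np.ndarray, str, str]]  # (coords, element, residue)
    seed: int

    def __post_init__(self) -> None:
        if len(self.positions) < 8:
            raise ValueError(f"motif needs >= 8 positions, got {len(self.positions)}")
        coords = self.coords()
        for i in range(len(coords)):
            for j in range(i + 1, len(coords)):
                d = float(np.linalg.norm(coords[i] - coords[j]))
                if d < MIN_POSITION_DIST - 1e-9:
                    raise ValueError(
                        f"motif positions {i},{j} only {d:.2f} Å apart"
                    )

    def coords(self) -> np.ndarray:
        return np.array([p[0] for p in self.positions])

    def __len__(self) -> int:
        return len(self.positions)


@dataclass
class SyntheticBenchmark:
    structures: list[ProteinStructure]
    labels: dict[str, bool]
    positive_motif: MotifTemplate
    negative_motif: MotifTemplate
    noise_sigma: float
    dropout: float
    confusability: float
    seed: int

    def write_to(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for s in self.structures:
            write_structure(s, out_dir / f"{s.id}.pdb")
        lines = ["id\tlabel"]
        for sid in sorted(self.labels):
            lines.append(f"{sid}\t{'interacting' if self.labels[sid] else 'non-interacting'}")
        (out_dir / "labels.tsv").write_text("\n".join(lines) + "\n")
        truth = {
            "seed": self.seed,
            "noise_sigma": self.noise_sigma,
            "dropout": self.dropout,
            "confusability": self.confusability,
            "positive_motif": _motif_to_dict(self.positive_motif),
            "negative_motif": _motif_to_dict(self.negative_motif),
        }
        (out_dir / "truth.json").write_text(json.dumps(truth, indent=1) + "\n")


def _motif_to_dict(m: MotifTemplate) -> dict:
    return {
        "id": m.id,
        "seed": m.seed,
        "positions": [
            {"coords": [float(x) for x in c], "element": e, "residue": r}
            for c, e, r in m.positions
        ],
    }


def _sample_point_in_ball(rng: np.random.Generator, radius: float) -> np.ndarray:
    while True:
        p = rng.uniform(-radius, radius, size=3)
        if np.linalg.norm(p) <= radius:
            return p


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation (quaternion method)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def make_motif(n_positions: int, seed: int, motif_id: str = "motif") -> MotifTemplate:
    """Rejection-sample a motif: spread points in a 10 Å ball with types."""
    if n_positions < 8:
        raise ValueError(f"need n_positions >= 8, got {n_positions}")
    rng = np.random.default_rng(seed)
    coords: list[np.ndarray] = []
    attempts = 0
    while len(coords) < n_positions:
        attempts += 1
        if attempts > 100000:
            raise RuntimeError("motif sampling failed to honor minimum distance")
        p = _sample_point_in_ball(rng, MOTIF_RADIUS / 2.0)
        if all(np.linalg.norm(p - q) >= MIN_POSITION_DIST for q in coords):
            coords.append(p)
    positions = [
        (c, str(rng.choice(ELEMENTS)), str(rng.choice(RESIDUES))) for c in coords
    ]
    return MotifTemplate(id=motif_id, positions=positions, seed=seed)


def embed_motif(
    motif: MotifTemplate,
    noise_sigma: float,
    dropout: float,
    scaffold_size: int | None = None,
    seed: int = 0,
    structure_id: str | None = None,
) -> ProteinStructure:
    """Plant a noisy motif copy inside a hollow scaffold shell.

    Per-coordinate Gaussian noise, independent position dropout
    (0 <= dropout < 0.5), type perturbation with probability 0.1, then a
    random rigid transform of the whole structure. Scaffold atoms stay at
    least 4 Å from motif atoms so the motif lines a closed cavity.
    """
    if not 0 <= dropout < 0.5:
        raise ValueError(f"dropout must be in [0, 0.5), got {dropout}")
    rng = np.random.default_rng(seed)
    sid = structure_id or f"{motif.id}_s{seed}"

    kept: list[tuple[np.ndarray, str, str]] = []
    for c, e, r in motif.positions:
        if rng.random() < dropout:
            continue
        cc = c + rng.normal(0.0, noise_sigma, size=3)
        if rng.random() < TYPE_PERTURB_PROB:
            e = str(rng.choice(ELEMENTS))
        if rng.random() < TYPE_PERTURB_PROB:
            r = str(rng.choice(RESIDUES))
        kept.append((cc, e, r))
    if len(kept) < 3:  # pathological dropout draw; keep first 3 positions
        kept = [(c.copy(), e, r) for c, e, r in motif.positions[:3]]

    motif_coords = np.array([c for c, _, _ in kept])
    center = motif_coords.mean(axis=0)
    # per-structure shell radius jitter: decoy walls of different members
    # must not stack up into spurious consensus positions
    r_inner = (
        float(np.max(np.linalg.norm(motif_coords - center, axis=1)))
        + SCAFFOLD_CLEARANCE
        + float(rng.uniform(0.0, 3.0))
    )
    if scaffold_size is None:
        # keep wall coverage roughly constant as the shell grows
        r_mid = r_inner + SHELL_THICKNESS / 2.0
        scaffold_size = int(0.045 * 4.0 * np.pi * r_mid**2)

    scaffold: list[np.ndarray] = []
    attempts = 0
    while len(scaffold) < scaffold_size and attempts < 200000:
        attempts += 1
        d = rng.normal(size=3)
        norm = np.linalg.norm(d)
        if norm < 1e-9:
            continue
        d /= norm
        radius = r_inner + rng.uniform(0.0, SHELL_THICKNESS)
        p = center + d * radius
        if any(np.linalg.norm(p - m) < SCAFFOLD_CLEARANCE for m in motif_coords):
            continue
        if any(np.linalg.norm(p - s) < SCAFFOLD_MIN_DIST for s in scaffold):
            continue
        scaffold.append(p)

    R = _random_rotation(rng)
    t = rng.uniform(-5.0, 5.0, size=3)

    atoms: list[AtomRecord] = []
    serial = 1
    resseq = 1
    for c, e, r in kept:
        atoms.append(AtomRecord(
            serial=serial, atom_name=e, element=e, residue_name=r,
            residue_seq=resseq, chain_id="A", coords=R @ c + t, is_hetero=False,
        ))
        serial += 1
        resseq += 1
    for p in scaffold:
        # Cbeta-like carbon pseudo-atoms; residue labels drawn at random so
        # decoy walls carry no consistent sequence signal across structures
        atoms.append(AtomRecord(
            serial=serial, atom_name="CB", element="C",
            residue_name=str(rng.choice(RESIDUES)),
            residue_seq=resseq, chain_id="A", coords=R @ p + t, is_hetero=False,
        ))
        serial += 1
        resseq += 1
    return ProteinStructure(id=sid, atoms=atoms)


def make_negative_motif(
    positive: MotifTemplate, confusability: float, seed: int,
) -> MotifTemplate:
    """A motif sharing round(confusability * n) positions with the positive.

    The shared positions are copied verbatim; the rest are resampled under
    the same min-distance constraint.
    """
    if not 0 <= confusability <= 1:
        raise ValueError(f"confusability must be in [0, 1], got {confusability}")
    n = len(positive)
    n_shared = int(round(confusability * n))
    rng = np.random.default_rng(seed)
    positions = [
        (c.copy(), e, r) for c, e, r in positive.positions[:n_shared]
    ]
    attempts = 0
    while len(positions) < n:
        attempts += 1
        if attempts > 100000:
            raise RuntimeError("negative motif sampling failed")
        p = _sample_point_in_ball(rng, MOTIF_RADIUS / 2.0)
        if all(np.linalg.norm(p - c) >= MIN_POSITION_DIST for c, _, _ in positions):
            positions.append((p, str(rng.choice(ELEMENTS)), str(rng.choice(RESIDUES))))
    return MotifTemplate(id=f"{positive.id}_neg", positions=positions, seed=seed)


def make_benchmark(
    n_pos: int,
    n_neg: int,
    noise_sigma: float = 0.3,
    dropout: float = 0.2,
    confusability: float = 0.0,
    seed: int = 0,
    n_motif_positions: int = 12,
    scaffold_size: int | None = None,
) -> SyntheticBenchmark:
    """Positive and negative structure sets with planted motifs."""
    if n_pos < 10 or n_neg < 10:
        raise ValueError("need n_pos, n_neg >= 10 for cross-validation use")
    pos_motif = make_motif(n_motif_positions, seed, motif_id="pos")
    neg_motif = make_negative_motif(pos_motif, confusability, seed + 1)

    structures: list[ProteinStructure] = []
    labels: dict[str, bool] = {}
    for i in range(n_pos):
        sid = f"P{i:03d}"
        structures.append(embed_motif(
            pos_motif, noise_sigma, dropout, scaffold_size,
            seed=seed * 100003 + 7 * i + 13, structure_id=sid,
        ))
        labels[sid] = True
    for i in range(n_neg):
        sid = f"N{i:03d}"
        structures.append(embed_motif(
            neg_motif, noise_sigma, dropout, scaffold_size,
            seed=seed * 100003 + 7 * (n_pos + i) + 13, structure_id=sid,
        ))
        labels[sid] = False
    return SyntheticBenchmark(
        structures=structures,
        labels=labels,
        positive_motif=pos_motif,
        negative_motif=neg_motif,
        noise_sigma=noise_sigma,
        dropout=dropout,
        confusability=confusability,
        seed=seed,
    )
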