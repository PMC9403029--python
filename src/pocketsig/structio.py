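"""File formats touched by the pipeline.

PDB structures (read/write), FASTA sequences, signature JSON files,
docking-score TSV tables and prediction TSV output.

PDB dialect: ATOM and HETATM records only; ANISOU/TER/CONECT ignored.
Model 1 only for multi-model files. Alternate locations resolved by
highest occupancy (tie: first in file). Element from columns 77-78,
falling back to the first alphabetic character of the atom name.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from Bio import SeqIO

SIGNATURE_SCHEMA_VERSION = 1

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


class PDBFormatError(ValueError):
    """Raised when a PDB file cannot be parsed under the supported dialect."""


class SignatureSchemaError(ValueError):
    """Raised when a signature file violates its declared schema."""


@dataclass
class AtomRecord:
    serial: int
    atom_name: str
    element: str
    residue_name: str
    residue_seq: int
    chain_id: str
    coords: np.ndarray  # shape (3,), Å
    is_hetero: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,):
            raise ValueError(f"coords must be a 3-vector, got {self.coords.shape}")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords must be finite")
        if not self.element:
            raise ValueError("element must be non-empty")


@dataclass
class ProteinStructure:
    """A parsed structure: ordered atoms plus derived views.

    ligand_groups maps (residue_name, chain_id, residue_seq) of each hetero
    residue to the indices of its atoms. chain_sequences holds the 1-letter
    polymer sequence per chain (unknown residues become 'X').
    """

    id: str
    atoms: list[AtomRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            raise ValueError(f"structure {self.id}: duplicate atom serials")
        if not any(not a.is_hetero for a in self.atoms):
            raise ValueError(f"structure {self.id}: no polymer (ATOM) atoms")

    @property
    def ligand_groups(self) -> dict[tuple[str, str, int], list[int]]:
        groups: dict[tuple[str, str, int], list[int]] = {}
        for i, a in enumerate(self.atoms):
            if a.is_hetero:
                key = (a.residue_name, a.chain_id, a.residue_seq)
                groups.setdefault(key, []).append(i)
        return groups

    @property
    def chain_sequences(self) -> dict[str, str]:
        seqs: dict[str, list[str]] = {}
        seen: set[tuple[str, int]] = set()
        for a in self.atoms:
            if a.is_hetero:
                continue
            key = (a.chain_id, a.residue_seq)
            if key in seen:
                continue
            seen.add(key)
            seqs.setdefault(a.chain_id, []).append(
                THREE_TO_ONE.get(a.residue_name, "X")
            )
        return {c: "".join(r) for c, r in seqs.items()}

    def heavy_atom_indices(self, include_hetero: bool = False) -> list[int]:
        """Indices of non-hydrogen atoms; water always excluded."""
        out = []
        for i, a in enumerate(self.atoms):
            if a.element.upper() in ("H", "D"):
                continue
            if a.residue_name == "HOH":
                continue
            if a.is_hetero and not include_hetero:
                continue
            out.append(i)
        return out

    def coords_array(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)


def _guess_element(atom_name: str) -> str:
    for ch in atom_name:
        if ch.isalpha():
            return ch.upper()
    return ""


def read_structure(path: str | Path, structure_id: str | None = None) -> ProteinStructure:
    """Parse a PDB file into a ProteinStructure (model 1, best altlocs)."""
    path = Path(path)
    sid = structure_id or path.stem
    raw: list[tuple[int, str, float]] = []  # (lineno, line, occupancy)
    in_model = 0
    saw_model = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec.startswith("MODEL"):
                saw_model = True
                in_model += 1
                continue
            if rec.startswith("ENDMDL"):
                continue
            if rec not in ("ATOM  ", "HETATM"):
                continue
            if saw_model and in_model > 1:
                continue
            try:
                occ = float(line[54:60])
            except (ValueError, IndexError):
                occ = 1.0
            raw.append((lineno, line.rstrip("\n"), occ))

    if not any(ln.startswith("ATOM") for _, ln, _ in raw):
        raise PDBFormatError(f"{path}: no ATOM records found")

    # altloc resolution: keep highest occupancy per atom site, tie -> first
    best: dict[tuple, tuple[int, int, str, float]] = {}
    order = 0
    for lineno, line, occ in raw:
        altloc = line[16] if len(line) > 16 else " "
        key = (
            line[:6],
            line[12:16],  # atom name
            line[17:20],  # residue name
            line[21] if len(line) > 21 else " ",
            line[22:26],  # residue seq
        )
        if altloc.strip() == "":
            key = key + (order,)  # no altloc: always unique
        if key not in best or occ > best[key][3]:
            if key not in best:
                best[key] = (order, lineno, line, occ)
            else:
                best[key] = (best[key][0], lineno, line, occ)
        order += 1

    atoms: list[AtomRecord] = []
    for pos, lineno, line, _occ in sorted(best.values()):
        try:
            x = float(line[30:38])
            y = float(line[38:46])
            z = float(line[46:54])
        except (ValueError, IndexError) as exc:
            raise PDBFormatError(
                f"{path}:{lineno}: unparseable coordinate field"
            ) from exc
        try:
            serial = int(line[6:11])
        except ValueError:
            serial = len(atoms) + 1
        name = line[12:16].strip()
        element = line[76:78].strip() if len(line) >= 78 else ""
        if not element:
            element = _guess_element(name)
        if not element:
            raise PDBFormatError(f"{path}:{lineno}: cannot determine element")
        resname = line[17:20].strip()
        chain = line[21] if len(line) > 21 and line[21].strip() else "A"
        try:
            resseq = int(line[22:26])
        except (ValueError, IndexError):
            raise PDBFormatError(f"{path}:{lineno}: unparseable residue number")
        atoms.append(
            AtomRecord(
                serial=serial,
                atom_name=name,
                element=element.upper(),
                residue_name=resname,
                residue_seq=resseq,
                chain_id=chain,
                coords=np.array([x, y, z]),
                is_hetero=line.startswith("HETATM"),
            )
        )
    # serials may collide across altloc pruning of sloppy files; renumber dups
    if len({a.serial for a in atoms}) != len(atoms):
        for i, a in enumerate(atoms):
            a.serial = i + 1
    return ProteinStructure(id=sid, atoms=atoms)


def _fmt_coord(x: float) -> str:
    s = f"{x:8.3f}"
    if len(s) > 8:
        raise ValueError(f"coordinate {x} exceeds PDB field width")
    return s


def write_structure(structure: ProteinStructure, path: str | Path) -> None:
    """Write a ProteinStructure as a PDB file (ATOM/HETATM + END)."""
    lines = []
    for a in structure.atoms:
        rec = "HETATM" if a.is_hetero else "ATOM  "
        name = a.atom_name
        if len(name) < 4:
            name = f" {name:<3s}"
        xs, ys, zs = (_fmt_coord(c) for c in a.coords)
        lines.append(
            f"{rec}{a.serial:5d} {name:<4.4s} {a.residue_name:>3.3s} "
            f"{a.chain_id:1.1s}{a.residue_seq:4d}    "
            f"{xs}{ys}{zs}{1.0:6.2f}{0.0:6.2f}          {a.element:>2.2s}"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an id -> sequence map (order-preserving)."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"{path}: duplicate sequence id {rec.id!r}")
        out[rec.id] = str(rec.seq).upper()
    return out


# -- signature JSON ---------------------------------------------------------

def write_signature(signature, path: str | Path) -> None:
    """Serialize a StructuralSignature to JSON (schema v1, lossless)."""
    doc = {
        "schema_version": SIGNATURE_SCHEMA_VERSION,
        "drug_id": signature.drug_id,
        "polarity": signature.polarity,
        "n_structures": signature.n_structures,
        "preservation_cutoff": signature.preservation_cutoff,
        "params": signature.params.to_dict(),
        "positions": [
            {
                "index": p.index,
                "centroid": [float(c) for c in p.centroid],
                "atom_freqs": dict(p.atom_freqs),
                "res_freqs": dict(p.res_freqs),
                "preservation": p.preservation,
                "support": p.support,
            }
            for p in signature.positions
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")


def read_signature(path: str | Path):
    """Load a StructuralSignature written by write_signature."""
    from .signature import PositionProfile, StructuralSignature
    from .params import ScoringParams

    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise SignatureSchemaError(f"{path}: not valid JSON") from exc
    version = doc.get("schema_version")
    if version != SIGNATURE_SCHEMA_VERSION:
        raise SignatureSchemaError(
            f"{path}: schema version {version!r}, expected {SIGNATURE_SCHEMA_VERSION}"
        )
    for key in ("polarity", "positions", "n_structures", "preservation_cutoff"):
        if key not in doc:
            raise SignatureSchemaError(f"{path}: missing field {key!r}")
    if doc["polarity"] not in ("positive", "negative"):
        raise SignatureSchemaError(f"{path}: invalid polarity {doc['polarity']!r}")
    try:
        positions = [
            PositionProfile(
                index=p["index"],
                centroid=np.asarray(p["centroid"], dtype=float),
                atom_freqs=dict(p["atom_freqs"]),
                res_freqs=dict(p["res_freqs"]),
                preservation=float(p["preservation"]),
                support=int(p["support"]),
            )
            for p in doc["positions"]
        ]
        sig = StructuralSignature(
            drug_id=doc.get("drug_id", ""),
            polarity=doc["polarity"],
            positions=positions,
            n_structures=int(doc["n_structures"]),
            preservation_cutoff=float(doc["preservation_cutoff"]),
            params=ScoringParams.from_dict(doc.get("params", {})),
        )
    except SignatureSchemaError:
        raise
    except (ValueError, KeyError) as exc:
        raise SignatureSchemaError(f"{path}: invalid signature content: {exc}") from exc
    bad = [p.index for p in sig.positions if p.preservation < sig.preservation_cutoff]
    if bad:
        raise SignatureSchemaError(
            f"{path}: positions {bad} below recorded preservation cutoff "
            f"{sig.preservation_cutoff}"
        )
    return sig


# -- score tables and predictions -------------------------------------------

def read_score_table(path: str | Path) -> dict[str, float]:
    """Read a two-column TSV (id, docking score) into a map.

    Lines starting with '#' are skipped; a first line whose second field is
    non-numeric is treated as a header. Duplicate ids are an error.
    """
    out: dict[str, float] = {}
    with open(path) as fh:
        first = True
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                fields = line.split()
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            pid, raw = fields[0].strip(), fields[1].strip()
            try:
                score = float(raw)
            except ValueError:
                if first:
                    first = False
                    continue  # header
                raise ValueError(f"{path}:{lineno}: non-numeric score {raw!r}")
            first = False
            if pid in out:
                raise ValueError(f"{path}:{lineno}: duplicate id {pid!r}")
            out[pid] = score
    return out


PREDICTION_COLUMNS = [
    "id", "pocket_rank", "score_pos", "score_neg", "delta",
    "predicted", "docking_score", "significance",
]


def write_predictions(predictions: Iterable, path: str | Path) -> None:
    """Write Prediction records as a TSV with the documented column set."""
    def cell(v):
        if v is None:
            return ""
        if isinstance(v, bool):
            return "true" if v else "false"
        if isinstance(v, float):
            return "inf" if math.isinf(v) else f"{v:.6g}"
        return str(v)

    lines = ["\t".join(PREDICTION_COLUMNS)]
    for p in predictions:
        lines.append("\t".join(cell(v) for v in (
            p.protein_id, p.pocket_rank, p.score_positive, p.score_negative,
            p.delta, p.predicted, p.docking_score, p.significance,
        )))
    Path(path).write_text("\n".join(lines) + "\n")
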