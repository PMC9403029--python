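"""Structural signature construction.

Pocket sets are turned into a consensus signature by: pairwise alignment to
get a score matrix, average-linkage clustering for a guide tree, progressive
profile merging along the tree, and preservation-ratio pruning (positions
present in fewer than half the member structures are dropped; the cutoff is
raised stepwise while the signature exceeds the position cap).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np

from .align import (
    align_point_sets,
    align_point_sets_anchored,
    align_pockets,
    PocketAlignment,
)
from .params import ScoringParams
from .pockets import Pocket, detect_pockets
from .structio import ProteinStructure

MAX_SIGNATURE_ATOMS = 100
MIN_PRESERVATION = 0.5
CUTOFF_STEP = 0.05
MIN_POOLED = 4  # a merge contributing fewer pooled positions is rejected


@dataclass
class PositionProfile:
    """One consensus position: centroid plus type-frequency tables.

    Frequencies are fractions of member structures contributing that type at
    this position; preservation is the fraction contributing any atom at all.
    """

    index: int
    centroid: np.ndarray
    atom_freqs: dict[str, float]
    res_freqs: dict[str, float]
    preservation: float
    support: int

    def __post_init__(self) -> None:
        self.centroid = np.asarray(self.centroid, dtype=float)
        if not (0.0 < self.preservation <= 1.0 + 1e-12):
            raise ValueError(f"preservation {self.preservation} outside (0, 1]")
        if not self.atom_freqs or max(self.atom_freqs.values()) <= 0:
            raise ValueError("position needs a non-empty atom frequency table")
        for table in (self.atom_freqs, self.res_freqs):
            for t, f in table.items():
                if f > self.preservation + 1e-9:
                    raise ValueError(
                        f"frequency {f} of {t!r} exceeds preservation {self.preservation}"
                    )

    def modal_element(self) -> str:
        return min(self.atom_freqs, key=lambda e: (-self.atom_freqs[e], e))

    def modal_residue(self) -> str:
        return min(self.res_freqs, key=lambda r: (-self.res_freqs[r], r))


@dataclass
class StructuralSignature:
    drug_id: str
    polarity: str  # "positive" | "negative"
    positions: list[PositionProfile]
    n_structures: int
    preservation_cutoff: float
    params: ScoringParams = field(default_factory=ScoringParams)

    def __post_init__(self) -> None:
        if self.polarity not in ("positive", "negative"):
            raise ValueError(f"polarity must be positive|negative, got {self.polarity!r}")
        if len(self.positions) > MAX_SIGNATURE_ATOMS:
            raise ValueError(
                f"signature has {len(self.positions)} positions, cap is {MAX_SIGNATURE_ATOMS}"
            )
        low = [p.index for p in self.positions
               if p.preservation < self.preservation_cutoff - 1e-9]
        if low:
            raise ValueError(
                f"positions {low} below preservation cutoff {self.preservation_cutoff}"
            )

    def __eq__(self, other) -> bool:
        if not isinstance(other, StructuralSignature):
            return NotImplemented
        if (self.drug_id, self.polarity, self.n_structures) != (
            other.drug_id, other.polarity, other.n_structures
        ):
            return False
        if abs(self.preservation_cutoff - other.preservation_cutoff) > 1e-12:
            return False
        if len(self.positions) != len(other.positions):
            return False
        for a, b in zip(self.positions, other.positions):
            if a.index != b.index or a.support != b.support:
                return False
            if abs(a.preservation - b.preservation) > 1e-12:
                return False
            if not np.allclose(a.centroid, b.centroid, atol=1e-9):
                return False
            if a.atom_freqs.keys() != b.atom_freqs.keys():
                return False
            if a.res_freqs.keys() != b.res_freqs.keys():
                return False
            if any(abs(a.atom_freqs[k] - b.atom_freqs[k]) > 1e-12 for k in a.atom_freqs):
                return False
            if any(abs(a.res_freqs[k] - b.res_freqs[k]) > 1e-12 for k in a.res_freqs):
                return False
        return True


# -- pairwise score matrix ---------------------------------------------------

def pairwise_score_matrix(
    pockets: list[Pocket],
    structures: list[ProteinStructure],
    params: ScoringParams | None = None,
) -> np.ndarray:
    """Symmetric matrix of pairwise combined alignment scores, diagonal 0.

    Unalignable pairs get +inf (they merge last in the guide tree).
    """
    if len(pockets) < 2:
        raise ValueError("need at least 2 pockets for a pairwise matrix")
    if len(pockets) != len(structures):
        raise ValueError("pockets and structures must be parallel lists")
    params = params or ScoringParams()
    n = len(pockets)
    M = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            aln = align_pockets(pockets[i], structures[i], pockets[j], structures[j], params)
            M[i, j] = M[j, i] = aln.combined_score
    return M


# -- guide tree --------------------------------------------------------------

def guide_tree(matrix: np.ndarray) -> list[tuple[int, int, float]]:
    """Average-linkage (UPGMA) merge list.

    Leaves are 0..n-1; the i-th merge creates cluster n+i. Ties are broken by
    the lexicographically smallest (id, id) pair. Returns (a, b, height)
    triples with a < b.
    """
    M = np.asarray(matrix, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("matrix must be square")
    if not np.allclose(M, M.T, equal_nan=True):
        raise ValueError("matrix must be symmetric")
    n = M.shape[0]
    if n < 2:
        raise ValueError("need at least 2 items")
    dist: dict[tuple[int, int], float] = {
        (i, j): float(M[i, j]) for i in range(n) for j in range(i + 1, n)
    }
    size = {i: 1 for i in range(n)}
    active = set(range(n))
    merges: list[tuple[int, int, float]] = []
    next_id = n
    while len(active) > 1:
        best_pair = min(
            ((d, pair) for pair, d in dist.items()),
            key=lambda t: (t[0] if np.isfinite(t[0]) else np.inf, t[1]),
        )[1]
        a, b = best_pair
        h = dist.pop((a, b))
        merges.append((a, b, h))
        new = next_id
        next_id += 1
        active.discard(a)
        active.discard(b)
        for k in list(active):
            ka = (min(a, k), max(a, k))
            kb = (min(b, k), max(b, k))
            da, db = dist.pop(ka), dist.pop(kb)
            dist[(k, new)] = (size[a] * da + size[b] * db) / (size[a] + size[b])
        size[new] = size[a] + size[b]
        active.add(new)
    return merges


# -- progressive profiling ---------------------------------------------------

@dataclass
class _RawPosition:
    centroid: np.ndarray
    support: int
    atom_counts: dict[str, int]
    res_counts: dict[str, int]


@dataclass
class _Cluster:
    positions: list[_RawPosition]
    member_ids: list[str]

    @property
    def n_members(self) -> int:
        return len(self.member_ids)


def _leaf_cluster(pocket: Pocket, structure: ProteinStructure) -> _Cluster:
    coords = pocket.coords(structure)
    elements = pocket.elements(structure)
    residues = pocket.residues(structure)
    positions = [
        _RawPosition(
            centroid=coords[i].copy(),
            support=1,
            atom_counts={elements[i]: 1},
            res_counts={residues[i]: 1},
        )
        for i in range(len(coords))
    ]
    return _Cluster(positions=positions, member_ids=[structure.id])


def _cluster_profile_tables(cluster: _Cluster) -> tuple[list[dict], list[dict]]:
    n = cluster.n_members
    atom = [{e: c / n for e, c in p.atom_counts.items()} for p in cluster.positions]
    res = [{r: c / n for r, c in p.res_counts.items()} for p in cluster.positions]
    return atom, res


def _merge_clusters(
    small: _Cluster, large: _Cluster, params: ScoringParams,
) -> tuple[_Cluster, list[str]]:
    """Align the smaller profile onto the larger and pool positions.

    Returns (merged cluster, dropped member ids). On alignment failure the
    smaller branch's members are dropped with a warning.
    """
    q_coords = np.array([p.centroid for p in small.positions])
    q_elems = [
        min(p.atom_counts, key=lambda e: (-p.atom_counts[e], e)) for p in small.positions
    ]
    q_res = [
        min(p.res_counts, key=lambda r: (-p.res_counts[r], r)) for p in small.positions
    ]
    ref_coords = np.array([p.centroid for p in large.positions])
    atom_freqs, res_freqs = _cluster_profile_tables(large)
    if large.n_members > 1:
        # anchor on the emerging conserved cores: high-support positions of
        # both profiles (a leaf has no core; its whole pocket is used)
        anchor = sorted(
            range(len(large.positions)),
            key=lambda i: (-large.positions[i].support, i),
        )[:24]
        q_anchor = None
        if small.n_members > 1:
            q_anchor = sorted(
                range(len(small.positions)),
                key=lambda i: (-small.positions[i].support, i),
            )[:24]
        aln = align_point_sets_anchored(
            q_coords, q_elems, q_res, ref_coords, atom_freqs, res_freqs,
            anchor, params, query_anchor=q_anchor,
        )
    else:
        aln = align_point_sets(
            q_coords, q_elems, q_res, ref_coords, atom_freqs, res_freqs, params
        )
    if not aln.is_valid:
        warnings.warn(
            f"profile merge failed for members {small.member_ids}; dropped"
        )
        return large, list(small.member_ids)
    min_pooled = min(
        MIN_POOLED, len(small.positions) // 2, len(large.positions) // 2
    )

    # pool only tight correspondences; a loose match under the alignment
    # threshold is evidence of proximity, not of the same consensus position.
    # The transform is re-fit on the tight pairs so that loose decoy matches
    # cannot drag the consensus off the conserved core.
    from .align import kabsch_superpose

    large_res = [
        min(p.res_counts, key=lambda r: (-p.res_counts[r], r)) for p in large.positions
    ]

    def _poolable(q: int, r: int, d: float) -> bool:
        if d > params.pool_distance:
            return False
        # a loose geometric match must be corroborated by residue agreement
        return d <= 0.6 * params.pool_distance or q_res[q] == large_res[r]

    R, t = aln.rotation, aln.translation
    matched_small: dict[int, int] = {}
    for _ in range(3):
        moved = q_coords @ R.T + t
        tight = {
            q: r
            for q, r in aln.correspondences
            if _poolable(q, r, float(np.linalg.norm(moved[q] - ref_coords[r])))
        }
        if tight == matched_small:
            break
        matched_small = tight
        if len(tight) >= 3:
            try:
                R, t, _ = kabsch_superpose(
                    q_coords[list(tight)], ref_coords[[tight[q] for q in tight]]
                )
            except ValueError:
                break
    moved = q_coords @ R.T + t
    if len(matched_small) < min_pooled:
        warnings.warn(
            f"merge of {small.member_ids} pooled only {len(matched_small)} "
            f"positions; branch dropped"
        )
        return large, list(small.member_ids)
    new_positions: list[_RawPosition] = []
    merged_into: dict[int, _RawPosition] = {}
    for r_idx, p in enumerate(large.positions):
        np_pos = _RawPosition(
            centroid=p.centroid.copy(),
            support=p.support,
            atom_counts=dict(p.atom_counts),
            res_counts=dict(p.res_counts),
        )
        new_positions.append(np_pos)
        merged_into[r_idx] = np_pos
    for q_idx, sp in enumerate(small.positions):
        if q_idx in matched_small:
            tgt = merged_into[matched_small[q_idx]]
            total = tgt.support + sp.support
            tgt.centroid = (tgt.centroid * tgt.support + moved[q_idx] * sp.support) / total
            tgt.support = total
            for e, c in sp.atom_counts.items():
                tgt.atom_counts[e] = tgt.atom_counts.get(e, 0) + c
            for r, c in sp.res_counts.items():
                tgt.res_counts[r] = tgt.res_counts.get(r, 0) + c
        else:
            new_positions.append(
                _RawPosition(
                    centroid=moved[q_idx].copy(),
                    support=sp.support,
                    atom_counts=dict(sp.atom_counts),
                    res_counts=dict(sp.res_counts),
                )
            )
    member_ids = sorted(large.member_ids + small.member_ids)
    return _Cluster(positions=new_positions, member_ids=member_ids), []


def progressive_profile(
    pockets: list[Pocket],
    structures: list[ProteinStructure],
    tree: list[tuple[int, int, float]],
    params: ScoringParams | None = None,
) -> tuple[list[PositionProfile], int, list[str]]:
    """Merge pockets leaf-to-root along the guide tree into position profiles.

    Returns (profiles, n_structures, dropped member ids). Frequencies and
    preservations are normalized by the number of members that merged
    successfully; members whose merge fails are dropped with a warning.
    """
    params = params or ScoringParams()
    n = len(pockets)
    if len(tree) != n - 1:
        raise ValueError("tree must contain exactly n-1 merges")
    clusters: dict[int, _Cluster] = {
        i: _leaf_cluster(pockets[i], structures[i]) for i in range(n)
    }
    dropped: list[str] = []
    next_id = n
    for a, b, _h in tree:
        ca, cb = clusters.pop(a), clusters.pop(b)
        # smaller profile aligned onto larger; ties by members then min id
        key_a = (len(ca.positions), ca.n_members, min(ca.member_ids))
        key_b = (len(cb.positions), cb.n_members, min(cb.member_ids))
        small, large = (ca, cb) if key_a <= key_b else (cb, ca)
        merged, drop = _merge_clusters(small, large, params)
        dropped.extend(drop)
        clusters[next_id] = merged
        next_id += 1
    root = clusters.popitem()[1]
    n_structures = root.n_members
    if n_structures < 2:
        raise ValueError("fewer than 2 members survived profiling")
    profiles = [
        PositionProfile(
            index=i,
            centroid=p.centroid,
            atom_freqs={e: c / n_structures for e, c in sorted(p.atom_counts.items())},
            res_freqs={r: c / n_structures for r, c in sorted(p.res_counts.items())},
            preservation=p.support / n_structures,
            support=p.support,
        )
        for i, p in enumerate(root.positions)
    ]
    return profiles, n_structures, dropped


def _refine_profiles(
    pockets: list[Pocket],
    structures: list[ProteinStructure],
    profiles: list[PositionProfile],
    params: ScoringParams,
    rounds: int = 2,
) -> tuple[list[PositionProfile], int]:
    """Re-register every member against the provisional high-support core.

    Progressive merging is greedy: one mis-anchored merge fragments a
    conserved position into copies with split support. Re-aligning each
    member pocket to the emerging core and re-estimating support,
    frequencies and centroids from scratch concentrates support back onto
    the consistently placed copies; a second round uses the improved core.
    Members that fail to re-register do not count toward the denominators.
    """
    core = [p for p in profiles if p.support >= 2]
    core.sort(key=lambda p: (-p.support, p.index))
    core = core[:60]
    if len(core) < 3:
        return profiles, 0

    raw = [
        _RawPosition(
            centroid=p.centroid.copy(),
            support=p.support,
            atom_counts={},  # filled per round
            res_counts={},
        )
        for p in core
    ]
    # frequency tables for scoring come from the original profiles
    tables = [(dict(p.atom_freqs), dict(p.res_freqs)) for p in core]
    n_used = 0
    for _ in range(rounds):
        ref_coords = np.array([p.centroid for p in raw])
        atom_freqs = [t[0] for t in tables]
        res_freqs = [t[1] for t in tables]
        sub_min = min(params.min_aligned, max(3, (3 * len(raw)) // 4))
        reg_params = params if sub_min == params.min_aligned else _params_min(params, sub_min)

        counts = [
            {"support": 0, "atoms": {}, "res": {}, "csum": np.zeros(3)}
            for _ in raw
        ]
        n_used = 0
        for pocket, structure in zip(pockets, structures):
            q_coords = pocket.coords(structure)
            q_elems = pocket.elements(structure)
            q_res = pocket.residues(structure)
            aln = align_point_sets(
                q_coords, q_elems, q_res, ref_coords, atom_freqs, res_freqs,
                reg_params,
            )
            if not aln.is_valid:
                continue
            moved = q_coords @ aln.rotation.T + aln.translation
            modal_res = [
                min(t[1], key=lambda x: (-t[1][x], x)) if t[1] else None
                for t in tables
            ]
            pooled = []
            for q, r in aln.correspondences:
                d = float(np.linalg.norm(moved[q] - ref_coords[r]))
                if d > params.pool_distance:
                    continue
                # loose matches need residue corroboration (as in merging)
                if d <= 0.6 * params.pool_distance or q_res[q] == modal_res[r]:
                    pooled.append((q, r))
            if len(pooled) < 3:
                continue
            n_used += 1
            for q, r in pooled:
                c = counts[r]
                c["support"] += 1
                c["atoms"][q_elems[q]] = c["atoms"].get(q_elems[q], 0) + 1
                c["res"][q_res[q]] = c["res"].get(q_res[q], 0) + 1
                c["csum"] += moved[q]
        if n_used < 2:
            return profiles, 0
        kept_raw, kept_tables = [], []
        for p, c, t in zip(raw, counts, tables):
            if c["support"] == 0:
                continue
            kept_raw.append(
                _RawPosition(
                    centroid=c["csum"] / c["support"],
                    support=c["support"],
                    atom_counts=dict(c["atoms"]),
                    res_counts=dict(c["res"]),
                )
            )
            kept_tables.append((
                {e: n / n_used for e, n in c["atoms"].items()},
                {r: n / n_used for r, n in c["res"].items()},
            ))
        if not kept_raw:
            return profiles, 0
        raw, tables = kept_raw, kept_tables

    refined = [
        PositionProfile(
            index=i,
            centroid=p.centroid,
            atom_freqs={e: c / n_used for e, c in sorted(p.atom_counts.items())},
            res_freqs={r: c / n_used for r, c in sorted(p.res_counts.items())},
            preservation=p.support / n_used,
            support=p.support,
        )
        for i, p in enumerate(raw)
    ]
    return refined, n_used


def _params_min(params: ScoringParams, min_aligned: int) -> ScoringParams:
    from dataclasses import replace as _replace

    return _replace(params, min_aligned=min_aligned)


# -- pruning -----------------------------------------------------------------

def prune(
    profiles: list[PositionProfile],
    min_preservation: float = MIN_PRESERVATION,
    max_atoms: int = MAX_SIGNATURE_ATOMS,
    *,
    drug_id: str = "",
    polarity: str = "positive",
    n_structures: int = 0,
    params: ScoringParams | None = None,
) -> StructuralSignature:
    """Apply the preservation cutoff and the position cap.

    The cutoff starts at ``min_preservation`` and rises in 0.05 steps while
    more than ``max_atoms`` positions survive; if stepping cannot get below
    the cap (ties), the highest-preservation positions are kept, ties broken
    by larger modal atom frequency then lower index.
    """
    if not profiles:
        raise ValueError("no profiles to prune")
    params = params or ScoringParams()
    cutoff = min_preservation
    kept = [p for p in profiles if p.preservation >= cutoff - 1e-12]
    if not kept:
        raise ValueError("no conserved core: all positions below preservation cutoff")
    while len(kept) > max_atoms:
        next_cutoff = round(cutoff + CUTOFF_STEP, 10)
        next_kept = [p for p in profiles if p.preservation >= next_cutoff - 1e-12]
        if not next_kept or next_cutoff > 1.0 + 1e-12:
            # ties: cap by preservation, then modal atom frequency, then index
            kept = sorted(
                kept,
                key=lambda p: (-p.preservation, -max(p.atom_freqs.values()), p.index),
            )[:max_atoms]
            break
        cutoff, kept = next_cutoff, next_kept

    # order positions by descending preservation, stable by original index
    kept = sorted(kept, key=lambda p: (-p.preservation, p.index))
    positions = [
        PositionProfile(
            index=i,
            centroid=p.centroid,
            atom_freqs=dict(p.atom_freqs),
            res_freqs=dict(p.res_freqs),
            preservation=p.preservation,
            support=p.support,
        )
        for i, p in enumerate(kept)
    ]
    return StructuralSignature(
        drug_id=drug_id,
        polarity=polarity,
        positions=positions,
        n_structures=n_structures,
        preservation_cutoff=cutoff,
        params=params,
    )


# -- end-to-end builders -----------------------------------------------------

def build_positive_signature(
    structures: list[ProteinStructure],
    binding_pockets: list[Pocket],
    params: ScoringParams | None = None,
    drug_id: str = "",
) -> StructuralSignature:
    """Pairwise matrix -> guide tree -> progressive profile -> prune."""
    return _build_signature(structures, binding_pockets, params, drug_id, "positive")


def _build_signature(
    structures: list[ProteinStructure],
    pockets: list[Pocket],
    params: ScoringParams | None,
    drug_id: str,
    polarity: str,
) -> StructuralSignature:
    if len(pockets) < 2:
        raise ValueError("need at least 2 pockets to build a signature")
    params = params or ScoringParams()
    M = pairwise_score_matrix(pockets, structures, params)
    tree = guide_tree(M)
    profiles, n_structures, _dropped = progressive_profile(pockets, structures, tree, params)
    refined, n_used = _refine_profiles(pockets, structures, profiles, params)
    if n_used >= 2:
        profiles, n_structures = refined, n_used
    return prune(
        profiles,
        drug_id=drug_id,
        polarity=polarity,
        n_structures=n_structures,
        params=params,
    )


def select_negative_pocket(
    structure: ProteinStructure,
    reference_binding_pocket: Pocket,
    reference_structure: ProteinStructure,
    params: ScoringParams | None = None,
    candidate_pockets: list[Pocket] | None = None,
) -> Pocket | None:
    """The structure's pocket most similar to the reference binding pocket.

    Returns None (with a warning) when no pocket aligns.
    """
    params = params or ScoringParams()
    if candidate_pockets is None:
        candidate_pockets = detect_pockets(structure)
    # a pocket "similar to the binding pocket" must be of comparable extent;
    # tiny cavities can otherwise win on a handful of lucky matches
    size_floor = max(params.min_aligned,
                     len(reference_binding_pocket.atom_indices) // 4)
    sized = [p for p in candidate_pockets if len(p.atom_indices) >= size_floor]
    if sized:
        candidate_pockets = sized
    best: Pocket | None = None
    best_key = None
    for p in candidate_pockets:
        aln = align_pockets(p, structure, reference_binding_pocket, reference_structure, params)
        if not aln.is_valid:
            continue
        key = (aln.combined_score, p.rank)
        if best_key is None or key < best_key:
            best, best_key = p, key
    if best is None:
        warnings.warn(
            f"structure {structure.id}: no pocket aligns to the reference; skipped"
        )
    return best


def build_negative_signature(
    structures: list[ProteinStructure],
    reference_binding_pocket: Pocket,
    reference_structure: ProteinStructure,
    params: ScoringParams | None = None,
    drug_id: str = "",
    candidate_pockets: dict[str, list[Pocket]] | None = None,
) -> StructuralSignature:
    """Per-structure most-binding-pocket-like pocket, then the same pipeline."""
    params = params or ScoringParams()
    selected_structures: list[ProteinStructure] = []
    selected_pockets: list[Pocket] = []
    for s in structures:
        cands = candidate_pockets.get(s.id) if candidate_pockets else None
        p = select_negative_pocket(
            s, reference_binding_pocket, reference_structure, params, cands
        )
        if p is not None:
            selected_structures.append(s)
            selected_pockets.append(p)
    if len(selected_pockets) < 2:
        raise ValueError("need at least 2 negative structures with selectable pockets")
    return _build_signature(selected_structures, selected_pockets, params, drug_id, "negative")
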