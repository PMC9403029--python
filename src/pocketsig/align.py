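"""Sequence-order-independent pocket alignment and the combined score.

Correspondences between two atom sets (or an atom set and a signature's
position centroids) are searched geometrically: congruent-triangle seeds are
Kabsch-superposed and grown by iterated optimal bipartite assignment under a
distance threshold. The candidate minimizing

    combined = rmsd * N**(-1/3) + alpha * (1 - similarity / best_similarity)

is returned. For tiny inputs the search is exhaustive.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .params import ScoringParams
from .pockets import Pocket
from .structio import ProteinStructure

EXACT_MAX = 6  # exhaustive correspondence search up to this many points/side
_BIG = 1e9


# -- closed-form score components -------------------------------------------

def structural_score(rmsd: float, n: int) -> float:
    """rmsd * n^(-1/3); lower is better."""
    if n < 1:
        raise ValueError("undefined alignment: n must be >= 1")
    if rmsd < 0:
        raise ValueError(f"rmsd must be >= 0, got {rmsd}")
    return rmsd * float(n) ** (-1.0 / 3.0)


def sequence_score(similarity: float, best_similarity: float) -> float:
    """1 - similarity/best_similarity, in [0, 1]."""
    if best_similarity <= 0:
        raise ValueError("empty profile: best_similarity must be > 0")
    if similarity < 0 or similarity > best_similarity + 1e-12:
        raise ValueError(
            f"similarity {similarity} outside [0, {best_similarity}]"
        )
    return 1.0 - similarity / best_similarity

def combined_score(structural: float, sequence: float, alpha: float = 1.2) -> float:
    """structural + alpha * sequence."""
    if not np.isfinite(structural) or not np.isfinite(sequence):
        raise ValueError("score components must be finite")
    if sequence < -1e-12 or sequence > 1 + 1e-12:
        raise ValueError(f"sequence score {sequence} outside [0, 1]")
    return structural + alpha * sequence


# -- rigid superposition ------------------------------------------------------

def kabsch_superpose(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of P onto Q.

    Returns (rotation, translation, rmsd) with rotation a proper orthonormal
    matrix such that ``P @ rotation.T + translation`` best matches Q.
    Raises on degenerate (collinear) input.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("point sets must both be (n, 3)")
    if len(P) < 3:
        raise ValueError("need >= 3 point pairs")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    s = np.linalg.svd(P0, compute_uv=False)
    if s[1] < 1e-8 * max(1.0, s[0]):
        raise ValueError("degenerate (collinear) point set")
    H = P0.T @ Q0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    diff = (P @ R.T + t) - Q
    rmsd = float(np.sqrt((diff**2).sum() / len(P)))
    return R, t, rmsd


# -- alignment result ---------------------------------------------------------

@dataclass
class PocketAlignment:
    """A one-to-one correspondence between query atoms and reference positions."""

    correspondences: list[tuple[int, int]]  # (query atom idx, ref position idx)
    N: int
    rmsd: float
    rotation: np.ndarray
    translation: np.ndarray
    structural_score: float
    sequence_similarity: float
    best_sequence_similarity: float
    sequence_score: float
    combined_score: float

    def __post_init__(self) -> None:
        if self.N != len(self.correspondences):
            raise ValueError("N must equal the number of correspondences")
        qs = [q for q, _ in self.correspondences]
        rs = [r for _, r in self.correspondences]
        if len(set(qs)) != len(qs) or len(set(rs)) != len(rs):
            raise ValueError("correspondence must be one-to-one both ways")

    @property
    def is_valid(self) -> bool:
        return self.N > 0 and np.isfinite(self.combined_score)

    @classmethod
    def no_alignment(cls) -> "PocketAlignment":
        return cls(
            correspondences=[], N=0, rmsd=float("inf"),
            rotation=np.eye(3), translation=np.zeros(3),
            structural_score=float("inf"), sequence_similarity=0.0,
            best_sequence_similarity=0.0, sequence_score=1.0,
            combined_score=float("inf"),
        )


def _similarity_terms(
    correspondences: list[tuple[int, int]],
    query_elements: list[str],
    query_residues: list[str],
    ref_atom_freqs: list[dict],
    ref_res_freqs: list[dict],
) -> tuple[float, float]:
    sim = 0.0
    best = 0.0
    for q, r in correspondences:
        af, rf = ref_atom_freqs[r], ref_res_freqs[r]
        sim += af.get(query_elements[q], 0.0) + rf.get(query_residues[q], 0.0)
        best += max(af.values()) + max(rf.values())
    return sim, best


def _finish(
    correspondences: list[tuple[int, int]],
    query_coords: np.ndarray,
    ref_coords: np.ndarray,
    query_elements: list[str],
    query_residues: list[str],
    ref_atom_freqs: list[dict],
    ref_res_freqs: list[dict],
    alpha: float,
) -> PocketAlignment | None:
    """Superpose on the matched set and assemble a scored alignment."""
    correspondences = sorted(correspondences)
    P = query_coords[[q for q, _ in correspondences]]
    Q = ref_coords[[r for _, r in correspondences]]
    try:
        R, t, rmsd = kabsch_superpose(P, Q)
    except ValueError:
        return None
    n = len(correspondences)
    ss = structural_score(rmsd, n)
    sim, best = _similarity_terms(
        correspondences, query_elements, query_residues,
        ref_atom_freqs, ref_res_freqs,
    )
    if best <= 0:
        return None
    seq = sequence_score(sim, best)
    return PocketAlignment(
        correspondences=correspondences, N=n, rmsd=rmsd,
        rotation=R, translation=t,
        structural_score=ss, sequence_similarity=sim,
        best_sequence_similarity=best, sequence_score=seq,
        combined_score=combined_score(ss, seq, alpha),
    )


def _candidate_key(aln: PocketAlignment) -> tuple:
    return (round(aln.combined_score, 9), -aln.N, tuple(aln.correspondences))


def _max_dist_ok(aln: PocketAlignment, query_coords, ref_coords, match_distance) -> bool:
    P = query_coords[[q for q, _ in aln.correspondences]]
    Q = ref_coords[[r for _, r in aln.correspondences]]
    d = np.linalg.norm(P @ aln.rotation.T + aln.translation - Q, axis=1)
    return bool(np.all(d <= match_distance + 1e-9))


def _exact_search(
    query_coords, ref_coords, query_elements, query_residues,
    ref_atom_freqs, ref_res_freqs, params: ScoringParams,
) -> PocketAlignment:
    nq, nr = len(query_coords), len(ref_coords)
    kmin = max(3, params.min_aligned)
    best: PocketAlignment | None = None
    best_key = None
    for k in range(kmin, min(nq, nr) + 1):
        for qsub in itertools.combinations(range(nq), k):
            for rperm in itertools.permutations(range(nr), k):
                corr = list(zip(qsub, rperm))
                aln = _finish(
                    corr, query_coords, ref_coords, query_elements,
                    query_residues, ref_atom_freqs, ref_res_freqs, params.alpha,
                )
                if aln is None:
                    continue
                if not _max_dist_ok(aln, query_coords, ref_coords, params.match_distance):
                    continue
                key = _candidate_key(aln)
                if best_key is None or key < best_key:
                    best, best_key = aln, key
    return best if best is not None else PocketAlignment.no_alignment()


def _farthest_point_subset(coords: np.ndarray, k: int) -> list[int]:
    """Deterministic well-spread subset (ties broken by lowest index)."""
    n = len(coords)
    if n <= k:
        return list(range(n))
    centroid = coords.mean(axis=0)
    d0 = np.linalg.norm(coords - centroid, axis=1)
    selected = [int(np.argmax(np.round(d0, 9)))]
    mind = np.linalg.norm(coords - coords[selected[0]], axis=1)
    while len(selected) < k:
        nxt = int(np.argmax(np.round(mind, 9)))
        selected.append(nxt)
        mind = np.minimum(mind, np.linalg.norm(coords - coords[nxt], axis=1))
    return sorted(selected)


def _triangles(coords: np.ndarray, subset: list[int]) -> tuple[np.ndarray, np.ndarray]:
    """All non-degenerate triangles among subset: (index triples, sorted sides)."""
    triples = np.array(list(itertools.combinations(subset, 3)), dtype=int)
    if len(triples) == 0:
        return np.empty((0, 3), int), np.empty((0, 3))
    a = coords[triples[:, 0]]
    b = coords[triples[:, 1]]
    c = coords[triples[:, 2]]
    sides = np.column_stack([
        np.linalg.norm(a - b, axis=1),
        np.linalg.norm(a - c, axis=1),
        np.linalg.norm(b - c, axis=1),
    ])
    area = 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)
    ok = (sides.min(axis=1) >= 1.0) & (area >= 0.1)
    return triples[ok], sides[ok]


_PERMS3 = list(itertools.permutations(range(3)))
# side index within the sides triple: 0=(0,1), 1=(0,2), 2=(1,2)
_SIDE_OF = {frozenset((0, 1)): 0, frozenset((0, 2)): 1, frozenset((1, 2)): 2}
# for each vertex permutation, the reference side matching query side k
_PERM_SIDE = [
    [_SIDE_OF[frozenset((perm[va], perm[vb]))] for va, vb in ((0, 1), (0, 2), (1, 2))]
    for perm in _PERMS3
]
_MAX_PAIRS_SCANNED = 800


def _match_triangles(
    qt, qsides, rt, rsides,
    q_elems: list[str] | None, r_elems: list[str] | None,
    tol: float, cap: int,
) -> list[tuple[float, tuple[tuple[int, int], ...]]]:
    """Congruent triangle pairs as (discrepancy, 3-pair correspondence).

    When element lists are given, matched vertices must agree on element.
    """
    if len(qt) == 0 or len(rt) == 0:
        return []
    qsort = np.sort(qsides, axis=1)
    rsort = np.sort(rsides, axis=1)
    diff = np.abs(qsort[:, None, :] - rsort[None, :, :]).max(axis=2)
    qi, ri = np.nonzero(diff <= tol)
    if len(qi) == 0:
        return []
    order = np.argsort(diff[qi, ri], kind="stable")
    qi, ri = qi[order], ri[order]
    seeds: list[tuple[float, tuple[tuple[int, int], ...]]] = []
    seen: set[tuple] = set()
    for q_idx, r_idx in zip(qi[:_MAX_PAIRS_SCANNED], ri[:_MAX_PAIRS_SCANNED]):
        qs, rs = qsides[q_idx], rsides[r_idx]
        qtri, rtri = qt[q_idx], rt[r_idx]
        for perm, psides in zip(_PERMS3, _PERM_SIDE):
            # vertex v of the query triangle maps to vertex perm[v] of ref
            if q_elems is not None and (
                q_elems[qtri[0]] != r_elems[rtri[perm[0]]]
                or q_elems[qtri[1]] != r_elems[rtri[perm[1]]]
                or q_elems[qtri[2]] != r_elems[rtri[perm[2]]]
            ):
                continue
            d0 = abs(qs[0] - rs[psides[0]])
            d1 = abs(qs[1] - rs[psides[1]])
            d2 = abs(qs[2] - rs[psides[2]])
            if d0 > tol or d1 > tol or d2 > tol:
                continue
            corr = tuple(sorted(
                (int(qtri[v]), int(rtri[perm[v]])) for v in range(3)
            ))
            if corr in seen:
                continue
            seen.add(corr)
            seeds.append((d0 + d1 + d2, corr))
        if len(seeds) >= cap:
            break
    seeds.sort(key=lambda s: (round(s[0], 9), s[1]))
    return seeds


def _rare_type_subset(elements: list[str], cap: int = 12) -> list[int]:
    """Atoms of under-represented elements (informative seed anchors)."""
    n = len(elements)
    counts: dict[str, int] = {}
    for e in elements:
        counts[e] = counts.get(e, 0) + 1
    thresh = max(3, int(np.ceil(0.25 * n)))
    rare = [i for i, e in enumerate(elements) if counts[e] <= thresh]
    rare.sort(key=lambda i: (counts[elements[i]], i))
    return rare[:cap]


_SMALL_REF = 24  # positions; below this, profile-guided seeding kicks in


def _profile_guided_seeds(
    query_coords: np.ndarray,
    query_elements: list[str],
    query_residues: list[str],
    ref_coords: np.ndarray,
    ref_atom_freqs: list[dict],
    ref_res_freqs: list[dict],
    params: ScoringParams,
) -> list[tuple[float, tuple[tuple[int, int], ...]]]:
    """Seeds against a small reference profile (e.g. a pruned signature).

    For every reference-position triangle, query atoms compatible with each
    position's frequency tables are tried as vertices, pruned by side-length
    agreement. Compatibility favours atoms the profile would actually score.
    """
    nq, nr = len(query_coords), len(ref_coords)
    tol = 2.0 * params.triangle_side_tol
    # per-position candidate query atoms, best-scoring first
    comp: list[list[int]] = []
    for r in range(nr):
        af, rf = ref_atom_freqs[r], ref_res_freqs[r]
        scored = []
        for q in range(nq):
            s = af.get(query_elements[q], 0.0) + rf.get(query_residues[q], 0.0)
            if s > 0:
                scored.append((-s, q))
        scored.sort()
        comp.append([q for _, q in scored[:15]])

    qd = cdist(query_coords, query_coords)
    rd = cdist(ref_coords, ref_coords)
    seeds: list[tuple[float, tuple[tuple[int, int], ...]]] = []
    seen: set[tuple] = set()
    for r0, r1, r2 in itertools.combinations(range(nr), 3):
        if min(rd[r0, r1], rd[r0, r2], rd[r1, r2]) < 1.0:
            continue
        for q0 in comp[r0]:
            for q1 in comp[r1]:
                if q1 == q0:
                    continue
                d01 = abs(qd[q0, q1] - rd[r0, r1])
                if d01 > tol:
                    continue
                for q2 in comp[r2]:
                    if q2 == q0 or q2 == q1:
                        continue
                    d02 = abs(qd[q0, q2] - rd[r0, r2])
                    if d02 > tol:
                        continue
                    d12 = abs(qd[q1, q2] - rd[r1, r2])
                    if d12 > tol:
                        continue
                    corr = tuple(sorted(((q0, r0), (q1, r1), (q2, r2))))
                    if corr in seen:
                        continue
                    seen.add(corr)
                    seeds.append((d01 + d02 + d12, corr))
        if len(seeds) > 4000:
            break
    seeds.sort(key=lambda s: (round(s[0], 9), s[1]))
    return seeds


def _seed_correspondences(
    query_coords: np.ndarray,
    query_elements: list[str],
    ref_coords: np.ndarray,
    ref_elements: list[str],
    params: ScoringParams,
) -> list[list[tuple[int, int]]]:
    """Congruent-triangle seeds: 3-pair correspondences.

    Two pools: element-matched triangles among rare-typed atoms (tried
    first — they anchor conserved motifs inside large pockets), then
    geometry-only triangles among a spread subset.
    """
    tol = params.triangle_side_tol
    cap = params.max_seeds * 4

    rare_seeds: list[tuple[float, tuple]] = []
    q_rare = _rare_type_subset(query_elements)
    r_rare = _rare_type_subset(ref_elements)
    if len(q_rare) >= 3 and len(r_rare) >= 3:
        qt, qs = _triangles(query_coords, q_rare)
        rt, rs = _triangles(ref_coords, r_rare)
        rare_seeds = _match_triangles(
            qt, qs, rt, rs, query_elements, ref_elements, tol, cap
        )
        if len(rare_seeds) < 8:
            # noisy copies of a sparse motif rarely stay congruent at the
            # strict tolerance; retry the typed pool with a relaxed one
            rare_seeds = _match_triangles(
                qt, qs, rt, rs, query_elements, ref_elements, 2.0 * tol, cap
            )

    qsub = _farthest_point_subset(query_coords, params.max_triangle_atoms)
    rsub = _farthest_point_subset(ref_coords, params.max_triangle_atoms)
    qt, qs = _triangles(query_coords, qsub)
    rt, rs = _triangles(ref_coords, rsub)
    spread_seeds = _match_triangles(qt, qs, rt, rs, None, None, tol, cap)

    out: list[list[tuple[int, int]]] = []
    seen: set[tuple] = set()
    budget_rare = min(len(rare_seeds), max(params.max_seeds // 2, params.max_seeds - len(spread_seeds)))
    for _, corr in rare_seeds[:budget_rare]:
        if corr not in seen:
            seen.add(corr)
            out.append(list(corr))
    for _, corr in spread_seeds:
        if len(out) >= params.max_seeds:
            break
        if corr not in seen:
            seen.add(corr)
            out.append(list(corr))
    return out


def _grow(
    seed: list[tuple[int, int]],
    query_coords: np.ndarray,
    ref_coords: np.ndarray,
    params: ScoringParams,
) -> list[tuple[int, int]] | None:
    """Iterated assignment growth of a 3-pair seed to a fixed point."""
    P = query_coords[[q for q, _ in seed]]
    Q = ref_coords[[r for _, r in seed]]
    try:
        R, t, _ = kabsch_superpose(P, Q)
    except ValueError:
        return None
    matched = None
    for _ in range(params.max_refine_iter):
        moved = query_coords @ R.T + t
        D = cdist(moved, ref_coords)
        cost = np.where(D <= params.match_distance, D, _BIG)
        rows, cols = linear_sum_assignment(cost)
        pairs = sorted(
            (int(q), int(r))
            for q, r in zip(rows, cols)
            if D[q, r] <= params.match_distance
        )
        if len(pairs) < 3:
            return None
        if pairs == matched:
            break
        matched = pairs
        P = query_coords[[q for q, _ in matched]]
        Q = ref_coords[[r for _, r in matched]]
        try:
            R, t, _ = kabsch_superpose(P, Q)
        except ValueError:
            return None
    return matched


def align_point_sets(
    query_coords: np.ndarray,
    query_elements: list[str],
    query_residues: list[str],
    ref_coords: np.ndarray,
    ref_atom_freqs: list[dict],
    ref_res_freqs: list[dict],
    params: ScoringParams | None = None,
) -> PocketAlignment:
    """Align typed query points to reference positions with frequency profiles.

    Exhaustive for tiny inputs (both sides <= 6 points), congruent-triangle
    seeding plus iterated assignment otherwise. Returns a no-alignment result
    (infinite score) when fewer than ``params.min_aligned`` positions match.
    """
    params = params or ScoringParams()
    query_coords = np.asarray(query_coords, dtype=float)
    ref_coords = np.asarray(ref_coords, dtype=float)
    nq, nr = len(query_coords), len(ref_coords)
    if min(nq, nr) < max(3, params.min_aligned):
        return PocketAlignment.no_alignment()

    if nq <= EXACT_MAX and nr <= EXACT_MAX:
        return _exact_search(
            query_coords, ref_coords, query_elements, query_residues,
            ref_atom_freqs, ref_res_freqs, params,
        )

    ref_elements = [
        min(t, key=lambda e: (-t[e], e)) if t else "" for t in ref_atom_freqs
    ]
    seeds = _seed_correspondences(
        query_coords, query_elements, ref_coords, ref_elements, params
    )
    if nr <= _SMALL_REF:
        guided = _profile_guided_seeds(
            query_coords, query_elements, query_residues,
            ref_coords, ref_atom_freqs, ref_res_freqs, params,
        )
        merged = [list(c) for _, c in guided[: params.max_seeds]]
        have = {tuple(s) for s in merged}
        merged.extend(s for s in seeds if tuple(s) not in have)
        seeds = merged
    # keep the top-priority seeds (typed/guided pools come first), then fill
    # the growth budget with the best of the rest by a cheap vote: how many
    # atoms land near a reference position under the 3-pair superposition
    if len(seeds) > params.max_grown:
        n_keep = params.max_grown // 2
        head, tail = seeds[:n_keep], seeds[n_keep:]
        ref_tree = cKDTree(ref_coords)
        voted = []
        for pos, seed in enumerate(tail):
            P = query_coords[[q for q, _ in seed]]
            Q = ref_coords[[r for _, r in seed]]
            try:
                R, t, _ = kabsch_superpose(P, Q)
            except ValueError:
                continue
            d, _ = ref_tree.query(query_coords @ R.T + t, k=1,
                                  distance_upper_bound=params.match_distance)
            voted.append((-int(np.isfinite(d).sum()), pos, seed))
        voted.sort(key=lambda v: (v[0], v[1]))
        seeds = head + [s for _, _, s in voted[: params.max_grown - n_keep]]

    best: PocketAlignment | None = None
    best_key = None
    tried: set[tuple] = set()
    for n_seen, seed in enumerate(seeds, start=1):
        matched = _grow(seed, query_coords, ref_coords, params)
        if matched is None or len(matched) < params.min_aligned:
            continue
        mkey = tuple(matched)
        if mkey in tried:
            continue
        tried.add(mkey)
        aln = _finish(
            matched, query_coords, ref_coords, query_elements,
            query_residues, ref_atom_freqs, ref_res_freqs, params.alpha,
        )
        if aln is None:
            continue
        key = _candidate_key(aln)
        if best_key is None or key < best_key:
            best, best_key = aln, key
        if (
            best is not None
            and n_seen >= params.early_stop_min_seeds
            and best.combined_score <= params.early_stop_score
        ):
            break
    return best if best is not None else PocketAlignment.no_alignment()


def align_point_sets_anchored(
    query_coords: np.ndarray,
    query_elements: list[str],
    query_residues: list[str],
    ref_coords: np.ndarray,
    ref_atom_freqs: list[dict],
    ref_res_freqs: list[dict],
    anchor: list[int],
    params: ScoringParams | None = None,
    query_anchor: list[int] | None = None,
) -> PocketAlignment:
    """Like align_point_sets, but the transform is found between anchor
    subsets before correspondences are grown against the full sets. Used for
    profile merging, where the high-support positions are far more reliable
    landmarks than the one-off ones.
    """
    params = params or ScoringParams()
    query_coords = np.asarray(query_coords, dtype=float)
    ref_coords = np.asarray(ref_coords, dtype=float)
    anchor = list(anchor)
    q_anchor = list(query_anchor) if query_anchor is not None else list(range(len(query_coords)))
    sub_min = min(params.min_aligned, max(3, (3 * min(len(anchor), len(q_anchor))) // 4))
    sub_params = params if sub_min == params.min_aligned else _params_with_min(params, sub_min)
    sub = align_point_sets(
        query_coords[q_anchor],
        [query_elements[i] for i in q_anchor],
        [query_residues[i] for i in q_anchor],
        ref_coords[anchor],
        [ref_atom_freqs[i] for i in anchor],
        [ref_res_freqs[i] for i in anchor],
        sub_params,
    )
    if sub.is_valid:
        seed = [(q_anchor[q], anchor[r]) for q, r in sub.correspondences]
        matched = _grow(seed, query_coords, ref_coords, params)
        if matched is not None and len(matched) >= params.min_aligned:
            aln = _finish(
                matched, query_coords, ref_coords, query_elements,
                query_residues, ref_atom_freqs, ref_res_freqs, params.alpha,
            )
            if aln is not None:
                return aln
    # no usable anchor alignment: fall back to the unrestricted search
    return align_point_sets(
        query_coords, query_elements, query_residues,
        ref_coords, ref_atom_freqs, ref_res_freqs, params,
    )


def _params_with_min(params: ScoringParams, min_aligned: int) -> ScoringParams:
    from dataclasses import replace as _replace

    return _replace(params, min_aligned=min_aligned)


def _pocket_arrays(pocket: Pocket, structure: ProteinStructure):
    coords = pocket.coords(structure)
    elements = pocket.elements(structure)
    residues = pocket.residues(structure)
    return coords, elements, residues


def align_pockets(
    pocket_a: Pocket,
    structure_a: ProteinStructure,
    pocket_b: Pocket,
    structure_b: ProteinStructure,
    params: ScoringParams | None = None,
) -> PocketAlignment:
    """Align pocket_a (query) to pocket_b (reference).

    The reference pocket acts as a single-member profile: a matched pair
    contributes 1 per matching atom type and 1 per matching residue type,
    and the best attainable similarity is 2 per aligned position.
    """
    ca, ea, ra = _pocket_arrays(pocket_a, structure_a)
    cb, eb, rb = _pocket_arrays(pocket_b, structure_b)
    atom_freqs = [{e: 1.0} for e in eb]
    res_freqs = [{r: 1.0} for r in rb]
    return align_point_sets(ca, ea, ra, cb, atom_freqs, res_freqs, params)


def align_to_signature(
    pocket: Pocket,
    structure: ProteinStructure,
    signature,
    params: ScoringParams | None = None,
) -> PocketAlignment:
    """Align a pocket to a signature's position centroids.

    Per aligned position, similarity adds the signature's stored frequency of
    the query atom's element and residue type; the best similarity adds the
    modal frequencies of the same positions.
    """
    if len(signature.positions) == 0:
        raise ValueError("signature has no positions")
    params = params or ScoringParams()
    # a signature smaller than min_aligned would otherwise demand a perfect
    # match of every position; cap the requirement at 3/4 of its size
    effective = min(params.min_aligned,
                    max(3, (3 * len(signature.positions)) // 4))
    if effective != params.min_aligned:
        from dataclasses import replace as _replace
        params = _replace(params, min_aligned=effective)
    coords, elements, residues = _pocket_arrays(pocket, structure)
    ref_coords = np.array([p.centroid for p in signature.positions])
    atom_freqs = [p.atom_freqs for p in signature.positions]
    res_freqs = [p.res_freqs for p in signature.positions]
    return align_point_sets(coords, elements, residues, ref_coords, atom_freqs, res_freqs, params)
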