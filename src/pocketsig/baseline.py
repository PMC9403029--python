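"""Sequence-similarity nearest-neighbor baseline and redundancy reduction.

Global Needleman-Wunsch alignment (BLOSUM62, gap open 10 / extend 0.5).
Similarity is the fraction of aligned residue pairs with a positive
substitution score, identity the fraction of identical pairs, both
normalized by the shorter sequence's length.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align
from Bio.Align import substitution_matrices

from .predict import EvalResult

VALID_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")
SIMILARITY_CUTOFF = 0.6


@dataclass
class LabeledSequence:
    id: str
    sequence: str
    label: bool  # True = interacting

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.id}: empty sequence")
        bad = set(self.sequence) - VALID_ALPHABET
        if bad:
            raise ValueError(f"{self.id}: invalid residue code(s) {sorted(bad)}")


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


_ALIGNER = _make_aligner()
_BLOSUM = substitution_matrices.load("BLOSUM62")


def _aligned_pairs(seq_a: str, seq_b: str):
    aln = _ALIGNER.align(seq_a, seq_b)[0]
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        for off in range(a1 - a0):
            yield seq_a[a0 + off], seq_b[b0 + off]


def global_similarity(seq_a: str, seq_b: str) -> float:
    """Fraction of aligned pairs with positive BLOSUM62 score (shorter-length norm)."""
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    positive = sum(1 for a, b in _aligned_pairs(seq_a, seq_b) if _BLOSUM[a, b] > 0)
    return positive / min(len(seq_a), len(seq_b))


def global_identity(seq_a: str, seq_b: str) -> float:
    """Fraction of identical aligned pairs, normalized by the shorter length."""
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    same = sum(1 for a, b in _aligned_pairs(seq_a, seq_b) if a == b)
    return same / min(len(seq_a), len(seq_b))


def loo_assign(
    sequences: list[LabeledSequence],
    cutoff: float = SIMILARITY_CUTOFF,
) -> tuple[dict[str, bool | None], EvalResult]:
    """Leave-one-out nearest-neighbor label assignment.

    Each left-out protein takes the label of its single most similar
    neighbor, provided that similarity strictly exceeds the cutoff; ties for
    the maximum, or no similarity above cutoff, leave it unassigned (None).
    The evaluation covers assigned proteins only.
    """
    if len(sequences) < 2:
        raise ValueError("need at least 2 sequences")
    labels = {s.label for s in sequences}
    if labels != {True, False}:
        raise ValueError("both labels must be present")
    ids = [s.id for s in sequences]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids")

    n = len(sequences)
    sim = [[0.0] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            s = global_similarity(sequences[i].sequence, sequences[j].sequence)
            sim[i][j] = sim[j][i] = s

    assigned: dict[str, bool | None] = {}
    tp = fp = tn = fn = 0
    for i, s in enumerate(sequences):
        others = [(sim[i][j], j) for j in range(n) if j != i]
        best = max(v for v, _ in others)
        if best <= cutoff:
            assigned[s.id] = None
            continue
        winners = {sequences[j].label for v, j in others if v == best}
        if len(winners) > 1:
            assigned[s.id] = None
            continue
        label = winners.pop()
        assigned[s.id] = label
        if label and s.label:
            tp += 1
        elif label and not s.label:
            fp += 1
        elif not label and not s.label:
            tn += 1
        else:
            fn += 1
    return assigned, EvalResult(tp=tp, fp=fp, tn=tn, fn=fn)


def reduce_redundancy(
    sequences: dict[str, str],
    identity_cutoff: float,
    mandatory_ids: set[str] | None = None,
) -> list[str]:
    """Greedy identity-based redundancy reduction.

    Mandatory ids are always kept (in sorted order), then the remaining
    sequences are considered by descending length (ties by id); a candidate
    is kept iff its identity to every already-kept sequence is below the
    cutoff. Mandatory members are exempt from the check themselves.
    """
    if not 0 < identity_cutoff <= 1:
        raise ValueError(f"identity cutoff must be in (0, 1], got {identity_cutoff}")
    mandatory_ids = mandatory_ids or set()
    unknown = mandatory_ids - set(sequences)
    if unknown:
        raise ValueError(f"mandatory id(s) not in sequence set: {sorted(unknown)}")
    kept: list[str] = sorted(mandatory_ids)
    rest = sorted(
        (sid for sid in sequences if sid not in mandatory_ids),
        key=lambda sid: (-len(sequences[sid]), sid),
    )
    for sid in rest:
        if all(
            global_identity(sequences[sid], sequences[k]) < identity_cutoff
            for k in kept
        ):
            kept.append(sid)
    return kept
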