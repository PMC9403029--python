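"""Target prediction, ranking, empirical significance and cross-validation.

A protein is predicted as a target when one of its top-k largest pockets
scores better (lower) against the positive signature than the same pocket
scores against the negative signature (score_positive - score_negative < 0).
Predicted targets are ranked by externally supplied docking scores, whose
significance is the fraction of random-structure scores at least as good.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .align import align_to_signature
from .params import ScoringParams
from .pockets import Pocket, detect_pockets, top_pockets
from .signature import (
    StructuralSignature,
    build_positive_signature,
    build_negative_signature,
)
from .structio import ProteinStructure

INF = float("inf")


@dataclass
class Prediction:
    protein_id: str
    pocket_rank: int  # 0 when no pocket could be scored
    score_positive: float
    score_negative: float
    delta: float
    predicted: bool
    docking_score: float | None = None
    significance: float | None = None

    def __post_init__(self) -> None:
        if math.isfinite(self.score_positive) and math.isfinite(self.score_negative):
            if abs(self.delta - (self.score_positive - self.score_negative)) > 1e-12:
                raise ValueError("delta must equal score_positive - score_negative")
        if self.predicted != (self.delta < 0):
            raise ValueError("predicted flag must equal (delta < 0)")


@dataclass
class EvalResult:
    tp: int
    fp: int
    tn: int
    fn: int
    fold_assignment: dict[str, int] = field(default_factory=dict)
    seed: int = 0

    @property
    def sensitivity(self) -> float:
        denom = self.tp + self.fn
        return self.tp / denom if denom else float("nan")

    @property
    def specificity(self) -> float:
        denom = self.tn + self.fp
        return self.tn / denom if denom else float("nan")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def score_protein(
    structure: ProteinStructure,
    pos_sig: StructuralSignature,
    neg_sig: StructuralSignature,
    params: ScoringParams | None = None,
    pockets: list[Pocket] | None = None,
) -> Prediction:
    """Score the top-k pockets against both signatures; report the best delta.

    The delta of each pocket is computed on the SAME pocket against both
    signatures; the pocket minimizing the delta is reported. Pockets that do
    not align get infinite scores: an unalignable positive side gives
    delta = +inf (non-target), an unalignable negative side with a finite
    positive score gives delta = -inf (the pocket is unlike the negatives).
    No scoreable pocket -> non-target with an infinite-delta sentinel.
    """
    params = params or ScoringParams()
    if pockets is None:
        try:
            pockets = detect_pockets(structure)
        except ValueError:
            pockets = []
    candidates = top_pockets(pockets, params.top_k_pockets) if pockets else []
    if not candidates:
        warnings.warn(f"{structure.id}: no detectable pockets; reported as non-target")

    best: tuple[float, int, float, float] | None = None  # (delta, rank, pos, neg)
    for p in candidates:
        pos = align_to_signature(p, structure, pos_sig, params).combined_score
        neg = align_to_signature(p, structure, neg_sig, params).combined_score
        if math.isfinite(pos) and math.isfinite(neg):
            delta = pos - neg
        elif not math.isfinite(pos):
            delta = INF
        else:
            delta = -INF
        key = (delta, p.rank, pos, neg)
        if best is None or key < best:
            best = key
    if best is None or best[0] == INF:
        rank = best[1] if best is not None else 0
        pos = best[2] if best is not None else INF
        neg = best[3] if best is not None else INF
        return Prediction(
            protein_id=structure.id, pocket_rank=rank,
            score_positive=pos, score_negative=neg,
            delta=INF, predicted=False,
        )
    delta, rank, pos, neg = best
    return Prediction(
        protein_id=structure.id, pocket_rank=rank,
        score_positive=pos, score_negative=neg,
        delta=delta, predicted=delta < 0,
    )


def prediction_from_scores(
    protein_id: str,
    score_positive: float,
    score_negative: float,
    pocket_rank: int = 1,
    docking_score: float | None = None,
) -> Prediction:
    """Apply the decision rule to externally supplied component scores."""
    delta = score_positive - score_negative
    return Prediction(
        protein_id=protein_id, pocket_rank=pocket_rank,
        score_positive=score_positive, score_negative=score_negative,
        delta=delta, predicted=delta < 0, docking_score=docking_score,
    )


def classify_positive_only(score_positive: float, cutoff: float = 0.85) -> bool:
    """Positive-signature-only decision: target iff score < cutoff (strict)."""
    return score_positive < cutoff


def rank_targets(
    predictions: list[Prediction],
    docking_scores: dict[str, float] | None = None,
) -> list[Prediction]:
    """Predicted targets sorted by ascending docking score.

    Targets without a docking score are kept but placed after scored ones
    (with a warning); ties break by ascending delta then id.
    """
    docking_scores = docking_scores or {}
    targets = []
    for p in predictions:
        if not p.predicted:
            continue
        ds = docking_scores.get(p.protein_id, p.docking_score)
        targets.append(replace(p, docking_score=ds))
    missing = [p.protein_id for p in targets if p.docking_score is None]
    if missing:
        warnings.warn(f"no docking score for predicted target(s): {missing}")
    return sorted(
        targets,
        key=lambda p: (
            p.docking_score is None,
            p.docking_score if p.docking_score is not None else 0.0,
            p.delta,
            p.protein_id,
        ),
    )


def empirical_significance(target_docking_score: float, random_scores: list[float]) -> float:
    """Fraction of random scores at least as good (<=) as the target's."""
    if not random_scores:
        raise ValueError("random score set must be non-empty")
    hits = sum(1 for r in random_scores if r <= target_docking_score)
    return hits / len(random_scores)


def annotate_significance(
    predictions: list[Prediction],
    random_scores: list[float],
    params: ScoringParams | None = None,
) -> list[Prediction]:
    """Attach empirical significance to every prediction with a docking score."""
    params = params or ScoringParams()
    if len(random_scores) < params.n_random_significance:
        raise ValueError(
            f"need >= {params.n_random_significance} random scores, "
            f"got {len(random_scores)}"
        )
    out = []
    for p in predictions:
        if p.docking_score is None:
            out.append(p)
        else:
            out.append(replace(
                p, significance=empirical_significance(p.docking_score, random_scores)
            ))
    return out


def evaluate(predictions: list[Prediction], truth: dict[str, bool]) -> EvalResult:
    """Confusion counts of predicted flags against boolean truth labels."""
    tp = fp = tn = fn = 0
    for p in predictions:
        if p.protein_id not in truth:
            raise ValueError(f"no truth label for {p.protein_id!r}")
        actual = truth[p.protein_id]
        if p.predicted and actual:
            tp += 1
        elif p.predicted and not actual:
            fp += 1
        elif not p.predicted and not actual:
            tn += 1
        else:
            fn += 1
    return EvalResult(tp=tp, fp=fp, tn=tn, fn=fn)


def stratified_folds(
    labels: dict[str, bool], folds: int, seed: int,
) -> dict[str, int]:
    """Seeded label-stratified fold assignment (fold ids 0..folds-1)."""
    rng = np.random.RandomState(seed)
    assignment: dict[str, int] = {}
    for value in (True, False):
        ids = sorted(k for k, v in labels.items() if v is value)
        rng.shuffle(ids)
        for i, sid in enumerate(ids):
            assignment[sid] = i % folds
    return assignment


def cross_validate(
    structures: list[ProteinStructure],
    labels: dict[str, bool],
    folds: int = 5,
    seed: int = 0,
    params: ScoringParams | None = None,
    mode: str = "pos+neg",
    pocket_cache: dict[str, list[Pocket]] | None = None,
    binding_pockets: dict[str, Pocket] | None = None,
) -> EvalResult:
    """Stratified k-fold cross-validation of the full pipeline.

    Per fold, both signatures are built on the training split only and the
    held-out proteins are scored with the requested decision rule
    ("pos+neg": delta < 0; "pos-only": score_positive < cutoff, the negative
    signature is never built). Confusion counts are pooled across folds.

    binding_pockets optionally maps positive structure ids to their known
    binding pocket; by default the rank-1 detected pocket is used.
    """
    params = params or ScoringParams()
    if mode not in ("pos+neg", "pos-only"):
        raise ValueError(f"unknown mode {mode!r}")
    n_pos = sum(1 for v in labels.values() if v)
    n_neg = sum(1 for v in labels.values() if not v)
    if n_pos < folds or n_neg < folds:
        raise ValueError(
            f"need >= {folds} structures per class, got {n_pos} positives / {n_neg} negatives"
        )
    by_id = {s.id: s for s in structures}
    missing = set(labels) - set(by_id)
    if missing:
        raise ValueError(f"no structure for labeled id(s): {sorted(missing)}")

    if pocket_cache is None:
        pocket_cache = {}
    for s in structures:
        if s.id not in pocket_cache:
            try:
                pocket_cache[s.id] = detect_pockets(s)
            except ValueError:
                pocket_cache[s.id] = []

    def positive_pocket(sid: str) -> Pocket | None:
        if binding_pockets and sid in binding_pockets:
            return binding_pockets[sid]
        plist = pocket_cache[sid]
        return plist[0] if plist else None

    assignment = stratified_folds(labels, folds, seed)
    tp = fp = tn = fn = 0
    for fold in range(folds):
        train_pos = sorted(
            sid for sid, f in assignment.items() if f != fold and labels[sid]
        )
        train_neg = sorted(
            sid for sid, f in assignment.items() if f != fold and not labels[sid]
        )
        test_ids = sorted(sid for sid, f in assignment.items() if f == fold)

        pos_structs, pos_pockets = [], []
        for sid in train_pos:
            p = positive_pocket(sid)
            if p is not None:
                pos_structs.append(by_id[sid])
                pos_pockets.append(p)
        if len(pos_pockets) < 2:
            raise ValueError(f"fold {fold}: too few positive pockets to build a signature")
        try:
            pos_sig = build_positive_signature(pos_structs, pos_pockets, params)
        except ValueError as exc:
            raise ValueError(f"fold {fold}: positive signature failed: {exc}") from exc

        neg_sig = None
        if mode == "pos+neg":
            ref_pocket, ref_struct = pos_pockets[0], pos_structs[0]
            neg_structs = [by_id[sid] for sid in train_neg]
            try:
                neg_sig = build_negative_signature(
                    neg_structs, ref_pocket, ref_struct, params,
                    candidate_pockets={s.id: pocket_cache[s.id] for s in neg_structs},
                )
            except ValueError as exc:
                raise ValueError(f"fold {fold}: negative signature failed: {exc}") from exc

        for sid in test_ids:
            s = by_id[sid]
            cands = top_pockets(pocket_cache[sid], params.top_k_pockets)
            if mode == "pos+neg":
                pred = score_protein(s, pos_sig, neg_sig, params, pockets=cands)
                predicted = pred.predicted
            else:
                best_pos = INF
                for p in cands:
                    sc = align_to_signature(p, s, pos_sig, params).combined_score
                    best_pos = min(best_pos, sc)
                predicted = classify_positive_only(best_pos, params.positive_only_cutoff)
            actual = labels[sid]
            if predicted and actual:
                tp += 1
            elif predicted and not actual:
                fp += 1
            elif not predicted and not actual:
                tn += 1
            else:
                fn += 1
    return EvalResult(tp=tp, fp=fp, tn=tn, fn=fn, fold_assignment=assignment, seed=seed)
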