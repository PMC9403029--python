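"""Scoring and pipeline parameters shared across modules."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


@dataclass(frozen=True)
class ScoringParams:
    """Knobs of the alignment/scoring pipeline.

    alpha
        Weight of the sequence term in the combined score.
    match_distance
        Maximum post-superposition distance (Å) for an accepted atom
        correspondence.
    min_aligned
        Minimum number of aligned positions for a valid alignment.
    positive_only_cutoff
        Score threshold for positive-signature-only classification.
    top_k_pockets
        Number of largest pockets scored per query protein.
    n_random_significance
        Minimum size of the random docking-score background.
    seed
        Seed for every stochastic step downstream.
    """

    alpha: float = 1.2
    match_distance: float = 2.0
    min_aligned: int = 8
    positive_only_cutoff: float = 0.85
    top_k_pockets: int = 3
    n_random_significance: int = 100
    seed: int = 0
    # alignment search budget (heuristic path only; exact path ignores these)
    max_seeds: int = 32
    max_grown: int = 12
    max_refine_iter: int = 20
    max_triangle_atoms: int = 18
    triangle_side_tol: float = 0.5
    early_stop_score: float = 0.3
    early_stop_min_seeds: int = 6
    # profile merging: matched positions closer than this are pooled into one
    # consensus position; looser matches stay separate positions
    pool_distance: float = 1.5

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ValueError(f"alpha must be > 0, got {self.alpha}")
        if not self.match_distance > 0:
            raise ValueError(f"match_distance must be > 0, got {self.match_distance}")
        if self.min_aligned < 3:
            raise ValueError(f"min_aligned must be >= 3, got {self.min_aligned}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ScoringParams":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter(s): {sorted(unknown)}")
        return cls(**d)


def load_params(path: str | Path) -> ScoringParams:
    """Load a ScoringParams snapshot from a YAML config file."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must hold a mapping")
    return ScoringParams.from_dict(data)
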