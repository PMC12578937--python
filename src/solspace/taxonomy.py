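"""Classification of an explored solution space into five structural types.

- **Single** — one valid partition, found repeatedly until the posterior
  stabilised.  The partition can be reported as representative.
- **Dominant** — several partitions, but one is probabilistically separated
  from all alternatives (its interval lower bound clears every other upper
  bound).
- **Multiple** — several comparable partitions with overlapping credible
  intervals and no lower bound above one half; no single run is
  representative.
- **Sparse** — nearly every trial produced a novel partition (the number of
  unique solutions is close to the trial count), each with low probability;
  often a sign of incoherent or absent community structure.
- **Empty** — no valid partition at all: every solution was structurally
  invalid (one big community, all singletons, internally disconnected) or,
  under the default policy, degenerate (more inter- than intra-community
  edges).

The boundary between Multiple and Sparse is inherently grey; it is drawn by
``sparse_ratio`` (default 0.8: at least 80% of counted trials produced novel
solutions) and always reported in the rationale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import bayes
from .explorer import ExplorationResult

__all__ = ["SpaceClassification", "classify", "symmetry_note", "LABELS"]

SINGLE = "SINGLE"
DOMINANT = "DOMINANT"
MULTIPLE = "MULTIPLE"
SPARSE = "SPARSE"
EMPTY = "EMPTY"

LABELS = (SINGLE, DOMINANT, MULTIPLE, SPARSE, EMPTY)


@dataclass
class SpaceClassification:
    label: str
    n_valid: int
    dominant_index: Optional[int] = None
    rationale: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")
        if (self.label == DOMINANT) != (self.dominant_index is not None):
            raise ValueError("dominant_index must be present iff label is DOMINANT")

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "n_valid": self.n_valid,
            "dominant_index": self.dominant_index,
            "rationale": list(self.rationale),
        }


def classify(
    result: ExplorationResult,
    treat_degenerate_as_invalid: bool = True,
    sparse_ratio: float = 0.8,
) -> SpaceClassification:
    """Assign exactly one of the five labels to an exploration result.

    Decision cascade: Empty (no valid solutions; degenerate ones count as
    invalid unless ``treat_degenerate_as_invalid=False``), then Single
    (stabilised with exactly one valid solution), then Dominant (separated
    with a valid dominant solution), then Sparse (the fraction of unique
    valid solutions over counted trials reaches ``sparse_ratio`` — a sparse
    space may stop either at the trial budget or by stabilising on many
    small, precise probabilities), else Multiple.
    """
    if not 0.0 < sparse_ratio <= 1.0:
        raise ValueError("sparse_ratio must be in (0, 1]")
    rationale: list[str] = []

    def invalid(v) -> bool:
        return (not v.is_valid) or (treat_degenerate_as_invalid and v.is_degenerate)

    valid_flags = [not invalid(v) for v in result.validity]
    n_valid = sum(valid_flags)
    counted_trials = result.model.t
    cause = result.termination.cause
    rationale.append(f"n_solutions={result.n_solutions}, n_valid={n_valid}, trials={counted_trials}, termination={cause}")

    if n_valid == 0:
        rationale.append("no valid solutions -> EMPTY")
        return SpaceClassification(EMPTY, 0, rationale=rationale)

    if n_valid == 1 and cause == bayes.STABILISATION:
        rationale.append("stabilised with exactly one valid solution -> SINGLE")
        return SpaceClassification(SINGLE, 1, rationale=rationale)

    if cause == bayes.SEPARATION:
        i_star = result.termination.dominant_index
        if i_star is not None and valid_flags[i_star]:
            rationale.append(f"separation with valid dominant solution {i_star} -> DOMINANT")
            return SpaceClassification(DOMINANT, n_valid, dominant_index=i_star, rationale=rationale)
        rationale.append("separation but dominant solution invalid; falling through")

    novelty = n_valid / counted_trials if counted_trials else 0.0
    rationale.append(f"novelty ratio n_valid/trials = {novelty:.3f} (sparse threshold {sparse_ratio})")
    if novelty >= sparse_ratio:
        rationale.append("nearly every trial novel -> SPARSE")
        return SpaceClassification(SPARSE, n_valid, rationale=rationale)

    # Multiple: report both of its defining conditions; overlap decides.
    if result.model.t >= 1 and result.model.k > 1:
        _, intervals = result.model.posterior()
        lo, hi = intervals[:, 0], intervals[:, 1]
        i_top = int(np.argmax(lo))
        overlap = lo[i_top] <= float(np.max(np.delete(hi, i_top)))
        max_lower_lt_half = float(np.max(lo)) < 0.5
        rationale.append(f"intervals overlapping={overlap}, max lower bound < 0.5: {max_lower_lt_half}")
        if overlap != max_lower_lt_half:
            rationale.append("note: the two Multiple conditions disagree; overlap decides")
    rationale.append("comparable solutions without separation -> MULTIPLE")
    return SpaceClassification(MULTIPLE, n_valid, rationale=rationale)


def symmetry_note(result: ExplorationResult, k_symmetric: int) -> str:
    """Diagnostic: is the observed maximum probability consistent with a
    ``k_symmetric``-fold symmetry, under which no solution should exceed
    roughly ``1/k``?  Consistency is judged by whether ``1/k`` lies inside
    the credible interval of the most probable solution.
    """
    if k_symmetric < 2:
        raise ValueError("k_symmetric must be at least 2")
    p_hat, intervals = result.model.posterior()
    i_max = int(np.argmax(p_hat))
    lo, hi = intervals[i_max]
    target = 1.0 / k_symmetric
    if lo <= target <= hi:
        return (
            f"consistent with {k_symmetric}-fold symmetry: max p_hat={p_hat[i_max]:.3f} "
            f"with interval [{lo:.3f}, {hi:.3f}] containing 1/{k_symmetric}={target:.3f}"
        )
    return (
        f"inconsistent with {k_symmetric}-fold symmetry: max p_hat={p_hat[i_max]:.3f} "
        f"with interval [{lo:.3f}, {hi:.3f}] excluding 1/{k_symmetric}={target:.3f}"
    )
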