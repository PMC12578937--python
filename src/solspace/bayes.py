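"""Sequential Dirichlet–Multinomial model over the unique solutions observed.

Each unique partition discovered during exploration is one category of a
multinomial whose probabilities are unknown.  With a symmetric Dirichlet
prior of concentration ``gamma0`` per category, the posterior after counts
``c = (c_1..c_k)`` over ``t = sum(c)`` trials is

    p | c  ~  Dirichlet(gamma0 + c_1, ..., gamma0 + c_k)

so the posterior mean of category i is ``(gamma0 + c_i) / (k*gamma0 + t)``
and its marginal is ``Beta(gamma0 + c_i, (k-1)*gamma0 + t - c_i)``, which
yields equal-tailed credible intervals.  The model is *expandable*: when a
novel solution appears a new category is added and the symmetric prior is
re-formed over the enlarged support, so the state depends on counts only
(observation order is irrelevant).

Two stopping predicates turn the posterior into a sequential stopping rule:

- *stabilisation* — every credible interval is narrower than a tolerance
  ``delta``: the probability estimates are as precise as required;
- *separation* — one category's interval lower bound exceeds every other
  category's upper bound: a single solution is unambiguously dominant.

With one known solution (k = 1) the posterior over that solution's
probability is a point mass at 1 (the model conditions on the observed
support), so stabilisation would fire immediately; a minimum trial count
``t_min`` guards against declaring convergence before the process has had a
realistic chance to surface alternatives.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

__all__ = ["NEW", "DirichletModel", "ConvergenceStatus"]


class _NewSolution:
    """Sentinel: the observed partition matched no existing category."""

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "NEW"


NEW = _NewSolution()

STABILISATION = "STABILISATION"
SEPARATION = "SEPARATION"
MAX_TRIALS = "MAX_TRIALS"
RUNNING = "RUNNING"


@dataclass(frozen=True)
class ConvergenceStatus:
    converged: bool
    cause: str  # STABILISATION | SEPARATION | MAX_TRIALS | RUNNING
    dominant_index: Optional[int] = None

    def __post_init__(self) -> None:
        if (self.cause == SEPARATION) != (self.dominant_index is not None):
            raise ValueError("dominant_index must be set iff cause is SEPARATION")


class DirichletModel:
    """Expandable Dirichlet–Multinomial posterior over observed solutions.

    Initialised with a single category and a weakly informative symmetric
    prior (``gamma0 = 1`` by default, the uniform prior), reflecting the
    belief that at least one solution exists.
    """

    def __init__(self, gamma0: float = 1.0, level: float = 0.95) -> None:
        if gamma0 <= 0:
            raise ValueError("gamma0 must be positive")
        if not 0.0 < level < 1.0:
            raise ValueError("credible level must be in (0, 1)")
        self.gamma0 = float(gamma0)
        self.level = float(level)
        self.counts: list[int] = [0]

    @property
    def k(self) -> int:
        return len(self.counts)

    @property
    def t(self) -> int:
        return sum(self.counts)

    def observe(self, index) -> "DirichletModel":
        """Record one trial outcome: an existing category index, or ``NEW``.

        The very first observation fills the initial category instead of
        expanding, so a fresh model after one trial has k = 1, c = (1).
        Returns ``self`` for chaining.
        """
        if index is NEW:
            if self.t == 0 and self.counts == [0]:
                self.counts[0] = 1
            else:
                self.counts.append(1)
        else:
            i = int(index)
            if not 0 <= i < self.k:
                raise IndexError(f"solution index {i} out of range for k={self.k}")
            self.counts[i] += 1
        return self

    def posterior(self) -> tuple[np.ndarray, np.ndarray]:
        """Posterior means and equal-tailed credible intervals.

        Returns ``(p_hat, intervals)`` with ``p_hat`` of shape (k,) summing
        to one and ``intervals`` of shape (k, 2).  With a single category the
        posterior is the point mass at 1 with a zero-width interval.
        Undefined before the first observation.
        """
        t = self.t
        if t < 1:
            raise ValueError("posterior is undefined before the first observation")
        c = np.asarray(self.counts, dtype=float)
        k = self.k
        p_hat = (self.gamma0 + c) / (k * self.gamma0 + t)
        if k == 1:
            return np.array([1.0]), np.array([[1.0, 1.0]])
        a = self.gamma0 + c
        b = (k - 1) * self.gamma0 + t - c
        alpha = 1.0 - self.level
        lo = stats.beta.ppf(alpha / 2.0, a, b)
        hi = stats.beta.ppf(1.0 - alpha / 2.0, a, b)
        return p_hat, np.column_stack([lo, hi])

    def check_convergence(self, delta: float, t_max: int, t_min: int = 10) -> ConvergenceStatus:
        """Evaluate the stopping predicates on the current posterior.

        Stabilisation (checked first, and only once ``t >= t_min``), then
        separation; ``MAX_TRIALS`` once ``t >= t_max`` with neither met.
        """
        if delta <= 0:
            raise ValueError("delta must be positive")
        if t_max < 1:
            raise ValueError("t_max must be at least 1")
        t = self.t
        if t < 1:
            return ConvergenceStatus(False, RUNNING)
        _, intervals = self.posterior()
        widths = intervals[:, 1] - intervals[:, 0]
        if t >= t_min and float(np.max(widths)) <= delta:
            return ConvergenceStatus(True, STABILISATION)
        if self.k > 1:
            lo = intervals[:, 0]
            hi = intervals[:, 1]
            i_star = int(np.argmax(lo))
            others_hi = np.delete(hi, i_star)
            if lo[i_star] > float(np.max(others_hi)):
                return ConvergenceStatus(True, SEPARATION, dominant_index=i_star)
        if t >= t_max:
            return ConvergenceStatus(False, MAX_TRIALS)
        return ConvergenceStatus(False, RUNNING)

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        return {"gamma0": self.gamma0, "level": self.level, "counts": list(self.counts)}

    @classmethod
    def from_dict(cls, d: dict) -> "DirichletModel":
        m = cls(gamma0=d["gamma0"], level=d["level"])
        counts = [int(c) for c in d["counts"]]
        if not counts or any(c < 0 for c in counts):
            raise ValueError("counts must be a nonempty vector of nonnegative integers")
        m.counts = counts
        return m
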