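"""Laplace-mechanism primitives and privacy-budget accounting.

Everything here works under pure ``epsilon``-differential privacy
(``delta = 0``).  The neighboring-dataset convention is *unbounded* DP
(add/remove one record), under which a single count has l1 global
sensitivity 1; the bounded convention (sensitivity 2 for a count) is
available by passing ``sensitivity=2`` explicitly.

Laplace noise is generated by inverse-CDF transformation of a uniform
stream so that draws are bit-reproducible across platforms for a fixed
seeded generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PrivacyBudget",
    "LaplaceNoiseSpec",
    "BudgetLedger",
    "BudgetExhaustedError",
    "draw_laplace_noise",
    "sanitize_statistic",
    "allocate_budget",
    "sequential_composition",
    "parallel_composition",
]

_WEIGHT_TOL = 1e-12


class BudgetExhaustedError(RuntimeError):
    """Raised when a draw would exceed the total privacy budget."""


@dataclass(frozen=True)
class PrivacyBudget:
    """Total privacy loss and how it is divided.

    Parameters
    ----------
    epsilon_total : float
        Total privacy loss epsilon > 0 for the whole release.
    m : int
        Number of independent releases (sequential composition splits
        ``epsilon_total`` equally across them).
    stage_weights : tuple of float
        Nonnegative weights, summing to 1, allocating each release's
        share across pipeline stages (e.g. posterior draw vs statistic).
    delta : float
        Fixed at 0; pure epsilon-DP only.
    """

    epsilon_total: float
    m: int = 1
    stage_weights: tuple[float, ...] = (1.0,)
    delta: float = 0.0

    def __post_init__(self) -> None:
        if not self.epsilon_total > 0:
            raise ValueError("epsilon_total must be positive")
        if self.delta != 0.0:
            raise ValueError("only pure epsilon-DP (delta = 0) is supported")
        if int(self.m) != self.m or self.m < 1:
            raise ValueError("m must be a positive integer")
        w = np.asarray(self.stage_weights, dtype=float)
        if w.ndim != 1 or w.size == 0 or np.any(w < 0):
            raise ValueError("stage_weights must be nonnegative")
        if abs(w.sum() - 1.0) > _WEIGHT_TOL:
            raise ValueError(
                f"stage_weights must sum to 1 (got {w.sum()!r})"
            )

    @property
    def per_release(self) -> float:
        """Privacy loss available to each of the m releases."""
        return self.epsilon_total / self.m

    def share(self, stage: int) -> float:
        """Share for one (release, stage) pair: eps * w_s / m."""
        return self.epsilon_total * self.stage_weights[stage] / self.m


@dataclass(frozen=True)
class LaplaceNoiseSpec:
    """Sensitivity/epsilon pair fixing a Laplace noise scale.

    Invariant: ``scale == sensitivity / epsilon_share`` exactly.
    """

    sensitivity: float
    epsilon_share: float

    def __post_init__(self) -> None:
        if not self.sensitivity > 0:
            raise ValueError("sensitivity must be positive")
        if not self.epsilon_share > 0:
            raise ValueError("epsilon_share must be positive")

    @property
    def scale(self) -> float:
        return self.sensitivity / self.epsilon_share


def draw_laplace_noise(
    scale: float, count: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``count`` iid Laplace(0, scale) variates.

    Uses the inverse CDF  x = -b * sgn(u) * log(1 - 2|u|)  applied to
    u ~ Uniform(-1/2, 1/2), so a fixed seed reproduces draws exactly.
    """
    if not scale > 0:
        raise ValueError("scale must be positive")
    if int(count) != count or count < 1:
        raise ValueError("count must be a positive integer")
    u = rng.random(int(count)) - 0.5
    return -scale * np.sign(u) * np.log1p(-2.0 * np.abs(u))


def sanitize_statistic(
    values,
    sensitivity: float,
    epsilon_share: float,
    rng: np.random.Generator,
    ledger: "BudgetLedger | None" = None,
    stage: str = "statistic",
) -> np.ndarray:
    """Release values + Laplace noise at scale sensitivity/epsilon_share.

    Element-wise independent noise.  If a ``ledger`` is given the spend
    is recorded (and refused once the budget is exhausted).
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot sanitize an empty statistic")
    spec = LaplaceNoiseSpec(sensitivity=sensitivity, epsilon_share=epsilon_share)
    if ledger is not None:
        ledger.spend(stage, epsilon_share)
    noise = draw_laplace_noise(spec.scale, values.size, rng)
    return values + noise.reshape(values.shape)


def allocate_budget(budget: PrivacyBudget) -> np.ndarray:
    """Per-(release, stage) epsilon shares as an (m, n_stages) array.

    The equal split across releases is sequential composition made
    explicit: the m*n_stages shares sum back to ``epsilon_total``.
    """
    w = np.asarray(budget.stage_weights, dtype=float)
    shares = np.tile(budget.epsilon_total * w / budget.m, (budget.m, 1))
    # guard against floating drift so the ledger closes exactly
    shares *= budget.epsilon_total / shares.sum()
    return shares


def sequential_composition(epsilons) -> float:
    """Total loss of mechanisms applied to the *same* data: the sum."""
    eps = np.asarray(epsilons, dtype=float)
    if np.any(eps <= 0):
        raise ValueError("all epsilons must be positive")
    return float(eps.sum())


def parallel_composition(epsilons) -> float:
    """Total loss of mechanisms applied to *disjoint* data: the max."""
    eps = np.asarray(epsilons, dtype=float)
    if np.any(eps <= 0):
        raise ValueError("all epsilons must be positive")
    return float(eps.max())


@dataclass
class BudgetLedger:
    """Append-only record of privacy spending for one release set.

    Sequential-composition bookkeeping made executable: every noisy
    draw is logged with its stage label and epsilon share, and the
    ledger refuses draws once ``epsilon_total`` is exhausted.
    """

    epsilon_total: float
    entries: list[tuple[str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.epsilon_total > 0:
            raise ValueError("epsilon_total must be positive")

    @property
    def spent(self) -> float:
        return float(sum(share for _, share in self.entries))

    @property
    def remaining(self) -> float:
        return self.epsilon_total - self.spent

    def spend(self, stage: str, epsilon_share: float) -> None:
        if not epsilon_share > 0:
            raise ValueError("epsilon_share must be positive")
        # small relative tolerance: exact equality must not be refused
        if self.spent + epsilon_share > self.epsilon_total * (1 + 1e-9):
            raise BudgetExhaustedError(
                f"spending {epsilon_share} at stage {stage!r} would exceed "
                f"the total budget {self.epsilon_total} "
                f"(already spent {self.spent})"
            )
        self.entries.append((stage, float(epsilon_share)))

    def to_dict(self) -> dict:
        return {
            "epsilon_total": self.epsilon_total,
            "spent": self.spent,
            "entries": [
                {"stage": s, "epsilon_share": e} for s, e in self.entries
            ],
        }
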