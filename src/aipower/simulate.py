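"""Trinomial simulation of allele-specific RNA-seq read counts.

Each read drawn for a replicate originates from allele g1 with probability
``theta`` and from g2 otherwise.  A g1 read maps unambiguously to g1 with
probability ``r_g1`` (likewise ``r_g2`` for g2); otherwise it maps equally
well to both alleles and is recorded as ambiguous.  A replicate is therefore
a single multinomial draw over three categories:

* ``x`` — unambiguous g1 reads, probability ``theta * r_g1``;
* ``y`` — unambiguous g2 reads, probability ``(1 - theta) * r_g2``;
* ``z`` — ambiguous reads, the remainder.

``x + y`` are the allele-specific (informative) reads.  The simulator targets
a requested number of informative reads in expectation by drawing
``M = round(target / E[informative fraction])`` total reads, so the ambiguous
column keeps its natural sampling variation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .scenario import Scenario

__all__ = [
    "ReplicateCounts",
    "ExperimentData",
    "allele_specific_fraction",
    "simulate_replicate",
    "simulate_condition",
    "simulate_experiment",
    "split_reads",
    "experiment_rng",
]


@dataclass(frozen=True)
class ReplicateCounts:
    """Read counts for one biological replicate: unambiguous g1 (``x``),
    unambiguous g2 (``y``) and ambiguous (``z``) reads."""

    x: int
    y: int
    z: int

    def __post_init__(self) -> None:
        if min(self.x, self.y, self.z) < 0:
            raise ValueError("read counts must be nonnegative")

    @property
    def informative(self) -> int:
        return self.x + self.y

    @property
    def total(self) -> int:
        return self.x + self.y + self.z


@dataclass(frozen=True)
class ExperimentData:
    """Two-condition collection of replicate counts for one simulated dataset."""

    condition1: tuple[ReplicateCounts, ...]
    condition2: tuple[ReplicateCounts, ...]
    scenario: Optional[Scenario] = None
    sim_index: int = 0

    def condition(self, i: int) -> tuple[ReplicateCounts, ...]:
        if i == 1:
            return self.condition1
        if i == 2:
            return self.condition2
        raise ValueError(f"condition must be 1 or 2, got {i!r}")

    def swap_alleles(self) -> "ExperimentData":
        """Exchange the x and y columns in every replicate (g1 <-> g2)."""
        sw = lambda reps: tuple(ReplicateCounts(r.y, r.x, r.z) for r in reps)
        return ExperimentData(sw(self.condition1), sw(self.condition2),
                              self.scenario, self.sim_index)

    def swap_conditions(self) -> "ExperimentData":
        return ExperimentData(self.condition2, self.condition1,
                              self.scenario, self.sim_index)


def allele_specific_fraction(theta: float, r_g1: float, r_g2: float) -> float:
    """Expected fraction of drawn reads that are allele-specific,
    ``theta * r_g1 + (1 - theta) * r_g2``."""
    for name, v in (("theta", theta), ("r_g1", r_g1), ("r_g2", r_g2)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v!r}")
    return theta * r_g1 + (1.0 - theta) * r_g2


def simulate_replicate(
    n_as_target: int,
    theta: float,
    r_g1: float,
    r_g2: float,
    rng: np.random.Generator,
) -> ReplicateCounts:
    """Draw one replicate targeting ``n_as_target`` informative reads.

    The total draw size is ``round(n_as_target / allele_specific_fraction)``
    so that ``E[x + y] = n_as_target`` up to rounding, and the plug-in
    estimand ``(x/r_g1) / (x/r_g1 + y/r_g2)`` has expectation ``theta``.
    """
    if n_as_target < 1:
        raise ValueError("n_as_target must be >= 1")
    if not 0.0 < theta < 1.0:
        raise ValueError(f"theta must be in (0, 1), got {theta!r}")
    if not (0.0 < r_g1 <= 1.0 and 0.0 < r_g2 <= 1.0):
        raise ValueError("mapping probabilities must be in (0, 1]")
    frac = allele_specific_fraction(theta, r_g1, r_g2)
    if frac <= 0.0:
        raise ValueError("degenerate scenario: no informative reads possible")
    m = int(round(n_as_target / frac))
    p_x = theta * r_g1
    p_y = (1.0 - theta) * r_g2
    p_z = 1.0 - p_x - p_y
    x, y, z = rng.multinomial(m, [p_x, p_y, max(p_z, 0.0)])
    return ReplicateCounts(int(x), int(y), int(z))


def split_reads(n_reads_total: int, n_bioreps: int) -> list[int]:
    """Divide a read total across replicates, spreading any remainder over
    the first ``total mod k`` replicates so the printed total is preserved."""
    if n_bioreps < 1:
        raise ValueError("n_bioreps must be >= 1")
    base, rem = divmod(int(n_reads_total), int(n_bioreps))
    return [base + (1 if k < rem else 0) for k in range(n_bioreps)]


def simulate_condition(
    n_reads_total: int,
    n_bioreps: int,
    theta: float,
    r_g1: float,
    r_g2: float,
    rng: np.random.Generator,
) -> tuple[ReplicateCounts, ...]:
    """Simulate ``n_bioreps`` independent replicates whose informative-read
    targets sum to ``n_reads_total``."""
    targets = split_reads(n_reads_total, n_bioreps)
    return tuple(
        simulate_replicate(t, theta, r_g1, r_g2, rng) for t in targets
    )


def experiment_rng(seed: int, sim_index: int) -> np.random.Generator:
    """RNG stream for one simulated dataset.

    Streams are keyed by ``(seed, sim_index)`` through a ``SeedSequence`` so
    that any single dataset is reconstructible and results do not depend on
    how simulations are distributed across workers.
    """
    return np.random.default_rng(np.random.SeedSequence((int(seed), int(sim_index))))


def simulate_experiment(
    scenario: Scenario,
    rng: Optional[np.random.Generator] = None,
    sim_index: int = 0,
) -> ExperimentData:
    """Simulate one two-condition dataset for a scenario.

    If ``rng`` is omitted, the stream is derived from the scenario's seed and
    ``sim_index`` via :func:`experiment_rng`.
    """
    if rng is None:
        rng = experiment_rng(scenario.seed, sim_index)
    c1 = simulate_condition(
        scenario.n_reads_total, scenario.n_bioreps, scenario.theta1,
        scenario.r_g1, scenario.r_g2, rng,
    )
    c2 = simulate_condition(
        scenario.n_reads_total, scenario.n_bioreps, scenario.theta2,
        scenario.r_g1, scenario.r_g2, rng,
    )
    return ExperimentData(c1, c2, scenario=scenario, sim_index=sim_index)
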