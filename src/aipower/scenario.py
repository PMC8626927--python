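"""Scenario algebra for allelic-imbalance (AI) simulation studies.

The level of AI in condition ``i`` is measured by ``theta_i``, the proportion
of reads originating from allele g1.  ``theta = 0.5`` is perfect allelic
balance; 0 and 1 are the two extremes of complete imbalance.  An equivalent
parameterisation uses ``alpha`` with ``theta = 1 / (1 + alpha**2)``, so that
balance corresponds to ``alpha = 1``.

Effect sizes are reported as relative deviations ``dAI``:

* within a condition, against the balance reference ``theta0 = 0.5``:
  ``dAI = |theta - theta0| / theta0``;
* between two conditions: ``dAI = |theta2 - theta1| / theta1``.

Three canonical simulation cases tie scenarios to the three null hypotheses
H1 (``theta1 = 0.5``), H2 (``theta2 = 0.5``) and H3 (``theta1 = theta2``):

* case ``a`` — complete null, ``theta1 = theta2 = 0.5`` (all nulls hold);
* case ``b`` — ``theta1 = 0.5``, ``theta2 != 0.5`` (only H1 holds);
* case ``c`` — ``theta1 = theta2 != 0.5`` (only H3 holds).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

__all__ = [
    "THETA_NULL",
    "alpha_from_theta",
    "theta_from_alpha",
    "delta_ai_within",
    "delta_ai_between",
    "make_case",
    "case_interpretations",
    "Scenario",
    "CASE_LABELS",
]

#: Reference AI level under allelic balance.
THETA_NULL = 0.5

#: Canonical case labels plus accepted aliases (mapped in :func:`make_case`).
CASE_LABELS = ("a", "b", "c", "alt-H1", "alt-H3", "null-both-imbalanced")

_CASE_ALIASES = {
    "a": "a",
    "b": "b",
    "c": "c",
    "alt-h3": "b",
    "null-both-imbalanced": "c",
    "alt-h1": "alt-H1",
}


def alpha_from_theta(theta: float) -> float:
    """Convert an AI proportion ``theta`` to the ``alpha`` parameter.

    ``alpha = sqrt(1/theta - 1)``, the inverse of ``theta = 1/(1+alpha**2)``.
    Balance (``theta = 0.5``) maps to ``alpha = 1``.

    Raises
    ------
    ValueError
        If ``theta`` is outside ``(0, 1]``.
    """
    if not 0.0 < theta <= 1.0:
        raise ValueError(f"theta must be in (0, 1], got {theta!r}")
    return math.sqrt(1.0 / theta - 1.0)


def theta_from_alpha(alpha: float) -> float:
    """Convert ``alpha`` back to the AI proportion ``theta = 1/(1+alpha**2)``."""
    if alpha < 0.0:
        raise ValueError(f"alpha must be nonnegative, got {alpha!r}")
    return 1.0 / (1.0 + alpha * alpha)


def delta_ai_within(theta: float, theta0: float = THETA_NULL) -> float:
    """Relative deviation of ``theta`` from the balance reference ``theta0``."""
    if not 0.0 <= theta <= 1.0:
        raise ValueError(f"theta must be in [0, 1], got {theta!r}")
    return abs(theta - theta0) / theta0


def delta_ai_between(theta1: float, theta2: float) -> float:
    """Relative difference in AI between two conditions, ``|t2 - t1| / t1``."""
    if not 0.0 < theta1 <= 1.0:
        raise ValueError(f"theta1 must be in (0, 1], got {theta1!r}")
    if not 0.0 <= theta2 <= 1.0:
        raise ValueError(f"theta2 must be in [0, 1], got {theta2!r}")
    return abs(theta2 - theta1) / theta1


def make_case(case_label: str, theta_alt: float = 0.55) -> tuple[float, float]:
    """Return ``(theta1, theta2)`` for a canonical simulation case.

    ``a`` gives the complete null ``(0.5, 0.5)``; ``b`` gives
    ``(0.5, theta_alt)``; ``c`` gives ``(theta_alt, theta_alt)``.  The aliases
    ``alt-H3`` (== b), ``null-both-imbalanced`` (== c) and ``alt-H1``
    (condition-swapped b, ``(theta_alt, 0.5)``) are accepted.
    """
    canon = _CASE_ALIASES.get(str(case_label).lower())
    if canon is None:
        raise ValueError(
            f"unknown case label {case_label!r}; expected one of {CASE_LABELS}"
        )
    if canon != "a" and not 0.0 < theta_alt < 1.0:
        raise ValueError(f"theta_alt must be in (0, 1), got {theta_alt!r}")
    if canon == "a":
        return (THETA_NULL, THETA_NULL)
    if canon == "b":
        return (THETA_NULL, theta_alt)
    if canon == "c":
        return (theta_alt, theta_alt)
    return (theta_alt, THETA_NULL)  # alt-H1


def case_interpretations(case_label: str) -> dict[str, str]:
    """Map each hypothesis to ``"type_I_error"`` or ``"power"`` for a case.

    A rejection proportion estimates the type I error for hypotheses whose
    null is satisfied by the case, and the power for those it violates.
    """
    canon = _CASE_ALIASES.get(str(case_label).lower())
    if canon is None:
        raise ValueError(f"unknown case label {case_label!r}")
    if canon == "a":
        return {"H1": "type_I_error", "H2": "type_I_error", "H3": "type_I_error"}
    if canon == "b":
        return {"H1": "type_I_error", "H2": "power", "H3": "power"}
    if canon == "c":
        return {"H1": "power", "H2": "power", "H3": "type_I_error"}
    return {"H1": "power", "H2": "type_I_error", "H3": "power"}  # alt-H1


@dataclass(frozen=True)
class Scenario:
    """One simulation configuration.

    Exactly one of ``n_reads_total`` (allele-specific reads per condition) or
    ``n_reads_per_rep`` (allele-specific reads per biological replicate) is
    given at construction; the other is derived.
    """

    n_sim: int
    n_bioreps: int
    theta1: float
    theta2: float
    n_reads_total: Optional[int] = None
    n_reads_per_rep: Optional[int] = None
    r_g1: float = 0.8
    r_g2: float = 0.8
    case: str = "b"
    seed: int = 0
    scenario_id: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if self.n_reads_total is None and self.n_reads_per_rep is None:
            raise ValueError(
                "one of n_reads_total and n_reads_per_rep must be given"
            )
        if self.n_reads_total is not None and self.n_reads_per_rep is not None:
            if self.n_reads_total != self.n_reads_per_rep * self.n_bioreps:
                raise ValueError(
                    "n_reads_total and n_reads_per_rep are both given but "
                    f"inconsistent: {self.n_reads_total} != "
                    f"{self.n_reads_per_rep} x {self.n_bioreps}"
                )
        if self.n_sim < 1:
            raise ValueError("n_sim must be >= 1")
        if self.n_bioreps < 1:
            raise ValueError("n_bioreps must be >= 1")
        for name in ("theta1", "theta2"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v!r}")
        for name in ("r_g1", "r_g2"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {v!r}")
        canon = _CASE_ALIASES.get(str(self.case).lower())
        if canon is None:
            raise ValueError(f"unknown case label {self.case!r}")
        self._check_case_consistency(canon)
        if self.n_reads_total is None:
            object.__setattr__(
                self, "n_reads_total", self.n_reads_per_rep * self.n_bioreps
            )
        if self.n_reads_total < 1:
            raise ValueError("total allele-specific reads must be >= 1")

    def _check_case_consistency(self, canon: str) -> None:
        t1, t2, t0 = self.theta1, self.theta2, THETA_NULL
        ok = {
            "a": t1 == t0 and t2 == t0,
            "b": t1 == t0 and t2 != t0,
            "c": t1 == t2 and t1 != t0,
            "alt-H1": t1 != t0 and t2 == t0,
        }[canon]
        if not ok:
            raise ValueError(
                f"case {self.case!r} inconsistent with theta1={t1}, theta2={t2}"
            )

    @property
    def reads_per_rep(self) -> float:
        """Average allele-specific reads per replicate, ``total / bioreps``."""
        return self.n_reads_total / self.n_bioreps

    @property
    def delta_ai(self) -> float:
        """The scenario's effect size on the hypothesis it varies.

        Case ``b`` (and ``alt-H1``): deviation of the imbalanced condition
        from balance (equals the between-condition deviation when the other
        condition sits at 0.5).  Case ``c``: within-condition deviation.
        Case ``a``: 0.
        """
        t_alt = self.theta2 if self.theta1 == THETA_NULL else self.theta1
        return delta_ai_within(t_alt)

    @property
    def interpretations(self) -> dict[str, str]:
        return case_interpretations(self.case)

    def with_n_sim(self, n_sim: int) -> "Scenario":
        return replace(self, n_sim=n_sim)
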