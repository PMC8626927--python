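"""Monte-Carlo estimation of type I error and power over scenario grids.

For each scenario, ``n_sim`` datasets are simulated, the hierarchical model
is fitted to each, and the three null hypotheses are tested at the given
significance level.  The rejection proportion estimates the type I error
for hypotheses whose null the scenario satisfies and the power for those it
violates; which is which follows mechanically from the scenario's case
label.  Monte-Carlo uncertainty is reported as
``sqrt(p * (1 - p) / n_completed)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .inference import FitSettings, decide, evidence_between, evidence_within, fit_experiment
from .scenario import Scenario
from .simulate import simulate_experiment

__all__ = [
    "PowerEstimate",
    "SimRecord",
    "estimate_scenario",
    "run_grid",
    "summarize_by",
    "results_frame",
    "RESULT_COLUMNS",
]

logger = logging.getLogger(__name__)

HYPOTHESES = ("H1", "H2", "H3")

RESULT_COLUMNS = [
    "scenario_id", "hypothesis", "interpretation", "n_sim_requested",
    "n_sim_completed", "rejection_proportion", "mc_se", "level",
    "n_reads_total", "n_bioreps", "reads_per_rep", "theta1", "theta2",
    "delta_ai", "r_g1", "r_g2", "seed",
]


@dataclass(frozen=True)
class PowerEstimate:
    """Rejection proportion for one scenario and hypothesis, with its
    Monte-Carlo standard error and interpretation."""

    scenario: Scenario
    hypothesis: str
    n_sim_requested: int
    n_sim_completed: int
    n_rejections: int
    level: float
    warning: str = ""

    @property
    def rejection_proportion(self) -> float:
        if self.n_sim_completed == 0:
            return float("nan")
        return self.n_rejections / self.n_sim_completed

    @property
    def mc_standard_error(self) -> float:
        if self.n_sim_completed == 0:
            return float("nan")
        p = self.rejection_proportion
        return float(np.sqrt(p * (1.0 - p) / self.n_sim_completed))

    @property
    def interpretation(self) -> str:
        return self.scenario.interpretations[self.hypothesis]


@dataclass(frozen=True)
class SimRecord:
    """Evidence values for a single simulated dataset."""

    sim_index: int
    e_h1: float
    e_h2: float
    e_h3: float
    flagged: bool


def _simulate_and_fit(scenario: Scenario, sim_index: int,
                      settings: FitSettings) -> SimRecord:
    data = simulate_experiment(scenario, sim_index=sim_index)
    post = fit_experiment(data, scenario.r_g1, scenario.r_g2, settings)
    return SimRecord(
        sim_index=sim_index,
        e_h1=evidence_within(post, 1),
        e_h2=evidence_within(post, 2),
        e_h3=evidence_between(post),
        flagged=post.flagged,
    )


def simulate_scenario_evidence(
    scenario: Scenario,
    settings: Optional[FitSettings] = None,
    n_jobs: int = 1,
) -> list[SimRecord]:
    """Run the scenario's ``n_sim`` simulate-fit cycles and return per-dataset
    evidence records in simulation order.

    RNG streams are keyed by ``(scenario.seed, sim_index)``, so the result is
    independent of ``n_jobs``.
    """
    settings = settings or FitSettings()
    indices = range(scenario.n_sim)
    if n_jobs == 1:
        return [_simulate_and_fit(scenario, j, settings) for j in indices]
    from joblib import Parallel, delayed

    return Parallel(n_jobs=n_jobs)(
        delayed(_simulate_and_fit)(scenario, j, settings) for j in indices
    )


def estimate_scenario(
    scenario: Scenario,
    level: float = 0.05,
    settings: Optional[FitSettings] = None,
    n_jobs: int = 1,
) -> tuple[PowerEstimate, PowerEstimate, PowerEstimate]:
    """Estimate rejection proportions for H1, H2 and H3 for one scenario.

    Fits flagged as numerically degenerate (already retried once inside
    :func:`~aipower.inference.fit_experiment`) are excluded from the
    denominator; if more than 5% of fits are excluded, the estimates carry a
    scenario-level warning.
    """
    records = simulate_scenario_evidence(scenario, settings, n_jobs)
    ok = [r for r in records if not r.flagged]
    n_excluded = len(records) - len(ok)
    warning = ""
    if n_excluded:
        logger.warning("scenario %s: excluded %d/%d degenerate fits",
                       scenario.scenario_id or "<unnamed>", n_excluded,
                       len(records))
        if n_excluded > 0.05 * len(records):
            warning = f"excluded {n_excluded}/{len(records)} fits"
    out = []
    for hyp, attr in zip(HYPOTHESES, ("e_h1", "e_h2", "e_h3")):
        n_rej = sum(decide(getattr(r, attr), level) for r in ok)
        out.append(PowerEstimate(
            scenario=scenario, hypothesis=hyp,
            n_sim_requested=scenario.n_sim, n_sim_completed=len(ok),
            n_rejections=n_rej, level=level, warning=warning,
        ))
    return tuple(out)  # type: ignore[return-value]


def results_frame(estimates: Iterable[PowerEstimate]) -> pd.DataFrame:
    """Long-format results table, one row per scenario x hypothesis."""
    rows = []
    for est in estimates:
        s = est.scenario
        rows.append({
            "scenario_id": s.scenario_id,
            "hypothesis": est.hypothesis,
            "interpretation": est.interpretation,
            "n_sim_requested": est.n_sim_requested,
            "n_sim_completed": est.n_sim_completed,
            "rejection_proportion": est.rejection_proportion,
            "mc_se": est.mc_standard_error,
            "level": est.level,
            "n_reads_total": s.n_reads_total,
            "n_bioreps": s.n_bioreps,
            "reads_per_rep": s.reads_per_rep,
            "theta1": s.theta1,
            "theta2": s.theta2,
            "delta_ai": s.delta_ai,
            "r_g1": s.r_g1,
            "r_g2": s.r_g2,
            "seed": s.seed,
        })
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def run_grid(
    scenarios: Sequence[Scenario],
    level: float = 0.05,
    settings: Optional[FitSettings] = None,
    n_jobs: int = 1,
) -> pd.DataFrame:
    """Estimate all scenarios in a grid; output order equals input order.

    A failing scenario is reported (rejection proportions NaN, warning set)
    without aborting the rest of the grid.
    """
    if len(scenarios) == 0:
        raise ValueError("scenario grid is empty")
    all_estimates: list[PowerEstimate] = []
    for i, scenario in enumerate(scenarios):
        try:
            ests = estimate_scenario(scenario, level, settings, n_jobs)
        except Exception as exc:  # pragma: no cover - defensive
            logger.error("scenario row %d (%s) failed: %s", i,
                         scenario.scenario_id, exc)
            ests = tuple(
                PowerEstimate(scenario=scenario, hypothesis=h,
                              n_sim_requested=scenario.n_sim,
                              n_sim_completed=0, n_rejections=0,
                              level=level, warning=f"failed: {exc}")
                for h in HYPOTHESES
            )
        logger.info("scenario %s: %d/%d simulations completed",
                    scenario.scenario_id or f"row {i}",
                    ests[0].n_sim_completed, scenario.n_sim)
        all_estimates.extend(ests)
    return results_frame(all_estimates)


_FACETS = {
    "reads": "n_reads_total",
    "reads_per_rep": "reads_per_rep",
    "bioreps": "n_bioreps",
    "delta_ai": "delta_ai",
    "n_sim": "n_sim_requested",
}


def summarize_by(results: pd.DataFrame, facet: str) -> pd.DataFrame:
    """Re-key a results table on one facet (``reads``, ``reads_per_rep``,
    ``bioreps``, ``delta_ai`` or ``n_sim``), long format, averaging rejection
    proportions within each (facet value, hypothesis, interpretation) cell."""
    if facet not in _FACETS:
        raise ValueError(
            f"unknown facet {facet!r}; expected one of {sorted(_FACETS)}"
        )
    col = _FACETS[facet]
    if results.empty:
        return pd.DataFrame(columns=[facet, "hypothesis", "interpretation",
                                     "rejection_proportion", "n_scenarios"])
    grouped = (
        results.groupby([col, "hypothesis", "interpretation"], as_index=False)
        .agg(rejection_proportion=("rejection_proportion", "mean"),
             n_scenarios=("scenario_id", "count"))
        .rename(columns={col: facet})
    )
    return grouped
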