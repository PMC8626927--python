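"""Benchmark scenarios at the published operating points of the AI test.

These are the read/replicate/effect-size combinations at which the power of
the hierarchical test crosses (or provably fails to cross) 80%, plus null
grids for type I error.  They serve as a regression surface: rerunning them
at a few hundred simulations reproduces the documented behaviour of the
method within Monte-Carlo error.
"""

from __future__ import annotations

from typing import Optional

from .inference import FitSettings
from .power import estimate_scenario
from .scenario import Scenario

__all__ = [
    "benchmark_scenario",
    "estimate_cell",
    "POWER_THRESHOLDS_WITHIN",
    "POWER_THRESHOLD_BETWEEN",
    "CEILING_WITHIN",
    "CEILING_BETWEEN",
    "TYPE_I_GRID_GLOBAL",
    "TYPE_I_GRID_NOMINAL",
    "EXTREME_EFFECT",
]

#: (theta_alt, total reads per condition, bioreps) where within-condition
#: power crosses 80%: effect 0.1 needs 2400 reads over 12 replicates,
#: 0.2 needs 480/5 (or 960/3), 0.3 needs only 240/3.
POWER_THRESHOLDS_WITHIN = (
    (0.55, 2400, 12),
    (0.60, 480, 5),
    (0.65, 240, 3),
    (0.60, 960, 3),
)

#: Between-condition effect 0.2 crosses 80% power at 960 reads over 8 reps.
POWER_THRESHOLD_BETWEEN = (0.60, 960, 8)

#: With only 3 replicates, effect 0.1 within a condition stays below 40%
#: power no matter the depth (here the deepest cell, 2400 reads).
CEILING_WITHIN = (0.55, 2400, 3)

#: Between-condition effect 0.1 stays below 60% power even in the
#: best-powered grid cell.
CEILING_BETWEEN = (0.55, 2400, 12)

#: Null (case a) grid including the deep, heavily replicated corner where
#: type I error is largest; it stays below 0.08 everywhere.
TYPE_I_GRID_GLOBAL = tuple(
    (reads, k) for reads in (240, 960, 2400) for k in (3, 8, 12)
)

#: Null grid with at most 2400 total reads, where type I error stays at or
#: below the nominal 5%.
TYPE_I_GRID_NOMINAL = tuple(
    (reads, k) for reads in (240, 480, 960) for k in (3, 5, 8)
)

#: Extreme imbalance (effect 0.5): near-certain detection at low depth.
EXTREME_EFFECT = (0.75, 240, 3)


def benchmark_scenario(theta_alt: float, reads: int, k: int, n_sim: int,
                       seed: int) -> Scenario:
    """Two-condition scenario with condition 1 balanced and condition 2 at
    ``theta_alt`` (case a when ``theta_alt`` is 0.5), r_g1 = r_g2 = 0.8."""
    case = "a" if theta_alt == 0.5 else "b"
    return Scenario(
        n_sim=n_sim, n_bioreps=k, theta1=0.5, theta2=theta_alt,
        n_reads_total=reads, r_g1=0.8, r_g2=0.8, case=case, seed=seed,
        scenario_id=f"bench_t{theta_alt:g}_r{reads}_k{k}",
    )


def estimate_cell(theta_alt: float, reads: int, k: int, n_sim: int,
                  seed: int, level: float = 0.05,
                  settings: Optional[FitSettings] = None) -> dict:
    """Rejection proportions for one benchmark cell.

    Returns a dict with keys ``H1``, ``H2``, ``H3`` (rejection proportions),
    the matching ``*_se`` Monte-Carlo standard errors and ``n`` completed
    simulations.
    """
    s = benchmark_scenario(theta_alt, reads, k, n_sim, seed)
    ests = estimate_scenario(s, level=level, settings=settings)
    out: dict = {"n": ests[0].n_sim_completed}
    for e in ests:
        out[e.hypothesis] = e.rejection_proportion
        out[f"{e.hypothesis}_se"] = e.mc_standard_error
    return out
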