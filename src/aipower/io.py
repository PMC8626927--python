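"""Delimited-text I/O: scenario tables, count tables, evidence records and
results tables.

All files are UTF-8, tab-separated with a header row and ``.`` decimals.
Scientific notation is accepted on read; writes use plain decimals so that
re-runs are diffable.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .scenario import Scenario, make_case
from .simulate import ExperimentData, ReplicateCounts

__all__ = [
    "read_scenarios",
    "write_scenarios",
    "read_counts",
    "write_counts",
    "write_evidence",
    "read_results",
    "write_results",
    "make_default_grid",
    "ScenarioTableError",
    "SCENARIO_COLUMNS",
    "COUNT_COLUMNS",
    "DEFAULT_READ_LEVELS",
    "DEFAULT_BIOREPS",
    "DEFAULT_DELTA_AI",
]

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

SCENARIO_COLUMNS = [
    "scenario_id", "n_sim", "n_reads_total", "n_reads_per_rep", "n_bioreps",
    "theta1", "theta2", "r_g1", "r_g2", "case", "seed",
]
_REQUIRED_SCENARIO_COLUMNS = ["scenario_id", "n_bioreps", "theta1", "theta2", "case"]

COUNT_COLUMNS = ["scenario_id", "sim_index", "condition", "biorep", "x", "y", "z"]

EVIDENCE_COLUMNS = ["scenario_id", "sim_index", "e_h1", "e_h2", "e_h3", "flagged"]

#: Grid defaults mirroring the simulation sweep: six replicate counts, eight
#: total allele-specific read levels, and moderate-to-extreme effect sizes.
DEFAULT_READ_LEVELS = (120, 240, 480, 640, 960, 1920, 2400, 4800)
DEFAULT_BIOREPS = (3, 4, 5, 6, 8, 12)
DEFAULT_DELTA_AI = (0.1, 0.2, 0.3, 0.5)
DEFAULT_R = 0.8
DEFAULT_N_SIM = 1000
DEFAULT_LEVEL = 0.05


class ScenarioTableError(ValueError):
    """Raised when a scenario table fails validation; carries one message
    per offending row."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid scenario table:\n" + "\n".join(errors))


def _cell(row: pd.Series, name: str):
    v = row.get(name)
    if v is None or (isinstance(v, float) and np.isnan(v)) or v == "":
        return None
    return v


def read_scenarios(path: PathLike, sep: str = "\t") -> list[Scenario]:
    """Read and validate a scenario table.

    Required columns: ``scenario_id, n_bioreps, theta1, theta2, case`` plus
    exactly one of ``n_reads_total`` / ``n_reads_per_rep`` per row.  Missing
    ``r_g1``/``r_g2`` default to 0.8, missing ``n_sim`` to 1000 and missing
    ``seed`` to the row number; every applied default is logged.  Validation
    problems are collected and reported together, addressed by row number.
    """
    df = pd.read_csv(path, sep=sep, dtype={"scenario_id": str, "case": str})
    missing = [c for c in _REQUIRED_SCENARIO_COLUMNS if c not in df.columns]
    if missing:
        raise ScenarioTableError([f"missing required column(s): {missing}"])
    if "n_reads_total" not in df.columns and "n_reads_per_rep" not in df.columns:
        raise ScenarioTableError(
            ["missing read-count column: need n_reads_total or n_reads_per_rep"]
        )
    if df.empty:
        logger.warning("scenario table %s contains a header but no rows", path)
        return []

    scenarios: list[Scenario] = []
    errors: list[str] = []
    seen_ids: set[str] = set()
    for idx, row in df.iterrows():
        rowno = idx + 2  # 1-based, after the header
        try:
            sid = str(_cell(row, "scenario_id") or "")
            if not sid:
                raise ValueError("empty scenario_id")
            if sid in seen_ids:
                raise ValueError(f"duplicate scenario_id {sid!r}")
            total = _cell(row, "n_reads_total")
            per_rep = _cell(row, "n_reads_per_rep")
            if (total is None) == (per_rep is None):
                raise ValueError(
                    "exactly one of n_reads_total and n_reads_per_rep "
                    "must be populated"
                )
            n_sim = _cell(row, "n_sim")
            if n_sim is None:
                n_sim = DEFAULT_N_SIM
                logger.info("row %d: defaulting n_sim to %d", rowno, n_sim)
            r_g1 = _cell(row, "r_g1")
            r_g2 = _cell(row, "r_g2")
            if r_g1 is None:
                r_g1 = DEFAULT_R
                logger.info("row %d: defaulting r_g1 to %.2f", rowno, r_g1)
            if r_g2 is None:
                r_g2 = DEFAULT_R
                logger.info("row %d: defaulting r_g2 to %.2f", rowno, r_g2)
            seed = _cell(row, "seed")
            if seed is None:
                seed = int(idx)
                logger.info("row %d: defaulting seed to %d", rowno, seed)
            scenarios.append(Scenario(
                n_sim=int(n_sim),
                n_bioreps=int(row["n_bioreps"]),
                theta1=float(row["theta1"]),
                theta2=float(row["theta2"]),
                n_reads_total=None if total is None else int(total),
                n_reads_per_rep=None if per_rep is None else int(per_rep),
                r_g1=float(r_g1),
                r_g2=float(r_g2),
                case=str(row["case"]),
                seed=int(seed),
                scenario_id=sid,
            ))
            seen_ids.add(sid)
        except (ValueError, TypeError) as exc:
            errors.append(f"row {rowno}: {exc}")
    if errors:
        raise ScenarioTableError(errors)
    return scenarios


def write_scenarios(scenarios: Sequence[Scenario], path: PathLike) -> None:
    rows = []
    for s in scenarios:
        rows.append({
            "scenario_id": s.scenario_id,
            "n_sim": s.n_sim,
            "n_reads_total": s.n_reads_total,
            "n_reads_per_rep": "",
            "n_bioreps": s.n_bioreps,
            "theta1": s.theta1,
            "theta2": s.theta2,
            "r_g1": s.r_g1,
            "r_g2": s.r_g2,
            "case": s.case,
            "seed": s.seed,
        })
    pd.DataFrame(rows, columns=SCENARIO_COLUMNS).to_csv(path, sep="\t", index=False)


def write_counts(experiments: Iterable[ExperimentData], path: PathLike) -> None:
    """Write simulated experiments as a long count table with columns
    ``scenario_id, sim_index, condition, biorep, x, y, z``."""
    rows = []
    for exp in experiments:
        sid = exp.scenario.scenario_id if exp.scenario is not None else ""
        for ci in (1, 2):
            for k, rep in enumerate(exp.condition(ci), start=1):
                rows.append((sid, exp.sim_index, ci, k, rep.x, rep.y, rep.z))
    pd.DataFrame(rows, columns=COUNT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_counts(path: PathLike) -> list[tuple[str, ExperimentData]]:
    """Read a count table back into ``(scenario_id, experiment)`` pairs,
    grouped by ``(scenario_id, sim_index)`` in file order."""
    df = pd.read_csv(path, sep="\t", dtype={"scenario_id": str})
    missing = [c for c in COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"count table missing column(s): {missing}")
    out = []
    for (sid, sim), grp in df.groupby(["scenario_id", "sim_index"], sort=False):
        conds: dict[int, list[ReplicateCounts]] = {1: [], 2: []}
        for _, r in grp.sort_values(["condition", "biorep"]).iterrows():
            conds[int(r["condition"])].append(
                ReplicateCounts(int(r["x"]), int(r["y"]), int(r["z"]))
            )
        if not conds[1] or not conds[2]:
            raise ValueError(
                f"dataset ({sid}, {sim}) lacks replicates for one condition"
            )
        out.append((str(sid), ExperimentData(tuple(conds[1]), tuple(conds[2]),
                                             scenario=None, sim_index=int(sim))))
    return out


def write_evidence(records: Iterable[tuple], path: PathLike) -> None:
    """Write per-dataset evidence records
    ``(scenario_id, sim_index, e_h1, e_h2, e_h3, flagged)``."""
    pd.DataFrame(list(records), columns=EVIDENCE_COLUMNS).to_csv(
        path, sep="\t", index=False
    )


def write_results(results: pd.DataFrame, path: PathLike) -> None:
    results.to_csv(path, sep="\t", index=False)


def read_results(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"scenario_id": str})


def make_default_grid(
    out_path: Optional[PathLike] = None,
    read_levels: Sequence[int] = DEFAULT_READ_LEVELS,
    bioreps: Sequence[int] = DEFAULT_BIOREPS,
    delta_ai: Sequence[float] = DEFAULT_DELTA_AI,
    n_sim: int = DEFAULT_N_SIM,
    r: float = DEFAULT_R,
    base_seed: int = 20210,
) -> list[Scenario]:
    """Build the default replication grid: case a (complete null) plus cases
    b and c at each effect size, crossed with all read levels and replicate
    counts.  Row seeds are ``base_seed + row index`` so the grid is fully
    reproducible.  If ``out_path`` is given the table is also written there.
    """
    scenarios: list[Scenario] = []
    row = 0
    for case in ("a", "b", "c"):
        dais = (0.0,) if case == "a" else tuple(delta_ai)
        for dai in dais:
            theta_alt = 0.5 * (1.0 + dai)
            for reads in read_levels:
                for k in bioreps:
                    theta1, theta2 = make_case(case, theta_alt)
                    sid = f"case{case}_dai{dai:g}_reads{reads}_k{k}"
                    scenarios.append(Scenario(
                        n_sim=n_sim, n_bioreps=k, theta1=theta1, theta2=theta2,
                        n_reads_total=reads, r_g1=r, r_g2=r, case=case,
                        seed=base_seed + row, scenario_id=sid,
                    ))
                    row += 1
    if out_path is not None:
        write_scenarios(scenarios, out_path)
    return scenarios
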