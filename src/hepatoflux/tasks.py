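"""Metabolic-task feasibility checking.

A metabolic task asks: given bounded uptake of a set of metabolites, can
the network produce a set of outputs?  Context-specific models are
validated by running a panel of such tasks (e.g. 256 hepatocyte functions)
and reporting the fraction that pass — the task occurrence score.

Convention (configurable): all exchange reactions are closed during a task
check and replaced by temporary task-specific uptake/production reactions;
the model is restored bit-identically afterwards.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np

from .core import FLUX_TOL, fba, InfeasibleModelError
from .model import MetabolicModel, Metabolite, Reaction

__all__ = ["MetabolicTask", "TaskResult", "TaskReport", "check_tasks", "read_tasks_tsv"]


@dataclass
class MetabolicTask:
    id: str
    description: str = ""
    #: (metabolite id, min uptake, max uptake)
    inputs: list[tuple[str, float, float]] = field(default_factory=list)
    #: (metabolite id, min production, max production)
    outputs: list[tuple[str, float, float]] = field(default_factory=list)
    should_fail: bool = False

    def __post_init__(self) -> None:
        for met, lo, hi in list(self.inputs) + list(self.outputs):
            if not (np.isfinite(lo) and np.isfinite(hi)):
                raise ValueError(f"task {self.id!r}: non-finite bound on {met!r}")
            if lo > hi:
                raise ValueError(f"task {self.id!r}: min > max for {met!r}")


@dataclass
class TaskResult:
    task_id: str
    passed: bool
    achieved_flux: float
    unresolved: bool = False
    reason: str = ""


@dataclass
class TaskReport:
    results: list[TaskResult]

    @property
    def occurrence_score(self) -> float:
        """Fraction of resolvable tasks that pass."""
        scored = [r for r in self.results if not r.unresolved]
        if not scored:
            return float("nan")
        return sum(r.passed for r in scored) / len(scored)

    def result(self, task_id: str) -> TaskResult:
        for r in self.results:
            if r.task_id == task_id:
                return r
        raise KeyError(task_id)


def check_tasks(
    model: MetabolicModel,
    tasks: list[MetabolicTask],
    pass_tolerance: float = FLUX_TOL,
    close_exchanges: bool = True,
) -> TaskReport:
    """Run a task panel against ``model``.

    For each task a scratch copy of the model is built: exchange reactions
    closed (if ``close_exchanges``), a temporary uptake reaction per input
    and a temporary sink per output added with the task's bounds, and total
    output production maximized.  A task passes iff the optimum exceeds
    ``pass_tolerance`` and every output sink can be active at its minimum
    (inverted for ``should_fail`` tasks).  ``model`` itself is never
    modified.
    """
    met_ids = set(model.metabolite_ids)
    results: list[TaskResult] = []
    for task in tasks:
        missing = [m for m, _, _ in task.inputs + task.outputs if m not in met_ids]
        if missing:
            results.append(
                TaskResult(task.id, False, 0.0, unresolved=True,
                           reason=f"unknown metabolites: {missing}")
            )
            continue
        scratch = model.copy()
        if close_exchanges:
            for r in scratch.reactions:
                if r.is_exchange:
                    r.lower_bound = 0.0
                    r.upper_bound = 0.0
        for met, lo, hi in task.inputs:
            scratch.reactions.append(
                Reaction(f"__task_in_{met}", {met: 1.0}, lo, hi, "task",
                         is_exchange=True)
            )
        sink_ids = []
        for met, lo, hi in task.outputs:
            rid = f"__task_out_{met}"
            sink_ids.append(rid)
            scratch.reactions.append(
                Reaction(rid, {met: -1.0}, lo, hi, "task", is_exchange=True)
            )
        scratch._validate()
        # objective: total production across all output sinks
        obj_met = Metabolite("__task_total", compartment="task")
        scratch.metabolites.append(obj_met)
        for rid in sink_ids:
            scratch.reaction(rid).stoichiometry["__task_total"] = 1.0
        scratch.reactions.append(
            Reaction("__task_obj", {"__task_total": -1.0}, 0.0, 1e6, "task",
                     is_exchange=True)
        )
        scratch._validate()
        try:
            sol = fba(scratch, "__task_obj", sense="max")
            achieved = sol.objective_value
        except InfeasibleModelError:
            achieved = 0.0
        raw_pass = achieved > pass_tolerance
        results.append(
            TaskResult(task.id, raw_pass != task.should_fail, achieved)
        )
    return TaskReport(results)


def read_tasks_tsv(path: str) -> list[MetabolicTask]:
    """Read a task list from TSV.

    Columns: id, description, in_mets, in_lb, in_ub, out_mets, out_lb,
    out_ub, should_fail.  Multi-metabolite fields are semicolon-separated
    and bounds align positionally with their metabolite list.
    """

    def split(s: str) -> list[str]:
        return [x.strip() for x in s.split(";") if x.strip()]

    tasks = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            in_mets = split(row["in_mets"])
            out_mets = split(row["out_mets"])
            in_lb = [float(x) for x in split(row["in_lb"])]
            in_ub = [float(x) for x in split(row["in_ub"])]
            out_lb = [float(x) for x in split(row["out_lb"])]
            out_ub = [float(x) for x in split(row["out_ub"])]
            tasks.append(
                MetabolicTask(
                    id=row["id"],
                    description=row.get("description", ""),
                    inputs=list(zip(in_mets, in_lb, in_ub)),
                    outputs=list(zip(out_mets, out_lb, out_ub)),
                    should_fail=row.get("should_fail", "0").strip().lower()
                    in ("1", "true", "yes"),
                )
            )
    return tasks
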