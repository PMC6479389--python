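"""Sensitivity grids over key transition rates.

Scans one or more transition rates over a range of values while holding
every other rate at its Modified-Case value, re-running the scenario
comparison at each grid point (deterministic, draw-free runs) and
recording total premature deaths prevented. The *net-neutral* cells are
those where the benefit is exactly offset (deaths prevented ≤ 0).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .engine import CohortConfig, run_cohort
from .mortality import ERRParams, MortalitySuite
from .transitions import TransitionTable, _as_pair

__all__ = ["GridSpec", "GridResult", "run_grid", "single_cohort_evaluator"]


@dataclass
class GridSpec:
    """Axes of a sensitivity scan.

    Each axis is ``(edge, values)``; values are absolute per-step rates by
    default, or multipliers of the Modified-Case rate when
    ``dialect='multiplier'``.
    """

    axes: list[tuple[object, Sequence[float]]]
    dialect: str = "absolute"

    def __post_init__(self) -> None:
        if not self.axes:
            raise ValueError("grid needs at least one axis")
        if self.dialect not in ("absolute", "multiplier"):
            raise ValueError("dialect must be 'absolute' or 'multiplier'")
        self.axes = [(_as_pair(edge), list(values)) for edge, values in self.axes]
        for edge, values in self.axes:
            if not values:
                raise ValueError(f"empty value list on axis {edge}")
            if self.dialect == "absolute" and not all(0.0 <= v <= 1.0 for v in values):
                raise ValueError(f"axis {edge} has rates outside [0, 1]")


@dataclass
class GridResult:
    """Deaths prevented over the scanned grid."""

    spec: GridSpec
    matrix: np.ndarray  # shape = tuple(len(values) per axis)

    @property
    def net_neutral_mask(self) -> np.ndarray:
        """Cells where the net benefit is offset (deaths prevented <= 0)."""
        return self.matrix <= 0.0

    def to_frame(self) -> pd.DataFrame:
        cols = {
            f"axis{i + 1}_value": []
            for i in range(len(self.spec.axes))
        }
        vals = []
        for idx in itertools.product(*(range(len(v)) for _, v in self.spec.axes)):
            for i, (_, values) in enumerate(self.spec.axes):
                cols[f"axis{i + 1}_value"].append(values[idx[i]])
            vals.append(self.matrix[idx])
        out = pd.DataFrame(cols)
        out["deaths_prevented"] = vals
        return out


def single_cohort_evaluator(
    cfg: CohortConfig,
    base_table: TransitionTable,
    models: MortalitySuite,
    err: ERRParams = ERRParams(),
    at_age: int | None = None,
) -> Callable[[TransitionTable], float]:
    """Evaluator returning survivors(scenario) − survivors(base) at one age."""
    if at_age is None:
        at_age = cfg.report_ages[-1]
    base_survivors = run_cohort(cfg, base_table, models, err).survivors(at_age)

    def evaluate(table: TransitionTable) -> float:
        return run_cohort(cfg, table, models, err).survivors(at_age) - base_survivors

    return evaluate


def run_grid(
    spec: GridSpec,
    modified_table: TransitionTable,
    evaluate: Callable[[TransitionTable], float],
    scan_ages: Sequence[int] | None = None,
) -> GridResult:
    """Evaluate deaths prevented at every grid point.

    At each point the scanned edges are pinned to the axis values (at
    ``scan_ages``, defaulting to the ages where the Modified-Case table has
    a nonzero rate on that edge, or all ages otherwise) and ``evaluate`` is
    called with the perturbed table. Grid points are independent; the
    matrix is identical under any evaluation order.
    """
    edge_ages: dict[tuple, list[int]] = {}
    for edge, _ in spec.axes:
        if scan_ages is not None:
            edge_ages[edge] = list(scan_ages)
        else:
            active = [a for a in modified_table.ages if modified_table.get(a, edge) > 0]
            edge_ages[edge] = active or list(modified_table.ages)

    shape = tuple(len(values) for _, values in spec.axes)
    matrix = np.empty(shape)
    for idx in itertools.product(*(range(n) for n in shape)):
        table = modified_table.copy()
        for i, (edge, values) in enumerate(spec.axes):
            v = values[idx[i]]
            for a in edge_ages[edge]:
                rate = v if spec.dialect == "absolute" else v * modified_table.get(a, edge)
                table.set(a, edge, rate)
        table.validate()
        matrix[idx] = evaluate(table)
    return GridResult(spec, matrix)
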