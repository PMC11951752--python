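"""The five scenario experiments and the two-phase replication protocol.

Each experiment is a grid of scenario cells replicated (by default) 2000
times.  Every cell is run in two phases:

* **phase 1** — 260 simulated weeks starting from the time-zero backlog,
  reporting the years-1–5 window (0, 260];
* **phase 2** — an independent 312-week run with the same backlog, reporting
  only the year-6 window (260, 312] (a 5-year warm-up that is discarded, to
  see whether waiting times have stabilised).

Replication ``i`` draws its backlog, arrival and screening streams from
seeds derived only from ``(base_seed, i)`` — not from the cell — so cells
run at the same base seed share arrival streams (common random numbers for
low-variance scenario contrasts) while remaining independently reproducible.

The experiments:

1. status quo vs. screening all of A–C at Se = Sp = 0.95;
2. sensitivity/specificity sweep, including the asymmetric (0.90, 0.95) and
   (0.95, 0.90) cells and symmetric low values 0.80/0.50/0.25;
3. laboratory capacity 10/12/14 slots per week, screening on;
4. demand growth up to +25 %, screening on;
5. screening restricted to a single referral group (A, B or C).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .pathway_des import ReplicationResult, ScenarioConfig, run_replication
from .referral_stream import default_group_params, generate_backlog, generate_referrals
from .screening_model import ScreeningParams

__all__ = [
    "PHASE1_WEEKS",
    "PHASE2_WEEKS",
    "YEAR6_WINDOW",
    "ExperimentGrid",
    "MetricSummary",
    "ScenarioSummary",
    "build_experiment",
    "two_phase_run",
    "run_all",
]

logger = logging.getLogger(__name__)

PHASE1_WEEKS = 260.0
PHASE2_WEEKS = 312.0
YEAR6_WINDOW = (260.0, 312.0)

# Stream tags keeping backlog/arrival draws distinct per phase.
_BACKLOG_TAG = 11
_ARRIVALS_P1_TAG = 13
_ARRIVALS_P2_TAG = 15
_SCREEN_SEED_TAG = 7

_METRICS = (
    "wait_y1_5",
    "n_served_y1_5",
    "wait_y6",
    "n_served_y6",
    "n_referred_5y",
    "n_screened_5y",
    "n_screened_out_5y",
    "edt_required_5y",
    "edt_performed_5y",
    "fn_5y",
    "fp_5y",
    "tp_5y",
    "tn_5y",
    "end_queue_5y",
)


@dataclass(frozen=True)
class ExperimentGrid:
    experiment_id: int
    cells: tuple
    n_replications: int = 2000

    def __post_init__(self) -> None:
        if not (1 <= self.experiment_id <= 5):
            raise ValueError(f"experiment_id must be in 1..5, got {self.experiment_id}")
        if self.n_replications < 1:
            raise ValueError(f"n_replications must be >= 1, got {self.n_replications}")
        object.__setattr__(self, "cells", tuple(self.cells))


@dataclass(frozen=True)
class MetricSummary:
    """Across-replication mean with its standard error."""

    mean: float
    se: float
    n: int

    @property
    def ci95(self) -> tuple[float, float]:
        """Normal-approximation 95 % confidence interval (NaN half-width for n < 2)."""
        half = 1.96 * self.se
        return (self.mean - half, self.mean + half)


@dataclass(frozen=True)
class ScenarioSummary:
    """Table-shaped summary of one scenario cell across replications."""

    label: str
    n_replications: int
    config: ScenarioConfig
    metrics: dict

    def to_row(self) -> dict:
        scr = self.config.screening
        row = {
            "scenario": self.label,
            "n_replications": self.n_replications,
            "screening_enabled": self.config.screening_enabled,
            "sensitivity": scr.sensitivity,
            "specificity": scr.specificity,
            "screened_groups": "".join(sorted(scr.screened_groups)),
            "capacity_per_week": self.config.capacity_per_week,
            "backlog": self.config.backlog,
            "demand_scale": self.config.demand_scale,
        }
        for name in _METRICS:
            m = self.metrics.get(name)
            row[f"{name}_mean"] = math.nan if m is None else m.mean
            row[f"{name}_se"] = math.nan if m is None else m.se
        return row


def _screening_cell(
    se: float = 0.95,
    sp: float = 0.95,
    groups: Sequence[str] = ("A", "B", "C"),
    label: str = "",
    **overrides,
) -> ScenarioConfig:
    return ScenarioConfig(
        screening_enabled=True,
        screening=ScreeningParams(se, sp, frozenset(groups)),
        label=label,
        **overrides,
    )


def build_experiment(experiment_id: int, n_replications: int = 2000) -> ExperimentGrid:
    """Scenario grid for one of the five experiments (non-varied fields at defaults)."""
    if experiment_id == 1:
        cells = [
            ScenarioConfig(label="status quo"),
            _screening_cell(label="screening Se=0.95 Sp=0.95"),
        ]
    elif experiment_id == 2:
        points = [(0.95, 0.95), (0.90, 0.95), (0.95, 0.90), (0.80, 0.80), (0.50, 0.50), (0.25, 0.25)]
        cells = [
            _screening_cell(se, sp, label=f"screening Se={se:.2f} Sp={sp:.2f}")
            for se, sp in points
        ]
    elif experiment_id == 3:
        cells = [
            _screening_cell(capacity_per_week=c, label=f"screening, {c} slots/week")
            for c in (10, 12, 14)
        ]
    elif experiment_id == 4:
        cells = [
            _screening_cell(
                demand_scale=s, label=f"screening, demand +{round((s - 1) * 100):d}%"
            )
            for s in (1.00, 1.05, 1.10, 1.15, 1.20, 1.25)
        ]
    elif experiment_id == 5:
        cells = [
            _screening_cell(groups=(g,), label=f"screen group {g} only")
            for g in ("A", "B", "C")
        ]
    else:
        raise ValueError(f"unknown experiment id {experiment_id!r}; expected 1..5")
    return ExperimentGrid(experiment_id, tuple(cells), n_replications)


def _replication_seed(base_seed: int, rep: int) -> int:
    ss = np.random.SeedSequence([int(base_seed), int(rep), _SCREEN_SEED_TAG])
    return int(ss.generate_state(1)[0] % (2**31))


def _run_phase(
    cell: ScenarioConfig,
    group_params,
    base_seed: int,
    rep: int,
    horizon: float,
    windows,
    arrivals_tag: int,
) -> ReplicationResult:
    backlog = generate_backlog(
        cell.backlog, group_params, rng_seed=[base_seed, rep, _BACKLOG_TAG]
    )
    referrals = generate_referrals(
        group_params,
        horizon,
        cell.demand_scale,
        rng_seed=[base_seed, rep, arrivals_tag],
        id_start=cell.backlog,
    )
    cfg = replace(
        cell,
        horizon_weeks=horizon,
        report_windows=windows,
        rng_seed=_replication_seed(base_seed, rep),
    )
    return run_replication(backlog + referrals, cfg, copy_input=False)


def two_phase_run(
    cell: ScenarioConfig,
    n_reps: int = 2000,
    base_seed: int = 0,
    group_params=None,
    phases: Sequence[int] = (1, 2),
    return_replications: bool = False,
):
    """Run one scenario cell under the two-phase protocol and summarise it.

    Returns a :class:`ScenarioSummary`; with ``return_replications=True``
    also returns the per-replication DataFrame.  ``phases`` may restrict the
    run to phase 1 (5-year window) or phase 2 (year-6 window) only.
    """
    if n_reps < 1:
        raise ValueError(f"n_reps must be >= 1, got {n_reps}")
    if base_seed < 0:
        raise ValueError(f"base_seed must be >= 0, got {base_seed}")
    gp = default_group_params() if group_params is None else group_params
    rows = []
    for i in range(n_reps):
        row: dict = {"replication": i}
        if 1 in phases:
            res1 = _run_phase(
                cell, gp, base_seed, i, PHASE1_WEEKS, ((0.0, PHASE1_WEEKS),), _ARRIVALS_P1_TAG
            )
            wait, served = res1.window_waits[0]
            row.update(
                wait_y1_5=wait,
                n_served_y1_5=served,
                n_referred_5y=res1.n_referred,
                n_screened_5y=res1.n_screened,
                n_screened_out_5y=res1.n_screened_out,
                edt_required_5y=res1.n_edt_required,
                edt_performed_5y=res1.n_edt_performed,
                fn_5y=res1.fn,
                fp_5y=res1.fp,
                tp_5y=res1.tp,
                tn_5y=res1.tn,
                end_queue_5y=res1.end_queue_length,
            )
        if 2 in phases:
            res2 = _run_phase(
                cell, gp, base_seed, i, PHASE2_WEEKS, (YEAR6_WINDOW,), _ARRIVALS_P2_TAG
            )
            wait6, served6 = res2.window_waits[0]
            row.update(wait_y6=wait6, n_served_y6=served6)
        rows.append(row)

    metrics = {}
    for name in _METRICS:
        if name not in rows[0]:
            continue
        values = np.asarray([r[name] for r in rows], dtype=float)
        mean = float(values.mean())
        se = float(values.std(ddof=1) / math.sqrt(len(values))) if len(values) > 1 else math.nan
        metrics[name] = MetricSummary(mean=mean, se=se, n=len(values))

    summary = ScenarioSummary(
        label=cell.label or _describe(cell),
        n_replications=n_reps,
        config=cell,
        metrics=metrics,
    )
    if return_replications:
        return summary, pd.DataFrame(rows)
    return summary


def _describe(cell: ScenarioConfig) -> str:
    if not cell.screening_enabled:
        base = "status quo"
    else:
        scr = cell.screening
        base = (
            f"screen {''.join(sorted(scr.screened_groups))} "
            f"Se={scr.sensitivity:.2f} Sp={scr.specificity:.2f}"
        )
    extras = []
    if cell.capacity_per_week != 12:
        extras.append(f"c={cell.capacity_per_week}")
    if cell.demand_scale != 1.0:
        extras.append(f"demand x{cell.demand_scale:g}")
    return base + (f" ({', '.join(extras)})" if extras else "")


def run_all(
    grids: Sequence[ExperimentGrid],
    base_seed: int = 0,
    n_reps: Optional[int] = None,
    out_dir=None,
    group_params=None,
) -> dict[int, list[ScenarioSummary]]:
    """Run every cell of every grid; optionally write per-experiment CSVs.

    Writes ``summary_<id>.csv`` (one row per cell) and
    ``replications_<id>.csv`` (one row per replication) under ``out_dir``.
    A failing cell is logged and skipped; the run continues.  Deterministic
    given ``base_seed``.
    """
    results: dict[int, list[ScenarioSummary]] = {}
    for grid in grids:
        reps = n_reps if n_reps is not None else grid.n_replications
        summaries: list[ScenarioSummary] = []
        rep_frames = []
        for cell in grid.cells:
            label = cell.label or _describe(cell)
            try:
                summary, rep_df = two_phase_run(
                    cell, reps, base_seed, group_params, return_replications=True
                )
            except Exception:
                logger.exception(
                    "experiment %d cell %r failed; continuing", grid.experiment_id, label
                )
                continue
            logger.info(
                "experiment %d cell %r: %d replications, seed %d",
                grid.experiment_id,
                summary.label,
                reps,
                base_seed,
            )
            rep_df.insert(0, "scenario", summary.label)
            summaries.append(summary)
            rep_frames.append(rep_df)
        results[grid.experiment_id] = summaries
        if out_dir is not None and summaries:
            out = Path(out_dir)
            out.mkdir(parents=True, exist_ok=True)
            pd.DataFrame([s.to_row() for s in summaries]).to_csv(
                out / f"summary_{grid.experiment_id}.csv", index=False
            )
            pd.concat(rep_frames, ignore_index=True).to_csv(
                out / f"replications_{grid.experiment_id}.csv", index=False
            )
    return results
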