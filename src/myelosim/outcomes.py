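"""Outcome measures read off a cohort trace.

Per-line expected progression-free years are *unconditional* — years per
starting patient, so that overall survival decomposes exactly as the sum
of per-line progression-free years plus any post-progression years in the
final line.  Conditional (per line-entrant) times are exposed separately.
Survival is not discounted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
import pandas as pd

from .engine import CohortTrace, SimulationSettings


def round_half_up(x: float, decimals: int) -> float:
    """Decimal half-up rounding (5 rounds away from zero), as printed tables use."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class SequenceOutcomes:
    """Survival outcomes of one simulated sequence (years per starting patient)."""

    label: str
    per_line_years: tuple[float, ...]
    final_line_pp_years: float
    os_years: float
    per_entrant_years: tuple[float, ...] = ()
    entry_fractions: tuple[float, ...] = ()
    settings: SimulationSettings | None = field(default=None, compare=False)

    def __post_init__(self):
        if any(v < -1e-12 for v in self.per_line_years) or self.final_line_pp_years < -1e-12:
            raise ValueError("expected times must be non-negative")
        total = sum(self.per_line_years) + self.final_line_pp_years
        if abs(total - self.os_years) > 1e-9:
            raise ValueError(
                f"overall survival {self.os_years} does not equal the sum of "
                f"state times {total}"
            )


def line_expected_times(trace: CohortTrace) -> np.ndarray:
    """Expected years progression-free in each line, per starting patient."""
    return trace.pf.sum(axis=0) * trace.settings.cycle_len


def overall_survival_years(trace: CohortTrace) -> float:
    """Expected total years alive (progression-free in any line + post-progression)."""
    return float(trace.alive.sum() * trace.settings.cycle_len)


def final_line_post_progression_years(trace: CohortTrace) -> float:
    return float(trace.post_progression.sum() * trace.settings.cycle_len)


def sequence_outcomes(trace: CohortTrace, label: str = "") -> SequenceOutcomes:
    """Bundle a trace into its outcome summary."""
    per_line = line_expected_times(trace)
    entry = np.array([e.sum() for e in trace.entrants])
    with np.errstate(invalid="ignore", divide="ignore"):
        conditional = np.where(entry > 0, per_line / np.where(entry > 0, entry, 1.0), 0.0)
    return SequenceOutcomes(
        label=label,
        per_line_years=tuple(float(v) for v in per_line),
        final_line_pp_years=final_line_post_progression_years(trace),
        os_years=overall_survival_years(trace),
        per_entrant_years=tuple(float(v) for v in conditional),
        entry_fractions=tuple(float(v) for v in entry),
        settings=trace.settings,
    )


def incremental_os(a: SequenceOutcomes, b: SequenceOutcomes) -> float:
    """Signed OS difference a - b; requires identical simulation settings."""
    if a.settings is not None and b.settings is not None and a.settings != b.settings:
        raise ValueError("outcomes were computed under different simulation settings")
    return a.os_years - b.os_years


def summarize(
    outcomes: Sequence[SequenceOutcomes],
    optimal_label: str | None = None,
    n_lines: int = 4,
) -> tuple[pd.DataFrame, dict]:
    """Outcome table plus aggregate statistics.

    The table has one row per sequence with per-line progression-free
    years (half-up to 2 decimals), OS, and — when an optimal sequence is
    named — the OS difference versus it.  Aggregates: the non-weighted
    mean OS over the non-optimal sequences (1 decimal), and the ratio of
    the optimal sequence's first-line progression-free time to each
    comparator's (1 decimal).
    """
    if not outcomes:
        raise ValueError("need at least one sequence outcome")
    optimal = None
    if optimal_label is not None:
        matches = [o for o in outcomes if o.label == optimal_label]
        if not matches:
            raise KeyError(f"optimal sequence {optimal_label!r} not in outcomes")
        optimal = matches[0]

    rows = []
    for o in outcomes:
        row: dict = {"sequence": o.label}
        for i in range(n_lines):
            v = o.per_line_years[i] if i < len(o.per_line_years) else float("nan")
            row[f"pfs_l{i + 1}"] = round_half_up(v, 2) if np.isfinite(v) else np.nan
        row["os"] = round_half_up(o.os_years, 2)
        if optimal is not None:
            row["delta_os_vs_optimal"] = (
                np.nan
                if o is optimal
                else round_half_up(incremental_os(o, optimal), 2)
            )
        rows.append(row)
    table = pd.DataFrame(rows)

    aggregates: dict = {}
    if optimal is not None:
        comparators = [o for o in outcomes if o is not optimal]
        if comparators:
            aggregates["mean_os_common"] = round_half_up(
                float(np.mean([o.os_years for o in comparators])), 1
            )
            aggregates["first_line_pfs_fold"] = {
                o.label: round_half_up(
                    optimal.per_line_years[0] / o.per_line_years[0], 1
                )
                for o in comparators
                if o.per_line_years[0] > 0
            }
    return table, aggregates
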