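"""Population-level life-years projection.

Scales per-patient overall survival to the annual national cohort that
reaches a full four-line sequence:

    n_tie    = round(new_cases * tie_share)
    n_fourth = round(n_tie * fourth_line_share)
    LY       = round(n_fourth * OS)          per scenario
    LY gained = LY(optimal) - LY(comparator)

Rounding is half-up to whole patients / whole life-years at each named
step, as national projections are typically printed; the single-step
unrounded product is also reported for sensitivity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from .outcomes import round_half_up


@dataclass(frozen=True)
class ProjectionInputs:
    new_cases_per_year: int
    tie_share: float
    fourth_line_share: float
    os_by_scenario: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.new_cases_per_year < 0:
            raise ValueError("new_cases_per_year must be >= 0")
        for name, share in (
            ("tie_share", self.tie_share),
            ("fourth_line_share", self.fourth_line_share),
        ):
            if not 0.0 <= share <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {share}")
        for label, os_years in self.os_by_scenario.items():
            if not (math.isfinite(os_years) and os_years >= 0):
                raise ValueError(f"OS for scenario {label!r} must be >= 0")


@dataclass(frozen=True)
class ProjectionResult:
    n_tie: int
    n_fourth: int
    table: pd.DataFrame
    ly_gained: dict[str, int]


def project_life_years(
    inputs: ProjectionInputs, optimal_label: str | None = None
) -> ProjectionResult:
    """Life-years by scenario, with gains versus the optimal scenario.

    The returned table has one row per scenario: rounded life-years
    (``ly``), the unrounded single-step product (``ly_unrounded``), and,
    when ``optimal_label`` is given, rounded life-years gained by
    switching that scenario's patients to the optimal sequence.
    """
    if optimal_label is not None and optimal_label not in inputs.os_by_scenario:
        raise KeyError(f"scenario {optimal_label!r} missing from os_by_scenario")
    n_tie = int(round_half_up(inputs.new_cases_per_year * inputs.tie_share, 0))
    n_fourth = int(round_half_up(n_tie * inputs.fourth_line_share, 0))

    rows = []
    ly_rounded: dict[str, int] = {}
    for label, os_years in inputs.os_by_scenario.items():
        ly = int(round_half_up(n_fourth * os_years, 0))
        ly_rounded[label] = ly
        rows.append(
            {
                "scenario": label,
                "os_years": os_years,
                "ly": ly,
                "ly_unrounded": (
                    inputs.new_cases_per_year
                    * inputs.tie_share
                    * inputs.fourth_line_share
                    * os_years
                ),
            }
        )
    table = pd.DataFrame(rows)

    gained: dict[str, int] = {}
    if optimal_label is not None:
        ly_opt = ly_rounded[optimal_label]
        gained = {
            label: ly_opt - ly
            for label, ly in ly_rounded.items()
            if label != optimal_label
        }
        table["ly_gained_vs_optimal"] = [
            gained.get(label, 0) if label != optimal_label else pd.NA
            for label in ly_rounded
        ]
    return ProjectionResult(n_tie=n_tie, n_fourth=n_fourth, table=table, ly_gained=gained)
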