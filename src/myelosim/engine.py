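"""Discrete-cycle cohort simulation of a treatment sequence.

A cohort of unit mass starts newly diagnosed on the first-line regimen and
moves through up to four sequential treatment lines.  Within each line the
progression-free fraction follows that line's PFS curve; because the curves
are time-dependent, the cohort is tracked by time-in-line (tunnel states):
entrants at different calendar cycles each follow the curve from their own
clock.  Each cycle a fraction of the progression-free cohort has a PFS
event; the attrition fraction of those events moves on to the next line,
the rest die.  After the final line the default is terminal disease (all
events are deaths); a partitioned-survival mode is available where the
final line's overall-survival curve separates post-progression survival
from death.

The engine is deterministic: cohort fractions are exact expectations, not
Monte-Carlo draws.  Events resolve at cycle end and progressors enter the
next line at the start of the following cycle; no half-cycle correction is
applied.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .curves import (
    HazardRatioEntry,
    LineSetting,
    SurvivalCurve,
    apply_hazard_ratio,
)

logger = logging.getLogger(__name__)

#: 2-week cycles on a 40-year horizon
DEFAULT_CYCLE_LEN = 14.0 / 365.25
DEFAULT_N_CYCLES = math.ceil(40.0 * 365.25 / 14.0)  # 1044

MAX_LINES = 4


class FinalLineMode(str, enum.Enum):
    TERMINAL_DEATH = "terminal_death"
    PARTITIONED_SURVIVAL = "partitioned_survival"


@dataclass(frozen=True)
class TreatmentSequence:
    """An ordered list of 1-4 regimen identifiers."""

    lines: tuple[str, ...]
    label: str = ""
    allow_duplicates: bool = False

    def __post_init__(self):
        lines = tuple(str(r) for r in self.lines)
        if not 1 <= len(lines) <= MAX_LINES:
            raise ValueError(
                f"a sequence has between 1 and {MAX_LINES} lines, got {len(lines)}"
            )
        if len(set(lines)) != len(lines) and not self.allow_duplicates:
            raise ValueError(
                f"duplicate regimen in {lines}; set allow_duplicates to permit"
            )
        object.__setattr__(self, "lines", lines)
        if not self.label:
            object.__setattr__(self, "label", " + ".join(lines))

    def __len__(self) -> int:
        return len(self.lines)


@dataclass(frozen=True)
class LineModel:
    """One line's simulation inputs.

    ``attrition`` is the fraction of PFS events that are progressions to
    the next line; the complement are deaths.  It is ignored for the final
    line in terminal-death mode.
    """

    regimen: str
    pfs_curve: object  # anything with .survival(t)
    attrition: float = 0.0
    os_curve: object | None = None

    def __post_init__(self):
        if not 0.0 <= self.attrition <= 1.0:
            raise ValueError(f"attrition must be in [0, 1], got {self.attrition}")


@dataclass(frozen=True)
class SimulationSettings:
    cycle_len: float = DEFAULT_CYCLE_LEN
    n_cycles: int = DEFAULT_N_CYCLES
    final_line_mode: FinalLineMode = FinalLineMode.TERMINAL_DEATH
    survival_floor: float = 1e-12
    strict_partition: bool = False

    def __post_init__(self):
        object.__setattr__(
            self, "final_line_mode", FinalLineMode(self.final_line_mode)
        )
        if self.cycle_len <= 0:
            raise ValueError("cycle_len must be > 0")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")

    @property
    def horizon_years(self) -> float:
        return self.cycle_len * self.n_cycles


@dataclass
class CohortTrace:
    """Per-cycle state occupancy of the whole cohort.

    ``pf[t, k]`` is the fraction of the starting cohort progression-free in
    line ``k`` at the start of cycle ``t`` (summed over time-in-line);
    ``post_progression[t]`` the fraction alive post-progression in the
    final line (partitioned mode only); ``dead[t]`` the cumulative dead
    fraction.  Full time-in-line detail is recoverable via
    :meth:`occupancy`.
    """

    pf: np.ndarray
    post_progression: np.ndarray
    dead: np.ndarray
    settings: SimulationSettings
    entrants: list[np.ndarray] = field(repr=False)
    surv_grids: list[np.ndarray] = field(repr=False)

    @property
    def n_lines(self) -> int:
        return self.pf.shape[1]

    @property
    def alive(self) -> np.ndarray:
        return self.pf.sum(axis=1) + self.post_progression

    def occupancy(self, cycle: int, line: int, u: int) -> float:
        """Fraction progression-free in ``line`` at ``cycle`` having spent
        ``u`` cycles there (0-based line index)."""
        if u > cycle:
            return 0.0
        return float(self.entrants[line][cycle - u] * self.surv_grids[line][u])

    def validate(self, tol: float = 1e-9) -> None:
        total = self.alive + self.dead
        bad = np.nonzero(np.abs(total - 1.0) > tol)[0]
        if bad.size:
            raise RuntimeError(
                f"mass conservation violated at cycle {bad[0]}: "
                f"total = {total[bad[0]]!r}"
            )
        if np.any(np.diff(self.dead) < -tol):
            raise RuntimeError("dead fraction decreased between cycles")


def _grid_survival(curve, n_cycles: int, cycle_len: float, floor: float) -> np.ndarray:
    """S on the cycle grid, floored to exactly 0 below the survival floor."""
    ts = np.arange(n_cycles + 1) * cycle_len
    s = np.asarray(curve.survival(ts), dtype=float)
    s[s <= floor] = 0.0
    return s


def simulate_sequence(
    models: Sequence[LineModel], settings: SimulationSettings | None = None
) -> CohortTrace:
    """Run the cohort through the sequence; returns the full trace.

    Per line the update is an exact convolution of the line's entrant
    stream with its survival grid, so entrants at every cycle follow the
    PFS curve from their own time-in-line clock.
    """
    if settings is None:
        settings = SimulationSettings()
    if not 1 <= len(models) <= MAX_LINES:
        raise ValueError(f"need 1 to {MAX_LINES} line models, got {len(models)}")

    n = settings.n_cycles
    dt = settings.cycle_len
    n_lines = len(models)
    partitioned = settings.final_line_mode is FinalLineMode.PARTITIONED_SURVIVAL
    if partitioned and models[-1].os_curve is None:
        raise ValueError("partitioned-survival mode requires an OS curve on the final line")

    pf = np.zeros((n, n_lines))
    pp = np.zeros(n)
    deaths_per_cycle = np.zeros(n)  # deaths occurring during cycle t
    entrants_list: list[np.ndarray] = []
    grids: list[np.ndarray] = []

    entrants = np.zeros(n)
    entrants[0] = 1.0
    for k, model in enumerate(models):
        final = k == n_lines - 1
        s_pfs = _grid_survival(model.pfs_curve, n, dt, settings.survival_floor)
        pf[:, k] = np.convolve(entrants, s_pfs[:n])[:n]
        events = np.convolve(entrants, -np.diff(s_pfs))[:n]
        entrants_list.append(entrants)
        grids.append(s_pfs)

        if not final:
            deaths_per_cycle += (1.0 - model.attrition) * events
            nxt = np.zeros(n)
            nxt[1:] = model.attrition * events[:-1]
            entrants = nxt
        elif not partitioned:
            deaths_per_cycle += events
        else:
            s_os = _grid_survival(model.os_curve, n, dt, settings.survival_floor)
            crossing = s_pfs > s_os + 1e-12
            if crossing.any():
                msg = (
                    "final-line PFS exceeds OS at "
                    f"{int(crossing.sum())} grid points (first at cycle "
                    f"{int(np.argmax(crossing))}); post-progression clamped to 0"
                )
                if settings.strict_partition:
                    raise ValueError(msg)
                logger.warning(msg)
            alive_grid = np.maximum(s_os, s_pfs)
            pp[:] = np.convolve(entrants, (alive_grid - s_pfs)[:n])[:n]
            deaths_per_cycle += np.convolve(entrants, -np.diff(alive_grid))[:n]

    dead = np.concatenate([[0.0], np.cumsum(deaths_per_cycle)[:-1]])
    trace = CohortTrace(
        pf=pf,
        post_progression=pp,
        dead=dead,
        settings=settings,
        entrants=entrants_list,
        surv_grids=grids,
    )
    trace.validate()
    return trace


# ---------------------------------------------------------------------------
# curve library and line-model resolution


@dataclass(frozen=True)
class CurveRecord:
    """One curve-library entry: either a direct curve or a reference + HR."""

    regimen: str
    line_setting: LineSetting
    endpoint: str  # "PFS" | "OS"
    curve: SurvivalCurve | None = None
    reference: str | None = None
    hr: float | None = None

    def __post_init__(self):
        object.__setattr__(self, "line_setting", LineSetting(self.line_setting))
        if self.endpoint not in ("PFS", "OS"):
            raise ValueError(f"endpoint must be PFS or OS, got {self.endpoint!r}")
        direct = self.curve is not None
        linked = self.reference is not None and self.hr is not None
        if direct == linked:
            raise ValueError(
                f"record for {self.regimen} must have either a curve or "
                "a (reference, hr) pair"
            )
        if linked and self.hr <= 0:
            raise ValueError(f"hr must be > 0, got {self.hr}")


class CurveLibrary:
    """Lookup of survival functions by (regimen, line setting, endpoint).

    A regimen resolves either to its own parametric curve or, via
    proportional hazards, to a reference regimen's curve raised to an HR.
    The HR may come from the library record itself or from a separate
    hazard-ratio table.
    """

    def __init__(self, records: Sequence[CurveRecord] = ()):
        self._records: dict[tuple[str, LineSetting, str], CurveRecord] = {}
        for rec in records:
            self.add(rec)

    def add(self, rec: CurveRecord) -> None:
        key = (rec.regimen, rec.line_setting, rec.endpoint)
        if key in self._records:
            raise ValueError(f"duplicate curve-library entry for {key}")
        self._records[key] = rec

    def __len__(self) -> int:
        return len(self._records)

    def records(self) -> list[CurveRecord]:
        return list(self._records.values())

    def has(self, regimen: str, setting: LineSetting, endpoint: str = "PFS") -> bool:
        return (regimen, LineSetting(setting), endpoint) in self._records

    def resolve(
        self,
        regimen: str,
        setting: LineSetting,
        endpoint: str = "PFS",
        hr_table: Sequence[HazardRatioEntry] = (),
    ):
        """Return the survival function for a regimen, or raise KeyError."""
        setting = LineSetting(setting)
        rec = self._records.get((regimen, setting, endpoint))
        hr_hits = [
            e
            for e in hr_table
            if e.target_regimen == regimen and e.line_setting == setting
        ]
        if rec is not None and rec.curve is not None:
            if hr_hits:
                raise KeyError(
                    f"ambiguous resolution for {regimen} ({setting.value}, "
                    f"{endpoint}): both a direct curve and a hazard-ratio entry"
                )
            return rec.curve
        if rec is not None:  # reference + hr record
            if hr_hits:
                raise KeyError(
                    f"ambiguous resolution for {regimen} ({setting.value}, "
                    f"{endpoint}): library link and hazard-ratio table both match"
                )
            reference, hr = rec.reference, rec.hr
        elif len(hr_hits) == 1:
            reference, hr = hr_hits[0].reference_regimen, hr_hits[0].hr
        elif len(hr_hits) > 1:
            raise KeyError(
                f"ambiguous resolution for {regimen} ({setting.value}, "
                f"{endpoint}): {len(hr_hits)} hazard-ratio entries match"
            )
        else:
            raise KeyError(
                f"no curve for regimen {regimen!r} in setting {setting.value!r} "
                f"({endpoint}): not in the curve library or hazard-ratio table"
            )
        ref_rec = self._records.get((reference, setting, endpoint))
        if ref_rec is None or ref_rec.curve is None:
            raise KeyError(
                f"reference curve {reference!r} for {regimen!r} "
                f"({setting.value}, {endpoint}) is not a direct library entry"
            )
        return apply_hazard_ratio(ref_rec.curve, hr)


def _setting_for_line(
    regimen: str,
    position: int,
    library: CurveLibrary,
    hr_table: Sequence[HazardRatioEntry],
    endpoint: str = "PFS",
) -> LineSetting:
    """Map a line position to the evidence setting the regimen resolves in.

    Line 1 uses first-line evidence; lines 2+ the relapsed/refractory
    setting.  Lines 3-4 fall back to the double-refractory setting for
    regimens licensed only there; a regimen resolvable in both is
    ambiguous.
    """

    def resolvable(setting: LineSetting) -> bool:
        if library.has(regimen, setting, endpoint):
            return True
        rec_keys = any(
            e.target_regimen == regimen and e.line_setting == setting
            for e in hr_table
        )
        return rec_keys

    if position == 1:
        return LineSetting.FIRST
    in_rr = resolvable(LineSetting.RELAPSED_REFRACTORY)
    if position == 2:
        return LineSetting.RELAPSED_REFRACTORY
    in_dr = resolvable(LineSetting.DOUBLE_REFRACTORY)
    if in_rr and in_dr:
        raise KeyError(
            f"regimen {regimen!r} at line {position} resolves in both the "
            "relapsed/refractory and double-refractory settings"
        )
    if in_dr:
        return LineSetting.DOUBLE_REFRACTORY
    return LineSetting.RELAPSED_REFRACTORY


def build_line_models(
    seq: TreatmentSequence,
    library: CurveLibrary,
    hr_table: Sequence[HazardRatioEntry] = (),
    attrition_by_line: Mapping[int, float] | Sequence[float] | None = None,
    final_line_mode: FinalLineMode = FinalLineMode.TERMINAL_DEATH,
) -> list[LineModel]:
    """Resolve each line of a sequence to a LineModel.

    ``attrition_by_line`` maps 1-based line position to the fraction of
    that line's PFS events progressing to the next line (default 0.7).
    """
    if attrition_by_line is None:
        attrition_by_line = {}
    if not isinstance(attrition_by_line, Mapping):
        attrition_by_line = {i + 1: a for i, a in enumerate(attrition_by_line)}
    models = []
    for pos, regimen in enumerate(seq.lines, start=1):
        setting = _setting_for_line(regimen, pos, library, hr_table)
        pfs = library.resolve(regimen, setting, "PFS", hr_table)
        os_curve = None
        final = pos == len(seq)
        if final and final_line_mode is FinalLineMode.PARTITIONED_SURVIVAL:
            os_setting = _setting_for_line(regimen, pos, library, hr_table, "OS")
            os_curve = library.resolve(regimen, os_setting, "OS", hr_table)
        models.append(
            LineModel(
                regimen=regimen,
                pfs_curve=pfs,
                attrition=float(attrition_by_line.get(pos, 0.7)),
                os_curve=os_curve,
            )
        )
    return models


# ---------------------------------------------------------------------------
# sequence validation against the licensing table


@dataclass(frozen=True)
class EligibilityTable:
    """Regimens licensed per line setting, plus reimbursement annotations."""

    newly_diagnosed: frozenset[str]
    relapsed_refractory: frozenset[str]
    double_refractory: frozenset[str]
    not_approved: frozenset[str] = frozenset()

    @property
    def all_regimens(self) -> frozenset[str]:
        return self.newly_diagnosed | self.relapsed_refractory | self.double_refractory


@dataclass
class ValidationReport:
    sequence: TreatmentSequence
    violations: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_sequence(
    seq: TreatmentSequence, eligibility: EligibilityTable
) -> ValidationReport:
    """Check each line's regimen against the licensing table.

    Line 1 must be licensed for newly diagnosed patients; line 2 for the
    relapsed/refractory setting; lines 3-4 for relapsed/refractory or
    double-refractory.  Unknown regimens raise; duplicates and
    not-approved regimens are warnings.
    """
    report = ValidationReport(sequence=seq)
    for pos, regimen in enumerate(seq.lines, start=1):
        if regimen not in eligibility.all_regimens:
            raise KeyError(f"unknown regimen identifier {regimen!r}")
        if pos == 1:
            allowed = eligibility.newly_diagnosed
            label = "newly diagnosed"
        elif pos == 2:
            allowed = eligibility.relapsed_refractory
            label = "relapsed/refractory"
        else:
            allowed = eligibility.relapsed_refractory | eligibility.double_refractory
            label = "relapsed/refractory or double-refractory"
        if regimen not in allowed:
            report.violations.append(
                f"line {pos}: {regimen} is not licensed in the {label} setting"
            )
        if regimen in eligibility.not_approved:
            report.warnings.append(f"line {pos}: {regimen} is flagged not approved")
    seen: set[str] = set()
    for regimen in seq.lines:
        if regimen in seen:
            report.warnings.append(f"duplicate regimen {regimen} in sequence")
        seen.add(regimen)
    return report
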