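"""Synthetic data and calibrated model inputs.

The trial-derived PFS curves behind the reference outcome table are not
public, so this module bridges the gap: it calibrates exponential
per-line curves such that the cohort engine reproduces the published
per-line expected progression-free times exactly, generates pseudo
Kaplan-Meier datasets for curve-fitting tests, and ships the regimen
licensing table and the expert-panel treatment sequences for Portuguese
transplant-ineligible multiple myeloma practice (September 2022).

Calibration targets one moment per line (the unconditional expected
progression-free time), so a one-parameter exponential per line is the
natural choice: the fixed point is well-posed and, in terminal-death
mode, overall survival is then the sum of the per-line targets for any
feasible attrition.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .curves import Family, KMPoints, LineSetting, SurvivalCurve
from .engine import (
    CurveLibrary,
    CurveRecord,
    EligibilityTable,
    LineModel,
    SimulationSettings,
    TreatmentSequence,
    simulate_sequence,
)
from .outcomes import line_expected_times

DEFAULT_SEED = 20221101
DEFAULT_ATTRITION = 0.7

OPTIMAL_SEQUENCE_LABEL = "DRd + PVd + Kd + Vd"
COMMON_SEQUENCE_LABELS = (
    "VMP + DRd + Pd + Kd",
    "VMP + DRd + Kd + Pd",
    "Rd + VCd + D + Pd",
    "Rd + VCd + Pd + D",
)


@dataclass(frozen=True)
class CalibrationTarget:
    """Per-line unconditional expected progression-free times to reproduce."""

    label: str
    per_line_target_years: tuple[float, ...]
    attrition_by_line: tuple[float, ...]

    def __post_init__(self):
        targets = tuple(float(v) for v in self.per_line_target_years)
        attr = tuple(float(a) for a in self.attrition_by_line)
        if len(attr) < len(targets) - 1:
            raise ValueError("need an attrition fraction between consecutive lines")
        if any(v < 0 for v in targets):
            raise ValueError("targets must be non-negative")
        if any(not 0 <= a <= 1 for a in attr):
            raise ValueError("attrition fractions must be in [0, 1]")
        object.__setattr__(self, "per_line_target_years", targets)
        object.__setattr__(self, "attrition_by_line", attr)

    @property
    def entry_fractions(self) -> tuple[float, ...]:
        out, e = [], 1.0
        for k in range(len(self.per_line_target_years)):
            out.append(e)
            if k < len(self.attrition_by_line):
                e *= self.attrition_by_line[k]
        return tuple(out)


def calibrate_exponential_library(
    target: CalibrationTarget,
    settings: SimulationSettings | None = None,
    tol: float = 1e-3,
    max_iter: int = 20,
) -> list[LineModel]:
    """Exponential per-line curves whose simulated times match the targets.

    The fraction of the cohort entering line k is e_k = prod of upstream
    attritions, so the conditional mean time in line k is target_k / e_k
    and the starting rate is its reciprocal.  A multiplicative fixed-point
    update then absorbs the discrete-cycle and horizon-truncation bias:
    rates are scaled by achieved/target until every line's unconditional
    time is within ``tol`` years.
    """
    if settings is None:
        settings = SimulationSettings()
    targets = np.array(target.per_line_target_years)
    entry = np.array(target.entry_fractions)
    infeasible = (entry <= 0) & (targets > 0)
    if infeasible.any():
        k = int(np.argmax(infeasible))
        raise ValueError(
            f"line {k + 1} target {targets[k]} is unreachable: upstream "
            "attrition gives zero entry probability"
        )
    active = targets > 0
    rates = np.full(targets.size, 1e6)
    rates[active] = entry[active] / targets[active]

    def build(rs):
        return [
            LineModel(
                regimen=f"line{k + 1}",
                pfs_curve=SurvivalCurve(Family.EXPONENTIAL, (rs[k],)),
                attrition=(
                    target.attrition_by_line[k]
                    if k < len(target.attrition_by_line)
                    else 0.0
                ),
            )
            for k in range(targets.size)
        ]

    achieved = np.zeros_like(targets)
    for _ in range(max_iter):
        models = build(rates)
        achieved = line_expected_times(simulate_sequence(models, settings))
        resid = np.abs(achieved - targets)
        if np.all(resid[active] <= tol) and np.all(resid[~active] <= tol):
            return models
        ratio = np.ones_like(rates)
        ratio[active] = achieved[active] / targets[active]
        rates = rates * np.clip(ratio, 0.1, 10.0)
    raise RuntimeError(
        f"calibration for {target.label!r} did not converge in {max_iter} "
        f"iterations; residuals {np.abs(achieved - targets)}"
    )


def generate_km_dataset(
    curve, n: int, censor_frac: float = 0.0, seed: int = DEFAULT_SEED
) -> KMPoints:
    """Pseudo Kaplan-Meier summary data from a known survival curve.

    Samples ``n`` event times by inverse transform, censors each subject
    independently with probability ``censor_frac`` at a uniform time
    before its event, and returns the product-limit estimate at the
    distinct event times, with numbers at risk.
    """
    if n < 10:
        raise ValueError("need at least 10 subjects")
    if not 0.0 <= censor_frac < 1.0:
        raise ValueError("censor_frac must be in [0, 1)")
    rng = np.random.default_rng(seed)
    event_times = curve.sample_times(n, rng)
    censored = rng.random(n) < censor_frac
    durations = np.where(censored, rng.uniform(size=n) * event_times, event_times)
    observed = ~censored

    kmf = KaplanMeierFitter()
    kmf.fit(durations, event_observed=observed)
    table = kmf.event_table
    event_rows = table[table["observed"] > 0]
    times = event_rows.index.to_numpy(dtype=float)
    surv = kmf.survival_function_["KM_estimate"].reindex(event_rows.index).to_numpy()
    n_at_risk = event_rows["at_risk"].to_numpy()
    return KMPoints(times, surv, n_at_risk)


def expert_panel_sequences() -> list[TreatmentSequence]:
    """The four most common national-practice sequences plus the optimal one.

    The last entry is the optimal sequence (see
    :data:`OPTIMAL_SEQUENCE_LABEL`); the first four are the common ones.
    """
    defs = [
        ("VMP", "DRd", "Pd", "Kd"),
        ("VMP", "DRd", "Kd", "Pd"),
        ("Rd", "VCd", "D", "Pd"),
        ("Rd", "VCd", "Pd", "D"),
        ("DRd", "PVd", "Kd", "Vd"),
    ]
    return [TreatmentSequence(lines) for lines in defs]


def licensing_table() -> EligibilityTable:
    """Regimens licensed in Portugal per setting (September 2022).

    VCd carries a not-approved (non-reimbursed) annotation.
    """
    return EligibilityTable(
        newly_diagnosed=frozenset({"DRd", "DVMP", "Rd", "VRd", "VMP"}),
        relapsed_refractory=frozenset(
            {"DRd", "DVd", "Rd", "Vd", "VCd", "KRd", "Kd", "IRd", "PVd", "EloRd"}
        ),
        double_refractory=frozenset({"D", "Pd", "IsaPd"}),
        not_approved=frozenset({"VCd"}),
    )


def line_targets_table() -> pd.DataFrame:
    """Shipped per-line expected progression-free times (years) per sequence."""
    path = importlib.resources.files("myelosim") / "data" / "per_line_targets.tsv"
    with importlib.resources.as_file(path) as p:
        return pd.read_csv(p, sep="\t")


def calibration_targets(
    attrition: float | Sequence[float] = DEFAULT_ATTRITION,
    table: pd.DataFrame | None = None,
) -> list[CalibrationTarget]:
    """Calibration targets for every shipped sequence row.

    ``attrition`` is either one fraction used between all lines or a
    per-gap sequence.  The shipped source only constrains unconditional
    per-line times, so overall survival in terminal-death mode is
    insensitive to this choice.
    """
    if table is None:
        table = line_targets_table()
    if np.isscalar(attrition):
        attrition = (float(attrition),) * 3
    out = []
    for _, row in table.iterrows():
        out.append(
            CalibrationTarget(
                label=row["sequence"],
                per_line_target_years=tuple(
                    float(row[f"pfs_l{i}"]) for i in range(1, 5)
                ),
                attrition_by_line=tuple(attrition),
            )
        )
    return out


_DEFAULT_PARAM_RANGES: dict[Family, tuple[tuple[float, float], ...]] = {
    Family.EXPONENTIAL: ((0.1, 2.0),),
    Family.WEIBULL: ((0.5, 3.0), (0.5, 5.0)),
    Family.LOGNORMAL: ((-1.0, 1.5), (0.3, 1.5)),
    Family.LOGLOGISTIC: ((0.8, 3.0), (0.5, 5.0)),
    Family.GOMPERTZ: ((0.05, 1.0), (0.1, 1.5)),
}


def random_curve_library(
    seed: int,
    n_regimens: int,
    param_ranges: Mapping[Family, tuple[tuple[float, float], ...]] | None = None,
    settings: Sequence[LineSetting] = tuple(LineSetting),
) -> CurveLibrary:
    """Reproducible mixed-family curve library for property tests."""
    if param_ranges is None:
        param_ranges = _DEFAULT_PARAM_RANGES
    rng = np.random.default_rng(seed)
    families = sorted(param_ranges, key=lambda f: list(Family).index(f))
    lib = CurveLibrary()
    for i in range(n_regimens):
        for setting in settings:
            fam = families[rng.integers(len(families))]
            params = tuple(rng.uniform(lo, hi) for lo, hi in param_ranges[fam])
            lib.add(
                CurveRecord(
                    regimen=f"R{i + 1}",
                    line_setting=setting,
                    endpoint="PFS",
                    curve=SurvivalCurve(fam, params),
                )
            )
    return lib
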