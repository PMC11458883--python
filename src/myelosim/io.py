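"""File formats, run configuration, and the end-to-end pipeline.

All on-disk formats are plain text: YAML or JSON for structured inputs
(curve libraries, sequences, attrition, hazard ratios, eligibility,
run configs), CSV for Kaplan-Meier summaries, and tab-separated tables
for outputs.  Dot decimals and UTF-8 throughout.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .curves import HazardRatioEntry, SurvivalCurve
from .engine import (
    CohortTrace,
    CurveLibrary,
    CurveRecord,
    EligibilityTable,
    FinalLineMode,
    SimulationSettings,
    TreatmentSequence,
    build_line_models,
    simulate_sequence,
    validate_sequence,
)
from .fixtures import licensing_table
from .outcomes import SequenceOutcomes, sequence_outcomes, summarize

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Bad or inconsistent run configuration."""


class SequenceValidationError(ValueError):
    """A sequence violates the licensing table."""


class SimulationError(RuntimeError):
    """The cohort simulation failed an internal invariant."""


def _load_structured(path) -> object:
    """Parse a YAML or JSON file by extension (YAML is a JSON superset)."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"file not found: {path}")
    text = path.read_text()
    try:
        if path.suffix == ".json":
            return json.loads(text)
        return yaml.safe_load(text)
    except (yaml.YAMLError, json.JSONDecodeError) as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# readers / writers


def read_curve_library(path) -> CurveLibrary:
    """Curve-library file: a list of records, each either
    ``{regimen, line_setting, endpoint, family, params}`` or
    ``{regimen, line_setting, endpoint, reference, hr}``."""
    raw = _load_structured(path)
    if not isinstance(raw, list):
        raise ConfigError(f"{path}: curve library must be a list of records")
    lib = CurveLibrary()
    for i, rec in enumerate(raw):
        try:
            common = {
                "regimen": rec["regimen"],
                "line_setting": rec["line_setting"],
                "endpoint": rec.get("endpoint", "PFS"),
            }
            if "family" in rec:
                lib.add(
                    CurveRecord(
                        curve=SurvivalCurve(rec["family"], rec["params"]), **common
                    )
                )
            else:
                lib.add(
                    CurveRecord(
                        reference=rec["reference"], hr=float(rec["hr"]), **common
                    )
                )
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigError(f"{path}: record {i}: {exc}") from exc
    return lib


def write_curve_library(lib: CurveLibrary, path) -> None:
    records = []
    for rec in lib.records():
        out = {
            "regimen": rec.regimen,
            "line_setting": rec.line_setting.value,
            "endpoint": rec.endpoint,
        }
        if rec.curve is not None:
            out["family"] = rec.curve.family.value
            out["params"] = [float(p) for p in rec.curve.params]
        else:
            out["reference"] = rec.reference
            out["hr"] = float(rec.hr)
        records.append(out)
    Path(path).write_text(yaml.safe_dump(records, sort_keys=False))


def read_sequences(path) -> list[TreatmentSequence]:
    """Sequence file: list of ``{label, lines: [regimen, ...]}``."""
    raw = _load_structured(path)
    if not isinstance(raw, list) or not raw:
        raise ConfigError(f"{path}: no sequences")
    out = []
    for i, rec in enumerate(raw):
        try:
            out.append(
                TreatmentSequence(
                    lines=tuple(rec["lines"]),
                    label=rec.get("label", ""),
                    allow_duplicates=bool(rec.get("allow_duplicates", False)),
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigError(f"{path}: sequence {i}: {exc}") from exc
    return out


def write_sequences(seqs: Sequence[TreatmentSequence], path) -> None:
    Path(path).write_text(
        yaml.safe_dump(
            [{"label": s.label, "lines": list(s.lines)} for s in seqs],
            sort_keys=False,
        )
    )


def read_attrition(path) -> dict[int, float]:
    """Attrition file: mapping of 1-based line position to the fraction of
    that line's PFS events progressing to the next line."""
    raw = _load_structured(path)
    if isinstance(raw, list):
        raw = {i + 1: v for i, v in enumerate(raw)}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: attrition must be a mapping or list")
    out = {}
    for k, v in raw.items():
        pos, frac = int(k), float(v)
        if not 0.0 <= frac <= 1.0:
            raise ConfigError(f"{path}: attrition for line {pos} not in [0, 1]")
        out[pos] = frac
    return out


def read_hr_table(path) -> list[HazardRatioEntry]:
    """Hazard-ratio file: list of ``{reference, target, line_setting, hr}``."""
    raw = _load_structured(path)
    if not isinstance(raw, list):
        raise ConfigError(f"{path}: hazard-ratio table must be a list")
    out = []
    for i, rec in enumerate(raw):
        try:
            out.append(
                HazardRatioEntry(
                    reference_regimen=rec["reference"],
                    target_regimen=rec["target"],
                    line_setting=rec["line_setting"],
                    hr=float(rec["hr"]),
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigError(f"{path}: entry {i}: {exc}") from exc
    return out


def read_eligibility(path) -> EligibilityTable:
    raw = _load_structured(path)
    try:
        return EligibilityTable(
            newly_diagnosed=frozenset(raw["newly_diagnosed"]),
            relapsed_refractory=frozenset(raw["relapsed_refractory"]),
            double_refractory=frozenset(raw["double_refractory"]),
            not_approved=frozenset(raw.get("not_approved", ())),
        )
    except (KeyError, TypeError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def write_eligibility(table: EligibilityTable, path) -> None:
    Path(path).write_text(
        yaml.safe_dump(
            {
                "newly_diagnosed": sorted(table.newly_diagnosed),
                "relapsed_refractory": sorted(table.relapsed_refractory),
                "double_refractory": sorted(table.double_refractory),
                "not_approved": sorted(table.not_approved),
            },
            sort_keys=False,
        )
    )


def write_outcome_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.2f")


def write_trace(trace: CohortTrace, path) -> None:
    """Per-cycle trace TSV: cycle, per-line PF fractions, post-progression, dead."""
    data = {"cycle": range(trace.pf.shape[0])}
    for k in range(trace.n_lines):
        data[f"pf_line{k + 1}"] = trace.pf[:, k]
    data["post_progression"] = trace.post_progression
    data["dead"] = trace.dead
    pd.DataFrame(data).to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# run configuration and pipeline

_CONFIG_KEYS = {
    "curves",
    "sequences",
    "attrition",
    "hr_table",
    "eligibility",
    "cycle_len",
    "n_cycles",
    "mode",
    "optimal",
    "out_table",
    "out_trace_dir",
}


@dataclass
class RunConfig:
    curve_library: CurveLibrary
    sequences: list[TreatmentSequence]
    attrition: dict[int, float] = field(default_factory=dict)
    hr_table: list[HazardRatioEntry] = field(default_factory=list)
    eligibility: EligibilityTable = field(default_factory=licensing_table)
    settings: SimulationSettings = field(default_factory=SimulationSettings)
    optimal_label: str | None = None
    out_table: Path | None = None
    out_trace_dir: Path | None = None


def load_config(path) -> RunConfig:
    """Load and validate a run-config file (YAML/JSON).

    Paths inside the config resolve relative to the config file.  Defaults:
    2-week cycles, 1044 cycles (40 years), terminal-death final line,
    attrition 0.7 between lines, shipped licensing table.  Unknown keys
    are rejected.
    """
    path = Path(path)
    raw = _load_structured(path)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
    for key in ("curves", "sequences"):
        if key not in raw:
            raise ConfigError(f"{path}: missing required key {key!r}")
    base = path.parent

    def rel(p):
        return base / p

    library = read_curve_library(rel(raw["curves"]))
    sequences = read_sequences(rel(raw["sequences"]))
    attrition = read_attrition(rel(raw["attrition"])) if "attrition" in raw else {}
    hr_table = read_hr_table(rel(raw["hr_table"])) if "hr_table" in raw else []
    eligibility = (
        read_eligibility(rel(raw["eligibility"]))
        if "eligibility" in raw
        else licensing_table()
    )
    try:
        settings = SimulationSettings(
            cycle_len=float(raw.get("cycle_len", SimulationSettings.cycle_len)),
            n_cycles=int(raw.get("n_cycles", SimulationSettings.n_cycles)),
            final_line_mode=FinalLineMode(
                raw.get("mode", FinalLineMode.TERMINAL_DEATH)
            ),
        )
    except ValueError as exc:
        raise ConfigError(f"{path}: {exc}") from exc

    config = RunConfig(
        curve_library=library,
        sequences=sequences,
        attrition=attrition,
        hr_table=hr_table,
        eligibility=eligibility,
        settings=settings,
        optimal_label=raw.get("optimal"),
        out_table=rel(raw["out_table"]) if "out_table" in raw else None,
        out_trace_dir=rel(raw["out_trace_dir"]) if "out_trace_dir" in raw else None,
    )
    if settings.final_line_mode is FinalLineMode.PARTITIONED_SURVIVAL:
        # cross-field check: every final-line regimen needs an OS curve
        for seq in sequences:
            try:
                build_line_models(
                    seq,
                    library,
                    hr_table,
                    attrition,
                    final_line_mode=settings.final_line_mode,
                )
            except KeyError as exc:
                raise ConfigError(
                    f"{path}: partitioned mode needs final-line OS curves: {exc}"
                ) from exc
    if config.optimal_label is not None and config.optimal_label not in {
        s.label for s in sequences
    }:
        raise ConfigError(
            f"{path}: optimal sequence {config.optimal_label!r} not in sequence file"
        )
    return config


def run_pipeline(config: RunConfig) -> tuple[pd.DataFrame, dict, list[SequenceOutcomes]]:
    """Validate, simulate, and summarize every sequence in the config.

    Writes the outcome table (and optional per-sequence traces) when
    output paths are configured; returns the summary table, the aggregate
    statistics, and the raw per-sequence outcomes.
    """
    if not config.sequences:
        raise ConfigError("no sequences")
    outcomes = []
    for seq in config.sequences:
        report = validate_sequence(seq, config.eligibility)
        for warning in report.warnings:
            logger.warning("sequence=%r %s", seq.label, warning)
        if not report.ok:
            raise SequenceValidationError(
                f"sequence {seq.label!r}: " + "; ".join(report.violations)
            )
        try:
            models = build_line_models(
                seq,
                config.curve_library,
                config.hr_table,
                config.attrition,
                final_line_mode=config.settings.final_line_mode,
            )
        except KeyError as exc:
            raise SequenceValidationError(str(exc)) from exc
        try:
            trace = simulate_sequence(models, config.settings)
        except RuntimeError as exc:
            raise SimulationError(f"sequence {seq.label!r}: {exc}") from exc
        out = sequence_outcomes(trace, label=seq.label)
        logger.info("sequence=%r os_years=%.4f", seq.label, out.os_years)
        outcomes.append(out)
        if config.out_trace_dir is not None:
            config.out_trace_dir.mkdir(parents=True, exist_ok=True)
            safe = seq.label.replace(" ", "").replace("+", "-")
            write_trace(trace, config.out_trace_dir / f"trace_{safe}.tsv")

    table, aggregates = summarize(outcomes, optimal_label=config.optimal_label)
    if config.out_table is not None:
        Path(config.out_table).parent.mkdir(parents=True, exist_ok=True)
        write_outcome_table(table, config.out_table)
    for key, value in aggregates.items():
        logger.info("aggregate %s=%r", key, value)
    return table, aggregates, outcomes
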