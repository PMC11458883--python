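"""Cohort engine: mass balance, exponential oracle, resolution, validation."""

import numpy as np
import pytest

from myelosim import (
    SurvivalCurve,
    apply_hazard_ratio,
    simulate_sequence,
    validate_sequence,
)
from myelosim.engine import (
    CurveLibrary,
    CurveRecord,
    FinalLineMode,
    LineModel,
    LineSetting,
    SimulationSettings,
    TreatmentSequence,
    build_line_models,
)
from myelosim.curves import HazardRatioEntry
from myelosim.fixtures import licensing_table
from myelosim.outcomes import line_expected_times, overall_survival_years

from conftest import oracle_os, random_exponential_models

DT = 14 / 365.25


def exp_line(mean, attrition=0.0, regimen="X"):
    return LineModel(
        regimen=regimen,
        pfs_curve=SurvivalCurve("exponential", (1.0 / mean,)),
        attrition=attrition,
    )


class TestTreatmentSequence:
    def test_length_bounds(self):
        with pytest.raises(ValueError):
            TreatmentSequence(("A", "B", "C", "D", "E"))
        with pytest.raises(ValueError):
            TreatmentSequence(())

    def test_duplicates_need_override(self):
        with pytest.raises(ValueError):
            TreatmentSequence(("A", "A"))
        seq = TreatmentSequence(("A", "A"), allow_duplicates=True)
        assert len(seq) == 2

    def test_default_label(self):
        assert TreatmentSequence(("DRd", "PVd")).label == "DRd + PVd"


class TestSimulate:
    def test_zero_hazard_cohort_never_dies(self):
        class Immortal:
            def survival(self, t):
                return np.ones_like(np.asarray(t, dtype=float))

        trace = simulate_sequence(
            [LineModel(regimen="X", pfs_curve=Immortal())],
            SimulationSettings(n_cycles=200),
        )
        assert trace.alive[-1] == pytest.approx(1.0, abs=1e-12)
        assert trace.dead[-1] == 0.0

    def test_single_exponential_line_mean(self):
        """Expected time in line matches 1/rate within one cycle length."""
        trace = simulate_sequence([exp_line(2.0)])
        t = line_expected_times(trace)[0]
        assert t == pytest.approx(2.0, abs=DT)

    def test_two_line_closed_form(self):
        models = [exp_line(2.0, attrition=0.7), exp_line(1.0)]
        os_years = overall_survival_years(simulate_sequence(models))
        assert os_years == pytest.approx(2.7, abs=0.08)

    def test_cycle_refinement_converges_to_oracle(self):
        """Discretization error shrinks under cycle refinement (dt, dt/2, dt/4)."""
        means, attritions = (2.0, 1.0, 0.6), (0.7, 0.5)
        truth = oracle_os(means, attritions)
        errors = []
        for factor in (1, 2, 4):
            models = [
                exp_line(means[0], attritions[0]),
                exp_line(means[1], attritions[1]),
                exp_line(means[2]),
            ]
            settings = SimulationSettings(cycle_len=DT / factor, n_cycles=1044 * factor)
            errors.append(abs(overall_survival_years(simulate_sequence(models, settings)) - truth))
        # left-endpoint bias is ~dt/2 per unit of line-entry mass
        entry_mass = 1 + attritions[0] + attritions[0] * attritions[1]
        assert errors[0] <= entry_mass * DT
        assert errors[1] < errors[0]
        assert errors[2] < errors[1]

    @pytest.mark.parametrize("draw", range(50))
    def test_mass_conservation_and_monotone_mortality(self, draw):
        rng = np.random.default_rng(1000 + draw)
        models = random_exponential_models(rng)
        trace = simulate_sequence(models, SimulationSettings(n_cycles=400))
        total = trace.alive + trace.dead
        assert np.max(np.abs(total - 1.0)) < 1e-9
        assert np.all(np.diff(trace.dead) >= -1e-12)
        assert np.all(np.diff(trace.alive) <= 1e-12)

    def test_initial_occupancy(self):
        trace = simulate_sequence([exp_line(2.0, 0.5), exp_line(1.0)])
        assert trace.occupancy(0, 0, 0) == 1.0
        assert trace.pf[0, 0] == 1.0
        assert trace.pf[0, 1] == 0.0

    def test_zero_attrition_never_reaches_later_lines(self):
        models = [exp_line(1.0, attrition=0.0), exp_line(1.0, 0.0), exp_line(1.0)]
        trace = simulate_sequence(models, SimulationSettings(n_cycles=500))
        assert np.all(trace.pf[:, 1] == 0.0)
        assert np.all(trace.pf[:, 2] == 0.0)

    def test_full_attrition_os_is_sum_of_line_times(self):
        models = [exp_line(2.0, 1.0), exp_line(1.0, 1.0), exp_line(0.5)]
        trace = simulate_sequence(models)
        assert overall_survival_years(trace) == pytest.approx(
            float(line_expected_times(trace).sum()), abs=1e-12
        )

    def test_engine_tracks_oracle_under_line_swap(self):
        """Swapping two lines changes OS exactly as the closed form predicts."""
        a = 0.6
        for means in [(3.0, 1.0), (1.0, 3.0)]:
            models = [exp_line(means[0], a), exp_line(means[1])]
            os_years = overall_survival_years(simulate_sequence(models))
            assert os_years == pytest.approx(oracle_os(means, (a,)), abs=DT)

    def test_model_count_bounds(self):
        with pytest.raises(ValueError):
            simulate_sequence([])
        with pytest.raises(ValueError):
            simulate_sequence([exp_line(1.0)] * 5)


class TestPartitionedMode:
    settings = SimulationSettings(
        n_cycles=600, final_line_mode=FinalLineMode.PARTITIONED_SURVIVAL
    )

    def test_equal_curves_give_zero_post_progression(self):
        c = SurvivalCurve("exponential", (0.8,))
        models = [LineModel(regimen="X", pfs_curve=c, os_curve=c)]
        trace = simulate_sequence(models, self.settings)
        assert np.all(trace.post_progression == 0.0)

    def test_post_progression_positive_when_os_dominates(self):
        models = [
            LineModel(
                regimen="X",
                pfs_curve=SurvivalCurve("exponential", (1.0,)),
                os_curve=SurvivalCurve("exponential", (0.5,)),
            )
        ]
        trace = simulate_sequence(models, self.settings)
        assert trace.post_progression.max() > 0.05
        assert np.max(np.abs(trace.alive + trace.dead - 1.0)) < 1e-9

    def test_crossing_curves_clamped_with_warning(self, caplog):
        models = [
            LineModel(
                regimen="X",
                pfs_curve=SurvivalCurve("exponential", (0.5,)),
                os_curve=SurvivalCurve("exponential", (1.0,)),  # OS below PFS
            )
        ]
        with caplog.at_level("WARNING", logger="myelosim.engine"):
            trace = simulate_sequence(models, self.settings)
        assert any("clamped" in r.message for r in caplog.records)
        assert np.all(trace.post_progression >= 0.0)
        assert np.max(np.abs(trace.alive + trace.dead - 1.0)) < 1e-9

    def test_crossing_curves_strict_mode_raises(self):
        models = [
            LineModel(
                regimen="X",
                pfs_curve=SurvivalCurve("exponential", (0.5,)),
                os_curve=SurvivalCurve("exponential", (1.0,)),
            )
        ]
        strict = SimulationSettings(
            n_cycles=600,
            final_line_mode=FinalLineMode.PARTITIONED_SURVIVAL,
            strict_partition=True,
        )
        with pytest.raises(ValueError):
            simulate_sequence(models, strict)

    def test_missing_os_curve_rejected(self):
        with pytest.raises(ValueError):
            simulate_sequence([exp_line(1.0)], self.settings)


class TestBuildLineModels:
    @staticmethod
    def library():
        rd_first = SurvivalCurve("weibull", (1.2, 3.0))
        return CurveLibrary(
            [
                CurveRecord("DRd", LineSetting.FIRST, "PFS", curve=SurvivalCurve("exponential", (0.1,))),
                CurveRecord("Rd", LineSetting.FIRST, "PFS", curve=rd_first),
                CurveRecord("VMP", LineSetting.FIRST, "PFS", reference="Rd", hr=0.8),
                CurveRecord("Rd", LineSetting.RELAPSED_REFRACTORY, "PFS", curve=SurvivalCurve("exponential", (0.5,))),
                CurveRecord("Kd", LineSetting.RELAPSED_REFRACTORY, "PFS", curve=SurvivalCurve("exponential", (0.9,))),
                CurveRecord("Pd", LineSetting.DOUBLE_REFRACTORY, "PFS", curve=SurvivalCurve("exponential", (1.4,))),
            ]
        )

    def test_direct_lookup(self):
        models = build_line_models(TreatmentSequence(("DRd",)), self.library())
        assert models[0].pfs_curve.params == (0.1,)

    def test_reference_plus_hr_matches_power(self):
        models = build_line_models(TreatmentSequence(("VMP",)), self.library())
        rd = SurvivalCurve("weibull", (1.2, 3.0))
        expected = apply_hazard_ratio(rd, 0.8)
        ts = np.linspace(0, 20, 50)
        assert models[0].pfs_curve.survival(ts) == pytest.approx(
            expected.survival(ts), abs=1e-12
        )

    def test_hr_table_resolution(self):
        lib = self.library()
        hr_table = [
            HazardRatioEntry("Rd", "IRd", LineSetting.RELAPSED_REFRACTORY, 0.7)
        ]
        models = build_line_models(
            TreatmentSequence(("DRd", "IRd")), lib, hr_table=hr_table
        )
        rd_rr = SurvivalCurve("exponential", (0.5,))
        assert models[1].pfs_curve.survival(2.0) == pytest.approx(
            rd_rr.survival(2.0) ** 0.7, abs=1e-12
        )

    def test_double_refractory_fallback(self):
        models = build_line_models(
            TreatmentSequence(("DRd", "Kd", "Pd")), self.library()
        )
        assert models[2].pfs_curve.params == (1.4,)

    def test_missing_regimen_raises(self):
        with pytest.raises(KeyError, match="Vd"):
            build_line_models(TreatmentSequence(("Vd",)), self.library())

    def test_ambiguous_double_setting_raises(self):
        lib = self.library()
        lib.add(
            CurveRecord(
                "Pd",
                LineSetting.RELAPSED_REFRACTORY,
                "PFS",
                curve=SurvivalCurve("exponential", (1.0,)),
            )
        )
        with pytest.raises(KeyError, match="both"):
            build_line_models(TreatmentSequence(("DRd", "Kd", "Pd")), lib)

    def test_attrition_assignment(self):
        models = build_line_models(
            TreatmentSequence(("DRd", "Kd")),
            self.library(),
            attrition_by_line={1: 0.4, 2: 0.9},
        )
        assert [m.attrition for m in models] == [0.4, 0.9]


class TestValidateSequence:
    def test_reference_optimal_sequence_passes(self):
        report = validate_sequence(
            TreatmentSequence(("DRd", "PVd", "Kd", "Vd")), licensing_table()
        )
        assert report.ok
        assert not report.warnings

    def test_double_refractory_regimen_invalid_first_line(self):
        report = validate_sequence(TreatmentSequence(("Pd",)), licensing_table())
        assert not report.ok
        assert "line 1" in report.violations[0]

    def test_double_refractory_regimen_invalid_second_line(self):
        report = validate_sequence(
            TreatmentSequence(("DRd", "Pd", "Kd")), licensing_table()
        )
        assert any("line 2" in v for v in report.violations)

    def test_unknown_regimen_raises(self):
        with pytest.raises(KeyError):
            validate_sequence(TreatmentSequence(("XYZ",)), licensing_table())

    def test_not_approved_flagged(self):
        report = validate_sequence(
            TreatmentSequence(("Rd", "VCd")), licensing_table()
        )
        assert report.ok
        assert any("not approved" in w for w in report.warnings)

    def test_duplicate_warning_with_override(self):
        report = validate_sequence(
            TreatmentSequence(("DRd", "Rd", "Rd"), allow_duplicates=True),
            licensing_table(),
        )
        assert any("duplicate" in w for w in report.warnings)
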