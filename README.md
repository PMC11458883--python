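# myelosim

Treatment-sequencing survival simulation for transplant-ineligible (TIE)
multiple myeloma.

Patients with multiple myeloma relapse repeatedly and typically receive up
to four sequential lines of therapy.  Because no clinical trial compares
whole treatment *sequences*, the order in which regimens are used must be
evaluated by simulation.  `myelosim` implements a discrete-cycle
state-transition cohort model for this: line-specific parametric
progression-free-survival (PFS) curves drive transitions between lines,
and the model reports expected progression-free years per line and overall
survival (OS) per sequence.  It is aimed at health-outcomes researchers and
modellers comparing sequencing strategies.

## Model

A cohort of unit mass starts first-line treatment.  Within line *k* the
progression-free fraction follows a parametric survival curve
*S<sub>k</sub>(u)* in time-in-line *u*; per 2-week cycle of length Δ the
conditional event probability is

> q<sub>k</sub>(u) = 1 − S<sub>k</sub>((u+1)Δ) / S<sub>k</sub>(uΔ).

A PFS event is a progression with probability *a<sub>k</sub>* (the
attrition fraction) and a death otherwise; progressors enter line *k*+1
with a reset clock.  Because transition probabilities depend on
time-in-line, the cohort is tracked over tunnel states — an exact
convolution of each line's entrant stream with its survival grid.  After
the final line's progression the patient is treated as having terminal
disease (a partitioned-survival mode using a final-line OS curve is also
available).  The horizon is 40 years (1044 cycles); no half-cycle
correction and no discounting are applied.

Per-line expected progression-free years are unconditional (per starting
patient), so in terminal-death mode OS decomposes exactly as the sum of
per-line times.  Supporting machinery includes five parametric families
(exponential, Weibull, log-normal, log-logistic, Gompertz), fitting to
Kaplan–Meier summary points by weighted least squares on the
complementary log-log scale, proportional-hazards curve adjustment
(S<sub>target</sub> = S<sub>ref</sub><sup>HR</sup>), and a population
projection scaling per-patient OS to annual national case counts.

## Worked example

The published per-line times for the five Portuguese expert-panel
sequences ship with the package; exponential line curves are calibrated to
them and the engine recomputes everything else:

```python
from myelosim import simulate_sequence
from myelosim.fixtures import (
    OPTIMAL_SEQUENCE_LABEL, calibrate_exponential_library, calibration_targets,
)
from myelosim.outcomes import sequence_outcomes, summarize

outcomes = []
for target in calibration_targets(attrition=0.7):
    models = calibrate_exponential_library(target)
    trace = simulate_sequence(models)
    outcomes.append(sequence_outcomes(trace, label=target.label))

table, aggregates = summarize(outcomes, optimal_label=OPTIMAL_SEQUENCE_LABEL)
print(table.to_string(index=False))
```

```
           sequence  pfs_l1  pfs_l2  pfs_l3  pfs_l4   os  delta_os_vs_optimal
VMP + DRd + Pd + Kd    1.97    4.74    0.46    0.42 7.59                -2.17
VMP + DRd + Kd + Pd    1.97    4.74    0.72    0.38 7.81                -1.95
  Rd + VCd + D + Pd    4.13    0.95    0.71    0.38 6.17                -3.59
  Rd + VCd + Pd + D    4.13    0.95    0.46    0.59 6.13                -3.63
DRd + PVd + Kd + Vd    7.48    1.29    0.71    0.28 9.76                  NaN
```

Each row is one sequence: expected years progression-free in lines 1–4,
total OS in years, and the OS deficit versus the optimal sequence
(DRd + PVd + Kd + Vd).  The optimal sequence gains 1.95–3.63 life-years
per patient over common practice, driven almost entirely by first-line
PFS (`aggregates["first_line_pfs_fold"]` reports 3.8× and 1.8× versus the
VMP- and Rd-first sequences; the non-weighted mean OS of the four common
sequences is 6.9 years).

The same pipeline is scriptable from the shell:

```sh
myelosim fixtures --reference-tables --calibrate per_line_targets.tsv --out-dir work/
myelosim compare --curves work/curves_DRd-PVd-Kd-Vd.yaml --sequences work/sequences.yaml \
    --attrition attrition.yaml --optimal "DRd + PVd + Kd + Vd" --out work/summary.tsv
myelosim project --cases 886 --tie-share 0.60 --fourth-share 0.175 \
    --os-optimal 9.76 --os-comparator 6.13 --out work/projection.tsv
```

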