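# batkit

Analysis toolkit for the **basophil activation test (BAT)** in peanut-allergy
diagnostics: synthetic flow-cytometry cohort simulation, reproducible basophil
gating and quality control, the **AC50 basophil allergen threshold
sensitivity** statistic, and the nonparametric group/ROC statistics used to
ask whether the BAT can separate severely peanut-allergic (PA) patients from
merely peanut-sensitized (PS) ones.

It is written for biostatisticians and allergy researchers who want a tested,
scriptable re-implementation of this analysis chain — from raw per-tube event
tables to a diagnostic cutoff — without access to patient-level data: a
calibrated synthetic-cohort generator with known ground truth stands in for
the clinical cohort, so every stage is testable end to end.

## The statistic at the core

Each subject's blood is stimulated with an allergen extract serially diluted
in 10-fold steps from an initial 1/30 dilution (12 dilutions for peanut).
Activation per tube is the percentage of basophils (CD203c⁺, SSC-low events)
whose CD63 exceeds a threshold set from the subject's negative control.  With
*d* the log10 dilution factor and *pc* the stimulation-control activation,
the **AC50** is the largest *d* at which the piecewise-linear interpolant of
%CD63⁺(*d*) still reaches *pc*/2:

```
AC50 = max { d : %CD63+(d) = pc / 2 }   (linear interpolation between tested dilutions)
```

Higher AC50 ⇒ the subject reacts to more dilute allergen ⇒ greater
sensitivity.  Subjects whose response never reaches *pc*/2 are
non-responders; a response still above *pc*/2 at the most dilute point is
right-censored at the end of the tested range.  Group comparisons use
Mann-Whitney U, associations Spearman's rank correlation, and diagnostic
discrimination the empirical ROC curve with a Youden-index optimal cutoff.

## Worked example

```python
from batkit import DoseResponseCurve, ac50

curve = DoseResponseCurve(
    subject_id="demo", allergen="peanut",
    d=[2, 3, 4, 5, 6], activation=[55, 48, 40, 20, 5],
    positive_control_activation=60.0,
)
print(ac50(curve))
```

The positive control is 60 %, so the threshold is 30 %; the response crosses
30 % between *d* = 4 (40 %) and *d* = 5 (20 %), hence
AC50 = 4 + (40−30)/(40−20) = **4.5**, status `interpolated`.

Running the whole pipeline on the calibrated synthetic cohort
(`python examples/group_comparison_roc.py`) prints, for seed 8:

```
group    variable  n   median      iqr
   PA ac50_peanut 43 7.314636 5.102412
   PS ac50_peanut 21 2.684202 2.708791

Mann-Whitney U = 706.0, p = 2.76e-04 (n = 43/21)
ROC AUC = 0.782; optimal cutoff AC50 = 6.11 (sensitivity 60 %, specificity 95 %)
```

i.e. the allergic group tolerates ~4–5 more decades of dilution at its median
than the sensitized group, and an AC50 cutoff separates the groups with the
stated sensitivity/specificity on this simulated cohort.  The other scripts
in `examples/` walk through simulation, gating/QC, the AC50 arithmetic and
the full artifact-writing run; `batkit --help` exposes the same stages as a
command line (`simulate`, `gate`, `ac50`, `stats`, `roc`, `run`,
`calibration`).

## Layout

- `src/batkit/simulate.py` — synthetic cohorts (latent sensitivity model,
  event-level mixtures, planted QC violations)
- `src/batkit/gating.py` — basophil gate, CD63 threshold, %CD63⁺, QC rules
- `src/batkit/dose_response.py` — dose-response curves and the AC50 statistic
- `src/batkit/stats.py` — Mann-Whitney, Spearman, median/IQR, percentages
- `src/batkit/roc.py` — ROC curve, AUC, Youden-optimal cutoff
- `src/batkit/pipeline.py`, `cli.py`, `io.py` — orchestration, CLI, CSV/YAML
- `docs/methods.md` — model assumptions, parameter choices, limitations
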