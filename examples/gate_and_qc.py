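"""Gate basophils, set the CD63 threshold, and QC one subject.

The basophil gate (CD203c-positive, SSC-low) and the CD63 positivity
threshold are estimated once per subject from the negative-control tube and
reused for all of that subject's tubes.
"""

from batkit import (
    CohortSpec,
    GatingConfig,
    gate_basophils,
    generate_cohort,
    percent_activated,
    qc_subject,
    set_cd63_threshold,
)

spec = CohortSpec(seed=4).subset(groups=("PA",), allergens=("peanut",))
cohort = generate_cohort(spec)
config = GatingConfig()

subject_id = cohort.subjects[0].subject_id
tubes = cohort.tubes_of(subject_id)
neg_tube = cohort.events[tubes[tubes.stimulus == "negctrl"].iloc[0]["tube_id"]]

gate = gate_basophils(neg_tube, config)
threshold = set_cd63_threshold(gate.basophils, config)
print(f"{subject_id}: CD203c gate > {gate.cd203c_threshold:.0f}, "
      f"SSC <= {gate.ssc_threshold:.0f}, CD63 threshold {threshold:.0f}")

measurements = []
for _, row in tubes.iterrows():
    g = gate_basophils(cohort.events[row["tube_id"]], config, gate=gate)
    m = percent_activated(g.basophils, threshold)
    measurements.append(m)
    step = "" if row["dilution_step"] is None else f" step {row['dilution_step']}"
    print(f"  {row['stimulus']:8s}{step:8s} {m.n_basophils:4d} basophils, "
          f"{m.percent_cd63_positive:5.1f} % CD63+")

qc = qc_subject(measurements, config)
print(f"\nQC: included={qc.included}, peanut responder={qc.responder['peanut']}")
# %CD63+ should fall from near the positive-control level toward the
# spontaneous baseline as the allergen is diluted out.
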