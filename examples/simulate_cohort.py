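"""Generate the calibrated synthetic study cohort and look at its ground truth.

The default spec emulates the study design: PA n=47, PS n=22, C n=22; per
subject a negative control, a stimulation control, and 12 (peanut) / 5 (soy,
birch) serial 10-fold dilution tubes with ~600 basophils each.
"""

from batkit import CohortSpec, generate_cohort

spec = CohortSpec(seed=1)
cohort = generate_cohort(spec)

groups = [s.group for s in cohort.subjects]
print(f"subjects: {len(cohort.subjects)} "
      f"(PA {groups.count('PA')}, PS {groups.count('PS')}, C {groups.count('C')})")
print(f"tubes:    {len(cohort.manifest)}")

s = cohort.subject("PA001")
print(f"\n{s.subject_id}: latent peanut AC50 = {s.latent_ac50['peanut']:.2f} "
      f"(log10 dilution units)")
print(f"  spontaneous activation {s.latent_spontaneous:.1f} %, "
      f"positive control {s.latent_posctrl:.1f} %")

ev = cohort.events[cohort.tubes_of("PA001").iloc[0]["tube_id"]]
print(f"  negative-control tube: {ev.n_events} events, "
      f"{int(ev.truth_basophil.sum())} basophils")

# The latent AC50 is the dilution (log10 scale) at which this subject's
# basophil response drops to half the stimulation-control level; the event
# tables are what the gating pipeline sees.
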