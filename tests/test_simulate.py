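import dataclasses

import numpy as np
import pytest

from batkit import (
    CohortConfigError,
    CohortSpec,
    LatentGroupParams,
    generate_cohort,
    sample_latent_ac50,
    simulate_tube,
)
from batkit.dilution import PEANUT_SERIES
from batkit.simulate import SubjectRecord

D_MAX = PEANUT_SERIES.d_max


def test_default_cohort_composition():
    cohort = generate_cohort(CohortSpec(seed=3).subset(allergens=("peanut",)))
    groups = [s.group for s in cohort.subjects]
    assert len(cohort.subjects) == 91
    assert groups.count("PA") == 47
    assert groups.count("PS") == 22
    assert groups.count("C") == 22
    # one negctrl + one posctrl + 12 peanut tubes per subject
    assert len(cohort.manifest) == 91 * 14
    per_subject = cohort.manifest.groupby("subject_id")["stimulus"].agg(
        lambda s: (list(s).count("negctrl"), list(s).count("posctrl"))
    )
    assert all(v == (1, 1) for v in per_subject)


def test_empty_cohort():
    spec = CohortSpec(seed=0).subset(allergens=("peanut",))
    spec = spec.subset(
        group_sizes={g: 0 for g in spec.group_sizes},
        planted_spontaneous={g: 0 for g in spec.group_sizes},
        planted_posctrl_nonresponders={g: 0 for g in spec.group_sizes},
    )
    cohort = generate_cohort(spec)
    assert cohort.subjects == []
    assert cohort.manifest.empty


@pytest.mark.parametrize(
    "overrides, field",
    [
        ({"group_sizes": {"PA": -1, "PS": 22, "C": 22}}, "group_sizes"),
        ({"events_per_tube": 0}, "events_per_tube"),
        ({"hill_slope": 0.0}, "hill_slope"),
        ({"planted_spontaneous": {"PA": 99, "PS": 0, "C": 0}},
         "planted_spontaneous"),
    ],
)
def test_invalid_spec_names_field(overrides, field):
    spec = dataclasses.replace(CohortSpec(), **overrides)
    with pytest.raises(CohortConfigError, match=field):
        generate_cohort(spec)


def test_invalid_latent_iqr_rejected():
    params = LatentGroupParams(5.0, target_iqr=0.0)
    with pytest.raises(CohortConfigError, match="target_iqr"):
        params.validate("PA.peanut")


def test_latent_sampling_matches_configured_median_and_iqr():
    # population median/IQR of the logistic family equal the targets; at
    # n = 100,000 the Monte-Carlo error of both is well below 0.05
    pa = LatentGroupParams(6.84, 4.50)
    x = sample_latent_ac50(pa, 100_000, 123, d_max=D_MAX)
    assert np.median(x) == pytest.approx(6.84, abs=0.05)
    q1, q3 = np.percentile(x, [25, 75])
    assert q3 - q1 == pytest.approx(4.50, abs=0.05)

    ps = LatentGroupParams(3.55, 4.15)
    y = sample_latent_ac50(ps, 100_000, 124, d_max=D_MAX)
    assert np.median(y) == pytest.approx(3.55, abs=0.05)

    assert sample_latent_ac50(pa, 0, 1, d_max=D_MAX).size == 0


def test_latent_values_stay_in_range():
    p = LatentGroupParams(1.0, 8.0)
    x = sample_latent_ac50(p, 50_000, 5, d_max=D_MAX, clip_margin=2.0)
    assert x.min() >= 0.0
    assert x.max() <= D_MAX + 2.0


def test_determinism_identical_seed():
    spec = CohortSpec(seed=42).subset(groups=("PS",), allergens=("peanut",))
    a = generate_cohort(spec)
    b = generate_cohort(spec)
    assert a.manifest.equals(b.manifest)
    for tid in a.events:
        np.testing.assert_array_equal(a.events[tid].cd63, b.events[tid].cd63)
        np.testing.assert_array_equal(a.events[tid].ssc, b.events[tid].ssc)


def _subject(spont=2.0, posctrl=60.0, ac50=6.0, nr=False, plateau=8.0):
    s = SubjectRecord(
        subject_id="X",
        group="PA",
        latent_ac50={"peanut": None if nr else ac50},
        non_responder={"peanut": nr},
        latent_spontaneous=spont,
        latent_posctrl=posctrl,
    )
    if nr:
        s._plateau["peanut"] = plateau
        s._anchor["peanut"] = ac50
    return s


def test_tube_activation_matches_binomial_expectation():
    spec = CohortSpec().subset(allergens=("peanut",))
    rng = np.random.default_rng(9)
    # negative control of a subject with 2 % spontaneous activation
    ev = simulate_tube(_subject(spont=2.0), "negctrl", None, spec, rng)
    frac = ev.truth_activated[ev.truth_basophil].mean()
    n = ev.truth_basophil.sum()
    assert abs(frac - 0.02) < 4 * np.sqrt(0.02 * 0.98 / n)
    # positive control at 60 %
    ev = simulate_tube(_subject(posctrl=60.0), "posctrl", None, spec, rng)
    frac = ev.truth_activated[ev.truth_basophil].mean()
    n = ev.truth_basophil.sum()
    assert abs(frac - 0.60) < 4 * np.sqrt(0.6 * 0.4 / n)


def test_tube_far_beyond_ac50_at_baseline():
    spec = CohortSpec().subset(allergens=("peanut",))
    rng = np.random.default_rng(10)
    # latent AC50 of 3: at step 12 (d ~ 12.5) the curve has fully decayed
    ev = simulate_tube(_subject(ac50=3.0, spont=2.0), "peanut", 12, spec, rng)
    frac = ev.truth_activated[ev.truth_basophil].mean()
    assert frac < 0.06


def test_nonresponder_curve_stays_below_cutoff():
    spec = CohortSpec().subset(allergens=("peanut",))
    rng = np.random.default_rng(11)
    fracs = [
        simulate_tube(_subject(nr=True, plateau=9.0), "peanut", k, spec, rng)
        for k in range(1, 13)
    ]
    for ev in fracs:
        frac = ev.truth_activated[ev.truth_basophil].mean()
        assert frac < 0.15


def test_unknown_stimulus_rejected():
    spec = CohortSpec().subset(allergens=("peanut",))
    with pytest.raises(ValueError, match="unknown stimulus"):
        simulate_tube(_subject(), "latex", 1, spec, np.random.default_rng(0))
    with pytest.raises(ValueError):
        simulate_tube(_subject(), "peanut", 99, spec, np.random.default_rng(0))


def test_basophils_separable_from_other_events():
    spec = CohortSpec().subset(allergens=("peanut",))
    ev = simulate_tube(_subject(), "negctrl", None, spec, np.random.default_rng(12))
    b = ev.truth_basophil
    assert np.median(ev.cd203c[b]) > 4 * np.median(ev.cd203c[~b])
    assert np.median(ev.ssc[b]) < np.median(ev.ssc[~b])


def test_nonresponder_tail_assignment(study_run):
    """Non-responders are the least sensitive subjects of each group."""
    cohort, _ = study_run
    for group in ("PA", "PS"):
        anchors_nr = [
            s._anchor["peanut"]
            for s in cohort.subjects
            if s.group == group and s.non_responder["peanut"]
        ]
        latents_resp = [
            s.latent_ac50["peanut"]
            for s in cohort.subjects
            if s.group == group and s.latent_ac50["peanut"] is not None
        ]
        assert max(anchors_nr) <= min(latents_resp)


def test_planted_nonresponder_counts(study_run):
    cohort, _ = study_run
    nr_pa = sum(
        s.non_responder["peanut"] for s in cohort.subjects if s.group == "PA"
    )
    nr_ps = sum(
        s.non_responder["peanut"] for s in cohort.subjects if s.group == "PS"
    )
    assert nr_pa == 3  # round(3/47 * 47)
    assert nr_ps == 5  # round(5/22 * 22)
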