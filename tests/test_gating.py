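import numpy as np
import pytest

from batkit import (
    CohortSpec,
    EventTable,
    GatingConfig,
    InsufficientEventsError,
    gate_basophils,
    percent_activated,
    qc_subject,
    set_cd63_threshold,
    simulate_tube,
)
from batkit.gating import ActivationMeasurement
from batkit.simulate import SubjectRecord


def _subject(spont=2.0, posctrl=60.0):
    return SubjectRecord(
        subject_id="X",
        group="PA",
        latent_ac50={"peanut": 6.0},
        non_responder={"peanut": False},
        latent_spontaneous=spont,
        latent_posctrl=posctrl,
    )


def _tube(rng, n_baso=600, n_other=5400):
    spec = CohortSpec(events_per_tube=n_baso, non_basophil_events=n_other).subset(
        allergens=("peanut",)
    )
    return simulate_tube(_subject(), "negctrl", None, spec, rng)


def test_recovers_planted_basophil_count(rng):
    ev = _tube(rng)
    gate = gate_basophils(ev)
    planted = int(ev.truth_basophil.sum())
    assert not gate.insufficient_events
    assert abs(gate.n_basophils - planted) <= 0.05 * planted


def test_event_conservation(rng):
    ev = _tube(rng)
    gate = gate_basophils(ev)
    in_gate = (ev.cd203c > gate.cd203c_threshold) & (ev.ssc <= gate.ssc_threshold)
    assert gate.n_basophils + int((~in_gate).sum()) == ev.n_events


def test_pure_basophil_input_passes_through(rng):
    ev = _tube(rng)
    baso_only = ev.subset(ev.truth_basophil)
    gate = gate_basophils(baso_only)
    assert gate.n_basophils == baso_only.n_events


def test_gating_is_idempotent(rng):
    ev = _tube(rng)
    once = gate_basophils(ev)
    twice = gate_basophils(once.basophils)
    assert twice.n_basophils == once.n_basophils
    np.testing.assert_array_equal(once.basophils.cd63, twice.basophils.cd63)


def test_no_cd203c_high_population_flagged(rng):
    # only dim (non-basophil) events; with an absolute floor configured the
    # gate comes back empty-handed and flags the tube
    n = 3000
    ev = EventTable(
        ssc=rng.lognormal(6.5, 0.5, n),
        cd203c=rng.lognormal(3.9, 0.5, n),
        cd63=rng.lognormal(3.4, 0.5, n),
    )
    cfg = GatingConfig(cd203c_min=500.0)
    gate = gate_basophils(ev, cfg)
    assert gate.insufficient_events
    assert gate.n_basophils < cfg.min_basophils


def test_too_few_events_flagged(rng):
    ev = _tube(rng)
    ev = ev.subset(np.arange(ev.n_events) < 50)
    gate = gate_basophils(ev)
    assert gate.insufficient_events


def test_reapplied_gate_uses_identical_thresholds(rng):
    ev1 = _tube(rng)
    ev2 = _tube(rng)
    gate = gate_basophils(ev1)
    reap = gate_basophils(ev2, gate=gate)
    assert reap.cd203c_threshold == gate.cd203c_threshold
    assert reap.ssc_threshold == gate.ssc_threshold


# --- CD63 threshold ---------------------------------------------------------


def test_threshold_of_point_mass_is_that_constant():
    ev = EventTable(
        ssc=np.ones(400), cd203c=np.ones(400), cd63=np.full(400, 7.5)
    )
    assert set_cd63_threshold(ev) == pytest.approx(7.5)


def test_threshold_matches_lognormal_quantile(rng):
    # standard log-normal resting CD63: the 0.995 parametric quantile is
    # exp(z_0.995 * sigma) with sigma = 1
    ev = EventTable(
        ssc=np.ones(200_000),
        cd203c=np.ones(200_000),
        cd63=rng.lognormal(0.0, 1.0, 200_000),
    )
    thr = set_cd63_threshold(ev)
    assert np.log(thr) == pytest.approx(2.5758, rel=0.05)


def test_threshold_robust_to_activated_tail(rng):
    """A 15 % spontaneously-activated tail must not push the threshold into
    the activated component: an empirical 0.995 quantile would land above the
    activated cells and hide the spontaneous activation entirely, while the
    robust parametric quantile keeps counting them."""
    n = 50_000
    resting = rng.lognormal(3.4, 0.5, n)
    activated = rng.lognormal(3.4 + 5 * 0.5, 0.5, int(0.15 * n))
    cd63 = np.concatenate([resting, activated])
    mixed = EventTable(
        ssc=np.ones(cd63.size), cd203c=np.ones(cd63.size), cd63=cd63
    )
    t_mixed = set_cd63_threshold(mixed)
    # the naive empirical quantile sits inside the activated cloud ...
    assert np.quantile(cd63, 0.995) > np.median(activated)
    # ... the robust threshold stays well below it
    assert t_mixed < np.median(activated) / 2
    # nearly all activated cells are counted as CD63+
    assert (activated > t_mixed).mean() > 0.95
    # and the measured percentage still trips the >10 % spontaneous QC rule
    pct = percent_activated(mixed, t_mixed).percent_cd63_positive
    assert pct > 10.0


def test_threshold_insufficient_events():
    ev = EventTable(ssc=np.ones(10), cd203c=np.ones(10), cd63=np.ones(10))
    with pytest.raises(InsufficientEventsError):
        set_cd63_threshold(ev)


def test_distinct_subjects_distinct_thresholds(rng):
    a = EventTable(np.ones(500), np.ones(500), rng.lognormal(3.0, 0.4, 500))
    b = EventTable(np.ones(500), np.ones(500), rng.lognormal(4.0, 0.4, 500))
    assert set_cd63_threshold(a) != set_cd63_threshold(b)


# --- percent activated ------------------------------------------------------


def test_percent_activated_boundaries():
    cd63 = np.concatenate([np.full(510, 1.0), np.full(90, 100.0)])
    ev = EventTable(np.ones(600), np.ones(600), cd63, subject_id="s")
    assert percent_activated(ev, 200.0).percent_cd63_positive == 0.0
    assert percent_activated(ev, 0.5).percent_cd63_positive == 100.0
    # 90 of 600 above: 15.0 %
    assert percent_activated(ev, 10.0).percent_cd63_positive == pytest.approx(15.0)


# --- subject QC -------------------------------------------------------------


def _meas(stimulus, pct, step=None, subject="s"):
    return ActivationMeasurement(
        subject_id=subject,
        stimulus=stimulus,
        dilution_step=step,
        n_basophils=600,
        percent_cd63_positive=pct,
        cd63_threshold=10.0,
    )


def test_spontaneous_activation_excludes_subject():
    qc = qc_subject([_meas("negctrl", 12.0), _meas("posctrl", 60.0)])
    assert qc.excluded_spontaneous
    assert not qc.included


def test_exclusion_cutoff_is_strict():
    qc = qc_subject([_meas("negctrl", 10.0), _meas("posctrl", 60.0)])
    assert not qc.excluded_spontaneous


def test_nonresponder_below_cutoff_stays_included():
    ms = [_meas("negctrl", 1.0), _meas("posctrl", 60.0)]
    ms += [_meas("peanut", 14.9, step=k) for k in range(1, 13)]
    qc = qc_subject(ms)
    assert qc.included
    assert qc.responder["peanut"] is False


def test_responder_boundary_inclusive_at_15():
    ms = [_meas("negctrl", 0.0), _meas("posctrl", 60.0), _meas("peanut", 15.0, 1),
          _meas("peanut", 3.0, 2)]
    qc = qc_subject(ms)
    assert qc.responder["peanut"] is True


def test_posctrl_nonresponder_excluded():
    qc = qc_subject([_meas("negctrl", 1.0), _meas("posctrl", 5.0)])
    assert qc.excluded_posctrl_nonresponder
    assert not qc.included


def test_missing_controls_is_structural_error():
    with pytest.raises(ValueError, match="control"):
        qc_subject([_meas("peanut", 20.0, 1)])


def test_negctrl_percent_tracks_baseline_plus_quantile_complement(study_run):
    """Included subjects' negative-control %CD63+ ~ spontaneous baseline plus
    the threshold quantile complement (0.5 %), within binomial error."""
    cohort, report = study_run
    qc = report.qc_table
    truth = {s.subject_id: s.latent_spontaneous for s in cohort.subjects}
    ok = qc[qc["included"]]
    resid = [
        row["negctrl_percent"] - (truth[row["subject_id"]] + 0.5)
        for _, row in ok.iterrows()
    ]
    # binomial sd at p ~ 0.03, n ~ 600 is ~0.7 percentage points
    assert abs(np.mean(resid)) < 0.5
    assert np.percentile(np.abs(resid), 95) < 2.5
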