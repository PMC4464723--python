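"""Synthetic BAT cohorts with known ground truth.

Generates whole cohorts — subjects, tube manifests and per-tube flow-cytometry
event tables — whose statistical structure matches the study design the rest of
the package analyses: three groups (peanut-allergic PA, peanut-sensitized PS,
healthy controls C), per subject one negative-control tube, one
stimulation-control tube and serial 10-fold allergen dilutions, with roughly
600 basophils acquired per tube.

Latent model
------------
Each responding subject carries a latent threshold sensitivity *a* (the "true"
AC50, in log10 dilution units) drawn from a logistic distribution parameterised
by the group's target median and IQR (for a logistic, IQR = 2 s ln 3).  The
subject's activation curve is a descending Hill-type logistic in the dilution
coordinate *d*::

    activation(d) = s + (pc - s) / (1 + 10 ** (h * (d - m)))

with spontaneous baseline *s*, positive-control plateau *pc* and Hill slope
*h*; the midpoint *m* is placed so that the curve crosses ``pc / 2`` exactly at
*a*.  Non-responders are the least-sensitive ``round(fraction * n)`` subjects
of each group: their plateau is drawn below the 15 % positivity cutoff, so the
analysis pipeline flags them exactly as the operational definition demands.
Healthy controls never respond to allergen (flat at baseline).

Event model
-----------
Each tube draws a Poisson number of basophils (high CD203c, low SSC) and
non-basophil events (the converse); channel intensities are log-normal
mixtures with configurable separation.  Activated basophils shift their CD63
intensity up by a configurable number of resting standard deviations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dilution import DEFAULT_SERIES, DilutionSeries

__all__ = [
    "CohortConfigError",
    "LatentGroupParams",
    "ChannelModel",
    "CohortSpec",
    "SubjectRecord",
    "SyntheticCohort",
    "sample_latent_ac50",
    "activation_curve",
    "simulate_tube",
    "generate_cohort",
    "default_cohort_spec",
]

GROUPS = ("PA", "PS", "C")


class CohortConfigError(ValueError):
    """An invalid field in a :class:`CohortSpec`."""


@dataclass(frozen=True)
class LatentGroupParams:
    """Latent AC50 distribution for one group x allergen.

    ``target_median`` / ``target_iqr`` are in log10 dilution units.  A ``None``
    median marks a group that never responds to this allergen (healthy
    controls).  ``non_responder_fraction`` of the group (rounded to a count)
    are non-responders: the least-sensitive subjects, whose activation plateau
    is drawn below the positivity cutoff.
    """

    target_median: float | None
    target_iqr: float | None = None
    family: str = "logistic"
    non_responder_fraction: float = 0.0

    def validate(self, name: str) -> None:
        if self.family != "logistic":
            raise CohortConfigError(
                f"latent[{name}].family: unsupported family {self.family!r}"
            )
        if self.target_median is not None:
            if self.target_iqr is None or self.target_iqr <= 0:
                raise CohortConfigError(
                    f"latent[{name}].target_iqr must be > 0, got {self.target_iqr}"
                )
        if not 0.0 <= self.non_responder_fraction <= 1.0:
            raise CohortConfigError(
                f"latent[{name}].non_responder_fraction must be in [0, 1], "
                f"got {self.non_responder_fraction}"
            )


@dataclass(frozen=True)
class ChannelModel:
    """Log-normal intensity components, as (mean, sd) of the natural log.

    ``cd63_activated_shift`` is the upward shift of activated-cell CD63, in
    units of the resting log-sd; 5 sd keeps >99 % of activated cells above a
    0.995 resting-quantile threshold, so measured %CD63+ tracks the activation
    probability to within binomial error.
    """

    cd203c_basophil: tuple[float, float] = (6.9, 0.5)
    cd203c_other: tuple[float, float] = (3.9, 0.5)
    ssc_basophil: tuple[float, float] = (5.0, 0.3)
    ssc_other: tuple[float, float] = (6.5, 0.5)
    cd63_resting: tuple[float, float] = (3.4, 0.5)
    cd63_activated_shift: float = 5.0


def _default_latent() -> dict[str, dict[str, LatentGroupParams]]:
    # Peanut targets are the study's printed group medians/IQRs and
    # non-responder counts (3/47 PA, 5/22 PS). Soy and birch were reported
    # only as figures without significant group separation; their values here
    # are loose choices with overlapping distributions over the 5-step range.
    return {
        "PA": {
            "peanut": LatentGroupParams(6.84, 4.50, non_responder_fraction=3 / 47),
            "soy": LatentGroupParams(2.8, 3.5, non_responder_fraction=0.35),
            "birch": LatentGroupParams(2.0, 3.0, non_responder_fraction=0.50),
        },
        "PS": {
            "peanut": LatentGroupParams(3.55, 4.15, non_responder_fraction=5 / 22),
            "soy": LatentGroupParams(2.0, 3.5, non_responder_fraction=0.45),
            "birch": LatentGroupParams(2.5, 3.0, non_responder_fraction=0.40),
        },
        "C": {
            "peanut": LatentGroupParams(None),
            "soy": LatentGroupParams(None),
            "birch": LatentGroupParams(None),
        },
    }


# Synthetic covariates: per-group log10-median and log10-sd of loosely
# realistic IgE-type quantities (kU/l or ISU) plus an SPT wheal grade. They
# exist to exercise correlation code only; no biological accuracy is claimed.
_COVARIATE_MODEL: dict[str, dict[str, tuple[float, float]]] = {
    # name: {group: (log10 median, log10 sd)}
    "total_ige": {"PA": (2.3, 0.5), "PS": (2.0, 0.5), "C": (1.2, 0.5)},
    "ige_peanut": {"PA": (1.3, 0.6), "PS": (0.3, 0.5), "C": (-1.0, 0.3)},
    "ige_arah2": {"PA": (0.9, 0.7), "PS": (-1.0, 0.4), "C": (-1.3, 0.2)},
    "ige_arah6": {"PA": (0.9, 0.7), "PS": (-1.0, 0.4), "C": (-1.3, 0.2)},
    "ige_arah8": {"PA": (-0.5, 0.6), "PS": (0.6, 0.6), "C": (-1.0, 0.3)},
    "spt_peanut": {"PA": (0.9, 0.2), "PS": (0.6, 0.2), "C": (-1.0, 0.2)},
}
#: Loading of log10 covariate on (latent peanut AC50 - group median); small,
#: so covariate/AC50 correlations are present but weak, as in the study.
_COVARIATE_AC50_LOADING = 0.08


@dataclass(frozen=True)
class CohortSpec:
    """Full description of a synthetic cohort; the defaults are the study
    conditions (see :func:`default_cohort_spec`)."""

    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"PA": 47, "PS": 22, "C": 22}
    )
    series: dict[str, DilutionSeries] = field(
        default_factory=lambda: dict(DEFAULT_SERIES)
    )
    latent: dict[str, dict[str, LatentGroupParams]] = field(
        default_factory=_default_latent
    )
    hill_slope: float = 1.5
    #: Uniform range (percent) of normal spontaneous CD63 positivity.
    spontaneous_range: tuple[float, float] = (0.5, 5.0)
    #: Uniform range for planted spontaneous-activation QC violators; sits
    #: well above the 10 % exclusion rule so binomial noise cannot hide them.
    spontaneous_violation_range: tuple[float, float] = (14.0, 20.0)
    #: Normal(mean, sd) positive-control activation, clipped to a range.
    posctrl_mean: float = 60.0
    posctrl_sd: float = 8.0
    posctrl_clip: tuple[float, float] = (30.0, 95.0)
    #: Uniform range for planted positive-control non-responders; sits well
    #: below the 10 % responder floor.
    posctrl_violation_range: tuple[float, float] = (2.0, 6.0)
    #: Uniform range of the activation plateau of allergen non-responders,
    #: kept below the 15 % positivity cutoff.
    nonresponder_plateau_range: tuple[float, float] = (2.0, 10.0)
    planted_spontaneous: dict[str, int] = field(
        default_factory=lambda: {"PA": 3, "PS": 1, "C": 0}
    )
    planted_posctrl_nonresponders: dict[str, int] = field(
        default_factory=lambda: {"PA": 1, "PS": 0, "C": 0}
    )
    events_per_tube: int = 600
    non_basophil_events: int = 2400
    #: Latent AC50 values are clipped to [0, d_max + latent_clip_margin].
    latent_clip_margin: float = 2.0
    channel_model: ChannelModel = field(default_factory=ChannelModel)
    covariates: bool = True
    seed: int = 0

    def validate(self) -> None:
        for g, n in self.group_sizes.items():
            if n < 0:
                raise CohortConfigError(f"group_sizes[{g}] must be >= 0, got {n}")
        if self.events_per_tube < 1:
            raise CohortConfigError(
                f"events_per_tube must be >= 1, got {self.events_per_tube}"
            )
        if self.non_basophil_events < 0:
            raise CohortConfigError(
                f"non_basophil_events must be >= 0, got {self.non_basophil_events}"
            )
        if self.hill_slope <= 0:
            raise CohortConfigError(f"hill_slope must be > 0, got {self.hill_slope}")
        for g in self.group_sizes:
            if g not in self.latent:
                raise CohortConfigError(f"latent has no entry for group {g!r}")
            for allergen in self.series:
                if allergen not in self.latent[g]:
                    raise CohortConfigError(
                        f"latent[{g}] has no entry for allergen {allergen!r}"
                    )
                self.latent[g][allergen].validate(f"{g}.{allergen}")
        for label, planted in (
            ("planted_spontaneous", self.planted_spontaneous),
            ("planted_posctrl_nonresponders", self.planted_posctrl_nonresponders),
        ):
            for g, k in planted.items():
                if k < 0 or k > self.group_sizes.get(g, 0):
                    raise CohortConfigError(
                        f"{label}[{g}] = {k} exceeds group size "
                        f"{self.group_sizes.get(g, 0)}"
                    )

    def subset(self, groups=None, allergens=None, **overrides) -> "CohortSpec":
        """A copy restricted to some groups and/or allergens."""
        groups = tuple(groups) if groups is not None else tuple(self.group_sizes)
        allergens = tuple(allergens) if allergens is not None else tuple(self.series)
        kwargs = {
            "group_sizes": {g: self.group_sizes[g] for g in groups},
            "series": {a: self.series[a] for a in allergens},
            "latent": {
                g: {a: self.latent[g][a] for a in allergens} for g in groups
            },
            "planted_spontaneous": {
                g: self.planted_spontaneous.get(g, 0) for g in groups
            },
            "planted_posctrl_nonresponders": {
                g: self.planted_posctrl_nonresponders.get(g, 0) for g in groups
            },
        }
        kwargs.update(overrides)  # explicit overrides win
        return replace(self, **kwargs)


def default_cohort_spec(seed: int = 0, **overrides) -> CohortSpec:
    """The calibrated default cohort: PA n=47, PS n=22, C n=22; peanut, soy
    and birch series; printed group medians/IQRs and non-responder counts;
    3 PA + 1 PS planted spontaneous-activation violations and 1 PA planted
    positive-control non-responder."""
    return replace(CohortSpec(seed=seed), **overrides) if overrides else CohortSpec(
        seed=seed
    )


@dataclass
class SubjectRecord:
    """Ground truth for one synthetic subject."""

    subject_id: str
    group: str
    #: latent AC50 per allergen (log10 dilution units); None for allergen
    #: non-responders and for never-responding groups.
    latent_ac50: dict[str, float | None]
    #: True where the subject is an allergen non-responder by construction.
    non_responder: dict[str, bool]
    latent_spontaneous: float
    latent_posctrl: float
    planted_spontaneous_violation: bool = False
    planted_posctrl_nonresponder: bool = False
    covariates: dict[str, float] = field(default_factory=dict)
    #: internal: curve plateau per allergen for non-responders, and the curve
    #: midpoint anchor (the underlying latent draw, kept even when the subject
    #: is a non-responder).
    _plateau: dict[str, float] = field(default_factory=dict, repr=False)
    _anchor: dict[str, float] = field(default_factory=dict, repr=False)


@dataclass
class SyntheticCohort:
    """A generated cohort: subject ground truth, tube manifest and events.

    ``manifest`` columns: tube_id, subject_id, group, stimulus, dilution_step,
    event_file (empty until written to disk).  ``events`` maps tube_id to its
    :class:`~batkit.gating.EventTable`.
    """

    spec: CohortSpec
    subjects: list[SubjectRecord]
    manifest: pd.DataFrame
    events: dict[str, "EventTable"]  # noqa: F821 - see batkit.gating

    def subject(self, subject_id: str) -> SubjectRecord:
        for s in self.subjects:
            if s.subject_id == subject_id:
                return s
        raise KeyError(subject_id)

    def tubes_of(self, subject_id: str) -> pd.DataFrame:
        return self.manifest[self.manifest["subject_id"] == subject_id]


def sample_latent_ac50(
    params: LatentGroupParams,
    n: int,
    rng: np.random.Generator | int,
    *,
    d_max: float,
    clip_margin: float = 2.0,
) -> np.ndarray:
    """Draw latent AC50 values for one group x allergen.

    Logistic with location = target median and scale s = IQR / (2 ln 3), so
    the population median and IQR equal the configured targets; values are
    clipped to [0, d_max + clip_margin].  Clipping (rather than re-drawing)
    leaves every quantile between the clip points — in particular the median
    and, at the default parameters, the quartiles — unchanged.
    """
    params.validate("sample_latent_ac50")
    if n < 0:
        raise CohortConfigError(f"n must be >= 0, got {n}")
    if params.target_median is None:
        raise CohortConfigError("sample_latent_ac50 called for a non-responding group")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    scale = params.target_iqr / (2.0 * math.log(3.0))
    values = rng.logistic(params.target_median, scale, size=n)
    return np.clip(values, 0.0, d_max + clip_margin)


def activation_curve(
    d,
    *,
    anchor: float,
    spontaneous: float,
    plateau: float,
    hill_slope: float,
    anchored_at_half_plateau: bool = True,
) -> np.ndarray:
    """Activation (percent) at log10 dilution *d* for one subject.

    ``plateau`` is the maximal activation (the positive-control level for
    responders, a sub-cutoff value for non-responders).  When
    ``anchored_at_half_plateau`` the curve midpoint is positioned so that
    activation crosses ``plateau / 2`` exactly at ``anchor`` — the subject's
    true AC50.  Degenerate cases (plateau at or below baseline) are flat at
    the spontaneous baseline.
    """
    d = np.asarray(d, dtype=float)
    if plateau / 2.0 <= spontaneous or plateau <= spontaneous:
        return np.full(d.shape, spontaneous)
    if anchored_at_half_plateau:
        m = anchor - math.log10((plateau / 2.0) / (plateau / 2.0 - spontaneous)) / (
            hill_slope
        )
    else:
        m = anchor
    return spontaneous + (plateau - spontaneous) / (
        1.0 + 10.0 ** (hill_slope * (d - m))
    )


def _tube_activation_probability(
    subject: SubjectRecord, stimulus: str, dilution_step, spec: CohortSpec
) -> float:
    if stimulus == "negctrl":
        return subject.latent_spontaneous / 100.0
    if stimulus == "posctrl":
        return subject.latent_posctrl / 100.0
    if stimulus not in spec.series:
        raise ValueError(f"unknown stimulus {stimulus!r}")
    series = spec.series[stimulus]
    d = float(series.log10_dilution(dilution_step))
    s = subject.latent_spontaneous
    if subject.non_responder.get(stimulus, False):
        plateau = subject._plateau.get(stimulus, s)
        anchor = subject._anchor.get(stimulus, d)
        act = activation_curve(
            d,
            anchor=anchor,
            spontaneous=s,
            plateau=plateau,
            hill_slope=spec.hill_slope,
            anchored_at_half_plateau=False,
        )
    elif subject.latent_ac50.get(stimulus) is None:
        act = s  # never-responding group: flat at baseline
    else:
        act = activation_curve(
            d,
            anchor=subject.latent_ac50[stimulus],
            spontaneous=s,
            plateau=subject.latent_posctrl,
            hill_slope=spec.hill_slope,
        )
    return float(act) / 100.0


def simulate_tube(
    subject: SubjectRecord,
    stimulus: str,
    dilution_step,
    spec: CohortSpec,
    rng: np.random.Generator | int,
):
    """Simulate one tube's event table.

    Event counts are Poisson around the configured totals; the number of
    CD63-activated basophils is binomial with the subject's modelled
    activation probability for this stimulus.  The returned
    :class:`~batkit.gating.EventTable` carries ``truth_basophil`` /
    ``truth_activated`` masks for generator-level checks; they are not written
    to event CSVs.
    """
    from .gating import EventTable  # local import to avoid a cycle

    if stimulus in ("negctrl", "posctrl"):
        if dilution_step is not None:
            raise ValueError(f"{stimulus} tubes carry no dilution step")
    elif stimulus in spec.series:
        if dilution_step is None or not 1 <= int(dilution_step) <= spec.series[
            stimulus
        ].n_steps:
            raise ValueError(
                f"dilution_step {dilution_step!r} invalid for {stimulus!r}"
            )
    else:
        raise ValueError(f"unknown stimulus {stimulus!r}")

    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    p = _tube_activation_probability(subject, stimulus, dilution_step, spec)
    cm = spec.channel_model

    n_b = max(1, int(rng.poisson(spec.events_per_tube)))
    n_o = int(rng.poisson(spec.non_basophil_events)) if spec.non_basophil_events else 0
    k = int(rng.binomial(n_b, p))

    mu63, sd63 = cm.cd63_resting
    mu63_act = mu63 + cm.cd63_activated_shift * sd63
    cd63_b = np.empty(n_b)
    cd63_b[:k] = rng.lognormal(mu63_act, sd63, size=k)
    cd63_b[k:] = rng.lognormal(mu63, sd63, size=n_b - k)
    activated = np.zeros(n_b, dtype=bool)
    activated[:k] = True

    cd203c = np.concatenate(
        [
            rng.lognormal(*cm.cd203c_basophil, size=n_b),
            rng.lognormal(*cm.cd203c_other, size=n_o),
        ]
    )
    ssc = np.concatenate(
        [
            rng.lognormal(*cm.ssc_basophil, size=n_b),
            rng.lognormal(*cm.ssc_other, size=n_o),
        ]
    )
    cd63 = np.concatenate([cd63_b, rng.lognormal(mu63, 0.6, size=n_o)])
    truth_b = np.concatenate([np.ones(n_b, dtype=bool), np.zeros(n_o, dtype=bool)])
    truth_a = np.concatenate([activated, np.zeros(n_o, dtype=bool)])

    order = rng.permutation(n_b + n_o)
    return EventTable(
        ssc=ssc[order],
        cd203c=cd203c[order],
        cd63=cd63[order],
        subject_id=subject.subject_id,
        stimulus=stimulus,
        dilution_step=None if dilution_step is None else int(dilution_step),
        truth_basophil=truth_b[order],
        truth_activated=truth_a[order],
    )


def _draw_subjects(spec: CohortSpec, rng: np.random.Generator) -> list[SubjectRecord]:
    subjects: list[SubjectRecord] = []
    for group in spec.group_sizes:
        n = spec.group_sizes[group]
        if n == 0:
            continue
        spont = rng.uniform(*spec.spontaneous_range, size=n)
        posctrl = np.clip(
            rng.normal(spec.posctrl_mean, spec.posctrl_sd, size=n), *spec.posctrl_clip
        )

        # Planted QC violations on disjoint subject sets.
        k_sp = spec.planted_spontaneous.get(group, 0)
        k_pc = spec.planted_posctrl_nonresponders.get(group, 0)
        chosen = rng.choice(n, size=k_sp + k_pc, replace=False) if k_sp + k_pc else []
        sp_idx = set(np.asarray(chosen[:k_sp], dtype=int).tolist())
        pc_idx = set(np.asarray(chosen[k_sp:], dtype=int).tolist())
        for i in sp_idx:
            spont[i] = rng.uniform(*spec.spontaneous_violation_range)
        for i in pc_idx:
            posctrl[i] = rng.uniform(*spec.posctrl_violation_range)

        group_subjects = [
            SubjectRecord(
                subject_id=f"{group}{i + 1:03d}",
                group=group,
                latent_ac50={},
                non_responder={},
                latent_spontaneous=float(spont[i]),
                latent_posctrl=float(posctrl[i]),
                planted_spontaneous_violation=i in sp_idx,
                planted_posctrl_nonresponder=i in pc_idx,
            )
            for i in range(n)
        ]

        for allergen, series in spec.series.items():
            params = spec.latent[group][allergen]
            if params.target_median is None:
                for s in group_subjects:
                    s.latent_ac50[allergen] = None
                    s.non_responder[allergen] = False
                continue
            latents = sample_latent_ac50(
                params,
                n,
                rng,
                d_max=series.d_max,
                clip_margin=spec.latent_clip_margin,
            )
            n_nr = round(params.non_responder_fraction * n)
            nr_idx = set(np.argsort(latents, kind="stable")[:n_nr].tolist())
            plateaus = rng.uniform(*spec.nonresponder_plateau_range, size=n)
            for i, s in enumerate(group_subjects):
                s._anchor[allergen] = float(latents[i])
                if i in nr_idx:
                    s.latent_ac50[allergen] = None
                    s.non_responder[allergen] = True
                    s._plateau[allergen] = float(plateaus[i])
                else:
                    s.latent_ac50[allergen] = float(latents[i])
                    s.non_responder[allergen] = False

        if spec.covariates:
            for s in group_subjects:
                a = s._anchor.get("peanut")
                med = spec.latent.get(group, {}).get("peanut")
                centred = (
                    a - med.target_median
                    if a is not None and med is not None and med.target_median
                    else 0.0
                )
                for name, by_group in _COVARIATE_MODEL.items():
                    if group not in by_group:
                        continue
                    m, sd = by_group[group]
                    log10v = (
                        m
                        + _COVARIATE_AC50_LOADING * centred
                        + rng.normal(0.0, sd)
                    )
                    s.covariates[name] = float(10.0**log10v)

        subjects.extend(group_subjects)
    return subjects


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate a full synthetic cohort (deterministic for a fixed seed).

    Per subject: one ``negctrl`` tube, one ``posctrl`` tube, and one tube per
    allergen dilution step.  Returns the subjects (with ground truth), the
    tube manifest and the simulated event tables.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    subjects = _draw_subjects(spec, rng)

    rows = []
    events = {}
    tube_no = 0
    for s in subjects:
        layout = [("negctrl", None), ("posctrl", None)]
        for allergen, series in spec.series.items():
            layout.extend((allergen, int(k)) for k in series.steps)
        for stimulus, step in layout:
            tube_no += 1
            tube_id = f"T{tube_no:05d}"
            events[tube_id] = simulate_tube(s, stimulus, step, spec, rng)
            rows.append(
                {
                    "tube_id": tube_id,
                    "subject_id": s.subject_id,
                    "group": s.group,
                    "stimulus": stimulus,
                    "dilution_step": step,
                    "event_file": "",
                }
            )
    manifest = pd.DataFrame(
        rows,
        columns=[
            "tube_id",
            "subject_id",
            "group",
            "stimulus",
            "dilution_step",
            "event_file",
        ],
    )
    if not manifest.empty:
        manifest["dilution_step"] = manifest["dilution_step"].astype("Int64")
    return SyntheticCohort(spec=spec, subjects=subjects, manifest=manifest, events=events)
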