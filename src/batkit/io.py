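"""CSV and YAML interfaces.

Canonical on-disk formats:

* tube manifest CSV: ``tube_id, subject_id, group, stimulus, dilution_step,
  event_file`` (event_file relative to the manifest's directory);
* event CSV per tube: ``ssc, cd203c, cd63`` (floating point, arbitrary
  fluorescence units);
* subject ground-truth CSV (synthetic cohorts only);
* activation-measurement, QC, AC50 and results CSVs written by the pipeline;
* run configuration as a YAML document mirroring the spec dataclasses.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dilution import DilutionSeries
from .gating import ActivationMeasurement, EventTable, GatingConfig, QCStatus
from .simulate import (
    ChannelModel,
    CohortSpec,
    LatentGroupParams,
    SubjectRecord,
    SyntheticCohort,
)

__all__ = [
    "write_cohort",
    "read_cohort",
    "write_measurements",
    "read_measurements",
    "write_qc",
    "cohort_spec_to_dict",
    "cohort_spec_from_dict",
    "load_cohort_spec",
    "dump_cohort_spec",
    "gating_config_from_dict",
]


def write_cohort(cohort: SyntheticCohort, outdir) -> Path:
    """Write a synthetic cohort: manifest, per-tube event CSVs, ground truth."""
    outdir = Path(outdir)
    (outdir / "events").mkdir(parents=True, exist_ok=True)
    manifest = cohort.manifest.copy()
    paths = []
    for tube_id in manifest["tube_id"]:
        rel = f"events/{tube_id}.csv"
        cohort.events[tube_id].to_frame().to_csv(outdir / rel, index=False)
        paths.append(rel)
    manifest["event_file"] = paths
    manifest.to_csv(outdir / "manifest.csv", index=False)
    subjects_frame(cohort.subjects).to_csv(outdir / "subjects.csv", index=False)
    return outdir / "manifest.csv"


def subjects_frame(subjects: list[SubjectRecord]) -> pd.DataFrame:
    """Ground-truth table, one row per subject x allergen."""
    rows = []
    for s in subjects:
        base = {
            "subject_id": s.subject_id,
            "group": s.group,
            "latent_spontaneous": s.latent_spontaneous,
            "latent_posctrl": s.latent_posctrl,
            "planted_spontaneous_violation": s.planted_spontaneous_violation,
            "planted_posctrl_nonresponder": s.planted_posctrl_nonresponder,
        }
        base.update({f"cov_{k}": v for k, v in s.covariates.items()})
        for allergen in s.latent_ac50:
            row = dict(base)
            row["allergen"] = allergen
            row["latent_ac50"] = (
                np.nan if s.latent_ac50[allergen] is None else s.latent_ac50[allergen]
            )
            row["non_responder"] = s.non_responder[allergen]
            rows.append(row)
    return pd.DataFrame(rows)


def read_cohort(directory, spec: CohortSpec | None = None) -> SyntheticCohort:
    """Read a cohort written by :func:`write_cohort` (manifest + event CSVs).

    Ground truth is not reconstructed into SubjectRecords; the returned
    cohort carries an empty subject list unless ``subjects.csv`` is only
    needed via pandas by the caller.
    """
    directory = Path(directory)
    manifest = pd.read_csv(directory / "manifest.csv")
    manifest["dilution_step"] = manifest["dilution_step"].astype("Int64")
    events = {}
    for _, row in manifest.iterrows():
        df = pd.read_csv(directory / row["event_file"])
        step = row["dilution_step"]
        events[row["tube_id"]] = EventTable.from_frame(
            df,
            subject_id=row["subject_id"],
            stimulus=row["stimulus"],
            dilution_step=None if pd.isna(step) else int(step),
        )
    return SyntheticCohort(spec=spec, subjects=[], manifest=manifest, events=events)


def write_measurements(measurements: list[ActivationMeasurement], path) -> None:
    pd.DataFrame([dataclasses.asdict(m) for m in measurements]).to_csv(
        path, index=False
    )


def read_measurements(path) -> list[ActivationMeasurement]:
    df = pd.read_csv(path)
    out = []
    for _, r in df.iterrows():
        step = r["dilution_step"]
        out.append(
            ActivationMeasurement(
                subject_id=str(r["subject_id"]),
                stimulus=str(r["stimulus"]),
                dilution_step=None if pd.isna(step) else int(step),
                n_basophils=int(r["n_basophils"]),
                percent_cd63_positive=float(r["percent_cd63_positive"]),
                cd63_threshold=float(r["cd63_threshold"]),
                insufficient_events=bool(r.get("insufficient_events", False)),
            )
        )
    return out


def write_qc(statuses: list[QCStatus], path) -> None:
    rows = []
    for s in statuses:
        row = {
            "subject_id": s.subject_id,
            "excluded_spontaneous": s.excluded_spontaneous,
            "excluded_posctrl_nonresponder": s.excluded_posctrl_nonresponder,
            "excluded_insufficient_events": s.excluded_insufficient_events,
            "included": s.included,
            "negctrl_percent": s.negctrl_percent,
            "posctrl_percent": s.posctrl_percent,
        }
        row.update({f"responder_{k}": v for k, v in s.responder.items()})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# configuration documents


def cohort_spec_to_dict(spec: CohortSpec) -> dict:
    d = {
        "group_sizes": dict(spec.group_sizes),
        "series": {
            a: {
                "n_steps": s.n_steps,
                "initial_dilution_factor": s.initial_dilution_factor,
                "fold_per_step": s.fold_per_step,
                "stock_protein_concentration_mg_ml":
                    s.stock_protein_concentration_mg_ml,
                "convention": s.convention,
            }
            for a, s in spec.series.items()
        },
        "latent": {
            g: {
                a: {
                    "target_median": p.target_median,
                    "target_iqr": p.target_iqr,
                    "family": p.family,
                    "non_responder_fraction": p.non_responder_fraction,
                }
                for a, p in by_allergen.items()
            }
            for g, by_allergen in spec.latent.items()
        },
        "channel_model": dataclasses.asdict(spec.channel_model),
    }
    for f in dataclasses.fields(spec):
        if f.name in d or f.name in ("series", "latent", "channel_model"):
            continue
        v = getattr(spec, f.name)
        d[f.name] = list(v) if isinstance(v, tuple) else v
    return d


def cohort_spec_from_dict(d: dict) -> CohortSpec:
    d = dict(d)
    kwargs = {}
    if "series" in d:
        kwargs["series"] = {
            a: DilutionSeries(allergen=a, **sd) for a, sd in d.pop("series").items()
        }
    if "latent" in d:
        kwargs["latent"] = {
            g: {a: LatentGroupParams(**pd_) for a, pd_ in by_a.items()}
            for g, by_a in d.pop("latent").items()
        }
    if "channel_model" in d:
        cm = {
            k: tuple(v) if isinstance(v, (list, tuple)) else v
            for k, v in d.pop("channel_model").items()
        }
        kwargs["channel_model"] = ChannelModel(**cm)
    field_names = {f.name for f in dataclasses.fields(CohortSpec)}
    for k, v in d.items():
        if k not in field_names:
            raise ValueError(f"unknown CohortSpec field {k!r}")
        kwargs[k] = tuple(v) if isinstance(v, list) and k.endswith(("_range", "_clip")) else v
    spec = CohortSpec(**kwargs)
    spec.validate()
    return spec


def load_cohort_spec(path) -> CohortSpec:
    with open(path) as fh:
        return cohort_spec_from_dict(yaml.safe_load(fh) or {})


def dump_cohort_spec(spec: CohortSpec, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cohort_spec_to_dict(spec), fh, sort_keys=False)


def gating_config_from_dict(d: dict | None) -> GatingConfig:
    return GatingConfig(**(d or {}))
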