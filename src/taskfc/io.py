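"""Flat-file serialization: everything is TSV or JSON, nothing binary."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import (
    Cohort,
    NetworkPartition,
    ParcelGeometry,
    RegionalTimeseries,
    ReceptorProfile,
)
from .task_design import TaskEvents

__all__ = [
    "write_timeseries",
    "read_timeseries",
    "write_events",
    "read_events",
    "write_matrix",
    "read_matrix",
    "write_geometry",
    "read_geometry",
    "write_partition",
    "read_partition",
    "write_receptors",
    "read_receptors",
    "write_cohort",
]


def write_timeseries(ts: RegionalTimeseries, path, region_ids) -> None:
    """One file per subject/task: header = region IDs, one row per volume."""
    pd.DataFrame(ts.data, columns=region_ids).to_csv(path, sep="\t", index=False)


def read_timeseries(path, tr: float, subject_id="", group="", task="") -> tuple[RegionalTimeseries, list]:
    df = pd.read_csv(path, sep="\t")
    ts = RegionalTimeseries(
        data=df.to_numpy(float), tr=tr, subject_id=subject_id, group=group, task=task
    )
    return ts, list(df.columns)


def write_events(events: TaskEvents, path) -> None:
    events.to_frame().to_csv(path, sep="\t", index=False)


def read_events(path) -> TaskEvents:
    return TaskEvents.from_frame(pd.read_csv(path, sep="\t"))


def write_matrix(values: np.ndarray, path, region_ids) -> None:
    pd.DataFrame(values, index=region_ids, columns=region_ids).to_csv(path, sep="\t")


def read_matrix(path) -> tuple[np.ndarray, list]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(float), list(df.columns)


def write_geometry(geom: ParcelGeometry, path, region_ids) -> None:
    pd.DataFrame(
        {
            "region": region_ids,
            "x": geom.coords[:, 0],
            "y": geom.coords[:, 1],
            "z": geom.coords[:, 2],
            "hemisphere": geom.hemisphere,
            "is_cortical": geom.is_cortical.astype(int),
        }
    ).to_csv(path, sep="\t", index=False)


def read_geometry(path) -> tuple[ParcelGeometry, list]:
    df = pd.read_csv(path, sep="\t")
    geom = ParcelGeometry(
        coords=df[["x", "y", "z"]].to_numpy(float),
        hemisphere=df["hemisphere"].to_numpy(object),
        is_cortical=df["is_cortical"].to_numpy(bool),
    )
    return geom, list(df["region"])


def write_partition(partition: NetworkPartition, path, region_ids) -> None:
    df = partition.labels_frame()
    df["region"] = region_ids
    df.to_csv(path, sep="\t", index=False)


def read_partition(path, networks) -> NetworkPartition:
    df = pd.read_csv(path, sep="\t")
    membership = np.zeros((len(df), len(networks)), dtype=bool)
    for r, labels in enumerate(df["networks"]):
        for name in str(labels).split(";"):
            membership[r, networks.index(name)] = True
    return NetworkPartition(membership, tuple(networks))


def write_receptors(receptors: ReceptorProfile, path, region_ids) -> None:
    df = pd.DataFrame({"region": region_ids})
    for name, vals in receptors.values.items():
        df[name] = vals
    df.to_csv(path, sep="\t", index=False)


def read_receptors(path) -> ReceptorProfile:
    df = pd.read_csv(path, sep="\t")
    values = {c: df[c].to_numpy(float) for c in df.columns if c != "region"}
    return ReceptorProfile(values=values)


def write_cohort(cohort: Cohort, out_dir) -> dict:
    """Write a full synthetic cohort as flat files; returns the file map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {}
    write_geometry(cohort.geometry, out / "geometry.tsv", cohort.region_ids)
    write_partition(cohort.partition, out / "networks.tsv", cohort.region_ids)
    write_receptors(cohort.receptors, out / "receptors.tsv", cohort.region_ids)
    files.update(
        geometry="geometry.tsv", networks="networks.tsv", receptors="receptors.tsv"
    )
    spec = dataclasses.asdict(cohort.spec)
    spec["coupling_effects"] = [dataclasses.asdict(e) for e in cohort.spec.coupling_effects]
    spec["condition_effects"] = [dataclasses.asdict(e) for e in cohort.spec.condition_effects]
    (out / "cohort_spec.json").write_text(json.dumps(spec, indent=2, default=str))
    ts_dir = out / "timeseries"
    ts_dir.mkdir(exist_ok=True)
    for task in cohort.spec.tasks:
        first = cohort.subjects[0]["data"][task]
        write_events(first.events, out / f"events_{task}.tsv")
        for s in cohort.subjects:
            name = f"{s['subject_id']}_task-{task}.tsv"
            write_timeseries(s["data"][task].timeseries, ts_dir / name, cohort.region_ids)
    groups = pd.DataFrame(
        {
            "subject_id": [s["subject_id"] for s in cohort.subjects],
            "group": [s["group"] for s in cohort.subjects],
        }
    )
    groups.to_csv(out / "participants.tsv", sep="\t", index=False)
    return files
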