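"""End-to-end orchestration: cohort -> task design -> miFC -> group stats ->
state dynamics -> receptor PLS.

A run is described by a :class:`RunConfig` (loadable from YAML/JSON).  All
randomness flows from the single config seed through named substreams
(cohort, per-stage permutations, spins), so enabling or disabling one
stage never shifts another's draws, and identical configs reproduce
identical outputs bit for bit.  Results are flat TSV/JSON under the output
directory, with a manifest of checksums and stage timings.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as tfio
from .cohort import (
    Cohort,
    CohortSpec,
    ConditionEffect,
    CouplingEffect,
    NETWORKS,
    generate_cohort,
)
from .group_stats import (
    EdgeComparison,
    cohens_d,
    degree_from_significance,
    direction_proportions,
    ec_group_difference,
    edge_permutation_test,
    eigenvector_centrality,
    permutation_test_columns,
)
from .mifc import contrast_mifc, mifc_matrix
from .receptor_pls import (
    build_spin_null,
    network_mean_scores,
    normalize_receptor,
    pls_fit,
    spearman_spin,
    spin_pvalue,
)
from .state_dynamics import dynamics_summary, state_sequence
from .task_design import condition_volumes

logger = logging.getLogger("taskfc")

__all__ = ["RunConfig", "RunManifest", "run_pipeline", "validate_inputs"]

#: condition of interest and neutral condition per task
DEFAULT_CONTRASTS = {
    "mid": ("reward_anticipation", "neutral_anticipation"),
    "cue": ("drug", "neutral"),
}


@dataclass
class RunConfig:
    seed: int
    out_dir: str
    mode: str = "synthetic"              # or "load"
    input_dir: str | None = None         # for load mode
    tasks: tuple[str, ...] = ("mid", "cue")
    contrasts: dict = field(default_factory=lambda: dict(DEFAULT_CONTRASTS))
    n_perm: int = 1000
    n_spins: int = 1000
    n_bins: int = 8
    floor_factor: int = 8    # min condition volumes = floor_factor * n_bins
    alpha: float = 0.05
    threshold_frac: float = 0.5
    pls_components: int = 2
    tr: float = 2.0
    cohort: dict = field(default_factory=dict)   # CohortSpec overrides
    dump_perms: bool = False

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
        if "tasks" in raw:
            raw["tasks"] = tuple(raw["tasks"])
        return cls(**raw)


@dataclass
class RunManifest:
    config_hash: str
    package_version: str
    checksums: dict
    stage_seconds: dict
    warnings: list

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _build_spec(config: RunConfig) -> CohortSpec:
    from .cohort import CueTiming, MidTiming, StateSequenceParams

    overrides = dict(config.cohort)
    for key, cls in (("coupling_effects", CouplingEffect),
                     ("condition_effects", ConditionEffect)):
        if key in overrides:
            overrides[key] = tuple(
                e if isinstance(e, cls) else cls(**{**e, "pair": tuple(e["pair"])})
                for e in overrides[key]
            )
    for key, cls in (("mid_timing", MidTiming), ("cue_timing", CueTiming),
                     ("state_params", StateSequenceParams)):
        if key in overrides and isinstance(overrides[key], dict):
            overrides[key] = cls(**overrides[key])
    seed = overrides.pop("seed", None)
    if seed is None:
        seed = int(np.random.SeedSequence(config.seed).spawn(1)[0].generate_state(1)[0]
                   % (2**31))
    return CohortSpec(seed=seed, tasks=tuple(config.tasks), tr=config.tr, **overrides)


def _edge_table(cmp: EdgeComparison, region_ids, matrices_a, matrices_b) -> pd.DataFrame:
    iu = np.triu_indices(cmp.n_regions, 1)
    ua = np.stack([m.values[iu] for m in matrices_a])
    ub = np.stack([m.values[iu] for m in matrices_b])
    d = np.array([
        cohens_d(ua[:, e], ub[:, e]) if (ua[:, e].std() or ub[:, e].std()) else 0.0
        for e in range(ua.shape[1])
    ])
    ids = np.asarray(region_ids)
    return pd.DataFrame(
        {
            "region_i": ids[iu[0]],
            "region_j": ids[iu[1]],
            "t": cmp.t_stat[iu],
            "p_fwe": cmp.p_fwe[iu],
            "significant": cmp.significant[iu].astype(int),
            "cohens_d": d,
        }
    )


def _network_pair_table(cmp: EdgeComparison, partition) -> pd.DataFrame:
    """Significant-edge counts per network pair (circle-plot summary)."""
    rows = []
    nets = partition.networks
    member = [set(partition.members(n)) for n in nets]
    iu = np.triu_indices(cmp.n_regions, 1)
    sig_t = cmp.t_stat[iu][cmp.significant[iu]]
    sig_edges = [(i, j) for (i, j), s in
                 zip(zip(*iu), cmp.significant[iu]) if s]
    for a in range(len(nets)):
        for b in range(a, len(nets)):
            n_pos = n_neg = 0
            for (i, j), t in zip(sig_edges, sig_t):
                inc = ((i in member[a] and j in member[b])
                       or (i in member[b] and j in member[a]))
                if inc:
                    if t > 0:
                        n_pos += 1
                    else:
                        n_neg += 1
            if n_pos or n_neg:
                rows.append({"network_a": nets[a], "network_b": nets[b],
                             "stronger_a": n_pos, "stronger_b": n_neg})
    return pd.DataFrame(rows, columns=["network_a", "network_b",
                                       "stronger_a", "stronger_b"])


def validate_inputs(input_dir, tasks=("mid", "cue"), tr: float = 2.0,
                    contrasts: dict | None = None) -> dict:
    """Schema/alignment checks for a cohort directory on disk.

    Returns {"fatal": [...], "warnings": [...]}; the run aborts on fatal.
    """
    contrasts = contrasts or DEFAULT_CONTRASTS
    root = Path(input_dir)
    fatal, warnings = [], []
    try:
        _, ids_geo = tfio.read_geometry(root / "geometry.tsv")
    except Exception as exc:  # noqa: BLE001
        return {"fatal": [f"geometry.tsv: {exc}"], "warnings": []}
    ref = list(ids_geo)
    for name in ("networks.tsv", "receptors.tsv"):
        try:
            df = pd.read_csv(root / name, sep="\t")
            ids = list(df["region"])
            if ids != ref:
                diff = sorted(set(ids) ^ set(ref))
                fatal.append(f"{name}: region set mismatch: {diff}")
        except Exception as exc:  # noqa: BLE001
            fatal.append(f"{name}: {exc}")
    try:
        participants = pd.read_csv(root / "participants.tsv", sep="\t")
    except Exception as exc:  # noqa: BLE001
        fatal.append(f"participants.tsv: {exc}")
        return {"fatal": fatal, "warnings": warnings}
    for task in tasks:
        try:
            events = tfio.read_events(root / f"events_{task}.tsv")
            for label in contrasts.get(task, ()):
                if label not in set(events.condition.astype(str)):
                    fatal.append(
                        f"events_{task}.tsv: missing condition label {label!r}"
                    )
        except FileNotFoundError:
            fatal.append(f"events_{task}.tsv missing")
            continue
        for sid in participants["subject_id"]:
            f = root / "timeseries" / f"{sid}_task-{task}.tsv"
            if not f.exists():
                fatal.append(f"{f.name} missing")
                continue
            header = pd.read_csv(f, sep="\t", nrows=0)
            if list(header.columns) != ref:
                diff = sorted(set(header.columns) ^ set(ref))
                fatal.append(f"{f.name}: region mismatch: {diff}")
    return {"fatal": fatal, "warnings": warnings}


def _load_cohort(config: RunConfig) -> Cohort:
    root = Path(config.input_dir)
    report = validate_inputs(root, config.tasks, config.tr, config.contrasts)
    if report["fatal"]:
        raise ValueError("input validation failed: " + "; ".join(report["fatal"]))
    geometry, region_ids = tfio.read_geometry(root / "geometry.tsv")
    partition = tfio.read_partition(root / "networks.tsv", list(NETWORKS))
    receptors = tfio.read_receptors(root / "receptors.tsv")
    participants = pd.read_csv(root / "participants.tsv", sep="\t")
    subjects = []
    spec_file = root / "cohort_spec.json"
    for _, row in participants.iterrows():
        data = {}
        for task in config.tasks:
            ts, _ = tfio.read_timeseries(
                root / "timeseries" / f"{row.subject_id}_task-{task}.tsv",
                tr=config.tr, subject_id=row.subject_id,
                group=row.group, task=task,
            )
            events = tfio.read_events(root / f"events_{task}.tsv")
            from .cohort import SubjectTaskData

            data[task] = SubjectTaskData(
                timeseries=ts, events=events,
                true_states=np.zeros(ts.n_volumes, dtype=int),
            )
        subjects.append({"subject_id": row.subject_id, "group": row.group,
                         "data": data})
    n_a = sum(1 for s in subjects if s["group"] == "A")
    spec = CohortSpec(
        seed=config.seed, n_group_a=n_a, n_group_b=len(subjects) - n_a,
        n_regions=len(region_ids), tr=config.tr, tasks=tuple(config.tasks),
        n_volumes={t: subjects[0]["data"][t].timeseries.n_volumes
                   for t in config.tasks},
    )
    return Cohort(spec=spec, partition=partition, geometry=geometry,
                  receptors=receptors, subjects=subjects, region_ids=region_ids)


def run_pipeline(config: RunConfig) -> RunManifest:
    """Run every stage and write all result files; returns the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    warnings: list[str] = []
    stage_seconds: dict[str, float] = {}
    root_ss = np.random.SeedSequence(config.seed)
    ss_cohort, ss_edges, ss_dyn, ss_spin = root_ss.spawn(4)

    def stage(name):
        logger.info("stage %s", name)
        return time.perf_counter()

    try:
        # ----- cohort -----
        t0 = stage("cohort")
        if config.mode == "synthetic":
            cohort = generate_cohort(_build_spec(config))
            tfio.write_cohort(cohort, out / "inputs")
        elif config.mode == "load":
            cohort = _load_cohort(config)
        else:
            raise ValueError(f"unknown mode {config.mode!r}")
        stage_seconds["cohort"] = time.perf_counter() - t0

        region_ids = cohort.region_ids
        groups = [s["group"] for s in cohort.subjects]
        idx_a = [i for i, g in enumerate(groups) if g == "A"]
        idx_b = [i for i, g in enumerate(groups) if g == "B"]
        edge_seeds = {task: child for task, child
                      in zip(config.tasks, ss_edges.spawn(len(config.tasks)))}
        dyn_seeds = {task: int(child.generate_state(1)[0] % (2**31))
                     for task, child
                     in zip(config.tasks, ss_dyn.spawn(len(config.tasks)))}

        ec_diff = {}
        degree = {}
        for task in config.tasks:
            task_dir = out / task
            task_dir.mkdir(exist_ok=True)
            # ----- miFC matrices -----
            t0 = stage(f"{task}:mifc")
            tss = [s["data"][task].timeseries for s in cohort.subjects]
            events = cohort.subjects[0]["data"][task].events
            coi, neutral = config.contrasts[task]
            vols_coi = condition_volumes(events, coi, config.tr,
                                         tss[0].n_volumes, config.threshold_frac)
            vols_neu = condition_volumes(events, neutral, config.tr,
                                         tss[0].n_volumes, config.threshold_frac)
            ff = config.floor_factor
            whole = [mifc_matrix(ts, None, config.n_bins) for ts in tss]
            cond = [mifc_matrix(ts, vols_coi, config.n_bins, ff) for ts in tss]
            contrast = [contrast_mifc(ts, vols_coi, vols_neu, config.n_bins,
                                      coi, neutral, ff) for ts in tss]
            np.savetxt(task_dir / "condition_volumes.tsv",
                       np.stack([vols_coi]).T if len(vols_coi) else np.empty((0, 1)),
                       fmt="%d", header="volume", comments="")
            stage_seconds[f"{task}:mifc"] = time.perf_counter() - t0

            # ----- edge tests -----
            t0 = stage(f"{task}:edges")
            seeds = [int(c.generate_state(1)[0] % (2**31))
                     for c in edge_seeds[task].spawn(3)]
            for name, mats, seed in (
                ("whole", whole, seeds[0]),
                ("condition", cond, seeds[1]),
                ("contrast", contrast, seeds[2]),
            ):
                cmp = edge_permutation_test(
                    [mats[i] for i in idx_a], [mats[i] for i in idx_b],
                    n_perm=config.n_perm, alpha=config.alpha, seed=seed,
                )
                table = _edge_table(cmp, region_ids,
                                    [mats[i] for i in idx_a],
                                    [mats[i] for i in idx_b])
                table.to_csv(task_dir / f"edges_{name}.tsv", sep="\t", index=False)
                pct_a, pct_b = direction_proportions(cmp)
                summary = {
                    "n_significant": cmp.n_significant_edges,
                    "pct_stronger_a": pct_a,
                    "pct_stronger_b": pct_b,
                }
                (task_dir / f"edges_{name}_summary.json").write_text(
                    json.dumps(summary, indent=2)
                )
                _network_pair_table(cmp, cohort.partition).to_csv(
                    task_dir / f"network_pairs_{name}.tsv", sep="\t", index=False
                )
                if name == "whole":
                    degree[task] = degree_from_significance(cmp)
            stage_seconds[f"{task}:edges"] = time.perf_counter() - t0

            # ----- region summaries -----
            t0 = stage(f"{task}:regions")
            ec = np.stack([eigenvector_centrality(m) for m in whole])
            ec_diff[task] = ec_group_difference(ec[idx_a], ec[idx_b])
            pd.DataFrame(
                {
                    "region": region_ids,
                    "degree": degree[task],
                    "ec_mean_a": ec[idx_a].mean(axis=0),
                    "ec_mean_b": ec[idx_b].mean(axis=0),
                    "ec_difference_a_minus_b": ec_diff[task],
                }
            ).to_csv(task_dir / "region_summary.tsv", sep="\t", index=False)
            stage_seconds[f"{task}:regions"] = time.perf_counter() - t0

            # ----- state dynamics -----
            t0 = stage(f"{task}:dynamics")
            rows = []
            for s in cohort.subjects:
                states = state_sequence(s["data"][task].timeseries, cohort.partition)
                if states.n_ties:
                    warnings.append(
                        f"{task}/{s['subject_id']}: {states.n_ties} coherence ties"
                    )
                summ = dynamics_summary(states)
                row = {"subject_id": s["subject_id"], "group": s["group"],
                       "lzc": summ.lzc, "bdmc": summ.bdmc}
                for k, net in enumerate(summ.templates):
                    row[f"lifetime_{net}"] = summ.lifetime[k]
                    row[f"probability_{net}"] = summ.probability[k]
                for o in range(5):
                    row[f"te_order{o}"] = summ.transition_entropy[o]
                rows.append(row)
            dyn = pd.DataFrame(rows)
            dyn.to_csv(task_dir / "dynamics_metrics.tsv", sep="\t", index=False)
            metric_cols = [c for c in dyn.columns if c not in ("subject_id", "group")]
            da = dyn.loc[dyn.group == "A", metric_cols].to_numpy(float)
            db = dyn.loc[dyn.group == "B", metric_cols].to_numpy(float)
            keep = [c for c in range(da.shape[1])
                    if da[:, c].std() > 0 or db[:, c].std() > 0]
            t_obs, p_fwe = permutation_test_columns(
                da[:, keep], db[:, keep], n_perm=config.n_perm,
                alpha=config.alpha, seed=dyn_seeds[task],
            )
            d_vals = [cohens_d(da[:, c], db[:, c]) for c in keep]
            pd.DataFrame(
                {"metric": [metric_cols[c] for c in keep], "t": t_obs,
                 "p_fwe": p_fwe, "cohens_d": d_vals,
                 "significant": (p_fwe < config.alpha).astype(int)}
            ).to_csv(task_dir / "dynamics_tests.tsv", sep="\t", index=False)
            stage_seconds[f"{task}:dynamics"] = time.perf_counter() - t0

        # ----- receptor PLS -----
        t0 = stage("pls")
        pls_dir = out / "pls"
        pls_dir.mkdir(exist_ok=True)
        X = np.column_stack(
            [normalize_receptor(cohort.receptors.values[r])
             for r in sorted(cohort.receptors.values)]
        )
        predictor_names = sorted(cohort.receptors.values)
        resp = {}
        for task in config.tasks:
            resp[f"ec_diff_{task}"] = ec_diff[task]
            resp[f"degree_{task}"] = degree[task].astype(float)
        Y_raw = np.column_stack(list(resp.values()))
        sd = Y_raw.std(axis=0, ddof=1)
        const = sd == 0
        if const.any():
            warnings.append(
                f"constant response column(s) dropped: "
                f"{[n for n, c in zip(resp, const) if c]}"
            )
        keep_cols = ~const
        Y = (Y_raw[:, keep_cols] - Y_raw[:, keep_cols].mean(axis=0)) / sd[keep_cols]
        response_names = [n for n, c in zip(resp, const) if not c]
        res = pls_fit(X, Y, n_components=config.pls_components)

        spin_seed = int(ss_spin.generate_state(1)[0] % (2**31))
        spin = build_spin_null(cohort.geometry, n_perm=config.n_spins,
                               seed=spin_seed)
        null_cov = np.empty((config.n_spins, config.pls_components))
        null_yv = np.empty((config.n_spins, config.pls_components))
        for i, perm in enumerate(spin.maps):
            r = pls_fit(X, Y[perm], n_components=config.pls_components)
            null_cov[i] = r.singular_values[: config.pls_components] ** 2
            null_yv[i] = r.y_variance_share
        comp_rows = []
        for a in range(config.pls_components):
            comp_rows.append(
                {
                    "component": a + 1,
                    "cov_share_pct": 100 * res.cov_share[a],
                    "y_variance_pct": 100 * res.y_variance_share[a],
                    "spin_p_cov": spin_pvalue(
                        res.singular_values[a] ** 2, null_cov[:, a]
                    ),
                    "spin_p_yvar": spin_pvalue(
                        res.y_variance_share[a], null_yv[:, a]
                    ),
                }
            )
        pd.DataFrame(comp_rows).to_csv(pls_dir / "components.tsv", sep="\t",
                                       index=False)
        pd.DataFrame({"predictor": predictor_names, "vip": res.vip}).to_csv(
            pls_dir / "vip.tsv", sep="\t", index=False
        )
        corr_rows = []
        for j, name in enumerate(response_names):
            rho, p, p_spin = spearman_spin(res.x_scores[:, 0], Y[:, j], spin)
            corr_rows.append({"response": name, "rho": rho, "p": p,
                              "p_spin": p_spin})
        pd.DataFrame(corr_rows).to_csv(pls_dir / "spearman.tsv", sep="\t",
                                       index=False)
        net_scores = network_mean_scores(res.x_scores[:, 0], cohort.partition)
        pd.DataFrame(
            {"network": list(net_scores), "mean_predictor_score":
             list(net_scores.values())}
        ).to_csv(pls_dir / "network_scores.tsv", sep="\t", index=False)
        meta = {
            "orientation": "responses are group A (HC-like) minus group B",
            "subcortical_null": "within-class permutation (cannot be rotated)",
            "spin_seed": spin_seed,
        }
        if config.dump_perms:
            np.savetxt(pls_dir / "spin_maps.tsv", spin.maps, fmt="%d",
                       delimiter="\t")
        (pls_dir / "metadata.json").write_text(json.dumps(meta, indent=2))
        stage_seconds["pls"] = time.perf_counter() - t0
    finally:
        logger.removeHandler(handler)
        handler.close()

    checksums = {
        str(p.relative_to(out)): _sha256(p)
        for p in sorted(out.rglob("*"))
        if p.is_file() and p.name != "run.log" and p.name != "manifest.json"
    }
    manifest = RunManifest(
        config_hash=_config_hash(config),
        package_version=_version(),
        checksums=checksums,
        stage_seconds=stage_seconds,
        warnings=warnings,
    )
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest


def _version() -> str:
    try:
        from importlib.metadata import version

        return version("taskfc")
    except Exception:  # noqa: BLE001
        return "unknown"
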