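"""Synthetic two-group, two-task fMRI cohort generator.

Emulates a case-control task-fMRI study: two groups of subjects scanned
during an event-related monetary-incentive-delay ("mid") task and a
block-design cue-reactivity ("cue") task, with BOLD timeseries parcellated
into cortical parcels (8 canonical networks) plus subcortical regions, and
a ninth, partially overlapping ventromedial reward network (VMN).

The generative model, per subject and task:

1. a hidden state sequence over the 9 networks (semi-Markov dwell process
   at 1 s resolution) marks which network is episodically dominant;
2. each network has a latent band-limited (0.02-0.1 Hz) signal at 1 s
   resolution whose amplitude is boosted while its network is dominant;
3. each region mixes the latents of its own network(s) plus weak cross-
   network couplings; coupling gains can be modified per group and, inside
   condition windows, per condition (how group/condition effects are
   planted);
4. the neural signal is convolved with the canonical HRF, sampled at the
   TR, and white measurement noise is added.

The hidden state sequence is returned as ground truth so that state
assignment can be scored, and planted coupling effects make group and
condition contrasts recoverable.  Everything is deterministic given the
spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

from ._filters import butter_bandpass
from .task_design import TaskEvents, build_boxcar, canonical_hrf

__all__ = [
    "NETWORKS",
    "RegionalTimeseries",
    "ParcelGeometry",
    "ReceptorProfile",
    "NetworkPartition",
    "CouplingEffect",
    "ConditionEffect",
    "StateSequenceParams",
    "MidTiming",
    "CueTiming",
    "CohortSpec",
    "Cohort",
    "default_partition",
    "default_geometry",
    "generate_events",
    "generate_receptor_map",
    "generate_cohort",
]

#: fixed template order; the ninth (VMN) overlaps cortical membership
NETWORKS = (
    "visual",
    "somatomotor",
    "dorsal_attention",
    "salience_ventral_attention",
    "limbic",
    "control",
    "default_mode",
    "temporal_parietal",
    "vmn",
)


@dataclass(frozen=True)
class RegionalTimeseries:
    """Volumes x regions BOLD matrix with acquisition metadata."""

    data: np.ndarray
    tr: float
    subject_id: str = ""
    group: str = ""
    task: str = ""

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2:
            raise ValueError("data must be volumes x regions")
        if data.shape[0] < 2:
            raise ValueError("need at least 2 volumes")
        if not np.isfinite(data).all():
            raise ValueError("data contains non-finite values")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        object.__setattr__(self, "data", data)

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class ParcelGeometry:
    """Region centroids: unit-sphere points (cortical) or interior points."""

    coords: np.ndarray          # n_regions x 3
    hemisphere: np.ndarray      # 'L' / 'R'
    is_cortical: np.ndarray     # bool

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        hemi = np.asarray(self.hemisphere)
        cort = np.asarray(self.is_cortical, dtype=bool)
        if coords.shape != (len(hemi), 3) or len(hemi) != len(cort):
            raise ValueError("inconsistent geometry shapes")
        norms = np.linalg.norm(coords[cort], axis=1)
        if cort.any() and not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("cortical centroids must have unit norm")
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "hemisphere", hemi)
        object.__setattr__(self, "is_cortical", cort)

    @property
    def n_regions(self) -> int:
        return self.coords.shape[0]


@dataclass(frozen=True)
class ReceptorProfile:
    """Per-region availability for each receptor, arbitrary binding units."""

    values: dict[str, np.ndarray]
    provenance: str = "synthetic"

    def __post_init__(self) -> None:
        for name, v in self.values.items():
            v = np.asarray(v, dtype=float)
            if not np.isfinite(v).all():
                raise ValueError(f"receptor {name}: non-finite values")
            self.values[name] = v


class NetworkPartition:
    """Region -> network membership; overlapping labels are allowed."""

    def __init__(self, membership: np.ndarray, networks: tuple[str, ...] = NETWORKS):
        membership = np.asarray(membership, dtype=bool)
        if membership.ndim != 2 or membership.shape[1] != len(networks):
            raise ValueError("membership must be n_regions x n_networks")
        if not membership.any(axis=1).all():
            raise ValueError("every region needs at least one network label")
        if not membership.any(axis=0).all():
            empty = [networks[i] for i in np.flatnonzero(~membership.any(axis=0))]
            raise ValueError(f"empty network(s): {empty}")
        self.membership = membership
        self.networks = tuple(networks)

    @property
    def n_regions(self) -> int:
        return self.membership.shape[0]

    def members(self, network: str) -> np.ndarray:
        return np.flatnonzero(self.membership[:, self.networks.index(network)])

    def labels_frame(self):
        import pandas as pd

        rows = []
        for r in range(self.n_regions):
            nets = [self.networks[k] for k in np.flatnonzero(self.membership[r])]
            rows.append(";".join(nets))
        return pd.DataFrame({"region": np.arange(self.n_regions), "networks": rows})


@dataclass(frozen=True)
class CouplingEffect:
    """Multiplicative gain on the cross-coupling of a network pair, per group."""

    pair: tuple[str, str]
    group: str
    gain: float


@dataclass(frozen=True)
class ConditionEffect:
    """As CouplingEffect, but active only inside a condition's event windows."""

    pair: tuple[str, str]
    condition: str
    group: str
    gain: float


@dataclass(frozen=True)
class StateSequenceParams:
    """Semi-Markov dwell process for the hidden dominant network."""

    mean_dwell: float = 30.0   # seconds
    min_dwell: float = 10.0    # seconds
    probs: tuple[float, ...] | None = None  # stationary network draw, default uniform


@dataclass(frozen=True)
class MidTiming:
    """Event-related design: interleaved anticipation/target/outcome trials."""

    n_trials: int = 84
    anticipation: float = 4.0
    target: float = 1.0
    outcome: float = 2.0
    iti: float = 3.0
    lead_in: float = 10.0

    @property
    def trial_length(self) -> float:
        return self.anticipation + self.target + self.outcome + self.iti

    @property
    def total_seconds(self) -> float:
        return self.lead_in + self.n_trials * self.trial_length


@dataclass(frozen=True)
class CueTiming:
    """Block design: alternating drug/neutral blocks with inter-block rest."""

    n_blocks_per_condition: int = 7
    block: float = 20.0
    rest: float = 10.0
    lead_in: float = 10.0

    @property
    def total_seconds(self) -> float:
        n = 2 * self.n_blocks_per_condition
        return self.lead_in + n * self.block + n * self.rest


@dataclass(frozen=True)
class CohortSpec:
    """Full description of a synthetic cohort; same spec + seed => identical data."""

    seed: int
    n_group_a: int = 22
    n_group_b: int = 25
    n_regions: int = 214
    tr: float = 2.0
    tasks: tuple[str, ...] = ("mid", "cue")
    n_volumes: dict = field(default_factory=lambda: {"mid": 430, "cue": 220})
    coupling_effects: tuple[CouplingEffect, ...] = ()
    condition_effects: tuple[ConditionEffect, ...] = ()
    state_params: StateSequenceParams = field(default_factory=StateSequenceParams)
    mid_timing: MidTiming = field(default_factory=MidTiming)
    cue_timing: CueTiming = field(default_factory=CueTiming)
    cross_coupling: float = 0.15
    state_boost: float = 6.0
    region_noise_sd: float = 2.0
    noise_sd: float = 0.5

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if min(self.n_group_a, self.n_group_b) <= 0 or self.n_regions <= 0:
            raise ValueError("group sizes and n_regions must be positive")
        for eff in tuple(self.coupling_effects) + tuple(self.condition_effects):
            if eff.gain <= 0:
                raise ValueError("all gains must be > 0")
            for net in eff.pair:
                if net not in NETWORKS:
                    raise ValueError(f"unknown network {net!r}")
        for task in self.tasks:
            if task not in ("mid", "cue"):
                raise ValueError(f"unknown task {task!r}")
            span = (self.mid_timing if task == "mid" else self.cue_timing).total_seconds
            if self.n_volumes[task] * self.tr < span:
                raise ValueError(
                    f"{task}: {self.n_volumes[task]} volumes x {self.tr}s TR is "
                    f"shorter than the {span:.0f}s event span"
                )

    @property
    def n_subjects(self) -> int:
        return self.n_group_a + self.n_group_b


# ---------------------------------------------------------------------------
# parcellation, geometry, receptors


def default_partition(n_regions: int = 214) -> NetworkPartition:
    """Mirror of the study parcellation at any size.

    Cortical parcels are split evenly over the 8 canonical networks in
    left/right mirrored pairs; the remaining regions are subcortical.  The
    VMN comprises all subcortical regions plus a few medial cortical parcels
    (taken from the limbic and default-mode networks), overlapping their
    cortical membership.
    """
    if n_regions < 20:
        raise ValueError("need at least 20 regions for a 9-network partition")
    n_sub = max(4, int(round(n_regions * 14 / 214)))
    if (n_regions - n_sub) % 2:
        n_sub += 1
    n_cort = n_regions - n_sub
    n_pairs = n_cort // 2
    membership = np.zeros((n_regions, len(NETWORKS)), dtype=bool)
    # pairs cycle through the 8 cortical networks
    for p in range(n_pairs):
        net = p % 8
        membership[2 * p, net] = True       # left
        membership[2 * p + 1, net] = True   # right
    vmn = NETWORKS.index("vmn")
    membership[n_cort:, vmn] = True         # all subcortical
    # medial cortical VMN members: first pair(s) of limbic and default_mode
    n_overlap_pairs = max(1, int(round(n_regions * 6 / 214)) // 2)
    for net_name in ("limbic", "default_mode"):
        net = NETWORKS.index(net_name)
        pair_ids = [p for p in range(n_pairs) if p % 8 == net]
        for p in pair_ids[:n_overlap_pairs]:
            membership[2 * p, vmn] = True
            membership[2 * p + 1, vmn] = True
    return NetworkPartition(membership)


def default_geometry(n_regions: int = 214) -> ParcelGeometry:
    """Deterministic mirrored centroids: cortical on the unit sphere,
    subcortical in the interior.

    Each hemisphere's parcels tile a full unit sphere (the spherical-
    registration convention), with the left hemisphere the mirror image of
    the right, so spherical rotations map a hemisphere onto itself.
    """
    part = default_partition(n_regions)
    n_sub = int((~part.membership[:, :8].any(axis=1)).sum())
    n_cort = n_regions - n_sub
    n_pairs = n_cort // 2

    def spiral(n: int) -> np.ndarray:
        # golden-angle spiral covering the whole sphere
        k = np.arange(n) + 0.5
        phi = np.arccos(1 - 2 * k / n)
        theta = np.pi * (1 + 5**0.5) * k
        pts = np.stack(
            [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)],
            axis=1,
        )
        return pts / np.linalg.norm(pts, axis=1, keepdims=True)

    right = spiral(n_pairs)
    left = right * np.array([-1.0, 1.0, 1.0])
    coords = np.empty((n_regions, 3))
    coords[0:n_cort:2] = left
    coords[1:n_cort:2] = right
    hemi = np.empty(n_regions, dtype=object)
    hemi[0:n_cort:2] = "L"
    hemi[1:n_cort:2] = "R"
    # subcortical: mirrored interior points near the centre
    n_sub_pairs = n_sub // 2
    sub_right = spiral(max(n_sub_pairs, 1))[:n_sub_pairs] * 0.3
    coords[n_cort::2] = sub_right * np.array([-1.0, 1.0, 1.0])
    coords[n_cort + 1::2] = sub_right
    hemi[n_cort::2] = "L"
    hemi[n_cort + 1::2] = "R"
    is_cort = np.zeros(n_regions, dtype=bool)
    is_cort[:n_cort] = True
    return ParcelGeometry(coords=coords, hemisphere=hemi, is_cortical=is_cort)


def _receptor_covariance(
    geometry: ParcelGeometry,
    autocorr_length: float,
    homotopy: float,
    nugget: float,
) -> np.ndarray:
    """Spatial covariance of a receptor-style map on the parcellation.

    Cortical parcels live on per-hemisphere spheres; distances are taken in
    mirror-aligned (right-hemisphere frame) coordinates, with full kernel
    weight within a hemisphere and a uniform ``homotopy`` weight across
    hemispheres — the covariance is then exactly invariant under mirrored
    rotations of the two hemispheres.  The subcortical block is an
    independent kernel on its own centroids.  A ``nugget`` fraction of
    white, parcel-level variance models measurement noise.
    """
    coords = geometry.coords.copy()
    cort = geometry.is_cortical
    left = cort & (geometry.hemisphere == "L")
    coords[left, 0] = -coords[left, 0]  # mirror-align to the right frame
    d = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
    k = np.exp(-((d / autocorr_length) ** 2))
    n = geometry.n_regions
    cov = np.zeros((n, n))
    same_hemi = geometry.hemisphere[:, None] == geometry.hemisphere[None, :]
    cc = np.outer(cort, cort)
    cov[cc] = np.where(same_hemi, k, homotopy * k)[cc]
    # subcortical regions are distinct nuclei, not samples of a smooth
    # sheet: independent values, uncoupled from the cortical field
    cov[~cort, ~cort] = 1.0
    cov = (1.0 - nugget) * cov + nugget * np.eye(n)
    cov[np.diag_indices(n)] += 1e-8
    return cov


def generate_receptor_map(
    geometry: ParcelGeometry,
    autocorr_length: float,
    vmn_enrichment: float = 1.0,
    seed: int | None = None,
    vmn_mask: np.ndarray | None = None,
    homotopy: float = 0.5,
    nugget: float = 0.2,
) -> np.ndarray:
    """Spatially autocorrelated receptor-availability map.

    Draws from a Gaussian process with squared-exponential kernel (length
    scale ``autocorr_length``, chord units) in per-hemisphere mirror-aligned
    coordinates, uniform homotopic cross-hemisphere coupling, an independent
    subcortical block, and a white nugget component (see
    :func:`_receptor_covariance`).  The draw is shifted by a fixed +5 SD
    (clipped at 0) to be nonnegative, then VMN regions are multiplied by
    ``vmn_enrichment``.
    """
    if autocorr_length <= 0:
        raise ValueError("autocorr_length must be > 0")
    if not (0.0 <= homotopy <= 1.0 and 0.0 <= nugget < 1.0):
        raise ValueError("homotopy must be in [0,1], nugget in [0,1)")
    rng = np.random.default_rng(seed)
    cov = _receptor_covariance(geometry, autocorr_length, homotopy, nugget)
    chol = np.linalg.cholesky(cov)
    vals = chol @ rng.standard_normal(geometry.n_regions)
    # fixed +5 SD shift keeps values nonnegative without coupling regions
    # through a draw-dependent offset
    vals = np.maximum(vals + 5.0, 0.0)
    if vmn_mask is not None and vmn_enrichment != 1.0:
        vals = vals.copy()
        vals[vmn_mask] *= vmn_enrichment
    return vals


# ---------------------------------------------------------------------------
# events


def generate_events(
    task: str,
    timing: MidTiming | CueTiming | None = None,
    seed: int | None = None,
) -> TaskEvents:
    """Event table for one run of the mid or cue task.

    mid: interleaved trials of {reward, neutral, loss} anticipation (drawn
    evenly, order shuffled), each followed by a target and an outcome event.
    cue: alternating drug/neutral blocks separated by rest.
    """
    if task == "mid":
        t = timing if timing is not None else MidTiming()
        rng = np.random.default_rng(seed)
        kinds = ["reward_anticipation", "neutral_anticipation", "loss_anticipation"]
        reps = int(np.ceil(t.n_trials / 3))
        labels = np.array((kinds * reps)[: t.n_trials], dtype=object)
        rng.shuffle(labels)
        onsets, durs, conds = [], [], []
        clock = t.lead_in
        for lab in labels:
            onsets += [clock, clock + t.anticipation, clock + t.anticipation + t.target]
            durs += [t.anticipation, t.target, t.outcome]
            conds += [lab, "target", "outcome"]
            clock += t.trial_length
        return TaskEvents(np.array(onsets), np.array(durs), np.array(conds, dtype=object))
    if task == "cue":
        t = timing if timing is not None else CueTiming()
        onsets, durs, conds = [], [], []
        clock = t.lead_in
        for b in range(2 * t.n_blocks_per_condition):
            onsets.append(clock)
            durs.append(t.block)
            conds.append("drug" if b % 2 == 0 else "neutral")
            clock += t.block + t.rest
        return TaskEvents(np.array(onsets), np.array(durs), np.array(conds, dtype=object))
    raise ValueError(f"unknown task {task!r}")


# ---------------------------------------------------------------------------
# cohort


@dataclass
class SubjectTaskData:
    timeseries: RegionalTimeseries
    events: TaskEvents
    true_states: np.ndarray  # per-volume hidden network index (neural time)


@dataclass
class Cohort:
    spec: CohortSpec
    partition: NetworkPartition
    geometry: ParcelGeometry
    receptors: ReceptorProfile
    subjects: list          # list of dicts: subject_id, group, data: {task: SubjectTaskData}
    region_ids: list

    def timeseries(self, task: str, group: str | None = None) -> list[RegionalTimeseries]:
        out = []
        for s in self.subjects:
            if group is None or s["group"] == group:
                out.append(s["data"][task].timeseries)
        return out


def _draw_states(rng: np.random.Generator, total_seconds: int,
                 params: StateSequenceParams, n_states: int) -> np.ndarray:
    probs = params.probs
    if probs is None:
        probs = np.full(n_states, 1.0 / n_states)
    probs = np.asarray(probs, dtype=float)
    probs = probs / probs.sum()
    states = np.empty(total_seconds, dtype=np.int64)
    t = 0
    current = -1
    while t < total_seconds:
        # redraw until a genuine transition (no self-repeat)
        k = int(rng.choice(n_states, p=probs))
        if n_states > 1 and k == current:
            continue
        dwell = max(1, int(round(
            params.min_dwell
            + rng.exponential(max(params.mean_dwell - params.min_dwell, 1e-9)))))
        states[t: t + dwell] = k
        t += dwell
        current = k
    return states


def _static_loadings(membership: np.ndarray, cross: float,
                     effects: Iterable[CouplingEffect], group: str) -> np.ndarray:
    """Region x network loading matrix for one group (time-invariant part)."""
    n_regions, n_nets = membership.shape
    gains = np.ones((n_nets, n_nets))
    for eff in effects:
        if eff.group != group:
            continue
        i, j = NETWORKS.index(eff.pair[0]), NETWORKS.index(eff.pair[1])
        gains[i, j] = gains[j, i] = eff.gain
    load = np.zeros((n_regions, n_nets))
    for q in range(n_nets):
        member = membership[:, q]
        load[member, q] += 1.0
        # cross-coupling from each of a region's own networks onto network q
        for p in range(n_nets):
            if p == q:
                continue
            rows = membership[:, p] & ~member
            load[rows, q] = np.maximum(load[rows, q], cross * gains[p, q])
    return load


def _delta_loadings(membership: np.ndarray, cross: float,
                    eff: ConditionEffect) -> np.ndarray:
    """Additional loading active inside one condition's windows."""
    n_regions, n_nets = membership.shape
    i, j = NETWORKS.index(eff.pair[0]), NETWORKS.index(eff.pair[1])
    delta = np.zeros((n_regions, n_nets))
    extra = cross * (eff.gain - 1.0)
    rows_i = membership[:, i] & ~membership[:, j]
    rows_j = membership[:, j] & ~membership[:, i]
    delta[rows_i, j] += extra
    delta[rows_j, i] += extra
    return delta


def _band_limited(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    """Unit-SD band-limited (0.02-0.1 Hz) noise at 1 s resolution, rows = series."""
    white = rng.standard_normal(shape)
    filt = butter_bandpass(white, fs=1.0, axis=1)
    sd = filt.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return filt / sd


def _simulate_subject_task(
    rng: np.random.Generator,
    spec: CohortSpec,
    membership: np.ndarray,
    load_static: np.ndarray,
    events: TaskEvents,
    task: str,
    group: str,
) -> SubjectTaskData:
    n_vol = spec.n_volumes[task]
    total_seconds = int(np.ceil(n_vol * spec.tr))
    n_nets = membership.shape[1]

    states = _draw_states(rng, total_seconds, spec.state_params, n_nets)
    latents = _band_limited(rng, (n_nets, total_seconds))
    amp = 1.0 + (spec.state_boost - 1.0) * (states[None, :] == np.arange(n_nets)[:, None])
    modulated = latents * amp

    neural = load_static @ modulated  # regions x seconds
    for eff in spec.condition_effects:
        if eff.group != group:
            continue
        if eff.condition not in set(events.condition.astype(str)):
            continue
        delta = _delta_loadings(membership, spec.cross_coupling, eff)
        if not delta.any():
            continue
        window = build_boxcar(events, eff.condition, total_seconds)
        neural += (delta @ modulated) * window[None, :]

    neural += spec.region_noise_sd * _band_limited(
        rng, (membership.shape[0], total_seconds)
    )

    # haemodynamics: canonical HRF at 1 s, then sample at volume starts
    from scipy.signal import fftconvolve

    kernel = canonical_hrf(1.0)
    bold = fftconvolve(neural, kernel[None, :], axes=1)[:, :total_seconds]
    times = np.arange(n_vol) * spec.tr
    i0 = np.minimum(times.astype(int), total_seconds - 1)
    i1 = np.minimum(i0 + 1, total_seconds - 1)
    frac = times - i0
    sampled = bold[:, i0] * (1 - frac) + bold[:, i1] * frac
    # rescale to unit typical SD so noise_sd is a fraction of signal scale
    # (the HRF has gain ~5 in the infra-slow band)
    scale = sampled.std(axis=1).mean()
    if scale > 0:
        sampled = sampled / scale
    sampled = sampled + spec.noise_sd * rng.standard_normal(sampled.shape)

    true_states = states[np.minimum(np.round(times).astype(int), total_seconds - 1)]
    ts = RegionalTimeseries(data=sampled.T, tr=spec.tr, group=group, task=task)
    return SubjectTaskData(timeseries=ts, events=events, true_states=true_states)


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate the full cohort: timeseries + events + geometry + receptors."""
    partition = default_partition(spec.n_regions)
    geometry = default_geometry(spec.n_regions)
    membership = partition.membership
    vmn_mask = membership[:, NETWORKS.index("vmn")]

    root = np.random.SeedSequence(spec.seed)
    ss_events, ss_receptors, ss_subjects = root.spawn(3)

    # one event schedule per task, shared across subjects (fixed design)
    events = {}
    for task, child in zip(("mid", "cue"), ss_events.spawn(2)):
        if task in spec.tasks:
            timing = spec.mid_timing if task == "mid" else spec.cue_timing
            events[task] = generate_events(task, timing,
                                           seed=child.generate_state(1)[0])

    rec_seeds = ss_receptors.spawn(2)
    receptors = ReceptorProfile(
        values={
            "MOR": generate_receptor_map(
                geometry, autocorr_length=0.5, vmn_enrichment=3.0,
                seed=rec_seeds[0].generate_state(1)[0], vmn_mask=vmn_mask),
            "D2DR": generate_receptor_map(
                geometry, autocorr_length=0.5, vmn_enrichment=2.0,
                seed=rec_seeds[1].generate_state(1)[0], vmn_mask=vmn_mask),
        },
        provenance="synthetic GP, VMN-enriched",
    )

    groups = ["A"] * spec.n_group_a + ["B"] * spec.n_group_b
    subjects = []
    subject_seeds = ss_subjects.spawn(len(groups))
    for s, (group, child) in enumerate(zip(groups, subject_seeds)):
        load_static = _static_loadings(
            membership, spec.cross_coupling, spec.coupling_effects, group
        )
        rng = np.random.default_rng(child)
        data = {}
        for task in spec.tasks:
            std = _simulate_subject_task(
                rng, spec, membership, load_static, events[task], task, group
            )
            sid = f"sub-{s:03d}"
            std.timeseries = replace(std.timeseries, subject_id=sid)
            data[task] = std
        subjects.append({"subject_id": f"sub-{s:03d}", "group": group, "data": data})

    region_ids = [f"R{i:03d}" for i in range(spec.n_regions)]
    return Cohort(
        spec=spec, partition=partition, geometry=geometry,
        receptors=receptors, subjects=subjects, region_ids=region_ids,
    )
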