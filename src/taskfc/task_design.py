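"""Condition regressors for task fMRI.

A task condition is described by a table of events (onset, duration,
condition label, all in seconds).  The per-second indicator ("boxcar") of a
condition is convolved with the canonical double-gamma haemodynamic response
function (HRF) and sampled at the volume acquisition times, yielding a
condition regressor on the volume grid.  Volumes belonging to a condition
are those where the regressor exceeds a fraction of its maximum, which
captures the HRF-lagged plateau of each block or trial.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TaskEvents",
    "ConditionRegressor",
    "build_boxcar",
    "canonical_hrf",
    "convolve_and_sample",
    "select_volumes",
]

HRF_DURATION = 32.0  # seconds of kernel support


@dataclass(frozen=True)
class TaskEvents:
    """Event table: onsets and durations in seconds, one row per event."""

    onset: np.ndarray
    duration: np.ndarray
    condition: np.ndarray

    def __post_init__(self) -> None:
        onset = np.asarray(self.onset, dtype=float)
        duration = np.asarray(self.duration, dtype=float)
        condition = np.asarray(self.condition, dtype=object)
        if not (len(onset) == len(duration) == len(condition)):
            raise ValueError("onset, duration and condition must have equal length")
        if np.any(onset < 0):
            raise ValueError("onsets must be >= 0")
        if np.any(duration <= 0):
            raise ValueError("durations must be > 0")
        if np.any(np.diff(onset) < 0):
            raise ValueError("onsets must be non-decreasing")
        # reject overlap between events of the same condition
        for label in np.unique(condition.astype(str)):
            sel = condition.astype(str) == label
            o, d = onset[sel], duration[sel]
            if np.any(o[1:] < (o[:-1] + d[:-1]) - 1e-12):
                raise ValueError(f"overlapping events within condition {label!r}")
        object.__setattr__(self, "onset", onset)
        object.__setattr__(self, "duration", duration)
        object.__setattr__(self, "condition", condition)

    @property
    def conditions(self) -> list[str]:
        return sorted(set(self.condition.astype(str)))

    @property
    def span(self) -> float:
        """End time of the last event, seconds."""
        return float(np.max(self.onset + self.duration)) if len(self.onset) else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"onset": self.onset, "duration": self.duration,
             "trial_type": self.condition.astype(str)}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TaskEvents":
        return cls(
            onset=df["onset"].to_numpy(float),
            duration=df["duration"].to_numpy(float),
            condition=df["trial_type"].to_numpy(object),
        )


@dataclass(frozen=True)
class ConditionRegressor:
    """Per-second boxcar, its HRF convolution, and the TR-sampled version."""

    boxcar: np.ndarray
    convolved: np.ndarray
    sampled: np.ndarray
    condition: str
    tr: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.convolved).all():
            raise ValueError("convolved regressor contains non-finite values")


def build_boxcar(events: TaskEvents, condition: str, total_seconds: int) -> np.ndarray:
    """Per-second 0/1 indicator: second s is 1 iff onset <= s < onset+duration.

    ``total_seconds`` is the acquisition length; events must fit inside it.
    """
    labels = events.condition.astype(str)
    if condition not in labels:
        raise ValueError(f"unknown condition label {condition!r}")
    if events.span > total_seconds + 1e-9:
        raise ValueError(
            f"events extend to {events.span:.1f}s, beyond the {total_seconds}s acquisition"
        )
    box = np.zeros(int(total_seconds), dtype=float)
    s = np.arange(int(total_seconds), dtype=float)
    for onset, dur in zip(events.onset[labels == condition],
                          events.duration[labels == condition]):
        box[(s >= onset) & (s < onset + dur)] = 1.0
    return box


def canonical_hrf(dt: float = 1.0) -> np.ndarray:
    """Canonical double-gamma HRF sampled on a 32 s grid at step ``dt``.

    h(t) = gampdf(t; 6, 1) - gampdf(t; 16, 1)/6, rescaled to unit peak.  The
    positive lobe peaks near 5 s and the undershoot near 15 s.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    t = np.arange(0.0, HRF_DURATION + dt / 2, dt)
    h = stats.gamma.pdf(t, a=6.0, scale=1.0) - stats.gamma.pdf(t, a=16.0, scale=1.0) / 6.0
    return h / np.max(h)


def convolve_and_sample(
    boxcar: np.ndarray,
    kernel: np.ndarray,
    tr: float,
    n_volumes: int,
    condition: str = "",
) -> ConditionRegressor:
    """Convolve the per-second boxcar with the HRF and sample at volume times.

    Volume v is timestamped at the start of the volume, t = v * tr.  The
    linear convolution is truncated to the acquisition span; the sampled
    value is linearly interpolated from the 1 s grid so non-integer TRs are
    supported.
    """
    boxcar = np.asarray(boxcar, dtype=float)
    convolved = np.convolve(boxcar, kernel)[: len(boxcar)]
    times = np.arange(n_volumes) * tr
    if n_volumes and times[-1] > len(boxcar) - 1 + 1e-9:
        raise ValueError(
            f"volume times extend to {times[-1]:.1f}s, beyond the "
            f"{len(boxcar)}s convolved support"
        )
    sampled = np.interp(times, np.arange(len(boxcar), dtype=float), convolved)
    return ConditionRegressor(
        boxcar=boxcar, convolved=convolved, sampled=sampled,
        condition=condition, tr=tr,
    )


def select_volumes(regressor: ConditionRegressor, threshold_frac: float = 0.5) -> np.ndarray:
    """Volumes whose regressor value reaches ``threshold_frac`` of its maximum.

    Returns a sorted, duplicate-free index array; empty when the regressor is
    identically zero.
    """
    if not (0.0 < threshold_frac <= 1.0):
        raise ValueError("threshold_frac must be in (0, 1]")
    sampled = regressor.sampled
    peak = float(np.max(sampled)) if len(sampled) else 0.0
    if peak <= 0.0:
        return np.array([], dtype=int)
    return np.flatnonzero(sampled >= threshold_frac * peak)


def condition_volumes(
    events: TaskEvents,
    condition: str,
    tr: float,
    n_volumes: int,
    threshold_frac: float = 0.5,
    use_convolved: bool = True,
) -> np.ndarray:
    """Convenience chain: boxcar -> HRF convolution -> sampling -> selection.

    With ``use_convolved=False`` the HRF is skipped and a volume is
    selected iff the raw boxcar is 1 at its timestamp (the unlagged
    reading of "volumes where the task timeseries is coded as 1").
    """
    total_seconds = int(np.ceil(n_volumes * tr))
    box = build_boxcar(events, condition, total_seconds)
    if not use_convolved:
        times = np.minimum((np.arange(n_volumes) * tr).astype(int),
                           total_seconds - 1)
        return np.flatnonzero(box[times] == 1.0)
    reg = convolve_and_sample(box, canonical_hrf(1.0), tr, n_volumes, condition)
    return select_volumes(reg, threshold_frac)
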