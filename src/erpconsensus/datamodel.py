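"""Core domain types for epoched EEG and ERP time-window analysis.

An :class:`EpochSet` holds all trials of one subject/condition as
``time × electrodes`` matrices (time points are the clustering observations,
electrodes the features).  A :class:`Labeling` assigns every time point of an
epoch to one of ``K`` clusters.  A :class:`TemplateMap` describes the target
ERP component (reference topography, expected-latency search interval, and the
electrode site used for amplitude scoring), and a :class:`TimeWindow` is the
determined contiguous latency range of that component together with its mean
topography and quality scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

__all__ = [
    "EpochSet",
    "Labeling",
    "TemplateMap",
    "TimeWindow",
    "ScoreRow",
    "PipelineConfig",
    "ms_to_idx",
    "idx_to_ms",
    "validate_epochset",
]


@dataclass
class EpochSet:
    """All trials of one subject in one condition.

    Parameters
    ----------
    subject_id : str
    condition : str
    trials : list of ndarray, each ``(n_time, n_chan)`` in µV
    times : ndarray of ms, strictly increasing with constant step ``1000/sfreq``
    channels : list of channel names, length ``n_chan``
    sfreq : sampling frequency in Hz
    """

    subject_id: str
    condition: str
    trials: list[np.ndarray]
    times: np.ndarray
    channels: list[str]
    sfreq: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.trials = [np.asarray(t, dtype=float) for t in self.trials]

    @property
    def n_time(self) -> int:
        return len(self.times)

    @property
    def n_chan(self) -> int:
        return len(self.channels)

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def erp(self, trial_ids: Sequence[int] | None = None) -> np.ndarray:
        """Average of trials (all, or the given subset) — the subject ERP."""
        if trial_ids is None:
            stack = self.trials
        else:
            stack = [self.trials[i] for i in trial_ids]
        if not stack:
            raise ValueError("cannot average an empty trial set")
        return np.mean(stack, axis=0)

    def channel_index(self, name: str) -> int:
        try:
            return self.channels.index(name)
        except ValueError:
            raise KeyError(f"unknown channel {name!r}") from None


@dataclass
class Labeling:
    """Hard cluster assignment of every time point of one epoch.

    ``labels`` take integer values in ``1..K``.
    """

    labels: np.ndarray
    K: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1:
            raise ValueError("labels must be a 1-D vector")
        if self.labels.size and (self.labels.min() < 1 or self.labels.max() > self.K):
            raise ValueError(f"labels must lie in 1..{self.K}")

    @property
    def n_time(self) -> int:
        return self.labels.size


@dataclass
class TemplateMap:
    """Reference topography of the target ERP component.

    ``interval`` is the experimentally interesting latency interval (ms) inside
    which candidate cluster maps are searched; ``site`` is the electrode used
    for mean-amplitude scoring (e.g. Fz for N2, Cz for P3).
    """

    name: str
    topography: np.ndarray
    interval: tuple[float, float]
    site: str

    def __post_init__(self) -> None:
        self.topography = np.asarray(self.topography, dtype=float)
        if not np.linalg.norm(self.topography) > 0:
            raise ValueError("template topography must have nonzero norm")
        lo, hi = self.interval
        if not lo <= hi:
            raise ValueError("interval must satisfy start <= end")


@dataclass
class TimeWindow:
    """Determined component time window (inclusive sample range)."""

    start_ms: float
    end_ms: float
    start_idx: int
    end_idx: int
    mean_topo: np.ndarray | None = None
    innersim: float = math.nan
    corr: float = math.nan

    def __post_init__(self) -> None:
        if self.start_idx > self.end_idx:
            raise ValueError("window start must not exceed end")

    @property
    def n_samples(self) -> int:
        return self.end_idx - self.start_idx + 1

    @property
    def duration_ms(self) -> float:
        return self.end_ms - self.start_ms

    @property
    def sl(self) -> slice:
        """Slice covering the window (inclusive end)."""
        return slice(self.start_idx, self.end_idx + 1)


@dataclass
class ScoreRow:
    """One scoring record: window bounds, inner similarity, site amplitude,
    spatial correlation to the template."""

    tw_start: float
    tw_end: float
    innersim: float
    amplitude: float
    corr: float

    def as_dict(self) -> dict[str, float]:
        return {
            "TW_start_ms": self.tw_start,
            "TW_end_ms": self.tw_end,
            "Innsim": self.innersim,
            "Amp_uV": self.amplitude,
            "Corr": self.corr,
        }


@dataclass
class PipelineConfig:
    """Thresholds and knobs of the full pipeline.

    Defaults follow the published operating points: trial examination uses
    inner similarity > 0.90 and a spatial-correlation threshold swept from
    0.70 down to 0.50 until at least ``retain_frac`` of trials survive;
    subject-level windows require inner similarity > 0.95 and correlation
    > 0.90 (relaxable to 0.50); cluster maps thinner than 10 ms merge into a
    neighbour correlated > 0.90; candidate-method screening requires inner
    similarity > 0.95 over windows longer than 50 ms.
    """

    K: int = 6
    k_range: tuple[int, int] = (2, 15)
    innersim_trial_thr: float = 0.90
    corr_trial_start: float = 0.70
    corr_trial_floor: float = 0.50
    corr_step: float = 0.05
    retain_frac: float = 0.50
    innersim_tw_thr: float = 0.95
    corr_tw_thr: float = 0.90
    corr_tw_floor: float = 0.50
    innersim_floor: float = 0.20
    thin_map_ms: float = 10.0
    thin_map_corr: float = 0.90
    mn_innersim_thr: float = 0.95
    mn_duration_ms: float = 50.0
    mn_repeats: int = 10
    mc_iters: int = 1000
    centered: bool = False
    merge_thin: bool = True
    normalize_maps: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.retain_frac <= 1:
            raise ValueError("retain_frac must lie in (0, 1]")
        for name in ("innersim_trial_thr", "corr_trial_start", "corr_trial_floor",
                     "innersim_tw_thr", "corr_tw_thr", "corr_tw_floor",
                     "thin_map_corr", "mn_innersim_thr"):
            v = getattr(self, name)
            if not -1.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [-1, 1], got {v}")
        if self.k_range[0] < 2:
            raise ValueError("k_range must start at 2 or above")

    def with_(self, **kw) -> "PipelineConfig":
        return replace(self, **kw)


def ms_to_idx(t: float, times: np.ndarray) -> int:
    """Index of the time sample nearest to ``t`` (ms), rounding half-up.

    Raises ``ValueError`` when ``t`` falls outside the epoch.
    """
    times = np.asarray(times, dtype=float)
    if t < times[0] or t > times[-1]:
        raise ValueError(f"t={t} ms outside epoch [{times[0]}, {times[-1]}] ms")
    step = times[1] - times[0]
    # floor(x + 1/2) implements deterministic round-half-up
    idx = int(math.floor((t - times[0]) / step + 0.5))
    return min(idx, len(times) - 1)


def idx_to_ms(i: int, times: np.ndarray) -> float:
    times = np.asarray(times, dtype=float)
    if not 0 <= i < len(times):
        raise ValueError(f"sample index {i} out of range 0..{len(times) - 1}")
    return float(times[i])


def validate_epochset(e: EpochSet) -> list[str]:
    """Return a list of invariant violations (empty list means valid)."""
    problems: list[str] = []
    if e.n_chan < 2:
        problems.append("fewer than 2 channels")
    if e.n_time < 2:
        problems.append("fewer than 2 time samples")
    else:
        steps = np.diff(e.times)
        if np.any(steps <= 0):
            problems.append("time axis not strictly increasing")
        elif not np.allclose(steps, steps[0], rtol=0, atol=1e-9 * abs(steps[0])):
            problems.append("non-uniform time axis")
        elif not math.isclose(steps[0], 1000.0 / e.sfreq, rel_tol=1e-9):
            problems.append(
                f"time step {steps[0]:g} ms inconsistent with sfreq {e.sfreq:g} Hz"
            )
    for k, tr in enumerate(e.trials):
        if tr.shape != (e.n_time, e.n_chan):
            problems.append(
                f"trial {k} has shape {tr.shape}, expected {(e.n_time, e.n_chan)}"
            )
        elif not np.all(np.isfinite(tr)):
            problems.append(f"trial {k} contains non-finite values")
    return problems
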