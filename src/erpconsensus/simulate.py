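"""Synthetic single-trial EEG study generator.

Emulates a stimulus-locked ERP study: 20 subjects × 2 conditions × 70 trials
recorded at 32 scalp electrodes, epochs −100..700 ms at 500 Hz (400 samples).
Four components are embedded — N1 and P2 as background activity, N2 and P3 as
the targets with a built-in condition effect:

* N2: frontal negativity (peak Fz, scored at Fz), subject latency 200–250 ms,
  duration 100–200 ms, magnitude −2.5..−1.5 µV; per-trial jitter ±50 ms
  latency, ±2 µV amplitude, ±50 ms duration.
* P3: centro-parietal positivity (peak Pz, scored at Cz), latency 250–450 ms,
  duration 350–500 ms, magnitude 4–6 µV; jitter ±100 ms, ±3 µV, ±100 ms.

Each component contributes ``waveform(t) ⊗ topography``.  The waveform is a
truncated (bi-)Gaussian pulse whose total support equals the drawn duration:
a fraction ``rise_frac`` of the duration lies before the peak and the rest
after, with σ = extent/3 on each side (the conventional ±3σ full extent of a
Gaussian ERP pulse, as in SEREEGA-style simulators).  The early components
are symmetric (``rise_frac=0.5``); the P3 uses ``rise_frac=0.10`` — a
steep-onset/slow-decay P3 morphology — so that its long 350–500 ms duration
never smears backwards over the N2 latency range (with the stated latency
and duration ranges the P3 support then always begins after 200 ms, leaving
every subject an uncontaminated N2 flank).  The N1 and P2
backgrounds are early and compact, finished before the N2 latency range
begins, as the frontal negativity's observable onset requires.  The topography
is a spatial Gaussian bump on the projected electrode layout with unit peak
(of the component's polarity) at the centre channel; centres and widths are
chosen so the target maps are spatially distinct, as published component
topographies are.  White
Gaussian noise (1 µV per channel/sample) is added.  The condition effect is an
amplitude scaling of the target components in condition 2 (N2 × 0.64,
P3 × 0.49 by default), giving the smaller second-condition deflections a
repeated-measures design can detect.

Everything drawn is recorded in a ground-truth table so that recovery of
latencies, windows, and topographies can be checked exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import EpochSet, TemplateMap

__all__ = [
    "ComponentSpec",
    "StudySpec",
    "electrode_layout",
    "component_topography",
    "erp_waveform",
    "simulate_study",
    "default_components",
    "ground_truth_template",
    "DEFAULT_INTERVALS",
    "DEFAULT_SITES",
]

# schematic 10-20/10-10 positions projected onto the unit disk (x: left→right,
# y: back→front); 32 channels including the Fz/FCz/Cz/Pz midline
_LAYOUT_32: list[tuple[str, float, float]] = [
    ("Fp1", -0.31, 0.95), ("Fp2", 0.31, 0.95),
    ("F7", -0.80, 0.59), ("F3", -0.45, 0.55), ("Fz", 0.0, 0.50),
    ("F4", 0.45, 0.55), ("F8", 0.80, 0.59),
    ("FC5", -0.59, 0.28), ("FC1", -0.23, 0.26), ("FCz", 0.0, 0.25),
    ("FC2", 0.23, 0.26), ("FC6", 0.59, 0.28),
    ("T7", -1.0, 0.0), ("C3", -0.50, 0.0), ("Cz", 0.0, 0.0),
    ("C4", 0.50, 0.0), ("T8", 1.0, 0.0),
    ("CP5", -0.59, -0.28), ("CP1", -0.23, -0.26), ("CP2", 0.23, -0.26),
    ("CP6", 0.59, -0.28),
    ("P7", -0.80, -0.59), ("P3", -0.45, -0.55), ("Pz", 0.0, -0.50),
    ("P4", 0.45, -0.55), ("P8", 0.80, -0.59),
    ("PO3", -0.33, -0.74), ("POz", 0.0, -0.75), ("PO4", 0.33, -0.74),
    ("O1", -0.31, -0.95), ("Oz", 0.0, -0.98), ("O2", 0.31, -0.95),
]


def electrode_layout(n: int = 32) -> tuple[list[str], np.ndarray]:
    """Standard scalp layout: channel names and 2-D unit-disk coordinates."""
    if n != 32:
        raise ValueError(f"only the 32-channel layout is defined, got n={n}")
    names = [c[0] for c in _LAYOUT_32]
    coords = np.array([[c[1], c[2]] for c in _LAYOUT_32])
    return names, coords


@dataclass
class ComponentSpec:
    """One ERP component's spatial and temporal generating parameters.

    Subject-level parameters are drawn uniformly from the ``*_range``
    intervals; every trial then deviates from its subject's value by a uniform
    jitter within ``trial_jitter = (latency ms, amplitude µV, duration ms)``.
    ``magnitude_range`` is signed and must match ``polarity``.
    """

    name: str
    center_channel: str
    spread: float
    polarity: int
    latency_range: tuple[float, float]
    duration_range: tuple[float, float]
    magnitude_range: tuple[float, float]
    trial_jitter: tuple[float, float, float] = (0.0, 0.0, 0.0)
    rise_frac: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.rise_frac < 1.0:
            raise ValueError("rise_frac must lie in (0, 1)")
        if self.polarity not in (-1, 1):
            raise ValueError("polarity must be +1 or -1")
        if self.spread <= 0:
            raise ValueError("topography spread must be positive")
        lo, hi = self.magnitude_range
        if lo > hi:
            raise ValueError("magnitude_range must be a valid interval")
        if np.sign(lo) != self.polarity or np.sign(hi) != self.polarity:
            raise ValueError("magnitude sign must match polarity")
        for rng in (self.latency_range, self.duration_range):
            if rng[0] > rng[1]:
                raise ValueError("ranges must satisfy lo <= hi")


def default_components() -> list[ComponentSpec]:
    """The four study components (N1/P2 background, N2/P3 targets)."""
    return [
        ComponentSpec("N1", "Oz", 0.50, -1, (85, 105), (40, 80), (-2.5, -1.5),
                      (10, 1, 10)),
        ComponentSpec("P2", "FCz", 0.50, +1, (110, 130), (40, 80), (1.5, 2.5),
                      (10, 1, 10)),
        ComponentSpec("N2", "Fz", 0.60, -1, (200, 250), (100, 200), (-2.5, -1.5),
                      (50, 2, 50)),
        ComponentSpec("P3", "Pz", 0.60, +1, (250, 450), (350, 500), (4.0, 6.0),
                      (100, 3, 100), rise_frac=0.10),
    ]


#: template-map search intervals (ms) and scoring sites for the two targets
DEFAULT_INTERVALS: dict[str, tuple[float, float]] = {"N2": (150, 350), "P3": (250, 600)}
DEFAULT_SITES: dict[str, str] = {"N2": "Fz", "P3": "Cz"}


@dataclass
class StudySpec:
    """Full study design (defaults are the reference simulation protocol)."""

    n_subjects: int = 20
    n_conditions: int = 2
    n_trials: int = 70
    n_channels: int = 32
    sfreq: float = 500.0
    epoch_ms: tuple[float, float] = (-100.0, 700.0)
    noise_sd: float = 1.0
    components: list[ComponentSpec] = field(default_factory=default_components)
    condition_scale: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: {"N2": (1.0, 0.64), "P3": (1.0, 0.49)}
    )
    seed: int = 0

    @property
    def times(self) -> np.ndarray:
        step = 1000.0 / self.sfreq
        n = int(round((self.epoch_ms[1] - self.epoch_ms[0]) / step))
        return self.epoch_ms[0] + step * np.arange(n)

    def scale(self, component: str, cond_idx: int) -> float:
        return self.condition_scale.get(component, (1.0,) * self.n_conditions)[cond_idx]


def component_topography(spec: ComponentSpec, layout: tuple[list[str], np.ndarray]
                         ) -> np.ndarray:
    """Spatial Gaussian bump with unit peak of the component's polarity."""
    names, coords = layout
    try:
        ci = names.index(spec.center_channel)
    except ValueError:
        raise KeyError(f"center channel {spec.center_channel!r} not in layout") from None
    d2 = ((coords - coords[ci]) ** 2).sum(axis=1)
    return spec.polarity * np.exp(-d2 / (2.0 * spec.spread**2))


def erp_waveform(latency: float, duration: float, amplitude: float,
                 times: np.ndarray, rise_frac: float = 0.5) -> np.ndarray:
    """Truncated (bi-)Gaussian pulse with total support = ``duration``.

    The support runs from ``latency − rise_frac·duration`` to
    ``latency + (1 − rise_frac)·duration`` with σ = extent/3 on each side, so
    each flank spans 3σ and truncation removes only ~0.3% of the peak.  With
    the default ``rise_frac=0.5`` this is the symmetric Gaussian pulse with
    σ = duration/6.  The value at ``t = latency`` is exactly ``amplitude``;
    outside the support the waveform is identically zero.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if not 0.0 < rise_frac < 1.0:
        raise ValueError("rise_frac must lie in (0, 1)")
    t = np.asarray(times, dtype=float)
    left, right = rise_frac * duration, (1.0 - rise_frac) * duration
    sigma = np.where(t < latency, left / 3.0, right / 3.0)
    w = amplitude * np.exp(-((t - latency) ** 2) / (2.0 * sigma**2))
    w[(t < latency - left) | (t > latency + right)] = 0.0
    return w


def _draw(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(rng.uniform(lo, hi))


def simulate_study(spec: StudySpec | None = None
                   ) -> tuple[list[EpochSet], pd.DataFrame]:
    """Generate the full study.

    Returns one :class:`EpochSet` per subject/condition plus a ground-truth
    table with every drawn parameter (one row per
    subject/condition/trial/component; trial ``-1`` rows hold the subject-level
    parameters).
    """
    spec = spec or StudySpec()
    layout = electrode_layout(spec.n_channels)
    names, _ = layout
    times = spec.times
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    topos = {c.name: component_topography(c, layout) for c in spec.components}

    epochsets: list[EpochSet] = []
    records: list[dict] = []
    for s in range(spec.n_subjects):
        subj_id = f"S{s + 1}"
        # subject-level parameters are shared across conditions; only the
        # amplitude scale differs between conditions
        subj = {}
        for c in spec.components:
            subj[c.name] = dict(
                latency=_draw(rng, *c.latency_range),
                duration=_draw(rng, *c.duration_range),
                magnitude=_draw(rng, *c.magnitude_range),
            )
        for cond in range(spec.n_conditions):
            cond_name = f"Cond{cond + 1}"
            for c in spec.components:
                p = subj[c.name]
                records.append(dict(
                    subject=subj_id, condition=cond_name, trial=-1,
                    component=c.name, latency=p["latency"],
                    duration=p["duration"],
                    amplitude=p["magnitude"] * spec.scale(c.name, cond),
                ))
            trials = []
            for tr in range(spec.n_trials):
                X = np.zeros((len(times), len(names)))
                for c in spec.components:
                    p = subj[c.name]
                    jl, ja, jd = c.trial_jitter
                    lat = p["latency"] + _draw(rng, -jl, jl)
                    dur = max(p["duration"] + _draw(rng, -jd, jd), 4.0)
                    amp = p["magnitude"] * spec.scale(c.name, cond) + _draw(rng, -ja, ja)
                    # topography carries the polarity sign (unit peak of the
                    # component's sign), so the waveform uses the unsigned bump:
                    # the centre-channel peak then equals the signed amplitude
                    X += np.outer(erp_waveform(lat, dur, amp, times,
                                               rise_frac=c.rise_frac),
                                  c.polarity * topos[c.name])
                    records.append(dict(
                        subject=subj_id, condition=cond_name, trial=tr,
                        component=c.name, latency=lat, duration=dur,
                        amplitude=amp,
                    ))
                if spec.noise_sd > 0:
                    X += rng.normal(0.0, spec.noise_sd, size=X.shape)
                trials.append(X)
            epochsets.append(EpochSet(
                subject_id=subj_id, condition=cond_name, trials=trials,
                times=times.copy(), channels=list(names), sfreq=spec.sfreq,
            ))
    return epochsets, pd.DataFrame.from_records(records)


def ground_truth_template(component: str, spec: StudySpec | None = None
                          ) -> TemplateMap:
    """Template map for a target component from the generator's ground truth."""
    spec = spec or StudySpec()
    comp = next((c for c in spec.components if c.name == component), None)
    if comp is None:
        raise KeyError(f"no component named {component!r} in the study spec")
    layout = electrode_layout(spec.n_channels)
    interval = DEFAULT_INTERVALS.get(component)
    if interval is None:
        lo = comp.latency_range[0] - comp.duration_range[1] / 4
        hi = comp.latency_range[1] + comp.duration_range[1] / 4
        interval = (max(lo, spec.epoch_ms[0]), min(hi, spec.epoch_ms[1]))
    site = DEFAULT_SITES.get(component, comp.center_channel)
    return TemplateMap(name=component,
                       topography=component_topography(comp, layout),
                       interval=interval, site=site)
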