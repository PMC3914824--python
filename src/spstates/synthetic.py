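"""Seeded piecewise-stationary EEG simulator with known oscillatory states.

Real EEG behaves, over short stretches, like a concatenation ("gluing") of
quasi-stationary processes, each dominated by a small set of narrowband
oscillations riding on a 1/f-plus-white background. This module generates
such signals with full ground truth: every analysis window knows which
state produced it, and whole multi-subject studies can be designed with a
planted universal/optional/unique cluster structure, so each downstream
pipeline stage can be verified against a recoverable truth.

Not emulated: volume conduction, inter-channel topographic correlation,
ocular/muscle artifacts. Channels are independent realizations of the same
state plan, with per-channel substreams spawned from the root seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .records import EEGRecord
from .spectral import SpectralConfig, n_windows

__all__ = [
    "StateDef",
    "StatePlan",
    "StudyDesign",
    "ClusterSpec",
    "gen_oscillation",
    "gen_piecewise_record",
    "gen_study",
    "truth_window_labels",
]


@dataclass(frozen=True)
class StateDef:
    """One quasi-stationary oscillatory state.

    peak_freqs : Hz, each in [1, 30]
    peak_amps : microvolt amplitude of each sinusoid
    noise_sd : microvolt SD of additive white Gaussian noise
    pink_scale : microvolt SD of the 1/f (spectrally shaped) background
    """

    state_id: str
    peak_freqs: tuple[float, ...] = ()
    peak_amps: tuple[float, ...] = ()
    noise_sd: float = 0.0
    pink_scale: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "peak_freqs", tuple(self.peak_freqs))
        object.__setattr__(self, "peak_amps", tuple(self.peak_amps))
        if len(self.peak_freqs) != len(self.peak_amps):
            raise ValueError("peak_freqs and peak_amps must have equal length")
        for f in self.peak_freqs:
            if not (1.0 <= f <= 30.0):
                raise ValueError(f"peak frequency {f} Hz outside [1, 30]")
        if any(a < 0 for a in self.peak_amps) or self.noise_sd < 0 or self.pink_scale < 0:
            raise ValueError("amplitudes and noise scales must be nonnegative")


@dataclass
class StatePlan:
    """Ordered (state_id, duration-in-seconds) entries for one recording."""

    entries: list[tuple[str, float]]

    def __post_init__(self) -> None:
        if any(d <= 0 for _, d in self.entries):
            raise ValueError("all plan durations must be positive")

    @property
    def total_duration(self) -> float:
        return sum(d for _, d in self.entries)


@dataclass(frozen=True)
class ClusterSpec:
    """Where a designed state may occur and how often per subject."""

    conditions: tuple[str, ...]
    probability: float = 1.0

    def __post_init__(self) -> None:
        if not self.conditions:
            raise ValueError("a designed state must occur in >= 1 condition")
        if not (0.0 <= self.probability <= 1.0):
            raise ValueError("probability must be in [0, 1]")


@dataclass
class StudyDesign:
    """Multi-subject, multi-condition study with planted cluster structure.

    cluster_matrix maps each designed state_id to the conditions in which
    it may occur and its per-subject occurrence probability. The truth
    universality category of each state follows from the realized
    per-condition presence by the same thresholds the pipeline applies.
    """

    states: dict[str, StateDef]
    cluster_matrix: dict[str, ClusterSpec]
    conditions: list[str]
    n_subjects: int
    n_channels: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or not self.conditions:
            raise ValueError("need >= 1 subject and >= 1 condition")
        unknown = set(self.cluster_matrix) - set(self.states)
        if unknown:
            raise ValueError(f"cluster_matrix refers to undefined states {unknown}")
        for sid, spec in self.cluster_matrix.items():
            bad = set(spec.conditions) - set(self.conditions)
            if bad:
                raise ValueError(f"state {sid} assigned to unknown conditions {bad}")


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-SD 1/f noise by spectral shaping of white Gaussian noise."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    spec[0] = 0.0
    spec[1:] /= np.sqrt(freqs[1:])
    pink = np.fft.irfft(spec, n)
    sd = pink.std()
    return pink / sd if sd > 0 else pink


def gen_oscillation(
    state: StateDef,
    duration: float,
    fs: float,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Generate one single-channel realization of a state.

    Sinusoid phases are drawn uniformly from the seeded generator, so two
    calls with the same seed are bit-identical while distinct segments of
    one recording get independent phases.
    """
    if fs < 64:
        raise ValueError(f"fs must be >= 64 Hz, got {fs}")
    if duration <= 0:
        raise ValueError("duration must be positive")
    for f in state.peak_freqs:
        if f > fs / 2:
            raise ValueError(f"peak {f} Hz above Nyquist ({fs / 2} Hz)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    x = np.zeros(n)
    for f, a in zip(state.peak_freqs, state.peak_amps):
        phase = rng.uniform(0.0, 2.0 * np.pi)
        x += a * np.sin(2.0 * np.pi * f * t + phase)
    if state.noise_sd > 0:
        x += state.noise_sd * rng.standard_normal(n)
    if state.pink_scale > 0 and n > 1:
        x += state.pink_scale * _pink_noise(n, rng)
    return x


def truth_window_labels(
    boundaries: list[tuple[str, int, int]],
    n_samples: int,
    fs: float = 128.0,
    cfg: SpectralConfig | None = None,
) -> np.ndarray:
    """Assign each sliding analysis window the state containing its centre.

    ``boundaries`` lists (state_id, start_sample, stop_sample) intervals.
    Window k covers samples [shift*k, shift*k + window); its centre is
    shift*k + window/2. Centre membership is unambiguous for overlapping
    windows.
    """
    cfg = cfg or SpectralConfig()
    win = cfg.window_samples(fs)
    nw = n_windows(n_samples, fs, cfg)
    centres = cfg.shift * np.arange(nw) + win / 2.0
    labels = np.empty(nw, dtype=object)
    for state_id, start, stop in boundaries:
        mask = (centres >= start) & (centres < stop)
        labels[mask] = state_id
    # a centre landing exactly on the record end belongs to the last state
    if nw and labels[-1] is None:
        labels[-1] = boundaries[-1][0]
    return labels


def gen_piecewise_record(
    plan: StatePlan,
    defs: dict[str, StateDef],
    n_channels: int,
    fs: float = 128.0,
    seed: int = 0,
    subject_id: str = "",
    condition: str = "",
    channel_labels: list[str] | None = None,
) -> tuple[EEGRecord, np.ndarray]:
    """Glue state realizations into a piecewise-stationary record.

    Returns the record and the per-window truth labels (state_id of the
    state whose interval contains each analysis-window centre, for the
    default 256-sample/50-shift window scheme).
    """
    for sid, _ in plan.entries:
        if sid not in defs:
            raise ValueError(f"plan references undefined state {sid!r}")
    if channel_labels is None:
        channel_labels = [f"ch{i}" for i in range(n_channels)]
    root = np.random.SeedSequence(seed)
    channel_seeds = root.spawn(n_channels)
    chans = []
    boundaries: list[tuple[str, int, int]] = []
    for ci in range(n_channels):
        rng = np.random.default_rng(channel_seeds[ci])
        parts = []
        pos = 0
        for sid, dur in plan.entries:
            seg = gen_oscillation(defs[sid], dur, fs, rng)
            parts.append(seg)
            if ci == 0:
                boundaries.append((sid, pos, pos + seg.size))
            pos += seg.size
        chans.append(np.concatenate(parts))
    samples = np.vstack(chans)
    record = EEGRecord(samples, fs, channel_labels, subject_id, condition)
    labels = truth_window_labels(boundaries, samples.shape[1], fs)
    return record, labels


def _subject_plan(
    allowed: list[str],
    specs: dict[str, ClusterSpec],
    epoch_len: float,
    rng: np.random.Generator,
) -> StatePlan:
    """Draw which designed states a subject expresses and order them.

    Each allowed state is included by an independent Bernoulli draw of its
    occurrence probability; if none is drawn, the highest-probability
    allowed state is used so every recording contains signal. Each
    included state occupies one epoch-length block, in shuffled order, so
    state changes fall exactly on epoch boundaries: analysis windows
    never straddle epochs, hence no window mixes two states' spectra.
    """
    included = [s for s in allowed if rng.uniform() < specs[s].probability]
    if not included:
        included = [max(allowed, key=lambda s: (specs[s].probability, s))]
    order = list(included)
    rng.shuffle(order)
    return StatePlan([(s, epoch_len) for s in order])


def gen_study(
    design: StudyDesign,
    epoch_len: float = 20.0,
    fs: float = 128.0,
    subject_fraction: float = 0.80,
    universal_fraction: float = 0.85,
) -> tuple[list[tuple[EEGRecord, np.ndarray]], pd.DataFrame, dict]:
    """Generate a whole study and its truth tables.

    Returns
    -------
    dataset : list of (EEGRecord, truth window labels), one per
        subject x condition.
    manifest : DataFrame with subject, condition, fs, n_channels rows.
    truth : dict with per-condition realized state presence
        (``presence[condition]`` = set of state_ids expressed by >=
        ``subject_fraction`` of subjects), per-state condition counts
        (``condition_count``) and universality categories (``category``),
        using the same thresholds as the pipeline's categorization.
    """
    from .repertoire import universality_category

    root = np.random.SeedSequence(design.seed)
    dataset = []
    rows = []
    plans: dict[str, list[str]] = {}
    expressed: dict[tuple[str, str], set[str]] = {}
    ci_seeds = root.spawn(len(design.conditions))
    for ci, cond in enumerate(design.conditions):
        allowed = sorted(
            s for s, spec in design.cluster_matrix.items() if cond in spec.conditions
        )
        if not allowed:
            raise ValueError(f"condition {cond!r} has no designed states")
        subj_seeds = ci_seeds[ci].spawn(design.n_subjects)
        for si in range(design.n_subjects):
            subject = f"S{si + 1:02d}"
            rng = np.random.default_rng(subj_seeds[si])
            plan = _subject_plan(allowed, design.cluster_matrix, epoch_len, rng)
            rec_seed = int(rng.integers(0, 2**31 - 1))
            record, labels = gen_piecewise_record(
                plan, design.states, design.n_channels, fs, rec_seed,
                subject_id=subject, condition=cond,
            )
            dataset.append((record, labels))
            plans[f"{cond}|{subject}"] = [sid for sid, _ in plan.entries]
            expressed[(cond, subject)] = {sid for sid, _ in plan.entries}
            rows.append(
                {"subject": subject, "condition": cond, "fs": fs,
                 "n_channels": design.n_channels, "epoch_len": epoch_len}
            )
    manifest = pd.DataFrame(rows)

    presence: dict[str, set[str]] = {}
    for cond in design.conditions:
        counts = {s: 0 for s in design.cluster_matrix}
        for si in range(design.n_subjects):
            for s in expressed[(cond, f"S{si + 1:02d}")]:
                counts[s] += 1
        presence[cond] = {
            s for s, c in counts.items() if c / design.n_subjects >= subject_fraction
        }
    condition_count = {
        s: sum(s in presence[c] for c in design.conditions)
        for s in design.cluster_matrix
    }
    n_cond = len(design.conditions)
    category = {
        s: universality_category(n1, n_cond, universal_fraction)
        for s, n1 in condition_count.items()
        if n1 > 0
    }
    truth = {
        "presence": {c: sorted(p) for c, p in presence.items()},
        "condition_count": condition_count,
        "category": category,
        "plans": plans,
    }
    return dataset, manifest, truth


def example_six_state_design(seed: int = 3, n_subjects: int = 3,
                             n_channels: int = 2) -> StudyDesign:
    """Reference design: six well-separated single-tone states, one condition.

    Tone frequencies are spaced by >= 3.5 Hz so every pair of templates
    correlates well below the acceptance threshold; all states occur for
    every subject. Used to validate that the classifier recovers the
    designed state set and window labels.
    """
    freqs = {"S1": 2.5, "S2": 6.5, "S3": 10.5, "S4": 15.0, "S5": 21.0,
             "S6": 27.0}
    states = {s: StateDef(s, (f,), (20.0,), 1.0, 1.0) for s, f in freqs.items()}
    matrix = {s: ClusterSpec(("rest",), 1.0) for s in states}
    return StudyDesign(states, matrix, ["rest"], n_subjects, n_channels,
                       seed=seed)


def example_universality_design(seed: int = 11, n_subjects: int = 5,
                                n_channels: int = 2) -> StudyDesign:
    """Reference design: 13 conditions with a planted universality split.

    Two states occur in all 13 conditions (universal), three in
    intermediate subsets (optional), and two in exactly one condition
    each (unique); all occurrence probabilities are 1, so the designed
    categorization is deterministic.
    """
    freqs = {"U1": 2.5, "U2": 6.0, "O1": 10.0, "O2": 14.0, "O3": 19.0,
             "Q1": 24.0, "Q2": 28.0}
    states = {s: StateDef(s, (f,), (20.0,), 1.0, 1.0) for s, f in freqs.items()}
    conds = [f"C{i:02d}" for i in range(1, 14)]
    matrix = {
        "U1": ClusterSpec(tuple(conds), 1.0),
        "U2": ClusterSpec(tuple(conds), 1.0),
        "O1": ClusterSpec(tuple(conds[0:6]), 1.0),
        "O2": ClusterSpec(tuple(conds[3:10]), 1.0),
        "O3": ClusterSpec(tuple(conds[6:12]), 1.0),
        "Q1": ClusterSpec((conds[0],), 1.0),
        "Q2": ClusterSpec((conds[12],), 1.0),
    }
    return StudyDesign(states, matrix, conds, n_subjects, n_channels, seed=seed)


def state_frequencies(design: StudyDesign) -> dict[str, float]:
    """First peak frequency of each designed state (for truth mapping)."""
    return {sid: s.peak_freqs[0] for sid, s in design.states.items()
            if s.peak_freqs}
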