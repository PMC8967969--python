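"""Synthetic multichannel sEMG with known ground truth.

The generator produces interference-pattern surrogates: band-limited
(30-500 Hz) Gaussian noise carriers, amplitude-modulated by smooth
raised-cosine activation envelopes, plus continuous low-level baseline noise
and optional 50 Hz mains contamination. Impairment is controlled by three
knobs with direct physiological readings:

* ``selectivity`` — the fraction of intended drive that stays on the target
  agonist/antagonist pair; the remainder leaks to the other ipsilateral
  muscles through a co-activation matrix,
* ``mirror_gain`` — leakage of the intended drive onto the homologous
  contralateral muscles,
* ``baseline_noise_uv`` — resting background activity.

Each generated session carries an event table marking the 3 repetitions of
all 8 tasks and a ground-truth table of the noiseless activation RMS per
channel and task, so every downstream estimate can be checked against what
was actually injected.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from importlib import resources
from scipy import signal

from .errors import ValidationError
from .io import ArtifactTable, EmgRecording, EventTable
from .montage import (
    ALL_TASKS,
    CANONICAL_CHANNELS,
    CHANNEL_INDEX,
    MIRROR_PERMUTATION,
    TARGET_MUSCLES,
    ChannelLabel,
    TaskId,
)

_N = len(CANONICAL_CHANNELS)

#: RMS of the raised-cosine (sin^2) envelope over whole half-cycles.
ENVELOPE_RMS = float(np.sqrt(3.0 / 8.0))


def load_group_defaults() -> dict:
    """Cohort parameter distributions shipped with the package (YAML)."""
    text = resources.files("emgsi").joinpath("group_defaults.yaml").read_text()
    return yaml.safe_load(text)


def leakage_matrix(strength: float) -> np.ndarray:
    """Within-leg co-activation matrix: diagonal 1, same-side off-diagonal
    entries equal to ``strength``, no cross-leg terms (mirroring is separate)."""
    if strength < 0:
        raise ValidationError("leakage strength must be nonnegative")
    c = np.zeros((_N, _N))
    for i, ci in enumerate(CANONICAL_CHANNELS):
        for j, cj in enumerate(CANONICAL_CHANNELS):
            if i == j:
                c[i, j] = 1.0
            elif ci.side == cj.side:
                c[i, j] = strength
    return c


@dataclass(frozen=True)
class TaskScript:
    """Timing of one session: 3 repetitions of ~2 s per task, with rests."""

    rep_duration_s: float = 2.0
    n_reps: int = 3
    rep_gap_s: float = 0.5
    task_gap_s: float = 1.5
    initial_rest_s: float = 3.5
    tasks: tuple[TaskId, ...] = ALL_TASKS

    def __post_init__(self) -> None:
        if self.rep_duration_s <= 0 or self.n_reps < 1:
            raise ValidationError("repetitions must have positive duration and count >= 1")

    def timeline(self) -> tuple[list[tuple[TaskId, int, float, float]], float]:
        """(task, repetition, start_s, end_s) rows plus the total duration."""
        rows = []
        t = self.initial_rest_s
        for task in self.tasks:
            for rep in range(1, self.n_reps + 1):
                rows.append((task, rep, t, t + self.rep_duration_s))
                t += self.rep_duration_s + self.rep_gap_s
            t += self.task_gap_s
        return rows, t


@dataclass(frozen=True)
class SubjectProfile:
    """Ground-truth impairment parameters of one synthetic subject.

    ``selectivity`` may be a scalar or a per-task mapping (joint-to-joint
    variation); the co-activation matrix must have unit diagonal and
    nonnegative entries.
    """

    selectivity: float | dict = 1.0
    coactivation: np.ndarray = field(default_factory=lambda: leakage_matrix(0.8))
    mirror_gain: float = 0.0
    baseline_noise_uv: float = 2.0
    mains_amplitude_uv: float = 0.0
    group: str = "control"
    seed: int = 0
    subject_id: str = "synthetic"
    side_map: dict = field(default_factory=lambda: {"less": "r", "more": "l"})
    target_amplitude_uv: float = 60.0
    antagonist_ratio: float = 0.6

    def __post_init__(self) -> None:
        c = np.asarray(self.coactivation, float)
        object.__setattr__(self, "coactivation", c)
        if c.shape != (_N, _N) or (c < 0).any():
            raise ValidationError("coactivation must be a nonnegative 10x10 matrix")
        if not np.allclose(np.diag(c), 1.0):
            raise ValidationError("coactivation diagonal must be 1")
        for s in self._selectivities().values():
            if not 0 <= s <= 1:
                raise ValidationError(f"selectivity {s} outside [0, 1]")
        if self.mirror_gain < 0 or self.baseline_noise_uv < 0 or self.mains_amplitude_uv < 0:
            raise ValidationError("gains and noise amplitudes must be nonnegative")

    def _selectivities(self) -> dict[TaskId, float]:
        if isinstance(self.selectivity, dict):
            return {t: float(self.selectivity.get(t, 1.0)) for t in ALL_TASKS}
        return {t: float(self.selectivity) for t in ALL_TASKS}


def _activation_vector(profile: SubjectProfile, task: TaskId) -> np.ndarray:
    """Per-channel activation amplitude (uV) during one task's movement."""
    side = profile.side_map[task.leg]
    agonist, antagonist = TARGET_MUSCLES[task.joint]
    a = np.zeros(_N)
    a[CHANNEL_INDEX[ChannelLabel(agonist, side)]] = profile.target_amplitude_uv
    a[CHANNEL_INDEX[ChannelLabel(antagonist, side)]] = (
        profile.target_amplitude_uv * profile.antagonist_ratio
    )
    sel = profile._selectivities()[task]
    leak = a @ profile.coactivation - a  # off-diagonal propagation only
    spread = a + (1.0 - sel) * leak
    spread = spread + profile.mirror_gain * a[list(MIRROR_PERMUTATION)]
    return spread


def _band_limited_noise(rng: np.random.Generator, n: int, n_ch: int, fs: float) -> np.ndarray:
    """Unit-RMS Gaussian noise band-passed to the 30-500 Hz hardware band."""
    high = min(500.0, 0.45 * fs)
    sos = signal.butter(4, [30.0, high], btype="bandpass", fs=fs, output="sos")
    # single pass: phase is irrelevant for a stochastic carrier
    x = signal.sosfilt(sos, rng.standard_normal((n, n_ch)), axis=0)
    return x / x.std(axis=0, keepdims=True)


def generate_subject(
    profile: SubjectProfile,
    script: TaskScript = TaskScript(),
    fs: float = 1500.0,
    session: str = "test",
) -> tuple[EmgRecording, EventTable, pd.DataFrame]:
    """Synthesise one session: recording, event table and ground truth.

    Ground truth holds the analytic noiseless activation RMS per channel and
    task (amplitude x envelope RMS), i.e. what a perfect pipeline would
    recover before baseline contamination.
    """
    rows, duration = script.timeline()
    n = int(round(duration * fs))
    rng = np.random.default_rng(profile.seed if session == "test" else profile.seed + 10_000_019)

    amp = np.zeros((n, _N))
    truth_rows = []
    half = script.rep_duration_s / 2.0
    for task in script.tasks:
        spread = _activation_vector(profile, task)
        for t, rep, start, end in [r for r in rows if r[0] == task]:
            i0, i1 = int(round(start * fs)), int(round(end * fs))
            tt = np.arange(i1 - i0) / fs
            env = np.sin(np.pi * tt / half) ** 2
            amp[i0:i1] += env[:, None] * spread[None, :]
        for ch, a in zip(CANONICAL_CHANNELS, spread):
            truth_rows.append(
                {
                    "joint": task.joint,
                    "leg": task.leg,
                    "channel": str(ch),
                    "activation_rms": a * ENVELOPE_RMS,
                }
            )

    carrier_act = _band_limited_noise(rng, n, _N, fs)
    carrier_base = _band_limited_noise(rng, n, _N, fs)
    samples = amp * carrier_act + profile.baseline_noise_uv * carrier_base
    if profile.mains_amplitude_uv > 0:
        phases = rng.uniform(0, 2 * np.pi, _N)
        t_axis = np.arange(n) / fs
        samples = samples + profile.mains_amplitude_uv * np.sin(
            2 * np.pi * 50.0 * t_axis[:, None] + phases[None, :]
        )
    notch_flags = np.full(_N, profile.mains_amplitude_uv > 0)

    rec = EmgRecording(
        samples=samples,
        fs=fs,
        notch_flags=notch_flags,
        subject_id=profile.subject_id,
        session=session,
        side_map=dict(profile.side_map),
    )
    events = EventTable(
        pd.DataFrame(
            [
                {
                    "joint": task.joint,
                    "leg": task.leg,
                    "repetition": rep,
                    "start_s": start,
                    "end_s": end,
                }
                for task, rep, start, end in rows
            ]
        )
    )
    return rec, events, pd.DataFrame(truth_rows)


@dataclass(frozen=True)
class SubjectDataset:
    """One synthetic subject: signals, events, truth, and clinical stand-ins."""

    recording: EmgRecording
    events: EventTable
    ground_truth: pd.DataFrame
    profile: SubjectProfile
    scale_scores: dict  # TaskId -> int in {0, 1, 2}
    gmfcs: int | None
    task_selectivity: dict  # TaskId -> float


def _scale_score(selectivity: float) -> int:
    """Map a task's true selectivity onto the 0/1/2 ordinal grading."""
    if selectivity >= 0.8:
        return 2
    if selectivity >= 0.45:
        return 1
    return 0


def _gmfcs_level(mean_selectivity: float) -> int:
    for level, thresh in ((1, 0.75), (2, 0.6), (3, 0.45)):
        if mean_selectivity >= thresh:
            return level
    return 4


def generate_cohort(
    n: int,
    group: str,
    seed: int,
    script: TaskScript = TaskScript(),
    fs: float = 1500.0,
    session: str = "test",
    params: dict | None = None,
) -> list[SubjectDataset]:
    """Reproducible cohort of ``n`` subjects drawn from a group's distributions.

    Per-subject seeds derive from the master seed; the same (n, group, seed)
    always yields bit-identical datasets. ``params`` overrides the shipped
    group defaults. Synthetic ordinal joint scores and (for the CP group)
    GMFCS levels are derived from the true selectivities, so concurrent- and
    discriminative-validity analyses have a known ground truth to recover.
    """
    if n < 1:
        raise ValidationError("cohort size must be >= 1")
    defaults = load_group_defaults()
    if group not in defaults:
        raise ValidationError(f"unknown group {group!r}; expected one of {sorted(defaults)}")
    p = dict(defaults[group])
    if params:
        p.update(params)

    master = np.random.default_rng(seed)
    out = []
    for i in range(n):
        sub_seed = int(master.integers(0, 2**31 - 1))
        rng = np.random.default_rng(sub_seed)
        base_sel = rng.uniform(*p["selectivity_range"])
        task_sel = {
            t: float(np.clip(base_sel + rng.normal(0, p["joint_jitter_sd"]), 0, 1))
            for t in ALL_TASKS
        }
        if session == "retest":
            # day-to-day physiological drift of the true selectivity;
            # deterministic given the subject seed, independent of the test day
            drift = np.random.default_rng(sub_seed + 500_009)
            task_sel = {
                t: float(np.clip(s + drift.normal(0, p["session_jitter_sd"]), 0, 1))
                for t, s in task_sel.items()
            }
        profile = SubjectProfile(
            selectivity=task_sel,
            coactivation=leakage_matrix(p["coactivation_strength"]),
            mirror_gain=float(rng.uniform(*p["mirror_range"])),
            baseline_noise_uv=float(p["baseline_noise_uv"]),
            mains_amplitude_uv=float(p["mains_amplitude_uv"]),
            group=group,
            seed=int(rng.integers(0, 2**31 - 1)),
            subject_id=f"{group}_{i:03d}",
        )
        rec, events, truth = generate_subject(profile, script, fs, session)
        scales = {t: _scale_score(s) for t, s in task_sel.items()}
        gmfcs = _gmfcs_level(float(np.mean(list(task_sel.values())))) if group == "CP" else None
        out.append(
            SubjectDataset(
                recording=rec,
                events=events,
                ground_truth=truth,
                profile=profile,
                scale_scores=scales,
                gmfcs=gmfcs,
                task_selectivity=task_sel,
            )
        )
    return out


@dataclass(frozen=True)
class ArtifactSpec:
    """How many artifacts to inject and how they look."""

    n_global: int = 1
    n_channel: int = 0
    duration_range: tuple[float, float] = (0.1, 0.5)
    amplitude_uv: float = 500.0


def inject_artifacts(
    rec: EmgRecording, events: EventTable, spec: ArtifactSpec, seed: int
) -> tuple[EmgRecording, ArtifactTable]:
    """Add large band-limited transients at random logged positions.

    Global artifacts are placed so they never swallow an entire repetition
    window (that case is an explicit downstream error path, not a random
    one); channel-scoped artifacts land anywhere. Returns the corrupted
    recording and the matching artifact table for ``cut_artifacts``.
    """
    rng = np.random.default_rng(seed)
    samples = rec.samples.copy()
    rows = []

    def covers_full_rep(s: float, e: float) -> bool:
        ev = events.df
        return bool(((ev["start_s"] >= s) & (ev["end_s"] <= e)).any())

    def burst(n_samp: int, n_ch: int) -> np.ndarray:
        high = min(200.0, 0.45 * rec.fs)
        sos = signal.butter(4, [30.0, high], btype="bandpass", fs=rec.fs, output="sos")
        x = signal.sosfilt(sos, rng.standard_normal((n_samp, n_ch)), axis=0)
        x = x / x.std(axis=0, keepdims=True)
        taper = np.sin(np.pi * np.arange(n_samp) / n_samp)[:, None] ** 2
        return spec.amplitude_uv * x * taper

    for scope_kind, count in (("all", spec.n_global), ("channel", spec.n_channel)):
        for _ in range(count):
            dur = rng.uniform(*spec.duration_range)
            for _ in range(100):
                start = rng.uniform(0, rec.duration_s - dur)
                if scope_kind != "all" or not covers_full_rep(start, start + dur):
                    break
            sl = rec.sample_slice(start, start + dur)
            n_samp = sl.stop - sl.start
            if scope_kind == "all":
                samples[sl] += burst(n_samp, samples.shape[1])
                scope = "all"
                reason = "cable contact"
            else:
                ch = CANONICAL_CHANNELS[int(rng.integers(0, _N))]
                samples[sl, CHANNEL_INDEX[ch]] += burst(n_samp, 1)[:, 0]
                scope = str(ch)
                reason = "sensor touched"
            rows.append(
                {"start_s": start, "end_s": start + dur, "scope": scope, "reason": reason}
            )

    table = (
        ArtifactTable(pd.DataFrame(rows)) if rows else ArtifactTable.empty()
    )
    return rec.with_samples(samples), table
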