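"""Surface EMG signal conditioning.

The chain mirrors standard practice for voluntary-activation analysis:

1. 20 Hz linear-phase FIR high-pass on every channel (movement-artifact and
   baseline-drift rejection), applied with group-delay compensation so the
   output has zero net phase shift.
2. A 2nd-order IIR 50 Hz notch applied *only* to channels flagged as
   contaminated by mains interference, forward-backward for zero phase.
3. "Minimal cutting" of documented artifact segments: globally-scoped
   segments are excised from the time axis (event windows shift left);
   channel-scoped segments mark the overlapped repetitions of that channel
   for exclusion from RMS averaging.
4. Background-activity baseline: for each channel, the quietest 3-second
   window anywhere in the measurement, found by a sliding RMS scan. The
   baseline RMS is later subtracted (floored at zero) from movement-window
   RMS values.
5. Windowed RMS over half-open repetition windows.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .errors import DataError, ExclusionError, ParameterError
from .io import ArtifactTable, EmgRecording, EventTable
from .montage import CANONICAL_CHANNELS, CHANNEL_INDEX, ChannelLabel, TaskId


@dataclass(frozen=True)
class FilterSpec:
    """High-pass / notch design parameters.

    ``fir_order=None`` selects the automatic order ``4 * ceil(fs / cutoff)``
    rounded to even, i.e. a windowed-sinc long enough for a sharp 20 Hz edge
    at EMG sampling rates.
    """

    highpass_cutoff_hz: float = 20.0
    fir_order: int | None = None
    notch_freq_hz: float = 50.0
    notch_q: float = 30.0

    def resolved_order(self, fs: float) -> int:
        if self.fir_order is not None:
            order = int(self.fir_order)
        else:
            order = 4 * math.ceil(fs / self.highpass_cutoff_hz)
        if order % 2:
            order += 1
        return order

    def highpass_taps(self, fs: float) -> np.ndarray:
        if not 0 < self.highpass_cutoff_hz < fs / 2:
            raise ParameterError(
                f"high-pass cutoff {self.highpass_cutoff_hz} Hz outside (0, fs/2)"
            )
        order = self.resolved_order(fs)
        # odd tap count -> type-I linear phase, valid as a high-pass
        return signal.firwin(
            order + 1, self.highpass_cutoff_hz, pass_zero=False, window="hamming", fs=fs
        )


@dataclass(frozen=True)
class BaselineProfile:
    """Per-channel quietest-window RMS and its location."""

    baseline_rms: np.ndarray  # (10,) microvolts, >= 0
    window_start_s: np.ndarray  # (10,) seconds
    window_s: float = 3.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "baseline_rms", np.asarray(self.baseline_rms, float))
        object.__setattr__(self, "window_start_s", np.asarray(self.window_start_s, float))
        if self.baseline_rms.shape != (len(CANONICAL_CHANNELS),):
            raise ParameterError("baseline profile needs one entry per montage channel")
        if (self.baseline_rms < 0).any():
            raise ParameterError("baseline RMS must be nonnegative")

    @classmethod
    def zero(cls) -> "BaselineProfile":
        n = len(CANONICAL_CHANNELS)
        return cls(np.zeros(n), np.zeros(n))


def highpass(rec: EmgRecording, spec: FilterSpec = FilterSpec()) -> EmgRecording:
    """Apply the linear-phase FIR high-pass to every channel, length preserved.

    The symmetric FIR is applied in a single pass and the constant group
    delay (order/2 samples) is removed, so the measured response equals the
    designed magnitude response and the net phase is zero.
    """
    taps = spec.highpass_taps(rec.fs)
    order = len(taps) - 1
    if order >= rec.n_samples / 3:
        raise ParameterError(
            f"FIR order {order} too long for a {rec.n_samples}-sample recording"
        )
    full = signal.oaconvolve(rec.samples, taps[:, None], axes=0)
    delay = order // 2
    return rec.with_samples(full[delay : delay + rec.n_samples])


def notch(rec: EmgRecording, spec: FilterSpec = FilterSpec()) -> EmgRecording:
    """Zero-phase 50 Hz rejection on flagged channels only.

    Channels whose ``notch_flags`` entry is false are returned bit-identical.
    """
    if not rec.notch_flags.any():
        return rec
    if not 0 < spec.notch_freq_hz < rec.fs / 2:
        raise ParameterError(f"notch frequency {spec.notch_freq_hz} Hz outside (0, fs/2)")
    b, a = signal.iirnotch(spec.notch_freq_hz, spec.notch_q, fs=rec.fs)
    out = rec.samples.copy()
    idx = np.flatnonzero(rec.notch_flags)
    out[:, idx] = signal.filtfilt(b, a, rec.samples[:, idx], axis=0)
    return rec.with_samples(out)


def _merge_intervals(intervals: list[tuple[float, float]]) -> list[tuple[float, float]]:
    merged: list[list[float]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def cut_artifacts(
    rec: EmgRecording, artifacts: ArtifactTable, events: EventTable
) -> tuple[EmgRecording, EventTable, frozenset[tuple[TaskId, int, ChannelLabel]]]:
    """Excise globally-scoped artifact segments and collect channel exclusions.

    Returns the shortened recording, the event table with all windows shifted
    left by the excised duration before them, and the set of
    ``(task, repetition, channel)`` triples whose RMS must be skipped because
    a channel-scoped artifact overlaps that repetition window.

    Raises :class:`ExclusionError` if a global segment swallows an entire
    repetition window (no data would remain for any channel).
    """
    artifacts.check_inside(rec.duration_s)
    events.check_inside(rec.duration_s)
    df = artifacts.df
    global_ivs = _merge_intervals(
        [(float(r["start_s"]), float(r["end_s"])) for _, r in df[df["scope"] == "all"].iterrows()]
    )

    for _, row in events.df.iterrows():
        for s, e in global_ivs:
            if s <= row["start_s"] and e >= row["end_s"]:
                raise ExclusionError(
                    f"global artifact [{s}, {e}) covers all of "
                    f"{row['joint']}_{row['leg']} repetition {int(row['repetition'])}"
                )

    exclusions: set[tuple[TaskId, int, ChannelLabel]] = set()
    for _, row in df[df["scope"] != "all"].iterrows():
        ch = ChannelLabel.parse(str(row["scope"]))
        a_s, a_e = float(row["start_s"]), float(row["end_s"])
        for _, ev in events.df.iterrows():
            if a_s < ev["end_s"] and a_e > ev["start_s"]:  # half-open overlap
                exclusions.add(
                    (TaskId(ev["joint"], ev["leg"]), int(ev["repetition"]), ch)
                )

    if not global_ivs:
        return rec, events, frozenset(exclusions)

    keep = np.ones(rec.n_samples, dtype=bool)
    for s, e in global_ivs:
        keep[rec.sample_slice(s, e)] = False
    new_samples = rec.samples[keep]

    def shifted(t: float) -> float:
        cut_before = sum(min(e, t) - s for s, e in global_ivs if s < t)
        return t - cut_before

    ev = events.df.copy()
    ev["start_s"] = ev["start_s"].map(shifted)
    ev["end_s"] = ev["end_s"].map(shifted)
    return rec.with_samples(new_samples), EventTable(ev), frozenset(exclusions)


def _sliding_rms(x: np.ndarray, window: int, step: int) -> tuple[np.ndarray, np.ndarray]:
    """RMS of every window of ``window`` samples starting each ``step`` samples.

    Returns (rms values, start indices); the final admissible start is always
    included so the scan covers the end of the recording.
    """
    n = x.shape[0]
    csum = np.concatenate([np.zeros((1,) + x.shape[1:]), np.cumsum(x * x, axis=0)])
    starts = np.arange(0, n - window + 1, step)
    if starts[-1] != n - window:
        starts = np.append(starts, n - window)
    sumsq = csum[starts + window] - csum[starts]
    return np.sqrt(np.maximum(sumsq, 0.0) / window), starts


def estimate_baseline(
    rec: EmgRecording, window_s: float = 3.0, step_s: float = 0.1
) -> BaselineProfile:
    """Locate the quietest ``window_s`` stretch of each channel.

    Slides a ``window_s`` RMS window over the whole measurement with stride
    ``step_s`` and keeps, per channel, the minimum RMS and its start time.
    A stride of one sample (``step_s = 1/fs``) gives the exhaustive scan.
    """
    window = int(round(window_s * rec.fs))
    if window > rec.n_samples:
        raise DataError(
            f"recording of {rec.duration_s:.2f} s shorter than the {window_s} s baseline window"
        )
    step = max(1, int(round(step_s * rec.fs)))
    rms, starts = _sliding_rms(rec.samples, window, step)
    best = np.argmin(rms, axis=0)
    n_ch = rec.samples.shape[1]
    return BaselineProfile(
        baseline_rms=rms[best, np.arange(n_ch)],
        window_start_s=starts[best] / rec.fs,
        window_s=window_s,
    )


def window_rms(
    rec: EmgRecording, start_s: float, end_s: float, channel: ChannelLabel | int | None = None
) -> float | np.ndarray:
    """RMS over the half-open window ``[start_s, end_s)``.

    With ``channel=None`` returns the 10-vector of per-channel RMS values.
    """
    sl = rec.sample_slice(start_s, end_s)
    seg = rec.samples[sl]
    if seg.shape[0] == 0:
        raise DataError(f"empty RMS window [{start_s}, {end_s})")
    rms = np.sqrt(np.mean(seg * seg, axis=0))
    if channel is None:
        return rms
    idx = CHANNEL_INDEX[channel] if isinstance(channel, ChannelLabel) else int(channel)
    return float(rms[idx])
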