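"""Response vectors, prototype vectors and the similarity index.

For each selective joint movement, the ten baseline-corrected RMS amplitudes
(one per muscle) form a nonnegative *response vector* (RV). Averaging the
RVs of a neurologically intact reference cohort elementwise gives the
*prototype response vector* (PRV) for that task. The *similarity index* (SI)
of a participant's RV is the cosine of the angle between RV and PRV:

    SI = (RV . PRV) / (|RV| |PRV|)

Since both vectors are nonnegative the SI lies in [0, 1]; 1 means the
relative distribution of muscle activity matches the reference exactly
(selective activation), values near 0 mean activity concentrated in muscles
the reference leaves quiet (co-activation of the tested limb and/or mirror
activity of the contralateral limb).

Side handling: vectors are re-indexed into an *ipsilateral-first* layout
(the five channels of the tested side first) before comparison, so left- and
right-leg tasks of the same joint can share one pooled prototype.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import DataError, DegenerateReferenceError, ExclusionError, ParameterError
from .io import EmgRecording, EventTable
from .montage import (
    CANONICAL_CHANNELS,
    CHANNEL_INDEX,
    JOINTS,
    LEGS,
    MIRROR_PERMUTATION,
    TARGET_MUSCLES,
    ChannelLabel,
    TaskId,
)
from .preprocess import BaselineProfile, window_rms

logger = logging.getLogger(__name__)

_N = len(CANONICAL_CHANNELS)


def ipsilateral_first(values: np.ndarray, tested_side: str) -> np.ndarray:
    """Re-index a canonical 10-vector so the tested side occupies entries 0-4."""
    values = np.asarray(values, float)
    if tested_side == "r":
        return values.copy()
    if tested_side == "l":
        return values[list(MIRROR_PERMUTATION)]
    raise ParameterError(f"tested side must be 'r' or 'l', got {tested_side!r}")


@dataclass(frozen=True)
class ResponseVector:
    """Ten baseline-corrected RMS amplitudes for one task, canonical order."""

    values: np.ndarray
    task: TaskId
    subject_id: str = "anonymous"
    side: str = "r"  # physical tested side
    n_reps_used: np.ndarray = field(default_factory=lambda: np.full(_N, 3, dtype=int))

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "n_reps_used", np.asarray(self.n_reps_used, int))
        if v.shape != (_N,):
            raise ParameterError(f"response vector must have {_N} entries, got {v.shape}")
        if (v < 0).any() or not np.all(np.isfinite(v)):
            raise ParameterError("response vector entries must be finite and nonnegative")
        if not np.all((self.n_reps_used >= 1) & (self.n_reps_used <= 3)):
            raise ParameterError("n_reps_used entries must lie in 1..3")

    @property
    def ipsi_first(self) -> np.ndarray:
        return ipsilateral_first(self.values, self.side)


@dataclass(frozen=True)
class PrototypeResponseVector:
    """Elementwise reference-cohort mean, stored ipsilateral-first."""

    values: np.ndarray
    joint: str
    n_reference: int
    pooled: bool = True
    side: str | None = None  # physical side when not pooled

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        object.__setattr__(self, "values", v)
        if v.shape != (_N,):
            raise ParameterError(f"prototype vector must have {_N} entries")
        if (v < 0).any():
            raise ParameterError("prototype entries must be nonnegative")
        if not np.linalg.norm(v) > 0:
            raise DegenerateReferenceError(f"zero-magnitude prototype for joint {self.joint}")


def magnitude(rv: ResponseVector | np.ndarray) -> float:
    """Euclidean norm of a response vector (its overall activation level)."""
    v = rv.values if isinstance(rv, ResponseVector) else np.asarray(rv, float)
    return float(np.linalg.norm(v))


def response_vector(
    rec: EmgRecording,
    events: EventTable,
    task: TaskId,
    baseline: BaselineProfile | None = None,
    exclusions: frozenset[tuple[TaskId, int, ChannelLabel]] = frozenset(),
) -> ResponseVector:
    """Build the RV for one task: per-repetition RMS, baseline-subtracted
    (floored at 0), averaged over the usable repetitions of each channel.

    A channel whose three repetitions are all excluded raises
    :class:`ExclusionError`.
    """
    if baseline is None:
        baseline = BaselineProfile.zero()
    excluded_reps = {
        (rep, ch) for (t, rep, ch) in exclusions if t == task
    }
    per_rep = {}
    for rep in (1, 2, 3):
        start, end = events.window(task, rep)
        per_rep[rep] = np.asarray(window_rms(rec, start, end))

    values = np.empty(_N)
    n_used = np.empty(_N, dtype=int)
    for i, ch in enumerate(CANONICAL_CHANNELS):
        usable = [rep for rep in (1, 2, 3) if (rep, ch) not in excluded_reps]
        if not usable:
            raise ExclusionError(
                f"channel {ch} has no usable repetition for task {task}"
            )
        corrected = [max(per_rep[rep][i] - baseline.baseline_rms[i], 0.0) for rep in usable]
        values[i] = float(np.mean(corrected))
        n_used[i] = len(usable)
    return ResponseVector(
        values=values,
        task=task,
        subject_id=rec.subject_id,
        side=rec.tested_side(task),
        n_reps_used=n_used,
    )


def prototype_response_vector(
    rvs: list[ResponseVector], pool_sides: bool = True
) -> PrototypeResponseVector:
    """Elementwise mean of reference RVs for one joint.

    With ``pool_sides=True`` (default) left- and right-leg RVs of the same
    joint are pooled after mirroring into the ipsilateral-first layout; with
    ``pool_sides=False`` all RVs must share one physical side.
    """
    if not rvs:
        raise DataError("cannot build a prototype from an empty reference list")
    joints = {rv.task.joint for rv in rvs}
    if len(joints) != 1:
        raise DataError(f"reference RVs span several joints: {sorted(joints)}")
    side: str | None = None
    if not pool_sides:
        sides = {rv.side for rv in rvs}
        if len(sides) != 1:
            raise DataError(f"pool_sides=False but reference RVs span sides {sorted(sides)}")
        side = sides.pop()
    stacked = np.stack([rv.ipsi_first for rv in rvs])
    mean = stacked.mean(axis=0)
    return PrototypeResponseVector(
        values=mean,
        joint=joints.pop(),
        n_reference=len(rvs),
        pooled=pool_sides,
        side=side,
    )


def similarity_index(
    rv: ResponseVector | np.ndarray, prv: PrototypeResponseVector | np.ndarray
) -> float:
    """Cosine similarity between a response vector and the prototype.

    Returns NaN (with a logged warning) for a degenerate all-zero RV — no
    recorded activity is not the same thing as a maximally abnormal pattern.
    """
    v = rv.ipsi_first if isinstance(rv, ResponseVector) else np.asarray(rv, float)
    p = prv.values if isinstance(prv, PrototypeResponseVector) else np.asarray(prv, float)
    pnorm = np.linalg.norm(p)
    if not pnorm > 0:
        raise DegenerateReferenceError("prototype vector has zero magnitude")
    vnorm = np.linalg.norm(v)
    if not vnorm > 0:
        who = rv.subject_id if isinstance(rv, ResponseVector) else "<array>"
        logger.warning("degenerate all-zero response vector (subject %s); SI is undefined", who)
        return float("nan")
    if np.array_equal(v, p):  # self-similarity is 1 exactly, not 1 - 1 ulp
        return 1.0
    si = float(np.dot(v, p) / (vnorm * pnorm))
    return min(max(si, 0.0), 1.0)


@dataclass(frozen=True)
class SiScores:
    """Per-task similarity indices with leg and total aggregates."""

    per_task: dict  # TaskId -> float (NaN = missing)
    leg_means: dict  # leg label -> float
    total_mean: float
    subject_id: str = "anonymous"


def aggregate(
    per_task: dict[TaskId, float],
    subject_id: str = "anonymous",
    min_tasks: int | None = None,
) -> SiScores:
    """Leg means (over 4 joints) and the overall mean (over all 8 tasks).

    Missing (NaN) task scores propagate: by default any missing joint makes
    its leg mean — and the total — missing. ``min_tasks`` relaxes this to
    "average the available scores if at least that many are present"
    (per leg, and 2*min_tasks for the total).
    """
    full = {TaskId(j, leg): float(per_task.get(TaskId(j, leg), np.nan)) for leg in LEGS for j in JOINTS}

    def _mean(vals: list[float], needed: int) -> float:
        ok = [v for v in vals if not np.isnan(v)]
        if min_tasks is None:
            return float(np.mean(vals))  # NaN if any missing
        if len(ok) >= needed:
            return float(np.mean(ok))
        return float("nan")

    leg_means = {
        leg: _mean([full[TaskId(j, leg)] for j in JOINTS], min_tasks or 0) for leg in LEGS
    }
    total = _mean(list(full.values()), 2 * (min_tasks or 0))
    return SiScores(per_task=full, leg_means=leg_means, total_mean=total, subject_id=subject_id)


@dataclass(frozen=True)
class Decomposition:
    """Shares of an RV's squared magnitude by channel group.

    ``target_share`` — the agonist/antagonist pair of the tested joint;
    ``ipsilateral_offtarget_share`` — the other three tested-side muscles
    (co-activation); ``contralateral_share`` — the five opposite-side
    muscles (mirror activity). Shares sum to 1 for a nonzero RV.
    """

    target_share: float
    ipsilateral_offtarget_share: float
    contralateral_share: float
    joint: str
    degenerate: bool = False


def decompose(rv: ResponseVector) -> Decomposition:
    """Attribute the RV's energy to target, co-activation and mirror groups."""
    joint = rv.task.joint
    v = rv.ipsi_first
    total = float(np.dot(v, v))
    if not total > 0:
        logger.warning("degenerate all-zero response vector; decomposition undefined")
        return Decomposition(float("nan"), float("nan"), float("nan"), joint, degenerate=True)
    target_pair = TARGET_MUSCLES[joint]
    # ipsilateral-first layout: entries 0-4 are the tested side in muscle order
    muscle_order = [c.muscle for c in CANONICAL_CHANNELS[:5]]
    tgt_idx = [muscle_order.index(m) for m in target_pair]
    off_idx = [i for i in range(5) if i not in tgt_idx]
    target = float(np.sum(v[tgt_idx] ** 2)) / total
    off = float(np.sum(v[off_idx] ** 2)) / total
    contra = float(np.sum(v[5:] ** 2)) / total
    return Decomposition(target, off, contra, joint)
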