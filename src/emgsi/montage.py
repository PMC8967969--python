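"""Channel montage and task vocabulary.

Ten surface EMG channels are recorded bilaterally from five lower-extremity
muscles: tibialis anterior (TA), peroneus longus (PL), rectus femoris (RF),
gastrocnemius medialis (GM) and semitendinosus (ST). All numeric code in the
package indexes channels in one fixed canonical order (right-side block then
left-side block) so that vectors from different subjects and files are always
comparable position by position.

Tasks are selective single-joint movements (hip, knee, ankle, subtalar) of
one leg; legs are labelled clinically as ``less`` (less affected, or dominant
in unimpaired participants) and ``more`` (more affected / non-dominant). The
physical side a clinical leg label refers to is a per-subject property and is
carried by the recording metadata, not by the task identifier.
"""
from __future__ import annotations

from dataclasses import dataclass

MUSCLES: tuple[str, ...] = ("TA", "PL", "RF", "GM", "ST")
SIDES: tuple[str, ...] = ("r", "l")
JOINTS: tuple[str, ...] = ("hip", "knee", "ankle", "STJ")
LEGS: tuple[str, ...] = ("less", "more")

#: Agonist/antagonist muscle pair held primarily responsible for each joint
#: movement. Used only by the co-activation/mirror decomposition report.
TARGET_MUSCLES: dict[str, tuple[str, str]] = {
    "ankle": ("TA", "GM"),
    "knee": ("RF", "ST"),
    "STJ": ("PL", "TA"),
    "hip": ("RF", "ST"),
}


@dataclass(frozen=True, order=True)
class ChannelLabel:
    """One electrode site: a muscle abbreviation plus a body side."""

    muscle: str
    side: str

    def __post_init__(self) -> None:
        if self.muscle not in MUSCLES:
            raise ValueError(f"unknown muscle {self.muscle!r}; expected one of {MUSCLES}")
        if self.side not in SIDES:
            raise ValueError(f"unknown side {self.side!r}; expected one of {SIDES}")

    def __str__(self) -> str:
        return f"{self.muscle}_{self.side}"

    @classmethod
    def parse(cls, text: str) -> "ChannelLabel":
        parts = text.strip().split("_")
        if len(parts) != 2:
            raise ValueError(f"channel label {text!r} is not of the form MUSCLE_side")
        return cls(parts[0], parts[1])

    @property
    def mirrored(self) -> "ChannelLabel":
        """The homologous channel on the opposite side."""
        return ChannelLabel(self.muscle, "l" if self.side == "r" else "r")


#: Canonical storage order: TA_r, PL_r, RF_r, GM_r, ST_r, TA_l, PL_l, RF_l, GM_l, ST_l.
CANONICAL_CHANNELS: tuple[ChannelLabel, ...] = tuple(
    ChannelLabel(m, s) for s in SIDES for m in MUSCLES
)

CHANNEL_INDEX: dict[ChannelLabel, int] = {c: i for i, c in enumerate(CANONICAL_CHANNELS)}

#: Index permutation that swaps the right and left halves of a canonical vector.
MIRROR_PERMUTATION: tuple[int, ...] = tuple(
    CHANNEL_INDEX[c.mirrored] for c in CANONICAL_CHANNELS
)


@dataclass(frozen=True, order=True)
class TaskId:
    """One selective movement task: a joint and a clinical leg label."""

    joint: str
    leg: str

    def __post_init__(self) -> None:
        if self.joint not in JOINTS:
            raise ValueError(f"unknown joint {self.joint!r}; expected one of {JOINTS}")
        if self.leg not in LEGS:
            raise ValueError(f"unknown leg label {self.leg!r}; expected one of {LEGS}")

    def __str__(self) -> str:
        return f"{self.joint}_{self.leg}"

    @classmethod
    def parse(cls, text: str) -> "TaskId":
        parts = text.strip().rsplit("_", 1)
        if len(parts) != 2:
            raise ValueError(f"task id {text!r} is not of the form joint_leg")
        return cls(parts[0], parts[1])


#: All 8 tasks of one session, in the tested order per leg
#: (knee, ankle, subtalar, hip — chosen to minimise positional changes).
TASK_ORDER_JOINTS: tuple[str, ...] = ("knee", "ankle", "STJ", "hip")
ALL_TASKS: tuple[TaskId, ...] = tuple(
    TaskId(j, leg) for leg in LEGS for j in TASK_ORDER_JOINTS
)


def side_channel_indices(side: str) -> list[int]:
    """Canonical indices of the five channels on one physical side."""
    return [i for i, c in enumerate(CANONICAL_CHANNELS) if c.side == side]
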