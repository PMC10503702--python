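"""Core data containers for behavioural trials and cohorts.

A participant's raw record consists of mirror-game (MG) trials -- horizontal
hand-position traces sampled by a motion sensor whose reported position is in
arbitrary units saturating at +/-0.5 -- and trail-making-task (TMT) click
logs.  Cohort labels are ``CC`` (control cohort) and ``SU`` (service users);
SU participants additionally carry a CAARMS score (0 = neither at-risk nor
psychotic, 2 = at-risk mental state, 4 = first-episode psychosis).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import InvalidArgumentError

POSITION_BOUND = 0.5

#: Canonical feature order (TMT block, Solo block, Leader-Follower block).
FEATURE_NAMES: tuple[str, ...] = (
    "TMT ICT mean",
    "TMT ICT std",
    "TMT ICT median",
    "TMT IoTCT mean",
    "TMT IoTCT std",
    "TMT IoTCT median",
    "S GWS p pf",
    "S GWS p mean",
    "S GWS v pf",
    "S GWS v mean",
    "LF GWS pos. mean",
    "LF GWS pos. 5HZ",
    "LF GWS vel. mean",
    "LF GWS vel. 5HZ",
    "LF RP frequency",
    "LF RP time mean",
    "LF RP time std",
    "LF RP time median",
)

TMT_FEATURES: tuple[str, ...] = FEATURE_NAMES[:6]
SOLO_FEATURES: tuple[str, ...] = FEATURE_NAMES[6:10]
LF_FEATURES: tuple[str, ...] = FEATURE_NAMES[10:18]

FEATURE_GROUPS: dict[str, tuple[str, ...]] = {
    "TMT": TMT_FEATURES,
    "Solo": SOLO_FEATURES,
    "LF": LF_FEATURES,
}


@dataclass
class SampledSeries:
    """A timestamped scalar trace (position in arbitrary units or velocity).

    ``timestamps`` are seconds, strictly increasing; raw position values are
    bounded to [-0.5, 0.5] by the sensor.  ``nominal_rate`` records the
    intended sampling rate in Hz (the actual spacing may jitter around it).
    """

    timestamps: np.ndarray
    values: np.ndarray
    nominal_rate: float

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.timestamps.shape != self.values.shape:
            raise InvalidArgumentError("timestamps and values must have equal length")
        if self.timestamps.ndim != 1:
            raise InvalidArgumentError("series must be one-dimensional")
        if len(self.timestamps) > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise InvalidArgumentError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.timestamps)

    @property
    def duration(self) -> float:
        return float(self.timestamps[-1] - self.timestamps[0]) if len(self) else 0.0

    def copy(self) -> "SampledSeries":
        return SampledSeries(self.timestamps.copy(), self.values.copy(), self.nominal_rate)


@dataclass
class MGTrial:
    """One mirror-game trial: a Solo trace or a leader-follower pair.

    Leader-follower trials carry both the computer-generated leader trace and
    the participant's follower trace, logged on the same raw timestamps.
    """

    participant_id: str
    game_kind: str  # "solo" | "leader_follower"
    session_index: int  # 1..3
    repetition_index: int
    follower_series: SampledSeries
    leader_series: Optional[SampledSeries] = None

    def __post_init__(self) -> None:
        if self.game_kind not in ("solo", "leader_follower"):
            raise InvalidArgumentError(f"unknown game_kind {self.game_kind!r}")
        if (self.leader_series is not None) != (self.game_kind == "leader_follower"):
            raise InvalidArgumentError(
                "leader_series must be present exactly for leader_follower trials"
            )
        if self.session_index not in (1, 2, 3):
            raise InvalidArgumentError("session_index must be 1, 2 or 3")


@dataclass
class TMTClickLog:
    """One trail-making-task run: click times in ms with on-target flags.

    Parts: ``A`` (numbers 1-25 in order) and ``B`` (alternating numbers and
    letters).  Each part has 25 targets and was repeated three times.
    """

    participant_id: str
    part: str  # "A" | "B"
    repetition: int  # 1..3
    click_times_ms: np.ndarray
    on_target: np.ndarray
    n_targets: int = 25

    def __post_init__(self) -> None:
        self.click_times_ms = np.asarray(self.click_times_ms, dtype=float)
        self.on_target = np.asarray(self.on_target, dtype=bool)
        if self.part not in ("A", "B"):
            raise InvalidArgumentError(f"unknown TMT part {self.part!r}")
        if self.repetition not in (1, 2, 3):
            raise InvalidArgumentError("repetition must be 1, 2 or 3")
        if self.click_times_ms.shape != self.on_target.shape:
            raise InvalidArgumentError("click_times and on_target must align")
        if len(self.click_times_ms) > 1 and not np.all(np.diff(self.click_times_ms) > 0):
            raise InvalidArgumentError("click times must be ascending")
        if int(self.on_target.sum()) > self.n_targets:
            raise InvalidArgumentError("more on-target clicks than targets")


@dataclass
class ParticipantRecord:
    """All trials of one participant plus cohort/demographic metadata."""

    id: str
    cohort: str  # "CC" | "SU"
    caarms: Optional[int]  # 0 | 2 | 4 for SU, None (unknown) for CC
    age: float
    sex: str  # "male" | "female"
    mg_trials: list[MGTrial] = field(default_factory=list)
    tmt_logs: list[TMTClickLog] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.cohort not in ("CC", "SU"):
            raise InvalidArgumentError(f"unknown cohort {self.cohort!r}")
        if self.cohort == "CC" and self.caarms is not None:
            raise InvalidArgumentError("CC participants have no CAARMS score")
        if self.cohort == "SU" and self.caarms not in (0, 2, 4):
            raise InvalidArgumentError("SU participants need CAARMS in {0, 2, 4}")

    def solo_trials(self) -> list[MGTrial]:
        return [t for t in self.mg_trials if t.game_kind == "solo"]

    def lf_trials(self) -> list[MGTrial]:
        return [t for t in self.mg_trials if t.game_kind == "leader_follower"]


@dataclass
class CohortDataset:
    """A full two-cohort dataset plus provenance of how it was produced."""

    participants: list[ParticipantRecord]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [p.id for p in self.participants]
        if len(ids) != len(set(ids)):
            raise InvalidArgumentError("participant ids must be unique")

    def by_cohort(self, cohort: str) -> list[ParticipantRecord]:
        return [p for p in self.participants if p.cohort == cohort]


def feature_group_of(name: str) -> str:
    """Task group ("TMT", "Solo" or "LF") a feature belongs to."""
    for group, names in FEATURE_GROUPS.items():
        if name in names:
            return group
    raise InvalidArgumentError(f"unknown feature {name!r}")
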