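"""Health-state space of the Markov model.

States follow the clinical event tree: patients start in the AF baseline
state on their assigned anticoagulant, may switch to ASA (after survivable
bleeds or other treatment discontinuation), pass through a one-cycle drug
holiday after a non-HS intracranial haemorrhage, and settle in post-event
states. SE and MI states are absorbing apart from death; post-stroke states
admit at most one recurrent stroke.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional


class Therapy(str, Enum):
    APIXABAN = "apixaban"
    VKA = "vka"
    ASA = "asa"
    #: Long-term disease-specific maintenance only (post-HS, post-MI).
    NONE = "none"


SEVERITIES = ("mild", "moderate", "severe")


@dataclass(frozen=True)
class State:
    kind: str  # baseline | holiday | post_is | post_hs | post_se | post_mi | dead
    therapy: Optional[Therapy] = None
    severity: Optional[str] = None
    recurrent: bool = False

    @property
    def alive(self) -> bool:
        return self.kind != "dead"

    @property
    def label(self) -> str:
        parts = [self.kind]
        if self.severity:
            parts.append(self.severity)
        if self.recurrent:
            parts.append("recurrent")
        if self.therapy is not None:
            parts.append(self.therapy.value)
        return ":".join(parts)


@dataclass(frozen=True)
class EventKey:
    """Annotation attached to transitions for event tallying."""

    event: str  # is | hs | se | mi | other_ich | other_mb | crnm | discontinuation
    subtype: Optional[str] = None  # severity for strokes, gi/non_gi for other MB
    fatal: bool = False
    recurrent: bool = False

    @property
    def label(self) -> str:
        parts = [self.event]
        if self.subtype:
            parts.append(self.subtype)
        parts.append("fatal" if self.fatal else "nonfatal")
        if self.recurrent:
            parts.append("recurrent")
        return ":".join(parts)


def all_event_keys() -> list[EventKey]:
    """Canonical ordering of every event annotation the engine can emit."""
    keys: list[EventKey] = []
    for ev in ("is", "hs"):
        for rec in (False, True):
            for sev in SEVERITIES:
                keys.append(EventKey(ev, sev, False, rec))
            keys.append(EventKey(ev, None, True, rec))
    for ev in ("se", "mi", "other_ich"):
        keys.append(EventKey(ev, None, False))
        keys.append(EventKey(ev, None, True))
    keys.append(EventKey("other_mb", "gi", False))
    keys.append(EventKey("other_mb", "non_gi", False))
    keys.append(EventKey("other_mb", None, True))
    keys.append(EventKey("crnm", None, False))
    keys.append(EventKey("crnm", None, True))
    keys.append(EventKey("discontinuation", None, False))
    return keys


class StateSpace:
    """Enumerated states for one treatment arm, with index lookups."""

    def __init__(self, arm: Therapy):
        if arm not in (Therapy.APIXABAN, Therapy.VKA, Therapy.ASA):
            raise ValueError(f"arm must be an active therapy, got {arm}")
        self.arm = arm
        therapies = [arm, Therapy.ASA] if arm != Therapy.ASA else [Therapy.ASA]
        states: list[State] = []
        for th in therapies:
            states.append(State("baseline", th))
        for th in therapies:
            states.append(State("holiday", th))
        for th in therapies:
            for rec in (False, True):
                for sev in SEVERITIES:
                    states.append(State("post_is", th, sev, rec))
        for rec in (False, True):
            for sev in SEVERITIES:
                states.append(State("post_hs", Therapy.NONE, sev, rec))
        for th in therapies:
            states.append(State("post_se", th))
        states.append(State("post_mi", Therapy.NONE))
        states.append(State("dead"))
        self.states = states
        self.index = {s: i for i, s in enumerate(states)}
        self.dead_index = self.index[State("dead")]
        self.entry_index = self.index[State("baseline", arm)]

    def __len__(self) -> int:
        return len(self.states)

    def __getitem__(self, i: int) -> State:
        return self.states[i]

    def idx(self, state: State) -> int:
        return self.index[state]
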