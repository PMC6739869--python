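"""Per-session behavioral measures from trial-level event logs.

A Pavlovian conditioned approach (PavCA) session is a sequence of trials in
which an 8-s lever conditioned stimulus (CS) precedes response-independent
food delivery into a magazine. Each trial carries timestamped lever contacts
and magazine entries; this module reduces them to the six session measures
the composite PavCA index is built from — lever/magazine counts, per-trial
response probabilities, and mean latencies — plus the intertrial-interval
(ITI) magazine-entry count used as a general-activity index.

Conventions (documented because the scores depend on them):

* A trial with no response to a target is *censored* at the full CS duration:
  its latency contributes ``cs_duration`` (8 s by default) to the mean. This
  is what lets the latency-difference component span the full [-1, +1] range.
* Response probability is the fraction of trials with >= 1 target event, not
  an event count.
* The CS window is half-open, ``[cs_on, cs_off)``: a magazine entry exactly
  at CS offset belongs to the ITI.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

__all__ = [
    "TrialRecord",
    "SessionSummary",
    "trial_latency",
    "summarize_session",
    "iti_activity",
]

Phase = Literal["pretrain", "acquisition", "rescreen", "test"]


@dataclass(frozen=True)
class TrialRecord:
    """One CS trial: window timings plus timestamped events.

    Timestamps are seconds from session start. ``lever_events`` must lie in
    the CS window (the lever is retracted otherwise); ``mag_events_cs`` holds
    magazine entries inside ``[cs_on_s, cs_off_s)`` and ``mag_events_iti``
    those outside it.
    """

    rat_id: str
    phase: str
    session: int
    trial: int
    cs_on_s: float
    cs_off_s: float
    lever_events: tuple[float, ...] = ()
    mag_events_cs: tuple[float, ...] = ()
    mag_events_iti: tuple[float, ...] = ()
    pellet_retrieved: bool = True

    def __post_init__(self) -> None:
        if self.cs_off_s <= self.cs_on_s:
            raise ValueError(
                f"CS offset {self.cs_off_s} not after onset {self.cs_on_s} "
                f"(rat {self.rat_id}, session {self.session}, trial {self.trial})"
            )
        for t in self.lever_events:
            if not (self.cs_on_s <= t < self.cs_off_s):
                raise ValueError(
                    f"lever event at {t} s outside CS window "
                    f"[{self.cs_on_s}, {self.cs_off_s}) (rat {self.rat_id}, "
                    f"session {self.session}, trial {self.trial})"
                )
        for t in self.mag_events_cs:
            if not (self.cs_on_s <= t < self.cs_off_s):
                raise ValueError(
                    f"CS magazine event at {t} s outside CS window "
                    f"(rat {self.rat_id}, session {self.session}, trial {self.trial})"
                )

    @property
    def cs_duration_s(self) -> float:
        return self.cs_off_s - self.cs_on_s


@dataclass(frozen=True)
class SessionSummary:
    """The six PavCA measures plus the ITI activity count for one rat-session."""

    rat_id: str
    phase: str
    session: int
    lever_contacts: int
    mag_entries_cs: int
    prob_lever: float
    prob_mag: float
    lat_lever_s: float
    lat_mag_s: float
    iti_mag_entries: int
    n_trials: int
    cs_duration_s: float = 8.0


def trial_latency(trial: TrialRecord, target: str) -> float:
    """First-response latency to ``target`` ("lever" or "magazine"), in seconds.

    Returns ``first event - cs_on``; a trial without a target response is
    censored at the CS duration.
    """
    if target == "lever":
        events = trial.lever_events
    elif target == "magazine":
        events = trial.mag_events_cs
    else:
        raise ValueError(f"unknown latency target {target!r}")
    if not events:
        return trial.cs_duration_s
    return min(events) - trial.cs_on_s


def summarize_session(trials: Sequence[TrialRecord]) -> SessionSummary:
    """Reduce one rat-session's trials to the six PavCA measures.

    Counts are summed over trials, probabilities are fractions of trials with
    at least one target event, latencies are means of per-trial latencies
    with non-responding trials contributing the full CS duration.
    """
    trials = list(trials)
    if not trials:
        raise ValueError("cannot summarize an empty trial list")
    keys = {(t.rat_id, t.phase, t.session) for t in trials}
    if len(keys) > 1:
        raise ValueError(f"trials mix rat/phase/session keys: {sorted(keys)}")
    rat_id, phase, session = keys.pop()
    durations = {round(t.cs_duration_s, 6) for t in trials}
    if len(durations) > 1:
        raise ValueError(f"trials mix CS durations: {sorted(durations)}")
    cs_duration = durations.pop()

    n = len(trials)
    lever_contacts = sum(len(t.lever_events) for t in trials)
    mag_entries_cs = sum(len(t.mag_events_cs) for t in trials)
    prob_lever = sum(bool(t.lever_events) for t in trials) / n
    prob_mag = sum(bool(t.mag_events_cs) for t in trials) / n
    # censored latencies equal each trial's own cs_duration_s, which can sit a
    # few ulp above the rounded session duration; clamp so means stay in range.
    # fsum makes the means exact, hence invariant to trial order
    lat_lever = math.fsum(min(trial_latency(t, "lever"), cs_duration) for t in trials) / n
    lat_mag = math.fsum(min(trial_latency(t, "magazine"), cs_duration) for t in trials) / n
    iti_entries = sum(len(t.mag_events_iti) for t in trials)

    return SessionSummary(
        rat_id=rat_id,
        phase=phase,
        session=session,
        lever_contacts=lever_contacts,
        mag_entries_cs=mag_entries_cs,
        prob_lever=prob_lever,
        prob_mag=prob_mag,
        lat_lever_s=lat_lever,
        lat_mag_s=lat_mag,
        iti_mag_entries=iti_entries,
        n_trials=n,
        cs_duration_s=cs_duration,
    )


def iti_activity(summaries: Iterable[SessionSummary]) -> float:
    """Mean ITI magazine entries per session over a window of sessions."""
    counts = [s.iti_mag_entries for s in summaries]
    if not counts:
        raise ValueError("no sessions in window")
    return sum(counts) / len(counts)
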