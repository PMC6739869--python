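"""Conditioned-reinforcement test (CRT) scoring.

In a CRT session the food magazine is removed; nose pokes into the active
port earn a brief (2-s) lever-CS presentation on a fixed-ratio-1 schedule
while pokes into the inactive port do nothing. A cue with conditioned
reinforcing value supports more active than inactive responding, and a cue
with incentive value additionally attracts contacts during its presentation.
The single summary statistic is the incentive value index:

    (active pokes + lever contacts) - inactive pokes

Presentations are reconstructed under the FR1 rule with a 2-s refractory
period: a poke that lands during an ongoing presentation still counts as an
active poke but does not retrigger the lever.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["CRTSummary", "incentive_value_index", "summarize_crt"]

PRESENTATION_S = 2.0


@dataclass(frozen=True)
class CRTSummary:
    """Event counts and the incentive value index for one CRT session."""

    rat_id: str
    active_pokes: int
    inactive_pokes: int
    lever_contacts: int
    presentations: int
    incentive_value_index: int


def incentive_value_index(active: int, inactive: int, lever: int) -> int:
    """(active pokes + lever contacts) - inactive pokes; may be negative."""
    if min(active, inactive, lever) < 0:
        raise ValueError("event counts must be non-negative")
    return (active + lever) - inactive


def summarize_crt(
    events: pd.DataFrame,
    rat_id: str = "",
    session_duration_s: float = 2400.0,
    presentation_s: float = PRESENTATION_S,
) -> CRTSummary:
    """Tally a CRT event log and reconstruct FR1 lever presentations.

    ``events`` needs columns ``event_type`` (active_poke, inactive_poke,
    lever_contact) and ``time_s``; rows must fall inside the session bounds.
    A presentation is credited to an active poke only when no presentation is
    ongoing (2-s refractory window).
    """
    if events.empty:
        return CRTSummary(rat_id, 0, 0, 0, 0, 0)
    if (events["time_s"] < 0).any() or (events["time_s"] > session_duration_s).any():
        bad = events.loc[
            (events["time_s"] < 0) | (events["time_s"] > session_duration_s), "time_s"
        ]
        raise ValueError(
            f"{len(bad)} event(s) outside session bounds [0, {session_duration_s}] "
            f"(first at {bad.iloc[0]} s)"
        )
    counts = events["event_type"].value_counts()
    active = int(counts.get("active_poke", 0))
    inactive = int(counts.get("inactive_poke", 0))
    lever = int(counts.get("lever_contact", 0))

    poke_times = events.loc[events["event_type"] == "active_poke", "time_s"].sort_values()
    presentations = 0
    pres_end = float("-inf")
    for t in poke_times:
        if t >= pres_end:
            presentations += 1
            pres_end = t + presentation_s

    return CRTSummary(
        rat_id=rat_id,
        active_pokes=active,
        inactive_pokes=inactive,
        lever_contacts=lever,
        presentations=presentations,
        incentive_value_index=incentive_value_index(active, inactive, lever),
    )
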