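"""PavCA composite index, phenotype classification, counterbalanced assignment.

The PavCA index summarizes whether a rat's conditioned response is directed
at the lever CS (sign-tracking) or at the food magazine (goal-tracking). It
is the unweighted mean of three components, each in [-1, +1]:

* response bias      (L - M) / (L + M)          over session event counts
* probability diff   P(lever) - P(magazine)     per-trial response fractions
* latency diff       -(lat_lever - lat_mag) / cs_duration

+1 is an extreme sign-tracker (every response at the lever, zero latency),
-1 an extreme goal-tracker. Phenotypes are called from a window mean:
classification regime ``exp1`` averages sessions 4-5 with thresholds at
+/-0.30; regime ``exp2`` uses session 3 alone with thresholds at +/-0.20
(conditioning is not asymptotic by session 3, hence the narrower band).
Thresholds are inclusive. Rats between the thresholds are intermediates (IN)
and are flagged for exclusion.

A session with zero CS-period responses leaves the response bias 0/0; it is
substituted with 0 and the score is flagged ``defined=False`` rather than
dropped, so the audit trail survives.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .metrics import SessionSummary

__all__ = [
    "PavCAScore",
    "PhenotypeCall",
    "CLASSIFICATION_REGIMES",
    "response_bias",
    "probability_difference",
    "latency_difference",
    "pavca_index",
    "classify",
    "assign_groups",
]


@dataclass(frozen=True)
class PavCAScore:
    """Component scores and composite index for one rat-session."""

    rat_id: str
    phase: str
    session: int
    response_bias: float
    prob_diff: float
    latency_diff: float
    index: float
    defined: bool = True


@dataclass(frozen=True)
class PhenotypeCall:
    """A rat's phenotype call from its classification-window mean index."""

    rat_id: str
    window_sessions: tuple[int, ...]
    mean_index: float
    call: str  # ST | GT | IN
    regime: str
    excluded: bool  # True for IN calls (exclusion band)


#: regime -> (window sessions, inclusive threshold)
CLASSIFICATION_REGIMES: dict[str, tuple[tuple[int, ...], float]] = {
    "exp1": ((4, 5), 0.30),
    "exp2": ((3,), 0.20),
}


def response_bias(lever_contacts: int, mag_entries_cs: int) -> tuple[float, bool]:
    """(L - M) / (L + M) with a flagged 0 substituted when no responses occurred.

    Returns ``(value, defined)``; ``defined`` is False only for the 0/0 case.
    """
    if lever_contacts < 0 or mag_entries_cs < 0:
        raise ValueError("event counts must be non-negative")
    total = lever_contacts + mag_entries_cs
    if total == 0:
        return 0.0, False
    return (lever_contacts - mag_entries_cs) / total, True


def probability_difference(prob_lever: float, prob_mag: float) -> float:
    """P(lever) - P(magazine); inputs are per-trial response fractions."""
    for p in (prob_lever, prob_mag):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"probability {p} outside [0, 1]")
    return prob_lever - prob_mag


def latency_difference(
    lat_lever_s: float, lat_mag_s: float, cs_duration_s: float = 8.0
) -> float:
    """-(lat_lever - lat_mag) / cs_duration, so faster lever approach is positive."""
    if cs_duration_s <= 0:
        raise ValueError("cs_duration_s must be positive")
    for lat in (lat_lever_s, lat_mag_s):
        if not 0.0 <= lat <= cs_duration_s:
            raise ValueError(f"latency {lat} outside [0, {cs_duration_s}]")
    return -(lat_lever_s - lat_mag_s) / cs_duration_s


def pavca_index(summary: SessionSummary) -> PavCAScore:
    """Composite PavCA index for one session: mean of the three components."""
    bias, defined = response_bias(summary.lever_contacts, summary.mag_entries_cs)
    pdiff = probability_difference(summary.prob_lever, summary.prob_mag)
    ldiff = latency_difference(
        summary.lat_lever_s, summary.lat_mag_s, summary.cs_duration_s
    )
    return PavCAScore(
        rat_id=summary.rat_id,
        phase=summary.phase,
        session=summary.session,
        response_bias=bias,
        prob_diff=pdiff,
        latency_diff=ldiff,
        index=(bias + pdiff + ldiff) / 3.0,
        defined=defined,
    )


def classify(
    session_indices: Mapping[int, float], regime: str = "exp1", rat_id: str = ""
) -> PhenotypeCall:
    """Call ST/GT/IN from the regime's window mean with inclusive thresholds.

    ``session_indices`` maps session number -> PavCA index for that session;
    all of the regime's window sessions must be present.
    """
    try:
        window, threshold = CLASSIFICATION_REGIMES[regime]
    except KeyError:
        raise ValueError(
            f"unknown regime {regime!r}; expected one of {sorted(CLASSIFICATION_REGIMES)}"
        ) from None
    missing = [s for s in window if s not in session_indices]
    if missing:
        raise ValueError(f"missing classification-window sessions {missing} for rat {rat_id!r}")
    mean_index = sum(session_indices[s] for s in window) / len(window)
    if mean_index >= threshold:
        call = "ST"
    elif mean_index <= -threshold:
        call = "GT"
    else:
        call = "IN"
    return PhenotypeCall(
        rat_id=rat_id,
        window_sessions=window,
        mean_index=mean_index,
        call=call,
        regime=regime,
        excluded=(call == "IN"),
    )


def classify_table(scores: pd.DataFrame, regime: str = "exp1") -> pd.DataFrame:
    """Vectorized :func:`classify` over a per-session score table.

    ``scores`` needs columns ``rat_id``, ``session``, ``index``. Returns one
    row per rat: mean window index, call, and the exclusion flag.
    """
    calls = []
    for rat_id, grp in scores.groupby("rat_id", sort=True):
        call = classify(
            dict(zip(grp["session"], grp["index"])), regime=regime, rat_id=str(rat_id)
        )
        calls.append(
            {
                "rat_id": call.rat_id,
                "mean_index": call.mean_index,
                "call": call.call,
                "regime": call.regime,
                "excluded": call.excluded,
            }
        )
    return pd.DataFrame(calls)


def assign_groups(
    calls: Sequence[PhenotypeCall],
    arms: Sequence[str],
    seed: int = 0,
    include_intermediates: bool = False,
) -> pd.DataFrame:
    """Counterbalance rats into treatment arms, matched on mean PavCA index.

    Within each phenotype, rats are sorted by mean index (seeded random
    tie-break) and dealt round-robin into the arms, so arm-wise mean indices
    are matched by construction. IN rats are left out unless
    ``include_intermediates``. A phenotype with fewer rats than arms is
    assigned as far as possible.
    """
    if not arms:
        raise ValueError("arms must be nonempty")
    rng = np.random.default_rng(seed)
    rows = []
    kept = [c for c in calls if include_intermediates or not c.excluded]
    by_pheno: dict[str, list[PhenotypeCall]] = {}
    for c in kept:
        by_pheno.setdefault(c.call, []).append(c)
    for pheno in sorted(by_pheno):
        group = by_pheno[pheno]
        jitter = rng.random(len(group))  # tie-break only
        order = sorted(
            range(len(group)), key=lambda i: (-group[i].mean_index, jitter[i])
        )
        for rank, i in enumerate(order):
            rows.append(
                {
                    "rat_id": group[i].rat_id,
                    "phenotype": pheno,
                    "mean_index": group[i].mean_index,
                    "arm": arms[rank % len(arms)],
                }
            )
    return pd.DataFrame(rows, columns=["rat_id", "phenotype", "mean_index", "arm"])


def phenotype_change_audit(
    acquisition_calls: Iterable[PhenotypeCall],
    rescreen_calls: Iterable[PhenotypeCall],
) -> pd.DataFrame:
    """Flag rats whose rescreen phenotype differs from their acquisition call.

    Returns a table with both calls and a ``changed`` flag; exclusion is left
    to the caller (a pipeline config switch), the audit only reports.
    """
    acq = {c.rat_id: c for c in acquisition_calls}
    res = {c.rat_id: c for c in rescreen_calls}
    rows = []
    for rat_id in sorted(set(acq) & set(res)):
        rows.append(
            {
                "rat_id": rat_id,
                "acquisition_call": acq[rat_id].call,
                "rescreen_call": res[rat_id].call,
                "changed": acq[rat_id].call != res[rat_id].call,
            }
        )
    return pd.DataFrame(
        rows, columns=["rat_id", "acquisition_call", "rescreen_call", "changed"]
    )
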