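"""Agent-based generator of PavCA, conditioned-reinforcement and microdialysis data.

Real sign-tracker/goal-tracker experiments cannot be redistributed, so this
module simulates cohorts with the statistical structure the analysis stack
assumes. Each rat is a minimal latent-bias agent: a single parameter
``theta`` in [-1, 1] governs how CS-period responses are allocated between
lever and magazine (lever with probability ``(1 + theta) / 2``). Across
sessions theta drifts geometrically toward a phenotype asymptote
(sign-trackers +0.6, goal-trackers -0.6, intermediates 0), and a treatment
can shift theta additively from a given session onward — the effect the
downstream interaction test must detect.

Session structure follows the standard task: 25 trials, each an intertrial
interval drawn uniformly on a variable-time schedule (VT-90 s, range
30-150 s by default) followed by an 8-s lever CS and response-independent
pellet delivery. On each trial the agent responds with probability
``respond_prob``; a responding trial gets one or more timestamped events at
the chosen target with a first-event latency drawn from an exponential of
scale ``lat_scale_s`` truncated to the CS window. ITI magazine entries are
Poisson per trial. Conditioned-reinforcement (CRT) sessions are Poisson nose
pokes on an FR1 schedule with a 2-s non-retriggering lever presentation.
Microdialysis series couple the dopamine channel linearly to the realized
PavCA index with Gaussian noise; other analytes carry no coupling.

Reproducibility: one seed per cohort; each rat gets an independent substream
keyed by a stable hash of its rat id, so adding rats to a design never
perturbs the data of existing ones.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .metrics import TrialRecord

__all__ = [
    "TrialConfig",
    "AgentParams",
    "CohortDesign",
    "PHENOTYPE_ASYMPTOTES",
    "make_agent",
    "theta_at_session",
    "simulate_pavca_session",
    "simulate_cohort",
    "simulate_crt_events",
    "simulate_crt_session",
    "simulate_dialysis_series",
    "expected_session_duration_min",
    "rat_rng",
]

ANALYTES = ("DA", "ACh", "GABA", "Glu", "5-HT")

#: fractions per phase of a complete dialysis series (5-min bins)
DIALYSIS_SCHEDULE = {"baseline": 6, "pre": 5, "session": 7}

PHENOTYPE_ASYMPTOTES = {"ST": 0.6, "GT": -0.6, "IN": 0.0}


@dataclass(frozen=True)
class TrialConfig:
    """Trial structure of one PavCA session (defaults: the standard task)."""

    n_trials: int = 25
    cs_duration_s: float = 8.0
    iti_mean_s: float = 90.0
    iti_range_s: tuple[float, float] = (30.0, 150.0)

    def __post_init__(self) -> None:
        lo, hi = self.iti_range_s
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.cs_duration_s <= 0:
            raise ValueError("cs_duration_s must be positive")
        if not lo <= self.iti_mean_s <= hi:
            raise ValueError(f"iti_mean_s {self.iti_mean_s} outside range {self.iti_range_s}")


@dataclass(frozen=True)
class AgentParams:
    """Latent parameters of one simulated rat.

    ``theta0`` is the starting lever bias; each session it moves a fraction
    ``learn_rate`` of the remaining distance toward ``theta_asym`` (the
    phenotype asymptote). ``treat_shift`` is added to theta from the first
    treated session onward; theta is clamped to [-1, 1] after all shifts.
    """

    rat_id: str
    phenotype_truth: str  # ST | GT | IN
    theta0: float
    theta_asym: float
    learn_rate: float = 0.5
    treat_shift: float = 0.0
    respond_prob: float = 0.9
    lat_scale_s: float = 2.0
    iti_rate: float = 2.0
    da_base_nM: float = 1.0
    da_coupling: float = 50.0
    da_noise_sd: float = 5.0

    def __post_init__(self) -> None:
        if not -1.0 <= self.theta0 <= 1.0:
            raise ValueError("theta0 must be in [-1, 1]")
        if not -2.0 <= self.treat_shift <= 2.0:
            raise ValueError("treat_shift must be in [-2, 2]")
        if self.learn_rate < 0:
            raise ValueError("learn_rate must be >= 0")
        if not 0.0 <= self.respond_prob <= 1.0:
            raise ValueError("respond_prob must be in [0, 1]")
        if self.lat_scale_s <= 0:
            raise ValueError("lat_scale_s must be positive")
        if self.iti_rate < 0 or self.da_base_nM <= 0 or self.da_noise_sd < 0:
            raise ValueError("iti_rate >= 0, da_base_nM > 0, da_noise_sd >= 0 required")


@dataclass(frozen=True)
class CohortDesign:
    """A phenotype x treatment cohort layout with its session timeline.

    Session ranges are inclusive (start, end) pairs and must be disjoint and
    ordered; treatment arms receive their theta shift from
    ``treatment_onset_session`` onward. ``treat_shifts`` maps phenotype ->
    additive theta shift for treated rats (0 for a null cohort).
    """

    n_per_cell: int
    sessions_acquisition: tuple[int, int] = (1, 5)
    sessions_rescreen: tuple[int, int] = (6, 10)
    sessions_test: tuple[int, int] = (11, 16)
    treatment_onset_session: int = 11
    seed: int = 0
    trial_config: TrialConfig = field(default_factory=TrialConfig)
    phenotypes: tuple[str, ...] = ("ST", "GT")
    treatments: tuple[str, ...] = ("VEH", "CNO")
    treat_shifts: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ranges = [
            r
            for r in (self.sessions_acquisition, self.sessions_rescreen, self.sessions_test)
            if r is not None
        ]
        last_end = 0
        for lo, hi in ranges:
            if lo > hi:
                raise ValueError(f"session range ({lo}, {hi}) is inverted")
            if lo <= last_end:
                raise ValueError("session ranges must be disjoint and ordered")
            last_end = hi
        if self.n_per_cell < 1:
            raise ValueError("n_per_cell must be >= 1")
        for p in self.phenotypes:
            if p not in PHENOTYPE_ASYMPTOTES:
                raise ValueError(f"unknown phenotype {p!r}")

    @property
    def phases(self) -> dict[str, tuple[int, int]]:
        out = {}
        for name, rng in (
            ("acquisition", self.sessions_acquisition),
            ("rescreen", self.sessions_rescreen),
            ("test", self.sessions_test),
        ):
            if rng is not None:
                out[name] = rng
        return out

    def phase_of(self, session: int) -> str:
        for name, (lo, hi) in self.phases.items():
            if lo <= session <= hi:
                return name
        raise ValueError(f"session {session} outside all phase ranges")

    def all_sessions(self) -> list[int]:
        return [s for lo, hi in self.phases.values() for s in range(lo, hi + 1)]


def _stable_hash(text: str) -> int:
    """Stable 32-bit hash of a string (independent of PYTHONHASHSEED)."""
    return int.from_bytes(hashlib.blake2s(text.encode()).digest()[:4], "little")


def rat_rng(cohort_seed: int, rat_id: str) -> np.random.Generator:
    """Per-rat RNG substream: adding rats never perturbs existing ones."""
    return np.random.default_rng(
        np.random.SeedSequence([cohort_seed & 0x7FFFFFFF, _stable_hash(rat_id)])
    )


def make_agent(phenotype: str, seed: int, rat_id: str | None = None, **overrides) -> AgentParams:
    """Build an agent whose asymptotic measured index lands in the phenotype band.

    Deterministic for a fixed seed: only ``theta0`` and ``iti_rate`` carry
    seeded jitter; the theta asymptote is the phenotype constant
    (ST +0.6, GT -0.6, IN 0.0) unless overridden.
    """
    if phenotype not in PHENOTYPE_ASYMPTOTES:
        raise ValueError(f"unknown phenotype {phenotype!r}; expected ST, GT or IN")
    rng = np.random.default_rng(seed)
    params = dict(
        rat_id=rat_id if rat_id is not None else f"{phenotype}_{seed}",
        phenotype_truth=phenotype,
        theta0=float(rng.uniform(-0.2, 0.2)),
        theta_asym=PHENOTYPE_ASYMPTOTES[phenotype],
        iti_rate=float(rng.uniform(1.0, 3.0)),
    )
    params.update(overrides)
    return AgentParams(**params)


def theta_at_session(agent: AgentParams, session: int, treated: bool = False) -> float:
    """Latent lever bias at a session: geometric approach to the asymptote.

    ``theta_s = asym + (theta0 - asym) * (1 - learn_rate)^(s-1)``, plus
    ``treat_shift`` when ``treated``, clamped to [-1, 1].
    """
    if session < 1:
        raise ValueError("session must be >= 1")
    resid = (1.0 - min(agent.learn_rate, 1.0)) ** (session - 1)
    theta = agent.theta_asym + (agent.theta0 - agent.theta_asym) * resid
    if treated:
        theta += agent.treat_shift
    return float(np.clip(theta, -1.0, 1.0))


def _truncated_exp(rng: np.random.Generator, scale: float, upper: float, size: int) -> np.ndarray:
    """Exponential(scale) truncated to [0, upper) by inverse-CDF sampling."""
    u = rng.random(size)
    cap = 1.0 - np.exp(-upper / scale)
    return -scale * np.log1p(-u * cap)


def simulate_pavca_session(
    agent: AgentParams,
    session: int,
    cfg: TrialConfig | None = None,
    rng: np.random.Generator | None = None,
    treated: bool = False,
    phase: str = "acquisition",
) -> list[TrialRecord]:
    """Simulate one PavCA session: returns ``cfg.n_trials`` trial records.

    Each trial draws its ITI uniformly on ``cfg.iti_range_s``; during the CS
    the agent responds with probability ``respond_prob``, allocating the
    response to the lever with probability ``(1 + theta) / 2``. Responding
    trials get 1 + Poisson(0.5) events at the chosen target, the first at an
    exponential latency truncated to the CS window. ITI magazine entries are
    Poisson(``iti_rate``) per trial and the pellet is always retrieved.
    """
    cfg = cfg or TrialConfig()
    rng = rng if rng is not None else np.random.default_rng(0)
    theta = theta_at_session(agent, session, treated=treated)
    p_lever = (1.0 + theta) / 2.0

    lo, hi = cfg.iti_range_s
    itis = rng.uniform(lo, hi, cfg.n_trials)
    responds = rng.random(cfg.n_trials) < agent.respond_prob
    to_lever = rng.random(cfg.n_trials) < p_lever
    latencies = _truncated_exp(rng, agent.lat_scale_s, cfg.cs_duration_s, cfg.n_trials)
    n_extra = rng.poisson(0.5, cfg.n_trials)
    n_iti_entries = rng.poisson(agent.iti_rate, cfg.n_trials)

    # offsets are rounded to ms and kept strictly inside the CS window
    max_off = cfg.cs_duration_s - 1e-3

    trials: list[TrialRecord] = []
    t = 0.0
    for i in range(cfg.n_trials):
        iti_events = tuple(
            round(e, 3) for e in np.sort(rng.uniform(t, t + itis[i], n_iti_entries[i]))
        )
        t += itis[i]
        cs_on = round(t, 3)
        cs_off = round(cs_on + cfg.cs_duration_s, 3)
        lever: tuple[float, ...] = ()
        mag_cs: tuple[float, ...] = ()
        if responds[i]:
            first = min(round(latencies[i], 3), max_off)
            extras = rng.uniform(latencies[i], cfg.cs_duration_s, n_extra[i])
            offsets = sorted([first] + [min(round(e, 3), max_off) for e in extras])
            # round absolute times so they survive text round trips bit-exactly
            events = tuple(round(cs_on + off, 3) for off in offsets)
            if to_lever[i]:
                lever = events
            else:
                mag_cs = events
        t = cs_off
        trials.append(
            TrialRecord(
                rat_id=agent.rat_id,
                phase=phase,
                session=session,
                trial=i + 1,
                cs_on_s=cs_on,
                cs_off_s=cs_off,
                lever_events=lever,
                mag_events_cs=mag_cs,
                mag_events_iti=iti_events,
                pellet_retrieved=True,
            )
        )
    return trials


def simulate_cohort(
    design: CohortDesign,
) -> tuple[list[TrialRecord], pd.DataFrame]:
    """Simulate every rat x session of a cohort design.

    Returns the full trial-record list plus a ground-truth table with one row
    per rat-session: phenotype, treatment arm, and the session's latent theta.
    Treated rats receive their phenotype's ``treat_shifts`` entry from
    ``treatment_onset_session`` onward. Byte-identical for a fixed design.
    """
    trials: list[TrialRecord] = []
    truth_rows = []
    for pheno in design.phenotypes:
        for arm in design.treatments:
            for k in range(design.n_per_cell):
                rat_id = f"{pheno}-{arm}-{k:03d}"
                rng = rat_rng(design.seed, rat_id)
                agent = make_agent(
                    pheno,
                    seed=int(rng.integers(0, 2**31 - 1)),
                    rat_id=rat_id,
                    treat_shift=float(design.treat_shifts.get(pheno, 0.0)),
                )
                is_treated_arm = arm != design.treatments[0]
                for session in design.all_sessions():
                    treated = is_treated_arm and session >= design.treatment_onset_session
                    phase = design.phase_of(session)
                    trials.extend(
                        simulate_pavca_session(
                            agent,
                            session,
                            design.trial_config,
                            rng=rng,
                            treated=treated,
                            phase=phase,
                        )
                    )
                    truth_rows.append(
                        {
                            "rat_id": rat_id,
                            "phenotype_truth": pheno,
                            "treatment": arm,
                            "session": session,
                            "phase": phase,
                            "theta": theta_at_session(agent, session, treated=treated),
                            "treated_session": treated,
                        }
                    )
    return trials, pd.DataFrame(truth_rows)


def simulate_crt_events(
    duration_s: float,
    active_rate_hz: float,
    inactive_rate_hz: float,
    p_contact: float,
    rng: np.random.Generator,
    presentation_s: float = 2.0,
) -> pd.DataFrame:
    """Low-level CRT event generator (event_type, time_s), time-sorted.

    Active-port pokes are a Poisson process; each poke outside an ongoing
    lever presentation triggers a ``presentation_s`` presentation (FR1, no
    retrigger), during which a lever contact occurs with probability
    ``p_contact`` at a uniform time. Inactive pokes are an independent
    Poisson process.
    """
    if duration_s < 0:
        raise ValueError("duration_s must be >= 0")
    rows: list[tuple[str, float]] = []

    def poisson_times(rate_hz: float) -> np.ndarray:
        if rate_hz <= 0 or duration_s == 0:
            return np.empty(0)
        n = rng.poisson(rate_hz * duration_s)
        return np.sort(rng.uniform(0.0, duration_s, n))

    active = poisson_times(active_rate_hz)
    inactive = poisson_times(inactive_rate_hz)
    rows += [("active_poke", float(t)) for t in active]
    rows += [("inactive_poke", float(t)) for t in inactive]

    # FR1 presentation reconstruction with the 2-s refractory rule
    pres_end = -np.inf
    for t in active:
        if t >= pres_end:
            pres_end = t + presentation_s
            if rng.random() < p_contact:
                contact = float(rng.uniform(t, min(pres_end, duration_s)))
                rows.append(("lever_contact", contact))

    df = pd.DataFrame(rows, columns=["event_type", "time_s"])
    return df.sort_values("time_s", kind="stable").reset_index(drop=True)


def simulate_crt_session(
    agent: AgentParams,
    duration_s: float = 2400.0,
    rng: np.random.Generator | None = None,
    theta: float | None = None,
) -> pd.DataFrame:
    """CRT session for an agent: poke rates and contact probability from theta.

    Active-poke rate rises with ``max(theta, 0)`` (only cue-attracted rats
    work for lever presentations above a floor rate); lever contacts within
    presentations become likelier with theta; inactive pokes are a low
    phenotype-independent rate.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    if theta is None:
        theta = theta_at_session(agent, session=6)
    base_per_min, gain_per_min = 0.5, 1.5
    active_rate = (base_per_min + gain_per_min * max(theta, 0.0)) / 60.0
    inactive_rate = 0.25 / 60.0
    p_contact = float(np.clip(0.5 + 0.5 * theta, 0.0, 1.0))
    return simulate_crt_events(duration_s, active_rate, inactive_rate, p_contact, rng)


def simulate_dialysis_series(
    agent: AgentParams,
    realized_index: float,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Microdialysis fraction table for one rat: 6 baseline + 5 pre + 7 session.

    Every fraction of every analyte carries multiplicative noise
    ``conc = base * (1 + (coupling_i * index + eps) / 100)`` with
    ``eps ~ Normal(0, da_noise_sd)``; the coupling term is nonzero only for
    dopamine during in-session fractions, so the other analytes and phases
    are pure noise around baseline. Columns: rat_id, analyte, fraction,
    phase, minutes, conc_nM.
    """
    if not -1.0 <= realized_index <= 1.0:
        raise ValueError("realized_index must be in [-1, 1]")
    rng = rng if rng is not None else np.random.default_rng(0)
    rows = []
    for analyte in ANALYTES:
        base = agent.da_base_nM if analyte == "DA" else agent.da_base_nM * 2.0
        idx = 0
        for phase, n_frac in DIALYSIS_SCHEDULE.items():
            for _ in range(n_frac):
                idx += 1
                coupling = (
                    agent.da_coupling * realized_index
                    if (analyte == "DA" and phase == "session")
                    else 0.0
                )
                eps = rng.normal(0.0, agent.da_noise_sd) if agent.da_noise_sd > 0 else 0.0
                conc = base * (1.0 + (coupling + eps) / 100.0)
                rows.append(
                    {
                        "rat_id": agent.rat_id,
                        "analyte": analyte,
                        "fraction": idx,
                        "phase": phase,
                        "minutes": idx * 5,
                        "conc_nM": max(conc, 0.0),
                    }
                )
    return pd.DataFrame(rows)


def expected_session_duration_min(
    n_trials: int = 25, iti_mean_s: float = 90.0, cs_duration_s: float = 8.0
) -> float:
    """Closed-form expected session duration in minutes.

    Each trial is one mean inter-event interval plus the CS period; with a
    variable-time schedule the expectation is exactly ``n * (iti + cs)``.
    Pre-training (pellet on VT-30 s, no lever) uses ``cs_duration_s = 0``:
    25 trials on VT-30 s give 12.5 min.
    """
    if n_trials < 1 or iti_mean_s < 0 or cs_duration_s < 0:
        raise ValueError("invalid schedule parameters")
    return n_trials * (iti_mean_s + cs_duration_s) / 60.0
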