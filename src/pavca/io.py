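"""Interchange formats, run configuration, and pipeline orchestration.

Everything is delimited UTF-8 text with a header row. The event log is one
row per event with columns

    rat_id, phase, session, trial, event_type, time_s

where ``event_type`` is one of cs_on, cs_off, lever_contact, mag_entry,
pellet (PavCA phases) or active_poke, inactive_poke, lever_contact (CRT).
Times are seconds from session start; sessions and trials are 1-based. Each
PavCA trial must carry exactly one cs_on and one cs_off separated by the
configured CS duration. A documented column mapping (``column_map``) lets
typical operant-chamber exports be ingested without editing files.

``run_pipeline`` chains the stages — simulate, score sessions, PavCA index,
classify, assign, CRT scoring, dialysis, inference — writing every stage's
table plus a manifest (config, seed, exclusion log) so each number in the
report traces back to config + inputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import dialysis as dia
from . import stats as st
from .crt import summarize_crt
from .metrics import SessionSummary, TrialRecord, summarize_session
from .scoring import (
    PavCAScore,
    assign_groups,
    classify_table,
    pavca_index,
)
from .synth import CohortDesign, TrialConfig, rat_rng, simulate_cohort

__all__ = [
    "EVENT_TYPES",
    "RunConfig",
    "trials_to_event_log",
    "event_log_to_trials",
    "read_event_log",
    "write_event_log",
    "summaries_to_frame",
    "scores_to_frame",
    "run_pipeline",
]

EVENT_TYPES = (
    "cs_on",
    "cs_off",
    "lever_contact",
    "mag_entry",
    "pellet",
    "active_poke",
    "inactive_poke",
)

_COLUMNS = ["rat_id", "phase", "session", "trial", "event_type", "time_s"]


@dataclass(frozen=True)
class RunConfig:
    """All tunables of a pipeline run; defaults are the standard task constants."""

    trial_config: TrialConfig = field(default_factory=TrialConfig)
    regime: str = "exp1"  # classification regime: exp1 (+/-0.30, s4-5) or exp2 (+/-0.20, s3)
    arms: tuple[str, ...] = ("VEH", "CNO")
    n_perm: int = 4999
    seed: int = 0
    alpha: float = 0.05
    exclude_phenotype_changes: bool = False
    crt_duration_s: float = 2400.0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["trial_config"] = asdict(self.trial_config)
        return d


# --- event-log round trip -------------------------------------------------


def trials_to_event_log(trials: Sequence[TrialRecord]) -> pd.DataFrame:
    """Flatten trial records to the one-row-per-event log table."""
    rows = []
    for t in trials:
        base = (t.rat_id, t.phase, t.session, t.trial)
        rows.append((*base, "cs_on", t.cs_on_s))
        for ts in t.lever_events:
            rows.append((*base, "lever_contact", ts))
        for ts in t.mag_events_cs:
            rows.append((*base, "mag_entry", ts))
        for ts in t.mag_events_iti:
            rows.append((*base, "mag_entry", ts))
        rows.append((*base, "cs_off", t.cs_off_s))
        if t.pellet_retrieved:
            rows.append((*base, "pellet", t.cs_off_s))
    df = pd.DataFrame(rows, columns=_COLUMNS)
    return df.sort_values(
        ["rat_id", "session", "trial", "time_s"], kind="stable"
    ).reset_index(drop=True)


def event_log_to_trials(
    log: pd.DataFrame, cs_duration_s: float = 8.0
) -> list[TrialRecord]:
    """Rebuild trial records from an event-log table, validating structure.

    Magazine entries inside the half-open CS window become CS entries; all
    others are ITI entries. Raises with the offending (rat, session, trial)
    on missing/duplicated CS markers or a wrong CS duration.
    """
    # numpy segment slicing: one pass over the sorted log, no per-group pandas
    df = log.sort_values(["rat_id", "phase", "session", "trial"], kind="stable")
    rat = df["rat_id"].astype(str).to_numpy()
    phase = df["phase"].astype(str).to_numpy()
    session = df["session"].to_numpy()
    trial = df["trial"].to_numpy()
    etype = df["event_type"].to_numpy()
    time_s = df["time_s"].to_numpy(dtype=float)

    n = len(df)
    if n == 0:
        return []
    new_group = np.ones(n, dtype=bool)
    new_group[1:] = (
        (rat[1:] != rat[:-1])
        | (phase[1:] != phase[:-1])
        | (session[1:] != session[:-1])
        | (trial[1:] != trial[:-1])
    )
    starts = np.flatnonzero(new_group)
    ends = np.append(starts[1:], n)

    trials = []
    for lo, hi in zip(starts, ends):
        et = etype[lo:hi]
        ts = time_s[lo:hi]
        where = f"rat {rat[lo]!r}, session {session[lo]}, trial {trial[lo]}"
        ons = ts[et == "cs_on"]
        offs = ts[et == "cs_off"]
        if len(ons) != 1 or len(offs) != 1:
            raise ValueError(f"{where}: expected exactly one cs_on and one cs_off")
        cs_on, cs_off = float(ons[0]), float(offs[0])
        if cs_off <= cs_on:
            raise ValueError(f"{where}: cs_off at {cs_off} not after cs_on at {cs_on}")
        if abs((cs_off - cs_on) - cs_duration_s) > 1e-6:
            raise ValueError(
                f"{where}: CS duration {cs_off - cs_on} != configured {cs_duration_s}"
            )
        mags = ts[et == "mag_entry"]
        in_cs = (mags >= cs_on) & (mags < cs_off)
        trials.append(
            TrialRecord(
                rat_id=str(rat[lo]),
                phase=str(phase[lo]),
                session=int(session[lo]),
                trial=int(trial[lo]),
                cs_on_s=cs_on,
                cs_off_s=cs_off,
                lever_events=tuple(np.sort(ts[et == "lever_contact"])),
                mag_events_cs=tuple(np.sort(mags[in_cs])),
                mag_events_iti=tuple(np.sort(mags[~in_cs])),
                pellet_retrieved=bool((et == "pellet").any()),
            )
        )
    return trials


def read_event_log(
    path: str | Path, column_map: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Read and validate a delimited event log.

    ``column_map`` renames external column names onto the canonical schema
    (e.g. ``{"subject": "rat_id", "event": "event_type"}``) so third-party
    operant-chamber exports can be ingested. Structural violations are
    reported with row numbers.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    df = df[_COLUMNS]
    bad_type = ~df["event_type"].isin(EVENT_TYPES)
    if bad_type.any():
        rows = df.index[bad_type][:5].tolist()
        raise ValueError(
            f"{path}: unknown event_type at rows {rows}: "
            f"{df.loc[bad_type, 'event_type'].unique()[:5].tolist()}"
        )
    neg = df["time_s"] < 0
    if neg.any():
        raise ValueError(f"{path}: negative time_s at rows {df.index[neg][:5].tolist()}")
    return df


def write_event_log(log: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    log.to_csv(path, index=False)


def summaries_to_frame(summaries: Sequence[SessionSummary]) -> pd.DataFrame:
    return pd.DataFrame([asdict(s) for s in summaries])


def scores_to_frame(scores: Sequence[PavCAScore]) -> pd.DataFrame:
    return pd.DataFrame([asdict(s) for s in scores])


def score_trials(trials: Sequence[TrialRecord]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Trial records -> (session-summary table, per-session PavCA score table)."""
    by_session: dict[tuple, list[TrialRecord]] = {}
    for t in trials:
        by_session.setdefault((t.rat_id, t.phase, t.session), []).append(t)
    summaries = [summarize_session(v) for v in by_session.values()]
    scores = [pavca_index(s) for s in summaries]
    return summaries_to_frame(summaries), scores_to_frame(scores)


def score_event_log(
    log: pd.DataFrame, cs_duration_s: float = 8.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Event log -> (session-summary table, per-session PavCA score table)."""
    return score_trials(event_log_to_trials(log, cs_duration_s=cs_duration_s))


def cohort_block_table(design: CohortDesign) -> pd.DataFrame:
    """Simulate a design and export the long rescreen/test block table.

    One row per rat x session with columns ``rat_id``, ``block`` (rescreen or
    test), ``treatment``, ``value`` (the session PavCA index) — the table the
    interaction permutation test consumes, and the export hook for fitting
    mixed models in external software.
    """
    trials, truth = simulate_cohort(design)
    _, scores = score_trials(trials)
    arm = truth[["rat_id", "treatment"]].drop_duplicates()
    tab = (
        scores[scores["phase"].isin(["rescreen", "test"])]
        .rename(columns={"phase": "block", "index": "value"})[
            ["rat_id", "block", "value"]
        ]
        .merge(arm, on="rat_id")
    )
    return tab


# --- orchestration ---------------------------------------------------------


def run_pipeline(
    design: CohortDesign,
    out_dir: str | Path,
    config: RunConfig | None = None,
) -> dict:
    """Simulate a cohort and run every analysis stage, writing all tables.

    Stages: simulate -> score-sessions -> pavca-index -> classify -> assign
    -> score-crt -> dialysis -> analyze. Returns the manifest dict (also
    written as ``manifest.json``) listing stages, outputs, exclusions, and
    headline statistics.
    """
    config = config or RunConfig(trial_config=design.trial_config, seed=design.seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "design": {
            "n_per_cell": design.n_per_cell,
            "phenotypes": list(design.phenotypes),
            "treatments": list(design.treatments),
            "treat_shifts": dict(design.treat_shifts),
            "seed": design.seed,
        },
        "stages": [],
        "exclusions": {},
    }

    def record(stage: str, path: Path | None) -> None:
        manifest["stages"].append(
            {"stage": stage, "output": str(path.name) if path else None}
        )

    # simulate
    trials, truth = simulate_cohort(design)
    log = trials_to_event_log(trials)
    write_event_log(log, out / "event_log.csv")
    truth.to_csv(out / "ground_truth.csv", index=False)
    record("simulate", out / "event_log.csv")

    # score-sessions + pavca-index
    summaries, scores = score_event_log(log, design.trial_config.cs_duration_s)
    summaries.to_csv(out / "session_summaries.csv", index=False)
    record("score-sessions", out / "session_summaries.csv")
    scores.to_csv(out / "pavca_scores.csv", index=False)
    record("pavca-index", out / "pavca_scores.csv")

    # classify on the acquisition window
    calls = classify_table(scores, regime=config.regime)
    calls.to_csv(out / "phenotype_calls.csv", index=False)
    record("classify", out / "phenotype_calls.csv")
    n_in = int(calls["excluded"].sum())
    manifest["exclusions"]["intermediate_band"] = n_in

    # assign treatment arms counterbalanced on the classification index
    from .scoring import PhenotypeCall

    call_objs = [
        PhenotypeCall(
            rat_id=r.rat_id,
            window_sessions=(),
            mean_index=r.mean_index,
            call=r.call,
            regime=r.regime,
            excluded=r.excluded,
        )
        for r in calls.itertuples()
    ]
    assignment = assign_groups(call_objs, arms=list(config.arms), seed=config.seed)
    assignment.to_csv(out / "assignments.csv", index=False)
    record("assign", out / "assignments.csv")

    # CRT: one session per included rat, driven by its test-phase theta
    from .synth import make_agent, simulate_crt_session

    crt_rows = []
    theta_by_rat = truth.groupby("rat_id")["theta"].last()
    for rat_id in assignment["rat_id"]:
        rng = rat_rng(design.seed + 1, str(rat_id))
        agent = make_agent(
            str(truth.loc[truth["rat_id"] == rat_id, "phenotype_truth"].iloc[0]),
            seed=int(rng.integers(0, 2**31 - 1)),
            rat_id=str(rat_id),
        )
        events = simulate_crt_session(
            agent, config.crt_duration_s, rng=rng, theta=float(theta_by_rat[rat_id])
        )
        s = summarize_crt(events, rat_id=str(rat_id), session_duration_s=config.crt_duration_s)
        crt_rows.append(asdict(s))
    crt_table = pd.DataFrame(crt_rows)
    crt_table.to_csv(out / "crt_summaries.csv", index=False)
    record("score-crt", out / "crt_summaries.csv")

    # dialysis: one series per included rat from its realized final index
    from .synth import simulate_dialysis_series

    final_scores = (
        scores.sort_values("session").groupby("rat_id")["index"].last().clip(-1, 1)
    )
    dia_frames = []
    excluded_series = 0
    for rat_id in assignment["rat_id"]:
        rng = rat_rng(design.seed + 2, str(rat_id))
        agent = make_agent(
            str(truth.loc[truth["rat_id"] == rat_id, "phenotype_truth"].iloc[0]),
            seed=int(rng.integers(0, 2**31 - 1)),
            rat_id=str(rat_id),
        )
        series = simulate_dialysis_series(agent, float(final_scores[rat_id]), rng=rng)
        da = series[series["analyte"] == "DA"]
        if not dia.validate_series(da):
            excluded_series += 1
            continue
        dia_frames.append(series.assign(
            session_avg_da_pct=dia.session_average_change(da)
        ))
    dialysis_table = pd.concat(dia_frames, ignore_index=True)
    dialysis_table.to_csv(out / "dialysis_fractions.csv", index=False)
    record("dialysis", out / "dialysis_fractions.csv")
    manifest["exclusions"]["incomplete_dialysis_series"] = excluded_series

    # analyze: rescreen-vs-test permutation interaction per phenotype
    # inference uses the cohort's actual treatment labels; the assignment
    # table above is the prospective counterbalancing stage, not the analysis
    arm_truth = truth[["rat_id", "phenotype_truth", "treatment"]].drop_duplicates()
    merged = scores.merge(arm_truth, on="rat_id")
    merged = merged[merged["rat_id"].isin(assignment["rat_id"])]
    analysis: dict = {}
    long = merged[merged["phase"].isin(["rescreen", "test"])]
    if not long.empty and long["phase"].nunique() == 2:
        for pheno, grp in long.groupby("phenotype_truth"):
            tab = grp.rename(columns={"phase": "block"})[
                ["rat_id", "block", "treatment", "index"]
            ].rename(columns={"index": "value"})
            res = st.interaction_permutation_test(
                tab,
                n_perm=config.n_perm,
                seed=config.seed,
                treated=design.treatments[1] if len(design.treatments) == 2 else None,
            )
            analysis[f"interaction_{pheno}"] = {
                "observed_did": res["observed"],
                "p": res["p"],
            }
    # dopamine-behavior regression over included rats
    da_avg = (
        dialysis_table[dialysis_table["analyte"] == "DA"]
        .groupby("rat_id")["session_avg_da_pct"]
        .first()
    )
    paired = final_scores.reindex(da_avg.index).dropna()
    if len(paired) >= 3 and np.ptp(da_avg[paired.index].to_numpy()) > 0:
        reg = dia.regress_behavior_on_da(
            da_avg[paired.index].to_numpy(), paired.to_numpy()
        )
        analysis["da_regression"] = {
            "slope": reg.slope,
            "r_squared": reg.r_squared,
            "F": reg.f_statistic,
            "df": list(reg.df),
            "p": reg.p_value,
        }
    manifest["analysis"] = analysis
    record("analyze", None)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
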