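# pavca

Quantitative analysis of **Pavlovian conditioned approach (PavCA)**
experiments — the sign-tracker / goal-tracker paradigm used to study how
animals attribute motivational (incentive) value to reward cues — plus an
agent-based synthetic cohort generator so the whole pipeline can be
developed, tested and calibrated without animal data.

## Who this is for

Behavioral neuroscientists running lever-CS / food-US autoshaping tasks who
need reproducible, scriptable scoring of operant event logs: per-session
measures, the composite PavCA index, phenotype classification,
conditioned-reinforcement scoring, microdialysis normalization, and
permutation-based treatment inference.

## The core quantities

For each 25-trial session (8-s lever CS, food on a VT-90 s schedule), six
measures are reduced to three components, each in [−1, +1]:

- **response bias** = (lever contacts − magazine entries) / (lever contacts + magazine entries)
- **probability difference** = P(lever) − P(magazine), per-trial response fractions
- **latency difference** = −(lat_lever − lat_mag) / 8, with non-responding
  trials censored at the full 8-s CS duration

**PavCA index** = mean of the three. +1 is an extreme sign-tracker (every
response at the lever, zero latency), −1 an extreme goal-tracker. Rats are
classified from a window mean (sessions 4–5 at ±0.30, or session 3 at ±0.20
for short protocols); intermediates are flagged for exclusion.

Conditioned-reinforcement sessions (FR1 nose-poking for 2-s lever
presentations) are summarized by the **incentive value index** =
(active pokes + lever contacts) − inactive pokes.

Microdialysis fraction series (6 baseline + 5 pre + 7 session 5-min
fractions) are normalized to **percent change from the baseline mean**, and
behavior is related to dopamine by OLS regression of the PavCA index on the
session-mean %DA change (r² = squared Pearson correlation,
F = r²(n−2)/(1−r²)).

Treatment effects on repeated-measures designs are tested by a
**permutation difference-in-differences**: the observed statistic is the
(test − rescreen) change in the treated arm minus the same change in the
vehicle arm, with treatment labels permuted across rats. Effect sizes are
Cohen's d (pooled SD); outliers follow the 1.5×IQR boxplot rule; balanced
factorial tables get a classical two-way ANOVA.

## Worked example

```bash
python examples/score_pavca_sessions.py
```

prints, for a simulated sign-tracker's fifth session:

```
ST rat, session 5 (25 trials)
  lever contacts  31   magazine entries   3
  P(lever) 0.88   P(magazine) 0.08
  latency lever 2.22 s   magazine 7.45 s
  response bias +0.824  prob diff +0.800  latency diff +0.655
  PavCA index +0.759  (+1 extreme sign-tracker, -1 extreme goal-tracker)
```

i.e. this rat responded on 88% of trials at the lever, reached it in ~2 s,
and rarely checked the magazine during the cue — a clear sign-tracker
(index ≥ +0.30). The other examples cover classification and
counterbalanced arm assignment, CRT scoring, dialysis normalization and
regression, permutation inference, and the end-to-end pipeline
(`examples/full_pipeline.py`, equivalent to the `pavca run-all` CLI
command).

A thin CLI mirrors the library:
`pavca simulate | score-sessions | pavca-index | classify | assign |
score-crt | dialysis | analyze | run-all`.

## Data formats

Everything is delimited UTF-8 text with headers. Event logs are one row per
event (`rat_id, phase, session, trial, event_type, time_s`); a
`column_map` argument on `read_event_log` adapts typical operant-chamber
exports. Dialysis tables are `rat_id, analyte, fraction, phase, conc_nM`.
See `docs/methods.md` for the model, conventions and limitations.
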