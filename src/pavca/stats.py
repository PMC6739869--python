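"""Inference utilities: outlier screening, effect sizes, t-tests, balanced
two-way ANOVA, and a permutation test for treatment x session-block effects.

Repeated-measures designs here have exactly two session blocks per rat (e.g.
mean PavCA index during rescreening vs during treatment). The treatment x
block interaction — did the treated arm change more across blocks than the
vehicle arm? — is tested by permutation: the observed statistic is the
difference-in-differences of arm means, and the null distribution is built
by permuting treatment labels across rats while keeping each rat's block
pair intact. This is exact under exchangeability of rats and needs no
covariance-structure assumptions.

Outliers follow the boxplot convention: values beyond 1.5 interquartile
ranges outside the quartile box are flagged, with quartiles computed by
linear interpolation between order statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "OutlierReport",
    "ComparisonResult",
    "iqr_outliers",
    "cohens_d",
    "two_sample_t",
    "interaction_permutation_test",
    "balanced_two_way_anova",
    "bonferroni",
    "power_by_simulation",
]


@dataclass(frozen=True)
class OutlierReport:
    """1.5 x IQR screening result; kept + removed partition the input."""

    kept: np.ndarray
    removed: np.ndarray
    q1: float
    q3: float
    iqr: float
    bounds: tuple[float, float]
    warning: str | None = None


@dataclass(frozen=True)
class ComparisonResult:
    """A two-group comparison: test statistic, p, and Cohen's d."""

    statistic: float
    df: float
    p: float
    effect_size_d: float
    n1: int
    n2: int
    method: str


def iqr_outliers(values) -> OutlierReport:
    """Flag values outside [Q1 - 1.5 IQR, Q3 + 1.5 IQR].

    Quartiles use linear interpolation between order statistics. With fewer
    than 4 values quartiles are too unstable to screen on: nothing is
    flagged and the report carries a warning.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("values must be 1-D")
    if x.size < 4:
        return OutlierReport(
            kept=x.copy(),
            removed=np.empty(0),
            q1=float("nan"),
            q3=float("nan"),
            iqr=float("nan"),
            bounds=(float("-inf"), float("inf")),
            warning=f"n={x.size} < 4: outlier screening skipped",
        )
    q1, q3 = np.percentile(x, [25, 75])  # linear interpolation
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    mask = (x >= lo) & (x <= hi)
    return OutlierReport(
        kept=x[mask],
        removed=x[~mask],
        q1=float(q1),
        q3=float(q3),
        iqr=float(iqr),
        bounds=(float(lo), float(hi)),
    )


def cohens_d(group1, group2) -> float:
    """Cohen's d with the df-weighted pooled standard deviation.

    d = (mean1 - mean2) / s_pooled, s_pooled^2 = ((n1-1)s1^2 + (n2-1)s2^2)
    / (n1 + n2 - 2). Conventional bands: < 0.2 small, 0.2-0.8 medium,
    > 0.8 large.
    """
    x = np.asarray(group1, dtype=float)
    y = np.asarray(group2, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs n >= 2")
    pooled_var = (
        (x.size - 1) * x.var(ddof=1) + (y.size - 1) * y.var(ddof=1)
    ) / (x.size + y.size - 2)
    if pooled_var == 0:
        raise ValueError("pooled SD is zero; d undefined")
    return float((x.mean() - y.mean()) / np.sqrt(pooled_var))


def two_sample_t(group1, group2, paired: bool = False) -> ComparisonResult:
    """Two-sided t-test (Student's pooled-variance, or paired) with Cohen's d.

    Unpaired df is n1 + n2 - 2; paired df is n - 1 (d then uses the two
    groups' pooled SD, not the difference SD).
    """
    x = np.asarray(group1, dtype=float)
    y = np.asarray(group2, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs n >= 2")
    if paired:
        if x.size != y.size:
            raise ValueError("paired groups must have equal n")
        res = sps.ttest_rel(x, y)
        df = x.size - 1
        method = "paired t"
    else:
        res = sps.ttest_ind(x, y, equal_var=True)
        df = x.size + y.size - 2
        method = "unpaired t (pooled variance)"
    return ComparisonResult(
        statistic=float(res.statistic),
        df=float(df),
        p=float(res.pvalue),
        effect_size_d=cohens_d(x, y),
        n1=int(x.size),
        n2=int(y.size),
        method=method,
    )


def _did_statistic(block_diff: np.ndarray, treated: np.ndarray) -> float:
    """Difference-in-differences of arm means over per-rat block changes."""
    return float(block_diff[treated].mean() - block_diff[~treated].mean())


def interaction_permutation_test(
    table: pd.DataFrame,
    n_perm: int = 4999,
    seed: int = 0,
    value: str = "value",
    treated: str | None = None,
) -> dict:
    """Permutation test of the treatment x session-block interaction.

    ``table`` is long-format with columns ``rat_id``, ``block`` (exactly two
    levels), ``treatment`` (exactly two levels) and a numeric value column.
    The observed statistic is the difference-in-differences of arm means
    across blocks (``treated`` names the arm reported with positive sign;
    default: the lexicographically later label). The null permutes treatment
    labels across rats, keeping each rat's block pairing intact. p uses the
    add-one rule (1 + #{|null| >= |obs|}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    required = {"rat_id", "block", "treatment", value}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"table missing columns {sorted(missing)}")
    blocks = sorted(table["block"].unique())
    arms = sorted(table["treatment"].unique())
    if len(blocks) != 2 or len(arms) != 2:
        raise ValueError("need exactly two blocks and two treatment arms")
    if treated is not None:
        if treated not in arms:
            raise ValueError(f"treated label {treated!r} not among arms {arms}")
        arms = [a for a in arms if a != treated] + [treated]

    wide = table.pivot_table(index="rat_id", columns="block", values=value, aggfunc="mean")
    arm_of = table.groupby("rat_id")["treatment"].agg(lambda s: s.iloc[0])
    if wide.isna().any().any():
        raise ValueError("every rat needs a value in both blocks")
    block_diff = (wide[blocks[1]] - wide[blocks[0]]).to_numpy()
    treated = (arm_of.reindex(wide.index) == arms[1]).to_numpy()
    n_treated = int(treated.sum())
    if n_treated < 2 or (treated.size - n_treated) < 2:
        raise ValueError("need at least 2 rats per arm")

    observed = _did_statistic(block_diff, treated)
    rng = np.random.default_rng(seed)
    n = treated.size
    exceed = 0
    for _ in range(n_perm):
        perm = np.zeros(n, dtype=bool)
        perm[rng.choice(n, size=n_treated, replace=False)] = True
        if abs(_did_statistic(block_diff, perm)) >= abs(observed) - 1e-12:
            exceed += 1
    p = (1 + exceed) / (n_perm + 1)
    return {
        "observed": observed,
        "p": p,
        "n_perm": n_perm,
        "arms": tuple(arms),
        "blocks": tuple(blocks),
        "n_rats": n,
    }


def balanced_two_way_anova(
    table: pd.DataFrame,
    factor_a: str,
    factor_b: str,
    value: str = "value",
) -> pd.DataFrame:
    """Classical sums-of-squares two-way ANOVA for a balanced crossed design.

    Requires every factor_a x factor_b cell to hold the same number (>= 2) of
    replicates; with balance the Type I/II/III decompositions coincide and
    SS_A + SS_B + SS_AB + SS_error = SS_total. Unbalanced tables are
    rejected (use the permutation test instead). Returns a table indexed by
    effect with columns ss, df, ms, F, p.
    """
    for col in (factor_a, factor_b, value):
        if col not in table.columns:
            raise ValueError(f"table missing column {col!r}")
    cells = table.groupby([factor_a, factor_b], observed=True)[value]
    counts = cells.count()
    a_levels = table[factor_a].nunique()
    b_levels = table[factor_b].nunique()
    if len(counts) != a_levels * b_levels or counts.nunique() != 1:
        raise ValueError(
            "unbalanced design: all cells must be present with equal n "
            "(consider the permutation interaction test)"
        )
    r = int(counts.iloc[0])
    if r < 2:
        raise ValueError("need >= 2 replicates per cell")

    y = table[value].to_numpy(dtype=float)
    grand = y.mean()
    a_means = table.groupby(factor_a, observed=True)[value].mean()
    b_means = table.groupby(factor_b, observed=True)[value].mean()
    cell_means = cells.mean()

    n_per_a = b_levels * r
    n_per_b = a_levels * r
    ss_a = float(n_per_a * ((a_means - grand) ** 2).sum())
    ss_b = float(n_per_b * ((b_means - grand) ** 2).sum())
    interaction_dev = (
        cell_means
        - a_means.reindex(cell_means.index.get_level_values(0)).to_numpy()
        - b_means.reindex(cell_means.index.get_level_values(1)).to_numpy()
        + grand
    )
    ss_ab = float(r * (interaction_dev**2).sum())
    fitted = table.set_index([factor_a, factor_b]).index.map(cell_means)
    ss_err = float(((y - np.asarray(fitted, dtype=float)) ** 2).sum())
    ss_tot = float(((y - grand) ** 2).sum())

    df_a = a_levels - 1
    df_b = b_levels - 1
    df_ab = df_a * df_b
    df_err = a_levels * b_levels * (r - 1)

    rows = []
    for name, ss, df in (
        (factor_a, ss_a, df_a),
        (factor_b, ss_b, df_b),
        (f"{factor_a}:{factor_b}", ss_ab, df_ab),
    ):
        ms = ss / df
        ms_err = ss_err / df_err
        f_stat = ms / ms_err if ms_err > 0 else float("inf")
        rows.append(
            {
                "effect": name,
                "ss": ss,
                "df": df,
                "ms": ms,
                "F": f_stat,
                "p": float(sps.f.sf(f_stat, df, df_err)) if np.isfinite(f_stat) else 0.0,
            }
        )
    rows.append(
        {
            "effect": "error",
            "ss": ss_err,
            "df": df_err,
            "ms": ss_err / df_err,
            "F": float("nan"),
            "p": float("nan"),
        }
    )
    rows.append(
        {"effect": "total", "ss": ss_tot, "df": len(y) - 1, "ms": float("nan"),
         "F": float("nan"), "p": float("nan")}
    )
    return pd.DataFrame(rows).set_index("effect")


def bonferroni(p_values, alpha: float = 0.05) -> pd.DataFrame:
    """Bonferroni correction for post-hoc pairwise comparisons."""
    p = np.asarray(p_values, dtype=float)
    adj = np.minimum(p * p.size, 1.0)
    return pd.DataFrame(
        {"p_raw": p, "p_adj": adj, "reject": adj <= alpha}
    )


def power_by_simulation(
    simulate_cohort_table,
    n_sim: int = 200,
    alpha: float = 0.05,
    n_perm: int = 199,
    seed: int = 0,
) -> dict:
    """Estimate interaction-test power by simulating whole cohorts.

    ``simulate_cohort_table(seed)`` must return a long table acceptable to
    :func:`interaction_permutation_test`. Returns the rejection fraction
    with a 95% Wilson interval. With a zero effect this calibrates the test:
    power should approximate alpha.
    """
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100 for a stable estimate")
    rng = np.random.default_rng(seed)
    p_values = []
    for _ in range(n_sim):
        cohort_seed = int(rng.integers(0, 2**31 - 1))
        table = simulate_cohort_table(cohort_seed)
        res = interaction_permutation_test(
            table, n_perm=n_perm, seed=int(rng.integers(0, 2**31 - 1))
        )
        p_values.append(res["p"])
    phat = float(np.mean(np.asarray(p_values) <= alpha))
    z = sps.norm.ppf(0.975)
    denom = 1 + z**2 / n_sim
    center = (phat + z**2 / (2 * n_sim)) / denom
    half = z * np.sqrt(phat * (1 - phat) / n_sim + z**2 / (4 * n_sim**2)) / denom
    return {
        "power": phat,
        "ci95": (max(0.0, center - half), min(1.0, center + half)),
        "n_sim": n_sim,
        "alpha": alpha,
        "p_values": np.asarray(p_values),
    }
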