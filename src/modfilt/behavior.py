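"""Scoring and statistics for the sound-picture matching task.

Subjects heard 24 animal and 24 tool sounds and matched each to one of six
photographs, so chance performance is 1/6 per trial.  The analyses here are
the ones used to characterise that task: an exact one-tailed binomial test
of above-chance performance, a paired t confidence interval on the
animal-tool score difference, and per-group summary tables reported to the
same conventions as the published patient table (mean, SD, minimum; 1 dp).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CHANCE_6AFC",
    "N_TRIALS_PER_CATEGORY",
    "sd_patient_scores",
    "CONTROL_PRINTED_SUMMARY",
    "binomial_above_chance",
    "paired_mean_difference_ci",
    "group_summary",
    "above_chance_report",
    "load_scores",
]

#: six-alternative forced choice
CHANCE_6AFC = 1.0 / 6.0
N_TRIALS_PER_CATEGORY = 24

# Published per-patient sound-picture matching scores (out of 24 per
# category) for the nine semantic dementia cases; input data for the
# reproduction analyses.
_SD_ANIMAL = [9, 12, 14, 23, 12, 10, 4, 7, 0]
_SD_TOOL = [10, 17, 14, 20, 8, 10, 6, 3, 0]

#: group-level control scores as printed (raw control scores unpublished)
CONTROL_PRINTED_SUMMARY = {
    "animal_mean": 21.7, "animal_sd": 1.9, "animal_min": 15,
    "tool_mean": 19.9, "tool_sd": 2.1, "tool_min": 16,
}


def sd_patient_scores() -> pd.DataFrame:
    """Score table for the nine SD patients (published raw scores)."""
    return pd.DataFrame(
        {
            "subject_id": [f"case_{i}" for i in range(1, 10)],
            "group": "SD",
            "animal_correct": _SD_ANIMAL,
            "tool_correct": _SD_TOOL,
        }
    )


def binomial_above_chance(
    correct: int,
    n_trials: int,
    p_chance: float = CHANCE_6AFC,
    alpha: float = 0.05,
) -> tuple[float, bool]:
    """Exact one-tailed binomial test of above-chance performance.

    Returns the upper-tail probability P(X >= correct | n_trials, p_chance)
    and whether it falls below ``alpha``.
    """
    if not (0 <= correct <= n_trials):
        raise ValueError(f"correct must lie in [0, {n_trials}], got {correct}")
    p = float(stats.binom.sf(correct - 1, n_trials, p_chance))
    return p, p < alpha


def paired_mean_difference_ci(
    a, b, level: float = 0.95
) -> tuple[float, float, float]:
    """Mean of paired differences a - b with a Student-t confidence interval.

    The interval uses n - 1 degrees of freedom on the differences, the
    standard paired t construction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired score vectors must have equal length")
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    mean = float(d.mean())
    se = float(d.std(ddof=1) / np.sqrt(n))
    if se == 0.0:
        return mean, mean, mean
    tcrit = float(stats.t.ppf(0.5 + level / 2, n - 1))
    return mean, mean - tcrit * se, mean + tcrit * se


def group_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Per-group mean / SD / min per category plus the animal-tool gap.

    Values are returned at full precision; round to 1 dp for reporting.
    Single-subject groups get NaN SDs (flagged, not an error).
    """
    required = {"group", "animal_correct", "tool_correct"}
    if table.empty or not required.issubset(table.columns):
        raise ValueError(f"score table must be non-empty with columns {required}")
    rows = []
    for group, sub in table.groupby("group", sort=False):
        a = sub["animal_correct"].astype(float)
        t = sub["tool_correct"].astype(float)
        rows.append(
            {
                "group": group,
                "n": len(sub),
                "animal_mean": a.mean(),
                "animal_sd": a.std(ddof=1) if len(sub) > 1 else np.nan,
                "animal_min": a.min(),
                "tool_mean": t.mean(),
                "tool_sd": t.std(ddof=1) if len(sub) > 1 else np.nan,
                "tool_min": t.min(),
                "animal_tool_gap": a.mean() - t.mean(),
            }
        )
    return pd.DataFrame(rows).set_index("group")


def above_chance_report(
    table: pd.DataFrame,
    n_per_category: int = N_TRIALS_PER_CATEGORY,
    p_chance: float = CHANCE_6AFC,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-subject above-chance tests, pooled and per category.

    The pooled test combines both categories (2 * n_per_category trials);
    the per-category tests reproduce the chance-level flags attached to the
    individual scores in the published table (flag = *not* above chance).
    """
    rows = []
    for _, r in table.iterrows():
        pooled_k = int(r["animal_correct"]) + int(r["tool_correct"])
        p_pooled, sig_pooled = binomial_above_chance(
            pooled_k, 2 * n_per_category, p_chance, alpha
        )
        p_animal, sig_animal = binomial_above_chance(
            int(r["animal_correct"]), n_per_category, p_chance, alpha
        )
        p_tool, sig_tool = binomial_above_chance(
            int(r["tool_correct"]), n_per_category, p_chance, alpha
        )
        rows.append(
            {
                "subject_id": r["subject_id"],
                "pooled_p": p_pooled,
                "pooled_above_chance": sig_pooled,
                "animal_p": p_animal,
                "animal_above_chance": sig_animal,
                "tool_p": p_tool,
                "tool_above_chance": sig_tool,
            }
        )
    return pd.DataFrame(rows).set_index("subject_id")


def load_scores(path) -> pd.DataFrame:
    """Read a delimited score table (subject_id, group, animal_correct,
    tool_correct); delimiter sniffed by pandas."""
    df = pd.read_csv(path, sep=None, engine="python")
    missing = {"subject_id", "group", "animal_correct", "tool_correct"} - set(df.columns)
    if missing:
        raise ValueError(f"score table missing columns: {sorted(missing)}")
    return df
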