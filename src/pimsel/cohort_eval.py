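"""Retrospective evaluation of historical embryo selections.

For each patient with two or more embryos, two statistics summarise how much
the ML-score could have mattered and whether it was used well:

* the heterogeneity index (H-index) is the spread of ML-scores across the
  patient's embryos, ``max - min``;
* the selection-status index (S-index) is the selected embryo's ML-score
  minus the patient's minimum ML-score, i.e. how far the historical choice
  sat above the best available embryo.

With a quality-difference threshold ``t`` (default 0.03 on the ML-score
scale), patients fall into three groups: *similar* quality embryos
(H <= t), *superior* selection (H > t, S <= t) and *inferior* selection
(H > t and S > t).  Group outcome tables are compared with one-sided
Fisher exact tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DEFAULT_QUALITY_THRESHOLD",
    "GROUPS",
    "h_index",
    "s_index",
    "categorize_patient",
    "evaluate_patients",
    "group_outcome_table",
    "compare_groups",
    "age_ttest",
]

#: Minimum ML-score difference regarded as a real embryo-quality difference.
DEFAULT_QUALITY_THRESHOLD = 0.03

GROUPS = ("similar", "superior", "inferior")


def h_index(ml_scores) -> float:
    """Embryo heterogeneity of one patient: max minus min ML-score."""
    s = np.asarray(ml_scores, dtype=float)
    if s.size < 2:
        raise ValueError("H-index requires at least two embryos")
    return float(s.max() - s.min())


def s_index(selected_score: float, ml_scores) -> float:
    """Selection status: selected embryo's ML-score minus the patient minimum.

    ``selected_score`` must be one of ``ml_scores`` (the selected embryo is
    part of the available set).  Zero means the best-scoring embryo was
    selected; for a single-embryo patient the index is trivially zero.
    """
    s = np.asarray(ml_scores, dtype=float)
    if s.size == 0:
        raise ValueError("no embryo scores supplied")
    if not np.any(np.isclose(s, selected_score)):
        raise ValueError("selected embryo's score not among the patient's scores")
    return float(selected_score - s.min())


def categorize_patient(h: float, s: float,
                       threshold: float = DEFAULT_QUALITY_THRESHOLD) -> str:
    """Assign the three-way selection group from H- and S-index.

    Boundary values sit on the "no significant difference" side: a
    difference counts only when strictly greater than the threshold.
    """
    if s > h + 1e-12:
        raise ValueError("S-index cannot exceed H-index")
    if h <= threshold:
        return "similar"
    if s <= threshold:
        return "superior"
    return "inferior"


@dataclass(frozen=True)
class PatientEvaluation:
    patient_id: str
    h_index: float
    s_index: float
    group: str
    n_embryos: int
    selected_embryo_id: str
    selected_outcome: str


def evaluate_patients(scores: pd.DataFrame,
                      threshold: float = DEFAULT_QUALITY_THRESHOLD) -> pd.DataFrame:
    """Per-patient H/S indices and groups for all evaluable patients.

    ``scores`` needs columns embryo_id, patient_id, ml_score, selected,
    outcome.  Patients are evaluable when they have >= 2 embryos and exactly
    one embryo flagged as selected.  Returns one row per evaluable patient.
    """
    required = {"embryo_id", "patient_id", "ml_score", "selected", "outcome"}
    missing = required - set(scores.columns)
    if missing:
        raise ValueError(f"scores table missing columns {sorted(missing)}")
    rows = []
    for pid, grp in scores.groupby("patient_id", sort=True):
        if len(grp) < 2 or int(grp["selected"].sum()) != 1:
            continue
        sel = grp.loc[grp["selected"]].iloc[0]
        h = h_index(grp["ml_score"])
        s = s_index(float(sel["ml_score"]), grp["ml_score"])
        rows.append(PatientEvaluation(
            patient_id=pid,
            h_index=h,
            s_index=s,
            group=categorize_patient(h, s, threshold),
            n_embryos=len(grp),
            selected_embryo_id=sel["embryo_id"],
            selected_outcome=sel["outcome"],
        ))
    return pd.DataFrame([r.__dict__ for r in rows])


def group_outcome_table(evaluations: pd.DataFrame) -> pd.DataFrame:
    """Counts of selected-embryo outcomes (Birth/Failed) per selection group."""
    tab = (evaluations.groupby(["group", "selected_outcome"])
           .size().unstack(fill_value=0))
    for col in ("Birth", "Failed"):
        if col not in tab.columns:
            tab[col] = 0
    return tab.reindex(list(GROUPS)).fillna(0).astype(int)[["Birth", "Failed"]]


def compare_groups(table, alternative: str = "greater") -> tuple[float, float]:
    """One-sided Fisher exact test on a 2x2 outcome table.

    ``table`` is [[a, b], [c, d]] with rows = the two patient groups and
    columns = (favourable, unfavourable) outcome counts.  The default
    alternative "greater" tests whether the first row has higher odds of the
    favourable outcome.  Returns (odds_ratio, p_value).
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (t < 0).any():
        raise ValueError("negative counts in contingency table")
    odds, p = stats.fisher_exact(t, alternative=alternative)
    return float(odds), float(p)


def age_ttest(ages_a, ages_b) -> tuple[float, float]:
    """Plain two-sided two-sample t-test on maternal ages (descriptive check)."""
    t, p = stats.ttest_ind(np.asarray(ages_a, float), np.asarray(ages_b, float))
    return float(t), float(p)
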