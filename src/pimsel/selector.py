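"""Combined scoring, simulated embryo selection and discriminability.

The final per-embryo score mixes the two predictors on the probability
scale: the TSS-score (promoter-signature classifier) and the GLM-predicted
birth probability of the ML-score, combined as a weighted mean with a
default TSS:linear weighting of 1:2.

Selection is simulated retrospectively on patients known to have exactly
one birth embryo and one or more failed embryos: the model "selects" the
embryo with the highest combined score, and the selection is correct when
that embryo is the birth one.  Per patient, the discriminability index

    DI = score(birth embryo) - mean(score of failed embryos)

measures how far the model separates the labels; a one-sample t-test of
the DIs against zero summarises whether the model discriminates at all.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["DEFAULT_WEIGHTS", "combine_scores", "simulate_selection",
           "di_summary"]

#: (w_tss, w_linear): the TSS-score enters with weight 1, the linear
#: (GLM-probability) score with weight 2.
DEFAULT_WEIGHTS = (1.0, 2.0)


def combine_scores(tss, linear, weights=DEFAULT_WEIGHTS):
    """Convex combination of TSS-score and GLM birth probability.

    ``(w_tss * tss + w_linear * linear) / (w_tss + w_linear)``; both inputs
    must be probabilities in [0, 1] and both weights positive.  Scalars and
    aligned arrays are accepted.
    """
    w_tss, w_linear = weights
    if w_tss < 0 or w_linear < 0 or w_tss + w_linear == 0:
        raise ValueError("weights must be non-negative with a positive sum")
    t = np.asarray(tss, dtype=float)
    l = np.asarray(linear, dtype=float)
    if np.any((t < 0) | (t > 1)) or np.any((l < 0) | (l > 1)):
        raise ValueError("scores must lie in [0, 1]")
    out = (w_tss * t + w_linear * l) / (w_tss + w_linear)
    return float(out) if np.isscalar(tss) and np.isscalar(linear) else out


def simulate_selection(scores: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Pick the top-scoring embryo of every patient; check it against truth.

    ``scores`` needs columns embryo_id, patient_id, outcome, pims_score and
    (for tie-breaking) glm_prob and ml_score.  Every patient must have
    exactly one Birth embryo and at least one Failed embryo.  Ties on the
    combined score break on higher glm_prob, then lower ml_score, then
    lexicographically smallest embryo_id.

    Returns (per-patient results, overall accuracy).  Result columns:
    patient_id, chosen_embryo_id, correct, di, p_birth, p_failed_mean,
    n_embryos.
    """
    required = {"embryo_id", "patient_id", "outcome", "pims_score"}
    missing = required - set(scores.columns)
    if missing:
        raise ValueError(f"scores table missing columns {sorted(missing)}")
    rows = []
    for pid, grp in scores.groupby("patient_id", sort=True):
        birth = grp[grp["outcome"] == "Birth"]
        failed = grp[grp["outcome"] == "Failed"]
        if len(birth) != 1 or len(failed) == 0:
            raise ValueError(
                f"patient {pid}: simulated selection needs exactly one Birth "
                f"and >= 1 Failed embryo (got {len(birth)} and {len(failed)})")
        order = ["pims_score"]
        ascending = [False]
        for col, asc in (("glm_prob", False), ("ml_score", True)):
            if col in grp.columns:
                order.append(col)
                ascending.append(asc)
        order.append("embryo_id")
        ascending.append(True)
        chosen = grp.sort_values(order, ascending=ascending).iloc[0]
        p_birth = float(birth["pims_score"].iloc[0])
        p_failed = float(failed["pims_score"].mean())
        rows.append({
            "patient_id": pid,
            "chosen_embryo_id": chosen["embryo_id"],
            "correct": chosen["outcome"] == "Birth",
            "di": p_birth - p_failed,
            "p_birth": p_birth,
            "p_failed_mean": p_failed,
            "n_embryos": len(grp),
        })
    results = pd.DataFrame(rows)
    accuracy = float(results["correct"].mean())
    return results, accuracy


def di_summary(dis, alternative: str = "two-sided") -> tuple[float, float, float]:
    """Mean DI and a one-sample t-test of the DIs against zero.

    Returns (mean, t, p).  Degenerate inputs: all-zero DIs give t = 0 and
    p = 1; zero variance with a nonzero mean gives the limiting p of 0
    (two-sided and matching one-sided) with t signed infinity.
    """
    d = np.asarray(dis, dtype=float)
    if d.size < 2:
        raise ValueError("need at least two DI values")
    mean = float(d.mean())
    if np.allclose(d.std(ddof=1), 0.0):
        if np.isclose(mean, 0.0):
            return 0.0, 0.0, 1.0
        t = float(np.sign(mean) * np.inf)
        if alternative == "two-sided":
            p = 0.0
        elif alternative == "greater":
            p = 0.0 if mean > 0 else 1.0
        elif alternative == "less":
            p = 0.0 if mean < 0 else 1.0
        else:
            raise ValueError(f"unknown alternative {alternative!r}")
        return mean, t, p
    res = stats.ttest_1samp(d, 0.0, alternative=alternative)
    return mean, float(res.statistic), float(res.pvalue)
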