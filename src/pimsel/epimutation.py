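"""Promoter epimutation calling against the birth-group baseline.

A promoter of an embryo carries an *epimutation* when its methylation level
deviates strongly from what birth embryos show at that promoter, both in
absolute and in relative terms:

    AM = |value - mean(birth)|          (absolute mutation level)
    RM = AM / sd(birth)                 (relative mutation level)

with the call made when AM > 0.1 and RM > 3.  Baselines (mean and standard
deviation per promoter) are computed over all birth embryos, including — for
a birth embryo's own call — itself.  When the birth-group standard deviation
is zero and AM > 0, RM is defined as +infinity, so the call reduces to the
absolute criterion alone.

Before calling, promoters observed in fewer than 10% of samples in either
outcome group are removed, so every retained promoter has a usable baseline
and a usable failed-group comparison.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DEFAULT_AM_CUTOFF",
    "DEFAULT_RM_CUTOFF",
    "DEFAULT_MIN_GROUP_FRACTION",
    "filter_covered_promoters",
    "promoter_baselines",
    "call_epimutations",
    "embryo_epimutation_frequency",
    "promoter_group_frequency",
    "differential_epimutation",
]

DEFAULT_AM_CUTOFF = 0.1
DEFAULT_RM_CUTOFF = 3.0
DEFAULT_MIN_GROUP_FRACTION = 0.10


def _split_labels(labels: pd.Series) -> tuple[pd.Index, pd.Index]:
    birth = labels.index[labels == "Birth"]
    failed = labels.index[labels == "Failed"]
    if len(birth) == 0 or len(failed) == 0:
        raise ValueError("both outcome groups must be non-empty")
    return birth, failed


def filter_covered_promoters(matrix, labels: pd.Series,
                             min_fraction: float = DEFAULT_MIN_GROUP_FRACTION,
                             ) -> list:
    """Promoters observed in >= ``min_fraction`` of samples in BOTH groups.

    ``matrix`` is a :class:`~pimsel.methylome_io.PromoterMatrix`; ``labels``
    maps embryo_id to "Birth"/"Failed" for (a subset of) its rows.
    """
    birth, failed = _split_labels(labels)
    vals = matrix.values
    frac_birth = vals.loc[birth].notna().mean(axis=0)
    frac_failed = vals.loc[failed].notna().mean(axis=0)
    keep = (frac_birth >= min_fraction) & (frac_failed >= min_fraction)
    return list(vals.columns[keep])


def promoter_baselines(matrix, labels: pd.Series,
                       promoters=None) -> pd.DataFrame:
    """Birth-group mean and standard deviation per promoter.

    Standard deviation is the sample SD (ddof=1); promoters covered in a
    single birth embryo get sd 0.  Returns columns mean_birth, sd_birth,
    n_birth_covered indexed by promoter id.
    """
    birth, _ = _split_labels(labels)
    vals = matrix.values.loc[birth]
    if promoters is not None:
        vals = vals[list(promoters)]
    n = vals.notna().sum(axis=0)
    mean = vals.mean(axis=0)
    sd = vals.std(axis=0, ddof=1).where(n > 1, 0.0)
    out = pd.DataFrame({"mean_birth": mean, "sd_birth": sd,
                        "n_birth_covered": n.astype(int)})
    out.index.name = "promoter_id"
    return out


def call_epimutations(matrix, baselines: pd.DataFrame,
                      am_cutoff: float = DEFAULT_AM_CUTOFF,
                      rm_cutoff: float = DEFAULT_RM_CUTOFF,
                      sd_floor: float = 0.0) -> pd.DataFrame:
    """AM/RM and the epimutation flag for every non-missing matrix cell.

    Cells of promoters absent from ``baselines`` are ignored.  ``sd_floor``
    optionally bounds the baseline SD away from zero; at the default 0, a
    zero-SD promoter with AM > 0 yields RM = +inf and the call reduces to
    the AM criterion.

    Returns a long table: embryo_id, promoter_id, value, am, rm,
    is_epimutation.
    """
    vals = matrix.values[list(baselines.index)]
    mean = baselines["mean_birth"].to_numpy()
    sd = np.maximum(baselines["sd_birth"].to_numpy(), sd_floor)

    v = vals.to_numpy(dtype=float)
    am = np.abs(v - mean[None, :])
    with np.errstate(divide="ignore", invalid="ignore"):
        rm = np.where(sd[None, :] > 0, am / sd[None, :],
                      np.where(am > 0, np.inf, 0.0))
    flag = (am > am_cutoff) & (rm > rm_cutoff)

    rows, cols = np.nonzero(~np.isnan(v))
    out = pd.DataFrame({
        "embryo_id": vals.index.to_numpy()[rows],
        "promoter_id": vals.columns.to_numpy()[cols],
        "value": v[rows, cols],
        "am": am[rows, cols],
        "rm": rm[rows, cols],
        "is_epimutation": flag[rows, cols],
    })
    return out


def embryo_epimutation_frequency(calls: pd.DataFrame) -> pd.Series:
    """Per-embryo epimutation count over covered-promoter count."""
    if len(calls) == 0:
        raise ValueError("no epimutation calls supplied")
    grp = calls.groupby("embryo_id")["is_epimutation"]
    freq = grp.sum() / grp.count()
    freq.name = "epimutation_frequency"
    return freq


def promoter_group_frequency(calls: pd.DataFrame,
                             labels: pd.Series) -> pd.DataFrame:
    """Per-promoter epimutated-sample fraction in each outcome group.

    Returns columns birth_epi, birth_covered, failed_epi, failed_covered,
    birth_freq, failed_freq.  Promoters must have been coverage-filtered so
    that both groups have covered samples at every promoter.
    """
    birth, failed = _split_labels(labels)
    lab = calls["embryo_id"].map(labels)
    out = {}
    for name, mask in (("birth", lab == "Birth"), ("failed", lab == "Failed")):
        grp = calls.loc[mask].groupby("promoter_id")["is_epimutation"]
        out[f"{name}_epi"] = grp.sum()
        out[f"{name}_covered"] = grp.count()
    tab = pd.DataFrame(out)
    if tab.isna().any().any() or (tab[["birth_covered", "failed_covered"]] == 0).any().any():
        raise ValueError("promoter without covered samples in one group; "
                         "run filter_covered_promoters first")
    tab = tab.astype(int)
    tab["birth_freq"] = tab["birth_epi"] / tab["birth_covered"]
    tab["failed_freq"] = tab["failed_epi"] / tab["failed_covered"]
    tab.index.name = "promoter_id"
    return tab


def differential_epimutation(freqs: pd.DataFrame, alpha: float = 0.05,
                             bh_correct: bool = False) -> pd.DataFrame:
    """Failed-minus-birth frequency difference and two-sided Fisher p-value.

    For each promoter the 2x2 table (epimutated / not) x (failed / birth)
    is tested with the two-sided Fisher exact test.  ``higher_in_failed``
    flags promoters with a positive difference and p < ``alpha``; when
    ``bh_correct`` is set, the flag uses Benjamini-Hochberg adjusted p-values
    instead (off by default).
    """
    out = freqs.copy()
    out["diff"] = out["failed_freq"] - out["birth_freq"]
    pvals = np.empty(len(out))
    for i, (_, r) in enumerate(out.iterrows()):
        table = [[int(r["failed_epi"]), int(r["failed_covered"] - r["failed_epi"])],
                 [int(r["birth_epi"]), int(r["birth_covered"] - r["birth_epi"])]]
        pvals[i] = stats.fisher_exact(table, alternative="two-sided")[1]
    out["p_value"] = pvals
    if bh_correct:
        from statsmodels.stats.multitest import multipletests
        out["p_adj"] = multipletests(pvals, method="fdr_bh")[1]
        crit = out["p_adj"] < alpha
    else:
        crit = out["p_value"] < alpha
    out["higher_in_failed"] = (out["diff"] > 0) & crit
    return out
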