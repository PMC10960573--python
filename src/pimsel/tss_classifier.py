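"""Promoter-signature classifier producing TSS-scores.

The TSS-score of an embryo is a predicted live-birth probability obtained
from its promoter methylation profile.  The procedure, end to end:

1. *Feature selection.*  On the training embryos only, each promoter is
   tested for a birth-vs-failed difference with a one-way ANOVA and a
   two-sided Wilcoxon rank-sum test; promoters significant at ``alpha`` in
   either test are kept (union rule).
2. *Model.*  Gradient-boosted decision trees (scikit-learn
   ``GradientBoostingClassifier`` with library-default hyperparameters).
   Because the small sample size makes single fits seed-sensitive, an
   ensemble of more than 10 fits with distinct seeds is trained and the
   final TSS-score is the mean of the member probabilities.
3. *Cross-validation.*  Repeated stratified 5-fold CV; feature selection
   and median imputation are re-run inside every training fold so no
   information leaks from held-out embryos.  Each embryo's cross-validated
   score is its out-of-fold prediction averaged over repeats.
4. *Noise-label cleaning.*  Clinical outcome labels are noisy (a failure
   can be unrelated to embryo quality).  The cleaning loop computes
   cross-validated scores, assigns each embryo the noise probability
   ``N = |label - score|``, removes the failed-labelled embryo with maximal
   N, and repeats — stopping after a fixed small number of removals to
   avoid over-filtering.  Birth-labelled embryos are never removed.

Missing promoter values (coverage-filtered cells) are imputed with the
training-set median of the feature; an all-missing feature falls back to a
neutral level of 0.5.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.model_selection import StratifiedKFold

from .metrics import auc_score

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_ALPHA",
    "DEFAULT_N_REPEATS",
    "DEFAULT_N_FOLDS",
    "MIN_ENSEMBLE_REPEATS",
    "FeatureSet",
    "TrainedScorer",
    "CleaningResult",
    "encode_labels",
    "select_features",
    "fit_scorer",
    "tss_score",
    "cross_validated_scores",
    "clean_noise",
]

DEFAULT_ALPHA = 0.05
DEFAULT_N_REPEATS = 20
DEFAULT_N_FOLDS = 5
#: The ensemble/CV repeat count must strictly exceed this floor.
MIN_ENSEMBLE_REPEATS = 10
_NEUTRAL_LEVEL = 0.5


def encode_labels(outcomes) -> pd.Series:
    """Map Birth/Failed outcome labels to 1/0."""
    s = pd.Series(outcomes)
    bad = set(s.unique()) - {"Birth", "Failed"}
    if bad:
        raise ValueError(f"unknown outcome labels {sorted(bad)}")
    return (s == "Birth").astype(int)


@dataclass(frozen=True)
class FeatureSet:
    """Promoters retained for classification, with their selection p-values."""

    promoters: tuple
    p_anova: pd.Series
    p_ranksum: pd.Series

    def __len__(self):
        return len(self.promoters)


def select_features(X: pd.DataFrame, y, alpha: float = DEFAULT_ALPHA) -> FeatureSet:
    """Union-rule feature selection: ANOVA p < alpha OR rank-sum p < alpha.

    ``X`` is embryos x promoters with NaN for missing cells; ``y`` is the
    0/1 outcome vector aligned with the rows.  Tests run on the non-missing
    values of each promoter; promoters that are constant, or observed in
    fewer than two embryos of either class, cannot be significant and are
    never selected.
    """
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("feature selection requires both classes")
    g1 = X.loc[y == 1].to_numpy(dtype=float)
    g0 = X.loc[y == 0].to_numpy(dtype=float)

    # scipy's nan_policy="omit" path is orders of magnitude slower than the
    # dense one; run it only on the columns that actually contain NaNs
    has_nan = np.isnan(g1).any(axis=0) | np.isnan(g0).any(axis=0)
    p_anova = np.empty(X.shape[1])
    p_ranksum = np.empty(X.shape[1])
    with np.errstate(invalid="ignore", divide="ignore"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if (~has_nan).any():
                d1, d0 = g1[:, ~has_nan], g0[:, ~has_nan]
                p_anova[~has_nan] = stats.f_oneway(d1, d0, axis=0).pvalue
                p_ranksum[~has_nan] = stats.mannwhitneyu(
                    d1, d0, axis=0, alternative="two-sided").pvalue
            if has_nan.any():
                n1, n0 = g1[:, has_nan], g0[:, has_nan]
                p_anova[has_nan] = stats.f_oneway(
                    n1, n0, axis=0, nan_policy="omit").pvalue
                p_ranksum[has_nan] = stats.mannwhitneyu(
                    n1, n0, axis=0, nan_policy="omit",
                    alternative="two-sided").pvalue
    p_anova = np.asarray(p_anova, dtype=float)
    p_ranksum = np.asarray(p_ranksum, dtype=float)

    # degenerate columns (too few observations, zero variance) yield NaN
    enough = ((~np.isnan(g1)).sum(axis=0) >= 2) & ((~np.isnan(g0)).sum(axis=0) >= 2)
    p_anova = np.where(np.isnan(p_anova) | ~enough, 1.0, p_anova)
    p_ranksum = np.where(np.isnan(p_ranksum) | ~enough, 1.0, p_ranksum)

    keep = (p_anova < alpha) | (p_ranksum < alpha)
    cols = X.columns
    return FeatureSet(
        promoters=tuple(cols[keep]),
        p_anova=pd.Series(p_anova, index=cols, name="p_anova"),
        p_ranksum=pd.Series(p_ranksum, index=cols, name="p_ranksum"),
    )


def _median_imputer(X: pd.DataFrame) -> pd.Series:
    med = X.median(axis=0)
    return med.fillna(_NEUTRAL_LEVEL)


def _impute(X: pd.DataFrame, medians: pd.Series) -> np.ndarray:
    return X.fillna(medians).to_numpy(dtype=float)


def _spawn_seeds(master_seed: int, n: int) -> list[int]:
    """Expand a master seed into n distinct 31-bit child seeds."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s) % (2 ** 31) for s in ss.generate_state(n)]


@dataclass
class TrainedScorer:
    """Ensemble of boosted-tree classifiers plus its preprocessing state."""

    features: FeatureSet
    medians: pd.Series
    models: list = field(repr=False, default_factory=list)
    train_ids: tuple = ()
    seeds: tuple = ()
    constant_score: float | None = None  # fallback when no feature passed

    @property
    def n_repeats(self) -> int:
        return len(self.models) if self.constant_score is None else len(self.seeds)


def fit_scorer(X: pd.DataFrame, y, features: FeatureSet | None = None,
               n_repeats: int = DEFAULT_N_REPEATS, seed: int = 0,
               alpha: float = DEFAULT_ALPHA) -> TrainedScorer:
    """Fit the TSS-score ensemble on a training set.

    ``n_repeats`` boosted-tree classifiers are fitted with distinct seeds
    derived from ``seed``; predictions later average over the ensemble.
    ``n_repeats`` must exceed 10.  When ``features`` is omitted, selection
    runs on the supplied training data.  If no promoter passes selection,
    the scorer degrades to a constant prediction at the training birth rate.
    """
    if n_repeats <= MIN_ENSEMBLE_REPEATS:
        raise ValueError(f"n_repeats must exceed {MIN_ENSEMBLE_REPEATS}")
    y = np.asarray(y, dtype=int)
    if min((y == 0).sum(), (y == 1).sum()) < 2:
        raise ValueError("need at least 2 embryos per class")
    if features is None:
        features = select_features(X, y, alpha=alpha)
    seeds = _spawn_seeds(seed, n_repeats)

    if len(features) == 0:
        logger.warning("no promoter passed feature selection; "
                       "scoring falls back to the training birth rate")
        return TrainedScorer(features=features, medians=pd.Series(dtype=float),
                             train_ids=tuple(X.index), seeds=tuple(seeds),
                             constant_score=float(y.mean()))

    Xf = X[list(features.promoters)]
    medians = _median_imputer(Xf)
    Xi = _impute(Xf, medians)
    models = []
    for s in seeds:
        clf = GradientBoostingClassifier(random_state=s)
        clf.fit(Xi, y)
        models.append(clf)
    return TrainedScorer(features=features, medians=medians, models=models,
                         train_ids=tuple(X.index), seeds=tuple(seeds))


def tss_score(scorer: TrainedScorer, X: pd.DataFrame) -> pd.Series:
    """Ensemble-mean predicted birth probability for each embryo in ``X``.

    Missing or unseen feature values are imputed with the training medians;
    they are never rejected.
    """
    if scorer.constant_score is not None:
        return pd.Series(scorer.constant_score, index=X.index, name="tss_score")
    cols = list(scorer.features.promoters)
    Xf = X.reindex(columns=cols)
    Xi = _impute(Xf, scorer.medians)
    preds = np.mean([m.predict_proba(Xi)[:, 1] for m in scorer.models], axis=0)
    return pd.Series(preds, index=X.index, name="tss_score")


def _single_fit_predict(Xtr: pd.DataFrame, ytr: np.ndarray, Xte: pd.DataFrame,
                        seed: int, alpha: float, select: bool,
                        features: FeatureSet | None) -> np.ndarray:
    """One boosted-tree fit inside a CV fold, honouring fold-local selection."""
    if select:
        features = select_features(Xtr, ytr, alpha=alpha)
    if features is None or len(features) == 0:
        return np.full(len(Xte), float(ytr.mean()))
    cols = list(features.promoters)
    med = _median_imputer(Xtr[cols])
    clf = GradientBoostingClassifier(random_state=seed)
    clf.fit(_impute(Xtr[cols], med), ytr)
    return clf.predict_proba(_impute(Xte.reindex(columns=cols), med))[:, 1]


def cross_validated_scores(X: pd.DataFrame, y,
                           n_repeats: int = DEFAULT_N_REPEATS,
                           n_folds: int = DEFAULT_N_FOLDS, seed: int = 0,
                           alpha: float = DEFAULT_ALPHA,
                           select_in_folds: bool = True,
                           features: FeatureSet | None = None) -> pd.DataFrame:
    """Repeated stratified k-fold out-of-fold TSS-scores.

    Each repeat draws a fresh fold partition; every embryo receives exactly
    one out-of-fold prediction per repeat.  The returned frame has one
    column per repeat plus ``score`` (the across-repeat mean).

    ``select_in_folds=True`` (default, leakage-free) reruns feature
    selection within every training fold.  Setting it to False with a
    precomputed ``features`` reproduces the leaky variant where promoters
    were chosen on the full dataset; it exists for diagnostics only.
    """
    if n_repeats <= MIN_ENSEMBLE_REPEATS:
        raise ValueError(f"n_repeats must exceed {MIN_ENSEMBLE_REPEATS}")
    y = np.asarray(y, dtype=int)
    if min((y == 0).sum(), (y == 1).sum()) < n_folds:
        raise ValueError("each class needs at least n_folds embryos")
    seeds = _spawn_seeds(seed, 2 * n_repeats)
    preds = np.empty((len(X), n_repeats))
    for r in range(n_repeats):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                              random_state=seeds[2 * r])
        for tr_idx, te_idx in skf.split(np.zeros(len(y)), y):
            if len(np.unique(y[tr_idx])) < 2:  # pragma: no cover - stratified
                raise RuntimeError("single-class training fold")
            preds[te_idx, r] = _single_fit_predict(
                X.iloc[tr_idx], y[tr_idx], X.iloc[te_idx],
                seed=seeds[2 * r + 1], alpha=alpha,
                select=select_in_folds, features=features)
    out = pd.DataFrame(preds, index=X.index,
                       columns=[f"repeat_{r}" for r in range(n_repeats)])
    out["score"] = preds.mean(axis=1)
    return out


@dataclass
class CleaningResult:
    """Outcome of the iterative noise-label cleaning loop."""

    kept_ids: tuple
    history: pd.DataFrame      # iteration, removed_id, noise_prob, cv_auc
    final_scores: pd.DataFrame | None


def clean_noise(X: pd.DataFrame, y: pd.Series,
                max_removals: int = 5,
                n_repeats: int = DEFAULT_N_REPEATS,
                n_folds: int = DEFAULT_N_FOLDS, seed: int = 0,
                alpha: float = DEFAULT_ALPHA,
                final_cv: bool = True) -> CleaningResult:
    """Iteratively remove the most noise-like failed-labelled embryos.

    Each iteration computes cross-validated scores on the current training
    set, assigns every embryo the noise probability ``N = |label - score|``,
    and removes the failed-labelled embryo with the largest N (ties broken
    by lexicographically smallest embryo id).  Birth-labelled embryos are
    never removed.  The loop stops after ``max_removals`` removals — an
    early stop against over-filtering — and records the cross-validated AUC
    of every iteration as a learning curve.  ``final_cv=False`` skips the
    closing CV round on the cleaned set when the curve endpoint is not
    needed.
    """
    y = pd.Series(np.asarray(y, dtype=int), index=X.index)
    n_failed = int((y == 0).sum())
    if max_removals < 0:
        raise ValueError("max_removals must be non-negative")
    if max_removals >= n_failed:
        raise ValueError("max_removals must be smaller than the number of "
                         "failed-labelled embryos")
    if max_removals == 0:
        empty = pd.DataFrame(columns=["iteration", "removed_id",
                                      "noise_prob", "cv_auc"])
        return CleaningResult(kept_ids=tuple(X.index), history=empty,
                              final_scores=None)
    seeds = _spawn_seeds(seed, max_removals + 1)

    cur = X.index.to_list()
    records = []
    final_scores = None
    n_rounds = max_removals + 1 if final_cv else max_removals
    for it in range(n_rounds):
        Xc, yc = X.loc[cur], y.loc[cur]
        scores = cross_validated_scores(Xc, yc, n_repeats=n_repeats,
                                        n_folds=n_folds, seed=seeds[it],
                                        alpha=alpha)
        cv_auc = auc_score(yc.to_numpy(), scores["score"].to_numpy())
        final_scores = scores
        if it == max_removals:
            records.append({"iteration": it, "removed_id": None,
                            "noise_prob": np.nan, "cv_auc": cv_auc})
            break
        noise = (yc - scores["score"]).abs()
        failed = noise[yc == 0]
        # max noise probability; ties -> smallest embryo id
        top = failed[np.isclose(failed, failed.max())].sort_index().index[0]
        records.append({"iteration": it, "removed_id": top,
                        "noise_prob": float(noise[top]), "cv_auc": cv_auc})
        cur.remove(top)
    history = pd.DataFrame(records)
    return CleaningResult(kept_ids=tuple(cur), history=history,
                          final_scores=final_scores)
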