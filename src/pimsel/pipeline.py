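"""End-to-end orchestration: from CpG call files to a selection report.

``run_pipeline`` executes every stage in order — input parsing, whole-genome
scoring and GLM calibration, retrospective patient evaluation, epimutation
analysis, classifier training with noise-label cleaning, score combination
and simulated selection — writing each stage's table plus a machine-readable
``summary.json`` into the run directory.  All randomness derives from one
master seed, so a rerun with the same config reproduces every output
byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (cohort_eval, epimutation, linear_model, methylome_io,
               selector, tss_classifier)
from .metrics import auc_score

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "split_train_test", "run_pipeline"]


@dataclass
class RunConfig:
    """Paths, thresholds, repeat counts and the master seed of one run."""

    calls_dir: str = ""
    annotation: str = ""
    sample_sheet: str = ""
    out_dir: str = "pimsel_run"

    optimum_ml: float = linear_model.DEFAULT_OPTIMUM_ML
    quality_threshold: float = cohort_eval.DEFAULT_QUALITY_THRESHOLD
    min_coverage: int = 30
    min_group_fraction: float = epimutation.DEFAULT_MIN_GROUP_FRACTION
    am_cutoff: float = epimutation.DEFAULT_AM_CUTOFF
    rm_cutoff: float = epimutation.DEFAULT_RM_CUTOFF
    alpha: float = tss_classifier.DEFAULT_ALPHA
    max_removals: int = 5
    weights: tuple = selector.DEFAULT_WEIGHTS

    n_repeats_fit: int = tss_classifier.DEFAULT_N_REPEATS
    n_repeats_cv: int = tss_classifier.DEFAULT_N_REPEATS
    n_folds: int = tss_classifier.DEFAULT_N_FOLDS
    seed: int = 0

    def validate(self) -> None:
        for name in ("quality_threshold", "min_coverage", "min_group_fraction",
                     "am_cutoff", "rm_cutoff", "alpha"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.max_removals < 0:
            raise ValueError("max_removals must be non-negative")
        w = tuple(self.weights)
        if len(w) != 2 or min(w) < 0 or sum(w) == 0:
            raise ValueError("weights must be two non-negative numbers")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        cfg = cls(**data)
        cfg.weights = tuple(cfg.weights)
        return cfg

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["weights"] = list(self.weights)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


def split_train_test(samples: pd.DataFrame) -> tuple[list, list]:
    """Patient-disjoint train/test split by transfer history.

    Test embryos are all embryos of patients who underwent two or more
    transfers and whose final transfer (highest transfer order) resulted in
    a live birth; everything else is training data.  The two sets are
    patient-disjoint by construction.
    """
    test_ids, train_ids = [], []
    for _, grp in samples.groupby("patient_id", sort=True):
        last = grp.loc[grp["transfer_order"].idxmax()]
        if len(grp) >= 2 and last["outcome"] == "Birth":
            test_ids.extend(grp["embryo_id"])
        else:
            train_ids.extend(grp["embryo_id"])
    assert not set(train_ids) & set(test_ids)
    return train_ids, test_ids


def _stage(name):
    logger.info("stage: %s", name)


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write all outputs under ``config.out_dir``.

    Returns the summary dict (also written as ``summary.json``).  Any stage
    failure propagates with the stage named in the log.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "resolved_config.yaml")

    log_handler = logging.FileHandler(out / "run.log", mode="w")
    log_handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("pimsel")
    root.addHandler(log_handler)
    root.setLevel(logging.INFO)
    summary: dict = {"seed": config.seed}
    try:
        _log_versions()

        _stage("methylome_io")
        samples = methylome_io.read_sample_sheet(config.sample_sheet)
        regions = methylome_io.read_promoter_annotation(config.annotation)
        calls = {e: methylome_io.read_cpg_calls(Path(config.calls_dir) / f"{e}.bedgraph")
                 for e in samples["embryo_id"]}
        summary["n_embryos"] = len(samples)
        summary["n_patients"] = int(samples["patient_id"].nunique())
        summary["n_promoters_annotated"] = len(regions)

        _stage("linear_model")
        ml = pd.Series({e: methylome_io.whole_genome_ml(c)
                        for e, c in calls.items()}, name="ml")
        scores = samples.set_index("embryo_id").copy()
        scores["ml"] = ml
        scores["ml_score"] = linear_model.ml_score(scores["ml"].to_numpy(),
                                                   optimum=config.optimum_ml)
        y_all = tss_classifier.encode_labels(scores["outcome"])
        fit = linear_model.fit_outcome_glm(scores["ml_score"], y_all)
        scores["glm_prob"] = linear_model.predict_birth_probability(
            fit, scores["ml_score"].to_numpy())["prob"].to_numpy()
        summary["glm"] = {"intercept": fit.intercept, "slope": fit.slope,
                          "se_intercept": fit.se_intercept,
                          "se_slope": fit.se_slope}

        _stage("cohort_eval")
        evals = cohort_eval.evaluate_patients(
            scores.reset_index(), threshold=config.quality_threshold)
        summary["patients_evaluated"] = len(evals)
        if len(evals):
            evals.to_csv(out / "patient_eval.tsv", sep="\t", index=False)
            tab = cohort_eval.group_outcome_table(evals)
            tab.to_csv(out / "group_outcomes.tsv", sep="\t")
            summary["group_counts"] = {g: int(tab.loc[g].sum()) for g in tab.index}
            sup, inf = tab.loc["superior"], tab.loc["inferior"]
            if sup.sum() and inf.sum():
                _, p = cohort_eval.compare_groups(
                    [[sup["Birth"], sup["Failed"]],
                     [inf["Birth"], inf["Failed"]]])
                summary["superior_vs_inferior_birth_p"] = p

        _stage("epimutation")
        matrix = methylome_io.build_promoter_matrix(
            calls, regions, min_coverage=config.min_coverage)
        labels = scores["outcome"]
        kept = epimutation.filter_covered_promoters(
            matrix, labels, min_fraction=config.min_group_fraction)
        summary["n_promoters_covered"] = len(kept)
        baselines = epimutation.promoter_baselines(matrix, labels, promoters=kept)
        epi_calls = epimutation.call_epimutations(
            matrix, baselines, am_cutoff=config.am_cutoff,
            rm_cutoff=config.rm_cutoff)
        epi_calls.to_csv(out / "epimutation_calls.tsv", sep="\t", index=False)
        freqs = epimutation.embryo_epimutation_frequency(epi_calls)
        grp_freq = epimutation.promoter_group_frequency(epi_calls, labels)
        diff = epimutation.differential_epimutation(grp_freq)
        diff.to_csv(out / "differential_promoters.tsv", sep="\t")
        summary["n_promoters_higher_in_failed"] = int(diff["higher_in_failed"].sum())
        summary["mean_epimutation_freq"] = {
            "Birth": float(freqs[labels == "Birth"].mean()),
            "Failed": float(freqs[labels == "Failed"].mean()),
        }

        _stage("tss_classifier")
        train_ids, test_ids = split_train_test(samples)
        summary["n_train"] = len(train_ids)
        summary["n_test"] = len(test_ids)
        X = matrix.values
        y = y_all
        n_failed_train = int((y.loc[train_ids] == 0).sum())
        if config.max_removals >= n_failed_train:
            raise ValueError(
                f"max_removals={config.max_removals} must be below the "
                f"failed-embryo count in the train set ({n_failed_train})")
        cleaning = tss_classifier.clean_noise(
            X.loc[train_ids], y.loc[train_ids],
            max_removals=config.max_removals, n_repeats=config.n_repeats_cv,
            n_folds=config.n_folds, seed=config.seed, alpha=config.alpha)
        cleaning.history.to_csv(out / "cleaning_history.tsv", sep="\t",
                                index=False)
        kept_ids = list(cleaning.kept_ids)
        if len(cleaning.history):
            summary["cv_auc_before_cleaning"] = float(
                cleaning.history["cv_auc"].iloc[0])
            summary["cv_auc_after_cleaning"] = float(
                cleaning.history["cv_auc"].iloc[-1])
            cv_final = cleaning.final_scores["score"]
        else:
            cv = tss_classifier.cross_validated_scores(
                X.loc[kept_ids], y.loc[kept_ids],
                n_repeats=config.n_repeats_cv, n_folds=config.n_folds,
                seed=config.seed, alpha=config.alpha)
            cv_final = cv["score"]
            summary["cv_auc_after_cleaning"] = auc_score(
                y.loc[kept_ids], cv_final)
        scorer = tss_classifier.fit_scorer(
            X.loc[kept_ids], y.loc[kept_ids],
            n_repeats=config.n_repeats_fit, seed=config.seed,
            alpha=config.alpha)
        summary["n_selected_features"] = len(scorer.features)
        scores["tss_score"] = np.nan
        scores.loc[cv_final.index, "tss_score"] = cv_final
        if test_ids:
            scores.loc[test_ids, "tss_score"] = tss_classifier.tss_score(
                scorer, X.loc[test_ids])
            if y.loc[test_ids].nunique() == 2:
                summary["test_auc_tss"] = auc_score(
                    y.loc[test_ids], scores.loc[test_ids, "tss_score"])
        # embryos dropped by cleaning still get an (in-sample) ensemble score
        remaining = scores.index[scores["tss_score"].isna()]
        if len(remaining):
            scores.loc[remaining, "tss_score"] = tss_classifier.tss_score(
                scorer, X.loc[remaining])

        _stage("selector")
        scores["pims_score"] = selector.combine_scores(
            scores["tss_score"].to_numpy(),
            scores["glm_prob"].to_numpy(), weights=config.weights)
        scores["split"] = np.where(scores.index.isin(test_ids), "test", "train")
        scores.reset_index().to_csv(out / "scores.tsv", sep="\t", index=False)
        if test_ids:
            test_scores = scores.loc[test_ids].reset_index()
            if y.loc[test_ids].nunique() == 2:
                summary["test_auc_pims"] = auc_score(
                    y.loc[test_ids], scores.loc[test_ids, "pims_score"])
            eligible = test_scores.groupby("patient_id").filter(
                lambda g: (g["outcome"] == "Birth").sum() == 1
                and (g["outcome"] == "Failed").sum() >= 1)
            summary["n_selection_patients"] = int(
                eligible["patient_id"].nunique())
            if len(eligible):
                results, accuracy = selector.simulate_selection(eligible)
                results.to_csv(out / "selection.tsv", sep="\t", index=False)
                summary["selection_accuracy"] = accuracy
                summary["n_selection_correct"] = int(results["correct"].sum())
                if len(results) >= 2:
                    mean_di, t, p = selector.di_summary(results["di"])
                    summary["mean_di"] = mean_di
                    summary["di_t"] = t
                    summary["di_p"] = p
    except Exception:
        logger.exception("pipeline failed")
        raise
    finally:
        root.removeHandler(log_handler)
        log_handler.close()

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary


def _log_versions() -> None:
    import sklearn
    import scipy
    import statsmodels
    logger.info("versions: numpy=%s pandas=%s scipy=%s sklearn=%s statsmodels=%s",
                np.__version__, pd.__version__, scipy.__version__,
                sklearn.__version__, statsmodels.__version__)
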