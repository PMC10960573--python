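"""Synthetic embryo-methylome cohorts for testing the screening pipeline.

Real preimplantation methylome cohorts are small clinical datasets that are
not publicly deposited, so every downstream stage of this package is
exercised on simulated cohorts that reproduce the statistical structure the
pipeline assumes:

* each embryo has a latent whole-genome methylation level (ML) distributed
  around an optimum (default 0.26), drawn as optimum + a random-signed
  half-normal deviation, giving a unimodal level distribution with a tail of
  large deviations;
* the true live-birth outcome is Bernoulli with
  ``logit(p) = glm_intercept + glm_slope * |ML - optimum|``, so birth
  probability decays logistically with the deviation score;
* a designated subset of promoters is epimutation-prone: embryos carry a
  methylation shift of ``+/- epimut_shift`` there, at a higher per-promoter
  rate in truly failed embryos than in birth embryos, producing recurrent
  differential epimutations;
* the recorded clinical label equals the true outcome except for a small
  fraction of flipped (noisy) labels;
* per-CpG read coverage is Poisson and methylated counts are binomial around
  the local methylation level, so coverage-based filters operate on
  realistic counts.

Patients receive 1-4 embryos; one embryo per patient is marked as the
historically selected (transferred first) embryo uniformly at random.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import methylome_io

logger = logging.getLogger(__name__)

__all__ = ["CohortConfig", "SyntheticCohort", "generate_cohort", "write_fixture"]


@dataclass(frozen=True)
class CohortConfig:
    """Generative parameters of a synthetic cohort.

    The defaults describe the study conditions the pipeline targets: an
    optimal whole-genome level of 0.26, a steep logistic decay of birth
    probability with the deviation score, and a failed-embryo excess of
    promoter epimutations concentrated on a prone promoter subset.
    """

    n_patients: int = 64
    embryos_min: int = 1
    embryos_max: int = 4
    n_promoters: int = 2000
    cpgs_per_promoter: int = 6
    n_background_cpgs: int = 4000
    optimum_ml: float = 0.26
    ml_scale: float = 0.05           # half-normal scale of |ML - optimum|
    glm_intercept: float = 1.5       # logit scale
    glm_slope: float = -30.0         # logit per ML-score unit; negative
    epimut_rate_birth: float = 0.02  # per prone promoter, birth embryos
    epimut_rate_failed: float = 0.15  # per prone promoter, failed embryos
    epimut_shift: float = 0.20       # methylation delta of a planted epimutation
    epimut_promoter_fraction: float = 0.10  # fraction of promoters that are prone
    promoter_noise_sd: float = 0.03  # embryo-level noise around promoter baselines
    label_flip_rate: float = 0.03    # recorded label != true outcome
    coverage_mean: float = 8.0       # Poisson mean reads per CpG
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be positive")
        if not (1 <= self.embryos_min <= self.embryos_max):
            raise ValueError("embryo range must satisfy 1 <= min <= max")
        for name in ("n_promoters", "cpgs_per_promoter", "n_background_cpgs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        for name in ("epimut_rate_birth", "epimut_rate_failed",
                     "label_flip_rate", "optimum_ml",
                     "epimut_promoter_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.epimut_rate_failed < self.epimut_rate_birth:
            raise ValueError("epimut_rate_failed must be >= epimut_rate_birth")
        if self.coverage_mean <= 0:
            raise ValueError("coverage_mean must be positive")
        if self.ml_scale < 0 or self.promoter_noise_sd < 0:
            raise ValueError("scales must be non-negative")

    def with_seed(self, seed: int) -> "CohortConfig":
        return replace(self, seed=seed)


# genome layout: promoters every PROMOTER_SPACING bp on one chromosome,
# background CpGs in the downstream intergenic space
PROMOTER_SPACING = 6000
FIRST_TSS = 5000
BACKGROUND_STEP = 50
CHROM = "chr1"


@dataclass
class SyntheticCohort:
    """In-memory synthetic cohort: metadata, truth table and CpG counts."""

    config: CohortConfig
    samples: pd.DataFrame          # sample sheet (recorded labels)
    truth: pd.DataFrame            # per-embryo latent ML, true/recorded outcome, flips
    promoters: pd.DataFrame        # 6-column BED-like annotation
    prone_promoters: list          # promoter ids carrying planted epimutations
    promoter_levels: pd.DataFrame  # latent per-cell methylation level (pre-sampling)
    cpg_pos: np.ndarray            # shared CpG positions on CHROM
    cpg_coverage: np.ndarray       # embryos x CpGs read depth
    cpg_meth: np.ndarray           # embryos x CpGs methylated reads
    _n_promoter_cpgs: int = field(repr=False, default=0)

    @property
    def embryo_ids(self):
        return list(self.samples["embryo_id"])

    def calls_frame(self, embryo_id: str) -> pd.DataFrame:
        """CpG calls of one embryo in the 4-column input layout (covered only)."""
        i = self.embryo_ids.index(embryo_id)
        cov = self.cpg_coverage[i]
        keep = cov > 0
        return pd.DataFrame({
            "chrom": CHROM,
            "pos": self.cpg_pos[keep],
            "meth_count": self.cpg_meth[i, keep],
            "total_count": cov[keep],
        })

    def calls_by_embryo(self) -> dict:
        return {e: self.calls_frame(e) for e in self.embryo_ids}

    def whole_genome_ml(self) -> pd.Series:
        """Observed whole-genome level per embryo (mean beta over covered CpGs)."""
        cov = self.cpg_coverage.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            beta = np.where(cov > 0, self.cpg_meth / cov, np.nan)
        return pd.Series(np.nanmean(beta, axis=1), index=self.embryo_ids,
                         name="ml")

    def promoter_matrix(self, min_coverage: int = 30) -> methylome_io.PromoterMatrix:
        """Promoter matrix computed directly from the stored count arrays.

        Equivalent (within float tolerance) to writing the cohort to disk and
        aggregating the CpG files with :mod:`pimsel.methylome_io`.
        """
        k = self.config.cpgs_per_promoter
        npro = self.config.n_promoters
        cov = self.cpg_coverage[:, :npro * k].reshape(len(self.embryo_ids), npro, k)
        meth = self.cpg_meth[:, :npro * k].reshape(len(self.embryo_ids), npro, k)
        with np.errstate(invalid="ignore", divide="ignore"):
            beta = np.where(cov > 0, meth / cov.astype(float), np.nan)
        with np.errstate(invalid="ignore"):
            vals = np.nanmean(beta, axis=2)
        total = cov.sum(axis=2)
        gene_ids = list(self.promoters["gene_id"])
        idx = pd.Index(self.embryo_ids, name="embryo_id")
        return methylome_io.PromoterMatrix(
            pd.DataFrame(vals, index=idx, columns=gene_ids),
            pd.DataFrame(total, index=idx, columns=gene_ids),
            min_coverage=min_coverage,
        )


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Draw a full synthetic cohort from the generative model.

    Output is byte-deterministic in ``config.seed``: the same configuration
    always yields identical samples, truth table and CpG counts.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    # --- patients and embryos -------------------------------------------
    n_per = rng.integers(config.embryos_min, config.embryos_max + 1,
                         size=config.n_patients)
    n = int(n_per.sum())
    patient_ids = np.repeat([f"P{i:04d}" for i in range(config.n_patients)], n_per)
    embryo_ids = np.array([f"E{i:05d}" for i in range(n)])

    dev = np.abs(rng.standard_normal(n)) * config.ml_scale
    sign = rng.choice([-1.0, 1.0], size=n)
    ml_true = np.clip(config.optimum_ml + sign * dev, 0.001, 0.999)
    score = np.abs(ml_true - config.optimum_ml)
    p_birth = 1.0 / (1.0 + np.exp(-(config.glm_intercept
                                    + config.glm_slope * score)))
    true_birth = rng.random(n) < p_birth
    flipped = rng.random(n) < config.label_flip_rate
    recorded_birth = true_birth ^ flipped

    transfer_order = np.empty(n, dtype=int)
    selected = np.zeros(n, dtype=bool)
    start = 0
    ages = np.clip(rng.normal(33.7, 3.5, size=config.n_patients), 25.0, 43.0)
    age_per_embryo = np.repeat(np.round(ages, 1), n_per)
    for k in n_per:
        order = rng.permutation(k) + 1
        transfer_order[start:start + k] = order
        selected[start + int(rng.integers(k))] = True
        start += k

    samples = pd.DataFrame({
        "embryo_id": embryo_ids,
        "patient_id": patient_ids,
        "outcome": np.where(recorded_birth, "Birth", "Failed"),
        "transfer_order": transfer_order,
        "selected": selected,
        "maternal_age": age_per_embryo,
    })
    truth = pd.DataFrame({
        "embryo_id": embryo_ids,
        "ml_true": ml_true,
        "true_outcome": np.where(true_birth, "Birth", "Failed"),
        "recorded_outcome": samples["outcome"],
        "flipped": flipped,
    })

    # --- promoter annotation and latent levels --------------------------
    npro = config.n_promoters
    tss = FIRST_TSS + PROMOTER_SPACING * np.arange(npro)
    strand = np.where(np.arange(npro) % 2 == 0, "+", "-")
    gene_ids = [f"G{i:05d}" for i in range(npro)]
    promoters = pd.DataFrame({
        "chrom": CHROM,
        "start": np.where(strand == "+", tss, tss - 2000),
        "end": np.where(strand == "+", tss + 2000, tss + 1),
        "gene_id": gene_ids,
        "score": 0,
        "strand": strand,
    })

    # promoter baselines average ~optimum so the genome-wide mean tracks
    # the latent ML (promoters are mostly lowly methylated)
    baseline = rng.beta(1.3, 3.7, size=npro)
    n_prone = max(1, int(round(config.epimut_promoter_fraction * npro)))
    prone_idx = np.sort(rng.choice(npro, size=n_prone, replace=False))
    prone_ids = [gene_ids[i] for i in prone_idx]

    levels = (baseline[None, :]
              + (ml_true - config.optimum_ml)[:, None]
              + rng.normal(0.0, config.promoter_noise_sd, size=(n, npro)))
    rate = np.where(true_birth, config.epimut_rate_birth,
                    config.epimut_rate_failed)
    epi = np.zeros((n, npro), dtype=bool)
    epi[:, prone_idx] = rng.random((n, n_prone)) < rate[:, None]
    shift_sign = rng.choice([-1.0, 1.0], size=(n, npro))
    levels = levels + epi * shift_sign * config.epimut_shift
    levels = np.clip(levels, 0.01, 0.99)
    promoter_levels = pd.DataFrame(levels, index=pd.Index(embryo_ids,
                                                          name="embryo_id"),
                                   columns=gene_ids)
    truth["n_epimutations"] = epi.sum(axis=1)

    # --- CpG layer -------------------------------------------------------
    k = config.cpgs_per_promoter
    step = 2000 // k
    offsets = step * np.arange(k) + step // 2
    pro_pos = ((tss - methylome_io.PROMOTER_WINDOW)[:, None]
               + offsets[None, :]).ravel()
    bg_start = FIRST_TSS + PROMOTER_SPACING * npro + 2000
    bg_pos = bg_start + BACKGROUND_STEP * np.arange(config.n_background_cpgs)
    cpg_pos = np.concatenate([pro_pos, bg_pos])

    level_per_cpg = np.concatenate(
        [np.repeat(levels, k, axis=1),
         np.broadcast_to(ml_true[:, None], (n, config.n_background_cpgs))],
        axis=1)
    coverage = rng.poisson(config.coverage_mean, size=level_per_cpg.shape)
    meth = rng.binomial(coverage, level_per_cpg)

    return SyntheticCohort(
        config=config,
        samples=samples,
        truth=truth,
        promoters=promoters,
        prone_promoters=prone_ids,
        promoter_levels=promoter_levels,
        cpg_pos=cpg_pos,
        cpg_coverage=coverage,
        cpg_meth=meth,
        _n_promoter_cpgs=npro * k,
    )


def write_fixture(cohort: SyntheticCohort, directory) -> dict:
    """Write a cohort as the on-disk file set the pipeline consumes.

    Emits ``calls/<embryo_id>.bedgraph`` (4-column TSV, covered CpGs only),
    ``promoters.bed``, ``samples.csv`` and ``truth.csv`` under ``directory``.
    Returns a dict of the written paths.
    """
    if len(cohort.samples) == 0:
        raise ValueError("refusing to write an empty cohort")
    directory = Path(directory)
    calls_dir = directory / "calls"
    calls_dir.mkdir(parents=True, exist_ok=True)

    paths = {"calls": [], "annotation": directory / "promoters.bed",
             "samples": directory / "samples.csv",
             "truth": directory / "truth.csv"}
    for embryo in cohort.embryo_ids:
        p = calls_dir / f"{embryo}.bedgraph"
        cohort.calls_frame(embryo).to_csv(p, sep="\t", header=False, index=False)
        paths["calls"].append(p)
    cohort.promoters.to_csv(paths["annotation"], sep="\t", header=False,
                            index=False)
    cohort.samples.to_csv(paths["samples"], index=False)
    cohort.truth.to_csv(paths["truth"], index=False)
    logger.info("wrote %d CpG files + annotation + sample sheet to %s",
                len(paths["calls"]), directory)
    return paths
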