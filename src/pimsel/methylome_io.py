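"""Input parsing and promoter-level aggregation of CpG methylation calls.

Input formats
-------------
CpG calls
    Tab-separated, four columns, no header: chrom, 0-based position,
    methylated read count, total read count (a bedGraph dialect carrying
    counts instead of a ratio).
Promoter annotation
    Six-column BED-like table: chrom, start, end, gene_id, score, strand.
    The TSS is ``start`` for genes on the + strand and ``end - 1`` on the
    - strand.  The promoter window is the half-open interval
    ``[tss - 1000, tss + 1000)`` regardless of strand: 1 kb upstream and
    downstream of the TSS.
Sample sheet
    Header CSV with columns embryo_id, patient_id, outcome
    (``Birth``/``Failed``), transfer_order, selected, maternal_age.

All coordinates are 0-based half-open, following BED conventions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CPG_COLUMNS",
    "PROMOTER_WINDOW",
    "PromoterMatrix",
    "read_cpg_calls",
    "read_promoter_annotation",
    "read_sample_sheet",
    "whole_genome_ml",
    "build_promoter_matrix",
]

CPG_COLUMNS = ["chrom", "pos", "meth_count", "total_count"]

#: Promoter half-window around the TSS, in bp.
PROMOTER_WINDOW = 1000

SAMPLE_SHEET_COLUMNS = [
    "embryo_id",
    "patient_id",
    "outcome",
    "transfer_order",
    "selected",
    "maternal_age",
]

OUTCOME_LABELS = ("Birth", "Failed")


def read_cpg_calls(path) -> pd.DataFrame:
    """Read a per-embryo CpG call file.

    Returns a DataFrame with columns chrom, pos, meth_count, total_count.
    Malformed rows (non-numeric fields, negative positions, zero total
    coverage, or meth_count > total_count) raise ``ValueError`` naming the
    offending 1-based line number.  An empty file yields an empty frame and
    a logged warning.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", header=None, names=CPG_COLUMNS,
                         dtype={"chrom": str}, comment="#")
    except pd.errors.EmptyDataError:
        logger.warning("CpG call file %s is empty", path)
        return pd.DataFrame(columns=CPG_COLUMNS)
    if df.shape[0] == 0:
        logger.warning("CpG call file %s is empty", path)
        return df

    for col in ("pos", "meth_count", "total_count"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    bad = (
        df[["pos", "meth_count", "total_count"]].isna().any(axis=1)
        | (df["pos"] < 0)
        | (df["meth_count"] < 0)
        | (df["total_count"] <= 0)
        | (df["meth_count"] > df["total_count"])
    )
    if bad.any():
        line = int(df.index[bad][0]) + 1
        raise ValueError(f"{path}: malformed CpG call at line {line}")
    return df.astype({"pos": np.int64, "meth_count": np.int64,
                      "total_count": np.int64})


def read_promoter_annotation(path, window: int = PROMOTER_WINDOW) -> pd.DataFrame:
    """Read a 6-column BED-like gene table and derive promoter windows.

    Returns one row per gene with columns gene_id, chrom, tss, strand,
    win_start, win_end where ``[win_start, win_end)`` is the symmetric
    promoter interval around the TSS.
    """
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "gene_id", "score", "strand"],
                     dtype={"chrom": str, "gene_id": str, "strand": str})
    if not df["strand"].isin(["+", "-"]).all():
        bad = df.loc[~df["strand"].isin(["+", "-"]), "strand"].iloc[0]
        raise ValueError(f"unknown strand value {bad!r} in {path}")
    tss = np.where(df["strand"] == "+", df["start"], df["end"] - 1)
    out = pd.DataFrame({
        "gene_id": df["gene_id"],
        "chrom": df["chrom"],
        "tss": tss.astype(np.int64),
        "strand": df["strand"],
    })
    out["win_start"] = out["tss"] - window
    out["win_end"] = out["tss"] + window
    if out["gene_id"].duplicated().any():
        raise ValueError("duplicate gene_id in promoter annotation")
    return out


def read_sample_sheet(path) -> pd.DataFrame:
    """Read the embryo sample sheet (header CSV)."""
    df = pd.read_csv(path)
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sample sheet {path} missing columns {missing}")
    bad = set(df["outcome"]) - set(OUTCOME_LABELS)
    if bad:
        raise ValueError(f"unknown outcome labels {sorted(bad)}; "
                         f"expected {OUTCOME_LABELS}")
    df = df.copy()
    df["selected"] = df["selected"].astype(bool)
    df["transfer_order"] = df["transfer_order"].astype(int)
    return df


def whole_genome_ml(calls: pd.DataFrame) -> float:
    """Whole-genome methylation level: unweighted mean beta over covered CpGs.

    Each CpG contributes meth_count / total_count once, regardless of its
    coverage depth.
    """
    if len(calls) == 0:
        raise ValueError("cannot compute a methylation level from zero CpG calls")
    beta = calls["meth_count"].to_numpy(float) / calls["total_count"].to_numpy(float)
    return float(beta.mean())


@dataclass
class PromoterMatrix:
    """Embryos x promoters methylation matrix with per-cell CpG coverage.

    ``raw_values`` holds the unweighted mean beta over CpGs falling in each
    promoter window (NaN where no CpG is covered); ``coverage`` the summed
    read counts of those CpGs.  ``values`` masks cells whose summed coverage
    falls below ``min_coverage`` — the low-coverage promoter filter is
    applied per embryo-promoter cell.
    """

    raw_values: pd.DataFrame
    coverage: pd.DataFrame
    min_coverage: int = 30
    values: pd.DataFrame = field(init=False, repr=False)

    def __post_init__(self):
        if not self.raw_values.index.equals(self.coverage.index) or \
           not self.raw_values.columns.equals(self.coverage.columns):
            raise ValueError("values and coverage must be aligned")
        self.values = self.raw_values.where(self.coverage >= self.min_coverage)

    @property
    def embryo_ids(self):
        return list(self.raw_values.index)

    @property
    def promoter_ids(self):
        return list(self.raw_values.columns)

    def with_min_coverage(self, min_coverage: int) -> "PromoterMatrix":
        """Re-apply the coverage filter at a different threshold."""
        return PromoterMatrix(self.raw_values, self.coverage, min_coverage)


def build_promoter_matrix(
    calls_by_embryo: Mapping[str, pd.DataFrame],
    regions: pd.DataFrame,
    min_coverage: int = 30,
) -> PromoterMatrix:
    """Aggregate CpG calls into a promoter methylation matrix.

    For each embryo and promoter, the cell value is the unweighted mean of
    per-CpG betas inside the half-open promoter window and the cell coverage
    is the sum of total read counts of those CpGs.  Cells with coverage below
    ``min_coverage`` are masked as missing.  A CpG falling in several
    (overlapping) promoter windows contributes to each of them.  Calls on
    chromosomes absent from the annotation are skipped and counted in a log
    message.
    """
    embryo_ids = list(calls_by_embryo)
    if not embryo_ids:
        raise ValueError("no embryos supplied")
    gene_ids = list(regions["gene_id"])
    values = np.full((len(embryo_ids), len(gene_ids)), np.nan)
    cover = np.zeros((len(embryo_ids), len(gene_ids)), dtype=np.int64)

    regions_by_chrom = {c: g for c, g in regions.groupby("chrom", sort=False)}
    col_of = {g: i for i, g in enumerate(gene_ids)}
    skipped = 0

    for row, embryo in enumerate(embryo_ids):
        calls = calls_by_embryo[embryo]
        if len(calls) == 0:
            continue
        for chrom, chunk in calls.groupby("chrom", sort=False):
            reg = regions_by_chrom.get(chrom)
            if reg is None:
                skipped += len(chunk)
                continue
            chunk = chunk.sort_values("pos")
            pos = chunk["pos"].to_numpy()
            beta = chunk["meth_count"].to_numpy(float) / chunk["total_count"].to_numpy(float)
            tot = chunk["total_count"].to_numpy()
            beta_cum = np.concatenate([[0.0], np.cumsum(beta)])
            tot_cum = np.concatenate([[0], np.cumsum(tot)])
            lo = np.searchsorted(pos, reg["win_start"].to_numpy(), side="left")
            hi = np.searchsorted(pos, reg["win_end"].to_numpy(), side="left")
            n_cpg = hi - lo
            with np.errstate(invalid="ignore"):
                mean_beta = (beta_cum[hi] - beta_cum[lo]) / n_cpg
            cov = tot_cum[hi] - tot_cum[lo]
            cols = [col_of[g] for g in reg["gene_id"]]
            has = n_cpg > 0
            values[row, np.asarray(cols)[has]] = mean_beta[has]
            cover[row, cols] += cov
    if skipped:
        logger.info("skipped %d CpG calls on chromosomes absent from the "
                    "annotation", skipped)

    raw = pd.DataFrame(values, index=pd.Index(embryo_ids, name="embryo_id"),
                       columns=gene_ids)
    cov_df = pd.DataFrame(cover, index=raw.index, columns=gene_ids)
    return PromoterMatrix(raw, cov_df, min_coverage=min_coverage)
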