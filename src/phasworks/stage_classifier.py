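"""The three-condition call for EAT1-dependent, ST.2-enriched expression.

A locus (coding gene, lincRNA or TE) qualifies when all of:

1. mean FPKM in wild-type ST.2 is strictly more than 2-fold above both the
   wild-type ST.1 and ST.4 means,
2. strictly more than 2-fold above the eat1-4 ST.2 mean, and
3. the standard deviation of the wild-type ST.2 replicates is strictly
   less than half their mean.

Fold changes use a pseudocount in the denominator because mutant values
can be exactly zero.  Condition 1 compares against replicate means by
default (configurable to the per-replicate maximum); condition 3 uses the
sample (n-1) SD by default, conventional for three replicates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .iolib import SampleKey, Thresholds


def sample_columns(matrix: pd.DataFrame, genotype: str | None = None,
                   stage: str | None = None, assay: str | None = None) -> list[str]:
    """Columns of an expression matrix matching a genotype/stage/assay."""
    out = []
    for col in matrix.columns:
        key = SampleKey.parse(col)
        if ((genotype is None or key.genotype == genotype)
                and (stage is None or key.stage == stage)
                and (assay is None or key.assay == assay)):
            out.append(col)
    return out


def _group(matrix: pd.DataFrame, genotype: str, stage: str) -> pd.DataFrame:
    cols = sample_columns(matrix, genotype=genotype, stage=stage)
    if not cols:
        raise ValueError(f"expression matrix has no {genotype} {stage} samples")
    return matrix[cols]


def classify_eat1_dependent(matrix: pd.DataFrame,
                            thresholds: Thresholds | None = None,
                            reference_stat: str = "mean",
                            sd_ddof: int = 1) -> pd.DataFrame:
    """Apply the three conditions to every row of an FPKM matrix.

    Returns a DataFrame indexed like ``matrix`` with the per-condition
    booleans, the fold changes (pseudocounted denominators) and the
    conjunction ``verdict``.  ``reference_stat`` selects how condition 1
    summarises the ST.1/ST.4 references ("mean" or "max").
    """
    thr = thresholds or Thresholds()
    eps = thr.pseudocount
    wt2 = _group(matrix, "WT", "ST.2")
    wt1 = _group(matrix, "WT", "ST.1")
    wt4 = _group(matrix, "WT", "ST.4")
    mut2 = _group(matrix, "eat1-4", "ST.2")

    mean2 = wt2.mean(axis=1)
    if reference_stat == "mean":
        ref1, ref4 = wt1.mean(axis=1), wt4.mean(axis=1)
    elif reference_stat == "max":
        ref1, ref4 = wt1.max(axis=1), wt4.max(axis=1)
    else:
        raise ValueError(f"unknown reference_stat {reference_stat!r}")

    fold_vs_st1 = mean2 / (ref1 + eps)
    fold_vs_st4 = mean2 / (ref4 + eps)
    fold_vs_mutant = mean2 / (mut2.mean(axis=1) + eps)
    cond1 = (fold_vs_st1 > thr.fold_change_min) & (fold_vs_st4 > thr.fold_change_min)
    cond2 = fold_vs_mutant > thr.fold_change_min
    sd2 = wt2.std(axis=1, ddof=sd_ddof)
    # with a single replicate the dispersion bound cannot be evaluated and
    # is vacuously satisfied
    cond3 = (sd2 < thr.sd_over_mean_max * mean2) | sd2.isna()

    out = pd.DataFrame({
        "cond1": cond1, "cond2": cond2, "cond3": cond3,
        "fold_vs_st1": fold_vs_st1, "fold_vs_st4": fold_vs_st4,
        "fold_vs_mutant": fold_vs_mutant,
        "wt_st2_mean": mean2, "wt_st2_sd": sd2,
    })
    out["verdict"] = out["cond1"] & out["cond2"] & out["cond3"]
    out.index.name = matrix.index.name or "locus_id"
    return out
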