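"""MEL1-associated siRNA (masiRNA) calling, origin classes, 5' composition.

RIP-seq against the germline Argonaute MEL1 yields per-library read
tables of 24-nt species.  A species is a canonical masiRNA when its RPM
reaches 15 in wild-type flowers at ST.1, ST.2 or ST.4 (replicate mean,
maximised over stages) and that same stage shows at least 4-fold
enrichment over the stage-matched mel1-1 control (pseudocounted, because
mel1-1 RIP libraries are nearly empty of 24-nt reads).  Called species
are assigned a genomic origin with precedence PHAS > coding > repeat >
intergenic over all of their alignments, and summarised as per-stage
origin compositions (RPM-weighted) and a positional nucleotide-frequency
table whose first row is the 5'-nucleotide distribution.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .iolib import SampleKey, Thresholds
from .stage_classifier import sample_columns

ORIGIN_PRECEDENCE = ("PHAS", "coding", "repeat", "intergenic")


def build_rpm_table(rip_reads: Mapping[SampleKey, pd.DataFrame],
                    library_totals: Mapping[SampleKey, float] | None = None
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sequence RPM matrix plus one genomic alignment table.

    Each RIP read table must carry a ``sequence`` column.  RPM is
    ``copies * 1e6 / library_total`` (total defaults to the table's copy
    sum).  Returns ``(rpm_table, alignments)`` where alignments holds one
    row per (sequence, position) seen in any library.
    """
    cols, aln_frames = {}, []
    for key, df in rip_reads.items():
        total = (library_totals[key] if library_totals is not None
                 else float(df["copies"].sum()))
        grouped = df.groupby("sequence")["copies"].sum()
        cols[key.encode()] = grouped * 1e6 / total
        aln_frames.append(df[["sequence", "chrom", "start", "end", "strand"]])
    rpm = pd.DataFrame(cols).fillna(0.0)
    rpm.index.name = "sequence"
    alignments = (pd.concat(aln_frames, ignore_index=True)
                  .drop_duplicates()
                  .reset_index(drop=True))
    return rpm, alignments


def _stage_means(rpm: pd.DataFrame, genotype: str) -> pd.DataFrame:
    """Replicate-mean RPM per stage for one genotype; columns are stages."""
    out = {}
    for col in rpm.columns:
        key = SampleKey.parse(col)
        if key.genotype == genotype:
            out.setdefault(key.stage, []).append(col)
    return pd.DataFrame({stage: rpm[cols].mean(axis=1) for stage, cols in out.items()})


def call_masirnas(rpm: pd.DataFrame, thresholds: Thresholds | None = None
                  ) -> pd.DataFrame:
    """Apply the RPM and mel1-1-enrichment thresholds to every sequence.

    The calling stage is the wild-type stage of maximal RPM; a sequence
    is called iff that RPM is >= 15 and >= 4-fold above the stage-matched
    mel1-1 RPM (pseudocounted).  Output is restricted to called species
    and the operation is idempotent.
    """
    thr = thresholds or Thresholds()
    wt = _stage_means(rpm, "WT")
    mel1 = _stage_means(rpm, "mel1-1")
    if not len(wt.columns):
        raise ValueError("RPM table has no wild-type libraries")
    missing = set(wt.columns) - set(mel1.columns)
    if missing:
        raise ValueError(f"missing mel1-1 library for stage(s): {sorted(missing)}")
    best_stage = wt.idxmax(axis=1)
    max_wt_rpm = wt.max(axis=1)
    mel1_at_best = pd.Series(
        mel1.to_numpy()[np.arange(len(mel1)),
                        [list(mel1.columns).index(s) for s in best_stage]],
        index=rpm.index)
    fold = max_wt_rpm / (mel1_at_best + thr.pseudocount)
    called = (max_wt_rpm >= thr.masirna_min_rpm) & (fold >= thr.masirna_min_fold)
    out = pd.DataFrame({
        "max_wt_rpm": max_wt_rpm, "best_stage": best_stage,
        "mel1_rpm": mel1_at_best, "fold_vs_mel1": fold, "called": called,
    })
    out["five_prime_nt"] = [s[0] for s in out.index]
    return out.loc[called.to_numpy()]


def _trees(frame: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for row in frame.itertuples(index=False):
        trees.setdefault(row.chrom, IntervalTree()).addi(row.start, row.end)
    return trees


def classify_origin(alignments: pd.DataFrame, phas_loci: pd.DataFrame,
                    coding: pd.DataFrame, repeats: pd.DataFrame) -> pd.Series:
    """Origin label per sequence with precedence PHAS > coding > repeat >
    intergenic over all alignments; sequences without alignment are
    ``unmapped``."""
    trees = {
        "PHAS": _trees(phas_loci), "coding": _trees(coding), "repeat": _trees(repeats),
    }
    rank = {c: i for i, c in enumerate(ORIGIN_PRECEDENCE)}
    labels: dict[str, str] = {}
    for row in alignments.itertuples(index=False):
        label = "intergenic"
        for cat in ("PHAS", "coding", "repeat"):
            tree = trees[cat].get(row.chrom)
            if tree is not None and tree.overlap(row.start, row.end):
                label = cat
                break
        prev = labels.get(row.sequence)
        if prev is None or rank[label] < rank[prev]:
            labels[row.sequence] = label
    out = pd.Series(labels, name="origin")
    out.index.name = "sequence"
    return out


def origin_composition(rpm: pd.DataFrame, origins: pd.Series) -> pd.DataFrame:
    """Per-stage, RPM-weighted origin-category fractions of WT libraries.

    Rows are stages, columns the origin categories; each row sums to 1
    (over mapped sequences with nonzero stage RPM).
    """
    wt = _stage_means(rpm, "WT")
    mapped = origins.reindex(wt.index).fillna("unmapped")
    rows = {}
    for stage in wt.columns:
        weights = wt[stage].to_numpy()
        keep = mapped.to_numpy() != "unmapped"
        total = weights[keep].sum()
        rows[stage] = {
            cat: float(weights[keep & (mapped.to_numpy() == cat)].sum() / total)
            if total > 0 else np.nan
            for cat in ORIGIN_PRECEDENCE
        }
    return pd.DataFrame(rows).T[list(ORIGIN_PRECEDENCE)]


def five_prime_composition(sequences, length: int = 24) -> pd.DataFrame:
    """Position-wise nucleotide frequencies (1-based rows 1..length).

    Row 1 is the 5'-nucleotide distribution; every row sums to 1.
    Raises on an empty subset.
    """
    seqs = [s.upper().replace("U", "T") for s in sequences]
    if not seqs:
        raise ValueError("empty sequence subset")
    if any(len(s) != length for s in seqs):
        raise ValueError(f"all sequences must be {length} nt")
    arr = np.frombuffer("".join(seqs).encode(), dtype="S1").reshape(len(seqs), length)
    out = pd.DataFrame(
        {nt: (arr == nt.encode()).mean(axis=0) for nt in "ACGT"},
        index=pd.RangeIndex(1, length + 1, name="position"),
    )
    return out
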