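"""lincRNA extraction and 24-PHAS locus calling.

Candidate lincRNAs are transcribed intergenic segments: mRNA coverage is
segmented at a configurable floor (default 1 read), bookended or
overlapping segments are merged, every region sharing even a single base
with a protein-coding gene is discarded wholesale, and only regions
strictly longer than 200 bp survive.  A surviving, EAT1-dependent lincRNA
becomes a 24-PHAS locus when its 24-nt small-RNA FPKM strictly exceeds 10
in at least one wild-type sample.  A user-supplied rescue list re-admits
loci excluded by length or coding overlap; rescued loci carry a
provenance flag.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .iolib import GenomicInterval, Thresholds, log_filter
from .stage_classifier import sample_columns


def merge_intervals(df: pd.DataFrame, gap: int = 0) -> pd.DataFrame:
    """Merge overlapping or bookended (within ``gap`` bp) intervals."""
    if not len(df):
        return pd.DataFrame(columns=["chrom", "start", "end"])
    rows = []
    for chrom, sub in df.sort_values(["chrom", "start", "end"]).groupby("chrom", sort=True):
        cur_s, cur_e = None, None
        for s, e in zip(sub["start"], sub["end"]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e + gap:
                cur_e = max(cur_e, e)
            else:
                rows.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        rows.append((chrom, cur_s, cur_e))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def transcribed_regions(mrna_reads: pd.DataFrame,
                        chrom_lengths: Mapping[str, int],
                        min_coverage: int = 1) -> pd.DataFrame:
    """Strandless segments where mRNA read coverage reaches the floor."""
    rows = []
    for chrom, length in chrom_lengths.items():
        sub = mrna_reads[mrna_reads["chrom"] == chrom]
        delta = np.zeros(length + 1, dtype=np.int64)
        if len(sub):
            np.add.at(delta, sub["start"].to_numpy(), sub["copies"].to_numpy())
            np.add.at(delta, sub["end"].to_numpy(), -sub["copies"].to_numpy())
        cov = np.cumsum(delta[:-1])
        above = cov >= min_coverage
        edges = np.diff(above.astype(np.int8))
        starts = np.nonzero(edges == 1)[0] + 1
        ends = np.nonzero(edges == -1)[0] + 1
        if above[0]:
            starts = np.insert(starts, 0, 0)
        if above[-1]:
            ends = np.append(ends, length)
        rows += [(chrom, int(s), int(e)) for s, e in zip(starts, ends)]
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _coding_trees(coding: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for row in coding.itertuples(index=False):
        trees.setdefault(row.chrom, IntervalTree()).addi(row.start, row.end)
    return trees


def extract_lincrnas(transcribed: pd.DataFrame, coding: pd.DataFrame,
                     thresholds: Thresholds | None = None) -> pd.DataFrame:
    """Merged transcribed regions, coding-free, strictly longer than 200 bp."""
    thr = thresholds or Thresholds()
    merged = merge_intervals(transcribed)
    trees = _coding_trees(coding)
    keep = []
    for row in merged.itertuples(index=False):
        tree = trees.get(row.chrom)
        if tree is not None and tree.overlap(row.start, row.end):
            continue
        if row.end - row.start <= thr.lincrna_min_len:
            continue
        keep.append(row)
    out = pd.DataFrame(keep, columns=["chrom", "start", "end"]).reset_index(drop=True)
    out["locus_id"] = [f"linc_{i + 1:04d}" for i in range(len(out))]
    out["length"] = out["end"] - out["start"]
    log_filter("extract_lincrnas", len(merged), len(out))
    return out


def call_24phas(lincrnas: pd.DataFrame, srna24_matrix: pd.DataFrame,
                thresholds: Thresholds | None = None) -> pd.DataFrame:
    """Flag lincRNAs whose 24-nt sRNA FPKM strictly exceeds the cutoff in
    at least one wild-type sample."""
    thr = thresholds or Thresholds()
    missing = set(lincrnas["locus_id"]) - set(srna24_matrix.index)
    if missing:
        raise KeyError(f"loci absent from sRNA matrix: {sorted(missing)[:5]}")
    wt_cols = sample_columns(srna24_matrix, genotype="WT")
    if not wt_cols:
        raise ValueError("sRNA matrix has no wild-type samples")
    max_wt = srna24_matrix.loc[lincrnas["locus_id"], wt_cols].max(axis=1)
    out = lincrnas.copy()
    out["srna24_max_wt_fpkm"] = max_wt.to_numpy()
    out["is_phas"] = out["srna24_max_wt_fpkm"] > thr.phas_min_srna_fpkm
    return out


def assemble_phas_set(phas_candidates: pd.DataFrame,
                      dependence_verdicts: pd.Series,
                      rescue_list: pd.DataFrame | None = None,
                      genome_lengths: Mapping[str, int] | None = None
                      ) -> pd.DataFrame:
    """Final locus set: (PHAS and EAT1-dependent) plus rescued intervals.

    ``rescue_list`` rows need ``chrom,start,end`` (optionally ``locus_id``);
    rescued loci get ``provenance == "rescue"``.  Duplicated intervals are
    dropped, first (primary) occurrence wins.
    """
    verdict = dependence_verdicts.reindex(phas_candidates["locus_id"]).fillna(False)
    primary = phas_candidates.loc[
        phas_candidates["is_phas"].to_numpy() & verdict.to_numpy(),
        ["chrom", "start", "end", "locus_id"],
    ].copy()
    primary["provenance"] = "primary"
    frames = [primary]
    if rescue_list is not None and len(rescue_list):
        rescue = rescue_list[["chrom", "start", "end"]].copy()
        if genome_lengths is not None:
            for row in rescue.itertuples(index=False):
                limit = genome_lengths.get(row.chrom)
                if limit is None or row.start < 0 or row.end > limit:
                    raise ValueError(
                        f"rescue interval {row.chrom}:{row.start}-{row.end} "
                        "lies outside the genome")
        rescue["locus_id"] = (rescue_list["locus_id"].to_numpy()
                              if "locus_id" in rescue_list.columns
                              else [f"rescue_{i + 1:03d}" for i in range(len(rescue))])
        rescue["provenance"] = "rescue"
        frames.append(rescue)
    out = pd.concat(frames, ignore_index=True)
    out = out.drop_duplicates(subset=["chrom", "start", "end"], keep="first")
    return out.sort_values(["chrom", "start"]).reset_index(drop=True)
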