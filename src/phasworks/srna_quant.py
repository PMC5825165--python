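"""Read filtering, per-locus FPKM/RPM quantification and window landscapes.

FPKM is fixed as ``assigned_count * 1e9 / (locus_length_bp * library_total)``
with reads assigned to every locus containing their biological 5' end —
unambiguous for 24-nt reads against kbp-scale loci.  Multi-mapping reads
(hits > 1) are counted with weight ``1/hits`` by default ("fractional"),
with a ``primary`` mode counting each record once; both are provided
because clustered PHAS regions would otherwise be double-counted.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .iolib import (
    GenomicInterval, SampleKey, Thresholds,
    five_prime_positions, log_filter, validate_read_table,
)


def filter_reads(reads: pd.DataFrame, length: int,
                 thresholds: Thresholds | None = None) -> pd.DataFrame:
    """Keep reads of exactly ``length`` nt with <= ``max_mismatches``
    mismatches and <= ``max_hits`` genomic hits.

    Idempotent; an empty result is not an error.
    """
    thr = thresholds or Thresholds()
    validate_read_table(reads)
    keep = (
        (reads["read_length"] == length)
        & (reads["mismatches"] <= thr.max_mismatches)
        & (reads["hits"] <= thr.max_hits)
    )
    out = reads.loc[keep].reset_index(drop=True)
    log_filter(f"filter_reads(len={length})", len(reads), len(out))
    return out


def read_weights(reads: pd.DataFrame, count_mode: str = "fractional") -> np.ndarray:
    """Per-record counting weight: ``copies/hits`` (fractional) or ``copies``."""
    copies = reads["copies"].to_numpy(dtype=float)
    if count_mode == "fractional":
        return copies / reads["hits"].to_numpy(dtype=float)
    if count_mode == "primary":
        return copies
    raise ValueError(f"unknown count_mode {count_mode!r}")


def count_reads_in_loci(reads: pd.DataFrame, loci: pd.DataFrame,
                        count_mode: str = "fractional") -> np.ndarray:
    """Weighted read count per locus, assigning by 5'-end containment.

    ``loci`` needs columns ``chrom,start,end``; overlapping loci each
    receive every read whose 5' end they contain.
    """
    counts = np.zeros(len(loci))
    if not len(reads):
        return counts
    pos = five_prime_positions(reads)
    w = read_weights(reads, count_mode)
    chroms = reads["chrom"].to_numpy()
    by_chrom = {}
    for chrom in np.unique(chroms):
        m = chroms == chrom
        order = np.argsort(pos[m], kind="stable")
        by_chrom[chrom] = (pos[m][order], np.concatenate([[0.0], np.cumsum(w[m][order])]))
    for i, row in enumerate(loci.itertuples(index=False)):
        entry = by_chrom.get(row.chrom)
        if entry is None:
            continue
        sorted_pos, cum = entry
        lo = np.searchsorted(sorted_pos, row.start, side="left")
        hi = np.searchsorted(sorted_pos, row.end, side="left")
        counts[i] = cum[hi] - cum[lo]
    return counts


def quantify_fpkm(reads: pd.DataFrame, loci: pd.DataFrame, library_total: float,
                  count_mode: str = "fractional") -> pd.Series:
    """FPKM per locus: ``count * 1e9 / (length * library_total)``.

    ``loci`` needs ``chrom,start,end`` and, if present, a ``locus_id``
    column used as the index of the returned Series.
    """
    if library_total <= 0:
        raise ValueError("library_total must be > 0")
    if not len(loci):
        raise ValueError("loci must be non-empty")
    lengths = (loci["end"] - loci["start"]).to_numpy(dtype=float)
    if (lengths <= 0).any():
        raise ValueError("zero-length locus")
    counts = count_reads_in_loci(reads, loci, count_mode)
    fpkm = counts * 1e9 / (lengths * float(library_total))
    index = loci["locus_id"] if "locus_id" in loci.columns else loci.index
    return pd.Series(fpkm, index=index, name="fpkm")


def build_expression_matrix(reads_by_sample: Mapping[SampleKey, pd.DataFrame],
                            loci: pd.DataFrame,
                            library_totals: Mapping[SampleKey, float] | None = None,
                            count_mode: str = "fractional") -> pd.DataFrame:
    """FPKM matrix: one row per locus, one SampleKey-encoded column per library.

    ``library_totals`` defaults to each table's total copies (mapped reads).
    """
    cols = {}
    for key, reads in reads_by_sample.items():
        total = (library_totals[key] if library_totals is not None
                 else float(reads["copies"].sum()))
        cols[key.encode()] = quantify_fpkm(reads, loci, total, count_mode)
    mat = pd.DataFrame(cols)
    mat.index.name = "locus_id"
    return mat


# ---------------------------------------------------------------------------
# sliding-window landscapes
# ---------------------------------------------------------------------------

def window_grid(genome_lengths: Mapping[str, int], window: int, step: int
                ) -> pd.DataFrame:
    """The window tiling: starts every ``step`` bp, width ``window`` bp
    (clipped at the chromosome end)."""
    rows = []
    for chrom, length in genome_lengths.items():
        start = 0
        while start < length:
            rows.append((chrom, start, min(start + window, length)))
            start += step
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def window_abundance(reads: pd.DataFrame, genome_lengths: Mapping[str, int],
                     thresholds: Thresholds | None = None,
                     library_total: float | None = None,
                     count_mode: str = "fractional") -> pd.DataFrame:
    """Per-million-normalised 5'-end counts in a sliding window track.

    Returns the window grid with a ``value`` column (reads per million
    whose 5' end lies in the window).
    """
    thr = thresholds or Thresholds()
    grid = window_grid(genome_lengths, thr.window, thr.step)
    total = float(library_total) if library_total is not None else float(reads["copies"].sum())
    counts = count_reads_in_loci(reads, grid, count_mode) if len(reads) else np.zeros(len(grid))
    grid["value"] = counts * 1e6 / total if total > 0 else 0.0
    return grid


def wt_minus_mutant(track_wt: pd.DataFrame, track_mut: pd.DataFrame) -> pd.DataFrame:
    """Element-wise WT minus mutant landscape (values may be negative)."""
    same = (len(track_wt) == len(track_mut)
            and (track_wt["chrom"].to_numpy() == track_mut["chrom"].to_numpy()).all()
            and (track_wt["start"].to_numpy() == track_mut["start"].to_numpy()).all()
            and (track_wt["end"].to_numpy() == track_mut["end"].to_numpy()).all())
    if not same:
        raise ValueError("window grids differ between tracks")
    out = track_wt.copy()
    out["value"] = track_wt["value"].to_numpy() - track_mut["value"].to_numpy()
    return out
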