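"""Trigger-site scanning and 24-nt phase-register statistics.

A 22-nt miRNA trigger (miR2275) base-pairs with a complementary site on
the long precursor transcript; AGO-guided cleavage between site positions
12 and 13 sets the 5' boundary ("phase origin") from which DCL5 dices the
double-stranded precursor into 24-nt increments (one-hit processing).  The
operations here:

* :func:`scan_mir_site` — deterministic complementarity scan of a locus
  sequence against the trigger on both orientations, with G:U wobble pairs
  weighted 0.5 mismatch.  This replaces de-novo motif discovery: the
  conserved motif at these loci *is* the trigger complement, so a direct
  scan is its reproducible equivalent.
* :func:`predict_cleavage` — the phase origin, the site's 13th nucleotide
  in the site's own 5'->3' orientation.
* :func:`assign_register` — per-read in-phase flags.  A plus-strand read
  is in-phase iff ``(start - origin) % 24 == 0``; a minus-strand read iff
  ``(end - origin - 2) % 24 == 0``, the 2-nt offset being the 3' overhang
  of a dicer duplex (configurable).
* :func:`in_phase_fraction` and :func:`phasing_score` — the copy-weighted
  in-phase share, and a log-form phasing score computed over a sliding
  window of phase cycles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .iolib import GenomicInterval, five_prime_positions

_COMP = str.maketrans("ACGTN", "TGCAN")
_CODE = {b: i for i, b in enumerate("ACGTN")}


def rna_to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def revcomp_dna(seq: str) -> str:
    return seq.upper().translate(_COMP)[::-1]


@dataclass(frozen=True)
class MirSite:
    """One complementary trigger site on a locus.

    Coordinates are relative to the scanned sequence unless the site was
    produced by :func:`scan_locus`, in which case they are genomic.
    ``orientation`` is the strand of the precursor that pairs with the
    trigger: a ``+`` site means the plus strand carries the reverse
    complement of the trigger.
    """

    site_start: int
    site_end: int
    orientation: str
    mismatch_count: float
    cleavage_pos: int
    chrom: str | None = None
    locus_id: str | None = None


def predict_cleavage(site_start: int, site_end: int, orientation: str,
                     offset_in_site: int = 13) -> int:
    """Genomic (or sequence-relative) coordinate of the phase origin.

    The origin is the site's ``offset_in_site``-th nucleotide (1-based) in
    the site's own 5'->3' orientation: ``site_start + offset - 1`` for a
    plus-orientation site, ``site_end - offset`` for minus.
    """
    if orientation == "+":
        return site_start + offset_in_site - 1
    return site_end - offset_in_site


def _mismatch_luts(mir_dna: str, orientation: str) -> np.ndarray:
    """Per-window-position lookup of weighted mismatch for each base code.

    Pairing geometry: window position ``u`` pairs trigger base
    ``mir[m-1-u]`` on a plus-orientation site (the window itself is the
    target 5'->3') and ``mir[u]`` on minus (the target is the window's
    reverse complement).  Complement = 0, G:U wobble = 0.5, anything else
    (including N) = 1.
    """
    m = len(mir_dna)
    lut = np.ones((m, 5), dtype=np.float64)
    for u in range(m):
        mirb = mir_dna[m - 1 - u] if orientation == "+" else mir_dna[u]
        if orientation == "+":
            perfect = mirb.translate(_COMP)
            wobble = "T" if mirb == "G" else "G" if mirb == "T" else None
        else:
            perfect = mirb
            wobble = "A" if mirb == "G" else "C" if mirb == "T" else None
        lut[u, _CODE[perfect]] = 0.0
        if wobble is not None:
            lut[u, _CODE[wobble]] = 0.5
    return lut


def scan_mir_site(locus_seq: str, mir_seq: str, max_mismatch: float = 4.0,
                  offset_in_site: int = 13) -> list[MirSite]:
    """Scan a locus sequence for trigger-complementary sites, both strands.

    Returns sites with weighted mismatches <= ``max_mismatch``, sorted by
    position.  Ambiguous (N) bases score as full mismatches.
    """
    mir = rna_to_dna(mir_seq)
    m = len(mir)
    if m < 15:
        raise ValueError("trigger sequence implausibly short")
    seq = locus_seq.upper()
    if len(seq) < m:
        raise ValueError("locus sequence shorter than the trigger site")
    codes = np.fromiter((_CODE.get(b, 4) for b in seq), dtype=np.int64, count=len(seq))
    n_win = len(seq) - m + 1
    sites: list[MirSite] = []
    for orientation in ("+", "-"):
        lut = _mismatch_luts(mir, orientation)
        mm = np.zeros(n_win)
        for u in range(m):
            mm += lut[u][codes[u:u + n_win]]
        for i in np.nonzero(mm <= max_mismatch)[0]:
            s = int(i)
            sites.append(MirSite(
                site_start=s, site_end=s + m, orientation=orientation,
                mismatch_count=float(round(mm[s], 3)),
                cleavage_pos=predict_cleavage(s, s + m, orientation, offset_in_site),
            ))
    sites.sort(key=lambda x: (x.site_start, x.orientation))
    return sites


def scan_locus(genome: dict, locus: GenomicInterval, mir_seq: str,
               max_mismatch: float = 4.0, offset_in_site: int = 13,
               locus_id: str | None = None) -> list[MirSite]:
    """Scan one genomic locus; returned coordinates are genomic."""
    seq = genome[locus.chrom][locus.start:locus.end]
    return [
        replace(s, site_start=s.site_start + locus.start,
                site_end=s.site_end + locus.start,
                cleavage_pos=s.cleavage_pos + locus.start,
                chrom=locus.chrom, locus_id=locus_id)
        for s in scan_mir_site(seq, mir_seq, max_mismatch, offset_in_site)
    ]


def choose_origin_site(sites: Sequence[MirSite], locus: GenomicInterval) -> MirSite:
    """Pick the site that defines the phase origin.

    The most 5' site in its own orientation wins (distance from the locus
    start for plus sites, from the locus end for minus); ties break to the
    lowest weighted mismatch, then to the leftmost coordinate.
    """
    if not sites:
        raise ValueError("no sites to choose from")

    def key(s: MirSite):
        d5 = (s.site_start - locus.start if s.orientation == "+"
              else locus.end - s.site_end)
        return (d5, s.mismatch_count, s.site_start)

    return min(sites, key=key)


# ---------------------------------------------------------------------------
# register arithmetic
# ---------------------------------------------------------------------------

def register_positions(reads: pd.DataFrame, antisense_offset: int = 2) -> np.ndarray:
    """Phase-register coordinate of each read: 5' start on plus, ``end -
    antisense_offset`` on minus (so in-phase reads of both strands map to
    the same grid)."""
    starts = reads["start"].to_numpy()
    ends = reads["end"].to_numpy()
    return np.where(reads["strand"].to_numpy() == "+",
                    starts, ends - antisense_offset)


def assign_register(reads: pd.DataFrame, origin: int, locus: GenomicInterval,
                    cycle: int = 24, antisense_offset: int = 2) -> pd.DataFrame:
    """Flag each read inside the locus as in-phase or not.

    Reads whose 5' end falls outside the locus are dropped.  Returns a
    copy with an ``in_phase`` boolean column.
    """
    if not locus.contains_point(locus.chrom, origin):
        raise ValueError(f"origin {origin} lies outside locus "
                         f"{locus.chrom}:{locus.start}-{locus.end}")
    pos5 = five_prime_positions(reads)
    inside = ((reads["chrom"].to_numpy() == locus.chrom)
              & (pos5 >= locus.start) & (pos5 < locus.end))
    sub = reads.loc[inside].copy()
    reg = register_positions(sub, antisense_offset)
    sub["in_phase"] = (reg - origin) % cycle == 0
    return sub


def in_phase_fraction(flags: Iterable[bool], weights: Iterable[float] | None = None
                      ) -> float:
    """Copy-weighted share of in-phase reads.  Undefined (error) for zero reads."""
    flags = np.asarray(list(flags), dtype=bool)
    w = np.ones(len(flags)) if weights is None else np.asarray(list(weights), dtype=float)
    total = w.sum()
    if len(flags) == 0 or total <= 0:
        raise ValueError("in-phase fraction undefined for zero reads")
    return float(w[flags].sum() / total)


def phasing_score(reads: pd.DataFrame, origin: int, locus: GenomicInterval,
                  cycle: int = 24, window_cycles: int = 9,
                  antisense_offset: int = 2) -> float:
    """Log-form phasing score, maximised over sliding windows of cycles.

    Within a window of ``window_cycles`` consecutive phase cycles, with P
    the copy-weighted count on in-phase positions, U the copy-weighted
    count off-phase, and k the number of distinct occupied in-phase
    positions, the window score is ``(k - 2) * ln(1 + 10 P / (1 + U))``,
    reported only when k >= 3 (else 0).  The locus score is the maximum
    over windows.
    """
    flagged = assign_register(reads, origin, locus, cycle, antisense_offset)
    if not len(flagged):
        return 0.0
    reg = register_positions(flagged, antisense_offset)
    copies = flagged["copies"].to_numpy().astype(float)
    in_phase = flagged["in_phase"].to_numpy()
    cyc = np.floor_divide(reg - origin, cycle)
    c_min, c_max = int(cyc.min()), int(cyc.max())
    best = 0.0
    for w0 in range(c_min, c_max + 1):
        in_win = (cyc >= w0) & (cyc < w0 + window_cycles)
        p_mask = in_win & in_phase
        k = len(np.unique(reg[p_mask]))
        if k < 3:
            continue
        P = copies[p_mask].sum()
        U = copies[in_win & ~in_phase].sum()
        best = max(best, (k - 2) * math.log1p(10.0 * P / (1.0 + U)))
    return best


@dataclass(frozen=True)
class PhasingResult:
    """Phase-register summary of one locus."""

    locus_id: str
    origin: int
    in_phase_reads: float
    total_reads: float
    in_phase_fraction: float
    phasing_score: float
    occupied_cycles: int


def phasing_result(locus_id: str, reads: pd.DataFrame, origin: int,
                   locus: GenomicInterval, cycle: int = 24,
                   window_cycles: int = 9, antisense_offset: int = 2
                   ) -> PhasingResult:
    """Convenience wrapper producing the full per-locus summary."""
    flagged = assign_register(reads, origin, locus, cycle, antisense_offset)
    if not len(flagged):
        raise ValueError(f"no reads inside locus {locus_id}")
    copies = flagged["copies"].to_numpy().astype(float)
    in_ph = flagged["in_phase"].to_numpy()
    reg = register_positions(flagged, antisense_offset)
    frac = in_phase_fraction(in_ph, copies)
    score = phasing_score(reads, origin, locus, cycle, window_cycles, antisense_offset)
    occupied = len(np.unique(reg[in_ph]))
    return PhasingResult(
        locus_id=locus_id, origin=origin,
        in_phase_reads=float(copies[in_ph].sum()), total_reads=float(copies.sum()),
        in_phase_fraction=frac, phasing_score=score, occupied_cycles=occupied,
    )
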