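"""Deterministic simulator of a miniature genome and its sequencing libraries.

The generator emulates the statistical structure the downstream analysis
assumes in real anther data:

* a small multi-chromosome genome carrying protein-coding genes, repeat
  families, and planted 24-PHAS precursor loci, each with exactly one
  embedded 22-nt reverse-complement match to the miR2275 trigger near the
  precursor 5' end;
* stage/genotype-structured mRNA-seq and 24-nt sRNA-seq libraries (WT and
  eat1-4 at stages ST.1/ST.2/ST.4, three replicates) with lognormal
  replicate noise around per-class expression means; the default effect
  sizes mirror the published fold changes (precursor FPKM 688x over ST.1,
  24x over ST.4, 55x over eat1-4 at ST.2);
* 24-nt read stacks whose 5' ends sit on the 24-nt phase grid anchored at
  the planted cleavage position with a tunable in-phase fraction
  (default 0.8);
* degradome libraries (20/21-nt reads) with a 5'-end peak planted at the
  predicted cleavage position for a tunable fraction of loci;
* MEL1 RIP libraries sampling 24-nt species from PHAS / coding /
  intergenic / repeat origins with stage-dependent mixtures, a 5'-C bias
  for PHAS-derived species, and mel1-1 libraries in which the same species
  are depleted far beyond the 4-fold calling threshold.

Four planted decoy classes give every published filter a negative to
reject: ST.2-enriched but EAT1-independent loci, constitutively expressed
lincRNAs, loci with erratic replicate behaviour, and phased loci lacking a
trigger site.  Truth labels are emitted alongside, so recall and precision
of every downstream classifier are computable without re-reading configs.

Everything is driven by ``numpy.random.default_rng`` streams derived from
``SimConfig.seed`` plus a fixed per-library tag, so identical seeds give
byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .iolib import (
    ASSAYS, GENOTYPES, STAGES, GenomicInterval, SampleKey,
    empty_read_table, validate_read_table,
    write_bed, write_fasta, write_gff3_genes, write_results_tsv,
)
from .phasing import revcomp_dna, rna_to_dna, scan_mir_site

#: Packaged default trigger: a synthetic 22-nt stand-in for mature miR2275.
#: Any 22-mer works for synthetic runs; real analyses pass the real sequence.
DEFAULT_MIR2275 = "UGCGAUCCUAGGUUCAACUCAU"

LOCUS_CLASSES = ("eat1_dep", "eat1_indep", "constitutive", "high_var", "no_site")
#: Classes that carry an embedded trigger site.
SITE_CLASSES = ("eat1_dep", "eat1_indep", "constitutive", "high_var")
#: Classes that are planted negatives for the end-to-end recovery test.
DECOY_CLASSES = ("eat1_indep", "constitutive", "high_var", "no_site")

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def default_expression_profile() -> dict:
    """Per-locus mean read counts per library, by assay / class / condition.

    The eat1_dep means encode the published fold structure: precursor
    (mRNA) abundance 688-fold over ST.1, 24-fold over ST.4 and 55-fold over
    eat1-4 at ST.2; 24-nt sRNAs persist into ST.4 but collapse in eat1-4.
    """
    dep_mrna = {
        ("WT", "ST.1"): 2000 / 688, ("WT", "ST.2"): 2000.0, ("WT", "ST.4"): 2000 / 24,
        ("eat1-4", "ST.1"): 2000 / 688, ("eat1-4", "ST.2"): 2000 / 55, ("eat1-4", "ST.4"): 2000 / 55,
    }
    dep_srna = {
        ("WT", "ST.1"): 30.0, ("WT", "ST.2"): 3000.0, ("WT", "ST.4"): 3000.0,
        ("eat1-4", "ST.1"): 30.0, ("eat1-4", "ST.2"): 3000 / 55, ("eat1-4", "ST.4"): 3000 / 55,
    }
    indep_mrna = {(g, s): 20.0 for g in ("WT", "eat1-4") for s in STAGES}
    indep_mrna[("WT", "ST.2")] = 2000.0
    indep_mrna[("eat1-4", "ST.2")] = 2000.0
    indep_srna = {(g, s): 30.0 for g in ("WT", "eat1-4") for s in STAGES}
    indep_srna[("WT", "ST.2")] = 3000.0
    indep_srna[("eat1-4", "ST.2")] = 3000.0
    const_mrna = {(g, s): 500.0 for g in ("WT", "eat1-4") for s in STAGES}
    const_srna = {(g, s): 500.0 for g in ("WT", "eat1-4") for s in STAGES}
    return {
        "mRNA": {
            "eat1_dep": dep_mrna, "high_var": dep_mrna, "no_site": dep_mrna,
            "eat1_indep": indep_mrna, "constitutive": const_mrna,
            "coding": {(g, s): 1000.0 for g in ("WT", "eat1-4") for s in STAGES},
        },
        "sRNA": {
            "eat1_dep": dep_srna, "high_var": dep_srna, "no_site": dep_srna,
            "eat1_indep": indep_srna, "constitutive": const_srna,
            "repeat": {(g, s): 1000.0 for g in ("WT", "eat1-4") for s in STAGES},
        },
    }


def default_rip_mixture() -> dict:
    """Stage-dependent origin mixtures for WT and eat1-4 RIP libraries.

    WT values follow the published pie-chart shares (PHAS-derived species
    essentially absent at ST.1, 5.2% at ST.2, 9.0% at ST.4); eat1-4 keeps
    PHAS species near zero at every stage.
    """
    wt = {
        "ST.1": {"PHAS": 0.0005, "coding": 0.102, "intergenic": 0.326, "repeat": 0.571},
        "ST.2": {"PHAS": 0.052, "coding": 0.111, "intergenic": 0.287, "repeat": 0.550},
        "ST.4": {"PHAS": 0.090, "coding": 0.107, "intergenic": 0.276, "repeat": 0.527},
    }
    eat1 = {
        st: {"PHAS": 0.0005, "coding": wt[st]["coding"], "intergenic": wt[st]["intergenic"],
             "repeat": wt[st]["repeat"]}
        for st in STAGES
    }
    return {"WT": wt, "eat1-4": eat1}


@dataclass
class SimConfig:
    """All knobs of the simulator; defaults define the study conditions."""

    seed: int = 1
    n_chroms: int = 2
    chrom_len: int = 200_000
    n_coding_genes: int = 30
    coding_len: int = 2000
    n_repeats: int = 20
    repeat_len: int = 500
    n_phas_eat1_dep: int = 20
    n_phas_eat1_indep: int = 10
    n_decoy_lincrna: int = 10          # constitutively expressed lincRNAs
    n_decoy_highvar: int = 10
    n_decoy_nosite: int = 10
    phas_len: tuple = (500, 1000)
    in_phase_fraction: float = 0.8
    mir_seq: str = DEFAULT_MIR2275
    expression_profile: dict = field(default_factory=default_expression_profile)
    n_replicates: int = 3
    replicate_cv: float = 0.15
    highvar_multipliers: tuple = (0.05, 0.05, 2.9)   # WT ST.2 replicate scaling
    mrna_read_len: int = 100
    mrna_background_reads: int = 50
    srna_background_reads: int = 5000
    srna_mismatch_fraction: float = 0.02
    # degradome
    degradome_reads_per_locus: float = 200.0
    degradome_peak_fraction: float = 0.5
    degradome_match_fraction: float = 0.7
    degradome_background_reads: int = 1000
    # RIP
    rip_lib_size: int = 50_000
    rip_replicates: int = 2
    rip_mixture: dict = field(default_factory=default_rip_mixture)
    fivep_c_bias: float = 0.9
    mel1_depletion: float = 20.0
    n_rip_species: dict = field(default_factory=lambda: {
        "PHAS": 60, "coding": 30, "intergenic": 60, "repeat": 100, "background": 300,
    })
    min_feature_gap: int = 300
    max_site_mismatch: float = 4.0     # scrubbing threshold for spurious sites

    def __post_init__(self) -> None:
        if not (0.0 <= self.in_phase_fraction <= 1.0):
            raise ValueError("in_phase_fraction must be in [0, 1]")
        if not (0.0 <= self.fivep_c_bias <= 1.0):
            raise ValueError("fivep_c_bias must be in [0, 1]")
        if self.phas_len[0] <= len(self.mir_seq):
            raise ValueError("phas_len must exceed the trigger site length")
        if self.replicate_cv >= 0.5:
            raise ValueError("replicate_cv must stay below 0.5 so clean loci pass "
                             "the replicate-dispersion condition by construction")

    @property
    def mir_dna(self) -> str:
        return rna_to_dna(self.mir_seq)


def library_rng(seed: int, key: SampleKey) -> np.random.Generator:
    """One documented PRNG stream per library."""
    return np.random.default_rng(
        [seed, ASSAYS.index(key.assay), GENOTYPES.index(key.genotype),
         STAGES.index(key.stage), key.replicate]
    )


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

@dataclass
class SyntheticGenome:
    """Genome sequence, annotation and the planted-locus truth table."""

    genome: dict                 # chrom -> sequence (str)
    genes: pd.DataFrame          # chrom,start,end,strand,gene_id,biotype
    repeats: pd.DataFrame        # chrom,start,end,name,family_hits,strand
    truth: pd.DataFrame          # locus_id,chrom,start,end,strand,locus_class,
                                 # has_site,site_start,site_end,origin
    config: SimConfig

    @property
    def chrom_lengths(self) -> dict:
        return {c: len(s) for c, s in self.genome.items()}

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(self.genome, out / "genome.fa")
        write_gff3_genes(self.genes, out / "genes.gff3")
        rep = self.repeats.rename(columns={"family_hits": "score"})
        write_bed(rep[["chrom", "start", "end", "name", "score", "strand"]],
                  out / "repeats.bed")
        bed = self.truth.rename(columns={"locus_id": "name"})
        bed["score"] = 0
        write_bed(bed[["chrom", "start", "end", "name", "score", "strand"]],
                  out / "phas_truth.bed")
        write_results_tsv(self.truth, out / "phas_truth.tsv")


def _random_seq_array(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=n)]


def _place_features(rng, chrom_len, lengths, min_gap):
    """Place features of given lengths on one chromosome without overlap.

    Returns sorted start positions.  Raises if the chromosome cannot hold
    them at the requested minimum gap.
    """
    n = len(lengths)
    total = int(np.sum(lengths))
    slack = chrom_len - total - (n + 1) * min_gap
    if slack < 0:
        raise ValueError(
            f"cannot place {n} features (total {total} bp) on a {chrom_len} bp "
            f"chromosome without overlap at gap {min_gap}"
        )
    cuts = np.sort(rng.integers(0, slack + 1, size=n))
    starts = np.empty(n, dtype=np.int64)
    pos = min_gap
    for i, length in enumerate(lengths):
        starts[i] = pos + cuts[i]
        pos += length + min_gap
    return starts


def generate_genome(cfg: SimConfig) -> SyntheticGenome:
    """Build the miniature genome with embedded trigger sites and truth."""
    rng = np.random.default_rng([cfg.seed, 7])
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    seqs = {c: _random_seq_array(rng, cfg.chrom_len) for c in chroms}

    # assemble the feature roster, shuffle, deal round-robin to chromosomes
    roster: list[tuple[str, int]] = []
    roster += [("coding", cfg.coding_len)] * cfg.n_coding_genes
    roster += [("repeat", cfg.repeat_len)] * cfg.n_repeats
    class_counts = {
        "eat1_dep": cfg.n_phas_eat1_dep, "eat1_indep": cfg.n_phas_eat1_indep,
        "constitutive": cfg.n_decoy_lincrna, "high_var": cfg.n_decoy_highvar,
        "no_site": cfg.n_decoy_nosite,
    }
    for cls, n in class_counts.items():
        roster += [(cls, int(L)) for L in rng.integers(cfg.phas_len[0],
                                                       cfg.phas_len[1] + 1, size=n)]
    order = rng.permutation(len(roster))
    per_chrom: dict[str, list] = {c: [] for c in chroms}
    for idx, ri in enumerate(order):
        per_chrom[chroms[idx % len(chroms)]].append(roster[ri])

    genes, repeats, truth = [], [], []
    counters: dict[str, int] = {}
    mir_dna = cfg.mir_dna
    site_len = len(mir_dna)

    for chrom in chroms:
        feats = per_chrom[chrom]
        starts = _place_features(rng, cfg.chrom_len,
                                 [L for _, L in feats], cfg.min_feature_gap)
        for (kind, length), start in zip(feats, starts):
            start, end = int(start), int(start + length)
            counters[kind] = counters.get(kind, 0) + 1
            idx = counters[kind]
            if kind == "coding":
                genes.append((chrom, start, end, "+" if rng.random() < 0.5 else "-",
                              f"gene{idx:03d}", "protein_coding"))
                continue
            if kind == "repeat":
                repeats.append((chrom, start, end, f"repeat{idx:03d}",
                                int(rng.integers(2, 61)), "+"))
                continue
            strand = "+" if rng.random() < 0.5 else "-"
            has_site = kind != "no_site"
            if has_site:
                # plant the site in the 5' third of the precursor orientation
                lo = start + 10 if strand == "+" else end - length // 3
                hi = (start + length // 3 - site_len) if strand == "+" else end - 10 - site_len
                s = int(rng.integers(lo, hi + 1))
                site_start, site_end = s, s + site_len
                origin = s + 12 if strand == "+" else site_end - 13
            else:
                site_start = site_end = -1
                origin = start + length // 4
            truth.append((f"{kind}_{idx:03d}", chrom, start, end, strand, kind,
                          has_site, site_start, site_end, int(origin)))

    truth_df = pd.DataFrame(truth, columns=[
        "locus_id", "chrom", "start", "end", "strand", "locus_class",
        "has_site", "site_start", "site_end", "origin"])
    genes_df = pd.DataFrame(genes, columns=["chrom", "start", "end", "strand",
                                            "gene_id", "biotype"])
    repeats_df = pd.DataFrame(repeats, columns=["chrom", "start", "end", "name",
                                                "family_hits", "strand"])

    # embed sites, then scrub every planted locus of chance trigger matches
    for row in truth_df.itertuples(index=False):
        if row.has_site:
            patt = revcomp_dna(mir_dna) if row.strand == "+" else mir_dna
            seqs[row.chrom][row.site_start:row.site_end] = np.frombuffer(
                patt.encode(), dtype="S1")
    _scrub_spurious_sites(rng, seqs, truth_df, mir_dna, cfg.max_site_mismatch)

    genome = {c: seqs[c].tobytes().decode() for c in chroms}
    return SyntheticGenome(genome=genome, genes=genes_df, repeats=repeats_df,
                           truth=truth_df, config=cfg)


def _scrub_spurious_sites(rng, seqs, truth_df, mir_dna, max_mm, max_iter=50):
    """Resample locus sequence until only the planted site matches the trigger.

    Guarantees the truth labels: site-bearing loci contain exactly one
    scorable site, no-site decoys contain none.
    """
    for row in truth_df.itertuples(index=False):
        arr = seqs[row.chrom]
        for _ in range(max_iter):
            locus_seq = arr[row.start:row.end].tobytes().decode()
            sites = scan_mir_site(locus_seq, mir_dna, max_mismatch=max_mm)
            keep = [s for s in sites
                    if row.has_site and s.site_start == row.site_start - row.start]
            spurious = [s for s in sites if s not in keep]
            if not spurious and len(sites) == len(keep):
                break
            for s in spurious:
                a, b = row.start + s.site_start, row.start + s.site_end
                # avoid touching the planted site itself
                if row.has_site and a < row.site_end and row.site_start < b:
                    a = max(a, row.site_end) if a >= row.site_start else a
                    b = min(b, row.site_start) if b <= row.site_end else b
                    if a >= b:
                        continue
                arr[a:b] = _random_seq_array(rng, b - a)
        else:  # pragma: no cover - astronomically unlikely
            raise RuntimeError(f"could not scrub spurious trigger sites in {row.locus_id}")


# ---------------------------------------------------------------------------
# read-table assembly helpers
# ---------------------------------------------------------------------------

def _grid_starts(lo: int, hi: int, anchor: int, step: int = 24) -> np.ndarray:
    """All positions p in [lo, hi] with p == anchor (mod step)."""
    k_min = math.ceil((lo - anchor) / step)
    k_max = math.floor((hi - anchor) / step)
    if k_max < k_min:
        return np.empty(0, dtype=np.int64)
    return anchor + step * np.arange(k_min, k_max + 1, dtype=np.int64)


def _noise(rng, cv: float, size=None) -> np.ndarray:
    """Mean-one lognormal multiplier with coefficient of variation ``cv``."""
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return rng.lognormal(mean=-sigma * sigma / 2.0, sigma=sigma, size=size)


def _assemble(chroms, starts, ends, strands, mismatches, hits) -> pd.DataFrame:
    n = len(starts)
    df = pd.DataFrame({
        "chrom": chroms,
        "start": np.asarray(starts, dtype=np.int64),
        "end": np.asarray(ends, dtype=np.int64),
        "name": ".",
        "copies": np.ones(n, dtype=np.int64),
        "strand": strands,
        "read_length": np.asarray(ends, dtype=np.int64) - np.asarray(starts, dtype=np.int64),
        "mismatches": np.asarray(mismatches, dtype=np.int64),
        "hits": np.asarray(hits, dtype=np.int64),
    })
    return df


def _background_reads(rng, chrom_lengths: Mapping[str, int], n: int,
                      lengths: np.ndarray, mismatch_p=0.0, multihit_p=0.0) -> pd.DataFrame:
    names = list(chrom_lengths)
    sizes = np.array([chrom_lengths[c] for c in names], dtype=float)
    ci = rng.choice(len(names), size=n, p=sizes / sizes.sum())
    lens = rng.choice(lengths, size=n)
    starts = (rng.random(n) * (sizes[ci] - lens)).astype(np.int64)
    mm = (rng.random(n) < mismatch_p).astype(np.int64)
    hits = np.ones(n, dtype=np.int64)
    multi = rng.random(n) < multihit_p
    hits[multi] = rng.integers(2, 81, size=int(multi.sum()))
    strands = np.where(rng.random(n) < 0.5, "+", "-")
    return _assemble(np.array(names, dtype=object)[ci], starts, starts + lens,
                     strands, mm, hits)


# ---------------------------------------------------------------------------
# sRNA libraries
# ---------------------------------------------------------------------------

def _locus_mean(cfg: SimConfig, assay: str, cls: str, key: SampleKey,
                replicate_index: int) -> float:
    prof = cfg.expression_profile[assay].get(cls)
    if prof is None:
        return 0.0
    mean = prof.get((key.genotype, key.stage), 0.0)
    if cls == "high_var" and key.genotype == "WT" and key.stage == "ST.2":
        mean *= cfg.highvar_multipliers[replicate_index % len(cfg.highvar_multipliers)]
    return mean


def generate_srna_library(gnm: SyntheticGenome, key: SampleKey,
                          cfg: SimConfig | None = None) -> pd.DataFrame:
    """Simulate one 24-nt small-RNA library as a BED6+3 read table.

    PHAS-class loci emit 24-nt reads whose 5' ends sit on the phase grid
    anchored at the planted origin with probability ``in_phase_fraction``
    (plus-strand reads start at origin + 24k; minus-strand reads end at
    origin + 24k + 2, the dicer-duplex register); off-phase reads are
    uniform within the locus but never on-grid, so the planted fraction is
    exactly binomial.  Repeat loci emit constitutive multi-mapping reads;
    background reads of mixed length, mismatch and hit count are scattered
    genome-wide to exercise the read filter.
    """
    cfg = cfg or gnm.config
    rng = library_rng(cfg.seed, key)
    parts = []
    for row in gnm.truth.itertuples(index=False):
        mean = _locus_mean(cfg, "sRNA", row.locus_class, key, key.replicate - 1)
        n = int(rng.poisson(mean * _noise(rng, cfg.replicate_cv)))
        if n == 0:
            continue
        n_in = int(rng.binomial(n, cfg.in_phase_fraction))
        n_plus_in = int(rng.binomial(n_in, 0.5))
        plus_grid = _grid_starts(row.start, row.end - 24, row.origin)
        minus_grid = _grid_starts(row.start + 24, row.end, row.origin + 2) - 24
        starts, strands = [], []
        if n_plus_in:
            starts.append(rng.choice(plus_grid, size=n_plus_in))
            strands.append(np.repeat("+", n_plus_in))
        if n_in - n_plus_in:
            starts.append(rng.choice(minus_grid, size=n_in - n_plus_in))
            strands.append(np.repeat("-", n_in - n_plus_in))
        n_out = n - n_in
        if n_out:
            p = rng.integers(row.start, row.end - 23, size=n_out)
            s_out = np.where(rng.random(n_out) < 0.5, "+", "-")
            anchor = np.where(s_out == "+", row.origin, row.origin + 2 - 24)
            on_grid = (p - anchor) % 24 == 0
            p = np.where(on_grid, p + rng.integers(1, 24, size=n_out), p)
            p = np.where(p > row.end - 24, p - 24, p)
            starts.append(p)
            strands.append(s_out)
        st = np.concatenate(starts)
        sd = np.concatenate(strands)
        mm = (rng.random(len(st)) < cfg.srna_mismatch_fraction).astype(np.int64)
        parts.append(_assemble(row.chrom, st, st + 24, sd, mm, np.ones(len(st), int)))

    rep_mean = cfg.expression_profile["sRNA"]["repeat"]
    for row in gnm.repeats.itertuples(index=False):
        mean = rep_mean.get((key.genotype, key.stage), 0.0)
        n = int(rng.poisson(mean * _noise(rng, cfg.replicate_cv)))
        if n == 0:
            continue
        st = rng.integers(row.start, row.end - 23, size=n)
        sd = np.where(rng.random(n) < 0.5, "+", "-")
        parts.append(_assemble(row.chrom, st, st + 24, sd,
                               np.zeros(n, int), np.full(n, row.family_hits, int)))

    if cfg.srna_background_reads:
        parts.append(_background_reads(
            rng, gnm.chrom_lengths, cfg.srna_background_reads,
            lengths=np.arange(20, 27), mismatch_p=0.15, multihit_p=0.15))
    df = pd.concat(parts, ignore_index=True) if parts else empty_read_table()
    return validate_read_table(df)


def generate_mrna_library(gnm: SyntheticGenome, key: SampleKey,
                          cfg: SimConfig | None = None) -> pd.DataFrame:
    """Simulate one mRNA-seq library (coding genes + precursor transcripts)."""
    cfg = cfg or gnm.config
    rng = library_rng(cfg.seed, key)
    L = cfg.mrna_read_len
    parts = []
    feats = [(row, "coding") for row in gnm.genes.itertuples(index=False)]
    feats += [(row, row.locus_class) for row in gnm.truth.itertuples(index=False)]
    for row, cls in feats:
        mean = _locus_mean(cfg, "mRNA", cls, key, key.replicate - 1)
        n = int(rng.poisson(mean * _noise(rng, cfg.replicate_cv)))
        if n == 0:
            continue
        hi = max(row.start + 1, row.end - L)
        st = rng.integers(row.start, hi, size=n)
        en = np.minimum(st + L, row.end)
        sd = np.where(rng.random(n) < 0.5, "+", "-")
        parts.append(_assemble(row.chrom, st, en, sd, np.zeros(n, int), np.ones(n, int)))
    if cfg.mrna_background_reads:
        parts.append(_background_reads(rng, gnm.chrom_lengths,
                                       cfg.mrna_background_reads,
                                       lengths=np.array([L])))
    df = pd.concat(parts, ignore_index=True) if parts else empty_read_table()
    return validate_read_table(df)


# ---------------------------------------------------------------------------
# degradome
# ---------------------------------------------------------------------------

def generate_degradome_library(gnm: SyntheticGenome, cfg: SimConfig | None = None
                               ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one degradome (PARE) library of 20/21-nt reads.

    For a fraction ``degradome_match_fraction`` of site-bearing loci the
    dominant 5'-end stack is planted exactly at the predicted cleavage
    position on the precursor strand; for the rest it is displaced by
    10-49 nt.  Returns ``(read table, per-locus truth)`` where the truth
    records the planted peak and whether it matches the prediction.
    """
    cfg = cfg or gnm.config
    rng = np.random.default_rng([cfg.seed, 11])
    parts, truth = [], []
    for row in gnm.truth.itertuples(index=False):
        if not row.has_site:
            continue
        matched = bool(rng.random() < cfg.degradome_match_fraction)
        n = int(rng.poisson(cfg.degradome_reads_per_locus))
        if n == 0:
            truth.append((row.locus_id, -1, matched, 0))
            continue
        if matched:
            peak = int(row.origin)
        else:
            shift = int(rng.integers(10, 50)) * (1 if rng.random() < 0.5 else -1)
            peak = int(np.clip(row.origin + shift, row.start, row.end - 22))
        n_peak = int(rng.binomial(n, cfg.degradome_peak_fraction))
        fivep = np.full(n_peak, peak, dtype=np.int64)
        rest = rng.integers(row.start, row.end - 21, size=n - n_peak)
        pos5 = np.concatenate([fivep, rest])
        lens = rng.choice([20, 21], size=n)
        if row.strand == "+":
            st, en = pos5, pos5 + lens
        else:
            en = pos5 + 1
            st = en - lens
        sd = np.repeat(row.strand, n)
        parts.append(_assemble(row.chrom, st, en, sd, np.zeros(n, int), np.ones(n, int)))
        truth.append((row.locus_id, peak, matched, n))
    if cfg.degradome_background_reads:
        parts.append(_background_reads(rng, gnm.chrom_lengths,
                                       cfg.degradome_background_reads,
                                       lengths=np.arange(19, 23)))
    df = pd.concat(parts, ignore_index=True) if parts else empty_read_table()
    truth_df = pd.DataFrame(truth, columns=["locus_id", "planted_peak", "planted_match", "n_reads"])
    return validate_read_table(df), truth_df


# ---------------------------------------------------------------------------
# RIP
# ---------------------------------------------------------------------------

_COMP = str.maketrans("ACGTN", "TGCAN")


def _slice_seq(genome: Mapping[str, str], chrom: str, start: int, end: int,
               strand: str) -> str:
    s = genome[chrom][start:end]
    return s if strand == "+" else s[::-1].translate(_COMP)


def build_rip_species(gnm: SyntheticGenome, cfg: SimConfig | None = None) -> pd.DataFrame:
    """Build the deterministic pool of 24-nt species the RIP libraries sample.

    PHAS-derived species sit on the phase grid of expressed (eat1_dep)
    loci and start with C with probability ``fivep_c_bias``; coding,
    repeat and intergenic species are uniform 24-mers from their region
    type.  A separate pool of background species fills the mel1-1
    libraries so that true masiRNAs stay >= 4-fold WT-enriched.
    """
    cfg = cfg or gnm.config
    rng = np.random.default_rng([cfg.seed, 13])
    genome = gnm.genome
    rows = []

    dep = gnm.truth[gnm.truth.locus_class == "eat1_dep"]
    cells = []
    for row in dep.itertuples(index=False):
        for s in _grid_starts(row.start, row.end - 24, row.origin):
            cells.append((row.chrom, int(s), "+"))
        for s in _grid_starts(row.start + 24, row.end, row.origin + 2) - 24:
            cells.append((row.chrom, int(s), "-"))
    seqs = [_slice_seq(genome, c, s, s + 24, sd) for c, s, sd in cells]
    c_start = [i for i, q in enumerate(seqs) if q[0] == "C"]
    other = [i for i, q in enumerate(seqs) if q[0] != "C"]
    n_phas = cfg.n_rip_species["PHAS"]
    want_c = rng.random(n_phas) < cfg.fivep_c_bias
    picked: list[int] = []
    pool_c, pool_o = list(rng.permutation(c_start)), list(rng.permutation(other))
    for w in want_c:
        src = pool_c if (w and pool_c) else pool_o if pool_o else pool_c
        picked.append(int(src.pop()))
    for j, i in enumerate(picked):
        c, s, sd = cells[i]
        rows.append((f"phas_sp{j:03d}", "PHAS", c, s, s + 24, sd, seqs[i]))

    def _uniform_species(label, cat, frame, n):
        idx = rng.integers(0, len(frame), size=n)
        for j, fi in enumerate(idx):
            row = frame.iloc[int(fi)]
            s = int(rng.integers(row.start, row.end - 23))
            sd = "+" if rng.random() < 0.5 else "-"
            rows.append((f"{label}{j:03d}", cat, row.chrom, s, s + 24, sd,
                         _slice_seq(genome, row.chrom, s, s + 24, sd)))

    _uniform_species("coding_sp", "coding", gnm.genes, cfg.n_rip_species["coding"])
    _uniform_species("repeat_sp", "repeat", gnm.repeats, cfg.n_rip_species["repeat"])

    # intergenic: rejection-sample positions clear of every annotated feature
    occupied = pd.concat([
        gnm.genes[["chrom", "start", "end"]],
        gnm.repeats[["chrom", "start", "end"]],
        gnm.truth[["chrom", "start", "end"]],
    ], ignore_index=True)
    lengths = gnm.chrom_lengths
    names = list(lengths)
    need = cfg.n_rip_species["intergenic"] + cfg.n_rip_species["background"]
    got = 0
    while got < need:
        c = names[int(rng.integers(0, len(names)))]
        s = int(rng.integers(0, lengths[c] - 24))
        occ = occupied[occupied.chrom == c]
        if ((occ.start < s + 24) & (s < occ.end)).any():
            continue
        cat = "intergenic" if got < cfg.n_rip_species["intergenic"] else "background"
        j = got if cat == "intergenic" else got - cfg.n_rip_species["intergenic"]
        sd = "+" if rng.random() < 0.5 else "-"
        rows.append((f"{cat}_sp{j:03d}", cat, c, s, s + 24, sd,
                     _slice_seq(genome, c, s, s + 24, sd)))
        got += 1

    df = pd.DataFrame(rows, columns=["species_id", "origin_class", "chrom",
                                     "start", "end", "strand", "sequence"])
    df = df.drop_duplicates(subset="sequence").reset_index(drop=True)
    # per-species within-category weight, fixed once for all libraries
    df["weight"] = rng.uniform(0.5, 1.5, size=len(df))
    return df


def generate_rip_library(species: pd.DataFrame, key: SampleKey,
                         cfg: SimConfig) -> pd.DataFrame:
    """Simulate one MEL1 RIP library over the shared species pool.

    WT and eat1-4 libraries draw ``rip_lib_size`` reads from the stage
    mixture over origin categories; mel1-1 libraries keep the same species
    at 1/``mel1_depletion`` of the matched WT share, topped up with
    background species, so every pooled species is >= 4-fold WT-enriched.
    """
    rng = library_rng(cfg.seed, key)
    w = species["weight"].to_numpy().copy()
    cat = species["origin_class"].to_numpy()
    probs = np.zeros(len(species))
    mixture = cfg.rip_mixture["WT"] if key.genotype == "mel1-1" else cfg.rip_mixture[key.genotype]
    share = dict(mixture[key.stage])
    total_share = sum(share.values())
    for c, frac in share.items():
        mask = cat == c
        if mask.any():
            probs[mask] = (frac / total_share) * w[mask] / w[mask].sum()
    if key.genotype == "mel1-1":
        probs = probs / cfg.mel1_depletion
        bg = cat == "background"
        probs[bg] = (1.0 - probs.sum()) * w[bg] / w[bg].sum()
    probs = probs / probs.sum()
    counts = rng.multinomial(cfg.rip_lib_size, probs)
    keep = counts > 0
    sub = species.loc[keep].reset_index(drop=True)
    df = pd.DataFrame({
        "chrom": sub["chrom"],
        "start": sub["start"].astype(np.int64),
        "end": sub["end"].astype(np.int64),
        "name": sub["species_id"],
        "copies": counts[keep].astype(np.int64),
        "strand": sub["strand"],
        "read_length": np.int64(24),
        "mismatches": np.int64(0),
        "hits": np.int64(1),
    })
    df["sequence"] = sub["sequence"]
    validate_read_table(df)
    return df


# ---------------------------------------------------------------------------
# whole dataset
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    """Everything one seed produces: genome, truth and all libraries."""

    genome: SyntheticGenome
    mrna: dict          # SampleKey -> read table
    srna: dict          # SampleKey -> read table
    degradome: pd.DataFrame
    degradome_truth: pd.DataFrame
    rip_species: pd.DataFrame
    rip: dict           # SampleKey -> read table (with sequence column)


def generate_dataset(cfg: SimConfig) -> SyntheticDataset:
    """Generate the full study design for one seed."""
    gnm = generate_genome(cfg)
    mrna, srna, rip = {}, {}, {}
    for genotype in ("WT", "eat1-4"):
        for stage in STAGES:
            for rep in range(1, cfg.n_replicates + 1):
                for assay, store, gen in (("mRNA", mrna, generate_mrna_library),
                                          ("sRNA", srna, generate_srna_library)):
                    key = SampleKey(genotype, stage, rep, assay)
                    store[key] = gen(gnm, key, cfg)
    species = build_rip_species(gnm, cfg)
    for genotype in ("WT", "mel1-1", "eat1-4"):
        for stage in STAGES:
            for rep in range(1, cfg.rip_replicates + 1):
                key = SampleKey(genotype, stage, rep, "RIP")
                rip[key] = generate_rip_library(species, key, cfg)
    deg, deg_truth = generate_degradome_library(gnm, cfg)
    return SyntheticDataset(genome=gnm, mrna=mrna, srna=srna, degradome=deg,
                            degradome_truth=deg_truth, rip_species=species, rip=rip)
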