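"""File formats, domain types, run configuration and logging.

Every coordinate exchanged between modules is 0-based half-open.  BED is
the native convention and is preserved bit-exactly; GFF3 (1-based
inclusive) is converted at the parse boundary and nowhere else.

Aligned reads travel as pandas DataFrames in the BED6+3 dialect
(``READ_TABLE_COLUMNS``): the BED score column carries the collapsed copy
number, and three extra columns carry read length, mismatch count and the
number of genomic alignments (hits).  A thin SAM converter is provided for
interoperability; BAM/CRAM handling is out of scope.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("phasworks")

STRANDS = ("+", "-", ".")
GENOTYPES = ("WT", "eat1-4", "mel1-1", "other")
STAGES = ("ST.1", "ST.2", "ST.4")
ASSAYS = ("mRNA", "sRNA", "RIP", "degradome")

#: Column order of the BED6+3 read-table dialect.
READ_TABLE_COLUMNS = [
    "chrom", "start", "end", "name", "copies", "strand",
    "read_length", "mismatches", "hits",
]

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains_point(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end


@dataclass(frozen=True)
class AlignedReadRecord:
    """One aligned (possibly collapsed) small-RNA or mRNA read."""

    interval: GenomicInterval
    read_length: int
    copies: int = 1
    mismatches: int = 0
    hits: int = 1
    five_prime_nt: str = "N"

    def __post_init__(self) -> None:
        if len(self.interval) != self.read_length:
            raise ValueError("interval span must equal read_length")
        if self.copies < 1:
            raise ValueError("copies must be >= 1 for an emitted record")
        if self.mismatches < 0 or self.hits < 1:
            raise ValueError("mismatches must be >= 0 and hits >= 1")
        if self.five_prime_nt not in ("A", "C", "G", "T", "U", "N"):
            raise ValueError(f"invalid 5' nucleotide {self.five_prime_nt!r}")


@dataclass(frozen=True)
class SampleKey:
    """Genotype x stage x replicate x assay label of one library."""

    genotype: str
    stage: str
    replicate: int
    assay: str

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValueError(f"genotype must be one of {GENOTYPES}")
        if self.stage not in STAGES:
            raise ValueError(f"stage must be one of {STAGES} (only these were sequenced)")
        if self.replicate < 1:
            raise ValueError("replicate must be a positive integer")
        if self.assay not in ASSAYS:
            raise ValueError(f"assay must be one of {ASSAYS}")

    def encode(self) -> str:
        return f"{self.assay}|{self.genotype}|{self.stage}|r{self.replicate}"

    @classmethod
    def parse(cls, text: str) -> "SampleKey":
        assay, genotype, stage, rep = text.split("|")
        return cls(genotype=genotype, stage=stage, replicate=int(rep.lstrip("r")), assay=assay)


@dataclass(frozen=True)
class Thresholds:
    """All tunable cutoffs of the pipeline with their published defaults.

    The defaults encode the analysis exactly as stated: strictly >2-fold
    enrichment tests, replicate SD strictly below half the mean, lincRNA
    length strictly >200 bp, 24-nt sRNA FPKM strictly >10 for a PHAS call,
    reads discarded above 50 genomic hits or any mismatch, 20/21-nt
    degradome reads, masiRNAs at >=15 RPM and >=4-fold over mel1-1, a
    50 kbp / 25 kbp sliding window, and the phase origin at the 13th
    nucleotide of the 22-mer trigger site.
    """

    fold_change_min: float = 2.0
    sd_over_mean_max: float = 0.5
    lincrna_min_len: int = 200          # strict >
    phas_min_srna_fpkm: float = 10.0    # strict >
    max_hits: int = 50
    max_mismatches: int = 0
    srna_len: int = 24
    degradome_lens: tuple = (20, 21)
    masirna_min_rpm: float = 15.0       # >=
    masirna_min_fold: float = 4.0       # >=
    window: int = 50_000
    step: int = 25_000
    mir_site_len: int = 22
    cleavage_offset_in_site: int = 13   # 1-based within the site
    pseudocount: float = 0.01           # FPKM/RPM added to fold-change denominators
    antisense_offset: int = 2           # dicer duplex 3' overhang, nt
    max_site_mismatch: float = 4.0      # weighted; G:U wobble = 0.5
    degradome_tolerance: int = 0
    degradome_min_reads: int = 5
    window_cycles: int = 9              # phasing-score window, in 24-nt cycles

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if f.name in ("max_mismatches", "degradome_tolerance"):
                if v < 0:
                    raise ValueError(f"{f.name} must be >= 0")
            elif f.name == "degradome_lens":
                if not v or any(x <= 0 for x in v):
                    raise ValueError("degradome_lens must be positive")
            elif isinstance(v, (int, float)) and v <= 0:
                raise ValueError(f"{f.name} must be strictly positive")
        if self.cleavage_offset_in_site > self.mir_site_len:
            raise ValueError("cleavage_offset_in_site must lie within the site")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path) -> pd.DataFrame:
    """Read a BED3/BED6 file into a DataFrame (0-based half-open, native).

    Returns columns ``chrom,start,end,name,score,strand``; absent optional
    columns are filled with ``.``/``0``/``.``.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 tab-separated fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric coordinates") from exc
            if start >= end:
                raise ValueError(f"{path}:{lineno}: empty or inverted interval ({start} >= {end})")
            name = fields[3] if len(fields) > 3 else "."
            score = fields[4] if len(fields) > 4 else "0"
            strand = fields[5] if len(fields) > 5 else "."
            if strand not in STRANDS:
                raise ValueError(f"{path}:{lineno}: invalid strand {strand!r}")
            rows.append((fields[0], start, end, name, score, strand))
    df = pd.DataFrame(rows, columns=BED_COLUMNS)
    if len(df):
        # interval invariants already enforced line-by-line
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    cols = [c for c in BED_COLUMNS if c in df.columns]
    df.to_csv(path, sep="\t", header=False, index=False, columns=cols)


def intervals_from_frame(df: pd.DataFrame) -> list[GenomicInterval]:
    return [
        GenomicInterval(r.chrom, int(r.start), int(r.end),
                        r.strand if getattr(r, "strand", ".") in STRANDS else ".")
        for r in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# read tables (BED6+3)
# ---------------------------------------------------------------------------

def empty_read_table() -> pd.DataFrame:
    return pd.DataFrame({
        "chrom": pd.Series(dtype=object),
        "start": pd.Series(dtype=np.int64),
        "end": pd.Series(dtype=np.int64),
        "name": pd.Series(dtype=object),
        "copies": pd.Series(dtype=np.int64),
        "strand": pd.Series(dtype=object),
        "read_length": pd.Series(dtype=np.int64),
        "mismatches": pd.Series(dtype=np.int64),
        "hits": pd.Series(dtype=np.int64),
    })


def validate_read_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in READ_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"read table missing columns: {missing}")
    if len(df):
        if ((df["end"] - df["start"]) != df["read_length"]).any():
            raise ValueError("read table: interval span != read_length")
        if (df["copies"] < 1).any() or (df["hits"] < 1).any() or (df["mismatches"] < 0).any():
            raise ValueError("read table: copies/hits must be >=1, mismatches >=0")
        if (df["start"] < 0).any():
            raise ValueError("read table: negative start")
        if ~df["strand"].isin(("+", "-")).all():
            raise ValueError("read table: read strand must be + or -")
    return df


def read_reads_bed(path) -> pd.DataFrame:
    """Read an aligned-read table from the BED6+3 dialect."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=READ_TABLE_COLUMNS,
        dtype={"chrom": str, "name": str},
        comment="#",
    )
    return validate_read_table(df)


def write_reads_bed(df: pd.DataFrame, path) -> None:
    validate_read_table(df)
    df.to_csv(path, sep="\t", header=False, index=False, columns=READ_TABLE_COLUMNS)


def sam_to_read_table(path) -> pd.DataFrame:
    """Convert a (headered) SAM file to the BED6+3 read table.

    Mismatches come from the ``NM`` tag, hit counts from ``NH`` (default 1);
    unmapped records are skipped.  Provided for interoperability only — the
    pipeline itself exchanges BED6+3.
    """
    import pysam

    rows = []
    with pysam.AlignmentFile(str(path), "r") as fh:
        for aln in fh:
            if aln.is_unmapped:
                continue
            length = aln.query_length or aln.infer_query_length()
            rows.append((
                aln.reference_name,
                aln.reference_start,
                aln.reference_start + length,
                aln.query_name,
                1,
                "-" if aln.is_reverse else "+",
                length,
                aln.get_tag("NM") if aln.has_tag("NM") else 0,
                aln.get_tag("NH") if aln.has_tag("NH") else 1,
            ))
    df = pd.DataFrame(rows, columns=READ_TABLE_COLUMNS)
    return validate_read_table(df) if len(df) else empty_read_table()


def five_prime_positions(df: pd.DataFrame) -> np.ndarray:
    """Genomic coordinate of each read's biological 5' end."""
    starts = df["start"].to_numpy()
    ends = df["end"].to_numpy()
    return np.where(df["strand"].to_numpy() == "+", starts, ends - 1)


def five_prime_nucleotides(df: pd.DataFrame, genome: Mapping[str, str]) -> np.ndarray:
    """5'-terminal nucleotide of each read, read off the genome.

    Minus-strand reads report the complement of the base at ``end - 1``.
    """
    comp = str.maketrans("ACGTN", "TGCAN")
    out = np.empty(len(df), dtype=object)
    pos = five_prime_positions(df)
    for i, (chrom, p, strand) in enumerate(zip(df["chrom"], pos, df["strand"])):
        base = genome[chrom][p].upper()
        out[i] = base if strand == "+" else base.translate(comp)
    return out


# ---------------------------------------------------------------------------
# GFF3 / FASTA
# ---------------------------------------------------------------------------

def read_gff3_genes(path, biotype_attr: str = "biotype",
                    feature_type: str = "gene") -> pd.DataFrame:
    """Read gene records from a GFF3 file.

    Coordinates are converted from GFF3's 1-based inclusive convention to
    0-based half-open.  The biotype is taken from ``biotype_attr`` in
    column 9 (default ``biotype``), falling back to ``.``.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns")
            if fields[2] != feature_type:
                continue
            try:
                start1, end1 = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric coordinates") from exc
            attrs = dict(
                kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
            )
            rows.append((
                fields[0], start1 - 1, end1,
                fields[6] if fields[6] in STRANDS else ".",
                attrs.get("ID", attrs.get("gene_id", f"gene{lineno}")),
                attrs.get(biotype_attr, "."),
            ))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "gene_id", "biotype"])


def write_gff3_genes(df: pd.DataFrame, path) -> None:
    """Write gene records as GFF3 (converting back to 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in df.itertuples(index=False):
            attrs = f"ID={r.gene_id};biotype={r.biotype}"
            fh.write(
                f"{r.chrom}\tphasworks\tgene\t{r.start + 1}\t{r.end}\t.\t{r.strand}\t.\t{attrs}\n"
            )


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into ``{name: uppercase sequence}``."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate FASTA record {rec.id!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"empty sequence for FASTA record {rec.id!r}")
        out[rec.id] = seq
    return out


def write_fasta(seqs: Mapping[str, str], path, width: int = 60) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


# ---------------------------------------------------------------------------
# TSV results
# ---------------------------------------------------------------------------

def write_results_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    """Write a result table with deterministic column order and float format."""
    df.to_csv(path, sep="\t", index=index, float_format="%.6g")


def read_results_tsv(path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


# ---------------------------------------------------------------------------
# configuration / logging
# ---------------------------------------------------------------------------

def load_config(path) -> dict:
    """Load a YAML-or-JSON run configuration.

    Recognised top-level keys: ``seed`` (int), ``thresholds`` (field
    overrides for :class:`Thresholds`), ``sim`` (overrides for the
    synthetic-data :class:`~phasworks.synthetic_data.SimConfig`), and
    ``samples`` (a sample-sheet list of SampleKey mappings).
    """
    text = Path(path).read_text()
    cfg = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping")
    return cfg


def thresholds_from_config(cfg: dict) -> Thresholds:
    overrides = dict(cfg.get("thresholds", {}))
    if "degradome_lens" in overrides:
        overrides["degradome_lens"] = tuple(overrides["degradome_lens"])
    return Thresholds(**overrides)


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )


def log_filter(name: str, n_in: int, n_out: int) -> None:
    """INFO-log a records-in/records-out count for a filtering step."""
    logger.info("%s: %d records in, %d out (%.1f%% kept)",
                name, n_in, n_out, 100.0 * n_out / n_in if n_in else 100.0)
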