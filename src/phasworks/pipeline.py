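"""End-to-end orchestration over a synthetic dataset.

The run mirrors the published analysis order: filter 24-nt sRNA reads,
segment transcribed regions from pooled wild-type mRNA coverage, extract
intergenic lincRNAs, apply the three-condition EAT1-dependence call to
their mRNA FPKM, call 24-PHAS loci from 24-nt sRNA FPKM, scan each final
locus for the trigger site, anchor the phase register at the predicted
cleavage position, summarise in-phase fractions and phasing scores,
verify cleavage against the degradome, and call/classify masiRNAs from
the RIP libraries.  The ``site_confirmed`` subset (PHAS, EAT1-dependent
*and* trigger-bearing) is the analogue of the published 93-locus set and
is what recovery is scored on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from . import degradome as deg
from . import masirna as mas
from . import phas_discovery as disc
from . import phasing as ph
from . import srna_quant as quant
from . import stage_classifier as stc
from .iolib import GenomicInterval, SampleKey, Thresholds, write_bed, write_results_tsv
from .synthetic_data import SimConfig, SyntheticDataset, generate_dataset


@dataclass
class PipelineResult:
    dataset: SyntheticDataset
    thresholds: Thresholds
    lincrnas: pd.DataFrame
    dependence: pd.DataFrame
    candidates: pd.DataFrame
    final_loci: pd.DataFrame          # with provenance column
    loci: pd.DataFrame                # per-locus site/phasing/degradome summary
    degradome_table: pd.DataFrame
    degradome_matched: int
    degradome_evaluated: int
    masirna_calls: pd.DataFrame
    masirna_origins: pd.Series
    origin_composition: pd.DataFrame
    srna_track_diff: pd.DataFrame

    @property
    def site_confirmed(self) -> pd.DataFrame:
        return self.loci[self.loci["has_site"]]


def run_pipeline(config: SimConfig | None = None,
                 thresholds: Thresholds | None = None,
                 rescue_list: pd.DataFrame | None = None,
                 out_dir=None) -> PipelineResult:
    cfg = config or SimConfig()
    thr = thresholds or Thresholds()
    ds = generate_dataset(cfg)
    gnm = ds.genome
    chrom_lengths = gnm.chrom_lengths

    # --- 24-nt sRNA read filtering -------------------------------------
    srna24 = {k: quant.filter_reads(v, thr.srna_len, thr) for k, v in ds.srna.items()}

    # --- transcribed regions from pooled WT mRNA coverage ---------------
    wt_mrna = pd.concat([v for k, v in ds.mrna.items() if k.genotype == "WT"],
                        ignore_index=True)
    transcribed = disc.transcribed_regions(wt_mrna, chrom_lengths, min_coverage=1)
    lincrnas = disc.extract_lincrnas(transcribed, gnm.genes, thr)

    # --- expression matrices and the three-condition call ---------------
    mrna_matrix = quant.build_expression_matrix(ds.mrna, lincrnas)
    dependence = stc.classify_eat1_dependent(mrna_matrix, thr)
    srna_matrix = quant.build_expression_matrix(srna24, lincrnas)
    candidates = disc.call_24phas(lincrnas, srna_matrix, thr)
    final = disc.assemble_phas_set(candidates, dependence["verdict"],
                                   rescue_list, chrom_lengths)

    # --- trigger sites, phase register, degradome ------------------------
    wt_late = pd.concat(
        [v for k, v in srna24.items()
         if k.genotype == "WT" and k.stage in ("ST.2", "ST.4")],
        ignore_index=True)
    deg_reads = ds.degradome[
        (ds.degradome["read_length"].isin(thr.degradome_lens))
        & (ds.degradome["mismatches"] <= thr.max_mismatches)
        & (ds.degradome["hits"] <= thr.max_hits)
    ].reset_index(drop=True)

    rows, profiles, predictions = [], [], {}
    for row in final.itertuples(index=False):
        interval = GenomicInterval(row.chrom, int(row.start), int(row.end))
        sites = ph.scan_locus(gnm.genome, interval, cfg.mir_seq,
                              thr.max_site_mismatch, thr.cleavage_offset_in_site,
                              locus_id=row.locus_id)
        rec = {
            "locus_id": row.locus_id, "chrom": row.chrom, "start": row.start,
            "end": row.end, "provenance": row.provenance,
            "has_site": bool(sites), "site_start": -1, "site_end": -1,
            "site_orientation": ".", "site_mismatch": np.nan, "origin": -1,
            "in_phase_reads": np.nan, "total_reads": np.nan,
            "in_phase_fraction": np.nan, "phasing_score": np.nan,
            "occupied_cycles": 0, "degradome_match": None,
        }
        if sites:
            site = ph.choose_origin_site(sites, interval)
            origin = site.cleavage_pos
            rec.update(site_start=site.site_start, site_end=site.site_end,
                       site_orientation=site.orientation,
                       site_mismatch=site.mismatch_count, origin=origin)
            locus = GenomicInterval(row.chrom, int(row.start), int(row.end),
                                    site.orientation)
            try:
                pres = ph.phasing_result(row.locus_id, wt_late, origin, locus,
                                         cycle=thr.srna_len,
                                         window_cycles=thr.window_cycles,
                                         antisense_offset=thr.antisense_offset)
                rec.update(in_phase_reads=pres.in_phase_reads,
                           total_reads=pres.total_reads,
                           in_phase_fraction=pres.in_phase_fraction,
                           phasing_score=pres.phasing_score,
                           occupied_cycles=pres.occupied_cycles)
            except ValueError:
                pass
            profile = deg.build_profile(deg_reads, locus, flank=200,
                                        strand="sense", locus_id=row.locus_id)
            profiles.append(profile)
            predictions[row.locus_id] = origin
            rec["degradome_match"] = deg.verify_cleavage(
                profile, origin, thr.degradome_tolerance, thr.degradome_min_reads)
        rows.append(rec)
    loci = pd.DataFrame(rows)
    deg_table, matched, evaluated = (
        deg.summarize_cleavage(profiles, predictions, thr)
        if profiles else (pd.DataFrame(), 0, 0))

    # --- masiRNAs --------------------------------------------------------
    rpm, alignments = mas.build_rpm_table(ds.rip)
    calls = mas.call_masirnas(rpm, thr)
    confirmed = loci[loci["has_site"]][["chrom", "start", "end"]]
    origins = mas.classify_origin(alignments, confirmed, gnm.genes, gnm.repeats)
    composition = mas.origin_composition(rpm.loc[calls.index], origins)

    # --- 24-nt landscape: WT minus eat1-4 at ST.2 ------------------------
    wt2 = pd.concat([v for k, v in srna24.items()
                     if k.genotype == "WT" and k.stage == "ST.2"], ignore_index=True)
    mut2 = pd.concat([v for k, v in srna24.items()
                      if k.genotype == "eat1-4" and k.stage == "ST.2"], ignore_index=True)
    diff = quant.wt_minus_mutant(
        quant.window_abundance(wt2, chrom_lengths, thr),
        quant.window_abundance(mut2, chrom_lengths, thr))

    result = PipelineResult(
        dataset=ds, thresholds=thr, lincrnas=lincrnas, dependence=dependence,
        candidates=candidates, final_loci=final, loci=loci,
        degradome_table=deg_table, degradome_matched=matched,
        degradome_evaluated=evaluated, masirna_calls=calls,
        masirna_origins=origins, origin_composition=composition,
        srna_track_diff=diff,
    )
    if out_dir is not None:
        save_results(result, out_dir)
    return result


def save_results(result: PipelineResult, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.dataset.genome.save(out / "genome")
    bed = result.final_loci.rename(columns={"locus_id": "name"}).copy()
    bed["score"] = 0
    bed["strand"] = "."
    write_bed(bed[["chrom", "start", "end", "name", "score", "strand"]],
              out / "phas_loci.bed")
    write_results_tsv(result.lincrnas, out / "lincrnas.tsv")
    write_results_tsv(result.dependence, out / "dependence_calls.tsv", index=True)
    write_results_tsv(result.loci, out / "phas_loci.tsv")
    write_results_tsv(result.degradome_table, out / "degradome_verification.tsv")
    write_results_tsv(result.masirna_calls, out / "masirna_calls.tsv", index=True)
    write_results_tsv(result.origin_composition, out / "masirna_origin_composition.tsv",
                      index=True)
    write_results_tsv(result.srna_track_diff, out / "srna24_wt_minus_eat1_st2.tsv")


# ---------------------------------------------------------------------------
# truth scoring
# ---------------------------------------------------------------------------

def _overlap_any(tree_map: dict[str, IntervalTree], chrom, start, end) -> bool:
    tree = tree_map.get(chrom)
    return tree is not None and bool(tree.overlap(start, end))


def score_recovery(result: PipelineResult) -> dict:
    """Recall/precision of the site-confirmed locus set against truth.

    A planted EAT1-dependent locus counts as recovered when a
    site-confirmed final locus overlaps it; any site-confirmed locus
    overlapping a planted decoy of whatever class counts as a leak.
    """
    truth = result.dataset.genome.truth
    confirmed = result.site_confirmed
    conf_trees: dict[str, IntervalTree] = {}
    for row in confirmed.itertuples(index=False):
        conf_trees.setdefault(row.chrom, IntervalTree()).addi(row.start, row.end)

    planted = truth[truth.locus_class == "eat1_dep"]
    recovered = sum(_overlap_any(conf_trees, r.chrom, r.start, r.end)
                    for r in planted.itertuples(index=False))
    decoy_trees: dict[str, IntervalTree] = {}
    for row in truth[truth.locus_class != "eat1_dep"].itertuples(index=False):
        decoy_trees.setdefault(row.chrom, IntervalTree()).addi(row.start, row.end)
    leaks = sum(_overlap_any(decoy_trees, r.chrom, r.start, r.end)
                for r in confirmed.itertuples(index=False))
    return {
        "n_planted": int(len(planted)),
        "n_recovered": int(recovered),
        "n_confirmed_loci": int(len(confirmed)),
        "n_final_loci": int(len(result.final_loci)),
        "n_decoy_leaks": int(leaks),
    }
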