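import numpy as np
import pandas as pd
import pytest

from conftest import small_sim_config
from phasworks.iolib import SampleKey
from phasworks.phasing import register_positions
from phasworks.synthetic_data import (
    SimConfig, build_rip_species, generate_degradome_library, generate_genome,
    generate_rip_library, generate_srna_library,
)


def _phas_read_mask(reads, truth):
    """Reads whose 5' end lies inside any planted PHAS-class locus."""
    from phasworks.iolib import five_prime_positions
    pos = five_prime_positions(reads)
    mask = np.zeros(len(reads), dtype=bool)
    for r in truth.itertuples(index=False):
        mask |= ((reads["chrom"].to_numpy() == r.chrom)
                 & (pos >= r.start) & (pos < r.end))
    return mask


class TestGenome:
    def test_same_seed_identical(self, small_cfg, small_genome):
        again = generate_genome(small_cfg)
        assert again.genome == small_genome.genome
        pd.testing.assert_frame_equal(again.truth, small_genome.truth)
        pd.testing.assert_frame_equal(again.genes, small_genome.genes)

    def test_planted_sites_exact_and_unique(self, small_cfg, small_genome):
        from phasworks.phasing import revcomp_dna
        mir = small_cfg.mir_dna
        for r in small_genome.truth.itertuples(index=False):
            if not r.has_site:
                continue
            embedded = small_genome.genome[r.chrom][r.site_start:r.site_end]
            expected = revcomp_dna(mir) if r.strand == "+" else mir
            assert embedded == expected

    def test_sites_in_five_prime_third(self, small_genome):
        for r in small_genome.truth.itertuples(index=False):
            if not r.has_site:
                continue
            length = r.end - r.start
            if r.strand == "+":
                assert r.site_end - r.start <= length // 3 + 22
            else:
                assert r.end - r.site_start <= length // 3 + 22

    def test_features_do_not_overlap(self, small_genome):
        feats = pd.concat([
            small_genome.genes[["chrom", "start", "end"]],
            small_genome.repeats[["chrom", "start", "end"]],
            small_genome.truth[["chrom", "start", "end"]],
        ]).sort_values(["chrom", "start"])
        for _, sub in feats.groupby("chrom"):
            assert (sub["start"].to_numpy()[1:] >= sub["end"].to_numpy()[:-1]).all()

    def test_save_is_deterministic(self, small_cfg, tmp_path):
        for d in ("a", "b"):
            generate_genome(small_cfg).save(tmp_path / d)
        for f in (tmp_path / "a").iterdir():
            assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes()


class TestSrnaLibrary:
    def test_same_seed_identical(self, small_genome):
        key = SampleKey("WT", "ST.2", 1, "sRNA")
        a = generate_srna_library(small_genome, key)
        b = generate_srna_library(small_genome, key)
        pd.testing.assert_frame_equal(a, b)

    def test_full_in_phase_fraction_puts_every_read_on_grid(self):
        cfg = small_sim_config(seed=6, in_phase_fraction=1.0,
                               srna_background_reads=0, srna_mismatch_fraction=0.0)
        gnm = generate_genome(cfg)
        reads = generate_srna_library(gnm, SampleKey("WT", "ST.2", 1, "sRNA"), cfg)
        phas = reads[_phas_read_mask(reads, gnm.truth)]
        reg = register_positions(phas)
        ok = np.zeros(len(phas), dtype=bool)
        for r in gnm.truth.itertuples(index=False):
            m = phas["chrom"].to_numpy() == r.chrom
            in_locus = m & (phas["start"].to_numpy() >= r.start) & (phas["end"].to_numpy() <= r.end)
            ok |= in_locus & ((reg - r.origin) % 24 == 0)
        assert ok.all()

    def test_default_fraction_is_binomial(self, small_genome):
        cfg = small_genome.config
        reads = generate_srna_library(small_genome, SampleKey("WT", "ST.2", 1, "sRNA"))
        truth = small_genome.truth
        n_in = n_tot = 0
        for r in truth.itertuples(index=False):
            sub = reads[(reads["chrom"] == r.chrom) & (reads["start"] >= r.start)
                        & (reads["end"] <= r.end) & (reads["read_length"] == 24)]
            reg = register_positions(sub)
            n_tot += len(sub)
            n_in += int(((reg - r.origin) % 24 == 0).sum())
        p = cfg.in_phase_fraction
        sd = np.sqrt(p * (1 - p) / n_tot)
        assert abs(n_in / n_tot - p) < 3 * sd

    def test_eat1_dependent_fold_change(self, small_genome):
        truth = small_genome.truth
        dep = truth[truth.locus_class == "eat1_dep"]
        counts = {}
        for genotype in ("WT", "eat1-4"):
            total = 0
            for rep in (1, 2, 3):
                reads = generate_srna_library(
                    small_genome, SampleKey(genotype, "ST.2", rep, "sRNA"))
                total += int(_phas_read_mask(reads, dep).sum())
            counts[genotype] = total / 3
        fold = counts["WT"] / counts["eat1-4"]
        assert 40 < fold < 75  # generator default effect size is 55x

    def test_zero_expression_zero_background_gives_empty_table(self):
        cfg = small_sim_config(seed=7, srna_background_reads=0)
        for assay_prof in cfg.expression_profile.values():
            for prof in assay_prof.values():
                for k in prof:
                    prof[k] = 0.0
        gnm = generate_genome(cfg)
        reads = generate_srna_library(gnm, SampleKey("WT", "ST.2", 1, "sRNA"), cfg)
        assert len(reads) == 0


class TestDegradome:
    def test_peak_fraction_one_puts_all_locus_reads_at_peak(self):
        cfg = small_sim_config(seed=8, degradome_peak_fraction=1.0,
                               degradome_background_reads=0)
        gnm = generate_genome(cfg)
        reads, truth = generate_degradome_library(gnm, cfg)
        from phasworks.iolib import five_prime_positions
        pos = five_prime_positions(reads)
        planted = dict(zip(truth["locus_id"], truth["planted_peak"]))
        for r in gnm.truth.itertuples(index=False):
            if not r.has_site:
                continue
            m = ((reads["chrom"] == r.chrom) & (pos >= r.start) & (pos < r.end)).to_numpy()
            if m.any():
                assert set(pos[m]) == {planted[r.locus_id]}

    def test_locus_reads_are_20_or_21_nt(self):
        cfg = small_sim_config(seed=8, degradome_background_reads=0)
        gnm = generate_genome(cfg)
        reads, _ = generate_degradome_library(gnm, cfg)
        assert set(reads["read_length"]) <= {20, 21}

    def test_peak_share_is_binomial(self, small_dataset):
        cfg = small_dataset.genome.config
        reads = small_dataset.degradome
        truth = small_dataset.degradome_truth
        from phasworks.iolib import five_prime_positions
        pos = five_prime_positions(reads)
        loci = small_dataset.genome.truth.set_index("locus_id")
        at_peak = total = 0
        for r in truth.itertuples(index=False):
            locus = loci.loc[r.locus_id]
            m = ((reads["chrom"] == locus.chrom) & (pos >= locus.start)
                 & (pos < locus.end)).to_numpy()
            total += int(m.sum())
            at_peak += int((pos[m] == r.planted_peak).sum())
        p = cfg.degradome_peak_fraction
        sd = np.sqrt(p * (1 - p) / total)
        # uniform remainder can also land on the peak position, hence >=
        assert at_peak / total > p - 3 * sd


class TestRip:
    def test_full_c_bias_means_all_phas_species_start_with_c(self):
        cfg = small_sim_config(seed=9, fivep_c_bias=1.0)
        gnm = generate_genome(cfg)
        species = build_rip_species(gnm, cfg)
        phas = species[species.origin_class == "PHAS"]
        assert all(s.startswith("C") for s in phas["sequence"])

    def test_st1_library_nearly_free_of_phas_reads(self, small_dataset):
        species = small_dataset.rip_species.set_index("species_id")
        lib = small_dataset.rip[SampleKey("WT", "ST.1", 1, "RIP")]
        cls = species.loc[lib["name"], "origin_class"].to_numpy()
        share = lib.loc[cls == "PHAS", "copies"].sum() / lib["copies"].sum()
        assert share < 0.001

    def test_mixture_recovered_within_3sd(self, small_dataset):
        cfg = small_dataset.genome.config
        species = small_dataset.rip_species.set_index("species_id")
        lib = small_dataset.rip[SampleKey("WT", "ST.2", 1, "RIP")]
        cls = species.loc[lib["name"], "origin_class"].to_numpy()
        n = lib["copies"].sum()
        mix = cfg.rip_mixture["WT"]["ST.2"]
        total_share = sum(mix.values())
        for cat, frac in mix.items():
            p = frac / total_share
            obs = lib.loc[cls == cat, "copies"].sum() / n
            assert abs(obs - p) < 3 * np.sqrt(p * (1 - p) / n) + 1e-9

    def test_mel1_libraries_depleted(self, small_dataset):
        cfg = small_dataset.genome.config
        wt = small_dataset.rip[SampleKey("WT", "ST.2", 1, "RIP")]
        mel = small_dataset.rip[SampleKey("mel1-1", "ST.2", 1, "RIP")]
        species = small_dataset.rip_species
        pooled = species[species.origin_class != "background"]["species_id"]
        wt_share = wt[wt["name"].isin(pooled)]["copies"].sum() / wt["copies"].sum()
        mel_share = mel[mel["name"].isin(pooled)]["copies"].sum() / mel["copies"].sum()
        assert wt_share / mel_share > 4  # comfortably beyond the calling threshold


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        dict(in_phase_fraction=1.5),
        dict(fivep_c_bias=-0.1),
        dict(replicate_cv=0.6),
        dict(phas_len=(20, 30)),
    ])
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimConfig(**kwargs)
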