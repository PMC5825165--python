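import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from phasworks.iolib import GenomicInterval
from phasworks.phasing import (
    assign_register, choose_origin_site, in_phase_fraction, phasing_score,
    predict_cleavage, register_positions, revcomp_dna, rna_to_dna, scan_mir_site,
)

MIR = "UUAGGUCGACUUGCAUACCUAG"  # arbitrary 22-nt trigger for these tests


def _rand_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def _reads(rows):
    df = pd.DataFrame(rows, columns=["chrom", "start", "strand", "copies"])
    df["end"] = df["start"] + 24
    df["name"] = "."
    df["read_length"] = 24
    df["mismatches"] = 0
    df["hits"] = 1
    return df


def brute_weighted_mismatch(window: str, mir_dna: str, orientation: str) -> float:
    """Position-by-position duplex scoring, written independently."""
    m = len(mir_dna)
    target = window if orientation == "+" else revcomp_dna(window)
    total = 0.0
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    for j in range(m):
        mirb = mir_dna[m - 1 - j]
        t = target[j]
        if t == comp.get(mirb):
            continue
        if (mirb == "G" and t == "T") or (mirb == "T" and t == "G"):
            total += 0.5
        else:
            total += 1.0
    return total


class TestScan:
    def test_planted_exact_site_found_both_orientations(self):
        rng = np.random.default_rng(13)
        mir_dna = rna_to_dna(MIR)
        for orientation, patt in (("+", revcomp_dna(mir_dna)), ("-", mir_dna)):
            seq = list(_rand_seq(rng, 300))
            seq[100:122] = patt
            sites = [s for s in scan_mir_site("".join(seq), MIR, max_mismatch=0.0)
                     if s.orientation == orientation]
            assert any(s.site_start == 100 and s.mismatch_count == 0.0 for s in sites)

    def test_matches_brute_force_sliding_comparison(self):
        rng = np.random.default_rng(14)
        mir_dna = rna_to_dna(MIR)
        seq = _rand_seq(rng, 500)
        sites = scan_mir_site(seq, MIR, max_mismatch=4.0)
        found = {(s.site_start, s.orientation): s.mismatch_count for s in sites}
        for i in range(len(seq) - 21):
            for orientation in ("+", "-"):
                mm = brute_weighted_mismatch(seq[i:i + 22], mir_dna, orientation)
                if mm <= 4.0:
                    assert found.get((i, orientation)) == pytest.approx(mm)
                else:
                    assert (i, orientation) not in found

    def test_short_inputs_rejected(self):
        with pytest.raises(ValueError):
            scan_mir_site("ACGT", MIR)
        with pytest.raises(ValueError):
            scan_mir_site("ACGT" * 20, "ACGU")


class TestPredictCleavage:
    def test_plus_site_13th_base(self):
        assert predict_cleavage(100, 122, "+") == 112
        assert predict_cleavage(0, 22, "+") == 12

    def test_minus_site_13th_base_from_its_own_five_prime(self):
        assert predict_cleavage(100, 122, "-") == 109  # 122 - 13

    def test_random_placements_match_enumeration(self):
        rng = np.random.default_rng(15)
        for _ in range(50):
            s = int(rng.integers(0, 10_000))
            # enumerate the site's bases in 5'->3' orientation and take the 13th
            plus_positions = list(range(s, s + 22))
            minus_positions = list(range(s + 21, s - 1, -1))
            assert predict_cleavage(s, s + 22, "+") == plus_positions[12]
            assert predict_cleavage(s, s + 22, "-") == minus_positions[12]


class TestChooseOriginSite:
    def test_five_prime_most_wins_then_mismatch(self):
        from phasworks.phasing import MirSite
        locus = GenomicInterval("chr1", 0, 1000)
        near5 = MirSite(50, 72, "+", 2.0, 62)
        far = MirSite(300, 322, "+", 0.0, 312)
        assert choose_origin_site([far, near5], locus) == near5
        tie = MirSite(50, 72, "-", 0.0, 59)  # minus: 5' distance = 1000-72
        assert choose_origin_site([near5, tie], locus) == near5


class TestRegister:
    def test_definition_and_boundaries(self):
        locus = GenomicInterval("chr1", 0, 2000)
        origin = 100
        df = _reads([("chr1", origin + 48, "+", 1), ("chr1", origin + 47, "+", 1),
                     ("chr1", origin + 48 + 2 - 24, "-", 1)])
        out = assign_register(df, origin, locus)
        assert out["in_phase"].tolist() == [True, False, True]

    def test_shift_by_24_preserves_flags(self):
        rng = np.random.default_rng(16)
        locus = GenomicInterval("chr1", 0, 5000)
        starts = rng.integers(100, 4000, size=200)
        df = _reads([("chr1", int(s), str(x), 1) for s, x in
                     zip(starts, rng.choice(["+", "-"], 200))])
        a = assign_register(df, 500, locus)["in_phase"]
        shifted = df.copy()
        shifted["start"] += 24
        shifted["end"] += 24
        b = assign_register(shifted, 500, locus)["in_phase"]
        assert a.tolist() == b.tolist()

    def test_translation_invariance(self):
        rng = np.random.default_rng(17)
        starts = rng.integers(100, 4000, size=200)
        df = _reads([("chr1", int(s), str(x), 1) for s, x in
                     zip(starts, rng.choice(["+", "-"], 200))])
        a = assign_register(df, 500, GenomicInterval("chr1", 0, 5000))["in_phase"]
        moved = df.copy()
        moved["start"] += 1_000_000
        moved["end"] += 1_000_000
        b = assign_register(moved, 1_000_500,
                            GenomicInterval("chr1", 1_000_000, 1_005_000))["in_phase"]
        assert a.tolist() == b.tolist()

    def test_matches_brute_force_modular_arithmetic(self):
        rng = np.random.default_rng(18)
        locus = GenomicInterval("chr1", 0, 60_000)
        origin = 1234
        starts = rng.integers(0, 59_000, size=2000)
        strands = rng.choice(["+", "-"], size=2000)
        df = _reads([("chr1", int(s), str(x), 1) for s, x in zip(starts, strands)])
        out = assign_register(df, origin, locus)
        for row in out.itertuples(index=False):
            if row.strand == "+":
                expected = (row.start - origin) % 24 == 0
            else:
                expected = (row.end - origin - 2) % 24 == 0
            assert row.in_phase == expected

    def test_origin_outside_locus_errors(self):
        with pytest.raises(ValueError, match="outside"):
            assign_register(_reads([("chr1", 10, "+", 1)]), 5000,
                            GenomicInterval("chr1", 0, 1000))


class TestFractionAndScore:
    def test_all_on_grid_gives_one(self):
        origin = 96
        df = _reads([("chr1", origin + 24 * k, "+", 2) for k in range(10)])
        out = assign_register(df, origin, GenomicInterval("chr1", 0, 1000))
        assert in_phase_fraction(out["in_phase"], out["copies"]) == 1.0

    def test_uniform_reads_give_one_in_24(self):
        rng = np.random.default_rng(19)
        n = 5000
        starts = rng.integers(0, 59_000, size=n)
        df = _reads([("chr1", int(s), str(x), 1) for s, x in
                     zip(starts, rng.choice(["+", "-"], n))])
        out = assign_register(df, 777, GenomicInterval("chr1", 0, 60_000))
        frac = in_phase_fraction(out["in_phase"], out["copies"])
        p = 1 / 24
        assert abs(frac - p) < 3 * np.sqrt(p * (1 - p) / n)

    def test_zero_reads_error(self):
        with pytest.raises(ValueError):
            in_phase_fraction([])

    @settings(derandomize=True, max_examples=30)
    @given(st.integers(min_value=1, max_value=1000))
    def test_fraction_invariant_under_copy_scaling(self, c):
        flags = [True, False, True, True]
        w = np.array([1.0, 2.0, 3.0, 4.0])
        assert in_phase_fraction(flags, w) == pytest.approx(
            in_phase_fraction(flags, w * c))

    def test_score_zero_below_three_occupied_cycles(self):
        origin = 96
        locus = GenomicInterval("chr1", 0, 1000)
        two = _reads([("chr1", origin, "+", 50), ("chr1", origin + 24, "+", 50)])
        assert phasing_score(two, origin, locus) == 0.0
        three = _reads([("chr1", origin + 24 * k, "+", 50) for k in range(3)])
        assert phasing_score(three, origin, locus) > 0.0

    def test_score_monotone_in_phased_copies(self):
        origin = 96
        locus = GenomicInterval("chr1", 0, 1000)
        prev = -1.0
        for c in (1, 5, 25):
            df = _reads([("chr1", origin + 24 * k, "+", c) for k in range(5)]
                        + [("chr1", origin + 7, "+", 10)])
            score = phasing_score(df, origin, locus)
            assert score > prev
            prev = score

    def test_perfect_stack_beats_noisy_stack(self):
        origin = 96
        locus = GenomicInterval("chr1", 0, 1000)
        clean = _reads([("chr1", origin + 24 * k, "+", 10) for k in range(6)])
        noisy = pd.concat([clean,
                           _reads([("chr1", origin + 24 * k + 11, "+", 10)
                                   for k in range(6)])], ignore_index=True)
        assert phasing_score(clean, origin, locus) > phasing_score(noisy, origin, locus)
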