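from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest

from corsivscreen.context import (
    count_variant_concordance,
    flank_strata,
    genic_annotation,
    match_controls,
    repeat_flank_profile,
    tss_enrichment_test,
    variant_concordance_test,
    yates_2x2,
)
from corsivscreen.types import GeneModel, GenomicInterval, RepeatFeature, VariantRecord


def region(chrom, start, end, n_cpg):
    return SimpleNamespace(chrom=chrom, start=start, end=end, n_cpg=n_cpg)


def pool_table(rows):
    """rows: (chrom, start, n_cpg, enters_screen)"""
    return pd.DataFrame(
        [{"chrom": c, "start": s, "end": s + 100, "n_cpg": n,
          "enters_screen": ok} for c, s, n, ok in rows]
    )


class TestMatchControls:
    def test_exact_match_found(self):
        corsiv = region("chr1", 0, 300, 6)
        table = pool_table(
            [("chr1", 0, 2, True), ("chr1", 100, 2, True),
             ("chr1", 200, 2, True),
             ("chr1", 1000, 2, True), ("chr1", 1100, 2, True),
             ("chr1", 1200, 2, True)]
        )
        controls, unmatched = match_controls(
            [corsiv], table, {"chr1": 5000}, seed=1
        )
        assert unmatched == []
        (c,) = controls
        assert c.interval == GenomicInterval("chr1", 1000, 1300)
        assert c.n_cpg == 6 and c.relaxation_count == 0

    def test_forced_size_relaxation(self):
        corsiv = region("chr1", 0, 300, 6)
        # no 300 bp window reaches 6 CpGs; [1000,1400) does
        table = pool_table(
            [("chr1", 0, 2, True), ("chr1", 100, 2, True),
             ("chr1", 200, 2, True),
             ("chr1", 1000, 2, True), ("chr1", 1100, 1, True),
             ("chr1", 1200, 1, True), ("chr1", 1300, 2, True)]
        )
        controls, unmatched = match_controls(
            [corsiv], table, {"chr1": 5000}, seed=3
        )
        assert unmatched == []
        (c,) = controls
        assert c.relaxation_count == 1
        assert c.interval.size == 400
        assert c.n_cpg == 6

    def test_unmatched_reported_not_fabricated(self):
        corsiv = region("chr1", 0, 300, 6)
        table = pool_table([("chr1", 0, 2, True), ("chr1", 100, 2, True),
                            ("chr1", 200, 2, True),
                            ("chr1", 1000, 1, True)])
        controls, unmatched = match_controls(
            [corsiv], table, {"chr1": 1500}, seed=1, max_attempts=50
        )
        assert controls == []
        assert unmatched == ["chr1:0-300"]

    def test_deterministic_and_order_invariant(self):
        corsivs = [region("chr1", i * 10_000, i * 10_000 + 300, 6)
                   for i in range(6)]
        rows = []
        for i in range(6):
            for j in range(3):
                rows.append(("chr1", i * 10_000 + j * 100, 2, True))
            for j in range(30):  # roomy pool between CoRSIVs
                rows.append(("chr1", i * 10_000 + 3_000 + j * 100, 2, True))
        table = pool_table(rows)
        sizes = {"chr1": 80_000}
        a, _ = match_controls(corsivs, table, sizes, seed=5)
        b, _ = match_controls(corsivs, table, sizes, seed=5)
        assert a == b
        shuffled, _ = match_controls(list(reversed(corsivs)), table, sizes,
                                     seed=5)
        assert {c.matched_corsiv_id: c.interval for c in shuffled} == \
               {c.matched_corsiv_id: c.interval for c in a}

    def test_invariants_on_synthetic_screen(self, small_cohort, screen_params):
        from corsivscreen import (build_blocks, classify_corsivs, make_bins,
                                  screen_bins)

        g = small_cohort["genome"]
        table = screen_bins(make_bins(g, screen_params),
                            small_cohort["libraries"], "s1", "s2",
                            small_cohort["tissues"], screen_params)
        blocks, _ = build_blocks(table, "s1", "s2", small_cohort["tissues"],
                                 screen_params)
        _, corsivs = classify_corsivs(blocks, screen_params)
        assert corsivs
        for seed in (0, 1, 2):
            controls, _ = match_controls(corsivs, table, g.chrom_sizes,
                                         seed=seed)
            by_id = {b.id: b for b in corsivs}
            ivs = [c.interval for c in controls]
            for c in controls:
                src = by_id[c.matched_corsiv_id]
                assert c.interval.chrom == src.chrom
                assert c.n_cpg == src.n_cpg
                assert c.interval.size == src.size + 100 * c.relaxation_count
                assert not any(
                    c.interval.overlaps(b.interval) for b in corsivs
                )
            for i, iv in enumerate(ivs):
                assert not any(iv.overlaps(o) for o in ivs[i + 1:])


class TestGenicAnnotation:
    genes = [GeneModel("chr1", "+", 10_000, 20_000, "gA"),
             GeneModel("chr1", "-", 40_000, 50_000, "gB")]

    def annotate(self, iv):
        return genic_annotation([iv], self.genes).iloc[0]

    def test_tss_within_window(self):
        row = self.annotate(GenomicInterval("chr1", 8_000, 8_200))
        assert row["tss"] and not row["gene_body"] and not row["intergenic"]

    def test_minus_strand_tss_is_tx_end(self):
        row = self.annotate(GenomicInterval("chr1", 51_000, 51_100))
        assert row["tss"] and not row["tes"]

    def test_gene_body_only_deep_inside(self):
        row = self.annotate(GenomicInterval("chr1", 14_000, 14_200))
        assert row["gene_body"] and not row["tss"] and not row["tes"]

    def test_intergenic(self):
        row = self.annotate(GenomicInterval("chr1", 30_000, 30_200))
        assert row["intergenic"] and not (row["tss"] or row["tes"]
                                          or row["gene_body"])

    def test_boundary_inclusive_at_2500(self):
        row = self.annotate(GenomicInterval("chr1", 7_400, 7_500))
        # distance from last base (7499) to TSS 10000 is exactly 2501 -> out
        assert not row["tss"]
        row = self.annotate(GenomicInterval("chr1", 7_400, 7_501))
        assert row["tss"]

    def test_flags_stable_under_gene_permutation(self):
        ivs = [GenomicInterval("chr1", s, s + 200)
               for s in range(0, 60_000, 3_000)]
        a = genic_annotation(ivs, self.genes)
        b = genic_annotation(ivs, list(reversed(self.genes)))
        pd.testing.assert_frame_equal(a, b)


class TestTssEnrichment:
    def test_identical_distributions(self):
        flags = [True] * 10 + [False] * 40
        odds, chi2, p = tss_enrichment_test(flags, flags)
        assert odds == pytest.approx(1.0)
        assert p > 0.9

    def test_matches_hand_computed_yates(self):
        # table [[60,157],[30,187]]
        corsiv = [True] * 60 + [False] * 157
        control = [True] * 30 + [False] * 187
        _, chi2, p = tss_enrichment_test(corsiv, control)
        a, b, c, d = 60, 157, 30, 187
        n = a + b + c + d
        expect = (n * (abs(a * d - b * c) - n / 2) ** 2
                  / ((a + b) * (c + d) * (a + c) * (b + d)))
        assert chi2 == pytest.approx(expect)
        assert p < 0.01

    def test_zero_margin_undefined(self):
        odds, chi2, p = tss_enrichment_test([False] * 5, [False] * 5)
        assert p is None

    def test_power_on_planted_bias(self):
        rng = np.random.default_rng(11)
        corsiv = rng.random(200) < 0.3   # 2x the control rate
        control = rng.random(200) < 0.15
        _, _, p = tss_enrichment_test(corsiv.tolist(), control.tolist())
        assert p < 0.05


class TestVariantConcordance:
    subjects = ("s1", "s2")

    @staticmethod
    def var(pos, g1, g2, chrom="chr1"):
        return VariantRecord(chrom, pos, "C", "T", 50.0,
                             {"s1": g1, "s2": g2})

    def test_window_edges(self):
        iv = GenomicInterval("chr1", 1_000, 1_200)  # mid 1100, window [600,1600)
        inside = self.var(600, "hom_ref", "hom_alt")
        outside = self.var(1_600, "hom_ref", "hom_alt")
        conc, disc = count_variant_concordance([iv], [inside, outside],
                                               self.subjects)
        assert (conc, disc) == (0, 1)

    def test_missing_genotypes_ignored(self):
        iv = GenomicInterval("chr1", 1_000, 1_200)
        v = self.var(1_100, "missing", "missing")
        assert count_variant_concordance([iv], [v], self.subjects) == (0, 0)

    def test_shared_hom_ref_not_concordant(self):
        iv = GenomicInterval("chr1", 1_000, 1_200)
        v = self.var(1_100, "hom_ref", "hom_ref")
        assert count_variant_concordance([iv], [v], self.subjects) == (0, 0)

    def test_shared_het_is_concordant(self):
        iv = GenomicInterval("chr1", 1_000, 1_200)
        v = self.var(1_100, "het", "het")
        assert count_variant_concordance([iv], [v], self.subjects) == (1, 0)

    def test_concordance_ratio_difference_detected(self):
        """CoRSIV-style windows at 1.38x concordant:discordant vs 2x in
        controls, ~217 regions per set."""
        rng = np.random.default_rng(2)
        corsiv_ivs, control_ivs, variants = [], [], []
        pos = 10_000
        for i in range(217):
            iv = GenomicInterval("chr1", pos, pos + 200)
            corsiv_ivs.append(iv)
            mid = pos + 100
            for _ in range(rng.poisson(1.38)):
                variants.append(self.var(int(mid + rng.integers(-400, 400)),
                                         "het", "het"))
            for _ in range(rng.poisson(1.0)):
                variants.append(self.var(int(mid + rng.integers(-400, 400)),
                                         "hom_ref", "hom_alt"))
            pos += 2_000
        for i in range(217):
            iv = GenomicInterval("chr1", pos, pos + 200)
            control_ivs.append(iv)
            mid = pos + 100
            for _ in range(rng.poisson(2.0)):
                variants.append(self.var(int(mid + rng.integers(-400, 400)),
                                         "het", "het"))
            for _ in range(rng.poisson(1.0)):
                variants.append(self.var(int(mid + rng.integers(-400, 400)),
                                         "hom_ref", "hom_alt"))
            pos += 2_000
        cc = count_variant_concordance(corsiv_ivs, variants, self.subjects)
        kk = count_variant_concordance(control_ivs, variants, self.subjects)
        chi2, p = variant_concordance_test(cc, kk)
        assert cc[1] / cc[0] > kk[1] / kk[0]  # relatively more discordant
        assert p < 0.05


class TestRepeatFlanks:
    def test_repeat_in_first_left_stratum(self):
        iv = GenomicInterval("chr1", 100_000, 100_200)
        rep = RepeatFeature(GenomicInterval("chr1", 97_000, 99_500), "LINE", "L1")
        prof = repeat_flank_profile([iv], [rep])
        assert prof.loc["LINE", "0-5kb"] == 1
        assert prof.loc["LINE", "overlap"] == 0

    def test_direct_overlap_stratum_only(self):
        iv = GenomicInterval("chr1", 100_000, 100_200)
        rep = RepeatFeature(GenomicInterval("chr1", 99_900, 100_100), "LTR", "ERV1")
        prof = repeat_flank_profile([iv], [rep])
        assert prof.loc["LTR", "overlap"] == 1
        assert prof.loc["LTR"].drop("overlap").sum() == 0

    def test_symmetric_strata_pooled(self):
        iv = GenomicInterval("chr1", 100_000, 100_200)
        left = RepeatFeature(GenomicInterval("chr1", 92_000, 93_000), "SINE", "x")
        right = RepeatFeature(GenomicInterval("chr1", 107_500, 108_000), "SINE", "x")
        prof = repeat_flank_profile([iv], [left, right])
        assert prof.loc["SINE", "5-10kb"] == 1  # one region, pooled sides

    def test_against_brute_force_on_random_tracks(self):
        rng = np.random.default_rng(8)
        flank, step = 20_000, 5_000
        for _ in range(20):
            regions = [
                GenomicInterval("chr1", int(s), int(s) + int(rng.integers(100, 800)))
                for s in rng.integers(30_000, 400_000, size=8)
            ]
            repeats = [
                RepeatFeature(
                    GenomicInterval("chr1", int(s), int(s) + int(rng.integers(50, 3_000))),
                    str(rng.choice(["LINE", "SINE", "LTR"])), "f")
                for s in rng.integers(0, 450_000, size=60)
            ]
            got = repeat_flank_profile(regions, repeats, flank, step)
            labels = flank_strata(flank, step)
            for cls in got.index:
                for k, label in enumerate(labels):
                    count = 0
                    for iv in regions:
                        hit = False
                        for r in repeats:
                            if r.repeat_class != cls:
                                continue
                            overlaps_region = r.interval.overlaps(iv)
                            if label == "overlap":
                                hit = hit or overlaps_region
                            elif not overlaps_region:
                                lo = (k - 1) * step
                                hi = k * step
                                windows = []
                                if iv.start - hi >= 0:
                                    windows.append((iv.start - hi, iv.start - lo))
                                windows.append((iv.end + lo, iv.end + hi))
                                for ws, we in windows:
                                    if r.interval.start < we and ws < r.interval.end:
                                        hit = True
                        count += hit
                    assert got.loc[cls, label] == count


def test_yates_helper_zero_margin():
    chi2, p = yates_2x2([[0, 0], [5, 5]])
    assert p is None and chi2 == 0.0
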