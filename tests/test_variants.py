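"""SNP selection, LD computation/expansion, variant regions and windows."""

import numpy as np
import pytest

from oracle_utils import bruteforce_r2
from starrcre.motifs import Pwm
from starrcre.variants import (
    HaplotypeMatrix,
    Snp,
    compute_r2,
    define_variant_regions,
    expand_by_ld,
    read_association_table,
    select_trait_snps,
    variant_window,
    scan_variant_windows,
)


def snp(sid, pos, p, contig="chr12", trait="PR"):
    return Snp(id=sid, contig=contig, pos=pos, ref_allele="A", alt_allele="G",
               p_value=p, trait=trait)


class TestSelectTraitSnps:
    def test_lead_pulls_in_subthreshold_neighbor(self):
        assoc = [snp("lead", 1_000_000, 1e-9), snp("near", 1_050_000, 0.01),
                 snp("weak", 1_050_001, 0.2)]
        ids = {s.id for s in select_trait_snps(assoc, locus_gap=100_000)}
        assert ids == {"lead", "near"}

    def test_no_lead_means_empty_selection(self):
        assert select_trait_snps([snp("a", 10, 0.01)]) == []

    def test_neighbor_outside_gap_excluded(self):
        assoc = [snp("lead", 1_000_000, 1e-9), snp("far", 1_200_001, 0.01)]
        ids = {s.id for s in select_trait_snps(assoc, locus_gap=100_000)}
        assert ids == {"lead"}

    def test_two_clusters_match_bruteforce(self, rng):
        gap = 50_000
        leads = [snp(f"L{i}", int(p), 1e-10) for i, p in enumerate([100_000, 900_000])]
        others = [
            snp(f"s{i}", int(rng.integers(0, 1_200_000)), float(rng.uniform(0.001, 0.3)))
            for i in range(200)
        ]
        assoc = leads + others
        got = {s.id for s in select_trait_snps(assoc, locus_gap=gap)}
        # brute force: distance to the nearest lead-cluster span <= gap
        expected = set()
        for s in assoc:
            if s.p_value >= 0.05:
                continue
            if any(l.pos - gap <= s.pos <= l.pos + gap for l in leads):
                expected.add(s.id)
        assert got == expected

    def test_monotone_in_sub_threshold(self):
        assoc = [snp("lead", 0, 1e-9)] + [
            snp(f"s{i}", 1_000 + i, 0.001 * (i + 1)) for i in range(40)
        ]
        a = {s.id for s in select_trait_snps(assoc, sub_threshold=0.01)}
        b = {s.id for s in select_trait_snps(assoc, sub_threshold=0.04)}
        assert a <= b


class TestComputeR2:
    def make_h(self, cols):
        return HaplotypeMatrix(np.column_stack(cols), [f"s{i}" for i in range(len(cols))])

    def test_perfect_coinheritance(self):
        col = np.array([0, 1] * 5)
        assert compute_r2(self.make_h([col, col]), "s0", "s1") == pytest.approx(1.0)

    def test_hand_counted_example(self):
        # AB=4, Ab=1, aB=1, ab=4 over 10 haplotypes: D=0.15, r2=0.36
        a = np.array([1] * 5 + [0] * 5)
        b = np.array([1] * 4 + [0, 1] + [0] * 4)
        assert compute_r2(self.make_h([a, b]), "s0", "s1") == pytest.approx(0.36)

    def test_symmetry_and_label_swap_invariance(self, rng):
        a = (rng.random(200) < 0.4).astype(np.int8)
        b = (rng.random(200) < 0.6).astype(np.int8)
        h = self.make_h([a, b])
        h_swapped = self.make_h([1 - a, 1 - b])
        r = compute_r2(h, "s0", "s1")
        assert r == pytest.approx(compute_r2(h, "s1", "s0"))
        assert r == pytest.approx(compute_r2(h_swapped, "s0", "s1"))

    def test_independent_sites_near_zero(self, rng):
        a = (rng.random(20_000) < 0.5).astype(np.int8)
        b = (rng.random(20_000) < 0.5).astype(np.int8)
        assert compute_r2(self.make_h([a, b]), "s0", "s1") < 0.01

    def test_monomorphic_site_warns_and_returns_none(self):
        h = self.make_h([np.zeros(10, np.int8), np.array([0, 1] * 5, np.int8)])
        with pytest.warns(UserWarning, match="monomorphic"):
            assert compute_r2(h, "s0", "s1") is None


class TestExpandByLd:
    def setup_method(self):
        rng = np.random.default_rng(7)
        self.lead_col = (rng.random(400) < 0.5).astype(np.int8)
        perfect = self.lead_col.copy()
        weak_a = np.concatenate([[1] * 5 + [0] * 5] * 40).astype(np.int8)
        indep = (rng.random(400) < 0.5).astype(np.int8)
        self.h = HaplotypeMatrix(
            np.column_stack([self.lead_col, perfect, indep]),
            ["lead", "perfect", "indep"],
        )
        self.snps = [
            snp("lead", 100, 1e-9),
            snp("perfect", 200, 0.3),
            snp("indep", 300, 0.3),
        ]

    def test_perfect_satellite_added(self):
        out = expand_by_ld([self.snps[0]], [self.snps[0]], self.h, all_snps=self.snps)
        ids = {s.id for s in out}
        assert "perfect" in ids and "indep" not in ids
        r2s = {s.id: s.r2_to_lead for s in out}
        assert r2s["perfect"] == pytest.approx(1.0)

    def test_threshold_zero_adds_all_polymorphic(self):
        out = expand_by_ld(
            [self.snps[0]], [self.snps[0]], self.h, all_snps=self.snps, r2_threshold=0.0
        )
        assert {s.id for s in out} == {"lead", "perfect", "indep"}

    def test_missing_lead_named_in_error(self):
        ghost = snp("rs_ghost", 1, 1e-9)
        with pytest.raises(KeyError, match="rs_ghost"):
            expand_by_ld([], [ghost], self.h)

    def test_matches_bruteforce_all_pairs(self, rng):
        n_sites = 30
        cols = [(rng.random(300) < rng.uniform(0.1, 0.9)).astype(np.int8)
                for _ in range(n_sites)]
        ids = [f"s{i}" for i in range(n_sites)]
        h = HaplotypeMatrix(np.column_stack(cols), ids)
        catalogue = [snp(ids[i], i * 10, 0.5) for i in range(n_sites)]
        lead = catalogue[0]
        out = expand_by_ld([lead], [lead], h, all_snps=catalogue, r2_threshold=0.3)
        expected = {"s0"}
        for i in range(1, n_sites):
            r2 = bruteforce_r2(cols[0], cols[i])
            if r2 is not None and r2 > 0.3:
                expected.add(ids[i])
        assert {s.id for s in out} == expected


class TestDefineVariantRegions:
    def test_two_clusters_136kb_apart_stay_distinct(self):
        cluster1 = [snp(f"a{i}", 200_000 + i * 10_000, 0.01, trait="PR") for i in range(4)]
        cluster2 = [snp(f"b{i}", 366_000 + i * 10_000, 0.01, trait="QRS") for i in range(4)]
        vrs = define_variant_regions(cluster1 + cluster2, max_gap=100_000)
        assert [vr.label for vr in vrs] == ["VR1", "VR2"]
        assert vrs[0].traits == {"PR"} and vrs[1].traits == {"QRS"}
        assert vrs[1].interval.start - vrs[0].interval.end == pytest.approx(136_000, abs=1_000)

    def test_single_snp_is_one_bp_region(self):
        (vr,) = define_variant_regions([snp("x", 500, 0.01)], max_gap=10)
        assert (vr.interval.start, vr.interval.end) == (500, 501)

    def test_huge_gap_gives_single_region(self, rng):
        snps = [snp(f"s{i}", int(p), 0.01) for i, p in
                enumerate(rng.integers(0, 10**6, size=50))]
        vrs = define_variant_regions(snps, max_gap=10**7)
        assert len(vrs) == 1 and len(vrs[0].snps) == 50


class TestVariantWindow:
    SEQ = "ACGTACGTACGTACGTACGTACGTACGTAC"

    def test_default_flank_gives_21_bp(self):
        ref, alt = variant_window(self.SEQ, 15, "T", "C")
        assert len(ref) == len(alt) == 21
        assert ref[10] == "T" and alt[10] == "C"
        assert ref[:10] == alt[:10] and ref[11:] == alt[11:]

    def test_flank_zero_is_single_base(self):
        assert variant_window(self.SEQ, 3, "T", "A", flank=0) == ("T", "A")

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError, match="bounds"):
            variant_window(self.SEQ, 5, "C", "T", flank=10)

    def test_reference_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            variant_window(self.SEQ, 15, "G", "C")


class TestScanVariantWindows:
    def test_planted_motif_lost_when_destroyed(self):
        counts = np.zeros((4, 6))
        for j, b in enumerate("TTAATT"):
            counts["ACGT".index(b), j] = 20
        pwm = Pwm.from_counts("boxA", counts)
        ref = "ACGCG" + "TTAATT" + "CGCGCGCGCG"  # 21 bp
        alt = ref[:7] + "G" + ref[8:]            # kills the core
        changes = scan_variant_windows([("v1", ref, alt)], [pwm], 0.9)
        assert changes[0].lost == ["boxA"] and changes[0].gained == []
        same = scan_variant_windows([("v2", ref, ref)], [pwm], 0.9)
        assert same[0].lost == [] and same[0].gained == []

    def test_all_n_window_matches_nothing(self):
        counts = np.zeros((4, 4))
        counts[0] = 20  # AAAA
        pwm = Pwm.from_counts("polyA", counts)
        changes = scan_variant_windows([("v", "N" * 21, "N" * 21)], [pwm], 0.8)
        assert changes[0].lost == [] and changes[0].gained == []


def test_association_table_positions_become_zero_based(tmp_path):
    p = tmp_path / "assoc.tsv"
    p.write_text("id\tchrom\tpos\tref\talt\tp\ttrait\nrs1\tchr12\t100\tA\tG\t0.01\tPR\n")
    (s,) = read_association_table(p)
    assert s.pos == 99 and s.trait == "PR"
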