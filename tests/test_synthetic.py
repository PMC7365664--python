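"""Generators: determinism, stated distributions, and truth consistency."""

import numpy as np
import pytest

from starrcre import activity, variants
from starrcre.intervals import GenomicInterval, RegionSet
from starrcre.liftover import map_interval
from starrcre.motifs import Pwm
from starrcre.synthetic import (
    PlantedElement,
    VrSpec,
    simulate_association_study,
    simulate_bac_library,
    simulate_candidate_study,
    simulate_chain,
    simulate_feature_tracks,
    simulate_locus,
    simulate_motif_sets,
    simulate_starr_counts,
)


class TestLocus:
    def test_seed_determinism(self):
        assert simulate_locus(500, seed=42) == simulate_locus(500, seed=42)
        assert simulate_locus(500, seed=42) != simulate_locus(500, seed=43)

    def test_gc_content_within_binomial_bound(self):
        seq = simulate_locus(1_000_000, gc=0.5, seed=1)
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert abs(gc - 0.5) < 0.01

    def test_gc_one_is_all_strong_bases(self):
        assert set(simulate_locus(200, gc=1.0, seed=0)) <= {"G", "C"}

    def test_invalid_gc_rejected(self):
        with pytest.raises(ValueError):
            simulate_locus(100, gc=0.0)


class TestBacLibrary:
    def test_fragment_lengths_in_selection_window(self):
        frags, _ = simulate_bac_library(locus_length=200_000, n_bacs=3,
                                        n_fragments=5_000, seed=2)
        lengths = np.array([iv.length for iv in frags])
        assert lengths.min() >= 500 and lengths.max() <= 1_000

    def test_fragments_confined_to_bacs(self):
        frags, bacs = simulate_bac_library(locus_length=200_000, n_bacs=3,
                                           n_fragments=2_000, seed=2)
        for f in frags:
            assert any(f.start >= b.start and f.end <= b.end for b in bacs)

    def test_zero_fragments(self):
        frags, bacs = simulate_bac_library(locus_length=100_000, n_bacs=2,
                                           n_fragments=0, seed=0)
        assert len(frags) == 0 and len(bacs) == 2

    def test_seed_determinism(self):
        a, _ = simulate_bac_library(locus_length=100_000, n_bacs=2,
                                    n_fragments=500, seed=9)
        b, _ = simulate_bac_library(locus_length=100_000, n_bacs=2,
                                    n_fragments=500, seed=9)
        assert a == b


@pytest.fixture(scope="module")
def small_library():
    return simulate_bac_library(locus_length=150_000, n_bacs=3,
                                n_fragments=30_000, seed=3)


class TestStarrCounts:
    def test_null_construction_calls_nothing(self, small_library):
        frags, _ = small_library
        libs = simulate_starr_counts(frags, [], mean_count=1.0, seed=4)
        cmp = activity.compare_tracks(
            activity.count_fragments_to_bins(libs.sg4),
            activity.count_fragments_to_bins(libs.ctrl),
        )
        regions = activity.call_responsive_regions(cmp)
        called_bp = sum(r.interval.length for r in regions)
        assert called_bp / 150_000 < 0.01

    def test_condition_specific_element(self, small_library):
        frags, _ = small_library
        el = PlantedElement(GenomicInterval("chrS", 60_000, 62_000), fc_sg4=3.0)
        libs = simulate_starr_counts(frags, [el], mean_count=1.0, seed=5)
        ctrl = activity.count_fragments_to_bins(libs.ctrl)

        def call(lib):
            return activity.call_responsive_regions(
                activity.compare_tracks(activity.count_fragments_to_bins(lib), ctrl)
            )

        sg4_calls = call(libs.sg4)
        assert any(r.interval.overlap_bp(el.interval) >= 50 for r in sg4_calls)
        wnt_calls = call(libs.wnt)
        assert not any(r.interval.overlap_bp(el.interval) >= 50 for r in wnt_calls)

    def test_element_mean_enrichment_near_fold_change(self, small_library):
        frags, _ = small_library
        el = PlantedElement(GenomicInterval("chrS", 60_000, 70_000), fc_sg4=3.0)
        libs = simulate_starr_counts(frags, [el], mean_count=1.0, seed=6)
        sg4 = activity.count_fragments_to_bins(libs.sg4).counts["chrS"]
        ctrl = activity.count_fragments_to_bins(libs.ctrl).counts["chrS"]
        core = slice((60_000 + 1_000) // 50, (70_000 - 1_000) // 50)
        ratio = sg4[core].sum() / ctrl[core].sum()
        assert ratio == pytest.approx(3.0, rel=0.15)

    def test_poisson_mode_and_determinism(self, small_library):
        frags, _ = small_library
        a = simulate_starr_counts(frags, [], dispersion=0.0, seed=7)
        b = simulate_starr_counts(frags, [], dispersion=0.0, seed=7)
        assert a.ctrl == b.ctrl and a.sg4 == b.sg4


class TestAssociationStudy:
    def test_truth_recovered_by_selection_and_expansion(self):
        specs = [
            VrSpec(start=200_000, end=240_000, trait="PR|QRS"),
            VrSpec(start=376_000, end=455_000, trait="PR"),
        ]
        snps, h, truth = simulate_association_study(specs, seed=8)
        selected = variants.select_trait_snps(snps)
        leads = [s for s in snps if s.p_value < variants.GW_THRESHOLD]
        expanded = variants.expand_by_ld(selected, leads, h, all_snps=snps)
        assert sorted(s.id for s in expanded) == truth["expected_selected"]

    def test_two_vrs_at_printed_spacing_stay_distinct(self):
        # VR spans mirror the published topology: 40 kb and 79 kb spans
        # separated by 136 kb, resolved at the default 100-kb locus gap
        specs = [
            VrSpec(start=200_000, end=240_000),
            VrSpec(start=376_000, end=455_000),
        ]
        snps, h, _ = simulate_association_study(specs, seed=9)
        selected = variants.select_trait_snps(snps)
        vrs = variants.define_variant_regions(selected, max_gap=100_000)
        assert len(vrs) == 2

    def test_no_specs_selects_nothing(self):
        snps, h, truth = simulate_association_study([], seed=0)
        assert snps == [] and variants.select_trait_snps(snps) == []

    def test_seed_determinism(self):
        layout = [VrSpec(start=0, end=10_000)]
        a = simulate_association_study(layout, seed=3)
        b = simulate_association_study(layout, seed=3)
        assert [s.id for s in a[0]] == [s.id for s in b[0]]
        assert np.array_equal(a[1].data, b[1].data)


class TestChain:
    def test_zero_indels_is_identity(self):
        ch, truth = simulate_chain(5_000, 0, seed=0)
        assert ch.blocks == [(5_000, 0, 0)]
        assert np.array_equal(truth, np.arange(5_000))

    def test_truth_map_agrees_with_mapper(self, rng):
        ch, truth = simulate_chain(50_000, 30, seed=10)
        for _ in range(1_000):
            s = int(rng.integers(0, 49_000))
            e = s + int(rng.integers(1, 500))
            m = map_interval(GenomicInterval("chrS", s, e), [ch],
                             min_mapped_fraction=1e-9)
            vals = truth[s:e]
            mapped = vals[vals >= 0]
            if len(mapped) == 0:
                assert m.target is None
            else:
                assert (m.target.start, m.target.end) == (
                    int(mapped.min()), int(mapped.max()) + 1,
                )

    def test_inversion_reverses_order(self):
        ch, truth = simulate_chain(10_000, 5, seed=11, inversion=True)
        assert ch.target_strand == "-"
        a = map_interval(GenomicInterval("chrS", 100, 200), [ch]).target
        b = map_interval(GenomicInterval("chrS", 5_000, 5_100), [ch]).target
        assert a.start > b.start  # source order reversed on the target

    def test_too_many_indels_rejected(self):
        with pytest.raises(ValueError, match="indels"):
            simulate_chain(1_000, 500, seed=0)


class TestMotifSets:
    def make_pwm(self):
        counts = np.zeros((4, 8))
        for j, b in enumerate("GATTACAT"):
            counts["ACGT".index(b), j] = 50
        return Pwm.from_counts("planted", counts)

    def test_rate_validation(self):
        with pytest.raises(ValueError, match="rates"):
            simulate_motif_sets(self.make_pwm(), target_rate=1.5)

    def test_zero_rates_give_no_hits_at_stringent_threshold(self):
        from starrcre.motifs import scan_sequence

        pwm = self.make_pwm()
        t, b, _ = simulate_motif_sets(pwm, n_target=20, n_background=20,
                                      target_rate=0.0, background_rate=0.0,
                                      seq_length=100, seed=12)
        hits = sum(bool(scan_sequence(pwm, s, 0.99)) for s in t + b)
        assert hits == 0

    def test_planting_matches_truth_flags(self):
        from starrcre.motifs import scan_sequence

        pwm = self.make_pwm()
        t, _, truth = simulate_motif_sets(pwm, n_target=40, n_background=1,
                                          target_rate=0.5, background_rate=0.0,
                                          seq_length=120, seed=13)
        # instances are sampled from the matrix, so allow a mismatch or two
        for seq, has in zip(t, truth["target_planted"]):
            if has:
                assert scan_sequence(pwm, seq, 0.75)


class TestFeatureTracks:
    def test_shapes_and_determinism(self):
        fm, labels, truth = simulate_feature_tracks(n_bins=200, n_datasets=3, seed=14)
        assert fm.values.shape == (200, 3) and len(labels) == 200
        fm2, labels2, _ = simulate_feature_tracks(n_bins=200, n_datasets=3, seed=14)
        assert np.array_equal(fm.values, fm2.values)
        assert np.array_equal(labels, labels2)

    def test_null_weights_give_chance_level_model(self):
        from starrcre.emerge import predict_track, train_model

        fm, labels, _ = simulate_feature_tracks(
            n_bins=3_000, n_datasets=5, true_weights=[0] * 5, seed=15
        )
        model = train_model(fm, labels, seed=0)
        probs = predict_track(model, fm)
        pos, neg = probs[labels == 1], probs[labels == 0]
        auc = (pos[:, None] > neg[None, :]).mean()
        assert abs(auc - 0.5) < 0.05


def test_candidate_study_is_deterministic_per_seed():
    a = simulate_candidate_study(seed=2, n_fragments=5_000)
    b = simulate_candidate_study(seed=2, n_fragments=5_000)
    assert a.fragments == b.fragments
    assert a.libraries.sg4 == b.libraries.sg4
    assert [s.id for s in a.snps] == [s.id for s in b.snps]
    assert np.array_equal(a.chain_truth, b.chain_truth)
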