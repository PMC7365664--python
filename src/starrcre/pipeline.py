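"""End-to-end orchestration: from raw inputs to variant-bearing candidates.

Runs the full analysis route on a :class:`~starrcre.synthetic.CandidateStudy`
(or equivalently assembled real inputs): activity calling under both
stimulation contexts, enhancer prediction, orthology mapping, variant
prioritization, evidence integration and per-VR summarization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import activity, emerge, integrate, liftover, variants
from .intervals import GenomicInterval, RegionSet
from .synthetic import CandidateStudy

__all__ = ["StudyResult", "run_candidate_study"]


@dataclass
class StudyResult:
    """Everything the integration stage produced, plus the run summary."""

    starr_sg4: RegionSet
    starr_wnt: RegionSet
    emerge_regions: RegionSet
    ortholog_regions: RegionSet
    mapping_report: liftover.MappingReport
    selected_snps: list[variants.Snp]
    variant_regions: list[variants.VariantRegion]
    candidates: list[integrate.CandidateRE]
    candidates_in_vr: list[integrate.CandidateRE]
    variant_bearing: list[integrate.CandidateRE]
    variant_free: list[integrate.CandidateRE]
    summary: dict


def run_candidate_study(
    study: CandidateStudy,
    bin_size: int = activity.DEFAULT_BIN_SIZE,
    min_raw_total: int = activity.DEFAULT_MIN_RAW_TOTAL,
    log2_threshold: float = activity.DEFAULT_LOG2_THRESHOLD,
    emerge_threshold: float = 0.5,
    emerge_l2: float = emerge.DEFAULT_L2_STRENGTH,
    locus_gap: int = variants.DEFAULT_LOCUS_GAP,
    seed: int = 0,
) -> StudyResult:
    """Execute the whole pipeline on a simulated (or assembled) study."""
    tag = study.fragments.genome_tag

    # 1. STARR activity calling, one comparison per stimulation context
    ctrl = activity.count_fragments_to_bins(study.libraries.ctrl, bin_size)
    sg4 = activity.count_fragments_to_bins(study.libraries.sg4, bin_size)
    wnt = activity.count_fragments_to_bins(study.libraries.wnt, bin_size)
    sg4_regions = activity.call_responsive_regions(
        activity.compare_tracks(sg4, ctrl), min_raw_total, log2_threshold
    )
    wnt_regions = activity.call_responsive_regions(
        activity.compare_tracks(wnt, ctrl), min_raw_total, log2_threshold
    )
    starr_sg4 = RegionSet((r.interval for r in sg4_regions), tag)
    starr_wnt = RegionSet((r.interval for r in wnt_regions), tag)

    # 2. enhancer prediction from the feature compendium
    model = emerge.train_model(
        study.feature_matrix, study.feature_labels, l2_strength=emerge_l2, seed=seed
    )
    probs = emerge.predict_track(model, study.feature_matrix)
    emerge_regions = emerge.call_predicted_enhancers(
        probs, emerge_threshold, study.feature_matrix.bins, genome_tag=tag
    )

    # 3. orthology: translate the mouse-side regions onto the human locus
    ortholog_regions, report = liftover.map_region_set(
        study.mouse_regions, [study.chain], target_genome_tag=tag
    )

    # 4. variant prioritization
    selected = variants.select_trait_snps(study.snps, locus_gap=locus_gap)
    leads = [s for s in study.snps if s.p_value < variants.GW_THRESHOLD]
    expanded = variants.expand_by_ld(
        selected, leads, study.haplotypes, all_snps=study.snps
    )
    vrs = variants.define_variant_regions(expanded, max_gap=locus_gap)

    # 5. integration
    candidates = integrate.combine_evidence(
        starr_sg4, starr_wnt, emerge_regions, ortholog_regions
    )
    in_vr = integrate.filter_by_variant_regions(candidates, vrs)
    bearing, free = integrate.annotate_with_variants(in_vr, expanded)

    summary = integrate.summarize_candidates(in_vr)
    summary.update(
        {
            "n_candidates_total": len(candidates),
            "n_starr_sg4": len(starr_sg4),
            "n_starr_wnt": len(starr_wnt),
            "n_emerge": len(emerge_regions),
            "n_orthologs_mapped": report.n_mapped,
            "n_snps_selected": len(expanded),
            "n_variant_regions": len(vrs),
            "parameters": {
                "bin_size": bin_size,
                "min_raw_total": min_raw_total,
                "log2_threshold": log2_threshold,
                "emerge_threshold": emerge_threshold,
                "locus_gap": locus_gap,
                "seed": seed,
            },
        }
    )
    return StudyResult(
        starr_sg4=starr_sg4,
        starr_wnt=starr_wnt,
        emerge_regions=emerge_regions,
        ortholog_regions=ortholog_regions,
        mapping_report=report,
        selected_snps=expanded,
        variant_regions=vrs,
        candidates=candidates,
        candidates_in_vr=in_vr,
        variant_bearing=bearing,
        variant_free=free,
        summary=summary,
    )
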