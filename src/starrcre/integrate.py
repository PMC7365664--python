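"""Three-evidence integration into variant-bearing candidate REs.

Candidate regulatory elements are the merged union (>= 1 bp overlap) of
four evidence streams: stimulus-responsive STARR regions under the two
signaling contexts, predicted enhancer regions, and mouse orthologous
regions translated to the target assembly.  Candidates are restricted to
trait-variant regions, annotated with the prioritized SNPs they harbor,
and summarized; conservation overlap statistics between translated and
native region sets use a configurable minimum-overlap rule (50 bp by
default, reserved for set-vs-set comparisons).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .intervals import GenomicInterval, RegionSet, intersect_min_overlap
from .variants import Snp, VariantRegion

__all__ = [
    "CandidateRE",
    "EVIDENCE_FLAGS",
    "combine_evidence",
    "filter_by_variant_regions",
    "annotate_with_variants",
    "conservation_overlap",
    "ConservationOverlap",
    "summarize_candidates",
    "candidates_to_region_set",
]

EVIDENCE_FLAGS = ("starr_sg4", "starr_wnt", "emerge", "ortholog")
_FLAG_SHORT = {
    "starr_sg4": "SG4",
    "starr_wnt": "WNT",
    "emerge": "EMERGE",
    "ortholog": "ORTH",
}


@dataclass
class CandidateRE:
    """A merged evidence cluster with flags, sources, variants and VR label."""

    interval: GenomicInterval
    evidence: frozenset[str]
    sources: dict[str, list[GenomicInterval]] = field(default_factory=dict)
    variants: list[Snp] = field(default_factory=list)
    vr_label: str | None = None

    def __post_init__(self) -> None:
        if not self.evidence:
            raise ValueError("a candidate must carry at least one evidence flag")
        unknown = self.evidence - set(EVIDENCE_FLAGS)
        if unknown:
            raise ValueError(f"unknown evidence flags: {sorted(unknown)}")

    @property
    def name(self) -> str:
        return "|".join(
            _FLAG_SHORT[f] for f in EVIDENCE_FLAGS if f in self.evidence
        )


def combine_evidence(
    starr_sg4: RegionSet,
    starr_wnt: RegionSet,
    emerge: RegionSet,
    orthologs: RegionSet,
    genome_tag: str | None = None,
) -> list[CandidateRE]:
    """Merge the four evidence streams into candidate REs.

    Intervals overlapping by >= 1 bp (strictly; bookended intervals stay
    apart) merge into one candidate carrying the union of evidence flags and
    the source intervals per flag.  All inputs must be on one assembly.
    """
    streams = {
        "starr_sg4": starr_sg4,
        "starr_wnt": starr_wnt,
        "emerge": emerge,
        "ortholog": orthologs,
    }
    tags = {rs.genome_tag for rs in streams.values() if rs.genome_tag}
    if genome_tag:
        tags.add(genome_tag)
    if len(tags) > 1:
        raise ValueError(f"evidence sets on different assemblies: {sorted(tags)}")
    tag = tags.pop() if tags else ""
    tagged = sorted(
        ((iv, flag) for flag, rs in streams.items() for iv in rs),
        key=lambda x: x[0],
    )
    out: list[CandidateRE] = []
    cur: list[tuple[GenomicInterval, str]] = []
    cur_contig: str | None = None
    cur_end = 0

    def flush() -> None:
        if not cur:
            return
        sources: dict[str, list[GenomicInterval]] = {}
        for iv, flag in cur:
            sources.setdefault(flag, []).append(iv)
        span = GenomicInterval(
            cur[0][0].contig,
            min(iv.start for iv, _ in cur),
            max(iv.end for iv, _ in cur),
        )
        out.append(
            CandidateRE(
                interval=span, evidence=frozenset(sources), sources=sources
            )
        )

    for iv, flag in tagged:
        if iv.contig == cur_contig and iv.start < cur_end:
            cur.append((iv, flag))
            cur_end = max(cur_end, iv.end)
        else:
            flush()
            cur = [(iv, flag)]
            cur_contig, cur_end = iv.contig, iv.end
    flush()
    for c in out:
        c.interval = GenomicInterval(
            c.interval.contig, c.interval.start, c.interval.end, name=c.name
        )
    return out


def filter_by_variant_regions(
    candidates: list[CandidateRE],
    vrs: list[VariantRegion],
    containment: bool = False,
) -> list[CandidateRE]:
    """Keep candidates located within a variant region.

    Membership is >= 1 bp overlap by default ("genomic location within" a
    VR); ``containment=True`` demands the candidate lie entirely inside.
    Each kept candidate is labelled with the VR it overlaps most.
    """
    kept: list[CandidateRE] = []
    for cand in candidates:
        best: VariantRegion | None = None
        best_overlap = 0
        for vr in vrs:
            ov = cand.interval.overlap_bp(vr.interval)
            if containment:
                ok = (
                    cand.interval.contig == vr.interval.contig
                    and cand.interval.start >= vr.interval.start
                    and cand.interval.end <= vr.interval.end
                )
            else:
                ok = ov > 0
            if ok and ov > best_overlap:
                best, best_overlap = vr, ov
        if best is not None:
            cand.vr_label = best.label
            kept.append(cand)
    return kept


def annotate_with_variants(
    candidates: list[CandidateRE], snps: list[Snp]
) -> tuple[list[CandidateRE], list[CandidateRE]]:
    """Attach SNPs falling inside each candidate (half-open span semantics).

    Returns the (variant-bearing, variant-free) split; candidates are
    modified in place.
    """
    for cand in candidates:
        cand.variants = [
            s for s in snps if cand.interval.contains_point(s.contig, s.pos)
        ]
    bearing = [c for c in candidates if c.variants]
    free = [c for c in candidates if not c.variants]
    return bearing, free


@dataclass
class ConservationOverlap:
    n_mapped: int
    n_overlapping: int
    fraction: float | None


def conservation_overlap(
    mapped_regions: RegionSet, target_regions: RegionSet, min_bp: int = 50
) -> ConservationOverlap:
    """Fraction of translated regions overlapping the native set by >= min_bp.

    An empty mapped set leaves the fraction undefined (``None``).
    """
    if len(mapped_regions) == 0:
        return ConservationOverlap(n_mapped=0, n_overlapping=0, fraction=None)
    kept, _ = intersect_min_overlap(mapped_regions, target_regions, min_bp=min_bp)
    return ConservationOverlap(
        n_mapped=len(mapped_regions),
        n_overlapping=len(kept),
        fraction=len(kept) / len(mapped_regions),
    )


def candidates_to_region_set(
    candidates: list[CandidateRE], genome_tag: str = ""
) -> RegionSet:
    """BED6 view: evidence flags in the name field."""
    return RegionSet(
        (
            GenomicInterval(
                c.interval.contig,
                c.interval.start,
                c.interval.end,
                name=(f"{c.vr_label}:" if c.vr_label else "") + c.name,
                score=len(c.variants),
            )
            for c in candidates
        ),
        genome_tag,
    )


def summarize_candidates(candidates: list[CandidateRE]) -> dict:
    """JSON-ready counts: per evidence flag, per VR, variant-bearing."""
    summary: dict = {
        "n_candidates": len(candidates),
        "per_evidence": {
            flag: sum(flag in c.evidence for c in candidates)
            for flag in EVIDENCE_FLAGS
        },
        "per_vr": {},
        "variant_bearing": sum(bool(c.variants) for c in candidates),
    }
    for c in candidates:
        if c.vr_label:
            vr = summary["per_vr"].setdefault(
                c.vr_label, {"candidates": 0, "variant_bearing": 0}
            )
            vr["candidates"] += 1
            vr["variant_bearing"] += bool(c.variants)
    return summary
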