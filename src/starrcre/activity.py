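"""STARR-seq activity calling on binned fragment coverage.

The locus is cut into fixed-width bins (default 50 bp).  Each aligned
fragment increments every bin it overlaps by at least one base.  Stimulated
and control libraries are compared per bin as a depth-normalized, pseudo-
counted log2 ratio; bins below a combined raw-count floor are excluded;
surviving bins above the fold-change threshold are merged into responsive
regions whose region-level fold change is recomputed from summed counts.

Default thresholds: combined raw count >= 75 per bin, log2 fold change
strictly > 0.585 (fold change > 1.5).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, RegionSet

__all__ = [
    "DEFAULT_BIN_SIZE",
    "DEFAULT_MIN_RAW_TOTAL",
    "DEFAULT_LOG2_THRESHOLD",
    "BinnedTrack",
    "ComparisonTrack",
    "ResponsiveRegion",
    "count_fragments_to_bins",
    "compare_tracks",
    "call_responsive_regions",
    "call_threshold_regions",
    "library_coverage_qc",
    "read_fragments_sam",
    "responsive_regions_to_bed",
    "comparison_to_bedgraph",
]

DEFAULT_BIN_SIZE = 50
DEFAULT_MIN_RAW_TOTAL = 75
#: log2 threshold equivalent to a 1.5-fold change (log2 1.5 = 0.585 to 3 dp)
DEFAULT_LOG2_THRESHOLD = 0.585


@dataclass
class BinnedTrack:
    """Per-contig fragment-overlap counts on a fixed bin grid.

    ``library_size`` counts fragments, not bin increments: a fragment that
    spans several bins is one library member but raises several bins.
    """

    bin_size: int
    counts: dict[str, np.ndarray]
    library_size: int

    def n_bins(self, contig: str) -> int:
        return len(self.counts[contig])


@dataclass
class ComparisonTrack:
    """Per-bin treat-vs-ctrl comparison with the raw-coverage filter state."""

    bin_size: int
    log2_ratio: dict[str, np.ndarray]
    raw_total: dict[str, np.ndarray]
    treat_counts: dict[str, np.ndarray]
    ctrl_counts: dict[str, np.ndarray]
    scale_treat: float
    scale_ctrl: float
    pseudocount: float

    def coverage_pass(self, min_raw_total: int) -> dict[str, np.ndarray]:
        return {c: v >= min_raw_total for c, v in self.raw_total.items()}


@dataclass
class ResponsiveRegion:
    """A merged run of responsive bins with its region-level statistics."""

    interval: GenomicInterval
    log2_fc: float
    treat_count: int
    ctrl_count: int


def count_fragments_to_bins(
    fragments: RegionSet, bin_size: int = DEFAULT_BIN_SIZE
) -> BinnedTrack:
    """Count, per bin, the fragments overlapping it by >= 1 bp.

    An empty fragment set yields an empty track with library size 0.
    """
    if bin_size < 1:
        raise ValueError(f"bin_size must be >= 1, got {bin_size}")
    # difference-array per contig: fragments overlap a contiguous bin range
    ends: dict[str, int] = {}
    for iv in fragments:
        last_bin = (iv.end - 1) // bin_size
        ends[iv.contig] = max(ends.get(iv.contig, 0), last_bin + 1)
    diffs = {c: np.zeros(n + 1, dtype=np.int64) for c, n in ends.items()}
    for iv in fragments:
        d = diffs[iv.contig]
        d[iv.start // bin_size] += 1
        d[(iv.end - 1) // bin_size + 1] -= 1
    counts = {c: np.cumsum(d[:-1]) for c, d in diffs.items()}
    return BinnedTrack(bin_size=bin_size, counts=counts, library_size=len(fragments))


def _align_layouts(a: BinnedTrack, b: BinnedTrack) -> dict[str, int]:
    layout: dict[str, int] = {}
    for c in set(a.counts) | set(b.counts):
        layout[c] = max(
            len(a.counts.get(c, ())), len(b.counts.get(c, ()))
        )
    return layout


def compare_tracks(
    treat: BinnedTrack, ctrl: BinnedTrack, pseudocount: float = 1.0
) -> ComparisonTrack:
    """Depth-normalized per-bin log2 ratio of two binned libraries.

    Both libraries are scaled to the mean library size before the pseudocount
    is added, so doubling both libraries leaves every ratio unchanged.
    ``raw_total`` keeps the unscaled combined count for the coverage filter.
    """
    if treat.bin_size != ctrl.bin_size:
        raise ValueError(
            f"bin_size mismatch: {treat.bin_size} vs {ctrl.bin_size}"
        )
    mean_size = (treat.library_size + ctrl.library_size) / 2.0
    s_t = mean_size / treat.library_size if treat.library_size else 1.0
    s_c = mean_size / ctrl.library_size if ctrl.library_size else 1.0
    layout = _align_layouts(treat, ctrl)
    log2_ratio, raw_total, tcounts, ccounts = {}, {}, {}, {}
    for contig, n in layout.items():
        t = np.zeros(n, dtype=np.int64)
        c = np.zeros(n, dtype=np.int64)
        tc = treat.counts.get(contig)
        cc = ctrl.counts.get(contig)
        if tc is not None:
            t[: len(tc)] = tc
        if cc is not None:
            c[: len(cc)] = cc
        log2_ratio[contig] = np.log2(
            (s_t * t + pseudocount) / (s_c * c + pseudocount)
        )
        raw_total[contig] = t + c
        tcounts[contig] = t
        ccounts[contig] = c
    return ComparisonTrack(
        bin_size=treat.bin_size,
        log2_ratio=log2_ratio,
        raw_total=raw_total,
        treat_counts=tcounts,
        ctrl_counts=ccounts,
        scale_treat=s_t,
        scale_ctrl=s_c,
        pseudocount=pseudocount,
    )


def _runs(mask: np.ndarray, max_gap: int) -> list[tuple[int, int]]:
    """Maximal runs of True indices allowing internal gaps of <= max_gap."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    runs: list[tuple[int, int]] = []
    start = prev = int(idx[0])
    for i in idx[1:]:
        i = int(i)
        if i - prev - 1 <= max_gap:
            prev = i
        else:
            runs.append((start, prev))
            start = prev = i
    runs.append((start, prev))
    return runs


def call_responsive_regions(
    cmp: ComparisonTrack,
    min_raw_total: int = DEFAULT_MIN_RAW_TOTAL,
    log2_threshold: float = DEFAULT_LOG2_THRESHOLD,
    max_gap: int = 0,
    merge_before_threshold: bool = False,
) -> list[ResponsiveRegion]:
    """Call stimulus-responsive regions from a comparison track.

    Default order: (1) drop bins whose combined raw count is below
    ``min_raw_total``; (2) keep bins whose log2 ratio strictly exceeds
    ``log2_threshold``; (3) merge surviving bins separated by at most
    ``max_gap`` bins; (4) recompute the region-level log2 fold change from
    the depth-scaled, pseudocounted counts summed over the merged span and
    keep regions that still clear the threshold.

    ``merge_before_threshold=True`` instead merges all coverage-passing bins
    first and applies the fold-change threshold only at the region level;
    this is useful for sensitivity analysis on sparse libraries but with
    uniformly deep coverage it fuses the whole locus into one region.
    """
    out: list[ResponsiveRegion] = []
    for contig in sorted(cmp.raw_total):
        raw = cmp.raw_total[contig]
        covered = raw >= min_raw_total
        if merge_before_threshold:
            seed_mask = covered
        else:
            seed_mask = covered & (cmp.log2_ratio[contig] > log2_threshold)
        for first, last in _runs(seed_mask, max_gap):
            t_sum = int(cmp.treat_counts[contig][first : last + 1].sum())
            c_sum = int(cmp.ctrl_counts[contig][first : last + 1].sum())
            fc = math.log2(
                (cmp.scale_treat * t_sum + cmp.pseudocount)
                / (cmp.scale_ctrl * c_sum + cmp.pseudocount)
            )
            if fc > log2_threshold:
                iv = GenomicInterval(
                    contig,
                    first * cmp.bin_size,
                    (last + 1) * cmp.bin_size,
                    score=fc,
                )
                out.append(
                    ResponsiveRegion(
                        interval=iv, log2_fc=fc, treat_count=t_sum, ctrl_count=c_sum
                    )
                )
    return out


def call_threshold_regions(
    signal: np.ndarray | dict[str, np.ndarray],
    threshold: float,
    bin_size: int = 1,
    contig: str = "chr",
    genome_tag: str = "",
) -> RegionSet:
    """Maximal contiguous runs of signal strictly above a local threshold.

    This is the locus-specific peak selection used for accessible-region
    calling: the entire span surpassing the threshold becomes one region.
    Signal may be per-base (``bin_size=1``) or per-bin.
    """
    if not math.isfinite(threshold):
        raise ValueError("threshold must be finite")
    tracks = signal if isinstance(signal, dict) else {contig: np.asarray(signal)}
    out: list[GenomicInterval] = []
    for ctg in sorted(tracks):
        for first, last in _runs(np.asarray(tracks[ctg]) > threshold, 0):
            out.append(GenomicInterval(ctg, first * bin_size, (last + 1) * bin_size))
    return RegionSet(out, genome_tag)


@dataclass
class CoverageQC:
    """Input-library coverage inside single-BAC vs two-BAC overlap segments."""

    single_mean: float
    overlap_mean: float | None
    ratio: float | None
    n_single_bins: int
    n_overlap_bins: int


def library_coverage_qc(input_track: BinnedTrack, bac_layout: RegionSet) -> CoverageQC:
    """Check that two-BAC overlap segments carry ~2x the single-BAC coverage.

    Bins are assigned to a segment class only when the BAC copy depth is
    constant across the whole bin.  With no pairwise-overlap segment the
    ratio is reported as absent (``None``).
    """
    bs = input_track.bin_size
    single_vals: list[np.ndarray] = []
    overlap_vals: list[np.ndarray] = []
    for contig, counts in input_track.counts.items():
        n = len(counts)
        depth_diff = np.zeros(n * bs + 1, dtype=np.int64)
        for iv in bac_layout:
            if iv.contig != contig:
                continue
            depth_diff[min(iv.start, n * bs)] += 1
            depth_diff[min(iv.end, n * bs)] -= 1
        depth = np.cumsum(depth_diff[:-1])
        per_bin = depth.reshape(n, bs)
        uniform = (per_bin == per_bin[:, :1]).all(axis=1)
        bin_depth = per_bin[:, 0]
        single_vals.append(counts[uniform & (bin_depth == 1)])
        overlap_vals.append(counts[uniform & (bin_depth == 2)])
    single = np.concatenate(single_vals) if single_vals else np.array([])
    overlap = np.concatenate(overlap_vals) if overlap_vals else np.array([])
    single_mean = float(single.mean()) if single.size else 0.0
    overlap_mean = float(overlap.mean()) if overlap.size else None
    ratio = (
        overlap_mean / single_mean
        if overlap_mean is not None and single_mean > 0
        else None
    )
    return CoverageQC(
        single_mean=single_mean,
        overlap_mean=overlap_mean,
        ratio=ratio,
        n_single_bins=int(single.size),
        n_overlap_bins=int(overlap.size),
    )


def read_fragments_sam(path, genome_tag: str = "") -> RegionSet:
    """Collapse paired SAM records to fragment intervals.

    Only mapped, primary, properly-paired records contribute; each template
    yields one fragment, taken from read 1 as
    ``[reference_start, reference_start + template_length)``.
    """
    import pysam

    out: list[GenomicInterval] = []
    with pysam.AlignmentFile(str(path), "r") as sam:
        for rec in sam:
            if (
                rec.is_unmapped
                or rec.is_secondary
                or rec.is_supplementary
                or not rec.is_paired
                or not rec.is_proper_pair
                or rec.template_length <= 0
            ):
                continue
            out.append(
                GenomicInterval(
                    rec.reference_name,
                    rec.reference_start,
                    rec.reference_start + rec.template_length,
                    name=rec.query_name,
                )
            )
    return RegionSet(out, genome_tag)


def responsive_regions_to_bed(regions: list[ResponsiveRegion], genome_tag: str = "") -> RegionSet:
    """BED6 view: score = region log2 fold change x 1000, rounded."""
    out = [
        GenomicInterval(
            r.interval.contig,
            r.interval.start,
            r.interval.end,
            name=f"region_{i + 1}",
            score=round(r.log2_fc * 1000),
        )
        for i, r in enumerate(regions)
    ]
    return RegionSet(out, genome_tag)


def comparison_to_bedgraph(cmp: ComparisonTrack) -> pd.DataFrame:
    """Per-bin log2 ratio as a bedGraph frame."""
    rows = []
    for contig in sorted(cmp.log2_ratio):
        vals = cmp.log2_ratio[contig]
        starts = np.arange(len(vals)) * cmp.bin_size
        rows.append(
            pd.DataFrame(
                {
                    "contig": contig,
                    "start": starts,
                    "end": starts + cmp.bin_size,
                    "value": vals,
                }
            )
        )
    return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["contig", "start", "end", "value"]
    )
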