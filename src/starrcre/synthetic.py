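"""Synthetic inputs with known ground truth for every pipeline stage.

Every generator is deterministic given its seed and ships the truth needed
to recompute its expected outputs: planted responsive elements with their
condition fold changes, the causal SNP/LD layout, the exact per-base chain
mapping, planted motif placements, and the true logistic weights.

The STARR generator emulates the study geometry at desk scale: a ~1.3-Mb
locus tiled by overlapping BACs, fragments of 500-1000 bp sampled uniformly
within BACs (so two-BAC overlap segments show doubled input coverage), and
per-fragment reporter counts that are negative-binomial (Poisson at
dispersion 0) around a depth target.  A planted responsive element is a
multi-kb span of uniformly active sequence: a fragment transcribes at the
elevated rate for a condition only when it lies entirely inside such a
span, so the activation footprint — and therefore the calling truth — is
the planted interval itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .emerge import FeatureMatrix, make_bin_grid
from .intervals import GenomicInterval, RegionSet
from .liftover import ChainAlignment
from .motifs import Pwm
from .variants import HaplotypeMatrix, Snp

__all__ = [
    "PlantedElement",
    "StarrLibraries",
    "VrSpec",
    "simulate_locus",
    "simulate_bac_library",
    "simulate_starr_counts",
    "simulate_association_study",
    "simulate_chain",
    "simulate_motif_sets",
    "simulate_feature_tracks",
    "simulate_candidate_study",
    "CandidateStudy",
]

_BASES = np.array(list("ACGT"))


def simulate_locus(length_bp: int, gc: float = 0.41, seed: int = 0) -> str:
    """I.i.d. random sequence at the stated GC content."""
    if length_bp < 1:
        raise ValueError("length_bp must be >= 1")
    if not 0 < gc <= 1:
        raise ValueError("gc must be in (0, 1]")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=length_bp, p=p)])


def simulate_bac_library(
    locus_length: int = 1_300_000,
    n_bacs: int = 13,
    bac_length: int | None = None,
    frag_min: int = 500,
    frag_max: int = 1000,
    n_fragments: int = 50_000,
    seed: int = 0,
    contig: str = "chrS",
    genome_tag: str = "sim",
) -> tuple[RegionSet, RegionSet]:
    """Overlapping BAC tiling of the locus plus a sheared fragment library.

    BACs are equimolar: fragments pick a BAC uniformly, then a start
    uniformly within it, with lengths uniform in [frag_min, frag_max].
    Pairwise BAC overlap segments therefore receive ~2x single-BAC input
    coverage, the QC signature of an evenly represented library.
    """
    if n_bacs < 1:
        raise ValueError("n_bacs must be >= 1")
    if bac_length is None:
        bac_length = int(locus_length / n_bacs * 1.15)
    if bac_length <= frag_max:
        raise ValueError("bac_length must exceed frag_max")
    if n_bacs == 1:
        starts = np.array([0])
        bac_length = min(bac_length, locus_length)
    else:
        step = (locus_length - bac_length) / (n_bacs - 1)
        if step >= bac_length:
            raise ValueError("BAC tiling must have pairwise overlaps")
        starts = np.round(np.arange(n_bacs) * step).astype(int)
    bacs = [
        GenomicInterval(contig, int(s), int(min(s + bac_length, locus_length)),
                        name=f"BAC{i + 1}")
        for i, s in enumerate(starts)
    ]
    rng = np.random.default_rng(seed)
    frags: list[GenomicInterval] = []
    if n_fragments > 0:
        which = rng.integers(0, n_bacs, size=n_fragments)
        lengths = rng.integers(frag_min, frag_max + 1, size=n_fragments)
        for b, ln in zip(which, lengths):
            bac = bacs[b]
            ln = int(min(ln, bac.length))
            start = int(rng.integers(bac.start, bac.end - ln + 1))
            frags.append(GenomicInterval(contig, start, start + ln))
    return RegionSet(frags, genome_tag), RegionSet(bacs, genome_tag)


@dataclass(frozen=True)
class PlantedElement:
    """A span of uniformly active regulatory sequence with per-condition
    fold changes (1.0 = inert under that condition)."""

    interval: GenomicInterval
    fc_sg4: float = 1.0
    fc_wnt: float = 1.0

    def __post_init__(self) -> None:
        if self.fc_sg4 <= 0 or self.fc_wnt <= 0:
            raise ValueError("fold changes must be > 0")


@dataclass
class StarrLibraries:
    """Sequenced fragment sets for the three transfection conditions."""

    ctrl: RegionSet
    sg4: RegionSet
    wnt: RegionSet


def _fragment_weights(
    fragments: RegionSet, elements: list[PlantedElement], condition: str
) -> np.ndarray:
    starts = np.fromiter((f.start for f in fragments), dtype=np.int64, count=len(fragments))
    ends = np.fromiter((f.end for f in fragments), dtype=np.int64, count=len(fragments))
    w = np.ones(len(fragments))
    for el in elements:
        fc = {"ctrl": 1.0, "sg4": el.fc_sg4, "wnt": el.fc_wnt}[condition]
        if fc == 1.0:
            continue
        inside = (starts >= el.interval.start) & (ends <= el.interval.end)
        w[inside] *= fc
    return w


def simulate_starr_counts(
    fragments: RegionSet,
    elements: list[PlantedElement],
    mean_count: float = 1.0,
    dispersion: float = 0.1,
    seed: int = 0,
) -> StarrLibraries:
    """Per-condition reporter read sets over a shared fragment pool.

    Each fragment's read count is negative-binomial with mean
    ``mean_count x weight``, where the weight is the element fold change for
    fragments entirely inside a planted element and 1 elsewhere; dispersion
    0 gives Poisson counts.  The returned region sets repeat each fragment
    interval once per read.
    """
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    rng = np.random.default_rng(seed)
    libs: dict[str, RegionSet] = {}
    for condition in ("ctrl", "sg4", "wnt"):
        mu = mean_count * _fragment_weights(fragments, elements, condition)
        if dispersion > 0:
            lam = rng.gamma(shape=1.0 / dispersion, scale=mu * dispersion)
            counts = rng.poisson(lam)
        else:
            counts = rng.poisson(mu)
        reads: list[GenomicInterval] = []
        for frag, c in zip(fragments, counts):
            reads.extend([frag] * int(c))
        libs[condition] = RegionSet(reads, fragments.genome_tag)
    return StarrLibraries(**libs)


@dataclass
class VrSpec:
    """Layout of one simulated variant region.

    ``sub_positions`` (p < 0.05 satellites), ``null_positions`` (p > 0.05,
    excluded) and ``linked_positions`` (p > 0.05 but in high LD with the
    lead, included only through LD expansion) may be given explicitly;
    unset lists are drawn uniformly within the span.
    """

    start: int
    end: int
    trait: str = "PR"
    lead_pos: int | None = None
    lead_p: float = 1e-9
    n_sub: int = 6
    n_null: int = 3
    n_linked: int = 2
    sub_positions: list[int] | None = None
    null_positions: list[int] | None = None
    linked_positions: list[int] | None = None


def simulate_association_study(
    vr_specs: list[VrSpec],
    n_haplotypes: int = 400,
    seed: int = 0,
    contig: str = "chrH",
    flip_prob: float = 0.05,
) -> tuple[list[Snp], HaplotypeMatrix, dict]:
    """Association table plus phased haplotypes with a planted LD structure.

    Per VR: one genome-wide significant lead (frequency 1/2), sub-threshold
    satellites with p in (0.005, 0.045), excluded satellites with p in
    (0.06, 0.5), and linked sites whose haplotype copies the lead allele
    with per-site flip probability ``flip_prob`` (expected r^2 ~
    (1-2*flip_prob)^2, 0.81 at the default — above the 0.5 expansion
    threshold).  All other sites are independent draws at intermediate
    frequency.  The truth records exactly which SNP ids survive selection
    plus LD expansion.
    """
    rng = np.random.default_rng(seed)
    snps: list[Snp] = []
    columns: list[np.ndarray] = []
    site_ids: list[str] = []
    truth: dict = {"vrs": [], "expected_selected": []}

    def lead_column() -> np.ndarray:
        col = np.zeros(n_haplotypes, dtype=np.int8)
        col[rng.choice(n_haplotypes, n_haplotypes // 2, replace=False)] = 1
        return col

    def add(pos: int, p: float, trait: str, col: np.ndarray) -> str:
        sid = f"rs_{contig}_{pos}"
        ref, alt = rng.choice(list("ACGT"), size=2, replace=False)
        snps.append(
            Snp(id=sid, contig=contig, pos=pos, ref_allele=str(ref),
                alt_allele=str(alt), p_value=p, trait=trait)
        )
        columns.append(col)
        site_ids.append(sid)
        return sid

    for vr in vr_specs:
        if not vr.start < vr.end:
            raise ValueError("VR span must be non-empty")
        used: set[int] = set()

        def draw(n: int) -> list[int]:
            out: list[int] = []
            while len(out) < n:
                pos = int(rng.integers(vr.start, vr.end))
                if pos not in used:
                    used.add(pos)
                    out.append(pos)
            return out

        lead_pos = vr.lead_pos if vr.lead_pos is not None else (vr.start + vr.end) // 2
        used.add(lead_pos)
        subs = vr.sub_positions if vr.sub_positions is not None else draw(vr.n_sub)
        nulls = vr.null_positions if vr.null_positions is not None else draw(vr.n_null)
        linked = (
            vr.linked_positions if vr.linked_positions is not None else draw(vr.n_linked)
        )
        used.update(subs + nulls + linked)

        lead_col = lead_column()
        lead_id = add(lead_pos, vr.lead_p, vr.trait, lead_col)
        expected = [lead_id]
        for pos in subs:
            freq = rng.uniform(0.2, 0.8)
            col = (rng.random(n_haplotypes) < freq).astype(np.int8)
            if col.sum() in (0, n_haplotypes):  # keep polymorphic
                col[0] = 1 - col[0]
            expected.append(add(pos, float(rng.uniform(0.005, 0.045)), vr.trait, col))
        for pos in nulls:
            freq = rng.uniform(0.2, 0.8)
            col = (rng.random(n_haplotypes) < freq).astype(np.int8)
            if col.sum() in (0, n_haplotypes):
                col[0] = 1 - col[0]
            add(pos, float(rng.uniform(0.06, 0.5)), vr.trait, col)
        for pos in linked:
            flips = rng.random(n_haplotypes) < flip_prob
            col = np.where(flips, 1 - lead_col, lead_col).astype(np.int8)
            expected.append(add(pos, float(rng.uniform(0.06, 0.5)), vr.trait, col))
        truth["vrs"].append(
            {
                "span": [vr.start, vr.end],
                "trait": vr.trait,
                "lead": lead_id,
                "expected_member_ids": sorted(expected),
            }
        )
        truth["expected_selected"].extend(expected)

    truth["expected_selected"] = sorted(truth["expected_selected"])
    h = HaplotypeMatrix(
        data=np.column_stack(columns) if columns else np.zeros((n_haplotypes, 0)),
        site_ids=site_ids,
    )
    return snps, h, truth


def simulate_chain(
    source_length: int,
    n_indels: int,
    indel_size_range: tuple[int, int] = (5, 50),
    inversion: bool = False,
    seed: int = 0,
    source_contig: str = "chrS",
    target_contig: str = "chrT",
) -> tuple[ChainAlignment, np.ndarray]:
    """A valid chain with random indels plus its exact per-base truth map.

    The truth is an array of length ``source_length`` giving, for every
    source base, its forward-strand target coordinate or -1 if the base
    falls in a deletion gap.  With ``inversion`` the chain is written on the
    target minus strand and the truth positions run in reverse order.
    """
    lo, hi = indel_size_range
    if not 1 <= lo <= hi:
        raise ValueError("bad indel size range")
    rng = np.random.default_rng(seed)
    spacing = hi + 2  # room for a deletion between consecutive breakpoints
    max_events = max(0, (source_length - 2) // spacing - 1)
    if n_indels > max_events:
        raise ValueError(
            f"{n_indels} indels do not fit in {source_length} bp at sizes <= {hi}"
        )
    blocks: list[tuple[int, int, int]] = []
    if n_indels == 0:
        blocks = [(source_length, 0, 0)]
    else:
        cuts = np.sort(
            rng.choice(np.arange(1, max_events + 1), size=n_indels, replace=False)
        ) * spacing
        pos = 0
        for cut in cuts:
            size = int(cut) - pos
            g = int(rng.integers(lo, hi + 1))
            if rng.random() < 0.5:
                blocks.append((size, g, 0))  # deletion: source bases unaligned
                pos = int(cut) + g
            else:
                blocks.append((size, 0, g))  # insertion in target
                pos = int(cut)
        blocks.append((source_length - pos, 0, 0))
    aligned = sum(b[0] for b in blocks)
    target_length = aligned + sum(b[2] for b in blocks)

    truth = np.full(source_length, -1, dtype=np.int64)
    s = t = 0
    for size, sgap, tgap in blocks:
        truth[s : s + size] = np.arange(t, t + size)
        s += size + sgap
        t += size + tgap
    if inversion:
        truth = np.where(truth >= 0, target_length - 1 - truth, -1)
    chain = ChainAlignment(
        score=float(aligned),
        source_name=source_contig,
        source_size=source_length,
        source_strand="+",
        source_start=0,
        source_end=source_length,
        target_name=target_contig,
        target_size=target_length,
        target_strand="-" if inversion else "+",
        target_start=0,
        target_end=target_length,
        blocks=blocks,
        chain_id=1,
    )
    return chain, truth


def simulate_motif_sets(
    pwm: Pwm,
    n_target: int = 150,
    n_background: int = 150,
    target_rate: float = 0.8,
    background_rate: float = 0.05,
    seq_length: int = 300,
    seed: int = 0,
) -> tuple[list[str], list[str], dict]:
    """Two sequence sets with the motif planted at stated per-sequence rates."""
    for rate in (target_rate, background_rate):
        if not 0 <= rate <= 1:
            raise ValueError("rates must be in [0, 1]")
    if seq_length < pwm.width:
        raise ValueError("sequences must be at least motif width long")
    rng = np.random.default_rng(seed)
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}

    def sample_instance() -> str:
        inst = "".join(
            _BASES[rng.choice(4, p=pwm.probs[:, j])] for j in range(pwm.width)
        )
        if rng.random() < 0.5:
            inst = "".join(comp[b] for b in reversed(inst))
        return inst

    def sample_set(n: int, rate: float) -> tuple[list[str], list[bool]]:
        seqs: list[str] = []
        planted: list[bool] = []
        for _ in range(n):
            seq = "".join(_BASES[rng.choice(4, p=pwm.background, size=seq_length)])
            has = bool(rng.random() < rate)
            if has:
                off = int(rng.integers(0, seq_length - pwm.width + 1))
                inst = sample_instance()
                seq = seq[:off] + inst + seq[off + pwm.width :]
            seqs.append(seq)
            planted.append(has)
        return seqs, planted

    targets, t_flags = sample_set(n_target, target_rate)
    background, b_flags = sample_set(n_background, background_rate)
    truth = {
        "motif": pwm.name,
        "target_planted": t_flags,
        "background_planted": b_flags,
    }
    return targets, background, truth


def simulate_feature_tracks(
    n_bins: int = 5_000,
    n_datasets: int = 10,
    true_weights: np.ndarray | None = None,
    intercept: float = 0.0,
    seed: int = 0,
    bin_size: int = 100,
    contig: str = "chrF",
) -> tuple[FeatureMatrix, np.ndarray, dict]:
    """Standard-normal feature tracks with Bernoulli(sigmoid(Xw+b)) labels."""
    rng = np.random.default_rng(seed)
    if true_weights is None:
        true_weights = rng.normal(0, 1.5, size=n_datasets)
    true_weights = np.asarray(true_weights, dtype=float)
    if len(true_weights) != n_datasets:
        raise ValueError("true_weights length must equal n_datasets")
    x = rng.standard_normal((n_bins, n_datasets))
    p = 1.0 / (1.0 + np.exp(-(x @ true_weights + intercept)))
    labels = (rng.random(n_bins) < p).astype(np.int64)
    fm = FeatureMatrix(
        bins=make_bin_grid(contig, n_bins * bin_size, bin_size),
        values=x,
        dataset_names=[f"dataset_{i + 1}" for i in range(n_datasets)],
    )
    truth = {"weights": true_weights.tolist(), "intercept": intercept}
    return fm, labels, truth


# --------------------------------------------------------------------------
# End-to-end locus study


@dataclass
class CandidateStudy:
    """All pipeline inputs for a simulated locus, with the planted truth."""

    contig_human: str
    contig_mouse: str
    locus_length: int
    fragments: RegionSet
    bac_layout: RegionSet
    libraries: StarrLibraries
    elements: list[PlantedElement]
    feature_matrix: FeatureMatrix
    feature_labels: np.ndarray
    mouse_regions: RegionSet
    chain: ChainAlignment
    chain_truth: np.ndarray
    snps: list[Snp]
    haplotypes: HaplotypeMatrix
    association_truth: dict
    truth: dict


def _source_span_for_target(
    chain_truth: np.ndarray, target_start: int, target_end: int
) -> tuple[int, int]:
    """Source interval whose aligned bases map into [target_start, target_end)."""
    valid = np.flatnonzero(chain_truth >= 0)
    mapped = chain_truth[valid]
    lo = int(np.searchsorted(mapped, target_start, side="left"))
    hi = int(np.searchsorted(mapped, target_end, side="left"))
    if hi <= lo:
        raise ValueError("target span has no aligned source bases")
    return int(valid[lo]), int(valid[hi - 1]) + 1


def simulate_candidate_study(
    seed: int = 0,
    locus_length: int = 1_300_000,
    footprint: int = 2_000,
    fold_change: float = 3.0,
    mean_count: float = 2.0,
    dispersion: float = 0.1,
    n_fragments: int = 250_000,
) -> CandidateStudy:
    """A full locus study with a planted two-VR candidate topology.

    Twenty-five candidate REs are planted: 7 inside the distal variant
    region, 13 inside the proximal one (the two VR spans sit 136 kb apart)
    and 5 outside both.  Candidates cycle through the four evidence streams
    (SG4-responsive STARR element, Wnt-responsive STARR element, predicted
    enhancer, mouse orthologous region carried through a simulated indel
    chain), every fifth candidate carrying a second stream.  Six candidates
    per VR harbor a prioritized variant: sub-threshold satellites placed at
    candidate centres, plus one candidate reachable only through LD
    expansion from the proximal lead.  The truth records the planted per-VR
    candidate and variant-bearing counts that the integration stage must
    recover exactly.
    """
    rng = np.random.default_rng(seed)
    contig_h, contig_m = "chrH", "chrM"

    vr1_starts = [202_000 + 5_000 * i for i in range(7)]
    vr2_starts = [378_000 + 6_000 * i for i in range(13)]
    outside_starts = [600_000 + 8_000 * i for i in range(5)]
    all_starts = vr1_starts + vr2_starts + outside_starts
    streams = ("starr_sg4", "starr_wnt", "emerge", "ortholog")

    elements: list[PlantedElement] = []
    emerge_spans: list[tuple[int, int]] = []
    orth_target_spans: list[tuple[int, int]] = []
    planted: list[dict] = []
    for i, start in enumerate(all_starts):
        primary = streams[i % 4]
        flags = [primary]
        if i % 5 == 0:
            flags.append("emerge" if primary != "emerge" else "ortholog")
        span = (start, start + footprint)
        inner = (start + 800, start + 1200)
        for flag in flags:
            sub = span if flag == primary else inner
            if flag == "starr_sg4":
                elements.append(
                    PlantedElement(
                        GenomicInterval(contig_h, *sub), fc_sg4=fold_change
                    )
                )
            elif flag == "starr_wnt":
                elements.append(
                    PlantedElement(
                        GenomicInterval(contig_h, *sub), fc_wnt=fold_change
                    )
                )
            elif flag == "emerge":
                emerge_spans.append(sub)
            else:
                orth_target_spans.append(sub)
        planted.append({"span": span, "flags": flags})

    # STARR libraries over a BAC-tiled locus
    fragments, bac_layout = simulate_bac_library(
        locus_length=locus_length,
        n_fragments=n_fragments,
        seed=int(rng.integers(2**31)),
        contig=contig_h,
        genome_tag="simH",
    )
    libraries = simulate_starr_counts(
        fragments,
        elements,
        mean_count=mean_count,
        dispersion=dispersion,
        seed=int(rng.integers(2**31)),
    )

    # predicted-enhancer feature tracks: a clean indicator plus noise
    grid = make_bin_grid(contig_h, locus_length, 100)
    indicator = np.zeros(len(grid))
    for lo, hi in emerge_spans:
        indicator[lo // 100 : hi // 100] = 1.0
    noise_rng = np.random.default_rng(int(rng.integers(2**31)))
    tracks: dict[str, np.ndarray] = {"enhancer_mark": indicator}
    for k in range(4):
        tracks[f"noise_{k + 1}"] = noise_rng.standard_normal(len(grid))
    feature_matrix = FeatureMatrix(
        bins=grid,
        values=np.column_stack([tracks[n] for n in tracks]),
        dataset_names=list(tracks),
    )
    feature_labels = indicator.astype(np.int64)

    # mouse orthologous regions carried through an indel chain
    chain, chain_truth = simulate_chain(
        source_length=locus_length,
        n_indels=25,
        seed=int(rng.integers(2**31)),
        source_contig=contig_m,
        target_contig=contig_h,
    )
    mouse_regions = RegionSet(
        (
            GenomicInterval(contig_m, *_source_span_for_target(chain_truth, lo, hi))
            for lo, hi in orth_target_spans
        ),
        "simM",
    )

    # association study: two variant regions 136 kb apart
    vr1_bearing = list(range(0, 6))          # candidates 0-5 of VR1
    vr2_bearing_sub = list(range(0, 5))      # candidates 0-4 of VR2
    vr2_bearing_ld = 5                       # candidate 5 of VR2, LD-only
    vr1_spec = VrSpec(
        start=200_000,
        end=240_000,
        trait="PR|QRS",
        lead_pos=210_500,
        sub_positions=[vr1_starts[i] + 1_000 for i in vr1_bearing]
        + [200_500, 238_999],
        null_positions=[205_500, 230_500],
        linked_positions=[],
        n_linked=0,
    )
    vr2_spec = VrSpec(
        start=375_000,
        end=455_000,
        trait="PR",
        lead_pos=375_000,
        sub_positions=[vr2_starts[i] + 1_000 for i in vr2_bearing_sub]
        + [376_500, 454_200],
        null_positions=[382_500, 423_000],
        linked_positions=[vr2_starts[vr2_bearing_ld] + 1_000],
    )
    snps, haplotypes, association_truth = simulate_association_study(
        [vr1_spec, vr2_spec],
        seed=int(rng.integers(2**31)),
        contig=contig_h,
    )

    truth = {
        "planted_candidates": planted,
        "vr1_candidates": len(vr1_starts),
        "vr2_candidates": len(vr2_starts),
        "outside_candidates": len(outside_starts),
        "vr1_variant_bearing": len(vr1_bearing),
        "vr2_variant_bearing": len(vr2_bearing_sub) + 1,
        "vr_gap_bp": 375_000 - 239_000,  # realized span gap: 136 kb
    }
    return CandidateStudy(
        contig_human=contig_h,
        contig_mouse=contig_m,
        locus_length=locus_length,
        fragments=fragments,
        bac_layout=bac_layout,
        libraries=libraries,
        elements=elements,
        feature_matrix=feature_matrix,
        feature_labels=feature_labels,
        mouse_regions=mouse_regions,
        chain=chain,
        chain_truth=chain_truth,
        snps=snps,
        haplotypes=haplotypes,
        association_truth=association_truth,
        truth=truth,
    )
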