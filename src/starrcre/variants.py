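"""Trait-associated variant selection, LD expansion and variant regions.

Selection follows the GWAS sub-threshold rule: within loci marked by
genome-wide significant SNPs (p < 5e-8), all SNPs with p < 0.05 are taken
along, plus common variants in high LD (r^2 > 0.5) with the lead SNPs.
Selected SNPs are clustered into variant regions (VR1, VR2, ...) by
single-linkage on genomic distance.  The 21-bp variant window (the variant
nucleotide plus 10 bases either side) supports motif disruption/creation
checks on reference vs alternative alleles.

All inequalities are strict, matching their printed forms.  Positions are
1-based in association tables and converted to 0-based at the parser.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, RegionSet, merge_regions

__all__ = [
    "Snp",
    "HaplotypeMatrix",
    "VariantRegion",
    "read_association_table",
    "read_haplotype_matrix",
    "write_haplotype_matrix",
    "select_trait_snps",
    "compute_r2",
    "expand_by_ld",
    "define_variant_regions",
    "variant_window",
    "scan_variant_windows",
    "GW_THRESHOLD",
    "SUB_THRESHOLD",
    "R2_THRESHOLD",
    "DEFAULT_LOCUS_GAP",
    "VARIANT_WINDOW_FLANK",
]

GW_THRESHOLD = 5e-8
SUB_THRESHOLD = 0.05
R2_THRESHOLD = 0.5
#: loci anchored by genome-wide significant SNPs extend this many bp
DEFAULT_LOCUS_GAP = 100_000
#: bases either side of the variant nucleotide (21-bp window)
VARIANT_WINDOW_FLANK = 10


@dataclass(frozen=True)
class Snp:
    """One association record; ``pos`` is stored 0-based."""

    id: str
    contig: str
    pos: int
    ref_allele: str
    alt_allele: str
    p_value: float
    trait: str = ""
    r2_to_lead: float | None = None

    def __post_init__(self) -> None:
        if not (0 < self.p_value <= 1):
            raise ValueError(f"{self.id}: p_value must be in (0, 1]")
        if not self.ref_allele or not self.alt_allele:
            raise ValueError(f"{self.id}: alleles must be non-empty")


@dataclass
class HaplotypeMatrix:
    """Phased haplotypes (rows) x variant sites (columns), values in {0, 1}."""

    data: np.ndarray
    site_ids: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.int8)
        if self.data.ndim != 2:
            raise ValueError("haplotype matrix must be 2-D")
        if self.data.shape[1] != len(self.site_ids):
            raise ValueError("site_ids length must match matrix columns")
        if not np.isin(self.data, (0, 1)).all():
            raise ValueError("haplotype values must be 0/1 (pre-imputed, no missing)")
        self._index = {s: i for i, s in enumerate(self.site_ids)}

    def site_index(self, site: str | int) -> int:
        if isinstance(site, str):
            try:
                return self._index[site]
            except KeyError:
                raise KeyError(f"site {site!r} absent from haplotype matrix") from None
        return site

    @property
    def n_haplotypes(self) -> int:
        return self.data.shape[0]


@dataclass
class VariantRegion:
    """A cluster of selected SNPs spanning ``[min pos, max pos + 1)``."""

    interval: GenomicInterval
    traits: frozenset[str]
    snps: list[Snp]
    label: str


def read_association_table(path) -> list[Snp]:
    """Read a TSV of (id, chrom, pos, ref, alt, p, trait); pos is 1-based."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "id": str})
    required = {"id", "chrom", "pos", "ref", "alt", "p"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"association table missing columns: {sorted(missing)}")
    return [
        Snp(
            id=row.id,
            contig=row.chrom,
            pos=int(row.pos) - 1,
            ref_allele=row.ref,
            alt_allele=row.alt,
            p_value=float(row.p),
            trait=getattr(row, "trait", "") or "",
        )
        for row in df.itertuples(index=False)
    ]


def read_haplotype_matrix(path) -> HaplotypeMatrix:
    """Read a TSV of phased haplotypes (rows) x sites (header columns)."""
    df = pd.read_csv(path, sep="\t")
    return HaplotypeMatrix(data=df.to_numpy(), site_ids=list(df.columns))


def write_haplotype_matrix(h: HaplotypeMatrix, path) -> None:
    pd.DataFrame(h.data, columns=h.site_ids).to_csv(path, sep="\t", index=False)


def select_trait_snps(
    assoc: list[Snp],
    gw_threshold: float = GW_THRESHOLD,
    sub_threshold: float = SUB_THRESHOLD,
    locus_gap: int = DEFAULT_LOCUS_GAP,
) -> list[Snp]:
    """Sub-threshold SNP selection inside genome-wide significant loci.

    Loci are the merge (at ``max_gap=locus_gap``) of genome-wide significant
    SNP positions; any SNP with p < ``sub_threshold`` lying within
    ``locus_gap`` bp of a locus span is selected.  Genome-wide significant
    SNPs are always included.  No significant SNP means an empty selection.
    """
    if not (0 < gw_threshold <= sub_threshold < 1):
        raise ValueError("require 0 < gw_threshold <= sub_threshold < 1")
    leads = [s for s in assoc if s.p_value < gw_threshold]
    if not leads:
        return []
    loci = merge_regions(
        RegionSet(GenomicInterval(s.contig, s.pos, s.pos + 1) for s in leads),
        max_gap=locus_gap,
    )
    selected: list[Snp] = []
    for s in sorted(assoc, key=lambda x: (x.contig, x.pos, x.id)):
        if s.p_value >= sub_threshold:
            continue
        for locus in loci:
            if locus.contig != s.contig:
                continue
            if locus.start - locus_gap <= s.pos < locus.end + locus_gap:
                selected.append(s)
                break
    return selected


def compute_r2(
    h: HaplotypeMatrix, a: str | int, b: str | int
) -> float | None:
    """Squared LD correlation r^2 = D^2 / (pA(1-pA) pB(1-pB)) from phase.

    ``D = p_AB - p_A p_B`` with frequencies taken directly from haplotype
    counts.  A monomorphic site has undefined r^2: a warning is issued and
    ``None`` returned.
    """
    ia, ib = h.site_index(a), h.site_index(b)
    xa = h.data[:, ia].astype(float)
    xb = h.data[:, ib].astype(float)
    pa, pb = xa.mean(), xb.mean()
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        warnings.warn(
            f"r^2 undefined for monomorphic site pair ({a!r}, {b!r})",
            stacklevel=2,
        )
        return None
    pab = (xa * xb).mean()
    d = pab - pa * pb
    return float(d * d / (pa * (1 - pa) * pb * (1 - pb)))


def expand_by_ld(
    selected: list[Snp],
    lead_snps: list[Snp],
    h: HaplotypeMatrix,
    all_snps: list[Snp] | None = None,
    r2_threshold: float = R2_THRESHOLD,
) -> list[Snp]:
    """Union of the selection with all sites in high LD with any lead SNP.

    Every site of ``h`` with r^2 strictly above ``r2_threshold`` to a lead is
    added (record taken from ``all_snps`` when given, else a minimal record is
    synthesized from the matrix site id); ``r2_to_lead`` stores the maximum
    r^2 to any lead.  A lead absent from the matrix is an error naming it.
    """
    for lead in lead_snps:
        if lead.id not in h.site_ids:
            raise KeyError(f"lead SNP {lead.id!r} absent from haplotype matrix")
    catalogue = {s.id: s for s in (all_snps if all_snps is not None else selected)}
    for lead in lead_snps:
        catalogue.setdefault(lead.id, lead)
    out: dict[str, Snp] = {s.id: s for s in selected}
    for site in h.site_ids:
        best: float | None = None
        for lead in lead_snps:
            if site == lead.id:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                r2 = compute_r2(h, site, lead.id)
            if r2 is not None and (best is None or r2 > best):
                best = r2
        if best is not None and best > r2_threshold:
            base = catalogue.get(site)
            if base is None:
                continue  # site not in the association catalogue
            out[site] = Snp(
                id=base.id,
                contig=base.contig,
                pos=base.pos,
                ref_allele=base.ref_allele,
                alt_allele=base.alt_allele,
                p_value=base.p_value,
                trait=base.trait,
                r2_to_lead=best,
            )
    return sorted(out.values(), key=lambda s: (s.contig, s.pos, s.id))


def define_variant_regions(
    snps: list[Snp], max_gap: int
) -> list[VariantRegion]:
    """Single-linkage clustering of SNP positions into labelled VRs.

    SNPs on the same contig whose inter-SNP gap is <= ``max_gap`` join one
    region; the region span is ``[min pos, max pos + 1)`` and its trait set
    the union of member traits.  Labels VR1, VR2, ... follow genomic order.
    """
    if max_gap <= 0:
        raise ValueError("max_gap must be > 0")
    ordered = sorted(snps, key=lambda s: (s.contig, s.pos, s.id))
    clusters: list[list[Snp]] = []
    for s in ordered:
        if (
            clusters
            and clusters[-1][-1].contig == s.contig
            and s.pos - clusters[-1][-1].pos <= max_gap
        ):
            clusters[-1].append(s)
        else:
            clusters.append([s])
    out: list[VariantRegion] = []
    for i, members in enumerate(clusters, 1):
        lo = members[0].pos
        hi = members[-1].pos + 1
        out.append(
            VariantRegion(
                interval=GenomicInterval(members[0].contig, lo, hi, name=f"VR{i}"),
                traits=frozenset(m.trait for m in members if m.trait),
                snps=members,
                label=f"VR{i}",
            )
        )
    return out


def variant_window(
    sequence: str, pos: int, ref: str, alt: str, flank: int = VARIANT_WINDOW_FLANK
) -> tuple[str, str]:
    """Reference and alternative sequence windows centred on a variant.

    Returns the ``2*flank + 1`` bp window around position ``pos`` (0-based)
    for both alleles.  A window leaving the sequence bounds is an error, not
    a silent truncation.  Restricted to single-nucleotide variants.
    """
    if len(ref) != 1 or len(alt) != 1:
        raise ValueError("variant_window supports single-nucleotide variants only")
    if flank < 0:
        raise ValueError("flank must be >= 0")
    if pos - flank < 0 or pos + flank + 1 > len(sequence):
        raise ValueError(
            f"window [{pos - flank}, {pos + flank + 1}) exceeds sequence bounds "
            f"[0, {len(sequence)})"
        )
    observed = sequence[pos].upper()
    if observed != ref.upper():
        raise ValueError(
            f"reference mismatch at {pos}: sequence has {observed}, record says {ref}"
        )
    ref_win = sequence[pos - flank : pos + flank + 1].upper()
    alt_win = ref_win[:flank] + alt.upper() + ref_win[flank + 1 :]
    return ref_win, alt_win


@dataclass
class MotifChange:
    """Motifs matched in exactly one allele of a variant window."""

    variant_id: str
    lost: list[str]
    gained: list[str]


def scan_variant_windows(
    windows: list[tuple[str, str, str]],
    pwms,
    rel_score_threshold: float = 0.8,
) -> list[MotifChange]:
    """Per-variant motifs lost/gained between ref and alt windows.

    ``windows`` holds (variant_id, ref_window, alt_window) triples.  A motif
    counts as matched when any offset on either strand reaches the relative
    log-odds score threshold.  Motifs matched in the reference window only
    are reported lost, in the alternative window only gained.
    """
    from .motifs import scan_sequence

    out: list[MotifChange] = []
    for vid, ref_win, alt_win in windows:
        lost: list[str] = []
        gained: list[str] = []
        for pwm in pwms:
            if pwm.width > len(ref_win):
                continue
            in_ref = bool(scan_sequence(pwm, ref_win, rel_score_threshold))
            in_alt = bool(scan_sequence(pwm, alt_win, rel_score_threshold))
            if in_ref and not in_alt:
                lost.append(pwm.name)
            elif in_alt and not in_ref:
                gained.append(pwm.name)
        out.append(MotifChange(variant_id=vid, lost=lost, gained=gained))
    return out
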