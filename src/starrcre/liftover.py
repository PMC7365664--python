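"""Cross-assembly coordinate translation through UCSC chain alignments.

A chain is an ordered list of gapless aligned blocks between a source and a
target assembly.  Intervals are mapped through the single highest-scoring
overlapping chain (liftOver's default single-mapping behavior): every source
base inside an aligned block is translated to its target offset and the
target interval spans min..max of the translated bases, absorbing unaligned
gaps internal to the span.  Regions, not alignments, are the downstream
currency.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .intervals import GenomicInterval, RegionSet

__all__ = [
    "ChainAlignment",
    "MappedRegion",
    "parse_chain",
    "format_chain",
    "invert_chain",
    "map_interval",
    "map_region_set",
]


@dataclass
class ChainAlignment:
    """One UCSC chain: header coordinates plus (size, source_gap, target_gap)
    block triples.  The final block has both gaps equal to 0.

    Coordinates follow the chain format: ``target_start/end`` are given on
    ``target_strand``; for a ``-`` strand chain they count from the end of the
    target contig.  Source strand is always ``+``.
    """

    score: float
    source_name: str
    source_size: int
    source_strand: str
    source_start: int
    source_end: int
    target_name: str
    target_size: int
    target_strand: str
    target_start: int
    target_end: int
    blocks: list[tuple[int, int, int]]
    chain_id: int = 0

    def __post_init__(self) -> None:
        if self.source_strand != "+":
            raise ValueError(f"chain {self.chain_id}: source strand must be '+'")
        if self.target_strand not in "+-":
            raise ValueError(f"chain {self.chain_id}: bad target strand")
        if not self.blocks:
            raise ValueError(f"chain {self.chain_id}: no blocks")
        for size, sgap, tgap in self.blocks:
            if size <= 0 or sgap < 0 or tgap < 0:
                raise ValueError(
                    f"chain {self.chain_id}: block sizes must be > 0, gaps >= 0"
                )
        if self.blocks[-1][1] != 0 or self.blocks[-1][2] != 0:
            raise ValueError(f"chain {self.chain_id}: final block must have no gaps")
        s_span = sum(size + sgap for size, sgap, _ in self.blocks)
        t_span = sum(size + tgap for size, _, tgap in self.blocks)
        if s_span != self.source_end - self.source_start:
            raise ValueError(
                f"chain {self.chain_id}: blocks cover {s_span} source bp, "
                f"header spans {self.source_end - self.source_start}"
            )
        if t_span != self.target_end - self.target_start:
            raise ValueError(
                f"chain {self.chain_id}: blocks cover {t_span} target bp, "
                f"header spans {self.target_end - self.target_start}"
            )


@dataclass
class MappedRegion:
    """Result of translating one interval: target span (or absent) plus the
    fraction of source bases that fell inside aligned blocks."""

    source: GenomicInterval
    target: GenomicInterval | None
    mapped_fraction: float
    chain_id: int | None


def parse_chain(text: str) -> list[ChainAlignment]:
    """Parse chain-format text; block-sum invariants are verified per chain."""
    chains: list[ChainAlignment] = []
    lines = iter(text.splitlines())
    for line in lines:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if not line.startswith("chain"):
            raise ValueError(f"expected chain header, got {line!r}")
        fields = line.split()
        if len(fields) != 13:
            raise ValueError(f"malformed chain header: {line!r}")
        (
            _,
            score,
            s_name,
            s_size,
            s_strand,
            s_start,
            s_end,
            t_name,
            t_size,
            t_strand,
            t_start,
            t_end,
            chain_id,
        ) = fields
        blocks: list[tuple[int, int, int]] = []
        for bline in lines:
            bline = bline.strip()
            if not bline:
                break
            parts = [int(x) for x in bline.split()]
            if len(parts) == 3:
                blocks.append((parts[0], parts[1], parts[2]))
            elif len(parts) == 1:
                blocks.append((parts[0], 0, 0))
                break
            else:
                raise ValueError(f"malformed chain block line: {bline!r}")
        chains.append(
            ChainAlignment(
                score=float(score),
                source_name=s_name,
                source_size=int(s_size),
                source_strand=s_strand,
                source_start=int(s_start),
                source_end=int(s_end),
                target_name=t_name,
                target_size=int(t_size),
                target_strand=t_strand,
                target_start=int(t_start),
                target_end=int(t_end),
                blocks=blocks,
                chain_id=int(chain_id),
            )
        )
    return chains


def format_chain(chains: Iterable[ChainAlignment]) -> str:
    """Serialize chains back to the chain format (inverse of parse_chain)."""
    parts: list[str] = []
    for ch in chains:
        score = int(ch.score) if float(ch.score).is_integer() else ch.score
        parts.append(
            f"chain {score} {ch.source_name} {ch.source_size} {ch.source_strand} "
            f"{ch.source_start} {ch.source_end} {ch.target_name} {ch.target_size} "
            f"{ch.target_strand} {ch.target_start} {ch.target_end} {ch.chain_id}"
        )
        for size, sgap, tgap in ch.blocks[:-1]:
            parts.append(f"{size} {sgap} {tgap}")
        parts.append(f"{ch.blocks[-1][0]}")
        parts.append("")
    return "\n".join(parts) + "\n"


def invert_chain(chain: ChainAlignment) -> ChainAlignment:
    """Swap source and target of a forward-strand chain."""
    if chain.target_strand != "+":
        raise ValueError("only forward-strand chains can be inverted directly")
    return ChainAlignment(
        score=chain.score,
        source_name=chain.target_name,
        source_size=chain.target_size,
        source_strand="+",
        source_start=chain.target_start,
        source_end=chain.target_end,
        target_name=chain.source_name,
        target_size=chain.source_size,
        target_strand="+",
        target_start=chain.source_start,
        target_end=chain.source_end,
        blocks=[(size, tgap, sgap) for size, sgap, tgap in chain.blocks],
        chain_id=chain.chain_id,
    )


def _mapped_chunks(
    chain: ChainAlignment, iv: GenomicInterval
) -> list[tuple[int, int]]:
    """Forward-strand target spans of the aligned pieces of ``iv``."""
    chunks: list[tuple[int, int]] = []
    s = chain.source_start
    t = chain.target_start
    for size, sgap, tgap in chain.blocks:
        a = max(iv.start, s)
        b = min(iv.end, s + size)
        if a < b:
            lo = t + (a - s)
            hi = t + (b - s)
            if chain.target_strand == "+":
                chunks.append((lo, hi))
            else:
                # reverse-strand coordinates -> forward strand
                chunks.append((chain.target_size - hi, chain.target_size - lo))
        s += size + sgap
        t += size + tgap
        if s >= iv.end:
            break
    return chunks


def map_interval(
    iv: GenomicInterval,
    chains: Sequence[ChainAlignment],
    min_mapped_fraction: float = 0.1,
) -> MappedRegion:
    """Translate one interval through the best overlapping chain.

    The highest-scoring chain whose source span overlaps ``iv`` is selected;
    with no overlapping chain the target is absent and the fraction 0.  A
    reverse-strand chain yields forward-strand target coordinates with the
    base order reversed.  Targets mapping less than ``min_mapped_fraction``
    of the source bases are reported absent (fraction still recorded).
    """
    if not 0 < min_mapped_fraction <= 1:
        raise ValueError("min_mapped_fraction must be in (0, 1]")
    best: ChainAlignment | None = None
    for ch in chains:
        if ch.source_name != iv.contig:
            continue
        if ch.source_end <= iv.start or ch.source_start >= iv.end:
            continue
        if best is None or ch.score > best.score:
            best = ch
    if best is None:
        return MappedRegion(source=iv, target=None, mapped_fraction=0.0, chain_id=None)
    chunks = _mapped_chunks(best, iv)
    mapped_bp = sum(hi - lo for lo, hi in chunks)
    fraction = mapped_bp / iv.length
    if not chunks or fraction < min_mapped_fraction:
        return MappedRegion(
            source=iv, target=None, mapped_fraction=fraction, chain_id=best.chain_id
        )
    lo = min(c[0] for c in chunks)
    hi = max(c[1] for c in chunks)
    target = GenomicInterval(
        best.target_name, lo, hi, name=iv.name, score=iv.score, strand=iv.strand
    )
    return MappedRegion(
        source=iv, target=target, mapped_fraction=fraction, chain_id=best.chain_id
    )


@dataclass
class MappingReport:
    n_input: int
    n_mapped: int
    n_unmapped: int
    records: list[MappedRegion]


def map_region_set(
    rs: RegionSet,
    chains: Sequence[ChainAlignment],
    min_mapped_fraction: float = 0.1,
    target_genome_tag: str = "",
) -> tuple[RegionSet, MappingReport]:
    """Vectorized :func:`map_interval` over a region set, with a report."""
    records = [map_interval(iv, chains, min_mapped_fraction) for iv in rs]
    mapped = [r.target for r in records if r.target is not None]
    report = MappingReport(
        n_input=len(rs),
        n_mapped=len(mapped),
        n_unmapped=len(rs) - len(mapped),
        records=records,
    )
    return RegionSet(mapped, target_genome_tag), report
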