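"""PWM scanning and set-vs-set motif enrichment.

Position frequency matrices (JASPAR dialects) are normalized to probability
matrices with a background-distributed pseudocount, scored as log2 odds
against the background, and matched by relative score: the score rescaled
to [0, 1] between the matrix's minimum and maximum attainable log-odds.
Enrichment between a target and a background sequence set is per-sequence
presence/absence with a one-sided hypergeometric tail and Benjamini-Hochberg
correction across motifs; both sets can be subsampled to equal size with a
seeded generator, mirroring equal-n comparisons between region sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "Pwm",
    "EnrichmentResult",
    "read_jaspar",
    "log_odds_score",
    "relative_score",
    "scan_sequence",
    "enrichment_test",
    "DEFAULT_REL_SCORE_THRESHOLD",
    "DEFAULT_PSEUDOCOUNT",
]

DEFAULT_REL_SCORE_THRESHOLD = 0.8
#: distributed by background when normalizing count matrices
DEFAULT_PSEUDOCOUNT = 0.8

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class Pwm:
    """A probability matrix (rows A, C, G, T) with its background."""

    name: str
    probs: np.ndarray
    background: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.shape[0] != 4 or self.probs.shape[1] < 1:
            raise ValueError(f"{self.name}: matrix must be 4 x width, width >= 1")
        if not np.allclose(self.probs.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError(f"{self.name}: columns must sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-9):
            raise ValueError(f"{self.name}: background must sum to 1")
        self.log_odds = np.log2(self.probs / self.background[:, None])
        self.min_score = float(self.log_odds.min(axis=0).sum())
        self.max_score = float(self.log_odds.max(axis=0).sum())

    @property
    def width(self) -> int:
        return self.probs.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.probs.argmax(axis=0))

    @classmethod
    def from_counts(
        cls,
        name: str,
        counts: np.ndarray,
        pseudocount: float = DEFAULT_PSEUDOCOUNT,
        background: np.ndarray | None = None,
    ) -> "Pwm":
        """Normalize a 4 x width count (or frequency) matrix.

        The pseudocount is distributed over bases proportionally to the
        background before normalization, the common practice for JASPAR
        count matrices.
        """
        counts = np.asarray(counts, dtype=float)
        bg = (
            np.full(4, 0.25) if background is None else np.asarray(background, float)
        )
        padded = counts + pseudocount * bg[:, None]
        return cls(name=name, probs=padded / padded.sum(axis=0), background=bg)


def read_jaspar(path, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> list[Pwm]:
    """Read JASPAR-format PFMs (header or raw 4-line dialects)."""
    from Bio import motifs as bio_motifs

    with open(path) as fh:
        text = fh.read()
    fmt = "jaspar" if ">" in text else "pfm"
    import io

    records = bio_motifs.parse(io.StringIO(text), fmt)
    out: list[Pwm] = []
    for i, m in enumerate(records):
        counts = np.array([m.counts[b] for b in _BASES], dtype=float)
        name = m.name or (m.matrix_id if getattr(m, "matrix_id", None) else f"motif_{i + 1}")
        out.append(Pwm.from_counts(str(name), counts, pseudocount=pseudocount))
    return out


def _encode(seq: str) -> np.ndarray:
    """Map a sequence to base indices; non-ACGT (incl. N) become -1."""
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    lookup = np.full(256, -1, dtype=np.int64)
    for b, i in _BASE_INDEX.items():
        lookup[ord(b)] = i
    return lookup[arr]


def log_odds_score(pwm: Pwm, kmer: str) -> float:
    """Sum of per-position log2(p / background); N contributes 0."""
    if len(kmer) != pwm.width:
        raise ValueError(
            f"kmer length {len(kmer)} != motif width {pwm.width} ({pwm.name})"
        )
    idx = _encode(kmer)
    cols = np.arange(pwm.width)
    valid = idx >= 0
    return float(pwm.log_odds[idx[valid], cols[valid]].sum())


def relative_score(pwm: Pwm, score: float) -> float:
    """Score rescaled to [0, 1] over the matrix's attainable log-odds range."""
    rng = pwm.max_score - pwm.min_score
    if rng <= 0:
        return 1.0
    return (score - pwm.min_score) / rng


@dataclass(frozen=True)
class MotifHit:
    offset: int
    strand: str
    score: float
    rel_score: float


def _scan_strand(pwm: Pwm, idx: np.ndarray) -> np.ndarray:
    """Raw log-odds score at every offset of an encoded sequence."""
    n = len(idx) - pwm.width + 1
    if n <= 0:
        return np.empty(0)
    scores = np.zeros(n)
    for j in range(pwm.width):
        col_idx = idx[j : j + n]
        valid = col_idx >= 0
        contrib = np.zeros(n)
        contrib[valid] = pwm.log_odds[col_idx[valid], j]
        scores += contrib
    return scores


def scan_sequence(
    pwm: Pwm, seq: str, rel_score_threshold: float = DEFAULT_REL_SCORE_THRESHOLD
) -> list[MotifHit]:
    """All offsets on either strand reaching the relative-score threshold.

    Reverse-strand hits are reported at their forward-strand offset.
    """
    if not 0 < rel_score_threshold <= 1:
        raise ValueError("rel_score_threshold must be in (0, 1]")
    hits: list[MotifHit] = []
    fwd = _encode(seq)
    rev = _encode(seq.upper().translate(_COMPLEMENT)[::-1])
    for strand, idx in (("+", fwd), ("-", rev)):
        scores = _scan_strand(pwm, idx)
        for off in np.flatnonzero(
            (scores - pwm.min_score)
            >= rel_score_threshold * (pwm.max_score - pwm.min_score)
        ):
            off = int(off)
            fwd_off = off if strand == "+" else len(seq) - pwm.width - off
            score = float(scores[off])
            hits.append(
                MotifHit(
                    offset=fwd_off,
                    strand=strand,
                    score=score,
                    rel_score=relative_score(pwm, score),
                )
            )
    return sorted(hits, key=lambda h: (h.offset, h.strand))


@dataclass
class EnrichmentResult:
    """Per-motif presence/absence enrichment of target over background."""

    motif: str
    target_hits: int
    target_n: int
    background_hits: int
    background_n: int
    p_value: float
    q_value: float
    log2_enrichment: float


def enrichment_test(
    target_seqs: list[str],
    background_seqs: list[str],
    pwms: list[Pwm],
    seed: int | None = None,
    subsample_to_equal_n: bool = False,
    rel_score_threshold: float = DEFAULT_REL_SCORE_THRESHOLD,
) -> list[EnrichmentResult]:
    """Motif enrichment of a target set against a background set.

    Per motif, the number of target sequences with at least one hit is
    tested against the pooled hit total with a one-sided hypergeometric
    tail; q-values are Benjamini-Hochberg across motifs.  With
    ``subsample_to_equal_n`` both sets are first reduced to the smaller
    size using the seeded generator (bit-reproducible).  Results are sorted
    by (q, p).
    """
    if not target_seqs or not background_seqs:
        raise ValueError("both sequence sets must be non-empty")

    def clean(seqs: list[str], label: str) -> list[str]:
        kept = [s for s in seqs if len(s) > 0]
        if len(kept) < len(seqs):
            warnings.warn(
                f"skipped {len(seqs) - len(kept)} zero-length {label} sequences",
                stacklevel=2,
            )
        return kept

    targets = clean(target_seqs, "target")
    background = clean(background_seqs, "background")
    if subsample_to_equal_n:
        rng = np.random.default_rng(seed)
        n = min(len(targets), len(background))
        targets = [targets[i] for i in sorted(rng.choice(len(targets), n, replace=False))]
        background = [
            background[i] for i in sorted(rng.choice(len(background), n, replace=False))
        ]
    n_t, n_b = len(targets), len(background)
    results: list[EnrichmentResult] = []
    for pwm in pwms:
        k_t = sum(bool(scan_sequence(pwm, s, rel_score_threshold)) for s in targets)
        k_b = sum(bool(scan_sequence(pwm, s, rel_score_threshold)) for s in background)
        p = float(hypergeom.sf(k_t - 1, n_t + n_b, k_t + k_b, n_t))
        log2_enr = float(
            np.log2(((k_t + 0.5) / (n_t + 1)) / ((k_b + 0.5) / (n_b + 1)))
        )
        results.append(
            EnrichmentResult(
                motif=pwm.name,
                target_hits=k_t,
                target_n=n_t,
                background_hits=k_b,
                background_n=n_b,
                p_value=p,
                q_value=np.nan,
                log2_enrichment=log2_enr,
            )
        )
    if results:
        qs = multipletests([r.p_value for r in results], method="fdr_bh")[1]
        for r, q in zip(results, qs):
            r.q_value = float(q)
    return sorted(results, key=lambda r: (r.q_value, r.p_value, r.motif))
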