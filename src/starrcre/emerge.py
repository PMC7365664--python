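"""EMERGE-style enhancer prediction.

Many functional-genomic datasets (histone-mark ChIP, accessibility, TF
binding) are summarized onto a common bin grid, a logistic regression with
L2 penalty is trained on bins labelled by validated enhancers, and the
fitted per-dataset weights yield a per-bin enhancer probability track from
which candidate regions are thresholded.  The mechanism, not any published
weight set, is the deliverable: bin width, regularization strength and
summarization are explicit parameters with plain defaults (100-bp bins,
L2 strength 1.0, mean-signal summarization).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression

from .activity import call_threshold_regions
from .intervals import GenomicInterval, RegionSet

__all__ = [
    "FeatureMatrix",
    "EnhancerModel",
    "make_bin_grid",
    "build_feature_matrix",
    "label_bins",
    "train_model",
    "predict_track",
    "call_predicted_enhancers",
    "DEFAULT_BIN_SIZE",
    "DEFAULT_L2_STRENGTH",
    "DEFAULT_NEGATIVE_RATIO",
]

DEFAULT_BIN_SIZE = 100
DEFAULT_L2_STRENGTH = 1.0
#: random unlabeled bins drawn as negatives per positive bin
DEFAULT_NEGATIVE_RATIO = 10


@dataclass
class FeatureMatrix:
    """Bins x datasets matrix of per-bin summarized signal (absent = 0)."""

    bins: list[GenomicInterval]
    values: np.ndarray
    dataset_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.bins), len(self.dataset_names)):
            raise ValueError("values must be n_bins x n_datasets")
        widths = {iv.length for iv in self.bins}
        if len(widths) > 1:
            raise ValueError("all bins must share one width")
        if np.isnan(self.values).any():
            raise ValueError("feature matrix must have no missing values")

    @property
    def bin_size(self) -> int:
        return self.bins[0].length if self.bins else 0


@dataclass
class EnhancerModel:
    """Per-dataset logistic weights plus intercept and training metadata."""

    weights: np.ndarray
    intercept: float
    dataset_names: list[str]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.weights) != len(self.dataset_names):
            raise ValueError("one weight per dataset required")

    def to_json(self) -> str:
        return json.dumps(
            {
                "weights": self.weights.tolist(),
                "intercept": self.intercept,
                "dataset_names": self.dataset_names,
                "metadata": self.metadata,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "EnhancerModel":
        obj = json.loads(text)
        return cls(
            weights=np.asarray(obj["weights"]),
            intercept=float(obj["intercept"]),
            dataset_names=list(obj["dataset_names"]),
            metadata=obj.get("metadata", {}),
        )


def make_bin_grid(
    contig: str, length_bp: int, bin_size: int = DEFAULT_BIN_SIZE
) -> list[GenomicInterval]:
    """A contiguous fixed-width bin grid covering ``[0, length_bp)``."""
    n = length_bp // bin_size
    return [
        GenomicInterval(contig, i * bin_size, (i + 1) * bin_size) for i in range(n)
    ]


def build_feature_matrix(
    tracks: dict[str, "RegionSet | np.ndarray | dict[str, np.ndarray]"],
    bins: list[GenomicInterval],
) -> FeatureMatrix:
    """Summarize heterogeneous inputs onto a shared bin grid.

    Region-set inputs become 0/1 overlap indicators per bin; per-bin arrays
    must match the grid length; per-base arrays (dict contig -> signal) are
    averaged over each bin span.
    """
    n = len(bins)
    names = list(tracks)
    values = np.zeros((n, len(names)))
    for j, name in enumerate(names):
        track = tracks[name]
        if isinstance(track, RegionSet):
            by_contig: dict[str, list[GenomicInterval]] = {}
            for iv in track:
                by_contig.setdefault(iv.contig, []).append(iv)
            for i, b in enumerate(bins):
                values[i, j] = float(
                    any(b.overlap_bp(iv) > 0 for iv in by_contig.get(b.contig, ()))
                )
        elif isinstance(track, dict):
            for i, b in enumerate(bins):
                sig = track.get(b.contig)
                if sig is None or b.start >= len(sig):
                    continue
                chunk = np.asarray(sig[b.start : b.end], dtype=float)
                if len(chunk):
                    values[i, j] = chunk.mean()
        else:
            arr = np.asarray(track, dtype=float)
            if len(arr) != n:
                raise ValueError(
                    f"per-bin track {name!r} has {len(arr)} bins, grid has {n}"
                )
            values[:, j] = arr
    return FeatureMatrix(bins=bins, values=values, dataset_names=names)


def label_bins(
    bins: list[GenomicInterval],
    enhancers: RegionSet,
    negative_ratio: int = DEFAULT_NEGATIVE_RATIO,
    seed: int = 0,
) -> np.ndarray:
    """Training labels: 1 on enhancer-overlapping bins, 0 on a seeded random
    sample of non-overlapping bins (``negative_ratio`` per positive), -1
    (unlabeled) elsewhere."""
    by_contig: dict[str, list[GenomicInterval]] = {}
    for iv in enhancers:
        by_contig.setdefault(iv.contig, []).append(iv)
    labels = np.full(len(bins), -1, dtype=np.int64)
    for i, b in enumerate(bins):
        if any(b.overlap_bp(iv) > 0 for iv in by_contig.get(b.contig, ())):
            labels[i] = 1
    n_pos = int((labels == 1).sum())
    candidates = np.flatnonzero(labels == -1)
    rng = np.random.default_rng(seed)
    n_neg = min(len(candidates), negative_ratio * n_pos)
    labels[rng.choice(candidates, n_neg, replace=False)] = 0
    return labels


def train_model(
    fm: FeatureMatrix,
    labels: np.ndarray,
    l2_strength: float = DEFAULT_L2_STRENGTH,
    seed: int = 0,
) -> EnhancerModel:
    """Fit L2-penalized logistic regression on the labelled bins.

    ``labels`` holds {0, 1} on labelled bins and -1 on unlabeled bins, which
    are excluded from the fit.  Both classes must be present.  The fit is
    deterministic given the data and seed.
    """
    labels = np.asarray(labels)
    mask = labels >= 0
    y = labels[mask]
    if len(np.unique(y)) < 2:
        raise ValueError("training labels must contain both classes")
    if l2_strength <= 0:
        raise ValueError("l2_strength must be > 0")
    clf = LogisticRegression(
        C=1.0 / l2_strength,
        solver="lbfgs",
        max_iter=2000,
        random_state=seed,
    )
    clf.fit(fm.values[mask], y)
    return EnhancerModel(
        weights=clf.coef_[0],
        intercept=float(clf.intercept_[0]),
        dataset_names=list(fm.dataset_names),
        metadata={
            "l2_strength": l2_strength,
            "seed": seed,
            "n_positive": int((y == 1).sum()),
            "n_negative": int((y == 0).sum()),
            "bin_size": fm.bin_size,
        },
    )


def predict_track(model: EnhancerModel, fm: FeatureMatrix) -> np.ndarray:
    """Per-bin enhancer probability: sigmoid of the linear score."""
    if list(fm.dataset_names) != list(model.dataset_names):
        raise ValueError(
            "feature matrix dataset names do not match the model "
            f"({fm.dataset_names} vs {model.dataset_names})"
        )
    score = fm.values @ model.weights + model.intercept
    return 1.0 / (1.0 + np.exp(-score))


def call_predicted_enhancers(
    track: np.ndarray,
    threshold: float,
    bins: list[GenomicInterval],
    genome_tag: str = "",
) -> RegionSet:
    """Merge contiguous above-threshold bins into candidate regions."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    track = np.asarray(track)
    if len(track) != len(bins):
        raise ValueError("track length must match bin grid")
    # group by contig; the grid is contiguous per contig
    out: list[GenomicInterval] = []
    i = 0
    while i < len(bins):
        contig = bins[i].contig
        j = i
        while j < len(bins) and bins[j].contig == contig:
            j += 1
        rs = call_threshold_regions(
            track[i:j], threshold, bin_size=bins[i].length, contig=contig
        )
        shift = bins[i].start
        for iv in rs:
            out.append(GenomicInterval(contig, iv.start + shift, iv.end + shift))
        i = j
    return RegionSet(out, genome_tag)
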