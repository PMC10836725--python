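"""Screen readout analysis and design inversion.

Implements the readout chain of a pooled antigen screen: Overton
percent-positive from matched flow histograms, GFP-positive area from
background-subtracted intensity matrices, per-well Z-scores over the
experiment, geometric-mean aggregation of technical replicates, positive
well calling, and deconvolution of positive wells back to candidate
targets via the pooled design's well signatures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import (
    DegenerateExperimentError,
    InvalidInputError,
    OffsetTooSmallError,
)
from .pools import PoolDesign


# ---------------------------------------------------------------------------
# Overton percent positive
# ---------------------------------------------------------------------------

@dataclass
class HistogramPair:
    """Sample and control histograms on identical binning."""

    bin_edges: np.ndarray
    sample_counts: np.ndarray
    control_counts: np.ndarray

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.sample_counts = np.asarray(self.sample_counts)
        self.control_counts = np.asarray(self.control_counts)
        nbins = len(self.bin_edges) - 1
        if nbins < 1 or np.any(np.diff(self.bin_edges) <= 0):
            raise InvalidInputError("bin_edges must be ascending with >= 2 edges")
        if self.sample_counts.shape != (nbins,) or self.control_counts.shape != (nbins,):
            raise InvalidInputError(
                "sample/control counts must both have length len(bin_edges) - 1"
            )
        if np.any(self.sample_counts < 0) or np.any(self.control_counts < 0):
            raise InvalidInputError("histogram counts must be non-negative")
        if self.sample_counts.sum() == 0 or self.control_counts.sum() == 0:
            raise InvalidInputError("sample and control must each have total counts > 0")

    @classmethod
    def from_events(
        cls, sample: np.ndarray, control: np.ndarray, bins: int = 256
    ) -> "HistogramPair":
        """Bin raw events on shared equal-width bins over the pooled range."""
        sample = np.asarray(sample, dtype=float)
        control = np.asarray(control, dtype=float)
        if sample.size == 0 or control.size == 0:
            raise InvalidInputError("sample and control events must be non-empty")
        pooled = np.concatenate([sample, control])
        lo, hi = pooled.min(), pooled.max()
        if lo == hi:  # all events identical; make a non-degenerate bin
            lo, hi = lo - 0.5, hi + 0.5
        edges = np.linspace(lo, hi, bins + 1)
        s, _ = np.histogram(sample, bins=edges)
        c, _ = np.histogram(control, bins=edges)
        return cls(edges, s, c)


def overton_percent_positive(h: HistogramPair) -> float:
    """Percent of sample events not accounted for by the control histogram.

    Classic population-comparison (Overton) subtraction on shared binning:
    normalize each histogram to unit mass and integrate the positive part
    of the per-bin difference, times 100.  Identical distributions give 0;
    disjoint supports give 100.
    """
    s = h.sample_counts / h.sample_counts.sum()
    c = h.control_counts / h.control_counts.sum()
    return float(100.0 * np.clip(s - c, 0.0, None).sum())


# ---------------------------------------------------------------------------
# GFP-positive area
# ---------------------------------------------------------------------------

def gfp_positive_area(image: np.ndarray, background: float, threshold: float) -> float:
    """Fraction of pixels whose background-subtracted intensity (floored at
    zero) reaches ``threshold``."""
    if threshold <= 0:
        raise InvalidInputError("threshold must be > 0")
    image = np.asarray(image, dtype=float)
    if image.size == 0:
        raise InvalidInputError("empty image")
    if np.any(image < 0):
        raise InvalidInputError("intensities must be non-negative")
    corrected = np.clip(image - background, 0.0, None)
    return float(np.mean(corrected >= threshold))


# ---------------------------------------------------------------------------
# Z-scores, aggregation, calling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WellReadout:
    """One measured assay well: pool index, technical replicate, signal."""

    pool_index: int
    replicate: int
    signal: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.signal) or self.signal < 0:
            raise InvalidInputError(
                f"signal must be finite and non-negative, got {self.signal}"
            )


def well_zscores(readouts: Sequence[WellReadout]) -> dict[tuple[int, int], float]:
    """Z-score each well against the distribution of all wells in the
    experiment (population SD)."""
    if len(readouts) < 3:
        raise InvalidInputError("need >= 3 wells to standardize an experiment")
    values = np.array([r.signal for r in readouts], dtype=float)
    sd = values.std()  # population SD over all wells of the experiment
    if sd == 0:
        raise DegenerateExperimentError("all wells identical; Z-scores undefined")
    mean = values.mean()
    return {(r.pool_index, r.replicate): float((r.signal - mean) / sd) for r in readouts}


def aggregate_replicates(
    z_by_well: Mapping[tuple[int, int], float], offset: float = 10.0
) -> dict[int, float]:
    """Aggregate technical replicates by offset geometric mean.

    Z-scores can be negative, so the geometric mean is taken on
    ``z + offset`` and the offset subtracted afterwards; single replicates
    pass through unchanged.
    """
    from scipy.stats import gmean

    pools: dict[int, list[float]] = {}
    for (pool, _rep), z in z_by_well.items():
        pools.setdefault(pool, []).append(z)
    counts = {len(v) for v in pools.values()}
    if len(counts) > 1:
        raise InvalidInputError(
            f"unequal replicate counts across pools: {sorted(counts)}"
        )
    scores: dict[int, float] = {}
    for pool, zs in pools.items():
        shifted = np.asarray(zs, dtype=float) + offset
        if np.any(shifted <= 0):
            raise OffsetTooSmallError(
                f"offset {offset} leaves non-positive values for pool {pool}; "
                f"min z = {min(zs)}"
            )
        scores[pool] = float(gmean(shifted) - offset)
    return scores


def call_positive_wells(
    score_by_pool: Mapping[int, float], z_threshold: float = 3.0
) -> set[int]:
    """Pools whose aggregated score reaches the threshold."""
    return {pool for pool, s in score_by_pool.items() if s >= z_threshold}


# ---------------------------------------------------------------------------
# Deconvolution
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Candidate:
    """A target scored against the positive-well pattern.

    ``support`` is the fraction of the target's signature wells that read
    positive; ``extra_positives`` counts positive wells outside the
    signature; ``exact`` marks full-signature support.
    """

    target_id: int
    support: float
    exact: bool
    extra_positives: int


@dataclass
class ScreenResult:
    """Full analysis output for one screened TCR."""

    z_by_well: dict[tuple[int, int], float]
    score_by_pool: dict[int, float]
    positive_pools: set[int]
    candidates: list[Candidate] = field(default_factory=list)


def deconvolute(design: PoolDesign, positive_pools: Iterable[int]) -> list[Candidate]:
    """Invert the pooled design: rank targets by signature support.

    Support = |signature ∩ positives| / |signature|.  Ranking is by support
    descending, then fewer positive wells outside the signature, then
    target id; support == 1 is flagged exact.  Several exact candidates can
    coexist only when the positives are a union of signatures (a multi-hit
    screen).  An empty positive set yields an empty candidate list.
    """
    positives = set(positive_pools)
    if not positives:
        return []
    candidates = []
    for t, sig in enumerate(design.signatures()):
        if not sig:
            continue
        hit = len(sig & positives)
        support = hit / len(sig)
        candidates.append(
            Candidate(
                target_id=t,
                support=support,
                exact=(hit == len(sig)),
                extra_positives=len(positives - sig),
            )
        )
    candidates.sort(key=lambda c: (-c.support, c.extra_positives, c.target_id))
    return candidates


def analyze_screen(
    design: PoolDesign,
    readouts: Sequence[WellReadout],
    z_threshold: float = 3.0,
    offset: float = 10.0,
) -> ScreenResult:
    """Run the full chain: Z-scores -> replicate geometric means ->
    positive-well calls -> deconvoluted, ranked candidates."""
    z = well_zscores(readouts)
    scores = aggregate_replicates(z, offset=offset)
    positives = call_positive_wells(scores, z_threshold=z_threshold)
    return ScreenResult(
        z_by_well=z,
        score_by_pool=scores,
        positive_pools=positives,
        candidates=deconvolute(design, positives),
    )
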