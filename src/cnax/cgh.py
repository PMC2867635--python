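"""Pooled aCGH analysis: normalization, CBS segmentation, gain/loss calling.

The analysis chain mirrors a pooled tumor-vs-normal two-color CGH design run
in technical triplicate: median normalization per replicate, replicate
averaging, per-chromosome circular binary segmentation (CBS), a gain/loss
cutoff derived as one SD of the probe variation pooled over all arrays, and
per-stage alteration summaries (kb gained/lost per chromosome, percent of
genome altered, chromosome alteration-event counts).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import _cbs
from .genome import GenomeBuild, GenomicInterval

__all__ = [
    "Segment",
    "SegmentCall",
    "CallParams",
    "StageAlterationSummary",
    "CBSSegmenter",
    "median_normalize",
    "average_replicates",
    "cbs_segment",
    "segment_stage",
    "derive_call_cutoff",
    "segment_mean_percentiles",
    "call_segments",
    "summarize_alterations",
    "round_half_away",
]

GAIN = "gain"
LOSS = "loss"
NEUTRAL = "neutral"


@dataclass(frozen=True)
class Segment:
    """Contiguous run of probes with a common mean log2 ratio."""

    interval: GenomicInterval
    mean: float
    n_probes: int
    stage: str

    def __post_init__(self) -> None:
        if self.n_probes < 1:
            raise ValueError("segment must contain at least one probe")


@dataclass(frozen=True)
class SegmentCall:
    segment: Segment
    call: str  # gain | loss | neutral

    def __post_init__(self) -> None:
        if self.call not in (GAIN, LOSS, NEUTRAL):
            raise ValueError(f"unknown call {self.call!r}")


@dataclass
class CallParams:
    """Segmentation and calling parameters.

    cutoff=None derives the cutoff from pooled probe SD; alpha and nperm are
    the CBS split-acceptance level and permutation count; min_width is the
    minimum segment width in probes.
    """

    cutoff: float | None = None
    alpha: float = 0.01
    nperm: int = 10_000
    min_width: int = 2

    def __post_init__(self) -> None:
        if self.cutoff is not None and self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


def median_normalize(matrix: np.ndarray) -> np.ndarray:
    """Subtract each replicate's median (rows = replicates, columns = probes)."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim == 1:
        matrix = matrix[None, :]
    if matrix.shape[1] < 1:
        raise ValueError("need at least one probe")
    med = np.nanmedian(matrix, axis=1, keepdims=True)
    if np.isnan(med).any():
        raise ValueError("replicate with all values missing")
    return matrix - med


def average_replicates(matrix: np.ndarray) -> np.ndarray:
    """Per-probe mean over non-missing replicates; all-missing probes -> NaN."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim == 1:
        matrix = matrix[None, :]
    with np.errstate(invalid="ignore"):
        return np.nanmean(matrix, axis=0)


class CBSSegmenter(BaseEstimator):
    """Circular binary segmentation of an ordered probe log-ratio vector.

    Recursively finds the arc maximizing the mean-difference statistic between
    probes inside and outside the arc, accepts the split when its permutation
    p-value falls below ``alpha``, and recurses on the resulting pieces.

    Parameters
    ----------
    alpha : split-acceptance level for the permutation test.
    nperm : permutations per split test.
    min_width : minimum arc width in probes.
    random_state : seed for the permutation stream.

    Attributes
    ----------
    breakpoints_ : sorted interior cut indices (half-open convention).
    segments_ : list of (start_index, end_index, mean, n_probes).
    """

    def __init__(self, alpha: float = 0.01, nperm: int = 10_000,
                 min_width: int = 2, random_state: int = 0):
        self.alpha = alpha
        self.nperm = nperm
        self.min_width = min_width
        self.random_state = random_state

    def fit(self, X, y=None):
        x = np.asarray(X, dtype=float).ravel()
        if x.size < 1:
            raise ValueError("empty probe vector")
        if np.isnan(x).any():
            raise ValueError("probe vector contains missing values; drop them first")
        seeds = np.random.SeedSequence(self.random_state).generate_state(1_000_000) % (2**31)
        counter = [0]
        pieces: list[tuple[int, int]] = []

        def recurse(lo: int, hi: int) -> None:
            n = hi - lo
            if n < 2 * self.min_width:
                pieces.append((lo, hi))
                return
            seg = x[lo:hi]
            if np.ptp(seg) == 0.0:
                pieces.append((lo, hi))
                return
            T, i, j = _cbs.max_arc(seg, self.min_width)
            seed = int(seeds[counter[0] % seeds.size])
            counter[0] += 1
            pv = _cbs.perm_pvalue(seg, T, self.nperm, self.alpha, self.min_width, seed)
            cuts = sorted({i, j} - {0, n})
            if pv < self.alpha and cuts:
                points = [0] + cuts + [n]
                for a, b in zip(points[:-1], points[1:]):
                    recurse(lo + a, lo + b)
            else:
                pieces.append((lo, hi))

        recurse(0, x.size)
        pieces.sort()
        self.breakpoints_ = [b for _, b in pieces[:-1]]
        self.segments_ = [
            (a, b, float(np.mean(x[a:b])), b - a) for a, b in pieces
        ]
        return self

    def predict(self, X=None):
        """Per-probe segment mean for the fitted vector."""
        out = np.empty(self.segments_[-1][1])
        for a, b, mean, _ in self.segments_:
            out[a:b] = mean
        return out


def _probe_boundaries(positions: np.ndarray) -> np.ndarray:
    """Base-pair boundary grid: midpoint-to-midpoint between flanking probes.

    boundary[0] = first probe position; boundary[n] = last position + 1;
    interior boundary[i] = midpoint of probes i-1 and i.
    """
    n = positions.size
    bounds = np.empty(n + 1, dtype=np.int64)
    bounds[0] = positions[0]
    bounds[n] = positions[-1] + 1
    if n > 1:
        bounds[1:n] = (positions[:-1] + positions[1:] + 1) // 2
    return bounds


def cbs_segment(
    values: np.ndarray,
    params: CallParams,
    positions: np.ndarray | None = None,
    chrom: str = "chr?",
    stage: str = "?",
    random_state: int = 0,
) -> list[Segment]:
    """Segment one chromosome's probe vector into contiguous Segments."""
    values = np.asarray(values, dtype=float)
    if positions is None:
        positions = np.arange(values.size, dtype=np.int64)
    positions = np.asarray(positions, dtype=np.int64)
    seg = CBSSegmenter(
        alpha=params.alpha, nperm=params.nperm,
        min_width=params.min_width, random_state=random_state,
    ).fit(values)
    bounds = _probe_boundaries(positions)
    out = []
    for a, b, mean, n in seg.segments_:
        out.append(
            Segment(
                interval=GenomicInterval(chrom, int(bounds[a]), int(bounds[b])),
                mean=mean,
                n_probes=n,
                stage=stage,
            )
        )
    return out


def segment_stage(
    probes: pd.DataFrame,
    values: np.ndarray,
    params: CallParams,
    stage: str,
    random_state: int = 0,
) -> list[Segment]:
    """Segment a whole stage: per-chromosome CBS over an averaged probe vector.

    ``probes`` must have columns chrom, pos aligned with ``values``; probes
    with missing values are excluded from segmentation.
    """
    values = np.asarray(values, dtype=float)
    segments: list[Segment] = []
    for k, chrom in enumerate(dict.fromkeys(probes["chrom"])):
        mask = (probes["chrom"] == chrom).to_numpy()
        v = values[mask]
        pos = probes.loc[mask, "pos"].to_numpy()
        keep = ~np.isnan(v)
        v, pos = v[keep], pos[keep]
        if v.size == 0:
            continue
        segments.extend(
            cbs_segment(v, params, positions=pos, chrom=chrom, stage=stage,
                        random_state=random_state * 1_009 + k)
        )
    return segments


def derive_call_cutoff(values: np.ndarray) -> float:
    """Gain/loss cutoff = sample SD of pooled normalized probe values."""
    values = np.asarray(values, dtype=float).ravel()
    values = values[~np.isnan(values)]
    if values.size < 2:
        raise ValueError("need at least two probe values")
    sd = float(np.std(values, ddof=1))
    if sd == 0.0:
        raise ValueError("zero probe variance; cutoff undefined")
    return sd


def segment_mean_percentiles(segments: list[Segment], q=(20.0, 80.0)) -> tuple[float, float]:
    """Diagnostic: percentiles of segment means (cutoff should sit near them)."""
    means = np.array([s.mean for s in segments], dtype=float)
    lo, hi = np.percentile(means, q)
    return float(lo), float(hi)


def call_segments(segments: list[Segment], cutoff: float) -> list[SegmentCall]:
    """Strict-inequality calls; a mean exactly at +/-cutoff is neutral."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    calls = []
    for seg in segments:
        if seg.mean > cutoff:
            call = GAIN
        elif seg.mean < -cutoff:
            call = LOSS
        else:
            call = NEUTRAL
        calls.append(SegmentCall(segment=seg, call=call))
    return calls


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (report convention)."""
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


@dataclass
class StageAlterationSummary:
    """Per-stage alteration summary in the shape of a kb-per-chromosome table."""

    stage: str
    table: pd.DataFrame = field(repr=False)  # index chrom; gained_bases, lost_bases
    genome_size: int = 0

    @property
    def total_gained(self) -> int:
        return int(self.table["gained_bases"].sum())

    @property
    def total_lost(self) -> int:
        return int(self.table["lost_bases"].sum())

    @property
    def fraction_altered(self) -> float:
        return (self.total_gained + self.total_lost) / self.genome_size

    @property
    def percent_altered(self) -> int:
        return round_half_away(100.0 * self.fraction_altered)

    @property
    def event_count(self) -> int:
        """Chromosomes with any gain plus chromosomes with any loss."""
        return int((self.table["gained_bases"] > 0).sum()
                   + (self.table["lost_bases"] > 0).sum())


def summarize_alterations(
    calls: list[SegmentCall], genome: GenomeBuild, stage: str | None = None
) -> StageAlterationSummary:
    """Aggregate gained/lost bases per chromosome for one stage's calls."""
    gained = {c: 0 for c in genome.names}
    lost = {c: 0 for c in genome.names}
    stages = {sc.segment.stage for sc in calls}
    if stage is None:
        stage = stages.pop() if len(stages) == 1 else "?"
    for sc in calls:
        span = len(sc.segment.interval)
        chrom = sc.segment.interval.chrom
        if sc.call == GAIN:
            gained[chrom] += span
        elif sc.call == LOSS:
            lost[chrom] += span
    table = pd.DataFrame(
        {"gained_bases": pd.Series(gained), "lost_bases": pd.Series(lost)}
    ).loc[genome.names]
    return StageAlterationSummary(stage=stage, table=table, genome_size=genome.total_size)
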