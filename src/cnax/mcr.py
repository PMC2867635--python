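"""Minimal common regions (MCRs) across stage-wise gain/loss calls.

An MCR here is a maximal genomic interval over which the set of stages
carrying a same-sign copy-number alteration is constant: the sweep-line
decomposition of the per-stage altered intervals.  Gains and losses are
decomposed independently and never merge.
"""

from __future__ import annotations

from dataclasses import dataclass

from .cgh import GAIN, LOSS, SegmentCall
from .genome import GenomicInterval

__all__ = ["MCRegion", "compute_mcr", "recurrence_coverage"]


@dataclass(frozen=True)
class MCRegion:
    interval: GenomicInterval
    sign: str  # gain | loss
    stages: frozenset

    @property
    def support(self) -> int:
        return len(self.stages)


def _altered_intervals(calls: list[SegmentCall], sign: str) -> list[GenomicInterval]:
    return [sc.segment.interval for sc in calls if sc.call == sign]


def _check_no_conflicts(calls: list[SegmentCall], stage: str) -> None:
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for sc in calls:
        if sc.call == "neutral":
            continue
        iv = sc.segment.interval
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, sc.call))
    for chrom, spans in by_chrom.items():
        spans.sort()
        for (s1, e1, c1), (s2, e2, c2) in zip(spans[:-1], spans[1:]):
            if s2 < e1 and c1 != c2:
                raise ValueError(
                    f"stage {stage}: conflicting overlapping calls on {chrom} "
                    f"at [{s2}, {min(e1, e2)})"
                )


def compute_mcr(calls_by_stage: dict[str, list[SegmentCall]]) -> list[MCRegion]:
    """Support-constant decomposition of per-stage altered intervals.

    Returns MCRegions ordered by (chromosome input order, start, sign); each
    region is maximal: extending it changes the supporting stage set.
    """
    for stage, calls in calls_by_stage.items():
        _check_no_conflicts(calls, stage)

    regions: list[MCRegion] = []
    chroms: list[str] = []
    for calls in calls_by_stage.values():
        for sc in calls:
            c = sc.segment.interval.chrom
            if c not in chroms:
                chroms.append(c)
    chroms.sort()

    for chrom in chroms:
        for sign in (GAIN, LOSS):
            # per-stage altered intervals on this chromosome
            stage_ivs = {
                stage: [
                    iv for iv in _altered_intervals(calls, sign) if iv.chrom == chrom
                ]
                for stage, calls in calls_by_stage.items()
            }
            points = sorted(
                {p for ivs in stage_ivs.values() for iv in ivs for p in (iv.start, iv.end)}
            )
            if len(points) < 2:
                continue
            pending: tuple[int, int, frozenset] | None = None
            for lo, hi in zip(points[:-1], points[1:]):
                support = frozenset(
                    stage
                    for stage, ivs in stage_ivs.items()
                    if any(iv.start <= lo and hi <= iv.end for iv in ivs)
                )
                if not support:
                    piece = None
                else:
                    piece = (lo, hi, support)
                if pending is not None:
                    if piece is not None and piece[0] == pending[1] and piece[2] == pending[2]:
                        pending = (pending[0], piece[1], pending[2])
                        continue
                    regions.append(
                        MCRegion(
                            GenomicInterval(chrom, pending[0], pending[1]),
                            sign,
                            pending[2],
                        )
                    )
                pending = piece
            if pending is not None:
                regions.append(
                    MCRegion(GenomicInterval(chrom, pending[0], pending[1]), sign, pending[2])
                )

    regions.sort(key=lambda r: (r.interval.chrom, r.interval.start, r.sign))
    return regions


def recurrence_coverage(mcrs: list[MCRegion], k: int) -> float:
    """Fraction of aberrant bases lying in MCRs supported by >= k stages."""
    if k < 1:
        raise ValueError("k must be >= 1")
    total = sum(len(r.interval) for r in mcrs)
    if total == 0:
        return 0.0
    hit = sum(len(r.interval) for r in mcrs if r.support >= k)
    return hit / total
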