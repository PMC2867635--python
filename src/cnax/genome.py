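"""Genome coordinate system, probe/feature annotation tables, and interval I/O.

All coordinates are 0-based half-open internally and BED-convention on disk.
Sex chromosomes are excluded by default so that genome-wide denominators match
autosome-only reporting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CoordinateError",
    "GenomeBuild",
    "GenomicInterval",
    "ProbeTable",
    "FeatureAnnotation",
    "genes_in_interval",
    "read_probe_table",
    "write_probe_table",
    "read_feature_table",
    "write_feature_table",
    "read_segments",
    "write_segments",
]


class CoordinateError(ValueError):
    """An interval refers to an unknown chromosome or is out of bounds."""


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise CoordinateError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains_point(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end


@dataclass
class GenomeBuild:
    """Ordered chromosome catalogue (name, length); autosomes only by default."""

    chromosomes: list[tuple[str, int]]

    def __post_init__(self) -> None:
        names = [c for c, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name} has non-positive length")

    @classmethod
    def synthetic(cls, n_chromosomes: int = 10, size: int = 100_000_000) -> "GenomeBuild":
        """Uniform synthetic autosome set chr1..chrN of equal size."""
        return cls([(f"chr{i + 1}", size) for i in range(n_chromosomes)])

    @property
    def names(self) -> list[str]:
        return [c for c, _ in self.chromosomes]

    def length(self, chrom: str) -> int:
        for name, size in self.chromosomes:
            if name == chrom:
                return size
        raise CoordinateError(f"unknown chromosome {chrom!r}")

    @property
    def total_size(self) -> int:
        return sum(size for _, size in self.chromosomes)

    def validate(self, interval: GenomicInterval) -> None:
        if interval.end > self.length(interval.chrom):
            raise CoordinateError(
                f"interval {interval.chrom}:{interval.start}-{interval.end} exceeds "
                f"chromosome length {self.length(interval.chrom)}"
            )


def _sorted_by_position(df: pd.DataFrame, poscol: str) -> pd.DataFrame:
    return df.sort_values(["chrom", poscol], kind="mergesort").reset_index(drop=True)


def _blockwise_sorted(df: pd.DataFrame, poscol: str) -> bool:
    """Chromosomes in contiguous blocks (any block order) and positions
    non-decreasing within each chromosome."""
    chroms = df["chrom"].to_numpy()
    seen: set = set()
    prev = None
    for c in chroms:
        if c != prev:
            if c in seen:
                return False
            seen.add(c)
            prev = c
    return bool(
        df.groupby("chrom", sort=False)[poscol]
        .apply(lambda s: s.is_monotonic_increasing)
        .all()
    )


@dataclass
class ProbeTable:
    """Probe annotation backbone: id, chromosome, midpoint position, array type.

    ``table`` columns: id, chrom, pos, array_type (cgh | mrna | mirna).
    Probes are kept sorted by (chrom, pos); ids are unique per array type.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = {"id", "chrom", "pos", "array_type"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"probe table missing columns {sorted(missing)}")
        if (self.table["pos"] < 0).any():
            raise ValueError("probe positions must be non-negative")
        dup = self.table.duplicated(subset=["id", "array_type"])
        if dup.any():
            raise ValueError("probe ids must be unique per array type")
        t = self.table
        if not _blockwise_sorted(t, "pos"):
            warnings.warn("probe table not sorted by (chrom, pos); sorting on load")
            self.table = _sorted_by_position(t, "pos")
        else:
            self.table = t.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    def for_type(self, array_type: str) -> pd.DataFrame:
        return self.table[self.table["array_type"] == array_type].reset_index(drop=True)

    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.table["chrom"]))


@dataclass
class FeatureAnnotation:
    """Gene / microRNA loci: id, chrom, start, end, feature_class (gene | mirna)."""

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = {"id", "chrom", "start", "end", "feature_class"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"feature table missing columns {sorted(missing)}")
        if self.table["id"].duplicated().any():
            raise ValueError("feature ids must be unique")
        bad = self.table["start"] >= self.table["end"]
        if bad.any():
            raise ValueError("feature intervals must satisfy start < end")
        if not _blockwise_sorted(self.table, "start"):
            self.table = _sorted_by_position(self.table, "start")
        else:
            self.table = self.table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    def for_class(self, feature_class: str) -> "FeatureAnnotation":
        sub = self.table[self.table["feature_class"] == feature_class]
        return FeatureAnnotation(sub.reset_index(drop=True))

    def ids(self) -> set[str]:
        return set(self.table["id"])

    def validate_against(self, build: GenomeBuild) -> None:
        for _, row in self.table.iterrows():
            build.validate(GenomicInterval(row["chrom"], int(row["start"]), int(row["end"])))


def genes_in_interval(
    features: FeatureAnnotation,
    region: GenomicInterval,
    rule: str = "any-overlap",
    build: GenomeBuild | None = None,
) -> set[str]:
    """Feature ids assigned to ``region`` under the given overlap rule.

    rule="any-overlap": any base shared with the half-open region.
    rule="midpoint": the feature's (integer) midpoint falls inside the region.
    """
    if rule not in ("any-overlap", "midpoint"):
        raise ValueError(f"unknown rule {rule!r}")
    if build is not None:
        build.validate(region)
    t = features.table
    on_chrom = t[t["chrom"] == region.chrom]
    if on_chrom.empty:
        return set()
    start = on_chrom["start"].to_numpy()
    end = on_chrom["end"].to_numpy()
    if rule == "any-overlap":
        mask = (start < region.end) & (end > region.start)
    else:
        mid = (start + end) // 2
        mask = (mid >= region.start) & (mid < region.end)
    return set(on_chrom.loc[mask, "id"])


# ---------------------------------------------------------------------------
# File I/O (TSV probe/feature tables; BED5-like segments)


class ParseError(ValueError):
    pass


def read_probe_table(path) -> ProbeTable:
    """Read a TSV probe table (header: id, chrom, pos, array_type)."""
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "chrom": str})
    for lineno, (_, row) in enumerate(df.iterrows(), start=2):
        if row["pos"] < 0:
            raise ParseError(f"{path}: line {lineno}: negative probe position {row['pos']}")
    df["pos"] = df["pos"].astype(np.int64)
    return ProbeTable(df)


def write_probe_table(path, probes: ProbeTable) -> None:
    probes.table.to_csv(path, sep="\t", index=False)


def read_feature_table(path) -> FeatureAnnotation:
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "chrom": str})
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return FeatureAnnotation(df)


def write_feature_table(path, features: FeatureAnnotation) -> None:
    features.table.to_csv(path, sep="\t", index=False)


def write_segments(path, calls) -> None:
    """Write segment calls as BED5: chrom, start, end, name=stage:call, score=mean."""
    rows = []
    for sc in calls:
        seg = sc.segment
        rows.append(
            (
                seg.interval.chrom,
                seg.interval.start,
                seg.interval.end,
                f"{seg.stage}:{sc.call}",
                f"{seg.mean:.6g}",
            )
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)


def read_segments(path):
    """Read BED5 segment calls written by :func:`write_segments`."""
    from .cgh import Segment, SegmentCall  # local import to avoid cycle

    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "name", "score"],
        dtype={"chrom": str, "name": str},
    )
    calls = []
    for lineno, (_, row) in enumerate(df.iterrows(), start=1):
        try:
            stage, call = row["name"].split(":")
            interval = GenomicInterval(row["chrom"], int(row["start"]), int(row["end"]))
        except (ValueError, CoordinateError) as exc:
            raise ParseError(f"{path}: line {lineno}: {exc}") from exc
        seg = Segment(interval=interval, mean=float(row["score"]), n_probes=1, stage=stage)
        calls.append(SegmentCall(segment=seg, call=call))
    return calls
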