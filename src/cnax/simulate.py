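"""Synthetic pooled-array data with planted ground truth.

Emulates the study design the pipeline expects: four tumor stages (Dukes
A-D), each one pooled tumor-vs-normal comparison of six patients; aCGH and
mRNA arrays in technical triplicate and single-channel microRNA arrays in
duplicate; probe noise around SD 0.1 (log2); stage-progressive planted
gain/loss segments (nested by default, gains only in stage A); gene
expression fold-changes driven by copy dosage for genes under planted
segments plus a background of stage-independent DE; and the nuisance
structure each normalization step is meant to remove (per-replicate channel
offsets for median normalization, an intensity-dependent curvature for
lowess, per-array affine distortions for quantile normalization).

Everything is deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genome import FeatureAnnotation, GenomeBuild, GenomicInterval, ProbeTable

__all__ = [
    "ConfigError",
    "PlantedSegment",
    "SimulationConfig",
    "TruthProfile",
    "SyntheticDataset",
    "default_planted_segments",
    "plant_progressive_cna",
    "simulate_cgh",
    "simulate_mrna",
    "simulate_mirna",
    "simulate_all",
    "segmentation_recovery",
]

STAGES = ("A", "B", "C", "D")


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class PlantedSegment:
    """A planted copy-number segment and the stages that carry it."""

    chrom: str
    start: int
    end: int
    amplitude: float  # signed log2 ratio; > 0 gain, < 0 loss
    stages: frozenset

    @property
    def sign(self) -> int:
        return 1 if self.amplitude > 0 else -1

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)


@dataclass
class SimulationConfig:
    """Study-design parameters; defaults reproduce the assumed conditions."""

    seed: int = 0
    n_chromosomes: int = 10
    chrom_size: int = 100_000_000
    stages: tuple = STAGES
    patients_per_stage: int = 6
    cgh_replicates: int = 3
    mrna_replicates: int = 3
    mirna_replicates: int = 2
    noise_sd: float = 0.1
    cgh_probes_per_chrom: int = 2000
    genes_per_chrom: int = 200
    n_mirnas: int = 200
    planted: list[PlantedSegment] | None = None  # None -> default progressive set
    channel_offset_sd: float = 0.05
    coupling: float = 4.0
    coupling_sd: float = 0.25
    coupled_fraction: float = 0.8
    background_de_fraction: float = 0.05
    background_effect: float = 1.5
    mirna_de_fraction: float = 0.15
    mirna_effect: float = 0.8
    curvature: float = 0.02
    mirna_scale_sd: float = 0.05
    mirna_offset_sd: float = 0.3
    tumor_purity: float = 1.0  # optional dilution of planted amplitudes; 1 = off
    extra_pool_sd: float = 0.0  # patient-pool heterogeneity folded into one term
    allow_loss_in_a: bool = False

    def __post_init__(self) -> None:
        for name in ("cgh_replicates", "mrna_replicates", "mirna_replicates"):
            if getattr(self, name) < 2:
                raise ConfigError(f"{name} must be >= 2")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be non-negative")

    def genome(self) -> GenomeBuild:
        return GenomeBuild.synthetic(self.n_chromosomes, self.chrom_size)

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


def default_planted_segments(config: SimulationConfig) -> list[PlantedSegment]:
    """Nested progressive default: every early segment persists in later stages,
    stage A carries gains only, and altered bases grow from A to D."""
    size = config.chrom_size
    abcd = frozenset(config.stages)
    bcd = frozenset(config.stages[1:])
    cd = frozenset(config.stages[2:])
    d = frozenset(config.stages[3:])
    frac = lambda lo, hi: (int(lo * size), int(hi * size))
    spec = [
        ("chr1", 0.10, 0.25, +0.3, abcd),
        ("chr2", 0.40, 0.55, +0.3, abcd),
        ("chr3", 0.10, 0.30, +0.3, bcd),
        ("chr4", 0.50, 0.70, -0.3, bcd),
        ("chr5", 0.20, 0.45, +0.3, cd),
        ("chr6", 0.30, 0.55, -0.3, cd),
        ("chr7", 0.60, 0.80, +0.3, cd),
        ("chr8", 0.10, 0.40, +0.3, d),
        ("chr9", 0.40, 0.60, -0.3, d),
    ]
    out = []
    names = {c for c, _ in config.genome().chromosomes}
    for chrom, lo, hi, amp, stages in spec:
        if chrom not in names:
            continue
        start, end = frac(lo, hi)
        out.append(PlantedSegment(chrom, start, end, amp, stages))
    return out


@dataclass
class TruthProfile:
    """Planted ground truth: segments, dosage-coupled genes, background DE."""

    config: SimulationConfig
    genome: GenomeBuild
    segments: list[PlantedSegment]
    probes: ProbeTable = field(repr=False)
    genes: FeatureAnnotation = field(repr=False)
    mirnas: FeatureAnnotation = field(repr=False)
    coupled_genes: dict = field(repr=False)  # gene id -> (segment index, coefficient)
    background_de: dict = field(repr=False)  # gene id -> sign (+1 / -1)
    mirna_de: dict = field(repr=False)  # mirna id -> sign

    def segments_for_stage(self, stage: str) -> list[PlantedSegment]:
        return [s for s in self.segments if stage in s.stages]

    def altered_bases(self, stage: str) -> int:
        return sum(s.end - s.start for s in self.segments_for_stage(stage))

    def amplitude_at(self, stage: str, chrom: str, positions: np.ndarray) -> np.ndarray:
        out = np.zeros(len(positions))
        scale = self.config.tumor_purity
        for seg in self.segments_for_stage(stage):
            if seg.chrom == chrom:
                inside = (positions >= seg.start) & (positions < seg.end)
                out[inside] = seg.amplitude * scale
        return out

    def expected_logfc(self, stage: str) -> pd.Series:
        """Per-gene expected M-value mean in a stage (dosage + background)."""
        lfc = pd.Series(0.0, index=self.genes.table["id"].to_numpy())
        for gene, (seg_idx, coef) in self.coupled_genes.items():
            seg = self.segments[seg_idx]
            if stage in seg.stages:
                lfc[gene] = coef * seg.amplitude * self.config.tumor_purity
        for gene, sign in self.background_de.items():
            lfc[gene] += sign * self.config.background_effect
        return lfc

    def coupled_gene_stages(self, gene: str) -> frozenset:
        seg_idx, _ = self.coupled_genes[gene]
        return self.segments[seg_idx].stages

    def late_only_coupled_genes(self, early=("A", "B"), late=("C", "D")) -> set:
        """Dosage-coupled genes whose segment is absent in every early stage."""
        out = set()
        for gene in self.coupled_genes:
            stages = self.coupled_gene_stages(gene)
            if not stages & set(early) and stages & set(late):
                out.add(gene)
        return out


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed) % (2**31), stream])


def _tile_probes(config: SimulationConfig, array_type: str, per_chrom: int) -> ProbeTable:
    rows = []
    for chrom, size in config.genome().chromosomes:
        step = size / per_chrom
        for i in range(per_chrom):
            rows.append((f"{array_type}_{chrom}_{i}", chrom, int((i + 0.5) * step), array_type))
    return ProbeTable(pd.DataFrame(rows, columns=["id", "chrom", "pos", "array_type"]))


def _tile_genes(config: SimulationConfig) -> FeatureAnnotation:
    rows = []
    width = min(10_000, config.chrom_size // (2 * config.genes_per_chrom) or 1)
    for chrom, size in config.genome().chromosomes:
        step = size / config.genes_per_chrom
        for i in range(config.genes_per_chrom):
            start = int((i + 0.5) * step)
            rows.append((f"g_{chrom}_{i}", chrom, start, start + width, "gene"))
    return FeatureAnnotation(
        pd.DataFrame(rows, columns=["id", "chrom", "start", "end", "feature_class"])
    )


def _place_mirnas(config: SimulationConfig, rng: np.random.Generator) -> FeatureAnnotation:
    chroms = config.genome().chromosomes
    rows = []
    for i in range(config.n_mirnas):
        chrom, size = chroms[i % len(chroms)]
        start = int(rng.integers(0, size - 200))
        rows.append((f"mir_{i}", chrom, start, start + 100, "mirna"))
    return FeatureAnnotation(
        pd.DataFrame(rows, columns=["id", "chrom", "start", "end", "feature_class"])
    )


def plant_progressive_cna(config: SimulationConfig) -> TruthProfile:
    """Resolve the planted-segment design into a full ground-truth profile."""
    genome = config.genome()
    segments = config.planted if config.planted is not None else default_planted_segments(config)

    for seg in segments:
        genome.validate(seg.interval)
        unknown = seg.stages - set(config.stages)
        if unknown:
            raise ConfigError(f"segment on {seg.chrom} names unknown stages {sorted(unknown)}")
        if seg.amplitude == 0:
            raise ConfigError("planted amplitude must be non-zero")
    if not config.allow_loss_in_a and config.stages:
        first = config.stages[0]
        for seg in segments:
            if seg.amplitude < 0 and first in seg.stages:
                raise ConfigError(
                    f"loss segment on {seg.chrom} assigned to earliest stage {first!r}; "
                    "the default design carries no early-stage losses "
                    "(set allow_loss_in_a=True to override)"
                )
    # same-stage overlaps with conflicting signs are contradictory
    for stage in config.stages:
        on_stage = [s for s in segments if stage in s.stages]
        for i, a in enumerate(on_stage):
            for b in on_stage[i + 1:]:
                if a.interval.overlaps(b.interval) and a.sign != b.sign:
                    raise ConfigError(
                        f"stage {stage}: overlapping planted segments with "
                        f"conflicting signs on {a.chrom}"
                    )

    probes = _tile_probes(config, "cgh", config.cgh_probes_per_chrom)
    planted_chroms = {s.chrom for s in segments}
    probe_chroms = set(probes.table["chrom"])
    if planted_chroms - probe_chroms:
        raise ConfigError(f"no probes on planted chromosomes {sorted(planted_chroms - probe_chroms)}")

    genes = _tile_genes(config)
    rng = _rng(config, 1)
    mirnas = _place_mirnas(config, rng)

    # dosage-coupled genes: per planted segment, a fixed fraction of the genes
    # it covers, with a gene-specific coefficient around the configured value
    coupled: dict[str, tuple[int, float]] = {}
    gt = genes.table
    for idx, seg in enumerate(segments):
        mask = (
            (gt["chrom"] == seg.chrom)
            & (gt["start"] < seg.end)
            & (gt["end"] > seg.start)
        )
        ids = gt.loc[mask, "id"].to_numpy()
        if len(ids) == 0:
            continue
        n_pick = int(round(config.coupled_fraction * len(ids)))
        picked = rng.choice(ids, size=n_pick, replace=False) if n_pick else []
        for gene in picked:
            coef = config.coupling + rng.normal(0.0, config.coupling_sd)
            coupled[str(gene)] = (idx, float(coef))
    if segments and config.coupled_fraction > 0 and config.coupling != 0 and not coupled:
        raise ConfigError("dosage coupling requested but no genes under any planted segment")

    # background DE: stage-independent effects on genes outside the coupled set
    free = [g for g in gt["id"] if g not in coupled]
    n_bg = int(round(config.background_de_fraction * len(gt)))
    n_bg = min(n_bg, len(free))
    bg_ids = rng.choice(free, size=n_bg, replace=False) if n_bg else []
    background = {str(g): int(rng.choice([-1, 1])) for g in bg_ids}

    # DE microRNAs: global set; signs concordant with any covering planted segment
    mt = mirnas.table
    n_de = int(round(config.mirna_de_fraction * len(mt)))
    de_ids = rng.choice(mt["id"].to_numpy(), size=n_de, replace=False) if n_de else []
    mirna_de = {}
    for mid in de_ids:
        row = mt[mt["id"] == mid].iloc[0]
        sign = int(rng.choice([-1, 1]))
        for seg in segments:
            if seg.chrom == row["chrom"] and seg.start <= row["start"] < seg.end:
                sign = seg.sign
                break
        mirna_de[str(mid)] = sign

    return TruthProfile(
        config=config,
        genome=genome,
        segments=list(segments),
        probes=probes,
        genes=genes,
        mirnas=mirnas,
        coupled_genes=coupled,
        background_de=background,
        mirna_de=mirna_de,
    )


def simulate_cgh(truth: TruthProfile, config: SimulationConfig | None = None) -> dict:
    """Per stage: replicate x probe matrix of log2 tumor/normal ratios."""
    config = config or truth.config
    rng = _rng(config, 2)
    pt = truth.probes.table
    out = {}
    for stage in config.stages:
        base = np.concatenate([
            truth.amplitude_at(stage, chrom, grp["pos"].to_numpy())
            for chrom, grp in pt.groupby("chrom", sort=False)
        ])
        if config.extra_pool_sd > 0:
            base = base + rng.normal(0.0, config.extra_pool_sd, size=base.size)
        reps = []
        for _ in range(config.cgh_replicates):
            offset = rng.normal(0.0, config.channel_offset_sd) if config.channel_offset_sd else 0.0
            noise = rng.normal(0.0, config.noise_sd, size=base.size) if config.noise_sd else 0.0
            reps.append(base + offset + noise)
        out[stage] = np.vstack(reps)
    return out


def simulate_mrna(truth: TruthProfile, config: SimulationConfig | None = None) -> dict:
    """Per stage: (M, A) replicate x gene matrices for the two-color design."""
    config = config or truth.config
    rng = _rng(config, 3)
    gene_ids = truth.genes.table["id"].to_numpy()
    a_base = rng.uniform(6.0, 14.0, size=gene_ids.size)
    curve = config.curvature * ((a_base - 10.0) ** 2)
    curve = curve - curve.mean()
    out = {}
    for stage in config.stages:
        lfc = truth.expected_logfc(stage).to_numpy()
        M_reps, A_reps = [], []
        for _ in range(config.mrna_replicates):
            noise = rng.normal(0.0, config.noise_sd, size=gene_ids.size) if config.noise_sd else 0.0
            M_reps.append(lfc + curve + noise)
            A_reps.append(a_base.copy())
        out[stage] = (np.vstack(M_reps), np.vstack(A_reps))
    return out


def simulate_mirna(truth: TruthProfile, config: SimulationConfig | None = None) -> dict:
    """Per stage: single-channel tumor and normal intensity matrices.

    Each array carries an affine per-replicate distortion (removed by
    quantile normalization) on top of the planted tumor-vs-normal effects.
    """
    config = config or truth.config
    rng = _rng(config, 4)
    ids = truth.mirnas.table["id"].to_numpy()
    baseline = rng.uniform(4.0, 10.0, size=ids.size)
    effect = np.array([truth.mirna_de.get(str(m), 0) for m in ids], dtype=float)
    effect *= config.mirna_effect
    out = {}
    for stage in config.stages:
        arrays = {}
        for label, true_level in (("tumor", baseline + effect), ("normal", baseline)):
            reps = []
            for _ in range(config.mirna_replicates):
                a = 1.0 + (rng.normal(0.0, config.mirna_scale_sd) if config.mirna_scale_sd else 0.0)
                b = rng.normal(0.0, config.mirna_offset_sd) if config.mirna_offset_sd else 0.0
                noise = rng.normal(0.0, config.noise_sd, size=ids.size) if config.noise_sd else 0.0
                reps.append(a * true_level + b + noise)
            arrays[label] = np.vstack(reps)
        out[stage] = arrays
    return out


@dataclass
class SyntheticDataset:
    truth: TruthProfile
    cgh: dict = field(repr=False)
    mrna: dict = field(repr=False)
    mirna: dict = field(repr=False)


def simulate_all(config: SimulationConfig) -> SyntheticDataset:
    truth = plant_progressive_cna(config)
    return SyntheticDataset(
        truth=truth,
        cgh=simulate_cgh(truth, config),
        mrna=simulate_mrna(truth, config),
        mirna=simulate_mirna(truth, config),
    )


# ---------------------------------------------------------------------------
# Ground-truth evaluation


def segmentation_recovery(truth: TruthProfile, calls_by_stage: dict) -> dict:
    """Compare gain/loss calls against the planted segments.

    Returns base_accuracy (fraction of planted altered bases receiving the
    correct call, over all stages) and breakpoint_errors (probe-index distance
    from each planted boundary to the nearest called segment boundary).
    """
    from .cgh import NEUTRAL

    pt = truth.probes.table
    pos_by_chrom = {c: g["pos"].to_numpy() for c, g in pt.groupby("chrom", sort=False)}

    total = 0
    correct = 0
    bp_errors = []
    for stage, calls in calls_by_stage.items():
        called = [
            (sc.segment.interval, 1 if sc.call == "gain" else -1)
            for sc in calls
            if sc.call != NEUTRAL
        ]
        for seg in truth.segments_for_stage(stage):
            total += seg.end - seg.start
            for iv, sign in called:
                if iv.chrom == seg.chrom and sign == seg.sign:
                    overlap = min(iv.end, seg.end) - max(iv.start, seg.start)
                    if overlap > 0:
                        correct += overlap
            # breakpoint error in probe indices
            pos = pos_by_chrom.get(seg.chrom)
            if pos is None:
                continue
            boundaries = sorted(
                {b for sc in calls if sc.segment.interval.chrom == seg.chrom
                 for b in (sc.segment.interval.start, sc.segment.interval.end)}
            )
            for true_bp in (seg.start, seg.end):
                ti = int(np.searchsorted(pos, true_bp))
                err = min(
                    (abs(int(np.searchsorted(pos, b)) - ti) for b in boundaries),
                    default=len(pos),
                )
                bp_errors.append(err)
    return {
        "base_accuracy": correct / total if total else 1.0,
        "breakpoint_errors": bp_errors,
        "median_breakpoint_error": float(np.median(bp_errors)) if bp_errors else 0.0,
    }
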