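"""DNA-RNA interaction scan: enrichment of DE features in aberrant DNA.

For each stage the scan tests whether differentially expressed genes are
enriched inside copy-number-altered DNA at three scopes — the pooled aberrant
genome, each chromosome carrying an aberration, and each aberrant segment —
with a two-sided Fisher exact test on the (in/out region) x (DE/non-DE)
table.  Genes whose DE direction is concordant with the covering call (gain &
up, loss & down) and that sit in a significant segment are "interaction
genes"; comparing their per-stage sets yields early/late stage-discriminating
candidates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cgh import GAIN, LOSS, NEUTRAL, SegmentCall
from .expression import DOWN, NONE, UP, bh_fdr
from .genome import FeatureAnnotation, GenomicInterval, genes_in_interval

__all__ = [
    "InteractionTest",
    "ConcordantGene",
    "StageGeneSets",
    "fisher_exact_2x2",
    "region_enrichment",
    "scan_interactions",
    "concordance_filter",
    "interaction_genes",
    "early_late_discrimination",
    "mirna_segment_interactions",
]


@dataclass(frozen=True)
class InteractionTest:
    stage: str
    scope: str  # genome | chromosome | segment
    scope_id: str
    table: tuple  # ((de_in, nonde_in), (de_out, nonde_out))
    p: float
    odds_ratio: float
    genes_in_region: frozenset = field(default_factory=frozenset)


@dataclass(frozen=True)
class ConcordantGene:
    gene: str
    call: str  # gain | loss
    direction: str  # up | down
    stage: str


@dataclass
class StageGeneSets:
    """Interaction-gene set comparisons between early (A+B) and late (C+D)."""

    early_union: set
    late_union: set
    late_only: set
    early_only: set
    all_stage: set
    d_only: set


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher exact p (point-probability rule) and odds ratio a*d/(b*c)."""
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (t < 0).any():
        raise ValueError("table entries must be non-negative")
    if t.sum() == 0:
        raise ValueError("table has no observations")
    p = float(stats.fisher_exact(t, alternative="two-sided")[1])
    a, b, c, d = t.ravel()
    if b * c == 0:
        odds = np.inf if a * d > 0 else np.nan
    else:
        odds = (a * d) / (b * c)
    return p, float(odds)


def _de_genes(de_results: pd.DataFrame) -> set[str]:
    return set(de_results.loc[de_results["direction"] != NONE, "feature"])


def region_enrichment(
    region_genes: set[str],
    de_results: pd.DataFrame,
    stage: str,
    scope: str,
    scope_id: str,
    all_genes: set[str] | None = None,
) -> InteractionTest | None:
    """Fisher test of DE enrichment among ``region_genes`` vs the rest.

    The background is every annotated gene not in the region.  Regions with
    no genes, or covering the whole background, are skipped with a warning.
    """
    if all_genes is None:
        all_genes = set(de_results["feature"])
    region_genes = region_genes & all_genes
    outside = all_genes - region_genes
    if not region_genes or not outside:
        warnings.warn(f"{stage}/{scope}/{scope_id}: degenerate region; test skipped")
        return None
    de = _de_genes(de_results) & all_genes
    a = len(region_genes & de)
    b = len(region_genes) - a
    c = len(de) - a
    d = len(outside) - c
    p, odds = fisher_exact_2x2([[a, b], [c, d]])
    return InteractionTest(
        stage=stage,
        scope=scope,
        scope_id=scope_id,
        table=((a, b), (c, d)),
        p=p,
        odds_ratio=odds,
        genes_in_region=frozenset(region_genes),
    )


def _aberrant_segments(calls: list[SegmentCall]) -> list[SegmentCall]:
    return [sc for sc in calls if sc.call != NEUTRAL]


def _segment_key(iv: GenomicInterval) -> str:
    return f"{iv.chrom}:{iv.start}-{iv.end}"


def scan_interactions(
    calls_by_stage: dict[str, list[SegmentCall]],
    de_by_stage: dict[str, pd.DataFrame],
    annotations: FeatureAnnotation,
    rule: str = "any-overlap",
    adjust: str = "none",
) -> list[InteractionTest]:
    """Per stage: genome-, chromosome- and segment-scope enrichment tests.

    ``adjust="bh"`` replaces segment-scope p-values by BH q-values within each
    stage's segment scan (off by default: the scan is reported unadjusted).
    """
    if adjust not in ("none", "bh"):
        raise ValueError("adjust must be 'none' or 'bh'")
    all_genes = annotations.ids()
    tests: list[InteractionTest] = []
    for stage in calls_by_stage:
        calls = _aberrant_segments(calls_by_stage[stage])
        de = de_by_stage[stage]
        if not calls:
            continue
        gene_sets = {
            _segment_key(sc.segment.interval): genes_in_interval(
                annotations, sc.segment.interval, rule=rule
            )
            for sc in calls
        }
        # genome scope: all aberrant bases pooled
        genome_genes = set().union(*gene_sets.values())
        t = region_enrichment(genome_genes, de, stage, "genome", "genome", all_genes)
        if t is not None:
            tests.append(t)
        # chromosome scope: aberrant bases pooled within each chromosome
        chroms = sorted({sc.segment.interval.chrom for sc in calls})
        for chrom in chroms:
            cg = set().union(
                *(
                    gene_sets[_segment_key(sc.segment.interval)]
                    for sc in calls
                    if sc.segment.interval.chrom == chrom
                )
            )
            t = region_enrichment(cg, de, stage, "chromosome", chrom, all_genes)
            if t is not None:
                tests.append(t)
        # segment scope
        seg_tests = []
        for sc in sorted(
            calls, key=lambda s: (s.segment.interval.chrom, s.segment.interval.start)
        ):
            key = _segment_key(sc.segment.interval)
            t = region_enrichment(gene_sets[key], de, stage, "segment", key, all_genes)
            if t is not None:
                seg_tests.append(t)
        if adjust == "bh" and seg_tests:
            qs = bh_fdr([t.p for t in seg_tests])
            seg_tests = [
                InteractionTest(t.stage, t.scope, t.scope_id, t.table, float(q),
                                t.odds_ratio, t.genes_in_region)
                for t, q in zip(seg_tests, qs)
            ]
        tests.extend(seg_tests)
    return tests


def _covering_call(
    gene_iv: tuple[str, int, int], calls: list[SegmentCall]
) -> SegmentCall | None:
    """Aberrant call covering the gene; the highest-|mean| segment wins ties."""
    chrom, start, end = gene_iv
    best = None
    for sc in calls:
        iv = sc.segment.interval
        if iv.chrom == chrom and iv.start < end and start < iv.end:
            if best is None or abs(sc.segment.mean) > abs(best.segment.mean):
                best = sc
    return best


def concordance_filter(
    de_results: pd.DataFrame,
    calls: list[SegmentCall],
    annotations: FeatureAnnotation,
    stage: str,
) -> tuple[list[ConcordantGene], list[ConcordantGene]]:
    """Split DE genes in aberrant DNA into concordant and discordant lists.

    Concordant: (gain, up) or (loss, down); discordant: the inverse pairs.
    Genes in neutral DNA appear in neither.
    """
    aberrant = _aberrant_segments(calls)
    ann = annotations.table.set_index("id")
    concordant, discordant = [], []
    de = de_results[de_results["direction"] != NONE]
    for _, row in de.iterrows():
        gene = row["feature"]
        if gene not in ann.index:
            continue
        g = ann.loc[gene]
        sc = _covering_call((g["chrom"], int(g["start"]), int(g["end"])), aberrant)
        if sc is None:
            continue
        item = ConcordantGene(gene=gene, call=sc.call, direction=row["direction"], stage=stage)
        if (sc.call, row["direction"]) in ((GAIN, UP), (LOSS, DOWN)):
            concordant.append(item)
        else:
            discordant.append(item)
    return concordant, discordant


def interaction_genes(
    tests: list[InteractionTest],
    concordant: list[ConcordantGene],
    stage: str,
    alpha: float = 0.05,
) -> set[str]:
    """Genes counted as 'interacting' in a stage: concordant DE direction AND
    membership in a significant (p < alpha) segment-scope region."""
    significant = set()
    for t in tests:
        if t.stage == stage and t.scope == "segment" and t.p < alpha:
            significant |= set(t.genes_in_region)
    return {c.gene for c in concordant if c.stage == stage and c.gene in significant}


def early_late_discrimination(
    genes_by_stage: dict[str, set[str]],
    early: tuple[str, ...] = ("A", "B"),
    late: tuple[str, ...] = ("C", "D"),
) -> StageGeneSets:
    """Compare per-stage interaction-gene sets between early and late stages.

    The late-discriminating set is present in C or D but in neither A nor B;
    genes interacting in every stage form the all-stage ("carcinogenesis")
    set; D-only genes appear in no other stage.
    """
    missing = [s for s in (*early, *late) if s not in genes_by_stage]
    if missing:
        raise ValueError(f"missing stages {missing}")
    early_union = set().union(*(genes_by_stage[s] for s in early))
    late_union = set().union(*(genes_by_stage[s] for s in late))
    all_stage = set.intersection(*(set(genes_by_stage[s]) for s in (*early, *late)))
    last = late[-1]
    others = [s for s in (*early, *late) if s != last]
    d_only = set(genes_by_stage[last]) - set().union(*(genes_by_stage[s] for s in others))
    return StageGeneSets(
        early_union=early_union,
        late_union=late_union,
        late_only=late_union - early_union,
        early_only=early_union - late_union,
        all_stage=all_stage,
        d_only=d_only,
    )


def mirna_segment_interactions(
    mirna_de_by_stage: dict[str, pd.DataFrame],
    calls_by_stage: dict[str, list[SegmentCall]],
    mirna_annotations: FeatureAnnotation,
) -> dict:
    """Per-stage interacting microRNA sets and their cross-stage structure.

    A microRNA interacts in a stage when it is DE in that stage and its locus
    lies inside an aberrant segment of that stage.  Returns the per-stage
    sets, the all-stage intersection, and whether every early-stage (first
    two stages) interacting microRNA recurs in the late stages.
    """
    ann = mirna_annotations.table.set_index("id")
    per_stage: dict[str, set[str]] = {}
    for stage, de in mirna_de_by_stage.items():
        aberrant = _aberrant_segments(calls_by_stage.get(stage, []))
        hits = set()
        for gene in _de_genes(de):
            if gene not in ann.index:
                continue
            g = ann.loc[gene]
            if _covering_call((g["chrom"], int(g["start"]), int(g["end"])), aberrant):
                hits.add(gene)
        per_stage[stage] = hits
    stages = list(per_stage)
    all_stage = set.intersection(*per_stage.values()) if per_stage else set()
    early = stages[:2]
    late = stages[2:]
    early_union = set().union(*(per_stage[s] for s in early)) if early else set()
    late_union = set().union(*(per_stage[s] for s in late)) if late else set()
    return {
        "per_stage": per_stage,
        "all_stage": all_stage,
        "early_nested_in_late": early_union <= late_union,
    }
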