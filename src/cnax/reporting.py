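"""Pipeline orchestration and summary reporting.

Renders the per-stage alteration and DE summaries in the shape of the
published kb-per-chromosome and count-per-chromosome tables, derives the
stage-level percentages and chromosome alteration-event counts from them,
and runs the whole synthetic pipeline end to end with a manifest of output
checksums for reproducibility.

Reference summary tables (transcribed totals for a four-stage pooled
colon-cancer dataset) ship with the package so the reporting layer can be
exercised without simulation.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cgh as cgh_mod
from . import expression as expr_mod
from . import interaction as inter_mod
from . import mcr as mcr_mod
from .cgh import CallParams, round_half_away
from .expression import DECutoffs
from .genome import write_segments
from .simulate import SimulationConfig, simulate_all

__all__ = [
    "STAGES",
    "load_reference_tables",
    "alteration_summary_from_kb",
    "de_summary_from_counts",
    "render_summary",
    "RunConfig",
    "PipelineResult",
    "run_pipeline",
]

STAGES = ("A", "B", "C", "D")


def load_reference_tables() -> dict[str, pd.DataFrame]:
    """Shipped reference tables: cna_kb, mrna_de, mirna_de (per chromosome)."""
    out = {}
    base = resources.files("cnax").joinpath("data")
    for key, fname in (
        ("cna_kb", "reference_cna_kb.tsv"),
        ("mrna_de", "reference_mrna_de_counts.tsv"),
        ("mirna_de", "reference_mirna_de_counts.tsv"),
    ):
        with base.joinpath(fname).open() as fh:
            out[key] = pd.read_csv(fh, sep="\t", dtype={"chrom": str})
    return out


def alteration_summary_from_kb(table: pd.DataFrame, stages=STAGES) -> pd.DataFrame:
    """Stage summary from a kb-per-chromosome gain/loss table.

    Returns per stage: gained_kb, lost_kb, percent_altered (integer, halves
    away from zero) and event_count (#chromosomes with any gain + #with any
    loss)."""
    genome_kb = float(table["chrom_kb"].sum())
    rows = []
    for s in stages:
        gained = float(table[f"gain_{s}"].sum())
        lost = float(table[f"loss_{s}"].sum())
        rows.append(
            {
                "stage": s,
                "gained_kb": gained,
                "lost_kb": lost,
                "fraction_altered": (gained + lost) / genome_kb,
                "percent_altered": round_half_away(100.0 * (gained + lost) / genome_kb),
                "event_count": int((table[f"gain_{s}"] > 0).sum())
                + int((table[f"loss_{s}"] > 0).sum()),
            }
        )
    return pd.DataFrame(rows)


def de_summary_from_counts(
    table: pd.DataFrame, total_col: str, stages=STAGES
) -> pd.DataFrame:
    """Stage summary from an up/down count-per-chromosome table.

    Missing per-chromosome entries (NA) are treated as zero counts.  Adds the
    1-df chi-square of the up/down split per stage."""
    n_features = float(table[total_col].sum())
    rows = []
    for s in stages:
        up = int(np.nansum(table[f"up_{s}"].to_numpy(dtype=float)))
        down = int(np.nansum(table[f"down_{s}"].to_numpy(dtype=float)))
        chi2, p = expr_mod.direction_frequency_test(up, down)
        rows.append(
            {
                "stage": s,
                "up": up,
                "down": down,
                "percent_de": round_half_away(100.0 * (up + down) / n_features),
                "chi2_direction": chi2,
                "p_direction": p,
            }
        )
    return pd.DataFrame(rows)


def render_summary(
    alteration: pd.DataFrame | None,
    mrna: pd.DataFrame | None,
    mirna: pd.DataFrame | None,
) -> str:
    """Human-readable per-stage summary of the three analysis arms."""
    lines = []
    if alteration is not None and len(alteration):
        lines.append("DNA copy-number alterations per stage:")
        for _, r in alteration.iterrows():
            lines.append(
                f"  {r['stage']}: gained {r['gained_kb']:.0f} kb, "
                f"lost {r['lost_kb']:.0f} kb, {r['percent_altered']}% of genome, "
                f"{r['event_count']} chromosome alteration events"
            )
    elif alteration is not None:
        lines.append("DNA copy-number alterations per stage: none (zero aberrant bases)")
    for label, df in (("mRNA", mrna), ("microRNA", mirna)):
        if df is None:
            continue
        lines.append(f"{label} differential expression per stage:")
        for _, r in df.iterrows():
            lines.append(
                f"  {r['stage']}: {r['up']} up / {r['down']} down "
                f"({r['percent_de']}% of features)"
            )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# End-to-end pipeline


@dataclass
class RunConfig:
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    call: CallParams = field(default_factory=lambda: CallParams(nperm=1000))
    mrna_cutoffs: DECutoffs = field(default_factory=DECutoffs.mrna)
    mirna_cutoffs: DECutoffs = field(default_factory=DECutoffs.mirna)
    interaction_alpha: float = 0.05
    interaction_adjust: str = "none"
    gene_rule: str = "any-overlap"
    outdir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = SimulationConfig(**raw.get("sim", {}))
        call = CallParams(**raw.get("call", {"nperm": 1000}))
        return cls(
            sim=sim,
            call=call,
            mrna_cutoffs=DECutoffs(**raw.get("mrna_cutoffs", {"fc": 1.0, "fdr": 0.05})),
            mirna_cutoffs=DECutoffs(**raw.get("mirna_cutoffs", {"fc": 0.5, "fdr": 0.05})),
            interaction_alpha=raw.get("interaction_alpha", 0.05),
            interaction_adjust=raw.get("interaction_adjust", "none"),
            gene_rule=raw.get("gene_rule", "any-overlap"),
            outdir=raw.get("outdir"),
        )


@dataclass
class PipelineResult:
    truth: object
    cutoff: float
    calls_by_stage: dict
    alteration_summaries: dict
    mcrs: list
    recurrence_k3: float
    mrna_de: dict
    mirna_de: dict
    trend: pd.DataFrame
    tests: list
    concordant: dict
    discordant: dict
    interacting_genes: dict
    stage_sets: inter_mod.StageGeneSets
    mirna_interactions: dict
    summary_text: str
    manifest: dict | None = None


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Simulate, segment, call DE, compute MCRs and interactions, summarize."""
    data = simulate_all(config.sim)
    truth = data.truth
    stages = list(config.sim.stages)
    probes = truth.probes.table

    # --- aCGH arm
    normalized = {s: cgh_mod.median_normalize(data.cgh[s]) for s in stages}
    averaged = {s: cgh_mod.average_replicates(normalized[s]) for s in stages}
    pooled = np.concatenate([normalized[s].ravel() for s in stages])
    cutoff = config.call.cutoff or cgh_mod.derive_call_cutoff(pooled)
    calls_by_stage = {}
    for k, s in enumerate(stages):
        segs = cgh_mod.segment_stage(
            probes, averaged[s], config.call, stage=s,
            random_state=config.sim.seed * 131 + k,
        )
        calls_by_stage[s] = cgh_mod.call_segments(segs, cutoff)
    summaries = {
        s: cgh_mod.summarize_alterations(calls_by_stage[s], truth.genome, stage=s)
        for s in stages
    }

    # --- MCRs
    mcrs = mcr_mod.compute_mcr(calls_by_stage)
    recurrence_k3 = mcr_mod.recurrence_coverage(mcrs, k=3)

    # --- mRNA arm
    gene_ids = truth.genes.table["id"].to_numpy()
    mrna_de = {}
    mrna_norm = {}
    for s in stages:
        M, A = data.mrna[s]
        Mn = expr_mod.lowess_normalize(M, A)
        mrna_norm[s] = Mn
        res, _ = expr_mod.moderated_t(Mn, feature_ids=gene_ids)
        mrna_de[s] = expr_mod.call_de(res, config.mrna_cutoffs)
    trend = expr_mod.trend_test({s: mrna_norm[s] for s in stages}, feature_ids=gene_ids)

    # --- microRNA arm
    mirna_ids = truth.mirnas.table["id"].to_numpy()
    mirna_de = {}
    for s in stages:
        arrays = data.mirna[s]
        stacked = np.vstack([arrays["tumor"], arrays["normal"]])
        qn = expr_mod.quantile_normalize(stacked)
        nrep = arrays["tumor"].shape[0]
        M = expr_mod.paired_mvalues(qn[:nrep], qn[nrep:])
        res, _ = expr_mod.moderated_t(M, feature_ids=mirna_ids)
        mirna_de[s] = expr_mod.call_de(res, config.mirna_cutoffs)

    # --- interaction scan
    tests = inter_mod.scan_interactions(
        calls_by_stage, mrna_de, truth.genes,
        rule=config.gene_rule, adjust=config.interaction_adjust,
    )
    concordant, discordant, interacting = {}, {}, {}
    for s in stages:
        conc, disc = inter_mod.concordance_filter(
            mrna_de[s], calls_by_stage[s], truth.genes, s
        )
        concordant[s], discordant[s] = conc, disc
        interacting[s] = inter_mod.interaction_genes(
            tests, conc, s, alpha=config.interaction_alpha
        )
    stage_sets = inter_mod.early_late_discrimination(
        interacting, early=tuple(stages[:2]), late=tuple(stages[2:])
    )
    mirna_inter = inter_mod.mirna_segment_interactions(
        mirna_de, calls_by_stage, truth.mirnas
    )

    # --- summaries
    alt = pd.DataFrame(
        {
            "stage": stages,
            "gained_kb": [summaries[s].total_gained / 1000.0 for s in stages],
            "lost_kb": [summaries[s].total_lost / 1000.0 for s in stages],
            "percent_altered": [summaries[s].percent_altered for s in stages],
            "event_count": [summaries[s].event_count for s in stages],
        }
    )
    de_sum = {
        label: pd.DataFrame(
            {
                "stage": stages,
                "up": [int((de[s]["direction"] == "up").sum()) for s in stages],
                "down": [int((de[s]["direction"] == "down").sum()) for s in stages],
                "percent_de": [
                    round_half_away(
                        100.0 * (de[s]["direction"] != "none").sum() / len(de[s])
                    )
                    for s in stages
                ],
            }
        )
        for label, de in (("mrna", mrna_de), ("mirna", mirna_de))
    }
    summary_text = render_summary(alt, de_sum["mrna"], de_sum["mirna"])

    result = PipelineResult(
        truth=truth,
        cutoff=cutoff,
        calls_by_stage=calls_by_stage,
        alteration_summaries=summaries,
        mcrs=mcrs,
        recurrence_k3=recurrence_k3,
        mrna_de=mrna_de,
        mirna_de=mirna_de,
        trend=trend,
        tests=tests,
        concordant=concordant,
        discordant=discordant,
        interacting_genes=interacting,
        stage_sets=stage_sets,
        mirna_interactions=mirna_inter,
        summary_text=summary_text,
    )
    if config.outdir is not None:
        result.manifest = _write_artifacts(result, config)
    return result


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_artifacts(result: PipelineResult, config: RunConfig) -> dict:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = list(config.sim.stages)

    for s in stages:
        write_segments(outdir / f"segments_{s}.bed", result.calls_by_stage[s])
        result.mrna_de[s].to_csv(outdir / f"de_mrna_{s}.tsv", sep="\t", index=False)
        result.mirna_de[s].to_csv(outdir / f"de_mirna_{s}.tsv", sep="\t", index=False)
    mcr_rows = [
        (
            r.interval.chrom, r.interval.start, r.interval.end,
            f"{r.sign}:{'+'.join(sorted(r.stages))}", r.support,
        )
        for r in result.mcrs
    ]
    pd.DataFrame(mcr_rows).to_csv(outdir / "mcr.bed", sep="\t", index=False, header=False)
    pd.DataFrame(
        [
            {
                "stage": t.stage, "scope": t.scope, "scope_id": t.scope_id,
                "de_in": t.table[0][0], "nonde_in": t.table[0][1],
                "de_out": t.table[1][0], "nonde_out": t.table[1][1],
                "p": t.p, "odds_ratio": t.odds_ratio,
            }
            for t in result.tests
        ]
    ).to_csv(outdir / "interaction_tests.tsv", sep="\t", index=False)
    sets = result.stage_sets
    (outdir / "stage_sets.json").write_text(
        json.dumps(
            {
                "early_union": sorted(sets.early_union),
                "late_union": sorted(sets.late_union),
                "late_only": sorted(sets.late_only),
                "early_only": sorted(sets.early_only),
                "all_stage": sorted(sets.all_stage),
                "d_only": sorted(sets.d_only),
            },
            indent=1,
        )
    )
    (outdir / "summary.txt").write_text(result.summary_text)

    manifest = {
        p.name: _sha256(p)
        for p in sorted(outdir.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
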