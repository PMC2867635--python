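"""Fisher enrichment scan, concordance filtering, stage discrimination."""

import math

import numpy as np
import pandas as pd
import pytest

from cnax.cgh import Segment, SegmentCall
from cnax.genome import FeatureAnnotation, GenomicInterval
from cnax.interaction import (
    concordance_filter,
    early_late_discrimination,
    fisher_exact_2x2,
    interaction_genes,
    mirna_segment_interactions,
    region_enrichment,
    scan_interactions,
)


def enumeration_fisher(table):
    """Independent oracle: two-sided p by full enumeration of the
    hypergeometric support with the point-probability rule."""
    (a, b), (c, d) = table
    row1, col1, n = a + b, a + c, a + b + c + d
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)

    def point_prob(x):
        return (
            math.comb(col1, x)
            * math.comb(n - col1, row1 - x)
            / math.comb(n, row1)
        )

    # tie tolerance guards float rounding of exactly-equal point probabilities
    p_obs = point_prob(a)
    return sum(point_prob(x) for x in range(lo, hi + 1)
               if point_prob(x) <= p_obs * (1 + 1e-9))


def _call(chrom, start, end, mean, call, stage):
    return SegmentCall(Segment(GenomicInterval(chrom, start, end), mean, 5, stage), call)


def _annotations(n, chrom="chr1", spacing=1000, width=500):
    return FeatureAnnotation(
        pd.DataFrame(
            {
                "id": [f"g{i}" for i in range(n)],
                "chrom": chrom,
                "start": [i * spacing for i in range(n)],
                "end": [i * spacing + width for i in range(n)],
                "feature_class": "gene",
            }
        )
    )


def _de_frame(ids, de_ids, direction="up"):
    return pd.DataFrame(
        {
            "feature": list(ids),
            "direction": [direction if i in de_ids else "none" for i in ids],
        }
    )


class TestFisherExact:
    @pytest.mark.parametrize(
        "table,expected",
        [
            ([[3, 1], [1, 3]], 0.4857142857),
            ([[5, 5], [5, 5]], 1.0),
            ([[10, 0], [0, 10]], 2 / math.comb(20, 10)),
        ],
    )
    def test_reference_values(self, table, expected):
        p, _ = fisher_exact_2x2(table)
        assert p == pytest.approx(expected, rel=1e-9)

    def test_exhaustive_small_tables_match_enumeration(self):
        for n in range(1, 23):
            for a in range(n + 1):
                for b in range(n + 1 - a):
                    for c in range(n + 1 - a - b):
                        d = n - a - b - c
                        if (a + b) == 0 or (c + d) == 0:
                            continue
                        table = [[a, b], [c, d]]
                        p, _ = fisher_exact_2x2(table)
                        assert p == pytest.approx(
                            enumeration_fisher(table), rel=1e-8, abs=1e-12
                        ), table

    @pytest.mark.parametrize("seed", range(20))
    def test_random_tables_margins_to_forty(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c, d = rng.integers(0, 21, size=4)  # margins up to 40
        if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
            a += 1
            d += 1
        table = [[int(a), int(b)], [int(c), int(d)]]
        p, _ = fisher_exact_2x2(table)
        assert p == pytest.approx(enumeration_fisher(table), rel=1e-8)

    def test_odds_ratio_and_errors(self):
        _, odds = fisher_exact_2x2([[4, 2], [1, 3]])
        assert odds == pytest.approx(6.0)
        _, odds = fisher_exact_2x2([[4, 0], [0, 3]])
        assert odds == np.inf
        _, odds = fisher_exact_2x2([[0, 5], [0, 3]])
        assert np.isnan(odds)
        with pytest.raises(ValueError):
            fisher_exact_2x2([[1, -1], [1, 1]])


class TestRegionEnrichment:
    def test_enriched_region_example(self):
        ids = [f"g{i}" for i in range(1000)]
        region = set(ids[:10])
        de = set(ids[:5]) | set(ids[100:145])  # 5 of 10 inside, 45 outside
        t = region_enrichment(region, _de_frame(ids, de), "A", "segment", "s1")
        assert t.table == ((5, 5), (45, 945))
        assert t.p == pytest.approx(enumeration_fisher(t.table), rel=1e-8)
        assert t.p < 0.05

    def test_all_de_everywhere_is_null(self):
        ids = [f"g{i}" for i in range(50)]
        t = region_enrichment(set(ids[:10]), _de_frame(ids, set(ids)), "A", "segment", "s")
        assert t.p == 1.0

    def test_degenerate_region_skipped_with_warning(self):
        ids = [f"g{i}" for i in range(20)]
        with pytest.warns(UserWarning, match="degenerate"):
            assert region_enrichment(set(ids), _de_frame(ids, set()), "A", "genome", "g") is None
        with pytest.warns(UserWarning, match="degenerate"):
            assert region_enrichment(set(), _de_frame(ids, set()), "A", "segment", "s") is None


class TestScan:
    def test_scope_counting_contract(self):
        ann = _annotations(100)
        calls = [
            _call("chr1", 0, 10_000, 0.3, "gain", "A"),
            _call("chr1", 20_000, 30_000, 0.3, "gain", "A"),
            _call("chr1", 40_000, 50_000, -0.3, "loss", "A"),
        ]
        # place a second chromosome's segment
        ann2 = FeatureAnnotation(
            pd.concat(
                [
                    ann.table,
                    pd.DataFrame(
                        {
                            "id": [f"h{i}" for i in range(20)],
                            "chrom": "chr2",
                            "start": [i * 1000 for i in range(20)],
                            "end": [i * 1000 + 500 for i in range(20)],
                            "feature_class": "gene",
                        }
                    ),
                ],
                ignore_index=True,
            )
        )
        calls.append(_call("chr2", 0, 5_000, 0.4, "gain", "A"))
        de = _de_frame(ann2.table["id"], set(ann2.table["id"][:5]))
        tests = scan_interactions({"A": calls}, {"A": de}, ann2)
        scopes = [(t.scope, t.scope_id) for t in tests]
        assert scopes.count(("genome", "genome")) == 1
        assert sum(s == "chromosome" for s, _ in scopes) == 2
        assert sum(s == "segment" for s, _ in scopes) == 4

    def test_no_aberrant_segments_empty(self):
        ann = _annotations(10)
        calls = [_call("chr1", 0, 10_000, 0.0, "neutral", "A")]
        de = _de_frame(ann.table["id"], set())
        assert scan_interactions({"A": calls}, {"A": de}, ann) == []

    def test_row_order_invariance(self):
        ann = _annotations(60)
        calls = [
            _call("chr1", 0, 10_000, 0.3, "gain", "A"),
            _call("chr1", 30_000, 40_000, -0.3, "loss", "A"),
        ]
        de = _de_frame(ann.table["id"], {f"g{i}" for i in range(0, 60, 7)})
        t1 = scan_interactions({"A": calls}, {"A": de}, ann)
        t2 = scan_interactions(
            {"A": calls[::-1]}, {"A": de.iloc[::-1].reset_index(drop=True)}, ann
        )
        assert [(t.scope, t.scope_id, t.table, t.p) for t in t1] == [
            (t.scope, t.scope_id, t.table, t.p) for t in t2
        ]


class TestConcordance:
    def _setup(self):
        ann = _annotations(10)
        calls = [
            _call("chr1", 0, 3_000, 0.3, "gain", "A"),     # covers g0-g2
            _call("chr1", 3_000, 6_000, -0.3, "loss", "A"),  # covers g3-g5
            _call("chr1", 6_000, 10_000, 0.0, "neutral", "A"),
        ]
        return ann, calls

    def test_gain_up_concordant(self):
        ann, calls = self._setup()
        de = pd.DataFrame({"feature": ["g0"], "direction": ["up"]})
        conc, disc = concordance_filter(de, calls, ann, "A")
        assert [c.gene for c in conc] == ["g0"] and disc == []

    def test_gain_down_discordant(self):
        ann, calls = self._setup()
        de = pd.DataFrame({"feature": ["g1"], "direction": ["down"]})
        conc, disc = concordance_filter(de, calls, ann, "A")
        assert conc == [] and [d.gene for d in disc] == ["g1"]

    def test_loss_down_concordant(self):
        ann, calls = self._setup()
        de = pd.DataFrame({"feature": ["g4"], "direction": ["down"]})
        conc, _ = concordance_filter(de, calls, ann, "A")
        assert [c.gene for c in conc] == ["g4"]

    def test_neutral_region_excluded(self):
        ann, calls = self._setup()
        de = pd.DataFrame({"feature": ["g8"], "direction": ["up"]})
        conc, disc = concordance_filter(de, calls, ann, "A")
        assert conc == [] and disc == []

    def test_highest_amplitude_covering_segment_wins(self):
        ann = _annotations(1, spacing=1000, width=3000)  # g0 spans [0, 3000)
        calls = [
            _call("chr1", 0, 2_000, 0.2, "gain", "A"),
            _call("chr1", 2_000, 4_000, -0.5, "loss", "A"),
        ]
        de = pd.DataFrame({"feature": ["g0"], "direction": ["down"]})
        conc, _ = concordance_filter(de, calls, ann, "A")
        assert [c.gene for c in conc] == ["g0"]  # loss segment has larger |mean|


class TestStageSets:
    def test_late_discriminating_logic(self):
        genes = {
            "A": {"shared", "early1"},
            "B": {"shared"},
            "C": {"shared", "late1", "late2"},
            "D": {"shared", "late1", "donly"},
        }
        sets = early_late_discrimination(genes)
        assert sets.late_only == {"late1", "late2", "donly"}
        assert sets.early_only == {"early1"}
        assert sets.all_stage == {"shared"}
        assert sets.d_only == {"donly"}
        assert sets.d_only <= sets.late_only | sets.late_union

    def test_all_stage_gene_not_discriminating(self):
        genes = {s: {"g"} for s in "ABCD"}
        sets = early_late_discrimination(genes)
        assert sets.late_only == set() and sets.all_stage == {"g"}

    def test_empty_everywhere(self):
        sets = early_late_discrimination({s: set() for s in "ABCD"})
        assert not (sets.late_only or sets.early_only or sets.all_stage or sets.d_only)

    def test_missing_stage_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            early_late_discrimination({"A": set(), "B": set(), "C": set()})

    def test_interaction_genes_require_significance_and_concordance(self):
        ann = _annotations(100)
        calls = [_call("chr1", 0, 30_000, 0.3, "gain", "A")]
        region_ids = {f"g{i}" for i in range(30)}
        de = _de_frame(ann.table["id"], set(list(region_ids)[:20]))
        tests = scan_interactions({"A": calls}, {"A": de}, ann)
        conc, _ = concordance_filter(de, calls, ann, "A")
        seg_tests = [t for t in tests if t.scope == "segment"]
        assert seg_tests[0].p < 0.05
        genes = interaction_genes(tests, conc, "A")
        assert genes == {c.gene for c in conc}
        # with a non-significant scan nothing qualifies
        assert interaction_genes([], conc, "A") == set()


class TestMiRNAInteractions:
    def _ann(self):
        return FeatureAnnotation(
            pd.DataFrame(
                {
                    "id": ["m0", "m1", "m2"],
                    "chrom": "chr1",
                    "start": [500, 15_000, 40_000],
                    "end": [600, 15_100, 40_100],
                    "feature_class": "mirna",
                }
            )
        )

    def test_de_inside_aberrant_segment_interacts_everywhere(self):
        ann = self._ann()
        calls = {s: [_call("chr1", 0, 1_000, 0.3, "gain", s)] for s in "ABCD"}
        de = {s: _de_frame(["m0", "m1", "m2"], {"m0"}) for s in "ABCD"}
        out = mirna_segment_interactions(de, calls, ann)
        assert out["all_stage"] == {"m0"}
        assert out["early_nested_in_late"]

    def test_de_in_neutral_dna_not_interacting(self):
        ann = self._ann()
        calls = {s: [_call("chr1", 0, 1_000, 0.3, "gain", s)] for s in "ABCD"}
        de = {s: _de_frame(["m0", "m1", "m2"], {"m1"}) for s in "ABCD"}
        out = mirna_segment_interactions(de, calls, ann)
        assert all(not v for v in out["per_stage"].values())

    def test_non_de_inside_segment_not_interacting(self):
        ann = self._ann()
        calls = {s: [_call("chr1", 0, 1_000, 0.3, "gain", s)] for s in "ABCD"}
        de = {s: _de_frame(["m0", "m1", "m2"], set()) for s in "ABCD"}
        out = mirna_segment_interactions(de, calls, ann)
        assert out["all_stage"] == set()

    def test_nesting_detection(self):
        ann = self._ann()
        calls = {
            "A": [_call("chr1", 0, 1_000, 0.3, "gain", "A")],
            "B": [_call("chr1", 0, 1_000, 0.3, "gain", "B")],
            "C": [],
            "D": [],
        }
        de = {s: _de_frame(["m0", "m1", "m2"], {"m0"}) for s in "ABCD"}
        out = mirna_segment_interactions(de, calls, ann)
        assert not out["early_nested_in_late"]
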