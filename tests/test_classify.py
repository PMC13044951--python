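"""Zone rule, contrast evidence, BH correction, partition properties."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import k79zones as kz
from k79zones.classify import ZONE_LABELS, classify, zone_summary
from k79zones.stats import bh_adjust, paired_evidence_p
from conftest import run_pipeline


def contrast_frame(l32, l31, l21, q=0.01):
    return pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(len(l32))],
            "lfc_me3_vs_me2": l32,
            "lfc_me3_vs_me1": l31,
            "lfc_me2_vs_me1": l21,
            "p_me3_vs_me2": q,
            "p_me3_vs_me1": q,
            "p_me2_vs_me1": q,
            "q_me3_vs_me2": q,
            "q_me3_vs_me1": q,
            "q_me2_vs_me1": q,
        }
    )


class TestBenjaminiHochberg:
    def test_hand_computed_step_up(self):
        q = bh_adjust([0.01, 0.02, 0.04, 0.5])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04 * 4 / 3, 0.5], rtol=1e-12)

    def test_monotone_and_bounded(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=100)
        q = bh_adjust(p)
        assert np.all((0 <= q) & (q <= 1))
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestPairedEvidence:
    def test_identical_observations_give_p_one(self):
        p, low = paired_evidence_p(np.zeros(8))
        assert p == 1.0 and not low

    def test_constant_twofold_difference_is_significant(self):
        # A = 2B in every window/replicate: log2 diffs all exactly 1
        p, low = paired_evidence_p(np.ones(8))
        assert p < 0.05 and not low

    def test_too_few_observations_flagged(self):
        p, low = paired_evidence_p(np.array([0.5, 0.4]))
        assert p == 1.0 and low


class TestClassifyRule:
    def test_clear_me3_dominance(self):
        calls = classify(contrast_frame([0.8], [1.2], [0.4]))
        assert calls["zone"][0] == "me3"

    def test_total_tie_is_ambiguous(self):
        calls = classify(contrast_frame([0.0], [0.0], [0.0]))
        assert calls["zone"][0] == "ambiguous"

    def test_me3_me2_tie_above_me1_is_mixed_one(self):
        calls = classify(contrast_frame([0.1], [0.95], [0.85]))
        assert calls["zone"][0] == "MixedI"

    def test_me2_me1_tie_above_me3_is_mixed_two(self):
        calls = classify(contrast_frame([-0.9], [-0.95], [-0.05]))
        assert calls["zone"][0] == "MixedII"

    def test_boundary_log2fc_is_not_a_zone_call(self):
        # strict inequality: exactly 0.25 fails the zone test but satisfies
        # the Mixed I tie band
        calls = classify(contrast_frame([0.25], [0.9], [0.65]))
        assert calls["zone"][0] == "MixedI"

    def test_insignificant_q_blocks_zone_call(self):
        calls = classify(contrast_frame([0.8], [1.2], [0.4], q=0.7))
        assert calls["zone"][0] != "me3"

    def test_missing_contrast_column_raises(self):
        df = contrast_frame([0.5], [0.9], [0.4]).drop(columns=["q_me2_vs_me1"])
        with pytest.raises(ValueError, match="missing"):
            classify(df)

    @given(
        st.lists(
            st.tuples(
                st.floats(-2, 2, allow_nan=False),
                st.floats(-2, 2, allow_nan=False),
                st.floats(0, 1, allow_nan=False),
                st.floats(0, 1, allow_nan=False),
                st.floats(0, 1, allow_nan=False),
            ),
            min_size=1,
            max_size=30,
        )
    )
    @settings(max_examples=80, deadline=None)
    def test_every_gene_gets_exactly_one_label(self, rows):
        # lfc_me3_vs_me1 is implied by additivity of the other two so the
        # contrast triple is internally consistent
        l32 = [r[0] for r in rows]
        l21 = [r[1] for r in rows]
        l31 = [a + b for a, b in zip(l32, l21)]
        df = contrast_frame(l32, l31, l21)
        for (col, vals) in (("q_me3_vs_me2", [r[2] for r in rows]),
                            ("q_me3_vs_me1", [r[3] for r in rows]),
                            ("q_me2_vs_me1", [r[4] for r in rows])):
            df[col] = vals
        calls = classify(df)
        assert calls["zone"].isin(ZONE_LABELS).all()
        assert len(calls) == len(rows)

    def test_raising_lfc_threshold_never_adds_zone_calls(self, default_run):
        contrasts = kz.compute_contrasts(default_run["table"])
        counts = []
        for lfc_min in (0.1, 0.25, 0.5):
            calls = classify(contrasts, lfc_min=lfc_min)
            counts.append(int(calls["zone"].isin(("me3", "me2", "me1")).sum()))
        assert counts[0] >= counts[1] >= counts[2]


class TestContrastComputation:
    def test_equal_states_give_zero_lfc_and_p_one(self, noise_free_run):
        """Mixed I genes have me3 == me2 by construction: lfc 0, no evidence
        of gene-body difference."""
        truth = noise_free_run["truth"]
        contrasts = kz.compute_contrasts(noise_free_run["table"])
        ids = truth.loc[truth["true_zone"] == "MixedI", "gene_id"]
        sub = contrasts[contrasts["gene_id"].isin(ids)]
        np.testing.assert_allclose(sub["lfc_me3_vs_me2"], 0.0, atol=1e-9)

    def test_constructed_twofold_gene(self):
        """A gene with state A = 2 x state B in every window and replicate."""
        rows_b, rows_w = [], []
        for rep in (1, 2):
            base = {"gene_id": "g1", "replicate": rep, "me1": 10.0, "me2": 20.5, "me3": 41.5, "H3": 20.5}
            rows_b.append(base)
            for w in range(4):
                jitter = 1.0 + 0.1 * w
                rows_w.append({"gene_id": "g1", "replicate": rep, "window": w,
                               "me1": 10.0 * jitter, "me2": 20.5 * jitter, "me3": 41.5 * jitter, "H3": 20.5 * jitter})
        body = kz.h3_normalize(pd.DataFrame(rows_b).set_index(["gene_id", "replicate"]), 0.5)
        windows = kz.h3_normalize(pd.DataFrame(rows_w).set_index(["gene_id", "replicate", "window"]), 0.5)
        table = kz.StateSignalTable(body, windows, 0.5)
        contrasts = kz.compute_contrasts(table)
        assert contrasts["lfc_me3_vs_me2"][0] == pytest.approx(1.0, abs=1e-6)
        assert contrasts["p_me3_vs_me2"][0] < 0.05  # 8 same-sign observations


class TestZoneSummary:
    def test_empty_zone_reports_missing_median(self):
        calls = classify(contrast_frame([0.8, 0.9], [1.2, 1.1], [0.4, 0.2]))
        summary = zone_summary(calls).set_index("zone")
        assert summary.at["me3", "n"] == 2
        assert summary.at["me1", "n"] == 0
        assert np.isnan(summary.at["me1", "median_dom_vs_runnerup"])

    def test_default_run_recovers_configured_medians(self, default_run):
        """Recovered per-zone dominant-vs-runner-up medians track the generator."""
        summary = default_run["result"].summary().set_index("zone")
        for zone, target in (("me3", 0.778), ("me2", 0.443), ("me1", 0.897)):
            assert summary.at[zone, "median_dom_vs_runnerup"] == pytest.approx(target, abs=0.05)


class TestRecovery:
    def test_accuracy_at_wide_effect_spread(self):
        """>= 90% zone-class accuracy even at effect spread 0.3."""
        cfg = kz.GeneratorConfig(seed=321, effect_spread=0.3)
        run = run_pipeline(cfg)
        assert kz.zone_accuracy(run["result"].calls, run["truth"]) >= 0.90

    def test_mirrored_effects_swap_me3_and_me1_calls(self):
        """Swapping the me3 and me1 class sizes mirrors the call pattern."""
        a = kz.GeneratorConfig(seed=15, n_genes_per_class={"me3": 120, "me2": 0, "me1": 40, "MixedI": 0, "MixedII": 0},
                               zone_effect_medians={"me3": 0.8, "me2": 0.443, "me1": 0.8})
        b = kz.GeneratorConfig(seed=15, n_genes_per_class={"me3": 40, "me2": 0, "me1": 120, "MixedI": 0, "MixedII": 0},
                               zone_effect_medians={"me3": 0.8, "me2": 0.443, "me1": 0.8})
        run_a, run_b = run_pipeline(a), run_pipeline(b)
        counts_a = run_a["result"].zone_counts
        counts_b = run_b["result"].zone_counts
        # the roles of me3 and me1 swap; tolerance covers classification noise
        assert abs(counts_a["me3"] - counts_b["me1"]) <= 4
        assert abs(counts_a["me1"] - counts_b["me3"]) <= 4
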