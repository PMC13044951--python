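"""Generator contracts: determinism, spatial profiles, noise calibration."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import k79zones as kz
from k79zones.synthetic import DEFAULT_ZONE_EFFECT_MEDIANS
from conftest import run_pipeline


def small_config(**kw):
    base = dict(
        seed=42,
        n_genes_per_class={"me3": 40, "me2": 25, "me1": 40, "MixedI": 20, "MixedII": 20},
    )
    base.update(kw)
    return kz.GeneratorConfig(**base)


class TestGenerateGenome:
    def test_single_class_config_yields_only_that_class(self):
        cfg = kz.GeneratorConfig(seed=1, n_genes_per_class={"me3": 10, "me2": 0, "me1": 0, "MixedI": 0, "MixedII": 0})
        genes, truth = kz.generate_genome(cfg)
        assert len(genes) == 10
        assert set(truth["true_zone"]) == {"me3"}

    def test_same_seed_reproduces_byte_identical_outputs(self, tmp_path):
        cfg = small_config()
        out = []
        for run in range(2):
            genes, truth = kz.generate_genome(cfg)
            sheet = kz.build_sample_sheet(cfg)
            tracks = kz.simulate_tracks(genes, truth, sheet, cfg)
            p = tmp_path / f"r{run}.bedgraph"
            kz.write_bedgraph(tracks["me3_WT_plusN_r1"], p)
            tp = tmp_path / f"t{run}.tsv"
            kz.write_table(truth, tp)
            out.append((p.read_bytes(), tp.read_bytes()))
        assert out[0] == out[1]

    def test_inter_gene_gap_at_least_spacing(self, default_run):
        genes = default_run["genes"]
        by_chrom: dict[str, list] = {}
        for g in genes:
            by_chrom.setdefault(g.chrom, []).append(g)
        gaps = []
        for glist in by_chrom.values():
            glist = sorted(glist, key=lambda g: g.start)
            gaps += [b.start - a.end for a, b in zip(glist, glist[1:])]
        assert min(gaps) >= 2000

    def test_infeasible_packing_raises(self):
        cfg = kz.GeneratorConfig(seed=0, n_chromosomes=1, chrom_length=10_000,
                                 n_genes_per_class={"me3": 50, "me2": 0, "me1": 0, "MixedI": 0, "MixedII": 0})
        with pytest.raises(ValueError, match="pack"):
            kz.generate_genome(cfg)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            kz.GeneratorConfig(seed=0, condition_switch={("me3", "me2"): 0.7, ("me3", "me1"): 0.7}).validate()
        with pytest.raises(ValueError):
            kz.GeneratorConfig(seed=0, nb_dispersion=0.0).validate()


class TestStateMeanProfile:
    def test_me3_state_peaks_mid_body_in_me3_zone(self):
        assert kz.state_mean_profile("me3", "me3", 0.5) > kz.state_mean_profile("me3", "me3", 0.0)

    def test_me1_state_flank_exceeds_body_in_me3_zone(self):
        assert kz.state_mean_profile("me3", "me1", -0.05) > kz.state_mean_profile("me3", "me1", 0.5)

    @pytest.mark.parametrize("zone, dominant, runner", [("me3", "me3", "me2"), ("me2", "me2", "me1"), ("me1", "me1", "me2")])
    def test_body_integral_ratio_matches_configured_median(self, zone, dominant, runner):
        x = np.linspace(0.0, 1.0, 4001)
        dom = np.trapezoid(kz.state_mean_profile(zone, dominant, x), x)
        run = np.trapezoid(kz.state_mean_profile(zone, runner, x), x)
        assert dom / run == pytest.approx(2.0 ** DEFAULT_ZONE_EFFECT_MEDIANS[zone], rel=1e-6)

    def test_unknown_pair_raises(self):
        with pytest.raises(ValueError):
            kz.state_mean_profile("me3", "me4", 0.5)


class TestSimulateTracks:
    def test_poisson_limit_sample_mean_matches_expectation(self):
        """With dispersion -> inf, bin counts are Poisson around the profile mean."""
        cfg = small_config(nb_dispersion=float("inf"))
        genes, truth = kz.generate_genome(cfg)
        sheet = kz.build_sample_sheet(cfg)
        tracks = kz.simulate_tracks(genes, truth, sheet, cfg)
        noise_free = kz.GeneratorConfig(**{**cfg.__dict__, "noise_free": True})
        expected = kz.simulate_tracks(genes, truth, sheet, noise_free)
        obs = np.concatenate([tracks["H3_WT_plusN_r1"].values[c] for c in tracks["H3_WT_plusN_r1"].values])
        exp = np.concatenate([expected["H3_WT_plusN_r1"].values[c] for c in expected["H3_WT_plusN_r1"].values])
        n = obs.size
        assert n > 10_000
        se = np.sqrt(exp.sum()) / n  # Poisson SE of the mean
        assert abs(obs.mean() - exp.mean()) < 2 * se

    def test_missing_core_mark_raises(self):
        cfg = small_config()
        genes, truth = kz.generate_genome(cfg)
        sheet = kz.build_sample_sheet(cfg)
        with pytest.raises(ValueError, match="missing marks"):
            kz.simulate_tracks(genes, truth, sheet[sheet["mark"] != "H3"], cfg)

    def test_null_genotype_effect_gives_uniform_rank_sum_p(self):
        """With zero genotype effects, per-gene WT-vs-mutant tests are null.

        Window x replicate observations per gene feed a rank-sum test; the
        resulting 500 p-values should be indistinguishable from U(0,1).
        """
        cfg = kz.GeneratorConfig(
            seed=77,
            genotypes=("WT", "nullmut"),
            genotype_effects={"nullmut": {}},
            n_genes_per_class={"me3": 150, "me2": 100, "me1": 150, "MixedI": 50, "MixedII": 50},
        )
        genes, truth = kz.generate_genome(cfg)
        sheet = kz.build_sample_sheet(cfg)
        tracks = {sid: kz.normalize_depth(t) for sid, t in kz.simulate_tracks(genes, truth, sheet, cfg).items()}
        wt = kz.build_state_table(tracks, sheet, genes, "WT", "plusN")
        mut = kz.build_state_table(tracks, sheet, genes, "nullmut", "plusN")
        pvals = []
        wt_win = wt.windows["log2_me2"].groupby(level="gene_id")
        mut_win = mut.windows["log2_me2"].groupby(level="gene_id")
        for (gid, a), (_, b) in zip(wt_win, mut_win):
            pvals.append(kz.wilcoxon_rank_sum(a.to_numpy(), b.to_numpy()))
        ks = sps.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_rad6_default_reduces_me1_in_me1_zone_by_configured_median(self, rad6_run):
        """rad6d me1-zone H3K79me1 drops ~2.7-fold (median log2FC -1.44)."""
        truth = rad6_run["truth"]
        ids = truth.loc[truth["true_zone"] == "me1", "gene_id"]
        wt = rad6_run["wt"].rep_mean().loc[ids, "log2_me1"]
        mut = rad6_run["mut"].rep_mean().loc[ids, "log2_me1"]
        assert float((mut - wt).median()) == pytest.approx(-1.44, abs=0.1)


class TestNoiseFreeMode:
    def test_noise_free_classification_recovers_every_gene(self, noise_free_run):
        calls = noise_free_run["result"].calls
        truth = noise_free_run["truth"]
        merged = calls.merge(truth[["gene_id", "true_zone"]], on="gene_id")
        assert (merged["zone"] == merged["true_zone"]).all()

    def test_noise_free_medians_equal_configured_values_exactly(self, noise_free_run):
        summary = noise_free_run["result"].summary().set_index("zone")
        for zone, target in DEFAULT_ZONE_EFFECT_MEDIANS.items():
            assert summary.at[zone, "median_dom_vs_runnerup"] == pytest.approx(target, abs=1e-6)


class TestMonotonicity:
    def test_stronger_zone_separation_never_hurts_accuracy(self):
        """Classification accuracy is non-decreasing in the zone-effect medians."""
        accs = []
        for scale in (0.35, 0.7, 1.0):
            medians = {z: v * scale for z, v in DEFAULT_ZONE_EFFECT_MEDIANS.items()}
            cfg = small_config(zone_effect_medians=medians, seed=99)
            run = run_pipeline(cfg)
            accs.append(kz.zone_accuracy(run["result"].calls, run["truth"]))
        assert accs[0] <= accs[1] <= accs[2]


class TestSimulateExpression:
    def test_null_de_spec_false_positive_rate_below_nominal(self):
        """No true DE: the call rate stays below the analytic t-tail bound."""
        cfg = small_config(de_spec={z: (0.0, 0.0, 0.0) for z in ("me3", "me2", "me1", "MixedI", "MixedII")},
                           n_genes_per_class={"me3": 500, "me2": 250, "me1": 500, "MixedI": 125, "MixedII": 125})
        _, truth = kz.generate_genome(cfg)
        expr = kz.simulate_expression(truth, cfg)
        de = kz.call_de(expr, mut="dot1d", condition="minusN")
        rate = float((de["status"] != "unchanged").mean())
        # fold-change gate alone: two-sided t tail at log2(1.4) with the
        # generator's replicate sd and the Welch df of a 2+2 design
        nominal = 2 * sps.t.sf(np.log2(1.4) / cfg.expression_rep_sd, df=2)
        n = len(de)
        assert rate <= nominal + 3 * np.sqrt(nominal * (1 - nominal) / n)

    def test_true_down_gene_is_depressed_in_expectation(self):
        cfg = small_config()
        _, truth = kz.generate_genome(cfg)
        expr = kz.simulate_expression(truth, cfg)
        piv = expr[expr["condition"] == "minusN"].pivot_table(index="gene_id", columns="genotype", values="value")
        down_ids = truth.loc[truth["true_de_status"] == "down", "gene_id"]
        ratios = piv.loc[down_ids, "dot1d"] / piv.loc[down_ids, "WT"]
        assert ratios.median() <= 1 / 1.4

    def test_configured_me3_down_fraction_is_recovered(self):
        """A DE spec with 92% down in the me3 zone reproduces that crosstab share."""
        cfg = kz.GeneratorConfig(seed=31,
                                 n_genes_per_class={"me3": 860, "me2": 400, "me1": 840, "MixedI": 200, "MixedII": 200},
                                 n_chromosomes=32)
        _, truth = kz.generate_genome(cfg)
        expr = kz.simulate_expression(truth, cfg)
        de = kz.call_de(expr, mut="dot1d", condition="minusN")
        zone_calls = truth[["gene_id"]].assign(zone=truth["true_zone"])
        ct = kz.zone_de_crosstab(zone_calls, de)
        n_de = ct.zone_total("me3")
        target = 0.198 / (0.198 + 0.017)  # down share implied by the DE spec
        band = 2.58 * np.sqrt(target * (1 - target) / n_de)
        assert ct.counts.at["me3", "down"] / n_de == pytest.approx(target, abs=band)
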