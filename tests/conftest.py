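"""Shared fixtures: synthetic runs reused across test modules.

The expensive full-pipeline simulations are session-scoped; individual tests
read from them without re-simulating.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import k79zones as kz


def run_pipeline(config: kz.GeneratorConfig, genotype: str = "WT", condition: str = "plusN"):
    """Generate -> simulate -> normalize -> quantify -> classify one cohort."""
    genes, truth = kz.generate_genome(config)
    sheet = kz.build_sample_sheet(config)
    tracks = {sid: kz.normalize_depth(t) for sid, t in kz.simulate_tracks(genes, truth, sheet, config).items()}
    table = kz.build_state_table(tracks, sheet, genes, genotype, condition, pseudocount=config.pseudocount)
    result = kz.ZoneClassifier(table).fit()
    return {"config": config, "genes": genes, "truth": truth, "sheet": sheet,
            "tracks": tracks, "table": table, "result": result}


@pytest.fixture(scope="session")
def default_run():
    """1500 genes under generator defaults (2 replicates, NB dispersion 10)."""
    return run_pipeline(kz.GeneratorConfig(seed=123))


@pytest.fixture(scope="session")
def noise_free_run():
    """Deterministic expected-signal run: classification must be exact."""
    config = kz.GeneratorConfig(
        seed=7,
        noise_free=True,
        n_genes_per_class={"me3": 60, "me2": 40, "me1": 60, "MixedI": 40, "MixedII": 40},
    )
    return run_pipeline(config)


@pytest.fixture(scope="session")
def rad6_run():
    """WT + rad6d cohorts with the default redistribution effect table."""
    config = kz.GeneratorConfig(
        seed=11,
        genotypes=("WT", "rad6d"),
        n_genes_per_class={"me3": 500, "me2": 500, "me1": 500, "MixedI": 100, "MixedII": 100},
        n_chromosomes=24,
    )
    genes, truth = kz.generate_genome(config)
    sheet = kz.build_sample_sheet(config)
    tracks = {sid: kz.normalize_depth(t) for sid, t in kz.simulate_tracks(genes, truth, sheet, config).items()}
    wt = kz.build_state_table(tracks, sheet, genes, "WT", "plusN", pseudocount=config.pseudocount)
    mut = kz.build_state_table(tracks, sheet, genes, "rad6d", "plusN", pseudocount=config.pseudocount)
    calls = kz.ZoneClassifier(wt).fit().calls
    shifts = kz.ZoneShiftModel(wt, mut, calls).fit()
    return {"config": config, "truth": truth, "wt": wt, "mut": mut, "calls": calls, "shifts": shifts}


@pytest.fixture(scope="session")
def switch_run():
    """Two conditions; 30% of me3-zone genes switch to the me2 zone under the second."""
    config = kz.GeneratorConfig(
        seed=5,
        conditions=("plusN", "minusN"),
        condition_switch={("me3", "me2"): 0.30},
        n_genes_per_class={"me3": 500, "me2": 150, "me1": 150, "MixedI": 50, "MixedII": 50},
    )
    genes, truth = kz.generate_genome(config)
    sheet = kz.build_sample_sheet(config)
    tracks = {sid: kz.normalize_depth(t) for sid, t in kz.simulate_tracks(genes, truth, sheet, config).items()}
    tables = {
        c: kz.build_state_table(tracks, sheet, genes, "WT", c, pseudocount=config.pseudocount)
        for c in ("plusN", "minusN")
    }
    calls = {c: kz.ZoneClassifier(t).fit().calls for c, t in tables.items()}
    dyn = kz.ZoneDynamics(calls["plusN"], calls["minusN"]).fit()
    return {"config": config, "truth": truth, "tables": tables, "calls": calls, "dynamics": dyn}


@pytest.fixture
def toy_genes():
    return [
        kz.GeneModel("GA", "chrT", 1000, 2000, "+"),
        kz.GeneModel("GB", "chrT", 4000, 5500, "-"),
        kz.GeneModel("GC", "chrT", 8000, 8600, "+"),
    ]


@pytest.fixture
def constant_track():
    sizes = {"chrT": 12_000}
    return kz.CoverageTrack(
        sample_id="const",
        bin_width=50,
        values={"chrT": np.full(240, 4.0)},
        total_raw_reads=10_000_000,
        chrom_sizes=sizes,
        normalized=True,
    )


def brute_force_rank_sum_p(a, b) -> float:
    """Independent oracle: exhaustive permutation enumeration of rank sums.

    Two-sided p as the fraction of all label reassignments whose rank-sum
    statistic deviates from its mean at least as much as observed; midranks
    for ties.
    """
    import itertools

    from scipy.stats import rankdata

    pooled = np.concatenate([np.asarray(a, float), np.asarray(b, float)])
    ranks = rankdata(pooled)
    na, n = len(a), len(pooled)
    mu = na * (n + 1) / 2.0
    t_obs = ranks[: len(a)].sum()
    hits = total = 0
    for combo in itertools.combinations(range(n), na):
        t = ranks[list(combo)].sum()
        total += 1
        if abs(t - mu) >= abs(t_obs - mu) - 1e-12:
            hits += 1
    return hits / total
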