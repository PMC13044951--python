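"""Synthetic multi-mark ChIP-seq and expression data with ground truth.

Emulates the statistical structure the zone analysis assumes: three H3K79
methylation states with zone-specific dominance, zone-specific spatial
profiles across gene bodies and 1 kb flanks, negative-binomial replicate
noise, genotype-specific redistribution of states across zones, condition-
dependent zone switching, and zone-structured differential expression.

Every gene carries a ground-truth record so downstream stages can be tested
for parameter recovery.  All draws flow from a single seed through keyed
PRNG substreams, so adding samples never perturbs existing ones.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .genome_io import CORE_MARKS, CoverageTrack, GeneModel

ZONES = ("me3", "me2", "me1", "MixedI", "MixedII")
STATES = ("me1", "me2", "me3")

#: median dominant-vs-runner-up log2 fold-change per zone (gene-body,
#: H3-normalized): me3 vs me2 in the me3 zone, me2 vs me1 in the me2 zone,
#: me1 vs me2 in the me1 zone.
DEFAULT_ZONE_EFFECT_MEDIANS = {"me3": 0.778, "me2": 0.443, "me1": 0.897}

#: (dominant, runner-up, third) state per zone; Mixed classes have a
#: co-dominant pair (me2 ~ me3 > me1 for Mixed I, me1 ~ me2 > me3 for Mixed II).
ZONE_ROLES = {
    "me3": ("me3", "me2", "me1"),
    "me2": ("me2", "me1", "me3"),
    "me1": ("me1", "me2", "me3"),
    "MixedI": (("me3", "me2"), "me1"),
    "MixedII": (("me1", "me2"), "me3"),
}

#: log2 gap between the runner-up (or co-dominant pair) and the third state.
#: Strong anti-correlation of me3/me1 in each other's zones; in the me2 zone
#: the two minority states sit at comparable levels, me3 slightly lower so
#: the runner-up identity (me1) is stable.
THIRD_STATE_GAP = {"me3": 1.0, "me2": 0.3, "me1": 1.0, "MixedI": 0.6, "MixedII": 0.6}

#: genotype -> (zone, state) -> log2 shift of the state's gene-body level in
#: that zone.  rad6d models loss of Rad6-Bre1 H2B ubiquitination; sas2d loss
#: of Sas2 H4K16 acetylation.  The rad6d (me3, me3) value of -3.0 is a
#: synthetic stand-in for the near-complete loss of H3K79me3 (no published
#: magnitude); the remaining values are the reported redistribution medians.
DEFAULT_GENOTYPE_EFFECTS = {
    "rad6d": {
        ("me1", "me1"): -1.44,
        ("me2", "me2"): -0.601,
        ("me3", "me1"): +1.42,
        ("me3", "me2"): +0.328,
        ("me3", "me3"): -3.0,
    },
    "sas2d": {
        ("me1", "me1"): -1.11,
        ("me3", "me1"): +0.415,
    },
}

#: (origin zone, destination zone) -> fraction switching under the second
#: condition.  Chosen so ~2/3 of genes keep their zone, me3-origin genes are
#: the most stable, and net flow is biased toward the me2 zone.
DEFAULT_CONDITION_SWITCH = {
    ("me3", "me2"): 0.15,
    ("me3", "me1"): 0.05,
    ("me2", "me3"): 0.20,
    ("me2", "me1"): 0.20,
    ("me1", "me2"): 0.35,
    ("me1", "MixedII"): 0.10,
    ("MixedI", "me3"): 0.15,
    ("MixedI", "me2"): 0.15,
    ("MixedII", "me2"): 0.20,
    ("MixedII", "me1"): 0.15,
}

#: zone -> (fraction up, fraction down, log2 effect) of differential
#: expression in the mutant under the second condition.  Fractions follow the
#: observed zone x DE structure: mostly down-regulation in the me3/me2 zones,
#: an even up/down split in the me1 zone.
DEFAULT_DE_SPEC = {
    "me3": (0.017, 0.198, 1.2),
    "me2": (0.084, 0.180, 1.2),
    "me1": (0.139, 0.142, 1.2),
    "MixedI": (0.12, 0.12, 1.2),
    "MixedII": (0.12, 0.12, 1.2),
}

#: class sizes for a 1500-gene genome, proportional to the observed zone
#: partition of the 5750-gene annotation.
DEFAULT_CLASS_SIZES = {"me3": 430, "me2": 199, "me1": 422, "MixedI": 235, "MixedII": 214}


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic genome.

    Defaults are the study conditions the analysis is validated against; see
    the methods note for the rationale behind each numeric choice.
    """

    n_genes_per_class: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_SIZES))
    gene_length_range: tuple = (500, 2500)
    zone_effect_medians: dict = field(default_factory=lambda: dict(DEFAULT_ZONE_EFFECT_MEDIANS))
    effect_spread: float = 0.12
    amplitude_spread: float = 0.25
    base_signal_rpm: float = 60.0
    background_rpm: float = 5.0
    nb_dispersion: float = 10.0
    n_replicates: int = 2
    genotype_effects: dict = field(default_factory=lambda: {g: dict(v) for g, v in DEFAULT_GENOTYPE_EFFECTS.items()})
    condition_switch: dict = field(default_factory=lambda: dict(DEFAULT_CONDITION_SWITCH))
    de_spec: dict = field(default_factory=lambda: dict(DEFAULT_DE_SPEC))
    genotypes: tuple = ("WT",)
    conditions: tuple = ("plusN",)
    expression_genotypes: tuple = ("WT", "dot1d")
    expression_conditions: tuple = ("plusN", "minusN")
    expression_baseline_log2: float = 6.6
    expression_baseline_spread: float = 1.2
    expression_condition_spread: float = 0.8
    expression_rep_sd: float = 0.15
    pseudocount: float = 0.5
    bin_width: int = 50
    flank_bp: int = 1000
    gene_spacing: int = 2000
    n_chromosomes: int = 16
    chrom_length: int = 400_000
    covariate_marks: tuple = ()
    n_outliers: int = 0
    outlier_covariate_shift: float = 2.5
    noise_free: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0 (use inf for the Poisson limit)")
        for zone in self.n_genes_per_class:
            if zone not in ZONES:
                raise ValueError(f"unknown class {zone!r}")
        per_origin: dict[str, float] = {}
        for (origin, dest), frac in self.condition_switch.items():
            if not 0 <= frac <= 1:
                raise ValueError(f"switch fraction {frac} for {origin}->{dest} outside [0,1]")
            per_origin[origin] = per_origin.get(origin, 0.0) + frac
        for origin, total in per_origin.items():
            if total > 1 + 1e-9:
                raise ValueError(f"switch fractions for origin {origin} sum to {total} > 1")
        for zone, (up, down, _eff) in self.de_spec.items():
            if not (0 <= up <= 1 and 0 <= down <= 1 and up + down <= 1):
                raise ValueError(f"de_spec fractions for {zone} invalid")
        lo, hi = self.gene_length_range
        if not (0 < lo <= hi):
            raise ValueError("gene_length_range must satisfy 0 < min <= max")

    def to_dict(self) -> dict:
        """JSON/YAML-friendly dict: tuple keys become 'a:b' strings."""
        d = asdict(self)
        d["genotype_effects"] = {
            g: {f"{z}:{s}": v for (z, s), v in eff.items()} for g, eff in d["genotype_effects"].items()
        }
        d["condition_switch"] = {f"{o}:{dest}": v for (o, dest), v in d["condition_switch"].items()}
        d["de_spec"] = {z: list(v) for z, v in d["de_spec"].items()}
        for key in ("gene_length_range", "genotypes", "conditions", "expression_genotypes",
                    "expression_conditions", "covariate_marks"):
            d[key] = list(d[key])
        return d


@dataclass
class SyntheticTruth:
    """Ground-truth labels for one generated gene (one row of the truth table)."""

    gene_id: str
    true_zone: str
    true_destination_zone: str
    true_de_status: str
    off_me1: float
    off_me2: float
    off_me3: float
    amplitude: float
    covariate_level: float
    outlier: bool


def _substream(config: GeneratorConfig, *keys) -> np.random.Generator:
    ints = [config.seed] + [zlib.crc32(str(k).encode()) for k in keys]
    return np.random.default_rng(np.random.SeedSequence(ints))


def gene_state_offset(zone: str, state: str, effect: float, gaps: dict | None = None) -> float:
    """log2 level of ``state`` relative to the zone's runner-up state.

    Dominant state: +effect; runner-up (or co-dominant pair): 0; third state:
    minus the zone's gap.
    """
    gaps = gaps or THIRD_STATE_GAP
    roles = ZONE_ROLES[zone]
    if zone in ("MixedI", "MixedII"):
        pair, third = roles
        return -gaps[zone] if state == third else 0.0
    dom, runner, third = roles
    if state == dom:
        return effect
    if state == runner:
        return 0.0
    return -gaps[zone]


# ---------------------------------------------------------------------------
# spatial profiles


def _flank_distance(x: np.ndarray) -> np.ndarray:
    # distance outside the body, in flank units (flank spans one unit)
    return np.where(x < 0, -x, np.where(x > 1, x - 1, 0.0))


def _shape_plateau(x: np.ndarray) -> np.ndarray:
    d = _flank_distance(x)
    return np.where(d == 0, 1.0, 0.15 + 0.85 * np.exp(-((d / 0.25) ** 2)))


def _shape_moderate(x: np.ndarray) -> np.ndarray:
    d = _flank_distance(x)
    return np.where(d == 0, 1.0, 0.3 + 0.7 * np.exp(-((d / 0.35) ** 2)))


def _shape_midbump(x: np.ndarray) -> np.ndarray:
    d = _flank_distance(x)
    body = 0.8 + 0.51 * np.exp(-(((x - 0.5) / 0.22) ** 2))
    return np.where(d == 0, body, 0.8 * (0.2 + 0.8 * np.exp(-((d / 0.3) ** 2))))


def _shape_flankhigh(x: np.ndarray) -> np.ndarray:
    d = _flank_distance(x)
    return np.where(d == 0, 1.0, 0.5 + 3.5 * np.exp(-((d / 0.5) ** 2)))


_ZONE_STATE_SHAPES = {
    ("me3", "me3"): _shape_midbump,
    ("me3", "me2"): _shape_moderate,
    ("me3", "me1"): _shape_flankhigh,
    ("me2", "me2"): _shape_plateau,
    ("me2", "me1"): _shape_moderate,
    ("me2", "me3"): _shape_moderate,
    ("me1", "me1"): _shape_plateau,
    ("me1", "me2"): _shape_moderate,
    ("me1", "me3"): _shape_moderate,
    ("MixedI", "me3"): _shape_midbump,
    ("MixedI", "me2"): _shape_moderate,
    ("MixedI", "me1"): _shape_flankhigh,
    ("MixedII", "me1"): _shape_plateau,
    ("MixedII", "me2"): _shape_plateau,
    ("MixedII", "me3"): _shape_moderate,
}

_SHAPE_NORM_CACHE: dict[tuple[str, str], float] = {}


def _shape_norm(zone: str, state: str) -> float:
    """Body-mean of the raw shape, so normalized shapes average 1 over the body."""
    key = (zone, state)
    if key not in _SHAPE_NORM_CACHE:
        grid = np.linspace(0.0, 1.0, 8193)
        _SHAPE_NORM_CACHE[key] = float(np.trapezoid(_ZONE_STATE_SHAPES[key](grid), grid))
    return _SHAPE_NORM_CACHE[key]


def state_mean_profile(
    true_zone: str,
    state: str,
    relative_position,
    zone_effect_medians: dict | None = None,
    gaps: dict | None = None,
):
    """Expected signal multiplier at a scaled position for a (zone, state) pair.

    ``relative_position`` runs over [-1, 2]: the upstream 1 kb flank maps to
    [-1, 0), the scaled gene body to [0, 1), and the downstream flank to
    [1, 2].  The dominant state's body mean is 2^median above the runner-up's,
    so noise-free gene-body means reproduce the configured zone-effect
    medians exactly.
    """
    medians = zone_effect_medians or DEFAULT_ZONE_EFFECT_MEDIANS
    if state == "H3":
        return np.ones_like(np.asarray(relative_position, dtype=float))
    key = (true_zone, state)
    if key not in _ZONE_STATE_SHAPES:
        raise ValueError(f"unknown (zone, state) pair {key}")
    x = np.asarray(relative_position, dtype=float)
    shape = _ZONE_STATE_SHAPES[key](x) / _shape_norm(true_zone, state)
    effect = medians[true_zone] if true_zone in medians else 0.0
    level = 2.0 ** gene_state_offset(true_zone, state, effect, gaps)
    out = level * shape
    return float(out) if np.isscalar(relative_position) else out


# ---------------------------------------------------------------------------
# genome + truth


def generate_genome(config: GeneratorConfig) -> tuple[list[GeneModel], pd.DataFrame]:
    """Place genes on synthetic chromosomes and draw their ground truth.

    Genes are spaced >= ``gene_spacing`` bp apart (so 1 kb flanks never
    overlap), lengths are uniform in ``gene_length_range`` rounded to the bin
    width, strands alternate deterministically, and everything is a pure
    function of the config (byte-identical under a fixed seed).
    """
    config.validate()
    rng = _substream(config, "genome")
    labels = [z for z, n in config.n_genes_per_class.items() for _ in range(n)]
    order = rng.permutation(len(labels))
    labels = [labels[i] for i in order]
    n_genes = len(labels)
    if n_genes == 0:
        return [], pd.DataFrame()

    bw = config.bin_width
    lo, hi = config.gene_length_range
    lengths = rng.integers(lo, hi + 1, size=n_genes)
    lengths = np.maximum((lengths // bw) * bw, 2 * bw)
    spacing = ((config.gene_spacing + bw - 1) // bw) * bw
    margin = ((config.flank_bp + bw - 1) // bw) * bw

    genes: list[GeneModel] = []
    chrom_idx, cursor = 0, margin
    for i, (zone, length) in enumerate(zip(labels, lengths)):
        if cursor + length + margin > config.chrom_length:
            chrom_idx += 1
            cursor = margin
            if chrom_idx >= config.n_chromosomes:
                raise ValueError(
                    f"cannot pack {n_genes} genes into {config.n_chromosomes} chromosomes "
                    f"of {config.chrom_length} bp"
                )
        strand = "+" if i % 2 == 0 else "-"
        genes.append(GeneModel(f"SYNG{i:05d}", f"chrS{chrom_idx + 1:02d}", cursor, cursor + int(length), strand))
        cursor += int(length) + spacing

    # ground truth draws
    spread = 0.0 if config.noise_free else config.effect_spread
    amp_spread = 0.0 if config.noise_free else config.amplitude_spread
    records = []
    outlier_budget = config.n_outliers
    for gene, zone in zip(genes, labels):
        effect = config.zone_effect_medians.get(zone, 0.0)
        if spread > 0 and zone in config.zone_effect_medians:
            effect = max(float(rng.normal(effect, spread)), 0.05)
        amplitude = float(rng.normal(0.0, amp_spread)) if amp_spread > 0 else 0.0
        offsets = {s: gene_state_offset(zone, s, effect) for s in STATES}
        # condition switch
        dests, probs = [zone], [1.0]
        for (origin, dest), frac in config.condition_switch.items():
            if origin == zone and frac > 0:
                dests.append(dest)
                probs.append(frac)
                probs[0] -= frac
        destination = str(rng.choice(dests, p=np.maximum(probs, 0.0) / np.sum(np.maximum(probs, 0.0))))
        # DE status
        up, down, _eff = config.de_spec.get(zone, (0.0, 0.0, 0.0))
        de_status = str(rng.choice(["up", "down", "none"], p=[up, down, max(1.0 - up - down, 0.0)]))
        # covariate (e.g. H2Bubi): mildly tracks the me3 offset, outliers high
        cov = 0.3 * offsets["me3"] + (0.0 if config.noise_free else float(rng.normal(0.0, 0.3)))
        outlier = False
        if outlier_budget > 0 and zone == "me2":
            outlier = True
            cov += config.outlier_covariate_shift
            outlier_budget -= 1
        records.append(
            SyntheticTruth(
                gene_id=gene.gene_id,
                true_zone=zone,
                true_destination_zone=destination,
                true_de_status=de_status,
                off_me1=offsets["me1"],
                off_me2=offsets["me2"],
                off_me3=offsets["me3"],
                amplitude=amplitude,
                covariate_level=cov,
                outlier=outlier,
            )
        )
    truth = pd.DataFrame([asdict(r) for r in records])
    # per-gene drawn effect on the dominant state, recoverable from offsets
    return genes, truth


def chrom_sizes_for(genes: list[GeneModel], config: GeneratorConfig) -> dict[str, int]:
    """Chromosome sizes implied by a generated gene set (fixed per-chrom length)."""
    chroms = sorted({g.chrom for g in genes})
    return {c: config.chrom_length for c in chroms}


def build_sample_sheet(config: GeneratorConfig) -> pd.DataFrame:
    """Core marks (plus configured covariates) x genotypes x conditions x replicates."""
    rows = []
    for genotype in config.genotypes:
        for condition in config.conditions:
            for mark in CORE_MARKS + tuple(config.covariate_marks):
                for rep in range(1, config.n_replicates + 1):
                    sid = f"{mark}_{genotype}_{condition}_r{rep}"
                    rows.append(
                        {
                            "sample_id": sid,
                            "mark": mark,
                            "genotype": genotype,
                            "condition": condition,
                            "replicate": rep,
                            "path": f"tracks/{sid}.bedgraph",
                            "total_reads": 10_000_000,
                        }
                    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# coverage simulation


def _gene_zone_for_condition(row, config: GeneratorConfig, condition: str) -> str:
    if len(config.conditions) > 1 and condition == config.conditions[1]:
        return row.true_destination_zone
    return row.true_zone


def _expected_track(
    genes: list[GeneModel],
    truth: pd.DataFrame,
    config: GeneratorConfig,
    mark: str,
    genotype: str,
    condition: str,
    sizes: dict[str, int],
) -> dict[str, np.ndarray]:
    """Per-bin expected RPM for one sample, before noise."""
    bw = config.bin_width
    base = config.base_signal_rpm
    pc = config.pseudocount
    arrays = {c: np.full(-(-size // bw), base if mark == "H3" else config.background_rpm) for c, size in sizes.items()}
    if mark == "H3":
        return arrays
    truth_by_id = truth.set_index("gene_id")
    geno_eff = config.genotype_effects.get(genotype, {})
    fbins = config.flank_bp // bw
    for g in genes:
        row = truth_by_id.loc[g.gene_id]
        zone = _gene_zone_for_condition(row, config, condition)
        if mark in STATES:
            # the per-gene dominant-effect magnitude travels with the gene:
            # stored offsets belong to true_zone; a Mixed-origin gene switching
            # into a zone uses the configured median for that zone
            if row.true_zone in ("me3", "me2", "me1"):
                effect = float(row[f"off_{ZONE_ROLES[row.true_zone][0]}"])
            else:
                effect = config.zone_effect_medians.get(zone, 0.0)
            offset = gene_state_offset(zone, mark, effect) + row.amplitude
            offset += geno_eff.get((zone, mark), 0.0)
            shape_fn = _ZONE_STATE_SHAPES[(zone, mark)]
        else:
            offset = row.covariate_level + row.amplitude
            shape_fn = _shape_plateau
        s = max((base + pc) * 2.0**offset - pc, 0.0)
        vec = arrays[g.chrom]
        b0, b1 = g.start // bw, g.end // bw
        centers = (np.arange(b0, b1) + 0.5) * bw
        xb = (centers - g.start) / (g.end - g.start)
        body = shape_fn(xb)
        mean_body = body.mean()
        vec[b0:b1] = body * (s / mean_body) if mean_body > 0 else 0.0
        # flanks: shape relative to the (normalized) body mean
        norm = _shape_norm(zone, mark) if mark in STATES else _shape_norm("me1", "me1")
        for fstart in (b0 - fbins, b1):
            f0, f1 = max(fstart, 0), min(fstart + fbins, len(vec))
            if f1 <= f0:
                continue
            centers = (np.arange(f0, f1) + 0.5) * bw
            xf = np.where(
                centers < g.start,
                (centers - g.start) / config.flank_bp,
                1.0 + (centers - g.end) / config.flank_bp,
            )
            flank_vals = shape_fn(xf) / norm * s
            vec[f0:f1] = np.maximum(vec[f0:f1], flank_vals)
    return arrays


def simulate_tracks(
    genes: list[GeneModel],
    truth: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    config: GeneratorConfig,
) -> dict[str, CoverageTrack]:
    """Draw one raw-count CoverageTrack per sample-sheet row.

    Per-bin counts are negative binomial around the expected profile
    (``nb_dispersion = inf`` gives the Poisson limit; ``noise_free`` yields
    the expectation exactly).  PRNG substreams are keyed by (sample_id,
    chromosome).
    """
    config.validate()
    sizes = chrom_sizes_for(genes, config)
    # every (genotype, condition, replicate) must carry all four core marks
    for (genotype, condition, rep), grp in sample_sheet.groupby(["genotype", "condition", "replicate"]):
        missing = set(CORE_MARKS) - set(grp["mark"])
        if missing:
            raise ValueError(f"sample sheet missing marks {sorted(missing)} for ({genotype}, {condition}, r{rep})")
    tracks: dict[str, CoverageTrack] = {}
    for _, srow in sample_sheet.iterrows():
        expected = _expected_track(genes, truth, config, srow["mark"], srow["genotype"], srow["condition"], sizes)
        total = int(srow.get("total_reads", 10_000_000))
        scale = total / 10_000_000
        values: dict[str, np.ndarray] = {}
        for chrom, mu in expected.items():
            mu = mu * scale
            if config.noise_free:
                values[chrom] = mu.astype(float)
                continue
            rng = _substream(config, "tracks", srow["sample_id"], chrom)
            if np.isinf(config.nb_dispersion):
                values[chrom] = rng.poisson(mu).astype(float)
            else:
                r = config.nb_dispersion
                p = np.where(mu > 0, r / (r + mu), 1.0)
                values[chrom] = rng.negative_binomial(r, p).astype(float)
        tracks[srow["sample_id"]] = CoverageTrack(
            sample_id=srow["sample_id"],
            bin_width=config.bin_width,
            values=values,
            total_raw_reads=total,
            chrom_sizes=dict(sizes),
            normalized=False,
        )
    return tracks


# ---------------------------------------------------------------------------
# expression simulation


def simulate_expression(truth: pd.DataFrame, config: GeneratorConfig) -> pd.DataFrame:
    """Per-gene, per-replicate expression for two genotypes x two conditions.

    log2 expression = gene baseline + condition effect + (mutant x DE status
    x log2 effect, applied under the second condition) + Gaussian replicate
    noise.  Returns a long table (gene_id, genotype, condition, replicate,
    value) on the linear scale.
    """
    config.validate()
    rng = _substream(config, "expression")
    genotypes = config.expression_genotypes
    conditions = config.expression_conditions
    n_genes = len(truth)
    baseline = rng.normal(config.expression_baseline_log2, config.expression_baseline_spread, size=n_genes)
    cond_effect = rng.normal(0.0, config.expression_condition_spread, size=n_genes)
    rep_sd = 0.0 if config.noise_free else config.expression_rep_sd
    rows = []
    for i, row in enumerate(truth.itertuples()):
        _, _, eff = config.de_spec.get(row.true_zone, (0.0, 0.0, 0.0))
        de_shift = {"up": eff, "down": -eff, "none": 0.0}[row.true_de_status]
        for genotype in genotypes:
            is_mut = genotype != genotypes[0]
            for ci, condition in enumerate(conditions):
                for rep in range(1, config.n_replicates + 1):
                    log2val = baseline[i]
                    if ci == 1:
                        log2val += cond_effect[i]
                        if is_mut:
                            log2val += de_shift
                    if rep_sd > 0:
                        log2val += rng.normal(0.0, rep_sd)
                    rows.append(
                        {
                            "gene_id": row.gene_id,
                            "genotype": genotype,
                            "condition": condition,
                            "replicate": rep,
                            "value": float(2.0**log2val),
                        }
                    )
    return pd.DataFrame(rows)
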