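"""End-to-end pipeline stages over an on-disk workspace.

Each stage reads the previous stage's TSV artifacts, writes its own, and
records a machine-readable manifest (parameters, input checksums, package
version, seed) so reruns with identical config and inputs are byte-identical.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .classify import ZoneClassifier
from .contrasts import ZoneShiftModel
from .dynamics import ZoneDynamics
from .expression import DEModel, zone_de_crosstab
from .genome_io import (
    CORE_MARKS,
    read_annotation,
    read_bedgraph,
    read_chrom_sizes,
    read_sample_sheet,
    read_table,
    write_annotation,
    write_bedgraph,
    write_chrom_sizes,
    write_table,
)
from .quant import StateSignalTable, build_state_table, normalize_depth
from .synthetic import (
    GeneratorConfig,
    build_sample_sheet,
    chrom_sizes_for,
    generate_genome,
    simulate_expression,
    simulate_tracks,
)

logger = logging.getLogger(__name__)


class MissingArtifactError(FileNotFoundError):
    """A stage prerequisite has not been produced yet."""


@dataclasses.dataclass
class PipelineConfig:
    """Validated pipeline parameters (see ``default_config`` for the defaults)."""

    outdir: str = "k79zones_out"
    seed: int = 0
    annotation: str | None = None
    sample_sheet: str | None = None
    expression: str | None = None
    bin_width: int = 50
    pseudocount: float = 0.5
    window_bp: int = 200
    flank_bp: int = 1000
    body_bins: int = 100
    lfc_min: float = 0.25
    q_max: float = 0.5
    de_fold_min: float = 1.4
    de_q_max: float = 0.5
    wt_genotype: str = "WT"
    mutant_genotypes: tuple = ("rad6d",)
    expression_mutant: str = "dot1d"
    classify_genotype: str = "WT"
    generator: dict = dataclasses.field(default_factory=dict)

    def validate(self) -> None:
        if self.lfc_min <= 0 or self.q_max <= 0 or self.de_fold_min <= 1 or self.de_q_max <= 0:
            raise ValueError("classifier/DE thresholds must be positive (fold > 1)")
        if self.bin_width <= 0 or self.pseudocount <= 0:
            raise ValueError("bin_width and pseudocount must be positive")

    def generator_config(self) -> GeneratorConfig:
        gen = dict(self.generator)
        # genotype_effects / condition_switch keys arrive as "zone:state" /
        # "origin:dest" strings from YAML; convert to tuples
        if "genotype_effects" in gen:
            gen["genotype_effects"] = {
                g: {tuple(k.split(":")): v for k, v in eff.items()} for g, eff in gen["genotype_effects"].items()
            }
        if "condition_switch" in gen:
            gen["condition_switch"] = {tuple(k.split(":")): v for k, v in gen["condition_switch"].items()}
        if "de_spec" in gen:
            gen["de_spec"] = {z: tuple(v) for z, v in gen["de_spec"].items()}
        for key in ("gene_length_range", "genotypes", "conditions", "expression_genotypes",
                    "expression_conditions", "covariate_marks"):
            if key in gen:
                gen[key] = tuple(gen[key])
        cfg = GeneratorConfig(**gen)
        cfg.seed = self.seed
        cfg.bin_width = self.bin_width
        cfg.pseudocount = self.pseudocount
        cfg.validate()
        return cfg


def default_config() -> dict:
    """The bundled default configuration: a small fully synthetic run."""
    return {
        "outdir": "k79zones_out",
        "seed": 0,
        "bin_width": 50,
        "pseudocount": 0.5,
        "window_bp": 200,
        "flank_bp": 1000,
        "body_bins": 100,
        "lfc_min": 0.25,
        "q_max": 0.5,
        "de_fold_min": 1.4,
        "de_q_max": 0.5,
        "wt_genotype": "WT",
        "mutant_genotypes": ["rad6d"],
        "expression_mutant": "dot1d",
        "generator": {
            "n_genes_per_class": {"me3": 60, "me2": 30, "me1": 60, "MixedI": 30, "MixedII": 30},
            "genotypes": ["WT", "rad6d"],
            "conditions": ["plusN", "minusN"],
        },
    }


def load_config(path: str | None, overrides: dict | None = None) -> PipelineConfig:
    data = default_config()
    if path:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for key, val in user.items():
            data[key] = val
    for key, val in (overrides or {}).items():
        if val is not None:
            data[key] = val
    if "mutant_genotypes" in data:
        data["mutant_genotypes"] = tuple(data["mutant_genotypes"])
    cfg = PipelineConfig(**data)
    cfg.validate()
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(outdir: Path, stage: str, params: dict, inputs: list[Path], outputs: list[Path]) -> None:
    manifest = {
        "stage": stage,
        "version": __version__,
        "params": params,
        "inputs": {str(p.relative_to(outdir)) if p.is_relative_to(outdir) else str(p): _sha256(p) for p in inputs},
        "outputs": sorted(str(p.relative_to(outdir)) for p in outputs),
    }
    path = outdir / f"manifest_{stage}.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise MissingArtifactError(f"missing artifact {path}; run the '{producer}' stage first")
    return path


# ---------------------------------------------------------------------------
# stages


def stage_simulate(cfg: PipelineConfig) -> None:
    out = Path(cfg.outdir) / "inputs"
    out.mkdir(parents=True, exist_ok=True)
    (out / "tracks").mkdir(exist_ok=True)
    gen = cfg.generator_config()
    genes, truth = generate_genome(gen)
    logger.info("simulate: %d genes on %d chromosomes", len(genes), len({g.chrom for g in genes}))
    sheet = build_sample_sheet(gen)
    tracks = simulate_tracks(genes, truth, sheet, gen)
    sizes = chrom_sizes_for(genes, gen)
    write_annotation(genes, out / "annotation.bed")
    write_chrom_sizes(sizes, out / "chrom.sizes")
    write_table(sheet, out / "samples.tsv")
    write_table(truth, out / "truth.tsv")
    expr = simulate_expression(truth, gen)
    write_table(expr, out / "expression.tsv")
    outputs = [out / "annotation.bed", out / "chrom.sizes", out / "samples.tsv", out / "truth.tsv", out / "expression.tsv"]
    for sid, track in tracks.items():
        p = out / "tracks" / f"{sid}.bedgraph"
        write_bedgraph(track, p)
        outputs.append(p)
    _write_manifest(Path(cfg.outdir), "simulate", {"seed": cfg.seed, "generator": gen.to_dict()}, [], outputs)


def _input_paths(cfg: PipelineConfig) -> tuple[Path, Path, Path]:
    base = Path(cfg.outdir) / "inputs"
    annotation = Path(cfg.annotation) if cfg.annotation else base / "annotation.bed"
    sheet = Path(cfg.sample_sheet) if cfg.sample_sheet else base / "samples.tsv"
    sizes = base / "chrom.sizes" if not cfg.annotation else Path(cfg.annotation).with_name("chrom.sizes")
    return annotation, sheet, sizes


def stage_quantify(cfg: PipelineConfig) -> None:
    outdir = Path(cfg.outdir)
    annotation, sheet_path, sizes_path = _input_paths(cfg)
    _require(annotation, "simulate")
    _require(sheet_path, "simulate")
    genes = read_annotation(annotation)
    sheet = read_sample_sheet(sheet_path)
    sizes = read_chrom_sizes(_require(sizes_path, "simulate"))
    tracks = {}
    for _, row in sheet.iterrows():
        p = Path(row["path"])
        if not p.is_absolute():
            p = sheet_path.parent / p
        raw = read_bedgraph(_require(p, "simulate"), sizes, cfg.bin_width,
                            total_raw_reads=int(row["total_reads"]), sample_id=row["sample_id"])
        tracks[row["sample_id"]] = normalize_depth(raw)
    qdir = outdir / "quant"
    qdir.mkdir(parents=True, exist_ok=True)
    outputs = []
    for (genotype, condition), grp in sheet.groupby(["genotype", "condition"]):
        if not set(CORE_MARKS) <= set(grp["mark"]):
            continue
        table = build_state_table(tracks, sheet, genes, genotype, condition,
                                  pseudocount=cfg.pseudocount, window_bp=cfg.window_bp)
        body, windows = table.to_frames()
        for kind, frame in (("body", body), ("windows", windows)):
            p = qdir / f"{kind}_{genotype}_{condition}.tsv"
            write_table(frame, p)
            outputs.append(p)
        logger.info("quantify: (%s, %s) -> %d genes x %d replicates", genotype, condition,
                    len(table.gene_ids), len(table.replicates))
    _write_manifest(outdir, "quantify",
                    {"bin_width": cfg.bin_width, "pseudocount": cfg.pseudocount, "window_bp": cfg.window_bp,
                     "seed": cfg.seed},
                    [annotation, sheet_path], outputs)


def _load_table(cfg: PipelineConfig, genotype: str, condition: str) -> StateSignalTable:
    qdir = Path(cfg.outdir) / "quant"
    body = read_table(_require(qdir / f"body_{genotype}_{condition}.tsv", "quantify"))
    windows = read_table(_require(qdir / f"windows_{genotype}_{condition}.tsv", "quantify"))
    return StateSignalTable.from_frames(body, windows, cfg.pseudocount, genotype, condition)


def _conditions(cfg: PipelineConfig) -> list[str]:
    sheet_path = _input_paths(cfg)[1]
    sheet = read_sample_sheet(_require(sheet_path, "simulate"))
    # first-appearance order: the baseline condition is listed first
    return list(pd.unique(sheet["condition"]))


def stage_classify(cfg: PipelineConfig) -> None:
    outdir = Path(cfg.outdir)
    conditions = _conditions(cfg)
    # check every prerequisite before creating any output
    for condition in conditions:
        for kind in ("body", "windows"):
            _require(outdir / "quant" / f"{kind}_{cfg.classify_genotype}_{condition}.tsv", "quantify")
    cdir = outdir / "classify"
    cdir.mkdir(parents=True, exist_ok=True)
    outputs = []
    for condition in conditions:
        table = _load_table(cfg, cfg.classify_genotype, condition)
        result = ZoneClassifier(table, lfc_min=cfg.lfc_min, q_max=cfg.q_max).fit()
        calls = result.calls.copy()
        calls["lfc_min"] = cfg.lfc_min
        calls["q_max"] = cfg.q_max
        p1 = cdir / f"zone_calls_{cfg.classify_genotype}_{condition}.tsv"
        p2 = cdir / f"zone_summary_{cfg.classify_genotype}_{condition}.tsv"
        write_table(calls, p1)
        write_table(result.summary(), p2)
        outputs += [p1, p2]
        logger.info("classify: (%s, %s)\n%s", cfg.classify_genotype, condition, result.summary().to_string(index=False))
    _write_manifest(outdir, "classify", {"lfc_min": cfg.lfc_min, "q_max": cfg.q_max, "seed": cfg.seed}, [], outputs)


def _load_calls(cfg: PipelineConfig, condition: str) -> pd.DataFrame:
    p = Path(cfg.outdir) / "classify" / f"zone_calls_{cfg.classify_genotype}_{condition}.tsv"
    calls = read_table(_require(p, "classify"))
    if "lfc_min" in calls.columns:
        calls.attrs["lfc_min"] = float(calls["lfc_min"].iloc[0])
        calls.attrs["q_max"] = float(calls["q_max"].iloc[0])
    return calls


def stage_contrast(cfg: PipelineConfig) -> None:
    outdir = Path(cfg.outdir)
    condition = _conditions(cfg)[0]
    calls = _load_calls(cfg, condition)
    wt_table = _load_table(cfg, cfg.wt_genotype, condition)
    sdir = outdir / "contrast"
    sdir.mkdir(parents=True, exist_ok=True)
    outputs = []
    for mut in cfg.mutant_genotypes:
        mut_table = _load_table(cfg, mut, condition)
        result = ZoneShiftModel(wt_table, mut_table, calls).fit()
        p = sdir / f"shifts_{mut}_{condition}.tsv"
        write_table(result.shifts, p)
        outputs.append(p)
        logger.info("contrast: %s vs %s\n%s", mut, cfg.wt_genotype, result.shifts.to_string(index=False))
    _write_manifest(outdir, "contrast", {"wt": cfg.wt_genotype, "mutants": list(cfg.mutant_genotypes),
                                         "seed": cfg.seed}, [], outputs)


def stage_dynamics(cfg: PipelineConfig) -> None:
    outdir = Path(cfg.outdir)
    conditions = _conditions(cfg)
    if len(conditions) < 2:
        raise MissingArtifactError("dynamics needs two conditions in the sample sheet")
    calls_a, calls_b = _load_calls(cfg, conditions[0]), _load_calls(cfg, conditions[1])
    result = ZoneDynamics(calls_a, calls_b, condition_a=conditions[0], condition_b=conditions[1]).fit()
    ddir = outdir / "dynamics"
    ddir.mkdir(parents=True, exist_ok=True)
    paths = [ddir / "transitions.tsv", ddir / "transition_matrix.tsv", ddir / "sankey.tsv"]
    write_table(result.transitions, paths[0])
    result.matrix.to_csv(paths[1], sep="\t")
    write_table(result.sankey_table(), paths[2])
    logger.info("dynamics: overall stable fraction %.3f", result.stable_fraction)
    _write_manifest(outdir, "dynamics", {"conditions": conditions, "seed": cfg.seed}, [], paths)


def stage_integrate(cfg: PipelineConfig) -> None:
    outdir = Path(cfg.outdir)
    expr_path = Path(cfg.expression) if cfg.expression else outdir / "inputs" / "expression.tsv"
    expr = read_table(_require(expr_path, "simulate"))
    de_condition = list(pd.unique(expr["condition"]))[-1]
    result = DEModel(expr, mut=cfg.expression_mutant, wt=cfg.wt_genotype, condition=de_condition,
                     fold_min=cfg.de_fold_min, q_max=cfg.de_q_max, pseudocount=cfg.pseudocount).fit()
    zone_condition = _conditions(cfg)[0]
    calls = _load_calls(cfg, zone_condition)
    crosstab = zone_de_crosstab(calls, result.calls)
    idir = outdir / "integrate"
    idir.mkdir(parents=True, exist_ok=True)
    paths = [idir / "de_calls.tsv", idir / "zone_de_crosstab.tsv"]
    write_table(result.calls.drop(columns=[]), paths[0])
    crosstab.summary().to_csv(paths[1], sep="\t")
    logger.info("integrate: %s", result.summary())
    _write_manifest(outdir, "integrate", {"fold_min": cfg.de_fold_min, "q_max": cfg.de_q_max,
                                          "mutant": cfg.expression_mutant, "condition": de_condition,
                                          "seed": cfg.seed}, [expr_path], paths)


def stage_report(cfg: PipelineConfig) -> None:
    outdir = Path(cfg.outdir)
    rdir = outdir / "report"
    rdir.mkdir(parents=True, exist_ok=True)
    outputs = []
    collect = {
        "zone_summary.tsv": outdir / "classify" / f"zone_summary_{cfg.classify_genotype}_{_conditions(cfg)[0]}.tsv",
        "transition_matrix.tsv": outdir / "dynamics" / "transition_matrix.tsv",
        "zone_de_crosstab.tsv": outdir / "integrate" / "zone_de_crosstab.tsv",
    }
    for mut in cfg.mutant_genotypes:
        collect[f"shifts_{mut}.tsv"] = outdir / "contrast" / f"shifts_{mut}_{_conditions(cfg)[0]}.tsv"
    for name, src in collect.items():
        if src.exists():
            dst = rdir / name
            dst.write_text(src.read_text())
            outputs.append(dst)
    defaults = rdir / "defaults.yaml"
    defaults.write_text(yaml.safe_dump({"pipeline": default_config(),
                                        "generator": GeneratorConfig().to_dict()}, sort_keys=True))
    outputs.append(defaults)
    _write_manifest(outdir, "report", {"seed": cfg.seed}, [], outputs)


STAGES = {
    "simulate": stage_simulate,
    "quantify": stage_quantify,
    "classify": stage_classify,
    "contrast": stage_contrast,
    "dynamics": stage_dynamics,
    "integrate": stage_integrate,
    "report": stage_report,
}


def run(subcommand: str, cfg: PipelineConfig) -> None:
    """Run one stage, or all of them in order."""
    if subcommand == "all":
        for name in STAGES:
            logger.info("=== stage %s ===", name)
            STAGES[name](cfg)
        return
    if subcommand not in STAGES:
        raise ValueError(f"unknown stage {subcommand!r}")
    STAGES[subcommand](cfg)
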