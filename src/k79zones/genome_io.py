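"""Genomic file formats and the coordinate conventions used throughout.

All coordinates are 0-based half-open (BED convention) internally; GFF3 input
is converted on read.  Coverage is held as fixed-width binned signal per
chromosome, the resolution at which every downstream quantity (gene-body
means, metagenes) is computed.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

CORE_MARKS = ("me1", "me2", "me3", "H3")
KNOWN_MARKS = CORE_MARKS + ("H2Bubi", "H4K16ac", "Dot1", "Rpb3", "input")


class ParseError(ValueError):
    """Malformed record in a text format; message names the offending line."""


@dataclass(frozen=True)
class GeneModel:
    """One gene: interval, strand and identifier.

    TSS/TES derive from strand: for ``+`` the TSS is ``start`` and the TES is
    ``end``; for ``-`` they swap.  The 1 kb flanks used by metagene profiles
    are taken relative to these.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"gene {self.gene_id}: require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def tes(self) -> int:
        return self.end if self.strand == "+" else self.start

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SampleSpec:
    """Metadata for one ChIP-seq sample."""

    sample_id: str
    mark: str
    genotype: str
    condition: str
    replicate: int


@dataclass
class CoverageTrack:
    """Binned coverage for one sample.

    ``values`` maps chromosome name to a float vector of per-bin signal;
    bin ``i`` covers ``[i*bin_width, (i+1)*bin_width)``.  Bin values are
    per-base means within the bin (length-weighted on read), so the signal
    mass of the track is ``sum(values) * bin_width``.
    """

    sample_id: str
    bin_width: int
    values: dict[str, np.ndarray]
    total_raw_reads: int
    chrom_sizes: dict[str, int] = field(default_factory=dict)
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        for chrom, vec in self.values.items():
            vec = np.asarray(vec, dtype=float)
            if not np.all(np.isfinite(vec)) or np.any(vec < 0):
                raise ValueError(f"track {self.sample_id}, {chrom}: values must be finite and >= 0")
            self.values[chrom] = vec

    def copy(self) -> "CoverageTrack":
        return CoverageTrack(
            sample_id=self.sample_id,
            bin_width=self.bin_width,
            values={c: v.copy() for c, v in self.values.items()},
            total_raw_reads=self.total_raw_reads,
            chrom_sizes=dict(self.chrom_sizes),
            normalized=self.normalized,
        )


def _sniff_format(path: str) -> str:
    lower = str(path).lower()
    if lower.endswith((".gff", ".gff3")):
        return "gff3"
    if lower.endswith(".bed"):
        return "bed"
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            return "gff3" if len(line.rstrip("\n").split("\t")) == 9 else "bed"
    return "bed"


def read_annotation(path, fmt: str | None = None, feature_type: str = "gene") -> list[GeneModel]:
    """Read a BED6 or GFF3 annotation into GeneModels sorted by (chrom, start).

    BED coordinates are taken verbatim (0-based half-open); GFF3 records are
    filtered to ``feature_type`` and converted from 1-based closed intervals
    (start - 1).  Duplicate gene ids and degenerate intervals are errors.
    """
    fmt = fmt or _sniff_format(path)
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if fmt == "bed":
                    if len(fields) < 6:
                        raise ValueError(f"expected >= 6 BED columns, got {len(fields)}")
                    chrom, start, end, name, _score, strand = fields[:6]
                    gene = GeneModel(name, chrom, int(start), int(end), strand)
                else:
                    if len(fields) != 9:
                        raise ValueError(f"expected 9 GFF3 columns, got {len(fields)}")
                    chrom, _src, ftype, start, end, _score, strand, _frame, attrs = fields
                    if ftype != feature_type:
                        continue
                    gene_id = None
                    for item in attrs.rstrip(";").split(";"):
                        key, _, val = item.strip().partition("=")
                        if key in ("ID", "Name") and gene_id is None or key == "ID":
                            gene_id = val
                    if not gene_id:
                        raise ValueError("no ID/Name attribute")
                    gene = GeneModel(gene_id, chrom, int(start) - 1, int(end), strand)
            except ValueError as exc:
                raise ParseError(f"{path}, line {lineno}: {exc}") from exc
            genes.append(gene)
    seen: set[str] = set()
    for g in genes:
        if g.gene_id in seen:
            raise ParseError(f"{path}: duplicate gene_id {g.gene_id!r}")
        seen.add(g.gene_id)
    genes.sort(key=lambda g: (g.chrom, g.start))
    return genes


def write_annotation(genes, path) -> None:
    """Write GeneModels as BED6 (score column 0)."""
    with open(path, "w") as fh:
        for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


def read_chrom_sizes(path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 2:
                raise ParseError(f"{path}, line {lineno}: expected 2 columns")
            sizes[fields[0]] = int(fields[1])
    return sizes


def write_chrom_sizes(sizes: dict[str, int], path) -> None:
    with open(path, "w") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")


def read_bedgraph(
    path,
    chrom_sizes: dict[str, int],
    bin_width: int = 50,
    total_raw_reads: int | None = None,
    sample_id: str | None = None,
) -> CoverageTrack:
    """Read a bedGraph into a binned CoverageTrack (raw counts, pre-normalization).

    Interval values are length-weighted into fixed-width bins; uncovered
    positions contribute 0.  A comment header of the form
    ``# sample_id=... total_raw_reads=... normalized=...`` is honoured as
    sidecar metadata; explicit arguments override it.
    """
    meta: dict[str, str] = {}
    intervals: dict[str, list[tuple[int, int, float]]] = {c: [] for c in chrom_sizes}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith("#"):
                for item in line.lstrip("# ").split():
                    key, _, val = item.partition("=")
                    if val:
                        meta[key] = val
                continue
            if not line.strip() or line.startswith(("track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path}, line {lineno}: expected 4 columns")
            chrom, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            if chrom not in chrom_sizes:
                raise ParseError(f"{path}, line {lineno}: unknown chromosome {chrom!r}")
            if end > chrom_sizes[chrom]:
                raise ParseError(
                    f"{path}, line {lineno}: interval end {end} beyond {chrom} size {chrom_sizes[chrom]}"
                )
            if value < 0:
                raise ParseError(f"{path}, line {lineno}: negative value {value}")
            if start >= end:
                raise ParseError(f"{path}, line {lineno}: empty interval")
            intervals[chrom].append((start, end, value))

    values: dict[str, np.ndarray] = {}
    for chrom, size in chrom_sizes.items():
        nbins = math.ceil(size / bin_width)
        vec = np.zeros(nbins)
        ivs = sorted(intervals[chrom])
        for i, (s, e, v) in enumerate(ivs):
            if i and s < ivs[i - 1][1]:
                raise ParseError(f"{path}: overlapping intervals on {chrom} at {s}")
            b0, b1 = s // bin_width, (e - 1) // bin_width
            if b0 == b1:
                vec[b0] += v * (e - s) / bin_width
            else:
                vec[b0] += v * ((b0 + 1) * bin_width - s) / bin_width
                vec[b1] += v * (e - b1 * bin_width) / bin_width
                vec[b0 + 1 : b1] += v
        values[chrom] = vec

    total = total_raw_reads if total_raw_reads is not None else int(meta.get("total_raw_reads", 0))
    if total <= 0:
        raise ValueError(f"{path}: total_raw_reads must be supplied (argument or '# total_raw_reads=' header)")
    return CoverageTrack(
        sample_id=sample_id or meta.get("sample_id", str(path)),
        bin_width=bin_width,
        values=values,
        total_raw_reads=total,
        chrom_sizes=dict(chrom_sizes),
        normalized=meta.get("normalized", "false").lower() == "true",
    )


def write_bedgraph(track: CoverageTrack, path) -> None:
    """Write a binned track as bedGraph, collapsing runs of equal value.

    Zero bins are omitted (uncovered on re-read).  A comment header carries the
    sidecar metadata read_bedgraph understands.
    """
    bw = track.bin_width
    with open(path, "w") as fh:
        fh.write(
            f"# sample_id={track.sample_id} total_raw_reads={track.total_raw_reads} "
            f"normalized={'true' if track.normalized else 'false'} bin_width={bw}\n"
        )
        for chrom in track.values:
            vec = track.values[chrom]
            size = track.chrom_sizes.get(chrom, len(vec) * bw)
            # run-length encode equal adjacent bins
            change = np.flatnonzero(np.diff(vec)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(vec)]))
            for b0, b1 in zip(starts, ends):
                v = vec[b0]
                if v == 0:
                    continue
                fh.write(f"{chrom}\t{b0 * bw}\t{min(b1 * bw, size)}\t{v:.10g}\n")


def read_bigwig(path, bin_width: int = 50, total_raw_reads: int | None = None,
                sample_id: str | None = None) -> CoverageTrack:
    """Optionally read a bigWig into the same binned representation.

    Requires pyBigWig (not a hard dependency; bedGraph is the canonical
    text format for this package's fixtures and pipelines).
    """
    try:
        import pyBigWig  # noqa: PLC0415
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading bigWig requires the optional pyBigWig package") from exc
    bw = pyBigWig.open(str(path))
    try:
        sizes = dict(bw.chroms())
        values: dict[str, np.ndarray] = {}
        for chrom, size in sizes.items():
            nbins = math.ceil(size / bin_width)
            # per-base sum / bin_width: uncovered positions count as zero,
            # matching the bedGraph binning convention
            stats = bw.stats(chrom, 0, size, type="sum", nBins=nbins, exact=True)
            values[chrom] = np.array([v if v is not None else 0.0 for v in stats], dtype=float) / bin_width
    finally:
        bw.close()
    if total_raw_reads is None or total_raw_reads <= 0:
        raise ValueError("total_raw_reads must be supplied for bigWig input")
    return CoverageTrack(sample_id=sample_id or str(path), bin_width=bin_width, values=values,
                         total_raw_reads=total_raw_reads, chrom_sizes=sizes, normalized=False)


SAMPLE_SHEET_COLUMNS = ["sample_id", "mark", "genotype", "condition", "replicate", "path", "total_reads"]


def read_sample_sheet(path) -> pd.DataFrame:
    """Read the sample sheet TSV and validate its uniqueness invariants."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "mark": str, "genotype": str, "condition": str})
    missing = [c for c in SAMPLE_SHEET_COLUMNS[:5] if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: sample sheet missing columns {missing}")
    key = ["mark", "genotype", "condition", "replicate"]
    if df.duplicated(key).any():
        dupes = df[df.duplicated(key, keep=False)].sort_values(key)
        raise ParseError(f"{path}: duplicate (mark, genotype, condition, replicate):\n{dupes}")
    if df["sample_id"].duplicated().any():
        raise ParseError(f"{path}: duplicate sample_id")
    return df


def write_table(records, path) -> None:
    """Write a DataFrame (or records with a shared schema) as deterministic TSV.

    Rows are ordered by gene_id when that column exists; floats use a fixed
    general format so reruns are byte-identical.
    """
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(list(records))
    if "gene_id" in df.columns:
        df = df.sort_values("gene_id", kind="mergesort")
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
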