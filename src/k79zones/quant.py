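"""Per-gene signal quantification and metagene matrices.

Turns depth-normalized coverage tracks into the quantities the rest of the
analysis consumes: mean gene-body RPM per methylation state and replicate,
H3-normalized log2 ratios, window-level signals for per-gene evidence, and
scale-regions (metagene) matrices oriented 5'->3'.

RPM here means coverage normalized to a depth of 10 million uniquely mapped
reads.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome_io import CORE_MARKS, CoverageTrack, GeneModel

logger = logging.getLogger(__name__)

RPM_SCALE = 10_000_000
DEFAULT_PSEUDOCOUNT = 0.5
LOG2_COLUMNS = {"me1": "log2_me1", "me2": "log2_me2", "me3": "log2_me3"}


def normalize_depth(track: CoverageTrack) -> CoverageTrack:
    """Scale a raw-count track to RPM units (reads per 10 million mapped)."""
    if track.total_raw_reads <= 0:
        raise ValueError(f"track {track.sample_id}: total_raw_reads must be positive")
    if track.normalized:
        raise ValueError(f"track {track.sample_id}: already normalized")
    out = track.copy()
    scale = RPM_SCALE / track.total_raw_reads
    for chrom in out.values:
        out.values[chrom] = out.values[chrom] * scale
    out.normalized = True
    return out


def interval_mean(vec: np.ndarray, bin_width: int, a: float, b: float) -> float:
    """Length-weighted mean of piecewise-constant binned signal over [a, b).

    Positions outside the vector contribute 0 (flanks running off a
    chromosome end), but the divisor is always the full interval length.
    """
    if b <= a:
        raise ValueError("empty interval")
    lo = max(a, 0.0)
    hi = min(b, len(vec) * bin_width)
    if hi <= lo:
        return 0.0
    i0 = int(lo // bin_width)
    i1 = int(math.ceil(hi / bin_width))
    edges = np.arange(i0, i1 + 1, dtype=float) * bin_width
    w = np.minimum(edges[1:], hi) - np.maximum(edges[:-1], lo)
    return float(np.dot(vec[i0:i1], w)) / (b - a)


def gene_body_signal(track: CoverageTrack, genes: list[GeneModel]) -> pd.Series:
    """Mean RPM over each gene body [TSS, TES); flanks excluded."""
    out = {}
    for g in genes:
        if g.chrom not in track.values:
            raise ValueError(f"gene {g.gene_id}: chromosome {g.chrom} absent from track {track.sample_id}")
        out[g.gene_id] = interval_mean(track.values[g.chrom], track.bin_width, g.start, g.end)
    return pd.Series(out, name=track.sample_id)


def h3_normalize(table: pd.DataFrame, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> pd.DataFrame:
    """Add log2((state + c) / (H3 + c)) columns for each methylation state."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    out = table.copy()
    for state, col in LOG2_COLUMNS.items():
        out[col] = np.log2((out[state] + pseudocount) / (out["H3"] + pseudocount))
    return out


def _window_bounds(start: int, end: int, window_bp: int) -> list[tuple[float, float]]:
    # at least two windows per gene so the paired evidence test has
    # within-gene observations even for short genes
    n = max(2, (end - start) // window_bp)
    edges = np.linspace(start, end, n + 1)
    return list(zip(edges[:-1], edges[1:]))


class StateSignalTable:
    """Per-gene, per-replicate gene-body signal for one (genotype, condition).

    ``body`` is indexed by (gene_id, replicate) with one RPM column per mark
    plus H3-normalized log2 columns; ``windows`` adds a window level used for
    the per-gene paired evidence test.  Construct with
    :func:`build_state_table` or :meth:`from_frames`.
    """

    def __init__(
        self,
        body: pd.DataFrame,
        windows: pd.DataFrame,
        pseudocount: float = DEFAULT_PSEUDOCOUNT,
        genotype: str = "",
        condition: str = "",
    ):
        self.body = body
        self.windows = windows
        self.pseudocount = pseudocount
        self.genotype = genotype
        self.condition = condition

    @property
    def gene_ids(self) -> list[str]:
        return list(self.body.index.get_level_values("gene_id").unique())

    @property
    def replicates(self) -> list[int]:
        return sorted(self.body.index.get_level_values("replicate").unique())

    def rep_mean(self) -> pd.DataFrame:
        """Replicate-averaged per-gene table.

        RPM columns are averaged on the linear scale; log2 ratio columns are
        averaged on the log2 scale, keeping the ratio interpretation
        symmetric.
        """
        return self.body.groupby(level="gene_id").mean()

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        return self.body.reset_index(), self.windows.reset_index()

    @classmethod
    def from_frames(
        cls,
        body: pd.DataFrame,
        windows: pd.DataFrame,
        pseudocount: float = DEFAULT_PSEUDOCOUNT,
        genotype: str = "",
        condition: str = "",
    ) -> "StateSignalTable":
        body = body.set_index(["gene_id", "replicate"]).sort_index()
        windows = windows.set_index(["gene_id", "replicate", "window"]).sort_index()
        return cls(body, windows, pseudocount, genotype, condition)


def build_state_table(
    tracks: dict[str, CoverageTrack],
    sample_sheet: pd.DataFrame,
    genes: list[GeneModel],
    genotype: str,
    condition: str,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    window_bp: int = 200,
) -> StateSignalTable:
    """Quantify gene-body signal for one (genotype, condition).

    Requires normalized tracks for every core mark (me1/me2/me3/H3) and
    replicate; any additional marks present for the same genotype and
    condition become covariate columns (replicate-matched when possible,
    otherwise averaged and broadcast).
    """
    sheet = sample_sheet[(sample_sheet["genotype"] == genotype) & (sample_sheet["condition"] == condition)]
    reps = sorted(sheet.loc[sheet["mark"].isin(CORE_MARKS), "replicate"].unique())
    if not reps:
        raise ValueError(f"no core-mark samples for ({genotype}, {condition})")
    for mark in CORE_MARKS:
        have = set(sheet.loc[sheet["mark"] == mark, "replicate"])
        if not set(reps) <= have:
            raise ValueError(f"({genotype}, {condition}): mark {mark} missing replicates {set(reps) - have}")

    def _get_track(mark, rep) -> CoverageTrack:
        row = sheet[(sheet["mark"] == mark) & (sheet["replicate"] == rep)]
        track = tracks[row["sample_id"].iloc[0]]
        if not track.normalized:
            raise ValueError(f"track {track.sample_id} is not depth-normalized")
        return track

    covariates = sorted(set(sheet["mark"]) - set(CORE_MARKS))
    body_rows = []
    window_rows = []
    windows_per_gene = {g.gene_id: _window_bounds(g.start, g.end, window_bp) for g in genes}
    for rep in reps:
        mark_tracks = {mark: _get_track(mark, rep) for mark in CORE_MARKS}
        for g in genes:
            row = {"gene_id": g.gene_id, "replicate": rep}
            for mark, track in mark_tracks.items():
                if g.chrom not in track.values:
                    raise ValueError(f"gene {g.gene_id}: chromosome {g.chrom} absent from track {track.sample_id}")
                row[mark] = interval_mean(track.values[g.chrom], track.bin_width, g.start, g.end)
            body_rows.append(row)
            for w, (a, b) in enumerate(windows_per_gene[g.gene_id]):
                wrow = {"gene_id": g.gene_id, "replicate": rep, "window": w}
                for mark, track in mark_tracks.items():
                    wrow[mark] = interval_mean(track.values[g.chrom], track.bin_width, a, b)
                window_rows.append(wrow)

    body = pd.DataFrame(body_rows).set_index(["gene_id", "replicate"]).sort_index()
    windows = pd.DataFrame(window_rows).set_index(["gene_id", "replicate", "window"]).sort_index()
    body = h3_normalize(body, pseudocount)
    windows = h3_normalize(windows, pseudocount)

    for cov in covariates:
        cov_sheet = sheet[sheet["mark"] == cov]
        per_rep = {}
        for _, srow in cov_sheet.iterrows():
            track = tracks[srow["sample_id"]]
            if not track.normalized:
                raise ValueError(f"track {track.sample_id} is not depth-normalized")
            per_rep[srow["replicate"]] = gene_body_signal(track, genes)
        if set(per_rep) >= set(reps):
            col = pd.concat({r: per_rep[r] for r in reps}, names=["replicate", "gene_id"])
            col = col.reorder_levels(["gene_id", "replicate"]).sort_index()
        else:
            mean = pd.concat(per_rep.values(), axis=1).mean(axis=1)
            col = pd.concat({r: mean for r in reps}, names=["replicate", "gene_id"])
            col = col.reorder_levels(["gene_id", "replicate"]).sort_index()
        body[cov] = col
        body[f"log2_{cov}"] = np.log2((body[cov] + pseudocount) / (body["H3"] + pseudocount))

    return StateSignalTable(body, windows, pseudocount, genotype, condition)


@dataclass
class MetageneMatrix:
    """Genes x bins matrix in scale-regions layout, oriented TSS->TES.

    Columns are ``flank_bins`` fixed-width upstream bins, ``body_bins``
    length-scaled body bins, then ``flank_bins`` downstream bins.  Rows for
    minus-strand genes are reversed so orientation is always 5'->3'.
    """

    matrix: np.ndarray
    gene_ids: list[str]
    flank_bins: int
    body_bins: int
    flank_bin_bp: int

    @property
    def n_bins(self) -> int:
        return 2 * self.flank_bins + self.body_bins

    def body_slice(self) -> slice:
        return slice(self.flank_bins, self.flank_bins + self.body_bins)


def metagene(
    track: CoverageTrack,
    genes: list[GeneModel],
    flank_bp: int = 1000,
    body_bins: int = 100,
    flank_bin_bp: int = 50,
) -> MetageneMatrix:
    """Scale-regions matrix over gene bodies with +/- ``flank_bp`` flanks.

    The body is resampled to ``body_bins`` by length-weighted interpolation.
    Genes with bodies shorter than ``body_bins`` bp are dropped with a logged
    warning.
    """
    if flank_bp % flank_bin_bp != 0:
        raise ValueError("flank_bp must be a multiple of flank_bin_bp")
    fbins = flank_bp // flank_bin_bp
    rows = []
    kept = []
    for g in genes:
        if g.length < body_bins:
            logger.warning("metagene: dropping %s (body %d bp < %d bins)", g.gene_id, g.length, body_bins)
            continue
        vec = track.values[g.chrom]
        bw = track.bin_width
        row = np.empty(2 * fbins + body_bins)
        for k in range(fbins):
            a = g.start - flank_bp + k * flank_bin_bp
            row[k] = interval_mean(vec, bw, a, a + flank_bin_bp)
        edges = np.linspace(g.start, g.end, body_bins + 1)
        for k in range(body_bins):
            row[fbins + k] = interval_mean(vec, bw, edges[k], edges[k + 1])
        for k in range(fbins):
            a = g.end + k * flank_bin_bp
            row[fbins + body_bins + k] = interval_mean(vec, bw, a, a + flank_bin_bp)
        if g.strand == "-":
            row = row[::-1]
        rows.append(row)
        kept.append(g.gene_id)
    matrix = np.vstack(rows) if rows else np.empty((0, 2 * fbins + body_bins))
    return MetageneMatrix(matrix, kept, fbins, body_bins, flank_bin_bp)


def average_profile(mm: MetageneMatrix) -> pd.DataFrame:
    """Column-wise mean +/- standard error over the gene set."""
    n = max(mm.matrix.shape[0], 1)
    mean = mm.matrix.mean(axis=0) if mm.matrix.size else np.zeros(mm.n_bins)
    se = mm.matrix.std(axis=0, ddof=1) / math.sqrt(n) if mm.matrix.shape[0] > 1 else np.zeros(mm.n_bins)
    return pd.DataFrame({"bin": np.arange(mm.n_bins), "mean": mean, "se": se})


def write_metagene(mm: MetageneMatrix, path) -> None:
    """Export a metagene matrix as TSV with a 3-line layout header."""
    with open(path, "w") as fh:
        fh.write(f"# flank_bins={mm.flank_bins} body_bins={mm.body_bins} flank_bin_bp={mm.flank_bin_bp}\n")
        fh.write("# layout=upstream_flank,body,downstream_flank orientation=5to3\n")
        fh.write("gene_id\t" + "\t".join(f"bin{i}" for i in range(mm.n_bins)) + "\n")
        for gid, row in zip(mm.gene_ids, mm.matrix):
            fh.write(gid + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")
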