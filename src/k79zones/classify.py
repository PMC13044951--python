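"""Zone classification: assign each gene to a state-specific methylation zone.

A gene belongs to the me3, me2 or me1 zone when that state's gene-body,
H3-normalized signal exceeds both other states by log2FC > ``lfc_min`` with
BH-adjusted q < ``q_max`` on both pairwise comparisons.  Genes failing every
zone test fall into Mixed I (me2 ~ me3 > me1), Mixed II (me1 ~ me2 > me3),
or ambiguous.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .quant import StateSignalTable
from .stats import bh_adjust, paired_evidence_p

ZONE_LABELS = ("me3", "me2", "me1", "MixedI", "MixedII", "ambiguous")

#: ordered pairwise contrasts (A over B)
CONTRASTS = (("me3", "me2"), ("me3", "me1"), ("me2", "me1"))


def _cname(a: str, b: str) -> str:
    return f"{a}_vs_{b}"


def compute_contrasts(table: StateSignalTable, pooled_fdr: bool = False) -> pd.DataFrame:
    """Per-gene pairwise log2FCs with paired-evidence p and BH q values.

    The log2FC is the difference of replicate-averaged gene-body
    log2(state/H3) values.  The p-value comes from a two-sided paired test on
    per-window log2 differences pooled over replicates (windows x replicates
    as observations); genes with fewer than four paired observations get
    p = 1 and a low-evidence flag.  BH is applied across genes separately per
    contrast by default, or pooled over all three contrasts.
    """
    rep_mean = table.body.groupby(level="gene_id")[["log2_me1", "log2_me2", "log2_me3"]].mean()
    win = table.windows
    out = pd.DataFrame(index=rep_mean.index)
    out.index.name = "gene_id"
    for a, b in CONTRASTS:
        name = _cname(a, b)
        out[f"lfc_{name}"] = rep_mean[f"log2_{a}"] - rep_mean[f"log2_{b}"]
        diffs = win[f"log2_{a}"] - win[f"log2_{b}"]
        pvals = {}
        low = {}
        for gid, d in diffs.groupby(level="gene_id"):
            p, flag = paired_evidence_p(d.to_numpy())
            pvals[gid] = p
            low[gid] = flag
        out[f"p_{name}"] = pd.Series(pvals)
        out[f"low_evidence_{name}"] = pd.Series(low)
    if pooled_fdr:
        stacked = np.concatenate([out[f"p_{_cname(a, b)}"].to_numpy() for a, b in CONTRASTS])
        q = bh_adjust(stacked)
        n = len(out)
        for i, (a, b) in enumerate(CONTRASTS):
            out[f"q_{_cname(a, b)}"] = q[i * n : (i + 1) * n]
    else:
        for a, b in CONTRASTS:
            name = _cname(a, b)
            out[f"q_{name}"] = bh_adjust(out[f"p_{name}"].to_numpy())
    return out.reset_index()


def classify(contrasts: pd.DataFrame, lfc_min: float = 0.25, q_max: float = 0.5) -> pd.DataFrame:
    """Apply the thresholded zone rule to a contrast table.

    Inequalities are strict at both thresholds.  Evaluation order: the three
    zones, then Mixed I, then Mixed II, then ambiguous; every gene gets
    exactly one label.
    """
    required = [f"{kind}_{_cname(a, b)}" for a, b in CONTRASTS for kind in ("lfc", "q")]
    missing = [c for c in required if c not in contrasts.columns]
    if missing:
        raise ValueError(f"contrast table missing columns {missing}")
    df = contrasts.copy()
    l32 = df[f"lfc_{_cname('me3', 'me2')}"].to_numpy()
    l31 = df[f"lfc_{_cname('me3', 'me1')}"].to_numpy()
    l21 = df[f"lfc_{_cname('me2', 'me1')}"].to_numpy()
    q32 = df[f"q_{_cname('me3', 'me2')}"].to_numpy()
    q31 = df[f"q_{_cname('me3', 'me1')}"].to_numpy()
    q21 = df[f"q_{_cname('me2', 'me1')}"].to_numpy()

    is_me3 = (l32 > lfc_min) & (l31 > lfc_min) & (q32 < q_max) & (q31 < q_max)
    is_me2 = (-l32 > lfc_min) & (l21 > lfc_min) & (q32 < q_max) & (q21 < q_max)
    is_me1 = (-l31 > lfc_min) & (-l21 > lfc_min) & (q31 < q_max) & (q21 < q_max)
    mixed1 = (np.abs(l32) <= lfc_min) & (l31 > 0) & (l21 > 0)
    mixed2 = (np.abs(l21) <= lfc_min) & (-l31 > 0) & (-l32 > 0)

    zone = np.full(len(df), "ambiguous", dtype=object)
    zone[mixed2] = "MixedII"
    zone[mixed1] = "MixedI"  # Mixed I takes precedence over Mixed II
    zone[is_me1] = "me1"
    zone[is_me2] = "me2"
    zone[is_me3] = "me3"
    df["zone"] = zone
    df.attrs["lfc_min"] = lfc_min
    df.attrs["q_max"] = q_max
    return df


def zone_summary(calls: pd.DataFrame) -> pd.DataFrame:
    """Per-zone gene counts and median dominant-vs-runner-up log2FC.

    The runner-up is, per gene, the larger of the two non-dominant states, so
    the dominant-over-runner-up log2FC is the smaller of the dominant state's
    two pairwise log2FCs.  Mixed/ambiguous classes have no dominant state and
    report a missing median.  The three per-contrast medians are reported for
    every class.
    """
    l32 = calls[f"lfc_{_cname('me3', 'me2')}"]
    l31 = calls[f"lfc_{_cname('me3', 'me1')}"]
    l21 = calls[f"lfc_{_cname('me2', 'me1')}"]
    dom_vs_runner = pd.Series(np.nan, index=calls.index)
    zone = calls["zone"]
    dom_vs_runner[zone == "me3"] = np.minimum(l32, l31)[zone == "me3"]
    dom_vs_runner[zone == "me2"] = np.minimum(-l32, l21)[zone == "me2"]
    dom_vs_runner[zone == "me1"] = np.minimum(-l31, -l21)[zone == "me1"]
    rows = []
    for label in ZONE_LABELS:
        mask = zone == label
        n = int(mask.sum())
        rows.append(
            {
                "zone": label,
                "n": n,
                "median_dom_vs_runnerup": float(dom_vs_runner[mask].median()) if label in ("me3", "me2", "me1") and n else np.nan,
                "median_lfc_me3_vs_me2": float(l32[mask].median()) if n else np.nan,
                "median_lfc_me3_vs_me1": float(l31[mask].median()) if n else np.nan,
                "median_lfc_me2_vs_me1": float(l21[mask].median()) if n else np.nan,
            }
        )
    return pd.DataFrame(rows)


def zone_accuracy(calls: pd.DataFrame, truth: pd.DataFrame, labels=("me3", "me2", "me1")) -> float:
    """Fraction of truth genes in ``labels`` whose call matches their true zone."""
    merged = calls.merge(truth[["gene_id", "true_zone"]], on="gene_id")
    merged = merged[merged["true_zone"].isin(labels)]
    if merged.empty:
        raise ValueError("no genes with the requested true labels")
    return float((merged["zone"] == merged["true_zone"]).mean())


@dataclass
class ZoneClassificationResult:
    """Results of a zone-classification fit.

    ``calls`` carries one row per gene with the zone label, the three
    pairwise log2FCs and their p/q values; ``thresholds`` records the rule
    parameters so every label is reproducible from the stored contrasts.
    """

    calls: pd.DataFrame
    lfc_min: float
    q_max: float
    genotype: str = ""
    condition: str = ""

    @property
    def zone_counts(self) -> pd.Series:
        return self.calls["zone"].value_counts().reindex(ZONE_LABELS, fill_value=0)

    def summary(self) -> pd.DataFrame:
        return zone_summary(self.calls)

    def __str__(self) -> str:
        head = f"Zone classification ({self.genotype or 'sample'}, {self.condition or 'condition'}): " \
               f"lfc_min={self.lfc_min}, q_max={self.q_max}, n={len(self.calls)}"
        return head + "\n" + self.summary().to_string(index=False)


class ZoneClassifier:
    """Model object: thresholded pairwise-contrast zone classifier.

    Parameters
    ----------
    table : StateSignalTable
        Per-gene, per-replicate gene-body signal (with window-level values).
    lfc_min, q_max : float
        The pairwise log2FC and FDR thresholds of the zone rule.
    pooled_fdr : bool
        Apply BH across all three contrasts pooled instead of per contrast.
    """

    def __init__(self, table: StateSignalTable, lfc_min: float = 0.25, q_max: float = 0.5, pooled_fdr: bool = False):
        self.table = table
        self.lfc_min = lfc_min
        self.q_max = q_max
        self.pooled_fdr = pooled_fdr

    def fit(self) -> ZoneClassificationResult:
        contrasts = compute_contrasts(self.table, pooled_fdr=self.pooled_fdr)
        calls = classify(contrasts, self.lfc_min, self.q_max)
        return ZoneClassificationResult(
            calls=calls,
            lfc_min=self.lfc_min,
            q_max=self.q_max,
            genotype=self.table.genotype,
            condition=self.table.condition,
        )
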