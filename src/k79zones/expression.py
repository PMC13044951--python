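"""Differential expression between genotypes and its integration with zones.

DE calling uses the thresholded rule of the study design — up/down means a
1.4-fold change with BH q < 0.5 — on top of a transparent Welch t-test on
log2 expression (the engine is deliberately simple; the zone x DE
cross-tabulation is the analysis of interest).
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import bh_adjust, welch_t_p

DEFAULT_FOLD_MIN = 1.4
DEFAULT_Q_MAX = 0.5
ZONE_ORDER = ("me3", "me2", "me1", "MixedI", "MixedII", "ambiguous")


def call_de(
    expr: pd.DataFrame,
    mut: str,
    wt: str = "WT",
    condition: str | None = None,
    fold_min: float = DEFAULT_FOLD_MIN,
    q_max: float = DEFAULT_Q_MAX,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Call differential expression, mutant over WT.

    ``expr`` is long-format (gene_id, genotype, condition, replicate, value).
    Genes without expression > 0 in either group are excluded; log2FC is
    computed on pseudocounted group means; p comes from a two-sided Welch
    t-test on log2(value + pseudocount) and q from BH across tested genes.
    Status: up iff log2fc > log2(fold_min) and q < q_max; down iff
    log2fc < -log2(fold_min) and q < q_max; else unchanged.
    """
    df = expr
    if condition is not None:
        df = df[df["condition"] == condition]
    groups = {}
    for label in (wt, mut):
        sub = df[df["genotype"] == label]
        if sub.empty:
            raise ValueError(f"no expression rows for genotype {label!r}")
        piv = sub.pivot_table(index="gene_id", columns="replicate", values="value")
        if piv.shape[1] < 2:
            raise ValueError(f"genotype {label!r} needs >= 2 replicates")
        groups[label] = piv
    wt_v, mut_v = groups[wt], groups[mut]
    common = wt_v.index.intersection(mut_v.index)
    wt_v, mut_v = wt_v.loc[common], mut_v.loc[common]

    mean_wt = wt_v.mean(axis=1)
    mean_mut = mut_v.mean(axis=1)
    tested = (mean_wt > 0) | (mean_mut > 0)
    rows = []
    lfc_cut = math.log2(fold_min)
    for gid in common[tested]:
        x = np.log2(mut_v.loc[gid].to_numpy(dtype=float) + pseudocount)
        y = np.log2(wt_v.loc[gid].to_numpy(dtype=float) + pseudocount)
        lfc = math.log2((mean_mut[gid] + pseudocount) / (mean_wt[gid] + pseudocount))
        rows.append({"gene_id": gid, "mean_wt": mean_wt[gid], "mean_mut": mean_mut[gid],
                     "log2fc": lfc, "p": welch_t_p(x, y)})
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    status = np.full(len(out), "unchanged", dtype=object)
    status[(out["log2fc"] > lfc_cut) & (out["q"] < q_max)] = "up"
    status[(out["log2fc"] < -lfc_cut) & (out["q"] < q_max)] = "down"
    out["status"] = status
    out.attrs["fold_min"] = fold_min
    out.attrs["q_max"] = q_max
    return out


@dataclass
class ZoneDECrosstab:
    """Zone x DE-status counts over differentially expressed genes.

    ``counts`` is indexed by zone with ``down``/``up`` columns; percentages
    are derived from the stored counts, so reported numbers are always
    internally consistent.
    """

    counts: pd.DataFrame

    @classmethod
    def from_calls(cls, zone_calls: pd.DataFrame, de_calls: pd.DataFrame) -> "ZoneDECrosstab":
        zones = zone_calls.set_index("gene_id")["zone"]
        de = de_calls[de_calls["status"].isin(("up", "down"))].set_index("gene_id")["status"]
        zone_of_de = zones.reindex(de.index)
        tab = pd.crosstab(zone_of_de, de)
        tab = tab.reindex(index=[z for z in ZONE_ORDER if z in tab.index], fill_value=0)
        for col in ("down", "up"):
            if col not in tab.columns:
                tab[col] = 0
        return cls(counts=tab[["down", "up"]].astype(int))

    @classmethod
    def from_counts(cls, counts: dict[str, tuple[int, int]]) -> "ZoneDECrosstab":
        """Build directly from {zone: (down, up)} counts."""
        tab = pd.DataFrame.from_dict(counts, orient="index", columns=["down", "up"]).astype(int)
        tab.index.name = "zone"
        return cls(counts=tab)

    @property
    def n_de(self) -> int:
        return int(self.counts.to_numpy().sum())

    def zone_total(self, zone: str) -> int:
        return int(self.counts.loc[zone].sum())

    def three_zone_total(self) -> int:
        zones = [z for z in ("me3", "me2", "me1") if z in self.counts.index]
        return int(self.counts.loc[zones].to_numpy().sum())

    def down_percent(self, zone: str) -> float:
        """down / (down + up) x 100 within a zone, rounded to integer."""
        down, up = self.counts.at[zone, "down"], self.counts.at[zone, "up"]
        if down + up == 0:
            return float("nan")
        return round(100.0 * down / (down + up))

    def status_share_percent(self, zone: str, status: str) -> float:
        """Share of all DE genes of a status that sit in ``zone``, in percent.

        E.g. the fraction of all up-regulated genes located in the me1 zone.
        """
        total = int(self.counts[status].sum())
        if total == 0:
            return float("nan")
        return round(100.0 * self.counts.at[zone, status] / total)

    def summary(self) -> pd.DataFrame:
        df = self.counts.copy()
        df["n_de"] = df.sum(axis=1)
        df["down_percent"] = [self.down_percent(z) for z in df.index]
        return df


def zone_de_crosstab(zone_calls: pd.DataFrame, de_calls: pd.DataFrame) -> ZoneDECrosstab:
    """Cross-tabulate DE genes (status != unchanged) by zone label."""
    return ZoneDECrosstab.from_calls(zone_calls, de_calls)


@dataclass
class DEResult:
    """DE calls plus the thresholds that produced them."""

    calls: pd.DataFrame
    wt: str
    mut: str
    condition: str | None

    @property
    def n_up(self) -> int:
        return int((self.calls["status"] == "up").sum())

    @property
    def n_down(self) -> int:
        return int((self.calls["status"] == "down").sum())

    def crosstab(self, zone_calls: pd.DataFrame) -> ZoneDECrosstab:
        return ZoneDECrosstab.from_calls(zone_calls, self.calls)

    def summary(self) -> str:
        return (
            f"DE {self.mut} vs {self.wt}"
            + (f" ({self.condition})" if self.condition else "")
            + f": {len(self.calls)} tested, {self.n_up} up, {self.n_down} down "
            f"(fold >= {self.calls.attrs.get('fold_min')}, q < {self.calls.attrs.get('q_max')})"
        )


class DEModel:
    """Model object for the thresholded mutant-vs-WT DE call."""

    def __init__(self, expr: pd.DataFrame, mut: str, wt: str = "WT", condition: str | None = None,
                 fold_min: float = DEFAULT_FOLD_MIN, q_max: float = DEFAULT_Q_MAX, pseudocount: float = 0.5):
        self.expr = expr
        self.mut = mut
        self.wt = wt
        self.condition = condition
        self.fold_min = fold_min
        self.q_max = q_max
        self.pseudocount = pseudocount

    def fit(self) -> DEResult:
        calls = call_de(self.expr, self.mut, self.wt, self.condition, self.fold_min, self.q_max, self.pseudocount)
        return DEResult(calls, self.wt, self.mut, self.condition)
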