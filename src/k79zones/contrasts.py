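"""Genotype-driven redistribution of methylation states across zones.

Quantifies, per (zone, state), the mutant-minus-WT shift of gene-body
log2(state/H3) signal — the paired per-gene median is the effect size, the
unpaired two-sided Wilcoxon rank-sum supplies the significance level — and
runs covariate-ranking outlier analyses (e.g. genes sorted by H2Bubi or Dot1
occupancy).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .quant import StateSignalTable
from .stats import wilcoxon_rank_sum

_STATE_LOG2 = {"me1": "log2_me1", "me2": "log2_me2", "me3": "log2_me3"}


def log2fc_to_fold(x: float, sig_figs: int = 3) -> tuple[float, str]:
    """Convert a log2 fold-change to (fold magnitude, direction).

    The magnitude is 2^|x| rounded to ``sig_figs`` significant figures; the
    direction is ``lower`` for negative x, ``higher`` for positive, ``none``
    for zero.  E.g. -1.44 -> (2.7, 'lower') at two significant figures.
    """
    if not np.isfinite(x):
        raise ValueError("log2 fold-change must be finite")
    magnitude = float(f"%.{sig_figs}g" % (2.0 ** abs(x)))
    direction = "none" if x == 0 else ("lower" if x < 0 else "higher")
    return magnitude, direction


def per_zone_state_shift(
    wt: StateSignalTable,
    mut: StateSignalTable,
    calls: pd.DataFrame,
) -> pd.DataFrame:
    """Per-(zone, state) shift of gene-body log2(state/H3), mutant vs WT.

    Zones come from the WT classification; for each zone and methylation
    state the paired per-gene difference of replicate-averaged log2 values is
    summarized by its median (fold = 2^|median| with a direction flag), and a
    two-sided Wilcoxon rank-sum test compares the WT and mutant per-gene
    log2 distributions.  Empty zones are skipped.
    """
    wt_mean = wt.rep_mean()
    mut_mean = mut.rep_mean()
    common = wt_mean.index.intersection(mut_mean.index)
    if len(common) != len(wt_mean) or len(common) != len(mut_mean):
        raise ValueError("WT and mutant tables must share a gene universe")
    zones = calls.set_index("gene_id")["zone"].reindex(common)
    rows = []
    for zone in ("me3", "me2", "me1", "MixedI", "MixedII", "ambiguous"):
        ids = zones.index[zones == zone]
        if len(ids) == 0:
            continue
        for state, col in _STATE_LOG2.items():
            a = wt_mean.loc[ids, col].to_numpy()
            b = mut_mean.loc[ids, col].to_numpy()
            median = float(np.median(b - a))
            fold, direction = log2fc_to_fold(median)
            rows.append(
                {
                    "zone": zone,
                    "state": state,
                    "n_genes": len(ids),
                    "median_log2fc": median,
                    "fold_change": fold,
                    "direction": direction,
                    "wilcoxon_p": wilcoxon_rank_sum(a, b),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class ZoneShiftResult:
    """Per-(zone, state) redistribution table with a summary() view."""

    shifts: pd.DataFrame
    wt_label: str = "WT"
    mut_label: str = "mutant"

    def lookup(self, zone: str, state: str) -> pd.Series:
        sel = self.shifts[(self.shifts["zone"] == zone) & (self.shifts["state"] == state)]
        if sel.empty:
            raise KeyError((zone, state))
        return sel.iloc[0]

    def summary(self) -> pd.DataFrame:
        return self.shifts.copy()

    def __str__(self) -> str:
        return (
            f"Zone/state shifts: {self.mut_label} vs {self.wt_label}\n"
            + self.shifts.to_string(index=False)
        )


class ZoneShiftModel:
    """Model object for mutant-vs-WT redistribution across WT-defined zones."""

    def __init__(self, wt: StateSignalTable, mut: StateSignalTable, calls: pd.DataFrame):
        self.wt = wt
        self.mut = mut
        self.calls = calls

    def fit(self) -> ZoneShiftResult:
        shifts = per_zone_state_shift(self.wt, self.mut, self.calls)
        return ZoneShiftResult(shifts, wt_label=self.wt.genotype or "WT", mut_label=self.mut.genotype or "mutant")


@dataclass
class RankedOutlierReport:
    """Genes ordered by a covariate, with state means inside/outside the top set."""

    covariate: str
    order: list
    top_n: int
    state_means: pd.DataFrame  # index: state; columns: top, remainder

    def top_genes(self) -> list:
        return self.order[: self.top_n]


def _elbow_top_n(sorted_values: np.ndarray) -> int:
    """Default top-n: the elbow of the descending covariate curve.

    Marks the point maximizing the discrete second difference, bounded away
    from the ends.
    """
    n = len(sorted_values)
    if n < 10:
        return max(1, n // 5)
    second = np.diff(sorted_values, n=2)
    lo, hi = 2, max(3, n // 2)
    k = int(np.argmax(second[lo:hi])) + lo + 1
    return min(max(k, 5), n - 5)


def rank_outliers(table: StateSignalTable, covariate: str, top_n: int | None = None) -> RankedOutlierReport:
    """Rank genes by a covariate (descending) and contrast the top-n subset.

    Reports the mean log2(state/H3) of each methylation state inside the
    top-n set versus the remainder.  Ties in the covariate are broken by
    gene_id so the ordering is a deterministic permutation of the gene set.
    """
    mean = table.rep_mean()
    col = f"log2_{covariate}" if f"log2_{covariate}" in mean.columns else covariate
    if col not in mean.columns:
        raise ValueError(f"covariate {covariate!r} not present in the signal table")
    ordered = mean.iloc[np.lexsort((mean.index.to_numpy(), -mean[col].to_numpy()))]
    n = len(ordered)
    if top_n is None:
        top_n = _elbow_top_n(ordered[col].to_numpy())
    if not 0 < top_n < n:
        raise ValueError(f"top_n must be in (0, {n})")
    top = ordered.iloc[:top_n]
    rest = ordered.iloc[top_n:]
    state_means = pd.DataFrame(
        {
            "top": {s: float(top[c].mean()) for s, c in _STATE_LOG2.items()},
            "remainder": {s: float(rest[c].mean()) for s, c in _STATE_LOG2.items()},
        }
    )
    state_means.index.name = "state"
    return RankedOutlierReport(covariate=covariate, order=list(ordered.index), top_n=top_n, state_means=state_means)
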