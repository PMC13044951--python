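"""Zone stability and directional transitions between two conditions.

Genes classified under two conditions with identical thresholds are paired
into transitions; a gene is stable when it keeps its label and dynamic when
it switches.  The transition matrix (origin rows, destination columns)
yields per-origin stability fractions and the net flow toward each zone.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import ZONE_LABELS


def compare_conditions(calls_a: pd.DataFrame, calls_b: pd.DataFrame, zones_only: bool = False) -> pd.DataFrame:
    """Pair two classifications into per-gene zone transitions.

    Requires identical gene universes and identical classifier thresholds
    (mixed-threshold comparisons are refused).  ``zones_only`` restricts
    origins to the three zones {me3, me2, me1}; any label change, including
    into a Mixed class, counts as dynamic.
    """
    for key in ("lfc_min", "q_max"):
        ta, tb = calls_a.attrs.get(key), calls_b.attrs.get(key)
        if ta is not None and tb is not None and ta != tb:
            raise ValueError(f"classifier thresholds differ between conditions ({key}: {ta} vs {tb})")
    a = calls_a.set_index("gene_id")["zone"]
    b = calls_b.set_index("gene_id")["zone"]
    if set(a.index) != set(b.index):
        diff = sorted(set(a.index) ^ set(b.index))
        raise ValueError(f"gene universes differ; symmetric difference: {diff[:20]}{'...' if len(diff) > 20 else ''}")
    b = b.reindex(a.index)
    out = pd.DataFrame({"gene_id": a.index, "zone_a": a.to_numpy(), "zone_b": b.to_numpy()})
    if zones_only:
        out = out[out["zone_a"].isin(("me3", "me2", "me1"))].reset_index(drop=True)
    out["status"] = np.where(out["zone_a"] == out["zone_b"], "stable", "dynamic")
    return out


def transition_matrix(transitions: pd.DataFrame) -> pd.DataFrame:
    """Labels x labels count matrix; rows = origin, columns = destination."""
    if transitions.empty:
        raise ValueError("no transitions")
    mat = pd.crosstab(transitions["zone_a"], transitions["zone_b"])
    mat = mat.reindex(index=ZONE_LABELS, columns=ZONE_LABELS, fill_value=0)
    mat = mat.loc[mat.sum(axis=1) > 0]
    mat.index.name = "origin"
    mat.columns.name = "destination"
    return mat


def stability_fractions(matrix: pd.DataFrame) -> tuple[pd.Series, float]:
    """Per-origin stable fraction (diagonal / row sum) and the overall fraction."""
    diag = pd.Series({z: matrix.at[z, z] if z in matrix.columns else 0 for z in matrix.index}, dtype=float)
    row_sums = matrix.sum(axis=1).astype(float)
    per_origin = diag / row_sums
    overall = float(diag.sum() / row_sums.sum())
    return per_origin, overall


def directional_bias(matrix: pd.DataFrame) -> pd.Series:
    """Net flow (inflow - outflow among dynamic genes) per destination label.

    Net flows sum to zero; the attribute ``max_inflow_label`` on the returned
    Series names the label with maximal net inflow.
    """
    labels = sorted(set(matrix.index) | set(matrix.columns), key=ZONE_LABELS.index)
    full = matrix.reindex(index=labels, columns=labels, fill_value=0).astype(float)
    off = full.to_numpy().copy()
    np.fill_diagonal(off, 0.0)
    inflow = off.sum(axis=0)
    outflow = off.sum(axis=1)
    net = pd.Series(inflow - outflow, index=labels, name="net_flow")
    net.attrs["max_inflow_label"] = str(net.idxmax())
    return net


@dataclass
class ZoneTransitionResult:
    """Transitions, counts and stability diagnostics for one condition pair."""

    transitions: pd.DataFrame
    condition_a: str = "A"
    condition_b: str = "B"

    @property
    def matrix(self) -> pd.DataFrame:
        return transition_matrix(self.transitions)

    @property
    def stable_fraction(self) -> float:
        return stability_fractions(self.matrix)[1]

    def per_origin_stability(self) -> pd.Series:
        return stability_fractions(self.matrix)[0]

    def net_flow(self) -> pd.Series:
        return directional_bias(self.matrix)

    def sankey_table(self) -> pd.DataFrame:
        """Long-format (source, target, count) table for Sankey-style plots."""
        mat = self.matrix
        rows = [
            {"source": o, "target": d, "count": int(mat.at[o, d])}
            for o in mat.index
            for d in mat.columns
            if mat.at[o, d] > 0
        ]
        return pd.DataFrame(rows)

    def summary(self) -> pd.DataFrame:
        per_origin, overall = stability_fractions(self.matrix)
        df = pd.DataFrame({"n": self.matrix.sum(axis=1), "stable_fraction": per_origin})
        df.loc["overall"] = [int(self.matrix.to_numpy().sum()), overall]
        return df

    def __str__(self) -> str:
        return (
            f"Zone transitions {self.condition_a} -> {self.condition_b}: "
            f"{(self.transitions['status'] == 'stable').sum()} stable / "
            f"{(self.transitions['status'] == 'dynamic').sum()} dynamic\n"
            + self.summary().to_string()
        )


class ZoneDynamics:
    """Model object pairing two same-threshold classifications."""

    def __init__(self, calls_a: pd.DataFrame, calls_b: pd.DataFrame, zones_only: bool = False,
                 condition_a: str = "A", condition_b: str = "B"):
        self.calls_a = calls_a
        self.calls_b = calls_b
        self.zones_only = zones_only
        self.condition_a = condition_a
        self.condition_b = condition_b

    def fit(self) -> ZoneTransitionResult:
        transitions = compare_conditions(self.calls_a, self.calls_b, zones_only=self.zones_only)
        return ZoneTransitionResult(transitions, self.condition_a, self.condition_b)
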