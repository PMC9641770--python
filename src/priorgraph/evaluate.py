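"""Scoring inferred networks: confusion counts, MCC, replication summaries.

Two networks are compared over the union of their node sets; a node absent
from one network contributes no edges there, so all its pairs count as
non-edges for that network. Each unordered node pair is classified exactly
once into TP/TN/FP/FN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import PSEUDO_PRIOR, PriorMatrix, UndirectedNetwork
from .simulate import OmicsDataset


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion(pred: UndirectedNetwork, truth: UndirectedNetwork) -> ConfusionCounts:
    """Edge/non-edge confusion counts over the union of node sets."""
    nodes = sorted(set(pred.nodes) | set(truth.nodes))
    tp = tn = fp = fn = 0
    for k, a in enumerate(nodes):
        for b in nodes[k + 1 :]:
            in_p = pred.has_edge(a, b)
            in_t = truth.has_edge(a, b)
            if in_p and in_t:
                tp += 1
            elif in_p:
                fp += 1
            elif in_t:
                fn += 1
            else:
                tn += 1
    return ConfusionCounts(tp, tn, fp, fn)


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when any denominator factor is 0."""
    tp, tn, fp, fn = float(c.tp), float(c.tn), float(c.fp), float(c.fn)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / np.sqrt(denom)


def sensitivity_specificity(c: ConfusionCounts) -> tuple[float, float]:
    """(TP/(TP+FN), TN/(TN+FP)) with the 0/0 -> 0 convention."""
    sens = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else 0.0
    spec = c.tn / (c.tn + c.fp) if (c.tn + c.fp) > 0 else 0.0
    return sens, spec


def cross_cohort_mcc(net_a: UndirectedNetwork, net_b: UndirectedNetwork) -> float:
    """MCC between two independently inferred networks (replication score)."""
    return mcc(confusion(net_a, net_b))


def edge_support_summary(
    inferred: UndirectedNetwork,
    P: PriorMatrix,
    replication_data: OmicsDataset,
    replication_net: UndirectedNetwork,
) -> pd.DataFrame:
    """Per-edge prior/replication status with replication-data correlation.

    For each inferred edge: whether it carries a non-pseudo prior, whether it
    is present in the replication network, and the absolute marginal
    correlation of its endpoints in the (gaussianised) replication data.
    Edges with an endpoint missing from the replication data are flagged and
    get no correlation.
    """
    from .infer import gaussianize

    gauss = gaussianize(
        OmicsDataset(replication_data.values.dropna(axis=1),)
    ).values
    prior_nodes = set(P.nodes)
    rows = []
    for a, b in sorted(inferred.edges):
        has_prior = (a in prior_nodes and b in prior_nodes
                     and P.get(a, b) > PSEUDO_PRIOR)
        replicated = replication_net.has_edge(a, b)
        if a in gauss.columns and b in gauss.columns:
            r = float(np.corrcoef(gauss[a], gauss[b])[0, 1])
            missing = False
        else:
            r = np.nan
            missing = True
        rows.append({
            "node_a": a, "node_b": b, "has_prior": has_prior,
            "replicated": replicated, "abs_correlation": abs(r) if not missing else np.nan,
            "endpoint_missing": missing,
        })
    return pd.DataFrame(rows)
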