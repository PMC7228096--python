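"""Rooting-accuracy measures.

For true (error-free) gene trees, rooting error is the clade-based rooted RF
distance between the inferred rooting and the true rooting of the same
unrooted topology: zero iff the root edge was recovered exactly, and
otherwise the number of intermediate nodes between the inferred and true root
edges.  For reconstructed (error-prone) trees the *adjusted* RF distance,
RF(T1, T2) - URF(T1, T2), isolates rooting disagreement from topological
disagreement.  For collections without a known root, the root balance ratio
(smaller root-child clade over larger) is the proxy metric.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .trees import RootedTree, TreeError, rf_rooted, rf_unrooted

__all__ = [
    "AccuracyRecord",
    "rooting_error",
    "adjusted_rf",
    "root_balance",
    "balance_squared_error",
    "aggregate_accuracy",
]


@dataclass
class AccuracyRecord:
    """Accuracy of one method on one gene family."""

    family: str
    method: str
    dataset: str = ""
    correct: bool = False
    rf_absolute: float = 0.0
    rf_normalized: float = 0.0
    rf_adjusted: Optional[float] = None
    balance: Optional[float] = None
    tie_count: int = 1


def rooting_error(
    true_tree: RootedTree, inferred: RootedTree
) -> tuple[int, float, bool]:
    """(absolute RF, normalized RF, correct?) between the true rooting and an
    inferred rooting of the same unrooted topology.  Normalization divides by
    the leaf count.  Raises for topologically different trees (use
    :func:`adjusted_rf` for those)."""
    if rf_unrooted(true_tree, inferred) != 0:
        raise TreeError(
            "trees differ in unrooted topology; rooting_error is undefined "
            "(use adjusted_rf)"
        )
    absolute = rf_rooted(true_tree, inferred)
    return absolute, absolute / true_tree.n_leaves, absolute == 0


def adjusted_rf(true_tree: RootedTree, recon_tree: RootedTree) -> int:
    """RF(T1, T2) - URF(T1, T2): the rooting component of the disagreement
    between a true tree and a (possibly misreconstructed) rooted tree on the
    same leaves.  Always >= 0; zero when the reconstructed tree is rooted at
    the position matching the true root."""
    return rf_rooted(true_tree, recon_tree) - rf_unrooted(true_tree, recon_tree)


def root_balance(tree: RootedTree) -> float:
    """Leaves in the smaller root-child clade divided by leaves in the
    larger; 1 for a perfectly balanced root."""
    if tree.n_leaves < 2:
        raise TreeError("root balance needs at least 2 leaves")
    a, b = tree.root.children
    na = sum(1 for n in RootedTree(a, validate=False).postorder() if n.is_leaf)
    nb = tree.n_leaves - na
    return min(na, nb) / max(na, nb)


def balance_squared_error(balances: list[float], expected: float) -> float:
    """Mean squared deviation of observed root balance ratios from an
    expected ratio (e.g. the species-level taxonomic split)."""
    if not balances:
        raise ValueError("need at least one balance ratio")
    arr = np.asarray(balances, dtype=float)
    return float(np.mean((arr - expected) ** 2))


def aggregate_accuracy(records: list[AccuracyRecord]) -> pd.DataFrame:
    """Per (dataset, method): percent correct, mean absolute/normalized RF,
    and the three quartiles of the absolute RF distribution (inclusive
    linear-interpolation convention)."""
    if not records:
        raise ValueError("need at least one accuracy record")
    df = pd.DataFrame(
        {
            "dataset": r.dataset,
            "method": r.method,
            "correct": bool(r.correct),
            "rf_absolute": r.rf_absolute,
            "rf_normalized": r.rf_normalized,
        }
        for r in records
    )

    def agg(group: pd.DataFrame) -> pd.Series:
        q1, q2, q3 = np.quantile(group["rf_absolute"], [0.25, 0.5, 0.75])
        return pd.Series(
            {
                "n": len(group),
                "percent_correct": 100.0 * group["correct"].mean(),
                "mean_rf": group["rf_absolute"].mean(),
                "mean_rf_normalized": group["rf_normalized"].mean(),
                "rf_q1": q1,
                "rf_q2": q2,
                "rf_q3": q3,
            }
        )

    out = (
        df.groupby(["dataset", "method"], sort=True)
        .apply(agg, include_groups=False)
        .reset_index()
    )
    out["n"] = out["n"].astype(int)
    return out
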