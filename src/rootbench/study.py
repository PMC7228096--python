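"""Desk-scale reproductions of the headline benchmark quantities.

Each function runs the full pipeline at a reduced number of families per set
(default 25, against 100 in the full study) and returns summary statistics
together with the problem size and the standard error of the estimate, so
callers can judge sampling uncertainty.  All randomness derives from the
given seed.
"""

from __future__ import annotations

import math

import numpy as np

from .metrics import root_balance
from .pipeline import ExperimentConfig, run_experiment
from .simulate import ScalingScheme
from .trees import RootedTree, TreeNode

__all__ = [
    "dtl_baseline_study",
    "mad_autocorrelated_study",
    "random_rooting_study",
    "expected_root_balance",
    "AUTOCORRELATED_LOW_DEVIATION",
    "UNIFORM_WIDE",
]

AUTOCORRELATED_LOW_DEVIATION = ScalingScheme(
    "autocorrelated", start_rate=1.0, sigma2=0.05
)
UNIFORM_WIDE = ScalingScheme("uniform", lo=0.3, hi=3.0)


def _se(values: np.ndarray) -> float:
    n = len(values)
    return float(np.std(values, ddof=1) / math.sqrt(n)) if n > 1 else float("nan")


def _cluster_se(records, column: str) -> float:
    """Standard error of the overall mean with records clustered by family.

    The four branch-scaling schemes of a set reuse the same simulated
    families (and, for length-blind methods, essentially the same rooting),
    so the independent unit of replication is the family, not the record."""
    per_family = records.groupby(["preset", "family"])[column].mean()
    return _se(per_family.to_numpy(dtype=float))


def dtl_baseline_study(
    preset: str, families: int = 25, seed: int = 1
) -> dict:
    """DTL rooting (costs <1,2,3>) on one baseline event-rate preset:
    ``families`` families are simulated independently for each of the four
    branch-scaling schemes; the mean absolute RF to the true rooting and the
    percentage of exactly recovered roots (seeded arbitrary tie pick) are
    pooled over all of them."""
    from .pipeline import DEFAULT_SCHEMES, derive_seed

    rf_all, correct_all = [], []
    for i, scheme in enumerate(DEFAULT_SCHEMES):
        cfg = ExperimentConfig(
            collections=("baseline",),
            presets_filter=(preset,),
            families_per_set=families,
            methods=("dtl",),
            schemes=(scheme,),
            master_seed=derive_seed(seed, "scheme", i),
        )
        res = run_experiment(cfg)
        rf_all.append(res.records["rf_absolute"].to_numpy(dtype=float))
        correct_all.append(res.records["correct"].to_numpy(dtype=float))
    rf = np.concatenate(rf_all)
    correct = np.concatenate(correct_all)
    return {
        "mean_rf": float(rf.mean()),
        "percent_correct": 100.0 * float(correct.mean()),
        "n": len(rf),
        "n_families": len(rf),  # one independent family per record
        "se_rf": _se(rf),
        "se_percent": 100.0 * _se(correct),
    }


def mad_autocorrelated_study(families: int = 25, seed: int = 1) -> dict:
    """MAD rooting under the low-deviation autocorrelated clock (start rate
    1, sigma^2 = 0.05), averaged over the three baseline event-rate
    presets."""
    cfg = ExperimentConfig(
        collections=("baseline",),
        families_per_set=families,
        methods=("mad",),
        schemes=(AUTOCORRELATED_LOW_DEVIATION,),
        master_seed=seed,
    )
    res = run_experiment(cfg)
    rf = res.records["rf_absolute"].to_numpy(dtype=float)
    return {
        "mean_rf": float(rf.mean()),
        "n": len(rf),
        "se_rf": _cluster_se(res.records, "rf_absolute"),
    }


def random_rooting_study(families: int = 25, seed: int = 1) -> dict:
    """Uniformly random rooting on low-DTL baseline families (wide uniform
    scaling): the mean RF any real method must beat."""
    cfg = ExperimentConfig(
        collections=("baseline",),
        presets_filter=("low",),
        families_per_set=families,
        methods=("random",),
        schemes=(UNIFORM_WIDE,),
        master_seed=seed,
    )
    res = run_experiment(cfg)
    rf = res.records["rf_absolute"].to_numpy(dtype=float)
    return {"mean_rf": float(rf.mean()), "n": len(rf), "se_rf": _se(rf)}


def expected_root_balance(larger: int = 406, smaller: int = 98) -> float:
    """Root balance ratio of a tree whose root splits ``larger`` vs
    ``smaller`` leaves (the expected taxonomic split of the two-phyla
    empirical design), computed by building such a tree and measuring it."""

    def caterpillar(labels):
        node = TreeNode(labels[0], 1.0)
        for lab in labels[1:]:
            parent = TreeNode(None, 1.0)
            parent.add_child(node)
            parent.add_child(TreeNode(lab, 1.0))
            node = parent
        return node

    root = TreeNode(None, 0.0)
    root.add_child(caterpillar([f"x{i}" for i in range(larger)]))
    root.add_child(caterpillar([f"y{i}" for i in range(smaller)]))
    return root_balance(RootedTree(root))
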