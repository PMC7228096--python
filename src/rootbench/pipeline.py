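"""Experiment orchestration: simulate gene-family collections, root every
family with every configured method, and aggregate accuracy tables.

The study design mirrored here: ``families_per_set`` species trees are drawn
once and reused across event-rate presets (each species tree hosts one gene
family per preset); each resulting true gene tree is branch-scaled under
every configured scaling scheme; branch-length methods (midpoint, MAD, MV)
root the scaled trees while DTL and random rooting see topology only.  DTL
results are therefore computed once per family and cost vector and reused
across scaling schemes (only the seeded arbitrary tie pick varies per
scheme).  All randomness derives from the master seed through a stable
hashing scheme, so runs are reproducible end to end.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from .metrics import AccuracyRecord, aggregate_accuracy, root_balance, rooting_error
from .rooting import (
    EventCosts,
    RootingResult,
    dtl_root,
    mad_root,
    midpoint_root,
    mv_root,
    random_root,
)
from .simulate import (
    EventRates,
    GeneFamilyHistory,
    ScalingScheme,
    SpeciesTreeTimed,
    scale_branches,
    simulate_gene_history,
    simulate_species_tree,
    summarize_families,
)
from .trees import root_at, unroot, write_newick

__all__ = [
    "ExperimentConfig",
    "ExperimentResult",
    "run_experiment",
    "event_cost_sweep",
    "derive_seed",
    "BASELINE_PRESETS",
    "ADDITIVE_PRESETS",
    "VERY_HIGH_PRESETS",
    "DEFAULT_SCHEMES",
    "DEFAULT_COST_VECTORS",
    "simulate_set",
]

# Event-rate presets: (duplication rate, total transfer rate); the loss rate
# is derived as 0.8 * (duplication + additive transfer rate) in EventRates.
BASELINE_PRESETS = {
    "low": (0.13, 0.27),
    "medium": (0.3, 0.6),
    "high": (0.6, 1.2),
}
VERY_HIGH_PRESETS = {
    "vh2": (0.6, 2.0),
    "vh3": (0.6, 3.0),
    "vh4": (0.6, 4.0),
}
ADDITIVE_PRESETS = BASELINE_PRESETS  # additive collection: additive_fraction 1

DEFAULT_SCHEMES = (
    ScalingScheme("uniform", lo=0.3, hi=3.0),
    ScalingScheme("uniform", lo=0.2, hi=5.0),
    ScalingScheme("autocorrelated", start_rate=1.0, sigma2=0.05),
    ScalingScheme("autocorrelated", start_rate=1.0, sigma2=0.25),
)

DEFAULT_COST_VECTORS = ((1.0, 2.0, 3.0), (1.0, 1.0, 2.0), (1.0, 2.0, 4.0), (1.0, 2.0, 5.0))


def derive_seed(*parts) -> int:
    """Stable sub-seed derived from heterogeneous parts (below 2**31)."""
    text = ":".join(str(p) for p in parts)
    digest = hashlib.sha256(text.encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


@dataclass
class ExperimentConfig:
    """Configuration of a full benchmark run.

    ``collections`` is any subset of {baseline, additive, very_high};
    ``cost_vectors`` are (loss, duplication, transfer) triples for the DTL
    sweep.  ``families_per_set`` defaults to the full-study 100; scaled-down
    runs simply lower it."""

    collections: Sequence[str] = ("baseline",)
    presets_filter: Optional[Sequence[str]] = None  # None = all presets
    families_per_set: int = 100
    n_taxa: int = 100
    birth: float = 5.0
    death: float = 1.0
    methods: Sequence[str] = ("midpoint", "mad", "mv", "dtl", "random")
    cost_vectors: Sequence[tuple[float, float, float]] = ((1.0, 2.0, 3.0),)
    schemes: Sequence[ScalingScheme] = DEFAULT_SCHEMES
    master_seed: int = 0
    outdir: Optional[str] = None

    def __post_init__(self):
        known = {"baseline", "additive", "very_high"}
        bad = set(self.collections) - known
        if bad:
            raise ValueError(f"unknown collections: {sorted(bad)}")
        known_methods = {"midpoint", "mad", "mv", "dtl", "random"}
        bad = set(self.methods) - known_methods
        if bad:
            raise ValueError(f"unknown methods: {sorted(bad)}")

    def presets(self, collection: str) -> dict[str, EventRates]:
        if collection == "baseline":
            table, af = BASELINE_PRESETS, 0.3
        elif collection == "additive":
            table, af = ADDITIVE_PRESETS, 1.0
        else:
            table, af = VERY_HIGH_PRESETS, 0.3
        return {
            name: EventRates(d, t, additive_fraction=af, birth_rate=self.birth, death_rate=self.death)
            for name, (d, t) in table.items()
            if self.presets_filter is None or name in self.presets_filter
        }

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text())
        schemes = []
        for s in raw.pop("schemes", []):
            schemes.append(ScalingScheme(**s))
        kwargs = dict(raw)
        if schemes:
            kwargs["schemes"] = tuple(schemes)
        if "cost_vectors" in kwargs:
            kwargs["cost_vectors"] = tuple(tuple(v) for v in kwargs["cost_vectors"])
        return cls(**kwargs)


@dataclass
class ExperimentResult:
    records: pd.DataFrame  # one row per family x scheme x method (x costs)
    summary: pd.DataFrame  # per (dataset, method) aggregates
    manifest: dict


def _simulate_families(
    config: ExperimentConfig,
    collection: str,
    preset_name: str,
    rates: EventRates,
) -> tuple[list[SpeciesTreeTimed], list[GeneFamilyHistory], dict]:
    """Simulate the families of one set, resimulating extinct families with
    fresh derived seeds.  Species trees depend only on the family index, so
    the same species trees host every preset (and collection)."""
    strees, histories = [], []
    resimulations = 0
    for fam in range(config.families_per_set):
        sp_seed = derive_seed(config.master_seed, "species", fam)
        stree = simulate_species_tree(
            config.n_taxa, rates.birth_rate, rates.death_rate, seed=sp_seed
        )
        attempt = 0
        while True:
            g_seed = derive_seed(
                config.master_seed, "gene", collection, preset_name, fam, attempt
            )
            hist = simulate_gene_history(stree, rates, seed=g_seed)
            if not hist.extinct:
                break
            attempt += 1
            resimulations += 1
            if attempt > 1000:
                raise RuntimeError(
                    f"family {fam} of {collection}/{preset_name} kept going extinct"
                )
        strees.append(stree)
        histories.append(hist)
    log = {
        "resimulations": resimulations,
        "degraded_transfers": sum(h.degraded_transfers for h in histories),
    }
    return strees, histories, log


def simulate_set(
    config: ExperimentConfig, collection: str, preset_name: str
) -> tuple[list[SpeciesTreeTimed], list[GeneFamilyHistory], dict]:
    """Public wrapper: simulate one (collection, preset) set of families."""
    rates = config.presets(collection)[preset_name]
    return _simulate_families(config, collection, preset_name, rates)


def run_experiment(config: ExperimentConfig) -> ExperimentResult:
    """Run the full benchmark defined by ``config`` and return per-family
    records, per-set summaries, and a reproducibility manifest."""
    rows = []
    records: list[AccuracyRecord] = []
    manifest: dict = {
        "master_seed": config.master_seed,
        "families_per_set": config.families_per_set,
        "n_taxa": config.n_taxa,
        "birth": config.birth,
        "death": config.death,
        "sets": {},
    }

    for collection in config.collections:
        for preset_name, rates in config.presets(collection).items():
            strees, histories, log = _simulate_families(
                config, collection, preset_name, rates
            )
            set_base = f"{collection}/{preset_name}"
            manifest["sets"][set_base] = {
                **log,
                "loss_rate": rates.loss_rate,
                "summary": summarize_families(histories).iloc[0].to_dict(),
            }

            # topology-only methods: once per family (and cost vector)
            dtl_cache: dict[tuple[int, tuple], RootingResult] = {}
            unrooted_cache = {}
            for fam, hist in enumerate(histories):
                unrooted_cache[fam] = unroot(hist.tree)
            if "dtl" in config.methods:
                for fam, hist in enumerate(histories):
                    for cv in config.cost_vectors:
                        dtl_cache[(fam, cv)] = dtl_root(
                            unrooted_cache[fam],
                            strees[fam].tree,
                            hist.leaf_map,
                            EventCosts(*cv),
                        )

            for scheme in config.schemes:
                dataset = f"{set_base}/{scheme.name}"
                for fam, hist in enumerate(histories):
                    scale_seed = derive_seed(
                        config.master_seed, "scale", collection, preset_name,
                        scheme.name, fam,
                    )
                    scaled = scale_branches(hist.tree, scheme, seed=scale_seed)
                    scaled_unrooted = unroot(scaled)

                    results: list[tuple[str, str, RootingResult]] = []
                    for method in config.methods:
                        if method == "midpoint":
                            results.append((method, "", midpoint_root(scaled_unrooted)))
                        elif method == "mad":
                            results.append((method, "", mad_root(scaled_unrooted)))
                        elif method == "mv":
                            results.append((method, "", mv_root(scaled_unrooted)))
                        elif method == "random":
                            seed = derive_seed(
                                config.master_seed, "randroot", dataset, fam
                            )
                            results.append((method, "", random_root(scaled_unrooted, seed)))
                        elif method == "dtl":
                            for cv in config.cost_vectors:
                                results.append(
                                    (method, ",".join(f"{c:g}" for c in cv), dtl_cache[(fam, cv)])
                                )

                    for method, cv_label, result in results:
                        pick_seed = derive_seed(
                            config.master_seed, "pick", dataset, fam, method, cv_label
                        )
                        pos = result.pick(pick_seed)
                        # topology-only picks refer to edges of the unscaled
                        # unrooted tree; length-aware picks to the scaled one
                        host = (
                            unrooted_cache[fam]
                            if pos.topology_only
                            else scaled_unrooted
                        )
                        inferred = root_at(host, pos)
                        rf, rf_norm, correct = rooting_error(hist.tree, inferred)
                        method_label = (
                            method if not cv_label else f"{method}<{cv_label}>"
                        )
                        rec = AccuracyRecord(
                            family=f"{set_base}:{fam}",
                            method=method_label,
                            dataset=dataset,
                            correct=correct,
                            rf_absolute=rf,
                            rf_normalized=rf_norm,
                            balance=root_balance(inferred),
                            tie_count=result.tie_count,
                        )
                        records.append(rec)
                        rows.append(
                            {
                                "collection": collection,
                                "preset": preset_name,
                                "scheme": scheme.name,
                                "family": fam,
                                "n_leaves": hist.n_leaves,
                                "method": method_label,
                                "rf_absolute": rf,
                                "rf_normalized": rf_norm,
                                "correct": correct,
                                "balance": rec.balance,
                                "tie_count": result.tie_count,
                            }
                        )

    records_df = pd.DataFrame(rows)
    summary = aggregate_accuracy(records)
    result = ExperimentResult(records_df, summary, manifest)
    if config.outdir:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        records_df.to_csv(outdir / "accuracy.tsv", sep="\t", index=False)
        summary.to_csv(outdir / "summary.tsv", sep="\t", index=False)
        (outdir / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))
    return result


def event_cost_sweep(config: ExperimentConfig) -> pd.DataFrame:
    """Compare DTL rooting accuracy across event-cost vectors: per cost
    vector and data set, percent correct and mean absolute RF."""
    if len(config.cost_vectors) < 2:
        raise ValueError("event_cost_sweep needs at least 2 cost vectors")
    cfg = ExperimentConfig(
        collections=config.collections,
        families_per_set=config.families_per_set,
        n_taxa=config.n_taxa,
        birth=config.birth,
        death=config.death,
        methods=("dtl",),
        cost_vectors=config.cost_vectors,
        schemes=config.schemes,
        master_seed=config.master_seed,
    )
    result = run_experiment(cfg)
    summary = result.summary.copy()
    summary["cost_vector"] = summary["method"].str.extract(r"<(.*)>")
    return summary[
        ["dataset", "cost_vector", "n", "percent_correct", "mean_rf"]
    ].sort_values(["dataset", "cost_vector"], ignore_index=True)


def export_set(
    outdir: str | Path,
    strees: list[SpeciesTreeTimed],
    histories: list[GeneFamilyHistory],
    manifest: Optional[dict] = None,
) -> None:
    """Write one simulated set to disk: per-family newicks (true rooted and
    unrooted gene trees), leaf->species mappings, event logs, and the shared
    species trees."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for i, (stree, hist) in enumerate(zip(strees, histories)):
        (outdir / f"species_tree_{i}.nwk").write_text(write_newick(stree.tree) + "\n")
        (outdir / f"genetree_{i}.true.nwk").write_text(write_newick(hist.tree) + "\n")
        (outdir / f"genetree_{i}.unrooted.nwk").write_text(
            write_newick(unroot(hist.tree)) + "\n"
        )
        with open(outdir / f"mapping_{i}.tsv", "w") as fh:
            for leaf, sp in sorted(hist.leaf_map.items()):
                fh.write(f"{leaf}\t{sp}\n")
        with open(outdir / f"genetree_{i}.events.tsv", "w") as fh:
            fh.write("kind\ttime\tdonor\trecipient\tsurviving\n")
            for ev in hist.events:
                rec = "" if ev.recipient is None else str(ev.recipient)
                fh.write(f"{ev.kind}\t{ev.time:.6f}\t{ev.donor}\t{rec}\t{int(ev.surviving)}\n")
    if manifest is not None:
        (outdir / "set_manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))
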