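"""Orchestration of the iterative inference loop.

Starting from the preprocessed gene-level matrix, a sequence of iteration
plans is executed: the baseline network is inferred without priors, then
each subsequent iteration merges the cumulative FISH-derived prior set,
re-infers the network at the requested sparsity, and records structure
descriptors, Louvain clustering and comparisons against the previous
iteration and the baseline.
"""

from __future__ import annotations

import json
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .clustering import (
    Clustering,
    clustering_significance,
    compare_clusterings,
    louvain_cluster,
    nmi,
)
from .ggm import PenaltySpec, infer_network, select_lambda
from .netstats import density, edge_overlap, key_gene_deltas, node_stats
from .priors import PriorEdgeSet


@dataclass(frozen=True)
class IterationPlan:
    """One inference iteration: name, priors introduced, sparsity, seed.

    Priors are *incremental*: the effective prior set of iteration i is the
    merge of all priors up to and including i.  Exactly one of
    ``target_density`` (density-targeted λ selection, the default mode) or
    ``lam`` (fixed penalty) must be given.
    """

    name: str
    priors: PriorEdgeSet = field(default_factory=PriorEdgeSet.empty)
    target_density: float | None = 3.5
    lam: float | None = None
    rho: float = 0.5
    enforce_must: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.target_density is None) == (self.lam is None):
            raise ValueError(
                f"iteration {self.name!r}: give exactly one of "
                "target_density or lam"
            )


@dataclass(frozen=True)
class IterationResult:
    """Outputs of one iteration of the loop."""

    name: str
    network: nx.Graph
    lam: float
    density: float
    stats: pd.DataFrame
    clustering: Clustering
    priors: PriorEdgeSet
    significance_p: float | None = None
    nmi_vs_previous: float | None = None
    nmi_vs_baseline: float | None = None
    edge_overlap_vs_previous: float | None = None
    edge_overlap_vs_baseline: float | None = None
    deltas_vs_baseline: pd.DataFrame | None = None


def run_plan(
    expression: pd.DataFrame,
    plans: Sequence[IterationPlan],
    *,
    significance_permutations: int = 0,
) -> tuple[list[IterationResult], dict]:
    """Run the iterative inference loop on a gene-level expression matrix.

    The first plan must carry no priors (the baseline network).  Prior sets
    accumulate across iterations; a pair flipping between must and forbidden
    raises.  Set ``significance_permutations`` > 0 to run the
    degree-preserving permutation test on each iteration's clustering.
    Returns the per-iteration results and a reproducibility manifest.
    """
    if not plans:
        raise ValueError("at least one iteration plan is required")
    if len(plans[0].priors) != 0:
        raise ValueError(
            f"the first iteration ({plans[0].name!r}) is the baseline and "
            "must have an empty prior set"
        )
    names = [p.name for p in plans]
    if len(set(names)) != len(names):
        raise ValueError(f"iteration names must be unique, got {names}")

    results: list[IterationResult] = []
    cumulative = PriorEdgeSet.empty()
    baseline: IterationResult | None = None
    previous: IterationResult | None = None
    for plan in plans:
        cumulative = cumulative.merge(plan.priors)
        if plan.lam is not None:
            lam = plan.lam
        else:
            lam = select_lambda(
                expression,
                cumulative,
                plan.target_density,
                rho=plan.rho,
                enforce_must=plan.enforce_must,
            )
        network = infer_network(
            expression,
            cumulative,
            PenaltySpec(lam=lam, rho=plan.rho, enforce_must=plan.enforce_must),
        )
        clustering = louvain_cluster(network, seed=plan.seed)
        sig_p = None
        if significance_permutations > 0:
            sig_p = clustering_significance(
                network,
                b=significance_permutations,
                seed=plan.seed,
                observed=clustering,
            ).p_value
        kwargs: dict = {}
        if previous is not None:
            kwargs["nmi_vs_previous"] = nmi(previous.clustering, clustering)
            kwargs["edge_overlap_vs_previous"] = (
                edge_overlap(previous.network, network)
                if previous.network.number_of_edges()
                else None
            )
        if baseline is not None:
            kwargs["nmi_vs_baseline"] = nmi(baseline.clustering, clustering)
            kwargs["edge_overlap_vs_baseline"] = (
                edge_overlap(baseline.network, network)
                if baseline.network.number_of_edges()
                else None
            )
            kwargs["deltas_vs_baseline"] = key_gene_deltas(baseline.network, network)
        result = IterationResult(
            name=plan.name,
            network=network,
            lam=lam,
            density=density(network),
            stats=node_stats(network),
            clustering=clustering,
            priors=cumulative,
            significance_p=sig_p,
            **kwargs,
        )
        results.append(result)
        if baseline is None:
            baseline = result
        previous = result

    from . import __version__

    manifest = {
        "colocnet_version": __version__,
        "numpy_version": np.__version__,
        "networkx_version": nx.__version__,
        "python_version": sys.version.split()[0],
        "n_genes": int(expression.shape[0]),
        "n_samples": int(expression.shape[1]),
        "iterations": [
            {
                "name": p.name,
                "seed": p.seed,
                "target_density": p.target_density,
                "lam_fixed": p.lam,
                "lam_used": r.lam,
                "rho": p.rho,
                "enforce_must": p.enforce_must,
                "n_must_priors": len(r.priors.must),
                "n_forbidden_priors": len(r.priors.forbidden),
                "n_edges": r.network.number_of_edges(),
                "density_pct": r.density,
                "modularity": r.clustering.modularity,
                "n_clusters": r.clustering.n_clusters,
                "significance_p": r.significance_p,
            }
            for p, r in zip(plans, results)
        ],
    }
    return results, manifest


def write_results(
    results: list[IterationResult], manifest: dict, outdir: str | Path
) -> None:
    """Write per-iteration networks, stats, clusterings and the manifest."""
    from . import io

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for r in results:
        io.write_network_tsv(r.network, outdir / f"{r.name}.edges.tsv")
        io.write_network_graphml(r.network, outdir / f"{r.name}.graphml")
        r.stats.to_csv(outdir / f"{r.name}.stats.tsv", sep="\t")
        io.write_clustering_tsv(
            r.clustering.assignment, outdir / f"{r.name}.clusters.tsv"
        )
        if r.deltas_vs_baseline is not None:
            r.deltas_vs_baseline.to_csv(
                outdir / f"{r.name}.deltas_vs_baseline.tsv", sep="\t"
            )
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)


def plans_from_config(config: dict, base_dir: str | Path = ".") -> list[IterationPlan]:
    """Build iteration plans from a parsed study configuration.

    Expected schema (YAML/JSON)::

        iterations:
          - name: network0
            seed: 42
            target_density: 3.5      # or: lam: 0.4
            rho: 0.0
            priors: priors1.tsv      # optional, incremental for this iteration

    Prior paths are resolved relative to ``base_dir``.
    """
    base_dir = Path(base_dir)
    plans = []
    for item in config.get("iterations", []):
        priors = PriorEdgeSet.empty()
        if item.get("priors"):
            priors = PriorEdgeSet.from_tsv(base_dir / item["priors"])
        plans.append(
            IterationPlan(
                name=item["name"],
                priors=priors,
                target_density=item.get(
                    "target_density", None if "lam" in item else 3.5
                ),
                lam=item.get("lam"),
                rho=float(item.get("rho", 0.5)),
                enforce_must=bool(item.get("enforce_must", True)),
                seed=int(item.get("seed", 0)),
            )
        )
    return plans
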