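"""Stabilization and fusion of causal graphs around the hypertension node.

A single random data split can make the learned graph unrepresentative, so
per statistical metric the search is repeated on ten subject-level
subsamples; each resulting CPDAG is pruned to the edges directly incident
to the hypertension node, and edges surviving a strict majority of the
iterations form that metric's consensus subgraph.  The six per-metric
consensus subgraphs are then fused: the union of target-adjacent features
across metrics is the causal feature list, and features sharing a base
index (the same waveform feature observed under different metrics) collapse
to one node of the final causal graph.

"Direct causal association" is operationalized as CPDAG adjacency to the
target, directed either way or undirected: orientation adjacent to a
discrete sink is weakly identifiable, and both arc directions are
scientifically meaningful (disease altering the waveform vs. risk markers).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .aggregate import split_summary_column
from .ges import MixedDataset, ScoreModel, ges_search
from .graphs import Cpdag

__all__ = [
    "SubgraphEnsemble",
    "FinalCausalGraph",
    "subsample_iterations",
    "prune_to_target",
    "majority_merge",
    "fuse_across_metrics",
]

log = logging.getLogger(__name__)


def subsample_iterations(
    df: pd.DataFrame,
    target: str,
    model: ScoreModel,
    runs: int = 10,
    frac: float = 0.8,
    seed: int = 0,
    max_subset: int | None = 2,
) -> list[Cpdag]:
    """One GES run per subject-level subsample.

    Each iteration draws ``frac`` of the rows without replacement (fresh
    seed per run, recorded in the graph's provenance) and re-runs the
    search.  A subsample that loses one of the label classes is redrawn
    with a logged retry.  ``frac=1.0`` makes all runs identical.
    """
    if not 0 < frac <= 1:
        raise ValueError("frac must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    n = len(df)
    k = max(2, int(round(frac * n)))
    graphs: list[Cpdag] = []
    for it in range(runs):
        for attempt in range(20):
            draw_seed = int(rng.integers(0, 2**31 - 1))
            sub = df.sample(n=k, replace=False, random_state=draw_seed)
            if sub[target].nunique() == 2:
                break
            log.warning("iteration %d: subsample lost a class, redrawing", it)
        else:
            raise RuntimeError("could not draw a subsample containing both classes")
        data = MixedDataset.from_dataframe(sub, target=target)
        g = ges_search(data, model, seed=draw_seed, max_subset=max_subset)
        g.provenance.update({"iteration": it, "subsample_seed": draw_seed, "frac": frac})
        graphs.append(g)
    return graphs


def prune_to_target(cpdag: Cpdag, target: str) -> Cpdag:
    """Keep exactly the edges incident to ``target`` and their endpoints."""
    if target not in cpdag.nodes:
        raise ValueError(f"target {target!r} is not a node of the graph")
    out = Cpdag([target], provenance=dict(cpdag.provenance))
    for x, y in cpdag.directed_edges:
        if target in (x, y):
            out.add_node(x)
            out.add_node(y)
            out.add_directed(x, y)
    for x, y in cpdag.undirected_edges:
        if target in (x, y):
            out.add_node(x)
            out.add_node(y)
            out.add_undirected(x, y)
    return out


@dataclass
class SubgraphEnsemble:
    """Per-metric iteration graphs plus their majority-rule consensus."""

    metric: str
    target: str
    graphs: list[Cpdag]
    edge_counts: pd.DataFrame = field(default_factory=pd.DataFrame)
    consensus: Cpdag | None = None


def majority_merge(
    pruned: list[Cpdag],
    target: str,
    threshold: float = 0.5,
    metric: str = "",
) -> SubgraphEnsemble:
    """Majority-rule consensus of target-incident edges across iterations.

    An adjacency to the target is kept iff it occurs in strictly more than
    ``threshold`` of the iterations (default: strict majority, so 5/10 is
    dropped and 6/10 kept).  Its direction is the majority among directed
    occurrences; ties - or a majority of undirected occurrences - yield an
    undirected consensus edge.
    """
    if not pruned:
        raise ValueError("need at least one graph")
    runs = len(pruned)
    counts: dict[str, dict[str, int]] = {}
    for g in pruned:
        if target not in g.nodes:
            continue
        for x, y in g.directed_edges:
            other = y if x == target else x
            kind = "outgoing" if x == target else "incoming"
            rec = counts.setdefault(other, {"incoming": 0, "outgoing": 0, "undirected": 0})
            rec[kind] += 1
        for x, y in g.undirected_edges:
            if target in (x, y):
                other = y if x == target else x
                rec = counts.setdefault(other, {"incoming": 0, "outgoing": 0, "undirected": 0})
                rec["undirected"] += 1
    consensus = Cpdag([target])
    rows = []
    for other, rec in sorted(counts.items(), key=lambda kv: str(kv[0])):
        total = rec["incoming"] + rec["outgoing"] + rec["undirected"]
        keep = total > threshold * runs
        rows.append(
            {
                "feature": other,
                "incoming": rec["incoming"],
                "outgoing": rec["outgoing"],
                "undirected": rec["undirected"],
                "total": total,
                "kept": keep,
            }
        )
        if not keep:
            continue
        consensus.add_node(other)
        if rec["incoming"] > rec["outgoing"]:
            consensus.add_directed(other, target)
        elif rec["outgoing"] > rec["incoming"]:
            consensus.add_directed(target, other)
        else:
            consensus.add_undirected(other, target)
    consensus.provenance = {"metric": metric, "runs": runs, "threshold": threshold}
    return SubgraphEnsemble(
        metric=metric,
        target=target,
        graphs=pruned,
        edge_counts=pd.DataFrame(
            rows, columns=["feature", "incoming", "outgoing", "undirected", "total", "kept"]
        ),
        consensus=consensus,
    )


@dataclass
class FinalCausalGraph:
    """Cross-metric consensus graph with collapsed feature-index nodes.

    ``causal_features`` is the metric-qualified list (one entry per metric
    under which the feature is target-adjacent); ``collapsed_nodes`` the
    distinct base features, which are the nodes of the final graph besides
    the target.
    """

    target: str
    causal_features: list[tuple[str, str]]  # (metric, base feature)
    collapsed_nodes: list[str]
    edges: pd.DataFrame  # base feature, metric, direction

    @property
    def nodes(self) -> list[str]:
        return [*self.collapsed_nodes, self.target]

    def features_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"metric": m, "feature": f, "qualified": f"{m}__{f}"}
                for m, f in self.causal_features
            ]
        )


def _base_feature(node: str) -> str:
    """Strip a metric qualifier if present: ``sd__f052`` -> ``f052``."""
    if "__" in node:
        return split_summary_column(node)[1]
    return node


def fuse_across_metrics(
    ensembles: dict[str, SubgraphEnsemble] | dict[str, Cpdag],
    target: str,
) -> FinalCausalGraph:
    """Union the per-metric consensus subgraphs into the final causal graph.

    Features adjacent to the target under any metric enter the causal
    feature list with their metric of origin; features sharing a base index
    collapse to a single node carrying per-metric edge provenance.  The
    result is invariant to the order of the metrics.
    """
    causal: list[tuple[str, str]] = []
    edge_rows = []
    for metric in sorted(ensembles):
        ens = ensembles[metric]
        g = ens.consensus if isinstance(ens, SubgraphEnsemble) else ens
        if g is None or target not in g.nodes:
            continue
        for rec in g.edge_records():
            x, y = rec["source"], rec["target"]
            if target not in (x, y):
                continue
            other = y if x == target else x
            base = _base_feature(other)
            causal.append((metric, base))
            if rec["kind"] == "undirected":
                direction = "undirected"
            else:
                direction = "to_target" if y == target else "from_target"
            edge_rows.append({"feature": base, "metric": metric, "direction": direction})
    causal = sorted(set(causal))
    collapsed = sorted({f for _, f in causal})
    return FinalCausalGraph(
        target=target,
        causal_features=causal,
        collapsed_nodes=collapsed,
        edges=pd.DataFrame(edge_rows, columns=["feature", "metric", "direction"]).sort_values(
            ["feature", "metric"], kind="mergesort", ignore_index=True
        ),
    )
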