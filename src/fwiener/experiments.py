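"""End-to-end clustering experiments on synthetic network collections.

Three experiment families compare hierarchical clustering of a graph
collection using raw index vectors against normalized ones:

* ``exp1.1`` .. ``exp1.5`` -- random networks: 10 each from the ER,
  preferential-attachment (SF) and 3-D geometric (GE) models, node counts on
  a grid; sub-experiment x uses SF edges-per-step m = x.  Truth = model.
* ``exp2`` -- deterministic trees: 10 paths, 10 stars, 10 brooms
  (pendant-leaf count n // 2), 10 path-like caterpillars (2 leaves per spine
  node) and 10 star-like caterpillars (50 leaves per spine node).
  Truth = family.
* ``exp3`` -- the union of both kinds; every vector is normalized on the
  graphs domain so the mixed collection shares one scale.

Each run computes both characteristic vectors for every graph, Ward-clusters
each, cuts at the true family count, and scores both cuts with the ARI.
The default node grid is 500, 550, ..., 950.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .clustering import adjusted_rand_index, characteristic_vector, cut_k, ward_linkage
from .functions import IndexFunction, builtin_catalog
from .graphs import make_special
from .random_models import ModelConfig, child_seed, generate

__all__ = [
    "ExperimentSpec",
    "ExperimentResult",
    "DEFAULT_N_GRID",
    "build_tree_collection",
    "build_network_collection",
    "run_experiment",
    "random_clustering_baseline",
    "summarize",
]

DEFAULT_N_GRID = tuple(range(500, 951, 50))

EXPERIMENT_NAMES = tuple(f"exp1.{i}" for i in range(1, 6)) + ("exp2", "exp3")

TREE_FAMILIES = ("path", "star", "broom", "caterpillar_pathlike", "caterpillar_starlike")
NETWORK_MODELS = ("er", "sf", "ge")


@dataclass(frozen=True)
class ExperimentSpec:
    """Configuration of one experiment.

    ``sf_m`` defaults to the sub-experiment number for exp1.x; ``er_p`` and
    ``ge_q`` default to 0.05.
    """

    name: str
    n_grid: tuple[int, ...] = DEFAULT_N_GRID
    replicates: int = 1
    base_seed: int = 0
    er_p: float = 0.05
    sf_m: int | None = None
    ge_q: float = 0.05

    def __post_init__(self) -> None:
        if self.name not in EXPERIMENT_NAMES:
            raise ValueError(f"unknown experiment {self.name!r}")
        if not self.n_grid or min(self.n_grid) < 4:
            raise ValueError("n_grid must be non-empty with all n >= 4")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    @property
    def effective_sf_m(self) -> int:
        if self.sf_m is not None:
            return self.sf_m
        if self.name.startswith("exp1."):
            return int(self.name.split(".")[1])
        return 2


@dataclass(frozen=True)
class ExperimentResult:
    spec: ExperimentSpec
    ari_raw: float
    ari_normalized: float
    ari_raw_reps: tuple[float, ...]
    ari_normalized_reps: tuple[float, ...]
    truth: tuple[int, ...]
    labels_raw: tuple[int, ...]
    labels_normalized: tuple[int, ...]

    @property
    def sd_raw(self) -> float:
        return float(np.std(self.ari_raw_reps, ddof=1)) if len(self.ari_raw_reps) > 1 else 0.0

    @property
    def sd_normalized(self) -> float:
        reps = self.ari_normalized_reps
        return float(np.std(reps, ddof=1)) if len(reps) > 1 else 0.0


def build_tree_collection(
    n_grid: tuple[int, ...] = DEFAULT_N_GRID,
) -> tuple[list[nx.Graph], np.ndarray]:
    """Five tree families per grid size, with family-index truth labels.

    Brooms carry n // 2 pendant leaves; path-like caterpillars carry 2
    leaves per spine node and star-like ones 50.
    """
    if min(n_grid) < 10:
        raise ValueError("tree collection requires every n >= 10")
    graphs: list[nx.Graph] = []
    truth: list[int] = []
    builders = (
        lambda n: make_special("path", n),
        lambda n: make_special("star", n),
        lambda n: make_special("broom", n, n // 2),
        lambda n: make_special("caterpillar", n, 2),
        lambda n: make_special("caterpillar", n, 50),
    )
    for fam_idx, build in enumerate(builders):
        for n in n_grid:
            graphs.append(build(n))
            truth.append(fam_idx)
    return graphs, np.array(truth)


def build_network_collection(
    spec: ExperimentSpec, replicate: int = 0
) -> tuple[list[nx.Graph], np.ndarray]:
    """10 networks per random model over the node grid, truth = model index."""
    graphs: list[nx.Graph] = []
    truth: list[int] = []
    for model_idx, model in enumerate(NETWORK_MODELS):
        for n_idx, n in enumerate(spec.n_grid):
            seed = child_seed(spec.base_seed, replicate, model_idx, n_idx)
            if model == "er":
                cfg = ModelConfig("er", n, p=spec.er_p, seed=seed)
            elif model == "sf":
                cfg = ModelConfig("sf", n, m=spec.effective_sf_m, seed=seed)
            else:
                cfg = ModelConfig("ge", n, q=spec.ge_q, seed=seed)
            graphs.append(generate(cfg))
            truth.append(model_idx)
    return graphs, np.array(truth)


def _cluster_and_score(
    graphs: list[nx.Graph],
    truth: np.ndarray,
    catalog: list[IndexFunction],
    domain: str,
) -> tuple[float, float, np.ndarray, np.ndarray]:
    k = len(np.unique(truth))
    raw = [characteristic_vector(g, catalog, normalized=False, domain=domain) for g in graphs]
    norm = [characteristic_vector(g, catalog, normalized=True, domain=domain) for g in graphs]
    labels_raw = cut_k(ward_linkage(raw), k)
    labels_norm = cut_k(ward_linkage(norm), k)
    return (
        adjusted_rand_index(truth, labels_raw),
        adjusted_rand_index(truth, labels_norm),
        labels_raw,
        labels_norm,
    )


def run_experiment(spec: ExperimentSpec, catalog: list[IndexFunction] | None = None) -> ExperimentResult:
    """Run one experiment, replicated; reports mean ARI for raw and
    normalized vectors (exp2 is deterministic, so one pass suffices)."""
    catalog = catalog if catalog is not None else builtin_catalog()
    raws: list[float] = []
    norms: list[float] = []
    last: tuple = ()
    n_reps = 1 if spec.name == "exp2" else spec.replicates
    for rep in range(n_reps):
        if spec.name == "exp2":
            graphs, truth = build_tree_collection(spec.n_grid)
            domain = "trees"
        elif spec.name == "exp3":
            net_graphs, net_truth = build_network_collection(spec, rep)
            tree_graphs, tree_truth = build_tree_collection(spec.n_grid)
            graphs = net_graphs + tree_graphs
            truth = np.concatenate([net_truth, tree_truth + len(NETWORK_MODELS)])
            domain = "graphs"
        else:
            graphs, truth = build_network_collection(spec, rep)
            domain = "graphs"
        ari_raw, ari_norm, lr, ln = _cluster_and_score(graphs, truth, catalog, domain)
        raws.append(ari_raw)
        norms.append(ari_norm)
        last = (truth, lr, ln)
    truth, lr, ln = last
    return ExperimentResult(
        spec=spec,
        ari_raw=float(np.mean(raws)),
        ari_normalized=float(np.mean(norms)),
        ari_raw_reps=tuple(raws),
        ari_normalized_reps=tuple(norms),
        truth=tuple(int(t) for t in truth),
        labels_raw=tuple(int(t) for t in lr),
        labels_normalized=tuple(int(t) for t in ln),
    )


def random_clustering_baseline(
    truth: np.ndarray | list[int],
    n_classes: int,
    replicates: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Mean and sd of the ARI between a fixed partition and uniform random
    assignments of the items to ``n_classes`` clusters."""
    truth = np.asarray(truth)
    rng = np.random.default_rng(seed)
    aris = np.empty(replicates)
    for i in range(replicates):
        aris[i] = adjusted_rand_index(truth, rng.integers(0, n_classes, truth.size))
    return float(aris.mean()), float(aris.std(ddof=1))


def summarize(results: list[ExperimentResult]) -> pd.DataFrame:
    """Table of mean ARI (sd in parentheses) per experiment, raw vs
    normalized."""
    if not results:
        raise ValueError("no results to summarize")

    def fmt(mean: float, sd: float, reps: int) -> str:
        return f"{mean:.2f} ({sd:.2f})" if reps > 1 else f"{mean:.2f}"

    rows = []
    for r in results:
        reps = len(r.ari_raw_reps)
        rows.append(
            {
                "experiment": r.spec.name,
                "non_normalized": fmt(r.ari_raw, r.sd_raw, reps),
                "normalized": fmt(r.ari_normalized, r.sd_normalized, reps),
            }
        )
    return pd.DataFrame(rows)
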