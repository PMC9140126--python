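"""Per-condition co-expression networks: ensemble importances, edge
selection, communities, hubs, enrichment, cross-condition matching.

Edge weights come from a tree-ensemble regression of each target gene on
all other genes (random-forest impurity importances, normalized per
target) -- the standard ensemble recipe for expression networks.  The
direction of co-expression is taken from the Spearman correlation, and
only positively correlated pairs become edges.  Edge counts are either
fixed (top-k) or chosen by binary search so the network's node count
lands closest to a target -- the "keep gene size near half the number
of selected genes" sizing recipe, which for a 3108-gene input targets
1554 nodes.

Communities come from seeded Louvain modularity optimization and hubs
from exact (Brandes) betweenness centrality on the unweighted selected
graph, flagged at mean + 2 SD.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from statsmodels.stats.multitest import multipletests

from .dataio import DataError, ExpressionMatrix, GeneSetCollection

logger = logging.getLogger(__name__)

MIN_SAMPLES = 10
HUB_SD_MULTIPLIER = 2.0
MATCH_JACCARD_THRESHOLD = 0.2


def pair_weight_count(n_genes: int) -> int:
    """Number of per-condition ordered gene-pair weights enumerated for
    ``n_genes`` selected genes (every gene regressed on every gene)."""
    return n_genes * n_genes


def default_node_target(n_selected_genes: int) -> int:
    """Default node-count target for edge selection: half the selected
    gene set, the sizing that avoids network saturation."""
    return round(n_selected_genes / 2)


@dataclass
class WeightMatrix:
    """Directed importance weights and the paired Spearman rho matrix."""

    weights: pd.DataFrame  # rows = regulators, columns = targets
    rho: pd.DataFrame

    def __post_init__(self) -> None:
        w = self.weights.to_numpy()
        if (w < 0).any():
            raise DataError("negative importance weight")
        if np.abs(np.diag(w)).max() > 0:
            raise DataError("nonzero diagonal importance")


@dataclass
class StageNetwork:
    """One condition's co-expression graph with partition and centrality."""

    condition: str
    graph: nx.Graph
    partition: dict[str, int] | None = None
    modularity: float | None = None
    betweenness: pd.Series | None = None
    hubs: list[str] = field(default_factory=list)


def ensemble_importance(
    matrix: ExpressionMatrix,
    genes: list[str] | None = None,
    n_trees: int = 500,
    seed: int = 0,
) -> WeightMatrix:
    """Random-forest importance weights w(regulator -> target).

    For each target, a seeded random forest (``sqrt(p)`` candidate
    features per split) regresses the target on all remaining genes;
    the impurity importances are normalized to sum to 1 per target.
    Spearman correlations are computed for all pairs alongside.
    Requires at least 10 samples (forests are unstable below).
    """
    if genes is None:
        genes = matrix.genes
    sub = matrix.subset_genes(list(genes))
    n_samples = sub.shape[1]
    if n_samples < MIN_SAMPLES:
        raise DataError(f"need >= {MIN_SAMPLES} samples, got {n_samples}")
    X = sub.data.to_numpy().T  # samples x genes
    p = X.shape[1]
    weights = np.zeros((p, p))
    for i in range(p):
        predictors = np.delete(np.arange(p), i)
        rf = RandomForestRegressor(
            n_estimators=n_trees,
            max_features="sqrt",
            random_state=seed + i,
            n_jobs=1,
        )
        rf.fit(X[:, predictors], X[:, i])
        imp = rf.feature_importances_
        total = imp.sum()
        if total > 0:
            imp = imp / total
        weights[predictors, i] = imp
    rho = stats.spearmanr(X).statistic
    rho = np.atleast_2d(rho)
    return WeightMatrix(
        weights=pd.DataFrame(weights, index=list(genes), columns=list(genes)),
        rho=pd.DataFrame(rho, index=list(genes), columns=list(genes)),
    )


def _candidate_pairs(wm: WeightMatrix) -> pd.DataFrame:
    genes = list(wm.weights.index)
    w = wm.weights.to_numpy()
    sym = np.maximum(w, w.T)
    rho = wm.rho.to_numpy()
    iu = np.triu_indices(len(genes), k=1)
    df = pd.DataFrame(
        {
            "gene_a": np.asarray(genes, dtype=object)[iu[0]],
            "gene_b": np.asarray(genes, dtype=object)[iu[1]],
            "weight": sym[iu],
            "spearman_rho": rho[iu],
        }
    )
    df = df[df["spearman_rho"] > 0]
    return df.sort_values(
        ["weight", "gene_a", "gene_b"], ascending=[False, True, True]
    ).reset_index(drop=True)


def select_edges(
    weights: WeightMatrix,
    mode: str = "top_k",
    k_or_target: int = 5600,
) -> pd.DataFrame:
    """Undirected edge list from a weight matrix.

    Directed importances are symmetrized by the pairwise maximum; pairs
    with Spearman rho <= 0 are discarded.  ``top_k`` keeps the k largest
    pair weights; ``target_nodes`` binary-searches k so the node count
    of the resulting graph is closest to the target (ties resolved
    toward the smaller k).  Asking for more pairs than exist keeps all,
    with a warning.
    """
    pairs = _candidate_pairs(weights)
    if mode == "top_k":
        k = k_or_target
        if k > len(pairs):
            logger.warning(
                "top_k=%d exceeds %d positive-rho pairs; keeping all", k, len(pairs)
            )
            k = len(pairs)
        return pairs.head(k).reset_index(drop=True)
    if mode != "target_nodes":
        raise ValueError(f"unknown mode {mode!r}")

    def node_count(k: int) -> int:
        if k == 0:
            return 0
        top = pairs.head(k)
        return len(set(top["gene_a"]) | set(top["gene_b"]))

    lo, hi = 0, len(pairs)
    target = k_or_target
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if node_count(mid) < target:
            lo = mid
        else:
            hi = mid
    best_k = min(
        (lo, hi),
        key=lambda k: (abs(node_count(k) - target), k),
    )
    return pairs.head(best_k).reset_index(drop=True)


def build_graph(edges: pd.DataFrame, condition: str = "") -> StageNetwork:
    graph = nx.Graph()
    for row in edges.itertuples(index=False):
        graph.add_edge(
            row.gene_a,
            row.gene_b,
            weight=float(row.weight),
            spearman_rho=float(row.spearman_rho),
        )
    return StageNetwork(condition=condition, graph=graph)


def louvain(
    graph: nx.Graph, resolution: float = 1.0, seed: int = 0
) -> tuple[dict[str, int], float]:
    """Seeded Louvain partition and its weighted modularity Q."""
    if graph.number_of_edges() == 0:
        raise DataError("cannot cluster an empty graph")
    communities = nx.community.louvain_communities(
        graph, weight="weight", resolution=resolution, seed=seed
    )
    communities = sorted(communities, key=lambda c: (-len(c), sorted(c)[0]))
    partition = {node: i for i, comm in enumerate(communities) for node in comm}
    q = nx.community.modularity(
        graph, communities, weight="weight", resolution=resolution
    )
    return partition, float(q)


def betweenness_hubs(
    network: StageNetwork,
    sd_multiplier: float = HUB_SD_MULTIPLIER,
    top_per_community: int = 5,
) -> pd.DataFrame:
    """Exact betweenness centrality, hub flags, per-community top list.

    Betweenness is computed unnormalized on the unweighted selected
    graph.  A node is flagged as a hub when its betweenness exceeds the
    graph-wide mean + ``sd_multiplier`` x SD; the top
    ``top_per_community`` nodes per community are flagged alongside so
    both readings of "hub" are available.
    """
    graph = network.graph
    b = nx.betweenness_centrality(graph, normalized=False, weight=None)
    bs = pd.Series(b, name="betweenness").sort_values(ascending=False)
    threshold = bs.mean() + sd_multiplier * bs.std(ddof=1)
    out = bs.to_frame()
    out["hub"] = out["betweenness"] > threshold
    if network.partition is not None:
        out["community"] = pd.Series(network.partition)
        out["community_top"] = False
        for _, idx in out.groupby("community").groups.items():
            top = out.loc[idx, "betweenness"].nlargest(top_per_community).index
            out.loc[top, "community_top"] = True
    network.betweenness = out["betweenness"]
    network.hubs = list(out.index[out["hub"]])
    return out


def community_enrichment(
    community: list[str],
    sets: GeneSetCollection,
    universe: list[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation of each set in a community.

    One-sided p = P(overlap >= observed) under sampling
    ``len(community)`` genes from the universe; Benjamini-Hochberg q
    across sets.  The community must be contained in the universe.
    """
    universe_set = set(universe)
    if not universe_set:
        raise DataError("empty universe")
    comm = set(community)
    if not comm <= universe_set:
        raise DataError("community not contained in universe")
    rows = []
    for name, members in sets.sets.items():
        in_universe = set(members) & universe_set
        overlap = len(comm & in_universe)
        p = float(
            stats.hypergeom.sf(
                overlap - 1, len(universe_set), len(in_universe), len(comm)
            )
        )
        rows.append(
            {
                "set": name,
                "set_size": len(in_universe),
                "overlap": overlap,
                "p": min(p, 1.0),
            }
        )
    table = pd.DataFrame(rows)
    table["q"] = multipletests(table["p"], method="fdr_bh")[1]
    return table.sort_values("p", kind="stable").reset_index(drop=True)


def match_communities(
    networks: list[StageNetwork],
    top_n: int = 5,
    threshold: float = MATCH_JACCARD_THRESHOLD,
) -> pd.DataFrame:
    """Match the largest communities across condition networks.

    For each network's ``top_n`` communities by gene count, pairwise
    Jaccard similarities to the first network's top communities are
    computed and matched greedily above ``threshold``.  The returned
    table reports, per matched community of the reference condition,
    which conditions carry a match and how many genes are shared across
    all matched conditions.
    """
    if len(networks) < 2:
        raise DataError("need at least two networks to match")
    for net in networks:
        if net.partition is None:
            raise DataError(f"network {net.condition!r} lacks a partition")

    def top_communities(net: StageNetwork) -> list[set[str]]:
        groups: dict[int, set[str]] = {}
        for node, comm in net.partition.items():
            groups.setdefault(comm, set()).add(node)
        return sorted(groups.values(), key=len, reverse=True)[:top_n]

    ref, *others = networks
    ref_comms = top_communities(ref)
    rows = []
    for i, rc in enumerate(ref_comms):
        shared = set(rc)
        matched_conditions = [ref.condition]
        for net in others:
            candidates = top_communities(net)
            jaccards = [
                len(rc & c) / len(rc | c) if rc | c else 0.0 for c in candidates
            ]
            best = int(np.argmax(jaccards)) if jaccards else -1
            if best >= 0 and jaccards[best] > threshold:
                matched_conditions.append(net.condition)
                shared &= candidates[best]
        rows.append(
            {
                "ref_community": i,
                "ref_size": len(rc),
                "n_conditions_matched": len(matched_conditions),
                "conditions": ",".join(matched_conditions),
                "n_shared_genes": len(shared) if len(matched_conditions) == len(networks) else len(shared),
                "matched_all": len(matched_conditions) == len(networks),
            }
        )
    return pd.DataFrame(rows)
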