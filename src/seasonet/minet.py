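"""Mutual-information co-expression network inference.

Implements the ARACNe-style workflow used to probe seasonal
immunoregulation: an adaptive-partitioning MI estimator on rank-transformed
log2 expression, a null-calibrated MI threshold (exponential tail fit with
optional correction for the number of markers), hub-restricted network
construction with data-processing-inequality (DPI) pruning, bootstrap
consensus over sample resamples, topology statistics, hub-module
extraction and module-overlap meta-networks, interface ("key") gene
scoring, and the immune / non-immune edge-partition summary.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from ._mi import mi_from_scaled_ranks, mi_pairs
from .enrich import overlap_test
from .study import ExpressionStudy

log = logging.getLogger(__name__)

__all__ = [
    "MIParams",
    "estimate_mi",
    "MIThreshold",
    "calibrate_mi_threshold",
    "build_network",
    "bootstrap_consensus",
    "node_topology",
    "extract_modules",
    "module_overlap_graph",
    "interface_scores",
    "edge_partition_stats",
    "write_sif",
]


@dataclass(frozen=True)
class MIParams:
    """Knobs of the adaptive-partitioning estimator.

    ``alpha_split`` is the significance level of the chi-square uniformity
    test that decides whether a cell is quadrisected further; ``min_split``
    the smallest cell (points) eligible for splitting; ``max_depth`` caps
    the partition at a 2^max_depth marginal resolution.
    """

    alpha_split: float = 0.05
    min_split: int = 8
    max_depth: int = 4

    @property
    def chi2_crit(self) -> float:
        # median splits fix both cell margins, leaving the four quadrant
        # counts a single free degree of freedom
        return float(stats.chi2.isf(self.alpha_split, 1))


def _scaled_ranks(x: np.ndarray) -> np.ndarray:
    # 2x average ranks keeps tied ranks integral
    return (2.0 * stats.rankdata(x, method="average", axis=-1)).astype(np.int64)


def estimate_mi(x, y, params: MIParams = MIParams()) -> float:
    """Adaptive-partitioning MI estimate (nats) between two vectors.

    Symmetric in its arguments; returns 0 for a constant input vector.
    """
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    if x.size != y.size:
        raise ValueError("vectors must have equal length")
    if x.size < 8:
        raise ValueError("need at least 8 observations")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        return 0.0
    rx = _scaled_ranks(x)
    ry = _scaled_ranks(y)
    return float(
        mi_from_scaled_ranks(
            rx.copy(), ry.copy(), np.sort(rx), np.sort(ry),
            params.chi2_crit, params.min_split, params.max_depth,
        )
    )


def _as_log2_matrix(data, pseudocount: float = 1.0) -> tuple[np.ndarray, pd.Index]:
    if isinstance(data, ExpressionStudy):
        L = data.log2(pseudocount)
        return L.to_numpy(), L.index
    df = pd.DataFrame(data)
    return df.to_numpy(float), df.index


@dataclass
class MIThreshold:
    threshold: float
    p_cut: float
    p_effective: float
    slope: float        # a in P(MI > t) = exp(-(a t + b))
    intercept: float    # b
    n_null: int


def calibrate_mi_threshold(
    data,
    p_cut: float = 1e-5,
    marker_correction: bool = True,
    n_null_pairs: int = 3000,
    seed: int = 0,
    n_markers: int | None = None,
    correct_by: str = "pairs",
    params: MIParams = MIParams(),
    pseudocount: float = 1.0,
) -> MIThreshold:
    """Estimate the MI threshold for a target edge p value from a null run.

    Null MI values come from gene pairs whose sample orders are permuted
    independently (a fresh pair of permutations per draw, so the null
    sample size is not limited by the number of distinct gene pairs).  An
    exponential tail P(MI > t) = exp(-(a t + b)) is fitted to the upper
    decile and inverted at ``p_cut`` - divided, when ``marker_correction``
    is on, by the number of tested pairs (``correct_by="pairs"``, the
    default) or by the number of genes (``correct_by="genes"``).
    """
    if n_null_pairs < 1000:
        raise ValueError("need at least 1000 null pairs for the tail fit")
    X, genes = _as_log2_matrix(data, pseudocount)
    g, n = X.shape
    if g < 2:
        raise ValueError("need at least two genes")
    rng = np.random.default_rng(seed)
    R = _scaled_ranks(X)
    S = np.sort(R, axis=1)

    mis = np.empty(n_null_pairs)
    for k in range(n_null_pairs):
        i, j = rng.choice(g, size=2, replace=False)
        rx = R[i][rng.permutation(n)].copy()
        ry = R[j][rng.permutation(n)].copy()
        mis[k] = mi_from_scaled_ranks(
            rx, ry, S[i], S[j], params.chi2_crit, params.min_split,
            params.max_depth,
        )

    v = np.sort(mis)[::-1]
    k_tail = max(n_null_pairs // 10, 100)
    vv = v[:k_tail]
    surv = np.arange(1, k_tail + 1) / (n_null_pairs + 1.0)
    pos = vv > 0
    if pos.sum() < 10:
        raise RuntimeError(
            "null MI tail degenerate (too few positive values to fit)"
        )
    a, b = np.polyfit(vv[pos], -np.log(surv[pos]), 1)
    if a <= 0:
        raise RuntimeError("tail fit produced a non-positive slope")

    if marker_correction:
        if n_markers is None:
            n_markers = g * (g - 1) // 2 if correct_by == "pairs" else g
        p_eff = p_cut / n_markers
    else:
        p_eff = p_cut
    thr = max((-math.log(p_eff) - b) / a, 0.0)
    return MIThreshold(
        threshold=float(thr),
        p_cut=p_cut,
        p_effective=p_eff,
        slope=float(a),
        intercept=float(b),
        n_null=n_null_pairs,
    )


# ---------------------------------------------------------------------------
# network construction
# ---------------------------------------------------------------------------

def _hub_pairs(n_genes: int, hub_idx: np.ndarray) -> np.ndarray:
    """All unordered gene pairs with at least one hub member."""
    is_hub = np.zeros(n_genes, dtype=bool)
    is_hub[hub_idx] = True
    pairs = []
    for h in hub_idx:
        for j in range(n_genes):
            if j == h:
                continue
            if is_hub[j] and j < h:
                continue  # hub-hub pair handled once from the smaller index
            pairs.append((h, j) if h < j else (j, h))
    if not pairs:
        return np.empty((0, 2), dtype=np.int64)
    return np.unique(np.array(pairs, dtype=np.int64), axis=0)


def _dpi(edges: dict[tuple[int, int], float], tolerance: float) -> set[tuple[int, int]]:
    """Edges marked for removal by the data-processing inequality.

    For every fully connected triple, edge (i, j) is marked when
    MI(i, j) < min(MI(i, k), MI(j, k)) * (1 - tolerance).  Marks are
    collected over the full scan and applied afterwards, so the result
    does not depend on scan order.
    """
    adj: dict[int, dict[int, float]] = {}
    for (i, j), w in edges.items():
        adj.setdefault(i, {})[j] = w
        adj.setdefault(j, {})[i] = w
    to_remove: set[tuple[int, int]] = set()
    for (i, j), w in edges.items():
        ni, nj = adj[i], adj[j]
        small, other = (ni, nj) if len(ni) < len(nj) else (nj, ni)
        for k in small:
            if k == i or k == j or k not in other:
                continue
            if w < min(adj[i][k], adj[j][k]) * (1.0 - tolerance):
                to_remove.add((i, j))
                break
    return to_remove


def _edge_scan(
    R: np.ndarray,
    S: np.ndarray,
    pairs: np.ndarray,
    threshold: float,
    dpi_tolerance: float,
    params: MIParams,
) -> dict[tuple[int, int], float]:
    if len(pairs) == 0:
        return {}
    mi = mi_pairs(R, S, pairs, params.chi2_crit, params.min_split, params.max_depth)
    edges = {
        (int(i), int(j)): float(m)
        for (i, j), m in zip(pairs, mi)
        if m > threshold
    }
    if edges:
        for key in _dpi(edges, dpi_tolerance):
            del edges[key]
    return edges


def build_network(
    data,
    hubs,
    mi_threshold: float | MIThreshold,
    dpi_tolerance: float = 0.0,
    params: MIParams = MIParams(),
    pseudocount: float = 1.0,
    bias_labels: pd.Series | None = None,
) -> nx.Graph:
    """Single-pass MI network over hub-incident gene pairs.

    MI is computed on log2(FPKM + pseudocount) for every hub-gene and
    hub-hub pair; edges with MI above the threshold are kept and then DPI
    pruning removes the weakest edge of each fully connected triple (the
    scan only sees triangles wholly inside the computed edge set, as in
    hub-restricted inference).  Every gene of the input appears as a node;
    hubs carry ``hub=True`` and, when provided, nodes carry their
    seasonal-bias label.
    """
    hubs = list(hubs)
    if not hubs:
        raise ValueError("empty hub list")
    X, genes = _as_log2_matrix(data, pseudocount)
    gene_pos = {gname: i for i, gname in enumerate(genes)}
    missing = [h for h in hubs if h not in gene_pos]
    if missing:
        raise KeyError(f"hubs absent from data: {missing[:5]}")
    thr = (
        mi_threshold.threshold
        if isinstance(mi_threshold, MIThreshold)
        else float(mi_threshold)
    )
    R = _scaled_ranks(X)
    S = np.sort(R, axis=1)
    hub_idx = np.array(sorted(gene_pos[h] for h in hubs), dtype=np.int64)
    pairs = _hub_pairs(len(genes), hub_idx)
    edges = _edge_scan(R, S, pairs, thr, dpi_tolerance, params)

    G = nx.Graph(mi_threshold=thr, dpi_tolerance=dpi_tolerance)
    hub_set = set(hubs)
    for gname in genes:
        G.add_node(gname, hub=gname in hub_set)
    if bias_labels is not None:
        nx.set_node_attributes(G, bias_labels.to_dict(), "bias")
    for (i, j), w in edges.items():
        G.add_edge(genes[i], genes[j], mi=w)
    return G


def bootstrap_consensus(
    data,
    hubs,
    mi_threshold: float | MIThreshold,
    dpi_tolerance: float = 0.0,
    n_boot: int = 200,
    edge_p_cut: float = 1e-6,
    seed: int = 0,
    params: MIParams = MIParams(),
    pseudocount: float = 1.0,
    bias_labels: pd.Series | None = None,
    max_redraws: int = 100,
) -> nx.Graph:
    """Bootstrap consensus network.

    Samples (columns) are resampled with replacement ``n_boot`` times and
    the network rebuilt per resample.  Each candidate edge's support count
    is tested against a pooled binomial null whose success probability is
    the mean edge-occurrence rate over all candidate edges; edges with a
    one-sided binomial tail probability <= ``edge_p_cut`` are retained.
    When the input is an :class:`ExpressionStudy`, resamples missing a
    season are redrawn (and logged).
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    hubs = list(hubs)
    if not hubs:
        raise ValueError("empty hub list")
    X, genes = _as_log2_matrix(data, pseudocount)
    seasons = (
        data.samples["season"].to_numpy()
        if isinstance(data, ExpressionStudy)
        else None
    )
    gene_pos = {gname: i for i, gname in enumerate(genes)}
    hub_idx = np.array(sorted(gene_pos[h] for h in hubs), dtype=np.int64)
    pairs = _hub_pairs(len(genes), hub_idx)
    thr = (
        mi_threshold.threshold
        if isinstance(mi_threshold, MIThreshold)
        else float(mi_threshold)
    )
    rng = np.random.default_rng(seed)
    n = X.shape[1]

    support: dict[tuple[int, int], int] = {}
    mi_sum: dict[tuple[int, int], float] = {}
    for b in range(n_boot):
        for attempt in range(max_redraws):
            idx = rng.integers(0, n, size=n)
            if seasons is None or len(set(seasons[idx])) == 2:
                break
            log.info("bootstrap %d: degenerate resample, redrawing", b)
        else:
            raise RuntimeError("could not draw a resample with both seasons")
        Rb = _scaled_ranks(X[:, idx])
        Sb = np.sort(Rb, axis=1)
        edges = _edge_scan(Rb, Sb, pairs, thr, dpi_tolerance, params)
        for key, w in edges.items():
            support[key] = support.get(key, 0) + 1
            mi_sum[key] = mi_sum.get(key, 0.0) + w

    G = nx.Graph(
        mi_threshold=thr,
        dpi_tolerance=dpi_tolerance,
        n_boot=n_boot,
        edge_p_cut=edge_p_cut,
    )
    hub_set = set(hubs)
    for gname in genes:
        G.add_node(gname, hub=gname in hub_set)
    if bias_labels is not None:
        nx.set_node_attributes(G, bias_labels.to_dict(), "bias")
    if support:
        p_bar = sum(support.values()) / (len(support) * n_boot)
        for (i, j), k in support.items():
            p_cons = float(stats.binom.sf(k - 1, n_boot, p_bar))
            if p_cons <= edge_p_cut:
                G.add_edge(
                    genes[i],
                    genes[j],
                    mi=mi_sum[(i, j)] / k,
                    support=k,
                    consensus_p=p_cons,
                )
    return G


# ---------------------------------------------------------------------------
# topology, modules, interface
# ---------------------------------------------------------------------------

def node_topology(G: nx.Graph) -> pd.DataFrame:
    """Betweenness (Brandes, normalised), eccentricity and degree per node.

    Eccentricity is computed within each connected component; singletons
    get eccentricity 0.
    """
    if G.number_of_nodes() == 0:
        raise ValueError("empty network")
    btw = nx.betweenness_centrality(G, normalized=True)
    ecc: dict = {}
    for comp in nx.connected_components(G):
        sub = G.subgraph(comp)
        if len(comp) == 1:
            ecc[next(iter(comp))] = 0
        else:
            ecc.update(nx.eccentricity(sub))
    return pd.DataFrame(
        {
            "betweenness": pd.Series(btw),
            "eccentricity": pd.Series(ecc),
            "degree": pd.Series(dict(G.degree())),
        }
    ).sort_index()


def extract_modules(G: nx.Graph, hubs) -> dict[str, set]:
    """Module of each hub: the hub plus its consensus neighbours."""
    modules = {}
    for h in hubs:
        if h not in G:
            raise KeyError(f"hub {h!r} not in network")
        modules[h] = {h} | set(G.neighbors(h))
    return modules


def module_overlap_graph(
    modules: dict[str, set],
    jaccard_cutoff: float = 0.1,
    bias_sets: dict[str, set] | None = None,
    universe=None,
) -> tuple[nx.Graph, pd.DataFrame]:
    """Meta-network of modules plus per-module bias/organismal enrichment.

    Nodes are modules (sized by member count); edges connect modules with
    Jaccard similarity >= the cutoff.  When ``bias_sets`` (e.g. winter- and
    summer-biased genes, organismal sets) and a gene universe are given,
    every module is tested for overlap with every set.
    """
    if len(modules) < 2:
        raise ValueError("need at least two modules")
    M = nx.Graph()
    for h, members in modules.items():
        M.add_node(h, size=len(members))
    for a, b in itertools.combinations(sorted(modules), 2):
        inter = len(modules[a] & modules[b])
        union = len(modules[a] | modules[b])
        j = inter / union if union else 0.0
        if j >= jaccard_cutoff:
            M.add_edge(a, b, jaccard=j)

    rows = []
    if bias_sets:
        if universe is None:
            universe = set().union(*modules.values(), *bias_sets.values())
        for h, members in modules.items():
            for set_name, s in bias_sets.items():
                res = overlap_test(members, s, universe)
                rows.append(
                    (h, set_name, res.n_overlap, res.p, res.odds_ratio, res.jaccard)
                )
    enrichment = pd.DataFrame(
        rows, columns=["module", "set", "n_overlap", "p", "odds_ratio", "jaccard"]
    )
    return M, enrichment


def interface_scores(
    G: nx.Graph,
    bias_labels: pd.Series | dict,
    cross_min: int = 1,
    within_quantile: float = 0.5,
    core_nodes=None,
) -> pd.DataFrame:
    """Winter-summer interface ("key") gene scoring over core nodes.

    For each core node: the cross-season edge count (edges to core nodes
    of the opposite bias) and the within-set degree (edges to same-bias
    cores).  A node is flagged ``key`` when it has at least ``cross_min``
    cross-season edges and its within-set degree reaches the
    ``within_quantile`` quantile of its own bias set.  Rows are ordered by
    (cross desc, within desc, gene id), which defines the interface score
    ranking.
    """
    labels = dict(bias_labels)
    cores = sorted(core_nodes) if core_nodes is not None else sorted(G.nodes)
    unlabeled = [c for c in cores if labels.get(c) not in ("winter", "summer")]
    if unlabeled:
        raise ValueError(f"core nodes without bias label: {unlabeled[:5]}")
    core_set = set(cores)
    rows = []
    for c in cores:
        cross = within = 0
        for nb in G.neighbors(c):
            if nb not in core_set:
                continue
            if labels[nb] == labels[c]:
                within += 1
            else:
                cross += 1
        rows.append((c, labels[c], cross, within))
    table = pd.DataFrame(
        rows, columns=["gene", "bias", "cross_edges", "within_degree"]
    )
    table["key"] = False
    for bias_value, grp in table.groupby("bias"):
        q = float(np.quantile(grp["within_degree"], within_quantile))
        flag = (grp["cross_edges"] >= cross_min) & (grp["within_degree"] >= q)
        table.loc[grp.index, "key"] = flag
    table = table.sort_values(
        ["cross_edges", "within_degree", "gene"], ascending=[False, False, True]
    ).reset_index(drop=True)
    return table


@dataclass
class EdgePartitionStats:
    per_node: pd.DataFrame
    pearson_r: float | None
    pearson_p: float | None
    fisher_odds: float | None
    fisher_p: float | None
    degenerate: bool = False


def edge_partition_stats(
    G: nx.Graph,
    immune_flags: pd.Series | dict,
    key_flags: pd.Series | dict,
    nonimmune_edge_threshold: int = 7,
) -> EdgePartitionStats:
    """Immune vs non-immune edge partition for core immune nodes.

    ``key_flags`` defines the core immune nodes under study (its keys) and
    which of them are winter-summer interface genes.  Reports per-node
    immune / non-immune edge counts, the Pearson correlation between the
    two counts, and a Fisher exact test of key status against having more
    than ``nonimmune_edge_threshold`` non-immune edges.
    """
    imm = dict(immune_flags)
    keys = dict(key_flags)
    missing = [n for n in G.nodes if n not in imm]
    if missing:
        raise ValueError(f"nodes without immune flag: {missing[:5]}")
    rows = []
    for node in sorted(keys):
        if node not in G:
            raise KeyError(f"core node {node!r} not in network")
        n_imm = sum(1 for nb in G.neighbors(node) if imm[nb])
        n_non = G.degree(node) - n_imm
        rows.append((node, bool(keys[node]), n_imm, n_non))
    per_node = pd.DataFrame(
        rows, columns=["gene", "key", "immune_edges", "nonimmune_edges"]
    )
    if len(per_node) < 3:
        return EdgePartitionStats(per_node, None, None, None, None, True)
    x = per_node["immune_edges"].to_numpy(float)
    y = per_node["nonimmune_edges"].to_numpy(float)
    if np.std(x) == 0 or np.std(y) == 0:
        r = p_r = None
        degenerate = True
    else:
        r, p_r = (float(v) for v in stats.pearsonr(x, y))
        degenerate = False
    hi = per_node["nonimmune_edges"] > nonimmune_edge_threshold
    table = [
        [int((per_node["key"] & hi).sum()), int((per_node["key"] & ~hi).sum())],
        [int((~per_node["key"] & hi).sum()), int((~per_node["key"] & ~hi).sum())],
    ]
    odds, p_f = stats.fisher_exact(table, alternative="greater")
    return EdgePartitionStats(
        per_node, r, p_r, float(odds), float(p_f), degenerate
    )


def write_sif(G: nx.Graph, path: str) -> None:
    """Export edges as SIF (source <TAB> mi <TAB> target)."""
    with open(path, "w") as fh:
        for u, v in sorted(G.edges):
            fh.write(f"{u}\tmi\t{v}\n")
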