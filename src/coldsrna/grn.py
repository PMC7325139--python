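"""miRNA-TF gene regulatory network: construction from tiered evidence,
module detection, cold-responsive subnetwork extraction, and edge
validation by target-expression prediction.

Edges carry an evidence source: experimentally validated TF connections,
PlantRegMap-style conserved-element (CE) and FunTFBS tiers, and
miRNA_predicted edges from target scoring.  Network versions are nested
on the validated base: validated_only < +CE < +FunTFBS < combined (the
last adding miRNA edges).

Predictive power is the mean out-of-fold Pearson correlation between
measured target expression and the prediction of a gradient-boosted
regression-tree model whose inputs are the time point, the familywise
aggregated expression of the target's regulators, and the target's
binding-site count; cross-validation is partitioned by target gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import networkx as nx
import numpy as np
import pandas as pd
from networkx.algorithms.community import modularity
from scipy import stats
from sklearn.ensemble import GradientBoostingRegressor

logger = logging.getLogger(__name__)

TF_SOURCE_PRECEDENCE = ("validated", "CE", "FunTFBS")
ALL_SOURCES = TF_SOURCE_PRECEDENCE + ("miRNA_predicted",)

#: Nested network versions (each a superset of the previous).
VERSIONS: dict[str, tuple[str, ...]] = {
    "validated_only": ("validated",),
    "+CE": ("validated", "CE"),
    "+FunTFBS": ("validated", "CE", "FunTFBS"),
    "combined": ALL_SOURCES,
}


def build_network(
    edges: pd.DataFrame,
    families: Optional[Mapping[str, str]] = None,
    known_ids: Optional[set[str]] = None,
) -> nx.DiGraph:
    """Directed regulatory network from an edge table.

    ``edges`` columns: (regulator, target, source, binding_site_count).
    Duplicate (regulator, target) edges collapse keeping the
    highest-confidence TF source (validated > CE > FunTFBS); miRNA edges
    never collapse with TF edges because a regulator id is either a miRNA
    or a TF.  When ``known_ids`` is given, edges touching unknown ids are
    dropped with a logged count.  Node roles (miRNA / TF / target) are
    inferred from edge membership; a node may hold several roles.
    """
    required = {"regulator", "target", "source", "binding_site_count"}
    missing = required - set(edges.columns)
    if missing:
        raise ValueError(f"edge table missing columns: {sorted(missing)}")
    bad_source = set(edges["source"]) - set(ALL_SOURCES)
    if bad_source:
        raise ValueError(f"unknown edge sources: {sorted(bad_source)}")

    if known_ids is not None:
        ok = edges["regulator"].isin(known_ids) & edges["target"].isin(known_ids)
        dropped = int((~ok).sum())
        if dropped:
            logger.warning("dropped %d edge(s) with dangling ids", dropped)
        edges = edges[ok]

    rank = {s: i for i, s in enumerate(ALL_SOURCES)}
    g = nx.DiGraph()
    # deterministic regardless of input row order
    for row in edges.sort_values(
        ["regulator", "target", "source"],
        key=lambda col: col.map(rank) if col.name == "source" else col,
        kind="mergesort",
    ).itertuples(index=False):
        reg, tgt = str(row.regulator), str(row.target)
        if g.has_edge(reg, tgt):
            continue  # first (highest-confidence) source wins
        if row.source == "miRNA_predicted" and reg == tgt:
            raise ValueError(f"self-loop miRNA edge {reg}->{tgt}")
        g.add_edge(reg, tgt, source=str(row.source),
                   binding_site_count=int(row.binding_site_count))

    for node in g.nodes:
        roles = set()
        for _u, _v, d in g.out_edges(node, data=True):
            roles.add("miRNA" if d["source"] == "miRNA_predicted" else "TF")
        if g.in_degree(node) > 0:
            roles.add("target")
        g.nodes[node]["roles"] = frozenset(roles)
        fam = families.get(node) if families else None
        g.nodes[node]["family"] = fam
    return g


def subset_network(network: nx.DiGraph, sources: Iterable[str]) -> nx.DiGraph:
    """Edge-subgraph restricted to the given evidence sources (roles rebuilt)."""
    sources = set(sources)
    keep = [(u, v) for u, v, d in network.edges(data=True) if d["source"] in sources]
    sub = network.edge_subgraph(keep).copy()
    for node in sub.nodes:
        roles = set()
        for _u, _v, d in sub.out_edges(node, data=True):
            roles.add("miRNA" if d["source"] == "miRNA_predicted" else "TF")
        if sub.in_degree(node) > 0:
            roles.add("target")
        sub.nodes[node]["roles"] = frozenset(roles)
    return sub


def regulators_of(network: nx.DiGraph) -> dict[str, set[tuple[str, str]]]:
    """Map each target-role node to its {(regulator, source)} set."""
    out: dict[str, set[tuple[str, str]]] = {}
    for u, v, d in network.edges(data=True):
        out.setdefault(v, set()).add((u, d["source"]))
    return out


# ---------------------------------------------------------------------------
# Module detection (Louvain-style greedy modularity maximization)


def detect_modules(
    network: nx.Graph,
    resolution: float = 1.0,
    seed: int = 0,
    restarts: int = 8,
) -> tuple[dict[str, int], float]:
    """Louvain-style community detection on the undirected projection.

    Local greedy moves followed by community aggregation, repeated until
    the modularity Q = sum_c (e_c/m - (d_c/2m)^2) stops improving; the
    best partition over ``restarts`` seeded node-order shuffles is
    returned as (node -> module id, Q).
    """
    if network.number_of_nodes() == 0:
        raise ValueError("network is empty")
    g = nx.Graph()
    g.add_nodes_from(network.nodes)
    for u, v in network.edges():
        if g.has_edge(u, v):
            g[u][v]["weight"] += 1.0
        else:
            g.add_edge(u, v, weight=1.0)

    if g.number_of_edges() == 0:
        communities = [{n} for n in g.nodes]
    else:
        ss = np.random.SeedSequence(seed)
        best_q, communities = -np.inf, None
        for child in ss.spawn(restarts):
            rng = np.random.default_rng(child)
            cand = _louvain(g, resolution, rng)
            q = modularity(g, cand, resolution=resolution, weight="weight")
            if q > best_q + 1e-15:
                best_q, communities = q, cand

    communities = sorted(communities, key=lambda c: sorted(c)[0])
    assignment = {n: i for i, comm in enumerate(communities) for n in comm}
    q = (modularity(g, communities, resolution=resolution, weight="weight")
         if g.number_of_edges() else 0.0)
    return assignment, float(q)


def _louvain(g: nx.Graph, resolution: float, rng: np.random.Generator) -> list[set]:
    """One full Louvain run: local moves + aggregation until Q stops improving."""
    # each current node maps to the set of original nodes it contains
    members = {n: {n} for n in g.nodes}
    current = g
    while True:
        node2com, moved = _one_level(current, resolution, rng)
        if not moved:
            break
        groups: dict[int, set] = {}
        for n, c in node2com.items():
            groups.setdefault(c, set()).update(members[n])
        agg = nx.Graph()
        agg.add_nodes_from(groups)
        for u, v, d in current.edges(data=True):
            cu, cv = node2com[u], node2com[v]
            w = d.get("weight", 1.0)
            if agg.has_edge(cu, cv):
                agg[cu][cv]["weight"] += w
            else:
                agg.add_edge(cu, cv, weight=w)
        members = groups
        current = agg
        if current.number_of_nodes() == len(groups) == 1:
            break
    return list(members.values())


def _one_level(g: nx.Graph, resolution: float, rng: np.random.Generator
               ) -> tuple[dict, bool]:
    """Greedy node moves; returns (node -> community, any move made)."""
    nodes = list(g.nodes)
    node2com = {n: i for i, n in enumerate(nodes)}
    degree = dict(g.degree(weight="weight"))  # self-loops counted twice
    sigma_tot = {node2com[n]: degree[n] for n in nodes}
    m = g.size(weight="weight")
    two_m = 2.0 * m
    any_move = False

    improved = True
    while improved:
        improved = False
        order = list(nodes)
        rng.shuffle(order)
        for n in order:
            com_n = node2com[n]
            # weights to neighboring communities (self-loops excluded)
            w_nc: dict[int, float] = {}
            for nbr, d in g[n].items():
                if nbr == n:
                    continue
                c = node2com[nbr]
                w_nc[c] = w_nc.get(c, 0.0) + d.get("weight", 1.0)
            sigma_tot[com_n] -= degree[n]
            # gain (x m) of joining community c from isolation
            best_c, best_gain = com_n, w_nc.get(com_n, 0.0) - (
                resolution * sigma_tot.get(com_n, 0.0) * degree[n] / two_m)
            for c in sorted(w_nc):
                gain = w_nc[c] - resolution * sigma_tot.get(c, 0.0) * degree[n] / two_m
                if gain > best_gain + 1e-12:
                    best_gain, best_c = gain, c
            sigma_tot[best_c] = sigma_tot.get(best_c, 0.0) + degree[n]
            if best_c != com_n:
                node2com[n] = best_c
                improved = True
                any_move = True
    return node2com, any_move


# ---------------------------------------------------------------------------
# Cold-responsive subnetwork


def extract_cold_subnetwork(network: nx.DiGraph,
                            de_sets: Mapping[str, set[str]]) -> nx.DiGraph:
    """Induced subnetwork of cold-responsive regulation.

    Kept nodes: DE miRNAs (DE at >= 1 time point); their targets DE at
    >= 1 time point; TF intermediaries among those kept targets; and such
    TFs' own downstream targets DE at >= 1 time point.  Edges are the
    original edges among kept nodes.
    """
    de_any: set[str] = set()
    for s in de_sets.values():
        de_any |= set(s)

    def has_role(n: str, role: str) -> bool:
        return role in network.nodes[n].get("roles", frozenset())

    de_mirnas = {n for n in network.nodes if has_role(n, "miRNA") and n in de_any}
    mirna_targets = {
        v for u in de_mirnas for v in network.successors(u) if v in de_any
    }
    tf_intermediaries = {n for n in mirna_targets if has_role(n, "TF")}
    tf_targets = {
        v for tf in tf_intermediaries for v in network.successors(tf) if v in de_any
    }
    keep = de_mirnas | mirna_targets | tf_intermediaries | tf_targets
    return network.subgraph(keep).copy()


# ---------------------------------------------------------------------------
# Predictive power


@dataclass
class PredictivePowerReport:
    """Out-of-fold predictive power of one network version."""

    version: str
    mean_r: float
    per_target_r: pd.Series
    n_targets: int
    n_excluded: int
    summary: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.per_target_r):
            q = self.per_target_r.quantile([0.25, 0.5, 0.75])
            self.summary = {"q25": float(q.iloc[0]), "median": float(q.iloc[1]),
                            "q75": float(q.iloc[2])}


def _feature_matrix(
    network: nx.DiGraph,
    expression: pd.DataFrame,
    design: pd.DataFrame,
    binding_site_counts: Optional[Mapping[str, float]] = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Rows are (target, sample) pairs; returns (X, y, target labels, excluded)."""
    samples = [s for s in design["sample"] if s in expression.columns]
    times = sorted(design["time"].unique())
    time_of = design.set_index("sample")["time"]

    reg_map = regulators_of(network)
    targets = sorted(
        t for t in reg_map
        if t in expression.index and reg_map[t]
        and all(r in expression.index for r, _ in reg_map[t])
    )
    excluded = len([t for t in reg_map if t not in targets])
    if excluded:
        logger.info("%d target(s) without usable regulators/expression excluded",
                    excluded)

    families = sorted({
        (network.nodes[r].get("family") or r)
        for regs in reg_map.values() for r, _src in regs
    })
    fam_idx = {f: i for i, f in enumerate(families)}

    if binding_site_counts is None:
        binding_site_counts = {
            t: float(sum(network.edges[r, t]["binding_site_count"]
                         for r, _src in reg_map[t]))
            for t in targets
        }

    n_time, n_fam = len(times), len(families)
    rows, ys, labels = [], [], []
    expr = expression[samples]
    for t in targets:
        regs = sorted(r for r, _src in reg_map[t])
        reg_expr = expr.loc[regs].to_numpy()
        reg_fams = [fam_idx[network.nodes[r].get("family") or r] for r in regs]
        for j, s in enumerate(samples):
            x = np.zeros(n_time + n_fam + 1)
            x[times.index(time_of[s])] = 1.0
            for ri, fi in enumerate(reg_fams):
                x[n_time + fi] += reg_expr[ri, j]
            x[-1] = binding_site_counts.get(t, 0.0)
            rows.append(x)
            ys.append(expr.at[t, s])
            labels.append(t)
    if not rows:
        return (np.empty((0, n_time + n_fam + 1)), np.empty(0),
                np.asarray([], dtype=object), excluded)
    return np.vstack(rows), np.asarray(ys, float), np.asarray(labels, object), excluded


def predictive_power(
    network: nx.DiGraph,
    expression: pd.DataFrame,
    design: pd.DataFrame,
    binding_site_counts: Optional[Mapping[str, float]] = None,
    cv_folds: int = 5,
    seed: int = 0,
    version: str = "combined",
) -> PredictivePowerReport:
    """Mean out-of-fold Pearson r between predicted and measured target
    expression, with cross-validation partitioned by target gene."""
    x, y, labels, excluded = _feature_matrix(
        network, expression, design, binding_site_counts)
    if len(y) == 0:
        return PredictivePowerReport(version, float("nan"), pd.Series(dtype=float),
                                     0, excluded)

    targets = sorted(set(labels))
    rng = np.random.default_rng(seed)
    shuffled = list(targets)
    rng.shuffle(shuffled)
    n_folds = min(cv_folds, len(shuffled))
    fold_of = {t: i % n_folds for i, t in enumerate(shuffled)}
    fold_ids = np.asarray([fold_of[t] for t in labels])

    predictions = np.full(len(y), np.nan)
    for fold in range(n_folds):
        test = fold_ids == fold
        model = GradientBoostingRegressor(
            n_estimators=200, learning_rate=0.1, max_depth=3, random_state=seed)
        model.fit(x[~test], y[~test])
        predictions[test] = model.predict(x[test])

    per_target = {}
    for t in targets:
        mask = labels == t
        if mask.sum() >= 3 and np.std(y[mask]) > 0 and np.std(predictions[mask]) > 0:
            per_target[t] = float(stats.pearsonr(y[mask], predictions[mask])[0])
    series = pd.Series(per_target, dtype=float).sort_index()
    mean_r = float(series.mean()) if len(series) else float("nan")
    return PredictivePowerReport(version, mean_r, series, len(targets), excluded)


def compare_versions(
    network: nx.DiGraph,
    expression: pd.DataFrame,
    design: pd.DataFrame,
    cv_folds: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Predictive power of every nested network version, ranked by mean r."""
    reports = []
    for version, sources in VERSIONS.items():
        sub = subset_network(network, sources)
        rep = predictive_power(sub, expression, design, cv_folds=cv_folds,
                               seed=seed, version=version)
        reports.append({"version": version, "mean_r": rep.mean_r,
                        "n_targets": rep.n_targets,
                        "median_r": rep.summary.get("median", float("nan"))})
    table = pd.DataFrame(reports)
    return table.sort_values("mean_r", ascending=False, ignore_index=True)


# ---------------------------------------------------------------------------
# Export


def _serializable(network: nx.DiGraph) -> nx.DiGraph:
    g = network.copy()
    for n, d in g.nodes(data=True):
        if isinstance(d.get("roles"), frozenset):
            d["roles"] = ",".join(sorted(d["roles"]))
        if d.get("family") is None:
            d.pop("family", None)
    return g


def write_gexf(network: nx.DiGraph, path) -> None:
    nx.write_gexf(_serializable(network), path)


def write_graphml(network: nx.DiGraph, path) -> None:
    nx.write_graphml(_serializable(network), path)
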