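"""Fungal co-occurrence network: correlation screening, module detection,
and Zi-Pi topological node roles.

The network is built over prevalence-filtered, rarefied ASVs: every
unordered ASV pair gets a Spearman rank correlation across samples with a
two-sided p-value from the t approximation; p-values are Benjamini-Hochberg
adjusted across all pairs; an edge exists when |rho| >= r_min (default 0.6)
and q < q_max (default 0.05).  Negative correlations ("mutual exclusion")
are kept as signed edges with weight |rho|.  ASVs left without any
surviving edge are excluded from the node set — only connected taxa take
part in module statistics.

Modules are detected with seeded weighted Louvain modularity optimisation
(resolution configurable, default 1.0), the same algorithm behind desktop
tools' modularity buttons.  Node roles follow the within-module degree
z-score (Zi) and the among-module participation coefficient (Pi):
peripheral, connector, module hub or network hub depending on the Zi = 2.5
and Pi = 0.62 thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CorrelationResult",
    "ModulePartition",
    "pairwise_spearman",
    "bh_adjust",
    "build_network",
    "detect_modules",
    "zipi",
    "classify_roles",
    "write_edge_list",
    "write_graphml",
    "read_graphml",
]


@dataclass(frozen=True)
class CorrelationResult:
    """Per-pair Spearman results in tidy form.

    ``pairs`` has one row per unordered ASV pair with columns
    ``asv_a, asv_b, rho, p, q``.  Pairs where either series is constant have
    ``rho`` = NaN and are flagged in ``constant_pairs``; they never become
    edges and are excluded from the BH adjustment.
    """

    pairs: pd.DataFrame
    n_samples: int
    constant_asvs: tuple[str, ...]


def pairwise_spearman(table: pd.DataFrame) -> CorrelationResult:
    """Spearman rho (average ranks for ties) for all ASV pairs across samples.

    Two-sided p-values come from the t approximation
    ``t = rho * sqrt((n-2) / (1 - rho^2))`` with n-2 degrees of freedom.
    Requires at least 4 samples for the approximation to be usable.
    """
    n = table.shape[1]
    if n < 4:
        raise ValueError("pairwise Spearman needs at least 4 samples")
    ids = [str(i) for i in table.index]
    x = table.to_numpy(dtype=float)
    constant = x.std(axis=1) == 0
    ranks = scipy.stats.rankdata(x, axis=1)
    rc = ranks - ranks.mean(axis=1, keepdims=True)
    norm = np.sqrt((rc ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (rc @ rc.T) / np.outer(norm, norm)
    rho = np.clip(rho, -1.0, 1.0)
    rho[constant, :] = np.nan
    rho[:, constant] = np.nan

    iu, ju = np.triu_indices(len(ids), k=1)
    r = rho[iu, ju]
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r ** 2))
    p = 2.0 * scipy.stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isclose(np.abs(r), 1.0), 0.0, p)
    ok = ~np.isnan(r)
    q = np.full_like(p, np.nan)
    if ok.any():
        q[ok] = bh_adjust(p[ok])
    pairs = pd.DataFrame({
        "asv_a": np.asarray(ids)[iu],
        "asv_b": np.asarray(ids)[ju],
        "rho": r,
        "p": p,
        "q": q,
    })
    return CorrelationResult(
        pairs=pairs,
        n_samples=n,
        constant_asvs=tuple(np.asarray(ids)[constant]),
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def build_network(
    corr: CorrelationResult, r_min: float = 0.6, q_max: float = 0.05
) -> nx.Graph:
    """Threshold the correlation screen into a signed weighted graph.

    Edge iff |rho| >= r_min and q < q_max.  Isolated ASVs (no surviving
    edge) are excluded from the node set entirely.
    """
    pairs = corr.pairs
    keep = pairs[(pairs.rho.abs() >= r_min) & (pairs.q < q_max)]
    g = nx.Graph()
    g.graph["r_min"] = r_min
    g.graph["q_max"] = q_max
    for row in keep.itertuples():
        g.add_edge(
            row.asv_a,
            row.asv_b,
            rho=float(row.rho),
            weight=float(abs(row.rho)),
            sign="+" if row.rho >= 0 else "-",
        )
    return g


@dataclass(frozen=True)
class ModulePartition:
    """Node -> dense integer module id, plus the weighted modularity Q."""

    assignment: dict[str, int]
    modularity: float
    resolution: float

    @property
    def n_modules(self) -> int:
        return len(set(self.assignment.values()))

    def members(self, module_id: int) -> list[str]:
        return sorted(n for n, m in self.assignment.items() if m == module_id)

    def modules(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for n, m in self.assignment.items():
            out.setdefault(m, []).append(n)
        return {m: sorted(v) for m, v in sorted(out.items())}


def detect_modules(
    network: nx.Graph, resolution: float = 1.0, seed: int = 0
) -> ModulePartition:
    """Louvain community detection on edge weights |rho|.

    Module ids are dense integers ordered by decreasing module size (ties
    broken by smallest member id) so that ids are stable for a given
    partition regardless of Louvain's internal ordering.
    """
    if network.number_of_nodes() == 0:
        raise ValueError("cannot detect modules in an empty network")
    comms = nx.community.louvain_communities(
        network, weight="weight", resolution=resolution, seed=seed
    )
    comms = sorted(comms, key=lambda c: (-len(c), min(str(n) for n in c)))
    assignment = {str(n): i for i, c in enumerate(comms) for n in c}
    q = nx.community.modularity(
        network, comms, weight="weight", resolution=resolution
    )
    return ModulePartition(assignment=assignment, modularity=float(q), resolution=resolution)


def zipi(network: nx.Graph, partition: ModulePartition, weighted: bool = False) -> pd.DataFrame:
    """Within-module degree z-score (Zi) and participation coefficient (Pi).

    With k_i the degree of node i, k_im its links into module m and s its
    own module: Zi = (k_is - mean_{j in s} k_js) / sd_{j in s}(k_js) and
    Pi = 1 - sum_m (k_im / k_i)^2.  Degree is the unweighted link count by
    default (the original formulation); ``weighted=True`` uses |rho| sums.
    Modules where the within-degree standard deviation is zero (e.g. 2-node
    modules) get Zi = 0 for every member, so no NaN ever leaves this
    function.
    """
    missing = [n for n in network.nodes if str(n) not in partition.assignment]
    if missing:
        raise ValueError(f"partition does not cover nodes: {missing[:5]}")
    nodes = sorted(str(n) for n in network.nodes)
    mod_of = partition.assignment

    k_in_module: dict[str, dict[int, float]] = {n: {} for n in nodes}
    for a, b, data in network.edges(data=True):
        w = float(data["weight"]) if weighted else 1.0
        a, b = str(a), str(b)
        k_in_module[a][mod_of[b]] = k_in_module[a].get(mod_of[b], 0.0) + w
        k_in_module[b][mod_of[a]] = k_in_module[b].get(mod_of[a], 0.0) + w

    within = {n: k_in_module[n].get(mod_of[n], 0.0) for n in nodes}
    zi = {}
    for m, members in partition.modules().items():
        vals = np.array([within[n] for n in members], dtype=float)
        sd = vals.std()
        mean = vals.mean()
        for n in members:
            zi[n] = 0.0 if sd == 0 else (within[n] - mean) / sd

    rows = []
    for n in nodes:
        k = sum(k_in_module[n].values())
        pi = 0.0 if k == 0 else 1.0 - sum((v / k) ** 2 for v in k_in_module[n].values())
        rows.append({"asv_id": n, "module_id": mod_of[n], "zi": zi[n], "pi": pi})
    return pd.DataFrame(rows).set_index("asv_id")


def classify_roles(
    topology: pd.DataFrame, zi_threshold: float = 2.5, pi_threshold: float = 0.62
) -> pd.DataFrame:
    """Assign the four topological roles from Zi/Pi thresholds.

    peripheral (Zi < t_z, Pi < t_p), connector (Zi < t_z, Pi >= t_p),
    module_hub (Zi >= t_z, Pi < t_p), network_hub (Zi >= t_z, Pi >= t_p).
    """
    out = topology.copy()
    hub = out["zi"] >= zi_threshold
    conn = out["pi"] >= pi_threshold
    role = np.where(
        hub & conn, "network_hub",
        np.where(hub, "module_hub", np.where(conn, "connector", "peripheral")),
    )
    out["role"] = role
    return out


# ---------------------------------------------------------------------------
# Export / import


def write_edge_list(network: nx.Graph, path) -> None:
    rows = [
        {"source": a, "target": b, "rho": d["rho"], "sign": d["sign"], "weight": d["weight"]}
        for a, b, d in sorted(network.edges(data=True))
    ]
    pd.DataFrame(rows, columns=["source", "target", "rho", "sign", "weight"]).to_csv(
        path, sep="\t", index=False
    )


def write_graphml(network: nx.Graph, path) -> None:
    nx.write_graphml(network, path)


def read_graphml(path) -> nx.Graph:
    g = nx.read_graphml(path)
    for _, _, d in g.edges(data=True):
        if "weight" not in d and "rho" in d:
            d["weight"] = abs(float(d["rho"]))
        if "sign" not in d and "rho" in d:
            d["sign"] = "+" if float(d["rho"]) >= 0 else "-"
    return g
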