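"""Network- and node-level statistics for bipartite co-occurrence networks.

Implements the standard two-mode metric suite: connectance, links per
species, NODF nestedness, quantitative linkage density, interaction Shannon
diversity and evenness, guild-wise clustering coefficients of the one-mode
projections, compartment (connected component) counts, and the Blüthgen
specialization index d' per node.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .bipartite import BipartiteNetwork

#: weights are |rho| in [0,1]; scaled by this factor and rounded to integers
#: wherever a metric needs integer interaction counts (d', Patefield nulls)
INTEGER_SCALE = 100


def _as_weights(net) -> np.ndarray:
    if isinstance(net, BipartiteNetwork):
        return net.weights
    return np.asarray(net, dtype=float)


def integer_scaled(net, scale: int = INTEGER_SCALE) -> np.ndarray:
    """Round the weight matrix to integer interaction counts."""
    return np.rint(_as_weights(net) * scale).astype(int)


# ---------------------------------------------------------------- network level


def connectance(net) -> float:
    """Realized fraction of possible inter-guild links, L / (rows * cols)."""
    w = _as_weights(net)
    if w.size == 0 or not (w > 0).any():
        raise ValueError("empty network")
    return float((w > 0).sum() / (w.shape[0] * w.shape[1]))


def links_per_species(net) -> float:
    """L / (rows + cols)."""
    w = _as_weights(net)
    if w.size == 0 or not (w > 0).any():
        raise ValueError("empty network")
    return float((w > 0).sum() / (w.shape[0] + w.shape[1]))


def nodf(matrix) -> float:
    """NODF nestedness (0 disordered .. 100 perfectly nested) of a binary matrix.

    For every ordered pair with strictly decreasing marginal fill, the paired
    overlap is the percentage of the smaller set contained in the larger;
    equal-fill pairs contribute 0. NODF is the mean over all row pairs and
    column pairs.
    """
    m = (np.asarray(_as_weights(matrix)) > 0).astype(int)
    if m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need at least 2 rows and 2 columns")
    if m.sum() == 0:
        raise ValueError("all-zero matrix")

    def _pairs(mat: np.ndarray) -> tuple[float, int]:
        fills = mat.sum(axis=1)
        n = mat.shape[0]
        total = 0.0
        count = 0
        overlap = mat @ mat.T
        for i in range(n):
            for j in range(i + 1, n):
                count += 1
                fi, fj = fills[i], fills[j]
                if fi == fj or min(fi, fj) == 0:
                    continue
                hi, lo = (i, j) if fi > fj else (j, i)
                total += 100.0 * overlap[hi, lo] / fills[lo]
        return total, count

    rt, rc = _pairs(m)
    ct, cc = _pairs(m.T)
    return float((rt + ct) / (rc + cc))


def interaction_shannon(net) -> float:
    """Shannon diversity (natural log) of the interaction weight distribution."""
    w = _as_weights(net)
    total = w.sum()
    if total <= 0:
        raise ValueError("total weight must be positive")
    p = w[w > 0] / total
    return float(-(p * np.log(p)).sum())


def interaction_evenness(net) -> float:
    """Interaction evenness, H / ln(rows * cols)."""
    w = _as_weights(net)
    denom = np.log(w.shape[0] * w.shape[1])
    if denom <= 0:
        raise ValueError("evenness undefined for a 1x1 matrix")
    return float(interaction_shannon(net) / denom)


def linkage_density(net) -> float:
    """Quantitative (weighted) linkage density.

    LD = 1/2 * [ sum_j (w_.j/m) 2**H_j + sum_i (w_i./m) 2**H_i ]

    where H is each node's Shannon entropy (base 2) of its interaction
    weights, i.e. the marginal-weighted mean number of effective partners.
    """
    w = _as_weights(net)
    m = w.sum()
    if m <= 0:
        raise ValueError("total weight must be positive")

    def _term(mat: np.ndarray) -> float:
        marg = mat.sum(axis=1)
        out = 0.0
        for i in range(mat.shape[0]):
            if marg[i] <= 0:
                continue
            p = mat[i][mat[i] > 0] / marg[i]
            h2 = -(p * np.log2(p)).sum()
            out += (marg[i] / m) * 2.0**h2
        return out

    return float(0.5 * (_term(w) + _term(w.T)))


def guild_cluster_coefficient(net, guild: str = "rows") -> float:
    """Mean local clustering of the one-mode projection onto one guild.

    Two guild members are linked in the projection iff they share at least one
    partner; nodes with fewer than two projection neighbours contribute 0.
    """
    w = _as_weights(net)
    mat = (w > 0).astype(int) if guild == "rows" else (w > 0).astype(int).T
    n = mat.shape[0]
    if n < 2:
        raise ValueError("guild needs at least 2 nodes")
    shared = mat @ mat.T
    adj = (shared > 0).astype(int)
    np.fill_diagonal(adj, 0)
    g = nx.from_numpy_array(adj)
    return float(np.mean(list(nx.clustering(g).values())))


def compartments(net) -> int:
    """Number of connected components of the bipartite graph."""
    w = _as_weights(net)
    if w.size == 0:
        raise ValueError("empty network")
    r, c = w.shape
    biadj = csr_matrix((w > 0).astype(int))
    full = csr_matrix((r + c, r + c), dtype=int).tolil()
    full[:r, r:] = biadj
    full[r:, :r] = biadj.T
    n_comp, labels = connected_components(full.tocsr(), directed=False)
    # count only components containing at least one linked node
    linked = np.concatenate([(w > 0).any(axis=1), (w > 0).any(axis=0)])
    return int(len(set(labels[linked])))


# ------------------------------------------------------------------ node level


def _dmin_integer(total: int, q: np.ndarray) -> float:
    """KL divergence of the most availability-proportional integer allocation.

    Allocates ``total`` integer interactions across partners proportionally to
    the marginal shares ``q`` by largest remainder, then evaluates
    sum p' ln(p'/q) for that allocation.
    """
    ideal = total * q
    base = np.floor(ideal).astype(int)
    short = total - base.sum()
    if short > 0:
        rema = ideal - base
        order = np.lexsort((np.arange(len(q)), -rema))
        base[order[:short]] += 1
    p = base[base > 0] / total
    qq = q[base > 0]
    return float((p * np.log(p / qq)).sum())


def specialization_d(net, scale: int = INTEGER_SCALE) -> pd.DataFrame:
    """Blüthgen standardized specialization index d' for every node.

    d_i = sum_j p'_ij ln(p'_ij / q_j) with p'_ij the node's interaction share
    and q_j the partner marginal share; standardized as
    d' = (d - d_min) / (d_max - d_min) on the integer-scaled matrix, with
    d_max = ln(m / A_i) (attained by an exclusive partner) and d_min from the
    most availability-proportional integer allocation. Nodes for which the
    bounds collapse (single possible partner) get d' = 0.
    """
    mat = integer_scaled(net, scale)
    row_ids = net.row_ids if isinstance(net, BipartiteNetwork) else [f"R{i}" for i in range(mat.shape[0])]
    col_ids = net.col_ids if isinstance(net, BipartiteNetwork) else [f"C{j}" for j in range(mat.shape[1])]
    records = []
    for guild, ids, m2 in (("microeukaryote", row_ids, mat), ("bacteria", col_ids, mat.T)):
        total = m2.sum()
        q = m2.sum(axis=0) / total
        for i, node in enumerate(ids):
            a = m2[i].sum()
            if a == 0:
                continue
            p = m2[i][m2[i] > 0] / a
            qi = q[m2[i] > 0]
            d = float((p * np.log(p / qi)).sum())
            dmax = float(np.log(total / a))
            dmin = _dmin_integer(int(a), q)
            if dmax - dmin <= 1e-12:
                dprime = 0.0
            else:
                dprime = float(np.clip((d - dmin) / (dmax - dmin), 0.0, 1.0))
            records.append(
                {
                    "otu_id": node,
                    "guild": guild,
                    "degree": int((m2[i] > 0).sum()),
                    "strength": float(m2[i].sum()) / scale,
                    "d_prime": dprime,
                }
            )
    return pd.DataFrame(records, columns=["otu_id", "guild", "degree", "strength", "d_prime"])


def count_perfect_specialists(net, tol: float = 1e-9) -> int:
    """Number of nodes (both guilds) with d' = 1, i.e. exclusive pairings."""
    d = specialization_d(net)
    if d.empty:
        return 0
    return int((d["d_prime"] >= 1.0 - tol).sum())


# -------------------------------------------------------------------- assembly


@dataclass
class NetworkLevelMetrics:
    """The full network-level metric report (Table-style overview)."""

    n_rows: int
    n_cols: int
    n_links: int
    total_weight: float
    links_per_species: float
    connectance: float
    nodf: float
    linkage_density: float
    interaction_shannon: float
    interaction_evenness: float
    cluster_coefficient_rows: float
    cluster_coefficient_cols: float
    n_compartments: int

    def to_dict(self) -> dict:
        return asdict(self)


def network_report(net: BipartiteNetwork) -> NetworkLevelMetrics:
    """Assemble every network-level metric for a nonempty network."""
    if net.is_empty():
        raise ValueError("empty network")
    return NetworkLevelMetrics(
        n_rows=net.n_rows,
        n_cols=net.n_cols,
        n_links=net.n_links,
        total_weight=net.total_weight,
        links_per_species=links_per_species(net),
        connectance=connectance(net),
        nodf=nodf(net.binary()) if net.n_rows >= 2 and net.n_cols >= 2 else float("nan"),
        linkage_density=linkage_density(net),
        interaction_shannon=interaction_shannon(net),
        interaction_evenness=interaction_evenness(net)
        if net.n_rows * net.n_cols > 1
        else float("nan"),
        cluster_coefficient_rows=guild_cluster_coefficient(net, "rows")
        if net.n_rows >= 2
        else float("nan"),
        cluster_coefficient_cols=guild_cluster_coefficient(net, "cols")
        if net.n_cols >= 2
        else float("nan"),
        n_compartments=compartments(net),
    )
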