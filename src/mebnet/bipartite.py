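"""Signed bipartite (two-mode) networks between microeukaryotes and bacteria.

Rows of the incidence matrix are microeukaryote OTUs, columns are bacterial
OTUs, and weights are the absolute SparCC correlation of each retained edge.
Positive and negative associations live in separate networks of the same
shape of metadata, which is what the core-taxa (nodes with links of both
signs) and degree-symmetry analyses compare.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .tables import TaxonomyTable


@dataclass
class BipartiteNetwork:
    """A weighted bipartite incidence matrix with node metadata.

    ``weights[i, j] >= 0`` is the interaction weight between row node i
    (microeukaryote) and column node j (bacterium); isolated nodes are pruned
    at construction. ``edges`` optionally carries the originating edge list
    (rho, p) for export.
    """

    row_ids: list[str]
    col_ids: list[str]
    weights: np.ndarray
    sign: str = "positive"
    habitat: str = ""
    row_phyla: dict[str, str] = field(default_factory=dict)
    col_phyla: dict[str, str] = field(default_factory=dict)
    edges: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if (self.weights < 0).any():
            raise ValueError("weights must be non-negative")
        if self.weights.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValueError("weights shape does not match node id lengths")
        if len(set(self.row_ids)) != len(self.row_ids) or len(set(self.col_ids)) != len(
            self.col_ids
        ):
            raise ValueError("duplicate node ids")

    @classmethod
    def from_incidence(
        cls, matrix, row_ids=None, col_ids=None, sign="positive", habitat=""
    ) -> "BipartiteNetwork":
        matrix = np.asarray(matrix, dtype=float)
        r, c = matrix.shape
        if row_ids is None:
            row_ids = [f"R{i}" for i in range(r)]
        if col_ids is None:
            col_ids = [f"C{j}" for j in range(c)]
        return cls(list(row_ids), list(col_ids), matrix, sign, habitat)

    @property
    def n_rows(self) -> int:
        return len(self.row_ids)

    @property
    def n_cols(self) -> int:
        return len(self.col_ids)

    @property
    def n_links(self) -> int:
        return int((self.weights > 0).sum())

    @property
    def total_weight(self) -> float:
        return float(self.weights.sum())

    def binary(self) -> np.ndarray:
        return (self.weights > 0).astype(int)

    def row_degrees(self) -> np.ndarray:
        return (self.weights > 0).sum(axis=1)

    def col_degrees(self) -> np.ndarray:
        return (self.weights > 0).sum(axis=0)

    def is_empty(self) -> bool:
        return self.n_links == 0

    def prune_isolated(self) -> "BipartiteNetwork":
        """Drop rows/columns without any link (edge set unchanged)."""
        rmask = (self.weights > 0).any(axis=1)
        cmask = (self.weights > 0).any(axis=0)
        rows = [r for r, k in zip(self.row_ids, rmask) if k]
        cols = [c for c, k in zip(self.col_ids, cmask) if k]
        return BipartiteNetwork(
            rows,
            cols,
            self.weights[np.ix_(rmask, cmask)],
            self.sign,
            self.habitat,
            {r: p for r, p in self.row_phyla.items() if r in set(rows)},
            {c: p for c, p in self.col_phyla.items() if c in set(cols)},
            self.edges,
        )

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        rdeg = self.row_degrees()
        cdeg = self.col_degrees()
        for i, r in enumerate(self.row_ids):
            g.add_node(
                r,
                bipartite=0,
                guild="microeukaryote",
                phylum=self.row_phyla.get(r, "unclassified"),
                degree=int(rdeg[i]),
            )
        for j, c in enumerate(self.col_ids):
            g.add_node(
                c,
                bipartite=1,
                guild="bacteria",
                phylum=self.col_phyla.get(c, "unclassified"),
                degree=int(cdeg[j]),
            )
        sgn = 1.0 if self.sign == "positive" else -1.0
        lookup = {}
        if self.edges is not None:
            for rec in self.edges.itertuples(index=False):
                lookup[(rec.source, rec.target)] = rec
        for i, r in enumerate(self.row_ids):
            for j, c in enumerate(self.col_ids):
                w = self.weights[i, j]
                if w > 0:
                    rec = lookup.get((r, c))
                    g.add_edge(
                        r,
                        c,
                        weight=float(w),
                        rho=float(rec.rho) if rec is not None else sgn * float(w),
                        p=float(rec.p) if rec is not None else float("nan"),
                        sign=self.sign,
                    )
        return g


def extract_cross_kingdom(
    edges: pd.DataFrame, euk_ids, bact_ids
) -> pd.DataFrame:
    """Keep only edges with one microeukaryote and one bacterial endpoint.

    Endpoints are reordered so ``source`` is always the microeukaryote.
    """
    euk = set(euk_ids)
    bact = set(bact_ids)
    rows = []
    for rec in edges.itertuples(index=False):
        a, b = rec.source, rec.target
        for x in (a, b):
            if x not in euk and x not in bact:
                raise ValueError(f"node {x!r} has unknown kingdom")
        if a in euk and b in bact:
            rows.append((a, b, rec.rho, rec.p, rec.sign))
        elif b in euk and a in bact:
            rows.append((b, a, rec.rho, rec.p, rec.sign))
    return pd.DataFrame(rows, columns=["source", "target", "rho", "p", "sign"])


def split_by_sign(
    edges: pd.DataFrame,
    habitat: str = "",
    row_phyla: dict[str, str] | None = None,
    col_phyla: dict[str, str] | None = None,
) -> tuple[BipartiteNetwork, BipartiteNetwork]:
    """Split a cross-kingdom edge list into positive and negative networks.

    Weights are ``|rho|``; nodes isolated within a sign are absent from that
    network, so an OTU with links of both signs appears in both.
    """
    if (edges["rho"] == 0).any():
        raise ValueError("edges must have nonzero rho")
    nets = []
    for sign in ("positive", "negative"):
        sub = edges[edges["rho"] > 0] if sign == "positive" else edges[edges["rho"] < 0]
        rows = list(dict.fromkeys(sub["source"]))
        cols = list(dict.fromkeys(sub["target"]))
        w = np.zeros((len(rows), len(cols)))
        ri = {r: i for i, r in enumerate(rows)}
        ci = {c: j for j, c in enumerate(cols)}
        for rec in sub.itertuples(index=False):
            w[ri[rec.source], ci[rec.target]] = abs(rec.rho)
        net = BipartiteNetwork(
            rows,
            cols,
            w,
            sign,
            habitat,
            {r: (row_phyla or {}).get(r, "unclassified") for r in rows},
            {c: (col_phyla or {}).get(c, "unclassified") for c in cols},
            sub.reset_index(drop=True),
        )
        nets.append(net)
    return nets[0], nets[1]


@dataclass
class CoreTaxaSummary:
    """Core taxa (nodes with links of both signs) and their degree symmetry.

    ``asymmetry = (d_pos - d_neg) / (d_pos + d_neg)`` per core node, in
    [-1, 1]; 0 means perfectly balanced positive and negative degrees.
    ``coverage`` is the fraction of all degrees (both networks pooled)
    incident to a core node, overall and per guild.
    """

    core_rows: list[str]
    core_cols: list[str]
    node_table: pd.DataFrame
    coverage: float
    coverage_rows: float
    coverage_cols: float


def core_taxa(pos: BipartiteNetwork, neg: BipartiteNetwork) -> CoreTaxaSummary:
    """Identify nodes present in both the positive and negative networks."""
    dpos = dict(zip(pos.row_ids, pos.row_degrees()))
    dpos.update(zip(pos.col_ids, pos.col_degrees()))
    dneg = dict(zip(neg.row_ids, neg.row_degrees()))
    dneg.update(zip(neg.col_ids, neg.col_degrees()))

    core_rows = sorted(set(pos.row_ids) & set(neg.row_ids))
    core_cols = sorted(set(pos.col_ids) & set(neg.col_ids))
    records = []
    phyla = {**pos.row_phyla, **pos.col_phyla, **neg.row_phyla, **neg.col_phyla}
    for guild, ids in (("microeukaryote", core_rows), ("bacteria", core_cols)):
        for n in ids:
            dp, dn = int(dpos.get(n, 0)), int(dneg.get(n, 0))
            records.append(
                {
                    "otu_id": n,
                    "guild": guild,
                    "phylum": phyla.get(n, "unclassified"),
                    "d_pos": dp,
                    "d_neg": dn,
                    "asymmetry": (dp - dn) / (dp + dn) if dp + dn else 0.0,
                }
            )
    table = pd.DataFrame(
        records, columns=["otu_id", "guild", "phylum", "d_pos", "d_neg", "asymmetry"]
    )

    def _coverage(core: set[str], nodes_deg: list[tuple[str, int]]) -> tuple[float, float]:
        tot = sum(d for _, d in nodes_deg)
        cov = sum(d for n, d in nodes_deg if n in core)
        return cov, tot

    core = set(core_rows) | set(core_cols)
    row_nodes = [(n, int(dpos.get(n, 0)) + int(dneg.get(n, 0))) for n in set(pos.row_ids) | set(neg.row_ids)]
    col_nodes = [(n, int(dpos.get(n, 0)) + int(dneg.get(n, 0))) for n in set(pos.col_ids) | set(neg.col_ids)]
    cr, tr = _coverage(core, row_nodes)
    cc, tc = _coverage(core, col_nodes)
    return CoreTaxaSummary(
        core_rows,
        core_cols,
        table,
        (cr + cc) / (tr + tc) if tr + tc else 0.0,
        cr / tr if tr else 0.0,
        cc / tc if tc else 0.0,
    )


def phylum_summary(
    net: BipartiteNetwork, taxonomy: TaxonomyTable | None = None
) -> pd.DataFrame:
    """Per-phylum node and degree percentages within each guild.

    Percentages sum to 100 within each guild. Phylum labels come from the
    network's own metadata, overridden by ``taxonomy`` when given; missing
    labels are reported as "unclassified".
    """
    records = []
    for guild, ids, degs, phyla in (
        ("microeukaryote", net.row_ids, net.row_degrees(), net.row_phyla),
        ("bacteria", net.col_ids, net.col_degrees(), net.col_phyla),
    ):
        if not ids:
            continue
        lab = []
        for n in ids:
            if taxonomy is not None and n in taxonomy.lineages:
                lab.append(taxonomy.phylum(n))
            else:
                lab.append(phyla.get(n, "unclassified"))
        df = pd.DataFrame({"phylum": lab, "degree": degs})
        agg = df.groupby("phylum").agg(nodes=("degree", "size"), degree=("degree", "sum"))
        agg["node_pct"] = 100.0 * agg["nodes"] / agg["nodes"].sum()
        agg["degree_pct"] = 100.0 * agg["degree"] / max(agg["degree"].sum(), 1)
        agg = agg.reset_index()
        agg.insert(0, "guild", guild)
        records.append(agg)
    return (
        pd.concat(records, ignore_index=True)
        if records
        else pd.DataFrame(columns=["guild", "phylum", "nodes", "degree", "node_pct", "degree_pct"])
    )


def export_graphml(net: BipartiteNetwork, path) -> None:
    """Write the network as GraphML (Gephi-compatible node/edge attributes)."""
    nx.write_graphml(net.to_networkx(), path)


def read_graphml(path) -> nx.Graph:
    return nx.read_graphml(path)
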