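"""Barber bipartite modularity, weighted label propagation, and z-c node roles.

Barber's modularity for a bipartite weight matrix A with row/column module
labels g, h is

    Q = (1/m) * sum_{i,j: g_i = h_j} (A_ij - k_i * d_j / m)

with m the total weight and k, d the row/column marginal strengths. Modules
are found with weighted label propagation on the two guilds alternately
(LPAwb+), keeping only label moves that increase Q, with multiple restarts
from varied initial module counts (DIRTLPAwb+).

Node topological roles follow the within-module degree z-score and
among-module connectivity c (participation coefficient), with the classic
thresholds z = 2.5 and c = 0.62 separating peripherals, connectors, module
hubs and network hubs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bipartite import BipartiteNetwork

Z_THRESHOLD = 2.5
C_THRESHOLD = 0.62


@dataclass
class ModulePartition:
    """Module labels for both guilds (shared label space) and their Barber Q."""

    row_labels: np.ndarray
    col_labels: np.ndarray
    q: float

    @property
    def n_modules(self) -> int:
        return len(set(self.row_labels) | set(self.col_labels))

    def relabelled(self) -> "ModulePartition":
        """Consecutive integer labels starting at 0, in first-seen order."""
        seen: dict[int, int] = {}
        out = []
        for lab in list(self.row_labels) + list(self.col_labels):
            if lab not in seen:
                seen[lab] = len(seen)
            out.append(seen[lab])
        r = len(self.row_labels)
        return ModulePartition(np.array(out[:r]), np.array(out[r:]), self.q)


def _weights(net) -> np.ndarray:
    if isinstance(net, BipartiteNetwork):
        return net.weights
    return np.asarray(net, dtype=float)


def barber_q(net, row_labels, col_labels) -> float:
    """Barber's bipartite modularity of a given partition."""
    w = _weights(net)
    row_labels = np.asarray(row_labels)
    col_labels = np.asarray(col_labels)
    m = w.sum()
    if m <= 0:
        raise ValueError("total weight must be positive")
    k = w.sum(axis=1)
    d = w.sum(axis=0)
    q = 0.0
    for lab in set(row_labels) | set(col_labels):
        rmask = row_labels == lab
        cmask = col_labels == lab
        e = w[np.ix_(rmask, cmask)].sum()
        q += e / m - (k[rmask].sum() * d[cmask].sum()) / m**2
    return float(q)


def _sweep(w, row_labels, col_labels, rng) -> None:
    """One in-place label-propagation sweep over both guilds."""
    m = w.sum()
    k = w.sum(axis=1)
    d = w.sum(axis=0)
    for guild in ("rows", "cols"):
        if guild == "rows":
            own, other = row_labels, col_labels
            mat, marg_own, marg_other = w, k, d
        else:
            own, other = col_labels, row_labels
            mat, marg_own, marg_other = w.T, d, k
        order = rng.permutation(len(own))
        # strength of the other guild per label
        for i in order:
            nbr = mat[i] > 0
            if not nbr.any():
                continue
            cand = np.unique(other[nbr])
            scores = np.array(
                [
                    mat[i, other == lab].sum()
                    - marg_own[i] * marg_other[other == lab].sum() / m
                    for lab in cand
                ]
            )
            best = scores.max()
            cur = own[i]
            at_cur = scores[cand == cur]
            # keep the current label on ties for stability
            if not (at_cur.size and at_cur[0] >= best - 1e-12):
                own[i] = cand[int(np.argmax(scores))]


def lpawb_plus(net, seed=None, init_modules: int | None = None) -> ModulePartition:
    """Weighted label propagation (LPAwb+) maximizing Barber Q.

    Rows start in singleton modules (or ``init_modules`` random labels);
    columns adopt the label of their strongest row partner; guilds are then
    swept alternately, each node taking the neighbouring label with the best
    modularity gain, until Q stops improving. Deterministic under ``seed``.
    """
    w = _weights(net)
    r, c = w.shape
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if init_modules is None:
        row_labels = np.arange(r)
    else:
        row_labels = rng.integers(0, max(init_modules, 1), size=r)
    col_labels = np.empty(c, dtype=int)
    for j in range(c):
        col = w[:, j]
        col_labels[j] = row_labels[int(np.argmax(col))] if col.any() else r + j

    q = barber_q(w, row_labels, col_labels)
    for _ in range(200):
        _sweep(w, row_labels, col_labels, rng)
        q_new = barber_q(w, row_labels, col_labels)
        if q_new <= q + 1e-12:
            q = max(q, q_new)
            break
        q = q_new
    return ModulePartition(row_labels, col_labels, q).relabelled()


def dirt_lpawb_plus(net, n_restarts: int = 10, seed=None) -> ModulePartition:
    """Best-Q LPAwb+ partition over restarts with varied initial module counts."""
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    w = _weights(net)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_restarts)
    best: ModulePartition | None = None
    for r_idx in range(n_restarts):
        rng = np.random.default_rng(children[r_idx])
        init = None if r_idx == 0 else 2 + (r_idx - 1) % max(min(w.shape), 2)
        part = lpawb_plus(w, seed=rng, init_modules=init)
        if best is None or part.q > best.q:
            best = part
    return best


def node_roles(net, partition: ModulePartition) -> pd.DataFrame:
    """Classify nodes by within-module degree z and among-module connectivity c.

    z is the z-score of a node's number of links to its own module, taken over
    all nodes (both guilds) of that module (population sd; sd = 0 gives z = 0).
    c = 1 - sum_t (k_it / k_i)**2 over modules t. Roles: module hub
    (z > 2.5, c <= 0.62), network hub (z > 2.5, c > 0.62), connector
    (z <= 2.5, c > 0.62), peripheral (z <= 2.5, c <= 0.62). Degrees are
    binary link counts.
    """
    w = _weights(net)
    b = (w > 0).astype(int)
    r, c_n = b.shape
    row_lab = np.asarray(partition.row_labels)
    col_lab = np.asarray(partition.col_labels)
    labels = sorted(set(row_lab) | set(col_lab))

    row_ids = net.row_ids if isinstance(net, BipartiteNetwork) else [f"R{i}" for i in range(r)]
    col_ids = net.col_ids if isinstance(net, BipartiteNetwork) else [f"C{j}" for j in range(c_n)]

    # links from each node into each module (partners live in the other guild)
    row_to_mod = np.stack([b[:, col_lab == lab].sum(axis=1) for lab in labels], axis=1)
    col_to_mod = np.stack([b.T[:, row_lab == lab].sum(axis=1) for lab in labels], axis=1)
    lab_index = {lab: t for t, lab in enumerate(labels)}

    within_row = row_to_mod[np.arange(r), [lab_index[l] for l in row_lab]]
    within_col = col_to_mod[np.arange(c_n), [lab_index[l] for l in col_lab]]

    z_row = np.zeros(r)
    z_col = np.zeros(c_n)
    for lab in labels:
        members = np.concatenate([within_row[row_lab == lab], within_col[col_lab == lab]])
        if members.size == 0:
            continue
        mu, sd = members.mean(), members.std()
        if sd > 0:
            z_row[row_lab == lab] = (within_row[row_lab == lab] - mu) / sd
            z_col[col_lab == lab] = (within_col[col_lab == lab] - mu) / sd

    def _c(to_mod: np.ndarray) -> np.ndarray:
        k = to_mod.sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = np.where(k[:, None] > 0, to_mod / np.maximum(k[:, None], 1), 0.0)
        return 1.0 - (frac**2).sum(axis=1)

    c_row = _c(row_to_mod)
    c_col = _c(col_to_mod)

    records = []
    for guild, ids, lab, zz, cc, deg in (
        ("microeukaryote", row_ids, row_lab, z_row, c_row, b.sum(axis=1)),
        ("bacteria", col_ids, col_lab, z_col, c_col, b.sum(axis=0)),
    ):
        for i, node in enumerate(ids):
            records.append(
                {
                    "otu_id": node,
                    "guild": guild,
                    "module": int(lab[i]),
                    "degree": int(deg[i]),
                    "z": float(zz[i]),
                    "c": float(cc[i]),
                    "role": classify_role(zz[i], cc[i]),
                }
            )
    return pd.DataFrame(records, columns=["otu_id", "guild", "module", "degree", "z", "c", "role"])


def classify_role(z: float, c: float) -> str:
    """Map a (z, c) pair to its topological role."""
    if z > Z_THRESHOLD:
        return "module hub" if c <= C_THRESHOLD else "network hub"
    return "connector" if c > C_THRESHOLD else "peripheral"
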