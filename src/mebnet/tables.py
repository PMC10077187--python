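"""OTU count tables and taxonomy: reading, writing, prevalence filtering, rarefaction.

Count tables are OTUs x samples matrices of non-negative integers, tagged with
the kingdom they describe (``"bacteria"`` for 16S-derived tables,
``"microeukaryote"`` for 18S). Taxonomy maps each OTU id to a ranked lineage
(kingdom, phylum, class, order, family, genus).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

KINGDOMS = ("bacteria", "microeukaryote")

#: ranks expected in a lineage, outermost first
LINEAGE_RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")


@dataclass
class OtuTable:
    """An OTU abundance table for one kingdom.

    Parameters
    ----------
    otu_ids : list of str
        Unique OTU identifiers, one per row of ``counts``.
    sample_ids : list of str
        Unique sample identifiers, one per column of ``counts``.
    counts : ndarray of int, shape (n_otus, n_samples)
        Non-negative read counts.
    kingdom : {"bacteria", "microeukaryote"}
    """

    otu_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    kingdom: str

    def __post_init__(self) -> None:
        self.otu_ids = [str(x) for x in self.otu_ids]
        self.sample_ids = [str(x) for x in self.sample_ids]
        if self.kingdom not in KINGDOMS:
            raise ValueError(f"kingdom must be one of {KINGDOMS}, got {self.kingdom!r}")
        if len(set(self.otu_ids)) != len(self.otu_ids):
            raise ValueError("duplicate OTU ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.otu_ids), len(self.sample_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.otu_ids)} OTUs x {len(self.sample_ids)} samples"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            rounded = np.rint(self.counts)
            if not np.allclose(self.counts, rounded):
                raise ValueError("counts must be integers")
            self.counts = rounded.astype(np.int64)
        if (self.counts < 0).any():
            i, j = np.argwhere(self.counts < 0)[0]
            raise ValueError(
                f"negative count at OTU {self.otu_ids[i]!r}, sample {self.sample_ids[j]!r}"
            )

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.otu_ids, columns=self.sample_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, kingdom: str) -> "OtuTable":
        return cls(list(df.index), list(df.columns), df.to_numpy(), kingdom)

    def select_otus(self, mask_or_ids) -> "OtuTable":
        """Return a new table restricted to the given OTUs (mask or id list)."""
        if isinstance(mask_or_ids, np.ndarray) and mask_or_ids.dtype == bool:
            idx = np.flatnonzero(mask_or_ids)
        else:
            pos = {o: i for i, o in enumerate(self.otu_ids)}
            idx = np.array([pos[o] for o in mask_or_ids], dtype=int)
        return OtuTable(
            [self.otu_ids[i] for i in idx],
            list(self.sample_ids),
            self.counts[idx],
            self.kingdom,
        )


@dataclass
class TaxonomyTable:
    """OTU id -> ranked lineage mapping.

    Lineages are tuples of at least two ranks; an empty phylum is replaced by
    the sentinel ``"unclassified"``.
    """

    lineages: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, tuple[str, ...]] = {}
        for otu, lin in self.lineages.items():
            lin = tuple(str(x).strip() for x in lin)
            if len(lin) < 2:
                raise ValueError(f"lineage for {otu!r} has fewer than 2 ranks")
            if lin[1] == "":
                lin = (lin[0], "unclassified") + lin[2:]
            clean[str(otu)] = lin
        self.lineages = clean

    def phylum(self, otu_id: str) -> str:
        lin = self.lineages.get(otu_id)
        if lin is None or len(lin) < 2 or not lin[1]:
            return "unclassified"
        return lin[1]

    def __len__(self) -> int:
        return len(self.lineages)

    @classmethod
    def read(cls, path) -> "TaxonomyTable":
        """Read a two-column TSV: otu_id <tab> semicolon-delimited lineage."""
        lineages = {}
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                otu, _, lin = line.partition("\t")
                lineages[otu] = tuple(p.strip() for p in lin.split(";"))
        return cls(lineages)

    def write(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("#OTU_ID\tlineage\n")
            for otu, lin in self.lineages.items():
                fh.write(f"{otu}\t{';'.join(lin)}\n")


def read_otu_table(path, kingdom: str) -> OtuTable:
    """Read a tab-separated OTU table (first column OTU id, header = sample ids)."""
    df = pd.read_csv(path, sep="\t", header=0, index_col=0, comment=None)
    if df.shape[0] == 0:
        raise ValueError("no OTUs in table")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate OTU id {dup!r}")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any():
            row = df.index[coerced.isna()][0]
            raise ValueError(f"non-numeric count at OTU {row!r}, sample {col!r}")
        df[col] = coerced
    return OtuTable.from_dataframe(df, kingdom)


def write_otu_table(table: OtuTable, path) -> None:
    """Write the canonical TSV format (``#OTU_ID`` header)."""
    df = table.to_dataframe()
    df.index.name = "#OTU_ID"
    df.to_csv(path, sep="\t")


def prevalence_filter(table: OtuTable, min_fraction: float = 0.5) -> OtuTable:
    """Keep OTUs detected (count > 0) in at least ``ceil(min_fraction * n_samples)`` samples.

    With the study's 48 samples and the default 0.5, an OTU must be present in
    at least 24 samples to be kept.
    """
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    min_samples = int(np.ceil(min_fraction * table.n_samples))
    occupancy = (table.counts > 0).sum(axis=1)
    mask = occupancy >= min_samples
    if not mask.any():
        warnings.warn("prevalence filter removed every OTU", stacklevel=2)
    return table.select_otus(mask)


def rarefy(table: OtuTable, depth: int, seed: int | None = None) -> OtuTable:
    """Rarefy each sample to ``depth`` reads by subsampling without replacement.

    Uses multivariate hypergeometric draws per sample so each output column
    sums exactly to ``depth``.
    """
    depth = int(depth)
    if depth <= 0:
        raise ValueError("depth must be positive")
    totals = table.counts.sum(axis=0)
    low = np.flatnonzero(totals < depth)
    if low.size:
        s = table.sample_ids[low[0]]
        raise ValueError(
            f"depth {depth} exceeds total count {totals[low[0]]} of sample {s!r}"
        )
    rng = np.random.default_rng(seed)
    out = np.empty_like(table.counts)
    for j in range(table.n_samples):
        col = table.counts[:, j]
        if totals[j] == depth:
            out[:, j] = col
        else:
            out[:, j] = rng.multivariate_hypergeometric(col, depth)
    return OtuTable(list(table.otu_ids), list(table.sample_ids), out, table.kingdom)


def align_samples(a: OtuTable, b: OtuTable) -> tuple[OtuTable, OtuTable]:
    """Restrict two tables to their shared samples, in a's order for both."""
    shared = [s for s in a.sample_ids if s in set(b.sample_ids)]
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared samples (need >= 3)")

    def _take(t: OtuTable) -> OtuTable:
        pos = {s: i for i, s in enumerate(t.sample_ids)}
        idx = [pos[s] for s in shared]
        return OtuTable(list(t.otu_ids), shared, t.counts[:, idx], t.kingdom)

    return _take(a), _take(b)
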