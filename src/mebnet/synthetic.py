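"""Synthetic paired-kingdom communities with known ground truth.

Emulates the structure of a paired 16S/18S amplicon survey of aquaculture
ponds: 48 paired samples, log-normally distributed basis abundances, and
compositional counts drawn multinomially at a fixed sequencing depth per
kingdom. Signed inter-kingdom associations are planted as correlations in
the latent (basis log-abundance) covariance, which is exactly the scale on
which the SparCC estimator operates, so "planted correlation" is
well-defined and downstream edge recovery can be scored against it.

Also provides deterministic incidence-matrix fixtures: perfectly nested
staircases (for nestedness metrics) and block-diagonal modular matrices
(for modularity optimizers).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import OtuTable

# Representative phylum frequencies (percent of nodes per guild) for coastal
# aquaculture pond communities; used to draw synthetic taxonomy labels.
BACTERIAL_PHYLUM_PCT = {
    "Proteobacteria": 34.3,
    "Bacteroidetes": 13.5,
    "Actinobacteria": 14.0,
    "Cyanobacteria": 14.0,
    "Planctomycetes": 8.3,
    "Chloroflexi": 4.2,
    "Verrucomicrobia": 3.7,
    "Patescibacteria": 2.7,
    "Firmicutes": 1.2,
    "Acidobacteria": 0.2,
    "Spirochaetes": 0.2,
    "Epsilonbacteraeota": 0.2,
    "unclassified": 3.5,
}

MICROEUKARYOTE_PHYLUM_PCT = {
    "Chlorophyta": 23.5,
    "Ciliophora": 14.5,
    "Fungi": 13.5,
    "Ochrophyta": 12.5,
    "Cercozoa": 8.0,
    "Cryptophyta": 8.0,
    "Stramenopiles X": 5.0,
    "Dinoflagellata": 2.5,
    "Choanoflagellida": 1.5,
    "Apicomplexa": 1.5,
    "Conosa": 1.0,
    "Centroheliozoa": 0.5,
    "unclassified": 8.0,
}


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic paired-kingdom community.

    ``planted_edges`` is a list of ``(euk_index, bact_index, sign, magnitude)``
    with sign in {+1, -1} and magnitude in (0, 1] on the latent basis
    log-abundance correlation scale. ``depth_eukaryotes``/``depth_bacteria``
    are per-sample sequencing depths of the two libraries.
    """

    n_samples: int = 48
    n_bacteria: int = 120
    n_eukaryotes: int = 40
    planted_edges: list[tuple[int, int, int, float]] = field(default_factory=list)
    log_mean: float = 0.0
    log_sd: float = 1.0
    depth_bacteria: int = 20000
    depth_eukaryotes: int = 20000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth_bacteria <= 0 or self.depth_eukaryotes <= 0:
            raise ValueError("sequencing depth must be positive")
        seen = set()
        norm = []
        for e, b, s, mag in self.planted_edges:
            s = 1 if s in (1, "+", "positive") else -1 if s in (-1, "-", "negative") else s
            if s not in (1, -1):
                raise ValueError(f"sign must be +1 or -1, got {s!r}")
            if not 0 < mag <= 1:
                raise ValueError("planted correlation magnitude must be in (0, 1]")
            if not (0 <= e < self.n_eukaryotes and 0 <= b < self.n_bacteria):
                raise ValueError(f"planted edge ({e},{b}) references a missing OTU")
            if (e, b) in seen:
                raise ValueError(f"duplicate planted pair ({e},{b})")
            seen.add((e, b))
            norm.append((int(e), int(b), int(s), float(mag)))
        self.planted_edges = norm

    @classmethod
    def study_scale(cls, seed: int = 0) -> "SyntheticSpec":
        """The surveyed community's scale: 48 paired samples, post-filter OTU
        richness of the water habitat (1210 bacterial, 406 microeukaryotic
        OTUs) and the study's rarefaction depths (49,706 / 31,781)."""
        return cls(
            n_samples=48,
            n_bacteria=1210,
            n_eukaryotes=406,
            depth_bacteria=49706,
            depth_eukaryotes=31781,
            seed=seed,
        )

    @classmethod
    def benchmark(cls, seed: int = 0, magnitude: float = 0.9) -> "SyntheticSpec":
        """Edge-recovery benchmark conditions: 200 samples, strong planted
        associations (|r| = 0.9 on the basis scale), 20 + 40 OTUs and a
        sequencing depth of 50 reads per OTU."""
        rng = np.random.default_rng(seed)
        edges = plant_random_edges(
            n_eukaryotes=20, n_bacteria=40, n_positive=8, n_negative=4,
            magnitude=magnitude, rng=rng,
        )
        return cls(
            n_samples=200,
            n_bacteria=40,
            n_eukaryotes=20,
            planted_edges=edges,
            depth_bacteria=3000,
            depth_eukaryotes=3000,
            seed=seed,
        )


@dataclass
class GroundTruth:
    """Planted inter-kingdom associations and synthetic taxonomy labels."""

    planted_edges: list[tuple[str, str, int, float]]
    euk_phyla: dict[str, str]
    bact_phyla: dict[str, str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.planted_edges, columns=["euk_id", "bact_id", "sign", "magnitude"]
        )

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def plant_random_edges(
    n_eukaryotes: int,
    n_bacteria: int,
    n_positive: int,
    n_negative: int,
    magnitude: float = 0.9,
    rng: np.random.Generator | None = None,
) -> list[tuple[int, int, int, float]]:
    """Choose disjoint (euk, bact) pairs and assign signed correlations.

    Pairs are node-disjoint so the planted covariance stays positive-definite
    for any magnitude below 1.
    """
    rng = rng or np.random.default_rng()
    n_edges = n_positive + n_negative
    if n_edges > min(n_eukaryotes, n_bacteria):
        raise ValueError("not enough OTUs for node-disjoint planted edges")
    euks = rng.permutation(n_eukaryotes)[:n_edges]
    bacts = rng.permutation(n_bacteria)[:n_edges]
    signs = [1] * n_positive + [-1] * n_negative
    return [
        (int(e), int(b), s, float(magnitude))
        for e, b, s in zip(euks, bacts, signs)
    ]


def _sample_phyla(n: int, pct: dict[str, float], rng: np.random.Generator) -> list[str]:
    names = list(pct)
    p = np.array([pct[k] for k in names], dtype=float)
    p /= p.sum()
    return [names[i] for i in rng.choice(len(names), size=n, p=p)]


def generate_community(spec: SyntheticSpec) -> tuple[OtuTable, OtuTable, GroundTruth]:
    """Draw paired kingdom count tables from the log-normal/multinomial model.

    Basis log-abundances are multivariate normal with the planted signed
    correlations embedded in the (otherwise diagonal) covariance; per-sample
    counts are multinomial at the kingdom's sequencing depth on the closed
    basis abundances. Reproducible under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n_e, n_b = spec.n_eukaryotes, spec.n_bacteria
    p = n_e + n_b

    corr = np.eye(p)
    for e, b, s, mag in spec.planted_edges:
        corr[e, n_e + b] = corr[n_e + b, e] = s * mag
    sd = np.full(p, float(spec.log_sd))
    cov = corr * np.outer(sd, sd)
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "planted covariance is not positive-definite; lower the planted "
            "correlation magnitudes or use fewer edges per OTU"
        ) from exc

    z = rng.standard_normal((spec.n_samples, p)) @ chol.T + spec.log_mean
    basis = np.exp(z)  # samples x OTUs

    euk_ids = [f"Euk_{i:04d}" for i in range(n_e)]
    bact_ids = [f"Bact_{i:04d}" for i in range(n_b)]

    def _counts(block: np.ndarray, depth: int) -> np.ndarray:
        frac = block / block.sum(axis=1, keepdims=True)
        out = np.empty((block.shape[1], block.shape[0]), dtype=np.int64)
        for s in range(block.shape[0]):
            out[:, s] = rng.multinomial(depth, frac[s])
        return out

    euk_counts = _counts(basis[:, :n_e], spec.depth_eukaryotes)
    bact_counts = _counts(basis[:, n_e:], spec.depth_bacteria)
    sample_ids = [f"S{j:02d}" for j in range(spec.n_samples)]

    euk_table = OtuTable(euk_ids, sample_ids, euk_counts, "microeukaryote")
    bact_table = OtuTable(bact_ids, sample_ids, bact_counts, "bacteria")

    truth = GroundTruth(
        planted_edges=[
            (euk_ids[e], bact_ids[b], s, mag) for e, b, s, mag in spec.planted_edges
        ],
        euk_phyla=dict(zip(euk_ids, _sample_phyla(n_e, MICROEUKARYOTE_PHYLUM_PCT, rng))),
        bact_phyla=dict(zip(bact_ids, _sample_phyla(n_b, BACTERIAL_PHYLUM_PCT, rng))),
    )
    return euk_table, bact_table, truth


def generate_nested_incidence(n_rows: int, n_cols: int, fill: float) -> np.ndarray:
    """A left-filled staircase with strictly decreasing row fills.

    Row fills are proportional to a triangular profile scaled so the matrix
    fill matches ``fill`` as closely as integer, strictly decreasing fills
    allow. The canonical square maximal staircase (e.g. 3x3 at fill 2/3) is
    perfectly nested with NODF = 100.
    """
    if n_rows < 2:
        raise ValueError("need at least 2 rows (no row pairs otherwise)")
    if n_cols < 2:
        raise ValueError("need at least 2 columns")
    if not 0 < fill <= 1:
        raise ValueError("fill must be in (0, 1]")
    if n_cols < n_rows:
        raise ValueError(
            "strictly decreasing row fills need n_cols >= n_rows"
        )
    target = fill * n_rows * n_cols
    weights = np.arange(n_rows, 0, -1, dtype=float)
    fills = np.rint(target * weights / weights.sum()).astype(int)
    fills = np.clip(fills, 1, n_cols)
    # enforce strict decrease bottom-up
    for i in range(n_rows - 2, -1, -1):
        fills[i] = max(fills[i], fills[i + 1] + 1)
    if fills[0] > n_cols:
        raise ValueError(
            f"fill {fill} infeasible for a strictly nested {n_rows}x{n_cols} matrix"
        )
    out = np.zeros((n_rows, n_cols), dtype=int)
    for i, f in enumerate(fills):
        out[i, :f] = 1
    return out


def generate_modular_incidence(
    blocks: int, block_rows: int, block_cols: int
) -> np.ndarray:
    """Block-diagonal complete bipartite blocks with no inter-block links."""
    if blocks < 2:
        raise ValueError("need at least 2 blocks")
    if block_rows < 1 or block_cols < 1:
        raise ValueError("block dimensions must be positive")
    return np.kron(np.eye(blocks, dtype=int), np.ones((block_rows, block_cols), dtype=int))


def modular_block_labels(
    blocks: int, block_rows: int, block_cols: int
) -> tuple[np.ndarray, np.ndarray]:
    """Ground-truth module labels matching ``generate_modular_incidence``."""
    return (
        np.repeat(np.arange(blocks), block_rows),
        np.repeat(np.arange(blocks), block_cols),
    )
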