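"""Model/Results interface for the cross-kingdom co-occurrence analysis.

``CrossKingdomInteractions`` wraps a pair of prepared OTU tables (one per
kingdom, same samples); ``fit()`` runs the SparCC estimator on the pooled
counts, bootstraps p-values, applies the edge thresholds (|rho| > 0.6 and
p < 0.05 by default), extracts the inter-kingdom edges and splits them into
the positive and negative bipartite networks. The returned
``CrossKingdomResults`` exposes the downstream analyses — topology metrics,
nestedness significance, modularity and node roles, core-taxa symmetry, and
co-extinction robustness — as methods, plus a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import bipartite, metrics, modularity, nestedness, robustness, sparcc
from .bipartite import BipartiteNetwork
from .sparcc import CorrelationEstimate, SignificanceResult
from .tables import OtuTable, TaxonomyTable, align_samples, prevalence_filter, rarefy


class CrossKingdomInteractions:
    """Co-occurrence model between a microeukaryote and a bacterial OTU table.

    Parameters
    ----------
    euk_table, bact_table : OtuTable
        Prepared (filtered/rarefied) tables sharing a sample set; samples are
        aligned at construction.
    taxonomy : TaxonomyTable or dict, optional
        OTU -> phylum labels for reporting. A plain dict is interpreted as
        otu_id -> phylum.
    habitat : str
        Free-text label (e.g. "water", "sediment") carried into the networks.
    """

    def __init__(
        self,
        euk_table: OtuTable,
        bact_table: OtuTable,
        taxonomy=None,
        habitat: str = "",
    ) -> None:
        if euk_table.kingdom != "microeukaryote" or bact_table.kingdom != "bacteria":
            raise ValueError(
                "expected a microeukaryote table and a bacteria table, got "
                f"{euk_table.kingdom!r} and {bact_table.kingdom!r}"
            )
        overlap = set(euk_table.otu_ids) & set(bact_table.otu_ids)
        if overlap:
            raise ValueError(f"OTU ids shared between kingdoms: {sorted(overlap)[:3]}")
        self.euk_table, self.bact_table = align_samples(euk_table, bact_table)
        self.habitat = habitat
        if isinstance(taxonomy, TaxonomyTable):
            ids = euk_table.otu_ids + bact_table.otu_ids
            self.phyla = {o: taxonomy.phylum(o) for o in ids if o in taxonomy.lineages}
        elif isinstance(taxonomy, dict):
            self.phyla = dict(taxonomy)
        else:
            self.phyla = {}

    @classmethod
    def from_counts(
        cls,
        euk_table: OtuTable,
        bact_table: OtuTable,
        taxonomy=None,
        habitat: str = "",
        prevalence: float | None = 0.5,
        rarefy_depth: tuple[int | None, int | None] = (None, None),
        rarefy_first: bool = True,
        seed: int | None = None,
    ) -> "CrossKingdomInteractions":
        """Build a model from raw tables, applying rarefaction and the
        prevalence filter (rarefy-then-filter by default)."""
        ss = np.random.SeedSequence(seed)
        seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(2)]

        def _prepare(t: OtuTable, depth, sd):
            steps = []
            if rarefy_first and depth:
                steps.append(lambda x: rarefy(x, depth, sd))
            if prevalence:
                steps.append(lambda x: prevalence_filter(x, prevalence))
            if not rarefy_first and depth:
                steps.append(lambda x: rarefy(x, depth, sd))
            for s in steps:
                t = s(t)
            return t

        euk = _prepare(euk_table, rarefy_depth[0], seeds[0])
        bact = _prepare(bact_table, rarefy_depth[1], seeds[1])
        return cls(euk, bact, taxonomy, habitat)

    @classmethod
    def from_synthetic(cls, spec, habitat: str = "synthetic"):
        """Generate a community from a ``SyntheticSpec``; returns
        ``(model, ground_truth)``."""
        from .synthetic import generate_community

        euk, bact, truth = generate_community(spec)
        model = cls(
            euk, bact, taxonomy={**truth.euk_phyla, **truth.bact_phyla}, habitat=habitat
        )
        return model, truth

    @property
    def pooled_counts(self) -> np.ndarray:
        return np.vstack([self.euk_table.counts, self.bact_table.counts])

    @property
    def pooled_ids(self) -> list[str]:
        return self.euk_table.otu_ids + self.bact_table.otu_ids

    def fit(
        self,
        r_threshold: float = 0.6,
        p_threshold: float = 0.05,
        n_draws: int = 20,
        n_boot: int = 100,
        pseudocount: float = 1.0,
        exclusion_threshold: float = 0.1,
        max_exclusion_rounds: int = 10,
        seed: int | None = None,
    ) -> "CrossKingdomResults":
        """Estimate SparCC correlations on the pooled table and build the
        signed bipartite networks from the significant inter-kingdom edges."""
        if not 0 < r_threshold < 1 or not 0 < p_threshold < 1:
            raise ValueError("thresholds must be in (0, 1)")
        ss = np.random.SeedSequence(seed)
        s_corr, s_boot = (int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(2))
        counts = self.pooled_counts
        ids = self.pooled_ids
        est = sparcc.dirichlet_average(
            counts,
            n_draws=n_draws,
            seed=s_corr,
            pseudocount=pseudocount,
            exclusion_threshold=exclusion_threshold,
            max_exclusion_rounds=max_exclusion_rounds,
        )
        est.otu_ids = ids
        sig = sparcc.bootstrap_pvalues(
            counts,
            est,
            n_boot=n_boot,
            seed=s_boot,
            pseudocount=pseudocount,
            exclusion_threshold=exclusion_threshold,
            max_exclusion_rounds=max_exclusion_rounds,
        )
        edges = sparcc.significant_edges(
            est.rho, sig.p, ids, r_threshold=r_threshold, p_threshold=p_threshold
        )
        cross = bipartite.extract_cross_kingdom(
            edges, self.euk_table.otu_ids, self.bact_table.otu_ids
        )
        pos, neg = bipartite.split_by_sign(
            cross, habitat=self.habitat, row_phyla=self.phyla, col_phyla=self.phyla
        )
        return CrossKingdomResults(
            model=self,
            correlations=est,
            significance=sig,
            all_edges=edges,
            cross_edges=cross,
            positive=pos,
            negative=neg,
            thresholds=(r_threshold, p_threshold),
        )


@dataclass
class CrossKingdomResults:
    """Fitted networks plus the downstream analyses of the study design."""

    model: CrossKingdomInteractions
    correlations: CorrelationEstimate
    significance: SignificanceResult
    all_edges: pd.DataFrame
    cross_edges: pd.DataFrame
    positive: BipartiteNetwork
    negative: BipartiteNetwork
    thresholds: tuple[float, float] = (0.6, 0.05)
    _cache: dict = field(default_factory=dict, repr=False)

    def network(self, sign: str = "positive") -> BipartiteNetwork:
        if sign not in ("positive", "negative"):
            raise ValueError("sign must be 'positive' or 'negative'")
        return self.positive if sign == "positive" else self.negative

    def network_metrics(self, sign: str = "positive") -> metrics.NetworkLevelMetrics:
        return metrics.network_report(self.network(sign))

    def node_metrics(self, sign: str = "positive") -> pd.DataFrame:
        return metrics.specialization_d(self.network(sign))

    def nestedness(self, sign: str = "positive", n_rand: int = 100, seed=None):
        return nestedness.nodf_significance(self.network(sign), n_rand=n_rand, seed=seed)

    def modules(
        self, sign: str = "positive", n_restarts: int = 10, seed=None
    ) -> modularity.ModulePartition:
        key = ("modules", sign, n_restarts, seed)
        if key not in self._cache:
            self._cache[key] = modularity.dirt_lpawb_plus(
                self.network(sign), n_restarts=n_restarts, seed=seed
            )
        return self._cache[key]

    def node_roles(
        self, sign: str = "positive", n_restarts: int = 10, seed=None
    ) -> pd.DataFrame:
        part = self.modules(sign, n_restarts=n_restarts, seed=seed)
        return modularity.node_roles(self.network(sign), part)

    def core_taxa(self) -> bipartite.CoreTaxaSummary:
        return bipartite.core_taxa(self.positive, self.negative)

    def phylum_summary(self, sign: str = "positive") -> pd.DataFrame:
        return bipartite.phylum_summary(self.network(sign))

    def robustness(
        self,
        sign: str = "positive",
        removed_guild: str = "rows",
        scheme: str = "random",
        n_reps: int = 100,
        seed=None,
    ) -> robustness.RobustnessResult:
        net = self.network(sign)
        if scheme == "random":
            return robustness.extinction_random(net, removed_guild, n_reps=n_reps, seed=seed)
        if scheme == "generalist_first":
            return robustness.extinction_generalist_first(
                net, removed_guild, seed=seed, n_reps=n_reps
            )
        raise ValueError("scheme must be 'random' or 'generalist_first'")

    def summary(self, n_rand: int = 100, seed=None) -> pd.DataFrame:
        """Table-style overview of both signed networks (one column each)."""
        cols = {}
        for sign in ("positive", "negative"):
            net = self.network(sign)
            if net.is_empty():
                cols[sign] = {"Nodes of microeukaryotes": 0, "Nodes of bacteria": 0}
                continue
            rep = self.network_metrics(sign)
            part = self.modules(sign, seed=seed)
            cols[sign] = {
                "Nodes of microeukaryotes": rep.n_rows,
                "Nodes of bacteria": rep.n_cols,
                "Links per species": round(rep.links_per_species, 2),
                "Degree": rep.n_links,
                "Connectance": round(rep.connectance, 2),
                "NODF": round(rep.nodf, 1),
                "Module number": part.n_modules,
                "Number of compartment": rep.n_compartments,
                "linkage density": round(rep.linkage_density, 1),
                "Shannon diversity": round(rep.interaction_shannon, 1),
                "Interaction evenness": round(rep.interaction_evenness, 2),
                "Cluster coefficient of microeukaryotes": round(
                    rep.cluster_coefficient_rows, 2
                ),
                "Cluster coefficient of bacteria": round(rep.cluster_coefficient_cols, 2),
            }
        return pd.DataFrame(cols)
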