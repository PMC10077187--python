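"""End-to-end pipeline: config parsing, stage orchestration, report bundle.

A run takes either a pair of on-disk OTU tables or a synthetic community
spec, applies rarefaction and the prevalence filter, fits the SparCC model,
and writes — per sign — metrics, nestedness nulls, module partitions and
node roles, core-taxa summaries, robustness results, GraphML exports, and a
manifest with all derived seeds. A single master seed fans out
deterministically to every stochastic stage.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .bipartite import export_graphml
from .model import CrossKingdomInteractions
from .synthetic import SyntheticSpec
from .tables import TaxonomyTable, read_otu_table, write_otu_table

log = logging.getLogger("mebnet")

SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    """Configuration of a full run (YAML-serializable key/value form)."""

    euk_table: str | None = None
    bact_table: str | None = None
    taxonomy: str | None = None
    synthetic: dict | None = None
    habitat: str = ""
    prevalence: float = 0.5
    rarefy_depth_eukaryotes: int | None = None
    rarefy_depth_bacteria: int | None = None
    rarefy_first: bool = True
    r_threshold: float = 0.6
    p_threshold: float = 0.05
    sparcc_n_draws: int = 20
    sparcc_n_boot: int = 100
    sparcc_pseudocount: float = 1.0
    sparcc_exclusion_threshold: float = 0.1
    sparcc_max_exclusion_rounds: int = 10
    null_n_rand: int = 100
    robustness_n_reps: int = 100
    robustness_signs: tuple[str, ...] = ("positive",)
    modularity_restarts: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.r_threshold < 1 or not 0 < self.p_threshold < 1:
            raise ValueError("r/p thresholds must be in (0, 1)")
        if self.synthetic is None and (self.euk_table is None or self.bact_table is None):
            raise ValueError("config needs either input tables or a synthetic spec")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "robustness_signs" in raw:
            raw["robustness_signs"] = tuple(raw["robustness_signs"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["robustness_signs"] = list(d["robustness_signs"])
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


def _stage_seeds(master: int, names: list[str]) -> dict[str, int]:
    ss = np.random.SeedSequence(master)
    return {
        n: int(s.generate_state(1)[0] % 2**31) for n, s in zip(names, ss.spawn(len(names)))
    }


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON-serializable: {type(o)}")


def _write_json(path: Path, obj) -> None:
    obj = {"schema_version": SCHEMA_VERSION, **obj}
    path.write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute every stage and write the report bundle under ``outdir``.

    Returns the manifest dict. Any stage failure aborts with a stage-named
    error message.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(
        config.seed,
        ["synthetic", "prepare", "fit", "nestedness", "modules", "robustness"],
    )
    manifest = {
        "mebnet_version": __version__,
        "master_seed": config.seed,
        "stage_seeds": seeds,
        "config": {**asdict(config), "robustness_signs": list(config.robustness_signs)},
        "stages": [],
    }

    def stage(name):
        log.info("stage: %s", name)
        manifest["stages"].append(name)

    try:
        if config.synthetic is not None:
            stage("simulate")
            spec = SyntheticSpec(**{**config.synthetic, "seed": seeds["synthetic"]})
            model, truth = CrossKingdomInteractions.from_synthetic(
                spec, habitat=config.habitat or "synthetic"
            )
            truth.write(outdir / "ground_truth.tsv")
            write_otu_table(model.euk_table, outdir / "euk_table.tsv")
            write_otu_table(model.bact_table, outdir / "bact_table.tsv")
            euk_raw, bact_raw = model.euk_table, model.bact_table
            phyla = model.phyla
            taxonomy = None
        else:
            stage("load")
            euk_raw = read_otu_table(config.euk_table, "microeukaryote")
            bact_raw = read_otu_table(config.bact_table, "bacteria")
            taxonomy = (
                TaxonomyTable.read(config.taxonomy) if config.taxonomy else None
            )
            phyla = None
    except Exception as exc:
        raise RuntimeError(f"input stage failed: {exc}") from exc

    try:
        stage("filter")
        model = CrossKingdomInteractions.from_counts(
            euk_raw,
            bact_raw,
            taxonomy=taxonomy if phyla is None else phyla,
            habitat=config.habitat,
            prevalence=config.prevalence,
            rarefy_depth=(config.rarefy_depth_eukaryotes, config.rarefy_depth_bacteria),
            rarefy_first=config.rarefy_first,
            seed=seeds["prepare"],
        )
    except Exception as exc:
        raise RuntimeError(f"filter stage failed: {exc}") from exc

    try:
        stage("sparcc")
        results = model.fit(
            r_threshold=config.r_threshold,
            p_threshold=config.p_threshold,
            n_draws=config.sparcc_n_draws,
            n_boot=config.sparcc_n_boot,
            pseudocount=config.sparcc_pseudocount,
            exclusion_threshold=config.sparcc_exclusion_threshold,
            max_exclusion_rounds=config.sparcc_max_exclusion_rounds,
            seed=seeds["fit"],
        )
        results.cross_edges.to_csv(outdir / "cross_kingdom_edges.tsv", sep="\t", index=False)
    except Exception as exc:
        raise RuntimeError(f"sparcc stage failed: {exc}") from exc

    report: dict = {"habitat": config.habitat, "networks": {}}
    for sign in ("positive", "negative"):
        net = results.network(sign)
        block: dict = {"n_links": net.n_links}
        if net.is_empty():
            report["networks"][sign] = block
            continue
        try:
            stage(f"metrics:{sign}")
            block["metrics"] = results.network_metrics(sign).to_dict()
            results.node_metrics(sign).to_csv(
                outdir / f"node_metrics_{sign}.tsv", sep="\t", index=False
            )
            results.phylum_summary(sign).to_csv(
                outdir / f"phylum_summary_{sign}.tsv", sep="\t", index=False
            )
            export_graphml(net, outdir / f"network_{sign}.graphml")
        except Exception as exc:
            raise RuntimeError(f"metrics stage ({sign}) failed: {exc}") from exc
        try:
            stage(f"nestedness:{sign}")
            if net.n_rows >= 2 and net.n_cols >= 2:
                block["nestedness"] = results.nestedness(
                    sign, n_rand=config.null_n_rand, seed=seeds["nestedness"]
                ).summary()
        except Exception as exc:
            raise RuntimeError(f"nestedness stage ({sign}) failed: {exc}") from exc
        try:
            stage(f"modules:{sign}")
            part = results.modules(
                sign, n_restarts=config.modularity_restarts, seed=seeds["modules"]
            )
            block["modularity"] = {"Q": part.q, "n_modules": part.n_modules}
            roles = results.node_roles(
                sign, n_restarts=config.modularity_restarts, seed=seeds["modules"]
            )
            roles.to_csv(outdir / f"node_roles_{sign}.tsv", sep="\t", index=False)
            block["roles"] = roles["role"].value_counts().to_dict()
        except Exception as exc:
            raise RuntimeError(f"modularity stage ({sign}) failed: {exc}") from exc
        if sign in config.robustness_signs:
            try:
                stage(f"robustness:{sign}")
                rb = {}
                for guild in ("rows", "cols"):
                    for scheme in ("random", "generalist_first"):
                        res = results.robustness(
                            sign,
                            removed_guild=guild,
                            scheme=scheme,
                            n_reps=config.robustness_n_reps,
                            seed=seeds["robustness"],
                        )
                        rb[f"{guild}_{scheme}"] = res.summary()
                block["robustness"] = rb
            except Exception as exc:
                raise RuntimeError(f"robustness stage ({sign}) failed: {exc}") from exc
        report["networks"][sign] = block

    try:
        stage("core_taxa")
        core = results.core_taxa()
        core.node_table.to_csv(outdir / "core_taxa.tsv", sep="\t", index=False)
        report["core_taxa"] = {
            "n_core_microeukaryotes": len(core.core_rows),
            "n_core_bacteria": len(core.core_cols),
            "degree_coverage": core.coverage,
            "degree_coverage_microeukaryotes": core.coverage_rows,
            "degree_coverage_bacteria": core.coverage_cols,
        }
    except Exception as exc:
        raise RuntimeError(f"core-taxa stage failed: {exc}") from exc

    _write_json(outdir / "report.json", report)
    _write_json(outdir / "manifest.json", manifest)
    return manifest


def setup_logging(verbose: bool = False) -> None:
    logging.basicConfig(
        stream=sys.stderr,
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(levelname)s %(name)s: %(message)s",
    )
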