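import json

import numpy as np
import pytest
from click.testing import CliRunner

from mebnet import CrossKingdomInteractions, SyntheticSpec
from mebnet.cli import main
from mebnet.pipeline import PipelineConfig, run_pipeline

SMALL_SYNTH = {
    "n_samples": 60,
    "n_bacteria": 15,
    "n_eukaryotes": 8,
    "planted_edges": [[0, 0, 1, 0.9], [1, 1, 1, 0.9], [2, 2, -1, 0.9]],
    "depth_bacteria": 2000,
    "depth_eukaryotes": 2000,
}


@pytest.fixture(scope="module")
def fitted():
    spec = SyntheticSpec(**{**SMALL_SYNTH, "seed": 5})
    model, truth = CrossKingdomInteractions.from_synthetic(spec)
    return model, truth, model.fit(n_draws=5, n_boot=30, seed=5)


class TestModel:
    def test_networks_contain_planted_edges(self, fitted):
        _, truth, res = fitted
        pos_pairs = {
            (truth.planted_edges[i][0], truth.planted_edges[i][1])
            for i in range(2)
        }
        got = {
            (r, c)
            for i, r in enumerate(res.positive.row_ids)
            for j, c in enumerate(res.positive.col_ids)
            if res.positive.weights[i, j] > 0
        }
        assert pos_pairs <= got

    def test_edge_conservation(self, fitted):
        _, _, res = fitted
        assert res.positive.n_links + res.negative.n_links == len(res.cross_edges)

    def test_summary_has_both_signs(self, fitted):
        _, _, res = fitted
        s = res.summary(seed=0)
        assert set(s.columns) == {"positive", "negative"}
        assert s.loc["Degree", "positive"] == res.positive.n_links

    def test_refit_deterministic(self, fitted):
        model, _, res = fitted
        res2 = model.fit(n_draws=5, n_boot=30, seed=5)
        assert np.array_equal(res.correlations.rho, res2.correlations.rho)
        assert res.cross_edges.equals(res2.cross_edges)

    def test_invalid_threshold_rejected(self, fitted):
        model, _, _ = fitted
        with pytest.raises(ValueError):
            model.fit(r_threshold=0.0)

    def test_kingdom_mismatch_rejected(self, fitted):
        model, _, _ = fitted
        with pytest.raises(ValueError, match="expected"):
            CrossKingdomInteractions(model.bact_table, model.euk_table)


class TestPipeline:
    def test_end_to_end_report_bundle(self, tmp_path):
        config = PipelineConfig(synthetic=SMALL_SYNTH, habitat="synthetic",
                                sparcc_n_draws=5, sparcc_n_boot=25,
                                null_n_rand=25, robustness_n_reps=20,
                                modularity_restarts=3, seed=11)
        run_pipeline(config, tmp_path)
        for name in [
            "report.json", "manifest.json", "cross_kingdom_edges.tsv",
            "ground_truth.tsv", "core_taxa.tsv", "euk_table.tsv", "bact_table.tsv",
        ]:
            assert (tmp_path / name).exists(), name
        report = json.loads((tmp_path / "report.json").read_text())
        assert "positive" in report["networks"]
        pos = report["networks"]["positive"]
        if pos["n_links"]:
            assert "metrics" in pos and "modularity" in pos and "robustness" in pos

    def test_rerun_identical_reports(self, tmp_path):
        config = PipelineConfig(synthetic=SMALL_SYNTH, sparcc_n_draws=3,
                                sparcc_n_boot=22, null_n_rand=20,
                                robustness_n_reps=5, modularity_restarts=2, seed=3)
        run_pipeline(config, tmp_path / "a")
        run_pipeline(config, tmp_path / "b")
        ra = (tmp_path / "a" / "report.json").read_text()
        rb = (tmp_path / "b" / "report.json").read_text()
        assert ra == rb

    def test_bad_threshold_rejected(self):
        with pytest.raises(ValueError):
            PipelineConfig(synthetic=SMALL_SYNTH, r_threshold=0.0)

    def test_missing_inputs_rejected(self):
        with pytest.raises(ValueError):
            PipelineConfig()

    def test_yaml_round_trip(self, tmp_path):
        config = PipelineConfig(synthetic=SMALL_SYNTH, seed=4)
        path = tmp_path / "c.yaml"
        config.to_yaml(path)
        back = PipelineConfig.from_yaml(path)
        assert back.seed == 4 and back.synthetic["n_samples"] == 60


class TestCli:
    def test_help_lists_subcommands(self):
        result = CliRunner().invoke(main, ["--help"])
        assert result.exit_code == 0
        for cmd in ["run", "simulate", "filter", "sparcc", "build", "metrics",
                    "nestedness", "modules", "robustness", "core", "report"]:
            assert cmd in result.output

    def test_unknown_subcommand_usage_error(self):
        result = CliRunner().invoke(main, ["frobnicate"])
        assert result.exit_code != 0
        assert "No such command" in result.output

    def test_simulate_deterministic(self, tmp_path):
        runner = CliRunner()
        for d in ("a", "b"):
            r = runner.invoke(main, [
                "simulate", "--seed", "1", "--n-samples", "12",
                "--n-bacteria", "10", "--n-eukaryotes", "6", "--depth", "500",
                "--n-positive", "2", "--n-negative", "1",
                "--outdir", str(tmp_path / d),
            ])
            assert r.exit_code == 0, r.output
        assert (tmp_path / "a" / "euk_table.tsv").read_text() == (
            tmp_path / "b" / "euk_table.tsv"
        ).read_text()
        assert (tmp_path / "a" / "ground_truth.tsv").exists()

    def test_stagewise_matches_pipeline_metrics(self, tmp_path, fitted):
        _, _, res = fitted
        edges = tmp_path / "edges.tsv"
        res.cross_edges.to_csv(edges, sep="\t", index=False)
        out = tmp_path / "metrics.json"
        r = CliRunner().invoke(main, ["metrics", str(edges), "--sign", "positive",
                                      "--out", str(out)])
        assert r.exit_code == 0, r.output
        got = json.loads(out.read_text())["metrics"]
        expect = res.network_metrics("positive").to_dict()
        assert got["n_links"] == expect["n_links"]
        assert got["nodf"] == pytest.approx(expect["nodf"])

    def test_filter_command(self, tmp_path):
        table = tmp_path / "t.tsv"
        lines = ["#OTU_ID\t" + "\t".join(f"S{i}" for i in range(4))]
        lines.append("A\t5\t5\t5\t5")
        lines.append("B\t5\t0\t0\t0")
        table.write_text("\n".join(lines) + "\n")
        out = tmp_path / "f.tsv"
        r = CliRunner().invoke(main, ["filter", str(table), "--kingdom", "bacteria",
                                      "--out", str(out)])
        assert r.exit_code == 0, r.output
        assert "A" in out.read_text() and "\nB" not in out.read_text()
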