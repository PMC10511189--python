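import json

import pandas as pd
import pytest
from click.testing import CliRunner

from optionvalue import ExperimentConfig, run_experiment
from optionvalue.cli import main as cli_main


def synth_block(**overrides):
    base = {
        "n_tips": 60,
        "n_trees": 3,
        "prevalence": {"food": 0.15, "pets": 0.3},
        "clumping": {"food": 0.0, "pets": 0.9},
        "seed": 5,
    }
    base.update(overrides)
    return base


class TestExperimentConfig:
    def test_fractions_must_increase(self):
        with pytest.raises(ValueError):
            ExperimentConfig(synth=synth_block(), fractions=[0.2, 0.1])

    def test_unknown_strategy_rejected(self):
        with pytest.raises(ValueError):
            ExperimentConfig(synth=synth_block(), strategies=["best_pd"])

    def test_inputs_required(self):
        with pytest.raises(ValueError):
            ExperimentConfig()

    def test_yaml_round_trip(self, tmp_path):
        p = tmp_path / "exp.yaml"
        import yaml

        yaml.safe_dump(
            {"synth": synth_block(), "fractions": [0.1, 0.2], "out_dir": "x"},
            p.open("w"),
        )
        cfg = ExperimentConfig.from_yaml(p)
        assert cfg.fractions == [0.1, 0.2]


class TestRunExperiment:
    def base_config(self, tmp_path, **overrides):
        kw = dict(
            out_dir=str(tmp_path / "out"),
            synth=synth_block(),
            fractions=[0.1, 0.25],
            strategies=["greedy_pd"],
            categories=["food", "pets"],
            replicates=40,
            sets_per_tree=2,
            seed=3,
        )
        kw.update(overrides)
        return ExperimentConfig(**kw)

    def test_manifest_lists_all_cells(self, tmp_path):
        cfg = self.base_config(tmp_path)
        manifest = run_experiment(cfg)
        assert len(manifest["cells"]) == 2 * 2  # fractions x categories
        report = pd.read_csv(tmp_path / "out" / "capture_report.csv")
        assert set(report["category"]) == {"food", "pets"}
        assert set(report["fraction"]) == {0.1, 0.25}
        assert {"ses", "tier", "mean", "ci_low", "ci_high"} <= set(report.columns)

    def test_rerun_is_byte_identical(self, tmp_path):
        cfg = self.base_config(tmp_path)
        run_experiment(cfg)
        report1 = (tmp_path / "out" / "capture_report.csv").read_bytes()
        manifest1 = (tmp_path / "out" / "manifest.json").read_bytes()
        run_experiment(cfg)
        assert (tmp_path / "out" / "capture_report.csv").read_bytes() == report1
        assert (tmp_path / "out" / "manifest.json").read_bytes() == manifest1

    def test_missing_input_fails_before_outputs(self, tmp_path):
        cfg = ExperimentConfig(
            out_dir=str(tmp_path / "out"),
            trees=str(tmp_path / "absent.nwk"),
            species=str(tmp_path / "absent.csv"),
        )
        with pytest.raises(FileNotFoundError):
            run_experiment(cfg)
        assert not (tmp_path / "out" / "capture_report.csv").exists()

    def test_threatened_universe_strategies(self, tmp_path):
        cfg = self.base_config(
            tmp_path,
            synth=synth_block(
                n_tips=80,
                rl_proportions={
                    "LC": 0.4, "NT": 0.1, "VU": 0.2, "EN": 0.15, "CR": 0.15,
                },
            ),
            strategies=["greedy_pd_threatened", "edge_rank", "fdist_rank"],
            null_strategy="rl_weighted",
            universe="threatened",
            fractions=[0.25],
            categories=["food"],
        )
        manifest = run_experiment(cfg)
        assert len(manifest["cells"]) == 3
        # selections live under out/selections, one file per strategy/fraction
        sel_dir = tmp_path / "out" / "selections"
        names = {p.name for p in sel_dir.iterdir()}
        assert any(n.startswith("greedy_pd_threatened") for n in names)
        assert any(n.startswith("rl_weighted") for n in names)
        rec = json.loads(
            next(sel_dir.glob("greedy_pd_threatened*")).read_text().splitlines()[0]
        )
        assert rec["strategy"] == "greedy_pd_threatened"

    def test_rl_controlled_uses_greedy_templates(self, tmp_path):
        cfg = self.base_config(
            tmp_path,
            synth=synth_block(
                n_tips=80,
                rl_proportions={
                    "LC": 0.4, "NT": 0.1, "VU": 0.2, "EN": 0.15, "CR": 0.15,
                },
            ),
            strategies=["greedy_pd_threatened"],
            null_strategy="rl_controlled",
            universe="threatened",
            fractions=[0.25],
            categories=["food"],
        )
        manifest = run_experiment(cfg)
        assert len(manifest["cells"]) == 1


class TestCLI:
    def test_end_to_end_stage_commands(self, tmp_path):
        runner = CliRunner()
        cfg = tmp_path / "synth.yaml"
        import yaml

        yaml.safe_dump(synth_block(n_tips=40, n_trees=2), cfg.open("w"))
        out = tmp_path / "data"
        r = runner.invoke(
            cli_main,
            ["synthdata", "generate", "--config", str(cfg), "--out-dir", str(out)],
        )
        assert r.exit_code == 0, r.output
        assert (out / "trees.nwk").exists() and (out / "species.csv").exists()

        r = runner.invoke(
            cli_main,
            ["diversity", "ed", "--trees", str(out / "trees.nwk"),
             "--out", str(tmp_path / "ed.csv")],
        )
        assert r.exit_code == 0, r.output
        ed = pd.read_csv(tmp_path / "ed.csv")
        assert {"species", "ed_median", "ed_mean", "n_trees"} <= set(ed.columns)

        common = [
            "--trees", str(out / "trees.nwk"),
            "--species", str(out / "species.csv"),
            "--fraction", "0.2", "--seed", "1",
        ]
        r = runner.invoke(
            cli_main,
            ["select", "--strategy", "greedy_pd", *common,
             "--sets-per-tree", "2", "--out", str(tmp_path / "sets.jsonl")],
        )
        assert r.exit_code == 0, r.output
        r = runner.invoke(
            cli_main,
            ["select", "--strategy", "random_uniform", *common,
             "--replicates", "30", "--out", str(tmp_path / "null.jsonl")],
        )
        assert r.exit_code == 0, r.output
        r = runner.invoke(
            cli_main,
            ["evaluate", "capture", "--sets", str(tmp_path / "sets.jsonl"),
             "--species", str(out / "species.csv"), "--category", "food",
             "--null-sets", str(tmp_path / "null.jsonl"),
             "--out", str(tmp_path / "report.csv")],
        )
        assert r.exit_code == 0, r.output
        report = pd.read_csv(tmp_path / "report.csv")
        assert report.loc[0, "category"] == "food"

    def test_dispersion_command(self, tmp_path):
        runner = CliRunner()
        cfg = tmp_path / "synth.yaml"
        import yaml

        yaml.safe_dump(synth_block(n_tips=40, n_trees=2), cfg.open("w"))
        out = tmp_path / "data"
        runner.invoke(
            cli_main,
            ["synthdata", "generate", "--config", str(cfg), "--out-dir", str(out)],
        )
        r = runner.invoke(
            cli_main,
            ["diversity", "dispersion", "--trees", str(out / "trees.nwk"),
             "--species", str(out / "species.csv"), "--category", "pets",
             "--shuffles", "99", "--seed", "1"],
        )
        assert r.exit_code == 0, r.output
        assert "ses=" in r.output

    def test_run_command(self, tmp_path):
        runner = CliRunner()
        cfg = tmp_path / "exp.yaml"
        import yaml

        yaml.safe_dump(
            {
                "out_dir": str(tmp_path / "out"),
                "synth": synth_block(n_tips=40, n_trees=2),
                "fractions": [0.2],
                "strategies": ["greedy_pd"],
                "categories": ["food"],
                "replicates": 20,
                "sets_per_tree": 1,
            },
            cfg.open("w"),
        )
        r = runner.invoke(cli_main, ["run", "--config", str(cfg)])
        assert r.exit_code == 0, r.output
        assert (tmp_path / "out" / "manifest.json").exists()

    def test_overlap_command(self, tmp_path):
        runner = CliRunner()
        a = pd.DataFrame({"species": [f"s{i}" for i in range(40)],
                          "score": range(40)})
        b = a.assign(score=list(range(40))[::-1])
        a.to_csv(tmp_path / "a.csv", index=False)
        b.to_csv(tmp_path / "b.csv", index=False)
        r = runner.invoke(
            cli_main,
            ["evaluate", "overlap",
             "--scores", f"{tmp_path}/a.csv,{tmp_path}/b.csv",
             "--fractions", "0.1,0.25", "--out", str(tmp_path / "ov.csv")],
        )
        assert r.exit_code == 0, r.output
        ov = pd.read_csv(tmp_path / "ov.csv")
        assert list(ov["both"]) == [0, 0]
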