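"""Schedule arithmetic, simulation determinism, log round-trips, pipeline, CLI."""

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

import tplsim as t
from tplsim.cli import main as cli_main


class TestSchedule:
    def test_training_counts_match_protocol(self):
        sched = t.build_schedule("EI")
        assert sched.training_trials() == 2880
        for session in (1, 2, 3, 4):
            assert sched.training_trials(session) == 720

    def test_total_includes_practice_and_tests(self):
        sched = t.build_schedule("FI")
        assert sched.total_trials == 10 + 240 + 2880 + 240

    @pytest.mark.parametrize(
        "group,cond", [("EI", ("empty", 200)), ("FI", ("filled", 200))]
    )
    def test_trained_condition_per_group(self, group, cond):
        sched = t.build_schedule(group)
        train = [b for b in sched.blocks if b.phase == "train"]
        assert len(train) == 48 and all(b.condition == cond for b in train)

    def test_pre_and_post_cover_all_conditions_once(self):
        sched = t.build_schedule("EI")
        for phase in ("pre", "post"):
            conds = [b.condition for b in sched.blocks if b.phase == phase]
            assert sorted(conds) == sorted(t.CONDITIONS)

    def test_practice_uses_trained_condition(self):
        sched = t.build_schedule("EI")
        practice = [b for b in sched.blocks if b.phase == "practice"]
        assert len(practice) == 1
        assert practice[0].n_trials == 10
        assert practice[0].condition == ("empty", 200)

    def test_unknown_group_rejected(self):
        with pytest.raises(t.ConfigurationError):
            t.build_schedule("XX")

    def test_test_block_order_shuffles_with_rng(self):
        cfg = t.ExperimentConfig()
        orders = set()
        for seed in range(8):
            sched = t.build_schedule("EI", cfg, np.random.default_rng(seed))
            orders.add(tuple(b.condition for b in sched.blocks if b.phase == "pre"))
        assert len(orders) > 1


class TestSimulation:
    def test_participant_row_count(self):
        obs = t.make_cohort("EI", 1, 0)[0]
        df = t.simulate_participant(obs, t.ExperimentConfig(), np.random.SeedSequence(1))
        assert len(df) == 3370
        assert list(df.columns) == t.experiment.LOG_COLUMNS

    def test_same_seed_reproduces_exactly(self, tiny_config):
        a = t.simulate_experiment(tiny_config, seed=9)
        b = t.simulate_experiment(tiny_config, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_different_seeds_differ(self, tiny_config):
        a = t.simulate_experiment(tiny_config, seed=9)
        b = t.simulate_experiment(tiny_config, seed=10)
        assert not a["correct"].equals(b["correct"])

    def test_csv_round_trip_is_bit_exact(self, tiny_config, tmp_path):
        trials = t.simulate_experiment(tiny_config, seed=2)
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        t.write_trials(trials, p1)
        t.write_trials(t.read_trials(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()


class TestPipeline:
    @pytest.fixture(scope="class")
    def trials(self):
        return t.simulate_experiment(t.ExperimentConfig(n_ei=2, n_fi=2), seed=4)

    def test_simulator_output_passes_schema(self, trials, tmp_path):
        path = tmp_path / "trials.csv"
        t.write_trials(trials, path)
        res = t.run_pipeline(path)
        assert set(res) >= {"blocks", "sessions", "summary", "group_summary"}

    def test_rerun_reproduces_identical_tables(self, trials):
        r1 = t.run_pipeline(trials)
        r2 = t.run_pipeline(trials)
        pd.testing.assert_frame_equal(r1["summary"], r2["summary"])

    def test_truncated_block_excluded_pipeline_continues(self, trials):
        mask = (
            (trials["participant"] == "EI01")
            & (trials["phase"] == "train")
            & (trials["session"] == 1)
            & (trials["block"] == 0)
            & (trials["trial"] >= 10)
        )
        res = t.run_pipeline(trials[~mask])
        blocks = res["blocks"]
        row = blocks[
            (blocks["participant"] == "EI01")
            & (blocks["phase"] == "train")
            & (blocks["session"] == 1)
            & (blocks["block"] == 0)
        ]
        assert row["exclusion_reason"].iloc[0] == "too-few-reversals"
        assert len(res["summary"]) > 0

    def test_empty_file_is_schema_error(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("")
        with pytest.raises(t.SchemaError):
            t.read_trials(path)

    def test_missing_column_is_schema_error(self, trials, tmp_path):
        path = tmp_path / "bad.csv"
        trials.drop(columns=["delta_ms"]).to_csv(path, index=False)
        with pytest.raises(t.SchemaError):
            t.read_trials(path)

    def test_bad_value_reports_row_number(self, tiny_config, tmp_path):
        trials = t.simulate_experiment(tiny_config, seed=2).head(50).copy()
        trials.loc[7, "phase"] = "warmup"
        path = tmp_path / "bad.csv"
        t.write_trials(trials, path)
        with pytest.raises(t.SchemaError, match="line 9"):
            t.read_trials(path)

    def test_default_cohort_keeps_everyone(self, trials):
        assert t.run_pipeline(trials)["excluded"] == []

    def test_inflated_participant_excluded_end_to_end(self):
        # 3-SD screening needs a real cohort behind the group mean
        trials = t.simulate_experiment(t.ExperimentConfig(n_ei=1, n_fi=12), seed=8)
        mask = (
            (trials["participant"] == "FI05")
            & (trials["phase"] == "train")
            & (trials["session"].isin([2, 3]))
        )
        trials = trials.copy()
        trials.loc[mask, "delta_ms"] *= 10
        res = t.run_pipeline(trials)
        assert res["excluded"] == ["FI05"]
        assert "FI05" not in set(res["summary"]["participant"])


class TestConfigFiles:
    def test_yaml_sections_override_defaults(self, tmp_path):
        cfg_file = tmp_path / "cfg.yaml"
        cfg_file.write_text(
            "observer:\n  wf_start: 0.3\n  lapse_rate: 0.05\n"
            "staircase:\n  trials_per_block: 40\n"
            "schedule:\n  n_ei: 3\n  practice_trials: 0\n"
            "analysis:\n  mad_center: group-mean\n"
        )
        cfg = t.load_config(cfg_file)
        assert cfg.observer.wf_start == 0.3
        assert cfg.trials_per_block == 40
        assert cfg.n_ei == 3 and cfg.practice_trials == 0
        assert cfg.analysis.mad_center == "group-mean"

    def test_unknown_key_rejected(self, tmp_path):
        cfg_file = tmp_path / "cfg.yaml"
        cfg_file.write_text("staircase:\n  stepsize: 0.1\n")
        with pytest.raises(t.ConfigurationError):
            t.load_config(cfg_file)

    def test_unknown_section_rejected(self, tmp_path):
        cfg_file = tmp_path / "cfg.yaml"
        cfg_file.write_text("display:\n  hz: 100\n")
        with pytest.raises(t.ConfigurationError):
            t.load_config(cfg_file)


class TestCLI:
    def test_convergence_command(self):
        result = CliRunner().invoke(cli_main, ["convergence", "--down", "3"])
        assert result.exit_code == 0
        assert "0.7937" in result.output

    def test_convergence_rejects_bad_rule(self):
        result = CliRunner().invoke(cli_main, ["convergence", "--down", "0"])
        assert result.exit_code == 2

    def test_schedule_command(self):
        result = CliRunner().invoke(cli_main, ["schedule", "--group", "EI"])
        assert result.exit_code == 0
        assert "2880 training" in result.output

    def test_simulate_then_analyze(self, tmp_path):
        cfg_file = tmp_path / "cfg.yaml"
        cfg_file.write_text("schedule:\n  n_ei: 1\n  n_fi: 1\n")
        out = tmp_path / "out"
        runner = CliRunner()
        res = runner.invoke(
            cli_main,
            ["simulate", "--config", str(cfg_file), "--out", str(out), "--seed", "5"],
        )
        assert res.exit_code == 0, res.output
        assert (out / "trials.csv").exists() and (out / "manifest.json").exists()
        res = runner.invoke(
            cli_main,
            ["analyze", "--log", str(out / "trials.csv"), "--out", str(out / "tables")],
        )
        assert res.exit_code == 0, res.output
        assert (out / "tables" / "summary.csv").exists()
        assert "learner ratio" in res.output

    def test_analyze_missing_log_exits_3(self, tmp_path):
        res = CliRunner().invoke(
            cli_main,
            ["analyze", "--log", str(tmp_path / "no.csv"), "--out", str(tmp_path)],
        )
        assert res.exit_code == 3
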