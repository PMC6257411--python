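"""Network builder, balanced fixture, recordings, config files and CLI."""

import json

import numpy as np
import pytest
import yaml
from click.testing import CliRunner

from spinnlite import graph, models, netapi, runtime
from spinnlite.cli import main as cli_main


class TestFixture:
    def test_partitions_to_five_machine_vertices(self, balanced_network):
        machine = netapi.build_machine(balanced_network, seed=1)
        neuron_and_source = [v for v in machine.manifest["vertices"]]
        assert len(neuron_and_source) == 5
        by_pop = {}
        for v in neuron_and_source:
            by_pop.setdefault(v["population"], []).append(v)
        assert len(by_pop["excitatory"]) == 2
        assert len(by_pop["inhibitory"]) == 1

    def test_same_seed_identical_connectivity(self, balanced_network):
        m1 = netapi.build_machine(balanced_network, seed=4)
        m2 = netapi.build_machine(netapi.build_balanced_fixture(1), seed=4)
        for c1, c2 in zip(m1.neuron_cores, m2.neuron_cores):
            assert set(c1.matrices) == set(c2.matrices)
            for addr in c1.matrices:
                assert (c1.matrices[addr] == c2.matrices[addr]).all()

    def test_excitatory_membranes_initialised_between_reset_and_threshold(
            self, balanced_network):
        machine = netapi.build_machine(balanced_network, seed=1)
        exc = [c for c in machine.neuron_cores
               if c.vertex.population.label == "excitatory"]
        v0 = np.concatenate([c._v_float() for c in exc])
        assert len(v0) == 500
        assert (v0 >= -65.0).all() and (v0 <= -50.0).all()
        assert v0.std() > 1.0          # actually distributed, not constant

    def test_short_run_active_and_responds_to_stimulus(
            self, balanced_results_short):
        res = balanced_results_short
        assert len(res.spikes("excitatory").data) > 0
        assert len(res.spikes("inhibitory").data) > 0


class TestRecording:
    def _tiny(self, record_v=True):
        net = netapi.Network()
        net.add_population(graph.Population(
            "p", 3, "lif", models.LifParams(i_offset=1.0)))
        net.record("p", "spikes")
        if record_v:
            net.record("p", "v")
        return net

    def test_v_trace_has_duration_over_dt_plus_one_samples(self):
        res = netapi.run(self._tiny(), 50.0, seed=1)
        assert res.v("p").data.shape == (51, 3)

    def test_recording_disabled_flagged(self):
        res = netapi.run(self._tiny(record_v=False), 10.0, seed=1)
        rec = res.v("p")
        assert not rec.enabled
        assert rec.data.size == 0

    def test_spikes_sorted_by_time_then_id(self, balanced_results_short):
        data = balanced_results_short.spikes("excitatory").data
        order = np.lexsort((data[:, 1], data[:, 0]))
        assert (order == np.arange(len(data))).all()

    def test_manifest_reproduces_run_settings(self):
        res = netapi.run(self._tiny(), 10.0, seed=9)
        man = res.manifest().as_dict()
        assert man["seed"] == 9
        assert man["duration"] == 10.0
        assert man["shift"] >= 0
        assert man["recording"] == {"p": ["spikes", "v"]}


class TestConfigFiles:
    CONFIG = {
        "dt": 1.0,
        "duration": 20.0,
        "populations": [
            {"label": "noise", "size": 5, "kind": "poisson",
             "params": {"rates": 200.0}},
            {"label": "cells", "size": 10, "kind": "lif",
             "params": {"tau_m": 20.0, "i_offset": 1.0},
             "v_init": {"kind": "uniform", "low": -65, "high": -55},
             "record": ["spikes", "v"]},
        ],
        "projections": [
            {"pre": "noise", "post": "cells",
             "connector": {"kind": "fixed_probability", "p_connect": 0.5},
             "weight": 0.2,
             "delay": {"kind": "uniform_int", "low": 1, "high": 4}},
        ],
    }

    def test_yaml_round_trip_runs(self, tmp_path):
        path = tmp_path / "net.yaml"
        path.write_text(yaml.safe_dump(self.CONFIG))
        network, cfg = netapi.load_config(path)
        res = netapi.run(network, cfg["duration"], seed=2)
        assert res.v("cells").data.shape == (21, 10)

    def test_unknown_population_in_projection_rejected(self):
        bad = dict(self.CONFIG)
        bad["projections"] = [dict(self.CONFIG["projections"][0],
                                   post="nonexistent")]
        with pytest.raises(ValueError, match="unknown population"):
            netapi.network_from_dict(bad)


class TestCli:
    def test_missing_config_is_usage_error(self):
        result = CliRunner().invoke(cli_main,
                                    ["run", "--config", "no-such-file.yaml"])
        assert result.exit_code != 0

    def test_zero_duration_produces_valid_empty_outputs(self, tmp_path):
        result = CliRunner().invoke(cli_main, [
            "run", "--duration", "0", "--seed", "1",
            "--out-dir", str(tmp_path)])
        assert result.exit_code == 0, result.output
        assert (tmp_path / "spikes.csv").read_text() == \
            "time_ms,population,neuron_id\n"
        json.loads((tmp_path / "diagnostics.json").read_text())
        json.loads((tmp_path / "manifest.json").read_text())

    def test_same_config_and_seed_byte_identical_spike_csv(self, tmp_path):
        cfg = tmp_path / "net.yaml"
        cfg.write_text(yaml.safe_dump(TestConfigFiles.CONFIG))
        outs = []
        for sub in ("a", "b"):
            result = CliRunner().invoke(cli_main, [
                "run", "--config", str(cfg), "--seed", "5",
                "--out-dir", str(tmp_path / sub)])
            assert result.exit_code == 0, result.output
            outs.append((tmp_path / sub / "spikes.csv").read_bytes())
        assert outs[0] == outs[1]
        assert len(outs[0]) > len("time_ms,population,neuron_id\n")

    def test_netgen_manifest(self, tmp_path):
        out = tmp_path / "machine.json"
        result = CliRunner().invoke(cli_main,
                                    ["netgen", "--seed", "1",
                                     "--out", str(out)])
        assert result.exit_code == 0, result.output
        manifest = json.loads(out.read_text())
        assert len(manifest["vertices"]) == 5

    def test_costmodel_point(self):
        result = CliRunner().invoke(cli_main,
                                    ["costmodel", "--n", "128", "--p", "1.0"])
        assert result.exit_code == 0
        assert "5922" in result.output

    def test_costmodel_grid_csv(self, tmp_path):
        out = tmp_path / "grid.csv"
        result = CliRunner().invoke(cli_main,
                                    ["costmodel", "--csv", str(out)])
        assert result.exit_code == 0
        assert out.read_text().startswith("n,P,events")

    def test_inspect_round_trip(self, tmp_path):
        from spinnlite import synformat
        rows = [synformat.build_row(
            [synformat.Synapse(12, 1.15, 10, synformat.INHIBITORY)],
            shift=6, max_row_length=1)]
        path = tmp_path / "m.bin"
        synformat.write_matrix(path, rows, shift=6)
        result = CliRunner().invoke(cli_main,
                                    ["inspect", str(path), "--json"])
        assert result.exit_code == 0, result.output
        decoded = json.loads(result.output)
        assert decoded["rows"][0]["static"][0]["weight_raw"] == 589
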