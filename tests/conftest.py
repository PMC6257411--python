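"""Shared fixtures: tiny networks built programmatically at test time."""

from __future__ import annotations

import numpy as np
import pytest

from spinnlite import graph, models, netapi, sources


def single_synapse_network(delay_steps: int, weight: float = 1.0,
                           spike_at_ms: float = 3.0,
                           charge_compensation: bool = False) -> netapi.Network:
    """One spike-source-array unit firing once into one LIF neuron."""
    net = netapi.Network(charge_compensation=charge_compensation)
    net.add_population(graph.Population(
        "src", 1, "spike_array",
        sources.SpikeArraySchedule([[spike_at_ms]], dt=net.dt)))
    net.add_population(graph.Population("tgt", 1, "lif", models.LifParams()))
    net.connect(graph.Projection("src", "tgt",
                                 graph.ConnectorSpec("all_to_all"),
                                 weight=weight, delay=float(delay_steps)))
    net.record("tgt", "v")
    return net


def first_deflection_step(delay_steps: int) -> int | None:
    """Timestep at which the target membrane first moves: the end-to-end
    delivery time of the single spike (emission step + configured delay)."""
    net = single_synapse_network(delay_steps)
    res = netapi.run(net, 3 + delay_steps + 5, seed=7)
    v = res.v("tgt").data[:, 0]
    moved = np.nonzero(np.abs(v - v[0]) > 1e-9)[0]
    # sample index k holds the state after the update of step k-1, so the
    # arrival step is one less than the first moved sample index
    return int(moved[0]) - 1 if len(moved) else None


@pytest.fixture(scope="session")
def balanced_network():
    return netapi.build_balanced_fixture(seed=1)


@pytest.fixture(scope="session")
def balanced_results_short():
    """A 400 ms balanced-network run shared by structural tests."""
    net = netapi.build_balanced_fixture(seed=1)
    return netapi.run(net, 400.0, seed=1)
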