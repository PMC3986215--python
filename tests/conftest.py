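"""Shared fixtures: small deterministic graphs and a desk-scale scenario."""

from __future__ import annotations

import dataclasses

import networkx as nx
import pytest

import netprio.synthdata as synthdata


@pytest.fixture
def triangle() -> nx.Graph:
    g = nx.Graph()
    g.add_edges_from([("a", "b"), ("b", "c"), ("a", "c")])
    return g


@pytest.fixture
def path3() -> nx.Graph:
    """s - a - b."""
    g = nx.Graph()
    g.add_edges_from([("s", "a"), ("a", "b")])
    return g


@pytest.fixture(scope="session")
def small_spec() -> synthdata.ScenarioSpec:
    """A fast generator spec for unit tests (not one of the frozen presets)."""
    return synthdata.ScenarioSpec(
        n_nodes=3000,
        mean_degree=8.0,
        seeds_per_phenotype=25,
        module_cohesion=0.15,
        path_redundancy=3,
        functional_diversity=5,
        rng_seed=42,
    )


@pytest.fixture(scope="session")
def small_scenario(small_spec):
    """Generated network + planted phenotype, shared across tests."""
    net = synthdata.generate_interactome(small_spec)
    planted = synthdata.plant_phenotype(net, small_spec, phenotype_id="toy")
    return small_spec, net, planted


def make_scenario(preset_name: str, rng_seed: int):
    spec = synthdata.preset(preset_name, rng_seed=rng_seed)
    net = synthdata.generate_interactome(spec)
    return spec, synthdata.plant_phenotype(net, spec, phenotype_id=preset_name)


@pytest.fixture
def null_spec(small_spec) -> synthdata.ScenarioSpec:
    """Cohesion-0 control: seeds scattered, no planted signal."""
    return dataclasses.replace(small_spec, module_cohesion=0.0)
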