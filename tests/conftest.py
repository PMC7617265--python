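import logging

import numpy as np
import pandas as pd
import pytest

import transwalker as tw

logging.getLogger("transwalker").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def scenario_config() -> tw.ScenarioConfig:
    return tw.ScenarioConfig(seed=3)


@pytest.fixture(scope="session")
def bundle_dir(tmp_path_factory, scenario_config):
    d = tmp_path_factory.mktemp("bundle")
    tw.write_fixture_bundle(scenario_config, d)
    return d


@pytest.fixture(scope="session")
def scenario(scenario_config):
    """In-memory artifacts of the reference scenario."""
    from transwalker.synthetic import (
        generate_covariates,
        generate_cpg_annotation,
    )

    cfg = scenario_config
    dosages, snp_anno = tw.generate_genotypes(cfg)
    ppi = tw.generate_ppi(cfg)
    truth, gene_anno, tracks = tw.generate_regulatory_scenario(cfg, ppi)
    covariates = generate_covariates(cfg)
    expression = tw.generate_expression(cfg, dosages, truth, covariates)
    methylation = tw.generate_methylation(cfg, dosages, truth, covariates,
                                          expression)
    return {
        "config": cfg, "dosages": dosages, "snp_anno": snp_anno,
        "cpg_anno": generate_cpg_annotation(cfg), "gene_anno": gene_anno,
        "ppi": ppi, "truth": truth, "tracks": tracks,
        "covariates": covariates, "expression": expression,
        "methylation": methylation,
    }


def random_connected_graph(rng: np.random.Generator, n: int, p: float = 0.05):
    """Erdos-Renyi graph forced connected (and non-bipartite) by adding a
    ring plus one odd chord."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from((i, (i + 1) % n) for i in range(n))
    g.add_edge(0, 2)  # odd cycle -> non-bipartite
    mask = rng.random((n, n)) < p
    for i in range(n):
        for j in range(i + 1, n):
            if mask[i, j]:
                g.add_edge(i, j)
    return nx.relabel_nodes(g, {i: f"n{i:03d}" for i in range(n)})


def closed_form_aggregated(g) -> tuple[list, np.ndarray]:
    """Independent dense oracle: M = (I - T + psi0 psi0^T)^-1 - I."""
    import networkx as nx

    nodes = sorted(g.nodes)
    a = nx.to_numpy_array(g, nodelist=nodes)
    d = a.sum(axis=1)
    t = a / np.sqrt(np.outer(d, d))
    psi0 = np.sqrt(d) / np.linalg.norm(np.sqrt(d))
    m = np.linalg.inv(np.eye(len(nodes)) - t + np.outer(psi0, psi0)) \
        - np.eye(len(nodes))
    return nodes, m
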