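import numpy as np
import pytest

import strucphylo as sp
from strucphylo.structio import Residue, StructureModel


def make_model(plddt, model_id="m", seed=0):
    """Structure on a realistic template backbone with prescribed pLDDT."""
    plddt = np.asarray(plddt, dtype=float)
    backbone = sp.make_template(max(len(plddt), 60), seed=seed)
    residues = [
        Residue(r.seq_index, r.aa, r.ca_coord, float(plddt[i]))
        for i, r in enumerate(backbone.residues[: len(plddt)])
    ]
    return StructureModel(model_id=model_id, residues=residues)


@pytest.fixture(scope="session")
def low_noise_dataset():
    """6 leaves, weakly correlated low noise: topology is recoverable."""
    spec = sp.SimulationSpec(n_leaves=6, template_len=120,
                             noise_per_unit_branch=0.5,
                             spatial_correlation_length=2.0, seed=2)
    models, tree, template = sp.simulate_dataset(spec)
    return models, tree, template


@pytest.fixture(scope="session")
def correlated_dataset():
    """8 leaves with strongly correlated noise (the block-jackknife regime)."""
    spec = sp.SimulationSpec(n_leaves=8, template_len=120,
                             noise_per_unit_branch=0.5,
                             spatial_correlation_length=15.0, seed=1)
    models, tree, template = sp.simulate_dataset(spec)
    return models, tree, template


@pytest.fixture(scope="session")
def low_noise_core(low_noise_dataset):
    models, tree, _ = low_noise_dataset
    core, scores = sp.build_core(models)
    return models, tree, core, scores


@pytest.fixture(scope="session")
def correlated_core(correlated_dataset):
    models, tree, _ = correlated_dataset
    core, scores = sp.build_core(models)
    return models, tree, core, scores


def random_tree_newick(rng, n_leaves):
    """Random binary tree over t1..tn as a Newick string (test helper)."""
    nodes = [f"t{i + 1}:{rng.uniform(0.1, 2.0):.3f}" for i in range(n_leaves)]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = f"({nodes[i]},{nodes[j]}):{rng.uniform(0.1, 2.0):.3f}"
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)]
        nodes.append(merged)
    return "(" + ",".join(nodes) + ");"
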