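import numpy as np
import pandas as pd
import pytest

from spheretrace import synthetic
from spheretrace.gsea import ExpressionDataset, NodeSetCollection


@pytest.fixture
def node_sets() -> NodeSetCollection:
    return synthetic.gen_node_sets(n_modules=10, nodes_per_module=6, seed=0)


@pytest.fixture
def planted_dataset(node_sets) -> ExpressionDataset:
    truth = synthetic.ExpressionTruth(
        planted_modules={"M0000": 1}, effect_size=2.0, seed=11
    )
    return synthetic.gen_expression_dataset(
        n_probes=80, samples_per_group=(10, 10), node_sets=node_sets, truth=truth
    )


@pytest.fixture
def tiny_dataset() -> ExpressionDataset:
    """Four probes, two ECs (one shared by two probes), 3v3 samples."""
    rng = np.random.default_rng(5)
    values = pd.DataFrame(
        rng.standard_normal((4, 6)),
        index=["p1", "p2", "p3", "p4"],
        columns=[f"s{i}" for i in range(6)],
    )
    labels = pd.Series(["A"] * 3 + ["B"] * 3, index=values.columns)
    probe_to_gene = {"p1": "g1", "p2": "g2", "p3": "g3", "p4": "g4"}
    gene_to_ec = {
        "g1": ("1.1.1.1",),
        "g2": ("1.1.1.1",),
        "g3": ("2.2.2.2",),
        "g4": ("2.2.2.2", "3.3.3.3"),
    }
    return ExpressionDataset(
        values=values,
        labels=labels,
        probe_to_gene=probe_to_gene,
        gene_to_ec=gene_to_ec,
        classes=("A", "B"),
    )
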