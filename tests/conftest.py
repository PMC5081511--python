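from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from lncmod.data_io import ExpressionMatrix, GoResource
from lncmod.simulate import generate_dataset


def make_go(edges, direct, namespace="biological_process", names=None):
    """Build a GoResource from child->parent edges and direct annotations."""
    dag = nx.DiGraph()
    terms = {t for e in edges for t in e} | {t for ts in direct.values() for t in ts}
    dag.add_nodes_from(terms)
    dag.add_edges_from(edges)
    namespaces = {t: namespace for t in dag.nodes}
    term_names = names or {t: t for t in dag.nodes}
    return GoResource(dag, namespaces, term_names, {g: set(ts) for g, ts in direct.items()})


@pytest.fixture
def chain_go():
    """root <- A <- B with one gene on B and one on root."""
    return make_go(
        edges=[("A", "root"), ("B", "A")],
        direct={"g1": {"B"}, "g2": {"root"}},
    )


@pytest.fixture
def specificity_go():
    """5 annotated genes; term t carries 1 of them (p(t) = 0.2)."""
    return make_go(
        edges=[("t", "root")],
        direct={"g1": {"t"}, "g2": {"root"}, "g3": {"root"},
                "g4": {"root"}, "g5": {"root"}},
    )


@pytest.fixture
def sibling_go():
    """Siblings t1, t2 (p = 0.2 each) under parent P (p = 0.5), 10 genes."""
    direct = {f"g{i}": {"t1"} for i in (1, 2)}
    direct.update({f"g{i}": {"t2"} for i in (3, 4)})
    direct["g5"] = {"P"}
    direct.update({f"g{i}": {"root"} for i in range(6, 11)})
    return make_go(edges=[("P", "root"), ("t1", "P"), ("t2", "P")], direct=direct)


@pytest.fixture
def triangle_ppi():
    g = nx.Graph()
    g.add_edges_from([("A", "B"), ("B", "C"), ("A", "C")])
    return g


def expression_from_array(values, lncs, mrnas, samples=None):
    genes = list(lncs) + list(mrnas)
    samples = samples or [f"S{i}" for i in range(np.asarray(values).shape[1])]
    return ExpressionMatrix(
        pd.DataFrame(np.asarray(values, dtype=float), index=genes, columns=samples),
        {g: ("lncRNA" if g in set(lncs) else "mRNA") for g in genes},
    )


@pytest.fixture(scope="session")
def planted_dataset():
    """The standard planted-module benchmark (10 modules of 8 partners)."""
    return generate_dataset(seed=0)
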