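import numpy as np
import pandas as pd
import pytest

from hiccnet.graph_core import DirectedNetwork
from hiccnet.grn import ExpressionMatrix


def make_expression(profiles: dict[str, np.ndarray],
                    covariates: pd.DataFrame | None = None) -> ExpressionMatrix:
    """Assemble an ExpressionMatrix from named profile vectors."""
    genes = sorted(profiles)
    values = pd.DataFrame({g: profiles[g] for g in genes}).T
    values.columns = [f"S{j:03d}" for j in range(values.shape[1])]
    if covariates is None:
        covariates = pd.DataFrame(
            {"disease": 0, "hba1c": 5.5, "age": 50.0, "sex": 0},
            index=values.columns)
    else:
        covariates = covariates.copy()
        covariates.index = values.columns
    return ExpressionMatrix(values=values, covariates=covariates)


def random_digraph(n: int, p: float, rng: np.random.Generator,
                   prefix: str = "n") -> DirectedNetwork:
    nodes = [f"{prefix}{i:02d}" for i in range(n)]
    edges = [(nodes[i], nodes[j]) for i in range(n) for j in range(n)
             if i != j and rng.random() < p]
    return DirectedNetwork(edges, nodes=nodes)


@pytest.fixture
def chain7() -> DirectedNetwork:
    return DirectedNetwork([(f"x{i}", f"x{i+1}") for i in range(1, 7)])


@pytest.fixture
def triangle() -> DirectedNetwork:
    return DirectedNetwork([("a", "b"), ("b", "c"), ("c", "a")])


@pytest.fixture
def out_star() -> DirectedNetwork:
    return DirectedNetwork([("hub", "l1"), ("hub", "l2"), ("hub", "l3")])


@pytest.fixture(scope="session")
def default_instance():
    """The default synthetic study used by the end-to-end recovery tests."""
    from hiccnet import synth
    net, truth = synth.generate_regulatory_network(seed=0)
    expr = synth.simulate_expression(net, truth, n_samples=60, seed=1000)
    pathways = synth.generate_pathways(truth, n_decoys=20, seed=2000)
    prior = synth.generate_prior(truth, fraction=0.5, seed=3000)
    return {"net": net, "truth": truth, "expr": expr,
            "pathways": pathways, "prior": prior}
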