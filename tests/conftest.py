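import numpy as np
import pandas as pd
import pytest

from glutmet.matrix import ExpressionMatrix
from glutmet.registry import load_registry, load_routes
from glutmet.simulate import synthetic_reaction


def make_matrix(values, groups, cohorts=None, genes=None, samples=None):
    """Build an ExpressionMatrix from an array and group labels."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    genes = genes or [f"G{i}" for i in range(1, n_genes + 1)]
    samples = samples or [f"S{j}" for j in range(1, n_samples + 1)]
    cohorts = cohorts or ["X"] * n_samples
    ann = pd.DataFrame(
        {"group": list(groups), "cohort": list(cohorts)},
        index=pd.Index(samples, name="sample"),
    )
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), ann)


@pytest.fixture(scope="session")
def registry():
    return load_registry()


@pytest.fixture(scope="session")
def routes(registry):
    return load_routes(registry=registry)


@pytest.fixture(scope="session")
def synthetic():
    """(registry, reaction) with two disjoint reactant routes."""
    return synthetic_reaction(n_reactants=2, genes_per_reactant=5, genes_per_product=6)


@pytest.fixture()
def random_matrix():
    """50 genes x 20 samples of lognormal-ish log2 expression, two groups."""
    rng = np.random.default_rng(11)
    values = rng.normal(7.0, 1.0, (50, 20))
    return make_matrix(values, ["cancer"] * 10 + ["control"] * 10)
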