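import numpy as np
import pytest

import wgchna as w
from wgchna.io import ExpressionMatrix


@pytest.fixture(scope="session")
def default_dataset():
    """The canonical planted-module scenario (fixed seed, generated once)."""
    return w.generate(w.default_scenario())


def random_expression(rng, n_genes, n_samples):
    values = rng.standard_normal((n_genes, n_samples))
    return ExpressionMatrix(
        values,
        [f"g{i}" for i in range(n_genes)],
        [f"s{j}" for j in range(n_samples)],
    )


def random_hypergraph(rng, n_genes, n_samples, tau=1.0, beta=1):
    """A weighted hypergraph built from a random complete expression matrix."""
    X = random_expression(rng, n_genes, n_samples)
    Z = w.standardize(X)
    hg = w.build_incidence(Z, tau)
    keep = [X.gene_ids.index(g) for g in hg.node_ids]
    Xk = ExpressionMatrix(X.values[keep], list(hg.node_ids), list(X.sample_ids))
    return Xk, w.hyperedge_weights_corr(Xk, hg, beta=beta)
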