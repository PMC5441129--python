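"""Shared helper: random linear-Gaussian DAG data for structure-learning tests."""

import numpy as np
import pandas as pd


def random_dag_data(rng, n_nodes=6, n=2000, coef_low=0.5, coef_high=0.9, p_edge=0.4):
    """Linear-Gaussian DAG over a random topological order; returns (df, true skeleton)."""
    order = list(range(n_nodes))
    X = np.zeros((n, n_nodes))
    edges = set()
    for j_pos, j in enumerate(order):
        X[:, j] = rng.standard_normal(n)
        for i in order[:j_pos]:
            if rng.random() < p_edge:
                coef = rng.uniform(coef_low, coef_high) * rng.choice([-1, 1])
                X[:, j] += coef * X[:, i]
                edges.add(frozenset((f"v{i}", f"v{j}")))
        X[:, j] /= X[:, j].std()
    df = pd.DataFrame(X, columns=[f"v{i}" for i in range(n_nodes)])
    return df, edges
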