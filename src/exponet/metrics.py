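"""Strength centrality and network summary statistics.

Strength centrality of a node is the sum of the absolute weights of its
incident edges; it is the centrality index reported for psychometric
networks of this kind.  The module also packages, as a worked-example
fixture, the published 11-node exposome–psychopathology network (exposome
score, six symptom domains, age, education, gender, employment) whose
known row sums anchor the unit tests.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from importlib import resources

import numpy as np
import pandas as pd

from .mgm import PairwiseNetwork

__all__ = [
    "CentralityReport",
    "strength",
    "network_summary",
    "load_reference_network",
]


def _round_half_up(x: float, decimals: int) -> float:
    scale = 10 ** decimals
    return np.floor(x * scale + 0.5) / scale


@dataclass
class CentralityReport:
    """Summary of an estimated network."""

    strength: dict[str, float]
    edge_count: int
    possible_edges: int
    nonzero_fraction_pct: float  # percentage, one decimal
    mean_predictability: float

    def to_dict(self) -> dict:
        return asdict(self)


def strength(network: PairwiseNetwork, node: str) -> float:
    """Sum of absolute edge weights incident to ``node``."""
    if node not in network.node_names:
        raise ValueError(f"unknown node {node!r}")
    i = network.node_names.index(node)
    return float(np.abs(network.weights[i]).sum())


def network_summary(network: PairwiseNetwork) -> CentralityReport:
    """Edge counts, density as a percentage, strengths, mean predictability."""
    p = network.n_nodes
    possible = p * (p - 1) // 2
    triu = np.triu_indices(p, k=1)
    edge_count = int(np.count_nonzero(network.weights[triu]))
    fraction = 100.0 * edge_count / possible if possible else 0.0
    preds = [v for v in network.predictability.values() if not np.isnan(v)]
    return CentralityReport(
        strength={name: strength(network, name) for name in network.node_names},
        edge_count=edge_count,
        possible_edges=possible,
        nonzero_fraction_pct=_round_half_up(fraction, 1),
        mean_predictability=float(np.mean(preds)) if preds else float("nan"),
    )


_REFERENCE_KINDS = {
    "ES": "continuous", "D": "continuous", "ANX": "continuous",
    "M": "continuous", "ADHD": "continuous", "PLEs": "continuous",
    "OCD": "continuous", "Age": "continuous",
    "Ed": "binary", "G": "binary", "Emp": "binary",
}


def load_reference_network(path: str | None = None) -> PairwiseNetwork:
    """Load the packaged published edge-weight matrix as a PairwiseNetwork.

    The fixture is the lower triangle of an empirical 11-node network
    (all edges non-negative) stored as an edge-list CSV; zero rows are
    kept so the full 55-pair triangle round-trips.
    """
    if path is None:
        with resources.files("exponet.data").joinpath("reference_edges.csv").open() as fh:
            df = pd.read_csv(fh)
    else:
        df = pd.read_csv(path)
    names: list[str] = []
    for col in ("node_j", "node_i"):
        for name in df[col]:
            if name not in names:
                names.append(name)
    idx = {n: i for i, n in enumerate(names)}
    p = len(names)
    W = np.zeros((p, p))
    for _, row in df.iterrows():
        i, j = idx[row["node_i"]], idx[row["node_j"]]
        W[i, j] = W[j, i] = float(row["weight"])
    S = np.sign(W)
    return PairwiseNetwork(
        node_names=names,
        node_kinds=[_REFERENCE_KINDS.get(n, "continuous") for n in names],
        weights=W, signs=S,
        metadata={"source": "packaged worked-example fixture"},
    )
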