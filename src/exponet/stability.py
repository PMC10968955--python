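"""Bootstrap accuracy and stability analysis of estimated networks.

Two resampling schemes, both with full re-estimation of the network in
every iteration:

* the non-parametric bootstrap resamples respondents with replacement and
  retains the per-iteration edge weights, giving sampling distributions
  for edge weights and bootstrapped difference tests;
* the case-drop bootstrap re-estimates on subsamples with an increasing
  proportion of respondents removed and correlates the subsample node
  strengths with the full-sample ones.  The correlation-stability
  coefficient (CS-C) is the largest drop proportion at which that
  correlation stays >= 0.7 in >= 95% of iterations; values above 0.25 are
  conventionally considered acceptable.

Iteration seeds are derived from the run seed by a counter-based spawn
scheme, so per-iteration results do not depend on execution order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from typing import Callable, Sequence

import numpy as np

from .mgm import EstimationConfig, MixedDataset, estimate_network
from .metrics import strength

__all__ = [
    "BootstrapRun",
    "StabilityResult",
    "DifferenceTestResult",
    "DEFAULT_DROP_PROPORTIONS",
    "nonparametric_boot",
    "casedrop_boot",
    "cs_coefficient",
    "summarize_stability",
    "difference_test",
]

logger = logging.getLogger(__name__)

#: Case-drop grid, 5% steps up to 75% of the sample removed.
DEFAULT_DROP_PROPORTIONS: tuple[float, ...] = tuple(
    round(0.05 * k, 2) for k in range(1, 16)
)

#: CS-C acceptability rule for network stability.
CS_ACCEPTABILITY_CUTOFF = 0.25

StatKey = str | tuple[str, str]


@dataclass
class BootstrapRun:
    """Per-iteration statistics of one bootstrap execution."""

    mode: str  # "nonparametric" | "casedrop"
    n_iterations: int
    seed: int
    node_names: list[str]
    edge_pairs: list[tuple[str, str]]
    point_edges: np.ndarray  # p(p-1)/2 magnitudes, full-sample estimate
    point_strengths: np.ndarray
    edge_samples: np.ndarray | None = None      # B x n_pairs, NaN = skipped
    strength_samples: np.ndarray | None = None  # B x p, NaN = skipped
    drop_proportions: tuple[float, ...] = ()
    correlations: dict[float, np.ndarray] = dc_field(default_factory=dict)
    n_skipped: int = 0

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        props = list(self.drop_proportions)
        if props and (sorted(props) != props or len(set(props)) != len(props)
                      or min(props) <= 0 or max(props) >= 1):
            raise ValueError("drop proportions must be strictly increasing in (0, 1)")

    def _edge_column(self, pair: tuple[str, str]) -> int:
        key = frozenset(pair)
        for i, p in enumerate(self.edge_pairs):
            if frozenset(p) == key:
                return i
        raise KeyError(f"unknown edge {pair!r}")

    def statistic_samples(self, key: StatKey) -> np.ndarray:
        """Bootstrap draws of an edge weight (name pair) or node strength (name)."""
        if isinstance(key, tuple):
            if self.edge_samples is None:
                raise ValueError("run holds no edge samples")
            return self.edge_samples[:, self._edge_column(key)]
        if self.strength_samples is None:
            raise ValueError("run holds no strength samples")
        try:
            return self.strength_samples[:, self.node_names.index(key)]
        except ValueError:
            raise KeyError(f"unknown node {key!r}") from None


def _upper_pairs(names: Sequence[str]) -> list[tuple[str, str]]:
    return [(names[i], names[j])
            for i in range(len(names)) for j in range(i + 1, len(names))]


def _condense(weights: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(weights.shape[0], k=1)
    return weights[iu]


def _has_degenerate_column(data: MixedDataset, rows: np.ndarray) -> str | None:
    sub = data.values[rows]
    for j, name in enumerate(data.names):
        col = sub[:, j]
        if col.min() == col.max():
            return name
    return None


def _iteration_rng(seed: int, *counters: int) -> np.random.Generator:
    # counter-based: result for iteration i is independent of execution order
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=counters))


def nonparametric_boot(
    data: MixedDataset,
    config: EstimationConfig | None = None,
    B: int = 1000,
    seed: int = 0,
    resampler: Callable[[np.random.Generator, int], np.ndarray] | None = None,
) -> BootstrapRun:
    """Resample respondents with replacement, re-estimating the network B times.

    Iterations whose resample leaves a column constant are skipped and
    logged (their rows are NaN in the retained sample matrices), never
    silently imputed.  ``resampler`` may override the with-replacement draw
    (it receives the iteration generator and n and returns row indices).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    cfg = config or EstimationConfig()
    full = estimate_network(data, cfg)
    names = data.names
    pairs = _upper_pairs(names)
    point_edges = _condense(full.weights)
    point_strengths = np.array([strength(full, n) for n in names])

    edge_samples = np.full((B, len(pairs)), np.nan)
    strength_samples = np.full((B, len(names)), np.nan)
    n = data.n_rows
    n_skipped = 0
    for i in range(B):
        rng = _iteration_rng(seed, i)
        rows = resampler(rng, n) if resampler is not None \
            else rng.integers(0, n, size=n)
        bad = _has_degenerate_column(data, rows)
        if bad is not None:
            logger.warning("bootstrap iteration %d skipped: column %r constant "
                           "in resample", i, bad)
            n_skipped += 1
            continue
        net = estimate_network(data.take_rows(rows), cfg)
        edge_samples[i] = _condense(net.weights)
        strength_samples[i] = [strength(net, name) for name in names]

    return BootstrapRun(
        mode="nonparametric", n_iterations=B, seed=seed,
        node_names=list(names), edge_pairs=pairs,
        point_edges=point_edges, point_strengths=point_strengths,
        edge_samples=edge_samples, strength_samples=strength_samples,
        n_skipped=n_skipped,
    )


def casedrop_boot(
    data: MixedDataset,
    config: EstimationConfig | None = None,
    proportions: Sequence[float] = DEFAULT_DROP_PROPORTIONS,
    B: int = 1000,
    seed: int = 0,
) -> BootstrapRun:
    """Case-drop bootstrap of node-strength stability.

    For each drop proportion, B subsamples without replacement retain
    (1 - proportion) * n rows; each subsample's strength vector is
    Pearson-correlated with the full-sample strengths.  Correlations are
    NaN (flagged, excluded from quantiles) when either strength vector is
    constant; proportions leaving fewer than p + 1 rows are skipped with a
    warning.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    props = sorted(float(d) for d in proportions)
    if not props or min(props) <= 0 or max(props) >= 1:
        raise ValueError("proportions must lie strictly inside (0, 1)")
    cfg = config or EstimationConfig()
    full = estimate_network(data, cfg)
    names = data.names
    s0 = np.array([strength(full, n) for n in names])
    n, p = data.n_rows, data.n_cols

    correlations: dict[float, np.ndarray] = {}
    kept_props: list[float] = []
    n_skipped = 0
    for k, d in enumerate(props):
        m = int(round((1 - d) * n))
        if m < p + 1:
            logger.warning("drop proportion %.2f skipped: subsample of %d rows "
                           "is below p + 1 = %d", d, m, p + 1)
            continue
        kept_props.append(d)
        corr = np.full(B, np.nan)
        for i in range(B):
            rng = _iteration_rng(seed, k, i)
            rows = rng.choice(n, size=m, replace=False)
            if _has_degenerate_column(data, rows) is not None:
                n_skipped += 1
                continue
            net = estimate_network(data.take_rows(rows), cfg)
            s = np.array([strength(net, name) for name in names])
            if s.std() == 0 or s0.std() == 0:
                n_skipped += 1
                continue  # correlation undefined; iteration flagged
            corr[i] = np.corrcoef(s, s0)[0, 1]
        correlations[d] = corr

    return BootstrapRun(
        mode="casedrop", n_iterations=B, seed=seed,
        node_names=list(names), edge_pairs=_upper_pairs(names),
        point_edges=_condense(full.weights), point_strengths=s0,
        drop_proportions=tuple(kept_props), correlations=correlations,
        n_skipped=n_skipped,
    )


def cs_coefficient(run: BootstrapRun, correlation_threshold: float = 0.7,
                   probability_level: float = 0.95) -> float:
    """Correlation-stability coefficient of a case-drop run.

    The largest drop proportion at which the fraction of (retained)
    iterations with correlation >= ``correlation_threshold`` is at least
    ``probability_level``; 0.0 if no proportion qualifies.
    """
    if run.mode != "casedrop":
        raise ValueError("CS coefficient requires a case-drop run")
    if not run.correlations:
        raise ValueError("empty bootstrap run")
    cs = 0.0
    for d in run.drop_proportions:
        corr = run.correlations[d]
        valid = corr[~np.isnan(corr)]
        if valid.size == 0:
            continue
        if np.mean(valid >= correlation_threshold) >= probability_level:
            cs = max(cs, d)
    return cs


@dataclass
class StabilityResult:
    """CS coefficient with its per-proportion correlation quantiles."""

    cs_coefficient: float
    correlation_threshold: float
    probability_level: float
    quantiles: dict[float, dict[str, float]]  # proportion -> {q05, median, q95}
    cs_acceptable: bool  # CS-C > 0.25 acceptability rule

    def to_dict(self) -> dict:
        return {
            "cs_coefficient": self.cs_coefficient,
            "correlation_threshold": self.correlation_threshold,
            "probability_level": self.probability_level,
            "cs_acceptable": self.cs_acceptable,
            "quantiles": {str(k): v for k, v in self.quantiles.items()},
        }


def summarize_stability(run: BootstrapRun, correlation_threshold: float = 0.7,
                        probability_level: float = 0.95) -> StabilityResult:
    cs = cs_coefficient(run, correlation_threshold, probability_level)
    quantiles = {}
    for d in run.drop_proportions:
        corr = run.correlations[d]
        valid = corr[~np.isnan(corr)]
        if valid.size == 0:
            quantiles[d] = {"q05": float("nan"), "median": float("nan"),
                            "q95": float("nan")}
        else:
            q05, med, q95 = np.quantile(valid, [0.05, 0.5, 0.95])
            quantiles[d] = {"q05": float(q05), "median": float(med),
                            "q95": float(q95)}
    return StabilityResult(
        cs_coefficient=cs,
        correlation_threshold=correlation_threshold,
        probability_level=probability_level,
        quantiles=quantiles,
        cs_acceptable=cs > CS_ACCEPTABILITY_CUTOFF,
    )


@dataclass
class DifferenceTestResult:
    significant: bool
    lower: float
    upper: float
    alpha: float
    n_retained: int
    warning: str | None = None

    @property
    def verdict(self) -> str:
        return "significant" if self.significant else "not_significant"


def difference_test(run: BootstrapRun, statistic_a: StatKey,
                    statistic_b: StatKey, alpha: float = 0.05) -> DifferenceTestResult:
    """Bootstrapped difference test between two edge weights or strengths.

    Significant iff the two-sided (1 - alpha) percentile interval of the
    per-iteration difference excludes zero.  A precision warning is
    attached when fewer than 100 iterations were retained.
    """
    a = run.statistic_samples(statistic_a)
    b = run.statistic_samples(statistic_b)
    diffs = a - b
    diffs = diffs[~np.isnan(diffs)]
    if diffs.size == 0:
        raise ValueError("no retained iterations for the requested statistics")
    lower, upper = np.quantile(diffs, [alpha / 2, 1 - alpha / 2])
    warning = None
    if diffs.size < 100:
        warning = (f"only {diffs.size} retained iterations; "
                   "percentile interval is imprecise")
    return DifferenceTestResult(
        significant=bool(lower > 0 or upper < 0),
        lower=float(lower), upper=float(upper), alpha=alpha,
        n_retained=int(diffs.size), warning=warning,
    )
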