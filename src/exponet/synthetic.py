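"""Synthetic survey cohorts and samples from known mixed graphical models.

The participant data behind the exposome–psychopathology network are not
public, so this module provides the two substitutes the rest of the package
is exercised with:

* :func:`generate_cohort` draws respondent-level raw survey answers whose
  binarized exposure prevalences, symptom-score moments and missingness
  rates are calibrated to requested marginals (defaults mirror a community
  sample of 1100 young adults);
* :func:`sample_mgm` draws exact-in-distribution samples from a known
  pairwise mixed graphical model (MGM) — a Markov random field whose
  continuous nodes have linear-Gaussian and binary nodes logistic full
  conditionals — so that network-estimation code can be tested against a
  known ground truth;
* :func:`inject_dependence` re-samples chosen cohort columns from such a
  model while moment-matching their marginals, coupling exposures and
  symptoms so the estimated network has recoverable edges.

Sampling uses a parallel-chain Gibbs scheme: each of the ``n`` requested
rows is an independent chain run for ``burn_in + thin`` full sweeps, which
vectorizes across rows and returns independent draws.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, logit

from .mgm import MixedDataset

__all__ = [
    "TrueGraph",
    "CohortSpec",
    "INSTRUMENT_RANGES",
    "DEFAULT_PREVALENCES",
    "DEFAULT_SYMPTOM_MARGINALS",
    "DEFAULT_MISSINGNESS",
    "sample_mgm",
    "generate_cohort",
    "inject_dependence",
    "make_recovery_graph",
]


class GraphValidationError(ValueError):
    """Invalid graph specification (asymmetry, shape mismatch, bad variance)."""


class GraphModelError(ValueError):
    """Structurally valid graph that defines an improper joint distribution."""


# ---------------------------------------------------------------------------
# Ground-truth graphs
# ---------------------------------------------------------------------------


@dataclass
class TrueGraph:
    """A known pairwise MGM used as ground truth.

    ``interaction_matrix[s, t]`` is the pairwise coupling between nodes
    ``s`` and ``t`` (symmetric, zero diagonal).  Continuous node ``s`` has
    full conditional N(sigma_s^2 * (threshold_s + sum_t J_st x_t),
    sigma_s^2); binary node ``s`` (0/1 coded) has
    P(x_s = 1 | rest) = sigmoid(threshold_s + sum_t J_st x_t).
    """

    node_specs: list[tuple[str, str]]  # (name, "continuous" | "binary")
    interaction_matrix: np.ndarray
    node_thresholds: np.ndarray | None = None
    continuous_variances: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        p = len(self.node_specs)
        J = np.asarray(self.interaction_matrix, dtype=float)
        if J.shape != (p, p):
            raise GraphValidationError(
                f"interaction matrix shape {J.shape} does not match {p} nodes"
            )
        if not np.allclose(J, J.T, atol=1e-12):
            raise GraphValidationError("interaction matrix must be symmetric")
        if np.any(np.diag(J) != 0):
            raise GraphValidationError("interaction matrix diagonal must be zero")
        self.interaction_matrix = J
        if self.node_thresholds is None:
            self.node_thresholds = np.zeros(p)
        else:
            self.node_thresholds = np.asarray(self.node_thresholds, dtype=float)
            if self.node_thresholds.shape != (p,):
                raise GraphValidationError("thresholds must have one entry per node")
        for name, kind in self.node_specs:
            if kind not in ("continuous", "binary"):
                raise GraphValidationError(f"node {name!r}: unknown type {kind!r}")
        variances = dict(self.continuous_variances or {})
        for name, kind in self.node_specs:
            if kind == "continuous":
                v = variances.setdefault(name, 1.0)
                if not v > 0:
                    raise GraphValidationError(
                        f"continuous variance for node {name!r} must be positive"
                    )
        self.continuous_variances = variances
        self._check_proper()

    # The joint density over the continuous block (binary nodes fixed) is
    # Gaussian with precision K, K_ss = 1/sigma_s^2, K_st = -J_st.  If K is
    # not positive definite the joint is improper and Gibbs diverges.
    def _check_proper(self) -> None:
        cont = [i for i, (_, k) in enumerate(self.node_specs) if k == "continuous"]
        if not cont:
            return
        J = self.interaction_matrix[np.ix_(cont, cont)]
        K = -J
        for pos, i in enumerate(cont):
            K[pos, pos] = 1.0 / self.continuous_variances[self.node_specs[i][0]]
        eigvals = np.linalg.eigvalsh(K)
        if eigvals.min() <= 1e-12:
            # name the node whose leading principal minor first fails
            for m in range(1, len(cont) + 1):
                if np.linalg.det(K[:m, :m]) <= 0:
                    bad = self.node_specs[cont[m - 1]][0]
                    break
            else:  # pragma: no cover - eigvals and minors disagree only numerically
                bad = self.node_specs[cont[0]][0]
            raise GraphModelError(
                f"continuous block is not positive definite near node {bad!r}: "
                "a conditional variance becomes non-positive"
            )

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.node_specs]

    @property
    def n_nodes(self) -> int:
        return len(self.node_specs)

    def edges(self, tol: float = 0.0) -> list[tuple[str, str, float]]:
        """Non-zero couplings as (name_i, name_j, value), i < j in node order."""
        out = []
        J = self.interaction_matrix
        for i in range(self.n_nodes):
            for j in range(i + 1, self.n_nodes):
                if abs(J[i, j]) > tol:
                    out.append((self.names[i], self.names[j], float(J[i, j])))
        return out

    def to_json(self, path: str) -> None:
        payload = {
            "nodes": [{"name": n, "type": k} for n, k in self.node_specs],
            "interaction_matrix": self.interaction_matrix.tolist(),
            "thresholds": self.node_thresholds.tolist(),
            "continuous_variances": dict(self.continuous_variances),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path: str) -> "TrueGraph":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            node_specs=[(d["name"], d["type"]) for d in payload["nodes"]],
            interaction_matrix=np.asarray(payload["interaction_matrix"]),
            node_thresholds=np.asarray(payload["thresholds"]),
            continuous_variances=payload["continuous_variances"],
        )


def sample_mgm(
    graph: TrueGraph,
    n: int,
    burn_in: int = 1000,
    thin: int = 10,
    seed: int | None = None,
    thresholds: np.ndarray | None = None,
) -> MixedDataset:
    """Draw ``n`` independent samples from a pairwise mixed graphical model.

    Runs ``n`` parallel Gibbs chains for ``burn_in + thin`` full sweeps and
    returns the final state of each chain, so rows are independent draws.
    Deterministic given ``seed``.
    """
    if n <= 0 or burn_in <= 0 or thin <= 0:
        raise ValueError("n, burn_in and thin must be positive")
    rng = np.random.default_rng(seed)
    p = graph.n_nodes
    J = graph.interaction_matrix
    theta = np.asarray(thresholds, dtype=float) if thresholds is not None \
        else graph.node_thresholds
    kinds = [k for _, k in graph.node_specs]
    sigma = np.array(
        [np.sqrt(graph.continuous_variances[name]) if kind == "continuous" else 0.0
         for (name, kind) in graph.node_specs]
    )

    X = np.empty((n, p))
    for s in range(p):
        if kinds[s] == "continuous":
            X[:, s] = rng.normal(0.0, sigma[s], size=n)
        else:
            X[:, s] = rng.random(n) < expit(theta[s])

    for _ in range(burn_in + thin):
        for s in range(p):
            eta = theta[s] + X @ J[:, s]  # J[s, s] == 0
            if kinds[s] == "continuous":
                X[:, s] = rng.normal(sigma[s] ** 2 * eta, sigma[s])
            else:
                X[:, s] = rng.random(n) < expit(eta)

    return MixedDataset.from_arrays(graph.names, kinds, X)


def make_recovery_graph() -> TrueGraph:
    """The canonical 11-node ground-truth MGM for estimator-recovery runs.

    Six continuous and five binary nodes with ten true edges of standardized
    magnitude 0.25–0.45; coupling sizes are chosen so each edge carries at
    least roughly five standard errors of signal at n = 2000, and the
    continuous block stays positive definite.
    """
    specs = [(f"c{i}", "continuous") for i in range(1, 7)] + \
            [(f"b{i}", "binary") for i in range(1, 6)]
    names = [n for n, _ in specs]
    idx = {n: i for i, n in enumerate(names)}
    J = np.zeros((11, 11))
    true_edges = [
        ("c1", "c2", 0.30), ("c2", "c3", 0.25), ("c3", "c4", 0.30),
        ("c4", "c5", 0.25), ("c5", "c6", 0.30),
        ("c1", "b1", 0.35), ("c3", "b2", 0.30), ("c5", "b3", 0.35),
        ("b1", "b4", 0.45), ("b2", "b5", 0.45),
    ]
    for a, b, w in true_edges:
        J[idx[a], idx[b]] = J[idx[b], idx[a]] = w
    return TrueGraph(node_specs=specs, interaction_matrix=J)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

#: Score range (min, max) of each symptom instrument.
INSTRUMENT_RANGES: dict[str, tuple[int, int]] = {
    "pq16": (0, 16),
    "gad7": (0, 21),
    "phq9": (0, 27),
    "mdq": (0, 13),
    "ocir": (0, 72),
    "asrs5": (0, 24),
}

DEFAULT_PREVALENCES: dict[str, float] = {
    "winter_birth": 0.245,
    "obstetric_complications": 0.319,
    "advanced_paternal_age": 0.248,
    "non_right_handedness": 0.097,
    "emotional_neglect": 0.524,
    "emotional_abuse": 0.434,
    "bullying": 0.539,
    "sexual_abuse": 0.212,
    "cannabis_use": 0.065,
    "urban_upbringing": 0.611,
}

DEFAULT_SYMPTOM_MARGINALS: dict[str, tuple[float, float, int, int]] = {
    "pq16": (5.3, 4.0, 0, 16),
    "gad7": (7.6, 5.5, 0, 21),
    "phq9": (9.4, 6.2, 0, 27),
    "mdq": (5.5, 3.7, 0, 13),
    "ocir": (22.3, 14.7, 0, 72),
    "asrs5": (10.1, 4.3, 0, 24),
}

DEFAULT_COVARIATES: dict[str, object] = {
    "age": (27.1, 5.1, 18, 35),
    "gender_male": 0.486,
    "education": {"primary": 0.055, "vocational": 0.081,
                  "secondary": 0.503, "higher": 0.361},
    "employment": {"unemployed": 0.149, "part_time": 0.155,
                   "student": 0.184, "full_time": 0.513},
}

DEFAULT_MISSINGNESS: dict[str, float] = {
    "paternal_age": 0.182,
    "obstetric_complications": 0.215,
}

RESIDENCE_URBAN_SPLIT = {"city_le_100k": 0.60, "city_200k_500k": 0.18,
                         "city_gt_500k": 0.22}


@dataclass
class CohortSpec:
    """Marginal targets for a synthetic respondent cohort."""

    n_respondents: int = 1100
    exposure_prevalences: dict[str, float] = dc_field(
        default_factory=lambda: dict(DEFAULT_PREVALENCES))
    symptom_marginals: dict[str, tuple[float, float, int, int]] = dc_field(
        default_factory=lambda: dict(DEFAULT_SYMPTOM_MARGINALS))
    covariate_marginals: dict[str, object] = dc_field(
        default_factory=lambda: dict(DEFAULT_COVARIATES))
    missingness: dict[str, float] = dc_field(
        default_factory=lambda: dict(DEFAULT_MISSINGNESS))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_respondents <= 0:
            raise ValueError("n_respondents must be positive")
        for name, p in {**self.exposure_prevalences, **self.missingness}.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability for {name!r} outside [0, 1]: {p}")
        for scale, (mean, sd, lo, hi) in self.symptom_marginals.items():
            if scale in INSTRUMENT_RANGES and (lo, hi) != INSTRUMENT_RANGES[scale]:
                raise ValueError(
                    f"{scale}: range ({lo}, {hi}) does not match the instrument "
                    f"range {INSTRUMENT_RANGES[scale]}"
                )
            if not lo < hi:
                raise ValueError(f"{scale}: min must be below max")
            if not lo <= mean <= hi:
                raise ValueError(f"{scale}: mean {mean} outside range [{lo}, {hi}]")
            if not sd > 0:
                raise ValueError(f"{scale}: sd must be positive")


def _clipped_normal_mean(mu: float, sd: float, lo: float, hi: float) -> float:
    a, b = (lo - mu) / sd, (hi - mu) / sd
    return (lo * stats.norm.cdf(a)
            + hi * stats.norm.sf(b)
            + mu * (stats.norm.cdf(b) - stats.norm.cdf(a))
            + sd * (stats.norm.pdf(a) - stats.norm.pdf(b)))


def _solve_latent_mean(target: float, sd: float, lo: float, hi: float) -> float:
    """Latent normal mean whose clipped expectation equals ``target``.

    Clipping to the instrument range pulls the mean inward; solving the
    location keeps generated sample means on target (rounding to integers
    is mean-neutral to first order).
    """
    f = lambda mu: _clipped_normal_mean(mu, sd, lo, hi) - target
    span = max(4 * sd, hi - lo)
    return optimize.brentq(f, lo - span, hi + span, xtol=1e-9)


def _solve_paternal_loc(prevalence: float, sd: float = 6.0,
                        lo: float = 16.0, hi: float = 70.0,
                        cut: float = 35.0) -> float:
    """Location of the truncated-normal paternal-age law hitting P(age>=35)."""
    def tail(mu: float) -> float:
        a, b, c = (lo - mu) / sd, (hi - mu) / sd, (cut - mu) / sd
        denom = stats.norm.cdf(b) - stats.norm.cdf(a)
        return (stats.norm.cdf(b) - stats.norm.cdf(c)) / denom - prevalence
    return optimize.brentq(tail, lo, cut + 3 * sd, xtol=1e-9)


def _yesno(mask: np.ndarray) -> np.ndarray:
    return np.where(mask, "yes", "no")


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Generate a raw-answer cohort table calibrated to the spec marginals.

    Columns are the unscored survey answers (month of birth, three
    obstetric-complication items, paternal age, handedness, trauma screens,
    eleven cannabis-problem items, residence category), the six symptom
    sum-scores, and the covariates.  Missing cells are NaN / empty;
    "don't know" obstetric answers are stored verbatim as ``dont_know``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_respondents
    prev = spec.exposure_prevalences
    miss = spec.missingness
    df = pd.DataFrame({"respondent_id": np.arange(n)})

    # month of birth: uniform within winter / non-winter, re-weighted so the
    # winter prevalence matches the target
    w = prev["winter_birth"]
    month_probs = np.full(12, (1 - w) / 9)
    for m in (12, 1, 2):
        month_probs[m - 1] = w / 3
    df["month"] = rng.choice(np.arange(1, 13), size=n, p=month_probs)

    # obstetric complications: three yes/no items, independent with item
    # probability solving 1-(1-q)^3 = prevalence; an MCAR fraction of
    # respondents answers "don't know" to all three items
    p_oc = prev["obstetric_complications"]
    q = 1 - (1 - p_oc) ** (1 / 3)
    oc = rng.random((n, 3)) < q
    oc_missing = rng.random(n) < miss.get("obstetric_complications", 0.0)
    for j, col in enumerate(("oc_csection", "oc_low_weight", "oc_preterm")):
        df[col] = np.where(oc_missing, "dont_know", _yesno(oc[:, j]))

    # paternal age: truncated normal, sd 6 on [16, 70], location solved so
    # P(age >= 35) matches the advanced-paternal-age prevalence
    p_apa = prev["advanced_paternal_age"]
    loc = _solve_paternal_loc(p_apa)
    a, b = (16 - loc) / 6.0, (70 - loc) / 6.0
    ages = stats.truncnorm.rvs(a, b, loc=loc, scale=6.0, size=n, random_state=rng)
    ages = np.round(ages, 1)
    pa_missing = rng.random(n) < miss.get("paternal_age", 0.0)
    df["paternal_age"] = np.where(pa_missing, np.nan, ages)

    # handedness: non-right split 2:1 between left and mixed
    p_nr = prev["non_right_handedness"]
    df["handedness"] = rng.choice(
        ["right", "left", "mixed"], size=n,
        p=[1 - p_nr, 2 * p_nr / 3, p_nr / 3])

    for comp in ("emotional_neglect", "emotional_abuse", "bullying", "sexual_abuse"):
        vals = _yesno(rng.random(n) < prev[comp])
        m = miss.get(comp, 0.0)
        if m > 0:
            vals = np.where(rng.random(n) < m, "", vals)
        df[comp] = vals

    # cannabis: 11 problem items, independent, any "yes" marks the exposure
    q_cpq = 1 - (1 - prev["cannabis_use"]) ** (1 / 11)
    for i in range(1, 12):
        df[f"cpq_{i:02d}"] = _yesno(rng.random(n) < q_cpq)

    p_urb = prev["urban_upbringing"]
    levels = ["rural"] + list(RESIDENCE_URBAN_SPLIT)
    probs = [1 - p_urb] + [p_urb * f for f in RESIDENCE_URBAN_SPLIT.values()]
    df["residence"] = rng.choice(levels, size=n, p=np.asarray(probs) / np.sum(probs))

    # covariates
    cov = spec.covariate_marginals
    mean, sd, lo, hi = cov["age"]
    mu = _solve_latent_mean(mean, sd, lo, hi)
    df["age"] = np.clip(np.round(rng.normal(mu, sd, size=n)), lo, hi).astype(int)
    df["gender"] = np.where(rng.random(n) < cov["gender_male"], "male", "female")
    for name in ("education", "employment"):
        dist: dict[str, float] = cov[name]  # type: ignore[assignment]
        lv, pr = list(dist), np.asarray(list(dist.values()), dtype=float)
        df[name] = rng.choice(lv, size=n, p=pr / pr.sum())

    # symptom sum-scores: latent normal with location solved so the clipped
    # expectation hits the target mean; rounded and truncated to range
    for scale, (mean, sd, lo, hi) in spec.symptom_marginals.items():
        mu = _solve_latent_mean(mean, sd, lo, hi)
        raw = rng.normal(mu, sd, size=n)
        vals = np.clip(np.round(raw), lo, hi).astype(float)
        m = miss.get(scale, 0.0)
        if m > 0:
            vals[rng.random(n) < m] = np.nan
        df[scale] = vals

    return df


# ---------------------------------------------------------------------------
# Dependence injection
# ---------------------------------------------------------------------------


def inject_dependence(
    cohort: pd.DataFrame,
    graph: TrueGraph,
    seed: int | None = None,
    burn_in: int = 300,
    calibration_rounds: int = 40,
    calibration_n: int = 4000,
) -> pd.DataFrame:
    """Re-sample the graph's columns from the MGM, moment-matched marginally.

    The named columns are replaced by a joint draw from ``graph`` whose
    couplings act on the standardized scale: continuous columns are
    affine-rescaled to the original column mean/sd (exact moment match),
    binary columns have their model thresholds calibrated by damped
    stochastic approximation so prevalences drift by well under two
    percentage points.  All other columns are left untouched, so the
    result is a cohort with known conditional-dependence structure.
    """
    missing_cols = [name for name in graph.names if name not in cohort.columns]
    if missing_cols:
        raise GraphValidationError(
            f"graph nodes absent from cohort columns: {missing_cols}"
        )
    rng = np.random.default_rng(seed)
    n = len(cohort)
    kinds = dict(graph.node_specs)

    targets_mean, targets_sd, targets_p = {}, {}, {}
    for name in graph.names:
        col = pd.to_numeric(cohort[name], errors="coerce")
        if col.isna().any():
            raise GraphValidationError(
                f"column {name!r} must be numeric and complete for injection"
            )
        if kinds[name] == "binary":
            vals = set(np.unique(col))
            if not vals <= {0.0, 1.0}:
                raise GraphValidationError(f"binary column {name!r} must be 0/1")
            targets_p[name] = float(np.clip(col.mean(), 1e-4, 1 - 1e-4))
        else:
            targets_mean[name] = float(col.mean())
            targets_sd[name] = float(col.std(ddof=0)) or 1.0

    # calibrate binary thresholds by damped Robbins-Monro on the logit scale
    theta = np.array(
        [logit(targets_p[name]) if kinds[name] == "binary" else 0.0
         for name in graph.names]
    )
    binary_idx = [i for i, name in enumerate(graph.names) if kinds[name] == "binary"]
    if binary_idx and graph.edges():
        for r in range(calibration_rounds):
            ds = sample_mgm(graph, calibration_n, burn_in=60, thin=1,
                            seed=int(rng.integers(2**31)), thresholds=theta)
            phat = np.clip(ds.values.mean(axis=0), 1e-4, 1 - 1e-4)
            step = 0.8 / (1 + r / 20)
            for i in binary_idx:
                name = graph.names[i]
                theta[i] += step * (logit(targets_p[name]) - logit(phat[i]))

    ds = sample_mgm(graph, n, burn_in=burn_in, thin=1,
                    seed=int(rng.integers(2**31)), thresholds=theta)
    out = cohort.copy()
    for j, name in enumerate(graph.names):
        col = ds.values[:, j]
        if kinds[name] == "continuous":
            mu, sd = col.mean(), col.std() or 1.0
            col = (col - mu) / sd * targets_sd[name] + targets_mean[name]
        out[name] = col
    return out
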