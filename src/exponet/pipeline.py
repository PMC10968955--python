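"""Configuration, file round-tripping and end-to-end orchestration.

The pipeline chains the analysis stages: simulate (or load) a respondent
cohort, score the exposome, assemble the 11-node mixed dataset (six
symptom scales + ES + age as continuous nodes; education, gender and
employment binarized), estimate the network, summarize centrality, and
run the bootstrap stability analysis.  Every numeric artifact is traceable
to the run manifest (config hash + seed + library versions), and re-running
with the same config and seed reproduces byte-identical outputs.

Files: cohorts and edge lists as CSV (UTF-8, missing cell = empty string,
"don't know" answers preserved verbatim as the ``dont_know`` level),
reports as JSON, config as YAML, network export as GraphML.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .exposome import load_weight_table, score_cohort
from .mgm import EstimationConfig, MixedDataset, estimate_network
from .metrics import load_reference_network, network_summary
from .stability import (casedrop_boot, difference_test, nonparametric_boot,
                        summarize_stability)
from .synthetic import CohortSpec, TrueGraph, generate_cohort, inject_dependence

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "DEFAULT_NODE_TYPES",
    "load_config",
    "read_cohort",
    "write_cohort",
    "prepare_network_data",
    "run_pipeline",
]

#: Default network variables: symptom scales, ES and age continuous;
#: education (higher vs other), gender (male vs female) and employment
#: (employed vs not) binary.
DEFAULT_NODE_TYPES: dict[str, str] = {
    "es": "continuous",
    "phq9": "continuous",
    "gad7": "continuous",
    "mdq": "continuous",
    "asrs5": "continuous",
    "pq16": "continuous",
    "ocir": "continuous",
    "age": "continuous",
    "education": "binary",
    "gender": "binary",
    "employment": "binary",
}

#: Raw cohort columns the generator emits (besides the respondent id).
RAW_COLUMNS = (
    ["month", "oc_csection", "oc_low_weight", "oc_preterm", "paternal_age",
     "handedness", "emotional_neglect", "emotional_abuse", "bullying",
     "sexual_abuse"]
    + [f"cpq_{i:02d}" for i in range(1, 12)]
    + ["residence", "age", "gender", "education", "employment",
       "pq16", "gad7", "phq9", "mdq", "ocir", "asrs5"]
)

_EMPLOYED_LEVELS = frozenset({"part_time", "full_time"})


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs; loadable from YAML."""

    simulate: bool = True
    cohort: CohortSpec = dc_field(default_factory=CohortSpec)
    true_graph_path: str | None = None
    input_csv: str | None = None
    weights_path: str | None = None
    denominator_policy: str = "fixed_total"
    node_types: dict[str, str] = dc_field(
        default_factory=lambda: dict(DEFAULT_NODE_TYPES))
    estimation: EstimationConfig = dc_field(default_factory=EstimationConfig)
    bootstrap_B: int = 1000
    casedrop_B: int = 1000
    drop_proportions: tuple[float, ...] = tuple(
        round(0.05 * k, 2) for k in range(1, 16))
    run_bootstrap: bool = True
    output_dir: str = "exponet_out"
    seed: int = 0
    log_level: str = "INFO"

    def to_canonical_yaml(self) -> str:
        d = dataclasses.asdict(self)
        d["cohort"] = dataclasses.asdict(self.cohort)
        d["estimation"] = dataclasses.asdict(self.estimation)
        d["drop_proportions"] = list(self.drop_proportions)
        return yaml.safe_dump(d, sort_keys=True)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_canonical_yaml().encode()).hexdigest()[:16]


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = PipelineConfig()
    cohort_block = raw.pop("cohort", {})
    if cohort_block:
        spec_kwargs = {}
        if "n" in cohort_block:
            spec_kwargs["n_respondents"] = int(cohort_block["n"])
        if "seed" in cohort_block:
            spec_kwargs["seed"] = int(cohort_block["seed"])
        defaults = CohortSpec()
        for yaml_key, attr in (("prevalences", "exposure_prevalences"),
                               ("symptom_marginals", "symptom_marginals"),
                               ("missingness", "missingness")):
            merged = dict(getattr(defaults, attr))
            merged.update({
                k: tuple(v) if isinstance(v, list) else v
                for k, v in cohort_block.get(yaml_key, {}).items()
            })
            spec_kwargs[attr] = merged
        cfg.cohort = CohortSpec(**spec_kwargs)
    est_block = raw.pop("estimation", {})
    if est_block:
        cfg.estimation = EstimationConfig(**est_block)
    boot_block = raw.pop("bootstrap", {})
    if boot_block:
        cfg.bootstrap_B = int(boot_block.get("B", cfg.bootstrap_B))
        cfg.casedrop_B = int(boot_block.get("casedrop_B", cfg.casedrop_B))
        if "proportions" in boot_block:
            cfg.drop_proportions = tuple(float(x) for x in boot_block["proportions"])
        cfg.run_bootstrap = bool(boot_block.get("enabled", cfg.run_bootstrap))
    if "nodes" in raw:
        cfg.node_types = dict(raw.pop("nodes"))
    for key, value in raw.items():
        if not hasattr(cfg, key):
            logger.warning("unknown config key %r ignored", key)
            continue
        setattr(cfg, key, value)
    return cfg


# ---------------------------------------------------------------------------
# Cohort file round-tripping
# ---------------------------------------------------------------------------


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort CSV: one row per respondent, missing cell = empty."""
    cohort.to_csv(path, index=False, na_rep="")


def read_cohort(
    path: str | Path,
    variable_spec: dict[str, str] | None = None,
    denominator_policy: str = "fixed_total",
    weights_path: str | None = None,
) -> tuple[MixedDataset, pd.DataFrame]:
    """Read a raw cohort CSV and assemble the typed network dataset.

    Returns the complete-case :class:`MixedDataset` over the network
    variables plus the full raw table.  The exposome score is computed on
    the fly when the spec requests an ``es`` node that is not already a
    column.  Rows missing any network variable are listwise-deleted with a
    logged count; ES scoring itself tolerates missing exposure components,
    so a respondent with an undetermined exposure still receives a score.
    Unknown columns are ignored with a warning; an empty file is an error.
    """
    variable_spec = dict(variable_spec or DEFAULT_NODE_TYPES)
    try:
        raw = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise PipelineError(f"cohort file {path} is empty") from None
    if raw.empty:
        raise PipelineError(f"cohort file {path} contains no rows")
    known = set(RAW_COLUMNS) | set(variable_spec) | {"respondent_id"}
    unknown = [c for c in raw.columns if c not in known]
    if unknown:
        logger.warning("ignoring unknown cohort columns: %s", unknown)
        raw = raw.drop(columns=unknown)
    dataset = prepare_network_data(raw, variable_spec, denominator_policy,
                                   weights_path)
    return dataset, raw


def _binarize_covariate(name: str, col: pd.Series) -> pd.Series:
    """Collapse a categorical covariate to the 0/1 coding the network uses."""
    if pd.api.types.is_numeric_dtype(col):
        return col.astype(float)
    text = col.astype(str).str.strip().str.lower()
    text = text.where(~col.isna(), other=None)
    if name == "education":
        return (text == "higher").astype(float).where(col.notna())
    if name == "gender":
        return (text == "male").astype(float).where(col.notna())
    if name == "employment":
        return text.isin(_EMPLOYED_LEVELS).astype(float).where(col.notna())
    raise PipelineError(f"cannot binarize non-numeric column {name!r}")


def prepare_network_data(
    cohort: pd.DataFrame,
    variable_spec: dict[str, str] | None = None,
    denominator_policy: str = "fixed_total",
    weights_path: str | None = None,
) -> MixedDataset:
    """Typed complete-case matrix of the network variables of a cohort."""
    variable_spec = dict(variable_spec or DEFAULT_NODE_TYPES)
    frame = pd.DataFrame(index=cohort.index)
    for node, kind in variable_spec.items():
        if node == "es" and "es" not in cohort.columns:
            weights = load_weight_table(weights_path)
            scored = score_cohort(cohort, weights, denominator_policy)
            frame["es"] = scored["es"].to_numpy()
            continue
        if node not in cohort.columns:
            raise PipelineError(f"network variable {node!r} missing from cohort")
        col = cohort[node]
        if kind == "binary":
            frame[node] = _binarize_covariate(node, col)
        else:
            frame[node] = pd.to_numeric(col, errors="coerce")
    complete = frame.dropna()
    n_dropped = len(frame) - len(complete)
    if n_dropped:
        logger.info("listwise deletion: dropped %d of %d rows with missing "
                    "network variables", n_dropped, len(frame))
    if complete.empty:
        raise PipelineError("no complete cases among the network variables")
    return MixedDataset.from_dataframe(complete, variable_spec)


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


def _write_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, allow_nan=True)


def _dense_matrix_frame(net) -> pd.DataFrame:
    return pd.DataFrame(net.weights, index=net.node_names, columns=net.node_names)


def run_pipeline(config: PipelineConfig,
                 stages: tuple[str, ...] = ("simulate", "score", "estimate",
                                            "report", "bootstrap")) -> Path:
    """Run the configured stages, writing all artifacts plus a manifest.

    Returns the artifact directory.  Hard errors propagate (non-zero exit
    in the CLI); stage completion is recorded in the manifest.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20),
                        format="%(asctime)s %(levelname)s %(name)s: %(message)s")
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash,
        "seed": config.seed,
        "versions": _versions(),
        "stages": {},
    }
    rng = np.random.default_rng(config.seed)

    cohort: pd.DataFrame | None = None
    if "simulate" in stages and config.simulate:
        cohort = generate_cohort(config.cohort)
        if config.true_graph_path:
            graph = TrueGraph.from_json(config.true_graph_path)
            cohort = inject_dependence(cohort, graph,
                                       seed=int(rng.integers(2**31)))
        write_cohort(cohort, outdir / "cohort.csv")
        manifest["stages"]["simulate"] = {"n": len(cohort)}
        logger.info("simulated cohort of %d respondents", len(cohort))
    elif config.input_csv:
        cohort = pd.read_csv(config.input_csv)
        if cohort.empty:
            raise PipelineError("input cohort is empty")

    if cohort is None:
        raise PipelineError("no cohort: enable simulate or provide input_csv")

    if "score" in stages:
        weights = load_weight_table(config.weights_path)
        scored = score_cohort(cohort, weights, config.denominator_policy)
        scored.to_csv(outdir / "exposome_scores.csv", index=False)
        cohort = cohort.assign(es=scored["es"].to_numpy())
        manifest["stages"]["score"] = {
            "mean_es": float(scored["es"].mean()),
            "denominator_policy": config.denominator_policy,
        }

    data = prepare_network_data(cohort, config.node_types,
                                config.denominator_policy, config.weights_path)
    manifest["n_complete_cases"] = data.n_rows

    net = None
    if "estimate" in stages:
        net = estimate_network(data, config.estimation)
        net.edge_list().to_csv(outdir / "edges.csv", index=False)
        _dense_matrix_frame(net).to_csv(outdir / "weight_matrix.csv")
        pd.DataFrame({
            "node": net.node_names,
            "predictability": [net.predictability.get(n) for n in net.node_names],
            "lambda": [net.lambda_per_node.get(n) for n in net.node_names],
        }).to_csv(outdir / "predictability.csv", index=False)
        import networkx as nx
        nx.write_graphml(net.to_networkx(), outdir / "network.graphml")
        manifest["stages"]["estimate"] = dict(net.metadata)

    if "report" in stages and net is not None:
        report = network_summary(net)
        _write_json(report.to_dict(), outdir / "centrality.json")
        manifest["stages"]["report"] = {
            "edge_count": report.edge_count,
            "possible_edges": report.possible_edges,
        }

    if "bootstrap" in stages and config.run_bootstrap:
        np_run = nonparametric_boot(data, config.estimation,
                                    B=config.bootstrap_B,
                                    seed=int(rng.integers(2**31)))
        qlo, qmed, qhi = np.nanquantile(
            np_run.edge_samples, [0.025, 0.5, 0.975], axis=0)
        pd.DataFrame({
            "node_i": [a for a, _ in np_run.edge_pairs],
            "node_j": [b for _, b in np_run.edge_pairs],
            "estimate": np_run.point_edges,
            "q025": qlo, "median": qmed, "q975": qhi,
        }).to_csv(outdir / "edge_bootstrap.csv", index=False)

        cd_run = casedrop_boot(data, config.estimation,
                               proportions=config.drop_proportions,
                               B=config.casedrop_B,
                               seed=int(rng.integers(2**31)))
        stab = summarize_stability(cd_run)
        _write_json(stab.to_dict(), outdir / "stability.json")
        manifest["stages"]["bootstrap"] = {
            "B": config.bootstrap_B,
            "casedrop_B": config.casedrop_B,
            "cs_coefficient": stab.cs_coefficient,
            "cs_acceptable": stab.cs_acceptable,
            "skipped_iterations": np_run.n_skipped + cd_run.n_skipped,
        }

    _write_json(manifest, outdir / "manifest.json")
    with open(outdir / "config.yaml", "w") as fh:
        fh.write(config.to_canonical_yaml())
    return outdir


def metrics_report(network_csv: str | None = None) -> dict:
    """Centrality report for a stored edge-list CSV (default: the packaged
    published worked-example network)."""
    net = load_reference_network(network_csv)
    return network_summary(net).to_dict()


def _versions() -> dict[str, str]:
    import sklearn

    return {
        "exponet": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scikit-learn": sklearn.__version__,
    }
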