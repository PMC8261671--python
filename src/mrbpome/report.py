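"""QC statistics and end-to-end pipeline orchestration.

Quality control mirrors what is reported alongside the main analysis:
pairwise Pearson correlations between replicate samples (per method, on log2
normalized values over proteins detected in both samples), correlations
between methods on the average fold-change, and the per-method standard
deviation of the average fold-change.  ``run_pipeline`` chains
preprocess -> differential -> consensus for every method of a run (simulated
or file-based) and ``write_results`` emits a deterministic results directory.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .consensus import integrate_methods
from .core_io import (
    NormalizedDataset,
    QuantDataset,
    read_design,
    read_quant_table,
    write_design,
    write_quant_table,
)
from .differential import DifferentialConfig, NullModel, call_differential
from .errors import ConfigurationError, ValidationError
from .preprocessing import FilterReport, PreprocessConfig, preprocess
from .simulate import (
    GroundTruth,
    RecoveryMetrics,
    SimulationParams,
    simulate_ric_experiment,
    summarize_truth,
)

logger = logging.getLogger(__name__)


def pearson_correlation(x, y) -> float:
    """Product-moment correlation after dropping pairs with a NaN entry.

    Returns NaN when fewer than 3 complete pairs remain or either vector has
    zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("x and y must have equal length")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 3 or x.std() == 0 or y.std() == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def fc_dispersion(table: pd.DataFrame) -> float:
    """Sample standard deviation (n-1) of avg_fc over all retained proteins."""
    if len(table) < 2:
        raise ValidationError("fc_dispersion needs >= 2 proteins")
    return float(table["avg_fc"].std(ddof=1))


def sample_correlation_matrix(norm: NormalizedDataset) -> pd.DataFrame:
    """Pearson r between every pair of samples on log2 normalized values,
    restricted per pair to proteins detected (raw area > 0) in both."""
    ids = norm.sample_ids
    m = len(ids)
    mat = np.ones((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            both = (norm.areas[:, i] > 0) & (norm.areas[:, j] > 0)
            r = pearson_correlation(
                norm.log2_values[both, i], norm.log2_values[both, j]
            )
            mat[i, j] = mat[j, i] = r
    return pd.DataFrame(mat, index=ids, columns=ids)


def method_correlation_matrix(tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Pearson r between methods on avg_fc over shared proteins."""
    methods = list(tables)
    m = len(methods)
    mat = np.ones((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            a = tables[methods[i]].set_index("protein_id")["avg_fc"]
            b = tables[methods[j]].set_index("protein_id")["avg_fc"]
            shared = a.index.intersection(b.index)
            r = pearson_correlation(a.loc[shared], b.loc[shared])
            mat[i, j] = mat[j, i] = r
    return pd.DataFrame(mat, index=methods, columns=methods)


@dataclass
class QCReport:
    sample_correlations: dict[str, pd.DataFrame]
    method_correlations: pd.DataFrame
    fc_stdev: dict[str, float]
    filter_reports: dict[str, list[FilterReport]]
    metadata: dict


@dataclass
class MethodResult:
    method: str
    normalized: NormalizedDataset
    filter_reports: list[FilterReport]
    table: pd.DataFrame
    null_model: NullModel


@dataclass
class PipelineResult:
    methods: dict[str, MethodResult]
    consensus: pd.DataFrame
    qc: QCReport
    truth: GroundTruth | None = None
    recovery: RecoveryMetrics | None = None


@dataclass
class PipelineConfig:
    """One run: either a simulation or >= 2 method input tables."""

    simulation: SimulationParams | None = None
    inputs: dict[str, tuple[str, str]] | None = None  # method -> (quant, design)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    differential: DifferentialConfig = field(default_factory=DifferentialConfig)
    min_methods: int = 2
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        sim = d.get("simulation")
        if sim is not None:
            sim = SimulationParams(**sim)
        inputs = d.get("inputs")
        if inputs is not None:
            inputs = {
                m: (spec["quant"], spec["design"]) for m, spec in inputs.items()
            }
        return cls(
            simulation=sim,
            inputs=inputs,
            preprocess=PreprocessConfig(**d.get("preprocess", {})),
            differential=DifferentialConfig(**d.get("differential", {})),
            min_methods=d.get("consensus", {}).get("min_methods", 2),
            seed=d.get("seed", 0),
        )


def _load_inputs(config: PipelineConfig) -> tuple[dict[str, QuantDataset], GroundTruth | None]:
    if (config.simulation is None) == (config.inputs is None):
        raise ConfigurationError(
            "config must specify exactly one of 'simulation' or 'inputs'"
        )
    if config.simulation is not None:
        params = dataclasses.replace(config.simulation, seed=config.seed)
        return simulate_ric_experiment(params)
    assert config.inputs is not None
    if len(config.inputs) < 2:
        raise ConfigurationError("consensus requires >= 2 methods")
    datasets = {}
    for method, (quant_path, design_path) in config.inputs.items():
        design = read_design(design_path)
        datasets[method] = read_quant_table(quant_path, design)
    return datasets, None


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """preprocess -> call_differential per method -> consensus -> QC."""
    datasets, truth = _load_inputs(config)
    if len(datasets) < 2:
        raise ConfigurationError("consensus requires >= 2 methods")

    methods: dict[str, MethodResult] = {}
    for i, (method, dataset) in enumerate(datasets.items()):
        logger.info("preprocessing method %s", method)
        norm, reports = preprocess(dataset, config.preprocess)
        diff_cfg = dataclasses.replace(
            config.differential, method=method, seed=config.seed + i
        )
        logger.info("differential analysis for method %s", method)
        table, model = call_differential(norm, diff_cfg)
        methods[method] = MethodResult(
            method=method,
            normalized=norm,
            filter_reports=reports,
            table=table,
            null_model=model,
        )

    tables = {m: r.table for m, r in methods.items()}
    consensus = integrate_methods(
        list(tables.values()),
        min_methods=config.min_methods,
        cutoff=config.differential.fdr_cutoff,
    )
    qc = QCReport(
        sample_correlations={
            m: sample_correlation_matrix(r.normalized) for m, r in methods.items()
        },
        method_correlations=method_correlation_matrix(tables),
        fc_stdev={m: fc_dispersion(r.table) for m, r in methods.items()},
        filter_reports={m: r.filter_reports for m, r in methods.items()},
        metadata={
            "seed": config.seed,
            "tail_mode": config.differential.tail_mode,
            "fit_region": config.differential.fit_region,
            "fdr_cutoff": config.differential.fdr_cutoff,
            "min_methods": config.min_methods,
            "n_experiments": config.differential.n_experiments,
        },
    )
    recovery = summarize_truth(truth, consensus) if truth is not None else None
    return PipelineResult(
        methods=methods,
        consensus=consensus,
        qc=qc,
        truth=truth,
        recovery=recovery,
    )


# ---------------------------------------------------------------------------
# deterministic result writing
# ---------------------------------------------------------------------------

_FLOAT_FORMAT = "%.10g"


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=_FLOAT_FORMAT)


def _write_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def filter_reports_frame(reports: list[FilterReport]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "stage": [r.stage for r in reports],
            "proteins_in": [r.proteins_in for r in reports],
            "proteins_out": [r.proteins_out for r in reports],
            "removed": [",".join(r.removed) for r in reports],
        }
    )


def write_results(result: PipelineResult, out_dir) -> None:
    """Write all pipeline artifacts; byte-identical for identical runs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for method, mr in result.methods.items():
        _write_tsv(mr.table, out / f"differential_{method}.tsv")
        _write_json(mr.null_model.to_dict(), out / f"null_model_{method}.json")
        _write_tsv(
            filter_reports_frame(mr.filter_reports),
            out / f"filter_report_{method}.tsv",
        )
        _write_tsv(
            result.qc.sample_correlations[method],
            out / f"sample_correlations_{method}.tsv",
            index=True,
        )
    _write_tsv(result.consensus, out / "consensus.tsv")
    _write_tsv(
        result.qc.method_correlations, out / "method_correlations.tsv", index=True
    )
    manifest = {
        "metadata": result.qc.metadata,
        "fc_stdev": result.qc.fc_stdev,
        "n_selected": int(result.consensus["selected"].sum()),
        "n_less": int((result.consensus["consensus_direction"] == "less").sum()),
        "n_more": int((result.consensus["consensus_direction"] == "more").sum()),
    }
    if result.recovery is not None:
        manifest["recovery"] = {
            k: (None if isinstance(v, float) and np.isnan(v) else v)
            for k, v in dataclasses.asdict(result.recovery).items()
        }
    _write_json(manifest, out / "manifest.json")
    if result.truth is not None:
        _write_tsv(result.truth.to_frame(), out / "truth.tsv")


def write_simulation(
    datasets: dict[str, QuantDataset], truth: GroundTruth, out_dir
) -> None:
    """Write one quantification TSV + design TSV per method plus truth.tsv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for method, ds in datasets.items():
        write_quant_table(ds, out / f"quant_{method}.tsv")
        write_design(ds.design, out / f"design_{method}.tsv")
    truth.to_frame().to_csv(
        out / "truth.tsv", sep="\t", index=False, float_format=_FLOAT_FORMAT
    )
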