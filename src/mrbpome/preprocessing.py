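"""Filter cascade and normalization for quantification tables.

Stage order: minimum-peptide filter -> total-area normalization (with
pseudocount-1 log2 layer) -> competition-control enrichment filter (on raw
areas) -> replicate-presence filter.  Normalization is computed once, on the
peptide-filtered table, and not recomputed after later filters unless
``renormalize_after_filters`` is set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .core_io import (
    CONDITIONS,
    NormalizedDataset,
    QuantDataset,
    samples_where,
)
from .errors import ConfigurationError

logger = logging.getLogger(__name__)


@dataclass
class FilterReport:
    stage: str
    proteins_in: int
    proteins_out: int
    removed: list[str]


@dataclass
class PreprocessConfig:
    min_peptides: int = 2
    ratio: float = 3.0
    min_reps: int = 2
    total: float = 1e6
    renormalize_after_filters: bool = False


def _report(stage: str, dataset: QuantDataset, keep: np.ndarray) -> FilterReport:
    removed = [p for p, k in zip(dataset.proteins, keep) if not k]
    return FilterReport(
        stage=stage,
        proteins_in=len(dataset.proteins),
        proteins_out=int(np.count_nonzero(keep)),
        removed=removed,
    )


def filter_min_peptides(
    dataset: QuantDataset, min_peptides: int = 2
) -> tuple[QuantDataset, FilterReport]:
    """Keep proteins with >= *min_peptides* peptides in >= 1 biological sample.

    Competition-control samples are ignored for this criterion.
    """
    bio = samples_where(dataset.design, assay="biological")
    if bio:
        keep = dataset.peptide_counts[:, bio].max(axis=1) >= min_peptides
    else:
        keep = np.zeros(len(dataset.proteins), dtype=bool)
    report = _report("min_peptides", dataset, keep)
    return dataset.subset(keep), report


def normalize_total_area(
    dataset: QuantDataset, total: float = 1e6
) -> NormalizedDataset:
    """Scale each sample column to sum to *total*; add pseudocount-1 log2 layer.

    All-zero columns are preserved as-is with a logged warning.
    """
    sums = dataset.areas.sum(axis=0)
    zero_cols = sums == 0
    for j in np.flatnonzero(zero_cols):
        logger.warning(
            "sample %r has zero total area; left unnormalized",
            dataset.design[j].sample_id,
        )
    factors = np.where(zero_cols, 1.0, total / np.where(zero_cols, 1.0, sums))
    normalized = dataset.areas * factors[None, :]
    return NormalizedDataset(
        proteins=list(dataset.proteins),
        areas=dataset.areas,
        peptide_counts=dataset.peptide_counts,
        design=dataset.design,
        normalized=normalized,
        log2_values=np.log2(normalized + 1.0),
    )


def filter_control_enrichment(
    dataset: QuantDataset, ratio: float = 3.0
) -> tuple[QuantDataset, FilterReport]:
    """Keep proteins whose mean raw biological area is >= *ratio* x the mean
    raw competition-control area in BOTH conditions (inclusive >=).

    A condition whose control mean is 0 passes iff its biological mean is > 0.
    Operates on raw areas regardless of any normalization layer present.
    """
    keep = np.ones(len(dataset.proteins), dtype=bool)
    for condition in CONDITIONS:
        bio = samples_where(dataset.design, condition=condition, assay="biological")
        ctrl = samples_where(
            dataset.design, condition=condition, assay="competition_control"
        )
        if not bio:
            continue
        if not ctrl:
            raise ConfigurationError(
                f"condition {condition!r} has no competition_control samples"
            )
        bio_mean = dataset.areas[:, bio].mean(axis=1)
        ctrl_mean = dataset.areas[:, ctrl].mean(axis=1)
        passes = np.where(
            ctrl_mean > 0, bio_mean >= ratio * ctrl_mean, bio_mean > 0
        )
        keep &= passes
    report = _report("control_enrichment", dataset, keep)
    return dataset.subset(keep), report


def filter_replicate_presence(
    dataset: QuantDataset, min_reps: int = 2
) -> tuple[QuantDataset, FilterReport]:
    """Keep proteins identified (raw area > 0) in >= *min_reps* biological
    replicates of at least one condition."""
    keep = np.zeros(len(dataset.proteins), dtype=bool)
    for condition in CONDITIONS:
        bio = samples_where(dataset.design, condition=condition, assay="biological")
        if not bio:
            continue
        keep |= (dataset.areas[:, bio] > 0).sum(axis=1) >= min_reps
    report = _report("replicate_presence", dataset, keep)
    return dataset.subset(keep), report


def preprocess(
    dataset: QuantDataset, config: PreprocessConfig | None = None
) -> tuple[NormalizedDataset, list[FilterReport]]:
    """Run the full ordered cascade; returns the surviving normalized dataset
    and one report per filter stage."""
    config = config or PreprocessConfig()
    filtered, rep1 = filter_min_peptides(dataset, config.min_peptides)
    norm = normalize_total_area(filtered, config.total)
    norm, rep2 = filter_control_enrichment(norm, config.ratio)
    norm, rep3 = filter_replicate_presence(norm, config.min_reps)
    if config.renormalize_after_filters:
        renorm = normalize_total_area(norm, config.total)
        norm = replace(
            norm, normalized=renorm.normalized, log2_values=renorm.log2_values
        )
    return norm, [rep1, rep2, rep3]
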