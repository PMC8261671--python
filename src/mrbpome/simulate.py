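"""Synthetic RIC-like multi-method quantification datasets with ground truth.

Generative model (log2 scale unless stated otherwise):

1. latent base abundance ``a_p ~ LogNormal(ln 1e4, 1.5^2)`` (arbitrary MS
   intensity units);
2. subgroup sizes are deterministic — ``n_rbp = round(f_rbp * n_proteins)``,
   ``n_diff = round(f_diff * n_rbp)``, ``n_up = round(f_up * n_diff)`` —
   assigned to the first proteins of one seeded random permutation;
3. true effect magnitudes ``|delta_p| ~ Normal(effect_mean, effect_sd^2)``
   truncated at 0, signed per the up/down assignment;
4. biological sample log2 intensity
   ``log2 a_p + condition * method_scale * delta_p + N(0, sigma_rep^2)``,
   replicate noise independent per replicate and per method;
5. the competition-control mean area is ``control_suppression`` times the
   biological mean area for true poly(A) binders, and equal to it for
   non-binders (so non-binders fail the 3-fold enrichment filter in
   expectation); control replicates get the same ``sigma_rep`` noise;
6. each cell independently drops to 0 with probability
   ``logistic((dropout_midpoint - latent_log2) * dropout_steepness)``;
7. peptide counts are ``1 + Poisson(max(0, log2 a_p - 8))`` for identified
   cells, 0 for dropped cells.

The same seed yields bit-identical output; all methods observe one shared
latent truth through independent noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import truncnorm

from .core_io import Sample, QuantDataset
from .errors import ValidationError

DEFAULT_METHOD_SCALES = {"TOP3": 1.5, "iBAQ": 0.8, "LFQ": 1.0}


@dataclass
class SimulationParams:
    n_proteins: int = 1000
    f_rbp: float = 0.8
    f_diff: float = 0.25
    f_up: float = 0.58
    effect_mean: float = 1.5
    effect_sd: float = 0.75
    sigma_rep: float = 0.5
    method_scales: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_METHOD_SCALES)
    )
    control_suppression: float = 1 / 20
    dropout_midpoint: float = 5.0
    dropout_steepness: float = 0.7
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 10:
            raise ValidationError("n_proteins must be >= 10")
        for name in ("f_rbp", "f_diff", "f_up"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        for name in ("effect_sd", "sigma_rep"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not self.method_scales:
            raise ValidationError("method_scales must name >= 1 method")
        if any(s <= 0 for s in self.method_scales.values()):
            raise ValidationError("method_scales must be > 0")
        if not 0 < self.control_suppression:
            raise ValidationError("control_suppression must be > 0")
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1")


@dataclass
class GroundTruth:
    """Per-protein simulation labels enabling recovery tests."""

    proteins: list[str]
    is_rbp: np.ndarray
    is_differential: np.ndarray
    true_delta: np.ndarray

    def __post_init__(self) -> None:
        self.is_rbp = np.asarray(self.is_rbp, dtype=bool)
        self.is_differential = np.asarray(self.is_differential, dtype=bool)
        self.true_delta = np.asarray(self.true_delta, dtype=float)
        if np.any(self.is_differential & ~self.is_rbp):
            raise ValidationError("is_differential implies is_rbp")
        if not np.array_equal(self.true_delta != 0, self.is_differential):
            raise ValidationError("true_delta must be nonzero iff differential")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "protein_id": self.proteins,
                "is_rbp": self.is_rbp.astype(int),
                "is_differential": self.is_differential.astype(int),
                "true_delta": self.true_delta,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GroundTruth":
        return cls(
            proteins=df["protein_id"].astype(str).tolist(),
            is_rbp=df["is_rbp"].to_numpy(dtype=bool),
            is_differential=df["is_differential"].to_numpy(dtype=bool),
            true_delta=df["true_delta"].to_numpy(dtype=float),
        )


@dataclass
class RecoveryMetrics:
    """Recovery of simulated differential calls by a consensus table."""

    sensitivity: float
    precision: float
    direction_agreement: float
    tp: int
    fp: int
    fn: int
    no_selection: bool = False


def _make_design(method: str, n_replicates: int) -> list[Sample]:
    design = []
    for condition in ("untreated", "stress"):
        for assay, tag in (("biological", "bio"), ("competition_control", "ctrl")):
            for r in range(1, n_replicates + 1):
                design.append(
                    Sample(
                        sample_id=f"{method}_{condition}_{tag}_{r}",
                        condition=condition,
                        assay=assay,
                        replicate=r,
                        method=method,
                    )
                )
    return design


def simulate_ric_experiment(
    params: SimulationParams,
) -> tuple[dict[str, QuantDataset], GroundTruth]:
    """Simulate one RIC study observed through all configured methods.

    Returns one :class:`QuantDataset` per quantification method (shared
    truth, independent noise) plus the :class:`GroundTruth`.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_proteins
    proteins = [f"P{i + 1:05d}" for i in range(n)]

    order = rng.permutation(n)
    n_rbp = round(params.f_rbp * n)
    n_diff = round(params.f_diff * n_rbp)
    n_up = round(params.f_up * n_diff)

    is_rbp = np.zeros(n, dtype=bool)
    is_rbp[order[:n_rbp]] = True
    diff_idx = order[:n_diff]
    up_idx = order[:n_up]

    true_delta = np.zeros(n)
    if n_diff > 0:
        if params.effect_sd > 0:
            a = (0.0 - params.effect_mean) / params.effect_sd
            mag = truncnorm.rvs(
                a, np.inf,
                loc=params.effect_mean, scale=params.effect_sd,
                size=n_diff, random_state=rng,
            )
        else:
            mag = np.full(n_diff, params.effect_mean)
        mag = np.maximum(mag, np.finfo(float).tiny)  # truncation boundary
        signs = np.full(n_diff, -1.0)
        signs[np.isin(diff_idx, up_idx)] = 1.0
        true_delta[diff_idx] = mag * signs
    is_differential = true_delta != 0

    log2_abundance = np.log2(rng.lognormal(math.log(1e4), 1.5, size=n))
    log2_suppression = np.where(
        is_rbp, np.log2(params.control_suppression), 0.0
    )

    # per-cell peptide rate depends on base abundance only
    pep_lambda = np.maximum(0.0, log2_abundance - 8.0)

    datasets: dict[str, QuantDataset] = {}
    for method, scale in params.method_scales.items():
        design = _make_design(method, params.n_replicates)
        latent = np.empty((n, len(design)))
        for j, s in enumerate(design):
            shift = (s.condition == "stress") * scale * true_delta
            mean = log2_abundance + shift
            if s.assay == "competition_control":
                mean = mean + log2_suppression
            latent[:, j] = mean + rng.normal(0.0, params.sigma_rep, size=n)
        p_drop = expit(
            (params.dropout_midpoint - latent) * params.dropout_steepness
        )
        dropped = rng.random(latent.shape) < p_drop
        areas = np.where(dropped, 0.0, np.exp2(latent))
        peptides = 1 + rng.poisson(
            np.broadcast_to(pep_lambda[:, None], latent.shape)
        )
        peptides = np.where(dropped, 0, peptides)
        datasets[method] = QuantDataset(
            proteins=list(proteins),
            areas=areas,
            peptide_counts=peptides,
            design=design,
        )

    truth = GroundTruth(
        proteins=list(proteins),
        is_rbp=is_rbp,
        is_differential=is_differential,
        true_delta=true_delta,
    )
    return datasets, truth


def summarize_truth(truth: GroundTruth, consensus: pd.DataFrame) -> RecoveryMetrics:
    """Score a consensus table against the simulation labels.

    Sensitivity is computed over truly differential proteins present in the
    consensus table (i.e. those that survived preprocessing in >= 1 method);
    precision over all selected proteins; direction agreement over true
    positives.  With no selections, precision and agreement are NaN and
    ``no_selection`` is set.
    """
    known = set(truth.proteins)
    extra = [p for p in consensus["protein_id"].astype(str) if p not in known]
    if extra:
        raise ValidationError(
            f"consensus contains proteins absent from truth: {extra[:5]}"
        )
    tdf = truth.to_frame().set_index("protein_id")
    cdf = consensus.set_index(consensus["protein_id"].astype(str))

    surviving = tdf.loc[cdf.index]
    true_diff = surviving["is_differential"].to_numpy(dtype=bool)
    selected = cdf["selected"].to_numpy(dtype=bool)
    direction = cdf["consensus_direction"].to_numpy()

    tp_mask = selected & true_diff
    tp = int(tp_mask.sum())
    fp = int((selected & ~true_diff).sum())
    fn = int((~selected & true_diff).sum())

    sensitivity = tp / (tp + fn) if (tp + fn) > 0 else float("nan")
    if tp + fp == 0:
        return RecoveryMetrics(
            sensitivity=sensitivity,
            precision=float("nan"),
            direction_agreement=float("nan"),
            tp=tp, fp=fp, fn=fn, no_selection=True,
        )
    precision = tp / (tp + fp)
    if tp > 0:
        true_sign = np.sign(surviving["true_delta"].to_numpy())[tp_mask]
        called_sign = np.where(direction[tp_mask] == "more", 1.0, -1.0)
        agreement = float(np.mean(true_sign == called_sign))
    else:
        agreement = float("nan")
    return RecoveryMetrics(
        sensitivity=sensitivity,
        precision=precision,
        direction_agreement=agreement,
        tp=tp, fp=fp, fn=fn,
    )
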