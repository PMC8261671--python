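"""Average pairwise fold-change statistic with a shuffle-based FDR model.

For an unpaired design the per-protein statistic is the mean of the log2
fold-changes over all ordered (stress replicate, untreated replicate) pairs.
The null is built by pooling every per-protein pairwise fold-change and, for
each of ``n_experiments`` random experiments, drawing one protein's worth of
values without replacement from the pool and recording their mean.  The
percentage of null means beyond each threshold of a fixed grid gives an FDR
curve, which is smoothed by an ordinary-least-squares line and used to assign
an FDR percentage to every observed average fold-change.

Two tail conventions are supported.  ``signed`` (default) counts
``null mean >= t`` on the -10..10 grid and uses the mirrored model (fit on
the negated null means) for negative fold-changes; it stays calibrated when
total-area normalization shifts the null off zero (strong one-sided changes
alter the column totals).  ``folded`` counts ``|null mean| >= t`` on a 0..10
grid and applies one line to ``|avg_fc|``.

By default the line is fit on the grid's transition region — the points
between the last threshold still at 100% and the first at 0%, inclusive —
because a fit across the whole fixed grid is dominated by its saturated ends
rather than by the null distribution (``fit_region="full"`` restores the
literal behaviour).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import NormalizedDataset, samples_where
from .errors import ConfigurationError, ValidationError

TAIL_MODES = ("folded", "signed")
FIT_REGIONS = ("transition", "full")
SHUFFLE_SCOPES = ("global_pool", "within_protein_signflip")


@dataclass
class PairwiseFC:
    """Per-protein cross-condition pairwise log2 fold-changes."""

    proteins: list[str]
    fcs: np.ndarray  # (n_proteins, n_stress * n_untreated)
    avg_fc: np.ndarray

    @property
    def pairs_per_protein(self) -> int:
        return self.fcs.shape[1]


@dataclass
class NullModel:
    pooled_fcs: np.ndarray
    null_means: np.ndarray
    thresholds: np.ndarray
    grid_fdr: np.ndarray
    slope: float
    intercept: float
    tail_mode: str
    seed: int | None
    fit_region: str = "transition"
    # mirrored-model coefficients (signed mode only)
    slope_neg: float | None = None
    intercept_neg: float | None = None

    def to_dict(self) -> dict:
        d = {
            "n_experiments": int(len(self.null_means)),
            "pool_size": int(len(self.pooled_fcs)),
            "thresholds": self.thresholds.tolist(),
            "grid_fdr": self.grid_fdr.tolist(),
            "slope": self.slope,
            "intercept": self.intercept,
            "tail_mode": self.tail_mode,
            "fit_region": self.fit_region,
            "seed": self.seed,
        }
        if self.tail_mode == "signed":
            d["slope_neg"] = self.slope_neg
            d["intercept_neg"] = self.intercept_neg
        return d


@dataclass
class DifferentialConfig:
    n_experiments: int = 10_000
    tail_mode: str = "signed"
    fit_region: str = "transition"
    shuffle_scope: str = "global_pool"
    fdr_cutoff: float = 5.0
    seed: int = 0
    thresholds: np.ndarray | None = None
    method: str = ""

    def __post_init__(self) -> None:
        if self.tail_mode not in TAIL_MODES:
            raise ValidationError(f"tail_mode must be one of {TAIL_MODES}")
        if self.fit_region not in FIT_REGIONS:
            raise ValidationError(f"fit_region must be one of {FIT_REGIONS}")
        if self.shuffle_scope not in SHUFFLE_SCOPES:
            raise ValidationError(
                f"shuffle_scope must be one of {SHUFFLE_SCOPES}"
            )


def default_thresholds(tail_mode: str = "folded") -> np.ndarray:
    """0..10 step 0.5 (folded, 21 points) or -10..10 step 0.5 (signed, 41)."""
    lo = 0.0 if tail_mode == "folded" else -10.0
    n = 21 if tail_mode == "folded" else 41
    return lo + 0.5 * np.arange(n)


def compute_pairwise_fcs(norm: NormalizedDataset) -> PairwiseFC:
    """All ordered cross-condition log2 differences, stress_i - untreated_j."""
    stress = samples_where(norm.design, condition="stress", assay="biological")
    untreated = samples_where(norm.design, condition="untreated", assay="biological")
    if not stress or not untreated:
        raise ConfigurationError(
            "need >= 1 biological replicate in each condition"
        )
    s = norm.log2_values[:, stress]
    u = norm.log2_values[:, untreated]
    fcs = (s[:, :, None] - u[:, None, :]).reshape(len(norm.proteins), -1)
    # difference of condition means == mean of all ordered pairwise FCs, and
    # is float-exactly antisymmetric under a condition-label swap
    avg_fc = s.mean(axis=1) - u.mean(axis=1)
    return PairwiseFC(proteins=list(norm.proteins), fcs=fcs, avg_fc=avg_fc)


def build_null_distribution(
    pairwise: PairwiseFC,
    n_experiments: int = 10_000,
    seed: int | None = None,
    shuffle_scope: str = "global_pool",
    rng: np.random.Generator | None = None,
) -> NullModel:
    """Resampled null of mean fold-changes (model partially filled: pool and
    null means; grid and coefficients are added by the caller)."""
    if rng is None:
        rng = np.random.default_rng(seed)
    k = pairwise.pairs_per_protein
    pool = pairwise.fcs.ravel()
    if len(pool) < k:
        raise ValidationError(
            f"pool of {len(pool)} fold-changes smaller than one experiment's "
            f"draw ({k})"
        )
    if shuffle_scope == "global_pool":
        null_means = np.empty(n_experiments)
        for i in range(n_experiments):
            null_means[i] = rng.choice(pool, size=k, replace=False).mean()
    elif shuffle_scope == "within_protein_signflip":
        n = pairwise.fcs.shape[0]
        rows = rng.integers(0, n, size=n_experiments)
        flips = rng.choice([-1.0, 1.0], size=n_experiments)
        null_means = pairwise.fcs[rows].mean(axis=1) * flips
    else:  # pragma: no cover - guarded by DifferentialConfig
        raise ValidationError(f"unknown shuffle_scope {shuffle_scope!r}")
    return NullModel(
        pooled_fcs=pool,
        null_means=null_means,
        thresholds=np.empty(0),
        grid_fdr=np.empty(0),
        slope=float("nan"),
        intercept=float("nan"),
        tail_mode="folded",
        seed=seed,
    )


def compute_fdr_grid(
    null_means: np.ndarray,
    thresholds: np.ndarray,
    tail_mode: str = "folded",
) -> np.ndarray:
    """Percentage of null means at or beyond each threshold."""
    null_means = np.asarray(null_means, dtype=float)
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.size == 0:
        raise ValidationError("thresholds must be non-empty")
    values = np.abs(null_means) if tail_mode == "folded" else null_means
    counts = (values[:, None] >= thresholds[None, :]).sum(axis=0)
    return 100.0 * counts / len(values)


def _transition_slice(grid_fdr: np.ndarray) -> slice:
    """Grid window between the last 100% point and the first 0% point."""
    at100 = np.flatnonzero(grid_fdr >= 100.0)
    lo = int(at100[-1]) if at100.size else 0
    at0 = np.flatnonzero(grid_fdr <= 0.0)
    at0 = at0[at0 > lo]
    hi = int(at0[0]) if at0.size else len(grid_fdr) - 1
    return slice(lo, hi + 1)


def fit_fdr_model(
    thresholds: np.ndarray,
    grid_fdr: np.ndarray,
    fit_region: str = "transition",
) -> tuple[float, float]:
    """Ordinary least squares of grid percentages on thresholds.

    Returns (slope, intercept).  With ``fit_region="transition"`` the fit
    uses only the grid's transition window (falling back to the full grid
    when that window has < 2 points).
    """
    x = np.asarray(thresholds, dtype=float)
    y = np.asarray(grid_fdr, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("thresholds and grid_fdr must align")
    if np.unique(x).size < 2:
        raise ValidationError("need >= 2 distinct thresholds for the fit")
    if fit_region == "transition":
        sl = _transition_slice(y)
        if np.unique(x[sl]).size >= 2:
            x, y = x[sl], y[sl]
    xbar, ybar = x.mean(), y.mean()
    slope = float(np.sum((x - xbar) * (y - ybar)) / np.sum((x - xbar) ** 2))
    return slope, ybar - slope * xbar


def assign_fdr(
    avg_fc: np.ndarray | float,
    model: NullModel,
    cutoff: float = 5.0,
) -> pd.DataFrame:
    """Per-protein FDR percentages from the fitted line, clamped to [0, 100].

    Folded mode applies the line to |avg_fc|; signed mode applies it to
    positive fold-changes and the mirrored model to negated negative ones.
    """
    fc = np.atleast_1d(np.asarray(avg_fc, dtype=float))
    if model.tail_mode == "folded":
        raw = model.intercept + model.slope * np.abs(fc)
    else:
        if model.slope_neg is None or model.intercept_neg is None:
            raise ValidationError("signed model missing mirrored coefficients")
        raw = np.where(
            fc >= 0,
            model.intercept + model.slope * fc,
            model.intercept_neg + model.slope_neg * (-fc),
        )
    fdr = np.clip(raw, 0.0, 100.0)
    direction = np.where(fc > 0, "more", np.where(fc < 0, "less", "none"))
    return pd.DataFrame(
        {
            "avg_fc": fc,
            "fdr_percent": fdr,
            "significant": fdr <= cutoff,
            "direction": direction,
        }
    )


def call_differential(
    norm: NormalizedDataset,
    config: DifferentialConfig | None = None,
) -> tuple[pd.DataFrame, NullModel]:
    """Full statistic: pairwise FCs -> shuffle null -> grid -> line -> FDRs.

    Returns a per-protein table (protein_id, avg_fc, fdr_percent, significant,
    direction, method) and the fitted :class:`NullModel`.
    """
    config = config or DifferentialConfig()
    pairwise = compute_pairwise_fcs(norm)
    model = build_null_distribution(
        pairwise,
        n_experiments=config.n_experiments,
        seed=config.seed,
        shuffle_scope=config.shuffle_scope,
    )
    thresholds = (
        np.asarray(config.thresholds, dtype=float)
        if config.thresholds is not None
        else default_thresholds(config.tail_mode)
    )
    model.tail_mode = config.tail_mode
    model.fit_region = config.fit_region
    model.thresholds = thresholds
    model.grid_fdr = compute_fdr_grid(
        model.null_means, thresholds, config.tail_mode
    )
    model.slope, model.intercept = fit_fdr_model(
        thresholds, model.grid_fdr, config.fit_region
    )
    if config.tail_mode == "signed":
        mirror_grid = compute_fdr_grid(-model.null_means, thresholds, "signed")
        model.slope_neg, model.intercept_neg = fit_fdr_model(
            thresholds, mirror_grid, config.fit_region
        )
    table = assign_fdr(pairwise.avg_fc, model, cutoff=config.fdr_cutoff)
    table.insert(0, "protein_id", pairwise.proteins)
    table["method"] = config.method or (
        norm.design[0].method if norm.design else ""
    )
    return table, model
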