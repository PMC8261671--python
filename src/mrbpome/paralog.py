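"""Paralog-specialization analysis.

Classify paralog pairs against a query set (both / exactly one / neither
member in it), compare abundances of RNA-binding members of one-in pairs vs
their non-binding partners with a Mann-Whitney test, and test category
over-representation among the unique (one-in) differential paralogs using
all paired proteins as the background.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import norm

from .core_io import GeneSetCollection, ParalogTable
from .enrichment import ora
from .errors import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class ParalogClassification:
    pairs_both: list[tuple[str, str]]
    pairs_one: list[tuple[str, str]]  # (in-set member, out-of-set member)
    pairs_neither: list[tuple[str, str]]

    @property
    def n_both(self) -> int:
        return len(self.pairs_both)

    @property
    def n_one(self) -> int:
        return len(self.pairs_one)

    @property
    def n_neither(self) -> int:
        return len(self.pairs_neither)


@dataclass
class MannWhitneyResult:
    U: float
    n1: int
    n2: int
    p_value: float
    method: str  # "exact" or "normal_approx"


def classify_pairs(
    pairs: ParalogTable, query_set: set[str]
) -> ParalogClassification:
    """Exhaustive, mutually exclusive partition of the pairs by membership of
    their members in *query_set*."""
    query_set = set(query_set)
    both, one, neither = [], [], []
    for a, b in pairs.pairs:
        ina, inb = a in query_set, b in query_set
        if ina and inb:
            both.append((a, b))
        elif ina or inb:
            one.append((a, b) if ina else (b, a))
        else:
            neither.append((a, b))
    return ParalogClassification(
        pairs_both=both, pairs_one=one, pairs_neither=neither
    )


def _u_statistic(group1: np.ndarray, group2: np.ndarray) -> float:
    """U for group1: #(x > y) pairs plus half the tied pairs."""
    diff = group1[:, None] - group2[None, :]
    return float(np.sum(diff > 0) + 0.5 * np.sum(diff == 0))


def mann_whitney(
    group1, group2, exact_limit: int = 20
) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test.

    Exact p by full enumeration of group-label assignments when
    ``n1 + n2 <= exact_limit`` and there are no ties; otherwise a normal
    approximation with tie and continuity corrections.
    """
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    n1, n2 = len(g1), len(g2)
    if n1 == 0 or n2 == 0:
        raise ValidationError("both groups must be non-empty")
    u_obs = _u_statistic(g1, g2)
    pooled = np.concatenate([g1, g2])
    has_ties = len(np.unique(pooled)) < n1 + n2
    mu = n1 * n2 / 2.0

    if not has_ties and n1 + n2 <= exact_limit:
        dev_obs = abs(u_obs - mu)
        count = total = 0
        for idx in combinations(range(n1 + n2), n1):
            mask = np.zeros(n1 + n2, dtype=bool)
            mask[list(idx)] = True
            u = _u_statistic(pooled[mask], pooled[~mask])
            total += 1
            if abs(u - mu) >= dev_obs - 1e-12:
                count += 1
        return MannWhitneyResult(
            U=u_obs, n1=n1, n2=n2, p_value=count / total, method="exact"
        )

    # normal approximation with tie correction and continuity correction
    N = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (N * (N - 1)) if N > 1 else 0.0
    var = n1 * n2 / 12.0 * ((N + 1) - tie_term)
    if var <= 0:
        return MannWhitneyResult(
            U=u_obs, n1=n1, n2=n2, p_value=1.0, method="normal_approx"
        )
    z = (abs(u_obs - mu) - 0.5) / np.sqrt(var)
    z = max(z, 0.0)
    p = min(1.0, 2.0 * float(norm.sf(z)))
    return MannWhitneyResult(
        U=u_obs, n1=n1, n2=n2, p_value=p, method="normal_approx"
    )


@dataclass
class SpecializationReport:
    rbp_classification: ParalogClassification
    differential_classification: ParalogClassification
    abundance_test: MannWhitneyResult | None
    enrichment: pd.DataFrame | None
    warnings: list[str]


def specialization_report(
    pairs: ParalogTable,
    rbp_set: set[str],
    differential_set: set[str],
    abundance: dict[str, float],
    collection: GeneSetCollection | None = None,
    background: set[str] | None = None,
    min_overlap: int = 2,
) -> SpecializationReport:
    """Full specialization analysis against an RBP set and a differential set.

    The abundance comparison pits the in-set member of each one-in RBP pair
    against its partner (pairs with a missing abundance value are dropped
    with a warning); the ORA step tests the unique differential paralogs
    against *collection* with all paired proteins as the background.
    """
    warnings: list[str] = []
    rbp_cls = classify_pairs(pairs, rbp_set)
    diff_cls = classify_pairs(pairs, differential_set)

    in_values, out_values = [], []
    for in_member, out_member in rbp_cls.pairs_one:
        if in_member in abundance and out_member in abundance:
            in_values.append(abundance[in_member])
            out_values.append(abundance[out_member])
        else:
            warnings.append(
                f"pair ({in_member}, {out_member}) dropped from abundance "
                f"comparison: missing abundance value"
            )
    if in_values:
        abundance_test = mann_whitney(in_values, out_values)
    else:
        abundance_test = None
        warnings.append("no one-in pairs with abundance values; test skipped")
    for w in warnings:
        logger.warning(w)

    enrichment = None
    if collection is not None:
        unique_diff = {a for a, _b in diff_cls.pairs_one}
        if not unique_diff:
            warnings.append("no unique differential paralogs; ORA skipped")
            logger.warning(warnings[-1])
        else:
            bg = set(background) if background is not None else pairs.proteins
            enrichment = ora(
                unique_diff, collection, bg, min_overlap=min_overlap
            )
    return SpecializationReport(
        rbp_classification=rbp_cls,
        differential_classification=diff_cls,
        abundance_test=abundance_test,
        enrichment=enrichment,
        warnings=warnings,
    )
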