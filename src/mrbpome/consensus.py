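"""Cross-method consensus: proteins selected by >= min_methods analyses.

A protein is selected when at least ``min_methods`` per-method tables call it
at ``fdr_percent <= cutoff`` AND the selecting methods agree on the sign of
the fold-change; sign disagreements are flagged ``discordant`` and never
selected.  Proteins absent from a method's table count as not significant in
that method (they failed its filters), not as excluded from consensus.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ValidationError


def integrate_methods(
    tables: list[pd.DataFrame],
    min_methods: int = 2,
    cutoff: float = 5.0,
) -> pd.DataFrame:
    """Integrate per-method differential tables over the union of proteins.

    Returns one row per protein with per-method ``avg_fc_<m>``,
    ``fdr_percent_<m>``, ``significant_<m>`` columns plus
    ``n_significant_methods``, ``consensus_direction`` and ``selected``.
    """
    if len(tables) < 2:
        raise ValidationError("consensus requires >= 2 method tables")
    methods = [str(t["method"].iloc[0]) if len(t) else "" for t in tables]
    if len(set(methods)) != len(methods):
        raise ValidationError(f"duplicate method labels: {methods}")

    merged: pd.DataFrame | None = None
    for table, method in zip(tables, methods):
        sub = table[["protein_id", "avg_fc", "fdr_percent"]].copy()
        sub.columns = ["protein_id", f"avg_fc_{method}", f"fdr_percent_{method}"]
        merged = (
            sub
            if merged is None
            else merged.merge(sub, on="protein_id", how="outer")
        )
    assert merged is not None
    merged = merged.sort_values("protein_id", kind="stable").reset_index(drop=True)

    sig_cols = []
    for method in methods:
        sig = merged[f"fdr_percent_{method}"] <= cutoff
        sig &= merged[f"fdr_percent_{method}"].notna()
        merged[f"significant_{method}"] = sig
        sig_cols.append(sig.to_numpy())
    sig_mat = np.column_stack(sig_cols)
    fc_mat = merged[[f"avg_fc_{m}" for m in methods]].to_numpy()

    n_sig = sig_mat.sum(axis=1)
    directions = []
    for i in range(len(merged)):
        signs = np.sign(fc_mat[i, sig_mat[i]])
        if len(signs) == 0:
            directions.append("none")
        elif np.all(signs > 0):
            directions.append("more")
        elif np.all(signs < 0):
            directions.append("less")
        else:
            directions.append("discordant")
    directions = np.array(directions)

    merged["n_significant_methods"] = n_sig
    merged["consensus_direction"] = directions
    merged["selected"] = (n_sig >= min_methods) & np.isin(
        directions, ("less", "more")
    )
    return merged
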