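"""Domain types and readers/writers for quantification tables, sample designs,
GMT gene sets and paralog-pair tables.

All tabular formats are plain TSV:

* quantification table — header ``protein_id``, one area column per
  ``sample_id``, optional ``<sample_id>.peptides`` integer columns (or a
  single ``peptides`` column applied to every sample);
* sample design — columns ``sample_id, condition, assay, replicate, method``;
* gene sets — standard GMT (name, description, members...);
* paralog pairs — two columns, one unordered pair per line.

Blank or missing numeric cells read as 0 ("not identified"); protein IDs are
opaque case-sensitive strings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

CONDITIONS = ("untreated", "stress")
ASSAYS = ("biological", "competition_control")


@dataclass(frozen=True)
class Sample:
    """One MS sample: a (condition, assay, replicate) cell of the design."""

    sample_id: str
    condition: str
    assay: str
    replicate: int
    method: str = ""

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValidationError(
                f"sample {self.sample_id!r}: condition must be one of "
                f"{CONDITIONS}, got {self.condition!r}"
            )
        if self.assay not in ASSAYS:
            raise ValidationError(
                f"sample {self.sample_id!r}: assay must be one of {ASSAYS}, "
                f"got {self.assay!r}"
            )
        if int(self.replicate) < 1:
            raise ValidationError(
                f"sample {self.sample_id!r}: replicate must be >= 1"
            )


def validate_design(design: list[Sample]) -> None:
    """Check design invariants (unique sample ids)."""
    ids = [s.sample_id for s in design]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate sample_id values in design: {dupes}")


def samples_where(
    design: list[Sample],
    condition: str | None = None,
    assay: str | None = None,
) -> list[int]:
    """Indices into *design* of samples matching the given condition/assay."""
    return [
        i
        for i, s in enumerate(design)
        if (condition is None or s.condition == condition)
        and (assay is None or s.assay == assay)
    ]


@dataclass
class QuantDataset:
    """Protein x sample matrix of raw peak areas with peptide counts.

    ``areas[i, j]`` is the raw peak area of ``proteins[i]`` in ``design[j]``;
    0 encodes "not identified".
    """

    proteins: list[str]
    areas: np.ndarray
    peptide_counts: np.ndarray
    design: list[Sample]

    def __post_init__(self) -> None:
        self.areas = np.asarray(self.areas, dtype=float)
        self.peptide_counts = np.asarray(self.peptide_counts)
        n, m = len(self.proteins), len(self.design)
        if self.areas.shape != (n, m):
            raise ValidationError(
                f"areas shape {self.areas.shape} != ({n}, {m})"
            )
        if self.peptide_counts.shape != (n, m):
            raise ValidationError(
                f"peptide_counts shape {self.peptide_counts.shape} != ({n}, {m})"
            )
        if np.any(self.areas < 0):
            i, j = np.argwhere(self.areas < 0)[0]
            raise ValidationError(
                f"negative area for protein {self.proteins[i]!r} in sample "
                f"{self.design[j].sample_id!r}"
            )
        if np.any(self.peptide_counts < 0):
            raise ValidationError("peptide counts must be >= 0")
        if not np.all(np.equal(np.mod(self.peptide_counts, 1), 0)):
            raise ValidationError("peptide counts must be integer-valued")
        self.peptide_counts = self.peptide_counts.astype(int)
        validate_design(self.design)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.design]

    def subset(self, keep: np.ndarray) -> "QuantDataset":
        """Row-subset by a boolean mask or index array over proteins."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return replace(
            self,
            proteins=[self.proteins[i] for i in keep],
            areas=self.areas[keep],
            peptide_counts=self.peptide_counts[keep],
        )


@dataclass
class NormalizedDataset(QuantDataset):
    """QuantDataset plus per-sample total-area normalization and log2 layer.

    Each nonzero sample column of ``normalized`` sums to the normalization
    total (default 1e6); ``log2_values = log2(normalized + 1)``.
    """

    normalized: np.ndarray = field(default=None)  # type: ignore[assignment]
    log2_values: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.normalized is None or self.log2_values is None:
            raise ValidationError(
                "NormalizedDataset requires normalized and log2_values"
            )
        self.normalized = np.asarray(self.normalized, dtype=float)
        self.log2_values = np.asarray(self.log2_values, dtype=float)
        for name in ("normalized", "log2_values"):
            if getattr(self, name).shape != self.areas.shape:
                raise ValidationError(f"{name} shape mismatch with areas")

    def subset(self, keep: np.ndarray) -> "NormalizedDataset":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return replace(
            self,
            proteins=[self.proteins[i] for i in keep],
            areas=self.areas[keep],
            peptide_counts=self.peptide_counts[keep],
            normalized=self.normalized[keep],
            log2_values=self.log2_values[keep],
        )


@dataclass
class GeneSetCollection:
    """Named gene sets with an optional explicit background universe."""

    sets: dict[str, tuple[str, list[str]]]
    background: set[str] | None = None


@dataclass
class ParalogTable:
    """Disjoint unordered protein pairs (a pairing, not a general graph)."""

    pairs: list[tuple[str, str]]

    @property
    def proteins(self) -> set[str]:
        return {p for pair in self.pairs for p in pair}


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_design(path) -> list[Sample]:
    """Read a sample-design TSV (sample_id, condition, assay, replicate, method)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "condition", "assay", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"design file missing columns: {sorted(missing)}")
    design = [
        Sample(
            sample_id=row.sample_id,
            condition=row.condition,
            assay=row.assay,
            replicate=int(row.replicate),
            method=getattr(row, "method", "") or "",
        )
        for row in df.itertuples(index=False)
    ]
    validate_design(design)
    return design


def write_design(design: list[Sample], path) -> None:
    df = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in design],
            "condition": [s.condition for s in design],
            "assay": [s.assay for s in design],
            "replicate": [s.replicate for s in design],
            "method": [s.method for s in design],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_quant_table(path, design: list[Sample]) -> QuantDataset:
    """Read a quantification TSV against a declared sample design.

    Missing/blank numeric cells are read as 0.  A missing area column for a
    declared sample is a :class:`FormatError`; a negative area is a
    :class:`ValidationError` naming protein and sample.
    """
    validate_design(design)
    df = pd.read_csv(path, sep="\t")
    if "protein_id" not in df.columns:
        raise FormatError(f"{path}: missing required column 'protein_id'")
    for s in design:
        if s.sample_id not in df.columns:
            raise FormatError(
                f"{path}: missing area column for declared sample "
                f"{s.sample_id!r}"
            )
    proteins = df["protein_id"].astype(str).tolist()
    areas = (
        df[[s.sample_id for s in design]]
        .apply(pd.to_numeric, errors="coerce")
        .fillna(0.0)
        .to_numpy(dtype=float)
    )
    if np.any(areas < 0):
        i, j = np.argwhere(areas < 0)[0]
        raise ValidationError(
            f"{path}: negative area for protein {proteins[i]!r} in sample "
            f"{design[j].sample_id!r}"
        )

    pep_cols = [f"{s.sample_id}.peptides" for s in design]
    if all(c in df.columns for c in pep_cols):
        peptides = (
            df[pep_cols]
            .apply(pd.to_numeric, errors="coerce")
            .fillna(0)
            .to_numpy()
        )
    elif "peptides" in df.columns:
        # D-io-3 fallback: one per-protein column applied to all samples
        col = pd.to_numeric(df["peptides"], errors="coerce").fillna(0).to_numpy()
        peptides = np.tile(col[:, None], (1, len(design)))
    else:
        logger.warning(
            "%s: no peptide-count columns; defaulting to 1 where area > 0",
            path,
        )
        peptides = (areas > 0).astype(int)
    return QuantDataset(
        proteins=proteins, areas=areas, peptide_counts=peptides, design=design
    )


def write_quant_table(dataset: QuantDataset, path) -> None:
    """Write a quantification TSV that :func:`read_quant_table` inverts exactly."""
    data: dict[str, object] = {"protein_id": dataset.proteins}
    for j, s in enumerate(dataset.design):
        data[s.sample_id] = dataset.areas[:, j]
    for j, s in enumerate(dataset.design):
        data[f"{s.sample_id}.peptides"] = dataset.peptide_counts[:, j]
    pd.DataFrame(data).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: one gene set per line (name, description, members...)."""
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(
                    f"{path}:{lineno}: GMT line has fewer than 2 fields"
                )
            name, desc, *members = fields
            seen: list[str] = []
            for m in members:
                if m == "":
                    continue
                if m in seen:
                    logger.warning(
                        "%s:%d: duplicate member %r in set %r dropped",
                        path, lineno, m, name,
                    )
                else:
                    seen.append(m)
            sets[name] = (desc, seen)
    return GeneSetCollection(sets=sets)


def read_paralog_pairs(path) -> ParalogTable:
    """Read a two-column TSV of unordered paralog pairs.

    Duplicate pairs (in either order) collapse with a warning; self-pairs and
    proteins occurring in two different pairs are validation errors.
    """
    pairs: list[tuple[str, str]] = []
    seen_pairs: set[frozenset[str]] = set()
    membership: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(
                    f"{path}:{lineno}: expected 2 tab-separated columns"
                )
            a, b = fields
            if a == b:
                raise ValidationError(f"{path}:{lineno}: self-pair ({a}, {b})")
            key = frozenset((a, b))
            if key in seen_pairs:
                logger.warning(
                    "%s:%d: duplicate pair (%s, %s) collapsed", path, lineno, a, b
                )
                continue
            for p in (a, b):
                if p in membership:
                    raise ValidationError(
                        f"{path}:{lineno}: protein {p!r} appears in more than "
                        f"one pair"
                    )
            seen_pairs.add(key)
            membership[a] = key
            membership[b] = key
            pairs.append((a, b))
    return ParalogTable(pairs=pairs)


def read_id_list(path) -> list[str]:
    """Read a one-ID-per-line text file (blank lines ignored)."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]
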