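"""Expression transforms and pre-classification filters.

Two filters run before any fate classification: genes whose log2(FPKM+1)
value is below 1 in every tissue are treated as transcriptional noise and
removed, and duplicate triples whose synonymous divergence Ks is >= 3 (or
missing) are removed to avoid substitution saturation. Both thresholds are
strict inequalities: a value exactly at the boundary is kept by the
low-expression filter and removed by the Ks filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import LOG2P1, RAW, ExpressionMatrix, PairTables

LOW_EXPRESSION_CUTOFF = 1.0  # on the log2(x+1) scale, per tissue
KS_CUTOFF = 3.0


@dataclass
class FilterReport:
    """Accounting for one filter pass: what went in, what was removed, why."""

    n_input: int
    removed: dict[str, list[str]] = field(default_factory=dict)

    @property
    def n_removed(self) -> int:
        return sum(len(v) for v in self.removed.values())

    @property
    def n_retained(self) -> int:
        return self.n_input - self.n_removed

    def summary(self) -> str:
        parts = ", ".join(f"{k}={len(v)}" for k, v in self.removed.items()) or "none"
        return (
            f"{self.n_input} input, {self.n_retained} retained, "
            f"removed: {parts}"
        )


def log_transform(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Replace every value v by log2(v + 1) and flag the matrix as transformed.

    Applying the transform twice is almost always a bug, so a second call
    raises instead of silently compressing the scale again.
    """
    if matrix.scale != RAW:
        raise ValueError("matrix is already log2(x+1)-transformed")
    return ExpressionMatrix(values=np.log2(matrix.values + 1.0), scale=LOG2P1)


def inverse_log_transform(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Back-transform log2(x+1) values to the raw scale (2**v - 1)."""
    if matrix.scale != LOG2P1:
        raise ValueError("matrix is not on the log2(x+1) scale")
    return ExpressionMatrix(values=2.0 ** matrix.values - 1.0, scale=RAW)


def filter_low_expression(
    matrix: ExpressionMatrix, cutoff: float = LOW_EXPRESSION_CUTOFF
) -> tuple[ExpressionMatrix, FilterReport]:
    """Drop genes whose transformed value is below ``cutoff`` in all tissues.

    The decision depends only on the gene's own row: a gene survives iff at
    least one tissue reaches the cutoff (boundary values survive).
    """
    if matrix.scale != LOG2P1:
        raise ValueError("filter_low_expression expects a log2(x+1) matrix")
    low = (matrix.values < cutoff).all(axis=1)
    report = FilterReport(
        n_input=len(matrix),
        removed={"low_expression": list(matrix.values.index[low])},
    )
    kept = ExpressionMatrix(values=matrix.values.loc[~low], scale=LOG2P1)
    return kept, report


def filter_ks(
    pairs: PairTables, cutoff: float = KS_CUTOFF
) -> tuple[PairTables, FilterReport]:
    """Drop duplicate triples whose Ks is saturated (>= cutoff) or missing.

    A triple is retained iff both its duplicate copies have a Ks value in the
    table and both are strictly below the cutoff. Missing-Ks removals are
    counted separately from saturated ones.
    """
    trip = pairs.duplicate_triples
    ks = pairs.kaks["ks"]
    missing_ids, saturated_ids, keep_mask = [], [], []
    for _, row in trip.iterrows():
        copies = (row["parent"], row["child"])
        vals = [ks.get(g, np.nan) for g in copies]
        if any(np.isnan(v) for v in vals):
            missing_ids.append(_triple_id(row))
            keep_mask.append(False)
        elif any(v >= cutoff for v in vals):
            saturated_ids.append(_triple_id(row))
            keep_mask.append(False)
        else:
            keep_mask.append(True)
    report = FilterReport(
        n_input=len(trip),
        removed={"ks_saturated": saturated_ids, "ks_missing": missing_ids},
    )
    filtered = PairTables(
        ortholog_pairs=pairs.ortholog_pairs,
        duplicate_triples=trip.loc[keep_mask].reset_index(drop=True),
        kaks=pairs.kaks,
    )
    return filtered, report


def drop_filtered_triples(
    pairs: PairTables, surviving_genes
) -> tuple[PairTables, FilterReport]:
    """Drop triples with any member removed by the expression filter."""
    surviving = set(surviving_genes)
    trip = pairs.duplicate_triples
    keep = trip[["ancestral", "parent", "child"]].isin(surviving).all(axis=1)
    report = FilterReport(
        n_input=len(trip),
        removed={"member_filtered": [_triple_id(r) for _, r in trip[~keep].iterrows()]},
    )
    filtered = PairTables(
        ortholog_pairs=pairs.ortholog_pairs,
        duplicate_triples=trip.loc[keep].reset_index(drop=True),
        kaks=pairs.kaks,
    )
    return filtered, report


def _triple_id(row) -> str:
    return f"{row['ancestral']}|{row['parent']}|{row['child']}"
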