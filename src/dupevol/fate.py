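"""Distance-based classification of duplicate-gene retention mechanisms.

Each duplicate triple (ancestral gene A in the sister species, parent P and
child C copies in the focal genome) is classified by comparing Euclidean
distances between log-scale expression profiles against a divergence cutoff
E_div drawn from the distribution of single-copy ortholog distances:

* conserved            E(P,A) <= E_div and E(C,A) <= E_div
* neofunctionalized    exactly one copy's distance exceeds E_div
  (the diverged copy is recorded)
* subfunctionalized    both exceed E_div but the combined P+C profile does not
* specialized          both copies and the combined profile all exceed E_div

The combined profile sums the two copies' transcript abundances on the raw
scale and re-log-transforms, because abundance of a merged P+C unit is
additive in transcripts, not in log space. Boundary ties (distance exactly
E_div) count as "<=", i.e. toward conservation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import DUP_TYPES, PairTables

CONSERVED = "conserved"
NEO_PARENT = "neofunctionalized(parent)"
NEO_CHILD = "neofunctionalized(child)"
SUBFUNCTIONALIZED = "subfunctionalized"
SPECIALIZED = "specialized"

FATES = (CONSERVED, NEO_PARENT, NEO_CHILD, SUBFUNCTIONALIZED, SPECIALIZED)

#: the four coarse fates (both neofunctionalized flavours collapsed)
FATES_COARSE = ("conserved", "neofunctionalized", "subfunctionalized", "specialized")

DEFAULT_EDIV_QUANTILE = 0.90
MIN_SINGLE_COPY_PAIRS = 30


@dataclass(frozen=True)
class FateCall:
    """One triple's distances and its assigned retention mechanism."""

    triple_id: str
    e_parent: float
    e_child: float
    e_combined: float
    e_div: float
    fate: str

    @property
    def fate_coarse(self) -> str:
        return "neofunctionalized" if self.fate.startswith("neo") else self.fate


def euclidean_distance(p, q) -> float:
    """Euclidean distance between two expression profiles (same tissue order)."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError(f"profile length mismatch: {p.shape} vs {q.shape}")
    return float(np.linalg.norm(p - q))


def combined_profile(parent, child) -> np.ndarray:
    """Merge two log2(x+1) profiles by summing raw abundances, then re-log.

    Per tissue: log2((2**p - 1) + (2**c - 1) + 1). An all-zero child leaves
    the parent profile unchanged (raw-scale additive identity).
    """
    p = np.asarray(parent, dtype=float)
    c = np.asarray(child, dtype=float)
    if p.shape != c.shape:
        raise ValueError(f"profile length mismatch: {p.shape} vs {c.shape}")
    return np.log2(2.0**p + 2.0**c - 1.0)


def select_ediv(
    single_copy_distances,
    quantile: float = DEFAULT_EDIV_QUANTILE,
    e_div: float | None = None,
    min_pairs: int = MIN_SINGLE_COPY_PAIRS,
) -> float:
    """Choose the divergence cutoff E_div.

    By default E_div is the ``quantile``-th linear-interpolation empirical
    quantile of the Euclidean distances between single-copy ortholog
    profiles — a high quantile of between-species divergence of genes that
    did NOT duplicate, i.e. the expression change expected from speciation
    alone. A user-supplied ``e_div`` overrides the selection.
    """
    if e_div is not None:
        if e_div < 0:
            raise ValueError("e_div must be non-negative")
        return float(e_div)
    d = np.asarray(list(single_copy_distances), dtype=float)
    if d.size < min_pairs:
        raise ValueError(
            f"only {d.size} single-copy distances (< {min_pairs}); "
            "supply e_div explicitly"
        )
    if not 0.0 < quantile < 1.0:
        raise ValueError("quantile must lie in (0, 1)")
    return float(np.quantile(d, quantile))


def classify_fate(
    e_parent: float,
    e_child: float,
    e_combined: float,
    e_div: float,
    triple_id: str = "",
) -> FateCall:
    """Assign exactly one retention mechanism from the three distances.

    The four rules partition the (e_parent, e_child, e_combined) space for
    any finite inputs; the combined distance only matters when both copies
    individually diverged.
    """
    for name, value in (
        ("e_parent", e_parent),
        ("e_child", e_child),
        ("e_combined", e_combined),
        ("e_div", e_div),
    ):
        if not np.isfinite(value):
            raise ValueError(f"{name} is not finite: {value}")
    if e_div < 0:
        raise ValueError("e_div must be non-negative")

    if e_parent <= e_div and e_child <= e_div:
        fate = CONSERVED
    elif e_parent <= e_div:  # child diverged
        fate = NEO_CHILD
    elif e_child <= e_div:  # parent diverged
        fate = NEO_PARENT
    elif e_combined <= e_div:
        fate = SUBFUNCTIONALIZED
    else:
        fate = SPECIALIZED
    return FateCall(triple_id, e_parent, e_child, e_combined, e_div, fate)


def classify_triples(
    pairs: PairTables,
    ancestor_matrix,
    focal_matrix,
    e_div: float,
) -> list[FateCall]:
    """Run the fate rules over every triple in ``pairs``.

    Ancestral profiles come from the sister-species matrix, parent/child
    profiles from the focal-genome matrix; both must be log2(x+1)-scaled
    with identical tissue order.
    """
    if ancestor_matrix.scale != "log2p1" or focal_matrix.scale != "log2p1":
        raise ValueError("fate classification expects log2(x+1) matrices")
    if ancestor_matrix.tissues != focal_matrix.tissues:
        raise ValueError("tissue order differs between matrices")
    calls = []
    for _, row in pairs.duplicate_triples.iterrows():
        a = ancestor_matrix.profile(row["ancestral"])
        p = focal_matrix.profile(row["parent"])
        c = focal_matrix.profile(row["child"])
        calls.append(
            classify_fate(
                e_parent=euclidean_distance(p, a),
                e_child=euclidean_distance(c, a),
                e_combined=euclidean_distance(combined_profile(p, c), a),
                e_div=e_div,
                triple_id=f"{row['ancestral']}|{row['parent']}|{row['child']}",
            )
        )
    return calls


def single_copy_distances(pairs: PairTables, matrix_s1, matrix_s2) -> np.ndarray:
    """E(S1,S2) for every single-copy ortholog pair present in both matrices."""
    out = []
    for _, row in pairs.ortholog_pairs.iterrows():
        g1, g2 = row["gene_s1"], row["gene_s2"]
        if g1 in matrix_s1.gene_ids and g2 in matrix_s2.gene_ids:
            out.append(euclidean_distance(matrix_s1.profile(g1), matrix_s2.profile(g2)))
    return np.asarray(out)


def fate_by_dup_type(calls, pairs: PairTables) -> pd.DataFrame:
    """Cross-tabulate fate calls by duplication type.

    Returns a DataFrame with coarse fates as rows and the five duplication
    types as columns, plus ``<fate>_prop`` rows with column-normalized
    proportions (each dup-type column of proportions sums to 1).
    """
    trip = pairs.duplicate_triples
    type_by_id = {
        f"{r['ancestral']}|{r['parent']}|{r['child']}": r["dup_type"]
        for _, r in trip.iterrows()
    }
    dup_order = ["WGD", "TD", "PD", "DSD", "TRD"]
    counts = pd.DataFrame(0, index=list(FATES_COARSE), columns=dup_order, dtype=int)
    for call in calls:
        dtype = type_by_id.get(call.triple_id)
        if dtype is None or dtype not in DUP_TYPES:
            raise ValueError(f"triple {call.triple_id!r} has unknown dup_type {dtype!r}")
        counts.loc[call.fate_coarse, dtype] += 1
    totals = counts.sum(axis=0)
    props = counts / totals.replace(0, np.nan)
    props.index = [f"{f}_prop" for f in props.index]
    return pd.concat([counts, props])


def calls_to_frame(calls, pairs: PairTables | None = None) -> pd.DataFrame:
    """Flatten fate calls to the TSV-ready output table."""
    df = pd.DataFrame(
        {
            "triple_id": [c.triple_id for c in calls],
            "e_parent": [c.e_parent for c in calls],
            "e_child": [c.e_child for c in calls],
            "e_combined": [c.e_combined for c in calls],
            "e_div": [c.e_div for c in calls],
            "fate": [c.fate for c in calls],
        }
    )
    if pairs is not None:
        type_by_id = {
            f"{r['ancestral']}|{r['parent']}|{r['child']}": r["dup_type"]
            for _, r in pairs.duplicate_triples.iterrows()
        }
        df.insert(1, "dup_type", df["triple_id"].map(type_by_id))
    return df
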