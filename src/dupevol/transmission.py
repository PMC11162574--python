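"""Generational transmission of homoeolog bias states.

Each homoeolog pair has a bias state in each generation — A-copy higher,
no significant difference, or C-copy higher — derived from a significance
call (FDR-adjusted q-value) plus a direction. The 3 x 3 grid of
(parental state, progeny state) defines nine transmission patterns in
three groups:

  group A (I-III)   state inherited unchanged ("parental legacy")
  group B (IV-V)    parental bias lost (biased -> equal)
  group C (VI-IX)   novel bias in the progeny (equal -> biased, or reversal)

The same machinery classifies expression bias (homoeolog read-count tests)
and DNA methylation bias (region-level methylation difference tests); only
the q-value/direction inputs differ.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cistrans import bh_fdr

A_GT_C = "A_gt_C"
A_EQ_C = "A_eq_C"
A_LT_C = "A_lt_C"
STATES = (A_GT_C, A_EQ_C, A_LT_C)

DEFAULT_ALPHA = 0.05

#: fixed enumeration of the 3x3 grid: (parental, progeny) -> (pattern, group)
PATTERNS: dict[tuple[str, str], tuple[str, str]] = {
    (A_GT_C, A_GT_C): ("I", "A"),
    (A_EQ_C, A_EQ_C): ("II", "A"),
    (A_LT_C, A_LT_C): ("III", "A"),
    (A_GT_C, A_EQ_C): ("IV", "B"),
    (A_LT_C, A_EQ_C): ("V", "B"),
    (A_EQ_C, A_GT_C): ("VI", "C"),
    (A_EQ_C, A_LT_C): ("VII", "C"),
    (A_GT_C, A_LT_C): ("VIII", "C"),
    (A_LT_C, A_GT_C): ("IX", "C"),
}

PATTERN_ORDER = ("I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX")


@dataclass(frozen=True)
class TransmissionRecord:
    pair_id: str
    parental: str
    progeny: str
    pattern: str
    group: str


def bias_state(q_value: float, direction_sign: int, alpha: float = DEFAULT_ALPHA) -> str:
    """Collapse a (q-value, direction) test result to a bias state.

    Non-significant pairs (q >= alpha) are A_eq_C regardless of direction;
    significant pairs take the state matching the sign. A significant call
    with a zero sign is contradictory input and raises.
    """
    if not 0 <= q_value <= 1:
        raise ValueError(f"q-value outside [0, 1]: {q_value}")
    if q_value >= alpha:
        return A_EQ_C
    if direction_sign > 0:
        return A_GT_C
    if direction_sign < 0:
        return A_LT_C
    raise ValueError("significant difference with zero direction sign")


def assign_pattern(parental: str, progeny: str, pair_id: str = "") -> TransmissionRecord:
    """Map a (parental, progeny) state pair onto the nine-pattern grid."""
    if parental not in STATES or progeny not in STATES:
        raise ValueError(f"unknown state in ({parental!r}, {progeny!r})")
    pattern, group = PATTERNS[(parental, progeny)]
    return TransmissionRecord(pair_id, parental, progeny, pattern, group)


def classify_pairs(
    parental: pd.DataFrame, progeny: pd.DataFrame, alpha: float = DEFAULT_ALPHA
) -> list[TransmissionRecord]:
    """Classify every pair present in both generations' test tables.

    Each table needs columns ``q`` and ``sign`` indexed by pair id; pairs
    missing from either generation are skipped.
    """
    shared = parental.index.intersection(progeny.index)
    records = []
    for pid in shared:
        par = bias_state(parental.at[pid, "q"], parental.at[pid, "sign"], alpha)
        pro = bias_state(progeny.at[pid, "q"], progeny.at[pid, "sign"], alpha)
        records.append(assign_pattern(par, pro, pid))
    return records


def transmission_summary(records) -> dict:
    """Count grid, pattern/group proportions and the eq-maintenance rate.

    The maintenance rate is the fraction of pairs with no parental bias
    whose progeny state is also unbiased (pattern II among parental-eq
    pairs) — the headline "parental legacy" number.
    """
    if not records:
        raise ValueError("no transmission records to summarize")
    grid = pd.DataFrame(0, index=list(STATES), columns=list(STATES), dtype=int)
    pattern_counts = {p: 0 for p in PATTERN_ORDER}
    group_counts = {"A": 0, "B": 0, "C": 0}
    for rec in records:
        grid.loc[rec.parental, rec.progeny] += 1
        pattern_counts[rec.pattern] += 1
        group_counts[rec.group] += 1
    n = len(records)
    parental_eq = int(grid.loc[A_EQ_C].sum())
    maintained = int(grid.loc[A_EQ_C, A_EQ_C])
    return {
        "n": n,
        "grid": grid,
        "pattern_counts": pattern_counts,
        "pattern_proportions": {p: c / n for p, c in pattern_counts.items()},
        "group_counts": group_counts,
        "group_proportions": {g: c / n for g, c in group_counts.items()},
        "maintenance_rate": maintained / parental_eq if parental_eq else float("nan"),
    }


def methylation_difference_tests(
    counts: pd.DataFrame, alpha: float = DEFAULT_ALPHA
) -> pd.DataFrame:
    """Two-proportion test of region methylation between A and C copies.

    ``counts`` is indexed by pair id with columns ``m_a, t_a, m_c, t_c``
    (pooled methylated/total read counts over the region for each copy).
    Each pair is tested with a chi-squared 2x2 test on
    (methylated, unmethylated) x (A, C); p-values are BH-adjusted. Returns
    a (q, sign) table ready for :func:`classify_pairs`.
    """
    pvals, signs = [], []
    for _, row in counts.iterrows():
        tbl = np.array(
            [[row["m_a"], row["t_a"] - row["m_a"]],
             [row["m_c"], row["t_c"] - row["m_c"]]],
            dtype=float,
        )
        if row["t_a"] == 0 or row["t_c"] == 0 or tbl.sum(axis=0).min() == 0:
            pvals.append(1.0)  # untestable -> no evidence of difference
            signs.append(0)
            continue
        res = stats.chi2_contingency(tbl, correction=False)
        pvals.append(float(res.pvalue))
        level_a = row["m_a"] / row["t_a"]
        level_c = row["m_c"] / row["t_c"]
        signs.append(int(np.sign(level_a - level_c)))
    return pd.DataFrame(
        {"q": bh_fdr(pvals), "sign": signs}, index=counts.index
    )


def records_to_frame(records) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "pair_id": [r.pair_id for r in records],
            "parental": [r.parental for r in records],
            "progeny": [r.progeny for r in records],
            "pattern": [r.pattern for r in records],
            "group": [r.group for r in records],
        }
    )
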