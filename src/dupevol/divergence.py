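"""Tissue specificity and divergence correlation statistics.

The tissue-specificity index tau (Yanai et al. style) summarizes expression
breadth: 0 for uniform expression across tissues, 1 for single-tissue
expression. Expression divergence (the Euclidean distance from the fate
module) is correlated against sequence divergence (Ka, Ks, Ka/Ks) and tau
with Pearson's product-moment correlation, one covariate at a time with
pairwise-complete deletion.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

COVARIATES = ("ka", "ks", "kaks", "tau")


def tau(profile) -> float:
    """Tissue-specificity index: sum_i (1 - x_i/x_max) / (n - 1).

    Requires a non-negative profile with at least two tissues and at least
    one positive value (tau is undefined on an all-zero profile). Invariant
    under positive rescaling of the profile.
    """
    x = np.asarray(profile, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("tau needs a 1-D profile of at least two tissues")
    if (x < 0).any():
        raise ValueError("tau is defined for non-negative profiles only")
    xmax = x.max()
    if xmax == 0:
        raise ValueError("tau is undefined for an all-zero profile")
    return float(np.sum(1.0 - x / xmax) / (x.size - 1))


def pearson(x, y) -> tuple[float, float]:
    """Sample Pearson r with a two-sided t-based p-value (n - 2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in input")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in x or y")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def correlate_divergence(records: pd.DataFrame) -> pd.DataFrame:
    """Correlate expression divergence with each sequence/specificity covariate.

    ``records`` needs a ``divergence`` column plus any of ``ka``, ``ks``,
    ``kaks``, ``tau``. Rows missing a covariate are dropped for that
    covariate only (pairwise-complete). Returns one row per covariate with
    n, r, p and a reason string when the correlation is undefined.
    """
    if "divergence" not in records.columns:
        raise ValueError("records must have a 'divergence' column")
    rows = []
    for cov in COVARIATES:
        if cov not in records.columns:
            rows.append({"covariate": cov, "n": 0, "r": np.nan, "p": np.nan,
                         "reason": "covariate absent"})
            continue
        sub = records[["divergence", cov]].dropna()
        n = len(sub)
        if n < 3:
            rows.append({"covariate": cov, "n": n, "r": np.nan, "p": np.nan,
                         "reason": f"only {n} complete pairs"})
            continue
        try:
            r, p = pearson(sub["divergence"], sub[cov])
        except ValueError as exc:
            rows.append({"covariate": cov, "n": n, "r": np.nan, "p": np.nan,
                         "reason": str(exc)})
            continue
        rows.append({"covariate": cov, "n": n, "r": r, "p": p, "reason": ""})
    return pd.DataFrame(rows)


def divergence_records(calls, pairs, focal_matrix) -> pd.DataFrame:
    """Build one correlation record per duplicate copy.

    Each parent and child copy contributes its own row: the copy's distance
    to the ancestral profile, its tau (computed on the log2(x+1) profile
    used for the distances) and its Ka/Ks entries, keyed by gene id.
    """
    kaks = pairs.kaks
    id_parts = {
        f"{r['ancestral']}|{r['parent']}|{r['child']}": (r["parent"], r["child"])
        for _, r in pairs.duplicate_triples.iterrows()
    }
    rows = []
    for call in calls:
        parent_gene, child_gene = id_parts[call.triple_id]
        for gene, dist in ((parent_gene, call.e_parent), (child_gene, call.e_child)):
            profile = focal_matrix.profile(gene)
            row = {
                "gene_id": gene,
                "divergence": dist,
                "tau": tau(profile) if profile.max() > 0 else np.nan,
            }
            if gene in kaks.index:
                row.update(
                    ka=kaks.at[gene, "ka"],
                    ks=kaks.at[gene, "ks"],
                    kaks=kaks.at[gene, "kaks"],
                )
            else:
                row.update(ka=np.nan, ks=np.nan, kaks=np.nan)
            rows.append(row)
    return pd.DataFrame(rows)
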