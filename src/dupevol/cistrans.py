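"""Cis/trans regulatory divergence of homoeolog pairs in an allopolyploid.

For each homoeolog pair the progenitor-mix divergence A = log2(A/C) carries
both cis and trans effects, while the within-allopolyploid divergence
B = log2(An/Cn) isolates cis effects (both subgenomes share one trans
environment); the trans contribution is A - B. Three significance calls —
A != 0, B != 0, A != B, each at BH FDR < 0.05 — plus the signs of B and
A - B place every pair in one of seven regulatory categories:

  I    cis only           A!=0, B!=0, A==B
  II   trans only         A!=0, B==0, A!=B
  III  cis + trans        A!=0, B!=0, A!=B, sign(B) == sign(A-B)
  IV   cis x trans        A!=0, B!=0, A!=B, sign(B) != sign(A-B)
  V    compensatory       A==0, B!=0, A!=B
  VI   conserved          A==0, B==0, A==B
  VII  ambiguous          every remaining combination

The default significance machinery is self-contained: an exact binomial
test on pooled counts for A != 0 and B != 0, a Welch t-test on replicate
log ratios for A != B, and Benjamini-Hochberg FDR. Externally computed
p-values (e.g. from a negative-binomial model) can be substituted through
the ``test_backend`` hook.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import CountTable

CATEGORIES = (
    "I cis-only",
    "II trans-only",
    "III cis+trans enhancing",
    "IV cis*trans opposing",
    "V compensatory",
    "VI conserved",
    "VII ambiguous",
)

DEFAULT_PSEUDOCOUNT = 0.5
DEFAULT_FDR_ALPHA = 0.05


@dataclass(frozen=True)
class RatioPair:
    """Log2 divergence of one homoeolog pair in the two generations.

    ``a`` = progenitor-mix log2(A/C) (cis + trans combined); ``b`` =
    allopolyploid log2(An/Cn) (cis only); ``trans`` = a - b exactly.
    Per-replicate log ratios are retained for the trans t-test.
    """

    pair_id: str
    a: float
    b: float
    parent_rep_ratios: tuple[float, ...]
    allo_rep_ratios: tuple[float, ...]

    @property
    def trans(self) -> float:
        return self.a - self.b


@dataclass(frozen=True)
class CategoryCall:
    pair_id: str
    a: float
    b: float
    trans: float
    q_a: float
    q_b: float
    q_ab: float
    category: str
    reason: str = ""


def compute_ratios(
    table: CountTable,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    scale_libraries: bool = True,
) -> tuple[list[RatioPair], list[str]]:
    """Compute A/B log ratios for every testable pair in a count table.

    Ratios use replicate-summed counts with ``pseudocount`` added to each
    side; per-replicate log ratios are kept for the trans test. With
    ``scale_libraries`` the progenitor-mix counts are rescaled so their
    total sequencing depth matches the allopolyploid's, putting the two
    generations' count magnitudes on a common footing. Pairs with zero
    counts on both sides of a ratio are untestable and returned separately.
    """
    df = table.counts
    pm_a = np.vstack(df["pm_a"].to_numpy()).astype(float)
    pm_c = np.vstack(df["pm_c"].to_numpy()).astype(float)
    al_a = np.vstack(df["allo_an"].to_numpy()).astype(float)
    al_c = np.vstack(df["allo_cn"].to_numpy()).astype(float)
    if scale_libraries:
        pm_depth = pm_a.sum() + pm_c.sum()
        al_depth = al_a.sum() + al_c.sum()
        if pm_depth > 0 and al_depth > 0:
            f = al_depth / pm_depth
            pm_a, pm_c = pm_a * f, pm_c * f
    pairs: list[RatioPair] = []
    untestable: list[str] = []
    for i, pid in enumerate(df.index):
        if (pm_a[i].sum() == 0 and pm_c[i].sum() == 0) or (
            al_a[i].sum() == 0 and al_c[i].sum() == 0
        ):
            untestable.append(pid)
            continue
        a = float(np.log2((pm_a[i].sum() + pseudocount) / (pm_c[i].sum() + pseudocount)))
        b = float(np.log2((al_a[i].sum() + pseudocount) / (al_c[i].sum() + pseudocount)))
        pairs.append(
            RatioPair(
                pair_id=pid,
                a=a,
                b=b,
                parent_rep_ratios=tuple(
                    np.log2((pm_a[i] + pseudocount) / (pm_c[i] + pseudocount))
                ),
                allo_rep_ratios=tuple(
                    np.log2((al_a[i] + pseudocount) / (al_c[i] + pseudocount))
                ),
            )
        )
    return pairs, untestable


def test_divergence(counts_x, counts_y) -> float:
    """Two-sided exact binomial test that the X:Y count split departs 1:1.

    Counts are pooled across replicates; X successes out of X + Y trials are
    tested against p = 0.5. Returns NaN (untestable) when the pooled total
    is zero. Counts are rounded to integers (library-size scaling can
    produce fractional values).
    """
    x = int(round(float(np.sum(counts_x))))
    y = int(round(float(np.sum(counts_y))))
    if x + y == 0:
        return float("nan")
    return float(stats.binomtest(x, x + y, 0.5).pvalue)


def test_ratio_mean(rep_ratios) -> float:
    """One-sample t-test that the mean replicate log ratio departs 0.

    The replicate-aware default for the A != 0 and B != 0 contrasts: unlike
    the pooled binomial test, it respects biological overdispersion between
    replicates (counts with NB dispersion fluctuate far beyond binomial
    sampling noise, so a binomial test is anticonservative on them).
    Returns NaN with fewer than two replicates.
    """
    r = np.asarray(rep_ratios, dtype=float)
    if r.size < 2:
        return float("nan")
    if r.std() == 0:
        return 1.0 if r.mean() == 0 else 0.0
    res = stats.ttest_1samp(r, 0.0)
    return float(res.pvalue)


def test_trans(parent_ratios, allo_ratios) -> float:
    """Welch two-sided t-test on replicate-level log ratios (A != B).

    Returns NaN with fewer than two replicates on either side; degenerate
    identical vectors give p = 1.
    """
    pr = np.asarray(parent_ratios, dtype=float)
    ar = np.asarray(allo_ratios, dtype=float)
    if pr.size < 2 or ar.size < 2:
        return float("nan")
    if pr.std() == 0 and ar.std() == 0:
        # Welch statistic is 0/0 on two constant samples; resolve by equality
        return 1.0 if pr.mean() == ar.mean() else 0.0
    res = stats.ttest_ind(pr, ar, equal_var=False)
    return float(res.pvalue)


def _pooled_tests(parent_mat: np.ndarray, allo_mat: np.ndarray):
    """Pooled-variance z-tests for A != 0, B != 0 and A != B.

    Per-replicate log ratios have near-homogeneous variance across pairs
    when overdispersion dominates counting noise, so the per-pair variance
    (2 df at 3 replicates, far too weak for FDR selection) is replaced by
    the variance pooled over all pairs — the same information-sharing idea
    as limma's moderated t / DESeq2's dispersion shrinkage, in its
    simplest form. With thousands of pairs the pooled estimate is
    effectively exact, so the statistics are treated as standard normal.
    """
    n_par = parent_mat.shape[1]
    n_al = allo_mat.shape[1]
    var_par = parent_mat.var(axis=1, ddof=1).mean()
    var_al = allo_mat.var(axis=1, ddof=1).mean()
    mean_par = parent_mat.mean(axis=1)
    mean_al = allo_mat.mean(axis=1)

    def ztest(delta, se):
        if se == 0:
            return np.where(delta == 0.0, 1.0, 0.0)
        return 2.0 * stats.norm.sf(np.abs(delta) / se)

    p_a = ztest(mean_par, np.sqrt(var_par / n_par))
    p_b = ztest(mean_al, np.sqrt(var_al / n_al))
    p_ab = ztest(mean_par - mean_al, np.sqrt(var_par / n_par + var_al / n_al))
    return p_a, p_b, p_ab


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, clipped to <= 1.

    NaN entries (untestable pairs) are passed through as NaN without
    affecting the adjustment of the remaining values.
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if ((p[mask] < 0) | (p[mask] > 1)).any():
        raise ValueError("p-values outside [0, 1]")
    if mask.any():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def assign_category(
    sig_a: bool,
    sig_b: bool,
    sig_ab: bool,
    sign_b: int,
    sign_trans: int,
) -> str:
    """Map a significance/sign pattern to its regulatory category.

    A pure function of the three significance flags and the signs of B and
    A - B; the seven categories partition all combinations.
    """
    if not sig_a and not sig_b and not sig_ab:
        return CATEGORIES[5]  # VI conserved
    if sig_a and sig_b and not sig_ab:
        return CATEGORIES[0]  # I cis-only
    if sig_a and not sig_b and sig_ab:
        return CATEGORIES[1]  # II trans-only
    if not sig_a and sig_b and sig_ab:
        return CATEGORIES[4]  # V compensatory
    if sig_a and sig_b and sig_ab:
        if sign_b == sign_trans:
            return CATEGORIES[2]  # III enhancing
        return CATEGORIES[3]  # IV opposing
    return CATEGORIES[6]  # VII ambiguous


def call_categories(
    table: CountTable,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    fdr_alpha: float = DEFAULT_FDR_ALPHA,
    scale_libraries: bool = True,
    test_backend=None,
) -> list[CategoryCall]:
    """Full pipeline: ratios, three tests, BH FDR, category per pair.

    ``test_backend`` selects the significance machinery: ``"pooled"``
    (default) tests all three contrasts with pooled-variance z-tests on the
    per-replicate log ratios, sharing the dispersion estimate across pairs;
    ``"t"`` uses per-pair one-sample t (A, B) and Welch t (A vs B) tests;
    ``"binomial"`` uses the exact binomial test on pooled counts for A and
    B (appropriate when counts are Poisson-like) with Welch for A vs B; a
    callable is invoked as ``test_backend(pair_ids) ->
    DataFrame(p_a, p_b, p_ab)`` to inject externally computed p-values
    (e.g. a negative-binomial model fit). Untestable pairs are routed to
    category VII with a reason.
    """
    ratios, untestable = compute_ratios(table, pseudocount, scale_libraries)
    calls: list[CategoryCall] = []
    if ratios:
        if callable(test_backend):
            pv = test_backend([r.pair_id for r in ratios])
            p_a = pv["p_a"].to_numpy(dtype=float)
            p_b = pv["p_b"].to_numpy(dtype=float)
            p_ab = pv["p_ab"].to_numpy(dtype=float)
        elif test_backend in (None, "pooled"):
            p_a, p_b, p_ab = _pooled_tests(
                np.array([r.parent_rep_ratios for r in ratios]),
                np.array([r.allo_rep_ratios for r in ratios]),
            )
        elif test_backend == "t":
            p_a = np.array([test_ratio_mean(r.parent_rep_ratios) for r in ratios])
            p_b = np.array([test_ratio_mean(r.allo_rep_ratios) for r in ratios])
            p_ab = np.array(
                [test_trans(r.parent_rep_ratios, r.allo_rep_ratios) for r in ratios]
            )
        elif test_backend == "binomial":
            df = table.counts
            p_a = np.array(
                [test_divergence(df.at[r.pair_id, "pm_a"], df.at[r.pair_id, "pm_c"])
                 for r in ratios]
            )
            p_b = np.array(
                [test_divergence(df.at[r.pair_id, "allo_an"], df.at[r.pair_id, "allo_cn"])
                 for r in ratios]
            )
            p_ab = np.array(
                [test_trans(r.parent_rep_ratios, r.allo_rep_ratios) for r in ratios]
            )
        else:
            raise ValueError(f"unknown test backend {test_backend!r}")
        q_a, q_b, q_ab = bh_fdr(p_a), bh_fdr(p_b), bh_fdr(p_ab)
        for i, r in enumerate(ratios):
            if np.isnan(q_a[i]) or np.isnan(q_b[i]) or np.isnan(q_ab[i]):
                calls.append(
                    CategoryCall(r.pair_id, r.a, r.b, r.trans,
                                 q_a[i], q_b[i], q_ab[i],
                                 CATEGORIES[6], reason="untestable contrast")
                )
                continue
            category = assign_category(
                sig_a=bool(q_a[i] < fdr_alpha),
                sig_b=bool(q_b[i] < fdr_alpha),
                sig_ab=bool(q_ab[i] < fdr_alpha),
                sign_b=int(np.sign(r.b)),
                sign_trans=int(np.sign(r.trans)),
            )
            calls.append(
                CategoryCall(r.pair_id, r.a, r.b, r.trans,
                             q_a[i], q_b[i], q_ab[i], category)
            )
    for pid in untestable:
        calls.append(
            CategoryCall(pid, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan,
                         CATEGORIES[6], reason="all-zero counts")
        )
    return calls


def category_summary(calls, tissues=None) -> pd.DataFrame:
    """Counts and proportions per category, pooled and (optionally) per tissue.

    ``tissues`` maps pair id -> tissue label; when given, per-tissue rows are
    emitted alongside the pooled summary.
    """
    if not calls:
        raise ValueError("no category calls to summarize")
    df = pd.DataFrame({"pair_id": [c.pair_id for c in calls],
                       "category": [c.category for c in calls]})
    groups = [("pooled", df)]
    if tissues is not None:
        df = df.assign(tissue=df["pair_id"].map(tissues))
        groups += [(t, sub) for t, sub in df.groupby("tissue")]
    rows = []
    for label, sub in groups:
        counts = sub["category"].value_counts()
        total = len(sub)
        for cat in CATEGORIES:
            n = int(counts.get(cat, 0))
            rows.append({"tissue": label, "category": cat,
                         "n": n, "proportion": n / total})
    return pd.DataFrame(rows)


def compare_call_sets(calls_x, calls_y) -> tuple[float, float]:
    """Pearson chi-squared comparison of two category distributions (2 x 7).

    Categories absent from both sets are dropped from the table; identical
    distributions give p = 1 (statistic 0).
    """
    cx = pd.Series([c.category for c in calls_x]).value_counts()
    cy = pd.Series([c.category for c in calls_y]).value_counts()
    tbl = pd.DataFrame({"x": cx, "y": cy}).reindex(CATEGORIES).fillna(0)
    tbl = tbl.loc[tbl.sum(axis=1) > 0]
    res = stats.chi2_contingency(tbl.to_numpy().T, correction=False)
    return float(res.statistic), float(res.pvalue)


def calls_to_frame(calls) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "pair_id": [c.pair_id for c in calls],
            "A": [c.a for c in calls],
            "B": [c.b for c in calls],
            "trans": [c.trans for c in calls],
            "q_A": [c.q_a for c in calls],
            "q_B": [c.q_b for c in calls],
            "q_AB": [c.q_ab for c in calls],
            "category": [c.category for c in calls],
            "reason": [c.reason for c in calls],
        }
    )
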