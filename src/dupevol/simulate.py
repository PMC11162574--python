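"""Synthetic datasets with planted ground truth for every pipeline stage.

Each generator emulates one facet of the study design — four-tissue
expression profiles in three genomes, negative-binomial homoeolog read
counts, a bisulfite-called methylome on a linear two-strand genome, and
two-generation bias-test tables — and returns a machine-readable truth
table aligned by id with the data, so recovery rates can be measured
against the generative parameters.

Noise models: Gaussian on log2 expression, negative binomial (mean mu,
variance mu + dispersion * mu^2) for read counts, binomial for methylation
calls. All randomness flows through one :class:`numpy.random.Generator`
seeded from the config, so identical seeds give identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (
    DEFAULT_TISSUES,
    LOG2P1,
    ExpressionMatrix,
    CountTable,
    GeneModel,
    PairTables,
)

# ---------------------------------------------------------------------------
# fate dataset


@dataclass
class FateSimConfig:
    """Planted-fate expression simulation.

    Two stochastic components shape the profiles. ``noise_sd`` is
    per-tissue technical/replicate noise (log2 scale) added to every
    observed profile. ``species_sd`` is neutral between-species expression
    drift: it separates the two members of a single-copy ortholog pair (and
    "null" duplicates), but NOT planted conserved copies — functional
    conservation means selection holds the copy at the ancestral optimum,
    while the single-copy calibration set drifts. ``divergence_offset`` is
    the log2 shift applied to diverging copies, over at least half the
    tissues. Offsets at or below the noise SD make recovery unreliable
    (a warning is recorded in the returned truth table attrs).
    """

    seed: int
    n_per_fate: int = 100
    n_single_copy: int = 2000
    noise_sd: float = 0.25
    species_sd: float = 0.35
    divergence_offset: float = 1.5
    tissues: tuple[str, ...] = DEFAULT_TISSUES
    baseline_lo: float = 2.0  # log2 expression of ancestral profiles
    baseline_hi: float = 8.0
    fates: tuple[str, ...] = (
        "conserved",
        "neofunctionalized(parent)",
        "neofunctionalized(child)",
        "subfunctionalized",
        "specialized",
    )
    dup_types: tuple[str, ...] = ("WGD", "TD", "PD", "DSD", "TRD")
    ks_saturated_fraction: float = 0.05  # planted Ks >= 3, exercises the filter


def simulate_fate_dataset(cfg: FateSimConfig):
    """Simulate ancestor/focal expression matrices, pair tables and fate truth.

    Returns ``(ancestor_matrix, focal_matrix, pairs, truth)``; matrices are
    log2(x+1)-scaled. Single-copy ortholog profiles differ only by noise.
    Planted fates follow the classification geometry: conserved copies sit
    at the ancestor; a neofunctionalized copy is shifted by
    ``divergence_offset`` in a random tissue subset; subfunctionalized
    copies split the ancestral raw abundance complementarily (their raw sum
    equals the ancestor exactly before noise); specialized copies both
    shift upward so the combined profile diverges too.
    """
    rng = np.random.default_rng(cfg.seed)
    n_t = len(cfg.tissues)
    if cfg.divergence_offset <= cfg.noise_sd:
        warning = "divergence_offset <= noise_sd: recovery not guaranteed"
    else:
        warning = ""

    def noisy(profile):
        out = profile + rng.normal(0.0, cfg.noise_sd, size=profile.shape)
        return np.maximum(out, 0.0)

    def baseline():
        return rng.uniform(cfg.baseline_lo, cfg.baseline_hi, size=n_t)

    anc_rows, focal_rows = {}, {}
    # single-copy orthologs: the focal-species member drifts away from the
    # shared baseline by species_sd (speciation), both carry technical noise
    sc_pairs = []
    for i in range(cfg.n_single_copy):
        a = baseline()
        g1, g2 = f"sc_a_{i:05d}", f"sc_b_{i:05d}"
        anc_rows[g1] = noisy(a)
        focal_rows[g2] = noisy(a + rng.normal(0.0, cfg.species_sd, size=n_t))
        sc_pairs.append((g1, g2))

    triples, truth_rows = [], []
    k = 0
    for fate in cfg.fates:
        for _ in range(cfg.n_per_fate):
            a = baseline()
            anc_id, par_id, chi_id = (
                f"anc_{k:05d}", f"par_{k:05d}", f"chi_{k:05d}",
            )
            par, chi = _planted_copies(a, fate, cfg, rng)
            anc_rows[anc_id] = noisy(a)
            focal_rows[par_id] = noisy(par)
            focal_rows[chi_id] = noisy(chi)
            dup_type = cfg.dup_types[k % len(cfg.dup_types)]
            triples.append((anc_id, par_id, chi_id, dup_type))
            truth_rows.append(
                {"triple_id": f"{anc_id}|{par_id}|{chi_id}", "fate": fate,
                 "dup_type": dup_type}
            )
            k += 1

    ancestor = ExpressionMatrix(
        values=pd.DataFrame.from_dict(anc_rows, orient="index",
                                      columns=list(cfg.tissues)),
        scale=LOG2P1,
    )
    focal = ExpressionMatrix(
        values=pd.DataFrame.from_dict(focal_rows, orient="index",
                                      columns=list(cfg.tissues)),
        scale=LOG2P1,
    )
    pairs = PairTables(
        ortholog_pairs=pd.DataFrame(sc_pairs, columns=["gene_s1", "gene_s2"]),
        duplicate_triples=pd.DataFrame(
            triples, columns=["ancestral", "parent", "child", "dup_type"]
        ),
        kaks=_simulate_kaks(triples, cfg, rng),
    )
    truth = pd.DataFrame(truth_rows)
    truth.attrs["warning"] = warning
    return ancestor, focal, pairs, truth


def _planted_copies(a, fate, cfg: FateSimConfig, rng):
    """Noise-free parent/child log profiles realizing one fate for ancestor a."""
    n_t = a.size
    off = cfg.divergence_offset

    def shifted(profile):
        # divergence spans at least half the tissues: a single-tissue shift
        # of 1.5 log2 sits right at a typical E_div and is not recoverable
        k = rng.integers(max(2, n_t // 2), n_t)
        idx = rng.choice(n_t, size=k, replace=False)
        out = profile.copy()
        out[idx] += off
        return out

    if fate == "conserved":
        return a.copy(), a.copy()
    if fate == "null":
        # behaves exactly like a single-copy ortholog pair: each copy
        # drifts independently by species_sd (calibration mode)
        drift = lambda: a + rng.normal(0.0, cfg.species_sd, size=n_t)
        return drift(), drift()
    if fate == "neofunctionalized(child)":
        return a.copy(), shifted(a)
    if fate == "neofunctionalized(parent)":
        return shifted(a), a.copy()
    if fate == "subfunctionalized":
        # complementary split of the raw abundance across a proper subset
        k = rng.integers(1, n_t)
        idx = rng.choice(n_t, size=k, replace=False)
        mask = np.zeros(n_t, dtype=bool)
        mask[idx] = True
        raw = 2.0**a - 1.0
        par = np.log2(np.where(mask, raw, 0.0) + 1.0)
        chi = np.log2(np.where(mask, 0.0, raw) + 1.0)
        return par, chi
    if fate == "specialized":
        return shifted(a), shifted(a)
    raise ValueError(f"unknown fate {fate!r}")


def _simulate_kaks(triples, cfg: FateSimConfig, rng):
    """Per-duplicate-gene Ka/Ks table; a planted fraction has saturated Ks."""
    genes = [g for (_a, p, c, _t) in triples for g in (p, c)]
    n = len(genes)
    ks = rng.uniform(0.05, 2.5, size=n)
    saturated = rng.random(n) < cfg.ks_saturated_fraction
    ks[saturated] = rng.uniform(3.0, 5.0, size=int(saturated.sum()))
    ratio = rng.gamma(shape=2.0, scale=0.15, size=n)  # Ka/Ks mostly < 1
    return pd.DataFrame(
        {"ka": ks * ratio, "ks": ks, "kaks": ratio}, index=pd.Index(genes, name="gene_id")
    )


# ---------------------------------------------------------------------------
# divergence-correlation records


def simulate_divergence_records(
    seed: int,
    n: int = 2000,
    r_tau: float = 0.8,
    r_ka: float = 0.45,
    r_ks: float = 0.15,
    r_kaks: float = 0.4,
) -> pd.DataFrame:
    """Correlation records with planted Pearson structure.

    Draws (divergence, ka, ks, kaks, tau) from a multivariate normal whose
    first row carries the planted correlations, then maps each margin to a
    plausible range with near-linear (clip-only) transforms so the Pearson
    coefficients survive the mapping.
    """
    rng = np.random.default_rng(seed)
    corr = np.eye(5)
    for j, r in enumerate((r_ka, r_ks, r_kaks, r_tau), start=1):
        corr[0, j] = corr[j, 0] = r
    # make the matrix positive definite if the requested r's conflict
    w, v = np.linalg.eigh(corr)
    if w.min() <= 1e-8:
        corr = v @ np.diag(np.maximum(w, 1e-6)) @ v.T
        d = np.sqrt(np.diag(corr))
        corr = corr / np.outer(d, d)
    z = rng.multivariate_normal(np.zeros(5), corr, size=n)
    return pd.DataFrame(
        {
            "divergence": np.clip(2.0 + 0.6 * z[:, 0], 0.0, None),
            "ka": np.clip(0.3 + 0.08 * z[:, 1], 0.0, None),
            "ks": np.clip(1.5 + 0.4 * z[:, 2], 0.0, None),
            "kaks": np.clip(0.4 + 0.1 * z[:, 3], 0.0, None),
            "tau": np.clip(0.5 + 0.13 * z[:, 4], 0.0, 1.0),
        }
    )


# ---------------------------------------------------------------------------
# cis/trans count dataset


@dataclass
class CountSimConfig:
    """Negative-binomial homoeolog counts with planted cis/trans effects.

    Per pair, the progenitor-mix A:C mean ratio is 2**(cis + trans) and the
    allopolyploid An:Cn mean ratio is 2**cis; effect magnitudes default to
    1.5 log2 units. ``dispersion`` is the NB overdispersion (variance =
    mu + dispersion * mu^2); ``library_size`` is the expected total count
    per sample spread over the pairs.
    """

    seed: int
    n_pairs: int = 1000
    effect_size: float = 2.0
    dispersion: float = 0.05
    library_size: float = 1e6
    n_replicates: int = 3
    category_mix: dict = field(
        default_factory=lambda: {
            "VI conserved": 0.4,
            "I cis-only": 0.2,
            "II trans-only": 0.2,
            "III cis+trans enhancing": 0.1,
            "IV cis*trans opposing": 0.05,
            "V compensatory": 0.05,
        }
    )


def _planted_effects(category: str, e: float):
    """(cis, trans) log2 effects realizing one regulatory category."""
    if category == "VI conserved":
        return 0.0, 0.0
    if category == "I cis-only":
        return e, 0.0
    if category == "II trans-only":
        return 0.0, e
    if category == "III cis+trans enhancing":
        return e, e  # sign(B) == sign(A - B)
    if category == "IV cis*trans opposing":
        return e, -2.0 * e  # A = -e significant, signs oppose
    if category == "V compensatory":
        return e, -e  # A = 0, B significant
    raise ValueError(f"unknown category {category!r}")


def simulate_count_dataset(cfg: CountSimConfig):
    """Simulate a homoeolog count table with planted regulatory categories.

    Returns ``(CountTable, truth)`` where truth records each pair's planted
    category and (cis, trans) effects. Base pair expression varies
    log-uniformly over ~1.5 orders of magnitude around the per-pair share
    of the library.
    """
    rng = np.random.default_rng(cfg.seed)
    cats = list(cfg.category_mix)
    probs = np.array([cfg.category_mix[c] for c in cats], dtype=float)
    if not np.isclose(probs.sum(), 1.0):
        raise ValueError("category_mix must sum to 1")
    assignment = rng.choice(len(cats), size=cfg.n_pairs, p=probs)

    base_mean = cfg.library_size / (2 * cfg.n_pairs)
    data = {k: [] for k in ("pm_a", "pm_c", "allo_an", "allo_cn")}
    truth_rows = []
    for i in range(cfg.n_pairs):
        cat = cats[assignment[i]]
        cis, trans = _planted_effects(cat, cfg.effect_size)
        b = base_mean * 2.0 ** rng.uniform(-1.5, 1.5)
        mu = {
            "pm_a": b * 2.0 ** ((cis + trans) / 2.0),
            "pm_c": b * 2.0 ** (-(cis + trans) / 2.0),
            "allo_an": b * 2.0 ** (cis / 2.0),
            "allo_cn": b * 2.0 ** (-cis / 2.0),
        }
        for key, m in mu.items():
            data[key].append(_nb_draw(rng, m, cfg.dispersion, cfg.n_replicates))
        truth_rows.append(
            {"pair_id": f"pair_{i:05d}", "category": cat,
             "cis": cis, "trans": trans}
        )
    index = pd.Index([r["pair_id"] for r in truth_rows], name="pair_id")
    table = CountTable(counts=pd.DataFrame(data, index=index))
    return table, pd.DataFrame(truth_rows).set_index("pair_id")


def _nb_draw(rng, mu: float, dispersion: float, size: int) -> np.ndarray:
    """Negative binomial with variance mu + dispersion * mu^2 (Poisson at 0)."""
    if dispersion <= 0:
        return rng.poisson(mu, size=size)
    shape = 1.0 / dispersion
    return rng.negative_binomial(shape, shape / (shape + mu), size=size)


# ---------------------------------------------------------------------------
# methylome


@dataclass
class MethylomeSimConfig:
    """Methylome with planted expression-class-dependent landscapes.

    Genes sit on non-overlapping slots of a linear genome, strand drawn at
    random; cytosines occur every ``site_spacing`` bp on alternating
    contexts. Methylation probability is ``flank_level`` outside gene
    bodies and the class-specific ``body_levels`` inside; calls are
    binomial at ``coverage`` reads. With ``expression_corr`` set, per-gene
    body levels are instead drawn jointly with expression at the requested
    Pearson correlation (continuous anticorrelation mode).
    """

    seed: int
    n_genes: int = 500
    genome_length: int = 2_000_000
    gene_length_lo: int = 800
    gene_length_hi: int = 1200
    site_spacing: int = 10
    coverage: int = 20
    flank_level: float = 0.8
    body_levels: dict = field(
        default_factory=lambda: {"non": 0.35, "low": 0.25, "medium": 0.15,
                                 "high": 0.05}
    )
    expression_corr: float | None = None  # e.g. -0.5 for anticorrelation mode
    tissues: tuple[str, ...] = DEFAULT_TISSUES
    flank_bp: int = 2000

    #: FPKM sampling ranges per class (log-uniform within)
    class_fpkm: dict = field(
        default_factory=lambda: {"non": (1e-5, 5e-4), "low": (0.01, 5.0),
                                 "medium": (5.5, 50.0), "high": (55.0, 500.0)}
    )


def simulate_methylome(cfg: MethylomeSimConfig):
    """Simulate gene models, methylation calls, expression and truth.

    Returns ``(genes, calls, expression_matrix, truth)``. ``truth`` has one
    row per gene: class, planted body level, planted flank level, FPKM.
    The expression matrix holds raw FPKM, constant across tissues up to a
    small lognormal wobble (region-level analyses use the mean).
    """
    rng = np.random.default_rng(cfg.seed)
    slot = cfg.genome_length // cfg.n_genes
    if slot < cfg.gene_length_hi + 200:
        raise ValueError(
            f"genome too short: slot {slot} bp < gene {cfg.gene_length_hi} bp + margin"
        )

    classes = list(cfg.body_levels)
    genes: list[GeneModel] = []
    truth_rows = []
    if cfg.expression_corr is not None:
        rho = cfg.expression_corr
        z = rng.multivariate_normal(
            [0, 0], [[1, rho], [rho, 1]], size=cfg.n_genes
        )

    for i in range(cfg.n_genes):
        length = int(rng.integers(cfg.gene_length_lo, cfg.gene_length_hi + 1))
        start = i * slot + (slot - length) // 2 + 1
        strand = "+" if rng.random() < 0.5 else "-"
        gid = f"gene_{i:05d}"
        genes.append(GeneModel("chr1", start, start + length - 1, strand, gid))
        if cfg.expression_corr is not None:
            log_expr = np.clip(5.0 + 1.5 * z[i, 0], 0.0, None)
            fpkm = float(2.0**log_expr - 1.0)
            body = float(np.clip(0.5 + 0.15 * z[i, 1], 0.02, 0.98))
            cls = _class_of(fpkm)
        else:
            cls = classes[i % len(classes)]
            lo, hi = cfg.class_fpkm[cls]
            fpkm = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            body = float(cfg.body_levels[cls])
        truth_rows.append(
            {"gene_id": gid, "class": cls, "body_level": body,
             "flank_level": cfg.flank_level, "fpkm": fpkm}
        )
    truth = pd.DataFrame(truth_rows).set_index("gene_id")

    # per-position methylation probability: body level inside a gene body,
    # flank level everywhere else
    positions = np.arange(1, cfg.genome_length + 1, cfg.site_spacing)
    prob = np.full(positions.size, cfg.flank_level)
    for g, (_, t) in zip(genes, truth.iterrows()):
        inside = (positions >= g.start) & (positions <= g.end)
        prob[inside] = t["body_level"]
    n_meth = rng.binomial(cfg.coverage, prob)
    context_cycle = np.array(["CG", "CHG", "CHH"])
    calls = pd.DataFrame(
        {
            "chrom": "chr1",
            "position": positions,
            "context": context_cycle[np.arange(positions.size) % 3],
            "n_methylated": n_meth,
            "n_total": cfg.coverage,
        }
    )

    expr = np.outer(
        truth["fpkm"].to_numpy(),
        np.ones(len(cfg.tissues)),
    ) * rng.lognormal(0.0, 0.05, size=(cfg.n_genes, len(cfg.tissues)))
    matrix = ExpressionMatrix(
        values=pd.DataFrame(expr, index=truth.index, columns=list(cfg.tissues)),
        scale="raw",
    )
    return genes, calls, matrix, truth


def _class_of(fpkm: float) -> str:
    if fpkm < 0.001:
        return "non"
    if fpkm <= 5:
        return "low"
    if fpkm <= 50:
        return "medium"
    return "high"


# ---------------------------------------------------------------------------
# transmission tables


@dataclass
class TransmissionSimConfig:
    """Two-generation bias-state tables drawn from planted pattern frequencies.

    ``pattern_freqs`` maps pattern (I..IX) to probability; must sum to 1.
    Significance inputs realize each state deterministically: biased states
    get q = alpha / 10 with the matching sign, unbiased states q = 0.5.
    """

    seed: int
    n_pairs: int = 10_000
    alpha: float = 0.05
    #: default composition: parental legacy (group A) dominates, loss of
    #: parental bias is the main change, novel/reversed bias is rare and
    #: reversals (VIII/IX) rarest; gives an eq-maintenance rate of ~97%
    pattern_freqs: dict = field(
        default_factory=lambda: {
            "I": 0.12, "II": 0.62, "III": 0.12,
            "IV": 0.06, "V": 0.06,
            "VI": 0.0095, "VII": 0.0095, "VIII": 0.0005, "IX": 0.0005,
        }
    )


def simulate_transmission(cfg: TransmissionSimConfig):
    """Simulate parental/progeny (q, sign) tables plus pattern truth.

    Returns ``(parental, progeny, truth)`` where the two test tables are
    indexed by pair id with columns q and sign, and truth records each
    pair's planted pattern.
    """
    from .transmission import PATTERNS  # state grid is the single source

    freqs = cfg.pattern_freqs
    probs = np.array(list(freqs.values()), dtype=float)
    if not np.isclose(probs.sum(), 1.0):
        raise ValueError("pattern_freqs must sum to 1")
    patterns = list(freqs)
    state_of = {pat: states for states, (pat, _g) in PATTERNS.items()}
    unknown = set(patterns) - set(state_of)
    if unknown:
        raise ValueError(f"unknown pattern(s) {sorted(unknown)}")

    rng = np.random.default_rng(cfg.seed)
    draw = rng.choice(len(patterns), size=cfg.n_pairs, p=probs)

    def realize(state: str):
        if state == "A_eq_C":
            return 0.5, 0
        sign = 1 if state == "A_gt_C" else -1
        return cfg.alpha / 10.0, sign

    rows_par, rows_pro, truth_rows = [], [], []
    for i in range(cfg.n_pairs):
        pat = patterns[draw[i]]
        par_state, pro_state = state_of[pat]
        q1, s1 = realize(par_state)
        q2, s2 = realize(pro_state)
        pid = f"hp_{i:06d}"
        rows_par.append({"pair_id": pid, "q": q1, "sign": s1})
        rows_pro.append({"pair_id": pid, "q": q2, "sign": s2})
        truth_rows.append({"pair_id": pid, "pattern": pat})
    parental = pd.DataFrame(rows_par).set_index("pair_id")
    progeny = pd.DataFrame(rows_pro).set_index("pair_id")
    truth = pd.DataFrame(truth_rows).set_index("pair_id")
    return parental, progeny, truth
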