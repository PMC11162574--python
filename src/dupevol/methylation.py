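"""Region-level methylation and expression-stratified meta-gene profiles.

Genes are stratified into four expression classes (non / low / medium /
high, on raw FPKM) and per-cytosine bisulfite calls are summarized two
ways: coverage-weighted levels over whole regions (promoter, gene body,
downstream flank), and meta-gene profiles that average methylation in bins
anchored at the TSS and TES — fixed-width bins over the 2 kb flanks and
proportional bins over the gene body, strand-aware so that "upstream" is
always 5' of the TSS. Levels are read-count weighted (sum methylated reads
over sum total reads), which makes per-bin values additive across split
call files and robust to coverage variation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .divergence import pearson
from .io import CONTEXTS, GeneModel

log = logging.getLogger(__name__)

EXPRESSION_CLASSES = ("non", "low", "medium", "high")

FLANK_BP = 2000
DEFAULT_FLANK_BIN_WIDTH = 100
DEFAULT_N_BODY_BINS = 40
DEFAULT_MIN_SITES = 3

PROMOTER = "promoter"
GENE_BODY = "gene_body"
DOWNSTREAM = "downstream"
REGIONS = (PROMOTER, GENE_BODY, DOWNSTREAM)


def classify_expression(fpkm: float) -> str:
    """Assign the four-way expression class from a raw FPKM value.

    non: < 0.001; low: 0.001–5 (inclusive); medium: (5, 50]; high: > 50.
    The "between x and y" intervals are read closed on the right.
    """
    if fpkm < 0:
        raise ValueError(f"negative FPKM: {fpkm}")
    if fpkm < 0.001:
        return "non"
    if fpkm <= 5:
        return "low"
    if fpkm <= 50:
        return "medium"
    return "high"


@dataclass
class RegionMethylation:
    gene_id: str
    region: str
    context: str
    level: float  # NaN when covered sites < min_sites
    n_sites: int


@dataclass
class MetaGeneProfile:
    """Per-expression-class binned methylation around and across genes.

    ``levels`` maps class -> vector over n_flank + n_body + n_flank bins
    (upstream flank, body, downstream flank in transcriptional order);
    ``n_genes`` maps class -> contributing gene count. Bin means are
    coverage-weighted across all genes of the class.
    """

    context: str
    n_flank_bins: int
    n_body_bins: int
    levels: dict[str, np.ndarray] = field(default_factory=dict)
    n_genes: dict[str, int] = field(default_factory=dict)
    n_excluded_short: int = 0

    @property
    def n_bins(self) -> int:
        return 2 * self.n_flank_bins + self.n_body_bins


class _CallIndex:
    """Per-chromosome sorted position index over a call table."""

    def __init__(self, calls: pd.DataFrame, context: str | None):
        if context is not None:
            if context not in CONTEXTS:
                raise ValueError(f"unknown context {context!r}")
            calls = calls[calls["context"] == context]
        self._by_chrom = {}
        for chrom, sub in calls.groupby("chrom"):
            sub = sub.sort_values("position")
            self._by_chrom[chrom] = (
                sub["position"].to_numpy(),
                sub["n_methylated"].to_numpy(dtype=float),
                sub["n_total"].to_numpy(dtype=float),
            )

    def window(self, chrom: str, lo: int, hi: int):
        """Positions / methylated / total arrays for calls in [lo, hi]."""
        if chrom not in self._by_chrom or lo > hi:
            empty = np.array([])
            return empty, empty, empty
        pos, m, t = self._by_chrom[chrom]
        i = np.searchsorted(pos, lo, side="left")
        j = np.searchsorted(pos, hi, side="right")
        return pos[i:j], m[i:j], t[i:j]


def region_bounds(gene: GeneModel, region: str, flank_bp: int = FLANK_BP):
    """1-based inclusive bounds of a region, strand-aware.

    The promoter is ``flank_bp`` upstream of the TSS, downstream is
    ``flank_bp`` past the TES; regions running past the chromosome start are
    truncated at position 1 (logged by the caller).
    """
    if region == GENE_BODY:
        return gene.start, gene.end
    if (region == PROMOTER and gene.strand == "+") or (
        region == DOWNSTREAM and gene.strand == "-"
    ):
        return gene.start - flank_bp, gene.start - 1
    return gene.end + 1, gene.end + flank_bp


def region_methylation(
    calls: pd.DataFrame,
    gene: GeneModel,
    region: str,
    context: str | None = "CG",
    min_sites: int = DEFAULT_MIN_SITES,
    flank_bp: int = FLANK_BP,
    index: "_CallIndex | None" = None,
) -> RegionMethylation:
    """Coverage-weighted methylation level of one region of one gene.

    level = sum(n_methylated) / sum(n_total) over covered cytosines of the
    requested context inside the region; NaN when fewer than ``min_sites``
    cytosines are covered.
    """
    if region not in REGIONS:
        raise ValueError(f"unknown region {region!r}")
    idx = index if index is not None else _CallIndex(calls, context)
    lo, hi = region_bounds(gene, region, flank_bp)
    if lo < 1:
        log.info("gene %s: %s truncated at chromosome start", gene.gene_id, region)
        lo = 1
    pos, m, t = idx.window(gene.chrom, lo, hi)
    n_sites = int(pos.size)
    level = float(m.sum() / t.sum()) if n_sites >= min_sites else float("nan")
    return RegionMethylation(gene.gene_id, region, context or "all", level, n_sites)


def region_methylation_table(
    calls: pd.DataFrame,
    genes,
    context: str | None = "CG",
    min_sites: int = DEFAULT_MIN_SITES,
    flank_bp: int = FLANK_BP,
) -> pd.DataFrame:
    """Region levels for all genes x all three regions, as a tidy table."""
    idx = _CallIndex(calls, context)
    rows = []
    for gene in genes:
        for region in REGIONS:
            rm = region_methylation(
                calls, gene, region, context, min_sites, flank_bp, index=idx
            )
            rows.append(
                {"gene_id": rm.gene_id, "region": rm.region, "context": rm.context,
                 "level": rm.level, "n_sites": rm.n_sites}
            )
    return pd.DataFrame(rows)


def metagene_profile(
    calls: pd.DataFrame,
    genes,
    classes: dict[str, str],
    n_body_bins: int = DEFAULT_N_BODY_BINS,
    flank_bin_width: int = DEFAULT_FLANK_BIN_WIDTH,
    context: str | None = "CG",
    flank_bp: int = FLANK_BP,
) -> MetaGeneProfile:
    """Expression-class-stratified meta-gene methylation profile.

    For each gene, cytosine positions in the 2 kb upstream flank, the gene
    body and the 2 kb downstream flank are mapped to bins: fixed
    ``flank_bin_width`` bins over the flanks and ``n_body_bins`` relative
    (proportional-position) bins over the body. Minus-strand genes are
    flipped so bin 0 is always the far 5' end. Per bin and class the level
    is the coverage-weighted mean over all contributing genes. Genes
    shorter than ``n_body_bins`` bp are excluded and counted; classes with
    no genes get an all-NaN vector.
    """
    if flank_bp % flank_bin_width:
        raise ValueError("flank_bp must be a multiple of flank_bin_width")
    n_flank = flank_bp // flank_bin_width
    n_bins = 2 * n_flank + n_body_bins
    idx = _CallIndex(calls, context)
    sums_m = {c: np.zeros(n_bins) for c in EXPRESSION_CLASSES}
    sums_t = {c: np.zeros(n_bins) for c in EXPRESSION_CLASSES}
    n_genes = {c: 0 for c in EXPRESSION_CLASSES}
    n_short = 0

    for gene in genes:
        cls = classes.get(gene.gene_id)
        if cls is None:
            continue
        if cls not in EXPRESSION_CLASSES:
            raise ValueError(f"gene {gene.gene_id}: unknown class {cls!r}")
        if gene.length < n_body_bins:
            n_short += 1
            continue
        lo = max(1, gene.start - flank_bp)
        hi = gene.end + flank_bp
        pos, m, t = idx.window(gene.chrom, lo, hi)
        if pos.size == 0:
            n_genes[cls] += 1
            continue
        bins = _map_bins(pos, gene, n_flank, n_body_bins, flank_bin_width, flank_bp)
        valid = bins >= 0
        np.add.at(sums_m[cls], bins[valid], m[valid])
        np.add.at(sums_t[cls], bins[valid], t[valid])
        n_genes[cls] += 1

    profile = MetaGeneProfile(
        context=context or "all",
        n_flank_bins=n_flank,
        n_body_bins=n_body_bins,
        n_genes=n_genes,
        n_excluded_short=n_short,
    )
    for cls in EXPRESSION_CLASSES:
        with np.errstate(invalid="ignore", divide="ignore"):
            profile.levels[cls] = sums_m[cls] / sums_t[cls]
        if n_genes[cls] == 0:
            log.info("meta-gene profile: no genes in class %r", cls)
    return profile


def _map_bins(pos, gene: GeneModel, n_flank, n_body, flank_bin_width, flank_bp):
    """Map genomic positions to transcription-oriented bin indices (-1 = out)."""
    bins = np.full(pos.shape, -1, dtype=int)
    if gene.strand == "+":
        d = pos - gene.start  # <0 upstream, 0..len-1 body, >=len downstream
    else:
        d = gene.end - pos
    length = gene.length
    up = d < 0
    body = (d >= 0) & (d < length)
    down = d >= length
    # upstream: distance 1..flank_bp before TSS -> bins 0..n_flank-1
    ud = -d[up]  # 1..flank_bp
    ub = n_flank - 1 - (ud - 1) // flank_bin_width
    ok = (ud >= 1) & (ud <= flank_bp)
    bins[np.flatnonzero(up)[ok]] = ub[ok]
    # body: proportional position -> n_body relative bins
    bb = (d[body] * n_body) // length
    bins[body] = n_flank + bb.astype(int)
    # downstream: distance 1..flank_bp past TES
    dd = d[down] - length + 1
    db = (dd - 1) // flank_bin_width
    ok = (dd >= 1) & (dd <= flank_bp)
    bins[np.flatnonzero(down)[ok]] = n_flank + n_body + db[ok].astype(int)
    return bins


def methylation_expression_association(
    region_levels: pd.DataFrame, fpkm: pd.Series
) -> pd.DataFrame:
    """Pearson association of region methylation with log2(FPKM + 1).

    One (r, p, n) row per region x context present in ``region_levels``;
    degenerate inputs (constant level, < 3 genes) yield NaN with a reason.
    """
    rows = []
    for (region, context), sub in region_levels.groupby(["region", "context"]):
        merged = sub.dropna(subset=["level"]).merge(
            fpkm.rename("fpkm"), left_on="gene_id", right_index=True
        )
        n = len(merged)
        if n < 3:
            rows.append({"region": region, "context": context, "n": n,
                         "r": np.nan, "p": np.nan, "reason": f"only {n} genes"})
            continue
        try:
            r, p = pearson(merged["level"], np.log2(merged["fpkm"] + 1.0))
        except ValueError as exc:
            rows.append({"region": region, "context": context, "n": n,
                         "r": np.nan, "p": np.nan, "reason": str(exc)})
            continue
        rows.append({"region": region, "context": context, "n": n,
                     "r": r, "p": p, "reason": ""})
    return pd.DataFrame(rows)


def profile_to_frame(profile: MetaGeneProfile) -> pd.DataFrame:
    """Flatten a meta-gene profile to the TSV-ready (bin, class, level) table."""
    rows = []
    for cls in EXPRESSION_CLASSES:
        levels = profile.levels[cls]
        for b in range(profile.n_bins):
            if b < profile.n_flank_bins:
                segment = "upstream"
            elif b < profile.n_flank_bins + profile.n_body_bins:
                segment = "body"
            else:
                segment = "downstream"
            rows.append(
                {"bin": b, "segment": segment, "class": cls,
                 "level": levels[b], "n_genes": profile.n_genes[cls],
                 "context": profile.context}
            )
    return pd.DataFrame(rows)
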