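"""End-to-end orchestration: config, stages, manifest.

``run_all`` wires the modules together over files on disk: expression
matrices and pair tables feed the fate and correlation stages, homoeolog
counts feed the cis/trans stage (whose per-generation tests also provide
the expression bias states for the transmission stage), and the gene
models + methylation calls feed the methylation stage. Every stage writes
a TSV; a JSON manifest records the resolved configuration, the selected
E_div and all filter counts so a run is self-describing and repeatable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, cistrans, divergence, fate, io, methylation, preprocess
from . import simulate as sim
from . import transmission as trans

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All input paths and tunables for a pipeline run.

    Unknown keys in a config file are rejected (typos must fail loudly, not
    silently fall back to defaults).
    """

    # inputs
    ancestor_expression: str = "species_a_expression.tsv"
    focal_expression: str = "species_b_expression.tsv"
    ortholog_pairs: str = "ortholog_pairs.tsv"
    duplicate_triples: str = "duplicate_triples.tsv"
    kaks_table: str = "kaks.tsv"
    count_table: str = "homoeolog_counts.tsv"
    gff: str = "genes.gff3"
    methylation_calls: str = "methylation_calls.tsv"
    methylome_expression: str = "methylome_expression.tsv"
    methylation_bias: str = "methylation_bias.tsv"  # parental/progeny m/t counts

    # tunables
    ediv_quantile: float = fate.DEFAULT_EDIV_QUANTILE
    e_div: float | None = None
    fdr_alpha: float = cistrans.DEFAULT_FDR_ALPHA
    pseudocount: float = cistrans.DEFAULT_PSEUDOCOUNT
    test_backend: str = "pooled"
    scale_libraries: bool = True
    n_replicates: int = 3
    n_body_bins: int = methylation.DEFAULT_N_BODY_BINS
    flank_bin_width: int = methylation.DEFAULT_FLANK_BIN_WIDTH
    min_sites: int = methylation.DEFAULT_MIN_SITES
    context: str | None = None  # None = all contexts combined
    low_expression_cutoff: float = preprocess.LOW_EXPRESSION_CUTOFF
    ks_cutoff: float = preprocess.KS_CUTOFF
    seed: int = 0


def load_config(path) -> RunConfig:
    """Read a flat YAML config; unknown keys raise with the key named."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    return RunConfig(**raw)


def write_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(cfg), fh, sort_keys=True)


def simulate_inputs(cfg: RunConfig, indir, seed: int) -> None:
    """Materialize a complete synthetic input set under ``indir``.

    Writes exactly the file formats the readers consume, plus truth tables
    (``truth_*.tsv``) aligned by id for recovery checks.
    """
    indir = Path(indir)
    indir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    sub = lambda: int(rng.integers(0, 2**31 - 1))

    anc, foc, pairs, fate_truth = sim.simulate_fate_dataset(
        sim.FateSimConfig(seed=sub())
    )
    # matrices are written on the raw scale; the pipeline re-log-transforms
    io.write_expression_matrix(
        preprocess.inverse_log_transform(anc), indir / cfg.ancestor_expression
    )
    io.write_expression_matrix(
        preprocess.inverse_log_transform(foc), indir / cfg.focal_expression
    )
    pairs.ortholog_pairs.to_csv(indir / cfg.ortholog_pairs, sep="\t", index=False)
    pairs.duplicate_triples.to_csv(
        indir / cfg.duplicate_triples, sep="\t", index=False
    )
    pairs.kaks.to_csv(indir / cfg.kaks_table, sep="\t")
    fate_truth.to_csv(indir / "truth_fates.tsv", sep="\t", index=False)

    table, cat_truth = sim.simulate_count_dataset(sim.CountSimConfig(seed=sub()))
    io.write_count_table(table, indir / cfg.count_table)
    cat_truth.to_csv(indir / "truth_categories.tsv", sep="\t")

    genes, calls, expr, meth_truth = sim.simulate_methylome(
        sim.MethylomeSimConfig(seed=sub())
    )
    io.write_gff3_genes(genes, indir / cfg.gff)
    io.write_methylation_calls(calls, indir / cfg.methylation_calls)
    io.write_expression_matrix(expr, indir / cfg.methylome_expression)
    meth_truth.to_csv(indir / "truth_methylome.tsv", sep="\t")

    # methylation bias counts for the transmission stage: gene-body pooled
    # counts for the two copies in each generation, driven by planted states
    _write_methylation_bias(indir / cfg.methylation_bias, sub())


def _write_methylation_bias(path, seed: int, n_pairs: int = 2000) -> None:
    """Pooled region counts for parental and progeny methylation bias tests."""
    tcfg = sim.TransmissionSimConfig(seed=seed, n_pairs=n_pairs)
    parental, progeny, truth = sim.simulate_transmission(tcfg)
    rng = np.random.default_rng(seed + 1)
    rows = []
    for gen, table in (("parental", parental), ("progeny", progeny)):
        for pid, row in table.iterrows():
            # realize the planted state as methylation proportions
            base = 0.5
            delta = 0.15 * row["sign"]
            t_a = t_c = int(rng.integers(400, 600))
            rows.append(
                {"pair_id": pid, "generation": gen,
                 "m_a": rng.binomial(t_a, base + delta),
                 "t_a": t_a,
                 "m_c": rng.binomial(t_c, base - delta),
                 "t_c": t_c}
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    truth.to_csv(Path(path).with_name("truth_methylation_patterns.tsv"), sep="\t")


def run_all(cfg: RunConfig, indir, outdir) -> dict:
    """Run every stage over the inputs in ``indir``, writing to ``outdir``.

    Returns the manifest dict (also written as ``manifest.json``). Missing
    inputs are reported before any stage runs.
    """
    indir, outdir = Path(indir), Path(outdir)
    missing = [
        name
        for name in (
            cfg.ancestor_expression, cfg.focal_expression, cfg.ortholog_pairs,
            cfg.duplicate_triples, cfg.kaks_table, cfg.count_table, cfg.gff,
            cfg.methylation_calls, cfg.methylome_expression, cfg.methylation_bias,
        )
        if not (indir / name).exists()
    ]
    if missing:
        raise FileNotFoundError(f"missing input file(s): {', '.join(missing)}")
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "config": dataclasses.asdict(cfg)}

    # --- preprocess + fate
    anc = preprocess.log_transform(
        io.read_expression_matrix(indir / cfg.ancestor_expression)
    )
    foc = preprocess.log_transform(
        io.read_expression_matrix(indir / cfg.focal_expression)
    )
    anc, rep_anc = preprocess.filter_low_expression(anc, cfg.low_expression_cutoff)
    foc, rep_foc = preprocess.filter_low_expression(foc, cfg.low_expression_cutoff)
    pairs = io.read_pair_tables(
        indir / cfg.ortholog_pairs, indir / cfg.duplicate_triples,
        indir / cfg.kaks_table,
    )
    pairs, rep_ks = preprocess.filter_ks(pairs, cfg.ks_cutoff)
    surviving = set(anc.gene_ids) | set(foc.gene_ids)
    pairs, rep_member = preprocess.drop_filtered_triples(pairs, surviving)
    manifest["filters"] = {
        "ancestor_low_expression": rep_anc.summary(),
        "focal_low_expression": rep_foc.summary(),
        "ks": rep_ks.summary(),
        "triple_members": rep_member.summary(),
    }
    sc = fate.single_copy_distances(pairs, anc, foc)
    e_div = fate.select_ediv(sc, cfg.ediv_quantile, e_div=cfg.e_div)
    manifest["e_div"] = e_div
    manifest["ediv_quantile"] = cfg.ediv_quantile
    calls = fate.classify_triples(pairs, anc, foc, e_div)
    fate.calls_to_frame(calls, pairs).to_csv(
        outdir / "fates.tsv", sep="\t", index=False
    )
    fate.fate_by_dup_type(calls, pairs).to_csv(outdir / "fate_by_dup_type.tsv", sep="\t")

    # --- divergence correlations
    records = divergence.divergence_records(calls, pairs, foc)
    divergence.correlate_divergence(records).to_csv(
        outdir / "divergence_correlations.tsv", sep="\t", index=False
    )

    # --- cis/trans
    counts = io.read_count_table(indir / cfg.count_table, cfg.n_replicates)
    cat_calls = cistrans.call_categories(
        counts,
        pseudocount=cfg.pseudocount,
        fdr_alpha=cfg.fdr_alpha,
        scale_libraries=cfg.scale_libraries,
        test_backend=cfg.test_backend,
    )
    cat_frame = cistrans.calls_to_frame(cat_calls)
    cat_frame.to_csv(outdir / "cistrans.tsv", sep="\t", index=False)
    cistrans.category_summary(cat_calls).to_csv(
        outdir / "cistrans_summary.tsv", sep="\t", index=False
    )

    # --- expression transmission, from the cis/trans q-values
    valid = cat_frame.dropna(subset=["q_A", "q_B"])

    def bias_table(q_col, ratio_col):
        q = valid[q_col].to_numpy(dtype=float).copy()
        sign = np.sign(valid[ratio_col].to_numpy()).astype(int)
        q[sign == 0] = 1.0  # a zero-magnitude divergence is no bias
        return pd.DataFrame({"q": q, "sign": sign}, index=valid["pair_id"])

    parental = bias_table("q_A", "A")
    progeny = bias_table("q_B", "B")
    expr_records = trans.classify_pairs(parental, progeny, cfg.fdr_alpha)
    trans.records_to_frame(expr_records).to_csv(
        outdir / "transmission_expression.tsv", sep="\t", index=False
    )
    expr_summary = trans.transmission_summary(expr_records)
    _write_transmission_summary(expr_summary, outdir / "transmission_expression_summary.tsv")
    manifest["expression_maintenance_rate"] = expr_summary["maintenance_rate"]

    # --- methylation transmission, from region-count difference tests
    bias = pd.read_csv(indir / cfg.methylation_bias, sep="\t")
    meth_tables = {
        gen: trans.methylation_difference_tests(
            sub.set_index("pair_id"), cfg.fdr_alpha
        )
        for gen, sub in bias.groupby("generation")
    }
    meth_records = trans.classify_pairs(
        meth_tables["parental"], meth_tables["progeny"], cfg.fdr_alpha
    )
    trans.records_to_frame(meth_records).to_csv(
        outdir / "transmission_methylation.tsv", sep="\t", index=False
    )
    meth_summary = trans.transmission_summary(meth_records)
    _write_transmission_summary(meth_summary, outdir / "transmission_methylation_summary.tsv")
    manifest["methylation_maintenance_rate"] = meth_summary["maintenance_rate"]

    # --- methylation profiles
    genes = io.read_gff3_genes(indir / cfg.gff)
    calls_df = io.read_methylation_calls(indir / cfg.methylation_calls)
    meth_expr = io.read_expression_matrix(indir / cfg.methylome_expression)
    fpkm = meth_expr.values.mean(axis=1)
    classes = {g: methylation.classify_expression(v) for g, v in fpkm.items()}
    region_tbl = methylation.region_methylation_table(
        calls_df, genes, context=cfg.context, min_sites=cfg.min_sites
    )
    region_tbl.to_csv(outdir / "region_methylation.tsv", sep="\t", index=False)
    profile = methylation.metagene_profile(
        calls_df, genes, classes,
        n_body_bins=cfg.n_body_bins, flank_bin_width=cfg.flank_bin_width,
        context=cfg.context,
    )
    methylation.profile_to_frame(profile).to_csv(
        outdir / "metagene_profile.tsv", sep="\t", index=False
    )
    methylation.methylation_expression_association(region_tbl, fpkm).to_csv(
        outdir / "methylation_expression_association.tsv", sep="\t", index=False
    )

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _write_transmission_summary(summary: dict, path) -> None:
    rows = [
        {"pattern": p, "n": summary["pattern_counts"][p],
         "proportion": summary["pattern_proportions"][p]}
        for p in trans.PATTERN_ORDER
    ]
    df = pd.DataFrame(rows)
    df.attrs["maintenance_rate"] = summary["maintenance_rate"]
    with open(path, "w") as fh:
        fh.write(f"# maintenance_rate\t{summary['maintenance_rate']:.6f}\n")
        fh.write(f"# n\t{summary['n']}\n")
        df.to_csv(fh, sep="\t", index=False)
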