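"""Readers and writers for the tabular formats the pipeline consumes.

All downstream modules work on the in-memory containers defined here:
expression matrices, ortholog/duplicate pair tables, gene models,
per-cytosine methylation calls, and homoeolog replicate count tables.
Every reader validates and rejects malformed rows rather than coercing.

Genomic coordinates are 1-based inclusive throughout (GFF3 convention);
any 0-based half-open input converts at the boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: canonical tissue order; Euclidean distances are order-sensitive, so all
#: matrices entering a comparison must share this order.
DEFAULT_TISSUES = ("stem", "leaf", "flower", "silique")

#: the five duplication types produced by whole-genome / small-scale events
DUP_TYPES = frozenset({"WGD", "TD", "PD", "DSD", "TRD"})

RAW = "raw"
LOG2P1 = "log2p1"


class LoadError(ValueError):
    """A file violated the format contract; message names the offending row."""


@dataclass
class ExpressionMatrix:
    """Gene x tissue expression values (FPKM/TPM or log2(x+1) thereof).

    ``values`` is a DataFrame indexed by gene id with one column per tissue;
    ``scale`` records whether values are on the raw or log2(x+1) scale.
    """

    values: pd.DataFrame
    scale: str = RAW

    def __post_init__(self) -> None:
        if self.scale not in (RAW, LOG2P1):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.values.isna().any().any():
            bad = self.values.index[self.values.isna().any(axis=1)][0]
            raise LoadError(f"missing expression value for gene {bad!r}")
        if (self.values.values < 0).any():
            bad = self.values.index[(self.values < 0).any(axis=1)][0]
            raise LoadError(f"negative expression value for gene {bad!r}")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise LoadError(f"duplicated gene id(s): {', '.join(map(str, dups))}")

    @property
    def tissues(self) -> tuple[str, ...]:
        return tuple(self.values.columns)

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    def profile(self, gene_id: str) -> np.ndarray:
        """Expression vector of one gene, in tissue order."""
        return self.values.loc[gene_id].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class PairTables:
    """Single-copy ortholog pairs, duplicate triples and the Ka/Ks table."""

    ortholog_pairs: pd.DataFrame  # columns: gene_s1, gene_s2
    duplicate_triples: pd.DataFrame  # columns: ancestral, parent, child, dup_type
    kaks: pd.DataFrame  # index: gene id; columns: ka, ks, kaks

    def __post_init__(self) -> None:
        bad = set(self.duplicate_triples["dup_type"]) - DUP_TYPES
        if bad:
            raise LoadError(f"unknown duplication type(s): {sorted(bad)}")
        same = self.duplicate_triples["parent"] == self.duplicate_triples["child"]
        if same.any():
            gid = self.duplicate_triples.loc[same, "parent"].iloc[0]
            raise LoadError(f"gene {gid!r} is both parent and child in one triple")


@dataclass(frozen=True)
class GeneModel:
    """A gene interval, 1-based inclusive, with strand."""

    chrom: str
    start: int
    end: int
    strand: str
    gene_id: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise LoadError(
                f"gene {self.gene_id!r}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise LoadError(f"gene {self.gene_id!r}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def tes(self) -> int:
        return self.end if self.strand == "+" else self.start


CONTEXTS = ("CG", "CHG", "CHH")


@dataclass
class CountTable:
    """Replicate read counts for homoeolog pairs.

    One row per pair; each of the four count columns holds an equal-length
    integer replicate vector: progenitor-mix A and C counts, and allopolyploid
    An and Cn subgenome counts.
    """

    counts: pd.DataFrame  # index pair_id; columns pm_a, pm_c, allo_an, allo_cn

    def __post_init__(self) -> None:
        for pid, row in self.counts.iterrows():
            lens = {len(row[c]) for c in ("pm_a", "pm_c", "allo_an", "allo_cn")}
            if len(lens) != 1:
                raise LoadError(f"pair {pid!r}: unequal replicate counts {lens}")

    @property
    def pair_ids(self) -> pd.Index:
        return self.counts.index

    def __len__(self) -> int:
        return len(self.counts)


# ---------------------------------------------------------------------------
# expression matrices


def read_expression_matrix(path, tissue_labels=DEFAULT_TISSUES) -> ExpressionMatrix:
    """Read a TSV with a gene-id first column and one column per tissue.

    The header must contain every requested tissue label; columns are
    reordered to ``tissue_labels``. Values are validated as non-negative
    and complete; duplicated gene ids are rejected.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    missing = set(tissue_labels) - set(df.columns)
    if missing:
        raise LoadError(f"{path}: missing tissue column(s) {sorted(missing)}")
    df = df.loc[:, list(tissue_labels)]
    try:
        df = df.astype(float)
    except ValueError as exc:  # non-numeric cell
        raise LoadError(f"{path}: non-numeric expression value ({exc})") from exc
    return ExpressionMatrix(values=df, scale=RAW)


def write_expression_matrix(matrix: ExpressionMatrix, path) -> None:
    out = matrix.values.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", float_format="%.17g")


# ---------------------------------------------------------------------------
# pair tables


def read_pair_tables(ortholog_path, triple_path, kaks_path) -> PairTables:
    """Load ortholog pairs, duplicate triples and the per-gene Ka/Ks table.

    Ka/Ks values are consumed, never computed: the table is expected to come
    from an external codon-model fit (one row per duplicate gene).
    """
    orth = pd.read_csv(ortholog_path, sep="\t", dtype=str)
    if list(orth.columns[:2]) != ["gene_s1", "gene_s2"]:
        raise LoadError(f"{ortholog_path}: expected columns gene_s1, gene_s2")
    trip = pd.read_csv(triple_path, sep="\t", dtype=str)
    need = ["ancestral", "parent", "child", "dup_type"]
    if list(trip.columns[: len(need)]) != need:
        raise LoadError(f"{triple_path}: expected columns {need}")
    kaks = pd.read_csv(kaks_path, sep="\t", index_col=0)
    for col in ("ka", "ks", "kaks"):
        if col not in kaks.columns:
            raise LoadError(f"{kaks_path}: missing column {col!r}")
    return PairTables(ortholog_pairs=orth, duplicate_triples=trip, kaks=kaks)


# ---------------------------------------------------------------------------
# gene models (GFF3)


def read_gff3_genes(path) -> list[GeneModel]:
    """Extract ``gene`` records from a GFF3 file as :class:`GeneModel`.

    Only feature type ``gene`` is retained (mRNA/exon/CDS lines are skipped).
    Coordinates stay 1-based inclusive as in GFF3. The gene id is taken from
    the ``ID=`` attribute, falling back to ``Name=``.
    """
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise LoadError(f"{path}:{lineno}: expected 9 columns")
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = fields
            if ftype != "gene":
                continue
            gene_id = _gff3_attr(attrs, "ID") or _gff3_attr(attrs, "Name")
            if gene_id is None:
                raise LoadError(f"{path}:{lineno}: gene record without ID attribute")
            try:
                genes.append(
                    GeneModel(chrom, int(start), int(end), strand, gene_id)
                )
            except (ValueError, LoadError) as exc:
                raise LoadError(f"{path}:{lineno}: {exc}") from exc
    return genes


def _gff3_attr(attrs: str, key: str) -> str | None:
    for part in attrs.split(";"):
        part = part.strip()
        if part.startswith(key + "="):
            return part[len(key) + 1 :]
    return None


def write_gff3_genes(genes, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\t.\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# methylation calls


def read_methylation_calls(path) -> pd.DataFrame:
    """Read a 5-column CGmap-like TSV of per-cytosine methylation calls.

    Columns (with header): chrom, position (1-based), context (CG/CHG/CHH),
    n_methylated, n_total. Rows with ``n_total == 0`` are uncovered cytosines
    and are dropped with a logged count; ``n_methylated > n_total`` is an
    error. Returns a DataFrame with those five columns.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"chrom": str, "context": str},
    )
    need = ["chrom", "position", "context", "n_methylated", "n_total"]
    if list(df.columns[: len(need)]) != need:
        raise LoadError(f"{path}: expected columns {need}")
    bad_ctx = set(df["context"]) - set(CONTEXTS)
    if bad_ctx:
        raise LoadError(f"{path}: unknown context(s) {sorted(bad_ctx)}")
    if (df["n_methylated"] < 0).any() or (df["n_total"] < 0).any():
        raise LoadError(f"{path}: negative read count")
    over = df["n_methylated"] > df["n_total"]
    if over.any():
        row = df.loc[over].iloc[0]
        raise LoadError(
            f"{path}: n_methylated > n_total at {row['chrom']}:{row['position']}"
        )
    uncovered = int((df["n_total"] == 0).sum())
    if uncovered:
        log.info("%s: dropped %d uncovered cytosines (n_total == 0)", path, uncovered)
        df = df[df["n_total"] > 0]
    return df.reset_index(drop=True)


def methylation_from_bedgraph_fraction(df: pd.DataFrame) -> pd.DataFrame:
    """Convert bedGraph-style (chrom, start0, end, level, coverage) calls.

    Converts 0-based half-open single-base intervals to the canonical 1-based
    5-column call table, reconstructing ``n_methylated`` by rounding
    ``level * coverage``.
    """
    need = ["chrom", "start", "end", "level", "coverage"]
    if list(df.columns[: len(need)]) != need:
        raise LoadError(f"bedGraph table: expected columns {need}")
    if ((df["level"] < 0) | (df["level"] > 1)).any():
        raise LoadError("bedGraph table: level outside [0, 1]")
    out = pd.DataFrame(
        {
            "chrom": df["chrom"].astype(str),
            "position": df["start"].astype(int) + 1,  # 0-based -> 1-based
            "context": df.get("context", pd.Series(["CG"] * len(df))),
            "n_methylated": np.rint(df["level"] * df["coverage"]).astype(int),
            "n_total": df["coverage"].astype(int),
        }
    )
    return out[out["n_total"] > 0].reset_index(drop=True)


def write_methylation_calls(calls: pd.DataFrame, path) -> None:
    calls.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# homoeolog count tables


_COUNT_COLS = ("pm_a", "pm_c", "allo_an", "allo_cn")


def read_count_table(path, n_replicates: int = 3) -> CountTable:
    """Read replicate homoeolog counts from a wide TSV.

    Expected header: ``pair_id`` then ``pm_a_1..pm_a_R, pm_c_1.., allo_an_1..,
    allo_cn_1..`` for R replicates (progenitor-mix A/C and allopolyploid
    An/Cn subgenome counts).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    data = {}
    for col in _COUNT_COLS:
        names = [f"{col}_{i + 1}" for i in range(n_replicates)]
        missing = [n for n in names if n not in df.columns]
        if missing:
            raise LoadError(f"{path}: missing count column(s) {missing}")
        arr = df[names].to_numpy()
        if (arr < 0).any() or not np.issubdtype(arr.dtype, np.number):
            raise LoadError(f"{path}: negative or non-numeric count in {col}")
        data[col] = list(arr.astype(int))
    return CountTable(counts=pd.DataFrame(data, index=df.index))


def write_count_table(table: CountTable, path) -> None:
    wide = {}
    for col in _COUNT_COLS:
        arr = np.vstack(table.counts[col].to_numpy())
        for i in range(arr.shape[1]):
            wide[f"{col}_{i + 1}"] = arr[:, i]
    out = pd.DataFrame(wide, index=table.counts.index)
    out.index.name = "pair_id"
    out.to_csv(path, sep="\t")
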