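"""Readers and writers for the external formats the pipeline touches.

Every reader validates its input and raises :class:`FormatError` with the
file, the offending record, and the field, so that malformed inputs fail
loudly at the boundary rather than deep inside a stage.

Coordinate convention: GTF-style, 1-based inclusive, everywhere. Conversions
happen nowhere else in the package.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd

__all__ = [
    "FormatError",
    "ExpressionMatrix",
    "TranscriptModel",
    "InteractionTable",
    "PPITable",
    "GeneSetCollection",
    "read_counts",
    "read_fpkm",
    "read_design",
    "read_gtf",
    "write_gtf",
    "read_fasta",
    "write_fasta",
    "read_interactions",
    "read_ppi",
    "read_gmt",
    "write_gmt",
    "write_network",
    "read_network",
    "write_expression",
]

INTERACTION_SOURCES = frozenset({"mirtarbase", "mirdb", "targetscan"})
BIOTYPES = frozenset(
    {"protein_coding", "lncRNA_candidate", "known_lncRNA", "miRNA"}
)
RNA_CLASSES = ("mRNA", "lncRNA", "miRNA")


class FormatError(ValueError):
    """Malformed external input; message names file, record and field."""


# ---------------------------------------------------------------------------
# domain containers


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with condition and class labels.

    ``values`` is a DataFrame indexed by gene id with sample columns;
    ``sample_condition`` maps each sample to one of exactly two condition
    labels; ``gene_class`` maps each gene to mRNA/lncRNA/miRNA; ``unit`` is
    ``"counts"`` or ``"FPKM"``.
    """

    values: pd.DataFrame
    sample_condition: pd.Series
    gene_class: pd.Series
    unit: str

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.unit not in ("counts", "FPKM"):
            raise FormatError(f"unknown expression unit {self.unit!r}")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise FormatError(f"duplicate gene ids: {list(dups)[:5]}")
        if (self.values.to_numpy() < 0).any():
            col = (self.values < 0).any(axis=0)
            bad_col = col[col].index[0]
            bad_row = self.values.index[(self.values[bad_col] < 0)][0]
            raise FormatError(
                f"negative value at gene {bad_row!r}, sample {bad_col!r}"
            )
        missing = set(self.values.columns) - set(self.sample_condition.index)
        if missing:
            raise FormatError(f"samples without condition label: {sorted(missing)}")
        conditions = set(self.sample_condition[self.values.columns])
        if len(conditions) != 2:
            raise FormatError(
                f"exactly two condition labels required, got {sorted(conditions)}"
            )
        unclassed = set(self.values.index) - set(self.gene_class.index)
        if unclassed:
            raise FormatError(
                f"genes without RNA class: {sorted(unclassed)[:5]}"
            )
        bad = set(self.gene_class.unique()) - set(RNA_CLASSES)
        if bad:
            raise FormatError(f"unknown RNA classes: {sorted(bad)}")

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def conditions(self) -> list[str]:
        return sorted(set(self.sample_condition[self.values.columns]))

    def samples_of(self, condition: str) -> list[str]:
        return [s for s in self.values.columns if self.sample_condition[s] == condition]


@dataclass
class TranscriptModel:
    """One transcript: location, strand, exons, biotype, optional sequence."""

    transcript_id: str
    gene_id: str
    chromosome: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]]
    biotype: str
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise FormatError(
                f"transcript {self.transcript_id}: unknown strand {self.strand!r}"
            )
        if self.start > self.end:
            raise FormatError(
                f"transcript {self.transcript_id}: start {self.start} > end {self.end}"
            )
        if not self.exons:
            raise FormatError(f"transcript {self.transcript_id}: no exons")
        self.exons = sorted(self.exons)
        prev_end = None
        for (s, e) in self.exons:
            if s > e:
                raise FormatError(
                    f"transcript {self.transcript_id}: exon {s}-{e} inverted"
                )
            if s < self.start or e > self.end:
                raise FormatError(
                    f"transcript {self.transcript_id}: exon {s}-{e} outside "
                    f"transcript span {self.start}-{self.end}"
                )
            if prev_end is not None and s <= prev_end:
                raise FormatError(
                    f"transcript {self.transcript_id}: overlapping exons at {s}"
                )
            prev_end = e
        if self.biotype not in BIOTYPES:
            raise FormatError(
                f"transcript {self.transcript_id}: unknown biotype {self.biotype!r}"
            )

    @property
    def spliced_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    @property
    def exon_count(self) -> int:
        return len(self.exons)


@dataclass
class InteractionTable:
    """miRNA -> target edge list with a source tag per edge."""

    edges: pd.DataFrame  # columns: miRNA, target, source

    def __post_init__(self) -> None:
        required = {"miRNA", "target", "source"}
        if not required.issubset(self.edges.columns):
            raise FormatError(
                f"interaction table needs columns {sorted(required)}"
            )
        bad = set(self.edges["source"].unique()) - INTERACTION_SOURCES
        if bad:
            raise FormatError(f"unknown interaction sources: {sorted(bad)}")
        if self.edges.duplicated(["miRNA", "target", "source"]).any():
            row = self.edges[self.edges.duplicated(["miRNA", "target", "source"])]
            raise FormatError(
                f"duplicate interaction rows, e.g. {row.iloc[0].tolist()}"
            )

    def pairs(self) -> set[tuple[str, str]]:
        return set(zip(self.edges["miRNA"], self.edges["target"]))

    def sources_of(self, mirna: str, target: str) -> frozenset[str]:
        m = (self.edges["miRNA"] == mirna) & (self.edges["target"] == target)
        return frozenset(self.edges.loc[m, "source"])


@dataclass
class PPITable:
    """Undirected protein-protein edges with a combined score in [0, 1].

    STRING exports scores on a 0-1000 scale; any score above 1 triggers
    auto-detection and division by 1000.
    """

    edges: pd.DataFrame  # columns: protein_a, protein_b, combined_score

    def __post_init__(self) -> None:
        required = {"protein_a", "protein_b", "combined_score"}
        if not required.issubset(self.edges.columns):
            raise FormatError(f"PPI table needs columns {sorted(required)}")
        edges = self.edges.copy()
        if (edges["combined_score"] > 1).any():
            edges["combined_score"] = edges["combined_score"] / 1000.0
        if ((edges["combined_score"] < 0) | (edges["combined_score"] > 1)).any():
            raise FormatError("PPI combined_score outside [0, 1] after scaling")
        edges = edges[edges["protein_a"] != edges["protein_b"]]
        # canonical undirected order, drop duplicates keeping max score
        a = edges[["protein_a", "protein_b"]].min(axis=1)
        b = edges[["protein_a", "protein_b"]].max(axis=1)
        edges = pd.DataFrame(
            {"protein_a": a, "protein_b": b, "combined_score": edges["combined_score"]}
        )
        edges = (
            edges.groupby(["protein_a", "protein_b"], as_index=False)["combined_score"]
            .max()
        )
        self.edges = edges.reset_index(drop=True)


@dataclass
class GeneSetCollection:
    """Named gene sets plus an optional background universe."""

    sets: dict[str, list[str]]
    universe: list[str] | None = None

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if len(members) != len(set(members)):
                raise FormatError(f"gene set {name!r} has duplicate members")


# ---------------------------------------------------------------------------
# expression matrices


def read_design(path: str | Path) -> pd.Series:
    """Read a two-column sample/condition TSV into a Series."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: design needs sample and condition columns")
    df = df.iloc[:, :2]
    df.columns = ["sample", "condition"]
    return df.set_index("sample")["condition"]


def _read_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate gene id {dup!r}")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise FormatError(f"{path}: non-numeric values in column {col!r}")
    neg = df.lt(0)
    if neg.any().any():
        col = neg.any(axis=0)
        bad_col = col[col].index[0]
        bad_row = df.index[neg[bad_col]][0]
        raise FormatError(
            f"{path}: negative value at row {bad_row!r}, column {bad_col!r}"
        )
    return df


def read_counts(
    path: str | Path,
    design: Mapping[str, str] | pd.Series,
    gene_class: Mapping[str, str] | pd.Series,
) -> ExpressionMatrix:
    """Read a genes x samples count TSV; counts coerced to integers."""
    df = _read_matrix(path)
    design = pd.Series(dict(design)) if not isinstance(design, pd.Series) else design
    missing = set(df.columns) - set(design.index)
    if missing:
        raise FormatError(f"{path}: samples missing from design: {sorted(missing)}")
    df = df.round().astype("int64")
    gene_class = (
        pd.Series(dict(gene_class)) if not isinstance(gene_class, pd.Series) else gene_class
    )
    return ExpressionMatrix(df, design, gene_class, unit="counts")


def read_fpkm(
    path: str | Path,
    design: Mapping[str, str] | pd.Series,
    gene_class: Mapping[str, str] | pd.Series,
) -> ExpressionMatrix:
    df = _read_matrix(path).astype(float)
    design = pd.Series(dict(design)) if not isinstance(design, pd.Series) else design
    missing = set(df.columns) - set(design.index)
    if missing:
        raise FormatError(f"{path}: samples missing from design: {sorted(missing)}")
    gene_class = (
        pd.Series(dict(gene_class)) if not isinstance(gene_class, pd.Series) else gene_class
    )
    return ExpressionMatrix(df, design, gene_class, unit="FPKM")


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    out = matrix.values.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# GTF


def read_gtf(path: str | Path) -> list[TranscriptModel]:
    """Parse a GTF into TranscriptModels (transcript + exon features).

    Attributes must carry ``transcript_id`` and ``gene_id``; ``gene_biotype``
    on the transcript record sets the biotype (default protein_coding).
    """
    db = gffutils.create_db(
        str(path),
        ":memory:",
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        merge_strategy="create_unique",
    )
    models: list[TranscriptModel] = []
    exons: dict[str, list[tuple[int, int]]] = {}
    for ex in db.features_of_type("exon"):
        tid = ex.attributes.get("transcript_id", [None])[0]
        if tid is None:
            raise FormatError(f"{path}: exon at {ex.seqid}:{ex.start} lacks transcript_id")
        exons.setdefault(tid, []).append((ex.start, ex.end))
    for tr in db.features_of_type("transcript"):
        tid = tr.attributes.get("transcript_id", [None])[0]
        gid = tr.attributes.get("gene_id", [None])[0]
        if tid is None or gid is None:
            raise FormatError(
                f"{path}: transcript at {tr.seqid}:{tr.start} lacks "
                "transcript_id/gene_id"
            )
        biotype = tr.attributes.get("gene_biotype", ["protein_coding"])[0]
        try:
            models.append(
                TranscriptModel(
                    transcript_id=tid,
                    gene_id=gid,
                    chromosome=tr.seqid,
                    strand=tr.strand,
                    start=tr.start,
                    end=tr.end,
                    exons=exons.get(tid, [(tr.start, tr.end)]),
                    biotype=biotype,
                )
            )
        except FormatError as err:
            raise FormatError(f"{path}: {err}") from err
    return models


def write_gtf(models: Sequence[TranscriptModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in models:
            attrs = (
                f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}"; '
                f'gene_biotype "{m.biotype}";'
            )
            fh.write(
                f"{m.chromosome}\tcerna_switch\ttranscript\t{m.start}\t{m.end}"
                f"\t.\t{m.strand}\t.\t{attrs}\n"
            )
            for (s, e) in m.exons:
                fh.write(
                    f"{m.chromosome}\tcerna_switch\texon\t{s}\t{e}"
                    f"\t.\t{m.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# edge tables, gene sets


def read_interactions(path: str | Path) -> InteractionTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return InteractionTable(df)


def read_ppi(path: str | Path) -> PPITable:
    df = pd.read_csv(path, sep="\t")
    df["combined_score"] = pd.to_numeric(df["combined_score"], errors="raise")
    return PPITable(df)


def read_gmt(path: str | Path) -> GeneSetCollection:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: GMT rows need name, description "
                    "and at least one gene"
                )
            name, _desc, *genes = fields
            genes = [g for g in genes if g]
            if name in sets:
                raise FormatError(f"{path}: line {lineno}: duplicate set {name!r}")
            sets[name] = genes
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.sets.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")


# ---------------------------------------------------------------------------
# network export


def write_network(network, path: str | Path, dialect: str = "tsv") -> None:
    """Export a ceRNA network as a Cytoscape-importable edge list.

    ``dialect="sif"`` writes a SIF file; ``"tsv"`` writes an edge table with
    an interaction-type column. A node attribute table (``<path>.nodes.tsv``)
    with RNA class and direction is written alongside.
    """
    if dialect not in ("sif", "tsv"):
        raise FormatError(f"unknown network dialect {dialect!r}")
    node_class = network.node_class
    node_direction = network.node_direction
    untyped = [n for n in network.nodes() if n not in node_class]
    if untyped:
        raise FormatError(f"untyped network nodes: {sorted(untyped)[:5]}")
    edges = network.edge_list()
    path = Path(path)
    with open(path, "w") as fh:
        if dialect == "tsv":
            fh.write("source\tinteraction\ttarget\n")
            for a, kind, b in edges:
                fh.write(f"{a}\t{kind}\t{b}\n")
        else:
            for a, kind, b in edges:
                fh.write(f"{a}\t{kind}\t{b}\n")
    attr_path = path.with_suffix(path.suffix + ".nodes.tsv")
    with open(attr_path, "w") as fh:
        fh.write("node\trna_class\tdirection\n")
        for n in sorted(network.nodes()):
            fh.write(f"{n}\t{node_class[n]}\t{node_direction[n]}\n")


def read_network(path: str | Path) -> list[tuple[str, str, str]]:
    """Read back an exported edge list as (source, interaction, target)."""
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["source", "interaction", "target"]:
            # SIF dialect: the first line is already an edge
            if len(header) == 3:
                out.append(tuple(header))
            elif header != [""]:
                raise FormatError(f"{path}: unrecognized network header {header}")
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 3:
                raise FormatError(f"{path}: line {lineno}: expected 3 fields")
            out.append(tuple(fields))
    return out
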