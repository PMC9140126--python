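"""Core data model and readers/writers for the standard text formats.

The central in-memory containers are thin, validated wrappers around
pandas objects: an :class:`ExpressionMatrix` (genes x samples, log2
scale), a :class:`SampleTable` (per-sample stage/batch/survival
annotation) and a :class:`GeneSetCollection` (named gene sets, with an
optional per-gene sign for regulons).  File formats are plain TSV, the
standard GMT dialect (plus a documented ``GENE|+1`` sign suffix for
regulons), and GraphML for networks.

All coordinates in inputs and outputs are label-based; nothing is ever
addressed positionally.  The loaders never impute silently: every
dropped or collapsed record is reported through the module logger.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Ordered disease-stage labels: non-malignant adjacent urothelium first,
#: then pathologic tumor stages by increasing spread.
STAGES: tuple[str, ...] = ("NAU", "Ta", "T1", "T2", "T3", "T4")

#: The five tumor stages compared against the NAU baseline.
TUMOR_STAGES: tuple[str, ...] = STAGES[1:]

STAGE_DTYPE = pd.CategoricalDtype(categories=list(STAGES), ordered=True)


class DataError(ValueError):
    """Raised when an input file or container violates the data model."""


@dataclass
class ExpressionMatrix:
    """Dense genes x samples expression matrix on the log2 scale.

    Parameters
    ----------
    data
        DataFrame indexed by gene symbol with sample IDs as columns.
        Values are unitless log2 intensities unless a caller explicitly
        works on the linear scale (deconvolution does).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        idx, cols = self.data.index, self.data.columns
        if idx.duplicated().any():
            dupes = idx[idx.duplicated()].unique().tolist()
            raise DataError(f"duplicate gene IDs: {dupes[:5]}")
        if cols.duplicated().any():
            dupes = cols[cols.duplicated()].unique().tolist()
            raise DataError(f"duplicate sample IDs: {dupes[:5]}")
        if self.data.isna().any().any():
            raise DataError("expression matrix contains missing values")
        self.data = self.data.astype(float)

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_genes(self, genes: list[str]) -> "ExpressionMatrix":
        missing = set(genes) - set(self.data.index)
        if missing:
            raise DataError(f"genes not in matrix: {sorted(missing)[:5]}")
        return ExpressionMatrix(self.data.loc[list(genes)].copy())

    def subset_samples(self, samples: list[str]) -> "ExpressionMatrix":
        missing = set(samples) - set(self.data.columns)
        if missing:
            raise DataError(f"samples not in matrix: {sorted(missing)[:5]}")
        return ExpressionMatrix(self.data[list(samples)].copy())

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index_label="gene")


@dataclass
class SampleTable:
    """Per-sample annotation: ordered stage, batch, demographics, survival.

    ``data`` is indexed by sample ID.  ``stage`` is an ordered categorical
    over :data:`STAGES`; ``batch`` a plain categorical.  ``time`` (months)
    and ``event`` (0/1) are optional but must be present together.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.duplicated().any():
            raise DataError("duplicate sample IDs in sample table")
        if "stage" not in df.columns:
            raise DataError("sample table requires a 'stage' column")
        unknown = set(df["stage"].dropna().astype(str)) - set(STAGES)
        if unknown:
            raise DataError(f"unknown stage labels: {sorted(unknown)}")
        df = df.copy()
        df["stage"] = df["stage"].astype(STAGE_DTYPE)
        if "batch" in df.columns:
            df["batch"] = df["batch"].astype("category")
        has_time = "time" in df.columns
        has_event = "event" in df.columns
        if has_time != has_event:
            raise DataError("'time' and 'event' must be present together")
        if has_time:
            t = pd.to_numeric(df["time"])
            if (t.dropna() < 0).any():
                raise DataError("negative survival times")
            ev = set(pd.to_numeric(df["event"]).dropna().unique()) - {0, 1}
            if ev:
                raise DataError(f"event indicator outside {{0,1}}: {sorted(ev)}")
        self.data = df

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    @property
    def stage(self) -> pd.Series:
        return self.data["stage"]

    @property
    def batch(self) -> pd.Series:
        return self.data["batch"]

    def has_survival(self) -> bool:
        return "time" in self.data.columns

    def stage_samples(self, stage: str) -> list[str]:
        return list(self.data.index[self.data["stage"] == stage])

    def validate_against(self, matrix: ExpressionMatrix) -> None:
        missing = set(self.samples) - set(matrix.samples)
        if missing:
            raise DataError(
                f"samples missing from expression matrix: {sorted(missing)[:5]}"
            )

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index_label="sample_id")


@dataclass
class GeneSetCollection:
    """Named gene sets, optionally signed (regulons).

    ``sets`` maps a unique set name to a list of member gene symbols;
    ``signs``, when given for a set, maps every member to +1 or -1
    (mode of regulation for a transcription-factor regulon).
    """

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)
    signs: dict[str, dict[str, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise DataError(f"gene set {name!r} is empty")
            if len(set(members)) != len(members):
                raise DataError(f"gene set {name!r} has duplicate members")
        for name, sgn in self.signs.items():
            members = set(self.sets[name])
            if set(sgn) != members:
                raise DataError(f"signs for {name!r} do not cover every member")
            bad = set(sgn.values()) - {1, -1}
            if bad:
                raise DataError(f"signs for {name!r} outside {{+1,-1}}: {bad}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def restrict_to(self, genes, min_size: int = 1) -> "GeneSetCollection":
        """Intersect every set with ``genes``; drop sets below ``min_size``."""
        universe = set(genes)
        sets, desc, signs = {}, {}, {}
        for name, members in self.sets.items():
            kept = [g for g in members if g in universe]
            if len(kept) < min_size:
                logger.warning(
                    "gene set %s dropped (%d of %d members in matrix, min_size=%d)",
                    name, len(kept), len(members), min_size,
                )
                continue
            sets[name] = kept
            if name in self.descriptions:
                desc[name] = self.descriptions[name]
            if name in self.signs:
                signs[name] = {g: self.signs[name][g] for g in kept}
        return GeneSetCollection(sets, desc, signs)


# ---------------------------------------------------------------------------
# readers / writers


def percent_breakdown(counts: dict[str, int], decimals: int = 1) -> dict[str, float]:
    """Percentages of a categorical count breakdown, rounded for reporting."""
    total = sum(counts.values())
    if total <= 0:
        raise DataError("counts must sum to a positive total")
    return {k: round(100.0 * v / total, decimals) for k, v in counts.items()}


def read_expression_matrix(path, missing_policy: str = "fail") -> ExpressionMatrix:
    """Read a genes x samples TSV (header = sample IDs, first column = genes).

    ``missing_policy`` is ``"fail"`` (any NA aborts) or ``"drop_gene"``
    (rows with NAs are removed, each logged).  Duplicate gene rows are
    collapsed by their mean on the log scale and logged; a duplicated
    sample ID in the header is an error.
    """
    if missing_policy not in ("fail", "drop_gene"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    seen: set[str] = set()
    dupes: set[str] = set()
    for sid in header:
        if sid in seen:
            dupes.add(sid)
        seen.add(sid)
    if dupes:
        raise DataError(f"duplicate sample ID(s) in header: {sorted(dupes)}")
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", "NaN", ""])
    # locate non-numeric cells explicitly so the error names row and column
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.any().any():
        gene = bad.index[bad.any(axis=1)][0]
        col = bad.columns[bad.loc[gene]][0]
        raise DataError(
            f"non-numeric value {df.loc[gene, col]!r} at gene {gene!r}, "
            f"sample {col!r}"
        )
    df = numeric
    if df.isna().any().any():
        if missing_policy == "fail":
            gene = df.index[df.isna().any(axis=1)][0]
            raise DataError(f"missing value in gene row {gene!r}")
        dropped = df.index[df.isna().any(axis=1)].tolist()
        for g in dropped:
            logger.warning("dropping gene %s: missing values", g)
        df = df.dropna(axis=0)
    if df.index.duplicated().any():
        for g in df.index[df.index.duplicated()].unique():
            logger.warning("collapsing duplicate gene rows for %s by mean", g)
        df = df.groupby(level=0, sort=False).mean()
    return ExpressionMatrix(df)


def read_sample_table(path) -> SampleTable:
    """Read a per-sample annotation TSV (first column = sample IDs)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return SampleTable(df)


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: ``name<TAB>description<TAB>gene...`` per line.

    Supports the signed-regulon dialect where a member is written
    ``GENE|+1`` or ``GENE|-1``.  A line with fewer than three fields or
    a repeated set name is an error naming the offending line.
    """
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    signs: dict[str, dict[str, int]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataError(f"GMT line {lineno}: fewer than 3 fields")
            name, desc, *members = fields
            if name in sets:
                raise DataError(f"GMT line {lineno}: duplicate set name {name!r}")
            genes: list[str] = []
            set_signs: dict[str, int] = {}
            for m in members:
                if not m:
                    continue
                if "|" in m:
                    gene, _, s = m.partition("|")
                    if s not in ("+1", "-1", "1"):
                        raise DataError(
                            f"GMT line {lineno}: bad sign suffix {m!r}"
                        )
                    set_signs[gene] = 1 if s in ("+1", "1") else -1
                    genes.append(gene)
                else:
                    genes.append(m)
            if set_signs and len(set_signs) != len(genes):
                raise DataError(
                    f"GMT line {lineno}: signs must cover all members of {name!r}"
                )
            sets[name] = genes
            descriptions[name] = desc
            if set_signs:
                signs[name] = set_signs
    return GeneSetCollection(sets, descriptions, signs)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            sgn = collection.signs.get(name)
            if sgn is None:
                cells = members
            else:
                cells = [f"{g}|{sgn[g]:+d}" for g in members]
            fh.write("\t".join([name, desc, *cells]) + "\n")


def write_network(network, path_prefix) -> tuple[str, str]:
    """Write a stage network as an edge-list TSV plus a GraphML file.

    The edge list has columns ``gene_a, gene_b, weight, spearman_rho``
    and re-reading it with :func:`read_network_edges` reproduces the
    graph exactly.  The GraphML carries ``community`` and ``betweenness``
    node attributes when the network has them.  An empty graph yields a
    header-only edge list.
    """
    graph = network.graph if hasattr(network, "graph") else network
    edge_path = f"{path_prefix}.edges.tsv"
    graphml_path = f"{path_prefix}.graphml"
    rows = [
        {
            "gene_a": a,
            "gene_b": b,
            "weight": d["weight"],
            "spearman_rho": d["spearman_rho"],
        }
        for a, b, d in graph.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["gene_a", "gene_b", "weight", "spearman_rho"]).to_csv(
        edge_path, sep="\t", index=False
    )
    gml = nx.Graph()
    gml.add_nodes_from(graph.nodes(data=True))
    gml.add_edges_from(graph.edges(data=True))
    nx.write_graphml(gml, graphml_path)
    return edge_path, graphml_path


def read_network_edges(path) -> nx.Graph:
    """Re-read an edge-list TSV written by :func:`write_network`."""
    df = pd.read_csv(path, sep="\t")
    graph = nx.Graph()
    for row in df.itertuples(index=False):
        graph.add_edge(
            row.gene_a,
            row.gene_b,
            weight=float(row.weight),
            spearman_rho=float(row.spearman_rho),
        )
    return graph
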