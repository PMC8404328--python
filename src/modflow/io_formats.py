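"""Domain types and file formats.

All external formats the workflow touches are plain text:

* STRING-style edge list TSV: ``node1  node2  combined_score`` with an
  integer confidence score in [0, 1000] (header optional, auto-detected).
* GWAS summary statistics TSV: required header ``snp  chr  pos  p`` with
  1-based positions; positions are converted to the package-wide 0-based
  convention at read time.
* Omics matrices: TSV, first column the feature id, remaining columns
  samples; a companion labels TSV maps ``sample`` to ``group``
  (case/control).
* Gene coordinates: BED4 (``chrom  start  end  name``), 0-based half-open,
  kept verbatim.
* Gene sets: GMT (name, description, member genes, tab-separated).
* Modules: one gene per line, provenance carried in ``# key=value`` header
  comments.

Readers validate strictly and reject invariant-violating input with an
error naming the offending line or identifier; they never silently coerce.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "GeneNetwork",
    "GeneCoordinates",
    "GwasSummary",
    "OmicsMatrix",
    "Module",
    "GeneSetCollection",
    "read_network",
    "write_network",
    "read_gwas",
    "write_gwas",
    "read_omics_matrix",
    "write_omics_matrix",
    "read_gene_sets",
    "write_gene_sets",
    "read_gene_coords",
    "write_gene_coords",
    "read_module",
    "write_module",
]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneNetwork:
    """Undirected weighted gene–gene interaction graph.

    Backed by a :class:`networkx.Graph` whose edges carry an integer
    ``score`` attribute in [0, 1000].  Gene identity is the bare symbol
    string, case-sensitive.
    """

    graph: nx.Graph

    def __post_init__(self) -> None:
        for u, v, data in self.graph.edges(data=True):
            if u == v:
                raise ValueError(f"self-loop on node {u!r}")
            score = data.get("score")
            if score is None or not (0 <= int(score) <= 1000):
                raise ValueError(f"edge ({u!r}, {v!r}) score {score!r} outside [0, 1000]")

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def filtered(self, min_score: int) -> "GeneNetwork":
        """Return the sub-network keeping edges with score > ``min_score``."""
        g = nx.Graph()
        for u, v, data in self.graph.edges(data=True):
            if data["score"] > min_score:
                g.add_edge(u, v, score=data["score"])
        return GeneNetwork(g)


@dataclass(frozen=True)
class GeneCoordinates:
    """Gene body intervals, 0-based half-open, at most one record per gene."""

    table: pd.DataFrame  # columns: gene, chrom, start, end

    def __post_init__(self) -> None:
        t = self.table
        required = ["gene", "chrom", "start", "end"]
        if list(t.columns) != required:
            raise ValueError(f"expected columns {required}, got {list(t.columns)}")
        if t["gene"].duplicated().any():
            dup = t.loc[t["gene"].duplicated(), "gene"].iloc[0]
            raise ValueError(f"duplicate coordinate record for gene {dup!r}")
        bad = t[t["start"] >= t["end"]]
        if len(bad):
            raise ValueError(f"start >= end for gene {bad['gene'].iloc[0]!r}")

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self.table["gene"])

    def __len__(self) -> int:
        return len(self.table)


@dataclass(frozen=True)
class GwasSummary:
    """SNP-level association p-values.

    Positions are stored 0-based; the TSV dialect on disk is 1-based and the
    conversion happens in :func:`read_gwas` / :func:`write_gwas`.
    """

    table: pd.DataFrame  # columns: snp, chrom, pos0, p

    def __post_init__(self) -> None:
        t = self.table
        required = ["snp", "chrom", "pos0", "p"]
        if list(t.columns) != required:
            raise ValueError(f"expected columns {required}, got {list(t.columns)}")
        if t["snp"].duplicated().any():
            dup = t.loc[t["snp"].duplicated(), "snp"].iloc[0]
            raise ValueError(f"duplicate variant id {dup!r}")
        if ((t["p"] <= 0) | (t["p"] > 1)).any():
            bad = t.loc[(t["p"] <= 0) | (t["p"] > 1), "snp"].iloc[0]
            raise ValueError(f"p-value outside (0, 1] for variant {bad!r}")
        if (t["pos0"] < 0).any():
            bad = t.loc[t["pos0"] < 0, "snp"].iloc[0]
            raise ValueError(f"negative position for variant {bad!r}")

    def __len__(self) -> int:
        return len(self.table)


@dataclass(frozen=True)
class OmicsMatrix:
    """Feature × sample value grid with case/control labels.

    ``kind`` is ``"expression"`` (log-scale intensities, unbounded) or
    ``"methylation-beta"`` (beta values, constrained to [0, 1]).
    """

    values: pd.DataFrame  # features × samples
    labels: pd.Series  # sample -> "case" | "control"
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in ("expression", "methylation-beta"):
            raise ValueError(f"unknown omics kind {self.kind!r}")
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate feature id {dup!r}")
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id {dup!r}")
        missing = set(self.values.columns) - set(self.labels.index)
        if missing:
            raise ValueError(f"samples missing from labels: {sorted(missing)}")
        bad_labels = set(self.labels.loc[list(self.values.columns)]) - {"case", "control"}
        if bad_labels:
            raise ValueError(f"labels must be case/control, got {sorted(bad_labels)}")
        if self.kind == "methylation-beta":
            vals = self.values.to_numpy()
            if np.nanmin(vals) < 0 or np.nanmax(vals) > 1:
                raise ValueError("methylation beta values must lie in [0, 1]")

    @property
    def case_samples(self) -> list[str]:
        lab = self.labels.loc[list(self.values.columns)]
        return [s for s in self.values.columns if lab[s] == "case"]

    @property
    def control_samples(self) -> list[str]:
        lab = self.labels.loc[list(self.values.columns)]
        return [s for s in self.values.columns if lab[s] == "control"]

    @property
    def features(self) -> pd.Index:
        return self.values.index


@dataclass(frozen=True)
class Module:
    """A gene set with provenance.  Empty modules are legal objects.

    ``added_order`` optionally records the order in which an iterative
    detector admitted genes; it does not participate in equality and is not
    serialised.
    """

    genes: frozenset[str]
    method: str = ""
    dataset: str = ""
    omic: str = ""
    added_order: tuple[str, ...] = field(default=(), compare=False)

    def __len__(self) -> int:
        return len(self.genes)

    def with_provenance(self, **kwargs: str) -> "Module":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets with GMT semantics (name, description, members)."""

    sets: tuple[tuple[str, str, frozenset[str]], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        names = [name for name, _, _ in self.sets]
        if len(names) != len(set(names)):
            seen: set[str] = set()
            dup = next(n for n in names if n in seen or seen.add(n))
            raise ValueError(f"duplicate gene-set name {dup!r}")
        for name, _, members in self.sets:
            if not members:
                raise ValueError(f"gene set {name!r} is empty")

    @property
    def names(self) -> list[str]:
        return [name for name, _, _ in self.sets]

    def members(self, name: str) -> frozenset[str]:
        for set_name, _, genes in self.sets:
            if set_name == name:
                return genes
        raise KeyError(name)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------


def read_network(path: str | Path, min_score: int = 700) -> GeneNetwork:
    """Read a STRING-style edge list, keeping edges with score > ``min_score``.

    The score filter is strict; reversed duplicate edges collapse to the
    maximum score.  The node set is exactly the endpoints of retained edges.
    """
    path = Path(path)
    best: dict[tuple[str, str], int] = {}
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 columns, got {len(fields)}")
            try:
                score = int(fields[2])
            except ValueError:
                if lineno == 1:  # header row auto-detected
                    continue
                raise FormatError(
                    f"{path}:{lineno}: score {fields[2]!r} is not an integer"
                ) from None
            if not 0 <= score <= 1000:
                raise FormatError(f"{path}:{lineno}: score {score} outside [0, 1000]")
            u, v = fields[0], fields[1]
            if u == v:
                raise FormatError(f"{path}:{lineno}: self-loop on {u!r}")
            key = (u, v) if u < v else (v, u)
            best[key] = max(best.get(key, 0), score)
    g = nx.Graph()
    for (u, v), score in best.items():
        if score > min_score:
            g.add_edge(u, v, score=score)
    return GeneNetwork(g)


def write_network(network: GeneNetwork, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("node1\tnode2\tcombined_score\n")
        for u, v, data in sorted(network.graph.edges(data=True)):
            fh.write(f"{u}\t{v}\t{data['score']}\n")


# ---------------------------------------------------------------------------
# GWAS
# ---------------------------------------------------------------------------

_GWAS_COLUMNS = ["snp", "chr", "pos", "p"]


def read_gwas(path: str | Path) -> GwasSummary:
    """Read GWAS summary statistics (header ``snp chr pos p``, 1-based positions).

    Zero p-values are rejected: they break the chi-square transforms used
    downstream.  Pre-floor them at the smallest positive representable value
    if your source contains exact zeros.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"snp": str, "chr": str})
    missing = [c for c in _GWAS_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    if df["snp"].duplicated().any():
        dup = df.loc[df["snp"].duplicated(), "snp"].iloc[0]
        raise FormatError(f"{path}: duplicate variant id {dup!r}")
    if ((df["p"] <= 0) | (df["p"] > 1)).any():
        bad = df.loc[(df["p"] <= 0) | (df["p"] > 1), "snp"].iloc[0]
        raise FormatError(f"{path}: p-value outside (0, 1] for variant {bad!r}")
    if (df["pos"] < 1).any():
        bad = df.loc[df["pos"] < 1, "snp"].iloc[0]
        raise FormatError(f"{path}: position < 1 for variant {bad!r}")
    out = pd.DataFrame(
        {
            "snp": df["snp"],
            "chrom": df["chr"],
            "pos0": df["pos"].astype(int) - 1,
            "p": df["p"].astype(float),
        }
    )
    return GwasSummary(out.reset_index(drop=True))


def write_gwas(gwas: GwasSummary, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "snp": gwas.table["snp"],
            "chr": gwas.table["chrom"],
            "pos": gwas.table["pos0"] + 1,
            "p": gwas.table["p"],
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# omics matrices
# ---------------------------------------------------------------------------


def read_omics_matrix(
    path: str | Path, labels_path: str | Path, kind: str = "expression"
) -> OmicsMatrix:
    """Read a feature × sample TSV and its sample/group labels file."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate feature id {dup!r}")
    labels_df = pd.read_csv(labels_path, sep="\t", dtype=str)
    if not {"sample", "group"} <= set(labels_df.columns):
        raise FormatError(f"{labels_path}: expected columns 'sample' and 'group'")
    labels = labels_df.set_index("sample")["group"]
    missing = [s for s in df.columns if s not in labels.index]
    if missing:
        raise FormatError(f"{path}: samples missing from labels file: {missing}")
    try:
        return OmicsMatrix(values=df, labels=labels, kind=kind)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_omics_matrix(matrix: OmicsMatrix, path: str | Path, labels_path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="feature")
    pd.DataFrame(
        {"sample": list(matrix.values.columns),
         "group": [matrix.labels[s] for s in matrix.values.columns]}
    ).to_csv(labels_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    path = Path(path)
    sets: list[tuple[str, str, frozenset[str]]] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs name, description and >= 1 gene"
                )
            name, description = fields[0], fields[1]
            genes = frozenset(g for g in fields[2:] if g)
            if not genes:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} has no members")
            sets.append((name, description, genes))
    try:
        return GeneSetCollection(tuple(sets))
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_gene_sets(collection: GeneSetCollection, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for name, description, genes in collection:
            fh.write("\t".join([name, description, *sorted(genes)]) + "\n")


# ---------------------------------------------------------------------------
# gene coordinates (BED4)
# ---------------------------------------------------------------------------


def read_gene_coords(path: str | Path) -> GeneCoordinates:
    path = Path(path)
    records = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 4:
                raise FormatError(f"{path}:{lineno}: BED4 needs chrom, start, end, name")
            chrom, start_s, end_s, gene = fields[:4]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer interval bounds") from None
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start >= end for gene {gene!r}")
            records.append({"gene": gene, "chrom": chrom, "start": start, "end": end})
    df = pd.DataFrame(records, columns=["gene", "chrom", "start", "end"])
    try:
        return GeneCoordinates(df)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_gene_coords(coords: GeneCoordinates, path: str | Path) -> None:
    coords.table[["chrom", "start", "end", "gene"]].to_csv(
        path, sep="\t", header=False, index=False
    )


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------


def read_module(path: str | Path) -> Module:
    """Read a module file (one gene per line, ``# key=value`` provenance header).

    Duplicate gene lines are de-duplicated with a logged warning.
    """
    path = Path(path)
    provenance = {"method": "", "dataset": "", "omic": ""}
    genes: list[str] = []
    with path.open() as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, value = body.partition("=")
                    if key.strip() in provenance:
                        provenance[key.strip()] = value.strip()
                continue
            genes.append(line)
    unique = frozenset(genes)
    if len(unique) != len(genes):
        logger.warning("%s: %d duplicate gene lines de-duplicated", path, len(genes) - len(unique))
    return Module(genes=unique, **provenance)


def write_module(module: Module, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write(f"# method={module.method}\n")
        fh.write(f"# dataset={module.dataset}\n")
        fh.write(f"# omic={module.omic}\n")
        for gene in sorted(module.genes):
            fh.write(gene + "\n")
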