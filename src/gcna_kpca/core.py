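"""Domain types and file I/O for the gene-module identification pipeline.

The pipeline operates on a handful of shared containers: a dense gene x
sample expression matrix, a tumor/normal sample grouping, a thresholded
co-expression network, a module partition with per-module eigengenes,
flat annotation gene sets (GMT), a survival table, and a protein-protein
interaction graph.  All on-disk formats are plain text (TSV/CSV, GMT,
JSON) so that runs are fully reproducible and diffable.

Gene and sample identifiers are opaque, case-sensitive strings; no
symbol/accession mapping is attempted here.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger("gcna_kpca")

#: Default seed used by every randomized operation in the package.
DEFAULT_SEED = 17

#: Version tag written into (and required from) partition JSON files.
PARTITION_FORMAT_VERSION = 1

TUMOR = "tumor"
NORMAL = "normal"


class DataFormatError(ValueError):
    """Raised when an input file violates a documented format contract."""


# ---------------------------------------------------------------------------
# Expression matrix
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Dense genes x samples expression table (FPKM/RPKM-like values).

    Parameters
    ----------
    gene_ids : sequence of str
        Unique row identifiers.
    sample_ids : sequence of str
        Unique column identifiers.
    values : ndarray of shape (n_genes, n_samples)
        Finite numeric expression values.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DataFormatError("expression values must be a 2-D matrix")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise DataFormatError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        for kind, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            dup = _first_duplicate(ids)
            if dup is not None:
                raise DataFormatError(f"duplicate {kind} id {dup!r}")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise DataFormatError(
                f"non-finite value at gene {self.gene_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_index(self, gene_id: str) -> int:
        return self.gene_ids.index(gene_id)

    def gene_vector(self, gene_id: str) -> np.ndarray:
        return self.values[self.gene_index(gene_id)]

    def subset_genes(self, genes: Sequence[str] | np.ndarray) -> "ExpressionMatrix":
        if isinstance(genes, np.ndarray) and genes.dtype == bool:
            idx = np.flatnonzero(genes)
        else:
            pos = {g: i for i, g in enumerate(self.gene_ids)}
            idx = np.array([pos[g] for g in genes], dtype=int)
        return ExpressionMatrix(
            [self.gene_ids[i] for i in idx], list(self.sample_ids), self.values[idx]
        )

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = np.array([pos[s] for s in samples], dtype=int)
        return ExpressionMatrix(
            list(self.gene_ids), [self.sample_ids[i] for i in idx],
            self.values[:, idx],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


def _first_duplicate(ids: Iterable[str]) -> str | None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            return x
        seen.add(x)
    return None


def read_expression(path: str | Path, orientation: str = "genes-rows") -> ExpressionMatrix:
    """Read a TSV/CSV expression table.

    The file has a header row of sample ids and a first column of gene ids
    (``orientation="genes-rows"``, the default) or the transpose
    (``orientation="samples-rows"``).  The delimiter is sniffed from the
    extension: ``.csv`` means comma, anything else tab.
    """
    if orientation not in ("genes-rows", "samples-rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    if orientation == "samples-rows":
        df = df.T
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise DataFormatError(
            f"non-numeric cell {df.iat[i, j]!r} at row {df.index[i]!r}, "
            f"column {df.columns[j]!r} in {path}"
        )
    if numeric.isna().to_numpy().any():
        i, j = np.argwhere(numeric.isna().to_numpy())[0]
        raise DataFormatError(
            f"missing value at row {df.index[i]!r}, column {df.columns[j]!r} in {path}"
        )
    return ExpressionMatrix(
        list(numeric.index.astype(str)),
        list(numeric.columns.astype(str)),
        numeric.to_numpy(dtype=float),
    )


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    expr.to_frame().to_csv(path, sep=sep, index_label="gene_id")


# ---------------------------------------------------------------------------
# Sample groups
# ---------------------------------------------------------------------------

@dataclass
class SampleGroups:
    """Mapping from sample id to group label (``tumor`` or ``normal``)."""

    labels: dict[str, str]

    def __post_init__(self) -> None:
        bad = {v for v in self.labels.values() if v not in (TUMOR, NORMAL)}
        if bad:
            raise DataFormatError(
                f"group labels must be '{TUMOR}' or '{NORMAL}', got {sorted(bad)}"
            )

    def group_ids(self, group: str) -> list[str]:
        return [s for s, g in self.labels.items() if g == group]

    def mask(self, sample_ids: Sequence[str], group: str) -> np.ndarray:
        missing = [s for s in sample_ids if s not in self.labels]
        if missing:
            raise DataFormatError(f"sample {missing[0]!r} has no group assignment")
        return np.array([self.labels[s] == group for s in sample_ids], dtype=bool)

    def require_both_groups(self, sample_ids: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
        """Boolean tumor/normal masks over ``sample_ids``; both non-empty."""
        t = self.mask(sample_ids, TUMOR)
        n = self.mask(sample_ids, NORMAL)
        if not t.any() or not n.any():
            raise DataFormatError("need at least one sample in each of tumor and normal")
        return t, n


def read_groups(path: str | Path) -> SampleGroups:
    """Read a two-column TSV ``sample_id<TAB>group`` (header optional)."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise DataFormatError(f"{path}: expected two columns (sample_id, group)")
    rows = df.iloc[:, :2].itertuples(index=False)
    labels: dict[str, str] = {}
    for sample, group in rows:
        g = str(group).strip().lower()
        if g in ("sample_id", "group"):  # header line
            continue
        if sample in labels:
            raise DataFormatError(f"duplicate sample id {sample!r} in {path}")
        labels[str(sample)] = g
    return SampleGroups(labels)


def write_groups(groups: SampleGroups, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s, g in groups.labels.items():
            fh.write(f"{s}\t{g}\n")


# ---------------------------------------------------------------------------
# Co-expression network
# ---------------------------------------------------------------------------

@dataclass
class CoexpressionNetwork:
    """Undirected gene graph; edge weight is |Pearson r|, sign retained.

    Every input gene is a node, so genes isolated by thresholding remain
    visible to downstream stages.
    """

    graph: nx.Graph
    threshold: float

    def __post_init__(self) -> None:
        loops = list(nx.selfloop_edges(self.graph))
        if loops:
            raise DataFormatError(f"self-loop on {loops[0][0]!r} in co-expression network")
        for u, v, d in self.graph.edges(data=True):
            w = d.get("weight", None)
            if w is None or w < self.threshold - 1e-12:
                raise DataFormatError(
                    f"edge {u!r}-{v!r} weight {w} below threshold {self.threshold}"
                )

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def isolated_nodes(self) -> list[str]:
        return [n for n, deg in self.graph.degree if deg == 0]


def write_network(net: CoexpressionNetwork, path: str | Path) -> None:
    """Write the edge list as TSV: gene1, gene2, r, p."""
    with open(path, "w") as fh:
        fh.write("gene1\tgene2\tr\tp\n")
        for u, v, d in net.graph.edges(data=True):
            r = d["weight"] * d.get("sign", 1)
            fh.write(f"{u}\t{v}\t{r:.10g}\t{d.get('p', float('nan')):.10g}\n")


# ---------------------------------------------------------------------------
# Module partition
# ---------------------------------------------------------------------------

@dataclass
class ModulePartition:
    """Assignment of genes to modules 0..K-1, with per-module eigengenes.

    An eigengene is the first principal component of the standardized
    expression of a module's genes: a unit-norm per-sample profile that
    serves as the module's cluster center.
    """

    labels: dict[str, int]
    n_modules: int
    eigengenes: dict[int, np.ndarray] = field(default_factory=dict)
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        distinct = set(self.labels.values())
        if distinct and distinct != set(range(self.n_modules)):
            raise DataFormatError(
                f"labels use {sorted(distinct)} but n_modules={self.n_modules}"
            )
        if not distinct and self.n_modules != 0:
            raise DataFormatError("empty label map but n_modules > 0")
        self.eigengenes = {int(k): np.asarray(v, dtype=float) for k, v in self.eigengenes.items()}
        for k, me in self.eigengenes.items():
            nrm = float(np.linalg.norm(me))
            if abs(nrm - 1.0) > 1e-6:
                raise DataFormatError(f"eigengene of module {k} has norm {nrm}, expected 1")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.labels)

    def module_genes(self, module: int) -> list[str]:
        return [g for g, m in self.labels.items() if m == module]

    def module_sizes(self) -> dict[int, int]:
        sizes = {k: 0 for k in range(self.n_modules)}
        for m in self.labels.values():
            sizes[m] += 1
        return sizes


def write_partition(partition: ModulePartition, path: str | Path) -> None:
    doc = {
        "format_version": PARTITION_FORMAT_VERSION,
        "n_modules": partition.n_modules,
        "labels": partition.labels,
        "eigengenes": {str(k): [float(x) for x in v] for k, v in partition.eigengenes.items()},
        "sample_ids": partition.sample_ids,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def read_partition(path: str | Path) -> ModulePartition:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format_version") != PARTITION_FORMAT_VERSION:
        raise DataFormatError(
            f"{path}: partition format_version {doc.get('format_version')!r} "
            f"!= {PARTITION_FORMAT_VERSION}"
        )
    for key in ("n_modules", "labels"):
        if key not in doc:
            raise DataFormatError(f"{path}: missing required field {key!r}")
    return ModulePartition(
        labels={str(g): int(m) for g, m in doc["labels"].items()},
        n_modules=int(doc["n_modules"]),
        eigengenes={int(k): np.array(v, dtype=float) for k, v in doc.get("eigengenes", {}).items()},
        sample_ids=doc.get("sample_ids"),
    )


# ---------------------------------------------------------------------------
# Annotation sets (GMT)
# ---------------------------------------------------------------------------

@dataclass
class AnnotationSets:
    """Named flat gene sets (GO-BP-like), keyed by term id."""

    sets: dict[str, tuple[str, frozenset[str]]]

    def __post_init__(self) -> None:
        for term, (_, genes) in self.sets.items():
            if not genes:
                raise DataFormatError(f"annotation term {term!r} has an empty gene set")

    def __len__(self) -> int:
        return len(self.sets)

    def genes(self, term: str) -> frozenset[str]:
        return self.sets[term][1]

    def items(self):
        return self.sets.items()


def read_gmt(path: str | Path) -> AnnotationSets:
    """Read a GMT file: ``term<TAB>description<TAB>gene1<TAB>gene2...``.

    Duplicate genes within one line are collapsed; term order is preserved.
    """
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise DataFormatError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields"
                )
            term, desc = parts[0], parts[1]
            if term in sets:
                raise DataFormatError(f"{path}:{lineno}: duplicate term id {term!r}")
            genes = frozenset(g for g in parts[2:] if g)
            if not genes:
                raise DataFormatError(f"{path}:{lineno}: term {term!r} lists no genes")
            sets[term] = (desc, genes)
    return AnnotationSets(sets)


def write_gmt(sets: AnnotationSets, path: str | Path) -> None:
    with open(path, "w") as fh:
        for term, (desc, genes) in sets.items():
            fh.write("\t".join([term, desc, *sorted(genes)]) + "\n")


# ---------------------------------------------------------------------------
# Survival table
# ---------------------------------------------------------------------------

@dataclass
class SurvivalTable:
    """Per-sample follow-up time and event indicator (1=event, 0=censored)."""

    sample_ids: list[str]
    time: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if not (len(self.sample_ids) == len(self.time) == len(self.event)):
            raise DataFormatError("survival columns have mismatched lengths")
        dup = _first_duplicate(self.sample_ids)
        if dup is not None:
            raise DataFormatError(f"duplicate sample id {dup!r} in survival table")
        if (self.time < 0).any():
            bad = self.sample_ids[int(np.argmax(self.time < 0))]
            raise DataFormatError(f"negative follow-up time for sample {bad!r}")
        if not np.isin(self.event, (0, 1)).all():
            bad = self.sample_ids[int(np.argmax(~np.isin(self.event, (0, 1))))]
            raise DataFormatError(f"event indicator for {bad!r} must be 0 or 1")

    def align(self, sample_ids: Sequence[str]) -> "SurvivalTable":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise DataFormatError(f"sample {missing[0]!r} absent from survival table")
        idx = [pos[s] for s in sample_ids]
        return SurvivalTable(list(sample_ids), self.time[idx], self.event[idx])


def read_survival(path: str | Path) -> SurvivalTable:
    """Read a TSV with columns ``sample_id``, ``time``, ``event``."""
    df = pd.read_csv(path, sep="\t")
    for col in ("sample_id", "time", "event"):
        if col not in df.columns:
            raise DataFormatError(f"{path}: missing column {col!r}")
    return SurvivalTable(
        list(df["sample_id"].astype(str)),
        df["time"].to_numpy(dtype=float),
        df["event"].to_numpy(dtype=int),
    )


def write_survival(surv: SurvivalTable, path: str | Path) -> None:
    pd.DataFrame(
        {"sample_id": surv.sample_ids, "time": surv.time, "event": surv.event}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# PPI network
# ---------------------------------------------------------------------------

@dataclass
class PPINetwork:
    """Undirected protein-protein interaction graph, optional edge scores."""

    graph: nx.Graph

    def __post_init__(self) -> None:
        loops = list(nx.selfloop_edges(self.graph))
        if loops:
            raise DataFormatError(f"self-loop on {loops[0][0]!r} in PPI network")


def read_edge_list(path: str | Path) -> PPINetwork:
    """Read a 2-3 column TSV edge list (gene1, gene2[, score]).

    Repeated edges keep the maximum score; self-loops are dropped (their
    endpoints are retained as nodes) and the drop count is logged.
    """
    g = nx.Graph()
    dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise DataFormatError(f"{path}:{lineno}: need at least two columns")
            a, b = parts[0], parts[1]
            if lineno == 1 and parts[:2] in (["gene1", "gene2"], ["protein1", "protein2"]):
                continue
            score = None
            if len(parts) >= 3 and parts[2] != "":
                try:
                    score = float(parts[2])
                except ValueError as exc:
                    raise DataFormatError(
                        f"{path}:{lineno}: non-numeric score {parts[2]!r}"
                    ) from exc
            if a == b:
                dropped += 1
                g.add_node(a)
                continue
            if g.has_edge(a, b):
                old = g[a][b].get("score")
                if score is not None and (old is None or score > old):
                    g[a][b]["score"] = score
            else:
                if score is None:
                    g.add_edge(a, b)
                else:
                    g.add_edge(a, b, score=score)
    if dropped:
        logger.info("dropped %d self-loop(s) while reading %s", dropped, path)
    return PPINetwork(g)


def write_edge_list(ppi: PPINetwork, path: str | Path) -> None:
    # Isolated nodes are not representable in an edge list and are dropped.
    with open(path, "w") as fh:
        for u, v, d in ppi.graph.edges(data=True):
            if "score" in d:
                fh.write(f"{u}\t{v}\t{d['score']:.10g}\n")
            else:
                fh.write(f"{u}\t{v}\n")
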