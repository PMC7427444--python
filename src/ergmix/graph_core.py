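"""Binary graph container, validation, and ERGM sufficient statistics.

The statistics computed here define the vector g(y) entering every model
specification: edge count, selective-mixing cell counts, structural nodal
covariate sums, latent-cluster homophily, and the fixed-decay GWESP term.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .model import STRUCT_COVARIATES, ModelSpec, mixing_cells

__all__ = [
    "BrainGraph",
    "NodeAttributeTable",
    "EspDistribution",
    "StatisticVector",
    "MixingMatrix",
    "GraphValidationError",
    "validate_graph",
    "density",
    "esp_distribution",
    "gwesp_from_esp",
    "gwesp_statistic",
    "mixing_counts",
    "compute_statistics",
    "read_adjacency",
    "write_adjacency",
    "read_attributes",
    "write_attributes",
]


class GraphValidationError(ValueError):
    """Raised when an adjacency matrix violates the binary-graph contract."""


@dataclass(frozen=True)
class BrainGraph:
    """An undirected, unweighted graph on a fixed node set.

    ``adjacency`` is a symmetric hollow 0/1 integer matrix; ``node_ids``
    preserves user-supplied identifiers (0-based integers by default).
    """

    adjacency: np.ndarray
    node_ids: tuple = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.node_ids is None:
            object.__setattr__(self, "node_ids", tuple(range(self.n_nodes)))
        if len(self.node_ids) != self.n_nodes:
            raise GraphValidationError(
                f"{len(self.node_ids)} node ids for {self.n_nodes} nodes"
            )
        self.adjacency.setflags(write=False)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def edge_list(self) -> np.ndarray:
        """(E, 2) array of edges with i < j, positional indices."""
        iu, ju = np.nonzero(np.triu(self.adjacency, k=1))
        return np.column_stack([iu, ju])

    def neighbor_masks(self) -> list[int]:
        """Adjacency rows as python int bitmasks (bit k set iff edge to k)."""
        return adjacency_to_bitmasks(self.adjacency)

    def to_networkx(self) -> nx.Graph:
        g = nx.from_numpy_array(self.adjacency)
        return nx.relabel_nodes(g, dict(enumerate(self.node_ids)))


def adjacency_to_bitmasks(adjacency: np.ndarray) -> list[int]:
    n = adjacency.shape[0]
    masks = []
    for i in range(n):
        row = 0
        for j in np.nonzero(adjacency[i])[0]:
            row |= 1 << int(j)
        masks.append(row)
    return masks


def bitmasks_to_adjacency(masks: Sequence[int], n: int) -> np.ndarray:
    adj = np.zeros((n, n), dtype=np.int8)
    for i, row in enumerate(masks):
        while row:
            low = row & -row
            adj[i, low.bit_length() - 1] = 1
            row ^= low
    return adj


def validate_graph(adjacency, node_ids: Sequence | None = None) -> BrainGraph:
    """Check symmetry, hollowness, and binarity; return a ``BrainGraph``.

    Error messages name the first offending entry so malformed input files
    can be fixed by inspection.
    """
    a = np.asarray(adjacency)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise GraphValidationError(f"adjacency must be square, got shape {a.shape}")
    bad = np.argwhere(~np.isin(a, (0, 1)))
    if bad.size:
        i, j = bad[0]
        raise GraphValidationError(
            f"non-binary entry a[{i},{j}] = {a[i, j]!r}"
        )
    a = a.astype(np.int8)
    asym = np.argwhere(a != a.T)
    if asym.size:
        i, j = asym[0]
        raise GraphValidationError(
            f"asymmetric pair a[{i},{j}]={a[i, j]} vs a[{j},{i}]={a[j, i]}"
        )
    diag = np.nonzero(np.diag(a))[0]
    if diag.size:
        i = diag[0]
        raise GraphValidationError(f"self-loop at a[{i},{i}]")
    ids = tuple(node_ids) if node_ids is not None else None
    return BrainGraph(adjacency=a, node_ids=ids)


def density(g: BrainGraph) -> float:
    if g.n_nodes < 2:
        raise GraphValidationError("density undefined for graphs with < 2 nodes")
    return g.n_edges / (g.n_nodes * (g.n_nodes - 1) / 2)


@dataclass(frozen=True)
class EspDistribution:
    """Histogram of edges by shared-partner count.

    ``counts[i]`` is the number of edges whose endpoints have exactly ``i``
    common neighbors.  The counts sum to the edge count.
    """

    counts: Mapping[int, int]

    @property
    def n_edges(self) -> int:
        return sum(self.counts.values())

    def as_array(self, max_sp: int | None = None) -> np.ndarray:
        m = max(self.counts, default=0) if max_sp is None else max_sp
        out = np.zeros(m + 1, dtype=np.int64)
        for i, c in self.counts.items():
            if i <= m:
                out[i] = c
        return out


def esp_distribution(g: BrainGraph) -> EspDistribution:
    masks = g.neighbor_masks()
    counts: dict[int, int] = {}
    for i, j in g.edge_list():
        c = (masks[i] & masks[j]).bit_count()
        counts[c] = counts.get(c, 0) + 1
    return EspDistribution(counts=counts)


def gwesp_from_esp(esp: EspDistribution, decay: float) -> float:
    """Fixed-decay GWESP statistic from an ESP histogram.

    e^λ · Σ_{i≥1} [1 − (1 − e^{−λ})^i] · EP_i ; edges with zero shared
    partners contribute nothing.
    """
    if decay < 0:
        raise ValueError("gwesp decay must be >= 0")
    q = 1.0 - math.exp(-decay)
    total = sum((1.0 - q**i) * c for i, c in esp.counts.items() if i >= 1)
    return math.exp(decay) * total


def gwesp_statistic(g: BrainGraph, decay: float) -> float:
    """GWESP computed directly from the adjacency (matrix-product route).

    Independent of :func:`gwesp_from_esp`; the two must agree, which the
    test suite exploits as a cross-check.
    """
    if decay < 0:
        raise ValueError("gwesp decay must be >= 0")
    a = g.adjacency.astype(np.int64)
    common = a @ a  # common[i,j] = shared partners of dyad (i,j)
    iu, ju = np.nonzero(np.triu(a, k=1))
    sp = common[iu, ju]
    q = 1.0 - math.exp(-decay)
    return float(math.exp(decay) * np.sum(1.0 - q**sp.astype(float)))


@dataclass(frozen=True)
class MixingMatrix:
    """Edge counts per unordered label pair; zero cells are materialized."""

    counts: Mapping[tuple[str, str], int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class StatisticVector:
    term_names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        if len(self.term_names) != len(self.values):
            raise ValueError("term_names and values length mismatch")

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.term_names))

    def __getitem__(self, term: str) -> float:
        return float(self.values[self.term_names.index(term)])


@dataclass
class NodeAttributeTable:
    """Per-node categorical labels and structural covariates.

    Rows align positionally with ``BrainGraph.node_ids``.  Required columns:
    ``rsn_label`` and ``cortical_group``; the structural covariates and the
    latent cluster id are added by the structural-covariates stage.
    """

    table: pd.DataFrame
    _label_index: np.ndarray = field(init=False, repr=False)

    REQUIRED = ("rsn_label", "cortical_group")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"attribute table missing columns: {missing}")
        if self.table["rsn_label"].isna().any():
            bad = int(np.nonzero(self.table["rsn_label"].isna().to_numpy())[0][0])
            raise ValueError(f"node at row {bad} has no rsn_label")
        labs = self.labels
        lut = {lab: k for k, lab in enumerate(labs)}
        self._label_index = self.table["rsn_label"].map(lut).to_numpy(dtype=np.int64)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def labels(self) -> tuple[str, ...]:
        """Sorted universe of mixing labels."""
        return tuple(sorted(self.table["rsn_label"].unique()))

    @property
    def label_index(self) -> np.ndarray:
        """Per-node integer code into :attr:`labels`."""
        return self._label_index

    @property
    def rsn_label(self) -> np.ndarray:
        return self.table["rsn_label"].to_numpy()

    @property
    def cortical_group(self) -> np.ndarray:
        return self.table["cortical_group"].to_numpy()

    def cortical_group_of(self, label: str) -> str:
        rows = self.table.loc[self.table["rsn_label"] == label, "cortical_group"]
        if rows.empty:
            raise KeyError(f"unknown mixing label {label!r}")
        return str(rows.iloc[0])

    def has_structural(self) -> bool:
        return all(c in self.table.columns for c in STRUCT_COVARIATES) and (
            "latent_cluster" in self.table.columns
        )

    def covariate(self, name: str) -> np.ndarray:
        if name not in self.table.columns:
            raise KeyError(f"covariate {name!r} absent from attribute table")
        return self.table[name].to_numpy(dtype=float)

    def zscored_covariate(self, name: str) -> np.ndarray:
        """Covariate standardized across nodes (zeros when constant)."""
        x = self.covariate(name)
        sd = x.std()
        if sd == 0:
            return np.zeros_like(x)
        return (x - x.mean()) / sd

    @property
    def latent_cluster(self) -> np.ndarray:
        if "latent_cluster" not in self.table.columns:
            raise KeyError("latent_cluster absent from attribute table")
        return self.table["latent_cluster"].to_numpy()

    def check_alignment(self, g: BrainGraph) -> None:
        if len(self) != g.n_nodes:
            raise ValueError(
                f"attribute table has {len(self)} rows for a "
                f"{g.n_nodes}-node graph"
            )


def mixing_counts(g: BrainGraph, attrs: NodeAttributeTable) -> MixingMatrix:
    """Edge count for every unordered label pair, zero cells included."""
    attrs.check_alignment(g)
    labs = attrs.labels
    counts: dict[tuple[str, str], int] = {
        (labs[i], labs[j]): 0
        for i in range(len(labs))
        for j in range(i, len(labs))
    }
    lab = attrs.rsn_label
    for i, j in g.edge_list():
        a, b = sorted((lab[i], lab[j]))
        counts[(a, b)] += 1
    return MixingMatrix(counts=counts)


def compute_statistics(
    g: BrainGraph, attrs: NodeAttributeTable, spec: ModelSpec
) -> StatisticVector:
    """The sufficient-statistic vector g(y) for one model specification.

    Term order: edges; mixing cells (reference cell excluded); structural
    nodal-covariate sums Σ_{(u,v)∈E}(x_u + x_v) with z-scored covariates;
    latent-cluster match count; GWESP at the spec decay.
    """
    attrs.check_alignment(g)
    label_vec = attrs.rsn_label
    names = spec.term_names(label_vec)
    vals: list[float] = [float(g.n_edges)]

    mix = mixing_counts(g, attrs)
    for a, b in mixing_cells(label_vec)[1:]:
        vals.append(float(mix.counts[(a, b)]))

    if spec.has_structural:
        if not attrs.has_structural():
            raise KeyError(
                "spec requires structural covariates but the attribute "
                "table lacks them"
            )
        deg = g.adjacency.sum(axis=1).astype(float)
        for cov in STRUCT_COVARIATES:
            x = (
                attrs.zscored_covariate(cov)
                if spec.standardize_covariates
                else attrs.covariate(cov)
            )
            vals.append(float(deg @ x))
        clus = attrs.latent_cluster
        nm = sum(1 for i, j in g.edge_list() if clus[i] == clus[j])
        vals.append(float(nm))

    if spec.has_gwesp:
        vals.append(gwesp_from_esp(esp_distribution(g), spec.gwesp_decay))

    return StatisticVector(term_names=tuple(names), values=np.asarray(vals))


# ---------------------------------------------------------------------------
# file I/O


def read_adjacency(path: str | Path) -> BrainGraph:
    """Dense CSV/TSV (header row of node ids) or GraphML adjacency."""
    path = Path(path)
    if path.suffix == ".graphml":
        gx = nx.read_graphml(path)
        nodes = list(gx.nodes)
        a = nx.to_numpy_array(gx, nodelist=nodes, dtype=int)
        return validate_graph(a, node_ids=nodes)
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep, index_col=None)
    return validate_graph(df.to_numpy(), node_ids=list(df.columns))


def write_adjacency(g: BrainGraph, path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".graphml":
        nx.write_graphml(g.to_networkx(), path)
        return
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    pd.DataFrame(g.adjacency, columns=[str(i) for i in g.node_ids]).to_csv(
        path, sep=sep, index=False
    )


def read_attributes(path: str | Path) -> NodeAttributeTable:
    df = pd.read_csv(path, sep="\t")
    if "node_id" in df.columns:
        df = df.drop(columns=["node_id"])
    return NodeAttributeTable(df)


def write_attributes(attrs: NodeAttributeTable, path: str | Path) -> None:
    out = attrs.table.copy()
    out.insert(0, "node_id", range(len(out)))
    out.to_csv(path, sep="\t", index=False)
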