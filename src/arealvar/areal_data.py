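"""Areal datasets: adjacency structures, per-area counts, expected counts.

The analyses in this package operate on a set of small geographic areas
(healthcare areas, districts, ...) with, for each area, an observed admission
count, a population at risk and an expected count obtained by indirect
standardization.  The neighborhood structure of the areas (two areas are
neighbors when they share a boundary) is represented as an undirected graph
and drives the spatially structured priors of the Bayesian models.

All vectors are aligned to the area ordering fixed when the adjacency
structure is built; that ordering is the canonical index everywhere else in
the package.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "AdjacencyStructure",
    "ArealCounts",
    "GenderPairedDataset",
    "ValidationReport",
    "load_adjacency",
    "write_adjacency",
    "load_counts",
    "write_counts",
    "expected_counts",
    "validate_paired_dataset",
    "export_choropleth_geojson",
]


class ArealDataError(ValueError):
    """Raised for malformed areal inputs (duplicate ids, self-loops, ...)."""


@dataclass(frozen=True)
class AdjacencyStructure:
    """Symmetric neighborhood graph over ``n_areas`` labelled areas.

    Edges are stored once as unordered index pairs ``(i, j)`` with ``i < j``
    against the fixed area ordering in ``area_ids``.  Self-loops are
    rejected.  The number of connected components is recorded because the
    intrinsic CAR prior is improper with rank deficiency equal to it.
    """

    area_ids: tuple
    edge_index: np.ndarray  # (m, 2) int array, i < j, sorted lexicographically

    def __post_init__(self):
        ids = tuple(str(a) for a in self.area_ids)
        object.__setattr__(self, "area_ids", ids)
        if len(set(ids)) != len(ids):
            seen, dup = set(), None
            for a in ids:
                if a in seen:
                    dup = a
                    break
                seen.add(a)
            raise ArealDataError(f"duplicate area id: {dup!r}")
        e = np.asarray(self.edge_index, dtype=np.int64).reshape(-1, 2)
        if e.size and (e.min() < 0 or e.max() >= len(ids)):
            raise ArealDataError("edge refers to an area index out of range")
        if np.any(e[:, 0] == e[:, 1]):
            i = int(e[e[:, 0] == e[:, 1]][0, 0])
            raise ArealDataError(f"self-loop on area {ids[i]!r}")
        e = np.sort(e, axis=1)
        e = np.unique(e, axis=0) if e.size else e.reshape(0, 2)
        e.setflags(write=False)
        object.__setattr__(self, "edge_index", e)

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_edges(cls, area_ids: Sequence, edges: Iterable[tuple]) -> "AdjacencyStructure":
        """Build from labelled unordered pairs; symmetrizes duplicates."""
        ids = [str(a) for a in area_ids]
        index = {a: k for k, a in enumerate(ids)}
        if len(index) != len(ids):
            # delegate duplicate detection to __post_init__
            return cls(tuple(ids), np.zeros((0, 2), dtype=np.int64))
        rows = []
        for a, b in edges:
            a, b = str(a), str(b)
            for x in (a, b):
                if x not in index:
                    raise ArealDataError(f"edge references undeclared area {x!r}")
            rows.append((index[a], index[b]))
        e = np.asarray(rows, dtype=np.int64).reshape(-1, 2)
        return cls(tuple(ids), e)

    # -- derived properties ------------------------------------------------

    @property
    def n_areas(self) -> int:
        return len(self.area_ids)

    @property
    def n_edges(self) -> int:
        return int(self.edge_index.shape[0])

    @property
    def edges(self) -> frozenset:
        """Unordered labelled pairs."""
        ids = self.area_ids
        return frozenset(frozenset((ids[i], ids[j])) for i, j in self.edge_index)

    @cached_property
    def degrees(self) -> np.ndarray:
        d = np.zeros(self.n_areas, dtype=np.int64)
        if self.n_edges:
            np.add.at(d, self.edge_index[:, 0], 1)
            np.add.at(d, self.edge_index[:, 1], 1)
        return d

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_areas))
        g.add_edges_from(map(tuple, self.edge_index))
        return g

    @cached_property
    def component_labels(self) -> np.ndarray:
        """Integer component label per area."""
        lab = np.full(self.n_areas, -1, dtype=np.int64)
        for k, comp in enumerate(nx.connected_components(self.to_graph())):
            lab[list(comp)] = k
        return lab

    @cached_property
    def n_components(self) -> int:
        return int(self.component_labels.max()) + 1 if self.n_areas else 0

    @cached_property
    def n_isolated(self) -> int:
        return int(np.sum(self.degrees == 0))

    @cached_property
    def adjacency_matrix(self) -> sp.csr_matrix:
        """Sparse symmetric 0/1 neighborhood matrix W."""
        n = self.n_areas
        if not self.n_edges:
            return sp.csr_matrix((n, n))
        i, j = self.edge_index[:, 0], self.edge_index[:, 1]
        data = np.ones(2 * self.n_edges)
        return sp.csr_matrix((data, (np.r_[i, j], np.r_[j, i])), shape=(n, n))

    def laplacian(self) -> np.ndarray:
        """Dense graph Laplacian D - W (precision structure of the ICAR prior)."""
        W = self.adjacency_matrix.toarray()
        return np.diag(self.degrees.astype(float)) - W

    def coloring(self) -> list[np.ndarray]:
        """Greedy proper coloring as index blocks (no two neighbors share a block).

        Used to update intrinsic-CAR fields with vectorized
        Metropolis steps while preserving detailed balance.
        """
        colors = nx.greedy_color(self.to_graph(), strategy="largest_first")
        n_col = max(colors.values(), default=0) + 1
        blocks = [[] for _ in range(n_col)]
        for node, c in colors.items():
            blocks[c].append(node)
        return [np.asarray(sorted(b), dtype=np.int64) for b in blocks]


@dataclass(frozen=True)
class ArealCounts:
    """Observed counts, population at risk and expected counts per area."""

    area_ids: tuple
    observed: np.ndarray
    population: np.ndarray
    expected: np.ndarray | None = None

    def __post_init__(self):
        ids = tuple(str(a) for a in self.area_ids)
        object.__setattr__(self, "area_ids", ids)
        o = np.asarray(self.observed)
        if not np.allclose(o, np.round(o)) or np.any(o < 0):
            raise ArealDataError("observed counts must be non-negative integers")
        o = np.round(o).astype(np.int64)
        N = np.asarray(self.population, dtype=float)
        if np.any(N <= 0):
            raise ArealDataError("populations must be strictly positive")
        if len(ids) != o.size or o.size != N.size:
            raise ArealDataError("area_ids, observed and population lengths differ")
        object.__setattr__(self, "observed", o)
        object.__setattr__(self, "population", N)
        if self.expected is not None:
            e = np.asarray(self.expected, dtype=float)
            if e.size != o.size:
                raise ArealDataError("expected has wrong length")
            if np.any(e <= 0):
                raise ArealDataError("expected counts must be strictly positive")
            object.__setattr__(self, "expected", e)

    @property
    def n_areas(self) -> int:
        return len(self.area_ids)

    @property
    def rates(self) -> np.ndarray:
        """Crude per-area rates o_i / N_i."""
        return self.observed / self.population

    def with_expected(self) -> "ArealCounts":
        """Attach indirectly standardized expected counts (whole-region rate)."""
        e = expected_counts(self.observed, self.population)
        return ArealCounts(self.area_ids, self.observed, self.population, e)


@dataclass(frozen=True)
class GenderPairedDataset:
    """Two aligned outcomes (men, women) over one adjacency structure."""

    adjacency: AdjacencyStructure
    men: ArealCounts
    women: ArealCounts


def expected_counts(observed, population) -> np.ndarray:
    """Indirectly standardized expected counts from the whole-region rate.

    ``e_i = r * N_i`` with ``r = sum(o) / sum(N)``; totals are conserved
    exactly up to floating error.  Computed per stratum (per gender) by the
    caller.
    """
    o = np.asarray(observed, dtype=float)
    N = np.asarray(population, dtype=float)
    if np.any(N <= 0):
        raise ArealDataError("populations must be strictly positive")
    r = o.sum() / N.sum()
    return r * N


# ---------------------------------------------------------------------------
# file I/O


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    return pd.read_csv(path, sep=sep, comment="#", dtype={"area_id": str})


def load_adjacency(path, format: str | None = None) -> AdjacencyStructure:
    """Read a neighborhood structure from an adjacency-list or edge-list file.

    * ``adjacency-list``: one whitespace-delimited line per area, the area id
      followed by its neighbor ids.  An area with no neighbors is a single
      token on its line.  Every referenced neighbor must have its own line.
    * ``edge-list``: delimited table (.csv/.tsv) whose first two columns name
      the endpoint areas; one row per unordered edge (symmetrized on read).

    When ``format`` is None it is guessed: .csv/.tsv -> edge-list,
    anything else -> adjacency-list.
    """
    path = Path(path)
    if format is None:
        format = "edge-list" if path.suffix.lower() in {".csv", ".tsv", ".tab"} else "adjacency-list"
    if format == "edge-list":
        df = _read_table(path)
        a = df.iloc[:, 0].astype(str)
        b = df.iloc[:, 1].astype(str)
        ids = list(dict.fromkeys(pd.concat([a, b])))
        return AdjacencyStructure.from_edges(ids, zip(a, b))
    if format != "adjacency-list":
        raise ValueError(f"unknown adjacency format {format!r}")
    ids: list[str] = []
    neighbor_lists: dict[str, list[str]] = {}
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        toks = line.split()
        aid, nbrs = toks[0], toks[1:]
        if aid in neighbor_lists:
            raise ArealDataError(f"duplicate area id: {aid!r}")
        ids.append(aid)
        neighbor_lists[aid] = nbrs
    edges = []
    for aid, nbrs in neighbor_lists.items():
        for b in nbrs:
            if b == aid:
                raise ArealDataError(f"self-loop on area {aid!r}")
            if b not in neighbor_lists:
                raise ArealDataError(f"area {aid!r} references undeclared area {b!r}")
            edges.append((aid, b))
    return AdjacencyStructure.from_edges(ids, edges)


def write_adjacency(adj: AdjacencyStructure, path, format: str | None = None) -> None:
    path = Path(path)
    if format is None:
        format = "edge-list" if path.suffix.lower() in {".csv", ".tsv", ".tab"} else "adjacency-list"
    if format == "edge-list":
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
        ids = adj.area_ids
        df = pd.DataFrame(
            {"area_a": [ids[i] for i, _ in adj.edge_index],
             "area_b": [ids[j] for _, j in adj.edge_index]}
        )
        df.to_csv(path, sep=sep, index=False)
        return
    g = adj.to_graph()
    ids = adj.area_ids
    lines = []
    for i, aid in enumerate(ids):
        nbrs = " ".join(ids[j] for j in sorted(g.neighbors(i)))
        lines.append(f"{aid} {nbrs}".rstrip())
    Path(path).write_text("\n".join(lines) + "\n")


def load_counts(path, gender: str | None = None) -> ArealCounts | dict[str, ArealCounts]:
    """Read a per-area counts table.

    Expected columns: ``area_id, observed, population`` and optionally
    ``expected`` and ``gender`` (values ``men``/``women``).  With a gender
    column and ``gender=None`` a dict keyed by gender is returned.
    """
    df = _read_table(path)
    required = {"area_id", "observed", "population"}
    missing = required - set(df.columns)
    if missing:
        raise ArealDataError(f"counts file missing columns: {sorted(missing)}")

    def build(sub: pd.DataFrame) -> ArealCounts:
        e = sub["expected"].to_numpy(float) if "expected" in sub.columns else None
        return ArealCounts(
            tuple(sub["area_id"]),
            sub["observed"].to_numpy(),
            sub["population"].to_numpy(float),
            e,
        )

    if "gender" in df.columns:
        groups = {str(g): build(sub) for g, sub in df.groupby("gender", sort=False)}
        if gender is not None:
            return groups[gender]
        return groups
    return build(df)


def write_counts(counts, path, header_lines: Sequence[str] = ()) -> None:
    """Write one ArealCounts or a {gender: ArealCounts} dict to a delimited table."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    frames = []
    items = counts.items() if isinstance(counts, dict) else [(None, counts)]
    for g, c in items:
        d = {"area_id": c.area_ids, "observed": c.observed, "population": c.population}
        if c.expected is not None:
            d["expected"] = c.expected
        df = pd.DataFrame(d)
        if g is not None:
            df.insert(0, "gender", g)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        out.to_csv(fh, sep=sep, index=False)


# ---------------------------------------------------------------------------
# validation


@dataclass
class ValidationReport:
    violations: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_paired_dataset(ds: GenderPairedDataset) -> ValidationReport:
    """Check alignment and positivity invariants; disconnection is a warning."""
    rep = ValidationReport()
    ids = ds.adjacency.area_ids
    for label, c in (("men", ds.men), ("women", ds.women)):
        if c.area_ids != ids:
            rep.violations.append(f"{label}: area ids misaligned with adjacency")
        if c.expected is None:
            rep.violations.append(f"{label}: expected counts missing")
        elif np.any(np.asarray(c.expected) <= 0):
            rep.violations.append(f"{label}: zero or negative expected count")
    if ds.men.area_ids != ds.women.area_ids:
        rep.violations.append("men and women area ids differ or are permuted")
    if ds.adjacency.n_components > 1:
        rep.warnings.append(
            f"adjacency graph has {ds.adjacency.n_components} connected components"
        )
    return rep


# ---------------------------------------------------------------------------
# choropleth export (geometry is carried through, never used in computation)


def export_choropleth_geojson(geojson_path, values: dict[str, dict], out_path) -> None:
    """Merge per-area result columns into a GeoJSON's feature properties.

    ``values`` maps column name -> {area_id: value}.  Features whose
    ``area_id`` property has no value get nulls.
    """
    gj = json.loads(Path(geojson_path).read_text())
    for feat in gj.get("features", []):
        aid = str(feat.get("properties", {}).get("area_id"))
        for col, mapping in values.items():
            feat.setdefault("properties", {})[col] = mapping.get(aid)
    Path(out_path).write_text(json.dumps(gj))
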