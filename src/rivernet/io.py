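"""Tabular and graph I/O for the pipeline.

Canonical interchange formats are plain tab-separated files (OTU tables,
sample metadata, land-use areas) and GraphML / edge-list TSV for networks.
All writers are deterministic: the same in-memory object always produces a
byte-identical file.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

TAXONOMIC_RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")

LANDUSE_CLASSES = ("farmlands", "forests", "freshwaters", "urban", "others")

#: relative tolerance for the land-use area-sum invariant
_AREA_SUM_RTOL = 0.005


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


@dataclass
class AbundanceMatrix:
    """Integer OTU counts, samples in rows, taxa in columns.

    Parameters
    ----------
    counts : pandas.DataFrame
        Nonnegative integer counts; index = sample ids, columns = taxon ids.
    taxonomy : pandas.DataFrame, optional
        One row per taxon, columns a subset of :data:`TAXONOMIC_RANKS`.
    sample_data : pandas.DataFrame, optional
        Per-sample annotations (reach, season, chemistry ...).
    attrs : dict
        Free-form provenance (e.g. simulation ground truth); never serialized.
    """

    counts: pd.DataFrame
    taxonomy: pd.DataFrame | None = None
    sample_data: pd.DataFrame | None = None
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            dup = c.index[c.index.duplicated()].tolist()
            raise ValidationError(f"duplicate sample ids: {dup}")
        if c.columns.has_duplicates:
            dup = c.columns[c.columns.duplicated()].tolist()
            raise ValidationError(f"duplicate taxon ids: {dup}")
        arr = c.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                r, k = np.argwhere(~np.isclose(arr, np.round(arr)))[0]
                raise ValidationError(
                    f"non-integer count at sample {c.index[r]!r}, taxon {c.columns[k]!r}: {arr[r, k]}"
                )
            self.counts = c.astype(np.int64)
            arr = self.counts.to_numpy()
        if (arr < 0).any():
            r, k = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative count at sample {c.index[r]!r}, taxon {c.columns[k]!r}: {arr[r, k]}"
            )
        if self.taxonomy is not None:
            extra = set(self.taxonomy.index) - set(c.columns)
            if extra:
                raise ValidationError(f"taxonomy rows not in count table: {sorted(extra)[:5]}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[1]

    def relative_abundance(self) -> pd.DataFrame:
        """Per-sample relative abundances (rows sum to 1)."""
        totals = self.counts.sum(axis=1)
        return self.counts.div(totals, axis=0)

    def subset_samples(self, sample_ids: Iterable[str]) -> "AbundanceMatrix":
        ids = list(sample_ids)
        sd = self.sample_data.loc[ids] if self.sample_data is not None else None
        return AbundanceMatrix(self.counts.loc[ids], self.taxonomy, sd, dict(self.attrs))

    def subset_taxa(self, taxon_ids: Iterable[str]) -> "AbundanceMatrix":
        ids = list(taxon_ids)
        tx = self.taxonomy.loc[self.taxonomy.index.intersection(ids)] if self.taxonomy is not None else None
        return AbundanceMatrix(self.counts[ids], tx, self.sample_data, dict(self.attrs))


@dataclass
class CoNetwork:
    """Undirected signed co-occurrence network.

    Nodes are taxon ids (optionally annotated with ``phylum`` and
    ``mean_abundance``); edges carry ``sign`` (+1/-1), ``correlation``,
    ``support`` (number of concordant significant measures) and ``q_value``.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)

    def __post_init__(self) -> None:
        for u, v in self.graph.edges:
            if u == v:
                raise ValidationError(f"self-loop on node {u!r}")
        for u, v, d in self.graph.edges(data=True):
            if "sign" in d and "correlation" in d:
                if d["sign"] != int(np.sign(d["correlation"])):
                    raise ValidationError(f"edge ({u},{v}): sign inconsistent with correlation")

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_signs(self) -> tuple[int, int]:
        """(positive, negative) edge counts."""
        signs = [d.get("sign", 1) for _, _, d in self.graph.edges(data=True)]
        pos = sum(1 for s in signs if s > 0)
        return pos, len(signs) - pos

    def sorted_edges(self) -> list[tuple[str, str, dict]]:
        """Edges with endpoints ordered and the list sorted lexicographically."""
        out = []
        for u, v, d in self.graph.edges(data=True):
            a, b = sorted((str(u), str(v)))
            out.append((a, b, d))
        return sorted(out, key=lambda e: (e[0], e[1]))


@dataclass
class LandUseTable:
    """Per sub-basin land-cover areas (km^2) in five classes."""

    areas: pd.DataFrame  # index = sub-basin id, columns = LANDUSE_CLASSES
    total: pd.Series  # total area per sub-basin

    def __post_init__(self) -> None:
        missing = set(LANDUSE_CLASSES) - set(self.areas.columns)
        if missing:
            raise ValidationError(f"missing land-use classes: {sorted(missing)}")
        if (self.areas.to_numpy() < 0).any():
            raise ValidationError("negative land-use area")
        class_sum = self.areas[list(LANDUSE_CLASSES)].sum(axis=1)
        bad = ~np.isclose(class_sum, self.total, rtol=_AREA_SUM_RTOL)
        if bad.any():
            rows = self.areas.index[bad].tolist()
            raise ValidationError(
                f"class areas do not sum to total (rtol {_AREA_SUM_RTOL}): {rows}"
            )


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_abundance(
    path: str | Path,
    taxa_in_rows: bool = True,
    taxonomy_path: str | Path | None = None,
    metadata_path: str | Path | None = None,
) -> AbundanceMatrix:
    """Read a tab-separated OTU count table.

    The common OTU-table dialect puts taxa in rows and samples in columns
    (``taxa_in_rows=True``, the default); set it to False for tables already
    oriented samples x taxa.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if taxa_in_rows:
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    df.index.name = None
    df.columns.name = None
    taxonomy = None
    if taxonomy_path is not None:
        taxonomy = pd.read_csv(taxonomy_path, sep="\t", index_col=0, dtype=str)
        taxonomy.index = taxonomy.index.astype(str)
    sample_data = None
    if metadata_path is not None:
        sample_data, _ = read_metadata(metadata_path, sample_ids=list(df.index))
    return AbundanceMatrix(df, taxonomy=taxonomy, sample_data=sample_data)


def write_abundance(matrix: AbundanceMatrix, path: str | Path, taxa_in_rows: bool = True) -> None:
    df = matrix.counts.T if taxa_in_rows else matrix.counts
    label = "#OTU_ID" if taxa_in_rows else "#Sample_ID"
    df.to_csv(path, sep="\t", index_label=label, lineterminator="\n")


def read_metadata(
    path: str | Path, sample_ids: list[str] | None = None
) -> tuple[pd.DataFrame, list[str]]:
    """Read a per-sample metadata table.

    Numeric columns are typed as floats; missing values stay missing (any
    imputation or pairwise deletion happens downstream, per analysis).
    Returns the table and a list of warnings for ids not present in
    ``sample_ids`` (when given).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    # drop columns that contain no data at all
    df = df.dropna(axis=1, how="all")
    warnings: list[str] = []
    if sample_ids is not None:
        unknown = [s for s in df.index if s not in set(sample_ids)]
        absent = [s for s in sample_ids if s not in set(df.index)]
        if unknown:
            warnings.append(f"metadata rows without matching samples: {unknown}")
        if absent:
            warnings.append(f"samples without metadata rows: {absent}")
    return df, warnings


def write_metadata(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index_label="sample", lineterminator="\n")


def read_landuse(path: str | Path) -> LandUseTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    if "total" in df.columns:
        total = df["total"].astype(float)
        areas = df.drop(columns=["total"]).astype(float)
    else:
        areas = df.astype(float)
        total = areas.sum(axis=1)
    return LandUseTable(areas, total)


def write_landuse(table: LandUseTable, path: str | Path) -> None:
    out = table.areas.copy()
    out["total"] = table.total
    out.to_csv(path, sep="\t", index_label="sub_basin", lineterminator="\n")


# ---------------------------------------------------------------------------
# network writers
# ---------------------------------------------------------------------------

_EDGE_COLUMNS = ("source", "target", "sign", "correlation", "supporting_measures", "q_value")


def write_network(net: CoNetwork, path: str | Path, fmt: str = "tsv") -> None:
    """Write a network as an edge-list TSV or GraphML.

    Edge order is stable (lexicographic by node pair) so writes are
    byte-reproducible; GraphML carries the same node and edge attributes and
    re-imports with any generic GraphML reader.
    """
    if fmt == "tsv":
        rows = []
        for u, v, d in net.sorted_edges():
            rows.append(
                {
                    "source": u,
                    "target": v,
                    "sign": "+" if d.get("sign", 1) > 0 else "-",
                    "correlation": f"{d.get('correlation', float('nan')):.6g}",
                    "supporting_measures": d.get("support", ""),
                    "q_value": f"{d.get('q_value', float('nan')):.6g}",
                }
            )
        pd.DataFrame(rows, columns=_EDGE_COLUMNS).to_csv(path, sep="\t", index=False, lineterminator="\n")
    elif fmt == "graphml":
        g = nx.Graph()
        for n in sorted(net.graph.nodes, key=str):
            g.add_node(n, **_clean_attrs(net.graph.nodes[n]))
        for u, v, d in net.sorted_edges():
            g.add_edge(u, v, **_clean_attrs(d))
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown network format: {fmt!r}")


def _clean_attrs(d: dict) -> dict:
    out = {}
    for k, v in d.items():
        if v is None or (isinstance(v, float) and math.isnan(v)):
            continue
        out[k] = v
    return out


def read_network(path: str | Path) -> CoNetwork:
    """Read an edge-list TSV written by :func:`write_network`."""
    df = pd.read_csv(path, sep="\t", dtype={"source": str, "target": str})
    g = nx.Graph()
    for row in df.itertuples(index=False):
        g.add_edge(
            row.source,
            row.target,
            sign=1 if row.sign == "+" else -1,
            correlation=float(row.correlation),
            support=int(row.supporting_measures) if not pd.isna(row.supporting_measures) else 0,
            q_value=float(row.q_value),
        )
    return CoNetwork(g)
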