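"""Feature tables, taxonomic aggregation, and network import/export.

The central container is :class:`FeatureTable`: a features x samples
non-negative matrix (OTU counts or array signal intensities) with optional
feature annotations (taxonomy lineages or gene categories) and per-sample
metadata. Networks are plain :class:`networkx.Graph` objects whose node
and edge attributes follow the conventions documented in
:func:`export_network`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: ranks recognised in semicolon-delimited lineages, outermost first
LINEAGE_RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")

#: Greengenes-style single-letter rank prefixes ("p__Proteobacteria")
RANK_PREFIXES = {r[0] + "__": r for r in LINEAGE_RANKS} | {"k__": "kingdom", "d__": "kingdom"}

UNCLASSIFIED = "unclassified"


class TableError(ValueError):
    """Raised when a feature table fails validation."""


@dataclass
class FeatureTable:
    """Features x samples matrix with annotations and sample metadata.

    Parameters
    ----------
    values
        DataFrame with feature ids as index and sample ids as columns.
        Must be finite and non-negative with unique ids on both axes.
    feature_annotation
        Optional map feature-id -> lineage string or gene category.
    sample_metadata
        Optional DataFrame indexed by sample id (factor columns such as
        soil_type, layer, stage, replicate).
    """

    values: pd.DataFrame
    feature_annotation: dict[str, str] = field(default_factory=dict)
    sample_metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.values.index = self.values.index.astype(str)
        self.values.columns = self.values.columns.astype(str)
        self.validate()

    # -- container protocol ------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_numpy(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def validate(self) -> None:
        idx, cols = self.values.index, self.values.columns
        if idx.duplicated().any():
            dupes = sorted(idx[idx.duplicated()].unique())
            raise TableError(f"duplicate feature id(s): {dupes}")
        if cols.duplicated().any():
            dupes = sorted(cols[cols.duplicated()].unique())
            raise TableError(f"duplicate sample id(s): {dupes}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            bad = self.values.map(lambda v: not isinstance(v, (int, float, np.number)))
            r, c = np.argwhere(bad.to_numpy())[0]
            raise TableError(
                f"non-numeric value at feature {idx[r]!r}, sample {cols[c]!r}"
            )
        if not np.isfinite(arr).all():
            r, c = np.argwhere(~np.isfinite(arr))[0]
            raise TableError(f"non-finite value at feature {idx[r]!r}, sample {cols[c]!r}")
        if (arr < 0).any():
            r, c = np.argwhere(arr < 0)[0]
            raise TableError(
                f"negative value {arr[r, c]} at feature {idx[r]!r}, sample {cols[c]!r}"
            )
        stray = set(self.feature_annotation) - set(idx)
        if stray:
            raise TableError(f"annotation keys not in table: {sorted(stray)[:5]}")

    def copy_with(self, values: pd.DataFrame) -> "FeatureTable":
        """New table with the same metadata restricted to ``values``'s axes."""
        ann = {f: self.feature_annotation[f] for f in values.index if f in self.feature_annotation}
        meta = None
        if self.sample_metadata is not None:
            meta = self.sample_metadata.loc[
                [s for s in values.columns if s in self.sample_metadata.index]
            ]
        return FeatureTable(values, ann, meta)

    def select_samples(self, sample_ids: list[str]) -> "FeatureTable":
        missing = [s for s in sample_ids if s not in self.values.columns]
        if missing:
            raise TableError(f"unknown sample id(s): {missing}")
        return self.copy_with(self.values[sample_ids])

    def relative_abundance(self) -> "FeatureTable":
        """Close each sample to unit sum (all-zero samples stay zero)."""
        totals = self.values.sum(axis=0)
        safe = totals.replace(0, 1.0)
        return self.copy_with(self.values / safe)


# -- I/O -------------------------------------------------------------------

def read_feature_table(
    path,
    orientation: str = "features_in_rows",
    annotation_path=None,
    metadata_path=None,
) -> FeatureTable:
    """Read a TSV feature table (header row + id column).

    ``orientation`` declares the layout on disk: ``features_in_rows``
    (default) or ``samples_in_rows`` (transposed on read).
    """
    if orientation not in ("features_in_rows", "samples_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.isna().any().any():
        r = df.index[df.isna().any(axis=1)][0]
        raise TableError(f"ragged or missing cell in row {r!r} of {path}")
    try:
        df = df.astype(float)
    except ValueError:
        for c in df.columns:
            bad = pd.to_numeric(df[c], errors="coerce").isna()
            if bad.any():
                raise TableError(
                    f"non-numeric cell at row {df.index[bad][0]!r}, column {c!r} of {path}"
                ) from None
        raise
    if orientation == "samples_in_rows":
        df = df.T
    annotation = {}
    if annotation_path is not None:
        ann = pd.read_csv(annotation_path, sep="\t", index_col=0, dtype=str)
        annotation = ann.iloc[:, 0].to_dict()
        annotation = {k: v for k, v in annotation.items() if k in set(df.index.astype(str))}
    metadata = None
    if metadata_path is not None:
        metadata = pd.read_csv(metadata_path, sep="\t", index_col=0, dtype=str)
    return FeatureTable(df, annotation, metadata)


def write_feature_table(table: FeatureTable, path) -> None:
    """Write the values matrix as TSV, features in rows."""
    table.values.to_csv(path, sep="\t")


# -- taxonomic aggregation -------------------------------------------------

def parse_lineage(lineage: str, delimiter: str = ";") -> dict[str, str]:
    """Split a lineage string into rank -> taxon name.

    Handles Greengenes-style prefixes (``p__Proteobacteria``) and plain
    positional lineages (kingdom;phylum;class;...). Empty fields are
    skipped.
    """
    out: dict[str, str] = {}
    parts = [p.strip() for p in lineage.split(delimiter)]
    prefixed = any(p[:3] in RANK_PREFIXES for p in parts if len(p) >= 3)
    for i, part in enumerate(parts):
        if not part:
            continue
        if prefixed:
            rank = RANK_PREFIXES.get(part[:3])
            name = part[3:].strip()
            if rank and name:
                out[rank] = name
        elif i < len(LINEAGE_RANKS):
            out[LINEAGE_RANKS[i]] = part
    return out


def aggregate_by_level(
    table: FeatureTable,
    level: str = "phylum",
    class_level_exceptions: tuple[str, ...] = ("Proteobacteria",),
    delimiter: str = ";",
) -> FeatureTable:
    """Sum features into taxa at ``level``.

    Taxa listed in ``class_level_exceptions`` (by their name at ``level``)
    are split out one rank finer, at class level — the convention used for
    Proteobacteria, whose classes behave as ecologically distinct groups.
    Features without a usable annotation are pooled into an
    ``unclassified`` bucket rather than dropped.
    """
    if level not in LINEAGE_RANKS:
        raise ValueError(f"unknown rank {level!r}")
    finer = LINEAGE_RANKS[min(LINEAGE_RANKS.index(level) + 1, len(LINEAGE_RANKS) - 1)]
    labels = []
    n_unclassified = 0
    for fid in table.feature_ids:
        lineage = table.feature_annotation.get(fid)
        ranks = parse_lineage(lineage, delimiter) if lineage else {}
        name = ranks.get(level)
        if name is None:
            labels.append(UNCLASSIFIED)
            n_unclassified += 1
            continue
        if name in class_level_exceptions:
            labels.append(ranks.get(finer, name))
        else:
            labels.append(name)
    if n_unclassified:
        logger.info("aggregate_by_level: %d features lacked a %s annotation", n_unclassified, level)
    grouped = table.values.groupby(pd.Index(labels, name=level), sort=True).sum()
    annotation = {str(lbl): str(lbl) for lbl in grouped.index}
    return FeatureTable(grouped, annotation, table.sample_metadata)


# -- network export --------------------------------------------------------

def _sign_str(weight: float) -> str:
    return "+" if weight >= 0 else "-"


def export_network(net: nx.Graph, path, fmt: str = "graphml") -> None:
    """Write a network as GraphML or edge-list TSV.

    GraphML carries every node attribute (``kind``, ``module``,
    annotations) and edge attribute (``weight``, ``sign``, and, for
    ensemble edges, ``support`` and ``combined_p``). The TSV edge list has
    columns source, target, weight, sign, support, combined_p (the last
    two blank when absent).
    """
    if fmt == "graphml":
        g = net.copy()
        for _, _, d in g.edges(data=True):
            d.setdefault("sign", _sign_str(d.get("weight", 0.0)))
        nx.write_graphml(g, path)
    elif fmt in ("tsv", "edgelist"):
        rows = []
        for u, v, d in net.edges(data=True):
            w = d.get("weight", 1.0)
            rows.append(
                {
                    "source": u,
                    "target": v,
                    "weight": w,
                    "sign": d.get("sign", _sign_str(w)),
                    "support": d.get("support", ""),
                    "combined_p": d.get("combined_p", ""),
                }
            )
        pd.DataFrame(rows, columns=["source", "target", "weight", "sign", "support", "combined_p"]).to_csv(
            path, sep="\t", index=False
        )
    else:
        raise ValueError(f"unknown network format {fmt!r}")


def import_network(path) -> nx.Graph:
    """Read a GraphML file back into a Graph (inverse of GraphML export)."""
    return nx.read_graphml(path)
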