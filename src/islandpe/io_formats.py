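"""Readers, writers and core containers.

The pipeline consumes three kinds of input: a rooted, dated phylogeny in
Newick format whose tips are genus names (branch lengths in millions of
years), delimited occurrence tables (genus, island, coordinates), and small
per-genus annotation tables (continental occurrence, native bounding box,
regional native status).  This module parses those formats and builds the
two in-memory objects everything downstream works with: :class:`DatedTree`
and :class:`IncidenceMatrix`.

Newick parsing is delegated to :mod:`dendropy`; this module only adds
validation (unique non-empty tips, branch lengths present and non-negative)
and a flat array view of the tree that the metric code consumes.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .endemism import EndemismScores
    from .null_model import TailFrequencies

logger = logging.getLogger("islandpe.io")

__all__ = [
    "NewickParseError",
    "ValidationError",
    "ConfigurationError",
    "DatedTree",
    "OccurrenceRecord",
    "OccurrenceReadResult",
    "IncidenceMatrix",
    "BoundingBox",
    "GenusAnnotations",
    "read_newick",
    "read_occurrences",
    "read_island_table",
    "build_incidence",
    "write_results",
    "read_results",
    "write_run_metadata",
]


class NewickParseError(ValueError):
    """Raised when a Newick file cannot be parsed."""


class ValidationError(ValueError):
    """Raised when parsed input violates a structural invariant."""


class ConfigurationError(ValueError):
    """Raised for bad dialects, missing columns or inconsistent options."""


def normalize_longitude(lon: float) -> float:
    """Map a longitude onto [-180, 180] (180 maps to 180, not -180)."""
    out = (float(lon) + 180.0) % 360.0 - 180.0
    if out == -180.0 and lon > 0:
        return 180.0
    return out


# ---------------------------------------------------------------------------
# DatedTree
# ---------------------------------------------------------------------------


@dataclass
class DatedTree:
    """Rooted dated phylogeny with a flat array view of its branches.

    Branches are the edges above every non-root node, indexed in postorder.
    ``desc[b, t]`` is True when tip ``t`` descends from (or is) the node
    under branch ``b``; ``parent[b]`` is the branch above it, or -1 for
    children of the root.  A root edge in the source Newick is ignored: it
    would lie on every tip-to-root path and only shift all scores by a
    constant.
    """

    tip_labels: list[str]
    branch_lengths: np.ndarray  # (n_branches,) float, My
    parent: np.ndarray  # (n_branches,) int, -1 for root children
    desc: np.ndarray  # (n_branches, n_tips) bool
    tip_branch: np.ndarray  # (n_tips,) terminal branch index per tip
    _dendropy: dendropy.Tree | None = field(default=None, repr=False, compare=False)

    # -- construction -------------------------------------------------------

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "DatedTree":
        root = tree.seed_node
        nodes = [nd for nd in tree.postorder_node_iter() if nd is not root]
        if not nodes:
            raise ValidationError("tree has no branches (bare root)")
        index = {id(nd): i for i, nd in enumerate(nodes)}

        labels: list[str] = []
        tip_nodes = [nd for nd in nodes if nd.is_leaf()]
        for nd in tip_nodes:
            name = nd.taxon.label if nd.taxon is not None else None
            if not name or not str(name).strip():
                raise ValidationError("tip with empty label")
            labels.append(str(name).strip())
        if len(set(labels)) != len(labels):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise ValidationError(f"duplicate tip labels: {dupes}")

        n_br, n_tips = len(nodes), len(tip_nodes)
        tip_col = {id(nd): j for j, nd in enumerate(tip_nodes)}
        lengths = np.zeros(n_br, dtype=float)
        parent = np.full(n_br, -1, dtype=np.int64)
        desc = np.zeros((n_br, n_tips), dtype=bool)
        tip_branch = np.zeros(n_tips, dtype=np.int64)

        for i, nd in enumerate(nodes):  # postorder: children before parents
            bl = nd.edge.length
            if bl is None:
                raise ValidationError(
                    f"missing branch length on node {nd.taxon.label if nd.taxon else '<internal>'}"
                )
            if bl < 0:
                raise ValidationError(
                    f"negative branch length {bl} on node "
                    f"{nd.taxon.label if nd.taxon else '<internal>'}"
                )
            lengths[i] = float(bl)
            if nd.parent_node is not None and nd.parent_node is not root:
                parent[i] = index[id(nd.parent_node)]
            if nd.is_leaf():
                j = tip_col[id(nd)]
                desc[i, j] = True
                tip_branch[j] = i
            else:
                for ch in nd.child_nodes():
                    desc[i] |= desc[index[id(ch)]]

        return cls(labels, lengths, parent, desc, tip_branch, _dendropy=tree)

    @classmethod
    def from_newick_string(cls, newick: str) -> "DatedTree":
        try:
            tree = dendropy.Tree.get(
                data=newick, schema="newick", suppress_internal_node_taxa=True
            )
        except Exception as exc:  # dendropy raises several error types
            raise NewickParseError(f"malformed Newick: {exc}") from exc
        return cls.from_dendropy(tree)

    # -- properties ---------------------------------------------------------

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def n_branches(self) -> int:
        return len(self.branch_lengths)

    @property
    def total_length(self) -> float:
        return float(self.branch_lengths.sum())

    @property
    def mean_branch_length(self) -> float:
        """Arithmetic mean over all non-root branches (the PEalt uniform length)."""
        return float(self.branch_lengths.mean())

    @property
    def tip_index(self) -> dict[str, int]:
        return {lab: j for j, lab in enumerate(self.tip_labels)}

    def path_to_root(self, tip_label: str) -> list[int]:
        """Branch indices on the path from a tip to the root (tip edge first)."""
        b = int(self.tip_branch[self.tip_index[tip_label]])
        path = [b]
        while self.parent[b] != -1:
            b = int(self.parent[b])
            path.append(b)
        return path

    def to_newick(self) -> str:
        if self._dendropy is None:
            raise ValidationError("tree was not built from a dendropy source")
        return self._dendropy.as_string(schema="newick", suppress_rooting=True).strip()


def read_newick(path: str | Path) -> DatedTree:
    """Read a rooted dated phylogeny from a Newick file.

    Raises :class:`NewickParseError` for syntax errors and
    :class:`ValidationError` when a non-root edge has no branch length.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    tree = DatedTree.from_newick_string(path.read_text())
    logger.info("read tree with %d tips, %d branches from %s", tree.n_tips, tree.n_branches, path)
    return tree


# ---------------------------------------------------------------------------
# Occurrences
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OccurrenceRecord:
    genus: str
    island_id: str
    latitude: float
    longitude: float
    native_flag: str | None = None  # "native" | "non_native" | None (unknown)


@dataclass
class OccurrenceReadResult:
    """Parsed occurrence records plus a count of rejected rows."""

    records: list[OccurrenceRecord]
    n_rejected: int = 0

    def __iter__(self):
        return iter(self.records)

    def __len__(self):
        return len(self.records)


DEFAULT_DIALECT = {
    "delimiter": ",",
    "genus_col": "genus",
    "island_col": "island_id",
    "lat_col": "latitude",
    "lon_col": "longitude",
    "native_col": None,
}


def read_occurrences(path: str | Path, dialect: Mapping | None = None) -> OccurrenceReadResult:
    """Read an occurrence table (one row per record).

    Rows with unparseable or out-of-bounds coordinates are dropped and
    counted in ``n_rejected``; longitudes are normalized to [-180, 180].
    """
    d = dict(DEFAULT_DIALECT)
    if dialect:
        d.update(dialect)
    df = pd.read_csv(path, sep=d["delimiter"], dtype=str)
    needed = [d["genus_col"], d["island_col"], d["lat_col"], d["lon_col"]]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ConfigurationError(f"missing mandatory column(s): {missing}")

    records: list[OccurrenceRecord] = []
    n_rejected = 0
    native_col = d.get("native_col")
    for row in df.itertuples(index=False):
        row = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        genus = str(row[d["genus_col"]]).strip()
        island = str(row[d["island_col"]]).strip()
        try:
            lat = float(row[d["lat_col"]])
            lon = float(row[d["lon_col"]])
        except (TypeError, ValueError):
            n_rejected += 1
            continue
        if not (np.isfinite(lat) and np.isfinite(lon)) or not (-90.0 <= lat <= 90.0):
            n_rejected += 1
            continue
        if not genus:
            n_rejected += 1
            continue
        flag = None
        if native_col is not None and native_col in df.columns:
            raw = row[native_col]
            if isinstance(raw, str) and raw.strip():
                flag = raw.strip()
        records.append(OccurrenceRecord(genus, island, lat, normalize_longitude(lon), flag))
    if not records:
        logger.warning("no valid occurrence records read from %s", path)
    if n_rejected:
        logger.info("rejected %d occurrence rows with bad coordinates", n_rejected)
    return OccurrenceReadResult(records, n_rejected)


def read_island_table(path: str | Path, delimiter: str = ",") -> pd.DataFrame:
    """Read island metadata (island_id, latitude, longitude, area, ...)."""
    df = pd.read_csv(path, sep=delimiter)
    if "island_id" not in df.columns:
        raise ConfigurationError("island table must have an 'island_id' column")
    df["island_id"] = df["island_id"].astype(str).str.strip()
    return df.set_index("island_id", drop=False)


# ---------------------------------------------------------------------------
# Incidence matrix
# ---------------------------------------------------------------------------


@dataclass
class IncidenceMatrix:
    """Binary islands x genera presence matrix with fixed identifier order.

    Rows and columns are sorted by identifier, so construction is invariant
    to input record order.  Row sums are genera per island; column sums are
    islands per genus — the marginals the fixed-fixed null model preserves.
    """

    island_ids: list[str]
    genus_names: list[str]
    matrix: np.ndarray  # (n_islands, n_genera) int8 in {0,1}
    unmatched_genera: tuple[str, ...] = ()

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.int8)
        if self.matrix.shape != (len(self.island_ids), len(self.genus_names)):
            raise ValidationError("incidence shape does not match identifier lists")
        if not np.isin(self.matrix, (0, 1)).all():
            raise ValidationError("incidence entries must be 0/1")

    @property
    def n_islands(self) -> int:
        return len(self.island_ids)

    @property
    def n_genera(self) -> int:
        return len(self.genus_names)

    @property
    def row_sums(self) -> np.ndarray:
        return self.matrix.sum(axis=1)

    @property
    def col_sums(self) -> np.ndarray:
        return self.matrix.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.island_ids, columns=self.genus_names)

    def island_index(self) -> dict[str, int]:
        return {i: k for k, i in enumerate(self.island_ids)}

    def subset_islands(self, keep: Sequence[str]) -> "IncidenceMatrix":
        keep_set = set(keep)
        rows = [k for k, i in enumerate(self.island_ids) if i in keep_set]
        return IncidenceMatrix(
            [self.island_ids[k] for k in rows],
            list(self.genus_names),
            self.matrix[rows, :],
            self.unmatched_genera,
        )


def build_incidence(
    records: Iterable[OccurrenceRecord],
    tree: DatedTree,
    min_genera: int = 1,
) -> IncidenceMatrix:
    """Collapse occurrence records into a binary islands x genera matrix.

    Genus names are matched to tree tips exactly (after whitespace trimming);
    unmatched names are reported on the result, never guessed.  Islands with
    fewer than ``min_genera`` matched genera are dropped.  Duplicate
    (genus, island) records collapse to a single presence.
    """
    tips = set(tree.tip_labels)
    pairs: set[tuple[str, str]] = set()
    unmatched: set[str] = set()
    for rec in records:
        g, isl = rec.genus.strip(), rec.island_id.strip()
        if g in tips:
            pairs.add((isl, g))
        else:
            unmatched.add(g)
    if not pairs:
        raise ValidationError("no occurrence record matched a tree tip")
    if unmatched:
        logger.info("%d genus name(s) not on the tree: %s", len(unmatched), sorted(unmatched)[:10])

    islands = sorted({isl for isl, _ in pairs})
    genera = sorted({g for _, g in pairs})
    gi = {g: j for j, g in enumerate(genera)}
    ii = {isl: k for k, isl in enumerate(islands)}
    mat = np.zeros((len(islands), len(genera)), dtype=np.int8)
    for isl, g in pairs:
        mat[ii[isl], gi[g]] = 1

    keep = mat.sum(axis=1) >= min_genera
    mat = mat[keep, :]
    islands = [isl for isl, k in zip(islands, keep) if k]
    # drop genera that end up on zero retained islands
    keep_g = mat.sum(axis=0) >= 1
    mat = mat[:, keep_g]
    genera = [g for g, k in zip(genera, keep_g) if k]
    return IncidenceMatrix(islands, genera, mat, tuple(sorted(unmatched)))


# ---------------------------------------------------------------------------
# Genus annotations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BoundingBox:
    """Native-range box; lon_min > lon_max means the box crosses the antimeridian."""

    lat_min: float
    lat_max: float
    lon_min: float
    lon_max: float

    def __post_init__(self):
        if self.lat_min > self.lat_max:
            raise ValidationError(f"bounding box lat_min {self.lat_min} > lat_max {self.lat_max}")

    @property
    def wraps(self) -> bool:
        return self.lon_min > self.lon_max

    def contains(self, lat: float, lon: float) -> bool:
        """Boundary-inclusive point test; wrapped boxes are two lon segments."""
        if not (self.lat_min <= lat <= self.lat_max):
            return False
        if self.wraps:
            return lon >= self.lon_min or lon <= self.lon_max
        return self.lon_min <= lon <= self.lon_max


@dataclass
class GenusAnnotations:
    """Per-genus side tables: continental occurrence, native box, regional status."""

    continental: dict[str, bool] = field(default_factory=dict)
    bounding_box: dict[str, BoundingBox] = field(default_factory=dict)
    native_status: dict[tuple[str, str], str] = field(default_factory=dict)

    def is_continental(self, genus: str) -> bool:
        return bool(self.continental.get(genus, False))

    def continental_vector(self, genus_names: Sequence[str]) -> np.ndarray:
        return np.array([self.is_continental(g) for g in genus_names], dtype=bool)

    @classmethod
    def from_frames(
        cls,
        continental: pd.DataFrame | None = None,
        boxes: pd.DataFrame | None = None,
        status: pd.DataFrame | None = None,
    ) -> "GenusAnnotations":
        ann = cls()
        if continental is not None:
            for row in continental.itertuples(index=False):
                ann.continental[str(row.genus).strip()] = bool(int(row.continental))
        if boxes is not None:
            for row in boxes.itertuples(index=False):
                ann.bounding_box[str(row.genus).strip()] = BoundingBox(
                    float(row.lat_min), float(row.lat_max),
                    float(row.lon_min), float(row.lon_max),
                )
        if status is not None:
            for row in status.itertuples(index=False):
                ann.native_status[(str(row.genus).strip(), str(row.region).strip())] = str(
                    row.status
                ).strip()
        return ann


# ---------------------------------------------------------------------------
# Results tables
# ---------------------------------------------------------------------------

RESULT_COLUMNS = [
    "island_id",
    "variant",
    "PE",
    "PEalt",
    "RPE",
    "freq_PE",
    "freq_PEalt_high",
    "freq_RPE_high",
    "freq_RPE_low",
    "category",
]


def _fmt(x: float) -> str:
    return format(float(x), ".12g")


def write_results(
    scores: "EndemismScores",
    frequencies: "TailFrequencies",
    categories: Mapping[str, str],
    path: str | Path,
) -> pd.DataFrame:
    """Write the per-island results table (TSV, sorted by island id).

    All three inputs must cover exactly the same islands; misaligned ids are
    a fatal error listing the offenders.  Floats are serialized with 12
    significant digits, which round-trips through :func:`read_results`.
    """
    ids_s = set(scores.island_ids)
    ids_f = set(frequencies.island_ids)
    ids_c = set(categories)
    if not (ids_s == ids_f == ids_c):
        bad = sorted((ids_s | ids_f | ids_c) - (ids_s & ids_f & ids_c))
        raise ValidationError(f"island ids misaligned across inputs: {bad}")

    srow = {i: k for k, i in enumerate(scores.island_ids)}
    frow = {i: k for k, i in enumerate(frequencies.island_ids)}
    rows = []
    for isl in sorted(ids_s):
        a, b = srow[isl], frow[isl]
        rows.append(
            [
                isl,
                scores.variant,
                _fmt(scores.pe[a]),
                _fmt(scores.pe_alt[a]),
                _fmt(scores.rpe[a]),
                _fmt(frequencies.freq_higher["PE"][b]),
                _fmt(frequencies.freq_higher["PEalt"][b]),
                _fmt(frequencies.freq_higher["RPE"][b]),
                _fmt(frequencies.freq_lower["RPE"][b]),
                categories[isl],
            ]
        )
    if not rows:
        logger.warning("writing header-only results table to %s", path)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(RESULT_COLUMNS)
        w.writerows(rows)
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def read_results(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"island_id": str})
    return df


def write_run_metadata(path: str | Path, **fields) -> None:
    """JSON sidecar with the seed, parameters and record counts of a run."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(fields, indent=2, sort_keys=True, default=str) + "\n")
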