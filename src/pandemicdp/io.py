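"""File formats: long-format count tables, location CSVs, edge lists.

Conventions
-----------
* Count tables: long-format CSV with a header, one column per factor
  (string levels) and a final nonnegative-integer ``count`` column.
* Locations: CSV with columns ``person_id,x,y``, one row per recorded
  location.  Coordinates must already be planar (pre-projected); no
  CRS handling happens here.
* Graphs: two-column edge list TSV, one edge per row, optional header.
  Non-integer node labels are mapped to 0-based ids in order of first
  appearance; the mapping is persisted in the JSON sidecar on write.

Every writer emits a ``*.meta.json`` sidecar recording epsilon, m,
seed, software version, and the budget ledger, so a run can be
reproduced bit-for-bit from its outputs.
"""

from __future__ import annotations

import csv
import importlib.resources
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .ctn import Graph
from .geo import HeatMap, IndividualTrack
from .surveillance import CellTable, SanitizedTableSet

__all__ = [
    "read_cell_table",
    "write_cell_table",
    "write_sanitized_tables",
    "load_cdc_death_counts",
    "read_locations",
    "write_locations",
    "read_graph",
    "write_graph",
    "write_heatmap",
    "write_sidecar",
]


def _version() -> str:
    from . import __version__

    return __version__


def write_sidecar(path, metadata: dict) -> Path:
    """Write the JSON sidecar next to an output file."""
    side = Path(str(path) + ".meta.json")
    payload = {"software": "pandemicdp", "version": _version(), **metadata}
    side.write_text(json.dumps(payload, indent=2, default=_jsonable))
    return side


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


# ---------------------------------------------------------------------------
# count tables
# ---------------------------------------------------------------------------


def read_cell_table(path, count_col: str = "count") -> CellTable:
    """Read a long-format contingency table CSV.

    Factor columns are every column except ``count_col``, in file
    order; levels are ordered by first appearance.  Duplicate factor
    combinations are an error; combinations absent from the file are
    filled with zero (with a warning).
    """
    df = pd.read_csv(path, dtype=str)
    if count_col not in df.columns:
        raise ValueError(
            f"{path}: missing required column {count_col!r} "
            "(is the header present?)"
        )
    factor_cols = [c for c in df.columns if c != count_col]
    if not factor_cols:
        raise ValueError(f"{path}: need at least one factor column")

    counts_raw = pd.to_numeric(df[count_col], errors="coerce")
    for i, v in enumerate(counts_raw):
        if pd.isna(v) or v < 0 or float(v) != int(v):
            raise ValueError(
                f"{path}: row {i + 2}: count must be a nonnegative integer, "
                f"got {df[count_col].iloc[i]!r}"
            )

    factors = tuple(
        (c, tuple(pd.unique(df[c]).tolist())) for c in factor_cols
    )
    shape = tuple(len(lv) for _, lv in factors)
    level_index = [
        {lev: i for i, lev in enumerate(levels)} for _, levels in factors
    ]
    counts = np.full(shape, np.nan)
    for i, row in df.iterrows():
        idx = tuple(level_index[j][row[c]] for j, c in enumerate(factor_cols))
        if not np.isnan(counts[idx]):
            raise ValueError(
                f"{path}: row {i + 2}: duplicate cell "
                f"{tuple(row[c] for c in factor_cols)}"
            )
        counts[idx] = float(counts_raw.iloc[i])
    if np.isnan(counts).any():
        warnings.warn(
            f"{path}: {int(np.isnan(counts).sum())} factor combinations "
            "absent; filled with zero counts"
        )
        counts = np.nan_to_num(counts)
    return CellTable(factors=factors, counts=counts.ravel())


def write_cell_table(table: CellTable, path, metadata: dict | None = None) -> Path:
    path = Path(path)
    table.to_dataframe().to_csv(path, index=False)
    if metadata is not None:
        write_sidecar(path, metadata)
    return path


def write_sanitized_tables(
    sanitized: SanitizedTableSet, outdir, seed: int | None = None
) -> list[Path]:
    """One CSV per release plus a shared JSON sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for l in range(sanitized.m):
        p = outdir / f"release_{l + 1}.csv"
        sanitized.release_table(l).to_dataframe().to_csv(p, index=False)
        paths.append(p)
    write_sidecar(
        outdir / "releases",
        {
            "epsilon_total": sanitized.budget.epsilon_total,
            "m": sanitized.budget.m,
            "postprocessing": sanitized.postprocessing,
            "seed": seed,
            "ledger": sanitized.ledger.to_dict() if sanitized.ledger else None,
        },
    )
    return paths


def load_cdc_death_counts() -> CellTable:
    """The bundled 7x7 age-by-race COVID-19 death-count table."""
    ref = importlib.resources.files("pandemicdp") / "data" / "cdc_death_counts.csv"
    with importlib.resources.as_file(ref) as p:
        return read_cell_table(p)


# ---------------------------------------------------------------------------
# locations
# ---------------------------------------------------------------------------


def read_locations(path) -> list[IndividualTrack]:
    """Read ``person_id,x,y`` rows into per-person tracks."""
    tracks: dict[str, list[tuple[float, float]]] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header[:3]] != ["person_id", "x", "y"]:
            raise ValueError(f"{path}: expected header 'person_id,x,y'")
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) < 3:
                raise ValueError(f"{path}: line {lineno}: expected 3 fields")
            try:
                x, y = float(row[1]), float(row[2])
            except ValueError:
                raise ValueError(
                    f"{path}: line {lineno}: non-numeric coordinates {row[1:3]!r}"
                )
            tracks.setdefault(row[0], []).append((x, y))
    if not tracks:
        warnings.warn(f"{path}: no location rows found")
        return []
    return [
        IndividualTrack(person_id=pid, points=np.array(pts))
        for pid, pts in tracks.items()
    ]


def write_locations(
    tracks: list[IndividualTrack], path, metadata: dict | None = None
) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["person_id", "x", "y"])
        for t in tracks:
            for x, y in t.points:
                writer.writerow([t.person_id, repr(float(x)), repr(float(y))])
    if metadata is not None:
        write_sidecar(path, metadata)
    return path


# ---------------------------------------------------------------------------
# graphs
# ---------------------------------------------------------------------------


def read_graph(path, n_nodes: int | None = None) -> Graph:
    """Read an edge-list TSV (optional header) into a Graph.

    ``n_nodes`` defaults to the sidecar's value if one exists, else to
    max node id + 1 (isolated tail nodes then need the sidecar or the
    explicit argument to be represented).
    """
    path = Path(path)
    if n_nodes is None:
        side = Path(str(path) + ".meta.json")
        if side.exists():
            n_nodes = json.loads(side.read_text()).get("n_nodes")

    edges: list[tuple[int, int]] = []
    labels: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 2:
                raise ValueError(
                    f"{path}: line {lineno}: expected two fields, got {len(parts)}"
                )
            a, b = parts
            if lineno == 1 and not (_intlike(a) and _intlike(b)):
                continue  # header row
            if _intlike(a) and _intlike(b) and not labels:
                u, v = int(a), int(b)
            else:
                u = labels.setdefault(a, len(labels))
                v = labels.setdefault(b, len(labels))
            if u == v:
                raise ValueError(f"{path}: line {lineno}: self-loop at {a!r}")
            edges.append((u, v))
    if n_nodes is None:
        n_nodes = max((max(e) for e in edges), default=-1) + 1
    if n_nodes < 1:
        raise ValueError(f"{path}: empty graph with unknown node count")
    return Graph(n_nodes=int(n_nodes), edges=frozenset(edges))


def _intlike(s: str) -> bool:
    try:
        int(s)
        return True
    except ValueError:
        return False


def write_graph(graph: Graph, path, metadata: dict | None = None) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("node_a\tnode_b\n")
        for u, v in sorted(graph.edges):
            fh.write(f"{u}\t{v}\n")
    write_sidecar(path, {"n_nodes": graph.n_nodes, **(metadata or {})})
    return path


# ---------------------------------------------------------------------------
# rasters
# ---------------------------------------------------------------------------


def write_heatmap(hm: HeatMap, path, metadata: dict | None = None) -> Path:
    """Raster as a plain CSV matrix (rows = x index) plus metadata."""
    path = Path(path)
    np.savetxt(path, hm.raster, delimiter=",")
    write_sidecar(
        path,
        {
            "bandwidth": hm.bandwidth,
            "grid": list(hm.raster.shape),
            "region": [hm.region.x_min, hm.region.x_max,
                       hm.region.y_min, hm.region.y_max],
            **(metadata or {}),
        },
    )
    return path
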