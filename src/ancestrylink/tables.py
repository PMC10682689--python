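"""Tree-sequence table data model: node, edge and population tables.

The package works on the minimal succinct-tree-sequence ingredients: a node
table (one row per contemporary or ancestral haplotype, with a time in
generations before present and an optional population label) and an edge
table whose rows ``(left, right, parent, child)`` state that ``child``
inherited the half-open genomic interval ``[left, right)`` from ``parent``.
Coordinates are 0-based, half-open and real-valued; the simulator emits
integer-valued positions so BED export is lossless.

Tables are stored column-wise as :class:`pandas.DataFrame` objects inside an
immutable :class:`TableBundle`.  A text dialect compatible with tskit text
dumps (tab-separated, header row) is the on-disk interchange format.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError

logger = logging.getLogger(__name__)

#: Column order of the node table.
NODE_COLUMNS = ("time", "population", "is_sample", "is_census")
#: Column order of the edge table.
EDGE_COLUMNS = ("left", "right", "parent", "child")

_NODE_DTYPES = {"time": np.float64, "population": np.int64,
                "is_sample": np.int64, "is_census": np.int64}
_EDGE_DTYPES = {"left": np.float64, "right": np.float64,
                "parent": np.int64, "child": np.int64}


def _empty_nodes() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=_NODE_DTYPES[c]) for c in NODE_COLUMNS})


def _empty_edges() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=_EDGE_DTYPES[c]) for c in EDGE_COLUMNS})


def _normalize_nodes(nodes: pd.DataFrame) -> pd.DataFrame:
    if len(nodes) == 0:
        return _empty_nodes()
    out = nodes.reset_index(drop=True)[list(NODE_COLUMNS)].astype(_NODE_DTYPES)
    return out


def _normalize_edges(edges: pd.DataFrame) -> pd.DataFrame:
    if len(edges) == 0:
        return _empty_edges()
    return edges.reset_index(drop=True)[list(EDGE_COLUMNS)].astype(_EDGE_DTYPES)


def _normalize_populations(populations: pd.DataFrame) -> pd.DataFrame:
    if len(populations) == 0:
        return pd.DataFrame({"name": pd.Series(dtype=object)})
    out = populations.reset_index(drop=True)[["name"]].copy()
    out["name"] = out["name"].astype(str)
    return out


@dataclass(frozen=True)
class TableBundle:
    """A tree sequence: sequence length plus node/edge/population tables.

    Node ids and population ids are the row numbers of their tables.
    Use :meth:`from_records` to build bundles from plain tuples.
    """

    sequence_length: float
    nodes: pd.DataFrame
    edges: pd.DataFrame
    populations: pd.DataFrame

    @staticmethod
    def from_records(
        sequence_length: float,
        nodes: Iterable[Sequence] = (),
        edges: Iterable[Sequence] = (),
        populations: Iterable[str] = (),
    ) -> "TableBundle":
        """Build a bundle from plain records.

        ``nodes`` rows are ``(time[, population=-1[, is_sample=0[, is_census=0]]])``;
        ``edges`` rows are ``(left, right, parent, child)``; ``populations``
        is a sequence of name strings (ids are positional).
        """
        node_rows = []
        for rec in nodes:
            rec = tuple(rec)
            time = rec[0]
            population = rec[1] if len(rec) > 1 else -1
            is_sample = rec[2] if len(rec) > 2 else 0
            is_census = rec[3] if len(rec) > 3 else 0
            node_rows.append((float(time), int(population), int(is_sample), int(is_census)))
        edge_rows = [(float(l), float(r), int(p), int(c)) for (l, r, p, c) in edges]
        nodes_df = pd.DataFrame(node_rows, columns=list(NODE_COLUMNS)) if node_rows else _empty_nodes()
        edges_df = pd.DataFrame(edge_rows, columns=list(EDGE_COLUMNS)) if edge_rows else _empty_edges()
        pops_df = pd.DataFrame({"name": [str(n) for n in populations]})
        return TableBundle(
            sequence_length=float(sequence_length),
            nodes=_normalize_nodes(nodes_df),
            edges=_normalize_edges(edges_df),
            populations=_normalize_populations(pops_df),
        )

    @property
    def num_nodes(self) -> int:
        return len(self.nodes)

    @property
    def num_edges(self) -> int:
        return len(self.edges)

    def equals(self, other: "TableBundle") -> bool:
        """Exact field equality (used by the I/O round-trip guarantee)."""
        return (
            self.sequence_length == other.sequence_length
            and self.nodes.equals(other.nodes)
            and self.edges.equals(other.edges)
            and self.populations.equals(other.populations)
        )


def _fmt_pos(x: float) -> str:
    return format(x, "g")


def canonical_edge_order(tables: TableBundle) -> np.ndarray:
    """Permutation putting edges in (parent time, parent, child, left) order."""
    edges = tables.edges
    if len(edges) == 0:
        return np.empty(0, dtype=np.intp)
    ptime = tables.nodes["time"].to_numpy()[edges["parent"].to_numpy()]
    # lexsort: last key is primary; stable, hence deterministic
    return np.lexsort((
        edges["left"].to_numpy(),
        edges["child"].to_numpy(),
        edges["parent"].to_numpy(),
        ptime,
    ))


def edges_canonically_sorted(tables: TableBundle) -> bool:
    order = canonical_edge_order(tables)
    return bool(np.all(order == np.arange(len(order))))


def sort_edges(tables: TableBundle) -> TableBundle:
    """Return a bundle with edges in canonical order.

    The canonical key is ascending ``(time(parent), parent id, child id,
    left)``, mirroring the standard tree-sequence sortedness requirement.
    The sort is stable (hence idempotent) and only permutes rows.
    """
    order = canonical_edge_order(tables)
    edges = tables.edges.iloc[order].reset_index(drop=True)
    return TableBundle(tables.sequence_length, tables.nodes, edges, tables.populations)


def validate_tables(tables: TableBundle) -> list[str]:
    """Check every structural invariant; return a list of violation messages.

    An empty list means the bundle is valid.  The input is never mutated and
    violations are reported, not raised, so a caller can display all of them
    at once.
    """
    report: list[str] = []
    L = tables.sequence_length
    nodes, edges, pops = tables.nodes, tables.edges, tables.populations
    n_nodes, n_pops = len(nodes), len(pops)

    if not (np.isfinite(L) and L > 0):
        report.append(f"sequence length must be positive and finite, got {L}")
        return report

    if n_pops and pops["name"].duplicated().any():
        dups = sorted(pops["name"][pops["name"].duplicated()].unique())
        report.append(f"duplicate population names: {dups}")

    times = nodes["time"].to_numpy()
    bad_time = np.flatnonzero(~(np.isfinite(times) & (times >= 0)))
    for i in bad_time:
        report.append(f"node {i}: time must be finite and >= 0, got {times[i]}")
    node_pop = nodes["population"].to_numpy()
    bad_pop = np.flatnonzero((node_pop != -1) & ((node_pop < 0) | (node_pop >= n_pops)))
    for i in bad_pop:
        report.append(f"node {i}: population {node_pop[i]} not in population table")

    left = edges["left"].to_numpy()
    right = edges["right"].to_numpy()
    parent = edges["parent"].to_numpy()
    child = edges["child"].to_numpy()

    for i in np.flatnonzero(~(left < right)):
        report.append(f"edge {i}: left {_fmt_pos(left[i])} must be < right {_fmt_pos(right[i])}")
    for i in np.flatnonzero((left < 0) | (right > L)):
        report.append(f"edge {i}: interval [{_fmt_pos(left[i])}, {_fmt_pos(right[i])}) outside [0, {_fmt_pos(L)}]")
    bad_id = np.flatnonzero(
        (parent < 0) | (parent >= n_nodes) | (child < 0) | (child >= n_nodes)
    )
    for i in bad_id:
        report.append(f"edge {i}: parent/child id out of range")
    ok_ids = np.setdiff1d(np.arange(len(edges)), bad_id, assume_unique=False)
    for i in ok_ids[parent[ok_ids] == child[ok_ids]]:
        report.append(f"edge {i}: parent equals child ({parent[i]})")
    ok = ok_ids[parent[ok_ids] != child[ok_ids]]
    older = ok[~(times[child[ok]] < times[parent[ok]])]
    for i in older:
        report.append(
            f"edge {i}: child time {_fmt_pos(times[child[i]])} >= parent time "
            f"{_fmt_pos(times[parent[i]])} (child {child[i]}, parent {parent[i]})"
        )

    # per-child parental intervals must be pairwise non-overlapping
    if len(ok):
        df = pd.DataFrame({"left": left[ok], "right": right[ok], "child": child[ok]})
        for c, grp in df.groupby("child", sort=True):
            grp = grp.sort_values(["left", "right"])
            gl = grp["left"].to_numpy()
            gr = grp["right"].to_numpy()
            for j in range(1, len(grp)):
                if gl[j] < gr[j - 1]:
                    lo, hi = gl[j], min(gr[j - 1], gr[j])
                    report.append(
                        f"overlapping parental intervals for child {c} on "
                        f"[{_fmt_pos(lo)},{_fmt_pos(hi)})"
                    )

    if not bad_id.size and not edges_canonically_sorted(tables):
        report.append("edges not in canonical (parent time, parent, child, left) order")

    return report


# ---------------------------------------------------------------------------
# Text I/O (tskit text-dump dialect: tab-separated, header row)
# ---------------------------------------------------------------------------

_SEQLEN_KEY = "#sequence_length="


def _read_tsv(path) -> tuple[list[str], list[tuple[int, list[str]]], dict]:
    """Return (header, [(lineno, fields), ...], metadata) for one table file."""
    meta: dict = {}
    header: list[str] | None = None
    rows: list[tuple[int, list[str]]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            if line.startswith("#"):
                if line.startswith(_SEQLEN_KEY):
                    try:
                        meta["sequence_length"] = float(line[len(_SEQLEN_KEY):])
                    except ValueError:
                        raise FormatError(
                            f"{path}: bad sequence_length metadata at line {lineno}: {line!r}"
                        ) from None
                continue
            fields = line.split("\t")
            if header is None:
                header = [f.strip() for f in fields]
            else:
                rows.append((lineno, fields))
    if header is None:
        header = []
    return header, rows, meta


def _parse_columns(path, header, rows, spec: dict[str, tuple[type, object]]) -> dict[str, np.ndarray]:
    """``spec`` maps column name -> (converter, default); default None = required."""
    for name, (_, default) in spec.items():
        if default is None and name not in header:
            raise FormatError(f"{path}: missing required column '{name}'")
    idx = {name: header.index(name) for name in spec if name in header}
    out: dict[str, list] = {name: [] for name in spec}
    for lineno, fields in rows:
        if len(fields) < len(header):
            raise FormatError(f"{path}: line {lineno} has {len(fields)} fields, expected {len(header)}")
        for name, (conv, default) in spec.items():
            if name in idx:
                cell = fields[idx[name]]
                try:
                    out[name].append(conv(cell))
                except ValueError:
                    raise FormatError(
                        f"{path}: non-numeric value {cell!r} in column '{name}' at line {lineno}"
                    ) from None
            else:
                out[name].append(default)
    return {k: np.asarray(v) for k, v in out.items()}


def _as_int(cell: str) -> int:
    return int(float(cell)) if "." in cell or "e" in cell or "E" in cell else int(cell)


def read_text_tables(
    node_path,
    edge_path,
    population_path=None,
    sequence_length: float | None = None,
) -> TableBundle:
    """Read a bundle from tab-separated text tables.

    Node files need columns ``id``, ``is_sample``, ``time`` (``population``
    and ``is_census`` are optional and default to -1 / 0); edge files need
    ``left``, ``right``, ``parent``, ``child``.  Extra columns are ignored,
    so tskit text dumps read directly.  The sequence length comes from the
    ``sequence_length`` argument or a ``#sequence_length=<L>`` metadata line
    in the edges file; one of the two is required.  ``edge_path=None`` loads
    a node table alone (empty edge table; explicit length then required).
    """
    if edge_path is None and sequence_length is None:
        raise FormatError("sequence_length is required when no edge file is given")
    nh, nrows, _ = _read_tsv(node_path)
    ncols = _parse_columns(node_path, nh, nrows, {
        "id": (_as_int, None),
        "is_sample": (_as_int, None),
        "time": (float, None),
        "population": (_as_int, -1),
        "is_census": (_as_int, 0),
    })
    ids = ncols["id"]
    if len(ids) and not np.array_equal(ids, np.arange(len(ids))):
        raise FormatError(f"{node_path}: node ids must be consecutive 0..n-1 in file order")

    if edge_path is not None:
        eh, erows, emeta = _read_tsv(edge_path)
        ecols = _parse_columns(edge_path, eh, erows, {
            "left": (float, None),
            "right": (float, None),
            "parent": (_as_int, None),
            "child": (_as_int, None),
        })
    else:
        erows, emeta = [], {}
        ecols = {c: np.empty(0) for c in EDGE_COLUMNS}

    if sequence_length is None:
        sequence_length = emeta.get("sequence_length")
    if sequence_length is None:
        raise FormatError(
            f"{edge_path}: no sequence length (pass one explicitly or add a "
            f"'#sequence_length=<L>' line)"
        )

    pop_names: list[str] = []
    if population_path is not None:
        ph, prows, _ = _read_tsv(population_path)
        if prows or ph:
            for name in ("id", "name"):
                if name not in ph:
                    raise FormatError(f"{population_path}: missing required column '{name}'")
            iid, iname = ph.index("id"), ph.index("name")
            for lineno, fields in prows:
                try:
                    pid = _as_int(fields[iid])
                except ValueError:
                    raise FormatError(
                        f"{population_path}: non-numeric value {fields[iid]!r} in column 'id' "
                        f"at line {lineno}"
                    ) from None
                if pid != len(pop_names):
                    raise FormatError(f"{population_path}: population ids must be consecutive 0..K-1")
                pop_names.append(fields[iname])

    nodes = pd.DataFrame({
        "time": ncols["time"].astype(np.float64),
        "population": ncols["population"].astype(np.int64),
        "is_sample": ncols["is_sample"].astype(np.int64),
        "is_census": ncols["is_census"].astype(np.int64),
    }) if len(nrows) else _empty_nodes()
    edges = pd.DataFrame({
        "left": ecols["left"].astype(np.float64),
        "right": ecols["right"].astype(np.float64),
        "parent": ecols["parent"].astype(np.int64),
        "child": ecols["child"].astype(np.int64),
    }) if len(erows) else _empty_edges()

    return TableBundle(
        sequence_length=float(sequence_length),
        nodes=_normalize_nodes(nodes),
        edges=_normalize_edges(edges),
        populations=_normalize_populations(pd.DataFrame({"name": pop_names})),
    )


def write_text_tables(tables: TableBundle, node_path, edge_path, population_path=None) -> None:
    """Write a bundle as tab-separated text; exact round-trip guaranteed.

    Real positions and times are printed with ``repr`` (shortest exact float
    representation) so ``read_text_tables(write_text_tables(x)) == x``.
    """
    with open(node_path, "w", encoding="utf-8") as fh:
        fh.write("id\tis_sample\ttime\tpopulation\tis_census\n")
        for i, row in enumerate(tables.nodes.itertuples(index=False)):
            fh.write(f"{i}\t{row.is_sample}\t{row.time!r}\t{row.population}\t{row.is_census}\n")
    with open(edge_path, "w", encoding="utf-8") as fh:
        fh.write(f"{_SEQLEN_KEY}{tables.sequence_length!r}\n")
        fh.write("left\tright\tparent\tchild\n")
        for row in tables.edges.itertuples(index=False):
            fh.write(f"{row.left!r}\t{row.right!r}\t{row.parent}\t{row.child}\n")
    if population_path is not None:
        with open(population_path, "w", encoding="utf-8") as fh:
            fh.write("id\tname\n")
            for i, name in enumerate(tables.populations["name"]):
                fh.write(f"{i}\t{name}\n")
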