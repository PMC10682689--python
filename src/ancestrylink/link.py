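"""Single-pass extraction of sample-to-ancestor inheritance intervals.

Given a tree sequence, a set of focal samples S and a set of recorded
ancestors A (typically all haplotypes alive at a census generation),
:func:`link_ancestors` computes, for every sample, the maximal genomic
intervals it inherits from each member of A.  The semantics: a position x
of sample s is assigned to the *first* member of A met on the child-to-
parent path from s toward the root of the local tree covering x (the
most-recent-ancestor rule); positions whose path reaches a root without
meeting A are left unassigned.

The algorithm makes one pass over the edges in ascending
(parent time, parent, child, left) order.  Each sample starts owning its
whole genome as one segment; each edge ``(l, r, p, c)`` moves the parts of
c's segments lying inside ``[l, r)`` up to p.  Because edges are processed
in parent-time order, a node's incoming segments are complete before any
edge transfers them onward.  When the parent is a member of A the moved
pieces are emitted as output rows instead of being retained, so segments
never propagate past the most recent ancestor.  Edges shared by many
samples are touched once, which is what makes the pass fast compared with
climbing every local tree separately.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, IdError
from .tables import TableBundle, edges_canonically_sorted, sort_edges

logger = logging.getLogger(__name__)

#: Column order of an ancestry-link table.
LINK_COLUMNS = ("left", "right", "ancestor", "sample")

_LINK_DTYPES = {"left": np.float64, "right": np.float64,
                "ancestor": np.int64, "sample": np.int64}


def _empty_links() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=_LINK_DTYPES[c]) for c in LINK_COLUMNS})


@dataclass(frozen=True)
class AncestryTable:
    """Output of the link pass: rows (left, right, ancestor, sample).

    Each row states that ``sample`` inherited ``[left, right)`` from
    ``ancestor``.  Rows are sorted by (sample, left, ancestor); per sample
    the intervals are pairwise disjoint, and exactly-adjacent rows with the
    same (ancestor, sample) pair are always merged, so the table is minimal
    and canonical.
    """

    rows: pd.DataFrame
    sequence_length: float

    @property
    def num_rows(self) -> int:
        return len(self.rows)

    def equals(self, other: "AncestryTable") -> bool:
        return (self.sequence_length == other.sequence_length
                and self.rows.equals(other.rows))


@dataclass(frozen=True)
class CoverageReport:
    """Per-sample decomposition of [0, L) into assigned and unassigned parts."""

    sequence_length: float
    assigned_length: dict[int, float]
    unassigned: dict[int, list[tuple[float, float]]] = field(repr=False)


def check_query(tables: TableBundle, samples: Sequence[int], ancestors: Sequence[int]):
    """Validate a (samples, ancestors) query; returns them as int lists.

    Shared by the single-pass algorithm and the per-tree reference
    implementation so both enforce identical preconditions.
    """
    samples = [int(s) for s in samples]
    ancestors = [int(a) for a in ancestors]
    if not samples:
        raise IdError("samples must be non-empty")
    if not ancestors:
        raise IdError("ancestors must be non-empty")
    if len(set(samples)) != len(samples):
        raise IdError("duplicate sample ids")
    if len(set(ancestors)) != len(ancestors):
        raise IdError("duplicate ancestor ids")
    overlap = set(samples) & set(ancestors)
    if overlap:
        raise IdError(f"samples and ancestors must be disjoint; shared ids: {sorted(overlap)}")
    n = tables.num_nodes
    unknown = [i for i in samples + ancestors if not (0 <= i < n)]
    if unknown:
        raise IdError(f"unknown node ids: {sorted(set(unknown))}")
    anc_times = tables.nodes["time"].to_numpy()[ancestors]
    if len(set(anc_times.tolist())) > 1:
        logger.warning(
            "ancestors span multiple times (%s); population-based ancestry is "
            "best defined with a single census time",
            sorted(set(anc_times.tolist())),
        )
    return samples, ancestors


def _split_intervals(ivs: list[tuple[float, float]], l: float, r: float):
    """Split a sorted disjoint interval list against [l, r).

    Returns (inside, outside): the parts clipped to [l, r) and the
    remainder, both sorted and disjoint.
    """
    inside: list[tuple[float, float]] = []
    outside: list[tuple[float, float]] = []
    for a, b in ivs:
        if b <= l or a >= r:
            outside.append((a, b))
            continue
        if a < l:
            outside.append((a, l))
        lo, hi = max(a, l), min(b, r)
        inside.append((lo, hi))
        if b > r:
            outside.append((r, b))
    return inside, outside


def _merge_into(dest: list[tuple[float, float]], src: list[tuple[float, float]]):
    """Merge two sorted disjoint lists, coalescing exactly-adjacent pieces.

    The inputs never overlap each other (each genome position sits at
    exactly one node at any point of the pass), so a plain two-way merge
    with adjacency coalescing suffices.
    """
    out: list[tuple[float, float]] = []
    i = j = 0
    while i < len(dest) or j < len(src):
        if j >= len(src) or (i < len(dest) and dest[i][0] <= src[j][0]):
            nxt = dest[i]
            i += 1
        else:
            nxt = src[j]
            j += 1
        if out and out[-1][1] == nxt[0]:
            out[-1] = (out[-1][0], nxt[1])
        else:
            out.append(nxt)
    return out


def finalize_links(
    rows: Iterable[tuple[int, float, float, int]], sequence_length: float
) -> AncestryTable:
    """Canonicalize raw (sample, left, right, ancestor) pieces.

    Merges exactly-adjacent pieces with equal (sample, ancestor) and sorts
    by (sample, left, ancestor).
    """
    rows = sorted(rows)  # (sample, left, right, ancestor)
    merged: list[list] = []
    for s, l, r, a in rows:
        if merged and merged[-1][0] == s and merged[-1][3] == a and merged[-1][2] == l:
            merged[-1][2] = r
        else:
            merged.append([s, l, r, a])
    if not merged:
        return AncestryTable(_empty_links(), float(sequence_length))
    df = pd.DataFrame(merged, columns=["sample", "left", "right", "ancestor"])
    df = df.sort_values(["sample", "left", "ancestor"], kind="mergesort").reset_index(drop=True)
    df = df[list(LINK_COLUMNS)].astype(_LINK_DTYPES)
    return AncestryTable(df, float(sequence_length))


def link_ancestors(
    tables: TableBundle,
    samples: Sequence[int],
    ancestors: Sequence[int],
) -> AncestryTable:
    """Link every sample genome to its most recent ancestors in ``ancestors``.

    Parameters
    ----------
    tables
        A valid tree sequence.  Edges are sorted into canonical order
        internally (with a log message) if they are not already.
    samples
        Focal node ids; traced independently, so internal samples are
        allowed (flagged in the log if segments flow through them).
    ancestors
        Recorded ancestor node ids, e.g. all nodes of one census
        generation.  Must be disjoint from ``samples``.

    Returns
    -------
    AncestryTable
        Maximal intervals of constant (sample, ancestor) assignment.
    """
    samples, ancestors = check_query(tables, samples, ancestors)
    if not edges_canonically_sorted(tables):
        logger.info("edges not in canonical order; sorting internally")
        tables = sort_edges(tables)

    L = float(tables.sequence_length)
    anc_set = set(ancestors)
    sample_set = set(samples)

    left = tables.edges["left"].to_numpy()
    right = tables.edges["right"].to_numpy()
    parent = tables.edges["parent"].to_numpy()
    child = tables.edges["child"].to_numpy()
    n_edges = len(left)

    # last edge index at which each node appears as a child: after that
    # edge the node can transfer nothing further, so its state is pruned.
    last_as_child: dict[int, int] = {}
    for i in range(n_edges):
        last_as_child[int(child[i])] = i

    # state: node -> {sample -> sorted disjoint interval list}
    state: dict[int, dict[int, list[tuple[float, float]]]] = {
        s: {s: [(0.0, L)]} for s in samples
    }
    out_rows: list[tuple[int, float, float, int]] = []
    warned_internal = False

    for i in range(n_edges):
        c = int(child[i])
        node_state = state.get(c)
        if node_state is not None:
            p = int(parent[i])
            l, r = float(left[i]), float(right[i])
            moved: dict[int, list[tuple[float, float]]] = {}
            emptied = []
            for s, ivs in node_state.items():
                inside, outside = _split_intervals(ivs, l, r)
                if inside:
                    moved[s] = inside
                    if outside:
                        node_state[s] = outside
                    else:
                        emptied.append(s)
            for s in emptied:
                del node_state[s]
            if moved:
                if p in anc_set:
                    for s, ivs in moved.items():
                        for a, b in ivs:
                            out_rows.append((s, a, b, p))
                else:
                    if p in sample_set and not warned_internal:
                        logger.warning(
                            "sample node %d is internal (ancestral to other "
                            "samples); each sample is traced independently", p)
                        warned_internal = True
                    dest = state.setdefault(p, {})
                    for s, ivs in moved.items():
                        if s in dest:
                            dest[s] = _merge_into(dest[s], ivs)
                        else:
                            dest[s] = ivs
        if last_as_child.get(int(child[i])) == i:
            # remaining segments have reached a root: unassigned
            state.pop(int(child[i]), None)

    return finalize_links(out_rows, L)


def coverage_report(
    links: AncestryTable, samples: Sequence[int], sequence_length: float | None = None
) -> CoverageReport:
    """Exact per-sample assigned/unassigned decomposition of [0, L).

    For every sample the assigned length plus the unassigned interval
    lengths equals L exactly (interval endpoints are reused unchanged, so
    no floating-point drift is introduced).
    """
    L = float(links.sequence_length if sequence_length is None else sequence_length)
    assigned: dict[int, float] = {}
    unassigned: dict[int, list[tuple[float, float]]] = {}
    by_sample: dict[int, list[tuple[float, float]]] = {int(s): [] for s in samples}
    for row in links.rows.itertuples(index=False):
        by_sample.setdefault(int(row.sample), []).append((row.left, row.right))
    for s in (int(x) for x in samples):
        ivs = sorted(by_sample[s])
        gaps: list[tuple[float, float]] = []
        cursor = 0.0
        total = 0.0
        for a, b in ivs:
            if a > cursor:
                gaps.append((cursor, a))
            total += b - a
            cursor = b
        if cursor < L:
            gaps.append((cursor, L))
        assigned[s] = total
        unassigned[s] = gaps
    return CoverageReport(L, assigned, unassigned)


# ---------------------------------------------------------------------------
# Link-table text I/O (tab-separated, same dialect as the table files)
# ---------------------------------------------------------------------------

def write_ancestry_table(table: AncestryTable, path) -> None:
    """Write an ancestry table as TSV with a sequence-length metadata line."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"#sequence_length={table.sequence_length!r}\n")
        fh.write("left\tright\tancestor\tsample\n")
        for row in table.rows.itertuples(index=False):
            fh.write(f"{row.left!r}\t{row.right!r}\t{row.ancestor}\t{row.sample}\n")


def read_ancestry_table(path, sequence_length: float | None = None) -> AncestryTable:
    from .tables import _parse_columns, _read_tsv  # same dialect helpers

    header, rows, meta = _read_tsv(path)
    cols = _parse_columns(path, header, rows, {
        "left": (float, None),
        "right": (float, None),
        "ancestor": (int, None),
        "sample": (int, None),
    })
    if sequence_length is None:
        sequence_length = meta.get("sequence_length")
    if sequence_length is None:
        raise FormatError(f"{path}: no sequence length metadata")
    if not rows:
        return AncestryTable(_empty_links(), float(sequence_length))
    df = pd.DataFrame({c: cols[c] for c in LINK_COLUMNS}).astype(_LINK_DTYPES)
    return AncestryTable(df, float(sequence_length))
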