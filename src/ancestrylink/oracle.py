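"""Tree-by-tree reference implementation of local ancestry extraction.

This module rebuilds each local tree explicitly with the standard
insertion/removal sweep over edges and climbs from every sample to the
first recorded ancestor, interval by interval.  It is deliberately simple
and slow — O(edges x trees) — and defines the semantics the single-pass
algorithm in :mod:`ancestrylink.link` must reproduce row for row.  It is
exposed on the command line as the ``naive`` engine.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, IdError
from .link import LINK_COLUMNS, _LINK_DTYPES, AncestryTable, _empty_links, check_query
from .tables import TableBundle


@dataclass(frozen=True)
class TreeInterval:
    """A genomic interval [left, right) over which the topology is constant."""

    left: float
    right: float


def local_trees(tables: TableBundle) -> Iterator[tuple[TreeInterval, dict[int, int]]]:
    """Yield ``(interval, parent_map)`` for each local tree, left to right.

    The breakpoints are the distinct edge left/right coordinates (recomb-
    ination events); the intervals tile [0, L) exactly.  ``parent_map``
    maps child node id to parent node id for exactly the edges covering
    the interval.
    """
    L = float(tables.sequence_length)
    edges = tables.edges
    left = edges["left"].to_numpy()
    right = edges["right"].to_numpy()
    parent = edges["parent"].to_numpy()
    child = edges["child"].to_numpy()

    breakpoints = np.unique(np.concatenate([[0.0, L], left, right]))
    breakpoints = breakpoints[(breakpoints >= 0.0) & (breakpoints <= L)]

    ins = np.argsort(left, kind="stable")     # insertion order
    rem = np.argsort(right, kind="stable")    # removal order
    pa: dict[int, int] = {}
    j = k = 0
    for x, nxt in zip(breakpoints[:-1], breakpoints[1:]):
        while k < len(rem) and right[rem[k]] <= x:
            pa.pop(int(child[rem[k]]), None)
            k += 1
        while j < len(ins) and left[ins[j]] <= x:
            e = ins[j]
            if right[e] > x:  # skip edges entirely left of this interval
                pa[int(child[e])] = int(parent[e])
            j += 1
        yield TreeInterval(float(x), float(nxt)), dict(pa)


def climb_to_ancestor(
    parent_map: dict[int, int], sample: int, ancestors: Sequence[int]
) -> int | None:
    """First member of ``ancestors`` on the strict ancestor chain of ``sample``.

    Returns ``None`` if the chain reaches a root without meeting one.
    Raises :class:`DataError` on a parent-pointer cycle (impossible for
    valid tables, where parent times strictly increase along any climb).
    """
    anc = set(int(a) for a in ancestors)
    if not anc:
        raise IdError("ancestors must be non-empty")
    seen = {int(sample)}
    node = parent_map.get(int(sample))
    while node is not None:
        if node in seen:
            raise DataError(f"cycle in parent pointers at node {node}")
        if node in anc:
            return node
        seen.add(node)
        node = parent_map.get(node)
    return None


def local_ancestry_naive(
    tables: TableBundle, samples: Sequence[int], ancestors: Sequence[int]
) -> AncestryTable:
    """Local ancestry by climbing every local tree separately.

    Output rows are maximal intervals of constant (sample, ancestor)
    assignment, sorted by (sample, left, ancestor) — the definition the
    fast single-pass implementation is tested against.
    """
    samples, ancestors = check_query(tables, samples, ancestors)
    L = float(tables.sequence_length)

    # current open run per sample: (start, ancestor) or None
    open_run: dict[int, tuple[float, int] | None] = {s: None for s in samples}
    rows: list[tuple[int, float, float, int]] = []

    def flush(s: int, end: float) -> None:
        run = open_run[s]
        if run is not None:
            rows.append((s, run[0], end, run[1]))
            open_run[s] = None

    prev_right = 0.0
    for interval, pa in local_trees(tables):
        for s in samples:
            a = climb_to_ancestor(pa, s, ancestors)
            run = open_run[s]
            if run is not None and run[1] != (a if a is not None else -1):
                flush(s, interval.left)
            if a is None:
                flush(s, interval.left)
            elif open_run[s] is None:
                open_run[s] = (interval.left, a)
        prev_right = interval.right
    for s in samples:
        flush(s, prev_right)

    if not rows:
        return AncestryTable(_empty_links(), L)
    rows.sort(key=lambda t: (t[0], t[1], t[3]))
    df = pd.DataFrame(rows, columns=["sample", "left", "right", "ancestor"])
    df = df[list(LINK_COLUMNS)].astype(_LINK_DTYPES)
    return AncestryTable(df, L)
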