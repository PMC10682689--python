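"""Population-level post-processing of ancestry links.

Takes the raw (left, right, ancestor, sample) links, annotates each row
with the population of the ancestor, squashes exactly-adjacent tracts of
the same population into maximal contiguous tracts, and summarises the
result (genome-wide ancestry fractions, tract-length statistics, BED
export).  Often only the population of an ancestor matters, not its
identity, which is why the ancestor column is dropped on squashing.
"""

from __future__ import annotations

import logging
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConsistencyError, LabelError
from .link import AncestryTable
from .tables import TableBundle

logger = logging.getLogger(__name__)

POP_ANCESTRY_COLUMNS = ("sample", "left", "right", "ancestor", "population")
SQUASHED_COLUMNS = ("sample", "left", "right", "population")


def annotate_populations(links: AncestryTable, tables: TableBundle) -> pd.DataFrame:
    """Add the ancestor's population label to every link row.

    Row count and order are preserved; the only change is the extra
    ``population`` column.  Every ancestor that appears must carry a real
    population label (not -1).
    """
    rows = links.rows
    node_pop = tables.nodes["population"].to_numpy()
    if len(rows) == 0:
        return pd.DataFrame({
            "sample": pd.Series(dtype=np.int64),
            "left": pd.Series(dtype=np.float64),
            "right": pd.Series(dtype=np.float64),
            "ancestor": pd.Series(dtype=np.int64),
            "population": pd.Series(dtype=np.int64),
        })
    anc = rows["ancestor"].to_numpy()
    pops = node_pop[anc]
    bad = np.flatnonzero(pops == -1)
    if bad.size:
        raise LabelError(
            f"ancestor node {int(anc[bad[0]])} has no population label (population == -1)"
        )
    out = pd.DataFrame({
        "sample": rows["sample"].to_numpy(),
        "left": rows["left"].to_numpy(),
        "right": rows["right"].to_numpy(),
        "ancestor": anc,
        "population": pops,
    })
    return out


def squash(pop_rows: pd.DataFrame) -> pd.DataFrame:
    """Merge exactly-adjacent same-population tracts of each sample.

    Rows are sorted by (sample, left) and consecutive rows are merged when
    they belong to the same sample and population and touch exactly
    (``right`` of one equals ``left`` of the next).  Unassigned gaps are
    never bridged, so total tract length per (sample, population) is
    preserved to the digit and the operation is idempotent.  The ancestor
    column, if present, is dropped.
    """
    if len(pop_rows) == 0:
        return pd.DataFrame({
            "sample": pd.Series(dtype=np.int64),
            "left": pd.Series(dtype=np.float64),
            "right": pd.Series(dtype=np.float64),
            "population": pd.Series(dtype=np.int64),
        })
    df = pop_rows.sort_values(["sample", "left"], kind="mergesort").reset_index(drop=True)
    sample = df["sample"].to_numpy()
    left = df["left"].to_numpy(dtype=np.float64)
    right = df["right"].to_numpy(dtype=np.float64)
    pop = df["population"].to_numpy()

    same_sample = sample[1:] == sample[:-1]
    if np.any(same_sample & (left[1:] < right[:-1])):
        i = int(np.flatnonzero(same_sample & (left[1:] < right[:-1]))[0]) + 1
        raise ConsistencyError(
            f"overlapping tracts for sample {int(sample[i])} at position {left[i]}"
        )

    new_run = np.ones(len(df), dtype=bool)
    new_run[1:] = ~(same_sample & (pop[1:] == pop[:-1]) & (left[1:] == right[:-1]))
    run_id = np.cumsum(new_run) - 1
    out = pd.DataFrame({
        "sample": sample,
        "left": left,
        "right": right,
        "population": pop,
        "_run": run_id,
    })
    agg = out.groupby("_run", sort=True).agg(
        sample=("sample", "first"),
        left=("left", "first"),
        right=("right", "last"),
        population=("population", "first"),
    ).reset_index(drop=True)
    return agg[list(SQUASHED_COLUMNS)].astype({
        "sample": np.int64, "left": np.float64, "right": np.float64,
    })


def ancestry_fractions(squashed: pd.DataFrame, sequence_length: float) -> pd.DataFrame:
    """Genome-wide ancestry fraction per (sample, population).

    ``fraction`` is the summed tract length divided by the sequence
    length; per sample the fractions sum to at most 1, with equality when
    the sample genome is fully painted.
    """
    L = float(sequence_length)
    if len(squashed) == 0:
        return pd.DataFrame({
            "sample": pd.Series(dtype=np.int64),
            "population": pd.Series(dtype=np.int64),
            "assigned_length": pd.Series(dtype=np.float64),
            "fraction": pd.Series(dtype=np.float64),
        })
    df = squashed.copy()
    df["assigned_length"] = df["right"] - df["left"]
    agg = (
        df.groupby(["sample", "population"], sort=True)["assigned_length"]
        .sum()
        .reset_index()
    )
    agg["fraction"] = agg["assigned_length"] / L
    return agg


def tract_length_stats(squashed: pd.DataFrame) -> pd.DataFrame:
    """Per-population count, mean, median, min and max tract length."""
    if len(squashed) == 0:
        return pd.DataFrame({
            "population": pd.Series(dtype=np.int64),
            "count": pd.Series(dtype=np.int64),
            "mean": pd.Series(dtype=np.float64),
            "median": pd.Series(dtype=np.float64),
            "min": pd.Series(dtype=np.float64),
            "max": pd.Series(dtype=np.float64),
        })
    lengths = squashed["right"] - squashed["left"]
    df = pd.DataFrame({"population": squashed["population"], "length": lengths})
    agg = df.groupby("population", sort=True)["length"].agg(
        count="count", mean="mean", median="median", min="min", max="max"
    ).reset_index()
    agg["count"] = agg["count"].astype(np.int64)
    return agg


def write_bed(
    squashed: pd.DataFrame,
    path,
    sample_names: Mapping[int, str] | None = None,
    population_names: Sequence[str] | Mapping[int, str] | None = None,
    round_coords: bool = False,
) -> None:
    """Write squashed tracts as BED3+ rows, one "chromosome" per haplotype.

    Each sample haplotype becomes its own chrom (its name, default the
    node id); chromStart/chromEnd are the 0-based half-open tract bounds,
    which match the internal convention exactly; the name column carries
    the population label.  Non-integer coordinates are an error unless
    ``round_coords`` is set, in which case starts are floored and ends
    ceiled with a loud log message (rounding changes tract lengths).
    """
    with open(path, "w", encoding="utf-8") as fh:
        for row in squashed.itertuples(index=False):
            l, r = float(row.left), float(row.right)
            if l != int(l) or r != int(r):
                if not round_coords:
                    raise ConsistencyError(
                        f"non-integer BED coordinates [{l}, {r}) for sample "
                        f"{int(row.sample)}; pass round_coords to floor/ceil"
                    )
                logger.warning(
                    "rounding BED coordinates [%s, %s) to [%d, %d); tract "
                    "lengths change", l, r, math.floor(l), math.ceil(r))
                l, r = math.floor(l), math.ceil(r)
            chrom = (sample_names or {}).get(int(row.sample), str(int(row.sample)))
            p = int(row.population)
            if population_names is None:
                name = str(p)
            elif isinstance(population_names, Mapping):
                name = population_names.get(p, str(p))
            else:
                name = population_names[p] if 0 <= p < len(population_names) else str(p)
            fh.write(f"{chrom}\t{int(l)}\t{int(r)}\t{name}\n")
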