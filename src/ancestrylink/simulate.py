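"""Forward-time Wright-Fisher simulator with recombination and admixture.

The simulator produces complete, unsimplified tree-sequence tables for a
discrete-generation haploid Wright-Fisher model: every genome of every
generation is retained as a node, so recording a census generation is
trivially exact — the census nodes are simply all genomes alive at that
generation, and every genomic lineage of the present-day sample passes
through them.

The default scenario mirrors a classic admixture design: two source
populations exchanging small amounts of gene flow, an admixture pulse
founding a third (admixed) population, samples drawn from the admixed
population at the present, and a census recorded just before admixture.

Transmission model: each child genome draws a parent population
(by the backward migration rules, or the admixture proportions at the
pulse), then recombines the genomes of two uniformly chosen parents from
that population, laying down Poisson(rho*l) crossover breakpoints at
uniform integer positions.  With per-base per-generation crossover rate
rho and chromosome length l, each generation back adds an expected rho*l
breakpoints, so the expected number of distinct ancestral segments at
census depth t is 1 + rho*l*t — the linear scaling the package's tests
check empirically.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .errors import ParamError
from .tables import TableBundle, _normalize_edges, _normalize_nodes, _normalize_populations, sort_edges

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Admixture:
    """A single admixture pulse.

    ``generation`` is the time (generations before present) at which the
    destination population is founded: its genomes at ``generation - 1``
    draw parents from the other populations with the given proportions.
    The destination population has no genomes at or above ``generation``.
    """

    generation: int
    proportions: tuple[float, ...]
    destination: int


@dataclass(frozen=True)
class SimParams:
    """Wright-Fisher scenario description.

    Parameters
    ----------
    pop_sizes
        Haploid genome count per population (constant while the
        population is active).
    generations
        Number of generations G simulated; genomes exist at times
        G, G-1, ..., 0 with samples at time 0.
    sequence_length
        Chromosome length l in bases (integer; breakpoints fall on
        integer positions so BED export is exact).
    rho
        Per-base, per-generation crossover probability.
    census_generations
        Generations (all strictly between 0 and G) whose genomes are
        flagged as census ancestors.
    sample_count
        Number of sample genomes flagged at time 0, drawn from the
        admixed population if an admixture pulse is configured, else
        from population 0.
    migration
        K x K backward migration matrix: entry [i][j] is the probability
        that a population-i genome draws its parents from population j;
        diagonals are implied (rows need not include them).
    admixture
        Optional admixture pulse; see :class:`Admixture`.
    seed
        Seed for the single named random generator; every draw flows
        through it.
    pop_names
        Optional population labels (default ``pop0 .. popK-1``).
    """

    pop_sizes: tuple[int, ...]
    generations: int
    sequence_length: int
    rho: float
    census_generations: tuple[int, ...] = ()
    sample_count: int = 1
    migration: tuple[tuple[float, ...], ...] | None = None
    admixture: Admixture | None = None
    seed: int = 1
    pop_names: tuple[str, ...] | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @staticmethod
    def from_dict(d: dict) -> "SimParams":
        d = dict(d)
        if d.get("admixture") is not None:
            a = d["admixture"]
            d["admixture"] = Admixture(
                int(a["generation"]),
                tuple(float(x) for x in a["proportions"]),
                int(a["destination"]),
            )
        if d.get("migration") is not None:
            d["migration"] = tuple(tuple(float(x) for x in row) for row in d["migration"])
        d["pop_sizes"] = tuple(int(x) for x in d["pop_sizes"])
        d["census_generations"] = tuple(int(x) for x in d.get("census_generations", ()))
        if d.get("pop_names") is not None:
            d["pop_names"] = tuple(str(x) for x in d["pop_names"])
        return SimParams(**d)


@dataclass(frozen=True)
class SimResult:
    """Simulator output: tables plus the census/sample node bookkeeping."""

    tables: TableBundle
    census_nodes: dict[int, list[int]]
    sample_nodes: list[int]
    params: SimParams


def _validate_params(p: SimParams) -> None:
    K = len(p.pop_sizes)
    if K == 0 or any(int(n) < 1 for n in p.pop_sizes):
        raise ParamError("pop_sizes must be positive integers")
    if p.generations < 1:
        raise ParamError("generations must be >= 1")
    if p.sequence_length < 1:
        raise ParamError("sequence_length must be >= 1")
    if p.rho < 0:
        raise ParamError("rho must be >= 0")
    if p.rho > 0 and p.sequence_length < 2:
        raise ParamError("sequence_length must be >= 2 when rho > 0")
    for g in p.census_generations:
        if not (1 <= int(g) <= p.generations - 1):
            raise ParamError(
                f"census generation {g} must lie strictly between 0 and {p.generations}"
            )
    if p.migration is not None:
        if len(p.migration) != K or any(len(row) != K for row in p.migration):
            raise ParamError("migration matrix must be K x K")
        for i, row in enumerate(p.migration):
            off = sum(float(row[j]) for j in range(K) if j != i)
            if any(float(x) < 0 for x in row):
                raise ParamError(f"migration row {i} has a negative rate")
            if off > 1.0 + 1e-12:
                raise ParamError(f"migration row {i} off-diagonal rates sum to {off} > 1")
    if p.admixture is not None:
        a = p.admixture
        if not (0 <= a.destination < K):
            raise ParamError(f"admixture destination {a.destination} not a population")
        if not (1 <= a.generation <= p.generations):
            raise ParamError("admixture generation must be in [1, generations]")
        if len(a.proportions) != K:
            raise ParamError("admixture proportions must have one entry per population")
        if any(x < 0 for x in a.proportions) or abs(sum(a.proportions) - 1.0) > 1e-9:
            raise ParamError("admixture proportions must be non-negative and sum to 1")
        if a.proportions[a.destination] != 0:
            raise ParamError("admixture proportions for the destination itself must be 0")
        if p.migration is not None:
            for i in range(K):
                if i != a.destination and float(p.migration[i][a.destination]) != 0:
                    raise ParamError(
                        "migration into the admixed destination from other "
                        "populations is not supported"
                    )
    sampling_pop = p.admixture.destination if p.admixture is not None else 0
    if not (1 <= p.sample_count <= int(p.pop_sizes[sampling_pop])):
        raise ParamError(
            f"sample_count must be in [1, {p.pop_sizes[sampling_pop]}] "
            f"(size of population {sampling_pop})"
        )


def _parent_pop_probs(p: SimParams, i: int, child_gen: int, K: int) -> np.ndarray:
    """Distribution over parent populations for a pop-i genome at child_gen."""
    a = p.admixture
    if a is not None and i == a.destination and child_gen == a.generation - 1:
        return np.asarray(a.proportions, dtype=float)
    probs = np.zeros(K)
    if p.migration is not None:
        row = np.asarray(p.migration[i], dtype=float)
        for j in range(K):
            if j != i:
                probs[j] = row[j]
    probs[i] = 1.0 - probs.sum()
    return probs


def simulate_wf(params: SimParams) -> SimResult:
    """Run the Wright-Fisher simulation; deterministic for a given seed.

    Returns valid, canonically sorted tables with every intermediate node
    retained (no simplification), the census node ids per requested
    generation, and the sample node ids.
    """
    _validate_params(params)
    p = params
    K = len(p.pop_sizes)
    G = int(p.generations)
    L = int(p.sequence_length)
    rng = np.random.default_rng(p.seed)
    adm = p.admixture
    sampling_pop = adm.destination if adm is not None else 0

    def active(pop: int, gen: int) -> bool:
        if adm is not None and pop == adm.destination:
            return gen <= adm.generation - 1
        return True

    # node layout: generations G down to 0; populations in id order
    node_time: list[float] = []
    node_pop: list[int] = []
    ids: dict[tuple[int, int], np.ndarray] = {}
    for g in range(G, -1, -1):
        for i in range(K):
            if active(i, g):
                n = int(p.pop_sizes[i])
                start = len(node_time)
                ids[(g, i)] = np.arange(start, start + n)
                node_time.extend([float(g)] * n)
                node_pop.extend([i] * n)

    mu = p.rho * L
    e_left: list[float] = []
    e_right: list[float] = []
    e_parent: list[int] = []
    e_child: list[int] = []

    for g in range(G - 1, -1, -1):
        for i in range(K):
            if not active(i, g):
                continue
            children = ids[(g, i)]
            n = len(children)
            probs = _parent_pop_probs(p, i, g, K)
            # any mass on a population inactive at g+1 is a scenario error
            for j in range(K):
                if probs[j] > 0 and not active(j, g + 1):
                    raise ParamError(
                        f"population {i} draws parents from population {j}, "
                        f"inactive at generation {g + 1}"
                    )
            parent_pops = rng.choice(K, size=n, p=probs)
            sizes = np.array([int(p.pop_sizes[j]) for j in parent_pops])
            p1 = (rng.random(n) * sizes).astype(np.int64)
            p2 = (rng.random(n) * sizes).astype(np.int64)
            n_bp = rng.poisson(mu, size=n)
            for idx in range(n):
                c = int(children[idx])
                pool = ids[(g + 1, int(parent_pops[idx]))]
                pa, pb = int(pool[p1[idx]]), int(pool[p2[idx]])
                k = int(n_bp[idx])
                if k == 0 or pa == pb:
                    e_left.append(0.0)
                    e_right.append(float(L))
                    e_parent.append(pa)
                    e_child.append(c)
                    continue
                bps = np.unique(rng.integers(1, L, size=k)).astype(float)
                cuts = np.concatenate([[0.0], bps, [float(L)]])
                for seg in range(len(cuts) - 1):
                    e_left.append(float(cuts[seg]))
                    e_right.append(float(cuts[seg + 1]))
                    e_parent.append(pa if seg % 2 == 0 else pb)
                    e_child.append(c)

    n_nodes = len(node_time)
    is_sample = np.zeros(n_nodes, dtype=np.int64)
    sample_nodes = [int(x) for x in ids[(0, sampling_pop)][: p.sample_count]]
    is_sample[sample_nodes] = 1

    is_census = np.zeros(n_nodes, dtype=np.int64)
    census: dict[int, list[int]] = {}
    for cg in p.census_generations:
        cg = int(cg)
        cids: list[int] = []
        for i in range(K):
            if active(i, cg):
                cids.extend(int(x) for x in ids[(cg, i)])
        cids.sort()
        census[cg] = cids
        is_census[cids] = 1

    nodes = pd.DataFrame({
        "time": np.asarray(node_time, dtype=np.float64),
        "population": np.asarray(node_pop, dtype=np.int64),
        "is_sample": is_sample,
        "is_census": is_census,
    })
    edges = pd.DataFrame({
        "left": np.asarray(e_left, dtype=np.float64),
        "right": np.asarray(e_right, dtype=np.float64),
        "parent": np.asarray(e_parent, dtype=np.int64),
        "child": np.asarray(e_child, dtype=np.int64),
    })
    names = p.pop_names if p.pop_names is not None else tuple(f"pop{i}" for i in range(K))
    pops = pd.DataFrame({"name": list(names)})
    tables = TableBundle(
        sequence_length=float(L),
        nodes=_normalize_nodes(nodes),
        edges=_normalize_edges(edges),
        populations=_normalize_populations(pops),
    )
    tables = sort_edges(tables)
    return SimResult(tables=tables, census_nodes=census,
                     sample_nodes=sample_nodes, params=p)


def census_nodes(result: SimResult, generation: int) -> list[int]:
    """Node ids recorded at a census generation requested in the params."""
    generation = int(generation)
    if generation not in result.census_nodes:
        raise ParamError(
            f"generation {generation} was not censused (requested: "
            f"{sorted(result.census_nodes)})"
        )
    return list(result.census_nodes[generation])


def expected_tract_count(rho: float, l: float, t: float) -> float:
    """Expected distinct ancestral segments at census depth ``t``.

    Each generation back adds an expected ``rho * l`` recombination
    breakpoints to a chromosome of length ``l``, so after ``t``
    generations the expectation is ``1 + rho * l * t``.
    """
    if rho < 0 or l < 0 or t < 0:
        raise ParamError("rho, l and t must be non-negative")
    return 1.0 + rho * l * t


def admixture_demo_params(
    seed: int = 1,
    census_generations: tuple[int, ...] = (11,),
    pop_size: int = 20,
    generations: int = 30,
    sequence_length: int = 100_000,
    rho: float = 1e-5,
    migration_rate: float = 0.01,
    admixture_generation: int = 10,
    sample_count: int = 10,
) -> SimParams:
    """The demonstration scenario: two sources with gene flow, a pulse.

    Two source populations of ``pop_size`` haploid genomes exchange
    migrants at ``migration_rate`` per generation; at
    ``admixture_generation`` an admixed population is founded 50:50 from
    the sources; a census is recorded at generation 11 (just before the
    pulse, looking backwards) by default; samples come from the admixed
    population at the present.
    """
    return SimParams(
        pop_sizes=(pop_size, pop_size, pop_size),
        generations=generations,
        sequence_length=sequence_length,
        rho=rho,
        census_generations=tuple(census_generations),
        sample_count=sample_count,
        migration=(
            (0.0, migration_rate, 0.0),
            (migration_rate, 0.0, 0.0),
            (0.0, 0.0, 0.0),
        ),
        admixture=Admixture(
            generation=admixture_generation,
            proportions=(0.5, 0.5, 0.0),
            destination=2,
        ),
        seed=seed,
        pop_names=("source_a", "source_b", "admixed"),
    )
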