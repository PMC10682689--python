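"""Shared fixtures and independent brute-force oracles for the test suite.

The helpers here are deliberately naive (position-wise repaints, pairwise
interval checks, per-breakpoint sweeps) so they stay independent of the
implementations they are used to verify.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ancestrylink import TableBundle, SimParams, Admixture, simulate_wf

SEQ = 10.0


def fixture_f() -> TableBundle:
    """Two samples, two recombination-split parents, one grandparent.

    L=10; nodes 0,1 are samples at t=0; 2 and 3 at t=1; 4 at t=2.
    Sample 1 inherits [0,5) from 2 and [5,10) from 3; sample 0 and node 2
    have full-span parents.
    """
    return TableBundle.from_records(
        SEQ,
        nodes=[(0, 0, 1), (0, 0, 1), (1, 0), (1, 1), (2,)],
        edges=[(0, 10, 2, 0), (0, 5, 2, 1), (5, 10, 3, 1), (0, 10, 4, 2)],
        populations=["A", "B"],
    )


def chain_bundle() -> TableBundle:
    """Chain c -> a1 -> a2 with full-span edges at times 0 < 1 < 2."""
    return TableBundle.from_records(
        SEQ,
        nodes=[(0, 0, 1), (1, 0), (2, 1)],
        edges=[(0, 10, 1, 0), (0, 10, 2, 1)],
        populations=["A", "B"],
    )


@pytest.fixture
def bundle_f() -> TableBundle:
    return fixture_f()


def split_edges_bundle(bundle: TableBundle, m_frac: float = 0.5) -> TableBundle:
    """Split every edge (l,r,p,c) into (l,m,p,c)+(m,r,p,c) at its midpoint."""
    rows = []
    for e in bundle.edges.itertuples(index=False):
        m = e.left + (e.right - e.left) * m_frac
        if e.left < m < e.right:
            rows.append((e.left, m, e.parent, e.child))
            rows.append((m, e.right, e.parent, e.child))
        else:
            rows.append((e.left, e.right, e.parent, e.child))
    out = TableBundle.from_records(
        bundle.sequence_length,
        nodes=[tuple(r) for r in bundle.nodes.itertuples(index=False)],
        edges=rows,
        populations=list(bundle.populations["name"]),
    )
    from ancestrylink import sort_edges
    return sort_edges(out)


def hand_instances() -> list[tuple[str, TableBundle, list[int], list[int]]]:
    """Hand-built (name, bundle, samples, ancestors) query instances."""
    f = fixture_f()
    chain = chain_bundle()
    single = TableBundle.from_records(
        SEQ, nodes=[(0, 0, 1), (3, 0)], edges=[(0, 10, 1, 0)], populations=["A"])
    # sample with a parentless gap in the middle
    gappy = TableBundle.from_records(
        SEQ,
        nodes=[(0, 0, 1), (1, 0), (1, 1)],
        edges=[(0, 4, 1, 0), (6, 10, 2, 0)],
        populations=["A", "B"],
    )
    # two samples sharing ancestry with interleaved breakpoints
    comb = TableBundle.from_records(
        SEQ,
        nodes=[(0, 0, 1), (0, 0, 1), (1, 0), (1, 1), (2, 0), (2, 1)],
        edges=[
            (0, 3, 2, 0), (3, 10, 3, 0),
            (0, 7, 3, 1), (7, 10, 2, 1),
            (0, 10, 4, 2), (0, 6, 5, 3), (6, 10, 4, 3),
        ],
        populations=["A", "B"],
    )
    return [
        ("f_both_parents", f, [0, 1], [2, 3]),
        ("f_most_recent", f, [0, 1], [2, 4]),
        ("f_grandparent", f, [0], [4]),
        ("f_partial", f, [0, 1], [3]),
        ("single_edge", single, [0], [1]),
        ("chain_both", chain, [0], [1, 2]),
        ("chain_old_only", chain, [0], [2]),
        ("gappy", gappy, [0], [1, 2]),
        ("gappy_deep", gappy, [0], [2]),
        ("f_split_edges", split_edges_bundle(f), [0, 1], [2, 3]),
        ("comb_mid", comb, [0, 1], [2, 3]),
        ("comb_deep", comb, [0, 1], [4, 5]),
        ("internal_sample", f, [0, 2], [4]),
    ]


def random_bundle(rng: np.random.Generator) -> TableBundle:
    """A random *valid* bundle with real-valued coordinates for I/O tests."""
    L = float(rng.uniform(5.0, 50.0))
    n_nodes = int(rng.integers(1, 12))
    times = np.sort(rng.uniform(0, 10, size=n_nodes))
    n_pops = int(rng.integers(0, 3))
    pops = [f"p{i}" for i in range(n_pops)]
    node_rows = []
    for i in range(n_nodes):
        pop = int(rng.integers(-1, n_pops)) if n_pops else -1
        node_rows.append((times[i], pop, int(times[i] == times[0]), 0))
    edge_rows = []
    for c in range(n_nodes - 1):
        olders = [p for p in range(n_nodes) if times[p] > times[c]]
        if not olders or rng.random() < 0.2:
            continue
        cuts = np.unique(np.concatenate([[0.0, L], rng.uniform(0, L, size=rng.integers(0, 4))]))
        for a, b in zip(cuts[:-1], cuts[1:]):
            if rng.random() < 0.25:
                continue  # leave a parentless gap
            p = int(rng.choice(olders))
            edge_rows.append((a, b, p, c))
    bundle = TableBundle.from_records(L, node_rows, edge_rows, pops)
    from ancestrylink import sort_edges
    return sort_edges(bundle)


def random_sim_params(rng: np.random.Generator, max_pop: int = 30, max_gen: int = 30) -> SimParams:
    """Random small admixture/migration scenario for the equivalence suite."""
    L = 100_000
    n_pops = int(rng.integers(2, 4))
    sizes = tuple(int(rng.integers(2, max_pop + 1)) for _ in range(n_pops))
    G = int(rng.integers(3, max_gen + 1))
    use_admix = bool(rng.random() < 0.5) and G >= 4
    admixture = None
    migration = None
    if use_admix:
        dest = n_pops - 1
        adm_gen = int(rng.integers(2, G))
        props = rng.dirichlet(np.ones(n_pops - 1))
        proportions = tuple(float(x) for x in props) + (0.0,)
        admixture = Admixture(adm_gen, proportions, dest)
        migration = tuple(
            tuple(0.02 if i != j and i != dest and j != dest else 0.0
                  for j in range(n_pops))
            for i in range(n_pops)
        )
    else:
        migration = tuple(
            tuple(0.02 if i != j else 0.0 for j in range(n_pops))
            for i in range(n_pops)
        )
    census = int(rng.integers(1, G))
    sampling_pop = admixture.destination if admixture else 0
    return SimParams(
        pop_sizes=sizes,
        generations=G,
        sequence_length=L,
        rho=0.5 / L,  # rho*l = 0.5
        census_generations=(census,),
        sample_count=int(min(5, sizes[sampling_pop])),
        migration=migration,
        admixture=admixture,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def repaint_oracle(pop_rows: pd.DataFrame) -> pd.DataFrame:
    """Position-sweep squash oracle: repaint at every breakpoint, then
    extract maximal constant-population intervals.  Quadratic and simple;
    independent of the run-merging implementation under test."""
    out = []
    for s, grp in pop_rows.groupby("sample", sort=True):
        bps = np.unique(np.concatenate([grp["left"].to_numpy(), grp["right"].to_numpy()]))
        run_start, run_pop = None, None
        for a, b in zip(bps[:-1], bps[1:]):
            mid = (a + b) / 2
            cover = grp[(grp["left"] <= mid) & (mid < grp["right"])]
            pop = int(cover["population"].iloc[0]) if len(cover) else None
            if pop != run_pop and run_pop is not None:
                out.append((s, run_start, a, run_pop))
                run_start, run_pop = None, None
            if pop is not None and run_pop is None:
                run_start, run_pop = a, pop
        if run_pop is not None:
            out.append((s, run_start, bps[-1], run_pop))
    df = pd.DataFrame(out, columns=["sample", "left", "right", "population"])
    return df.astype({"sample": np.int64, "left": np.float64,
                      "right": np.float64, "population": np.int64})


def random_tract_table(rng: np.random.Generator, n_samples: int = 3) -> pd.DataFrame:
    """Random disjoint per-sample tract rows with gaps and adjacent
    same-population runs, to exercise merging."""
    rows = []
    L = 100
    for s in range(n_samples):
        cuts = np.unique(np.concatenate([[0, L], rng.integers(0, L + 1, size=rng.integers(0, 12))]))
        for a, b in zip(cuts[:-1], cuts[1:]):
            paint = int(rng.integers(-1, 3))  # -1 = unassigned gap
            if paint >= 0:
                rows.append((s, float(a), float(b), rng.integers(0, 50), paint))
    return pd.DataFrame(rows, columns=["sample", "left", "right", "ancestor", "population"]).astype({
        "sample": np.int64, "left": np.float64, "right": np.float64,
        "ancestor": np.int64, "population": np.int64,
    })


@pytest.fixture(scope="session")
def demo_result():
    """One demo-scenario simulation shared across tests."""
    from ancestrylink import admixture_demo_params
    return simulate_wf(admixture_demo_params(seed=7))
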