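"""Single-pass ancestor linking: semantics, invariants, coverage."""

import numpy as np
import pytest

from ancestrylink import (IdError, TableBundle, census_nodes, coverage_report,
                          link_ancestors, read_ancestry_table, simulate_wf,
                          write_ancestry_table)
from ancestrylink.link import finalize_links
from conftest import chain_bundle, random_sim_params, split_edges_bundle


def rows_as_tuples(table):
    return [tuple(r) for r in table.rows.itertuples(index=False)]


class TestLinkSemantics:
    """Frozen expected outputs on the hand fixture (verified against the
    per-tree reference implementation and by manual tree-climbing)."""

    @pytest.mark.parametrize("samples,ancestors,expected", [
        ([0, 1], [2, 3], [(0, 10, 2, 0), (0, 5, 2, 1), (5, 10, 3, 1)]),
        # node 4 is ancestral to node 2: everything stops at the more
        # recent ancestor 2; (5,10) of sample 1 has no ancestor in A
        ([0, 1], [2, 4], [(0, 10, 2, 0), (0, 5, 2, 1)]),
        ([0], [4], [(0, 10, 4, 0)]),
        ([0, 1], [3], [(5, 10, 3, 1)]),
    ])
    def test_fixture_examples(self, bundle_f, samples, ancestors, expected):
        got = rows_as_tuples(link_ancestors(bundle_f, samples, ancestors))
        assert got == [(float(l), float(r), a, s) for (l, r, a, s) in expected]

    def test_single_edge_identity(self):
        b = TableBundle.from_records(
            7.0, nodes=[(0, -1, 1), (1,)], edges=[(0, 7, 1, 0)])
        got = rows_as_tuples(link_ancestors(b, [0], [1]))
        assert got == [(0.0, 7.0, 1, 0)]

    def test_most_recent_ancestor_rule_on_chain(self):
        b = chain_bundle()
        both = rows_as_tuples(link_ancestors(b, [0], [1, 2]))
        assert both == [(0.0, 10.0, 1, 0)]
        old = rows_as_tuples(link_ancestors(b, [0], [2]))
        assert old == [(0.0, 10.0, 2, 0)]

    def test_accepts_unsorted_edges(self, bundle_f):
        perm = [3, 1, 0, 2]
        shuffled = TableBundle(
            bundle_f.sequence_length, bundle_f.nodes,
            bundle_f.edges.iloc[perm].reset_index(drop=True),
            bundle_f.populations)
        assert link_ancestors(shuffled, [0, 1], [2, 3]).equals(
            link_ancestors(bundle_f, [0, 1], [2, 3]))


class TestPreconditions:
    def test_samples_and_ancestors_must_be_disjoint(self, bundle_f):
        with pytest.raises(IdError, match="disjoint"):
            link_ancestors(bundle_f, [0, 1], [1, 2])

    def test_empty_samples_or_ancestors(self, bundle_f):
        with pytest.raises(IdError):
            link_ancestors(bundle_f, [], [2])
        with pytest.raises(IdError):
            link_ancestors(bundle_f, [0], [])

    def test_unknown_ids(self, bundle_f):
        with pytest.raises(IdError, match="unknown"):
            link_ancestors(bundle_f, [0, 99], [2])

    def test_duplicate_ids(self, bundle_f):
        with pytest.raises(IdError, match="duplicate"):
            link_ancestors(bundle_f, [0, 0], [2])


class TestInvariants:
    def test_per_sample_intervals_disjoint_and_bounded(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            params = random_sim_params(rng)
            res = simulate_wf(params)
            anc = census_nodes(res, params.census_generations[0])
            links = link_ancestors(res.tables, res.sample_nodes, anc)
            for s, grp in links.rows.groupby("sample"):
                g = grp.sort_values("left")
                assert (g["left"].to_numpy()[1:] >= g["right"].to_numpy()[:-1]).all()
                assert (g["right"] - g["left"]).sum() <= res.tables.sequence_length

    def test_no_exactly_adjacent_rows_with_same_pair(self):
        rng = np.random.default_rng(13)
        params = random_sim_params(rng)
        res = simulate_wf(params)
        anc = census_nodes(res, params.census_generations[0])
        links = link_ancestors(res.tables, res.sample_nodes, anc)
        df = links.rows.sort_values(["sample", "ancestor", "left"])
        same = (df["sample"].to_numpy()[1:] == df["sample"].to_numpy()[:-1]) & \
               (df["ancestor"].to_numpy()[1:] == df["ancestor"].to_numpy()[:-1])
        touching = df["left"].to_numpy()[1:] == df["right"].to_numpy()[:-1]
        assert not np.any(same & touching)

    def test_refinement_under_edge_splitting(self, bundle_f):
        for frac in (0.25, 0.5, 0.9):
            split = split_edges_bundle(bundle_f, frac)
            assert link_ancestors(split, [0, 1], [2, 3]).equals(
                link_ancestors(bundle_f, [0, 1], [2, 3]))

    def test_refinement_on_simulated_tables(self):
        rng = np.random.default_rng(17)
        params = random_sim_params(rng, max_pop=8, max_gen=8)
        res = simulate_wf(params)
        anc = census_nodes(res, params.census_generations[0])
        base = link_ancestors(res.tables, res.sample_nodes, anc)
        split = split_edges_bundle(res.tables, 0.5)
        assert link_ancestors(split, res.sample_nodes, anc).equals(base)

    def test_deterministic_output_bytes(self, bundle_f, tmp_path):
        for tag in ("a", "b"):
            t = link_ancestors(bundle_f, [0, 1], [2, 3])
            write_ancestry_table(t, tmp_path / tag)
        assert (tmp_path / "a").read_bytes() == (tmp_path / "b").read_bytes()

    def test_internal_sample_traced_independently(self, bundle_f):
        # node 2 is both a sample and an ancestor of sample 0
        got = rows_as_tuples(link_ancestors(bundle_f, [0, 2], [4]))
        assert got == [(0.0, 10.0, 4, 0), (0.0, 10.0, 4, 2)]


class TestCoverage:
    def test_fully_assigned_fixture(self, bundle_f):
        links = link_ancestors(bundle_f, [0, 1], [2, 3])
        cov = coverage_report(links, [0, 1])
        assert cov.assigned_length == {0: 10.0, 1: 10.0}
        assert cov.unassigned == {0: [], 1: []}

    def test_partial_assignment(self, bundle_f):
        links = link_ancestors(bundle_f, [0, 1], [3])
        cov = coverage_report(links, [0, 1])
        assert cov.assigned_length[0] == 0.0
        assert cov.unassigned[0] == [(0.0, 10.0)]
        assert cov.assigned_length[1] == 5.0
        assert cov.unassigned[1] == [(0.0, 5.0)]

    def test_empty_table_everything_unassigned(self):
        empty = finalize_links([], 10.0)
        cov = coverage_report(empty, [0, 5])
        assert cov.assigned_length == {0: 0.0, 5: 0.0}
        assert cov.unassigned[5] == [(0.0, 10.0)]

    def test_decomposition_is_exact(self):
        rng = np.random.default_rng(19)
        params = random_sim_params(rng)
        res = simulate_wf(params)
        anc = census_nodes(res, params.census_generations[0])
        links = link_ancestors(res.tables, res.sample_nodes, anc)
        cov = coverage_report(links, res.sample_nodes)
        for s in res.sample_nodes:
            gaps = sum(b - a for a, b in cov.unassigned[s])
            assert cov.assigned_length[s] + gaps == res.tables.sequence_length


class TestLinkIO:
    def test_round_trip(self, bundle_f, tmp_path):
        t = link_ancestors(bundle_f, [0, 1], [2, 3])
        write_ancestry_table(t, tmp_path / "links.tsv")
        back = read_ancestry_table(tmp_path / "links.tsv")
        assert back.equals(t)

    def test_empty_round_trip(self, tmp_path):
        t = finalize_links([], 5.5)
        write_ancestry_table(t, tmp_path / "links.tsv")
        back = read_ancestry_table(tmp_path / "links.tsv")
        assert back.equals(t)
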