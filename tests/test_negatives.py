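import math
from itertools import combinations

import networkx as nx
import numpy as np
import pytest

from nipkit.data_io import InteractionSet, Protein, ProteinSet
from nipkit.negatives import (
    NegativeSamplingError,
    degree_profile,
    nip_rw,
    nip_rw_reachability,
    nip_ss,
    random_pairing,
    select_submatrix_proteins,
    subcellular_negatives,
)
from nipkit.similarity import pairwise_similarity
from conftest import random_sequence
from oracles import degree_bin_oracle


def to_nx(pairs: InteractionSet) -> nx.Graph:
    g = nx.Graph()
    g.add_edges_from(pairs)
    return g


def random_interactions(rng, n_nodes, n_edges, prefix="n"):
    nodes = [f"{prefix}{i:03d}" for i in range(n_nodes)]
    all_pairs = list(combinations(nodes, 2))
    idx = rng.choice(len(all_pairs), size=n_edges, replace=False)
    return InteractionSet([all_pairs[i] for i in idx])


class TestDegreeProfile:
    def test_single_pair(self):
        prof = degree_profile(InteractionSet([("A", "B")]))
        assert prof.degrees == {"A": 1, "B": 1}
        assert prof.r == 0.0
        assert prof.max_degree == 1

    def test_star_graph(self):
        prof = degree_profile(
            InteractionSet([("C", "A"), ("C", "B"), ("C", "D")])
        )
        assert prof.n_proteins == 4
        assert prof.r == pytest.approx(0.5)
        assert prof.max_degree == 3

    def test_perfect_matching_has_zero_repeatability(self):
        prof = degree_profile(
            InteractionSet([("a", "b"), ("c", "d"), ("e", "f")])
        )
        assert prof.r == 0.0

    def test_proportions_sum_to_one(self):
        rng = np.random.default_rng(9)
        prof = degree_profile(random_interactions(rng, 30, 60))
        assert prof.protein_prop.sum() == pytest.approx(1.0, abs=1e-9)
        assert prof.pair_prop.sum() == pytest.approx(1.0, abs=1e-9)

    def test_binning_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(10)
        pairs = random_interactions(rng, 30, 100)
        prof = degree_profile(pairs)
        expected_prop, _ = degree_bin_oracle(prof.degrees)
        np.testing.assert_allclose(prof.protein_prop, expected_prop)
        # endpoint proportions re-derived by brute force
        endpoint_bins = np.zeros(9)
        for a, b in pairs:
            for pid in (a, b):
                _, counts = degree_bin_oracle({pid: prof.degrees[pid]})
                endpoint_bins += counts
        np.testing.assert_allclose(
            prof.pair_prop, endpoint_bins / (2 * len(pairs))
        )

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            degree_profile(InteractionSet())


@pytest.fixture(scope="module")
def toy():
    rng = np.random.default_rng(11)
    proteins = ProteinSet(
        Protein(pid, random_sequence(rng, 60)) for pid in "ABCD"
    )
    sim = pairwise_similarity(proteins)
    positives = InteractionSet([("A", "B")])
    return proteins, positives, sim


class TestNipSS:

    def test_toy_matches_exhaustive_min_similarity_oracle(self, toy):
        proteins, positives, sim = toy
        result = nip_ss(proteins, positives, sim, target_count=2, m=5,
                        tolerance=0.5, seed=0)
        cap = degree_profile(positives).max_degree  # = 1
        candidates = [
            p for p in combinations(sorted(proteins.ids), 2)
            if p not in positives
        ]
        best, best_total = None, math.inf
        for subset in combinations(candidates, 2):
            degs: dict[str, int] = {}
            for a, b in subset:
                degs[a] = degs.get(a, 0) + 1
                degs[b] = degs.get(b, 0) + 1
            if max(degs.values()) > cap:
                continue
            total = sum(sim.s(*p) for p in subset)
            if total < best_total:
                best, best_total = set(subset), total
        assert set(result.pairs) == best

    def test_disjoint_from_positives(self, toy):
        proteins, positives, sim = toy
        result = nip_ss(proteins, positives, sim, target_count=2, m=5,
                        tolerance=0.5, seed=0)
        assert not (result.pairs & positives.pairs)

    def test_infinite_tolerance_reduces_to_pure_ranking(self, toy):
        proteins, positives, sim = toy
        result = nip_ss(proteins, positives, sim, target_count=3, m=5,
                        tolerance=math.inf, seed=0)
        candidates = sorted(
            (p for p in combinations(sorted(proteins.ids), 2)
             if p not in positives),
            key=lambda p: (sim.s(*p), p),
        )
        assert result.ordered_pairs == candidates[:3]

    def test_output_sorted_by_ascending_similarity(self, matched_fixture):
        result = nip_ss(
            matched_fixture["universe"], matched_fixture["positives"],
            matched_fixture["similarity"], seed=1,
        )
        s_values = [
            matched_fixture["similarity"].s(*p) for p in result.ordered_pairs
        ]
        assert s_values == sorted(s_values)

    def test_degree_control_on_matched_fixture(self, matched_fixture):
        positives = matched_fixture["positives"]
        pos_profile = degree_profile(positives)
        for seed in range(5):
            result = nip_ss(
                matched_fixture["universe"], positives,
                matched_fixture["similarity"], seed=seed,
            )
            assert len(result) == len(positives)
            assert result.profile.max_degree <= pos_profile.max_degree
            deviations = result.profile.pair_prop_deviation(pos_profile)
            assert deviations.max() <= 0.05 or result.deviations

    def test_target_exceeding_candidates_errors(self, toy):
        proteins, positives, sim = toy
        with pytest.raises((NegativeSamplingError, ValueError)):
            nip_ss(proteins, positives, sim, target_count=50, m=50, seed=0)


class TestReachability:
    def test_path_single_step_is_adjacency(self, path_graph):
        reach = nip_rw_reachability(path_graph, k=1)
        idx = {pid: i for i, pid in enumerate(reach.ids)}
        true_pairs = {
            (a, b)
            for a, b in combinations(reach.ids, 2)
            if reach.matrix[idx[a], idx[b]]
        }
        assert true_pairs == {("a", "b"), ("b", "c"), ("c", "d")}

    def test_path_two_steps_adds_distance_two_pairs(self, path_graph):
        reach = nip_rw_reachability(path_graph, k=2)
        idx = {pid: i for i, pid in enumerate(reach.ids)}
        assert reach.matrix[idx["a"], idx["c"]]
        assert reach.matrix[idx["b"], idx["d"]]
        assert not reach.matrix[idx["a"], idx["d"]]

    def test_full_reachability_at_diameter(self):
        rng = np.random.default_rng(12)
        for _ in range(5):
            pairs = random_interactions(rng, 20, 30)
            g = to_nx(pairs)
            reach = nip_rw_reachability(pairs, k=20)
            idx = {pid: i for i, pid in enumerate(reach.ids)}
            for a, b in combinations(reach.ids, 2):
                connected = nx.has_path(g, a, b)
                assert reach.matrix[idx[a], idx[b]] == connected

    def test_monotone_in_k(self, path_graph):
        r1 = nip_rw_reachability(path_graph, k=1).matrix
        r2 = nip_rw_reachability(path_graph, k=2).matrix
        r3 = nip_rw_reachability(path_graph, k=3).matrix
        assert (r1 <= r2).all() and (r2 <= r3).all()

    def test_invalid_k(self, path_graph):
        with pytest.raises(ValueError):
            nip_rw_reachability(path_graph, k=0)


class TestSelectSubmatrixProteins:
    def test_star_center_selected_first(self):
        star = InteractionSet([("C", "A"), ("C", "B"), ("C", "D")])
        assert select_submatrix_proteins(star, 2) == ["C", "A"]

    def test_full_selection_lexicographic_within_degree(self, path_graph):
        assert select_submatrix_proteins(path_graph, 4) == ["b", "c", "a", "d"]

    def test_matches_sort_oracle_on_random_graph(self):
        rng = np.random.default_rng(13)
        pairs = random_interactions(rng, 20, 40)
        prof = degree_profile(pairs)
        expected = sorted(
            prof.degrees, key=lambda pid: (-prof.degrees[pid], pid)
        )[:10]
        assert select_submatrix_proteins(pairs, 10) == expected

    def test_p_too_large_errors(self, path_graph):
        with pytest.raises(ValueError):
            select_submatrix_proteins(path_graph, 5)


class TestNipRW:
    def test_path_unique_candidate(self, path_graph):
        result = nip_rw(None, path_graph, k=2, p=4, target_count=1, seed=0)
        assert result.pairs == frozenset({("a", "d")})

    def test_triangle_exhausts_candidates(self, triangle_graph):
        with pytest.raises(NegativeSamplingError, match="insufficient candidates"):
            nip_rw(None, triangle_graph, k=1, p=3, target_count=1, seed=0)

    def test_outputs_beyond_k_by_bfs_oracle(self):
        rng = np.random.default_rng(14)
        checked = 0
        for trial in range(50):
            n = int(rng.integers(20, 51))
            pairs = random_interactions(rng, n, n, prefix=f"t{trial}_")
            g = to_nx(pairs)
            k = 2
            try:
                result = nip_rw(None, pairs, k=k, target_count=5,
                                seed=trial)
            except NegativeSamplingError:
                continue
            for a, b in result:
                try:
                    dist = nx.shortest_path_length(g, a, b)
                except nx.NetworkXNoPath:
                    dist = math.inf
                assert dist > k
                checked += 1
        assert checked > 50

    def test_default_p_is_half_the_network(self):
        star = InteractionSet([("c", x) for x in ("a", "b", "d", "e")])
        result = nip_rw(None, star, k=1, target_count=1, seed=0)
        # 5 proteins -> p defaults to 3: the hub plus two leaves; the only
        # candidates are leaf-leaf pairs (distance 2)
        assert result.provenance["p"] == 3
        (pair,) = result.pairs
        assert "c" not in pair


class TestRandomPairing:
    def test_saturated_positive_set_errors(self, triangle_graph):
        with pytest.raises(NegativeSamplingError):
            random_pairing(["a", "b", "c"], triangle_graph, target_count=1,
                           seed=0)

    def test_seed_determinism(self):
        ids = [f"p{i}" for i in range(8)]
        positives = InteractionSet([("p0", "p1")])
        one = random_pairing(ids, positives, target_count=5, seed=3)
        two = random_pairing(ids, positives, target_count=5, seed=3)
        other = random_pairing(ids, positives, target_count=5, seed=4)
        assert one.pairs == two.pairs
        assert one.pairs != other.pairs

    def test_draws_uniform_within_three_sigma(self):
        ids = list("abcdef")
        positives = InteractionSet([("a", "b")])
        n_candidates = 15 - 1
        draws = 2000
        counts: dict[tuple[str, str], int] = {}
        for seed in range(draws):
            result = random_pairing(ids, positives, target_count=1, seed=seed)
            pair = next(iter(result))
            counts[pair] = counts.get(pair, 0) + 1
        p = 1 / n_candidates
        sigma = math.sqrt(draws * p * (1 - p))
        assert len(counts) == n_candidates
        for count in counts.values():
            assert abs(count - draws * p) <= 3 * sigma


class TestSubcellularNegatives:
    def test_single_compartment_errors(self):
        with pytest.raises(NegativeSamplingError):
            subcellular_negatives(
                {"A": "nucleus", "B": "nucleus"}, InteractionSet(),
                target_count=1, seed=0,
            )

    def test_unique_cross_compartment_candidate(self):
        result = subcellular_negatives(
            {"A": "cytoplasm", "B": "nucleus"}, InteractionSet(),
            target_count=1, seed=0,
        )
        assert result.pairs == frozenset({("A", "B")})

    def test_every_output_spans_two_compartments(self):
        rng = np.random.default_rng(15)
        names = ["cyto", "nuc", "mito"]
        table = {f"p{i}": names[int(rng.integers(3))] for i in range(12)}
        positives = InteractionSet([("p0", "p1"), ("p2", "p3")])
        result = subcellular_negatives(table, positives, target_count=10,
                                       seed=1)
        for a, b in result:
            assert table[a] != table[b]
            assert (a, b) not in positives


class TestStrategyContracts:
    """Shared invariants: disjointness, size, no self-pairs, determinism."""

    @pytest.mark.parametrize("strategy", ["nip_ss", "nip_rw", "random",
                                          "subloc"])
    def test_common_invariants(self, small_world, strategy):
        world = small_world
        positives = world["observed"]
        universe = positives.protein_ids()
        target = 40

        def build(seed):
            if strategy == "nip_ss":
                return nip_ss(universe, positives, world["similarity"],
                              target_count=target, seed=seed)
            if strategy == "nip_rw":
                return nip_rw(universe, positives, k=2, target_count=target,
                              seed=seed)
            if strategy == "random":
                return random_pairing(universe, positives,
                                      target_count=target, seed=seed)
            return subcellular_negatives(world["localizations"], positives,
                                         target_count=target, seed=seed)

        result = build(seed=7)
        assert len(result) == target
        assert not (result.pairs & positives.pairs)
        assert all(a != b for a, b in result)
        assert all(a < b for a, b in result)
        rerun = build(seed=7)
        assert result.ordered_pairs == rerun.ordered_pairs

    def test_nip_ss_selects_lower_similarity_than_random(self, small_world):
        world = small_world
        positives = world["observed"]
        universe = positives.protein_ids()
        sim = world["similarity"]
        ss_means, random_means = [], []
        for seed in range(20):
            ss = nip_ss(universe, positives, sim, target_count=60, seed=seed)
            rnd = random_pairing(universe, positives, target_count=60,
                                 seed=seed)
            ss_means.append(np.mean([sim.s(a, b) for a, b in ss]))
            random_means.append(np.mean([sim.s(a, b) for a, b in rnd]))
        assert all(s <= r for s, r in zip(ss_means, random_means))
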