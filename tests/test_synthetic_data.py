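"""Coupled lexicon + trait simulator: determinism, limiting cases, signal."""

import numpy as np
import pytest

from galtonlex import (
    SimulationConfig,
    Wordlist,
    apply_borrowing,
    assign_groups,
    cognate_distance,
    evolve_lexicon,
    evolve_trait,
    make_dataset,
    matrix_correlation,
    pairwise_matrix,
    simulate_tree,
    variety_ldn,
)
from galtonlex.aggregation import group_distance_matrix


class TestSimulateTree:
    def test_unique_two_leaf_topology(self):
        t = simulate_tree(2, seed=0)
        assert sorted(t.leaf_labels) == ["v001", "v002"]
        assert t.root.height == pytest.approx(1.0)

    def test_determinism(self):
        assert simulate_tree(9, seed=5).to_newick() == simulate_tree(9, seed=5).to_newick()

    @pytest.mark.parametrize("n", [2, 3, 7, 25, 50])
    def test_leaf_count(self, n):
        assert len(simulate_tree(n, seed=1)) == n

    def test_ultrametric_height_one(self):
        t = simulate_tree(12, seed=2)
        coph = t.cophenetic_matrix()
        # all leaves at distance 2*height(root MRCA) <= 2; root at height 1
        assert t.root.height == pytest.approx(1.0)
        assert np.asarray(coph.data).max() == pytest.approx(2.0)


class TestEvolveLexicon:
    def test_frozen_evolution_identical_leaves(self):
        cfg = SimulationConfig(
            n_varieties=6, n_concepts=10, mutation_rate=0.0, replacement_rate=0.0,
            n_groups=2,
        )
        tree = simulate_tree(6, seed=3)
        wls = evolve_lexicon(tree, cfg, seed=4)
        m = pairwise_matrix(wls, "ldn")
        assert np.asarray(m.data).max() == 0.0
        assert pairwise_matrix(wls, "cognate").data.max() == 0.0

    def test_replacement_rate_monotonically_increases_cognate_distance(self):
        # replacement probability is rate x branch length, so higher rates
        # erase more shared etymologies; 50 Monte Carlo reps per rate
        means = {}
        for rate in (0.05, 0.25, 1.0):
            vals = []
            for rep in range(50):
                cfg = SimulationConfig(
                    n_varieties=6, n_concepts=20, replacement_rate=rate, n_groups=2
                )
                tree = simulate_tree(6, seed=100 + rep)
                wls = evolve_lexicon(tree, cfg, seed=200 + rep)
                vals.append(
                    float(np.asarray(pairwise_matrix(wls, "cognate").data).mean())
                )
            means[rate] = float(np.mean(vals))
        assert means[0.05] < means[0.25] < means[1.0]
        assert means[1.0] > 0.5

    def test_sister_leaves_closer_than_distant_leaves(self):
        cfg = SimulationConfig(n_varieties=8, n_concepts=40, n_groups=2)
        diffs = []
        for rep in range(50):
            tree = simulate_tree(8, seed=300 + rep)
            wls = evolve_lexicon(tree, cfg, seed=400 + rep)
            by_id = {w.variety_id: w for w in wls}
            coph = tree.cophenetic_matrix()
            ids = list(coph.ids)
            pairs = [(i, j) for i in range(8) for j in range(i + 1, 8)]
            dists = np.array([coph[ids[i], ids[j]] for i, j in pairs])
            closest = pairs[int(np.argmin(dists))]
            farthest = pairs[int(np.argmax(dists))]
            near = variety_ldn(by_id[ids[closest[0]]], by_id[ids[closest[1]]])
            far = variety_ldn(by_id[ids[farthest[0]]], by_id[ids[farthest[1]]])
            diffs.append(far - near)
        assert np.mean(diffs) > 0

    def test_determinism(self):
        cfg = SimulationConfig(n_varieties=5, n_concepts=12, n_groups=2)
        tree = simulate_tree(5, seed=6)
        assert evolve_lexicon(tree, cfg, seed=7) == evolve_lexicon(tree, cfg, seed=7)

    def test_cognate_classes_globally_consistent(self):
        # forms sharing a class descend from the same replacement: within a
        # class, all leaf forms derive from one word, so with zero mutation
        # they are identical strings
        cfg = SimulationConfig(
            n_varieties=10, n_concepts=15, mutation_rate=0.0, replacement_rate=0.5,
            n_groups=2,
        )
        tree = simulate_tree(10, seed=8)
        wls = evolve_lexicon(tree, cfg, seed=9)
        by_class: dict[str, set[str]] = {}
        for w in wls:
            for concept in w.entries:
                for form, klass in w.entries[concept]:
                    by_class.setdefault(klass, set()).add(form)
        assert all(len(forms) == 1 for forms in by_class.values())


class TestApplyBorrowing:
    def test_zero_rate_is_identity(self, small_dataset):
        cfg = SimulationConfig(n_varieties=12, n_concepts=30, n_groups=4)
        out, events = apply_borrowing(small_dataset.wordlists, cfg, seed=1)
        assert out == small_dataset.wordlists
        assert events == []

    def test_full_borrowing_two_varieties_converges(self):
        w1 = Wordlist("a", {"c1": [("xxx", "k1")], "c2": [("yyy", "k2")]})
        w2 = Wordlist("b", {"c1": [("zzz", "m1")], "c2": [("www", "m2")]})
        cfg = SimulationConfig(n_varieties=2, n_concepts=2, borrowing_rate=1.0,
                               n_groups=1)
        out, events = apply_borrowing([w1, w2], cfg, seed=2)
        a, b = out
        assert a.entries == b.entries
        assert len(events) == 4

    def test_event_log_replays_to_output(self):
        w1 = Wordlist("a", {"c1": [("xxx", "k1")]})
        w2 = Wordlist("b", {"c1": [("zzz", "m1")]})
        cfg = SimulationConfig(n_varieties=2, n_concepts=1, borrowing_rate=0.7,
                               n_groups=1)
        out, events = apply_borrowing([w1, w2], cfg, seed=3)
        state = {"a": {"c1": [["xxx", "k1"]]}, "b": {"c1": [["zzz", "m1"]]}}
        for ev in events:
            assert state[ev["recipient"]][ev["concept"]] == ev["old"]
            state[ev["recipient"]][ev["concept"]] = ev["new"]
        rebuilt = [
            Wordlist(v, {c: [tuple(p) for p in forms] for c, forms in state[v].items()})
            for v in ("a", "b")
        ]
        assert rebuilt == out

    def test_borrowing_pulls_ring_neighbors_together(self):
        vals = {}
        for rate in (0.0, 0.6):
            deltas = []
            for rep in range(30):
                cfg = SimulationConfig(
                    n_varieties=10, n_concepts=30, borrowing_rate=rate, n_groups=2,
                    seed=rep,
                )
                tree = simulate_tree(10, seed=500 + rep)
                wls = evolve_lexicon(tree, cfg, seed=600 + rep)
                wls, _ = apply_borrowing(wls, cfg, seed=700 + rep)
                by_id = {w.variety_id: w for w in wls}
                order = [w.variety_id for w in wls]
                ring = np.mean(
                    [
                        variety_ldn(by_id[order[i]], by_id[order[(i + 1) % 10]])
                        for i in range(10)
                    ]
                )
                deltas.append(ring)
            vals[rate] = float(np.mean(deltas))
        assert vals[0.6] < vals[0.0]


class TestEvolveTrait:
    def test_zero_variance_gives_half(self):
        cfg = SimulationConfig(n_varieties=5, trait_step_variance=0.0, n_groups=2)
        tree = simulate_tree(5, seed=10)
        traits = evolve_trait(tree, cfg, seed=11)
        assert all(v == pytest.approx(0.5) for v in traits.values())

    def test_determinism_and_range(self):
        cfg = SimulationConfig(n_varieties=8, n_groups=2)
        tree = simulate_tree(8, seed=12)
        t1 = evolve_trait(tree, cfg, seed=13)
        t2 = evolve_trait(tree, cfg, seed=13)
        assert t1 == t2
        assert all(0.0 <= v <= 1.0 for v in t1.values())

    def test_between_clade_variance_exceeds_within(self):
        # deep split: the two root clades should differ more between than within
        cfg = SimulationConfig(n_varieties=16, n_groups=2)
        ratios = []
        for rep in range(40):
            tree = simulate_tree(16, seed=800 + rep)
            traits = evolve_trait(tree, cfg, seed=900 + rep)
            clades = tree.cut(2)
            means = [np.mean([traits[v] for v in cl]) for cl in clades]
            within = np.mean(
                [np.var([traits[v] for v in cl]) for cl in clades if len(cl) > 1]
                or [0.0]
            )
            between = (means[0] - means[1]) ** 2
            ratios.append(between - within)
        assert np.median(ratios) > 0


class TestMakeDataset:
    def test_deterministic_and_complete(self):
        cfg = SimulationConfig(n_varieties=10, n_concepts=12, n_groups=3, seed=21)
        out1 = make_dataset(cfg)
        out2 = make_dataset(cfg)
        assert out1.wordlists == out2.wordlists
        assert out1.trait_table == out2.trait_table
        assert out1.tree.to_newick() == out2.tree.to_newick()
        assert set(out1.group_map) == {w.variety_id for w in out1.wordlists}
        assert set(out1.trait_table) == set(out1.group_map.values())

    def test_groups_are_clades(self):
        out = make_dataset(SimulationConfig(n_varieties=15, n_concepts=5, n_groups=5,
                                            seed=22))
        clades = set(out.tree.cut(5))
        by_group: dict[str, set] = {}
        for v, g in out.group_map.items():
            by_group.setdefault(g, set()).add(v)
        assert {frozenset(s) for s in by_group.values()} == clades

    def test_files_round_trip_through_readers(self, tmp_path, small_dataset):
        from galtonlex import read_group_map, read_trait_table, read_wordlists

        paths = small_dataset.write(tmp_path)
        wls = read_wordlists(paths["wordlists"])
        assert wls == sorted(small_dataset.wordlists, key=lambda w: w.variety_id)
        assert read_group_map(paths["groups"]) == small_dataset.group_map
        tt = read_trait_table(paths["traits"])
        assert tt == pytest.approx(small_dataset.trait_table)

    def test_lexicon_tracks_true_tree_without_borrowing(self):
        # median Mantel correlation between cognate distances and true
        # path distances is positive across replicates
        rs = []
        for rep in range(50):
            out = make_dataset(
                SimulationConfig(n_varieties=10, n_concepts=25, n_groups=3,
                                 seed=1000 + rep)
            )
            vmat = pairwise_matrix(out.wordlists, "cognate")
            coph = out.tree.cophenetic_matrix().filter(list(vmat.ids))
            rs.append(matrix_correlation(vmat, coph))
        assert np.median(rs) > 0


class TestAssignGroups:
    def test_every_leaf_assigned(self):
        tree = simulate_tree(20, seed=30)
        g = assign_groups(tree, 6)
        assert set(g) == set(tree.leaf_labels)
        assert len(set(g.values())) == 6
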