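import numpy as np
import pandas as pd
import pytest

from orthodyn import (CopyMatrix, GroupMap, cafe_inclusion_filter,
                      classify_orphan_origin, compute_coverage,
                      filter_families, find_orphans, fitch_presence_at_node,
                      fitch_state_sets, read_tree)

from _oracles import all_rooted_topologies, fitch_exhaustive, topology_to_newick


def matrix_from(rows, families, species):
    return CopyMatrix(pd.DataFrame(rows, index=families, columns=species))


class TestCoverage:
    def test_hand_computed_group_average(self):
        """Group A: 2 of 4 present (0.5); group B: 1 of 5 (0.2); unweighted
        average 0.35."""
        species = [f"a{i}" for i in range(4)] + [f"b{i}" for i in range(5)]
        groups = GroupMap({s: ("A" if s.startswith("a") else "B")
                           for s in species})
        row = [2, 1, 0, 0, 0, 0, 0, 3, 0]
        m = matrix_from([row], ["OG1"], species)
        cov = compute_coverage(m, groups)
        assert cov.loc["OG1", "A"] == pytest.approx(0.5)
        assert cov.loc["OG1", "B"] == pytest.approx(0.2)
        assert cov.loc["OG1", "average"] == pytest.approx(0.35)

    def test_everywhere_and_nowhere(self):
        species = ["a1", "a2", "b1", "b2"]
        groups = GroupMap({"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        m = matrix_from([[1, 2, 1, 4], [0, 0, 0, 0]], ["full", "empty"], species)
        cov = compute_coverage(m, groups)
        assert cov.loc["full", "average"] == 1.0
        assert cov.loc["empty", "average"] == 0.0

    def test_matches_bruteforce_set_counting(self, rng):
        """Vectorized coverage equals explicit per-group set counting on
        random matrices, and is invariant to species permutation."""
        for _ in range(5):
            n_fam, n_sp = 20, 30
            counts = rng.integers(0, 3, size=(n_fam, n_sp))
            species = [f"s{i}" for i in range(n_sp)]
            fams = [f"F{i}" for i in range(n_fam)]
            glabels = rng.choice(["G1", "G2", "G3"], n_sp)
            groups = GroupMap(dict(zip(species, glabels)))
            m = matrix_from(counts, fams, species)
            cov = compute_coverage(m, groups)
            for fam_i, fam in enumerate(fams):
                per_group = []
                for g in sorted(set(glabels)):
                    members = [i for i, gl in enumerate(glabels) if gl == g]
                    per_group.append(
                        sum(counts[fam_i, i] > 0 for i in members) / len(members))
                assert cov.loc[fam, "average"] == pytest.approx(
                    np.mean(per_group), abs=1e-12)
            perm = rng.permutation(n_sp)
            m2 = matrix_from(counts[:, perm], fams, [species[i] for i in perm])
            cov2 = compute_coverage(m2, groups)
            pd.testing.assert_frame_equal(cov, cov2)

    def test_threshold_boundaries_inclusive(self):
        cov = pd.DataFrame({"A": [1.0, 0.5, 0.0], "B": [0.0, 0.5, 0.0]},
                           index=["f1", "f2", "f3"])
        cov["average"] = cov.mean(axis=1)
        assert set(filter_families(cov, 0.0)) == {"f1", "f2", "f3"}
        assert set(filter_families(cov, 0.5)) == {"f1", "f2"}  # 0.5 kept
        assert set(filter_families(cov, 1.0)) == set()


class TestFitch:
    def test_hand_cases(self):
        t = read_tree("((A:1,B:1):1,(C:1,D:1):1);")
        sets = fitch_state_sets(t, {"A": 1, "B": 1, "C": 0, "D": 0})
        assert sets[t.seed_node] == frozenset({0, 1})
        assert fitch_presence_at_node(t, {"A": 1, "B": 1, "C": 1, "D": 1})
        assert not fitch_presence_at_node(t, {"A": 0, "B": 0, "C": 0, "D": 0})
        # ambiguous root counts as present under the inclusive policy
        assert fitch_presence_at_node(t, {"A": 1, "B": 1, "C": 0, "D": 0})
        assert not fitch_presence_at_node(
            t, {"A": 1, "B": 1, "C": 0, "D": 0}, ambiguous_is_present=False)

    def test_exhaustive_all_topologies_small(self):
        """Fitch bottom-up sets equal exhaustive minimal-change enumeration
        at every node, over all rooted topologies on <= 5 tips and every
        state vector."""
        labels = tuple("ABCDE")
        for n in (3, 4, 5):
            for top in all_rooted_topologies(labels[:n]):
                if isinstance(top, str):
                    continue
                t = read_tree(topology_to_newick(top) + ";")
                for bits in range(2 ** n):
                    presence = {labels[i]: (bits >> i) & 1 for i in range(n)}
                    sets = fitch_state_sets(t, presence)
                    for node in t.postorder_node_iter():
                        if node.is_leaf():
                            continue
                        assert sets[node] == fitch_exhaustive(node, presence)

    def test_exhaustive_random_8_tip_trees(self, rng):
        import dendropy
        labels = [f"T{i}" for i in range(8)]
        for _ in range(5):
            tns = dendropy.TaxonNamespace(labels)
            t = dendropy.simulate.treesim.birth_death_tree(
                birth_rate=1.0, death_rate=0.0, taxon_namespace=tns,
                num_extant_tips=8, rng=__import__("random").Random(int(rng.integers(1e9))))
            for _ in range(20):
                presence = {l: int(rng.integers(2)) for l in labels}
                sets = fitch_state_sets(t, presence)
                assert sets[t.seed_node] == fitch_exhaustive(t.seed_node, presence)


class TestCafeInclusion:
    def _setup(self):
        # focal order of 4 tips: a single presence leaves the order MRCA
        # unambiguously absent ({0,1} cherry intersected with {0} cherry)
        t = read_tree(
            "((((f1:1,f2:1):1,(f3:1,f4:1):1):1,(g1:1,g2:1):2):1,out:4);")
        groups = GroupMap({"f1": "F", "f2": "F", "f3": "F", "f4": "F",
                           "g1": "G", "g2": "G", "out": "OUT"})
        species = ["f1", "f2", "f3", "f4", "g1", "g2", "out"]
        return t, groups, species

    def test_three_criteria(self):
        t, groups, species = self._setup()
        rows = [
            [1, 0, 0, 0, 0, 0, 0],   # single focal tip, MRCA absent -> excluded
            [1, 1, 1, 0, 0, 0, 0],   # MRCA presence by parsimony -> included
            [1, 0, 0, 0, 1, 0, 0],   # focal + another order -> included
            [1, 0, 0, 0, 0, 0, 1],   # focal + outgroup -> included
            [0, 0, 0, 0, 1, 1, 1],   # no focal presence -> excluded
        ]
        fams = [f"F{i}" for i in range(5)]
        m = matrix_from(rows, fams, species)
        kept = cafe_inclusion_filter(m, groups, t, "F", ["out"])
        assert kept == ["F1", "F2", "F3"]

    def test_unknown_outgroup_rejected(self):
        t, groups, species = self._setup()
        m = matrix_from([[1] * len(species)], ["F0"], species)
        with pytest.raises(ValueError, match="outgroup"):
            cafe_inclusion_filter(m, groups, t, "F", ["nope"])


class TestOrphans:
    def _coverage(self, a, b):
        cov = pd.DataFrame({"A": [a], "B": [b]}, index=["f"])
        cov["average"] = cov.mean(axis=1)
        return cov

    def test_host_threshold_boundary(self):
        assert len(find_orphans(self._coverage(1.0, 0.0))) == 1
        assert len(find_orphans(self._coverage(0.98, 0.0))) == 1
        assert len(find_orphans(self._coverage(0.97, 0.0))) == 0
        assert len(find_orphans(self._coverage(1.0, 0.1))) == 0

    def test_closed_loop_on_planted_data(self, bundle):
        cov = compute_coverage(bundle.matrix, bundle.groups)
        orphans = find_orphans(cov)
        assert {r.family for r in orphans} == set(bundle.truth.orphan_host)
        classified = classify_orphan_origin(
            orphans, bundle.hits, bundle.gene_to_family,
            bundle.gene_to_species, bundle.groups)
        for rec in classified:
            assert rec.origin == bundle.truth.orphan_origin[rec.family]

    def test_threshold_rules_per_gene(self):
        groups = GroupMap({"h1": "H", "h2": "H", "x1": "X"})
        g2f = {"g1": "fam"}
        g2s = {"g1": "h1", "x1|s": "x1", "h2|s": "h2"}
        from orthodyn.filtering import OrphanRecord
        rec = [OrphanRecord(family="fam", host_order="H", host_coverage=1.0)]

        def classify(rows):
            hits = pd.DataFrame(
                rows, columns=["qseqid", "sseqid", "pident", "evalue",
                               "bitscore", "source"])
            return classify_orphan_origin(rec, hits, g2f, g2s, groups)[0].origin

        # in-dataset hit outside host order passing all three thresholds
        assert classify([("g1", "x1|s", 50, 1e-10, 100, "in_dataset")]) \
            == "duplication_speciation"
        # hit inside the host order does not count
        assert classify([("g1", "h2|s", 50, 1e-10, 100, "in_dataset")]) \
            == "de_novo"
        # external hit needs only e-value and bit score
        assert classify([("g1", "NR_1", 20, 1e-8, 60, "external_db")]) == "hgt"
        # failing identity in-dataset + passing external -> hgt
        assert classify([("g1", "x1|s", 30, 1e-10, 100, "in_dataset"),
                         ("g1", "NR_1", 20, 1e-8, 60, "external_db")]) == "hgt"
        # no rows at all -> de novo
        assert classify([("other", "x1|s", 50, 1e-10, 100, "in_dataset")]) \
            == "de_novo"
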