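import numpy as np
import pandas as pd
import pytest
from scipy import stats

from orthodyn import (AnnotationMap, CopyMatrix, enrich, fold_change_table,
                      net_change_tally)

from _oracles import hypergeom_tail, ks_exact_p


def matrix_for(fel_counts, sel_counts, families=None):
    """Build a matrix with given per-family count rows in each lineage."""
    fel_counts = np.atleast_2d(fel_counts)
    sel_counts = np.atleast_2d(sel_counts)
    n_fam = fel_counts.shape[0]
    families = families or [f"f{i}" for i in range(n_fam)]
    fel_tips = [f"fel{i}" for i in range(fel_counts.shape[1])]
    sel_tips = [f"sel{i}" for i in range(sel_counts.shape[1])]
    df = pd.DataFrame(np.hstack([fel_counts, sel_counts]), index=families,
                      columns=fel_tips + sel_tips)
    return CopyMatrix(df), fel_tips, sel_tips


class TestFoldChangeCategories:
    @pytest.mark.parametrize("fel,sel,expect", [
        ([2] * 4, [1] * 4, "expansion"),     # fc = 2 > 1.5
        ([0] * 4, [3] * 4, "loss"),
        ([1] * 4, [0] * 4, "gain"),
        ([0] * 4, [0] * 4, "undefined"),
        ([1] * 4, [2] * 4, "contraction"),   # fc = 0.5 < 0.67
        ([1] * 4, [1] * 4, "stable"),
    ])
    def test_category_rules(self, fel, sel, expect):
        m, ft, st = matrix_for([fel], [sel])
        df = fold_change_table(m, ft, st)
        assert df.loc[0, "category"] == expect

    def test_boundary_fold_changes_are_stable(self):
        """fc exactly 1.5 or 0.67 stays stable: the thresholds are strict
        ('exceeding' / 'less than')."""
        m, ft, st = matrix_for([[3, 3], [67, 67]], [[2, 2], [100, 100]])
        df = fold_change_table(m, ft, st)
        assert (df["category"] == "stable").all()

    def test_label_swap_symmetry(self, rng):
        """Swapping FEL and SEL inverts fold changes and mirrors the
        directional categories.  The conventional cutoffs 0.67 and 1.5 are
        not exact reciprocals (1/1.5 = 0.6667), so fold changes falling in
        the narrow bands (1.4925, 1.5] and [0.6667, 0.67) are legitimately
        asymmetric and excluded."""
        fel = rng.integers(0, 6, size=(30, 8))
        sel = rng.integers(0, 6, size=(30, 8))
        m, ft, st = matrix_for(fel, sel)
        fwd = fold_change_table(m, ft, st).set_index("family")
        rev = fold_change_table(m, st, ft).set_index("family")
        swap = {"loss": "gain", "gain": "loss", "contraction": "expansion",
                "expansion": "contraction", "stable": "stable",
                "undefined": "undefined"}
        for fam in fwd.index:
            fc_f, fc_r = fwd.loc[fam, "fold_change"], rev.loc[fam, "fold_change"]
            if np.isfinite(fc_f) and fc_f > 0:
                assert fc_r == pytest.approx(1 / fc_f)
                if 1 / 1.5 <= min(fc_f, fc_r) < 0.67:
                    continue  # asymmetry band of the conventional cutoffs
            assert rev.loc[fam, "category"] == swap[fwd.loc[fam, "category"]]

    def test_species_order_invariance(self, rng):
        fel = rng.integers(0, 5, size=(20, 6))
        sel = rng.integers(0, 5, size=(20, 6))
        m, ft, st = matrix_for(fel, sel)
        a = fold_change_table(m, ft, st)
        b = fold_change_table(m, ft[::-1], st[::-1])
        pd.testing.assert_frame_equal(a, b)

    def test_empty_lineage_rejected(self):
        m, ft, st = matrix_for([[1, 1]], [[1, 1]])
        with pytest.raises(ValueError, match="nonempty"):
            fold_change_table(m, [], st)


class TestFoldChangeSignificance:
    def test_ks_extreme_case_matches_enumeration(self):
        """All-zero FEL vs all-five SEL at n=m=10: D=1 and the exact
        two-sided p equals 2 * 10! * 10! / 20!."""
        m, ft, st = matrix_for([[0] * 10], [[5] * 10])
        df = fold_change_table(m, ft, st)
        from math import comb
        expect = 2 / comb(20, 10)
        assert df.loc[0, "p_raw"] == pytest.approx(expect, rel=1e-9)
        # Bonferroni multiplies by the number of tested families
        m3, ft3, st3 = matrix_for([[0] * 10] * 3, [[5] * 10] * 3)
        df3 = fold_change_table(m3, ft3, st3)
        assert np.allclose(df3["p_adj"], 3 * df3["p_raw"])

    def test_ks_p_matches_enumeration_on_random_noties_samples(self, rng):
        a = rng.normal(size=5)
        b = rng.normal(1.0, 1, size=5)
        d, p_enum = ks_exact_p(a, b)
        p_scipy = stats.ks_2samp(a, b, method="exact").pvalue
        assert p_scipy == pytest.approx(p_enum, rel=1e-9)

    def test_undefined_families_not_counted_in_bonferroni(self):
        m, ft, st = matrix_for([[0] * 6, [2] * 6], [[0] * 6, [5] * 6])
        df = fold_change_table(m, ft, st).set_index("family")
        assert np.isnan(df.loc["f0", "p_raw"])
        assert df.loc["f1", "p_adj"] == pytest.approx(df.loc["f1", "p_raw"])


class TestPlantedRecovery:
    def test_noiseless_blocks_classified_exactly(self):
        from conftest import noiseless_config
        from orthodyn import simulate_all
        b = simulate_all(noiseless_config())
        truth = b.truth
        fel = truth.fel_tips[b.config.fel_order]
        order_tips = b.groups.species_of(b.config.fel_order)
        sel = [t for t in order_tips if t not in set(fel)]
        df = fold_change_table(b.matrix, fel, sel).set_index("family")
        # contraction factor 0.4 -> fc = 0.4 for the contracted block
        expected = {"contracted_in_fel": "contraction", "lost_in_fel": "loss",
                    "gained_in_fel": "gain", "core": "stable"}
        for block, cat in expected.items():
            fams = truth.families_of(block)
            got = df.loc[fams, "category"]
            assert (got == cat).all(), f"{block}: {got.value_counts().to_dict()}"

    def test_poisson_noise_recalls(self, default_bundle):
        b = default_bundle
        truth = b.truth
        fel = truth.fel_tips[b.config.fel_order]
        order_tips = b.groups.species_of(b.config.fel_order)
        sel = [t for t in order_tips if t not in set(fel)]
        df = fold_change_table(b.matrix, fel, sel).set_index("family")
        lost = truth.families_of("lost_in_fel")
        assert (df.loc[lost, "category"] == "loss").all()  # structural zeros
        contracted = truth.families_of("contracted_in_fel")
        recall = (df.loc[contracted, "category"] == "contraction").mean()
        assert recall >= 0.9


class TestNetChange:
    def test_tally_and_categories(self):
        deltas = pd.DataFrame({"family": ["f1", "f1", "f2", "f2", "f3"],
                               "delta": [2, -1, 1, -1, -4]})
        net = net_change_tally(deltas).set_index("family")
        assert net.loc["f1", "net_change"] == 1
        assert net.loc["f1", "category"] == "expansion"
        assert net.loc["f2", "category"] == "no_change"
        assert net.loc["f3", "category"] == "contraction"

    def test_non_integer_deltas_rejected(self):
        with pytest.raises(ValueError, match="integer"):
            net_change_tally(pd.DataFrame({"family": ["f"], "delta": [0.5]}))

    def test_consistent_history_on_random_trees(self, rng):
        """Deltas generated from an explicit ancestral history sum to the
        independently accumulated per-branch total."""
        import dendropy
        for _ in range(5):
            labels = [f"T{i}" for i in range(8)]
            tns = dendropy.TaxonNamespace(labels)
            t = dendropy.simulate.treesim.birth_death_tree(
                birth_rate=1.0, death_rate=0.0, taxon_namespace=tns,
                num_extant_tips=8,
                rng=__import__("random").Random(int(rng.integers(1e9))))
            state = {id(t.seed_node): int(rng.integers(1, 6))}
            rows, total = [], 0
            for node in t.preorder_node_iter():
                if node is t.seed_node:
                    continue
                parent = state[id(node.parent_node)]
                child = max(0, parent + int(rng.integers(-2, 3)))
                state[id(node)] = child
                rows.append(("fam", child - parent))
                total += child - parent
            net = net_change_tally(pd.DataFrame(rows, columns=["family", "delta"]))
            assert net.loc[0, "net_change"] == total


class TestEnrichment:
    def _ann(self, mapping):
        return AnnotationMap({f: frozenset(ts) for f, ts in mapping.items()})

    def test_matches_hypergeometric_tail_oracle(self):
        """k=5 of n=10 targets annotated, K=10 of N=100 background."""
        background = [f"f{i}" for i in range(100)]
        target = background[:10]
        ann = self._ann({f: {"GO:X"} for f in background[:5] + background[20:25]})
        df = enrich(target, background, ann)
        expect = hypergeom_tail(5, 10, 10, 100)
        assert df.loc[0, "p"] == pytest.approx(expect, abs=1e-12)

    def test_target_equals_background_gives_p_one(self):
        background = [f"f{i}" for i in range(20)]
        ann = self._ann({f: {"GO:A", "GO:B"} for f in background})
        df = enrich(background, background, ann)
        assert np.allclose(df["p"], 1.0)

    def test_untested_terms_absent(self):
        background = ["f1", "f2", "f3"]
        ann = self._ann({"f1": {"GO:A"}, "f9": {"GO:Z"}})
        df = enrich(["f1"], background, ann)
        assert set(df["term"]) == {"GO:A"}

    def test_bh_preserves_p_ordering(self, rng):
        background = [f"f{i}" for i in range(60)]
        mapping = {}
        for i, f in enumerate(background):
            mapping[f] = {f"GO:{j}" for j in rng.choice(12, 3, replace=False)}
        ann = self._ann(mapping)
        df = enrich(background[:15], background, ann)
        assert (df["p"].is_monotonic_increasing
                and df["p_adj"].is_monotonic_increasing)
        assert (df["p_adj"] >= df["p"] - 1e-15).all()

    def test_planted_block_terms_enriched(self, bundle):
        truth = bundle.truth
        target = truth.families_of("contracted_in_fel")
        background = sorted(bundle.truth.family_block)
        df = enrich(target, background, bundle.annotations)
        top = df.iloc[0]
        assert top["term"].startswith("T:contracted_in_fel")
        assert top["p_adj"] < 1e-6
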