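import itertools

import numpy as np
import pandas as pd
import pytest

from phyloloc import paralog_localization as pl
from phyloloc.vocab import BRANCH_LABELS, COMPARTMENTS


class TestClassifyDuplication:
    @pytest.mark.parametrize(
        "parent,offspring,expected",
        [
            ("br-2", "br-1", "ancient"),
            ("br-2", "br0", "ancient"),
            ("br-1", "br0", "ancient"),
            ("br0", "br3", "recent"),
            ("br-2", "br1", "recent"),
            ("br2", "br6", "recent"),
        ],
    )
    def test_rule_set(self, parent, offspring, expected):
        assert pl.classify_duplication(parent, offspring) == expected

    def test_parent_must_be_older(self):
        with pytest.raises(ValueError):
            pl.classify_duplication("br3", "br3")
        with pytest.raises(ValueError):
            pl.classify_duplication("br3", "br0")

    def test_exactly_three_ancient_ordered_pairs(self):
        ancient = [
            (p, o)
            for p, o in itertools.permutations(BRANCH_LABELS, 2)
            if BRANCH_LABELS.index(p) < BRANCH_LABELS.index(o)
            and pl.classify_duplication(p, o) == "ancient"
        ]
        assert len(ancient) == 3


class TestClassifyChange:
    N = frozenset({"Nucleus"})
    NC = frozenset({"Nucleus", "Cytoplasm"})
    NE = frozenset({"Nucleus", "Extracellular"})
    E = frozenset({"Extracellular"})
    CE = frozenset({"Cytoplasm", "Extracellular"})

    @pytest.mark.parametrize(
        "parent,offspring,expected",
        [
            (N, N, "K"),
            (N, NE, "KE"),
            (NC, N, "S"),
            (N, E, "E"),
            (NC, CE, "SE"),
        ],
    )
    def test_defining_examples(self, parent, offspring, expected):
        assert pl.classify_change(parent, offspring) == expected

    def test_empty_sets_rejected(self):
        with pytest.raises(ValueError):
            pl.classify_change(frozenset(), self.N)

    def test_partition_over_random_set_pairs(self):
        """Exactly one label fires for every random non-empty set pair, and
        each label's defining set relation holds."""
        rng = np.random.default_rng(13)
        for _ in range(10_000):
            p = frozenset(
                rng.choice(COMPARTMENTS, size=rng.integers(1, 5), replace=False)
            )
            o = frozenset(
                rng.choice(COMPARTMENTS, size=rng.integers(1, 5), replace=False)
            )
            label = pl.classify_change(p, o)
            relations = {
                "K": o == p,
                "KE": p < o,
                "S": o < p,
                "E": not (o & p),
                "SE": bool(o & p) and bool(o - p) and bool(p - o),
            }
            assert relations[label]
            assert sum(relations.values()) == 1


def _pair(parent, offspring, pb, ob, p_set, o_set):
    return pl.ParalogPair(
        parent, offspring, pb, ob, p_set, o_set,
        pl.classify_duplication(pb, ob), pl.classify_change(p_set, o_set),
    )


class TestClassifyPairs:
    def test_orientation_filters_and_attrition(self):
        pairs = pd.DataFrame(
            [
                ("g_old", "g_young"),     # kept (reversed orientation)
                ("g_a", "g_b"),           # equal branch -> dropped
                ("g_multi", "g_young2"),  # g_multi reused -> both dropped
                ("g_multi", "g_young3"),
                ("g_unloc", "g_young4"),  # empty localization -> dropped
                ("g_missing", "g_young"),  # undated -> dropped
            ],
            columns=["gene_id", "paralog_gene_id"],
        )
        branch_of = {
            "g_old": "br-2", "g_young": "br3", "g_a": "br1", "g_b": "br1",
            "g_multi": "br-1", "g_young2": "br2", "g_young3": "br4",
            "g_unloc": "br0", "g_young4": "br5",
        }
        called = {g: frozenset({"Nucleus"}) for g in branch_of}
        called["g_unloc"] = frozenset()
        classified, attrition = pl.classify_pairs(pairs, branch_of, called)
        assert attrition["undated"] == 1
        assert attrition["equal_branch"] == 1
        assert attrition["not_one_to_one"] >= 2
        assert attrition["unlocalized"] == 1
        # the reversed pair is oriented old -> young
        kept = {(p.parent, p.offspring) for p in classified}
        assert ("g_old", "g_young") in kept

    def test_one_to_one_counts_both_columns(self):
        pairs = pd.DataFrame(
            [("a", "b"), ("c", "b")], columns=["gene_id", "paralog_gene_id"]
        )
        branch_of = {"a": "br-2", "b": "br3", "c": "br0"}
        called = {g: frozenset({"Nucleus"}) for g in branch_of}
        classified, attrition = pl.classify_pairs(pairs, branch_of, called)
        assert classified == []
        assert attrition["not_one_to_one"] == 2


class TestPatternSpectrum:
    def test_all_k(self):
        pairs = [_pair(f"p{i}", f"o{i}", "br0", "br3",
                       frozenset({"Nucleus"}), frozenset({"Nucleus"}))
                 for i in range(5)]
        table = pl.pattern_spectrum(pairs)
        row = table[(table["stratum"] == "all") & (table["pattern"] == "K")].iloc[0]
        assert row["percent"] == 100.0

    def test_mixed_tally(self):
        pairs = [
            _pair("p1", "o1", "br0", "br3", frozenset({"Nucleus"}), frozenset({"Nucleus"})),
            _pair("p2", "o2", "br0", "br3", frozenset({"Nucleus"}), frozenset({"Nucleus"})),
            _pair("p3", "o3", "br0", "br3", frozenset({"Nucleus"}), frozenset({"Extracellular"})),
            _pair("p4", "o4", "br0", "br3",
                  frozenset({"Nucleus", "Cytoplasm"}),
                  frozenset({"Cytoplasm", "Extracellular"})),
        ]
        table = pl.pattern_spectrum(pairs)
        sub = table[table["stratum"] == "all"].set_index("pattern")["percent"]
        assert sub["K"] == 50.0 and sub["E"] == 25.0 and sub["SE"] == 25.0
        assert sub["S"] == 0.0 and sub["KE"] == 0.0

    def test_percentages_sum_to_100_and_order_invariant(self):
        rng = np.random.default_rng(3)
        pairs = []
        for i in range(30):
            p = frozenset(rng.choice(COMPARTMENTS, size=rng.integers(1, 4), replace=False))
            o = frozenset(rng.choice(COMPARTMENTS, size=rng.integers(1, 4), replace=False))
            pairs.append(_pair(f"p{i}", f"o{i}", "br-2", "br4", p, o))
        t1 = pl.pattern_spectrum(pairs)
        t2 = pl.pattern_spectrum(pairs[::-1])
        assert t1.equals(t2)
        assert t1[t1["stratum"] == "all"]["percent"].sum() == pytest.approx(100.0)

    def test_spectrum_recovery_from_configured_mix(self):
        """The generator's configured K/SE/S/E/KE fractions are recovered by
        the classifier within multinomial tolerance."""
        from phyloloc import synthetic_data as sd
        from phyloloc.localization import called_sets_from_table

        fractions = {"K": 0.5, "KE": 0.2, "S": 0.15, "E": 0.1, "SE": 0.05}
        params = sd.SimulationParams(
            n_genes=1500, n_paralog_pairs=400, n_edges=0,
            pattern_fractions=fractions, seed=23,
        )
        ds = sd.simulate(params)
        called = called_sets_from_table(ds.localization)
        classified, _ = pl.classify_pairs(
            ds.paralog_pairs, ds.truth.true_branch, called
        )
        # offspring must sit on a non-oldest branch, which caps the pair count
        assert len(classified) >= 200
        table = pl.pattern_spectrum(classified).query("stratum == 'all'")
        n = len(classified)
        for _, row in table.iterrows():
            p = fractions[row["pattern"]]
            se = np.sqrt(p * (1 - p) / n)
            assert abs(row["percent"] / 100 - p) <= 4 * se


class TestKvsNonK:
    def test_identical_sequences_not_significant(self):
        pairs = [
            _pair("p1", "o1", "br0", "br3", frozenset({"Nucleus"}), frozenset({"Nucleus"})),
            _pair("p2", "o2", "br0", "br3", frozenset({"Nucleus"}), frozenset({"Extracellular"})),
        ]
        seqs = {k: "MKVLYACDEF" for k in ("p1", "o1", "p2", "o2")}
        res = pl.k_vs_nonk_comparison(pairs, seqs)
        assert res.similarity_p > 0.5

    def test_k_strictly_higher_identity_significant(self):
        rng = np.random.default_rng(4)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        pairs, seqs = [], {}
        for i in range(12):
            base = "".join(rng.choice(aas, size=40))
            seqs[f"kp{i}"] = base
            seqs[f"ko{i}"] = base  # identity 1.0
            pairs.append(_pair(f"kp{i}", f"ko{i}", "br0", "br3",
                               frozenset({"Nucleus"}), frozenset({"Nucleus"})))
        for i in range(12):
            base = "".join(rng.choice(aas, size=40))
            arr = list(base)
            for pos in rng.choice(40, size=12, replace=False):
                arr[pos] = str(rng.choice([a for a in aas if a != arr[pos]]))
            seqs[f"np{i}"] = base
            seqs[f"no{i}"] = "".join(arr)
            pairs.append(_pair(f"np{i}", f"no{i}", "br0", "br3",
                               frozenset({"Nucleus"}), frozenset({"Extracellular"})))
        res = pl.k_vs_nonk_comparison(pairs, seqs)
        assert res.similarity_p < 0.05
        assert min(res.k_similarity) > max(res.nonk_similarity)

    def test_missing_sequences_dropped_with_count(self):
        pairs = [
            _pair("p1", "o1", "br0", "br3", frozenset({"Nucleus"}), frozenset({"Nucleus"})),
        ]
        res = pl.k_vs_nonk_comparison(pairs, {})
        assert res.n_dropped == 1

    def test_synthetic_nonk_mutations_concentrate_nterminal(self):
        """Generator pairs built with N-terminal-concentrated substitutions
        show a higher N-terminal mutation fraction in the non-K group."""
        from phyloloc import synthetic_data as sd
        from phyloloc.localization import called_sets_from_table

        params = sd.SimulationParams(
            n_genes=1200, n_paralog_pairs=250, n_edges=0, seed=31,
        )
        ds = sd.simulate(params)
        called = called_sets_from_table(ds.localization)
        classified, _ = pl.classify_pairs(
            ds.paralog_pairs, ds.truth.true_branch, called
        )
        res = pl.k_vs_nonk_comparison(classified, ds.sequences)
        k_frac = res.k_bins[0] / max(1, sum(res.k_bins))
        nonk_frac = res.nonk_bins[0] / max(1, sum(res.nonk_bins))
        assert nonk_frac > k_frac
        assert res.position_p < 0.05
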