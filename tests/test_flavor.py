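import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flavoromics.flavor import (
    build_sensory_network,
    class_composition,
    classify_contribution,
    compute_roav,
    presence_by_group,
    roav_by_group,
    venn_partition,
)
from flavoromics.tables_io import validate_annotations


def make_ann(ot_by_id, descriptors=None, classes=None):
    ids = list(ot_by_id)
    return validate_annotations(
        pd.DataFrame(
            {
                "compound_name": ids,
                "cas": [None] * len(ids),
                "chemical_class": (
                    classes if classes else ["others"] * len(ids)
                ),
                "theoretical_ri": [1000.0] * len(ids),
                "odor_threshold": [ot_by_id[i] for i in ids],
                "descriptors": descriptors or [["sweet"]] * len(ids),
            },
            index=pd.Index(ids, name="feature_id"),
        )
    )


class TestRoav:
    def test_direct_formula(self):
        ann = make_ann({"A": 1.0, "B": 1.0})
        out = compute_roav(pd.Series({"A": 5.0, "B": 1.0}), ann)
        assert out.loc["A", "oav"] == 5.0
        assert out.loc["B", "oav"] == 1.0
        assert out.loc["A", "roav"] == 100.0
        assert out.loc["B", "roav"] == 20.0
        assert out.loc["A", "contribution_class"] == "key"
        assert out.loc["B", "contribution_class"] == "key"

    def test_scale_invariance(self, rng):
        ids = [f"v{i}" for i in range(10)]
        ann = make_ann({i: float(t) for i, t in zip(ids, rng.uniform(0.1, 5, 10))})
        contents = pd.Series(rng.uniform(0.5, 50, 10), index=ids)
        base = compute_roav(contents, ann)["roav"]
        for k in (0.001, 7.3, 1e6):
            scaled = compute_roav(contents * k, ann)["roav"]
            np.testing.assert_allclose(scaled, base, rtol=1e-12)

    def test_matches_two_pass_oracle(self, rng):
        ids = [f"v{i}" for i in range(30)]
        ot = rng.uniform(0.01, 10, 30)
        c = rng.uniform(0, 100, 30)
        ann = make_ann(dict(zip(ids, ot)))
        out = compute_roav(pd.Series(c, index=ids), ann)
        oav = c / ot
        oracle = 100.0 * oav / oav.max()
        np.testing.assert_allclose(out["roav"], oracle, atol=1e-12)

    def test_max_roav_exactly_100_and_rank_preserved(self, small_study, rng):
        from flavoromics.preprocess import preprocess_table

        vocs, _ = preprocess_table(
            small_study.vocs, peaks=small_study.voc_peaks,
            annotations=small_study.annotations,
        )
        tables = roav_by_group(vocs, small_study.annotations)
        assert set(tables) == {"GL", "SN", "XZ"}
        for frame in tables.values():
            scored = frame.dropna(subset=["roav"])
            assert scored["roav"].max() == 100.0
            assert scored["roav"].between(0, 100).all()
            order_oav = scored["oav"].rank()
            order_roav = scored["roav"].rank()
            pd.testing.assert_series_equal(
                order_oav, order_roav, check_names=False
            )

    def test_compound_without_threshold_listed_unscored_never_reference(self):
        ann = make_ann({"A": 1.0, "B": np.nan})
        out = compute_roav(pd.Series({"A": 1.0, "B": 1e9}), ann)
        assert np.isnan(out.loc["B", "oav"])
        assert out.loc["B", "contribution_class"] == "unscored"
        assert out.loc["A", "roav"] == 100.0  # huge unscored B is not OAV_max

    def test_all_zero_oav_is_error(self):
        ann = make_ann({"A": 1.0})
        with pytest.raises(ValueError, match="normalize"):
            compute_roav(pd.Series({"A": 0.0}), ann)

    def test_negative_content_rejected(self):
        ann = make_ann({"A": 1.0})
        with pytest.raises(ValueError, match="non-negative"):
            compute_roav(pd.Series({"A": -1.0}), ann)


class TestContributionClasses:
    @pytest.mark.parametrize(
        "roav, expected",
        [
            (1.5, "key"),
            (1.0, "moderate"),   # key requires strictly exceeding 1
            (0.1, "moderate"),   # inclusive lower bound
            (0.0999, "minor"),
            (100.0, "key"),
            (np.nan, "unscored"),
        ],
    )
    def test_boundaries(self, roav, expected):
        out = classify_contribution(pd.Series([roav]))
        assert out.iloc[0] == expected


class TestClassComposition:
    def test_single_class_is_100_percent(self, tiny_table):
        from flavoromics.preprocess import normalize_internal_standard

        t = normalize_internal_standard(tiny_table)
        ann = make_ann(
            {f: 1.0 for f in t.feature_ids},
            classes=["esters"] * len(t.feature_ids),
        )
        comp = class_composition(t, ann)
        np.testing.assert_allclose(comp["esters"], 100.0)

    def test_two_equal_classes_split_50_50(self):
        from flavoromics.tables_io import FeatureTable

        values = pd.DataFrame(
            {"a": [2.0, 2.0], "b": [2.0, 2.0]}, index=["s1", "s2"]
        )
        t = FeatureTable(values, pd.Series(["G", "G"], index=values.index))
        ann = make_ann({"a": 1.0, "b": 1.0}, classes=["esters", "ketones"])
        comp = class_composition(t, ann)
        assert comp.loc["G", "esters"] == pytest.approx(50.0)
        assert comp.loc["G", "ketones"] == pytest.approx(50.0)

    def test_matches_hand_summed_oracle_and_rows_sum_100(self, small_study):
        from flavoromics.preprocess import preprocess_table

        vocs, _ = preprocess_table(
            small_study.vocs, peaks=small_study.voc_peaks,
            annotations=small_study.annotations,
        )
        comp = class_composition(vocs, small_study.annotations)
        np.testing.assert_allclose(comp.sum(axis=1), 100.0, atol=1e-9)
        means = vocs.values.groupby(vocs.group_labels).mean()
        cls = small_study.annotations["chemical_class"]
        g = comp.index[0]
        for c in comp.columns:
            members = [f for f in vocs.feature_ids if cls.get(f) == c]
            expected = means.loc[g, members].sum() / means.loc[g].sum() * 100
            assert comp.loc[g, c] == pytest.approx(expected, abs=1e-9)


class TestVenn:
    def test_identical_sets_all_in_center(self):
        s = {"GL": set("abcde"), "SN": set("abcde"), "XZ": set("abcde")}
        regions = venn_partition(s)
        assert len(regions[("GL", "SN", "XZ")]) == 5
        assert all(
            not v for k, v in regions.items() if k != ("GL", "SN", "XZ")
        )

    def test_pairwise_disjoint_sets(self):
        s = {"GL": {"a"}, "SN": {"b", "c"}, "XZ": {"d"}}
        regions = venn_partition(s)
        assert regions[("GL",)] == {"a"}
        assert regions[("SN",)] == {"b", "c"}
        assert regions[("XZ",)] == {"d"}
        assert all(len(k) == 1 or not v for k, v in regions.items())

    @given(st.integers(min_value=0, max_value=2**30))
    @settings(max_examples=30, deadline=None)
    def test_partition_property_on_random_triples(self, seed):
        r = np.random.default_rng(seed)
        universe = [f"x{i}" for i in range(40)]
        s = {
            g: set(r.choice(universe, size=r.integers(0, 30), replace=False))
            for g in ("GL", "SN", "XZ")
        }
        regions = venn_partition(s)
        union = set.union(*s.values())
        assert set.union(set(), *regions.values()) == union
        flat = [x for v in regions.values() for x in v]
        assert len(flat) == len(set(flat))  # pairwise disjoint
        for g in s:  # per-group totals derivable
            total = sum(len(v) for k, v in regions.items() if g in k)
            assert total == len(s[g])

    def test_wrong_number_of_sets_rejected(self):
        with pytest.raises(ValueError, match="3"):
            venn_partition({"A": set(), "B": set()})

    def test_presence_by_group(self, small_study):
        pres = presence_by_group(small_study.vocs)
        assert set(pres) == {"GL", "SN", "XZ"}
        for members in pres.values():
            assert members <= set(small_study.vocs.feature_ids)


class TestSensoryNetwork:
    def test_single_voc_two_descriptors(self):
        ann = make_ann({"v1": 1.0}, descriptors=[["sweet", "fruity"]])
        g = build_sensory_network(["v1"], ann)
        assert g.number_of_edges() == 2
        assert g.nodes["sweet"]["degree"] == 1
        assert g.nodes["fruity"]["degree"] == 1
        assert g.nodes["v1"]["kind"] == "voc"

    def test_top_k_keeps_highest_degree_attribute(self):
        ann = make_ann(
            {f"v{i}": 1.0 for i in range(4)},
            descriptors=[["green"], ["green"], ["green"], ["waxy"]],
        )
        g = build_sensory_network([f"v{i}" for i in range(4)], ann, top_k=1)
        attrs = [n for n, d in g.nodes(data=True) if d["kind"] == "attribute"]
        assert attrs == ["green"]

    def test_degree_ranking_matches_brute_force_and_order_invariant(self, rng):
        ids = [f"v{i}" for i in range(20)]
        vocab = ["sweet", "fruity", "green", "waxy", "floral", "fatty", "rose"]
        desc = [
            sorted(rng.choice(vocab, size=rng.integers(1, 4), replace=False))
            for _ in ids
        ]
        ann = make_ann({i: 1.0 for i in ids}, descriptors=desc)
        g = build_sensory_network(ids, ann, top_k=3)
        counts: dict[str, int] = {}
        for lst in desc:
            for d in lst:
                counts[d] = counts.get(d, 0) + 1
        oracle = sorted(counts, key=lambda d: (-counts[d], d))[:3]
        attrs = {n for n, d in g.nodes(data=True) if d["kind"] == "attribute"}
        assert attrs == set(oracle)
        g2 = build_sensory_network(list(reversed(ids)), ann, top_k=3)
        assert attrs == {
            n for n, d in g2.nodes(data=True) if d["kind"] == "attribute"
        }

    def test_no_descriptors_warns_and_returns_empty(self):
        ann = make_ann({"v1": 1.0}, descriptors=[[]])
        with pytest.warns(UserWarning, match="empty network"):
            g = build_sensory_network(["v1"], ann)
        assert g.number_of_nodes() == 0
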