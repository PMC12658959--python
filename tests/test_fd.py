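"""Functional entities, hull/dispersion/evenness metrics, FUSE."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from depthfd.fd import (
    alpha_fd_filter,
    assign_functional_entities,
    classify_habitat,
    community_fspe,
    fdis,
    fe_metrics,
    feve,
    fric,
    fspe,
    fun,
    fuse,
    fuse_ranking,
    ge_from_iucn,
    hull_volume,
    metric_correlation_summary,
)
from depthfd.processing import CommunityMatrix
from depthfd.traits import Trait, TraitScheme


def tiny_scheme():
    return TraitScheme({
        "x": Trait("x", ("a", "b"), False),
        "y": Trait("y", ("p", "q"), False),
    })


class TestFunctionalEntities:
    def test_all_identical_share_one_fe(self):
        t = pd.DataFrame({"x": ["a"] * 4, "y": ["p"] * 4},
                         index=list("wxyz"))
        fe = assign_functional_entities(t, tiny_scheme())
        assert fe["fe_id"].nunique() == 1

    def test_all_distinct_get_own_fe(self):
        t = pd.DataFrame({"x": ["a", "a", "b", "b"], "y": ["p", "q", "p", "q"]},
                         index=list("wxyz"))
        fe = assign_functional_entities(t, tiny_scheme())
        assert fe["fe_id"].nunique() == 4

    def test_partition_sizes(self):
        t = pd.DataFrame(
            {"x": ["a"] * 4 + ["b", "b"], "y": ["p"] * 4 + ["p", "q"]},
            index=list("uvwxyz"),
        )
        fe = assign_functional_entities(t, tiny_scheme())
        sizes = sorted(fe.groupby("fe_id").size(), reverse=True)
        assert sizes == [4, 1, 1]

    def test_fe_ids_deterministic(self):
        t = pd.DataFrame({"x": ["b", "a"], "y": ["q", "p"]}, index=["s2", "s1"])
        fe1 = assign_functional_entities(t, tiny_scheme())
        fe2 = assign_functional_entities(t.iloc[::-1], tiny_scheme())
        assert fe1.loc["s1", "fe_id"] == fe2.loc["s1", "fe_id"]


class TestFEMetrics:
    @staticmethod
    def _fe(sizes):
        rows = []
        n = 0
        for k, s in enumerate(sizes):
            for _ in range(s):
                rows.append({"fe_id": f"FE{k}", "combination": k})
                n += 1
        return pd.DataFrame(rows, index=[f"sp{i}" for i in range(n)])

    def test_hand_formulas_4_1_1(self):
        m = fe_metrics(self._fe([4, 1, 1]))
        assert m.fred == pytest.approx(2.0)
        assert m.fvul == pytest.approx(200 / 3)  # 66.67%
        assert m.fover == pytest.approx(100 * 2 / 6)  # 33.33%

    def test_all_singletons(self):
        m = fe_metrics(self._fe([1] * 5))
        assert m.fred == 1.0 and m.fvul == 100.0 and m.fover == 0.0

    def test_single_crowded_fe(self):
        m = fe_metrics(self._fe([7]))
        assert m.fred == 7.0 and m.fvul == 0.0

    def test_identity_sum(self):
        m = fe_metrics(self._fe([3, 2, 1, 1]))
        assert m.fred * m.n_entities == pytest.approx(m.n_species)

    def test_community_subset(self):
        fe = self._fe([4, 1, 1])
        m = fe_metrics(fe, community=["sp0", "sp1", "sp4"])
        assert m.n_species == 3 and m.n_entities == 2
        assert m.fred == pytest.approx(1.5)

    def test_empty_community_rejected(self):
        with pytest.raises(ValueError):
            fe_metrics(self._fe([2]), community=[])


def cayley_menger_volume(points):
    """Simplex volume from the Cayley-Menger determinant (independent oracle)."""
    pts = np.asarray(points, dtype=float)
    n = pts.shape[0] - 1  # simplex dimension
    d2 = ((pts[:, None] - pts[None, :]) ** 2).sum(-1)
    cm = np.ones((n + 2, n + 2))
    cm[0, 0] = 0.0
    cm[1:, 1:] = d2
    det = np.linalg.det(cm)
    coef = (-1) ** (n + 1) / (2**n * math.factorial(n) ** 2)
    return math.sqrt(coef * det)


class TestFRic:
    def test_pool_normalizes_to_one(self, space_factory):
        rng = np.random.default_rng(0)
        space = space_factory(rng.normal(size=(12, 3)))
        assert fric(space, space.species) == pytest.approx(1.0)

    def test_interior_subset_below_one(self, space_factory):
        pts = np.array([[0, 0], [4, 0], [0, 4], [4, 4], [1, 1], [2, 1], [1, 2]],
                       dtype=float)
        space = space_factory(pts)
        inner = ["sp4", "sp5", "sp6"]
        assert 0 < fric(space, inner) < 1

    def test_simplex_volume_matches_cayley_menger(self, space_factory):
        """5-point simplices in 4-D against the determinant oracle."""
        rng = np.random.default_rng(1)
        for _ in range(5):
            pts = rng.normal(size=(5, 4))
            assert hull_volume(pts) == pytest.approx(
                cayley_menger_volume(pts), abs=1e-9, rel=1e-9
            )

    def test_adding_species_never_shrinks_hull(self, space_factory):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(15, 3))
        space = space_factory(pts)
        sub = space.species[:6]
        grown = space.species[:10]
        v1 = fric(space, sub)
        v2 = fric(space, grown)
        assert v2 >= v1 - 1e-12

    def test_degenerate_set_undefined(self, space_factory):
        space = space_factory(np.array([[0, 0], [1, 1], [2, 2], [3, 3.0]]))
        assert math.isnan(fric(space, space.species))


class TestFDis:
    def test_single_species_zero(self, space_factory):
        space = space_factory(np.array([[1.0, 2.0], [3.0, 4.0]]))
        w = pd.Series({"sp0": 5.0})
        assert fdis(space, w) == 0.0

    def test_two_equal_weights_half_distance(self, space_factory):
        space = space_factory(np.array([[0.0, 0.0], [0.0, 3.0]]))
        w = pd.Series({"sp0": 2.0, "sp1": 2.0})
        assert fdis(space, w) == pytest.approx(1.5)

    def test_weighted_1d_by_hand(self, space_factory):
        """Positions 0 and 1 with weights 3 and 1: centroid 0.25 from the
        heavy point, FDis = (3*0.25 + 1*0.75)/4 = 0.375."""
        space = space_factory(np.array([0.0, 1.0]))
        w = pd.Series({"sp0": 3.0, "sp1": 1.0})
        assert fdis(space, w) == pytest.approx(0.375)

    def test_translation_rotation_invariance(self, space_factory):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(8, 2))
        w = pd.Series(rng.uniform(1, 5, 8), index=[f"sp{i}" for i in range(8)])
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        moved = pts @ rot.T + np.array([5.0, -2.0])
        assert fdis(space_factory(pts), w) == pytest.approx(
            fdis(space_factory(moved), w), rel=1e-9
        )


class TestFEve:
    def test_equally_spaced_chain_is_one(self, space_factory):
        space = space_factory(np.arange(5, dtype=float))
        w = pd.Series(1.0, index=space.species)
        assert feve(space, w) == pytest.approx(1.0)

    def test_three_point_hand_formula(self, space_factory):
        """Chain 0-1-10 with equal abundances: branch lengths 1 and 9.

        EW = (1/(2/3), 9/(2/3)); PEW = (0.1, 0.9);
        FEve = (min(0.1,0.5) + min(0.9,0.5) - 0.5) / (1 - 0.5) = 0.2.
        """
        space = space_factory(np.array([0.0, 1.0, 10.0]))
        w = pd.Series(1.0, index=space.species)
        assert feve(space, w) == pytest.approx(0.2)

    def test_abundance_scale_invariance(self, space_factory):
        rng = np.random.default_rng(4)
        space = space_factory(rng.normal(size=(7, 3)))
        w = pd.Series(rng.uniform(1, 4, 7), index=space.species)
        assert feve(space, w) == pytest.approx(feve(space, 17.3 * w), rel=1e-12)

    def test_below_three_species_undefined(self, space_factory):
        space = space_factory(np.array([0.0, 1.0]))
        assert math.isnan(feve(space, pd.Series(1.0, index=space.species)))


class TestFSpeFUn:
    def test_centroid_species_zero_peripheral_one(self, space_factory):
        # symmetric cloud: the pool centroid sits exactly on sp0
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [-1.0, 0.0],
                        [0.0, 1.0], [0.0, -1.0], [4.0, 0.0], [-4.0, 0.0]])
        space = space_factory(pts)
        s = fspe(space)
        assert s["sp0"] == 0.0
        assert s.max() == pytest.approx(1.0)
        assert set(s[s == 1.0].index) == {"sp5", "sp6"}

    def test_community_of_one(self, space_factory):
        space = space_factory(np.array([0.0, 1.0, 2.0]))
        s = fspe(space)
        assert community_fspe(s, pd.Series({"sp2": 3.0})) == \
            pytest.approx(s["sp2"])

    def test_fun_exact_duplicate_zero(self, space_factory):
        pts = np.array([[0.0, 0.0], [0.0, 0.0], [3.0, 0.0], [5.0, 5.0]])
        u = fun(space_factory(pts), k_neighbors=1)
        assert u["sp0"] == 0.0 and u["sp1"] == 0.0
        assert u.max() == 1.0

    def test_fun_isolated_point_maximal(self, space_factory):
        space = space_factory(np.array([0.0, 0.1, 0.2, 5.0]))
        u = fun(space, k_neighbors=2)
        assert u.idxmax() == "sp3" and u["sp3"] == 1.0

    def test_fun_scaling_invariance(self, space_factory):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(9, 3))
        u1 = fun(space_factory(pts), k_neighbors=3)
        u2 = fun(space_factory(4.2 * pts), k_neighbors=3)
        pd.testing.assert_series_equal(u1, u2, atol=1e-12)

    def test_small_pool_reduces_k(self, space_factory):
        space = space_factory(np.array([0.0, 1.0, 2.0]))
        u = fun(space, k_neighbors=5)  # silently uses k=2
        assert len(u) == 3


class TestFUSE:
    # printed inputs from the worked examples: FUn, FSpe, IUCN, printed FUSE
    WORKED = [
        ("scalloped hammerhead shark", 0.44, 0.91, "CR", 2.56),
        ("shortspine spurdog", 0.49, 0.73, "EN", 2.06),
        ("panther electric ray", 0.44, 0.65, "EN", 1.92),
        ("silvertip shark", 0.58, 1.00, "VU", 1.87),
        ("eagle ray", 0.65, 0.78, "VU", 1.77),
        ("whitetip reef shark", 0.51, 0.76, "VU", 1.62),
        ("blacktip reef shark", 0.72, 0.48, "VU", 1.56),
        ("brown-marbled grouper", 0.36, 0.34, "VU", 1.07),
        ("tiger shark", 0.48, 0.76, "NT", 0.96),
        ("white stumpnose", 0.32, 0.27, "VU", 0.93),
    ]

    @pytest.mark.parametrize("name,fu,fs,iucn,expected",
                             WORKED, ids=[w[0] for w in WORKED])
    def test_worked_examples(self, name, fu, fs, iucn, expected):
        score = fuse(fu, fs, ge_from_iucn(iucn))
        assert score == pytest.approx(expected, abs=0.02)

    def test_least_concern_always_zero(self):
        assert fuse(0.9, 0.95, 0) == 0.0

    def test_monotone_in_each_argument(self):
        base = fuse(0.4, 0.5, 2)
        assert fuse(0.5, 0.5, 2) > base
        assert fuse(0.4, 0.6, 2) > base
        assert fuse(0.4, 0.5, 3) > base

    @pytest.mark.parametrize("fu,fs,ge", [(-0.1, 0.5, 2), (0.5, 1.2, 2),
                                          (0.5, 0.5, 5), (0.5, 0.5, 2.5)])
    def test_out_of_range_rejected(self, fu, fs, ge):
        with pytest.raises(ValueError):
            fuse(fu, fs, ge)

    def test_dd_category_has_no_rank(self):
        with pytest.raises(ValueError, match="impute"):
            ge_from_iucn("DD")


class TestFuseRanking:
    def test_constructed_cr_species_ranked_first(self):
        idx = ["a", "b", "c"]
        u = pd.Series([1.0, 0.2, 0.3], index=idx)
        s = pd.Series([1.0, 0.1, 0.2], index=idx)
        iucn = pd.Series(["CR", "LC", "VU"], index=idx)
        table = fuse_ranking(u, s, iucn)
        assert table.index[0] == "a"

    def test_all_least_concern_degenerate(self, caplog):
        idx = ["a", "b"]
        u = pd.Series([0.5, 0.7], index=idx)
        s = pd.Series([0.5, 0.7], index=idx)
        with caplog.at_level("WARNING"):
            table = fuse_ranking(u, s, pd.Series(["LC", "LC"], index=idx))
        assert (table["FUSE"] == 0).all()
        assert "degenerate" in caplog.text

    def test_top10_matches_sort_oracle(self):
        rng = np.random.default_rng(6)
        idx = [f"s{i:03d}" for i in range(300)]
        u = pd.Series(rng.uniform(size=300), index=idx)
        s = pd.Series(rng.uniform(size=300), index=idx)
        iucn = pd.Series(rng.choice(["LC", "NT", "VU", "EN", "CR"], 300),
                         index=idx)
        table = fuse_ranking(u, s, iucn)
        oracle = sorted(
            idx,
            key=lambda sp: (-np.log1p(u[sp] * ge_from_iucn(iucn[sp]))
                            - np.log1p(s[sp] * ge_from_iucn(iucn[sp])),
                            -u[sp], sp),
        )
        assert list(table.index[:10]) == oracle[:10]

    def test_habitat_occurrence_density_annotation(self):
        meta = pd.DataFrame({
            "transect_id": ["t1", "t2"], "atoll": ["A", "B"],
            "depth_band_m": [10, 250], "length_m": [250.0, 250.0],
            "width_m": [5.0, 5.0], "calibration_flag": [False, False],
        })
        data = pd.DataFrame(
            {"a": [4.0, 0.0], "b": [4.0, 2.0]}, index=["t1", "t2"]
        )
        cm = CommunityMatrix(data=data, kind="abundance",
                             species_columns=["a", "b"])
        idx = ["a", "b"]
        table = fuse_ranking(
            pd.Series([0.5, 0.6], index=idx), pd.Series([0.5, 0.6], index=idx),
            pd.Series(["VU", "EN"], index=idx), abundance=cm, meta=meta,
        )
        assert table.loc["a", "habitat"] == "shallow"
        assert table.loc["b", "habitat"] == "shallow"  # shallowest occurrence
        assert table.loc["b", "occurrence_atolls"] == 2
        # density per 1250 m^2 = mean over occupied transects x 12.5
        assert table.loc["a", "density_per_1250m2"] == pytest.approx(50.0)
        assert table.loc["b", "density_per_1250m2"] == pytest.approx(37.5)


class TestHabitat:
    @pytest.mark.parametrize("depth,expected", [
        (4, "shallow"), (10, "shallow"), (30, "MCE"), (120, "MCE"),
        (150, "MCE"), (250, "deep"), (500, "deep"),
    ])
    def test_cutoffs(self, depth, expected):
        assert classify_habitat(depth) == expected


class TestAlphaFilter:
    @staticmethod
    def _matrix(richness_by_transect):
        cols = [f"s{i}" for i in range(max(richness_by_transect.values()))]
        data = pd.DataFrame(0.0, index=list(richness_by_transect), columns=cols)
        for t, r in richness_by_transect.items():
            data.loc[t, cols[:r]] = 1.0
        return CommunityMatrix(data=data, kind="abundance", species_columns=cols)

    def test_min_zero_keeps_all(self):
        cm = self._matrix({"t1": 2, "t2": 6})
        kept, report = alpha_fd_filter(cm, min_species=0)
        assert kept == ["t1", "t2"] and len(report) == 0

    def test_thin_transects_reported(self):
        cm = self._matrix({"t1": 2, "t2": 6, "t3": 4, "t4": 1, "t5": 5})
        kept, report = alpha_fd_filter(cm, min_species=5)
        assert set(report["transect_id"]) == {"t1", "t3", "t4"}
        assert set(kept) == {"t2", "t5"}


class TestMetricCorrelation:
    def test_self_correlation_one_constant_undefined(self):
        rng = np.random.default_rng(7)
        df = pd.DataFrame({
            "m1": rng.normal(size=10),
            "m2": rng.normal(size=10),
            "flat": np.ones(10),
        })
        corr = metric_correlation_summary(df)
        assert corr.loc["m1", "m1"] == pytest.approx(1.0)
        assert np.isnan(corr.loc["flat", "m1"])

    def test_too_few_transects_rejected(self):
        with pytest.raises(ValueError):
            metric_correlation_summary(pd.DataFrame({"m": [1.0, 2.0]}))
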