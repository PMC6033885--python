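import math

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

import borerisk as br
from borerisk.enm import SuitabilityMap
from borerisk.grid import GridGeoref, ZoneSet
from borerisk.pipeline import beetle_smce_tree
from borerisk.smce import (SmceNode, evaluate_smce, load_tree, standardize_convex,
                           standardize_goal, zonal_risk)


class TestStandardization:
    def test_goal_endpoints_midpoint_and_clipping(self):
        x = np.array([0.0, 5.0, 10.0, -3.0, 99.0])
        out = standardize_goal(x, 0.0, 10.0)
        np.testing.assert_allclose(out, [0.0, 0.5, 1.0, 0.0, 1.0])

    def test_goal_rejects_degenerate_range(self):
        with pytest.raises(ValueError):
            standardize_goal(np.ones(3), 1.0, 1.0)

    def test_convex_endpoints_and_closed_form_midpoint(self):
        out = standardize_convex(np.array([0.0, 0.5, 1.0]), 2.0, 0.0, 1.0)
        assert out[0] == 0.0 and out[2] == pytest.approx(1.0)
        # (e - 1)/(e^2 - 1) at u = 0.5, a = 2
        assert out[1] == pytest.approx((math.e - 1) / (math.e ** 2 - 1), abs=1e-12)

    def test_convex_tends_to_goal_as_a_vanishes(self):
        u = np.linspace(0, 1, 11)
        out = standardize_convex(u, 1e-8, 0.0, 1.0)
        np.testing.assert_allclose(out, u, atol=1e-7)

    def test_convex_is_convex_and_below_linear(self):
        u = np.linspace(0.01, 0.99, 50)
        out = standardize_convex(u, 2.0, 0.0, 1.0)
        assert (out < u).all()
        assert (np.diff(out, 2) > 0).all()


class TestTree:
    def test_bad_weight_sum_cannot_be_instantiated(self):
        with pytest.raises(ValueError, match="sum"):
            SmceNode("root", 1.0, children=[
                SmceNode("a", 0.6, layer="a"), SmceNode("b", 0.6, layer="b")])

    def test_leaf_without_layer_rejected(self):
        with pytest.raises(ValueError, match="layer"):
            SmceNode("leaf", 1.0)

    def test_two_leaf_convex_combination(self):
        tree = SmceNode("root", 1.0, children=[
            SmceNode("a", 0.7, layer="a", params={"min": 0, "max": 1}),
            SmceNode("b", 0.3, layer="b", params={"min": 0, "max": 1})])
        comp = evaluate_smce(tree, {"a": np.ones((2, 2)), "b": np.zeros((2, 2))})
        np.testing.assert_allclose(comp.values, 0.7)

    def test_all_unit_leaves_give_unit_composite(self):
        tree = beetle_smce_tree("x", with_related=True, convex_a=2.0)
        layers = {lf.layer: np.ones((3, 3)) for lf in tree.leaves()}
        comp = evaluate_smce(tree, layers)
        np.testing.assert_allclose(comp.values, 1.0, atol=1e-12)

    def test_published_weight_structure(self):
        tree = beetle_smce_tree("x", with_related=True, convex_a=2.0)
        top = {c.name: c.weight for c in tree.children}
        assert top == {"potential_distribution": 0.4,
                       "hosts_and_related": 0.35, "forest_stress": 0.25}
        flat = tree.flat_weights()
        assert flat["beetle_continuous"] == pytest.approx(0.4 * 0.6)
        assert flat["beetle_binary"] == pytest.approx(0.4 * 0.4)
        # printed sub-weights 0.2/0.3/0.2 renormalized within their node
        assert flat["related_suitability"] == pytest.approx(0.35 * 0.3 / 0.7)
        assert sum(flat.values()) == pytest.approx(1.0)

    def test_missing_layer_error_names_leaf(self):
        tree = SmceNode("root", 1.0, children=[
            SmceNode("present", 0.5, layer="a"),
            SmceNode("absent", 0.5, layer="zzz")])
        with pytest.raises(KeyError, match="absent"):
            evaluate_smce(tree, {"a": np.ones((2, 2))})

    def test_roundtrip_through_config_file(self, tmp_path):
        tree = beetle_smce_tree("x", with_related=False, convex_a=2.0)
        p = tmp_path / "tree.json"
        import json
        p.write_text(json.dumps(tree.to_dict()))
        loaded = load_tree(p)
        assert loaded.flat_weights() == tree.flat_weights()


def random_tree(rng, depth, prefix="n"):
    if depth == 0 or rng.uniform() < 0.3:
        return SmceNode(f"{prefix}", 1.0, layer=f"L{prefix}",
                        standardization="goal", params={"min": 0.0, "max": 1.0})
    k = int(rng.integers(2, 4))
    w = rng.dirichlet(np.ones(k))
    w = w / w.sum()
    kids = []
    for i in range(k):
        child = random_tree(rng, depth - 1, f"{prefix}{i}")
        child.weight = float(w[i])
        kids.append(child)
    # re-validate after assigning weights
    return SmceNode(f"{prefix}", 1.0, children=[
        SmceNode(c.name, float(w[i]), children=c.children, layer=c.layer,
                 standardization=c.standardization, params=c.params)
        for i, c in enumerate(kids)])


class TestTreeAlgebra:
    def test_tree_evaluation_equals_flat_path_product_sum(self):
        rng = np.random.default_rng(12)
        for rep in range(30):
            tree = random_tree(rng, depth=3, prefix=f"t{rep}")
            leaves = tree.leaves()
            layers = {lf.layer: rng.uniform(0, 1, (4, 4)) for lf in leaves}
            comp = evaluate_smce(tree, layers)
            flat = tree.flat_weights()
            expected = sum(w * layers[f"L{name}"] for name, w in flat.items())
            np.testing.assert_allclose(comp.values, expected, atol=1e-10)
            assert np.nanmin(comp.values) >= 0 and np.nanmax(comp.values) <= 1

    def test_composite_monotone_in_every_leaf(self):
        rng = np.random.default_rng(13)
        tree = random_tree(rng, depth=2, prefix="m")
        leaves = tree.leaves()
        layers = {lf.layer: rng.uniform(0.1, 0.8, (3, 3)) for lf in leaves}
        base = evaluate_smce(tree, layers).values
        for lf in leaves:
            bumped = {k: v.copy() for k, v in layers.items()}
            bumped[lf.layer] = np.minimum(bumped[lf.layer] + 0.1, 1.0)
            up = evaluate_smce(tree, bumped).values
            assert (up >= base - 1e-12).all()

    def test_equal_weight_siblings_commute(self):
        a = SmceNode("root", 1.0, children=[
            SmceNode("x", 0.5, layer="p", params={"min": 0, "max": 1}),
            SmceNode("y", 0.5, layer="q", params={"min": 0, "max": 1})])
        b = SmceNode("root", 1.0, children=[
            SmceNode("y", 0.5, layer="q", params={"min": 0, "max": 1}),
            SmceNode("x", 0.5, layer="p", params={"min": 0, "max": 1})])
        rng = np.random.default_rng(14)
        layers = {"p": rng.uniform(0, 1, (3, 3)), "q": rng.uniform(0, 1, (3, 3))}
        np.testing.assert_allclose(evaluate_smce(a, layers).values,
                                   evaluate_smce(b, layers).values)


class TestZonalRisk:
    def _composite(self, values):
        values = np.asarray(values, float)
        return SuitabilityMap(values, "composite", GridGeoref(0.0, 10.0, 1.0),
                              ~np.isfinite(values))

    def _zones(self, n, width=2.0):
        return ZoneSet([(f"z{i}", box(i * width, 0.0, (i + 1) * width, 10.0), {})
                        for i in range(n)])

    def test_five_distinct_zones_one_per_class(self):
        vals = np.zeros((10, 10))
        for i in range(5):
            vals[:, 2 * i:2 * i + 2] = 0.1 * (i + 1)
        table = zonal_risk(self._composite(vals), self._zones(5), 5)
        assert sorted(table["risk_class"]) == sorted(
            ["very low", "low", "medium", "high", "very high"])
        np.testing.assert_allclose(np.sort(table["mean_risk"]),
                                   [0.1, 0.2, 0.3, 0.4, 0.5])
        # classes ordered by mean risk
        ordered = table.sort_values("mean_risk")["risk_class"].tolist()
        assert ordered == ["very low", "low", "medium", "high", "very high"]

    def test_identical_zones_collapse_to_one_class(self):
        table = zonal_risk(self._composite(np.full((10, 10), 0.4)),
                           self._zones(4), 5)
        assert set(table["risk_class"]) == {"very low"}

    def test_zone_outside_raster_flagged(self):
        zones = ZoneSet([("in", box(0, 0, 10, 10), {}),
                         ("out", box(50, 50, 60, 60), {})])
        table = zonal_risk(self._composite(np.full((10, 10), 0.3)), zones, 2)
        row = table.set_index("zone_id").loc["out"]
        assert row["no_valid_cells"] and pd.isna(row["mean_risk"])

    def test_production_attribute_carried_through(self):
        zones = ZoneSet([("a", box(0, 0, 10, 10), {"production": 123.0})])
        table = zonal_risk(self._composite(np.full((10, 10), 0.3)), zones, 2)
        assert table.loc[0, "production"] == 123.0
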