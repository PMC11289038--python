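"""Effect algebra: (conditional) indirect effects, indices, and totals.

Expected values for the worked examples are products of the demonstration
coefficient tables in conftest; properties are checked against independent
oracles (symbolic expansion, the total-effects matrix (I-B)^-1 - I, direct
subtraction).
"""

import numpy as np
import pandas as pd
import pytest

import mome
from mome.effects import cond_indirect_diff, indirect_proportion
from mome.exceptions import EffectError
from mome.wlevels import WLevels, WRow

from conftest import TABLE1_COEF, random_dag_model


def wrow_table(moderators, rows):
    """Small helper: WLevels from (label, values) pairs."""
    return WLevels(
        moderators=moderators,
        rows=[WRow(tuple(lab), vals) for lab, vals in rows],
    )


class TestConditionalCoefficient:
    def test_moderated_edge(self, table1_est):
        v = mome.conditional_coefficient(
            table1_est, ("x1", "m1"), {"w1": 1.011}
        )
        assert round(v, 3) == 0.505

    def test_second_moderated_edge(self, table1_est):
        v = mome.conditional_coefficient(
            table1_est, ("m2", "y1"), {"w2": 0.959}
        )
        assert round(v, 3) == 1.594

    def test_zero_moderator_returns_raw_coefficient(self, table1_est):
        v = mome.conditional_coefficient(table1_est, ("x1", "m1"), {"w1": 0.0})
        assert v == table1_est.coefficient("m1", "x1")

    def test_missing_moderator_defaults_to_zero_with_warning(self, table1_est):
        with pytest.warns(UserWarning, match="using 0"):
            v = mome.conditional_coefficient(table1_est, ("x1", "m1"), {})
        assert v == table1_est.coefficient("m1", "x1")


class TestIndirectEffect:
    def test_unmoderated_two_edge_product(self, model1):
        est = mome.ParamEstimates.from_coefficients(
            model1,
            {**TABLE1_COEF, "m3": {"x2": 0.49472, "x1": 0.321},
             "y2": {"m3": 0.55018, "x2": -0.016, "x1": 0.029, "m2": -0.033}},
        )
        e = mome.indirect_effect(est, "x2", ["m3"], "y2")
        assert round(e.value, 3) == 0.272
        assert e.trace == "(b.m3~x2)*(b.y2~m3)"
        assert e.computation == "(0.49472)*(0.55018)"

    def test_standardized_by_sd_ratio(self, model1):
        est = mome.ParamEstimates.from_coefficients(
            model1,
            {**TABLE1_COEF, "m3": {"x2": 0.49472},
             "y2": {"m3": 0.55018}},
            sds={"x2": 1.04844, "y2": 0.93431},
        )
        e = mome.indirect_effect(est, "x2", ["m3"], "y2",
                                 std_x=True, std_y=True)
        assert round(e.value, 3) == 0.305
        assert e.trace == "(b.m3~x2)*(b.y2~m3)*sd_x2/sd_y2"

    def test_zero_coefficient_annihilates(self, model1):
        coef = {k: dict(v) for k, v in TABLE1_COEF.items()}
        coef["m2"]["m1"] = 0.0
        est = mome.ParamEstimates.from_coefficients(model1, coef)
        e = mome.indirect_effect(est, "x2", ["m1", "m2"], "y2", warn=False)
        assert e.value == 0.0

    def test_conditional_three_edge_path(self, model1):
        est = mome.ParamEstimates.from_coefficients(
            model1,
            {**TABLE1_COEF,
             "m1": {"x1": 0.35235, "w1": 0.022, "w1x1": 0.15057, "x2": 0.158},
             "m2": {"m1": 0.54836},
             "y2": {"m3": 0.550, "x2": -0.016, "x1": 0.029, "m2": -0.03304}},
        )
        e = mome.indirect_effect(
            est, "x1", ["m1", "m2"], "y2", wvalues={"w1": 1.01052}
        )
        assert round(e.value, 3) == -0.009
        assert e.trace == "(b.m1~x1 + (b.w1x1)*(w1))*(b.m2~m1)*(b.y2~m2)"
        assert e.computation == (
            "((0.35235) + (0.15057)*(1.01052))*(0.54836)*(-0.03304)"
        )

    def test_warns_on_unset_moderators(self, table1_est):
        with pytest.warns(UserWarning, match="moderated"):
            e = mome.indirect_effect(table1_est, "x1", ["m1", "m2"], "y1")
        # effect at moderators = 0
        assert e.value == pytest.approx(0.352 * 0.548 * 0.826)

    def test_partial_standardization_composition(self, model1):
        est = mome.ParamEstimates.from_coefficients(
            model1, TABLE1_COEF, sds={"x2": 2.0, "y2": 4.0}
        )
        base = mome.indirect_effect(est, "x2", ["m3"], "y2").value
        ex = mome.indirect_effect(est, "x2", ["m3"], "y2", std_x=True)
        ey = mome.indirect_effect(est, "x2", ["m3"], "y2", std_y=True)
        exy = mome.indirect_effect(est, "x2", ["m3"], "y2",
                                   std_x=True, std_y=True)
        assert ex.value == pytest.approx(2 * base)
        assert ey.value == pytest.approx(base / 4)
        assert exy.value == pytest.approx(base * 2 / 4)
        assert exy.value == pytest.approx(ex.value / 4)

    def test_trace_consistency_value_equals_component_product(self, table1_est):
        e = mome.indirect_effect(
            table1_est, "x1", ["m1", "m2"], "y1",
            wvalues={"w1": 1.011, "w2": 0.959},
        )
        prod = np.prod([c.value for c in e.components])
        assert e.value == pytest.approx(prod, abs=1e-9)


class TestCondIndirectEffects:
    def test_demo_row(self, table1_est):
        wl = wrow_table(
            [("w1", ("w1",)), ("w2", ("w2",))],
            [(("M+1.0SD", "M+1.0SD"), {"w1": 1.011, "w2": 0.959})],
        )
        table = mome.cond_indirect_effects(
            table1_est, wl, "x1", ["m1", "m2"], "y1"
        )
        e = table.effect(1)
        assert round(e.value, 3) == 0.441
        assert [round(c.value, 3) for c in e.components] == [0.505, 0.548, 1.594]

    def test_rows_equal_without_interactions(self, model1):
        coef = {k: dict(v) for k, v in TABLE1_COEF.items()}
        coef["m1"]["w1x1"] = 0.0
        coef["y1"]["w2m2"] = 0.0
        est = mome.ParamEstimates.from_coefficients(model1, coef)
        wl = wrow_table(
            [("w1", ("w1",)), ("w2", ("w2",))],
            [(("hi", "hi"), {"w1": 1.0, "w2": 1.0}),
             (("lo", "lo"), {"w1": -1.0, "w2": -1.0})],
        )
        table = mome.cond_indirect_effects(
            est, wl, "x1", ["m1", "m2"], "y1"
        )
        assert table.values[0] == pytest.approx(table.values[1])

    def test_default_levels_from_estimates(self, model1):
        est = mome.ParamEstimates.from_coefficients(
            model1, TABLE1_COEF,
            means={"w1": 0.0, "w2": 0.0}, sds={"w1": 1.011, "w2": 0.959},
        )
        table = mome.cond_indirect_effects(
            est, ["w1", "w2"], "x1", ["m1", "m2"], "y1"
        )
        assert len(table) == 4  # two moderators -> 2 levels each
        assert round(table.effect(1).value, 3) == 0.441

    def test_irrelevant_moderator_warns(self, table1_est):
        wl = wrow_table(
            [("w1", ("w1",))], [(("hi",), {"w1": 1.0}), (("lo",), {"w1": -1.0})]
        )
        with pytest.warns(UserWarning, match="moderates no component path"):
            table = mome.cond_indirect_effects(
                table1_est, wl, "x2", ["m3"], "y2"
            )
        assert table.values[0] == pytest.approx(table.values[1])


class TestEffectAlgebra:
    def test_total_indirect_and_total_effect(self, table1_est):
        e1 = mome.indirect_effect(table1_est, "x2", ["m3"], "y2")
        e2 = mome.indirect_effect(table1_est, "x2", ["m1", "m2"], "y2")
        total_ind = e1 + e2
        assert round(total_ind.value, 3) == 0.269
        direct = mome.indirect_effect(table1_est, "x2", [], "y2")
        assert direct.trace == "(b.y2~x2)"
        total = total_ind + direct
        assert round(total.value, 3) == 0.253
        assert len(total.paths) == 3

    def test_self_subtraction_degenerate(self, mediation_model, mediation_data):
        data, _ = mediation_data
        est = mome.fit_equations(mediation_model, data)
        store = mome.bootstrap_estimates(mediation_model, data, R=50, seed=2)
        e = mome.indirect_effect(est, "x", ["m"], "y", store=store)
        z = e - e
        assert z.value == 0.0
        assert (z.ci.lo, z.ci.hi) == (0.0, 0.0)

    def test_mismatched_standardization_rejected(self, table1_est):
        a = mome.indirect_effect(table1_est, "x2", ["m3"], "y2")
        b = mome.indirect_effect(table1_est, "x2", ["m3"], "y2", std_x=True)
        with pytest.raises(EffectError, match="standardization"):
            a + b

    def test_mismatched_replicate_provenance_rejected(
        self, mediation_model, mediation_data
    ):
        data, _ = mediation_data
        est = mome.fit_equations(mediation_model, data)
        s1 = mome.bootstrap_estimates(mediation_model, data, R=20, seed=1)
        s2 = mome.bootstrap_estimates(mediation_model, data, R=20, seed=2)
        a = mome.indirect_effect(est, "x", ["m"], "y", store=s1)
        b = mome.indirect_effect(est, "x", [], "y", store=s2)
        with pytest.raises(EffectError, match="different stores"):
            a + b

    @pytest.mark.parametrize("seed", range(8))
    def test_sum_over_paths_equals_total_effects_matrix(self, seed):
        """In a linear model the sum of path products equals the (y, x)
        entry of (I - B_full)^-1 - I over all fitted coefficients."""
        rng = np.random.default_rng(300 + seed)
        nodes, edges, syntax = random_dag_model(rng, p_edge=0.5)
        if not edges:
            pytest.skip("degenerate draw with no edges")
        model = mome.parse_model(syntax)
        coef = {
            eq.outcome: {t: float(rng.normal(0, 0.5)) for t in eq.terms}
            for eq in model.equations
        }
        est = mome.ParamEstimates.from_coefficients(model, coef)
        present = sorted(model.variables)
        ix = {v: i for i, v in enumerate(present)}
        B = np.zeros((len(present), len(present)))
        for outcome, terms in coef.items():
            for t, v in terms.items():
                B[ix[outcome], ix[t]] = v
        T = np.linalg.inv(np.eye(len(present)) - B) - np.eye(len(present))
        for x in present:
            for y in present:
                if x == y:
                    continue
                paths = mome.enumerate_paths(model, x, y)
                total = sum(
                    mome.indirect_effect(est, query=q, warn=False).value
                    for q in paths
                )
                assert total == pytest.approx(T[ix[y], ix[x]], abs=1e-10)


class TestIndices:
    def test_index_of_mome(self, table1_est):
        ir = mome.index_of_mome(table1_est, "m1", ["m2"], "y1", "w2")
        assert round(ir.index, 3) == 0.439
        # recomputable from the stored cells
        assert ir.index == pytest.approx(
            ir.cells[0].value - ir.cells[1].value
        )

    def test_index_zero_without_interaction(self, model1):
        coef = {k: dict(v) for k, v in TABLE1_COEF.items()}
        coef["y1"]["w2m2"] = 0.0
        est = mome.ParamEstimates.from_coefficients(model1, coef)
        ir = mome.index_of_mome(est, "m1", ["m2"], "y1", "w2")
        assert ir.index == pytest.approx(0.0)

    def test_index_equals_symbolic_expansion(self):
        """For x -> m -> y with the second edge moderated, the index is
        exactly b_first * d (symbolic oracle)."""
        model = mome.parse_model("m ~ x\ny ~ m + w + w:m")
        b1, b2, d = 0.7, 0.4, 0.25
        est = mome.ParamEstimates.from_coefficients(
            model, {"m": {"x": b1}, "y": {"m": b2, "w": 0.1, "w:m": d}}
        )
        ir = mome.index_of_mome(est, "x", ["m"], "y", "w")
        assert ir.index == pytest.approx(b1 * d, abs=1e-12)

    def test_index_requires_relevant_moderator(self, table1_est):
        with pytest.raises(EffectError, match="moderates no component path"):
            mome.index_of_mome(table1_est, "x2", ["m3"], "y2", "w1")

    def test_index_of_momome(self, table1_est):
        ir = mome.index_of_momome(
            table1_est, "x1", ["m1", "m2"], "y1", "w1", "w2"
        )
        assert round(ir.index, 3) == 0.066
        cells = [c.value for c in ir.cells]
        assert ir.index == pytest.approx((cells[0] - cells[1]) - (cells[2] - cells[3]))

    def test_momome_equals_symbolic_expansion(self):
        """w, z moderating the first and last of three edges: index is
        d1 * b12 * d2 exactly."""
        model = mome.parse_model(
            "m1 ~ x + w + w:x\nm2 ~ m1\ny ~ m2 + z + z:m2"
        )
        d1, b12, d2 = 0.3, 0.6, 0.2
        est = mome.ParamEstimates.from_coefficients(
            model,
            {"m1": {"x": 0.5, "w": 0.1, "w:x": d1},
             "m2": {"m1": b12},
             "y": {"m2": 0.4, "z": 0.1, "z:m2": d2}},
        )
        ir = mome.index_of_momome(est, "x", ["m1", "m2"], "y", "w", "z")
        assert ir.index == pytest.approx(d1 * b12 * d2, abs=1e-12)

    def test_momome_zero_when_either_interaction_zero(self, model1):
        coef = {k: dict(v) for k, v in TABLE1_COEF.items()}
        coef["m1"]["w1x1"] = 0.0
        est = mome.ParamEstimates.from_coefficients(model1, coef)
        ir = mome.index_of_momome(est, "x1", ["m1", "m2"], "y1", "w1", "w2")
        assert ir.index == pytest.approx(0.0)


class TestCondIndirectDiff:
    def make_table(self, est):
        wl = wrow_table(
            [("w2", ("w2",))],
            [(("M+1.0SD",), {"w2": 0.959}), (("Mean",), {"w2": 0.0})],
        )
        return mome.cond_indirect_effects(est, wl, "m1", ["m2"], "y1")

    def test_one_sd_change(self, table1_est):
        table = self.make_table(table1_est)
        ir = cond_indirect_diff(table, from_row=2, to_row=1)
        assert round(ir.index, 3) == 0.421

    def test_same_row_is_zero(self, table1_est):
        table = self.make_table(table1_est)
        assert cond_indirect_diff(table, 1, 1).index == 0.0

    def test_equals_direct_subtraction(self, table1_est):
        table = self.make_table(table1_est)
        ir = cond_indirect_diff(table, 1, 2)
        assert ir.index == pytest.approx(table.values[1] - table.values[0])

    def test_row_out_of_range(self, table1_est):
        table = self.make_table(table1_est)
        with pytest.raises(EffectError, match="out of range"):
            cond_indirect_diff(table, 1, 3)


class TestIndirectProportion:
    def test_symmetric_simple_mediation(self, mediation_model):
        est = mome.ParamEstimates.from_coefficients(
            mediation_model, {"m": {"x": 1.0}, "y": {"m": 1.0, "x": 1.0}}
        )
        assert indirect_proportion(est, "x", ["m"], "y") == pytest.approx(0.5)

    def test_fully_mediated(self, mediation_model):
        est = mome.ParamEstimates.from_coefficients(
            mediation_model, {"m": {"x": 2.0}, "y": {"m": 0.5, "x": 0.0}}
        )
        assert indirect_proportion(est, "x", ["m"], "y") == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(500 + seed)
        model = mome.parse_model("m1 ~ x\nm2 ~ x\ny ~ m1 + m2 + x")
        coef = {
            "m1": {"x": rng.uniform(0.1, 1)},
            "m2": {"x": rng.uniform(0.1, 1)},
            "y": {"m1": rng.uniform(0.1, 1), "m2": rng.uniform(0.1, 1),
                  "x": rng.uniform(0.1, 1)},
        }
        est = mome.ParamEstimates.from_coefficients(model, coef)
        a1b1 = coef["m1"]["x"] * coef["y"]["m1"]
        a2b2 = coef["m2"]["x"] * coef["y"]["m2"]
        cp = coef["y"]["x"]
        expected = a1b1 / (a1b1 + a2b2 + cp)
        assert indirect_proportion(est, "x", ["m1"], "y") == pytest.approx(expected)

    def test_mixed_signs_refused(self, mediation_model):
        est = mome.ParamEstimates.from_coefficients(
            mediation_model, {"m": {"x": 1.0}, "y": {"m": 1.0, "x": -2.0}}
        )
        with pytest.raises(EffectError, match="mixed signs"):
            indirect_proportion(est, "x", ["m"], "y")

    def test_moderated_paths_refused(self, table1_est):
        with pytest.raises(EffectError, match="moderated"):
            indirect_proportion(table1_est, "x1", ["m1", "m2"], "y1")
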