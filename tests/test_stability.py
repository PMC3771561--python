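"""Eigenvalue classification, the determinant-ratio slope, and the LVG test."""

import numpy as np
import pytest

from circuitbreaking import (
    CBAConfig,
    analyze_fixed_points,
    assemble_fixed_points,
    build_igraph,
    classify_fixed_point,
    evaluate_characteristic,
    lvg_instability_test,
    parse_model,
    prop1_slope,
    reduced_determinant_sign,
    scc_decompose,
)
from circuitbreaking.errors import SingularReducedJacobianError
from circuitbreaking.graphs import CircuitCover, cover_for_subgraph
from circuitbreaking.models import methods_fixture, random_lvg_model


def _fd_slope_at(char, kappa, state, span):
    h = 1e-3 * span
    cs = [char.value_at(kappa + k * h, state) for k in (-2, -1, 1, 2)]
    return (cs[0] - 8 * cs[1] + 8 * cs[2] - cs[3]) / (12 * h)


class TestClassification:
    def test_linear_decay_is_stable(self):
        m = parse_model("variables: [x1]\nrates: {x1: -x1}\nbounds: {x1: [0, 1]}")
        rep = classify_fixed_point(m, [0.0])
        assert rep.classification == "asymptotically_stable"
        np.testing.assert_allclose(rep.eigenvalues, [-1.0])

    def test_intermediate_stem_cell_state_is_unstable(self, stem_cell):
        ov = {"eN": 0.5, "eM": 0.5}
        rep = assemble_fixed_points(stem_cell, overrides=ov)
        middle = sorted(rep.points, key=lambda p: p.x[1])[1]
        assert classify_fixed_point(stem_cell, middle.x, overrides=ov).classification == "unstable"

    @pytest.mark.parametrize("mu, expected", [
        (0.01, "asymptotically_stable"),
        (0.1, "unstable"),
        (0.2, "asymptotically_stable"),
    ])
    def test_tryptophan_stability_inside_and_outside_hopf_bubble(self, tryptophan, mu, expected):
        ov = {"mu": mu}
        rep = assemble_fixed_points(tryptophan, overrides=ov)
        assert len(rep) == 1
        assert classify_fixed_point(tryptophan, rep.points[0].x, overrides=ov).classification == expected


class TestDeterminantRatioSlope:
    @pytest.mark.parametrize("kind", ["3vertex", "4vertex"])
    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_slope_identity_on_dense_fixtures(self, kind, seed, fast_cfg):
        # the finite-difference slope of the characteristic must equal
        # det J / det J_reduced at arbitrary points on the curve, for any
        # smooth rate laws and a cover needing two closing steps
        m = methods_fixture(kind, seed=seed)
        g = build_igraph(m)
        comp = scc_decompose(g).components[0]
        cover = cover_for_subgraph(g, comp)
        assert len(cover.cover) == 2  # genuinely not an LVG
        char = evaluate_characteristic(m, g, comp, cover, cfg=fast_cfg,
                                       grid=np.linspace(*m.bounds[cover.leading_vertex], 31))
        v1 = cover.leading_vertex
        lo, hi = m.bounds[v1]
        rng = np.random.default_rng(seed)
        for kappa in lo + (0.15 + 0.7 * rng.random(4)) * (hi - lo):
            items = char._eval(float(kappa))
            assert items
            _, st = items[0]
            st = st.copy()
            st[v1] = kappa
            fd = _fd_slope_at(char, float(kappa), st, hi - lo)
            ratio = prop1_slope(m, st, v1, comp)
            assert abs(fd - ratio) < 1e-5 * max(1.0, abs(ratio))

    def test_repressilator_slope_is_beta_free_cubed_gain(self, repressilator):
        # at the symmetric point the ratio equals -1 + (r')^3, independent
        # of the protein turnover rate
        x = np.full(6, 12.0)
        rp = -2 * 290 * 12 / (1 + 144) ** 2
        expected = -1 + rp**3
        for beta in (0.1, 1.0, 10.0):
            ratio = prop1_slope(repressilator, x, 0, overrides={"beta": beta})
            assert ratio == pytest.approx(expected, rel=1e-10)

    def test_slope_matches_closed_form_derivative(self, repressilator):
        # c(kappa) = r(r(r(kappa))) - kappa, so c' = (r')^3 - 1 by the chain rule
        g = build_igraph(repressilator)
        comp = scc_decompose(g).components[0]
        cover = cover_for_subgraph(g, comp)
        char = evaluate_characteristic(repressilator, g, comp, cover)
        from circuitbreaking.engine import find_zeros

        zeros = find_zeros(char)
        assert len(zeros) == 1 and zeros[0].kappa == pytest.approx(12.0, abs=1e-9)
        rp = -2 * 290 * 12 / (1 + 144) ** 2
        assert zeros[0].slope == pytest.approx(rp**3 - 1, rel=1e-6)

    def test_singular_reduced_jacobian_is_flagged(self):
        m = parse_model(
            "variables: [x1, x2]\n"
            "rates: {x1: x2 - x1, x2: x1 - x2^2}\n"
            "bounds: {x1: [0, 2], x2: [0, 2]}"
        )
        # at x2 = 0 the reduced (1x1) Jacobian for leading vertex x1 vanishes
        with pytest.raises(SingularReducedJacobianError):
            prop1_slope(m, [0.0, 0.0], "x1")


class TestLVGCriterion:
    def test_positive_slope_certifies_instability(self, stem_cell):
        ov = {"eN": 0.5, "eM": 0.5}
        stabs = analyze_fixed_points(stem_cell, overrides=ov)
        by_x2 = sorted(stabs, key=lambda s: s.point[1])
        assert by_x2[1].char_slope > 0
        assert by_x2[1].lvg_verdict == "unstable_by_slope"
        assert by_x2[1].classification == "unstable"
        # outer states: negative slope is not a stability certificate
        for s in (by_x2[0], by_x2[2]):
            assert s.lvg_verdict == "inconclusive"

    def test_negative_slope_never_claims_stability(self, tryptophan):
        # inside the Hopf bubble the point is unstable although the
        # characteristic slope is negative: the verdict must stay inconclusive
        ov = {"mu": 0.1}
        stabs = analyze_fixed_points(tryptophan, overrides=ov)
        assert len(stabs) == 1
        s = stabs[0]
        assert s.char_slope < 0
        assert s.classification == "unstable"
        assert s.lvg_verdict == "inconclusive"

    def test_non_lvg_cover_is_not_applicable(self):
        cover = CircuitCover(circuits=((0, 1), (2, 3)), cover=(0, 2), complement=(1, 3))
        assert lvg_instability_test(5.0, cover) == "not_applicable"

    def test_verdicts_always_confirmed_by_eigenvalues(self, stem_cell, tryptophan):
        cases = [
            (stem_cell, {"eN": 0.5, "eM": 0.5}),
            (stem_cell, None),
            (tryptophan, None),
        ] + [(random_lvg_model(4, seed), None) for seed in (3, 4)]
        for model, ov in cases:
            for s in analyze_fixed_points(model, overrides=ov):
                if s.lvg_verdict == "unstable_by_slope":
                    assert s.max_real > 0  # soundness: no false certificate


class TestReducedDeterminant:
    def test_tryptophan_reduced_network_is_acyclic_with_negative_diagonal(self, tryptophan):
        rep = assemble_fixed_points(tryptophan)
        x = rep.points[0].x
        g = build_igraph(tryptophan)
        cover = cover_for_subgraph(g, range(4))
        res = reduced_determinant_sign(tryptophan, x, cover.leading_vertex, cover)
        assert res["ok"]
        assert res["sign"] == (-1) ** 3 == -1
        assert res["det"] == pytest.approx(res["diag_product"], rel=1e-10)

    def test_repressilator_reduced_determinant_is_minus_beta_cubed(self, repressilator):
        g = build_igraph(repressilator)
        cover = cover_for_subgraph(g, range(6))
        x = np.full(6, 12.0)
        for beta in (0.5, 2.0):
            res = reduced_determinant_sign(
                repressilator, x, cover.leading_vertex, cover, overrides={"beta": beta}
            )
            assert res["ok"] and res["sign"] == (-1) ** 5
            assert res["det"] == pytest.approx(-beta**3, rel=1e-12)

    def test_triangular_chain_sign_matches_parity(self):
        m = parse_model(
            "variables: [x1, x2, x3]\n"
            "rates: {x1: x3/(1+x3) - x1, x2: x1 - x2, x3: x2 - 2*x3}\n"
            "bounds: {x1: [0, 2], x2: [0, 2], x3: [0, 2]}"
        )
        g = build_igraph(m)
        cover = cover_for_subgraph(g, range(3))
        assert cover.is_lvg
        res = reduced_determinant_sign(m, [0.2, 0.2, 0.1], cover.leading_vertex, cover)
        assert res["ok"]
        assert res["det"] == pytest.approx(2.0)
        assert res["sign"] == (-1) ** 2 == 1

    def test_eigenvalues_depend_on_beta_while_characteristic_does_not(self, repressilator):
        # the characteristic collapses the loop to one effective circuit and
        # cancels the protein turnover rate; the spectrum does not
        x = np.full(6, 12.0)
        res = {
            beta: classify_fixed_point(repressilator, x, overrides={"beta": beta}).max_real
            for beta in (0.05, 5.0)
        }
        assert abs(res[0.05] - res[5.0]) > 0.1
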