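"""Circuit breaking, characteristics, zero finding and fixed-point assembly."""

import numpy as np
import pytest

from circuitbreaking import (
    CBAConfig,
    assemble_fixed_points,
    build_igraph,
    evaluate_characteristic,
    find_zeros,
    parse_model,
    scc_decompose,
)
from circuitbreaking.engine import SCCSolver, break_circuits
from circuitbreaking.graphs import cover_for_subgraph

from conftest import multistart_fixed_points


def _scc_setup(model, scc_index=None, overrides=None):
    g = build_igraph(model)
    dec = scc_decompose(g)
    if scc_index is None:
        scc_index = next(
            k for k, c in enumerate(dec.components)
            if cover_for_subgraph(g, c).circuits
        )
    comp = dec.components[scc_index]
    cover = cover_for_subgraph(g, comp)
    return g, dec, comp, cover


class TestBreakAndSolve:
    def test_stem_cell_release_structure(self, stem_cell):
        g, dec, comp, cover = _scc_setup(stem_cell)
        order = break_circuits(g, comp, cover)
        assert [stem_cell.names[v] for v in order] == ["x4", "x3"]

    def test_tryptophan_release_structure(self, tryptophan):
        g, dec, comp, cover = _scc_setup(tryptophan)
        order = break_circuits(g, comp, cover)
        assert [tryptophan.names[v] for v in order] == ["x1", "x2", "x3"]

    def test_downstream_matches_closed_form(self, stem_cell):
        # with the circuits cut at x2 = kappa the remaining equations have
        # explicit solutions x4 = eM / (1 + kappa^4), x3 = 5 x4/(1+x4)/(1+kappa^4)
        g, dec, comp, cover = _scc_setup(stem_cell)
        solver = SCCSolver(stem_cell, g, comp, cover, upstream={"x1": 0.2})
        kappa = 0.81
        branches = solver.downstream({stem_cell.index("x2"): kappa})
        assert len(branches) == 1
        x4 = 0.2 / (1 + kappa**4)
        x3 = 5 * x4 / (1 + x4) / (1 + kappa**4)
        assert branches[0][stem_cell.index("x4")] == pytest.approx(x4, abs=1e-9)
        assert branches[0][stem_cell.index("x3")] == pytest.approx(x3, abs=1e-9)
        assert x4 == pytest.approx(0.14, abs=5e-3)

    def test_linear_chain_is_exact(self):
        m = parse_model(
            "variables: [x1, x2]\n"
            "parameters: {u: 0.7}\n"
            "rates: {x1: u - x1, x2: x1 - x2}\n"
            "bounds: {x1: [0, 2], x2: [0, 2]}"
        )
        rep = assemble_fixed_points(m)
        assert len(rep) == 1
        np.testing.assert_allclose(rep.points[0].x, [0.7, 0.7], atol=1e-10)


class TestCharacteristic:
    def test_stem_cell_monotone_single_zero_below_fold(self, stem_cell):
        g, dec, comp, cover = _scc_setup(stem_cell)
        char = evaluate_characteristic(stem_cell, g, comp, cover, upstream={"x1": 0.2})
        assert char.n_branches == 1
        v = char.values[0]
        assert np.all(np.isfinite(v))
        assert np.all(np.diff(v) < 0)  # monotonically decreasing
        assert np.sum(np.sign(v[:-1]) != np.sign(v[1:])) == 1

    def test_repressilator_closed_form_and_beta_independence(self, repressilator):
        g, dec, comp, cover = _scc_setup(repressilator)
        grid = np.linspace(10, 300, 601)
        chars = {
            beta: evaluate_characteristic(
                repressilator, g, comp, cover, grid=grid, overrides={"beta": beta}
            )
            for beta in (0.1, 10.0)
        }
        r = lambda p: 290.0 / (1 + p**2) + 10.0
        closed = r(r(r(grid))) - grid
        for char in chars.values():
            assert char.n_branches == 1
            np.testing.assert_allclose(char.values[0], closed, atol=1e-9)
        assert np.max(np.abs(chars[0.1].values - chars[10.0].values)) < 1e-12

    def test_tryptophan_strictly_decreasing_for_all_dilutions(self, tryptophan):
        g, dec, comp, cover = _scc_setup(tryptophan)
        grid = np.linspace(0, 200, 201)
        for mu in (0.01, 0.1, 0.2):
            char = evaluate_characteristic(
                tryptophan, g, comp, cover, grid=grid, overrides={"mu": mu}
            )
            v = char.values[0]
            assert np.all(np.isfinite(v))
            assert np.all(np.diff(v) < 0)

    def test_single_variable_scc_without_self_loop_is_rate_itself(self):
        m = parse_model(
            "variables: [x1]\nparameters: {u: 0.3}\n"
            "rates: {x1: u - x1}\nbounds: {x1: [0, 1]}"
        )
        g = build_igraph(m)
        cover = cover_for_subgraph(g, [0])
        assert cover.cover == ()
        char = evaluate_characteristic(m, g, [0], cover)
        np.testing.assert_allclose(char.values[0], 0.3 - char.grid, atol=1e-12)


class TestFindZeros:
    def test_three_zeros_in_bistable_regime(self, stem_cell):
        g, dec, comp, cover = _scc_setup(stem_cell)
        char = evaluate_characteristic(
            stem_cell, g, comp, cover, upstream={"x1": 0.5},
            overrides={"eN": 0.5, "eM": 0.5},
        )
        zeros = find_zeros(char)
        kappas = [z.kappa for z in zeros if not z.tangency]
        assert len(kappas) == 3
        np.testing.assert_allclose(kappas, [0.20, 0.75, 1.66], atol=0.01)
        slopes = [z.slope for z in zeros]
        assert slopes[0] < 0 and slopes[1] > 0 and slopes[2] < 0

    def test_tangent_parabola_reports_candidate_not_zero(self):
        m = parse_model(
            "variables: [x1]\nrates: {x1: (x1 - 1)^2}\nbounds: {x1: [0, 2]}"
        )
        g = build_igraph(m)
        cover = cover_for_subgraph(g, [0])
        assert cover.is_lvg  # state-dependent self-influence is a self-loop
        char = evaluate_characteristic(m, g, [0], cover)
        zeros = find_zeros(char)
        assert [z.tangency for z in zeros] == [True]
        assert zeros[0].kappa == pytest.approx(1.0, abs=1e-3)

    def test_zero_locations_stable_under_grid_refinement(self, tryptophan):
        g, dec, comp, cover = _scc_setup(tryptophan)
        locs = []
        for npts in (301, 601):
            char = evaluate_characteristic(
                tryptophan, g, comp, cover, grid=np.linspace(0, 200, npts)
            )
            zeros = find_zeros(char)
            assert len(zeros) == 1
            locs.append(zeros[0].kappa)
        assert abs(locs[0] - locs[1]) < 1e-7


class TestAssembly:
    def test_unique_progenitor_state(self, stem_cell):
        rep = assemble_fixed_points(stem_cell)
        assert len(rep) == 1
        fp = rep.points[0]
        assert fp.residual < 1e-8
        np.testing.assert_allclose(fp.x[:4], [0.2, 0.81, 0.43, 0.14], atol=0.01)

    def test_bistable_regime_has_three_states(self, stem_cell):
        rep = assemble_fixed_points(stem_cell, overrides={"eN": 0.5, "eM": 0.5})
        assert len(rep) == 3
        xs = rep.coords()
        np.testing.assert_allclose(sorted(xs[:, 1]), [0.20, 0.75, 1.66], atol=0.01)

    @pytest.mark.parametrize("model_name, overrides", [
        ("stem_cell", None),
        ("stem_cell", {"eN": 0.5, "eM": 0.5}),
        ("repressilator", None),
        ("tryptophan", None),
    ])
    def test_equivalence_with_multistart_oracle(self, model_name, overrides, request):
        model = request.getfixturevalue(model_name)
        rep = assemble_fixed_points(model, overrides=overrides)
        oracle = multistart_fixed_points(model, overrides=overrides, seed=5)
        assert len(rep) == len(oracle)
        for fp, ox in zip(rep.points, oracle):
            scale = max(1.0, np.max(np.abs(ox)))
            assert np.max(np.abs(fp.x - ox)) < 1e-6 * scale

    def test_no_root_in_bounds_yields_empty_report_with_diagnostic(self):
        m = parse_model(
            "variables: [x1]\nrates: {x1: 2 - x1}\nbounds: {x1: [0, 1]}"
        )
        rep = assemble_fixed_points(m)
        assert len(rep) == 0
        assert rep.diagnostics

    def test_multiple_upstream_combinations_propagate(self):
        # a bistable upstream variable feeding a linear follower: the
        # follower inherits both upstream states
        m = parse_model(
            "variables: [x1, x2]\n"
            "rates: {x1: 4*x1^2/(1+x1^2) - x1, x2: x1 - x2}\n"
            "bounds: {x1: [0, 5], x2: [0, 5]}"
        )
        rep = assemble_fixed_points(m)
        oracle = multistart_fixed_points(m, seed=2)
        assert len(rep) == len(oracle) == 3
        for fp, ox in zip(rep.points, oracle):
            np.testing.assert_allclose(fp.x, ox, atol=1e-8)
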