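"""Core circuit-breaking steps: break, solve, close, characteristic, assemble.

For one strongly connected component with circuit cover ``(v_1, ..., v_m)``:

* breaking removes all in-edges of the cover, leaving an acyclic subproblem
  whose variables can be solved one-dimensionally in topological order for
  any cover values ``kappa`` (dense sign-change bracketing, multiple roots
  spawn branches);
* circuits are re-closed by releasing ``v_m, ..., v_2`` one after another,
  each release solving the implicit partial characteristic
  ``f_i(x_i, kappa, F(kappa)) = 0``;
* the remaining one-dimensional function ``c(kappa_1) = f_1(kappa_1,
  F(kappa_1))`` is the circuit-characteristic, whose zeros are the
  fixed-point coordinates of the leading variable;
* back-substitution at each zero and a damped-Newton polish assemble the
  full-system fixed points across the SCC hierarchy.

Everything here is deterministic: roots come from fixed grids and bracketed
refinement, never from random starts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.optimize import brentq, minimize_scalar

from .config import DEFAULT_CONFIG, CBAConfig
from .errors import EngineError
from .graphs import CircuitCover, cover_for_subgraph, scc_decompose
from .model import InteractionGraph, RegulatoryModel, build_igraph


# ---------------------------------------------------------------------------
# one-dimensional root machinery
# ---------------------------------------------------------------------------

def _bracket_roots(
    g_vec: Callable[[np.ndarray], np.ndarray],
    g_scalar: Callable[[float], float],
    lo: float,
    hi: float,
    n_scan: int,
    tol_root: float,
) -> list[float]:
    """All roots of ``g`` in ``[lo, hi]`` found by dense scan + brentq."""
    xs = np.linspace(lo, hi, n_scan + 1)
    with np.errstate(all="ignore"):
        ys = np.asarray(g_vec(xs), dtype=float)
    roots: list[float] = []
    sep = (hi - lo) * 1e-12 + 1e-300

    def push(r: float) -> None:
        for r0 in roots:
            if abs(r - r0) <= max(sep, 1e-9 * max(1.0, abs(r0))):
                return
        roots.append(r)

    for k in range(n_scan + 1):
        if np.isfinite(ys[k]) and ys[k] == 0.0:
            push(float(xs[k]))
    for k in range(n_scan):
        a, b = ys[k], ys[k + 1]
        if not (np.isfinite(a) and np.isfinite(b)):
            continue
        if a == 0.0 or b == 0.0 or a * b > 0:
            continue
        r = brentq(g_scalar, xs[k], xs[k + 1], xtol=1e-13, rtol=1e-15, maxiter=200)
        if abs(g_scalar(r)) <= max(tol_root, 1e-9 * max(np.abs(ys[np.isfinite(ys)]).max(), 1.0)):
            push(float(r))
    roots.sort()
    return roots


def _track_columns(per_point: list[list], vec: Callable) -> list[dict[int, object]]:
    """Group set-valued samples along a grid into continuation columns.

    ``per_point[t]`` is the list of items observed at grid index ``t``;
    ``vec(item)`` maps an item to a coordinate vector.  Items are matched to
    existing columns greedily by nearest distance; unmatched items open new
    columns.  Returns one ``{t: item}`` dict per column.
    """
    columns: list[dict[int, object]] = []
    last_vec: list[np.ndarray] = []
    for t, items in enumerate(per_point):
        if not items:
            continue
        vecs = [np.asarray(vec(it), dtype=float) for it in items]
        pairs = []
        for ci, lv in enumerate(last_vec):
            for ii, v in enumerate(vecs):
                d = float(np.max(np.abs(lv - v)))
                pairs.append((d, ci, ii))
        pairs.sort()
        used_c: set[int] = set()
        used_i: set[int] = set()
        for d, ci, ii in pairs:
            if ci in used_c or ii in used_i:
                continue
            used_c.add(ci)
            used_i.add(ii)
            columns[ci][t] = items[ii]
            last_vec[ci] = vecs[ii]
        for ii, it in enumerate(items):
            if ii not in used_i:
                columns.append({t: it})
                last_vec.append(vecs[ii])
    return columns


# ---------------------------------------------------------------------------
# SCC solver
# ---------------------------------------------------------------------------

def break_circuits(
    graph: InteractionGraph,
    scc_vertices: Sequence[int],
    cover: CircuitCover,
) -> tuple[int, ...]:
    """CBA step 2(c): evaluation order of the complement after breaking.

    Removes all in-edges of the cover within the SCC subgraph and returns a
    topological order of the complement vertices (cover values act as fixed
    inputs ``kappa``).  Raises if a residual cycle remains, which would mean
    the cover does not actually hit every circuit.
    """
    import networkx as nx

    vs = set(scc_vertices)
    g = nx.DiGraph()
    g.add_nodes_from(sorted(vs))
    for (j, i) in graph.edges:
        if j in vs and i in vs and i not in set(cover.cover):
            g.add_edge(j, i)
    if not nx.is_directed_acyclic_graph(g):
        raise EngineError("breaking the cover left a cycle; cover is not a hitting set")
    order = [v for v in nx.lexicographical_topological_sort(g) if v not in set(cover.cover)]
    return tuple(order)


class SCCSolver:
    """Solves one SCC's fixed-point structure for a given upstream input."""

    def __init__(
        self,
        model: RegulatoryModel,
        graph: InteractionGraph,
        scc_vertices: Sequence[int],
        cover: CircuitCover,
        upstream: Mapping | None = None,
        cfg: CBAConfig = DEFAULT_CONFIG,
        overrides: Mapping[str, float] | None = None,
    ) -> None:
        self.model = model
        self.cfg = cfg
        self.overrides = dict(overrides) if overrides else None
        self.scc = tuple(sorted(scc_vertices))
        self.cover = cover
        self.m = len(cover.cover)
        self.order = break_circuits(graph, self.scc, cover)
        self.no_root_events = 0
        template = 0.5 * (model.bounds[:, 0] + model.bounds[:, 1])
        for key, val in (upstream or {}).items():
            template[model.index(key)] = float(val)
        self.template = template

    # -- scalar rate helpers ------------------------------------------------
    def _f(self, i: int, state: np.ndarray) -> float:
        return float(self.model.rate_component(i, state, self.overrides))

    def _solve_var(self, p: int, state: np.ndarray) -> list[float]:
        lo, hi = self.model.bounds[p]
        g_vec = lambda xs: self.model.rate_component(
            p, state, self.overrides, scan_var=p, scan_values=xs
        )

        def g_scalar(x: float) -> float:
            st = state.copy()
            st[p] = x
            return self._f(p, st)

        return _bracket_roots(g_vec, g_scalar, lo, hi, self.cfg.n_scan, self.cfg.tol_root)

    # -- step 2(d): acyclic downstream solve --------------------------------
    def downstream(self, kappa: Mapping[int, float]) -> list[np.ndarray]:
        """Fixed-point coordinates of the complement, given cover values."""
        state = self.template.copy()
        for v, val in kappa.items():
            state[int(v)] = float(val)
        branches = [state]
        for p in self.order:
            nxt: list[np.ndarray] = []
            for st in branches:
                for r in self._solve_var(p, st):
                    st2 = st.copy()
                    st2[p] = r
                    nxt.append(st2)
            if not nxt:
                self.no_root_events += 1
            branches = nxt
            if len(branches) > self.cfg.max_branches:
                raise EngineError(
                    f"more than {self.cfg.max_branches} downstream branches; "
                    "raise max_branches in the configuration"
                )
        return branches

    # -- step 2(e): iterative circuit closing -------------------------------
    def _solve_from(self, j: int, kappa: dict[int, float]) -> list[np.ndarray]:
        """Branches of all SCC variables except ``v_1..v_j`` being fixed."""
        if j == self.m:
            return self.downstream(kappa)
        v = self.cover.cover[j]
        lo, hi = self.model.bounds[v]
        xs = np.linspace(lo, hi, self.cfg.n_scan + 1)
        evals: list[list[tuple[float, np.ndarray]]] = []
        for x in xs:
            states = self._solve_from(j + 1, {**kappa, v: float(x)})
            items = []
            for st in states:
                st = st.copy()
                st[v] = float(x)
                items.append((self._f(v, st), st))
            evals.append(items)
        idx = list(self.scc)
        cols = _track_columns(evals, vec=lambda it: it[1][idx])
        out: list[np.ndarray] = []
        for col in cols:
            ts = sorted(col)
            for a, b in zip(ts, ts[1:]):
                if b != a + 1:
                    continue
                fa, fb = col[a][0], col[b][0]
                if not (np.isfinite(fa) and np.isfinite(fb)):
                    continue
                if fa == 0.0:
                    out.append(col[a][1])
                    continue
                if fa * fb >= 0:
                    continue
                ref = col[a][1][idx]

                def g(x: float) -> float:
                    states = self._solve_from(j + 1, {**kappa, v: float(x)})
                    if not states:
                        return np.nan
                    st = min(states, key=lambda s: float(np.max(np.abs(s[idx] - ref))))
                    st = st.copy()
                    st[v] = float(x)
                    return self._f(v, st)

                r = brentq(g, xs[a], xs[b], xtol=1e-13, rtol=1e-15, maxiter=200)
                states = self._solve_from(j + 1, {**kappa, v: float(r)})
                if not states:
                    continue
                st = min(states, key=lambda s: float(np.max(np.abs(s[idx] - ref))))
                st = st.copy()
                st[v] = float(r)
                out.append(st)
            last = ts[-1]
            if col[last][0] == 0.0 and last == len(xs) - 1:
                out.append(col[last][1])
        if len(out) > self.cfg.max_branches:
            raise EngineError("released-vertex root set exceeds max_branches")
        return out

    # -- the characteristic -------------------------------------------------
    def branches_at(self, kappa1: float) -> list[tuple[float, np.ndarray]]:
        """All consistent ``(c, state)`` pairs at one leading-vertex value."""
        v1 = self.cover.cover[0]
        states = self._solve_from(1, {v1: float(kappa1)})
        items = []
        for st in states:
            st = st.copy()
            st[v1] = float(kappa1)
            items.append((self._f(v1, st), st))
        return items


# ---------------------------------------------------------------------------
# characteristic container
# ---------------------------------------------------------------------------

@dataclass
class Zero:
    """One zero (or tangency candidate) of a circuit-characteristic."""

    kappa: float
    slope: float
    tangency: bool
    branch: int
    state: np.ndarray  # full-model state with the SCC coordinates filled in


@dataclass
class Characteristic:
    """Sampled circuit-characteristic of one SCC for one upstream input."""

    scc: tuple[int, ...]
    cover: CircuitCover
    leading_vertex: int
    upstream: dict[int, float]
    grid: np.ndarray
    values: np.ndarray          # (n_branches, n_grid), NaN where a branch has a hole
    states: np.ndarray          # (n_branches, n_grid, n_model), NaN-padded
    zeros: list[Zero] = field(default_factory=list)
    _eval: Callable[[float], list[tuple[float, np.ndarray]]] | None = field(
        default=None, repr=False, compare=False
    )

    @property
    def n_branches(self) -> int:
        return self.values.shape[0]

    def value_at(self, kappa: float, ref_state: np.ndarray | None = None) -> float:
        """Continuous re-evaluation of ``c`` at ``kappa`` (branch-selected)."""
        items = self._eval(float(kappa))
        if not items:
            return np.nan
        if ref_state is None or len(items) == 1:
            return items[0][0]
        idx = list(self.scc)
        ref = np.asarray(ref_state)[idx]
        it = min(items, key=lambda t: float(np.nanmax(np.abs(t[1][idx] - ref))))
        return it[0]


def evaluate_characteristic(
    model: RegulatoryModel,
    graph: InteractionGraph,
    scc_vertices: Sequence[int],
    cover: CircuitCover,
    upstream: Mapping | None = None,
    grid: np.ndarray | None = None,
    cfg: CBAConfig = DEFAULT_CONFIG,
    overrides: Mapping[str, float] | None = None,
) -> Characteristic:
    """CBA step 2(e): sample ``c(kappa_1)`` over the leading variable's bounds.

    For a circuit-free singleton SCC the characteristic degenerates to the
    rate function itself restricted to the line (identity case), which is
    also what this returns when the cover is empty.
    """
    scc = tuple(sorted(scc_vertices))
    if not cover.cover:
        if len(scc) != 1:
            raise EngineError("empty cover on a multi-vertex SCC")
        v1 = scc[0]
        solver = SCCSolver(model, graph, scc, CircuitCover((), (v1,), ()), upstream, cfg, overrides)
    else:
        v1 = cover.cover[0]
        solver = SCCSolver(model, graph, scc, cover, upstream, cfg, overrides)
    if grid is None:
        lo, hi = model.bounds[v1]
        grid = np.linspace(lo, hi, cfg.grid_points)
    grid = np.asarray(grid, dtype=float)
    if grid.size < 3:
        raise EngineError("characteristic grid needs at least 3 points")

    per_point = [solver.branches_at(k) for k in grid]
    n_empty = sum(1 for it in per_point if not it)
    if n_empty > 0.5 * grid.size:
        raise EngineError(
            "no downstream roots at more than half of the grid; widen the bounds"
        )
    idx = list(scc)
    cols = _track_columns(per_point, vec=lambda it: it[1][idx])
    nb = max(1, len(cols))
    values = np.full((nb, grid.size), np.nan)
    states = np.full((nb, grid.size, model.n), np.nan)
    for b, col in enumerate(cols):
        for t, (c, st) in col.items():
            values[b, t] = c
            states[b, t] = st
    upstream_idx = {model.index(k): float(v) for k, v in (upstream or {}).items()}
    return Characteristic(
        scc=scc,
        cover=cover if cover.cover else CircuitCover((), (v1,), ()),
        leading_vertex=v1,
        upstream=upstream_idx,
        grid=grid,
        values=values,
        states=states,
        _eval=solver.branches_at,
    )


def _fd_slope(char: Characteristic, kappa: float, ref_state: np.ndarray) -> float:
    """Five-point central-difference slope of the (branch-selected) curve."""
    lo, hi = char.grid[0], char.grid[-1]
    span = hi - lo
    h = max(1e-7, 1e-3 * span)
    x0 = min(max(kappa, lo + 2 * h), hi - 2 * h)
    c = [char.value_at(x0 + k * h, ref_state) for k in (-2, -1, 1, 2)]
    if not all(np.isfinite(c)):
        h = max(1e-7, 1e-4 * span)
        x0 = min(max(kappa, lo + 2 * h), hi - 2 * h)
        c = [char.value_at(x0 + k * h, ref_state) for k in (-2, -1, 1, 2)]
    return float((c[0] - 8 * c[1] + 8 * c[2] - c[3]) / (12 * h))


def find_zeros(char: Characteristic, cfg: CBAConfig = DEFAULT_CONFIG) -> list[Zero]:
    """Zeros of the characteristic: bracketed sign changes plus tangencies.

    Sign changes between adjacent grid points are refined by Brent's method.
    Interior local minima of ``|c|`` below ``tol_tangent * max(1, max|c|)``
    without a sign change are refined continuously; if the refined extremum
    actually crosses zero the hidden pair is returned as two regular zeros,
    otherwise it is reported once with the tangency flag (a saddle-node
    candidate).  Slopes come from a five-point finite difference on the
    re-evaluated curve.  The zero list is also stored on ``char.zeros``.
    """
    grid = char.grid
    zeros: list[Zero] = []
    finite_vals = char.values[np.isfinite(char.values)]
    scale = max(1.0, np.max(np.abs(finite_vals)) if finite_vals.size else 1.0)
    for b in range(char.n_branches):
        v = char.values[b]
        sts = char.states[b]
        sign_change_cells: set[int] = set()
        for t in range(grid.size - 1):
            a, c2 = v[t], v[t + 1]
            if not (np.isfinite(a) and np.isfinite(c2)):
                continue
            if a == 0.0:
                z = grid[t]
                st = sts[t]
                prev = v[t - 1] if t > 0 else np.nan
                # an exact grid zero with same-sign neighbours is a tangency
                tang = bool(
                    np.isfinite(prev) and np.isfinite(c2) and prev * c2 > 0
                )
                zeros.append(Zero(float(z), _fd_slope(char, float(z), st), tang, b, st.copy()))
                sign_change_cells.add(t)
                if t > 0:
                    sign_change_cells.add(t - 1)
                continue
            if a * c2 < 0:
                ref = sts[t]
                g = lambda x: char.value_at(x, ref)
                r = brentq(g, grid[t], grid[t + 1], xtol=1e-13, rtol=1e-15, maxiter=200)
                items = char._eval(float(r))
                idx = list(char.scc)
                st = min(items, key=lambda it: float(np.max(np.abs(it[1][idx] - ref[idx]))))[1].copy()
                st[char.leading_vertex] = float(r)
                zeros.append(Zero(float(r), _fd_slope(char, float(r), st), False, b, st))
                sign_change_cells.add(t)
        # tangency candidates: interior local minima of |c| with no sign change
        for t in range(1, grid.size - 1):
            trio = v[t - 1 : t + 2]
            if not np.all(np.isfinite(trio)):
                continue
            if not (abs(v[t]) <= abs(v[t - 1]) and abs(v[t]) <= abs(v[t + 1])):
                continue
            if {t - 1, t} & sign_change_cells:
                continue
            if abs(v[t]) >= cfg.tol_tangent * scale:
                continue
            ref = sts[t]
            sgn = np.sign(v[t])
            g = lambda x: sgn * char.value_at(x, ref)
            res = minimize_scalar(g, bounds=(grid[t - 1], grid[t + 1]), method="bounded",
                                  options={"xatol": 1e-12})
            x_ext = float(res.x)
            c_ext = sgn * float(res.fun)
            if np.isfinite(c_ext) and c_ext * v[t - 1] < 0:
                # the extremum crosses zero between the grid points: hidden pair
                gg = lambda x: char.value_at(x, ref)
                for aa, bb in ((grid[t - 1], x_ext), (x_ext, grid[t + 1])):
                    try:
                        r = brentq(gg, aa, bb, xtol=1e-13, rtol=1e-15, maxiter=200)
                    except ValueError:
                        continue
                    st = ref.copy()
                    st[char.leading_vertex] = float(r)
                    zeros.append(Zero(float(r), _fd_slope(char, float(r), st), False, b, st))
            else:
                st = ref.copy()
                st[char.leading_vertex] = x_ext
                zeros.append(Zero(x_ext, _fd_slope(char, x_ext, st), True, b, st))
    zeros.sort(key=lambda z: z.kappa)
    # drop duplicates produced by adjacent cells
    dedup: list[Zero] = []
    span = grid[-1] - grid[0]
    for z in zeros:
        if dedup and abs(z.kappa - dedup[-1].kappa) < 1e-9 * span and z.tangency == dedup[-1].tangency:
            continue
        dedup.append(z)
    char.zeros = dedup
    return dedup


# ---------------------------------------------------------------------------
# full-system assembly
# ---------------------------------------------------------------------------

@dataclass
class FixedPoint:
    """One assembled fixed point with its provenance through the hierarchy."""

    x: np.ndarray
    residual: float
    provenance: tuple = ()

    def coord(self, model: RegulatoryModel, var: str) -> float:
        return float(self.x[model.index(var)])


@dataclass
class FixedPointReport:
    points: list[FixedPoint]
    diagnostics: list[str] = field(default_factory=list)
    characteristics: list[Characteristic] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.points)

    def coords(self) -> np.ndarray:
        if not self.points:
            return np.empty((0, 0))
        return np.vstack([p.x for p in self.points])


def newton_polish(
    model: RegulatoryModel,
    x0: Sequence[float],
    cfg: CBAConfig = DEFAULT_CONFIG,
    overrides: Mapping[str, float] | None = None,
) -> tuple[np.ndarray, float]:
    """Damped Newton refinement of ``f(x) = 0`` using the analytic Jacobian."""
    x = np.asarray(x0, dtype=float).copy()
    try:
        fx = model.rhs(x, overrides)
    except Exception:
        return x, np.inf
    for _ in range(cfg.newton_max_iter):
        nf = float(np.max(np.abs(fx)))
        if nf < 1e-14:
            break
        try:
            J = model.jacobian(x, overrides)
        except Exception:
            break
        try:
            step = np.linalg.solve(J, -fx)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(J, -fx, rcond=None)[0]
        lam = 1.0
        improved = False
        while lam > 1e-10:
            xn = x + lam * step
            try:
                fn = model.rhs(xn, overrides)
            except Exception:
                lam *= 0.5
                continue
            if np.all(np.isfinite(fn)) and float(np.max(np.abs(fn))) < nf:
                x, fx = xn, fn
                improved = True
                break
            lam *= 0.5
        if not improved:
            break
    return x, float(np.max(np.abs(fx)))


def _dedup_points(points: list[FixedPoint], tol: float) -> list[FixedPoint]:
    kept: list[FixedPoint] = []
    for p in points:
        scale = max(1.0, float(np.max(np.abs(p.x))))
        dup = False
        for q in kept:
            if float(np.max(np.abs(p.x - q.x))) < tol * scale:
                if p.residual < q.residual:
                    kept[kept.index(q)] = p
                dup = True
                break
        if not dup:
            kept.append(p)
    kept.sort(key=lambda p: tuple(np.round(p.x, 9)))
    return kept


def assemble_fixed_points(
    model: RegulatoryModel,
    cfg: CBAConfig = DEFAULT_CONFIG,
    overrides: Mapping[str, float] | None = None,
    graph: InteractionGraph | None = None,
    include_tangent: bool = False,
    keep_characteristics: bool = False,
) -> FixedPointReport:
    """Run the full CBA over the SCC hierarchy and return polished fixed points.

    SCCs are processed in hierarchical order; every combination of upstream
    fixed-point coordinates serves as constant input ``u`` for the next
    component, whose characteristic zeros are back-substituted into full
    coordinates.  Assembled states are polished by damped Newton and
    deduplicated; points escaping the bounds box or exceeding ``tol_fp``
    residual are dropped with a diagnostic.
    """
    if graph is None:
        graph = build_igraph(model, overrides=overrides)
    dec = scc_decompose(graph)
    diagnostics: list[str] = []
    chars: list[Characteristic] = []
    partials: list[dict[int, float]] = [{}]
    prov: list[tuple] = [()]

    for k, comp in enumerate(dec.components):
        cover = cover_for_subgraph(graph, comp, cfg.circuit_cap, cfg.exhaustive_cap)
        nxt_partials: list[dict[int, float]] = []
        nxt_prov: list[tuple] = []
        for st, pv in zip(partials, prov):
            if not cover.circuits:
                solver = SCCSolver(model, graph, comp, cover, st, cfg, overrides)
                sols = [
                    ({v: float(b[v]) for v in comp}, (k, "acyclic", None, None, False))
                    for b in solver.downstream({})
                ]
            else:
                char = evaluate_characteristic(
                    model, graph, comp, cover, st, None, cfg, overrides
                )
                zeros = find_zeros(char, cfg)
                if keep_characteristics:
                    chars.append(char)
                sols = []
                for z in zeros:
                    if z.tangency and not include_tangent:
                        continue
                    sols.append((
                        {v: float(z.state[v]) for v in comp},
                        (k, "zero", z.kappa, z.slope, cover.is_lvg),
                    ))
            if not sols:
                diagnostics.append(
                    f"SCC {k} ({[model.names[v] for v in comp]}) has no fixed point "
                    "in bounds for one upstream input"
                )
                continue
            for coords, meta in sols:
                nxt_partials.append({**st, **coords})
                nxt_prov.append(pv + (meta,))
        partials, prov = nxt_partials, nxt_prov
        if not partials:
            break

    points: list[FixedPoint] = []
    lo = model.bounds[:, 0]
    hi = model.bounds[:, 1]
    margin = 1e-7 * (hi - lo)
    for st, pv in zip(partials, prov):
        x0 = np.array([st[i] for i in range(model.n)], dtype=float)
        x, res = newton_polish(model, x0, cfg, overrides)
        if not np.isfinite(res) or res > cfg.tol_fp:
            diagnostics.append(
                f"candidate at {np.round(x0, 6).tolist()} failed to polish "
                f"(residual {res:.3g})"
            )
            continue
        if np.any(x < lo - margin) or np.any(x > hi + margin):
            diagnostics.append(
                f"polished point {np.round(x, 6).tolist()} left the bounds box"
            )
            continue
        points.append(FixedPoint(x=x, residual=res, provenance=pv))

    return FixedPointReport(
        points=_dedup_points(points, cfg.tol_dedup),
        diagnostics=diagnostics,
        characteristics=chars,
    )
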