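"""Parameter sweeps, fold location and Hopf detection along fixed-point branches.

A sweep reruns the full circuit-breaking assembly plus eigenvalue
classification on a parameter grid (optionally with linked parameters such
as a second synthesis rate tied to the swept one) and matches fixed points
across adjacent values by nearest continuation.  Saddle-node candidates are
where the characteristic touches zero without crossing - operationally, a
change of the zero count between adjacent sweep values, refined by
bisection.  Hopf candidates are sign changes of the largest eigenvalue real
part with nonzero imaginary part along a continued branch; the
characteristic itself is blind to them, so they are refined by Newton
continuation of the fixed point, not by re-gridding the characteristic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import sympy as sp

from .config import DEFAULT_CONFIG, CBAConfig
from .engine import assemble_fixed_points, newton_polish
from .errors import ModelError
from .model import InteractionGraph, RegulatoryModel, build_igraph
from .stability import classify_fixed_point


@dataclass
class BranchPoint:
    param: float
    x: np.ndarray
    classification: str
    max_re: float
    eigenvalues: np.ndarray


@dataclass
class Branch:
    id: int
    points: list[BranchPoint] = field(default_factory=list)


@dataclass
class BifurcationEvent:
    kind: str                 # saddle_node_candidate | hopf_candidate
    param: float
    bracket: tuple[float, float]
    state: np.ndarray | None = None
    branch: int | None = None
    frequency: float | None = None  # |Im lambda| at a Hopf crossing


@dataclass
class BifurcationScan:
    parameter: str
    values: np.ndarray
    linked: dict[str, str]
    branches: list[Branch]
    points_per_value: list[list[BranchPoint]]
    events: list[BifurcationEvent] = field(default_factory=list)

    def counts(self) -> list[int]:
        return [len(pts) for pts in self.points_per_value]


def _linked_fns(parameter: str, linked: Mapping[str, str] | None):
    """Compile ``name -> expression-of-swept-parameter`` linkages."""
    fns = {}
    psym = sp.Symbol(parameter)
    for name, expr in (linked or {}).items():
        e = sp.sympify(expr, locals={parameter: psym})
        extra = e.free_symbols - {psym}
        if extra:
            raise ModelError(
                f"linkage for {name!r} may only use the swept parameter {parameter!r}"
            )
        fns[name] = sp.lambdify(psym, e, modules="math")
    return fns


def _overrides_at(parameter: str, value: float, linked_fns: Mapping) -> dict[str, float]:
    ov = {parameter: float(value)}
    for name, fn in linked_fns.items():
        ov[name] = float(fn(value))
    return ov


def _rel_dist(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.max(np.abs(a - b)) / max(1.0, float(np.max(np.abs(b)))))


def sweep_parameter(
    model: RegulatoryModel,
    parameter: str,
    values: Sequence[float],
    linked: Mapping[str, str] | None = None,
    cfg: CBAConfig = DEFAULT_CONFIG,
    graph: InteractionGraph | None = None,
    jump_tol: float = 0.25,
) -> BifurcationScan:
    """Assemble and classify fixed points on a parameter grid.

    The interaction graph is derived once from the model's declared
    parameters: a parameter value that happens to null an interaction only
    removes circuits, and breaking a superset of circuits is always valid.
    """
    if parameter not in model.params:
        raise ModelError(f"unknown parameter {parameter!r}")
    fns = _linked_fns(parameter, linked)
    if graph is None:
        graph = build_igraph(model)
    vals = np.asarray(list(values), dtype=float)
    branches: list[Branch] = []
    per_value: list[list[BranchPoint]] = []
    active: dict[int, BranchPoint] = {}
    for v in vals:
        ov = _overrides_at(parameter, v, fns)
        report = assemble_fixed_points(model, cfg, ov, graph=graph)
        pts = []
        for fp in report.points:
            rep = classify_fixed_point(model, fp.x, cfg, ov)
            pts.append(BranchPoint(float(v), fp.x, rep.classification, rep.max_real, rep.eigenvalues))
        per_value.append(pts)
        pairs = []
        for bid, last in active.items():
            for i, p in enumerate(pts):
                pairs.append((_rel_dist(p.x, last.x), bid, i))
        pairs.sort()
        used_b: set[int] = set()
        used_i: set[int] = set()
        nxt_active: dict[int, BranchPoint] = {}
        # with an unchanged point count this is a pure continuation step and
        # the nearest matching is accepted unconditionally; the jump
        # threshold only guards steps where points appear or disappear
        free_match = len(pts) == len(active)
        for d, bid, i in pairs:
            if bid in used_b or i in used_i or (not free_match and d > jump_tol):
                continue
            used_b.add(bid)
            used_i.add(i)
            branches[bid].points.append(pts[i])
            nxt_active[bid] = pts[i]
        for i, p in enumerate(pts):
            if i not in used_i:
                b = Branch(id=len(branches), points=[p])
                branches.append(b)
                nxt_active[b.id] = p
        active = nxt_active
    return BifurcationScan(
        parameter=parameter,
        values=vals,
        linked=dict(linked or {}),
        branches=branches,
        points_per_value=per_value,
    )


def locate_saddle_node(
    scan: BifurcationScan,
    model: RegulatoryModel,
    cfg: CBAConfig = DEFAULT_CONFIG,
    graph: InteractionGraph | None = None,
) -> list[BifurcationEvent]:
    """Refine every change of the fixed-point count to a fold candidate.

    Bisects the parameter between adjacent sweep values whose counts differ
    until the bracket is below ``tol_param`` (relative); the tangent state is
    read off on the many-points side as the midpoint of the merging pair.
    Because the zero finder refines near-tangent local extrema of the
    characteristic continuously, the count stays correct arbitrarily close
    to the fold.
    """
    fns = _linked_fns(scan.parameter, scan.linked)
    if graph is None:
        graph = build_igraph(model)
    counts = scan.counts()

    def count_at(p: float) -> tuple[int, list[np.ndarray]]:
        ov = _overrides_at(scan.parameter, p, fns)
        rep = assemble_fixed_points(model, cfg, ov, graph=graph)
        return len(rep.points), [fp.x for fp in rep.points]

    events: list[BifurcationEvent] = []
    for i in range(len(scan.values) - 1):
        if counts[i] == counts[i + 1]:
            continue
        a, b = float(scan.values[i]), float(scan.values[i + 1])
        ca, cb = counts[i], counts[i + 1]
        for _ in range(cfg.bisect_max_iter):
            if abs(b - a) <= cfg.tol_param * max(1.0, abs(a)):
                break
            mid = 0.5 * (a + b)
            cm, _pts = count_at(mid)
            if cm == ca:
                a = mid
            else:
                b, cb = mid, cm
        hi_side = b if cb > ca else a
        n_pts, pts = count_at(hi_side)
        state = None
        if len(pts) >= 2:
            dists = [
                (float(np.max(np.abs(pts[p] - pts[q]))), p, q)
                for p in range(len(pts))
                for q in range(p + 1, len(pts))
            ]
            _, p, q = min(dists)
            state = 0.5 * (pts[p] + pts[q])
        events.append(
            BifurcationEvent(
                kind="saddle_node_candidate",
                param=0.5 * (a + b),
                bracket=(min(a, b), max(a, b)),
                state=state,
            )
        )
    scan.events.extend(events)
    return events


def detect_hopf(
    scan: BifurcationScan,
    model: RegulatoryModel,
    cfg: CBAConfig = DEFAULT_CONFIG,
) -> list[BifurcationEvent]:
    """Refine sign changes of ``max Re lambda`` along each continued branch.

    Only crossings whose critical eigenvalue has nonzero imaginary part are
    Hopf candidates; a real eigenvalue through zero belongs to a fold and is
    left to :func:`locate_saddle_node`.  Refinement continues the fixed
    point by damped Newton from the interpolated branch state, so it stays
    cheap even when the sweep grid is coarse.
    """
    fns = _linked_fns(scan.parameter, scan.linked)

    def eig_at(p: float, x0: np.ndarray):
        ov = _overrides_at(scan.parameter, p, fns)
        x, res = newton_polish(model, x0, cfg, ov)
        if not np.isfinite(res) or res > cfg.tol_fp:
            return None
        rep = classify_fixed_point(model, x, cfg, ov)
        return x, rep.max_real, rep.eigenvalues

    events: list[BifurcationEvent] = []
    for branch in scan.branches:
        for p0, p1 in zip(branch.points, branch.points[1:]):
            if not np.isfinite(p0.max_re) or not np.isfinite(p1.max_re):
                continue
            if np.sign(p0.max_re) == np.sign(p1.max_re) or p0.max_re == p1.max_re == 0:
                continue
            a, fa, xa = p0.param, p0.max_re, p0.x
            b, fb, xb = p1.param, p1.max_re, p1.x
            crit_im = None
            for _ in range(cfg.bisect_max_iter):
                if abs(b - a) <= cfg.tol_param * max(1.0, abs(a)):
                    break
                mid = 0.5 * (a + b)
                w = (mid - a) / (b - a) if b != a else 0.5
                res = eig_at(mid, (1 - w) * xa + w * xb)
                if res is None:
                    break
                xm, fm, eig = res
                crit = eig[np.argmax(eig.real)]
                crit_im = abs(float(crit.imag))
                if np.sign(fm) == np.sign(fa):
                    a, fa, xa = mid, fm, xm
                else:
                    b, fb, xb = mid, fm, xm
            tolJ = cfg.tol_eig_rel * max(
                1.0, float(np.linalg.norm(model.jacobian(xa)))
            )
            if crit_im is None:
                res = eig_at(0.5 * (a + b), 0.5 * (xa + xb))
                if res is not None:
                    eig = res[2]
                    crit_im = abs(float(eig[np.argmax(eig.real)].imag))
            if crit_im is not None and crit_im > tolJ:
                events.append(
                    BifurcationEvent(
                        kind="hopf_candidate",
                        param=0.5 * (a + b),
                        bracket=(min(a, b), max(a, b)),
                        state=0.5 * (xa + xb),
                        frequency=crit_im,
                    )
                )
    scan.events.extend(events)
    return events
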