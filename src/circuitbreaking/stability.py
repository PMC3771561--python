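"""Stability of fixed points and the determinant-ratio slope identity.

A hyperbolic fixed point is classified from the eigenvalues of the analytic
Jacobian.  The slope of the circuit-characteristic at a point on the curve
equals ``det J / det J_reduced``, where the reduced Jacobian deletes the
leading vertex's row and column; for a leading-vertex graph (LVG) the
reduced subnetwork is acyclic with negative diagonal, so its determinant has
the fixed sign ``(-1)^(n-1)`` and a positive slope at a zero forces an
eigenvalue with positive real part - the LVG instability test.  A negative
slope carries no stability information (the verdict stays inconclusive).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .config import DEFAULT_CONFIG, CBAConfig
from .engine import FixedPoint, FixedPointReport, assemble_fixed_points
from .errors import SingularReducedJacobianError
from .graphs import CircuitCover, cover_for_subgraph, scc_decompose
from .model import InteractionGraph, RegulatoryModel, build_igraph


@dataclass
class StabilityReport:
    """Eigenvalue classification and slope diagnostics of one fixed point."""

    point: np.ndarray
    eigenvalues: np.ndarray
    classification: str                     # asymptotically_stable | unstable | marginal
    char_slope: float | None = None         # finite-difference slope at the zero
    prop1_slope: float | None = None        # det J / det J_reduced
    lvg_verdict: str = "not_applicable"     # unstable_by_slope | inconclusive | not_applicable

    @property
    def max_real(self) -> float:
        return float(np.max(self.eigenvalues.real))


def classify_fixed_point(
    model: RegulatoryModel,
    x: Sequence[float],
    cfg: CBAConfig = DEFAULT_CONFIG,
    overrides: Mapping[str, float] | None = None,
) -> StabilityReport:
    """Hyperbolic classification from the analytic Jacobian's spectrum.

    Real parts within ``tol_eig_rel * ||J||`` of zero make the point
    ``marginal`` - it is then never claimed stable or unstable (a bifurcation
    scan is the right tool there).
    """
    xv = np.asarray(x, dtype=float)
    J = model.jacobian(xv, overrides)
    eig = np.linalg.eigvals(J)
    tol = cfg.tol_eig_rel * max(1.0, float(np.linalg.norm(J)))
    mx = float(np.max(eig.real))
    if mx > tol:
        cls = "unstable"
    elif mx < -tol:
        cls = "asymptotically_stable"
    else:
        cls = "marginal"
    return StabilityReport(point=xv, eigenvalues=eig, classification=cls)


def _submatrix(J: np.ndarray, keep: Sequence[int]) -> np.ndarray:
    keep = list(keep)
    return J[np.ix_(keep, keep)]


def prop1_slope(
    model: RegulatoryModel,
    x: Sequence[float],
    leading_vertex: int | str,
    scc_vertices: Sequence[int] | None = None,
    overrides: Mapping[str, float] | None = None,
) -> float:
    """Determinant-ratio slope ``det J * det^-1 J_{V minus v1}`` at ``x``.

    ``scc_vertices`` restricts the Jacobian to one component with upstream
    coordinates frozen (the characteristic is a per-SCC object); by default
    the whole system is used.  Raises
    :class:`~circuitbreaking.errors.SingularReducedJacobianError` when the
    reduced determinant vanishes, which typically flags a fold.
    """
    v1 = model.index(leading_vertex)
    J = model.jacobian(np.asarray(x, dtype=float), overrides)
    verts = sorted(scc_vertices) if scc_vertices is not None else list(range(model.n))
    if v1 not in verts:
        raise ValueError("leading vertex not in the SCC")
    Js = _submatrix(J, verts)
    keep = [i for i, v in enumerate(verts) if v != v1]
    Jr = Js[np.ix_(keep, keep)] if keep else np.ones((0, 0))
    det_full = float(np.linalg.det(Js))
    det_red = float(np.linalg.det(Jr)) if keep else 1.0
    scale = max(1.0, float(np.max(np.abs(Jr))) if keep else 1.0) ** max(1, len(keep))
    if abs(det_red) < 1e-12 * scale:
        raise SingularReducedJacobianError(
            f"reduced Jacobian is singular at x={np.round(np.asarray(x, float), 6).tolist()}"
        )
    return det_full / det_red


def lvg_instability_test(
    char_slope: float,
    cover: CircuitCover,
    grid_span: float = 1.0,
    cfg: CBAConfig = DEFAULT_CONFIG,
) -> str:
    """Topology-based instability verdict from the characteristic slope.

    ``unstable_by_slope`` requires both a leading-vertex graph and a slope
    safely above ``tol_slope`` (scaled by the grid span, so shallow
    tangencies are not misread as positive).  A negative slope is
    ``inconclusive`` - it never implies stability.
    """
    if not cover.is_lvg:
        return "not_applicable"
    if char_slope > cfg.tol_slope * max(1.0, grid_span):
        return "unstable_by_slope"
    return "inconclusive"


def reduced_determinant_sign(
    model: RegulatoryModel,
    x: Sequence[float],
    leading_vertex: int | str,
    cover: CircuitCover,
    scc_vertices: Sequence[int] | None = None,
    overrides: Mapping[str, float] | None = None,
    graph: InteractionGraph | None = None,
) -> dict:
    """LVG structure check of the reduced Jacobian.

    For a leading-vertex graph the subnetwork without ``v1`` is acyclic, so
    the reduced determinant equals the product of its diagonal entries; with
    all of them negative its sign is ``(-1)^(n-1)``.  Returns the sign, the
    determinant, the diagonal product and an ``ok`` flag that goes False
    when a non-negative diagonal entry violates the proof's premise.
    """
    if not cover.is_lvg:
        raise ValueError("reduced_determinant_sign requires a leading-vertex graph")
    v1 = model.index(leading_vertex)
    J = model.jacobian(np.asarray(x, dtype=float), overrides)
    verts = sorted(scc_vertices) if scc_vertices is not None else list(range(model.n))
    keep = [v for v in verts if v != v1]
    Jr = _submatrix(J, keep)
    det = float(np.linalg.det(Jr)) if keep else 1.0
    diag = np.diag(Jr)
    diag_product = float(np.prod(diag)) if keep else 1.0
    ok = bool(np.all(diag < 0))
    sign = int((-1) ** len(keep)) if ok else int(np.sign(det)) if det else 0
    return {
        "sign": sign,
        "det": det,
        "diag_product": diag_product,
        "ok": ok,
        "n_reduced": len(keep),
    }


def analyze_fixed_points(
    model: RegulatoryModel,
    cfg: CBAConfig = DEFAULT_CONFIG,
    overrides: Mapping[str, float] | None = None,
    graph: InteractionGraph | None = None,
    report: FixedPointReport | None = None,
) -> list[StabilityReport]:
    """Assemble fixed points via the CBA and attach stability diagnostics.

    Each point's characteristic slope is taken from the zero that produced
    it (stored in its provenance); the determinant-ratio slope and the LVG
    verdict are evaluated per cyclic SCC with upstream coordinates frozen.
    The overall verdict of a point is ``unstable_by_slope`` as soon as one
    of its SCC zeros has a certified positive slope.
    """
    if graph is None:
        graph = build_igraph(model, overrides=overrides)
    if report is None:
        report = assemble_fixed_points(model, cfg, overrides, graph=graph)
    dec = scc_decompose(graph)
    covers = {
        k: cover_for_subgraph(graph, comp, cfg.circuit_cap, cfg.exhaustive_cap)
        for k, comp in enumerate(dec.components)
    }
    out: list[StabilityReport] = []
    for fp in report.points:
        rep = classify_fixed_point(model, fp.x, cfg, overrides)
        verdicts: list[str] = []
        for meta in fp.provenance:
            k, kind, kappa, slope, is_lvg = meta
            if kind != "zero":
                continue
            cover = covers[k]
            comp = dec.components[k]
            rep.char_slope = slope
            try:
                rep.prop1_slope = prop1_slope(
                    model, fp.x, cover.leading_vertex, comp, overrides
                )
            except SingularReducedJacobianError:
                rep.prop1_slope = None
            v1 = cover.leading_vertex
            span = float(model.bounds[v1, 1] - model.bounds[v1, 0])
            verdicts.append(lvg_instability_test(slope, cover, span, cfg))
        if "unstable_by_slope" in verdicts:
            rep.lvg_verdict = "unstable_by_slope"
        elif "inconclusive" in verdicts:
            rep.lvg_verdict = "inconclusive"
        elif verdicts:
            rep.lvg_verdict = "not_applicable"
        out.append(rep)
    return out
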