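"""Regulatory-network ODE models and their interaction graphs.

A :class:`RegulatoryModel` holds one rate expression ``xdot_i = f_i(x; theta)``
per state variable, a parameter map and per-variable search bounds (the
trapping region).  Expressions are plain strings over the declared
identifiers using ``+ - * / ^`` (or ``**``), parentheses and ``exp``; they
are parsed once with sympy and compiled to vectorized numpy callables.

The interaction graph has an edge ``j -> i`` whenever ``d f_i / d x_j`` is
not identically zero; a self-edge marks state-dependent self-regulation
beyond plain linear decay (see :func:`build_igraph` for the two available
self-edge conventions).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import sympy as sp
import yaml
from sympy.parsing.sympy_parser import (
    convert_xor,
    parse_expr,
    standard_transformations,
)

from .errors import ModelError

_TRANSFORMS = standard_transformations + (convert_xor,)
_ALLOWED_FUNCS = {"exp": sp.exp}


def _parse_expression(text: str, where: str, allowed: Mapping[str, sp.Symbol]) -> sp.Expr:
    local = dict(allowed)
    local.update(_ALLOWED_FUNCS)
    try:
        expr = parse_expr(str(text), transformations=_TRANSFORMS, local_dict=local, evaluate=True)
    except Exception as exc:  # sympy raises a zoo of error types
        raise ModelError(f"malformed expression for {where}: {text!r} ({exc})") from exc
    undeclared = sorted(str(s) for s in expr.free_symbols if str(s) not in allowed)
    if undeclared:
        raise ModelError(
            f"undeclared identifier {undeclared[0]!r} in expression for {where}"
        )
    disallowed = sorted(
        {
            type(f).__name__
            for f in expr.atoms(sp.Function)
            if not isinstance(f, tuple(_ALLOWED_FUNCS.values()))
        }
    )
    if disallowed:
        raise ModelError(
            f"unknown function {disallowed[0]!r} in expression for {where}"
        )
    return expr


class RegulatoryModel:
    """An ODE model ``xdot = f(x; theta)`` with bounds and parameter map.

    Parameters
    ----------
    names
        Ordered state-variable identifiers.
    rate_exprs
        One expression string per variable, same order as ``names``.
    params
        Parameter name -> value.
    bounds
        Per-variable ``(lo, hi)`` with finite ``lo < hi``; the box doubles as
        root-search region and trapping-region annotation.
    name
        Optional model label used in serialized files and exports.
    """

    def __init__(
        self,
        names: Sequence[str],
        rate_exprs: Sequence[str],
        params: Mapping[str, float] | None = None,
        bounds: Sequence[tuple[float, float]] | None = None,
        name: str = "model",
    ) -> None:
        self.name = str(name)
        self.names: tuple[str, ...] = tuple(str(s) for s in names)
        if len(set(self.names)) != len(self.names):
            raise ModelError("duplicate variable names")
        self.rate_exprs: tuple[str, ...] = tuple(str(e) for e in rate_exprs)
        if len(self.rate_exprs) != self.n:
            raise ModelError(
                f"{self.n} variables but {len(self.rate_exprs)} rate expressions"
            )
        self.params: dict[str, float] = {
            str(k): float(v) for k, v in (params or {}).items()
        }
        overlap = set(self.names) & set(self.params)
        if overlap:
            raise ModelError(f"identifier {sorted(overlap)[0]!r} is both variable and parameter")
        if bounds is None:
            raise ModelError("missing bounds: every variable needs a finite [lo, hi]")
        bl = list(bounds)
        if len(bl) != self.n:
            raise ModelError(f"{self.n} variables but {len(bl)} bounds")
        arr = np.asarray([(float(lo), float(hi)) for lo, hi in bl], dtype=float)
        for i, (lo, hi) in enumerate(arr):
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ModelError(f"invalid bounds for variable {self.names[i]!r}: [{lo}, {hi}]")
        self.bounds: np.ndarray = arr

        self._state_syms = [sp.Symbol(s) for s in self.names]
        self._param_syms = [sp.Symbol(s) for s in self.params]
        allowed = {str(s): s for s in self._state_syms + self._param_syms}
        self._exprs = [
            _parse_expression(e, f"variable {v!r}", allowed)
            for v, e in zip(self.names, self.rate_exprs)
        ]
        self._args = self._state_syms + self._param_syms
        self._rate_fns = [sp.lambdify(self._args, e, modules="numpy") for e in self._exprs]
        self._jac_exprs = [
            [sp.diff(e, s) for s in self._state_syms] for e in self._exprs
        ]
        self._jac_fn = sp.lambdify(self._args, sp.Matrix(self._jac_exprs), modules="numpy")

    # ------------------------------------------------------------------ basics
    @property
    def n(self) -> int:
        return len(self.names)

    def index(self, var: str | int) -> int:
        if isinstance(var, (int, np.integer)):
            return int(var)
        return self.names.index(var)

    def sym_rate(self, i: int) -> sp.Expr:
        return self._exprs[i]

    def sym_partial(self, i: int, j: int) -> sp.Expr:
        return self._jac_exprs[i][j]

    def param_values(self, overrides: Mapping[str, float] | None = None) -> list[float]:
        if not overrides:
            return [self.params[k] for k in self.params]
        unknown = set(overrides) - set(self.params)
        if unknown:
            raise ModelError(f"unknown parameter {sorted(unknown)[0]!r}")
        merged = dict(self.params)
        merged.update({k: float(v) for k, v in overrides.items()})
        return [merged[k] for k in self.params]

    def with_params(self, **overrides: float) -> "RegulatoryModel":
        """A copy of the model with some parameter values replaced."""
        vals = dict(zip(self.params, self.param_values(overrides)))
        return RegulatoryModel(self.names, self.rate_exprs, vals,
                               [tuple(b) for b in self.bounds], name=self.name)

    # -------------------------------------------------------------- evaluation
    def rhs(self, x: Sequence[float], overrides: Mapping[str, float] | None = None) -> np.ndarray:
        """Evaluate ``f(x; theta)`` componentwise.  Pure; no state is mutated."""
        xv = np.asarray(x, dtype=float)
        if xv.shape != (self.n,):
            raise ModelError(f"state has shape {xv.shape}, expected ({self.n},)")
        pv = self.param_values(overrides)
        with np.errstate(all="ignore"):
            out = np.array(
                [fn(*xv, *pv) for fn in self._rate_fns], dtype=float
            )
        bad = np.flatnonzero(~np.isfinite(out))
        if bad.size:
            raise EngineNonFinite(
                f"non-finite rate for component {self.names[bad[0]]!r} at x={xv.tolist()}"
            )
        return out

    def rate_component(
        self,
        i: int,
        state: Sequence[float],
        overrides: Mapping[str, float] | None = None,
        scan_var: int | None = None,
        scan_values: np.ndarray | None = None,
    ):
        """Evaluate ``f_i`` at ``state``, optionally sweeping one coordinate.

        With ``scan_var``/``scan_values`` the named coordinate is replaced by
        the given array and a same-shaped array of rates is returned; the
        compiled expression broadcasts over it.
        """
        pv = self.param_values(overrides)
        args = list(state)
        if scan_var is not None:
            args[scan_var] = np.asarray(scan_values, dtype=float)
        with np.errstate(all="ignore"):
            out = self._rate_fns[i](*args, *pv)
        if scan_var is not None:
            out = np.broadcast_to(np.asarray(out, dtype=float), np.shape(args[scan_var])).copy()
        return out

    def jacobian(self, x: Sequence[float], overrides: Mapping[str, float] | None = None) -> np.ndarray:
        """Analytic Jacobian ``J[i, j] = d f_i / d x_j`` at ``x``."""
        xv = np.asarray(x, dtype=float)
        if xv.shape != (self.n,):
            raise ModelError(f"state has shape {xv.shape}, expected ({self.n},)")
        pv = self.param_values(overrides)
        with np.errstate(all="ignore"):
            J = np.asarray(self._jac_fn(*xv, *pv), dtype=float)
        bad = np.argwhere(~np.isfinite(J))
        if bad.size:
            i, j = bad[0]
            raise EngineNonFinite(f"non-finite Jacobian entry ({int(i)}, {int(j)}) at x={xv.tolist()}")
        return J

    def jacobian_fd(self, x: Sequence[float], overrides: Mapping[str, float] | None = None) -> np.ndarray:
        """Central finite-difference Jacobian with step ``max(1e-6, 1e-6|x_j|)``."""
        xv = np.asarray(x, dtype=float)
        J = np.empty((self.n, self.n), dtype=float)
        for j in range(self.n):
            h = max(1e-6, 1e-6 * abs(xv[j]))
            xp = xv.copy(); xp[j] += h
            xm = xv.copy(); xm[j] -= h
            J[:, j] = (self.rhs(xp, overrides) - self.rhs(xm, overrides)) / (2 * h)
        return J

    # ------------------------------------------------------------- decay shape
    def self_partial_constant(self, i: int) -> float | None:
        """Value of ``d f_i / d x_i`` if it is state-independent, else None."""
        part = self._jac_exprs[i][i]
        if part.free_symbols & set(self._state_syms):
            return None
        pv = dict(zip(self.params, self.param_values()))
        val = sp.lambdify(self._param_syms, part, modules="numpy")(*[pv[k] for k in self.params])
        return float(val)

    @property
    def decay_form(self) -> tuple[bool, ...]:
        """True per variable when f_i = r_i(x) - d_i x_i with constant d_i > 0."""
        out = []
        for i in range(self.n):
            c = self.self_partial_constant(i)
            out.append(c is not None and c < 0)
        return tuple(out)

    # ------------------------------------------------------------ serialization
    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "variables": list(self.names),
            "parameters": {k: float(v) for k, v in self.params.items()},
            "rates": {v: e for v, e in zip(self.names, self.rate_exprs)},
            "bounds": {v: [float(lo), float(hi)] for v, (lo, hi) in zip(self.names, self.bounds)},
        }

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_yaml())

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<RegulatoryModel {self.name!r}: n={self.n}, params={list(self.params)}>"


class EngineNonFinite(ModelError):
    """A rate or Jacobian entry evaluated to NaN/inf."""


def parse_model(text: str) -> RegulatoryModel:
    """Parse a YAML model-description document into a :class:`RegulatoryModel`.

    The document declares ``variables`` (ordered list), ``parameters`` (map),
    ``rates`` (map variable -> expression string) and ``bounds`` (map
    variable -> ``[lo, hi]``); ``name`` is optional.  Serialization through
    :meth:`RegulatoryModel.to_yaml` round-trips losslessly.
    """
    try:
        doc = yaml.safe_load(io.StringIO(text))
    except yaml.YAMLError as exc:
        raise ModelError(f"invalid model document: {exc}") from exc
    if not isinstance(doc, dict):
        raise ModelError("model document must be a mapping")
    try:
        variables = list(doc["variables"])
    except KeyError:
        raise ModelError("model document lacks a 'variables' list") from None
    rates = doc.get("rates") or {}
    bounds = doc.get("bounds")
    if bounds is None:
        raise ModelError("model document lacks 'bounds'")
    missing = [v for v in variables if v not in rates]
    if missing:
        raise ModelError(f"missing rate expression for variable {missing[0]!r}")
    missing_b = [v for v in variables if v not in bounds]
    if missing_b:
        raise ModelError(f"missing bounds for variable {missing_b[0]!r}")
    return RegulatoryModel(
        names=variables,
        rate_exprs=[rates[v] for v in variables],
        params=doc.get("parameters") or {},
        bounds=[tuple(bounds[v]) for v in variables],
        name=doc.get("name", "model"),
    )


def load_model(path) -> RegulatoryModel:
    with open(path) as fh:
        return parse_model(fh.read())


# ---------------------------------------------------------------------------
# Interaction graph
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InteractionGraph:
    """Directed dependence graph of a model.

    ``edges`` maps ``(j, i)`` (vertex indices, influence j -> i) to a sign
    label: ``'+'`` / ``'-'`` when the sampled partial derivative never
    changes sign over the bounds box, ``'0'`` when it does (unsigned).
    """

    vertices: tuple[int, ...]
    edges: dict[tuple[int, int], str]
    names: tuple[str, ...] = field(default=())

    @property
    def self_edges(self) -> tuple[int, ...]:
        return tuple(sorted(i for (j, i) in self.edges if j == i))

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.vertices)
        for (j, i), sign in self.edges.items():
            g.add_edge(j, i, sign=sign)
        return g

    def subgraph(self, vertices: Iterable[int]) -> "InteractionGraph":
        vs = tuple(sorted(vertices))
        keep = set(vs)
        return InteractionGraph(
            vertices=vs,
            edges={e: s for e, s in self.edges.items() if e[0] in keep and e[1] in keep},
            names=self.names,
        )

    def label(self, v: int) -> str:
        return self.names[v] if self.names else str(v)


def _low_discrepancy_states(model: RegulatoryModel, n_samples: int, seed: int) -> np.ndarray:
    from scipy.stats import qmc

    sampler = qmc.Sobol(d=model.n, scramble=True, seed=int(seed))
    u = sampler.random(max(1, int(n_samples)))
    lo = model.bounds[:, 0]
    hi = model.bounds[:, 1]
    return lo + u * (hi - lo)


def build_igraph(
    model: RegulatoryModel,
    n_samples: int = 64,
    seed: int = 0,
    self_edge_mode: str = "default",
    eps_edge: float = 1e-9,
    overrides: Mapping[str, float] | None = None,
) -> InteractionGraph:
    """Derive the interaction graph of a model.

    Off-diagonal edges come from the symbolic partial derivatives (edge iff
    the partial is not the zero expression), cross-checked and sign-labelled
    on ``n_samples`` states of a seeded low-discrepancy sequence in the
    bounds box.

    Self-edge conventions:

    * ``"default"`` - a self-edge is added whenever ``d f_i / d x_i`` is not
      a state-independent nonpositive constant, i.e. whenever there is
      self-regulation beyond plain linear decay.  This reproduces circuit
      sets of models with saturable self-inhibition, where the strict
      positive-partial rule would drop a genuine feedback circuit.
    * ``"strict-eq3"`` - a self-edge only where the sampled partial is
      positive somewhere (pure positive autoregulation).
    """
    if self_edge_mode not in ("default", "strict-eq3"):
        raise ModelError(f"unknown self-edge mode {self_edge_mode!r}")
    if n_samples < 1:
        raise ModelError("n_samples must be >= 1")
    if np.any(model.bounds[:, 1] - model.bounds[:, 0] <= 0):
        raise ModelError("degenerate bounds")

    states = _low_discrepancy_states(model, n_samples, seed)
    pv = model.param_values(overrides)
    edges: dict[tuple[int, int], str] = {}
    for i in range(model.n):
        for j in range(model.n):
            part = model.sym_partial(i, j)
            if part == 0 or sp.simplify(part) == 0:
                continue
            fn = sp.lambdify(model._args, part, modules="numpy")
            with np.errstate(all="ignore"):
                vals = np.asarray(fn(*states.T, *pv), dtype=float)
            vals = np.broadcast_to(vals, (states.shape[0],))
            finite = vals[np.isfinite(vals)]
            if i == j:
                const = model.self_partial_constant(i)
                if self_edge_mode == "strict-eq3":
                    if not (finite.size and np.max(finite) > eps_edge):
                        continue
                else:
                    if const is not None and const <= 0:
                        continue
            else:
                # symbolic route says nonzero; sanity: drop if numerically dead
                if finite.size and np.max(np.abs(finite)) <= eps_edge:
                    # partial is nonzero as an expression but vanishes over the
                    # box for the current parameters (e.g. a zero amplitude)
                    continue
            if finite.size and np.min(finite) >= -eps_edge and np.max(finite) > eps_edge:
                sign = "+"
            elif finite.size and np.max(finite) <= eps_edge and np.min(finite) < -eps_edge:
                sign = "-"
            else:
                sign = "0"
            edges[(j, i)] = sign
    return InteractionGraph(vertices=tuple(range(model.n)), edges=edges, names=model.names)


def suggest_bounds(
    model: RegulatoryModel,
    n_samples: int = 256,
    seed: int = 0,
    max_iter: int = 20,
    margin: float = 1.05,
) -> np.ndarray:
    """Propose upper bounds for decay-form variables.

    For ``f_i = r_i(x) - d_i x_i`` the trapping bound is
    ``hi_i = max r_i / d_i``; the maximum is taken over the current box and
    the box is shrunk iteratively until the bounds stabilize.  Because
    saturating rate laws are monotone in each argument, the box corners are
    always probed in addition to the interior samples (the maximum of a
    monotone function over a box sits at a corner).
    """
    import itertools

    bounds = model.bounds.copy()
    decay = model.decay_form
    for _ in range(max_iter):
        probe = RegulatoryModel(model.names, model.rate_exprs, model.params,
                                [tuple(b) for b in bounds], name=model.name)
        states = _low_discrepancy_states(probe, n_samples, seed)
        if model.n <= 12:
            corners = np.array(list(itertools.product(*bounds)))
            states = np.vstack([states, corners])
        new = bounds.copy()
        for i in range(model.n):
            if not decay[i]:
                continue
            d = -model.self_partial_constant(i)
            vals = np.array([model.rhs(s)[i] + d * s[model.index(model.names[i])]
                             for s in states])
            new[i, 1] = margin * float(np.max(vals)) / d
        if np.allclose(new, bounds, rtol=1e-3):
            bounds = new
            break
        bounds = new
    return bounds
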