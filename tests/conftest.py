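"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately bypass the circuit-breaking engine: fixed
points are found by multistart Newton (scipy ``root`` from a seeded
low-discrepancy cloud of starts), hitting sets by exhaustive subset search,
and elementary circuits by brute-force path enumeration.  They are the
yardsticks the CBA results are compared against.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from scipy.optimize import root
from scipy.stats import qmc

from circuitbreaking import CBAConfig
from circuitbreaking.errors import CBAError
from circuitbreaking.model import InteractionGraph
from circuitbreaking.models import (
    repressilator_model,
    stem_cell_model,
    tryptophan_model,
)


@pytest.fixture(scope="session")
def stem_cell():
    return stem_cell_model()


@pytest.fixture(scope="session")
def repressilator():
    return repressilator_model()


@pytest.fixture(scope="session")
def tryptophan():
    return tryptophan_model()


@pytest.fixture(scope="session")
def fast_cfg():
    """Config with reduced scan/grid density for the nested-release fixtures."""
    return CBAConfig(n_scan=50, grid_points=201)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def multistart_fixed_points(model, overrides=None, n_starts=256, seed=0, tol=1e-9):
    """All fixed points inside the bounds box, by multistart Newton.

    Independent of the CBA engine: seeded Sobol starts, scipy's hybrid
    Powell solver with the analytic Jacobian, dedup by relative max-norm.
    """
    lo, hi = model.bounds[:, 0], model.bounds[:, 1]
    starts = lo + qmc.Sobol(model.n, scramble=True, seed=seed).random(n_starts) * (hi - lo)

    def F(x):
        try:
            return model.rhs(x, overrides)
        except CBAError:
            return np.full(model.n, 1e8)

    def J(x):
        try:
            return model.jacobian(x, overrides)
        except CBAError:
            return np.eye(model.n)

    found: list[np.ndarray] = []
    margin = 1e-6 * (hi - lo)
    for s in starts:
        sol = root(F, s, jac=J, method="hybr")
        if not sol.success:
            continue
        x = sol.x
        if np.max(np.abs(F(x))) > tol:
            continue
        if np.any(x < lo - margin) or np.any(x > hi + margin):
            continue
        scale = max(1.0, float(np.max(np.abs(x))))
        if any(np.max(np.abs(x - y)) < 1e-6 * scale for y in found):
            continue
        found.append(x)
    found.sort(key=lambda x: tuple(np.round(x, 9)))
    return found


def brute_min_hitting_set(circuits):
    """Smallest vertex set intersecting every circuit, by subset enumeration."""
    verts = sorted({v for c in circuits for v in c})
    if not circuits:
        return set()
    for k in range(1, len(verts) + 1):
        for combo in itertools.combinations(verts, k):
            cs = set(combo)
            if all(cs & set(c) for c in circuits):
                return cs
    raise AssertionError("unreachable")


def brute_elementary_circuits(edges, n):
    """All vertex-simple directed cycles by explicit path enumeration."""
    adj = {v: sorted(w for (u, w) in edges if u == v) for v in range(n)}
    out = set()
    for length in range(1, n + 1):
        for perm in itertools.permutations(range(n), length):
            if perm[0] != min(perm):
                continue
            ok = all(perm[k + 1] in adj[perm[k]] for k in range(length - 1))
            if ok and perm[0] in adj[perm[-1]]:
                out.add(perm)
    return out


def random_digraph(n, seed, p=0.35, self_loops=True):
    """Seeded random directed graph as an :class:`InteractionGraph`."""
    rng = np.random.default_rng(seed)
    edges = {}
    for i in range(n):
        for j in range(n):
            if i == j and not self_loops:
                continue
            if rng.random() < p:
                edges[(i, j)] = "0"
    return InteractionGraph(vertices=tuple(range(n)), edges=edges)
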