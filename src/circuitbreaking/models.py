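"""Built-in network models and seeded random fixtures.

Three literature models ship with the package so every pipeline stage is
testable without external files:

* a six-variable hematopoietic stem-cell differentiation network (the two
  lineage-specific suppressors Gfi-1 and Egr with their transcription
  factors C/EBPa and PU.1 plus two downstream lineage read-outs), bistable
  beyond a saddle-node in the PU.1 synthesis rate;
* the repressilator, three mRNA/protein pairs in a single negative ring;
* a four-variable tryptophan regulation network for E. coli (operator,
  mRNA, enzyme, tryptophan) combining genetic regulation, attenuation,
  enzyme inhibition and saturable uptake, with a Hopf bubble in the
  dilution rate.

Additionally there are seeded random fixtures: small dense networks with the
3- and 4-vertex dependence structures that need two circuit-closing steps
(so they are *not* leading-vertex graphs), and random leading-vertex graphs
built as unions of circuits through one shared vertex.
"""

from __future__ import annotations

import numpy as np

from .model import RegulatoryModel


def stem_cell_model(e_N: float = 0.2, e_M: float = 0.2) -> RegulatoryModel:
    """Hematopoietic stem-cell differentiation network (dimensionless).

    ``e_N`` is the (rescaled) synthesis rate of C/EBPa and ``e_M`` the
    maximal synthesis rate of PU.1.  All six variables decay linearly; the
    single cyclic component {x2, x3, x4} carries two interrelated positive
    circuits.  Bounds [0, 6] comfortably cover all attainable states.
    """
    if e_N < 0 or e_M < 0:
        raise ValueError("synthesis rates must be nonnegative")
    rates = {
        "x1": "eN - x1",
        "x2": "5*x1/(1+x1) * 1/(1+x3^4) - x2",
        "x3": "5*x4/(1+x4) * 1/(1+x2^4) - x3",
        "x4": "eM/(1+x2^4) - x4",
        "x5": "x1*x4/(1+x1*x4) + 4*x3/(1+x3) * 1/(1+x2^4) - x5",
        "x6": "x1*x4/(1+x1*x4) + 4*x2/(1+x2) * 1/(1+x3^4) - x6",
    }
    names = list(rates)
    return RegulatoryModel(
        names=names,
        rate_exprs=[rates[v] for v in names],
        params={"eN": float(e_N), "eM": float(e_M)},
        bounds=[(0.0, 6.0)] * 6,
        name="stem_cell",
    )


def repressilator_model(
    alpha: float = 290.0,
    alpha0: float = 10.0,
    beta: float = 1.0,
    n_hill: float = 2.0,
) -> RegulatoryModel:
    """Repressilator: three repressor mRNA/protein pairs in a negative ring.

    ``m_i`` is repressed by the previous protein through
    ``r(p) = alpha/(1 + p^n) + alpha0``; proteins track their mRNA at rate
    ``beta``.  The trapping region is ``[alpha0, alpha + alpha0]`` for every
    variable, which is used for the bounds (widened to ``[0, alpha0 + 1]``
    in the degenerate ``alpha = 0`` case).
    """
    if alpha < 0 or alpha0 < 0 or beta <= 0 or n_hill <= 0:
        raise ValueError("repressilator parameters must be positive (alpha >= 0)")
    if alpha > 0:
        lo, hi = float(alpha0), float(alpha + alpha0)
    else:
        lo, hi = 0.0, float(alpha0 + 1.0)
    pairs = [("m1", "p3"), ("m2", "p1"), ("m3", "p2")]
    names: list[str] = []
    rates: dict[str, str] = {}
    for i, (m, rep) in enumerate(pairs, start=1):
        p = f"p{i}"
        rates[m] = f"alpha/(1+{rep}^n_hill) + alpha0 - {m}"
        rates[p] = f"beta*({m} - {p})"
        names += [m, p]
    return RegulatoryModel(
        names=names,
        rate_exprs=[rates[v] for v in names],
        params={
            "alpha": float(alpha),
            "alpha0": float(alpha0),
            "beta": float(beta),
            "n_hill": float(n_hill),
        },
        bounds=[(lo, hi)] * 6,
        name="repressilator",
    )


#: printed parameter set of the tryptophan regulation network
TRYPTOPHAN_PARAMS: dict[str, float] = {
    "k1": 50.0,      # operator synthesis, 1/min
    "Ot": 3.32,      # total operator sites, nM
    "t1": 3.53,      # genetic-regulation half saturation, uM
    "m1": 1.92,
    "gamma1": 0.5,   # operator degradation, 1/min
    "mu": 0.01,      # dilution rate, 1/min
    "k2": 15.0,      # transcription, 1/min
    "t2": 0.04,      # attenuation half saturation, uM
    "m2": 1.72,
    "gamma2": 15.0,  # mRNA degradation, 1/min
    "k3": 90.0,      # translation, 1/min
    "k4": 59.0,      # tryptophan synthesis, 1/min
    "t3": 810.0,     # enzyme-inhibition half saturation, uM
    "m3": 1.2,
    "g": 25.0,       # uptake capacity, uM
    "Kg": 0.2,       # uptake half saturation, uM
}


def tryptophan_model(**overrides: float) -> RegulatoryModel:
    """Tryptophan regulation in E. coli: operator, mRNA, enzyme, tryptophan.

    Tryptophan (x4) feeds back on all three upstream stages through the
    sigmoidally decreasing ``C(x, K, m) = K^m / (K^m + x^m)`` and inhibits
    its own net production via saturable uptake ``g x4 / (x4 + Kg)``; under
    the default convention that saturable self-influence is a length-1
    circuit at x4.  ``mu`` is the dilution rate (the bifurcation parameter
    of the Hopf bubble).  The x3 bound is generous because the enzyme level
    scales like ``k3 x2 / mu`` for small dilution.
    """
    params = dict(TRYPTOPHAN_PARAMS)
    unknown = set(overrides) - set(params)
    if unknown:
        raise ValueError(f"unknown tryptophan parameter {sorted(unknown)[0]!r}")
    params.update({k: float(v) for k, v in overrides.items()})
    rates = {
        "x1": "k1*Ot*(t1^m1/(t1^m1 + x4^m1)) - (gamma1+mu)*x1",
        "x2": "k2*x1*(t2^m2/(t2^m2 + x4^m2)) - (gamma2+mu)*x2",
        "x3": "k3*x2 - mu*x3",
        "x4": "k4*(t3^m3/(t3^m3 + x4^m3))*x3 - g*x4/(x4+Kg) - mu*x4",
    }
    names = list(rates)
    return RegulatoryModel(
        names=names,
        rate_exprs=[rates[v] for v in names],
        params=params,
        bounds=[(0.0, 400.0), (0.0, 500.0), (0.0, 1.2e7), (0.0, 200.0)],
        name="tryptophan",
    )


# ---------------------------------------------------------------------------
# randomized fixtures
# ---------------------------------------------------------------------------

_METHODS_DEPS = {
    "3vertex": {0: (1, 2), 1: (0, 2), 2: (0, 1)},
    "4vertex": {0: (2,), 1: (0, 3), 2: (0, 3), 3: (1,)},
}


def _hill_term(rng: np.random.Generator, src: str) -> str:
    a = round(float(rng.uniform(0.4, 1.2)), 6)
    t = round(float(rng.uniform(0.4, 1.5)), 6)
    h = int(rng.integers(2, 4))
    if rng.random() < 0.5:
        return f"{a}*{src}^{h}/({t}^{h} + {src}^{h})"
    return f"{a}*{t}^{h}/({t}^{h} + {src}^{h})"


def _random_rates(
    rng: np.random.Generator, n: int, deps: dict[int, tuple[int, ...]]
) -> tuple[list[str], float]:
    """Hill-sum rates minus linear decay for a given dependence structure."""
    names = [f"x{i + 1}" for i in range(n)]
    rates = []
    total_max = 0.0
    for i in range(n):
        d = round(float(rng.uniform(0.8, 1.6)), 6)
        basal = round(float(rng.uniform(0.05, 0.2)), 6)
        terms = [str(basal)] + [_hill_term(rng, names[j]) for j in deps[i]]
        rates.append(" + ".join(terms) + f" - {d}*{names[i]}")
        amp = basal + sum(
            float(t.split("*")[0]) for t in terms[1:]
        )
        total_max = max(total_max, amp / d)
    return rates, total_max


def methods_fixture(kind: str, seed: int = 1) -> RegulatoryModel:
    """Small dense fixtures that require two circuit-closing steps.

    ``"3vertex"`` is fully cross-connected; ``"4vertex"`` has the dependence
    structure f1(x1,x3), f2(x1,x2,x4), f3(x1,x3,x4), f4(x2,x4).  Rate laws
    are randomized (seed-fixed) sums of Hill terms minus linear decay:
    self-influence is pure decay, so the dependence structure alone fixes
    the interaction graph and the minimal circuit cover has two vertices
    (not a leading-vertex graph).  The determinant-ratio slope identity must
    hold for any smooth rates, which is what these fixtures exercise.
    """
    if kind not in _METHODS_DEPS:
        raise ValueError(f"unknown methods fixture kind {kind!r}")
    deps = _METHODS_DEPS[kind]
    n = len(deps)
    rng = np.random.default_rng(int(seed))
    rates, hi = _random_rates(rng, n, deps)
    bound = float(np.ceil(hi * 1.5 + 1.0))
    return RegulatoryModel(
        names=[f"x{i + 1}" for i in range(n)],
        rate_exprs=rates,
        params={},
        bounds=[(0.0, bound)] * n,
        name=f"methods_{kind}_seed{int(seed)}",
    )


def random_lvg_model(n_vars: int, seed: int = 0) -> RegulatoryModel:
    """Random leading-vertex graph: every circuit runs through x1.

    The vertices x2..xn are partitioned into up to three directed paths,
    each closed through x1; with the intermediate sets disjoint, the
    subgraph without x1 is a union of simple paths and hence acyclic, so x1
    lies on every elementary circuit by construction.  Edges carry random
    signed Hill interactions and every variable decays linearly.
    """
    if n_vars < 2:
        raise ValueError("need at least 2 variables")
    rng = np.random.default_rng(int(seed))
    rest = list(range(1, n_vars))
    rng.shuffle(rest)
    k = int(rng.integers(1, min(3, len(rest)) + 1))
    cuts = sorted(rng.choice(np.arange(1, len(rest)), size=k - 1, replace=False).tolist()) if k > 1 else []
    paths = []
    prev = 0
    for c in cuts + [len(rest)]:
        paths.append(rest[prev:c])
        prev = c
    deps: dict[int, list[int]] = {i: [] for i in range(n_vars)}
    for path in paths:
        chain = [0] + path + [0]
        for a, b in zip(chain, chain[1:]):
            deps[b].append(a)
    names = [f"x{i + 1}" for i in range(n_vars)]
    rates = []
    hi = 0.0
    for i in range(n_vars):
        d = round(float(rng.uniform(0.8, 1.6)), 6)
        basal = round(float(rng.uniform(0.05, 0.2)), 6)
        terms = [str(basal)] + [_hill_term(rng, names[j]) for j in deps[i]]
        rates.append(" + ".join(terms) + f" - {d}*{names[i]}")
        amp = basal + sum(float(t.split("*")[0]) for t in terms[1:])
        hi = max(hi, amp / d)
    bound = float(np.ceil(hi * 1.5 + 1.0))
    return RegulatoryModel(
        names=names,
        rate_exprs=rates,
        params={},
        bounds=[(0.0, bound)] * n_vars,
        name=f"random_lvg_n{n_vars}_seed{int(seed)}",
    )


BUILTINS = {
    "stem_cell": stem_cell_model,
    "repressilator": repressilator_model,
    "tryptophan": tryptophan_model,
}


def builtin(name: str, seed: int = 1, **params) -> RegulatoryModel:
    """Look up a fixture by registry name (used by the CLI)."""
    if name in BUILTINS:
        return BUILTINS[name](**params) if params else BUILTINS[name]()
    if name in ("methods_3vertex", "methods_4vertex"):
        return methods_fixture(name.replace("methods_", ""), seed=seed)
    if name.startswith("random_lvg"):
        n = int(params.pop("n_vars", 5))
        return random_lvg_model(n, seed=seed)
    raise KeyError(f"unknown builtin model {name!r}")
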