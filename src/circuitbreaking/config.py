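from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, replace


@dataclass(frozen=True)
class CBAConfig:
    """Numerical knobs of the circuit-breaking pipeline.

    All tolerances are absolute unless stated otherwise.  The defaults are
    deliberately conservative; every built-in model runs comfortably with
    them.

    Parameters
    ----------
    n_scan
        Number of subintervals of a variable's bounds scanned for sign
        changes when solving a one-dimensional fixed-point equation.
    tol_root
        Residual tolerance for accepting a bracketed root of an implicit
        equation.
    tol_zero
        Residual tolerance for a zero of the circuit-characteristic.
    tol_tangent
        Relative threshold (scaled by ``max(1, max|c|)`` on the grid) below
        which a local extremum of ``|c|`` without sign change is reported as
        a tangency / fold candidate.
    tol_fp
        Max-norm residual required of an assembled fixed point after Newton
        polishing.
    tol_dedup
        Relative max-norm distance under which two fixed points are merged.
    grid_points
        Default number of grid points of a characteristic over the leading
        variable's bounds.
    max_branches
        Cap on simultaneous downstream root branches.
    exhaustive_cap
        Maximum number of candidate vertices for the exact (branch-and-bound)
        minimum circuit cover; beyond it a greedy cover is used and flagged.
    circuit_cap
        Cap on enumerated elementary circuits; covers computed from a
        truncated circuit set are flagged as possibly non-minimal.
    tol_eig_rel
        Eigenvalue real-part threshold, relative to the Jacobian norm, inside
        which a fixed point is classified marginal.
    tol_slope
        Characteristic slopes below this (scaled by the grid span) are not
        treated as positive by the instability test.
    tol_param
        Relative tolerance of bifurcation-parameter bisection.
    newton_max_iter
        Iteration cap of the damped Newton polish.
    """

    n_scan: int = 200
    tol_root: float = 1e-10
    tol_zero: float = 1e-8
    tol_tangent: float = 1e-4
    tol_fp: float = 1e-8
    tol_dedup: float = 1e-6
    grid_points: int = 601
    max_branches: int = 16
    exhaustive_cap: int = 20
    circuit_cap: int = 10_000
    tol_eig_rel: float = 1e-8
    tol_slope: float = 1e-6
    tol_param: float = 1e-4
    newton_max_iter: int = 50
    bisect_max_iter: int = 40

    def replace(self, **kwargs) -> "CBAConfig":
        return replace(self, **kwargs)

    def digest(self) -> str:
        """Short stable hash of the configuration, for output metadata."""
        blob = repr(sorted(asdict(self).items())).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


DEFAULT_CONFIG = CBAConfig()
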