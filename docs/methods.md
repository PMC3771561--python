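# Methods

This note documents the model class, the algorithmic and numerical choices
of the circuit-breaking implementation, and what the packaged fixtures do
and do not exercise.

## Model class and interaction graph

Models are autonomous ODE systems $\dot x = f(x;\theta)$ with $f \in C^1$
on a finite box (the search region / trapping annotation).  Rate
expressions are strings over `+ - * / ^`, parentheses and `exp`, parsed
once with sympy and compiled to vectorized numpy callables; Jacobians are
symbolic, with a central-difference route (step $\max(10^{-6},
10^{-6}|x_j|)$) kept as a cross-check.  All built-ins are dimensionless
except the tryptophan network, whose µM/min units are documentation only —
no unit arithmetic is performed.

The interaction graph has edge $j \to i$ iff the symbolic partial
$\partial f_i/\partial x_j$ is not the zero expression; sign labels
(`+`/`-`/unsigned) and a numerical cross-check come from evaluating the
partial on a seeded scrambled-Sobol sample of the box (default 64 states,
edge threshold $10^{-9}$).

**Self-edges.**  Two conventions are provided because the strict rule
"self-edge iff the self-partial is positive somewhere" (selectable as
`strict-eq3`) discards genuine length-1 feedback when self-influence is
*negative but nonlinear* — e.g. saturable uptake of tryptophan, whose
single-vertex circuit belongs in the circuit set.  The default convention
therefore adds a self-edge whenever $\partial f_i/\partial x_i$ is anything
other than a state-independent nonpositive constant, i.e. whenever there is
self-regulation beyond plain linear decay.  The default reproduces the
published circuit sets of all three literature models.

## Graph analysis

SCCs, condensation and circuit enumeration (Johnson's algorithm) use
networkx; components are numbered along a topological order of the
condensation with ties broken by smallest member vertex, so the hierarchy
is deterministic.  Circuit enumeration is capped (default 10 000) and a
truncated set flags its cover as possibly non-minimal.

The minimum circuit cover is an exact branch-and-bound hitting set
(branching on the smallest uncovered circuit) whenever at most 20 candidate
vertices appear in circuits — biological SCCs are small, so this is the
common case; beyond that a greedy max-coverage fallback is used and flagged
`exact=False`.  Among equal-size covers, vertices contained in the most
circuits are preferred, ties by smallest index; the same rule orders the
cover, making $v_1$ the most-shared vertex.  The choice among symmetric
minimum covers (e.g. any repressilator vertex) shifts the $\kappa$-axis but
not the zeros; the chosen cover is recorded in all outputs.  Circuits are
re-closed in reverse cover order ($v_m$ first).

## One-dimensional root finding

Every scalar equation (acyclic solve, circuit closing, characteristic zero)
is solved the same way: the variable's bounds are scanned on `n_scan = 200`
subintervals, every sign change is refined by Brent's method
(`xtol = 1e-13`), and a root is accepted if its residual is below
`tol_root = 1e-10` (scaled when the rate magnitudes are large).  Multiple
roots spawn branches, continued across adjacent grid/scan points by
nearest-state matching and capped at `max_branches = 16`.  Intervals where
an equation has no root inside the bounds leave a hole in that branch
(recorded, not interpolated); more than half the grid empty raises an error
advising wider bounds.

The characteristic is sampled on `grid_points = 601` points over the
leading variable's bounds.  Zeros are bracketed sign changes refined by
Brent; slopes come from a five-point central difference of the continuously
re-evaluated curve with step $10^{-3}$ of the grid span, accurate to far
below the $10^{-5}$ relative agreement required of the determinant-ratio
identity.  Interior local minima of $|c|$ below
`tol_tangent = 1e-4 * max(1, max|c|)` without a sign change are refined by
bounded scalar minimization: if the refined extremum actually crosses zero
the hidden pair is returned as two ordinary zeros (this keeps the zero
count correct arbitrarily close to a fold, far below the grid resolution);
otherwise the point is reported once as a tangency / saddle-node candidate.
Assembled states are polished by damped Newton (analytic Jacobian, halving
line search, 50 iterations), accepted below residual `tol_fp = 1e-8`, and
deduplicated at $10^{-6}$ relative max-norm distance.  Nothing in the
engine is random.

## Stability and the slope identity

Classification is by the spectrum of the analytic Jacobian with a marginal
band of $10^{-8}\,\lVert J\rVert$: points inside the band are reported
`marginal`, never stable or unstable (a parameter scan is the right tool
there).  The determinant-ratio slope $\det J \cdot \det^{-1}
J^{V\setminus\{v_1\}}$ is evaluated per SCC with upstream coordinates
frozen, matching the per-component construction of the characteristic; a
singular reduced Jacobian (typically a fold) raises a dedicated error.  The
LVG instability verdict requires a slope above `tol_slope = 1e-6` scaled by
the grid span, so tangencies are not misread as positive slopes.  Negative
slopes always yield `inconclusive`; non-LVG components `not_applicable` —
the positive-slope implication is not extrapolated beyond leading-vertex
graphs.

## Bifurcation scans

Sweeps rerun the full assembly per parameter value; fixed points are
matched across values by nearest relative distance (unconditionally when
the point count is unchanged, with a 0.25 jump threshold when points appear
or disappear).  Folds are refined by bisection on the zero-count change to
`tol_param = 1e-4` relative (depth cap 40); the tangent state is read off
on the many-points side as the midpoint of the closest pair.  Hopf
candidates are sign changes of $\max \mathrm{Re}\,\lambda$ along a branch
with nonzero imaginary part at the crossing, refined by bisection with the
fixed point continued by damped Newton from the interpolated branch state —
cheap, so coarse sweep grids suffice.  Across a Hopf event the
characteristic's zero count is unchanged: the characteristic does not carry
the information needed to certify asymptotic stability, which is the point
the repressilator and tryptophan examples make.

## Fixtures: what they emulate and what they do not

* **Stem-cell network** (two counter-acting suppressors with their
  transcription factors and two read-out genes): exact transcription;
  bounds $[0,6]$ cover all attainable states (largest coordinate ≈ 2.7).
  The read-out variables $x_5, x_6$ are feed-forward and do not affect the
  switch.
* **Repressilator**: bounds follow the trapping region
  $[\alpha_0, \alpha + \alpha_0]$ (widened when $\alpha = 0$).  With
  $\alpha = 290$, $\alpha_0 = 10$, $n = 2$ the repression gain at the
  symmetric point is $|r'| \approx 0.331$, which keeps the symmetric fixed
  point linearly stable at every protein-turnover rate $\beta$; the spectrum
  still depends on $\beta$ while the characteristic provably does not,
  which is what the tests assert.
* **Tryptophan network**: exact transcription with the published parameter
  set.  The box is a root-search region, not itself invariant — the enzyme
  bound is set generously ($1.2\times 10^7$, enzyme scales like
  $k_3 x_2/\mu$ at small dilution) so the characteristic exists on the full
  tryptophan axis; boundedness of trajectories is verified by integration.
* **Dense 3-/4-vertex fixtures**: seed-fixed random Hill-sum rates on fixed
  dependence structures whose minimal cover has two vertices, exercising
  the nested (two-step) circuit closing and the slope identity, which must
  hold for *any* smooth rates.
* **Random leading-vertex graphs**: unions of vertex-disjoint circuits
  through a shared vertex, so the LVG property holds by construction.

All fixtures use smooth saturating (Hill/uptake) kinetics with linear
decay.  Passing tests therefore demonstrate correctness on the
well-behaved, dissipative model class the method targets — not robustness
to non-smooth rates, conservation relations, or near-degenerate Jacobians
away from folds.

## Known limitations

* Minimum hitting set is NP-hard; the exact search assumes small SCCs and
  falls back to a flagged greedy cover beyond 20 candidate vertices.
* Fixed points outside the declared bounds are invisible by design; the
  bounds are part of the model statement.
* Branch continuation is nearest-neighbour; characteristics with branch
  crossings inside one grid cell could be mis-threaded (none of the
  packaged models produce multivalued downstream sets at all).
* Tangency candidates are fold *candidates*: degenerate higher-order
  touches are reported the same way.
* Marginal points are deliberately left unclassified; no center-manifold
  analysis is attempted.
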