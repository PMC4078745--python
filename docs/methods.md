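# Methods

## Scope and model class

`dyncausal` treats causal inference for *dynamic processes*: which directed
interactions between time series can be established from observational data
alone, what latent (unrecorded) processes do to that inference, and how
observation artifacts — measurement noise, time aggregation, spatial
aggregation — manufacture "inconsistent positives": Granger-causality values
that are strictly positive although the generating structure contains no
corresponding arrow.

The ground-truth object is a **process graph**: one node per process,
directed edges `(src, dst, lag)` with integer lag ≥ 1, and a latent flag per
process.  All ground-truth influence is lagged; same-time dependence between
observed signals can only arise downstream, from latent common drivers or
from aggregation in the observation step.  Latent processes are assumed
*autocausal* (their present depends directly on their own past); this
excludes white-noise common drivers and is what separates latent mediators
from latent common drivers in the instantaneous-causality signature below.

Unrolling a process graph over a finite window yields the **causal
structure**, the microscopic DAG over `(process, t)` variables corresponding
to the parent sets of a functional model `V_{k,i+1} = f_k(pa(V_{k,i+1}),
U_{k,i})`.  Feedback between processes is unproblematic: cycles exist only
in the rolled (macroscopic) picture, never in the unrolled DAG.

The quantitative instantiation is the linear Gaussian VAR(1)

    V_{i+1} = C · V_i + ε_i,      ε_i ~ N(0, Σ) i.i.d.

observed through a linear map: signals `W · V_t` plus independent Gaussian
observation noise, read every `T`-th step.  Innovation covariances are
accepted positive *semi*-definite rather than strictly definite because the
companion-form augmentation used for time aggregation (below) has degenerate
innovations on its copied coordinates; every observed joint covariance that
enters an information measure must still be positive definite, and the CMI
routine enforces that.

## Separation machinery

d-separation is implemented for every graph flavor in the package with one
extended collider rule: a collider on a path is any node receiving
head-to-head arrowheads *of any edge type* (directed, dashed/potential,
solid/genuine, bidirectional); undirected edges are traversable both ways
and never contribute an arrowhead.  Ancestry (for the collider-opening
clause) follows single-headed edges only.

Two engines exist.  The default is a memoized reachability traversal over
`(node, entered-with-arrowhead)` states — linear in the graph size and valid
for node-set endpoints, which the Granger-criterion queries need.  An
explicit simple-path enumerator is retained as the reference semantics and
cross-checked exhaustively in the tests.  A third routine implements the
classical pruning procedure (restrict to ancestors of the query, delete
arrows leaving the conditioning set, test undirected connectivity).  The
procedure is stated in the literature without a moralization step; the test
suite compares it against path-based d-separation on *every* DAG over four
nodes and every query, plus random larger DAGs, and finds exact agreement —
the ancestral restriction performs the role moralization plays in the
moralize-and-separate formulation, so no patch was needed.

On macroscopic mixed graphs, the graphical sufficient conditions restrict
attention to paths ending with an arrowhead at the target (Granger
non-causality) or carrying arrowheads at both ends (instantaneous
non-causality).  They are sufficient in general and necessary under
faithfulness; the package treats random-coefficient VARs as faithful with
probability 1, and the tests verify soundness against the analytic Gaussian
oracle.

## Information measures

For stationary models the lagged autocovariances are exact: Γ₀ solves the
discrete Lyapunov equation Γ₀ = CΓ₀Cᵀ + Σ (scipy's solver), Γ_k = CΓ_{k−1},
and observed-signal covariances are Γ^obs_k = WΓ_{kT}Wᵀ with the observation
noise added on the lag-0 diagonal only.  Transfer entropy and the
instantaneous-causality measure,

    T_{X→Y|Z} = I(Y_{i+1}; X^i | Y^i, Z^i)
    T_{X·Y|Z} = I(X_{i+1}; Y_{i+1} | X^i, Y^i, Z^i)

are Gaussian conditional mutual informations, computed from log-determinants
(Cholesky factorizations) of submatrices of the stacked lag-covariance
matrix.  All values are in **nats**; bits are a display conversion.

Numerical choices:

* **Lag depth** L = 20 by default; a convergence flag compares against depth
  2L and requires agreement within 10⁻⁸ nats.  For the systems studied the
  truncated past converges well before 20 lags.
* **Numerical zero** for "T = 0" decisions: 10⁻⁹ nats (configurable).
  Faithful dependencies in the tested models are ≥ 10⁻⁶ nats, three orders
  of magnitude above the determinant round-off floor.
* **Stationarity margin** 10⁻⁶ on the spectral radius; non-stationary grid
  cells are reported with an explicit `"excluded"` marker in data files,
  never a sentinel number.
* Tiny negative CMI values (round-off) are clipped to 0; a non-positive-
  definite or severely ill-conditioned submatrix raises a numerical error
  rather than returning garbage.
* Only VAR order 1 is first-class.  Higher orders and windowed observations
  are representable by companion-form state augmentation (used internally
  for time aggregation); this is documented rather than wrapped in an API.

## Inference algorithms

All four structure learners consume an *oracle* — conditional independence
between variables, or transfer-entropy/instantaneous-causality between
processes — and are agnostic to how the oracle decides.  Two oracles are
provided: a graphical one reading d-separation off a known unrolled ground
truth (history window H, default 3 × #processes × max-lag), and the
analytic Gaussian one.  Finite-sample independence testing is explicitly out
of scope; oracle answers are cached keyed by (pair, frozen conditioning set).

* **IC** — skeleton by separating-set search, v-structure orientation, then
  Meek's completion rules R1–R3, which implement exactly the "orient
  whatever would otherwise create a new v-structure or a cycle" closure when
  no background knowledge is present (R4 only fires with background
  knowledge).  Separating sets are searched in increasing cardinality,
  lexicographic within a cardinality, first hit wins — a deterministic
  choice the algorithm statement leaves open.
* **IC\*** — same skeleton; Step 2 installs dashed (potential-cause)
  arrowheads; rule 3R1 promotes to a solid genuine arrow the only
  orientation that creates no new v-structure; rule 3R2 removes cycle-
  compatible readings.  The edge-type hierarchy runs undirected ⊃ potential
  ⊃ {genuine, common driver}, so "substitute by the type immediately below
  that excludes the cycle" is implemented as a *refinement*: an undirected
  link one of whose orientations would close a directed cycle becomes a
  potential cause pointing the other way, and a potential cause whose causal
  reading would close a cycle becomes a bidirectional (common-driver) link.
  A genuine arrow closing a cycle means the oracle's answers are
  inconsistent, and raises.
* **Temporal IC** — for latent-free dynamic processes, temporal precedence
  orients every edge and conditioning on the whole observed past minus the
  candidate source blocks every path except the direct arrow, so each edge
  needs exactly one CI test and the output is the complete microscopic DAG.
* **ICG\*** — macroscopic inference with latent processes.  Step 1 searches,
  per pair, for an observed conditioning set cancelling the instantaneous
  causality; failure to find one is proof of a latent common driver
  (instantaneous dependence cannot arise otherwise in this model class) and
  yields a bidirectional edge.  Steps 2–3 do the same for transfer entropy
  in each direction on the remaining pairs.  Pairs carrying a bidirectional
  edge are skipped in Steps 2–3 as the algorithm prescribes: the common
  driver already implies positive Granger measures there, so a bidirectional
  edge does not *exclude* additional direct coupling — a representational
  limit shared with IC\*'s output, documented rather than patched.

## The synthetic systems (what they emulate, what they do not)

The package's experiment generators *are* its study conditions:

* **Two-area aggregation system** (4 processes): pairwise unidirectional
  inter-areal coupling fixed at 0.8 (as are the driven processes'
  self-couplings), free intra-area couplings (c11, c12, c21, c22), identity
  innovations, observed signals `X = 0.3·X1 + 0.7·X2` and
  `Y = 0.7·Y1 + 0.3·Y2` by default.  The headline map sweeps (c12, c21)
  over [−1, 1] in steps of 0.05 with c11 = 0.8, c22 = 0.2, recording
  r = T_{Y→X}/T_{X→Y} on stationary cells.
* **N-per-area system** (2N+2 processes): intra-areal integration supplied
  by common drivers Z and W with couplings c_xz, c_yw; per-area averages
  observed.  Panels sweep c_yw ∈ [0, 1] (c_xz = 0.5) and c_yx ∈ [0.1, 1.4]
  (c_xz = 1.4, c_xx = 0.2), N ≤ 6 — sizes at which every quantity is exact
  and the full studies run in seconds to minutes on one CPU.
* The histogram study's four observation-weight combinations
  {(0.5, 0.5), (0.3, 0.7), (0.7, 0.3), (0.1, 0.9)} are this package's
  choice (one symmetric pair plus increasingly asymmetric ones) and are
  flagged as such in the output metadata.

Two reference quantities deserve explanation:

* The **pairwise reference** reported with the integration panel is the
  microscopic T_{X1→Y1 | pasts of all other processes}.  Conditioning on
  the rest isolates the direct link, so the value depends only on the
  pair's own coefficients and is constant across the whole (c_yw, N) panel
  — the property that makes it the correct yardstick.  Computed with the
  pair observed *alone* it is not constant, because the latent intra-area
  drivers change with c_yw.
* The **time-aggregation demonstration** uses block *averages* (via
  companion-form augmentation) read every T-th step.  Plain decimation of
  this order-1 system does **not** create a reverse positive: the
  subsampled driver remains Markov, so the reverse transfer entropy is
  exactly zero while the instantaneous-causality measure becomes positive.
  Both facts are computed and reported in the demo; the d-separation
  reading of the unrolled structure confirms each.

These are linear, Gaussian, order-1, stationary systems with faithful
random parameterizations.  Passing tests therefore demonstrate the *logic*
of the inference machinery and the aggregation artifacts exactly; they say
nothing about estimation error, non-Gaussian or nonlinear dynamics,
non-stationarity, or the discretization/binning and hemodynamic-response
artifacts, which require machinery (or modeling commitments) outside this
package's scope.

## Known limitations

* No finite-sample independence tests, significance levels, or multiple-
  testing control: oracles are exact by construction.  The simulation
  routine exists to support Monte-Carlo cross-checks, not estimation.
* ICG\*'s output cannot distinguish "common driver only" from "common driver
  plus direct coupling", nor direct from latent-mediated causation — limits
  inherited from observational equivalence, not implementation choices.
* The graphical Granger oracle truncates the infinite pasts at a finite
  history window; the default exceeds the dependence horizon of every
  system tested here, and the Gaussian oracle provides an independent check
  wherever both apply.
* Spectral-domain Granger measures and nonlinear transfer-entropy
  estimators are out of scope.
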