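# Methods

## Probability core

All computations are exact finite-alphabet manipulations of a dense joint
probability array (`JointPMF`): marginalization sums axes, channels are
row-normalized conditional slices, and every information quantity is a
base-2 Shannon functional with the 0·log 0 = 0 convention.  Masses must be
non-negative and sum to one within 1e-9; informational identities (chain
rule, symmetry, bounds) are asserted in the tests at the same tolerance.
Probabilities are floats; exact fractions ("1/4") are accepted at the I/O
boundary and converted once.

Conditioning on a zero-probability target symbol is undefined, so such
symbols are dropped from channel rows; composed distributions q then assign
them zero mass.  Multi-variable targets such as (T, Z) are handled by
merging the variables into a single composite (tuple-valued) variable before
computing, which keeps every measure a function of a single designated
target.

## The conditional-independence union measure

For a collection of sources A1..Am (subsets of the predictor variables), the
admissible family Q consists of the compositions q(t,a) = p(t)·∏ p(block|t)
over all partitions of A = ⋃Ai whose blocks are each contained in at least
one source.  This formalizes "combining their conditional distributions and
marginalizations thereof": a coalition agent may keep its block whole or
split it, so the family for {(Y1,Y2), Y3} has two members and the family for
{(Y1,Y2), (Y1,Y3), (Y2,Y3)} has four.  Partitions are enumerated by
restricted-growth strings, filtered by block coverage, and deduplicated by a
12-decimal fingerprint of the composed array (symmetric inputs can make two
partitions compose identically); ties in the maximum report the first
partition in canonical order.

The measure is min{I(A;T), max_q I_q(A;T)}.  The clip is essential: without
it a lone coalition agent could split its own conditional and report more
than I(A;T) (Adapted ReducedOR with r > 0.5 is the canonical case), breaking
self-redundancy.  Synergy subtracts the union information from I(Y;T)
computed over **all** declared predictors, not only ⋃Ai; this is what makes
the synergy of the single source {Y1} equal I(Y2;T|Y1).

**Source normalization.**  Before computing, sources contained in other
sources are dropped, and a source that is a deterministic function of a
*single* other source (conditional entropy below 1e-9 bits on the support,
e.g. a duplicated variable), or that is constant, is removed — scanning in
reverse declaration order with re-testing, so exactly one member of a
mutually-determining pair survives and the surviving set is stable.
Determinism given a whole *coalition* of other sources deliberately does not
trigger removal: a source that only the coalition can reconstruct (Y3 = Y1
xor Y2 in the XORLOSES system) is a genuine extra channel, and removing it
would flip that system's synergy from 0 to 1.  The 1e-9-bit threshold
replaces an exact-zero test because conditional entropies of float pmfs are
only zero to rounding.

## Degradation-order machinery

`blackwell_le` decides KQ ⪯_d K by the LP feasibility of {W row-stochastic:
K·W = KQ} (HiGHS), returning the garbling witness; a witness is accepted
when the max-norm reconstruction error is below 1e-7.

The degradation redundancy max I(Q;T) subject to KQ ⪯_d K(i) for all i is a
maximization of a convex function (mutual information in the channel for
fixed p(t)) over a polytope, so the optimum is attained at a vertex.  The
lifted polytope {(W1..Wm): K(1)W1 = K(i)Wi, Wi row-stochastic} is
parametrized on the nullspace of its equality system and vertices are
enumerated by batched active-set solves over all d-subsets of the
non-negativity constraints (d = nullspace dimension); every vertex of the
projected KQ-polytope is the projection of some lifted vertex, so evaluating
I(Q;T) at all projected vertices is exact.  Beyond 2·10^6 candidate bases
the enumerator falls back to a seeded random sample of bases and flags the
result `lower_bound`.  The output alphabet |Q| defaults to |T| and is
escalated by one until the optimum stops increasing, capped at the product
of the source alphabet sizes (the BOOM optimum is already attained at
|Q| = 3 and confirmed stable at 4).

The fixed-marginal union information min I(⋃Ai;T) s.t. p*(Ai,T) = p(Ai,T)
is solved as a convex program with linear constraints: cells that project
onto a zero constrained marginal are forced to zero and eliminated, the
remaining equality system is reduced to independent rows by pivoted QR (when
the constraints pin the joint completely, as for COPY, the solution is read
off directly), and scipy's trust-region interior-point method minimizes the
objective with an analytic gradient, started from the maximum-entropy (IPF)
distribution with the same marginals — feasible and interior.  Observed
accuracy on closed-form cases (AND: 0.3113, XOR: 0, COPY: 2) is ~1e-4 bits
or better, well inside the 5e-3 comparisons used.

## Legacy measures

Williams–Beer redundancy is the expected minimum specific information
Σ_t p(t)·min_i Σ_a p(a|t) log2[p(t|a)/p(t)]; the union measure is built from
it by inclusion–exclusion over non-empty sub-collections, and the synergy
subtracts from I(Y;T).  Whole-minus-sum is I(Y;T) − Σ I(Yi;T) (can be
negative).  Correlational importance is the Kullback–Leibler form
Σ p(t,y) log2[p(t|y)/p_ind(t|y)] with p_ind(t|y) ∝ p(t)∏p(yi|t), normalized
per y over the outcomes with p(y) > 0.  These conventions reproduce every
row of the quantitative comparison table, which is what fixes them (the
formulas are not otherwise pinned down).

Maximum-entropy distributions with fixed marginals use cyclic iterative
proportional fitting initialized uniformly on the support of the product of
constraint supports, with convergence measured in total variation per
constraint (tolerance 1e-8, cap 10^4 sweeps).  When the maxent solution has
zero cells not implied by any single marginal, IPF converges sublinearly and
may hit the sweep cap with a small residual (AND reaches ~1e-5); the
dependency decomposition therefore reports convergence status and residual
instead of raising, since the induced error is orders of magnitude below the
1e-3 comparisons made with it.  The fitted entropy always dominates H(p);
the sweep-by-sweep entropy trace is recorded but is not monotone in general.

## Axiom harness and fixtures

Random fixtures are Dirichlet-distributed joints over full outcome grids
with alphabets ≤ 3 and 2–3 sources, concentrations cycling through
{0.5, 1, 5}, and ~10% sparse fixtures (cells zeroed with probability 0.3
before renormalizing) to exercise support handling.  All randomness is
seeded; a failing property stores the fixture and collection as a replayable
witness.  Equality assertions use 1e-7 bits, inequalities a one-sided 1e-9
slack.  Self-redundancy is checked both per source and on the full-union
coalition treated as a single source — the latter is what detects the
broken (unclipped) variant of the measure.

These fixtures emulate dense small-alphabet discrete systems.  They do not
emulate large alphabets, structured low-rank dependencies, or empirical
(sampled) distributions — all inputs are exact pmfs, and estimation error is
out of scope — so passing tests certify the measures' algebraic properties,
not their statistical behaviour under sampling noise.

## Known discrepancies and limitations

* **Adapted-XOR mid-point values.**  For the adapted XOR family the
  implementation reproduces the published synergy values at r = 0 (0.270)
  and r = 0.5 (0.610) exactly, but at r = 0.25 computes S^CI = 0.4641 where
  0.552 is printed; hand computation of I(Y;T) = 0.6932 and I_q = 0.2303
  from the printed table confirms 0.4641 (0.552 lies at r = 0.4 on the same
  curve).  The non-convexity conclusion is unaffected (0.4641 > 0.440).
* **Adapted-XOR-v2 degradation synergy.**  Because K(1) = K(2) for this
  family, I_∪^d = I(Y1;T) exactly (couple Y2 := Y1), giving S^d = 0.3610,
  0.4230, 0.4955 at r = 0, 0.25, 0.5 — the convex program agrees to 4
  decimals — whereas 0.338 and an average of 0.3095 are printed.  At these
  three points the faithful S^d is locally convex, so the published
  degradation-synergy convexity violation does not reproduce; S^CI does
  violate convexity on both adapted families, and the counterexample
  harness reports each direction as measured.
* Full atom solving on the union semi-lattice for n ≥ 3 is out of scope
  (the decomposition from a union measure is not a Möbius inversion); the
  package computes top-level union/synergy for arbitrary collections and
  the complete atom set only for two sources.
* Continuous variables and estimation from samples are not supported.
* The degradation-redundancy enumerator is exponential in the nullspace
  dimension; instances beyond the basis cap return seeded lower bounds
  flagged in the result status.
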