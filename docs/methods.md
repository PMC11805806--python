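# Methods

## Model and scope

The package works with the generalized Lotka–Volterra ODE
`u̇_i = u_i (b_i + Σ_j a_ij u_j)` on the nonnegative orthant, restricted to
Volterra–Lyapunov (VL) stable interaction matrices: `A` is VL stable when
some positive diagonal `H` makes `HA + AᵀH` negative definite. VL stability
is exactly the class where every principal subsystem has a unique globally
asymptotically stable equilibrium, which is what makes the invasion graph
a faithful, purely algebraic summary of the attractor. Everything the
package computes — admissibility, invasion rates, the IG, the GASS — is
finite linear algebra; no Lyapunov functions, manifolds or connecting
orbits are constructed, and the hypergraph refinement of the attractor is
out of scope.

Two caveats are built into the verdicts rather than hidden. First, the IG
equals the connection graph only when all equilibria are hyperbolic (every
absent-species invasion rate nonzero); `structure_verdict` reports
`gradient_certified` only when hyperbolicity *and* acyclicity both hold,
and otherwise records that the IG may miss connections. Second, the
numerical VL-stability test is one-sided: a `vl_stable` verdict carries a
certificate that is re-checked by a single eigenvalue computation, while
`inconclusive` never means "not VL stable".

## The `H(S+J)` constructive characterization

`A` is VL stable iff `A = H(S + J)` with `H` positive diagonal, `S`
symmetric stable, `J` antisymmetric; then `H⁻¹A + AᵀH⁻¹ = 2S`, so the
decomposition doubles as a certificate. The random generator draws

- `H` diagonal uniform on (0.1, 1.1),
- `J = K − Kᵀ` with `K` standard normal times `scale` (default 1),
- `S = F + Fᵀ − αI` with `F` standard normal times `scale` and
  `α = max(0, λ_max(F + Fᵀ)) + margin`, `margin = 0.5` by default, so the
  spectrum of `S` is strictly negative with a definite gap.

The entry distributions and scales are the package's own choice (simple,
reproducible, strictly stable); all are keyword-configurable. One integer
seed feeds a single `numpy` Generator per call, so every generated matrix
is bit-reproducible.

VLDecomposition inputs are accepted when symmetric/antisymmetric to within
1e−12 absolute and then exactly (anti)symmetrized, so stored matrices
cannot drift.

## VL-stability detection

The objective `O(h) = λ_max(diag(h)A + Aᵀdiag(h))` is minimized over the
box `(ε, 1−ε)^N`, `ε = 1e−6`. It is positively homogeneous in `h`, so the
unit box loses no generality. The default local minimizer is L-BFGS-B with
the analytic subgradient `∂O/∂h_i = 2 v_i (Av)_i` (`v` the top unit
eigenvector); the objective is nonsmooth at eigenvalue crossings, but no
correctness claim rests on the optimizer — every evaluation is monitored
and the search stops at the first value below the threshold (default
−1e−10), which becomes the certificate. Start points are uniform on the
box from the seeded stream; the default is 50 starts. The 1-species case
is decided analytically (`a₁₁ < 0`).

The dense-sequence variant enumerates the dyadic rationals of `(0,1)^N`
(by denominator level, then lexicographically, skipping points already
seen at a coarser level) and stops at the first strictly negative
objective. It halts on every VL stable matrix given enough iterations and
cannot halt otherwise, so a practical cap (default 10⁴) maps
"non-termination" to `inconclusive`.

## Communities, equilibria, GASS

All `2^N` subsets are swept (bitmask enumeration, hard cap `N ≤ 20`).
For each nonempty `J`, `−A(J)u = b(J)` is solved directly; a condition
number above 1e12 marks the community rejected as `singular` rather than
aborting the sweep, and coordinates must exceed 1e−9 (absolute) to count
as strictly positive — near-zero solutions are boundary cases and are
rejected as `negative_coordinate`. The empty community is always
catalogued with the zero equilibrium and the convention `r_i(∅) = b_i`.
Communities are 1-based sorted tuples everywhere in the API and exports.

The GASS is identified as the unique *saturated* admissible equilibrium:
`r_i(I) ≤ tol` for every absent `i`. Saturation is the standard
characterization consistent with global stability under VL stability, but
the identification is deliberately loud: if zero or several saturated
equilibria are found (non-VL-stable input, or tolerances too tight),
`find_gass` raises instead of guessing.

Hyperbolicity and the IG edge rule share the rate-sign tolerance 1e−9:
an absent-species rate within ±tol makes the system non-hyperbolic and
licenses no edge, rather than being silently assigned a sign.

## Invasion graph and cycles

Edges follow the strict-inequality rule with vacuous difference sets
counting as satisfied; each edge stores its licensing rates so every edge
is auditable. Cycle existence is decided by strongly-connected-component
decomposition (exact, always completes); elementary cycles are enumerated
with Johnson's algorithm, capped (default 10⁵) with an explicit `cap_hit`
flag, and reported in a deterministic rotation/ordering. The empty
community is a genuine node (it is admissible, and `r_i(∅) = b_i` licenses
its out-edges); exports can hide it with a toggle.

Frondosity machinery: `check_frondosity` tests the hypothesis that every
community's candidate solution is strictly positive (maximal frondosity,
which excludes heteroclinic cycles outright and, under hyperbolicity,
forces the edge set `{(I,J): I ⊊ J}`). Two sufficient conditions are
provided as separate predicates — full cooperativity with positive growth
rates, and the strong diagonal-dominance bound
`max_i Σ_{j≠i} |a_ij/a_jj| < 1/(1+M)` with `M = max b / min b` — both
reported with their slack, and both only sufficient. The singleton-cycle
scanner evaluates the necessary product condition
`Π|a_{i,i+1}| ≥ Π|a_ii|` along each cyclic ordering found and flags the
(provably impossible) combination of a singleton cycle with row/column
diagonal dominance as a contradiction, i.e. a bug.

## Dynamics

`simulate` integrates with SciPy's adaptive LSODA at rtol 1e−9 /
atol 1e−12. Coordinates that start at exactly zero are removed from the
integrated subsystem instead of being carried as small numbers, so faces
of the orthant are invariant *exactly* and wall dynamics are true
restrictions. A state-norm event at 1e8 converts blow-up (impossible for
VL stable `A`, possible under misuse) into an error. The default horizon
`t_final = 200/|min diag A|` is a heuristic sized for the strongly
self-regulated fixtures. `omega_limit_check` declares convergence when the
terminal 10% of samples has diameter below 1e−6 and then reports the
nearest catalogued equilibrium.

## Experiments and the scales used

All experiments are bit-reproducible from `(seed, config)`; a master
Generator spawns per-cell seeds so cells are independent of each other's
sample counts.

- **Detector benchmark**: for each dimension, generate VL stable matrices
  (ground truth is free — they are stable by construction) and record the
  fraction certified. Defaults used by the test suite and acceptance
  script: dimensions 2–19, 10 matrices per dimension, 50 starts. The
  inconclusive rate at dimension 20 is reported but never asserted: it
  depends on the generator's scales, which are this package's choices.
- **Cycle density**: samples matrices with a prescribed
  antisymmetric-to-symmetric entrywise-norm ratio `|A_J|/|A_S|` by
  splitting a normal draw, shifting the symmetric part's diagonal to
  stability, and rescaling the antisymmetric part; with `H = I` these are
  VL stable by construction. Unit growth rates. The suite asserts only the
  qualitative claims: density 0 at ratio 0 (symmetric flows are gradient)
  and monotone growth with the ratio.
- **Diagonal-dominance sweep**: off-diagonal entries standard normal,
  diagonal negative with magnitude exceeding the off-diagonal row or
  column sum (coin flip) by a positive slack; growth rates standard
  normal, mixed sign. The suite runs 10⁴ samples over dimensions 3–6 and
  asserts that no cyclic IG — and in particular no singleton-community
  cycle — appears. Full-graph acyclicity for this class is an open
  conjecture; the sweep is evidence, the singleton part is a theorem.
- **RPSLS d-sweep**: the family `d·I + J₅` across the bifurcation at
  `d = −1`: cycles and 12 admissible communities for `−1 < d < 0`,
  non-hyperbolicity exactly at `d = −1`, and for `d < −1` maximal
  frondosity (32 communities) with an IG identical to that of the
  decoupled diagonal system `diag(d)`.

## What the synthetic systems do and do not show

The generators produce dense, homoscedastic Gaussian interactions with a
uniformly gapped stable symmetric part. Real ecological networks are
sparse, have heavy-tailed and block-structured interactions, and their
matrices are estimated with error; nothing here models estimation noise,
and a passing suite shows the *algorithms* are correct on the stated
classes, not that any particular empirical community is VL stable. VL
stability itself is an assumption the detector can certify but never
refute.

## Known limitations

- The community sweep is exponential (`2^N`); the cap at `N = 20` is a
  practicality, not a boundary of validity.
- The detector's `inconclusive` verdict is uninformative by design;
  deciding VL stability exactly (e.g. via semidefinite programming) is
  deliberately out of scope.
- Elementary-cycle counts can be astronomically large; only `has_cycle`
  (via SCCs) is exact when the enumeration cap is hit.
- `omega_limit_check` cannot distinguish slow convergence from
  non-convergence; it reports `inconclusive` windows rather than guessing.
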