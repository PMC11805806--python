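# lvig — invasion graphs for Lotka–Volterra systems

`lvig` analyzes the long-run assembly dynamics of generalized
Lotka–Volterra communities

$$\dot u_i = u_i\Big(b_i + \sum_{j=1}^N a_{ij} u_j\Big), \qquad i = 1,\dots,N,$$

where `b` holds intrinsic growth rates and `A = (a_ij)` the interaction
matrix. It targets the class of **Volterra–Lyapunov (VL) stable** matrices —
those for which some positive diagonal `H` makes `HA + AᵀH` negative
definite — where the flow has a global attractor and a unique globally
asymptotically stable stationary solution (the **GASS**). For this class the
attractor's skeleton is computable from linear algebra alone:

- a subset `I ⊆ {1..N}` is an **admissible community** when `−A(I)u = b(I)`
  has a strictly positive solution, giving the boundary equilibrium `u^I`;
- the **invasion rate** `r_i(I) = b_i + Σ_{j∈I} a_ij u^I_j` is the per-capita
  growth rate of species `i` introduced at vanishing density into `u^I`;
- the **invasion graph (IG)** has the admissible communities as nodes and an
  edge `I → J` when every species of `J∖I` can invade `I` (`r_j(I) > 0`) and
  every species of `I∖J` dies out at `J` (`r_i(J) < 0`).

When every equilibrium is hyperbolic (no zero absent-species invasion
rates), the IG coincides with the graph of actual heteroclinic connections,
so **cycles in the IG are the fingerprint of heteroclinic cycles** in the
attractor, and an acyclic IG certifies a gradient system whose attractor
structure is fully recovered. The package provides, per module:

| module | what it does |
|---|---|
| `lvig.matrices` | `A = H(S+J)` construction, random VL stable generation, symmetric/antisymmetric splits, entrywise/row norms, diagonal-dominance predicates, canonical fixtures (May–Leonard, rock–paper–scissors `rps3`, RPSLS `rpsls5`, a 4-species mixed-dimension cycle) |
| `lvig.detector` | numerical VL-stability test: multi-start bounded minimization of `λ_max(HA + AᵀH)` over `H ∈ (0,1)^N`, with checkable certificates, plus a dense-sequence semi-decision variant |
| `lvig.equilibria` | enumeration of all `2^N` communities, equilibria, invasion rates, hyperbolicity, GASS identification (unique saturated equilibrium) |
| `lvig.graph` | IG construction, SCC/elementary-cycle detection, gradient/frondosity verdicts, sufficient conditions excluding cycles, DOT/GraphML export |
| `lvig.dynamics` | face-invariant ODE integration for empirical validation |
| `lvig.experiments` | reproducible studies: detector recall benchmark, cycle density vs `|A_J|/|A_S|`, diagonally-dominant no-cycle sweep, RPSLS `d`-sweep |

## Worked example

The 5-species rock–paper–scissors–lizard–Spock system `A = d·I + J` with
`d = −0.5` and unit growth rates:

```python
import numpy as np
import lvig as lv

a, b = lv.rpsls5(-0.5)
catalog = lv.enumerate_admissible(a, b)
print("admissible communities:", len(catalog), "of", 2**catalog.n)
gass = lv.find_gass(catalog)
print("GASS support:", gass.community, "abundances:", np.round(gass.u, 3))

g = lv.build_ig(catalog)
report = lv.find_cycles(g)
print("IG:", g.number_of_nodes(), "nodes,", g.number_of_edges(), "edges;",
      "cycles:", len(report.elementary_cycles))
five = [c for c in report.elementary_cycles
        if len(c) == 5 and all(len(n) == 1 for n in c)][0]
print("singleton cycle:", " -> ".join(map(str, five)))

result = lv.detect_vl(a, n_initial=50, seed=0)
print("VL verdict:", result.verdict,
      "| objective at certificate:", f"{result.certificate.objective_value:.3e}")
```

prints

```
admissible communities: 12 of 32
GASS support: (1, 2, 3, 4, 5) abundances: [2. 2. 2. 2. 2.]
IG: 12 nodes, 26 edges; cycles: 13
singleton cycle: (1,) -> (2,) -> (3,) -> (4,) -> (5,)
VL verdict: vl_stable | objective at certificate: -9.598e-02
```

Twelve of the 32 communities support positive equilibria: the empty
community, the five singletons, five cyclically-consecutive species triples
and the full community, whose equilibrium `(2,2,2,2,2)` is the GASS. The IG
contains heteroclinic cycles — among them one through all five single-species
equilibria and one through all five triples — so the assembly dynamics can
circulate indefinitely along the boundary even though the interior
equilibrium attracts every fully-positive initial state. The detector
confirms VL stability with a certificate `h` whose objective value is
strictly negative, checkable independently with `lv.verify_certificate`.

Raising self-regulation to `d = −1.5` makes all 32 communities admissible
(*maximal frondosity*); the IG then has edge set exactly
`{(I, J) : I ⊊ J}`, is acyclic, and the attractor is gradient.

The same pipeline is scriptable from a shell:

```sh
lvig generate --n 6 --seed 1 --out A.csv
lvig detect --matrix A.csv --n-initial 50 --report detect.json
lvig ig --matrix A.csv --out graph.dot --cycles --verdict
lvig experiment density --out results/
```

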