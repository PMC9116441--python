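# Methods

## Model and pipeline

The package studies how randomly embedded knots occupy space.  A knot is
modelled as a closed equilateral polygon in R^3 with unit edges, so its
length equals its edge count `n`.  For each polygon the pipeline computes

1. **geometry** — radius of gyration `Rg` (root-mean-square vertex distance
   from the centroid), the exact minimal enclosing sphere (radius `RS`,
   volume `V_sphere`), convex-hull volume `V_hull` (Qhull), discrete total
   curvature (sum of turning angles, radians), discrete torsion (sum of
   signed dihedral angles between consecutive osculating planes; the signed
   and absolute sums are both reported), and the average crossing number
   (ACN);
2. **knot type** — via random generic projection, Reidemeister I/II
   reduction of the signed Gauss code, and the Alexander polynomial,
   normalized to lowest degree 0 and value +1 at t = 1, looked up in a table
   covering the unknot and all prime types through six crossings (majority
   vote over 5 projections; anything else is `"unknown"`);
3. **persistent homology** — the polygon is interpolated at 10 samples per
   unit edge (spacing 0.1) and the degree-1 Vietoris–Rips barcode of the
   resulting point cloud is computed.  Features: `I` (sum of bar lengths =
   integral of the Betti curve), `M` (longest bar), `#B` (bar count), and
   the Betti curve itself.  All filtration values are on the
   pairwise-distance (diameter) scale; neighbourhood radius `r` corresponds
   to parameter `2r`.
4. **deviation from ideality** — `delta_eps = (1/S) ∫_0^S f_{S,eps}(t) ·
   max(beta1(t) − 1, 0) dt`, where `S` is the end of the Betti-curve support
   and `f_{S,eps}` falls linearly from 1 at t = 0 to 0 at `S − eps`.  The
   integral is evaluated in closed form piece by piece (the integrand is
   piecewise linear); no quadrature is involved.

## Random polygon generator

Uniformly random equilateral polygons are approximated by a crankshaft
Markov chain: starting from the planar regular n-gon, a uniformly chosen
sub-chain between two random vertices is rigidly rotated about the chord
through them by an angle uniform on [0, 2π).  Each move is an isometry of
the sub-chain, preserving closure and unit edge lengths exactly; the chain
is ergodic on equilateral polygon space.  Defaults: burn-in `30 n` moves per
independent sample, exact re-equilateralization (alternating projection to
unit edges and closure, tolerance 1e-12) every 1000 moves and at the end.
Every polygon gets an independent, counter-derived seed stream, so datasets
are reproducible and order-independent.

Mixing was checked by comparing moment estimates at burn-ins 30 n, 100 n and
300 n (statistically indistinguishable) and against the Gaussian-ring limit
`E[Rg^2] ≈ n/12`: at n = 50 the sampled mean is about 1.7 % above `n/12`, a
finite-size effect of the equilateral ensemble consistent with the known
O(1/n) corrections; tests therefore use a 3 % band around `n/12` rather than
a purely statistical tolerance.  An exact small-n anchor is also tested: for
every closed equilateral 4-gon, `Rg^2 = (4 + d13^2 + d24^2)/16 ≤ 1/2`, where
`d13`, `d24` are the diagonals (equality holds when the diagonal midpoints
coincide, e.g. for planar rhombi).

Typed sampling is plain rejection: draw, classify, keep on label match.
Cells that exhaust their attempt budget are reported incomplete, never
padded.

## Knot identification

The Alexander polynomial replaces the HOMFLY polynomial used with external
software in comparable studies: it distinguishes all prime knots through six
crossings, which is exactly the supported label set.  Known caveats are
inherited deliberately: Alexander-trivial nontrivial knots (first at 11
crossings) are labelled `0_1`, and ≥ 7-crossing types are folded into
`"unknown"` unless their polynomial collides with a table entry (no
collisions exist through 8 crossings).

The crossing/arc matrix uses the Fox-calculus relations (`x_j − t x_i +
(t−1) x_k` for a positive crossing); one row and column are deleted and the
determinant over Z[t] is computed exactly by modular evaluation and
interpolation: Gaussian elimination over several 31-bit prime fields at
integer points, Lagrange interpolation, CRT reconstruction with a
stabilization check.  Because the polynomial's degree is usually far below
the matrix size, the interpolation grid grows adaptively and a candidate is
accepted only if it reproduces two held-out determinant evaluations in every
prime field.  This is exact integer arithmetic presented differently from
(and much faster than) symbolic fraction-free elimination; tests cross-check
it against fully symbolic sympy determinants on sampled diagrams.

Projection degeneracies (near-parallel overlaps, crossings at vertex images,
ambiguous depths, an edge collapsing to a point) are detected at tolerance
1e-9 and trigger a fresh random direction, with a budget of 20 directions.

The reference table entries for 3_1, 4_1 and 5_1 are verified end-to-end
from parametric curves (torus knots and the figure-eight parametrization);
the 5_2–6_3 entries are standard constants, checked for palindromic
symmetry, unit value at t = 1 and pairwise distinctness.

## Persistence engine

No persistent-homology library ships with the package's environment, so the
degree-1 Vietoris–Rips engine is implemented here: persistent cohomology
with clearing.  Minimum-spanning-tree edges (the degree-0 pairs) are
removed; the remaining edges are processed in decreasing filtration order,
and each is paired with the lowest cofacet triangle of its reduced
coboundary column.  The lowest cofacet is found by walking neighbours in
increasing distance with early termination; diameter ties are resolved by
the sorted-triple key, which is monotone in the apex index, so the first
qualifying apex in index order wins.  The overwhelming majority of columns
terminate immediately as zero-persistence apparent pairs; the rare genuine
reductions use an explicit binary heap over cofacet triangles with GF(2)
cancellation, adding stored columns (kept in compressed edge form) until the
pivot is free.  Simplex order is (diameter, combinatorial key) everywhere,
which makes the output deterministic.

Correctness is anchored to an independent oracle that builds the filtration
through dimension 2 explicitly and reduces the boundary matrix over GF(2)
(limited to 60 points); the two implementations must agree exactly on a
fixed random suite, on curve samples, and on closed-form cases (circle
death at diameter sqrt(3); the two-edge wedge class born at `4 d sin(θ/2)`
and dying at `d sqrt(5 − 4 cos θ)` for spacing d = 0.1, which exists exactly
for internal angles below arccos(3/4) ≈ 41.4°).

## ACN estimators

The primary ACN estimator is the definition itself: the mean transverse
crossing count over uniformly random projection directions (default 100,
seeded; degenerate directions resampled), reported with its standard error.
The cross-check is the Gauss double integral over non-adjacent segment
pairs, `(1/4π) ∬ |(e_i × e_j)·(x−y)| / |x−y|^3`, by tensor Gauss–Legendre
quadrature (default order 8).  Two refinements keep the quadrature at full
order: the numerator is affine in the two segment parameters, so each
parameter square is split along its straight zero line and the smooth pieces
are integrated with Duffy-mapped triangle rules; and pairs of segments
closer than 0.5 are subdivided into sub-squares comparable to their
separation before applying the rule.  Adjacent pairs vanish identically
(coplanar triple product) and are skipped.

## Parameters that matter

| parameter | default | units | rationale |
|---|---|---|---|
| samples per edge `s` | 10 | – | spacing 0.1; dense enough that the Rips filtration tracks the tubular neighbourhood, and the source of the spike just after t = 0.1 |
| burn-in | 30 n | moves | mixing-checked; config-exposed |
| `eps` (delta_eps cut-off) | 0.1 | diameter scale | one interpolation spacing; "sufficiently small" regime, checked by a sweep over {0.05, 0.1, 0.2} |
| spike filter window | births in [0.10, 0.13], persistence ≤ 0.05 | diameter scale | closed-form birth range of shallow-angle artefact bars for angles down to ~20° |
| classification tries | 5 | projections | majority vote; ties → `"unknown"` |
| ACN directions | 100 | – | standard error ≈ a few percent for the lengths studied |

`delta_eps` and all averaged curves are computed from the **unfiltered**
barcode by default; the spike filter is opt-in everywhere.  `delta_eps` is
covariant, not invariant, under rescaling: scaling the cloud by c and `eps`
by c leaves it unchanged.

## Desk-scale study sizes

The reference study design is 10^4 random polygons per length (lengths
10–100, step 10) and 10^3 per knot type and length (types through six
crossings, lengths 50–200, step 50).  The package's test suite reproduces
the qualitative structure of that design at desk scale, chosen for
statistical power on one CPU: 60 polygons per length at lengths {20, 50,
100}; 10 unknots per length at {50, 100, 150, 200}; 15 trefoils per length
at {50, 100}; 100 classified trefoils for the total-curvature bound; fixed
seeds throughout.  At these sizes the asserted signs and orderings (negative
I-vs-volume correlations growing with length, positive I-vs-ACN, positive
M-vs-hull, near-perfect linearity of per-type mean I in length) hold with
comfortable margins; correlation magnitudes are not asserted, since they are
estimated from figure-scale datasets two orders of magnitude larger.

For the "no significant correlation with curvature or torsion" claim, the
torsion variable is the **signed** dihedral sum: it is parity-odd while the
sampling ensemble is mirror-symmetric, so its population correlation with
any parity-even feature vanishes exactly — the claim is a true null for it.
The absolute torsion behaves like a curvature magnitude and shows the same
weak negative tendency as total curvature; both are reported in the feature
table.

## What the generator does and does not emulate

The crankshaft chain approximates the uniform distribution on equilateral
polygon space; it does not implement the direct symplectic samplers that
guarantee exact uniformity, nor excluded-volume (self-avoiding) ensembles,
confinement, or open chains.  Conclusions from passing tests therefore speak
to the ideal (phantom) ring ensemble, not to polymers with thickness.
Composite knots are not filtered from the long-length samples; at length
100 and above a non-negligible fraction of "unknown" labels are composite.

## Known limitations

* Ideal (ropelength-minimizing) embeddings are not computed; the near-ideal
  member of the trefoil family is approximated by the (2, 1) torus-curve
  embedding, and only the ordering delta(balanced) < delta(elongated) <
  delta(flattened) is asserted, not absolute values.
* The injectivity radius, ropelength, L/D and higher-degree persistence are
  out of scope.
* Chirality is ignored: the label set is achiral and the Alexander
  polynomial cannot see it.
* Classification of very long polygons (n ≳ 200) slows down as diagrams grow
  to ~100 crossings before simplification.
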