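# knotph

Statistical study of how randomly embedded knots occupy space, using
persistent homology.

Ring polymers — DNA minicircles, cyclic peptides, synthetic ring chains —
are modelled as closed equilateral polygons in 3-space ("length" = number of
unit edges).  This package asks how a random embedding's *topology* (its
knot type) and *geometry* (how much space it fills) are related, and probes
both through the first homology of a growing metric neighbourhood of the
curve.

For a polygon K the pipeline computes:

* **compactness** — radius of gyration Rg, minimal enclosing sphere volume
  V_sphere, convex-hull volume V_hull, discrete total curvature and torsion,
  and the average crossing number (ACN);
* **knot type** — generic projection → signed Gauss code → Reidemeister I/II
  reduction → Alexander polynomial Δ(t), normalized so Δ(1) = 1, matched
  against the unknot and all prime types through six crossings;
* **persistence features** — K is interpolated at 10 points per edge and
  the degree-1 Vietoris–Rips barcode of the cloud is computed (filtration
  values on the pairwise-distance scale).  The Betti curve
  β₁(t) = rk H₁ yields

      I(K)  = ∫ β₁ dt   (total bar length),
      M(K)  = longest bar,
      #B(K) = number of bars;

* **deviation from ideality** — with S = max{t : β₁(t) ≠ 0} and a weight
  f_{S,ε} falling linearly from 1 at t = 0 to 0 at S − ε,

      δ_ε(K) = (1/S) ∫₀^S f_{S,ε}(t) · max(β₁(t) − 1, 0) dt,

  which vanishes for embeddings whose thickened neighbourhood keeps a single
  loop class for as long as possible (the signature of ideal, ropelength-
  minimizing embeddings) and grows with early excess homology.

Random polygons come from a crankshaft Markov chain (exactly closure- and
edge-length-preserving moves); fixed knot types are obtained by rejection.
Statistical analyses (per-length and per-type Pearson/Spearman correlations
of the features above, averaged Betti curves, linear fits, split-half
robustness) reproduce, at desk scale, the known qualitative structure:
I(K) correlates *negatively* with occupied volume — increasingly so for
longer chains — and *positively* with ACN, while per-type mean I is almost
perfectly linear in length.  See `docs/methods.md` for the model details
and numerical choices.

## Worked example

```python
import numpy as np
import knotph as kp

rng = np.random.default_rng(7)
P = kp.sample_fixed_type(50, "3_1", max_attempts=500, rng=rng)  # a random trefoil
bc = kp.rips_h1_barcode(kp.interpolate(P, 10))
curve = kp.betti_curve(bc)
res = kp.delta_ideality(curve, 0.1)
g = kp.geometric_summary(P, n_dirs=100, rng=2)
print(kp.classify(P, rng=1), kp.integral_I(bc), kp.max_bar_M(bc),
      kp.num_bars_B(bc), res.S, res.delta, g.Rg, g.V_hull, g.acn)
```

prints (abridged):

```
label      = 3_1          # rejection-sampled trefoil, reclassified
I          = 6.737        # integral of the Betti curve
M          = 1.107        # longest bar: the dominant loop class
#B         = 100          # bars, most of them short-lived spike artefacts
S, delta   = 1.207, 3.4616  # support end; large delta = far from ideal
Rg         = 1.413        # compact conformation
V_sphere   = 56.76
V_hull     = 12.40
curvature  = 89.88 rad    # >> 4*pi, as Fary-Milnor requires for a knot
acn        = 63.52 +- 0.95
```

This embedding is compact (hull volume 12.4 vs sphere volume 56.8), heavily
entangled (ACN ≈ 64), and its δ = 3.46 says its Betti curve carries many
early excess classes — far from the single-loop signature of an ideal
trefoil.  For contrast, the near-ideal torus embedding
`kp.trefoil_family("balanced", 120)` has δ ≈ 0.03.

A command-line interface mirrors the library:

```sh
knotph sample --n 50 --type 3_1 --seed 7 --out trefoil.xyz
knotph classify --in trefoil.xyz
knotph features ph --in trefoil.xyz --out barcode.csv
knotph ideality --in trefoil.xyz --epsilon 0.1
knotph pipeline1 --seed 0 --out-dir artifacts/
```

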