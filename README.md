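# flowsle

Conformal-invariance and Schramm–Loewner-evolution (SLE) analysis of
two-dimensional collective-flow vorticity fields.

Collectively moving cells — bacterial monolayers, epithelial sheets — generate
disordered vortical flows. The line separating clockwise from counterclockwise
rotation, the **zero-vorticity isoline**, turns out to be a conformally
invariant random curve in the percolation universality class. `flowsle`
implements the complete analysis chain needed to establish (or refute) that
statement for any gridded 2D velocity field:

1. **fields** — read PIV-style velocity tables or grid files, compute the
   vorticity ω = ∂ₓu_y − ∂_yu_x with a fourth-order five-point stencil, and
   binarize it by sign;
2. **contours** — label vorticity clusters, trace oriented zero-vorticity
   isolines with a marching-squares walk that keeps positive vorticity on its
   right, and extract chordal "explorer" traces for SLE analysis;
3. **scaling** — gyration radii, fractal dimensions of the complete and
   accessible perimeters (l ~ R_g^D with D = 7/4 and D* = 4/3 for the
   percolation class, linked by the duality 4(D−1)(D*−1) = 1), and
   winding-angle statistics (Var θ = a + [2κ/(8+κ)] ln s);
4. **sle** — two independent estimators of the SLE diffusivity κ: the
   left-passage probability against Schramm's formula
   P_κ(φ) = 1/2 + Γ(4/κ)/(√π Γ((8−κ)/2κ)) · cot φ · ₂F₁(1/2, 4/κ; 3/2; −cot²φ),
   and the Loewner driving function U_t extracted by the vertical-slit zipper,
   with Var(U_t) = κt for SLE_κ;
5. **synthetic** — generators with exact ground truth: chordal
   critical-percolation interfaces (κ = 6), forward SLE_κ traces, loop-erased
   random walks (κ = 2), and a scaled-down active-nematic continuum model
   producing statistically stationary "active turbulence";
6. **pipeline / CLI** — an end-to-end `flow` command gluing the stages
   together into a reproducible report.

## Worked example

Estimate κ from five hundred critical-percolation interfaces — the exact
SLE₆ reference ensemble — using the left-passage probability:

```python
import numpy as np
from flowsle import (percolation_interface, empirical_left_passage,
                     estimate_kappa_lpp, winding_variance_fit)

rng = np.random.default_rng(1)
traces = [percolation_interface(300, 300, rng=rng)[0] for _ in range(500)]

est = estimate_kappa_lpp(empirical_left_passage(traces))
print(f"kappa (left passage) = {est.kappa:.2f} +/- {est.stderr:.2f}")

ws = winding_variance_fit(traces)
print(f"winding slope alpha  = {ws.slope_alpha:.3f}  (2k/(8+k) = {6/7:.3f})")
```

```
kappa (left passage) = 5.90 +/- 0.32
winding slope alpha  = 0.837  (2k/(8+k) = 0.857)
```

The left-passage estimate sits on the exact percolation value κ = 6 within
its standard error, and the winding-angle variance grows logarithmically with
arclength at the conformal-invariance slope 2κ/(8+κ) = 6/7.

The same analysis applied to a velocity field on disk:

```bash
flow vorticity --in field.txt --boundary crop --out omega.npz
flow contours  --in omega.npz --axis-row auto --out traces/
flow sle       --traces traces/chordal.tsv --method both --out kappa.json
```

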