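# morphomech

Theoretical-morphospace biomechanics of archosaur (dinosaur-grade) skulls.

Skull geometry is reduced to five lateral-view measurements: skull length,
rostrum length, orbital-region length, braincase length and skull height.
The three region lengths place each skull as a point on a ternary simplex
(rostrum : orbit : braincase), and length/height gives an elongation ratio.
`morphomech` builds parametric 2-D skull models across that morphospace,
solves each under two comparative load cases with a plane-stress
finite-element solver, and projects measured (or simulated) species and a
phylogeny onto the resulting performance surfaces.

## What it computes

**Theoretical grid.** All compositions `(r, o, b)` on a 10% lattice with
every component ≥ 10% — 36 viable hypothetical models.  Each model is a
parametric lateral-view outline (wedge snout, skull table, domed braincase,
orbit and upper-temporal openings), meshed with constant-strain triangles.

**Two load cases.**

- *Bending*: quadrates fixed, a dorsal point load at the snout tip,
  `F = F_ref · A/A_ref` (area-corrected, `F_ref = 100 N` on the 60/20/20
  base model) so that size alone does not change stress.
- *Muscle-driven biting*: quadrates fixed, the premaxillary bite point held
  vertically, total adductor force `F = σ_m · A_fenestra` (dry-skull
  estimate, specific tension `σ_m = 0.3 N/mm²`) distributed over the
  upper-temporal margin and directed toward a posteroventral insertion.

Per model: median element von Mises stress
`σ_vM = sqrt(σx² + σy² − σxσy + 3τxy²)` for both cases, and mechanical
advantage `MA = |bite reaction| / muscle force`.  Material is crocodilian
bone, `E = 15.00 GPa`, `ν = 0.29`.

**Species layer.** A measurement table (CSV) or the built-in synthetic
dataset generator (clade-structured Dirichlet compositions, lognormal sizes
and ratios, 204 species by default) is summarized, its convex-hull occupancy
of the simplex computed, its species interpolated on the performance
surfaces, and a phylogeny (Newick, or a generated Yule tree) drawn through
the morphospace using exact Brownian-motion ancestral states (weighted
squared-change parsimony).

## Worked example

```python
from morphomech import (SkullParams, TernaryCoord, build_outline, triangulate,
                        Material, solve, bending_case, ScenarioSpec)
from morphomech.pipeline import PipelineConfig, evaluate_model

params = SkullParams(tern=TernaryCoord(0.6, 0.2, 0.2), ratio=3.0, length=300.0)
metrics = evaluate_model(params, PipelineConfig())
print(f"bending median stress {metrics['bending_median_vm']/1e6:.3f} MPa")
print(f"biting  median stress {metrics['biting_median_vm']/1e6:.4f} MPa")
print(f"mechanical advantage  {metrics['mechanical_advantage']:.4f}")
```

prints

```
bending median stress 0.209 MPa
biting  median stress 0.0147 MPa
mechanical advantage  0.0529
```

i.e. the 60/20/20 base skull (300 mm long, ratio 3) carries a median
equivalent stress of ~0.21 MPa under the 100 N snout load, and converts
about 5.3% of its adductor force into vertical bite force — low, as expected
for a bite point at the snout tip (long out-lever).

The command line drives the whole analysis:

```bash
morphomech full --output-dir run      # grid + ratio sweep + species + phylogeny
morphomech species                    # dataset summary and occupancy only
morphomech check                      # solver verification battery
```

`run/report.txt` then shows, for the default synthetic dataset, the pattern
the pipeline is designed to expose: rostrum fraction spans the widest range
of the three components, the dataset occupies a narrow band (~26%) of the
ternary simplex, skull ratios cluster near 2, bending stress is lowest for
short-orbit/expanded-braincase models and highest for expanded-orbit models,
rostrum-varying transects are close to iso-stress, and biting stress and
mechanical advantage rise with braincase fraction.

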