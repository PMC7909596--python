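# anthroscan

Device-independent digital anthropometry: standard body circumferences
from 3D optical scans.

3D body scanners are cheap and fast, but every manufacturer measures at
its own undocumented anatomic sites, so readings cannot be pooled across
devices or compared to published tape-measure reference values.
`anthroscan` takes the raw output any scanner can produce — a triangular
surface mesh (OBJ, PLY or STL) of a standing adult in the A-pose — and
computes eleven standard circumferences at one fixed set of geometric
site definitions: chest, waist, hip, and left/right upper arm, thigh,
calf and ankle.

The pipeline is:

1. **canonicalize** — principal-axis alignment into a body frame
   (+z up, subject's left at +x), robust to vertex density via
   area-weighted moments;
2. **repair / fill_holes** — drop degenerate and duplicate faces, patch
   the boundary loops scanners leave at occluded regions so the surface
   is watertight, with patches that follow the local curvature;
3. **landmarks** — detect crotch, armpits, shoulders and feet from
   transverse cross-sections (the crotch is the height where two leg
   contours merge into one; an armpit is the highest section whose arm
   contour is disjoint from the torso contour), bisection-refined to 1 mm;
4. **segmentation** — partition faces into arms, legs and center body by
   the crotch plane and the shoulder–armpit cut planes;
5. **measure** — sweep section planes (transverse for the trunk,
   perpendicular to the limb axis for arms and legs, which sit at roughly
   45° in the A-pose) and report the *convex-hull perimeter* of the
   selected contour — the length a flexible tape would read.

The package also ships the method-comparison statistics used to validate
digital against conventional tape anthropometry (paired t tests, DA-on-CA
regression with R² and RMSE = √(SSE/(n−2)), Bland–Altman bias, limits of
agreement and proportional-bias slope, with Δ always meaning
mean(DA) − mean(CA)), and a synthetic A-pose avatar generator whose site
circumferences are known in closed form (a circular ring of radius *r* at
resolution *n* measures 2·n·r·sin(π/n)), so the entire pipeline is
testable without a scanner.  See `docs/methods.md` for the full model.

## Worked example

```sh
python examples/measure_synthetic_scan.py
```

builds a 175 cm phantom with known circumferences and runs the full
pipeline:

```
phantom: 14896 vertices, 29760 faces, height 175.0 cm

crotch height    80.3 cm
armpit height   140.2 cm

site              measured     truth    error
chest              101.02    101.01   0.003%
waist               81.46     81.46   0.003%
hip                104.27    104.27   0.003%
upper_arm_left      29.53     29.53   0.003%
thigh_left          53.40     53.40   0.002%
calf_left           37.69     37.69   0.002%
ankle_left          25.16     25.13   0.130%
...
```

The measured waist (81.46 cm) is the convex-hull perimeter of the
narrowest trunk section found in the waist band; it matches the
generator's analytic ring perimeter to a few thousandths of a percent,
and the detected crotch and armpit heights land within a few millimetres
of where the phantom was built (the residual offset is the ~1° tilt that
principal-axis alignment gives an asymmetric body).  `examples/degraded_scan_recovery.py` shows the same
loop with scanner artifacts injected (holes at crotch/armpits, vertex
noise), and `examples/method_comparison.py` the statistical report for a
simulated 35-subject validation cohort.

The same pipeline is available from the shell:

```sh
anthroscan simulate --out demo --seed 0        # phantom + ground truth
anthroscan measure demo/avatar.ply --out demo  # measurements.csv etc.
anthroscan compare --da demo/measurements.csv --ca tape.csv --out report
anthroscan selftest                            # end-to-end closure check
```

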