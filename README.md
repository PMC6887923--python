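# lascar

Quantification of left-atrial ablation scar from late-gadolinium-
enhancement (LGE) cardiac MR, for imaging researchers studying lesion
formation after pulmonary vein isolation (PVI). After PVI, durable
isolation depends on the ablation ring around each vein pair being wide
enough and free of gaps; `lascar` reconstructs those rings on an atrial
surface shell and measures total scar burden, per-ring scar width, and
ring continuity, then compares two treatment arms statistically.

The pipeline:

1. **Shell + projection** — segment the blood pool from a bright-blood
   volume, extract the endocardial surface, clip veins/appendage, and
   project onto each vertex the maximum LGE signal intensity within
   3 mm of the endocardial border along the outward normal (MIP).
2. **Threshold + burden** — classify a vertex as scar when its
   projected SI exceeds `μ_bp + 3.3 σ_bp`, the blood-pool mean plus
   3.3 SD; scar burden is the % of (clipped) shell area above threshold.
3. **Encirclement analysis** — reconstruct each vein-pair encirclement
   as a closed shortest-path loop through seed vertices, collect shell
   vertices within a 5 mm geodesic corridor, and parameterise them by
   arc length `s` and signed perpendicular offset `d`. Scar width per
   sector (100 equal sectors) is `max d − min d` over above-threshold
   points; a ring is *complete* when the mean SI in each of 16 equal
   sectors exceeds the threshold.
4. **Cohort statistics** — per-subject records compared between two
   groups with t-tests / Mann-Whitney U (continuous) and chi-square
   (completeness proportions).

No imaging data are bundled; a synthetic-phantom generator (ellipsoidal
atrium, vein stubs, annular scar bands of known width with optional
gaps, Gaussian intensities) provides ground truth for every stage.
`docs/methods.md` has the full model and numerical details.

## Worked example

Paint a phantom whose left/right rings have true widths 6.4 mm and
9.9 mm, then measure them back:

```python
import lascar as L

spec = L.PhantomSpec(scar_band_left=L.ScarBand(6.4),
                     scar_band_right=L.ScarBand(9.9),
                     noise_sd=10.0, seed=1)
shell, gt = L.generate_shell_phantom(spec)
thr = L.ScarThreshold.from_stats(100.0, 10.0, k=3.3)   # threshold 133.0
res = L.analyze_subject(shell, thr,
                        gt.seed_vertices["left"], gt.seed_vertices["right"])
print(f"burden {res.burden_percent:.1f}%  "
      f"width L {res.width_left:.2f} R {res.width_right:.2f} "
      f"total {res.width_total:.2f} mm  bilateral {res.complete_bilateral}")
```

Output:

```
burden 21.5%  width L 6.63 R 9.61 total 8.12 mm  bilateral True
```

The painted 6.4 / 9.9 mm rings come back as 6.63 / 9.61 mm under 10%
contrast noise (the right ring is slightly compressed because the
default 5 mm corridor caps measurable width at 10 mm — pass a larger
`half_width` to lift it); the burden (~21%) is simply the area of two
full annuli of that width on this chamber; both rings are gap-free, so
the bilateral encirclement is complete.

The same stages are scriptable from the shell — `lascar synth
volume|shell|cohort`, `lascar shell`, `lascar burden`, `lascar
encircle`, `lascar compare`, and `lascar run --config <json|yaml>` for
the full synthetic cohort pipeline with a provenance manifest. Run
`lascar --help` for the options.

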