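# atriarecon

Left-atrial (LA) volumetry and function from a handful of arbitrarily
oriented 2D cine contours — the data produced by a single breath-hold
multi-slice acquisition of two long-axis and three short-axis views.

LA dilatation accompanies most chronic pressure- and volume-overload
conditions, and 3D-measured LA volumes out-predict diameters and
single-plane areas. The standard alternatives either need many
breath-holds (full multi-slice coverage) or a geometric model (bi-plane
area-length), which makes them sensitive to how the imaging planes were
planned. This package implements the non-model-based alternative: treat
each slice's contour as the zero set of an inside/outside indicator
(+1 inside, −1 outside), interpolate the indicator into 3D, extract the
zero level set as a watertight triangle mesh, and take the mesh volume

&nbsp;&nbsp;&nbsp;&nbsp;*V* = |Σ_faces **a** · (**b** × **c**)| / 6,

per cardiac phase, yielding a full LA time–volume curve *V(t)* and the
derived reservoir/conduit/booster indices. The model-based comparator is
included:

&nbsp;&nbsp;&nbsp;&nbsp;*V*<sub>AL</sub> = 0.848 · *A*₄ch · *A*₂ch / ((*L*₄ch + *L*₂ch)/2),

with each length measured from the mitral valve mid-position to the
opposite wall. For whom: CMR physicists and cardiac image-analysis
developers who need orientation-robust chamber volumetry, a contour
exchange format, synthetic LA phantoms with exact reference volumes, and
the agreement statistics (Bland-Altman, paired t, 2×2 repeated-measures
ANOVA, endocardial border sharpness) used to validate such methods.

## Worked example

```python
from atriarecon import (
    make_phantom, SliceStrategy, generate_strategy,
    reconstruct_frame, ReconstructionConfig, indices_from_volumes,
)

# a 55 ml spherical phantom, sliced 2 long-axis + 3 short-axis with
# 0.5 mm contour noise, reconstructed on a 1 mm grid
ph = make_phantom("sphere", 55.0)
ds = generate_strategy(ph, SliceStrategy("D1"), noise_mm=0.5, seed=7)
planes, contours = ds.frame_set(0)
res = reconstruct_frame(planes, contours, ReconstructionConfig(grid_mm=1.0))
print(f"reconstructed volume: {res.volume_ml:.2f} ml "
      f"(reference {ds.ground_truth['volume_ml']:.1f} ml)")

# LA function indices from landmark volumes (ml)
idx = indices_from_volumes(v_max=82.6, v_min=43.6, v_pre_a=64.4, lv_sv=104.0)
print(f"total emptying {idx.total_emptying:.1f} ml, EF {idx.total_ef:.1f} %, "
      f"passive {idx.passive_emptying:.1f} ml, "
      f"active fraction {idx.active_fraction:.0f} %")
```

prints

```
reconstructed volume: 54.97 ml (reference 55.0 ml)
total emptying 39.0 ml, EF 47.2 %, passive 18.2 ml, active fraction 53 %
```

The 54.97 ml is the mesh volume enclosed by the interpolated indicator's
zero surface — within 0.1 % of truth despite the added contour noise. The
index line reproduces a published patient report: 39.0 ml total conduit
volume, 47.2 % total LA ejection fraction, and a 53 % active (booster)
share of emptying.

A command-line interface mirrors the library:

```bash
atriarecon phantom --family sphere --volume-ml 55 --strategy D1 --out contours.json
atriarecon reconstruct --contours contours.json --grid-mm 1.0 --curve-out curve.csv
atriarecon indices --curve curve.csv --lv-sv 104
atriarecon validate --out results/
```

`validate` runs the full five-shape × three-strategy suite and writes the
per-case table, agreement summaries and the alignment × method ANOVA.

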