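# octenamel

Quantitative analysis of dental enamel from optical coherence tomography
(OCT) B-scan stacks: enamel-thickness measurement from peak-flattened
A-scan depth profiles, depth-binned total-intensity fluctuation analysis,
and threshold-window volumetry of the enamel residual. A synthetic
tooth-phantom generator with known ground truth makes every stage testable
without clinical images.

## Who this is for

Demineralization — mineral loss from enamel — precedes caries and lowers
both enamel thickness and its optical backscatter. OCT resolves the enamel
band, the dentino-enamel junction (DEJ) and dentin at micrometre scale, so
early caries progression can be quantified from cross-sectional intensity
images long before radiography can see it. This package is for researchers
working with reconstructed 8-bit intensity B-scans (multi-page TIFF or raw
binary + JSON sidecar) who need reproducible thickness, depth-intensity and
volume numbers rather than qualitative images.

## The three quantities

**Enamel thickness.** A window of W = 15 adjacent A-scan lines is cropped
from a B-scan. The global maximum of each line locates the air–enamel
surface; each line is shifted by an integer row count so all surface peaks
align (flattening, reference = median peak index); the aligned lines are
summed, averaged and max-normalized into one depth profile. Thickness is
the surface-peak-to-DEJ-peak distance converted to physical length:

    thickness = (dej_index − surface_index) · ly / n

with axial pixel pitch ly = 12 μm and tooth refractive index n = 1.63.
Reduction vs a healthy reference is `100 · (1 − t/t_ref)` %.

**Depth-binned intensity.** Total pixel intensity is summed in half-open
250 μm depth bins over the visible 1 mm range, anchored at the tooth
surface, per frame and per stack. Demineralized tissue scatters less, so
every bin drops as caries progresses.

**Enamel-residual volumetry.** Inside a fixed image window, pixels with
intensity in the inclusive threshold range 45 ≤ I ≤ 255 are counted per
frame (N_i). With pixel area A_pix = lx·ly and frame spacing lz
(12 × 12 × 7 μm by default),

    V_tot = Σ_i N_i · lx · ly · lz

reported in mm³.

## Worked example

```python
from octenamel import (generate_volume, estimate_stack_thickness,
                       percent_reduction, residual_volume,
                       summarize_volume_bins, phantom_for_condition)

results = {}
for kind in ("healthy", "partial"):
    vol, gt = generate_volume(phantom_for_condition(kind, seed=1))
    thick = estimate_stack_thickness(vol, start_col=24)
    bins = summarize_volume_bins(
        vol, surface_rows=[int(gt.enamel_top_row[0])] * vol.count)
    volm = residual_volume(vol)
    results[kind] = thick.thickness_um
    print(f"{kind:8s} thickness {thick.thickness_um:7.2f} um   "
          f"V_tot {volm.volume_mm3:.4f} mm^3   "
          f"bins {['%.0f' % b for b in bins.per_frame_average]}")
print(f"enamel reduction vs healthy: "
      f"{percent_reduction(results['partial'], results['healthy'])}%")
```

prints (8-frame phantoms, 160 × 64 px):

```
healthy  thickness  250.31 um   V_tot 0.0414 mm^3   bins ['280977', '201958', '90395', '25473']
partial  thickness  154.60 um   V_tot 0.0257 mm^3   bins ['212772', '98490', '43066', '17400']
enamel reduction vs healthy: 38.2%
```

The healthy phantom carries 250 μm of enamel and is recovered at 250.31 μm
(one axial pixel is ly/n ≈ 7.4 μm). The partially demineralized phantom
(backscatter × 0.7, 100 μm erosion, true residual 150 μm) reads 154.6 μm, a
38.2% reduction; its residual volume and every 250 μm intensity bin sit
below the healthy values, the signature of progressing demineralization.

The same stages are available as a CLI:

```bash
octenamel phantom --kind healthy --out stack.tiff --truth truth.json --seed 1
octenamel profile --stack stack.tiff --frame 4 --col 24 --out profile.csv
octenamel bins --stack stack.tiff --edges 0,250,500,750,1000 --out bins.csv
octenamel volumetry --stack stack.tiff --thresh 45:255 --out vol.json
octenamel analyze --config run.yaml
```

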