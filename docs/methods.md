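# Methods

This note documents the models and procedures implemented in `octenamel`,
the parameter choices that matter, and what the synthetic phantoms do and
do not establish about real clinical data.

## Coordinate and depth conventions

A B-scan is stored with rows along the axial (depth) direction, row 0 on
the tissue-surface side, and columns along the lateral sweep; a stack adds
the slow-scan (frame) axis with spacing `lz`. Raw data keeps its axial
axis in optical-path pixels. Physical depth enters only in measurement
operations: a pixel `k` rows below the surface row sits at physical depth
`k · ly / n`, with axial pitch `ly = 12 μm` and tooth refractive index
`n = 1.63` by default (both overridable in `VoxelGeometry`). The standard
hard-tissue refractive index is used even though the instrument resolution
pair (6 μm in air, 3.61 μm in tissue) would imply n ≈ 1.66; the ~2%
difference is far below the speckle-driven measurement spread, and `n` is
a free parameter for users with calibrated instruments.

Indexing is 0-based throughout; rounding to the 8-bit scale is half-up,
which is deterministic across platforms; intensity normalization maps
`[min, max]` affinely onto `[0, 255]`.

## A-scan depth profile and enamel thickness

The profile procedure takes `W = 15` adjacent A-scan lines, finds each
line's global intensity maximum (ties break to the shallowest row; the
bright air–enamel Fresnel reflection makes this a surface detector),
shifts each line by an integer row count so all peaks align, then averages
and max-normalizes. Design choices:

- **Flattening reference = median of the W peak indices** (lower median
  for even W). A single misdetected line — a speckle spike deeper in the
  enamel — then cannot drag the reference away from the surface.
- **Integer shifts with zero fill, no interpolation.** Pixel intensities
  are preserved exactly for the downstream total-intensity analysis;
  sub-pixel alignment would resample and smear them.

Enamel thickness is read off the averaged profile as the distance from the
surface peak to the dentino-enamel junction (DEJ) peak, times `ly / n`.
How the boundary is identified is this package's own operational
definition (no standard exists for reading thickness off such profiles):
the profile of layered dental tissue shows the surface peak, an
exponential decay through enamel, a shallow valley at the enamel bottom,
and a secondary rise where the more reflective DEJ band begins. The DEJ is
located on a lightly smoothed copy (moving average, half-width 1, i.e.
window 3) as the **first local maximum beyond the surface with topographic
prominence ≥ 0.05 of the surface value**, then refined to the raw-profile
argmax within ±2 rows so smoothing cannot bias the boundary position.

Two numerical choices deserve justification. The smoothing window is
deliberately narrow: in heavily demineralized teeth the residual enamel is
thin (~100 μm ≈ 14 rows) and its valley–DEJ step spans only a few rows; a
wider window averages the step away. The prominence floor of 0.05 sits
roughly three standard deviations above the residual speckle amplitude of
a 15-line-averaged, window-3-smoothed profile (per-pixel speckle contrast
~0.18 shrinks to ~0.02 after averaging), while the weakest anatomical DEJ
step in the phantom model (thin enamel, where attenuation has removed
least signal) still reaches ~0.06. An earlier valley-depth rule — require
a valley below half the surface value — was rejected: with a realistic
enamel attenuation of 0.004 μm⁻¹, 100 μm of enamel only decays to ~0.67 of
its entry intensity, so the rule structurally fails exactly where the
method matters most.

A profile whose pre-normalization maximum is below 10 (of 255) is flagged
as having no detectable surface; a profile with no qualifying DEJ peak
returns an undefined thickness with a diagnostic rather than a number —
on strongly carious tissue the junction genuinely disappears into noise,
and reporting that honestly is preferable to guessing.

`estimate_stack_thickness` reduces a stack to one number as the median of
the per-frame estimates. Frames are independent speckle realizations of
the same anatomy, so this is a plain repeated-measurements reduction; the
per-frame operation is unchanged.

## Depth-binned total intensity

Pixel intensities are summed in half-open 250 μm bins over [0, 1000) μm of
physical depth. Depth 0 is anchored at each frame's tooth surface (the
median of per-column argmax rows, or a user-supplied row), not at image
row 0: B-scans carry an air gap above the tooth, and image-top anchoring
would dilute the first bin with background. Bin totals are computed in
64-bit integer arithmetic for 8-bit input, so they conserve the pixel sum
over the analyzed range exactly. Absolute arbitrary-unit magnitudes are
instrument-specific and not recoverable; only orderings, conservation and
a configurable reporting scale are supported.

## Enamel-residual volumetry

Within one rectangular image window applied identically to every frame,
pixels with intensity in the inclusive range `45 ≤ I ≤ 255` are counted
(N_i per frame) and converted to volume as
`V_tot = Σ N_i · lx · ly · lz`, in mm³. Both bounds are inclusive, as the
threshold is conventionally written; no morphological cleanup is applied —
raw qualifying pixels are what the formula counts. The per-voxel volume
(1008 μm³ at the default 12 × 12 × 7 μm geometry) can be overridden for
instruments with a different effective calibration. A helper,
`implied_voxel_volume_um3`, divides a reported volume by its reported
count — a consistency check for published volumetry tables, where the
implied constant should agree across rows acquired under one setting.
Applied to the reference volumetry table this package accompanies, all
five rows imply a common ≈1348 μm³ constant, which does not match the
nominal 1008 μm³ product; the formula is implemented literally and the
discrepancy is surfaced, not silently recalibrated.

## The tooth phantom

The generator emulates the features of layered tooth B-scans that the
analyses depend on, with exact ground truth:

- **Layers** (healthy default, physical depths): enamel [0, 250) μm at
  base reflectivity 200 with attenuation 0.004 μm⁻¹; a thin bright DEJ
  band [250, 290) μm at 150; dentin [290, 800) μm at 110 with 0.003 μm⁻¹.
  Within a layer, intensity decays exponentially from the layer top
  (Beer–Lambert behaviour). The DEJ band sits directly beneath the enamel
  because that is where the junction is anatomically — and it is what
  gives the depth profile its secondary peak. Reflectivities are chosen to
  mimic typical displayed contrast (bright enamel, distinct junction,
  dimmer dentin); they are configuration, not calibration.
- **Surface line**: the air–enamel interface contributes a near-specular
  reflection, rendered as a 250-reflectivity line at the first tissue row
  of each column. This is the feature that makes per-A-scan peak search a
  reliable surface detector on real images; omitting it would make the
  phantom unrealistically hostile to the method.
- **Speckle**: multiplicative gamma noise, mean 1, shape 30 (contrast
  ≈ 0.18), applied before half-up quantization to 8 bits. The analyzed
  images are display-scaled, log-compressed B-scans, whose speckle
  contrast is far below the unit contrast of raw linear single-look
  speckle; shape 30 reproduces that displayed-image regime.
- **Lesions** scale backscatter by `reflectivity_scale ≤ 1` over a lateral
  span and depth extent, and erode the enamel surface downward by
  `enamel_erosion_um` (material removed from the top; deeper layers keep
  their absolute depths). Presets: `partial` (scale 0.7, erosion 100 μm →
  residual 150 μm) and `carious` (scale 0.4, erosion 150 μm → residual
  100 μm), mirroring the study conditions the package accompanies.
- **Determinism**: every frame's RNG stream is keyed by
  `(seed, frame_index)`, so stacks are bit-identical across runs and
  platforms and independent of generation order.

Ground truth (per-column enamel top/bottom rows, geometric voxel count,
analytic volume) is computed with the same depth bookkeeping as the
intensity model and can be written as a JSON sidecar.

What the phantom does **not** model: wave-optics or Monte-Carlo photon
transport, polarization, refraction at the tilted surface, depth-dependent
speckle decorrelation, detector noise floors, motion artefacts, and the
irregular 3D topography of real caries (pits, fissures, cracks). Passing
the phantom-based tests therefore demonstrates that the implementation
measures what it claims on data satisfying its model assumptions — not
that the clinical accuracy figures transfer to real teeth.

## Problem sizes and tolerances in the test suite

The recovery studies use 160 × 40–64 px stacks of 1–8 frames: large enough
to hold the full 1 mm layer stack at the default geometry (≈ 136 optical
rows) plus an air gap, small enough that 100-phantom sweeps remain
interactive. Thickness recovery over 100 speckled phantoms (true thickness
uniform in 100–300 μm) is required to reach a median absolute error within
2 physical pixels (≈ 14.7 μm); observed medians are ≈ 5–7 μm. Noise-free
slab volumes must be recovered exactly (they are, by construction of the
half-open row mapping); speckled slab volumes within 5% (observed: exact,
since the 45-threshold sits far below the speckled enamel distribution and
far above the background). Percent reductions are reported to one decimal,
half-up; the worked-example pair (150.30, 255.45) computes to 41.16 → 41.2,
one rounding step away from the published 41.1, so that comparison carries
a ±0.1 point tolerance.

## Known limitations

- The DEJ rule assumes a junction band brighter than the attenuated enamel
  bottom. On profiles where demineralization has destroyed that contrast
  the thickness is (correctly) undefined; the `carious` preset phantom
  exercises this path.
- Depth conversion uses a single refractive index for the whole A-scan;
  real depth scales change slightly across enamel, DEJ and dentin.
- The image window is one rectangle per stack; per-frame adaptive windows
  are out of scope.
- Source-power compensation applies a user-supplied factor within ±5%; no
  estimation of the factor from the data is attempted.
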