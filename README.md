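# gridsol

**Gridded soil-property layers → crop-model-ready DSSAT `*.SOL` soil
profiles.**

Running a process-based crop model (DSSAT) over a region or continent
needs a soil profile for every grid cell, in the model's own fixed-width
`*.SOL` format, with parameters — hydraulic limits, root growth factor,
surface properties — that gridded soil databases do not provide
directly. `gridsol` closes that gap for anyone building gridded crop
simulation frameworks: it turns per-depth-layer rasters of sand/silt/
clay, organic carbon, bulk density, pH and CEC into complete, per-country
soil input files.

## What it computes

For each coarse output cell (default 5 arc-min, aggregated from
30 arc-sec pixels by arithmetic block averaging):

- **Hydraulic properties** from the Saxton–Rawls (2006) pedo-transfer
  regressions in texture (S, C as fractions) and organic matter
  (OM % = 2 × OC %):
  θ₁₅₀₀ (wilting point, SLLL), θ₃₃ (field capacity, SDUL), θS
  (saturation, SSAT) and KS = 1930 (θS − θ₃₃)^(3−λ) with
  λ = ln(θ₃₃/θ₁₅₀₀)/ln(1500/33) (SSKS, emitted in cm h⁻¹).
- **Generic-profile classification**: texture (clay/loam/sand) ×
  fertility (topsoil organic carbon) × rooting depth (available water
  content of the top metre, AWC = 1000 Σ(SDUL − SLLL)Δz mm) select one
  of the 27 generic profiles `HC_GEN0001`…`HC_GEN0027`, whose template
  supplies the surface parameters, root growth factor (SRGF) and total
  nitrogen (SLNI).
- **Depth remapping** of the template's seven horizons onto the six
  standard output layers (0–5, 5–15, 15–30, 30–60, 60–100, 100–200 cm)
  by fixed weighted averages.
- **Byte-stable `*.SOL` emission**, one file per country (ISO alpha-2
  filename), plus a JSON run report.

See `docs/methods.md` for the full equations, classification rules,
clamping policy and design decisions.

## Worked example

The package ships a seeded synthetic-input generator, so the whole chain
runs without any download:

```bash
gridsol fixtures make --out demo/stack --seed 1   # 80x80 grids + 27 templates
gridsol build --inputs demo/stack --out demo/out
```

The build report (printed and written to `demo/out/run_report.json`):

```json
{
 "cells_total": 64,
 "cells_complete": 59,
 "cells_skipped": 5,
 "cells_clamped": 4,
 "profiles_per_country": {"AA": 29, "AB": 30},
 "generic_class_counts": {"HC_GEN0005": 4, "HC_GEN0010": 9, "HC_GEN0011": 16, "...": "..."},
 "ptf_stage": "fine"
}
```

64 coarse cells were attempted; 5 fell below the 50 % valid-pixel
threshold inside the synthetic coastline and were skipped; 4 contained
fine pixels whose regression output had to be clamped to the validity
domain (flagged, never silent). The 59 complete profiles are split
between the two mask countries `AA.SOL` and `AB.SOL`. Inspecting one
profile:

```bash
gridsol inspect demo/out/AA.SOL --profile AA00000003
```

```text
*AA00000003  GRIDSOL     L     200  loam/low/deep from HC_GEN0016
@SITE        COUNTRY          LAT     LONG SCS FAMILY
 Grid        AA             -4.375   30.292 HC_GEN0016
@ SCOM  SALB  SLU1  SLDR  SLRO  SLNF  SLPF  SMHB  SMPX  SMKE
    BN  0.12   9.0  0.50  75.0  1.00  1.00 IB001 IB001 IB001
@  SLB  SLMH  SLLL  SDUL  SSAT  SRGF  SSKS  SBDM  SLOC  SLCL  SLSI  SLCF  SLNI  SLHW  SLHB  SCEC
     5     A 0.139 0.323 0.458 1.000  0.75  1.37  0.77  21.3  61.8   -99 0.048   6.3   -99  19.2
    15     A 0.143 0.323 0.448 0.952  0.59  1.40  0.58  22.5  60.7   -99 0.044   6.2   -99  18.6
```

This cell (centre 4.375°S, 30.292°E) classified as loam texture, low
fertility, deep rooting, so it inherits template `HC_GEN0016`'s surface
line and SRGF profile; its wilting point 0.139 and field capacity
0.323 cm³ cm⁻³ come from the retention regressions applied to the
cell's own texture (clay 21.3 %, silt 61.8 %) and organic carbon
(0.77 %); −99 marks fields the crop model fills with defaults.
`gridsol validate --standard-layers demo/out/AA.SOL` re-parses and
checks every profile.

The same works from Python:

```python
from gridsol import FixtureSpec, generate_input_stack, run_build
stack = generate_input_stack(FixtureSpec(shape=(80, 80), seed=1))
report = run_build(stack, "demo/out")
```

Real rasters go in as plain-text ESRI ASCII grids named
`{sand,silt,clay,oc,bd,ph,cec}_l{1..6}.asc` (plus an optional
`country_mask.asc` / `country_codes.json`), or directly as numpy arrays
through `InputStack`. Real generic-template `*.SOL` files can replace
the packaged synthetic defaults via the `template_dir` config key.

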