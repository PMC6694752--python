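# Methods

`gridsol` translates gridded soil-property layers into crop-model-ready
soil profile files (DSSAT `*.SOL`). This note documents the models and
procedures it implements, the parameters that matter, and the choices
made where the design was genuinely open.

## Pipeline overview

For every coarse output cell the pipeline:

1. aggregates the fine-resolution property grids (sand, silt, clay %,
   organic carbon g kg⁻¹, bulk density kg m⁻³, pH, CEC cmol kg⁻¹, each
   on six standard depth intervals 0–5, 5–15, 15–30, 30–60, 60–100,
   100–200 cm) by arithmetic block averaging;
2. derives soil hydraulic properties (wilting point θ₁₅₀₀ / SLLL, field
   capacity θ₃₃ / SDUL, saturation θS / SSAT, saturated conductivity
   KS / SSKS) from texture and organic matter with the Saxton–Rawls
   (2006) pedo-transfer regressions;
3. classifies the cell into one of 27 generic profiles by texture ×
   fertility × rooting depth and inherits the parameters the grids
   cannot supply (surface parameters, root growth factor SRGF, total
   nitrogen SLNI) from the matching template;
4. remaps the template's seven horizons onto the six output layers with
   fixed weighted averages;
5. writes one fixed-width `*.SOL` file per country (ISO 3166-1 alpha-2
   filename), plus a machine-readable run report.

## Pedo-transfer functions

The retention regressions predict volumetric water contents from sand
(S) and clay (C) as **decimal fractions** and organic matter (OM) in
mass %:

    θ1500t = −0.024 S + 0.487 C + 0.006 OM + 0.005 S·OM − 0.013 C·OM + 0.068 S·C + 0.031
    θ1500  = θ1500t + (0.14 θ1500t − 0.02)
    θ33t   = −0.251 S + 0.195 C + 0.011 OM + 0.006 S·OM − 0.027 C·OM + 0.452 S·C + 0.299
    θ33    = θ33t + (1.283 θ33t² − 0.374 θ33t − 0.015)
    θ(S−33)t = 0.278 S + 0.034 C + 0.022 OM − 0.018 S·OM − 0.027 C·OM − 0.584 S·C + 0.078
    θ(S−33)  = θ(S−33)t + (0.636 θ(S−33)t − 0.107)
    θS     = θ33 + θ(S−33) − 0.097 S + 0.043
    B      = [ln 1500 − ln 33] / [ln θ33 − ln θ1500],  λ = 1/B
    KS     = 1930 (θS − θ33)^(3−λ)   [mm h⁻¹]

Although the regression table labels S and C "%w", the printed
coefficients are those of the source publication, which takes sand and
clay as fractions and OM in percent; that is the only convention under
which the equations yield physical water contents, and it is enforced
by a unit-sanity assertion (S or C > 1.5 at the equation boundary is
rejected as percent-scale input). Organic carbon arrives in g kg⁻¹ and
is converted once at ingest: OC% = OC/10, OM% = 2 × OC% (the factor 2
is used deliberately; it is more accurate for converting OC to OM than
the conventional van-Bemmelen 1.724). Bulk density is passed through to
the output (kg m⁻³ → g cm⁻³) and does not density-adjust the PTFs. KS
is computed in mm h⁻¹ and emitted as SSKS in cm h⁻¹ (exactly KS/10).
The polynomials are evaluated in double precision, term by term in the
printed order, so they match an independent literal transcription to
better than 1e−12 relative.

**Validity domain and clamping.** The regressions were fitted on
agricultural soils; extreme texture/OM corners can produce negative or
inverted water contents. Outputs are constrained to θ₁₅₀₀ ≥ 0.01,
θ₃₃ − θ₁₅₀₀ ≥ 0.01, θS ≤ 0.60 and θS − θ₃₃ ≥ 0.002 by clamping to the
nearest bound. Every clamp sets a per-layer flag bit that is carried
into the run report — out-of-domain points are never emitted silently.
The 0.002 saturation spread floor is chosen at twice the 3-decimal
output precision so clamped layers remain strictly ordered after
rounding. No cap below total porosity is applied beyond θS ≤ 0.60.

## Generic-profile classification

Each cell is keyed by three classes; the 27 (texture, fertility, depth)
triples map bijectively onto `HC_GEN0001`…`HC_GEN0027` in the canonical
order clay < loam < sand, high < medium < low, deep < medium < shallow
(clay/high/deep = 0001, loam/high/deep = 0010, sand/low/shallow = 0027).

- **Texture** (from 0–30 cm thickness-weighted means): CLAY if
  clay ≥ 40 %; SAND if sand ≥ 65 % and clay < 18 %; else LOAM. The
  three-way collapse of the texture triangle is not prescribed anywhere
  authoritative; these thresholds are this package's defaults and are
  config keys (`texture_rule`).
- **Fertility** (topsoil organic carbon %, thickness-weighted over
  0–30 cm): HIGH ≥ 1.2 %, MEDIUM ∈ [0.7, 1.2), LOW < 0.7 %. Again a
  config default (`fertility_thresholds_pct`), not an inherited fact.
- **Rooting depth** from the available water content of the top metre,
  AWC = 1000 Σ (SDUL − SLLL) Δz (mm, layers clipped to 0–1 m so the
  100–200 cm layer contributes nothing), looked up per texture:
  CLAY deep > 150, medium (100, 150], shallow ≤ 100;
  LOAM deep > 150, medium (75, 150], shallow ≤ 75;
  SAND deep > 125, medium (75, 125], shallow ≤ 75 (all mm m⁻¹;
  intervals lower-exclusive/upper-inclusive). The published lookup
  table cannot be read unambiguously, so this reconstruction was fixed
  by three constraints: the worked example (clay with AWC 140 mm is
  *medium*), the HWSD class edges (150/125/100/75/50/15), and
  monotonicity of depth class in AWC at fixed texture. It is fully
  overridable via `depth_lookup_mm`.

## Templates

Template profiles supply the ten surface parameters (SCOM…SMKE), SRGF
and SLNI on seven horizons (0–10, 10–30, 30–60, 60–90, 90–120, 120–150,
150–180 cm). Real template `*.SOL` files (e.g. the published HC27 set)
can be supplied via `template_dir` and are validated hard: SRGF ∈ [0,1],
non-increasing with depth, and zero below the class rootable depth
(deep 180 cm, medium 120 cm, shallow 60 cm).

When no directory is given, a packaged **synthetic** default set is
generated by rule: SRGF = 1 for horizons with midpoint ≤ 15 cm, then
exp(−0.02 (mid − 15)), truncated to zero below the rootable depth;
topsoil total N 0.15/0.10/0.05 % for high/medium/low fertility with an
exp(−0.01 z) depth decay; surface parameters take crop-model
conventional per-texture values (albedo 0.13/0.12/0.15, drainage rate
0.30/0.50/0.75 day⁻¹, runoff curve number 85/75/65 for clay/loam/sand).
These defaults are stand-ins, not reproductions, of the published
generic profiles; the supported path for fidelity is supplying the real
files.

## Layer remapping

Template horizons are remapped to the six output layers with fixed
weights: 0–5 ← h1; 5–15 ← ½h1 + ½h2; 15–30 ← h2; 30–60 ← h3;
60–100 ← 0.75 h4 + 0.25 h5; 100–200 ← 0.2 h5 + 0.3 h6 + 0.5 h7. The
5–15 cm weights are the scheme's stated 0.5/0.5 rather than exact
overlap fractions. The same scheme is applied to SLNI as an extension
of the SRGF rule. Weights sum to one per output layer, so the map is
linear, conserves constants and preserves non-increasing inputs; SRGF
outputs are additionally clipped to [0, 1].

## Aggregation and gridding

Fine pixels (default 30 arc-seconds) are averaged arithmetically into
coarse cells (default 5 arc-minutes, 10 × 10 blocks); the coarse edge
must be an integer multiple of the fine edge. A coarse cell is emitted
only if at least `min_valid_fraction` (default 0.5) of its block is
valid; the threshold and the treatment of partial coastline blocks are
this package's decisions. Because sand, silt and clay are averaged
independently, their means are re-closed to sum to exactly 100 % (silt
as the closure remainder); the pre-closure deviation is reported.

`ptf_stage` controls whether the PTFs run on fine pixels with the
results block-averaged (`fine`, the default) or on coarse-cell mean
properties (`coarse`). The regressions are nonlinear, so the two orders
differ; the default follows the convention of deriving hydraulics at
the native resolution of the source grids. Block averaging can only
shrink spatial variance, which is the mechanism behind the narrower
distributions coarse aggregates show relative to point data.

Cell identity is the coarse-cell center (WGS84 degrees, north-up,
row-major); profile ids are the 2-letter country code plus an 8-digit
base-36 encoding of the row-major cell index (10 characters, unique and
deterministic). Profiles are partitioned by a categorical country mask
on the coarse grid (cell-center rule); cells outside the mask go to the
catch-all file (`catchall_iso`, default `ZZ.SOL`). Missing mask ⇒ one
combined file with a warning. The pipeline contains no randomness;
reruns are byte-identical.

## *.SOL emission

Per layer the output carries: PTF-derived SLLL/SDUL/SSAT/SSKS;
grid-derived SBDM, SLOC, SLCL, SLSI, SLHW, SCEC; template-derived SRGF
and SLNI; SLCF and SLHB fixed at −99 (model-default sentinel); master
horizons fixed at A, A, AB, BA, B, BC. All numeric fields are
right-aligned in 6-character columns with fixed precisions (3 decimals
for water contents, SRGF and SLNI; 2 for SSKS, SBDM, SLOC, albedo and
rates; 1 for the rest), ASCII with LF endings and no trailing
whitespace; "bit-exact" output is defined by the single format
descriptor table in `gridsol.sol`. The reader is tolerant
(whitespace-tokenised, unknown trailing columns preserved) with a
strict fixed-column mode used to verify the writer; write → read
recovers every field at its printed precision. Columns beyond SCEC
(e.g. SADC) are not written.

## Synthetic data generator

Tests and the acceptance run use seeded synthetic inputs, not
downloads. Spatially correlated fields are Gaussian-smoothed white
noise (correlation length = kernel σ, default 8 px) rescaled to
realistic ranges: sand 40 ± 22 %, clay 24 ± 13 % (closed exactly
against silt on a binary 2⁻²⁰ grid so the per-pixel sum is exactly
100), organic carbon lognormal around 13 g kg⁻¹ topsoil decaying with
depth, bulk density 1350 ± 140 kg m⁻³ clipped to [900, 1800], pH
6.4 ± 0.7 clipped to [4, 9], CEC lognormal around 15 cmol kg⁻¹. A
smoothed-noise threshold carves a synthetic coastline of nodata pixels,
identical across properties and layers, at the requested fraction. The
`three-zone` preset replaces the texture fields with three vertical
bands built to classify as clay / loam / sand, used to test class
recovery end to end. The default country mask splits the coarse grid
into two vertical-band countries (`AA`, `AB`).

The generator reproduces the *structure* the pipeline assumes
(closure, ranges, spatial correlation, consistent nodata), not the true
spatial statistics of any real soil database; passing tests demonstrate
correctness of the processing chain, not accuracy of the synthetic
fields as soil maps.

## Problem sizes and numerical choices

The default test/acceptance grids are 80 × 80 fine pixels (8 × 8 coarse
cells) and 60 × 90 for the three-zone preset — small enough to run the
whole chain in seconds while exercising every code path (nodata
handling, clamping, partitioning). Equation fidelity is checked over
the full 1 %-step texture simplex crossed with OM 0–8 % (46 359
points). Classification interval edges are lower-exclusive /
upper-inclusive throughout; texture closure tolerance on input is
0.5 percentage points.

## Known limitations

- The default templates are synthetic stand-ins; results inheriting
  SRGF/SLNI/surface parameters are only as faithful as the templates
  supplied.
- No reprojection: all inputs must share one geographic grid. No
  parallel execution.
- The PTFs are regression fits to a temperate agricultural soil
  database; very sandy, very clayey or highly organic soils trigger the
  clamping policy, and tropical-soil behaviour inherits the source
  regressions' biases.
- Uncertainty quantification (input error propagation, PTF sensitivity)
  is out of scope.
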