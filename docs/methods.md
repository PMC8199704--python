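# Methods

## Scope and data flow

`secr` evaluates radiation-induced second-cancer risk for a
radiotherapy plan from a 3D dose distribution and organ contours. The
chain is: dose grid → resample to reporting resolution → rasterize
contours → differential DVH → organ equivalent dose (OED) → excess
relative/absolute risk (ERR/EAR) over attained age → lifetime
attributable risk (LAR) per exposure age, compared against the
cumulative baseline incidence. Two side products feed an external
Monte Carlo dose engine: the HU→material stoichiometric calibration and
the per-segment VMAT delivery macro. The Monte Carlo transport itself
is out of scope; any RTDOSE-format dose grid is accepted.

## Stoichiometric calibration

The bundled table divides CT numbers from −1050 to 3095 HU into 27
reference tissues (air, lung, adipose/soft-tissue series, a graded
skeletal series, implant metals), each a 17-element weight-fraction
vector summing to 100 %. Queries between nodes interpolate each element
linearly and renormalize the result to exactly 100 %; queries at a node
return the stored row verbatim; queries outside the range clamp to the
nearest end node with a warning (scanner floors of −1024 HU and metal
artifacts would otherwise be unusable). The three highest-HU rows are
implant materials; their published element assignments are ambiguous,
so they are bundled as single-element metals (Ti at 1640 HU, Cu at
2923 HU, Ag at 3095 HU) — replace the CSV for a site-specific implant
model. Mass density is a separate piecewise-linear HU curve; the
bundled values follow the Schneider-style stoichiometric calibration
literature (air 0.00121 g/cm³, water ≈ 1 near 0 HU, bone ramp to
~1.96 g/cm³ at 1500 HU, metal densities at the implant nodes) and
should be replaced by a scanner-specific fit for production use. The
material-database export bins the HU range into `ceil(range/width)`
half-open intervals, evaluating composition and density at bin centres,
in the text dialect of the GATE toolkit.

## Geometry conventions

Grids are axis-aligned in the DICOM patient coordinate system; arrays
are indexed `[z, y, x]` with 0-based indices and voxel-centre
semantics. Contours are closed planar polygons assigned to the nearest
grid slice (tolerance dz/2, farther contours dropped with a warning).
A voxel belongs to an organ iff its centre lies inside the slice's
polygons under the even-odd rule — multiple polygons combine by parity,
so holes subtract and vertex orientation is irrelevant; centres exactly
on an edge count as inside (a deterministic tie-break). Partial-voxel
weighting is deliberately not attempted: the mask convention is exact
and testable, and at 2 mm reporting resolution the surface voxels are a
small fraction of typical organ volumes. Dose resampling is trilinear
at target voxel centres with clamping to the nearest source voxel
outside the extent, preserving the origin and physical extent; the
default reporting spacing is 2 mm isotropic.

## DVH

The internal representation is the differential DVH: uniform half-open
bins `[k·w, (k+1)·w)` (last bin closed above so the maximum dose is
counted), volume per bin in cm³, total volume V = member-voxel count ×
voxel volume. The bin-centre dose stands in for D_i — unbiased when
dose is uniform within a bin — and the default width is 0.1 Gy,
configurable; reported risks should cite the width used. The cumulative
curve (volume receiving ≥ dose) is derived on demand; no further DVH
metrics are computed because the risk chain does not use them.

## Organ equivalent dose

Three dose-response shapes over the DVH:

- linear: `(1/V) Σ V_i D_i` — the mean dose; valid in the low-dose
  regime where risk is proportional to dose;
- plateau: `(1/V) Σ V_i (1 − e^{−δ D_i})/δ` — risk saturates at high
  dose because heavily irradiated cells are killed rather than
  transformed; this is the default for second-cancer work;
- bell: `(1/V) Σ V_i D_i e^{−α D_i}` — risk peaks and then falls. The
  bell shape is only named, not specified, in the application this
  package follows; the standard competing-cell-kill form above is used
  and documented as an assumption.

δ and α (Gy⁻¹) are organ-specific dose-response factors supplied per
organ in the run configuration (demo default δ = 0.09 Gy⁻¹, a
literature-typical magnitude). The plateau OED is bounded above by the
mean dose for every δ > 0 (concavity) and tends to it as δ → 0; both
properties are regression-tested.

## Excess risk and LAR

ERR and EAR share the BEIR VII functional form
`β_s · D · exp(γ e*) · (a/60)^η`, with `e* = (e−30)/10` for e < 30 and
0 from age 30 on (both branches agree at 30). β_s is sex-specific: for
ERR the excess relative risk per Gy; for EAR excess cases per 10⁴
person-years per Gy. The bundled registry transcribes the BEIR VII
report's preferred incidence models (ERR: γ = −0.3 per decade,
η = −1.4; EAR: γ = −0.41, η = 2.8, lung 5.2), with an "all other
solid" fallback used, with a warning, for sites without their own row.
Two simplifications are documented: breast and thyroid are given the
generic age-dependence form rather than the report's special models,
and thyroid has no EAR model in the report so it falls back to the
"other" EAR row. The registry is a CSV and fully user-replaceable.

LAR combines the survival-weighted lifetime sums

```
A = Σ_{a=e}^{a_max} ERR(D,s,e,a) · λ_I^C(a) · S(a)/S(e)
B = Σ_{a=e}^{a_max} EAR(D,s,e,a) · S(a)/S(e) · 10
```

as `LAR = A^0.7 · B^0.3` — the 0.7/0.3 weighted average on the
logarithmic scale. The ×10 places B on the per-100,000 scale of A
(λ is per 100,000 per year, EAR per 10⁴ person-years), so the
geometric combination is dimensionally consistent and LAR is reported
both per 100,000 and as a percent (per-100k = 1000 × percent). Sums
run in inclusive integer-year steps from exposure age e to the life
expectancy a_max = 90 by default; a latency offset is configurable and
defaults to 0. If either sum is zero the LAR is taken as 0 (limit
convention, logged). An arithmetic combination `0.7A + 0.3B` — the
weighting the BEIR VII report itself uses — is available behind the
`combine: arithmetic` config switch, default off, because the geometric
form is the one this package's application chain specifies. Both ERR
and EAR are linear in D and in β, so LAR is homogeneous of degree 1 in
dose; with a flat life table and age-constant inputs it is
nonincreasing in exposure age (fewer summed years). The cumulative
baseline comparator is `Σ_{a=e}^{a_max} λ_I^C(a) · S(a)/S(e)`.

Note on units: ERR is conventionally dimensionless (a relative
excess); when a maximum over attained age is reported alongside EAR in
per-100,000 tables it should be read as computed from the formula
above, not rescaled. The report table exposes `err_max` and `ear_max`
(maxima over attained age from the exposure age to a_max) as the
summary reduction; the full series is available from the library API.

## Synthetic study conditions

No patient data ships with the package. The generators emulate:

- **Phantom**: a 64×64×24 voxel, 2 mm isotropic grid; a soft-tissue
  body cylinder (radius 55 mm, 8 HU) in air (−1000 HU); a spherical
  "target_ball" (r = 10 mm, 80 HU) on the beam axis and a box
  "far_organ" (20×20×10 mm, 120 HU) far off-axis. Organ shapes are
  restricted to spheres and boxes so voxel membership has an analytic
  oracle; contours are emitted per slice (64-gon circles, rectangles).
  Generation is deterministic; the seed is reserved for future noise
  models.
- **Dose**: the closed form `D0·e^{−μ·depth}·e^{−r²/2σ²} + ε·D0` with
  D0 = 50 Gy (a typical VMAT prescription scale), σ = 8 mm,
  μ = 0.005 mm⁻¹, and leakage fraction ε = 0.02 — a uniform floor
  standing in for the out-of-field scatter and leakage a Monte Carlo
  engine captures. The far organ sits where the Gaussian has decayed
  below 10⁻⁸ of D0, so its dose is uniform at ε·D0 = 1.0 Gy and its
  DVH occupies a single bin: the configuration with a closed-form LAR
  used as the end-to-end audit (agreement to < 10⁻⁹ relative).
- **Demography**: Weibull survival S(a) = exp(−(a/80)⁵) (S(90) ≈ 0.17,
  a plausible high-income life table shape) and exponential baseline
  incidence λ(a) = 5·e^{0.05a} per 100,000 (≈ 450 per 100,000 per year
  at age 90, a realistic solid-cancer magnitude).

What passing these tests does *not* show: fidelity of real CT noise,
inhomogeneity corrections, deformable anatomy, realistic out-of-field
spectra, or the accuracy of any particular Monte Carlo engine — the
fixtures validate the analysis chain, not the dose calculation.

## Numerical choices and problem sizes

DVH bin width 0.1 Gy default; composition queries renormalize after
interpolation to preserve the 100 % invariant; RTDOSE writing scales
doses to the top of the 32-bit integer range (quantization ≈ 10⁻⁸ of
the maximum dose); macro files serialize floats with full `repr`
precision so export→parse is the identity; report CSVs are written
with fixed formatting so reruns are byte-identical. Property suites
use 8³ random grids (50 draws) and the demo phantom (98k voxels),
sizes chosen so the full suite runs in seconds while still exercising
every branch of the chain.

## Known limitations

- Only axis-aligned (identity-orientation) grids are supported.
- No DDREF or uncertainty propagation; point estimates only.
- Breast/thyroid coefficient simplifications as noted above.
- The implant rows of the calibration table are assumptions; replace
  them for dosimetry near hardware.
- Absolute clinical risk values depend on user-supplied life tables,
  baseline incidence and organ-specific δ; the bundled demo values are
  synthetic stand-ins.
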