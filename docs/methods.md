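# Methods

## Phantoms

Each phantom is a 128 × 128 × 600 lattice of cubic voxels with
0.3125 cm side (a 40 × 40 × 187.5 cm field of view). The body is an
elliptic column in three height regions (legs 0–0.48 H, torso
0.48–0.82 H, neck/head 0.82–1.0 H with relative cross-section areas
0.62 : 1.00 : 0.30). Internal organs are analytic primitives:
ellipsoids for the liver (anterior right upper abdomen), two lungs
(above the liver, across the diaphragm gap), two kidneys
(posterior-inferior), and a vertebral column (elliptic cylinder) plus
pelvic ellipsoid whose interiors form the marrow compartment inside a
cortical-bone shell.

Habitus is controlled by sex, height and BMI. Reference heights are
1.63 m (female) and 1.76 m (male). The torso ellipse area is solved
analytically so the voxelized total mass equals BMI × height² — the
extra mass of a high BMI goes into the subcutaneous soft-tissue shell —
with a width/depth aspect ratio of 1.55 that caps at the lattice width
(very high BMIs grow front-to-back instead). Organ volumes scale as
(BMI/BMI_ref)^0.25, so organs grow mildly and monotonically with BMI
while the shell absorbs most of the change. Reference organ masses are
liver 1.40/1.80 kg, both lungs 0.70/0.90 kg, both kidneys
0.30/0.34 kg (female/male), chosen at the ICRP-adult scale and such
that the thirteen presets' liver masses span 1.4–2.0 kg, inside the
1.0–2.4 kg band implied by the reference self-S-values via
S ≈ 10⁶·E/m. Densities (g/cm³): soft tissue 1.04, liver and kidney
1.05, inflated lung 0.26, cortical bone 1.40, marrow 1.03 — all
overridable per spec.

Rasterization priority (lungs, liver, kidneys, marrow, skeleton)
guarantees the four critical organs are pairwise disjoint; a primitive
poking outside the body contour or lattice raises a geometry error.
Construction is fully deterministic: identical specs give bit-identical
lattices, and summed organ masses equal total body mass exactly.

Deliberate non-goals: no NURBS surfaces, no anatomical realism beyond
organ mass and relative position, no motion. The fidelity target is
the dosimetry, which depends on masses and distances.

## Source model

Y-90 is treated as a pure beta emitter with mean energy 0.937 MeV and
physical half-life 64.1 h; microspheres are permanently trapped, so the
effective half-life equals the physical one. Decays are sampled
uniformly per unit liver volume (uniform over source voxels, then
uniform inside the voxel) with isotropic directions. The default is
monoenergetic transport at the mean energy; a tabulated-spectrum mode
exists for sensitivity work but is not used in the reproduction
pipeline. The default history count (10⁶) puts the liver-mean
statistical uncertainty below 0.1%.

## Electron transport

The Monte Carlo engine steps each electron along its emission direction
in straight sub-voxel steps of voxel_side/4, depositing
ΔE = S(E)·ρ·Δs into the containing voxel until the residual energy
reaches the 10 keV cutoff (then deposited locally) or the particle
leaves the lattice. Stopping powers are an embedded ICRU-37/ESTAR-style
tabulation for liquid water (10 keV–3 MeV), log-log PCHIP
interpolated; all tissues are water-equivalent in mass stopping power
and differ only by density. The CSDA range is the cumulative integral
of 1/S on a dense log grid; for 0.937 MeV in unit-density water it
evaluates to 0.4005 cm (total stopping power) — about 1.3 voxel sides —
and is frozen as a test constant against an independent quadrature.

Bremsstrahlung is never transported. In the default `tally` mode the
radiative share S_rad/S_tot of each step's energy loss (≈1.1% of the
emitted energy overall) is booked to the deposition ledger as unscored
radiative loss; `off` removes radiative losses entirely for
closed-form benchmarks. Consequently cross-organ S-values for organs
beyond the electron range (lungs, kidneys) are exactly zero, and the
reference table's photon-borne cross-organ entries can only be used as
upper bounds, never matched. The ledger
(emitted = deposited + escaped + unscored radiative) is checked to a
relative 10⁻⁶ on every run.

There is no multiple-scattering angular deflection, no energy
straggling and no delta rays. At 3.1 mm voxels against a ~4 mm range,
angular detour mainly softens the dose kernel's edge; organ-level
S-values on these phantoms are insensitive to it, which the closed-form
and engine-agreement checks quantify (self-S within 5% of 10⁶·E/m,
the gap fully explained by surface escape).

Statistical uncertainty uses the batch method: histories are split into
10 equal batches, and the per-voxel relative uncertainty is the
standard error of the batch doses over their mean (NaN sentinel where
the dose is zero). Organ-level uncertainties propagate the per-voxel
standard errors through the mass-weighted mean assuming independent
voxels; intra-track correlations make this a mild underestimate, which
is why engine-agreement tests use 3σ windows with an additive kernel
closure term.

For speed, tallying is restricted to the emission bounding box plus a
full CSDA-range margin evaluated at the lowest tissue density present;
no electron can cross that margin inside matter, so the restriction is
exact for the shipped body contours (it can be disabled via
`TransportOptions(crop=False)`).

The dose-point-kernel engine freezes a per-decay kernel (Monte Carlo,
point source in uniform water, radiative off, 1% energy-closure check)
and convolves it with the source distribution by FFT. It is exact on
homogeneous lattices and is used as the deterministic cross-check; in
heterogeneous regions the kernel reach is not rescaled, a documented
approximation.

## MIRD quantities

S(target ← source) is the mass-weighted mean target dose per decay
scaled to 10⁶ decays (1 MBq·s), in mGy/MBq·s. The absorbed fraction is
deposited target energy over emitted energy. Total dose is
D = S · Ã (mGy → Gy). Two cumulated-activity conventions are
implemented and must not be confused:

- `simple`: Ã = A₀ · T_eff. This is what reproduces the published
  total-dose figures from the packaged reference S-values (e.g.
  1.2085 × 10⁻⁴ mGy/MBq·s × 3000 MBq × 230 760 s = 83.7 Gy, printed
  as 84 Gy), and is therefore the default of the reproduction
  pipeline.
- `mird`: Ã = A₀ · T_eff / ln 2, the physically standard mean-life
  integral of an exponentially decaying permanent implant. It yields
  doses exactly 1.4427× higher.

The discrepancy is prominent and deliberate: the reference dose ranges
are only reachable under the `simple` convention, so that convention is
the reproduction default while `mird` remains available for standard
practice. Equivalent dose uses w_R = 1 for beta radiation
(configurable). The dominance ratio is the liver self-S over the
largest cross-organ S of the same record; +∞ when all cross-organ
values vanish (the electron-only limit for distant organs).

## Reproduction vs simulation

The two entry paths are deliberately separate. `reproduce` is pure
arithmetic on the packaged reference table — deterministic, sub-second,
and lands every published range endpoint at printed precision (female
liver 84–54 Gy, male liver max 64 Gy, female lung 0.34–0.005 Gy, male
lung 0.26–0.004 Gy, female kidney max 0.48 Gy, male kidney
0.43–0.05 Gy, marrow < 0.1 Gy; minimum dominance ratio 122.6). Two
printed values are knowingly unreachable from the reference table under
either convention and are excluded: the male liver minimum quoted as
53 Gy (the table's own minimum converts to 42.6 Gy) and the female
kidney minimum quoted as 0.08 Gy (the table gives 0.0886 → 0.09 Gy).

`simulate` runs the in-repo pipeline end to end. Its S-values depend
on the synthetic anatomy and the electron-only physics, so they are
validated against closed forms, magnitude bands and invariants — never
for equality with the reference table. Self-S-values agree with the
reference band because they are controlled by E/m; cross-organ values
are lower by construction (no photons).

## Problem sizes

Default study runs use 10⁶ histories per phantom; the packaged test
suite and acceptance battery size individual checks between 10⁴ and
10⁶ histories — enough for the 3σ windows used — and run the
13-phantom integrity pipeline at 10⁵ histories per phantom, twice, to
verify bit-identical replay from the recorded configuration.

## Known limitations

- Straight-track CSDA without scattering slightly sharpens the dose
  kernel edge; absorbed fractions at organ interfaces (liver–marrow)
  carry a corresponding small bias.
- No photon transport: distant-organ doses are underestimated (zero)
  relative to full-physics codes; only the ledger records the
  radiative energy.
- Synthetic anatomy: organ shapes and separations are idealized; the
  liver–lung gap (~1.5 cm) exceeds the beta range, so the simulated
  lung dose is exactly zero rather than merely small. Passing tests
  demonstrate correct energy accounting and MIRD arithmetic on these
  conditions, not anatomical fidelity to any individual patient.
- Uniform per-volume activity ignores the vascular heterogeneity of
  real microsphere deposition; patient-specific (SPECT/CT-driven)
  dosimetry is out of scope.
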