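# Methods

This note records the models, conventions, parameter choices and known
limitations behind `emcharge`.  Nothing here states an empirical result the
test suite or `scripts/acceptance.py` does not itself compute.

## Scattering factors

Neutral-atom elastic electron scattering factors use the published
five-Gaussian parameterization (Peng et al., 1996; the International Tables
Vol. C Table 4.3.2.2 lineage), f(s) = Σᵢ aᵢ·exp(−bᵢ s²) with s = sinθ/λ =
1/(2d) in Å⁻¹.  X-ray form factors use the IT92 four-Gaussian + constant
table, including the O1⁻ ionic entry.  Both tables ship as a versioned JSON
data file (`src/emcharge/data/scattering_coefficients.json`) with their
provenance strings; the unit tests cross-check every electron entry against
gemmi's independent tabulation.

**Ions.**  The adopted electron table has no ionic entries, so ionic
electron factors are synthesized through the Mott–Bethe relation.  Rather
than transforming the full ionic X-ray factor, we anchor the ionic
*perturbation* on the adopted neutral curve:

    f_e,ion(s) = f_e,neutral(s) + k · (f_x,neutral(s) − f_x,ion(s)) / s²,
    k = 1/(8π²a₀) ≈ 0.023934 Å.

The two constructions differ by ~0.2 % (the residual between the Peng and
Mott–Bethe-of-IT92 neutral curves), but only this one makes q = 0 exact and
the q → −q antisymmetry of charged-vs-neutral difference maps hold to
machine precision.  Cations missing from the X-ray table (e.g. O1⁺) use the
mirrored valence-electron model f_x(+1) = 2·f_x(0) − f_x(−1), i.e. the
removed electron is modelled as the image of the added one.

**Partial charges** mix the neutral curve and the full ion of matching sign
linearly in |q|.  At s = 0 a net-charged factor diverges (sign of the net
charge); the grid evaluator substitutes the neutral value there, which is
never observable because F(000) is excluded from every synthesis.

The IT92 O1⁻ entry carries one slightly negative Gaussian width
(b₄ = −0.01404 Å²) as published; the b > 0 validity check therefore applies
to electron-kind parameterizations only.

## Map model and conventions

Structure factors follow the independent atom model on the FFT frequency
grid of an orthogonal P1 box:

    F(h) = Σⱼ occⱼ · fⱼ(s_h) · exp(−Bⱼ d*²/4) · exp(−2πi h·rⱼ),

evaluated by direct summation with the separable-phase trick (three 1-D
phase vectors per atom), which is exactly equivalent to the naive double
loop the tests use as oracle.  Real-space maps are the inverse FFT divided
by the box volume, node-centred (value at i·voxel, origin at the box
corner, 0-based indices); Parseval then gives σ² = Σ_band |F|²/V², which is
asserted in the tests.  Maps are periodic; peak search and interpolation
use wrapped boundaries.

* **σ** is the RMS deviation from the mean over *all* voxels, no mask.
  Contour statements (2σ, 4σ) depend on this choice.
* **Bands** select coefficients half-open in d* = 1/d:
  1/d_low ≤ d* < 1/d_high, with F(000) always excluded.  A d_low of 100 Å
  on a box smaller than 100 Å keeps every nonzero low-frequency term.
* **Default voxel size** is d_min/4 (0.2975 Å at d_min = 1.19 Å), which
  keeps the quadratic sub-voxel peak interpolation within 0.02 Å of a
  continuous-synthesis oracle (tested).
* **Nyquist guard**: voxel_size ≤ d_min/2 is enforced with an explicit
  error.  Anisotropic B and crystallographic symmetry are out of scope.
* Simulated maps are unsharpened; no post-processing model is applied.

## Difference maps

F_c comes from the (possibly hydrogen-omitted or all-neutral) model on the
observed grid; the difference w·(F_o − F_c) is band-limited and synthesized.
The default weight is w ≡ 1.  An optional per-shell Wiener-style weight
w = SNR/(1+SNR), estimated from a half-map pair (noise power =
mean|F₁−F₂|²/4 per shell), is provided; the hydrogen and charge signatures
studied here survive either scheme.  Difference maps store their data in
units of their own σ and keep the raw σ so a series can be compared on a
shared absolute scale — band series are reported both ways because each
map's σ collapses as its band narrows.

## Hydrogen peaks and bond classes

Peaks are 26-neighbourhood local maxima at or above the threshold, with
sub-voxel refinement by a quadratic fit to the 3×3×3 neighbourhood (offset
clipped to half a voxel per axis).  Assignment to riding-hydrogen sites is
greedy by peak height with ties to the nearer site, one peak per site,
within a maximum offset of 0.5 Å — a deterministic replacement for the
manual curation a human would do against riding positions.  Bond classes
follow the parent atom: aromatic-ring carbons by residue-template lookup
(Phe/Tyr/His/Trp), sp³ carbons by hydrogen count, N–H excluding lysine NZ
(solvent-facing side chain), O–H for hydroxyls; water is excluded unless
requested.  The aggregate C–H class is the union of C_alk–H and C_aro–H.
Statistics use the sample standard deviation (n−1), omitted for n < 2.

**Geminal overlap.**  In noiseless 1.19 Å band-limited maps the density
maxima of geminal hydrogens (CH₂, CH₃, side-chain NH₂) are pulled toward
each other, shortening peak-to-parent distances by up to ~0.17 Å.  This was
verified against a continuous direct-Fourier-summation oracle, so it is map
physics, not picker bias (the picker agrees with that oracle to ≤0.005 Å).
Parameter-recovery claims therefore hold for isolated hydrogens (C_alk–H,
C_aro–H, backbone amide N–H: within 0.02 Å of the placed distances) while
the geminal classes recover systematically short; the tests assert both
behaviours explicitly.

The distance-vs-height trend in noisy maps (weaker peaks sit farther out)
is driven by the noise geometry: a peak is tallest when a noise ripple
coincides with the hydrogen centre and is displaced when it does not.  The
test isolates this mechanism with a constant-B fixture, because B-factor
dispersion couples height and geminal pull with the opposite sign.

## Charge metrics

`negative_density_metric` reports, per atom, the minimum σ-scaled map value
within a radius (default 1.0 Å) and the sum of values at or below −level
(default 4σ) within that radius.  The interpolated value at the atom
position is always a candidate for the minimum, so the metric converges to
the local map value as the radius shrinks.  The partial-charge simulation
(charged-minus-neutral structure factors, default q = −0.3 on carboxylate
oxygens) is exactly linear and antisymmetric in q and noiseless by
construction.  The analysis is qualitative by design: no absolute charge is
estimated.

## RMSD₁/₂ and FSC

RMSD₁/₂ refits the model independently against each unfiltered half map and
reports the RMSD between the two results (non-hydrogen atoms by default,
matched by chain/residue/atom identifiers, no superposition — the models
share the map frame).  The refit is a deterministic capped gradient ascent
to the local interpolated density maximum (cubic spline, steps starting at
0.3 voxel, halved on non-improvement, total displacement clamped to
max_shift = 0.5 Å) — a desk-scale surrogate for a restrained-refinement
engine that preserves the metric's logic: independent fits to independent
noise realizations.

*Limitation of the surrogate*: a bonded atom is generally **not** at a
local maximum of the composite band-limited map.  A C=O pair's maxima are
pulled ~0.03 Å inward even at B = 5 Å² and merge entirely by B ≈ 20 Å², so
the unrestrained refit drifts shoulder atoms deterministically.  The drift
is common mode between the two half-map refits and cancels in RMSD₁/₂
(identical halves give exactly 0, asserted), but fixed-point and
displacement-recovery properties are only meaningful for atoms that own
their maximum; those tests use a separated-atom fixture (≥2.5 Å spacing).
Restraints would be needed to quote absolute refit accuracy on bonded
models.

FSC is the per-shell normalized cross-correlation of the half-map Fourier
coefficients, shells uniform in d* out to Nyquist, with the threshold
crossing (default 0.143) located by linear interpolation.  For white signal
plus white noise of per-shell SNR γ the curve matches γ/(1+γ) within
counting error (tested, and re-measured by the acceptance script).

Dose arithmetic is rate × frame time × frames / pixel², reported raw and
rounded; box rescaling preserves the physical extent
(box_in × pixel_in / box_out).

## Synthetic data

The generator stands in for a high-resolution reconstruction of a protein
interior:

* **Geometry** — residues are placed on an ideal extended backbone
  (φ = −140°, ψ = 135°, ω = 180°; N–CA 1.458, CA–C 1.525, C–N 1.329,
  C=O 1.231 Å) by superposing idealized residue templates (the bundled
  Chemical Component Dictionary ideal coordinates, one canonical conformer,
  no rotamer sampling).  Backbone N/CA/C/O are rebuilt exactly; side chains
  are rigid template copies.  Asp/Glu are deprotonated (their acid protons
  are stripped), matching a neutral-pH sample.
* **Riding hydrogens** — placed along template directions at the neutron
  reference distances (C_alk 1.09, C_aro 1.08, C–H₂/C–H₃ 1.09, N–H 1.02,
  O–H 0.98 Å) or the X-ray electron-cloud set (0.97/0.93/0.97/0.97/0.86/
  0.84 Å).  Backbone amide hydrogens are built in the peptide plane, anti
  to the preceding carbonyl; the N-terminal residue gets no amide H and no
  ammonium hydrogens (termini are irrelevant to the bond-class statistics).
* **B-factors** — spatially correlated: an AR(1) baseline per residue inside
  the 10–35 Å² default range plus ±2 Å² per-atom jitter.  Bonded atoms in
  well-ordered side chains differ by a few Å², not by the whole range; an
  i.i.d. draw would routinely place a B = 35 atom next to a B = 11 atom,
  which has no separate density maximum at the 1.19 Å band limit.
* **Noise** — white Gaussian in real space, RMS specified as a fraction of
  the signal-map σ, independent between half maps.  Real reconstruction
  noise is colored and CTF-shaped; all quantitative claims here are
  therefore either noiseless or trend/closed-form checks, not absolute σ
  levels.  One consequence worth knowing: band-limiting to ≥3 Å keeps only
  a small fraction of white-noise power, so band-limited difference maps
  from noisy synthetic data are much cleaner than their real counterparts.
* **Dose series** — noise variance ∝ 1/n_frames at fixed signal
  (noise_sigma refers to a single-frame sum), emulating frame summation;
  an optional b_per_frame inflates B linearly with frame count to emulate
  accumulated damage (off by default, as dose-weighted summation largely
  compensates damage in the emulated pipeline).

Everything is reproducible from (spec, seed); generator outputs round-trip
through the PDB/MRC writers within format precision (tested).

## I/O

PDB subset and MRC/CCP4 mode-2 maps go through gemmi.  Maps are normalized
to canonical X,Y,Z axis order on reading (verified against a hand-written
permuted-axis oracle); anisotropic voxel sizes are rejected.  PDB has no
fractional-charge field, so partial charges travel in a JSON sidecar
(`<path>.charges.json`) keyed by chain/residue/atom.  `RunConfig` validates
run parameters and serializes them (with the package version) next to the
outputs for provenance.  The package is used from Python; the examples
directory and `scripts/acceptance.py` are the runnable surface.

## Problem sizes

The shipped fixtures are deliberately small: 3–20 residue peptides,
50³–220×160×50 grids at 0.2975 Å voxels.  At these sizes the full test
suite runs in about a minute and the acceptance script in under a minute,
while every code path (including the ≥60-bond hydrogen recovery and the
five-band charge series) is exercised end to end.
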