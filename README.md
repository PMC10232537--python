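# emcharge

Analysis of **charges and hydrogen bonding in cryo-EM Coulomb potential
maps**, at desk scale.

Sub-1.2 Å single-particle cryo-EM maps resolve individual atoms and, in
hydrogen-omit difference maps, individual hydrogen atoms.  Because electrons
scatter off the Coulomb potential rather than the electron density, these
maps also carry charge information: the electron scattering factor of an
anion is strongly *negative* at low spatial frequency and converges to the
neutral curve only beyond ~2.5 Å resolution, so a negatively charged
carboxylate oxygen leaves a negative imprint in an all-neutral-model
difference map that disappears when low-resolution data are omitted.

`emcharge` packages this map-interpretation layer as a tested Python
library for structural biologists and methods developers:

* **Scattering factors** — Peng five-Gaussian electron factors for neutral
  atoms, ionic factors via the Mott–Bethe relation
  f<sub>e</sub>(s) = (8π²a₀)⁻¹ (Z − f<sub>x</sub>(s))/s², and partial
  charges as the linear combination
  f<sub>q</sub> = (1−|q|)·f<sub>neutral</sub> + |q|·f<sub>ion</sub>.
* **Map simulation** — independent-atom-model structure factors
  F(**h**) = Σ occ·f(s)·exp(−B d*²/4)·exp(−2πi **h**·**r**) on an FFT grid,
  band-limited Coulomb potential synthesis, σ statistics.
* **Difference maps** — hydrogen-omit and charged-vs-neutral
  F<sub>o</sub>−F<sub>c</sub> maps with resolution-band series and optional
  per-shell Wiener weighting from half maps.
* **Hydrogen peak statistics** — 26-neighbourhood peak picking with
  sub-voxel quadratic interpolation, greedy assignment to riding-hydrogen
  sites, bond-type classification (C<sub>alk</sub>–H, C<sub>aro</sub>–H,
  C–H₂, C–H₃, N–H, O–H) and per-class distance statistics.
* **Charge metrics** — minimum/integrated negative density around selected
  atoms across resolution and dose/frame series.
* **Model precision** — RMSD₁/₂ (RMSD between models refit independently
  against the two half maps), gold-standard FSC with threshold
  interpolation, dose and pixel-rescaling arithmetic.
* **Curation** — the stage-position proximity filter that discards
  micrographs taken within 1.5 µm of any previously exposed position.
* **Synthetic data** — seeded toy peptides with idealized residue geometry,
  riding hydrogens at neutron ("nuclear") or X-ray ("electron") reference
  bond lengths, correlated B-factors in 10–35 Å², fractional charges on
  carboxylate oxygens, half-map pairs and dose series.

## Worked example

`examples/03_charge_resolution_series.py` assigns q = −0.3 to the
carboxylate oxygens of a toy Asp/Glu peptide, subtracts the all-neutral
model and tracks the negative density per resolution band:

```
band (d_low-d_high A) -> mean minimum density at charged O (absolute scale)
   100.0 - 2.50   -0.0941
    20.0 - 2.50   -0.0747
    10.0 - 2.50   -0.0472
     5.0 - 2.50   -0.0132
     3.3 - 2.50   -0.0023
     2.5 - 1.19   -0.0005
```

The charge signal lives entirely below ~2.5 Å resolution: it shrinks
monotonically as low-resolution terms are removed and is ~0.5% of its full
value in the 2.5–1.19 Å band.  `examples/02_hydrogen_omit_peaks.py` runs
the hydrogen recovery pipeline (a noiseless 1.19 Å hydrogen-omit map of a
12-residue peptide finds all 76 hydrogens; isolated C–H classes average
1.087–1.090 Å against the placed 1.08/1.09 Å nuclear distances), and
`examples/05_halfmap_precision.py` sweeps RMSD₁/₂ from 0.030 to 0.170 Å as
half-map noise grows.  Each example script prints a short interpretation
with its numbers.

## Layout

```
src/emcharge/        library (scattering, maps, diffmaps, peaks, charges,
                     metrics, curation, synthetic, io)
src/emcharge/data/   versioned scattering-coefficient tables (JSON)
examples/            one narrative script per capability
tests/               pytest suite (unit, property and acceptance tests)
docs/methods.md      model assumptions, numerical choices, limitations
```
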