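"""Partial-charge difference maps across resolution bands.

Assigns q = -0.3 to the carboxylate oxygens of a toy Asp/Glu peptide,
subtracts the all-neutral model and tracks the negative density at each
oxygen as low-resolution data are progressively omitted.
"""

import emcharge as ec

spec = ec.SyntheticSpec(
    n_residues=6, residue_mix=("ALA", "ASP", "GLY", "GLU", "PHE", "ASN"), seed=21
)
model = ec.build_toy_model(spec)
oxygens = ec.carboxylate_oxygen_indices(model)
print("charged oxygens:",
      [f"{model.sites[i].residue_name}{model.sites[i].residue_number}/{model.sites[i].name}"
       for i in oxygens])

bands = [ec.ResolutionBand(d_low, 2.5) for d_low in (100.0, 20.0, 10.0, 5.0, 3.3)]
bands.append(ec.ResolutionBand(2.5, 1.19))
maps = ec.simulate_partial_charge_difference(model, oxygens, -0.3, bands, spec.voxel)

table = ec.map_series_analysis(maps, model, oxygens, radius=1.0, level=4.0,
                               absolute_scale=True)
summary = table.groupby("series_index")["min_density"].mean()
print("\nband (d_low-d_high A) -> mean minimum density at charged O (absolute scale)")
for k, band in enumerate(bands):
    print(f"  {band.d_low:6.1f} - {band.d_high:4.2f}   {summary[k]: .4f}")
print("\nThe negative signal shrinks monotonically as low-resolution terms are")
print("removed and is essentially zero in the 2.5-1.19 A band, because ionic")
print("and neutral electron scattering factors agree beyond ~2.5 A.")
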