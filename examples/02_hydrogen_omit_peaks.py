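"""Hydrogen-omit difference map and per-bond-type distance statistics.

Builds a 12-residue toy peptide with riding hydrogens at neutron reference
distances, simulates a noiseless 1.19 A map, computes the F_o - F_c map
against the hydrogen-omitted model, picks peaks at 2 and 4 sigma, assigns
them to hydrogen sites and prints per-bond-type distance statistics.
"""

import emcharge as ec
from emcharge.peaks import stats_to_frame

spec = ec.SyntheticSpec(seed=5)
model = ec.add_riding_hydrogens(ec.build_toy_model(spec), "nuclear")
n_h = sum(s.is_hydrogen for s in model.sites)
print(f"model: {len(model)} atoms, {n_h} riding hydrogens")

sf = ec.structure_factors_from_model(model, spec.voxel, d_min=1.19)
band = ec.ResolutionBand(ec.FULL_BAND_DLOW, 1.19)
dmap = ec.fourier_difference_map(sf, ec.omit_atoms(model, "hydrogens"), band)

peaks = ec.find_peaks(dmap, threshold=2.0)
assignments, unassigned = ec.assign_hydrogen_peaks(peaks, model, max_offset=0.5)
print(f"peaks >= 2 sigma: {len(peaks)}, assigned to H sites: {len(assignments)}")

stats = ec.bond_length_statistics(assignments, thresholds=(2.0, 4.0))
print(stats_to_frame(stats).to_string(index=False))
print("\nmean_distance is the peak-to-parent distance in A; at 4 sigma the")
print("isolated-H classes sit at the placed nuclear distances (C-H 1.09,")
print("N-H 1.02); geminal CH2/CH3 peaks are pulled inward by density overlap.")
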