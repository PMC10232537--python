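"""Half-map model precision (RMSD_1/2) and FSC resolution.

Generates half maps with independent noise, refits the model against each
half independently (local density-maximum refit) and reports the RMSD
between the two refits -- an estimate of the coordinate uncertainty the map
noise induces -- together with the gold-standard FSC resolution.
"""

import dataclasses

import emcharge as ec

base = ec.SyntheticSpec(n_residues=4, residue_mix=("ALA", "ASP", "PHE", "GLY"), seed=7)
model = ec.add_riding_hydrogens(ec.build_toy_model(base), "nuclear")

print("noise level   RMSD_1/2 [A]   FSC_0.143 resolution [A]")
for noise in (0.02, 0.05, 0.1, 0.2):
    spec = dataclasses.replace(base, noise_sigma=noise)
    pair, signal = ec.make_half_maps(model, spec)
    out = ec.rmsd_half(model, pair, max_shift=0.5)
    res = ec.fsc_curve(pair, n_shells=12).resolution_at(0.143)
    print(f"   {noise:4.2f}        {out['rmsd_half']:6.3f}          {res:5.2f}")
print("\nRMSD_1/2 is zero for identical halves and grows monotonically with")
print("the half-map noise; per-element values are in rmsd_half()['per_element'].")
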