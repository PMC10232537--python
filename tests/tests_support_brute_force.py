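"""Naive direct-summation structure factors (shared test oracle)."""

import numpy as np

from emcharge.scattering import electron_form_factor


def brute_force_structure_factors(model, voxel_size, d_min, shape):
    """Explicit loops over reciprocal voxels and atoms; no vectorization."""
    freqs = [np.fft.fftfreq(n, d=voxel_size) for n in shape]
    F = np.zeros(shape, dtype=complex)
    for i, fx in enumerate(freqs[0]):
        for j, fy in enumerate(freqs[1]):
            for k, fz in enumerate(freqs[2]):
                ds2 = fx * fx + fy * fy + fz * fz
                if ds2 > (1.0 / d_min) ** 2 + 1e-9:
                    continue
                s = np.sqrt(ds2) / 2.0
                for site in model.sites:
                    ff = electron_form_factor(site.element, site.partial_charge)
                    f = ff(np.array([s]))[0]
                    phase = np.exp(-2j * np.pi * (fx * site.position[0]
                                                  + fy * site.position[1]
                                                  + fz * site.position[2]))
                    F[i, j, k] += (site.occupancy * f
                                   * np.exp(-site.b_iso * ds2 / 4.0) * phase)
    return F
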