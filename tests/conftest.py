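"""Shared fixtures: synthetic models and maps reused across test modules.

Everything is generated at run time from seeded specs; session scope keeps
the expensive Fourier syntheses to one computation each.
"""

import numpy as np
import pytest

import emcharge as ec


@pytest.fixture(scope="session")
def tiny_model():
    """3-residue heavy-atom model (Ala-Asp-Phe)."""
    spec = ec.SyntheticSpec(n_residues=3, residue_mix=("ALA", "ASP", "PHE"), seed=1)
    return ec.build_toy_model(spec)


@pytest.fixture(scope="session")
def tiny_model_h(tiny_model):
    return ec.add_riding_hydrogens(tiny_model, "nuclear")


@pytest.fixture(scope="session")
def full_band():
    return ec.ResolutionBand(ec.FULL_BAND_DLOW, 1.19)


@pytest.fixture(scope="session")
def recovery_fixture(full_band):
    """12-residue model with riding H + noiseless H-omit difference map."""
    spec = ec.SyntheticSpec(seed=5)
    model = ec.add_riding_hydrogens(ec.build_toy_model(spec), "nuclear")
    sf = ec.structure_factors_from_model(model, spec.voxel, d_min=1.19)
    dmap = ec.fourier_difference_map(sf, ec.omit_atoms(model, "hydrogens"), full_band)
    return spec, model, sf, dmap


@pytest.fixture(scope="session")
def charge_fixture():
    """6-residue model containing Asp and Glu, with its carboxylate oxygens."""
    spec = ec.SyntheticSpec(
        n_residues=6, residue_mix=("ALA", "ASP", "GLY", "GLU", "PHE", "ASN"), seed=21
    )
    model = ec.build_toy_model(spec)
    return spec, model, ec.carboxylate_oxygen_indices(model)


@pytest.fixture(scope="session")
def separated_model():
    """8 heavy atoms on a 3 A lattice: each owns its density maximum."""
    from emcharge.model import AtomicModel, AtomSite

    rng = np.random.default_rng(3)
    elements = ["C", "N", "O", "C", "O", "N", "C", "C"]
    sites = []
    k = 0
    for x in range(2):
        for y in range(2):
            for z in range(2):
                sites.append(
                    AtomSite(elements[k], f"X{k}", "UNK", 1,
                             [4 + 3 * x, 4 + 3 * y, 4 + 3 * z],
                             b_iso=float(rng.uniform(10, 15)))
                )
                k += 1
    return AtomicModel(sites, [], cell=[11.0, 11.0, 11.0])
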