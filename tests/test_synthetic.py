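"""Synthetic generator: geometry, riding hydrogens, half maps, dose series."""

import dataclasses

import numpy as np
import pytest

import emcharge as ec
from emcharge.synthetic import NUCLEAR_H_DISTANCES, ELECTRON_H_DISTANCES


class TestToyModel:
    def test_single_alanine_heavy_atom_count(self):
        spec = ec.SyntheticSpec(n_residues=1, residue_mix=("ALA",), seed=0)
        m = ec.build_toy_model(spec)
        assert len(m) == 5  # N, CA, C, O, CB
        assert sorted(s.name for s in m.sites) == ["C", "CA", "CB", "N", "O"]

    def test_same_seed_reproduces_coordinates_and_b(self):
        spec = ec.SyntheticSpec(n_residues=4, seed=9)
        a, b = ec.build_toy_model(spec), ec.build_toy_model(spec)
        np.testing.assert_array_equal(a.positions, b.positions)
        assert [s.b_iso for s in a.sites] == [s.b_iso for s in b.sites]

    def test_bond_lengths_match_template_geometry(self, tiny_model):
        """Within-residue heavy-atom bond lengths agree with the idealized
        templates to 0.02 A (backbone links are rebuilt, side chains rigid)."""
        from emcharge.synthetic import _template

        by_res = {}
        for i, s in enumerate(tiny_model.sites):
            by_res.setdefault(s.residue_number, {})[s.name] = i
        checked = 0
        for rnum, atoms in by_res.items():
            rname = tiny_model.sites[next(iter(atoms.values()))].residue_name
            names, elements, coords, bonds = _template(rname)
            backbone = {"N", "CA", "C", "O"}
            for a, b in bonds:
                if elements[a] == "H" or elements[b] == "H":
                    continue
                if names[a] in backbone or names[b] in backbone:
                    continue  # backbone is rebuilt with peptide geometry
                if names[a] not in atoms or names[b] not in atoms:
                    continue
                want = np.linalg.norm(coords[a] - coords[b])
                got = np.linalg.norm(
                    tiny_model.sites[atoms[names[a]]].position
                    - tiny_model.sites[atoms[names[b]]].position
                )
                assert got == pytest.approx(want, abs=0.02), (rname, names[a], names[b])
                checked += 1
        assert checked >= 8

    def test_b_factors_inside_requested_range(self):
        spec = ec.SyntheticSpec(n_residues=8, seed=3, b_range=(10.0, 35.0))
        m = ec.build_toy_model(spec)
        bs = np.array([s.b_iso for s in m.sites])
        assert bs.min() >= 10.0 and bs.max() <= 35.0
        assert bs.std() > 0  # not constant

    def test_bonded_atoms_have_similar_b(self):
        """Displacement is spatially correlated: bonded atoms differ by
        far less than the full 10-35 A^2 range."""
        spec = ec.SyntheticSpec(n_residues=8, seed=3)
        m = ec.build_toy_model(spec)
        diffs = [abs(m.sites[i].b_iso - m.sites[j].b_iso) for i, j in m.bonds]
        assert max(diffs) < 10.0

    def test_charge_assignments_applied(self):
        spec = ec.SyntheticSpec(
            n_residues=2, residue_mix=("ALA", "ASP"), seed=0,
            charge_assignments=(("ASP", "OD1", -0.3), ("ASP", "OD2", -0.3)),
        )
        m = ec.build_toy_model(spec)
        charged = {s.name for s in m.sites if s.partial_charge == -0.3}
        assert charged == {"OD1", "OD2"}

    def test_unknown_residue_rejected(self):
        with pytest.raises(ValueError):
            ec.build_toy_model(ec.SyntheticSpec(n_residues=1, residue_mix=("XYZ",)))

    def test_model_fits_inside_its_box(self):
        m = ec.build_toy_model(ec.SyntheticSpec(n_residues=6, seed=1))
        m.check_inside_cell()

    def test_no_nonbonded_clashes(self):
        m = ec.add_riding_hydrogens(
            ec.build_toy_model(ec.SyntheticSpec(n_residues=8, seed=4)), "nuclear"
        )
        pos = m.positions
        d = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
        bonded = set()
        for a, b in m.bonds:
            bonded |= {(a, b), (b, a)}
        np.fill_diagonal(d, np.inf)
        for i, j in zip(*np.nonzero(d < 0.95)):
            assert (int(i), int(j)) in bonded


class TestRidingHydrogens:
    def test_alanine_hydrogen_inventory(self):
        spec = ec.SyntheticSpec(n_residues=2, residue_mix=("GLY", "ALA"), seed=0)
        m = ec.add_riding_hydrogens(ec.build_toy_model(spec), "nuclear")
        ala_h = sorted(s.name for s in m.sites
                       if s.residue_number == 2 and s.is_hydrogen)
        # HA + 3x HB + backbone amide H (residue 2 has a peptide bond)
        assert ala_h == ["H", "HA", "HB1", "HB2", "HB3"]

    def test_first_residue_has_no_amide_hydrogen(self):
        spec = ec.SyntheticSpec(n_residues=2, residue_mix=("ALA", "ALA"), seed=0)
        m = ec.add_riding_hydrogens(ec.build_toy_model(spec), "nuclear")
        first = [s.name for s in m.sites if s.residue_number == 1 and s.is_hydrogen]
        assert "H" not in first

    @pytest.mark.parametrize("distance_set,table", [
        ("nuclear", NUCLEAR_H_DISTANCES), ("electron", ELECTRON_H_DISTANCES),
    ])
    def test_bond_lengths_exactly_at_reference_distances(self, distance_set, table):
        spec = ec.SyntheticSpec(n_residues=3, residue_mix=("ALA", "TYR", "GLY"), seed=0)
        m = ec.add_riding_hydrogens(ec.build_toy_model(spec), distance_set)
        seen = set()
        for i, s in enumerate(m.sites):
            if not s.is_hydrogen:
                continue
            parent = m.sites[m.parent_of(i)]
            d = float(np.linalg.norm(s.position - parent.position))
            cls = ec.classify_bond_type(m.parent_of(i), m)
            if cls == "C_aro-H":
                assert d == pytest.approx(table["C_aro"], abs=1e-9)
            elif cls == "C-H3":
                assert d == pytest.approx(table["C_H3"], abs=1e-9)
            elif cls == "N-H":
                assert d == pytest.approx(table["N"], abs=1e-9)
            elif cls == "O-H":
                assert d == pytest.approx(table["O"], abs=1e-9)
            seen.add(cls)
        assert {"C_aro-H", "C-H3", "N-H", "O-H"} <= seen

    def test_deprotonated_carboxylates_have_no_hydroxyl_h(self):
        spec = ec.SyntheticSpec(n_residues=2, residue_mix=("ASP", "GLU"), seed=0)
        m = ec.add_riding_hydrogens(ec.build_toy_model(spec), "nuclear")
        for i in ec.carboxylate_oxygen_indices(m):
            assert not m.bonded_hydrogens(i)


class TestHalfMaps:
    def test_zero_noise_gives_identical_halves(self, tiny_model_h):
        spec = ec.SyntheticSpec(n_residues=3, residue_mix=("ALA", "ASP", "PHE"),
                                seed=1, noise_sigma=0.0)
        pair, signal = ec.make_half_maps(tiny_model_h, spec)
        np.testing.assert_array_equal(pair.half1.data, pair.half2.data)
        np.testing.assert_array_equal(pair.half1.data, signal.data)

    def test_independent_noise_same_signal(self, tiny_model_h):
        spec = ec.SyntheticSpec(n_residues=3, residue_mix=("ALA", "ASP", "PHE"),
                                seed=1, noise_sigma=0.1)
        pair, signal = ec.make_half_maps(tiny_model_h, spec)
        diff = pair.half1.data - pair.half2.data
        assert abs(diff.mean()) < 5 * diff.std() / np.sqrt(diff.size)
        assert diff.std() > 0
        # noise RMS close to requested level (sqrt(2) for the difference)
        assert diff.std() / np.sqrt(2) == pytest.approx(0.1 * signal.sigma, rel=0.05)

    def test_fsc_matches_per_shell_snr_closed_form(self, tiny_model_h):
        """FSC of generated halves ~ gamma/(1+gamma), gamma from the known
        signal spectrum and the analytic white-noise floor."""
        spec = ec.SyntheticSpec(n_residues=3, residue_mix=("ALA", "ASP", "PHE"),
                                seed=1, noise_sigma=0.25)
        pair, signal = ec.make_half_maps(tiny_model_h, spec)
        curve = ec.fsc_curve(pair, n_shells=10)
        f_sig = np.fft.fftn(signal.data)
        freqs = [np.fft.fftfreq(n, d=signal.voxel_size) for n in signal.data.shape]
        fx, fy, fz = np.meshgrid(*freqs, indexing="ij", sparse=True)
        ds = np.sqrt(fx**2 + fy**2 + fz**2).ravel()
        d_max = 1.0 / (2 * signal.voxel_size)
        edges = np.linspace(0, d_max, 11)
        idx = np.digitize(ds, edges) - 1
        valid = (idx >= 0) & (idx < 10) & (ds > 0)
        p_sig = np.bincount(idx[valid], np.abs(f_sig.ravel()[valid]) ** 2, 10)
        counts = np.bincount(idx[valid], minlength=10)
        sd = 0.25 * signal.sigma
        p_noise = sd**2 * signal.data.size  # flat white spectrum per coefficient
        keep = counts > 0
        gamma = (p_sig[keep] / counts[keep]) / p_noise
        expected = gamma / (1 + gamma)
        tol = np.maximum(4.0 / np.sqrt(counts[keep]), 0.05)
        assert np.all(np.abs(curve.fsc - expected) < tol)

    def test_round_trip_through_writers(self, tiny_model_h, tmp_path):
        """Generator outputs survive the PDB/MRC writers within format precision."""
        spec = ec.SyntheticSpec(n_residues=3, residue_mix=("ALA", "ASP", "PHE"),
                                seed=1, noise_sigma=0.05)
        pair, signal = ec.make_half_maps(tiny_model_h, spec)
        ec.write_map(signal, tmp_path / "signal.mrc")
        back = ec.read_map(tmp_path / "signal.mrc")
        assert np.max(np.abs(back.data - signal.data)) < 1e-5 * signal.sigma
        ec.write_model(tiny_model_h, tmp_path / "model.pdb")
        model_back = ec.read_model(tmp_path / "model.pdb")
        # hydrogens are regrouped into their residues on writing: match by key
        by_key = {s.key: s for s in model_back.sites}
        for s in tiny_model_h.sites:
            assert np.allclose(by_key[s.key].position, s.position, atol=1.5e-3)


class TestDoseSeries:
    def test_noise_rms_scales_with_inverse_sqrt_frames(self, tiny_model_h):
        spec = ec.SyntheticSpec(n_residues=3, residue_mix=("ALA", "ASP", "PHE"),
                                seed=1, noise_sigma=0.4)
        series = ec.make_dose_series(tiny_model_h, spec, (2, 20))
        rms = []
        for n, pair, signal in series:
            rms.append((pair.half1.data - signal.data).std())
        assert rms[0] / rms[1] == pytest.approx(np.sqrt(10), rel=0.05)

    def test_decreasing_frame_counts_rejected(self, tiny_model_h):
        spec = ec.SyntheticSpec(seed=1)
        with pytest.raises(ValueError):
            ec.make_dose_series(tiny_model_h, spec, (20, 2))

    def test_damage_mode_inflates_b(self, tiny_model_h):
        spec = ec.SyntheticSpec(n_residues=3, residue_mix=("ALA", "ASP", "PHE"), seed=1)
        series = ec.make_dose_series(tiny_model_h, spec, (2, 20), b_per_frame=0.25)
        # damage lowers high-resolution contrast: the 20-frame signal map is
        # blurrier, hence lower sigma, than the 2-frame one
        assert series[1][2].sigma < series[0][2].sigma
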