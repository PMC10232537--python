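"""Synthetic toy models and map pairs for the charge/hydrogen analyses.

The generator emulates the features of a high-resolution single-particle
reconstruction that the analyses depend on, at desk scale:

* short polypeptides with idealized residue geometry (one canonical
  conformer per residue, taken from the bundled Chemical Component
  Dictionary ideal coordinates) assembled on an extended backbone;
* riding hydrogens at either the neutron ("nuclear") or X-ray ("electron")
  reference bond lengths;
* per-atom isotropic B-factors drawn uniformly from 10-35 A^2, the range
  observed for well-ordered side chains in sub-1.2 A protein maps;
* optional fractional negative charges (q ~ -0.3) on carboxylate oxygens;
* band-limited maps at 1.19 A resolution, and half-map pairs with
  independent white Gaussian noise;
* dose/frame series in which noise variance scales inversely with the
  number of summed frames.

Everything is reproducible: the same spec and seed give identical output.
What the generator does *not* emulate -- colored reconstruction noise, CTF
residuals, radiation damage chemistry -- is discussed in docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .model import AtomicModel, AtomSite
from .maps import FULL_BAND_DLOW, PotentialMap, ResolutionBand, simulate_coulomb_map
from .metrics import HalfMapPair
from .peaks import _AROMATIC_CH

__all__ = [
    "SyntheticSpec",
    "NUCLEAR_H_DISTANCES",
    "ELECTRON_H_DISTANCES",
    "build_toy_model",
    "add_riding_hydrogens",
    "make_half_maps",
    "make_dose_series",
    "carboxylate_oxygen_indices",
]

#: Reference H bond lengths (A) by parent class; neutron-derived nuclear
#: positions and X-ray-derived electron-cloud positions.
NUCLEAR_H_DISTANCES = {"C_alk": 1.09, "C_aro": 1.08, "C_H2": 1.09, "C_H3": 1.09,
                       "N": 1.02, "O": 0.98}
ELECTRON_H_DISTANCES = {"C_alk": 0.97, "C_aro": 0.93, "C_H2": 0.97, "C_H3": 0.97,
                        "N": 0.86, "O": 0.84}

DEFAULT_RESIDUE_MIX = ("ALA", "ASP", "PHE", "GLY", "GLU", "ASN",
                       "TYR", "GLN", "LYS", "SER", "ALA", "ASP")

# idealized backbone internal coordinates (A, degrees)
_BB = dict(n_ca=1.458, ca_c=1.525, c_n=1.329, c_o=1.231,
           ang_n_ca_c=111.2, ang_ca_c_n=116.2, ang_c_n_ca=121.7,
           ang_ca_c_o=120.8, phi=-140.0, psi=135.0, omega=180.0)

_SKIP_TEMPLATE_ATOMS = {"OXT", "HXT", "H2", "H3"}
#: carboxylic-acid protons: the study condition is deprotonated Asp/Glu (pH 7.5)
_SKIP_RESIDUE_H = {("ASP", "HD2"), ("GLU", "HE2")}


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for the synthetic fixtures."""

    n_residues: int = 12
    residue_mix: tuple[str, ...] = DEFAULT_RESIDUE_MIX
    b_range: tuple[float, float] = (10.0, 35.0)
    d_min: float = 1.19
    voxel_size: float | None = None  # default d_min / 4
    noise_sigma: float = 0.0  # noise RMS as a fraction of the signal map sigma
    charge_assignments: tuple[tuple[str, str, float], ...] = ()
    seed: int = 0
    box_margin: float = 4.0

    @property
    def voxel(self) -> float:
        return self.voxel_size if self.voxel_size is not None else self.d_min / 4.0

    @property
    def band(self) -> ResolutionBand:
        return ResolutionBand(FULL_BAND_DLOW, self.d_min)


def _place_atom(a, b, c, bond: float, angle: float, torsion: float) -> np.ndarray:
    """NeRF placement: position d with |cd|=bond, angle(bcd), torsion(abcd)."""
    ang, tor = np.radians(angle), np.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond * np.array(
        [-np.cos(ang), np.sin(ang) * np.cos(tor), np.sin(ang) * np.sin(tor)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _backbone_frames(n_residues: int) -> list[dict[str, np.ndarray]]:
    """Ideal extended-chain N/CA/C/O positions per residue."""
    g = _BB
    frames = []
    n = np.array([0.0, 0.0, 0.0])
    ca = np.array([g["n_ca"], 0.0, 0.0])
    ang = np.radians(g["ang_n_ca_c"])
    c = ca + g["ca_c"] * np.array([-np.cos(ang), np.sin(ang), 0.0])
    for i in range(n_residues):
        frames.append({"N": n, "CA": ca, "C": c})
        n_next = _place_atom(n, ca, c, g["c_n"], g["ang_ca_c_n"], g["psi"])
        ca_next = _place_atom(ca, c, n_next, g["n_ca"], g["ang_c_n_ca"], g["omega"])
        c_next = _place_atom(c, n_next, ca_next, g["ca_c"], g["ang_n_ca_c"], g["phi"])
        frames[-1]["_N_next"] = n_next
        n, ca, c = n_next, ca_next, c_next
    # carbonyl O: anti to the next N in the peptide plane
    for i, fr in enumerate(frames):
        fr["O"] = _place_atom(fr["_N_next"], fr["CA"], fr["C"],
                              g["c_o"], g["ang_ca_c_o"], 180.0)
    return frames


from functools import lru_cache


@lru_cache(maxsize=None)
def _template(res_name: str):
    """Heavy/H atoms and bonds of the idealized residue template."""
    import biotite.structure.info as info

    arr = info.residue(res_name)
    if arr is None:
        raise ValueError(f"unknown residue {res_name!r}")
    keep = [
        i for i, nm in enumerate(arr.atom_name)
        if nm not in _SKIP_TEMPLATE_ATOMS and (res_name.upper(), nm) not in _SKIP_RESIDUE_H
    ]
    names = [arr.atom_name[i] for i in keep]
    elements = [arr.element[i].capitalize() for i in keep]
    coords = np.array([arr.coord[i] for i in keep], dtype=float)
    remap = {old: new for new, old in enumerate(keep)}
    bonds = [
        (remap[a], remap[b])
        for a, b, _ in arr.bonds.as_array()
        if a in remap and b in remap
    ]
    return names, elements, coords, bonds


def _kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rotation R and translation t minimizing |R P + t - Q|."""
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return R, qc - R @ pc


def build_toy_model(spec: SyntheticSpec) -> AtomicModel:
    """A polypeptide chain of idealized residues in an orthogonal box.

    Heavy atoms only (add hydrogens with :func:`add_riding_hydrogens`).
    B-factors are drawn uniformly from ``spec.b_range`` with the spec seed;
    charges from ``spec.charge_assignments`` (residue name, atom name, q)
    are applied to every matching site.
    """
    rng = np.random.default_rng(spec.seed)
    sequence = [spec.residue_mix[i % len(spec.residue_mix)]
                for i in range(spec.n_residues)]
    frames = _backbone_frames(len(sequence))
    # B-factors are spatially correlated: bonded/neighbouring atoms have
    # similar displacement, so draw a per-residue AR(1) baseline inside
    # b_range and add small per-atom jitter (clipped back to the range).
    lo, hi = spec.b_range
    pad = min(2.0, (hi - lo) / 4)
    b_base = np.empty(len(sequence))
    b_base[0] = rng.uniform(lo + pad, hi - pad)
    for i in range(1, len(sequence)):
        b_base[i] = np.clip(b_base[i - 1] + rng.normal(0, 3.0), lo + pad, hi - pad)
    sites: list[AtomSite] = []
    bonds: list[tuple[int, int]] = []
    prev_c = None
    for ri, (res, fr) in enumerate(zip(sequence, frames)):
        names, elements, coords, tbonds = _template(res)
        heavy = [i for i, el in enumerate(elements) if el != "H"]
        tri = [names.index(a) for a in ("N", "CA", "C")]
        R, t = _kabsch(coords[tri], np.array([fr["N"], fr["CA"], fr["C"]]))
        base = len(sites)
        index_of = {}
        for i in heavy:
            pos = R @ coords[i] + t
            if names[i] in ("N", "CA", "C", "O"):
                pos = fr[names[i]]
            index_of[i] = len(sites)
            sites.append(
                AtomSite(
                    element=elements[i], name=names[i], residue_name=res,
                    residue_number=ri + 1, position=pos,
                    b_iso=float(np.clip(b_base[ri] + rng.uniform(-pad, pad), lo, hi)),
                )
            )
        bonds.extend(
            (index_of[a], index_of[b])
            for a, b in tbonds
            if a in index_of and b in index_of
        )
        if prev_c is not None:
            n_idx = next(k for k in range(base, len(sites)) if sites[k].name == "N")
            bonds.append((prev_c, n_idx))
        prev_c = next(k for k in range(base, len(sites)) if sites[k].name == "C")
    model = AtomicModel(sites=sites, bonds=bonds)
    # centre in a padded box
    pos = model.positions
    extent = pos.max(axis=0) - pos.min(axis=0)
    cell = extent + 2 * spec.box_margin
    shift = spec.box_margin - pos.min(axis=0)
    for s in model.sites:
        s.position += shift
    model.cell = cell
    for res_name, atom_name, q in spec.charge_assignments:
        for s in model.sites:
            if s.residue_name == res_name and s.name == atom_name:
                s.partial_charge = q
    return model


def _h_distance(parent: AtomSite, n_h: int, distances: dict) -> float:
    el = parent.element.upper()
    if el == "N":
        return distances["N"]
    if el == "O":
        return distances["O"]
    if el == "C":
        if parent.name in _AROMATIC_CH.get(parent.residue_name.upper(), ()):
            return distances["C_aro"]
        return {1: distances["C_alk"], 2: distances["C_H2"],
                3: distances["C_H3"]}.get(n_h, distances["C_alk"])
    raise ValueError(f"no riding-hydrogen distance for element {parent.element!r}")


def add_riding_hydrogens(model: AtomicModel, distance_set: str = "nuclear") -> AtomicModel:
    """Place riding hydrogens at ideal geometry with reference bond lengths.

    Directions come from the residue template geometry (superposed on each
    residue's heavy atoms); backbone amide hydrogens are built explicitly in
    the peptide plane, anti to the preceding carbonyl, so the first residue
    (which has no peptide bond) gets no amide hydrogen.  ``distance_set`` is
    "nuclear" (neutron reference) or "electron" (X-ray reference).
    """
    distances = {"nuclear": NUCLEAR_H_DISTANCES,
                 "electron": ELECTRON_H_DISTANCES}[distance_set]
    out = model.copy()
    by_residue: dict[tuple, list[int]] = {}
    for i, s in enumerate(model.sites):
        by_residue.setdefault((s.chain, s.residue_number, s.residue_name), []).append(i)
    for (chain, rnum, rname), idxs in sorted(by_residue.items(), key=lambda kv: kv[0][:2]):
        names, elements, coords, tbonds = _template(rname)
        name_to_t = {nm: k for k, nm in enumerate(names)}
        common = [(i, name_to_t[model.sites[i].name]) for i in idxs
                  if model.sites[i].name in name_to_t]
        if len(common) < 3:
            raise ValueError(f"residue {rname}{rnum}: too few template atoms to orient")
        P = coords[[t for _, t in common]]
        Q = np.array([model.sites[i].position for i, _ in common])
        R, t = _kabsch(P, Q)
        t_neighbors: dict[int, list[int]] = {}
        for a, b in tbonds:
            t_neighbors.setdefault(a, []).append(b)
            t_neighbors.setdefault(b, []).append(a)
        for i in idxs:
            site = model.sites[i]
            if site.is_hydrogen:
                continue
            ti = name_to_t[site.name]
            t_hydrogens = [j for j in t_neighbors.get(ti, [])
                           if elements[j] == "H"]
            if not t_hydrogens:
                continue
            if site.name == "N":  # backbone amide: built from peptide geometry
                continue
            dist = _h_distance(site, len(t_hydrogens), distances)
            for j in t_hydrogens:
                u = R @ (coords[j] - coords[ti])
                u /= np.linalg.norm(u)
                h_pos = site.position + dist * u
                out.bonds.append((i, len(out.sites)))
                out.sites.append(
                    AtomSite(element="H", name=names[j], residue_name=rname,
                             residue_number=rnum, position=h_pos,
                             b_iso=site.b_iso, chain=chain)
                )
    # amide hydrogens for residues with a preceding peptide bond
    res_order = sorted(by_residue, key=lambda kv: kv[:2])
    lookup = {
        (s.chain, s.residue_number, s.name): i for i, s in enumerate(model.sites)
    }
    for (chain, rnum, rname) in res_order:
        if rname == "PRO":
            continue
        n_i = lookup.get((chain, rnum, "N"))
        ca_i = lookup.get((chain, rnum, "CA"))
        c_prev = lookup.get((chain, rnum - 1, "C"))
        if n_i is None or ca_i is None or c_prev is None:
            continue
        n_pos = model.sites[n_i].position
        u1 = model.sites[ca_i].position - n_pos
        u2 = model.sites[c_prev].position - n_pos
        u = -(u1 / np.linalg.norm(u1) + u2 / np.linalg.norm(u2))
        u /= np.linalg.norm(u)
        # index of N in the output model equals its index in the input model
        out.bonds.append((n_i, len(out.sites)))
        out.sites.append(
            AtomSite(element="H", name="H", residue_name=rname,
                     residue_number=rnum,
                     position=n_pos + distances["N"] * u,
                     b_iso=model.sites[n_i].b_iso, chain=chain)
        )
    return out


def carboxylate_oxygen_indices(model: AtomicModel) -> list[int]:
    """Indices of Asp/Glu side-chain terminal oxygens (OD1/OD2/OE1/OE2)."""
    targets = {("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2")}
    return [i for i, s in enumerate(model.sites)
            if (s.residue_name.upper(), s.name) in targets]


def make_half_maps(
    model: AtomicModel, spec: SyntheticSpec
) -> tuple[HalfMapPair, PotentialMap]:
    """Two maps of identical signal plus independent Gaussian noise.

    Noise RMS is ``spec.noise_sigma`` times the signal map sigma, identical
    in both halves but drawn independently.  Returns (pair, noiseless signal).
    """
    signal = simulate_coulomb_map(model, spec.voxel, spec.band)
    rng = np.random.default_rng(spec.seed)
    sd = spec.noise_sigma * signal.sigma
    halves = []
    for _ in range(2):
        noise = rng.normal(0.0, sd, size=signal.data.shape) if sd > 0 else 0.0
        halves.append(PotentialMap(signal.data + noise, signal.voxel_size))
    return HalfMapPair(*halves), signal


def make_dose_series(
    model: AtomicModel,
    spec: SyntheticSpec,
    frame_counts: Sequence[int] = (2, 3, 20, 40),
    b_per_frame: float = 0.0,
) -> list[tuple[int, HalfMapPair, PotentialMap]]:
    """Half-map pairs emulating frame-summation dose series.

    Noise variance scales as 1/n_frames (fixed signal), so the noise RMS
    ratio between a 2-frame and a 20-frame sum is sqrt(10).
    ``spec.noise_sigma`` is the noise fraction of a single-frame sum.
    ``b_per_frame > 0`` additionally inflates all B-factors linearly with
    the frame count to emulate accumulating radiation damage (off by
    default: the dose-weighted summation the series emulates compensates
    most of the damage in the real pipeline).
    """
    if list(frame_counts) != sorted(frame_counts):
        raise ValueError("frame_counts must be increasing")
    out = []
    for k, n in enumerate(frame_counts):
        damaged = model
        if b_per_frame > 0:
            damaged = model.copy()
            for s in damaged.sites:
                s.b_iso += b_per_frame * n
        sub = replace(spec, noise_sigma=spec.noise_sigma / np.sqrt(n),
                      seed=spec.seed + 1000 * (k + 1))
        pair, signal = make_half_maps(damaged, sub)
        out.append((n, pair, signal))
    return out
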