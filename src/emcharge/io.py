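"""Model and map readers/writers (PDB subset, MRC/CCP4 mode 2) plus RunConfig.

All formats go through gemmi.  Internal conventions: Angstrom everywhere,
right-handed axes, map origin at the box corner, node-centred voxels (value
at ``i * voxel_size``), 0-based indexing; PDB serial numbers are carried as
labels only.  PDB has no fractional-charge field, so partial charges travel
in a JSON sidecar (``<path>.charges.json``) keyed by chain/residue/atom.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .model import AtomicModel, AtomSite
from .maps import PotentialMap

__all__ = [
    "read_model",
    "write_model",
    "read_map",
    "write_map",
    "RunConfig",
]


def _sidecar(path) -> Path:
    return Path(str(path) + ".charges.json")


def write_model(model: AtomicModel, path, write_charges: bool = True) -> None:
    """Write a PDB-subset file (+ JSON charge sidecar when charges exist)."""
    import gemmi

    st = gemmi.Structure()
    st.cell = gemmi.UnitCell(*model.cell, 90, 90, 90)
    st.spacegroup_hm = "P 1"
    gmodel = gemmi.Model("1")
    charges = {}
    # group sites into residues first (hydrogens may be appended after the
    # heavy atoms in the site list), then build the gemmi hierarchy in order
    grouped: dict[str, dict[tuple, list]] = {}
    for i, s in enumerate(model.sites):
        grouped.setdefault(s.chain, {}).setdefault(
            (s.residue_number, s.residue_name), []
        ).append((i, s))
        if s.partial_charge:
            charges[f"{s.chain}/{s.residue_number}/{s.name}"] = s.partial_charge
    for chain_name, res_map in grouped.items():
        ch = gemmi.Chain(chain_name)
        for (rnum, rname), members in sorted(res_map.items(), key=lambda kv: kv[0][0]):
            res = gemmi.Residue()
            res.name = rname
            res.seqid = gemmi.SeqId(rnum, " ")
            for i, s in members:
                atom = gemmi.Atom()
                atom.name = s.name
                atom.element = gemmi.Element(s.element)
                atom.pos = gemmi.Position(*s.position)
                atom.b_iso = s.b_iso
                atom.occ = s.occupancy
                atom.serial = s.serial if s.serial is not None else i + 1
                res.add_atom(atom)
            ch.add_residue(res)
        gmodel.add_chain(ch)
    st.add_model(gmodel)
    st.setup_entities()
    st.write_pdb(str(path))
    if write_charges and charges:
        _sidecar(path).write_text(json.dumps(charges, indent=1))


def read_model(path) -> AtomicModel:
    """Read a PDB-subset file; charges restored from the sidecar if present.

    Elements missing from the file are inferred from the atom name (PDB
    convention).  A file with no atoms raises.  Bond topology is not stored
    in PDB; the returned model has an empty bond list.
    """
    import gemmi

    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    charges = {}
    if _sidecar(path).exists():
        charges = json.loads(_sidecar(path).read_text())
    sites = []
    for gmodel in st:
        for chain in gmodel:
            for res in chain:
                for atom in res:
                    el = atom.element.name
                    if el in ("", "X"):
                        el = atom.name.strip()[0]
                    key = f"{chain.name}/{res.seqid.num}/{atom.name}"
                    sites.append(
                        AtomSite(
                            element=el,
                            name=atom.name,
                            residue_name=res.name,
                            residue_number=res.seqid.num,
                            position=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                            b_iso=atom.b_iso,
                            occupancy=atom.occ,
                            partial_charge=float(charges.get(key, 0.0)),
                            chain=chain.name,
                            serial=atom.serial,
                        )
                    )
        break  # first model only
    if not sites:
        raise ValueError(f"no atoms found in {path}")
    cell = np.array([st.cell.a, st.cell.b, st.cell.c])
    return AtomicModel(sites=sites, bonds=[], cell=cell)


def write_map(pmap: PotentialMap, path) -> None:
    """Write an MRC/CCP4 mode-2 (float32) map with correct cell and origin."""
    import gemmi

    cell = pmap.cell
    grid = gemmi.FloatGrid(np.ascontiguousarray(pmap.data, dtype=np.float32))
    grid.set_unit_cell(gemmi.UnitCell(*cell, 90, 90, 90))
    grid.spacegroup = gemmi.SpaceGroup("P1")
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = grid
    ccp4.update_ccp4_header(mode=2)
    ccp4.set_header_float(50, float(pmap.origin[0]))
    ccp4.set_header_float(51, float(pmap.origin[1]))
    ccp4.set_header_float(52, float(pmap.origin[2]))
    ccp4.write_ccp4_map(str(path))


def read_map(path, iso_tol: float = 1e-3) -> PotentialMap:
    """Read an MRC/CCP4 map; axes normalized to canonical X,Y,Z order.

    Only isotropic voxel sizes are supported (within ``iso_tol`` relative
    spread); anisotropic maps raise.
    """
    import gemmi

    ccp4 = gemmi.read_ccp4_map(str(path))
    mode = ccp4.header_i32(4)
    if mode not in (0, 1, 2):
        raise ValueError(f"unsupported MRC mode {mode}")
    ccp4.setup(float("nan"))  # reorder axes to X,Y,Z, expand to full cell
    grid = ccp4.grid
    data = np.array(grid, copy=True, dtype=float)
    cell = np.array([grid.unit_cell.a, grid.unit_cell.b, grid.unit_cell.c])
    voxels = cell / np.array(data.shape)
    if voxels.max() - voxels.min() > iso_tol * voxels.mean():
        raise ValueError(f"anisotropic voxel sizes {voxels} are not supported")
    origin = np.array([ccp4.header_float(i) for i in (50, 51, 52)])
    return PotentialMap(data, float(voxels.mean()), origin=origin)


@dataclass
class RunConfig:
    """Validated run parameters, serialized alongside outputs for provenance."""

    seed: int = 0
    d_min: float = 1.19
    bands: tuple[tuple[float, float], ...] = ((100.0, 2.5), (2.5, 1.19))
    peak_thresholds: tuple[float, ...] = (2.0, 4.0)
    radius: float = 1.0
    level: float = 4.0
    output_dir: str = "."
    log_level: str = "INFO"
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.seed < 0 or self.seed >= 2**31:
            raise ValueError("seed must be in [0, 2^31)")
        if self.d_min <= 0:
            raise ValueError("d_min must be > 0")
        for lo, hi in self.bands:
            if not lo > hi > 0:
                raise ValueError(f"invalid band ({lo}, {hi})")
        if any(t <= 0 for t in self.peak_thresholds):
            raise ValueError("peak thresholds must be > 0")
        if self.radius <= 0 or self.level <= 0:
            raise ValueError("radius and level must be > 0")

    def dump(self, path) -> None:
        import emcharge

        payload = asdict(self)
        payload["emcharge_version"] = getattr(emcharge, "__version__", "unknown")
        Path(path).write_text(json.dumps(payload, indent=1))
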