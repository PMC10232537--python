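"""Structure factors and band-limited Coulomb potential map synthesis.

The forward model is the independent atom model evaluated directly in
reciprocal space on the FFT frequency grid of an orthogonal P1 box:

    F(h) = sum_j occ_j * f_j(s_h) * exp(-B_j d*^2 / 4) * exp(-2 pi i h . r_j)

with ``f_j`` the electron scattering factor of atom j's element and partial
charge, ``d* = 1/d = 2 s`` and the isotropic Debye-Waller factor
``exp(-B d*^2/4)``.  The real-space map is the inverse FFT divided by the box
volume, on node-centred grid points ``x_i = i * voxel`` -- the common
crystallographic FFT convention, so translating the model by an integer
number of voxels cyclically permutes the map.

The map ``sigma`` used for contour levels throughout the package is the RMS
deviation from the mean over *all* voxels of the box (no mask).  F(000) is
always excluded from synthesis, so band-limited maps have zero mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import AtomicModel
from .scattering import electron_form_factor

__all__ = [
    "ResolutionBand",
    "StructureFactorSet",
    "PotentialMap",
    "structure_factors_from_model",
    "synthesize_map",
    "simulate_coulomb_map",
    "FULL_BAND_DLOW",
]

#: Conventional "include everything low-resolution" band edge, in A.
FULL_BAND_DLOW = 1.0e6


@dataclass(frozen=True)
class ResolutionBand:
    """A resolution range d_low -> d_high in A, d_low > d_high > 0.

    Selection is half-open in d* = 1/d: a coefficient survives iff
    ``1/d_low <= d* < 1/d_high`` and ``d* > 0`` (F(000) never survives).
    A d_low of 100 A on a box smaller than 100 A therefore includes all
    low-frequency terms except F(000).
    """

    d_low: float
    d_high: float

    def __post_init__(self):
        if not (self.d_low > self.d_high > 0):
            raise ValueError(
                f"need d_low > d_high > 0, got ({self.d_low}, {self.d_high})"
            )

    def mask(self, d_star: np.ndarray) -> np.ndarray:
        return (d_star >= 1.0 / self.d_low) & (d_star < 1.0 / self.d_high) & (d_star > 0)


@dataclass
class StructureFactorSet:
    """Complex Fourier coefficients on the full FFT grid of an orthogonal box."""

    coefficients: np.ndarray  # complex, shape = grid_shape, np.fft layout
    voxel_size: float
    cell: np.ndarray  # box lengths in A (== grid_shape * voxel_size)
    d_min: float | None = None
    _d_star: np.ndarray | None = field(default=None, repr=False)

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return self.coefficients.shape

    @property
    def volume(self) -> float:
        return float(np.prod(self.cell))

    @property
    def d_star(self) -> np.ndarray:
        """|h| = 1/d in 1/A per reciprocal voxel (cached)."""
        if self._d_star is None:
            freqs = [
                np.fft.fftfreq(n, d=self.voxel_size) for n in self.grid_shape
            ]
            fx, fy, fz = np.meshgrid(*freqs, indexing="ij", sparse=True)
            self._d_star = np.sqrt(fx**2 + fy**2 + fz**2)
        return self._d_star

    def copy(self) -> "StructureFactorSet":
        return StructureFactorSet(
            self.coefficients.copy(), self.voxel_size, self.cell.copy(),
            self.d_min, self._d_star,
        )


@dataclass
class PotentialMap:
    """A real 3D scalar grid with isotropic voxel size and corner origin."""

    data: np.ndarray
    voxel_size: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be > 0")

    @property
    def sigma(self) -> float:
        """RMS deviation from the mean over all voxels (recomputed on access)."""
        return float(np.std(self.data))

    @property
    def cell(self) -> np.ndarray:
        return np.array(self.data.shape) * self.voxel_size

    def structure_factors(self) -> StructureFactorSet:
        """Forward transform back to Fourier coefficients (synthesis inverse)."""
        n = self.data.size
        volume = float(np.prod(self.cell))
        coeffs = np.fft.fftn(self.data) * (volume / n)
        return StructureFactorSet(coeffs, self.voxel_size, self.cell)

    def interpolate(self, positions, order: int = 1) -> np.ndarray:
        """Map values at Cartesian positions (A), periodic boundary."""
        from scipy.ndimage import map_coordinates

        pos = np.atleast_2d(np.asarray(positions, dtype=float)) - self.origin
        idx = (pos / self.voxel_size).T
        vals = map_coordinates(self.data, idx, order=order, mode="grid-wrap")
        return vals


def _grid_shape_for(cell, voxel_size) -> tuple[np.ndarray, np.ndarray]:
    """Even grid dimensions covering the cell; cell is padded up to n*voxel."""
    n = np.ceil(np.asarray(cell, dtype=float) / voxel_size).astype(int)
    n += n % 2  # even sizes keep the Nyquist layout simple
    n = np.maximum(n, 2)
    return n, n * voxel_size


def structure_factors_from_model(
    model: AtomicModel, voxel_size: float, d_min: float
) -> StructureFactorSet:
    """Direct-summation structure factors of an atomic model, cut at d_min.

    The phase factor is evaluated as an outer product of three 1-D phase
    vectors (the box is orthogonal, so ``exp(-2 pi i h.r)`` is separable),
    which keeps the cost at O(n_atoms * n_voxels) with small constants.
    Coefficients with d* > 1/d_min are zeroed.

    Raises ValueError when the voxel size violates the Nyquist bound
    ``voxel_size <= d_min / 2``.
    """
    if len(model) == 0:
        raise ValueError("model has no atoms")
    if voxel_size > d_min / 2:
        raise ValueError(
            f"voxel_size {voxel_size} A too coarse: Nyquist bound for "
            f"d_min {d_min} A is voxel_size <= {d_min / 2} A"
        )
    if np.any(model.cell <= 0):
        raise ValueError("model.cell must be positive box lengths")
    shape, cell = _grid_shape_for(model.cell, voxel_size)
    freqs = [np.fft.fftfreq(n, d=voxel_size) for n in shape]
    fx, fy, fz = np.meshgrid(*freqs, indexing="ij", sparse=True)
    ds2 = fx**2 + fy**2 + fz**2
    d_star = np.sqrt(ds2)
    keep = d_star <= 1.0 / d_min + 1e-12

    # species form factor f(s) with s = d*/2, cached per (element, charge)
    s_grid = d_star / 2.0
    f_cache: dict[tuple[str, float], np.ndarray] = {}
    F = np.zeros(tuple(shape), dtype=complex)
    for site in model.sites:
        key = (site.element.capitalize(), float(site.partial_charge))
        if key not in f_cache:
            ff = electron_form_factor(*key)
            f_cache[key] = np.asarray(ff(s_grid.ravel())).reshape(s_grid.shape)
        radial = (
            site.occupancy
            * f_cache[key]
            * np.exp(-site.b_iso * ds2 / 4.0)
        )
        phase = [np.exp(-2j * np.pi * f.ravel() * x) for f, x in zip((fx, fy, fz), site.position)]
        F += radial * np.einsum("i,j,k->ijk", *phase)
    F[~keep] = 0.0
    return StructureFactorSet(F, voxel_size, cell, d_min=d_min, _d_star=d_star)


def synthesize_map(sf: StructureFactorSet, band: ResolutionBand | None = None,
                   imag_tol: float = 1e-6) -> PotentialMap:
    """Band-limit the coefficients and inverse-transform to a real map.

    F(000) is always excluded; the map is divided by the box volume
    (crystallographic convention), so Parseval gives
    ``sigma^2 = sum_{h in band} |F(h)|^2 / V^2``.
    """
    coeffs = sf.coefficients
    if band is not None:
        mask = band.mask(sf.d_star)
    else:
        mask = sf.d_star > 0
    if not np.any(mask):
        raise ValueError(
            f"no coefficients survive band {band}; grid supports "
            f"d* < {float(np.max(sf.d_star)):.4f} 1/A"
        )
    masked = np.where(mask, coeffs, 0.0)
    grid = np.fft.ifftn(masked) * (masked.size / sf.volume)
    scale = float(np.max(np.abs(grid))) or 1.0
    if float(np.max(np.abs(grid.imag))) > imag_tol * scale:
        raise ValueError("synthesis produced a non-negligible imaginary part; "
                         "input coefficients are not Hermitian")
    return PotentialMap(grid.real.copy(), sf.voxel_size)


def simulate_coulomb_map(
    model: AtomicModel,
    voxel_size: float,
    band: ResolutionBand,
) -> PotentialMap:
    """Compose structure-factor calculation and band-limited synthesis."""
    sf = structure_factors_from_model(model, voxel_size, d_min=band.d_high)
    return synthesize_map(sf, band)
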