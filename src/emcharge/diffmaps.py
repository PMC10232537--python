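"""Fourier difference maps (observed minus calculated) with band selection.

The hydrogen-omit map is the workhorse: the model without hydrogens supplies
F_c, the observed map (or a simulation from the full model) supplies F_o, and
the band-limited synthesis of F_o - F_c shows positive density at hydrogen
positions.  The charged-vs-neutral variant subtracts an all-neutral model
from one carrying fractional charges, isolating the low-resolution signature
of the charge.

Weighting: the default is the unweighted difference (w = 1).  An optional
per-shell Wiener-style weight w = SNR/(1+SNR) can be estimated from a pair of
half maps; the charge and hydrogen signatures studied here survive either
scheme.

Difference-map data are stored in units of the difference map's own sigma
(RMS about the mean over the whole box); the raw-scale sigma is kept so maps
of a series can also be compared on a common absolute scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .model import AtomicModel, AtomSite
from .maps import (
    PotentialMap,
    ResolutionBand,
    StructureFactorSet,
    structure_factors_from_model,
    synthesize_map,
)

__all__ = [
    "DifferenceMap",
    "omit_atoms",
    "fourier_difference_map",
    "resolution_series_maps",
    "shell_wiener_weights",
]


@dataclass
class DifferenceMap:
    """A sigma-scaled difference map plus the raw sigma for absolute scale."""

    data: np.ndarray  # in sigma units of this map
    voxel_size: float
    band: ResolutionBand
    sigma_raw: float  # one sigma in the raw (unscaled) map units
    provenance: str = ""

    @property
    def absolute(self) -> np.ndarray:
        """The map on the raw (pre-sigma-scaling) scale."""
        return self.data * self.sigma_raw

    def as_map(self) -> PotentialMap:
        return PotentialMap(self.data, self.voxel_size)

    def interpolate(self, positions, order: int = 1) -> np.ndarray:
        return self.as_map().interpolate(positions, order=order)


def omit_atoms(model: AtomicModel, selector) -> AtomicModel:
    """A copy of the model with selected sites removed, bonds pruned.

    ``selector`` is a predicate over :class:`AtomSite`, or the shorthand
    string ``"hydrogens"``.  An empty result is allowed.
    """
    if selector == "hydrogens":
        selector = lambda s: s.is_hydrogen
    keep = [i for i, s in enumerate(model.sites) if not selector(s)]
    return model.subset(keep)


def _observed_sf(obs, voxel_size=None, d_min=None) -> StructureFactorSet:
    if isinstance(obs, StructureFactorSet):
        return obs
    if isinstance(obs, PotentialMap):
        return obs.structure_factors()
    raise TypeError(f"obs must be StructureFactorSet or PotentialMap, got {type(obs)}")


def shell_wiener_weights(
    half1: StructureFactorSet, half2: StructureFactorSet, n_shells: int = 30
) -> Callable[[np.ndarray], np.ndarray]:
    """Per-shell w = SNR/(1+SNR) estimated from two half-map transforms.

    With halves F_i = S + N_i (independent noise of equal variance), the
    full-map noise power is mean|F1-F2|^2 / 4 per shell and the signal power
    is the full-map power minus that estimate (floored at zero).
    """
    d1, d2 = half1.coefficients, half2.coefficients
    ds = half1.d_star
    edges = np.linspace(0, float(ds.max()) * (1 + 1e-9), n_shells + 1)
    idx = np.clip(np.digitize(ds.ravel(), edges) - 1, 0, n_shells - 1)
    full = (d1 + d2) / 2.0
    p_full = np.bincount(idx, np.abs(full.ravel()) ** 2, n_shells)
    p_noise = np.bincount(idx, np.abs((d1 - d2).ravel()) ** 2, n_shells) / 4.0
    counts = np.maximum(np.bincount(idx, minlength=n_shells), 1)
    p_signal = np.maximum(p_full - p_noise, 0.0) / counts
    p_noise = p_noise / counts
    with np.errstate(divide="ignore", invalid="ignore"):
        w_shell = np.where(p_signal + p_noise > 0, p_signal / (p_signal + p_noise), 0.0)

    def weight(d_star: np.ndarray) -> np.ndarray:
        j = np.clip(np.digitize(d_star.ravel(), edges) - 1, 0, n_shells - 1)
        return w_shell[j].reshape(d_star.shape)

    return weight


def fourier_difference_map(
    obs,
    calc_model: AtomicModel,
    band: ResolutionBand,
    weighting: str = "none",
    halfmaps: tuple[StructureFactorSet, StructureFactorSet] | None = None,
    calc_sf: StructureFactorSet | None = None,
    provenance: str = "",
) -> DifferenceMap:
    """Band-limited synthesis of w * (F_o - F_c), sigma-scaled.

    ``obs`` is a StructureFactorSet or PotentialMap; F_c is computed from
    ``calc_model`` on the observed grid (or supplied pre-computed through
    ``calc_sf``).  ``weighting`` is "none" (w = 1) or "shell_variance"
    (requires ``halfmaps``).
    """
    f_obs = _observed_sf(obs)
    if calc_sf is None:
        f_calc = structure_factors_from_model(
            calc_model, f_obs.voxel_size, d_min=band.d_high
        )
    else:
        f_calc = calc_sf
    if f_calc.grid_shape != f_obs.grid_shape:
        raise ValueError(
            f"grid mismatch: obs {f_obs.grid_shape} vs calc {f_calc.grid_shape}"
        )
    delta = f_obs.coefficients - f_calc.coefficients
    if weighting == "shell_variance":
        if halfmaps is None:
            raise ValueError("shell_variance weighting requires halfmaps")
        delta = delta * shell_wiener_weights(*halfmaps)(f_obs.d_star)
    elif weighting != "none":
        raise ValueError(f"unknown weighting {weighting!r}")
    sf_delta = StructureFactorSet(
        delta, f_obs.voxel_size, f_obs.cell, _d_star=f_obs._d_star
    )
    raw = synthesize_map(sf_delta, band)
    sigma = raw.sigma
    data = raw.data / sigma if sigma > 0 else raw.data
    return DifferenceMap(data, raw.voxel_size, band, sigma_raw=sigma,
                         provenance=provenance)


def resolution_series_maps(
    obs,
    calc_model: AtomicModel,
    bands: Sequence[ResolutionBand],
    weighting: str = "none",
    halfmaps=None,
) -> list[DifferenceMap]:
    """One difference map per band, F_c computed once at the finest limit.

    Each map is sigma-scaled individually; its ``sigma_raw`` restores the
    shared absolute scale (``.absolute``) for cross-band comparison.
    """
    f_obs = _observed_sf(obs)
    finest = min(b.d_high for b in bands)
    f_calc = structure_factors_from_model(calc_model, f_obs.voxel_size, d_min=finest)
    return [
        fourier_difference_map(
            f_obs, calc_model, band, weighting=weighting, halfmaps=halfmaps,
            calc_sf=f_calc, provenance=f"band {band.d_low}-{band.d_high} A",
        )
        for band in bands
    ]
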