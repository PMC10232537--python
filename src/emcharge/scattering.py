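"""Electron scattering factors for neutral, ionic and partially charged atoms.

Electrons are scattered by the Coulomb potential of an atom, not by its
electron cloud, so the elastic electron scattering factor ``f_e(s)`` behaves
very differently from the X-ray form factor ``f_x(s)`` at low spatial
frequency: for an ion with net charge ``Z - f_x(0) != 0`` the Mott-Bethe
relation

    f_e(s) = k * (Z - f_x(s)) / s**2,      k = 1 / (8 * pi**2 * a0)

diverges as ``s -> 0`` with the sign of the net charge.  An anion such as
O(-) therefore has a *negative* scattering factor at low resolution that
converges to the neutral curve around ~2.5 A resolution -- the physical basis
for detecting charged carboxylate oxygens by resolution-band selection in
difference maps.

Partial charges are modelled as a linear combination of the neutral and the
fully ionized species, ``f_q = (1-|q|) f_neutral + |q| f_ion``.

Conventions: spatial frequency ``s = sin(theta)/lambda = 1/(2 d)`` in 1/A for
resolution ``d`` in A.  Both entry points are provided (`s_from_d`,
`d_from_s`) because figure axes in the literature use either.

Coefficient tables (Peng 1996 five-Gaussian electron factors; IT92
four-Gaussian X-ray factors including the O1- ionic entry) are shipped as a
versioned JSON data file; see ``data/scattering_coefficients.json`` for
provenance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "MOTT_BETHE_K",
    "ScatteringSpecies",
    "FormFactorCurve",
    "PartialCharge",
    "MottBetheDivergence",
    "load_coefficient_table",
    "species",
    "evaluate_gaussian_ff",
    "mott_bethe_ff",
    "partial_charge_ff",
    "ff_difference_profile",
    "electron_form_factor",
    "s_from_d",
    "d_from_s",
]

#: Mott-Bethe prefactor 1/(8 pi^2 a0) in Angstrom (a0 = Bohr radius).
MOTT_BETHE_K = 0.023933754


def s_from_d(d):
    """Spatial frequency s = 1/(2 d) [1/A] from resolution d [A]."""
    d = np.asarray(d, dtype=float)
    if np.any(d <= 0):
        raise ValueError("resolution d must be positive")
    return 1.0 / (2.0 * d)


def d_from_s(s):
    """Resolution d = 1/(2 s) [A] from spatial frequency s [1/A]."""
    s = np.asarray(s, dtype=float)
    if np.any(s <= 0):
        raise ValueError("s must be positive to convert to a resolution")
    return 1.0 / (2.0 * s)


class MottBetheDivergence(ZeroDivisionError):
    """Raised when f_e(0) is requested for a net-charged species."""


@dataclass(frozen=True)
class ScatteringSpecies:
    """An element or ion with a Gaussian form-factor parameterization.

    ``kind`` distinguishes the electron five-Gaussian parameterization
    (``constant == 0``) from the X-ray four-Gaussian + constant one.  For a
    neutral X-ray species ``f_x(0) = sum(a) + c`` equals the electron count Z.
    """

    element_symbol: str
    atomic_number: int
    charge_state: int
    gaussian_terms: tuple[tuple[float, float], ...]
    kind: str = "electron"  # "electron" | "xray"
    constant: float = 0.0

    def __post_init__(self):
        if self.atomic_number < 1:
            raise ValueError("atomic_number must be >= 1")
        if len(self.gaussian_terms) < 1:
            raise ValueError("at least one Gaussian term required")
        if self.kind not in ("electron", "xray"):
            raise ValueError(f"unknown kind {self.kind!r}")
        # The published IT92 ionic X-ray entries may carry one (slightly)
        # negative b; the positivity constraint applies to electron tables.
        if self.kind == "electron" and any(b <= 0 for _, b in self.gaussian_terms):
            raise ValueError("electron-parameterization widths b_i must be > 0")

    @property
    def n_electrons(self) -> int:
        return self.atomic_number - self.charge_state

    def __call__(self, s):
        return evaluate_gaussian_ff(self, s)


@dataclass(frozen=True)
class PartialCharge:
    """A fractional charge q in [-1, 1]; negative = anion direction."""

    q: float

    def __post_init__(self):
        if abs(self.q) > 1:
            raise ValueError(f"|q| must be <= 1, got {self.q}")


@dataclass
class FormFactorCurve:
    """A sampled scattering-factor curve f(s) with s strictly increasing."""

    s_values: np.ndarray
    f_values: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.s_values = np.asarray(self.s_values, dtype=float)
        self.f_values = np.asarray(self.f_values, dtype=float)
        if self.s_values.shape != self.f_values.shape:
            raise ValueError("s_values and f_values must have equal length")
        if np.any(self.s_values < 0):
            raise ValueError("s_values must be >= 0")
        if np.any(np.diff(self.s_values) <= 0):
            raise ValueError("s_values must be strictly increasing")

    def to_dataframe(self):
        """Columns (d, s, f) for CSV export / plotting."""
        import pandas as pd

        with np.errstate(divide="ignore"):
            d = np.where(self.s_values > 0, 1.0 / (2.0 * self.s_values), np.inf)
        return pd.DataFrame({"d": d, "s": self.s_values, "f": self.f_values})


@lru_cache(maxsize=1)
def load_coefficient_table() -> dict:
    """The shipped coefficient tables (electron 5-Gaussian, X-ray IT92)."""
    ref = resources.files("emcharge.data").joinpath("scattering_coefficients.json")
    return json.loads(ref.read_text())


def _table_key(symbol: str, charge: int) -> str:
    if charge == 0:
        return symbol
    return f"{symbol}{abs(charge)}{'-' if charge < 0 else '+'}"


@lru_cache(maxsize=None)
def species(symbol: str, charge: int = 0, kind: str = "electron") -> ScatteringSpecies:
    """Look up a tabulated species, e.g. ``species('O')`` or ``species('O', -1, 'xray')``.

    Raises KeyError when the table has no entry (notably there is no O1-
    *electron* entry in the adopted tables; use :func:`electron_form_factor`
    which synthesizes it through Mott-Bethe).
    """
    table = load_coefficient_table()
    section = "electron_5g" if kind == "electron" else "xray_4g"
    key = _table_key(symbol, charge)
    try:
        entry = table[section]["entries"][key]
    except KeyError:
        raise KeyError(f"no {kind} coefficient entry for {key!r}") from None
    return ScatteringSpecies(
        element_symbol=symbol,
        atomic_number=entry["Z"],
        charge_state=charge,
        gaussian_terms=tuple(zip(entry["a"], entry["b"])),
        kind=kind,
        constant=float(entry.get("c", 0.0)),
    )


def evaluate_gaussian_ff(sp: ScatteringSpecies, s):
    """f(s) = sum_i a_i exp(-b_i s^2) (+ c for X-ray entries); vectorized in s."""
    s = np.asarray(s, dtype=float)
    if np.any(s < 0):
        raise ValueError("s must be >= 0")
    s2 = s * s
    a = np.array([t[0] for t in sp.gaussian_terms])
    b = np.array([t[1] for t in sp.gaussian_terms])
    f = np.tensordot(a, np.exp(-np.multiply.outer(b, s2)), axes=1) + sp.constant
    return f if f.ndim else float(f)


def mott_bethe_ff(Z: int, f_x, s, *, zero_tol: float = 1e-2):
    """Electron scattering factor from an X-ray form factor via Mott-Bethe.

    ``f_e(s) = MOTT_BETHE_K * (Z - f_x(s)) / s**2`` with Z the *nuclear*
    charge (atomic number).  ``f_x`` may be a callable or an X-ray
    :class:`ScatteringSpecies` (for which the neutral ``s = 0`` limit
    ``k * sum(a_i b_i)`` is evaluated analytically).

    Raises :class:`MottBetheDivergence` if ``s = 0`` is requested for a
    species with net charge (``f_x(0) != Z``), where the factor diverges.
    """
    s = np.asarray(s, dtype=float)
    if np.any(s < 0):
        raise ValueError("s must be >= 0")
    fx = f_x if callable(f_x) else None
    scalar = s.ndim == 0
    s = np.atleast_1d(s)
    out = np.empty_like(s)
    nz = s > 0
    fx_vals = f_x(s[nz]) if fx else evaluate_gaussian_ff(f_x, s[nz])
    out[nz] = MOTT_BETHE_K * (Z - np.asarray(fx_vals)) / (s[nz] ** 2)
    if np.any(~nz):
        fx0 = float(f_x(0.0)) if fx else evaluate_gaussian_ff(f_x, 0.0)
        if abs(Z - fx0) > zero_tol:
            raise MottBetheDivergence(
                f"f_e(0) diverges for net charge {Z - fx0:+.3f}; "
                "evaluate at s > 0 instead"
            )
        if isinstance(f_x, ScatteringSpecies):
            limit = MOTT_BETHE_K * sum(a * b for a, b in f_x.gaussian_terms)
        else:
            eps = 1e-4
            limit = MOTT_BETHE_K * (Z - float(f_x(eps))) / eps**2
        out[~nz] = limit
    return float(out[0]) if scalar else out


def partial_charge_ff(neutral, ion, q, s):
    """Linear combination (1-|q|) f_neutral(s) + |q| f_ion(s).

    ``neutral`` and ``ion`` must be parameterizations of the same chemical
    element; ``q`` is a :class:`PartialCharge` or a float in [-1, 1].  The
    ion's charge sign, when known, must agree with the sign of q.
    """
    if isinstance(q, PartialCharge):
        q = q.q
    if abs(q) > 1:
        raise ValueError(f"|q| must be <= 1, got {q}")
    if isinstance(neutral, ScatteringSpecies) and isinstance(ion, ScatteringSpecies):
        if neutral.element_symbol != ion.element_symbol:
            raise ValueError(
                f"element mismatch: {neutral.element_symbol} vs {ion.element_symbol}"
            )
    w = abs(q)
    f_n = neutral(s) if isinstance(neutral, ScatteringSpecies) else neutral(s)
    f_i = ion(s) if isinstance(ion, ScatteringSpecies) else ion(s)
    return (1.0 - w) * np.asarray(f_n) + w * np.asarray(f_i)


def ff_difference_profile(neutral, charged_f, d_grid, label: str = "") -> FormFactorCurve:
    """f_charged - f_neutral sampled on a resolution grid (descending d)."""
    d_grid = np.asarray(d_grid, dtype=float)
    if np.any(d_grid <= 0):
        raise ValueError("resolutions must be positive")
    s = s_from_d(d_grid)
    order = np.argsort(s)
    f_n = neutral(s[order]) if callable(neutral) else evaluate_gaussian_ff(neutral, s[order])
    f_c = charged_f(s[order])
    return FormFactorCurve(s[order], np.asarray(f_c) - np.asarray(f_n), label=label)


@lru_cache(maxsize=None)
def electron_form_factor(symbol: str, q: float = 0.0) -> Callable[[np.ndarray], np.ndarray]:
    """Electron scattering factor f_e(s) for an element with fractional charge q.

    * q == 0: the tabulated neutral five-Gaussian curve.
    * integer q: Mott-Bethe applied to the tabulated ionic X-ray curve.
    * fractional q: linear combination of the neutral curve and the full ion
      of matching sign, weighted by |q|.

    The returned callable accepts scalar or array s >= 0.  At s == 0 a
    net-charged factor diverges; the callable substitutes the *neutral*
    value there (the F(000) term is excluded from every map synthesis in
    this package, so the substitution is never observable in a map) rather
    than raising mid-grid.
    """
    q = float(q)
    if abs(q) > 1:
        raise ValueError(f"|q| must be <= 1, got {q}")
    neutral = species(symbol, 0, "electron")
    if q == 0.0:
        return neutral

    ion_charge = int(np.sign(q))
    Z = neutral.atomic_number
    neutral_x = species(symbol, 0, "xray")
    try:
        ion_x = species(symbol, ion_charge, "xray")
        fx_ion = ion_x  # ScatteringSpecies, used directly
    except KeyError:
        # Ion absent from the X-ray table (e.g. O1+): mirror the valence
        # electron of the opposite ion, f_x(+1) = 2 f_x(0) - f_x(-1).  This
        # treats the removed electron as the image of the added one, which
        # also makes the partial-charge difference antisymmetric in q.
        opp = species(symbol, -ion_charge, "xray")

        def fx_ion(s, _n=neutral_x, _o=opp):
            return 2.0 * evaluate_gaussian_ff(_n, s) - evaluate_gaussian_ff(_o, s)

    def f_ion(s):
        # Neutral Peng curve plus the Mott-Bethe transform of the ionic
        # charge redistribution (f_x0 - f_x,ion)/s^2.  Anchoring the ionic
        # perturbation on the adopted neutral curve keeps q = 0 exact and
        # makes the partial-charge difference antisymmetric in q.
        s = np.atleast_1d(np.asarray(s, dtype=float))
        out = np.empty_like(s)
        nz = s > 0
        fx0 = evaluate_gaussian_ff(neutral_x, s[nz])
        fxi = (fx_ion(s[nz]) if callable(fx_ion)
               else evaluate_gaussian_ff(fx_ion, s[nz]))
        out[nz] = evaluate_gaussian_ff(neutral, s[nz]) + MOTT_BETHE_K * (
            np.asarray(fx0) - np.asarray(fxi)
        ) / (s[nz] ** 2)
        out[~nz] = evaluate_gaussian_ff(neutral, 0.0)  # F(000) placeholder
        return out

    if q == float(ion_charge):
        result = f_ion
    else:
        def result(s, _w=abs(q)):
            return (1.0 - _w) * np.asarray(evaluate_gaussian_ff(neutral, s)) + _w * f_ion(s)

    return result
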