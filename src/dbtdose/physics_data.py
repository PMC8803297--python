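"""Embedded material definitions and photon-interaction coefficients, 1-40 keV.

Coefficient tables ship as delimited text files under :mod:`dbtdose.data`
(one per material, columns ``energy_keV, mu_total, mu_pe, mu_incoh, mu_coh,
mu_en`` in cm^2/g) together with a material registry and Cromer-Mann atomic
form-factor coefficients used for coherent-scatter angle sampling.  Lookups
interpolate log-log between grid points, the standard choice for photon
cross sections in this energy range.
"""
from __future__ import annotations

import functools
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

__all__ = [
    "Material",
    "CoefficientTable",
    "EnergyRangeError",
    "available_materials",
    "get_material",
    "get_table",
    "lookup_mu",
    "mixture_mu",
    "form_factor",
    "material_form_factor_sq",
]

E_MIN, E_MAX = 1.0, 40.0  # keV, table coverage

KINDS = {
    "total": "mu_total",
    "photoelectric": "mu_pe",
    "incoherent": "mu_incoh",
    "coherent": "mu_coh",
    "energy_absorption": "mu_en",
}


class EnergyRangeError(ValueError):
    """Photon energy outside the tabulated 1-40 keV range."""


@dataclass(frozen=True)
class Material:
    """A homogeneous material: density and elemental mass fractions."""

    name: str
    density: float  # g/cm^3
    composition: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError(f"material {self.name!r}: density must be > 0")
        total = sum(self.composition.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(
                f"material {self.name!r}: mass fractions sum to {total}, not 1"
            )


class CoefficientTable:
    """Mass attenuation / energy-absorption coefficients on an energy grid.

    Parameters
    ----------
    material
        The material the table belongs to.
    energies
        Strictly ascending grid in keV covering [1, 40].
    coefficients
        Mapping of column name (``mu_total`` ...) to arrays in cm^2/g.
    """

    def __init__(self, material: Material, energies: np.ndarray,
                 coefficients: dict[str, np.ndarray]) -> None:
        energies = np.asarray(energies, float)
        if not np.all(np.diff(energies) > 0):
            raise ValueError("energies must be strictly ascending")
        if energies[0] > E_MIN or energies[-1] < E_MAX:
            raise ValueError("table must cover [1, 40] keV")
        self.material = material
        self.energies = energies
        self.coefficients = {k: np.asarray(v, float) for k, v in coefficients.items()}
        self._log_e = np.log(energies)
        self._log_c = {k: np.log(np.maximum(v, 1e-300))
                       for k, v in self.coefficients.items()}

    def mu(self, energy, kind: str = "total"):
        """Interpolated mass coefficient (cm^2/g); log-log linear between
        grid points, exact at grid points."""
        col = KINDS.get(kind, kind)
        if col not in self.coefficients:
            raise KeyError(f"unknown interaction kind {kind!r}")
        e = np.asarray(energy, float)
        if np.any(e < E_MIN) or np.any(e > E_MAX):
            bad = e[(e < E_MIN) | (e > E_MAX)]
            raise EnergyRangeError(
                f"energy {np.atleast_1d(bad)[0]:g} keV outside "
                f"[{E_MIN:g}, {E_MAX:g}] keV for material "
                f"{self.material.name!r}"
            )
        out = np.exp(np.interp(np.log(e), self._log_e, self._log_c[col]))
        return float(out) if np.isscalar(energy) else out

    def linear_mu(self, energy, kind: str = "total"):
        """Linear attenuation coefficient (1/cm) at the material density."""
        return self.mu(energy, kind) * self.material.density


def _data_text(name: str) -> str:
    return resources.files("dbtdose.data").joinpath(name).read_text()


@functools.lru_cache(maxsize=1)
def _registry() -> dict[str, dict]:
    return yaml.safe_load(_data_text("materials.yaml"))


def available_materials() -> list[str]:
    return sorted(_registry())


@functools.lru_cache(maxsize=None)
def get_material(name: str) -> Material:
    try:
        entry = _registry()[name]
    except KeyError:
        raise KeyError(f"unknown material {name!r}; see available_materials()") from None
    return Material(name=name, density=float(entry["density"]),
                    composition={k: float(v) for k, v in entry["composition"].items()})


@functools.lru_cache(maxsize=None)
def get_table(name: str) -> CoefficientTable:
    material = get_material(name)
    rows = np.genfromtxt(_data_text(f"mu_{name}.tsv").splitlines(), names=True)
    cols = {k: np.asarray(rows[k]) for k in rows.dtype.names if k != "energy_keV"}
    return CoefficientTable(material, np.asarray(rows["energy_keV"]), cols)


def lookup_mu(table: CoefficientTable, energy, kind: str = "total"):
    """Functional wrapper around :meth:`CoefficientTable.mu`."""
    return table.mu(energy, kind)


def mixture_mu(composition: dict[str, float], energy, kind: str = "total"):
    """Bragg-additivity coefficient for an elemental mass-fraction map."""
    total = sum(composition.values())
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"mass fractions sum to {total}, not 1")
    out = 0.0
    for sym, w in composition.items():
        out = out + w * get_table(sym).mu(energy, kind)
    return out


# ---------------------------------------------------------------------------
# Atomic form factors (coherent-scatter angle sampling)

@functools.lru_cache(maxsize=1)
def _cromer_mann() -> dict[str, tuple[np.ndarray, np.ndarray, float, float]]:
    out = {}
    for line in _data_text("cromer_mann.tsv").splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        sym = parts[0]
        vals = [float(v) for v in parts[1:]]
        out[sym] = (np.array(vals[2:6]), np.array(vals[6:10]), vals[10], vals[1])
    return out


def form_factor(element: str, x):
    """Atomic form factor f0 at momentum transfer x = sin(theta/2)/lambda
    (1/Angstrom).  Clamped at the Cromer-Mann fit limit of 2/Angstrom."""
    a, b, c, _A = _cromer_mann()[element]
    x2 = np.minimum(np.asarray(x, float), 2.0) ** 2
    return np.sum(a[:, None] * np.exp(-b[:, None] * x2[None, :]), axis=0).reshape(
        np.shape(x)) + c if np.ndim(x) else float(np.sum(a * np.exp(-b * x2)) + c)


def material_form_factor_sq(material: Material, x: np.ndarray) -> np.ndarray:
    """Squared molecular form factor per gram (independent-atom sum),
    up to a constant factor -- only the shape matters for sampling."""
    x = np.asarray(x, float)
    out = np.zeros_like(x)
    cm = _cromer_mann()
    for sym, w in material.composition.items():
        a, b, c, A = cm[sym]
        x2 = np.minimum(x, 2.0) ** 2
        f = np.exp(-b[:, None] * x2[None, :]).T @ a + c
        out += (w / A) * f**2
    return out
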