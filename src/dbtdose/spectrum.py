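"""W-anode tube spectra, filtration, air kerma, HVL and the heel model.

The bremsstrahlung continuum follows the Kramers form (fluence per unit
energy proportional to (E0 - E)/E) with tungsten L characteristic lines
added below their excitation threshold; target self-attenuation and the
unknown inherent filtration of the housing are folded into a single
aluminium-equivalent thickness.  That thickness is the model's one free
parameter: it is tuned once so the 28 kV W/Rh beam reproduces the system's
measured half-value layer (0.54 mm Al) and is then held fixed for every
other tube voltage.  Beam-quality agreement at 25 and 34 kV is therefore a
prediction, not a fit.
"""
from __future__ import annotations

import functools
import io
from dataclasses import dataclass, field

import numpy as np

from .physics_data import get_material, get_table

__all__ = [
    "EnergySpectrum",
    "HeelModel",
    "generate_spectrum",
    "filter_spectrum",
    "air_kerma",
    "compute_hvl",
    "mean_energy",
    "heel_weight",
    "tune_inherent_filtration",
    "default_filtration",
    "read_spectrum",
    "write_spectrum",
]

E_FLOOR = 1.0          # keV, lower table limit and transport cutoff
DEFAULT_BIN_WIDTH = 0.25  # keV
HVL_REFERENCE_KVP = 28.0
HVL_REFERENCE_MM_AL = 0.54  # measured beam quality of the 28 kV W/Rh technique

# Tungsten L-series lines (keV) and approximate relative intensities.
_W_L_LINES = [(8.335, 0.11), (8.397, 1.00), (9.672, 0.67),
              (9.961, 0.21), (11.286, 0.13)]
_L_LINE_FRACTION = 0.03  # unfiltered L-line fluence relative to continuum


@dataclass
class EnergySpectrum:
    """Binned relative photon fluence for one tube voltage / filtration."""

    kvp: float
    bin_edges: np.ndarray      # keV, uniform, last edge == kvp
    fluence: np.ndarray        # relative photons per bin, >= 0
    anode: str = "W"
    filtration: list[tuple[str, float]] = field(default_factory=list)  # (material, mm)

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, float)
        self.fluence = np.asarray(self.fluence, float)
        widths = np.diff(self.bin_edges)
        if not np.allclose(widths, widths[0]):
            raise ValueError("bin widths must be uniform")
        if abs(self.bin_edges[-1] - self.kvp) > 1e-9:
            raise ValueError("maximum bin edge must equal the tube voltage")
        if np.any(self.fluence < 0):
            raise ValueError("fluence must be non-negative")
        if self.fluence.sum() <= 0:
            raise ValueError("total fluence must be positive")

    @property
    def energies(self) -> np.ndarray:
        """Bin midpoint energies (keV)."""
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def normalized(self) -> "EnergySpectrum":
        return EnergySpectrum(self.kvp, self.bin_edges,
                              self.fluence / self.fluence.sum(),
                              self.anode, list(self.filtration))


@dataclass(frozen=True)
class HeelModel:
    """Linear anode heel gradient along the chest-wall -> nipple axis.

    The fluence weight is 1.0 at the chest-wall field edge and falls
    linearly to ``endpoint_ratio`` at the far (nipple-side) edge.
    """

    endpoint_ratio: float = 0.85
    axis: tuple[float, float] = (0.0, 1.0)  # unit vector in the support plane

    def __post_init__(self) -> None:
        if not 0.0 < self.endpoint_ratio <= 1.0:
            raise ValueError("endpoint_ratio must be in (0, 1]")


def heel_weight(model: HeelModel, fractional_position) -> np.ndarray | float:
    """Heel weight at a fractional position along the heel axis.

    ``fractional_position`` is 0 at the chest-wall edge of the field and 1
    at the far edge; points outside the field raise a ``ValueError``.
    """
    f = np.asarray(fractional_position, float)
    if np.any((f < -1e-9) | (f > 1 + 1e-9)):
        raise ValueError("point outside the collimated field")
    w = 1.0 + (model.endpoint_ratio - 1.0) * np.clip(f, 0.0, 1.0)
    return float(w) if np.isscalar(fractional_position) else w


def generate_spectrum(kvp: float, anode: str = "W",
                      filtration: list[tuple[str, float]] | None = None,
                      bin_width: float = DEFAULT_BIN_WIDTH,
                      l_line_fraction: float = _L_LINE_FRACTION) -> EnergySpectrum:
    """Semi-empirical W-anode spectrum at ``kvp`` with the given filtration.

    ``filtration`` is a list of (material name, thickness in mm); ``None``
    selects the default W/Rh stack (Be window + Rh filter + tuned
    Al-equivalent inherent filtration).
    """
    if anode != "W":
        raise ValueError(f"unsupported anode {anode!r}: only W is modelled")
    if not 20.0 <= kvp <= 40.0:
        raise ValueError("tube voltage must lie in [20, 40] kV")
    n_bins = int(round((kvp - E_FLOOR) / bin_width))
    if abs(E_FLOOR + n_bins * bin_width - kvp) > 1e-9:
        raise ValueError("bin width must evenly divide (kvp - 1 keV)")
    edges = E_FLOOR + bin_width * np.arange(n_bins + 1)
    e = 0.5 * (edges[:-1] + edges[1:])
    fluence = np.clip(kvp - e, 0.0, None) / e  # Kramers continuum
    if l_line_fraction > 0:
        total = fluence.sum()
        lines = [(el, w) for el, w in _W_L_LINES if el < kvp]
        norm = sum(w for _, w in lines)
        for el, w in lines:
            idx = min(int((el - E_FLOOR) / bin_width), n_bins - 1)
            fluence[idx] += l_line_fraction * total * w / norm
    spec = EnergySpectrum(kvp, edges, fluence, anode, [])
    for mat, mm in (default_filtration() if filtration is None else filtration):
        spec = filter_spectrum(spec, mat, mm)
    return spec.normalized()


def filter_spectrum(s: EnergySpectrum, material, thickness_mm: float) -> EnergySpectrum:
    """Attenuate the spectrum through ``thickness_mm`` of ``material``
    (Beer-Lambert per bin, narrow-beam total attenuation)."""
    if thickness_mm < 0:
        raise ValueError("filter thickness must be >= 0")
    if thickness_mm == 0:
        return EnergySpectrum(s.kvp, s.bin_edges, s.fluence.copy(), s.anode,
                              list(s.filtration))
    name = material if isinstance(material, str) else material.name
    table = get_table(name)
    atten = np.exp(-table.linear_mu(s.energies) * thickness_mm / 10.0)
    return EnergySpectrum(s.kvp, s.bin_edges, s.fluence * atten, s.anode,
                          s.filtration + [(name, thickness_mm)])


@functools.lru_cache(maxsize=1)
def _muen_air_interp():
    table = get_table("air")
    return table


def air_kerma(s: EnergySpectrum) -> float:
    """Fluence-weighted air kerma, sum of fluence * E * (mu_en/rho)_air per
    bin (relative units)."""
    e = s.energies
    return float(np.sum(s.fluence * e * _muen_air_interp().mu(e, "energy_absorption")))


def mean_energy(s: EnergySpectrum) -> float:
    return float(np.sum(s.fluence * s.energies) / s.fluence.sum())


def compute_hvl(s: EnergySpectrum, tol_mm: float = 1e-4, max_iter: int = 200) -> float:
    """Half-value layer in mm Al: the Al thickness halving the air kerma,
    found by bisection."""
    k0 = air_kerma(s)
    lo, hi = 0.0, 5.0
    if air_kerma(filter_spectrum(s, "Al", hi)) > 0.5 * k0:
        raise RuntimeError("HVL bracket [0, 5] mm Al failed")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        if air_kerma(filter_spectrum(s, "Al", mid)) > 0.5 * k0:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol_mm:
            return 0.5 * (lo + hi)
    raise RuntimeError(f"HVL bisection did not converge in {max_iter} iterations")


# ---------------------------------------------------------------------------
# Inherent-filtration calibration

BASE_FILTRATION: list[tuple[str, float]] = [("Be", 1.0), ("Rh", 0.05)]


@functools.lru_cache(maxsize=8)
def tune_inherent_filtration(target_hvl_mm: float = HVL_REFERENCE_MM_AL,
                             kvp: float = HVL_REFERENCE_KVP,
                             tol_mm: float = 1e-4) -> float:
    """Al-equivalent inherent filtration (mm) that reproduces the measured
    HVL of the reference beam; bisection on the monotone HVL(thickness)."""
    def hvl_at(t_al: float) -> float:
        s = generate_spectrum(kvp, filtration=BASE_FILTRATION + [("Al", t_al)])
        return compute_hvl(s)

    lo, hi = 0.0, 10.0
    if hvl_at(lo) > target_hvl_mm or hvl_at(hi) < target_hvl_mm:
        raise RuntimeError("inherent-filtration bracket failed")
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if hvl_at(mid) < target_hvl_mm:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol_mm:
            break
    return 0.5 * (lo + hi)


def default_filtration() -> list[tuple[str, float]]:
    """Default W/Rh filtration stack with the tuned inherent Al."""
    return BASE_FILTRATION + [("Al", tune_inherent_filtration())]


# ---------------------------------------------------------------------------
# Spectrum file IO: two-column text (energy_keV, relative_fluence)

def write_spectrum(s: EnergySpectrum, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# kvp={s.kvp} anode={s.anode} "
                 f"filtration={';'.join(f'{m}:{t}' for m, t in s.filtration)}\n")
        fh.write("# energy_keV relative_fluence (bin midpoints)\n")
        for e, f in zip(s.energies, s.fluence):
            fh.write(f"{e:.6g} {f:.8e}\n")


def read_spectrum(path) -> EnergySpectrum:
    kvp = None
    anode = "W"
    filtration: list[tuple[str, float]] = []
    rows = []
    text = path.read_text() if hasattr(path, "read_text") else open(path).read()
    for line in io.StringIO(text):
        line = line.strip()
        if line.startswith("#"):
            for tokenpair in line[1:].split():
                if "=" in tokenpair:
                    key, val = tokenpair.split("=", 1)
                    if key == "kvp":
                        kvp = float(val)
                    elif key == "anode":
                        anode = val
                    elif key == "filtration" and val:
                        filtration = [(m, float(t)) for m, t in
                                      (pair.split(":") for pair in val.split(";"))]
            continue
        if line:
            e, f = line.split()
            rows.append((float(e), float(f)))
    e = np.array([r[0] for r in rows])
    fl = np.array([r[1] for r in rows])
    width = e[1] - e[0]
    edges = np.concatenate([e - width / 2, [e[-1] + width / 2]])
    if kvp is None:
        kvp = edges[-1]
    return EnergySpectrum(kvp, edges, fl, anode, filtration)
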