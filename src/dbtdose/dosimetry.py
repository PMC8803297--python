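"""The closed-form dosimetry chain from dosimeter readings to average
glandular dose (AGD).

The chain follows the standard quality-control formalism for
mammography/DBT dosimetry:

* OSLD calibration against a reference ionization chamber,
  C = Ki / (Ko - BG);
* entrance surface air kerma divided by the backscatter factor gives the
  incident air kerma at the breast upper surface, K = ESAK / BSF;
* AGD = K * g * c * s * T, where g converts incident air kerma to AGD for
  a 50%-glandularity breast, c corrects to the actual glandularity, s
  corrects for the non-Mo/Mo spectrum, and T corrects for the moving tube
  of the tomosynthesis (3D) acquisition.  T applies only in 3D mode; for
  the fixed-tube 2D acquisition it is identically 1.
* the combined measurement uncertainty is the quadrature sum of its
  components.

The g/c/s/T values and the per-beam calibration factors ship as a small
delimited table (one row per tube voltage) and can be overridden with a
user file of the same layout.
"""
from __future__ import annotations

import functools
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "ConversionFactors",
    "CalibrationRecord",
    "UncertaintyBudget",
    "AGDResult",
    "load_factor_table",
    "get_factors",
    "stored_calibration_factor",
    "pmma_to_breast",
    "calibration_factor",
    "apply_calibration",
    "incident_kerma_from_esak",
    "compute_agd",
    "combined_uncertainty",
    "percent_difference",
]

# PMMA phantom thickness (cm) -> (equivalent breast thickness cm, glandularity %)
PMMA_BREAST_TABLE = {
    2.0: (2.1, 97.0),
    4.0: (4.5, 40.0),
    7.0: (9.0, 4.0),
}


@dataclass(frozen=True)
class ConversionFactors:
    """g/c/s/T conversion factors for one tube voltage."""

    kvp: float
    g: float      # incident air kerma -> AGD, 50% glandularity
    c: float      # glandularity correction
    s: float      # target/filter (spectrum) correction
    T: float      # tube-motion correction, applied in 3D mode only

    def __post_init__(self) -> None:
        if min(self.g, self.c, self.s, self.T) <= 0:
            raise ValueError("conversion factors must be positive")
        if self.g >= 1:
            raise ValueError("g must be < 1 (AGD is below incident kerma)")
        if self.T > 1:
            raise ValueError("T must be <= 1")


@dataclass(frozen=True)
class CalibrationRecord:
    """OSLD calibration against the reference chamber for one beam."""

    Ki: float     # mean chamber incident air kerma, mGy
    Ko: float     # mean OSLD readout, mGy
    BG: float     # mean control-dot background, mGy

    def __post_init__(self) -> None:
        if self.Ki <= 0:
            raise ValueError("chamber kerma Ki must be positive")
        if self.Ko - self.BG <= 0:
            raise ValueError("OSLD signal below background (Ko <= BG)")

    @property
    def C(self) -> float:
        return self.Ki / (self.Ko - self.BG)


@dataclass(frozen=True)
class UncertaintyBudget:
    components: tuple[tuple[str, float], ...]

    @property
    def combined(self) -> float:
        return float(np.sqrt(sum(v**2 for _, v in self.components)))

    @property
    def display(self) -> float:
        """Combined uncertainty rounded to one decimal for reports."""
        return round(self.combined, 1)


@dataclass(frozen=True)
class AGDResult:
    mode: str
    breast_thickness: float   # cm
    glandularity: float       # percent
    K: float                  # incident air kerma at the surface, mGy
    factors: ConversionFactors
    AGD: float                # mGy


@functools.lru_cache(maxsize=4)
def load_factor_table(path: str | None = None) -> pd.DataFrame:
    """Factor table: columns kvp, C, g, c, s, T (one row per tube voltage)."""
    if path is None:
        text = resources.files("dbtdose.data").joinpath("factors.tsv").read_text()
        from io import StringIO
        return pd.read_csv(StringIO(text), sep="\t", comment="#")
    return pd.read_csv(path, sep=None, engine="python", comment="#")


def _row_for(kvp: float, path: str | None = None) -> pd.Series:
    table = load_factor_table(path)
    match = table[np.isclose(table["kvp"], kvp)]
    if match.empty:
        raise KeyError(f"no conversion factors stored for {kvp:g} kV")
    return match.iloc[0]


def get_factors(kvp: float, path: str | None = None) -> ConversionFactors:
    row = _row_for(kvp, path)
    return ConversionFactors(kvp=float(row["kvp"]), g=float(row["g"]),
                             c=float(row["c"]), s=float(row["s"]),
                             T=float(row["T"]))


def stored_calibration_factor(kvp: float, path: str | None = None) -> float:
    """The calibration factor C measured for this beam quality (stored as a
    constant alongside the conversion factors, not recomputed)."""
    return float(_row_for(kvp, path)["C"])


def pmma_to_breast(pmma_thickness_cm: float) -> tuple[float, float]:
    """Equivalent breast thickness (cm) and glandularity (%) for a PMMA
    phantom thickness; linear interpolation between the tabulated points
    for non-standard thicknesses."""
    t = float(pmma_thickness_cm)
    if not 2.0 <= t <= 7.0:
        raise ValueError(f"PMMA thickness {t:g} cm outside the 2.0-7.0 cm "
                         "equivalence table")
    if t in PMMA_BREAST_TABLE:
        return PMMA_BREAST_TABLE[t]
    keys = np.array(sorted(PMMA_BREAST_TABLE))
    thick = np.interp(t, keys, [PMMA_BREAST_TABLE[k][0] for k in keys])
    gland = np.interp(t, keys, [PMMA_BREAST_TABLE[k][1] for k in keys])
    return float(thick), float(gland)


def calibration_factor(Ki: float, Ko: float, BG: float) -> CalibrationRecord:
    """Calibration factor of the OSLD against the chamber:
    C = Ki / (Ko - BG)."""
    return CalibrationRecord(Ki=Ki, Ko=Ko, BG=BG)


def apply_calibration(readout_mGy: float, record: CalibrationRecord) -> float:
    """Background-subtracted, calibrated kerma: (readout - BG) * C."""
    if readout_mGy <= record.BG:
        raise ValueError("readout at or below background")
    return (readout_mGy - record.BG) * record.C


def incident_kerma_from_esak(esak_mGy: float, bsf: float) -> float:
    """Incident air kerma at the entrance plane: K = ESAK / BSF."""
    if bsf < 1.0:
        raise ValueError(f"backscatter factor {bsf:g} < 1 is unphysical")
    return esak_mGy / bsf


def compute_agd(K_mGy: float, factors: ConversionFactors,
                mode: str, breast_thickness_cm: float | None = None,
                glandularity_pct: float | None = None) -> AGDResult:
    """AGD = K * g * c * s * T, with T applied only for the moving-tube 3D
    acquisition."""
    if K_mGy < 0:
        raise ValueError("incident air kerma must be >= 0")
    if mode not in ("2D", "3D"):
        raise ValueError(f"unknown acquisition mode {mode!r}")
    t_factor = factors.T if mode == "3D" else 1.0
    agd = K_mGy * factors.g * factors.c * factors.s * t_factor
    return AGDResult(mode=mode,
                     breast_thickness=breast_thickness_cm or float("nan"),
                     glandularity=glandularity_pct or float("nan"),
                     K=K_mGy, factors=factors, AGD=agd)


def combined_uncertainty(*components_pct: float,
                         labels: tuple[str, ...] | None = None
                         ) -> UncertaintyBudget:
    """Quadrature combination of relative uncertainty components (%)."""
    if any(c < 0 for c in components_pct):
        raise ValueError("uncertainty components must be >= 0")
    if labels is None:
        labels = tuple(f"component_{i + 1}" for i in range(len(components_pct)))
    return UncertaintyBudget(tuple(zip(labels, components_pct)))


def percent_difference(test: float, reference: float) -> float:
    """Signed percent difference, 100 * (test - reference) / reference."""
    if reference == 0:
        raise ValueError("reference value must be nonzero")
    return 100.0 * (test - reference) / reference
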