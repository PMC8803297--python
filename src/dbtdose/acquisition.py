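"""Compose projections into 2D / 3D acquisitions: ESAK maps, backscatter
factors, angular response and surface-dose dispersion.

The 2D (fixed tube) acquisition is a single 0-degree projection; the 3D
(tomosynthesis) acquisition is 25 equally weighted projections across the
+-25 degree sweep.  The backscatter factor (BSF) of a configuration is the
per-disc ratio of entrance kerma with the phantom present to the free-in-air
kerma with the phantom removed (discs kept at the same heights), averaged
over the 20 dosimeter positions.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mc_transport import Scene, TallyResult, run_projection

__all__ = [
    "AcquisitionProtocol",
    "EsakMap",
    "BsfResult",
    "make_protocol",
    "run_acquisition",
    "angular_response",
    "compute_bsf",
    "esak_cv",
]

# Exposure parameters selected by the system's automatic exposure control
# for each PMMA thickness: kV -> (mAs 2D, mAs 3D, PMMA cm, HVL mm Al).
EXPOSURE_TABLE = {
    25.0: (71.0, 71.0, 2.0, 0.52),
    28.0: (125.0, 110.0, 4.0, 0.54),
    34.0: (200.0, 180.0, 7.0, 0.59),
}

N_PROJECTIONS_3D = 25
HALF_RANGE_3D = 24.0  # degrees; 25 angles at 2-degree pitch include 0


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Acquisition mode with its exposure parameters and projection set."""

    mode: str                  # "2D" | "3D"
    kvp: float
    mAs: float | None
    angles: tuple[float, ...]
    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.mode not in ("2D", "3D"):
            raise ValueError(f"unknown acquisition mode {self.mode!r}")
        if abs(sum(self.weights) - 1.0) > 1e-12:
            raise ValueError("projection weights must sum to 1")
        if len(self.angles) != len(self.weights):
            raise ValueError("angles and weights must pair up")


def make_protocol(mode: str, kvp: float,
                  n_projections: int = N_PROJECTIONS_3D,
                  half_range_deg: float = HALF_RANGE_3D) -> AcquisitionProtocol:
    """Build the standard acquisition protocol for a tube voltage.

    2D is a single full-weight projection at 0 degrees.  3D defaults to 25
    projections at -24..+24 degrees in 2-degree steps (symmetric, includes
    0) with uniform weight 1/25 each.
    """
    if mode not in ("2D", "3D"):
        raise ValueError(f"unknown acquisition mode {mode!r}")
    entry = EXPOSURE_TABLE.get(float(kvp))
    if mode == "2D":
        mas = entry[0] if entry else None
        return AcquisitionProtocol("2D", kvp, mas, (0.0,), (1.0,))
    mas = entry[1] if entry else None
    angles = tuple(np.linspace(-half_range_deg, half_range_deg,
                               n_projections))
    weights = (1.0 / n_projections,) * n_projections
    return AcquisitionProtocol("3D", kvp, mas, angles, weights)


@dataclass
class EsakMap:
    """Per-disc ESAK (per source photon) for one acquisition."""

    disc_ids: np.ndarray
    esak: np.ndarray
    uncertainty: np.ndarray         # absolute standard error
    protocol: AcquisitionProtocol
    per_angle: dict[float, TallyResult] = field(default_factory=dict)
    converged: bool = True

    @property
    def mean(self) -> float:
        return float(self.esak.mean())


def run_acquisition(protocol: AcquisitionProtocol, scene: Scene,
                    n_photons: int = 100_000, n_batches: int = 10,
                    seed: int = 0,
                    uncertainty_threshold: float = 0.02) -> EsakMap:
    """Run every projection of the protocol and combine them as the
    weighted sum over angles (uncertainties in quadrature)."""
    streams = np.random.SeedSequence(seed).spawn(len(protocol.angles))
    esak = None
    var = None
    per_angle = {}
    converged = True
    for angle, weight, stream in zip(protocol.angles, protocol.weights,
                                     streams):
        res = run_projection(scene.at_angle(angle), n_photons=n_photons,
                             n_batches=n_batches,
                             seed=int(stream.generate_state(1)[0] % 2**31),
                             uncertainty_threshold=uncertainty_threshold)
        per_angle[angle] = res
        converged &= bool(res.converged.all())
        if esak is None:
            esak = weight * res.kerma
            var = (weight * res.batch_se) ** 2
        else:
            esak = esak + weight * res.kerma
            var = var + (weight * res.batch_se) ** 2
    return EsakMap(per_angle[protocol.angles[0]].disc_ids, esak,
                   np.sqrt(var), protocol, per_angle, converged)


def angular_response(scene: Scene, angles, n_photons: int = 100_000,
                     n_batches: int = 10, seed: int = 0):
    """Relative mean ESAK versus the 0-degree projection.

    Runs one projection per angle at equal photon count and divides the
    mean ESAK over the 20 dosimeters by the 0-degree value.  Returns
    (angles, relative response, propagated standard error).
    """
    angles = [float(a) for a in angles]
    if 0.0 not in angles:
        raise ValueError("the angle list must include 0 degrees")
    streams = np.random.SeedSequence(seed).spawn(len(angles))
    means = {}
    errs = {}
    for angle, stream in zip(angles, streams):
        res = run_projection(scene.at_angle(angle), n_photons=n_photons,
                             n_batches=n_batches,
                             seed=int(stream.generate_state(1)[0] % 2**31))
        means[angle] = res.kerma.mean()
        errs[angle] = np.sqrt(np.sum(res.batch_se**2)) / res.kerma.size
    ref = means[0.0]
    rel = np.array([means[a] / ref for a in angles])
    rel_err = np.array([
        0.0 if a == 0.0 else
        (means[a] / ref) * np.hypot(errs[a] / means[a], errs[0.0] / ref)
        for a in angles
    ])
    return np.asarray(angles), rel, rel_err


@dataclass
class BsfResult:
    """Backscatter factors of one acquisition configuration."""

    disc_ids: np.ndarray
    bsf: np.ndarray                # per-disc
    uncertainty: np.ndarray        # absolute SE per disc
    esak: EsakMap                  # with phantom
    free_in_air: EsakMap           # phantom removed
    seeds: tuple[int, int]

    @property
    def mean(self) -> float:
        """Mean BSF over the dosimeter layout (20-dot average)."""
        return float(self.bsf.mean())

    @property
    def mean_uncertainty(self) -> float:
        return float(np.sqrt(np.sum(self.uncertainty**2)) / self.bsf.size)

    def disc(self, disc_id: int) -> float:
        return float(self.bsf[self.disc_ids == disc_id][0])


def compute_bsf(protocol: AcquisitionProtocol, scene: Scene,
                n_photons: int = 100_000, n_batches: int = 10,
                seed: int = 0) -> BsfResult:
    """Backscatter factors: run the acquisition with the phantom present
    and with it removed (independent seeds, both recorded), then form the
    per-disc ratio.  The phantom scene must carry a phantom."""
    if scene.phantom is None:
        raise ValueError("compute_bsf needs a scene with a phantom")
    seed_ph, seed_air = (int(s.generate_state(1)[0] % 2**31)
                         for s in np.random.SeedSequence(seed).spawn(2))
    with_ph = run_acquisition(protocol, scene, n_photons, n_batches, seed_ph)
    without = run_acquisition(protocol, scene.without_phantom(),
                              n_photons, n_batches, seed_air)
    bsf = with_ph.esak / without.esak
    unc = bsf * np.hypot(with_ph.uncertainty / with_ph.esak,
                         without.uncertainty / without.esak)
    return BsfResult(with_ph.disc_ids, bsf, unc, with_ph, without,
                     (seed_ph, seed_air))


def esak_cv(esak_map: EsakMap | np.ndarray) -> float:
    """Coefficient of variation (percent) of the per-disc ESAK, using the
    sample standard deviation (n - 1): the dots are a sample of the field."""
    values = esak_map.esak if isinstance(esak_map, EsakMap) else \
        np.asarray(esak_map, float)
    if values.size < 2:
        raise ValueError("CV needs at least two dosimeters")
    mean = values.mean()
    if mean == 0:
        raise ValueError("CV undefined for zero mean ESAK")
    return float(100.0 * values.std(ddof=1) / mean)
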