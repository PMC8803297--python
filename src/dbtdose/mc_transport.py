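"""Monte Carlo photon transport through the DBT acquisition scene.

The scene is a compressed PMMA slab on a carbon-fiber support with bare
Al2O3 dosimeter discs resting on the entrance surface.  Photons start at
the focal spot (which rotates about a horizontal axis for tomosynthesis
projections), are collimated to a rectangular field on the support plane,
and undergo photoelectric absorption, incoherent (Klein-Nishina) and
coherent (form-factor weighted) scattering down to a 1 keV cutoff.

The source emits a fixed number of photons per projection into a cone
rigidly attached to the tube head (the collimator aperture, sized to the
field rectangle at 0 degrees), as in the real acquisition where the
collimator does not re-shape during the sweep.  Tilted projections
therefore show the physical inverse-square and obliquity falloff of
entrance kerma per projection.

Dosimeter kerma is scored with a track-length estimator under the kerma
approximation (collision kerma, no electron transport; secondary-electron
ranges at these energies are far smaller than the disc), corrected for
the disc's own self-attenuation along each chord.  By default the
unscattered (primary) component is evaluated deterministically per
history and scatter is scored with a next-event (point-detector)
estimator regularized over the disc area for nearby events; the fully
analog track-length estimator remains available for validation.
"""
from __future__ import annotations

import functools as _functools

from dataclasses import dataclass, field, replace

import numpy as np

from .physics_data import get_material, get_table, material_form_factor_sq
from .spectrum import EnergySpectrum, HeelModel, heel_weight

__all__ = [
    "BeamGeometry",
    "PhantomStack",
    "DosimeterDisc",
    "ScenePhysics",
    "Scene",
    "TallyResult",
    "default_disc_layout",
    "load_disc_layout",
    "save_disc_layout",
    "rectangle_solid_angle",
    "sample_source_photons",
    "sample_compton",
    "sample_coherent_angle",
    "transport_photons",
    "transport_photon",
    "tally_kerma",
    "run_projection",
    "write_tally",
]

MEC2 = 510.99895          # keV
KEV_PER_G_TO_MGY = 1.602176634e-10  # (keV/g) -> mGy


@_functools.lru_cache(maxsize=8)
def _satt_table(radius: float, thickness: float):
    """Angle- and attenuation-dependent self-shielding of a cylinder.

    Returns (cos grid, log-mu grid, f) with
    f = <1 - exp(-mu l)> / (mu l_mean), the projected-area average over
    the true chord distribution of the disc for parallel incidence at
    polar angle arccos(c).  This is the correct fluence-to-mean-kerma
    factor for an attenuating disc; using the slab chord d/cos instead
    badly over-attenuates oblique (scattered) radiation, which mostly
    clips the rim with short chords.
    """
    R, d = radius, thickness
    cos_grid = np.concatenate([[1e-3], np.linspace(0.02, 1.0, 50)])
    mu_grid = np.geomspace(0.5, 4000.0, 40)
    volume = np.pi * R * R * d
    table = np.empty((cos_grid.size, mu_grid.size))
    nb, na = 81, 161
    b = np.linspace(-R, R, nb)
    for i, c in enumerate(cos_grid):
        s = np.sqrt(max(1.0 - c * c, 0.0))
        a_max = c * R + s * d / 2 + 1e-9
        a = np.linspace(-a_max, a_max, na)
        A, B = np.meshgrid(a, b, indexing="ij")
        if s < 1e-9:
            chord = np.where(A * A + B * B <= R * R, d, 0.0)
        else:
            t1 = (-d / 2 + s * A) / c
            t2 = (d / 2 + s * A) / c
            qa = s * s
            qb = 2.0 * c * A * s
            qc = c * c * A * A + B * B - R * R
            disc = qb * qb - 4.0 * qa * qc
            sq = np.sqrt(np.clip(disc, 0.0, None))
            tr1 = (-qb - sq) / (2.0 * qa)
            tr2 = (-qb + sq) / (2.0 * qa)
            chord = np.clip(np.minimum(t2, tr2) - np.maximum(t1, tr1),
                            0.0, None)
            chord = np.where(disc > 0, chord, 0.0)
        cell = (a[1] - a[0]) * (b[1] - b[0])
        for k, mu in enumerate(mu_grid):
            table[i, k] = np.sum(-np.expm1(-mu * chord)) * cell \
                / (mu * volume)
    return cos_grid, np.log(mu_grid), table


@_functools.lru_cache(maxsize=8)
def _geo_table(radius: float, thickness: float, r_near: float):
    """Tabulated disc-averaged <1/r^2>: area mean over the disc face,
    volume-averaged over its axial extent (see _Engine._geo_factor)."""
    R = radius
    half_d = 0.5 * thickness
    hs = np.geomspace(5e-3, np.sqrt(5.0) * (r_near + 0.4), 96)
    rs = np.linspace(0.0, np.sqrt(5.0) * (r_near + 0.4), 96)
    rp = np.linspace(R / 120, R - R / 120, 60)
    phi = np.linspace(0, 2 * np.pi, 60, endpoint=False)
    z_off = np.linspace(-half_d * 0.8, half_d * 0.8, 5)
    RP, PHI = np.meshgrid(rp, phi, indexing="ij")
    # broadcast: (hs, rs, z, rp, phi) summed over the last three axes
    table = np.empty((hs.size, rs.size))
    cosphi = np.cos(PHI)
    for i, hh in enumerate(hs):
        r2 = ((hh + z_off[:, None, None]) ** 2 + RP[None, :, :] ** 2
              + rs[:, None, None, None] ** 2
              - 2 * RP[None, :, :] * rs[:, None, None, None]
              * cosphi[None, :, :])
        table[i] = (RP[None, :, :] / r2).sum(axis=(1, 2, 3)) / z_off.size             * (R / rp.size) * (2 * np.pi / phi.size) / (np.pi * R**2)
    return np.log(hs), rs, table


# ---------------------------------------------------------------------------
# Scene description


@dataclass(frozen=True)
class BeamGeometry:
    """Focal-spot and collimation geometry.

    The coordinate frame has x lateral, y from the chest-wall edge toward
    the nipple, z upward with the support top surface at z = 0.  The focal
    spot sits above the chest-wall edge at ``source_to_support`` cm and,
    for tomosynthesis, sweeps laterally across the breast: it rotates
    about a horizontal axis that runs in the chest-wall -> nipple
    direction at ``rotation_axis_height`` cm above the support, so tilted
    projections stay mirror-symmetric about the midline, as in the real
    acquisition.  ``field`` is the collimated rectangle
    (x_lo, x_hi, y_lo, y_hi) on the support plane; it exceeds the phantom
    footprint so that tilted projections still illuminate every dosimeter.
    """

    source_to_support: float = 65.0
    rotation_axis_height: float = 4.0
    gantry_angle_deg: float = 0.0
    field: tuple[float, float, float, float] = (-15.0, 15.0, 0.0, 18.0)

    @property
    def focal_spot(self) -> np.ndarray:
        radius = self.source_to_support - self.rotation_axis_height
        theta = np.deg2rad(self.gantry_angle_deg)
        return np.array([
            -radius * np.sin(theta),
            0.0,
            self.rotation_axis_height + radius * np.cos(theta),
        ])

    def with_angle(self, angle_deg: float) -> "BeamGeometry":
        return replace(self, gantry_angle_deg=angle_deg)


@dataclass(frozen=True)
class PhantomStack:
    """Compressed breast-equivalent PMMA slab, flush with the chest wall."""

    thickness: float                 # cm
    material: str = "pmma"
    chest_nipple: float = 16.5       # cm, y extent
    lateral: float = 20.0            # cm, x extent

    def __post_init__(self) -> None:
        if self.thickness <= 0 or self.chest_nipple <= 0 or self.lateral <= 0:
            raise ValueError("phantom dimensions must be positive")

    @property
    def bounds(self) -> np.ndarray:
        hw = self.lateral / 2
        return np.array([[-hw, hw], [0.0, self.chest_nipple],
                         [0.0, self.thickness]])


@dataclass(frozen=True)
class DosimeterDisc:
    """Bare Al2O3 disc on the phantom entrance surface (nanoDot chip)."""

    id: int
    x: float
    y: float
    z: float                  # cm, bottom face height
    radius: float = 0.25      # cm
    thickness: float = 0.02   # cm
    material: str = "al2o3"

    @property
    def volume(self) -> float:
        return np.pi * self.radius**2 * self.thickness

    @property
    def center(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z + self.thickness / 2])


def default_disc_layout(surface_z: float) -> list[DosimeterDisc]:
    """The 20-dot grid: rows at 2/6/10/14 cm from the chest wall, columns at
    -8..+8 cm lateral, numbered row-major so dot 8 sits centrally 6 cm from
    the chest-wall edge."""
    discs = []
    n = 1
    for y in (2.0, 6.0, 10.0, 14.0):
        for x in (-8.0, -4.0, 0.0, 4.0, 8.0):
            discs.append(DosimeterDisc(id=n, x=x, y=y, z=surface_z))
            n += 1
    return discs


def load_disc_layout(path, surface_z: float) -> list[DosimeterDisc]:
    rows = np.atleast_2d(np.loadtxt(path))
    return [DosimeterDisc(id=int(r[0]), x=float(r[1]), y=float(r[2]),
                          z=surface_z) for r in rows]


def save_disc_layout(discs, path) -> None:
    with open(path, "w") as fh:
        fh.write("# id\tx_cm\ty_cm\n")
        for d in discs:
            fh.write(f"{d.id}\t{d.x}\t{d.y}\n")


@dataclass(frozen=True)
class ScenePhysics:
    """Physics toggles and estimator choice.

    ``estimator`` is ``"nee"`` (deterministic primary term plus next-event
    point-detector scoring of every scatter event; low variance, the
    default) or ``"analog"`` (pure track-length scoring of actual disc
    traversals; used for validation against closed forms).
    """

    scatter: bool = True          # enable incoherent+coherent channels
    coherent: bool = True         # coherent channel on top of incoherent
    estimator: str = "nee"
    nee_near_radius: float = 1.5  # cm; events closer than this to a disc use
    #                               the disc-averaged <1/r^2> geometry factor
    #                               instead of the point-detector 1/r^2
    disc_self_attenuation: bool = True  # chord-averaged attenuation in the disc
    cutoff_keV: float = 1.0
    vacuum: bool = False          # disable all interactions (geometry tests)

    def __post_init__(self) -> None:
        if self.estimator not in ("nee", "analog"):
            raise ValueError("estimator must be 'nee' or 'analog'")


@dataclass
class Scene:
    """Everything one projection needs: beam, media and dosimeters."""

    spectrum: EnergySpectrum
    geometry: BeamGeometry = field(default_factory=BeamGeometry)
    heel: HeelModel = field(default_factory=HeelModel)
    phantom: PhantomStack | None = None
    discs: list[DosimeterDisc] = field(default_factory=list)
    support_thickness: float = 0.2
    support_material: str = "carbon_fiber"
    paddle: bool = False
    paddle_thickness: float = 0.24
    physics: ScenePhysics = field(default_factory=ScenePhysics)
    # OSLD case wall above/below the chip, PMMA-equivalent cm (0 disables);
    # modeled as angle-dependent attenuation at tally time
    disc_case_pmma_cm: float = 0.077
    disc_surface_z: float | None = None   # height of the disc layer, cm

    def __post_init__(self) -> None:
        if self.disc_surface_z is None:
            self.disc_surface_z = (self.phantom.thickness
                                   if self.phantom is not None else 0.0)
        if not self.discs:
            self.discs = default_disc_layout(self.disc_surface_z)
        if self.phantom is not None:
            b = self.phantom.bounds
            x_lo, x_hi, y_lo, y_hi = self.geometry.field
            if not (x_lo <= b[0, 0] and b[0, 1] <= x_hi
                    and y_lo <= b[1, 0] and b[1, 1] <= y_hi):
                raise ValueError("collimated field must contain the phantom "
                                 "footprint")

    def without_phantom(self) -> "Scene":
        """The free-in-air companion scene: phantom removed, discs kept at
        the same heights (the backscatter-factor denominator)."""
        return Scene(self.spectrum, self.geometry, self.heel, None,
                     list(self.discs), self.support_thickness,
                     self.support_material, self.paddle,
                     self.paddle_thickness, self.physics,
                     disc_case_pmma_cm=self.disc_case_pmma_cm,
                     disc_surface_z=self.disc_surface_z)

    def at_angle(self, angle_deg: float) -> "Scene":
        return Scene(self.spectrum, self.geometry.with_angle(angle_deg),
                     self.heel, self.phantom, list(self.discs),
                     self.support_thickness, self.support_material,
                     self.paddle, self.paddle_thickness, self.physics,
                     disc_case_pmma_cm=self.disc_case_pmma_cm,
                     disc_surface_z=self.disc_surface_z)


@dataclass
class TallyResult:
    """Per-disc kerma estimates (per source photon) with batch statistics."""

    disc_ids: np.ndarray
    kerma: np.ndarray             # keV/g per source photon
    batch_se: np.ndarray
    n_events: np.ndarray          # tallied track segments per disc
    n_photons: int
    n_batches: int
    seed: int
    uncertainty_threshold: float = 0.02
    energy_ledger: dict = field(default_factory=dict)

    @property
    def rel_uncertainty(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.kerma > 0, self.batch_se / self.kerma, np.inf)

    @property
    def converged(self) -> np.ndarray:
        return self.rel_uncertainty <= self.uncertainty_threshold

    @property
    def zero_event_discs(self) -> np.ndarray:
        return self.disc_ids[self.n_events == 0]


# ---------------------------------------------------------------------------
# Geometry helpers


def rectangle_solid_angle(point, rect, plane_z: float = 0.0) -> float:
    """Exact solid angle of an axis-aligned rectangle in the plane
    z = plane_z as seen from ``point`` (corner-decomposition formula)."""
    px, py, pz = point
    h = abs(pz - plane_z)
    x_lo, x_hi, y_lo, y_hi = rect

    def omega(a, b):
        return np.arctan2(a * b, h * np.sqrt(a * a + b * b + h * h))

    return float(omega(x_hi - px, y_hi - py) - omega(x_lo - px, y_hi - py)
                 - omega(x_hi - px, y_lo - py) + omega(x_lo - px, y_lo - py))


def _box_exit(p: np.ndarray, u: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Distance to exit ``box`` (3x2 bounds) for points assumed inside."""
    with np.errstate(divide="ignore", invalid="ignore"):
        t_hi = np.where(u > 1e-12, (box[:, 1] - p) / u, np.inf)
        t_lo = np.where(u < -1e-12, (box[:, 0] - p) / u, np.inf)
    return np.minimum(t_hi, t_lo).min(axis=-1)


def _box_entry(p: np.ndarray, u: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Distance to enter ``box`` for outside points; inf if the ray misses."""
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = 1.0 / np.where(np.abs(u) > 1e-12, u, np.nan)
    t0 = (box[:, 0] - p) * inv
    t1 = (box[:, 1] - p) * inv
    # rays parallel to an axis: inside-slab -> (-inf, inf), outside -> miss
    inside = (p >= box[:, 0]) & (p <= box[:, 1])
    par = np.abs(u) <= 1e-12
    t0 = np.where(par, np.where(inside, -np.inf, np.inf), t0)
    t1 = np.where(par, np.where(inside, np.inf, -np.inf), t1)
    near = np.maximum.reduce([np.minimum(t0, t1)[..., i] for i in range(3)])
    far = np.minimum.reduce([np.maximum(t0, t1)[..., i] for i in range(3)])
    hit = (near < far) & (far > 1e-9) & (near > 1e-9)
    return np.where(hit, near, np.inf)


# ---------------------------------------------------------------------------
# Cross-section cache and samplers


class _XsCache:
    """Linear-grid lookup of interaction data for the scene media."""

    GRID = np.linspace(1.0, 40.0, 1951)

    def __init__(self, materials: list[str]) -> None:
        self.materials = materials
        e = self.GRID
        self.mu_lin = np.zeros((len(materials), e.size))
        self.frac_pe = np.zeros_like(self.mu_lin)
        self.frac_incoh = np.zeros_like(self.mu_lin)
        for i, name in enumerate(materials):
            t = get_table(name)
            rho = t.material.density
            total = t.mu(e, "total")
            self.mu_lin[i] = total * rho
            self.frac_pe[i] = t.mu(e, "photoelectric") / total
            self.frac_incoh[i] = t.mu(e, "incoherent") / total
        disc = get_table("al2o3")
        self.muen_disc = disc.mu(e, "energy_absorption")
        self.mu_disc_lin = disc.mu(e, "total") * disc.material.density
        case = get_table("pmma")
        self.mu_case_lin = case.mu(e, "total") * case.material.density
        air = get_table("air")
        self.mu_air_lin = air.mu(e, "total") * air.material.density

    def _idx(self, energy: np.ndarray) -> np.ndarray:
        return np.clip(((energy - 1.0) / 0.02).astype(np.int64),
                       0, self.GRID.size - 2)

    def interp(self, row: np.ndarray, energy: np.ndarray) -> np.ndarray:
        i = self._idx(energy)
        f = (energy - self.GRID[i]) / 0.02
        return row[i] * (1 - f) + row[i + 1] * f

    def mu_of(self, mat_idx: np.ndarray, energy: np.ndarray) -> np.ndarray:
        i = self._idx(energy)
        f = (energy - self.GRID[i]) / 0.02
        return (self.mu_lin[mat_idx, i] * (1 - f)
                + self.mu_lin[mat_idx, i + 1] * f)

    def channel_fracs(self, mat_idx, energy):
        i = self._idx(energy)
        f = (energy - self.GRID[i]) / 0.02
        pe = self.frac_pe[mat_idx, i] * (1 - f) + self.frac_pe[mat_idx, i + 1] * f
        inc = (self.frac_incoh[mat_idx, i] * (1 - f)
               + self.frac_incoh[mat_idx, i + 1] * f)
        return pe, inc


def sample_compton(energy, n: int, rng: np.random.Generator):
    """Sample Klein-Nishina scattering: returns (cos_theta, e_out_keV).

    Rejection sampling of eps = E'/E from the exact Klein-Nishina
    differential cross section (free-electron, no Doppler broadening).
    """
    e_in = np.broadcast_to(np.asarray(energy, float), (n,)).copy()
    k = e_in / MEC2
    eps_min = 1.0 / (1.0 + 2.0 * k)
    f_max = eps_min + 1.0 / eps_min  # >= f everywhere on [eps_min, 1]
    eps = np.empty(n)
    cos = np.empty(n)
    todo = np.arange(n)
    while todo.size:
        u = rng.random(todo.size)
        e = eps_min[todo] + u * (1.0 - eps_min[todo])
        c = 1.0 - (1.0 / e - 1.0) / k[todo]
        fval = e + 1.0 / e - (1.0 - c * c)
        acc = rng.random(todo.size) * f_max[todo] <= fval
        eps[todo[acc]] = e[acc]
        cos[todo[acc]] = c[acc]
        todo = todo[~acc]
    return cos, eps * e_in


def sigma_kn_reduced(k: np.ndarray) -> np.ndarray:
    """Total Klein-Nishina cross section per electron divided by
    2 pi r_e^2 (closed form); k = E / (m_e c^2)."""
    k = np.asarray(k, float)
    op2 = 1.0 + 2.0 * k
    log = np.log1p(2.0 * k)
    return ((1.0 + k) / k**2 * (2.0 * (1.0 + k) / op2 - log / k)
            + log / (2.0 * k) - (1.0 + 3.0 * k) / op2**2)


class _CoherentSampler:
    """Form-factor-weighted coherent (Rayleigh) angle sampling.

    Samples x^2 (squared momentum transfer) from the distribution
    proportional to F^2 via a tabulated inverse CDF, then applies the
    (1 + cos^2)/2 Thomson rejection factor.
    """

    HC = 12.398419843320026  # keV * Angstrom

    def __init__(self, material_name: str) -> None:
        mat = get_material(material_name)
        x_cap = 40.0 / self.HC
        x2 = np.concatenate([[0.0], np.geomspace(1e-6, x_cap**2, 2047)])
        f2 = material_form_factor_sq(mat, np.sqrt(x2))
        self.x2 = x2
        self.f2 = f2

        def cum(vals):
            return np.concatenate([[0.0], np.cumsum(0.5 * (vals[1:] + vals[:-1])
                                                    * np.diff(x2))])

        self.cdf = cum(f2)          # int F^2 dx^2
        self.cdf2 = cum(f2 * x2)    # int F^2 x^2 dx^2
        self.cdf4 = cum(f2 * x2**2)  # int F^2 x^4 dx^2

    def pdf_norm(self, x_e2: np.ndarray) -> np.ndarray:
        """Normalization of F^2(x) (1+cos^2)/2 over solid angle, where
        cos = 1 - 2 x^2 / x_e^2 (x_e = momentum transfer at 180 deg)."""
        a = np.interp(x_e2, self.x2, self.cdf)
        a2 = np.interp(x_e2, self.x2, self.cdf2)
        a4 = np.interp(x_e2, self.x2, self.cdf4)
        return (4.0 * np.pi / x_e2) * (a - 2.0 * a2 / x_e2
                                       + 2.0 * a4 / x_e2**2)

    def f2_at(self, x2: np.ndarray) -> np.ndarray:
        return np.interp(x2, self.x2, self.f2)

    def sample(self, energy: np.ndarray, rng: np.random.Generator):
        n = energy.size
        x_e2 = (energy / self.HC) ** 2  # x at 180 degrees, squared
        a_max = np.interp(x_e2, self.x2, self.cdf)
        cos = np.empty(n)
        todo = np.arange(n)
        while todo.size:
            u = rng.random(todo.size) * a_max[todo]
            x2s = np.interp(u, self.cdf, self.x2)
            c = 1.0 - 2.0 * x2s / x_e2[todo]
            acc = rng.random(todo.size) <= 0.5 * (1.0 + c * c)
            cos[todo[acc]] = c[acc]
            todo = todo[~acc]
        return cos


def sample_coherent_angle(material_name: str, energy, n: int,
                          rng: np.random.Generator) -> np.ndarray:
    """Cosines of coherent scattering angles in the given material."""
    sampler = _CoherentSampler(material_name)
    return sampler.sample(np.broadcast_to(np.asarray(energy, float), (n,)),
                          rng)


def _rotate(dirs: np.ndarray, cos_t: np.ndarray,
            rng: np.random.Generator) -> np.ndarray:
    """Rotate unit vectors by polar angle arccos(cos_t) and uniform azimuth."""
    n = dirs.shape[0]
    phi = rng.random(n) * 2.0 * np.pi
    sin_t = np.sqrt(np.clip(1.0 - cos_t**2, 0.0, None))
    # orthonormal frame: pick helper axis least aligned with dir
    helper = np.zeros_like(dirs)
    idx = np.argmin(np.abs(dirs), axis=1)
    helper[np.arange(n), idx] = 1.0
    v1 = np.cross(dirs, helper)
    v1 /= np.linalg.norm(v1, axis=1, keepdims=True)
    v2 = np.cross(dirs, v1)
    out = (cos_t[:, None] * dirs
           + sin_t[:, None] * (np.cos(phi)[:, None] * v1
                               + np.sin(phi)[:, None] * v2))
    return out / np.linalg.norm(out, axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# Source sampling


def sample_source_photons(spectrum: EnergySpectrum, geometry: BeamGeometry,
                          heel: HeelModel, rng: np.random.Generator,
                          n: int):
    """Sample ``n`` source photons at the focal spot.

    Directions are uniform over the solid angle of the collimator
    aperture -- the field rectangle as seen from the focal spot at 0
    degrees -- and the whole cone rotates rigidly with the gantry.
    Energies follow the spectrum; statistical weights equal the heel
    weight at the aperture intersection point (the heel gradient is a
    tube property, so it rotates with the cone).
    """
    focal = geometry.focal_spot
    s = geometry.source_to_support
    x_lo, x_hi, y_lo, y_hi = geometry.field
    # energies: bin index by fluence, uniform within bin
    p = spectrum.fluence / spectrum.fluence.sum()
    idx = rng.choice(p.size, size=n, p=p)
    width = spectrum.bin_edges[1] - spectrum.bin_edges[0]
    energy = spectrum.bin_edges[idx] + rng.random(n) * width
    # rejection in the tube frame (0-degree geometry): uniform-in-area
    # proposals on the aperture rectangle accepted with the cos/r^2 ratio,
    # so accepted directions are uniform over the aperture solid angle
    cx = np.clip(0.0, x_lo, x_hi)
    cy = np.clip(0.0, y_lo, y_hi)
    r2_min = cx**2 + cy**2 + s**2
    dens_max = s / r2_min**1.5
    fx = np.empty(n)
    fy = np.empty(n)
    todo = np.arange(n)
    while todo.size:
        px = x_lo + rng.random(todo.size) * (x_hi - x_lo)
        py = y_lo + rng.random(todo.size) * (y_hi - y_lo)
        r2 = px**2 + py**2 + s**2
        dens = s / r2**1.5
        acc = rng.random(todo.size) * dens_max <= dens
        fx[todo[acc]] = px[acc]
        fy[todo[acc]] = py[acc]
        todo = todo[~acc]
    d_tube = np.column_stack([fx, fy, np.full(n, -s)])
    d_tube /= np.linalg.norm(d_tube, axis=1, keepdims=True)
    # rotate the cone with the gantry (about the chest->nipple axis)
    theta = np.deg2rad(geometry.gantry_angle_deg)
    ct, st = np.cos(theta), np.sin(theta)
    dirs = np.column_stack([
        ct * d_tube[:, 0] - st * d_tube[:, 2],
        d_tube[:, 1],
        st * d_tube[:, 0] + ct * d_tube[:, 2],
    ])
    weights = heel_weight(heel, (fy - y_lo) / (y_hi - y_lo))
    pos = np.broadcast_to(focal, (n, 3)).copy()
    return pos, dirs, energy, np.asarray(weights, float)


# ---------------------------------------------------------------------------
# Transport engine


class _Engine:
    def __init__(self, scene: Scene) -> None:
        self.scene = scene
        mats = ["air"]
        self.boxes: list[np.ndarray] = []
        self.box_mat: list[int] = []
        if scene.phantom is not None:
            mats.append(scene.phantom.material)
            self.boxes.append(scene.phantom.bounds)
            self.box_mat.append(len(mats) - 1)
        if scene.paddle:
            mats.append("pmma")
            z0 = scene.disc_surface_z + 0.021
            self.boxes.append(np.array([[-10.0, 10.0], [0.0, 16.5],
                                        [z0, z0 + scene.paddle_thickness]]))
            self.box_mat.append(len(mats) - 1)
        if scene.support_thickness > 0:
            mats.append(scene.support_material)
            self.boxes.append(np.array([[-12.0, 12.0], [0.0, 20.0],
                                        [-scene.support_thickness, 0.0]]))
            self.box_mat.append(len(mats) - 1)
        self.materials = mats
        self.xs = _XsCache(mats)
        self.world = np.array([[-35.0, 35.0], [-5.0, 30.0],
                               [-scene.support_thickness - 0.05, 70.0]])
        self.coh_samplers = {i: _CoherentSampler(m)
                             for i, m in enumerate(mats)}
        d = scene.discs
        self.disc_xy = np.array([[dd.x, dd.y] for dd in d])
        self.disc_r2 = np.array([dd.radius**2 for dd in d])
        self.disc_vol = np.array([dd.volume for dd in d])
        self.z_lo = np.array([dd.z for dd in d])
        self.z_hi = np.array([dd.z + dd.thickness for dd in d])
        self.layer_lo = float(self.z_lo.min())
        self.layer_hi = float(self.z_hi.max())
        self.disc_centers = np.array([dd.center for dd in d])
        self.r_near = scene.physics.nee_near_radius
        self.box_mu_rows = [self.xs.mu_lin[mi] for mi in self.box_mat]
        self._geo_table = None
        self._disc_R = float(np.sqrt(self.disc_r2[0]))

    def _geo_factor(self, h: np.ndarray, rho: np.ndarray) -> np.ndarray:
        """Disc-averaged inverse-square factor <1/r^2> for an event at
        axial distance h (to the disc centre plane) and lateral offset rho
        (extended-detector replacement of the point-detector 1/r^2 for
        near events); tabulated once per disc geometry."""
        if self._geo_table is None:
            self._geo_table = _geo_table(
                self._disc_R, float(self.z_hi[0] - self.z_lo[0]),
                self.r_near)
        lh, rs, table = self._geo_table
        hi = np.clip(np.log(np.maximum(h, 5.1e-3)), lh[0], lh[-1])
        i = np.clip(np.searchsorted(lh, hi) - 1, 0, lh.size - 2)
        j = np.clip(np.searchsorted(rs, rho) - 1, 0, rs.size - 2)
        fi = (hi - lh[i]) / (lh[i + 1] - lh[i])
        fj = (rho - rs[j]) / (rs[j + 1] - rs[j])
        return (table[i, j] * (1 - fi) * (1 - fj)
                + table[i + 1, j] * fi * (1 - fj)
                + table[i, j + 1] * (1 - fi) * fj
                + table[i + 1, j + 1] * fi * fj)

    # -- region bookkeeping
    def region_of(self, p: np.ndarray) -> np.ndarray:
        reg = np.zeros(p.shape[0], dtype=np.int8)
        for b, box in enumerate(self.boxes):
            inside = np.all((p >= box[:, 0] - 1e-12)
                            & (p <= box[:, 1] + 1e-12), axis=1)
            reg[inside] = b + 1
        out = np.any((p < self.world[:, 0]) | (p > self.world[:, 1]), axis=1)
        reg[out] = -1
        return reg

    def boundary_distance(self, p, u, reg):
        d = np.full(p.shape[0], np.inf)
        in_air = reg == 0
        if in_air.any():
            d_air = _box_exit(p[in_air], u[in_air], self.world)
            for box in self.boxes:
                d_air = np.minimum(d_air, _box_entry(p[in_air], u[in_air], box))
            d[in_air] = d_air
        for b, box in enumerate(self.boxes):
            m = reg == b + 1
            if m.any():
                d[m] = _box_exit(p[m], u[m], box)
        return np.maximum(d, 1e-9)

    def mat_of_region(self, reg: np.ndarray) -> np.ndarray:
        mat = np.zeros_like(reg, dtype=np.int64)
        for b, mi in enumerate(self.box_mat):
            mat[reg == b + 1] = mi
        return mat

    # -- next-event (point-detector) estimator for scatter events
    def _segment_tau(self, q: np.ndarray, target: np.ndarray,
                     energy: np.ndarray):
        """Optical depth from event points ``q`` (n,3) to ``target`` (3,),
        summing slab path lengths through every box region plus air.
        Returns (tau, r, unit vectors)."""
        d = target[None, :] - q
        r = np.linalg.norm(d, axis=1)
        u = d / r[:, None]
        mu_air = self.xs.interp(self.xs.mu_air_lin, energy)
        tau = np.zeros_like(r)
        l_boxes = np.zeros_like(r)
        for box, mu_row in zip(self.boxes, self.box_mu_rows):
            with np.errstate(divide="ignore", invalid="ignore"):
                t0 = (box[:, 0] - q) / u
                t1 = (box[:, 1] - q) / u
            inside = (q >= box[:, 0]) & (q <= box[:, 1])
            par = np.abs(u) <= 1e-12
            t0 = np.where(par, np.where(inside, -np.inf, np.inf), t0)
            t1 = np.where(par, np.where(inside, np.inf, -np.inf), t1)
            near = np.maximum.reduce(
                [np.minimum(t0, t1)[:, i] for i in range(3)])
            far = np.minimum.reduce(
                [np.maximum(t0, t1)[:, i] for i in range(3)])
            seg = np.clip(np.minimum(far, r) - np.maximum(near, 0.0), 0.0, None)
            seg = np.where(near < far, seg, 0.0)
            tau += seg * self.xs.interp(mu_row, energy)
            l_boxes += seg
        tau += np.clip(r - l_boxes, 0.0, None) * mu_air
        return tau, r, u

    _GL_U, _GL_WU = np.polynomial.legendre.leggauss(10)

    def expected_near_scatter(self, p, u, d_bound, energy, weight, mat_idx,
                              kerma_acc, event_acc) -> None:
        """Expected-collision scoring for the near-sphere portion of each
        flight.

        For every (flight, disc) pair whose segment enters the sphere of
        radius ``r_near`` around the disc centre, the scatter contribution
        of a possible collision inside that window is integrated
        deterministically over the collision density mu exp(-mu t) dt,
        with Gauss-Legendre nodes concentrated around the point of closest
        approach by a sinh substitution (the disc-averaged <1/r^2> factor
        peaks on a millimetre scale there).  Sampled collisions inside a
        near sphere are then skipped by the event estimator, which keeps
        the plain 1/r^2 point-detector form valid everywhere it is used.
        This removes the heavy-tailed position randomness of collisions
        right next to a disc."""
        n = p.shape[0]
        if n == 0:
            return
        mu = self.xs.mu_of(mat_idx, energy)
        k_all = energy / MEC2
        s_red_all = sigma_kn_reduced(k_all)
        pe_frac, inc_frac = self.xs.channel_fracs(mat_idx, energy)
        coh_frac = np.clip(1.0 - pe_frac - inc_frac, 0.0, None)
        phys = self.scene.physics
        if not phys.coherent:
            inc_frac = inc_frac / (pe_frac + inc_frac)
            coh_frac = np.zeros_like(coh_frac)
        x_e2_all = (energy / _CoherentSampler.HC) ** 2
        n_nodes = self._GL_U.size
        for j in range(self.disc_centers.shape[0]):
            centre = self.disc_centers[j]
            v = centre[None, :] - p
            vu = np.einsum("ij,ij->i", v, u)
            disc_term = vu**2 - np.einsum("ij,ij->i", v, v) + self.r_near**2
            hit = (disc_term > 0) & (mu > 0)
            if not hit.any():
                continue
            sq = np.sqrt(disc_term[hit])
            w1 = np.maximum(vu[hit] - sq, 0.0)
            w2 = np.minimum(vu[hit] + sq, d_bound[hit])
            open_win = w2 > w1
            idx = np.nonzero(hit)[0][open_win]
            if idx.size == 0:
                continue
            w1, w2 = w1[open_win], w2[open_win]
            tc = vu[idx]
            h_line = np.sqrt(np.clip(
                np.einsum("ij,ij->i", v[idx], v[idx]) - tc**2, 0.0, None))
            a = np.maximum(h_line, 0.02)
            u_lo = np.arcsinh((w1 - tc) / a)
            u_hi = np.arcsinh((w2 - tc) / a)
            # nodes (idx, n_nodes): t = tc + a sinh(u), dt = a cosh(u) du
            uu = (0.5 * (u_hi - u_lo))[:, None] * self._GL_U[None, :] \
                + (0.5 * (u_hi + u_lo))[:, None]
            jac = (0.5 * (u_hi - u_lo))[:, None] * a[:, None] * np.cosh(uu)
            t_nodes = tc[:, None] + a[:, None] * np.sinh(uu)
            flat = np.repeat(idx, n_nodes)
            tq = t_nodes.ravel()
            q = p[flat] + u[flat] * tq[:, None]
            e_in = energy[flat]
            vec = centre[None, :] - q
            r2 = np.einsum("ij,ij->i", vec, vec)
            r = np.sqrt(r2)
            cos_c = np.clip(np.einsum("ij,ij->i", u[flat], vec) / r,
                            -1.0, 1.0)
            h = np.abs(centre[2] - q[:, 2])
            cos_inc = np.abs(vec[:, 2]) / r
            kk = k_all[flat]
            mats = mat_idx[flat]
            xe2 = x_e2_all[flat]
            # <pdf / r^2> over the disc face.  Far nodes use the centre
            # direction; nodes within a few disc radii use a 5-patch
            # product average (centre + 4 sector centroids, each patch a
            # sub-disc of radius R/sqrt(5)), which captures the positive
            # correlation between the scattering pdf and the solid-angle
            # weight right next to the disc.
            R = np.sqrt(self.disc_r2[j])
            rho_c = np.hypot(q[:, 0] - centre[0], q[:, 1] - centre[1])
            geo_c = self._geo_factor(h, rho_c)
            kk = k_all[flat]
            mats = mat_idx[flat]
            xe2 = x_e2_all[flat]
            eps_cc = 1.0 / (1.0 + kk * (1.0 - cos_c))
            f_cc = eps_cc + 1.0 / eps_cc - (1.0 - cos_c * cos_c)
            pg_inc = geo_c * (eps_cc * eps_cc * f_cc
                              / (4.0 * np.pi * s_red_all[flat]))
            pg_coh = np.zeros_like(pg_inc)
            if phys.coherent:
                x2_c = xe2 * (1.0 - cos_c) / 2.0
                for m in np.unique(mats):
                    ms = mats == m
                    smp = self.coh_samplers[int(m)]
                    pg_coh[ms] = geo_c[ms] * (
                        smp.f2_at(x2_c[ms]) * 0.5 * (1.0 + cos_c[ms] ** 2)
                        / smp.pdf_norm(xe2[ms]))
            ref = np.nonzero(r2 < (3.6 * R) ** 2)[0]
            if ref.size:
                sub = np.sqrt(5.0)
                qr = q[ref]
                ur = u[flat][ref]
                pg_i = np.zeros(ref.size)
                pg_r = np.zeros(ref.size)
                for ox, oy in ((0.0, 0.0), (0.76 * R, 0.0), (-0.76 * R, 0.0),
                               (0.0, 0.76 * R), (0.0, -0.76 * R)):
                    vx = centre[0] + ox - qr[:, 0]
                    vy = centre[1] + oy - qr[:, 1]
                    vz = centre[2] - qr[:, 2]
                    rk = np.sqrt(vx * vx + vy * vy + vz * vz)
                    cos_k = np.clip((ur[:, 0] * vx + ur[:, 1] * vy
                                     + ur[:, 2] * vz) / rk, -1.0, 1.0)
                    rho_k = np.hypot(vx, vy)
                    geo_k = 5.0 * self._geo_factor(sub * h[ref], sub * rho_k)
                    eps_k = 1.0 / (1.0 + kk[ref] * (1.0 - cos_k))
                    f_k = eps_k + 1.0 / eps_k - (1.0 - cos_k * cos_k)
                    pg_i += 0.2 * geo_k * (eps_k * eps_k * f_k
                                           / (4.0 * np.pi
                                              * s_red_all[flat][ref]))
                    if phys.coherent:
                        x2_k = xe2[ref] * (1.0 - cos_k) / 2.0
                        mk = mats[ref]
                        for m in np.unique(mk):
                            ms = mk == m
                            smp = self.coh_samplers[int(m)]
                            pg_r[ms] += 0.2 * geo_k[ms] * (
                                smp.f2_at(x2_k[ms])
                                * 0.5 * (1.0 + cos_k[ms] ** 2)
                                / smp.pdf_norm(xe2[ref][ms]))
                pg_inc[ref] = pg_i
                if phys.coherent:
                    pg_coh[ref] = pg_r
            # energy-dependent factors at the centre-ray scattering angle
            eps_c = 1.0 / (1.0 + kk * (1.0 - cos_c))
            e_out = eps_c * e_in
            tau_c, _, _ = self._segment_tau(q, centre, e_out)
            muen_c = self.xs.interp(self.xs.muen_disc, e_out)
            val = (inc_frac[flat] * pg_inc * np.exp(-tau_c) * e_out * muen_c
                   * self.detector_response(e_out, cos_inc))
            if phys.coherent:
                tau_r, _, _ = self._segment_tau(q, centre, e_in)
                muen_r = self.xs.interp(self.xs.muen_disc, e_in)
                val = val + (coh_frac[flat] * pg_coh * np.exp(-tau_r)
                             * e_in * muen_r
                             * self.detector_response(e_in, cos_inc))
            # collision density mu exp(-mu t) and the quadrature jacobian
            dens = mu[flat] * np.exp(-mu[flat] * tq)
            contrib = (weight[flat] * val * dens
                       * jac.ravel() * self._GL_WU[np.tile(
                           np.arange(n_nodes), idx.size)])
            kerma_acc[j] += contrib.sum()
            event_acc[j] += idx.size

    def nee_contribute(self, kind: str, mat_idx, p_int, u_in, energy, weight,
                       kerma_acc, event_acc) -> None:
        """Add the expected kerma delivered to every disc farther than the
        near radius by the scatter events at ``p_int`` with incoming
        directions ``u_in`` (point-detector form; events inside a near
        sphere are already covered by the expected-collision window
        integral and contribute nothing here)."""
        if p_int.shape[0] == 0:
            return
        k = energy / MEC2
        if kind == "compton":
            s_red = sigma_kn_reduced(k)
        for j in range(self.disc_centers.shape[0]):
            centre = self.disc_centers[j]
            vec = centre[None, :] - p_int
            r2 = np.einsum("ij,ij->i", vec, vec)
            cos = np.einsum("ij,ij->i", u_in, vec) / np.sqrt(r2)
            cos = np.clip(cos, -1.0, 1.0)
            if kind == "compton":
                eps = 1.0 / (1.0 + k * (1.0 - cos))
                e_out = eps * energy
                f = eps + 1.0 / eps - (1.0 - cos * cos)
                pdf = eps * eps * f / (4.0 * np.pi * s_red)
            else:
                e_out = energy
                x_e2 = (energy / _CoherentSampler.HC) ** 2
                x2 = x_e2 * (1.0 - cos) / 2.0
                pdf = np.zeros_like(energy)
                for m in np.unique(mat_idx):
                    sub = mat_idx == m
                    sampler = self.coh_samplers[int(m)]
                    pdf[sub] = (sampler.f2_at(x2[sub])
                                * 0.5 * (1.0 + cos[sub] ** 2)
                                / sampler.pdf_norm(x_e2[sub]))
            # point-detector 1/r^2; events inside the near sphere are
            # covered by the expected-collision window integral instead
            near = r2 <= self.r_near**2
            with np.errstate(divide="ignore"):
                geo = np.where(near, 0.0, 1.0 / r2)
            tau, r, _u = self._segment_tau(p_int, centre, e_out)
            muen = self.xs.interp(self.xs.muen_disc, e_out)
            cos_inc = np.abs(vec[:, 2]) / r
            satt = self.detector_response(e_out, cos_inc)
            contrib = weight * pdf * np.exp(-tau) * e_out * muen * geo * satt
            kerma_acc[j] += contrib.sum()
            event_acc[j] += int((~near).sum())

    # -- tallies
    def disc_path_lengths(self, p0, u, length, energy, weight, kerma_acc,
                          event_acc, records=None, ids=None, origins=None):
        """Accumulate track-length kerma for segments crossing the disc layer.

        When ``origins`` (flight start points) is given, a segment only
        scores on discs within the near radius of its origin -- the
        complement of the next-event far-field scoring."""
        z0 = p0[:, 2]
        z1 = z0 + u[:, 2] * length
        cand = (np.minimum(z0, z1) <= self.layer_hi + 1e-12) \
            & (np.maximum(z0, z1) >= self.layer_lo - 1e-12)
        if not cand.any():
            return
        orig_idx = np.nonzero(cand)[0]
        p0 = p0[cand]
        u = u[cand]
        length = length[cand]
        energy = energy[cand]
        weight = weight[cand]
        if origins is not None:
            origins = origins[cand]
        muen = self.xs.interp(self.xs.muen_disc, energy)
        uz = u[:, 2]
        safe = np.abs(uz) > 1e-12
        for j in range(self.disc_xy.shape[0]):
            with np.errstate(divide="ignore", invalid="ignore"):
                ta = (self.z_lo[j] - p0[:, 2]) / uz
                tb = (self.z_hi[j] - p0[:, 2]) / uz
            t1 = np.where(safe, np.minimum(ta, tb), 0.0)
            t2 = np.where(safe, np.maximum(ta, tb), length)
            horiz_in = ~safe & (p0[:, 2] >= self.z_lo[j]) \
                & (p0[:, 2] <= self.z_hi[j])
            t1 = np.where(~safe & ~horiz_in, np.inf, t1)
            dx = p0[:, 0] - self.disc_xy[j, 0]
            dy = p0[:, 1] - self.disc_xy[j, 1]
            a = u[:, 0]**2 + u[:, 1]**2
            b = 2.0 * (dx * u[:, 0] + dy * u[:, 1])
            c = dx * dx + dy * dy - self.disc_r2[j]
            disc = b * b - 4.0 * a * c
            vert = a <= 1e-14
            with np.errstate(divide="ignore", invalid="ignore"):
                sq = np.sqrt(np.clip(disc, 0.0, None))
                tr1 = (-b - sq) / (2.0 * a)
                tr2 = (-b + sq) / (2.0 * a)
            tr1 = np.where(vert, np.where(c < 0, -np.inf, np.inf), tr1)
            tr2 = np.where(vert, np.where(c < 0, np.inf, -np.inf), tr2)
            miss = (~vert) & (disc <= 0)
            lo = np.maximum.reduce([t1, tr1, np.zeros_like(t1)])
            hi = np.minimum.reduce([t2, tr2, length])
            seg = np.where(miss, 0.0, np.clip(hi - lo, 0.0, None))
            if origins is not None:
                near = (np.sum((origins - self.disc_centers[j]) ** 2, axis=1)
                        <= self.r_near**2)
                seg = np.where(near, seg, 0.0)
            hit = seg > 0
            if hit.any():
                seg_eff = seg[hit]
                if self.scene.physics.disc_self_attenuation:
                    mu_d = self.xs.interp(self.xs.mu_disc_lin, energy[hit])
                    seg_eff = -np.expm1(-mu_d * seg_eff) / mu_d
                t_case = self.scene.disc_case_pmma_cm
                if t_case > 0:
                    path = np.minimum(
                        t_case / np.maximum(np.abs(uz[hit]), 1e-3), 0.5)
                    seg_eff = seg_eff * np.exp(
                        -self.xs.interp(self.xs.mu_case_lin, energy[hit])
                        * path)
                contrib = (weight[hit] * seg_eff * energy[hit] * muen[hit]
                           / self.disc_vol[j])
                kerma_acc[j] += contrib.sum()
                event_acc[j] += int(hit.sum())
                if records is not None:
                    for i in np.nonzero(hit)[0]:
                        records.append(
                            (j + 1, float(seg[i]), float(energy[i]),
                             float(weight[i]),
                             int(ids[orig_idx[i]]) if ids is not None else -1))

    # -- deterministic primary term
    def primary_factors(self):
        """Per-disc geometry factor g_j, focal distance d_j and chord
        length L_j so that the primary kerma per source photon of energy E
        is g_j * exp(-mu_air(E) d_j) * E * muen_disc(E) * self_att(E, L_j).

        The aperture solid angle is evaluated once in the tube frame (it
        rotates rigidly with the gantry), and collimation plus heel weight
        are checked on the tube-frame field intersection of each ray.
        """
        geo = self.scene.geometry
        focal = geo.focal_spot
        s = geo.source_to_support
        omega = rectangle_solid_angle(np.array([0.0, 0.0, s]), geo.field)
        x_lo, x_hi, y_lo, y_hi = geo.field
        theta = np.deg2rad(geo.gantry_angle_deg)
        ct, st = np.cos(theta), np.sin(theta)
        g = np.zeros(len(self.scene.discs))
        d_air = np.zeros_like(g)
        cos_inc = np.zeros_like(g)
        for j, disc in enumerate(self.scene.discs):
            centre = disc.center
            vec = centre - focal
            r = np.linalg.norm(vec)
            if centre[2] >= focal[2]:
                continue
            # back-rotate the ray into the tube frame for collimation/heel
            dx = ct * vec[0] + st * vec[2]
            dz = -st * vec[0] + ct * vec[2]
            if dz >= 0:
                continue
            t_sup = s / (-dz)
            px, py = t_sup * dx, t_sup * vec[1]
            if not (x_lo <= px <= x_hi and y_lo <= py <= y_hi):
                continue  # disc outside the collimator aperture
            w = heel_weight(self.scene.heel, (py - y_lo) / (y_hi - y_lo))
            g[j] = w / (omega * r * r)
            d_air[j] = r
            cos_inc[j] = abs(vec[2]) / r
        return g, d_air, cos_inc

    def self_attenuation(self, energy: np.ndarray,
                         cos_inc: np.ndarray | float) -> np.ndarray:
        """Mean self-shielding factor of the disc for parallel incidence
        at |cos(theta)| = cos_inc: the projected-area average of
        (1 - exp(-mu l)) over the true chord distribution, divided by
        mu l_mean (tabulated); 1.0 when the correction is disabled."""
        energy = np.asarray(energy, float)
        if not self.scene.physics.disc_self_attenuation:
            return np.ones_like(energy)
        mu = self.xs.interp(self.xs.mu_disc_lin, energy)
        cos_g, logmu_g, table = _satt_table(
            self._disc_R, float(self.z_hi[0] - self.z_lo[0]))
        c = np.broadcast_to(np.asarray(cos_inc, float), energy.shape)
        lm = np.clip(np.log(mu), logmu_g[0], logmu_g[-1])
        i = np.clip(np.searchsorted(cos_g, c) - 1, 0, cos_g.size - 2)
        j = np.clip(np.searchsorted(logmu_g, lm) - 1, 0, logmu_g.size - 2)
        fi = np.clip((c - cos_g[i]) / (cos_g[i + 1] - cos_g[i]), 0.0, 1.0)
        fj = (lm - logmu_g[j]) / (logmu_g[j + 1] - logmu_g[j])
        return (table[i, j] * (1 - fi) * (1 - fj)
                + table[i + 1, j] * fi * (1 - fj)
                + table[i, j + 1] * (1 - fi) * fj
                + table[i + 1, j + 1] * fi * fj)

    def detector_response(self, energy, cos_inc):
        """Self-shielding of the chip times transmission of the plastic
        case wall at incidence |cos(theta)| = cos_inc (wall path capped at
        the case half-width for grazing rays)."""
        energy = np.asarray(energy, float)
        resp = self.self_attenuation(energy, cos_inc)
        t_case = self.scene.disc_case_pmma_cm
        if t_case > 0:
            path = np.minimum(t_case / np.maximum(
                np.asarray(cos_inc, float), 1e-3), 0.5)
            resp = resp * np.exp(-self.xs.interp(self.xs.mu_case_lin, energy)
                                 * path)
        return resp

    def primary_kerma(self, energy: np.ndarray) -> np.ndarray:
        """Mean primary kerma per source photon over the sampled energies."""
        g, d_air, cos_inc = self.primary_factors()
        mu_air = self.xs.interp(self.xs.mu_air_lin, energy)
        muen = self.xs.interp(self.xs.muen_disc, energy)
        ek = energy * muen
        out = np.empty(g.size)
        for j in range(g.size):
            if g[j] == 0.0:
                out[j] = 0.0
                continue
            satt = self.detector_response(energy, cos_inc[j])
            out[j] = g[j] * np.mean(ek * satt * np.exp(-mu_air * d_air[j]))
        return out


def transport_photons(engine: _Engine, pos, dirs, energy, weight,
                      rng: np.random.Generator, kerma_acc, event_acc,
                      record_crossings: bool = False):
    """Track a photon cohort to extinction, accumulating disc tallies.

    Returns the per-history energy ledger (injected, deposited, escaped,
    cutoff) and, optionally, individual crossing records."""
    phys = engine.scene.physics
    n = pos.shape[0]
    deposited = np.zeros(n)
    escaped = np.zeros(n)
    cutoff_bank = np.zeros(n)
    injected = np.asarray(energy, float).copy()
    records: list | None = [] if record_crossings else None
    analog = phys.estimator == "analog"

    p = np.asarray(pos, float).copy()
    u = np.asarray(dirs, float).copy()
    e = np.asarray(energy, float).copy()
    w = np.asarray(weight, float).copy()
    live_ids = np.arange(n)
    live_scat = np.zeros(n, dtype=bool)
    # flight origin = last scatter point; drives near-disc analog scoring
    origin = np.full((n, 3), np.inf)
    while live_ids.size:
        reg = engine.region_of(p)
        dead_out = reg < 0
        if dead_out.any():
            escaped[live_ids[dead_out]] += e[dead_out]
            keep = ~dead_out
            p, u, e, w, live_ids, live_scat, origin, reg = (
                p[keep], u[keep], e[keep], w[keep], live_ids[keep],
                live_scat[keep], origin[keep], reg[keep])
            if not live_ids.size:
                break
        mat = engine.mat_of_region(reg)
        if phys.vacuum:
            mu = np.zeros_like(e)
        else:
            mu = engine.xs.mu_of(mat, e)
        d_bound = engine.boundary_distance(p, u, reg)
        with np.errstate(divide="ignore"):
            rnd = rng.random(e.size)
            s_free = np.where(mu > 0, -np.log(rnd) / np.maximum(mu, 1e-300),
                              np.inf)
        interact = s_free < d_bound
        step = np.where(interact, s_free, d_bound + 1e-7)
        if analog:
            engine.disc_path_lengths(
                p, u, step, e, w, kerma_acc, event_acc,
                records, live_ids if record_crossings else None)
        elif phys.scatter and not phys.vacuum:
            # expected-collision scoring of the near-sphere windows; the
            # sampled collisions inside those spheres are skipped by the
            # point estimator in nee_contribute
            engine.expected_near_scatter(p, u, d_bound, e, w, mat,
                                         kerma_acc, event_acc)
        p = p + u * step[:, None]
        if interact.any():
            ii = np.nonzero(interact)[0]
            pe_frac, inc_frac = engine.xs.channel_fracs(mat[ii], e[ii])
            if not phys.scatter:
                pe_frac = np.ones_like(pe_frac)
            elif not phys.coherent:
                # coherent channel removed; renormalize the remainder
                inc_frac = inc_frac / (pe_frac + inc_frac)
                pe_frac = 1.0 - inc_frac
            urand = rng.random(ii.size)
            absorb = urand < pe_frac
            compton = (~absorb) & (urand < pe_frac + inc_frac)
            rayleigh = (~absorb) & (~compton)
            if absorb.any():
                g = ii[absorb]
                deposited[live_ids[g]] += e[g]
                e[g] = 0.0
            if compton.any():
                g = ii[compton]
                if not analog:
                    engine.nee_contribute("compton", mat[g], p[g], u[g],
                                          e[g], w[g], kerma_acc, event_acc)
                cos_t, e_new = sample_compton(e[g], g.size, rng)
                deposited[live_ids[g]] += e[g] - e_new
                e[g] = e_new
                u[g] = _rotate(u[g], cos_t, rng)
                live_scat[g] = True
                origin[g] = p[g]
                below = g[e[g] < phys.cutoff_keV]
                if below.size:
                    cutoff_bank[live_ids[below]] += e[below]
                    e[below] = 0.0
            if rayleigh.any():
                g = ii[rayleigh]
                if not analog:
                    engine.nee_contribute("coherent", mat[g], p[g], u[g],
                                          e[g], w[g], kerma_acc, event_acc)
                # coherent: energy unchanged, direction from the form factor
                for m in np.unique(mat[g]):
                    sub = g[mat[g] == m]
                    cos_t = engine.coh_samplers[int(m)].sample(e[sub], rng)
                    u[sub] = _rotate(u[sub], cos_t, rng)
                live_scat[g] = True
                origin[g] = p[g]
        keep = e > 0
        p, u, e, w = p[keep], u[keep], e[keep], w[keep]
        live_ids, live_scat = live_ids[keep], live_scat[keep]
        origin = origin[keep]
    ledger = {"injected": injected, "deposited": deposited,
              "escaped": escaped, "cutoff": cutoff_bank}
    if record_crossings:
        return ledger, records
    return ledger


def transport_photon(scene: Scene, position, direction, energy_keV,
                     weight: float = 1.0, seed: int = 0):
    """Transport a single photon analogically; returns its disc crossings
    as a list of (disc_id, path_length_cm, energy_keV, weight) tuples."""
    analog_scene = Scene(
        scene.spectrum, scene.geometry, scene.heel, scene.phantom,
        list(scene.discs), scene.support_thickness, scene.support_material,
        scene.paddle, scene.paddle_thickness,
        replace(scene.physics, estimator="analog"),
        disc_surface_z=scene.disc_surface_z)
    engine = _Engine(analog_scene)
    rng = np.random.default_rng(seed)
    k = np.zeros(len(scene.discs))
    ev = np.zeros(len(scene.discs), dtype=np.int64)
    _, records = transport_photons(
        engine, np.asarray([position], float), np.asarray([direction], float),
        np.asarray([energy_keV], float), np.asarray([weight], float),
        rng, k, ev, record_crossings=True)
    return [(r[0], r[1], r[2], r[3]) for r in records]


def tally_kerma(path_length_cm: float, energy_keV: float, weight: float,
                disc: DosimeterDisc) -> float:
    """Track-length collision-kerma contribution of one disc traversal
    (keV/g): weight * L * E * (mu_en/rho) / volume."""
    if path_length_cm < 0:
        raise ValueError("path length must be >= 0")
    muen = get_table(disc.material).mu(energy_keV, "energy_absorption")
    return weight * path_length_cm * energy_keV * muen / disc.volume


def run_projection(scene: Scene, n_photons: int = 100_000,
                   n_batches: int = 10, seed: int = 0,
                   uncertainty_threshold: float = 0.02,
                   keep_ledger: bool = False) -> TallyResult:
    """Run one projection and return per-disc kerma with batch statistics.

    Deterministic for a given seed.  With the default first-flight
    estimator the primary component is computed analytically per batch and
    only scattered photons are tallied analogically.
    """
    if n_photons < 1_000:
        raise ValueError("n_photons must be >= 1000")
    if n_batches < 2:
        raise ValueError("n_batches must be >= 2")
    engine = _Engine(scene)
    n_discs = len(scene.discs)
    per_batch = np.full(n_batches, n_photons // n_batches)
    per_batch[: n_photons % n_batches] += 1
    batch_kerma = np.zeros((n_batches, n_discs))
    events = np.zeros(n_discs, dtype=np.int64)
    ledgers = []
    streams = [np.random.default_rng(s)
               for s in np.random.SeedSequence(seed).spawn(n_batches)]
    for b, (nb, rng) in enumerate(zip(per_batch, streams)):
        pos, dirs, e, w = sample_source_photons(
            scene.spectrum, scene.geometry, scene.heel, rng, int(nb))
        acc = np.zeros(n_discs)
        ev = np.zeros(n_discs, dtype=np.int64)
        ledger = transport_photons(engine, pos, dirs, e, w, rng, acc, ev)
        kerma = acc / nb
        if scene.physics.estimator == "nee" and not scene.physics.vacuum:
            kerma = kerma + engine.primary_kerma(e)
        batch_kerma[b] = kerma
        events += ev
        if keep_ledger:
            ledgers.append(ledger)
    mean = batch_kerma.mean(axis=0)
    se = batch_kerma.std(axis=0, ddof=1) / np.sqrt(n_batches)
    result = TallyResult(
        disc_ids=np.array([d.id for d in scene.discs]),
        kerma=mean, batch_se=se, n_events=events,
        n_photons=int(per_batch.sum()), n_batches=n_batches, seed=seed,
        uncertainty_threshold=uncertainty_threshold,
    )
    if keep_ledger:
        result.energy_ledger = {
            k: np.concatenate([lg[k] for lg in ledgers]) for k in ledgers[0]
        }
    return result


def write_tally(result: TallyResult, path, meta_path=None) -> None:
    """Delimited text tally output (disc_id, kerma_per_photon,
    rel_uncertainty) plus a JSON run-metadata sidecar with the seed,
    photon counts and convergence flags."""
    import json

    with open(path, "w") as fh:
        fh.write("# disc_id\tkerma_per_photon\trel_uncertainty\n")
        for i, disc_id in enumerate(result.disc_ids):
            fh.write(f"{disc_id}\t{result.kerma[i]:.8e}\t"
                     f"{result.rel_uncertainty[i]:.4e}\n")
    if meta_path is None:
        meta_path = str(path) + ".json"
    meta = {
        "seed": int(result.seed),
        "n_photons": int(result.n_photons),
        "n_batches": int(result.n_batches),
        "uncertainty_threshold": result.uncertainty_threshold,
        "converged": bool(result.converged.all()),
        "zero_event_discs": [int(d) for d in result.zero_event_discs],
    }
    with open(meta_path, "w") as fh:
        json.dump(meta, fh, indent=1)
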