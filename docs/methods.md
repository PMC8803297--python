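# Methods

`dbtdose` models the dosimetry of a dual-mode digital breast tomosynthesis
(DBT) system: a W-anode, Rh-filtered mammography tube that either stays
fixed (2D mode) or sweeps ±25° across the breast in 25 low-dose
projections (3D mode).  The quantity chain is the standard one for
mammographic quality control: entrance surface air kerma (ESAK) measured
by Al₂O₃:C optically stimulated luminescence dosimeters (OSLDs, "nanoDot"
chips) on a PMMA phantom, divided by a Monte Carlo backscatter factor
(BSF) to give the incident air kerma K, converted to average glandular
dose (AGD) by the published g/c/s/T factors:

    AGD = K · g · c · s · T        (T applies only to the moving-tube mode)

## Photon-interaction data

Coefficient tables for 1–40 keV ship as text files and are regenerated by
`scripts/generate_physics_tables.py`:

* **Totals** are pinned to the standard published mass-attenuation
  tabulations at the conventional grid energies; between anchors the
  photoelectric component follows a log-log cubic spline, so stored totals
  are exact at the anchor energies.  The anchor set was cross-validated by
  mass-fraction sums: air, PMMA and water assembled from the elemental
  anchors match the published compound tables to <0.2% over 10–40 keV.
* **Coherent** cross sections are integrated from Cromer–Mann atomic form
  factors (the standard crystallographic f₀ fits, which sum exactly to Z
  at zero momentum transfer).
* **Incoherent** cross sections start from Klein–Nishina weighted by the
  Waller–Hartree-style incoherent function S = Z − f₀²/Z.  That S is a
  strict upper bound (it drops off-diagonal terms), so the result is
  rescaled by a smooth factor fixed by the identity
  `incoh = (total − coh − μen)/(1 − f_KN)` evaluated at 20/30/40 keV for
  air and aluminium, whose mass energy-absorption coefficients are known
  precisely.  The rescaling is ~0.90 at 20 keV, consistent with published
  incoherent data for low-Z media.
* **Mass energy-absorption** is photoelectric (minus a fluorescence-escape
  term) plus the Klein–Nishina energy-transfer share of incoherent
  scattering, with a final smooth correction pinning air and Al to the
  published μen values (exact at the anchors; air μen drives every kerma
  in the package).
* Al₂O₃:C is treated as stoichiometric Al₂O₃ at 3.97 g/cm³; the carbon
  doping is at the ppm level and dosimetrically irrelevant.
* Interpolation everywhere is log-log linear, the standard choice for
  photon cross sections in this range; requesting energies outside
  1–40 keV raises a range error naming the material.

## Spectrum model and beam-quality calibration

The continuum is the Kramers fluence form, N(E) ∝ (E₀ − E)/E, with the
tungsten L lines (8.3–11.3 keV) added below threshold; after the Rh
filter they carry <10⁻³ of the fluence.  Filtration is Beer–Lambert per
0.25 keV bin: 1 mm Be window, 0.05 mm Rh, plus a single Al-equivalent
*inherent* thickness that absorbs everything the model does not resolve
(target self-attenuation, housing, paddle).  That thickness is the one
free parameter of the source model: it is bisected once so the 28 kV beam
reproduces the system's measured half-value layer (0.54 mm Al) and is
then frozen.  The 25 and 34 kV HVLs are predictions: 0.500 and 0.595 mm
Al against measured 0.52 and 0.59.  A Thomson–Whiddington-style target
self-attenuation factor was evaluated and rejected: after re-anchoring at
28 kV it moves both predictions away from the measured values (it is
nearly degenerate with the tuned Al, and what little shape change remains
has the wrong sign).  The residual −0.02 mm at 25 kV is the known limit
of a one-parameter Kramers model against a beam whose measured 25→28 kV
hardness step is unusually small.

HVL itself is defined operationally: the Al thickness that halves the
spectrum's air kerma Σ φ(E)·E·(μen/ρ)_air(E), found by bisection to
10⁻⁴ mm.

## Scene and source geometry

Coordinates: x lateral, y chest-wall→nipple, z up, support surface at
z = 0.  Defaults (all configurable; the study does not print them):
source–support distance 65 cm; gantry rotation axis along y at 4 cm
height, so the tube sweeps *laterally* across the breast and tilted
projections are mirror-symmetric, as in the real acquisition; collimated
field (−15…15) × (0…18) cm on the support, i.e. the detector's lateral
extent, which keeps every dosimeter illuminated at ±25°; PMMA slab
16.5 × 20 cm footprint flush with the chest wall; 2 mm carbon-fiber
support; compression paddle off by default (its attenuation is inside
the HVL-anchored spectrum, and its presence cancels in BSF ratios).

The source emits a fixed number of photons per projection into a cone
rigidly attached to the tube head — the aperture the collimator subtends
at 0° — because the collimator does not re-shape during the sweep.
Directions are uniform over that aperture solid angle (rejection from
uniform-area proposals); the anode heel effect is a linear fluence ramp
along the chest→nipple axis of the aperture, weight 1.0 at the chest-wall
edge falling to 0.85 (configurable) at the far edge, applied as a
statistical weight.  Per-projection entrance kerma therefore shows the
physical inverse-square and obliquity falloff at tilted angles.

Twenty 2.5 mm-radius, 0.2 mm-thick Al₂O₃ discs lie on the phantom top
surface in a 4 × 5 grid (rows 2/6/10/14 cm from the chest wall, columns
±8/±4/0 cm), numbered row-major so dot 8 is the central dot 6 cm from
the chest wall.  Each chip sits inside its plastic OSLD case, modeled as
an angle-dependent attenuation of a 0.077 cm PMMA-equivalent wall (the
~0.9 mm of ~1.03 g/cm³ plastic above the chip) applied at tally time;
the wall's ~5% vertical attenuation largely cancels in backscatter
ratios but its 1/cos θ growth is a real part of the angular response.
Setting the wall thickness to zero recovers a bare chip.

## Transport and estimators

Photons undergo photoelectric absorption, incoherent scattering
(Klein–Nishina free-electron sampling of the angle and Compton energy
shift; no Doppler broadening) and coherent scattering (inverse-CDF
sampling of F² over squared momentum transfer with the Thomson
(1+cos²θ)/2 rejection), down to a 1 keV cutoff; histories also end on
leaving the world box.  The channel split uses the tabulated partial
coefficients, so attenuation is exact against the anchored totals even
though the sampled angular shapes are free-electron approximations.
Energy bookkeeping is exact per history: injected = locally deposited +
escaped + cutoff-terminated.

Dosimeter kerma uses the kerma approximation (collision kerma scored from
photon fluence; secondary-electron ranges ≪ disc size).  Every estimate
includes the detector response at the incidence angle: the chip's own
self-shielding — the projected-area average of (1 − e^(−μl)) over the
true cylinder chord distribution, tabulated against angle and μ (the
naive slab chord d/cos θ over-attenuates oblique scatter, which mostly
clips the rim with short chords) — times the case-wall transmission.
The disc remains *virtual* for transport (its perturbation of the
downstream field is neglected, which cancels in every ratio the package
reports).

Two estimators share this tally definition:

* **analog** — track-length scoring of actual chord traversals with
  exact per-chord attenuation, contribution w·L_eff·E·(μen/ρ)/V.
  Unbiased and assumption-free; the oracle in estimator-consistency
  tests, but slow to converge for 20 small discs (≈600 primary hits per
  disc per 10⁶ photons).
* **nee** (default) — three deterministic layers on top of the analog
  transport: (1) the primary component is computed analytically per
  history (heel × aperture solid angle × 1/r² × air attenuation ×
  detector response, averaged over the batch's sampled energies);
  (2) scatter events farther than 1.5 cm from a disc contribute their
  expected kerma through a next-event point-detector estimator with the
  same angular models as the transport sampling; (3) for the near-sphere
  portion of every flight the possible collision is integrated
  deterministically over the collision density μe^(−μt) dt
  (Gauss–Legendre nodes concentrated at the closest approach by a sinh
  substitution), using a tabulated disc-averaged ⟨1/r²⟩ and a 5-patch
  product average of pdf × solid angle across the disc face.  This
  removes the heavy-tailed randomness of collisions right next to a
  disc; per-disc batch uncertainty at 10⁶ photons is ~0.2–0.5%, versus
  ~4% analog.  Long analog reference runs bound the residual
  approximation error at ≈5% of the scatter component (≲0.6% of total
  kerma, well inside the backscatter-factor error budget).

Batch statistics: photons are split into n_batches (default 10)
independently seeded batches (`numpy` `SeedSequence` spawning, so results
are bit-reproducible for a given seed); the reported uncertainty is the
batch standard error over the mean, flagged against the study's 2%
convergence criterion.  Discs with zero tallied events are flagged rather
than reported as converged zeros.

## Acquisitions, BSF and angular response

2D mode is a single 0° projection.  3D mode defaults to 25 projections at
−24°…+24° in 2° steps, each weighted 1/25 — the sweep is quoted both as
"±25° at 2° intervals" (26 values) and as 25 projections with weight
1/25; the 25-projection reading is binding dosimetrically, and the ±25°
endpoints remain available to the angular-response curve.  The 3D ESAK is
the weighted per-angle sum with uncertainties combined in quadrature.

BSF is computed exactly as defined operationally: the same acquisition is
run with the phantom present and with it removed (discs kept at their
heights, independent logged seeds), and the per-disc ratio is averaged
over all 20 positions.  Per-disc BSFs support the central/off-central and
per-angle comparisons.  The surface-dose dispersion (CV) uses the sample
standard deviation (n−1): twenty dots are a sample.

The angular response divides the mean ESAK over the 20 dots at each
gantry angle by the 0° value at equal photons per projection.  Its
≈2% decrease at ±25° combines inverse-square growth of the focal–disc
distances (≈1%), the 1/cos θ lengthening of the case-wall path and the
chip's own oblique self-shielding (≈0.8%), and a small loss of
backscatter at oblique incidence — growing with tube voltage, as the
measured angular curves do.

## Synthetic measurement sessions

The generator emulates the study's session structure: 20 dots accumulate
3 irradiations and are read 3× each, plus 3 control dots and one
parallel-plate chamber reading per condition.  Readout model: dot-level
multiplicative lognormal sensitivity (default CV 7%, chosen so that added
to the simulated field non-uniformity of ~6–8% the reduced-session CV
lands in the study's reported 8.6–13.2% band), per-read multiplicative
Gaussian noise (1%), geometric per-read depletion (0.4%/read, well under
the cited 1.2% bound; the background depletes with the signal since both
are trapped charge), and an additive 0.05 mGy background (magnitude not
printed by the study; exposed in config).  The chamber is reference truth
by default; its uncertainty belongs to the 5% energy-response component
of the combined budget.  Reduction inverts this model exactly in the
noise-free limit: depletion-correct, average reads, subtract mean control
background, apply C, divide by the irradiation count; dots at or below
background are excluded and flagged.  Calibration recovery applies
C = Ki/(Ko − BG) to session means with a bootstrap-over-dots interval.

What the synthetic sessions do *not* emulate: reader optics, fading over
days, temperature effects, chamber drift — so end-to-end recovery tests
demonstrate correctness of the reduction chain, not hardware performance.

## Reported problem sizes

The acceptance computations use the study's own statistics where it
states them: 10⁶ photons for fixed-tube runs (per-disc tally uncertainty
then sits well below the 2% criterion thanks to the deterministic-primary
estimator) and 25 × 10⁵ photons for 3D sweeps.  Unit and property tests
run at 10³–10⁵ photons with fixed seeds.

## Known limitations

* One target/filter combination (W/Rh) and one sweep range (±25°); other
  combinations would need their own factor rows and HVL anchors.
* The spectrum model is calibrated, not ab initio; only its dosimetric
  content (HVL, BSF, relative responses) is validated.
* Free-electron Compton (no Doppler/binding in the *angular* shape) and
  independent-atom coherent form factors; binding enters through the
  anchored integrated cross sections.
* Kerma approximation and virtual discs: no electron transport, no
  inter-disc shadowing.
* The AGD conversion factors g/c/s/T and the OSLD calibration factors are
  consumed as published constants, not recomputed.
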