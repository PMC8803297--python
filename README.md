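# dbtdose

Entrance-surface and average glandular dosimetry for digital breast
tomosynthesis (DBT).

Mammography's dose metric is the **average glandular dose (AGD)** — the
mean absorbed dose to the glandular tissue of the compressed breast.  In
quality-control practice it is not measured directly: one measures the
**entrance surface air kerma (ESAK)** on a breast-equivalent PMMA phantom
(here with Al₂O₃:C optically stimulated luminescence dosimeters,
"nanoDots"), removes the phantom's backscatter with a Monte-Carlo
**backscatter factor (BSF)**, and converts the resulting incident air
kerma K with published factors:

    K   = ESAK / BSF
    AGD = K · g · c · s · T

where g converts incident air kerma to AGD for a 50%-glandularity breast,
c corrects the glandularity, s the W/Rh spectrum, and T the moving X-ray
tube of the 3D (tomosynthesis) acquisition; T ≡ 1 for the fixed-tube 2D
mode.  This package provides every piece of that chain for a dual-mode
DBT system (W anode, 0.05 mm Rh, 25/28/34 kV, ±25° sweep in 25
projections):

* `dbtdose.physics_data` — embedded 1–40 keV photon-interaction tables
  (anchored to the standard published tabulations) with log-log lookup;
* `dbtdose.spectrum` — a Kramers-form W/Rh spectrum model whose single
  free parameter (inherent Al-equivalent filtration) is tuned once to the
  measured 28 kV half-value layer; HVL, air kerma and heel model;
* `dbtdose.mc_transport` — vectorized Monte Carlo photon transport
  through the phantom scene with low-variance kerma estimators at the 20
  surface dosimeter positions (an analog track-length estimator is kept
  as the validation oracle);
* `dbtdose.acquisition` — 2D/3D acquisitions, backscatter factors,
  angular response, surface-dose dispersion;
* `dbtdose.dosimetry` — the closed-form chain above plus the OSLD
  calibration C = Ki/(Ko − BG) and the quadrature uncertainty budget;
* `dbtdose.synthetic` — synthetic nanoDot/chamber reading sessions with
  the study's structure (20 dots × 3 reads after 3 accumulated
  irradiations, 3 control dots), for end-to-end testing without hardware;
* `dbtdose.pipeline` / `dbtdose.cli` — a config-driven study replica and
  the `dbtdose` command-line tool.

See `docs/methods.md` for the physics and the modeling choices.

## Worked example

Half-value layers of the three beams (the 28 kV value is the calibration
anchor; 25 and 34 kV are predictions of the spectrum model):

```sh
$ dbtdose hvl --kvp 28
0.540
$ dbtdose hvl --kvp 34
0.595
```

Backscatter factors for 4 cm PMMA at 28 kV, fixed tube (per-disc table
plus the 20-dot mean; about half a minute at 10⁶ photons):

```sh
$ dbtdose simulate-bsf --kvp 28 --thickness 4 --mode 2D --photons 1e6 --seed 42
disc_id,bsf,se
1,1.0700,0.00099
2,1.0680,0.00148
...
mean,1.0673,0.00037
```

The mean BSF ≈ 1.07 says the phantom scatters about 7% extra kerma back
into a surface dosimeter on top of the incident beam.  Closing the chain
from an ESAK reading:

```sh
$ dbtdose agd --esak 2.0 --bsf 1.068 --kvp 28 --mode 3D --thickness 4
{"mode": "3D", "kvp": 28.0, "esak_mGy": 2.0, "bsf": 1.068, "K_mGy": 1.8727, "g": 0.306, "c": 1.035, "s": 1.042, "T": 0.97, "agd_mGy": 0.5995}
```

i.e. a 2.0 mGy entrance kerma on 4 cm PMMA (equivalent to a 4.5 cm,
40%-glandularity breast) corresponds to 0.60 mGy of average glandular dose per such
exposure in 3D mode.  `dbtdose run-study --out study/` produces the full
report bundle (HVL, BSF and angular-response tables, synthetic-session
AGD comparison, uncertainty budget, manifest with every seed).

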