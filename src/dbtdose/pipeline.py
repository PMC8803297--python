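"""End-to-end study replica: spectra and HVLs, backscatter factors for 2D
and 3D acquisitions, the angular-response curve, synthetic reading
sessions reduced to AGD, and the uncertainty budget -- all written as CSV
files plus a JSON manifest with every seed used.
"""
from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, acquisition, dosimetry, mc_transport, spectrum, synthetic
from .config import StudyConfig, validate_config

__all__ = ["run_study", "build_scene"]


def _spectrum_for(cfg: StudyConfig, kvp: float):
    sp = cfg.spectrum
    return spectrum.generate_spectrum(
        kvp, filtration=sp.get("filtration"),
        bin_width=sp.get("bin_width", 0.25),
        l_line_fraction=sp.get("l_line_fraction", 0.03))


def build_scene(cfg: StudyConfig, kvp: float,
                pmma_cm: float | None) -> mc_transport.Scene:
    geo = mc_transport.BeamGeometry(
        source_to_support=cfg.geometry.get("source_to_support", 65.0),
        rotation_axis_height=cfg.geometry.get("rotation_axis_height", 4.0),
        field=tuple(cfg.geometry.get("field", (-15.0, 15.0, 0.0, 18.0))))
    heel = spectrum.HeelModel(
        endpoint_ratio=cfg.heel.get("endpoint_ratio", 0.85))
    physics = mc_transport.ScenePhysics(
        estimator=cfg.mc.get("estimator", "nee"),
        coherent=cfg.mc.get("coherent", True),
    )
    phantom = mc_transport.PhantomStack(pmma_cm) if pmma_cm else None
    discs = []
    if cfg.disc_layout_file:
        surface = pmma_cm or 0.0
        discs = mc_transport.load_disc_layout(cfg.disc_layout_file, surface)
    return mc_transport.Scene(
        _spectrum_for(cfg, kvp), geo, heel, phantom, discs,
        support_thickness=cfg.mc.get("support_thickness", 0.2),
        paddle=cfg.mc.get("paddle", False), physics=physics)


def run_study(cfg: StudyConfig | None = None,
              output_dir: str | Path | None = None) -> dict:
    """Run the full study and write the report bundle.

    Returns the manifest dictionary.  Any stage failure aborts with the
    stage name; outputs written before the failure are left in place.
    """
    cfg = cfg or StudyConfig()
    findings = validate_config(cfg)
    if findings:
        raise ValueError("invalid config: " + "; ".join(findings))
    out = Path(output_dir or cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    root_ss = np.random.SeedSequence(cfg.seed)
    seeds = {}
    manifest = {"version": __version__, "seed": cfg.seed,
                "config": cfg.to_dict(), "outputs": [], "seeds": seeds,
                "started": time.strftime("%Y-%m-%dT%H:%M:%S")}
    stage = "hvl"
    try:
        # --- (a) HVL table ------------------------------------------------
        rows = []
        for block in cfg.configurations:
            kvp = float(block["kvp"])
            s = _spectrum_for(cfg, kvp)
            rows.append({"kvp": kvp, "hvl_mm_al": round(spectrum.compute_hvl(s), 3),
                         "mean_energy_keV": round(spectrum.mean_energy(s), 3)})
        _write_csv(pd.DataFrame(rows), out / "hvl.csv", cfg, manifest)

        # --- (b) BSF table (2D and 3D) -------------------------------------
        stage = "bsf"
        bsf_rows = []
        bsf_store = {}
        children = root_ss.spawn(2 * len(cfg.configurations))
        for i, block in enumerate(cfg.configurations):
            kvp, t = float(block["kvp"]), float(block["pmma_cm"])
            scene = build_scene(cfg, kvp, t)
            for j, mode in enumerate(("2D", "3D")):
                proto = acquisition.make_protocol(mode, kvp)
                n = cfg.photons if mode == "2D" else cfg.photons_3d
                seed = int(children[2 * i + j].generate_state(1)[0] % 2**31)
                seeds[f"bsf_{mode}_{kvp:g}kV_{t:g}cm"] = seed
                res = acquisition.compute_bsf(proto, scene, n_photons=n,
                                              n_batches=cfg.batches, seed=seed)
                bsf_store[(kvp, t, mode)] = res
                bsf_rows.append({
                    "pmma_cm": t, "kvp": kvp, "mode": mode,
                    "bsf_mean": round(res.mean, 4),
                    "bsf_se": round(res.mean_uncertainty, 5),
                    "esak_cv_pct": round(acquisition.esak_cv(res.esak), 2),
                    "seed": seed,
                })
        _write_csv(pd.DataFrame(bsf_rows), out / "bsf.csv", cfg, manifest)

        # --- (c) angular response ------------------------------------------
        stage = "angular_response"
        ang_cfg = cfg.angular
        scene = build_scene(cfg, float(ang_cfg["kvp"]), float(ang_cfg["pmma_cm"]))
        seed = int(root_ss.spawn(1)[0].generate_state(1)[0] % 2**31)
        seeds["angular_response"] = seed
        angles, rel, err = acquisition.angular_response(
            scene, ang_cfg["angles"], n_photons=cfg.photons,
            n_batches=cfg.batches, seed=seed)
        _write_csv(pd.DataFrame({"angle_deg": angles,
                                 "relative_esak": np.round(rel, 4),
                                 "se": np.round(err, 5)}),
                   out / "angular_response.csv", cfg, manifest)

        # --- (d) AGD table from synthetic sessions -------------------------
        stage = "agd"
        agd_rows = []
        for block in cfg.configurations:
            kvp, t = float(block["kvp"]), float(block["pmma_cm"])
            breast_cm, gland = dosimetry.pmma_to_breast(t)
            factors = dosimetry.get_factors(kvp, cfg.factors_file)
            c_stored = dosimetry.stored_calibration_factor(kvp, cfg.factors_file)
            out_const = cfg.output_mgy_per_mas.get(kvp, 0.04)
            for mode in ("2D", "3D"):
                res = bsf_store[(kvp, t, mode)]
                mas = acquisition.make_protocol(mode, kvp).mAs or 100.0
                # absolute scale: nominal output constant at the surface
                norm = out_const * mas / res.free_in_air.esak[
                    res.disc_ids == 8][0]
                true_map = res.esak.esak * norm
                seed = int(root_ss.spawn(1)[0].generate_state(1)[0] % 2**31)
                seeds[f"session_{mode}_{kvp:g}kV"] = seed
                session = synthetic.generate_session(
                    true_map, C_true=c_stored, seed=seed, kvp=kvp, mode=mode,
                    mAs=mas, phantom_cm=t, **cfg.noise)
                cal = dosimetry.CalibrationRecord(Ki=1.0, Ko=1.0 / c_stored,
                                                  BG=0.0)
                reduced = synthetic.reduce_session(session, cal)
                esak_dot8 = float(reduced.esak_mGy[reduced.dot_ids == 8][0])
                bsf = res.mean
                for source, esak in (
                        ("nanoDots", esak_dot8),
                        ("IC", session.chamber_mGy / session.n_irradiations),
                        ("simulation", true_map[res.disc_ids == 8][0])):
                    K = dosimetry.incident_kerma_from_esak(esak, bsf)
                    agd = dosimetry.compute_agd(K, factors, mode, breast_cm,
                                                gland)
                    agd_rows.append({
                        "breast_cm": breast_cm, "kvp": kvp, "mode": mode,
                        "source": source, "esak_mGy": round(esak, 3),
                        "bsf": round(bsf, 4), "K_mGy": round(K, 3),
                        "agd_mGy": round(agd.AGD, 2)})
        _write_csv(pd.DataFrame(agd_rows), out / "agd.csv", cfg, manifest)

        # --- (e) uncertainty budget ----------------------------------------
        stage = "uncertainty"
        budget = dosimetry.combined_uncertainty(
            5.0, 3.0, labels=("beam energy response", "angular response"))
        rows = [{"component": n, "percent": v} for n, v in budget.components]
        rows.append({"component": "combined", "percent": budget.display})
        _write_csv(pd.DataFrame(rows), out / "uncertainty.csv", cfg, manifest)
    except Exception as exc:
        raise RuntimeError(f"study stage {stage!r} failed: {exc}") from exc

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest


def _write_csv(df: pd.DataFrame, path: Path, cfg: StudyConfig,
               manifest: dict) -> None:
    with open(path, "w") as fh:
        fh.write(f"# dbtdose {__version__}; seed {cfg.seed}; "
                 f"manifest manifest.json\n")
        df.to_csv(fh, index=False)
    manifest["outputs"].append(path.name)
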