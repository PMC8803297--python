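"""Study configuration: loading, defaults and validation.

A study config is a YAML file with optional blocks; every omitted value
falls back to the package default, so ``StudyConfig()`` is a complete,
runnable configuration.  ``validate_config`` returns a list of findings
(strings) instead of raising, except for unparseable input.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import synthetic

__all__ = ["StudyConfig", "load_config", "validate_config"]

DEFAULT_CONFIGURATIONS = (
    {"kvp": 25.0, "pmma_cm": 2.0},
    {"kvp": 28.0, "pmma_cm": 4.0},
    {"kvp": 34.0, "pmma_cm": 7.0},
)

# Nominal tube output at the entrance surface (mGy per mAs) used only to
# put synthetic sessions on an absolute scale; configurable per beam.
DEFAULT_OUTPUT_MGY_PER_MAS = {25.0: 0.026, 28.0: 0.039, 34.0: 0.067}


@dataclass
class StudyConfig:
    seed: int = 1234
    output_dir: str = "study_outputs"
    photons: int = 100_000
    batches: int = 10
    photons_3d: int = 20_000          # per projection in 3D acquisitions
    spectrum: dict = field(default_factory=lambda: {
        "bin_width": 0.25, "l_line_fraction": 0.03, "filtration": None})
    geometry: dict = field(default_factory=lambda: {
        "source_to_support": 65.0, "rotation_axis_height": 4.0,
        "field": [-15.0, 15.0, 0.0, 18.0]})
    heel: dict = field(default_factory=lambda: {"endpoint_ratio": 0.85})
    mc: dict = field(default_factory=lambda: {
        "uncertainty_threshold": 0.02, "estimator": "nee",
        "coherent": True, "support_thickness": 0.2, "paddle": False})
    noise: dict = field(default_factory=lambda: {
        "cv_dot": synthetic.DEFAULT_CV_DOT,
        "read_noise": synthetic.DEFAULT_READ_NOISE,
        "depletion_per_read": synthetic.DEFAULT_DEPLETION,
        "bg_level": synthetic.DEFAULT_BG,
        "n_irradiations": synthetic.DEFAULT_N_IRRADIATIONS})
    configurations: tuple = DEFAULT_CONFIGURATIONS
    angular: dict = field(default_factory=lambda: {
        "kvp": 34.0, "pmma_cm": 7.0,
        "angles": [-25, -20, -15, -10, -5, 0, 5, 10, 15, 20, 25]})
    output_mgy_per_mas: dict = field(
        default_factory=lambda: dict(DEFAULT_OUTPUT_MGY_PER_MAS))
    factors_file: str | None = None
    disc_layout_file: str | None = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path: str | Path | None) -> StudyConfig:
    """Load a YAML study config; ``None`` yields the defaults."""
    cfg = StudyConfig()
    if path is None:
        return cfg
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    for key, value in data.items():
        if not hasattr(cfg, key):
            raise KeyError(f"unknown config key {key!r}")
        current = getattr(cfg, key)
        if isinstance(current, dict) and isinstance(value, dict):
            current.update(value)
        else:
            setattr(cfg, key, value)
    return cfg


def validate_config(cfg: StudyConfig) -> list[str]:
    """Schema / physical-range / cross-reference checks; returns findings."""
    findings: list[str] = []
    if not 0 < cfg.heel.get("endpoint_ratio", 0.85) <= 1.0:
        findings.append("heel ratio must be in (0, 1]")
    for block in cfg.configurations:
        kvp = float(block.get("kvp", 0))
        if not 20.0 <= kvp <= 40.0:
            findings.append(f"tube voltage {kvp:g} kV outside [20, 40]")
        t = float(block.get("pmma_cm", 0))
        if not 0.5 <= t <= 10.0:
            findings.append(f"PMMA thickness {t:g} cm outside [0.5, 10]")
    if cfg.mc.get("estimator") not in ("nee", "analog"):
        findings.append("mc.estimator must be 'nee' or 'analog'")
    if not 0 <= cfg.noise.get("depletion_per_read", 0.4) <= 1.2:
        findings.append("depletion per read must lie in [0, 1.2] percent")
    if cfg.photons < 1000 or cfg.photons_3d < 1000:
        findings.append("photon counts must be >= 1000")
    for key in ("factors_file", "disc_layout_file"):
        path = getattr(cfg, key)
        if path is not None and not Path(path).exists():
            findings.append(f"{key} does not exist: {path}")
    angles = cfg.angular.get("angles", [])
    if 0 not in [int(a) for a in angles]:
        findings.append("angular.angles must include 0 degrees")
    return findings
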