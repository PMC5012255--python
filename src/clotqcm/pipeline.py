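"""End-to-end orchestration: spectra -> kinetics -> rigidity, and
images -> fibre metrics, with a machine-readable JSON report.

Reports carry a schema version, the package version, a hash of the
resolved configuration and the seed, so a re-run with identical config and
inputs produces an identical report (timestamps excluded by design: none
are recorded).  Intermediate artifacts — the fitted shift series and the
per-time viscoelastic series — are written next to the report so each
analysis stage can be audited.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .errors import ConfigError
from .fibres import fibre_metrics
from .io import (
    read_image,
    read_shift_csv,
    read_spectra_csv,
    write_shift_csv,
    write_visco_csv,
)
from .kinetics import extract_kinetics
from .rigidity import ViscoConstants, rigidity_series, rigidity_summary
from .spectra import AirReference, track_resonance

__all__ = ["RunConfig", "run_qcm_pipeline", "run_image_pipeline", "load_config"]

logger = logging.getLogger("clotqcm.pipeline")

REPORT_SCHEMA = "clotqcm-report/1"


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    # QCM branch: either raw sweeps or a pre-referenced shift series
    spectra_path: str | None = None
    shift_path: str | None = None
    f_air: float = 5_000_000.0
    gamma_air: float = 30.0
    z_index: int = 0
    smooth_window: int = 11
    a: float = 2.5e-7
    b: float = 1e-3
    rf_floor: float = 1.0
    summary_window: tuple[float, float] | None = None
    # image branch
    image_paths: list[str] = field(default_factory=list)
    pixel_size_nm: float | None = None
    cutoff_px: float = 2.0
    # common
    out_dir: str = "."
    seed: int = 0

    def validate_qcm(self) -> None:
        if (self.spectra_path is None) == (self.shift_path is None):
            raise ConfigError("exactly one of spectra_path or shift_path is required")
        path = self.spectra_path or self.shift_path
        if not Path(path).exists():
            raise ConfigError(f"input not found: {path}")
        if self.a <= 0 or self.b <= 0:
            raise ConfigError("constants a and b must be positive")

    def validate_images(self) -> None:
        if self.image_paths and self.pixel_size_nm is None:
            raise ConfigError("pixel_size_nm is required for image analysis")
        for p in self.image_paths:
            if not Path(p).exists():
                raise ConfigError(f"image not found: {p}")

    def digest(self) -> str:
        # out_dir changes where results land, not what they are
        fields = {k: v for k, v in dataclasses.asdict(self).items() if k != "out_dir"}
        blob = json.dumps(fields, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(path: str | Path, **overrides) -> RunConfig:
    """Load a YAML key-value config file; keyword overrides win."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    raw.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    if "summary_window" in raw and raw["summary_window"] is not None:
        raw["summary_window"] = tuple(raw["summary_window"])
    return RunConfig(**raw)


def _provenance(cfg: RunConfig) -> dict:
    return {
        "schema": REPORT_SCHEMA,
        "version": __version__,
        "config_hash": cfg.digest(),
        "seed": cfg.seed,
    }


def run_qcm_pipeline(cfg: RunConfig) -> dict:
    """Spectra (or shift series) -> kinetics per channel -> rigidity.

    Returns the report dict; also writes report.json, the fitted shift
    series CSV and the viscoelastic series CSV under cfg.out_dir.
    """
    cfg.validate_qcm()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if cfg.spectra_path is not None:
        logger.info("fitting spectra from %s", cfg.spectra_path)
        spectra = read_spectra_csv(cfg.spectra_path)
        air = AirReference(f_air=cfg.f_air, gamma_air=cfg.gamma_air)
        series = track_resonance(spectra, air)
        if cfg.z_index:
            series = dataclasses.replace(series, z_index=cfg.z_index)
    else:
        series = read_shift_csv(cfg.shift_path, z_index=cfg.z_index)
    write_shift_csv(series, out / "shift_series.csv")

    kinetics = {}
    for channel in ("frequency", "bandwidth"):
        kp = extract_kinetics(series, channel=channel[0] if channel == "frequency" else "gamma",
                              smooth_window=cfg.smooth_window)
        kinetics[channel] = {
            "max_shift_hz": kp.max_shift,
            "R_qcm_s": kp.R_qcm,
            "MRCF_hz_per_s": kp.MRCF,
            "TMRCF_s": kp.TMRCF,
        }

    vs = rigidity_series(series, ViscoConstants(a=cfg.a, b=cfg.b), rf_floor=cfg.rf_floor)
    write_visco_csv(vs, out / "visco_series.csv")
    mu, M, rf = rigidity_summary(vs, cfg.summary_window)

    report = {
        **_provenance(cfg),
        "kind": "qcm",
        "kinetics": kinetics,
        "rigidity": {"mu_t": mu, "M_t": M, "RF": rf},
    }
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


def run_image_pipeline(cfg: RunConfig) -> dict:
    """Batch fibre-network analysis with row-level error isolation.

    A failing image yields an error row; the remaining images are still
    analysed.  An empty batch produces an empty report with a warning.
    """
    cfg.validate_images()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not cfg.image_paths:
        logger.warning("empty image batch: writing empty report")
    rows = []
    for path in cfg.image_paths:
        try:
            img = read_image(path, cfg.pixel_size_nm)
            m = fibre_metrics(img, min_size_px=cfg.cutoff_px)
            rows.append(
                {
                    "image": str(path),
                    "F_Por": m.F_Por,
                    "F_Dens_per_um": m.F_Dens,
                    "F_Diam_nm": m.F_Diam,
                    "peak_freq_px": m.peak_freq_px,
                    "flags": list(m.flags),
                }
            )
        except Exception as err:  # row-level isolation
            logger.error("image %s failed: %s", path, err)
            rows.append({"image": str(path), "error": f"{type(err).__name__}: {err}"})
    report = {**_provenance(cfg), "kind": "images", "images": rows}
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
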