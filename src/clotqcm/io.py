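"""Delimited-text and image IO for the pipeline.

Spectrum files are long-format CSV/TSV with columns ``timestamp_s,
frequency_hz, conductance`` — one block of rows per sweep, blocks in time
order.  Pre-fitted resonance series use ``time_s, f_hz, gamma_hz``; shift
series use ``time_s, dF_hz, dG_hz``.  Images are 8/16-bit grey TIFF or
PNG; the pixel size is never parsed from the image and must be supplied.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .fibres import FibreImage
from .rigidity import ViscoSeries
from .spectra import AirReference, ConductanceSpectrum, ShiftSeries

__all__ = [
    "read_spectra_csv",
    "write_spectra_csv",
    "read_fitted_csv",
    "read_shift_csv",
    "write_shift_csv",
    "write_visco_csv",
    "read_image",
    "write_image",
]

_SEP = {".tsv": "\t", ".tab": "\t"}


def _sep_for(path: Path) -> str:
    return _SEP.get(path.suffix.lower(), ",")


def read_spectra_csv(path: str | Path) -> list[ConductanceSpectrum]:
    """Read a long-format sweep file into per-timestamp spectra."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    required = {"timestamp_s", "frequency_hz", "conductance"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}, got {list(df.columns)}")
    spectra = []
    for ts, block in df.groupby("timestamp_s", sort=True):
        block = block.sort_values("frequency_hz")
        spectra.append(
            ConductanceSpectrum(
                timestamp=float(ts),
                frequencies=block["frequency_hz"].to_numpy(float),
                conductance=block["conductance"].to_numpy(float),
            )
        )
    return spectra


def write_spectra_csv(spectra: Sequence[ConductanceSpectrum], path: str | Path) -> None:
    path = Path(path)
    frames = [
        pd.DataFrame(
            {
                "timestamp_s": s.timestamp,
                "frequency_hz": s.frequencies,
                "conductance": s.conductance,
            }
        )
        for s in spectra
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, sep=_sep_for(path), index=False)


def read_fitted_csv(path: str | Path, air: AirReference, z_index: int = 0) -> ShiftSeries:
    """Read a pre-fitted (time, f, gamma) series and reference it to air."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    required = {"time_s", "f_hz", "gamma_hz"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}, got {list(df.columns)}")
    return ShiftSeries(
        t=df["time_s"].to_numpy(float),
        dF=air.f_air - df["f_hz"].to_numpy(float),
        dG=df["gamma_hz"].to_numpy(float) - air.gamma_air,
        z_index=z_index,
    )


def read_shift_csv(path: str | Path, z_index: int = 0) -> ShiftSeries:
    """Read an in-air-referenced shift series (time_s, dF_hz, dG_hz)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    required = {"time_s", "dF_hz", "dG_hz"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}, got {list(df.columns)}")
    return ShiftSeries(
        t=df["time_s"].to_numpy(float),
        dF=df["dF_hz"].to_numpy(float),
        dG=df["dG_hz"].to_numpy(float),
        z_index=z_index,
    )


def write_shift_csv(series: ShiftSeries, path: str | Path) -> None:
    path = Path(path)
    pd.DataFrame(
        {
            "time_s": series.t,
            "dF_hz": series.dF,
            "dG_hz": series.dG,
            "dF_star_hz": series.dF_star,
            "dG_star_hz": series.dG_star,
        }
    ).to_csv(path, sep=_sep_for(path), index=False)


def write_visco_csv(vs: ViscoSeries, path: str | Path) -> None:
    path = Path(path)
    pd.DataFrame(
        {"time_s": vs.t, "c": vs.c, "mu_t": vs.mu_t, "M_t": vs.M_t, "RF": vs.RF}
    ).to_csv(path, sep=_sep_for(path), index=False)


def read_image(path: str | Path, pixel_size_nm: float) -> FibreImage:
    """Load a grey-level TIFF/PNG; RGB inputs are averaged to grey."""
    arr = np.asarray(iio.imread(Path(path)))
    if arr.ndim == 3:
        arr = arr[..., :3].mean(axis=-1)
    return FibreImage(pixels=arr.astype(float), pixel_size=pixel_size_nm)


def write_image(img: FibreImage, path: str | Path) -> None:
    """Write pixels as 16-bit grey, rescaled to the full range."""
    px = img.pixels
    lo, hi = float(px.min()), float(px.max())
    scale = (px - lo) / (hi - lo) if hi > lo else np.zeros_like(px)
    iio.imwrite(Path(path), (scale * 65535).astype(np.uint16))
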