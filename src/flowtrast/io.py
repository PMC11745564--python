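"""File writers and readers: profile/metrics CSV, grayscale TIFF/PNG image
export, and JSON provenance sidecars.

CSV numbers are written with 9 significant digits so a round-trip read
reproduces the normalized signal to full working precision; Fnorm images are
scaled linearly onto the full 16-bit grayscale range (8-bit for PNG
previews), matching how an sCMOS frame would be stored.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .beam import IntensityField
from .flow import FnormImage, SignalProfile

__all__ = [
    "write_profile_csv",
    "read_profile_csv",
    "write_metrics_csv",
    "write_image_tiff",
    "write_image_png",
    "write_beam_field",
    "write_sidecar",
]

_FMT = "%.9g"

PROFILE_COLUMNS = ["x_um", "t_us", "F_raw", "F_norm"]
METRICS_COLUMNS = [
    "dye",
    "I0_kW_cm2",
    "Q_uL_min",
    "fwhm_broadening_um",
    "peak_shift_um",
    "decay_fraction",
]


def _profile_metadata(profile: SignalProfile) -> dict:
    beam = profile.beam
    return {
        "dye": profile.dye_name,
        "I0_kW_cm2": profile.I0 / 1e3,
        "Q_uL_min": profile.flow_rate_Q,
        "w_um": beam.waist_w if beam else float("nan"),
        "L_um": beam.stretch_L if beam else float("nan"),
        "order_n": beam.order_n if beam else 6,
        "wavelength_nm": beam.wavelength if beam else float("nan"),
        "velocity_m_s": profile.velocity,
    }


def write_profile_csv(profile: SignalProfile, path: str | Path) -> Path:
    """Write one signal profile with ``# key=value`` metadata header lines."""
    path = Path(path)
    lines = [f"# {k}={_FMT % v if isinstance(v, float) else v}"
             for k, v in _profile_metadata(profile).items()]
    df = pd.DataFrame(
        {"x_um": profile.x, "t_us": profile.t, "F_raw": profile.F,
         "F_norm": profile.Fnorm}
    )
    body = df.to_csv(index=False, float_format=_FMT)
    path.write_text("\n".join(lines) + "\n" + body)
    return path


def read_profile_csv(path: str | Path) -> tuple[pd.DataFrame, dict]:
    """Read a profile CSV back; returns (dataframe, metadata dict)."""
    path = Path(path)
    meta: dict = {}
    with path.open() as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if not line.startswith("#"):
                fh.seek(pos)
                break
            key, _, value = line[1:].strip().partition("=")
            try:
                meta[key] = float(value)
            except ValueError:
                meta[key] = value
            pos = fh.tell()
        df = pd.read_csv(fh)
    missing = set(PROFILE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"profile CSV {path} missing columns {sorted(missing)}")
    return df, meta


def write_metrics_csv(rows: list[dict], path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(rows, columns=METRICS_COLUMNS)
    df.to_csv(path, index=False, float_format=_FMT)
    return path


def write_image_tiff(image: FnormImage | IntensityField, path: str | Path) -> Path:
    """16-bit grayscale TIFF for Fnorm images; 32-bit float for beam fields."""
    path = Path(path)
    if isinstance(image, FnormImage):
        data = np.round(image.grid * 65535.0).astype(np.uint16)
    else:
        data = image.grid.astype(np.float32)
    tifffile.imwrite(path, data)
    return path


def write_image_png(image: FnormImage, path: str | Path) -> Path:
    """8-bit grayscale PNG preview."""
    import imageio.v3 as iio

    path = Path(path)
    data = np.round(image.grid * 255.0).astype(np.uint8)
    iio.imwrite(path, data)
    return path


def write_beam_field(fld: IntensityField, reference: np.ndarray,
                     basepath: str | Path) -> tuple[Path, Path]:
    """Beam export: 32-bit float TIFF of the field plus the normalized
    along-flow reference profile as CSV (x_um, I_norm)."""
    basepath = Path(basepath)
    tiff = write_image_tiff(fld, basepath.with_suffix(".tiff"))
    csv = basepath.with_suffix(".csv")
    pd.DataFrame({"x_um": fld.x, "I_norm": reference}).to_csv(
        csv, index=False, float_format=_FMT
    )
    return tiff, csv


def write_sidecar(payload: dict, path: str | Path) -> Path:
    """JSON provenance sidecar containing every input needed to regenerate
    the artifact."""
    path = Path(path)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=str))
    return path
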