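"""Run configuration: schema-validated YAML/JSON settings whose defaults
reproduce the reference experiment (488 nm, n=6, w=50 μm, L=100 μm beam;
100×50 μm² channel; 2048-pixel/6.5 μm/4×-binned/60× camera; the standard
irradiance and flow-rate grids)."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .beam import BeamSpec, peak_irradiance
from .catalog import dye_names
from .flow import CameraModel, FlowCell

__all__ = ["ConfigError", "RunConfig", "load_config", "DEFAULT_POWERS_MW",
           "DEFAULT_FLOW_RATES", "default_irradiances"]

# Laser output powers [mW] spanning the 5–300 mW range of 488 nm CW diode
# lasers; with the default beam they give I0 from 0.06 to 3.63 kW/cm².
DEFAULT_POWERS_MW = (5.0, 10.0, 25.0, 50.0, 100.0, 150.0, 300.0)
DEFAULT_FLOW_RATES = (100.0, 500.0, 1000.0, 2000.0)  # μL/min


class ConfigError(ValueError):
    """Malformed configuration file."""


@dataclass(frozen=True)
class RunConfig:
    dyes: tuple[str, ...] = ()
    order_n: int = 6
    waist_w: float = 50.0
    stretch_L: float = 100.0
    wavelength: float = 488.0
    powers_mW: tuple[float, ...] = DEFAULT_POWERS_MW
    irradiances: tuple[float, ...] = ()  # W/cm², derived from powers if empty
    channel_length: float = 221.86
    channel_width: float = 100.0
    channel_height: float = 50.0
    flow_rates: tuple[float, ...] = DEFAULT_FLOW_RATES
    native_pixels: int = 2048
    native_pixel_size: float = 6.5
    binning: int = 4
    magnification: float = 60.0
    outdir: str = "out"
    formats: tuple[str, ...] = ("csv", "tiff")

    def __post_init__(self) -> None:
        if not self.dyes:
            object.__setattr__(self, "dyes", tuple(dye_names()))
        if not self.irradiances:
            object.__setattr__(
                self,
                "irradiances",
                tuple(
                    peak_irradiance(p, self.waist_w, self.stretch_L, self.order_n)
                    for p in self.powers_mW
                ),
            )
        # instantiating the component specs validates their invariants
        self.beam(self.irradiances[0])
        self.cell(self.flow_rates[0])
        self.camera()
        bad = set(self.formats) - {"csv", "tiff", "png"}
        if bad:
            raise ConfigError(f"unknown output formats: {sorted(bad)}")

    def beam(self, I0: float) -> BeamSpec:
        return BeamSpec(order_n=self.order_n, waist_w=self.waist_w,
                        stretch_L=self.stretch_L, wavelength=self.wavelength,
                        I0=I0)

    def cell(self, Q: float) -> FlowCell:
        return FlowCell(channel_length=self.channel_length,
                        channel_width=self.channel_width,
                        channel_height=self.channel_height, flow_rate_Q=Q)

    def camera(self) -> CameraModel:
        return CameraModel(native_pixels=self.native_pixels,
                           native_pixel_size=self.native_pixel_size,
                           binning=self.binning,
                           magnification=self.magnification)

    def provenance(self) -> dict:
        return asdict(self)


_SECTION_KEYS = {
    "dyes": None,
    "beam": {"order_n", "waist_w", "stretch_L", "wavelength", "powers_mW",
             "I0_kW_cm2"},
    "flow": {"channel_length", "channel_width", "channel_height", "flow_rates"},
    "camera": {"native_pixels", "native_pixel_size", "binning", "magnification"},
    "outputs": {"directory", "formats"},
}


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a YAML (or JSON) configuration; missing keys take the defaults.

    The beam section accepts either ``powers_mW`` (laser output powers, mW)
    or ``I0_kW_cm2`` (peak irradiances); whichever is absent is derived
    through the beam power integral.  Unknown sections or keys are rejected.
    """
    if path is None:
        return RunConfig()
    text = Path(path).read_text()
    raw = yaml.safe_load(text) if text.strip() else {}
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    unknown = set(raw) - set(_SECTION_KEYS)
    if unknown:
        raise ConfigError(f"unknown config sections: {sorted(unknown)}")
    kwargs: dict = {}
    if "dyes" in raw:
        if not isinstance(raw["dyes"], list):
            raise ConfigError("dyes must be a list of catalog names")
        known = set(dye_names())
        bad = set(raw["dyes"]) - known
        if bad:
            raise ConfigError(f"unknown dyes: {sorted(bad)}; catalog has {sorted(known)}")
        kwargs["dyes"] = tuple(raw["dyes"])
    for section in ("beam", "flow", "camera", "outputs"):
        if section not in raw:
            continue
        body = raw[section] or {}
        allowed = _SECTION_KEYS[section]
        unknown = set(body) - allowed
        if unknown:
            raise ConfigError(f"unknown keys in [{section}]: {sorted(unknown)}")
        for key, value in body.items():
            if key == "I0_kW_cm2":
                kwargs["irradiances"] = tuple(1e3 * v for v in value)
            elif key == "directory":
                kwargs["outdir"] = value
            elif key in ("powers_mW", "flow_rates", "formats"):
                kwargs[key] = tuple(value)
            else:
                kwargs[key] = value
    try:
        return RunConfig(**kwargs)
    except ConfigError:
        raise
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc


def dump_config(cfg: RunConfig, path: str | Path) -> None:
    """Write the fully-resolved configuration as JSON provenance."""
    Path(path).write_text(json.dumps(cfg.provenance(), indent=2, sort_keys=True))
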