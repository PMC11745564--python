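"""Dye catalog: TRAST-measured photophysical constants of carboxyfluorescein
(CFl) and its brominated derivatives CFl-1Br, CFl-2Br and CFl-4Br (eosin-Y).

Bromination enhances spin-orbit coupling (the internal heavy-atom effect),
so the intrinsic ISC rate grows steeply along the series while the
fluorescence lifetime shortens.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .photophysics import DyeParams

__all__ = ["CatalogError", "load_catalog", "get_dye", "dye_names"]

_COLUMNS = [
    "name",
    "tau_f_ns",
    "sigma_exc_cm2",
    "kisc_per_us",
    "kT_per_us",
    "kred_per_us",
    "kox_per_us",
]


class CatalogError(KeyError):
    """Unknown dye name or malformed catalog file."""


def load_catalog(path: str | Path | None = None) -> dict[str, DyeParams]:
    """Load a dye catalog CSV; defaults to the built-in four-dye catalog."""
    if path is None:
        with resources.files("flowtrast.data").joinpath("dye_catalog.csv").open() as fh:
            df = pd.read_csv(fh)
    else:
        df = pd.read_csv(path)
    missing = set(_COLUMNS) - set(df.columns)
    if missing:
        raise CatalogError(f"catalog missing columns: {sorted(missing)}")
    dyes: dict[str, DyeParams] = {}
    for row in df.itertuples(index=False):
        dyes[row.name] = DyeParams(
            name=row.name,
            tau_f=row.tau_f_ns,
            sigma_exc=row.sigma_exc_cm2,
            k_isc=row.kisc_per_us,
            k_T=row.kT_per_us,
            k_red=row.kred_per_us,
            k_ox=row.kox_per_us,
        )
    return dyes


def get_dye(name: str, path: str | Path | None = None) -> DyeParams:
    """Look one dye up by name; raises :class:`CatalogError` if absent."""
    dyes = load_catalog(path)
    try:
        return dyes[name]
    except KeyError:
        raise CatalogError(
            f"unknown dye {name!r}; catalog has {sorted(dyes)}"
        ) from None


def dye_names(path: str | Path | None = None) -> list[str]:
    return list(load_catalog(path))
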