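"""Ekman upwelling velocity from wind stress and the upwelled-nitrate flux.

Ekman pumping at the base of the surface Ekman layer is the vertical
velocity forced by the curl of (wind stress / Coriolis parameter),

    w_E = (1/rho0) * k . curl( tau / f ),

evaluated here on a regular latitude-longitude grid with the full spherical
metric terms:

    w_E = (1/rho0) * 1/(R cos(phi)) * [ d(tau_y/f)/dlambda
                                        - d((tau_x/f) cos(phi))/dphi ].

Positive w_E is upwelling.  The equatorial band is masked (f -> 0
singularity).  The upwelled-nitrate proxy multiplies w_E by the nitrate
concentration immediately below the mixed layer (a user-supplied field).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "EARTH_RADIUS_M",
    "EARTH_OMEGA",
    "DEFAULT_RHO0",
    "DEFAULT_EQUATOR_MASK_DEG",
    "coriolis",
    "ekman_velocity",
    "upwelled_nitrate",
    "EkmanField",
    "read_grid",
    "write_grid",
]

EARTH_RADIUS_M = 6.371e6
EARTH_OMEGA = 7.2921159e-5  # rad/s
DEFAULT_RHO0 = 1025.0  # kg/m^3 surface seawater reference density
DEFAULT_EQUATOR_MASK_DEG = 5.0


def coriolis(lat_deg) -> np.ndarray:
    """Coriolis parameter f = 2*Omega*sin(lat) in s^-1."""
    return 2.0 * EARTH_OMEGA * np.sin(np.deg2rad(np.asarray(lat_deg, dtype=float)))


def _check_axes(lats, lons):
    lats = np.asarray(lats, dtype=float)
    lons = np.asarray(lons, dtype=float)
    for name, ax in (("lats", lats), ("lons", lons)):
        if ax.ndim != 1 or len(ax) < 2:
            raise ValueError(f"{name} must be a 1-D axis with >= 2 points")
        d = np.diff(ax)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError(f"{name} must be strictly monotone")
    return lats, lons


def ekman_velocity(taux, tauy, lats, lons, rho0: float = DEFAULT_RHO0,
                   equator_mask_deg: float = DEFAULT_EQUATOR_MASK_DEG) -> np.ndarray:
    """Ekman vertical velocity w_E (m/s) on a (nlat, nlon) grid.

    ``taux``/``tauy`` are zonal/meridional wind stress in N m^-2 on the same
    grid.  Centered finite differences (one-sided at the edges); cells with
    |lat| < ``equator_mask_deg`` return NaN."""
    lats, lons = _check_axes(lats, lons)
    taux = np.asarray(taux, dtype=float)
    tauy = np.asarray(tauy, dtype=float)
    shape = (len(lats), len(lons))
    if taux.shape != shape or tauy.shape != shape:
        raise ValueError(
            f"stress grids must have shape {shape}, got {taux.shape} / {tauy.shape}"
        )
    if not rho0 > 0:
        raise ValueError("rho0 must be > 0")
    phi = np.deg2rad(lats)[:, None]
    lam = np.deg2rad(lons)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = coriolis(lats)[:, None]
        a = tauy / f  # differentiated along longitude
        b = (taux / f) * np.cos(phi)  # differentiated along latitude
        da_dlam = np.gradient(a, lam, axis=1)
        db_dphi = np.gradient(b, np.deg2rad(lats), axis=0)
        w = (da_dlam - db_dphi) / (rho0 * EARTH_RADIUS_M * np.cos(phi))
    w = np.where(np.abs(lats)[:, None] < equator_mask_deg, np.nan, w)
    return w


def upwelled_nitrate(w_e, nitrate):
    """Elementwise upwelled-nitrate flux (µmol L^-1 · m s^-1).

    Downwelling (w_E < 0) is reported as zero flux; the raw signed product
    is returned alongside.  NaN (masked) cells propagate.  Returns
    ``(flux, raw_product)``."""
    w_e = np.asarray(w_e, dtype=float)
    nitrate = np.asarray(nitrate, dtype=float)
    if w_e.shape != nitrate.shape:
        raise ValueError(f"grid shapes differ: {w_e.shape} vs {nitrate.shape}")
    if np.any(nitrate[np.isfinite(nitrate)] < 0):
        raise ValueError("negative nitrate concentration")
    raw = w_e * nitrate
    flux = np.where(raw < 0, 0.0, raw)
    return flux, raw


@dataclass
class EkmanField:
    """Bundled wind-stress grids with derived Ekman and flux layers."""

    lats: np.ndarray
    lons: np.ndarray
    taux: np.ndarray
    tauy: np.ndarray
    rho0: float = DEFAULT_RHO0
    equator_mask_deg: float = DEFAULT_EQUATOR_MASK_DEG
    nitrate_below_ml: np.ndarray | None = None
    w_e: np.ndarray = field(init=False)
    flux: np.ndarray | None = field(init=False, default=None)
    raw_flux: np.ndarray | None = field(init=False, default=None)

    def __post_init__(self):
        self.lats, self.lons = _check_axes(self.lats, self.lons)
        self.w_e = ekman_velocity(
            self.taux, self.tauy, self.lats, self.lons,
            rho0=self.rho0, equator_mask_deg=self.equator_mask_deg,
        )
        if self.nitrate_below_ml is not None:
            self.flux, self.raw_flux = upwelled_nitrate(
                self.w_e, self.nitrate_below_ml
            )


def write_grid(path, lats, lons, values) -> None:
    """CSV grid layout: first column 'lat', remaining columns the longitude
    axis values; one row per latitude."""
    lats, lons = _check_axes(lats, lons)
    df = pd.DataFrame(np.asarray(values, dtype=float),
                      index=pd.Index(lats, name="lat"),
                      columns=[repr(float(x)) for x in lons])
    df.to_csv(path)


def read_grid(path):
    """Inverse of :func:`write_grid`; returns ``(lats, lons, values)``."""
    df = pd.read_csv(path, index_col="lat")
    lats = df.index.to_numpy(dtype=float)
    lons = np.array([float(c) for c in df.columns])
    return lats, lons, df.to_numpy(dtype=float)
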