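"""Per-profile corrections and water-column diagnostics for BGC float data.

A :class:`VerticalProfile` holds one ascent of a profiling float: co-located
vectors of depth, temperature, salinity, density, chlorophyll-a fluorescence,
dissolved oxygen, downwelling PAR and particulate backscattering.  The
functions here apply the standard fluorometer corrections (deep dark-offset
removal, the community factor-of-2 calibration for WET Labs ECO sensors, a
mixed-layer non-photochemical-quenching fill, the oxygen-optode gain factor)
and derive the scalars the phenology analysis consumes:

* euphotic depth ``Zeu`` — where PAR falls to 1 % of its surface value;
* first optical depth — ``Zeu / 4.6``, the layer an ocean-colour satellite
  effectively sees;
* surface chlorophyll — trapezoidal mean over the first optical depth;
* integrated chlorophyll — trapezoidal integral over a depth band (mg m^-2);
* mixed-layer depth — density-threshold criterion (+0.03 kg m^-3 relative to
  the density at 10 m);
* Brunt–Väisälä frequency squared ``N^2`` at layer mid-depths.

All operations are defined on depth in metres, positive down; a
pressure-to-depth conversion is applied at ingest (~1 dbar per metre near the
surface).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from datetime import datetime
from typing import NamedTuple, Optional, Sequence

import numpy as np

from .errors import ProcessingError, ValidationError

GRAVITY = 9.81  # m s^-2

#: ln(100): optical depths between the surface and the 1 % light level.
LN100 = math.log(100.0)

#: Zeu-to-first-optical-depth divisor (one optical depth of a remote sensor).
FOD_DIVISOR = 4.6


# ---------------------------------------------------------------------------
# seawater density (one-atmosphere International Equation of State, EOS-80)
# ---------------------------------------------------------------------------

def density_sigma0(salinity, temperature):
    """Seawater density at atmospheric pressure, EOS-80 (kg m^-3).

    UNESCO (1983) one-atmosphere equation; check value
    ``density_sigma0(35, 5) == 1027.67547``.  Used only when a profile does
    not carry a density vector of its own.
    """
    t = np.asarray(temperature, dtype=float)
    s = np.asarray(salinity, dtype=float)
    rho_w = (999.842594 + 6.793952e-2 * t - 9.095290e-3 * t**2
             + 1.001685e-4 * t**3 - 1.120083e-6 * t**4 + 6.536332e-9 * t**5)
    a = (8.24493e-1 - 4.0899e-3 * t + 7.6438e-5 * t**2
         - 8.2467e-7 * t**3 + 5.3875e-9 * t**4)
    b = -5.72466e-3 + 1.0227e-4 * t - 1.6546e-6 * t**2
    c = 4.8314e-4
    return rho_w + a * s + b * s**1.5 + c * s**2


def pressure_to_depth(pressure_dbar):
    """Approximate depth (m) from pressure (dbar); monotone, ~1 dbar = 1 m."""
    p = np.asarray(pressure_dbar, dtype=float)
    # Leroy & Parthiot style quadratic correction, adequate to 1000 dbar.
    return p * (1.0 - 2.2e-6 * p)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class VerticalProfile:
    """One float cycle: co-located sensor vectors on a common depth axis."""

    profile_id: str
    timestamp: datetime
    lon: float
    lat: float
    depth: np.ndarray                       # m, positive down, increasing
    pressure: Optional[np.ndarray] = None   # dbar
    temperature: Optional[np.ndarray] = None  # deg C
    salinity: Optional[np.ndarray] = None   # practical salinity
    density: Optional[np.ndarray] = None    # kg m^-3 (full rho or sigma)
    chl: Optional[np.ndarray] = None        # mg m^-3
    do: Optional[np.ndarray] = None         # umol kg^-1
    par: Optional[np.ndarray] = None        # umol photons m^-2 s^-1
    bbp700: Optional[np.ndarray] = None     # m^-1
    density_is_sigma: bool = False
    provenance: list = field(default_factory=list)

    _VECTORS = ("pressure", "temperature", "salinity", "density",
                "chl", "do", "par", "bbp700")

    def __post_init__(self):
        self.depth = np.asarray(self.depth, dtype=float)
        for name in self._VECTORS:
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, np.asarray(v, dtype=float))
        self.validate()

    def validate(self):
        if self.depth.ndim != 1 or len(self.depth) == 0:
            raise ValidationError("depth", "must be a non-empty 1-D vector")
        if np.any(np.diff(self.depth) <= 0):
            raise ValidationError("depth", "must be strictly increasing")
        for name in self._VECTORS:
            v = getattr(self, name)
            if v is not None and v.shape != self.depth.shape:
                raise ValidationError(name, "length must match depth")

    def full_density(self) -> np.ndarray:
        """Density as full rho (kg m^-3), resolving the sigma convention.

        Falls back to EOS-80 from T/S when no density vector is present.
        """
        if self.density is not None:
            rho = self.density
            if self.density_is_sigma or np.nanmax(rho) < 500.0:
                rho = rho + 1000.0
            return rho
        if self.temperature is not None and self.salinity is not None:
            return density_sigma0(self.salinity, self.temperature)
        raise ProcessingError("no_density", "no density and no T/S to derive it")

    def log(self, event: str, **info):
        self.provenance.append({"event": event, **info})


class MldResult(NamedTuple):
    depth: float
    flag: Optional[str]  # None | "mld_at_profile_bottom"


class BvfResult(NamedTuple):
    mid_depths: np.ndarray
    n2: np.ndarray
    unstable: bool  # any N^2 < 0


@dataclass
class ProfileDerived:
    """Per-profile scalars consumed by the time-series stage.

    Fields whose inputs were missing stay ``None`` — never silently zero.
    """

    profile_id: str
    timestamp: datetime
    lon: float
    lat: float
    zeu: Optional[float] = None            # m
    fod: Optional[float] = None            # m, = zeu / 4.6
    chl_surf: Optional[float] = None       # mg m^-3
    chl_int: Optional[float] = None        # mg m^-2, surface..Zeu
    mld: Optional[float] = None            # m
    bvf: Optional[BvfResult] = None
    chl_deep_100_200: Optional[float] = None  # mg m^-2
    bbp_surf: Optional[float] = None       # m^-1, first-optical-depth mean
    flags: dict = field(default_factory=dict)
    provenance: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# corrections
# ---------------------------------------------------------------------------

def correct_dark_offset(profile: VerticalProfile,
                        deep_window: tuple = (900.0, 1000.0),
                        min_samples: int = 3) -> VerticalProfile:
    """Remove the fluorometer dark offset (non-zero deep chlorophyll).

    The offset is the median chlorophyll within ``deep_window`` (default
    900–1000 m, near the float's parking depth where no phytoplankton live);
    it is subtracted everywhere and the result clipped at zero.  If the window
    holds fewer than ``min_samples`` points the correction is skipped with a
    warning logged.
    """
    if profile.chl is None:
        raise ProcessingError("no_chl", "profile has no chlorophyll")
    lo, hi = deep_window
    sel = (profile.depth >= lo) & (profile.depth <= hi)
    out = replace(profile, provenance=list(profile.provenance))
    if int(sel.sum()) < min_samples:
        out.log("dark_offset_skipped", reason="too_few_deep_samples",
                n_deep=int(sel.sum()), offset=None)
        return out
    offset = float(np.median(profile.chl[sel]))
    corrected = profile.chl - offset
    n_clipped = int(np.sum(corrected < 0))
    out.chl = np.clip(corrected, 0.0, None)
    out.log("dark_offset", offset=offset, n_clipped=n_clipped)
    return out


def apply_fluorescence_calibration(profile: VerticalProfile,
                                   factor: float = 2.0) -> VerticalProfile:
    """Divide fluorometric chlorophyll by the sensor calibration bias.

    WET Labs ECO fluorometers overestimate chlorophyll by a
    community-established factor of 2; ``chl' = chl / factor``.
    """
    if profile.chl is None:
        raise ProcessingError("no_chl", "profile has no chlorophyll")
    if not factor > 0:
        raise ValidationError("factor", "calibration factor must be > 0")
    out = replace(profile, provenance=list(profile.provenance))
    out.chl = profile.chl / factor
    out.log("fluorescence_calibration", factor=factor)
    return out


def correct_npq(profile: VerticalProfile, mld: Optional[float],
                is_daytime: bool = True) -> VerticalProfile:
    """Fill daytime non-photochemical quenching near the surface.

    Daytime fluorescence underestimates chlorophyll above a quench depth.
    For well-mixed upper layers the chlorophyll profile should be homogeneous
    within the mixed layer, so the quenched part is filled by extrapolating
    the mixed-layer maximum upward: locate the depth ``z_q`` of maximum
    chlorophyll within ``[0, mld]`` and replace values shallower than ``z_q``
    with ``chl(z_q)``.  Never decreases any value; identity at night.
    """
    if profile.chl is None:
        raise ProcessingError("no_chl", "profile has no chlorophyll")
    out = replace(profile, provenance=list(profile.provenance))
    if not is_daytime:
        out.log("npq_skipped", reason="night")
        return out
    if mld is None:
        out.log("npq_skipped", reason="mld_missing")
        return out
    in_ml = profile.depth <= mld
    if not np.any(in_ml):
        out.log("npq_skipped", reason="no_samples_in_mixed_layer")
        return out
    iq = int(np.argmax(np.where(in_ml, profile.chl, -np.inf)))
    z_q = float(profile.depth[iq])
    chl = profile.chl.copy()
    chl[profile.depth < z_q] = profile.chl[iq]
    out.chl = chl
    out.log("npq", quench_depth=z_q, fill_value=float(profile.chl[iq]))
    return out


def correct_oxygen(profile: VerticalProfile,
                   factor: float = 1.06) -> VerticalProfile:
    """Apply the optode gain correction: ``do' = do * factor`` (default 1.06)."""
    if profile.do is None:
        raise ProcessingError("no_do", "profile has no dissolved oxygen")
    out = replace(profile, provenance=list(profile.provenance))
    out.do = profile.do * factor
    out.log("oxygen_gain", factor=factor)
    return out


# ---------------------------------------------------------------------------
# derived scalars
# ---------------------------------------------------------------------------

def euphotic_depth(profile: VerticalProfile) -> float:
    """Depth (m) where PAR first falls to 1 % of its surface value.

    The surface reference is the shallowest valid (positive) PAR sample —
    floats rarely sample exactly at 0 m.  The crossing is located by linear
    interpolation of log(PAR), i.e. assuming exponential decay between
    samples.
    """
    if profile.par is None:
        raise ProcessingError("no_par", "profile has no PAR")
    valid = np.isfinite(profile.par) & (profile.par > 0)
    if not np.any(valid):
        raise ValidationError("par", "no positive PAR samples")
    z = profile.depth[valid]
    par = profile.par[valid]
    ref = par[0]
    target = ref / 100.0
    below = par <= target
    if not np.any(below):
        raise ProcessingError("zeu_below_profile",
                              "PAR never reaches 1% of surface within profile")
    i = int(np.argmax(below))
    if i == 0:
        return float(z[0])
    lp = np.log(par)
    lt = math.log(target)
    frac = (lp[i - 1] - lt) / (lp[i - 1] - lp[i])
    return float(z[i - 1] + frac * (z[i] - z[i - 1]))


def first_optical_depth(zeu: float) -> float:
    """First optical depth (m): ``zeu / 4.6``."""
    if not zeu > 0:
        raise ValidationError("zeu", "euphotic depth must be > 0")
    return zeu / FOD_DIVISOR


def _interp_at(depth, values, z):
    return float(np.interp(z, depth, values))


def surface_chl(profile: VerticalProfile, fod: float) -> float:
    """Trapezoidal (depth-weighted) mean chlorophyll over the first optical depth.

    The averaging interval is ``[shallowest sample, fod]``; the value at
    ``fod`` is linearly interpolated when it falls between samples.
    """
    if profile.chl is None:
        raise ProcessingError("no_chl", "profile has no chlorophyll")
    if not fod > 0:
        raise ValidationError("fod", "first optical depth must be > 0")
    z, chl = profile.depth, profile.chl
    if z[0] >= fod:
        raise ProcessingError("no_surface_samples",
                              "no samples shallower than the first optical depth")
    inside = z <= fod
    if inside.sum() >= 1 and z[-1] <= fod:
        # profile ends above fod: degenerate mean over what exists
        if inside.sum() == 1:
            return float(chl[0])
        zz, cc = z[inside], chl[inside]
    else:
        zz = np.append(z[inside], fod)
        cc = np.append(chl[inside], _interp_at(z, chl, fod))
    if len(zz) == 1:
        return float(cc[0])
    return float(np.trapezoid(cc, zz) / (zz[-1] - zz[0]))


def integrated_chl(profile: VerticalProfile, z_top: float,
                   z_bottom: float) -> float:
    """Trapezoidal chlorophyll integral over ``[z_top, z_bottom]`` (mg m^-2).

    Boundary values are linearly interpolated; above the shallowest sample the
    profile is extended with a constant equal to that sample.
    """
    if profile.chl is None:
        raise ProcessingError("no_chl", "profile has no chlorophyll")
    if not (0 <= z_top < z_bottom):
        raise ValidationError("z_top", "need 0 <= z_top < z_bottom")
    z, chl = profile.depth, profile.chl
    if z[-1] < z_bottom:
        raise ProcessingError("profile_too_shallow",
                              f"profile ends at {z[-1]:.1f} m above z_bottom")
    if z_top < z[0]:
        z = np.concatenate(([z_top], z))
        chl = np.concatenate(([chl[0]], chl))
    inside = (z > z_top) & (z < z_bottom)
    zz = np.concatenate(([z_top], z[inside], [z_bottom]))
    cc = np.concatenate(([_interp_at(z, chl, z_top)], chl[inside],
                         [_interp_at(z, chl, z_bottom)]))
    return float(np.trapezoid(cc, zz))


def mld(profile: VerticalProfile, delta_sigma: float = 0.03,
        ref_depth: float = 10.0) -> MldResult:
    """Mixed-layer depth by the density-threshold criterion.

    The reference density is interpolated at ``ref_depth`` (default 10 m); the
    MLD is the shallowest depth below the reference where density exceeds the
    reference by ``delta_sigma`` (default 0.03 kg m^-3), linearly interpolated
    between the bracketing samples.  If the threshold is never crossed the
    profile bottom is returned with the ``mld_at_profile_bottom`` flag so time
    series stay complete through deep winter mixing.
    """
    rho = profile.full_density()
    z = profile.depth
    if np.min(np.abs(z - ref_depth)) > 5.0:
        raise ProcessingError("no_reference_sample",
                              f"no sample within 5 m of {ref_depth} m")
    sigma_ref = _interp_at(z, rho, ref_depth)
    threshold = sigma_ref + delta_sigma
    below = z >= ref_depth
    zb, rb = z[below], rho[below]
    exceed = rb >= threshold
    if not np.any(exceed):
        return MldResult(float(z[-1]), "mld_at_profile_bottom")
    i = int(np.argmax(exceed))
    if i == 0:
        return MldResult(float(zb[0]), None)
    frac = (threshold - rb[i - 1]) / (rb[i] - rb[i - 1])
    return MldResult(float(zb[i - 1] + frac * (zb[i] - zb[i - 1])), None)


def bvf_profile(profile: VerticalProfile) -> BvfResult:
    """Brunt–Väisälä frequency squared at layer mid-depths.

    ``N^2 = (g / rho_mean) * (d rho / d z)`` for each adjacent sample pair;
    negative values (density inversions) are kept and flagged unstable.
    """
    rho = profile.full_density()
    z = profile.depth
    if len(z) < 2:
        raise ProcessingError("too_few_samples", "need >= 2 samples for N^2")
    dz = np.diff(z)
    drho = np.diff(rho)
    rho_mean = 0.5 * (rho[:-1] + rho[1:])
    n2 = (GRAVITY / rho_mean) * (drho / dz)
    mid = 0.5 * (z[:-1] + z[1:])
    return BvfResult(mid, n2, bool(np.any(n2 < 0)))


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

@dataclass
class CorrectionsConfig:
    """Which corrections to apply, and their parameters."""

    dark_offset: bool = True
    dark_window: tuple = (900.0, 1000.0)
    calibration_factor: Optional[float] = None  # None = already calibrated
    npq: bool = True
    is_daytime: bool = True
    do_factor: Optional[float] = 1.06
    mld_delta_sigma: float = 0.03
    mld_ref_depth: float = 10.0
    deep_band: Optional[tuple] = (100.0, 200.0)  # extra integral, or None

    def to_dict(self) -> dict:
        return {
            "dark_offset": self.dark_offset,
            "dark_window": list(self.dark_window),
            "calibration_factor": self.calibration_factor,
            "npq": self.npq,
            "is_daytime": self.is_daytime,
            "do_factor": self.do_factor,
            "mld_delta_sigma": self.mld_delta_sigma,
            "mld_ref_depth": self.mld_ref_depth,
            "deep_band": list(self.deep_band) if self.deep_band else None,
        }


def derive_all(profile: VerticalProfile,
               config: Optional[CorrectionsConfig] = None) -> ProfileDerived:
    """Apply corrections in order (dark offset, calibration, NPQ) and derive
    every per-profile scalar whose inputs are present.

    Corrections are applied exactly once, on a copy; missing inputs yield
    absent fields with the reason recorded in ``flags``.
    """
    cfg = config or CorrectionsConfig()
    out = ProfileDerived(profile.profile_id, profile.timestamp,
                         profile.lon, profile.lat)
    p = profile

    # physics first: MLD and N^2 need only density
    try:
        res = mld(p, cfg.mld_delta_sigma, cfg.mld_ref_depth)
        out.mld = res.depth
        if res.flag:
            out.flags["mld"] = res.flag
    except ProcessingError as e:
        out.flags["mld"] = e.code
    try:
        out.bvf = bvf_profile(p)
        if out.bvf.unstable:
            out.flags["bvf"] = "unstable_layers"
    except ProcessingError as e:
        out.flags["bvf"] = e.code

    if p.do is not None and cfg.do_factor is not None:
        p = correct_oxygen(p, cfg.do_factor)

    if p.chl is not None:
        if cfg.dark_offset:
            p = correct_dark_offset(p, cfg.dark_window)
        if cfg.calibration_factor is not None:
            p = apply_fluorescence_calibration(p, cfg.calibration_factor)
        if cfg.npq:
            p = correct_npq(p, out.mld, cfg.is_daytime)
    else:
        out.flags["chl"] = "no_chl"

    if p.par is not None:
        try:
            out.zeu = euphotic_depth(p)
            out.fod = first_optical_depth(out.zeu)
        except (ProcessingError, ValidationError) as e:
            out.flags["zeu"] = getattr(e, "code", "invalid_par")
    else:
        out.flags["zeu"] = "no_par"

    if p.chl is not None and out.fod is not None:
        try:
            out.chl_surf = surface_chl(p, out.fod)
        except ProcessingError as e:
            out.flags["chl_surf"] = e.code
    if p.chl is not None and out.zeu is not None:
        try:
            out.chl_int = integrated_chl(p, 0.0, out.zeu)
        except ProcessingError as e:
            out.flags["chl_int"] = e.code
    if p.chl is not None and cfg.deep_band is not None:
        try:
            out.chl_deep_100_200 = integrated_chl(p, *cfg.deep_band)
        except ProcessingError as e:
            out.flags["chl_deep"] = e.code
    if p.bbp700 is not None and out.fod is not None:
        bbp_prof = replace(p, chl=p.bbp700, provenance=[])
        try:
            out.bbp_surf = surface_chl(bbp_prof, out.fod)
        except ProcessingError as e:
            out.flags["bbp_surf"] = e.code

    out.provenance = list(p.provenance)
    return out


# ---------------------------------------------------------------------------
# I/O: fixture CSV dialect and Argo-style NetCDF
# ---------------------------------------------------------------------------

_CSV_COLUMNS = ["profile_id", "timestamp", "lon", "lat", "depth_m",
                "pres_dbar", "temp_C", "psal", "sigma_kg_m3", "chl_mg_m3",
                "do_umol_kg", "par", "bbp700_m1"]

_FIELD_BY_COLUMN = {"pres_dbar": "pressure", "temp_C": "temperature",
                    "psal": "salinity", "sigma_kg_m3": "density",
                    "chl_mg_m3": "chl", "do_umol_kg": "do", "par": "par",
                    "bbp700_m1": "bbp700"}


def write_profiles_csv(profiles: Sequence[VerticalProfile], path) -> None:
    """Write profiles in the fixture CSV dialect: one row per (profile, depth)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_CSV_COLUMNS)
        for p in profiles:
            for i, z in enumerate(p.depth):
                row = [p.profile_id, p.timestamp.isoformat(),
                       repr(p.lon), repr(p.lat), repr(float(z))]
                for col in _CSV_COLUMNS[5:]:
                    v = getattr(p, _FIELD_BY_COLUMN[col])
                    row.append("" if v is None or not np.isfinite(v[i])
                               else repr(float(v[i])))
                w.writerow(row)


def read_profiles_csv(path) -> list:
    """Read the fixture CSV dialect back into :class:`VerticalProfile` objects."""
    import pandas as pd
    df = pd.read_csv(path, dtype={"profile_id": str},
                     float_precision="round_trip")
    profiles = []
    for pid, g in df.groupby("profile_id", sort=False):
        g = g.sort_values("depth_m")
        kwargs = {}
        for col, name in _FIELD_BY_COLUMN.items():
            if col in g and g[col].notna().any():
                kwargs[name] = g[col].to_numpy(dtype=float)
        profiles.append(VerticalProfile(
            profile_id=str(pid),
            timestamp=datetime.fromisoformat(str(g["timestamp"].iloc[0])),
            lon=float(g["lon"].iloc[0]), lat=float(g["lat"].iloc[0]),
            depth=g["depth_m"].to_numpy(dtype=float), **kwargs))
    profiles.sort(key=lambda p: p.timestamp)
    return profiles


def write_profiles_netcdf(profiles: Sequence[VerticalProfile], path) -> None:
    """Write a minimal single-float multi-cycle Argo-style NetCDF file."""
    import xarray as xr
    n_prof = len(profiles)
    n_lev = max(len(p.depth) for p in profiles)

    def pad(vec):
        out = np.full(n_lev, np.nan)
        if vec is not None:
            out[:len(vec)] = vec
        return out

    var_map = {"PRES": "pressure", "TEMP": "temperature", "PSAL": "salinity",
               "SIGMA": "density", "CHLA": "chl", "DOXY": "do",
               "DOWNWELLING_PAR": "par", "BBP700": "bbp700"}
    data = {"DEPTH": (("N_PROF", "N_LEVELS"),
                      np.stack([pad(p.depth) for p in profiles]))}
    for var, attr in var_map.items():
        if any(getattr(p, attr) is not None for p in profiles):
            data[var] = (("N_PROF", "N_LEVELS"),
                         np.stack([pad(getattr(p, attr)) for p in profiles]))
    ds = xr.Dataset(
        data,
        coords={
            "JULD": ("N_PROF", [np.datetime64(p.timestamp, "ns") for p in profiles]),
            "LONGITUDE": ("N_PROF", [p.lon for p in profiles]),
            "LATITUDE": ("N_PROF", [p.lat for p in profiles]),
            "PROFILE_ID": ("N_PROF", [str(p.profile_id) for p in profiles]),
        })
    ds.to_netcdf(path, engine="scipy")


def read_profiles_netcdf(path) -> list:
    """Read a single-float multi-cycle Argo-style NetCDF file."""
    import pandas as pd
    import xarray as xr
    var_map = {"PRES": "pressure", "TEMP": "temperature", "PSAL": "salinity",
               "SIGMA": "density", "CHLA": "chl", "DOXY": "do",
               "DOWNWELLING_PAR": "par", "BBP700": "bbp700"}
    profiles = []
    with xr.open_dataset(path, engine="scipy") as ds:
        for i in range(ds.sizes["N_PROF"]):
            if "DEPTH" in ds:
                depth = ds["DEPTH"].values[i]
            else:
                depth = pressure_to_depth(ds["PRES"].values[i])
            ok = np.isfinite(depth)
            kwargs = {}
            for var, attr in var_map.items():
                if var in ds:
                    v = ds[var].values[i][ok]
                    if np.any(np.isfinite(v)):
                        kwargs[attr] = v
            pid = (str(ds["PROFILE_ID"].values[i]) if "PROFILE_ID" in ds.coords
                   else f"{i:04d}")
            profiles.append(VerticalProfile(
                profile_id=pid,
                timestamp=pd.Timestamp(ds["JULD"].values[i]).to_pydatetime(),
                lon=float(ds["LONGITUDE"].values[i]),
                lat=float(ds["LATITUDE"].values[i]),
                depth=depth[ok], **kwargs))
    return profiles


def write_derived_csv(derived: Sequence[ProfileDerived], path) -> None:
    """One CSV row per profile with all derived scalars and flags."""
    cols = ["profile_id", "timestamp", "lon", "lat", "zeu_m", "fod_m",
            "chl_surf_mg_m3", "chl_int_mg_m2", "mld_m",
            "chl_deep_100_200_mg_m2", "bbp_surf_m1", "flags"]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(cols)
        for d in derived:
            w.writerow([
                d.profile_id, d.timestamp.isoformat(), d.lon, d.lat,
                "" if d.zeu is None else f"{d.zeu:.6g}",
                "" if d.fod is None else f"{d.fod:.6g}",
                "" if d.chl_surf is None else f"{d.chl_surf:.6g}",
                "" if d.chl_int is None else f"{d.chl_int:.6g}",
                "" if d.mld is None else f"{d.mld:.6g}",
                "" if d.chl_deep_100_200 is None else f"{d.chl_deep_100_200:.6g}",
                "" if d.bbp_surf is None else f"{d.bbp_surf:.6g}",
                ";".join(f"{k}={v}" for k, v in sorted(d.flags.items())),
            ])
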