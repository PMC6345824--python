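"""Coupled synthetic float-profile and satellite surface chlorophyll generator.

Emulates one year of a subtropical/tropical annual cycle as sampled by a
profiling float and an ocean-colour satellite, with known (planted) phenology
so every downstream stage is testable without downloads:

* a subsurface chlorophyll maximum (SCM) at ~75–100 m during stratified
  seasons, eroded to zero during a winter deep-mixing bloom window;
* a surface chlorophyll plateau, homogeneous in the mixed layer, stepping
  from a background value to a bloom value inside the bloom window and
  tapering linearly to zero over 10 m below the mixed-layer depth;
* a smoothed two-layer density profile whose pycnocline tracks a seasonal
  mixed-layer-depth schedule (shallow in stratified seasons, deep in the
  bloom window);
* exponentially attenuating PAR with fixed surface irradiance;
* mixed-layer-homogeneous temperature and dissolved-oxygen analogues;
* instrument artifacts the processing chain must undo: a fluorometer dark
  offset, multiplicative lognormal noise, daytime near-surface quenching;
* a 3-pixel satellite matchup window per profile date with independent pixel
  noise and randomly missing composites.

Everything is deterministic given the scenario seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from datetime import date, datetime, time, timedelta
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .errors import ValidationError
from .profiles import (LN100, VerticalProfile, euphotic_depth,
                       first_optical_depth, surface_chl)
from .timeseries import MatchupRecord


@dataclass
class Schedule:
    """Piecewise-linear day -> value function, serialisable as breakpoints."""

    days: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.days = np.asarray(self.days, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.days.shape != self.values.shape or self.days.ndim != 1:
            raise ValidationError("schedule", "days/values must be 1-D, same length")
        if np.any(np.diff(self.days) < 0):
            raise ValidationError("schedule", "days must be non-decreasing")

    def __call__(self, day):
        return float(np.interp(day, self.days, self.values))

    def to_list(self):
        return [[float(d), float(v)] for d, v in zip(self.days, self.values)]

    @classmethod
    def from_list(cls, pairs):
        arr = np.asarray(pairs, dtype=float)
        return cls(arr[:, 0], arr[:, 1])


@dataclass
class SyntheticScenario:
    """Parameters of one synthetic annual cycle (the study conditions).

    Defaults follow a northern Red Sea-like year starting 30 September: a
    winter deep-mixing bloom (days 35–190, i.e. early November to early
    April, aligned to 5-day composite boundaries), background surface chlorophyll 0.1 mg m^-3 stepping to
    0.5 mg m^-3 in the bloom, an SCM at 75 m deepening to ~100 m in late
    summer with peak amplitude 0.35 mg m^-3 in spring, and a mixed layer
    cycling between 25 m and 150 m.  Schedules left as ``None`` are built
    from the bloom window by :meth:`_default_schedules`.
    """

    start_date: date = date(2015, 9, 30)
    n_days: int = 365
    profile_interval_days: float = 1.0
    depth_grid: np.ndarray = None
    bloom_start_day: int = 35
    bloom_end_day: int = 190
    surface_background_chl: float = 0.1    # mg m^-3
    bloom_surface_chl: float = 0.5         # mg m^-3
    scm_depth_schedule: Optional[Schedule] = None   # day -> m
    scm_sigma: float = 15.0                # m
    scm_amplitude_schedule: Optional[Schedule] = None  # day -> mg m^-3
    mld_schedule: Optional[Schedule] = None  # day -> m
    pycnocline_delta_sigma: float = 0.5    # kg m^-3
    pycnocline_width: float = 10.0         # m (linear ramp smoothing the step)
    kd_background: float = 0.05            # m^-1
    par0: float = 1500.0                   # umol photons m^-2 s^-1
    dark_offset: float = 0.02              # mg m^-3 fluorometer artifact
    noise_cv: float = 0.1
    gap_fraction: float = 0.1
    npq_depression: float = 0.3
    npq_quench_depth: float = 15.0         # m
    taper_width: float = 10.0              # m, plateau ramp below the MLD
    seed: int = 0

    def __post_init__(self):
        if self.depth_grid is None:
            self.depth_grid = np.arange(1.0, 1001.0, 1.0)
        self.depth_grid = np.asarray(self.depth_grid, dtype=float)
        if self.n_days < 1:
            raise ValidationError("n_days", "must be >= 1")
        if not (0 <= self.bloom_start_day < self.bloom_end_day <= self.n_days):
            raise ValidationError(
                "bloom_start_day",
                "need 0 <= bloom_start_day < bloom_end_day <= n_days")
        if self.scm_depth_schedule is None or self.scm_amplitude_schedule is None \
                or self.mld_schedule is None:
            self._default_schedules()
        self.validate()

    def _default_schedules(self):
        s, e, n = self.bloom_start_day, self.bloom_end_day, self.n_days
        last = max(n - 1, e + 1)
        ramp_up = min(s + max((e - s) // 3, 1), e - 1)
        if self.mld_schedule is None:
            # shallow (25 m) outside the bloom, deepening to 150 m inside
            self.mld_schedule = Schedule(
                [0, s, ramp_up, e - 1, min(e + 10, last), last],
                [25, 25, 150, 150, 25, 25])
        if self.scm_depth_schedule is None:
            # ~75 m in autumn/spring, deepening toward 100 m in late summer
            self.scm_depth_schedule = Schedule(
                [0, e, min(e + 60, last), last], [75, 75, 85, 100])
        if self.scm_amplitude_schedule is None:
            # eroded to zero in the bloom window; re-establishes in spring
            # only once the mixed layer has shoaled back above the SCM depth
            # (an SCM cannot persist inside a deep mixed layer)
            self.scm_amplitude_schedule = Schedule(
                [0, max(s - 10, 0), s, min(e + 12, last), min(e + 25, last),
                 min(e + 60, last), last],
                [0.2, 0.15, 0.0, 0.0, 0.35, 0.3, 0.2])

    def validate(self):
        def positive(name):
            if not getattr(self, name) > 0:
                raise ValidationError(name, "must be > 0")
        if self.n_days < 1:
            raise ValidationError("n_days", "must be >= 1")
        if not (0 <= self.bloom_start_day < self.bloom_end_day <= self.n_days):
            raise ValidationError(
                "bloom_start_day",
                "need 0 <= bloom_start_day < bloom_end_day <= n_days")
        if self.depth_grid.ndim != 1 or len(self.depth_grid) < 2:
            raise ValidationError("depth_grid", "need a 1-D grid of >= 2 depths")
        if np.any(np.diff(self.depth_grid) <= 0) or self.depth_grid[0] <= 0:
            raise ValidationError("depth_grid",
                                  "must be strictly increasing and positive")
        for name in ("profile_interval_days", "scm_sigma", "kd_background",
                     "par0", "pycnocline_width", "taper_width"):
            positive(name)
        for name in ("surface_background_chl", "bloom_surface_chl",
                     "dark_offset", "noise_cv", "pycnocline_delta_sigma"):
            if getattr(self, name) < 0:
                raise ValidationError(name, "must be >= 0")
        for name in ("gap_fraction", "npq_depression"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValidationError(name, "must lie in [0, 1]")

    # -- truth field ------------------------------------------------------

    def in_bloom(self, day: float) -> bool:
        return self.bloom_start_day <= day < self.bloom_end_day

    def surface_plateau(self, day: float) -> float:
        return self.bloom_surface_chl if self.in_bloom(day) \
            else self.surface_background_chl

    def true_chl(self, z: np.ndarray, day: float) -> np.ndarray:
        """Noise-free chlorophyll field without instrument artifacts."""
        mld = self.mld_schedule(day)
        plateau = self.surface_plateau(day)
        taper = np.clip(1.0 - (z - mld) / self.taper_width, 0.0, 1.0)
        scm = self.scm_amplitude_schedule(day) * np.exp(
            -((z - self.scm_depth_schedule(day)) ** 2)
            / (2.0 * self.scm_sigma ** 2))
        return plateau * taper + scm

    def true_zeu(self) -> float:
        """Planted euphotic depth on this grid.

        The 1 % rule is referenced to the shallowest sampled PAR value (a
        float rarely samples at 0 m), so the planted value is the analytic
        ``ln(100)/Kd`` offset by the first grid depth.
        """
        return float(self.depth_grid[0]) + LN100 / self.kd_background

    def true_surface_chl(self, day: float) -> float:
        """Noise-free first-optical-depth mean of the truth field (on the grid)."""
        p = self._truth_profile(day)
        return surface_chl(p, first_optical_depth(self.true_zeu()))

    def _truth_profile(self, day: float) -> VerticalProfile:
        z = self.depth_grid
        return VerticalProfile(
            profile_id="truth", timestamp=self._timestamp(day),
            lon=0.0, lat=0.0, depth=z, chl=self.true_chl(z, day))

    def _timestamp(self, day: float) -> datetime:
        # floats surface at local noon
        return datetime.combine(self.start_date + timedelta(days=float(day)),
                                time(12, 0))

    def profile_days(self) -> np.ndarray:
        return np.arange(0.0, float(self.n_days), self.profile_interval_days)

    # -- (de)serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "start_date": self.start_date.isoformat(),
            "n_days": self.n_days,
            "profile_interval_days": self.profile_interval_days,
            "depth_grid": {"start": float(self.depth_grid[0]),
                           "stop": float(self.depth_grid[-1]),
                           "n": int(len(self.depth_grid))},
            "bloom_start_day": self.bloom_start_day,
            "bloom_end_day": self.bloom_end_day,
            "surface_background_chl": self.surface_background_chl,
            "bloom_surface_chl": self.bloom_surface_chl,
            "scm_depth_schedule": self.scm_depth_schedule.to_list(),
            "scm_sigma": self.scm_sigma,
            "scm_amplitude_schedule": self.scm_amplitude_schedule.to_list(),
            "mld_schedule": self.mld_schedule.to_list(),
            "pycnocline_delta_sigma": self.pycnocline_delta_sigma,
            "pycnocline_width": self.pycnocline_width,
            "kd_background": self.kd_background,
            "par0": self.par0,
            "dark_offset": self.dark_offset,
            "noise_cv": self.noise_cv,
            "gap_fraction": self.gap_fraction,
            "npq_depression": self.npq_depression,
            "npq_quench_depth": self.npq_quench_depth,
            "taper_width": self.taper_width,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticScenario":
        d = dict(d)
        grid = d.pop("depth_grid", None)
        kwargs = {}
        if grid is not None:
            kwargs["depth_grid"] = np.linspace(grid["start"], grid["stop"],
                                               grid["n"])
        for key in ("scm_depth_schedule", "scm_amplitude_schedule",
                    "mld_schedule"):
            if d.get(key) is not None:
                d[key] = Schedule.from_list(d[key])
        d["start_date"] = date.fromisoformat(d["start_date"])
        return cls(**d, **kwargs)

    def to_yaml(self, path) -> None:
        import yaml
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticScenario":
        import yaml
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class TruthRecord:
    """Planted ground truth for recovery tests."""

    true_initiation_day: int
    true_termination_day: int
    sampling_days: np.ndarray
    true_mld_by_day: np.ndarray       # m, one per sampled profile
    true_zeu_by_day: np.ndarray       # m
    true_scm_depth_by_day: np.ndarray  # m, NaN when the SCM is eroded
    true_surface_chl_by_day: np.ndarray  # mg m^-3, first-optical-depth mean


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

_DEEP_T = 21.5        # deg C below the pycnocline (Red Sea deep water is warm)
_DEEP_DO = 160.0      # umol kg^-1
_DEEP_RHO = None      # derived from surface + delta
_SALINITY = 40.2      # practical salinity, roughly uniform


def _mixed_layer_profile(z, surface_value, deep_value, mld, width):
    """Homogeneous above the MLD, linear ramp of ``width`` m, constant below."""
    frac = np.clip((z - mld) / width, 0.0, 1.0)
    return surface_value + (deep_value - surface_value) * frac


def generate_profile_series(scenario: SyntheticScenario
                            ) -> Tuple[List[VerticalProfile], TruthRecord]:
    """Generate one float profile per sampling day plus the planted truth.

    The measured chlorophyll is ``true_chl + dark_offset`` with daytime NPQ
    depression above the quench depth, all multiplied by lognormal noise with
    the scenario's coefficient of variation.  Density is a smoothed two-layer
    profile stepping by ``pycnocline_delta_sigma`` across the scheduled MLD;
    PAR decays exponentially with the background diffuse attenuation;
    temperature and oxygen are mixed-layer-homogeneous analogues.
    Deterministic given ``scenario.seed``.
    """
    scenario.validate()
    rng = np.random.default_rng([int(scenario.seed) % (2**31), 11])
    z = scenario.depth_grid
    days = scenario.profile_days()
    sigma_ln = _lognormal_sigma(scenario.noise_cv)

    profiles: List[VerticalProfile] = []
    mlds, scms, surfs = [], [], []
    for i, day in enumerate(days):
        mld = scenario.mld_schedule(day)
        amp = scenario.scm_amplitude_schedule(day)
        chl_true = scenario.true_chl(z, day)
        chl_meas = chl_true + scenario.dark_offset
        if scenario.npq_depression > 0:
            quench = z < min(scenario.npq_quench_depth, mld)
            chl_meas = np.where(quench,
                                chl_meas * (1.0 - scenario.npq_depression),
                                chl_meas)
        if scenario.noise_cv > 0:
            chl_meas = chl_meas * rng.lognormal(-0.5 * sigma_ln**2, sigma_ln,
                                                size=z.shape)

        in_bloom = scenario.in_bloom(day)
        rho_surf = 1026.5 if in_bloom else 1026.0
        rho = _mixed_layer_profile(z, rho_surf,
                                   rho_surf + scenario.pycnocline_delta_sigma,
                                   mld, scenario.pycnocline_width)
        # weak stable stratification beneath the pycnocline
        deep = z > mld + scenario.pycnocline_width
        rho = rho + np.where(deep, 5e-4 * (z - (mld + scenario.pycnocline_width)),
                             0.0)
        t_surf = 24.0 if in_bloom else 26.0
        temp = _mixed_layer_profile(z, t_surf, _DEEP_T, mld,
                                    scenario.pycnocline_width)
        do_surf = 210.0 if in_bloom else 200.0
        do = _mixed_layer_profile(z, do_surf, _DEEP_DO, mld,
                                  scenario.pycnocline_width)
        par = scenario.par0 * np.exp(-scenario.kd_background * z)
        bbp = 3.0e-4 + 1.0e-3 * chl_true
        if scenario.noise_cv > 0:
            bbp = bbp * rng.lognormal(-0.5 * sigma_ln**2, sigma_ln,
                                      size=z.shape)

        profiles.append(VerticalProfile(
            profile_id=f"SYN{i:04d}", timestamp=scenario._timestamp(day),
            lon=34.5 + 0.002 * i, lat=27.0 - 0.001 * i,
            depth=z, pressure=z / (1.0 - 2.2e-6 * z),
            temperature=temp, salinity=np.full_like(z, _SALINITY),
            density=rho, chl=chl_meas, do=do, par=par, bbp700=bbp))
        mlds.append(mld)
        scms.append(scenario.scm_depth_schedule(day) if amp > 0 else np.nan)
        surfs.append(scenario.true_surface_chl(day))

    truth = TruthRecord(
        true_initiation_day=scenario.bloom_start_day,
        true_termination_day=scenario.bloom_end_day,
        sampling_days=days,
        true_mld_by_day=np.array(mlds),
        true_zeu_by_day=np.full(len(days), scenario.true_zeu()),
        true_scm_depth_by_day=np.array(scms),
        true_surface_chl_by_day=np.array(surfs))
    return profiles, truth


def _lognormal_sigma(cv: float) -> float:
    # lognormal with unit mean and coefficient of variation cv
    return math.sqrt(math.log(1.0 + cv**2)) if cv > 0 else 0.0


def generate_satellite_series(scenario: SyntheticScenario,
                              profiles: Sequence[VerticalProfile]
                              ) -> List[MatchupRecord]:
    """Per profile date, a 3-pixel longitudinal matchup window.

    Each pixel is the noise-free first-optical-depth mean of the truth field
    perturbed by independent lognormal noise; a fraction ``gap_fraction`` of
    windows is fully missing.  Deterministic given ``scenario.seed``.
    """
    scenario.validate()
    rng = np.random.default_rng([int(scenario.seed) % (2**31), 23])
    sigma_ln = _lognormal_sigma(scenario.noise_cv)
    start = scenario.start_date
    pixel = 4.0 / 111.0 / math.cos(math.radians(27.0))  # ~4 km in deg lon
    records: List[MatchupRecord] = []
    for p in profiles:
        day = (p.timestamp.date() - start).days
        truth = scenario.true_surface_chl(day)
        missing = rng.random() < scenario.gap_fraction
        if scenario.noise_cv > 0:
            noise = rng.lognormal(-0.5 * sigma_ln**2, sigma_ln, size=3)
        else:
            noise = np.ones(3)
        center_lon = round(p.lon / pixel) * pixel
        center_lat = round(p.lat / pixel) * pixel
        window = () if missing else tuple(float(truth * n) for n in noise)
        records.append(MatchupRecord(p.timestamp.date(), p.lon, p.lat,
                                     center_lon, center_lat, window))
    return records


def scenario_to_json(scenario: SyntheticScenario, path) -> None:
    with open(path, "w") as fh:
        json.dump(scenario.to_dict(), fh, indent=2, sort_keys=True)


def scenario_from_json(path) -> SyntheticScenario:
    with open(path) as fh:
        return SyntheticScenario.from_dict(json.load(fh))
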