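"""Synthetic two-buoy reservoir sensor data with the couplings the sensor exploits.

The generator emulates a eutrophic temperate reservoir monitored by two buoys
("beach": shallow, noisier; "dam": deeper, larger diel chlorophyll swings) at
a 15-minute cadence over multiple years:

* a latent chlorophyll-a series built from a summer seasonal envelope
  (June-September, peaking around early September) carrying seeded log-normal
  bloom pulses — blooms are ephemeral and patchy — plus a diel vertical
  migration term that is stronger at the deep dam site;
* pH coupled to algal activity through a saturating log-like link
  (photosynthesis raises pH, but pH stays within [0, 14]), on top of a diel
  cycle and noise;
* water temperature with seasonal and diel cycles;
* electrical conductivity drifting up through droughts and dropping sharply
  after seeded rain events with exponential recovery;
* a battery voltage sawtooth charged during the first daylight hours by the
  solar panel and discharging at night, with seasonal day length;
* a measured chlorophyll channel equal to the latent series plus sensor noise
  and occasional positive fluorometer spikes (debris misdetections).

Artifact injection plants, at seeded positions, values just inside the
cleaner's snap band, values beyond it, and missing values, so the cleaning
rules can be audited against exact planted counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .io_cleaning import CANONICAL_COLUMNS, NUMERIC_COLUMNS, ValidRanges

DAY_MINUTES = 24 * 60


@dataclass(frozen=True)
class BuoyProfile:
    """Site-specific generator parameters."""

    name: str
    diel_chl_amplitude: float      # fractional diel swing of latent Chl-a
    noise_scale: float             # multiplier on all sensor noise stds
    bloom_amplitude: float         # mean bloom pulse height, µg/L


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator configuration; defaults are the package's study conditions.

    Amplitudes and baselines are set to produce series with the broad ranges
    of a monitored eutrophic reservoir: temperature ~5-29 °C, conductivity
    ~35-100 µS/cm, pH ~6.5-10, battery ~12.7-14.8 V, chlorophyll-a from ~1
    µg/L in winter to >100 µg/L bloom spikes.
    """

    start: str = "2018-01-01"
    n_years: int = 3
    cadence_minutes: int = 15
    buoys: tuple[BuoyProfile, ...] = (
        BuoyProfile(name="beach", diel_chl_amplitude=0.15, noise_scale=1.3, bloom_amplitude=18.0),
        BuoyProfile(name="dam", diel_chl_amplitude=0.35, noise_scale=1.0, bloom_amplitude=22.0),
    )
    # seasonal bloom envelope
    bloom_onset_month: int = 6
    bloom_peak_doy: int = 248          # ~September 5
    bloom_season_width_days: float = 40.0
    chl_baseline: float = 2.0          # µg/L winter background
    n_blooms_per_year: float = 4.0     # mean seeded pulse count per summer
    bloom_duration_days: float = 6.0
    # diel cycles
    temp_mean: float = 15.0
    temp_seasonal_amplitude: float = 9.5
    temp_diel_amplitude: float = 1.2
    ph_base: float = 6.9
    ph_diel_amplitude: float = 0.12
    ph_chl_coupling: float = 0.55      # pH units per log-unit of Chl-a
    # conductivity
    ec_baseline: float = 65.0
    ec_drought_amplitude: float = 12.0
    rain_events_per_year: float = 35.0
    rain_drop_magnitude: float = 12.0  # µS/cm mean drop per event
    rain_recovery_days: float = 5.0
    # battery
    battery_full: float = 14.6
    battery_float: float = 12.9
    battery_charge_rate: float = 1.8   # V per daylight-power unit per hour
    battery_drain_rate: float = 0.09   # V per hour at night
    # noise stds (dam profile; beach scales them up)
    noise_std: dict = field(
        default_factory=lambda: {
            "temperature": 0.15,
            "conductivity": 0.8,
            "ph": 0.05,
            "battery": 0.03,
            "chlorophyll": 0.6,
        }
    )
    chl_spike_rate: float = 0.004      # fraction of samples hit by fluorometer spikes
    chl_spike_scale: float = 25.0      # µg/L median spike height
    seed: int = 0


@dataclass
class GroundTruth:
    """What the generator knows and the pipeline must rediscover."""

    latent_chl: pd.DataFrame           # timestamp, buoy_id, latent (noiseless, spike-free)
    ph_chl_coupling: float
    snap_positions: pd.DataFrame | None = None     # planted in-band artifacts
    removal_positions: pd.DataFrame | None = None  # planted beyond-band artifacts
    missing_positions: pd.DataFrame | None = None  # planted absent values


def _seasonal_envelope(doy: np.ndarray, cfg: SyntheticConfig) -> np.ndarray:
    """Smooth yearly bloom-season weight in [0, 1], peaking at ``bloom_peak_doy``."""
    d = np.minimum(np.abs(doy - cfg.bloom_peak_doy), 365 - np.abs(doy - cfg.bloom_peak_doy))
    return np.exp(-0.5 * (d / cfg.bloom_season_width_days) ** 2)


def _daylight(hours: np.ndarray, doy: np.ndarray) -> np.ndarray:
    """Relative solar power in [0, 1] with seasonal day length (temperate NH)."""
    half_day = 6.0 + 1.8 * np.cos(2 * np.pi * (doy - 172) / 365)  # hours from noon
    return np.clip(np.cos(np.pi * (hours - 13.0) / (2 * half_day)), 0.0, None) ** 1.5


def _one_buoy(
    index: pd.DatetimeIndex, profile: BuoyProfile, cfg: SyntheticConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, np.ndarray]:
    n = len(index)
    doy = index.dayofyear.to_numpy().astype(float)
    hours = (index.hour + index.minute / 60).to_numpy()
    years = index.year.to_numpy()
    dt_hours = cfg.cadence_minutes / 60.0
    noise = {k: v * profile.noise_scale for k, v in cfg.noise_std.items()}

    # --- latent chlorophyll: envelope + bloom pulses + diel migration
    envelope = _seasonal_envelope(doy, cfg)
    pulses = np.zeros(n)
    t_days = (index - index[0]).total_seconds().to_numpy() / 86400.0
    for year in np.unique(years):
        year_days = t_days[years == year]
        lo, hi = year_days.min(), year_days.max()
        k = rng.poisson(cfg.n_blooms_per_year)
        for _ in range(k):
            # bloom onsets drawn inside the season, heights log-normal
            center = cfg.bloom_peak_doy + rng.normal(0, cfg.bloom_season_width_days)
            start_of_year = lo - (doy[years == year][0] - 1)
            c = start_of_year + center
            if not (lo - 30 <= c <= hi + 30):
                continue
            height = rng.lognormal(np.log(profile.bloom_amplitude), 0.5)
            width = cfg.bloom_duration_days * rng.uniform(0.5, 1.5)
            pulses += height * np.exp(-0.5 * ((t_days - c) / width) ** 2)
    diel = 1.0 + profile.diel_chl_amplitude * np.sin(2 * np.pi * (hours - 10) / 24)
    latent = (cfg.chl_baseline + envelope * pulses) * diel
    latent = np.maximum(latent, 0.05)

    # --- temperature: seasonal + diel + AR(1) noise
    seasonal_t = cfg.temp_mean - cfg.temp_seasonal_amplitude * np.cos(2 * np.pi * (doy - 28) / 365)
    diel_t = cfg.temp_diel_amplitude * np.sin(2 * np.pi * (hours - 9) / 24)
    eps = rng.normal(0, noise["temperature"], n)
    eps[0] = 0.0
    ar = lfilter([1.0], [1.0, -0.95], eps)
    temperature = seasonal_t + diel_t + ar

    # --- pH: base + saturating algal coupling + diel + noise
    ph = (
        cfg.ph_base
        + cfg.ph_chl_coupling * np.log1p(latent)
        + cfg.ph_diel_amplitude * np.sin(2 * np.pi * (hours - 10) / 24)
        + rng.normal(0, noise["ph"], n)
    )
    ph = np.clip(ph, 0.0, 14.0)

    # --- conductivity: drought drift + rain-event exponential drops + noise
    ec = cfg.ec_baseline + cfg.ec_drought_amplitude * _seasonal_envelope(doy, cfg)
    n_rain = rng.poisson(cfg.rain_events_per_year * cfg.n_years)
    rain_times = rng.uniform(t_days.min(), t_days.max(), n_rain)
    # rain mostly outside the drought season
    for rt in rain_times:
        drop = rng.exponential(cfg.rain_drop_magnitude)
        after = t_days >= rt
        ec[after] -= drop * np.exp(-(t_days[after] - rt) / cfg.rain_recovery_days)
    ec = ec + rng.normal(0, noise["conductivity"], n)
    ec = np.maximum(ec, 5.0)

    # --- battery: solar charge / night drain sawtooth
    power = _daylight(hours, doy)
    battery = np.empty(n)
    b = cfg.battery_float
    b_lo, b_hi = cfg.battery_float - 0.3, cfg.battery_full
    charge = cfg.battery_charge_rate * power * dt_hours - cfg.battery_drain_rate * dt_hours
    battery[0] = b
    for i in range(1, n):
        b = b + charge[i]
        if b > b_hi:
            b = b_hi
        elif b < b_lo:
            b = b_lo
        battery[i] = b
    battery = battery + rng.normal(0, noise["battery"], n)

    # --- measured chlorophyll: latent + noise + positive fluorometer spikes
    chl = latent + rng.normal(0, noise["chlorophyll"], n)
    spikes = rng.random(n) < cfg.chl_spike_rate
    chl[spikes] += rng.lognormal(np.log(cfg.chl_spike_scale), 0.6, int(spikes.sum()))
    chl = np.maximum(chl, 0.0)

    frame = pd.DataFrame(
        {
            "timestamp": index,
            "buoy_id": profile.name,
            "temperature": temperature,
            "conductivity": ec,
            "ph": ph,
            "battery": battery,
            "chlorophyll": chl,
        }
    )
    return frame, latent


def generate(config: SyntheticConfig | None = None) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate the multi-buoy sensor table and its ground truth.

    Deterministic for a given config (including its seed): identical configs
    produce bit-identical tables.  Rows are sorted by (buoy_id, timestamp);
    each buoy contributes ``n_years * 365 * (1440 / cadence)`` rows.
    """
    cfg = config or SyntheticConfig()
    periods = cfg.n_years * 365 * (DAY_MINUTES // cfg.cadence_minutes)
    index = pd.date_range(cfg.start, periods=periods, freq=f"{cfg.cadence_minutes}min")
    frames, truths = [], []
    for i, profile in enumerate(sorted(cfg.buoys, key=lambda p: p.name)):
        rng = np.random.default_rng([cfg.seed, i])
        frame, latent = _one_buoy(index, profile, cfg, rng)
        frames.append(frame)
        truths.append(
            pd.DataFrame({"timestamp": index, "buoy_id": profile.name, "latent": latent})
        )
    table = pd.concat(frames, ignore_index=True)
    truth = GroundTruth(
        latent_chl=pd.concat(truths, ignore_index=True),
        ph_chl_coupling=cfg.ph_chl_coupling,
    )
    return table, truth


def inject_artifacts(
    table: pd.DataFrame,
    outlier_rate: float = 0.04,
    missing_rate: float = 0.03,
    seed: int = 0,
    ranges: ValidRanges | None = None,
    snap_fraction: float = 0.5,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Plant out-of-range and missing values at seeded positions.

    ``outlier_rate`` of the rows receive one out-of-range value each:
    a ``snap_fraction`` share lands just inside the cleaner's snap band
    (recoverable calibration drift) and the rest just beyond it
    (unrecoverable failures).  ``missing_rate`` of the rows lose one value.
    Rows are chosen disjointly across the three artifact classes, so planted
    counts equal observable snap/removal counts exactly.  At the default
    rates the beyond-band and missing rows together make cleaning remove
    about 5% of the table.

    Returns the corrupted table and a :class:`GroundTruth` carrying only the
    artifact positions (``latent_chl`` is empty).
    """
    if not (0 <= outlier_rate <= 1 and 0 <= missing_rate <= 1):
        raise ValueError("rates must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    ranges = ranges or ValidRanges()
    out = table.copy()
    n = len(out)
    n_outlier = int(round(outlier_rate * n))
    n_snap = int(round(snap_fraction * n_outlier))
    n_beyond = n_outlier - n_snap
    n_missing = int(round(missing_rate * n))
    chosen = rng.choice(n, size=min(n, n_snap + n_beyond + n_missing), replace=False)
    snap_rows = chosen[:n_snap]
    beyond_rows = chosen[n_snap : n_snap + n_beyond]
    missing_rows = chosen[n_snap + n_beyond :]

    def _plant(rows: np.ndarray, kind: str) -> pd.DataFrame:
        recs = []
        for r in rows:
            col = NUMERIC_COLUMNS[rng.integers(len(NUMERIC_COLUMNS))]
            lo, hi = ranges.limits[col]
            band = ranges.tolerance * (hi - lo)
            high_side = bool(rng.random() < 0.5)
            if kind == "missing":
                out.iat[r, out.columns.get_loc(col)] = np.nan
            elif kind == "snap":
                delta = band * rng.uniform(0.1, 0.95)
                out.iat[r, out.columns.get_loc(col)] = (hi + delta) if high_side else (lo - delta)
            else:  # beyond
                delta = band * rng.uniform(1.05, 3.0)
                out.iat[r, out.columns.get_loc(col)] = (hi + delta) if high_side else (lo - delta)
            recs.append({"row": int(r), "column": col, "kind": kind})
        return pd.DataFrame(recs, columns=["row", "column", "kind"])

    truth = GroundTruth(
        latent_chl=pd.DataFrame(columns=["timestamp", "buoy_id", "latent"]),
        ph_chl_coupling=np.nan,
        snap_positions=_plant(snap_rows, "snap"),
        removal_positions=_plant(beyond_rows, "beyond"),
        missing_positions=_plant(missing_rows, "missing"),
    )
    return out[CANONICAL_COLUMNS], truth
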