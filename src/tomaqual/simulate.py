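"""Synthetic greenhouse study generator.

Emulates the data the pipeline consumes when no real logger/camera data are
at hand: diurnal temperature/humidity/radiation series with AR(1) noise and
missingness, per-plant green→red ripening kinetics driven by cumulative
thermal time (growing degree days, GDD), rendered fruit-disc images whose
measured color ratios recover the generating fractions, and six quality
traits generated as smooth functions of the image-derived normalized a*
feature.

Defaults describe a spring greenhouse tomato stand: 80 plants monitored
hourly over a 45-day ripening window with staggered starts, temperature
22 ± 6 °C, humidity anti-phase 65 ± 15 %RH, midday radiation peak
800 W/m², GDD base 10 °C.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.color import hsv2rgb

from .color import rgb_to_a
from .preprocess import SensorSeries

__all__ = [
    "SimScenario",
    "TraitCurve",
    "SimStudy",
    "gen_environment",
    "gen_color_trajectory",
    "gen_quality",
    "render_fruit_image",
    "inject_missingness",
    "simulate_study",
]

VARIABLES = ["temperature", "humidity", "radiation"]
TRAITS = ["FI", "SSC", "SS", "TA", "VC", "LYC"]
TRAIT_UNITS = {
    "FI": "kg/cm2",
    "SSC": "degBrix",
    "SS": "mg/g",
    "TA": "%",
    "VC": "mg/g",
    "LYC": "mg/g",
}


@dataclass
class TraitCurve:
    """Smooth response of one trait to a_norm.

    ``kind='logistic'``: lo + (hi−lo)·σ(steepness·(a−midpoint)); a negative
    steepness gives a decreasing trait.  ``kind='bump'``: lo + (hi−lo)·
    exp(−((a−midpoint)/width)²), a concave rise-then-fall.
    """

    lo: float
    hi: float
    midpoint: float
    steepness: float = 15.0
    width: float = 0.15
    kind: str = "logistic"
    noise_sigma: float = 0.0

    def mean(self, a_norm: np.ndarray) -> np.ndarray:
        a = np.asarray(a_norm, dtype=float)
        if self.kind == "logistic":
            return self.lo + (self.hi - self.lo) / (1.0 + np.exp(-self.steepness * (a - self.midpoint)))
        if self.kind == "bump":
            return self.lo + (self.hi - self.lo) * np.exp(-(((a - self.midpoint) / self.width) ** 2))
        raise ValueError(f"unknown trait curve kind {self.kind!r}")


def _default_traits() -> dict:
    # Tomato-typical ranges; LYC/SSC/SS rise with ripening, FI/TA fall,
    # VC peaks mid-ripening.  Noise σ ≈ 4–6 % of each range.
    return {
        "FI": TraitCurve(6.5, 2.0, 0.55, 12.0, noise_sigma=0.20),
        "SSC": TraitCurve(4.0, 6.2, 0.55, 12.0, noise_sigma=0.10),
        "SS": TraitCurve(14.0, 30.0, 0.55, 12.0, noise_sigma=0.70),
        "TA": TraitCurve(0.65, 0.32, 0.55, 12.0, noise_sigma=0.015),
        "VC": TraitCurve(0.14, 0.26, 0.55, width=0.22, kind="bump", noise_sigma=0.006),
        "LYC": TraitCurve(0.004, 0.095, 0.58, 14.0, noise_sigma=0.004),
    }


@dataclass
class SimScenario:
    """Parameter set for the synthetic greenhouse/fruit generator."""

    days: int = 45
    step_hours: int = 1
    n_plants: int = 80
    stagger_days: int = 20  # plant monitoring starts spread over this span
    # environment
    temp_mean: float = 22.0
    temp_amplitude: float = 6.0
    temp_noise_sigma: float = 0.8
    humidity_mean: float = 65.0
    humidity_amplitude: float = 15.0
    humidity_noise_sigma: float = 3.0
    radiation_peak: float = 800.0
    day_length_hours: float = 14.0
    radiation_noise_sigma: float = 30.0
    ar1_phi: float = 0.7
    # color kinetics
    t_base: float = 10.0
    gdd50: float = 300.0
    kinetics_steepness: float = 0.025  # per °C·day
    yellow_amplitude: float = 0.25
    yellow_width: float = 80.0
    plant_jitter: float = 0.10  # relative spread of per-plant GDD50 / k
    # traits
    traits: dict = field(default_factory=_default_traits)
    trait_noise_scale: float = 1.0  # multiplies every trait's noise_sigma
    # missingness
    missing_rate: float = 0.03
    missing_max_run: int = 8
    # imaging
    image_size: int = 96
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if not 0.0 < self.day_length_hours < 24.0:
            raise ValueError("day_length_hours must lie in (0, 24)")
        if self.kinetics_steepness <= 0:
            raise ValueError("kinetics_steepness must be positive")
        for name, curve in self.traits.items():
            if curve.noise_sigma < 0:
                raise ValueError(f"negative noise sigma for trait {name}")

    @property
    def total_days(self) -> int:
        return self.days + self.stagger_days


def _ar1(rng: np.random.Generator, n: int, sigma: float, phi: float) -> np.ndarray:
    if sigma == 0:
        return np.zeros(n)
    eps = rng.normal(0.0, sigma * np.sqrt(1 - phi**2), size=n)
    out = np.empty(n)
    out[0] = rng.normal(0.0, sigma)
    for i in range(1, n):
        out[i] = phi * out[i - 1] + eps[i]
    return out


def gen_environment(scenario: SimScenario, rng: np.random.Generator | None = None) -> SensorSeries:
    """Hourly diurnal greenhouse series.

    Temperature peaks at 15:00 (sinusoid), humidity is anti-phase,
    radiation is a half-sine centered on solar noon and zero at night;
    each variable carries seeded AR(1) noise (radiation noise truncated so
    night values stay exactly zero and day values non-negative).
    """
    rng = rng or np.random.default_rng(scenario.seed)
    n = int(scenario.total_days * 24 / scenario.step_hours)
    timestamps = pd.date_range("2024-03-01", periods=n, freq=f"{scenario.step_hours}h")
    hours = timestamps.hour + timestamps.minute / 60.0
    diurnal = np.sin(2 * np.pi * (hours - 9.0) / 24.0)  # peak at 15:00
    temp = scenario.temp_mean + scenario.temp_amplitude * diurnal
    temp = temp + _ar1(rng, n, scenario.temp_noise_sigma, scenario.ar1_phi)
    hum = scenario.humidity_mean - scenario.humidity_amplitude * diurnal
    hum = np.clip(hum + _ar1(rng, n, scenario.humidity_noise_sigma, scenario.ar1_phi), 0.0, 100.0)
    half = scenario.day_length_hours / 2.0
    phase = (hours - 12.0) / half  # in [-1, 1] during daylight
    rad = np.where(np.abs(phase) < 1.0, scenario.radiation_peak * np.cos(np.pi * phase / 2.0), 0.0)
    rad_noise = _ar1(rng, n, scenario.radiation_noise_sigma, scenario.ar1_phi)
    rad = np.where(rad > 0.0, np.maximum(rad + rad_noise, 0.0), 0.0)
    values = np.column_stack([temp, hum, rad])
    return SensorSeries(timestamps, values, list(VARIABLES), np.zeros_like(values, dtype=bool))


def growing_degree_days(env: SensorSeries, t_base: float, start_index: int = 0) -> np.ndarray:
    """GDD(t) = Σ max(T − T_base, 0)·Δt/24 accumulated from ``start_index``."""
    temp = env.values[start_index:, env.variables.index("temperature")]
    dt_days = env.step / pd.Timedelta(days=1)
    return np.cumsum(np.maximum(temp - t_base, 0.0)) * dt_days


def gen_color_trajectory(
    env: SensorSeries,
    scenario: SimScenario,
    start_index: int = 0,
    gdd50: float | None = None,
    steepness: float | None = None,
) -> np.ndarray:
    """Per-time (red, yellow, green) fractions along the ripening span.

    Red follows a logistic in thermal time, yellow is a transient Gaussian
    bump around the midpoint (capped so red+yellow ≤ 1), green is the rest.
    """
    if len(env.timestamps) - start_index < int(24 / (env.step / pd.Timedelta(hours=1))):
        raise ValueError("environment must cover at least one day")
    gdd = growing_degree_days(env, scenario.t_base, start_index)
    g50 = scenario.gdd50 if gdd50 is None else gdd50
    k = scenario.kinetics_steepness if steepness is None else steepness
    red = 1.0 / (1.0 + np.exp(-k * (gdd - g50)))
    yellow = scenario.yellow_amplitude * np.exp(-(((gdd - g50) / scenario.yellow_width) ** 2))
    yellow = np.minimum(yellow, 1.0 - red)
    green = 1.0 - red - yellow
    return np.column_stack([red, yellow, green])


def gen_quality(
    a_norm, scenario: SimScenario, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Six quality traits as smooth functions of a_norm plus Gaussian noise.

    Outputs are clamped at zero (all traits are physical quantities).
    """
    rng = rng or np.random.default_rng(scenario.seed)
    a = np.asarray(a_norm, dtype=float)
    out = {}
    for name in TRAITS:
        curve = scenario.traits[name]
        mean = curve.mean(a)
        sigma = curve.noise_sigma * scenario.trait_noise_scale
        noise = rng.normal(0.0, sigma, size=a.shape) if sigma > 0 else 0.0
        out[name] = np.maximum(mean + noise, 0.0)
    return pd.DataFrame(out)


#: Base HSV hues (degrees) used to paint the red / yellow / green sectors.
_SECTOR_HUES = (5.0, 50.0, 120.0)


def render_fruit_image(
    fractions, size: int | None = None, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Disc-shaped synthetic fruit on a gray background.

    Pixels are colored by angular sectors proportional to the requested
    red/yellow/green fractions, with small seeded hue/value jitter.  The
    measured ``color_ratios`` of the result recover the inputs to ~0.02.
    """
    fractions = np.asarray(fractions, dtype=float)
    if fractions.shape != (3,) or np.any(fractions < -1e-9) or abs(fractions.sum() - 1.0) > 1e-6:
        raise ValueError("fractions must be three non-negative values summing to 1")
    size = size or 96
    rng = np.random.default_rng(seed)
    ys, xs = np.mgrid[0:size, 0:size]
    cy = cx = (size - 1) / 2.0
    r = np.hypot(ys - cy, xs - cx)
    mask = r <= 0.45 * size
    theta = (np.arctan2(ys - cy, xs - cx) + np.pi) / (2 * np.pi)  # [0, 1)
    bounds = np.cumsum(fractions)
    sector = np.digitize(theta, bounds[:2])
    hue = np.choose(sector, _SECTOR_HUES) + rng.uniform(-4.0, 4.0, size=sector.shape)
    hsv = np.zeros((size, size, 3))
    hsv[..., 0] = (hue % 360.0) / 360.0
    hsv[..., 1] = 0.85
    hsv[..., 2] = np.clip(0.80 + rng.uniform(-0.05, 0.05, size=sector.shape), 0.0, 1.0)
    rgb = (hsv2rgb(hsv) * 255.0).round().astype(np.uint8)
    image = np.full((size, size, 3), 180, dtype=np.uint8)
    image[mask] = rgb[mask]
    return image, mask


def inject_missingness(
    series: SensorSeries, rate: float, max_run: int, seed: int = 0
) -> SensorSeries:
    """Mask ~``rate`` of each variable's points in runs of length ≤ ``max_run``.

    When ``max_run`` > 5 at least one run longer than 5 points is planted
    per variable so both gap-filling branches are exercised.
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must lie in [0, 1)")
    out = series.copy()
    if rate == 0.0:
        return out
    rng = np.random.default_rng(seed)
    n = len(series.timestamps)
    for j in range(len(series.variables)):
        target = int(round(rate * n))
        planted = 0
        forced_long = max_run > 5
        guard = 0
        while planted < target and guard < 10 * n:
            guard += 1
            length = int(rng.integers(6, max_run + 1)) if forced_long else int(rng.integers(1, max_run + 1))
            forced_long = False
            start = int(rng.integers(1, max(2, n - length - 1)))
            if out.missing_mask[max(0, start - 1) : start + length + 1, j].any():
                continue
            out.missing_mask[start : start + length, j] = True
            planted += length
    return out


@dataclass
class SimStudy:
    """A complete simulated study: environment + per-plant fruit records.

    ``records`` has one row per plant per hour: plant_id, timestamp,
    env_index (row into ``env``), red/yellow/green fractions and a_norm.
    ``daily`` has one row per plant per day with the image-derived a_norm
    and the six quality traits.
    """

    scenario: SimScenario
    env: SensorSeries
    env_missing: SensorSeries
    records: pd.DataFrame
    daily: pd.DataFrame


def _a_norm_curve(fractions_daily: np.ndarray, size: int, seed: int) -> np.ndarray:
    """Image-derived a_norm for a stack of daily fraction triples."""
    out = np.empty(len(fractions_daily))
    for i, frac in enumerate(fractions_daily):
        img, mask = render_fruit_image(frac, size=size, seed=seed + i)
        _, out[i] = rgb_to_a(img, mask)
    return out


def simulate_study(scenario: SimScenario) -> SimStudy:
    """Generate the full synthetic study.

    The fruit-surface a_norm is measured from rendered images (daily, then
    linearly interpolated to the hourly grid) so the image pipeline — not an
    analytic shortcut — links color fractions to the quality feature.
    """
    rng = np.random.default_rng(scenario.seed)
    env = gen_environment(scenario, rng)
    env_missing = inject_missingness(
        env, scenario.missing_rate, scenario.missing_max_run, seed=scenario.seed + 1
    )
    steps_per_day = int(24 / scenario.step_hours)
    horizon = scenario.days * steps_per_day
    rec_rows, daily_rows = [], []
    for p in range(scenario.n_plants):
        plant = f"plant{p:03d}"
        start_day = int(round(p * scenario.stagger_days / max(1, scenario.n_plants - 1)))
        start = start_day * steps_per_day
        jit = 1.0 + scenario.plant_jitter * rng.standard_normal(2)
        fractions = gen_color_trajectory(
            env,
            scenario,
            start_index=start,
            gdd50=scenario.gdd50 * max(jit[0], 0.5),
            steepness=scenario.kinetics_steepness * max(jit[1], 0.3),
        )[:horizon]
        times = env.timestamps[start : start + horizon]
        day_idx = np.arange(0, horizon, steps_per_day)
        a_daily = _a_norm_curve(
            fractions[day_idx], scenario.image_size, seed=scenario.seed + 1000 * p
        )
        hours = np.arange(horizon, dtype=float)
        a_hourly = np.interp(hours, day_idx.astype(float), a_daily)
        traits = gen_quality(a_daily, scenario, rng)
        rec_rows.append(
            pd.DataFrame(
                {
                    "plant_id": plant,
                    "timestamp": times,
                    "env_index": np.arange(start, start + horizon),
                    "red": fractions[:, 0],
                    "yellow": fractions[:, 1],
                    "green": fractions[:, 2],
                    "a_norm": a_hourly,
                }
            )
        )
        daily = pd.DataFrame(
            {
                "plant_id": plant,
                "timestamp": times[day_idx],
                "day": start_day + day_idx // steps_per_day,
                "a_norm": a_daily,
                "red": fractions[day_idx, 0],
                "yellow": fractions[day_idx, 1],
                "green": fractions[day_idx, 2],
            }
        )
        daily_rows.append(pd.concat([daily, traits], axis=1))
    return SimStudy(
        scenario,
        env,
        env_missing,
        pd.concat(rec_rows, ignore_index=True),
        pd.concat(daily_rows, ignore_index=True),
    )
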