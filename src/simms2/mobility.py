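"""Drift-tube ion mobility: ATD fitting, stepped-field CCS, resolving power.

The measurement chain mirrors a stepped-field drift-tube experiment in
helium: arrival-time distributions (ATDs) are recorded at several drift
voltages, each ATD is centroided with a Gaussian fit, arrival time is
regressed on reciprocal drift voltage (slope = L^2/K, intercept = dead
time t0), the mobility is reduced to standard number density, and the
Mason–Schamp equation converts reduced mobility K0 into a collision
cross section in Å^2:

    Omega = (3 z e / 16 N0) * sqrt(2 pi / (mu kB T)) * 1 / K0

with mu the ion–helium reduced mass and CODATA constants throughout.

A synthetic generator inverts the same chain so that the full pipeline
can be exercised and validated on data with known ground truth.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize, signal, stats

from .chem import HELIUM_MASS
from .errors import FitError

# CODATA constants (SI)
ELEMENTARY_CHARGE = 1.602176634e-19  # C
BOLTZMANN = 1.380649e-23  # J/K
LOSCHMIDT = 2.686780111e25  # m^-3, gas number density at 273.15 K, 101325 Pa
ATOMIC_MASS = 1.66053906660e-27  # kg

#: FWHM of a unit-sigma Gaussian.
FWHM_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))
#: Base width (4 sigma) expressed in FWHM units.
BASE_WIDTH_FWHM = 4.0 / FWHM_SIGMA


@dataclass(frozen=True)
class InstrumentConfig:
    """Drift cell geometry and conditions; helium buffer gas throughout."""

    drift_length_m: float = 0.2505
    temperature_K: float = 300.0
    pressure_torr: float = 3.5
    buffer_gas_mass_u: float = HELIUM_MASS
    polarity: str = "negative"

    def __post_init__(self):
        for name in ("drift_length_m", "temperature_K", "pressure_torr",
                     "buffer_gas_mass_u"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


DEFAULT_CONFIG = InstrumentConfig()


@dataclass(frozen=True)
class ATD:
    """One arrival-time distribution at a fixed drift voltage."""

    time_ms: np.ndarray
    intensity: np.ndarray
    drift_voltage_V: float
    config: InstrumentConfig = DEFAULT_CONFIG

    def __post_init__(self):
        t = np.asarray(self.time_ms, dtype=float)
        y = np.asarray(self.intensity, dtype=float)
        if t.ndim != 1 or t.shape != y.shape:
            raise ValueError("time and intensity must be 1-D arrays of equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("arrival times must be strictly increasing")
        if np.any(y < 0):
            raise ValueError("intensities must be non-negative")
        object.__setattr__(self, "time_ms", t)
        object.__setattr__(self, "intensity", y)


@dataclass(frozen=True)
class SteppedFieldSeries:
    """ATDs across distinct drift voltages for one analyte."""

    atds: tuple
    mz: float | None = None
    charge: int | None = None

    def __post_init__(self):
        object.__setattr__(self, "atds", tuple(self.atds))
        if len({a.drift_voltage_V for a in self.atds}) < 2:
            raise ValueError("stepped-field series needs >= 2 distinct voltages")

    @property
    def config(self) -> InstrumentConfig:
        return self.atds[0].config

    @property
    def ion_mass_u(self) -> float | None:
        if self.mz is None or self.charge is None:
            return None
        return self.mz * self.charge


@dataclass(frozen=True)
class PeakFit:
    """One fitted conformer peak in an ATD."""

    centroid_ms: float
    fwhm_ms: float
    area: float


@dataclass(frozen=True)
class MobilityResult:
    """Stepped-field fit result, optionally converted to CCS."""

    slope_ms_V: float
    t0_ms: float
    r_squared: float
    K: float | None = None  # m^2 V^-1 s^-1 at cell conditions
    K0: float | None = None  # reduced mobility, m^2 V^-1 s^-1
    ccs_A2: float | None = None
    replicates: int = 1
    deviation: float = 0.0


def _multi_gaussian(t, *params):
    y = np.zeros_like(t)
    for i in range(0, len(params), 3):
        a, mu, sigma = params[i : i + 3]
        y = y + a * np.exp(-0.5 * ((t - mu) / sigma) ** 2)
    return y


def fit_atd(atd: ATD, prominence: float = 0.05) -> list:
    """Gaussian-centroid all conformer peaks in an ATD.

    Peaks are located with a prominence threshold relative to the trace
    maximum, then refined by a joint nonlinear least-squares fit of a
    sum of Gaussians initialised from the detected maxima and local
    widths.  Returns :class:`PeakFit` records sorted by centroid.
    """
    t, y = atd.time_ms, atd.intensity
    if t.size < 5:
        raise FitError("ATD needs at least 5 samples")
    ymax = float(y.max())
    if ymax <= 0 or np.ptp(y) == 0:
        raise FitError(f"flat ATD trace at {atd.drift_voltage_V} V: no peak")
    idx, props = signal.find_peaks(y, prominence=prominence * ymax)
    if idx.size == 0:
        raise FitError(f"no peak above prominence threshold at {atd.drift_voltage_V} V")

    dt = float(np.median(np.diff(t)))
    widths = signal.peak_widths(y, idx, rel_height=0.5)[0] * dt
    p0, lo, hi = [], [], []
    for i, w in zip(idx, widths):
        p0.extend([y[i], t[i], max(w, dt) / FWHM_SIGMA])
        lo.extend([0.0, t[0], dt / 10.0])
        hi.extend([np.inf, t[-1], t[-1] - t[0]])
    try:
        popt, _ = optimize.curve_fit(
            _multi_gaussian, t, y, p0=p0, bounds=(lo, hi), maxfev=20000
        )
    except (RuntimeError, ValueError) as exc:  # pragma: no cover - rare
        raise FitError(f"Gaussian fit did not converge: {exc}") from exc
    peaks = []
    for i in range(0, len(popt), 3):
        a, mu, sigma = popt[i : i + 3]
        sigma = abs(sigma)
        peaks.append(
            PeakFit(
                centroid_ms=float(mu),
                fwhm_ms=float(FWHM_SIGMA * sigma),
                area=float(a * sigma * math.sqrt(2.0 * math.pi)),
            )
        )
    return sorted(peaks, key=lambda p: p.centroid_ms)


def stepped_field_fit(
    series: SteppedFieldSeries,
    conformer_rank: int = 0,
    prominence: float = 0.05,
) -> MobilityResult:
    """Ordinary least squares of arrival time against reciprocal voltage.

    One centroid is taken per ATD — by default the largest-area peak;
    ``conformer_rank`` selects smaller conformer tracks by area rank.
    Duplicate voltages are averaged with a warning.  Returns slope
    (= L^2/K, in ms·V), dead time t0 and R^2, plus the mobility K.
    """
    volts, times = [], []
    for atd in series.atds:
        peaks = fit_atd(atd, prominence=prominence)
        by_area = sorted(peaks, key=lambda p: -p.area)
        if conformer_rank >= len(by_area):
            raise FitError(
                f"conformer rank {conformer_rank} not present at "
                f"{atd.drift_voltage_V} V"
            )
        volts.append(atd.drift_voltage_V)
        times.append(by_area[conformer_rank].centroid_ms)
    volts = np.asarray(volts)
    times = np.asarray(times)
    if np.unique(volts).size < volts.size:
        warnings.warn("duplicate drift voltages collapsed by averaging")
        uv = np.unique(volts)
        times = np.array([times[volts == v].mean() for v in uv])
        volts = uv
    res = stats.linregress(1.0 / volts, times)
    if res.slope <= 0:
        raise FitError("negative arrival-time slope: unphysical mobility")
    L = series.config.drift_length_m
    K = L**2 / (res.slope * 1e-3)  # ms·V -> V·s
    r2 = 1.0 if volts.size == 2 else float(res.rvalue**2)
    return MobilityResult(
        slope_ms_V=float(res.slope),
        t0_ms=float(res.intercept),
        r_squared=r2,
        K=K,
    )


def reduced_mobility(K: float, config: InstrumentConfig) -> float:
    """Mobility reduced to standard number density (273.15 K, 760 Torr)."""
    return K * (config.pressure_torr / 760.0) * (273.15 / config.temperature_K)


def ccs_from_mobility(
    K: float, z: int, ion_mass_u: float, config: InstrumentConfig
) -> float:
    """Mason–Schamp CCS in Å^2 from a drift-cell mobility."""
    if K <= 0 or z < 1 or ion_mass_u <= 0:
        raise ValueError("K, z and ion mass must be positive")
    K0 = reduced_mobility(K, config)
    mu = (
        ion_mass_u
        * config.buffer_gas_mass_u
        / (ion_mass_u + config.buffer_gas_mass_u)
        * ATOMIC_MASS
    )
    omega_m2 = (
        (3.0 * z * ELEMENTARY_CHARGE / (16.0 * LOSCHMIDT))
        * math.sqrt(2.0 * math.pi / (mu * BOLTZMANN * config.temperature_K))
        / K0
    )
    return omega_m2 * 1e20


def mobility_from_ccs(
    ccs_A2: float, z: int, ion_mass_u: float, config: InstrumentConfig
) -> float:
    """Inverse of :func:`ccs_from_mobility`: drift-cell K for a given CCS."""
    if ccs_A2 <= 0 or z < 1 or ion_mass_u <= 0:
        raise ValueError("ccs, z and ion mass must be positive")
    mu = (
        ion_mass_u
        * config.buffer_gas_mass_u
        / (ion_mass_u + config.buffer_gas_mass_u)
        * ATOMIC_MASS
    )
    K0 = (
        (3.0 * z * ELEMENTARY_CHARGE / (16.0 * LOSCHMIDT))
        * math.sqrt(2.0 * math.pi / (mu * BOLTZMANN * config.temperature_K))
        / (ccs_A2 * 1e-20)
    )
    return K0 / ((config.pressure_torr / 760.0) * (273.15 / config.temperature_K))


def ccs_from_series(
    series: SteppedFieldSeries, conformer_rank: int = 0
) -> MobilityResult:
    """Full pipeline: centroid, stepped-field fit, Mason–Schamp conversion."""
    if series.ion_mass_u is None:
        raise ValueError("series needs mz and charge to convert to CCS")
    res = stepped_field_fit(series, conformer_rank=conformer_rank)
    ccs = ccs_from_mobility(res.K, series.charge, series.ion_mass_u, series.config)
    return replace(res, K0=reduced_mobility(res.K, series.config), ccs_A2=ccs)


def replicate_ccs(ccs_values) -> MobilityResult:
    """Mean CCS over replicates with maximum relative deviation."""
    vals = np.asarray(list(ccs_values), dtype=float)
    if vals.size == 0:
        raise ValueError("no replicate values")
    mean = float(vals.mean())
    dev = float(np.abs(vals - mean).max() / mean) if vals.size > 1 else 0.0
    return MobilityResult(
        slope_ms_V=float("nan"),
        t0_ms=float("nan"),
        r_squared=float("nan"),
        ccs_A2=mean,
        replicates=int(vals.size),
        deviation=dev,
    )


def required_resolving_power(rel_ccs_diff: float, target_rpp: float = 0.75) -> float:
    """Minimum FWHM-based resolving power to separate two isomer peaks.

    Both peaks are equal-width Gaussians at resolving power Rp = t/FWHM.
    Peak-to-peak resolution uses base widths w_b = 4 sigma:
    Rpp = 2 (t2 - t1) / (w_b1 + w_b2), so Rp = (4/2.3548) Rpp / delta.
    """
    if not 0 < rel_ccs_diff < 1:
        raise ValueError("relative CCS difference must be in (0, 1)")
    if target_rpp <= 0:
        raise ValueError("target peak-to-peak resolution must be positive")
    return BASE_WIDTH_FWHM * target_rpp / rel_ccs_diff


def plate_number(resolving_power: float) -> float:
    """Theoretical plate number N = (t/sigma)^2 = (2.3548 Rp)^2."""
    if resolving_power <= 0:
        raise ValueError("resolving power must be positive")
    return (FWHM_SIGMA * resolving_power) ** 2


def peak_to_peak_resolution(p1: PeakFit, p2: PeakFit) -> float:
    """Two-peak resolution 2*dt/(w_b1 + w_b2) with base widths 4 sigma."""
    wb1 = BASE_WIDTH_FWHM * p1.fwhm_ms
    wb2 = BASE_WIDTH_FWHM * p2.fwhm_ms
    return 2.0 * abs(p2.centroid_ms - p1.centroid_ms) / (wb1 + wb2)


DEFAULT_VOLTAGES = tuple(np.linspace(50.0, 120.0, 8))


def _default_fwhm(t_ms: float) -> float:
    # constant apparent resolving power of 55, typical of the drift cell
    return t_ms / 55.0


def simulate_atd(
    peaks,
    drift_voltage_V: float,
    config: InstrumentConfig = DEFAULT_CONFIG,
    points_per_fwhm: int = 25,
    window_fwhm: float = 4.0,
    intensity_noise: float = 0.0,
    rng=None,
) -> ATD:
    """Sample a sum of Gaussian peaks [(centroid_ms, fwhm_ms, amplitude)]."""
    peaks = list(peaks)
    lo = min(c - window_fwhm * w for c, w, _ in peaks)
    hi = max(c + window_fwhm * w for c, w, _ in peaks)
    dt = min(w for _, w, _ in peaks) / points_per_fwhm
    t = np.arange(lo, hi + dt, dt)
    y = np.zeros_like(t)
    for c, w, a in peaks:
        sigma = w / FWHM_SIGMA
        y = y + a * np.exp(-0.5 * ((t - c) / sigma) ** 2)
    if intensity_noise > 0:
        rng = np.random.default_rng() if rng is None else rng
        y = np.clip(y + rng.normal(0, intensity_noise * y.max(), y.size), 0, None)
    return ATD(t, y, drift_voltage_V, config)


def simulate_stepped_field(
    ccs_A2: float,
    z: int,
    ion_mass_u: float,
    config: InstrumentConfig = DEFAULT_CONFIG,
    voltages=DEFAULT_VOLTAGES,
    t0_ms: float = 0.25,
    noise: float = 0.0,
    fwhm_model=None,
    intensity_noise: float = 0.0,
    seed=None,
) -> SteppedFieldSeries:
    """Generate the ATD series a given CCS would produce.

    Centroids follow t_A = L^2/(K V) + t0 with K from the inverse
    Mason–Schamp relation; ``noise`` is a relative standard deviation
    applied to each centroid.  Deterministic under a fixed ``seed``.
    """
    if ccs_A2 <= 0:
        raise ValueError("ccs must be positive")
    voltages = tuple(voltages)
    if len(voltages) < 2:
        raise ValueError("need at least two drift voltages")
    rng = np.random.default_rng(seed)
    fwhm_model = fwhm_model or _default_fwhm
    K = mobility_from_ccs(ccs_A2, z, ion_mass_u, config)
    L = config.drift_length_m
    atds = []
    for V in voltages:
        t_drift = L**2 / (K * V) * 1e3  # ms
        centroid = t_drift + t0_ms
        if noise > 0:
            centroid *= 1.0 + rng.normal(0.0, noise)
        atds.append(
            simulate_atd(
                [(centroid, fwhm_model(centroid), 1000.0)],
                V,
                config,
                intensity_noise=intensity_noise,
                rng=rng,
            )
        )
    return SteppedFieldSeries(tuple(atds), mz=ion_mass_u / z, charge=z)
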