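"""Sediment oxygen demand from incubation time series.

The chain mirrors the laboratory computation: interval sediment oxygen
consumption rates SOC = (m1 - m2)/t from headspace O2 mass, blank
correction against a sediment-free flask, Van't Hoff (Q10) normalisation to
20 degC with base 1.065 (valid for incubation temperatures >= 10 degC),
trapezoidal accumulation of the normalised rates to the total mass of
oxygen consumed over 0-5 days (SOC5) and 0-20 days (SOC20), and division by
the dry sediment mass to give SOD5 and SOD20 in mg O2 per g dry sediment.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .data_model import OxygenTimeSeries, ValidationError

logger = logging.getLogger(__name__)

Q10_BASE = 1.065
MIN_VALID_TEMPERATURE_C = 10.0

#: molar mass of O2, g/mol; gas constant, L kPa / (mol K)
_O2_MOLAR_MASS = 31.998
_R = 8.31446


@dataclass(frozen=True)
class SodResult:
    """Per-flask SOD outcome.

    ``rate_times``/``rates`` hold the blank-corrected, temperature-normalised
    interval rate series (mg O2/day at interval midpoints); negative
    corrected rates are retained there for diagnostics, but SOD values are
    clamped at zero.
    """

    flask_id: str
    rate_times: np.ndarray
    rates: np.ndarray
    soc5: float
    soc20: float
    sod5: float
    sod20: float


def soc_rate(series: OxygenTimeSeries):
    """Interval oxygen consumption rates (m1 - m2) / (t2 - t1).

    Returns ``(midpoints, rates)``: rates in mg O2/day assigned to interval
    midpoints, positive when oxygen is consumed.
    """
    t = series.times
    m = series.o2_mass
    if t.size < 2:
        raise ValidationError(f"flask {series.flask_id!r}: need >= 2 time points")
    dt = np.diff(t)
    if np.any(dt == 0):
        raise ValidationError(f"flask {series.flask_id!r}: duplicate time stamps")
    rates = -np.diff(m) / dt
    mid = t[:-1] + 0.5 * dt
    return mid, rates


def blank_correct(sample_times, sample_rates, blank_times, blank_rates):
    """Subtract the blank rate series from the sample rate series.

    The blank is linearly interpolated onto the sample midpoints; its time
    span must cover the sample's.
    """
    sample_times = np.asarray(sample_times, dtype=float)
    sample_rates = np.asarray(sample_rates, dtype=float)
    blank_times = np.asarray(blank_times, dtype=float)
    blank_rates = np.asarray(blank_rates, dtype=float)
    if blank_times[0] > sample_times[0] or blank_times[-1] < sample_times[-1]:
        raise ValidationError("blank series does not cover the sample time span")
    return sample_rates - np.interp(sample_times, blank_times, blank_rates)


def q10_normalize(rate, temperature_c: float):
    """Normalise a consumption rate to 20 degC: rate x 1.065^(20 - T).

    Valid for incubation temperatures of 10 degC or more.
    """
    if temperature_c < MIN_VALID_TEMPERATURE_C:
        raise ValidationError(
            f"Q10 correction only valid for T >= {MIN_VALID_TEMPERATURE_C} degC "
            f"(got {temperature_c})"
        )
    return rate * Q10_BASE ** (20.0 - temperature_c)


def integrate_soc(rate_times, rates, window) -> float:
    """Total oxygen mass consumed over ``window = [t0, t1]`` days.

    Trapezoidal accumulation of the midpoint rate series, linearly
    interpolated inside the window and held constant beyond the first/last
    midpoint.  The window must lie within the measured span.
    """
    rate_times = np.asarray(rate_times, dtype=float)
    rates = np.asarray(rates, dtype=float)
    t0, t1 = float(window[0]), float(window[1])
    if t1 < t0:
        raise ValidationError("integration window reversed")
    # midpoints of the first/last interval sit half a step inside the span
    span_hi = rate_times[-1] + (rate_times[-1] - rate_times[-2]) / 2 if rate_times.size > 1 else rate_times[-1]
    if t1 > span_hi + 1e-9:
        raise ValidationError(
            f"integration window [{t0}, {t1}] exceeds data span (<= {span_hi:.4g})"
        )
    if t1 == t0:
        return 0.0
    inside = rate_times[(rate_times > t0) & (rate_times < t1)]
    grid = np.concatenate(([t0], inside, [t1]))
    vals = np.interp(grid, rate_times, rates)
    return float(np.trapezoid(vals, grid))


def sod_values(soc5: float, soc20: float, dry_mass_g: float):
    """Divide consumed oxygen masses by dry sediment mass.

    Returns ``(sod5, sod20)`` in mg O2 / g dry sediment; negative values
    (blank exceeding sample) are clamped to 0 with a warning.
    """
    if dry_mass_g is None:
        raise ValidationError("dry sediment mass missing")
    if not dry_mass_g > 0:
        raise ValidationError("dry sediment mass must be > 0")
    out = []
    for soc in (soc5, soc20):
        sod = soc / dry_mass_g
        if sod < 0:
            logger.warning("negative SOD clamped to 0 (blank exceeded sample)")
            sod = 0.0
        out.append(sod)
    return tuple(out)


def compute_sod(
    sample: OxygenTimeSeries,
    blank: OxygenTimeSeries | None = None,
    windows=((0.0, 5.0), (0.0, 20.0)),
) -> SodResult:
    """Full per-flask chain: rates, blank correction, Q10 normalisation,
    integration over 0-5 and 0-20 days, division by dry mass."""
    if sample.is_blank:
        raise ValidationError(f"flask {sample.flask_id!r} is a blank")
    mid, rates = soc_rate(sample)
    if blank is not None:
        bmid, brates = soc_rate(blank)
        rates = blank_correct(mid, rates, bmid, brates)
    rates20 = q10_normalize(rates, sample.temperature_c)
    soc5 = integrate_soc(mid, rates20, windows[0])
    soc20 = integrate_soc(mid, rates20, windows[1])
    sod5, sod20 = sod_values(soc5, soc20, sample.dry_mass_g)
    return SodResult(
        flask_id=sample.flask_id,
        rate_times=mid,
        rates=rates20,
        soc5=soc5,
        soc20=soc20,
        sod5=sod5,
        sod20=sod20,
    )


def o2_mass_from_fraction(
    volume_fraction,
    headspace_volume_l: float,
    temperature_c: float,
    pressure_kpa: float = 101.325,
):
    """Convert an O2 volume fraction of the headspace to mg O2 via the ideal
    gas law (optional sensor-conversion helper; the core chain consumes O2
    mass directly)."""
    n_total = pressure_kpa * headspace_volume_l / (_R * (temperature_c + 273.15))
    return np.asarray(volume_fraction, dtype=float) * n_total * _O2_MOLAR_MASS * 1000.0
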