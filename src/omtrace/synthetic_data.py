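"""Synthetic tracer panels and incubation series with known ground truth.

The generator emulates the study design: four organic-matter source
categories (farmyard manures/slurries, damaged road verges, decaying
instream vegetation, human septic waste), several composite samples per
category per subcatchment, and triplicate bed-sediment mixtures built as a
known convex combination of the category means.  The default tracer panel
mirrors the measured quantities: two stable isotope ratios, % organic
carbon and nitrogen, and near-infrared constituent band intensities.

Because sediment is constructed as an exact linear mixture (plus optional
noise), zero-noise fixtures conserve mass exactly and the unmixing solver
must recover the design proportions; this is the ground truth every
pipeline stage is tested against.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .data_model import (
    DEFAULT_CATEGORIES,
    SEDIMENT,
    SOURCE,
    OxygenTimeSeries,
    SampleRecord,
    TracerPanel,
    ValidationError,
)
from .sod import Q10_BASE

logger = logging.getLogger(__name__)

#: plausible central values for the measured fingerprint properties
_BASE_MEANS = {
    "d13C": -28.5,
    "d15N": 5.2,
    "TOC_pct": 9.0,
    "TN_pct": 0.7,
    "ArOH": 0.62,
    "ArNH2": 0.35,
    "Aromatic": 0.88,
    "CH": 0.55,
    "CH2": 1.10,
    "CH3": 0.74,
    "HC=CH": 0.42,
    "CONH2": 0.51,
    "CONHR": 0.47,
    "ROH": 0.93,
    "RNH2": 0.28,
    "Protein": 0.66,
    "Cellulose": 1.25,
    "Starch": 0.58,
    "Starch, glucose": 0.49,
    "H2O": 1.45,
}

_KINDS = {
    "d13C": "isotope",
    "d15N": "isotope",
    "TOC_pct": "elemental",
    "TN_pct": "elemental",
}


def default_panel() -> TracerPanel:
    """The default synthetic tracer panel (2 isotopes, 2 elemental contents,
    16 NIR constituent bands)."""
    names = tuple(_BASE_MEANS)
    kinds = {n: _KINDS.get(n, "nir_band") for n in names}
    ranges = {n: (0.0, 100.0) for n, k in kinds.items() if k == "elemental"}
    return TracerPanel(names=names, kinds=kinds, valid_ranges=ranges)


@dataclass(frozen=True)
class SourceModel:
    """Distributional model of the source categories.

    ``means`` maps category -> tracer -> mean; ``cv`` is the relative
    within-category spread; ``separation`` records the inter-category
    separation factor the means were built with (0 = indistinguishable).
    """

    panel: TracerPanel
    categories: tuple
    means: Mapping[str, Mapping[str, float]]
    cv: float = 0.08
    distribution: str = "normal"
    n_samples: int = 8
    separation: float = 1.0

    def __post_init__(self):
        if self.cv < 0:
            raise ValidationError("cv must be >= 0")
        if self.separation < 0:
            raise ValidationError("separation factor must be >= 0")
        if self.distribution not in ("normal", "lognormal"):
            raise ValidationError(f"unknown distribution {self.distribution!r}")
        for cat in self.categories:
            if cat not in self.means:
                raise ValidationError(f"no means for category {cat!r}")


@dataclass(frozen=True)
class MixtureDesign:
    """Known true mixture behind the synthetic sediment samples."""

    true_p: Mapping[str, float]
    sediment_noise_cv: float = 0.02
    n_sediment_samples: int = 3  # mirrors triplicate field sampling

    def __post_init__(self):
        p = np.array(list(self.true_p.values()), dtype=float)
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValidationError("true_p must lie on the simplex")
        if self.sediment_noise_cv < 0:
            raise ValidationError("sediment_noise_cv must be >= 0")


def default_source_model(
    panel: TracerPanel | None = None,
    categories: Sequence[str] = DEFAULT_CATEGORIES,
    separation: float = 1.0,
    cv: float = 0.08,
    n_samples: int = 8,
    seed: int = 0,
    distribution: str = "normal",
) -> SourceModel:
    """Build a source model with category means displaced from a common base.

    Each category's mean for each tracer is ``base * (1 + separation *
    delta)`` with ``delta`` a fixed draw in [-0.35, 0.35] seeded by ``seed``;
    ``separation=0`` makes the categories statistically indistinguishable.
    """
    panel = panel or default_panel()
    rng = np.random.default_rng(seed)
    means = {}
    for cat in categories:
        offsets = rng.uniform(-0.35, 0.35, size=len(panel.names))
        means[cat] = {
            t: _BASE_MEANS.get(t, 1.0) * (1.0 + separation * d)
            for t, d in zip(panel.names, offsets)
        }
    return SourceModel(
        panel=panel,
        categories=tuple(categories),
        means=means,
        cv=cv,
        distribution=distribution,
        n_samples=n_samples,
        separation=separation,
    )


def _draw(rng, mean: float, cv: float, distribution: str) -> float:
    if cv == 0.0:
        return mean
    sd = abs(mean) * cv
    if distribution == "lognormal" and mean > 0:
        sigma = np.sqrt(np.log1p(cv**2))
        mu = np.log(mean) - 0.5 * sigma**2
        return float(rng.lognormal(mu, sigma))
    if distribution == "lognormal":
        logger.warning("lognormal invalid for non-positive mean; normal used")
    return float(rng.normal(mean, sd))


def _clip_to_range(panel: TracerPanel, tracer: str, value: float) -> float:
    lo, hi = panel.valid_range(tracer)
    return float(min(max(value, lo), hi))


def generate_sources(
    model: SourceModel,
    seed: int | None = None,
    subcatchment: str = "synthetic",
    n_replicates: int = 1,
    replicate_cv: float = 0.02,
) -> list:
    """Reproducible source samples: ``model.n_samples`` composite samples per
    category, optionally with analytical replicate rows."""
    rng = np.random.default_rng(seed)
    records = []
    for cat in model.categories:
        for i in range(model.n_samples):
            values = {
                t: _clip_to_range(
                    model.panel,
                    t,
                    _draw(rng, model.means[cat][t], model.cv, model.distribution),
                )
                for t in model.panel.names
            }
            sample_id = f"{subcatchment}-{cat}-{i + 1:02d}"
            for rep in range(1, n_replicates + 1):
                if n_replicates == 1:
                    rep_values = values
                else:
                    rep_values = {
                        t: v * (1.0 + rng.normal(0.0, replicate_cv))
                        for t, v in values.items()
                    }
                records.append(
                    SampleRecord(
                        sample_id=sample_id,
                        role=SOURCE,
                        category=cat,
                        subcatchment=subcatchment,
                        values=rep_values,
                        replicate_index=rep,
                    )
                )
    return records


def generate_sediment(
    model: SourceModel,
    design: MixtureDesign,
    seed: int | None = None,
    subcatchment: str = "synthetic",
    basis: Mapping[str, Mapping[str, float]] | None = None,
) -> list:
    """Sediment samples as a known convex combination of per-category values.

    Each tracer value is ``sum_s true_p_s * basis_s`` perturbed
    multiplicatively by ``sediment_noise_cv``; ``basis`` defaults to the
    model's category means (pass observed per-category sample medians
    instead to make the mixing model's recovery exact at zero noise).  A
    noisy value falling outside the envelope of the basis values is redrawn
    (up to 100 times, then kept with a warning), so small-noise fixtures
    always pass the bracket test.
    """
    if set(design.true_p) != set(model.categories):
        raise ValidationError("design categories do not match the source model")
    basis = basis if basis is not None else model.means
    rng = np.random.default_rng(seed)
    records = []
    for i in range(design.n_sediment_samples):
        values = {}
        for t in model.panel.names:
            mix = sum(design.true_p[c] * basis[c][t] for c in model.categories)
            lo = min(basis[c][t] for c in model.categories)
            hi = max(basis[c][t] for c in model.categories)
            value = mix
            for _attempt in range(100):
                value = mix * (1.0 + rng.normal(0.0, design.sediment_noise_cv)) if design.sediment_noise_cv else mix
                if lo <= value <= hi:
                    break
            else:
                logger.warning(
                    "sediment tracer %r stayed outside the source-mean envelope", t
                )
            values[t] = _clip_to_range(model.panel, t, value)
        records.append(
            SampleRecord(
                sample_id=f"{subcatchment}-sed-{i + 1:02d}",
                role=SEDIMENT,
                subcatchment=subcatchment,
                values=values,
            )
        )
    return records


def generate_incubation(
    sod_target: float,
    dry_mass_g: float = 2.5,
    k: float = 0.15,
    temperature_c: float = 15.0,
    seed: int | None = None,
    duration_days: float = 25.0,
    dt_days: float = 0.1,
    noise_sd: float = 0.0,
    flask_id: str = "synthetic-flask",
) -> tuple:
    """Synthetic incubation: first-order decay of headspace O2 calibrated so
    the temperature-normalised 0-20-day consumption per gram equals
    ``sod_target`` (mg O2/g).  Returns ``(sample, blank)`` series; the blank
    is flat apart from optional noise.
    """
    if k <= 0:
        raise ValidationError("decay constant k must be > 0")
    if sod_target < 0:
        raise ValidationError("sod_target must be >= 0")
    rng = np.random.default_rng(seed)
    factor = Q10_BASE ** (20.0 - temperature_c)
    consumed_raw_20d = sod_target * dry_mass_g / factor
    amplitude = consumed_raw_20d / -np.expm1(-k * 20.0) if sod_target > 0 else 0.0
    m0 = amplitude * 1.1 + 5.0
    times = np.arange(0.0, duration_days + dt_days / 2, dt_days)
    mass = m0 - amplitude * -np.expm1(-k * times)
    blank_mass = np.full_like(times, m0)
    if noise_sd > 0:
        mass = np.clip(mass + rng.normal(0.0, noise_sd, size=times.size), 0.0, None)
        blank_mass = np.clip(
            blank_mass + rng.normal(0.0, noise_sd, size=times.size), 0.0, None
        )
    sample = OxygenTimeSeries(
        flask_id=flask_id,
        times=times,
        o2_mass=mass,
        temperature_c=temperature_c,
        is_blank=False,
        dry_mass_g=dry_mass_g,
    )
    blank = OxygenTimeSeries(
        flask_id=f"{flask_id}-blank",
        times=times,
        o2_mass=blank_mass,
        temperature_c=temperature_c,
        is_blank=True,
    )
    return sample, blank
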