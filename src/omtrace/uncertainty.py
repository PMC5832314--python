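"""Monte Carlo uncertainty analysis of the mixing model.

The medians entering the mixing model are estimated from few composite
samples, so each is perturbed: deviate medians are drawn from a normal
distribution centred on the group median with the Qn robust scale,
truncated to the observed [min, max], using Latin hypercube stratification
(one draw per equal-probability stratum per tracer, strata shuffled
independently).  Each joint deviate row defines a mixing problem whose
solution is retained when its goodness of fit exceeds a threshold; sampling
continues until the requested number of viable solutions is reached.

Accepted proportions are binned over [0, 1] into relative frequencies F_i
with midvalues v_i; the frequency-weighted average median contribution is
R = sum_i v_i F_i.  Per-signature results are combined across the set of
selected signatures with weights alpha_k = mean accepted GOF x overall
classification %, and subcatchment results averaged to a catchment summary.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import truncnorm

from .data_model import SedimentSummary, SourceSummary, ValidationError
from .robust import qn_scale  # noqa: F401  (re-exported: Qn is this module's scale)
from .signature_selection import CompositeSignature
from . import unmixing

logger = logging.getLogger(__name__)


class MonteCarloError(RuntimeError):
    """No viable solution found within the draw budget."""


@dataclass(frozen=True)
class MonteCarloConfig:
    """Monte Carlo settings.

    ``n_accept`` viable solutions are collected (paper-scale default 5000);
    a solution is viable when GOF > ``gof_threshold``.  ``n_bins`` intervals
    over [0, 1] discretise the posterior.  ``max_draws`` caps total draws
    (default 100 x n_accept).
    """

    n_accept: int = 5000
    gof_threshold: float = 0.85
    n_bins: int = 100
    max_draws: int | None = None
    seed: int | None = None

    def __post_init__(self):
        if not (0.0 <= self.gof_threshold < 1.0):
            raise ValidationError("gof_threshold must be in [0, 1)")
        if self.n_accept < 1:
            raise ValidationError("n_accept must be >= 1")
        if self.n_bins < 2:
            raise ValidationError("n_bins must be >= 2")

    @property
    def draw_budget(self) -> int:
        return self.max_draws if self.max_draws is not None else 100 * self.n_accept


@dataclass(frozen=True)
class PosteriorDistribution:
    """Binned relative frequencies of accepted proportions for one source."""

    category: str
    bin_mid: np.ndarray
    frequency: np.ndarray
    r_weighted_mean: float
    full_range: tuple

    def __post_init__(self):
        object.__setattr__(self, "bin_mid", np.asarray(self.bin_mid, dtype=float))
        object.__setattr__(self, "frequency", np.asarray(self.frequency, dtype=float))
        if abs(self.frequency.sum() - 1.0) > 1e-9:
            raise ValidationError("relative frequencies must sum to 1")
        if not (0.0 <= self.r_weighted_mean <= 1.0):
            raise ValidationError("R must lie in [0, 1]")
        lo, hi = self.full_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValidationError("full range must lie within [0, 1]")


def weighted_mean_R(dist: PosteriorDistribution) -> float:
    """Frequency-weighted average median contribution R = sum_i v_i F_i."""
    if abs(dist.frequency.sum() - 1.0) > 1e-9:
        raise ValidationError("frequencies are not normalised")
    return float(dist.bin_mid @ dist.frequency)


@dataclass(frozen=True)
class MonteCarloResult:
    """Accepted-solution summary for one composite signature."""

    categories: tuple
    posteriors: Mapping[str, PosteriorDistribution]
    mean_gof: float
    accepted_p: np.ndarray
    accepted_gof: np.ndarray
    n_drawn: int


def sample_deviates(
    summary: SourceSummary | SedimentSummary,
    n_draws: int,
    rng,
    tracers: Sequence[str] | None = None,
) -> np.ndarray:
    """Latin-hypercube deviate medians, one row per draw.

    Per tracer: Normal(median, Qn) truncated to the observed [min, max];
    the probability axis is split into ``n_draws`` equal strata, one draw
    per stratum, with stratum order shuffled independently per tracer.
    A tracer with Qn = 0 yields a constant column (logged).
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    tracers = tuple(tracers) if tracers is not None else summary.tracers
    out = np.empty((n_draws, len(tracers)))
    for j, t in enumerate(tracers):
        med, scale = summary.median[t], summary.qn[t]
        if scale == 0.0:
            logger.debug("tracer %r: Qn = 0, degenerate deviates", t)
            out[:, j] = med
            continue
        strata = rng.permutation(n_draws)
        u = (strata + rng.uniform(size=n_draws)) / n_draws
        a = (summary.vmin[t] - med) / scale
        b = (summary.vmax[t] - med) / scale
        out[:, j] = truncnorm.ppf(u, a, b, loc=med, scale=scale)
    return out


def run_monte_carlo(
    signature: CompositeSignature,
    source_summaries: Sequence[SourceSummary],
    sediment_summary: SedimentSummary,
    cfg: MonteCarloConfig,
    literal: bool = False,
    perturb_sediment: bool = True,
    solver_starts: str = "full",
) -> MonteCarloResult:
    """Collect viable mixing-model solutions under joint LHS perturbation.

    Each iteration perturbs all source and sediment medians simultaneously
    (one LHS row per entity), solves the weighted mixing model on the
    signature's tracers, and accepts the solution when GOF > threshold.
    Stops at ``cfg.n_accept`` accepted solutions or when the draw budget is
    exhausted; errors if nothing is accepted at all.
    """
    tracers = signature.tracers
    for summ in list(source_summaries) + [sediment_summary]:
        missing = [t for t in tracers if t not in summ.tracers]
        if missing:
            raise ValidationError(f"summary lacks signature tracers {missing}")

    base = unmixing.problem_from_summaries(
        tracers, source_summaries, sediment_summary, signature.tdw
    )
    rng = np.random.default_rng(cfg.seed)
    m = len(base.categories)
    accepted_p: list = []
    accepted_gof: list = []
    drawn = 0
    best_gof = -np.inf
    while len(accepted_p) < cfg.n_accept and drawn < cfg.draw_budget:
        block = min(max(cfg.n_accept - len(accepted_p), 64), cfg.draw_budget - drawn)
        src_dev = [sample_deviates(s, block, rng, tracers) for s in source_summaries]
        if perturb_sediment:
            sed_dev = sample_deviates(sediment_summary, block, rng, tracers)
        else:
            sed_dev = np.tile(base.c, (block, 1))
        for row in range(block):
            drawn += 1
            c = sed_dev[row]
            if np.any(c == 0.0):
                logger.debug("draw with zero sediment deviate skipped")
                continue
            s = np.stack([d[row] for d in src_dev])
            problem = unmixing.MixingProblem(
                tracers=tracers,
                categories=base.categories,
                c=c,
                s=s,
                sv=base.sv,
                w=base.w,
            )
            sol = unmixing.solve(problem, literal=literal, starts=solver_starts)
            best_gof = max(best_gof, sol.gof)
            if sol.gof > cfg.gof_threshold:
                accepted_p.append(sol.p)
                accepted_gof.append(sol.gof)
                if len(accepted_p) >= cfg.n_accept:
                    break

    if not accepted_p:
        raise MonteCarloError(
            f"no viable solution in {drawn} draws "
            f"(best GOF {best_gof:.4f} <= threshold {cfg.gof_threshold})"
        )
    if len(accepted_p) < cfg.n_accept:
        logger.warning(
            "draw budget exhausted: %d of %d viable solutions collected",
            len(accepted_p),
            cfg.n_accept,
        )
    P = np.vstack(accepted_p)
    G = np.asarray(accepted_gof)
    posteriors = {}
    edges = np.linspace(0.0, 1.0, cfg.n_bins + 1)
    mids = 0.5 * (edges[:-1] + edges[1:])
    for k, cat in enumerate(base.categories):
        counts, _ = np.histogram(P[:, k], bins=edges)
        freq = counts / counts.sum()
        dist = PosteriorDistribution(
            category=cat,
            bin_mid=mids,
            frequency=freq,
            r_weighted_mean=float(mids @ freq),
            full_range=(float(P[:, k].min()), float(P[:, k].max())),
        )
        posteriors[cat] = dist
    return MonteCarloResult(
        categories=base.categories,
        posteriors=posteriors,
        mean_gof=float(G.mean()),
        accepted_p=P,
        accepted_gof=G,
        n_drawn=drawn,
    )


def combine_signatures(results: Sequence) -> dict:
    """Combine per-signature R values across the signature set.

    ``results`` is a sequence of ``(R_by_category, mean_gof,
    overall_classification_pct)`` tuples.  Weights are
    alpha_k = mean_gof_k x overall_classification_pct_k; a missing factor is
    treated as neutral (equal-weight fallback when neither is available).
    Returns category -> combined proportion rounded to 2 decimals.
    """
    results = list(results)
    if not results:
        raise ValidationError("combine_signatures needs >= 1 signature result")
    categories = list(results[0][0].keys())
    for r_map, _g, _c in results:
        if set(r_map.keys()) != set(categories):
            raise ValidationError("signature results disagree on categories")
    alphas = []
    for _r, g, c in results:
        alpha = (g if g is not None else 1.0) * (c if c is not None else 1.0)
        if alpha <= 0:
            raise ValidationError("non-positive combination weight")
        alphas.append(alpha)
    total = sum(alphas)
    return {
        cat: round(sum(a * r_map[cat] for a, (r_map, _g, _c) in zip(alphas, results)) / total, 2)
        for cat in categories
    }


def catchment_summary(per_subcatchment: Mapping[str, Mapping[str, float]]) -> dict:
    """Unweighted mean of combined proportions across subcatchments,
    per category, reported as a percentage rounded to the nearest point."""
    if not per_subcatchment:
        raise ValidationError("catchment summary needs >= 1 subcatchment")
    subs = list(per_subcatchment.values())
    categories = list(subs[0].keys())
    return {
        cat: round(100.0 * float(np.mean([s[cat] for s in subs])))
        for cat in categories
    }
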