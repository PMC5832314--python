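"""Weighted mass-balance unmixing of sediment tracer signatures.

Given median tracer concentrations C_i of the channel bed sediment and S_si
of m source categories, the model finds the proportion vector P on the
simplex minimising the sum of squared weighted relative errors

    sum_i  W_i * SVbar_i(P) * ((C_i - sum_s P_s S_si) / C_i)^2

where W_i is the tracer discriminatory weighting and SVbar_i(P) the
proportion-weighted mean of the within-source variability weightings SV_si
(the inverse coefficient of variation of tracer i within source s).  This
default form conserves mass in the predicted mixture; the variant in which
SV_si multiplies S_si inside the predicted concentration is available as
``literal=True``.

Goodness of fit is a separate, unweighted criterion:
GOF = 1 - mean_i |C_i - Chat_i| / |C_i| (clamped below at zero).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize

from .data_model import SedimentSummary, SourceSummary, ValidationError

logger = logging.getLogger(__name__)

_SIMPLEX_TOL = 1e-9


@dataclass(frozen=True)
class MixingProblem:
    """One instance of the mixing model.

    ``c``: sediment medians (n,); ``s``: source medians (m, n);
    ``sv``: within-source variability weights (m, n); ``w``: tracer
    discriminatory weights (n,), each >= 1.
    """

    tracers: tuple
    categories: tuple
    c: np.ndarray
    s: np.ndarray
    sv: np.ndarray
    w: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.c, dtype=float)
        s = np.asarray(self.s, dtype=float)
        sv = np.asarray(self.sv, dtype=float)
        w = np.asarray(self.w, dtype=float)
        for name, arr in (("c", c), ("s", s), ("sv", sv), ("w", w)):
            object.__setattr__(self, name, arr)
        n, m = len(self.tracers), len(self.categories)
        if m < 2:
            raise ValidationError("mixing model needs >= 2 source categories")
        if n < 1:
            raise ValidationError("mixing model needs >= 1 tracer")
        if c.shape != (n,) or s.shape != (m, n) or sv.shape != (m, n) or w.shape != (n,):
            raise ValidationError("inconsistent mixing-problem dimensions")
        if np.any(c == 0.0):
            bad = [self.tracers[i] for i in np.flatnonzero(c == 0.0)]
            raise ValidationError(
                f"sediment median is zero for {bad}; exclude these tracers from "
                "the relative-error objective"
            )
        if np.any(w < 1.0 - 1e-9):
            raise ValidationError("tracer discriminatory weights must be >= 1")
        if np.any(sv <= 0) or not np.all(np.isfinite(sv)):
            raise ValidationError("SV weights must be positive and finite")


@dataclass(frozen=True)
class SourceProportions:
    """Optimised source contributions for one mixing problem."""

    categories: tuple
    p: np.ndarray
    objective_value: float
    gof: float
    degenerate: bool = False

    def __post_init__(self):
        p = np.asarray(self.p, dtype=float)
        object.__setattr__(self, "p", p)
        if np.any(p < -_SIMPLEX_TOL) or np.any(p > 1 + _SIMPLEX_TOL):
            raise ValidationError("proportions outside [0, 1]")
        if abs(p.sum() - 1.0) > _SIMPLEX_TOL:
            raise ValidationError("proportions must sum to 1")
        if self.objective_value < 0:
            raise ValidationError("objective value must be >= 0")

    def as_dict(self) -> dict:
        return {cat: float(v) for cat, v in zip(self.categories, self.p)}


def _check_simplex(p: np.ndarray, m: int):
    p = np.asarray(p, dtype=float)
    if p.shape != (m,):
        raise ValidationError("proportion vector has wrong length")
    if np.any(p < -1e-9) or abs(p.sum() - 1.0) > 1e-6:
        raise ValidationError("proportion vector must lie on the simplex")
    return p


def objective(problem: MixingProblem, p, literal: bool = False) -> float:
    """Weighted sum of squared relative errors at proportions ``p``."""
    p = _check_simplex(p, len(problem.categories))
    if literal:
        chat = p @ (problem.s * problem.sv)
        svbar = 1.0
    else:
        chat = p @ problem.s
        svbar = p @ problem.sv
    rel = (problem.c - chat) / problem.c
    return float(np.sum(problem.w * svbar * rel**2))


def gof(problem: MixingProblem, p) -> float:
    """Goodness of fit: 1 minus the absolute mean relative error between
    measured and mixture-predicted sediment tracer values (unweighted),
    clamped below at 0."""
    p = _check_simplex(p, len(problem.categories))
    chat = p @ problem.s
    amre = float(np.mean(np.abs(problem.c - chat) / np.abs(problem.c)))
    return max(1.0 - amre, 0.0)


def _duplicate_categories(problem: MixingProblem) -> bool:
    s = problem.s
    for i in range(s.shape[0]):
        for j in range(i + 1, s.shape[0]):
            scale = np.maximum(np.abs(s[i]), np.abs(s[j]))
            scale[scale == 0] = 1.0
            if np.all(np.abs(s[i] - s[j]) / scale < 1e-9):
                return True
    return False


def solve(
    problem: MixingProblem,
    literal: bool = False,
    starts: str = "full",
) -> SourceProportions:
    """Minimise the mixing-model objective over the probability simplex.

    Deterministic: sequential least squares from each simplex vertex plus
    the centroid (``starts="full"``), or from the centroid only
    (``starts="centroid"``, cheaper inside Monte Carlo loops); the best
    local solution is kept.  Near-identical source categories make the
    optimum non-unique; the result is then flagged ``degenerate``.
    """
    m = len(problem.categories)
    x0s = [np.full(m, 1.0 / m)]
    if starts == "full":
        x0s = [np.eye(m)[k] for k in range(m)] + x0s
    elif starts != "centroid":
        raise ValueError(f"unknown starts mode {starts!r}")

    def raw_fun(p):
        # optimizer may wander slightly off the simplex; evaluate as-is
        if literal:
            chat = p @ (problem.s * problem.sv)
            svbar = 1.0
        else:
            chat = p @ problem.s
            svbar = p @ problem.sv
        rel = (problem.c - chat) / problem.c
        return float(np.sum(problem.w * svbar * rel**2))

    constraints = {"type": "eq", "fun": lambda p: p.sum() - 1.0}
    bounds = [(0.0, 1.0)] * m
    best = None
    for x0 in x0s:
        res = minimize(
            raw_fun,
            x0,
            method="SLSQP",
            bounds=bounds,
            constraints=constraints,
            options={"maxiter": 300, "ftol": 1e-14},
        )
        if not np.all(np.isfinite(res.x)):
            continue
        p = np.clip(res.x, 0.0, 1.0)
        total = p.sum()
        if total <= 0:
            continue
        p = p / total
        value = raw_fun(p)
        if best is None or value < best[1]:
            best = (p, value)
    if best is None:
        raise ValidationError("unmixing failed to converge from every start")
    p, value = best
    degenerate = _duplicate_categories(problem)
    if degenerate:
        logger.warning("near-identical source categories: solution is non-unique")
    return SourceProportions(
        categories=problem.categories,
        p=p,
        objective_value=value,
        gof=gof(problem, p),
        degenerate=degenerate,
    )


def problem_from_summaries(
    tracers: Sequence[str],
    source_summaries: Sequence[SourceSummary],
    sediment_summary: SedimentSummary,
    tracer_weights=None,
) -> MixingProblem:
    """Assemble a MixingProblem from group summaries.

    SV_si is the inverse CV of tracer i in source s; where the CV is
    undefined (zero mean or single sample) or zero, a neutral weight of 1 is
    substituted (logged) so the tracer is neither inflated nor discarded.
    ``tracer_weights`` maps tracer -> W_i (defaults to 1).
    """
    tracers = tuple(tracers)
    categories = tuple(s.category for s in source_summaries)
    if len(set(categories)) != len(categories):
        raise ValidationError("duplicate source categories in summaries")
    c = np.array([sediment_summary.median[t] for t in tracers], dtype=float)
    s = np.array(
        [[summ.median[t] for t in tracers] for summ in source_summaries], dtype=float
    )
    sv = np.empty_like(s)
    for i, summ in enumerate(source_summaries):
        for j, t in enumerate(tracers):
            cv = summ.cv.get(t, float("nan"))
            if not np.isfinite(cv) or cv <= 0:
                logger.warning(
                    "tracer %r in category %r: CV undefined or zero; "
                    "neutral SV weight of 1 used",
                    t,
                    summ.category,
                )
                sv[i, j] = 1.0
            else:
                sv[i, j] = 1.0 / cv
    if tracer_weights is None:
        w = np.ones(len(tracers))
    else:
        w = np.array([tracer_weights[t] for t in tracers], dtype=float)
    return MixingProblem(
        tracers=tracers, categories=categories, c=c, s=s, sv=sv, w=w
    )
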