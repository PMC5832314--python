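"""Composite fingerprint selection and tracer discriminatory weightings.

Three routes build a composite signature (a tracer subset that jointly
discriminates the source categories):

* GA-DFA — a genetic algorithm searches tracer subsets, minimising the
  Wilks' lambda of a linear discriminant fit subject to each member tracer
  satisfying a stepwise-entry partial-F test;
* KW-H — tracers are ranked by their Kruskal-Wallis H statistic across the
  source categories and the signature grown from the top of the ranking;
* PCA — tracers are ranked by their largest absolute loading on the leading
  principal components of the standardised source matrix, then grown the
  same way.

Every signature reports, per tracer, the percentage of source samples a
single-tracer discriminant classifies correctly, and the tracer
discriminatory weighting (TDW): the ratio of that percentage to the weakest
member's, so the weakest tracer carries exactly 1.00.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .data_model import SOURCE, SampleRecord, ValidationError

logger = logging.getLogger(__name__)

GA_DFA = "GA-DFA"
KW_H = "KW-H"
PCA_METHOD = "PCA"

#: ridge added to scatter matrices when singular
_RIDGE = 1e-8


@dataclass(frozen=True)
class CompositeSignature:
    """A selected tracer subset with its discriminatory statistics.

    ``classification_pct`` maps each tracer to the % of source samples
    correctly classified by that tracer alone; ``tdw`` to its discriminatory
    weighting (>= 1, weakest tracer exactly 1.0);
    ``overall_classification_pct`` is the % classified by the full subset.
    """

    method: str
    tracers: tuple
    classification_pct: Mapping[str, float]
    tdw: Mapping[str, float]
    overall_classification_pct: float

    def __post_init__(self):
        if not self.tracers:
            raise ValidationError("signature needs at least one tracer")
        weights = [self.tdw[t] for t in self.tracers]
        if abs(min(weights) - 1.0) > 1e-12:
            raise ValidationError("weakest tracer must carry TDW exactly 1.0")
        if any(w < 1.0 - 1e-12 for w in weights):
            raise ValidationError("TDW weights must be >= 1")


# ---------------------------------------------------------------------------
# discriminant machinery


def _design_matrix(sources: Sequence[SampleRecord], tracers: Sequence[str]):
    if not tracers:
        raise ValidationError("tracer list must be non-empty")
    if any(r.role != SOURCE for r in sources):
        raise ValidationError("classification requires source records only")
    try:
        X = np.array([[r.values[t] for t in tracers] for r in sources], dtype=float)
    except KeyError as e:
        raise ValidationError(f"tracer {e.args[0]!r} absent from a record") from None
    y = np.array([r.category for r in sources])
    cats, counts = np.unique(y, return_counts=True)
    if len(cats) < 2:
        raise ValidationError("need >= 2 source categories")
    if counts.min() < 2:
        raise ValidationError("each category needs >= 2 samples")
    return X, y


def classify_rate(
    sources: Sequence[SampleRecord],
    tracers: Sequence[str],
    method: str = "resubstitution",
) -> float:
    """% of source samples a linear discriminant assigns to their true category.

    ``method="resubstitution"`` scores the training set itself (the
    convention behind reported composite-signature percentages);
    ``method="loo"`` uses leave-one-out cross-validation instead.
    """
    X, y = _design_matrix(sources, tracers)
    if method == "resubstitution":
        clf = _fit_lda(X, y)
        correct = np.mean(clf.predict(X) == y)
    elif method == "loo":
        hits = []
        for i in range(len(y)):
            mask = np.ones(len(y), dtype=bool)
            mask[i] = False
            if len(np.unique(y[mask])) < 2:
                raise ValidationError("leave-one-out removes a whole category")
            clf = _fit_lda(X[mask], y[mask])
            hits.append(clf.predict(X[i : i + 1])[0] == y[i])
        correct = np.mean(hits)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(100.0 * correct)


def _fit_lda(X, y):
    W, _T = _scatter_matrices(X, y)
    if X.shape[1] > 1 and np.linalg.matrix_rank(W) < X.shape[1]:
        logger.warning("singular within-group covariance; discriminant fit regularised")
    clf = LinearDiscriminantAnalysis(solver="svd")
    clf.fit(X, y)
    return clf


def _scatter_matrices(X, y):
    Xc = X - X.mean(axis=0)
    T = Xc.T @ Xc
    W = np.zeros_like(T)
    for cat in np.unique(y):
        Xg = X[y == cat]
        Xg = Xg - Xg.mean(axis=0)
        W += Xg.T @ Xg
    return W, T


def wilks_lambda(X, y) -> float:
    """Wilks' lambda det(W)/det(T) of the group separation; in (0, 1],
    smaller = better separation.  Singular scatter matrices are ridged."""
    W, T = _scatter_matrices(X, y)
    sW, ldW = np.linalg.slogdet(W)
    sT, ldT = np.linalg.slogdet(T)
    if sW <= 0 or sT <= 0:
        scale = np.trace(T) / max(X.shape[1], 1) or 1.0
        eye = _RIDGE * scale * np.eye(X.shape[1])
        sW, ldW = np.linalg.slogdet(W + eye)
        sT, ldT = np.linalg.slogdet(T + eye)
        if sW <= 0 or sT <= 0:
            raise ValidationError("degenerate scatter matrices")
    return float(np.exp(ldW - ldT))


def _entry_pvalue(lam_reduced: float, lam_full: float, n: int, g: int, q: int) -> float:
    """p-value of the stepwise partial-F test for the q-th tracer entering a
    discriminant model that already holds q-1 tracers."""
    df1 = g - 1
    df2 = n - g - q + 1
    if df2 < 1:
        return 1.0
    if lam_full <= 0:
        return 0.0
    F = (df2 / df1) * (lam_reduced / lam_full - 1.0)
    return float(stats.f.sf(max(F, 0.0), df1, df2))


def _subset_valid(X, y, subset: tuple, p_entry: float) -> tuple:
    """(n_failing, lambda) for a tracer-index subset: every member must pass
    the stepwise-entry F-test at p <= p_entry (valid iff n_failing == 0)."""
    n = len(y)
    g = len(np.unique(y))
    q = len(subset)
    lam_full = wilks_lambda(X[:, subset], y)
    n_failing = 0
    for j in subset:
        reduced = tuple(i for i in subset if i != j)
        lam_red = 1.0 if not reduced else wilks_lambda(X[:, reduced], y)
        if _entry_pvalue(lam_red, lam_full, n, g, q) > p_entry:
            n_failing += 1
    return n_failing, lam_full


# ---------------------------------------------------------------------------
# TDW


def tdw(classification_pcts: Sequence[float]) -> list:
    """Tracer discriminatory weightings: each percentage divided by the
    smallest, rounded to 2 decimals (weakest tracer exactly 1.00)."""
    pcts = list(classification_pcts)
    if not pcts:
        raise ValidationError("tdw requires at least one percentage")
    for p in pcts:
        if not (0.0 < p <= 100.0):
            raise ValidationError(f"classification percentage {p} outside (0, 100]")
    weakest = min(pcts)
    return [round(p / weakest, 2) for p in pcts]


def _finalize(sources, tracers: Sequence[str], method: str) -> CompositeSignature:
    tracers = tuple(tracers)
    pcts = {t: classify_rate(sources, [t]) for t in tracers}
    weights = tdw([pcts[t] for t in tracers])
    return CompositeSignature(
        method=method,
        tracers=tracers,
        classification_pct=pcts,
        tdw=dict(zip(tracers, weights)),
        overall_classification_pct=classify_rate(sources, tracers),
    )


# ---------------------------------------------------------------------------
# GA-DFA


def _rank_key(entry):
    """Ranking for candidate subsets: classification % desc, lambda asc,
    smaller subset, then lexicographic tracer order (deterministic ties)."""
    subset, lam, pct = entry
    return (-pct, lam, len(subset), subset)


def select_ga_dfa(
    sources: Sequence[SampleRecord],
    candidate_tracers: Sequence[str],
    n_repeats: int = 200,
    p_entry: float = 0.05,
    seed: int | None = None,
    population: int = 50,
    generations: int = 40,
    crossover_rate: float = 0.7,
    mutation_rate: float = 0.02,
    elitism: int = 2,
    n_signatures: int = 3,
) -> list:
    """Genetic-algorithm subset search over candidate tracers.

    Each of ``n_repeats`` restarts evolves binary chromosomes (one bit per
    candidate) minimising the Wilks' lambda of the discriminant fit, subject
    to every member tracer's stepwise-entry F-test satisfying p <= p_entry.
    Returns up to ``n_signatures`` distinct top signatures ranked by overall
    classification % then lambda.
    """
    candidates = tuple(candidate_tracers)
    if not candidates:
        raise ValidationError("no candidate tracers")
    if n_repeats < 1:
        raise ValidationError("n_repeats must be >= 1")
    X, y = _design_matrix(sources, candidates)
    n_bits = len(candidates)
    rng = np.random.default_rng(seed)

    cache: dict = {}

    def evaluate(subset: tuple):
        if subset not in cache:
            n_failing, lam = _subset_valid(X, y, subset, p_entry)
            valid = n_failing == 0
            pct = classify_rate(sources, [candidates[i] for i in subset]) if valid else -1.0
            cache[subset] = (valid, lam, pct, n_failing)
        return cache[subset]

    def fitness(subset: tuple) -> float:
        valid, lam, _pct, n_failing = evaluate(subset)
        # invalid subsets rank behind all valid ones, graded by how many
        # members fail the entry test so the search can descend to validity
        return lam if valid else 2.0 + n_failing + lam

    def repair(bits):
        if not bits.any():
            bits[rng.integers(n_bits)] = True
        return bits

    if n_bits <= 4:
        # exhaustive evaluation is cheaper than evolving a population
        for subset in itertools.chain.from_iterable(
            itertools.combinations(range(n_bits), r) for r in range(1, n_bits + 1)
        ):
            evaluate(subset)
    else:
        # initial chromosomes biased sparse: composite signatures are small
        p_init = min(0.5, 5.0 / n_bits)
        for _ in range(n_repeats):
            pop = rng.random((population, n_bits)) < p_init
            pop = np.array([repair(b) for b in pop])
            for _gen in range(generations):
                subsets = [tuple(np.flatnonzero(b)) for b in pop]
                fits = np.array([fitness(s) for s in subsets])
                order = np.argsort(fits, kind="stable")
                elite = pop[order[:elitism]].copy()
                children = [*elite]
                while len(children) < population:
                    # tournament selection, size 3
                    a = order[int(np.min(rng.integers(population, size=3)))]
                    b = order[int(np.min(rng.integers(population, size=3)))]
                    pa, pb = pop[a].copy(), pop[b].copy()
                    if rng.random() < crossover_rate:
                        mask = rng.random(n_bits) < 0.5
                        pa = np.where(mask, pa, pb)
                    pa ^= rng.random(n_bits) < mutation_rate
                    children.append(repair(pa))
                pop = np.array(children[:population])
            for b in pop:
                evaluate(tuple(np.flatnonzero(b)))

    valid_entries = [
        (subset, lam, pct) for subset, (ok, lam, pct, _nf) in cache.items() if ok
    ]
    if not valid_entries:
        degenerate = sorted(candidates)
        raise ValidationError(
            f"no tracer subset satisfied the stepwise entry test; candidates: {degenerate}"
        )
    valid_entries.sort(key=_rank_key)
    signatures = []
    for subset, _lam, _pct in valid_entries[:n_signatures]:
        signatures.append(_finalize(sources, [candidates[i] for i in subset], GA_DFA))
    return signatures


# ---------------------------------------------------------------------------
# KW-H and PCA rankings


def kruskal_h(sources: Sequence[SampleRecord], tracer: str) -> tuple:
    """(H, p) of the Kruskal-Wallis test for one tracer across categories.
    A tracer constant across all samples scores H=0, p=1."""
    groups: dict = {}
    for r in sources:
        groups.setdefault(r.category, []).append(r.values[tracer])
    try:
        with np.errstate(invalid="ignore"):
            h, p = stats.kruskal(*groups.values())
    except ValueError:  # all values identical
        return 0.0, 1.0
    if not (np.isfinite(h) and np.isfinite(p)):  # degenerate (constant) tracer
        return 0.0, 1.0
    return float(h), float(p)


def _grow_signature(sources, ranking: Sequence[str], min_size: int = 3):
    """Grow a signature from the top of a tracer ranking until the
    discriminant classification % stops increasing (minimum size 3,
    capped at the ranking length)."""
    ranking = list(ranking)
    size = min(min_size, len(ranking))
    chosen = ranking[:size]
    best = classify_rate(sources, chosen)
    for t in ranking[size:]:
        pct = classify_rate(sources, chosen + [t])
        if pct > best:
            chosen.append(t)
            best = pct
        else:
            break
    return chosen


def select_kw_h(
    sources: Sequence[SampleRecord],
    candidate_tracers: Sequence[str],
    alpha: float = 0.05,
    min_size: int = 3,
) -> CompositeSignature:
    """Kruskal-Wallis route: rank tracers by H among those significant at
    ``alpha``, then grow the signature from the top of the ranking."""
    scored = []
    for t in candidate_tracers:
        h, p = kruskal_h(sources, t)
        if p < alpha:
            scored.append((t, h))
    if not scored:
        raise ValidationError(f"no tracer significant at alpha={alpha}")
    scored.sort(key=lambda e: (-e[1], e[0]))
    ranking = [t for t, _h in scored]
    return _finalize(sources, _grow_signature(sources, ranking, min_size), KW_H)


def pca_loadings(sources: Sequence[SampleRecord], candidate_tracers, n_components=2):
    """Loadings (unit eigenvector entries) of the first components of the
    standardised source tracer matrix.  Zero-variance tracers are excluded
    (logged).  Returns (tracers_used, loadings[k, j], explained_ratio)."""
    candidates = tuple(candidate_tracers)
    X = np.array([[r.values[t] for t in candidates] for r in sources], dtype=float)
    if X.shape[0] < 3:
        raise ValidationError("PCA needs >= 3 samples")
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        dropped = [candidates[i] for i in np.flatnonzero(~keep)]
        logger.warning("PCA: dropping zero-variance tracers %s", dropped)
    used = tuple(candidates[i] for i in np.flatnonzero(keep))
    if len(used) < n_components:
        raise ValidationError("fewer (non-degenerate) tracers than components")
    Z = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    pca = PCA(n_components=n_components)
    pca.fit(Z)
    return used, pca.components_, pca.explained_variance_ratio_


def select_pca(
    sources: Sequence[SampleRecord],
    candidate_tracers: Sequence[str],
    n_components: int = 2,
    min_size: int = 3,
) -> CompositeSignature:
    """PCA route: rank tracers by their maximum absolute loading across the
    first ``n_components`` principal components, then grow the signature."""
    candidates = tuple(candidate_tracers)
    if len(candidates) < n_components:
        raise ValidationError("fewer candidate tracers than components")
    used, components, _ratio = pca_loadings(sources, candidates, n_components)
    score = np.max(np.abs(components), axis=0)
    order = sorted(range(len(used)), key=lambda j: (-score[j], used[j]))
    ranking = [used[j] for j in order]
    return _finalize(sources, _grow_signature(sources, ranking, min_size), PCA_METHOD)
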