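import itertools

import numpy as np
import pytest

import omtrace as ot
from omtrace.data_model import ValidationError
from omtrace.signature_selection import (
    _design_matrix,
    _rank_key,
    _subset_valid,
    kruskal_h,
    pca_loadings,
    select_ga_dfa,
    select_kw_h,
    select_pca,
    tdw,
    wilks_lambda,
)

CATS = list(ot.DEFAULT_CATEGORIES)


def records_from_groups(groups, tracers):
    """groups: {category: 2D array (n_samples, n_tracers)}."""
    out = []
    for cat, X in groups.items():
        for i, row in enumerate(np.atleast_2d(X)):
            out.append(
                ot.SampleRecord(
                    sample_id=f"{cat}-{i}",
                    role="source",
                    category=cat,
                    subcatchment="sub",
                    values=dict(zip(tracers, row)),
                )
            )
    return out


class TestClassifyRate:
    def test_disjoint_supports_classify_perfectly(self):
        groups = {
            CATS[0]: [[0.0], [0.1], [0.2]],
            CATS[1]: [[10.0], [10.1], [10.2]],
        }
        records = records_from_groups(groups, ["x"])
        assert ot.classify_rate(records, ["x"]) == 100.0

    def test_identical_distributions_classify_at_chance(self):
        # two categories drawn from the same distribution: expect ~50%
        # (large n keeps resubstitution optimism small)
        rng = np.random.default_rng(0)
        rates = []
        for _ in range(200):
            groups = {
                CATS[0]: rng.normal(size=(100, 1)),
                CATS[1]: rng.normal(size=(100, 1)),
            }
            rates.append(ot.classify_rate(records_from_groups(groups, ["x"]), ["x"]))
        assert 45.0 <= np.mean(rates) <= 55.0

    def test_full_separation_on_five_tracers(self, sources):
        # well-separated synthetic categories: composite of 5 tracers
        # classifies every source sample correctly
        tracers = ["d13C", "d15N", "TOC_pct", "CH2", "ArOH"]
        assert ot.classify_rate(sources, tracers) == 100.0

    def test_loo_no_higher_than_resubstitution_here(self, sources):
        tracers = ["d13C", "d15N"]
        resub = ot.classify_rate(sources, tracers)
        loo = ot.classify_rate(sources, tracers, method="loo")
        assert loo <= resub

    def test_needs_two_samples_per_category(self):
        groups = {CATS[0]: [[0.0]], CATS[1]: [[1.0], [1.1]]}
        with pytest.raises(ValidationError):
            ot.classify_rate(records_from_groups(groups, ["x"]), ["x"])


class TestTdw:
    @pytest.mark.parametrize(
        "pcts,expected",
        [
            ([100, 88], [1.14, 1.00]),
            ([94, 88], [1.07, 1.00]),
            ([70, 70, 70], [1.00, 1.00, 1.00]),
        ],
    )
    def test_ratio_to_weakest(self, pcts, expected):
        assert tdw(pcts) == expected

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            tdw([])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            tdw([0.0, 50.0])


class TestKruskal:
    def test_hand_computed_h(self):
        # {1,2,3} vs {7,8,9}: ranks 1..6, no ties
        # H = 12/(N(N+1)) * sum R_g^2/n_g - 3(N+1) = 12/42*(12+75) - 21
        groups = {CATS[0]: [[1.0], [2.0], [3.0]], CATS[1]: [[7.0], [8.0], [9.0]]}
        records = records_from_groups(groups, ["x"])
        h, p = kruskal_h(records, "x")
        assert h == pytest.approx(12 / 42 * (36 / 3 + 225 / 3) - 21)

    def test_constant_tracer_scores_zero(self):
        groups = {CATS[0]: [[1.0], [1.0]], CATS[1]: [[1.0], [1.0]]}
        h, p = kruskal_h(records_from_groups(groups, ["x"]), "x")
        assert (h, p) == (0.0, 1.0)


class TestSelectKwH:
    def test_single_discriminating_tracer(self):
        rng = np.random.default_rng(1)
        groups = {}
        for k, cat in enumerate(CATS):
            X = np.column_stack(
                [10 * k + rng.normal(size=4), np.full(4, 7.0)]
            )
            groups[cat] = X
        records = records_from_groups(groups, ["good", "const"])
        sig = select_kw_h(records, ["good", "const"])
        assert sig.tracers == ("good",)
        assert sig.tdw["good"] == 1.0

    def test_no_significant_tracer_rejected(self):
        groups = {c: [[1.0], [1.0]] for c in CATS[:2]}
        with pytest.raises(ValidationError):
            select_kw_h(records_from_groups(groups, ["x"]), ["x"])

    def test_growth_never_hurts_classification(self, sources, panel):
        sig = select_kw_h(sources, panel.names)
        scored = sorted(
            ((t, kruskal_h(sources, t)[0]) for t in panel.names
             if kruskal_h(sources, t)[1] < 0.05),
            key=lambda e: (-e[1], e[0]),
        )
        ranking = [t for t, _ in scored]
        final = sig.overall_classification_pct
        for size in range(1, len(sig.tracers) + 1):
            assert final >= ot.classify_rate(sources, ranking[:size])


class TestSelectPca:
    def test_dominant_tracer_ranked_first(self):
        # "big" carries the dominant shared component of the standardised
        # matrix; the others are mostly independent noise
        rng = np.random.default_rng(2)
        n = 16
        struct = np.repeat([0.0, 5.0, 10.0, 15.0], 4) + rng.normal(0, 0.1, n)
        z = (struct - struct.mean()) / struct.std()
        n1 = 0.3 * z + rng.normal(size=n)
        n2 = 0.3 * z + rng.normal(size=n)
        groups = {}
        for k, cat in enumerate(CATS):
            idx = slice(4 * k, 4 * k + 4)
            groups[cat] = np.column_stack([struct[idx], n1[idx], n2[idx]])
        records = records_from_groups(groups, ["big", "n1", "n2"])
        sig = select_pca(records, ["big", "n1", "n2"], n_components=1)
        assert sig.tracers[0] == "big"

    def test_loadings_match_eigendecomposition(self, sources, panel):
        used, components, _ = pca_loadings(sources, panel.names, n_components=2)
        X = np.array([[r.values[t] for t in used] for r in sources])
        corr = np.corrcoef(X, rowvar=False)
        evals, evecs = np.linalg.eigh(corr)
        order = np.argsort(evals)[::-1]
        top = evecs[:, order[:2]].T
        # loadings agree up to sign per component
        for k in range(2):
            assert np.allclose(
                np.abs(components[k]), np.abs(top[k]), atol=1e-8
            )

    def test_rank2_matrix_fully_explained_by_two_components(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=(2, 16))
        X = np.column_stack([a, b, a + b, a - b, 2 * a + 0.5 * b])
        groups = {cat: X[4 * k : 4 * k + 4] for k, cat in enumerate(CATS)}
        tracers = [f"t{i}" for i in range(5)]
        records = records_from_groups(groups, tracers)
        _, _, ratio = pca_loadings(records, tracers, n_components=2)
        assert ratio.sum() == pytest.approx(1.0, abs=1e-9)

    def test_too_few_tracers_rejected(self, sources):
        with pytest.raises(ValidationError):
            select_pca(sources, ["d13C"], n_components=2)


def xor_like_sources(seed=4, n_per_cat=6):
    """Four categories on a 2x2 grid of (A, B): both tracers are needed to
    separate all four; C..F are pure noise."""
    rng = np.random.default_rng(seed)
    centers = {
        CATS[0]: (0.0, 0.0),
        CATS[1]: (0.0, 10.0),
        CATS[2]: (10.0, 0.0),
        CATS[3]: (10.0, 10.0),
    }
    tracers = ["A", "B", "C", "D", "E", "F"]
    groups = {}
    for cat, (cx, cy) in centers.items():
        ab = np.column_stack(
            [cx + rng.normal(0, 0.5, n_per_cat), cy + rng.normal(0, 0.5, n_per_cat)]
        )
        noise = rng.normal(size=(n_per_cat, 4))
        groups[cat] = np.column_stack([ab, noise])
    return records_from_groups(groups, tracers), tracers


class TestSelectGaDfa:
    def test_single_candidate(self, sources):
        sigs = select_ga_dfa(sources, ["d13C"], n_repeats=1, seed=0)
        assert len(sigs) == 1
        assert sigs[0].tracers == ("d13C",)
        assert sigs[0].tdw["d13C"] == 1.0

    def test_matches_exhaustive_oracle(self):
        records, tracers = xor_like_sources()
        X, y = _design_matrix(records, tracers)
        oracle = []
        for r in range(1, len(tracers) + 1):
            for subset in itertools.combinations(range(len(tracers)), r):
                n_failing, lam = _subset_valid(X, y, subset, 0.05)
                if n_failing == 0:
                    pct = ot.classify_rate(
                        records, [tracers[i] for i in subset]
                    )
                    oracle.append((subset, lam, pct))
        oracle.sort(key=_rank_key)
        best_subset = tuple(tracers[i] for i in oracle[0][0])

        sigs = select_ga_dfa(records, tracers, n_repeats=3, seed=7,
                             population=30, generations=15)
        assert sigs[0].tracers == best_subset
        assert sigs[0].overall_classification_pct == 100.0
        assert set(sigs[0].tracers) <= {"A", "B"}

    def test_three_signatures_are_distinct(self, sources, panel):
        sigs = select_ga_dfa(sources, panel.names, n_repeats=2, seed=1,
                             population=30, generations=10)
        assert len(sigs) == 3
        sets = [frozenset(s.tracers) for s in sigs]
        assert len(set(sets)) == 3

    def test_seed_reproducible(self, sources, panel):
        kwargs = dict(n_repeats=2, seed=42, population=24, generations=8)
        a = select_ga_dfa(sources, panel.names, **kwargs)
        b = select_ga_dfa(sources, panel.names, **kwargs)
        assert [s.tracers for s in a] == [s.tracers for s in b]

    def test_min_tdw_is_one_for_all_methods(self, sources, panel):
        sigs = select_ga_dfa(sources, panel.names, n_repeats=1, seed=5,
                             population=24, generations=8)
        sigs += [select_kw_h(sources, panel.names), select_pca(sources, panel.names)]
        for s in sigs:
            weights = [s.tdw[t] for t in s.tracers]
            assert min(weights) == 1.0
            assert all(w >= 1.0 for w in weights)


class TestWilksLambda:
    def test_bounds_and_separation_ordering(self):
        rng = np.random.default_rng(6)
        X_sep = np.vstack([rng.normal(0, 1, (8, 2)), rng.normal(8, 1, (8, 2))])
        X_mix = rng.normal(0, 1, (16, 2))
        y = np.array(["a"] * 8 + ["b"] * 8)
        lam_sep = wilks_lambda(X_sep, y)
        lam_mix = wilks_lambda(X_mix, y)
        assert 0 < lam_sep < lam_mix <= 1.0 + 1e-12
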