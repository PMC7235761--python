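"""ROC engine, splitting, model enumeration, scoring, and exhaustive search."""

import itertools

import numpy as np
import pandas as pd
import pytest

from bcap import (
    CqMatrix,
    NormalizedMatrix,
    RatioModel,
    SearchConfig,
    detection_filter,
    enumerate_ratio_models,
    evaluate_model,
    rank_candidates,
    roc_auc,
    score_ratio_model,
    search_best_model,
    split_train_test,
)


def auc_pair_oracle(scores, labels):
    """Explicit O(n^2) pair counting: concordant + half of ties."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = conc = 0.0
    for p in pos:
        for n in neg:
            total += 1
            conc += (p > n) + 0.5 * (p == n)
    return conc / total


class TestRocAuc:
    def test_hand_counted_example(self):
        res = roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert res.auc == pytest.approx(0.75)
        assert res.oriented_auc == pytest.approx(0.75)
        assert res.orientation == "high-score-positive"

    def test_perfect_separation(self):
        assert roc_auc([1, 2, 3, 10, 11], [0, 0, 0, 1, 1]).auc == 1.0

    def test_all_tied_scores_give_half(self):
        res = roc_auc([5.0] * 6, [0, 1, 0, 1, 0, 1])
        assert res.auc == pytest.approx(0.5)

    def test_inverted_marker_orientation(self):
        res = roc_auc([0.9, 0.8, 0.2, 0.1], [0, 0, 1, 1])
        assert res.auc < 0.5 and res.oriented_auc == pytest.approx(1 - res.auc)
        assert res.orientation == "low-score-positive"

    def test_matches_pair_counting_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(4, 40))
            scores = rng.choice([0.1, 0.25, 0.5, 0.7, 0.9], n)  # force ties
            labels = rng.integers(0, 2, n)
            if labels.sum() in (0, n):
                continue
            assert roc_auc(scores, labels).auc == pytest.approx(
                auc_pair_oracle(scores, labels), abs=1e-12
            )

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.normal(size=50)
        labels = rng.integers(0, 2, 50)
        labels[0], labels[1] = 0, 1
        a = roc_auc(scores, labels).auc
        for f in (np.exp, lambda s: s**3, lambda s: 10 + 2 * s):
            assert roc_auc(f(scores), labels).auc == pytest.approx(a, abs=1e-12)

    def test_single_class_is_error(self):
        with pytest.raises(ValueError, match="class"):
            roc_auc([1, 2, 3], [1, 1, 1])


class TestSplit:
    def test_cohort_sizes_match_rounding(self):
        ids = [f"s{i}" for i in range(753)]
        sp = split_train_test(ids, 0.66, seed=3)
        assert len(sp.train_ids) == 497 and len(sp.test_ids) == 256
        assert set(sp.train_ids) | set(sp.test_ids) == set(ids)
        assert not set(sp.train_ids) & set(sp.test_ids)

    def test_same_seed_reproduces_split(self):
        ids = [f"s{i}" for i in range(100)]
        a = split_train_test(ids, 0.66, seed=11)
        b = split_train_test(ids, 0.66, seed=11)
        assert a.train_ids == b.train_ids and a.test_ids == b.test_ids
        c = split_train_test(ids, 0.66, seed=12)
        assert c.train_ids != a.train_ids

    @pytest.mark.parametrize("fraction", [0.0, 1.0, 1.5])
    def test_degenerate_fraction_is_error(self, fraction):
        with pytest.raises(ValueError):
            split_train_test(["a", "b", "c"], fraction, seed=0)


class TestDetectionFilter:
    def make_cq(self):
        vals = np.full((3, 40), 30.0)
        vals[0, :4] = np.nan  # detected in exactly 90% (36/40)
        vals[2, :] = np.nan  # never detected
        return CqMatrix(
            pd.DataFrame(vals, index=["border", "full", "dead"],
                         columns=[f"s{j}" for j in range(40)])
        )

    def test_strict_threshold_excludes_exact_90pct(self):
        kept = detection_filter(self.make_cq(), [f"s{j}" for j in range(40)], 0.90)
        assert kept == ["full"]

    def test_empty_subset_is_error(self):
        with pytest.raises(ValueError):
            detection_filter(self.make_cq(), [], 0.9)


class TestEnumeration:
    def brute_force(self, ids):
        """Independent generator of the counting convention."""
        out = set()
        for a, b in itertools.combinations(ids, 2):
            out.add(((a,), (b,)))
        for trio in itertools.combinations(ids, 3):
            for s in trio:
                pair = tuple(sorted(x for x in trio if x != s))
                out.add((pair, (s,)))
        for num in itertools.combinations(ids, 2):
            for den in itertools.combinations([x for x in ids if x not in num], 2):
                out.add((tuple(sorted(num)), tuple(sorted(den))))
        return out

    def test_panel_of_20_gives_printed_total(self):
        models = enumerate_ratio_models([f"m{i:02d}" for i in range(20)])
        assert len(models) == 32_680
        by_size = {k: sum(1 for m in models if m.size == k) for k in (2, 3, 4)}
        assert by_size == {2: 190, 3: 3_420, 4: 29_070}

    @pytest.mark.parametrize("m", range(2, 9))
    def test_matches_brute_force_generator(self, m):
        ids = [f"m{i}" for i in range(m)]
        models = enumerate_ratio_models(ids)
        keys = {mod.canonical_key() for mod in models}
        assert len(keys) == len(models)  # canonical forms unique
        assert keys == self.brute_force(ids)

    def test_small_panels(self):
        assert len(enumerate_ratio_models(["a", "b"])) == 1
        assert len(enumerate_ratio_models(["a", "b", "c", "d"])) == 24
        assert enumerate_ratio_models(["a"]) == []

    def test_unordered_convention_folds_reciprocals(self):
        ids = [f"m{i}" for i in range(6)]
        models = enumerate_ratio_models(ids, unordered=True)
        n4 = sum(1 for m in models if m.size == 4)
        assert n4 == 3 * 15  # C(6,4) * 3 partitions

    def test_model_invariants(self):
        with pytest.raises(ValueError):
            RatioModel(("a", "b"), ("a",))  # overlap
        with pytest.raises(ValueError):
            RatioModel(("a", "b", "c"), ("d",))  # side too large
        m = RatioModel(("b", "a"), ("d", "c"))
        assert m.numerator == ("a", "b") and m.denominator == ("c", "d")


class TestScoring:
    def test_cancellation_and_arithmetic(self):
        vals = pd.DataFrame(
            {"s1": [1.0, 1.0, 1.0, 1.0], "s2": [2.0, 1.0, 0.5, 0.5]},
            index=["a", "b", "c", "d"],
        )
        model = RatioModel(("a", "b"), ("c", "d"))
        s = score_ratio_model(model, NormalizedMatrix(vals))
        assert s["s1"] == 0.0
        assert s["s2"] == 2.0  # log2 of linear ratio 4

    def test_missing_constituent_gives_missing_score(self):
        vals = pd.DataFrame({"s1": [1.0, np.nan], "s2": [1.0, 2.0]}, index=["a", "b"])
        s = score_ratio_model(RatioModel(("a",), ("b",)), NormalizedMatrix(vals))
        assert np.isnan(s["s1"]) and s["s2"] == -1.0

    def test_absent_constituent_is_error(self):
        vals = pd.DataFrame({"s1": [1.0]}, index=["a"])
        with pytest.raises(ValueError, match="ghost"):
            score_ratio_model(RatioModel(("a",), ("ghost",)), NormalizedMatrix(vals))

    def test_balanced_models_need_no_normalization(self, rng):
        """Per-sample additive Cq shifts cancel in balanced (1/1, 2/2) models,
        and raw-Cq scores equal dCq scores exactly."""
        ids = ["ref1", "ref2", "a", "b", "c", "d"]
        base = rng.normal(26, 2, (6, 25))
        shifts = rng.normal(0, 3, 25)
        cq = CqMatrix(pd.DataFrame(base + shifts, index=ids,
                                   columns=[f"s{j}" for j in range(25)]))
        from bcap import NormalizationSpec, normalize_delta_cq

        norm = normalize_delta_cq(cq, NormalizationSpec(("ref1", "ref2")))
        for model in (RatioModel(("a", "b"), ("c", "d")), RatioModel(("a",), ("d",))):
            s_cq = score_ratio_model(model, cq)
            s_dcq = score_ratio_model(model, norm)
            assert np.allclose(s_cq, s_dcq, atol=1e-9)
            # and the shift itself never changes the score
            cq0 = CqMatrix(pd.DataFrame(base, index=ids, columns=cq.sample_ids))
            assert np.allclose(score_ratio_model(model, cq0), s_cq, atol=1e-9)


class TestSearch:
    def planted(self, rng, n0=40, n1=40, n_null=8, effect=1.2):
        ids = ["up1", "up2", "dn1", "dn2"] + [f"null{i}" for i in range(n_null)]
        n = n0 + n1
        X = rng.normal(0, 0.4, (len(ids), n))
        X[0, n0:] += effect
        X[1, n0:] += effect
        X[2, n0:] -= effect
        X[3, n0:] -= effect
        cols = [f"s{j}" for j in range(n)]
        norm = NormalizedMatrix(pd.DataFrame(X, index=ids, columns=cols))
        labels = pd.Series([0] * n0 + [1] * n1, index=cols)
        return norm, labels

    def test_planted_quartet_is_top_model(self, rng):
        hits = 0
        for _ in range(10):
            norm, labels = self.planted(rng)
            res = search_best_model(norm, labels, list(norm.mirna_ids))
            hits += res.best_model.members == frozenset({"up1", "up2", "dn1", "dn2"})
        assert hits >= 9

    def test_best_model_oriented_high_score_positive(self, rng):
        norm, labels = self.planted(rng)
        res = search_best_model(norm, labels, list(norm.mirna_ids))
        s = score_ratio_model(res.best_model, norm)
        assert s[labels == 1].mean() > s[labels == 0].mean()
        assert res.orientation == "high-score-positive"

    def test_panel_of_two_evaluates_single_model(self, rng):
        norm, labels = self.planted(rng, n_null=0)
        res = search_best_model(norm, labels, ["up1", "dn1"])
        assert res.best_model.size == 2
        assert len(res.ranking) == 1

    def test_rank_candidates_puts_discriminative_mirna_first(self, rng):
        norm, labels = self.planted(rng, effect=0.0)
        X = norm.values.copy()
        X.loc["up1", labels.index[labels == 1]] += 2.5  # single strong marker
        norm = NormalizedMatrix(X)
        cand = rank_candidates(norm, labels, SearchConfig(top_k=5))
        assert cand[0] == "up1"

    def test_rank_candidates_warns_when_panel_small(self, rng):
        norm, labels = self.planted(rng, n_null=0)
        with pytest.warns(UserWarning, match="detection filter"):
            cand = rank_candidates(norm, labels, SearchConfig(top_k=20))
        assert len(cand) == 4

    def test_evaluate_reproduces_search_auc(self, rng):
        norm, labels = self.planted(rng)
        res = search_best_model(norm, labels, list(norm.mirna_ids))
        rep = evaluate_model(
            res.best_model, norm, {"train": (list(labels.index), labels)}
        )
        assert rep["subsets"]["train"]["auc"] == pytest.approx(res.best_auc)

    def test_constant_psa_gives_half_auc(self, rng):
        norm, labels = self.planted(rng)
        res = search_best_model(norm, labels, list(norm.mirna_ids))
        psa = pd.Series(7.5, index=labels.index)
        rep = evaluate_model(
            res.best_model, norm, {"train": (list(labels.index), labels)}, psa=psa
        )
        assert rep["subsets"]["train"]["auc_psa"] == pytest.approx(0.5)

    def test_generalizes_to_held_out_data(self, rng):
        """Same generator, fresh draw: test AUC lands near training AUC."""
        gaps = []
        for _ in range(10):
            norm_tr, y_tr = self.planted(rng, n0=75, n1=75)
            res = search_best_model(norm_tr, y_tr, list(norm_tr.mirna_ids))
            norm_te, y_te = self.planted(rng, n0=75, n1=75)
            s = score_ratio_model(res.best_model, norm_te)
            auc_te = roc_auc(s.to_numpy(), y_te.to_numpy()).oriented_auc
            gaps.append(res.best_auc - auc_te)
        assert np.median(np.abs(gaps)) < 0.08
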