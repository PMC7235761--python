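"""Wilcoxon/BH screens, fold conversion, Cox regression, clinical endpoints."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import bcap
from bcap import (
    Group,
    NormalizedMatrix,
    bh_adjust,
    clinical_associations,
    compare_groups,
    cox_univariate,
    fold_from_ddcq,
    wilcoxon_rank_sum,
)


# -- independent oracles ----------------------------------------------------

def wilcoxon_enumeration_oracle(x, y):
    """Exact two-sided p by enumerating every label assignment."""
    pooled = np.concatenate([x, y])
    nx = len(x)
    mn = nx * len(y)

    def u_of(idx):
        xs = pooled[list(idx)]
        ys = np.delete(pooled, list(idx))
        return sum((xi > yj) + 0.5 * (xi == yj) for xi in xs for yj in ys)

    u_obs = u_of(range(nx))
    v_obs = min(u_obs, mn - u_obs)
    total = hits = 0
    for idx in itertools.combinations(range(len(pooled)), nx):
        total += 1
        u = u_of(idx)
        if min(u, mn - u) <= v_obs:
            hits += 1
    return hits / total


def bh_stepup_oracle(p):
    """Literal step-up definition: sort, take running minima of m*p/(rank)."""
    p = list(p)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [None] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p[i] / rank)
        adj[i] = running
    return adj


class TestWilcoxon:
    def test_exact_small_sample_values(self):
        _, p = wilcoxon_rank_sum([1, 2], [3, 4])
        assert p == pytest.approx(1 / 3)
        _, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)

    def test_identical_samples_give_p_one(self):
        _, p = wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    def test_empty_sample_is_error(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])

    def test_exact_path_matches_enumeration(self, rng):
        for nx in range(1, 5):
            for ny in range(1, 5):
                x = rng.normal(size=nx)
                y = rng.normal(size=ny)
                _, p = wilcoxon_rank_sum(x, y)
                assert p == pytest.approx(wilcoxon_enumeration_oracle(x, y), abs=1e-12)


class TestBH:
    def test_hand_computed_examples(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])
        assert bh_adjust([0.2]) == pytest.approx([0.2])
        assert bh_adjust([0.05, 0.05]) == pytest.approx([0.05, 0.05])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])
        with pytest.raises(ValueError):
            bh_adjust([-0.1])

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=50))
    def test_matches_stepup_oracle(self, p):
        assert bh_adjust(p) == pytest.approx(bh_stepup_oracle(p), abs=1e-12)

    def test_adjusted_at_least_raw_and_capped(self, rng):
        p = rng.random(40)
        q = bh_adjust(p)
        assert (q >= p - 1e-15).all() and (q <= 1.0).all()


class TestFoldConversion:
    @pytest.mark.parametrize("ddcq,fold", [(1.0, 2.0), (-1.0, -2.0), (0.0, 1.0), (2.0, 4.0)])
    def test_signed_linear_fold(self, ddcq, fold):
        assert fold_from_ddcq(ddcq) == pytest.approx(fold)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            fold_from_ddcq(float("nan"))


def planted_norm(rng, n_mir=92, n_a=50, n_b=50, n_de=10, effect=1.5, sigma=1.0):
    ids = [f"m{i:02d}" for i in range(n_mir)]
    cols = [f"a{j}" for j in range(n_a)] + [f"b{j}" for j in range(n_b)]
    vals = rng.normal(0, sigma, (n_mir, n_a + n_b))
    vals[:n_de, n_a:] += effect
    norm = NormalizedMatrix(pd.DataFrame(vals, index=ids, columns=cols))
    from bcap.qpcr import SampleRecord

    samples = [SampleRecord(c, Group.BPH) for c in cols[:n_a]] + [
        SampleRecord(c, Group.APC) for c in cols[n_a:]
    ]
    return norm, samples, ids[:n_de]


class TestCompareGroups:
    def test_planted_de_mirnas_all_recovered(self, rng):
        norm, samples, de_ids = planted_norm(rng)
        res = compare_groups(norm, samples, Group.BPH, Group.APC)
        sig = {r.mirna_id for r in res if r.significant}
        assert set(de_ids) <= sig
        for r in res:
            if r.mirna_id in de_ids:
                assert r.direction == "up" and r.delta_delta_cq > 1.0

    def test_antisymmetric_in_group_order(self, rng):
        norm, samples, _ = planted_norm(rng, n_mir=10)
        fwd = compare_groups(norm, samples, Group.BPH, Group.APC)
        rev = compare_groups(norm, samples, Group.APC, Group.BPH)
        for a, b in zip(fwd, rev):
            assert a.delta_delta_cq == pytest.approx(-b.delta_delta_cq)

    def test_same_groups_give_zero_ddcq(self, rng):
        norm, samples, _ = planted_norm(rng, n_mir=5)
        bph_only = [s for s in samples if s.group == Group.BPH]
        res = compare_groups(norm, bph_only, Group.BPH, Group.BPH)
        for r in res:
            assert r.delta_delta_cq == pytest.approx(0.0)
            assert r.p_adjusted == pytest.approx(1.0)

    def test_invariants_of_results(self, rng):
        norm, samples, _ = planted_norm(rng, n_mir=20)
        for r in compare_groups(norm, samples, Group.BPH, Group.APC):
            assert 0 <= r.p_raw <= 1 and r.p_adjusted >= r.p_raw
            assert math.copysign(1, r.fold_change_signed) == (
                1 if r.delta_delta_cq >= 0 else -1
            )

    def test_absent_group_is_error(self, rng):
        norm, samples, _ = planted_norm(rng, n_mir=5)
        with pytest.raises(ValueError, match="LPC"):
            compare_groups(norm, samples, Group.BPH, Group.LPC)

    def test_null_cohorts_rarely_yield_false_positives(self, rng):
        """BH at 0.05 keeps the per-cohort false-positive rate near alpha."""
        reps = 200
        fp = 0
        for _ in range(reps):
            vals = rng.normal(0, 1, (92, 50))
            p = [wilcoxon_rank_sum(row[:25], row[25:])[1] for row in vals]
            fp += (bh_adjust(p) < 0.05).any()
        assert fp / reps <= 0.08


class TestCox:
    def test_null_covariate_unbiased(self, rng):
        logs = []
        for _ in range(100):
            x = rng.normal(0, 1, 200)
            t = rng.exponential(1.0, 200)
            c = rng.uniform(0.5, 2.0, 200)
            hr, _, _ = cox_univariate(np.minimum(t, c), t < c, x)
            logs.append(math.log(hr))
        assert abs(np.mean(logs)) < 0.05

    def test_planted_log_hazard_recovered(self, rng):
        logs = []
        for _ in range(50):
            x = rng.normal(0, 1, 400)
            t = rng.exponential(np.exp(-math.log(2) * x))
            c = rng.uniform(0.5, 2.0, 400)
            hr, ci, p = cox_univariate(np.minimum(t, c), t < c, x)
            logs.append(math.log(hr))
            assert ci[0] < hr < ci[1]
        assert abs(np.mean(logs) - math.log(2)) < 0.15

    def test_matches_lifelines_on_untied_data(self, rng):
        from lifelines import CoxPHFitter

        x = rng.normal(0, 1, 150)
        t = rng.exponential(np.exp(-0.5 * x))
        c = rng.uniform(0.3, 3.0, 150)
        tt, e = np.minimum(t, c), t < c
        hr, _, p = cox_univariate(tt, e, x)
        cph = CoxPHFitter().fit(
            pd.DataFrame({"T": tt, "E": e, "x": x}), duration_col="T", event_col="E"
        )
        assert math.log(hr) == pytest.approx(cph.params_["x"], abs=1e-5)

    def test_constant_covariate_is_error(self):
        with pytest.raises(ValueError, match="constant"):
            cox_univariate([1, 2, 3, 4], [1, 1, 0, 1], [0.0, 0.0, 0.0, 0.0])

    def test_too_few_events_is_error(self):
        with pytest.raises(ValueError, match="events"):
            cox_univariate([1, 2, 3], [True, False, False], [1.0, 2.0, 3.0])


class TestClinicalAssociations:
    def test_planted_psa_stratum_mirna_detected(self):
        cohort = bcap.SyntheticConfig(seed=7)
        cq, samples, truth = bcap.generate_cohort(cohort)
        corrected = bcap.correct_batch(cq, [r.batch for r in samples])
        norm = bcap.normalize_delta_cq(corrected, bcap.NormalizationSpec())
        res = clinical_associations(norm, samples)
        psa_hits = {
            r.mirna_id for r in res if r.endpoint == "PSA<=10_vs_>10" and r.p_adjusted < 0.05
        }
        assert "hsa-miR-375" in psa_hits
        # effect on the planted marker is near the planted 1.49-fold magnitude
        eff = next(
            r.effect for r in res if r.endpoint == "PSA<=10_vs_>10" and r.mirna_id == "hsa-miR-375"
        )
        assert eff == pytest.approx(math.log2(1.49), abs=0.25)

    def test_endpoints_present_and_bounded(self):
        cq, samples, _ = bcap.generate_cohort(bcap.SyntheticConfig(seed=8))
        norm = bcap.normalize_delta_cq(cq, bcap.NormalizationSpec())
        res = clinical_associations(norm, samples)
        endpoints = {r.endpoint for r in res}
        assert {"PSA<=10_vs_>10", "pT<=T2_vs_>=T3", "GGG<=2_vs_>2",
                "CAPRA-S_spearman", "BCR_cox"} <= endpoints
        for r in res:
            if r.endpoint == "CAPRA-S_spearman":
                assert -1 <= r.effect <= 1
            if r.endpoint == "BCR_cox":
                assert r.effect > 0

    def test_no_events_skips_cox_with_warning(self, rng):
        from bcap.qpcr import SampleRecord, SurvivalRecord

        ids = [f"s{j}" for j in range(30)]
        vals = pd.DataFrame(rng.normal(0, 1, (4, 30)),
                            index=[f"m{i}" for i in range(4)], columns=ids)
        samples = [
            SampleRecord(s, Group.LPC, psa=5.0 + j,
                         survival=SurvivalRecord(bcr_event=False, time_months=24.0))
            for j, s in enumerate(ids)
        ]
        with pytest.warns(UserWarning, match="Cox"):
            res = clinical_associations(NormalizedMatrix(vals), samples)
        assert not any(r.endpoint == "BCR_cox" for r in res)
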