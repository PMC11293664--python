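"""Rank statistics, per-domain evaluation, and linear recalibration."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from stabbench.errors import KeyAlignmentError, StabbenchError
from stabbench.evaluation import (
    compare_collective_vs_single,
    evaluate_per_domain,
    recalibrate_per_domain,
    spearman_r,
    wilcoxon_rank_sum,
)


class TestSpearman:
    def test_identity_is_one(self):
        assert spearman_r([3, 1, 4, 1.5, 9], [3, 1, 4, 1.5, 9]) == pytest.approx(1.0)

    def test_hand_case_point_eight(self):
        # 1 - 6*Σd²/(n(n²-1)) with Σd² = 4
        assert spearman_r([1, 2, 3, 4, 5], [1, 3, 2, 5, 4]) == pytest.approx(0.8)

    def test_negation_gives_minus_one(self):
        x = [0.3, 1.2, -0.5, 2.0]
        assert spearman_r(x, [-v for v in x]) == pytest.approx(-1.0)

    def test_zero_variance_is_explicit_not_a_value(self):
        assert math.isnan(spearman_r([1.0, 1.0, 1.0], [1, 2, 3]))

    def test_agrees_with_scipy_on_tied_data(self):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 5, 40).astype(float)  # heavy ties
        y = rng.integers(0, 5, 40).astype(float)
        assert spearman_r(x, y) == pytest.approx(stats.spearmanr(x, y).statistic)

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(
        st.lists(st.integers(-20, 20), min_size=4, max_size=20, unique=True),
        st.sampled_from([np.exp, np.arctan, lambda v: v**3, lambda v: 2.5 * v + 7]),
    )
    def test_invariant_under_strictly_monotone_transforms(self, x, transform):
        x = np.asarray(x, dtype=float)  # unit-spaced: transforms stay injective
        rng = np.random.default_rng(len(x))
        y = rng.normal(size=len(x))
        base = spearman_r(x, y)
        assert spearman_r(transform(np.asarray(x)), y) == pytest.approx(base, abs=1e-9)
        assert spearman_r(x, transform(y)) == pytest.approx(base, abs=1e-9)


def rank_sum_enumeration_oracle(a, b):
    """Brute-force two-sided p: enumerate every split of the pooled values."""
    pooled = list(a) + list(b)
    m = len(a)
    ranks = stats.rankdata(pooled)
    center = m * (len(pooled) - m) / 2
    obs = abs(ranks[:m].sum() - m * (m + 1) / 2 - center)
    hits = total = 0
    for combo in itertools.combinations(range(len(pooled)), m):
        u = sum(ranks[i] for i in combo) - m * (m + 1) / 2
        total += 1
        if abs(u - center) >= obs - 1e-12:
            hits += 1
    return hits / total


class TestWilcoxonRankSum:
    def test_fully_separated_triples(self):
        res = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert res.p_value == pytest.approx(0.1)  # 2 of C(6,3)=20 splits as extreme
        assert res.method == "exact_enumeration"

    def test_identical_multisets_give_p_one(self):
        assert wilcoxon_rank_sum([1, 2, 3], [1, 2, 3]).p_value == pytest.approx(1.0)

    def test_degenerate_all_identical_is_not_a_value(self):
        res = wilcoxon_rank_sum([2, 2], [2, 2, 2])
        assert math.isnan(res.p_value)

    @pytest.mark.parametrize("seed", range(8))
    def test_exact_path_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m, n = rng.integers(2, 6), rng.integers(2, 6)
        a = rng.integers(0, 6, m).astype(float)  # ties likely
        b = rng.integers(0, 6, n).astype(float)
        res = wilcoxon_rank_sum(a, b)
        assert res.method == "exact_enumeration"
        assert res.p_value == pytest.approx(rank_sum_enumeration_oracle(a, b))

    @pytest.mark.parametrize("seed", range(4))
    def test_normal_approximation_close_to_exact_at_n12(self, seed):
        rng = np.random.default_rng(100 + seed)
        a = rng.normal(0, 1, 6)
        b = rng.normal(0.8, 1, 6)
        exact = wilcoxon_rank_sum(a, b, exact_max_n=12)
        approx = wilcoxon_rank_sum(a, b, exact_max_n=0)
        assert approx.method == "normal_approximation"
        assert approx.p_value == pytest.approx(exact.p_value, abs=0.05)


def _evals(values, partition="test_only"):
    return pd.DataFrame(
        {
            "domain_id": [f"d{i}" for i in range(len(values))],
            "partition": partition,
            "n_sequences": 10,
            "spearman_r": values,
            "max_identity_pct": 0.0,
            "skipped": False,
            "skip_reason": "",
        }
    )


class TestCompareCollectiveVsSingle:
    def test_identical_sets_have_zero_mean_difference(self):
        evals = _evals([0.5, 0.6, 0.7])
        cmp = compare_collective_vs_single(evals, evals.copy())
        assert cmp.mean_difference == pytest.approx(0.0)

    def test_uniform_improvement_detected_by_signed_rank(self):
        single = _evals(list(np.linspace(0.2, 0.65, 10)))
        collective = single.copy()
        collective["spearman_r"] = collective["spearman_r"] + 0.1
        cmp = compare_collective_vs_single(collective, single)
        assert cmp.mean_difference == pytest.approx(0.1)
        # exact signed-rank: all 10 signs positive, p = 2/2^10
        assert cmp.signed_rank_p_value == pytest.approx(2 / 1024)
        assert cmp.signed_rank_p_value < 0.05

    def test_no_shared_domains_is_an_error(self):
        a = _evals([0.5])
        b = _evals([0.4])
        b["domain_id"] = ["other"]
        with pytest.raises(StabbenchError, match="shared"):
            compare_collective_vs_single(a, b)


@pytest.fixture(scope="module")
def scored_world():
    rng = np.random.default_rng(5)
    rows = []
    for d in ("da", "db"):
        for i in range(8):
            rows.append((d, f"{d}_v{i}", f"SEQ{d}{i}", rng.normal()))
    curated = pd.DataFrame(rows, columns=["domain_id", "variant_id",
                                          "protein_sequence", "mean_dG"])
    assignment = curated[["domain_id", "variant_id", "protein_sequence"]].copy()
    assignment["split_label"] = ["test"] * 8 + ["test_only"] * 8
    assignment["seed"] = 0
    return curated, assignment


class TestEvaluatePerDomain:
    def test_perfect_predictor_scores_one_everywhere(self, scored_world):
        curated, assignment = scored_world
        preds = curated[["domain_id", "protein_sequence"]].copy()
        preds["predicted_dG"] = curated["mean_dG"]
        evals = evaluate_per_domain(preds, curated, assignment, {"da": 80.0})
        np.testing.assert_allclose(evals.spearman_r, 1.0)
        assert evals.n_sequences.sum() == len(curated)

    def test_antiperfect_predictor_scores_minus_one(self, scored_world):
        curated, assignment = scored_world
        preds = curated[["domain_id", "protein_sequence"]].copy()
        preds["predicted_dG"] = -curated["mean_dG"]
        evals = evaluate_per_domain(preds, curated, assignment)
        np.testing.assert_allclose(evals.spearman_r, -1.0)

    def test_missing_identity_entry_reports_zero(self, scored_world):
        curated, assignment = scored_world
        preds = curated[["domain_id", "protein_sequence"]].copy()
        preds["predicted_dG"] = curated["mean_dG"]
        evals = evaluate_per_domain(preds, curated, assignment, {"da": 80.0})
        db = evals.loc[evals.domain_id == "db"].iloc[0]
        assert db.max_identity_pct == 0.0

    def test_prediction_gap_is_a_key_alignment_error(self, scored_world):
        curated, assignment = scored_world
        preds = curated[["domain_id", "protein_sequence"]].iloc[:10].copy()
        preds["predicted_dG"] = 0.0
        with pytest.raises(KeyAlignmentError):
            evaluate_per_domain(preds, curated, assignment)

    def test_single_record_domain_reported_as_skipped(self):
        curated = pd.DataFrame(
            [("solo", "v0", "SEQX", 1.0)],
            columns=["domain_id", "variant_id", "protein_sequence", "mean_dG"])
        assignment = curated[["domain_id", "variant_id", "protein_sequence"]].copy()
        assignment["split_label"] = "test_only"
        assignment["seed"] = 0
        preds = curated[["domain_id", "protein_sequence"]].copy()
        preds["predicted_dG"] = 0.5
        evals = evaluate_per_domain(preds, curated, assignment, {"solo": 10.0})
        assert evals.iloc[0].skipped
        assert math.isnan(evals.iloc[0].spearman_r)


class TestRecalibration:
    def _scored(self, domain_id, preds, labels):
        return pd.DataFrame({"domain_id": domain_id, "predicted_dG": preds,
                             "mean_dG": labels})

    def test_exact_affine_miscalibration_fully_corrected(self):
        labels = np.array([0.5, 1.0, 2.0, 3.5, 4.0])
        scored = self._scored("d", 2 * labels + 1, labels)
        res = recalibrate_per_domain(scored).iloc[0]
        assert res.rmse_after == pytest.approx(0.0, abs=1e-12)
        assert res.r2_after == pytest.approx(1.0)
        assert res.slope == pytest.approx(0.5)
        assert res.intercept == pytest.approx(-0.5)

    def test_identity_predictions_unchanged(self):
        labels = np.array([0.0, 1.0, 2.0, 3.0])
        res = recalibrate_per_domain(self._scored("d", labels, labels)).iloc[0]
        assert res.slope == pytest.approx(1.0)
        assert res.intercept == pytest.approx(0.0, abs=1e-12)
        assert res.rmse_before == pytest.approx(res.rmse_after)

    def test_hand_computed_ols_case(self):
        # labels {0,1,2}, predictions {10,11,13}: slope 9/14, intercept -44/7
        res = recalibrate_per_domain(self._scored("d", [10, 11, 13], [0, 1, 2])).iloc[0]
        assert res.slope == pytest.approx(9 / 14)
        assert res.intercept == pytest.approx(-44 / 7)
        assert res.rmse_before == pytest.approx(math.sqrt(107))
        assert res.r2_before == pytest.approx(1 - 321 / 2)  # large negative
        assert res.rmse_after == pytest.approx(math.sqrt(1 / 42))
        assert res.r2_after == pytest.approx(27 / 28)

    def test_affine_distortion_recovery_on_noise_free_data(self):
        rng = np.random.default_rng(8)
        labels = rng.normal(1.5, 1.2, 50)
        a, b = 0.4, -2.0
        res = recalibrate_per_domain(self._scored("d", a * labels + b, labels)).iloc[0]
        assert res.slope == pytest.approx(1 / a, abs=1e-6)
        assert res.intercept == pytest.approx(-b / a, abs=1e-6)
        assert res.rmse_after == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("seed", range(6))
    def test_ols_never_hurts_in_sample(self, seed):
        rng = np.random.default_rng(seed)
        frames = []
        for d in range(4):
            labels = rng.normal(2, 1.5, 30)
            preds = 0.7 * labels + rng.normal(0, 1.0, 30) + d
            frames.append(self._scored(f"d{d}", preds, labels))
        res = recalibrate_per_domain(pd.concat(frames, ignore_index=True))
        assert (res.rmse_after <= res.rmse_before + 1e-12).all()
        assert (res.r2_after >= res.r2_before - 1e-12).all()

    def test_zero_variance_predictions_flagged_degenerate(self):
        res = recalibrate_per_domain(self._scored("d", [1.0] * 5, [0, 1, 2, 3, 4])).iloc[0]
        assert res.degenerate
        assert res.rmse_after <= res.rmse_before

    def test_too_few_points_reported_not_fitted(self):
        res = recalibrate_per_domain(self._scored("d", [1.0, 2.0], [0.0, 1.0])).iloc[0]
        assert res.degenerate
        assert math.isnan(res.slope)
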