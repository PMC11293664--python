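"""Per-domain evaluation, rank statistics, and linear recalibration.

Model quality is reported per protein domain: Spearman's R between
predicted and measured ΔG over that domain's evaluated mutants, alongside
the domain's maximum sequence identity to the training set (0% when no
alignment passes the e-value cutoff). Two training regimes — one model on
all domains pooled ("collective") versus one model per closest training
domain ("single") — are compared per held-out domain with Wilcoxon's rank
sum test (a signed-rank p-value is reported alongside since the samples
are paired by domain).

Predictions are often rank-accurate but offset or mis-scaled in absolute
ΔG. ``recalibrate_per_domain`` fits, per domain, an ordinary least-squares
line of measured ΔG on predicted ΔG and reports RMSE and the coefficient
of determination R² = 1 − SS_res/SS_tot (negative values allowed) before
and after; rank metrics are untouched by this affine correction.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import KeyAlignmentError, StabbenchError

logger = logging.getLogger(__name__)

EVALUATION_COLUMNS = ["domain_id", "partition", "n_sequences", "spearman_r",
                      "max_identity_pct", "skipped", "skip_reason"]


def spearman_r(x, y) -> float:
    """Spearman rank correlation: Pearson correlation of average ranks.

    Returns NaN (an explicit not-a-value) when either vector has zero rank
    variance, where the statistic is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("spearman_r needs two equal-length 1-d vectors with n >= 2")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("spearman_r requires finite values")
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    if rx.std() == 0 or ry.std() == 0:
        return float("nan")
    return float(np.corrcoef(rx, ry)[0, 1])


def evaluate_per_domain(
    predictions: pd.DataFrame,
    labels: pd.DataFrame,
    assignment: pd.DataFrame,
    identity: Mapping[str, float] | None = None,
    partitions: tuple[str, ...] = ("test", "test_only"),
) -> pd.DataFrame:
    """Per-domain Spearman's R on the evaluated partitions.

    ``predictions`` holds (domain_id, protein_sequence, predicted_dG);
    ``labels`` the curated table; ``assignment`` the split labels.
    ``identity`` maps domain_id → max identity (%) to the training set;
    missing domains get 0 with a warning (the no-alignment convention).
    Domains with fewer than 2 evaluable records are reported as skipped.
    """
    key = ["domain_id", "protein_sequence"]
    eval_records = assignment.loc[assignment["split_label"].isin(partitions)]
    merged = eval_records.merge(labels[key + ["mean_dG"]], on=key, how="left").merge(
        predictions[key + ["predicted_dG"]], on=key, how="left"
    )
    missing = merged.loc[merged["predicted_dG"].isna(), key]
    if len(missing):
        raise KeyAlignmentError(
            [tuple(r) for r in missing.itertuples(index=False)],
            "records without predictions",
        )

    identity = dict(identity or {})
    rows = []
    for (domain_id, label), grp in merged.groupby(["domain_id", "split_label"]):
        grp = grp.dropna(subset=["mean_dG"])
        if domain_id not in identity and label == "test_only":
            logger.warning("no identity entry for %s; assigning 0%%", domain_id)
        ident = identity.get(domain_id, 0.0)
        if len(grp) < 2:
            rows.append([domain_id, label, len(grp), np.nan, ident, True,
                         "fewer than 2 evaluable records"])
            continue
        r = spearman_r(grp["predicted_dG"], grp["mean_dG"])
        rows.append([domain_id, label, len(grp), r, ident, False, ""])
    return pd.DataFrame(rows, columns=EVALUATION_COLUMNS)


# --------------------------------------------------------------------------
# Wilcoxon rank-sum
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RankSumResult:
    statistic: float  # Mann-Whitney U of the first sample
    p_value: float
    method: str  # "exact_enumeration" | "normal_approximation"


def wilcoxon_rank_sum(sample_a, sample_b, exact_max_n: int = 12) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    For combined n ≤ ``exact_max_n`` the null is enumerated exactly over
    all C(m+n, m) assignments of the pooled (mid)ranks, which handles ties;
    the two-sided p-value is P(|U − mn/2| ≥ |u_obs − mn/2|) under the
    symmetric null. Larger samples use the tie-corrected normal
    approximation with continuity correction.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return RankSumResult(statistic=len(a) * len(b) / 2, p_value=float("nan"),
                             method="degenerate_all_tied")
    m, n = len(a), len(b)
    ranks = stats.rankdata(pooled)
    u_obs = float(ranks[:m].sum() - m * (m + 1) / 2)

    if m + n <= exact_max_n:
        center = m * n / 2
        d_obs = abs(u_obs - center)
        hits = total = 0
        for combo in itertools.combinations(range(m + n), m):
            u = ranks[list(combo)].sum() - m * (m + 1) / 2
            total += 1
            if abs(u - center) >= d_obs - 1e-12:
                hits += 1
        return RankSumResult(statistic=u_obs, p_value=hits / total,
                             method="exact_enumeration")

    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return RankSumResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                         method="normal_approximation")


@dataclass
class PairedComparison:
    """Collective-vs-single per-domain comparison."""

    pairs: pd.DataFrame  # domain_id, spearman_collective, spearman_single
    mean_difference: float
    statistic: float
    p_value: float
    test_name: str = "wilcoxon_rank_sum"
    signed_rank_statistic: float = float("nan")
    signed_rank_p_value: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "n_domains": int(len(self.pairs)),
            "mean_difference": self.mean_difference,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "test_name": self.test_name,
            "signed_rank_statistic": self.signed_rank_statistic,
            "signed_rank_p_value": self.signed_rank_p_value,
            "pairs": self.pairs.to_dict(orient="records"),
        }


def compare_collective_vs_single(
    evals_collective: pd.DataFrame, evals_single: pd.DataFrame
) -> PairedComparison:
    """Pair per-domain Spearman's R under the two regimes and test.

    The primary p-value is the (unpaired) rank-sum test between the two
    Spearman samples; because the samples are paired by domain, the exact
    signed-rank test on the differences is reported alongside.
    """
    cols = ["domain_id", "spearman_r"]
    pairs = (
        evals_collective.loc[~evals_collective["skipped"], cols]
        .merge(evals_single.loc[~evals_single["skipped"], cols],
               on="domain_id", suffixes=("_collective", "_single"))
        .dropna()
        .rename(columns={"spearman_r_collective": "spearman_collective",
                         "spearman_r_single": "spearman_single"})
        .sort_values("domain_id")
        .reset_index(drop=True)
    )
    if pairs.empty:
        raise StabbenchError("no shared domains between the two evaluation sets")
    diff = pairs["spearman_collective"] - pairs["spearman_single"]
    rank_sum = wilcoxon_rank_sum(pairs["spearman_collective"], pairs["spearman_single"])
    if np.allclose(diff, 0):
        sr_stat, sr_p = float("nan"), float("nan")
    else:
        sr = stats.wilcoxon(diff[diff != 0])
        sr_stat, sr_p = float(sr.statistic), float(sr.pvalue)
    return PairedComparison(
        pairs=pairs,
        mean_difference=float(diff.mean()),
        statistic=rank_sum.statistic,
        p_value=rank_sum.p_value,
        signed_rank_statistic=sr_stat,
        signed_rank_p_value=sr_p,
    )


# --------------------------------------------------------------------------
# per-domain linear recalibration
# --------------------------------------------------------------------------

RECALIBRATION_COLUMNS = ["domain_id", "n", "slope", "intercept", "rmse_before",
                         "rmse_after", "r2_before", "r2_after", "degenerate"]


def _rmse(pred, label):
    return float(np.sqrt(np.mean((np.asarray(pred) - np.asarray(label)) ** 2)))


def _r2(pred, label):
    label = np.asarray(label, dtype=float)
    ss_res = float(np.sum((label - np.asarray(pred)) ** 2))
    ss_tot = float(np.sum((label - label.mean()) ** 2))
    if ss_tot == 0:
        return float("nan")
    return 1.0 - ss_res / ss_tot


def recalibrate_per_domain(
    scored: pd.DataFrame, min_points: int = 3
) -> pd.DataFrame:
    """Per-domain OLS recalibration of predictions against measurements.

    ``scored`` holds (domain_id, predicted_dG, mean_dG). For each domain,
    measured ΔG is regressed on predicted ΔG; the recalibrated prediction
    slope·pred + intercept lives in kcal/mol. RMSE and R² are reported
    before and after; OLS optimality guarantees rmse_after ≤ rmse_before
    on the fitted points. Zero-variance predictions are flagged degenerate
    (intercept-only fit).
    """
    rows = []
    for domain_id, grp in scored.dropna(subset=["predicted_dG", "mean_dG"]).groupby("domain_id"):
        pred = grp["predicted_dG"].to_numpy(dtype=float)
        label = grp["mean_dG"].to_numpy(dtype=float)
        if len(grp) < min_points:
            rows.append([domain_id, len(grp)] + [np.nan] * 6 + [True])
            continue
        if pred.std() == 0:
            slope, intercept = 0.0, float(label.mean())
            degenerate = True
        else:
            slope, intercept = np.polyfit(pred, label, 1)
            degenerate = False
        recal = slope * pred + intercept
        rows.append([
            domain_id, len(grp), float(slope), float(intercept),
            _rmse(pred, label), _rmse(recal, label),
            _r2(pred, label), _r2(recal, label), degenerate,
        ])
    return pd.DataFrame(rows, columns=RECALIBRATION_COLUMNS)
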