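"""Model validation: ROC/AUC, binomial omission tests, the three-criterion
acceptance rule, and variable-set selection arithmetic.

A model ensemble is accepted for community construction only if

  (i)   mean test AUC over replicates exceeds 0.9,
  (ii)  every binomial omission test (eleven thresholds, training and test
        partitions, every replicate) rejects its null at p < 0.05, and
  (iii) the relative difference between mean training and mean test AUC
        is below five percent (a guard against over-fitting).

AUC is the rank-based (Mann-Whitney) statistic with ties credited 0.5,
with background cells serving as the negative class.  Each omission test
asks whether presences fall above a suitability threshold more often than
a random scatter would: with fractional predicted area a (the fraction of
background at or above the threshold) as the success probability, the
one-sided p-value is P(X >= k), X ~ Binomial(n, a), for k of n presences
at or above the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom, rankdata

__all__ = [
    "OmissionTest",
    "ValidationReport",
    "AcceptanceDecision",
    "compute_auc",
    "eleven_thresholds",
    "binomial_omission_tests",
    "evaluate_acceptance",
    "aggregate_expert_ranks",
    "select_best_model_per_species",
]


def compute_auc(presence_scores, background_scores) -> float:
    """Rank-based AUC of presences against background (ties count 0.5)."""
    p = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    if p.size == 0 or b.size == 0:
        raise ValueError("both score sets must be non-empty")
    ranks = rankdata(np.concatenate([p, b]))
    r_p = ranks[: p.size].sum()
    return float((r_p - p.size * (p.size + 1) / 2.0) / (p.size * b.size))


@dataclass(frozen=True)
class OmissionTest:
    """One threshold's omission statistics on one presence partition."""

    name: str
    threshold: float
    omission: float          # fraction of evaluated presences below threshold
    predicted_area: float    # fraction of background at/above threshold
    p_value: float
    partition: str           # "train" | "test"


THRESHOLD_NAMES = (
    "fixed_cumulative_1",
    "fixed_cumulative_5",
    "fixed_cumulative_10",
    "minimum_training_presence",
    "tenth_percentile_training_presence",
    "equal_training_sensitivity_specificity",
    "maximum_training_sensitivity_plus_specificity",
    "equal_test_sensitivity_specificity",
    "maximum_test_sensitivity_plus_specificity",
    "balance_training_omission_area",
    "equate_entropy",
)


def _cumulative_threshold(raw_bg: np.ndarray, bg_logistic: np.ndarray,
                          percent: float) -> float:
    """Logistic value at which the cumulative raw distribution reaches
    ``percent``.  The cumulative value of a cell is 100x the summed raw
    probability of all background cells with raw value <= its own."""
    order = np.argsort(raw_bg)
    csum = 100.0 * np.cumsum(raw_bg[order])
    idx = int(np.searchsorted(csum, percent, side="left"))
    idx = min(idx, len(order) - 1)
    return float(bg_logistic[order[idx]])


def _sens_spec_thresholds(scores: np.ndarray, bg_logistic: np.ndarray
                          ) -> tuple[float, float]:
    """(equal sens/spec, max sens+spec) thresholds from presence scores.

    Candidate thresholds are the distinct presence scores; sensitivity is
    1 - omission and specificity 1 - fractional predicted area.
    """
    cand = np.unique(scores)
    sens = np.array([(scores >= t).mean() for t in cand])
    spec = np.array([1.0 - (bg_logistic >= t).mean() for t in cand])
    eq = cand[int(np.argmin(np.abs(sens - spec)))]
    mx = cand[int(np.argmax(sens + spec))]
    return float(eq), float(mx)


def eleven_thresholds(
    bg_logistic: np.ndarray,
    raw_bg: np.ndarray,
    entropy: float,
    train_scores: np.ndarray,
    test_scores: np.ndarray,
) -> dict[str, float]:
    """The eleven logistic-scale thresholds used by the omission analyses.

    Mirrors the conventional threshold rows of maxent-style model reports:
    three fixed cumulative levels, minimum and 10th-percentile training
    presence, equalized / maximized sensitivity-specificity on each
    partition, a weighted balance of omission, area and threshold, and the
    area that equates the entropy of the thresholded and original
    distributions.
    """
    bg_logistic = np.asarray(bg_logistic, float)
    raw_bg = np.asarray(raw_bg, float)
    train = np.asarray(train_scores, float)
    test = np.asarray(test_scores, float)
    out: dict[str, float] = {}
    out["fixed_cumulative_1"] = _cumulative_threshold(raw_bg, bg_logistic, 1.0)
    out["fixed_cumulative_5"] = _cumulative_threshold(raw_bg, bg_logistic, 5.0)
    out["fixed_cumulative_10"] = _cumulative_threshold(raw_bg, bg_logistic, 10.0)
    out["minimum_training_presence"] = float(train.min())
    out["tenth_percentile_training_presence"] = float(np.percentile(train, 10))
    eq_tr, mx_tr = _sens_spec_thresholds(train, bg_logistic)
    out["equal_training_sensitivity_specificity"] = eq_tr
    out["maximum_training_sensitivity_plus_specificity"] = mx_tr
    eq_te, mx_te = _sens_spec_thresholds(test, bg_logistic)
    out["equal_test_sensitivity_specificity"] = eq_te
    out["maximum_test_sensitivity_plus_specificity"] = mx_te

    # balance rule: minimize 6*train_omission + 0.04*cumulative + 1.6*area
    # (cumulative at t = 100x summed raw probability of cells below t,
    # the logistic transform being monotone in raw)
    cand = np.unique(train)
    cost = []
    for t in cand:
        om = (train < t).mean()
        area = (bg_logistic >= t).mean()
        cum = 100.0 * raw_bg[bg_logistic < t].sum()
        cost.append(6.0 * om + 0.04 * cum + 1.6 * area)
    out["balance_training_omission_area"] = float(cand[int(np.argmin(cost))])

    # equate entropy: predicted area a with log(a * N) = H  =>  a = e^H / N
    n_bg = len(bg_logistic)
    a_star = min(1.0, np.exp(entropy) / n_bg)
    out["equate_entropy"] = float(np.quantile(bg_logistic, 1.0 - a_star))
    return out


def binomial_omission_tests(
    bg_logistic: np.ndarray,
    raw_bg: np.ndarray,
    entropy: float,
    train_scores: np.ndarray,
    test_scores: np.ndarray,
) -> list[OmissionTest]:
    """All eleven thresholds x both partitions, with exact binomial tails."""
    thresholds = eleven_thresholds(bg_logistic, raw_bg, entropy,
                                   train_scores, test_scores)
    bg_logistic = np.asarray(bg_logistic, float)
    tests: list[OmissionTest] = []
    for name in THRESHOLD_NAMES:
        t = thresholds[name]
        area = float((bg_logistic >= t).mean())
        for partition, scores in (("train", np.asarray(train_scores, float)),
                                  ("test", np.asarray(test_scores, float))):
            n = scores.size
            k = int((scores >= t).sum())
            p = float(binom.sf(k - 1, n, area))  # P(X >= k)
            tests.append(OmissionTest(
                name=name, threshold=float(t), omission=float((scores < t).mean()),
                predicted_area=area, p_value=p, partition=partition,
            ))
    return tests


@dataclass
class ValidationReport:
    """Replicate-averaged AUCs plus every omission test across replicates."""

    mean_train_auc: float
    mean_test_auc: float
    omission_tests: list[OmissionTest]
    n_replicates: int = 0

    @property
    def relative_auc_gap(self) -> float:
        if self.mean_train_auc == 0:
            return float("inf")
        return abs(self.mean_train_auc - self.mean_test_auc) / self.mean_train_auc

    @property
    def absolute_auc_gap(self) -> float:
        return abs(self.mean_train_auc - self.mean_test_auc)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([t.__dict__ for t in self.omission_tests])


@dataclass
class AcceptanceDecision:
    """Verdicts for the three acceptance criteria, and their conjunction."""

    accepted: bool
    auc_ok: bool
    omission_ok: bool
    gap_ok: bool
    mean_test_auc: float
    max_omission_p: float
    auc_gap: float

    def as_dict(self) -> dict:
        return dict(accepted=self.accepted, auc_ok=self.auc_ok,
                    omission_ok=self.omission_ok, gap_ok=self.gap_ok,
                    mean_test_auc=self.mean_test_auc,
                    max_omission_p=self.max_omission_p, auc_gap=self.auc_gap)


def evaluate_acceptance(
    report: ValidationReport,
    auc_min: float = 0.9,
    p_max: float = 0.05,
    gap_max: float = 0.05,
    gap_mode: str = "relative",
) -> AcceptanceDecision:
    """Apply the three-criterion acceptance rule to a validation report.

    ``gap_mode`` selects whether the train/test AUC difference is judged
    relative to the training AUC (default) or as an absolute difference.
    The omission criterion is strict: every test in every replicate must
    have p below ``p_max``.
    """
    if gap_mode not in ("relative", "absolute"):
        raise ValueError("gap_mode must be 'relative' or 'absolute'")
    auc_ok = report.mean_test_auc > auc_min
    ps = [t.p_value for t in report.omission_tests]
    max_p = max(ps) if ps else 1.0
    omission_ok = bool(ps) and max_p < p_max
    gap = (report.relative_auc_gap if gap_mode == "relative"
           else report.absolute_auc_gap)
    gap_ok = gap < gap_max
    return AcceptanceDecision(
        accepted=auc_ok and omission_ok and gap_ok,
        auc_ok=auc_ok, omission_ok=omission_ok, gap_ok=gap_ok,
        mean_test_auc=report.mean_test_auc, max_omission_p=max_p, auc_gap=gap,
    )


@dataclass
class VariableSetSelection:
    """Outcome of averaging expert ranks over candidate variable sets."""

    mean_ranks: pd.Series          # candidate id -> mean rank
    selected: list[str]
    tie_broken: bool


def aggregate_expert_ranks(table: pd.DataFrame, top_k: int = 2) -> VariableSetSelection:
    """Average independent expert ranks (1 = poor .. 5 = excellent) per
    candidate and return the ``top_k`` candidates by mean rank.

    ``table`` is experts (rows) x candidates (columns).  Candidates whose
    mean strictly exceeds the k-th best mean are always selected; when a
    boundary tie leaves more candidates than open slots, the
    lexicographically first tied ids fill them and the tie is flagged.
    """
    if table.empty or table.isna().any().any():
        raise ValueError("ranking table must be complete (no empty expert rows)")
    vals = table.to_numpy(dtype=float)
    if vals.min() < 1 or vals.max() > 5:
        raise ValueError("ranks must lie in [1, 5]")
    means = table.mean(axis=0)
    ordered = means.sort_values(ascending=False, kind="mergesort")
    cutoff = ordered.iloc[min(top_k, len(ordered)) - 1]
    above = sorted(means.index[means > cutoff].tolist())
    at = sorted(means.index[means == cutoff].tolist())
    n_slots = max(top_k - len(above), 0)
    tie = len(at) > n_slots
    selected = above + at[:n_slots]
    return VariableSetSelection(mean_ranks=means, selected=selected, tie_broken=tie)


def select_best_model_per_species(
    candidates: Mapping[str, ValidationReport],
) -> tuple[str, bool]:
    """Pick the candidate variable set with the highest mean test AUC.

    Ties go to the lexicographically lower set id; returns (id, tied).
    """
    if not candidates:
        raise ValueError("no candidate reports")
    best_auc = max(r.mean_test_auc for r in candidates.values())
    winners = sorted(k for k, r in candidates.items() if r.mean_test_auc == best_auc)
    return winners[0], len(winners) > 1
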