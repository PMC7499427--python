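"""Reader-study evaluation statistics.

Implements the diagnostic-accuracy stack used to compare a CNN's
malignancy probabilities with radiologists' calls on the same nodules:

* nonparametric ROC AUC (Mann-Whitney pair counting, ties at 1/2) with a
  DeLong standard error and Wald CI;
* DeLong's test for comparing two correlated AUCs measured on the same
  nodules;
* sensitivity / specificity / accuracy at a 0.5 threshold, reported as
  percentages with 95% CIs (Wald by default, Wilson optional);
* unweighted Cohen's kappa with the conventional interpretation bands
  (0.41-0.60 moderate, 0.61-0.80 substantial, >0.81 almost perfect);
* the two 10-point ordinal conversions — radiologist (call, 1-5 Likert
  confidence) pairs and CNN probabilities binned into deciles — plus
  low-confidence-zone (ordinals 4-7) counting and McNemar's test on
  paired zone membership.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .records import BENIGN, MALIGNANT

LOW_CONFIDENCE_ZONE = frozenset({4, 5, 6, 7})
_EXACT_MCNEMAR_MAX_DISCORDANT = 25


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AucResult:
    auc: float
    se: float
    ci_low: float
    ci_high: float


def _check_scores_labels(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-d arrays of equal length")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    if set(np.unique(labels)) != {0, 1}:
        raise ValueError("labels must contain both classes (0 and 1)")
    return scores, labels


def _delong_components(scores: np.ndarray, labels: np.ndarray):
    """Placement values V10 (positives) and V01 (negatives) of one score."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = pos.size, neg.size
    tz = stats.rankdata(np.concatenate([pos, neg]))
    tx = stats.rankdata(pos)
    ty = stats.rankdata(neg)
    v10 = (tz[:m] - tx) / n          # per-positive placements
    v01 = 1.0 - (tz[m:] - ty) / m    # per-negative placements
    auc = float(v10.mean())
    return auc, v10, v01


def roc_auc(scores, labels, alpha: float = 0.05) -> AucResult:
    """Nonparametric (Mann-Whitney) AUC with DeLong SE and Wald CI.

    Equals the proportion of positive-negative pairs ranked correctly,
    ties counted 1/2 — identical to the trapezoidal area under the
    empirical ROC curve.
    """
    scores, labels = _check_scores_labels(scores, labels)
    auc, v10, v01 = _delong_components(scores, labels)
    var = 0.0
    if v10.size > 1:
        var += np.var(v10, ddof=1) / v10.size
    if v01.size > 1:
        var += np.var(v01, ddof=1) / v01.size
    se = float(np.sqrt(var))
    z = stats.norm.ppf(1 - alpha / 2)
    return AucResult(
        auc=auc,
        se=se,
        ci_low=float(max(0.0, auc - z * se)),
        ci_high=float(min(1.0, auc + z * se)),
    )


def compare_paired_auc(scores_a, scores_b, labels) -> tuple[float, float]:
    """DeLong's two-sided test for two correlated AUCs on the same nodules.

    Returns ``(auc_a - auc_b, p_value)``.  Identical score vectors give a
    difference of 0 and p = 1.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    if scores_a.shape != scores_b.shape:
        raise ValueError("paired score vectors must have equal length")
    scores_a, labels = _check_scores_labels(scores_a, labels)
    scores_b, _ = _check_scores_labels(scores_b, labels)
    auc_a, v10_a, v01_a = _delong_components(scores_a, labels)
    auc_b, v10_b, v01_b = _delong_components(scores_b, labels)
    m, n = v10_a.size, v01_a.size
    s10 = np.cov(np.vstack([v10_a, v10_b])) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01_a, v01_b])) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    diff = auc_a - auc_b
    if var_diff <= 0:
        return diff, 1.0 if np.isclose(diff, 0.0) else 0.0
    z = diff / np.sqrt(var_diff)
    return diff, float(2 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# Threshold metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DiagnosticPerformance:
    """AUC plus threshold metrics, percentages with 95% CIs."""

    auc: float
    accuracy: float
    sensitivity: float
    sensitivity_ci: tuple[float, float]
    specificity: float
    specificity_ci: tuple[float, float]
    threshold: float
    n: int


def _proportion_ci(k: int, n: int, alpha: float, method: str) -> tuple[float, float]:
    p = k / n
    if method == "wald":
        z = stats.norm.ppf(1 - alpha / 2)
        half = z * np.sqrt(p * (1 - p) / n)
        lo, hi = p - half, p + half
    elif method == "wilson":
        z = stats.norm.ppf(1 - alpha / 2)
        den = 1 + z**2 / n
        center = (p + z**2 / (2 * n)) / den
        half = z * np.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / den
        lo, hi = center - half, center + half
    else:
        raise ValueError(f"unknown CI method {method!r}")
    return float(np.clip(lo, 0, 1) * 100), float(np.clip(hi, 0, 1) * 100)


def diagnostic_metrics(
    scores,
    labels,
    threshold: float = 0.5,
    alpha: float = 0.05,
    ci_method: str = "wald",
) -> DiagnosticPerformance:
    """Sensitivity/specificity/accuracy (in %) at ``threshold`` plus AUC.

    ``scores`` may be probabilities or already-binary calls; a score equal
    to the threshold is called malignant.
    """
    scores, labels = _check_scores_labels(scores, labels)
    calls = scores >= threshold
    pos = labels == 1
    if pos.sum() == 0:
        raise ValueError("no positive nodules: sensitivity undefined")
    if (~pos).sum() == 0:
        raise ValueError("no negative nodules: specificity undefined")
    tp = int(np.sum(calls & pos))
    tn = int(np.sum(~calls & ~pos))
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    return DiagnosticPerformance(
        auc=roc_auc(scores, labels).auc,
        accuracy=100.0 * (tp + tn) / labels.size,
        sensitivity=100.0 * tp / n_pos,
        sensitivity_ci=_proportion_ci(tp, n_pos, alpha, ci_method),
        specificity=100.0 * tn / n_neg,
        specificity_ci=_proportion_ci(tn, n_neg, alpha, ci_method),
        threshold=threshold,
        n=int(labels.size),
    )


# ---------------------------------------------------------------------------
# Agreement
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AgreementResult:
    kappa: float
    interpretation: str
    observed_agreement: float
    expected_agreement: float


def interpret_kappa(kappa: float) -> str:
    if kappa < 0:
        return "poor"
    if kappa <= 0.20:
        return "slight"
    if kappa <= 0.40:
        return "fair"
    if kappa <= 0.60:
        return "moderate"
    if kappa <= 0.80:
        return "substantial"
    return "almost perfect"


def cohen_kappa_unweighted(calls_a, calls_b) -> AgreementResult:
    """Unweighted Cohen's kappa between two paired binary call vectors."""
    a = np.asarray(calls_a, dtype=int)
    b = np.asarray(calls_b, dtype=int)
    if a.shape != b.shape or a.ndim != 1 or a.size == 0:
        raise ValueError("paired call vectors must be non-empty 1-d arrays of equal length")
    n = a.size
    p_o = float(np.mean(a == b))
    p_e = 0.0
    for cls in (0, 1):
        p_e += float(np.mean(a == cls)) * float(np.mean(b == cls))
    if np.isclose(p_e, 1.0):
        raise ValueError("chance agreement is 1 (both raters constant and equal): kappa undefined")
    kappa = (p_o - p_e) / (1 - p_e)
    return AgreementResult(
        kappa=float(kappa),
        interpretation=interpret_kappa(kappa),
        observed_agreement=p_o,
        expected_agreement=p_e,
    )


# ---------------------------------------------------------------------------
# Ordinal confidence scales
# ---------------------------------------------------------------------------

def radiologist_to_ordinal(call: str, confidence: int) -> int:
    """Map a (benign/malignant call, 1-5 Likert confidence) pair onto the
    combined 10-point scale: benign with confidence c -> 6 - c (so a
    high-confidence benign call is 1), malignant with confidence c ->
    5 + c (so a high-confidence malignant call is 10)."""
    if confidence not in (1, 2, 3, 4, 5):
        raise ValueError(f"confidence must be an integer in 1..5, got {confidence}")
    if call == BENIGN:
        return 6 - confidence
    if call == MALIGNANT:
        return 5 + confidence
    raise ValueError(f"call must be benign/malignant, got {call!r}")


def cnn_probability_to_ordinal(p: float) -> int:
    """Decile-bin a malignancy probability onto the 10-point scale:
    [0, 0.1] -> 1, (0.1, 0.2] -> 2, ..., (0.9, 1] -> 10."""
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"probability must be in [0,1], got {p}")
    return int(np.clip(np.ceil(np.round(p * 10, 9)), 1, 10))


@dataclass(frozen=True)
class ConfidenceDistribution:
    histogram: tuple[int, ...]  # counts for ordinals 1..10
    zone_count: int
    zone_fraction: float
    n: int


def low_confidence_fraction(ordinals) -> ConfidenceDistribution:
    """Count ratings in the low-confidence zone (ordinals 4, 5, 6 or 7)."""
    arr = np.asarray(ordinals, dtype=int)
    if arr.size == 0:
        raise ValueError("no ordinal ratings given")
    if np.any((arr < 1) | (arr > 10)):
        raise ValueError("ordinals must lie in 1..10")
    hist = tuple(int(np.sum(arr == level)) for level in range(1, 11))
    zone = int(np.sum(np.isin(arr, list(LOW_CONFIDENCE_ZONE))))
    return ConfidenceDistribution(
        histogram=hist,
        zone_count=zone,
        zone_fraction=zone / arr.size,
        n=int(arr.size),
    )


def mcnemar_low_confidence(zone_flags_a, zone_flags_b) -> float:
    """McNemar's test on paired binary zone-membership flags.

    Exact binomial on the discordant pairs when fewer than 25 are
    discordant, chi-square (no continuity correction) otherwise.  Zero
    discordant pairs give p = 1.
    """
    a = np.asarray(zone_flags_a, dtype=int)
    b = np.asarray(zone_flags_b, dtype=int)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired flag vectors must be 1-d arrays of equal length")
    n01 = int(np.sum((a == 0) & (b == 1)))
    n10 = int(np.sum((a == 1) & (b == 0)))
    disc = n01 + n10
    if disc == 0:
        return 1.0
    if disc < _EXACT_MCNEMAR_MAX_DISCORDANT:
        return float(stats.binomtest(n10, disc, 0.5).pvalue)
    chi2 = (n10 - n01) ** 2 / disc
    return float(stats.chi2.sf(chi2, df=1))
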