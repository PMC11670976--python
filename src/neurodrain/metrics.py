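"""Agreement and accuracy statistics for the drain pipeline.

Implements the study-level statistics: single-measure absolute-agreement
intraclass correlation from a two-way random-effects ANOVA (ICC(2,1)),
Bland-Altman limits of agreement with the outlier rule, Fleiss' kappa for
multi-rater categorical agreement, exact binomial (Clopper-Pearson)
confidence intervals for accuracy / sensitivity / specificity, and the
Mann-Whitney ROC-AUC with a DeLong confidence interval.

Sample standard deviations use the n-1 denominator throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "BinomialProportion",
    "ConfusionMetrics",
    "AgreementReport",
    "clopper_pearson",
    "confusion_metrics",
    "icc_2_1",
    "bland_altman",
    "fleiss_kappa",
    "roc_auc",
]


@dataclass
class BinomialProportion:
    """A proportion k/n with its exact 95% Clopper-Pearson interval."""

    value: float
    count: int
    nobs: int
    ci_low: float
    ci_high: float


@dataclass
class ConfusionMetrics:
    tp: int
    fn: int
    tn: int
    fp: int
    accuracy: BinomialProportion
    sensitivity: BinomialProportion
    specificity: BinomialProportion


@dataclass
class AgreementReport:
    """Bland-Altman summary of paired differences d = x - y."""

    bias: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    outlier_count: int
    outlier_fraction: float
    n: int


def clopper_pearson(count: int, nobs: int, alpha: float = 0.05) -> BinomialProportion:
    """Exact binomial proportion CI (always contains the point estimate)."""
    if nobs <= 0:
        raise ValueError("nobs must be positive")
    lo, hi = proportion_confint(count, nobs, alpha=alpha, method="beta")
    return BinomialProportion(count / nobs, int(count), int(nobs),
                              float(lo), float(hi))


def confusion_metrics(pred, truth) -> ConfusionMetrics:
    """Accuracy / sensitivity / specificity with exact 95% CIs.

    ``truth`` defines the positive class (True).  Sensitivity is the
    retained fraction of positives, specificity of negatives; either is
    reported as NaN (with a warning) when its class is absent.
    """
    pred = np.asarray(pred, bool).ravel()
    truth = np.asarray(truth, bool).ravel()
    if pred.shape != truth.shape or pred.size == 0:
        raise ValueError("pred and truth must be equal-length and nonempty")
    tp = int(np.sum(pred & truth))
    fn = int(np.sum(~pred & truth))
    fp = int(np.sum(pred & ~truth))
    tn = int(np.sum(~pred & ~truth))
    acc = clopper_pearson(tp + tn, tp + fn + fp + tn)

    def _rate(k, n, name):
        if n == 0:
            warnings.warn(f"{name} undefined: class absent", RuntimeWarning)
            return BinomialProportion(np.nan, 0, 0, np.nan, np.nan)
        return clopper_pearson(k, n)

    sens = _rate(tp, tp + fn, "sensitivity")
    spec = _rate(tn, tn + fp, "specificity")
    return ConfusionMetrics(tp, fn, tn, fp, acc, sens, spec)


def _icc_anova(ratings: np.ndarray):
    n, k = ratings.shape
    grand = ratings.mean()
    subj = ratings.mean(axis=1)
    rater = ratings.mean(axis=0)
    msr = k * np.sum((subj - grand) ** 2) / (n - 1)
    msc = n * np.sum((rater - grand) ** 2) / (k - 1)
    resid = ratings - subj[:, None] - rater[None, :] + grand
    mse = np.sum(resid ** 2) / ((n - 1) * (k - 1))
    return msr, msc, mse


def icc_2_1(x, y=None, alpha: float = 0.05):
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    Parameters
    ----------
    x, y : array-like
        Either two paired rating vectors, or ``x`` alone as an (n, k)
        subjects-by-raters matrix.

    Returns
    -------
    (icc, (ci_low, ci_high))
        Point estimate with the F-distribution based 95% interval of
        Shrout & Fleiss.
    """
    if y is not None:
        ratings = np.column_stack([np.asarray(x, float), np.asarray(y, float)])
    else:
        ratings = np.asarray(x, float)
    if ratings.ndim != 2 or ratings.shape[0] < 3 or ratings.shape[1] < 2:
        raise ValueError("need at least 3 subjects and 2 raters")
    if not np.all(np.isfinite(ratings)):
        raise ValueError("ratings must be finite (no missing cells)")
    n, k = ratings.shape
    msr, msc, mse = _icc_anova(ratings)
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom <= 1e-30 or msr <= 1e-12 * max(msc, mse, 1.0):
        warnings.warn("zero between-subject variance; ICC -> 0", RuntimeWarning)
        return 0.0, (0.0, 0.0)
    icc = (msr - mse) / denom

    # Satterthwaite df for the absolute-agreement interval
    fj = msc / mse if mse > 0 else np.inf
    if np.isfinite(fj):
        a = k * icc * fj + n * (1 + (k - 1) * icc) - k * icc
        vn = (k - 1) * (n - 1) * a ** 2
        vd = (n - 1) * k ** 2 * icc ** 2 * fj ** 2 \
            + (n * (1 + (k - 1) * icc) - k * icc) ** 2
        v = vn / vd if vd > 0 else np.inf
    else:
        v = float(k - 1)   # exact-agreement limit (MSE -> 0)
    f1 = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f2 = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - f1 * mse) / (
        f1 * (k * msc + (k * n - k - n) * mse) + n * msr)
    upper = n * (f2 * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f2 * msr)
    return float(icc), (float(lower), float(upper))


def bland_altman(x, y) -> AgreementReport:
    """Bland-Altman agreement of paired measurements.

    Differences d = x - y; bias = mean(d); limits of agreement =
    bias +/- 1.96 * SD(d).  A pair is an *outlier* when |d - bias|
    exceeds 1.96 * SD(d), i.e. when it falls outside the limits of
    agreement (about 5% expected under normal differences).
    """
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need >= 3 equal-length pairs")
    d = x - y
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    half = 1.96 * sd
    out = np.abs(d - bias) > half
    return AgreementReport(bias, sd, bias - half, bias + half,
                           int(out.sum()), float(out.mean()), x.size)


def fleiss_kappa(ratings) -> float:
    """Fleiss' kappa for n subjects rated by k raters into categories.

    ``ratings`` is an (n, k) array of categorical labels (any hashable
    values; binary correct / not-correct in this study).  Returns the
    chance-corrected agreement kappa = (Pbar - Pe) / (1 - Pe).
    Raises when every rating is one category (Pe = 1, undefined).
    """
    ratings = np.asarray(ratings)
    if ratings.ndim != 2 or ratings.shape[0] < 2 or ratings.shape[1] < 2:
        raise ValueError("need >= 2 subjects and >= 2 raters")
    n, k = ratings.shape
    cats = np.unique(ratings)
    counts = np.stack([(ratings == c).sum(axis=1) for c in cats], axis=1)
    p_j = counts.sum(axis=0) / (n * k)
    pe = float(np.sum(p_j ** 2))
    if pe >= 1.0 - 1e-15:
        raise ValueError("all ratings identical: expected agreement is 1, "
                         "kappa undefined")
    p_i = (np.sum(counts ** 2, axis=1) - k) / (k * (k - 1))
    pbar = float(p_i.mean())
    return (pbar - pe) / (1 - pe)


def _delong_variance(pos: np.ndarray, neg: np.ndarray) -> float:
    m, n = len(pos), len(neg)
    # placement values via mid-ranks (ties counted half)
    all_scores = np.concatenate([pos, neg])
    r_all = stats.rankdata(all_scores)
    r_pos = stats.rankdata(pos)
    r_neg = stats.rankdata(neg)
    v10 = (r_all[:m] - r_pos) / n          # P(X > Y) component per positive
    v01 = 1.0 - (r_all[m:] - r_neg) / m    # per negative
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def roc_auc(scores, truth, alpha: float = 0.05):
    """ROC-AUC as the Mann-Whitney statistic (ties counted 1/2) with a
    DeLong 95% confidence interval.

    ``truth`` is boolean (True = positive class); higher scores should
    rank positives higher.  Raises when only one class is present.
    """
    scores = np.asarray(scores, float).ravel()
    truth = np.asarray(truth, bool).ravel()
    if scores.shape != truth.shape:
        raise ValueError("scores and truth must be equal length")
    pos, neg = scores[truth], scores[~truth]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present for ROC-AUC")
    r = stats.rankdata(np.concatenate([pos, neg]))
    auc = (r[:len(pos)].sum() - len(pos) * (len(pos) + 1) / 2) / (len(pos) * len(neg))
    se = np.sqrt(_delong_variance(pos, neg))
    z = stats.norm.ppf(1 - alpha / 2)
    lo = max(0.0, auc - z * se)
    hi = min(1.0, auc + z * se)
    return float(auc), (float(lo), float(hi))
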