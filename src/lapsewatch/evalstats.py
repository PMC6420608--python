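"""Classifier evaluation (ROC/AUC) and BCa bootstrap confidence intervals.

CoP_MAD is evaluated as a per-trial lapse classifier: higher postural
instability is taken as more lapse-like, a criterion is swept over the
score, and the resulting ROC's area (AUC) equals the probability that a
random lapse trial outranks a random non-lapse trial, with ties counting
one half (the Mann–Whitney convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy.special import ndtr, ndtri
from sklearn import metrics as _skm

from .errors import ValidationError
from .session import SessionRecord, tag_lapses

__all__ = [
    "ROCCurve",
    "BootstrapCI",
    "roc_curve",
    "auc",
    "bca_bootstrap_ci",
    "classifier_report",
]


@dataclass
class ROCCurve:
    """ROC operating points from a descending criterion sweep.

    A trial is classified "lapse" when its score is >= the criterion, so
    ``fpr`` and ``tpr`` are nondecreasing along the sweep, starting at
    (0, 0) and ending at (1, 1).
    """

    criteria: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    n_pos: int = 0
    n_neg: int = 0

    def __post_init__(self) -> None:
        self.criteria = np.asarray(self.criteria, dtype=float)
        self.fpr = np.asarray(self.fpr, dtype=float)
        self.tpr = np.asarray(self.tpr, dtype=float)
        for name, arr in (("fpr", self.fpr), ("tpr", self.tpr)):
            if np.any(arr < -1e-12) or np.any(arr > 1 + 1e-12):
                raise ValidationError(f"{name} values must lie in [0, 1]")
            if np.any(np.diff(arr) < -1e-12):
                raise ValidationError(f"{name} must be nondecreasing")
        if not (0.0 <= self.auc <= 1.0):
            raise ValidationError("auc must lie in [0, 1]")


@dataclass
class BootstrapCI:
    """A bootstrap confidence interval with its method diagnostics."""

    lo: float
    hi: float
    level: float = 0.95
    n_resamples: int = 20000
    method: str = "BCa"
    estimate: Optional[float] = None
    z0: Optional[float] = None
    acceleration: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0.0 < self.level < 1.0):
            raise ValidationError("confidence level must be in (0, 1)")
        if self.lo > self.hi:
            raise ValidationError("interval lo must be <= hi")


def roc_curve(scores, labels) -> ROCCurve:
    """Sweep a "score >= criterion -> lapse" rule over all unique scores.

    *labels* are boolean lapse tags (True = lapse, the positive class).
    Requires at least one positive and one negative label and finite
    scores.  All operating points are kept (no convex-hull thinning).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValidationError("scores and labels must be equal-length 1-D")
    if not np.all(np.isfinite(scores)):
        raise ValidationError("scores must be finite")
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0:
        raise ValidationError("no positive (lapse) labels present")
    if n_neg == 0:
        raise ValidationError("no negative (non-lapse) labels present")
    fpr, tpr, thr = _skm.roc_curve(labels, scores, drop_intermediate=False)
    area = float(np.trapezoid(tpr, fpr))
    return ROCCurve(criteria=thr, fpr=fpr, tpr=tpr, auc=area,
                    n_pos=n_pos, n_neg=n_neg)


def auc(curve: ROCCurve) -> float:
    """Trapezoidal area under an ROC curve.

    Equals the tie-adjusted pairwise concordance probability
    P(score_pos > score_neg) + 0.5 P(score_pos = score_neg).
    """
    return float(np.trapezoid(curve.tpr, curve.fpr))


def bca_bootstrap_ci(
    data,
    statistic: Callable[[np.ndarray], float],
    level: float = 0.95,
    n_resamples: int = 20000,
    seed: Optional[int] = None,
) -> BootstrapCI:
    """Bias-corrected and accelerated (BCa) percentile bootstrap interval.

    The bias correction ``z0`` is the normal quantile of the proportion of
    bootstrap replicates below the point estimate (ties counted one half);
    the acceleration ``a`` comes from the jackknife skewness of the
    statistic.  Both adjust the percentile endpoints of the replicate
    distribution.

    Parameters
    ----------
    data
        1-D sample of scalars, or a 2-D array whose *rows* are resampled
        jointly (e.g. (score, label) pairs).
    statistic
        Function of a resampled array returning a scalar; may return NaN
        on degenerate resamples, which are then dropped with a warning.
    """
    data = np.asarray(data, dtype=float)
    n = data.shape[0]
    if n < 3:
        raise ValidationError("BCa needs a sample of size >= 3")
    if not (0.0 < level < 1.0):
        raise ValidationError("confidence level must be in (0, 1)")
    if n_resamples < 1:
        raise ValidationError("n_resamples must be >= 1")

    rng = np.random.default_rng(seed)
    theta_hat = float(statistic(data))

    idx = rng.integers(0, n, size=(n_resamples, n))
    reps = np.array([statistic(data[ix]) for ix in idx], dtype=float)
    bad = ~np.isfinite(reps)
    if bad.any():
        warnings.warn(
            f"dropping {int(bad.sum())} degenerate bootstrap replicate(s)",
            RuntimeWarning,
            stacklevel=2,
        )
        reps = reps[~bad]
        if reps.size == 0:
            raise ValidationError("all bootstrap replicates were degenerate")

    if np.ptp(reps) == 0.0:
        warnings.warn(
            "degenerate bootstrap distribution; returning a point interval",
            RuntimeWarning,
            stacklevel=2,
        )
        v = float(reps[0])
        return BootstrapCI(lo=v, hi=v, level=level, n_resamples=n_resamples,
                           estimate=theta_hat, z0=0.0, acceleration=0.0)

    b = reps.size
    prop = (np.sum(reps < theta_hat) + 0.5 * np.sum(reps == theta_hat)) / b
    prop = min(max(prop, 1.0 / (b + 1)), b / (b + 1.0))
    z0 = float(ndtri(prop))

    # jackknife acceleration (skewness of leave-one-out estimates)
    jack = np.empty(n)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        jack[i] = statistic(data[mask])
        mask[i] = True
    d = jack.mean() - jack
    denom = np.sum(d**2) ** 1.5
    a = float(np.sum(d**3) / (6.0 * denom)) if denom > 0 else 0.0

    alpha = 1.0 - level
    lo_hi = []
    for z_alpha in (ndtri(alpha / 2.0), ndtri(1.0 - alpha / 2.0)):
        num = z0 + z_alpha
        adj = ndtr(z0 + num / (1.0 - a * num))
        lo_hi.append(float(np.quantile(reps, adj)))
    return BootstrapCI(lo=lo_hi[0], hi=lo_hi[1], level=level,
                       n_resamples=n_resamples, estimate=theta_hat,
                       z0=z0, acceleration=a)


def classifier_report(
    session: SessionRecord,
    score_field: str = "cop_mad_sma",
    level: float = 0.95,
    n_resamples: int = 20000,
    seed: Optional[int] = None,
) -> dict:
    """ROC/AUC report for CoP_MAD as a lapse classifier on catch trials.

    Extracts catch-trial scores (``cop_mad`` or ``cop_mad_sma``) and lapse
    tags, builds the ROC, and attaches a BCa bootstrap interval for the AUC
    obtained by resampling catch trials (scores and labels jointly).  The
    classification direction — higher score means "lapse" — is recorded in
    the report so an inverse per-observer pattern remains representable.
    """
    if score_field not in ("cop_mad", "cop_mad_sma"):
        raise ValidationError(
            "score_field must be 'cop_mad' or 'cop_mad_sma'"
        )
    labels = tag_lapses(session)
    raw_scores = [getattr(t, score_field) for t in session.catch_trials]
    if any(s is None for s in raw_scores):
        raise ValidationError(
            f"score field {score_field!r} absent on some catch trials"
        )
    scores = np.asarray(raw_scores, dtype=float)
    curve = roc_curve(scores, labels)

    def auc_stat(rows: np.ndarray) -> float:
        lab = rows[:, 1] > 0.5
        if lab.all() or not lab.any():
            return np.nan
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return _skm.roc_auc_score(lab, rows[:, 0])

    pairs = np.column_stack([scores, labels.astype(float)])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        ci = bca_bootstrap_ci(pairs, auc_stat, level=level,
                              n_resamples=n_resamples, seed=seed)
    return {
        "score_field": score_field,
        "direction": "higher_score_means_lapse",
        "auc": curve.auc,
        "auc_ci": [ci.lo, ci.hi],
        "ci_level": level,
        "ci_method": ci.method,
        "n_resamples": n_resamples,
        "n_pos": curve.n_pos,
        "n_neg": curve.n_neg,
        "points": [
            {"criterion": float(c), "fpr": float(f), "tpr": float(t)}
            for c, f, t in zip(curve.criteria, curve.fpr, curve.tpr)
        ],
    }
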