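"""Mapping postural-instability scores to per-trial non-lapse weights.

The adaptive procedure consumes a weight ``alpha`` in [0, 1] per trial:
``alpha = 1 - P(lapse | score)``, so a definite lapse gets 0 (the trial is
ignored) and definite concentration gets 1 (a full Bayes update).  The
lapse probability is modeled as a logistic function of the smoothed
CoP_MAD score and can be calibrated by maximum likelihood from labeled
catch trials — the only trials on which ground truth (a missed
suprathreshold stimulus) is observable.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import statsmodels.api as sm
from scipy.special import expit

from .errors import CalibrationError, ValidationError

MAPPING_KINDS = ("logistic", "threshold", "constant")
DEFAULT_ALPHA_FLOOR = 0.05
DEFAULT_MAX_STEEPNESS = 100.0


@dataclass
class AlphaMapping:
    """Score -> lapse-probability mapping producing alpha = 1 - p.

    kinds:
      * ``logistic``: p(lapse|s) = expit(steepness * (s - midpoint));
        steepness >= 0 so alpha is nonincreasing in the score.
      * ``threshold``: hard step, p = 1 for score >= midpoint else 0.
      * ``constant``: p = p_lapse regardless of score.

    ``floor``/``ceiling`` clamp alpha: a small floor (default 0.05) bounds
    the damage a miscalibrated mapping can do, since a fully discarded
    trial can never be recovered.
    """

    kind: str = "logistic"
    midpoint: float = 0.0
    steepness: float = 1.0
    floor: float = DEFAULT_ALPHA_FLOOR
    ceiling: float = 1.0
    p_lapse: float = 0.0
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in MAPPING_KINDS:
            raise ValidationError(f"kind must be one of {MAPPING_KINDS}")
        if self.steepness < 0:
            raise ValidationError("steepness must be >= 0")
        if not (0.0 <= self.floor <= self.ceiling <= 1.0):
            raise ValidationError("need 0 <= floor <= ceiling <= 1")
        if not (0.0 <= self.p_lapse <= 1.0):
            raise ValidationError("p_lapse must be in [0, 1]")
        if not np.isfinite(self.midpoint):
            raise ValidationError("midpoint must be finite")

    def to_json(self, path) -> None:
        payload = asdict(self)
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "AlphaMapping":
        with open(path, encoding="utf-8") as fh:
            return cls(**json.load(fh))


def lapse_probability(score, mapping: AlphaMapping) -> np.ndarray:
    """P(lapse | score) under the mapping, before any alpha clamping."""
    s = np.asarray(score, dtype=float)
    if not np.all(np.isfinite(s)):
        raise ValidationError("score must be finite")
    if mapping.kind == "logistic":
        return expit(mapping.steepness * (s - mapping.midpoint))
    if mapping.kind == "threshold":
        return (s >= mapping.midpoint).astype(float)
    return np.full_like(s, mapping.p_lapse, dtype=float)


def alpha_from_score(score, mapping: AlphaMapping):
    """Non-lapse weight alpha = clamp(1 - P(lapse|score), floor, ceiling)."""
    a = np.clip(1.0 - lapse_probability(score, mapping),
                mapping.floor, mapping.ceiling)
    return float(a) if np.isscalar(score) or np.ndim(score) == 0 else a


def calibrate_mapping(
    scores,
    lapses,
    floor: float = DEFAULT_ALPHA_FLOOR,
    ceiling: float = 1.0,
    max_steepness: float = DEFAULT_MAX_STEEPNESS,
) -> AlphaMapping:
    """Fit a two-parameter logistic lapse-probability model by ML.

    *scores* are (smoothed) CoP_MAD values on catch trials and *lapses*
    their boolean lapse tags; requires >= 10 pairs with both classes
    present.  The returned mapping's steepness is the fitted slope clipped
    into [0, max_steepness] (a separation guard and the monotonicity
    constraint of the mapping); the raw fitted coefficients and their
    standard errors are kept in ``mapping.diagnostics``.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(lapses, dtype=bool)
    if s.shape != y.shape or s.ndim != 1:
        raise ValidationError("scores and lapses must be equal-length 1-D")
    if s.size < 10:
        raise ValidationError("need at least 10 labeled catch trials")
    if not np.all(np.isfinite(s)):
        raise ValidationError("scores must be finite")
    if y.all() or not y.any():
        missing = "non-lapse" if y.all() else "lapse"
        raise ValidationError(f"no {missing} examples among the labels")

    X = sm.add_constant(s)
    separated = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y.astype(float), X).fit(disp=0, maxiter=200)
            converged = bool(res.mle_retvals.get("converged", False))
            b0, b1 = (float(v) for v in res.params)
            bse = [float(v) for v in res.bse]
        except Exception as exc:  # perfect separation raises in statsmodels
            separated = True
            converged = True
            b0, b1, bse = np.nan, np.nan, [np.nan, np.nan]
            sep_reason = repr(exc)

    if not separated and (not converged or not np.isfinite(b1)):
        raise CalibrationError(
            "logistic calibration failed to converge",
            diagnostics={"converged": converged, "params": [b0, b1]},
        )

    if separated or abs(b1) > max_steepness:
        # perfectly (or nearly) separated scores: cap the slope and place
        # the midpoint between the two classes
        steep = max_steepness
        pos, neg = s[y], s[~y]
        midpoint = float((neg.max() + pos.min()) / 2.0) \
            if neg.max() < pos.min() else float(np.median(s))
    else:
        steep = float(np.clip(b1, 0.0, max_steepness))
        midpoint = float(-b0 / b1) if abs(b1) > 1e-12 else float(np.median(s))

    diagnostics = {
        "n": int(s.size),
        "n_lapse": int(y.sum()),
        "converged": converged,
        "separated": separated,
        "intercept_raw": b0,
        "slope_raw": b1,
        "intercept_se": bse[0],
        "slope_se": bse[1],
    }
    if separated:
        diagnostics["separation"] = sep_reason
    return AlphaMapping(
        kind="logistic",
        midpoint=midpoint,
        steepness=steep,
        floor=floor,
        ceiling=ceiling,
        diagnostics=diagnostics,
    )
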