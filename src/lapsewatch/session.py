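"""Trial and session containers, lapse tagging, and molar summaries.

A 2AFC psychophysical session interleaves adaptive *test* trials with
suprathreshold *catch* trials.  A lapse is an incorrect response on a catch
trial — a stimulus every attentive observer should get right — and the
session-level lapse rate is ``2L`` where ``L`` is the proportion of catch
trials lapsed (the factor 2 corrects for 50% correct guessing in 2AFC).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .copkit import smooth_sma
from .errors import FormatError, ValidationError

TRIAL_KINDS = ("test", "catch")
ATTENTION_STATES = ("attentive", "lapsed")

TRIAL_TABLE_COLUMNS = [
    "index",
    "kind",
    "stimulus_magnitude",
    "response_correct",
    "cop_mad",
    "cop_mad_sma",
    "alpha",
    "true_state",
]


@dataclass
class TrialRecord:
    """One trial: kind, stimulus, response, and optional CoP/weight fields.

    ``true_state`` is simulation ground truth only; it is never available
    for human data.
    """

    index: int
    kind: str
    stimulus_magnitude: float
    response_correct: bool
    cop_mad: Optional[float] = None
    cop_mad_sma: Optional[float] = None
    alpha: Optional[float] = None
    true_state: Optional[str] = None

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ValidationError("trial index must be >= 1")
        if self.kind not in TRIAL_KINDS:
            raise ValidationError(f"kind must be one of {TRIAL_KINDS}")
        if not np.isfinite(self.stimulus_magnitude):
            raise ValidationError("stimulus_magnitude must be finite")
        if self.alpha is not None and not (0.0 <= self.alpha <= 1.0):
            raise ValidationError("alpha must be in [0, 1]")
        if self.true_state is not None and self.true_state not in ATTENTION_STATES:
            raise ValidationError(
                f"true_state must be one of {ATTENTION_STATES}"
            )


@dataclass
class SessionRecord:
    """Ordered trials plus the configuration and seed that produced them."""

    trials: list[TrialRecord]
    config: object = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        idx = [t.index for t in self.trials]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValidationError("trial indices must be strictly increasing")

    @property
    def catch_trials(self) -> list[TrialRecord]:
        return [t for t in self.trials if t.kind == "catch"]

    @property
    def test_trials(self) -> list[TrialRecord]:
        return [t for t in self.trials if t.kind == "test"]

    @property
    def n_trials(self) -> int:
        return len(self.trials)


def tag_lapses(session: SessionRecord) -> np.ndarray:
    """Boolean lapse tag per catch trial: True iff the response was wrong.

    Test trials are untouched; raises if the session has no catch trials.
    """
    catch = session.catch_trials
    if not catch:
        raise ValidationError("session has no catch trials to tag")
    return np.array([not t.response_correct for t in catch], dtype=bool)


def raw_lapse_proportion(session: SessionRecord) -> float:
    """Uncorrected proportion L of catch trials on which a lapse occurred."""
    tags = tag_lapses(session)
    return float(np.mean(tags))


def lapse_rate(session: SessionRecord) -> float:
    """Session lapse rate ``min(1, 2 L)``.

    L is the proportion of lapsed catch trials; the doubling corrects for
    2AFC chance (half of true lapses still come out correct by guessing).
    Clamped at 1 since L > 0.5 would otherwise produce an uninterpretable
    rate above 1.
    """
    return min(1.0, 2.0 * raw_lapse_proportion(session))


def mean_cop_mad(session: SessionRecord) -> float:
    """Arithmetic mean of the available per-trial CoP_MAD values."""
    vals = [t.cop_mad for t in session.trials if t.cop_mad is not None]
    if not vals:
        raise ValidationError("no cop_mad values present in session")
    return float(np.mean(vals))


def split_half_series(session: SessionRecord) -> tuple[np.ndarray, np.ndarray]:
    """Partition per-trial CoP_MAD values by odd/even trial index.

    Returns ``(odd_half, even_half)``; used for split-half reliability of
    mean CoP_MAD.  Raises unless both halves are non-empty.
    """
    usable = [t for t in session.trials if t.cop_mad is not None]
    if len(usable) < 2:
        raise ValidationError("need >= 2 trials with cop_mad for a split")
    odd = np.array([t.cop_mad for t in usable if t.index % 2 == 1], dtype=float)
    even = np.array([t.cop_mad for t in usable if t.index % 2 == 0], dtype=float)
    if odd.size == 0 or even.size == 0:
        raise ValidationError("one parity half is empty; cannot split")
    return odd, even


def attach_sma(session: SessionRecord, window_n: int = 2,
               scope: str = "catch") -> SessionRecord:
    """Fill ``cop_mad_sma`` by smoothing the CoP_MAD series across trials.

    scope="catch" smooths the catch-trial subseries (one smoothed value per
    catch trial, the layout used for lapse classification); scope="all"
    smooths over every trial in session order.  Trials without a cop_mad
    value are skipped and keep ``cop_mad_sma = None``.
    """
    if scope not in ("catch", "all"):
        raise ValidationError("scope must be 'catch' or 'all'")
    pool = session.catch_trials if scope == "catch" else session.trials
    usable = [t for t in pool if t.cop_mad is not None]
    if usable:
        smoothed = smooth_sma([t.cop_mad for t in usable], window_n)
        for t, v in zip(usable, smoothed):
            t.cop_mad_sma = float(v)
    return session


def session_summary(session: SessionRecord) -> dict:
    """Molar (per-session) summary as a JSON-serializable dict."""
    summary = {
        "n_test": len(session.test_trials),
        "n_catch": len(session.catch_trials),
        "lapse_rate": None,
        "raw_lapse_proportion": None,
        "mean_cop_mad": None,
        "seed": session.seed,
    }
    if session.catch_trials:
        summary["lapse_rate"] = lapse_rate(session)
        summary["raw_lapse_proportion"] = raw_lapse_proportion(session)
    if any(t.cop_mad is not None for t in session.trials):
        summary["mean_cop_mad"] = mean_cop_mad(session)
    return summary


def write_trial_table(session: SessionRecord, path) -> None:
    """Write the trial table CSV (blank cells for absent optionals)."""
    rows = []
    for t in session.trials:
        rows.append(
            {
                "index": t.index,
                "kind": t.kind,
                "stimulus_magnitude": t.stimulus_magnitude,
                "response_correct": t.response_correct,
                "cop_mad": t.cop_mad,
                "cop_mad_sma": t.cop_mad_sma,
                "alpha": t.alpha,
                "true_state": t.true_state,
            }
        )
    pd.DataFrame(rows, columns=TRIAL_TABLE_COLUMNS).to_csv(path, index=False)


def _opt_float(v) -> Optional[float]:
    return None if pd.isna(v) else float(v)


def read_trial_table(path, seed: Optional[int] = None) -> SessionRecord:
    """Read a trial table CSV written by :func:`write_trial_table`."""
    df = pd.read_csv(path)
    missing = [c for c in ("index", "kind", "stimulus_magnitude",
                           "response_correct") if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s) {missing!r} in {path}")
    trials = []
    for _, row in df.iterrows():
        trials.append(
            TrialRecord(
                index=int(row["index"]),
                kind=str(row["kind"]),
                stimulus_magnitude=float(row["stimulus_magnitude"]),
                response_correct=bool(row["response_correct"]),
                cop_mad=_opt_float(row.get("cop_mad")),
                cop_mad_sma=_opt_float(row.get("cop_mad_sma")),
                alpha=_opt_float(row.get("alpha")),
                true_state=(None if pd.isna(row.get("true_state"))
                            else str(row["true_state"])),
            )
        )
    return SessionRecord(trials=trials, seed=seed)


def write_session_summary(session: SessionRecord, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(session_summary(session), fh, indent=2)
        fh.write("\n")
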