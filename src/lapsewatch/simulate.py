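"""Synthetic 2AFC sessions with a two-state attention process and CoP sway.

The generator reproduces the statistical structure the analysis assumes:
an observer with a known psychometric function completes adaptive test
trials (default 225) with suprathreshold catch trials (+30 task units)
interleaved every six to nine trials; a two-state Markov attention process
switches between "attentive" and "lapsed"; on lapsed trials responses are
pure 2AFC guesses (50% correct, independent of the stimulus); and each
trial carries an AR(1) center-of-pressure trace whose innovation SD is
inflated in the lapsed state, so within-trial CoP dispersion carries
information about lapses.

One master seed spawns independent per-component streams (scheduling,
attention, responses, CoP) so components can be varied independently while
a full session stays byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import yaml
from scipy.signal import lfilter

from . import copkit
from .adaptive import (
    ParameterGrid,
    PsychometricModel,
    QuestEngine,
    StimulusDomain,
    StopPolicy,
    make_default_domain,
    make_default_grid,
)
from .copkit import CoPTrace, compute_cop_mad
from .engagement import AlphaMapping, alpha_from_score
from .errors import ValidationError
from .session import SessionRecord, TrialRecord, attach_sma

ATTENTIVE, LAPSED = "attentive", "lapsed"


@dataclass
class AttentionProcess:
    """Two-state Markov chain over per-trial attention.

    ``p_enter`` is the attentive->lapsed transition probability per trial,
    ``p_exit`` the lapsed->attentive one.  When both are positive the
    stationary probability of being lapsed is p_enter/(p_enter+p_exit).
    Defaults give ~2% lapse occupancy in episodes of ~3 trials, i.e. an
    expected lapse rate (2L) near the 1.9% typical of cooperative
    observers.
    """

    p_enter: float = 0.006
    p_exit: float = 0.3
    initial_state: str = ATTENTIVE

    def __post_init__(self) -> None:
        for name, p in (("p_enter", self.p_enter), ("p_exit", self.p_exit)):
            if not (0.0 <= p <= 1.0):
                raise ValidationError(f"{name} must be in [0, 1]")
        if self.initial_state not in (ATTENTIVE, LAPSED):
            raise ValidationError("initial_state must be attentive|lapsed")

    @property
    def stationary_lapse_occupancy(self) -> float:
        if self.p_enter + self.p_exit == 0:
            raise ValidationError("stationary occupancy undefined for 0/0")
        return self.p_enter / (self.p_enter + self.p_exit)


@dataclass
class CoPGenParams:
    """AR(1) sway-trace generator parameters.

    Each coordinate follows x_k = ar_coef * x_{k-1} + e_k with innovation
    SD chosen by the attention state; the 0.95 default at 50 Hz gives
    slowly drifting traces qualitatively like seated sway.  Units are
    abstract device units throughout.
    """

    ar_coef: float = 0.95
    sd_attentive: float = 1.0
    sd_lapsed: float = 2.0
    fs: float = copkit.DEFAULT_SAMPLE_RATE_HZ
    trial_duration: float = 3.5

    def __post_init__(self) -> None:
        if not (0.0 <= self.ar_coef < 1.0):
            raise ValidationError("ar_coef must be in [0, 1)")
        if self.sd_attentive < 0 or self.sd_lapsed < 0:
            raise ValidationError("innovation SDs must be >= 0")
        if self.fs <= 0:
            raise ValidationError("fs must be > 0")
        if self.trial_duration * self.fs < 1:
            raise ValidationError("trial must span at least one sample")


@dataclass
class SessionConfig:
    """Full specification of a simulated session."""

    n_test: int = 225
    catch_gap: tuple[int, int] = (6, 9)
    catch_magnitude: float = 30.0
    observer: PsychometricModel = field(
        default_factory=lambda: PsychometricModel(threshold=11.5, slope=3.0)
    )
    attention: AttentionProcess = field(default_factory=AttentionProcess)
    cop: CoPGenParams = field(default_factory=CoPGenParams)
    seed: int = 0
    sma_window: int = 2
    sma_scope: str = "catch"
    gap_scope: str = "all"

    def __post_init__(self) -> None:
        if self.n_test < 1:
            raise ValidationError("n_test must be >= 1")
        lo, hi = self.catch_gap
        if not (1 <= lo <= hi):
            raise ValidationError("catch_gap must satisfy 1 <= lo <= hi")
        if self.gap_scope not in ("all", "test"):
            raise ValidationError("gap_scope must be 'all' or 'test'")

    @classmethod
    def from_dict(cls, d: dict) -> "SessionConfig":
        d = dict(d)
        if "observer" in d and isinstance(d["observer"], dict):
            d["observer"] = PsychometricModel(**d["observer"])
        if "attention" in d and isinstance(d["attention"], dict):
            d["attention"] = AttentionProcess(**d["attention"])
        if "cop" in d and isinstance(d["cop"], dict):
            d["cop"] = CoPGenParams(**d["cop"])
        if "catch_gap" in d:
            d["catch_gap"] = tuple(d["catch_gap"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SessionConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return {
            "n_test": self.n_test,
            "catch_gap": list(self.catch_gap),
            "catch_magnitude": self.catch_magnitude,
            "observer": vars(self.observer).copy(),
            "attention": vars(self.attention).copy(),
            "cop": vars(self.cop).copy(),
            "seed": self.seed,
            "sma_window": self.sma_window,
            "sma_scope": self.sma_scope,
            "gap_scope": self.gap_scope,
        }


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def simulate_attention_sequence(process: AttentionProcess, n: int,
                                seed=None) -> np.ndarray:
    """Realize the Markov attention chain over n trials (array of state names)."""
    if n < 1:
        raise ValidationError("n must be >= 1")
    rng = _rng(seed)
    u = rng.random(n)
    states = np.empty(n, dtype="<U9")
    cur = process.initial_state
    for i in range(n):
        states[i] = cur
        flip = u[i] < (process.p_enter if cur == ATTENTIVE else process.p_exit)
        if flip:
            cur = LAPSED if cur == ATTENTIVE else ATTENTIVE
    return states


def schedule_catch_trials(n_test: int, gap_range=(6, 9), seed=None,
                          gap_scope: str = "all") -> np.ndarray:
    """Draw 1-based catch positions in the merged test+catch trial stream.

    Successive catch trials are separated by gaps drawn uniformly from
    {lo..hi}.  With gap_scope="all" the gap counts positions in the merged
    stream; with "test" it counts intervening test trials only.  Catches
    are placed until the test trials are exhausted, so interleaving always
    preserves ``n_test``.
    """
    lo, hi = int(gap_range[0]), int(gap_range[1])
    if lo < 1:
        raise ValidationError("gap lower bound must be >= 1")
    if lo > hi:
        raise ValidationError("gap range must satisfy lo <= hi")
    rng = _rng(seed)
    positions: list[int] = []
    pos = 0
    tests_before = 0
    while True:
        g = int(rng.integers(lo, hi + 1))
        if gap_scope == "all":
            pos += g
            tests_before = pos - len(positions) - 1
        else:
            tests_before += g
            pos = tests_before + len(positions) + 1
        if tests_before >= n_test:
            break
        positions.append(pos)
    return np.asarray(positions, dtype=int)


def simulate_response(model: PsychometricModel, x: float, state: str,
                      rng) -> bool:
    """One 2AFC response draw.

    Attentive: Bernoulli with the model's P(correct | x).  Lapsed: the
    response is independent of the stimulus — Bernoulli with the guess
    rate (50% for 2AFC).
    """
    if not np.isfinite(x):
        raise ValidationError("stimulus magnitude must be finite")
    rng = _rng(rng)
    p = model.guess_rate if state == LAPSED else float(model.p_correct(x))
    return bool(rng.random() < p)


def simulate_cop_trace(params: CoPGenParams, state: str, rng,
                       trial_id: int = 0) -> CoPTrace:
    """AR(1) CoP trace for one trial; innovation SD set by attention state."""
    rng = _rng(rng)
    n = int(np.floor(params.trial_duration * params.fs))
    sd = params.sd_lapsed if state == LAPSED else params.sd_attentive
    innov = rng.normal(0.0, sd, size=(2, n))
    xy = lfilter([1.0], [1.0, -params.ar_coef], innov, axis=1)
    t = np.arange(n) / params.fs
    return CoPTrace(trial_id=trial_id, t=t, x=xy[0], y=xy[1],
                    nominal_rate=params.fs)


def _build_engine(config: SessionConfig,
                  engine: Optional[QuestEngine]) -> QuestEngine:
    if engine is not None:
        return engine
    return QuestEngine(
        grid=make_default_grid(guess_rate=config.observer.guess_rate),
        domain=make_default_domain(),
        stop=StopPolicy(max_trials=config.n_test),
    )


def simulate_session(
    config: SessionConfig,
    procedure: str = "quest",
    alpha_source: str = "none",
    mapping: Optional[AlphaMapping] = None,
    engine: Optional[QuestEngine] = None,
    fixed_magnitude: Optional[float] = None,
    generate_cop: bool = True,
    return_traces: bool = False,
):
    """Simulate one full session: schedule, attention, stimuli, responses, CoP.

    Parameters
    ----------
    procedure
        "quest" places test stimuli with the entropy-minimizing adaptive
        engine; "fixed" presents ``fixed_magnitude`` on every test trial.
    alpha_source
        Weight fed to the engine on each test trial: "none" (always 1),
        "oracle" (0 on true-lapse trials, 1 otherwise — simulation ground
        truth), or "engagement" (from *mapping* applied to a causal running
        SMA of the CoP_MAD series; requires generate_cop=True).
    generate_cop
        Set False to skip trace synthesis (fast response-only studies).
    return_traces
        Also return the list of per-trial CoP traces.

    Returns the :class:`SessionRecord` (and traces if requested); trial
    ``cop_mad_sma`` fields are filled per ``config.sma_scope`` afterwards.
    """
    if procedure not in ("quest", "fixed"):
        raise ValidationError("procedure must be 'quest' or 'fixed'")
    if procedure == "fixed" and fixed_magnitude is None:
        raise ValidationError("fixed procedure needs fixed_magnitude")
    if alpha_source not in ("none", "oracle", "engagement"):
        raise ValidationError(
            "alpha_source must be 'none', 'oracle' or 'engagement'"
        )
    if alpha_source == "engagement":
        if mapping is None:
            raise ValidationError("alpha_source='engagement' needs a mapping")
        if not generate_cop:
            raise ValidationError(
                "alpha_source='engagement' requires CoP generation"
            )

    ss = np.random.SeedSequence(config.seed)
    sched_s, att_s, resp_s, cop_s = ss.spawn(4)
    rng_resp = np.random.default_rng(resp_s)
    rng_cop = np.random.default_rng(cop_s)

    catch_pos = set(
        schedule_catch_trials(config.n_test, config.catch_gap, sched_s,
                              config.gap_scope).tolist()
    )
    n_total = config.n_test + len(catch_pos)
    states = simulate_attention_sequence(config.attention, n_total, att_s)

    eng = _build_engine(config, engine) if procedure == "quest" else None

    trials: list[TrialRecord] = []
    traces: list[CoPTrace] = []
    mad_series: list[float] = []
    for i in range(1, n_total + 1):
        state = states[i - 1]
        is_catch = i in catch_pos
        if is_catch:
            x = config.catch_magnitude
        elif procedure == "quest":
            x = eng.next_stimulus()
        else:
            x = float(fixed_magnitude)

        mad = sma_now = None
        if generate_cop:
            trace = simulate_cop_trace(config.cop, state, rng_cop, trial_id=i)
            traces.append(trace)
            mad = compute_cop_mad(trace)
            mad_series.append(mad)
            w = config.sma_window
            sma_now = float(np.mean(mad_series[max(0, len(mad_series) - 1 - w):]))

        r = simulate_response(config.observer, x, state, rng_resp)

        if alpha_source == "oracle":
            alpha = 0.0 if state == LAPSED else 1.0
        elif alpha_source == "engagement":
            alpha = float(alpha_from_score(sma_now, mapping))
        else:
            alpha = 1.0

        if not is_catch and procedure == "quest":
            eng.update(x, r, alpha)

        trials.append(
            TrialRecord(
                index=i,
                kind="catch" if is_catch else "test",
                stimulus_magnitude=float(x),
                response_correct=r,
                cop_mad=mad,
                alpha=alpha,
                true_state=str(state),
            )
        )

    sess = SessionRecord(trials=trials, config=config, seed=config.seed)
    if generate_cop:
        attach_sma(sess, config.sma_window, config.sma_scope)
    if return_traces:
        return sess, traces
    return sess
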