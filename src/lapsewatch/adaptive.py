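"""Grid-posterior Bayesian adaptive threshold estimation with lapse weighting.

A QUEST-style procedure maintains a discretized posterior over the
parameters of a 2AFC psychometric function

    P(correct | x) = gamma + (1 - gamma - lambda) * F((x - threshold) / slope)

with guess rate ``gamma`` (0.5 for 2AFC), upper-asymptote shortfall
``lambda``, and a fixed sigmoid family F (logistic by default, Weibull
available).  After each trial the posterior mass at every grid node is
multiplied by the trial likelihood raised to a per-trial weight
``alpha`` in [0, 1]:

    P_alpha(r | x, psi) = P(r | x, psi) ** alpha

``alpha = 1`` is the ordinary Bayes update; ``alpha = 0`` discards the
trial entirely (a definite lapse contributes nothing); intermediate values
give partial credit.  The threshold estimate is the posterior mean of the
threshold parameter, stimulus placement minimizes expected posterior
entropy, and stopping can be tied to an entropy criterion so that more
attentive observers finish in fewer trials.

All posterior arithmetic is in the log domain to stay stable over long
(225+ trial) sessions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.special import expit, logsumexp

from .errors import DegenerateUpdateError, ValidationError

FAMILIES = ("logistic", "weibull")


def _sigmoid(z: np.ndarray, family: str) -> np.ndarray:
    if family == "logistic":
        return expit(z)
    if family == "weibull":
        # Quick/Weibull on raw magnitude: F = 1 - 2^{-(x/t)^b}; callers pass
        # z as a precomputed pair, handled in psychometric_p_correct.
        raise ValueError("weibull handled in psychometric_p_correct")
    raise ValidationError(f"unknown sigmoid family {family!r}")


def psychometric_p_correct(
    x,
    threshold,
    slope,
    guess_rate: float = 0.5,
    lapse: float = 0.0,
    family: str = "logistic",
) -> np.ndarray:
    """P(correct | x) for the 2AFC psychometric model; broadcasts over inputs.

    logistic: F(z) = 1 / (1 + e^{-z}) with z = (x - threshold) / slope;
    F(0) = 0.5, so ``threshold`` is the midpoint of the rising portion
    (the 75% point when gamma = 0.5 and lambda = 0).
    weibull (Quick parameterization): F = 1 - 2^{-(x / threshold)^slope}
    for x > 0 (0 otherwise), so F(threshold) = 0.5 as well.
    """
    if family not in FAMILIES:
        raise ValidationError(f"family must be one of {FAMILIES}")
    x = np.asarray(x, dtype=float)
    threshold = np.asarray(threshold, dtype=float)
    slope = np.asarray(slope, dtype=float)
    if np.any(slope <= 0):
        raise ValidationError("slope must be > 0")
    if family == "logistic":
        F = expit((x - threshold) / slope)
    else:
        if np.any(threshold <= 0):
            raise ValidationError("weibull threshold must be > 0")
        xr = np.clip(x, 0.0, None)
        F = -np.expm1(np.log(0.5) * (xr / threshold) ** slope)
    return guess_rate + (1.0 - guess_rate - np.asarray(lapse)) * F


@dataclass
class PsychometricModel:
    """A 2AFC observer model: threshold, slope, guess rate, lapse parameter."""

    threshold: float
    slope: float
    guess_rate: float = 0.5
    lapse: float = 0.0
    family: str = "logistic"

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValidationError("slope must be > 0")
        if not (0.0 < self.guess_rate < 1.0):
            raise ValidationError("guess_rate must be in (0, 1)")
        if not (0.0 <= self.lapse < 1.0 - self.guess_rate):
            raise ValidationError("lapse must be in [0, 1 - guess_rate)")
        if self.family not in FAMILIES:
            raise ValidationError(f"family must be one of {FAMILIES}")

    def p_correct(self, x) -> np.ndarray:
        return psychometric_p_correct(
            x, self.threshold, self.slope, self.guess_rate, self.lapse,
            self.family,
        )


@dataclass
class ParameterGrid:
    """Threshold x slope (x optional lapse) lattice with fixed guess rate.

    Nodes are the flattened Cartesian product; ``node_threshold`` etc. give
    the parameter value at each node.
    """

    thresholds: np.ndarray
    slopes: np.ndarray
    lapses: np.ndarray = field(default_factory=lambda: np.array([0.0]))
    guess_rate: float = 0.5
    family: str = "logistic"

    def __post_init__(self) -> None:
        self.thresholds = np.atleast_1d(np.asarray(self.thresholds, float))
        self.slopes = np.atleast_1d(np.asarray(self.slopes, float))
        self.lapses = np.atleast_1d(np.asarray(self.lapses, float))
        if self.thresholds.size == 0 or self.slopes.size == 0:
            raise ValidationError("grid axes must be nonempty")
        if np.any(self.slopes <= 0):
            raise ValidationError("slope grid values must be > 0")
        if self.family not in FAMILIES:
            raise ValidationError(f"family must be one of {FAMILIES}")
        T, S, L = np.meshgrid(self.thresholds, self.slopes, self.lapses,
                              indexing="ij")
        self.node_threshold = T.ravel()
        self.node_slope = S.ravel()
        self.node_lapse = L.ravel()

    @property
    def n_nodes(self) -> int:
        return self.node_threshold.size

    def p_correct(self, x: float) -> np.ndarray:
        """Vector of P(correct | x) over all grid nodes."""
        return psychometric_p_correct(
            x, self.node_threshold, self.node_slope, self.guess_rate,
            self.node_lapse, self.family,
        )


@dataclass
class PosteriorState:
    """Normalized log posterior mass over a parameter grid plus history."""

    grid: ParameterGrid
    log_mass: np.ndarray
    history: list = field(default_factory=list)

    @property
    def mass(self) -> np.ndarray:
        return np.exp(self.log_mass)

    @property
    def n_trials(self) -> int:
        return len(self.history)


@dataclass
class StimulusDomain:
    """Finite ordered set of candidate stimulus magnitudes."""

    candidates: np.ndarray

    def __post_init__(self) -> None:
        self.candidates = np.atleast_1d(np.asarray(self.candidates, float))
        if self.candidates.size == 0:
            raise ValidationError("stimulus domain must be nonempty")
        if np.any(np.diff(self.candidates) <= 0):
            raise ValidationError("candidates must be sorted ascending")

    @property
    def bounds(self) -> tuple[float, float]:
        return float(self.candidates[0]), float(self.candidates[-1])


@dataclass
class StopPolicy:
    """Stop when trials >= max_trials or posterior entropy <= entropy_bits."""

    max_trials: Optional[int] = None
    entropy_bits: Optional[float] = None

    def __post_init__(self) -> None:
        if self.max_trials is None and self.entropy_bits is None:
            raise ValidationError("set at least one stopping criterion")


def init_posterior(grid: ParameterGrid, prior=None) -> PosteriorState:
    """Normalized posterior equal to the prior (uniform if omitted)."""
    if prior is None:
        prior = np.ones(grid.n_nodes)
    prior = np.asarray(prior, dtype=float).ravel()
    if prior.size != grid.n_nodes:
        raise ValidationError("prior length must match grid size")
    if np.any(prior < 0):
        raise ValidationError("prior must be nonnegative")
    total = prior.sum()
    if total <= 0:
        raise ValidationError("prior must not be all zero")
    with np.errstate(divide="ignore"):
        log_mass = np.log(prior / total)
    return PosteriorState(grid=grid, log_mass=log_mass, history=[])


def trial_likelihood(x: float, correct: bool, grid: ParameterGrid) -> np.ndarray:
    """Per-node likelihood of one response: P(correct|x) or its complement."""
    if not np.isfinite(x):
        raise ValidationError("stimulus magnitude must be finite")
    p = grid.p_correct(x)
    return p if correct else 1.0 - p


def weighted_update(
    state: PosteriorState, x: float, correct: bool, alpha: float = 1.0
) -> PosteriorState:
    """One lapse-weighted Bayes update: log_mass += alpha * log L, renormalize.

    ``alpha = 0`` returns the prior state unchanged (trial discarded);
    ``alpha = 1`` is the ordinary Bayes update.  Returns a new state; the
    (x, r, alpha) triple is appended to its history.
    """
    if not (0.0 <= alpha <= 1.0):
        raise ValidationError("alpha must be in [0, 1]")
    lik = trial_likelihood(x, correct, state.grid)
    with np.errstate(divide="ignore"):
        log_lik = np.log(lik)
    new_log = state.log_mass + alpha * np.where(
        np.isneginf(log_lik) & (alpha == 0.0), 0.0, log_lik
    )
    norm = logsumexp(new_log)
    if not np.isfinite(norm):
        raise DegenerateUpdateError(
            "likelihood is zero at every grid node; posterior annihilated"
        )
    return PosteriorState(
        grid=state.grid,
        log_mass=new_log - norm,
        history=state.history + [(float(x), bool(correct), float(alpha))],
    )


def estimate_threshold(state: PosteriorState) -> float:
    """Posterior mean of the threshold parameter (nuisance dims marginalized)."""
    return float(np.sum(state.mass * state.grid.node_threshold))


def posterior_entropy(state: PosteriorState) -> float:
    """Shannon entropy of the posterior mass in bits; 0 iff a delta."""
    p = state.mass
    nz = p > 0
    return float(-np.sum(p[nz] * np.log2(p[nz])))


def _entropy_bits(log_mass_rows: np.ndarray) -> np.ndarray:
    """Row-wise entropy (bits) of normalized log-mass rows."""
    p = np.exp(log_mass_rows)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * (log_mass_rows / np.log(2.0)), 0.0)
    return -plogp.sum(axis=-1)


def expected_posterior_entropies(
    state: PosteriorState,
    domain: StimulusDomain,
    alpha_forecast: float = 1.0,
    p_correct_table: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Expected post-trial entropy (bits) for each candidate magnitude.

    For each candidate x the expectation runs over the two responses with
    posterior-predictive probabilities, applying a tentative weighted
    update with ``alpha_forecast`` to score each outcome.
    """
    if not (0.0 <= alpha_forecast <= 1.0):
        raise ValidationError("alpha_forecast must be in [0, 1]")
    if p_correct_table is None:
        p_correct_table = np.stack(
            [state.grid.p_correct(x) for x in domain.candidates]
        )  # (n_cand, n_nodes)
    mass = state.mass
    pred_correct = p_correct_table @ mass  # posterior predictive per candidate

    with np.errstate(divide="ignore"):
        log_pc = np.log(p_correct_table)
        log_pi = np.log1p(-p_correct_table)
    out = np.zeros(domain.candidates.size)
    for log_l, pr in ((log_pc, pred_correct), (log_pi, 1.0 - pred_correct)):
        lm = state.log_mass[None, :] + alpha_forecast * log_l
        norm = logsumexp(lm, axis=1)
        ok = (pr > 0) & np.isfinite(norm)  # a response impossible at every
        if ok.any():                       # node contributes nothing
            h = _entropy_bits(lm[ok] - norm[ok, None])
            out[ok] += pr[ok] * h
    return out


def select_stimulus(
    state: PosteriorState,
    domain: StimulusDomain,
    alpha_forecast: float = 1.0,
    p_correct_table: Optional[np.ndarray] = None,
) -> float:
    """Most informative next magnitude: argmin of expected posterior entropy.

    Ties (including the fully-uninformative alpha_forecast = 0 case) break
    toward the smaller magnitude.
    """
    h = expected_posterior_entropies(state, domain, alpha_forecast,
                                     p_correct_table)
    return float(domain.candidates[int(np.argmin(h))])


def should_stop(state: PosteriorState, policy: StopPolicy) -> bool:
    """True once max_trials is reached or entropy falls to entropy_bits."""
    if policy.max_trials is not None and state.n_trials >= policy.max_trials:
        return True
    if (policy.entropy_bits is not None
            and posterior_entropy(state) <= policy.entropy_bits):
        return True
    return False


DEFAULT_GRID = dict(threshold=(0.5, 30.0, 61), slope=(0.5, 10.0, 7))
DEFAULT_DOMAIN = (0.25, 30.0, 25)


def make_default_grid(
    threshold=DEFAULT_GRID["threshold"],
    slope=DEFAULT_GRID["slope"],
    guess_rate: float = 0.5,
    lapses=(0.0,),
    family: str = "logistic",
) -> ParameterGrid:
    """Linear threshold grid crossed with a geometric slope grid."""
    t_lo, t_hi, t_n = threshold
    s_lo, s_hi, s_n = slope
    return ParameterGrid(
        thresholds=np.linspace(t_lo, t_hi, int(t_n)),
        slopes=np.geomspace(s_lo, s_hi, int(s_n)),
        lapses=np.asarray(lapses, dtype=float),
        guess_rate=guess_rate,
        family=family,
    )


def make_default_domain(bounds=DEFAULT_DOMAIN) -> StimulusDomain:
    lo, hi, n = bounds
    return StimulusDomain(candidates=np.geomspace(lo, hi, int(n)))


class QuestEngine:
    """Stateful driver: entropy-based placement + lapse-weighted updates.

    Wraps the functional operations with a cached per-candidate likelihood
    table so that repeated stimulus selection is cheap over long sessions.
    """

    def __init__(
        self,
        grid: Optional[ParameterGrid] = None,
        domain: Optional[StimulusDomain] = None,
        prior=None,
        alpha_forecast: float = 1.0,
        stop: Optional[StopPolicy] = None,
    ):
        self.grid = grid if grid is not None else make_default_grid()
        self.domain = domain if domain is not None else make_default_domain()
        self.state = init_posterior(self.grid, prior)
        self.alpha_forecast = alpha_forecast
        self.stop_policy = stop if stop is not None else StopPolicy(max_trials=225)
        self._pc_table = np.stack(
            [self.grid.p_correct(x) for x in self.domain.candidates]
        )
        self.trace: list[dict] = []

    def next_stimulus(self) -> float:
        return select_stimulus(self.state, self.domain, self.alpha_forecast,
                               self._pc_table)

    def update(self, x: float, correct: bool, alpha: float = 1.0) -> None:
        self.state = weighted_update(self.state, x, correct, alpha)
        self.trace.append(
            {
                "i": self.state.n_trials,
                "x": float(x),
                "r": bool(correct),
                "alpha": float(alpha),
                "entropy_bits": posterior_entropy(self.state),
                "threshold_mean": estimate_threshold(self.state),
            }
        )

    @property
    def finished(self) -> bool:
        return should_stop(self.state, self.stop_policy)

    @property
    def threshold(self) -> float:
        return estimate_threshold(self.state)

    @property
    def entropy_bits(self) -> float:
        return posterior_entropy(self.state)
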