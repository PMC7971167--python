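"""Simulated psychophysics: observer model, adaptive threshold estimation,
catch-trial auditing and model-vs-observed statistics.

The observer answers yes/no trials with probability
``p(I) = gamma + (1 - gamma - lambda) * W(I)`` where ``W`` is a Weibull
distribution function, ``W(I) = 1 - exp(-(I/alpha)^beta)``, parameterized so
that the p = 0.5 point sits at the observer's true threshold.

The adaptive estimator is a reconstruction of a hybrid procedure: a short
coarse staircase (3 reversals) seeds a maximum-likelihood Weibull fit that
proposes each next amplitude at the current p = 0.5 estimate, stopping once
the estimate stabilizes (successive change < 5% over a 10-trial window) or
the session budget runs out.  Blocks of six electrodes are interleaved in
random order with 32 stimulus-absent catch trials; blocks whose catch
false-positive rate exceeds 25% are excluded by the audit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import f_oneway, linregress, pearsonr

from .geometry import ConfigurationError

__all__ = [
    "ObserverModel",
    "HybridConfig",
    "ThresholdEstimate",
    "TrialLog",
    "observer_response",
    "weibull_probability",
    "fit_weibull_ml",
    "run_hybrid_threshold",
    "audit_block",
    "compare_thresholds",
    "block_anova",
]


def weibull_probability(
    amp_uA: np.ndarray,
    threshold_uA: float,
    slope_beta: float,
    guess_rate: float = 0.0,
    lapse_rate: float = 0.0,
) -> np.ndarray:
    """Yes-probability with the p=0.5 point at ``threshold_uA`` (for
    gamma = lambda = 0); guess/lapse fold in as floor and ceiling."""
    amp = np.asarray(amp_uA, dtype=float)
    alpha = threshold_uA / np.log(2.0) ** (1.0 / slope_beta)
    with np.errstate(divide="ignore"):
        expo = np.clip(slope_beta * np.log(np.maximum(amp, 1e-300) / alpha), -700.0, 700.0)
    w = np.where(amp > 0, -np.expm1(-np.exp(expo)), 0.0)
    return guess_rate + (1.0 - guess_rate - lapse_rate) * w


@dataclass
class ObserverModel:
    """Stochastic yes/no observer with a Weibull psychometric function."""

    true_threshold_uA: float
    slope_beta: float = 4.0
    guess_rate: float = 0.0
    lapse_rate: float = 0.0
    seed: int = 0
    _rng: np.random.Generator | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.true_threshold_uA <= 0 or self.slope_beta <= 0:
            raise ConfigurationError("threshold and slope must be positive")
        if not (0 <= self.guess_rate < 1 and 0 <= self.lapse_rate < 1):
            raise ConfigurationError("guess and lapse rates must lie in [0, 1)")

    @property
    def rng(self) -> np.random.Generator:
        if self._rng is None:
            self._rng = np.random.default_rng(self.seed)
        return self._rng

    def probability(self, amp_uA: float) -> float:
        return float(
            weibull_probability(
                amp_uA, self.true_threshold_uA, self.slope_beta, self.guess_rate, self.lapse_rate
            )
        )


def observer_response(obs: ObserverModel, amp_uA: float) -> bool:
    """One Bernoulli yes/no draw from the observer's seeded stream."""
    if amp_uA < 0:
        raise ConfigurationError("amplitude must be non-negative")
    return bool(obs.rng.random() < obs.probability(amp_uA))


# --------------------------------------------------------------------------
# Maximum-likelihood Weibull fit
# --------------------------------------------------------------------------


def fit_weibull_ml(
    amps_uA: np.ndarray,
    responses: np.ndarray,
    *,
    guess_rate: float = 0.0,
    lapse_rate: float = 0.0,
    beta_bounds: tuple[float, float] = (0.5, 20.0),
    x0_hint: tuple[float, float] | None = None,
) -> dict:
    """Fit (threshold, slope) by maximizing the Bernoulli likelihood.

    Returns {"threshold_uA", "slope_beta", "nll", "ok"}.  The fitted
    threshold is the p = 0.5 point of the fitted curve (for gamma = 0).
    """
    amps = np.asarray(amps_uA, dtype=float)
    resp = np.asarray(responses, dtype=bool)
    if len(amps) != len(resp) or len(amps) == 0:
        raise ConfigurationError("need matching, non-empty amplitude/response arrays")

    def nll(x) -> float:
        thr, beta = np.exp(x)
        p = weibull_probability(amps, thr, beta, guess_rate, lapse_rate)
        p = np.clip(p, 1e-9, 1 - 1e-9)
        return float(-np.sum(np.where(resp, np.log(p), np.log1p(-p))))

    amid = np.median(amps[amps > 0]) if (amps > 0).any() else 100.0
    if x0_hint is not None:
        starts = [(x0_hint[0], x0_hint[1])]
    else:
        starts = [(amid, 3.0), (2 * amid, 3.0), (0.5 * amid, 3.0)]
    best = None
    for thr0, beta0 in starts:
        res = minimize(
            nll,
            x0=[np.log(thr0), np.log(beta0)],
            method="Nelder-Mead",
            options={"xatol": 1e-4, "fatol": 1e-8, "maxiter": 400},
        )
        if best is None or res.fun < best.fun:
            best = res
    thr, beta = np.exp(best.x)
    beta = float(np.clip(beta, *beta_bounds))
    return {"threshold_uA": float(thr), "slope_beta": beta, "nll": float(best.fun), "ok": bool(best.success)}


# --------------------------------------------------------------------------
# Hybrid adaptive procedure
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class HybridConfig:
    trials_budget: int = 400
    catch_trials_per_block: int = 32
    start_amp_uA: float = 100.0
    staircase_reversals: int = 3
    amp_min_uA: float = 1.0
    amp_max_uA: float = 1000.0
    convergence_rel: float = 0.05
    convergence_window: int = 10
    min_trials_per_electrode: int = 15

    def __post_init__(self) -> None:
        if not 0 < self.amp_min_uA < self.amp_max_uA:
            raise ConfigurationError("invalid amplitude range")
        if not 300 <= self.trials_budget <= 400:
            # the session protocol runs 300-400 trials; allow smaller for tests
            if self.trials_budget <= 0:
                raise ConfigurationError("trial budget must be positive")


@dataclass(frozen=True)
class ThresholdEstimate:
    electrode: str
    threshold_uA: float
    slope_beta: float
    n_trials: int
    converged: bool


@dataclass
class TrialLog:
    """Per-trial record of one block (six electrodes + catch trials)."""

    trials: pd.DataFrame  # columns: trial, electrode, amplitude_uA, catch, response

    @property
    def catch_count(self) -> int:
        return int(self.trials["catch"].sum())

    @property
    def false_positive_rate(self) -> float:
        catch = self.trials[self.trials["catch"]]
        if len(catch) == 0:
            raise ConfigurationError("block has no catch trials; audit impossible")
        return float(catch["response"].mean())

    def to_csv(self, path: str) -> None:
        self.trials.to_csv(path, index=False)


class _ElectrodeSession:
    """Staircase-then-ML state machine for a single electrode."""

    def __init__(self, cfg: HybridConfig):
        self.cfg = cfg
        self.amps: list[float] = []
        self.resps: list[bool] = []
        self.estimates: list[float] = []
        self.next_amp = cfg.start_amp_uA
        self.reversals = 0
        self.in_staircase = True
        self.done = False

    def record(self, amp: float, resp: bool) -> None:
        cfg = self.cfg
        if self.in_staircase and self.resps:
            if resp != self.resps[-1]:
                self.reversals += 1
        self.amps.append(amp)
        self.resps.append(resp)
        if self.in_staircase:
            self.next_amp = float(
                np.clip(amp * (0.5 if resp else 2.0), cfg.amp_min_uA, cfg.amp_max_uA)
            )
            if self.reversals >= cfg.staircase_reversals:
                self.in_staircase = False
        if not self.in_staircase and len(set(self.resps)) == 2:
            hint = (self.estimates[-1], 3.0) if self.estimates else None
            fit = fit_weibull_ml(np.array(self.amps), np.array(self.resps), x0_hint=hint)
            est = float(np.clip(fit["threshold_uA"], cfg.amp_min_uA, cfg.amp_max_uA))
            self.estimates.append(est)
            self.next_amp = est
            w = cfg.convergence_window
            if (
                len(self.amps) >= cfg.min_trials_per_electrode
                and len(self.estimates) > w
            ):
                ref = np.array(self.estimates[-w - 1 : -1])
                cur = np.array(self.estimates[-w:])
                if np.all(np.abs(cur - ref) / np.maximum(ref, 1e-12) < cfg.convergence_rel):
                    self.done = True

    def final_estimate(self, electrode: str) -> ThresholdEstimate:
        if len(set(self.resps)) == 2:
            fit = fit_weibull_ml(np.array(self.amps), np.array(self.resps))
            thr, beta = fit["threshold_uA"], fit["slope_beta"]
        else:  # degenerate: all yes or all no
            thr, beta = (self.amps[-1] if self.amps else np.nan), np.nan
        return ThresholdEstimate(
            electrode=electrode,
            threshold_uA=float(thr),
            slope_beta=float(beta),
            n_trials=len(self.amps),
            converged=self.done,
        )


def run_hybrid_threshold(
    observers: dict[str, ObserverModel],
    config: HybridConfig | None = None,
    seed: int = 0,
) -> tuple[dict[str, ThresholdEstimate], TrialLog]:
    """Adaptive threshold estimation for a block of electrodes.

    ``observers`` maps electrode labels (typically six) to their simulated
    observers.  Electrode order is re-randomized throughout; catch trials
    are interleaved at random positions.  Returns per-electrode estimates
    and the full trial log.
    """
    cfg = config or HybridConfig()
    rng = np.random.default_rng(seed)
    labels = list(observers)
    sessions = {e: _ElectrodeSession(cfg) for e in labels}

    # pre-draw catch-trial slots within the whole block
    total_slots = cfg.trials_budget + cfg.catch_trials_per_block
    catch_slots = set(rng.choice(total_slots, size=cfg.catch_trials_per_block, replace=False))

    records = []
    stim_trials = 0
    for slot in range(total_slots):
        if slot in catch_slots:
            # stimulus-absent: route to a random observer's response stream
            e = labels[rng.integers(len(labels))]
            resp = observer_response(observers[e], 0.0)
            records.append((slot, e, 0.0, True, resp))
            continue
        open_electrodes = [e for e in labels if not sessions[e].done]
        if not open_electrodes or stim_trials >= cfg.trials_budget:
            continue
        e = open_electrodes[rng.integers(len(open_electrodes))]
        s = sessions[e]
        amp = float(s.next_amp)
        resp = observer_response(observers[e], amp)
        s.record(amp, resp)
        records.append((slot, e, amp, False, resp))
        stim_trials += 1

    log = TrialLog(
        trials=pd.DataFrame(
            records, columns=["trial", "electrode", "amplitude_uA", "catch", "response"]
        )
    )
    estimates = {e: sessions[e].final_estimate(e) for e in labels}
    return estimates, log


def audit_block(log: TrialLog, fpr_cutoff: float = 0.25) -> dict:
    """Catch-trial audit: exclude the block iff FPR strictly exceeds the cutoff."""
    fpr = log.false_positive_rate
    return {"false_positive_rate": fpr, "exclude": bool(fpr > fpr_cutoff), "keep": bool(fpr <= fpr_cutoff)}


# --------------------------------------------------------------------------
# Model-vs-observed statistics
# --------------------------------------------------------------------------


def compare_thresholds(
    model_uA: dict[str, float] | np.ndarray,
    observed_uA: dict[str, float] | np.ndarray,
    min_observed_uA: float | None = None,
) -> dict:
    """Pearson correlation and least-squares line between paired thresholds.

    Dict inputs are paired by electrode label; the optional filter drops
    pairs whose observed threshold is below ``min_observed_uA``.
    """
    if isinstance(model_uA, dict) and isinstance(observed_uA, dict):
        keys = sorted(set(model_uA) & set(observed_uA))
        x = np.array([observed_uA[k] for k in keys], dtype=float)
        y = np.array([model_uA[k] for k in keys], dtype=float)
    else:
        x = np.asarray(observed_uA, dtype=float)
        y = np.asarray(model_uA, dtype=float)
    if min_observed_uA is not None:
        keep = x >= min_observed_uA
        x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ConfigurationError("need at least 3 paired electrodes after filtering")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return {"r": np.nan, "p": np.nan, "slope": np.nan, "intercept": np.nan, "n": int(len(x)), "undefined": True}
    r, p = pearsonr(x, y)
    fit = linregress(x, y)
    return {
        "r": float(r),
        "p": float(p),
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "n": int(len(x)),
        "undefined": False,
    }


def block_anova(block_thresholds: list[np.ndarray]) -> dict:
    """One-way fixed-effects ANOVA across electrode testing blocks."""
    groups = [np.asarray(b, dtype=float) for b in block_thresholds]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ConfigurationError("need >= 2 blocks with >= 2 values each")
    flat = np.concatenate(groups)
    if np.ptp(flat) == 0:
        return {"F": 0.0, "p": 1.0}
    means = [g.mean() for g in groups]
    if np.ptp(means) == 0:
        return {"F": 0.0, "p": 1.0}
    F, p = f_oneway(*groups)
    return {"F": float(F), "p": float(p)}
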