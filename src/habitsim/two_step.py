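"""Two-step sequential decision task: simulator and hybrid MB/MF model.

In the two-step task a stage-1 choice leads with probability 0.7 to its
"common" second-stage state and with probability 0.3 to the other;
stage-2 choices are rewarded with slowly drifting probabilities.  The
hybrid reinforcement-learning model scores each participant's reliance
on model-based planning (using the transition structure) and model-free
caching at stage 1, a model-free stage-2 weight, a stage-1 perseverance
(choice-repetition) bias, and a shared learning rate:

    stage 1:  softmax( w_MB * Q_MB + w_MF1 * Q_MF1 + pi * repeat )
    stage 2:  softmax( w_MF2 * Q2(s2, .) )

Q2 is updated by the reward prediction error with rate alpha; the
stage-1 model-free value is backed up with eligibility lambda = 1 (the
net target is the trial reward); Q_MB(a) = sum_s P(s|a) max_a' Q2(s,a')
with the true transition probabilities (0.7 / 0.3).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from numba import njit
from scipy import optimize, stats

__all__ = [
    "TwoStepConfig",
    "TwoStepTrial",
    "HybridParams",
    "FitResult",
    "simulate_two_step",
    "hybrid_loglik",
    "fit_map",
    "exclusion_filters",
    "stay_probability_analysis",
    "trials_to_frame",
    "frame_to_trials",
]

Q_INIT = 0.5    # midpoint of the 0/1 reward scale


@dataclass
class TwoStepConfig:
    """Task parameters: transition structure and reward-probability walk."""

    common_transition_prob: float = 0.7
    n_trials: int = 200
    drift_sd: float = 0.025
    reward_prob_bounds: tuple[float, float] = (0.25, 0.75)
    response_deadline: float = 2.0

    def __post_init__(self) -> None:
        if not 0.0 < self.common_transition_prob < 1.0:
            raise ValueError("common_transition_prob must lie in (0, 1)")
        lo, hi = self.reward_prob_bounds
        if not 0.0 < lo < hi < 1.0:
            raise ValueError("reward_prob_bounds must lie inside (0, 1)")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")


@dataclass
class HybridParams:
    """Participant-level parameters of the hybrid RL model."""

    alpha: float = 0.4
    w_mb: float = 3.0
    w_mf1: float = 1.0
    w_mf2: float = 4.0
    perseverance: float = 0.3

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        for name in ("w_mb", "w_mf1", "w_mf2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not np.isfinite(self.perseverance):
            raise ValueError("perseverance must be finite")

    def to_array(self) -> np.ndarray:
        return np.array([self.alpha, self.w_mb, self.w_mf1, self.w_mf2,
                         self.perseverance])

    @classmethod
    def from_array(cls, x: Sequence[float]) -> "HybridParams":
        return cls(*[float(v) for v in x])


@dataclass
class TwoStepTrial:
    stage1_choice: int          # 0 or 1
    transition: str             # "common" or "rare"
    stage2_state: int           # 0 or 1
    stage2_choice: int          # 0 or 1
    reward: int                 # 0 or 1
    rt1: float = 0.5
    rt2: float = 0.5
    missed: bool = False


def _reflect(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    span = hi - lo
    x = np.mod(x - lo, 2 * span)
    return lo + np.where(x > span, 2 * span - x, x)


def simulate_two_step(params: HybridParams, config: TwoStepConfig,
                      seed: int) -> list[TwoStepTrial]:
    """Simulate a session with choices sampled from the model's own
    softmax policies and reward probabilities following reflecting
    Gaussian random walks."""
    rng = np.random.default_rng(seed)
    lo, hi = config.reward_prob_bounds
    reward_p = rng.uniform(lo, hi, size=(2, 2))     # [state, action]
    q2 = np.full((2, 2), Q_INIT)
    q_mf1 = np.full(2, Q_INIT)
    pc = config.common_transition_prob
    prev_choice = -1
    trials: list[TwoStepTrial] = []
    for _ in range(config.n_trials):
        q_mb = np.array([pc * q2[0].max() + (1 - pc) * q2[1].max(),
                         (1 - pc) * q2[0].max() + pc * q2[1].max()])
        net = params.w_mb * q_mb + params.w_mf1 * q_mf1
        if prev_choice >= 0:
            net[prev_choice] += params.perseverance
        p1 = _softmax(net)
        a1 = int(rng.random() < p1[1])
        common = rng.random() < pc
        s2 = a1 if common else 1 - a1
        p2 = _softmax(params.w_mf2 * q2[s2])
        a2 = int(rng.random() < p2[1])
        r = int(rng.random() < reward_p[s2, a2])

        delta1 = q2[s2, a2] - q_mf1[a1]
        delta2 = r - q2[s2, a2]
        q_mf1[a1] += params.alpha * (delta1 + delta2)   # lambda = 1 backup
        q2[s2, a2] += params.alpha * delta2
        prev_choice = a1

        trials.append(TwoStepTrial(
            stage1_choice=a1, transition="common" if common else "rare",
            stage2_state=s2, stage2_choice=a2, reward=r,
            rt1=float(rng.gamma(4.0, 0.15)), rt2=float(rng.gamma(4.0, 0.15))))
        reward_p = _reflect(reward_p + rng.normal(0, config.drift_sd, (2, 2)),
                            lo, hi)
    return trials


def _softmax(v: np.ndarray) -> np.ndarray:
    v = v - np.max(v)
    e = np.exp(v)
    return e / e.sum()


@njit(cache=False)
def _hybrid_loglik_core(a1, s2, a2, r, missed, alpha, w_mb, w_mf1, w_mf2,
                        persev, p_common):
    q2 = np.full((2, 2), 0.5)
    q_mf1 = np.full(2, 0.5)
    prev = -1
    ll = 0.0
    for t in range(a1.shape[0]):
        if missed[t]:
            continue
        mb0 = p_common * max(q2[0, 0], q2[0, 1]) \
            + (1.0 - p_common) * max(q2[1, 0], q2[1, 1])
        mb1 = (1.0 - p_common) * max(q2[0, 0], q2[0, 1]) \
            + p_common * max(q2[1, 0], q2[1, 1])
        v0 = w_mb * mb0 + w_mf1 * q_mf1[0]
        v1 = w_mb * mb1 + w_mf1 * q_mf1[1]
        if prev == 0:
            v0 += persev
        elif prev == 1:
            v1 += persev
        m = v0 if v0 > v1 else v1
        log_z = m + np.log(np.exp(v0 - m) + np.exp(v1 - m))
        ll += (v1 if a1[t] == 1 else v0) - log_z
        s = s2[t]
        u0 = w_mf2 * q2[s, 0]
        u1 = w_mf2 * q2[s, 1]
        m2 = u0 if u0 > u1 else u1
        log_z2 = m2 + np.log(np.exp(u0 - m2) + np.exp(u1 - m2))
        ll += (u1 if a2[t] == 1 else u0) - log_z2

        delta1 = q2[s, a2[t]] - q_mf1[a1[t]]
        delta2 = r[t] - q2[s, a2[t]]
        q_mf1[a1[t]] += alpha * (delta1 + delta2)
        q2[s, a2[t]] += alpha * delta2
        prev = a1[t]
    return ll


def _trial_arrays(trials: Sequence[TwoStepTrial]):
    a1 = np.array([t.stage1_choice for t in trials], dtype=np.int64)
    s2 = np.array([t.stage2_state for t in trials], dtype=np.int64)
    a2 = np.array([t.stage2_choice for t in trials], dtype=np.int64)
    r = np.array([t.reward for t in trials], dtype=np.float64)
    missed = np.array([t.missed for t in trials], dtype=np.bool_)
    return a1, s2, a2, r, missed


def hybrid_loglik(params: HybridParams, trials: Sequence[TwoStepTrial],
                  p_common: float = 0.7) -> float:
    """Summed log probability of the observed stage-1 and stage-2 choices
    under the hybrid model (missed trials are skipped)."""
    if not np.all(np.isfinite(params.to_array())):
        raise ValueError("non-finite parameters")
    a1, s2, a2, r, missed = _trial_arrays(trials)
    for arr, hi in ((a1, 2), (s2, 2), (a2, 2)):
        if arr.min(initial=0) < 0 or arr.max(initial=0) >= hi:
            raise ValueError("trial codes must be 0/1")
    return float(_hybrid_loglik_core(a1, s2, a2, r, missed, params.alpha,
                                     params.w_mb, params.w_mf1, params.w_mf2,
                                     params.perseverance, p_common))


@dataclass
class PriorSpec:
    """Weakly informative MAP priors: Beta(a, b) on the learning rate,
    half-normal-like Normal(0, sd) on the nonnegative weights and
    Normal(0, sd) on perseverance."""

    alpha_beta: tuple[float, float] = (2.0, 2.0)
    weight_sd: float = 5.0
    perseverance_sd: float = 2.0

    def logpdf(self, x: np.ndarray) -> float:
        a, b = self.alpha_beta
        lp = stats.beta.logpdf(x[0], a, b)
        lp += stats.norm.logpdf(x[1:4], scale=self.weight_sd).sum()
        lp += stats.norm.logpdf(x[4], scale=self.perseverance_sd)
        return float(lp)

    def sample(self, rng: np.random.Generator) -> np.ndarray:
        a, b = self.alpha_beta
        return np.array([
            rng.beta(a, b),
            *np.abs(rng.normal(0, self.weight_sd / 2, size=3)),
            rng.normal(0, self.perseverance_sd / 2)])


@dataclass
class FitResult:
    params: Optional[HybridParams]
    log_posterior: float
    loglik: float
    converged: bool
    n_starts: int
    grad_norm: float
    per_start: list = field(default_factory=list)
    message: str = ""


_BOUNDS = [(1e-3, 1 - 1e-3), (0.0, 30.0), (0.0, 30.0), (0.0, 30.0),
           (-10.0, 10.0)]


def fit_map(trials: Sequence[TwoStepTrial],
            priors: Optional[PriorSpec] = None, n_starts: int = 10,
            seed: int = 0, p_common: float = 0.7,
            min_trials: int = 50) -> FitResult:
    """Maximum a posteriori fit of the hybrid model by bounded L-BFGS-B
    from ``n_starts`` random initializations; the best start wins."""
    priors = priors or PriorSpec()
    valid = [t for t in trials if not t.missed]
    if len(valid) < min_trials:
        raise ValueError(f"need >= {min_trials} valid trials, "
                         f"got {len(valid)}")
    a1, s2, a2, r, missed = _trial_arrays(trials)
    rng = np.random.default_rng(seed)

    def neg_post(x):
        ll = _hybrid_loglik_core(a1, s2, a2, r, missed, x[0], x[1], x[2],
                                 x[3], x[4], p_common)
        return -(ll + priors.logpdf(x))

    best, per_start = None, []
    for k in range(n_starts):
        x0 = priors.sample(rng)
        try:
            res = optimize.minimize(neg_post, x0, method="L-BFGS-B",
                                    bounds=_BOUNDS,
                                    options={"maxfun": 2000})
        except Exception as exc:                     # pragma: no cover
            per_start.append({"start": k, "error": str(exc)})
            continue
        per_start.append({"start": k, "fun": float(res.fun),
                          "x": res.x.tolist(), "success": bool(res.success)})
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        return FitResult(params=None, log_posterior=-np.inf, loglik=-np.inf,
                         converged=False, n_starts=n_starts,
                         grad_norm=np.nan, per_start=per_start,
                         message="all starts failed")
    params = HybridParams.from_array(np.clip(
        best.x, [b[0] for b in _BOUNDS], [b[1] for b in _BOUNDS]))
    ll = float(_hybrid_loglik_core(a1, s2, a2, r, missed, *best.x, p_common))
    grad_norm = float(np.linalg.norm(getattr(best, "jac", np.nan)))
    return FitResult(params=params, log_posterior=float(-best.fun),
                     loglik=ll, converged=bool(best.success),
                     n_starts=n_starts, grad_norm=grad_norm,
                     per_start=per_start)


def exclusion_filters(trials: Sequence[TwoStepTrial],
                      cohort_rt_mean: float, cohort_rt_sd: float,
                      missed_threshold: float = 0.10,
                      same_key_threshold: float = 0.90) -> dict:
    """Engagement screens: missed fraction > 10%, mean response time
    beyond +/- 2 SD of the cohort mean, or > 90% same-key presses."""
    n = len(trials)
    if n == 0:
        raise ValueError("no trials")
    missed_frac = float(np.mean([t.missed for t in trials]))
    valid = [t for t in trials if not t.missed]
    reasons = []
    if missed_frac > missed_threshold:
        reasons.append("missed")
    if valid:
        rts = [t.rt1 for t in valid] + [t.rt2 for t in valid]
        mean_rt = float(np.mean(rts))
        if mean_rt < cohort_rt_mean - 2 * cohort_rt_sd:
            reasons.append("fast_rt")
        elif mean_rt > cohort_rt_mean + 2 * cohort_rt_sd:
            reasons.append("slow_rt")
        keys = [t.stage1_choice for t in valid] + [t.stage2_choice for t in valid]
        same = max(np.mean(np.array(keys) == 0), np.mean(np.array(keys) == 1))
        if same > same_key_threshold:
            reasons.append("same_key")
    return {"included": not reasons, "reasons": reasons,
            "missed_fraction": missed_frac}


def stay_probability_analysis(trials: Sequence[TwoStepTrial]) -> dict:
    """Classic stay/switch signature: logistic regression of repeating
    the stage-1 choice on previous reward, transition and their
    interaction.  The reward x transition coefficient indexes
    model-based control; the reward main effect indexes model-free
    control."""
    rows = []
    for prev, cur in zip(trials[:-1], trials[1:]):
        if prev.missed or cur.missed:
            continue
        rows.append({
            "stay": int(cur.stage1_choice == prev.stage1_choice),
            "reward": 1.0 if prev.reward else -1.0,
            "common": 1.0 if prev.transition == "common" else -1.0,
        })
    df = pd.DataFrame(rows)
    if len(df) < 20:
        raise ValueError("too few consecutive trial pairs")
    X = np.column_stack([np.ones(len(df)), df["reward"], df["common"],
                         df["reward"] * df["common"]])
    yv = df["stay"].to_numpy(dtype=float)
    beta = _logistic_irls(X, yv)
    return {"intercept": beta[0], "reward": beta[1], "transition": beta[2],
            "reward_x_transition": beta[3], "n_pairs": len(df)}


def _logistic_irls(X, y, n_iter=50, ridge=1e-6):
    beta = np.zeros(X.shape[1])
    for _ in range(n_iter):
        p = 1.0 / (1.0 + np.exp(-(X @ beta)))
        W = np.maximum(p * (1 - p), 1e-10)
        H = (X.T * W) @ X + ridge * np.eye(X.shape[1])
        g = X.T @ (y - p) - ridge * beta
        step = np.linalg.solve(H, g)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    return beta


TRIAL_COLUMNS = ["stage1_choice", "transition", "stage2_state",
                 "stage2_choice", "reward", "rt1", "rt2", "missed"]


def trials_to_frame(trials: Sequence[TwoStepTrial]) -> pd.DataFrame:
    return pd.DataFrame([{c: getattr(t, c) for c in TRIAL_COLUMNS}
                         for t in trials])


def frame_to_trials(df: pd.DataFrame) -> list[TwoStepTrial]:
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    out = []
    for r in df.itertuples(index=False):
        out.append(TwoStepTrial(
            stage1_choice=int(r.stage1_choice), transition=str(r.transition),
            stage2_state=int(r.stage2_state), stage2_choice=int(r.stage2_choice),
            reward=int(r.reward), rt1=float(r.rt1), rt2=float(r.rt2),
            missed=bool(r.missed) if not isinstance(r.missed, str)
            else r.missed.lower() in {"true", "1"}))
    return out
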