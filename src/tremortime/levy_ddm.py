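"""Levy-flight drift-diffusion simulator for temporal bisection.

A two-boundary accumulator decides whether a stimulus duration is "long"
(upper boundary) or "short" (lower boundary).  Evidence ``x`` starts at
``z * a`` and evolves by the Euler scheme

    x <- x + v * dt + dt**(1/alpha) * xi,

where ``xi`` is a standard symmetric alpha-stable variate.  ``alpha``
interpolates the momentary noise between Gaussian (alpha = 2) and Cauchy
(alpha -> 1): lower alpha makes the increment distribution narrower in the
bulk but heavy-tailed, so evidence occasionally "jumps" toward a boundary.
The decision time is the first passage out of (0, a); the response time
adds the nondecision time ``t0``.

Standardisation: stable variates are scaled so their characteristic
function is ``exp(-|t|**alpha / 2)``; at alpha = 2 this is exactly a
unit-variance Gaussian, which makes the simulator a standard
unit-diffusion Wiener process with the closed-form absorption probability

    P(upper) = (1 - exp(-2 v z a)) / (1 - exp(-2 v a))

available as an exact oracle (:func:`wiener_p_upper`).

The module also provides the three-level parameter-scaling study: for a
chosen parameter (drift ``v``, threshold ``a`` or stable exponent
``alpha``), three datasets are simulated with the parameter at 1x, 0.75x
and 0.75**2 of its base value, all else held fixed.  The signatures of
interest: lower drift or lower alpha flattens the psychometric curve
(higher CV), lower threshold both flattens it and speeds all responses
uniformly across durations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DDMParams",
    "SimTrial",
    "ConditionResult",
    "sample_stable",
    "simulate_trial",
    "simulate_condition",
    "scaling_study",
    "wiener_p_upper",
    "default_base_params",
]

#: time step of the Euler scheme (s)
DEFAULT_DT = 0.001
#: decision-time cap (s); trials still unabsorbed are flagged censored
MAX_DECISION_TIME = 10.0


@dataclass(frozen=True)
class DDMParams:
    """Five-parameter Levy-flight DDM configuration.

    Parameters
    ----------
    v : float
        Drift rate (evidence/s, signed; positive drives "long").
    a : float
        Boundary separation (> 0).
    z : float
        Relative starting point as a fraction of ``a``, in (0, 1).
    t0 : float
        Nondecision time (s, >= 0).
    alpha : float
        Stable-noise exponent in (1, 2]; 2 is Gaussian diffusion.
    """

    v: float
    a: float
    z: float = 0.5
    t0: float = 0.3
    alpha: float = 2.0

    def __post_init__(self) -> None:
        if not self.a > 0:
            raise ValueError(f"a must be > 0, got {self.a}")
        if not 0 < self.z < 1:
            raise ValueError(f"z must be in (0, 1), got {self.z}")
        if self.t0 < 0:
            raise ValueError(f"t0 must be >= 0, got {self.t0}")
        if not 1 < self.alpha <= 2:
            raise ValueError(f"alpha must be in (1, 2], got {self.alpha}")


@dataclass(frozen=True)
class SimTrial:
    """One simulated bisection trial."""

    choice: str  # "upper" (long) or "lower" (short)
    rt: float  # response time in seconds, > t0
    duration: float = np.nan  # stimulus duration (ms), if applicable
    censored: bool = False


@dataclass
class ConditionResult:
    """Vectorised output of :func:`simulate_condition` with summaries."""

    rt: np.ndarray  # response times (s), includes t0
    upper: np.ndarray  # bool, True = upper boundary ("long")
    censored: np.ndarray  # bool
    params: DDMParams

    @property
    def n(self) -> int:
        return self.rt.size

    @property
    def p_upper(self) -> float:
        """Choice proportion for the upper boundary among decided trials."""
        ok = ~self.censored
        return float(np.mean(self.upper[ok])) if ok.any() else np.nan

    def rt_quantiles(self, probs=(0.1, 0.3, 0.5, 0.7, 0.9)) -> np.ndarray:
        """RT quantiles over decided trials (linear interpolation)."""
        ok = ~self.censored
        if not ok.any():
            return np.full(len(probs), np.nan)
        return np.quantile(self.rt[ok], probs)

    def trials(self) -> list[SimTrial]:
        return [
            SimTrial(choice="upper" if u else "lower", rt=float(r), censored=bool(c))
            for r, u, c in zip(self.rt, self.upper, self.censored)
        ]


def sample_stable(alpha: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` standard symmetric alpha-stable variates (CMS construction).

    Chambers-Mallows-Stuck with skewness 0: with U ~ Uniform(-pi/2, pi/2)
    and W ~ Exp(1),

        X = sin(alpha U) / cos(U)**(1/alpha)
            * (cos((1 - alpha) U) / W)**((1 - alpha)/alpha),

    then scaled by ``2**(-1/alpha)`` so the characteristic function is
    ``exp(-|t|**alpha / 2)`` -- a unit-variance Gaussian at alpha = 2.
    """
    if not 1 < alpha <= 2:
        raise ValueError(f"alpha must be in (1, 2], got {alpha}")
    if n < 1:
        raise ValueError("n must be >= 1")
    return _stable(alpha, (int(n),), rng)


def _cms_transform(u: np.ndarray, w: np.ndarray, alpha: float) -> np.ndarray:
    """CMS map from (U uniform(-pi/2, pi/2), W Exp(1)) to standardised stable.

    Continuous in alpha; at alpha = 2 it yields exactly N(0, 1) after the
    ``2**(-1/alpha)`` standardisation.
    """
    au = alpha * u
    x = (np.sin(au) / np.cos(u) ** (1.0 / alpha)) * (
        np.cos(u - au) / w
    ) ** ((1.0 - alpha) / alpha)
    return 2.0 ** (-1.0 / alpha) * x


def _stable(alpha: float, shape, rng: np.random.Generator) -> np.ndarray:
    """Standardised symmetric stable variates of the given shape (no checks)."""
    if alpha == 2.0:
        return rng.standard_normal(shape)
    u = rng.uniform(-np.pi / 2, np.pi / 2, size=shape)
    w = rng.standard_exponential(size=shape)
    return _cms_transform(u, w, alpha)


try:  # optional acceleration; the numpy fallback implements the same scheme
    from numba import njit as _njit

    @_njit(cache=True)
    def _fpt_kernel(v, a, z, alpha, dt, n, max_steps, seed):  # pragma: no cover
        np.random.seed(seed)
        gaussian = alpha == 2.0
        scale = dt ** (1.0 / alpha)
        drift = v * dt
        inv_alpha = 1.0 / alpha
        stable_scale = 2.0 ** (-inv_alpha)
        half_dt = 0.5 * dt
        t_steps = np.empty(n, np.int64)
        upper = np.zeros(n, np.bool_)
        censored = np.zeros(n, np.bool_)
        for i in range(n):
            x = z * a
            k = 0
            done = False
            while k < max_steps:
                k += 1
                if gaussian:
                    xi = np.random.standard_normal()
                else:
                    u = (np.random.random() - 0.5) * np.pi
                    w = np.random.exponential()
                    au = alpha * u
                    xi = stable_scale * (
                        np.sin(au) / np.cos(u) ** inv_alpha
                    ) * (np.cos(u - au) / w) ** ((1.0 - alpha) * inv_alpha)
                x_new = x + drift + scale * xi
                if x_new >= a:
                    upper[i] = True
                    done = True
                elif x_new <= 0.0:
                    done = True
                elif gaussian:
                    # Brownian-bridge crossing between grid points; the
                    # Exp(1) variate is only drawn when the crossing
                    # probability exceeds ~4e-18 (gap < 40 * dt/2)
                    up_gap = (a - x) * (a - x_new)
                    lo_gap = x * x_new
                    near = 40.0 * half_dt
                    if up_gap < near or lo_gap < near:
                        e = half_dt * np.random.exponential()
                        if up_gap < e:
                            upper[i] = True
                            done = True
                        elif lo_gap < e:
                            done = True
                if done:
                    break
                x = x_new
            t_steps[i] = k
            if not done:
                censored[i] = True
                upper[i] = x > a / 2.0
        return t_steps, upper, censored

    @_njit(cache=True)
    def _replay_kernel(v, a, z, dt, alpha, noise, bridge_e):  # pragma: no cover
        """First passages replaying a fixed noise bank (common random numbers)."""
        n, K = noise.shape
        gaussian = alpha == 2.0
        scale = dt ** (1.0 / alpha)
        drift = v * dt
        half_dt = 0.5 * dt
        t_steps = np.full(n, K, np.int64)
        upper = np.zeros(n, np.bool_)
        absorbed = np.zeros(n, np.bool_)
        for i in range(n):
            x = z * a
            for k in range(K):
                x_new = x + drift + scale * noise[i, k]
                if x_new >= a:
                    upper[i] = True
                elif x_new <= 0.0:
                    pass
                elif gaussian:
                    e = half_dt * bridge_e[i, k]
                    if (a - x) * (a - x_new) < e:
                        upper[i] = True
                    elif x * x_new >= e:
                        x = x_new
                        continue
                else:
                    x = x_new
                    continue
                absorbed[i] = True
                t_steps[i] = k + 1
                break
        return t_steps, upper, absorbed

except ImportError:  # pragma: no cover
    _fpt_kernel = None

    def _replay_kernel(v, a, z, dt, alpha, noise, bridge_e):
        """Numpy fallback of the noise-bank replay (blocked columns)."""
        n, K = noise.shape
        gaussian = alpha == 2.0
        scale = dt ** (1.0 / alpha)
        drift = v * dt
        t_steps = np.full(n, K, dtype=np.int64)
        upper = np.zeros(n, dtype=bool)
        absorbed = np.zeros(n, dtype=bool)
        alive_idx = np.arange(n)
        x = np.full(n, z * a, dtype=float)
        block = 128
        for start in range(0, K, block):
            if alive_idx.size == 0:
                break
            stop = min(start + block, K)
            incr = drift + scale * noise[alive_idx, start:stop]
            paths = x[alive_idx, None] + np.cumsum(incr, axis=1)
            hit_up = paths >= a
            hit_lo = paths <= 0.0
            if gaussian:
                prev = np.concatenate([x[alive_idx, None], paths[:, :-1]], axis=1)
                thr = 0.5 * dt * bridge_e[alive_idx, start:stop]
                b_up = np.maximum(a - prev, 0) * np.maximum(a - paths, 0) < thr
                b_lo = np.maximum(prev, 0) * np.maximum(paths, 0) < thr
                hit_up |= b_up
                hit_lo |= b_lo & ~b_up
            hit = hit_up | hit_lo
            any_hit = hit.any(axis=1)
            rows = np.flatnonzero(any_hit)
            first = np.argmax(hit[rows], axis=1)
            idx = alive_idx[rows]
            t_steps[idx] = start + first + 1
            upper[idx] = hit_up[rows, first]
            absorbed[idx] = True
            keep = ~any_hit
            x[alive_idx[keep]] = paths[keep, -1]
            alive_idx = alive_idx[keep]
        return t_steps, upper, absorbed


def wiener_p_upper(v: float, a: float, z: float) -> float:
    """Closed-form upper-boundary absorption probability of a Wiener process.

    Unit diffusion, start ``z*a``: ``(1 - exp(-2 v z a)) / (1 - exp(-2 v a))``;
    equals ``z`` when v = 0.
    """
    if abs(v) < 1e-12:
        return float(z)
    za = z * a
    return float(np.expm1(-2.0 * v * za) / np.expm1(-2.0 * v * a))


def _first_passage(
    v: float,
    a: float,
    z: float,
    alpha: float,
    n: int,
    rng: np.random.Generator,
    dt: float = DEFAULT_DT,
    max_time: float = MAX_DECISION_TIME,
    block: int = 256,
):
    """Simulate ``n`` first passages out of (0, a) starting at ``z*a``.

    Dispatches to a numba kernel when available (identical scheme, much
    faster per-trial loop); otherwise the vectorised numpy path below.
    Both are deterministic given the caller's generator: the kernel is
    seeded from one draw of ``rng``.
    """
    if _fpt_kernel is not None:
        seed = int(rng.integers(0, 2**31 - 1))
        max_steps = int(round(max_time / dt))
        t_steps, up, cens = _fpt_kernel(
            float(v), float(a), float(z), float(alpha), float(dt), int(n),
            max_steps, seed,
        )
        return t_steps * dt, up, cens
    return _first_passage_numpy(
        v, a, z, alpha, n, rng, dt=dt, max_time=max_time, block=block
    )


def _first_passage_numpy(
    v: float,
    a: float,
    z: float,
    alpha: float,
    n: int,
    rng: np.random.Generator,
    dt: float = DEFAULT_DT,
    max_time: float = MAX_DECISION_TIME,
    block: int = 256,
):
    """Vectorised numpy first-passage simulation (fallback path).

    Returns ``(decision_time, upper, censored)`` arrays.  Noise is drawn in
    blocks of ``block`` steps for the still-alive trials only; all alive
    trials share the same elapsed step count, so block-wise cumulative sums
    give exact Euler paths.

    For alpha = 2 the Gaussian increments are exact Wiener increments and a
    Brownian-bridge correction accounts for boundary crossings *between*
    grid points (excursion probability ``exp(-2 (a-x_k)(a-x_{k+1}) / dt)``
    per step and boundary), which removes the O(sqrt(dt)) absorption bias
    of naive discrete monitoring and makes the closed-form Wiener oracle
    hold at any dt.  For alpha < 2 no bridge law is available in closed
    form and crossings are detected at grid points only.
    """
    max_steps = int(round(max_time / dt))
    scale = dt ** (1.0 / alpha)
    drift = v * dt

    dec_steps = np.zeros(n, dtype=np.int64)
    upper = np.zeros(n, dtype=bool)
    censored = np.zeros(n, dtype=bool)

    alive_idx = np.arange(n)
    x = np.full(n, z * a, dtype=float)[alive_idx]
    elapsed = 0
    while alive_idx.size and elapsed < max_steps:
        b = min(block, max_steps - elapsed)
        incr = drift + scale * _stable(alpha, (alive_idx.size, b), rng)
        paths = x[:, None] + np.cumsum(incr, axis=1)
        hit_up = paths >= a
        hit_lo = paths <= 0.0
        if alpha == 2.0:
            # Brownian-bridge crossing test via one exponential variate per
            # step: u < exp(-2*gap/dt)  <=>  gap < (dt/2) * Exp(1).
            prev = np.concatenate([x[:, None], paths[:, :-1]], axis=1)
            thresh = (0.5 * dt) * rng.standard_exponential(paths.shape)
            bridge_up = np.maximum(a - prev, 0.0) * np.maximum(a - paths, 0.0) < thresh
            bridge_lo = np.maximum(prev, 0.0) * np.maximum(paths, 0.0) < thresh
            hit_up = hit_up | bridge_up
            hit_lo = hit_lo | (bridge_lo & ~bridge_up)
        hit = hit_up | hit_lo
        any_hit = hit.any(axis=1)
        if any_hit.any():
            rows = np.flatnonzero(any_hit)
            first = np.argmax(hit[rows], axis=1)
            idx = alive_idx[rows]
            dec_steps[idx] = elapsed + first + 1
            upper[idx] = hit_up[rows, first]
        keep = ~any_hit
        alive_idx = alive_idx[keep]
        x = paths[keep, -1]
        elapsed += b
    if alive_idx.size:
        censored[alive_idx] = True
        dec_steps[alive_idx] = max_steps
        upper[alive_idx] = x > a / 2.0  # best guess for censored trials

    return dec_steps * dt, upper, censored


def simulate_trial(
    params: DDMParams,
    dt: float = DEFAULT_DT,
    rng: np.random.Generator | None = None,
    max_time: float = MAX_DECISION_TIME,
) -> SimTrial:
    """Simulate one trial; ``rt = t0 + decision time``; censoring flagged."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    rng = np.random.default_rng() if rng is None else rng
    t, up, cens = _first_passage(
        params.v, params.a, params.z, params.alpha, 1, rng, dt=dt, max_time=max_time
    )
    return SimTrial(
        choice="upper" if up[0] else "lower",
        rt=float(params.t0 + t[0]),
        censored=bool(cens[0]),
    )


def simulate_condition(
    params: DDMParams,
    n: int,
    rng: np.random.Generator,
    dt: float = DEFAULT_DT,
    max_time: float = MAX_DECISION_TIME,
) -> ConditionResult:
    """Simulate ``n`` i.i.d. trials of one condition (vectorised)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    t, up, cens = _first_passage(
        params.v, params.a, params.z, params.alpha, n, rng, dt=dt, max_time=max_time
    )
    n_cens = int(cens.sum())
    if n_cens:
        warnings.warn(f"{n_cens}/{n} trials censored at {max_time} s", stacklevel=2)
    return ConditionResult(rt=params.t0 + t, upper=up, censored=cens, params=params)


# --------------------------------------------------------------------------
# per-duration parameter tables and the three-level scaling study

#: the seven log-spaced stimulus durations (ms), 1-4 s about a 2 s midpoint
DURATIONS_MS = (1000, 1260, 1580, 2000, 2520, 3170, 4000)


def default_base_params(
    durations_ms: Sequence[float] = DURATIONS_MS,
    v_max: float = 3.0,
    a: float = 1.6,
    z: float = 0.5,
    t0: float = 0.3,
    alpha: float = 2.0,
    midpoint_ms: float = 2000.0,
) -> dict[float, DDMParams]:
    """Per-duration parameter table with drift antisymmetric in log duration.

    ``v(d) = v_max * log2(d / midpoint)``: negative (toward "short") below
    the geometric-mean duration, positive above, +-v_max at the extremes of
    a 1-4 s range.  The remaining parameters are shared across durations.
    """
    out = {}
    for d in durations_ms:
        v = v_max * np.log2(d / midpoint_ms)
        out[float(d)] = DDMParams(v=float(v), a=a, z=z, t0=t0, alpha=alpha)
    return out


_SCALE_FACTOR = 0.75
_ALPHA_FLOOR = 1.01


def _scaled(params: DDMParams, target: str, factor: float) -> DDMParams:
    if target == "v":
        return replace(params, v=params.v * factor)
    if target == "a":
        return replace(params, a=params.a * factor)
    if target == "alpha":
        new_alpha = params.alpha * factor
        if new_alpha <= 1.0:
            warnings.warn(
                f"alpha scaling left (1, 2]; clipping {new_alpha:.3f} -> {_ALPHA_FLOOR}",
                stacklevel=2,
            )
            new_alpha = _ALPHA_FLOOR
        return replace(params, alpha=new_alpha)
    raise ValueError(f"target must be one of 'v', 'a', 'alpha'; got {target!r}")


def scaling_study(
    base: Mapping[float, DDMParams],
    target: str,
    n_per_level: int,
    rng: np.random.Generator,
    n_levels: int = 3,
    dt: float = DEFAULT_DT,
) -> pd.DataFrame:
    """Simulate three datasets with ``target`` at 1x, 0.75x, 0.75**2 x base.

    Returns a long-format summary with one row per (level, duration):
    choice proportion, mean RT and RT quantiles of the simulated trials,
    plus the scaled parameter values.  Level 1 is the base model; each
    subsequent level multiplies the target parameter by 0.75 (alpha is
    clipped just above 1 if the cascade would leave the valid range).
    """
    rows = []
    for level in range(1, n_levels + 1):
        factor = _SCALE_FACTOR ** (level - 1)
        for d, p0 in base.items():
            p = _scaled(p0, target, factor)
            res = simulate_condition(p, n_per_level, rng, dt=dt)
            ok = ~res.censored
            q = res.rt_quantiles()
            rows.append(
                {
                    "level": level,
                    "target": target,
                    "duration_ms": d,
                    "v": p.v,
                    "a": p.a,
                    "z": p.z,
                    "t0": p.t0,
                    "alpha": p.alpha,
                    "n": res.n,
                    "n_censored": int(res.censored.sum()),
                    "p_long": res.p_upper,
                    "rt_mean": float(np.mean(res.rt[ok])) if ok.any() else np.nan,
                    "rt_q10": q[0],
                    "rt_q50": q[2],
                    "rt_q90": q[4],
                }
            )
    return pd.DataFrame(rows)


def scaling_study_cv(summary: pd.DataFrame) -> pd.DataFrame:
    """Psychometric BP/CV per scaling level from a :func:`scaling_study` table.

    Fits the cumulative-Gumbel psychometric function to each level's
    aggregated choice proportions and returns one row per level with bp_ms
    and cv.
    """
    from . import psychometrics  # local import: psychometrics is independent

    rows = []
    for level, g in summary.groupby("level"):
        n_long = np.round(g["p_long"].to_numpy() * g["n"].to_numpy()).astype(int)
        fit = psychometrics.fit_psychometric_counts(
            g["duration_ms"].to_numpy(), n_long, g["n"].to_numpy(dtype=int)
        )
        rows.append(
            {
                "level": level,
                "target": g["target"].iloc[0],
                "bp_ms": fit.bp_ms,
                "cv": fit.cv,
                "rt_mean": float(
                    np.average(g["rt_mean"], weights=g["n"])
                ),
            }
        )
    return pd.DataFrame(rows)


def to_trial_table(
    result: ConditionResult,
    duration_ms: float,
    subject: str = "sim",
    amplitude_N: int = 1,
    frequency_Hz: int = 4,
) -> pd.DataFrame:
    """Convert a simulated condition to the pipeline's trial-table schema."""
    return pd.DataFrame(
        {
            "subject": subject,
            "modality": "sim",
            "amplitude_N": amplitude_N,
            "frequency_Hz": frequency_Hz,
            "direction_deg": 0.0,
            "duration_ms": duration_ms,
            "choice": np.where(result.upper, "long", "short"),
            "rt_ms": result.rt * 1000.0,
            "censored": result.censored,
        }
    )
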