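"""Synthetic tremor-bisection experiments with planted effects.

No behavioural data accompany the study design this package analyses, so
every pipeline stage is exercised on synthetic experiments that carry the
assumed statistical structure:

* the two-session design -- 7 log-spaced durations (1,000-4,000 ms) x 3
  tremor amplitudes (1, 2, 3 N) x 3 tremor frequencies (4, 8, 12 Hz) x 6
  repetitions = 378 trials per subject, tremor direction uniform on
  [0, 180) degrees, 24 subjects per modality;
* a cue-combination observer: each condition's duration-estimate width is
  the fusion of a fixed sensory width (auditory narrower than visual) with
  a motor width that grows with tremor frequency, gated by amplitude (for
  the visual-style observer the frequency effect is only fully expressed
  at the highest amplitude);
* choices and RTs from the Levy DDM: the trial drift rate is the scaled
  log-distance of the duration from the true bisection point divided by
  the condition's combined width, so wider combined estimates produce
  shallower psychometric curves (higher CV) with the bisection point
  pinned at 2,000 ms (noise degrades precision, never accuracy).

Subject heterogeneity enters as log-normal multipliers on the widths and
the nondecision time.  Everything is deterministic under the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from . import cue_combination
from .levy_ddm import _first_passage

__all__ = [
    "DesignConfig",
    "ObserverConfig",
    "generate_design",
    "condition_sigma",
    "generate_dataset",
    "generate_experiment",
]

DURATIONS_MS = (1000, 1260, 1580, 2000, 2520, 3170, 4000)


@dataclass(frozen=True)
class DesignConfig:
    """The crossed session design; defaults reproduce one 378-trial session."""

    durations_ms: tuple = DURATIONS_MS
    amplitudes_N: tuple = (1, 2, 3)
    frequencies_Hz: tuple = (4, 8, 12)
    reps_per_cell: int = 6
    n_subjects: int = 24
    seed: int = 0

    def __post_init__(self):
        if len(self.durations_ms) != 7:
            raise ValueError("design uses 7 stimulus durations")
        if self.reps_per_cell < 1:
            raise ValueError("reps_per_cell must be >= 1")

    @property
    def trials_per_session(self) -> int:
        return (
            len(self.durations_ms)
            * len(self.amplitudes_N)
            * len(self.frequencies_Hz)
            * self.reps_per_cell
        )


@dataclass(frozen=True)
class ObserverConfig:
    """Generative observer: cue-combination widths -> DDM drift.

    ``sigma_sensory`` holds the base sensory width per modality (log-duration
    units; auditory < visual).  The motor width in a condition is

        sigma_M = sigma_motor_base * (1 + (freq_gain[f] - 1) * amp_gate[modality][A]),

    non-decreasing in frequency; ``amp_gate`` of 1 expresses the frequency
    effect fully (auditory default at every amplitude), while the visual
    default gates it so the effect is only full at 3 N.  The combined width
    ``sigma_c = combine(sigma_S, sigma_M)`` sets the trial drift

        v = drift_gain * ln(duration / bp_true) / sigma_c,

    so the psychometric slope (and hence CV) tracks the combined width
    while the bisection point stays at ``bp_true_ms``.  Subject-level
    log-normal multipliers (SDs ``subject_sd_sigma``, ``subject_sd_t0``)
    provide between-subject heterogeneity.
    """

    sigma_sensory: Mapping[str, float] = field(
        default_factory=lambda: {"auditory": 0.17, "visual": 0.32}
    )
    sigma_motor_base: float = 0.17
    freq_gain: Mapping[int, float] = field(
        default_factory=lambda: {4: 1.0, 8: 2.1, 12: 3.6}
    )
    amp_gate: Mapping[str, Mapping[int, float]] = field(
        default_factory=lambda: {
            "auditory": {1: 1.0, 2: 1.0, 3: 1.0},
            "visual": {1: 0.0, 2: 0.2, 3: 1.0},
        }
    )
    drift_gain: float = 0.52  # calibrated so baseline auditory CV ~ 0.17
    bp_true_ms: float = 2000.0
    a: float = 1.5
    z: float = 0.5
    t0: float = 0.3
    alpha: float = 2.0
    subject_sd_sigma: float = 0.12
    subject_sd_t0: float = 0.10

    def __post_init__(self):
        gains = [self.freq_gain[f] for f in sorted(self.freq_gain)]
        if any(np.diff(gains) < 0):
            raise ValueError("freq_gain must be non-decreasing in frequency")
        if self.sigma_motor_base <= 0 or any(
            s <= 0 for s in self.sigma_sensory.values()
        ):
            raise ValueError("widths must be > 0")


def null_observer(**overrides) -> ObserverConfig:
    """Observer with no planted frequency or amplitude effect (freq_gain = 1)."""
    defaults = dict(freq_gain={4: 1.0, 8: 1.0, 12: 1.0})
    defaults.update(overrides)
    return ObserverConfig(**defaults)


def generate_design(
    config: DesignConfig, modality: str = "auditory", rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Trial skeleton (no responses): fully crossed design, shuffled per subject.

    Tremor direction is drawn uniformly on [0, 180) per trial.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    rows = []
    for s in range(config.n_subjects):
        subj = f"{modality[:3]}{s + 1:02d}"
        cells = [
            (d, a, f)
            for d in config.durations_ms
            for a in config.amplitudes_N
            for f in config.frequencies_Hz
            for _ in range(config.reps_per_cell)
        ]
        order = rng.permutation(len(cells))
        for trial_i, k in enumerate(order):
            d, a, f = cells[k]
            rows.append(
                {
                    "subject": subj,
                    "modality": modality,
                    "trial": trial_i + 1,
                    "amplitude_N": a,
                    "frequency_Hz": f,
                    "direction_deg": rng.uniform(0.0, 180.0),
                    "duration_ms": d,
                }
            )
    return pd.DataFrame(rows)


def condition_sigma(
    observer: ObserverConfig,
    modality: str,
    amplitude: int,
    frequency: int,
    sensory_mult: float = 1.0,
    motor_mult: float = 1.0,
) -> float:
    """Combined sensorimotor width for one condition of one observer."""
    sigma_s = observer.sigma_sensory[modality] * sensory_mult
    gate = observer.amp_gate[modality][amplitude]
    gain = 1.0 + (observer.freq_gain[frequency] - 1.0) * gate
    sigma_m = observer.sigma_motor_base * motor_mult * gain
    return cue_combination.combined_sigma(sigma_s, sigma_m)


def generate_dataset(
    design: DesignConfig,
    observer: ObserverConfig,
    modality: str = "auditory",
    rng: np.random.Generator | None = None,
    dt: float = 0.001,
    kinematic_columns: bool = False,
) -> pd.DataFrame:
    """Full synthetic experiment: design skeleton plus DDM choices and RTs.

    Returns the canonical trial table (subject, modality, amplitude_N,
    frequency_Hz, direction_deg, duration_ms, choice, rt_ms).  Optional
    ``kinematic_columns`` adds placeholder movement length/force columns
    with no planted structure.
    """
    rng = np.random.default_rng(design.seed) if rng is None else rng
    trials = generate_design(design, modality=modality, rng=rng)

    subjects = trials["subject"].unique()
    sens_mult = dict(
        zip(subjects, np.exp(rng.normal(0, observer.subject_sd_sigma, len(subjects))))
    )
    mot_mult = dict(
        zip(subjects, np.exp(rng.normal(0, observer.subject_sd_sigma, len(subjects))))
    )
    t0_subj = dict(
        zip(
            subjects,
            observer.t0 * np.exp(rng.normal(0, observer.subject_sd_t0, len(subjects))),
        )
    )

    choice = np.empty(len(trials), dtype=object)
    rt_ms = np.empty(len(trials), dtype=float)
    log_bp = np.log(observer.bp_true_ms)
    for (subj, amp, freq, dur), grp in trials.groupby(
        ["subject", "amplitude_N", "frequency_Hz", "duration_ms"]
    ):
        sigma_c = condition_sigma(
            observer, modality, amp, freq, sens_mult[subj], mot_mult[subj]
        )
        v = observer.drift_gain * (np.log(dur) - log_bp) / sigma_c
        t, up, _ = _first_passage(
            v, observer.a, observer.z, observer.alpha, len(grp), rng, dt=dt
        )
        idx = trials.index.get_indexer(grp.index)
        choice[idx] = np.where(up, "long", "short")
        rt_ms[idx] = (t0_subj[subj] + t) * 1000.0
    trials = trials.assign(choice=choice, rt_ms=rt_ms)
    if kinematic_columns:
        n = len(trials)
        trials["move_length_cm"] = np.exp(rng.normal(np.log(30.0), 0.3, n))
        trials["move_force_N"] = np.exp(rng.normal(np.log(5.0), 0.3, n))
    return trials


def generate_experiment(
    modality: str,
    seed: int,
    design: DesignConfig | None = None,
    observer: ObserverConfig | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Convenience wrapper: one full experiment for a modality at a seed."""
    design = DesignConfig(seed=seed) if design is None else design
    observer = ObserverConfig() if observer is None else observer
    rng = np.random.default_rng(seed)
    return generate_dataset(design, observer, modality=modality, rng=rng, **kwargs)


def observer_sidecar(design: DesignConfig, observer: ObserverConfig) -> dict:
    """All generating parameters as a plain dict (YAML sidecar contents)."""

    def plain(obj):
        d = asdict(obj)
        return {
            k: ({kk: vv for kk, vv in v.items()} if isinstance(v, Mapping) else v)
            for k, v in d.items()
        }

    return {"design": plain(design), "observer": plain(observer)}
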